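# 55-segment systemic arterial tree (175 cm reference subject).
# Geometry defined at the nominal distending pressure P0 = 97 mmHg.
# Columns: id,name,parent,length_cm,r_in_cm,r_out_cm,RT,CT
# Units: lengths/radii cm; RT mmHg s/ml (nominal terminal resistance);
# CT ml/mmHg (nominal terminal compliance). RT/CT on terminal rows only.
id,name,parent,length_cm,r_in_cm,r_out_cm,RT,CT
1,ascending aorta,,4.0,1.47,1.44,,
2,aortic arch I,1,2.0,1.12,1.12,,
3,brachiocephalic,1,3.4,0.62,0.62,,
4,R subclavian I,3,3.4,0.423,0.423,,
5,R common carotid,3,17.7,0.37,0.37,,
6,R vertebral,4,14.8,0.188,0.183,19.0328,0.004926
7,R subclavian II,4,42.2,0.403,0.236,,
8,R radial,7,23.5,0.174,0.142,37.7522,0.002483
9,R ulnar I,7,6.7,0.215,0.215,,
10,R interosseous,9,7.9,0.091,0.091,125.5189,0.000747
11,R ulnar II,9,17.1,0.203,0.183,19.0328,0.004926
12,R internal carotid,5,17.6,0.177,0.083,160.9201,0.000583
13,R external carotid,5,17.7,0.177,0.083,160.9201,0.000583
14,aortic arch II,2,3.9,1.07,1.07,,
15,L common carotid,2,20.8,0.37,0.37,,
16,L internal carotid,15,17.6,0.177,0.083,160.9201,0.000583
17,L external carotid,15,17.7,0.177,0.083,160.9201,0.000583
18,L subclavian I,14,3.4,0.423,0.423,,
19,L vertebral,18,14.8,0.188,0.183,19.0328,0.004926
20,L subclavian II,18,42.2,0.403,0.236,,
21,L radial,20,23.5,0.174,0.142,37.7522,0.002483
22,L ulnar I,20,6.7,0.215,0.215,,
23,L interosseous,22,7.9,0.091,0.091,125.5189,0.000747
24,L ulnar II,22,17.1,0.203,0.183,19.0328,0.004926
25,intercostals,26,8.0,0.2,0.15,32.5593,0.002879
26,thoracic aorta I,14,5.2,1.0,0.95,,
27,thoracic aorta II,26,10.4,0.95,0.645,,
28,abdominal aorta I,27,5.3,0.61,0.6,,
29,celiac I,27,1.0,0.39,0.39,,
30,celiac II,29,1.0,0.2,0.2,,
31,hepatic,29,6.6,0.22,0.22,11.5766,0.008098
32,gastric,30,7.1,0.18,0.18,19.9015,0.004711
33,splenic,30,6.3,0.275,0.275,6.3376,0.014793
34,superior mesenteric,28,5.9,0.435,0.435,1.8374,0.051024
35,abdominal aorta II,28,1.0,0.6,0.6,,
36,L renal,35,3.2,0.26,0.26,7.3738,0.012714
37,abdominal aorta III,35,1.0,0.59,0.59,,
38,R renal,37,3.2,0.26,0.26,7.3738,0.012714
39,abdominal aorta IV,37,10.6,0.58,0.548,,
40,inferior mesenteric,39,5.0,0.16,0.16,27.3525,0.003427
41,abdominal aorta V,39,1.0,0.52,0.52,,
42,R common iliac,41,5.8,0.368,0.368,,
43,L common iliac,41,5.8,0.368,0.368,,
44,L external iliac,43,14.4,0.32,0.27,,
45,L internal iliac,43,5.0,0.2,0.2,14.9741,0.006261
46,L femoral,44,44.3,0.259,0.19,,
47,L deep femoral,44,12.6,0.255,0.186,18.2153,0.005147
48,L posterior tibial,46,32.1,0.247,0.141,38.4795,0.002436
49,L anterior tibial,46,34.3,0.13,0.13,47.9153,0.001957
50,R external iliac,42,14.4,0.32,0.27,,
51,R internal iliac,42,5.0,0.2,0.2,14.9741,0.006261
52,R femoral,50,44.3,0.259,0.19,,
53,R deep femoral,50,12.6,0.255,0.186,18.2153,0.005147
54,R posterior tibial,52,32.1,0.247,0.141,38.4795,0.002436
55,R anterior tibial,52,34.3,0.13,0.13,47.9153,0.001957
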