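# 7-segment reduced systemic arterial tree (175 cm reference subject).
# Geometry defined at the nominal distending pressure P0 = 97 mmHg.
# Columns: id,name,parent,length_cm,r_in_cm,r_out_cm,RT,CT
# Units: lengths/radii cm; RT mmHg s/ml (nominal terminal resistance);
# CT ml/mmHg (nominal terminal compliance). RT/CT on terminal rows only.
id,name,parent,length_cm,r_in_cm,r_out_cm,RT,CT
1,aorta,,15.0,1.40,1.10,,
2,arm artery,1,45.0,0.42,0.24,,
3,trunk aorta,1,45.0,1.05,0.55,,
4,radial artery,2,24.0,0.17,0.14,6.5,0.015
5,ulnar artery,2,24.0,0.21,0.18,5.5,0.017
6,visceral bed,3,8.0,0.45,0.40,1.1,0.085
7,leg artery,3,60.0,0.37,0.18,1.7,0.055
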