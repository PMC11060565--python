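# Fixed model constants (overridable): arterial wall law, blood properties,
# and elastance-ventricle parameters.  Units as noted; these are the values
# used when no config file is supplied.
wall:
  k1: 2.0e+7       # dyn/cm^2 (before the 4/3 factor)
  k2: -22.53       # 1/cm
  k3: 8.65e+5      # dyn/cm^2
  P0_mmHg: 97.0    # nominal distending pressure defining tree radii
  rho: 1.06        # g/cm^3
  mu: 0.049        # g/(cm s)
heart:
  T: 0.8           # s, heart period (overridden per subject)
  E_max: 2.6       # mmHg/ml (estimated per subject)
  E_min: 0.06      # mmHg/ml
  t_m: 0.55        # s (estimated per subject)
  a: 0.9           # activation shape
  b: 0.25          # activation shape
  V0: 15.0         # ml at zero transmural pressure (scaled by S^3)
  V_max: 120.0     # ml mitral-closure volume (scaled by S^3)
  P_la: 8.0        # mmHg constant left-atrial pressure
  R_la: 0.01       # mmHg s/ml mitral resistance
  L_la: 5.0e-4     # mmHg s^2/ml mitral inertance
  R_lv: 0.006      # mmHg s/ml aortic-valve resistance
  L_lv: 5.0e-4     # mmHg s^2/ml aortic-valve inertance
  Vb_bar: 1.5      # ml allowed aortic backflow before full closure
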