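{
 "description": "White Monte Carlo reference reflectance, semi-infinite medium, rho=20mm, n=1.4, isotropic scattering",
 "n_photons": 20000000,
 "seed": 20260926,
 "elapsed_s": 2490.2,
 "engine": {
  "r_min": 3.0,
  "r_max": 70.0,
  "l_max": 5000.0,
  "r_kill": 150.0
 },
 "records": [
  {
   "mua": 0.001,
   "musp": 0.3,
   "frequency_mhz": 0.0,
   "amplitude": 9.439397404794395e-05,
   "phase": -0.0
  },
  {
   "mua": 0.001,
   "musp": 0.5097132734541368,
   "frequency_mhz": 0.0,
   "amplitude": 7.217612989136049e-05,
   "phase": -0.0
  },
  {
   "mua": 0.001,
   "musp": 0.8660254037844386,
   "frequency_mhz": 0.0,
   "amplitude": 4.455947370073988e-05,
   "phase": -0.0
  },
  {
   "mua": 0.001,
   "musp": 1.4714154781913558,
   "frequency_mhz": 0.0,
   "amplitude": 2.364667309355308e-05,
   "phase": -0.0
  },
  {
   "mua": 0.001,
   "musp": 2.5,
   "frequency_mhz": 0.0,
   "amplitude": 1.1056391317938699e-05,
   "phase": -0.0
  },
  {
   "mua": 0.002783157683713741,
   "musp": 0.3,
   "frequency_mhz": 0.0,
   "amplitude": 7.453057303762299e-05,
   "phase": -0.0
  },
  {
   "mua": 0.002783157683713741,
   "musp": 0.5097132734541368,
   "frequency_mhz": 0.0,
   "amplitude": 5.348873265632046e-05,
   "phase": -0.0
  },
  {
   "mua": 0.002783157683713741,
   "musp": 0.8660254037844386,
   "frequency_mhz": 0.0,
   "amplitude": 2.962433140001821e-05,
   "phase": -0.0
  },
  {
   "mua": 0.002783157683713741,
   "musp": 1.4714154781913558,
   "frequency_mhz": 0.0,
   "amplitude": 1.3336747372750619e-05,
   "phase": -0.0
  },
  {
   "mua": 0.002783157683713741,
   "musp": 2.5,
   "frequency_mhz": 0.0,
   "amplitude": 4.990884305408462e-06,
   "phase": -0.0
  },
  {
   "mua": 0.0077459666924148355,
   "musp": 0.3,
   "frequency_mhz": 0.0,
   "amplitude": 4.5229148540182125e-05,
   "phase": -0.0
  },
  {
   "mua": 0.0077459666924148355,
   "musp": 0.5097132734541368,
   "frequency_mhz": 0.0,
   "amplitude": 2.881052466719902e-05,
   "phase": -0.0
  },
  {
   "mua": 0.0077459666924148355,
   "musp": 0.8660254037844386,
   "frequency_mhz": 0.0,
   "amplitude": 1.30462133698451e-05,
   "phase": -0.0
  },
  {
   "mua": 0.0077459666924148355,
   "musp": 1.4714154781913558,
   "frequency_mhz": 0.0,
   "amplitude": 4.360040480616699e-06,
   "phase": -0.0
  },
  {
   "mua": 0.0077459666924148355,
   "musp": 2.5,
   "frequency_mhz": 0.0,
   "amplitude": 1.075538471314846e-06,
   "phase": -0.0
  },
  {
   "mua": 0.02155824671778505,
   "musp": 0.3,
   "frequency_mhz": 0.0,
   "amplitude": 1.6544885427938152e-05,
   "phase": -0.0
  },
  {
   "mua": 0.02155824671778505,
   "musp": 0.5097132734541368,
   "frequency_mhz": 0.0,
   "amplitude": 8.554219980445387e-06,
   "phase": -0.0
  },
  {
   "mua": 0.02155824671778505,
   "musp": 0.8660254037844386,
   "frequency_mhz": 0.0,
   "amplitude": 2.726832318009843e-06,
   "phase": -0.0
  },
  {
   "mua": 0.02155824671778505,
   "musp": 1.4714154781913558,
   "frequency_mhz": 0.0,
   "amplitude": 5.458786006755853e-07,
   "phase": -0.0
  },
  {
   "mua": 0.02155824671778505,
   "musp": 2.5,
   "frequency_mhz": 0.0,
   "amplitude": 6.576343745447575e-08,
   "phase": -0.0
  },
  {
   "mua": 0.06,
   "musp": 0.3,
   "frequency_mhz": 0.0,
   "amplitude": 2.2983064616020584e-06,
   "phase": -0.0
  },
  {
   "mua": 0.06,
   "musp": 0.5097132734541368,
   "frequency_mhz": 0.0,
   "amplitude": 8.483537197634447e-07,
   "phase": -0.0
  },
  {
   "mua": 0.06,
   "musp": 0.8660254037844386,
   "frequency_mhz": 0.0,
   "amplitude": 1.512893975711331e-07,
   "phase": -0.0
  },
  {
   "mua": 0.06,
   "musp": 1.4714154781913558,
   "frequency_mhz": 0.0,
   "amplitude": 1.3109926484603855e-08,
   "phase": -0.0
  },
  {
   "mua": 0.06,
   "musp": 2.5,
   "frequency_mhz": 0.0,
   "amplitude": 4.531355707778258e-10,
   "phase": -0.0
  },
  {
   "mua": 0.001,
   "musp": 0.3,
   "frequency_mhz": 126.0,
   "amplitude": 8.42908635060011e-05,
   "phase": 0.47572631496085743
  },
  {
   "mua": 0.001,
   "musp": 0.5097132734541368,
   "frequency_mhz": 126.0,
   "amplitude": 6.18015727807338e-05,
   "phase": 0.5989090286879675
  },
  {
   "mua": 0.001,
   "musp": 0.8660254037844386,
   "frequency_mhz": 126.0,
   "amplitude": 3.54312432382056e-05,
   "phase": 0.8073649457131569
  },
  {
   "mua": 0.001,
   "musp": 1.4714154781913558,
   "frequency_mhz": 126.0,
   "amplitude": 1.668970511446174e-05,
   "phase": 1.119874992978548
  },
  {
   "mua": 0.001,
   "musp": 2.5,
   "frequency_mhz": 126.0,
   "amplitude": 6.5563677688034256e-06,
   "phase": 1.555298968611332
  },
  {
   "mua": 0.002783157683713741,
   "musp": 0.3,
   "frequency_mhz": 126.0,
   "amplitude": 6.999972102272368e-05,
   "phase": 0.4138389800277668
  },
  {
   "mua": 0.002783157683713741,
   "musp": 0.5097132734541368,
   "frequency_mhz": 126.0,
   "amplitude": 4.914968076598019e-05,
   "phase": 0.5160089054376733
  },
  {
   "mua": 0.002783157683713741,
   "musp": 0.8660254037844386,
   "frequency_mhz": 126.0,
   "amplitude": 2.620880315693315e-05,
   "phase": 0.6885863375997315
  },
  {
   "mua": 0.002783157683713741,
   "musp": 1.4714154781913558,
   "frequency_mhz": 126.0,
   "amplitude": 1.1113827120815107e-05,
   "phase": 0.9446236694392942
  },
  {
   "mua": 0.002783157683713741,
   "musp": 2.5,
   "frequency_mhz": 126.0,
   "amplitude": 3.810319565631514e-06,
   "phase": 1.3030571170246859
  },
  {
   "mua": 0.0077459666924148355,
   "musp": 0.3,
   "frequency_mhz": 126.0,
   "amplitude": 4.417849417341878e-05,
   "phase": 0.3216095895863158
  },
  {
   "mua": 0.0077459666924148355,
   "musp": 0.5097132734541368,
   "frequency_mhz": 126.0,
   "amplitude": 2.793123379102964e-05,
   "phase": 0.39358736754821433
  },
  {
   "mua": 0.0077459666924148355,
   "musp": 0.8660254037844386,
   "frequency_mhz": 126.0,
   "amplitude": 1.2488009797478441e-05,
   "phase": 0.5146131826755853
  },
  {
   "mua": 0.0077459666924148355,
   "musp": 1.4714154781913558,
   "frequency_mhz": 126.0,
   "amplitude": 4.094357012373201e-06,
   "phase": 0.6918492862946348
  },
  {
   "mua": 0.0077459666924148355,
   "musp": 2.5,
   "frequency_mhz": 126.0,
   "amplitude": 9.83291171507632e-07,
   "phase": 0.9384564673083586
  },
  {
   "mua": 0.02155824671778505,
   "musp": 0.3,
   "frequency_mhz": 126.0,
   "amplitude": 1.6433012679175682e-05,
   "phase": 0.23157571710089264
  },
  {
   "mua": 0.02155824671778505,
   "musp": 0.5097132734541368,
   "frequency_mhz": 126.0,
   "amplitude": 8.47941738449044e-06,
   "phase": 0.2760710559511505
  },
  {
   "mua": 0.02155824671778505,
   "musp": 0.8660254037844386,
   "frequency_mhz": 126.0,
   "amplitude": 2.694214815831649e-06,
   "phase": 0.35120889382015263
  },
  {
   "mua": 0.02155824671778505,
   "musp": 1.4714154781913558,
   "frequency_mhz": 126.0,
   "amplitude": 5.367725138300703e-07,
   "phase": 0.46061443557996534
  },
  {
   "mua": 0.02155824671778505,
   "musp": 2.5,
   "frequency_mhz": 126.0,
   "amplitude": 6.426291377747904e-08,
   "phase": 0.6150760049804882
  },
  {
   "mua": 0.06,
   "musp": 0.3,
   "frequency_mhz": 126.0,
   "amplitude": 2.294417605171035e-06,
   "phase": 0.16322641437429553
  },
  {
   "mua": 0.06,
   "musp": 0.5097132734541368,
   "frequency_mhz": 126.0,
   "amplitude": 8.465086910159859e-07,
   "phase": 0.18800638800144306
  },
  {
   "mua": 0.06,
   "musp": 0.8660254037844386,
   "frequency_mhz": 126.0,
   "amplitude": 1.5084751817320344e-07,
   "phase": 0.23189098356695484
  },
  {
   "mua": 0.06,
   "musp": 1.4714154781913558,
   "frequency_mhz": 126.0,
   "amplitude": 1.3056010800307989e-08,
   "phase": 0.2939739920206677
  },
  {
   "mua": 0.06,
   "musp": 2.5,
   "frequency_mhz": 126.0,
   "amplitude": 4.50851187909337e-10,
   "phase": 0.39534332195698285
  },
  {
   "mua": 0.01,
   "musp": 1.0,
   "frequency_mhz": 126.0,
   "amplitude": 6.967179142112885e-06,
   "phase": 0.5072679019912654,
   "anchor": true
  }
 ]
}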