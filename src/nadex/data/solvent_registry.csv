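label,sorbitol_pct,ethanol_pct,water_pct,malic_acid_pct,glycerin_pct,density_g_per_ml,epsilon,epsilon_halfwidth
1,2.00,91.0,7.00,0,0,0.815,26,
2,14.0,66.0,20.0,0,0,0.900,34,
3,34.0,42.0,24.0,0,0,1.018,41,
4,51.0,22.0,27.0,0,0,1.130,50,
5,72.0,0,28.0,0,0,1.298,61,
6,49.0,0,15.0,36.0,0,1.404,33,2
7,42.7,0,4.20,31.5,21.6,1.381,41,2
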