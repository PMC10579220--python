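T_K,P_MPa,rho_kg_m3,y_molefrac,S_g_L
308,12,768.42,3.02e-05,0.267
308,15,816.06,3.37e-05,0.316
308,18,848.87,3.59e-05,0.350
308,21,874.40,3.87e-05,0.389
308,24,895.54,4.41e-05,0.454
308,27,913.69,4.77e-05,0.500
308,30,929.68,5.17e-05,0.552
318,12,659.73,2.71e-05,0.206
318,15,743.17,3.52e-05,0.301
318,18,790.18,3.95e-05,0.358
318,21,823.70,4.49e-05,0.424
318,24,850.10,5.06e-05,0.494
318,27,872.04,5.30e-05,0.531
318,30,890.92,5.83e-05,0.596
328,12,506.85,2.39e-05,0.139
328,15,654.94,3.33e-05,0.250
328,18,724.13,4.26e-05,0.355
328,21,768.74,4.94e-05,0.436
328,24,801.92,5.51e-05,0.507
328,27,828.51,5.86e-05,0.557
328,30,850.83,6.51e-05,0.636
338,12,384.17,2.07e-05,0.092
338,15,555.23,3.03e-05,0.193
338,18,651.18,4.56e-05,0.341
338,21,709.69,5.53e-05,0.451
338,24,751.17,6.09e-05,0.525
338,27,783.29,6.35e-05,0.571
338,30,809.58,6.98e-05,0.649
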