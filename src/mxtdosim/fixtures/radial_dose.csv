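r_cm,g_abs_mc,g_water_mc,g_abs_ebt,g_water_ebt,ratio_water_abs_mc,diff_abs_mc_ebt,diff_water_mc_ebt
1.0,1.0,1.0,1.0,1.0,1.0,,
1.1,0.85,0.84,0.93,0.93,0.99,-0.08,-0.09
1.2,0.77,0.77,0.85,0.84,1.0,-0.08,-0.07
1.4,0.72,0.71,0.73,0.7,0.99,-0.01,0.01
1.6,0.71,0.67,0.6,0.57,0.94,0.11,0.1
1.8,0.61,0.55,0.53,0.5,0.9,0.08,0.05
2.0,0.6,0.57,0.51,0.47,0.95,0.09,0.1
2.2,0.5,0.46,0.45,0.41,0.92,0.05,0.05
2.4,0.51,0.43,0.43,0.38,0.84,0.08,0.05
2.6,0.47,0.39,0.38,0.33,0.83,0.09,0.06
2.8,0.45,0.37,0.37,0.31,0.82,0.08,0.06
3.0,0.44,0.38,0.34,0.29,0.86,0.1,0.09
3.2,0.41,0.36,0.34,0.28,0.88,0.07,0.08
3.4,0.37,0.33,0.31,0.25,0.89,0.06,0.08
3.6,0.37,0.29,0.28,0.22,0.78,0.09,0.07
3.8,0.33,0.26,0.26,0.2,0.79,0.07,0.06
4.0,0.34,0.25,0.23,0.18,0.74,0.11,0.07
4.2,0.31,0.24,0.21,0.16,0.77,0.1,0.08
4.4,0.31,0.24,0.22,0.16,0.77,0.09,0.08
4.6,0.3,0.21,0.21,0.15,0.7,0.09,0.06
4.8,0.3,0.19,0.18,0.12,0.63,0.12,0.07
5.0,0.26,0.18,0.16,0.11,0.69,0.1,0.07
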