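r_cm,g_abs_xr
2.0,0.54
3.0,0.33
4.0,0.25
5.0,0.2
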