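phi_deg,ratio
0,1.0
30,1.04
60,1.05
90,1.01
120,1.03
150,1.06
180,1.02
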