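r_cm,theta_deg,value,uncertain
2.8,20,1.02,True
3.0,20,0.94,False
3.2,20,0.98,False
3.4,20,1.08,False
3.6,20,1.02,False
3.8,20,1.07,False
4.0,20,1.1,False
4.2,20,1.21,False
2.0,30,1.05,False
2.2,30,1.1,False
2.4,30,1.1,False
2.6,30,1.16,False
2.8,30,1.2,False
3.0,30,1.13,False
3.2,30,1.19,False
3.4,30,1.32,False
3.6,30,1.23,False
3.8,30,1.21,False
4.0,30,1.33,False
4.2,30,1.28,False
1.6,40,0.94,False
1.8,40,0.97,False
2.0,40,0.96,False
2.2,40,1.03,False
2.4,40,1.0,False
2.6,40,1.12,False
2.8,40,1.14,False
3.0,40,1.07,False
3.2,40,1.16,False
3.4,40,1.19,False
3.6,40,1.22,False
3.8,40,1.18,False
4.0,40,1.32,False
4.2,40,1.3,False
1.4,50,0.92,False
1.6,50,1.01,False
1.8,50,0.99,False
2.0,50,0.97,False
2.2,50,1.04,False
2.4,50,1.04,False
2.6,50,1.09,False
2.8,50,1.16,False
3.0,50,1.1,False
3.2,50,1.07,False
3.4,50,1.18,False
3.6,50,1.14,False
3.8,50,1.2,False
4.0,50,1.24,False
4.2,50,1.31,False
1.2,60,0.94,False
1.4,60,0.93,False
1.6,60,1.01,False
1.8,60,1.0,False
2.0,60,0.99,False
2.2,60,1.05,False
2.4,60,1.02,False
2.6,60,1.05,False
2.8,60,1.08,False
3.0,60,1.08,False
3.2,60,1.06,False
3.4,60,1.11,False
3.6,60,1.12,False
3.8,60,1.11,False
4.0,60,1.21,False
4.2,60,1.15,False
1.1,70,0.93,False
1.2,70,0.93,False
1.4,70,0.98,False
1.6,70,0.99,False
1.8,70,1.01,False
2.0,70,1.0,False
2.2,70,1.02,False
2.4,70,1.0,False
2.6,70,1.05,False
2.8,70,1.11,False
3.0,70,1.05,False
3.2,70,1.04,False
3.4,70,1.05,False
3.6,70,1.01,False
3.8,70,1.02,False
4.0,70,1.03,False
4.2,70,1.01,False
1.1,80,0.97,False
1.2,80,0.95,False
1.4,80,0.99,False
1.6,80,0.98,False
1.8,80,1.01,False
2.0,80,1.01,False
2.2,80,1.01,False
2.4,80,1.01,False
2.6,80,1.06,False
2.8,80,1.09,False
3.0,80,1.03,False
3.2,80,1.0,False
3.4,80,1.11,False
3.6,80,0.98,False
3.8,80,0.98,False
4.0,80,1.1,False
4.2,80,1.13,False
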