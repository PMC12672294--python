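r_cm,theta_deg,value,uncertain
1.0,0,1.1,False
1.1,0,1.11,False
1.2,0,1.13,False
1.4,0,1.15,False
1.6,0,1.16,False
1.8,0,1.17,False
2.0,0,1.15,False
2.2,0,1.17,False
2.4,0,1.2,False
2.6,0,1.15,False
2.8,0,1.15,False
3.0,0,1.14,False
3.2,0,1.16,False
3.4,0,1.17,False
3.6,0,1.23,False
3.8,0,1.24,False
4.0,0,1.18,False
4.2,0,1.11,False
1.0,10,1.03,False
1.1,10,1.05,False
1.2,10,1.01,False
1.4,10,1.05,False
1.6,10,1.09,False
1.8,10,1.04,False
2.0,10,1.05,False
2.2,10,1.05,False
2.4,10,1.09,False
2.6,10,1.07,False
2.8,10,1.07,False
3.0,10,1.03,False
3.2,10,1.08,False
3.4,10,1.13,False
3.6,10,1.18,False
3.8,10,1.18,False
4.0,10,1.22,False
4.2,10,1.12,False
1.0,20,0.86,False
1.1,20,0.9,False
1.2,20,0.87,False
1.4,20,0.94,False
1.6,20,0.93,False
1.8,20,1.06,False
2.0,20,1.07,False
2.2,20,1.05,False
2.4,20,1.06,False
2.6,20,1.06,False
2.8,20,1.05,True
3.0,20,1.03,False
3.2,20,1.11,False
3.4,20,1.19,False
3.6,20,1.22,False
3.8,20,1.24,False
4.0,20,1.17,False
4.2,20,1.03,False
1.0,30,0.97,False
1.1,30,0.89,False
1.2,30,0.95,False
1.4,30,0.96,False
1.6,30,1.1,False
1.8,30,1.07,False
2.0,30,1.04,False
2.2,30,1.01,False
2.4,30,1.12,False
2.6,30,1.08,False
2.8,30,1.06,False
3.0,30,1.12,False
3.2,30,1.15,False
3.4,30,1.14,False
3.6,30,1.18,False
3.8,30,1.19,False
4.0,30,1.2,False
4.2,30,1.13,False
1.0,40,0.83,False
1.1,40,0.77,False
1.2,40,0.85,False
1.4,40,0.98,False
1.6,40,0.86,False
1.8,40,0.98,False
2.0,40,1.0,False
2.2,40,0.98,False
2.4,40,1.01,False
2.6,40,1.06,False
2.8,40,1.08,False
3.0,40,1.05,False
3.2,40,1.1,False
3.4,40,1.13,False
3.6,40,1.15,False
3.8,40,1.13,False
4.0,40,1.13,False
4.2,40,1.06,False
1.0,50,0.83,False
1.1,50,0.76,False
1.2,50,0.83,False
1.4,50,0.97,False
1.6,50,0.86,False
1.8,50,0.99,False
2.0,50,0.98,False
2.2,50,0.97,False
2.4,50,0.98,False
2.6,50,1.02,False
2.8,50,1.01,False
3.0,50,0.99,False
3.2,50,1.02,False
3.4,50,1.0,False
3.6,50,1.08,False
3.8,50,1.08,False
4.0,50,1.09,False
4.2,50,1.04,False
1.0,60,0.91,False
1.1,60,0.84,False
1.2,60,0.89,False
1.4,60,0.89,False
1.6,60,1.01,False
1.8,60,0.99,False
2.0,60,0.96,False
2.2,60,0.93,False
2.4,60,1.03,False
2.6,60,0.99,False
2.8,60,0.96,False
3.0,60,1.04,False
3.2,60,1.08,False
3.4,60,1.04,False
3.6,60,1.08,False
3.8,60,1.16,False
4.0,60,1.17,False
4.2,60,1.04,False
1.0,70,0.89,False
1.1,70,0.83,False
1.2,70,0.89,False
1.4,70,0.86,False
1.6,70,0.86,False
1.8,70,0.99,False
2.0,70,0.98,False
2.2,70,0.95,False
2.4,70,0.96,False
2.6,70,0.92,False
2.8,70,0.93,False
3.0,70,0.95,False
3.2,70,1.01,False
3.4,70,1.07,False
3.6,70,1.15,False
3.8,70,1.17,False
4.0,70,1.14,False
4.2,70,1.03,False
1.0,80,0.93,False
1.1,80,0.94,False
1.2,80,0.92,False
1.4,80,0.95,False
1.6,80,0.96,False
1.8,80,0.96,False
2.0,80,0.97,False
2.2,80,0.99,False
2.4,80,1.03,False
2.6,80,1.03,False
2.8,80,1.0,False
3.0,80,1.03,False
3.2,80,1.06,False
3.4,80,1.06,False
3.6,80,1.11,False
3.8,80,1.1,False
4.0,80,1.07,False
4.2,80,0.97,False
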