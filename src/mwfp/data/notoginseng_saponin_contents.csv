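sample_id,origin,G-Rb1,G-Rg1,G-Rd,NG-R1,NG-R2
S1,Sichuan,38.53,44.97,8.45,12.30,1.33
S2,Sichuan,39.00,51.62,7.63,11.09,0.87
S3,Sichuan,36.08,52.86,8.54,6.87,0.79
S4,Sichuan,25.92,42.00,5.11,4.64,0.49
S5,Sichuan,36.57,51.81,7.79,11.58,1.08
S6,Sichuan,30.76,39.28,6.79,5.95,0.61
S7,Sichuan,36.13,47.62,8.19,6.86,0.95
S8,Sichuan,35.44,35.40,7.37,6.96,0.57
S9,Sichuan,43.28,49.46,10.10,11.10,1.15
S10,Sichuan,31.00,39.92,7.02,8.82,0.79
S11,Sichuan,28.26,46.17,6.69,4.95,0.51
S12,Sichuan,42.40,46.75,11.42,11.91,1.38
S13,Sichuan,39.00,54.84,9.48,11.03,1.20
S14,Sichuan,37.22,44.20,9.23,7.96,0.98
S15,Sichuan,29.47,41.73,6.43,7.28,0.76
S16,Yunnan,32.17,45.56,6.46,7.75,0.93
S17,Yunnan,30.12,38.25,6.31,8.97,1.38
S18,Yunnan,20.47,29.86,3.53,6.30,0.87
S19,Yunnan,25.31,42.45,4.92,7.79,1.10
S20,Yunnan,22.49,25.41,5.04,8.08,0.91
S21,Yunnan,26.32,34.98,6.52,10.28,1.16
S22,Yunnan,31.28,30.11,6.57,8.01,1.09
S23,Yunnan,20.48,38.86,4.76,7.07,1.03
S24,Yunnan,22.90,35.51,6.19,8.02,1.23
S25,Yunnan,27.34,32.82,8.12,15.50,1.37
S26,Yunnan,25.79,36.53,8.25,6.06,0.85
S27,Yunnan,29.66,38.80,7.07,9.37,1.10
S28,Yunnan,23.30,39.43,6.29,10.10,1.04
S29,Yunnan,25.10,30.95,5.53,8.54,1.31
S30,Yunnan,24.25,34.25,6.28,7.31,1.20
S31,Yunnan,20.85,30.26,4.37,7.54,1.02
S32,Yunnan,20.08,29.34,3.81,7.86,1.17
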