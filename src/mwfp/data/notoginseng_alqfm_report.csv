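sample_id,origin,sm_203,pm_203,alpha_203,grade_203,sm_270,pm_270,alpha_270,grade_270,sm_325,pm_325,alpha_325,grade_325,sm_fused,pm_fused,alpha_fused,grade_fused
S1,Sichuan,0.962,117.4,0.031,4,0.929,116.5,0.009,4,0.930,123.6,0.010,5,0.883,94.3,0.047,3
S2,Sichuan,0.929,86.6,0.062,3,0.894,108.3,0.242,4,0.822,106.7,0.173,4,0.878,87.7,0.133,3
S3,Sichuan,0.951,106.6,0.017,2,0.927,111.0,0.027,3,0.963,138.5,0.009,6,0.936,113.2,0.007,3
S4,Sichuan,0.962,101.5,0.001,1,0.910,101.0,0.027,2,0.892,117.7,0.048,4,0.892,83.6,0.087,4
S5,Sichuan,0.988,109.4,0.004,2,0.971,111.3,0.070,3,0.955,112.4,0.031,3,0.899,86.4,0.090,3
S6,Sichuan,0.971,123.7,0.018,5,0.943,150.7,0.161,8,0.879,162.4,0.194,8,0.894,105.8,0.126,3
S7,Sichuan,0.974,122.0,0.004,5,0.953,138.8,0.164,6,0.874,151.5,0.180,8,0.893,101.3,0.111,3
S8,Sichuan,0.961,153.9,0.023,8,0.952,180.7,0.018,8,0.969,222.4,0.004,8,0.897,118.2,0.043,4
S9,Sichuan,0.953,91.5,0.015,2,0.930,88.9,0.095,3,0.965,80.6,0.033,4,0.892,78.9,0.119,5
S10,Sichuan,0.954,95.4,0.001,1,0.953,112.2,0.164,4,0.925,121.9,0.147,5,0.903,88.3,0.098,3
S11,Sichuan,0.960,114.2,0.023,3,0.936,127.2,0.015,5,0.938,138.4,0.043,6,0.901,94.2,0.064,2
S12,Sichuan,0.959,103.7,0.018,1,0.953,105.7,0.118,3,0.930,112.2,0.099,3,0.895,90.6,0.086,3
S13,Sichuan,0.961,114.4,0.030,3,0.964,121.6,0.016,5,0.939,155.2,0.074,8,0.897,82.9,0.075,4
S14,Sichuan,0.925,100.4,0.054,2,0.951,100.0,0.009,1,0.907,111.6,0.089,3,0.881,70.7,0.096,5
S15,Sichuan,0.933,102.0,0.077,2,0.974,99.3,0.032,1,0.917,100.1,0.027,2,0.888,72.0,0.136,5
S16,Yunnan,0.954,85.8,0.062,3,0.905,71.3,0.124,5,0.939,69.7,0.010,6,0.917,87.0,0.073,3
S17,Yunnan,0.948,78.7,0.057,5,0.901,67.4,0.117,6,0.912,64.9,0.072,6,0.913,79.5,0.069,5
S18,Yunnan,0.968,78.4,0.044,5,0.892,77.1,0.108,5,0.953,67.5,0.031,6,0.921,79.5,0.053,5
S19,Yunnan,0.978,84.1,0.003,4,0.947,77.8,0.119,5,0.910,69.3,0.077,6,0.922,86.1,0.011,3
S20,Yunnan,0.918,78.6,0.025,5,0.940,69.3,0.036,6,0.934,46.5,0.054,8,0.848,59.4,0.070,7
S21,Yunnan,0.963,100.4,0.068,2,0.962,83.1,0.024,4,0.957,65.0,0.027,6,0.882,69.3,0.127,6
S22,Yunnan,0.946,91.5,0.009,2,0.944,75.1,0.022,5,0.935,51.9,0.003,7,0.865,69.2,0.100,6
S23,Yunnan,0.932,85.0,0.078,4,0.931,69.9,0.017,6,0.911,58.4,0.016,7,0.864,60.6,0.158,6
S24,Yunnan,0.958,102.0,0.050,1,0.933,97.4,0.013,2,0.946,72.5,0.017,5,0.879,74.6,0.127,5
S25,Yunnan,0.953,91.9,0.001,2,0.965,87.0,0.030,3,0.947,75.8,0.037,5,0.873,70.0,0.083,5
S26,Yunnan,0.950,90.1,0.059,2,0.956,96.0,0.009,1,0.781,90.5,0.147,5,0.868,66.0,0.135,6
S27,Yunnan,0.957,94.3,0.018,2,0.968,78.5,0.034,5,0.961,70.0,0.005,6,0.881,71.2,0.104,5
S28,Yunnan,0.937,84.3,0.061,4,0.972,86.8,0.006,3,0.928,79.6,0.020,5,0.864,61.6,0.138,6
S29,Yunnan,0.957,92.2,0.052,2,0.968,76.4,0.010,5,0.945,59.6,0.021,7,0.878,66.2,0.126,6
S30,Yunnan,0.972,98.4,0.052,2,0.940,90.5,0.030,2,0.940,78.3,0.066,5,0.887,70.4,0.114,5
S31,Yunnan,0.957,92.3,0.061,2,0.964,91.1,0.012,2,0.947,75.8,0.023,5,0.892,64.4,0.111,6
S32,Yunnan,0.948,90.6,0.040,2,0.939,82.7,0.014,4,0.927,59.1,0.053,7,0.868,66.4,0.120,6
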