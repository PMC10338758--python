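patient_id,mean_pan_mm,mean_tilt_mm,mean_2d_mm,sd_pan_mm,sd_tilt_mm,sd_2d_mm,p90_pan_mm,p90_tilt_mm,p90_2d_mm
1,0.26,0.36,0.52,0.35,0.50,0.54,0.59,0.90,1.27
2,0.46,0.70,0.90,0.49,0.72,0.81,1.08,1.80,2.02
3,0.37,0.84,1.00,0.45,0.68,0.70,0.99,1.80,1.94
4,0.21,0.42,0.53,0.32,0.54,0.59,0.54,0.90,1.14
5,0.42,0.90,1.05,0.45,0.99,1.04,0.94,2.56,2.90
6,0.32,0.75,0.88,0.38,0.97,0.99,0.72,1.80,2.01
7,0.28,0.60,0.70,0.51,0.61,0.76,0.65,1.45,1.52
8,0.31,0.76,0.86,0.41,0.71,0.78,0.97,1.83,1.98
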