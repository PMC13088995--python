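disease_id,pollutant,form,age_band,theta,theta_se,alpha,mu,nu,z_cf,beta,beta_scale_ugm3,c0,min_age,note
IHD,PM2.5,GEMM,,0.2969,0.01787,1.9,12.0,40.2,2.4,,,,25,GEMM source transcription
stroke,PM2.5,GEMM,,0.272,0.07697,6.2,16.7,23.7,2.4,,,,25,GEMM source transcription
COPD,PM2.5,GEMM,,0.251,0.06762,6.5,2.5,32.0,2.4,,,,25,GEMM source transcription
LC,PM2.5,GEMM,,0.2942,0.06147,6.2,9.3,29.8,2.4,,,,25,GEMM source transcription
LRI,PM2.5,GEMM,,0.4468,0.11735,6.4,5.7,8.4,2.4,,,,0,GEMM source transcription; all ages
T2DM,PM2.5,GEMM,,0.092,0.03,1.6,15.5,36.8,2.4,,,,25,artifact extension (not in the GEMM five causes)
IHD,PM2.5,GEMM,25-29,0.5047,0.03038,1.9,12.0,40.2,2.4,,,,25,age-profile theta schedule (artifact)
IHD,PM2.5,GEMM,30-34,0.475,0.02859,1.9,12.0,40.2,2.4,,,,25,age-profile theta schedule (artifact)
IHD,PM2.5,GEMM,35-39,0.4454,0.02681,1.9,12.0,40.2,2.4,,,,25,age-profile theta schedule (artifact)
IHD,PM2.5,GEMM,40-44,0.4157,0.02502,1.9,12.0,40.2,2.4,,,,25,age-profile theta schedule (artifact)
IHD,PM2.5,GEMM,45-49,0.386,0.02323,1.9,12.0,40.2,2.4,,,,25,age-profile theta schedule (artifact)
IHD,PM2.5,GEMM,50-54,0.3563,0.02144,1.9,12.0,40.2,2.4,,,,25,age-profile theta schedule (artifact)
IHD,PM2.5,GEMM,55-59,0.3266,0.01966,1.9,12.0,40.2,2.4,,,,25,age-profile theta schedule (artifact)
IHD,PM2.5,GEMM,60-64,0.2969,0.01787,1.9,12.0,40.2,2.4,,,,25,age-profile theta schedule (artifact)
IHD,PM2.5,GEMM,65-69,0.2672,0.01608,1.9,12.0,40.2,2.4,,,,25,age-profile theta schedule (artifact)
IHD,PM2.5,GEMM,70-74,0.2375,0.0143,1.9,12.0,40.2,2.4,,,,25,age-profile theta schedule (artifact)
IHD,PM2.5,GEMM,75-79,0.2078,0.01251,1.9,12.0,40.2,2.4,,,,25,age-profile theta schedule (artifact)
IHD,PM2.5,GEMM,80-84,0.1781,0.01072,1.9,12.0,40.2,2.4,,,,25,age-profile theta schedule (artifact)
IHD,PM2.5,GEMM,85-89,0.1484,0.00894,1.9,12.0,40.2,2.4,,,,25,age-profile theta schedule (artifact)
IHD,PM2.5,GEMM,90-94,0.1336,0.00804,1.9,12.0,40.2,2.4,,,,25,age-profile theta schedule (artifact)
IHD,PM2.5,GEMM,95+,0.1336,0.00804,1.9,12.0,40.2,2.4,,,,25,age-profile theta schedule (artifact)
stroke,PM2.5,GEMM,25-29,0.4624,0.13085,6.2,16.7,23.7,2.4,,,,25,age-profile theta schedule (artifact)
stroke,PM2.5,GEMM,30-34,0.4352,0.12315,6.2,16.7,23.7,2.4,,,,25,age-profile theta schedule (artifact)
stroke,PM2.5,GEMM,35-39,0.408,0.11546,6.2,16.7,23.7,2.4,,,,25,age-profile theta schedule (artifact)
stroke,PM2.5,GEMM,40-44,0.3808,0.10776,6.2,16.7,23.7,2.4,,,,25,age-profile theta schedule (artifact)
stroke,PM2.5,GEMM,45-49,0.3536,0.10006,6.2,16.7,23.7,2.4,,,,25,age-profile theta schedule (artifact)
stroke,PM2.5,GEMM,50-54,0.3264,0.09236,6.2,16.7,23.7,2.4,,,,25,age-profile theta schedule (artifact)
stroke,PM2.5,GEMM,55-59,0.2992,0.08467,6.2,16.7,23.7,2.4,,,,25,age-profile theta schedule (artifact)
stroke,PM2.5,GEMM,60-64,0.272,0.07697,6.2,16.7,23.7,2.4,,,,25,age-profile theta schedule (artifact)
stroke,PM2.5,GEMM,65-69,0.2448,0.06927,6.2,16.7,23.7,2.4,,,,25,age-profile theta schedule (artifact)
stroke,PM2.5,GEMM,70-74,0.2176,0.06158,6.2,16.7,23.7,2.4,,,,25,age-profile theta schedule (artifact)
stroke,PM2.5,GEMM,75-79,0.1904,0.05388,6.2,16.7,23.7,2.4,,,,25,age-profile theta schedule (artifact)
stroke,PM2.5,GEMM,80-84,0.1632,0.04618,6.2,16.7,23.7,2.4,,,,25,age-profile theta schedule (artifact)
stroke,PM2.5,GEMM,85-89,0.136,0.03848,6.2,16.7,23.7,2.4,,,,25,age-profile theta schedule (artifact)
stroke,PM2.5,GEMM,90-94,0.1224,0.03464,6.2,16.7,23.7,2.4,,,,25,age-profile theta schedule (artifact)
stroke,PM2.5,GEMM,95+,0.1224,0.03464,6.2,16.7,23.7,2.4,,,,25,age-profile theta schedule (artifact)
CCVD-CO,CO,log-linear,,,,,,,,0.008,1000.0,0.0,0,"placeholder beta, per 1 mg/m3 CO"
RD-NO2,NO2,log-linear,,,,,,,,0.02,10.0,0.0,0,"placeholder beta, per 10 ug/m3"
CCVD-SO2,SO2,log-linear,,,,,,,,0.015,10.0,0.0,0,"placeholder beta, per 10 ug/m3"
RD-SO2,SO2,log-linear,,,,,,,,0.018,10.0,0.0,0,"placeholder beta, per 10 ug/m3"
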