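breed,n,analyte,family,mean,sd,median,min,max,units
A,156,RBC,truncated_normal,6.86,0.85,6.62,5.48,8.86,10^12/L
A,156,Hb,truncated_normal,15.36,1.74,15.00,12.20,19.00,g/dL
A,156,HCT,truncated_normal,43.89,4.39,43.40,36.70,52.90,%
A,156,MCV,truncated_normal,63.95,2.48,63.80,58.50,68.90,fL
A,156,MCH,truncated_normal,22.37,0.91,22.3,20.80,25.40,pg
A,156,MCHC,truncated_normal,34.99,1.20,35.10,31.50,38.30,g/dL
A,156,RDW,truncated_normal,15.85,1.87,15.30,13.40,21.10,%
A,156,PLT,truncated_normal,312.45,78.88,285,187,552.00,10^3/uL
A,156,WBC,truncated_normal,11.31,2.57,11.13,4.52,18.90,10^3/uL
A,156,Neutrophils,truncated_normal,7.68,1.96,7.73,2.47,13.98,10^3/uL
A,156,Lymphocytes,truncated_normal,2.37,0.77,2.27,0.83,4.34,10^3/uL
A,156,Monocytes,log_normal,0.51,0.27,0.47,0.04,1.35,10^3/uL
A,156,Eosinophils,log_normal,0.57,0.38,0.49,0.00,2.32,10^3/uL
A,156,Basophils,log_normal,0.01,0.009,0.01,0.00,0.045,10^3/uL
A,156,Albumin,truncated_normal,3.33,0.31,3.32,2.76,4.00,g/dL
A,156,TP,truncated_normal,6.5,0.4,6.60,4.30,7.70,g/dL
A,156,Urea,truncated_normal,27,9,27,9,51,mg/dL
A,156,Creatinine,truncated_normal,0.79,0.27,0.78,0.12,1.39,mg/dL
A,156,AST,truncated_normal,29,7,28,12,69,IU/L
A,156,ALT,truncated_normal,35,10,34,18,79,IU/L
A,156,ALP,log_normal,61,33,53,17,181,IU/L
B,52,RBC,truncated_normal,6.79,0.67,6.82,5.61,8.55,10^12/L
B,52,Hb,truncated_normal,14.68,0.77,14.50,13.40,16.00,g/dL
B,52,HCT,truncated_normal,44.40,3.82,45.00,36.50,52.60,%
B,52,MCV,truncated_normal,65.46,2.80,65.00,59.90,71.00,fL
B,52,MCH,truncated_normal,21.32,1.79,21.80,17.90,24.20,pg
B,52,MCHC,truncated_normal,32.54,2.15,32.20,28.60,36.00,g/dL
B,52,RDW,truncated_normal,15.32,1.19,15.50,13.20,17.40,%
B,52,PLT,truncated_normal,373.12,89.82,362,201,557,10^3/uL
B,52,WBC,truncated_normal,11.26,2.17,11.50,5.90,16.30,10^3/uL
B,52,Neutrophils,truncated_normal,7.59,1.80,8.16,2.90,10.59,10^3/uL
B,52,Lymphocytes,truncated_normal,2.74,1.04,2.63,0.52,4.97,10^3/uL
B,52,Monocytes,log_normal,0.44,0.22,0.44,0.11,0.86,10^3/uL
B,52,Eosinophils,log_normal,0.51,0.43,0.43,0.00,1.68,10^3/uL
B,52,Basophils,log_normal,0.01,0.03,0.00,0.00,0.11,10^3/uL
B,52,Albumin,truncated_normal,3.31,0.41,3.32,2.39,4.15,g/dL
B,52,TP,truncated_normal,6.9,0.4,7.00,6.00,7.80,g/dL
B,52,Urea,truncated_normal,23,6,23,12,40,mg/dL
B,52,Creatinine,truncated_normal,0.91,0.16,0.87,0.63,1.21,mg/dL
B,52,AST,truncated_normal,27,10,25,15,51,IU/L
B,52,ALT,truncated_normal,32.93,8.60,33,20,57,IU/L
B,52,ALP,log_normal,45,11,44,29,70,IU/L
C,64,RBC,truncated_normal,6.95,0.90,7.09,4.49,8.74,10^12/L
C,64,Hb,truncated_normal,15.85,1.89,15.90,10.80,18.50,g/dL
C,64,HCT,truncated_normal,47.10,5.58,47.70,35.90,60.70,%
C,64,MCV,truncated_normal,67.80,3.36,67.60,60.80,73.20,fL
C,64,MCH,truncated_normal,22.84,1.54,22.90,19.10,25.60,pg
C,64,MCHC,truncated_normal,33.92,2.38,34.45,29.10,37.60,g/dL
C,64,RDW,truncated_normal,14.38,1.45,14.05,12.20,17.90,%
C,64,PLT,truncated_normal,386.44,101.82,346,230,664,10^3/uL
C,64,WBC,truncated_normal,9.72,2.79,9.47,6.00,17.20,10^3/uL
C,64,Neutrophils,truncated_normal,6.52,2.06,6.17,4.13,11.86,10^3/uL
C,64,Lymphocytes,truncated_normal,2.39,0.87,2.21,1.20,4.375,10^3/uL
C,64,Monocytes,log_normal,0.27,0.17,0.24,0.06,1.02,10^3/uL
C,64,Eosinophils,log_normal,0.35,0.27,0.27,0.03,1.12,10^3/uL
C,64,Basophils,log_normal,0.02,0.03,0.007,0.00,0.17,10^3/uL
C,64,Albumin,truncated_normal,3.29,0.36,3.33,1.93,4.08,g/dL
C,64,TP,truncated_normal,6.6,0.4,6.55,5.80,7.50,g/dL
C,64,Urea,truncated_normal,36,11,35,12,61,mg/dL
C,64,Creatinine,truncated_normal,0.90,0.27,0.90,0.38,1.71,mg/dL
C,64,AST,truncated_normal,32,8,32,11,46,IU/L
C,64,ALT,truncated_normal,42.09,13.57,39,18,68,IU/L
C,64,ALP,log_normal,55,21,47,19,107,IU/L
D,123,RBC,truncated_normal,6.75,0.76,6.74,4.76,8.61,10^12/L
D,123,Hb,truncated_normal,15.38,1.93,15.20,11.00,20.40,g/dL
D,123,HCT,truncated_normal,43.66,4.43,43.30,30.40,53.90,%
D,123,MCV,truncated_normal,64.78,2.84,65.10,57.20,72.40,fL
D,123,MCH,truncated_normal,22.54,2.52,22.75,2.10,26.50,pg
D,123,MCHC,truncated_normal,35.22,2.07,35.00,28.60,42.50,g/dL
D,123,RDW,truncated_normal,15.73,1.52,15.35,13.00,19.90,%
D,123,PLT,truncated_normal,330.88,95.97,320,191,698,10^3/uL
D,123,WBC,truncated_normal,10.58,2.25,10.63,5.90,14.92,10^3/uL
D,123,Neutrophils,truncated_normal,6.84,1.60,6.84,3.21,10.15,10^3/uL
D,123,Lymphocytes,truncated_normal,2.49,0.89,2.32,0.55,4.98,10^3/uL
D,123,Monocytes,log_normal,0.45,0.28,0.40,0.02,1.44,10^3/uL
D,123,Eosinophils,log_normal,0.52,0.31,0.44,0.08,1.69,10^3/uL
D,123,Basophils,log_normal,0.02,0.02,0.01,0.00,0.20,10^3/uL
D,123,Albumin,truncated_normal,3.28,0.35,3.33,1.93,4.60,g/dL
D,123,TP,truncated_normal,6.7,0.5,6.65,5.60,8.20,g/dL
D,123,Urea,truncated_normal,26,9,28,8,56,mg/dL
D,123,Creatinine,truncated_normal,0.99,0.23,0.97,0.54,1.87,mg/dL
D,123,AST,truncated_normal,35,12,32,12,89,IU/L
D,123,ALT,truncated_normal,39.79,14.56,42,7,81,IU/L
D,123,ALP,log_normal,59,26,57,12,115,IU/L
E,50,RBC,truncated_normal,6.87,0.64,6.87,5.57,8.70,10^12/L
E,50,Hb,truncated_normal,15.15,1.72,15.40,11.20,18.10,g/dL
E,50,HCT,truncated_normal,44.50,4.08,44.80,35.40,52.60,%
E,50,MCV,truncated_normal,64.73,2.59,64.70,58.00,69.00,fL
E,50,MCH,truncated_normal,21.81,1.92,22.20,17.40,25.30,pg
E,50,MCHC,truncated_normal,34.55,2.19,34.70,28.10,37.90,g/dL
E,50,RDW,truncated_normal,15.50,1.46,15.20,13.20,19.10,%
E,50,PLT,truncated_normal,336.41,125.74,334,126,691,10^3/uL
E,50,WBC,truncated_normal,10.90,2.12,11.10,7.00,16.96,10^3/uL
E,50,Neutrophils,truncated_normal,6.99,1.33,7.10,4.55,9.67,10^3/uL
E,50,Lymphocytes,truncated_normal,2.61,0.83,2.50,1.26,4.42,10^3/uL
E,50,Monocytes,log_normal,0.38,0.21,0.36,0.07,0.79,10^3/uL
E,50,Eosinophils,log_normal,0.53,0.40,0.44,0.03,1.90,10^3/uL
E,50,Basophils,log_normal,0.01,0.02,0.01,0.00,0.11,10^3/uL
E,50,Albumin,truncated_normal,3.36,0.32,3.39,2.86,4.00,g/dL
E,50,TP,truncated_normal,6.7,0.4,6.70,6.00,8.00,g/dL
E,50,Urea,truncated_normal,32,10,30,15,62,mg/dL
E,50,Creatinine,truncated_normal,1.08,0.13,1.07,0.74,1.39,mg/dL
E,50,AST,truncated_normal,30.30,7.56,30,17,55,IU/L
E,50,ALT,truncated_normal,30.25,7.62,29,18,47,IU/L
E,50,ALP,log_normal,39,18,36,9,84,IU/L
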