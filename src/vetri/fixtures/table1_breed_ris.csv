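breed,analyte,low,high
A,RBC,5.48,8.8
A,Hb,12.2,18.95
A,HCT,36.93,52.84
A,MCV,59.61,69.90
A,MCH,20.8,25.1
A,MCHC,31.6,38.1
A,RDW,13.5,19.7
A,PLT,200,537
A,WBC,4.55,17.71
A,Neutrophils,2.59,13.65
A,Lymphocytes,1.02,4.27
A,Monocytes,0.04,1.23
A,Eosinophils,0.07,1.4
A,Basophils,0.00,0.03
A,Albumin,2.78,3.91
A,TP,5.90,7.50
A,Urea,11.3,48.85
A,Creatinine,0.15,1.37
A,AST,17.1,44.7
A,ALT,18.45,65.1
A,ALP,20.3,145.4
B,RBC,5.61,8.29
B,Hb,13.4,16.0
B,HCT,36.5,52.76
B,MCV,59.9,71.0
B,MCH,17.9,24.2
B,MCHC,28.6,35.8
B,RDW,13.2,17.1
B,PLT,201,554
B,WBC,5.90,15.67
B,Neutrophils,2.90,10.53
B,Lymphocytes,0.52,4.84
B,Monocytes,0.11,0.84
B,Eosinophils,0.00,1.68
B,Basophils,0.00,0.11
B,Albumin,2.39,4.15
B,TP,6.00,7.80
B,Urea,12,39.1
B,Creatinine,0.63,1.21
B,AST,15,51
B,ALT,20,54
B,ALP,29,69.1
C,RBC,4.57,8.71
C,Hb,10.9,18.4
C,HCT,35.91,60.58
C,MCV,60.9,73.19
C,MCH,19.1,25.5
C,MCHC,29.1,37.5
C,RDW,12.2,17.8
C,PLT,231,661
C,WBC,6.00,17.00
C,Neutrophils,4.13,11.79
C,Lymphocytes,1.20,4.37
C,Monocytes,0.06,1.00
C,Eosinophils,0.03,1.11
C,Basophils,0.00,0.16
C,Albumin,1.98,4.05
C,TP,5.80,7.49
C,Urea,12.52,60.7
C,Creatinine,0.38,1.68
C,AST,11.15,45.92
C,ALT,18.3,67.85
C,ALP,19.2,106.3
D,RBC,5.18,8.32
D,Hb,11.1,19.3
D,HCT,33.38,52.45
D,MCV,59.8,70.66
D,MCH,19.5,25.8
D,MCHC,29.6,41.3
D,RDW,13.0,19.2
D,PLT,193,659
D,WBC,6.15,14.43
D,Neutrophils,3.61,9.97
D,Lymphocytes,1.21,4.90
D,Monocytes,0.05,1.34
D,Eosinophils,0.10,1.30
D,Basophils,0.00,0.14
D,Albumin,2.62,3.77
D,TP,5.63,8.02
D,Urea,9.12,51.62
D,Creatinine,0.58,1.70
D,AST,18.37,74.25
D,ALT,11.37,69.5
D,ALP,17.1,112.2
E,RBC,5.58,8.61
E,Hb,11.2,18.0
E,HCT,35.59,52.57
E,MCV,58.12,69.0
E,MCH,17.4,25.2
E,MCHC,28.2,37.8
E,RDW,13.2,19.0
E,PLT,126,685
E,WBC,7.00,16.68
E,Neutrophils,4.57,9.59
E,Lymphocytes,1.27,4.39
E,Monocytes,0.07,0.79
E,Eosinophils,0.03,1.80
E,Basophils,0.00,0.10
E,Albumin,2.86,3.99
E,TP,6.00,7.98
E,Urea,15.1,61.1
E,Creatinine,0.75,1.38
E,AST,17.1,53.9
E,ALT,18.1,46.7
E,ALP,9.5,83.8
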