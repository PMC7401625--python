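breed,analyte,pct1,pct2,reported_new_ri
A,RBC,5,,0
A,Hb,5,,0
A,HCT,5,,0
A,MCV,10,,0
A,MCH,30,,1
A,MCHC,30,,1
A,RDW,5,,0
A,PLT,10,,0
A,WBC,5,,0
A,Neutrophils,5,,0
A,Lymphocytes,5,,0
A,Monocytes,45,,1
A,Eosinophils,5,,0
A,Basophils,0,,0
A,Albumin,45,,1
A,TP,10,,0
A,Urea,45,,1
A,Creatinine,30,,1
A,AST,10,,0
A,ALT,20,15,1
A,ALP,5,,0
B,RBC,5,,0
B,Hb,0,,0
B,HCT,5,,0
B,MCV,0,,0
B,MCH,50,,1
B,MCHC,75,,1
B,RDW,0,,0
B,PLT,20,20,1
B,WBC,0,,0
B,Neutrophils,0,,0
B,Lymphocytes,5,,0
B,Monocytes,45,,1
B,Eosinophils,25,25,1
B,Basophils,5,,0
B,Albumin,50,,1
B,TP,0,,0
B,Urea,30,,1
B,Creatinine,5,,0
B,AST,15,20,1
B,ALT,25,15,1
B,ALP,0,,0
C,RBC,10,,0
C,Hb,0,,0
C,HCT,15,25,1
C,MCV,20,10,0
C,MCH,25,30,1
C,MCHC,60,,0
C,RDW,15,20,1
C,PLT,30,,1
C,WBC,0,,0
C,Neutrophils,0,,0
C,Lymphocytes,0,,0
C,Monocytes,85,,1
C,Eosinophils,15,25,1
C,Basophils,15,10,0
C,Albumin,35,,1
C,TP,10,,0
C,Urea,20,35,1
C,Creatinine,30,,1
C,AST,10,,0
C,ALT,40,,1
C,ALP,0,,0
D,RBC,5,,0
D,Hb,5,,0
D,HCT,0,,0
D,MCV,0,,0
D,MCH,15,15,1
D,MCHC,5,,0
D,RDW,0,,0
D,PLT,0,,0
D,WBC,0,,0
D,Neutrophils,0,,0
D,Lymphocytes,5,,0
D,Monocytes,60,,1
D,Eosinophils,5,,0
D,Basophils,0,,0
D,Albumin,45,,1
D,TP,0,,0
D,Urea,25,30,1
D,Creatinine,45,,1
D,AST,15,25,1
D,ALT,50,,1
D,ALP,10,,0
E,RBC,5,,0
E,Hb,15,10,0
E,HCT,0,,0
E,MCV,10,,0
E,MCH,50,,1
E,MCHC,40,,1
E,RDW,0,,0
E,PLT,15,15,1
E,WBC,0,,0
E,Neutrophils,0,,0
E,Lymphocytes,0,,0
E,Monocytes,70,,1
E,Eosinophils,5,,0
E,Basophils,0,,0
E,Albumin,45,,1
E,TP,0,,0
E,Urea,35,,0
E,Creatinine,10,,0
E,AST,0,,0
E,ALT,5,,0
E,ALP,0,,0
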