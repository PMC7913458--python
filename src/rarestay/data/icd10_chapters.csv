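chapter_start,chapter_end,label
A00,B99,Certain infectious and parasitic diseases
C00,D48,Neoplasms
D50,D89,Diseases of the blood and blood-forming organs and certain disorders involving the immune mechanism
E00,E90,Endocrine nutritional and metabolic diseases
F00,F99,Mental and behavioural disorders
G00,G99,Diseases of the nervous system
H00,H59,Diseases of the eye and adnexa
H60,H95,Diseases of the ear and mastoid process
I00,I99,Diseases of the circulatory system
J00,J99,Diseases of the respiratory system
K00,K93,Diseases of the digestive system
L00,L99,Diseases of the skin and subcutaneous tissue
M00,M99,Diseases of the musculoskeletal system and connective tissue
N00,N99,Diseases of the genitourinary system
O00,O99,Pregnancy childbirth and the puerperium
P00,P96,Certain conditions originating in the perinatal period
Q00,Q99,"Congenital malformations, deformations and chromosomal abnormalities"
R00,R99,"Symptoms, signs and abnormal clinical and laboratory findings, not elsewhere classified"
S00,T98,"Injury, poisoning and certain other consequences of external causes"
U00,U99,Codes for special purposes
V01,Y98,External causes of morbidity and mortality
Z00,Z99,Factors influencing health status and contact with health services
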