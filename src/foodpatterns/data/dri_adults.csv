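population,nutrient,value,kind
F19-30,protein,56,rda_ai
F19-30,carbohydrate,130,rda_ai
F19-30,fiber,28,rda_ai
F19-30,linoleic_acid,17,rda_ai
F19-30,linolenic_acid,1.1,rda_ai
F19-30,calcium,1000,rda_ai
F19-30,iron,18,rda_ai
F19-30,magnesium,310,rda_ai
F19-30,phosphorus,700,rda_ai
F19-30,potassium,2600,rda_ai
F19-30,sodium,2300,cdrr
F19-30,zinc,8,rda_ai
F19-30,copper,0.9,rda_ai
F19-30,selenium,55,rda_ai
F19-30,vitamin_a,700,rda_ai
F19-30,vitamin_e,15,rda_ai
F19-30,vitamin_d,600,rda_ai
F19-30,vitamin_c,75,rda_ai
F19-30,thiamin,1.1,rda_ai
F19-30,riboflavin,1.1,rda_ai
F19-30,niacin,14,rda_ai
F19-30,vitamin_b6,1.3,rda_ai
F19-30,vitamin_b12,2.4,rda_ai
F19-30,choline,425,rda_ai
F19-30,vitamin_k,90,rda_ai
F19-30,folate,400,rda_ai
F31-50,protein,46,rda_ai
F31-50,carbohydrate,130,rda_ai
F31-50,fiber,25.2,rda_ai
F31-50,linoleic_acid,12,rda_ai
F31-50,linolenic_acid,1.1,rda_ai
F31-50,calcium,1000,rda_ai
F31-50,iron,18,rda_ai
F31-50,magnesium,320,rda_ai
F31-50,phosphorus,700,rda_ai
F31-50,potassium,2600,rda_ai
F31-50,sodium,2300,cdrr
F31-50,zinc,8,rda_ai
F31-50,copper,0.9,rda_ai
F31-50,selenium,55,rda_ai
F31-50,vitamin_a,700,rda_ai
F31-50,vitamin_e,15,rda_ai
F31-50,vitamin_d,600,rda_ai
F31-50,vitamin_c,75,rda_ai
F31-50,thiamin,1.1,rda_ai
F31-50,riboflavin,1.1,rda_ai
F31-50,niacin,14,rda_ai
F31-50,vitamin_b6,1.3,rda_ai
F31-50,vitamin_b12,2.4,rda_ai
F31-50,choline,425,rda_ai
F31-50,vitamin_k,90,rda_ai
F31-50,folate,400,rda_ai
M19-30,protein,56,rda_ai
M19-30,carbohydrate,130,rda_ai
M19-30,fiber,33.6,rda_ai
M19-30,linoleic_acid,17,rda_ai
M19-30,linolenic_acid,1.6,rda_ai
M19-30,calcium,1000,rda_ai
M19-30,iron,8,rda_ai
M19-30,magnesium,400,rda_ai
M19-30,phosphorus,700,rda_ai
M19-30,potassium,3400,rda_ai
M19-30,sodium,2300,cdrr
M19-30,zinc,11,rda_ai
M19-30,copper,0.9,rda_ai
M19-30,selenium,55,rda_ai
M19-30,vitamin_a,900,rda_ai
M19-30,vitamin_e,15,rda_ai
M19-30,vitamin_d,600,rda_ai
M19-30,vitamin_c,90,rda_ai
M19-30,thiamin,1.2,rda_ai
M19-30,riboflavin,1.3,rda_ai
M19-30,niacin,16,rda_ai
M19-30,vitamin_b6,1.3,rda_ai
M19-30,vitamin_b12,2.4,rda_ai
M19-30,choline,550,rda_ai
M19-30,vitamin_k,120,rda_ai
M19-30,folate,400,rda_ai
M31-50,protein,56,rda_ai
M31-50,carbohydrate,130,rda_ai
M31-50,fiber,30.8,rda_ai
M31-50,linoleic_acid,17,rda_ai
M31-50,linolenic_acid,1.6,rda_ai
M31-50,calcium,1000,rda_ai
M31-50,iron,8,rda_ai
M31-50,magnesium,420,rda_ai
M31-50,phosphorus,700,rda_ai
M31-50,potassium,3400,rda_ai
M31-50,sodium,2300,cdrr
M31-50,zinc,11,rda_ai
M31-50,copper,0.9,rda_ai
M31-50,selenium,55,rda_ai
M31-50,vitamin_a,900,rda_ai
M31-50,vitamin_e,15,rda_ai
M31-50,vitamin_d,600,rda_ai
M31-50,vitamin_c,90,rda_ai
M31-50,thiamin,1.2,rda_ai
M31-50,riboflavin,1.3,rda_ai
M31-50,niacin,16,rda_ai
M31-50,vitamin_b6,1.3,rda_ai
M31-50,vitamin_b12,2.4,rda_ai
M31-50,choline,550,rda_ai
M31-50,vitamin_k,120,rda_ai
M31-50,folate,400,rda_ai
M51+,protein,56,rda_ai
M51+,carbohydrate,130,rda_ai
M51+,fiber,28,rda_ai
M51+,linoleic_acid,14,rda_ai
M51+,linolenic_acid,1.6,rda_ai
M51+,calcium,1000,rda_ai
M51+,iron,8,rda_ai
M51+,magnesium,420,rda_ai
M51+,phosphorus,700,rda_ai
M51+,potassium,3400,rda_ai
M51+,sodium,2300,cdrr
M51+,zinc,11,rda_ai
M51+,copper,0.9,rda_ai
M51+,selenium,55,rda_ai
M51+,vitamin_a,900,rda_ai
M51+,vitamin_e,15,rda_ai
M51+,vitamin_d,600,rda_ai
M51+,vitamin_c,90,rda_ai
M51+,thiamin,1.2,rda_ai
M51+,riboflavin,1.3,rda_ai
M51+,niacin,16,rda_ai
M51+,vitamin_b6,1.7,rda_ai
M51+,vitamin_b12,2.4,rda_ai
M51+,choline,550,rda_ai
M51+,vitamin_k,120,rda_ai
M51+,folate,400,rda_ai
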