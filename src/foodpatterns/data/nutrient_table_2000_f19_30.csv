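nutrient,dri,dri_kind,hvdp,model1,model1_change,model1_pct,model2,model2_change,model2_pct,model3,model3_change,model3_pct
energy,2000,energy,1998,1991,-0.34,99.55,2000,0.11,100.00,2067,3.47,103.35
protein,56,rda_ai,80,80,0.21,142.86,87,8.97,155.36,78,-2.30,139.29
carbohydrate,130,rda_ai,250,251,0.48,193.08,250,0.08,192.31,247,-1.12,190.00
fiber,28,rda_ai,30,31,3.55,110.71,30,0.21,107.14,31,3.55,110.71
total_fat,,range,54,53,-2.46,,56,3.06,,62,14.10,
saturated_fat,,limit,10,10,-2.30,,11,7.46,,10,-2.30,
monounsaturated_fat,,none,20,19,-2.60,,20,2.53,,21,7.65,
polyunsaturated_fat,,none,21,21,1.82,,21,1.82,,27,30.91,
linoleic_acid,17,rda_ai,18,18,-1.02,105.88,18,-1.02,105.88,22,20.97,129.41
linolenic_acid,1.1,rda_ai,2.3,2.4,2.47,218.18,2.3,-1.80,209.09,2.8,19.55,254.55
epa,,none,0.000,0.000,,,0.073,,,0.073,,
dha,,none,0.009,0.000,,,0.165,1818.60,,0.156,1713.95,
cholesterol,,limit,105,25,-76.24,,131,24.48,,29,-72.44,
calcium,1000,rda_ai,1341,1342,0.09,134.20,1351,0.76,135.10,1325,-1.17,132.50
iron,18,rda_ai,16,17,3.49,94.44,17,3.49,94.44,19,15.67,105.56
magnesium,310,rda_ai,381,387,1.45,124.84,392,2.77,126.45,420,10.11,135.48
phosphorus,700,rda_ai,1609,1604,-0.29,229.14,1693,5.24,241.86,1296,-19.44,185.14
potassium,2600,rda_ai,3272,3282,0.31,126.23,3376,3.19,129.85,3422,4.59,131.62
sodium,2300,cdrr,1461,1455,-0.43,63.26,1546,5.80,67.22,1231,-15.76,53.52
zinc,8,rda_ai,11,11,-3.98,137.50,12,4.75,150.00,10,-12.71,125.00
copper,0.9,rda_ai,1.6,1.7,4.12,188.89,1.7,4.12,188.89,2.7,65.37,300.00
selenium,55,rda_ai,79,73,-7.81,132.73,95,19.97,172.73,80,1.03,145.45
vitamin_a,700,rda_ai,847,815,-3.75,116.43,859,1.44,122.71,883,4.28,126.14
vitamin_e,15,rda_ai,10,10,-2.36,66.67,11,7.41,73.33,11,7.41,73.33
vitamin_d,600,rda_ai,220,202,-8.08,33.67,299,36.06,49.83,430,95.68,71.67
vitamin_c,75,rda_ai,129,130,0.40,173.33,130,0.40,173.33,137,5.81,182.37
thiamin,1.1,rda_ai,1.8,1.8,0.64,163.64,1.7,-4.95,154.55,1.7,-4.95,154.55
riboflavin,1.1,rda_ai,1.8,1.8,-1.28,164.64,1.8,-1.28,163.64,2.0,9.69,181.82
niacin,14,rda_ai,17,17,3.01,121.43,18,9.07,128.57,20,21.18,142.86
vitamin_b6,1.3,rda_ai,1.8,1.8,-1.76,138.46,1.9,3.70,146.15,1.9,3.70,146.15
vitamin_b12,2.4,rda_ai,3.9,3.6,-6.51,150.00,5.0,29.84,208.33,7.7,99.96,320.83
choline,425,rda_ai,300,243,-18.88,57.18,322,7.50,75.76,345,15.17,81.18
vitamin_k,90,rda_ai,139,139,0.36,154.44,139,0.36,154.44,158,14.08,175.56
folate,400,rda_ai,612,616,0.65,154.00,618,0.98,154.50,631,3.10,157.75
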