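energy_level,pattern_id,total_kcal,protein_pct,carbohydrate_pct,fat_pct
1800,HVDP,1797,16.9,52.8,25.0
1800,model1_lacto,1790,16.8,53.2,24.6
1800,model2_pesca,1799,18.2,50.9,25.5
1800,model3_pescavegan,1866,15.6,50.2,28.0
2000,HVDP,1998,16.0,50.0,24.4
2000,model1_lacto,1991,16.1,50.4,24.0
2000,model2_pesca,2000,16.0,50.0,25.2
2000,model3_pescavegan,2067,15.1,47.8,27.0
2200,HVDP,2201,15.4,50.3,23.9
2200,model1_lacto,2197,15.5,50.7,23.8
2200,model2_pesca,2209,16.6,48.7,24.4
2200,model3_pescavegan,2279,14.7,48.3,26.4
2400,HVDP,2404,15.1,49.4,23.7
2400,model1_lacto,2400,15.2,49.8,23.2
2400,model2_pesca,2422,16.4,47.7,24.4
2400,model3_pescavegan,2488,14.6,47.4,26.0
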