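food_group,unit,HVDP,model1_lacto,model2_pesca,model3_pescavegan
vegetables,cup_eq_day,2.5,2.5,2.5,2.5
dark_green,cup_eq_week,1.5,1.5,1.5,1.5
red_orange,cup_eq_week,5.5,5.5,5.5,5.5
beans_peas_lentils_veg,cup_eq_week,1.5,1.5,1.5,1.5
starchy_veg,cup_eq_week,5.0,5.0,5.0,5.0
other_veg,cup_eq_week,4.0,4.0,4.0,4.0
fruits,cup_eq_day,2.0,2.0,2.0,2.0
grains,oz_eq_day,6.5,6.5,6.0,6.0
whole_grains,oz_eq_day,3.5,3.5,3.5,3.5
refined_grains,oz_eq_day,3.0,3.0,2.5,2.5
dairy,cup_eq_day,3.0,3.0,3.0,0.0
dairy_alt,cup_eq_day,0.0,0.0,0.0,3.0
protein_foods,oz_eq_day,3.5,3.5,4.64,4.64
eggs,oz_eq_week,3.0,0.0,3.0,0.0
beans_peas_lentils,oz_eq_week,6.0,7.0,6.0,7.0
soy_products,oz_eq_week,8.0,9.0,8.0,9.0
nuts_seeds,oz_eq_week,7.0,8.0,7.0,8.0
seafood,oz_eq_week,0.0,0.0,8.0,8.0
oils,g_day,27,27,27,27
discretionary,kcal_day,250,250,250,250
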