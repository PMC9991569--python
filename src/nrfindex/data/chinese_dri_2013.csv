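nutrient_id,unit,sex,age_min,age_max,value,basis
energy,kcal,male,18,49,2250,RNI
energy,kcal,male,50,100,2100,RNI
energy,kcal,female,18,49,1800,RNI
energy,kcal,female,50,100,1750,RNI
protein,g,male,18,100,65,RNI
protein,g,female,18,100,55,RNI
fibre,g,any,18,100,25,AI
vitamin_a,ug_rae,male,18,100,800,RNI
vitamin_a,ug_rae,female,18,100,700,RNI
vitamin_c,mg,any,18,100,100,RNI
vitamin_e,mg,any,18,100,14,AI
vitamin_b12,ug,any,18,100,2.4,RNI
calcium,mg,any,18,49,800,RNI
calcium,mg,any,50,100,1000,RNI
iron,mg,male,18,100,12,RNI
iron,mg,female,18,49,20,RNI
iron,mg,female,50,100,12,RNI
magnesium,mg,any,18,100,330,RNI
potassium,mg,any,18,100,2000,AI
zinc,mg,male,18,100,12.5,RNI
zinc,mg,female,18,100,7.5,RNI
phosphorus,mg,any,18,100,720,RNI
vitamin_b1,mg,male,18,100,1.4,RNI
vitamin_b1,mg,female,18,100,1.2,RNI
vitamin_b2,mg,male,18,100,1.4,RNI
vitamin_b2,mg,female,18,100,1.2,RNI
niacin,mg_ne,male,18,100,15,RNI
niacin,mg_ne,female,18,100,12,RNI
sat_fat,g,any,18,100,0.10,AMDR_fraction_of_energy
sodium,mg,any,18,100,2000,MRV
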