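id,name,incident_population,population_definition,cost_50,cost_80,cost_95,dalys_50,dalys_80,dalys_95
newborn_care,Community newborn care package,27662,Population 0-27 days of age,0.089,0.145,0.179,0.011,0.017,0.020
tetanus_toxoid,Tetanus toxoid,1067218,Population <1 year,0.058,0.118,0.194,0.005,0.007,0.009
syphilis_screening,Screening and treatment of syphilis,595029,Percentage of women 15-49 currently pregnant * population female 15-49,0.034,0.070,0.119,0.000,0.001,0.001
skilled_delivery,Normal delivery by a skilled attendant,595029,Percentage of women 15-49 currently pregnant * population female 15-49,0.157,0.259,0.334,0.004,0.007,0.008
maternal_sepsis,Management of maternal sepsis,70148,Incidence of maternal sepsis and other maternal infections,0.088,0.154,0.219,0.001,0.001,0.002
newborn_infections,Management of serious newborn infections,11264,Incidence of neonatal sepsis and other neonatal infections,0.150,0.268,0.403,0.003,0.004,0.005
measles_rubella,Measles rubella vaccine,1067218,Population <1 year,0.100,0.162,0.224,0.001,0.003,0.003
itn,Insecticide-treated bed nets (ITN),595029,Percentage of women 15-49 currently pregnant * population female 15-49,0.474,0.629,0.710,0.010,0.015,0.017
iptp,Intermittent presumptive treatment in pregnancy (IPTP),595029,Percentage of women 15-49 currently pregnant * population female 15-49,0.054,0.057,0.060,0.000,0.000,0.000
malaria_act,Case management of malaria with artemisinin-based combination therapy (ACT),8375236,Incidence of malaria,0.192,0.203,0.211,0.009,0.015,0.017
tb_dots,Treatment of new smear-positive TB cases only under DOTS,112918,Incidence of TB,0.428,0.768,1.069,0.068,0.109,0.130
vitamin_a_pregnancy,Vitamin A supplementation in pregnant women,595029,Percentage of women 15-49 currently pregnant * population female 15-49,0.077,0.394,0.725,0.001,0.002,0.003
severe_malnutrition,Management of severe malnutrition (children),122555,Incidence of protein-energy malnutrition among children under-5,5.039,8.085,9.651,0.000,0.000,0.000
vitamin_a_children,Vitamin A supplementation in infants and children 6-59 months,1118095,Incidence of vitamin A deficiency among children 6-59 months,0.077,0.394,0.725,0.001,0.002,0.003
pneumonia_children,Pneumonia treatment (children),462121,Incidence of pneumonia among children under-5,0.273,0.502,0.722,0.004,0.007,0.008
zinc,Zinc,1242620,Incidence of nutritional deficiencies,0.057,0.089,0.111,0.000,0.001,0.001
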