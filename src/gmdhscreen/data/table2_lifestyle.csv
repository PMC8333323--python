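feature,category,outcome,count_no,count_yes,p_value
sleep_cat,<=5h,worriedness,25,27,<0.001
sleep_cat,5-8h,worriedness,1629,678,<0.001
sleep_cat,>8h,worriedness,6242,1749,<0.001
sleep_cat,<=5h,depression,32,20,<0.001
sleep_cat,5-8h,depression,1736,571,<0.001
sleep_cat,>8h,depression,6502,1489,<0.001
sleep_cat,<=5h,mild_moderate,37,15,<0.001
sleep_cat,5-8h,mild_moderate,1953,354,<0.001
sleep_cat,>8h,mild_moderate,7215,776,<0.001
screen_cat,<=4h,worriedness,6600,1879,<0.001
screen_cat,>4h,worriedness,1296,575,<0.001
screen_cat,<=4h,depression,6865,1614,<0.001
screen_cat,>4h,depression,1405,466,<0.001
screen_cat,<=4h,mild_moderate,7653,826,<0.001
screen_cat,>4h,mild_moderate,1552,319,<0.001
physical_activity,mild,worriedness,2408,986,<0.001
physical_activity,moderate,worriedness,3026,860,<0.001
physical_activity,severe,worriedness,2462,608,<0.001
physical_activity,mild,depression,2599,795,<0.001
physical_activity,moderate,depression,3131,755,<0.001
physical_activity,severe,depression,2540,530,<0.001
physical_activity,mild,mild_moderate,2858,536,<0.001
physical_activity,moderate,mild_moderate,3500,386,<0.001
physical_activity,severe,mild_moderate,2847,223,<0.001
srh,good,worriedness,6299,1800,0.534
srh,moderate,worriedness,1481,303,0.534
srh,bad,worriedness,116,351,0.534
srh,good,depression,6612,1200,0.139
srh,moderate,depression,1523,401,0.139
srh,bad,depression,135,479,0.139
srh,good,mild_moderate,7364,704,0.644
srh,moderate,mild_moderate,1703,200,0.644
srh,bad,mild_moderate,138,241,0.644
breakfast_cat,non_skipper,worriedness,5719,1427,<0.001
breakfast_cat,semi_skipper,worriedness,939,402,<0.001
breakfast_cat,skipper,worriedness,1238,625,<0.001
breakfast_cat,non_skipper,depression,5900,1246,<0.001
breakfast_cat,semi_skipper,depression,1051,290,<0.001
breakfast_cat,skipper,depression,1319,544,<0.001
breakfast_cat,non_skipper,mild_moderate,6523,623,<0.001
breakfast_cat,semi_skipper,mild_moderate,1172,169,<0.001
breakfast_cat,skipper,mild_moderate,1510,353,<0.001
body_image,underweight,worriedness,2679,800,<0.001
body_image,normal,worriedness,3817,1086,<0.001
body_image,overweight,worriedness,1400,568,<0.001
body_image,underweight,depression,2817,662,<0.001
body_image,normal,depression,3978,925,<0.001
body_image,overweight,depression,1475,493,<0.001
body_image,underweight,mild_moderate,3088,391,<0.001
body_image,normal,mild_moderate,4443,460,<0.001
body_image,overweight,mild_moderate,1674,294,<0.001
n_friends_cat,0,worriedness,155,67,0.003
n_friends_cat,1,worriedness,1096,397,0.003
n_friends_cat,2,worriedness,1878,581,0.003
n_friends_cat,3+,worriedness,4767,1409,0.003
n_friends_cat,0,depression,169,53,0.070
n_friends_cat,1,depression,1181,312,0.070
n_friends_cat,2,depression,2005,454,0.070
n_friends_cat,3+,depression,4915,1261,0.070
n_friends_cat,0,mild_moderate,189,33,<0.001
n_friends_cat,1,mild_moderate,1299,194,<0.001
n_friends_cat,2,mild_moderate,2156,303,<0.001
n_friends_cat,3+,mild_moderate,5561,615,<0.001
diet_plan,no,worriedness,6999,2046,<0.001
diet_plan,yes,worriedness,897,408,<0.001
diet_plan,no,depression,7326,1719,<0.001
diet_plan,yes,depression,944,361,<0.001
diet_plan,no,mild_moderate,8101,944,<0.001
diet_plan,yes,mild_moderate,1104,201,<0.001
salty_snack,seldom_never,worriedness,4118,1183,<0.001
salty_snack,weekly,worriedness,2903,902,<0.001
salty_snack,daily,worriedness,875,369,<0.001
salty_snack,seldom_never,depression,4276,1025,<0.001
salty_snack,weekly,depression,3062,743,<0.001
salty_snack,daily,depression,932,312,<0.001
salty_snack,seldom_never,mild_moderate,4788,513,<0.001
salty_snack,weekly,mild_moderate,3375,430,<0.001
salty_snack,daily,mild_moderate,1042,202,<0.001
sweetened_beverage,seldom_never,worriedness,4981,257,<0.001
sweetened_beverage,weekly,worriedness,2436,787,<0.001
sweetened_beverage,daily,worriedness,479,1410,<0.001
sweetened_beverage,seldom_never,depression,5184,223,<0.001
sweetened_beverage,weekly,depression,2573,650,<0.001
sweetened_beverage,daily,depression,513,1207,<0.001
sweetened_beverage,seldom_never,mild_moderate,6860,130,<0.001
sweetened_beverage,weekly,mild_moderate,2851,372,<0.001
sweetened_beverage,daily,mild_moderate,5748,643,<0.001
fast_food,seldom_never,worriedness,5915,1698,<0.001
fast_food,weekly,worriedness,1802,652,<0.001
fast_food,daily,worriedness,179,104,<0.001
fast_food,seldom_never,depression,6161,1452,<0.001
fast_food,weekly,depression,1915,539,<0.001
fast_food,daily,depression,194,89,<0.001
fast_food,seldom_never,mild_moderate,606,753,<0.001
fast_food,weekly,mild_moderate,2124,330,<0.001
fast_food,daily,mild_moderate,221,62,<0.001
smoker,no,worriedness,4453,1139,<0.001
smoker,yes,worriedness,3443,1315,<0.001
smoker,no,depression,4656,936,<0.001
smoker,yes,depression,3614,1144,<0.001
smoker,no,mild_moderate,5111,481,<0.001
smoker,yes,mild_moderate,4094,664,<0.001
life_satisfaction_cat,low,worriedness,1241,1715,<0.001
life_satisfaction_cat,high,worriedness,6655,739,<0.001
life_satisfaction_cat,low,depression,1313,1413,<0.001
life_satisfaction_cat,high,depression,6957,667,<0.001
life_satisfaction_cat,low,mild_moderate,1537,702,<0.001
life_satisfaction_cat,high,mild_moderate,7668,443,<0.001
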