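feature,category,outcome,count_no,count_yes,p_value
family_size_cat,<=4,worriedness,4035,1125,<0.001
family_size_cat,>4,worriedness,3861,1329,<0.001
family_size_cat,<=4,depression,4166,994,0.035
family_size_cat,>4,depression,4104,1086,0.035
family_size_cat,<=4,mild_moderate,4667,493,<0.001
family_size_cat,>4,mild_moderate,4538,652,<0.001
residence,urban,worriedness,5888,1985,<0.001
residence,rural,worriedness,2008,469,<0.001
residence,urban,depression,6168,1705,<0.001
residence,rural,depression,2102,375,<0.001
residence,urban,mild_moderate,6946,927,<0.001
residence,rural,mild_moderate,2259,218,<0.001
sex,boy,worriedness,4112,1069,<0.001
sex,girl,worriedness,3784,1385,<0.001
sex,boy,depression,4224,957,<0.001
sex,girl,depression,4046,1123,<0.001
sex,boy,mild_moderate,4720,461,<0.001
sex,girl,mild_moderate,4485,684,<0.001
ses,weak,worriedness,2440,800,0.179
ses,moderate,worriedness,2647,825,0.179
ses,good,worriedness,2809,829,0.179
ses,weak,depression,2584,656,0.948
ses,moderate,depression,2780,692,0.948
ses,good,depression,2906,732,0.948
ses,weak,mild_moderate,2833,407,0.005
ses,moderate,mild_moderate,3109,363,0.005
ses,good,mild_moderate,3263,375,0.005
bmi_cat,underweight,worriedness,978,270,0.050
bmi_cat,healthy,worriedness,5239,1617,0.050
bmi_cat,overweight_obese,worriedness,1679,567,0.050
bmi_cat,underweight,depression,993,255,0.041
bmi_cat,healthy,depression,5523,1333,0.041
bmi_cat,overweight_obese,depression,1754,492,0.041
bmi_cat,underweight,mild_moderate,1108,140,0.980
bmi_cat,healthy,mild_moderate,6098,758,0.980
bmi_cat,overweight_obese,mild_moderate,1999,247,0.980
age_cat,6-10,worriedness,3071,416,<0.001
age_cat,11-14,worriedness,2711,916,<0.001
age_cat,15-19,worriedness,2114,1122,<0.001
age_cat,6-10,depression,3111,376,<0.001
age_cat,11-14,depression,2898,729,<0.001
age_cat,15-19,depression,2261,975,<0.001
age_cat,6-10,mild_moderate,3342,145,<0.001
age_cat,11-14,mild_moderate,3208,419,<0.001
age_cat,15-19,mild_moderate,2655,581,<0.001
abdominal_obesity,no,worriedness,6396,1942,0.042
abdominal_obesity,yes,worriedness,1500,512,0.042
abdominal_obesity,no,depression,6703,1635,0.013
abdominal_obesity,yes,depression,1567,445,0.013
abdominal_obesity,no,mild_moderate,7426,912,0.412
abdominal_obesity,yes,mild_moderate,1779,233,0.412
mother_education,illiterate,worriedness,1120,401,<0.001
mother_education,diploma,worriedness,6013,1870,<0.001
mother_education,university,worriedness,763,183,<0.001
mother_education,illiterate,depression,1202,319,0.064
mother_education,diploma,depression,6286,1597,0.064
mother_education,university,depression,782,164,0.064
mother_education,illiterate,mild_moderate,1316,205,0.001
mother_education,diploma,mild_moderate,7026,857,0.001
mother_education,university,mild_moderate,863,83,0.001
birth_weight_cat,<2500g,worriedness,705,251,0.042
birth_weight_cat,2500-4000g,worriedness,6624,2000,0.042
birth_weight_cat,>4000g,worriedness,567,203,0.042
birth_weight_cat,<2500g,depression,755,201,0.423
birth_weight_cat,2500-4000g,depression,6915,1709,0.423
birth_weight_cat,>4000g,depression,600,170,0.423
birth_weight_cat,<2500g,mild_moderate,831,125,0.109
birth_weight_cat,2500-4000g,mild_moderate,7696,928,0.109
birth_weight_cat,>4000g,mild_moderate,678,92,0.109
milk_type,others,worriedness,1226,389,0.699
milk_type,mother_milk,worriedness,6670,2065,0.699
milk_type,others,depression,1297,318,0.657
milk_type,mother_milk,depression,6973,1762,0.657
milk_type,others,mild_moderate,1430,185,0.586
milk_type,mother_milk,mild_moderate,7775,960,0.586
fh_sudden_death,no,worriedness,6940,2122,0.065
fh_sudden_death,yes,worriedness,956,332,0.065
fh_sudden_death,no,depression,7271,1791,0.027
fh_sudden_death,yes,depression,999,289,0.027
fh_sudden_death,no,mild_moderate,8084,978,0.023
fh_sudden_death,yes,mild_moderate,1121,167,0.023
fh_cancer,no,worriedness,6727,2082,0.668
fh_cancer,yes,worriedness,1169,372,0.668
fh_cancer,no,depression,7081,1728,0.004
fh_cancer,yes,depression,1189,352,0.004
fh_cancer,no,mild_moderate,7848,961,0.238
fh_cancer,yes,mild_moderate,1357,184,0.238
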