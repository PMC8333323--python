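# Feature registry for the 25-variable school-survey model matrix.
# Order and short ids follow the conventional x1..x25 wiring of the
# interaction-network figures; `ordered: true` marks ordinal scales and the
# level list is in ascending order of the scale.
features:
  - {name: sleep_cat,           ordered: true,  levels: ["<=5h", "5-8h", ">8h"]}
  - {name: screen_cat,          ordered: true,  levels: ["<=4h", ">4h"]}
  - {name: family_size_cat,     ordered: true,  levels: ["<=4", ">4"]}
  - {name: life_satisfaction_cat, ordered: true, levels: ["low", "high"]}
  - {name: residence,           ordered: false, levels: ["urban", "rural"]}
  - {name: sex,                 ordered: false, levels: ["boy", "girl"]}
  - {name: physical_activity,   ordered: true,  levels: ["mild", "moderate", "severe"]}
  - {name: ses,                 ordered: true,  levels: ["weak", "moderate", "good"]}
  - {name: srh,                 ordered: true,  levels: ["good", "moderate", "bad"]}
  - {name: bmi_cat,             ordered: true,  levels: ["underweight", "healthy", "overweight_obese"]}
  - {name: breakfast_cat,       ordered: true,  levels: ["non_skipper", "semi_skipper", "skipper"]}
  - {name: body_image,          ordered: true,  levels: ["underweight", "normal", "overweight"]}
  - {name: age_cat,             ordered: true,  levels: ["6-10", "11-14", "15-19"]}
  - {name: n_friends_cat,       ordered: true,  levels: ["0", "1", "2", "3+"]}
  - {name: diet_plan,           ordered: false, levels: ["no", "yes"]}
  - {name: salty_snack,         ordered: true,  levels: ["seldom_never", "weekly", "daily"]}
  - {name: sweetened_beverage,  ordered: true,  levels: ["daily", "weekly", "seldom_never"]}
  - {name: fast_food,           ordered: true,  levels: ["seldom_never", "weekly", "daily"]}
  - {name: smoker,              ordered: false, levels: ["no", "yes"]}
  - {name: abdominal_obesity,   ordered: false, levels: ["no", "yes"]}
  - {name: mother_education,    ordered: true,  levels: ["illiterate", "diploma", "university"]}
  - {name: birth_weight_cat,    ordered: true,  levels: ["<2500g", "2500-4000g", ">4000g"]}
  - {name: milk_type,           ordered: false, levels: ["others", "mother_milk"]}
  - {name: fh_sudden_death,     ordered: false, levels: ["no", "yes"]}
  - {name: fh_cancer,           ordered: false, levels: ["no", "yes"]}

# Ordinal response scales for the seven symptom items.
items:
  q_frequency: ["never", "rarely", "once_a_week", "more_than_once_a_week", "every_day"]
  q6: ["no", "yes"]
  q7: ["never", "rarely", "sometimes", "most_of_the_time", "always"]

outcomes: [depression, worriedness, mild_moderate, psychiatric, extended]
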