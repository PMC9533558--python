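# Fruit-and-vegetable serving registry (SYNTHETIC food-code vocabulary).
#
# Maps a coded food record to a food group and a guideline serving size in
# grams. `excluded` items (e.g. fruit-containing sweets where fruit is not
# the main ingredient) contribute zero servings. Codes are synthetic
# stand-ins for a real seven-digit food-coding scheme.
codes:
  "1100": {group: fruit,     serving_size_g: 150, label: raw apple}
  "1101": {group: fruit,     serving_size_g: 120, label: banana}
  "1102": {group: fruit,     serving_size_g: 150, label: orange}
  "1103": {group: fruit,     serving_size_g: 145, label: grapes}
  "1104": {group: fruit,     serving_size_g: 165, label: cubed melon}
  "2100": {group: vegetable, serving_size_g: 80,  label: cooked broccoli}
  "2101": {group: vegetable, serving_size_g: 90,  label: carrots}
  "2102": {group: vegetable, serving_size_g: 85,  label: raw leafy greens}
  "2103": {group: vegetable, serving_size_g: 80,  label: tomato}
  "2104": {group: vegetable, serving_size_g: 95,  label: mixed dish with vegetable main ingredient}
  "9100": {group: excluded,  serving_size_g: null, label: fruit pastry where fruit is not the main ingredient}
  "9101": {group: excluded,  serving_size_g: null, label: fruit-flavored candy}
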