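# Behavioral tips keyed by index component; selection cycles deterministically
# by study-day index so generated fixtures are stable.
total_fat:
  - "Try grilling or baking instead of frying to cut total fat."
  - "Choose lean cuts of meat and trim visible fat before cooking."
potassium:
  - "Bananas, potatoes and beans are easy ways to boost potassium."
  - "Add a serving of leafy greens or winter squash for extra potassium."
sodium:
  - "Check labels for sodium - canned soups and deli meats add up fast."
  - "Season with herbs, citrus or vinegar instead of salt."
magnesium:
  - "Nuts, seeds and whole grains are great magnesium sources."
  - "A handful of almonds or spinach salad adds magnesium to your day."
calcium:
  - "Low-fat dairy, fortified plant milks and tofu all add calcium."
  - "Try yogurt with fruit as a calcium-rich snack."
saturated_fat:
  - "Swap butter for olive or canola oil to lower saturated fat."
  - "Choose low-fat dairy versions to trim saturated fat."
protein:
  - "Add beans, fish or skinless poultry to reach your protein target."
  - "Greek yogurt or eggs can boost protein at breakfast."
cholesterol:
  - "Limit egg yolks and organ meats to keep cholesterol down."
  - "Swap some animal protein for beans or lentils to cut cholesterol."
fiber:
  - "Whole grains, beans and berries are fiber powerhouses."
  - "Swap white bread and rice for whole-grain versions to add fiber."
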