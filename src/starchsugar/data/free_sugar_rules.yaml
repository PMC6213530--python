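# Ordered free-sugar classification rules; first match wins.
# outcome: NONE_FREE | ALL_FREE | FRACTION | FROM_RECIPE
- ordinal: 10
  match:
    groups: ["sugars and jams", "confectionaries", "sugar-sweetened beverages", "fruit juices"]
  outcome: ALL_FREE
- ordinal: 20
  match:
    name_regex: "honey|syrup"
  outcome: ALL_FREE
- ordinal: 30
  match:
    groups: ["fruits", "vegetables", "mushrooms", "seaweeds", "potatoes", "pulses and nuts"]
    forms: ["raw", "cooked"]
  outcome: NONE_FREE
- ordinal: 35
  match:
    groups: ["dairy products"]
    name_regex: "sweetened|dessert|flavou?red"
  outcome: FRACTION
  fraction: 0.5
- ordinal: 40
  match:
    groups: ["dairy products"]
  outcome: NONE_FREE
- ordinal: 50
  match:
    groups: ["rice and grains", "other grain products", "noodle", "eggs", "fish and shellfish", "meats", "fat and oil", "vegetable juices", "tea and coffee", "alcoholic beverages"]
    forms: ["raw", "cooked"]
  outcome: NONE_FREE
- ordinal: 60
  match:
    groups: ["bread", "seasonings", "other foods"]
  outcome: FROM_RECIPE
- ordinal: 65
  match:
    groups: ["bread", "seasonings", "other foods"]
  outcome: FRACTION
  fraction: 0.5
- ordinal: 70
  match:
    forms: ["processed"]
  outcome: FRACTION
  fraction: 0.5
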