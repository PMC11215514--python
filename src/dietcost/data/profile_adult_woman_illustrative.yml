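# ILLUSTRATIVE requirement profile for a non-pregnant, non-breastfeeding
# adult woman. Values are plausible orders of magnitude chosen so the
# bundled examples and synthetic fixtures are exercised end to end; they are
# NOT authoritative dietary reference intakes and must not be used for real
# assessments. Supply a profile vetted by a nutritionist for real work.
group_label: adult_woman_illustrative
energy_target_kcal: 2330
bounds:
  protein: {lower: 46, upper: 250}
  fat: {lower: 26, upper: 104}
  carbohydrate: {lower: 100, upper: null}
  fiber: {lower: 25, upper: null}
  vitamin_a: {lower: 500, upper: 3000}
  vitamin_c: {lower: 60, upper: 2000}
  vitamin_d: {lower: 10, upper: 100}
  vitamin_e: {lower: 12, upper: 1000}
  thiamin: {lower: 0.9, upper: null}
  riboflavin: {lower: 0.9, upper: null}
  niacin: {lower: 11, upper: 900}
  vitamin_b6: {lower: 1.1, upper: 100}
  folate: {lower: 320, upper: 1500}
  vitamin_b12: {lower: 2.0, upper: null}
  calcium: {lower: 800, upper: 2500}
  iron: {lower: 18, upper: 45}
  zinc: {lower: 8, upper: 40}
  magnesium: {lower: 265, upper: null}
  potassium: {lower: 2600, upper: null}
  sodium: {lower: 500, upper: 2300}
  copper: {lower: 0.7, upper: 10}
  selenium: {lower: 45, upper: 400}
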