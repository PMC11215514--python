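# Default Healthy Diet Basket: 11 items across six food groups, 2330
# kcal/day total. Item counts follow the global basket (2 starchy staples,
# 3 vegetables, 2 fruits, 2 animal-source foods, 1 legumes/nuts/seeds,
# 1 fats/oils). Per-group energy allocations are taken from the published
# HDB methodology (externally sourced configuration, editable per country).
total_energy_kcal: 2330
groups:
  starchy_staples: {items: 2, energy_kcal: 1160}
  vegetables: {items: 3, energy_kcal: 110}
  fruits: {items: 2, energy_kcal: 160}
  animal_source_foods: {items: 2, energy_kcal: 300}
  legumes_nuts_seeds: {items: 1, energy_kcal: 300}
  fats_oils: {items: 1, energy_kcal: 300}
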