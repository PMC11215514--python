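# Default nutrient configuration: 22 essential nutrients tracked by the
# nutrient-adequacy optimizer. Amounts in composition tables are per 100 g
# edible portion in the unit declared here; requirement bounds use the same
# unit per day. The list is configuration, not code: supply your own file
# with the same schema to track a different set.
nutrients:
  - {name: protein, unit: g}
  - {name: fat, unit: g}
  - {name: carbohydrate, unit: g}
  - {name: fiber, unit: g}
  - {name: vitamin_a, unit: ug_rae}
  - {name: vitamin_c, unit: mg}
  - {name: vitamin_d, unit: ug}
  - {name: vitamin_e, unit: mg}
  - {name: thiamin, unit: mg}
  - {name: riboflavin, unit: mg}
  - {name: niacin, unit: mg}
  - {name: vitamin_b6, unit: mg}
  - {name: folate, unit: ug_dfe}
  - {name: vitamin_b12, unit: ug}
  - {name: calcium, unit: mg}
  - {name: iron, unit: mg}
  - {name: zinc, unit: mg}
  - {name: magnesium, unit: mg}
  - {name: potassium, unit: mg}
  - {name: sodium, unit: mg}
  - {name: copper, unit: mg}
  - {name: selenium, unit: ug}
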