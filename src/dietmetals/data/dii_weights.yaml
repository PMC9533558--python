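# Dietary inflammatory index component registry.
#
# 24 components scored from a single 24-hour recall. `weight` is the
# component's inflammatory weight oriented so that a POSITIVE contribution is
# ANTI-inflammatory (higher total score = more anti-inflammatory diet).
# These weights are SYNTHETIC placeholders with plausible signs and
# magnitudes; replace with literature-derived values for substantive use.
# `energy_adjust: true` means the intake is expressed per 1000 kcal before
# standardization (density method).
# `unit` is the native daily-intake unit of the component column.
components:
  - {name: carbohydrates,           weight: -0.10, energy_adjust: true,  unit: g}
  - {name: proteins,                weight:  0.02, energy_adjust: true,  unit: g}
  - {name: alcohol,                 weight:  0.10, energy_adjust: false, unit: g}
  - {name: fibers,                  weight:  0.50, energy_adjust: true,  unit: g}
  - {name: cholesterol,             weight: -0.30, energy_adjust: true,  unit: mg}
  - {name: saturated_fatty_acids,   weight: -0.40, energy_adjust: true,  unit: g}
  - {name: monounsaturated_fatty_acids, weight: 0.01, energy_adjust: true, unit: g}
  - {name: omega_3,                 weight:  0.45, energy_adjust: true,  unit: g}
  - {name: omega_6,                 weight: -0.10, energy_adjust: true,  unit: g}
  - {name: niacin,                  weight:  0.25, energy_adjust: true,  unit: mg}
  - {name: thiamin,                 weight:  0.10, energy_adjust: true,  unit: mg}
  - {name: riboflavin,              weight:  0.07, energy_adjust: true,  unit: mg}
  - {name: vitamin_b6,              weight:  0.35, energy_adjust: true,  unit: mg}
  - {name: vitamin_b12,             weight: -0.10, energy_adjust: true,  unit: ug}
  - {name: iron,                    weight: -0.03, energy_adjust: true,  unit: mg}
  - {name: magnesium,               weight:  0.45, energy_adjust: true,  unit: mg}
  - {name: zinc,                    weight:  0.30, energy_adjust: true,  unit: mg}
  - {name: vitamin_a,               weight:  0.40, energy_adjust: true,  unit: ug_rae}
  - {name: vitamin_c,               weight:  0.40, energy_adjust: true,  unit: mg}
  - {name: vitamin_d,               weight:  0.45, energy_adjust: true,  unit: ug}
  - {name: vitamin_e,               weight:  0.40, energy_adjust: true,  unit: mg}
  - {name: folic_acid,              weight:  0.20, energy_adjust: true,  unit: ug}
  - {name: beta_carotene,           weight:  0.40, energy_adjust: true,  unit: ug}
  - {name: caffeine,                weight:  0.10, energy_adjust: false, unit: mg}
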