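# Aedes vexans — floodwater mosquito.
# Development power laws d = A * T^(-a): exponents from the rearing
# literature; the A coefficients are stand-ins anchored so embryogenesis
# takes ~3 days and the larval/pupal stage ~8 days at 25 degC.
name: ae_vexans
development:
  embryo: {A: 1360.0, a: 1.90}   # 1360 * 25^-1.90 ~= 3.0 d
  larva: {A: 3190.0, a: 1.86}    # 3190 * 25^-1.86 ~= 8.0 d
  stage_time_sd: 1.0             # days
  temp_floor: 1.0                # degC clamp before the power law
gonotrophic:
  mean: {type: constant, value: 10.0}  # days
  sd: 1.0
  bounds: [7.0, 13.0]            # truncation of the cycle-length normal
survival:
  egg: 0.999                     # daily, baseline (eggs are drought-hardy)
  larva: {type: quadratic, opt: 25.0, peak: 0.95, half_width: 35.0}
  adult: {type: quadratic, opt: 25.0, peak: 0.90, half_width: 30.0}
  dry_penalty: 0.9               # multiplier when 10-day precip < threshold
  dry_threshold_mm: 1.0
density_dependence:
  egg_slope: 1.0e-6              # per-capita linear decline, 1/individuals
  larva_slope: 2.0e-5
bloodmeal:
  type: linear_humidity          # p = intercept + slope * rh10, clipped [0,1]
  intercept: -0.2
  slope: 0.01
eggs_per_batch:
  mean_intercept: 80.0           # eggs at zero rain
  mean_slope_per_mm: 5.0         # extra eggs per mm/day of rain
  sd: 20.0
female_fraction: 0.5
overwinter_stage: egg
diapause_temp: 15.0              # degC on the 10-day mean; autumn eggs hold over
hatch_rain_threshold_mm: 5.0     # embryonated eggs hatch when inundated
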