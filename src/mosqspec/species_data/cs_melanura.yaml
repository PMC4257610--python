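# Culiseta melanura — slow-developing swamp breeder.
# Development power laws d = A * T^(-a): exponents from the rearing
# literature (the printed embryogenesis exponent 0.30 is kept as published;
# swap here if it proves a truncation of 2.30).  A coefficients are
# stand-ins anchored to this species' exceptionally slow larval
# development in cool swamp crypts: months-long, ~165 days at 18 degC
# (~80 days at 25 degC).
name: cs_melanura
development:
  embryo: {A: 12.0, a: 0.30}      # 12 * 18^-0.30 ~= 5.0 d
  larva: {A: 110000.0, a: 2.25}   # 110000 * 18^-2.25 ~= 165 d
  stage_time_sd: 1.0
  temp_floor: 1.0
gonotrophic:
  mean: {type: linear_temp, intercept: 28.0, slope: -0.75, min: 1.0}
  sd: 1.0
  bounds: null                   # unbounded; sampler floors at 1 day
survival:
  egg: 0.998
  larva: {type: constant, value: 1.0}  # 1 under zero crowding, wet conditions
  adult: {type: quadratic, opt: 24.0, peak: 0.92, half_width: 30.0}
  dry_penalty: 0.97              # swamp crypts buffer dry spells
  dry_threshold_mm: 1.0
density_dependence:
  egg_slope: 1.0e-6
  larva_slope: 3.0e-6             # weak crowding: larvae spread over months
bloodmeal:
  type: quadratic_temp           # p = coeff * t10^2, clipped [0,1]
  coeff: 0.0016
eggs_per_batch:
  mean_intercept: 100.0
  mean_slope_per_mm: 5.0
  sd: 20.0
female_fraction: 0.5
overwinter_stage: larva
diapause_temp: 10.0
hatch_rain_threshold_mm: null    # permanent-water breeder: hatch on maturity
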