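# Long laboratory experiment: 8 worms fed 100 g at days 0, 161 and 315;
# 10 surviving adults transferred to fresh substrate on day 161.
# Initial mass is not printed; hatchling mass (Mb) is used (growth study).
name: gunadi2002
replicates: 4
duration_days: 400
arena_m2: 0.08
environment:
  mode: fixed
  temperature_c: 20
  moisture_pct: 80
initial_population:
  - stage: juvenile
    count: 8
    mass_g: 0.011
feeding:
  - {day: 0, grams: 100}
  - {day: 161, grams: 100}
  - {day: 315, grams: 100}
transfer:
  day: 161
  n_adults: 10
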