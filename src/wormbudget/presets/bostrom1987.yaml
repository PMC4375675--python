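# Laboratory growth experiment: 5 hatchling-sized worms, a single 150 g
# feed at day 0, 0.08 m^2 arena at 20 C / 80% soil moisture.
# Initial mass is not printed in the source; hatchling mass (Mb) is used
# because this is a growth-from-young experiment.
name: bostrom1987
replicates: 3
duration_days: 200
arena_m2: 0.08
environment:
  mode: fixed
  temperature_c: 20
  moisture_pct: 80
initial_population:
  - stage: juvenile
    count: 5
    mass_g: 0.011
feeding:
  - {day: 0, grams: 150}
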