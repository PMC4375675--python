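# Reproduction under optimal feeding: 10 worms aged 25 days, fed 20 g
# every 20 days in a 0.04 m^2 arena at 25 C.
name: reinecke1990_optimal
replicates: 4
duration_days: 200
arena_m2: 0.04
environment:
  mode: fixed
  temperature_c: 25
  moisture_pct: 80
initial_population:
  - stage: adult
    count: 10
    mass_g: 0.2914
feeding:
  - {day: 0, grams: 20}
  - {day: 20, grams: 20}
  - {day: 40, grams: 20}
  - {day: 60, grams: 20}
  - {day: 80, grams: 20}
  - {day: 100, grams: 20}
  - {day: 120, grams: 20}
  - {day: 140, grams: 20}
  - {day: 160, grams: 20}
  - {day: 180, grams: 20}
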