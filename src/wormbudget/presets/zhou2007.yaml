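# Chlorpyrifos toxicity test: 10 worms, 5 g feeds at days 0 and 28,
# 0.08 m^2 arena at 20 C.  Initial adult mass is a documented guess (0.30 g).
name: zhou2007
replicates: 4
duration_days: 56
arena_m2: 0.08
environment:
  mode: fixed
  temperature_c: 20
  moisture_pct: 80
initial_population:
  - stage: adult
    count: 10
    mass_g: 0.30
feeding:
  - {day: 0, grams: 5}
  - {day: 28, grams: 5}
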