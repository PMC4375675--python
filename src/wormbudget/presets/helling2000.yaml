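# Copper oxychloride toxicity test under near-optimal feeding: 10 worms,
# feeds 75/30/30/30 g at days 0/35/42/49, 0.06 m^2 arena at 25 C.
# Initial mass is a documented guess (young adults, 0.30 g); the source
# does not print starting masses.
name: helling2000
replicates: 4
duration_days: 70
arena_m2: 0.06
environment:
  mode: fixed
  temperature_c: 25
  moisture_pct: 80
initial_population:
  - stage: adult
    count: 10
    mass_g: 0.30
feeding:
  - {day: 0, grams: 75}
  - {day: 35, grams: 30}
  - {day: 42, grams: 30}
  - {day: 49, grams: 30}
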