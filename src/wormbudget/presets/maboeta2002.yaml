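# Copper oxychloride test under severely limited food: 20 adults with a
# single 0.54 g feed in a 0.08 m^2 arena at 25 C; biomass declines
# throughout.  Initial adult mass is a documented guess (0.35 g).
name: maboeta2002
replicates: 3
duration_days: 56
arena_m2: 0.08
environment:
  mode: fixed
  temperature_c: 25
  moisture_pct: 80
initial_population:
  - stage: adult
    count: 20
    mass_g: 0.35
feeding:
  - {day: 0, grams: 0.54}
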