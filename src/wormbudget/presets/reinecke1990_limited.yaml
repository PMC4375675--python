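# Reproduction under limiting, pulsed feeding: 10 worms aged 25 days,
# fed 10/50/25 g at days 10/60/140 in a 0.04 m^2 arena at 25 C.
# Initial mass is the von Bertalanffy mass at age 25 days (0.2914 g).
name: reinecke1990_limited
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
  - {day: 10, grams: 10}
  - {day: 60, grams: 50}
  - {day: 140, grams: 25}
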