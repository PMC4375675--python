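# Seasonal field scenario: a 1 m^2 slice of a temporary cow-manure heap.
# Soil temperature/moisture and manure stocks follow the derived seasonal
# values; daily variation SD 5 C (temperature) and 10 points (moisture),
# patch food replenished at season boundaries with SD 10% of the mean.
name: field_manure_heap
replicates: 4
duration_days: 3650
arena_m2: 1.0
environment:
  mode: field
initial_population:
  - stage: adult
    count: 50
  - stage: juvenile
    count: 100
  - stage: cocoon
    count: 100
record_events: false
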