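# wormbudget

An energy-budget agent-based model of *Eisenia fetida* (compost earthworm)
populations, built for mechanistic ecotoxicology: it simulates how
individual physiology — ingestion, maintenance, growth, reproduction,
starvation — responds to food, temperature, moisture and pesticide exposure,
and how population dynamics emerge from those individual budgets.  It is
aimed at ecological modellers and ecotoxicologists who want to interpret
laboratory toxicity tests mechanistically or explore population-level
consequences of sublethal chemical stress.

## The model in brief

Each individual earns assimilated energy `A = Ae · Ex · IGmax · f(T) ·
X/(h+X) · M^(2/3)` from the food density `X` of its 0.01 m² patch, with the
Arrhenius factor `f(T) = exp((−E/k_B)(1/T − 1/Tref))`.  Energy is spent in
strict priority order:

1. maintenance `B = B0 · M^(3/4) · e^(−E/(k_B T))`,
2. reproduction (mated adults), up to `rm · f(T) · M` per day — one cocoon
   per `Mc(Ec+Es)` kJ accumulated,
3. growth, up to the von Bertalanffy increment
   `rB · f(T) · (Mm^(1/3) M^(2/3) − M)` at `Ec+Es` kJ/g,
4. storage as reserve (glycogen), capped at `M·Ec`.

Reserves fund maintenance and reproduction when food runs short, down to
half capacity; past that, tissue is catabolised at `Ec` kJ/g and the worm
dies when its mass falls to the birth mass.  Pesticides act through four
alternative "toxicity submodels" that map an exponential dose-response
`R(C) = e^(k·C)` onto physiological parameters (T1: `IGmax`; T2: `IGmax`,
`rm`; T3: `rB`, `rm`; T4: `B0` raised above 100 mg/kg); candidate submodels
are ranked against observations by small-sample AIC and evidence ratios
`exp(Δᵢ/2)`.  See `docs/methods.md` for the full account.

## Worked example

Simulate a classic laboratory growth experiment (5 hatchlings, one 150 g
food ration, 0.08 m² arena at 20 °C) and rank toxicity submodels from
published AICc differences:

```python
import wormbudget as wb

cfg = wb.load_preset("bostrom1987")          # 5 worms, 150 g feed, 0.08 m2, 20 C
results = wb.run(cfg, seed=1)                # 3 replicates from one master seed

for i, r in enumerate(results):
    print(f"replicate {i}: survival {r.initial_survivors}/{r.n_initial}, "
          f"final mean mass {r.mean_individual_biomass()[-1]:.3f} g, "
          f"cocoons produced {r.cocoons_cum[-1]}")

table = wb.compare({"T1": 30.7, "T2": 34.0, "T3": 0.0, "T4": 34.7})
print(table.to_string(index=False))
```

Output:

```
replicate 0: survival 5/5, final mean mass 0.158 g, cocoons produced 280
replicate 1: survival 5/5, final mean mass 0.194 g, cocoons produced 289
replicate 2: survival 5/5, final mean mass 0.171 g, cocoons produced 273
submodel  aicc  delta  evidence_ratio
      T3   0.0    0.0    1.000000e+00
      T1  30.7   30.7    4.638956e+06
      T2  34.0   34.0    2.415495e+07
      T4  34.7   34.7    3.427751e+07
```

Every initial worm survives the 200 simulated days (the population grows,
depletes the ration, and the worms then shrink by catabolising tissue —
hence the sub-asymptotic final masses), while reproduction continues into
the starvation phase.  In the ranking table, submodel T3 (reproduction and
growth directly stressed) is the best-supported hypothesis; the evidence
ratio says the odds against T1 being the better model are about 4.6
million to one.

The same machinery is available from the shell:

```sh
wormbudget simulate --preset bostrom1987 --seed 1 --out results/
wormbudget fixtures --k-tox -0.005 --noise-cv 0.05 --out dr.csv
wormbudget fit-dr --table dr.csv
wormbudget compare-submodels --obs obs.csv --preset zhou2008 --curves fits.json
wormbudget sensitivity --reps 20 --parameters E,Tref,soil_T --seed 1
```

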