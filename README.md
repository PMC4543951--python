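# trophospec

Trophic-niche and individual diet-specialization analysis for
stomach-content data.

Dietary studies of insectivorous predators ask three related questions:
how wide is the population's trophic niche, which prey are actively
selected given what the environment offers, and do individuals differ in
what they eat?  `trophospec` answers all three for count data (prey items
per predator stomach, prey items per environmental sample), packaged
around its reference case — the Spectacled Salamander *Salamandrina
perspicillata*, a Collembola specialist whose published pooled seasonal
prey table ships with the package.

It is written for ecologists doing stomach-flushing or fecal-content
studies who want a reproducible, seeded, scriptable version of the usual
analysis battery:

- **Diversity**: Shannon–Weaver H (nats), evenness J = H/ln S, Hutcheson's
  t-test for comparing two Shannon indices, ANOSIM on Bray–Curtis
  dissimilarities, Mann–Whitney contrasts.
- **Feeding strategy**: Amundsen-modified Costello metrics — frequency of
  occurrence FO and prey-specific abundance Pi per taxon.
- **Prey selection**: Vanderploeg–Scavia relativized electivity
  E\* = (W − 1/n)/(W + 1/n) with W the normalized forage ratio, an
  availability filter (> 4 environmental individuals) and the
  5th-percentile-of-|E\*| significance rule; logistic resource selection
  probability functions (RSPF) under a use–availability design with
  forward-stepwise AIC ranking and Hosmer–Lemeshow calibration.
- **Condition**: scaled mass index SMI_i = M_i (L0/L_i)^b with b the
  standardized-major-axis allometric slope; foraging intensity FORI.
- **Individual specialization**: the niche decomposition
  TNW = WIC + BIC (Shannon entropy of the pooled diet split into its
  within- and between-individual components), the WIC/TNW ratio, the
  proportional similarity index PSi_i = 1 − ½Σ|p_ij − q_j| and its mean
  (IS), Monte Carlo generalist-null resampling for p-values and the PSi
  threshold splitting the population into specialist/generalist groups.
- **Synthetic populations**: a Dirichlet–multinomial generator with
  tunable specialization, condition-coupled prey choice and seasonal
  presets matching the reference dataset's sample sizes and prey columns.

## Worked example

```python
import trophospec as ts

# pooled reference table: diversity and prey selection
fx = ts.load_table1_fixture()
d = ts.shannon(fx.diet_counts["autumn"])
e = ts.shannon(fx.env_counts["autumn"])
print(f"diet H={d.H:.3f} J={d.J:.2f}; environment H={e.H:.3f} J={e.J:.2f}")

res = ts.electivity_estar(fx.diet_counts["autumn"], fx.availability("autumn"))
x = {r.taxon.label: r.Estar for r in res}
print(f"E*: Collembola {x['Collembola']:.2f}, Araneae {x['Araneae']:.2f}, "
      f"Acarina {x['Acarina']:.2f}  ({res[0].n_categories} categories)")

# per-individual analysis on a seeded synthetic autumn population
diet, cov, avail = ts.paper_scenario("autumn", seed=1)
dec, psires, nulls = ts.specialization_analysis(diet, reps=999, seed=1)
print(f"TNW {dec.tnw:.2f} = WIC {dec.wic:.2f} + BIC {dec.bic:.2f}; "
      f"WIC/TNW {dec.ratio:.2f} (p = {dec.p_ratio:.3f}), IS {psires.is_index:.2f}")
```

prints

```
diet H=1.174 J=0.41; environment H=2.216 J=0.68
E*: Collembola 0.54, Araneae 0.62, Acarina -0.66  (19 categories)
TNW 1.15 = WIC 0.73 + BIC 0.42; WIC/TNW 0.63 (p = 0.001), IS 0.70
```

Reading: the autumn diet is far less diverse than the prey community
(H 1.17 vs 2.22), Collembola and spiders are positively selected while
mites are avoided despite being abundant, and the population's niche
width is dominated by its within-individual component with a WIC/TNW
ratio of 0.63 — significantly below the generalist null at the resolution
999 Monte Carlo replicates allow (p = 0.001).

The same analyses run from the shell:

```
trophospec simulate  --scenario autumn --seed 1 --out out/
trophospec full      --scenario autumn --seed 1 --out out/
trophospec electivity --season autumn --seed 1 --out out/
```

Each stage writes CSV/JSON reports (electivity tables, feeding-strategy
points, condition indices, RSPF model rankings, per-individual PSi and
group assignments, null-distribution histograms) plus a consolidated
JSON for the full run; reruns with the same seed are byte-identical.

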