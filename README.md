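# stomgeo

Geometric-constraint analysis of stomatal morphology: why stomatal
density (SD) falls as stomatal size (SS) grows, and how much of that
relationship is pure packing geometry versus developmental control.

`stomgeo` is aimed at plant ecophysiologists and comparative
morphologists working with species-level stomatal trait compilations
(density, guard-cell length/width, epidermal cell size, stomatal index)
and, optionally, a dated phylogeny of the same species.

## The model

A leaf epidermis tiled by *m* stomata of area SS (µm²) and *n* pavement
cells of area ES (µm²) has stomatal density

```
SD = 10⁶ / (SS + ES·(n/m))          [mm⁻²]
```

With stomatal index SI = 100·m/(m+n) and the area ratio a = ES/SS this
becomes

```
SD = 10⁶ / (SS · c(SI, a)),   c(SI, a) = 1 + a·(100/SI − 1)
```

so at fixed SI and a, SD ∝ SS⁻¹ exactly — the **geometric constraint**
(dilution: five-fold larger stomata means five-fold lower density, e.g.
900 → 180 mm⁻²). Because a single stoma's plan area is well approximated
by SS = (π/2)·SL·SW with SW ≈ 0.36·SL, the same law reads
SD ≈ 1.77×10⁶ / c(SI, a) · SL⁻². Everything else the package does builds
on this identity:

- **allometry** — standardized major axis (SMA) fits of log₁₀ traits with
  one-sample slope tests against the intrinsic exponents −1 (SD–SS) and
  −2 (SD–SL);
- **partition** — decomposition of the adjusted R² of lg SD into a
  geometric part (lg SL⁻²), a non-geometric part (lg SI), and their
  overlap;
- **sensitivity** — the partial derivatives ∂SD/∂SS < 0 and ∂SD/∂SI > 0
  and the constraint ratio R_gc/nge = |∂SD/∂SS| / (∂SD/∂SI)
  = SI²·c/(100·a·SS);
- **geometry** — estimation of a by direct ES-on-SS proportionality
  fitting (documented value 2.78) and by calibration against observed SI
  (documented value 1.06);
- **phylocomp** — phylogenetically independent contrasts, Blomberg's K
  with a permutation test, Brownian trait simulation;
- **groupstats** — one-way ANOVA with Tukey HSD letters across
  pteridophytes / gymnosperms / angiosperms (and angiosperm subgroups);
- **synth** — a generator of fully consistent synthetic trait tables and
  matching trees, so the entire pipeline is testable without the
  compiled literature dataset.

## Worked example

```python
import numpy as np
import stomgeo as sg

sg.predict_density(ss=100, si=10, a=1.06)   # 948.7666034155598 mm^-2
sg.predict_si(sd=900, ss=100, a=1.06)       # 9.488760692261788 %
sg.constraint_ratio(ss=100, si=10, a=1.06)  # 0.09943396226415094

table, tree = sg.generate_study_preset(seed=1)   # 300 species + phylogeny
df = table.to_dataframe()

fit = sg.sma_fit(np.log10(df.ss_um2), np.log10(df.sd_per_mm2),
                 hypothesized_slope=-1)
# SMA slope -0.998  CI (-1.031, -0.967)  p vs -1: 0.924

part = sg.variation_partition(table)
# pure geometric 0.891  pure non-geometric 0.015  overlap 0.028

per_species, summary = sg.table_sensitivities(table, a=1.06,
                                              si_mode="predicted")
# mean R_gc/nge 0.0515  below 1: 100.0%

k = sg.blomberg_k(tree, {r.species: np.log10(r.r_gc_nge)
                         for r in per_species}, n_perm=999, seed=0)
# Blomberg K 0.036  p 0.591
```

Reading the numbers: at SS = 100 µm², SI = 10 % and a = 1.06 the packing
identity gives ≈ 949 stomata mm⁻². On the synthetic table the log–log
SD–SS slope is statistically indistinguishable from the intrinsic −1
(p = 0.92), nearly all explainable lg SD variance is carried by the
geometric predictor, and the constraint ratio shows no phylogenetic
signal (K ≈ 0.04, permutation p ≈ 0.59) on the accompanying random tree.

The same analyses run from the shell on any trait CSV
(`species,group,subgroup,sd_per_mm2,sl_um,sw_um,ss_um2,es_um2,si_pct`)
and Newick tree:

```sh
stomgeo simulate --seed 1 --out demo/
stomgeo report --input demo/traits.csv --tree demo/tree.nwk --out demo/
```

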