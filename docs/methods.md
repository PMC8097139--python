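# Methods

## The packing identity and its parameters

The core of the package is a deterministic identity, not a fitted model.
If a unit of leaf epidermis holds *m* stomata of plan area SS (µm²) and
*n* pavement cells of area ES (µm²), density is SD = 10⁶/(SS + ES·(n/m))
per mm². Substituting the stomatal index SI = 100·m/(m+n) (so n/m =
100/SI − 1) and the area ratio a = ES/SS gives

    SD = 10⁶ / (SS · c(SI, a)),    c(SI, a) = 1 + a·(100/SI − 1).

Assumptions worth keeping in mind:

- the epidermis is treated as fully tiled by exactly two cell classes of
  uniform within-leaf area; trichomes, veins and subsidiary cells are
  absorbed into ES;
- SS from length uses the plan-area approximation SS = (π/2)·SL·SW and,
  when width is unmeasured, SW = 0.36·SL. The leading coefficient of the
  resulting SL⁻² law, 1/((π/2)·0.36) = 1.768, is conventionally printed
  as 1.77;
- SI may take the value 100 in the forward model (all-stomata limit,
  c = 1) but observed records require 0 < SI < 100.

Tunable parameters, defaults, units:

| parameter | meaning | default | unit |
|---|---|---|---|
| a | ES/SS area ratio | 1.06 | — |
| width_ratio | SW/SL | 0.36 | — |
| unit factor | µm² per mm² | 10⁶ (fixed) | µm²/mm² |

The value 1.06 is the SI-calibrated default; 2.78 is the documented
direct-fit value. Both are ordinary arguments everywhere — the printed
constants 106 and 0.06 in c(SI, 1.06) = 106/SI − 0.06 are recovered by
computation, never hard-coded, so the machinery works for any a.

### Estimating a

`estimate_a` fits ES = a·SS through the origin by least squares (a is
defined as a ratio; there is no offset to estimate). Alternatives —
mean of per-record ES/SS ratios, and the geometric-mean (log-log
intercept) version — are selectable and recorded in the output, since
the through-origin choice, while natural, is a convention.

`calibrate_a` instead chooses a to minimize Σ(predicted SI − observed
SI)², where predicted SI inverts the density identity at the record's
(SD, SS). This is the "1:1 line" criterion: make SI predictions track
observations. Minimization is bounded scalar search on a ∈ (0.01, 100)
with an absolute tolerance of 1e−8 — deterministic and derivative-free.
Records violating the packing bound SD·SS < 10⁶ (stomata alone exceeding
the surface) are excluded with a logged count, never clamped.

## Line fitting

All scaling analyses run on log₁₀-transformed traits. SMA is implemented
directly (slope = sign(r)·sd(y)/sd(x)); its 95% CI uses the closed form
b·(√(B+1) ± √B) with B = F₀.₉₅;₁,ₙ₋₂·(1−r²)/(n−2), and the one-sample
slope test exploits the fact that the residual axis y − b₀x and fitted
axis y + b₀x are uncorrelated exactly when b₀ is the population SMA
slope (t test on that correlation, df = n − 2). The through-origin
variant used for independent contrasts replaces moments by uncentered
sums and df by n − 1. Perfectly collinear input yields a width-zero CI
and p = 1 for the true slope; zero-variance input raises rather than
returning NaN. OLS fits (plain and through-origin) delegate to
statsmodels; adjusted R² uses 1 − (1−R²)(n−1)/(n−p−1).

## Variance partitioning

lg SD is regressed on lg(SL⁻²) (= −2·lg SL — the stated geometric
predictor; using lg SL would only rescale the slope), on lg SI, and on
both. With adjusted R² values R²gc, R²nge, R²o, the overlap is
R²gc + R²nge − R²o and the pure components follow by subtraction; the
three-way identity pure_gc + pure_nge + overlap = R²o then holds to
machine precision by construction. Adjusted R² is the default because
the single- and two-predictor models differ in parameter count; plain R²
is available behind a flag. Slightly negative adjusted components are
reported as computed and flagged, not clamped. Only records with SD, SL
and an *observed* (not derived/predicted) SI enter.

## Sensitivities and the constraint ratio

From the identity, ∂SD/∂SS = −10⁶/(SS²·c) and ∂SD/∂SI =
10⁶·100a/(SI²·SS·c²); both are validated against central finite
differences in the test suite (relative tolerance 1e−6), and the ratio

    R_gc/nge = |∂SD/∂SS| / (∂SD/∂SI) = SI²·c(SI, a) / (100·a·SS)

against its closed form (1e−10). R_gc/nge compares a 1 µm² change in
stomatal size against a 1-percentage-point change in stomatal index; it
is treated as a dimensionless index, but those two unit steps are not
commensurable quantities, which should be remembered when interpreting
its absolute magnitude (at realistic SS of 10²–10³ µm² and SI of 5–30 %
the ratio is well below 1). Summaries report the arithmetic mean, the
median and the mean of lg R_gc/nge (group comparisons run on the lg
scale), plus the fraction of records below 1. SI can be taken as
observed or predicted from (SD, SS); the mode is an explicit argument
because the two can differ systematically.

## Phylogenetic comparative machinery

Trees are rooted, with strictly positive branch lengths required on
every non-root edge (Newick via dendropy). Independent contrasts follow
the standard pruning recursion: contrast (xᵢ − xⱼ)/√(bᵢ + bⱼ),
precision-weighted ancestral value, parent branch extended by
bᵢbⱼ/(bᵢ + bⱼ). Polytomies are refused by default; an explicit policy
resolves them arbitrarily with 1e−8-length branches and records that
choice in the result. Correctness is checked two ways: the linear map
from tip values to contrasts whitens the Brownian covariance
(A·V·Aᵀ = I, A·1 = 0) on every rooted binary topology with ≤ 6 tips, and
values agree with ape::pic on random trees. Contrast regressions go
through the origin.

Blomberg's K uses the MSE0/MSE ratio with the GLS mean under the tree
covariance V, normalized by its Brownian expectation
[tr V − n/(1ᵀV⁻¹1)]/(n − 1); the permutation p-value shuffles tip
assignments with a seeded generator and uses the add-one estimator
(1 + hits)/(n_perm + 1), so p is never 0 and every result is
reproducible from its recorded seed. A star phylogeny gives K = 1
identically; values agree with picante::Kcalc. Brownian simulation adds
independent N(0, σ²·branch length) steps down the tree; pure-birth tree
generation draws exponential waiting times with rate proportional to the
number of extant lineages.

## Group comparisons

One-way ANOVA (classical F) with Tukey HSD post-hoc and a compact letter
display built by insert-and-absorb from the pairwise significance matrix
at α = 0.05. Tukey HSD is a choice — any single-step pairwise procedure
would serve — and is recorded in the output metadata. Letter displays
are deterministic given the group ordering by descending mean.

## The synthetic generator

`synth` emulates the joint trait structure the analysis assumes, per
taxonomic group: log₁₀-normal SS (group means 3.1 / 2.9 / 2.3–2.5 for
pteridophytes / gymnosperms / angiosperm subgroups, sd 0.25 — large
fern and conifer stomata, small angiosperm stomata, realistic 10²–10³
µm² sizes); SI linear in lg SS (intercept 1.0, slope 0.05, lg-noise
0.05), giving SI ≈ 10–20 % with a weak positive SI–SS coupling; ES =
a_true·SS with lg-noise 0.05; and SD from the packing identity with
lg-noise 0.10. Defaults were fixed once to reproduce the documented
study regime: an SD–SS SMA slope statistically indistinguishable from
−1 (and SD–SL from −2), geometric dominance in the variance partition,
and a positive SI–SS correlation. All noise is multiplicative and
mean-one (the 10^N(0,s²) draw is divided by exp((s·ln10)²/2)), so
raw-scale proportionalities such as E[ES|SS] = a·SS hold exactly and
ratio estimators are consistent. SI is rejection-sampled into
(0.5, 99.5) % by redrawing the whole (SS, SI) pair, never by clipping.
The default preset pairs the 300-species table with a pure-birth tree
whose tips are assigned to species in shuffled order, so traits carry no
phylogenetic signal — the regime in which the constraint ratio is
expected to be independent of phylogeny.

What the generator does **not** emulate: empirical moments of any real
compilation (its SS ranges and group proportions are stylized), a-
variation across species, measurement error correlated between traits,
group-structured phylogenies, or polytomies. Passing tests on synthetic
data therefore demonstrate correctness of the machinery under the
model's own assumptions, not dataset-level agreement with any published
compilation.

## Problem sizes and numerical choices

The default study size is 300 species (500 for the parameter-recovery
simulations, 100 replicate seeds); statistical calibration uses 2,000
simulated samples of n = 50 for the slope test's type-I error and 200
Brownian replicates on a 50-tip tree for K. Monte-Carlo acceptance bands
follow from those sizes. Permutation counts default to 999. Degenerate
inputs (zero variance, constant predictors, exact collinearity,
polytomies, infeasible SD·SS) raise informative errors rather than
propagating NaNs; boundary SI = 100 is accepted in the forward model
only.

## Known limitations

- **SI-calibration bias under density noise.** Predicted SI is a
  nonlinear function of SD, so multiplicative SD noise does not average
  out: with the generator's default lg-noise of 0.10 on SD, the
  least-squares calibration recovers a ≈ 1.009 instead of 1.06
  (n = 500, 100 seeds) — a real inconsistency of the estimator, present
  whenever observed densities deviate multiplicatively from the packing
  identity, and documented deliberately by the recovery test rather than
  hidden by reducing the generator's noise. Calibration is exact when
  densities follow the identity (verified to 1e−6). A bias-aware
  calibration (e.g., log-scale or errors-in-variables objective) is out
  of scope because the plain least-squares criterion is part of the
  method's definition.
- R_gc/nge mixes per-µm² and per-SI-point sensitivities; its absolute
  scale depends on that unit convention (see above).
- The permutation test for K, not K itself, is the inferential quantity;
  K's sampling distribution under Brownian motion is calibrated only in
  mean (≈ 1) in the test suite.
- Tip-label matching between tables and trees is exact after whitespace
  normalization; no taxonomic synonym resolution is attempted.
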