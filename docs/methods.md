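# Methods

## The analysis problem

The package analyses marked planar point patterns recorded inside
polygonal observation windows — in the motivating application, positions
of sessile benthic fauna (sea pens and co-occurring tube anemones or
stalked sponges) annotated on orthorectified photogrammetry transects of
roughly 11 × 2 m, with 30–70 individuals per taxon and densities of
0.6–3 ind·m⁻². All coordinates are planar metres; the third dimension is
discarded after orthorectification, and no geographic CRS handling is
attempted. The question the pipeline answers is ecological: is the
pattern random, clustered or overdispersed at scales of centimetres to a
metre, and which generative mechanism — habitat association, dispersal
limitation, facilitation, competition — best accounts for it?

## Summary statistics

The workhorse is the pair correlation function (PCF) g(r), the
non-cumulative density of point pairs at distance r relative to a Poisson
process of equal intensity. The estimator is

g(r) = Σ_{i≠j} k_h(r − d_ij) · w(x_i, d_ij) / (2π r λ² |W|),

with an Epanechnikov kernel k_h, Ripley's isotropic edge-correction
weight w (the reciprocal of the in-window circumference fraction of the
circle through the neighbour), and the unbiased pair-intensity
convention λ² = n(n−1)/|W|² — at n of 30–70 the n² convention is visibly
biased. The kernel is reflected at r = 0 so no mass leaks to negative
distances; the value at r = 0 is undefined and values below h/2 are
flagged unreliable. The smoothing bandwidth defaults to Stoyan's rule of
thumb h = 0.15/√λ̂, recorded in the output metadata. K and L functions
use the same weights; L(r) = √(K(r)/π) equals r under complete spatial
randomness (CSR) and is the summary used for goodness-of-fit.

Edge-correction weights are computed in closed form for axis-aligned
rectangular windows (arc overlaps at corners handled analytically) and by
exact circle–segment intersection with midpoint point-in-polygon arc
classification for arbitrary simple polygons. The second path is exact
for non-convex rings too, so no quadrature fallback is needed; both are
verified against a circumference-sampling oracle.

Inhomogeneous and multitype variants weight pairs by 1/(λ(x_i)λ(x_j))
and by the per-type intensities respectively; cross-pair weights are
symmetrised, (w_a + w_b)/2, so g₁₂ ≡ g₂₁ exactly.

**Scale rule.** No summary function is evaluated beyond half the shortest
edge of the window bounding box — ~1 m for a 2 m-wide transect. Beyond
that scale a slender window supports too few pair geometries for the edge
correction to be meaningful. Exceeding it requires an explicit override.

## Intensity and the heterogeneous Poisson family

Nonparametric intensity surfaces use an isotropic Gaussian kernel with a
1 m standard deviation by default (the "kernel size = 1" convention at
transect scale), on a 0.05 m grid, with per-kernel edge correction: each
point's kernel is renormalised by its in-window mass, so the surface
integrates to n. Parametric ("heterogeneous Poisson") models are
log-linear Poisson processes, log λ(u) = β·z(u) with z ∈ {1, x, y,
(x, y), log(taxon density + 10⁻⁸)}, fitted by maximising
Σᵢ log λ(xᵢ) − ∫_W λ(u) du with the integral evaluated by quadrature on
the intensity grid; AIC = 2k − 2ℓ.

## The model menu

* **Thomas cluster process** (Poisson parents, Gaussian-dispersed Poisson
  offspring): simulated with parents on the window dilated by 4σ; fitted
  by minimum contrast on K with the standard Diggle–Gratton exponents
  (q = 1/4, p = 2), σ and κ on log scale with multi-start Nelder–Mead,
  μ recovered from n/(κ|W|). The inhomogeneous variant thins offspring by
  a fitted log-linear trend and uses the inhomogeneous K. Fits whose
  cluster strength is indistinguishable from CSR (fitted g(0) − 1 < 0.15)
  or whose σ hits a boundary are flagged, not silently returned.
* **Linked Thomas process**: both taxa are offspring of one shared parent
  process (type-specific μ, shared κ and σ) — the minimal shared-parent
  model for facilitation. Because cross pairs share a parent, its cross-K
  has the same closed form as the univariate Thomas K, which is what the
  fitter exploits.
* **Gibbs hard-core / soft-core processes**: pairwise interaction
  h(d) = 0 for d < hc (hard core) or h(d) = exp(−(σ/d)^(2/κ)) with
  κ ∈ [0.1, 0.9] (soft core). Simulation is a fixed-count Metropolis
  shift chain (every use site conditions on the observed n, so the
  birth–death moves of the general sampler are unnecessary); 10⁴–10⁵
  proposals suffice at n ≈ 60, checked by a burn-in adequacy test
  (doubling the chain moves mean NND by < 5%). Fitting is maximum
  pseudolikelihood via Berman–Turner quadrature (data + dummy grid,
  counting weights); the hard-core radius is profiled at its MPLE, the
  minimum nearest-neighbour distance, and the soft-core κ on the grid
  {0.1, …, 0.9}; pseudo-AIC = 2k − 2 log PL.

AIC-type criteria are comparable only within a family — a minimum
contrast value is not a likelihood — so model selection is two-step:
rank within family by the family's criterion and keep the best two, then
decide across families by the Diggle goodness-of-fit p_d (below).

## Monte-Carlo machinery

All Monte-Carlo p-values are (1 + #{sim ≥ obs})/(n_sim + 1); at the
default 999 simulations the smallest attainable p is 0.001. CSR nulls are
simulated conditionally on the observed n; fitted models parametrically.

* **Quadrat homogeneity test**: 3 × 2 quadrats by default (expected
  counts ≥ 5 at n = 30 on a slender window; layout configurable and
  recorded), χ² against clipped-area-proportional expectations, p by
  conditional CSR simulation. p > 0.05 is read as homogeneity.
* **Envelopes**: pointwise limits at the 49th largest/smallest of 999
  simulated curves (two-sided level 2·49/1000 = 0.098 per distance).
  When n_sim is reduced the rank is rescaled as
  ⌊49(n_sim+1)/1000⌋ to preserve that level. Excursions above the band
  indicate clustering, below overdispersion; single-grid-step grazes are
  reported but flagged weak.
* **Diggle (DCLF) test**: u = ∫(L_obs − L̄)² dr by trapezoid on the shared
  r grid; every simulated curve is scored against the mean of the others,
  making observation and simulations exchangeable under the null, hence
  p_d exactly uniform there. p_d near 1 indicates a good fit.
* **Segregation**: Dixon's nearest-neighbour contingency test; the
  overall statistic has 2 degrees of freedom for two types, per-type
  components 1. p-values by random relabelling (the NN graph is fixed);
  the asymptotic χ² p is reported alongside but the Monte-Carlo p is
  authoritative.
* **Kendall's τ-b** (tie-corrected) correlates per-transect densities;
  exact p for n ≤ 10 without ties.

## The driver ladder

Per transect: an n ≥ 30 filter (excluded transects are reported with the
reason, never dropped silently) → quadrat test → PCF + envelope →
classification → model menu → per-model DCLF → driver verdict, with every
intermediate artefact, seed and decision echoed into the report. The
focal taxon receives the full univariate ladder; a second taxon gets a
classification-only univariate pass (the bivariate competition rule needs
it), and the pair the bivariate analysis.

Three design points deserve explicit statement:

1. **The CSR gate is the global DCLF test, not the envelope.** Pointwise
   49/999 envelopes have a per-distance level of 0.098 and a considerably
   higher family-wise one when scanned across all distances; treating any
   excursion as "non-random" would flag a third of genuinely random
   transects. The ladder therefore calls a departure only when the global
   deviation test rejects at α = 0.05 (or the pattern is inhomogeneous,
   next point); the envelope remains the scale-by-scale evidence trail
   that localises and signs the departure.
2. **Inhomogeneity is itself a departure from CSR.** CSR is the
   *homogeneous* Poisson process, so a pattern whose quadrat test rejects
   homogeneity enters the model menu even when its residual second-order
   structure is null; a pure first-order departure is habitat
   association, which the heterogeneous Poisson family then wins (cluster
   fits flag "no cluster evidence" on such data). One guard applies: a
   homogeneity rejection with *neither* residual structure *nor* any
   trend model beating the constant by BIC is uncorroborated — two
   independent lines of evidence both failing — and is reported as no
   departure rather than habitat association. This keeps the ladder's
   false-alarm rate on genuinely random patterns near the tests' nominal
   level instead of the union of two testing paths. For inhomogeneous
   patterns the envelope/DCLF null is the fitted kernel-intensity surface
   ("fitted-trend null", with a CSR-null switch), and the *plain*
   PCF/L of observation and simulations are compared: the first-order
   inflation then cancels between the two, whereas freezing an estimated
   surface inside an inhomogeneous statistic would bias the observed
   curve relative to the simulated ones (the surface contains the
   observed points' own kernels). The inhomogeneous PCF with a
   leave-one-out intensity remains available as an exploratory estimate.
3. **Branching and trend carry-over.** The cluster/habitat families are
   fitted when clustering dominates, the inhibition families when
   overdispersion does; dominance is the integrated area outside the
   envelope (a tall clustering spike outweighs a wide shallow deficit,
   which matters because conditional-on-n clustered patterns mechanically
   show mid-range deficits). Whether the Thomas model carries a trend
   follows first-order evidence: the BIC-best log-linear trend among
   {constant, x, y, x+y} — BIC rather than AIC because clustered counts
   induce spurious AIC trends.

Verdict mapping: heterogeneous Poisson → habitat association; homogeneous
Thomas → reproductive/dispersal; inhomogeneous Thomas → dispersal with
habitat association; hard/soft-core → competition. Bivariate clustered
patterns are fitted with three heterogeneous Poisson models (intensity
from the kernel density of taxon A, of taxon B, and of the superposition)
plus the linked Thomas: a single-taxon-density or linked-Thomas best fit
means facilitation, the joint-density model mutual habitat association;
p_d gaps below 0.05 are called indeterminate, naming both candidates.
Bivariate overdispersion means competition only when neither taxon's
univariate PCF shows overdispersion at overlapping scales — otherwise it
is read as habitat-driven. "Best-fitting" across the shortlist is always
the highest p_d; exact ties are indeterminate.

## Synthetic scenarios

The generator realises six regimes in study-shaped windows (length ~
N(11.16, 0.4) truncated above 8 m, width 2 m, 60 points per taxon by
default): uniform (CSR); a shared log-linear gradient of 0.35 m⁻¹ along
the transect for both taxa (habitat association); homogeneous Thomas
clusters with κ|W| ≈ 30 parents, μ = 2, σ = 0.10 m (dispersal); the same
thinned by the gradient (dispersal + habitat); linked Thomas with ~15
shared parents and μ = 4 per taxon (facilitation); and a two-type Gibbs
chain with *cross-type-only* soft-core repulsion (σ = 0.20 m, κ = 0.2),
whose marginals stay unstructured — the competition signature. Effect
sizes were chosen once so each regime is detectable but not trivial at
n = 60 (cluster σ well below the kernel bandwidth; gradient strong enough
for first-order tests; inhibition radius removing ~60% of close cross
pairs) and then frozen. Counts are conditional on the target where the
regime allows, otherwise deterministically resampled into ±20% of it.

What the generator does *not* emulate: photogrammetric positioning noise,
annotation error, organism withdrawal into the sediment, within-taxon
morphospecies mixtures, and irregular (non-rectangular) transect
outlines. Passing recovery tests therefore demonstrates that the ladder
identifies these mechanisms under its own modelling assumptions at field-
realistic sizes, not that real transects are free of the confounding the
original imagery workflow can introduce.

## Numerical choices and problem sizes

Kernel smoothing of the PCF is accumulated by chunked binning, keeping
dense patterns (10⁶ pairs) at a few seconds. The r grid has 512 points up
to r_max by default; validation suites use 192–256 grid points, 99–199
Monte-Carlo simulations per test (with the envelope rank rescaled as
above), 8 000–20 000 Gibbs proposals, and 50 replicates per recovery
condition — sizes at which every check is stable over reruns while the
whole validation battery completes in minutes. Degenerate inputs fail
loudly: empty patterns, duplicate coordinates (annotation errors; an
override flag exists), self-intersecting rings, infeasible hard-core
packings, zero intensities at data points, and missing mark labels all
raise typed errors naming the offender.

## Known limitations

* The quadrat homogeneity test conditions on CSR, so strong small-scale
  clustering can reject homogeneity without any first-order trend;
  downstream this blurs homogeneous vs trend-thinned Thomas regimes (the
  hardest pair to separate at n = 60, as their recovery rates reflect).
* Kernel bandwidth 1 m cannot represent habitat patchiness below ~1 m;
  habitat association expressed at finer scales would be attributed to
  clustering mechanisms.
* The Berman–Turner soft-core fit profiles κ on a fixed grid of 9 values;
  σ̂ is back-transformed from θ̂ = σ̂^(2/κ) and is therefore unstable when
  the fitted interaction is weak (θ̂ → 0).
* Monte-Carlo p-values inherit the discreteness of their simulation
  count; at n_sim = 99 the p lattice is 0.01.
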