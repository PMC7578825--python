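# Methods

This note records the models implemented in `trophicniche`, the defaults and
their rationale, what the synthetic-data generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Diet indices

Diet profiles are simplexes over a shared prey vocabulary, by mass (%W/100)
or by count (%N/100). Detritus cannot be counted as items, so it is excluded
from count-based metrics (configurable exclusion list); an individual left
with no countable items is dropped from %N with a warning. Profiles within
1e-9 of a simplex are accepted as-is; otherwise they are renormalized —
published tables list only major items, so their rows do not sum exactly
to 100.

The simplified Morisita index is computed on group-mean %W profiles by
default. This is a deliberate choice: it is the only reading under which the
published pairwise overlap matrix is recomputable from the published diet
table (all six pairs agree to ±0.005), and per-individual pooling remains
available. The 0.6 significance convention is applied strictly (> 0.6).

## Individual specialization

The Shannon form of Roughgarden's niche decomposition is used throughout,
in nats:

- `TNW = −Σ_k q_k ln q_k`, with `q_k` the pooled proportion of resource k;
- `WIC = Σ_i p_i (−Σ_k p_ik ln p_ik)`, with `p_ik` individual i's own
  proportions and `p_i` its share of the pooled total;
- `BIC = Σ_i p_i Σ_k p_ik ln(p_ik/q_k)`, the individual–resource mutual
  information, so `TNW = WIC + BIC` holds as an identity (tested to 1e-9
  against a term-by-term oracle).

`p_i` is taken from actual totals (individuals that ate more weigh more);
`equal_weights=True` normalizes individuals first. Counts are the default
basis, matching the "proportional numerical abundance" convention of the
RInSp-style tools; mass is available. When a group uses a single shared
resource, TNW = 0 and WIC/TNW is reported as 1 with a degeneracy flag:
with no niche to subdivide there is no between-individual structure, which
is the generalist limit. "Diet similarity" is mean pairwise proportional
similarity `PS_ij = Σ_k min(p_ik, p_jk)` — the RInSp convention — chosen
explicitly because the name alone does not pin down a formula.

## Isotope niche geometry

All metrics operate on the (δ13C, δ15N) plane in ‰. The standard ellipse is
the 1-SD covariance ellipse (χ² scale factor 1), which encloses
1 − e^(−1/2) ≈ 39.35% of a bivariate normal — the "40%" convention.
`SEA = π√(λ₁λ₂)` uses the (n−1)-denominator sample covariance;
`SEAc = SEA·(n−1)/(n−2)` (defined for n ≥ 4). The convex hull is computed
with scipy's Qhull; collinear clouds return area 0 with a degeneracy flag.
MNND's spread is the sample SD (ddof = 1) of per-point nearest-neighbour
distances.

Ellipse overlap is computed by intersecting regular inscribed boundary
polygons (shapely), with the vertex count as the resolution parameter
(default 4096). This is deterministic and has relative area error
O(resolution⁻²) ≈ 1e-7 at the default — comfortably below the 1e-3 the
validation against the closed-form circular-lens formula demands, which
grid-counting quadrature at a practical cell size cannot guarantee. The
overlap is reported as an absolute area plus fractions of each ellipse, of
the smaller ellipse, and of the union, because published "percentage
overlap" figures rarely state their denominator. Coverage is an explicit
parameter: published overlap areas in this literature sometimes exceed
every group's SEAc, which is only possible at a larger coverage (e.g. 95%),
so no single convention is hard-wired.

## Mixing model

The likelihood for consumer value `x_ij` on tracer j is
`N(Σ_k p_k(μ_jk + λ_jk), Σ_k p_k²(ω_jk² + τ_jk²) + σ_j²)`: source
signatures `μ ± ω`, TEFs `λ ± τ` applied uniformly to all sources (the
study assigns a single TEF pair for the whole mixture: 1.3 ± 0.3 ‰ for
δ13C, 2.3 ± 0.18 ‰ for δ15N), and per-tracer residual SDs `σ_j` with
half-Normal(0, 2 ‰) priors — weakly informative at the ‰ scale of the
data. The prior on `p` is Dirichlet(1, …, 1). Concentration (C/N) weighting
is off by default, matching the concentration-free classic model.

Sampling: affine-invariant ensemble MCMC (emcee) on the additive-log-ratio
transform of the simplex, with the log-Jacobian `Σ ln p_k` included, and
`ln σ_j` as free coordinates. Defaults: 32 walkers, 1000 exploratory steps,
then all walkers restarted in a 0.01-radius ball around the best point
found and run for 3000 steps, discarding 1000 and thinning by 5. The
restart step matters: from a dispersed start an isolated walker can stall
in the heavy-tailed large-σ direction, where stretch moves toward the bulk
traverse a low-probability valley; restarting from the located mode removes
this failure while leaving the posterior untouched. Convergence is
summarized by the max split-R̂ over source proportions (walkers as chains);
R̂ > 1.1 emits a warning, never a silent pass. A geometry warning fires when
the consumer centroid lies well outside the TEF-shifted source hull.
Posterior means shift by < 0.01 when the chain length is doubled at the
default problem sizes.

With twelve sources and two tracers the problem is under-determined by
construction; posteriors then concentrate near the prior mean 1/12 with
lower credible bounds near 0. This is a property of the model, not a
failure, and is what group-level contribution tables in this setting look
like.

## Group comparisons

Hotelling's T² uses the pooled covariance and the exact F transform
`F = T²(n₁+n₂−p−1)/((n₁+n₂−2)p)`, p = 2. The RPP builds its null by
centering each group on its centroid, pooling the residuals, reassigning
them to groups of the original sizes around the common grand centroid, and
recomputing the statistic; `p = (1 + #{null ≥ obs})/(B + 1)` with B = 9999
by default and a mandatory seed. Raw-label permutation is available behind
a flag for the centroid test. Pairwise p-values are reported raw; a Holm
adjustment exists but defaults off, mirroring common practice in this
literature.

The fullness model treats FF (0–5) as numeric — the linear-mixed-model
formulation implies exactly that — with a single season random intercept,
fitted by ML (not REML) because the likelihood-ratio tests compare fixed
effects. Fitting goes through statsmodels MixedLM with an optimizer cascade
(default BFGS, then Powell, then Nelder–Mead) because the season variance
frequently sits on the zero boundary, where individual optimizers can
report an infinite likelihood. The step-down order is configurable:
`interaction_first` (default) drops Group×Time from the full model, then
tests Time and Group against the additive model; `from_full` tests each
term jointly against the full model. The order is configurable precisely
because published χ² values rarely state which reduction produced them.

## Synthetic data

The generators are pure functions of their config; one master seed drives
per-generator child streams (`SeedSequence` spawn keys), so components are
independently reproducible.

- **Diet**: individual proportions `p_i ~ Dirichlet(α·q_g)`, counts
  `~ Multinomial(items, p_i)`, masses = counts × per-taxon unit mass
  (default 1 g, so %W ∝ counts unless configured). Defaults mirror the
  study's gut-content subsample — 9/6/15/7 individuals per group, baselines
  from the published %N table — with α = 2 and 200 items per gut, inside
  the moderately specialized WIC/TNW band the study reports. α is the
  specialization dial: WIC/TNW is monotone in α (validated by a
  20-seed × 4-α Spearman check).
- **Isotopes**: per-group bivariate normals with the published means/SDs
  and sample sizes (11/12/15/8), independent tracers by default.
- **Consumers**: drawn from the mixing model's own generative law, so
  posterior parameter recovery is a well-posed check.
- **Fullness**: `ff = round(clip(μ + time + group + season + ε, 0, 5))`
  with a diel sinusoid (amplitude 0.8, peak at 16:00) as the default time
  effect, zero group effects, season SD 0.3 and residual SD 1 on the latent
  scale; eight 3-hourly sampling times, four size groups, four seasons,
  three fish per cell (~384 observations, the scale of the field design).

What the generators do **not** emulate: prey-taxon covariance structure
beyond the Dirichlet (e.g. co-occurring prey), isotope–length correlation
within groups (lengths are drawn independently; the between-group gradient
still produces a positive δ15N–SL slope), gut-content/isotope coupling
within individuals, and non-normal isotope tails. Passing tests therefore
validate the estimators and their calibration under the stated models, not
robustness to field-data pathologies.

## Problem sizes and calibration studies

Type-I calibration of the LRT uses a six-season, two-per-cell design
(n = 384): with only four seasons the ML variance estimate is noisy enough
to make the χ² reference visibly anticonservative (empirically ~0.08–0.09
at nominal 0.05), which is a genuine small-sample property of
likelihood-ratio tests with few random-effect levels, not an implementation
artifact — the same code calibrates to 0.045–0.06 once the season count
grows. The qualitative feeding-rhythm recovery study uses the same design.
This limitation is worth remembering when reading mixed-model χ² values
from field studies with a handful of seasons. Hotelling calibration uses
1000 bivariate-normal null replicates at n = 15 vs 12; RPP uniformity uses
1000 replicates at B = 199.

## Known limitations

- Published absolute TNW/WIC values for this system are not recomputable
  from any published table (the printed small-juvenile TNW is an order of
  magnitude below the entropy of the printed diet profile); the package
  therefore validates the decomposition by identity and oracle, not against
  those numbers.
- The mixing model is single-group; hierarchical multi-group variants
  (random effects across groups) are out of scope.
- FF is modelled as numeric; an ordinal link is out of scope.
- Ellipse overlap assumes both ellipses are non-degenerate; near-singular
  covariances should be handled upstream (they raise at construction).
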