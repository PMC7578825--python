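# trophicniche

Quantitative trophic-niche analysis for gut-content and stable-isotope data,
built around the ontogenetic diet study of black amur bream (*Megalobrama
terminalis*) in the Pearl River: four size groups (small juvenile, large
juvenile, sub-adult, adult) compared for diet composition, niche width,
niche overlap, individual specialization, source contributions and feeding
rhythm.

The package is aimed at fish and food-web ecologists who work with the
standard two-tracer (δ13C, δ15N) toolkit and per-individual gut contents,
and want every index in one tested pipeline rather than scattered scripts.

## What it computes

**Gut contents** (`trophicniche.diet`)

- %W / %N diet profiles per individual and group (detritus excluded from
  count-based metrics by convention), GSI and fullness indices,
  taxonomic richness.
- Simplified Morisita dietary overlap
  `C_ij = 2 Σ p_ik p_jk / (Σ p_ik² + Σ p_jk²)`, with `C_ij > 0.6` the
  conventional significance call.
- Roughgarden's Shannon decomposition of total niche width,
  `TNW = −Σ q_k ln q_k = WIC + BIC`, where
  `WIC = Σ p_i (−Σ p_ik ln p_ik)`; the ratio WIC/TNW measures individual
  specialization (0 = all specialists, 1 = all generalists). Mean pairwise
  proportional similarity `PS_ij = Σ min(p_ik, p_jk)` complements it.

**Isotope niche geometry** (`trophicniche.isotopes`)

- Layman metrics: δ15N range (NR), δ13C range (CR), mean distance to
  centroid (CD), mean nearest-neighbour distance (MNND), convex-hull area
  (TA).
- Standard ellipse area `SEA = π√(λ₁λ₂)` from the sample covariance, the
  small-sample correction `SEAc = SEA·(n−1)/(n−2)`, pairwise ellipse
  overlap at any coverage, and OLS of a tracer on standard length.

**Bayesian mixing model** (`trophicniche.mixing`) — consumer tracer values
modelled as `x_j ~ N(Σ p_k(μ_jk+λ_jk), Σ p_k²(ω_jk²+τ_jk²) + σ_j²)` with a
Dirichlet prior on the source-proportion simplex `p`, trophic enrichment
factors λ±τ (1.3±0.3 ‰ for δ13C, 2.3±0.18 ‰ for δ15N), and half-Normal
residual SDs; sampled by ensemble MCMC with split-R̂ diagnostics.

**Inference** (`trophicniche.inference`) — two-sample Hotelling T², the
residual permutation procedure (RPP) for CD/MNND/centroid contrasts,
Pearson correlation, and the gut-fullness linear mixed model
`FF ~ Group + Time + Group×Time + (1|Season)` fitted by ML with
likelihood-ratio χ² tests.

**Synthetic data** (`trophicniche.simulate`) — generators for all four
input tables (Dirichlet-multinomial diets with tunable specialization,
bivariate-normal isotopes from the published group summaries, consumers
drawn from the mixing model's own generative law, and latent-Gaussian
ordinal fullness series).

## Worked example

```python
import numpy as np
from trophicniche import diet, reference, inference

profiles = reference.diet_profiles(basis="mass")   # published %W means
c = diet.morisita_index(profiles["small_juvenile"], profiles["large_juvenile"])
print(round(c, 3), diet.overlap_significant(c))

x = [reference.NICHE_TABLE["WIC_over_TNW"][g] for g in reference.GROUPS]
y = [reference.NICHE_TABLE["diet_similarity"][g] for g in reference.GROUPS]
r = inference.pearson(x, y)
print(round(r.statistic, 3), round(r.p_value, 3))
```

prints

```
0.982 True
-0.642 0.358
```

— the small- and large-juvenile diets overlap almost completely (Morisita
0.982, far above the 0.6 threshold), and across the four size groups the
specialization ratio WIC/TNW correlates at r = −0.642 (p = 0.358, n = 4)
with within-group diet similarity.

The full analysis is laid out as numbered drivers:

```bash
python analysis/01_simulate_datasets.py      # synthetic input tables
python analysis/02_diet_composition.py       # %W/%N + Morisita overlap matrix
python analysis/03_isotope_niche.py          # Layman/SEA/SEAc + ellipse overlap
python analysis/04_mixing_model.py           # 12-source posterior contributions
python analysis/05_feeding_rhythm.py         # mixed model + step-down LRTs
python analysis/06_specialization_correlation.py
```

each printing its findings and writing tables under `results/`. On the
default seed the rhythm step reports, e.g.,
`time: chi2 = 152.771, p = 1.062e-29` against `group: chi2 = 1.328,
p = 0.7226` — a strong diel feeding rhythm with no size-group difference.

There is also a CLI mirroring the same stages
(`trophic simulate|diet|niche|overlap|mix|rhythm|test`, exit code 2 on
validation errors).

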