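# Methods

## The model

A sample's element panel x = [x₁, …, x_D] (D ≥ 3, all parts > 0) is treated
as a composition: only ratios are informative, and any per-sample or
per-element multiplicative factor is nuisance.  All analysis happens in
log-ratio coordinates:

- **clr** — clr(x)ᵢ = ln(xᵢ/g(x)), g(x) = (∏xᵢ)^{1/D}.  Scale-invariant,
  symmetric in the parts, but singular (coordinates sum to 0).
- **ilr** — the pivot (sequential binary partition) basis
  zᵢ = √(i/(i+1)) ln((x₁⋯xᵢ)^{1/i}/x_{i+1}), an isometry of clr onto
  ℝ^{D−1}.  Used wherever a full-rank covariance is required (MANOVA,
  Hotelling T²).  The basis follows the panel's element order and is
  recorded as `pivot-sbp`; every reported statistic is invariant to this
  choice (verified by a permutation test in the suite).

**PCA.** The clr matrix is column-centered (equivalently: each element is
divided by its across-sample geometric mean) and decomposed by SVD.
Variance shares are squared singular values over their sum.  Because clr
column rescaling only shifts columns by constants, the whole decomposition
is invariant to per-element units — Fe can stay in % w/w without changing
a single variance share, though units are harmonized anyway so that raw
outputs stay interpretable.

**Biplot and ratio loadings.** With arrows G = V·S/√(n−1) (covariance
scaling, α = 0), G Gᵀ reproduces the clr covariance exactly and
‖Gᵢ−Gⱼ‖² = var ln(xᵢ/xⱼ) when all components are kept; truncation to two
components gives the usual biplot approximation.  The multiplicative ratio
loading of PC k on the pair (i, j) is h = exp(Gᵢₖ−Gⱼₖ); h ≍ 1 plays the
role of a zero loading.  The α = 0 convention and the 1/√(n−1) denominator
are package choices: the denominator makes arrow products unbiased
covariance estimates, and favouring the variable structure over inter-sample
distances is what the ratio-loading interpretation needs.

**Group tests.** One-way MANOVA on ilr coordinates uses Wilks'
Λ = det(W)/det(W+B) with Rao's F transformation (exact for ≤ 3 groups,
which covers the bundled survey; cross-checked against statsmodels).
Pairwise comparisons use two-sample Hotelling T² with the pooled covariance
and an F conversion on (p, n₁+n₂−p−1) df.  Multiplicity correction is Holm
step-down by default (uniformly more powerful than Bonferroni; both are
available and reports name the method used).

**Contamination index.** PC1 sample scores, after a deterministic sign
rule: the geometric mean of the multiplicative loadings of
{source elements}/reference on PC1 must exceed 1 (sources default to
Ni, Cr, Co; reference to Ti).  SVD sign ambiguity is thereby removed and
"larger = more contaminated" holds by construction.  Exports are CSV or
RFC 7946 GeoJSON (WGS84, [lon, lat]).

## Pre-processing defaults and why

- **Unit harmonization** (% w/w × 10⁴ → µg g⁻¹) runs before everything;
  provably irrelevant to the clr-PCA, required for ratios and geometric
  means.
- **LOD** = 3 × SD of repeated analytical blanks, sample SD (n−1): the
  convention is a recorded package choice.
- **Below-LOD cells** are replaced by 0.65 × LOD (simple multiplicative
  substitution; configurable fraction in (0, 1]).  Compositional methods
  need strictly positive parts, so zeros may never enter the log-ratio
  stage.
- **Replicates** ("bis" rows) can be kept (`keep_all`), collapsed to the
  element-wise geometric mean per thallus (`geometric_mean`), or dropped
  after the first measurement (`first`).  Replicate re-measurements are not
  independent statistical units, so the merged mode is the reporting
  default in the acceptance script; the bundled survey reproduces its
  reference ordination only in the 34-sample modes, which is why both modes
  are always computed and reported side by side.

## The bundled survey

39 measurement rows (34 thalli; replicates for samples 11, 23, 16, 19, 32)
over Co, Cu, Cr, Fe, Ni, Zn, Ti in groups COUN/NOU/PORO.  Two caveats are
worth knowing when using the printed per-group geometric-mean rows as
checks: the PORO Cu and Cr summary values shipped with the data are not
consistent with any reading of the sample rows (a single ×10 slip in one Cu
cell would explain the Cu value exactly), and the NOU Cu summary is ~5 %
off.  The concentration cells themselves are internally consistent — every
other group × element geometric mean matches within print rounding — and
the analysis never uses the summary rows.  Sample coordinates are synthetic
plausible points (three area centroids plus deterministic jitter) intended
only to exercise the mapping exports; the survey itself carries
no coordinates.

## Synthetic survey generator

Each sample's log-concentration is baseline + gradient + noise:

- baselines: round numbers of the order of the background group
  (Co 3, Cu 4, Cr 30, Fe 4000, Ni 50, Zn 50, Ti 300 µg g⁻¹);
- gradient: a latent exposure t = U(0.5, 1.5) · ln f_g (0 in clean groups)
  added to the source elements and t/2 to Fe ("affected to a lesser
  extent"); group factors default to 1 / 8 / 30 for background / city /
  mine, matching the enrichment span of the bundled survey;
- noise: independent per-element lognormal, σ calibrated on the bundled
  survey — 0.4 for the source elements (from the scatter of their pairwise
  log-ratios), 0.5 for Fe, 1.2 for Ti (crustal dust load varies far more
  than the source ratios), plus an antithetic Zn/Cu axis (σ = 0.65) that is
  uncorrelated with the contamination gradient by construction;
- replicates: each row is duplicated with probability 0.15 with extra
  lognormal measurement noise (σ = 0.3, the value observed between the
  bundled survey's replicate pairs).

The recorded truth is the log-enrichment actually applied, so index
recovery can be scored by rank correlation.  What the generator does *not*
emulate: spatial structure (no distance–decay or wind model; coordinates
are decorative), inter-element noise correlation beyond the Zn/Cu axis,
and heavy-tailed measurement error.  Passing recovery and calibration tests
therefore demonstrates correctness of the machinery under the assumed
lognormal model, not robustness to real-world artifacts.

## Numerical choices

- Geometric means and products always via log space (no overflow).
- clr-inverse requires the coordinate sum to vanish within 1e-8 relative
  tolerance; closure is computed with a max-shift for safety.
- PCA keeps all SVD components; "rank" questions use a 1e-10 relative
  threshold on singular values.  Sign orientation is applied only through
  `orient_pc` (PC1); other components keep the LAPACK convention, and every
  comparison in the suite treats per-component signs as arbitrary.
- Degenerate inputs fail loudly: constant matrices (no variance), singular
  pooled covariances, orientation exactly 1, non-positive parts.

## Sizes used by the checks

The null-calibration check runs 2000 simulated surveys of 3 × 8 samples
with 5 elements (ilr dimension 4) — small enough to complete in seconds,
large enough that the binomial 95 % band around α = 0.05 is ±0.01.
Convergence checks of the generator use n = 5000 per group.  The recovery
check uses the default survey sizes (11/15/8 plus replicates).

## Known limitations

- The Rao F approximation is exact only for ≤ 3 groups or ≤ 2 dimensions;
  for larger designs its p-values are approximate (as in standard software).
- No robust PCA, shrinkage covariances, alr transform, zero-imputation
  beyond the LOD substitution, spatial interpolation, or varimax rotation
  (the oriented PC1 makes rotation unnecessary for this design).
- Display binning of the index for maps is cosmetic and untested by design.
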