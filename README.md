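# lichencoda

Compositional data analysis (CoDA) for trace-metal biomonitoring surveys —
built around the use of epiphytic lichens to map the atmospheric impact of
nickel mining and ore treatment.

Element concentrations measured in a biomonitor are *compositional*: only
the ratios between parts carry information, and the closure constraint makes
raw correlations (and therefore ordinary PCA and MANOVA) misleading.
`lichencoda` implements the standard log-ratio workflow for multi-group
concentration surveys:

- **Survey handling** — wide-CSV I/O, unit harmonization (% w/w → µg g⁻¹),
  detection limits (LOD = 3 × SD of analytical blanks), multiplicative
  below-LOD substitution, replicate aggregation, per-group geometric means,
  and the classical single-reference (metal/Ti) normalization for comparison.
- **Log-ratio transforms** — clr(x)ᵢ = ln(xᵢ / g(x)) with g the geometric
  mean of the parts, and the orthonormal ilr (pivot basis)
  zᵢ = √(i/(i+1)) · ln( (x₁⋯xᵢ)^{1/i} / x_{i+1} ).
- **Compositional PCA** — SVD of the column-centered clr matrix, covariance
  biplots (arrow link length ≈ SD of the pairwise log-ratio), and per-pair
  **ratio loadings** hᵢⱼ,ₖ = exp(arrowᵢₖ − arrowⱼₖ), the multiplicative
  influence of PC k on the ratio xᵢ/xⱼ (h = 1 ⇔ no influence).
- **Group inference** — one-way MANOVA (Wilks' Λ, Rao's F) and pairwise
  Hotelling T² tests in ilr coordinates with Holm or Bonferroni correction.
- **Contamination index** — the PC1 sample score, sign-oriented so that the
  source elements (Ni, Cr, Co) over the crustal reference (Ti) load
  positively; exported as CSV or GeoJSON for mapping.
- **Synthetic surveys** — a lognormal generator with a latent contamination
  gradient and known ground truth, used for calibration and recovery tests.

## Worked example

The package bundles a 39-row survey (34 lichen thalli, 5 measured twice) of
Co, Cu, Cr, Fe, Ni, Zn and Ti in three groups: countryside background
(COUN), the Noumea peninsula near a pyrometallurgical plant (NOU), and an
open-cast Ni mine (PORO).

```python
import lichencoda as lc

survey = lc.datasets.lichen_survey()
res = lc.analyze(survey, replicate_mode="geometric_mean")

print((100 * res["var_explained"][:2]).round(1))   # [57.6 24. ]
print(round(100 * res["cum2"], 1))                 # 81.6
print(f"{res['manova'].p_value:.1e}")              # 4.2e-16
print(res["index"].groupby("group")["index"].mean().round(2))
# COUN   -1.46
# NOU    -0.12
# PORO    2.24
```

The first two principal components carry 81.6 % of the total log-ratio
variance.  PC1 is dominated by the (Ni, Cr, Co)/Ti ratios — the mining
signature — and orders the groups PORO > NOU > COUN; the MANOVA confirms
the group separation (p ≈ 4e-16), as do all pairwise Hotelling T² tests
after Holm adjustment (all p < 1e-4).  The per-sample PC1 score is the
contamination index exported for mapping.

The same pipeline runs from the shell:

```sh
lichencoda run --mode geometric_mean --out-dir demo_run --plots
lichencoda simulate --out synth.csv --truth-out truth.csv --seed 7
lichencoda run --input synth.csv --out-dir synth_run
```

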