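# foramenflow

Paleophysiology from a hole in a bone: the femoral **nutrient foramen** is
the opening through which the nutrient artery enters the shaft, so its size
bounds the arterial lumen and thereby the blood flow perfusing the femur —
an osteological proxy for aerobic capacity that fossilizes.  `foramenflow`
implements the full inference chain used to compare extinct giant
xenarthrans (ground sloths, glyptodonts) with extant mammals:

1. **Hemodynamics.**  Foramen minor diameter → circular area (summed over
   foramina) → arterial lumen radius `r = sqrt(0.2·ΣA/π)` (the lumen
   occupies ~20 % of the foramen on average) → flow via the empirical
   polynomial `log₁₀ Q̇ = −0.20 (log₁₀ r)² + 1.91 log₁₀ r + 1.82`
   (Q̇ in cm³ s⁻¹, r in mm), plus the legacy Poiseuille-style index
   `Qi = r⁴/L`.
2. **Phylogenetic signal.**  BM, single-optimum OU and white-noise models
   fitted by ML to log₁₀ body mass and log₁₀ Q̇ on a time-calibrated,
   *non-ultrametric* phylogeny (fossil tips end before the present), with
   Akaike weights choosing the working correlation.
3. **Allometry and ANCOVA.**  PGLS of `log₁₀ Q̇ = b·log₁₀ Bm + a_g` with the
   OU-derived "corMartins" correlation `exp(−α·d)` (α profiled by ML);
   common-slope vs per-group-slope comparison by AIC/BIC and Wald tests;
   Cholesky-whitened residuals checked with a Monte-Carlo Lilliefors test;
   pairwise elevation contrasts with Bonferroni adjustment.  An intercept
   difference `Δ` is a **flow ratio** `10^Δ` at equal body mass.
4. **Metabolic-rate imputation.**  A joint multivariate OU model of
   (log MMR, log Q̇, log Bm) on the tree; missing fossil MMR and ancestral
   states are exact conditional-Gaussian means with 95 % intervals;
   mass-independent MMR is reported as mL O₂ h⁻¹ g⁻⁰·⁶⁷.

A first-class synthetic-data generator (`simulate_tree`,
`simulate_allometry`, `emit_specimens`) reproduces the statistical design —
88 tips with 19 fossils, slope 0.74, group elevations −5.31 / −5.47 /
−5.77 / −5.35 — so every stage is testable without museum data.

## Worked example

```bash
python examples/06_full_pipeline.py
```

generates a synthetic bundle at the study design and runs every stage:

```
stages: aggregate, model_selection, pgls, residual_normality, ancova, mvou, mmr_estimates

common slope: 0.740 +/- 0.037
  Epitheria                intercept  -5.313
  Prototheria+Metatheria   intercept  -5.539
  Xenarthra                intercept  -5.680
  Xenarthra_fossil         intercept  -5.393

residual normality (Lilliefors MC): p = 0.189
joint model: mvOU (AIC gap over mvBM = 21.0)
leave-one-out MMR prediction R^2 = 0.960
significant elevation contrasts: 4 of 6
  Epitheria vs Xenarthra: flow ratio 2.33
  ...
```

Read: the common-slope PGLS recovers the generating allometry (slope 0.740,
true 0.74; intercepts within sampling error of the generating elevations);
whitened residuals are compatible with normality; the joint OU model beats
multivariate BM decisively and predicts a held-out tip's MMR with R² ≈ 0.96;
at equal body mass, the Epitheria-like group moves ~2.3× the femoral blood
volume of the extant-xenarthran-like group in this replicate.

The other examples isolate one capability each: `01` the foramen→flow
chain, `02` tree kernels on a non-ultrametric tree, `03` BM/OU/WN model
selection, `04` the group allometry and contrasts, `05` fossil MMR
imputation.

There is also a thin CLI:

```bash
foramenflow simulate --seed 13 --out bundle/
foramenflow tree-check --tree bundle/tree.nwk
foramenflow run-all --tree bundle/tree.nwk --specimens bundle/specimens.csv \
    --table bundle/taxa.csv --seed 2 --out report.json
```

## Layout

- `src/foramenflow/tree.py` — newick ingestion (dendropy-backed), shared-path
  and corMartins kernels, non-ultrametric utilities
- `hemodynamics.py` — foramen → Q̇/Qi chain, specimen aggregation, CSV I/O
- `evomodels.py` — BM/OU/WN maximum likelihood and Akaike weights
- `pgls.py` — phylogenetic GLS, model comparison, whitened-residual
  Lilliefors test, pairwise ANCOVA, flow ratios
- `mvou.py` — multivariate OU kernel, ML fitting, conditional imputation
  and ancestral states
- `simulate.py` — study-design generator (trees, traits, specimens)
- `validation.py` — replicate calibration experiments
- `pipeline.py`, `cli.py` — one-call replication and the shell front end
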