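# Methods

## The measurement model

The nutrient artery's lumen cannot be observed in dry or fossil bone, so it
is reconstructed from the foramen it passed through.  Per femur:

- each foramen's area is the circle of its **minor** diameter, `π(d/2)²` —
  the minor axis is the binding constraint on the vessel, so this is the
  conservative choice (an elliptical minor×major option is deliberately out
  of scope);
- multiple foramina on one femur are **summed before** any scaling, so two
  foramina are exactly equivalent to one foramen of their combined area;
- the arterial lumen is taken to occupy 20 % of the summed foramen area
  (`occupancy`, configurable), giving the effective lumen radius
  `r = sqrt(0.2·ΣA/π)` in mm;
- flow follows the empirical curved allometry
  `log₁₀ Q̇ = −0.20 x² + 1.91 x + 1.82`, `x = log₁₀ r`, with Q̇ in cm³ s⁻¹
  and r in mm.  The polynomial is applied verbatim in these units; its
  dimensional bookkeeping is inherited from its calibration on live mammals
  and is not re-derived here.  It increases for `x < 4.775`, far above any
  anatomical radius, so flow is monotone in foramen size throughout.
- the legacy index `Qi = r⁴/L` uses the **foramen-equivalent** radius
  `sqrt(ΣA/π)` (not the 20 % lumen radius) over femur length, matching its
  historical definition; both radii are exposed since usage in the
  literature is not uniform.

Specimens are aggregated to taxa by the **geometric mean** of per-specimen
Q̇ (and Qi): all downstream analyses operate on log₁₀ Q̇, and the geometric
mean is the mean on that scale.  An arithmetic-mean option exists.  Only
adult femora with at least one observed foramen contribute; a taxon with no
usable specimen yields "no estimate", never zero flow.

## Trees and kernels

Trees are rooted, time-calibrated (Ma) and may be non-ultrametric: a fossil
tip's depth is the present-day height minus its age.  Branch lengths are
kept in absolute time — OU rates are then "per Ma" — with an optional
unit-height normalization flag.  Two kernels are used:

- BM covariance `C_ij = depth(MRCA(i,j))` (shared root-to-MRCA path);
- the OU-derived "corMartins" correlation `exp(−α·d_ij)` on patristic
  distances, unit diagonal.

Zero-length terminal branches are permitted with a warning (they make two
tips perfectly correlated under BM); polytomies are accepted as-is.

## Univariate evolutionary models

BM, single-optimum OU and WN are Gaussian, fitted by exact ML with the mean
and scale profiled in closed form; only the OU pull α needs numerical work
(bounded search over ln α ∈ [−10, 10] from a deterministic 41-point grid,
then Brent refinement).  On a non-ultrametric tree the OU covariance is
`σ²/(2α)·e^{−α d_ij}(1 − e^{−2α t_ij})` with `t_ij` the root-to-MRCA time;
the process starts at the optimum at the root (θ = z₀), the simplest
single-optimum form that handles unequal tip depths.  `α → 0` recovers BM
analytically (`expm1` keeps the limit stable).  Parameter counts: BM 2,
OU 3, WN 2; comparison by AIC and Akaike weights (AICc differs negligibly
at n = 88 and is available by flag).

## PGLS, ANCOVA and diagnostics

The allometry `log₁₀ Q̇ = b·log₁₀ Bm + a_g` is fitted by GLS with working
correlation corMartins(α), α either fixed or profiled by ML (plain ML, not
REML, so AIC/BIC compare across fixed-effect structures; the univariate OU
α̂ initializes the profile search).  Group intercepts use cell-means coding;
the interaction variant adds slope deviations for all non-reference groups,
tested jointly by Wald χ².  The selection convention: keep the common slope
unless the interaction is jointly significant at 0.05; ΔAIC/ΔBIC are
reported verbatim rather than folded into a hard rule.  Coefficient
covariance uses the bias-corrected scale `RSS_w/(n−p)`; contrasts use a
normal (z) reference (a t option exists), Bonferroni-adjusted over all
G(G−1)/2 = 6 pairs.  An elevation difference Δ maps to a flow ratio 10^Δ at
equal mass.  The single joint common-slope fit is used for the per-group
equations — that is what makes the four printed slopes identical by
construction.

Residual normality is assessed on whitened residuals `u = L⁻¹(y − Xβ̂)`
with `V = LLᵀ` (equivalently a Cholesky root of `V⁻¹`), using the
Lilliefors statistic with a **Monte-Carlo** null: 10⁴ seeded standard-normal
samples of the same n, cached per (n, replicates, seed).  The add-one
estimator `(1+#{D₀ ≥ D})/(10⁴+1)` keeps p-values in (0, 1].

## The joint multivariate OU model

(log MMR, log Q̇, log Bm) follow
`dX = −A(X − θ)dt + R dW`, `Σ = RRᵀ`, started at θ at the root (a
stationary-root variant, where the root is drawn from the process's
stationary distribution, is available by flag).  For nodes
at depths `T_u, T_v` separating at depth `s`,
`Cov = e^{−A(T_u−s)} V(s) e^{−Aᵀ(T_v−s)}` with
`V(s) = ∫₀ˢ e^{−Aw} Σ e^{−Aᵀw} dw`, evaluated in the eigenbasis of the
symmetric positive-definite pull A (a quadrature oracle cross-checks this
in the tests).  ML runs over log-Cholesky factors of A and Σ with θ
profiled by GLS; `mode="full"` (k = 15 at p = 3) or `mode="diagonal"`
(diagonal pull, k = 12), the latter the default in replicate experiments
for speed — cross-trait coupling then enters through Σ alone.  Multivariate
BM (k = 9) is the AIC reference.  Optimizer: L-BFGS-B, initialized from
per-trait univariate OU grid fits and empirical cross-correlations
(off-diagonals shrunk until positive definite).

Any subset of tip×trait entries may be missing (fossils lack MMR but keep
Q̇ and Bm).  The likelihood marginalizes by row/column deletion; missing
tips and internal nodes are estimated as **exact conditional means** of the
joint Gaussian — the normative definition here, verified against explicit
Schur-complement computation.  Intervals are ±1.96 sd **conditional on the
point estimates of (A, Σ, θ)**: parameter uncertainty is not propagated, so
empirical coverage runs slightly below nominal (≈93 % pooled in the
calibration experiment, within the accepted 90–99 % band).  Predictive
ability is summarized as the squared Pearson correlation of observed vs
predicted values, with predictions taken **leave-one-out** (each observed
MMR masked and re-estimated) so the statistic is not trivially 1.
Mass-independent MMR is `MMR/Bm^0.67` (mL O₂ h⁻¹ g⁻⁰·⁶⁷).  MMR enters the
model as a raw log₁₀ total with Bm as a coordinate of the process, not
pre-mass-corrected — the joint covariance carries the mass dependence.

## The synthetic study and what it does (not) show

The generator reproduces the design, not the data: a Yule tree rescaled to
180 Ma (crown-mammal scale) with 69 extant tips and 19 fossil tips whose
ages are uniform on (0.01, 0.6)×height (a Pleistocene-to-Miocene spread);
clade-painted groups (targets 26 and 14 extant tips for the non-placental
and xenarthran clades) so group and phylogeny are confounded exactly as in
the real design; log₁₀ Bm by BM (root 3.5, rate 0.0125/Ma, tip sd ≈ 1.5);
log₁₀ Q̇ = 0.74·log₁₀ Bm + a_g + ε with the four published elevations and
ε OU-correlated (α = 0.02/Ma, i.e. ~35 Ma half-life; stationary sd 0.25);
log₁₀ MMR drawn from its conditional under a joint OU with
A = diag(0.03, 0.03, 0.02), θ = (4.3, −2.72, 3.5) (consistent with the
Epitheria line at Bm = 3.5 and ~100 mL O₂ h⁻¹ g⁻⁰·⁶⁷), and diffusion
correlations (0.90, 0.95, 0.85) for (MMR,Q̇), (MMR,Bm), (Q̇,Bm) — MMR is
empirically tied to mass and flow about this strongly.  Specimen emission
inverts the measurement chain exactly; measurement noise is expressed on
the log₁₀-flow scale (`r = inverse_qdot(Q̇·10^{N(0, 0.02)})`) so `noise_sd`
is directly the specimen-level sd of log₁₀ Q̇ — noise placed on the radius
would be amplified ~1.9× by the polynomial's local slope and decouple the
knob from the quantity analysed.  About 4 % of femora carry two foramina
splitting one area; femur length follows geometric similarity
(`log₁₀ L = log₁₀ Bm/3 + 1`), a device to exercise Qi only.

Passing calibrations on these data show the estimators are correct and
well-calibrated **under the assumed model with confounded group/phylogeny
structure**.  They do not validate the 20 % occupancy constant, the flow
polynomial's external calibration, body-mass compilations, or measurement
protocols — none of which are statistical claims of this package.

## Replicate experiment sizes

Calibration experiments (also run by `scripts/acceptance.py`) use one
seeded study-design tree with fresh trait draws per replicate: 100
replicates for slope-CI coverage and ANCOVA type-I error, 50 for
interaction power, 200 for imputation R²/coverage (diagonal-pull fits).
These sizes put Monte-Carlo error comfortably inside the decision bands
(binomial sd ≈ 2 % at n = 100).

## Known limitations

- Single-optimum OU only; no multi-regime (OUM) or early-burst models.
- CIs on imputed values ignore parameter uncertainty (see above).
- The corMartins structure is a correlation, not the stationary OU
  covariance; tips of very different depths are treated as homoskedastic
  on the residual scale.
- The Yule-with-truncation tree model is not a fossilized birth–death
  process; fossil placement is random with respect to groups.
- `pgls_fit` requires every table taxon in the tree but tolerates a table
  smaller than the tree; the pipeline requires full coverage.
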