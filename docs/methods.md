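# Methods

`lfapp` implements two computational arms around one biological question:
does the soluble amyloid precursor protein ectodomain (sAPPα) bind
iron-saturated lactoferrin (holo-Lf), and why does the lactoferrin gene
(*LTF*) rank at the top of a tree-ensemble feature selection of an
Alzheimer's case/control brain RNA-seq cohort while a parametric
differential-expression analysis ranks it far down the list. This note
documents the models, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Hydrodynamics

**Svedberg/Stokes closed form.** A species with sedimentation coefficient
*s* (Svedberg, 1 S = 1e−13 s) and frictional ratio *f/f₀* in a solvent of
density ρ, viscosity η and partial specific volume v̄ has molar mass

    M = [ s·N_A·(f/f₀)·6πη·(3v̄/4πN_A)^(1/3) / (1 − v̄ρ) ]^(3/2)

obtained by eliminating the friction coefficient between the Svedberg
relation and Stokes' law for the anhydrous sphere of the same mass.
`s_from_mass` is its exact inverse (s ∝ M^(2/3) at fixed *f/f₀*), and the
Stokes–Einstein diffusion coefficient D = kT/f satisfies the Svedberg
identity D·M·(1 − v̄ρ) = s·R·T, which the tests verify to 1e−6 relative.

*Solution conditions.* v̄ = 0.73 mL/g, ρ = 0.99823 g/mL, η = 1.002 mPa·s
at 293.15 K — canonical values for an unmodified protein in water at
20 °C; all are configurable. Under them the four observed c(S) peaks
(3.9 S/1.40, 5.1 S/1.38, 6.9 S/1.39, 9.8 S/1.36) map to masses within
15% of the reported 61/79/142/223 kDa. The residual mismatch is
attributable to the unreported buffer conditions and to glycosylation:
lactoferrin is glycosylated, which lowers its effective v̄, and indeed the
79 kDa (free lactoferrin) point reproduces worst at v̄ = 0.73. The mass
report therefore also prints, for each peak, the v̄ that would reproduce
the printed mass exactly (`implied_vbar`); these all fall in the
protein-plausible 0.70–0.76 mL/g band. No resolution of the ambiguity is
hard-coded.

**Lamm equation.** Transport in the sector-shaped cell obeys
∂c/∂t = (1/r)·∂/∂r[rD∂c/∂r − sω²r²c]. The solver is a conservative
finite volume on a uniform radial grid (default 400 cells between the
6.00 cm meniscus and 7.25 cm base at 50,000 rpm): the face flux is
upwinded in the (outward) sedimentation term and centred in diffusion,
integrated by Crank–Nicolson with automatic sub-stepping keeping the
advective CFL number at 0.5 and the diffusive step below 4Δr²/D (an
accuracy cap; the scheme is unconditionally stable). Zero-flux walls make
the discrete sector mass Σcᵢrᵢ Δr conserved to machine precision, and the
boundary midpoint follows the ideal migration law r_m·exp(sω²t) to
better than 0.1% on the test configurations. Numerical (upwind) diffusion
at 400 cells is roughly 1.5e−7 cm²/s, a quarter of a 60 kDa protein's
physical D — acceptable for desk-scale kernels, and the c(S) round-trip
tests confirm peak positions are unaffected.

**c(S) deconvolution.** Scans are modelled as Σⱼ cⱼ·Kⱼ with Kⱼ the
unit-loading Lamm kernel of grid species sⱼ (D derived from a shared
*f/f₀*), fitted by non-negative least squares with a second-difference
Tikhonov penalty — a convex, reproducible substitution for the
maximum-entropy regulariser used by the original analysis software; both
are smoothness priors on a non-negative distribution, and the quantities
carried forward (peak position, integrated signal, weight-average s) are
insensitive to the choice at desk scale. λ defaults to the discrepancy
principle: the largest value whose residual RMS does not exceed the
stated noise SD (0.005 AU absorbance noise by default). The default grid
is 30 log-spaced points on 1–15 S. Radii within 0.015 cm of the meniscus
and 0.06 cm of the base are excluded from the fit: the pellet build-up in
the last cell is grid-resolution-dependent and would otherwise dominate
the least squares. The weight-average sedimentation coefficient is the
trapezoidal s_w = ∫s·c(s)ds / ∫c(s)ds over the requested range.

## Binding

**Sequential two-site scheme (s_w observable).** A + L ⇌ AL (Kd₁),
AL + L ⇌ AL₂ (Kd₂). Free ligand is the unique root in [0, l_tot] of the
ligand balance; the scalar solver brackets it with Brent's method, and
the vectorised forward model solves the equivalent cubic by safeguarded
Newton (the two agree to 1e−6 and the tests check conservation at 1e−9
and mass action at 1e−8 over random draws). The observable is the
signal-weighted species average s_w = Σwᵢcᵢsᵢ/Σwᵢcᵢ over {A, L, AL, AL₂}
— free lactoferrin contributes because the experiment integrates
whole-mixture c(S) distributions; a flag restricts the average to
acceptor-containing species if desired. Species s values default to the
four observed peak positions and signal weights to the species masses
(A280 extinction scales roughly with mass); both can be overridden or,
in principle, freed, though with 8-point titrations fixing them avoids
over-parameterisation. The sequential parameterisation was chosen for
the sedimentation arm and the independent-sites parameterisation for the
fluorescence arm to match how each measurement is usually modelled; the
two conventions are related by statistical factors (for two identical
independent sites, Kd₁:₁ = K/2 and Kd₁:₂ = 2K).

**Independent-two-site fluorescence model.** F = f₀ + ΔF₁θ₁ + ΔF₂θ₂ with
θᵢ = L/(Kdᵢ + L) and free L the root of l_tot = L + a_tot(θ₁ + θ₂) —
ligand depletion handled exactly. The fractional-occupancy normalisation
of the amplitudes is adopted (the change in fluorescence is taken as
proportional to the fraction of each site occupied). Default amplitudes
ΔF₁ = 0.10·f₀ and ΔF₂ = 0.05·f₀ sum to the observed 1.15-fold total
fluorescence increase at saturation.

**Fitting.** Weighted least squares (per-point 1/σ²; σ defaults to 1% of
the observable) minimised by trust-region reflective least squares on
log₁₀-Kd coordinates (box [1 nM, 1 mM]) from n_starts = 32 log-uniform
random starts, base seed 20210816; the best converged start is returned
with delta-method standard errors, R², and per-point residuals. One-site
and two-site fits are compared by ΔR², by small-sample-corrected AIC,
and by an exact Wald–Wolfowitz runs test on the residual signs (lower
tail: too few runs = systematically curved residuals; p-values from the
exact combinatorial distribution, validated against full enumeration).
Stoichiometry selection enumerates integer (n_A, n_L) pairs and minimises
the relative mass mismatch against the complex peak mass; with the
observed 61/79/223 kDa peaks this selects 1 APP : 2 lactoferrin with <2%
mismatch.

## Transcriptomics

**TMM.** Trimmed mean of M-values with the canonical trims (30% on M,
5% on A), inverse asymptotic binomial-variance weights, the
75th-percentile rule for the reference sample, and factors centred to
geometric mean 1. Agrees with edgeR's `calcNormFactors` within 2% on
mixed fixtures (cross-checked in the test suite through Rscript).
"Trimmed mean of means" in the originating description is read as TMM.

**log-CPM.** log₂((count + 0.5) / (TMM-effective library size) × 1e6).

**ComBat.** Parametric empirical-Bayes location/scale batch adjustment:
gene-wise standardisation retaining preserved design columns (the
case/control indicator is preserved by default, so the biological signal
is not removed along with batch), per-batch location γ and scale δ²
shrunk toward across-gene normal and inverse-gamma priors with
method-of-moments hyperparameters, conditional updates iterated to
ΔL∞ < 1e−4. Two deliberate conventions differ from the reference R
implementation: the pooled gene variance uses the unbiased denominator
(n − rank of design) rather than n, which makes the no-shrinkage mode an
exact projection (re-adjusting adjusted data is a no-op, tested at
1e−6); and degenerate priors (zero across-gene variance) fall back to
the unshrunk estimates, which makes the EB path exact on fixtures whose
batch effect is a constant shift in standardised units. Adjusted values
correlate with `sva::ComBat` output above 0.9995 on shift fixtures, with
residual differences explained by the variance-denominator convention.
With EB shrinkage enabled, exact idempotence is mathematically
unattainable (each pass re-shrinks the shrinkage residuals); the exact
mode exists for workflows that need a strict fixed point.

**NB differential expression.** Per-gene NB2 log-linear model with
offset log(TMM-effective library size) and design intercept + batch +
sex + study + centred age + centred RIN + group, fitted by IRLS
vectorised across genes. Dispersions: the Cox–Reid adjusted profile
likelihood (APL = ℓ − ½log det XᵀWX) is evaluated on a shared 15-point
log-spaced grid (1e−4 to 4); the common dispersion maximises the summed
APL and per-gene dispersions the per-gene APL (quadratic interpolation
on the grid), then each gene's estimate is shrunk toward the common
value by a log-scale weighted average with 20 prior degrees of freedom
against the residual degrees of freedom. The group coefficient is tested
by the likelihood-ratio χ²₁ statistic at the shrunken dispersion, with
Benjamini–Hochberg FDR and ranking by (FDR, p). This is a deliberate,
documented simplification of edgeR — no trended dispersion, no
quasi-likelihood — because the package's point is the contrast with
feature selection, not edgeR internals; the null calibration (type-I
fraction at nominal 0.05 within [0.03, 0.07] on 2,000 null NB genes at
n = 20 + 20) and the log2FC recovery checks are the accuracy contract.
Genes with all-zero counts are dropped; no other filtering.

## Feature selection

**Importance.** Out-of-bag permutation importance over a scikit-learn
random forest: per tree, the decrease in OOB accuracy (classification)
or increase in OOB MSE (regression) when one feature column is permuted
among that tree's OOB samples, averaged over trees. Only features a tree
actually splits on can change its predictions, so all others contribute
exactly zero for that tree — the implementation walks the fitted tree
structures directly, which makes the statistic affordable at thousands
of features. The statistic is signed; noise features centre on zero.

**Boruta.** Each run appends one independently permuted shadow copy of
every undecided real feature (minimum 5 shadows), and every undecided
real feature whose importance exceeds the best shadow importance scores
a hit. Decisions are exact binomial tail tests against
Binomial(n_runs, ½) with Bonferroni correction over the starting feature
count: the upper tail confirms, the lower tail rejects; rejected
features leave the model, confirmed features remain (they stay available
to the forest and keep accumulating importance history). The run loop
stops when every feature is decided or max_runs is reached; remaining
tentative features can be resolved by comparing their median importance
with the median per-run shadow maximum. Two Z-scores are reported:
`z_history` (a feature's importance-history mean over its SD) and
`z_population` (how many across-feature SDs a feature's mean importance
sits above the mean feature). Ranking uses z_population with z_history
as tie-break: it matches the "standard deviations more important than
the mean feature" reading, and history-internal Z ranking empirically
rewards tiny-but-stable importances over genuinely informative features
at desk-scale run counts. Desk defaults are max_runs = 100 and
n_trees = 300; the originating analysis ran 10,000 iterations over
23,056 genes, which is cluster-scale, and the scaling is linear in both.

**Ranking contrast.** `compare_rankings` aligns the Boruta rank
(z_population) with the DEA rank (FDR) over a shared gene universe,
reports the confirmed-versus-DEG overlap, a per-gene divergence score
(DEA rank − Boruta rank), and an outlier-sensitivity table: for each
confirmed feature, the share of its total signal in the group opposite
its fold-change direction that is carried by that group's four highest
samples — the diagnostic that explains parametric/ensemble rank
divergence.

## Synthetic data

All generators are pure functions of (config, seed).

**Counts.** NB counts with log-normal baselines (ln-mean 5, ln-SD 2),
gamma(2, 0.05) gene dispersions (mean 0.1, typical bulk tissue), 17% DE
genes (the DEG prevalence reported for the emulated cohort) with
N(0, 0.8) log2 effects, three batches with N(0, 0.25) gene×batch log
effects, per-sample depth log-SD 0.15, and covariates (age, sex, RIN,
study) with mild case/control imbalance. The covariates carry no
expression effect; they are present so the DE design matches the
original model specification.

**Sentinel gene.** Cases are drawn at a moderate mean with low-to-middling
dispersion (a consistent elevation); controls are drawn from a
near-zero, overdispersed background, the four largest are
deterministically rescaled so they carry exactly the configured share
(default 55%) of the total control signal, and the whole control group
is rescaled so the realised case/control mean ratio is 2^0.5338. This
reproduces, by construction, the emulated structure: a modest measured
fold change, a control group whose signal is concentrated in four
outlier subjects, and a case group whose elevation is consistent. The
exact-share scaling guarantees the 55% property in every realisation
rather than in expectation. What the generator does *not* emulate:
gene–gene co-expression modules, cell-type composition effects,
count-level technical artefacts, or any real LTF biology — so passing
divergence tests show that the pipeline behaves as designed under this
statistical structure, not that it would reproduce the original cohort's
gene lists.

**Pathology burden.** softplus(effect × standardised sentinel expression
+ group offset + Gaussian noise) — a non-negative, sentinel-linked
surrogate for an areal-fraction immunoreactivity measure, used to
exercise the regression mode of the selector.

**Titrations.** s_w titrations apply multiplicative Gaussian noise
(CV 1% by default) to the two-site forward model on the experimental
design (acceptor 2.5 µM, ligand 0–5 µM, 8 points). Fluorescence
titrations use a 13-point log-spaced ligand grid to 25 µM acquired in
triplicate (the fluorescence measurements being emulated were acquired
in triplicate) and additive noise scaled to the titration's dynamic
range — relative noise on the raw 340 nm intensity would be ~8× the
binding signal because the curve rides on a large unliganded baseline,
which is inconsistent with the near-unity fit quality such titrations
reach in practice. Sedimentation scans are the Lamm solver plus i.i.d.
Gaussian absorbance noise (SD 0.005 AU).

## Problem sizes used in the test suite

The suite runs the full pipelines at desk scale, chosen to exercise
every code path with meaningful statistics: 2,000 genes × 120 samples
for the divergence fixtures (20 seeds), 500-feature noise fixtures for
selector type-I control (20 seeds), 2,000-gene nulls for DE calibration,
50 seeded replicates for titration-recovery statistics, and 150–400
radial cells / 4–8 scans for the sedimentation round trips. The
cohort-scale preset (`rosmap_like.yaml`: 23,056 genes, 589 samples,
10,000 selector iterations) ships for completeness and runs for hours.

## Known limitations

- The Lamm solver is first-order accurate in the sedimentation term;
  very sharp boundaries at high s are numerically broadened. No
  time-invariant or radial-invariant noise elements, no meniscus/base
  fitting, no 2-D size-and-shape analysis.
- The exact algebraic form of the originating supplementary s_w model is
  not public; the signal-weighted species average implemented here is
  the natural reading and is flagged with a config switch for the
  complexes-only convention.
- The NB DE arm is not an edgeR clone (see above); it is calibrated, not
  byte-identical.
- Boruta decisions are slightly anti-conservative in the same way the
  original is: a noise feature whose in-sample correlation with the
  label is persistently extreme can be confirmed; the binomial-vs-½ null
  absorbs most but not all of this (family-wise rate ≈ α across seeds).
- The QC step for outlier samples reports PCA/clustering diagnostics
  only and never drops samples automatically, since no thresholds were
  specified for the original workflow.
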