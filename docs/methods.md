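# Methods

This note documents the models, parameter choices and numerical decisions
behind `longimeth`, and what the synthetic benchmark does and does not show
about real array data.

## Synthetic cohort model

The generator emulates an EPIC-like longitudinal blood methylome study with
three maternal-condition groups (C / Ob / ObDia) and three timepoints
(t0 birth = cord blood, t6, t12 = peripheral blood; 12-month follow-up
sparse). The default layout is 13 / 15 / 11 subjects with 4 per group at
t12, 90 samples in all; every size is configurable through `CohortDesign`.

**Baseline betas** are drawn per probe from a three-part mixture —
hypomethylated Beta(2, 20), hypermethylated Beta(20, 2) (45% each) and a
hemimethylated Beta(10, 10) minority (10%) — clipped to (0.03, 0.97). This
reproduces the bimodality of array data; it does not reproduce probe-type
chemistry differences beyond a design-type label, nor probe-specific
variance structure.

**Sample generation.** For sample s with cell weights w (Dirichlet, see
below), probe i has

    beta(i, s) = sum_k w_k * expit( logit(R_ik) + delta_i(s) + a_subj + b_plate + e_is )

with R the tissue's reference panel, `a_subj ~ N(0, subject_sd²)`,
`b_plate ~ N(0, plate_sd²)` and `e_is ~ N(0, noise_sd²)`, all on the logit
(natural log-odds) scale. Planted shifts `delta_i` are computed as
`logit(mu + dBeta) − logit(mu)` at the probe's baseline `mu`, so the
noise-free mean beta moves by exactly the requested amount; shifts that
would push the mean outside (0.01, 0.99) are rejected.

Defaults: `subject_sd = noise_sd = 0.2`, giving an intraclass correlation
of 0.5 on the M-value scale and a per-sample beta-scale SD of roughly
0.02–0.05 — the range typical of array technical plus short-term biological
variation. (A logit SD of 0.4 was considered and rejected as unrealistically
noisy: it implies beta-scale SD near 0.1 at mid-range probes.)
`plate_sd = 0.1` adds a modest batch effect over two plates assigned by
subject (plate structure is this package's construct; the study design does
not specify one). Detection p-values are ~Uniform(0, 10⁻³) with a 0.1%
failure rate drawn from Uniform(0.011, 0.5).

**Cell composition.** Cord blood uses a 7-type panel (CD4T, CD8T, B, NK,
granulocytes, monocytes, nucleated RBC), peripheral blood a 6-type panel;
the granulocyte column carries the same name in both, as analysts harmonise
flow-sorted cord and peripheral references when one longitudinal model
spans both tissues. Per-timepoint Dirichlet parameters make cord samples
granulocyte/nRBC-rich and shift lymphocyte fractions upward over the first
year, mimicking the developmental composition drift reported for infant
blood. Each panel's cell types are displaced by ±0.7 beta at 60 dedicated
probes (cap-scaled for small manifests), giving the |Δβ| > 0.5
discriminating loci reference-based deconvolution needs.

**Planted truth.** Cross-sectional effects shift the first-named group at
all timepoints; longitudinal effects are persistent changes acquired at the
later timepoint (a 0>6 effect is present at t6 and t12). Region-level truth
is planted on *isolated clusters* of exactly the requested probe count
(cluster separated from neighbours by more than the region window): if a
planted run is a slice of a larger cluster, correlation-aware smoothing
legitimately drags the surrounding null probes into the grown region and
the "truth" is ill-defined, not the caller wrong.

**OGTT labelling.** Simulated mothers can be screened with the two-step
rule: a 50 g glucose challenge above 140 mg/dL triggers the 100 g OGTT, and
gestational diabetes requires at least two of the four plasma values to be
at or above 105 / 190 / 165 / 145 mg/dL (fasting / 1 h / 2 h / 3 h).

## Preprocessing

Probes are removed in a fixed order — detection p > 0.01 in *any* sample,
sex-chromosome, cross-reactive, SNP-overlapping — with each probe
attributed to the first criterion that removes it, so per-criterion counts
are reproducible and filtering is idempotent. Gap signals use the
gaphunter rule (gap threshold 0.25; a probe is outlier-driven when all
sample groups but one hold at most 5/90 of samples); the default discards
all gap signals, with `outlier_driven_only` available since the two kinds
are distinguished in the field.

BMIQ-style normalisation fits a three-state (U/H/M) beta mixture per sample
and design type by EM with a moment-matching M-step (initial state cuts at
beta 0.2/0.8, ≤100 iterations, log-likelihood tolerance 10⁻⁴); type-II U-
and M-state betas are quantile-mapped onto the type-I state distributions
and the hemimethylated stretch is linearly rescaled between the mapped
boundaries. State assignment is by beta-value interval (cutpoints where
state responsibilities cross), which makes the map monotone by
construction; a final cumulative-max pass guarantees it numerically. EM
non-convergence falls back to an identity map for that sample with a
warning. M-values use logit clipping at 10⁻⁶ (configurable); betas exactly
0 or 1 have no finite M-value and clipping is the standard resolution.

## Cell deconvolution

Probe selection takes, per cell type, the top 50 probes by one-vs-rest
t-statistic in each direction (union over types, uninformative probes
dropped). Proportions solve min ‖b − Rw‖² s.t. w ≥ 0 with a soft
sum-to-one row appended to the design (weight √n_probes), then renormalise
to Σw = 1; a pre-normalisation sum outside [0.85, 1.15] warns. The solver
is plain NNLS, hence deterministic. t0 samples are routed to the cord
panel, later samples to the peripheral panel.

## Probe-level differential methylation

The design is treatment-coded (C and t0 as references) with sex, plate and
cell-proportion covariates; one cell type (the most abundant) is dropped to
break the sum-to-one collinearity, and rank is checked with the aliased
columns named on failure. The "Group" model does not include time as a
covariate (switchable); the cross-sectional Δβ pools all timepoints per
group, consistent with one DMP set per group contrast across the year.

The consensus correlation is estimated by evaluating, for a seeded
5,000-probe subsample, the restricted (REML) likelihood of the
equicorrelated model on a ρ grid (−0.20 to 0.98, step 0.01). The
block-Helmert eigenbasis diagonalises the equicorrelation covariance —
block means have variance 1 + (m−1)ρ, within-block contrasts 1 − ρ — so
each grid point costs one weighted least squares pass over all probes at
once. Per-probe maximisers are pooled by a 15%-trimmed mean on the atanh
scale, mapped back with tanh and capped at 0.99. The grid step (0.01) is an
order of magnitude finer than any tolerance used downstream.

GLS fitting whitens both the design and the M-value matrix through the
same eigenbasis and reduces to ordinary least squares. The empirical-Bayes
prior (d₀, s₀²) is fitted by matching log-variance moments to a scaled F
(trigamma inversion by Newton's method); equal sample variances drive
d₀ → ∞ and the moderated t to the fully pooled statistic, while d₀ = 0
(available as an override) recovers ordinary GLS t. Moderated p-values use
the t distribution with d₀ + d_g degrees of freedom (normal when d₀ = ∞);
BH adjustment is applied within each contrast separately.

Calibration caveat: with multi-cell-type panels, the cell-type-specific
probes are genuinely differentially methylated across timepoints (tissue
and composition change), and a linear composition adjustment cannot fully
absorb the nonlinear mixture; type-I error statements therefore refer to
probes without cell-type-specific signal, and the dedicated null
simulations use a single-cell-type panel.

## Region calling

Defaults pinned (and recorded in output headers): seed p = 0.01, smoothing
window and region gap = 1,000 bp, ACF bins of 50 bp up to 1,000 bp, BH
selection of smoothed seeds at 0.05 before the Sidak step. The ACF floors
negative estimates at zero; bins with fewer than 10 pairs inherit the
previous bin. Non-PSD correlation matrices assembled from binned ACF values
are repaired by eigenvalue clipping with a warning. The Sidak exponent is
(total bp spanned by tested probes per chromosome, summed) / region width,
the published method's convention. Manifest positions are 1-based; emitted
BED intervals are 0-based half-open. The final filters are exactly the
bespoke three: ≥3 CpGs, ≥66% of member CpGs sharing the modal direction,
|mean Δβ| > 0.01 (absolute change; the relative-change reading of "1% of
mean methylation" was considered and not adopted).

## Trajectory clustering

Mean betas at (t0, t6, t12) per significant longitudinal DMP are z-scaled
per probe; zero-variance trajectories are dropped with a warning. Scaled
three-point trajectories lie on a circle in the zero-sum plane, and
Spearman correlation between them takes few distinct values, so the
distance is 1 − ρ_Spearman with squared Euclidean distance folded in as a
strict tie-breaker (scaled to stay below the smallest Spearman gap of 0.5).
Clustering is PAM-style k-medoids with greedy maximin initialisation and
10 seeded restarts — chosen because it accepts arbitrary distances.

k is selected from the within-cluster sum-of-squares curve by maximum
perpendicular distance to the chord **of the log-WSS curve**. The raw-scale
chord rule provably locks onto the first (largest) merge when cluster
separations are comparable — WSS declines multiplicatively, so proportional
drops must be linearised before the chord comparison; on the six-shape
benchmark the raw rule returns k = 3 and the log rule the correct k = 6. A
normalised distance-to-chord below 0.05 is reported as a weak elbow and the
smallest k returned; an exactly flat curve does the same.

The six-shape benchmark places one template at the centre of each of the
six rank-ordering arcs of the scaled-trajectory circle (amplitude 0.08
around a 0.3 baseline, noise SD 0.01): gradual up/down, early up/down, and
the two non-monotone patterns. These are maximally and equally separated;
"early" shapes that differ from gradual ones only in timing (not ordering)
are deliberately not used, since no ordering-based distance separates them.

## Interplay classification

Developmental CpGs are probes significant (FDR < 0.05) in at least one
longitudinal window whose direction is preserved: a probe significant in
one window is excluded only if the other window's Δβ has the strictly
opposite sign (zero does not contradict). Maternal classification uses the
±1% rule — Hyper (Δβ > +0.01), Hypo (Δβ < −0.01), Equal otherwise, with the
boundary landing in Equal. Direction association crosses developmental
{hyper, hypo} with maternal {Hyper, Hypo} (Equal excluded) via Fisher's
exact test; the odds ratio is the Haldane-corrected cross-product.
Percentages in flow tables use largest-remainder rounding so they sum
to 100.

## Gene-set testing

Per-gene probe counts come from the manifest (multi-gene probes count for
every listed gene; intergenic probes for none). The probability that a gene
is selected is fitted by isotonic regression of the selection indicator on
probe count; a set's Wallenius odds is the **odds ratio** of the mean fitted
probability inside vs outside the set — the noncentral parameter is an
odds, and a plain probability ratio demonstrably under-corrects when
selection probabilities are large (null rejection 0.12 instead of ≤0.05 in
the probe-count-biased null). The tail probability uses the Wallenius
noncentral hypergeometric distribution; at w = 1 it reduces exactly to the
central hypergeometric (one-sided Fisher) tail. The test is conservative by
construction, like the bias-corrected methods in this area. Note that with
*uniformly random* gene sets plain Fisher is not anti-conservative (the
overlap is marginally hypergeometric by exchangeability); the bias bites —
and the calibration benchmark therefore samples sets — with membership
skewed towards probe-dense genes, as real pathway sets are.

## Benchmark problem sizes

The acceptance script and test suite use 3,000–6,000-probe manifests for
end-to-end stages, 10,000-probe cohorts for null calibration and region
recovery, 10⁶ draws for the Stouffer–Liptak Monte-Carlo oracle, and a
90-subject single-panel cohort for the intraclass-correlation recovery
measurement (at 39 subjects the realized between-subject variance of a
single cohort fluctuates enough to dominate the estimator's own error).
These sizes make every stage's behaviour measurable in minutes on one CPU
while leaving all thresholds at their study values.

## What passing does not show

The generator has no probe-type intensity chemistry, no raw two-channel
signal (so background/dye-bias correction is out of scope), no genetic
variation beneath SNP flags, no cross-reactive hybridisation signal, and
independent probes apart from planted regions — so spatial ACF estimates on
synthetic nulls are flat by construction. Recovery results bound what the
pipeline can do under its own assumptions; they do not certify performance
on real arrays, where unmodelled confounders (age drift within timepoint,
batch-by-group imbalance, population structure) are the usual failure
modes.
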