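# Methods

## The model

`pcafe` selects case/control-relevant features from an expression matrix
without using the class labels in the embedding step, then assembles
miRNA–mRNA interaction candidates from the selected features.

Let `x_ij` be the expression of feature `i` (an mRNA probe, gene, or
miRNA) in sample `j`, arranged in a matrix `X` of shape
`(N features, S samples)`. Every sample column is standardized over the
features so that `(1/N) Σ_i x_ij = 0` and `(1/N) Σ_i x_ij² = 1`. The
*population* (1/N) variance is used deliberately: the second identity
then holds exactly, which the unit tests assert to 1e−10. Profiles
distributed on a log2 scale can be de-logged (`2^x`) first; overflow in
the de-log raises instead of silently producing infinities.

### Feature-side PCA

Standard PCA embeds samples. Here the *features* are embedded: the
k-th PC score vector `u_k` is an eigenvector of the gram matrix
`G = X Xᵀ` (eigenvalue `λ_k`, descending), and the loading attributed to
sample `j` is `v_kj = (Xᵀ u_k)_j`, an eigenvector of `XᵀX`. The
implementation goes through the thin SVD of `X`, which solves the
sample-side problem; the `N × N` gram matrix is never materialized, so
cost is `O(N S²)` and a 22k-probe × 400-sample matrix is routine.
Components with `λ_k < 1e−10 · λ_1` are dropped. Because each sample
column is centered over features, the all-ones vector is a null
eigenvector of `G`; every retained `u_k` is therefore orthogonal to it
and has exactly zero mean over features. Signs of eigenvectors are
arbitrary; we fix them deterministically (largest-magnitude score entry
positive), and every downstream statistic is even in `u_k`, which a
property test asserts.

### Component selection and the outlier statistic

The discriminative component set Ω collects the components whose
loadings differ between cases and controls by a two-sample
unequal-variance (Welch) t-test at unadjusted p < 0.05. Welch rather
than the pooled-variance test is a documented choice (it is the common
default of the statistical environments used for this kind of analysis)
and is the same test used later for the regulation calls. Ω can be
empty — on a label-free null matrix it is empty with probability about
`0.95^K` — and downstream stages treat that as the explicit
`NoDiscriminativeComponentsError` rather than guessing.

Each feature is then scored by

    T_i = Σ_{k∈Ω} (u_ki / σ_k)²,

where `σ_k` is the standard deviation of the k-th scores over features
(mean subtracted, denominator n−1; since `u_k` has zero mean and unit
norm this equals `1/√(N−1)` exactly, and the 1/n vs 1/(n−1) choice only
rescales `T_i` by `(N−1)/N`, a negligible and documented effect).
Assuming Gaussian scores under the null, `T_i` is chi-squared with
`|Ω|` degrees of freedom, and `P_i` is its upper-tail probability.
Features with Benjamini–Hochberg-adjusted `P_i < 0.01` are selected.
Null calibration is tested directly: on 2000 × (15 vs 15) Gaussian
matrices the realized `P_i` pass a Kolmogorov–Smirnov uniformity check
and BH selection at 0.01 yields essentially zero features over 20 seeds.

A structural property worth knowing: when the class signal concentrates
on `n_p` planted features, the leading discriminative eigenvector
spreads its unit mass over them, so `T_i` saturates near `(N−1)/n_p`
no matter how large the effect size is. Power therefore depends on the
*planted fraction*, not only on the effect: a 10% planted fraction in a
small (say 80-feature) matrix cannot clear the BH 0.01 gate even at
enormous effects, while the same absolute signal in a 2000-feature
matrix is found easily. The synthetic defaults (2.5% and 3.3% planted)
sit in the regime the method is designed for.

### Regulation calls and reciprocal pairs

Among the selected features only, up/down regulation is called by Welch
t-test with BH correction *over the selected set* (adjusted p < 0.05);
the alternative universe (all features) is available as a configuration
but not the default, and a test asserts that adding non-selected
features to the matrix does not change the calls. Direction is the sign
of (case mean − control mean); an exact zero difference (measure zero)
excludes the feature.

Conserved miRNA targets are read from a TargetScan-style
family-info TSV (family, gene symbol, species columns; filtered to one
taxon; duplicate rows collapse to set membership). Mature miRNA names
are normalized (species prefix stripped, case-folded, arm suffix
-3p/-5p preserved) and resolved to families first by exact mature-name
lookup, then by matching the family string; unresolved names are
counted and excluded. A pair (miRNA, gene) is emitted iff the gene is a
conserved target of the miRNA's family and the two directions are
opposite — both orientations (miRNA-up/mRNA-down and the reverse) are
accepted. Probes mapping to gene symbols are handled by an optional
two-column map; identity by default.

### Discrimination (validation)

PC loadings are recomputed on the submatrix of selected features —
re-normalized column-wise over that restricted set — and each sample's
first `L` loadings feed a linear discriminant with pooled within-class
covariance and *equal priors* (1/2, 1/2) regardless of class imbalance.
Leave-one-out cross-validation refits the classifier per fold; the
embedding itself is computed once on all samples. This mirrors the
original procedure for this method and is required to reproduce its
published confusion matrices, but it does leak information (the
held-out sample participates in the embedding); the resulting accuracy
should be read as a consistency check on the selected features, not as
an unbiased generalization estimate. `L` is a per-run parameter; a
helper scans `L = 1..L_max` and keeps the best LOOCV accuracy
(smallest L on ties), mirroring the trial-and-error choice the
procedure calls for. A singular pooled covariance raises with a
suggestion to reduce `L`.

Note that re-normalization over the restricted set removes any shift
common to all selected features within a sample; a selection in which
every feature moves the same way therefore carries no signal into the
recomputed loadings. Real selections contain both directions.

### Fisher's exact test

The 2×2 LOOCV confusion matrix (rows predicted, columns true, case
first) is scored by Fisher's exact test. The two-sided p-value uses the
minimum-likelihood rule (sum the probabilities of all tables with the
observed margins that are no more probable than the observed one) — the
convention of `scipy.stats.fisher_exact` and of R's `fisher.test`, and
the only convention supported. The odds ratio is the conditional
maximum-likelihood estimate under Fisher's noncentral hypergeometric
model: the unique root of the score equation
`E_ψ[x11 | margins] = x11`, solved by bracketed root-finding on
`log ψ` to relative tolerance better than 1e−8. If `x11` sits at the
top of its conditional support the estimate is `+∞`; at the bottom, 0.
Tests cross-check the estimate against full-enumeration and
grid-search oracles and against an independent library implementation.
R's `fisher.test` reports the same estimand but solves on the
reciprocal scale with a loose default tolerance, so its printed values
can differ from the exact root by up to about 1% at large odds ratios;
published values computed with it inherit that granularity.

### q-values

As a secondary criterion the chi-squared p-values are converted to
Storey q-values: `π0` is estimated by the smoother
(`π0(λ) = #{p > λ} / (m(1−λ))` on the grid λ = 0.05…0.95, cubic
polynomial fit, evaluated at λ = 0.95, clipped to (0, 1]), and
`q_(r) = min_{r'≥r} π0 · m · p_(r') / r'`. With `π0` pinned to 1 the
q-values equal BH-adjusted p-values *exactly* (bitwise; a regression
test asserts it). This is a deliberate reimplementation of the q-value
idea rather than of any particular package's density machinery, so
FDR-count comparisons against outputs of other tools are qualitative
(zero vs nonzero patterns), not numeric. An FDR-control simulation
(80% uniform nulls, 20% Beta(0.1, 1) alternatives, m = 2000, 100
seeds) keeps the realized false-discovery proportion at q < 0.05 below
0.08. π0 estimation needs at least 20 p-values; below that, pass `pi0`
explicitly.

## Synthetic data

The generator emulates exactly what the pipeline consumes: two
column-normalizable case/control matrices (unmatched mRNA/miRNA cohorts
supported, as real paired designs often are), a conserved-target table,
and the planted truth. Baseline expression is i.i.d. Gaussian
(mean 0, `noise_sd`); each planted feature receives an additive shift
of ±`effect` pre-normalization units in the case samples, direction
random. Planted miRNAs point a fraction `reciprocal_fraction` of their
`targets_per_mirna` conserved targets at planted mRNAs of the opposite
direction (these are the true pairs); the remainder, and all targets of
null miRNAs, are decoys among null mRNAs. Defaults — 2000 mRNA / 300
miRNA features, 20 vs 20 samples per cohort, 50/10 planted, effect 2.0,
noise 1.0, 20 targets per miRNA, reciprocal fraction 0.8 — constitute
the reference scenario used by the acceptance checks; `targets_per_mirna
= 20` was fixed once as a desk-scale stand-in for the order of magnitude
of conserved-family out-degree. Generation is fully deterministic per
seed (byte-identical outputs).

What the generator does *not* emulate: probe-level effects (multiple
probes per gene, cross-hybridization), platform/batch structure,
heavy-tailed or correlated noise, and expression-dependent variance.
Passing the recovery tests therefore demonstrates correctness of the
pipeline's statistics under its own Gaussian assumptions, not
performance on any particular microarray platform. A heavier-tailed
noise knob exists for robustness exploration but is not the default,
since the chi-squared statistic's stated assumption is Gaussian scores.

## Numerical and design choices

- Eigen-solver: `numpy.linalg.svd` (LAPACK), deterministic for fixed
  input; component sign fixed by the largest-score convention.
- Degrees of freedom of the outlier statistic: `|Ω|` — the only reading
  consistent with summing `|Ω|` squared standardized Gaussian scores.
- Ω uses *unadjusted* p < 0.05 (no correction at the component stage;
  components are few and the stage is a screen, not an inference).
- BH for outlier gating at 0.01; regulation calls at 0.05 over the
  selected set; q-value criterion at 0.01. All thresholds are config
  parameters of the pipeline.
- Missing values: rows with any missing entry are dropped at ingestion
  (logged); this keeps the gram matrix well-defined without imputation.
- Multiple probes per feature are retained as distinct features.
- Degenerate inputs raise early with named coordinates: non-numeric
  cells, duplicate identifiers, constant sample columns, single-class
  labels, empty Ω, singular pooled covariance.

## Problem sizes

The test suite and the acceptance script run the reference scenario at
its stated size (2000/300 features, 40 samples per cohort, 20 replicate
seeds) — the full-scale conditions of the synthetic study design, which
complete in seconds because the decomposition works on the sample side.

## Known limitations

- The LOOCV embedding leak described above.
- `π0` smoothing uses a cubic polynomial rather than a smoothing
  spline; for very sparse alternatives the estimate is conservative
  (clipped at 1).
- The outlier statistic's planted-fraction saturation (see above)
  limits power on small feature panels.
- TargetScan parsing covers the family-info TSV layout; context scores
  and non-conserved site tables are out of scope.
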