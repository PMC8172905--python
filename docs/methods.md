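# Methods

This note documents the models, defaults and numerical choices behind
rsikit, and what the synthetic cohorts do and do not establish.

## RSI scoring

The radiosensitivity index is a linear form in within-sample ranks. For each
sample, the ten signature genes are ranked among themselves (ascending;
highest expression → rank 10; ties receive average ranks, so ranks always
sum to 55), and the score is the coefficient-weighted rank sum. Decisions:

- **Ranking scope** is the ten signature genes only, per sample — not
  genome-wide. This is the only reading under which "the highest-expressed
  gene is ranked 10" is coherent for a ten-gene list, and it makes the score
  invariant to monotone per-sample transforms (verified by property tests
  and exhaustive enumeration of all 10! rank assignments, which brackets the
  score in [−0.60510, 1.21910]).
- **Ties**: average ranks — the standard convention, and the only one that
  conserves the rank sum.
- **Boundary**: RSI-Low is score < θ strictly; θ defaults to the published
  0.46 and is configurable everywhere it is consumed (a 0.3745 variant
  circulates in the radiosensitivity literature).
- **No clipping**: the linear form is unbounded; extreme rank configurations
  legitimately score outside [0, 1] and are reported as computed.

Signature QC compares two datasets by per-gene rank means/sds, gene–gene
Spearman co-correlation and score dispersion; identical or monotonely
related datasets produce zero cross-dataset rank deltas.

## Single-sample enrichment

The TCIA statistic follows the kernel-CDF pathway: per gene, a Gaussian
kernel CDF against the gene's cross-sample distribution with bandwidth
sd/4 (a constant gene has no distribution; its statistic is defined as 0.5
and logged); per sample, genes are ordered by decreasing statistic and the
centred rank |p/2 − rank| weights the in-set steps of a Kolmogorov–Smirnov
random walk (τ = 1 by default; τ = 0 reduces to the unweighted KS
difference, which the tests check against an independent ECDF oracle). The
max-diff score is the maximum positive plus the minimum negative deviation
of the walk. Scores are z-transformed per cohort and per gene set using the
population sd; a sample is enriched when z > 0.35.

Two threshold variants appear in the source literature (0.35 in the methods
text, 0.32 in a figure legend); the default is 0.35 and both are ordinary
parameters. The 18-gene TCIA list ships as an editable GMT file — it is
configuration, not code — and any user-supplied set of ≥ 2 genes scores the
same way.

## Immune statistics

- **log2(M1/M2)**: deconvolution zeros are structural (the cell type is
  called absent), so zero-bearing samples are excluded rather than
  pseudo-counted — a pseudo-count would silently shape the reported
  correlation — and exclusions are counted in every report.
- **Spearman p-values**: exact permutation for n ≤ 10 without ties (the null
  distribution of Σd² is enumerated once per n and cached), asymptotic t
  approximation otherwise. Matrix correlations are pairwise-complete with
  per-cell n; cells with < 4 pairs are flagged missing. P-values are
  reported raw, with no multiplicity adjustment — callers comparing many
  pairs should adjust downstream.
- **Mann–Whitney U**: exact enumeration over all group assignments of the
  observed (tie-averaged) ranks when both groups have n ≤ 8, tie-corrected
  normal approximation otherwise; the two branches agree within 0.02
  absolute p at the crossover.
- **Differential filter**: retain |logFC| > 1 and adjusted p < 0.05, both
  strict, applied to externally produced tables. The underlying
  negative-binomial fit is out of scope by design — only the filter rule
  belongs to this pipeline.

## C2 classifier

Feature importance is the impurity-based mean decrease in Gini from a
random forest (500 trees, Gini criterion, √p features per split, unlimited
depth — the canonical defaults of the reference implementation; a seed is
mandatory). scikit-learn normalises importances to sum to one; the
above-mean selection rule is scale-free, so this changes nothing. Genes
strictly above the mean importance feed the classifier.

Evaluation defaults to stratified 5-fold cross-validation with metrics on
pooled out-of-fold class-1 probabilities: resubstitution would be
optimistic, and no particular holdout is canonical. Accuracy carries an
exact (Clopper–Pearson) binomial 95% CI; AUC uses the Mann–Whitney rank
formulation (ties count half), which the tests verify against brute-force
pair counting. Youden cutpoints scan midpoints between consecutive distinct
scores, choose the direction maximising sensitivity + specificity − 1, and
break ties toward the lower cutpoint.

## Survival

Kaplan–Meier, the log-rank test and the univariate Cox fit use lifelines
(Efron tie handling, Wald CIs; non-convergence yields a flagged estimate
rather than an exception). The optimal cutpoint maximises the absolute
standardised log-rank statistic |O−E|/√V over all splits leaving at least
`minprop` (default 0.1) of samples on each side.

**Selection caveat**: the replicated workflow selects the cutpoint and tests
it on the same data, which inflates the apparent separation. The test suite
quantifies this by re-testing null-selected cutpoints on independent
replicates (rejection stays at the nominal 5%); users should do the same on
real cohorts.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, not
any particular tumour biology:

- **Expression**: log-scale values with per-gene Gaussian noise
  (sd 1 by default). Background genes draw heterogeneous baselines
  (N(7, 2²)); the signature genes share one baseline (7.0) so their
  within-sample ranks are exchangeable under the null and the RSI spans its
  permutation range — with heterogeneous signature baselines the entire
  cohort can land on one side of the threshold, collapsing the latent
  groups.
- **C2 effect**: C2 samples (default 25% of the cohort, within C1–C6
  proportions 0.35/0.25/0.15/0.10/0.05/0.10) receive δ_RSI = 1.5 sd on the
  five classifier genes and δ_TCIA = 2 sd on the TCIA genes. Because the
  RSI mixes coefficient signs, the shift directions are a calibrated
  constant — up on JUN, CDK1, IRF1, STAT1 (the direction reported for
  RSI-Low tumours), down on ABL1 — whose sign-weighted coefficient sum
  (−0.122) guarantees C2 scores lower;
  `analysis/00_calibrate_shift_directions.py` re-verifies this empirically.
- **Immune fractions**: flat Dirichlet (concentration 1) over the 22
  standard deconvolution cell types; samples below the RSI threshold gain
  β_M1·(θ − RSI) of M1 mass (β_M1 = 0.1) before renormalisation, planting
  the negative RSI↔log2(M1/M2) correlation.
- **Survival**: exponential with baseline rate 0.1 per time unit; the
  RSI-High latent group's hazard is multiplied by h = 0.5 (high RSI
  protective, matching the reported direction), with independent
  exponential censoring calibrated to ~30% against the baseline hazard (the
  realised censored fraction varies with the group mix).
- Identical config + seed reproduces every table bitwise.

Effect sizes are chosen for testability — the source cohorts publish no
per-gene effect estimates — and are configurable. What passing tests show:
the pipeline recovers planted rank shifts, enrichment, couplings and
hazards at realistic cohort sizes, and produces no spurious signal under
null configurations. What they do not show: performance under real-data
features the generator omits — batch effects, platform-specific artefacts,
correlated background genes, non-exponential hazards, pan-cancer covariance
structure — nor any of the published cohort-specific magnitudes, which
derive from external data.

## Problem sizes

Defaults throughout target laptop-scale runs: cohorts of 600 samples and a
few hundred background genes, 500-tree forests, exhaustive 10! enumeration
(~4 s) and 100–1000-replicate simulations. All are parameters, not limits.
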