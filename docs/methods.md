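# Methods

This note documents the statistical procedures, the synthetic-cohort
model, and the numerical/design choices made where the published
description of the analysis chain left the design open.

## Data model

All analyses operate on homotopic region pairs: each pair has one left
and one right region with its own volume (mm³).  Asymmetry is always
left − right, so leftward dominance is positive.  Task contrasts are
dimensionless BOLD differences (sentence minus word-list) for three
tasks — production (PROD), listening (LISN), reading (READ).  Resting
data are per-subject T × N regional mean time series with a fixed
sampling interval (TR, seconds).  Missing cells are load errors, never
imputed: the analyses assume complete cases.

## Preprocessing of resting series

Per subject, each regional series is residualized against an intercept,
a linear trend, and any measured nuisance signals (white-matter-like and
CSF-like means) by ordinary least squares, then bandpassed 0.01–0.1 Hz
with a least-squares linear-phase FIR design applied forward–backward.
Defaults: 64 taps at TR = 2 s, transition bands 0.005–0.01 Hz and
0.10–0.15 Hz.  The filter class is given by the source analysis but not
its order or transitions; these defaults are feasible for 240-sample
runs and give ≥ 10 dB stopband attenuation after the two passes.  The
tap sum is forced to zero so a constant input is nulled exactly.
Zero-phase application was chosen over single-pass linear phase so that
filtering cannot introduce inter-regional lags into the correlations.
Operations are applied in the order regression → filter.

## Conjunction selection

Per pair and task, a two-sided one-sample t test of the left values
against zero (activation) and a paired t of left − right (asymmetry),
each with an explicit positivity guard on the mean.  Whether the
original tests were one- or two-sided is unstated; two-sided with a sign
guard is conservative and has the power of a one-sided test at α/2.  A
pair is selected when it passes both families in all three tasks.  No
multiplicity correction is applied beyond the product thresholds — the
conjunction null is exactly what the multiplied alphas control.
Zero-variance pairs are reported as failures with a warning; the run
aborts only if more than 1% of pairs are degenerate.

## Connectivity and clustering

Subject matrices are Pearson correlations with the diagonal set to zero
and off-diagonals capped at ±(1 − 10⁻¹²) so the Fisher transform stays
finite.  The group matrix is the arithmetic mean of the subject z
matrices.  Before clustering, the mean is back-transformed (tanh) to the
correlation scale and converted to d = (1 − r)/2; back-transforming
keeps d inside [0, 1], whereas z-scale distances would not be bounded.
Ward linkage uses the Lance–Williams recurrence (scipy); ties break
toward the smallest condensed index, which makes merge order
deterministic across platforms.

The number of networks is a plurality vote over ten classical indices —
silhouette, Calinski–Harabasz, Davies–Bouldin, Dunn, C-index,
McClain–Rao, point-biserial, Baker–Hubert gamma, Ball–Hall (largest
drop), and a Xie–Beni analogue on medoids — with ties resolved toward
the smaller k.  The original battery had 30 indices whose exact
composition is not recoverable; a fixed, documented subset with a
plurality vote preserves the decision rule.  Centroid-based indices use
each region's correlation profile (its row of the mean matrix) as the
feature vector, the only feature space available from the inputs.

### Multiscale bootstrap support

For each relative scale ρ ∈ {0.5, …, 1.4}, round(ρ·n) subjects are
resampled with replacement, the mean matrix rebuilt and re-clustered,
and each reference cluster counted when its exact leaf set occurs as a
clade.  The probit counts are fitted by weighted least squares to
z(σ) = vσ + c/σ with σ = √(1/ρ), weights from the delta-method binomial
variance, and AU = 1 − Φ(v − c).  Numerical care: counts pinned at 0 or
at the replicate ceiling are censored, not binomial, so they are
excluded from the two-parameter fit when at least two informative scales
remain; an exactly flat profile is fitted with c = 0 (the only value the
model allows), which reduces AU to the plain bootstrap proportion; all
counts at ceiling give AU = 1, all zero give AU = 0, with a degenerate
flag either way.

### Robustness

Average-linkage, diagonal-covariance Gaussian-mixture (best of 20
restarts by likelihood) and k-means (100 restarts by inertia) partitions
at the chosen k are compared with the Ward partition by the adjusted
Rand index.

## Network characterization

Network activation/asymmetry per subject and task is the volume-weighted
mean over member regions.  Profiles are compared by a two-factor
repeated-measures ANOVA (network × task) with Holm-corrected paired task
contrasts inside each network; this approximates the original
mixed-model ANOVA with Tukey HSD, whose exact error strata are
unstated — the testable claims are the qualitative orderings, which the
approximation preserves.  Inter-network correlations use unweighted
network-mean time series per subject (the source averaged voxels;
per-voxel volumes are unavailable at region level; a volume-weighted
variant is available behind a flag), Fisher-z averaging across subjects,
and a one-sided exact binomial sign test in the direction of the
observed majority with Bonferroni correction over network pairs.  The
one-sided convention reproduces the published worked examples
(78/138 → p ≈ 0.074; 86/138 → p ≈ 0.0024), which are inconsistent with a
two-sided test.

## Graph metrics and hubs

Graphs keep only positive correlations (signed graph analysis remains
contentious).  DC is the summed positive weight; BC uses Brandes'
algorithm with edge cost w⁻ᵅ and α = 1 (the cited weighted-path method
leaves α free; α = 1 is the pure weighted shortest path).  Centralities
are computed per subject and averaged; hub thresholds are the mean plus
one sample SD (ddof = 1) across the per-region means — this convention
reproduces the published thresholds (5.556 / 10.254 against the printed
5.55 / 10.26) from the printed table.  The participation index is
computed on the group-mean positive graph over all selected regions with
the final partition as modules; connector hubs are the top
⌈0.15 × N_selected⌉ participation values over the full selected set
(with 32 selected regions this yields 5, matching the published count,
whereas 15% of the 18-region core would give 3).  Published
participation values above the 3-module maximum of the Guimerà formula
(1 − 1/3) are not reproducible; the standard formula is used.

## Coupling between DC and activation

Per region: Pearson r between subjects' DC and left activation per task;
a DC main effect from regressing the subject's task-mean activation on
DC; and a DC × task interaction testing equality of task-specific slopes
after within-subject centering (the original repeated-measures MANCOVA
specification is unstated).  The hemisphere-wide control recomputes DC
against every left-hemisphere region.  Pooled coupling is the Pearson r
over all subject × region points per task, treating points as
exchangeable (no clustering correction — a documented limitation of the
pooled approach).  Task correlations sharing the DC variable are
compared with the Steiger z for overlapping dependent correlations.

## Synthetic cohort

The generator plants every feature the chain is supposed to find.

* **Selected set and tasks.**  32 of 185 pairs get left activation means
  0.73/0.43/0.55 and asymmetries 0.41/0.25/0.28 (PROD/LISN/READ), the
  published volume-weighted core profile; residual SD 0.3 per cell.
  Non-selected pairs have zero means.  At n = 144 the per-task tests
  have essentially full power on planted pairs and the nominal false
  positive rate elsewhere, so the selected set is recovered exactly in
  almost every cohort.
* **Connectivity.**  A population correlation matrix with within-module
  blocks 0.35/0.25/0.25 (sizes 18/8/6), three hub regions whose
  within-core rows are boosted by +0.15, background entries
  N(0, 0.05), and between-module blocks derived from *network-level*
  targets (−0.27 core–mem, +0.06 mem–visu, −0.04 core–visu) via
  r_pair = R·√(v̄_a·v̄_b), where v̄ is the variance of the module-mean
  series.  The network-level quantity is what the analysis measures, so
  the targets are specified on that scale.  PSD repair clips eigenvalues
  at 10⁻⁶ and renormalizes the diagonal; the build errors out if repair
  moves a planted block mean by more than 0.05.
* **Time series.**  Per subject, innovations N(0, C_s) pass through an
  AR(1) recursion (φ = 0.3, unit marginal variance, 50-sample burn-in),
  T = 240 at TR = 2 s.  Nuisance components (linear trend plus two
  smooth regressors with random loadings) are added and written
  alongside so the preprocessing stage has real work to do.
* **Coupling.**  Subject s carries w_s = clip(N(1, σ_w), 0.2, 1.0); the
  subject matrix is the blend I + w_s(C − I) (the upper clip keeps it
  PSD, since the repaired C sits on the PSD boundary) and the planted
  left activation of selected regions is shifted by c·(w_s − w̄),
  c = 1, equally across tasks.  σ_w is found by bisection on a
  closed-form predictor of the pooled DC–activation correlation whose
  noise term uses the large-sample covariance of Pearson correlations
  and an effective sample size computed from the AR(1) spectrum times
  the squared power response of the zero-phase bandpass (a filtfilt pass
  has amplitude |H|² and power gain |H|⁴).  With the default target
  ρ = 0.25 the measured pooled coupling across seeds centres on
  0.24–0.25.
* **What it does not emulate.**  Hemodynamics, spatial structure,
  physiological noise spectra, motion, or between-region differences in
  activation means.  Passing recovery tests therefore demonstrates the
  chain's correctness and calibration under the planted statistical
  structure, not robustness to real-data artefacts.

Determinism: one integer seed drives every stage through per-stage
seeds derived by hashing the stage name into a `SeedSequence`; the
pipeline report is byte-identical across reruns (timestamps go to the
log, not the report).

## Problem sizes used by tests and the reproduction script

Unit tests use a reduced profile (40 pairs, 40 subjects, T = 240) and
small bootstrap replicate counts (150–1000); the acceptance-style
recovery checks run 20 full-size cohorts (185 pairs, 144/138 subjects)
without the bootstrap stage, and one full-size bootstrap with 10,000
replicates, which keeps the whole suite within a few minutes on one
CPU.

## Known limitations

* AU values for clusters supported in nearly every replicate are
  reported as 1 (degenerate fit) rather than extrapolated; the WLS fit
  is only meaningful when several scales are informative.
* The pooled coupling analysis ignores within-subject dependence of the
  subject × region points.
* The index battery is a 10-index stand-in for the original 30-index
  vote; on well-separated planted structure the plurality decision is
  unchanged, but ambiguous real data could vote differently.
* The repeated-measures ANOVA assumes sphericity (no correction is
  applied); the paired contrasts with Holm correction do not rely on it.
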