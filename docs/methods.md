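# Methods

This note documents the models and procedures connlife implements, the
choices made where the design was genuinely open, and what the synthetic
cohort does and does not establish about real data.

## Temporal preprocessing

Node (or voxel) time series are cleaned in a fixed order: confound
regression first, then band-pass filtering. The two operations do not
commute; regressing first prevents the filter from re-introducing
confound energy into the regression residuals.

The confound design contains 31 columns: the 24 motion regressors
{R_t, R_t², R_{t−1}, R_{t−1}²} built from the six rigid-body parameters
(translations in mm, rotations in rad), three nuisance signals (CSF,
white matter, global), their first differences, and an intercept. Lag-1
columns have their first row set to 0 rather than dropping a volume, so
the series length is preserved. Removal is ordinary least squares; a
rank-deficient design falls back to the pseudoinverse with a warning
(the result is the same residual, since the fitted subspace is what
matters). Residuals are orthogonal to every design column to machine
precision.

Framewise displacement uses the Power convention: the sum of absolute
backward differences of the three translations plus the three rotations
converted to arc length on a 50 mm sphere — the radius is the common
convention; FD of the first volume is 0 by definition. Screening excludes
a subject when mean FD ≥ 0.2 mm **or** more than 20% of volumes exceed
0.2 mm; the decision object records which criterion fired. Note that the
mean criterion is inclusive ("equal or greater").

The band-pass (0.01–0.1 Hz at TR = 2.5 s) is a second-order Butterworth
filter applied forward-backward (zero phase). Zero-phase filtering is
chosen because phase shifts would bias pairwise correlations; the
effective magnitude response is the squared single-pass response, which
keeps a 0.05 Hz sinusoid within 5% of its amplitude and attenuates
0.18 Hz below 10%.

## Dual regression

Both stages are joint (multivariate) least squares: stage 1 fits every
volume on all K templates simultaneously, stage 2 fits every voxel's
series on all K subject time courses simultaneously. This matters when
templates are spatially correlated — one-template-at-a-time (marginal)
regression gives biased coefficients, and the test suite asserts the
joint answer against an explicit normal-equations oracle in exactly that
situation. Stage-2 time courses are scaled to unit variance by default
(the usual design-normalization convention, exposed as a flag), which
affects only the scale of the subject maps, not their pattern. Group ICA
itself is out of scope: templates are inputs.

## η² network integrity

For maps a and b over V voxels, with m the voxelwise mean map and M̄ its
grand mean:

η² = 1 − Σ[(a−m)² + (b−m)²] / Σ[(a−M̄)² + (b−M̄)²].

The identity Σ[(a−M̄)² + (b−M̄)²] = 2Σ(m−M̄)² + ½Σ(a−b)² shows the
numerator never exceeds the denominator, so η² ∈ [0, 1]; η² = 1 iff
a = b, and η² = 0 in the degenerate anti-similar case m ≡ M̄ (e.g.
b = −a). When both maps are constant and equal the statistic is
undefined and an error is raised. η² is computed over the whole shared
grid by default; an explicit mask is supported (the voxel count V
changes the statistic, so the masking rule is recorded in run
provenance).

The reference map per RSN is the voxelwise mean of subject-specific maps
from subjects aged ≤ 30 years (configurable; 40 gives nearly the same
reference under weak planted decay, which the tests verify). Subjects in
the reference subgroup contribute their own map to the reference; with
small reference groups this slightly inflates their η², which is
inherent to the mean-reference construction.

## Graph analysis

Connectivity is the full Pearson matrix over node time series; a
constant node series is a hard error naming the node. Graphs are binary,
undirected, and built from positive correlations only, with a strict
r > threshold rule (a tie at exactly the threshold is excluded — measure
zero in floats but deterministic), over the sweep
r ∈ {0.20, 0.25, 0.30, 0.35, 0.40}.

Conventions for quantities whose upstream tooling conventions are not
recoverable — these are this package's documented choices, emitted in
run provenance, not claims about any other tool:

- **Characteristic path length**: mean geodesic distance over reachable
  ordered pairs; unreachable pairs are excluded and their count is
  reported alongside the number of connected components.
- **Global efficiency**: mean of 1/d over ordered pairs with 1/∞ = 0, so
  disconnection is handled natively (complete graph → 1, empty → 0).
- **Betweenness**: per node, the fraction of geodesics between all other
  node pairs passing through it, ties split fractionally (Brandes);
  a maximal star's centre scores 1 and any complete graph 0. Raw
  (unnormalized) means are also emitted. The C implementation in
  python-igraph is used when importable, with networkx as fallback; both
  are validated against an explicit path-enumeration oracle.
- **Modularity**: Louvain, best of 10 seeded restarts by Q; deterministic
  under a fixed seed. Q = Σ_c (e_cc − a_c²).
- **Hierarchy β**: negative slope of log C(k) on log k over nodes with
  degree > 1 and positive clustering; NaN when fewer than two distinct
  degrees qualify.

All scalar metrics agree with brute-force all-pairs enumeration to
1e−12 on every random graph of ≤ 8 nodes tested (500 instances).
Node-order invariance holds exactly for the deterministic metrics;
Louvain's partition (and hence Q) can depend on node order through its
traversal, which is why Q is reported with its seed.

## Network-level connectivity

Correlations are transformed to z = atanh(r) *before* averaging (|r| ≥ 1
is clipped to 1 − 1e−7 with a warning). WNFC of a k-node network averages
exactly k(k−1)/2 pair values; BNFC of a (k, l) pair averages exactly k·l
values; self-connections never enter. Over the default 142-node RSN
subset the pair counts across all 14 + 91 cells sum to 142·141/2. The
full 91-cell BNFC table is always emitted; significance filtering is the
inference layer's job.

## Inference

Partial correlation residualizes both variables on an intercept plus the
covariates and correlates the residuals; p-values use Student's t with
df = n − 2 − (number of covariates). This is algebraically identical to
the regression-coefficient route, which the tests check to 1e−10 (and
against pingouin as an independent reference).

BH-FDR is the step-up rule at q = 0.05, applied per table family:
the 13–14 RSN rows of the similarity table, the metric set within each
graph threshold, and the 14 + 91 network-FC cells.

Normality screening is a one-sample KS test of *standardized* values
against the standard normal. Standardizing makes the test a composite
screen (Lilliefors-type situation) and its p-values conservative; with
raw values against N(0, 1) the test would reject trivially whenever the
measure's scale differs from 1, so the standardized variant is the one
implemented.

Mediation fits three OLS regressions sharing the covariate set (sex in
the pipeline), so ab = c − c′ holds exactly — on the point estimate and
on every bootstrap draw, both asserted to 1e−10. Bootstrap inference
resamples subjects with replacement (default 10,000 draws, seeded);
per path z = bootstrap mean / SD and p = 2·min(frac ≤ 0, frac ≥ 0),
floored at 2/n_boot. Percentile confidence intervals are the default for
transparency; BCa (bias correction from the bootstrap distribution,
acceleration from the jackknife) is available behind a flag. A
degenerate draw (singular normal equations, e.g. a constant resampled
regressor) is redrawn and counted. Candidate measures for mediation are
those with uncorrected p < 0.05 against both age and cognition.

Under a planted null (a = 0, b ≠ 0) the bootstrap ab test at p < 0.05
rejects at a rate inside [0.02, 0.08] over 200 simulations with
n_boot = 2000 — the reduced draw count keeps the calibration run inside
the test suite while leaving the rejection-rate target unchanged.

## The synthetic cohort

The generator's defaults are the study conditions: 129 subjects (ages
uniform on [21, 86]; the source cohort is roughly decade-balanced and
uniform is the simplest faithful stand-in), 72% female (93/129),
193 volumes at TR 2.5 s (198 acquired minus 5 dropped at ingestion),
ACE-R centered near 96 and clipped to [0, 100] with a cognitive-screen
flag at ≥ 89.

Node time series are drawn from an age-dependent block correlation
matrix: within-network blocks at 0.35 with a planted slope of −0.10 per
centered-age unit ((age − 50)/35), cross-network blocks at 0.08 with
slopes of ±0.08 planted on the visuospatial network's pairs (positive
with sensorimotor, primary visual, precuneus and anterior salience;
negative with language), and a weak 0.03 coupling for the 357
unassigned nodes. Any block leaving (−0.99, 0.99) is a hard error naming
the block; an assembled matrix that fails Cholesky is repaired by
eigenvalue clipping at 1e−6 and rescaling to unit diagonal. Volumes are
i.i.d. by default; an AR(1) option (unit marginal variance) is available
since the serial correlation of filtered data is unspecified. The slope
magnitudes are calibrated to produce partial correlations of roughly
|r| ≈ 0.3–0.5 at the cohort scale — the qualitative regime of interest —
not to reproduce any particular dataset's values.

Subject spatial maps drift from their group template with age:
map_k = (1 − λ)·template_k + λ·mean(other templates) + noise, with
λ = clip(0.20 + 0.22·age_c − 0.05·ε, 0, 0.95). The per-subject innovation
ε is *shared* with the cognition model: the latent mediator is
M = a·age_c + ε (a = −0.8) and
ACE-R = 96 + c′·age_c + b·M + 0.5·sex + noise (b = 1.2, c′ = −0.8,
noise SD 1.5). Sharing ε between the maps and the score is what makes
the planted mediation recoverable from the *measured* η² downstream
rather than only from the latent — the design goal of the generator.
Templates are smooth random blobs on a small grid (24×24×12 voxels,
z-map-like peak of 3); full MNI resolution adds nothing to testing a
voxelwise statistic.

Motion traces are 6-parameter random walks; rotation increments are
scaled by 1/50 mm⁻¹ so translations and rotations contribute equally to
FD. The low-motion scale (0.02 mm per step) yields mean FD ≈ 0.1 mm and
passes screening; the high-motion scale (0.06 mm) yields ≈ 0.29 mm and
fails it. The default high-motion fraction is 0 because the default
cohort emulates the *included* subjects; screening behaviour is
exercised by configuring the fraction explicitly.

Every generator draws from a child stream derived as
SeedSequence([seed, stage, subject]), so cohorts are byte-reproducible
under a fixed seed, per subject and per stage, independent of evaluation
order. Because stages regenerate deterministically from the master seed,
pipeline re-runs reproduce rather than resume: caching would change no
byte of output.

What passing tests show — and do not. The synthetic cohort has Gaussian
node signals, block-constant couplings, spatially unstructured map noise,
and a linear age model. Real rsfMRI data have none of these simplicities
(hemodynamic autocorrelation, spatially structured noise, non-linear
lifespan trajectories, arousal and physiological confounds). Passing the
suite therefore establishes the correctness of the *computations* —
formulas, conventions, inference calibration, and end-to-end sign
recovery under known ground truth — not the substantive neuroscience
conclusions one would draw on real data.

## Problem sizes used by the test suite

The suite runs the analytic and oracle checks at full stringency
(e.g. 10,000 random map pairs; 500 random graphs against brute force;
the 499-node parcellation end to end on single subjects) and the
simulation-based checks at cohort sizes chosen to estimate the relevant
signs and rates stably: 150-subject cohorts across 20 seeds for
end-to-end sign recovery, 200 simulations at n = 129 with 2,000
bootstrap draws for type-I calibration, and 40–100 seeds for the
per-generator sign-recovery checks.
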