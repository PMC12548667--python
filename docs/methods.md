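# Methods

`connrel` asks a narrow question with many moving parts: when the same brain
is scanned twice in a row, how similar are the two resting-state functional
connectomes — and how does the answer depend on defensible processing
choices?  This note describes the statistical model behind each stage, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical decisions a maintainer would want written down.

## Reliability model

Reliability is quantified with the intraclass correlation ICC(3,1): the
two-way mixed-effects, single-rater, consistency model.  For an n-subject,
k-session table (k = 2 throughout), the two-way ANOVA decomposition yields
between-subject (BMS) and error (EMS) mean squares, and

    ICC(3,1) = (BMS − EMS) / (BMS + (k − 1)·EMS).

The 95% confidence interval comes from F-distribution bounds on
F = BMS/EMS with df1 = n − 1 and df2 = (n − 1)(k − 1):
F_L = F / F_{0.975}(df1, df2), F_U = F · F_{0.975}(df2, df1), and each bound
maps to the ICC scale via (F* − 1)/(F* + k − 1).  Consistency ICC ignores
the session main effect, so a constant shift between sessions leaves it
unchanged — the property that makes it the standard choice for back-to-back
scans.  Estimates are binned poor (< 0.40), fair [0.40, 0.60), good
[0.60, 0.80], excellent (> 0.80); boundary values resolve downward
(0.60 → good boundary rule: 0.40 → fair, 0.60 → good, 0.80 → good) because
the verbal criteria fix only the open ends ("less than 0.40", "greater than
0.80").  Negative estimates are reported as computed and binned poor;
flooring them at zero would distort the estimator's sampling distribution,
which the simulation checks rely on.

Group contrasts of reliability Fisher-transform each group's per-atlas ICCs
and apply an independent two-sample pooled-variance t test; with 8 atlases
per group this yields df = 14, and Cohen's d is the mean difference over the
pooled SD on the z scale.  The network-size analysis pools (network, group,
atlas) cells and correlates network node count with Fisher-z ICC; with 123
network cells per group and two groups the test has df = 244.

## Synthetic two-session cohorts

The generator produces, per subject and session, a T × N parcellated signal
matrix plus six rigid-body motion parameters and three nuisance traces
(global, white-matter, CSF means) — the inputs a parcellated two-session
MRI study would provide.  Defaults mirror a realistic design: 300 volumes at
TR = 2 s (≈ 10 min per session), two groups of 45 and 41 subjects, group
mean framewise displacement 0.32 mm (between-subject SD 0.23) versus
0.24 mm (SD 0.11).

### Edge-level reliability calibration

Write z_ijs for the Fisher-z connectivity of edge j in subject i, session s.
The generative model is an additive hierarchy on the z scale:

    z_ijs = z0_j + b_ij + w_ijs,   Var(b) = σ_b²,  Var(w) = σ_w²,

so the latent edge ICC is ρ = σ_b²/(σ_b² + σ_w²).  Rather than adding iid
perturbations to a correlation matrix and repairing the result — at
realistic amplitudes (σ ≈ 0.2–0.3) an iid symmetric perturbation has
spectral radius ≈ 2σ√N, far beyond the template's smallest eigenvalue, and
the projection needed to restore positive semidefiniteness shrinks the
perturbation and silently destroys the σ_b/σ_w calibration — each level is
realized by Wishart resampling: the subject matrix is the correlation matrix
of a Wishart draw centred on the block template with m_b degrees of freedom,
and each session matrix is a Wishart-resampled copy of the subject matrix
with m_w degrees of freedom.  The classic result that a sample correlation
from m observations has Fisher-z variance ≈ 1/(m − 3), independent of the
edge's strength, gives the closed-form map m = 3 + 1/σ² (rounded to an
integer; the rounding error in ρ is < 1%).  Every intermediate matrix is a
valid (possibly rank-deficient) correlation matrix by construction — no
repair step, no calibration drift.

Estimating an edge from T volumes adds irreducible sampling noise with
z-variance ≈ 1/(T − 3), so the ICC of the *measured* edge is

    ρ_obs = σ_b² / (σ_b² + σ_w² + 1/(T − 3)),

reported by `GroundTruth.expected_observed_icc`.  With the default total
latent SD of 0.30 z-units (split σ_b/σ_w according to `target_edge_icc`),
ρ_obs stays within 0.03 of ρ at T = 296 — close enough that recovered edge
ICCs land within the ±0.05 acceptance band around the target, while keeping
between-subject connectome variability at the high end of what is plausible
for stable individual differences.  Recovery checks estimate edges from the
raw session signals without negative-edge censoring: censoring truncates the
edge distribution subject-selectively and would bias the estimator check,
and it is a masking convention orthogonal to the calibration being tested.

The block template uses within-network correlation 0.45 and between-network
0.12 — mid-range values for parcellated resting-state data that keep
negative-edge censoring from dominating within-network pairs.

### Motion and artifacts

Each subject owns a motion propensity μ_i drawn from a Gamma distribution
with the group's mean and SD; per-frame FD is exponential with mean μ_i
(frame 0 is the reference).  Each frame's FD is split randomly across the
six rigid-body parameters (rotations converted on a 50 mm sphere) and
integrated into positions, so the Power FD recomputed downstream equals the
injected trace.  This two-level skewed model reproduces the qualitative
scrubbing accounting of a real aging/TBI cohort from first principles: at
thresholds 2.0 / 1.0 / 0.5 mm the high-motion group loses on the order of
2 / 13 / 48 volumes per 296-volume run and the low-motion group much less,
with threshold and group orderings strict.

With probability `spike_rate` (default 0.10) a frame carries an additive
signal artifact: a fresh random spatial pattern scaled by `spike_gain`
(default 2.0 signal-SD per mm) times that frame's FD.  Two structural
choices matter.  The pattern is drawn per spike volume, not per run: a
single shared pattern would make the artifact temporally rank-one and the
global-signal regressor would absorb it almost completely, making scrubbing
inconsequential under the primary pipeline.  And because a subject's FD
propensity persists across sessions, the artifact contributes a
subject-stable component to connectivity — which is exactly what lets
scrubbing (which removes it) visibly change reliability.

Nuisance traces are unit-SD sinusoid-plus-AR(1) drifts (frequency uniform
in 0.01–0.03 Hz, AR coefficient 0.95) added with configurable amplitudes
(defaults: global 0.5, WM 0.3, CSF 0.3 signal-SD) and node loadings uniform
in [0.8, 1.2].  The measured "global" nuisance column is the realized mean
across nodes of the final signals — so global signal regression sees
artifacts, as it does in real data.

### What the generator does not emulate

Signals are stationary multivariate normal draws; there is no hemodynamic
forward model, no voxel level, no spatial autocorrelation within parcels, no
scanner drift beyond the AR(1) term, and session matrices are exchangeable
(no systematic session effects).  Rank-deficiency of the session
correlation matrices (rank ≈ m_b) is statistically harmless for pairwise
correlations but means the signals occupy a low-dimensional subspace, unlike
real BOLD.  Passing tests therefore certify the estimators and the pipeline
logic under a controlled model, not the behaviour of any particular scanner
or population.

## Post-processing variants

The canonical motion-handling multiverse has five cells: `primary` (GSR, no
scrubbing), `no-gsr`, and `scrub-2.0` / `scrub-1.0` / `scrub-0.5` (GSR plus
censoring of volumes with FD strictly above the threshold).  All variants
discard the first 4 non-steady-state volumes, regress a 36-parameter
confound model (32 without GSR: 6 motion + tissue means, their backward
differences, and squares of all of those, plus linear trend and intercept),
and band-pass filter with a zero-phase second-order Butterworth at
0.01–0.08 Hz.

Order of operations: discard → interpolate to-be-censored volumes (linear,
from retained neighbours) → band-pass the signals *and* the 36/32 continuous
confounds → regress → drop censored volumes.  Two choices deserve
justification:

* **Filtered confounds.**  Regressing unfiltered confounds from filtered
  data (or filtering after regression) reintroduces out-of-band variance and
  leaves the cleaned data correlated with the global signal; filtering both
  sides identically restores exact orthogonality.  This is the standard
  spectral-consistency correction and matches what current post-processing
  tools do.
* **Interpolate-filter-censor.**  Filtering the uncensored series would
  smear each suprathreshold-volume spike over tens of seconds of retained
  data (the pass band rings slowly), partially defeating scrubbing.
  Interpolating the censored volumes first keeps the series contiguous for
  the filter without letting artifacts bleed outward; the censored rows are
  dropped at the end.  A hard censor-before-filter order (filter the
  concatenated retained volumes) remains available via
  `PipelineVariant.censor_before_filter` for sensitivity analyses.

FD uses the Power convention: sum of absolute backward differences of the
three translations plus 50 mm times the summed absolute rotation
differences, FD_0 = 0.  Scrubbing removes only suprathreshold volumes (no
neighbour augmentation).  Runs with fewer than 10 retained volumes are
flagged unusable and excluded with a logged reason.  Despiking is a no-op by
default (the spike-interpolation behaviour of externally despiked data is
out of scope); derivatives are zero-filled at the first retained volume.

## Connectome conventions

Pearson correlation across nodes; diagonal set missing; nodes with coverage
strictly below 50% get fully missing rows/columns (coverage of exactly 0.5
is retained); strictly negative correlations set missing; Fisher z on what
remains (|r| = 1 clipped to 1 − 1e-7 with a warning).  Censoring and the
coverage rule commute, and both precede the z transform, so no finite stored
entry is negative.  The negative-edge fraction is computed on the pre-censor
matrix over finite upper-triangle entries.

## Graph metrics

Ten metrics at three aggregation levels, all NaN-aware.  Missing entries are
excluded from means (within/between-network connectivity) and treated as
absent edges (weight 0) for topology metrics (modularity, path length,
degree, density, clustering, eigenvector centrality); nodes with fully
missing rows are excluded from every node set.  Degree and density threshold
at τ = 0.10 applied to the stored Fisher-z weights (at 0.10 the difference
between thresholding r and z is < 0.0004; configurable).  Details:

* within/between-network connectivity: mean finite z over same-network /
  spanning node pairs, per network and pooled;
* system segregation: (WN − BN)/WN on the pooled means; undefined when
  WN ≤ 0;
* modularity: Newman weighted Q; the default partition is the canonical
  atlas assignment (deterministic, matching its use as a network-level
  metric); Louvain optimization (10 seeded restarts, resolution 1) is
  available by flag;
* characteristic path length: Dijkstra over edge lengths 1/z; unreachable
  pairs are excluded from the mean and counted;
* nodal strength: sum of finite incident z;
* clustering: Onnela form on weights normalized by the maximum finite z,
  with k_i the count of finite incident edges; nodes with k_i < 2 score 0;
* eigenvector centrality: leading eigenvector of the missing-as-zero weight
  matrix, unit Euclidean norm, nonnegative orientation; on disconnected
  graphs the dominant component carries the scores (logged, not an error).

## Multiverse orchestration

`run_multiverse` evaluates every (pipeline variant, parcellation) cell over
a stored cohort: both sessions of every subject are post-processed,
connectomes built, all metrics computed, and ICC(3,1) estimated per
(group, atlas, variant, metric, network) cell.  Missing cells are emitted as
explicit NA rows, never dropped; unusable runs are excluded with a logged
reason and counted.  Report tables (reliability grid, per-network grid with
the size correlation, scrubbing accounting, negative-edge fractions, group
contrasts, edge-wise bin proportions) are written as TSV with fixed float
formatting plus a manifest (config hash, seed, package version), making two
runs with identical config byte-identical.  Six fixture parcellations ship
at 100–400 nodes with 12–19 networks, mirroring the node/network diversity
of widely used atlases at desk scale; 700- and 1000-node presets are
optional.

## Problem sizes in tests and the acceptance script

Estimator-correctness checks run at the study's subject scale (45 × 2
tables).  Edge-ICC recovery uses a 12-node, 2-network parcellation and 1000
replicate cohorts per target ρ — edge count does not affect the per-edge
calibration, so small N buys replicates.  Scrubbing-effect checks use a
100-node, 10-network parcellation (the qualitative pattern needs enough
within-network pairs for the metric to be stable) with the full 45 + 41
cohort.  The end-to-end determinism check runs the full 5-variant ×
6-atlas grid with 6 subjects per group, the grid being the object under
test rather than the cohort size.  The acceptance script reruns the same
computations at reduced replicate counts and records the numbers each stage
computes.

## Known limitations

* The generator controls *edge-level* reliability; metric-level ICCs emerge
  from it and are not directly tunable.
* Group labels are cosmetic (`groupA`/`groupB`); nothing in the pipeline
  special-cases a diagnosis, so clinical semantics live entirely in the
  configuration.
* Coverage fractions are a property of the parcellation fixture, constant
  across runs; per-run coverage variation is not modelled.
* ICC variants other than (3,1), absolute-agreement models, and
  connectome fingerprinting are out of scope.
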