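# Methods

## Scope

`plinet` re-implements, as a reusable pipeline, an EEG functional
brain-network analysis used to compare two arms of a longitudinal
clinical trial: band-filtered multichannel EEG is turned into Phase Lag
Index (PLI) connectivity matrices; each matrix is summarized by weighted
clustering (Cw) and weighted path length (Lw) and normalized against
weight-shuffled surrogate networks (gamma, lambda); and the per-subject,
per-visit network measures are compared between arms with a mixed model
for repeated measures (MMRM). Because no patient EEGs are distributed
with this package, a two-tier synthetic generator produces (a) coupled
oscillator signals with a known ground-truth coupling topology and (b)
outcome-level trial tables with controlled means, variance components
and missingness. Everything the tests and the acceptance script assert
is computed on those synthetic inputs.

## Preprocessing

Recordings follow multi-site clinical conventions: a 19-channel 10-20
montage, sample rates of 200-512 Hz (a warning outside that range), and
amplitudes in microvolts. The pipeline re-references off-line to the
average reference, band-filters, and cuts four non-overlapping
4096-sample artifact-free epochs per recording.

* **Filtering.** Band-pass filters are order-4 Butterworth applied
  forward-backward (`sosfiltfilt`), i.e. zero-phase. Phase distortion
  would corrupt the PLI, which is entirely phase-based; a causal filter
  is therefore not offered. Default bands: delta 0.5-4, theta 4-8,
  alpha 8-13, beta 13-25 Hz (half-open, partitioning 0.5-25 Hz). The
  continuous record is filtered before epoching by default; a config
  flag (`epoch_before_filter`) switches the order, since either is
  defensible and the difference is confined to epoch-edge transients.
* **Artifact handling.** The original analyses relied on expert visual
  epoch selection, which is not reproducible. The package substitutes a
  deterministic heuristic: a sample is bad if any channel exceeds 100 uV
  in magnitude or is exactly constant for at least one second. Epochs
  are then chosen greedily left to right, restarting just past each
  flagged sample. This is intentionally conservative and simple; it does
  not attempt ocular or muscle artifact subtraction (out of scope).
* **Resampling** uses polyphase anti-aliased resampling
  (`resample_poly`) and is off by default; heterogeneous sample rates
  are instead carried into the statistics as a covariate, mirroring the
  study design.

## Connectivity: the Phase Lag Index

Instantaneous phase is the argument of the analytic signal (Hilbert
transform) of each band-filtered channel; 128 samples are trimmed from
each epoch end to suppress transform edge effects. For channels i, j:

    PLI_ij = | < sign(sin(phi_i(t) - phi_j(t))) >_t |,  sign(0) = 0

PLI is 1 when one signal leads the other by a consistent nonzero lag and
0 when the phase-difference distribution is symmetric about 0 or pi. The
`sign(0) = 0` convention is essential: a single source mixed
instantaneously into several electrodes (volume conduction) produces
exactly zero-lag correlation, which contributes nothing to the index.
The tests verify this both analytically (a duplicated channel has PLI
exactly 0) and by construction (mixing a common narrowband source into
two independent oscillators at any strength leaves PLI below the
independent-phase sampling bound 3/sqrt(L)).

PLI matrices are computed per epoch. By default network measures are
computed per epoch and then averaged ("measure-level" averaging); the
alternative (averaging the PLI matrices first) is available behind
`average_order="matrix"`, as the original software lineage is ambiguous
on this point. Both variants are exercised in tests; at trial scale the
choice shifts absolute values slightly but not group contrasts.

## Network measures

For a weighted network W (symmetric, zero diagonal, weights in [0, 1]):

* **Weighted clustering.** Per node i,
  `C_i = sum_{k != l} w_ik w_il w_kl / sum_{k != l} w_ik w_il`
  (indices distinct from i); Cw is the node mean. Nodes with zero
  denominator (isolated or degree-1) contribute C_i = 0 rather than
  being dropped, keeping Cw defined on stars and other degenerate
  graphs. The implementation is closed-form
  (`(W^3)_ii / (s_i^2 - q_i)`) and is checked against a literal triple
  loop to 1e-12 on random graphs.
* **Weighted path length.** Edge length is 1/w (strong functional
  connection = short functional distance); w = 0 means no edge. Pairwise
  distances follow Dijkstra (scipy's csgraph); Lw is the mean over all
  ordered pairs, checked against Floyd-Warshall to 1e-12. Real PLI
  matrices on 19 channels are essentially complete; should a degenerate
  input be disconnected, unreachable distances are set to 1/eps with eps
  the smallest positive weight, with a warning, so Lw stays finite.
* **Surrogate normalization.** Each network is compared with 50
  surrogates obtained by uniformly permuting the upper-triangle weights
  (mirrored for symmetry), which preserves the weight multiset and
  destroys topology. gamma = Cw / mean(Cw_surrogate) and
  lambda = Lw / mean(Lw_surrogate). Division by the surrogate mean (not
  median) follows the method's definition. Both ratios are exactly
  invariant under global rescaling of the weights and equal 1 (up to one
  float rounding in the surrogate mean) on uniform complete graphs,
  where shuffling is the identity. Surrogate RNG streams derive
  deterministically from a master seed.

## Synthetic data

### Coupling topologies

`watts_strogatz_topology` builds a weighted ring lattice (n nodes, k
nearest neighbors at `w_strong` on a background of `w_weak`) and, with
probability p per lattice edge, removes the edge and re-places it on a
uniformly random vacant pair. Re-placement is done in two phases
(remove all marked edges, then place) so that at p = 1 the strong edges
form a *uniformly random* subset of pairs — the same distribution as the
weight-shuffle surrogate null, which makes the expected gamma and lambda
exactly 1 there. The classic "keep one endpoint" rewiring was tried
first and rejected: it leaves every node with at least k/2 attached
edges, so even at p = 1 the placement is not uniform and the normalized
measures sit a few percent below 1, muddying the ordered-to-random
trajectory the generator is meant to traverse.

### Coupled signals

Each channel carries a narrowband oscillator near the band center
(default 19 Hz, i.e. mid-beta). Channel frequencies are spread evenly
across +/- 4 Hz and randomly assigned, and each phase accumulates a slow
Brownian jitter (0.2 rad/sqrt(s)); together these keep uncoupled pairs'
phase differences drifting through full cycles within one epoch, so
their PLI concentrates near zero (empirically ~99% of uncoupled pairs
fall below the 3/sqrt(L) i.i.d. bound at L = 4096). White measurement
noise (0.3 of the 30 uV oscillation amplitude) is added per sample.

Coupling is directed by convention — the lower-indexed channel of a
coupled pair drives the higher-indexed one — because a symmetric
exchange of delayed admixtures swaps the two sources and produces no
phase locking. The driven channel mixes in the driver's oscillation
delayed by between one eighth and three eighths of a cycle (drawn
per edge). A fixed quarter-cycle delay for every edge was tried first
and rejected: two channels driven by a common neighbor then receive the
same delayed source at *zero relative lag*, their PLI is suppressed by
the sign(0) convention, and the induced PLI network comes out
anti-clustered relative to its coupling topology. With per-edge delay
jitter, shared-driver pairs carry a nonzero relative lag and the PLI
network inherits the topology's clustering. Expected pairwise PLI is
monotone in the coupling strength (verified over replicates).

### Outcome-level trial generator

`simulate_trial_outcomes` draws a 2-arm, 3-visit (0/12/24 weeks),
multi-site table: outcome = arm-visit mean + site effect + subject
effect + residual, all Gaussian. Defaults are the study conditions: 93
control and 86 active subjects across 9 sites; beta-band gamma means of
(1.026, 1.022, 1.014) for control and (1.028, 1.024, 1.029) for active;
SDs sd_site = 0.006, sd_subject = 0.009, sd_residual = 0.027, chosen so
the total SD (~0.030) and the grouping share of variance (~0.14) match
the trial-scale descriptives the defaults emulate; 20% missing baselines; 6.7% monotone
dropout (missing from a uniformly chosen post-baseline visit onward).
A memory score can be linked to the outcome (none / linear / quadratic)
for exercising the association analyses.

### Signal-level trial fixture

`simulate_full_trial` writes ASCII recordings plus a manifest for a
whole trial. Each arm has a per-visit rewiring schedule (default:
control 0.1 -> 0.3 -> 0.6, active constant 0.1), expressing the
hypothesis that the control arm's network organisation degrades from
small-world toward random while the active arm's is preserved. Each
subject's visit topologies are drawn from a persistent subject-specific
randomness stream: the rewiring uniforms are identical across visits, so
a larger scheduled p rewires a superset of the edges rewired earlier —
the subject's own network degrades progressively instead of being
resampled from scratch, and a constant schedule keeps it fixed. This is
simultaneously the scientifically coherent longitudinal model and a
common-random-numbers design that makes paired within-subject contrasts
far less noisy. Defaults (19 channels, lattice k = 6, coupling strength
0.4, 2 epochs per recording at reduced scale) were chosen so that both
gamma and lambda respond clearly to the schedule through the full
pipeline; the true signal-level effect sizes in patients are unknowable
from the network read-out alone, so the schedule is a plausibility
device, not an estimate.

## Trial statistics

The primary analysis models the post-baseline visits (wk12, wk24) only:

    outcome ~ group * visit + baseline + sample_rate
              + (1 | site) + (1 | subject within site),   REML

with visit categorical. Missing baseline covariates are imputed with the
site mean of observed baselines (grand mean as a flagged fallback);
sites smaller than 16 subjects are pooled, smallest first, until every
pool reaches 16. Continuous covariates are z-scored internally — sample
rates are O(100) against O(1) outcomes and the raw scale conditions the
REML optimization badly. Covariates without variance (e.g. a single-rate
study) are dropped to keep the design full rank.

* **Estimation.** statsmodels `MixedLM` fitted by REML with a small
  optimizer portfolio (default gradient method and Powell), keeping the
  fit with the higher restricted likelihood. The REML optimum in this
  design frequently lies on the variance boundary — the baseline
  covariate absorbs most between-subject variance — where single
  optimizers can stall; the portfolio reproduces lme4's optima on the
  same data and makes results invariant to row order and site
  relabeling. Hard failures (singular linear algebra) trigger a refit
  with a subject-only random intercept, flagged on the result.
* **Contrasts.** The treatment signal is the joint 2-df Wald F-test of
  the group difference at wk12 and wk24 ("trajectory") plus the t
  contrast of the group difference at wk24 ("endpoint"). Denominator
  degrees of freedom use a between-within approximation by default
  (n_obs - n_subjects - p_within); a residual option (n_obs - p) is
  available, and the method used is always reported rather than matched
  to any particular software. Under the null generator the trajectory
  test's type-I error is ~5% (calibrated over 500 replicates); under
  the default trajectory parameterization it rejects in ~86% of
  replicates with the control arm's fitted trajectory declining.
* **ICC** is reported as (site + subject variance) / total variance —
  the share of outcome variance attributable to the grouping structure.
  An alternative subject-only definition would be smaller; since the
  source analyses do not define theirs, the components are reported
  separately as well. ICC is consistent but noisy at trial size
  (sampling SD ~0.1), which the tests respect by checking its
  zero-variance limit at larger n.
* **Memory association.** "Flexible regression" is implemented as a
  quadratic polynomial probe: memory ~ outcome + outcome^2 by OLS per
  time point (arms combined at baseline, separate afterwards), testing
  the quadratic term with a 1-df test; and per arm across visits as a
  mixed model with a subject random intercept, falling back (flagged) to
  OLS when no subject has repeated visits. The outcome is centered
  before squaring for conditioning. No multiple-testing correction is
  applied, matching the source design (two measures by four bands); the
  family size is noted in the report.

## Pipeline and provenance

`plinet run -c config.yaml` executes preprocess -> PLI -> metrics ->
statistics from a manifest CSV, writing per-recording measures, a
per-band summary table (mean (SD) [n] per group and visit with
trajectory and endpoint p-values), a JSON results blob, and a
provenance file (config, master seed, per-file epoch offsets, filter
realization, library versions). Per-recording surrogate seeds derive
from the master seed by hashing subject/visit/band, so reruns are
byte-identical and any single output is reproducible in isolation.
Per-file failures are logged and skipped; the CLI exits nonzero if any
stage failed. A `pp_exclude` manifest column triggers a parallel
per-protocol analysis next to the intention-to-treat one.

## Problem sizes used in the checks

Analytic and oracle checks run at full epoch length (L = 4096) and on
200 random graphs (4-10 nodes). Normalization and regime checks use
19-node networks with 50 surrogates and 50-100 replicates. Mixed-model
calibration uses 500 null and 200 effect replicates at the study's
sample size. The end-to-end fixture runs 30 subjects per arm with two
epochs per recording — enough for decisive sign tests on the paired
within-subject changes while keeping a full run in the tens of seconds.

## Known limitations

* The synthetic signals are phase-coupled oscillators, not biophysical
  EEG: no 1/f background, no ocular/muscle artifacts beyond the
  amplitude/flat-line heuristic's targets, no nonstationary band power,
  and a single oscillation per channel. Passing tests demonstrate the
  pipeline's correctness and sensitivity under controlled coupling, not
  performance on clinical recordings.
* Patient-level results of any real trial (specific F, t, p, ICC
  values) are not reproducible without that trial's data and are not
  targets of this package; only directions of effect and calibration properties
  are checked.
* PLI discards genuine zero-lag coupling by design; estimators that
  recover some of it (e.g. weighted PLI variants) are out of scope.
* Denominator-df approximations beyond between-within/residual
  (Satterthwaite, Kenward-Roger) are not implemented.
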