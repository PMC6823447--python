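# Methods

This note documents the models, statistical conventions, and design
choices behind `wmconn`, and what the synthetic-cohort validation does and
does not establish about real data.

## Data model

Epochs are real arrays `(trials, regions, samples)` at 600 Hz, spanning
−1 s to +2 s around stimulus onset (1801 samples); time 0 is the onset of
the sample stimulus. Task windows are millisecond intervals interpreted
half-open `[start, end)`: baseline −500..0, encoding 0..250, retention
250..1250. The full parcellation is the 90-region AAL atlas (labels in
`wmconn.atlas`); smaller region counts get generic `ROI_*` labels.

## Preprocessing

* Broadband filter: 1–150 Hz 4th-order Butterworth, applied
  forward-backward (`sosfiltfilt`, zero phase), then a 60 Hz notch
  (2nd-order IIR, quality factor 30, also two-pass). The notch realization
  is a package choice; Q = 30 is a standard power-line notch width.
* Band filters: 4th-order two-pass Butterworth into theta (4–7), alpha
  (8–14), beta (15–30), low gamma (30–55 Hz).
* Epochs are filtered whole and the analysis then uses only
  −500..1250 ms (`wmconn.pipeline.ANALYSIS_WINDOW_MS`), so filter and
  Hilbert edge transients (the Hilbert transform is computed on a
  zero-padded fast FFT length) fall outside every analysis window.
* Trial screening: a trial is rejected iff strictly more than 10% of its
  head-position samples exceed 5 mm (strictly), or any channel's peak
  absolute amplitude strictly exceeds 2000 fT. Boundary values are kept;
  when both rules fire the recorded reason is `motion`. For synthetic
  source-space data the "channels" of the amplitude rule are the region
  traces themselves — an emulation, documented as such. The reference
  head position is interpreted per trial (the trial's own trace is a
  distance-from-reference series); a session-median variant would screen
  identically on these traces.

## wPLI estimation

The weighted phase lag index is estimated per time sample from
single-sample analytic cross-products across trials (the time-resolved
Hilbert framing), not from multitaper spectra:

    wPLI_ij(t) = |sum_k Im X_k| / sum_k |Im X_k|,   X_k = z_ik(t) conj(z_jk(t)).

Conventions:

* 0/0 (all imaginary components vanish) is defined as 0 — no evidence of
  lagged phase coupling. This is conservative.
* The standard amplitude-weighted estimator is the default; the debiased
  squared estimator is available (`debiased=True`) but is not used by the
  pipeline.
* Outputs are symmetric with zero diagonal and, raw, lie in [0, 1];
  these invariants are asserted in tests on every estimator output and
  against a naive triple-loop reference at 1e-12.

With finite trials the null value is not 0 but ~1/sqrt(n_trials); all
calibration work below therefore uses baseline-relative statistics.

## Baseline normalization

Each edge's wPLI timeseries is z-scored to its own baseline window
(−500..0 ms): subtract the baseline mean, divide by the baseline SD. The
SD uses the population convention (ddof = 0) by default, switchable to
ddof = 1; the choice only rescales all z-values per edge and does not
change permutation inference. A zero baseline SD is an error naming the
edge: it indicates a degenerate estimate (e.g. a constant wPLI of 1.0
across the whole baseline, which can occur with very few trials).
Whole-brain timeseries are computed as the mean over the N(N−1)/2
upper-triangle edges, by default *after* z-scoring (z-score, then
average; the reverse order is also supported).

## Supra-threshold-window permutation test

Two sets of whole-brain timeseries are compared per sample with a t
statistic (paired: one-sample t on per-subject differences; unpaired:
pooled two-sample t; zero variance gives t = 0 by convention). Observed
clusters are maximal runs of consecutive samples with t > 1.7 (strict,
one-sided by default as conventionally thresholded; |t| optional). Each
of n = 1000 permutations exchanges condition labels — independent
per-subject swaps for paired designs, equivalent to sign-flipping the
differences; group-label shuffles otherwise — and records the largest
supra-threshold run length into the null. A cluster is significant iff
its length strictly exceeds the 95th percentile (linear interpolation) of
that null; ties are non-significant. Reported per-cluster p-values use
the exceedance convention p = (1 + #{null ≥ length}) / (1 + n_perm),
whose floor at n_perm = 1000 is 1/1001.

## Network-Based Statistic

Edge-wise retention-vs-baseline contrasts are paired t-tests across
subjects on (window-mean difference) per edge, computed on z-scored wPLI.
The t-matrix is thresholded at t > 2.0 (one-sided default) and connected
components of supra-threshold edges are found (via networkx; an
independent union-find oracle checks this in tests). The permutation null
sign-flips each subject's window difference (window labels are
within-subject), rebuilds the full t-matrix, and records the maximal
component size; component size is the edge count (node count available).
p_corr = (1 + #{null max ≥ size}) / (1 + n_perm) with n_perm = 5000 by
default. Hubs are ranked by node degree, ties broken by node index.

Unequal window lengths (1000 ms retention vs 500 ms baseline) make the
two window means differentially precise; the package keeps plain means
and notes the asymmetry here rather than reweighting.

Between-group tests mask each subject's connectivity to the edges of a
reference component (typically a group's significant within-group NBS
component), sum the window-averaged z-scored wPLI over the mask to one
value per subject, and compare groups by difference of means under
group-label permutation (two-sided exceedance p).

## Behaviour statistics

Printed cohort tables report mean (SD) per group; the package reproduces
their inferential statistics with pooled-variance two-sample t-tests
(df = n1 + n2 − 2 — the df printed in such tables identifies the pooled,
not Welch, convention) and Pearson chi-square without continuity
correction (with Yates' correction the canonical 2×2 sex-distribution
value is not recovered). A raw-data route (`pooled_t_from_data`)
cross-checks the summary route to 1e-12. Note that recomputing a t from a
*printed* table inherits the rounding of the printed means/SDs: two
decimal places in the inputs move the t statistic by up to ~±0.05 here,
so agreement is asserted to that precision, not beyond it.
Brain–behaviour associations are Pearson correlations between
retention-averaged, baseline-normalized whole-brain connectivity
(correct trials only) and task accuracy, per group.

## Synthetic cohort generator

Per region and band the signal is A_b·cos(φ(t)) plus white noise
(amplitude 1 and noise SD 1 by default; after band filtering the in-band
noise is small relative to the oscillation). φ is an integrated
instantaneous frequency f_c + δ(t), with δ an Ornstein–Uhlenbeck process
(correlation time 50 ms, stationary SD 0.15 × band half-width, clipped at
0.9 × half-width). These constants keep ≥ 99% of the component's power
inside its band (the suite asserts ≥ 90%) while accumulating ~1 rad of
phase diffusion over the 1.75 s analysis span, so uncoupled regions
decorrelate across trials (initial phases are uniform per trial).

Planted coupling: each network lists edges, a band, a window, a group, a
condition, and κ ∈ [0, 1]. κ acts as a trial-level mixture — on each
trial the network is fully coupled with probability κ and independent
otherwise. On coupled trials every node of a connected component follows
one shared component phase plus a per-node lag, gated by the window
indicator with 50 ms cosine ramps (abrupt phase-regime switches would
inject broadband transients). The across-trial phase-difference
distribution on a planted edge is therefore a κ:(1−κ) mixture of a
constant-lag point mass and circular uniform, making the downstream wPLI
monotone and nearly linear in κ (measured ≈ 0.11/0.41/0.64/0.83/0.97 at
κ = 0/0.3/0.6/0.8/1 with 50 trials). A per-sample linear blend of
unwrapped phases was evaluated first and rejected: the (1−κ)-scaled
independent residual spans the full circle, leaving mid-range κ
statistically invisible to wPLI. Per-node lags are resampled until every
planted edge's lag difference has magnitude in [0.8, 2.4] rad — clear of
the wPLI-blind neighbourhoods of 0 and π and large enough that
|sin(Δlag)| ≥ 0.67; very dense planted graphs (cliques beyond 4 nodes)
cannot satisfy this and are rejected with an explanatory error.

Because one shared phase drives a whole connected component, *every*
within-component pair is synchronized, not only the listed edges. The
ground-truth synchronized edge set is therefore the within-component pair
closure, reported as `closure_edges` in `SimulationTruth`; recovery
analyses score detected components against that closure. Planted
networks that must stay mutually independent should be specified as
disjoint components (each gets its own common phase). Contradictory
specifications — two networks on the same band sharing a node while
simultaneously active — are rejected at validation.

Realized per-subject coupling κ_s = clip(κ + N(0, subject_kappa_sd), 0, 1)
is recorded in the truth object, and the behaviour table links accuracy to
it: accuracy = intercept + slope·κ̄_s + N(0, noise_sd), clamped to
[0, 100]. Artifact traces emulate the screening inputs: clean
head-position wander stays below 4.5 mm; with probability `p_motion` a
trial gets a contiguous supra-5 mm block covering a configurable fraction
of samples; with probability `p_spike` one channel's peak exceeds
2000 fT. Contamination labels are stored as ground truth, and screening
reproduces them exactly by construction of the clean background.

Seeding: a master seed spawns one `numpy` SeedSequence per subject and
per (subject, trial) via fixed entropy tuples recorded in the truth
object; identical config + seed reproduce every array bit-exactly
(HDF5 outputs are written without timestamps so file digests match too).

## Validation design and problem sizes

The statistical guarantees are established on reduced cohorts sized for a
single CPU; subject counts match the target scenarios:

* **Type-I error** of the paired whole-brain cluster test: 200 null
  cohorts (8 regions, 20 trials/condition, 8 subjects, alpha band only,
  κ = 0, n_perm = 500); the fraction with any significant cluster must
  lie in [0.02, 0.08] (measured 0.055).
* **NBS FWER**: first 100 of those cohorts, n_perm = 500; fraction with
  any p_corr ≤ 0.05 component in [0.01, 0.11] (measured 0.08).
* **Recovery**: 20 cohorts of 10 subjects (14 regions, 36
  trials/condition) with a 10-edge path planted at κ = 0.8 in retention,
  correct trials; ≥ 90% of replicates must yield a significant NBS
  component with Jaccard ≥ 0.5 against the synchrony closure *and* a
  significant whole-brain cluster overlapping 250–1250 ms (measured
  20/20 and 20/20).
* **Brain–behaviour**: 100 cohorts of 15 subjects (9 regions, 30 correct
  trials) with κ = 0.6 ± 0.2 and a link calibrated to a true r of 0.6;
  the estimated r must be positive in ≥ 95% of replicates.

What passing these tests shows: the estimators are exact on their defining
cases, the permutation machinery is calibrated at nominal error rates
under the generator's null, and planted effects of realistic strength are
recovered. What it does not show: robustness to properties of real MEG
the generator deliberately omits — volume conduction / field spread
(no forward model; wPLI's zero-lag insensitivity is therefore exercised
only through the lag constraints), 1/f background spectra, heteroscedastic
artifacts, ocular/cardiac components (ICA cleaning is out of scope), or
between-subject anatomical variability.

## Numerical conventions collected

* Windows: ms, half-open [start, end), 1 µs tolerance on the time axis.
* t-tests: ddof = 1; zero variance ⇒ t = 0 (documented convention).
* Baseline z-score: ddof = 0 default.
* Percentiles: linear interpolation; significance strictly greater than
  the critical value; permutation p-values always (1 + exceedances) /
  (1 + n_perm).
* One-sided thresholds (t > 1.7, t > 2.0) by default; two-sided variants
  by flag.
* All randomized operations take explicit integer seeds; nothing seeds
  from the clock.
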