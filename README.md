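# wmconn

Time-resolved functional-connectivity analysis of working-memory MEG data,
with a ground-truth coupled-oscillator simulator.

`wmconn` implements the analysis chain used to study how children maintain
visual information in working memory: source-space MEG epochs on a
90-region AAL parcellation are band-pass filtered into physiological bands
(theta 4–7 Hz, alpha 8–14 Hz, beta 15–30 Hz, low gamma 30–55 Hz), converted
to instantaneous phase with the Hilbert transform, and turned into a
time-resolved N × N connectivity matrix with the **weighted phase lag
index** (wPLI). At each time sample *t*, with analytic signals
*z<sub>i,k</sub>(t)* over trials *k*,

```
wPLI_ij(t) = | Σ_k Im(z_i,k(t) · conj(z_j,k(t))) | / Σ_k | Im(z_i,k(t) · conj(z_j,k(t))) |
```

which is 0 for random phase differences, 1 for a constant phase
difference, and — because it uses only the imaginary cross-spectrum —
insensitive to zero-lag volume-conduction artefacts. On top of the wPLI
timeseries the package provides:

* **whole-brain connectivity timeseries** (mean over all region pairs,
  z-scored per edge to the −500..0 ms pre-stimulus baseline) with a
  **supra-threshold-window permutation test** (default n = 1000, t > 1.7,
  clusters significant when longer than the 95th percentile of the
  max-run-length null);
* the **Network-Based Statistic** for retention-vs-baseline edge
  contrasts (t > 2.0, n = 5000 sign-flip permutations, FWER control at
  the level of connected components), with node-degree hub ranking;
* **masked network-sum group tests** (sum of z-scored wPLI over a
  component's edges per subject, group-label permutation test);
* **brain–behaviour correlations** (retention-averaged whole-brain
  connectivity vs. task accuracy) and the pooled-t / chi-square summary
  statistics used for cohort demographics tables;
* a **synthetic cohort generator**: narrowband stochastic oscillators
  (bounded-drift instantaneous frequency) with phase-coupled networks
  planted in chosen bands/windows/groups/conditions at coupling strength
  κ ∈ [0, 1], head-position and sensor-amplitude artifact traces for the
  screening rules (> 10% of samples beyond 5 mm, or > 2000 fT), a
  coupling-linked behaviour table, and a JSON ground-truth record that
  makes every downstream inference testable.

Real MEG data of this kind are rarely deposited, so the simulator is a
first-class component: it defines the statistical conditions under which
the inference machinery is validated (type-I error, FWER, recovery of
planted networks, sign-recovery of brain–behaviour links).

## Worked example

Simulate a 6 + 6 subject cohort with an alpha-band network (a 3-edge path
on regions 0–3) planted only in the FT group's correct trials during the
retention interval (κ = 0.8), then run the full pipeline:

```yaml
# config.yaml
n_regions: 12
n_trials_per_condition: 30
groups: [[FT, 6], [VPT, 6]]
bands: [[alpha, 8, 14]]
planted_networks:
  - band: alpha
    edges: [[0, 1], [1, 2], [2, 3]]
    kappa: 0.8
    window: retention
    group: FT
    condition: correct
subject_kappa_sd: 0.1
behaviour_link: {intercept: 60.0, slope: 25.0, noise_sd: 4.0}
master_seed: 7
```

```bash
wmconn simulate --config config.yaml --out data
wmconn connectivity --epochs data --band alpha:8:14 --condition correct   --out conn
wmconn connectivity --epochs data --band alpha:8:14 --condition incorrect --out conn
wmconn wholebrain-test --conn conn --band alpha --group FT --n-perm 1000 --seed 11 --out wholebrain.json
wmconn nbs        --conn conn --band alpha --group FT --n-perm 1000 --seed 12 --out nbs_ft
wmconn group-test --conn conn --band alpha --mask nbs_ft.tsv \
                  --group-a FT --group-b VPT --n-perm 5000 --seed 13 --out group.json
wmconn behaviour  --table data/behaviour.tsv --conn conn --band alpha --out behaviour.json
```

Output (abridged):

```
[wmconn] wrote 12 subjects to data
[wmconn] screening kept 720/720 trials
[wmconn] 6 subjects, 1000 permutations: 1 significant cluster(s)
[wmconn] 6 subjects: 3 component(s), 1 significant
[wmconn] network-sum difference 79.556, p = 0.0018
[wmconn] FT: r = 0.336, p = 0.5156 (n = 6)
```

What the numbers mean: the correct-vs-incorrect whole-brain contrast in
the FT group finds one significant supra-threshold window spanning
228–1085 ms (p = 0.040) — overlapping the 250–1250 ms retention interval
where the coupling was planted. The FT retention-vs-baseline NBS finds a
significant component of 6 edges / 5 nodes (p_corr = 0.016): the pair
closure of the planted 4-node path (a connected component driven by one
shared phase is synchronized on *every* internal pair) plus one attached
noise edge. Masking all other connections and summing, FT subjects recruit
this network far more strongly than VPT subjects (difference 79.6 z-units,
permutation p = 0.0018). The FT brain–behaviour correlation is positive
(r = 0.34) but, at n = 6, far from significant — sign recovery at such
sample sizes is assessed over replicates in the test suite.

Every command appends input/output SHA-256 digests to a `manifest.json`;
re-running a stage with identical inputs and seeds reproduces identical
files.

The same operations are available as a library
(`wmconn.make_cohort`, `wmconn.subject_connectivity`,
`wmconn.cluster_permutation_test`, `wmconn.nbs`, `wmconn.network_sum`,
`wmconn.brain_behaviour`, ...); see `docs/methods.md` for the model and
all statistical conventions.

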