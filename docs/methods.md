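# Methods

`eegfc` analyses paired resting-state EEG sessions (a "pre" and a "post"
condition per subject) as weighted functional-connectivity networks and
asks two questions: *which band-wise network properties changed between
conditions*, and *do those changes track changes in cognitive performance*.
Because paired clinical EEG recordings are rarely shareable, the package
ships a first-class synthetic-cohort generator whose defaults encode the
target design: 21 subjects, two conditions, ten non-consecutive clean 2-s epochs
per session, 19 channels of the international 10-20 montage at 200 Hz.

## Connectivity estimation

Two complementary estimators are computed for every channel pair in each
of the five clinical bands (delta 0.1-4, theta 4-8, alpha 8-13, beta
13-30, gamma 30-50 Hz):

**Magnitude-squared coherence.**
COH_xy(f) = |S_xy(f)|² / (S_xx(f) S_yy(f)), with the spectral densities
estimated Welch-style: one Hann-tapered, demeaned segment per 2-s epoch,
periodograms averaged over epochs, nfft = epoch length (0.5 Hz grid at
200 Hz).  Band values average the bins with lo ≤ f < hi.  Consequences of
these choices: coherence from a single segment is identically 1, so at
least two epochs are required; the delta band's nominal 0.1 Hz edge is
below the 0.5 Hz grid, so delta coherence effectively uses 0.5-4 Hz.
Whether the original analysis pooled epochs or averaged per-epoch spectra
is unknowable from the text; Welch-across-epochs is the standard choice
and is what the estimator's bias behaviour (≈ 1/n_epochs for independent
signals) is tested against.

**Phase lag index.**  PLI = |⟨ sign Δφ(t_k) ⟩|, with instantaneous phases
from the analytic (Hilbert) signal of the band-passed epoch, 10% of
samples discarded at each epoch edge against end effects, and the
per-epoch PLI averaged across epochs.  PLI is 0 both for no coupling and
for phase differences centred on 0 mod π — exactly the zero-lag mixtures
that volume conduction produces and that coherence cannot reject — and 1
for a constant asymmetric lag.  PLI carries a positive small-sample bias
of order 1/√(n_independent) because narrowband phase differences are
autocorrelated within an epoch; with 2-s epochs this floor is ≈ 0.2-0.3,
which is why estimator-limit tests use long epochs and why small PLI
values should not be over-read.

Band-pass filtering is a 4th-order Butterworth applied forward-backward
(zero phase, effective 8th order) as second-order sections.  The filter is
applied to the *continuous* recording before epochs are cut — a 2-s epoch
cannot absorb the transient of a 0.1 Hz edge.  This is a deliberate
ordering deviation from filtering epochs directly; it changes nothing for
stationary signals and avoids edge transients for real ones.

Epoch extraction is deterministic (the human artifact-review selection is
out of scope): `evenly_spaced` lays epochs proportionally across the
recording, falling back to tight packing near the minimum length, and
`listed_onsets` takes explicit onsets.  "Non-consecutive" is enforced as a
minimum inter-epoch gap, default 1 s (`min_gap_s`); ten 2-s epochs
therefore need at least 29 s of recording, and the generator's default
recording length is 30 s.

## Graph measures

Each connectivity matrix is a weighted undirected graph (no binarization;
edge length = 1/weight for path-based measures, the convention of the
standard brain-connectivity toolboxes).  Twelve global measures are
computed — average degree, average strength, radius, diameter,
characteristic path length, global and local efficiency, clustering
coefficient, transitivity, modularity, assortativity, small-worldness —
plus five nodal ones (degree, strength, global/local efficiency,
clustering).

Numerical conventions, all exercised by brute-force-oracle tests:

- *Degree* on a dense coherence matrix would saturate at N−1, so degree
  counts edges above `degree_threshold` (default 0.5 for coherence, 0.05
  for PLI — the same cutoffs used for display). This is an interpretation,
  flagged as such; strength always sums unthresholded weights.
- *Paths*: Dijkstra on 1/weight lengths; characteristic path length
  averages finite pairwise distances; radius/diameter are eccentricity
  extremes over the largest connected component; efficiency counts
  unreachable pairs as 0.
- *Clustering* uses the geometric-mean (Onnela) triangle form
  C_i = 2 t_i / (k_i (k_i − 1)) with t_i = ½ Σ (w_ij w_ih w_jh)^{1/3};
  transitivity is the matched global ratio Σ 2t_i / Σ k_i(k_i−1).
- *Local efficiency* of a node is the global efficiency of the weighted
  subgraph induced on its neighbours.
- *Modularity* is Newman's weighted Q, optimized by seeded Louvain
  restarts (default 10) followed by a deterministic greedy refinement:
  single-node moves (including split-offs into new communities),
  coordinated two-node exchanges and joint moves, and pairwise community
  merges.  The two-node moves cost ~n⁴ per pass and are enabled for
  n ≤ 12, where they make the optimizer match exhaustive partition search
  on every random graph tried; at n = 19 the restarts plus single-node
  refinement are used.  The reported Q always equals the direct formula
  applied to the returned partition.
- *Assortativity* is the Pearson correlation of endpoint strengths over
  the (doubled) edge list; degenerate variance yields NaN, a documented
  undefined-value signal rather than an exception.
- *Small-worldness* σ = (C/⟨C_rand⟩)/(L/⟨L_rand⟩) against an ensemble
  (default 100) of degree-preserving rewired topologies with the original
  weights shuffled onto them, 10 rewires per edge, seeded.  Complete
  graphs admit no rewires; the weight shuffle alone then provides the
  null.  Graphs that are disconnected, too small, or triangle-free raise
  a null-model error.

## Group statistics

Paired condition differences are tested with a sign-flip permutation test:
statistic = mean(post − pre), null from independent per-subject sign
flips, 1000 permutations by default, two-sided add-one p-value
(#{|null| ≥ |obs|} + 1)/(n_perm + 1).  Sign flipping is the natural
exchangeability for a paired design.  Benjamini-Hochberg FDR is applied
per measure across the five bands (configurable to one global family —
which family the original analysis used is not stated, and per-measure
matches how the band panels are presented).  Cognitive scores are compared
with the classical paired t-test; zero-variance rows (ceiling effects) are
flagged degenerate rather than tested.

For brain-behaviour coupling, per-subject changes of each graph measure
and of the cognitive score are z-scored across subjects (measures live on
incomparable scales) and Pearson-correlated, two-sided p from the
t-distribution with n−2 df, one test per (measure, band) with no
cross-measure correction — the tests are interpreted independently by
design.  Trail Making B is timed, so its improvement is pre − post; with
that sign convention beneficial network change correlates positively with
improvement.

Edge-level summaries mirror the display conventions: the top-k (default
10) most increased edges of the subject-averaged matrices, ties broken by
channel-pair lexicographic order, and per-node scores that sum the
post-condition weights of listed incident edges.

## The synthetic cohort

Every signal component is band-limited Gaussian noise synthesized in the
frequency domain (pure tones would make coherence trivially 1).  Per
channel and band, the signal sums: an independent oscillation (amplitudes
delta 0.5, theta 0.6, alpha 1.0, beta 0.4, gamma 0.3 a.u., with alpha
doubled on posterior channels to give the classic posterior-dominant
rhythm); two *community* shared sources — anterior (Fp1-C4) and posterior
(P3-O2) — at constant gain 0.6, which give the baseline network its
modular structure; and a *bridging* shared source over the
fronto-centro-parietal set (F3, Fz, F4, C3, Cz, C4, P3, Pz, P4) whose
gain rises from 0.2 to 0.7 in delta and gamma in the post condition.
1/f background noise (exponent 1.0, amplitude 0.5) is added per channel.

The bridge is the condition effect, and its placement is the point:
because it spans both baseline communities, raising its gain increases
strength, efficiency and clustering while *decreasing* modularity in the
affected bands — the reorganization-toward-integration pattern the
pipeline is built to detect.  A naive single-group gain increase would
strengthen one community and push modularity the wrong way.  Shared
sources reach each channel with a nonzero, channel-dependent phase offset
(defaults spread over 0.1-1.2 rad), so the phase-lag index sees them;
zero-lag mixing would by construction give PLI 0.

Subject-level variation enters as truncated-Gaussian jitter (sd 0.05) on
every coupling gain, drawn independently per band and condition.  A
subject's *realized coupling increment* (total post − pre gain) drives the
cognitive score model: score change = intercept + slope × (increment −
mean increment) + Gaussian noise.  Score baselines (Trail Making B
5.80 ± 1.41 s, Digit Span forward 8.52 ± 0.75, backward 6.24 ± 1.76)
follow the emulated population; the Trail Making slope is −2 s per unit
increment, so stronger network change means faster completion.
`ScoreModel.noise_sd_for_correlation` inverts the variance decomposition
to hit a target population correlation, which the correlation-recovery
experiments use.

What the generator does *not* emulate: artifacts, drowsiness, eye blinks,
volume conduction geometry, non-stationarity, and any realistic spatial
falloff of coupling.  Passing tests therefore demonstrate that the
estimators and statistics behave correctly on signals with the designed
statistical structure — not that the pipeline is robust to the failure
modes of real clinical EEG.

## Problem sizes and determinism

Every random draw is seeded: the generator derives per-subject,
per-condition streams from (seed, subject id, condition) via CRC-stable
hashing, the permutation test derives one stream per (measure, band), and
graph null ensembles take explicit seeds.  Identical configuration gives
bitwise-identical recordings, tables and EDF files.

Validation experiments run at sizes chosen to make their Monte-Carlo error
small relative to the tolerance being checked: oracle equivalence on 200+
random graphs of ≤ 6 nodes (exhaustive modularity search is exponential);
permutation calibration on 2000 null datasets of 20 subjects; FDR control
on 1000 all-null families; null-exchangeability of the full pipeline on
500 reduced cohorts (6 subjects, 4 epochs, one band, exact 2⁶
enumeration); effect recovery on 20 full-size cohorts per configuration.

## Known limitations

- The degree threshold is the only binarizing step and is a documented
  interpretation; average degree is meaningless without it on dense
  coherence graphs.
- PLI's small-sample bias makes absolute PLI levels from 2-s epochs
  interpretable only comparatively.
- Louvain-plus-refinement is exact in practice at small n but remains a
  heuristic at n = 19; Q values there are lower bounds attained by the
  best partition found, reported self-consistently.
- The delta band inherits the spectral-resolution limit of 2-s epochs;
  its 0.1-0.5 Hz content is invisible to the coherence grid.
- The score model is linear with Gaussian noise; real neuropsychological
  scores are discrete and bounded (the generator does not round or clip
  them).
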