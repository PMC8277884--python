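# eegfc

Resting-state EEG functional-connectivity analysis for paired (pre/post)
designs: band-wise **coherence** and **phase-lag-index** networks, weighted
graph-theoretic characterization, paired sign-flip **permutation tests**
with FDR control, and correlation of network changes with cognitive-score
changes.  It is written for studies that record a small cohort twice — for
example before and after a pharmacological or dietary intervention — and
ask whether the brain's functional network shifted toward a more
integrated, efficient configuration.

Because such datasets are rarely shared, the package includes a
first-class synthetic-cohort generator that emulates the design it
targets: 21 subjects × 2 conditions × 10 non-consecutive 2-s clean epochs,
19 channels (10-20 montage) at 200 Hz, alpha-dominant posterior rhythm,
1/f background, and band-limited inter-channel coupling with nonzero phase
lags whose delta- and gamma-band gain rises in the post condition.

## The model in brief

For channels x, y and band B, connectivity is estimated two ways:

- coherence  COH_xy = |S_xy(f)|² / (S_xx(f) S_yy(f)), Welch-averaged over
  2-s Hann-tapered epochs and averaged over the bins of B;
- phase lag index  PLI = |⟨ sign Δφ(t) ⟩|, from analytic-signal phases of
  the band-passed epochs — insensitive to amplitude and to the zero-lag
  coupling produced by volume conduction.

Each 19×19 matrix is treated as a weighted undirected graph (edge length
= 1/weight) and summarized by 12 global measures (average degree and
strength, radius, diameter, characteristic path length, global/local
efficiency, clustering coefficient, transitivity, modularity,
assortativity, small-worldness σ) and 5 nodal ones.  Conditions are
compared per (measure, band) with a paired sign-flip permutation test
(1000 permutations, add-one two-sided p) under Benjamini-Hochberg FDR;
score changes and graph-measure changes are z-scored across subjects and
Pearson-correlated.  Full definitions and numerical conventions are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from eegfc import PipelineConfig, run_pipeline
from eegfc.synth import SynthConfig

config = PipelineConfig(
    synth=SynthConfig(seed=7),              # the simulated cohort
    methods=("coherence",),
    graph_measures=("average_strength", "global_efficiency", "modularity"),
    seed=7,
)
result = run_pipeline(config)
print(result.comparisons.query("q_fdr < 0.05")
      [["measure", "band", "mean_pre", "mean_post", "p_perm", "q_fdr"]]
      .round(4).to_string(index=False))
```

prints

```
          measure  band  mean_pre  mean_post  p_perm  q_fdr
 average_strength delta    2.9162     3.3694   0.001 0.0025
 average_strength gamma    4.3821     4.5542   0.001 0.0025
global_efficiency delta    0.1733     0.2010   0.001 0.0025
global_efficiency gamma    0.2465     0.2654   0.001 0.0025
       modularity delta    0.1851     0.1518   0.001 0.0025
       modularity gamma    0.2907     0.2052   0.001 0.0025
```

Exactly the injected effect is recovered: in the delta and gamma bands —
where the generator raises the shared-source coupling gain post — average
strength and global efficiency increase and modularity decreases
(the bridging source merges the baseline anterior/posterior communities),
while the untouched bands show no significant rows.  `result.correlations`
holds the measure-by-measure Pearson correlations with the cognitive
score change; with the default subject-level coupling jitter these are
noise-dominated (|r| ≈ 0.2 at n = 21), which is the realistic regime —
score-level correlation recovery is exercised directly through the
generator's score model instead (see below).

The same pipeline runs from the shell, including EDF export/import:

```sh
eegfc simulate --outdir sim            # 42 EDF files + manifest + scores.csv
eegfc run --outdir results --seed 7    # tables + SVG/PNG figures
```

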