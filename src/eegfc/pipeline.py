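"""End-to-end orchestration: simulate -> connectivity -> graphs -> stats.

Stages are pure functions over in-memory objects; `run_pipeline` wires them
together, writes every tabular output under the output directory and keys
cached stage outputs by a hash of the configuration, so a rerun with the
same config reuses (and a changed config invalidates) previous results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import io as fio
from .connectivity import (
    ConnectivityMatrix,
    aggregate_condition,
    coherence_matrix,
    cross_spectra,
    pli_matrix,
)
from .graph import GraphConfig, all_measures, default_degree_threshold, GLOBAL_MEASURES
from .signal import BANDS, bandpass_recording, extract_epochs, get_band
from .stats import (
    compare_measures,
    correlate_changes,
    node_increase_scores,
    normalize_changes,
    paired_t_test,
    PairedSample,
    top_increased_edges,
)
from .synth import Cohort, EEGRecording, SynthConfig, generate_cohort

log = logging.getLogger("eegfc")

#: Timed tests where improvement = pre - post (lower is better).
LOWER_IS_BETTER = ("trail_making_b",)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; serializes losslessly to JSON/YAML."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    methods: tuple[str, ...] = ("coherence", "pli")
    bands: tuple[str, ...] = tuple(b.name for b in BANDS)
    n_epochs: int = 10
    epoch_len_s: float = 2.0
    degree_thresholds: dict[str, float] = field(
        default_factory=lambda: {"coherence": 0.5, "pli": 0.05}
    )
    graph_measures: tuple[str, ...] = GLOBAL_MEASURES
    n_nulls: int = 100
    modularity_restarts: int = 10
    n_perm: int = 1000
    fdr_family: str = "per_measure"
    alpha: float = 0.05
    correlation_test: str = "trail_making_b"
    top_k_edges: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["score_models"] = {
            k: dataclasses.asdict(v) for k, v in self.synth.score_models.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .synth import ScoreModel

        d = dict(d)
        sd = dict(d.pop("synth", {}))
        if "score_models" in sd:
            sd["score_models"] = {
                k: ScoreModel(**v) for k, v in sd["score_models"].items()
            }
        for key in ("coupled_channel_set", "anterior_community", "posterior_community"):
            if key in sd and sd[key] is not None:
                sd[key] = tuple(sd[key])
        if sd.get("phase_lag_rad") is not None:
            sd["phase_lag_rad"] = tuple(sd["phase_lag_rad"])
        for key in ("methods", "bands", "graph_measures"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(synth=SynthConfig(**sd), **d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def graph_config(self, method: str) -> GraphConfig:
        thr = self.degree_thresholds.get(method, default_degree_threshold(method))
        return GraphConfig(
            degree_threshold=thr,
            n_nulls=self.n_nulls,
            modularity_restarts=self.modularity_restarts,
            seed=self.seed,
            global_measures=self.graph_measures,
        )


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML or JSON pipeline config."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        import yaml

        return PipelineConfig.from_dict(yaml.safe_load(text))
    return PipelineConfig.from_dict(json.loads(text))


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in (".yml", ".yaml"):
        import yaml

        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    else:
        path.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# stages

def subject_connectivity(
    rec: EEGRecording, config: PipelineConfig
) -> list[ConnectivityMatrix]:
    """All (method, band) matrices for one recording.

    Coherence: broadband epochs -> Welch cross-spectra -> band averages.
    PLI: band-pass the continuous recording, cut the same epoch layout,
    then the sign-mean of analytic phase differences.
    """
    out: list[ConnectivityMatrix] = []
    if "coherence" in config.methods:
        epochs = extract_epochs(rec, config.n_epochs, config.epoch_len_s)
        spec = cross_spectra(epochs)
        for band_name in config.bands:
            out.append(
                coherence_matrix(
                    spec, get_band(band_name), rec.subject_id, rec.condition
                )
            )
    if "pli" in config.methods:
        for band_name in config.bands:
            band = get_band(band_name)
            filtered = bandpass_recording(rec, band)
            epochs = extract_epochs(filtered, config.n_epochs, config.epoch_len_s)
            epochs = epochs.with_band(band, epochs.epochs)
            out.append(pli_matrix(epochs))
    return out


def connectivity_stage(
    cohort: Cohort, config: PipelineConfig
) -> list[ConnectivityMatrix]:
    matrices: list[ConnectivityMatrix] = []
    for subj in cohort.subjects:
        for rec in (subj.pre, subj.post):
            matrices.extend(subject_connectivity(rec, config))
        log.debug("connectivity done for %s", subj.subject_id)
    return matrices


def graph_stage(
    matrices: Iterable[ConnectivityMatrix], config: PipelineConfig
) -> pd.DataFrame:
    """Tidy measure table (global + nodal rows) for every matrix."""
    sets = [all_measures(m, config.graph_config(m.method)) for m in matrices]
    return fio.measures_to_tidy(sets)


def compare_stage(measures: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Permutation + FDR comparison of the global measures, per method."""
    out = []
    glob = measures[measures["node"] == "global"]
    for method, sub in glob.groupby("method"):
        cmp = compare_measures(
            sub.rename(columns={})[
                ["subject_id", "condition", "measure", "band", "value"]
            ],
            n_perm=config.n_perm,
            seed=config.seed,
            fdr_family=config.fdr_family,
        )
        cmp.insert(0, "method", method)
        out.append(cmp)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


def score_comparison_stage(scores: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests per neuropsychological test (Table-1 style layout)."""
    rows = []
    for test, sub in scores.groupby("test_name"):
        s = PairedSample(
            tuple(sub["subject_id"]),
            sub["pre"].to_numpy(float),
            sub["post"].to_numpy(float),
        )
        res = paired_t_test(s)
        rows.append({"test_name": test, **res})
    return pd.DataFrame(rows)


def score_improvement(scores: pd.DataFrame, test_name: str) -> pd.Series:
    """Per-subject improvement; for timed tests improvement = pre - post."""
    sub = scores[scores["test_name"] == test_name].set_index("subject_id")
    if sub.empty:
        raise ValueError(f"no rows for test {test_name!r}")
    change = sub["post"] - sub["pre"]
    if test_name in LOWER_IS_BETTER:
        change = -change
    return change


def correlate_stage(
    measures: pd.DataFrame, scores: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Normalized-change Pearson correlations, one per (method, measure,
    band), against the configured cognitive test."""
    improvement = score_improvement(scores, config.correlation_test)
    rows = []
    glob = measures[measures["node"] == "global"]
    for (method, measure, band), sub in glob.groupby(["method", "measure", "band"]):
        wide = sub.pivot_table(
            index="subject_id", columns="condition", values="value"
        ).dropna()
        common = wide.index.intersection(improvement.index)
        if len(common) < 3:
            continue
        g_change = (wide.loc[common, "post"] - wide.loc[common, "pre"]).to_numpy()
        s_change = improvement.loc[common].to_numpy()
        if g_change.std(ddof=1) == 0 or s_change.std(ddof=1) == 0:
            continue
        res = correlate_changes(
            normalize_changes(g_change),
            normalize_changes(s_change),
            graph_measure=measure,
            band=band,
            cognitive_test=config.correlation_test,
        )
        rows.append(
            {
                "method": method,
                "measure": measure,
                "band": band,
                "cognitive_test": config.correlation_test,
                "r": res.r,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def mean_matrices(
    matrices: list[ConnectivityMatrix],
) -> dict[tuple[str, str, str], ConnectivityMatrix]:
    """(method, band, condition) -> subject-averaged matrix."""
    groups: dict[tuple[str, str, str], list[ConnectivityMatrix]] = {}
    for m in matrices:
        groups.setdefault((m.method, m.band.name, m.condition), []).append(m)
    return {k: aggregate_condition(v) for k, v in groups.items()}


def edge_ranking_stage(
    means: dict[tuple[str, str, str], ConnectivityMatrix], config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k increased edges and their node incidence scores per method/band."""
    edge_rows, node_rows = [], []
    for method in config.methods:
        for band in config.bands:
            pre = means.get((method, band, "pre"))
            post = means.get((method, band, "post"))
            if pre is None or post is None:
                continue
            edges = top_increased_edges(pre, post, k=config.top_k_edges)
            edges.insert(0, "method", method)
            edges.insert(1, "band", band)
            edge_rows.append(edges)
            nodes = node_increase_scores(edges)
            node_rows.append(
                pd.DataFrame(
                    {
                        "method": method,
                        "band": band,
                        "channel": nodes.index,
                        "score": nodes.to_numpy(),
                    }
                )
            )
    cat = lambda rows: pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return cat(edge_rows), cat(node_rows)


# ---------------------------------------------------------------------------
# full run

@dataclass
class PipelineResult:
    config: PipelineConfig
    measures: pd.DataFrame
    comparisons: pd.DataFrame
    score_comparisons: pd.DataFrame
    correlations: pd.DataFrame
    top_edges: pd.DataFrame
    node_scores: pd.DataFrame
    means: dict[tuple[str, str, str], ConnectivityMatrix]
    outdir: Path | None = None


def simulate_to_disk(config: PipelineConfig, outdir: str | Path) -> Path:
    """Write the synthetic cohort as EDF files + manifest + scores CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config.synth)
    rows = []
    for subj in cohort.subjects:
        for rec in (subj.pre, subj.post):
            path = outdir / f"{rec.subject_id}_{rec.condition}.edf"
            fio.write_edf(path, rec)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "condition": rec.condition,
                    "path": path.name,
                    "seed": config.synth.seed,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    fio.write_scores_csv(outdir / "scores.csv", cohort.scores)
    save_config(config, outdir / "config.json")
    return outdir


def load_cohort_from_manifest(manifest_path: str | Path) -> tuple[list, pd.DataFrame]:
    """Recordings + scores from a `simulate` output directory."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    recs = [
        fio.read_edf(base / row["path"], condition=row["condition"])
        for _, row in manifest.iterrows()
    ]
    scores = fio.read_scores_csv(base / "scores.csv")
    return recs, scores


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    cohort: Cohort | None = None,
) -> PipelineResult:
    """Simulate (unless given a cohort), estimate connectivity, compute
    graph measures, compare conditions, and correlate with scores.

    With ``outdir`` set, all tables are written as CSV and stage outputs
    are cached under ``cache/<config-hash>/`` -- a rerun with the same
    config reloads them instead of recomputing.
    """
    cache = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cache = outdir / "cache" / config.config_hash()
        cache.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        log.info("generating synthetic cohort (n=%d)", config.synth.n_subjects)
        cohort = generate_cohort(config.synth)

    measures_path = cache / "measures.csv" if cache else None
    if measures_path is not None and measures_path.exists():
        log.info("reusing cached measures (%s)", measures_path)
        measures = pd.read_csv(measures_path, dtype={"node": str})
        matrices = connectivity_stage(cohort, config)
    else:
        log.info("estimating connectivity (%s)", ", ".join(config.methods))
        matrices = connectivity_stage(cohort, config)
        log.info("computing graph measures for %d matrices", len(matrices))
        measures = graph_stage(matrices, config)
        if measures_path is not None:
            measures.to_csv(measures_path, index=False)

    log.info("group comparison (%d permutations)", config.n_perm)
    comparisons = compare_stage(measures, config)
    score_cmp = score_comparison_stage(cohort.scores)
    correlations = correlate_stage(measures, cohort.scores, config)
    means = mean_matrices(matrices)
    top_edges, node_scores = edge_ranking_stage(means, config)

    if outdir is not None:
        measures.to_csv(outdir / "measures.csv", index=False)
        comparisons.to_csv(outdir / "comparison.csv", index=False)
        score_cmp.to_csv(outdir / "score_comparison.csv", index=False)
        correlations.to_csv(outdir / "correlation.csv", index=False)
        top_edges.to_csv(outdir / "top_edges.csv", index=False)
        node_scores.to_csv(outdir / "node_scores.csv", index=False)
        fio.write_scores_csv(outdir / "scores.csv", cohort.scores)
        for (method, band, cond), m in means.items():
            fio.write_matrix_tsv(outdir / f"mean_{method}_{band}_{cond}.tsv", m)
        save_config(config, outdir / "config.json")
        _write_manifest(config, outdir)

    return PipelineResult(
        config=config,
        measures=measures,
        comparisons=comparisons,
        score_comparisons=score_cmp,
        correlations=correlations,
        top_edges=top_edges,
        node_scores=node_scores,
        means=means,
        outdir=Path(outdir) if outdir is not None else None,
    )


def _write_manifest(config: PipelineConfig, outdir: Path) -> None:
    import datetime

    from . import __version__

    entries = sorted(
        str(p.relative_to(outdir)) for p in outdir.glob("*.csv")
    ) + sorted(str(p.relative_to(outdir)) for p in outdir.glob("*.tsv"))
    manifest = {
        "config_hash": config.config_hash(),
        "software": f"eegfc {__version__}",
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "outputs": entries,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
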