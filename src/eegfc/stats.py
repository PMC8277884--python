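"""Group-level inference for paired pre/post designs.

Graph measures are compared across conditions with a paired sign-flip
permutation test: the statistic is the mean post-pre difference, the null
is built by independently negating each subject's difference, and the
two-sided p-value uses the add-one convention
p = (#{|null| >= |observed|} + 1) / (n_perm + 1), so p is never 0.
Multiple comparisons are handled with Benjamini-Hochberg FDR, by default
per measure across the five bands.  Cognitive scores are compared with the
classical paired t-test; change scores are z-normalized across subjects
before Pearson correlation so measures on different scales are comparable.
Trail Making B is timed (lower = better): its improvement is pre - post.
"""

from __future__ import annotations

from dataclasses import dataclass
import zlib

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class PairedSample:
    """Aligned per-subject values for the two conditions."""

    subject_ids: tuple[str, ...]
    values_pre: np.ndarray
    values_post: np.ndarray

    def __post_init__(self) -> None:
        pre = np.asarray(self.values_pre, dtype=float)
        post = np.asarray(self.values_post, dtype=float)
        if pre.shape != post.shape or pre.ndim != 1:
            raise ValueError("pre/post must be 1-D arrays of equal length")
        if len(self.subject_ids) != pre.size:
            raise ValueError("subject_ids must align with the values")
        object.__setattr__(self, "values_pre", pre)
        object.__setattr__(self, "values_post", post)

    @property
    def differences(self) -> np.ndarray:
        return self.values_post - self.values_pre

    @property
    def n(self) -> int:
        return self.values_pre.size


@dataclass(frozen=True)
class GroupComparison:
    measure: str
    band: str
    observed_mean_diff: float
    p_perm: float
    q_fdr: float
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class CorrelationResult:
    graph_measure: str
    band: str
    cognitive_test: str
    r: float
    p: float


def paired_permutation_test(
    s: PairedSample, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Two-sided sign-flip permutation p for the mean paired difference."""
    if s.n < 2:
        raise ValueError("need at least 2 subjects")
    d = s.differences
    observed = float(d.mean())
    if np.all(d == 0):
        return observed, 1.0
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, s.n))
    null = (signs * d).mean(axis=1)
    exceed = np.count_nonzero(np.abs(null) >= abs(observed) - 1e-15)
    p = (exceed + 1) / (n_perm + 1)
    return observed, float(p)


def exhaustive_sign_flip_p(d: np.ndarray) -> float:
    """Exact two-sided sign-flip p over all 2^n patterns (n <= ~16)."""
    d = np.asarray(d, dtype=float)
    n = d.size
    if n > 20:
        raise ValueError("exhaustive enumeration is only for small n")
    observed = abs(d.mean())
    patterns = np.array(
        [[1.0 if (k >> i) & 1 else -1.0 for i in range(n)] for k in range(2**n)]
    )
    null = np.abs((patterns * d).mean(axis=1))
    return float(np.count_nonzero(null >= observed - 1e-15) / 2**n)


def fdr_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one family)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_t_test(s: PairedSample) -> dict:
    """Classical paired t-test with per-condition summaries.

    Zero difference variance is a degenerate case: t/p are NaN and the
    ``degenerate`` flag is set, mirroring the untestable ceiling-effect
    rows of a score table.
    """
    if s.n < 2:
        raise ValueError("need at least 2 subjects")
    d = s.differences
    degenerate = bool(np.allclose(d.std(ddof=1), 0.0))
    if degenerate:
        t, p = float("nan"), float("nan")
    else:
        res = sstats.ttest_rel(s.values_post, s.values_pre)
        t, p = float(res.statistic), float(res.pvalue)
    return {
        "t": t,
        "p": p,
        "mean_pre": float(s.values_pre.mean()),
        "sd_pre": float(s.values_pre.std(ddof=1)),
        "mean_post": float(s.values_post.mean()),
        "sd_post": float(s.values_post.std(ddof=1)),
        "degenerate": degenerate,
    }


def normalize_changes(changes: np.ndarray) -> np.ndarray:
    """z-score across subjects: (x - mean) / sample sd (ddof=1)."""
    x = np.asarray(changes, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 subjects")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: changes cannot be normalized")
    return (x - x.mean()) / sd


def correlate_changes(
    graph_changes: np.ndarray,
    score_changes: np.ndarray,
    graph_measure: str = "",
    band: str = "",
    cognitive_test: str = "",
) -> CorrelationResult:
    """Pearson r (two-sided t-distribution p, n-2 df) between normalized
    change vectors; one test per (measure, band), uncorrected across
    measures by design."""
    g = np.asarray(graph_changes, dtype=float)
    c = np.asarray(score_changes, dtype=float)
    if g.shape != c.shape or g.ndim != 1:
        raise ValueError("change vectors must align")
    if g.size < 3:
        raise ValueError("need at least 3 subjects")
    r, p = sstats.pearsonr(g, c)
    return CorrelationResult(graph_measure, band, cognitive_test, float(r), float(p))


def compare_measures(
    table: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    fdr_family: str = "per_measure",
) -> pd.DataFrame:
    """Permutation comparisons for a tidy measure table.

    ``table`` columns: subject_id, condition, measure, band, value.
    Returns one row per (measure, band) with mean_pre/mean_post, the
    permutation p and the BH q (family per measure across bands, or one
    global family).
    """
    rows = []
    for (measure, band), sub in table.groupby(["measure", "band"], sort=True):
        wide = sub.pivot_table(
            index="subject_id", columns="condition", values="value"
        ).dropna()
        s = PairedSample(
            tuple(wide.index), wide["pre"].to_numpy(), wide["post"].to_numpy()
        )
        # independent stream per comparison, reproducible from the root seed
        # (zlib.crc32 is stable across processes, unlike str hash)
        tag = zlib.crc32(f"{measure}|{band}".encode())
        sub_seed = np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31)
        diff, p = paired_permutation_test(s, n_perm=n_perm, seed=int(sub_seed))
        rows.append(
            {
                "measure": measure,
                "band": band,
                "mean_pre": float(s.values_pre.mean()),
                "mean_post": float(s.values_post.mean()),
                "mean_diff": diff,
                "p_perm": p,
                "n_permutations": n_perm,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q_fdr"] = np.nan
    if fdr_family == "global":
        out["q_fdr"] = fdr_adjust(out["p_perm"].to_numpy())
    elif fdr_family == "per_measure":
        for measure, idx in out.groupby("measure").groups.items():
            out.loc[idx, "q_fdr"] = fdr_adjust(out.loc[idx, "p_perm"].to_numpy())
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    return out


def top_increased_edges(
    mean_pre, mean_post, k: int = 10
) -> pd.DataFrame:
    """The k channel pairs with the largest post-pre weight increase.

    Ties break by channel-pair lexicographic order, so the ranking is
    deterministic; an all-zero increase is flagged.
    """
    if mean_pre.method != mean_post.method or mean_pre.band != mean_post.band:
        raise ValueError("matrices must share method and band")
    if mean_pre.values.shape != mean_post.values.shape:
        raise ValueError("matrix shapes differ")
    labels = mean_pre.channel_labels or tuple(
        str(i) for i in range(mean_pre.values.shape[0])
    )
    diff = mean_post.values - mean_pre.values
    iu, ju = np.triu_indices(diff.shape[0], k=1)
    order = np.lexsort((ju, iu, -diff[iu, ju]))  # decreasing, then lexicographic
    order = order[:k]
    return pd.DataFrame(
        {
            "chan_i": [labels[i] for i in iu[order]],
            "chan_j": [labels[j] for j in ju[order]],
            "increase": diff[iu[order], ju[order]],
            "weight_post": mean_post.values[iu[order], ju[order]],
            "all_zero": bool(np.all(diff[iu, ju] == 0)),
        }
    )


def node_increase_scores(edges: pd.DataFrame, top_n: int = 10) -> pd.Series:
    """Per-node sum of post-condition weights of the listed edges incident
    to it; the ``top_n`` highest-scoring nodes, descending."""
    scores: dict[str, float] = {}
    for _, row in edges.iterrows():
        for ch in (row["chan_i"], row["chan_j"]):
            scores[ch] = scores.get(ch, 0.0) + float(row["weight_post"])
    s = pd.Series(scores, dtype=float).sort_values(ascending=False, kind="stable")
    return s.head(top_n)
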