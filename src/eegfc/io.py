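"""File formats: EDF recordings, connectivity tables, tidy measure CSVs.

Recordings are exchanged as EDF (16-bit European Data Format).  Reading
goes through MNE's EDF reader; writing uses the minimal EDF writer below
(one data record per second, per-channel physical scaling), since no
installed library writes EDF.  Connectivity matrices round-trip as TSV
with channel-label headers and as long-format CSV; graph measures and
cognitive scores as tidy CSV.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .montage import MontageSpec, normalize_label
from .signal import get_band
from .synth import EEGRecording

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, rec: EEGRecording) -> Path:
    """Write a recording as 16-bit EDF (one 1-s data record per second).

    The recording is truncated to a whole number of seconds (the generator
    always produces integer-second recordings, so nothing is lost there).
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))  # samples per record (1-s records)
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = rec.data.shape[1] // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one data record")
    data = rec.data[:, : n_rec * spr]
    n_ch = data.shape[0]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(f"{rec.subject_id} {rec.condition}", 80),
            _edf_field("eegfc synthetic", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (1 + n_ch), 8),
            _edf_field("", 44),
            _edf_field(n_rec, 8),
            _edf_field(1, 8),
            _edf_field(n_ch, 4),
        ]
    )
    labels = [f"EEG {c}" for c in rec.montage.channel_labels]
    per_sig = b"".join(
        [
            b"".join(_edf_field(lab, 16) for lab in labels),
            b"".join(_edf_field("AgAgCl electrode", 80) for _ in labels),
            b"".join(_edf_field("uV", 8) for _ in labels),
            b"".join(_edf_field(f"{phys_min[i]:.8g}"[:8], 8) for i in range(n_ch)),
            b"".join(_edf_field(f"{phys_max[i]:.8g}"[:8], 8) for i in range(n_ch)),
            b"".join(_edf_field(_EDF_DIG_MIN, 8) for _ in labels),
            b"".join(_edf_field(_EDF_DIG_MAX, 8) for _ in labels),
            b"".join(_edf_field("", 80) for _ in labels),
            b"".join(_edf_field(spr, 8) for _ in labels),
            b"".join(_edf_field("", 32) for _ in labels),
        ]
    )

    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_max - phys_min)
    digital = np.round(
        (data - phys_min[:, None]) * scale[:, None] + _EDF_DIG_MIN
    ).astype("<i2")

    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())  # channel-sequential within record
    return path


def read_edf(path: str | Path, condition: str | None = None) -> EEGRecording:
    """Read a 19-channel EDF through MNE; labels normalized to the
    T3/T4/T5/T6 dialect and reordered to the canonical montage order."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = [ch.removeprefix("EEG ").strip() for ch in raw.ch_names]
    canon = [normalize_label(lab) for lab in labels]
    montage = MontageSpec()
    order = [canon.index(c) for c in montage.channel_labels]
    data = raw.get_data()[order] * 1e6  # MNE loads EEG in volts
    # subject/condition ride in the EDF patient field ("<id> <condition>")
    with open(path, "rb") as fh:
        fh.seek(8)
        patient = fh.read(80).decode("ascii").strip()
    parts = patient.split()
    subject_id = parts[0] if parts else Path(path).stem
    cond = condition or (parts[1] if len(parts) > 1 else "pre")
    return EEGRecording(subject_id, cond, montage, data, float(raw.info["sfreq"]))


# ---------------------------------------------------------------------------
# connectivity matrices

def write_matrix_tsv(path: str | Path, m: ConnectivityMatrix) -> Path:
    """Square TSV with channel-label header row/column and a comment line
    carrying provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = list(m.channel_labels) or [str(i) for i in range(m.n_channels)]
    with open(path, "w") as fh:
        fh.write(
            f"# method={m.method} band={m.band.name} subject={m.subject_id} "
            f"condition={m.condition} n_epochs={m.n_epochs_used}\n"
        )
        fh.write("channel\t" + "\t".join(labels) + "\n")
        for i, lab in enumerate(labels):
            row = "\t".join(f"{v:.10g}" for v in m.values[i])
            fh.write(f"{lab}\t{row}\n")
    return path


def read_matrix_tsv(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    with open(path) as fh:
        meta_line = fh.readline().strip().lstrip("# ")
    meta = dict(kv.split("=", 1) for kv in meta_line.split())
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return ConnectivityMatrix(
        values=df.to_numpy(dtype=float),
        method=meta["method"],
        band=get_band(meta["band"]),
        subject_id=meta["subject"],
        condition=meta["condition"],
        n_epochs_used=int(meta["n_epochs"]),
        channel_labels=tuple(df.columns),
    )


def matrix_to_long(m: ConnectivityMatrix) -> pd.DataFrame:
    """Long-format edge list (chan_i, chan_j, method, band, value), i < j."""
    labels = list(m.channel_labels) or [str(i) for i in range(m.n_channels)]
    iu, ju = np.triu_indices(m.n_channels, k=1)
    return pd.DataFrame(
        {
            "chan_i": [labels[i] for i in iu],
            "chan_j": [labels[j] for j in ju],
            "method": m.method,
            "band": m.band.name,
            "subject_id": m.subject_id,
            "condition": m.condition,
            "value": m.values[iu, ju],
        }
    )


# ---------------------------------------------------------------------------
# tidy tables

def measures_to_tidy(measure_sets) -> pd.DataFrame:
    """GraphMeasureSets -> tidy CSV rows (subject, condition, method, band,
    measure, node, value); global rows carry node='global'."""
    rows = []
    for ms in measure_sets:
        base = {
            "subject_id": ms.subject_id,
            "condition": ms.condition,
            "method": ms.method,
            "band": ms.band,
        }
        for measure, value in ms.global_measures.items():
            rows.append({**base, "measure": measure, "node": "global", "value": value})
        for measure, vec in ms.nodal_measures.items():
            for node, value in enumerate(np.asarray(vec)):
                rows.append(
                    {**base, "measure": measure, "node": str(node), "value": value}
                )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "condition", "method", "band", "measure", "node", "value",
        ],
    )


def write_scores_csv(path: str | Path, scores: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    scores.to_csv(path, index=False)
    return path


def read_scores_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "test_name", "pre", "post"}
    if not required.issubset(df.columns):
        raise ValueError(f"score table must have columns {sorted(required)}")
    return df
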