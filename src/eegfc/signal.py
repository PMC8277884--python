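"""Epoch handling and band-pass decomposition.

The five analysis bands are the conventional clinical EEG bands:
delta 0.1-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-50 Hz.

Band-pass filtering is zero-phase (forward-backward) 4th-order Butterworth
(effective 8th order), applied per channel with reflect padding.  For the
full pipeline the filter is applied to the *continuous* recording before
epochs are cut, so that the long transient of the 0.1 Hz delta edge never
touches a 2-s epoch; `bandpass` on an EpochSet is also provided for
epoch-level work.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Literal, Sequence

import numpy as np
from scipy import signal as sps

if TYPE_CHECKING:  # pragma: no cover
    from .synth import EEGRecording


@dataclass(frozen=True)
class BandDefinition:
    """One analysis band: half-open frequency interval [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi):
            raise ValueError(f"invalid band edges {self.lo}-{self.hi}")


#: Canonical analysis bands, in spectral order.
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.1, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in BANDS)
_BAND_MAP = {b.name: b for b in BANDS}


def get_band(name: str) -> BandDefinition:
    try:
        return _BAND_MAP[name]
    except KeyError:
        raise KeyError(f"unknown band {name!r}; expected one of {BAND_NAMES}")


class EpochLengthError(ValueError):
    """Recording too short for the requested epoch layout."""


class EpochOverlapError(ValueError):
    """Listed onsets produce overlapping or consecutive epochs."""


@dataclass(frozen=True)
class EpochSet:
    """Clean 2-s segments of one subject/condition used for spectral work.

    ``band`` is None for broadband epochs; band-passed sets carry their band
    so downstream estimators can refuse broadband input where narrowband is
    required (PLI).
    """

    subject_id: str
    condition: str
    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)
    fs: float
    band: BandDefinition | None = None
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.epochs, dtype=float)
        if arr.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        if arr.shape[0] < 1:
            raise ValueError("need at least one epoch")
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite samples in epochs")
        object.__setattr__(self, "epochs", arr)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def with_band(self, band: BandDefinition, data: np.ndarray) -> "EpochSet":
        return replace(self, epochs=data, band=band)


def evenly_spaced_onsets(
    n_total: int, n_epochs: int, epoch_len: int, min_gap: int
) -> np.ndarray:
    """Onset sample indices of ``n_epochs`` evenly laid-out epochs.

    Epoch k starts at floor(k * n_total / n_epochs).  Raises
    EpochLengthError when the layout cannot honour ``min_gap`` samples
    between consecutive epochs.
    """
    if n_total < n_epochs * epoch_len + (n_epochs - 1) * min_gap:
        need = n_epochs * epoch_len + (n_epochs - 1) * min_gap
        raise EpochLengthError(
            f"recording of {n_total} samples too short: need >= {need} "
            f"({n_epochs} epochs x {epoch_len} + {n_epochs - 1} gaps of {min_gap})"
        )
    onsets = np.floor(np.arange(n_epochs) * n_total / n_epochs).astype(int)
    if np.any(np.diff(onsets) < epoch_len + min_gap):
        # near the minimum length the proportional layout under-gaps;
        # fall back to tight packing at exactly epoch_len + min_gap spacing
        onsets = np.arange(n_epochs) * (epoch_len + min_gap)
    if onsets[-1] + epoch_len > n_total:
        raise EpochLengthError("evenly spaced layout does not fit the recording")
    return onsets


def extract_epochs(
    rec: "EEGRecording",
    n_epochs: int = 10,
    epoch_len_s: float = 2.0,
    strategy: Literal["evenly_spaced", "listed_onsets"] = "evenly_spaced",
    onsets_s: Sequence[float] | None = None,
    min_gap_s: float = 1.0,
) -> EpochSet:
    """Cut non-overlapping, non-consecutive epochs from a recording.

    ``evenly_spaced`` lays epochs out deterministically over the whole
    recording; ``listed_onsets`` takes explicit onset times (seconds) and
    validates the gap.  The human artifact-review selection this stands in
    for is not modelled; synthetic recordings are generated clean.
    """
    epoch_len = int(round(epoch_len_s * rec.fs))
    min_gap = int(round(min_gap_s * rec.fs))
    n_total = rec.data.shape[1]

    if strategy == "evenly_spaced":
        onsets = evenly_spaced_onsets(n_total, n_epochs, epoch_len, min_gap)
    elif strategy == "listed_onsets":
        if onsets_s is None:
            raise ValueError("listed_onsets strategy requires onsets_s")
        onsets = np.array(sorted(int(round(t * rec.fs)) for t in onsets_s))
        if len(onsets) == 0:
            raise ValueError("empty onset list")
        if np.any(np.diff(onsets) < epoch_len + min_gap):
            raise EpochOverlapError(
                "listed onsets overlap or are consecutive "
                f"(need >= {epoch_len + min_gap} samples between onsets)"
            )
        if onsets[0] < 0 or onsets[-1] + epoch_len > n_total:
            raise EpochLengthError("listed onsets run past the recording")
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    epochs = np.stack([rec.data[:, o : o + epoch_len] for o in onsets])
    return EpochSet(
        subject_id=rec.subject_id,
        condition=rec.condition,
        epochs=epochs,
        fs=rec.fs,
        band=None,
        channel_labels=tuple(rec.montage.channel_labels),
    )


def _band_sos(band: BandDefinition, fs: float, order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    if band.hi >= nyq:
        raise ValueError(f"band {band.name} upper edge {band.hi} >= Nyquist {nyq}")
    return sps.butter(order, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")


def bandpass_array(x: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Zero-phase band-pass along the last axis (reflect-padded filtfilt)."""
    sos = _band_sos(band, fs)
    # sosfiltfilt pads by odd reflection; extend padding for the slow delta edge
    padlen = min(x.shape[-1] - 1, max(3 * int(fs), 24))
    return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def bandpass(epochs: EpochSet, band: BandDefinition) -> EpochSet:
    """Band-pass an EpochSet per channel; output tagged with the band."""
    if epochs.band is not None:
        raise ValueError("input epochs are already band-limited")
    out = bandpass_array(epochs.epochs, band, epochs.fs)
    return epochs.with_band(band, out)


def bandpass_recording(rec: "EEGRecording", band: BandDefinition) -> "EEGRecording":
    """Band-pass the continuous recording (pipeline ordering: filter, then cut)."""
    from dataclasses import replace as dc_replace

    return dc_replace(rec, data=bandpass_array(rec.data, band, rec.fs))
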