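"""Band-wise coherence and phase-lag-index connectivity matrices.

Coherence is the magnitude-squared coherency

    COH_xy(f) = |S_xy(f)|^2 / (S_xx(f) S_yy(f)),

with the cross-/auto-spectral densities S estimated Welch-style: one
Hann-tapered segment per 2-s epoch, periodograms averaged across epochs,
nfft equal to the epoch length (0.5 Hz resolution at 200 Hz).  Band values
are the mean over bins with lo <= f < hi; the delta band's 0.1 Hz edge is
below the grid, so delta effectively uses 0.5-4 Hz.

The phase lag index (PLI) is |< sign(dphi(t_k)) >| over samples, where dphi
is the instantaneous phase difference from the analytic signal of the
band-passed epoch; PLI is computed per epoch and averaged.  PLI is 0 both
for no coupling and for phase differences centred on 0 mod pi (the
volume-conduction case coherence cannot reject), and 1 for a constant
nonzero asymmetric lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .signal import BandDefinition, EpochSet


class DegenerateEstimateError(ValueError):
    """Raised when coherence is requested from a single segment (identically 1)."""


class BandResolutionError(ValueError):
    """Raised when a band contains no bins of the frequency grid."""


@dataclass(frozen=True)
class SpectralEstimate:
    """Averaged auto- and cross-spectral densities on a common grid."""

    frequencies: np.ndarray  # (n_freqs,)
    sxx: np.ndarray  # (n_channels, n_freqs) real, >= 0
    sxy: np.ndarray  # (n_channels, n_channels, n_freqs) complex
    n_epochs_used: int
    channel_labels: tuple[str, ...] = ()

    @property
    def n_channels(self) -> int:
        return self.sxx.shape[0]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric 19x19 weighted adjacency for one (method, band, subject,
    condition); entries in [0, 1], diagonal fixed at 0 (self-connections
    excluded by convention)."""

    values: np.ndarray
    method: str  # "coherence" | "pli"
    band: BandDefinition
    subject_id: str
    condition: str
    n_epochs_used: int
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=0):
            raise ValueError("connectivity matrix must be exactly symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("entries must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def cross_spectra(
    epochs: EpochSet, window: str = "hann", nfft: int | None = None
) -> SpectralEstimate:
    """Welch cross-spectral estimate with one segment per epoch.

    Scaling constants cancel in every coherence ratio, so densities are
    reported up to the common taper normalization.
    """
    if epochs.n_epochs < 2:
        raise DegenerateEstimateError(
            "coherence from a single segment is identically 1; need >= 2 epochs"
        )
    x = epochs.epochs  # (E, C, N)
    n = x.shape[2]
    if nfft is None:
        nfft = n
    if window == "hann":
        taper = np.hanning(n)
    elif window in ("boxcar", "rect", "none"):
        taper = np.ones(n)
    else:
        from scipy.signal import get_window

        taper = get_window(window, n)

    xt = (x - x.mean(axis=2, keepdims=True)) * taper  # demean per epoch/channel
    spec = np.fft.rfft(xt, n=nfft, axis=2)  # (E, C, F)
    freqs = np.fft.rfftfreq(nfft, 1.0 / epochs.fs)
    # S_xy = < X conj(Y) > over epochs; Hermitian under pair swap
    sxy = np.einsum("ecf,edf->cdf", spec, np.conj(spec)) / x.shape[0]
    sxx = np.real(np.einsum("ccf->cf", sxy)).copy()
    return SpectralEstimate(
        frequencies=freqs,
        sxx=sxx,
        sxy=sxy,
        n_epochs_used=x.shape[0],
        channel_labels=epochs.channel_labels,
    )


def _band_bin_mask(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    mask = (freqs >= band.lo) & (freqs < band.hi)
    if not np.any(mask):
        raise BandResolutionError(
            f"band {band.name} [{band.lo}, {band.hi}) contains no frequency bins"
        )
    return mask


def coherence_matrix(
    spec: SpectralEstimate,
    band: BandDefinition,
    subject_id: str = "",
    condition: str = "",
) -> ConnectivityMatrix:
    """Magnitude-squared coherence averaged over the band's bins."""
    mask = _band_bin_mask(spec.frequencies, band)
    sxx = spec.sxx[:, mask]
    sxy = spec.sxy[:, :, mask]
    denom = sxx[:, None, :] * sxx[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(sxy) ** 2 / denom
    coh = np.where(denom > 0, coh, 0.0)
    values = coh.mean(axis=2)
    values = 0.5 * (values + values.T)  # exact symmetry against fp noise
    np.fill_diagonal(values, 0.0)
    values = np.clip(values, 0.0, 1.0)
    return ConnectivityMatrix(
        values=values,
        method="coherence",
        band=band,
        subject_id=subject_id,
        condition=condition,
        n_epochs_used=spec.n_epochs_used,
        channel_labels=spec.channel_labels,
    )


def pli_from_phase_difference(dphi: np.ndarray, axis: int = -1) -> np.ndarray:
    """|< sign(dphi) >| over samples; sign taken on the wrapped difference
    (sign(sin) is wrap-safe), so 0-mod-pi differences contribute nothing."""
    return np.abs(np.sign(np.sin(dphi)).mean(axis=axis))


def pli_matrix(
    epochs: EpochSet,
    edge_fraction: float = 0.1,
    subject_id: str | None = None,
    condition: str | None = None,
) -> ConnectivityMatrix:
    """Phase lag index over all channel pairs of band-passed epochs.

    Instantaneous phases come from the analytic signal; ``edge_fraction``
    of samples is discarded at each epoch edge to suppress Hilbert end
    effects.  PLI is computed per epoch then averaged.
    """
    if epochs.band is None:
        raise ValueError("PLI requires band-passed epochs (band tag missing)")
    x = epochs.epochs
    n = x.shape[2]
    trim = int(np.floor(edge_fraction * n))
    analytic = hilbert(x, axis=2)
    phases = np.angle(analytic)
    if trim > 0:
        phases = phases[:, :, trim : n - trim]
    dphi = phases[:, :, None, :] - phases[:, None, :, :]
    pli = pli_from_phase_difference(dphi, axis=3)  # (E, C, C)
    values = pli.mean(axis=0)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(
        values=np.clip(values, 0.0, 1.0),
        method="pli",
        band=epochs.band,
        subject_id=subject_id if subject_id is not None else epochs.subject_id,
        condition=condition if condition is not None else epochs.condition,
        n_epochs_used=x.shape[0],
        channel_labels=epochs.channel_labels,
    )


def aggregate_condition(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean across subjects of one (method, band, condition)."""
    if not matrices:
        raise ValueError("nothing to aggregate")
    first = matrices[0]
    for m in matrices[1:]:
        if m.method != first.method or m.band != first.band:
            raise ValueError("cannot aggregate across methods or bands")
        if m.condition != first.condition:
            raise ValueError("cannot aggregate across conditions")
        if m.values.shape != first.values.shape:
            raise ValueError("matrix shapes differ")
    mean = np.mean([m.values for m in matrices], axis=0)
    return ConnectivityMatrix(
        values=mean,
        method=first.method,
        band=first.band,
        subject_id="group",
        condition=first.condition,
        n_epochs_used=sum(m.n_epochs_used for m in matrices),
        channel_labels=first.channel_labels,
    )
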