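"""Synthetic resting-state EEG cohorts with controllable band-wise coupling.

Paired resting-state EEG cohorts are rarely shared, so the generator
stands in for real recordings statistically: 21 subjects x 2 conditions
(pre/post) x 10 clean 2-s epochs at 200 Hz on the 19-channel 10-20 montage,
with an alpha-dominant posterior rhythm, 1/f background noise, and
band-limited inter-channel coupling with nonzero phase lags.

Signal model, per channel c and band b (all components band-limited
Gaussian noise, synthesized in the frequency domain):

    x_c = sum_b [ a_{b,c} z_{c,b}
                  + h_b  u^{A}_b e^{-i phi_c}   (c in anterior community)
                  + h_b  u^{B}_b e^{-i phi_c}   (c in posterior community)
                  + g_{b} s_b    e^{-i phi_c}   (c in coupled set) ] + 1/f noise

where z are channel-independent oscillations, u^A / u^B are two *community*
shared sources constant across conditions (they give the baseline network
its modular anterior/posterior structure), and s_b is the *bridging* shared
source over the whole fronto-centro-parietal set whose gain g rises in the
post condition (delta and gamma by default).  Because the bridge spans both
communities, raising its gain increases strength/efficiency/clustering and
*decreases* modularity in the affected bands -- the reorganization-toward-
integration pattern the pipeline is meant to detect.  Phase lags phi_c are
nonzero and channel-dependent so the phase-lag index sees the coupling.

Cognitive scores are drawn so that each subject's post-minus-pre score
change is a linear function of that subject's realized coupling-gain
increment plus Gaussian noise, enabling correlation-recovery experiments.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import (
    FRONTO_CENTRO_PARIETAL,
    POSTERIOR_CHANNELS,
    MontageSpec,
    standard_montage,
)
from .signal import BAND_NAMES

CONDITIONS = ("pre", "post")

#: Baseline community sources: anterior and posterior channel groups.
ANTERIOR_COMMUNITY: tuple[str, ...] = ("Fp1", "Fp2", "F3", "Fz", "F4", "C3", "Cz", "C4")
POSTERIOR_COMMUNITY: tuple[str, ...] = ("P3", "Pz", "P4", "T5", "T6", "O1", "O2")


def _default_amps() -> dict[str, float]:
    # a.u.; alpha dominant, gamma weakest -- a plausible resting spectrum
    return {"delta": 0.5, "theta": 0.6, "alpha": 1.0, "beta": 0.4, "gamma": 0.3}


def _default_gains_pre() -> dict[str, float]:
    return {b: 0.2 for b in BAND_NAMES}


def _default_gains_post() -> dict[str, float]:
    g = {b: 0.2 for b in BAND_NAMES}
    g["delta"] = 0.7
    g["gamma"] = 0.7
    return g


def _default_community_gains() -> dict[str, float]:
    return {b: 0.6 for b in BAND_NAMES}


def _default_score_models() -> dict[str, "ScoreModel"]:
    # baselines typical of a healthy, educated young-adult cohort;
    # Trail Making B is timed in seconds (lower = better), span tests in digits
    return {
        "trail_making_b": ScoreModel(5.80, 1.41, -0.93, -2.0, 0.45),
        "digit_span_forward": ScoreModel(8.52, 0.75, 0.43, 0.0, 0.35),
        "digit_span_backward": ScoreModel(6.24, 1.76, 1.05, 0.0, 0.80),
    }


@dataclass(frozen=True)
class ScoreModel:
    """Linear link from a subject's coupling-gain increment to a score change.

    post - pre = change_intercept + change_slope * (increment - mean increment)
                 + N(0, change_noise_sd^2)
    """

    baseline_mean: float
    baseline_sd: float
    change_intercept: float
    change_slope: float
    change_noise_sd: float

    def noise_sd_for_correlation(self, rho: float, increment_sd: float) -> float:
        """Noise level giving population correlation ``rho`` between the
        score change and the coupling increment at this slope."""
        if not 0 < abs(rho) <= 1:
            raise ValueError("rho must be in (0, 1]")
        return abs(self.change_slope) * increment_sd * np.sqrt(1.0 / rho**2 - 1.0)


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults are the emulated study conditions."""

    n_subjects: int = 21
    fs: float = 200.0
    epoch_len_s: float = 2.0
    n_epochs: int = 10
    duration_s: float = 30.0
    band_source_amps: dict[str, float] = field(default_factory=_default_amps)
    coupling_gain_pre: dict[str, float] = field(default_factory=_default_gains_pre)
    coupling_gain_post: dict[str, float] = field(default_factory=_default_gains_post)
    coupled_channel_set: tuple[str, ...] = FRONTO_CENTRO_PARIETAL
    community_gain: dict[str, float] = field(default_factory=_default_community_gains)
    anterior_community: tuple[str, ...] = ANTERIOR_COMMUNITY
    posterior_community: tuple[str, ...] = POSTERIOR_COMMUNITY
    phase_lag_rad: tuple[float, ...] | None = None  # default: index-proportional
    posterior_alpha_boost: float = 2.0
    noise_exponent: float = 1.0
    noise_amp: float = 0.5
    subject_gain_sd: float = 0.05
    score_models: dict[str, ScoreModel] = field(default_factory=_default_score_models)
    seed: int = 0

    def __post_init__(self) -> None:
        n_samp = self.fs * self.epoch_len_s
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError(
                f"fs * epoch_len_s = {n_samp} is not an integer sample count"
            )
        for gains in (self.coupling_gain_pre, self.coupling_gain_post):
            if set(gains) != set(BAND_NAMES):
                raise ValueError(f"coupling gains must cover bands {BAND_NAMES}")
            for b, g in gains.items():
                if not 0.0 <= g <= 1.0:
                    raise ValueError(f"coupling gain {b}={g} outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def null_config(self) -> "SynthConfig":
        """The no-effect configuration: post gains equal pre gains."""
        return replace(self, coupling_gain_post=dict(self.coupling_gain_pre))

    @property
    def increment_sd(self) -> float:
        """SD across subjects of the realized total coupling-gain increment
        (pre and post jitters are independent per band)."""
        return self.subject_gain_sd * np.sqrt(2 * len(BAND_NAMES))


@dataclass(frozen=True)
class EEGRecording:
    """One subject/condition multichannel time series (uV; a.u. here)."""

    subject_id: str
    condition: str
    montage: MontageSpec
    data: np.ndarray  # (19, n_samples)
    fs: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != self.montage.n_channels:
            raise ValueError(f"data must be ({self.montage.n_channels}, n_samples)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite samples in recording")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        object.__setattr__(self, "data", arr)

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject realized coupling gains (after subject-level jitter)."""

    subject_id: str
    gains_pre: dict[str, float]
    gains_post: dict[str, float]

    @property
    def increment(self) -> float:
        return float(
            sum(self.gains_post[b] - self.gains_pre[b] for b in self.gains_pre)
        )


@dataclass(frozen=True)
class SubjectRecordings:
    pre: EEGRecording
    post: EEGRecording
    params: SubjectParams

    @property
    def subject_id(self) -> str:
        return self.params.subject_id


@dataclass(frozen=True)
class Cohort:
    """Full synthetic cohort: recordings plus the cognitive score table."""

    subjects: tuple[SubjectRecordings, ...]
    scores: pd.DataFrame  # columns subject_id, test_name, pre, post
    config: SynthConfig


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode("utf8"))


def _rng_for(config_seed: int, *keys: str) -> np.random.Generator:
    entropy = [int(config_seed) & 0x7FFFFFFF] + [_stable_hash(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def default_phase_lags(n_channels: int = 19) -> np.ndarray:
    """Channel-index-proportional lags in (0.1, 1.2) rad -- nonzero so the
    phase-lag index sees the shared sources (zero-lag mixing gives PLI 0)."""
    return 0.1 + 1.1 * np.arange(n_channels) / max(n_channels - 1, 1)


def draw_subject_params(config: SynthConfig, subject_id: str) -> SubjectParams:
    """Realized per-subject gains: configured gain + N(0, subject_gain_sd),
    truncated to [0, 1]; jitter independent per band and condition."""
    rng = _rng_for(config.seed, subject_id, "gains")
    gains = {}
    for cond, base in (("pre", config.coupling_gain_pre), ("post", config.coupling_gain_post)):
        jit = rng.normal(0.0, config.subject_gain_sd, size=len(BAND_NAMES))
        gains[cond] = {
            b: float(np.clip(base[b] + jit[i], 0.0, 1.0))
            for i, b in enumerate(BAND_NAMES)
        }
    return SubjectParams(subject_id, gains["pre"], gains["post"])


def _band_bins(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (freqs >= lo) & (freqs < hi) & (freqs > 0)


def _band_noise_coeffs(
    rng: np.random.Generator, mask: np.ndarray, n: int
) -> np.ndarray:
    """Unit-variance (in time domain, expectation) band-limited Gaussian
    noise as rfft coefficients."""
    m = int(mask.sum())
    if m == 0:
        return np.zeros(mask.shape, dtype=complex)
    c = np.zeros(mask.shape, dtype=complex)
    c[mask] = rng.normal(size=m) + 1j * rng.normal(size=m)
    # irfft variance of CN(0, 2) coeffs on m interior bins is 4m/n^2
    c *= n / np.sqrt(4.0 * m)
    return c


def _pink_noise_coeffs(
    rng: np.random.Generator, freqs: np.ndarray, n: int, exponent: float, amp: float
) -> np.ndarray:
    """1/f^exponent background synthesized by spectral shaping."""
    c = np.zeros(freqs.shape, dtype=complex)
    pos = freqs > 0
    shape = freqs[pos] ** (-exponent / 2.0)
    c[pos] = (rng.normal(size=pos.sum()) + 1j * rng.normal(size=pos.sum())) * shape
    var = 4.0 * np.sum(shape**2) / n**2
    if var > 0:
        c *= amp / np.sqrt(var)
    return c


def _synthesize_recording(
    config: SynthConfig,
    subject_id: str,
    condition: str,
    gains: dict[str, float],
    montage: MontageSpec,
) -> EEGRecording:
    from .signal import BANDS  # local import to avoid cycle at module load

    n = config.n_samples
    freqs = np.fft.rfftfreq(n, 1.0 / config.fs)
    labels = montage.channel_labels
    n_ch = montage.n_channels

    lags = (
        np.asarray(config.phase_lag_rad, dtype=float)
        if config.phase_lag_rad is not None
        else default_phase_lags(n_ch)
    )
    if lags.shape != (n_ch,):
        raise ValueError("phase_lag_rad must give one lag per channel")
    phase = np.exp(-1j * lags)  # per-channel rotation of shared sources

    coupled = np.array([c in config.coupled_channel_set for c in labels])
    in_a = np.array([c in config.anterior_community for c in labels])
    in_b = np.array([c in config.posterior_community for c in labels])
    posterior = np.array([c in POSTERIOR_CHANNELS for c in labels])

    rng = _rng_for(config.seed, subject_id, condition, "signal")
    spectra = np.zeros((n_ch, freqs.size), dtype=complex)

    for band in BANDS:
        mask = _band_bins(freqs, band.lo, band.hi)
        amp = config.band_source_amps[band.name]
        # channel-independent oscillations; posterior alpha dominance
        ch_amp = np.full(n_ch, amp)
        if band.name == "alpha":
            ch_amp[posterior] *= config.posterior_alpha_boost
        for i in range(n_ch):
            spectra[i] += ch_amp[i] * _band_noise_coeffs(rng, mask, n)
        # community sources (constant across conditions) and the bridge
        h = config.community_gain[band.name]
        src_a = _band_noise_coeffs(rng, mask, n)
        src_b = _band_noise_coeffs(rng, mask, n)
        bridge = _band_noise_coeffs(rng, mask, n)
        g = gains[band.name]
        for i in range(n_ch):
            shared = np.zeros(freqs.size, dtype=complex)
            if in_a[i]:
                shared += h * src_a
            if in_b[i]:
                shared += h * src_b
            if coupled[i]:
                shared += g * bridge
            spectra[i] += shared * phase[i]

    for i in range(n_ch):
        spectra[i] += _pink_noise_coeffs(
            rng, freqs, n, config.noise_exponent, config.noise_amp
        )

    data = np.fft.irfft(spectra, n=n, axis=1)
    return EEGRecording(subject_id, condition, montage, data, config.fs)


def generate_subject(
    config: SynthConfig, subject_id: str
) -> tuple[EEGRecording, EEGRecording]:
    """Pre and post recordings for one subject (deterministic in config.seed
    and subject_id; independent components re-drawn per condition)."""
    montage = standard_montage()
    params = draw_subject_params(config, subject_id)
    pre = _synthesize_recording(config, subject_id, "pre", params.gains_pre, montage)
    post = _synthesize_recording(config, subject_id, "post", params.gains_post, montage)
    return pre, post


def subject_ids(config: SynthConfig) -> list[str]:
    width = max(2, len(str(config.n_subjects)))
    return [f"sub-{i + 1:0{width}d}" for i in range(config.n_subjects)]


def draw_cohort_scores(
    config: SynthConfig, params: list[SubjectParams]
) -> pd.DataFrame:
    """Cognitive score table tied to the realized coupling increments."""
    rows = []
    mean_inc = float(
        sum(config.coupling_gain_post[b] - config.coupling_gain_pre[b] for b in BAND_NAMES)
    )
    for p in params:
        rng = _rng_for(config.seed, p.subject_id, "scores")
        for test, m in config.score_models.items():
            pre = m.baseline_mean + m.baseline_sd * rng.normal()
            change = (
                m.change_intercept
                + m.change_slope * (p.increment - mean_inc)
                + m.change_noise_sd * rng.normal()
            )
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "test_name": test,
                    "pre": pre,
                    "post": pre + change,
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "test_name", "pre", "post"])


def generate_cohort(config: SynthConfig) -> Cohort:
    """Full cohort: n_subjects recording pairs plus the score table."""
    subjects = []
    params_list = []
    for sid in subject_ids(config):
        montage = standard_montage()
        params = draw_subject_params(config, sid)
        pre = _synthesize_recording(config, sid, "pre", params.gains_pre, montage)
        post = _synthesize_recording(config, sid, "post", params.gains_post, montage)
        subjects.append(SubjectRecordings(pre, post, params))
        params_list.append(params)
    scores = draw_cohort_scores(config, params_list)
    return Cohort(tuple(subjects), scores, config)


def draw_cohort_parameters(config: SynthConfig) -> list[SubjectParams]:
    """Subject-level gain draws without synthesizing any signal -- for
    score-model experiments where the waveforms are not needed."""
    return [draw_subject_params(config, sid) for sid in subject_ids(config)]
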