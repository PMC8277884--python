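"""Standard 19-channel 10-20 scalp montage.

The clinical 19-channel montage uses the older temporal labels T3/T4/T5/T6;
the modern equivalents T7/T8/P7/P8 are accepted on input and normalized.
Positions are schematic 2-D head-circle coordinates (unitless, nose up),
used only for layout plots -- no volume-conduction geometry is implied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical channel order for all 19x19 connectivity matrices.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Modern-name aliases accepted when reading external recordings.
CHANNEL_ALIASES: dict[str, str] = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

# Schematic (x, y) positions on a unit head circle, nose at +y.
_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.51), "Fz": (0.0, 0.50),
    "F4": (0.40, 0.51), "F8": (0.81, 0.59),
    "T3": (-1.00, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T4": (1.00, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.40, -0.51), "Pz": (0.0, -0.50),
    "P4": (0.40, -0.51), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

#: Posterior channels carrying the dominant resting alpha rhythm.
POSTERIOR_CHANNELS: tuple[str, ...] = ("T5", "P3", "Pz", "P4", "T6", "O1", "O2")

#: Fronto-centro-parietal set -- the region where the condition effect lives.
FRONTO_CENTRO_PARIETAL: tuple[str, ...] = (
    "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4",
)


def normalize_label(label: str) -> str:
    """Map a channel label to the canonical T3/T4/T5/T6 dialect."""
    clean = label.strip()
    # case-insensitive match against canonical names and aliases
    for canon in CHANNELS_1020:
        if clean.lower() == canon.lower():
            return canon
    for alias, canon in CHANNEL_ALIASES.items():
        if clean.lower() == alias.lower():
            return canon
    raise ValueError(f"unknown 10-20 channel label: {label!r}")


@dataclass(frozen=True)
class MontageSpec:
    """The electrode montage: ordered labels plus schematic 2-D positions."""

    channel_labels: tuple[str, ...] = CHANNELS_1020
    positions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_POSITIONS)
    )

    def __post_init__(self) -> None:
        if len(self.channel_labels) != 19:
            raise ValueError("montage must have exactly 19 channels")
        if len(set(self.channel_labels)) != 19:
            raise ValueError("channel labels must be unique")
        for lab in self.channel_labels:
            x, y = self.positions[lab]
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"non-finite position for {lab}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def index(self, label: str) -> int:
        return self.channel_labels.index(normalize_label(label))

    def position_array(self) -> np.ndarray:
        """(19, 2) array of positions in channel order."""
        return np.array([self.positions[c] for c in self.channel_labels])


def standard_montage() -> MontageSpec:
    """The default 19-channel 10-20 montage."""
    return MontageSpec()
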