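"""Scalp electrode montages.

The analysis operates on a fixed ordered set of electrodes with 2-D head
coordinates (orthographic projection onto the unit disc, +x toward the right
ear, +y toward the nasion).  The default montage is the 16-channel subset of
the International 10-20 System used for eyes-closed resting recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelMontage", "standard_1020_16"]

# Approximate unit-disc projections of 10-20 positions: outer ring at r≈0.9,
# parasagittal ring at r≈0.57, C3/C4 on the ear-to-ear axis.
_POS_1020: dict[str, tuple[float, float]] = {
    "Fp1": (-0.28, 0.85),
    "Fp2": (0.28, 0.85),
    "F3": (-0.38, 0.42),
    "F4": (0.38, 0.42),
    "Fz": (0.0, 0.45),
    "F7": (-0.72, 0.53),
    "F8": (0.72, 0.53),
    "C3": (-0.45, 0.0),
    "C4": (0.45, 0.0),
    "P3": (-0.38, -0.42),
    "P4": (0.38, -0.42),
    "Pz": (0.0, -0.45),
    "T5": (-0.72, -0.53),
    "T6": (0.72, -0.53),
    "O1": (-0.28, -0.85),
    "O2": (0.28, -0.85),
}

#: Channel order of the default montage.
DEFAULT_CHANNELS = (
    "Fp1", "Fp2", "F3", "F4", "Fz", "F7", "F8", "C3",
    "C4", "P3", "P4", "Pz", "T5", "T6", "O1", "O2",
)


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered electrode labels with 2-D unit-disc positions.

    Parameters
    ----------
    names
        Ordered channel labels; must be unique.
    positions
        Array of shape ``(n_channels, 2)``; column 0 is the left-right axis
        (+ right), column 1 the posterior-anterior axis (+ anterior).  Every
        position must lie inside the unit disc.
    """

    names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if pos.shape != (len(names), 2):
            raise ValueError(
                f"positions must have shape ({len(names)}, 2), got {pos.shape}"
            )
        radii = np.hypot(pos[:, 0], pos[:, 1])
        if np.any(radii > 1.0):
            bad = names[int(np.argmax(radii))]
            raise ValueError(f"channel {bad} lies outside the unit disc")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        return self.names.index(name)


def standard_1020_16() -> ChannelMontage:
    """The default 16-channel 10-20 montage (Fp1..O2, no midline Cz)."""
    pos = np.array([_POS_1020[name] for name in DEFAULT_CHANNELS])
    return ChannelMontage(names=DEFAULT_CHANNELS, positions=pos)
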