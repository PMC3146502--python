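"""Epoch preprocessing: band-pass filtering, average reference, GFP.

Global field power (GFP) is the spatial standard deviation of the
average-referenced potentials at one sample.  Topography is most reliable at
local maxima of the GFP, so only peak samples enter the clustering stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .montage import ChannelMontage

__all__ = [
    "EEGEpoch",
    "GFPSeries",
    "bandpass_filter",
    "average_reference",
    "compute_gfp",
    "find_gfp_peaks",
]


@dataclass
class EEGEpoch:
    """One artifact-free multichannel EEG segment.

    ``data`` is ``(n_channels, n_samples)`` in microvolts; channel order
    follows ``montage.names``.
    """

    data: np.ndarray = field(repr=False)
    sampling_rate: float
    montage: ChannelMontage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"{self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if self.data.shape[1] < 3:
            raise ValueError("epoch must contain at least 3 samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class GFPSeries:
    """Per-sample global field power of one epoch (microvolts, >= 0)."""

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("GFP values must be non-negative")


def bandpass_filter(
    epoch: EEGEpoch, low_hz: float = 2.0, high_hz: float = 20.0, order: int = 4
) -> EEGEpoch:
    """Zero-phase Butterworth band-pass applied channel-wise.

    A forward-backward (filtfilt) realization is used so that topography
    timing is preserved; the default 2-20 Hz band covers the rhythms that
    drive microstate alternation in eyes-closed recordings.
    """
    nyquist = epoch.sampling_rate / 2.0
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"invalid band ({low_hz}, {high_hz}) Hz for sampling rate "
            f"{epoch.sampling_rate} Hz"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=epoch.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, epoch.data, axis=1)
    return EEGEpoch(filtered, epoch.sampling_rate, epoch.montage)


def average_reference(epoch: EEGEpoch) -> EEGEpoch:
    """Re-reference so the channel mean is zero at every sample."""
    if epoch.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    data = epoch.data - epoch.data.mean(axis=0, keepdims=True)
    return EEGEpoch(data, epoch.sampling_rate, epoch.montage)


def compute_gfp(epoch: EEGEpoch) -> GFPSeries:
    """Spatial standard deviation across channels at each sample.

    The input is re-referenced internally, so the result equals the RMS of
    the average-referenced potentials whether or not the caller already
    applied :func:`average_reference`.
    """
    centered = epoch.data - epoch.data.mean(axis=0, keepdims=True)
    values = np.sqrt(np.mean(centered**2, axis=0))
    return GFPSeries(values, epoch.sampling_rate)


def find_gfp_peaks(gfp: GFPSeries) -> np.ndarray:
    """Indices of interior local maxima of the GFP curve.

    A plateau of equal maximal values contributes its center sample (the
    left-center one when the plateau length is even).  The first and last
    samples are never returned.
    """
    v = np.asarray(gfp.values, dtype=float)
    n = v.size
    if n < 3:
        raise ValueError("GFP series must have at least 3 samples")
    peaks: list[int] = []
    i = 1
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j < n - 1 and v[j + 1] < v[i]:
                peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return np.asarray(peaks, dtype=int)
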