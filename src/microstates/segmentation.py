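"""Back-fitting, run segmentation and per-subject microstate profiles.

Clustering uses only the GFP-peak maps, so continuous labelling is
reconstructed by assigning each peak to its best class and letting every
other sample inherit the label of its nearest peak.  Maximal same-class runs
are the microstates; no minimal duration is imposed and single-peak runs are
kept, as are runs truncated by the epoch edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import TemplateSet
from .preprocess import EEGEpoch, compute_gfp, find_gfp_peaks

__all__ = [
    "LabelSequence",
    "MicrostateRun",
    "MicrostateProfile",
    "backfit_labels",
    "segment_runs",
    "compute_profile",
]


@dataclass
class LabelSequence:
    """Per-sample class labels (indices into the template set) for one epoch."""

    labels: np.ndarray
    sampling_rate: float
    peak_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D sequence")

    @property
    def n_samples(self) -> int:
        return self.labels.size


@dataclass
class MicrostateRun:
    """A maximal same-class run: ``[start, end)`` in samples."""

    label: int
    start: int
    end: int
    duration_ms: float
    n_gfp_peaks: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("run must contain at least one sample")


@dataclass
class MicrostateProfile:
    """Per-class duration/occurrence/coverage summary for one subject.

    ``duration_ms[c]`` is NaN when class ``c`` produced no runs (reported as
    missing and excluded pairwise from group tests).
    """

    subject_id: str
    group: str
    duration_ms: np.ndarray  # mean run duration per class
    occurrence_per_s: np.ndarray  # runs of the class per analyzed second
    percent_total_time: np.ndarray
    total_time_s: float
    severity: int | None = None


def backfit_labels(
    epoch: EEGEpoch,
    templates: TemplateSet,
    mode: str = "nearest-peak",
) -> LabelSequence:
    """Assign a class label to every sample of an epoch.

    GFP peaks are labelled with the class of maximal squared spatial
    correlation (polarity-invariant).  In ``nearest-peak`` mode (default)
    every non-peak sample inherits the label of its nearest peak — exact
    midpoints go to the earlier peak, samples before the first / after the
    last peak take that peak's label.  In ``per-sample`` mode every sample is
    labelled by its own squared correlation with the templates.
    """
    gfp = compute_gfp(epoch)
    peaks = find_gfp_peaks(gfp)
    if peaks.size == 0:
        raise ValueError("epoch has no GFP peaks; cannot back-fit labels")

    centered = epoch.data - epoch.data.mean(axis=0, keepdims=True)
    if mode == "per-sample":
        norms = np.linalg.norm(centered, axis=0)
        norms[norms == 0] = 1.0
        corr = (centered / norms).T @ templates.maps.T
        labels = np.argmax(corr**2, axis=1)
        return LabelSequence(labels, epoch.sampling_rate, peaks)
    if mode != "nearest-peak":
        raise ValueError(f"unknown labeling mode {mode!r}")

    peak_maps = centered[:, peaks].T
    peak_maps = peak_maps / np.linalg.norm(peak_maps, axis=1, keepdims=True)
    corr = peak_maps @ templates.maps.T
    peak_labels = np.argmax(corr**2, axis=1)

    labels = np.empty(epoch.n_samples, dtype=int)
    labels[: peaks[0] + 1] = peak_labels[0]
    for i in range(len(peaks) - 1):
        p, q = peaks[i], peaks[i + 1]
        boundary = (p + q) // 2  # midpoint tie goes to the earlier peak
        labels[p: boundary + 1] = peak_labels[i]
        labels[boundary + 1: q + 1] = peak_labels[i + 1]
    labels[peaks[-1]:] = peak_labels[-1]
    return LabelSequence(labels, epoch.sampling_rate, peaks)


def segment_runs(sequence: LabelSequence) -> list[MicrostateRun]:
    """Maximal same-class runs, in temporal order.

    No merging or smoothing is applied; runs touching the epoch edges are
    kept.  ``n_gfp_peaks`` counts the peaks of ``sequence.peak_indices``
    falling inside each run (zero when the sequence carries no peak
    information, e.g. hand-constructed label arrays).
    """
    labels = sequence.labels
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    runs = []
    for s, e in zip(starts, ends):
        n_peaks = int(
            np.count_nonzero(
                (sequence.peak_indices >= s) & (sequence.peak_indices < e)
            )
        )
        runs.append(
            MicrostateRun(
                label=int(labels[s]),
                start=int(s),
                end=int(e),
                duration_ms=(e - s) * 1000.0 / sequence.sampling_rate,
                n_gfp_peaks=n_peaks,
            )
        )
    return runs


def compute_profile(
    runs_per_epoch: list[list[MicrostateRun]],
    sampling_rate: float,
    n_classes: int = 4,
    subject_id: str = "",
    group: str = "",
    severity: int | None = None,
    include_edge_runs: bool = True,
) -> MicrostateProfile:
    """Pool runs over a subject's epochs into the per-class profile.

    duration = mean run duration of the class (ms); occurrence = runs of the
    class per second of analyzed time; percent total time = share of samples
    carrying the class label.  ``include_edge_runs=False`` drops runs that
    touch an epoch boundary from the duration and occurrence statistics
    (sensitivity analysis; coverage always uses all samples).
    """
    if not runs_per_epoch or not any(runs_per_epoch):
        raise ValueError("no segmented epochs supplied")
    total_samples = sum(r.end - r.start for runs in runs_per_epoch for r in runs)
    total_time_s = total_samples / sampling_rate

    durations: list[list[float]] = [[] for _ in range(n_classes)]
    class_samples = np.zeros(n_classes)
    for runs in runs_per_epoch:
        if not runs:
            continue
        epoch_len = runs[-1].end
        for r in runs:
            if r.label >= n_classes:
                raise ValueError(f"run label {r.label} out of range")
            class_samples[r.label] += r.end - r.start
            is_edge = r.start == 0 or r.end == epoch_len
            if include_edge_runs or not is_edge:
                durations[r.label].append(r.duration_ms)

    duration_ms = np.array(
        [np.mean(d) if d else np.nan for d in durations]
    )
    occurrence = np.array([len(d) for d in durations]) / total_time_s
    coverage = 100.0 * class_samples / total_samples
    return MicrostateProfile(
        subject_id=subject_id,
        group=group,
        duration_ms=duration_ms,
        occurrence_per_s=occurrence,
        percent_total_time=coverage,
        total_time_s=total_time_s,
        severity=severity,
    )
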