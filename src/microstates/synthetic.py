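"""Synthetic resting-state EEG cohorts with planted microstate structure.

The generator emulates a two-group eyes-closed resting study: each subject
contributes a set of 2.56 s, 512-sample, 16-channel epochs in which four
prototype topographies alternate every ~50-120 ms.  Within a state the
topography is fixed while its polarity oscillates with a sinusoidal carrier
(alpha-band by default), which is the signature that makes polarity-invariant
clustering necessary.  Group differences are planted through class-specific
mean state durations.

Prototype geometry (classic eyes-closed map classes):

* **A** - diagonal field axis, right-anterior to left-posterior
* **B** - diagonal field axis, left-anterior to right-posterior
* **C** - symmetric anterior-posterior field axis
* **D** - fronto-central extreme (radial blob)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr, ndtri

from .clustering import TemplateSet
from .montage import ChannelMontage, standard_1020_16
from .preprocess import EEGEpoch

__all__ = [
    "SynthConfig",
    "SubjectRecord",
    "make_prototype_maps",
    "sample_state_sequence",
    "render_epoch",
    "generate_cohort",
    "GROUPS",
    "CLASS_LETTERS",
]

GROUPS = ("patient", "control")
CLASS_LETTERS = ("A", "B", "C", "D")

# Planted group x class mean run durations (ms) and run-to-run SDs (ms),
# patient row first.  These magnitudes reproduce a realistic class-specific
# group effect: class A runs longer in patients, other classes comparable.
DEFAULT_MEAN_DURATION_MS = {
    "patient": (63.81, 58.47, 64.21, 83.40),
    "control": (54.55, 61.03, 66.63, 74.14),
}
DEFAULT_SD_DURATION_MS = {
    "patient": (14.71, 10.47, 18.92, 25.34),
    "control": (10.14, 13.75, 18.17, 17.62),
}


def _uniform_offdiag(k: int) -> np.ndarray:
    m = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(m, 0.0)
    return m


@dataclass
class SynthConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated design: 18 subjects per group, 18-61
    epochs each, 200 Hz sampling, 512-sample epochs, four classes whose mean
    durations fall in the 50-120 ms microstate range, a 10 Hz carrier
    (eyes-closed alpha dominance; two GFP peaks per cycle, i.e. one every
    ~50 ms) and a signal-to-noise ratio of 2 (moderate-quality scalp EEG).
    """

    n_subjects_per_group: int = 18
    epochs_per_subject: tuple[int, int] = (18, 61)  # inclusive uniform range
    sampling_rate: float = 200.0
    epoch_samples: int = 512
    class_mean_duration_ms: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_DURATION_MS)
    )
    class_duration_sd_ms: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SD_DURATION_MS)
    )
    oscillation_freq_hz: float = 10.0
    snr: float = 2.0
    base_amplitude_uv: float = 10.0
    transition_matrix: np.ndarray | None = None
    severity_duration_slope_ms: float = 0.0  # optional planted severity effect (class A)
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(next(iter(self.class_mean_duration_ms.values())))

    def validate(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        lo, hi = self.epochs_per_subject
        if not (1 <= lo <= hi):
            raise ValueError("invalid epochs_per_subject range")
        if self.sampling_rate <= 0 or self.epoch_samples < 3:
            raise ValueError("invalid epoch geometry")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        for g in GROUPS:
            means = np.asarray(self.class_mean_duration_ms[g])
            sds = np.asarray(self.class_duration_sd_ms[g])
            if np.any(means <= 0) or np.any(sds < 0):
                raise ValueError("durations must be positive, SDs non-negative")
        if self.transition_matrix is not None:
            m = np.asarray(self.transition_matrix, dtype=float)
            k = self.n_classes
            if m.shape != (k, k):
                raise ValueError("transition matrix shape mismatch")
            if np.any(np.diagonal(m) != 0):
                raise ValueError("transition matrix diagonal must be zero")
            if not np.allclose(m.sum(axis=1), 1.0):
                raise ValueError("transition matrix rows must sum to 1")

    def transitions(self) -> np.ndarray:
        if self.transition_matrix is not None:
            return np.asarray(self.transition_matrix, dtype=float)
        return _uniform_offdiag(self.n_classes)


@dataclass
class SubjectRecord:
    """One synthetic subject: metadata, epochs and generating ground truth."""

    subject_id: str
    group: str
    severity: int | None  # ordinal 1-4; None for controls
    epochs: list[EEGEpoch]
    true_sequences: list[list[tuple[int, float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if (self.severity is not None) != (self.group == "patient"):
            raise ValueError("severity is present iff the subject is a patient")
        if not self.epochs:
            raise ValueError("a subject needs at least one epoch")


def make_prototype_maps(
    montage: ChannelMontage | None = None,
    k: int = 4,
) -> TemplateSet:
    """Four average-referenced, unit-norm prototype topographies.

    Classes A and B are smooth gradients along diagonal axes tilted 30
    degrees off the left-right axis (right-anterior/left-posterior and
    left-anterior/right-posterior), class C a pure anterior-posterior
    gradient, and class D a fronto-central Gaussian extreme.  The tilt keeps
    all pairwise absolute spatial correlations below 0.7 on the default
    montage (quasi-orthogonality) while preserving the canonical appearance.
    """
    if k != 4:
        raise ValueError(
            "only k=4 prototype maps are supported; supply custom templates "
            "for other class counts"
        )
    if montage is None:
        montage = standard_1020_16()
    x = montage.positions[:, 0]
    y = montage.positions[:, 1]
    theta = np.deg2rad(30.0)
    map_a = np.cos(theta) * x + np.sin(theta) * y
    map_b = -np.cos(theta) * x + np.sin(theta) * y
    map_c = y
    r2 = x**2 + (y - 0.25) ** 2
    map_d = np.exp(-r2 / (2 * 0.35**2))
    maps = np.vstack([map_a, map_b, map_c, map_d])
    return TemplateSet(maps, channel_names=montage.names)


def _truncnorm_draw(
    mean: float, sd: float, lower: float, rng: np.random.Generator
) -> float:
    """One draw from N(mean, sd) truncated below at ``lower``."""
    if sd == 0.0:
        return max(mean, lower)
    a = ndtr((lower - mean) / sd)
    u = rng.random()
    return mean + sd * float(ndtri(a + u * (1.0 - a)))


def sample_state_sequence(
    config: SynthConfig,
    group: str,
    rng: np.random.Generator,
    subject_mean_shift_ms: np.ndarray | None = None,
) -> list[tuple[int, float]]:
    """Sample ``(class_index, duration_ms)`` states that exactly fill an epoch.

    Durations are truncated-normal with the configured group x class mean
    and SD, truncated below at two sampling intervals; successive classes
    always differ (first-order chain with the configured transition matrix).
    The last state is truncated so the total equals the epoch length.

    ``subject_mean_shift_ms`` optionally shifts the per-class means (used to
    plant subject-level heterogeneity or severity effects).
    """
    config.validate()
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    means = np.asarray(config.class_mean_duration_ms[group], dtype=float)
    if subject_mean_shift_ms is not None:
        means = means + np.asarray(subject_mean_shift_ms, dtype=float)
    sds = np.asarray(config.class_duration_sd_ms[group], dtype=float)
    lower = 2.0 * 1000.0 / config.sampling_rate
    trans_cum = np.cumsum(config.transitions(), axis=1)
    epoch_ms = config.epoch_samples * 1000.0 / config.sampling_rate

    k = config.n_classes
    state = int(rng.integers(k))
    total = 0.0
    seq: list[tuple[int, float]] = []
    while total < epoch_ms:
        dur = _truncnorm_draw(means[state], sds[state], lower, rng)
        if total + dur > epoch_ms:
            dur = epoch_ms - total
        seq.append((state, dur))
        total += dur
        state = int(np.searchsorted(trans_cum[state], rng.random(), side="right"))
    return seq


def _sequence_to_sample_counts(
    seq: list[tuple[int, float]], config: SynthConfig
) -> list[tuple[int, int]]:
    """Convert a (class, ms) sequence to per-state sample counts summing to
    ``epoch_samples`` (cumulative rounding so no drift accumulates)."""
    counts: list[tuple[int, int]] = []
    ms_per_sample = 1000.0 / config.sampling_rate
    cum_ms = 0.0
    prev_edge = 0
    for cls, dur in seq:
        cum_ms += dur
        edge = min(int(round(cum_ms / ms_per_sample)), config.epoch_samples)
        if edge > prev_edge:
            counts.append((cls, edge - prev_edge))
            prev_edge = edge
    if prev_edge < config.epoch_samples:
        counts.append((seq[-1][0], config.epoch_samples - prev_edge))
    return counts


def render_epoch(
    seq: list[tuple[int, float]],
    templates: TemplateSet,
    config: SynthConfig,
    rng: np.random.Generator,
) -> EEGEpoch:
    """Render a state sequence into a multichannel epoch.

    Within each state interval the signal is ``template * a sin(2 pi f t +
    phi)`` with amplitude and phase redrawn at every state boundary, so the
    topography is constant while its polarity oscillates.  Spatially and
    temporally white Gaussian noise is added at the configured RMS
    signal-to-noise ratio, and the result is average-referenced.
    """
    montage = standard_1020_16()
    n_ch = templates.n_channels
    n = config.epoch_samples
    t = np.arange(n) / config.sampling_rate
    omega = 2 * np.pi * config.oscillation_freq_hz

    data = np.zeros((n_ch, n))
    start = 0
    for cls, count in _sequence_to_sample_counts(seq, config):
        stop = start + count
        amp = config.base_amplitude_uv * rng.uniform(0.5, 1.5)
        phase = rng.uniform(0.0, 2 * np.pi)
        carrier = amp * np.sin(omega * t[start:stop] + phase)
        data[:, start:stop] = np.outer(templates.maps[cls], carrier)
        start = stop

    if np.isfinite(config.snr):
        signal_rms = np.sqrt(np.mean(data**2))
        noise = rng.standard_normal(data.shape)
        noise *= (signal_rms / config.snr) / np.sqrt(np.mean(noise**2))
        data = data + noise
    data -= data.mean(axis=0, keepdims=True)
    return EEGEpoch(data, config.sampling_rate, montage)


def true_label_sequence(seq: list[tuple[int, float]], config: SynthConfig):
    """Ground-truth per-sample labels of a sampled state sequence.

    Uses the same cumulative rounding as :func:`render_epoch`, so the
    returned labels are exactly the classes that generated each sample.
    """
    from .segmentation import LabelSequence

    labels = np.empty(config.epoch_samples, dtype=int)
    start = 0
    for cls, count in _sequence_to_sample_counts(seq, config):
        labels[start:start + count] = cls
        start += count
    return LabelSequence(labels, config.sampling_rate)


def generate_cohort(config: SynthConfig) -> list[SubjectRecord]:
    """Generate the full two-group cohort, reproducibly from ``config.seed``.

    Patients receive severities drawn uniformly from {1, 2, 3, 4}; by
    default severity is independent of the planted effects.  Setting
    ``severity_duration_slope_ms`` adds ``slope * (severity - 2.5)`` ms to
    the class A mean duration of each patient, planting a monotone
    severity-duration association for power checks of the rank-correlation
    stage.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    templates = make_prototype_maps(standard_1020_16(), k=4)
    lo, hi = config.epochs_per_subject

    cohort: list[SubjectRecord] = []
    for group in GROUPS:
        prefix = "P" if group == "patient" else "C"
        for i in range(config.n_subjects_per_group):
            severity = int(rng.integers(1, 5)) if group == "patient" else None
            shift = None
            if severity is not None and config.severity_duration_slope_ms != 0.0:
                shift = np.zeros(config.n_classes)
                shift[0] = config.severity_duration_slope_ms * (severity - 2.5)
            n_epochs = int(rng.integers(lo, hi + 1))
            epochs: list[EEGEpoch] = []
            sequences: list[list[tuple[int, float]]] = []
            for _ in range(n_epochs):
                seq = sample_state_sequence(config, group, rng, shift)
                epochs.append(render_epoch(seq, templates, config, rng))
                sequences.append(seq)
            cohort.append(
                SubjectRecord(
                    subject_id=f"{prefix}{i + 1:02d}",
                    group=group,
                    severity=severity,
                    epochs=epochs,
                    true_sequences=sequences,
                )
            )
    return cohort


def simulate_sequence_profiles(config: SynthConfig, seed: int | None = None):
    """Ground-truth microstate profiles of a cohort, without rendering EEG.

    Samples each subject's state sequences, converts them to per-sample
    label sequences and summarizes them with the same run-segmentation and
    profile code used on real data.  Because the clustering and back-fitting
    stages are bypassed, this isolates the statistical properties of the
    planted design and runs orders of magnitude faster than the full
    pipeline — the tool of choice for power studies of the group tests.
    """
    from .segmentation import compute_profile, segment_runs

    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.epochs_per_subject
    profiles = []
    for group in GROUPS:
        prefix = "P" if group == "patient" else "C"
        for i in range(config.n_subjects_per_group):
            severity = int(rng.integers(1, 5)) if group == "patient" else None
            shift = None
            if severity is not None and config.severity_duration_slope_ms != 0.0:
                shift = np.zeros(config.n_classes)
                shift[0] = config.severity_duration_slope_ms * (severity - 2.5)
            n_epochs = int(rng.integers(lo, hi + 1))
            runs_per_epoch = []
            for _ in range(n_epochs):
                seq = sample_state_sequence(config, group, rng, shift)
                runs_per_epoch.append(
                    segment_runs(true_label_sequence(seq, config))
                )
            profiles.append(
                compute_profile(
                    runs_per_epoch,
                    sampling_rate=config.sampling_rate,
                    n_classes=config.n_classes,
                    subject_id=f"{prefix}{i + 1:02d}",
                    group=group,
                    severity=severity,
                )
            )
    return profiles


def null_config(**overrides) -> SynthConfig:
    """A configuration with no planted group differences (both groups use the
    control means/SDs); keyword overrides are applied on top."""
    cfg = SynthConfig(
        class_mean_duration_ms={
            "patient": DEFAULT_MEAN_DURATION_MS["control"],
            "control": DEFAULT_MEAN_DURATION_MS["control"],
        },
        class_duration_sd_ms={
            "patient": DEFAULT_SD_DURATION_MS["control"],
            "control": DEFAULT_SD_DURATION_MS["control"],
        },
    )
    return replace(cfg, **overrides)
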