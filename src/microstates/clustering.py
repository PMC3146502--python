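"""Polarity-invariant modified K-means clustering of GFP-peak topographies.

A scalp map and its negation describe the same generator configuration during
an oscillation, so cluster membership is decided by *squared* spatial
correlation and cluster centroids are computed as the dominant eigenvector of
the members' outer-product scatter rather than the arithmetic mean (which
polarity-inverted members would cancel).

The quality functional is the global explained variance (GEV): the
GFP-weighted fraction of topographic variance at the peak samples that the
template assignment accounts for.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .preprocess import EEGEpoch, compute_gfp, find_gfp_peaks

__all__ = [
    "TemplateSet",
    "PeakMapCollection",
    "extract_peak_maps",
    "spatial_correlation",
    "modified_kmeans",
    "compute_gev",
]


@dataclass
class TemplateSet:
    """``k`` unit-norm, average-referenced class topographies.

    The polarity of each map is arbitrary: flipping the sign of any map
    leaves every quantity derived from the set unchanged.
    """

    maps: np.ndarray = field(repr=False)  # (k, n_channels)
    gev: float | None = None
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        norms = np.linalg.norm(self.maps, axis=1)
        if np.any(norms == 0):
            raise ValueError("template maps must be non-zero")
        # enforce average reference + unit norm
        self.maps = self.maps - self.maps.mean(axis=1, keepdims=True)
        self.maps = self.maps / np.linalg.norm(self.maps, axis=1, keepdims=True)
        if self.gev is not None and not (-1e-12 <= self.gev <= 1 + 1e-12):
            raise ValueError("gev must lie in [0, 1]")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class PeakMapCollection:
    """Topographies observed at GFP peaks, with provenance.

    ``maps`` is ``(n_maps, n_channels)`` (average-referenced, original
    amplitude), ``gfp_values`` the GFP at each peak, and ``sources`` a list of
    ``(epoch_index, sample_index)`` pairs.
    """

    maps: np.ndarray = field(repr=False)
    gfp_values: np.ndarray
    sources: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        self.gfp_values = np.asarray(self.gfp_values, dtype=float)
        if not (len(self.maps) == len(self.gfp_values) == len(self.sources)):
            raise ValueError("maps, gfp_values and sources length mismatch")
        if np.any(self.gfp_values <= 0):
            raise ValueError("GFP at a peak must be positive")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    def normalized_maps(self) -> np.ndarray:
        """Average-referenced unit-norm copies of the peak maps."""
        centered = self.maps - self.maps.mean(axis=1, keepdims=True)
        return centered / np.linalg.norm(centered, axis=1, keepdims=True)


def extract_peak_maps(epochs: list[EEGEpoch]) -> PeakMapCollection:
    """Concatenate the topographies at all GFP peaks of a subject's epochs."""
    maps: list[np.ndarray] = []
    gfps: list[float] = []
    sources: list[tuple[int, int]] = []
    for e_idx, epoch in enumerate(epochs):
        gfp = compute_gfp(epoch)
        for s_idx in find_gfp_peaks(gfp):
            if gfp.values[s_idx] <= 0:
                continue
            centered = epoch.data[:, s_idx] - epoch.data[:, s_idx].mean()
            maps.append(centered)
            gfps.append(float(gfp.values[s_idx]))
            sources.append((e_idx, int(s_idx)))
    if not maps:
        raise ValueError("no GFP peaks found in the supplied epochs")
    return PeakMapCollection(np.array(maps), np.array(gfps), sources)


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two topographies across channels.

    Polarity-invariant similarity is obtained by squaring or taking the
    absolute value of this quantity.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("topographies must share the montage")
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0 or nb == 0:
        raise ValueError("correlation undefined for a zero-variance map")
    return float(np.clip(ac @ bc / (na * nb), -1.0, 1.0))


def compute_gev(
    peaks: PeakMapCollection, templates: TemplateSet, labels: np.ndarray
) -> float:
    """Global explained variance of a labelling.

    ``GEV = sum_m (GFP_m * corr(map_m, template_{label_m}))^2 / sum_m GFP_m^2``
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (peaks.n_maps,):
        raise ValueError("one label per peak map required")
    if labels.min() < 0 or labels.max() >= templates.k:
        raise ValueError("label out of range")
    corr = np.einsum(
        "mc,mc->m", peaks.normalized_maps(), templates.maps[labels]
    )
    g = peaks.gfp_values
    return float(np.sum((g * corr) ** 2) / np.sum(g**2))


def _dominant_eigvec(scatter: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(scatter)
    v = vecs[:, -1]
    return v / np.linalg.norm(v)


def _update_templates(
    V: np.ndarray,
    labels: np.ndarray,
    k: int,
    templates: np.ndarray,
    weights: np.ndarray | None,
) -> np.ndarray:
    """Eigenvector centroid per cluster; empty clusters keep their map."""
    out = templates.copy()
    for c in range(k):
        members = V[labels == c]
        if members.size == 0:
            continue
        if weights is not None:
            w = weights[labels == c][:, None]
            scatter = (members * w).T @ (members * w)
        else:
            scatter = members.T @ members
        out[c] = _dominant_eigvec(scatter)
    # re-center (eigenvector of centered maps is centered up to round-off)
    out = out - out.mean(axis=1, keepdims=True)
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def modified_kmeans(
    peaks: PeakMapCollection,
    k: int = 4,
    n_restarts: int = 20,
    seed: int | np.random.Generator | None = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    gfp_weighted_update: bool = False,
    return_history: bool = False,
) -> tuple[TemplateSet, np.ndarray] | tuple[TemplateSet, np.ndarray, list[float]]:
    """Cluster peak topographies into ``k`` polarity-free classes.

    Each restart initializes the templates from ``k`` distinct data maps
    and alternates (i) assignment by maximal squared spatial correlation and
    (ii) template re-estimation as the dominant eigenvector of the assigned
    maps' scatter, until the labelling is stable or the relative GEV
    improvement falls below ``tol``.  The restart with the highest GEV wins.
    When the instance is small enough that there are no more distinct
    ``k``-subsets of data maps than restarts, all of them are tried
    (deterministic, exhaustive over the initialization family); otherwise
    initializations are drawn at random.

    Parameters
    ----------
    gfp_weighted_update
        If True, weight each map's contribution to the scatter by its GFP,
        making the template update an exact ascent step on GEV.  The default
        treats all peak maps equally.

    Returns
    -------
    (TemplateSet, labels) and, if ``return_history``, the best restart's GEV
    trajectory (non-decreasing).
    """
    if peaks.n_maps < k:
        raise ValueError(f"need at least k={k} maps, got {peaks.n_maps}")
    rng = np.random.default_rng(seed)
    V = peaks.normalized_maps()
    weights = peaks.gfp_values if gfp_weighted_update else None

    # when there are no more distinct k-subsets of data maps than restarts,
    # enumerate them all instead of sampling (small instances become exact)
    n_subsets = math.comb(peaks.n_maps, k)
    if n_subsets <= max(1, n_restarts):
        inits: list[np.ndarray] = [
            np.asarray(c) for c in itertools.combinations(range(peaks.n_maps), k)
        ]
    else:
        inits = [
            rng.choice(peaks.n_maps, size=k, replace=False)
            for _ in range(max(1, n_restarts))
        ]

    best_gev = -np.inf
    best_templates: np.ndarray | None = None
    best_labels: np.ndarray | None = None
    best_history: list[float] = []

    for idx in inits:
        work = V[idx].copy()  # current working templates
        prev_labels: np.ndarray | None = None
        # best iterate of this restart (returned state; keeps history monotone)
        templates = work.copy()
        labels = np.zeros(peaks.n_maps, dtype=int)
        gev = -np.inf
        history: list[float] = []
        for _ in range(max_iter):
            corr = V @ work.T
            new_labels = np.argmax(corr**2, axis=1)
            # re-seed empty clusters with the worst-explained map
            fit = corr[np.arange(peaks.n_maps), new_labels] ** 2
            for c in range(k):
                if not np.any(new_labels == c):
                    worst = int(np.argmin(fit))
                    work[c] = V[worst]
                    new_labels[worst] = c
                    fit[worst] = 1.0
            stable = prev_labels is not None and np.array_equal(
                new_labels, prev_labels
            )
            new_templates = _update_templates(V, new_labels, k, work, weights)
            new_gev = compute_gev(
                peaks, TemplateSet(new_templates.copy()), new_labels
            )
            improved = new_gev > gev
            if improved:
                templates, labels = new_templates, new_labels
                rel_gain = (new_gev - gev) / gev if gev > 0 else np.inf
                gev = new_gev
                history.append(gev)
            else:
                rel_gain = 0.0
            work = new_templates
            prev_labels = new_labels
            if stable or rel_gain < tol:
                break
        if gev > best_gev:
            best_gev = gev
            best_templates = templates
            best_labels = labels
            best_history = history

    assert best_templates is not None and best_labels is not None
    result = TemplateSet(best_templates, gev=best_gev)
    if return_history:
        return result, best_labels, best_history
    return result, best_labels
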