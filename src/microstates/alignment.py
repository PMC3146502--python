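"""Cross-subject template alignment and canonical class lettering.

Per-subject clustering returns four maps in arbitrary order and with
arbitrary polarity.  Before group statistics the maps must be matched across
subjects: a permutation algorithm reorders each subject's templates so that
the common variance over subjects is maximal, and the class-mean maps are
then labelled A-D by matching against canonical prototypes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .clustering import TemplateSet, spatial_correlation

__all__ = ["AlignedTemplates", "align_subject_templates", "assign_class_letters"]


@dataclass
class AlignedTemplates:
    """Result of the cross-subject permutation alignment."""

    permutations: list[tuple[int, ...]]  # subject template index per class slot
    mean_maps: TemplateSet
    objective: float  # mean over subjects x classes of squared correlation
    objective_history: list[float] = field(default_factory=list)

    def reordered(self, subject_templates: list[TemplateSet]) -> list[TemplateSet]:
        """Each subject's templates permuted into the common class order."""
        out = []
        for perm, ts in zip(self.permutations, subject_templates):
            out.append(TemplateSet(ts.maps[list(perm)], gev=ts.gev,
                                   channel_names=ts.channel_names))
        return out


def _fix_sign(m: np.ndarray) -> np.ndarray:
    """Convention: the largest-magnitude channel is positive."""
    if m[np.argmax(np.abs(m))] < 0:
        return -m
    return m


def _mean_maps(
    maps_by_subject: np.ndarray, perms: list[tuple[int, ...]]
) -> np.ndarray:
    """Class-mean maps as dominant eigenvectors of the per-class scatter.

    The outer-product scatter is polarity-blind, so no explicit sign
    alignment is needed; the overall sign of each mean is fixed by the
    largest-magnitude-channel convention.
    """
    n_subj, k, n_ch = maps_by_subject.shape
    means = np.empty((k, n_ch))
    for c in range(k):
        stack = np.array(
            [maps_by_subject[s, perms[s][c]] for s in range(n_subj)]
        )
        scatter = stack.T @ stack
        vals, vecs = np.linalg.eigh(scatter)
        means[c] = _fix_sign(vecs[:, -1] / np.linalg.norm(vecs[:, -1]))
    return means


def _objective(
    maps_by_subject: np.ndarray, perms: list[tuple[int, ...]], means: np.ndarray
) -> float:
    n_subj, k, _ = maps_by_subject.shape
    total = 0.0
    for s in range(n_subj):
        for c in range(k):
            total += spatial_correlation(maps_by_subject[s, perms[s][c]], means[c]) ** 2
    return total / (n_subj * k)


def align_subject_templates(
    subject_templates: list[TemplateSet], max_iter: int = 100
) -> AlignedTemplates:
    """Align each subject's ``k`` templates to common classes.

    Starting from the first subject's maps as provisional class means, the
    algorithm alternates (a) choosing for every subject, among all ``k!``
    permutations, the one maximizing the summed squared spatial correlation
    with the current means, and (b) recomputing each class mean as the
    dominant eigenvector of that class's across-subject scatter.  The
    objective (mean squared correlation) is non-decreasing and the procedure
    stops when no permutation changes.

    Subjects must be passed in a deterministic order (the pipeline sorts by
    subject id); the first subject seeds the class order.
    """
    if not subject_templates:
        raise ValueError("no subjects to align")
    k = subject_templates[0].k
    n_ch = subject_templates[0].n_channels
    for ts in subject_templates:
        if ts.k != k or ts.n_channels != n_ch:
            raise ValueError("all subjects must share k and the montage")

    maps = np.array([ts.maps for ts in subject_templates])  # (S, k, n_ch)
    n_subj = maps.shape[0]
    all_perms = list(itertools.permutations(range(k)))

    perms: list[tuple[int, ...]] = [tuple(range(k))] * n_subj
    means = maps[0].copy()
    history: list[float] = []
    for _ in range(max_iter):
        # (a) best permutation per subject given current means
        corr2 = np.einsum("skc,jc->skj", maps, means) ** 2  # (S, k, k)
        new_perms: list[tuple[int, ...]] = []
        for s in range(n_subj):
            scores = [sum(corr2[s, p[c], c] for c in range(k)) for p in all_perms]
            new_perms.append(all_perms[int(np.argmax(scores))])
        # (b) recompute class means
        means = _mean_maps(maps, new_perms)
        history.append(_objective(maps, new_perms, means))
        if new_perms == perms:
            break
        perms = new_perms

    return AlignedTemplates(
        permutations=perms,
        mean_maps=TemplateSet(means, channel_names=subject_templates[0].channel_names),
        objective=history[-1],
        objective_history=history,
    )


def assign_class_letters(
    mean_maps: TemplateSet,
    canonical: TemplateSet,
    letters: tuple[str, ...] = ("A", "B", "C", "D"),
) -> tuple[dict[int, str], dict[int, float]]:
    """Label class indices with canonical letters.

    Solves the ``k x k`` assignment maximizing the total squared spatial
    correlation between the mean maps and the canonical prototypes.  Returns
    the index-to-letter mapping and the absolute correlation of each match.
    """
    if mean_maps.n_channels != canonical.n_channels:
        raise ValueError("mean maps and canonical maps must share the montage")
    k = mean_maps.k
    if canonical.k < k or len(letters) < canonical.k:
        raise ValueError("need at least as many canonical maps/letters as classes")
    corr = mean_maps.maps @ canonical.maps.T
    rows, cols = linear_sum_assignment(-(corr**2))
    mapping = {int(r): letters[int(c)] for r, c in zip(rows, cols)}
    scores = {int(r): float(abs(corr[r, c])) for r, c in zip(rows, cols)}
    return mapping, scores
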