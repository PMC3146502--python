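"""End-to-end pipeline: preprocess -> cluster -> align -> segment -> stats.

All stage outputs are plain TSV/JSON files; every report records the package
version, a hash of the configuration and the seed, so a rerun with the same
configuration is identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import AlignedTemplates, align_subject_templates, assign_class_letters
from .clustering import TemplateSet, extract_peak_maps, modified_kmeans
from .io import read_cohort, write_templates
from .montage import standard_1020_16
from .preprocess import average_reference, bandpass_filter
from .segmentation import (
    MicrostateProfile,
    backfit_labels,
    compute_profile,
    segment_runs,
)
from .stats import (
    mixed_anova,
    posthoc_ttests,
    profiles_to_frame,
    spearman_severity,
    syntax_ttests,
)
from .syntax import transition_stats
from .synthetic import CLASS_LETTERS, SubjectRecord, make_prototype_maps

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "analyze_cohort"]


@dataclass
class PipelineConfig:
    """Parameters of the full analysis run."""

    manifest: str | None = None  # input cohort manifest (TSV)
    out_dir: str | None = None
    band_low_hz: float = 2.0
    band_high_hz: float = 20.0
    k: int = 4
    n_restarts: int = 20
    seed: int = 0
    labeling_mode: str = "nearest-peak"  # or "per-sample"
    include_edge_runs: bool = True
    canonical_map_file: str | None = None  # defaults to built-in prototypes
    pooled_clustering: bool = False  # cluster all subjects' peaks together

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValueError("invalid filter band")
        if self.labeling_mode not in ("nearest-peak", "per-sample"):
            raise ValueError(f"unknown labeling mode {self.labeling_mode!r}")

    def config_hash(self) -> str:
        fields = dataclasses.asdict(self)
        fields.pop("out_dir", None)  # analysis identity, not output location
        payload = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory bundle of every pipeline stage output."""

    subject_templates: dict[str, TemplateSet]
    aligned: AlignedTemplates
    letter_map: dict[int, str]
    letter_scores: dict[int, float]
    profiles: list[MicrostateProfile]
    syntax: dict[str, object]  # subject_id -> TransitionStats
    anova: dict[str, list]
    posthoc: dict[str, dict]
    syntax_tests: pd.DataFrame
    severity: dict[str, dict]
    log: dict = field(default_factory=dict)


def _preprocess_subject(sub: SubjectRecord, config: PipelineConfig):
    return [
        average_reference(bandpass_filter(e, config.band_low_hz, config.band_high_hz))
        for e in sub.epochs
    ]


def analyze_cohort(
    cohort: list[SubjectRecord], config: PipelineConfig | None = None
) -> PipelineResult:
    """Run the full analysis on an in-memory cohort.

    Stages: band-pass + average reference per epoch; per-subject
    polarity-invariant clustering of GFP-peak maps (pooled clustering
    optionally); cross-subject permutation alignment; canonical A-D
    lettering; back-fitting and segmentation; per-subject profiles and
    transition syntax; split-plot ANOVA, post-hoc t-tests, severity
    correlations and per-transition t-tests.
    """
    config = config or PipelineConfig()
    config.validate()
    cohort = sorted(cohort, key=lambda s: s.subject_id)

    clean = {s.subject_id: _preprocess_subject(s, config) for s in cohort}

    # per-subject clustering (deterministic per-subject seeds)
    subject_templates: dict[str, TemplateSet] = {}
    peak_counts: dict[str, int] = {}
    if config.pooled_clustering:
        all_epochs = [e for s in cohort for e in clean[s.subject_id]]
        peaks = extract_peak_maps(all_epochs)
        pooled, _ = modified_kmeans(
            peaks, config.k, config.n_restarts, seed=config.seed
        )
        for sub in cohort:
            subject_templates[sub.subject_id] = pooled
            peak_counts[sub.subject_id] = peaks.n_maps
    else:
        for i, sub in enumerate(cohort):
            peaks = extract_peak_maps(clean[sub.subject_id])
            templates, _ = modified_kmeans(
                peaks, config.k, config.n_restarts, seed=config.seed + i
            )
            subject_templates[sub.subject_id] = templates
            peak_counts[sub.subject_id] = peaks.n_maps

    aligned = align_subject_templates(
        [subject_templates[s.subject_id] for s in cohort]
    )
    if config.canonical_map_file:
        from .io import read_templates

        canonical = read_templates(config.canonical_map_file)
    else:
        canonical = make_prototype_maps(standard_1020_16(), k=4)
    letter_map, letter_scores = assign_class_letters(aligned.mean_maps, canonical)
    # class order A..D for downstream profiles
    order = sorted(letter_map, key=lambda idx: letter_map[idx])

    reordered = aligned.reordered(
        [subject_templates[s.subject_id] for s in cohort]
    )
    profiles: list[MicrostateProfile] = []
    syntax: dict[str, object] = {}
    for sub, ts in zip(cohort, reordered):
        lettered = TemplateSet(ts.maps[order], gev=ts.gev,
                               channel_names=ts.channel_names)
        runs_per_epoch = [
            segment_runs(backfit_labels(e, lettered, mode=config.labeling_mode))
            for e in clean[sub.subject_id]
        ]
        profiles.append(
            compute_profile(
                runs_per_epoch,
                sampling_rate=sub.epochs[0].sampling_rate,
                n_classes=config.k,
                subject_id=sub.subject_id,
                group=sub.group,
                severity=sub.severity,
                include_edge_runs=config.include_edge_runs,
            )
        )
        syntax[sub.subject_id] = transition_stats(runs_per_epoch)

    anova = {}
    posthoc = {}
    severity = {}
    has_two_groups = len({s.group for s in cohort}) == 2
    if has_two_groups:
        for measure in ("duration", "occurrence", "coverage"):
            anova[measure] = mixed_anova(profiles, measure)
            posthoc[measure] = posthoc_ttests(profiles, measure)
    if any(s.severity is not None for s in cohort):
        for measure in ("duration", "occurrence", "coverage"):
            severity[measure] = {}
            for letter in CLASS_LETTERS:
                try:
                    severity[measure][letter] = spearman_severity(
                        profiles, measure, letter
                    )
                except ValueError:
                    severity[measure][letter] = None
    syntax_table = (
        syntax_ttests(syntax, {s.subject_id: s.group for s in cohort})
        if has_two_groups
        else pd.DataFrame()
    )

    log = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": len(cohort),
        "peak_counts": peak_counts,
        "subject_gev": {
            sid: ts.gev for sid, ts in subject_templates.items()
        },
        "alignment_objective": aligned.objective,
        "letter_map": {str(k): v for k, v in letter_map.items()},
    }
    return PipelineResult(
        subject_templates=subject_templates,
        aligned=aligned,
        letter_map=letter_map,
        letter_scores=letter_scores,
        profiles=profiles,
        syntax=syntax,
        anova=anova,
        posthoc=posthoc,
        syntax_tests=syntax_table,
        severity=severity,
        log=log,
    )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_report(result: PipelineResult, out_dir: str | Path) -> None:
    """Write the TSV/JSON report bundle of a pipeline run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_templates(result.aligned.mean_maps, out / "mean_maps.tsv",
                    meta={"objective": result.aligned.objective})
    profiles_to_frame(result.profiles).to_csv(
        out / "profiles.tsv", sep="\t", index=False, float_format="%.6f"
    )

    syntax_rows = []
    for sid, ts in result.syntax.items():
        for kind in ("doublet", "triplet"):
            fractions = getattr(ts, f"{kind}_fractions")
            counts = getattr(ts, f"{kind}_counts")
            if fractions is None:
                continue
            for key, frac in fractions.items():
                syntax_rows.append(
                    {
                        "subject_id": sid,
                        "sequence": ">".join(key),
                        "count": counts[key],
                        "fraction": frac,
                    }
                )
    pd.DataFrame(syntax_rows).to_csv(
        out / "syntax.tsv", sep="\t", index=False, float_format="%.6f"
    )
    if len(result.syntax_tests):
        result.syntax_tests.to_csv(
            out / "syntax_tests.tsv", sep="\t", index=False, float_format="%.6f"
        )

    stats_report = {
        "anova": _jsonable(result.anova),
        "posthoc": _jsonable(result.posthoc),
        "severity": _jsonable(result.severity),
        "letter_scores": _jsonable(result.letter_scores),
    }
    (out / "stats.json").write_text(json.dumps(stats_report, indent=2))
    (out / "run_log.json").write_text(
        json.dumps(_jsonable(result.log), indent=2)
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load the manifest cohort, analyze it and write the report bundle."""
    if not config.manifest:
        raise ValueError("config.manifest is required")
    cohort = read_cohort(config.manifest)
    result = analyze_cohort(cohort, config)
    if config.out_dir:
        write_report(result, config.out_dir)
    return result
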