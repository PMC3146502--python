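"""Reading and writing epochs, cohorts, templates and reports.

The canonical on-disk format is plain text so results diff cleanly:

* **epoch matrix TSV** — header row of channel names, one row per sample
  (so the file holds the channels x samples matrix column-wise), values in
  microvolts;
* **cohort manifest TSV** — one row per epoch file with columns
  ``subject_id``, ``group``, ``severity`` (empty for controls), ``path``
  (relative to the manifest), ``sampling_rate``;
* **template TSV** — one row per class, columns = channels, header row of
  channel names, with a JSON sidecar (k, gev, seed, restarts).

EDF recordings can additionally be *read* (via the optional ``mne``
dependency); they are chunked into fixed-length epochs and re-ordered onto
the montage.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import TemplateSet
from .montage import ChannelMontage, standard_1020_16
from .preprocess import EEGEpoch
from .synthetic import SubjectRecord

__all__ = [
    "write_epoch_tsv",
    "read_epoch_tsv",
    "write_cohort",
    "read_cohort",
    "read_eeg",
    "write_templates",
    "read_templates",
]


def write_epoch_tsv(epoch: EEGEpoch, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(epoch.data.T, columns=list(epoch.montage.names))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _reorder_to_montage(
    data: np.ndarray, names: list[str], montage: ChannelMontage
) -> np.ndarray:
    missing = [n for n in montage.names if n not in names]
    if missing:
        raise ValueError(f"missing montage channel(s): {', '.join(missing)}")
    order = [names.index(n) for n in montage.names]
    return data[order]


def read_epoch_tsv(
    path: str | Path,
    sampling_rate: float = 200.0,
    montage: ChannelMontage | None = None,
) -> EEGEpoch:
    montage = montage or standard_1020_16()
    df = pd.read_csv(path, sep="\t")
    data = _reorder_to_montage(df.to_numpy(float).T, list(df.columns), montage)
    return EEGEpoch(data, sampling_rate, montage)


def write_cohort(cohort: list[SubjectRecord], out_dir: str | Path) -> Path:
    """One TSV file per epoch plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in cohort:
        sub_dir = out_dir / sub.subject_id
        sub_dir.mkdir(exist_ok=True)
        for i, epoch in enumerate(sub.epochs):
            rel = Path(sub.subject_id) / f"epoch{i + 1:03d}.tsv"
            write_epoch_tsv(epoch, out_dir / rel)
            rows.append(
                {
                    "subject_id": sub.subject_id,
                    "group": sub.group,
                    "severity": "" if sub.severity is None else sub.severity,
                    "path": str(rel),
                    "sampling_rate": epoch.sampling_rate,
                }
            )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cohort(
    manifest_path: str | Path, montage: ChannelMontage | None = None
) -> list[SubjectRecord]:
    """Load a cohort from a manifest of pre-marked artifact-free epochs."""
    manifest_path = Path(manifest_path)
    montage = montage or standard_1020_16()
    table = pd.read_csv(manifest_path, sep="\t")
    required = {"subject_id", "group", "severity", "path", "sampling_rate"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    cohort = []
    for sid, rows in table.groupby("subject_id", sort=True):
        group = rows["group"].iloc[0]
        sev = rows["severity"].iloc[0]
        severity = None if pd.isna(sev) or sev == "" else int(sev)
        epochs = [
            read_epoch_tsv(
                manifest_path.parent / r["path"],
                sampling_rate=float(r["sampling_rate"]),
                montage=montage,
            )
            for _, r in rows.iterrows()
        ]
        cohort.append(SubjectRecord(str(sid), group, severity, epochs))
    return cohort


def read_eeg(
    path: str | Path,
    fmt: str = "tsv",
    sampling_rate: float = 200.0,
    epoch_samples: int = 512,
    montage: ChannelMontage | None = None,
) -> list[EEGEpoch]:
    """Read epochs from one file (``tsv`` matrix or ``edf`` recording).

    A TSV file holds exactly one epoch.  An EDF recording is split into
    consecutive non-overlapping ``epoch_samples`` windows (a trailing
    partial window is dropped); channels are matched by name onto the
    montage and a descriptive error names any missing channel.
    """
    montage = montage or standard_1020_16()
    if fmt == "tsv":
        return [read_epoch_tsv(path, sampling_rate, montage)]
    if fmt != "edf":
        raise ValueError(f"unknown format {fmt!r}")
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts -> microvolts
    data = _reorder_to_montage(data, list(raw.ch_names), montage)
    n = data.shape[1] // epoch_samples
    if n == 0:
        raise ValueError("recording shorter than one epoch")
    return [
        EEGEpoch(data[:, i * epoch_samples:(i + 1) * epoch_samples], fs, montage)
        for i in range(n)
    ]


def write_templates(
    templates: TemplateSet,
    path: str | Path,
    meta: dict | None = None,
) -> None:
    """Template TSV (classes x channels) plus a JSON sidecar."""
    path = Path(path)
    names = templates.channel_names or tuple(
        f"ch{i + 1}" for i in range(templates.n_channels)
    )
    pd.DataFrame(templates.maps, columns=list(names)).to_csv(
        path, sep="\t", index=False, float_format="%.8f"
    )
    sidecar = {"k": templates.k, "gev": templates.gev}
    sidecar.update(meta or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_templates(path: str | Path) -> TemplateSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    gev = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        gev = json.loads(sidecar.read_text()).get("gev")
    return TemplateSet(
        df.to_numpy(float), gev=gev, channel_names=tuple(df.columns)
    )
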