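"""Group-comparison statistics for microstate profiles and syntax.

The design is a split-plot (mixed) two-way ANOVA — subject group as the
between-subject factor, microstate class as the within-subject factor — per
measure (duration, occurrence, coverage), followed by per-class unpaired
two-tailed Student t-tests, Spearman rank correlations of each measure with
clinical severity in the patient group, and per-transition t-tests on the
syntax fractions.  Pooled-variance t-tests are used throughout (df = n1 +
n2 - 2); no multiple-testing correction is applied, but a Bonferroni column
accompanies the syntax report for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .segmentation import MicrostateProfile
from .syntax import TransitionStats, doublet_keys, triplet_keys

__all__ = [
    "AnovaResult",
    "TTestResult",
    "CorrelationResult",
    "profiles_to_frame",
    "mixed_anova",
    "posthoc_ttests",
    "ttest_from_summary",
    "spearman_severity",
    "syntax_ttests",
]

MEASURES = ("duration", "occurrence", "coverage")
_MEASURE_COLUMNS = {
    "duration": "duration_ms",
    "occurrence": "occurrence_per_s",
    "coverage": "percent_total_time",
}
CLASS_LETTERS = ("A", "B", "C", "D")


@dataclass
class AnovaResult:
    """One effect of the split-plot ANOVA.

    ``df_denominator`` is the canonical split-plot error df; for the
    within-subject rows ``df_denominator_alt`` additionally gives the
    (k-1)*N convention sometimes seen in print.
    """

    effect: str  # "group" | "class" | "group x class"
    F: float
    df_numerator: int
    df_denominator: int
    p: float
    df_denominator_alt: int | None = None


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int


def profiles_to_frame(profiles: list[MicrostateProfile]) -> pd.DataFrame:
    """Long-format table: subject_id, group, severity, class, one column per
    measure."""
    rows = []
    for p in profiles:
        for c, letter in enumerate(CLASS_LETTERS[: len(p.duration_ms)]):
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "group": p.group,
                    "severity": p.severity,
                    "class": letter,
                    "duration": p.duration_ms[c],
                    "occurrence": p.occurrence_per_s[c],
                    "coverage": p.percent_total_time[c],
                }
            )
    return pd.DataFrame(rows)


def _check_measure(measure: str) -> None:
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")


def _complete_cases(df: pd.DataFrame, measure: str) -> pd.DataFrame:
    incomplete = df.loc[df[measure].isna(), "subject_id"].unique()
    if len(incomplete):
        warnings.warn(
            f"excluding subjects with a missing {measure} cell: "
            f"{', '.join(map(str, incomplete))}",
            stacklevel=3,
        )
        df = df[~df["subject_id"].isin(incomplete)]
    return df


def mixed_anova(profiles: list[MicrostateProfile], measure: str) -> list[AnovaResult]:
    """Split-plot ANOVA of one measure: group (between) x class (within).

    Subjects missing a class (no runs of it) are excluded with a warning.
    The computation is delegated to a standard mixed-design ANOVA routine;
    uncorrected p-values are reported.
    """
    _check_measure(measure)
    import pingouin as pg

    df = _complete_cases(profiles_to_frame(profiles), measure)
    n_per_group = df.groupby("group")["subject_id"].nunique()
    if len(n_per_group) != 2 or (n_per_group < 2).any():
        raise ValueError("need two groups with at least 2 subjects each")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.mixed_anova(
            data=df, dv=measure, within="class", subject="subject_id",
            between="group", correction=False,
        )
    n_subjects = df["subject_id"].nunique()
    k = df["class"].nunique()
    results = []
    for _, row in table.iterrows():
        name = {"group": "group", "class": "class", "Interaction": "group x class"}[
            row["Source"]
        ]
        alt = (k - 1) * n_subjects if name != "group" else None
        results.append(
            AnovaResult(
                effect=name,
                F=float(row["F"]),
                df_numerator=int(row["DF1"]),
                df_denominator=int(row["DF2"]),
                p=float(row["p_unc"]),
                df_denominator_alt=alt,
            )
        )
    return results


def ttest_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TTestResult:
    """Pooled-variance two-sample t-test from summary statistics.

    ``t`` is positive when group 1 exceeds group 2; df = n1 + n2 - 2; the
    p-value is two-tailed.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("invalid standard deviations")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return TTestResult(
        t=float(res.statistic), df=n1 + n2 - 2, p=float(res.pvalue),
        mean1=mean1, sd1=sd1, n1=n1, mean2=mean2, sd2=sd2, n2=n2,
    )


def _group_values(
    df: pd.DataFrame, measure: str, letter: str
) -> tuple[np.ndarray, np.ndarray]:
    sub = df[df["class"] == letter]
    groups = sorted(sub["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    # patients first so that positive t means patients > controls
    if "patient" in groups:
        groups = ["patient"] + [g for g in groups if g != "patient"]
    g1 = sub.loc[sub["group"] == groups[0], measure].to_numpy(float)
    g2 = sub.loc[sub["group"] == groups[1], measure].to_numpy(float)
    return g1, g2


def posthoc_ttests(
    profiles: list[MicrostateProfile], measure: str
) -> dict[str, TTestResult]:
    """Per-class unpaired pooled-variance t-test (patients minus controls)."""
    _check_measure(measure)
    df = _complete_cases(profiles_to_frame(profiles), measure)
    out: dict[str, TTestResult] = {}
    for letter in sorted(df["class"].unique()):
        g1, g2 = _group_values(df, measure, letter)
        out[letter] = ttest_from_summary(
            float(np.mean(g1)), float(np.std(g1, ddof=1)), len(g1),
            float(np.mean(g2)), float(np.std(g2, ddof=1)), len(g2),
        )
    return out


def spearman_severity(
    profiles: list[MicrostateProfile], measure: str, class_letter: str
) -> CorrelationResult:
    """Spearman rank correlation of a measure with patient severity.

    Only patients carry a severity rating; ties are handled by midranks and
    the two-tailed p-value uses the t approximation.
    """
    _check_measure(measure)
    df = profiles_to_frame(profiles)
    sub = df[(df["class"] == class_letter) & df["severity"].notna()]
    sub = sub[sub[measure].notna()]
    if len(sub) < 3:
        raise ValueError("need at least 3 patients with severity")
    sev = sub["severity"].to_numpy(float)
    if np.all(sev == sev[0]):
        raise ValueError("severity is constant; correlation undefined")
    rho, p = sps.spearmanr(sev, sub[measure].to_numpy(float))
    return CorrelationResult(rho=float(rho), p=float(p), n=len(sub))


def syntax_ttests(
    subject_stats: dict[str, TransitionStats],
    groups: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-transition group t-tests on doublet and triplet fractions.

    Parameters
    ----------
    subject_stats
        Per-subject :class:`TransitionStats`.
    groups
        subject_id -> group label ("patient"/"control").

    Returns a table with one row per admissible sequence: the sequence
    string (``A>B`` / ``A>C>B``), kind, group means, t, df, two-tailed p, a
    significance flag at ``alpha`` and a Bonferroni-corrected p column.
    The attribute ``df.attrs["n_significant_triplets"]`` holds the count of
    uncorrected triplet hits (to compare with the 36 * alpha chance
    expectation).
    """
    ids = sorted(subject_stats)
    patient_ids = [s for s in ids if groups[s] == "patient"]
    control_ids = [s for s in ids if groups[s] == "control"]
    if not patient_ids or not control_ids:
        raise ValueError("both groups must be present")

    rows = []
    for kind, keys, attr in (
        ("doublet", doublet_keys(), "doublet_fractions"),
        ("triplet", triplet_keys(), "triplet_fractions"),
    ):
        n_tests = len(keys)
        for key in keys:
            pat = np.array(
                [getattr(subject_stats[s], attr)[key] for s in patient_ids
                 if getattr(subject_stats[s], attr) is not None]
            )
            con = np.array(
                [getattr(subject_stats[s], attr)[key] for s in control_ids
                 if getattr(subject_stats[s], attr) is not None]
            )
            df_t = len(pat) + len(con) - 2
            if np.std(pat, ddof=1) == 0 and np.std(con, ddof=1) == 0:
                t, p = 0.0, 1.0
            else:
                res = sps.ttest_ind(pat, con, equal_var=True)
                t, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {
                    "sequence": ">".join(key),
                    "kind": kind,
                    "mean_patient": float(np.mean(pat)),
                    "mean_control": float(np.mean(con)),
                    "t": t,
                    "df": df_t,
                    "p": p,
                    "significant": p < alpha,
                    "p_bonferroni": min(1.0, p * n_tests),
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["n_significant_triplets"] = int(
        table.loc[table["kind"] == "triplet", "significant"].sum()
    )
    table.attrs["chance_expectation"] = alpha * 36
    table.attrs["critical_t"] = float(
        sps.t.ppf(1 - alpha / 2, int(table["df"].iloc[0]))
    )
    return table
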