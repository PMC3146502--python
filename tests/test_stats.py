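"""Statistical layer: split-plot ANOVA, t-tests, Spearman, syntax tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from microstates import (
    SynthConfig,
    mixed_anova,
    posthoc_ttests,
    simulate_sequence_profiles,
    spearman_severity,
    syntax_ttests,
    ttest_from_summary,
)
from microstates.segmentation import MicrostateProfile
from microstates.stats import profiles_to_frame
from microstates.syntax import TransitionStats, doublet_keys, triplet_keys
from microstates.synthetic import null_config


def make_profiles(values, groups, severities=None):
    """Profiles with the given (n_subjects, 4) duration matrix; occurrence
    and coverage filled with the same values for convenience."""
    profiles = []
    for i, (row, g) in enumerate(zip(values, groups)):
        sev = severities[i] if severities is not None else (
            1 if g == "patient" else None
        )
        profiles.append(
            MicrostateProfile(
                subject_id=f"S{i:02d}",
                group=g,
                duration_ms=np.asarray(row, float),
                occurrence_per_s=np.asarray(row, float),
                percent_total_time=np.asarray(row, float),
                total_time_s=60.0,
                severity=sev,
            )
        )
    return profiles


def splitplot_oracle(df, dv="duration"):
    """Textbook split-plot sums-of-squares decomposition (balanced)."""
    grand = df[dv].mean()
    k = df["class"].nunique()
    subj = df.groupby("subject_id")[dv].mean()
    group_of = df.groupby("subject_id")["group"].first()
    grp = df.groupby("group")[dv].mean()
    cls = df.groupby("class")[dv].mean()
    cell = df.groupby(["group", "class"])[dv].mean()
    n_per_group = group_of.value_counts()
    N = len(subj)
    G = len(grp)

    ss_group = k * sum(n_per_group[g] * (grp[g] - grand) ** 2 for g in grp.index)
    ss_subj = k * sum((subj[s] - grp[group_of[s]]) ** 2 for s in subj.index)
    ss_class = N * sum((cls[c] - grand) ** 2 for c in cls.index)
    ss_int = sum(
        n_per_group[g] * (cell[(g, c)] - grp[g] - cls[c] + grand) ** 2
        for g in grp.index
        for c in cls.index
    )
    ss_err = sum(
        (row[dv] - cell[(row["group"], row["class"])]
         - subj[row["subject_id"]] + grp[row["group"]]) ** 2
        for _, row in df.iterrows()
    )
    F_group = (ss_group / (G - 1)) / (ss_subj / (N - G))
    F_class = (ss_class / (k - 1)) / (ss_err / ((k - 1) * (N - G)))
    F_int = (ss_int / ((G - 1) * (k - 1))) / (ss_err / ((k - 1) * (N - G)))
    return {
        "ss_interaction": ss_int,
        "F": {"group": F_group, "class": F_class, "group x class": F_int},
        "df": {
            "group": (G - 1, N - G),
            "class": (k - 1, (k - 1) * (N - G)),
            "group x class": ((G - 1) * (k - 1), (k - 1) * (N - G)),
        },
    }


class TestMixedAnova:
    def test_constructed_null_interaction_ss_zero(self):
        """Identical class means in both groups plus a pure per-subject
        additive offset leave an interaction sum of squares of zero."""
        base = np.array([60.0, 55.0, 70.0, 80.0])
        offsets = np.array([-2.0, 1.0, 0.5, -1.5, 3.0, -1.0])
        values = base[None, :] + offsets[:, None]
        groups = ["patient"] * 3 + ["control"] * 3
        df = profiles_to_frame(make_profiles(values, groups))
        oracle = splitplot_oracle(df)
        assert oracle["ss_interaction"] == pytest.approx(0.0, abs=1e-18)

    def test_matches_sums_of_squares_oracle(self, rng):
        values = 60 + 8 * rng.standard_normal((8, 4))
        groups = ["patient"] * 4 + ["control"] * 4
        profiles = make_profiles(values, groups)
        results = {r.effect: r for r in mixed_anova(profiles, "duration")}
        oracle = splitplot_oracle(profiles_to_frame(profiles))
        for effect, r in results.items():
            assert r.F == pytest.approx(oracle["F"][effect], abs=1e-8)
            assert (r.df_numerator, r.df_denominator) == oracle["df"][effect]
            expected_p = sps.f.sf(r.F, *oracle["df"][effect])
            assert r.p == pytest.approx(expected_p, abs=1e-10)

    def test_alternative_denominator_df_reported(self, rng):
        values = 60 + 8 * rng.standard_normal((8, 4))
        groups = ["patient"] * 4 + ["control"] * 4
        results = {r.effect: r for r in mixed_anova(
            make_profiles(values, groups), "duration")}
        # canonical within-error df is (k-1)(N-G); the (k-1)N convention is
        # carried alongside for comparison with printed tables
        assert results["group x class"].df_denominator == 3 * 6
        assert results["group x class"].df_denominator_alt == 3 * 8
        assert results["group"].df_denominator_alt is None

    def test_missing_class_excludes_subject(self, rng):
        values = 60 + 8 * rng.standard_normal((8, 4))
        values[0, 2] = np.nan
        groups = ["patient"] * 4 + ["control"] * 4
        with pytest.warns(UserWarning, match="S00"):
            results = mixed_anova(make_profiles(values, groups), "duration")
        assert results[0].df_denominator == 5  # 7 subjects - 2

    def test_planted_interaction_detected(self):
        """A class A duration offset of Table-1 magnitude yields a
        significant interaction in most seeded replicates."""
        hits = 0
        n_rep = 30
        for rep in range(n_rep):
            cfg = SynthConfig(
                n_subjects_per_group=18, epochs_per_subject=(20, 20),
                seed=5000 + rep,
            )
            profiles = simulate_sequence_profiles(cfg)
            results = {r.effect: r for r in mixed_anova(profiles, "duration")}
            if results["group x class"].p < 0.05:
                hits += 1
        assert hits / n_rep > 0.5


class TestTTests:
    @pytest.mark.parametrize(
        "m1,s1,m2,s2,expected_t",
        [
            (63.81, 14.71, 54.55, 10.14, 2.20),
            (58.47, 10.47, 61.03, 13.75, -0.63),
            (83.40, 25.34, 74.14, 17.62, 1.27),
        ],
    )
    def test_summary_ttest_known_values(self, m1, s1, m2, s2, expected_t):
        res = ttest_from_summary(m1, s1, 18, m2, s2, 18)
        assert res.t == pytest.approx(expected_t, abs=0.01)
        assert res.df == 34

    def test_equal_means_t_zero(self):
        res = ttest_from_summary(5.0, 1.0, 10, 5.0, 2.0, 10)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ttest_from_summary(1.0, 1.0, 1, 2.0, 1.0, 10)
        with pytest.raises(ValueError):
            ttest_from_summary(1.0, 0.0, 5, 2.0, 0.0, 5)

    def test_posthoc_identical_groups(self):
        values = np.tile([60.0, 55.0, 70.0, 80.0], (6, 1))
        values += np.arange(6)[:, None]  # subject offsets, same in both groups
        groups = ["patient", "patient", "patient", "control", "control", "control"]
        values[3:] = values[:3]
        res = posthoc_ttests(make_profiles(values, groups), "duration")
        for letter in "ABCD":
            assert res[letter].t == pytest.approx(0.0, abs=1e-12)

    def test_posthoc_equals_summary_identity(self, rng):
        values = 60 + 8 * rng.standard_normal((10, 4))
        groups = ["patient"] * 5 + ["control"] * 5
        profiles = make_profiles(values, groups)
        res = posthoc_ttests(profiles, "duration")
        for c, letter in enumerate("ABCD"):
            g1 = values[:5, c]
            g2 = values[5:, c]
            expected = ttest_from_summary(
                g1.mean(), g1.std(ddof=1), 5, g2.mean(), g2.std(ddof=1), 5
            )
            assert res[letter].t == pytest.approx(expected.t, abs=1e-12)
            assert res[letter].p == pytest.approx(expected.p, abs=1e-12)

    def test_sign_agrees_with_permutation_test(self, rng):
        """Direction of the class A effect agrees with a permutation test."""
        values = 60 + 5 * rng.standard_normal((20, 4))
        values[:10, 0] += 8.0  # planted patient excess in class A
        groups = ["patient"] * 10 + ["control"] * 10
        res = posthoc_ttests(make_profiles(values, groups), "duration")
        assert res["A"].t > 0
        observed = values[:10, 0].mean() - values[10:, 0].mean()
        perm_rng = np.random.default_rng(1)
        col = values[:, 0].copy()
        count = 0
        for _ in range(10_000):
            perm_rng.shuffle(col)
            if col[:10].mean() - col[10:].mean() >= observed:
                count += 1
        assert count / 10_000 < 0.05  # same direction, same conclusion

    def test_null_false_positive_rate(self):
        """Across null cohorts the post-hoc tests reject at ~5%."""
        cfg0 = null_config(
            n_subjects_per_group=10, epochs_per_subject=(10, 10)
        )
        rejections = 0
        total = 0
        for rep in range(200):
            profiles = simulate_sequence_profiles(cfg0, seed=20_000 + rep)
            res = posthoc_ttests(profiles, "duration")
            for letter in "ABCD":
                total += 1
                rejections += res[letter].p < 0.05
        rate = rejections / total
        sd = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 4 * sd


class TestSpearman:
    def test_monotone_relations(self):
        values = np.zeros((4, 4))
        values[:, 0] = [10, 20, 30, 40]
        sev = [1, 2, 3, 4]
        prof = make_profiles(values, ["patient"] * 4, severities=sev)
        up = spearman_severity(prof, "duration", "A")
        assert up.rho == pytest.approx(1.0)
        values[:, 0] = [40, 30, 20, 10]
        prof = make_profiles(values, ["patient"] * 4, severities=sev)
        down = spearman_severity(prof, "duration", "A")
        assert down.rho == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        sev = [1, 2, 2, 3, 4, 4, 4]
        vals = [5.0, 7.0, 6.5, 9.0, 8.0, 8.0, 10.0]
        values = np.zeros((7, 4))
        values[:, 1] = vals
        prof = make_profiles(values, ["patient"] * 7, severities=sev)
        res = spearman_severity(prof, "duration", "B")
        # oracle: midranks then Pearson
        r_sev = sps.rankdata(sev)
        r_val = sps.rankdata(vals)
        expected = np.corrcoef(r_sev, r_val)[0, 1]
        assert res.rho == pytest.approx(expected, abs=1e-12)
        assert res.n == 7

    def test_constant_severity_undefined(self):
        values = np.random.default_rng(0).normal(size=(4, 4))
        prof = make_profiles(values, ["patient"] * 4, severities=[2] * 4)
        with pytest.raises(ValueError):
            spearman_severity(prof, "duration", "A")

    def test_controls_excluded(self):
        values = np.zeros((6, 4))
        values[:, 0] = [1, 2, 3, 4, 5, 6]
        sev = [1, 2, 4, None, None, None]
        prof = make_profiles(
            values, ["patient"] * 3 + ["control"] * 3, severities=sev
        )
        res = spearman_severity(prof, "duration", "A")
        assert res.n == 3


def _uniform_syntax(rng, excess=None):
    d_keys, t_keys = doublet_keys(), triplet_keys()
    d = {k: 1 / 12 + 0.01 * rng.standard_normal() for k in d_keys}
    if excess:
        d[excess] += 0.08
    total = sum(d.values())
    d = {k: v / total for k, v in d.items()}
    t = {k: 1 / 36 for k in t_keys}
    return TransitionStats(
        doublet_counts={k: 1 for k in d_keys},
        doublet_fractions=d,
        triplet_counts={k: 1 for k in t_keys},
        triplet_fractions=t,
    )


class TestSyntaxTests:
    def test_identical_groups_all_t_zero(self):
        stats = _uniform_syntax(np.random.default_rng(0))
        subject_stats = {f"S{i}": stats for i in range(8)}
        groups = {f"S{i}": ("patient" if i < 4 else "control") for i in range(8)}
        table = syntax_ttests(subject_stats, groups)
        assert len(table) == 48
        assert np.allclose(table["t"], 0.0)
        assert np.allclose(table["p"], 1.0)

    def test_planted_doublet_excess_has_largest_t(self):
        rng = np.random.default_rng(3)
        subject_stats = {}
        groups = {}
        for i in range(20):
            is_patient = i < 10
            subject_stats[f"S{i:02d}"] = _uniform_syntax(
                rng, excess=("A", "B") if is_patient else None
            )
            groups[f"S{i:02d}"] = "patient" if is_patient else "control"
        table = syntax_ttests(subject_stats, groups)
        doublets = table[table["kind"] == "doublet"].set_index("sequence")
        assert doublets["t"].abs().idxmax() == "A>B"
        assert doublets.loc["A>B", "t"] > 0

    def test_critical_t_at_df_34(self):
        stats = _uniform_syntax(np.random.default_rng(1))
        subject_stats = {f"S{i:02d}": stats for i in range(36)}
        groups = {
            f"S{i:02d}": ("patient" if i < 18 else "control") for i in range(36)
        }
        table = syntax_ttests(subject_stats, groups)
        assert table["df"].iloc[0] == 34
        assert table.attrs["critical_t"] == pytest.approx(2.032, abs=1e-3)
        assert table.attrs["chance_expectation"] == pytest.approx(1.8)
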