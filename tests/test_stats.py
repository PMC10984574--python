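"""Mixed ANOVA, post-hoc contrasts, correlations and the clinical fixture."""

import numpy as np
import pandas as pd
import pytest

import asrtnet as a


def long_table(values: dict, within_name="time"):
    """values: subject -> (group, {level: value} or {(l1,l2): value})."""
    rows = []
    for subj, (group, cells) in values.items():
        for lev, v in cells.items():
            row = {"subject": subj, "group": group, "dv": v}
            if isinstance(lev, tuple):
                row["w1"], row["w2"] = lev
            else:
                row[within_name] = lev
            rows.append(row)
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_hand_worked_2x2_design(self):
        """4-subject 2x2 toy worked by hand with classic sums of squares.

        Cell values give SS_group = 162 over MS error 9 (F = 18),
        SS_time = 18 over MS error 1 (F = 18) and interaction SS = 8
        (F = 8), each on (1, 2) degrees of freedom.
        """
        data = long_table(
            {
                "s1": ("g1", {"w1": 10.0, "w2": 14.0}),
                "s2": ("g1", {"w1": 12.0, "w2": 18.0}),
                "s3": ("g2", {"w1": 20.0, "w2": 22.0}),
                "s4": ("g2", {"w1": 24.0, "w2": 24.0}),
            }
        )
        res = a.mixed_anova(
            data, dv="dv", between="group", within=["time"], subject="subject"
        ).set_index("effect")
        assert res.loc["group", "F"] == pytest.approx(18.0)
        assert res.loc["time", "F"] == pytest.approx(18.0)
        assert res.loc["group * time", "F"] == pytest.approx(8.0)
        assert (res["df_num"] == 1).all() and (res["df_den"] == 2).all()
        assert res.loc["group", "eta_p2"] == pytest.approx(0.9)
        assert res.loc["group * time", "eta_p2"] == pytest.approx(0.8)

    def test_constant_dv_gives_zero_F(self):
        data = long_table(
            {f"s{i}": ("g1" if i < 3 else "g2", {"w1": 5.0, "w2": 5.0})
             for i in range(6)}
        )
        res = a.mixed_anova(
            data, dv="dv", between="group", within=["time"], subject="subject"
        )
        assert (res["F"] == 0).all()

    def test_between_only_reduces_to_one_way(self):
        rng = np.random.default_rng(0)
        g1, g2 = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        data = pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(17)],
                "group": ["a"] * 8 + ["b"] * 9,
                "dv": np.r_[g1, g2],
            }
        )
        res = a.mixed_anova(
            data, dv="dv", between="group", within=[], subject="subject"
        ).set_index("effect")
        from scipy.stats import f_oneway

        f_ref, p_ref = f_oneway(g1, g2)
        assert res.loc["group", "F"] == pytest.approx(f_ref)
        assert res.loc["group", "P"] == pytest.approx(p_ref)

    def test_matches_pingouin_on_balanced_mixed_design(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        rows = []
        for i in range(16):
            g = "A" if i < 8 else "B"
            for w in ("t1", "t2", "t3"):
                rows.append(
                    {"subject": f"s{i}", "group": g, "time": w,
                     "dv": rng.normal((g == "A") * 0.5 + (w == "t2"))}
                )
        df = pd.DataFrame(rows)
        mine = a.mixed_anova(
            df, dv="dv", between="group", within=["time"], subject="subject"
        ).set_index("effect")
        ref = pg.mixed_anova(
            df, dv="dv", between="group", within="time", subject="subject"
        ).set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(ref.loc["group", "F"])
        assert mine.loc["time", "F"] == pytest.approx(ref.loc["time", "F"])
        assert mine.loc["group * time", "F"] == pytest.approx(
            ref.loc["Interaction", "F"]
        )

    def test_eta_identity_holds_for_every_effect(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(12):
            for p in ("hi", "lo"):
                for b in (1, 2, 3):
                    rows.append(
                        {"subject": f"s{i}", "group": "x" if i < 6 else "y",
                         "prob": p, "block": b, "dv": rng.normal()}
                    )
        res = a.mixed_anova(
            pd.DataFrame(rows), dv="dv", between="group",
            within=["prob", "block"], subject="subject",
        )
        recomputed = res["F"] * res["df_num"] / (
            res["F"] * res["df_num"] + res["df_den"]
        )
        assert np.allclose(res["eta_p2"], recomputed)

    def test_incomplete_subject_dropped(self):
        data = long_table(
            {
                "s1": ("g1", {"w1": 1.0, "w2": 2.0}),
                "s2": ("g1", {"w1": 2.0, "w2": 1.0}),
                "s3": ("g1", {"w1": 3.0}),  # missing cell
                "s4": ("g2", {"w1": 4.0, "w2": 2.0}),
                "s5": ("g2", {"w1": 5.0, "w2": 3.0}),
            }
        )
        res = a.mixed_anova(
            data, dv="dv", between="group", within=["time"], subject="subject"
        )
        assert res.attrs["n_subjects"] == 4

    def test_type3_dfs_match_study_design(self):
        """2 groups x 25 subjects x 2x4 within gives F(1,48) and F(3,144)."""
        rng = np.random.default_rng(5)
        rows = []
        for i in range(50):
            for p in ("hi", "lo"):
                for u in (1, 2, 3, 4):
                    rows.append(
                        {"subject": i, "group": "GTS" if i < 25 else "HC",
                         "prob": p, "unit": u, "dv": rng.normal()}
                    )
        res = a.mixed_anova(
            pd.DataFrame(rows), dv="dv", between="group",
            within=["prob", "unit"], subject="subject",
        ).set_index("effect")
        assert (res.loc["prob", ["df_num", "df_den"]] == [1, 48]).all()
        assert (res.loc["group * prob * unit", ["df_num", "df_den"]]
                == [3, 144]).all()


class TestPosthoc:
    def test_identical_cells_give_unit_p_zero_diff(self):
        data = long_table(
            {f"s{i}": ("g1" if i % 2 else "g2", {"w1": 3.0, "w2": 3.0})
             for i in range(8)}
        )
        res = a.posthoc_pairwise(
            data, dv="dv", between="group", within=["time"], subject="subject"
        )
        within = res[res["type"] == "within"]
        assert (within["diff"] == 0).all()
        assert (within["P"] == 1.0).all()

    def test_known_cell_mean_differences(self):
        data = long_table(
            {
                "s1": ("g1", {"w1": 10.0, "w2": 20.0}),
                "s2": ("g1", {"w1": 14.0, "w2": 26.0}),
                "s3": ("g2", {"w1": 30.0, "w2": 31.0}),
                "s4": ("g2", {"w1": 34.0, "w2": 37.0}),
            }
        )
        res = a.posthoc_pairwise(
            data, dv="dv", between="group", within=["time"], subject="subject"
        ).set_index("contrast")
        assert res.loc["g1 vs g2 @ w1", "diff"] == pytest.approx(-20.0)
        assert res.loc["g1: w1 vs w2", "diff"] == pytest.approx(-11.0)
        assert res.loc["g2: w1 vs w2", "diff"] == pytest.approx(-2.0)

    def test_asymmetric_simple_effect_detected(self):
        rng = np.random.default_rng(6)
        values = {}
        for i in range(24):
            g = "aff" if i < 12 else "ctl"
            delta = 2.0 if g == "aff" else 0.0
            values[f"s{i}"] = (g, {"w1": rng.normal(), "w2": rng.normal(delta, 1)})
        res = a.posthoc_pairwise(
            long_table(values), dv="dv", between="group", within=["time"],
            subject="subject",
        ).set_index("contrast")
        assert res.loc["aff: w1 vs w2", "P"] < 0.05
        assert res.loc["ctl: w1 vs w2", "P"] > 0.05


class TestSeverityCorrelation:
    def test_perfect_monotone_is_unit_spearman(self):
        res = a.severity_correlation([1, 2, 3, 4, 5], [2, 9, 11, 20, 50])
        assert res.coefficient == pytest.approx(1.0)
        assert res.df == 3

    def test_constant_input_flagged(self):
        res = a.severity_correlation([1.0] * 6, [3, 1, 4, 1, 5, 9])
        assert res.flagged and np.isnan(res.coefficient)

    def test_matches_scipy_rank_oracle_on_clinical_fixture(self):
        from scipy.stats import rankdata

        clin = a.clinical_table()
        tics = clin["ygtss_tics"].to_numpy(float)
        rng = np.random.default_rng(7)
        scores = rng.normal(1.5, 1.0, size=len(tics))
        res = a.severity_correlation(scores, tics, method="spearman")
        rx, ry = rankdata(scores), rankdata(tics)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.coefficient == pytest.approx(oracle)
        assert res.df == 23

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="4"):
            a.severity_correlation([1, 2, 3], [1, 2, 3])


class TestSensitivityRerun:
    def _cohort_scores(self, n_medicated):
        import warnings

        from asrtnet import pipeline as pl

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bundle = a.make_cohort(
                a.SimulationConfig(
                    include_eeg=False,
                    design=a.AsrtDesign(n_blocks=10),
                    gts=a.GroupSpec(name="GTS", n_subjects=8,
                                    n_medicated=n_medicated),
                    hc=a.GroupSpec(name="HC", n_subjects=8,
                                   acc_learning_pp_mean=0.7),
                    seed=17,
                )
            )
            scores, _ = pl.score_behavior_table(bundle.behavior)
        return scores, bundle.subjects

    def test_no_medicated_subjects_identical_to_full(self):
        scores, subjects = self._cohort_scores(n_medicated=0)
        res = a.sensitivity_rerun(
            scores, subjects,
            {"acc": dict(dv="mean_acc_pct", between="group",
                         within=["probability", "unit"])},
        )
        pd.testing.assert_frame_equal(res["full"]["acc"], res["reduced"]["acc"])
        assert res["n_excluded"] == 0

    def test_medicated_pairs_excluded(self):
        scores, subjects = self._cohort_scores(n_medicated=3)
        res = a.sensitivity_rerun(
            scores, subjects,
            {"acc": dict(dv="mean_acc_pct", between="group",
                         within=["probability", "unit"])},
        )
        assert res["n_excluded"] == 6
        assert res["reduced"]["acc"].attrs["n_subjects"] == 10

    def test_too_few_remaining_rejected(self):
        scores, subjects = self._cohort_scores(n_medicated=7)
        with pytest.raises(ValueError, match="fewer than 3"):
            a.sensitivity_rerun(
                scores, subjects,
                {"acc": dict(dv="mean_acc_pct", between="group",
                             within=["probability", "unit"])},
            )


class TestClinicalFixture:
    def test_fixture_shape(self):
        clin = a.clinical_table()
        assert clin.shape[0] == 25
        assert clin["rush"].notna().sum() == 20
        assert clin["medication"].notna().sum() == 13

    def test_column_means_match_printed_row(self):
        means = a.clinical_descriptives()
        assert means["age"] == pytest.approx(34.0)
        assert means["ygtss_total"] == pytest.approx(32.40)
        assert means["ygtss_tics"] == pytest.approx(23.20)
        assert means["rush"] == pytest.approx(12.30)
        assert means["dci"] == pytest.approx(69.0)
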