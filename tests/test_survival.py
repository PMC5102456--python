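import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import proportional_hazard_test

from ihctyper.survival import (
    attach_types,
    cox_model,
    km_estimate,
    logrank_test,
    ph_assumption,
    survival_report,
)
from ihctyper.synthetic import CohortSpec, generate_cohort


def records_from(times, events, group=None):
    n = len(times)
    df = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "os_months": times,
            "event": events,
        }
    )
    if group is not None:
        df["group"] = group
    return df


def cohort_records(seed=0, n=150, censoring=0.3, type_hr=None, resected=True):
    spec = CohortSpec(
        n_per_type={"EPB": n, "INT": n},
        missing_rate=0.0,
        seed=seed,
        censoring_rate=censoring,
        probe_resection_prob=1.0 if resected else 0.35,
        type_log_hr=type_hr
        or {"EPB": 0.0, "INT": np.log(0.19), "ICC": 0.0, "HCC": 0.0},
    )
    _, _, clinical = generate_cohort(spec)
    return clinical.rename(columns={"true_type": "ihc_type"})


class TestKm:
    def test_hand_computed_product_limit_median(self):
        # uncensored {2,4,6,8}: S = 0.75, 0.50, 0.25, 0 -> first S(t) <= 0.5
        # is at t = 4 under the product-limit step convention
        rec = records_from([2, 4, 6, 8], [1, 1, 1, 1], ["g"] * 4)
        km = km_estimate(rec, "group")
        assert km.groups.loc["g", "median_os"] == 4
        assert bool(km.groups.loc["g", "median_reached"])

    def test_all_censored_takes_restricted_mean_path(self):
        rec = records_from([5, 10, 15, 20, 3], [0, 0, 0, 0, 1] , ["g"] * 5)
        km = km_estimate(rec, "group")
        assert not bool(km.groups.loc["g", "median_reached"])
        assert np.isnan(km.groups.loc["g", "median_os"])
        assert km.groups.loc["g", "restricted_mean"] > 0

    def test_uncensored_curve_matches_empirical_survival(self):
        times = [1.0, 2, 3, 4, 5, 6, 7, 8]
        rec = records_from(times, [1] * 8, ["g"] * 8)
        km = km_estimate(rec, "group")
        curve = km.curves["g"].iloc[:, 0]
        for i, t in enumerate(times):
            assert curve.loc[t] == pytest.approx(1 - (i + 1) / 8)

    def test_curve_monotone_from_one(self, ):
        rec = cohort_records(seed=3)
        km = km_estimate(rec, "ihc_type")
        for curve in km.curves.values():
            s = curve.iloc[:, 0].to_numpy()
            assert s[0] == 1.0 or curve.index[0] == 0
            assert (np.diff(s) <= 1e-12).all()

    def test_empty_events_rejected(self):
        rec = records_from([1, 2], [0, 0], ["g", "g"])
        with pytest.raises(ValueError, match="no events"):
            km_estimate(rec, "group")


class TestLogrank:
    def test_identical_groups_not_rejected(self):
        times = list(range(1, 21))
        rec = records_from(
            times + times, [1] * 40, ["a"] * 20 + ["b"] * 20
        )
        stat, p = logrank_test(rec, "group")
        assert p > 0.99

    def test_strong_separation_detected(self):
        rng = np.random.default_rng(0)
        t_a = rng.exponential(10, 100)
        t_b = rng.exponential(50, 100)
        rec = records_from(
            np.concatenate([t_a, t_b]).clip(0.01),
            [1] * 200,
            ["a"] * 100 + ["b"] * 100,
        )
        stat, p = logrank_test(rec, "group")
        assert p < 0.001

    def test_single_group_rejected(self):
        rec = records_from([1, 2, 3], [1, 1, 1], ["a"] * 3)
        with pytest.raises(ValueError, match="two groups"):
            logrank_test(rec, "group")


class TestCox:
    def test_identical_groups_give_unit_hazard_ratio(self):
        times = np.arange(1.0, 41)
        rec = records_from(
            np.concatenate([times, times]),
            [1] * 80,
            ["a"] * 40 + ["b"] * 40,
        )
        fit = cox_model(rec, ["group"], baselines={"group": "a"})
        assert fit.summary["hr"].iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_recovers_planted_intestinal_hazard_ratio(self):
        # the generating hazard includes pT and pN effects, so the planted
        # type effect is recovered by the adjusted model (hazard ratios are
        # non-collapsible: the crude fit attenuates toward 1)
        rec = cohort_records(seed=1, n=500, censoring=0.2)
        fit = cox_model(rec, ["ihc_type", "pT", "pN"])
        hr = fit.summary.loc["ihc_type::INT", "hr"]
        assert 0.15 <= hr <= 0.24
        lo, hi = fit.summary.loc["ihc_type::INT", ["ci_lower", "ci_upper"]]
        assert lo < hr < hi

    def test_excluded_stages_never_enter_fit(self):
        rec = cohort_records(seed=2, n=100)
        rec.loc[rec.index[:10], "pT"] = "Tis"
        rec.loc[rec.index[10:20], "pN"] = "NX"
        fit = cox_model(rec, ["ihc_type", "pT", "pN"])
        assert not any("Tis" in i for i in fit.summary.index)
        assert not any("NX" in i for i in fit.summary.index)
        assert fit.n == len(rec) - 20

    def test_baseline_levels_are_reference(self):
        rec = cohort_records(seed=4, n=120)
        fit = cox_model(rec, ["ihc_type", "pT", "pN"])
        assert "ihc_type::EPB" not in fit.summary.index
        assert "pT::T3" not in fit.summary.index
        assert "pN::N1_2" not in fit.summary.index

    def test_too_few_events_rejected(self):
        rec = records_from([1, 2, 3, 4], [1, 0, 0, 0], ["a", "a", "b", "b"])
        rec["x1"], rec["x2"] = [0, 1, 0, 1], [1, 0, 1, 0]
        with pytest.raises(ValueError, match="too few events"):
            cox_model(rec, ["group", "x1", "x2"], baselines={"group": "a"})


class TestPhAssumption:
    def test_single_covariate_global_equals_per_covariate(self):
        rec = cohort_records(seed=5, n=150)
        fit = cox_model(rec, ["ihc_type"])
        ph = ph_assumption(fit)
        assert ph.loc["ihc_type::INT", "p"] == pytest.approx(
            ph.loc["GLOBAL", "p"], abs=1e-9
        )

    def test_per_covariate_matches_lifelines(self):
        # tie-free event times so that every rank-transform convention
        # (mid-ranks vs cumulative event counts) coincides exactly
        rng = np.random.default_rng(6)
        n = 200
        group = np.repeat(["a", "b"], n // 2)
        x = rng.normal(size=n)
        t = rng.exponential(20 * np.where(group == "a", 1.0, 0.6), n)
        rec = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "os_months": t,
                "event": rng.random(n) < 0.8,
                "group": group,
                "x": x,
            }
        )
        rec["event"] = rec["event"].astype(int)
        fit = cox_model(rec, ["group", "x"], baselines={"group": "a"})
        ph = ph_assumption(fit, time_transform="rank")
        ref = proportional_hazard_test(
            fit.fitter, fit.design, time_transform="rank"
        ).summary
        for cov in ("group::b", "x"):
            assert ph.loc[cov, "p"] == pytest.approx(
                float(ref.loc[cov, "p"]), abs=1e-8
            )

    def test_proportional_data_passes_time_varying_fails(self):
        # planted reversal: group effect flips sign at the median time
        rng = np.random.default_rng(7)
        n = 400
        group = np.repeat([0, 1], n // 2)
        rejections = 0
        for rep in range(5):
            rng2 = np.random.default_rng(100 + rep)
            t1 = rng2.exponential(20, n // 2)  # group 0
            # group 1: high hazard early, low hazard late
            early = rng2.exponential(6, n // 2)
            t2 = np.where(early < 8, early, 8 + rng2.exponential(60, n // 2))
            rec = records_from(
                np.concatenate([t1, t2]).clip(0.01), [1] * n,
                ["a"] * (n // 2) + ["b"] * (n // 2),
            )
            fit = cox_model(rec, ["group"], baselines={"group": "a"})
            rejections += ph_assumption(fit).loc["GLOBAL", "p"] < 0.05
        assert rejections >= 4


class TestReport:
    def test_table_contains_every_covariate_block(self):
        rec = cohort_records(seed=8, n=120)
        table = survival_report(rec)
        assert set(table["block"]) >= {"age_group", "sex", "pT", "pN", "ihc_type"}
        type_rows = table[table["block"] == "ihc_type"]
        base = type_rows[type_rows["is_baseline"]]
        assert (base["crude_hr"] == 1.0).all() and (base["adj_hr"] == 1.0).all()

    def test_age_split_at_cohort_median_is_balanced(self):
        rec = cohort_records(seed=9, n=120)
        table = survival_report(rec)
        ages = table[table["block"] == "age_group"]["n"]
        assert abs(ages.iloc[0] - ages.iloc[1]) <= len(rec) * 0.06 + 1

    def test_only_resected_patients_enter(self):
        rec = cohort_records(seed=10, n=100, resected=False)
        table = survival_report(rec)
        n_resected = int(rec["resected"].sum())
        assert table[table["block"] == "sex"]["n"].sum() == n_resected


class TestAttachTypes:
    def test_resection_sample_label_wins(self):
        meta = pd.DataFrame(
            {
                "patient_id": ["p1", "p1", "p2"],
                "probe_type": ["biopsy", "resection", "biopsy"],
            },
            index=["s1", "s1R", "s2"],
        )
        assignment = pd.Series({"s1": "EPB", "s1R": "INT", "s2": "ICC"})
        clinical = pd.DataFrame(
            {"patient_id": ["p1", "p2"], "os_months": [5.0, 6.0], "event": [1, 0]}
        )
        out = attach_types(clinical, assignment, meta)
        assert out.loc[out["patient_id"] == "p1", "ihc_type"].iloc[0] == "INT"
        assert out.loc[out["patient_id"] == "p2", "ihc_type"].iloc[0] == "ICC"
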