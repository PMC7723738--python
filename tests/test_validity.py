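"""Tests for the clustered diagnostic-validity statistics."""

import numpy as np
import pandas as pd
import pytest

from breathverify import (
    DiagnosticValidity,
    classify_ledger,
    clustered_sens_spec,
    gee_compare,
    rm_correlation,
    roc_auc,
    simulate_diagnostic_ledger,
    summarize_ledger,
)
from breathverify.validity import round_half_up

from oracles import brute_auc, brute_rm_corr, brute_sens_spec


def _ledger_from_table(tp, fn, fp, tn, n_clusters=5, rng=None):
    """Spread a 2x2 table over clusters (round-robin)."""
    rows = []
    cells = [(1, 1)] * tp + [(0, 1)] * fn + [(1, 0)] * fp + [(0, 0)] * tn
    if rng is not None:
        rng.shuffle(cells)
    for i, (idx, ref) in enumerate(cells):
        rows.append(
            {
                "participant_id": f"P{i % n_clusters}",
                "index_status": idx,
                "reference_status": ref,
            }
        )
    return pd.DataFrame(rows)


class TestSensSpec:
    def test_perfect_concordance(self):
        led = _ledger_from_table(tp=10, fn=0, fp=0, tn=10)
        out = clustered_sens_spec(led)
        assert out["sensitivity"] == 1.0
        assert out["specificity"] == 1.0

    def test_matches_cell_count_oracle(self):
        led = _ledger_from_table(tp=29, fn=3, fp=2, tn=32)
        out = clustered_sens_spec(led)
        sens, spec = brute_sens_spec(led.index_status, led.reference_status)
        assert out["sensitivity"] == pytest.approx(sens)
        assert out["specificity"] == pytest.approx(spec)
        assert out["sensitivity"] == pytest.approx(29 / 32)
        assert out["specificity"] == pytest.approx(32 / 34)

    @pytest.mark.parametrize("method", ["ratio_estimator", "cluster_bootstrap"])
    def test_random_tables_match_oracle(self, method, rng):
        for _ in range(200):
            tp, fn, fp, tn = rng.integers(1, 30, size=4)
            led = _ledger_from_table(tp, fn, fp, tn, rng=rng)
            out = clustered_sens_spec(led, method=method, seed=0)
            sens, spec = brute_sens_spec(led.index_status, led.reference_status)
            assert out["sensitivity"] == pytest.approx(sens)
            assert out["specificity"] == pytest.approx(spec)
            lo, hi = out["sensitivity_ci"]
            assert 0 <= lo <= out["sensitivity"] <= hi <= 1

    def test_single_cluster_degenerates_with_warning(self):
        led = _ledger_from_table(tp=8, fn=2, fp=1, tn=9, n_clusters=1)
        with pytest.warns(UserWarning, match="single cluster"):
            out = clustered_sens_spec(led)
        assert out["sensitivity_ci"] == (0.8, 0.8)

    def test_no_reference_positives_is_explicit_error(self):
        led = _ledger_from_table(tp=0, fn=0, fp=3, tn=7)
        with pytest.raises(ValueError, match="sensitivity undefined"):
            clustered_sens_spec(led)

    def test_clustering_widens_interval_under_strong_cluster_effects(self, rng):
        """Cluster-aware CI at least as wide as naive binomial in most studies."""
        wider = 0
        n_rep = 50
        for i in range(n_rep):
            led = simulate_diagnostic_ledger(
                10, 14, 0.85, 0.9, rng, prevalence=0.9, concentration=8.0
            )
            out = clustered_sens_spec(led)
            p = out["sensitivity"]
            n = len(led)
            naive = 2 * 1.96 * np.sqrt(p * (1 - p) / n)
            if (out["sensitivity_ci"][1] - out["sensitivity_ci"][0]) >= naive - 1e-12:
                wider += 1
        assert wider / n_rep >= 0.9


class TestRmCorrelation:
    def test_perfect_within_subject_linearity(self):
        rows = []
        for pid, offset in [("A", 0.0), ("B", 5.0), ("C", -3.0)]:
            for x in [1.0, 2.0, 3.0, 4.0]:
                rows.append({"participant_id": pid, "x": x, "y": x + offset})
        r, p = rm_correlation(pd.DataFrame(rows), "x", "y")
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_matches_sums_of_squares_oracle(self, rng):
        rows = []
        for pid in ["A", "B", "C"]:
            for _ in range(6):
                x = rng.uniform(0, 10)
                rows.append(
                    {
                        "participant_id": pid,
                        "x": x,
                        "y": 0.7 * x + rng.normal(0, 2.0),
                    }
                )
        df = pd.DataFrame(rows)
        r, p = rm_correlation(df, "x", "y")
        r_o, ss_reg, ss_err, dof = brute_rm_corr(df.participant_id, df.x, df.y)
        assert r == pytest.approx(r_o, rel=1e-10)
        from scipy import stats as sps

        f = ss_reg / (ss_err / dof)
        assert p == pytest.approx(float(sps.f.sf(f, 1, dof)), rel=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        rows = []
        for pid in range(5):
            base = rng.normal(0, 3)
            for _ in range(8):
                x = rng.uniform(0, 10)
                rows.append(
                    {
                        "participant_id": f"P{pid}",
                        "x": x,
                        "y": base + 0.5 * x + rng.normal(0, 1.0),
                    }
                )
        df = pd.DataFrame(rows)
        r, p = rm_correlation(df, "x", "y")
        out = pingouin.rm_corr(df, x="x", y="y", subject="participant_id")
        assert r == pytest.approx(float(out["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(out["pval"].iloc[0]), rel=1e-6)

    def test_constant_x_rejected(self):
        df = pd.DataFrame(
            {"participant_id": ["A"] * 4, "x": [2.0] * 4, "y": [1.0, 2, 3, 4]}
        )
        with pytest.raises(ValueError, match="constant"):
            rm_correlation(df, "x", "y")

    def test_null_rejection_rate_is_nominal(self):
        """Under independence the F test rejects at about its alpha level."""
        rng = np.random.default_rng(31)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            df = pd.DataFrame(
                {
                    "participant_id": np.repeat([f"P{i}" for i in range(6)], 8),
                    "x": rng.normal(size=48),
                    "y": rng.normal(size=48),
                }
            )
            _, p = rm_correlation(df, "x", "y")
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)


class TestRocAuc:
    def test_perfect_separation(self):
        led = pd.DataFrame(
            {
                "index_value": [10, 11, 12, 1, 2, 3],
                "reference_status": [1, 1, 1, 0, 0, 0],
            }
        )
        out = roc_auc(led, "index_value")
        assert out["auc"] == 1.0

    def test_constant_score_gives_half(self):
        led = pd.DataFrame(
            {"index_value": [5.0] * 8, "reference_status": [1, 0] * 4}
        )
        assert roc_auc(led, "index_value")["auc"] == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(200):
            n = 20
            scores = np.round(rng.uniform(0, 15, n), 1)  # induces ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            led = pd.DataFrame({"index_value": scores, "reference_status": labels})
            out = roc_auc(led, "index_value")
            assert out["auc"] == pytest.approx(brute_auc(scores, labels), abs=1e-12)

    def test_delong_interval_matches_reference_implementation(self):
        # frozen cross-check computed with pROC::ci.auc(method="delong")
        scores = [17.5, 4.3, 6.2, 20.0, 23.9, 6.8, 5.6, 7.6, 7.2, 7.4, 11.8,
                  16.3, 6.1, 11.3, 0.1, 13.3, 23.5, 20.0, 11.9, 6.5, 8.1, 8.9,
                  9.6, 17.5]
        labels = [1, 0, 0, 1, 1, 1, 1, 1, 0, 1, 0, 1, 1, 0, 0, 1, 1, 1, 0, 0,
                  1, 0, 1, 0]
        led = pd.DataFrame({"index_value": scores, "reference_status": labels})
        out = roc_auc(led, "index_value")
        assert out["auc"] == pytest.approx(0.6892857143, abs=1e-9)
        assert out["auc_ci"][0] == pytest.approx(0.4707234230, abs=1e-9)
        assert out["auc_ci"][1] == pytest.approx(0.9078480056, abs=1e-9)

    def test_single_class_is_explicit_error(self):
        led = pd.DataFrame({"index_value": [1.0, 2.0], "reference_status": [1, 1]})
        with pytest.raises(ValueError, match="single class"):
            roc_auc(led, "index_value")

    def test_curve_covers_unit_square_corners(self, rng):
        led = pd.DataFrame(
            {
                "index_value": rng.uniform(0, 10, 30),
                "reference_status": rng.integers(0, 2, 30),
            }
        )
        curve = roc_auc(led, "index_value")["curve"]
        assert curve["fpr"].iloc[-1] == 1.0 and curve["tpr"].iloc[-1] == 1.0


class TestGee:
    @staticmethod
    def _balanced_ledger(rng, effect=0.0, n_clusters=10, n_obs=14, rho=0.3):
        rows = []
        for c in range(n_clusters):
            e = rng.normal(0, 1)
            noise = np.empty(n_obs)
            noise[0] = rng.normal()
            for t in range(1, n_obs):
                noise[t] = rho * noise[t - 1] + rng.normal(0, np.sqrt(1 - rho**2))
            group = rng.integers(0, 2, n_obs)
            for t in range(n_obs):
                rows.append(
                    {
                        "participant_id": f"P{c}",
                        "y": e + effect * group[t] + noise[t],
                        "group": int(group[t]),
                        "order": t,
                    }
                )
        return pd.DataFrame(rows)

    def test_independence_on_iid_data_matches_ols(self, rng):
        import statsmodels.api as sm

        df = self._balanced_ledger(rng, effect=1.5)
        out = gee_compare(df, "y", "group", correlation="independence")
        X = sm.add_constant(df[["group"]].astype(float))
        ols = sm.OLS(df["y"], X).fit()
        assert out["coefficient"] == pytest.approx(float(ols.params["group"]), rel=1e-8)

    def test_recovers_injected_group_effect(self):
        rng = np.random.default_rng(77)
        coefs, ses = [], []
        for _ in range(20):
            df = self._balanced_ledger(rng, effect=5.0)
            out = gee_compare(df, "y", "group", correlation="ar1", time_col="order")
            coefs.append(out["coefficient"])
            ses.append(out["robust_se"])
        err = abs(np.mean(coefs) - 5.0)
        assert err < 3 * np.mean(ses)

    def test_constant_group_rejected(self, rng):
        df = self._balanced_ledger(rng)
        df["group"] = 1
        with pytest.raises(ValueError, match="constant"):
            gee_compare(df, "y", "group")

    def test_singular_design_rejected(self, rng):
        df = self._balanced_ledger(rng)
        df["dup"] = df["group"]
        with pytest.raises(ValueError, match="singular"):
            gee_compare(df, "y", "group", covariates=["dup"])

    def test_covariate_adjustment_runs(self, rng):
        df = self._balanced_ledger(rng, effect=2.0)
        df["cigs_24h"] = rng.integers(0, 15, len(df)).astype(float)
        out = gee_compare(
            df, "y", "group", covariates=["cigs_24h"], correlation="exchangeable"
        )
        assert np.isfinite(out["p_value"])


class TestSummaries:
    def test_rounding_half_away_from_zero(self):
        assert round_half_up(71.25, 1) == 71.3
        assert round_half_up(13.725, 0) == 14.0
        assert round_half_up(-2.5, 0) == -3.0
        assert round_half_up(50.0, 1) == 50.0

    def test_empty_ledger_yields_empty_summary(self):
        s = summarize_ledger(pd.DataFrame())
        assert s.n_in_office == 0
        assert np.isnan(s.recency_within_pct)

    def test_single_row_ledger(self):
        led = pd.DataFrame(
            {
                "test_id": ["T1"],
                "participant_id": ["P1"],
                "timestamp": [pd.Timestamp("2024-03-01 14:00")],
                "setting": ["in_office"],
                "momba_ppm": [9.0],
                "pico_ppm": [9.0],
                "cotinine_ng_ml": [250.0],
                "cigs_24h": [8],
                "last_cig_time": [pd.Timestamp("2024-03-01 12:00")],
                "pregnant_at_test": [True],
                "notification_status": [pd.NA],
                "verified_face": [True],
                "verified_mouth": [True],
                "audio_ok": [True],
                "challenged": [False],
            }
        )
        s = summarize_ledger(led)
        assert s.recency_within_pct == 100.0
        assert s.mean_tests_per_participant == 1.0

    def test_exchangeability_of_row_order(self, rng):
        led = simulate_diagnostic_ledger(8, 12, 0.85, 0.9, rng)
        led["index_value"] = led["index_status"] + rng.normal(0, 0.1, len(led))
        shuffled = led.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a = clustered_sens_spec(led)
        b = clustered_sens_spec(shuffled)
        assert a["sensitivity"] == pytest.approx(b["sensitivity"])
        assert a["sensitivity_ci"] == pytest.approx(b["sensitivity_ci"])
        assert roc_auc(led, "index_value")["auc"] == pytest.approx(
            roc_auc(shuffled, "index_value")["auc"]
        )


class TestModelResultsSurface:
    def test_fit_returns_populated_results(self):
        from breathverify import SimConfig, simulate_study

        led = classify_ledger(simulate_study(8, SimConfig(rng_seed=21)).ledger)
        res = DiagnosticValidity(led, "momba", "pico").fit()
        assert 0 <= res.sensitivity <= 1
        assert res.sensitivity_ci[0] <= res.sensitivity <= res.sensitivity_ci[1]
        assert -1 <= res.r <= 1
        assert res.n_clusters == 8
        text = res.summary()
        assert "Sensitivity" in text and "AUC" in text

    def test_index_must_differ_from_reference(self):
        with pytest.raises(ValueError, match="differ"):
            DiagnosticValidity(pd.DataFrame(), "pico", "pico")
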