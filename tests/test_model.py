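"""Additive CPUE model: frame building, smooth recovery, selection, report.

The fitted-smooth cross-check against an independent penalized-spline
implementation runs once through Rscript.
"""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from reefcpue.cpue_model import (CPUEModel, build_model_frame,
                                 complexity_effect, depth_effect,
                                 simulate_model_frame)
from reefcpue.gam import (AdditiveModel, LinearTerm, RandomIntercept,
                          SmoothTerm, select_model)


class TestModelFrame:
    def _cpue(self, values):
        return pd.DataFrame({"cell_id": np.arange(len(values)),
                             "year": 2008, "cpue_kg_per_h": values})

    def _covars(self, n):
        rng = np.random.default_rng(0)
        return pd.DataFrame({"cell_id": np.arange(n),
                             "complexity_mean": rng.uniform(0, 2, n),
                             "depth_mean": rng.uniform(3, 25, n),
                             "bpi_mean": rng.normal(size=n)})

    def test_log_of_e_is_one(self):
        frame = build_model_frame(self._cpue([np.e]), self._covars(1))
        assert frame.data["log_cpue"].iloc[0] == pytest.approx(1.0)

    def test_missing_covariate_dropped_and_counted(self):
        covars = self._covars(3)
        covars.loc[1, "bpi_mean"] = np.nan
        frame = build_model_frame(self._cpue([1.0, 2.0, 3.0]), covars)
        assert frame.n_dropped == 1 and len(frame.data) == 2

    def test_join_matches_manual(self):
        cpue = self._cpue(np.arange(1.0, 11.0))
        covars = self._covars(15)   # extra covariate-only cells
        frame = build_model_frame(cpue, covars)
        manual = set(cpue["cell_id"]) & set(covars["cell_id"])
        assert set(frame.data["cell_id"]) == manual
        # row conservation: rows_out + dropped = joined rows
        assert len(frame.data) + frame.n_dropped == len(manual)

    def test_empty_join_rejected(self):
        covars = self._covars(3)
        covars["cell_id"] += 100
        with pytest.raises(ValueError, match="join"):
            build_model_frame(self._cpue([1.0, 2.0, 3.0]), covars)


class TestFitRecovery:
    def test_planted_effects_recovered(self):
        frame = simulate_model_frame(n=1000, seed=42)
        res = CPUEModel(frame).fit()
        # complexity smooth correlates with the planted sinusoid
        pe = res.partial_effects("complexity_mean", 200)
        truth = complexity_effect(pe["value"])
        truth = truth - truth.mean()
        r = np.corrcoef(pe["effect"] - pe["effect"].mean(), truth)[0, 1]
        assert r > 0.9
        # depth smooth peaks near the planted 10 m optimum
        pd_eff = res.partial_effects("depth_mean", 400)
        argmax = pd_eff["value"].iloc[int(np.argmax(pd_eff["effect"]))]
        assert abs(argmax - 10.0) <= 2.0

    def test_null_response_shrinks_terms(self):
        # under a pure-noise response, smooth terms should mostly stay
        # near-linear and insignificant (a small type-I rate is expected)
        rejections = 0
        big_edf = 0
        for seed in (3, 7, 23):
            frame = simulate_model_frame(n=500, seed=seed, null=True)
            res = CPUEModel(frame).fit()
            tbl = res.term_table
            smooths = tbl[tbl["type"] == "smooth"]
            rejections += int((smooths["p"] <= 0.05).sum())
            big_edf += int((smooths["edf"] > 5.0).sum())
        assert rejections <= 2       # of 9 term-tests
        assert big_edf == 0

    def test_intervals_contain_fitted_curve(self):
        frame = simulate_model_frame(n=600, seed=3)
        res = CPUEModel(frame).fit()
        pe = res.partial_effects("depth_mean")
        assert (pe["lower"] <= pe["effect"]).all()
        assert (pe["effect"] <= pe["upper"]).all()

    def test_effect_centred_over_observed_values(self):
        frame = simulate_model_frame(n=800, seed=5)
        res = CPUEModel(frame).fit()
        obs = frame.data["complexity_mean"].to_numpy()
        pe = res.partial_effects("complexity_mean", values=np.sort(obs))
        assert abs(pe["effect"].mean()) < 0.05

    def test_extrapolation_refused(self):
        frame = simulate_model_frame(n=200, seed=9)
        res = CPUEModel(frame).fit()
        with pytest.raises(ValueError, match="range"):
            res.partial_effects("depth_mean", values=np.array([30.0]))

    def test_response_shift_moves_only_intercept(self):
        frame = simulate_model_frame(n=500, seed=11)
        res1 = CPUEModel(frame).fit()
        lam = res1.lambdas
        frame2 = simulate_model_frame(n=500, seed=11)
        frame2.data["log_cpue"] += 10.0
        res2 = CPUEModel(frame2).fit(lambdas=lam)
        pe1 = res1.partial_effects("depth_mean")
        pe2 = res2.partial_effects("depth_mean")
        np.testing.assert_allclose(pe1["effect"], pe2["effect"], atol=1e-8)
        assert res2.params[0] - res1.params[0] == pytest.approx(10.0, abs=1e-6)

    def test_duplicated_rows_same_shapes_at_matched_lambda(self):
        frame = simulate_model_frame(n=300, seed=13)
        res1 = CPUEModel(frame).fit()
        doubled = simulate_model_frame(n=300, seed=13)
        doubled.data = pd.concat([doubled.data, doubled.data],
                                 ignore_index=True)
        res2 = CPUEModel(doubled).fit(lambdas=2.0 * res1.lambdas)
        pe1 = res1.partial_effects("complexity_mean")
        pe2 = res2.partial_effects("complexity_mean")
        np.testing.assert_allclose(pe1["effect"], pe2["effect"], atol=1e-8)

    def test_constant_covariate_degrades_gracefully(self):
        frame = simulate_model_frame(n=200, seed=15)
        frame.data["bpi_mean"] = 1.0
        res = CPUEModel(frame).fit()
        tbl = res.term_table
        assert (tbl.loc[tbl["term"] == "bpi_mean", "type"] == "dropped").all()

    def test_report_and_summary_roundtrip(self, tmp_path):
        frame = simulate_model_frame(n=200, seed=17)
        res = CPUEModel(frame).fit()
        doc = res.report(tmp_path / "report.json")
        loaded = json.loads((tmp_path / "report.json").read_text())
        assert loaded["n"] == 200
        assert {t["term"] for t in loaded["terms"]} \
            >= {"complexity_mean", "depth_mean", "bpi_mean"}
        assert "AIC" in res.summary()


class TestSelection:
    def test_single_candidate_returned(self):
        frame = simulate_model_frame(n=200, seed=19)
        res = CPUEModel(frame).fit()
        assert select_model([res]) is res

    def test_tie_prefers_fewer_terms(self):
        frame = simulate_model_frame(n=200, seed=21)
        big = CPUEModel(frame).fit()
        small = CPUEModel(frame, smooth_terms=("depth_mean",)).fit()
        small._results.aic = big.aic            # forced tie
        assert select_model([big, small]) is small

    def test_mismatched_responses_rejected(self):
        a = CPUEModel(simulate_model_frame(n=200, seed=23)).fit()
        b = CPUEModel(simulate_model_frame(n=200, seed=24)).fit()
        with pytest.raises(ValueError, match="response"):
            select_model([a, b])

    def test_true_structure_wins_aic(self):
        # response depends on depth only: the depth-only model should win
        wins = 0
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            frame = simulate_model_frame(n=1000, seed=2000 + seed, null=True)
            d = frame.data["depth_mean"].to_numpy()
            frame.data["log_cpue"] = (depth_effect(d)
                                      + rng.normal(0, 0.5, len(d)))
            full = CPUEModel(frame, random=None).fit()
            true = CPUEModel(frame, smooth_terms=("depth_mean",),
                             random=None).fit()
            if select_model([full, true]) is true:
                wins += 1
        assert wins >= 0.8 * n_rep


class TestGenericAdditiveModel:
    def test_linear_term_and_random_intercept(self):
        rng = np.random.default_rng(31)
        n = 400
        x = rng.uniform(-2, 2, n)
        g = rng.choice(list("abcd"), n)
        offs = {"a": 0.5, "b": -0.5, "c": 0.2, "d": -0.2}
        y = 1.5 * x + np.vectorize(offs.get)(g) + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"y": y, "x": x, "g": g})
        res = AdditiveModel(df, "y", [LinearTerm("x"),
                                      RandomIntercept("g")]).fit()
        slope_hat = res.params[1]
        assert slope_hat == pytest.approx(1.5, abs=0.1)
        tbl = res.term_table
        assert tbl.loc[tbl["type"] == "random", "edf"].iloc[0] > 1.0


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_smooth_matches_reference_spline_fit(tmp_path):
    """Fitted smooth vs an independent penalized thin-plate spline fit."""
    rng = np.random.default_rng(77)
    n = 400
    x = rng.uniform(0, 4, n)
    y = 2.0 * np.sin(x) + rng.normal(0, 0.4, n)
    df = pd.DataFrame({"y": y, "x": x})
    res = AdditiveModel(df, "y", [SmoothTerm("x", k=10)]).fit()
    grid = np.linspace(x.min(), x.max(), 50)
    mine = res.partial_effects("x", values=grid)["effect"].to_numpy()
    mine = mine + res.params[0]

    payload = {"x": x.tolist(), "y": y.tolist(), "grid": grid.tolist()}
    (tmp_path / "data.json").write_text(json.dumps(payload))
    script = tmp_path / "oracle.R"
    script.write_text("""
suppressMessages(library(mgcv)); suppressMessages(library(jsonlite))
d <- fromJSON(commandArgs(TRUE)[1])
fit <- gam(y ~ s(x, k = 10), data = data.frame(x = d$x, y = d$y))
pred <- predict(fit, newdata = data.frame(x = d$grid))
cat(toJSON(as.numeric(pred), digits = 12))
""")
    out = subprocess.run(["Rscript", str(script), str(tmp_path / "data.json")],
                         capture_output=True, text=True, check=True)
    ref = np.array(json.loads(out.stdout))
    assert np.corrcoef(mine, ref)[0, 1] > 0.995
    assert np.max(np.abs(mine - ref)) < 0.25
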