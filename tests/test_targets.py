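import numpy as np
import pandas as pd
import pytest

from mirhinge import (
    ExpressionMatrix,
    InteractionTable,
    RegressionProblem,
    build_problem,
    combine_predictions,
    fit_linear_lad,
    fit_piecewise_milp,
    fit_score,
    grid_oracle_piecewise,
    predict_targets,
    znormalize,
)
from mirhinge.targets import FitScore, PiecewiseFit


def _zmat(rows: dict, kind="gene"):
    df = pd.DataFrame.from_dict(rows, orient="index").astype(float)
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return znormalize(ExpressionMatrix(df, kind=kind, unit="arbitrary"))


class TestBuildProblem:
    def _matrices(self, n_mirnas=3, S=10, seed=0):
        rng = np.random.default_rng(seed)
        genes = _zmat({"g": rng.normal(size=S)})
        mirnas = _zmat({f"m{i}": rng.normal(size=S) for i in range(n_mirnas)},
                       kind="miRNA")
        return genes, mirnas

    def test_all_candidates_admitted_under_cap(self):
        genes, mirnas = self._matrices()
        pairs = InteractionTable(pd.DataFrame(
            [("m0", "g"), ("m2", "g")], columns=["mirna", "gene"]))
        p = build_problem("g", pairs, genes, mirnas, k_cap=10)
        assert set(p.mirna_ids) == {"m0", "m2"}
        assert p.X.shape == (10, 2)

    def test_truncation_keeps_most_negative_correlations(self):
        genes, mirnas = self._matrices(n_mirnas=6, S=30, seed=1)
        pairs = InteractionTable(pd.DataFrame(
            [(f"m{i}", "g") for i in range(6)], columns=["mirna", "gene"]))
        p = build_problem("g", pairs, genes, mirnas, k_cap=3)
        y = genes.data.loc["g"].to_numpy()
        rs = {m: np.corrcoef(mirnas.data.loc[m], y)[0, 1]
              for m in mirnas.feature_ids}
        expected = sorted(rs, key=lambda m: (rs[m], m))[:3]
        assert p.mirna_ids == expected

    def test_zero_candidates_gives_skip_marker(self):
        genes, mirnas = self._matrices()
        pairs = InteractionTable(pd.DataFrame(
            [("absent", "g")], columns=["mirna", "gene"]))
        assert build_problem("g", pairs, genes, mirnas) is None

    def test_missing_gene_is_an_error(self):
        genes, mirnas = self._matrices()
        pairs = InteractionTable(pd.DataFrame(
            [("m0", "nope")], columns=["mirna", "gene"]))
        with pytest.raises(KeyError):
            build_problem("nope", pairs, genes, mirnas)


class TestFitScore:
    def _problem(self):
        y = np.array([-1.0, 0.0, 1.0, 2.0])
        return RegressionProblem("g", y, ["m"], np.zeros((4, 1)))

    def test_perfect_fit_scores_one(self):
        p = self._problem()
        fit = PiecewiseFit("g", 0, np.zeros(1), np.zeros(1), np.zeros(1),
                           np.zeros((4, 1), bool), np.zeros(1), 0.0,
                           np.zeros(4))
        s = fit_score(fit, p, tau=0.1)
        assert s.score == 1.0 and s.passes

    def test_median_equivalent_fit_scores_zero(self):
        p = self._problem()
        sae_null = np.abs(p.y - np.median(p.y)).sum()
        fit = PiecewiseFit("g", 0, np.zeros(1), np.zeros(1), np.zeros(1),
                           np.zeros((4, 1), bool), np.zeros(1),
                           float(sae_null), np.zeros(4))
        s = fit_score(fit, p, tau=0.1)
        assert s.score == pytest.approx(0.0)
        assert not s.passes

    def test_half_null_sae_scores_half(self):
        p = self._problem()
        sae_null = np.abs(p.y - np.median(p.y)).sum()
        fit = PiecewiseFit("g", 0, np.zeros(1), np.zeros(1), np.zeros(1),
                           np.zeros((4, 1), bool), np.zeros(1),
                           0.5 * float(sae_null), np.zeros(4))
        assert fit_score(fit, p).score == pytest.approx(0.5)

    def test_constant_response_is_an_error(self):
        p = RegressionProblem("g", np.ones(4), ["m"], np.zeros((4, 1)))
        fit = PiecewiseFit("g", 0, np.zeros(1), np.zeros(1), np.zeros(1),
                           np.zeros((4, 1), bool), np.zeros(1), 0.0,
                           np.zeros(4))
        with pytest.raises(ValueError):
            fit_score(fit, p)


class TestPredictTargets:
    def _fit(self, betas, sae=0.0):
        k = len(betas)
        return PiecewiseFit("g", 0.0, np.array(betas, float), np.zeros(k),
                            np.full(k, 0.1), np.zeros((4, k), bool),
                            np.zeros(k), sae, np.zeros(4))

    def _problem(self, k):
        return RegressionProblem("g", np.array([-1.0, 0, 1, 2]),
                                 [f"m{i}" for i in range(k)], np.zeros((4, k)))

    def test_only_active_slopes_emitted(self):
        fit = self._fit([-2.0, 0.0])
        p = self._problem(2)
        score = FitScore("g", "piecewise", 1.0, True)
        out = predict_targets([(fit, p, score)])
        assert list(out["mirna"]) == ["m0"]
        assert out.iloc[0]["beta"] == -2.0

    def test_failing_fit_emits_nothing(self):
        fit = self._fit([-2.0])
        p = self._problem(1)
        out = predict_targets([(fit, p, FitScore("g", "piecewise", 0.0, False))])
        assert len(out) == 0

    def test_all_zero_slopes_emit_nothing(self):
        fit = self._fit([0.0, 0.0])
        p = self._problem(2)
        out = predict_targets([(fit, p, FitScore("g", "piecewise", 1.0, True))])
        assert len(out) == 0

    def test_non_optimal_fit_excluded(self):
        fit = self._fit([-2.0])
        fit.optimal = False
        p = self._problem(1)
        out = predict_targets([(fit, p, FitScore("g", "piecewise", 1.0, True))])
        assert len(out) == 0


class TestCombinePredictions:
    def _df(self, pairs, model):
        return pd.DataFrame([
            {"mirna": m, "gene": g, "model": model, "beta": -1.0,
             "breakpoint": 0.2 if model == "piecewise" else np.nan,
             "score": 0.5}
            for m, g in pairs])

    def test_disjoint_union(self):
        lin = self._df([("m1", "g1"), ("m1", "g2"), ("m2", "g1")], "linear")
        pw = self._df([("m3", "g3"), ("m3", "g4")], "piecewise")
        out = combine_predictions(lin, pw)
        assert len(out) == 5

    def test_identical_sets_merge_supporting_models(self):
        lin = self._df([("m1", "g1")], "linear")
        pw = self._df([("m1", "g1")], "piecewise")
        out = combine_predictions(lin, pw)
        assert len(out) == 1
        assert out.iloc[0]["models"] == "linear+piecewise"
        assert out.iloc[0]["beta_linear"] == -1.0
        assert out.iloc[0]["beta_piecewise"] == -1.0

    def test_empty_set_is_identity(self):
        pw = self._df([("m1", "g1"), ("m2", "g2")], "piecewise")
        out = combine_predictions(self._df([], "linear"), pw)
        assert set(zip(out["mirna"], out["gene"])) == {("m1", "g1"),
                                                       ("m2", "g2")}

    def test_union_contains_both_inputs(self):
        rng = np.random.default_rng(0)
        pool = [(f"m{i}", f"g{j}") for i in range(4) for j in range(4)]
        lin_pairs = [pool[i] for i in rng.choice(16, 6, replace=False)]
        pw_pairs = [pool[i] for i in rng.choice(16, 6, replace=False)]
        out = combine_predictions(self._df(lin_pairs, "linear"),
                                  self._df(pw_pairs, "piecewise"))
        got = set(zip(out["mirna"], out["gene"]))
        assert got == set(lin_pairs) | set(pw_pairs)
        assert len(out) >= max(len(lin_pairs), len(pw_pairs))


class TestEndToEndFits:
    def test_linear_and_piecewise_agree_on_linear_truth(self):
        rng = np.random.default_rng(42)
        S = 20
        x = rng.normal(size=S)
        y = -1.5 * x
        p = RegressionProblem("g", y, ["m"], x[:, None])
        lin = fit_linear_lad(p)
        pw = fit_piecewise_milp(p)
        oracle = grid_oracle_piecewise(p)
        assert lin.sae == pytest.approx(0.0, abs=1e-8)
        assert pw.sae == pytest.approx(0.0, abs=1e-6)
        assert oracle.sae == pytest.approx(0.0, abs=1e-8)

    def test_cross_validated_score_tracks_signal_strength(self):
        from mirhinge import cross_validated_score
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        strong = RegressionProblem("g", -1.5 * x + rng.normal(0, 0.1, 40),
                                   ["m"], x[:, None])
        null = RegressionProblem("g", rng.normal(size=40), ["m"], x[:, None])
        cv_strong = cross_validated_score(strong, model="linear")
        cv_null = cross_validated_score(null, model="linear")
        assert cv_strong > 0.5
        assert cv_null < cv_strong
        # out-of-sample score never exceeds perfect prediction
        assert cv_strong <= 1.0

    def test_cross_validated_score_preconditions(self):
        from mirhinge import cross_validated_score
        p = RegressionProblem("g", np.zeros(6), ["m"], np.zeros((6, 1)))
        with pytest.raises(ValueError):
            cross_validated_score(p, n_folds=5)
        with pytest.raises(ValueError):
            cross_validated_score(p, model="nope")

    def test_sample_count_preconditions(self):
        p = RegressionProblem("g", np.zeros(3), ["a", "b"], np.zeros((3, 2)))
        with pytest.raises(ValueError):
            fit_linear_lad(p)
        with pytest.raises(ValueError):
            fit_piecewise_milp(p)
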