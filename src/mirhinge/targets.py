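"""Per-gene model fitting, fit scoring and target-pair extraction.

For every gene with candidate regulators (negatively correlated miRNAs) a
regression problem is built on z-scored data, fitted with the linear LAD
model and the piecewise (hinge) model, scored against the constant-median
baseline, and passing fits are turned into (miRNA, gene) target
predictions.  The combined model is the union of the pairs supported by
either single model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import SLOPE_TOL, HingeLADRegressor, LADRegressor, fit_hinge_grid
from .io import ExpressionMatrix, InteractionTable

__all__ = [
    "RegressionProblem",
    "LinearFit",
    "PiecewiseFit",
    "FitScore",
    "build_problem",
    "fit_linear_lad",
    "fit_piecewise_milp",
    "grid_oracle_piecewise",
    "fit_score",
    "cross_validated_score",
    "predict_targets",
    "combine_predictions",
    "run_target_prediction",
]


@dataclass
class RegressionProblem:
    """One gene's regression instance: y over S samples, K candidate miRNAs."""

    gene_id: str
    y: np.ndarray
    mirna_ids: list[str]
    X: np.ndarray  # (S, K), column order matches mirna_ids

    @property
    def n_samples(self) -> int:
        return len(self.y)

    @property
    def n_predictors(self) -> int:
        return len(self.mirna_ids)


@dataclass
class LinearFit:
    gene_id: str
    alpha: float
    beta: np.ndarray
    sae: float
    residuals: np.ndarray
    model: str = "linear"
    optimal: bool = True


@dataclass
class PiecewiseFit:
    gene_id: str
    alpha: float
    beta: np.ndarray
    gamma: np.ndarray
    breakpoints: np.ndarray
    below_threshold: np.ndarray
    big_m: np.ndarray
    sae: float
    residuals: np.ndarray
    model: str = "piecewise"
    optimal: bool = True


@dataclass
class FitScore:
    gene_id: str
    model: str
    score: float
    passes: bool


def build_problem(
    gene_id: str,
    pairs: InteractionTable,
    genes: ExpressionMatrix,
    mirnas: ExpressionMatrix,
    k_cap: int = 10,
) -> RegressionProblem | None:
    """Assemble a gene's problem from its candidate pairs.

    Candidates are ranked by ascending Pearson correlation with the gene
    (most negative first; ties broken by miRNA id) and truncated to
    ``k_cap``.  Returns None when the gene has no usable candidates.
    """
    if gene_id not in genes.data.index:
        raise KeyError(f"gene {gene_id!r} not in expression matrix")
    if list(genes.sample_ids) != list(mirnas.sample_ids):
        raise ValueError("gene and miRNA matrices must share sample order")
    mirna_index = set(mirnas.data.index)
    cand = [m for m in pairs.mirnas_of(gene_id) if m in mirna_index]
    if not cand:
        return None
    y = genes.data.loc[gene_id].to_numpy(dtype=float)
    ranked = []
    for m in cand:
        x = mirnas.data.loc[m].to_numpy(dtype=float)
        r = float(np.corrcoef(x, y)[0, 1])
        ranked.append((r, m))
    ranked.sort(key=lambda t: (t[0], t[1]))
    chosen = [m for _, m in ranked[:k_cap]]
    X = mirnas.data.loc[chosen].to_numpy(dtype=float).T
    return RegressionProblem(gene_id=gene_id, y=y, mirna_ids=chosen, X=X)


def fit_linear_lad(p: RegressionProblem, bound: float = 10.0) -> LinearFit:
    """Fit the sign-constrained linear LAD model (exact LP optimum)."""
    if p.n_samples < p.n_predictors + 2:
        raise ValueError(
            f"{p.gene_id}: {p.n_samples} samples too few for "
            f"{p.n_predictors} predictors"
        )
    est = LADRegressor(bound=bound).fit(p.X, p.y)
    return LinearFit(gene_id=p.gene_id, alpha=est.intercept_, beta=est.coef_,
                     sae=est.sae_, residuals=est.residuals_)


def fit_piecewise_milp(
    p: RegressionProblem,
    bound: float = 10.0,
    time_limit: float = 60.0,
    mip_gap: float = 1e-6,
) -> PiecewiseFit:
    """Fit the piecewise (hinge) LAD model by MILP."""
    if p.n_samples < p.n_predictors + 3:
        raise ValueError(
            f"{p.gene_id}: {p.n_samples} samples too few for "
            f"{p.n_predictors} hinge predictors"
        )
    est = HingeLADRegressor(bound=bound, time_limit=time_limit,
                            mip_gap=mip_gap).fit(p.X, p.y)
    return PiecewiseFit(
        gene_id=p.gene_id,
        alpha=est.intercept_,
        beta=est.coef_,
        gamma=est.offsets_,
        breakpoints=est.breakpoints_,
        below_threshold=est.below_threshold_,
        big_m=est.big_m_,
        sae=est.sae_,
        residuals=est.residuals_,
        optimal=est.optimal_,
    )


def grid_oracle_piecewise(p: RegressionProblem, bound: float = 10.0) -> PiecewiseFit:
    """Breakpoint-enumeration oracle for single-predictor problems."""
    if p.n_predictors != 1:
        raise ValueError("grid oracle handles exactly one predictor")
    best = fit_hinge_grid(p.X[:, 0], p.y, bound=bound)
    beta = np.array([best["beta"]])
    gamma = np.array([best["gamma"]])
    pred = best["alpha"] + np.minimum(0.0, beta[0] * p.X[:, 0] + gamma[0])
    return PiecewiseFit(
        gene_id=p.gene_id,
        alpha=best["alpha"],
        beta=beta,
        gamma=gamma,
        breakpoints=np.array([best["breakpoint"]]),
        below_threshold=(beta[0] * p.X[:, 0] + gamma[0] > 0)[:, None],
        big_m=np.array([np.nan]),
        sae=best["sae"],
        residuals=p.y - pred,
    )


def fit_score(fit, p: RegressionProblem, tau: float = 0.1) -> FitScore:
    """Score a fit against the constant-median baseline.

    score = 1 - SAE / SAE_null with SAE_null = sum_s |y_s - median(y)|;
    1 means exact interpolation, 0 no better than the best constant.
    """
    sae_null = float(np.abs(p.y - np.median(p.y)).sum())
    if sae_null <= 0:
        raise ValueError(f"{p.gene_id}: constant response, cannot score")
    score = 1.0 - fit.sae / sae_null
    return FitScore(gene_id=p.gene_id, model=fit.model, score=score,
                    passes=bool(score >= tau))


def cross_validated_score(
    p: RegressionProblem,
    model: str = "linear",
    n_folds: int = 5,
    bound: float = 10.0,
    time_limit: float = 60.0,
) -> float:
    """Out-of-sample fit score by deterministic k-fold cross-validation.

    Folds are strided sample subsets (fold k = samples k, k+n_folds, ...).
    Each held-out fold is scored as 1 - SAE_test / SAE0_test, where
    SAE0_test uses the training median as the constant baseline; the mean
    over folds is returned.  More conservative than the in-sample score
    for over-parameterised fits.
    """
    if model not in ("linear", "piecewise"):
        raise ValueError(f"unknown model {model!r}")
    S = p.n_samples
    if S < 2 * n_folds:
        raise ValueError(f"{p.gene_id}: too few samples for {n_folds} folds")
    scores = []
    for k in range(n_folds):
        test = np.zeros(S, dtype=bool)
        test[k::n_folds] = True
        if model == "linear":
            est = LADRegressor(bound=bound).fit(p.X[~test], p.y[~test])
        else:
            est = HingeLADRegressor(bound=bound, time_limit=time_limit).fit(
                p.X[~test], p.y[~test])
        sae_test = float(np.abs(p.y[test] - est.predict(p.X[test])).sum())
        sae_null = float(np.abs(p.y[test] - np.median(p.y[~test])).sum())
        if sae_null > 0:
            scores.append(1.0 - sae_test / sae_null)
    if not scores:
        raise ValueError(f"{p.gene_id}: constant response in every fold")
    return float(np.mean(scores))


def predict_targets(fits: list[tuple[object, RegressionProblem, FitScore]]) -> pd.DataFrame:
    """Emit (mirna, gene) pairs from passing fits with active slopes.

    A predictor supports a pair when its slope is strictly below -1e-6
    inside a fit that passes the score threshold and is proven optimal.
    """
    rows = []
    for fit, problem, score in fits:
        if not score.passes or not getattr(fit, "optimal", True):
            continue
        for i, mirna in enumerate(problem.mirna_ids):
            beta = float(fit.beta[i])
            if beta < -SLOPE_TOL:
                bp = float(fit.breakpoints[i]) if fit.model == "piecewise" else np.nan
                rows.append({
                    "mirna": mirna,
                    "gene": problem.gene_id,
                    "model": fit.model,
                    "beta": beta,
                    "breakpoint": bp,
                    "score": score.score,
                })
    return pd.DataFrame(
        rows, columns=["mirna", "gene", "model", "beta", "breakpoint", "score"]
    )


def combine_predictions(linear: pd.DataFrame, piecewise: pd.DataFrame) -> pd.DataFrame:
    """Union of the pairs supported by either model, per-model columns retained."""
    base_cols = ["mirna", "gene", "model", "beta", "breakpoint", "score"]
    linear = linear.reindex(columns=[c for c in base_cols
                                     if c in linear.columns or len(linear) == 0])
    piecewise = piecewise.reindex(
        columns=[c for c in base_cols
                 if c in piecewise.columns or len(piecewise) == 0])
    lin = linear.rename(columns={"beta": "beta_linear", "score": "score_linear"})
    lin = lin.drop(columns=[c for c in ("model", "breakpoint") if c in lin.columns])
    pw = piecewise.rename(columns={"beta": "beta_piecewise",
                                   "score": "score_piecewise"})
    pw = pw.drop(columns=[c for c in ("model",) if c in pw.columns])
    merged = lin.merge(pw, on=["mirna", "gene"], how="outer")
    models = []
    for _, row in merged.iterrows():
        supp = []
        if np.isfinite(row.get("beta_linear", np.nan)):
            supp.append("linear")
        if np.isfinite(row.get("beta_piecewise", np.nan)):
            supp.append("piecewise")
        models.append("+".join(supp))
    merged["models"] = models
    cols = ["mirna", "gene", "models", "beta_linear", "beta_piecewise",
            "breakpoint", "score_linear", "score_piecewise"]
    for c in cols:
        if c not in merged.columns:
            merged[c] = np.nan
    return (merged[cols]
            .sort_values(["mirna", "gene"], kind="mergesort")
            .reset_index(drop=True))


def run_target_prediction(
    genes: ExpressionMatrix,
    mirnas: ExpressionMatrix,
    pairs: InteractionTable,
    model: str = "combined",
    tau: float = 0.1,
    k_cap: int = 10,
    bound: float = 10.0,
    time_limit: float = 60.0,
    per_pair: bool = False,
) -> pd.DataFrame:
    """Fit the requested model(s) for every gene with candidates.

    Genes are processed in sorted order for run-to-run determinism.  With
    ``per_pair=True`` each candidate (miRNA, gene) pair is fitted as its own
    single-predictor problem instead of one joint model per gene.

    Returns the combined prediction table (columns: mirna, gene, models,
    beta_linear, beta_piecewise, breakpoint, score_linear, score_piecewise);
    for ``model='linear'`` or ``'piecewise'`` the other model's columns are
    NaN.
    """
    if model not in ("linear", "piecewise", "combined"):
        raise ValueError(f"unknown model {model!r}")
    lin_fits: list[tuple[object, RegressionProblem, FitScore]] = []
    pw_fits: list[tuple[object, RegressionProblem, FitScore]] = []

    problems: list[RegressionProblem] = []
    for gene in sorted(set(pairs.data["gene"])):
        if gene not in genes.data.index:
            continue
        problem = build_problem(gene, pairs, genes, mirnas, k_cap=k_cap)
        if problem is None:
            continue
        if per_pair:
            for i, m in enumerate(problem.mirna_ids):
                problems.append(RegressionProblem(
                    gene_id=gene, y=problem.y, mirna_ids=[m],
                    X=problem.X[:, [i]]))
        else:
            problems.append(problem)

    for problem in problems:
        if model in ("linear", "combined"):
            fit = fit_linear_lad(problem, bound=bound)
            lin_fits.append((fit, problem, fit_score(fit, problem, tau)))
        if model in ("piecewise", "combined"):
            fit = fit_piecewise_milp(problem, bound=bound,
                                     time_limit=time_limit)
            pw_fits.append((fit, problem, fit_score(fit, problem, tau)))

    lin_preds = predict_targets(lin_fits)
    pw_preds = predict_targets(pw_fits)
    if per_pair:
        # a gene may appear in several single-pair problems; keep best score
        for df in (lin_preds, pw_preds):
            if len(df):
                df.sort_values(["mirna", "gene", "score"], inplace=True,
                               kind="mergesort")
                df.drop_duplicates(subset=["mirna", "gene"], keep="last",
                                   inplace=True)
    return combine_predictions(lin_preds, pw_preds)
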