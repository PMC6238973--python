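"""Reproducible benchmark protocols for the regression core.

Three desk-scale experiments, each a pure function of a seed:

* :func:`oracle_equivalence` — random single-predictor problems fitted
  with the MILP and the independent pattern-enumeration oracle, plus the
  nested linear model, to verify exact agreement and the nesting bound.
* :func:`hinge_recovery` — slope/breakpoint recovery on noise-free and
  noisy threshold-repression data.
* :func:`model_comparison` — full pipeline runs on hinge-structured
  synthetic data comparing linear, piecewise and combined predictions by
  transfection-list enrichment and recovery of the true pairs.

The model-comparison generator places breakpoints in the upper quantiles
of the regulator distribution (0.55-0.85): repression that only engages at
high miRNA abundance is the regime the piecewise model exists for, and the
regime where a straight line genuinely misses targets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimators import HingeLADRegressor, fit_hinge_grid
from .preprocessing import correlation_filter, znormalize
from .simulate import SimulationConfig, generate_dataset, score_recovery, simulate_transfection
from .targets import RegressionProblem, fit_linear_lad, fit_piecewise_milp, run_target_prediction
from .transfection import compare_model_performance, enrichment_vs_transfection

__all__ = ["oracle_equivalence", "hinge_recovery", "comparison_config",
           "model_comparison"]


def _random_problem(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One random single-predictor problem: hinge, linear or pure noise."""
    S = int(rng.integers(8, 41))
    x = rng.normal(size=S)
    kind = rng.integers(0, 3)
    if kind == 0:  # hinge
        b = float(np.quantile(x, rng.uniform(0.25, 0.75)))
        y = rng.uniform(-2.5, -0.5) * np.maximum(0.0, x - b) \
            + rng.normal(0, rng.uniform(0.0, 0.4), S)
    elif kind == 1:  # linear (possibly positive trend, slope then clamps to 0)
        y = rng.uniform(-2.0, 1.0) * x + rng.normal(0, rng.uniform(0.0, 0.4), S)
    else:  # unrelated
        y = rng.normal(size=S)
    return x, y


def oracle_equivalence(seed: int, n_problems: int = 200,
                       time_limit: float = 30.0) -> pd.DataFrame:
    """Fit MILP, grid oracle and linear LAD on random problems.

    Returns one row per problem with sae_milp, sae_grid and sae_linear.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_problems):
        x, y = _random_problem(rng)
        problem = RegressionProblem(gene_id=f"p{i}", y=y, mirna_ids=["m"],
                                    X=x[:, None])
        milp_fit = HingeLADRegressor(time_limit=time_limit).fit(x[:, None], y)
        grid = fit_hinge_grid(x, y)
        lin = fit_linear_lad(problem)
        rows.append({
            "problem": i,
            "n_samples": len(x),
            "sae_milp": milp_fit.sae_,
            "sae_grid": grid["sae"],
            "sae_linear": lin.sae,
            "optimal": milp_fit.optimal_,
        })
    return pd.DataFrame(rows)


def hinge_recovery(seed: int, n_noise_free: int = 10, n_noisy: int = 50,
                   n_samples: int = 100, noise_sd: float = 0.1,
                   time_limit: float = 30.0) -> dict:
    """Slope/breakpoint recovery on synthetic threshold-repression data.

    Noise-free problems place the breakpoint strictly inside the observed
    range with at least 3 samples per side, so exact interpolation pins the
    parameters; noisy problems measure the median absolute breakpoint
    error.
    """
    rng = np.random.default_rng(seed)

    def _draw(S: int, sd: float):
        while True:
            x = rng.normal(size=S)
            b = float(np.quantile(x, rng.uniform(0.3, 0.7)))
            if min((x > b).sum(), (x <= b).sum()) >= 3:
                break
        slope = float(rng.uniform(-2.5, -0.8))
        alpha = float(rng.uniform(-1, 1))
        y = alpha + slope * np.maximum(0.0, x - b)
        if sd > 0:
            y = y + rng.normal(0, sd, S)
        return x, y, slope, b

    nf_beta_err, nf_bp_err = [], []
    for _ in range(n_noise_free):
        x, y, slope, b = _draw(20, 0.0)
        est = HingeLADRegressor(time_limit=time_limit).fit(x[:, None], y)
        nf_beta_err.append(abs(est.coef_[0] - slope))
        nf_bp_err.append(abs(est.breakpoints_[0] - b))

    noisy_bp_err = []
    for _ in range(n_noisy):
        x, y, slope, b = _draw(n_samples, noise_sd)
        est = HingeLADRegressor(time_limit=time_limit).fit(x[:, None], y)
        noisy_bp_err.append(abs(est.breakpoints_[0] - b))

    return {
        "noise_free_max_beta_error": float(np.max(nf_beta_err)),
        "noise_free_max_breakpoint_error": float(np.max(nf_bp_err)),
        "noisy_median_breakpoint_error": float(np.median(noisy_bp_err)),
        "n_noise_free": n_noise_free,
        "n_noisy": n_noisy,
    }


def comparison_config(seed: int) -> SimulationConfig:
    """Study conditions for the linear-vs-piecewise comparison runs."""
    return SimulationConfig(
        n_samples=120,
        n_mirnas=4,
        n_genes=8,
        regulators_per_gene=1,
        regulated_fraction=1.0,
        hinge_fraction=1.0,
        regulation_density=0.35,
        breakpoint_quantile_range=(0.55, 0.85),
        noise_sd=0.3,
        transfection_fn=0.1,
        transfection_fp=0.05,
        seed=seed,
    )


def model_comparison(seed: int, n_seeds: int = 20, tau: float = 0.1,
                     time_limit: float = 30.0) -> pd.DataFrame:
    """Linear vs piecewise vs combined over replicated synthetic studies.

    Each replicate generates hinge-structured data, runs the preprocessing
    and per-pair fits for both models, scores every transfection
    experiment's enrichment, and records per-model win counts (smaller
    enrichment p wins, ties credited to both) and recall of the true
    regulations.  Returns one row per replicate.
    """
    base = np.random.SeedSequence(seed).generate_state(n_seeds, dtype=np.uint32)
    rows = []
    for rep in range(n_seeds):
        cfg = comparison_config(int(base[rep]) % (2**31))
        genes, mirnas, pairs, truth = generate_dataset(cfg)
        gz, mz = znormalize(genes), znormalize(mirnas)
        kept, _ = correlation_filter(pairs, gz, mz)
        preds = {
            model: run_target_prediction(
                gz, mz, kept, model=model, tau=tau, per_pair=True,
                time_limit=time_limit)
            for model in ("linear", "piecewise")
        }
        nonempty = [df for df in preds.values() if len(df)]
        combined = (
            pd.concat(nonempty, ignore_index=True)
            .drop_duplicates(subset=["mirna", "gene"])
            .reset_index(drop=True)
        ) if nonempty else preds["linear"]
        experiments = simulate_transfection(truth, cfg)
        stats = {
            model: [enrichment_vs_transfection(df, e, model=model)
                    for e in experiments]
            for model, df in (("linear", preds["linear"]),
                              ("piecewise", preds["piecewise"]),
                              ("combined", combined))
        }
        table = compare_model_performance(
            {"linear": stats["linear"], "piecewise": stats["piecewise"]})
        wins = table.attrs["wins"]
        rows.append({
            "replicate": rep,
            "n_experiments": len(experiments),
            "wins_linear": wins["linear"],
            "wins_piecewise": wins["piecewise"],
            "recall_linear": score_recovery(preds["linear"], truth)["recall"],
            "recall_piecewise": score_recovery(preds["piecewise"], truth)["recall"],
            "recall_combined": score_recovery(combined, truth)["recall"],
        })
    return pd.DataFrame(rows)
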