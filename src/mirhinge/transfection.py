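"""Validation of predicted targets against miRNA transfection experiments.

Forced over-expression of a miRNA in a cell line yields an empirical list
of down-regulated genes.  Predicted targets of that miRNA are tested for
over-representation in the list with an exact upper-tail hypergeometric
test on the experiment's own measured universe; precision is reported
alongside.  A second screen tests candidate (miRNA, protein) pairs for
inverse correlation and compares candidate correlations against the
background of all other pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = [
    "TransfectionExperiment",
    "EnrichmentStat",
    "enrichment_vs_transfection",
    "compare_model_performance",
    "inverse_correlation_screen",
    "correlation_background_test",
]


@dataclass
class TransfectionExperiment:
    mirna_id: str
    downregulated_genes: set[str]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.downregulated_genes <= self.universe:
            extra = sorted(self.downregulated_genes - self.universe)[:3]
            raise ValueError(
                f"{self.mirna_id}: down-regulated genes outside universe: {extra}"
            )


@dataclass
class EnrichmentStat:
    mirna_id: str
    model: str
    k: int            # overlap
    n_pred: int       # predictions inside the universe
    n_down: int
    n_universe: int
    p: float
    precision: float | None


def enrichment_vs_transfection(
    predictions: pd.DataFrame,
    experiment: TransfectionExperiment,
    model: str = "combined",
) -> EnrichmentStat:
    """Upper-tail hypergeometric enrichment of predictions in the down list.

    Predictions are first restricted to the experiment's miRNA and to genes
    inside its measured universe.  With zero usable predictions p = 1 and
    precision is undefined (None).
    """
    mask = predictions["mirna"] == experiment.mirna_id
    predicted = set(predictions.loc[mask, "gene"]) & experiment.universe
    n_pred = len(predicted)
    n_down = len(experiment.downregulated_genes)
    N = len(experiment.universe)
    k = len(predicted & experiment.downregulated_genes)
    if n_pred == 0:
        return EnrichmentStat(experiment.mirna_id, model, 0, 0, n_down, N,
                              1.0, None)
    # P(X >= k) for X ~ Hypergeom(N, n_down, n_pred)
    p = float(stats.hypergeom.sf(k - 1, N, n_down, n_pred))
    return EnrichmentStat(experiment.mirna_id, model, k, n_pred, n_down, N,
                          p, k / n_pred)


def compare_model_performance(
    stats_by_model: dict[str, list[EnrichmentStat]],
) -> pd.DataFrame:
    """Per-experiment winner by smaller enrichment p; ties credited to both.

    ``stats_by_model`` maps model label -> one EnrichmentStat per experiment
    (same experiments, same order, for every model).  Returns a table with
    one row per experiment plus per-model win counts in ``.attrs['wins']``.
    """
    models = list(stats_by_model)
    lengths = {len(v) for v in stats_by_model.values()}
    if len(lengths) != 1:
        raise ValueError("every model must cover the same experiments")
    rows = []
    wins = {m: 0 for m in models}
    n_exp = lengths.pop()
    for i in range(n_exp):
        per = {m: stats_by_model[m][i] for m in models}
        best_p = min(st.p for st in per.values())
        winners = [m for m, st in per.items() if st.p == best_p]
        for m in winners:
            wins[m] += 1
        row = {"mirna": per[models[0]].mirna_id,
               "winner": "tie" if len(winners) == len(models) else "+".join(winners)}
        for m, st in per.items():
            row[f"p_{m}"] = st.p
            row[f"precision_{m}"] = st.precision
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["wins"] = wins
    return out


def inverse_correlation_screen(
    mirnas: ExpressionMatrix,
    proteins: ExpressionMatrix,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Per-pair Pearson correlation with a lower-tail p (r < 0).

    p comes from the t-transform of r with n-2 degrees of freedom.  Pairs
    with a constant member have undefined correlation and are flagged
    (r, p = NaN).
    """
    shared = [s for s in mirnas.sample_ids if s in set(proteins.sample_ids)]
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared samples, got {len(shared)}")
    mi = mirnas.data[shared]
    pr = proteins.data[shared]
    rows = []
    for mirna, protein in pairs:
        x = mi.loc[mirna].to_numpy(dtype=float)
        y = pr.loc[protein].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"mirna": mirna, "protein": protein,
                         "pearson_r": np.nan, "p": np.nan, "n": len(shared),
                         "flag": "constant"})
            continue
        res = stats.pearsonr(x, y, alternative="less")
        rows.append({"mirna": mirna, "protein": protein,
                     "pearson_r": float(res.statistic), "p": float(res.pvalue),
                     "n": len(shared), "flag": ""})
    return pd.DataFrame(rows)


def correlation_background_test(
    candidate_rs: np.ndarray, background_rs: np.ndarray
) -> dict:
    """One-sided two-sample Student's t-test: candidates lower than background."""
    cand = np.asarray(candidate_rs, dtype=float)
    back = np.asarray(background_rs, dtype=float)
    if len(cand) < 2 or len(back) < 2:
        raise ValueError("both samples need n >= 2")
    if np.ptp(cand) == 0 and np.ptp(back) == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(cand, back, equal_var=True, alternative="less")
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "n_candidates": len(cand), "n_background": len(back)}
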