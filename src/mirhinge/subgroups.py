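"""Molecular-subgroup analysis: one-vs-rest differential expression,
opposed-direction pair selection and directional mean-statistic GSEA.

Differential expression uses a two-sided equal-variance Student's t-test
per feature with Benjamini-Hochberg correction across the matrix.  The
enrichment step scores each gene set by the mean of its members' signed
statistics against a gene-randomization null (random same-size subsets of
the universe), with separate upper/lower-tail ("distinct directional")
p-values, each BH-adjusted across sets.  Small universes are enumerated
exhaustively, giving exact permutation p-values.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "differential_expression_one_vs_rest",
    "benjamini_hochberg",
    "select_opposed_pairs",
    "gsea_mean_statistic",
    "count_enrichment_summary",
]


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression_one_vs_rest(
    m: ExpressionMatrix,
    labels: dict[str, str],
    group: str,
) -> pd.DataFrame:
    """Per-feature t-test of one subgroup against all other labeled samples.

    ``labels`` maps sample id -> subgroup name; samples without a label are
    ignored.  Returns a table with columns feature_id, group, mean_in,
    mean_out, t, p, q (BH across all features), direction (up/down by sign
    of mean_in - mean_out).
    """
    labeled = [s for s in m.sample_ids if s in labels]
    groups = {labels[s] for s in labeled}
    if group not in groups:
        raise ValueError(f"group {group!r} absent from labels")
    in_ids = [s for s in labeled if labels[s] == group]
    out_ids = [s for s in labeled if labels[s] != group]
    if len(in_ids) < 2 or len(out_ids) < 2:
        raise ValueError("need >= 2 samples in the group and its complement")
    a = m.data[in_ids].to_numpy(dtype=float)
    b = m.data[out_ids].to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    # identical groups give 0/0 -> no evidence
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    mean_in = a.mean(axis=1)
    mean_out = b.mean(axis=1)
    return pd.DataFrame({
        "feature_id": m.feature_ids,
        "group": group,
        "mean_in": mean_in,
        "mean_out": mean_out,
        "t": t,
        "p": p,
        "q": benjamini_hochberg(p),
        "direction": np.where(mean_in - mean_out >= 0, "up", "down"),
    })


def select_opposed_pairs(
    mirna_de: pd.DataFrame,
    gene_de: pd.DataFrame,
    predictions: pd.DataFrame,
    subgroup: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Predicted pairs whose members are both significant with opposite direction.

    Keeps pairs where the miRNA and the gene each have BH-adjusted p <=
    ``alpha`` in the subgroup's one-vs-rest tests and their directions are
    opposed (miRNA up with gene down, or vice versa).
    """
    mi = mirna_de.set_index("feature_id")
    ge = gene_de.set_index("feature_id")
    rows = []
    for row in predictions.itertuples(index=False):
        if row.mirna not in mi.index or row.gene not in ge.index:
            continue
        mrec, grec = mi.loc[row.mirna], ge.loc[row.gene]
        if mrec["q"] <= alpha and grec["q"] <= alpha \
                and mrec["direction"] != grec["direction"]:
            rows.append({
                "mirna": row.mirna,
                "gene": row.gene,
                "subgroup": subgroup,
                "mirna_direction": mrec["direction"],
                "gene_direction": grec["direction"],
            })
    return pd.DataFrame(rows, columns=["mirna", "gene", "subgroup",
                                       "mirna_direction", "gene_direction"])


def gsea_mean_statistic(
    gene_stats: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 50_000,
    rng_seed: int = 0,
    exhaustive_limit: int = 10_000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Directional mean-statistic gene set enrichment with a permutation null.

    The set statistic is the mean of the member genes' signed statistics.
    The null draws random gene subsets of the same size from the universe;
    when C(|universe|, set size) <= ``exhaustive_limit`` all subsets are
    enumerated and the p-values are exact, otherwise they are Monte-Carlo
    estimates with a +1 pseudocount: p = (1 + #{null >= obs}) / (n_perm+1).
    Upper- and lower-tail p-values are BH-adjusted separately across sets;
    a set is significant when either adjusted tail is <= ``alpha``.
    """
    if not np.isfinite(gene_stats.to_numpy(dtype=float)).all():
        raise ValueError("gene statistics must be finite")
    if n_perm < 100:
        import warnings
        warnings.warn(f"n_perm={n_perm} is very low for permutation p-values")
    universe = gene_stats.index
    values = gene_stats.to_numpy(dtype=float)
    n = len(universe)
    rng = np.random.default_rng(rng_seed)
    eps = 1e-12

    rows = []
    for name in sets:
        gs = sets[name]
        members = [g for g in gs.members if g in gene_stats.index]
        k = len(members)
        if k < 1:
            continue
        observed = float(gene_stats.loc[members].mean())
        if comb(n, k) <= exhaustive_limit:
            null = np.array([values[list(idx)].mean()
                             for idx in combinations(range(n), k)])
            total = len(null)
            p_up = float((null >= observed - eps).sum()) / total
            p_dn = float((null <= observed + eps).sum()) / total
            mode = "exhaustive"
        else:
            null = np.empty(n_perm)
            for j in range(n_perm):
                null[j] = values[rng.choice(n, size=k, replace=False)].mean()
            p_up = (1.0 + float((null >= observed - eps).sum())) / (n_perm + 1.0)
            p_dn = (1.0 + float((null <= observed + eps).sum())) / (n_perm + 1.0)
            mode = "montecarlo"
        rows.append({
            "set_name": name,
            "category": gs.category,
            "n_members": k,
            "set_statistic": observed,
            "null_mode": mode,
            "p_distinct_dir_up": p_up,
            "p_distinct_dir_dn": p_dn,
        })
    out = pd.DataFrame(rows, columns=["set_name", "category", "n_members",
                                      "set_statistic", "null_mode",
                                      "p_distinct_dir_up", "p_distinct_dir_dn"])
    if len(out):
        out["q_distinct_dir_up"] = benjamini_hochberg(out["p_distinct_dir_up"])
        out["q_distinct_dir_dn"] = benjamini_hochberg(out["p_distinct_dir_dn"])
        out["significant"] = (out[["q_distinct_dir_up", "q_distinct_dir_dn"]]
                              .min(axis=1) <= alpha)
    else:
        out["q_distinct_dir_up"] = []
        out["q_distinct_dir_dn"] = []
        out["significant"] = []
    return out


def count_enrichment_summary(
    opposed_pairs: pd.DataFrame,
    gsea_results: pd.DataFrame,
    sets: GeneSetCollection | None = None,
) -> dict:
    """Per-subgroup counts and a top-set listing.

    Returns a dict with the number of up/down miRNAs among the opposed
    pairs, the number of significantly enriched sets per direction, and
    (when ``sets`` is given) a per-set table counting distinct regulating
    miRNAs and distinct targeted genes among the opposed pairs, ordered by
    (#miRNAs, #genes) descending.
    """
    n_mirnas_up = opposed_pairs.loc[
        opposed_pairs.get("mirna_direction", pd.Series(dtype=str)) == "up",
        "mirna"].nunique() if len(opposed_pairs) else 0
    n_mirnas_down = opposed_pairs.loc[
        opposed_pairs.get("mirna_direction", pd.Series(dtype=str)) == "down",
        "mirna"].nunique() if len(opposed_pairs) else 0
    if len(gsea_results):
        sig = gsea_results[gsea_results["significant"]]
        n_sets_up = int((sig["q_distinct_dir_up"]
                         <= sig["q_distinct_dir_dn"]).sum())
        n_sets_down = int(len(sig) - n_sets_up)
    else:
        n_sets_up = n_sets_down = 0
    summary = {
        "n_mirnas_up": int(n_mirnas_up),
        "n_mirnas_down": int(n_mirnas_down),
        "n_enriched_sets_up": n_sets_up,
        "n_enriched_sets_down": n_sets_down,
    }
    if sets is not None:
        rows = []
        for name in sets:
            members = set(sets[name].members)
            hits = opposed_pairs[opposed_pairs["gene"].isin(members)] \
                if len(opposed_pairs) else opposed_pairs
            rows.append({
                "set_name": name,
                "n_mirnas": hits["mirna"].nunique() if len(hits) else 0,
                "n_genes": hits["gene"].nunique() if len(hits) else 0,
            })
        table = pd.DataFrame(rows).sort_values(
            ["n_mirnas", "n_genes", "set_name"],
            ascending=[False, False, True], kind="mergesort",
        ).reset_index(drop=True)
        summary["top_sets"] = table
    return summary
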