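"""Tumor/stroma cell-type refinement and binding-site integration.

Expression datasets with samples sorted into tumor cells and stromal cells
(or tumor-associated fibroblasts) are tested feature-wise for differential
expression (paired t-test when patient pairing is available, unpaired
equal-variance otherwise; direction "up" = higher in stroma).  Candidate
target genes are kept when stroma-up in at least one gene-level dataset;
candidate miRNAs when significantly stroma-down in every miRNA-level
dataset where tested, or among the top-k strongest stroma-down in any one.
Surviving (miRNA, gene) combinations absent from the model predictions are
rescued when at least one binding-site prediction tool reports a site,
yielding the final candidate table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .subgroups import benjamini_hochberg

__all__ = [
    "CellTypeDataset",
    "RefinedSet",
    "celltype_differential_expression",
    "overlap_enrichment",
    "refine_candidates",
    "integrate_binding_sites",
    "summarize_candidates",
]


@dataclass
class CellTypeDataset:
    """One tumor-vs-stroma expression dataset (gene- or miRNA-level)."""

    name: str
    expression: ExpressionMatrix
    cell_type: dict[str, str]  # sample id -> "tumor" | "stroma"
    patient: dict[str, str] | None = None  # optional pairing

    def __post_init__(self) -> None:
        types = {self.cell_type.get(s) for s in self.expression.sample_ids}
        if not {"tumor", "stroma"} <= types:
            raise ValueError(f"{self.name}: need both tumor and stroma samples")
        if self.patient is not None:
            seen: dict[tuple[str, str], str] = {}
            for s in self.expression.sample_ids:
                key = (self.patient[s], self.cell_type[s])
                if key in seen:
                    raise ValueError(
                        f"{self.name}: patient {key[0]} has two {key[1]} samples"
                    )
                seen[key] = s


@dataclass
class RefinedSet:
    genes: set[str]
    mirnas: set[str]
    pairs: pd.DataFrame  # surviving model-predicted pairs (mirna, gene)


def celltype_differential_expression(d: CellTypeDataset) -> pd.DataFrame:
    """Stroma-vs-tumor differential expression for one dataset.

    Paired t-test over patients contributing both cell types when pairing
    information is available, otherwise an unpaired equal-variance t-test.
    Returns feature_id, dataset, mode, mean_stroma, mean_tumor, t, p,
    q (BH), direction ("up" = higher in stroma).
    """
    stroma_ids = [s for s in d.expression.sample_ids
                  if d.cell_type.get(s) == "stroma"]
    tumor_ids = [s for s in d.expression.sample_ids
                 if d.cell_type.get(s) == "tumor"]
    if not stroma_ids or not tumor_ids:
        raise ValueError(f"{d.name}: a cell type has no samples")
    if d.patient is not None:
        by_patient_s = {d.patient[s]: s for s in stroma_ids}
        by_patient_t = {d.patient[s]: s for s in tumor_ids}
        patients = sorted(set(by_patient_s) & set(by_patient_t))
        if len(patients) < 2:
            raise ValueError(f"{d.name}: need >= 2 complete pairs")
        a = d.expression.data[[by_patient_s[p] for p in patients]].to_numpy()
        b = d.expression.data[[by_patient_t[p] for p in patients]].to_numpy()
        t, p = stats.ttest_rel(a, b, axis=1)
        mode = "paired"
    else:
        if len(stroma_ids) < 2 or len(tumor_ids) < 2:
            raise ValueError(f"{d.name}: need >= 2 samples per cell type")
        a = d.expression.data[stroma_ids].to_numpy()
        b = d.expression.data[tumor_ids].to_numpy()
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
        mode = "unpaired"
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    mean_s = a.mean(axis=1)
    mean_t = b.mean(axis=1)
    return pd.DataFrame({
        "feature_id": d.expression.feature_ids,
        "dataset": d.name,
        "mode": mode,
        "mean_stroma": mean_s,
        "mean_tumor": mean_t,
        "t": t,
        "p": p,
        "q": benjamini_hochberg(p),
        "direction": np.where(mean_s - mean_t >= 0, "up", "down"),
    })


def overlap_enrichment(candidates: set[str], stroma_up: set[str],
                       universe: set[str]) -> float:
    """Exact upper-tail hypergeometric p for the candidate/stroma-up overlap."""
    if not universe:
        raise ValueError("empty universe")
    if not candidates <= universe or not stroma_up <= universe:
        raise ValueError("candidates and stroma_up must lie inside the universe")
    N = len(universe)
    k = len(candidates & stroma_up)
    return float(stats.hypergeom.sf(k - 1, N, len(stroma_up), len(candidates)))


def refine_candidates(
    candidate_pairs: pd.DataFrame,
    gene_de: list[pd.DataFrame],
    mirna_de: list[pd.DataFrame],
    q_threshold: float = 0.05,
    top_k: int = 5,
) -> RefinedSet:
    """Apply the cell-type refinement rule to candidate pairs.

    Genes survive when significantly stroma-up (q <= threshold, direction
    up) in at least one gene-level dataset.  MiRNAs survive when
    significantly stroma-down in every miRNA-level dataset where they were
    measured, or ranked among the ``top_k`` strongest stroma-down features
    (most negative t) in any single dataset.  Pairs survive when both
    members do.
    """
    if not gene_de or not mirna_de:
        raise ValueError("need >= 1 gene-level and >= 1 miRNA-level DE table")
    cand_genes = set(candidate_pairs["gene"])
    cand_mirnas = set(candidate_pairs["mirna"])

    genes_kept: set[str] = set()
    for de in gene_de:
        hits = de[(de["direction"] == "up") & (de["q"] <= q_threshold)]
        genes_kept |= cand_genes & set(hits["feature_id"])

    sig_down_everywhere: set[str] = set()
    for m in sorted(cand_mirnas):
        tested = [de for de in mirna_de
                  if m in set(de["feature_id"])]
        if not tested:
            continue
        ok = all(
            ((de.set_index("feature_id").loc[m, "direction"] == "down")
             and (de.set_index("feature_id").loc[m, "q"] <= q_threshold))
            for de in tested
        )
        if ok:
            sig_down_everywhere.add(m)
    top_down_anywhere: set[str] = set()
    for de in mirna_de:
        down = de[de["direction"] == "down"].sort_values(
            ["t", "feature_id"], kind="mergesort")
        top_down_anywhere |= cand_mirnas & set(down["feature_id"].head(top_k))

    mirnas_kept = sig_down_everywhere | top_down_anywhere
    pairs = candidate_pairs[
        candidate_pairs["gene"].isin(genes_kept)
        & candidate_pairs["mirna"].isin(mirnas_kept)
    ][["mirna", "gene"]].drop_duplicates().reset_index(drop=True)
    return RefinedSet(genes=genes_kept, mirnas=mirnas_kept, pairs=pairs)


def integrate_binding_sites(
    refined: RefinedSet,
    predictions: pd.DataFrame,
    sites: pd.DataFrame,
    gene_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Build the final candidate table over refined miRNAs x refined genes.

    A combination present in the model predictions is labeled
    ``combined_model``; one absent from the predictions is added with label
    ``binding_site`` iff at least one prediction tool reports a site
    (``sites`` columns: tool, mirna, gene).  Output columns are mirna,
    gene_symbol, gene_name, identification_method, sorted by (mirna,
    method, gene).
    """
    pred_pairs = set(zip(predictions["mirna"], predictions["gene"]))
    site_pairs = set(zip(sites["mirna"], sites["gene"])) if len(sites) else set()
    names = gene_names or {}
    rows = []
    for mirna in sorted(refined.mirnas):
        for gene in sorted(refined.genes):
            if (mirna, gene) in pred_pairs:
                method = "combined_model"
            elif (mirna, gene) in site_pairs:
                method = "binding_site"
            else:
                continue
            rows.append({
                "mirna": mirna,
                "gene_symbol": gene,
                "gene_name": names.get(gene, ""),
                "identification_method": method,
            })
    out = pd.DataFrame(rows, columns=["mirna", "gene_symbol", "gene_name",
                                      "identification_method"])
    return out.sort_values(
        ["mirna", "identification_method", "gene_symbol"], kind="mergesort"
    ).reset_index(drop=True)


def summarize_candidates(table: pd.DataFrame) -> dict:
    """Counts of candidate pairs per identification method and per miRNA."""
    if len(table):
        by_method = table["identification_method"].value_counts().to_dict()
        by_mirna = table["mirna"].value_counts().to_dict()
    else:
        by_method, by_mirna = {}, {}
    return {
        "n_total": int(len(table)),
        "n_combined_model": int(by_method.get("combined_model", 0)),
        "n_binding_site": int(by_method.get("binding_site", 0)),
        "per_mirna": {k: int(v) for k, v in sorted(by_mirna.items())},
    }
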