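"""Synthetic matched miRNA/gene expression with known regulatory structure.

The generator emulates the study conditions end to end: threshold-type
(hinge) and linear repression of genes by miRNAs with known slopes and
breakpoints, molecular-subgroup shifts of selected miRNAs (their targets
shift oppositely through the regulation itself), tumor/stroma cell-type
datasets with stroma-up genes and stroma-down miRNAs, and noisy
transfection readouts.  Everything is a pure function of the configuration
(including its seed), so reruns are bit-identical.

MiRNA values are drawn standard normal per sample, i.e. the simulated data
live on the z-score scale and enter the pipeline post-normalization; a raw
mode wraps them into RPKM-like positive values (with a few all-zero
features) solely to exercise the raw-input filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, InteractionTable
from .stroma import CellTypeDataset
from .transfection import TransfectionExperiment

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_raw_dataset",
    "simulate_transfection",
    "simulate_celltype_profiles",
    "score_recovery",
]


@dataclass
class SimulationConfig:
    """Knobs of the generative model (defaults mirror the study conditions).

    ``regulation_density`` is the fraction of the miRNA x gene grid present
    in the candidate interaction table; true pairs are topped up with
    decoys (no effect) to reach it.  ``hinge_fraction`` is the share of
    true regulations that are threshold-type rather than purely linear;
    breakpoints are drawn inside ``breakpoint_quantile_range`` of the
    regulator's empirical distribution so both segments are populated.
    """

    n_samples: int = 120
    n_mirnas: int = 15
    n_genes: int = 60
    regulators_per_gene: int = 1
    regulated_fraction: float = 0.8
    regulation_density: float = 0.03
    hinge_fraction: float = 0.7
    breakpoint_quantile_range: tuple[float, float] = (0.3, 0.7)
    slope_range: tuple[float, float] = (-2.5, -0.8)
    noise_sd: float = 0.3
    baseline_sd: float = 0.0
    # subgroup structure: name -> (sample share, [(mirna index, shift), ...])
    subgroups: dict[str, tuple[float, list[tuple[int, float]]]] | None = None
    # cell-type structure
    n_stroma: int = 20
    n_tumor: int = 20
    celltype_effect: float = 3.0
    celltype_noise_sd: float = 1.0
    paired_celltypes: bool = False
    # transfection readout noise
    transfection_fn: float = 0.0
    transfection_fp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_mirnas, self.n_genes) <= 0:
            raise ValueError("counts must be positive")
        for lo, hi in (self.breakpoint_quantile_range,):
            if not 0 <= lo < hi <= 1:
                raise ValueError("breakpoint quantile range must be ordered in [0,1]")
        if not (0 <= self.regulation_density <= 1
                and 0 <= self.hinge_fraction <= 1
                and 0 <= self.regulated_fraction <= 1
                and 0 <= self.transfection_fn <= 1
                and 0 <= self.transfection_fp <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows, for recovery scoring."""

    regulations: pd.DataFrame  # mirna, gene, type (hinge|linear), slope, breakpoint
    decoys: pd.DataFrame       # mirna, gene
    subgroup_labels: dict[str, str] = field(default_factory=dict)
    stroma_up_genes: set[str] = field(default_factory=set)
    stroma_down_mirnas: set[str] = field(default_factory=set)
    transfection_truth: dict[str, set[str]] = field(default_factory=dict)

    @property
    def true_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.regulations["mirna"], self.regulations["gene"]))


def _substream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def generate_dataset(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, InteractionTable, GroundTruth]:
    """Draw matched gene/miRNA matrices, candidate pairs and ground truth.

    Gene values follow ``y = baseline + sum_r effect_r(x) + N(0, noise_sd)``
    where a hinge regulator contributes ``slope * max(0, x - b)`` (inert
    below the threshold b) and a linear regulator ``slope * x``.
    """
    rng = _substream(cfg.seed, 0)
    S, Km, Kg = cfg.n_samples, cfg.n_mirnas, cfg.n_genes
    mirna_ids = [f"mir-{i:03d}" for i in range(Km)]
    gene_ids = [f"gene-{i:03d}" for i in range(Kg)]
    sample_ids = [f"s{i:03d}" for i in range(S)]

    X = rng.normal(size=(Km, S))

    # subgroup shifts applied to the miRNA matrix BEFORE gene generation, so
    # opposed target shifts emerge through the regulation itself
    labels: dict[str, str] = {}
    if cfg.subgroups:
        shares = [cfg.subgroups[k][0] for k in cfg.subgroups]
        names = list(cfg.subgroups)
        bounds = np.floor(np.cumsum([0] + shares) * S).astype(int)
        for gi, name in enumerate(names):
            members = sample_ids[bounds[gi]:bounds[gi + 1]]
            for s in members:
                labels[s] = name
            for mi, shift in cfg.subgroups[name][1]:
                cols = slice(bounds[gi], bounds[gi + 1])
                X[mi, cols] += shift

    n_regulated = int(round(cfg.regulated_fraction * Kg))
    regulated = list(rng.choice(Kg, size=n_regulated, replace=False))
    reg_rows = []
    Y = np.zeros((Kg, S))
    if cfg.baseline_sd > 0:
        Y += rng.normal(0, cfg.baseline_sd, size=(Kg, 1))
    for gi in regulated:
        regs = rng.choice(Km, size=min(cfg.regulators_per_gene, Km),
                          replace=False)
        for mi in regs:
            slope = float(rng.uniform(*cfg.slope_range))
            is_hinge = bool(rng.random() < cfg.hinge_fraction)
            x = X[mi]
            if is_hinge:
                lo, hi = cfg.breakpoint_quantile_range
                b = float(np.quantile(x, rng.uniform(lo, hi)))
                # keep >= 3 samples on each side of the threshold
                for _ in range(20):
                    if min((x > b).sum(), (x <= b).sum()) >= 3:
                        break
                    b = float(np.quantile(x, rng.uniform(lo, hi)))
                Y[gi] += slope * np.maximum(0.0, x - b)
            else:
                b = np.nan
                Y[gi] += slope * x
            reg_rows.append({
                "mirna": mirna_ids[mi],
                "gene": gene_ids[gi],
                "type": "hinge" if is_hinge else "linear",
                "slope": slope,
                "breakpoint": b,
            })
    if cfg.noise_sd > 0:
        Y += rng.normal(0, cfg.noise_sd, size=(Kg, S))

    regulations = pd.DataFrame(
        reg_rows, columns=["mirna", "gene", "type", "slope", "breakpoint"])
    true_pairs = set(zip(regulations["mirna"], regulations["gene"]))

    n_target = int(round(cfg.regulation_density * Km * Kg))
    if n_target > Km * Kg:
        raise ValueError("regulation density exceeds the miRNA x gene grid")
    n_decoys = max(0, n_target - len(true_pairs))
    free = [(m, g) for m in mirna_ids for g in gene_ids
            if (m, g) not in true_pairs]
    if n_decoys > len(free):
        raise ValueError("regulation density exceeds the miRNA x gene grid")
    decoy_idx = rng.choice(len(free), size=n_decoys, replace=False)
    decoys = pd.DataFrame([free[i] for i in sorted(decoy_idx)],
                          columns=["mirna", "gene"])

    cand = pd.concat(
        [regulations[["mirna", "gene"]], decoys], ignore_index=True
    ).sort_values(["mirna", "gene"], kind="mergesort").reset_index(drop=True)

    genes = ExpressionMatrix(
        pd.DataFrame(Y, index=gene_ids, columns=sample_ids),
        kind="gene", unit="arbitrary")
    mirnas = ExpressionMatrix(
        pd.DataFrame(X, index=mirna_ids, columns=sample_ids),
        kind="miRNA", unit="arbitrary")
    truth = GroundTruth(
        regulations=regulations,
        decoys=decoys,
        subgroup_labels=labels,
        transfection_truth={
            m: {g for mm, g in true_pairs if mm == m}
            for m in sorted({m for m, _ in true_pairs})
        },
    )
    return genes, mirnas, InteractionTable(cand), truth


def generate_raw_dataset(
    cfg: SimulationConfig, n_zero_features: int = 3
) -> tuple[ExpressionMatrix, ExpressionMatrix, InteractionTable, GroundTruth]:
    """RPKM/RPMM-like positive matrices exercising the raw-input filters.

    Wraps the z-scale draws through a lognormal map and appends a few
    all-zero features to each matrix.
    """
    genes, mirnas, cand, truth = generate_dataset(cfg)

    def _rawify(m: ExpressionMatrix, unit: str) -> ExpressionMatrix:
        raw = np.exp(0.8 * m.values + 4.0)
        df = pd.DataFrame(raw, index=m.data.index, columns=m.data.columns)
        zeros = pd.DataFrame(
            0.0,
            index=[f"unexpressed-{m.kind}-{i}" for i in range(n_zero_features)],
            columns=m.data.columns)
        return ExpressionMatrix(pd.concat([df, zeros]), kind=m.kind, unit=unit)

    return _rawify(genes, "RPKM"), _rawify(mirnas, "RPMM"), cand, truth


def simulate_transfection(
    truth: GroundTruth, cfg: SimulationConfig,
    universe: list[str] | None = None,
    mirnas: list[str] | None = None,
) -> list[TransfectionExperiment]:
    """Noisy down-regulated gene lists per transfected miRNA.

    True targets are retained with probability 1 - FN; non-targets enter
    the list with probability FP.  The universe defaults to every gene that
    appears in the regulation grid.
    """
    rng = _substream(cfg.seed, 1)
    if universe is None:
        universe = sorted(
            set(truth.regulations["gene"]) | set(truth.decoys["gene"]))
    uni = set(universe)
    chosen = mirnas if mirnas is not None else sorted(truth.transfection_truth)
    experiments = []
    for m in chosen:
        targets = truth.transfection_truth.get(m, set()) & uni
        down = {g for g in sorted(targets)
                if rng.random() >= cfg.transfection_fn}
        down |= {g for g in sorted(uni - targets)
                 if rng.random() < cfg.transfection_fp}
        experiments.append(TransfectionExperiment(
            mirna_id=m, downregulated_genes=down, universe=uni))
    return experiments


def simulate_celltype_profiles(
    truth: GroundTruth, cfg: SimulationConfig,
    stroma_up_genes: list[str] | None = None,
    stroma_down_mirnas: list[str] | None = None,
    n_datasets: int = 1,
) -> list[tuple[CellTypeDataset, CellTypeDataset]]:
    """Tumor/stroma datasets: one gene-level and one miRNA-level per study.

    Stroma samples get ``+celltype_effect`` on designated stroma-up genes
    and ``-celltype_effect`` on designated stroma-down miRNAs; tumor
    samples are unshifted.  With ``paired_celltypes`` each patient
    contributes one tumor and one stroma sample.
    """
    rng = _substream(cfg.seed, 2)
    if stroma_up_genes is None:
        stroma_up_genes = sorted(set(truth.regulations["gene"]))
    if stroma_down_mirnas is None:
        stroma_down_mirnas = sorted(set(truth.regulations["mirna"]))
    gene_ids = sorted(set(truth.regulations["gene"]) | set(truth.decoys["gene"]))
    mirna_ids = sorted(set(truth.regulations["mirna"]) | set(truth.decoys["mirna"]))
    truth.stroma_up_genes = set(stroma_up_genes)
    truth.stroma_down_mirnas = set(stroma_down_mirnas)

    out = []
    for d in range(n_datasets):
        ns, nt = cfg.n_stroma, cfg.n_tumor
        if cfg.paired_celltypes and ns != nt:
            raise ValueError("paired design needs n_stroma == n_tumor")
        samples = [f"d{d}-stroma-{i}" for i in range(ns)] \
            + [f"d{d}-tumor-{i}" for i in range(nt)]
        cell_type = {s: ("stroma" if "stroma" in s else "tumor")
                     for s in samples}
        patient = None
        if cfg.paired_celltypes:
            patient = {f"d{d}-stroma-{i}": f"p{i}" for i in range(ns)}
            patient.update({f"d{d}-tumor-{i}": f"p{i}" for i in range(nt)})

        def _matrix(ids, up_set, sign, kind):
            vals = rng.normal(0, cfg.celltype_noise_sd,
                              size=(len(ids), ns + nt))
            for fi, f in enumerate(ids):
                if f in up_set:
                    vals[fi, :ns] += sign * cfg.celltype_effect
            return ExpressionMatrix(
                pd.DataFrame(vals, index=ids, columns=samples),
                kind=kind, unit="arbitrary")

        gene_ds = CellTypeDataset(
            name=f"sim-genes-{d}",
            expression=_matrix(gene_ids, set(stroma_up_genes), +1.0, "gene"),
            cell_type=cell_type, patient=patient)
        mirna_ds = CellTypeDataset(
            name=f"sim-mirnas-{d}",
            expression=_matrix(mirna_ids, set(stroma_down_mirnas), -1.0, "miRNA"),
            cell_type=cell_type, patient=patient)
        out.append((gene_ds, mirna_ds))
    return out


def score_recovery(predictions: pd.DataFrame, truth: GroundTruth) -> dict:
    """Precision/recall of predicted pairs and breakpoint errors on hinge TPs."""
    pred_pairs = set(zip(predictions["mirna"], predictions["gene"])) \
        if len(predictions) else set()
    true_pairs = truth.true_pairs
    tp = pred_pairs & true_pairs
    precision = len(tp) / len(pred_pairs) if pred_pairs else None
    recall = len(tp) / len(true_pairs) if true_pairs else None

    bp_errors = []
    if len(predictions) and "breakpoint" in predictions.columns:
        true_bp = {(r.mirna, r.gene): r.breakpoint
                   for r in truth.regulations.itertuples(index=False)
                   if r.type == "hinge"}
        for row in predictions.itertuples(index=False):
            key = (row.mirna, row.gene)
            if key in true_bp and key in tp and np.isfinite(row.breakpoint):
                bp_errors.append(abs(row.breakpoint - true_bp[key]))
    return {
        "precision": precision,
        "recall": recall,
        "n_predicted": len(pred_pairs),
        "n_true": len(true_pairs),
        "breakpoint_abs_errors": bp_errors,
    }
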