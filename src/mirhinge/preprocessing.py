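"""Expression filtering and normalization ahead of model fitting.

Order of operations: remove all-zero features from the raw matrices, keep
only candidate pairs whose miRNA and gene are negatively correlated across
the shared samples, then z-normalize each feature across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, InteractionTable

__all__ = [
    "drop_unexpressed",
    "correlation_filter",
    "znormalize",
]

logger = logging.getLogger(__name__)


def drop_unexpressed(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove features with no measurable expression (exactly 0 in all samples).

    Requires a raw abundance unit; z-scored input indicates the steps were
    run out of order.
    """
    if m.unit == "zscore":
        raise ValueError("drop_unexpressed expects raw abundances, got z-scores")
    keep = ~(m.values == 0).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("drop_unexpressed: removed %d all-zero features (%s)",
                    n_dropped, m.kind)
    if not keep.any():
        logger.warning("drop_unexpressed: all features were zero (%s)", m.kind)
    return ExpressionMatrix(m.data.loc[keep].copy(), kind=m.kind, unit=m.unit)


def correlation_filter(
    pairs: InteractionTable,
    genes: ExpressionMatrix,
    mirnas: ExpressionMatrix,
) -> tuple[InteractionTable, pd.DataFrame]:
    """Keep candidate pairs with strictly negative Pearson correlation.

    Correlation is computed over the shared samples of the two matrices in a
    common order.  Pairs referencing features absent from either matrix are
    dropped with a warning.  Returns the retained pairs and the full audit
    table of computed correlations (columns mirna, gene, pearson_r, n).
    """
    shared = [s for s in genes.sample_ids if s in set(mirnas.sample_ids)]
    if len(shared) < 3:
        raise ValueError(
            f"correlation_filter: only {len(shared)} shared samples (need >= 3)"
        )
    g = genes.data[shared]
    mi = mirnas.data[shared]
    gene_set = set(g.index)
    mirna_set = set(mi.index)

    records = []
    keep_rows = []
    for row in pairs.data.itertuples(index=False):
        if row.gene not in gene_set or row.mirna not in mirna_set:
            logger.warning("correlation_filter: pair (%s, %s) references a "
                           "missing feature; dropped", row.mirna, row.gene)
            continue
        x = mi.loc[row.mirna].to_numpy()
        y = g.loc[row.gene].to_numpy()
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(x, y)[0, 1]
        if not np.isfinite(r):  # constant vector -> undefined correlation
            r = 0.0
        records.append((row.mirna, row.gene, float(r), len(shared)))
        if r < 0.0:
            keep_rows.append({"mirna": row.mirna, "gene": row.gene})
    audit = pd.DataFrame(records, columns=["mirna", "gene", "pearson_r", "n"])
    kept = InteractionTable(pd.DataFrame(keep_rows, columns=["mirna", "gene"]),
                            species_filter=pairs.species_filter)
    return kept, audit


def znormalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-normalize each feature across samples (sample sd, n-1 denominator).

    Zero-variance features carry no signal for regression and are removed
    with a warning.  The output unit is tagged ``zscore``; the operation is
    idempotent on its own output up to floating-point error.
    """
    if m.n_samples < 2:
        raise ValueError("znormalize requires at least 2 samples")
    values = m.values
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning("znormalize: removed %d zero-variance features (%s)",
                       int((~keep).sum()), m.kind)
    values = values[keep]
    mu = values.mean(axis=1, keepdims=True)
    z = (values - mu) / sd[keep, None]
    df = pd.DataFrame(z, index=m.data.index[keep], columns=m.data.columns)
    return ExpressionMatrix(df, kind=m.kind, unit="zscore")
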