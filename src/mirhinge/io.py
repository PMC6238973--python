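"""Readers and writers for the flat-text formats the pipeline consumes.

Expression matrices are TCGA-Level-3-style TSV files (rows = features,
columns = samples).  Interaction tables, identifier mappings, binding-site
tables and candidate tables are plain TSV; gene sets use the GMT dialect
(name, category/description, members...).  All writers emit UTF-8 with LF
line endings and a deterministic column order so repeated runs are
byte-identical.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "InteractionTable",
    "GeneSet",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_interaction_table",
    "write_interaction_table",
    "read_id_mapping",
    "collapse_to_precursor",
    "read_gene_sets",
    "write_gene_sets",
    "read_candidate_table",
    "write_candidate_table",
    "load_candidate_fixture",
    "write_results",
]

#: formatting used by every writer; round-trips float64 exactly
_FLOAT_FORMAT = "%.17g"

_METHOD_ALIASES = {
    "combined model": "combined_model",
    "combined_model": "combined_model",
    "binding site analysis": "binding_site",
    "binding_site": "binding_site",
}


@dataclass
class ExpressionMatrix:
    """A features x samples numeric matrix with a feature kind and unit tag.

    Parameters
    ----------
    data:
        DataFrame indexed by feature id with sample ids as columns.
    kind:
        One of ``gene``, ``miRNA``, ``protein``.
    unit:
        One of ``RPKM``, ``RPMM``, ``zscore``, ``arbitrary``.
    """

    data: pd.DataFrame
    kind: str = "gene"
    unit: str = "arbitrary"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if len(self.data) and not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset(self, features: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "ExpressionMatrix":
        df = self.data
        if features is not None:
            df = df.loc[list(features)]
        if samples is not None:
            df = df[list(samples)]
        return ExpressionMatrix(df.copy(), kind=self.kind, unit=self.unit)


@dataclass
class InteractionTable:
    """Unique candidate (miRNA, gene) regulation pairs with provenance."""

    data: pd.DataFrame  # columns: mirna, gene [, species, method]
    species_filter: str | None = None

    def __post_init__(self) -> None:
        for col in ("mirna", "gene"):
            if col not in self.data.columns:
                raise ValueError(f"interaction table lacks column {col!r}")
        if self.data.duplicated(subset=["mirna", "gene"]).any():
            self.data = self.data.drop_duplicates(
                subset=["mirna", "gene"], keep="first"
            ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.data["mirna"], self.data["gene"]))

    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    def mirnas_of(self, gene: str) -> list[str]:
        return list(self.data.loc[self.data["gene"] == gene, "mirna"])


@dataclass
class GeneSet:
    name: str
    members: tuple[str, ...]
    category: str = ""


class GeneSetCollection(dict):
    """Mapping of set name -> :class:`GeneSet`; names are unique by construction."""

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self:
            raise ValueError(f"duplicate gene set name: {gene_set.name!r}")
        if not gene_set.members:
            raise ValueError(f"gene set {gene_set.name!r} has no members")
        self[gene_set.name] = gene_set


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path: str | Path, kind: str = "gene",
                           unit: str = "arbitrary") -> ExpressionMatrix:
    """Read a TSV expression matrix (first column feature id, header = samples).

    Raises on duplicate feature/sample ids, non-numeric cells (reported with
    row/column coordinates) and an empty data section.
    """
    # round_trip parsing so write -> read restores float64 bit patterns
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no features (header-only file)")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric.astype(float), kind=kind, unit=unit)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT,
                  index_label="feature", lineterminator="\n")


# ---------------------------------------------------------------------------
# interaction tables and identifier mappings


def read_interaction_table(path: str | Path,
                           species_filter: str | None = None) -> InteractionTable:
    """Read a TSV of (mirna, gene, species, method) rows.

    Rows not matching ``species_filter`` are dropped; duplicates over
    (mirna, gene) collapse to the first occurrence irrespective of the
    detection method.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("mirna", "gene", "species", "method"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if species_filter is not None:
        df = df[df["species"] == species_filter]
    df = df.drop_duplicates(subset=["mirna", "gene"], keep="first")
    return InteractionTable(df.reset_index(drop=True),
                            species_filter=species_filter)


def write_interaction_table(t: InteractionTable, path: str | Path) -> None:
    cols = [c for c in ("mirna", "gene", "species", "method")
            if c in t.data.columns]
    t.data[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_id_mapping(path: str | Path) -> pd.DataFrame:
    """Read a mature->precursor miRNA id mapping (TSV: mature_id, precursor_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("mature_id", "precursor_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    for col in ("mature_id", "precursor_id"):
        if df[col].isna().any() or (df[col].str.len() == 0).any():
            raise ValueError(f"{path}: empty identifier in mapping")
    return df.drop_duplicates().reset_index(drop=True)


def collapse_to_precursor(
    table: InteractionTable, mapping: pd.DataFrame
) -> tuple[InteractionTable, list[str]]:
    """Merge target-gene sets of sibling mature miRNAs (-3p/-5p) per precursor.

    A mature id mapping to several precursors contributes its pairs to every
    one of them.  Mature ids without any mapping are returned in a side list
    and excluded from the output (so downstream joins never mix the mature
    and precursor id namespaces).
    """
    merged = table.data.merge(mapping, left_on="mirna", right_on="mature_id",
                              how="left")
    unmapped = sorted(merged.loc[merged["precursor_id"].isna(), "mirna"].unique())
    kept = merged.dropna(subset=["precursor_id"])
    out = (
        kept[["precursor_id", "gene"]]
        .rename(columns={"precursor_id": "mirna"})
        .drop_duplicates()
        .sort_values(["mirna", "gene"], kind="mergesort")
        .reset_index(drop=True)
    )
    return InteractionTable(out, species_filter=table.species_filter), unmapped


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> category <tab> member1 <tab> member2 ...

    The description column is stored as the set's category label; duplicate
    members within a set are collapsed (first occurrence kept).
    """
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, category, *members = parts
            members = [m for m in members if m]
            unique = tuple(dict.fromkeys(members))
            coll.add(GeneSet(name=name, members=unique, category=category))
    return coll


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in coll:
            gs = coll[name]
            fh.write("\t".join([gs.name, gs.category, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# candidate tables


def read_candidate_table(path: str | Path) -> pd.DataFrame:
    """Read a candidate-pair table (mirna, gene_symbol, gene_name, method).

    Method strings are normalized: ``Combined Model`` -> ``combined_model``,
    ``Binding site analysis`` -> ``binding_site``.  Unknown method strings
    are a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("mirna", "gene_symbol", "gene_name", "identification_method")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    normalized = []
    for raw in df["identification_method"]:
        key = str(raw).strip().lower()
        if key not in _METHOD_ALIASES:
            raise ValueError(f"{path}: unknown identification method {raw!r}")
        normalized.append(_METHOD_ALIASES[key])
    out = df.copy()
    out["identification_method"] = normalized
    return out.reset_index(drop=True)


def write_candidate_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["mirna", "gene_symbol", "gene_name", "identification_method"]
    df[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_candidate_fixture() -> pd.DataFrame:
    """Load the packaged 39-row refined candidate-pair table."""
    ref = importlib.resources.files("mirhinge").joinpath("data/table1.tsv")
    with importlib.resources.as_file(ref) as p:
        return read_candidate_table(p)


# ---------------------------------------------------------------------------
# generic results writer


def write_results(result: pd.DataFrame, path: str | Path) -> None:
    """Write any flat result table deterministically (TSV, LF, full precision)."""
    result.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT,
                  lineterminator="\n")
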