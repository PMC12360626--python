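"""Region- and class-filtered transcript summaries over a MERFISH-style cell table.

Consumes a pre-exported cell-by-gene table (CSV or AnnData) with per-cell
metadata (slice, parcellation label, neurotransmitter class, reconstructed
coordinates) and imputed expression values in log2(CPM+1).  Typical use:
subset to glutamatergic cells of one region across chosen slices, then
summarise opioid-receptor transcripts (oprk1, oprm1, oprd1) by quartiles.
This module does no atlas API access; it operates on whatever table it is
handed.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

META_COLUMNS = ["cell_id", "slice_id", "region_label", "nt_class", "x", "y"]


class CellTable:
    """A cell-by-gene expression table with per-cell metadata.

    ``frame`` holds the metadata columns (``cell_id, slice_id, region_label,
    nt_class, x, y``) followed by one column per gene (log2(CPM+1), >= 0).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in META_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"cell table missing metadata columns: {missing}")
        self.frame = frame.reset_index(drop=True)
        genes = [c for c in frame.columns if c not in META_COLUMNS]
        expr = frame[genes].to_numpy(dtype=float) if genes else np.empty((len(frame), 0))
        if expr.size and (expr < 0).any():
            raise DataError("expression values must be non-negative (log2(CPM+1) scale)")
        self.genes = genes

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_csv(cls, path) -> "CellTable":
        path = Path(path)
        if not path.exists():
            raise FormatError(f"no such file: {path}")
        return cls(pd.read_csv(path))

    @classmethod
    def from_anndata(cls, adata) -> "CellTable":
        """Build from an AnnData whose ``obs`` carries the metadata fields."""
        obs = adata.obs
        frame = pd.DataFrame(
            {
                "cell_id": obs.index.astype(str),
                "slice_id": obs["slice_id"].astype(str).to_numpy(),
                "region_label": obs["region_label"].astype(str).to_numpy(),
                "nt_class": obs["nt_class"].astype(str).to_numpy(),
                "x": obs["x"].to_numpy(),
                "y": obs["y"].to_numpy(),
            }
        )
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        for j, gene in enumerate(adata.var_names):
            frame[str(gene)] = np.asarray(X[:, j]).ravel()
        return cls(frame)


def filter_cells(
    table: CellTable,
    region: Optional[str] = None,
    nt_class: Optional[str] = None,
    slice_ids: Optional[Sequence[str]] = None,
) -> CellTable:
    """Conjoin region / neurotransmitter-class / slice predicates.

    Requested labels absent from the table's vocabulary yield an (explicitly
    warned) empty subset rather than an error; the predicates are commutative
    and idempotent.
    """
    df = table.frame
    mask = np.ones(len(df), dtype=bool)
    if region is not None:
        if region not in set(df["region_label"]):
            warnings.warn(f"region label {region!r} not present in table", stacklevel=2)
        mask &= (df["region_label"] == region).to_numpy()
    if nt_class is not None:
        if nt_class not in set(df["nt_class"]):
            warnings.warn(f"neurotransmitter class {nt_class!r} not present in table", stacklevel=2)
        mask &= (df["nt_class"] == nt_class).to_numpy()
    if slice_ids is not None:
        wanted = set(map(str, slice_ids))
        present = set(df["slice_id"].astype(str))
        missing = wanted - present
        if missing:
            warnings.warn(f"slice ids not present in table: {sorted(missing)}", stacklevel=2)
        mask &= df["slice_id"].astype(str).isin(wanted).to_numpy()
    return CellTable(df.loc[mask].reset_index(drop=True))


def expression_summary(table: CellTable, genes: Sequence[str]) -> pd.DataFrame:
    """Per-gene q25 / median / q75 / mean / n over the table's cells.

    Percentiles use linear interpolation between order statistics (NumPy's
    default, the type-7 convention).
    """
    if len(table) == 0:
        raise DataError("empty cell table; nothing to summarise")
    missing = [g for g in genes if g not in table.genes]
    if missing:
        raise DataError(f"genes not present in table: {missing}")
    rows = []
    for gene in genes:
        vals = table.frame[gene].to_numpy(dtype=float)
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "gene": gene,
                "q25": float(q25),
                "median": float(med),
                "q75": float(q75),
                "mean": float(vals.mean()),
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "q25", "median", "q75", "mean", "n"])
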