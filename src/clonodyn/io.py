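"""Readers and writers for the package's on-disk formats.

Tabular artifacts are TSV throughout (gzip accepted transparently on read);
expression matrices are MatrixMarket MTX in the genes x cells orientation with
sidecar ``genes.tsv`` / ``barcodes.tsv`` index files; genomic intervals are BED
(0-based half-open) and coverage tracks bedGraph.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_cell_table",
    "write_cell_table",
    "read_barcode_table",
    "write_table",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "read_config",
    "write_config",
]

DE_COLUMNS = ["mean_a", "mean_b", "log2fc", "pvalue", "padj", "significant"]


def write_matrix(adata: AnnData, path: str | Path) -> None:
    """Write counts as MTX (genes x cells) with gene and barcode index files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counts = adata.layers.get("counts", adata.X)
    mat = sparse.csr_matrix(np.asarray(counts).T)  # genes x cells
    spio.mmwrite(str(path / "matrix.mtx"), mat, field="integer")
    pd.Series(adata.var_names).to_csv(path / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)


def read_matrix(path: str | Path) -> AnnData:
    """Read an MTX directory back into an AnnData (cells x genes, integer counts).

    The MTX header dimensions must match the index files; a mismatch is an
    error naming both counts. Explicit stored zeros are canonicalized away so a
    write -> read round trip is exact.
    """
    path = Path(path)
    mat = sparse.csr_matrix(spio.mmread(str(path / "matrix.mtx")))
    mat.eliminate_zeros()
    mat.sum_duplicates()
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if mat.shape[0] != len(genes):
        raise ValueError(
            f"MTX declares {mat.shape[0]} genes but genes.tsv lists {len(genes)}"
        )
    if mat.shape[1] != len(cells):
        raise ValueError(
            f"MTX declares {mat.shape[1]} cells but barcodes.tsv lists {len(cells)}"
        )
    counts = np.asarray(mat.T.todense()).astype(np.int32)
    adata = AnnData(
        X=counts.copy(),
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    adata.layers["counts"] = counts
    return adata


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, sep="\t", index=True)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    cells = pd.read_csv(path, sep="\t", index_col=0)
    if "branch_tip" in cells.columns:
        cells["branch_tip"] = cells["branch_tip"].where(cells["branch_tip"].notna(), None)
    return cells


def read_barcode_table(path: str | Path) -> pd.DataFrame:
    """Barcode table TSV with columns cell_id, barcode."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"cell_id", "barcode"} - set(table.columns)
    if missing:
        raise ValueError(f"barcode table missing columns: {sorted(missing)}")
    return table


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, with_summit: bool = False) -> pd.DataFrame:
    """Read a BED file; malformed lines are rejected with their line number.

    With ``with_summit`` the 4th column is interpreted as the summit offset
    (narrowPeak-style); otherwise extra columns are ignored.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from err
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            row = {"chrom": parts[0], "start": start, "end": end}
            if with_summit and len(parts) >= 4:
                row["summit"] = int(parts[3])
            rows.append(row)
    return pd.DataFrame(rows)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end"] + (["summit"] if "summit" in df.columns else [])
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph coverage track (chrom, start, end, value)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                    "value": float(parts[3]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
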