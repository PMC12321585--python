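"""Screen for genes dynamic along pseudotime but conserved across stages.

The screen proceeds stage by stage and branch by branch (a branch is the full
root-to-tip path, so shared trunk cells participate in every branch's run):

1.  bin the branch's cells into ``n_bins`` pseudotime sections;
2.  per bin and gene, compute an expression change (log2 fold change of mean
    expm1(normalized) inside vs outside the bin) and an abundance change
    (difference in the fraction of cells whose scaled expression exceeds the
    expressed threshold, inside minus outside);
3.  fit a normal distribution to each change's across-gene values and select
    genes exceeding mean + k*SD on BOTH criteria;
4.  repeat for every bin; a branch's gene set is the union over bins;
5.  keep genes appearing in at least ``min_branches`` branches (stage set);
6.  the final set is the union of stage sets — dynamic along pseudotime yet
    conserved across stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from anndata import AnnData

__all__ = [
    "ScreenParams",
    "BinEnrichment",
    "DynamicGeneResult",
    "bin_pseudotime",
    "bin_enrichment",
    "gaussian_cutoff",
    "dynamic_gene_screen",
]

FC_PSEUDOCOUNT = 1e-9


@dataclass(frozen=True)
class ScreenParams:
    """Tunable parameters of the dynamic-gene screen (defaults as used throughout)."""

    n_bins: int = 10
    bin_scheme: str = "equal_width"
    expressed_threshold: float = 0.5
    k: float = 2.0
    min_branches: int = 2
    min_bin_cells: int = 3
    conjunctive: bool = True


def bin_pseudotime(
    cells: pd.DataFrame, n_bins: int = 10, scheme: str = "equal_width"
) -> pd.Series:
    """Assign each cell to one of ``n_bins`` ordered pseudotime bins.

    ``equal_width`` splits the observed pseudotime range into equal-width
    sections (half-open, last bin closed); ``quantile`` uses equal-occupancy
    bins. A zero pseudotime range is an error under equal_width.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    pt = cells["pseudotime"].to_numpy(float)
    if len(pt) < n_bins:
        raise ValueError("fewer cells than bins")
    if not np.all(np.isfinite(pt)):
        raise ValueError("pseudotime must be finite")
    if scheme == "equal_width":
        lo, hi = pt.min(), pt.max()
        if hi == lo:
            raise ValueError("zero pseudotime range: equal-width bins are undefined")
        edges = np.linspace(lo, hi, n_bins + 1)
        idx = np.minimum(np.searchsorted(edges, pt, side="right") - 1, n_bins - 1)
    elif scheme == "quantile":
        edges = np.quantile(pt, np.linspace(0, 1, n_bins + 1))
        idx = np.minimum(np.searchsorted(edges, pt, side="right") - 1, n_bins - 1)
    else:
        raise ValueError(f"unknown bin scheme {scheme!r}")
    return pd.Series(idx, index=cells.index, name="bin")


@dataclass
class BinEnrichment:
    """Per gene x bin expression and abundance changes for one branch run."""

    genes: pd.Index
    fold_change: np.ndarray  # genes x bins, log2 in/out ratio
    abundance_diff: np.ndarray  # genes x bins, expressed-fraction difference
    bin_cells: np.ndarray  # cells per bin
    flagged_bins: np.ndarray  # bins with too few cells (statistics are NaN)
    expressed_threshold: float


def bin_enrichment(
    adata: AnnData,
    bins: pd.Series,
    expressed_threshold: float = 0.5,
    min_bin_cells: int = 3,
) -> BinEnrichment:
    """In-bin vs out-bin expression fold change and expressed-fraction difference.

    Expression change is the log2 ratio of mean expm1(normalized) inside the bin
    to outside (pseudocount-stabilized); abundance change is the fraction of
    cells with scaled expression above ``expressed_threshold`` inside minus
    outside. Bins with fewer than ``min_bin_cells`` cells are flagged and their
    statistics reported as NaN.
    """
    rows = adata.obs_names.get_indexer(bins.index)
    if np.any(rows < 0):
        raise ValueError("bin assignment references unknown cells")
    expr = np.expm1(np.asarray(adata.layers["normalized"])[rows])
    expressed = np.asarray(adata.layers["scaled"])[rows] > expressed_threshold

    bin_ids = np.sort(bins.unique())
    n_bins = int(bin_ids.max()) + 1
    n_genes = adata.n_vars
    fc = np.full((n_genes, n_bins), np.nan)
    ab = np.full((n_genes, n_bins), np.nan)
    bin_cells = np.zeros(n_bins, dtype=int)
    flagged = np.zeros(n_bins, dtype=bool)

    total_expr = expr.sum(axis=0)
    total_n = expr.shape[0]
    total_expressed = expressed.sum(axis=0)
    codes = bins.to_numpy()
    for b in range(n_bins):
        mask = codes == b
        n_in = int(mask.sum())
        bin_cells[b] = n_in
        if n_in < min_bin_cells or total_n - n_in < min_bin_cells:
            flagged[b] = True
            continue
        in_expr = expr[mask].sum(axis=0)
        mean_in = in_expr / n_in
        mean_out = (total_expr - in_expr) / (total_n - n_in)
        fc[:, b] = np.log2((mean_in + FC_PSEUDOCOUNT) / (mean_out + FC_PSEUDOCOUNT))
        in_exp = expressed[mask].sum(axis=0)
        ab[:, b] = in_exp / n_in - (total_expressed - in_exp) / (total_n - n_in)
    if flagged.any():
        warnings.warn(f"{int(flagged.sum())} bins had fewer than {min_bin_cells} cells")
    return BinEnrichment(
        genes=adata.var_names.copy(),
        fold_change=fc,
        abundance_diff=ab,
        bin_cells=bin_cells,
        flagged_bins=flagged,
        expressed_threshold=expressed_threshold,
    )


def gaussian_cutoff(values: np.ndarray, k: float = 2.0) -> np.ndarray:
    """Boolean selection of values exceeding the fitted normal mean + k*SD.

    The normal is fitted by maximum likelihood (sample mean, population SD) to
    the finite values; with zero SD nothing can exceed the threshold and an
    empty selection is returned with a warning. Requires >= 10 finite values.
    """
    values = np.asarray(values, float)
    finite = np.isfinite(values)
    if finite.sum() < 10:
        raise ValueError("need at least 10 finite values to fit the cutoff distribution")
    mu = values[finite].mean()
    sd = values[finite].std()
    if sd == 0:
        warnings.warn("zero SD in enrichment values: empty selection")
        return np.zeros(len(values), bool)
    return finite & (values > mu + k * sd)


@dataclass
class DynamicGeneResult:
    """Full provenance of one screen run."""

    params: ScreenParams
    per_bin: dict  # (stage, branch, bin) -> set of gene ids
    per_branch: dict  # (stage, branch) -> set
    per_stage: dict  # stage -> set (genes in >= min_branches branches)
    final: set  # union over stages
    branch_counts: dict  # (stage, gene) -> number of branches selecting it
    excluded_branches: list  # (stage, branch) pairs skipped for size


def dynamic_gene_screen(
    adata: AnnData,
    cells: pd.DataFrame,
    branch_key: str = "branch_tip",
    stage_key: str = "stage",
    params: ScreenParams = ScreenParams(),
) -> DynamicGeneResult:
    """Run the full binned screen per stage and branch; see the module docstring.

    Cells without a branch label (the mitotic trunk) are included in every
    branch's run, since each branch is a root-to-tip path. Branches with fewer
    cells than bins are excluded from the >= min_branches denominator with a
    warning.
    """
    per_bin: dict = {}
    per_branch: dict = {}
    per_stage: dict = {}
    branch_counts: dict = {}
    excluded = []

    for stage, stage_cells in cells.groupby(stage_key, sort=True):
        trunk = stage_cells[stage_cells[branch_key].isna()]
        branches = sorted(stage_cells[branch_key].dropna().unique())
        stage_sets: dict[str, set] = {}
        for branch in branches:
            run_cells = pd.concat([trunk, stage_cells[stage_cells[branch_key] == branch]])
            if len(run_cells) < params.n_bins:
                warnings.warn(f"branch {branch!r} in stage {stage!r} has too few cells; excluded")
                excluded.append((stage, branch))
                continue
            bins = bin_pseudotime(run_cells, params.n_bins, params.bin_scheme)
            enr = bin_enrichment(
                adata, bins, params.expressed_threshold, params.min_bin_cells
            )
            branch_set: set = set()
            for b in range(enr.fold_change.shape[1]):
                if enr.flagged_bins[b]:
                    continue
                sel_fc = gaussian_cutoff(enr.fold_change[:, b], params.k)
                sel_ab = gaussian_cutoff(enr.abundance_diff[:, b], params.k)
                sel = sel_fc & sel_ab if params.conjunctive else sel_fc | sel_ab
                chosen = set(enr.genes[sel])
                per_bin[(stage, branch, b)] = chosen
                branch_set |= chosen
            stage_sets[branch] = branch_set
            per_branch[(stage, branch)] = branch_set
        counts: dict[str, int] = {}
        for s in stage_sets.values():
            for g in s:
                counts[g] = counts.get(g, 0) + 1
        for g, c in counts.items():
            branch_counts[(stage, g)] = c
        per_stage[stage] = {g for g, c in counts.items() if c >= params.min_branches}

    final = set().union(*per_stage.values()) if per_stage else set()
    return DynamicGeneResult(
        params=params,
        per_bin=per_bin,
        per_branch=per_branch,
        per_stage=per_stage,
        final=final,
        branch_counts=branch_counts,
        excluded_branches=excluded,
    )
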