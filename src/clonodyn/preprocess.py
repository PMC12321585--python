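"""Shared expression-layer plumbing: normalization, scaling, mitotic threshold,
composition, pseudobulk correlation, rank-sum differential expression, marker
set algebra and correlation-based label transfer.

Conventions (all recorded in ``adata.uns`` so layers are exactly recomputable):

* ``normalized`` = log1p(counts * target_depth / cell_depth); target depth
  defaults to the median cell depth. Zero-depth cells are dropped with a warning.
* ``scaled`` = per-gene z-score of the normalized layer using the population SD
  (denominator n), clipped to +/- ``clip`` (default 10); zero-variance genes
  map to all-zero.
* log2 fold changes are computed on per-group means of expm1(normalized) with a
  pseudocount of 1e-9, the common single-cell convention.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize_counts",
    "scale_genes",
    "mitotic_threshold",
    "state_composition",
    "pseudobulk_correlation",
    "rank_sum_de",
    "marker_intersection",
    "label_transfer",
    "highly_variable_genes",
]

LOG2FC_PSEUDOCOUNT = 1e-9


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)


def normalize_counts(adata: AnnData, target_depth: float | str = "median") -> AnnData:
    """Depth-normalize and log1p-transform the count layer.

    Cells with zero total counts cannot be depth-normalized; they are excluded
    with a warning (never imputed), so the returned object may have fewer cells.
    The resolved target depth is recorded in ``adata.uns['normalization']``.
    """
    counts = _dense(adata.layers["counts"]).astype(float)
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("count layer must contain non-negative integers")
    depth = counts.sum(axis=1)
    zero = depth == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} cells with zero total counts")
        adata = adata[~zero].copy()
        counts = counts[~zero]
        depth = depth[~zero]
    if target_depth == "median":
        target = float(np.median(depth))
    else:
        target = float(target_depth)
        if target <= 0:
            raise ValueError("target_depth must be positive")
    adata.layers["normalized"] = np.log1p(counts * (target / depth)[:, None])
    adata.uns["normalization"] = {"target_depth": target, "log": "log1p"}
    return adata


def scale_genes(adata: AnnData, clip: float = 10.0) -> AnnData:
    """Per-gene z-score of the normalized layer, population SD, clipped to +/- clip.

    Zero-variance genes map to all-zero rather than NaN.
    """
    if clip <= 0:
        raise ValueError("clip must be positive")
    norm = np.asarray(adata.layers["normalized"])
    mean = norm.mean(axis=0)
    sd = norm.std(axis=0)  # ddof=0: population SD convention
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (norm - mean) / sd
    z[:, sd == 0] = 0.0
    adata.layers["scaled"] = np.clip(z, -clip, clip)
    adata.uns["scaling"] = {"clip": clip, "ddof": 0, "mean": mean, "sd": sd}
    return adata


def mitotic_threshold(cells: pd.DataFrame, mitotic_clusters: Sequence[str]) -> tuple[float, pd.Series]:
    """Pseudotime cutoff = highest pseudotime among cells of the mitotic clusters.

    Returns the cutoff together with the induced per-cell postmitotic flag
    (pseudotime strictly greater than the cutoff).
    """
    mitotic_clusters = set(mitotic_clusters)
    if not mitotic_clusters:
        raise ValueError("mitotic_clusters must be nonempty")
    missing = mitotic_clusters - set(cells["cluster"])
    if missing:
        raise ValueError(f"clusters absent from the cell table: {sorted(missing)}")
    cutoff = float(cells.loc[cells["cluster"].isin(mitotic_clusters), "pseudotime"].max())
    postmitotic = cells["pseudotime"] > cutoff
    postmitotic.name = "postmitotic"
    return cutoff, postmitotic


def state_composition(cells: pd.DataFrame, group_by: str, states: str) -> pd.DataFrame:
    """Relative cell-state fractions per group (rows sum to one)."""
    for key in (group_by, states):
        if key not in cells.columns:
            raise KeyError(f"column {key!r} not in cell table")
    counts = pd.crosstab(cells[group_by], cells[states])
    empty = counts.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"omitting empty groups: {list(counts.index[empty])}")
        counts = counts[~empty]
    return counts.div(counts.sum(axis=1), axis=0)


def pseudobulk_correlation(
    adata: AnnData,
    cells: pd.DataFrame,
    groups: str,
    gene_set: Sequence[str],
    layer: str = "normalized",
) -> pd.DataFrame:
    """Pearson correlation between per-group mean expression vectors.

    Mirrors the cross-stage progenitor comparison: average expression of the
    chosen genes per group, then pairwise Pearson correlation.
    """
    gene_set = list(gene_set)
    if len(gene_set) < 3:
        raise ValueError("gene_set must contain at least 3 genes")
    missing = set(gene_set) - set(adata.var_names)
    if missing:
        raise ValueError(f"genes absent from the matrix: {sorted(missing)[:5]}")
    layer_m = np.asarray(adata.layers[layer])
    cols = adata.var_names.get_indexer(gene_set)
    labels = cells[groups]
    names = sorted(labels.unique())
    if len(names) < 2:
        raise ValueError("need at least two groups")
    centroids = []
    for g in names:
        mask = (labels == g).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} has zero cells")
        centroids.append(layer_m[mask][:, cols].mean(axis=0))
    corr = np.corrcoef(np.vstack(centroids))
    return pd.DataFrame(corr, index=names, columns=names)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass
class DETable:
    """Per-gene differential expression result between two cell groups."""

    table: pd.DataFrame  # mean_a, mean_b, log2fc, pvalue, padj, significant
    method: str
    lfc_threshold: float
    p_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def rank_sum_de(
    adata: AnnData,
    cells_a: Sequence[str],
    cells_b: Sequence[str],
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    adjust: str = "bonferroni",
) -> DETable:
    """Two-sided Wilcoxon rank-sum test per gene between two disjoint cell groups.

    P-values use the normal approximation with midrank tie correction and
    continuity correction; log2 fold changes are computed on group means of
    expm1(normalized) with a pseudocount. Adjustment is Bonferroni or
    Benjamini-Hochberg; significance flags apply |log2FC| and adjusted-p
    thresholds jointly.
    """
    cells_a, cells_b = list(cells_a), list(cells_b)
    if set(cells_a) & set(cells_b):
        raise ValueError("groups must be disjoint")
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ValueError("each group needs at least 3 cells")
    if adjust not in ("bonferroni", "BH"):
        raise ValueError(f"unknown adjustment method {adjust!r}")

    norm = np.asarray(adata.layers["normalized"])
    ia = adata.obs_names.get_indexer(cells_a)
    ib = adata.obs_names.get_indexer(cells_b)
    if np.any(ia < 0) or np.any(ib < 0):
        raise ValueError("unknown cell ids in group definitions")
    xa, xb = norm[ia], norm[ib]

    res = stats.mannwhitneyu(xa, xb, axis=0, method="asymptotic", alternative="two-sided")
    pvals = np.asarray(res.pvalue)

    ea, eb = np.expm1(xa).mean(axis=0), np.expm1(xb).mean(axis=0)
    log2fc = np.log2((ea + LOG2FC_PSEUDOCOUNT) / (eb + LOG2FC_PSEUDOCOUNT))

    if adjust == "bonferroni":
        padj = np.minimum(pvals * len(pvals), 1.0)
    else:
        padj = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "mean_a": ea,
            "mean_b": eb,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "significant": (np.abs(log2fc) > lfc_threshold) & (padj < p_threshold),
        },
        index=adata.var_names.copy(),
    )
    return DETable(table=table, method=adjust, lfc_threshold=lfc_threshold, p_threshold=p_threshold)


def marker_intersection(
    tables: Mapping[str, DETable | pd.DataFrame],
    lfc_min: float = 0.25,
    padj_max: float = 0.05,
) -> dict:
    """Marker sets per named DE table plus all pairwise/triple intersections.

    A marker is a gene with log2FC > lfc_min and adjusted p < padj_max (the
    Venn-diagram convention for cohort markers). Returns a dict with per-name
    marker sets and intersection cardinalities for every 2- and 3-way
    combination.
    """
    if len(tables) < 2:
        raise ValueError("need at least two named DE tables")
    sets = {}
    for name, t in tables.items():
        frame = t.table if isinstance(t, DETable) else t
        sets[name] = set(frame.index[(frame["log2fc"] > lfc_min) & (frame["padj"] < padj_max)])
    inter = {}
    for r in (2, 3):
        for combo in itertools.combinations(sorted(sets), r):
            common = set.intersection(*(sets[n] for n in combo))
            inter[combo] = {"genes": common, "size": len(common)}
    return {"markers": sets, "intersections": inter}


# ---------------------------------------------------------------------------
# label transfer
# ---------------------------------------------------------------------------

def highly_variable_genes(adata: AnnData, n_top: int = 2000) -> list[str]:
    """Top-n genes by variance-stabilized dispersion on the normalized layer."""
    import scanpy as sc

    n_top = min(n_top, adata.n_vars)
    tmp = AnnData(X=np.asarray(adata.layers["normalized"]).copy(), var=adata.var.copy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(tmp, n_top_genes=n_top, flavor="seurat")
    return list(tmp.var_names[tmp.var["highly_variable"]])


def label_transfer(
    reference: AnnData,
    reference_labels: pd.Series,
    query: AnnData,
    min_score: float = 0.5,
    n_hvg: int = 2000,
) -> pd.DataFrame:
    """Correlation-based label transfer with a 'not assigned' fallback.

    Per-label centroids of the reference normalized layer over shared highly
    variable genes; each query cell gets the label of its best-correlated
    centroid with score = max(Pearson r, 0). Cells whose best score falls below
    ``min_score`` are labeled ``"not assigned"``, mirroring prediction-score
    gating in reference-based mapping.
    """
    shared = [g for g in highly_variable_genes(reference, n_hvg) if g in set(query.var_names)]
    if not shared:
        raise ValueError("no shared genes between reference and query")
    ref_m = np.asarray(reference.layers["normalized"])[:, reference.var_names.get_indexer(shared)]
    qry_m = np.asarray(query.layers["normalized"])[:, query.var_names.get_indexer(shared)]

    labels = sorted(reference_labels.unique())
    centroids = np.vstack([
        ref_m[(reference_labels == lab).to_numpy()].mean(axis=0) for lab in labels
    ])

    def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        a_c = a - a.mean(axis=1, keepdims=True)
        b_c = b - b.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(a_c, axis=1)[:, None] * np.linalg.norm(b_c, axis=1)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (a_c @ b_c.T) / denom
        return np.nan_to_num(r)

    corr = _rowwise_corr(qry_m, centroids)  # cells x labels
    best = corr.argmax(axis=1)
    score = np.maximum(corr[np.arange(len(corr)), best], 0.0)
    predicted = np.array([labels[i] for i in best], object)
    predicted[score < min_score] = "not assigned"
    return pd.DataFrame(
        {"predicted": predicted, "score": score},
        index=query.obs_names.copy(),
    )
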