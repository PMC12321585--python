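"""Clone assembly, dispersion classification and clonal fate-coupling statistics.

A clone is the set of cells descending from one barcoded progenitor,
reconstructed as a connected component of the cell-barcode bipartite graph.
Multicellular clones whose members occupy a single trajectory branch tip are
*nondispersing*; clones spanning several tips are *dispersing*.

Fate coupling between clusters is measured as the number of multicellular
clones shared between each cluster pair, standardized against a permutation
null that shuffles cell -> cluster assignments while preserving both cluster
sizes and clone membership. The z-score is the number of shared clones relative
to the randomized data (positive = coupled, negative = anticoupled); one-sided
empirical P values are computed per direction with an add-one pseudocount and
corrected per direction with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CloneTable",
    "build_clones",
    "DispersionSummary",
    "classify_dispersion",
    "CouplingResult",
    "coupling_zscores",
    "enumerate_coupling_null",
    "progenitor_progeny_correlation",
]


@dataclass
class CloneTable:
    """Partition of barcoded cells into clones.

    ``membership`` maps each barcoded cell to its clone id; ``pairs`` keeps the
    raw (cell, barcode) incidence. Clone ids are deterministic: each clone is
    named after its lexicographically smallest cell id.
    """

    membership: pd.DataFrame  # index cell_id, column clone_id
    pairs: pd.DataFrame  # cell_id, barcode

    @property
    def clones(self) -> dict[str, list[str]]:
        return {
            cid: sorted(grp.index)
            for cid, grp in self.membership.groupby("clone_id", sort=True)
        }

    @property
    def multicellular(self) -> dict[str, list[str]]:
        return {cid: cells for cid, cells in self.clones.items() if len(cells) >= 2}

    def __len__(self) -> int:
        return self.membership["clone_id"].nunique()


def build_clones(barcode_table: pd.DataFrame, known_cells: Sequence[str] | None = None) -> CloneTable:
    """Assemble clones as connected components of the cell-barcode graph.

    Cells linked transitively through shared barcodes merge into one clone.
    Duplicate (cell, barcode) rows are deduplicated silently; rows with empty
    fields, or cells absent from ``known_cells`` when given, are rejected.
    """
    pairs = barcode_table[["cell_id", "barcode"]].copy()
    if pairs.isna().any().any() or (pairs.astype(str) == "").any().any():
        raise ValueError("malformed barcode rows (empty cell id or barcode)")
    pairs = pairs.astype(str).drop_duplicates(ignore_index=True)
    if known_cells is not None:
        unknown = set(pairs["cell_id"]) - set(known_cells)
        if unknown:
            raise ValueError(f"barcode table references unknown cells: {sorted(unknown)[:5]}")

    cells = pd.Index(sorted(pairs["cell_id"].unique()))
    barcodes = pd.Index(sorted(pairs["barcode"].unique()))
    i = cells.get_indexer(pairs["cell_id"])
    j = barcodes.get_indexer(pairs["barcode"]) + len(cells)
    n = len(cells) + len(barcodes)
    adj = sparse.coo_matrix(
        (np.ones(2 * len(pairs)), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    )
    _, comp = connected_components(adj, directed=False)
    comp_of_cell = comp[: len(cells)]

    clone_name: dict[int, str] = {}
    for comp_id in np.unique(comp_of_cell):
        members = cells[comp_of_cell == comp_id]
        clone_name[comp_id] = f"clone_{min(members)}"
    membership = pd.DataFrame(
        {"clone_id": [clone_name[c] for c in comp_of_cell]},
        index=pd.Index(cells, name="cell_id"),
    )
    return CloneTable(membership=membership, pairs=pairs)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

@dataclass
class DispersionSummary:
    """Dispersing/nondispersing labels over multicellular tip-resident clones."""

    labels: pd.Series  # per labeled clone: 'dispersing' | 'nondispersing'
    frequencies: pd.Series  # fraction of labeled clones per label
    tip_combinations: pd.DataFrame  # incidence counts per tip combination (upset input)
    n_unlabeled: int

    @property
    def dispersing_fraction(self) -> float:
        freq = self.frequencies.get("dispersing", 0.0)
        return float(freq)


def classify_dispersion(clones: CloneTable, cells: pd.DataFrame) -> DispersionSummary:
    """Label each multicellular clone by whether its tip cells span >= 2 tips.

    Clones are restricted to their branch-tip-resident members; clones with at
    least two tip cells in exactly one tip are nondispersing, those spanning
    several tips dispersing, and clones with fewer than two tip cells stay
    unlabeled. Tip-combination incidence counts (upset-plot input) are reported
    for all labeled clones.
    """
    tip_of = cells["branch_tip"]
    labels = {}
    combos: dict[tuple[str, ...], int] = {}
    n_unlabeled = 0
    for clone_id, members in clones.clones.items():
        tips = [tip_of.get(c) for c in members]
        tips = [t for t in tips if pd.notna(t)]
        if len(tips) < 2:
            n_unlabeled += 1
            continue
        unique = tuple(sorted(set(tips)))
        labels[clone_id] = "dispersing" if len(unique) >= 2 else "nondispersing"
        combos[unique] = combos.get(unique, 0) + 1
    labels_s = pd.Series(labels, name="label", dtype=object)
    if len(labels_s):
        freq = labels_s.value_counts(normalize=True)
    else:
        freq = pd.Series(dtype=float)
    combo_df = pd.DataFrame(
        [{"tips": ",".join(t), "n_tips": len(t), "n_clones": n} for t, n in sorted(combos.items())]
    )
    return DispersionSummary(
        labels=labels_s, frequencies=freq, tip_combinations=combo_df, n_unlabeled=n_unlabeled
    )


# ---------------------------------------------------------------------------
# coupling z-scores
# ---------------------------------------------------------------------------

@dataclass
class CouplingResult:
    """Observed and permutation-null shared-clone statistics per cluster pair."""

    clusters: list[str]
    observed: np.ndarray
    perm_mean: np.ndarray
    perm_sd: np.ndarray
    z: np.ndarray
    p_coupled: np.ndarray
    p_anticoupled: np.ndarray
    q_coupled: np.ndarray
    q_anticoupled: np.ndarray
    degenerate: np.ndarray  # pairs whose permutation SD was zero
    n_permutations: int
    seed: int | None

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        k = len(self.clusters)
        for i in range(k):
            for j in range(i, k):
                rows.append(
                    {
                        "cluster_i": self.clusters[i],
                        "cluster_j": self.clusters[j],
                        "observed": self.observed[i, j],
                        "mean": self.perm_mean[i, j],
                        "sd": self.perm_sd[i, j],
                        "z": self.z[i, j],
                        "p_coupled": self.p_coupled[i, j],
                        "p_anticoupled": self.p_anticoupled[i, j],
                        "q_coupled": self.q_coupled[i, j],
                        "q_anticoupled": self.q_anticoupled[i, j],
                        "degenerate_sd": bool(self.degenerate[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def pair(self, a: str, b: str) -> dict:
        i, j = self.clusters.index(a), self.clusters.index(b)
        if i > j:
            i, j = j, i
        return {
            "observed": self.observed[i, j],
            "z": self.z[i, j],
            "p_coupled": self.p_coupled[i, j],
            "q_coupled": self.q_coupled[i, j],
            "p_anticoupled": self.p_anticoupled[i, j],
            "q_anticoupled": self.q_anticoupled[i, j],
        }


def _shared_clone_matrix(clone_idx: np.ndarray, labels: np.ndarray, n_clones: int, k: int) -> np.ndarray:
    """Cluster-pair shared-clone counts for one labeling.

    Off-diagonal [i, j]: clones with >= 1 cell in each of i and j; diagonal
    [i, i]: clones with >= 2 cells in i.
    """
    counts = np.zeros((n_clones, k), dtype=np.int32)
    np.add.at(counts, (clone_idx, labels), 1)
    present = counts > 0
    shared = (present.T.astype(np.int32) @ present.astype(np.int32)).astype(float)
    np.fill_diagonal(shared, (counts >= 2).sum(axis=0))
    return shared


def coupling_zscores(
    clones: CloneTable,
    cells: pd.DataFrame,
    cluster_key: str = "cluster",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> CouplingResult:
    """Permutation z-scores and empirical P values for clonal coupling between clusters.

    The observed statistic for a cluster pair is the number of multicellular
    clones with members in both clusters. The null shuffles the cell -> cluster
    labels of all barcoded cells uniformly (preserving cluster sizes and clone
    membership); z = (observed - null mean) / null SD, with z set to 0 and the
    pair flagged when the null SD is zero. Empirical P values are one-sided per
    direction with the add-one convention, so they are never exactly zero, and
    are BH-corrected separately for the coupled and anticoupled families.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    multicell = clones.multicellular
    if not multicell:
        raise ValueError("no multicellular clones")

    barcoded = clones.membership.index
    labels_all = cells.loc[barcoded, cluster_key]
    cluster_names = sorted(labels_all.unique())
    k = len(cluster_names)
    if k < 2:
        raise ValueError("need at least two clusters containing barcoded cells")
    label_codes = pd.Categorical(labels_all, categories=cluster_names).codes.astype(np.intp)

    clone_ids = sorted(multicell)
    cell_rows = []
    clone_rows = []
    for ci, cid in enumerate(clone_ids):
        for cell in multicell[cid]:
            cell_rows.append(barcoded.get_loc(cell))
            clone_rows.append(ci)
    cell_rows = np.array(cell_rows, dtype=np.intp)
    clone_rows = np.array(clone_rows, dtype=np.intp)
    n_clones = len(clone_ids)

    observed = _shared_clone_matrix(clone_rows, label_codes[cell_rows], n_clones, k)

    rng = np.random.default_rng(seed)
    sum_ = np.zeros((k, k))
    sumsq = np.zeros((k, k))
    n_ge = np.zeros((k, k))
    n_le = np.zeros((k, k))
    for _ in range(n_permutations):
        perm = rng.permutation(label_codes)
        s = _shared_clone_matrix(clone_rows, perm[cell_rows], n_clones, k)
        sum_ += s
        sumsq += s * s
        n_ge += s >= observed
        n_le += s <= observed

    mean = sum_ / n_permutations
    var = np.maximum(sumsq / n_permutations - mean**2, 0.0)
    sd = np.sqrt(var)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (observed - mean) / sd
    z[degenerate] = 0.0

    p_coupled = (1.0 + n_ge) / (1.0 + n_permutations)
    p_anticoupled = (1.0 + n_le) / (1.0 + n_permutations)

    iu = np.triu_indices(k)
    q_coupled = np.ones((k, k))
    q_anticoupled = np.ones((k, k))
    q_coupled[iu] = multipletests(p_coupled[iu], method="fdr_bh")[1]
    q_anticoupled[iu] = multipletests(p_anticoupled[iu], method="fdr_bh")[1]
    q_coupled = np.minimum(q_coupled, q_coupled.T)
    q_anticoupled = np.minimum(q_anticoupled, q_anticoupled.T)

    return CouplingResult(
        clusters=cluster_names,
        observed=observed,
        perm_mean=mean,
        perm_sd=sd,
        z=z,
        p_coupled=p_coupled,
        p_anticoupled=p_anticoupled,
        q_coupled=q_coupled,
        q_anticoupled=q_anticoupled,
        degenerate=degenerate,
        n_permutations=n_permutations,
        seed=seed,
    )


def enumerate_coupling_null(
    clones: CloneTable,
    cells: pd.DataFrame,
    cluster_key: str = "cluster",
) -> dict:
    """Exhaustive permutation null for small instances (<= ~9 barcoded cells).

    Iterates every permutation of the cluster-label multiset and returns the
    exact null mean/SD, z and one-sided tail probabilities per cluster pair
    (add-one convention is NOT applied: these are exact probabilities). Intended
    as an oracle for :func:`coupling_zscores` on tiny instances.
    """
    import itertools

    multicell = clones.multicellular
    barcoded = clones.membership.index
    labels_all = cells.loc[barcoded, cluster_key]
    cluster_names = sorted(labels_all.unique())
    k = len(cluster_names)
    codes = pd.Categorical(labels_all, categories=cluster_names).codes.astype(np.intp)
    if len(codes) > 9:
        raise ValueError("exhaustive enumeration is limited to <= 9 barcoded cells")

    clone_ids = sorted(multicell)
    cell_rows, clone_rows = [], []
    for ci, cid in enumerate(clone_ids):
        for cell in multicell[cid]:
            cell_rows.append(barcoded.get_loc(cell))
            clone_rows.append(ci)
    cell_rows = np.array(cell_rows, dtype=np.intp)
    clone_rows = np.array(clone_rows, dtype=np.intp)
    n_clones = len(clone_ids)

    observed = _shared_clone_matrix(clone_rows, codes[cell_rows], n_clones, k)

    total = 0
    sum_ = np.zeros((k, k))
    sumsq = np.zeros((k, k))
    n_ge = np.zeros((k, k))
    n_le = np.zeros((k, k))
    for perm in itertools.permutations(codes):
        perm = np.array(perm, dtype=np.intp)
        s = _shared_clone_matrix(clone_rows, perm[cell_rows], n_clones, k)
        total += 1
        sum_ += s
        sumsq += s * s
        n_ge += s >= observed
        n_le += s <= observed
    mean = sum_ / total
    sd = np.sqrt(np.maximum(sumsq / total - mean**2, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (observed - mean) / sd
    z[sd == 0] = 0.0
    return {
        "clusters": cluster_names,
        "observed": observed,
        "mean": mean,
        "sd": sd,
        "z": z,
        "p_coupled": n_ge / total,
        "p_anticoupled": n_le / total,
        "n_enumerated": total,
    }


# ---------------------------------------------------------------------------
# progenitor -> progeny correlation
# ---------------------------------------------------------------------------

def progenitor_progeny_correlation(
    adata,
    clones: CloneTable,
    cells: pd.DataFrame,
    n_random_draws: int = 50,
    seed: int = 0,
    n_hvg: int = 500,
) -> dict:
    """Test whether mitotic members of nondispersing clones resemble their progeny.

    Nondispersing clones with both mitotic and postmitotic members are grouped
    by their postmitotic branch tip. Within each group, Pearson correlations
    over highly variable genes are computed between (a) every clonal mitotic
    cell and every cell of the group's postmitotic reference, and (b) randomly
    drawn, size-matched mitotic cells and the same reference (``n_random_draws``
    draws). Both all-pairs correlation distributions are returned; the attached
    two-sided rank-sum test compares per-mitotic-cell mean correlations (one
    value per cell, clonal vs random), which keeps the test unit exchangeable
    under the null.
    """
    from .preprocess import highly_variable_genes

    rng = np.random.default_rng(seed)
    summary = classify_dispersion(clones, cells)
    nondisp = set(summary.labels.index[summary.labels == "nondispersing"])

    clone_map = clones.clones
    groups: dict[str, dict[str, list[str]]] = {}
    for cid in nondisp:
        members = clone_map[cid]
        mit = [c for c in members if cells.at[c, "mitotic"]]
        post = [c for c in members if not cells.at[c, "mitotic"] and pd.notna(cells.at[c, "branch_tip"])]
        if not mit or not post:
            continue
        tip = cells.at[post[0], "branch_tip"]
        g = groups.setdefault(tip, {"mitotic": [], "postmitotic": []})
        g["mitotic"] += mit
        g["postmitotic"] += post
    if not groups:
        raise ValueError("no nondispersing clones with both mitotic and postmitotic members")

    hvg = highly_variable_genes(adata, n_hvg)
    cols = adata.var_names.get_indexer(hvg)
    norm = np.asarray(adata.layers["normalized"])[:, cols]
    mitotic_pool = np.array(cells.index[cells["mitotic"].to_numpy(bool)], object)

    def _pair_corrs(rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
        a = norm[rows_a] - norm[rows_a].mean(axis=1, keepdims=True)
        b = norm[rows_b] - norm[rows_b].mean(axis=1, keepdims=True)
        denom = np.linalg.norm(a, axis=1)[:, None] * np.linalg.norm(b, axis=1)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (a @ b.T) / denom
        return np.nan_to_num(r)

    clonal_corrs, random_corrs = [], []
    clonal_cellmeans, random_cellmeans = [], []
    for tip, g in sorted(groups.items()):
        ref_rows = adata.obs_names.get_indexer(g["postmitotic"])
        mit_rows = adata.obs_names.get_indexer(g["mitotic"])
        rc = _pair_corrs(mit_rows, ref_rows)
        clonal_corrs.append(rc.ravel())
        clonal_cellmeans.append(rc.mean(axis=1))
        for _ in range(n_random_draws):
            draw = rng.choice(mitotic_pool, size=len(g["mitotic"]), replace=False)
            rows = adata.obs_names.get_indexer(draw)
            rr = _pair_corrs(rows, ref_rows)
            random_corrs.append(rr.ravel())
            random_cellmeans.append(rr.mean(axis=1))

    clonal = np.concatenate(clonal_corrs)
    random_ = np.concatenate(random_corrs)
    stat = stats.mannwhitneyu(
        np.concatenate(clonal_cellmeans),
        np.concatenate(random_cellmeans),
        alternative="two-sided",
    )
    return {
        "clonal_correlations": clonal,
        "random_correlations": random_,
        "statistic": float(stat.statistic),
        "pvalue": float(stat.pvalue),
        "shift": float(np.median(clonal) - np.median(random_)),
        "groups": {t: {k: len(v) for k, v in g.items()} for t, g in groups.items()},
    }
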