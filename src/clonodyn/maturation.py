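"""Cohort maturation-shift testing, weighted maturation scores for bulk
replicates, and perturbation composition / pseudotime statistics.

The maturation score of a bulk replicate with inferred cell-state proportions
p_c is ``sum_c p_c * s_c`` where s_c is a per-cluster summary pseudotime from
the single-cell reference (median by default, mean optionally). Perturbation
composition shifts are log10 ratios of within-condition cluster fractions,
perturbed over control, per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cohort_pseudotime_shift",
    "cluster_summary_pseudotime",
    "weighted_maturation_score",
    "assign_conditions",
    "proportion_change",
    "per_state_pseudotime_comparison",
    "de_count_per_cluster",
]


def cohort_pseudotime_shift(
    cells: pd.DataFrame,
    cohort_a: str,
    cohort_b: str,
    subsample_n: int | None = None,
    seed: int = 0,
) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of pseudotime between two cohorts.

    With ``subsample_n`` set, each cohort is first randomly subsampled to that
    size (the figure convention for large cohorts). Reports the statistic,
    two-sided p, per-cohort medians and the direction of the shift.
    """
    rng = np.random.default_rng(seed)
    groups = {}
    for name in (cohort_a, cohort_b):
        pt = cells.loc[cells["cohort"] == name, "pseudotime"].to_numpy(float)
        if len(pt) == 0:
            raise ValueError(f"cohort {name!r} not present")
        if subsample_n is not None:
            if len(pt) < subsample_n:
                raise ValueError(f"cohort {name!r} smaller than subsample_n")
            pt = rng.choice(pt, size=subsample_n, replace=False)
        groups[name] = pt
    res = stats.mannwhitneyu(groups[cohort_a], groups[cohort_b], alternative="two-sided")
    med_a, med_b = float(np.median(groups[cohort_a])), float(np.median(groups[cohort_b]))
    direction = "b>a" if med_b > med_a else ("a>b" if med_a > med_b else "none")
    return {
        "statistic": float(res.statistic),
        "pvalue": float(res.pvalue),
        "median_a": med_a,
        "median_b": med_b,
        "direction": direction,
        "n_a": len(groups[cohort_a]),
        "n_b": len(groups[cohort_b]),
    }


def cluster_summary_pseudotime(
    cells: pd.DataFrame, cluster_key: str = "cluster", summary: str = "median"
) -> pd.Series:
    """Per-cluster summary pseudotime from the single-cell reference."""
    if summary not in ("median", "mean"):
        raise ValueError("summary must be 'median' or 'mean'")
    agg = cells.groupby(cluster_key)["pseudotime"].agg(summary)
    agg.name = f"pseudotime_{summary}"
    return agg


def weighted_maturation_score(
    proportions: pd.DataFrame | pd.Series,
    cluster_pseudotime: pd.Series | Mapping[str, float],
    proportion_tolerance: float = 1e-6,
) -> pd.Series:
    """Maturation score per replicate: proportions weighted by cluster pseudotime.

    ``proportions`` is a replicate x cluster table (or one replicate as a
    Series); rows must sum to 1 within tolerance and every cluster must have a
    summary pseudotime. The score is linear in the proportions and invariant to
    cluster ordering.
    """
    if isinstance(proportions, pd.Series):
        proportions = proportions.to_frame().T
    summaries = pd.Series(cluster_pseudotime, dtype=float)
    missing = set(proportions.columns) - set(summaries.index)
    if missing:
        raise ValueError(f"clusters without summary pseudotime: {sorted(missing)}")
    rowsum = proportions.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > proportion_tolerance):
        raise ValueError("replicate proportions must sum to 1")
    scores = proportions @ summaries.loc[proportions.columns]
    scores.name = "maturation_score"
    return scores


# ---------------------------------------------------------------------------
# perturbation conditions
# ---------------------------------------------------------------------------

def assign_conditions(
    guides: pd.DataFrame,
    perturbed_classes: Sequence[str],
    control_classes: Sequence[str],
) -> pd.DataFrame:
    """Derive per-cell perturbed/control/excluded labels from guide assignments.

    A cell is perturbed if it carries at least one perturbed-class guide and no
    control-class guide, control in the converse case, and excluded when it
    carries both classes (the dual-guide exclusion rule) or neither.
    ``guides`` has columns cell_id, guide_id and optionally replicate.
    """
    perturbed_set, control_set = set(perturbed_classes), set(control_classes)
    if perturbed_set & control_set:
        raise ValueError("guide class definitions must be disjoint")
    rows = []
    has_rep = "replicate" in guides.columns
    for cid, grp in guides.groupby("cell_id", sort=True):
        gset = set(grp["guide_id"])
        has_p = bool(gset & perturbed_set)
        has_c = bool(gset & control_set)
        if has_p and not has_c:
            cond = "perturbed"
        elif has_c and not has_p:
            cond = "control"
        else:
            cond = "excluded"
        rows.append(
            {
                "cell_id": cid,
                "condition": cond,
                "guides": ",".join(sorted(gset)),
                "replicate": grp["replicate"].iloc[0] if has_rep else "rep1",
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")


@dataclass
class ProportionChange:
    """Per replicate x cluster composition shift between conditions."""

    per_replicate: pd.DataFrame  # replicate, cluster, frac_perturbed, frac_control, log10_ratio
    aggregated: pd.DataFrame  # per cluster: mean and SD of log10 ratios
    pseudocount: float


def proportion_change(
    assignment: pd.DataFrame,
    cells: pd.DataFrame,
    cluster_key: str = "cluster",
    pseudocount: float | None = None,
    use_fractions: bool = True,
) -> ProportionChange:
    """log10 composition change per cluster, perturbed versus control.

    Within each replicate, cluster fractions are computed inside each condition
    (fractions by default, so the statistic is invariant to condition capture
    depth; raw counts behind ``use_fractions=False``) and the change is
    ``log10(frac_perturbed + pc) - log10(frac_control + pc)``. The default
    pseudocount is 1/(2 * n_cells of the smaller condition) per replicate,
    keeping zero-cluster ratios finite. Replicates missing a condition are
    skipped with a warning. Swapping condition labels negates every ratio.
    """
    joined = assignment.join(cells[[cluster_key]], how="inner")
    joined = joined[joined["condition"].isin(["perturbed", "control"])]
    # cells without a label (e.g. trunk cells under a branch-tip key) still
    # count toward condition totals but get no row of their own
    clusters = sorted(joined[cluster_key].dropna().unique())
    rows = []
    for rep, grp in joined.groupby("replicate", sort=True):
        pert = grp[grp["condition"] == "perturbed"]
        ctrl = grp[grp["condition"] == "control"]
        if len(pert) == 0 or len(ctrl) == 0:
            warnings.warn(f"replicate {rep!r} missing a condition; skipped")
            continue
        pc = pseudocount
        if pc is None:
            pc = 1.0 / (2 * min(len(pert), len(ctrl))) if use_fractions else 0.5
        for cl in clusters:
            npert = int((pert[cluster_key] == cl).sum())
            nctrl = int((ctrl[cluster_key] == cl).sum())
            if use_fractions:
                a, b = npert / len(pert), nctrl / len(ctrl)
            else:
                a, b = float(npert), float(nctrl)
            rows.append(
                {
                    "replicate": rep,
                    "cluster": cl,
                    "frac_perturbed": a,
                    "frac_control": b,
                    "log10_ratio": np.log10(a + pc) - np.log10(b + pc),
                    "pseudocount": pc,
                }
            )
    per_rep = pd.DataFrame(rows)
    if per_rep.empty:
        raise ValueError("no replicate carried both conditions")
    agg = (
        per_rep.groupby("cluster")["log10_ratio"]
        .agg(["mean", "std", "count"])
        .rename(columns={"count": "n_replicates"})
    )
    return ProportionChange(
        per_replicate=per_rep,
        aggregated=agg,
        pseudocount=float(per_rep["pseudocount"].iloc[0]),
    )


def per_state_pseudotime_comparison(
    cells: pd.DataFrame,
    assignment: pd.DataFrame,
    states: str = "broad_state",
    min_cells: int = 3,
) -> pd.DataFrame:
    """Two-sided rank-sum comparison of pseudotime between conditions per broad state.

    States with fewer than ``min_cells`` cells in either condition are emitted
    with a skipped flag and no p-value; no cross-state correction is applied by
    default (localized effects are read off per state).
    """
    joined = assignment.join(cells[[states, "pseudotime"]], how="inner")
    rows = []
    for state, grp in joined.groupby(states, sort=True):
        pert = grp.loc[grp["condition"] == "perturbed", "pseudotime"].to_numpy(float)
        ctrl = grp.loc[grp["condition"] == "control", "pseudotime"].to_numpy(float)
        row = {
            "state": state,
            "n_perturbed": len(pert),
            "n_control": len(ctrl),
            "median_perturbed": float(np.median(pert)) if len(pert) else np.nan,
            "median_control": float(np.median(ctrl)) if len(ctrl) else np.nan,
        }
        if len(pert) < min_cells or len(ctrl) < min_cells:
            warnings.warn(f"state {state!r} undersized; skipped")
            row.update({"pvalue": np.nan, "skipped": True, "direction": "none"})
        else:
            res = stats.mannwhitneyu(pert, ctrl, alternative="two-sided")
            diff = row["median_perturbed"] - row["median_control"]
            row.update(
                {
                    "pvalue": float(res.pvalue),
                    "skipped": False,
                    "direction": "perturbed>control"
                    if diff > 0
                    else ("control>perturbed" if diff < 0 else "none"),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("state")


def de_count_per_cluster(
    adata,
    cells: pd.DataFrame,
    assignment: pd.DataFrame,
    cluster_key: str = "cluster",
    padj_max: float = 0.01,
    adjust: str = "bonferroni",
    min_cells: int = 3,
) -> pd.DataFrame:
    """Count differentially expressed genes per cluster between conditions.

    Runs the rank-sum DE test within each cluster (perturbed vs control) and
    counts genes with adjusted p below ``padj_max``. Clusters lacking enough
    cells in either condition are absent from the output.
    """
    from .preprocess import rank_sum_de

    joined = assignment.join(cells[[cluster_key]], how="inner")
    rows = []
    for cl, grp in joined.groupby(cluster_key, sort=True):
        pert = list(grp.index[grp["condition"] == "perturbed"])
        ctrl = list(grp.index[grp["condition"] == "control"])
        if len(pert) < min_cells or len(ctrl) < min_cells:
            continue
        de = rank_sum_de(adata, pert, ctrl, lfc_threshold=0.0, p_threshold=padj_max, adjust=adjust)
        n_sig = int((de.table["padj"] < padj_max).sum())
        rows.append({"cluster": cl, "n_de_genes": n_sig, "n_perturbed": len(pert), "n_control": len(ctrl)})
    return pd.DataFrame(rows).set_index("cluster")
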