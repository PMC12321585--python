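"""Stage-enriched peak classification, summit-window signal and FRiP.

Genomic intervals are handled as pandas DataFrames with 0-based half-open
columns (chrom, start, end) plus optional ``summit`` (offset from start, the
narrowPeak convention) and ``score``. Overlap queries run on interval trees;
an any-overlap of at least ``min_overlap_bp`` (default 1 bp) counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "validate_intervals",
    "PeakClassification",
    "classify_peak_overlap",
    "summit_window_signal",
    "fraction_reads_in_peaks",
]


def validate_intervals(df: pd.DataFrame, name: str = "peaks") -> pd.DataFrame:
    """Check interval invariants: start < end, summit (if any) inside the peak."""
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"{name}: missing column {col!r}")
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValueError(f"{name}: interval with start >= end at row {bad}")
    if "summit" in df.columns and df["summit"].notna().any():
        s = df["summit"].dropna()
        width = (df.loc[s.index, "end"] - df.loc[s.index, "start"])
        if ((s < 0) | (s >= width)).any():
            raise ValueError(f"{name}: summit outside its interval")
    return df


def _trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            zip(grp["start"].astype(int), grp["end"].astype(int))
        )
    return trees


def _overlaps(df: pd.DataFrame, trees: dict[str, IntervalTree], min_bp: int) -> np.ndarray:
    hit = np.zeros(len(df), bool)
    for pos, (_, row) in enumerate(df.iterrows()):
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        for iv in tree.overlap(int(row["start"]), int(row["end"])):
            if min(iv.end, row["end"]) - max(iv.begin, row["start"]) >= min_bp:
                hit[pos] = True
                break
    return hit


@dataclass
class PeakClassification:
    """Partition of two peak sets into stage-enriched and overlapping subsets."""

    a_enriched: pd.DataFrame
    b_enriched: pd.DataFrame
    overlapping_a: pd.DataFrame
    overlapping_b: pd.DataFrame
    min_overlap_bp: int
    names: tuple[str, str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            f"{self.names[0]}_enriched": len(self.a_enriched),
            f"{self.names[1]}_enriched": len(self.b_enriched),
            f"overlapping_{self.names[0]}": len(self.overlapping_a),
            f"overlapping_{self.names[1]}": len(self.overlapping_b),
        }


def classify_peak_overlap(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    min_overlap_bp: int = 1,
    names: tuple[str, str] = ("a", "b"),
) -> PeakClassification:
    """Classify each peak as stage-enriched or overlapping across two stages.

    A peak of set A overlapping any peak of set B by at least ``min_overlap_bp``
    is *overlapping* (and symmetrically for B); otherwise it is enriched in its
    own stage. Every input peak lands in exactly one category per side, and the
    partition is symmetric under swapping A and B.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    set_a = validate_intervals(set_a, names[0])
    set_b = validate_intervals(set_b, names[1])
    hit_a = _overlaps(set_a, _trees(set_b), min_overlap_bp)
    hit_b = _overlaps(set_b, _trees(set_a), min_overlap_bp)
    return PeakClassification(
        a_enriched=set_a[~hit_a].reset_index(drop=True),
        b_enriched=set_b[~hit_b].reset_index(drop=True),
        overlapping_a=set_a[hit_a].reset_index(drop=True),
        overlapping_b=set_b[hit_b].reset_index(drop=True),
        min_overlap_bp=min_overlap_bp,
        names=names,
    )


def summit_window_signal(
    coverage: pd.DataFrame,
    peaks: pd.DataFrame,
    flank_bp: int = 500,
    library_size: int = 1_000_000,
) -> pd.DataFrame:
    """Mean per-base coverage around each peak summit, scaled to RPKM.

    The window is [summit - flank, summit + flank); the peak midpoint (floor)
    substitutes when no summit column is present. Coverage is a sorted
    bedGraph-style table (chrom, start, end, value). Windows extending past
    position 0 are truncated and flagged. The RPKM scaling treats the coverage
    values as read counts per base:
    ``rpkm = mean_coverage * 1e9 / library_size`` (i.e. reads per kilobase of
    window per million library reads).
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    peaks = validate_intervals(peaks, "peaks")
    cov_trees: dict[str, list] = {}
    for chrom, grp in coverage.groupby("chrom", sort=False):
        cov_trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), float(v))
            for s, e, v in zip(grp["start"], grp["end"], grp["value"])
            if e > s
        )
    rows = []
    for idx, row in peaks.iterrows():
        if "summit" in peaks.columns and pd.notna(row.get("summit")):
            center = int(row["start"]) + int(row["summit"])
        else:
            center = (int(row["start"]) + int(row["end"])) // 2
        lo, hi = center - flank_bp, center + flank_bp
        truncated = lo < 0
        lo = max(lo, 0)
        total = 0.0
        tree = cov_trees.get(row["chrom"])
        if tree is not None:
            for iv in tree.overlap(lo, hi):
                total += (min(iv.end, hi) - max(iv.begin, lo)) * iv.data
        mean_cov = total / (hi - lo)
        rows.append(
            {
                "chrom": row["chrom"],
                "start": row["start"],
                "end": row["end"],
                "window_start": lo,
                "window_end": hi,
                "mean_coverage": mean_cov,
                "rpkm": mean_cov * 1e9 / library_size,
                "truncated": truncated,
            }
        )
    return pd.DataFrame(rows, index=peaks.index)


def fraction_reads_in_peaks(fragments: pd.DataFrame, peaks: pd.DataFrame) -> float:
    """Fraction of fragments overlapping at least 1 bp of any peak (FRiP)."""
    if len(fragments) == 0:
        raise ValueError("fragment set is empty")
    fragments = validate_intervals(fragments, "fragments")
    if len(peaks) == 0:
        return 0.0
    peaks = validate_intervals(peaks, "peaks")
    hit = _overlaps(fragments, _trees(peaks), 1)
    return float(hit.mean())
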