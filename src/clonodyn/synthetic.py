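"""Synthetic lineage-barcoded single-cell data with planted, recoverable ground truth.

The generator emulates the structure of a ganglionic-eminence-style neurogenesis
experiment: a rooted differentiation trajectory (apical progenitors -> basal
progenitors -> bifurcation into interneuron-like and projection-neuron-like limbs
ending in five terminal branch tips), isochronic cohorts with controllable
pseudotime (maturation) shifts, negative-binomial expression with archetypal gene
programs, multicellular clones with a controllable probability of dispersing
across branch tips, CRISPR-style perturbation conditions with controllable
depletion of chosen clusters, and bulk replicates mixed from cluster pseudobulks.

Every simulation routine takes an explicit integer seed and regenerates its
output bit-for-bit. A master seed can be expanded into per-stage child seeds with
:func:`child_seed`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats

__all__ = [
    "TrajectoryModel",
    "CohortSpec",
    "GeneArchetype",
    "SyntheticTruth",
    "child_seed",
    "simulate_cells",
    "simulate_expression",
    "archetype_panel",
    "simulate_clones",
    "simulate_perturbation",
    "simulate_bulk",
    "simulate_replicate_proportions",
    "simulate_peak_data",
]

TERTILE_NAMES = ("early", "mid", "late")


def child_seed(master_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage child seed from a master seed.

    The child is the first 4 bytes of sha256(f"{master_seed}:{stage}") reduced
    modulo 2**31, so each pipeline stage is independently reproducible from the
    (master seed, stage name) pair alone.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class TrajectoryModel:
    """Topology and pseudotime geometry of the simulated trajectory.

    Root (AP state) -> BP state -> bifurcation at the mitotic cutoff -> five
    terminal branch tips, partitioned into interneuron-like and projection-
    neuron-like limbs. Pseudotime runs on [0, pseudotime_max]; cells below
    ``mitotic_cutoff`` are mitotic and carry no tip label.
    """

    in_tips: tuple[str, ...] = ("IN1", "IN2")
    pn_tips: tuple[str, ...] = ("PN1", "PN2", "PN3")
    pseudotime_max: float = 1.0
    mitotic_cutoff: float = 0.35
    ap_fraction: float = 0.5  # fraction of the mitotic range occupied by APs
    tip_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        tips = self.tips
        if len(tips) != 5 or len(set(tips)) != 5:
            raise ValueError("trajectory must have exactly five distinct branch tips")
        if not self.in_tips or not self.pn_tips:
            raise ValueError("both limbs must own at least one tip")
        if not 0.0 < self.mitotic_cutoff < self.pseudotime_max:
            raise ValueError("mitotic cutoff must lie strictly inside the pseudotime support")
        if self.tip_weights is not None and len(self.tip_weights) != 5:
            raise ValueError("tip_weights must have one weight per tip")

    @property
    def tips(self) -> tuple[str, ...]:
        return tuple(self.in_tips) + tuple(self.pn_tips)

    @property
    def tip_probabilities(self) -> np.ndarray:
        w = np.ones(5) if self.tip_weights is None else np.asarray(self.tip_weights, float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("tip weights must be non-negative with positive sum")
        return w / w.sum()

    def limb_of(self, tip: str) -> str:
        return "IN" if tip in self.in_tips else "PN"


@dataclass(frozen=True)
class CohortSpec:
    """One isochronic cohort: a labeling stage plus a pseudotime distribution.

    ``distribution`` is "truncnorm" (normal with the given location/scale,
    truncated to [0, pseudotime_max]) or "uniform" (on [loc, loc + scale]).
    Distributions that would place mass below zero are rejected.
    """

    name: str
    stage: str
    loc: float
    scale: float
    weight: float = 1.0
    distribution: str = "truncnorm"

    def __post_init__(self) -> None:
        if self.distribution not in ("truncnorm", "uniform"):
            raise ValueError(f"unknown cohort distribution {self.distribution!r}")
        if self.scale < 0:
            raise ValueError("cohort scale must be non-negative")
        if self.weight <= 0:
            raise ValueError("cohort weight must be positive")
        if self.distribution == "uniform" and self.loc < 0:
            raise ValueError("uniform cohort would place mass below pseudotime 0")

    def sample(self, n: int, upper: float, rng: np.random.Generator) -> np.ndarray:
        if self.distribution == "uniform":
            return self.loc + self.scale * rng.random(n)
        if self.scale == 0:
            return np.full(n, float(np.clip(self.loc, 0.0, upper)))
        a = (0.0 - self.loc) / self.scale
        b = (upper - self.loc) / self.scale
        return stats.truncnorm.rvs(a, b, loc=self.loc, scale=self.scale, size=n, random_state=rng)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulation stage.

    Only the tables relevant to the producing operation are populated; ``params``
    records every parameter needed to regenerate the output from ``seed``.
    """

    seed: int
    params: dict = field(default_factory=dict)
    cells: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None
    clones: pd.DataFrame | None = None
    perturbation: pd.DataFrame | None = None
    proportions: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

def _allocate(n: int, weights: np.ndarray) -> np.ndarray:
    """Deterministic proportional allocation of n items over weights."""
    frac = weights / weights.sum() * n
    base = np.floor(frac).astype(int)
    rest = n - base.sum()
    order = np.argsort(-(frac - base), kind="stable")
    base[order[:rest]] += 1
    return base


def simulate_cells(
    model: TrajectoryModel,
    n_cells: int,
    cohorts: Sequence[CohortSpec],
    seed: int,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a cell metadata table with planted pseudotime and branch truth.

    Each cell draws a pseudotime from its cohort's distribution; cells past the
    mitotic cutoff are postmitotic and carry a branch-tip label drawn from the
    model's tip probabilities. Cluster labels are derived deterministically as
    branch x pseudotime stratum (AP/BP in the mitotic range, tip x tertile in
    the postmitotic range), so cluster-level statistics have known composition.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if not cohorts:
        raise ValueError("at least one cohort is required")
    rng = np.random.default_rng(seed)

    weights = np.array([c.weight for c in cohorts], float)
    sizes = _allocate(n_cells, weights)

    pt = np.empty(n_cells)
    cohort_lab = np.empty(n_cells, object)
    stage_lab = np.empty(n_cells, object)
    offset = 0
    for spec, size in zip(cohorts, sizes):
        pt[offset : offset + size] = spec.sample(size, model.pseudotime_max, rng)
        cohort_lab[offset : offset + size] = spec.name
        stage_lab[offset : offset + size] = spec.stage
        offset += size
    pt = np.maximum(pt, 0.0)

    mitotic = pt < model.mitotic_cutoff
    tips = np.array(model.tips, object)
    tip_lab = np.full(n_cells, None, object)
    n_post = int((~mitotic).sum())
    if n_post:
        tip_lab[~mitotic] = rng.choice(tips, size=n_post, p=model.tip_probabilities)

    # deterministic cluster labels: AP/BP split of the mitotic range, tip x
    # pseudotime tertile in the postmitotic range
    ap_split = model.mitotic_cutoff * model.ap_fraction
    post_edges = np.linspace(model.mitotic_cutoff, model.pseudotime_max, 4)[1:3]
    cluster = np.empty(n_cells, object)
    broad = np.empty(n_cells, object)
    for i in range(n_cells):
        if mitotic[i]:
            cluster[i] = "AP" if pt[i] < ap_split else "BP"
            broad[i] = cluster[i]
        else:
            tertile = int(np.searchsorted(post_edges, pt[i], side="right"))
            cluster[i] = f"{tip_lab[i]}-{TERTILE_NAMES[tertile]}"
            broad[i] = f"{model.limb_of(tip_lab[i])}-precursor"

    cells = pd.DataFrame(
        {
            "stage": stage_lab,
            "cohort": cohort_lab,
            "cluster": cluster,
            "broad_state": broad,
            "branch_tip": tip_lab,
            "pseudotime": pt,
            "mitotic": mitotic,
        },
        index=pd.Index([f"cell{i:06d}" for i in range(n_cells)], name="cell_id"),
    )
    truth = SyntheticTruth(
        seed=seed,
        params={
            "model": model,
            "cohorts": tuple(cohorts),
            "n_cells": n_cells,
            "mitotic_cutoff": model.mitotic_cutoff,
        },
        cells=cells[["pseudotime", "branch_tip", "mitotic", "cohort"]].copy(),
    )
    return cells, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneArchetype:
    """Mean model of one gene under the negative-binomial count layer.

    kinds:
      constant       -- mean = base_mean everywhere
      branch_marker  -- mean multiplied by ``fold`` in cells of ``tip``
      dynamic        -- sigmoid or Gaussian-bump modulation along pseudotime;
                        with ``branches=None`` the program runs in every cell
                        (trunk included), whereas a branch-restricted program
                        runs only in cells of the listed tips (a postmitotic,
                        lineage-specific program)
      stage          -- mean multiplied by ``stage_factors[stage]``

    ``dispersion`` is the negative-binomial shape theta (var = mu + mu^2/theta).
    """

    kind: str
    base_mean: float
    dispersion: float
    tip: str | None = None
    fold: float = 1.0
    shape: str = "bump"
    center: float = 0.5
    width: float = 0.1
    amplitude: float = 0.0
    branches: tuple[str, ...] | None = None
    stage_factors: tuple[tuple[str, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "branch_marker", "dynamic", "stage"):
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if self.base_mean < 0:
            raise ValueError("base_mean must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.kind == "dynamic":
            if self.shape not in ("bump", "sigmoid"):
                raise ValueError(f"unknown dynamic shape {self.shape!r}")
            if self.width <= 0:
                raise ValueError("dynamic archetype with zero-width profile")

    def mean(
        self,
        pseudotime: np.ndarray,
        tip: np.ndarray,
        stage: np.ndarray,
        primed_tip: np.ndarray | None = None,
        priming: float = 0.0,
    ) -> np.ndarray:
        """Vectorized per-cell mean.

        ``primed_tip`` marks progenitors primed toward a branch tip: for
        branch-marker genes a primed cell's mean is raised by a fraction
        ``priming`` of the marker fold (a weak pre-expression of the progeny
        program, the signal of a fate-biased progenitor).
        """
        n = len(pseudotime)
        mu = np.full(n, self.base_mean, float)
        if self.kind == "branch_marker":
            mu[tip == self.tip] *= self.fold
            if primed_tip is not None and priming > 0:
                primed = (primed_tip == self.tip) & (tip != self.tip)
                mu[primed] *= 1.0 + priming * (self.fold - 1.0)
        elif self.kind == "dynamic" and self.amplitude != 0:
            if self.shape == "bump":
                prof = np.exp(-((pseudotime - self.center) ** 2) / (2 * self.width**2))
            else:
                prof = 1.0 / (1.0 + np.exp(-(pseudotime - self.center) / self.width))
            if self.branches is None:
                active = np.ones(n, bool)
            else:
                active = np.isin(tip, np.asarray(self.branches, object))
            mu = np.where(active, self.base_mean * (1.0 + self.amplitude * prof), mu)
        elif self.kind == "stage" and self.stage_factors:
            factors = dict(self.stage_factors)
            mu *= np.array([factors.get(s, 1.0) for s in stage])
        return mu


def simulate_expression(
    cells: pd.DataFrame,
    archetypes: Sequence[GeneArchetype],
    seed: int,
    library_sigma: float = 0.35,
    priming: float = 0.0,
) -> tuple[AnnData, SyntheticTruth]:
    """Draw a negative-binomial count matrix for the given cells and archetypes.

    Per-cell library size variation is log-normal with log-SD ``library_sigma``
    (mean-one), matching the overdispersion single-cell depth normalization is
    meant to remove. If the cell table carries a ``primed_tip`` column (see
    :func:`prime_progenitors`) and ``priming`` > 0, primed progenitors weakly
    pre-express the branch-marker program of their future tip. Returns an
    AnnData (cells x genes) whose ``layers['counts']`` and ``X`` hold the
    integer counts and whose ``obs`` is the cell table.
    """
    if len(cells) == 0:
        raise ValueError("cells table is empty")
    if not archetypes:
        raise ValueError("at least one archetype is required")
    rng = np.random.default_rng(seed)

    pt = cells["pseudotime"].to_numpy(float)
    tip = cells["branch_tip"].to_numpy(object)
    stage = cells["stage"].to_numpy(object)
    size_factor = rng.lognormal(mean=-(library_sigma**2) / 2, sigma=library_sigma, size=len(cells))
    primed = cells["primed_tip"].to_numpy(object) if "primed_tip" in cells.columns else None

    n_genes = len(archetypes)
    counts = np.empty((len(cells), n_genes), dtype=np.int32)
    for j, arch in enumerate(archetypes):
        mu = arch.mean(pt, tip, stage, primed_tip=primed, priming=priming) * size_factor
        theta = arch.dispersion
        p = theta / (theta + np.maximum(mu, 1e-12))
        draw = rng.negative_binomial(theta, p)
        counts[:, j] = np.where(mu > 0, draw, 0)

    genes = pd.DataFrame(
        {
            "kind": [a.kind for a in archetypes],
            "base_mean": [a.base_mean for a in archetypes],
            "dispersion": [a.dispersion for a in archetypes],
            "is_dynamic": [a.kind == "dynamic" and a.amplitude > 0 for a in archetypes],
            "tip": [a.tip for a in archetypes],
            "amplitude": [a.amplitude for a in archetypes],
            "center": [a.center for a in archetypes],
            "n_branches": [
                5 if a.branches is None else len(a.branches) for a in archetypes
            ],
        },
        index=pd.Index([f"g{j:05d}" for j in range(n_genes)], name="gene_id"),
    )
    adata = AnnData(X=counts.copy(), obs=cells.copy(), var=genes.copy())
    adata.layers["counts"] = counts
    truth = SyntheticTruth(
        seed=seed,
        params={"library_sigma": library_sigma, "n_genes": n_genes},
        genes=genes,
    )
    return adata, truth


def archetype_panel(
    n_genes: int,
    model: TrajectoryModel,
    stages: Sequence[str] = ("early", "late"),
    n_dynamic: int = 0,
    marker_frac: float = 0.15,
    stage_frac: float = 0.10,
    dynamic_amplitude: float = 2.0,
    dynamic_min_branches: int = 3,
    seed: int = 0,
) -> list[GeneArchetype]:
    """Assemble a realistic default gene panel.

    Baseline means are log-normal across ~2 orders of magnitude and dispersions
    heterogeneous, as in droplet scRNA-seq; a ``marker_frac`` fraction of genes
    are single-tip branch markers (fold 2-6), a ``stage_frac`` fraction carry a
    stage-specific multiplier, and ``n_dynamic`` genes follow bump or sigmoid
    pseudotime programs with peak amplitude ``dynamic_amplitude`` x baseline,
    active in at least ``dynamic_min_branches`` of the five branches.
    Branch-restricted programs are postmitotic by construction (a program
    confined to specific lineages runs after cell-cycle exit), so their centers
    are drawn from the postmitotic pseudotime range; programs active in all
    five branches use the full axis, trunk included. The first ``n_dynamic``
    panel entries are the dynamic genes.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(np.log(0.8), 1.0, size=n_genes)
    theta = rng.uniform(0.5, 3.0, size=n_genes)

    n_marker = int(round(marker_frac * n_genes))
    n_stage = int(round(stage_frac * n_genes))
    if n_dynamic + n_marker + n_stage > n_genes:
        raise ValueError("archetype fractions exceed the panel size")

    panel: list[GeneArchetype] = []
    tips = model.tips
    for j in range(n_dynamic):
        k = int(rng.integers(dynamic_min_branches, 6))
        branches = tuple(rng.choice(np.array(tips, object), size=k, replace=False))
        if k == 5:
            branches = None
            lo = 0.1 * model.pseudotime_max
        else:
            lo = model.mitotic_cutoff + 0.05 * model.pseudotime_max
        panel.append(
            GeneArchetype(
                kind="dynamic",
                base_mean=max(base[j], 0.5),
                dispersion=theta[j],
                shape="bump" if rng.random() < 0.5 else "sigmoid",
                center=rng.uniform(lo, 0.9 * model.pseudotime_max),
                width=rng.uniform(0.05, 0.15) * model.pseudotime_max,
                amplitude=dynamic_amplitude,
                branches=branches,
            )
        )
    for j in range(n_dynamic, n_dynamic + n_marker):
        panel.append(
            GeneArchetype(
                kind="branch_marker",
                base_mean=base[j],
                dispersion=theta[j],
                tip=str(rng.choice(np.array(tips, object))),
                fold=float(rng.uniform(2.0, 6.0)),
            )
        )
    for j in range(n_dynamic + n_marker, n_dynamic + n_marker + n_stage):
        boosted = str(rng.choice(np.array(list(stages), object)))
        panel.append(
            GeneArchetype(
                kind="stage",
                base_mean=base[j],
                dispersion=theta[j],
                stage_factors=tuple(
                    (s, float(rng.uniform(2.0, 4.0)) if s == boosted else 1.0) for s in stages
                ),
            )
        )
    for j in range(n_dynamic + n_marker + n_stage, n_genes):
        panel.append(GeneArchetype(kind="constant", base_mean=base[j], dispersion=theta[j]))
    return panel


# ---------------------------------------------------------------------------
# clones
# ---------------------------------------------------------------------------

def _size_sampler(spec, rng: np.random.Generator) -> Callable[[], int]:
    """Clone-size distribution spec: int, ('constant', k), ('geometric', p) or
    ('uniform', lo, hi); sizes are >= 2 (multicellular)."""
    if isinstance(spec, int):
        if spec < 2:
            raise ValueError("clone size must be >= 2")
        return lambda: spec
    kind = spec[0]
    if kind == "constant":
        if spec[1] < 2:
            raise ValueError("clone size must be >= 2")
        return lambda: int(spec[1])
    if kind == "geometric":
        return lambda: 1 + int(rng.geometric(spec[1]))
    if kind == "uniform":
        lo, hi = int(spec[1]), int(spec[2])
        if lo < 2 or hi < lo:
            raise ValueError("invalid uniform clone-size bounds")
        return lambda: int(rng.integers(lo, hi + 1))
    raise ValueError(f"unknown clone-size spec {spec!r}")


def simulate_clones(
    cells: pd.DataFrame,
    n_clones: int,
    cells_per_clone=("geometric", 0.5),
    dispersion_prob: float = 0.3,
    seed: int = 0,
    mitotic_members: float = 0.0,
    tip_sets: Sequence[Sequence[str]] | None = None,
    extra_barcode_prob: float = 0.1,
):
    """Plant multicellular clones over postmitotic branch-tip cells.

    Each clone is confined to a single tip with probability 1 - dispersion_prob,
    or spread over >= 2 tips otherwise. ``tip_sets`` optionally restricts which
    tip combinations dispersing clones may use (modeling fate restriction);
    ``mitotic_members`` is the expected number of additional mitotic cells per
    clone (Poisson), which gives clones progenitor members. Clones are disjoint.
    With probability ``extra_barcode_prob`` a clone carries a second barcode on
    an overlapping cell subset, exercising barcode-graph merging downstream.

    Returns ``(CloneTable, SyntheticTruth)``; the truth table records each
    clone's planted dispersion flag and tip combination.
    """
    from .clonal import build_clones

    if not 0.0 <= dispersion_prob <= 1.0:
        raise ValueError("dispersion_prob must be in [0, 1]")
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    rng = np.random.default_rng(seed)
    draw_size = _size_sampler(cells_per_clone, rng)

    tip_cells = cells[cells["branch_tip"].notna()]
    pools: dict[str, list[str]] = {}
    for t, grp in tip_cells.groupby("branch_tip", sort=True):
        ids = list(grp.index)
        rng.shuffle(ids)
        pools[t] = ids
    all_tips = sorted(pools)
    mitotic_pool = list(cells.index[cells["mitotic"].to_numpy(bool)])
    rng.shuffle(mitotic_pool)

    if tip_sets is not None:
        tip_sets = [tuple(ts) for ts in tip_sets]
        for ts in tip_sets:
            if len(ts) < 2:
                raise ValueError("dispersal tip sets need >= 2 tips")

    pairs: list[tuple[str, str]] = []
    truth_rows = []
    for c in range(n_clones):
        size = draw_size()
        disperse = bool(rng.random() < dispersion_prob) and size >= 2
        if disperse:
            if tip_sets is not None:
                candidates = list(tip_sets[int(rng.integers(len(tip_sets)))])
            else:
                candidates = all_tips
            avail = [t for t in candidates if pools[t]]
            if len(avail) < 2:
                raise ValueError("not enough postmitotic tip cells to host the requested clones")
            k = int(rng.integers(2, min(size, len(avail)) + 1))
            chosen = list(rng.choice(np.array(avail, object), size=k, replace=False))
            # every chosen tip gets >= 1 cell, the remainder spread at random
            alloc = {t: 1 for t in chosen}
            for _ in range(size - k):
                alloc[chosen[int(rng.integers(k))]] += 1
            members: list[str] = []
            for t, m in alloc.items():
                if len(pools[t]) < m:
                    raise ValueError("not enough postmitotic tip cells to host the requested clones")
                members += [pools[t].pop() for _ in range(m)]
        else:
            weights = np.array([len(pools[t]) for t in all_tips], float)
            if (weights >= size).sum() == 0:
                raise ValueError("not enough postmitotic tip cells to host the requested clones")
            weights[weights < size] = 0.0
            t = all_tips[int(rng.choice(len(all_tips), p=weights / weights.sum()))]
            members = [pools[t].pop() for _ in range(size)]
            chosen = [t]
        if mitotic_members > 0:
            m = int(rng.poisson(mitotic_members))
            m = min(m, len(mitotic_pool))
            members += [mitotic_pool.pop() for _ in range(m)]

        bc = f"bc{c:05d}"
        pairs += [(cell, bc) for cell in members]
        if rng.random() < extra_barcode_prob and len(members) >= 2:
            sub = rng.choice(np.array(members, object), size=max(1, len(members) // 2), replace=False)
            pairs += [(cell, f"{bc}x") for cell in sub]
        truth_rows.append(
            {
                "barcode": bc,
                "n_cells": len(members),
                "n_tip_cells": size,
                "tips": ",".join(sorted(set(chosen))),
                "dispersed": disperse,
                "min_cell": min(members),
            }
        )

    pair_table = pd.DataFrame(pairs, columns=["cell_id", "barcode"])
    clones = build_clones(pair_table, known_cells=cells.index)
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_clones": n_clones,
            "dispersion_prob": dispersion_prob,
            "cells_per_clone": cells_per_clone,
            "mitotic_members": mitotic_members,
        },
        clones=pd.DataFrame(truth_rows).set_index("barcode"),
    )
    return clones, truth


def prime_progenitors(cells: pd.DataFrame, clones) -> pd.DataFrame:
    """Mark mitotic clone members as primed toward their clone's branch tip.

    For every clone whose tip-resident cells occupy exactly one tip, the
    clone's mitotic members get that tip in a new ``primed_tip`` column. Used
    together with ``simulate_expression(..., priming=s)`` to plant a
    fate-biasing progenitor program.
    """
    out = cells.copy()
    out["primed_tip"] = None
    for _, members in clones.clones.items():
        tips = {cells.at[c, "branch_tip"] for c in members if pd.notna(cells.at[c, "branch_tip"])}
        if len(tips) != 1:
            continue
        (tip,) = tips
        for c in members:
            if cells.at[c, "mitotic"]:
                out.at[c, "primed_tip"] = tip
    return out


# ---------------------------------------------------------------------------
# perturbation
# ---------------------------------------------------------------------------

def simulate_perturbation(
    cells: pd.DataFrame,
    depletion: Mapping[str, float],
    ap_pseudotime_shift: float = 0.0,
    n_replicates: int = 2,
    seed: int = 0,
    perturbed_guides: Sequence[str] = ("sgKO-a", "sgKO-b"),
    control_guides: Sequence[str] = ("sgCtrl",),
    dual_guide_frac: float = 0.02,
):
    """Split cells into perturbed/control conditions with planted composition shifts.

    Cells are partitioned at random into ``n_replicates`` replicates and, within
    each, into perturbed and control halves. In the perturbed condition cells of
    clusters named in ``depletion`` survive with the stated factor (subsampling)
    and AP-state cells have their pseudotime shifted by ``ap_pseudotime_shift``.
    Guides of the matching class are assigned per cell; a small fraction of
    cells carries one guide of each class, to exercise downstream exclusion.

    Returns ``(assignment, cells_out, truth)`` where ``assignment`` is the
    per-cell condition table derived with :func:`clonodyn.maturation.assign_conditions`.
    """
    from .maturation import assign_conditions

    for cl, f in depletion.items():
        if cl not in set(cells["cluster"]):
            raise ValueError(f"unknown cluster in depletion map: {cl!r}")
        if not 0.0 < f <= 1.0:
            raise ValueError("depletion factors must lie in (0, 1]")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)

    idx = np.array(cells.index, object)
    rng.shuffle(idx)
    rep_of = {cid: i % n_replicates for i, cid in enumerate(idx)}
    perturbed_mask = rng.random(len(cells)) < 0.5
    pert_of = dict(zip(idx, perturbed_mask))

    keep = []
    for cid in cells.index:
        if pert_of[cid]:
            factor = depletion.get(cells.at[cid, "cluster"], 1.0)
            if rng.random() >= factor:
                continue
        keep.append(cid)
    out = cells.loc[keep].copy()
    is_pert = np.array([pert_of[c] for c in keep], bool)
    if ap_pseudotime_shift != 0.0:
        ap = (out["broad_state"] == "AP").to_numpy() & is_pert
        out.loc[ap, "pseudotime"] = np.maximum(out.loc[ap, "pseudotime"] + ap_pseudotime_shift, 0.0)

    rows = []
    for cid, pert in zip(keep, is_pert):
        own = perturbed_guides if pert else control_guides
        other = control_guides if pert else perturbed_guides
        rows.append((cid, str(own[int(rng.integers(len(own)))]), f"rep{rep_of[cid] + 1}"))
        if rng.random() < dual_guide_frac:
            rows.append((cid, str(other[int(rng.integers(len(other)))]), f"rep{rep_of[cid] + 1}"))
    guides = pd.DataFrame(rows, columns=["cell_id", "guide_id", "replicate"])

    assignment = assign_conditions(guides, tuple(perturbed_guides), tuple(control_guides))
    truth = SyntheticTruth(
        seed=seed,
        params={
            "depletion": dict(depletion),
            "ap_pseudotime_shift": ap_pseudotime_shift,
            "n_replicates": n_replicates,
            "dual_guide_frac": dual_guide_frac,
        },
        perturbation=pd.DataFrame(
            {"condition_truth": np.where(is_pert, "perturbed", "control")},
            index=pd.Index(keep, name="cell_id"),
        ),
    )
    return assignment, out, truth


# ---------------------------------------------------------------------------
# bulk
# ---------------------------------------------------------------------------

def simulate_bulk(
    cells: pd.DataFrame,
    adata: AnnData,
    proportions: Mapping[str, float],
    n_replicates: int = 3,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mix cluster pseudobulk profiles into bulk replicates with known proportions.

    Each replicate is ``sum_c p_c * pseudobulk_c`` with per-gene multiplicative
    log-normal noise of log-SD ``noise``. Returns (bulk table genes x replicates,
    true normalized proportion table replicates x clusters).
    """
    w = np.array([proportions[c] for c in proportions], float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("proportion weights must be >= 0 with positive sum")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)

    clusters = list(proportions)
    counts = np.asarray(adata.layers["counts"])
    profiles = np.column_stack(
        [counts[(cells["cluster"] == c).to_numpy(), :].mean(axis=0) for c in clusters]
    )  # genes x clusters
    p = w / w.sum()
    reps = {}
    for r in range(n_replicates):
        mix = profiles @ p
        if noise > 0:
            mix = mix * rng.lognormal(0.0, noise, size=mix.shape)
        reps[f"rep{r + 1}"] = mix
    bulk = pd.DataFrame(reps, index=adata.var_names)
    true_props = pd.DataFrame(
        np.tile(p, (n_replicates, 1)), index=list(reps), columns=clusters
    )
    return bulk, true_props


def simulate_replicate_proportions(
    cluster_pseudotime: Mapping[str, float],
    maturation_bias: float,
    n_replicates: int,
    concentration: float = 50.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Dirichlet cell-state proportion vectors biased along cluster pseudotime.

    Mean composition is softmax(maturation_bias * standardized cluster
    pseudotime): positive bias shifts mass toward more mature clusters (a
    late-host environment), negative toward immature ones. ``concentration``
    controls replicate-to-replicate variability.
    """
    rng = np.random.default_rng(seed)
    clusters = list(cluster_pseudotime)
    pt = np.array([cluster_pseudotime[c] for c in clusters], float)
    z = (pt - pt.mean()) / (pt.std() if pt.std() > 0 else 1.0)
    mean = np.exp(maturation_bias * z)
    mean /= mean.sum()
    draws = rng.dirichlet(concentration * mean, size=n_replicates)
    return pd.DataFrame(
        draws, index=[f"rep{r + 1}" for r in range(n_replicates)], columns=clusters
    )


# ---------------------------------------------------------------------------
# peaks / coverage (plumbing for the interval utilities and the pipeline)
# ---------------------------------------------------------------------------

def simulate_peak_data(
    seed: int,
    n_peaks_a: int = 120,
    n_peaks_b: int = 120,
    overlap_frac: float = 0.4,
    chrom_sizes: Mapping[str, int] = (("chr1", 2_000_000), ("chr2", 1_500_000)),
    peak_width: int = 400,
    n_fragments: int = 2000,
    frac_in_peaks: float = 0.5,
):
    """Two stage peak sets with planted overlap, fragments with a planted FRiP,
    and a pulse-shaped coverage track over the first set's summits.

    Returns ``(peaks_a, peaks_b, fragments, coverage, truth)`` where the peak and
    fragment tables use 0-based half-open BED coordinates and ``coverage`` is a
    bedGraph-style table (chrom, start, end, value).
    """
    rng = np.random.default_rng(seed)
    chrom_sizes = dict(chrom_sizes)
    chroms = list(chrom_sizes)

    def draw_peaks(n, forbid=None):
        rows = []
        occupied = {c: [] for c in chroms}
        if forbid is not None:
            for _, r in forbid.iterrows():
                occupied[r["chrom"]].append((r["start"], r["end"]))
        while len(rows) < n:
            c = chroms[int(rng.integers(len(chroms)))]
            s = int(rng.integers(0, chrom_sizes[c] - peak_width))
            iv = (s, s + peak_width)
            if any(iv[0] < e and b < iv[1] for b, e in occupied[c]):
                continue
            occupied[c].append(iv)
            rows.append({"chrom": c, "start": iv[0], "end": iv[1], "summit": peak_width // 2})
        return pd.DataFrame(rows)

    peaks_a = draw_peaks(n_peaks_a)
    n_shared = int(round(overlap_frac * n_peaks_b))
    shared_rows = []
    src = peaks_a.sample(n=n_shared, random_state=int(rng.integers(2**31)), replace=False)
    for _, r in src.iterrows():
        jitter = int(rng.integers(-peak_width // 2, peak_width // 2))
        s = max(0, r["start"] + jitter)
        shared_rows.append({"chrom": r["chrom"], "start": s, "end": s + peak_width, "summit": peak_width // 2})
    fresh = draw_peaks(n_peaks_b - n_shared, forbid=peaks_a)
    peaks_b = pd.concat([pd.DataFrame(shared_rows), fresh], ignore_index=True)
    peaks_b = peaks_b.sort_values(["chrom", "start"], ignore_index=True)
    peaks_a = peaks_a.sort_values(["chrom", "start"], ignore_index=True)

    # fragments: a planted fraction lands inside peaks_a
    frag_len = 150
    frags = []
    n_in = int(round(frac_in_peaks * n_fragments))
    for i in range(n_fragments):
        if i < n_in:
            r = peaks_a.iloc[int(rng.integers(len(peaks_a)))]
            s = int(rng.integers(r["start"], max(r["start"] + 1, r["end"] - frag_len)))
            frags.append({"chrom": r["chrom"], "start": s, "end": s + frag_len})
        else:
            # rejection-sample a fragment clear of every peak
            while True:
                c = chroms[int(rng.integers(len(chroms)))]
                s = int(rng.integers(0, chrom_sizes[c] - frag_len))
                sub = peaks_a[(peaks_a["chrom"] == c)]
                if not ((sub["start"] < s + frag_len) & (s < sub["end"])).any():
                    frags.append({"chrom": c, "start": s, "end": s + frag_len})
                    break
    fragments = pd.DataFrame(frags).sort_values(["chrom", "start"], ignore_index=True)

    # triangular coverage pulses centered on peaks_a summits
    cov_rows = []
    for _, r in peaks_a.iterrows():
        center = r["start"] + r["summit"]
        height = float(rng.integers(5, 20))
        half = peak_width // 2
        step = half // 4
        for k in range(4):
            value = height * (1 - k / 4)
            cov_rows.append(
                {"chrom": r["chrom"], "start": center - (k + 1) * step, "end": center - k * step, "value": value}
            )
            cov_rows.append(
                {"chrom": r["chrom"], "start": center + k * step, "end": center + (k + 1) * step, "value": value}
            )
    coverage = (
        pd.DataFrame(cov_rows)
        .query("start >= 0")
        .sort_values(["chrom", "start"], ignore_index=True)
    )
    truth = SyntheticTruth(
        seed=seed,
        params={
            "overlap_frac": overlap_frac,
            "frac_in_peaks": frac_in_peaks,
            "n_shared": n_shared,
        },
    )
    return peaks_a, peaks_b, fragments, coverage, truth
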