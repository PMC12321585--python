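"""End-to-end synthetic pipeline: simulate -> preprocess -> clonal -> dynamics
-> maturation -> peaks, with a checksummed artifact manifest.

Every artifact is a deterministic function of (config, master seed): the master
seed expands into per-stage child seeds via :func:`clonodyn.synthetic.child_seed`,
and rerunning with the same config yields byte-identical files (the determinism
audit asserts this over the manifest checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import clonal, dynamics, io, maturation, peaks, preprocess, synthetic

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("clonodyn")


@dataclass
class RunConfig:
    """Parameters of a full synthetic run; unknown keys are rejected.

    The defaults give a desk-scale dataset (a few thousand cells, hundreds of
    genes) that exercises every stage in about a minute.
    """

    out_dir: str = "clonodyn_run"
    seed: int = 0
    n_cells: int = 4000
    n_genes: int = 600
    n_dynamic_genes: int = 20
    n_clones: int = 250
    dispersion_prob: float = 0.3
    n_permutations: int = 2000
    depleted_cluster_quantile: float = 0.5  # which depleted cluster to pick (by name order)
    depletion_factor: float = 0.5
    ap_pseudotime_shift: float = -0.05
    cohort_shift: float = 0.15
    n_bulk_replicates: int = 8
    verbosity: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the artifact manifest (also written to disk).

    Any stage failure raises, with the failing stage named in the log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)

    io.write_config(asdict(config), out / "config.yaml")
    artifacts: list[dict] = []
    seed = config.seed

    def record(path: Path, stage: str) -> None:
        artifacts.append(
            {"file": str(path.relative_to(out)), "sha256": _sha256(path), "stage": stage}
        )

    def stage(name):
        logger.info("stage %s (seed %d)", name, synthetic.child_seed(seed, name))
        return time.time()

    try:
        # ------------------------------------------------------------- simulate
        t0 = stage("simulate")
        model = synthetic.TrajectoryModel()
        cohorts = [
            synthetic.CohortSpec("early+96h", "early", loc=0.45, scale=0.22),
            synthetic.CohortSpec(
                "late+96h", "late", loc=0.45 + config.cohort_shift, scale=0.22
            ),
        ]
        cells, cells_truth = synthetic.simulate_cells(
            model, config.n_cells, cohorts, synthetic.child_seed(seed, "cells")
        )
        panel = synthetic.archetype_panel(
            config.n_genes,
            model,
            stages=("early", "late"),
            n_dynamic=config.n_dynamic_genes,
            seed=synthetic.child_seed(seed, "panel"),
        )
        adata, expr_truth = synthetic.simulate_expression(
            cells, panel, synthetic.child_seed(seed, "expression")
        )
        clones, clone_truth = synthetic.simulate_clones(
            cells,
            config.n_clones,
            dispersion_prob=config.dispersion_prob,
            seed=synthetic.child_seed(seed, "clones"),
        )
        depleted = sorted(c for c in cells["cluster"].unique() if c not in ("AP", "BP"))
        target_cluster = depleted[int(config.depleted_cluster_quantile * (len(depleted) - 1))]
        assignment, pert_cells, pert_truth = synthetic.simulate_perturbation(
            cells,
            {target_cluster: config.depletion_factor},
            ap_pseudotime_shift=config.ap_pseudotime_shift,
            seed=synthetic.child_seed(seed, "perturbation"),
        )
        peaks_a, peaks_b, fragments, coverage, peak_truth = synthetic.simulate_peak_data(
            synthetic.child_seed(seed, "peaks")
        )

        io.write_cell_table(cells, out / "cells.tsv")
        io.write_matrix(adata, out / "matrix")
        io.write_table(clones.pairs, out / "barcode_table.tsv", index=False)
        io.write_table(clone_truth.clones, out / "clone_truth.tsv")
        io.write_table(expr_truth.genes, out / "gene_truth.tsv")
        io.write_bed(peaks_a, out / "peaks_a.bed")
        io.write_bed(peaks_b, out / "peaks_b.bed")
        io.write_bed(fragments, out / "fragments.bed")
        coverage.to_csv(out / "coverage.bedgraph", sep="\t", index=False, header=False)
        for f in (
            "cells.tsv",
            "matrix/matrix.mtx",
            "matrix/genes.tsv",
            "matrix/barcodes.tsv",
            "barcode_table.tsv",
            "clone_truth.tsv",
            "gene_truth.tsv",
            "peaks_a.bed",
            "peaks_b.bed",
            "fragments.bed",
            "coverage.bedgraph",
        ):
            record(out / f, "simulate")
        logger.info("simulate done in %.1fs", time.time() - t0)

        # ----------------------------------------------------------- preprocess
        t0 = stage("preprocess")
        adata = preprocess.normalize_counts(adata)
        adata = preprocess.scale_genes(adata)
        cells = adata.obs
        cutoff, _ = preprocess.mitotic_threshold(cells, ["AP", "BP"])
        composition = preprocess.state_composition(cells, "cohort", "broad_state")
        io.write_table(composition, out / "state_composition.tsv")
        record(out / "state_composition.tsv", "preprocess")
        logger.info("preprocess done in %.1fs (mitotic cutoff %.3f)", time.time() - t0, cutoff)

        # --------------------------------------------------------------- clonal
        t0 = stage("clonal")
        summary = clonal.classify_dispersion(clones, cells)
        io.write_table(summary.tip_combinations, out / "upset_incidence.tsv", index=False)
        coupling = clonal.coupling_zscores(
            clones,
            cells,
            cluster_key="cluster",
            n_permutations=config.n_permutations,
            seed=synthetic.child_seed(seed, "coupling"),
        )
        io.write_table(coupling.to_long_frame(), out / "coupling.tsv", index=False)
        freq = summary.frequencies.rename_axis("label").to_frame("frequency")
        io.write_table(freq, out / "dispersion_frequencies.tsv")
        for f in ("upset_incidence.tsv", "coupling.tsv", "dispersion_frequencies.tsv"):
            record(out / f, "clonal")
        logger.info("clonal done in %.1fs", time.time() - t0)

        # ------------------------------------------------------------- dynamics
        t0 = stage("dynamics")
        result = dynamics.dynamic_gene_screen(adata, cells)
        final = pd.DataFrame({"gene_id": sorted(result.final)})
        io.write_table(final, out / "dynamic_genes.tsv", index=False)
        provenance = {
            "params": asdict(result.params),
            "per_stage_sizes": {s: len(g) for s, g in result.per_stage.items()},
            "final_size": len(result.final),
        }
        io.write_config(provenance, out / "dynamic_genes_provenance.yaml")
        record(out / "dynamic_genes.tsv", "dynamics")
        record(out / "dynamic_genes_provenance.yaml", "dynamics")
        logger.info("dynamics done in %.1fs", time.time() - t0)

        # ----------------------------------------------------------- maturation
        t0 = stage("maturation")
        shift = maturation.cohort_pseudotime_shift(cells, "early+96h", "late+96h")
        io.write_table(pd.DataFrame([shift]), out / "cohort_shift.tsv", index=False)
        summaries = maturation.cluster_summary_pseudotime(cells)
        props = synthetic.simulate_replicate_proportions(
            summaries.to_dict(),
            maturation_bias=0.8,
            n_replicates=config.n_bulk_replicates,
            seed=synthetic.child_seed(seed, "bulk"),
        )
        scores = maturation.weighted_maturation_score(props, summaries)
        io.write_table(scores.to_frame(), out / "maturation_scores.tsv")
        change = maturation.proportion_change(assignment, pert_cells)
        io.write_table(change.aggregated, out / "proportion_change.tsv")
        states = maturation.per_state_pseudotime_comparison(pert_cells, assignment)
        io.write_table(states, out / "per_state_pseudotime.tsv")
        for f in (
            "cohort_shift.tsv",
            "maturation_scores.tsv",
            "proportion_change.tsv",
            "per_state_pseudotime.tsv",
        ):
            record(out / f, "maturation")
        logger.info("maturation done in %.1fs", time.time() - t0)

        # ---------------------------------------------------------------- peaks
        t0 = stage("peaks")
        classification = peaks.classify_peak_overlap(peaks_a, peaks_b, names=("stage_a", "stage_b"))
        counts = pd.DataFrame([classification.counts])
        signal = peaks.summit_window_signal(coverage, peaks_a, library_size=len(fragments))
        frip = peaks.fraction_reads_in_peaks(fragments, peaks_a)
        counts["frip"] = frip
        io.write_table(counts, out / "peak_classification.tsv", index=False)
        io.write_table(signal, out / "summit_signal.tsv", index=False)
        for f in ("peak_classification.tsv", "summit_signal.tsv"):
            record(out / f, "peaks")
        logger.info("peaks done in %.1fs (FRiP %.3f)", time.time() - t0, frip)
    except Exception:
        logger.exception("pipeline failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest = {"seed": seed, "artifacts": artifacts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
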