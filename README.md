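# clonodyn

Quantitative analysis of lineage-barcoded, pseudotime-ordered single-cell data
from branching neurodevelopmental trajectories — and a synthetic-data generator
that makes every statistic verifiable against planted ground truth, without any
download.

## The problem

In developing brain regions such as the ganglionic eminence, progenitors
produce postmitotic neurons whose identities diverge along a branching
differentiation trajectory. Two questions recur in studies that combine
heritable lineage barcodes (clonal tracing), isochronic birth-dating cohorts,
CRISPR perturbation sequencing and chromatin profiling:

* **Differentiation competence** — do single progenitors give rise to one or
  several terminal precursor states? Measured here by classifying multicellular
  clones as *nondispersing* (confined to one trajectory branch tip) or
  *dispersing* (spanning several), and by **clonal fate coupling**: for cluster
  pair (i, j), the observed number of clones shared between i and j is
  standardized against permutations of the cell→cluster assignment,

      z_ij = (S_ij − mean(S*_ij)) / sd(S*_ij),

  with one-sided empirical P values per direction, `p = (1 + #{S* ≥ S}) /
  (1 + N_perm)` (coupled) and the mirror image (anticoupled), each corrected
  with Benjamini–Hochberg.

* **Maturation competence** — do cohorts born at different times mature at
  different rates? Measured by two-sided Wilcoxon rank-sum tests on pseudotime
  between cohorts; by a **weighted maturation score** for bulk replicates,
  `score_r = Σ_c p_rc · s_c`, with p_rc the deconvolved cell-state proportions
  and s_c the per-cluster median (or mean) pseudotime of the single-cell
  reference; and by perturbation statistics: per-cluster
  `log10(fraction_perturbed / fraction_control)` composition shifts, per-state
  pseudotime comparisons, and per-cluster differentially-expressed-gene counts.

The package also implements a six-step **dynamic-gene screen** (ten pseudotime
sections per branch; per bin, genes whose expression fold change *and*
expressed-fraction difference exceed the across-gene mean + 2 SD of a fitted
normal; branch sets unioned over bins; genes kept when present in ≥ 2 of 5
branches; stage sets unioned) and genomic interval utilities (stage-enriched vs
overlapping peak classification, summit ±500 bp RPKM signal, FRiP).

## Worked example

`examples/02_clonal_coupling.py` plants 300 clones on a simulated five-tip
trajectory. Dispersing clones are restricted to the three projection-neuron
(PN) tips, so PN tip pairs should be coupled and PN–IN pairs anticoupled:

```
coupling between branch tips (z > 0 coupled, z < 0 anticoupled):
cluster_i cluster_j  observed      z  q_coupled  q_anticoupled
      IN1       IN2       0.0 -0.920      1.000          0.667
      IN1       PN1       0.0 -2.951      1.000          0.002
      IN2       PN1       0.0 -3.563      1.000          0.000
      PN1       PN2      89.0  5.380      0.001          1.000
      PN1       PN3      82.0  3.964      0.001          1.000
      PN2       PN3      75.0  3.513      0.001          1.000
```

(abridged) — the three planted PN pairs carry large positive z with small
coupled-side q; every PN–IN pair is significantly anticoupled; the IN1–IN2
pair, which received no planted structure beyond its single-tip clones, is
unremarkable. The other examples cover simulation (`01`), the dynamic-gene
screen (`03`), maturation and perturbation statistics (`04`) and peak-set
classification (`05`); each prints its numbers with a line of interpretation.

A thin CLI wraps the two shell-level entry points:

```bash
clonodyn simulate --seed 1 --out data/          # write a synthetic dataset
clonodyn run --seed 1 --out run/                # full pipeline + manifest
```

`clonodyn run` executes simulate → preprocess → clonal → dynamics → maturation
→ peaks and writes a manifest of sha256-checksummed artifacts; rerunning with
the same seed reproduces every file byte-for-byte.

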