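# symmeth

Genome-wide integration of bacterial DNA methylation with differential gene
expression between a free-living and an endosymbiotic (bacteroid) state.

Rhizobia such as *Bradyrhizobium diazoefficiens* differentiate dramatically
when they move from culture into soybean root-nodule cells, and part of that
switch may be epigenetic: single-molecule (SMRT) sequencing calls N6-methyl-
adenine (m6A) and N4-methyl-cytosine (m4C) marks directly from polymerase
kinetics, so the methylation state of every motif site in the genome can be
compared between the two lifestyles and joined with expression data.
`symmeth` implements that comparison as a reusable, tested pipeline:

* **Motif scanning** — every strand-specific methylatable position of a set
  of degenerate IUPAC motifs (`GANTC`, `CRAGGAT`, the bipartite Type I pair
  `GAGA(N)6RTG`/`CAY(N)6TCTC`, and the symbiosis-exclusive `CCTTGAG`),
  including overlapping occurrences and matches across the origin of a
  circular replicon.
* **Modification-call QC and state calling** — PacBio-style modifications
  GFF records are filtered at coverage ≥ 25 and modQV ≥ 30 (inclusive);
  a motif site is *methylated* in a condition iff a passing call of the right
  modification type sits exactly at its (position, strand).
* **Differential methylation** — per-site state flips (gain/loss) between
  conditions; per-motif summary tables (count, percent methylated, mean
  QV/coverage/IPD ratio); per-gene change counts split into coding vs 5′
  upstream compartments; tallies for genome / symbiosis island / remainder
  with per-kb normalisation; 1-kb sliding-window methylation and GC tracks.
* **Differential expression** — median-centering, quantile normalisation,
  spot averaging, a per-gene two-sample t on log2 intensities with variance
  shrinkage toward the genome-wide mean (prior weight d0 = 4; d0 = 0 gives
  the plain pooled t), Benjamini–Hochberg adjustment, significance at
  adjusted p < 0.001. log2FC = mean(free-living) − mean(bacteroid).
* **Integration** — the candidate list: genes with ≥ 1 methylation state
  change **and** a significant expression change, with headline counts and
  the island percentage.
* **Synthetic data** — a generator for a GC-rich circular genome with a
  lower-GC island, planted motif sites, two-condition methylation states at
  the published per-motif rates, noisy modification calls, and a spotted
  expression matrix with planted log2 fold changes — with full ground truth,
  so every stage is testable against what was planted.

## Worked example

```python
from pathlib import Path
import json, pandas as pd
from symmeth import SimulationConfig, simulate_dataset, run_pipeline

work = Path("example")
config = SimulationConfig(seed=42)          # 100-kb genome, island 30001-45000
dataset = simulate_dataset(config, work / "data")
out = run_pipeline(
    {
        "genome_fasta": str(work / "data/genome.fasta"),
        "annotation": str(work / "data/annotation.tsv"),
        "mods_a": str(work / "data/mods_free_living.gff"),
        "mods_b": str(work / "data/mods_bacteroid.gff"),
        "expression": str(work / "data/expression.tsv"),
        "island_start": config.island_start,
        "island_end": config.island_end,
    },
    work / "run",
)
summary = pd.read_csv(out / "motif_summary.tsv", sep="\t")
print(summary[["condition", "motif", "pct_methylated", "n_methylated", "n_motifs"]]
      .to_string(index=False))
print(json.dumps(json.load(open(out / "integration_counts.json")), indent=1))
```

prints

```
  condition       motif  pct_methylated  n_methylated  n_motifs
free_living       GANTC           99.83           573       574
free_living     CRAGGAT          100.00           408       408
free_living CRAGGAT-m4C            0.00             0       408
free_living GAGA(N)6RTG          100.00           406       406
free_living CAY(N)6TCTC          100.00           406       406
free_living     CCTTGAG            0.00             0       404
  bacteroid       GANTC           97.56           560       574
  bacteroid     CRAGGAT           87.25           356       408
  bacteroid CRAGGAT-m4C            0.00             0       408
  bacteroid GAGA(N)6RTG           84.48           343       406
  bacteroid CAY(N)6TCTC           86.21           350       406
  bacteroid     CCTTGAG           81.19           328       404
{
 "n_candidates_genome": 21,
 "n_candidates_island": 1,
 "n_genes": 83,
 "n_island_genes": 13,
 "n_symbiosis_candidates": 0,
 "n_up_in_a": 10,
 "n_up_in_b": 11,
 "pct_island": 7.7
}
```

Reading the table: the free-living culture is almost fully methylated at the
four constitutive motifs, the bacteroid loses 2–16 percentage points at each
of them, and `CCTTGAG` flips from completely unmethylated in culture to
~81 % methylated in the bacteroid — the simulated analogue of a
symbiosis-specific methyltransferase switching on. The counts block gives
the intersection list: 21 of 83 genes changed in both methylation and
expression, 1 of the 13 island genes. Every table the pipeline writes
(`diff_sites.tsv`, `gene_methylation.tsv`, `regional_tally.tsv`,
`de_results.tsv`, `gene_summaries.tsv`, bedGraph window tracks) lands in the
output directory alongside a run log of all thresholds.

The same stages are exposed as a CLI:

```bash
symmeth simulate --seed 42 --out-dir example/data
symmeth scan --fasta example/data/genome.fasta --out sites.tsv
symmeth run --config pipeline.yaml --out-dir example/run
```

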