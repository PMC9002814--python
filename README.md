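# tadassign

**TAD-aware target-gene assignment heuristics and their evaluation against
promoter-capture Hi-C interactions.**

Genome-wide studies routinely annotate a non-coding region of interest — an
enhancer, an ATAC peak, a GWAS SNP — with its *nearest gene*. Chromosome
conformation data show this is often wrong: most regulatory interactions
skip at least one gene, and their reach is bounded by topologically
associating domains (TADs) rather than by linear distance. `tadassign`
implements the four standard assignment rules and measures how well each
one predicts observed enhancer–promoter contacts:

| rule | definition |
|---|---|
| N. | nearest gene by genomic distance |
| N.E. | nearest gene expressed in the cell type (> 1 TPM in ≥ 1 replicate) |
| N. in TAD | nearest gene whose TSS lies in the region's TAD |
| N.E. in TAD | nearest expressed gene whose TSS lies in the region's TAD |

Evaluation uses promoter-capture Hi-C calls as the gold standard: for each
distal anchor:bait pair (cis, spanning ≤ 2 Mb) a heuristic's prediction is
a true positive when it names one of the genes whose promoters the bait
overlaps. Performance is summarised as the positive predictive value,

```
PPV = TP / (TP + FP)
```

i.e. the probability that an assignment made by the rule is supported by an
observed interaction. A seeded synthetic-landscape generator produces
genomes, TAD partitions, expression tables and truth-labelled interaction
sets, so the entire pipeline is testable at desk scale without any
downloads.

Intended users: computational genomicists who annotate non-coding variants
or peaks and want to quantify (or improve on) nearest-gene assignment, and
method developers needing a calibrated baseline with ground truth.

## Worked example

```python
from tadassign import SimulationParams, simulate, compare_heuristics

params = SimulationParams(seed=7, n_interactions=5000)
landscape, interactions, truth = simulate(params)
report = compare_heuristics(
    interactions, landscape.genes, landscape.tads, landscape.expression,
    unit="pair", denominator="all",
)
print(report[["cell_type", "heuristic", "n_units", "n_true_positive",
              "ppv", "coverage"]].to_string(index=False))
```

```
cell_type heuristic  n_units  n_true_positive    ppv  coverage
      sim         N     5000              756 0.1512    1.0000
      sim        NE     5000              872 0.1744    1.0000
      sim     N_TAD     5000              953 0.1906    0.9946
      sim    NE_TAD     5000             1091 0.2182    0.9208
```

The simulated landscape draws 14% of interactions onto the anchor's
nearest gene and confines 89% to the anchor's TAD, so the nearest-gene
rule recovers a PPV near 0.15 — most assignments are wrong — while
restricting the search to the TAD and to expressed genes raises precision
at a small cost in coverage (anchors whose TAD holds no expressed gene get
no prediction).

The same pipeline runs from the shell:

```sh
tadassign simulate --seed 7 --outdir out/
tadassign assign --regions anchors.bed --genes out/genes.gtf \
    --tads out/tads.bed --expression out/expression.tsv \
    --heuristic all --out assignments.tsv
tadassign evaluate --interactions out/interactions.ibed \
    --genes out/genes.gtf --tads out/tads.bed \
    --expression out/expression.tsv --outdir eval/
tadassign run-all --seed 7 --outdir out/      # all three stages at once
```

Real data drop in the same way: an Ensembl GTF, a BED3 of TAD calls, a TSV
of per-replicate TPM (columns `<cell_type>_<replicate>`), and interaction
calls in CHiCAGO-style ibed or 10-column BEDPE.

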