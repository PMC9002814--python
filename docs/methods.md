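# Methods

## Coordinates and core objects

All internal coordinates are 0-based half-open (BED convention); GTF input
(1-based closed) is converted on read and back on write, so a round trip
shifts the start column by exactly −1 and preserves the end. Chromosome
names are normalised on read (default: strip a leading `chr`) so
mixed-source inputs agree. A gene's TSS is the 5′ end of its body:
`start` on the plus strand, `end − 1` on the minus strand. TADs must form
a sorted, non-overlapping partition per chromosome; overlapping input
intervals are rejected, never repaired.

## Distance and the nearest-gene search

Distance between a query region and a gene is the inner gap between the
two intervals, 0 when they overlap *or abut* (the gap of `[100,200)` and
`[200,300)` is literally zero). A region inside a gene body is therefore
assigned that gene at distance 0 — there is no special intronic handling.
An alternative `distance_mode="tss"` measures the gap to the one-bp TSS
instead; it changes which gene wins when a region sits deep inside a long
gene whose neighbour's TSS is closer.

Ties are resolved by a fixed cascade: (1) smaller gap, (2) smaller
|region midpoint − TSS|, (3) lexicographically smaller `gene_id`. The
cascade makes every assignment a pure function of its inputs; the second
step reflects the intuition that among equally distant bodies the nearer
promoter is the better candidate, and the third is an arbitrary but
reproducible last resort.

The search itself is indexed: per chromosome an interval tree enumerates
overlapping gene bodies (distance 0), and two sorted arrays — genes by
start and genes by end — are walked outward from the region until a
candidate passes the active filter, collecting *all* candidates at the
minimal distance so the tie-break sees every contender. Filters (expressed
genes, TADs) therefore cost a longer walk, never a rebuilt index. The test
suite checks this search against an exhaustive all-pairs scan, tie-breaks
included, on hundreds of randomised instances.

## TAD membership

A query region belongs to the TAD containing its midpoint (a
boundary-spanning region is not split; `max_overlap` is available as an
alternative policy). A gene belongs to the TAD containing its TSS, so a
gene body straddling a boundary counts only where transcription starts.
Both rules are deterministic and cheap; fractional-overlap bookkeeping
buys nothing at TAD scale.

## Evaluation against interaction calls

Interaction calls arrive as bait (promoter fragment, with the names of the
gene promoters it overlaps — possibly several) versus distal anchor.
Before scoring, trans-chromosomal pairs are dropped and cis pairs are kept
only when their span is at most 2 Mb. Span is the inner gap between bait
and anchor (`span_mode="midpoint"` is provided as the alternative
reading). "Expressed" means TPM strictly greater than 1 in at least one
replicate of the cell type; both the threshold and the replicate count are
parameters.

The default evaluation unit is the anchor:bait pair; `unit="anchor"`
deduplicates anchors and pools the bait genes of all their baits. A unit
is a true positive when the heuristic's prediction is among its gold
genes. Two denominators are first-class because the choice is genuinely
ambiguous: `predicted` (the textbook precision, TP/(TP+FP)) and `all`
(units with no prediction — e.g. an anchor whose TAD holds no expressed
gene — count as failures). Reports carry both the counts and the mode, so
either convention can be recomputed from the output. Rows whose bait-gene
field resolves to nothing are retained by the parsers but excluded from
evaluation; anchors overlapping their own bait are kept unless
`drop_bait_anchors` is set.

Counting invariants (TP + FP = predicted; predicted + undefined = units)
and permutation invariance of the report are enforced by tests, as are the
degenerate identities: with a single chromosome-spanning TAD the
TAD-restricted rule equals the plain rule exactly, and with every gene
expressed the expressed variants collapse onto their parents.

## The synthetic landscape

The generator emulates the statistics that make nearest-gene assignment
interesting rather than the mechanics of any assay:

* **TADs**: each chromosome is tiled by non-overlapping intervals drawn
  from a log-normal with median 840 kb (σ = 0.45), the size scale reported
  for mammalian Hi-C maps; the last TAD is truncated at the chromosome
  end.
* **Genes**: a Poisson number per TAD (mean 4) with TSSs placed uniformly
  inside the TAD (minimum spacing 1 kb) and non-overlapping bodies
  (log-normal length, median 20 kb) clipped at the midpoints between
  neighbouring TSSs. A truncated terminal TAD caps its gene draw at what
  its width can hold; a configuration whose density is infeasible at the
  *median* TAD size errors out instead.
* **Expression**: a fixed fraction of genes (default 0.6) draws log-normal
  TPM (median 10, σ = 1) across 2 replicates; the rest draw uniform TPM
  below 1, so the > 1 TPM rule recovers the expressed set almost exactly.
* **Interactions**: for each of *n* interactions two Bernoulli draws fix
  the condition — target is the anchor's nearest gene with probability
  `p_nearest` (default 0.14, matching the reported scarcity of
  nearest-gene contacts), and target lies in the anchor's TAD with
  probability `p_within_tad` (default 0.89, the reported within-TAD
  fraction). Anchors are placed uniformly (so some land inside bystander
  gene bodies, the intronic-enhancer case) and redrawn under bounded
  retries until both conditions and the ≤ 2 Mb span constraint are
  satisfiable; non-nearest targets are then drawn uniformly from the
  eligible genes. The bait is the target's promoter window (TSS ± 2.5 kb,
  a conventional promoter definition), joined by the nearest neighbouring
  promoter with probability `p_multibait` (default 0.05) to exercise
  multi-gene baits. In `strict_mode` (default) a non-nearest target is
  verified against the final nearest-gene call. Truth flags
  (`is_nearest`, `is_within_tad`) are recomputed from the emitted gene and
  TAD sets, so they are consistent with them by construction.

The two Bernoulli draws are treated *jointly*: the within-TAD condition
applies to nearest-gene targets too, which keeps `p_within_tad = 1` an
exact guarantee that every target is within its anchor's TAD and makes the
marginal within-TAD fraction equal the parameter. One consequence used by
the tests: with `p_within_tad = 1` and single-gene baits, every true
positive of the plain nearest-gene rule is also a true positive of the
TAD-restricted rule, so the TAD restriction can only raise PPV — the
directional effect the evaluation is designed to expose.

`truth_ppv` recomputes any PPV by direct per-unit comparison against the
truth labels, sharing no code with the evaluation module's scorer; the two
must agree exactly when baits carry only the true target.

All randomness flows through a single `numpy.random.Generator` seeded from
the mandatory `seed`; outputs are byte-identical across runs.

### What the simulator does not emulate

Restriction-fragment geometry and bait design, distance decay of contact
frequency (non-nearest targets are uniform among eligible genes; a decay
option would sharpen nothing tested here), overlapping or nested gene
bodies (the parsers and search support them; the generator does not emit
them), trans interactions, CNV/mappability artefacts, and nested or
hierarchical TADs. Passing tests therefore demonstrate correctness of the
assignment and scoring machinery under the stated statistical structure,
not performance on any particular real dataset: on real promoter-capture
data the absolute PPVs depend on fragment sizes, bait annotation and TAD
calling upstream.

## Default sizes and numerical choices

The default simulation (4 chromosomes × 30 Mb, ≈ 140 TADs, ≈ 500 genes,
5,000 interactions; 20,000 in the acceptance script) is large enough that
binomial noise on a PPV is a few tenths of a percentage point, while the
whole pipeline runs in seconds. Integer arithmetic is used throughout the
coordinate layer (midpoints floor-divide); PPV with a zero denominator is
reported as NaN rather than 0 to keep "no predictions" distinguishable
from "all predictions wrong". Bounded rejection sampling (default 1,000
anchor redraws) raises a named error when a constraint combination is
unsatisfiable — e.g. a non-nearest target requested in a single-gene
genome — rather than looping forever.

## Known limitations

PPV is the only metric: with at most one prediction per unit and no
negative class, recall/specificity are not meaningful here. Multi-gene
baits make the gold standard slightly permissive (a prediction matching
*any* overlapped promoter counts). The expression rule treats genes absent
from the table as unexpressed, with a logged warning. The evaluation does
not test significance of PPV differences between heuristics.
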