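"""Synthetic regulatory landscapes with ground-truth enhancer targets.

The generator emulates the statistical structure reported for real
promoter-capture interaction maps: chromosomes partitioned into TADs with
a log-normal size distribution (median 840 kb), a few genes per TAD, a
configurable fraction of interactions confined to the anchor's TAD
(default 0.89) and a configurable — deliberately small — fraction whose
target is the anchor's nearest gene (default 0.14, i.e. most enhancers
skip at least one gene).  Every interaction carries a ground-truth target
label, so heuristic performance can be scored against the generative
truth as well as against the emitted interaction calls.

All randomness flows through a single ``numpy.random.Generator`` seeded
from ``SimulationParams.seed``; outputs are byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .assignment import locate_tad, nearest_gene
from .core import (
    Gene,
    GeneSet,
    GenomicRegion,
    Heuristic,
    Interaction,
    InteractionSet,
    SimulationError,
    TADSet,
    ValidationError,
)
from .io_formats import PPV_COLUMNS, ExpressionTable

TRUTH_COLUMNS = [
    "interaction",
    "anchor_chrom",
    "anchor_start",
    "anchor_end",
    "target_gene_id",
    "is_nearest",
    "is_within_tad",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic landscape; defaults encode the study conditions.

    seed is mandatory — there is no unseeded mode.
    """

    seed: int
    n_chromosomes: int = 4
    chromosome_length: int = 30_000_000
    tad_median_bp: int = 840_000      # median TAD size in human Hi-C maps
    tad_sigma: float = 0.45           # log-normal shape
    genes_per_tad: float = 4.0        # Poisson mean
    gene_length_median_bp: int = 20_000
    gene_length_sigma: float = 0.8
    min_tss_spacing: int = 1_000
    fraction_expressed: float = 0.6
    tpm_median: float = 10.0
    tpm_sigma: float = 1.0
    n_replicates: int = 2
    cell_type: str = "sim"
    n_interactions: int = 5_000
    p_within_tad: float = 0.89        # fraction of interactions inside the anchor's TAD
    p_nearest: float = 0.14           # fraction targeting the anchor's nearest gene
    p_multibait: float = 0.05         # fraction of baits covering two promoters
    anchor_size: int = 4_000
    promoter_halfwidth: int = 2_500
    max_span: int = 2_000_000
    strict_mode: bool = True
    max_retries: int = 1_000

    def __post_init__(self) -> None:
        for name in ("p_within_tad", "p_nearest", "p_multibait", "fraction_expressed"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "n_chromosomes", "chromosome_length", "tad_median_bp", "gene_length_median_bp",
            "n_interactions", "anchor_size", "promoter_halfwidth", "max_span",
            "n_replicates", "min_tss_spacing", "max_retries",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.genes_per_tad <= 0:
            raise ValidationError("genes_per_tad must be positive")


@dataclass(frozen=True)
class Landscape:
    genes: GeneSet
    tads: TADSet
    expression: ExpressionTable
    chrom_lengths: dict[str, int]


def promoter_region(gene: Gene, halfwidth: int = 2_500) -> GenomicRegion:
    """Promoter window TSS +/- halfwidth, clipped at the chromosome start."""
    return GenomicRegion(
        gene.region.chrom, max(0, gene.tss - halfwidth), gene.tss + halfwidth + 1
    )


def _tile_tads(rng: np.random.Generator, params: SimulationParams, chrom: str) -> list[GenomicRegion]:
    mu = math.log(params.tad_median_bp)
    out = []
    pos = 0
    L = params.chromosome_length
    while pos < L:
        size = max(10_000, int(rng.lognormal(mu, params.tad_sigma)))
        end = min(pos + size, L)  # last TAD truncated at the chromosome end
        out.append(GenomicRegion(chrom, pos, end))
        pos = end
    return out


def _place_genes(
    rng: np.random.Generator, params: SimulationParams, tad: GenomicRegion, counter: int
) -> tuple[list[Gene], int]:
    n = int(rng.poisson(params.genes_per_tad))
    if n == 0:
        return [], counter
    margin = min(params.promoter_halfwidth, len(tad) // 10)
    lo, hi = tad.start + margin, tad.end - margin
    # a truncated terminal TAD may be far smaller than the median; cap the
    # draw at what its width can hold instead of failing
    n = min(n, (hi - lo) // params.min_tss_spacing)
    if n == 0:
        return [], counter
    for _ in range(100):
        tss = np.sort(rng.integers(lo, hi, size=n))
        if n == 1 or (np.diff(tss) >= params.min_tss_spacing).all():
            break
    else:
        raise SimulationError(
            f"infeasible packing: could not draw {n} TSSs with spacing "
            f">= {params.min_tss_spacing} bp in TAD {tad.chrom}:{tad.start}-{tad.end}"
        )
    bounds = [tad.start] + [int((a + b) // 2) for a, b in zip(tss, tss[1:])] + [tad.end]
    genes = []
    mu = math.log(params.gene_length_median_bp)
    for i, t in enumerate(map(int, tss)):
        length = max(200, int(rng.lognormal(mu, params.gene_length_sigma)))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start, end = t, min(t + length, bounds[i + 1])
            end = max(end, t + 1)
        else:
            start, end = max(t + 1 - length, bounds[i]), t + 1
        counter += 1
        genes.append(
            Gene(
                gene_id=f"G{counter:05d}",
                name=f"SYN{counter:05d}",
                region=GenomicRegion(tad.chrom, start, end),
                strand=strand,
            )
        )
    return genes, counter


def simulate_landscape(
    params: SimulationParams, rng: Optional[np.random.Generator] = None
) -> Landscape:
    """Generate genes, TADs and an expression table.

    Chromosomes are tiled by non-overlapping TADs drawn from the log-normal
    size distribution; gene TSSs are placed uniformly inside TADs with
    non-overlapping bodies; a ``fraction_expressed`` subset of genes gets
    log-normal TPM across replicates, the rest get TPM < 1.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if params.genes_per_tad * params.min_tss_spacing > 0.5 * params.tad_median_bp:
        raise SimulationError(
            "infeasible packing: genes_per_tad x min_tss_spacing exceeds half "
            "the median TAD size; too many genes for the configured length"
        )
    tad_regions: list[GenomicRegion] = []
    genes: list[Gene] = []
    counter = 0
    chrom_lengths = {}
    for c in range(1, params.n_chromosomes + 1):
        chrom = str(c)
        chrom_lengths[chrom] = params.chromosome_length
        for tad in _tile_tads(rng, params, chrom):
            tad_regions.append(tad)
            placed, counter = _place_genes(rng, params, tad, counter)
            genes.extend(placed)
    if not genes:
        raise SimulationError("landscape contains no genes; increase genes_per_tad")
    gene_ids = [g.gene_id for g in genes]
    n_expressed = int(round(params.fraction_expressed * len(gene_ids)))
    expressed = set(rng.choice(gene_ids, size=n_expressed, replace=False)) if n_expressed else set()
    cols = [f"{params.cell_type}_{r + 1}" for r in range(params.n_replicates)]
    mu = math.log(params.tpm_median)
    data = {}
    for gid in gene_ids:
        if gid in expressed:
            data[gid] = rng.lognormal(mu, params.tpm_sigma, size=params.n_replicates)
        else:
            data[gid] = rng.uniform(0.0, 0.99, size=params.n_replicates)
    expr = ExpressionTable(pd.DataFrame.from_dict(data, orient="index", columns=cols))
    return Landscape(
        genes=GeneSet(genes),
        tads=TADSet(tad_regions),
        expression=expr,
        chrom_lengths=chrom_lengths,
    )


def simulate_interactions(
    landscape: Landscape,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[InteractionSet, pd.DataFrame]:
    """Draw anchor:bait interactions with ground-truth target labels.

    For each interaction two Bernoulli draws fix the condition: whether
    the true target is the anchor's nearest gene (``p_nearest``) and
    whether the target lies in the anchor's TAD (``p_within_tad``).
    Anchors are redrawn (bounded retries) until both conditions and the
    span constraint are satisfiable; non-nearest targets are chosen
    uniformly among eligible genes.  The bait is the target's promoter
    window, with a second neighbouring promoter added with probability
    ``p_multibait``.  Truth flags are recomputed from the final placement,
    so they are consistent with the emitted GeneSet/TADSet by
    construction.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    genes, tads = landscape.genes, landscape.tads
    chroms = [c for c in sorted(landscape.chrom_lengths) if genes.on_chromosome(c)]
    if not chroms:
        raise SimulationError("no chromosome carries genes")
    weights = np.array([landscape.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    hw = params.promoter_halfwidth
    tss_by_chrom = {c: genes.tss_index(c) for c in chroms}

    def prom_gap_ok(anchor: GenomicRegion, g: Gene) -> bool:
        return anchor.gap(promoter_region(g, hw)) <= params.max_span

    interactions: list[Interaction] = []
    truth_rows = []
    for idx in range(params.n_interactions):
        want_nearest = rng.random() < params.p_nearest
        want_within = rng.random() < params.p_within_tad
        do_multibait = rng.random() < params.p_multibait
        target: Optional[Gene] = None
        for _ in range(params.max_retries):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            L = landscape.chrom_lengths[chrom]
            a0 = int(rng.integers(0, L - params.anchor_size))
            anchor = GenomicRegion(chrom, a0, a0 + params.anchor_size)
            tid = locate_tad(anchor, tads)
            nearest_id = nearest_gene(anchor, genes).gene_id
            if nearest_id is None or tid is None:
                continue
            near = genes.get(nearest_id)
            tad = tads.region(tid)
            if want_nearest:
                if tad.contains_point(near.tss) != want_within or not prom_gap_ok(anchor, near):
                    continue
                target = near
                break
            # non-nearest branch: vectorised pool over TSS positions.  A
            # promoter [tss-hw, tss+hw+1) has gap <= max_span iff the TSS
            # lies inside the widened anchor window (clipping at the
            # chromosome start only shrinks the gap further).
            tss_arr, order = tss_by_chrom[chrom]
            span_ok = (tss_arr >= anchor.start - params.max_span - hw - 1) & (
                tss_arr <= anchor.end + params.max_span + hw
            )
            in_tad = (tss_arr >= tad.start) & (tss_arr < tad.end)
            pool_idx = np.nonzero(span_ok & (in_tad == want_within))[0]
            pool = [order[i] for i in pool_idx if order[i].gene_id != nearest_id]
            if not pool:
                continue
            target = pool[int(rng.integers(len(pool)))]
            if params.strict_mode and target.gene_id == nearest_id:
                target = None  # pragma: no cover - excluded by construction
                continue
            break
        if target is None:
            raise SimulationError(
                f"could not satisfy constraint (is_nearest={want_nearest}, "
                f"within_tad={want_within}) after {params.max_retries} anchor draws; "
                "the landscape may be too small or too uniform"
            )
        bait_genes = {target.gene_id}
        if do_multibait:
            _, order = tss_by_chrom[target.region.chrom]
            others = [g for g in order if g.gene_id != target.gene_id]
            if others:
                neighbour = min(others, key=lambda g: (abs(g.tss - target.tss), g.gene_id))
                bait_genes.add(neighbour.gene_id)
        bait = promoter_region(target, hw)
        interactions.append(
            Interaction(
                bait=bait,
                bait_genes=frozenset(bait_genes),
                anchor=anchor,
                score=float(np.round(rng.uniform(5.0, 20.0), 3)),
            )
        )
        truth_rows.append(
            {
                "interaction": idx,
                "anchor_chrom": anchor.chrom,
                "anchor_start": anchor.start,
                "anchor_end": anchor.end,
                "target_gene_id": target.gene_id,
                "is_nearest": target.gene_id == nearest_id,
                "is_within_tad": tads.region(tid).contains_point(target.tss),
            }
        )
    return InteractionSet(interactions), pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)


def simulate(params: SimulationParams) -> tuple[Landscape, InteractionSet, pd.DataFrame]:
    """Full simulation through one seeded generator: landscape then
    interactions."""
    rng = np.random.default_rng(params.seed)
    landscape = simulate_landscape(params, rng)
    interactions, truth = simulate_interactions(landscape, params, rng)
    return landscape, interactions, truth


def truth_ppv(
    interactions: InteractionSet,
    truth: pd.DataFrame,
    assignments: pd.DataFrame,
    unit: str = "pair",
    denominator: str = "predicted",
    cell_type: str = "truth",
) -> pd.DataFrame:
    """Recompute PPV by direct per-unit comparison against the generative
    truth.

    Independent oracle for the evaluation module: it never consults
    bait_genes, only the truth target labels.  With single-gene baits
    (bait_genes = {true target}) and matching unit/denominator settings it
    must agree exactly, count for count, with
    :func:`tadassign.evaluation.evaluate_heuristic`.
    """
    if assignments.empty:
        raise ValidationError("assignment table is empty")
    if len(truth) != len(interactions):
        raise ValidationError(
            f"truth table covers {len(truth)} interactions, set has {len(interactions)}"
        )
    if denominator not in ("predicted", "all"):
        raise ValidationError(f"unknown denominator mode {denominator!r}")
    for i, x in enumerate(interactions):
        row = truth.iloc[i]
        if (row["anchor_chrom"], row["anchor_start"], row["anchor_end"]) != (
            x.anchor.chrom, x.anchor.start, x.anchor.end,
        ):
            raise ValidationError(f"truth row {i} does not match interaction {i}")

    pred: dict[tuple, Optional[str]] = {}
    for r in assignments.itertuples(index=False):
        gid = r.gene_id if isinstance(r.gene_id, str) else None
        pred[(r.chrom, int(r.start), int(r.end), r.heuristic)] = gid
    heuristics = sorted({k[3] for k in pred}, key=lambda h: [x.value for x in Heuristic].index(h))

    # units: (anchor key, gold target set)
    if unit == "pair":
        units = [
            ((row["anchor_chrom"], int(row["anchor_start"]), int(row["anchor_end"])),
             {row["target_gene_id"]})
            for _, row in truth.iterrows()
        ]
    elif unit == "anchor":
        gold: dict[tuple, set[str]] = {}
        for _, row in truth.iterrows():
            key = (row["anchor_chrom"], int(row["anchor_start"]), int(row["anchor_end"]))
            gold.setdefault(key, set()).add(row["target_gene_id"])
        units = sorted(gold.items())
    else:
        raise ValidationError(f"unknown evaluation unit {unit!r}")

    rows = []
    for h in heuristics:
        n_pred = n_tp = 0
        for key, gold_set in units:
            k = key + (h,)
            if k not in pred:
                raise ValidationError(f"assignment table lacks a row for anchor {key}, {h}")
            p = pred[k]
            if p is not None:
                n_pred += 1
                if p in gold_set:
                    n_tp += 1
        denom = n_pred if denominator == "predicted" else len(units)
        rows.append(
            {
                "cell_type": cell_type,
                "heuristic": h,
                "unit": unit,
                "denominator_mode": denominator,
                "n_units": len(units),
                "n_predicted": n_pred,
                "n_true_positive": n_tp,
                "ppv": n_tp / denom if denom else math.nan,
                "coverage": n_pred / len(units) if units else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=PPV_COLUMNS)
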