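"""The four target-gene assignment heuristics.

Given a non-coding region of interest the heuristics assign a putative
target gene: the nearest gene (N), the nearest expressed gene (NE), and
each of those restricted to genes whose TSS lies in the region's TAD
(N_TAD, NE_TAD).

Distance semantics
------------------
By default distance is the inner gap between the query region and the gene
*body* (0 when they overlap or abut); ``distance_mode='tss'`` measures the
gap to the one-bp TSS instead.  Ties are broken by (1) smaller
|region midpoint - TSS|, then (2) lexicographically smaller gene_id, so an
assignment is a pure function of its inputs.

TAD membership is decided by the region midpoint for query regions and by
the TSS for genes; both rules are deterministic for boundary-spanning
intervals.
"""

from __future__ import annotations

import bisect
import logging
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd

from .core import (
    ALL_HEURISTICS,
    Assignment,
    Gene,
    GeneSet,
    GenomicRegion,
    Heuristic,
    TADSet,
    ValidationError,
)

log = logging.getLogger(__name__)

CandidateFilter = Callable[[Gene], bool]


def region_distance(a: GenomicRegion, b: GenomicRegion) -> int:
    """Genomic distance between two intervals on the same chromosome.

    0 when the intervals overlap or abut; otherwise the inner gap in bp.
    Symmetric.  Raises for intervals on different chromosomes.
    """
    return a.gap(b)


def _tss_distance(region: GenomicRegion, tss: int) -> int:
    # gap between the region and the single-bp interval [tss, tss+1)
    return max(tss - region.end, region.start - tss - 1, 0)


def locate_tad(region: GenomicRegion, tads: TADSet, policy: str = "midpoint") -> Optional[int]:
    """TAD containing the region, or None.

    policy='midpoint' (default): the TAD containing the region midpoint.
    policy='max_overlap': the TAD with the largest overlap in bp (midpoint
    breaks exact-overlap ties).
    """
    if policy == "midpoint":
        return tads.locate_point(region.chrom, region.midpoint)
    if policy == "max_overlap":
        best: Optional[int] = None
        best_ov = 0
        for tid, t in tads.on_chromosome(region.chrom):
            ov = min(region.end, t.end) - max(region.start, t.start)
            if ov > best_ov:
                best, best_ov = tid, ov
        if best is None:
            return None
        mid_tid = tads.locate_point(region.chrom, region.midpoint)
        if mid_tid is not None:
            mid_ov = min(region.end, tads.region(mid_tid).end) - max(
                region.start, tads.region(mid_tid).start
            )
            if mid_ov == best_ov:
                return mid_tid
        return best
    raise ValidationError(f"unknown TAD policy {policy!r}")


def genes_in_tad(tad_id: int, genes: GeneSet, tads: TADSet) -> list[str]:
    """gene_ids whose TSS lies inside the TAD interval, sorted by TSS."""
    tad = tads.region(tad_id)
    tss_arr, order = genes.tss_index(tad.chrom)
    if tss_arr is None:
        return []
    lo = bisect.bisect_left(tss_arr, tad.start)
    hi = bisect.bisect_left(tss_arr, tad.end)
    return [order[i].gene_id for i in range(lo, hi)]


def _pick(region: GenomicRegion, candidates: list[tuple[int, Gene]], heuristic: Heuristic,
          tad_id: Optional[int]) -> Assignment:
    mid = region.midpoint
    best = min(
        candidates,
        key=lambda dg: (dg[0], abs(mid - dg[1].tss), dg[1].gene_id),
    )
    return Assignment(
        region=region,
        heuristic=heuristic,
        gene_id=best[1].gene_id,
        distance=best[0],
        tad_id=tad_id,
    )


def nearest_gene(
    region: GenomicRegion,
    genes: GeneSet,
    candidate_filter: Optional[CandidateFilter] = None,
    heuristic: Heuristic = Heuristic.N,
    tad_id: Optional[int] = None,
    distance_mode: str = "body",
) -> Assignment:
    """Nearest gene to a region among candidates passing the filter.

    Uses the per-chromosome index: overlap candidates come from the
    interval tree, and the flanks are walked outward through the
    start-sorted (rightwards) and end-sorted (leftwards) gene arrays until
    a candidate passes the filter, collecting every candidate at the
    minimal distance so the tie-break cascade sees them all.
    """
    ok = candidate_filter or (lambda g: True)
    if distance_mode == "tss":
        return _nearest_by_tss(region, genes, ok, heuristic, tad_id)
    if distance_mode != "body":
        raise ValidationError(f"unknown distance mode {distance_mode!r}")

    candidates: list[tuple[int, Gene]] = [
        (0, g) for g in genes.overlapping(region) if ok(g)
    ]
    starts, start_order, ends_sorted, end_order = genes._index_arrays(region.chrom)

    best_right: Optional[int] = None
    right: list[tuple[int, Gene]] = []
    if starts is not None:
        i = bisect.bisect_left(starts, region.end)
        while i < len(starts):
            d = int(starts[i]) - region.end
            if best_right is not None and d > best_right:
                break
            g = start_order[i]
            if ok(g):
                best_right = d
                right.append((d, g))
            i += 1

    best_left: Optional[int] = None
    left: list[tuple[int, Gene]] = []
    if ends_sorted is not None:
        i = bisect.bisect_right(ends_sorted, region.start) - 1
        while i >= 0:
            d = region.start - int(ends_sorted[i])
            if best_left is not None and d > best_left:
                break
            g = end_order[i]
            if ok(g):
                best_left = d
                left.append((d, g))
            i -= 1

    flank_best = min(
        (d for d in (best_right, best_left) if d is not None), default=None
    )
    if candidates:
        # overlap candidates sit at distance 0; abutting flank genes tie
        if flank_best == 0:
            candidates += [dg for dg in right + left if dg[0] == 0]
    elif flank_best is not None:
        candidates = [dg for dg in right + left if dg[0] == flank_best]

    if not candidates:
        return Assignment(region=region, heuristic=heuristic, gene_id=None,
                          distance=None, tad_id=tad_id)
    return _pick(region, candidates, heuristic, tad_id)


def _nearest_by_tss(
    region: GenomicRegion,
    genes: GeneSet,
    ok: CandidateFilter,
    heuristic: Heuristic,
    tad_id: Optional[int],
) -> Assignment:
    tss_arr, order = genes.tss_index(region.chrom)
    if tss_arr is None:
        return Assignment(region=region, heuristic=heuristic, gene_id=None,
                          distance=None, tad_id=tad_id)
    candidates: list[tuple[int, Gene]] = []
    best: Optional[int] = None
    # inside the region: distance 0
    lo = bisect.bisect_left(tss_arr, region.start)
    hi = bisect.bisect_left(tss_arr, region.end)
    for i in range(lo, hi):
        if ok(order[i]):
            best = 0
            candidates.append((0, order[i]))
    # rightwards
    i = hi
    while i < len(tss_arr):
        d = _tss_distance(region, int(tss_arr[i]))
        if best is not None and d > best:
            break
        if ok(order[i]):
            if best is None or d < best:
                best = d
                candidates = [c for c in candidates if c[0] <= d]
            candidates.append((d, order[i]))
        i += 1
    # leftwards
    i = lo - 1
    while i >= 0:
        d = _tss_distance(region, int(tss_arr[i]))
        if best is not None and d > best:
            break
        if ok(order[i]):
            if best is None or d < best:
                best = d
                candidates = [c for c in candidates if c[0] <= d]
            candidates.append((d, order[i]))
        i -= 1
    candidates = [c for c in candidates if c[0] == best]
    if not candidates:
        return Assignment(region=region, heuristic=heuristic, gene_id=None,
                          distance=None, tad_id=tad_id)
    return _pick(region, candidates, heuristic, tad_id)


def assign(
    region: GenomicRegion,
    genes: GeneSet,
    tads: Optional[TADSet],
    expressed_ids: Optional[set[str]],
    heuristic: Heuristic,
    distance_mode: str = "body",
    tad_policy: str = "midpoint",
) -> Assignment:
    """Apply one heuristic to one region.

    N_TAD/NE_TAD return a NONE assignment when the region midpoint falls in
    no TAD or the TAD contains no (expressed) gene TSS.
    """
    heuristic = Heuristic(heuristic)
    tad_id: Optional[int] = None
    if heuristic.uses_tads:
        if tads is None:
            raise ValidationError(f"{heuristic.value} requires a TADSet")
        tad_id = locate_tad(region, tads, policy=tad_policy)
        if tad_id is None:
            return Assignment(region=region, heuristic=heuristic, gene_id=None,
                              distance=None, tad_id=None)
    if heuristic.uses_expression and expressed_ids is None:
        raise ValidationError(f"{heuristic.value} requires an expressed gene set")

    checks: list[CandidateFilter] = []
    if heuristic.uses_expression:
        expr = expressed_ids  # narrow for the closure
        checks.append(lambda g: g.gene_id in expr)
    if heuristic.uses_tads:
        tad = tads.region(tad_id)
        checks.append(lambda g: tad.contains_point(g.tss))
    flt: Optional[CandidateFilter] = None
    if checks:
        flt = lambda g: all(c(g) for c in checks)
    return nearest_gene(region, genes, candidate_filter=flt, heuristic=heuristic,
                        tad_id=tad_id, distance_mode=distance_mode)


def assign_batch(
    regions: Sequence[GenomicRegion],
    genes: GeneSet,
    tads: Optional[TADSet],
    expressed_ids: Optional[set[str]],
    heuristics: Iterable[Heuristic] = ALL_HEURISTICS,
    distance_mode: str = "body",
    tad_policy: str = "midpoint",
) -> pd.DataFrame:
    """Assign every region under every heuristic; one row per region x
    heuristic, sorted deterministically.

    Regions on chromosomes unknown to the GeneSet yield NONE rows with a
    single logged warning.
    """
    heuristics = [Heuristic(h) for h in heuristics]
    known = set(genes.chromosomes())
    unknown = sorted({r.chrom for r in regions} - known)
    if unknown:
        log.warning("regions on %d chromosome(s) without genes: %s",
                    len(unknown), ", ".join(unknown[:5]))
    rows = []
    order = sorted(set(regions))
    for region in order:
        for h in heuristics:
            a = assign(region, genes, tads, expressed_ids, h,
                       distance_mode=distance_mode, tad_policy=tad_policy)
            rows.append(
                {
                    "chrom": region.chrom,
                    "start": region.start,
                    "end": region.end,
                    "heuristic": h.value,
                    "gene_id": a.gene_id,
                    "distance": a.distance,
                    "tad_id": a.tad_id,
                }
            )
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "heuristic", "gene_id", "distance", "tad_id"]
    )
    return df
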