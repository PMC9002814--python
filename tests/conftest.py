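"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
import pytest

from tadassign import Gene, GeneSet, GenomicRegion, TADSet


def mk_gene(gene_id: str, chrom: str, start: int, end: int, strand: str = "+",
            name: Optional[str] = None) -> Gene:
    return Gene(gene_id=gene_id, name=name or gene_id,
                region=GenomicRegion(chrom, start, end), strand=strand)


@pytest.fixture
def two_gene_set() -> GeneSet:
    """A=[100,200)+ and B=[500,600)+ on chromosome 1 (TSS 100 and 500)."""
    return GeneSet([mk_gene("A", "1", 100, 200), mk_gene("B", "1", 500, 600)])


@pytest.fixture
def two_tads() -> TADSet:
    return TADSet([GenomicRegion("1", 0, 500_000), GenomicRegion("1", 500_000, 1_200_000)])


def brute_force_nearest(
    region: GenomicRegion,
    genes: list[Gene],
    candidate_filter: Optional[Callable[[Gene], bool]] = None,
) -> tuple[Optional[str], Optional[int]]:
    """Exhaustive all-pairs nearest-gene scan: gene-body gap, ties broken by
    |region midpoint - TSS| then lexicographic gene_id.  Independent of the
    indexed implementation."""
    ok = candidate_filter or (lambda g: True)
    best: Optional[tuple[int, int, str]] = None
    mid = region.midpoint
    for g in genes:
        if g.region.chrom != region.chrom or not ok(g):
            continue
        gap = max(g.region.start - region.end, region.start - g.region.end, 0)
        key = (gap, abs(mid - g.tss), g.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None, None
    return best[2], best[0]


def random_instance(rng: np.random.Generator, max_genes: int = 1000,
                    max_regions: int = 1000) -> tuple[list[Gene], list[GenomicRegion]]:
    """A random single-chromosome instance with overlapping gene bodies and
    deliberate coordinate duplicates so tie-breaks are exercised."""
    n_genes = int(rng.integers(1, max_genes + 1))
    n_regions = int(rng.integers(1, max_regions + 1))
    span = 10_000_000
    genes = []
    for i in range(n_genes):
        start = int(rng.integers(0, span))
        length = int(rng.integers(100, 50_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(mk_gene(f"g{i:04d}", "1", start, start + length, strand))
    # duplicate a few gene intervals under new ids: identical gap AND
    # identical TSS distance, so only the lexicographic id separates them
    for j in range(min(5, n_genes)):
        src = genes[int(rng.integers(len(genes)))]
        genes.append(mk_gene(f"dup{j}", "1", src.region.start, src.region.end, src.strand))
    regions = []
    for _ in range(n_regions):
        start = int(rng.integers(0, span))
        regions.append(GenomicRegion("1", start, start + int(rng.integers(1, 20_000))))
    return genes, regions
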