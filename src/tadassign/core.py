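"""Core domain types shared by every stage of the pipeline.

All genomic coordinates are 0-based, half-open (BED convention).  Files in
1-based closed conventions (GTF) are converted on read and back on write.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree


class TadassignError(Exception):
    """Base class for all package errors."""


class ValidationError(TadassignError):
    """Input data violates a documented invariant."""


class ParseError(TadassignError):
    """A file could not be parsed; carries file context when known."""

    def __init__(self, message: str, path: Optional[str] = None, line: Optional[int] = None):
        ctx = ""
        if path is not None:
            ctx += f"{path}"
        if line is not None:
            ctx += f":{line}"
        super().__init__(f"{ctx}: {message}" if ctx else message)
        self.path = path
        self.line = line


class SimulationError(TadassignError):
    """A simulation constraint could not be satisfied."""


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap(self, other: "GenomicRegion") -> int:
        """Inner gap in bp between the two intervals; 0 on overlap or abutment.

        Raises ValidationError for intervals on different chromosomes —
        callers must pre-filter trans pairs.
        """
        if self.chrom != other.chrom:
            raise ValidationError(
                f"gap undefined across chromosomes ({self.chrom} vs {other.chrom})"
            )
        return max(other.start - self.end, self.start - other.end, 0)

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Gene:
    """A gene with a strand-aware transcription start site.

    The TSS is the 5' end of the gene body: ``region.start`` on the plus
    strand, ``region.end - 1`` on the minus strand (last base of the
    half-open interval).
    """

    gene_id: str
    name: str
    region: GenomicRegion
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")

    @property
    def tss(self) -> int:
        return self.region.start if self.strand == "+" else self.region.end - 1


class GeneSet:
    """Genes indexed per chromosome for overlap and nearest-neighbour queries.

    Maintains, per chromosome: an interval tree over gene bodies (overlap
    enumeration) plus start-sorted and end-sorted arrays (outward walks for
    nearest-gap queries).
    """

    def __init__(self, genes: Iterable[Gene]):
        self._genes: dict[str, Gene] = {}
        self._by_name: dict[str, list[str]] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g
            self._by_name.setdefault(g.name, []).append(g.gene_id)
        self._build_index()

    def _build_index(self) -> None:
        self._chrom_genes: dict[str, list[Gene]] = {}
        for g in self._genes.values():
            self._chrom_genes.setdefault(g.region.chrom, []).append(g)
        self._starts: dict[str, np.ndarray] = {}
        self._ends_of_start_order: dict[str, np.ndarray] = {}
        self._start_order: dict[str, list[Gene]] = {}
        self._ends_sorted: dict[str, np.ndarray] = {}
        self._end_order: dict[str, list[Gene]] = {}
        self._tss_sorted: dict[str, np.ndarray] = {}
        self._tss_order: dict[str, list[Gene]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for chrom, gl in self._chrom_genes.items():
            by_start = sorted(gl, key=lambda g: (g.region.start, g.region.end, g.gene_id))
            by_end = sorted(gl, key=lambda g: (g.region.end, g.region.start, g.gene_id))
            by_tss = sorted(gl, key=lambda g: (g.tss, g.gene_id))
            self._start_order[chrom] = by_start
            self._starts[chrom] = np.array([g.region.start for g in by_start], dtype=np.int64)
            self._ends_of_start_order[chrom] = np.array(
                [g.region.end for g in by_start], dtype=np.int64
            )
            self._end_order[chrom] = by_end
            self._ends_sorted[chrom] = np.array([g.region.end for g in by_end], dtype=np.int64)
            self._tss_order[chrom] = by_tss
            self._tss_sorted[chrom] = np.array([g.tss for g in by_tss], dtype=np.int64)
            self._trees[chrom] = IntervalTree.from_tuples(
                (g.region.start, g.region.end, g) for g in gl
            )

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def get(self, gene_id: str) -> Gene:
        try:
            return self._genes[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id!r}") from None

    def ids(self) -> list[str]:
        return sorted(self._genes)

    def chromosomes(self) -> list[str]:
        return sorted(self._chrom_genes)

    def on_chromosome(self, chrom: str) -> list[Gene]:
        """Genes on a chromosome, sorted by (start, end, gene_id)."""
        return list(self._start_order.get(chrom, []))

    def resolve(self, label: str) -> Optional[str]:
        """Map a gene name or gene_id to a gene_id (name wins; case-sensitive)."""
        ids = self._by_name.get(label)
        if ids:
            return sorted(ids)[0]
        if label in self._genes:
            return label
        return None

    def overlapping(self, region: GenomicRegion) -> list[Gene]:
        tree = self._trees.get(region.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(region.start, region.end)]
        return sorted(hits, key=lambda g: (g.region.start, g.gene_id))

    # --- raw index accessors used by the nearest-gene walk ---

    def _index_arrays(self, chrom: str):
        return (
            self._starts.get(chrom),
            self._start_order.get(chrom),
            self._ends_sorted.get(chrom),
            self._end_order.get(chrom),
        )

    def tss_index(self, chrom: str):
        return self._tss_sorted.get(chrom), self._tss_order.get(chrom)


class TADSet:
    """A sorted, non-overlapping partition of each chromosome into TADs.

    TAD ids are stable integers assigned in (chromosome, start) order.
    """

    def __init__(self, regions: Iterable[GenomicRegion]):
        by_chrom: dict[str, list[GenomicRegion]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        self._regions: list[GenomicRegion] = []
        self._chrom_slices: dict[str, tuple[int, int]] = {}
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom in sorted(by_chrom):
            tads = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
            for a, b in zip(tads, tads[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"overlapping TADs on {chrom}: "
                        f"[{a.start}, {a.end}) and [{b.start}, {b.end})"
                    )
            lo = len(self._regions)
            self._regions.extend(tads)
            self._chrom_slices[chrom] = (lo, len(self._regions))
            self._starts[chrom] = np.array([t.start for t in tads], dtype=np.int64)
            self._ends[chrom] = np.array([t.end for t in tads], dtype=np.int64)

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self._regions)

    def region(self, tad_id: int) -> GenomicRegion:
        if not (0 <= tad_id < len(self._regions)):
            raise KeyError(f"unknown tad_id {tad_id}")
        return self._regions[tad_id]

    def chromosomes(self) -> list[str]:
        return sorted(self._chrom_slices)

    def on_chromosome(self, chrom: str) -> list[tuple[int, GenomicRegion]]:
        lo, hi = self._chrom_slices.get(chrom, (0, 0))
        return [(i, self._regions[i]) for i in range(lo, hi)]

    def locate_point(self, chrom: str, pos: int) -> Optional[int]:
        """TAD id containing a base-pair position, or None."""
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return None
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0:
            return None
        if pos < self._ends[chrom][i]:
            return self._chrom_slices[chrom][0] + i
        return None


class Heuristic(str, enum.Enum):
    """The four assignment rules."""

    N = "N"            # nearest gene
    NE = "NE"          # nearest expressed gene
    N_TAD = "N_TAD"    # nearest gene within the same TAD
    NE_TAD = "NE_TAD"  # nearest expressed gene within the same TAD

    @property
    def uses_expression(self) -> bool:
        return self in (Heuristic.NE, Heuristic.NE_TAD)

    @property
    def uses_tads(self) -> bool:
        return self in (Heuristic.N_TAD, Heuristic.NE_TAD)

    @property
    def label(self) -> str:
        return {
            Heuristic.N: "N.",
            Heuristic.NE: "N.E.",
            Heuristic.N_TAD: "N. in TAD",
            Heuristic.NE_TAD: "N.E. in TAD",
        }[self]


ALL_HEURISTICS: tuple[Heuristic, ...] = (
    Heuristic.N,
    Heuristic.NE,
    Heuristic.N_TAD,
    Heuristic.NE_TAD,
)


@dataclass(frozen=True)
class Assignment:
    """Result of applying one heuristic to one region."""

    region: GenomicRegion
    heuristic: Heuristic
    gene_id: Optional[str]
    distance: Optional[int]
    tad_id: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.gene_id is None) != (self.distance is None):
            raise ValidationError("gene_id is None iff distance is undefined")


@dataclass(frozen=True)
class Interaction:
    """One pcHi-C call: baited promoter fragment vs distal other-end anchor.

    ``bait_genes`` holds the gene_ids of the promoters the bait overlaps; a
    single bait can cover the promoters of several genes.  Rows with an
    empty bait-gene field are retained but are not evaluable.
    """

    bait: GenomicRegion
    bait_genes: frozenset[str]
    anchor: GenomicRegion
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.bait == self.anchor:
            raise ValidationError("bait and anchor must not denote the identical interval")
        if self.score is not None and self.score < 0:
            raise ValidationError(f"negative interaction score {self.score}")

    @property
    def is_trans(self) -> bool:
        return self.bait.chrom != self.anchor.chrom

    @property
    def evaluable(self) -> bool:
        return len(self.bait_genes) > 0

    def span(self, mode: str = "gap") -> Optional[int]:
        """Genomic span of the interaction; None for trans pairs.

        mode='gap': inner gap between bait and anchor (0 on overlap).
        mode='midpoint': |bait midpoint - anchor midpoint|.
        """
        if self.is_trans:
            return None
        if mode == "gap":
            return self.bait.gap(self.anchor)
        if mode == "midpoint":
            return abs(self.bait.midpoint - self.anchor.midpoint)
        raise ValidationError(f"unknown span mode {mode!r}")


class InteractionSet:
    """An ordered collection of interactions."""

    def __init__(self, interactions: Sequence[Interaction]):
        self._interactions = tuple(interactions)

    def __len__(self) -> int:
        return len(self._interactions)

    def __iter__(self) -> Iterator[Interaction]:
        return iter(self._interactions)

    def __getitem__(self, i: int) -> Interaction:
        return self._interactions[i]

    def filter(self, pred: Callable[[Interaction], bool]) -> "InteractionSet":
        return InteractionSet([x for x in self._interactions if pred(x)])

    @property
    def n_trans(self) -> int:
        return sum(1 for x in self._interactions if x.is_trans)

    @property
    def n_evaluable(self) -> int:
        return sum(1 for x in self._interactions if x.evaluable)
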