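"""Readers and writers for the standard formats the pipeline touches.

Conventions
-----------
* Internal coordinates are always 0-based half-open (BED).  GTF input
  (1-based, closed) is converted on read and back on write.
* Chromosome names are normalised on read; the default strips a leading
  ``chr`` so that mixed-source inputs ("chr1" vs "1") agree.
* Parsers reject malformed rows with the offending line number; they never
  silently repair input.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

from .core import (
    Gene,
    GeneSet,
    GenomicRegion,
    Interaction,
    InteractionSet,
    ParseError,
    TADSet,
    ValidationError,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

GENE_NAME_SEPARATOR = ";"


def normalize_chrom(chrom: str, policy: str = "strip") -> str:
    """Normalise a chromosome name. policy: 'strip' (drop leading 'chr'),
    'add' (ensure leading 'chr'), or 'none'."""
    if policy == "strip":
        return chrom[3:] if chrom.startswith("chr") else chrom
    if policy == "add":
        return chrom if chrom.startswith("chr") else f"chr{chrom}"
    if policy == "none":
        return chrom
    raise ValidationError(f"unknown chromosome normalisation policy {policy!r}")


# ---------------------------------------------------------------------------
# Gene annotation (GTF)
# ---------------------------------------------------------------------------

def read_gene_annotation(
    path: PathLike,
    feature_types: tuple[str, ...] = ("gene",),
    chrom_policy: str = "strip",
) -> GeneSet:
    """Read an Ensembl-flavoured GTF into a :class:`GeneSet`.

    Only rows whose feature column is in ``feature_types`` are kept (one
    Gene per ``gene_id``).  GTF 1-based closed coordinates are converted to
    0-based half-open; the strand-aware TSS is derived from the gene body.
    """
    genes: list[Gene] = []
    seen: set[str] = set()
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ParseError(
                    f"malformed GTF line: expected 9 tab-separated columns, "
                    f"got {len(line.split(chr(9)))}",
                    str(path), lineno,
                )
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:
                raise ParseError(f"malformed GTF line: {exc}", str(path), lineno) from exc
            if feat.featuretype not in feature_types:
                continue
            if feat.strand not in ("+", "-"):
                raise ParseError(
                    f"missing or invalid strand {feat.strand!r}", str(path), lineno
                )
            try:
                gene_id = feat.attributes["gene_id"][0]
            except KeyError:
                raise ParseError("missing gene_id attribute", str(path), lineno) from None
            if gene_id in seen:
                raise ParseError(f"duplicate gene_id {gene_id!r}", str(path), lineno)
            seen.add(gene_id)
            name = feat.attributes.get("gene_name", [gene_id])[0]
            try:
                region = GenomicRegion(
                    normalize_chrom(feat.seqid, chrom_policy),
                    feat.start - 1,  # 1-based closed -> 0-based half-open
                    feat.end,
                )
            except ValidationError as exc:
                raise ParseError(str(exc), str(path), lineno) from exc
            genes.append(Gene(gene_id=gene_id, name=name, region=region, strand=feat.strand))
    return GeneSet(genes)


def write_gene_annotation(genes: GeneSet, path: PathLike, source: str = "tadassign") -> None:
    """Write a GeneSet as GTF ``gene`` features (internal 0-based -> 1-based)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.region.chrom, g.region.start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.name}";'
            fh.write(
                "\t".join(
                    [
                        g.region.chrom,
                        source,
                        "gene",
                        str(g.region.start + 1),
                        str(g.region.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TADs (BED3)
# ---------------------------------------------------------------------------

def read_tads(path: PathLike, chrom_policy: str = "strip") -> TADSet:
    """Read TAD intervals from a BED3 file (0-based half-open).

    Overlapping intervals on one chromosome are a validation error; TAD
    calling upstream must emit a partition.
    """
    regions: list[GenomicRegion] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"expected >= 3 BED columns, got {len(fields)}", str(path), lineno
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", str(path), lineno) from exc
            if start >= end:
                raise ParseError(f"start {start} >= end {end}", str(path), lineno)
            regions.append(GenomicRegion(normalize_chrom(fields[0], chrom_policy), start, end))
    return TADSet(regions)


def write_tads(tads: TADSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for t in tads:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\n")


# ---------------------------------------------------------------------------
# Interactions (BEDPE / CHiCAGO-style ibed)
# ---------------------------------------------------------------------------

IBED_COLUMNS = [
    "bait_chr",
    "bait_start",
    "bait_end",
    "bait_name",
    "otherEnd_chr",
    "otherEnd_start",
    "otherEnd_end",
    "N_reads",
    "score",
]


def _resolve_bait_genes(
    field: str, genes: Optional[GeneSet], unmatched: set[str]
) -> frozenset[str]:
    labels = [x for x in field.replace(",", GENE_NAME_SEPARATOR).split(GENE_NAME_SEPARATOR) if x and x != "."]
    if genes is None:
        return frozenset(labels)
    resolved: set[str] = set()
    for label in labels:
        gid = genes.resolve(label)
        if gid is None:
            unmatched.add(label)
        else:
            resolved.add(gid)
    return frozenset(resolved)


def read_interactions(
    path: PathLike,
    dialect: str,
    genes: Optional[GeneSet] = None,
    chrom_policy: str = "strip",
) -> InteractionSet:
    """Read interaction calls into an :class:`InteractionSet`.

    dialect='ibed': CHiCAGO-style columns bait_chr/bait_start/bait_end/
    bait_name, otherEnd_chr/otherEnd_start/otherEnd_end, N_reads, score.
    dialect='bedpe': 10-column BEDPE; block 1 is the bait and the ``name``
    column carries the ';'-joined bait gene names.

    Bait gene labels are matched against ``genes`` by gene name first and
    gene_id second (case-sensitive); unmatched labels are reported once via
    the module logger.  Rows with no resolvable bait gene are kept but
    flagged non-evaluable; trans-chromosomal rows are kept and removed
    later by the span filter.
    """
    if dialect not in ("ibed", "bedpe"):
        raise ValidationError(f"unknown interaction dialect {dialect!r}")
    rows: list[Interaction] = []
    unmatched: set[str] = set()
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "ibed" and lineno == 1 and fields[0] == "bait_chr":
                continue  # header
            try:
                if dialect == "ibed":
                    if len(fields) < 9:
                        raise ParseError(
                            f"expected 9 ibed columns, got {len(fields)}", str(path), lineno
                        )
                    bait = GenomicRegion(
                        normalize_chrom(fields[0], chrom_policy), int(fields[1]), int(fields[2])
                    )
                    name_field = fields[3]
                    anchor = GenomicRegion(
                        normalize_chrom(fields[4], chrom_policy), int(fields[5]), int(fields[6])
                    )
                    score: Optional[float] = float(fields[8])
                else:
                    if len(fields) < 10:
                        raise ParseError(
                            f"expected 10 BEDPE columns, got {len(fields)}", str(path), lineno
                        )
                    bait = GenomicRegion(
                        normalize_chrom(fields[0], chrom_policy), int(fields[1]), int(fields[2])
                    )
                    anchor = GenomicRegion(
                        normalize_chrom(fields[3], chrom_policy), int(fields[4]), int(fields[5])
                    )
                    name_field = fields[6]
                    score = None if fields[7] == "." else float(fields[7])
            except ParseError:
                raise
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"malformed row: {exc}", str(path), lineno) from exc
            bait_genes = _resolve_bait_genes(name_field, genes, unmatched)
            try:
                rows.append(
                    Interaction(bait=bait, bait_genes=bait_genes, anchor=anchor, score=score)
                )
            except ValidationError as exc:
                raise ParseError(str(exc), str(path), lineno) from exc
    if unmatched:
        log.warning(
            "%d bait gene label(s) did not match any gene name or id: %s",
            len(unmatched),
            ", ".join(sorted(unmatched)[:10]),
        )
    return InteractionSet(rows)


def write_interactions(
    interactions: InteractionSet,
    path: PathLike,
    genes: Optional[GeneSet] = None,
    dialect: str = "ibed",
) -> None:
    """Write interactions; bait gene names are emitted when ``genes`` is given,
    raw ids otherwise."""

    def name_of(gid: str) -> str:
        return genes.get(gid).name if genes is not None and gid in genes else gid

    with open(path, "w") as fh:
        if dialect == "ibed":
            fh.write("\t".join(IBED_COLUMNS) + "\n")
            for x in interactions:
                names = GENE_NAME_SEPARATOR.join(sorted(name_of(g) for g in x.bait_genes)) or "."
                fh.write(
                    "\t".join(
                        [
                            x.bait.chrom,
                            str(x.bait.start),
                            str(x.bait.end),
                            names,
                            x.anchor.chrom,
                            str(x.anchor.start),
                            str(x.anchor.end),
                            "1",
                            f"{x.score if x.score is not None else 0.0:g}",
                        ]
                    )
                    + "\n"
                )
        elif dialect == "bedpe":
            for x in interactions:
                names = GENE_NAME_SEPARATOR.join(sorted(name_of(g) for g in x.bait_genes)) or "."
                fh.write(
                    "\t".join(
                        [
                            x.bait.chrom,
                            str(x.bait.start),
                            str(x.bait.end),
                            x.anchor.chrom,
                            str(x.anchor.start),
                            str(x.anchor.end),
                            names,
                            f"{x.score:g}" if x.score is not None else ".",
                            ".",
                            ".",
                        ]
                    )
                    + "\n"
                )
        else:
            raise ValidationError(f"unknown interaction dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Expression (TSV of per-replicate TPM)
# ---------------------------------------------------------------------------

class ExpressionTable:
    """Per-gene, per-replicate TPM values grouped into cell types.

    Replicate columns are named ``<cell_type>_<replicate>``; the cell-type
    label is everything before the final underscore (a column without an
    underscore is a single-replicate cell type of its own).
    """

    def __init__(self, table: pd.DataFrame):
        if table.empty:
            raise ValidationError("expression table is empty")
        if table.isna().any().any():
            raise ValidationError("expression table contains missing values")
        if (table.to_numpy() < 0).any():
            raise ValidationError("expression table contains negative TPM values")
        self._table = table.astype(float)
        self._cell_types: dict[str, list[str]] = {}
        for col in table.columns:
            label = col.rsplit("_", 1)[0] if "_" in col else col
            self._cell_types.setdefault(label, []).append(col)

    @property
    def table(self) -> pd.DataFrame:
        return self._table

    @property
    def cell_types(self) -> list[str]:
        return sorted(self._cell_types)

    def gene_ids(self) -> list[str]:
        return list(self._table.index)

    def replicates(self, cell_type: str) -> pd.DataFrame:
        """TPM sub-matrix for one cell type (genes x replicates)."""
        try:
            cols = self._cell_types[cell_type]
        except KeyError:
            raise ValidationError(
                f"unknown cell type {cell_type!r}; available: {', '.join(self.cell_types)}"
            ) from None
        return self._table[cols]

    def tpm(self, gene_id: str, cell_type: str) -> np.ndarray:
        return self.replicates(cell_type).loc[gene_id].to_numpy()


def read_expression(path: PathLike) -> ExpressionTable:
    """Read a TSV expression matrix: first column gene_id, remaining columns
    per-replicate TPM.  Non-numeric or missing cells are an error naming the
    row and column."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot read expression table: {exc}", str(path)) from exc
    if df.empty or df.shape[1] == 0:
        raise ParseError("expression table needs >= 1 gene row and >= 1 replicate column", str(path))
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"non-numeric or missing TPM at gene {gene!r}, column {col!r}", str(path)
            )
        numeric[col] = converted
    try:
        return ExpressionTable(numeric)
    except ValidationError as exc:
        raise ParseError(str(exc), str(path)) from exc


def write_expression(expr: ExpressionTable, path: PathLike) -> None:
    expr.table.to_csv(path, sep="\t", index_label="gene_id", float_format="%.4f")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

ASSIGNMENT_COLUMNS = [
    "chrom",
    "start",
    "end",
    "heuristic",
    "gene_id",
    "distance",
    "tad_id",
]

PPV_COLUMNS = [
    "cell_type",
    "heuristic",
    "unit",
    "denominator_mode",
    "n_units",
    "n_predicted",
    "n_true_positive",
    "ppv",
    "coverage",
]


def write_assignments(table: pd.DataFrame, path: PathLike) -> None:
    """Write an assignment table as TSV with a deterministic column order."""
    if table.empty:
        raise ValidationError("refusing to write an empty assignment table")
    missing = [c for c in ASSIGNMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"assignment table missing columns: {missing}")
    table[ASSIGNMENT_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NONE")


def write_ppv_report(report: pd.DataFrame, path: PathLike, format: str = "tsv") -> None:
    """Write a PPV report as TSV or JSON; both renderings carry the same
    numbers."""
    if report.empty:
        raise ValidationError("refusing to write an empty PPV report")
    missing = [c for c in PPV_COLUMNS if c not in report.columns]
    if missing:
        raise ValidationError(f"PPV report missing columns: {missing}")
    out = report[PPV_COLUMNS]
    if format == "tsv":
        out.to_csv(path, sep="\t", index=False, float_format="%.6f")
    elif format == "json":
        records = out.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2)
            fh.write("\n")
    else:
        raise ValidationError(f"unknown report format {format!r}")


def read_regions_bed(path: PathLike, chrom_policy: str = "strip") -> list[GenomicRegion]:
    """Read query regions (e.g. distal anchors, peaks, SNP windows) from BED."""
    regions: list[GenomicRegion] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"expected >= 3 BED columns", str(path), lineno)
            try:
                regions.append(
                    GenomicRegion(
                        normalize_chrom(fields[0], chrom_policy),
                        int(fields[1]),
                        int(fields[2]),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(str(exc), str(path), lineno) from exc
    return regions
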