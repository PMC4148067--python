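"""Readers and writers for every on-disk format the pipeline touches.

Formats and dialects
--------------------
* ``chrom.sizes`` — UCSC two-column whitespace-separated (name, length).
* clone table — BED-like TSV: chrom, start (0-based), end (half-open),
  clone_id, clone_type ∈ {cosmid, fosmid, yac} (case-insensitive on input).
* RepeatMasker ``.out`` — standard 3 header lines then whitespace-separated
  columns; query coordinates are 1-based inclusive and converted at the
  boundary.  Strand ``C`` (complement) is accepted and ignored — all
  analyses here are strand-agnostic.
* GFF3 — 1-based inclusive; gene category is derived from the feature type
  and the ``biotype``/``gene_biotype`` attribute (see
  :data:`GFF3_TYPE_CATEGORY`).

Every reader *rejects* malformed records with the offending line number —
silent skipping would let corrupt annotation files bias downstream
statistics.  Plain-gzip input is supported transparently (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional
from urllib.parse import unquote

import pandas as pd

from .intervals import ChromSizes, GenomicInterval

logger = logging.getLogger(__name__)

CLONE_TYPES = ("cosmid", "fosmid", "yac")


class ParseError(ValueError):
    """A malformed record, carrying file and line context."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass(frozen=True)
class CloneRecord:
    """A placed clone: cosmid/fosmid (bacteria-clonable) or YAC (yeast)."""

    clone_id: str
    clone_type: str
    interval: GenomicInterval
    parent_id: Optional[str] = None  # set on trimmed YAC-exclusive pieces

    def __post_init__(self):
        if self.clone_type not in CLONE_TYPES:
            raise ValueError(
                f"clone {self.clone_id!r}: unknown clone_type {self.clone_type!r} "
                f"(expected one of {CLONE_TYPES})"
            )

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class RepeatAnnotation:
    """One RepeatMasker element hit with its class/family label."""

    interval: GenomicInterval
    repeat_name: str
    repeat_class: str
    score: float = 0.0

    def __post_init__(self):
        if not self.repeat_class:
            raise ValueError("repeat_class must be non-empty")


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene with its product category and 21U-piRNA flag."""

    gene_id: str
    interval: GenomicInterval
    category: str  # CDS | ncRNA | tRNA | rRNA | other
    is_21u: bool = False

    def __post_init__(self):
        if self.category not in ("CDS", "ncRNA", "tRNA", "rRNA", "other"):
            raise ValueError(f"gene {self.gene_id!r}: bad category {self.category!r}")
        if self.is_21u and self.category != "ncRNA":
            raise ValueError(f"gene {self.gene_id!r}: is_21u requires category ncRNA")

    @property
    def length(self) -> int:
        return self.interval.length


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path) -> ChromSizes:
    """Read a UCSC-style two-column chromosome sizes file."""
    sizes = ChromSizes()
    n = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(path, lineno, f"expected 2 columns, got {len(fields)}")
            name, length_s = fields[0], fields[1]
            try:
                length = int(length_s)
            except ValueError:
                raise ParseError(path, lineno, f"non-integer length {length_s!r}") from None
            try:
                sizes.add(name, length)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            n += 1
    if n == 0:
        logger.warning("chrom sizes file %s is empty", path)
    return sizes


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    with open(path, "wt") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# clone table


def read_clone_table(path, sizes: Optional[ChromSizes] = None) -> List[CloneRecord]:
    """Read the 5-column BED-like clone table.

    Columns: chrom, start (0-based), end (half-open), clone_id, clone_type.
    When *sizes* is given each interval is validated against its chromosome
    length. An optional sixth column carries a parent clone id.
    """
    records: List[CloneRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(path, lineno, f"expected >=5 tab-separated columns, got {len(fields)}")
            chrom, start_s, end_s, clone_id, clone_type = fields[:5]
            parent = fields[5] if len(fields) > 5 and fields[5] else None
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            ctype = clone_type.strip().lower()
            if ctype not in CLONE_TYPES:
                raise ParseError(path, lineno, f"unknown clone_type {clone_type!r}")
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            if sizes is not None:
                if chrom not in sizes:
                    raise ParseError(path, lineno, f"unknown chromosome {chrom!r}")
                if end > sizes[chrom]:
                    raise ParseError(
                        path, lineno,
                        f"interval end {end} exceeds {chrom} length {sizes[chrom]}",
                    )
            records.append(CloneRecord(clone_id, ctype, interval, parent))
    return records


def write_clone_table(clones: Iterable[CloneRecord], path) -> None:
    with open(path, "wt") as fh:
        fh.write("#chrom\tstart\tend\tclone_id\tclone_type\tparent_id\n")
        for c in clones:
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                f"{c.clone_id}\t{c.clone_type}\t{c.parent_id or ''}\n"
            )


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def read_repeatmasker_out(path) -> List[RepeatAnnotation]:
    """Parse a standard RepeatMasker ``.out`` file.

    The first three lines are the fixed header; data lines are
    whitespace-separated with at least 11 columns.  Query begin/end are
    1-based inclusive and converted to internal half-open coordinates.
    Lines flagged with a trailing ``*`` (overlapping higher-scoring hit)
    are accepted like any other.
    """
    annotations: List[RepeatAnnotation] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if lineno <= 3:
                continue  # fixed 3-line header
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 11:
                raise ParseError(path, lineno, f"expected >=11 columns, got {len(fields)}")
            score_s, query = fields[0], fields[4]
            qbegin_s, qend_s = fields[5], fields[6]
            strand = fields[8]
            repeat_name, repeat_class = fields[9], fields[10]
            if strand not in ("+", "C"):
                raise ParseError(path, lineno, f"bad strand field {strand!r}")
            try:
                score = float(score_s)
                qbegin, qend = int(qbegin_s), int(qend_s)
            except ValueError:
                raise ParseError(path, lineno, "non-numeric score/coordinates") from None
            try:
                interval = GenomicInterval.from_one_based_inclusive(query, qbegin, qend)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            annotations.append(RepeatAnnotation(interval, repeat_name, repeat_class, score))
    return annotations


def write_repeatmasker_out(annotations: Iterable[RepeatAnnotation], path) -> None:
    """Write annotations in RepeatMasker ``.out`` layout (round-trippable)."""
    with open(path, "wt") as fh:
        fh.write(_RM_HEADER)
        for i, a in enumerate(annotations, 1):
            iv = a.interval
            fh.write(
                f"{a.score:>5.0f}  0.0  0.0  0.0  {iv.chrom} "
                f"{iv.start + 1} {iv.end} (0) + {a.repeat_name} {a.repeat_class} "
                f"1 {iv.length} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 genes

#: feature-type → gene category used when no biotype attribute decides first
GFF3_TYPE_CATEGORY = {
    "tRNA": "tRNA",
    "tRNA_gene": "tRNA",
    "rRNA": "rRNA",
    "rRNA_gene": "rRNA",
    "mRNA": "CDS",
    "CDS": "CDS",
    "protein_coding_gene": "CDS",
    "ncRNA": "ncRNA",
    "piRNA": "ncRNA",
    "snoRNA": "ncRNA",
    "snRNA": "ncRNA",
    "miRNA": "ncRNA",
    "lincRNA": "ncRNA",
    "ncRNA_gene": "ncRNA",
}

_GENE_TYPES = set(GFF3_TYPE_CATEGORY) | {"gene"}

_21U_NAME = re.compile(r"^21ur-", re.IGNORECASE)


def _parse_gff3_attributes(attr_field: str, path, lineno: int) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    if attr_field in (".", ""):
        return attrs
    for item in attr_field.rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ParseError(path, lineno, f"unparseable attribute {item!r}")
        key, _, value = item.partition("=")
        attrs[key.strip()] = unquote(value.strip())
    return attrs


def _categorize(ftype: str, biotype: Optional[str]) -> str:
    if biotype:
        b = biotype.lower()
        if b in ("trna",):
            return "tRNA"
        if b in ("rrna",):
            return "rRNA"
        if b == "protein_coding":
            return "CDS"
        if "rna" in b:
            return "ncRNA"
        return "other"
    return GFF3_TYPE_CATEGORY.get(ftype, "other")


def read_gff3_genes(path) -> List[GeneRecord]:
    """Read gene-level features from a GFF3 file.

    One :class:`GeneRecord` per gene-like feature (``gene`` plus the RNA
    feature types that appear without a ``gene`` parent).  Child features
    (mRNA/CDS/exon with a ``Parent``) refine the parent's category but do
    not produce records of their own.  A gene is flagged 21U-piRNA when its
    category is ncRNA and either its name matches the ``21ur-`` convention
    or its biotype is ``piRNA``.
    """
    genes: Dict[str, dict] = {}  # gene_id -> builder
    order: List[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, f"expected 9 columns, got {len(fields)}")
            chrom, _source, ftype, start_s, end_s, _score, _strand, _phase, attr_field = fields
            attrs = _parse_gff3_attributes(attr_field, path, lineno)
            parent = attrs.get("Parent")
            if parent is not None:
                # child feature: refine parent's category (mRNA/CDS ⇒ CDS)
                if parent in genes and ftype in ("mRNA", "CDS"):
                    genes[parent]["category"] = "CDS"
                continue
            if ftype not in _GENE_TYPES:
                continue
            try:
                start, end = int(start_s), int(end_s)
                interval = GenomicInterval.from_one_based_inclusive(chrom, start, end)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            gene_id = attrs.get("ID") or attrs.get("Name")
            if not gene_id:
                raise ParseError(path, lineno, "gene feature lacks ID/Name attribute")
            biotype = attrs.get("biotype") or attrs.get("gene_biotype")
            name = attrs.get("Name", gene_id)
            category = _categorize(ftype, biotype)
            if gene_id in genes:
                raise ParseError(path, lineno, f"duplicate gene ID {gene_id!r}")
            genes[gene_id] = {
                "interval": interval,
                "category": category,
                "name": name,
                "biotype": biotype,
            }
            order.append(gene_id)
    out: List[GeneRecord] = []
    for gid in order:
        g = genes[gid]
        looks_21u = bool(_21U_NAME.match(g["name"])) or (g["biotype"] or "").lower() == "pirna"
        is21 = looks_21u and g["category"] == "ncRNA"
        if looks_21u and g["category"] != "ncRNA":
            logger.warning(
                "gene %s matches the 21U naming convention but has category %s; "
                "not flagging as 21U", gid, g["category"],
            )
        out.append(GeneRecord(gid, g["interval"], g["category"], is21))
    return out


def write_gff3_genes(genes: Iterable[GeneRecord], path) -> None:
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            ftype = {"CDS": "gene", "other": "gene"}.get(g.category, g.category)
            biotype = {
                "CDS": "protein_coding",
                "ncRNA": "piRNA" if g.is_21u else "ncRNA",
                "tRNA": "tRNA",
                "rRNA": "rRNA",
                "other": "other",
            }[g.category]
            fh.write(
                f"{iv.chrom}\t.\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t+\t.\t"
                f"ID={g.gene_id};Name={g.gene_id};biotype={biotype}\n"
            )


# ---------------------------------------------------------------------------
# report writing


def write_report(tables: Dict[str, pd.DataFrame], outdir) -> List[Path]:
    """Write each named table as a TSV with deterministic formatting.

    Column order is the DataFrame's; floats are printed with 2 decimals
    (percentages and per-clone means are reported at that precision), so a
    fixed input yields a byte-identical file across runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.2f", lineterminator="\n")
        written.append(path)
    return written
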