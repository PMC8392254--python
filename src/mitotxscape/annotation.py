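"""Genome-annotation data model and I/O.

All coordinates are 0-based half-open internally.  Conversion to the 1-based
inclusive convention of GFF3 (and of boundary tables, which follow GFF3)
happens only at the I/O boundary; BED and bedGraph are already 0-based
half-open.  Annotations must be linearized: features spanning the origin of a
circular genome are not supported and must be split or rotated beforehand.
"""
from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from ._util import round_half_up

FEATURE_CLASSES = ("protein", "rRNA", "tRNA", "orf")
BOUNDARY_KINDS = ("tss", "terminus_3p")
SPLICE_TYPES = ("cis", "trans")
MECHANISMS = ("branching", "hydrolytic", "both")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


def _normalize_intervals(intervals: Sequence[tuple[int, int]], length: int,
                         what: str = "interval") -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted((int(s), int(e)) for s, e in intervals):
        if not (0 <= s < e <= length):
            raise AnnotationError(
                f"{what} ({s}, {e}) outside [0, {length}) or empty")
        if out and s <= out[-1][1]:
            # merge touching/overlapping intervals
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class GenomeRef:
    """A (linearized) reference genome with optional sequence and mask.

    ``masked_intervals`` are half-open regions excluded from every depth
    statistic — in plant mtDNA these are typically plastid-like insertions
    that attract mis-mapped chloroplast reads.
    """

    name: str
    length: int
    sequence: str | None = None
    masked_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise AnnotationError(f"genome length must be > 0, got {self.length}")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise AnnotationError(
                    f"sequence length {len(self.sequence)} != declared length {self.length}")
            bad = set(self.sequence) - set("ACGTN")
            if bad:
                raise AnnotationError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
        self.masked_intervals = _normalize_intervals(
            self.masked_intervals, self.length, "masked interval")


@dataclass
class GeneFeature:
    """A gene or gene region (trans-spliced genes contribute one region each,
    tied together by a shared ``coding_unit_id``)."""

    gene_id: str
    strand: str
    feature_class: str = "protein"
    exons: list[tuple[int, int]] = field(default_factory=list)
    coding_unit_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.feature_class not in FEATURE_CLASSES:
            raise AnnotationError(
                f"{self.gene_id}: feature_class {self.feature_class!r} not in {FEATURE_CLASSES}")
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: exons must be non-empty")
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        for s, e in self.exons:
            if s >= e:
                raise AnnotationError(f"{self.gene_id}: empty exon ({s}, {e})")
        if self.exons != sorted(self.exons):
            raise AnnotationError(f"{self.gene_id}: exons not sorted by start")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise AnnotationError(f"{self.gene_id}: overlapping exons")
        if self.coding_unit_id is None:
            self.coding_unit_id = self.gene_id

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint (first exon start, last exon end)."""
        return self.start, self.end

    @property
    def transcript_length(self) -> int:
        """Spliced length: sum of exon lengths."""
        return sum(e - s for s, e in self.exons)

    def exons_in_transcript_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def validate_against(self, ref: GenomeRef) -> None:
        if not (0 <= self.start and self.end <= ref.length):
            raise AnnotationError(
                f"{self.gene_id}: exons outside genome [0, {ref.length})")


@dataclass
class IntronFeature:
    """A group II intron.  ``donor_pos``/``acceptor_pos`` are genomic boundary
    coordinates (half-open cut points): donor is the exon|5'-intron boundary,
    acceptor the 3'-intron|exon boundary, both in transcript orientation —
    for a minus-strand intron the donor is therefore the genomically larger
    coordinate."""

    intron_id: str
    gene_id: str
    splice_type: str
    mechanism: str
    donor_pos: int
    acceptor_pos: int
    flanking_exon_lengths: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.splice_type not in SPLICE_TYPES:
            raise AnnotationError(
                f"{self.intron_id}: splice_type {self.splice_type!r} not in {SPLICE_TYPES}")
        if self.mechanism not in MECHANISMS:
            raise AnnotationError(
                f"{self.intron_id}: mechanism {self.mechanism!r} not in {MECHANISMS}")

    @property
    def genomic_interval(self) -> tuple[int, int]:
        lo, hi = sorted((self.donor_pos, self.acceptor_pos))
        return lo, hi


@dataclass
class KnownBoundary:
    """An experimentally determined transcript boundary (promoter/TSS or
    processed 3' terminus)."""

    gene_id: str
    kind: str
    position: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in BOUNDARY_KINDS:
            raise AnnotationError(f"{self.gene_id}: kind {self.kind!r} not in {BOUNDARY_KINDS}")


# ---------------------------------------------------------------------------
# readers


def _sniff_dialect(path: str) -> str:
    lower = path.lower()
    if lower.endswith((".gff", ".gff3")):
        return "gff3"
    if lower.endswith((".bed", ".bed12", ".bed6")):
        return "bed"
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gff-version"):
                return "gff3"
            if line.strip() and not line.startswith("#"):
                return "bed" if len(line.split("\t")) in (6, 12) else "gff3"
    raise AnnotationError(f"cannot determine annotation dialect of {path}")


def _read_gff3(path: str) -> tuple[GenomeRef, list[GeneFeature], list[IntronFeature]]:
    seq_region: tuple[str, int] | None = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    seq_region = (parts[1], int(parts[3]))
                break

    db = gffutils.create_db(path, dbfn=":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")

    if seq_region is None:
        regions = list(db.features_of_type(("region", "chromosome")))
        if regions:
            seq_region = (regions[0].seqid, regions[0].end)
    if seq_region is None:
        raise AnnotationError(
            f"{path}: no ##sequence-region pragma or region feature; genome length unknown")
    ref = GenomeRef(name=seq_region[0], length=seq_region[1])

    genes: list[GeneFeature] = []
    for g in db.features_of_type("gene"):
        gene_id = g.attributes.get("ID", [g.id])[0]
        exons = [(c.start - 1, c.end) for c in db.children(g, featuretype="exon")]
        if not exons:
            exons = [(g.start - 1, g.end)]
        try:
            gf = GeneFeature(
                gene_id=gene_id,
                strand=g.strand,
                feature_class=g.attributes.get("feature_class", ["protein"])[0],
                exons=sorted(exons),
                coding_unit_id=g.attributes.get("coding_unit", [None])[0],
            )
            gf.validate_against(ref)
        except AnnotationError as exc:
            raise AnnotationError(f"{path}: gene {gene_id}: {exc}") from exc
        genes.append(gf)
    gene_by_id = {g.gene_id: g for g in genes}

    introns: list[IntronFeature] = []
    for i in db.features_of_type("intron"):
        intron_id = i.attributes.get("ID", [i.id])[0]
        parent = i.attributes.get("Parent", [""])[0]
        start0, end = i.start - 1, i.end
        if i.strand == "+":
            donor, acceptor = start0, end
        else:
            donor, acceptor = end, start0
        flank = (0, 0)
        if parent in gene_by_id:
            flank = _flanking_exon_lengths(gene_by_id[parent], start0, end)
        introns.append(IntronFeature(
            intron_id=intron_id,
            gene_id=parent,
            splice_type=i.attributes.get("splice_type", ["cis"])[0],
            mechanism=i.attributes.get("mechanism", ["branching"])[0],
            donor_pos=donor,
            acceptor_pos=acceptor,
            flanking_exon_lengths=flank,
        ))
    return ref, genes, introns


def _flanking_exon_lengths(gene: GeneFeature, i_start: int, i_end: int) -> tuple[int, int]:
    """(upstream, downstream) exon lengths around a genomic intron interval,
    in transcript order."""
    left = next((e - s for s, e in gene.exons if e == i_start), 0)
    right = next((e - s for s, e in gene.exons if s == i_end), 0)
    return (left, right) if gene.strand == "+" else (right, left)


_BED12_COLS = ["chrom", "start", "end", "name", "score", "strand", "thickStart",
               "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts"]


def _read_bed(path: str, genome_length: int | None = None
              ) -> tuple[GenomeRef, list[GeneFeature], list[IntronFeature]]:
    rows = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    ncol = rows.shape[1]
    if ncol not in (6, 12):
        raise AnnotationError(f"{path}: expected BED6 or BED12, got {ncol} columns")
    rows.columns = _BED12_COLS[:ncol]
    genes: list[GeneFeature] = []
    for idx, r in rows.iterrows():
        try:
            start, end = int(r["start"]), int(r["end"])
            if ncol == 12:
                n = int(r["blockCount"])
                sizes = [int(x) for x in str(r["blockSizes"]).rstrip(",").split(",")]
                offs = [int(x) for x in str(r["blockStarts"]).rstrip(",").split(",")]
                if len(sizes) != n or len(offs) != n:
                    raise AnnotationError(f"blockCount={n} but {len(sizes)} sizes/{len(offs)} starts")
                exons = [(start + o, start + o + sz) for o, sz in zip(offs, sizes)]
                if exons[-1][1] != end:
                    raise AnnotationError("blocks do not end at chromEnd")
            else:
                exons = [(start, end)]
            genes.append(GeneFeature(gene_id=str(r["name"]), strand=str(r["strand"]),
                                     exons=exons))
        except (ValueError, AnnotationError) as exc:
            raise AnnotationError(f"{path}: line {idx + 1}: {exc}") from exc
    length = genome_length if genome_length is not None else max(g.end for g in genes)
    ref = GenomeRef(name=str(rows["chrom"].iloc[0]), length=length)
    for g in genes:
        g.validate_against(ref)
    return ref, genes, []


def read_boundary_table(path: str) -> list[KnownBoundary]:
    """Read a promoter/terminus TSV with columns gene_id, kind, position
    (1-based), label; positions are shifted to 0-based internally."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "kind", "position"}
    if not required.issubset(df.columns):
        raise AnnotationError(f"{path}: boundary table needs columns {sorted(required)}")
    out = []
    for idx, r in df.iterrows():
        try:
            out.append(KnownBoundary(
                gene_id=r["gene_id"], kind=r["kind"],
                position=int(r["position"]) - 1,
                label="" if "label" not in df.columns or pd.isna(r.get("label")) else str(r["label"]),
            ))
        except (ValueError, AnnotationError) as exc:
            raise AnnotationError(f"{path}: line {idx + 2}: {exc}") from exc
    return out


def read_mask_bed(path: str) -> list[tuple[int, int]]:
    """Read masked regions (plastid-like insertions) from a BED3 file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return [(int(r.start), int(r.end)) for r in df.itertuples()]


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def read_annotation(gff_or_bed_path: str, promoter_table_path: str | None = None,
                    fasta_path: str | None = None, mask_path: str | None = None,
                    dialect: str | None = None,
                    ) -> tuple[GenomeRef, list[GeneFeature], list[IntronFeature],
                               list[KnownBoundary]]:
    """Load a genome annotation bundle.

    Parameters
    ----------
    gff_or_bed_path
        GFF3 (genes, exons, introns with splice metadata) or BED6/BED12
        (genes only).  The dialect is sniffed unless given.
    promoter_table_path
        Optional TSV of known TSS / 3'-termini (1-based positions).
    fasta_path
        Optional genome FASTA; attaches the sequence (needed only for the
        promoter-sequence scan) and fixes the genome length for BED input.
    mask_path
        Optional BED3 of regions excluded from depth statistics.
    """
    if not os.path.exists(gff_or_bed_path):
        raise FileNotFoundError(gff_or_bed_path)
    dialect = dialect or _sniff_dialect(gff_or_bed_path)
    seqs = read_fasta(fasta_path) if fasta_path else {}
    if dialect == "gff3":
        ref, genes, introns = _read_gff3(gff_or_bed_path)
    elif dialect == "bed":
        glen = len(next(iter(seqs.values()))) if seqs else None
        ref, genes, introns = _read_bed(gff_or_bed_path, genome_length=glen)
    else:
        raise AnnotationError(f"unknown annotation dialect {dialect!r}")
    if seqs:
        seq = seqs.get(ref.name) or next(iter(seqs.values()))
        ref = GenomeRef(ref.name, len(seq), sequence=seq,
                        masked_intervals=ref.masked_intervals)
    if mask_path:
        ref.masked_intervals = _normalize_intervals(
            ref.masked_intervals + read_mask_bed(mask_path), ref.length, "masked interval")
    boundaries = read_boundary_table(promoter_table_path) if promoter_table_path else []
    for b in boundaries:
        if not (0 <= b.position < ref.length):
            raise AnnotationError(
                f"boundary {b.gene_id}/{b.kind} at {b.position} outside genome")
    return ref, genes, introns, boundaries


# ---------------------------------------------------------------------------
# writers


def write_gff3(ref: GenomeRef, genes: Iterable[GeneFeature],
               introns: Iterable[IntronFeature], path: str) -> None:
    lines = ["##gff-version 3", f"##sequence-region {ref.name} 1 {ref.length}"]
    introns_by_gene: dict[str, list[IntronFeature]] = {}
    for i in introns:
        introns_by_gene.setdefault(i.gene_id, []).append(i)
    for g in genes:
        attrs = f"ID={g.gene_id};feature_class={g.feature_class}"
        if g.coding_unit_id != g.gene_id:
            attrs += f";coding_unit={g.coding_unit_id}"
        lines.append("\t".join([ref.name, "mitotxscape", "gene", str(g.start + 1),
                                str(g.end), ".", g.strand, ".", attrs]))
        for k, (s, e) in enumerate(g.exons, 1):
            lines.append("\t".join([ref.name, "mitotxscape", "exon", str(s + 1), str(e),
                                    ".", g.strand, ".",
                                    f"ID={g.gene_id}.e{k};Parent={g.gene_id}"]))
        for i in introns_by_gene.get(g.gene_id, []):
            lo, hi = i.genomic_interval
            lines.append("\t".join([
                ref.name, "mitotxscape", "intron", str(lo + 1), str(hi), ".", g.strand, ".",
                f"ID={i.intron_id};Parent={i.gene_id};splice_type={i.splice_type}"
                f";mechanism={i.mechanism}"]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_bed12(ref: GenomeRef, genes: Iterable[GeneFeature], path: str) -> None:
    lines = []
    for g in genes:
        sizes = ",".join(str(e - s) for s, e in g.exons) + ","
        offs = ",".join(str(s - g.start) for s, e in g.exons) + ","
        lines.append("\t".join(map(str, [ref.name, g.start, g.end, g.gene_id, 0,
                                         g.strand, g.start, g.end, "0", len(g.exons),
                                         sizes, offs])))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_boundary_table(boundaries: Iterable[KnownBoundary], path: str) -> None:
    """Write known boundaries with 1-based positions (inverse of the reader)."""
    rows = [{"gene_id": b.gene_id, "kind": b.kind, "position": b.position + 1,
             "label": b.label} for b in boundaries]
    pd.DataFrame(rows, columns=["gene_id", "kind", "position", "label"]).to_csv(
        path, sep="\t", index=False)


def write_results_table(records: Sequence, path: str, float_decimals: int = 2,
                        columns: Sequence[str] | None = None) -> None:
    """Write homogeneous result records (dataclasses, mappings or named
    tuples) as a TSV with a header row.

    Floats are rendered at fixed precision with half-up rounding so that SE
    and ratio columns match the conventions of printed splicing tables.
    ``None`` renders as an empty cell (e.g. an undefined I3'E/EI5' ratio).
    """
    def as_dict(r):
        if dataclasses.is_dataclass(r):
            return dataclasses.asdict(r)
        if hasattr(r, "_asdict"):
            return r._asdict()
        if isinstance(r, Mapping):
            return dict(r)
        raise TypeError(f"unsupported record type {type(r).__name__}")

    rows = [as_dict(r) for r in records]
    if rows:
        first = list(rows[0])
        if any(list(r) != first for r in rows):
            raise TypeError("records are not homogeneous")
    df = pd.DataFrame(rows, columns=columns or (list(rows[0]) if rows else []))

    def render(v):
        if v is None or (isinstance(v, float) and v != v):
            return ""
        if isinstance(v, bool):
            return str(v)
        if isinstance(v, float):
            return f"{round_half_up(v, float_decimals):.{float_decimals}f}"
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(df.columns.astype(str)) + "\n" if len(df.columns) else "\n")
        for _, r in df.iterrows():
            fh.write("\t".join(render(v) for v in r) + "\n")


def read_results_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
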