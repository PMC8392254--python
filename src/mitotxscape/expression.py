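"""Per-gene read counting and RPKM normalization.

RPKM here follows the organellar convention of normalizing against the reads
mapped to *protein-coding* genes only (rRNA/tRNA are excluded from the
denominator), with the spliced transcript length for intron-containing genes:

    RPKM[g] = counts[g] * 1e9 / (transcript_length[g] * total_protein_counts)
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pysam

from .annotation import GeneFeature
from .coverage import StrandedDepth


class ExpressionError(ValueError):
    pass


@dataclass
class GeneExpression:
    gene_id: str
    reads_mapped: float
    transcript_length: int
    rpkm: float
    exon_depths: list[float] = field(default_factory=list)


def count_reads_from_sams(sam_by_gene: Mapping[str, str],
                          count_mates: bool = False) -> dict[str, float]:
    """Count retained alignments in per-gene SAM files.

    By default a read pair counts once (fragment counting: distinct query
    names); ``count_mates=True`` counts every mapped record instead.  A read
    aligning to several gene references counts once for each of them.
    """
    counts: dict[str, float] = {}
    for gene_id, path in sam_by_gene.items():
        n = 0
        seen: set[str] = set()
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for aln in sam:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                if count_mates:
                    n += 1
                elif aln.query_name not in seen:
                    seen.add(aln.query_name)
                    n += 1
        counts[gene_id] = n
    return counts


def count_reads_from_depth(depth: StrandedDepth, genes: list[GeneFeature],
                           read_length: int = 89) -> dict[str, float]:
    """Approximate per-gene counts from a depth track: total exonic depth on
    the gene's strand divided by the read length.  Useful when only coverage
    tracks (not per-gene alignments) are available."""
    counts: dict[str, float] = {}
    for g in genes:
        arr = depth.strand(g.strand)
        total = sum(int(arr[s:e].sum()) for s, e in g.exons)
        counts[g.gene_id] = total / read_length
    return counts


def count_reads_per_gene(alignments, genes: list[GeneFeature] | None = None,
                         **kwargs) -> dict[str, float]:
    """Dispatch to SAM-based (mapping gene_id -> SAM path) or depth-based
    counting (StrandedDepth plus gene list)."""
    if isinstance(alignments, StrandedDepth):
        if genes is None:
            raise ExpressionError("depth-based counting requires the gene list")
        return count_reads_from_depth(alignments, genes, **kwargs)
    if isinstance(alignments, Mapping):
        if genes is not None:
            missing = [g.gene_id for g in genes if g.gene_id not in alignments]
            if missing:
                raise ExpressionError(f"genes without a reference alignment: {missing}")
        return count_reads_from_sams(alignments, **kwargs)
    raise TypeError(f"unsupported alignments type {type(alignments).__name__}")


def rpkm(counts: Mapping[str, float], lengths: Mapping[str, int]) -> dict[str, float]:
    """RPKM over the supplied genes; the denominator is the total count of
    exactly the genes passed in (restrict the mapping to protein-coding genes
    before calling to follow the organellar convention)."""
    total = float(sum(counts.values()))
    if total <= 0:
        raise ExpressionError("zero total count: RPKM normalization undefined")
    out = {}
    for g, c in counts.items():
        length = lengths[g]
        if length <= 0:
            raise ExpressionError(f"{g}: non-positive length {length}")
        out[g] = c * 1e9 / (length * total)
    return out


def exon_level_depth(depth: StrandedDepth, gene: GeneFeature) -> list[float]:
    """Mean depth of each exon on the gene's strand, in transcript order."""
    arr = depth.strand(gene.strand)
    return [float(arr[s:e].mean()) for s, e in gene.exons_in_transcript_order()]


def expression_table(genes: list[GeneFeature], counts: Mapping[str, float],
                     depth: StrandedDepth | None = None) -> list[GeneExpression]:
    """Assemble per-gene expression records.  RPKM is computed over the
    protein-coding genes only; non-protein features get rpkm = nan."""
    protein = [g for g in genes if g.feature_class == "protein"]
    lengths = {g.gene_id: g.transcript_length for g in genes}
    prot_counts = {g.gene_id: counts.get(g.gene_id, 0) for g in protein}
    rpkms = rpkm(prot_counts, lengths)
    out = []
    for g in genes:
        out.append(GeneExpression(
            gene_id=g.gene_id,
            reads_mapped=counts.get(g.gene_id, 0),
            transcript_length=g.transcript_length,
            rpkm=rpkms.get(g.gene_id, float("nan")),
            exon_depths=exon_level_depth(depth, g) if depth is not None else [],
        ))
    return out
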