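"""Group II intron splicing efficiency from junction-spanning reads.

Reads are aligned to two per-gene references: the unspliced (genomic) gene
and the spliced transcript, each extended by ``extension`` bp (default 100)
on both ends.  For each intron three junctions are scored:

* EI5' — exon | 5'-intron boundary, on the unspliced reference;
* I3'E — 3'-intron | exon boundary, on the unspliced reference;
* EE   — exon | exon boundary, on the spliced reference.

A read supports a junction when its alignment crosses the boundary with at
least one aligned base on each side; the evaluation region is bounded by a
+/-``flank`` bp window (default 30) around the boundary.  Splicing
efficiency weights the two unspliced junctions by one half because an intact
precursor carries two unspliced junctions for every exon-exon junction of a
mature molecule:

    SE = N_EE / (N_EE + 0.5 * N_EI5 + 0.5 * N_I3E)

The I3'E / EI5' ratio is reported alongside: during splicing by either the
branching (lariat) or hydrolytic pathway, the 3' intron-exon junction
persists longer than the 5' one, so the ratio typically exceeds 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam
from scipy import stats

from ._util import round_half_up
from .annotation import GeneFeature, IntronFeature


class SplicingError(ValueError):
    pass


class ShortExonError(SplicingError):
    """A flanking exon is shorter than the junction flank window, so the
    junction cannot be evaluated (e.g. trans-spliced introns around a very
    short exon)."""


@dataclass
class JunctionCounts:
    intron_id: str
    n_EI5: int
    n_I3E: int
    n_EE: int

    def __post_init__(self) -> None:
        if min(self.n_EI5, self.n_I3E, self.n_EE) < 0:
            raise SplicingError(f"{self.intron_id}: negative junction count")


@dataclass
class SplicingRecord:
    intron_id: str
    splice_type: str
    mechanism: str
    n_EI5: int
    n_I3E: int
    n_EE: int
    ratio_I3E_EI5: float | None
    se: float


def junction_ref_positions(gene: GeneFeature, intron: IntronFeature,
                           extension: int = 100) -> tuple[int, int, int]:
    """Boundary coordinates of (EI5', I3'E, EE) on the extended per-gene
    references, as half-open cut points in reference-local coordinates.

    The unspliced reference is the genomic gene span plus ``extension`` bp on
    each side, in sense orientation (reverse-complemented for minus-strand
    genes).  The spliced reference is the exon concatenation with the same
    flanks.
    """
    s, e = gene.span
    if gene.strand == "+":
        def to_local(g: int) -> int:
            return g - s + extension
    else:
        def to_local(g: int) -> int:
            return (e + extension) - g
    ei5 = to_local(intron.donor_pos)
    i3e = to_local(intron.acceptor_pos)

    # EE cut point: extension + transcript length of exons 5' of the intron
    upstream = 0
    found = False
    for ex_s, ex_e in gene.exons_in_transcript_order():
        boundary = ex_e if gene.strand == "+" else ex_s
        upstream += ex_e - ex_s
        if boundary == intron.donor_pos:
            found = True
            break
    if not found:
        raise SplicingError(
            f"{intron.intron_id}: donor position {intron.donor_pos} does not "
            f"coincide with an exon boundary of {gene.gene_id}")
    ee = extension + upstream
    return ei5, i3e, ee


def _count_crossing(sam_path: str, boundary: int, flank: int) -> int:
    """Reads whose alignment covers >= 1 aligned base within ``flank`` bp on
    each side of the boundary; each query counted at most once."""
    lo, hi = boundary - flank, boundary + flank
    seen: set[str] = set()
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.query_name in seen:
                continue
            start, end = aln.reference_start, aln.reference_end
            # crossing with >=1 base each side, restricted to the flank window
            if start < boundary < end and end > lo and start < hi:
                seen.add(aln.query_name)
    return len(seen)


def count_junction_reads(alignments_unspliced: str, alignments_spliced: str,
                         intron: IntronFeature, gene: GeneFeature,
                         flank: int = 30, extension: int = 100) -> JunctionCounts:
    """Count junction-supporting reads for one intron from the two per-gene
    alignment files.  Refuses introns whose flanking exon is shorter than the
    flank window (the junction evidence would be ambiguous)."""
    if flank <= 0:
        raise SplicingError("flank must be positive")
    if intron.flanking_exon_lengths != (0, 0) and \
            min(intron.flanking_exon_lengths) < flank:
        raise ShortExonError(
            f"{intron.intron_id}: flanking exon of "
            f"{min(intron.flanking_exon_lengths)} bp is shorter than the "
            f"{flank}-bp flank window; junction not evaluated")
    ei5, i3e, ee = junction_ref_positions(gene, intron, extension)
    us_len = (gene.end - gene.start) + 2 * extension
    if not (0 < ei5 < us_len and 0 < i3e < us_len):
        raise SplicingError(f"{intron.intron_id}: junction outside reference")
    return JunctionCounts(
        intron_id=intron.intron_id,
        n_EI5=_count_crossing(alignments_unspliced, ei5, flank),
        n_I3E=_count_crossing(alignments_unspliced, i3e, flank),
        n_EE=_count_crossing(alignments_spliced, ee, flank),
    )


def splicing_efficiency(counts: JunctionCounts, splice_type: str = "cis",
                        mechanism: str = "branching") -> SplicingRecord:
    """Apply the SE formula to one intron's junction counts.

    The I3'E/EI5' ratio is None (rendered as an empty cell) when n_EI5 is
    zero.  SE and ratio are kept at full precision here; tables round them
    half-up to two decimals.
    """
    total = counts.n_EE + counts.n_EI5 + counts.n_I3E
    if total == 0:
        raise SplicingError(f"{counts.intron_id}: all junction counts are zero")
    se = counts.n_EE / (counts.n_EE + 0.5 * counts.n_EI5 + 0.5 * counts.n_I3E)
    ratio = counts.n_I3E / counts.n_EI5 if counts.n_EI5 > 0 else None
    return SplicingRecord(
        intron_id=counts.intron_id, splice_type=splice_type, mechanism=mechanism,
        n_EI5=counts.n_EI5, n_I3E=counts.n_I3E, n_EE=counts.n_EE,
        ratio_I3E_EI5=ratio, se=se)


def splicing_table(records: list[SplicingRecord]) -> list[dict]:
    """Rows for the printed splicing-efficiency table (2-decimal half-up)."""
    return [{
        "intron_id": r.intron_id, "splice_type": r.splice_type,
        "mechanism": r.mechanism, "n_EI5": r.n_EI5, "n_I3E": r.n_I3E,
        "n_EE": r.n_EE,
        "ratio_I3E_EI5": None if r.ratio_I3E_EI5 is None
        else round_half_up(r.ratio_I3E_EI5, 2),
        "se": round_half_up(r.se, 2),
    } for r in records]


def compare_groups(records: list[SplicingRecord], grouping: str = "splice_type"
                   ) -> tuple[float, float, dict[str, float]]:
    """One-way ANOVA of SE across intron groups (cis/trans splice type or
    splicing mechanism).  Returns (F, p, group means)."""
    if grouping not in ("splice_type", "mechanism"):
        raise ValueError("grouping must be 'splice_type' or 'mechanism'")
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(getattr(r, grouping), []).append(r.se)
    if len(groups) < 2:
        raise SplicingError(f"need >= 2 groups for ANOVA, got {len(groups)}")
    if all(len(v) < 2 for v in groups.values()):
        raise SplicingError("ANOVA needs at least one group with >= 2 records")
    means = {k: float(np.mean(v)) for k, v in groups.items()}
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    ms_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    grand = np.concatenate(values).mean()
    ms_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    if ms_within == 0:
        # degenerate separation: identical groups -> F=0; else perfect split
        return (0.0, 1.0, means) if ms_between == 0 else (float("inf"), 0.0, means)
    f_stat, p = stats.f_oneway(*values)
    return float(f_stat), float(p), means
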