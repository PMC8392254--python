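"""Transcript-boundary inference from the coverage profile.

Plant mitochondrial promoters have no conserved motif, so transcription start
sites are inferred from the shape of the read-depth profile instead: a sharp,
sustained rise in depth upstream of a gene marks a candidate initiation
region.  Slopes of the per-base depth are computed in non-overlapping windows
(default 50 bp) across the upstream span (default 2 kb), sign-oriented so that
a positive slope means depth increasing toward the gene; the highest-slope
windows are ranked as putative TSS and compared against experimentally known
promoters within a +/-50 bp radius (a 100-bp total window).

3' termini are detected as the first downstream window whose mean depth falls
below a fraction of the gene-body mean — the coverage signature of the
endonucleolytic processing (often at tRNA-like elements) that defines mature
3' ends.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .annotation import GeneFeature, GenomeRef, KnownBoundary
from .coverage import StrandedDepth


@dataclass
class SlopeProfile:
    """Windowed depth slopes across the upstream span of one gene, ordered
    from the most distal window to the gene-proximal one.  Window coordinates
    are genomic; slopes are in depth units per bp, positive toward the gene."""

    gene_id: str
    strand: str
    windows: list[tuple[int, int, float]]
    upstream_span: int = 2000
    window_size: int = 50
    truncated: bool = False


@dataclass
class TSSCall:
    gene_id: str
    window: tuple[int, int]
    slope: float
    rank: int
    match_status: str  # matched | upstream_of_known | unmatched | inside_upstream_gene
    matched_boundary: KnownBoundary | None = None

    @property
    def midpoint(self) -> float:
        return (self.window[0] + self.window[1]) / 2


@dataclass
class TerminusCall:
    gene_id: str
    drop_position: int | None
    depth_before: float
    depth_after: float
    match_status: str  # matched | unmatched | obscured_by_downstream_gene


def _lsq_slope(y: np.ndarray) -> float:
    """Least-squares slope of y against 0..n-1 (closed form)."""
    n = y.size
    if n < 2:
        return 0.0
    x = np.arange(n, dtype=float)
    x -= x.mean()
    denom = float((x * x).sum())
    return float((x * (y - y.mean())).sum() / denom)


def slope_profile(depth: StrandedDepth, gene: GeneFeature,
                  upstream_span: int = 2000, window: int = 50) -> SlopeProfile:
    """Windowed least-squares slopes of depth over the region upstream of the
    gene (strand-aware).  The span is truncated (and flagged) at genome edges.
    """
    if window > upstream_span:
        raise ValueError(f"window ({window}) larger than upstream span ({upstream_span})")
    if upstream_span % window:
        raise ValueError("window size must divide the upstream span")
    arr = depth.strand(gene.strand)
    glen = depth.ref.length
    truncated = False

    def window_slope(w0: int, w1: int) -> float:
        # one guard base on each side so a step landing exactly on a window
        # boundary still registers in the adjacent windows; on a linear ramp
        # the estimate is unchanged
        a, b = max(w0 - 1, 0), min(w1 + 1, glen)
        return _lsq_slope(arr[a:b].astype(float))

    if gene.strand == "+":
        lo = gene.start - upstream_span
        if lo < 0:
            lo, truncated = 0, True
        # distal -> proximal is ascending genomic order
        windows = []
        for w0 in range(lo, gene.start, window):
            w1 = min(w0 + window, gene.start)
            windows.append((w0, w1, window_slope(w0, w1)))
    else:
        hi = gene.end + upstream_span
        if hi > glen:
            hi, truncated = glen, True
        # distal -> proximal is descending genomic order; toward the gene the
        # genomic coordinate decreases, so flip the sign of the raw slope
        windows = []
        for w1 in range(hi, gene.end, -window):
            w0 = max(w1 - window, gene.end)
            windows.append((w0, w1, -window_slope(w0, w1)))
    return SlopeProfile(gene_id=gene.gene_id, strand=gene.strand, windows=windows,
                        upstream_span=upstream_span, window_size=window,
                        truncated=truncated)


def _proximity_rank(profile: SlopeProfile) -> dict[tuple[int, int], int]:
    """Index of each window in distal->proximal order (higher = closer to gene)."""
    return {(w0, w1): i for i, (w0, w1, _) in enumerate(profile.windows)}


def call_tss(profile: SlopeProfile, known: list[KnownBoundary],
             genes: list[GeneFeature], top_n: int = 3, match_radius: int = 50,
             slope_floor: float | None = None) -> list[TSSCall]:
    """Rank the top-``top_n`` windows by slope (ties broken toward the
    gene-proximal window) and label each against the known promoters of the
    gene.

    Labels: ``matched`` when a known TSS lies within ``match_radius`` of the
    window midpoint; ``inside_upstream_gene`` when the window overlaps another
    same-strand gene's exons (the depth there is uninformative);
    ``upstream_of_known`` when the window lies 5' of every known TSS of the
    gene; ``unmatched`` otherwise.
    """
    prox = _proximity_rank(profile)
    ranked = sorted(profile.windows,
                    key=lambda w: (-w[2], -prox[(w[0], w[1])]))
    known_tss = [b for b in known
                 if b.gene_id == profile.gene_id and b.kind == "tss"]
    others = [g for g in genes
              if g.gene_id != profile.gene_id and g.strand == profile.strand]
    calls = []
    for rank, (w0, w1, slope) in enumerate(ranked[:top_n], start=1):
        if slope_floor is not None and slope < slope_floor:
            break
        mid = (w0 + w1) / 2
        matched = next((b for b in known_tss if abs(mid - b.position) <= match_radius),
                       None)
        if matched is not None:
            status = "matched"
        elif any(s < w1 and w0 < e for g in others for s, e in g.exons):
            status = "inside_upstream_gene"
        elif known_tss and all(
                (mid < b.position) if profile.strand == "+" else (mid > b.position)
                for b in known_tss):
            status = "upstream_of_known"
        else:
            status = "unmatched"
        calls.append(TSSCall(gene_id=profile.gene_id, window=(w0, w1), slope=slope,
                             rank=rank, match_status=status, matched_boundary=matched))
    return calls


def call_terminus(depth: StrandedDepth, gene: GeneFeature,
                  downstream_span: int = 2000, window: int = 50,
                  drop_fraction: float = 0.5,
                  genes: list[GeneFeature] | None = None,
                  known: list[KnownBoundary] | None = None,
                  match_radius: int = 50) -> TerminusCall:
    """Scan downstream of the stop for the first window whose mean depth falls
    below ``drop_fraction`` x the gene-body mean.

    If a downstream same-strand gene's span is reached before any drop, the
    3' end is reported as obscured.  When known 3' termini are supplied, a
    detected drop within ``match_radius`` is labelled ``matched``.
    """
    arr = depth.strand(gene.strand)
    glen = depth.ref.length
    body = float(np.mean(np.concatenate([arr[s:e] for s, e in gene.exons]).astype(float)))
    threshold = drop_fraction * body
    others = [g for g in (genes or [])
              if g.gene_id != gene.gene_id and g.strand == gene.strand]

    prev_mean = body
    if gene.strand == "+":
        window_iter = [(w0, min(w0 + window, glen))
                       for w0 in range(gene.end, min(gene.end + downstream_span, glen), window)]
    else:
        window_iter = [(max(w1 - window, 0), w1)
                       for w1 in range(gene.start, max(gene.start - downstream_span, 0), -window)]
    for w0, w1 in window_iter:
        if w1 <= w0:
            break
        overlaps_gene = any(s < w1 and w0 < e for g in others for s, e in g.exons)
        m = float(arr[w0:w1].mean())
        if m < threshold:
            drop = w0 if gene.strand == "+" else w1
            status = "unmatched"
            for b in (known or []):
                if b.gene_id == gene.gene_id and b.kind == "terminus_3p" \
                        and abs(drop - b.position) <= match_radius:
                    status = "matched"
                    break
            return TerminusCall(gene_id=gene.gene_id, drop_position=drop,
                                depth_before=prev_mean, depth_after=m,
                                match_status=status)
        if overlaps_gene:
            return TerminusCall(gene_id=gene.gene_id, drop_position=None,
                                depth_before=prev_mean, depth_after=m,
                                match_status="obscured_by_downstream_gene")
        prev_mean = m
    return TerminusCall(gene_id=gene.gene_id, drop_position=None,
                        depth_before=prev_mean, depth_after=prev_mean,
                        match_status="unmatched")


def scan_promoter_sequences(genome: GenomeRef,
                            promoter_seqs: list[tuple[str, str]]
                            ) -> list[tuple[str, str, int]]:
    """Exact occurrences of each promoter sequence on both genome strands.

    Returns (label, strand, start) with 0-based start of the match on the
    plus-strand coordinate system (for minus-strand hits, the leftmost base of
    the reverse-complemented occurrence).  Overlapping occurrences all count.
    """
    if genome.sequence is None:
        raise ValueError("genome sequence required for promoter scanning")
    hits: list[tuple[str, str, int]] = []
    for label, query in promoter_seqs:
        q = query.upper()
        if not q or set(q) - set("ACGT"):
            raise ValueError(f"promoter {label!r}: sequence must be non-empty ACGT only")
        rc = str(Seq(q).reverse_complement())
        for strand, needle in (("+", q), ("-", rc)):
            pos = genome.sequence.find(needle)
            while pos != -1:
                hits.append((label, strand, pos))
                pos = genome.sequence.find(needle, pos + 1)
    return sorted(hits, key=lambda h: (h[0], h[2], h[1]))
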