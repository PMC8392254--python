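"""Strand-specific per-base read depth and genome-wide coverage statistics.

Depth is tracked separately for the two template strands of one reference.
Masked positions (plastid-like regions) are kept in the arrays so that
coordinates stay stable, but they never receive counts and are excluded from
every summary statistic.

Pileup semantics: a read contributes depth at each reference position it has
an aligned base on (matches and mismatches); deletions and reference skips do
not increment depth.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .annotation import GeneFeature, GenomeRef

logger = logging.getLogger(__name__)


class CoverageError(ValueError):
    """Ill-formed depth input."""


@dataclass
class StrandedDepth:
    """Per-base depth on the plus and minus template strands of one genome."""

    ref: GenomeRef
    depth_plus: np.ndarray
    depth_minus: np.ndarray

    def __post_init__(self) -> None:
        for name, arr in (("depth_plus", self.depth_plus), ("depth_minus", self.depth_minus)):
            arr = np.asarray(arr)
            if arr.shape != (self.ref.length,):
                raise CoverageError(f"{name} has shape {arr.shape}, expected ({self.ref.length},)")
            if (arr < 0).any():
                raise CoverageError(f"{name} contains negative depth")
        self.depth_plus = np.asarray(self.depth_plus, dtype=np.int64)
        self.depth_minus = np.asarray(self.depth_minus, dtype=np.int64)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True at masked (excluded) positions."""
        m = np.zeros(self.ref.length, dtype=bool)
        for s, e in self.ref.masked_intervals:
            m[s:e] = True
        return m

    def strand(self, strand: str) -> np.ndarray:
        if strand == "+":
            return self.depth_plus
        if strand == "-":
            return self.depth_minus
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    @classmethod
    def zeros(cls, ref: GenomeRef) -> "StrandedDepth":
        n = ref.length
        return cls(ref, np.zeros(n, dtype=np.int64), np.zeros(n, dtype=np.int64))


@dataclass
class CoverageSummary:
    """Genome-wide transcription statistics over unmasked positions."""

    mean_depth_both: float
    max_depth: int
    mean_depth_intergenic: float
    frac_ge: dict[int, float]
    window_hist: dict[tuple[float, float], int]
    n_unmasked: int = 0


def _template_strand(aln: pysam.AlignedSegment, mate_defines_strand: int) -> str:
    """Template-strand of the sequenced fragment.

    For paired-end stranded chemistry the mate given by ``mate_defines_strand``
    aligns in the sense of the transcript (TruSeq stranded: read 2).  Unpaired
    records are taken at face value: their alignment strand is the template
    strand.
    """
    read_strand = "-" if aln.is_reverse else "+"
    if not aln.is_paired:
        return read_strand
    defining = (aln.is_read2 and mate_defines_strand == 2) or \
               (aln.is_read1 and mate_defines_strand == 1)
    if defining:
        return read_strand
    return "-" if read_strand == "+" else "+"


def depth_from_alignments(sam_path: str, ref: GenomeRef, *,
                          mate_defines_strand: int = 2,
                          min_mapq: int | None = None) -> StrandedDepth:
    """Accumulate per-base, per-strand depth from a SAM file.

    Unmapped, secondary and supplementary records are skipped (a count is
    logged); records mapped to a different reference raise.  Reads overlapping
    masked intervals contribute only on their unmasked positions.
    """
    depth = StrandedDepth.zeros(ref)
    mask = depth.mask
    n_skipped = 0
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                n_skipped += 1
                continue
            if min_mapq is not None and aln.mapping_quality < min_mapq:
                n_skipped += 1
                continue
            if aln.reference_name != ref.name:
                raise CoverageError(
                    f"{sam_path}: read {aln.query_name} mapped to "
                    f"{aln.reference_name!r}, expected {ref.name!r}")
            positions = np.asarray(aln.get_reference_positions(), dtype=np.int64)
            if positions.size and positions[-1] >= ref.length:
                raise CoverageError(
                    f"{sam_path}: read {aln.query_name} extends past genome end")
            positions = positions[~mask[positions]] if positions.size else positions
            arr = depth.strand(_template_strand(aln, mate_defines_strand))
            np.add.at(arr, positions, 1)
    if n_skipped:
        logger.info("depth_from_alignments(%s): skipped %d unmapped/secondary/"
                    "filtered records", sam_path, n_skipped)
    return depth


def _fill_from_bedgraph(path: str, ref: GenomeRef) -> np.ndarray:
    arr = np.zeros(ref.length, dtype=np.int64)
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    if df.empty:
        return arr
    df = df.sort_values("start", kind="stable")
    prev_end = -1
    for r in df.itertuples():
        s, e, v = int(r.start), int(r.end), float(r.value)
        if not (0 <= s < e <= ref.length):
            raise CoverageError(f"{path}: interval ({s}, {e}) outside [0, {ref.length})")
        if s < prev_end:
            raise CoverageError(f"{path}: overlapping bedGraph intervals at {s}")
        if v < 0 or v != int(v):
            raise CoverageError(f"{path}: depth value {v} is not a non-negative integer")
        arr[s:e] = int(v)
        prev_end = e
    return arr


def depth_from_bedgraph(plus_path: str, minus_path: str, ref: GenomeRef) -> StrandedDepth:
    """Load per-strand depth from a pair of bedGraph tracks (absent positions
    are depth 0)."""
    return StrandedDepth(ref, _fill_from_bedgraph(plus_path, ref),
                         _fill_from_bedgraph(minus_path, ref))


def write_bedgraph(depth: StrandedDepth, plus_path: str, minus_path: str,
                   write_zero: bool = False) -> None:
    """Write each strand as a run-length-encoded bedGraph track."""
    for path, arr in ((plus_path, depth.depth_plus), (minus_path, depth.depth_minus)):
        with open(path, "w") as fh:
            if arr.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [arr.size]))
            for s, e in zip(starts, ends):
                v = int(arr[s])
                if v or write_zero:
                    fh.write(f"{depth.ref.name}\t{s}\t{e}\t{v}\n")


DEFAULT_HIST_EDGES = (0, 1, 2, 5, 10, 50, 100, 500, 1000, float("inf"))


def summarize_coverage(depth: StrandedDepth, genes: list[GeneFeature] | None = None,
                       thresholds: list[int] = (1, 2, 5), window: int = 100,
                       hist_edges: tuple = DEFAULT_HIST_EDGES) -> CoverageSummary:
    """Genome-wide coverage statistics.

    ``frac_ge[t]`` is the fraction of unmasked strand-positions (both strands,
    denominator 2 x unmasked length) with depth >= t.  The pooled mean/max
    sum the two strands per position.  ``mean_depth_intergenic`` excludes all
    exonic positions of known genes.  ``window_hist`` bins non-overlapping
    ``window``-bp windows per strand by their mean depth.
    """
    if depth.ref.length == 0:
        raise CoverageError("empty genome")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    mask = depth.mask
    keep = ~mask
    n_unmasked = int(keep.sum())
    if n_unmasked == 0:
        raise CoverageError("all positions are masked")
    plus = depth.depth_plus[keep]
    minus = depth.depth_minus[keep]
    pooled = plus + minus

    frac_ge = {int(t): float(((plus >= t).sum() + (minus >= t).sum()) / (2 * n_unmasked))
               for t in thresholds}

    exonic = np.zeros(depth.ref.length, dtype=bool)
    for g in genes or []:
        for s, e in g.exons:
            exonic[s:e] = True
    inter_keep = keep & ~exonic
    n_inter = int(inter_keep.sum())
    mean_inter = float((depth.depth_plus[inter_keep] + depth.depth_minus[inter_keep]).mean()) \
        if n_inter else float("nan")

    hist: dict[tuple[float, float], int] = {
        (float(lo), float(hi)): 0 for lo, hi in zip(hist_edges, hist_edges[1:])}
    for arr in (depth.depth_plus, depth.depth_minus):
        for w0 in range(0, depth.ref.length, window):
            w1 = min(w0 + window, depth.ref.length)
            sel = keep[w0:w1]
            if not sel.any():
                continue
            m = float(arr[w0:w1][sel].mean())
            for lo, hi in hist:
                if lo <= m < hi:
                    hist[(lo, hi)] += 1
                    break

    return CoverageSummary(
        mean_depth_both=float(pooled.mean()),
        max_depth=int(pooled.max()),
        mean_depth_intergenic=mean_inter,
        frac_ge=frac_ge,
        window_hist=hist,
        n_unmasked=n_unmasked,
    )


def zero_coverage_intervals(depth: StrandedDepth, max_depth: int = 0
                            ) -> list[tuple[str, int, int]]:
    """Maximal unmasked runs with depth <= ``max_depth`` per strand, sorted by
    (strand, start).  Masked positions split runs."""
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    mask = depth.mask
    out: list[tuple[str, int, int]] = []
    for strand in ("+", "-"):
        low = (depth.strand(strand) <= max_depth) & ~mask
        padded = np.concatenate(([False], low, [False])).astype(np.int8)
        delta = np.diff(padded)
        starts = np.flatnonzero(delta == 1)
        ends = np.flatnonzero(delta == -1)
        out.extend((strand, int(s), int(e)) for s, e in zip(starts, ends))
    return out
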