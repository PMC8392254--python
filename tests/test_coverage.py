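"""Depth accumulation and genome-wide coverage statistics, checked against
brute-force per-position oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_depth
from mitotxscape.annotation import GeneFeature, GenomeRef
from mitotxscape.coverage import (CoverageError, StrandedDepth,
                                  depth_from_alignments, depth_from_bedgraph,
                                  summarize_coverage, write_bedgraph,
                                  zero_coverage_intervals)

SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:mt\tLN:1000\n"


def sam_line(qname, flag, pos0, length):
    return "\t".join([qname, str(flag), "mt", str(pos0 + 1), "60",
                      f"{length}M", "*", "0", "0", "A" * length, "*"]) + "\n"


def test_single_forward_read(tmp_path, small_ref):
    p = tmp_path / "r.sam"
    p.write_text(SAM_HEADER + sam_line("r1", 0, 100, 89))
    d = depth_from_alignments(str(p), small_ref)
    assert d.depth_plus[100:189].tolist() == [1] * 89
    assert d.depth_plus.sum() == 89 and d.depth_minus.sum() == 0


def test_empty_sam(tmp_path, small_ref):
    p = tmp_path / "e.sam"
    p.write_text(SAM_HEADER)
    d = depth_from_alignments(str(p), small_ref)
    assert d.depth_plus.sum() == 0 and d.depth_minus.sum() == 0


def test_opposite_strand_overlap_brute_force(tmp_path, small_ref):
    """Two overlapping reads on opposite template strands: per-strand depth 1
    each, pooled 2 in the overlap — checked base by base."""
    p = tmp_path / "o.sam"
    p.write_text(SAM_HEADER + sam_line("r1", 0, 100, 50) + sam_line("r2", 16, 120, 50))
    d = depth_from_alignments(str(p), small_ref)
    plus = np.zeros(1000, int)
    plus[100:150] += 1
    minus = np.zeros(1000, int)
    minus[120:170] += 1
    assert d.depth_plus.tolist() == plus.tolist()
    assert d.depth_minus.tolist() == minus.tolist()
    pooled = d.depth_plus + d.depth_minus
    assert set(pooled[120:150]) == {2}


def test_paired_end_template_strand(tmp_path, small_ref):
    """TruSeq stranded: read 2 carries the template strand; read 1 is
    antisense.  A forward-aligned read1 therefore counts on minus."""
    flags_r1_fwd = 0x1 | 0x40          # paired, first in pair, forward
    flags_r2_rev = 0x1 | 0x80 | 0x10   # paired, second in pair, reverse
    p = tmp_path / "p.sam"
    p.write_text(SAM_HEADER + sam_line("f", flags_r1_fwd, 10, 20)
                 + sam_line("f", flags_r2_rev, 40, 20))
    d = depth_from_alignments(str(p), small_ref)
    assert d.depth_minus[10:30].sum() == 20 and d.depth_minus[40:60].sum() == 20
    assert d.depth_plus.sum() == 0


def test_deletions_do_not_increment(tmp_path, small_ref):
    p = tmp_path / "d.sam"
    p.write_text(SAM_HEADER + "\t".join(
        ["r", "0", "mt", "101", "60", "10M5D10M", "*", "0", "0", "A" * 20, "*"]) + "\n")
    d = depth_from_alignments(str(p), small_ref)
    assert d.depth_plus[100:110].sum() == 10
    assert d.depth_plus[110:115].sum() == 0  # deleted bases
    assert d.depth_plus[115:125].sum() == 10


def test_masked_positions_not_counted(tmp_path):
    ref = GenomeRef("mt", 1000, masked_intervals=[(120, 140)])
    p = tmp_path / "m.sam"
    p.write_text(SAM_HEADER + sam_line("r1", 100, 0, 0).replace("\t0\tmt\t1\t", "\t0\tmt\t101\t"))
    p.write_text(SAM_HEADER + sam_line("r1", 0, 100, 89))
    d = depth_from_alignments(str(p), ref)
    assert d.depth_plus[120:140].sum() == 0
    assert d.depth_plus.sum() == 89 - 20


def test_reference_mismatch_raises(tmp_path):
    ref = GenomeRef("other", 1000)
    p = tmp_path / "x.sam"
    p.write_text(SAM_HEADER + sam_line("r1", 0, 100, 10))
    with pytest.raises(CoverageError, match="other"):
        depth_from_alignments(str(p), ref)


def test_bedgraph_fill_and_round_trip(tmp_path, small_ref):
    plus = tmp_path / "p.bg"
    minus = tmp_path / "m.bg"
    plus.write_text("mt\t0\t10\t5\nmt\t10\t20\t2\n")
    minus.write_text("")
    d = depth_from_bedgraph(str(plus), str(minus), small_ref)
    assert d.depth_plus[0:10].tolist() == [5] * 10
    assert d.depth_plus[10:20].tolist() == [2] * 10
    assert d.depth_plus[20:].sum() == 0 and d.depth_minus.sum() == 0

    p2, m2 = tmp_path / "p2.bg", tmp_path / "m2.bg"
    write_bedgraph(d, str(p2), str(m2))
    d2 = depth_from_bedgraph(str(p2), str(m2), small_ref)
    assert np.array_equal(d2.depth_plus, d.depth_plus)
    assert np.array_equal(d2.depth_minus, d.depth_minus)


@pytest.mark.parametrize("track", ["mt\t0\t10\t5\nmt\t5\t15\t2\n",   # overlap
                                   "mt\t990\t1010\t1\n"])            # out of bounds
def test_bedgraph_ill_formed(tmp_path, small_ref, track):
    plus = tmp_path / "p.bg"
    minus = tmp_path / "m.bg"
    plus.write_text(track)
    minus.write_text("")
    with pytest.raises(CoverageError):
        depth_from_bedgraph(str(plus), str(minus), small_ref)


def test_uniform_depth_frac_ge(uniform_depth):
    s = summarize_coverage(uniform_depth, [], thresholds=[1, 2, 5, 6])
    assert s.frac_ge == {1: 1.0, 2: 1.0, 5: 1.0, 6: 0.0}
    assert s.mean_depth_both == 10.0 and s.max_depth == 10


def test_single_strand_coverage_is_half(small_ref):
    d = StrandedDepth(small_ref, np.ones(1000, dtype=np.int64),
                      np.zeros(1000, dtype=np.int64))
    s = summarize_coverage(d, [], thresholds=[1])
    assert s.frac_ge[1] == 0.5


def brute_force_summary(d, genes, thresholds):
    """Per-position tally, independent of the vectorized implementation."""
    mask = d.mask
    exonic = np.zeros(d.ref.length, bool)
    for g in genes:
        for s, e in g.exons:
            exonic[s:e] = True
    n_unmasked = 0
    ge = {t: 0 for t in thresholds}
    inter_total, inter_n = 0, 0
    for i in range(d.ref.length):
        if mask[i]:
            continue
        n_unmasked += 1
        for t in thresholds:
            ge[t] += int(d.depth_plus[i] >= t) + int(d.depth_minus[i] >= t)
        if not exonic[i]:
            inter_total += d.depth_plus[i] + d.depth_minus[i]
            inter_n += 1
    return ({t: ge[t] / (2 * n_unmasked) for t in thresholds},
            inter_total / inter_n if inter_n else float("nan"))


def brute_force_low_runs(d, max_depth):
    out = []
    mask = d.mask
    for strand in "+-":
        arr = d.strand(strand)
        run = None
        for i in range(d.ref.length + 1):
            low = i < d.ref.length and not mask[i] and arr[i] <= max_depth
            if low and run is None:
                run = i
            elif not low and run is not None:
                out.append((strand, run, i))
                run = None
    return out


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_summary_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    d = random_depth(rng, length=300, masked=[(50, 70)])
    genes = [GeneFeature("g", "+", exons=[(100, 160)])]
    s = summarize_coverage(d, genes, thresholds=[1, 2, 5])
    expected_frac, expected_inter = brute_force_summary(d, genes, [1, 2, 5])
    assert s.frac_ge == pytest.approx(expected_frac)
    assert s.mean_depth_intergenic == pytest.approx(expected_inter)


def test_zero_intervals_trivial(small_ref):
    all_zero = StrandedDepth.zeros(small_ref)
    ivs = zero_coverage_intervals(all_zero, 0)
    assert ivs == [("+", 0, 1000), ("-", 0, 1000)]

    one = StrandedDepth.zeros(small_ref)
    one.depth_plus[500] = 3
    ivs = [iv for iv in zero_coverage_intervals(one, 0) if iv[0] == "+"]
    assert ivs == [("+", 0, 500), ("+", 501, 1000)]


@pytest.mark.parametrize("seed", [3, 4, 5])
def test_zero_intervals_match_linear_scan(seed):
    rng = np.random.default_rng(seed)
    d = random_depth(rng, length=250, max_depth=3, masked=[(80, 90)])
    assert zero_coverage_intervals(d, 1) == brute_force_low_runs(d, 1)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_frac_ge_monotone_in_threshold(seed):
    rng = np.random.default_rng(seed)
    d = random_depth(rng, length=200, max_depth=8)
    s = summarize_coverage(d, [], thresholds=[0, 1, 2, 3, 5, 8, 9])
    values = [s.frac_ge[t] for t in sorted(s.frac_ge)]
    assert all(a >= b for a, b in zip(values, values[1:]))
    assert all(0.0 <= v <= 1.0 for v in values)


def test_summary_invariant_to_read_order(tmp_path, small_ref):
    lines = [sam_line("a", 0, 100, 30), sam_line("b", 16, 110, 30),
             sam_line("c", 0, 500, 30)]
    p1, p2 = tmp_path / "1.sam", tmp_path / "2.sam"
    p1.write_text(SAM_HEADER + "".join(lines))
    p2.write_text(SAM_HEADER + "".join(reversed(lines)))
    d1 = depth_from_alignments(str(p1), small_ref)
    d2 = depth_from_alignments(str(p2), small_ref)
    assert np.array_equal(d1.depth_plus, d2.depth_plus)
    assert np.array_equal(d1.depth_minus, d2.depth_minus)
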