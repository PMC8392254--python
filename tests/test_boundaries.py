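"""Slope profiles, TSS and terminus calling, promoter-sequence scanning."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitotxscape.annotation import GeneFeature, GenomeRef, KnownBoundary
from mitotxscape.boundaries import (call_terminus, call_tss,
                                    scan_promoter_sequences, slope_profile)
from mitotxscape.coverage import StrandedDepth
from mitotxscape.synthetic import SyntheticGene, SyntheticSpec, generate


def make_depth(plus, minus=None, masked=()):
    n = len(plus)
    ref = GenomeRef("mt", n, masked_intervals=list(masked))
    minus = np.zeros(n, dtype=np.int64) if minus is None else np.asarray(minus)
    return StrandedDepth(ref, np.asarray(plus, dtype=np.int64), minus)


GENE = GeneFeature("g", "+", exons=[(3000, 4000)])


def test_constant_depth_zero_slopes():
    d = make_depth(np.full(5000, 40))
    prof = slope_profile(d, GENE)
    assert len(prof.windows) == 40
    assert all(s == 0.0 for _, _, s in prof.windows)
    # windows tile the upstream span without overlap
    assert [w[0] for w in prof.windows] == list(range(1000, 3000, 50))


def test_step_inside_window_dominates():
    plus = np.full(5000, 10)
    plus[2225:] = 200  # step inside window [2200, 2250)
    prof = slope_profile(make_depth(plus), GENE)
    best = max(prof.windows, key=lambda w: w[2])
    assert (best[0], best[1]) == (2200, 2250)
    distal = [s for w0, _, s in prof.windows if w0 < 2100]
    assert all(abs(s) < 1e-9 for s in distal)


def test_linear_ramp_recovers_gradient_closed_form():
    g = 0.35
    plus = (np.arange(5000) * g).astype(np.int64)  # integer-valued staircase
    # use an exact ramp in float by scaling: gradient 2 avoids rounding
    plus = np.arange(5000, dtype=np.int64) * 2
    prof = slope_profile(make_depth(plus), GENE)
    assert all(s == pytest.approx(2.0) for _, _, s in prof.windows)


def test_slope_linearity_in_depth_scaling():
    rng = np.random.default_rng(4)
    plus = rng.integers(0, 30, 5000)
    p1 = slope_profile(make_depth(plus), GENE)
    p3 = slope_profile(make_depth(plus * 3), GENE)
    for (_, _, s1), (_, _, s3) in zip(p1.windows, p3.windows):
        assert s3 == pytest.approx(3 * s1, abs=1e-9)


def test_minus_strand_orientation():
    """On the minus strand a step rising toward the gene (leftward) must give
    a positive slope."""
    gene = GeneFeature("m", "-", exons=[(1000, 2000)])
    minus = np.full(5000, 10)
    minus[:2520] = 200  # elevated from gene through 2520; rise toward gene at 2520
    prof = slope_profile(make_depth(np.zeros(5000), minus), gene)
    best = max(prof.windows, key=lambda w: w[2])
    assert best[2] > 0
    assert best[0] <= 2520 <= best[1]


def test_window_must_divide_span():
    d = make_depth(np.zeros(5000))
    with pytest.raises(ValueError):
        slope_profile(d, GENE, upstream_span=2000, window=300)
    with pytest.raises(ValueError):
        slope_profile(d, GENE, upstream_span=100, window=200)


def test_truncation_flag_at_genome_edge():
    gene = GeneFeature("e", "+", exons=[(500, 900)])
    prof = slope_profile(make_depth(np.zeros(1000)), gene)
    assert prof.truncated and prof.windows[0][0] == 0


def test_flat_profile_unmatched_zero_slope():
    prof = slope_profile(make_depth(np.full(5000, 25)), GENE)
    calls = call_tss(prof, [], [])
    assert len(calls) == 3
    assert all(c.slope == 0.0 and c.match_status == "unmatched" for c in calls)


def test_single_promoter_matched_rank1():
    spec = SyntheticSpec(genome_length=8000, genes=[
        SyntheticGene("g", 3000, 4500, "+", promoters=[(730, 120.0)])],
        noise_model="none", seed=0)
    b = generate(spec)
    calls = call_tss(slope_profile(b.depth, b.genes[0]), b.boundaries, b.genes)
    true = b.truth.true_tss["g"][0]
    assert calls[0].match_status == "matched"
    assert abs(calls[0].midpoint - true) <= 50


def test_two_promoters_both_in_top2():
    spec = SyntheticSpec(genome_length=9000, genes=[
        SyntheticGene("g", 4000, 5500, "+",
                      promoters=[(1430, 150.0), (380, 60.0)])],
        noise_model="none", seed=0)
    b = generate(spec)
    calls = call_tss(slope_profile(b.depth, b.genes[0]), b.boundaries, b.genes,
                     top_n=2)
    mids = sorted(c.midpoint for c in calls)
    true = sorted(b.truth.true_tss["g"])
    assert len(calls) == 2
    for m, t in zip(mids, true):
        assert abs(m - t) <= 50
    assert all(c.match_status == "matched" for c in calls)


def test_tss_inside_upstream_gene_label():
    genes = [GeneFeature("a", "+", exons=[(500, 2600)]),
             GeneFeature("b", "+", exons=[(3000, 4000)])]
    plus = np.full(6000, 10)
    plus[2200:] = 150  # rise within gene a's exon
    prof = slope_profile(make_depth(plus), genes[1])
    calls = call_tss(prof, [], genes)
    assert calls[0].match_status == "inside_upstream_gene"


def test_tss_upstream_of_known_label():
    known = [KnownBoundary("g", "tss", 2800)]
    plus = np.full(6000, 10)
    plus[1500:] = 150  # rise 1300 bp upstream of the known TSS
    prof = slope_profile(make_depth(plus), GENE)
    calls = call_tss(prof, known, [])
    assert calls[0].match_status == "upstream_of_known"


def test_terminus_step_down_first_window():
    plus = np.full(8000, 10)
    plus[2500:4000] = 200  # gene body [3000,4000), drop right at gene end
    t = call_terminus(make_depth(plus), GENE)
    assert t.match_status in ("matched", "unmatched")
    assert t.drop_position == 4000
    assert t.depth_before > t.depth_after


def test_terminus_obscured_by_downstream_gene():
    genes = [GeneFeature("g", "+", exons=[(3000, 4000)]),
             GeneFeature("d", "+", exons=[(4100, 5200)])]
    plus = np.full(8000, 10)
    plus[2500:5400] = 200  # continuous elevation through the downstream gene
    t = call_terminus(make_depth(plus), genes[0], genes=genes)
    assert t.match_status == "obscured_by_downstream_gene"
    assert t.drop_position is None


def test_terminus_recovery_from_generator():
    spec = SyntheticSpec.random(n_genes=30, seed=13)
    b = generate(spec)
    for g in b.genes:
        t = call_terminus(b.depth, g, genes=b.genes, known=b.boundaries)
        true = b.truth.true_termini[g.gene_id]
        assert t.drop_position is not None
        assert abs(t.drop_position - true) <= 50  # within one window
        assert t.match_status == "matched"


def _naive_scan(seq, queries):
    from Bio.Seq import Seq
    hits = []
    for label, q in queries:
        rc = str(Seq(q).reverse_complement())
        for i in range(len(seq) - len(q) + 1):
            if seq[i:i + len(q)] == q:
                hits.append((label, "+", i))
            if seq[i:i + len(q)] == rc:
                hits.append((label, "-", i))
    return sorted(hits, key=lambda h: (h[0], h[2], h[1]))


def test_scan_finds_planted_motifs():
    spec = SyntheticSpec(genome_length=5000, genes=[],
                         planted_motifs=[("P1", "ACGTACGTACGTACGTT", 1200, "+"),
                                         ("P2", "GGGGCCCCAAAATTTTC", 3100, "-")],
                         seed=5)
    b = generate(spec)
    hits = scan_promoter_sequences(b.ref, [("P1", "ACGTACGTACGTACGTT"),
                                           ("P2", "GGGGCCCCAAAATTTTC")])
    assert ("P1", "+", 1200) in hits
    assert ("P2", "-", 3100) in hits


@pytest.mark.parametrize("seed", [0, 1])
def test_scan_equals_naive_oracle(seed):
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bases[rng.integers(0, 4, size=3000)].tobytes().decode()
    genome = GenomeRef("r", 3000, sequence=seq)
    queries = [(f"q{i}", seq[p:p + 8]) for i, p in
               enumerate(rng.integers(0, 2992, size=5))]
    assert scan_promoter_sequences(genome, queries) == _naive_scan(seq, queries)


def test_scan_rejects_ambiguous_query():
    genome = GenomeRef("r", 100, sequence="A" * 100)
    with pytest.raises(ValueError):
        scan_promoter_sequences(genome, [("bad", "ACGTN")])
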