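import numpy as np
import pandas as pd
import pytest

from duptrp.architecture import (ArchitectureError, HaplotypeWalk,
                                 JunctionEdge, Segment, SegmentPartition,
                                 WalkTruncationError, brute_force_enumerate,
                                 enumerate_architectures, evidence_roundtrip,
                                 gene_consequences, partition_segments,
                                 walk_length)
from duptrp.junctions import Breakend, JunctionCall
from duptrp.segmentation import CNSegment


def genes_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def simple_partition(ms, edges):
    bounds = list(range(0, (len(ms) + 1) * 10_000, 10_000))
    segments = [Segment(f"S{i}", bounds[i], bounds[i + 1], m)
                for i, m in enumerate(ms)]
    return SegmentPartition(segments=segments, edges=edges)


def test_no_junctions_single_reference_walk():
    part = simple_partition([1, 1, 1], [])
    walks = enumerate_architectures(part)
    assert len(walks) == 1
    assert walks[0].steps == (("S0", "+"), ("S1", "+"), ("S2", "+"))


def test_tandem_duplication_single_walk():
    edge = JunctionEdge.from_breakends((10_000, "H"), (20_000, "T"), 0)
    part = simple_partition([1, 2, 1], [edge])
    walks = enumerate_architectures(part)
    assert len(walks) == 1
    assert walks[0].steps == (("S0", "+"), ("S1", "+"), ("S1", "+"),
                              ("S2", "+"))
    assert walks == brute_force_enumerate(part)


def fig4_fixture():
    """Multiplicities (1,2,3,2,1) with the tail-to-tail distal junction and
    the head-to-head proximal junction of an inverted dup-triplication."""
    edges = [
        JunctionEdge.from_breakends((10_000, "H"), (20_000, "H"), 0),
        JunctionEdge.from_breakends((30_000, "T"), (40_000, "T"), 1),
    ]
    return simple_partition([1, 2, 3, 2, 1], edges)


def test_four_architectures_for_inverted_duplication_triplication():
    part = fig4_fixture()
    walks = enumerate_architectures(part)
    assert len(walks) == 4
    # the four structures differ only in the span of the central inverted run
    inverted_spans = sorted(
        tuple(sid for sid, o in w.steps if o == "-") for w in walks)
    assert inverted_spans == [("S2",), ("S2", "S1"), ("S3", "S2"),
                              ("S3", "S2", "S1")]
    assert walks == brute_force_enumerate(part)


def test_enumeration_matches_oracle_on_random_instances():
    rng = np.random.default_rng(21)
    classes = {"TT": ("T", "T"), "HH": ("H", "H"), "TH": ("T", "H"),
               "HT": ("H", "T")}
    checked = 0
    for _ in range(40):
        n_mid = int(rng.integers(1, 4))
        ms = [1] + [int(rng.integers(1, 4)) for _ in range(n_mid)] + [1]
        bounds = list(range(0, (len(ms) + 1) * 10_000, 10_000))
        n_j = int(rng.integers(0, 3))
        edges = []
        for cid in range(n_j):
            pa, pb = sorted(rng.choice(bounds[1:-1], size=2, replace=True))
            ka, kb = classes[str(rng.choice(list(classes)))]
            if pa == pb and {ka, kb} == {"T", "H"}:
                continue  # reference continuity, not a junction
            edges.append(JunctionEdge.from_breakends((int(pa), ka),
                                                     (int(pb), kb), cid))
        part = simple_partition(ms, edges)
        try:
            walks = enumerate_architectures(part, max_walks=5000)
        except WalkTruncationError:
            continue
        oracle = brute_force_enumerate(part, max_walks=5000)
        assert [w.steps for w in walks] == [w.steps for w in oracle]
        checked += 1
    assert checked >= 30


def test_walk_conservation_and_roundtrip_equivalence():
    part = fig4_fixture()
    walks = enumerate_architectures(part)
    expected_len = sum(len(s) * s.m for s in part.segments)
    for w in walks:
        assert walk_length(w, part) == expected_len
    evidence = [evidence_roundtrip(w, part) for w in walks]
    assert all(e == evidence[0] for e in evidence)
    calls, profile = evidence[0]
    assert [c.jclass for c in calls] == ["INV_HEAD_HEAD", "INV_TAIL_TAIL"]
    assert [cn for _, _, cn in profile] == [2, 3, 4, 3, 2]


def test_reference_walk_roundtrip_is_flat():
    part = simple_partition([1, 1, 1], [])
    walk = enumerate_architectures(part)[0]
    calls, profile = evidence_roundtrip(walk, part)
    assert calls == []
    assert [cn for _, _, cn in profile] == [2, 2, 2]


def test_tandem_walk_roundtrip_emits_tandem_junction():
    edge = JunctionEdge.from_breakends((10_000, "H"), (20_000, "T"), 0)
    part = simple_partition([1, 2, 1], [edge])
    walk = enumerate_architectures(part)[0]
    calls, _ = evidence_roundtrip(walk, part)
    assert [c.jclass for c in calls] == ["TANDEM_DUP_LIKE"]


def test_canonicalization_is_involutive_and_deduplicates():
    w = HaplotypeWalk((("S0", "+"), ("S1", "-"), ("S2", "+")))
    assert w.canonical().canonical() == w.canonical()
    assert w.reverse_complement().reverse_complement() == w
    assert w.canonical() == w.reverse_complement().canonical()
    part = fig4_fixture()
    walks = enumerate_architectures(part)
    assert len({w.canonical().steps for w in walks}) == len(walks)


def test_max_walks_truncation():
    part = fig4_fixture()
    with pytest.raises(WalkTruncationError):
        enumerate_architectures(part, max_walks=2)


def test_infeasible_constraints_yield_empty_set():
    # an inverted junction is required but multiplicities are all 1
    edge = JunctionEdge.from_breakends((10_000, "T"), (20_000, "T"), 0)
    part = simple_partition([1, 1, 1], [edge])
    assert enumerate_architectures(part) == []


# ---------------------------------------------------------------------------
# partition_segments
# ---------------------------------------------------------------------------

def cn_segments(profile, chrom="chr16", bin_size=500):
    return [CNSegment(chrom, s, e, cn, cn / 2.0, (e - s) // bin_size)
            for s, e, cn in profile]


def test_flat_profile_partitions_to_single_segment():
    part = partition_segments(cn_segments([(0, 100_000, 2)]), [])
    assert len(part.segments) == 1
    assert part.segments[0].m == 1


def test_stepped_profile_multiplicities():
    profile = [(0, 40_000, 2), (40_000, 70_000, 3), (70_000, 120_000, 4),
               (120_000, 150_000, 3), (150_000, 190_000, 2)]
    calls = [
        JunctionCall(a=Breakend("chr16", 40_000, "+"),
                     b=Breakend("chr16", 70_000, "+")),
        JunctionCall(a=Breakend("chr16", 120_000, "-"),
                     b=Breakend("chr16", 150_000, "-")),
    ]
    part = partition_segments(cn_segments(profile), calls)
    assert [s.m for s in part.segments] == [1, 2, 3, 2, 1]
    assert len(part.edges) == 2


def test_breakend_in_repeat_records_two_placements(fig4_partition):
    # the proximal call sits inside the palindrome: its paralogous placement
    # is recorded, but being homology-seamless it anchors no extra edge
    proximal_id = next(e.call_id for e in fig4_partition.edges
                       if "H" in {k for _, k in e.ends})
    assert len(fig4_partition.ambiguity[proximal_id]) >= 2
    assert sum(e.call_id == proximal_id for e in fig4_partition.edges) == 1


def test_homozygous_loss_rejected():
    with pytest.raises(ArchitectureError):
        partition_segments(cn_segments([(0, 50_000, 0)]), [])


# ---------------------------------------------------------------------------
# Gene consequences
# ---------------------------------------------------------------------------

def test_gene_inside_triplicated_segment_has_three_copies_everywhere():
    part = fig4_fixture()
    genes = genes_df([["chr16", 21_000, 29_000, "GENE_A"]])
    for walk in enumerate_architectures(part):
        (gc,) = gene_consequences(walk, part, genes)
        assert gc.copies_on_rearranged_allele == 3
        assert not gc.disrupted


def test_flank_and_outside_genes_are_untouched():
    part = fig4_fixture()
    genes = genes_df([["chr16", 1_000, 6_000, "FLANK_GENE"],
                      ["chr16", 200_000, 210_000, "OUTSIDE"]])
    for walk in enumerate_architectures(part):
        flank, outside = gene_consequences(walk, part, genes)
        assert flank.copies_on_rearranged_allele == 1
        assert not flank.disrupted
        assert outside.copies_on_rearranged_allele == 1
        assert not outside.disrupted


def test_gene_straddling_junction_breakend_has_truncated_copy():
    """A gene across a used junction breakend is disrupted; because all
    enumerated walks traverse the same junction set, the flag is shared by
    every walk (junction-attachment counts per boundary are conserved
    across evidence-equivalent walks)."""
    part = fig4_fixture()
    genes = genes_df([["chr16", 28_000, 32_000, "GENE_C"]])
    walks = enumerate_architectures(part)
    flags = [gene_consequences(w, part, genes)[0].disrupted for w in walks]
    assert all(flags)
    # it still has intact copies: the two reference-adjacency traversals
    copies = [gene_consequences(w, part, genes)[0].copies_on_rearranged_allele
              for w in walks]
    assert copies == [2, 2, 2, 2]
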