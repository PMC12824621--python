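import numpy as np
import pytest

import duptrp as dt
from duptrp.junctions import cluster_junctions
from duptrp.palindrome import revcomp
from duptrp.simulate import (SimConfig, SimConfigError, apply_architecture,
                             build_reference, simulate_depth,
                             simulate_expression, simulate_junction_evidence,
                             simulate_long_reads, simulate_population_cnv)

DUPTRPS = ["DUPTRP_1", "DUPTRP_2", "DUPTRP_3", "DUPTRP_4"]


# ---------------------------------------------------------------------------
# Configuration and reference construction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs", [
    {"flank_len": 0},
    {"mosaic_fraction": 1.2},
    {"arm_identity": 0.0},
    {"architecture_id": "NOPE"},
    {"cis_morphism_offsets": (0, 4200)},
    {"cis_morphism_offsets": (12100, 7900)},
    {"arm_identity": 1.0},  # incompatible with two cis-morphism sites
])
def test_invalid_configurations_rejected(kwargs):
    with pytest.raises(SimConfigError):
        SimConfig(**kwargs).validate()


def test_identity_one_without_sites_gives_exact_inverted_repeat():
    cfg = SimConfig(seed=3, arm_identity=1.0, cis_morphism_offsets=None,
                    palindrome_arm_len=5000)
    ref, layout = build_reference(cfg)
    (a1s, a1e), (a2s, a2e) = layout.palindrome.arm1, layout.palindrome.arm2
    assert ref[a2s:a2e] == revcomp(ref[a1s:a1e])
    assert layout.sites == ()


def test_divergent_position_count_matches_identity():
    """arm_len 10,000 at identity 0.998 -> exactly 20 mismatches between
    arm1 and revcomp(arm2), counted by brute-force comparison; the two
    cis-morphism sites are part of that total."""
    cfg = SimConfig(seed=4, palindrome_arm_len=10_000, arm_identity=0.998,
                    cis_morphism_offsets=(2_900, 7_100))
    ref, layout = build_reference(cfg)
    (a1s, a1e), (a2s, a2e) = layout.palindrome.arm1, layout.palindrome.arm2
    arm1, arm2 = ref[a1s:a1e], ref[a2s:a2e]
    mismatches = sum(a != b for a, b in zip(arm1, revcomp(arm2)))
    assert mismatches == 20


def test_cis_morphism_sites_are_4200_bp_apart(reference):
    _, layout = reference
    a, b = layout.sites
    assert b.arm1_pos - a.arm1_pos == 4_200
    assert a.arm2_pos - b.arm2_pos == 4_200  # reflected order in arm 2
    assert a.arm1_allele != a.arm2_allele
    assert b.arm1_allele != b.arm2_allele


def test_layout_tiles_the_reference(reference):
    ref, layout = reference
    records = layout.records
    assert records[0].start == 0
    assert records[-1].end == len(ref)
    for prev, nxt in zip(records[:-1], records[1:]):
        assert prev.end == nxt.start


# ---------------------------------------------------------------------------
# Architectures
# ---------------------------------------------------------------------------

def test_reference_architecture_is_identity(reference):
    ref, layout = reference
    hap, truth = apply_architecture(ref, layout, "REF")
    assert hap == ref
    assert truth.truth_junctions == ()
    assert truth.truth_cn_profile == ((0, len(ref), 2),)


@pytest.mark.parametrize("arch", DUPTRPS)
def test_duptrp_profile_junctions_and_length(reference, arch):
    ref, layout = reference
    hap, truth = apply_architecture(ref, layout, arch)
    cns = [cn for _, _, cn in truth.truth_cn_profile]
    assert cns == [2, 3, 4, 3, 2]
    # exactly two distinct junctions; the distal one is tail-to-tail
    assert len(truth.truth_junctions) == 2
    classes = {j.name: j.jclass for j in truth.truth_junctions}
    assert classes == {"proximal": "INV_HEAD_HEAD",
                       "distal": "INV_TAIL_TAIL"}
    # sequence length equals the CN-weighted segment sum (conservation)
    expected = sum((e - s) * (cn - 1) for s, e, cn in truth.truth_cn_profile)
    assert len(hap) == expected
    # walk multiplicities match the profile
    counts = {}
    for sid, _ in truth.rearranged_walk.steps:
        counts[sid] = counts.get(sid, 0) + 1
    assert [counts[s.id] for s in truth.sv_segments] == [1, 2, 3, 2, 1]


def test_four_duptrp_haplotypes_are_distinct_sequences(reference):
    ref, layout = reference
    haps = {apply_architecture(ref, layout, a)[0] for a in DUPTRPS}
    assert len(haps) == 4


def test_gene_inside_trp_has_three_copies_in_every_duptrp(reference):
    from duptrp.architecture import gene_consequences, partition_segments
    from tests.conftest import truth_to_evidence
    import pandas as pd
    ref, layout = reference
    trp = layout.record("trp")
    genes = pd.DataFrame(
        [[layout.chrom, trp.start + 1000, trp.end - 1000, "GENE_A"]],
        columns=["chrom", "start", "end", "name"])
    for arch in DUPTRPS:
        _, truth = apply_architecture(ref, layout, arch)
        cn, calls = truth_to_evidence(truth, layout.chrom)
        part = partition_segments(cn, calls, [layout.palindrome])
        for walk in dt.enumerate_architectures(part):
            (gc,) = gene_consequences(walk, part, genes)
            assert gc.copies_on_rearranged_allele == 3


def test_tandem_dup_and_del_inv_truths(reference):
    ref, layout = reference
    _, tandem = apply_architecture(ref, layout, "TANDEM_DUP")
    assert [j.jclass for j in tandem.truth_junctions] == ["TANDEM_DUP_LIKE"]
    assert sorted({cn for _, _, cn in tandem.truth_cn_profile}) == [2, 3]
    _, delinv = apply_architecture(ref, layout, "DEL_INV")
    assert sorted(j.jclass for j in delinv.truth_junctions) == \
        ["INV_HEAD_HEAD", "INV_TAIL_TAIL"]
    assert min(cn for _, _, cn in delinv.truth_cn_profile) == 1


# ---------------------------------------------------------------------------
# Depth
# ---------------------------------------------------------------------------

def test_noiseless_constitutional_depth_reproduces_profile(duptrp1):
    _, truth = duptrp1
    bins = simulate_depth(truth.truth_cn_profile, 60.0, 500, 1.0,
                          noise="none")
    for s, e, cn in truth.truth_cn_profile:
        inside = bins[(bins.start >= s) & (bins.end <= e)]
        assert np.allclose(inside["count"], 60.0 * cn)


def test_flat_profile_mean_is_diploid():
    rng = np.random.default_rng(9)
    bins = simulate_depth(((0, 5_000_000, 2),), 60.0, 500, 1.0, rng)
    assert bins["count"].mean() == pytest.approx(120.0, rel=0.01)


def test_mosaic_dup_ratio_matches_mixture_model():
    """f=0.35 duplication: mean ratio (2 + 0.35)/2 = 1.175, checked by
    Monte Carlo over 1e5 bins."""
    rng = np.random.default_rng(10)
    bins = simulate_depth(((0, 50_000_000, 3),), 60.0, 500, 0.35, rng)
    assert len(bins) == 100_000
    ratio = bins["count"].mean() / 120.0
    assert ratio == pytest.approx(1.175, abs=0.002)


def test_constitutional_trp_ratio_is_two(duptrp1):
    _, truth = duptrp1
    rng = np.random.default_rng(11)
    bins = simulate_depth(truth.truth_cn_profile, 60.0, 500, 1.0, rng)
    s, e, cn = truth.truth_cn_profile[2]
    assert cn == 4
    inside = bins[(bins.start >= s) & (bins.end <= e)]
    assert inside["count"].mean() / 120.0 == pytest.approx(2.0, abs=0.02)


def test_depth_input_validation(duptrp1):
    _, truth = duptrp1
    with pytest.raises(ValueError):
        simulate_depth(truth.truth_cn_profile, 0.0, 500)
    with pytest.warns(UserWarning):
        simulate_depth(((0, 1000, 2), (1000, 1500, 3), (1500, 3000, 2)),
                       60.0, 800, noise="none")


# ---------------------------------------------------------------------------
# Junction evidence
# ---------------------------------------------------------------------------

def test_zero_jitter_reproduces_truth_exactly(duptrp1):
    _, truth = duptrp1
    rows = simulate_junction_evidence(truth.truth_junctions, 5, 0,
                                      np.random.default_rng(0))
    calls = cluster_junctions(rows, min_support=1)
    got = {(c.a.pos, c.a.strand, c.b.pos, c.b.strand) for c in calls}
    want = {(j.a.pos, j.a.strand, j.b.pos, j.b.strand)
            for j in truth.truth_junctions}
    assert got == want


def test_jitter_stays_within_bounds(duptrp1):
    _, truth = duptrp1
    rows = simulate_junction_evidence(truth.truth_junctions, 50, 50,
                                      np.random.default_rng(1))
    for j in truth.truth_junctions:
        near_a = rows[(rows.start1 - j.a.pos).abs() <= 50]
        assert len(near_a) >= 50  # all rows of this junction within +/-50


def test_ref_truth_yields_empty_bedpe(reference):
    ref, layout = reference
    _, truth = apply_architecture(ref, layout, "REF")
    rows = simulate_junction_evidence(truth.truth_junctions, 10, 50,
                                      np.random.default_rng(2))
    assert len(rows) == 0


@pytest.mark.parametrize("arch,expected", [
    ("DUPTRP_1", {("-", "-"), ("+", "+")}),
    ("TANDEM_DUP", {("-", "+")}),
])
def test_emitted_strand_pairs_match_truth(reference, arch, expected):
    ref, layout = reference
    _, truth = apply_architecture(ref, layout, arch)
    rows = simulate_junction_evidence(truth.truth_junctions, 10, 50,
                                      np.random.default_rng(3))
    assert set(zip(rows.strand1, rows.strand2)) == expected


# ---------------------------------------------------------------------------
# Long reads
# ---------------------------------------------------------------------------

def test_no_reads_gives_empty_observation_table(reference, duptrp1):
    ref, layout = reference
    _, truth = duptrp1
    reads, obs = simulate_long_reads(ref, layout, truth, 0)
    assert reads == [] and len(obs) == 0


def test_reference_haplotype_reads_are_phase_pure(reference):
    ref, layout = reference
    _, truth = apply_architecture(ref, layout, "REF")
    rng = np.random.default_rng(6)
    _, obs = simulate_long_reads(ref, layout, truth, 300, 20_000, rng)
    a, b = layout.sites
    for _, grp in obs.groupby("read_id"):
        calls = dict(zip(grp.site_id, grp.allele))
        if len(calls) == 2 and len(grp) == 2:
            pattern = (calls[a.site_id] == a.arm1_allele,
                       calls[b.site_id] == b.arm1_allele)
            assert pattern in {(True, True), (False, False)}


def test_duptrp_junction_reads_are_chimeric(reference):
    """Reads crossing the seamless proximal junction carry one arm's allele
    at one site and the other arm's allele at the other -- the signal that
    localizes the breakpoint."""
    from duptrp.simulate import proximal_junction_hap_position
    ref, layout = reference
    _, truth = apply_architecture(ref, layout, "DUPTRP_1")
    jpos = proximal_junction_hap_position(truth)
    rng = np.random.default_rng(7)
    _, obs = simulate_long_reads(ref, layout, truth, 30, 20_000, rng,
                                 span_hap_positions=[(1, jpos)])
    a, b = layout.sites
    chimeric = 0
    for _, grp in obs.groupby("read_id"):
        calls = dict(zip(grp.site_id, grp.allele))
        if len(calls) == 2 and len(grp) == 2:
            is_arm1 = (calls[a.site_id] == a.arm1_allele,
                       calls[b.site_id] == b.arm1_allele)
            chimeric += is_arm1 in {(True, False), (False, True)}
    assert chimeric >= 25


def test_short_reads_warn_about_unphasable_sites(reference, duptrp1):
    ref, layout = reference
    _, truth = duptrp1
    with pytest.warns(UserWarning):
        simulate_long_reads(ref, layout, truth, 1, 1_000,
                            np.random.default_rng(8))


# ---------------------------------------------------------------------------
# Expression and population CNV
# ---------------------------------------------------------------------------

def test_unit_dosage_index_is_unremarkable():
    from duptrp.expression import fold_above_mean, housekeeping_normalize
    fcs = []
    for seed in range(20):
        tpm = simulate_expression(50, 1.0, 0.1, np.random.default_rng(seed))
        norm = housekeeping_normalize(tpm, "GAPDH")
        fcs.append(fold_above_mean(norm, "INDEX", "ATP6V0C"))
    assert np.mean(fcs) == pytest.approx(1.0, abs=0.05)


def test_housekeeping_genes_never_scaled():
    tpm = simulate_expression(20, 3.0, 0.0, np.random.default_rng(1))
    assert tpm.loc["GAPDH", "INDEX"] == pytest.approx(1500.0)
    assert tpm.loc["ATP6V0C", "INDEX"] == \
        pytest.approx(3.0 * tpm.loc["ATP6V0C"].drop("INDEX").mean())


def test_population_screen_recovers_planted_duplications():
    from duptrp.cohort import Interval, screen_population
    target = Interval(2_503_225, 2_529_370)
    table = simulate_population_cnv(500_000, target, 19,
                                    np.random.default_rng(2))
    hits, counts = screen_population(table, target, min_size=10_000)
    assert counts == {"DUP": 19, "TRIP": 0, "AMBIGUOUS": 0}


def test_subthreshold_calls_are_filtered():
    from duptrp.cohort import Interval, screen_population
    target = Interval(2_503_225, 2_529_370)
    table = simulate_population_cnv(10_000, target, 0,
                                    np.random.default_rng(3),
                                    n_background_calls=0,
                                    n_subthreshold_calls=8)
    hits, counts = screen_population(table, target, min_size=10_000)
    assert len(hits) == 0


# ---------------------------------------------------------------------------
# Full dataset round trip
# ---------------------------------------------------------------------------

def test_dataset_files_reparse_to_equal_objects(tmp_path):
    import duptrp.io as dio
    from duptrp.palindrome import sites_from_table
    cfg = SimConfig(seed=5, n_long_reads=20, expression_cohort_n=10)
    out = dt.simulate_dataset(cfg, tmp_path)
    depth = dio.read_depth_bins(tmp_path / "depth.tsv")
    assert np.allclose(depth["count"], out["depth"]["count"])
    bedpe = dio.read_bedpe(tmp_path / "junction_evidence.bedpe")
    assert bedpe.equals(out["junction_evidence"])
    fasta = dio.read_fasta(tmp_path / "reference.fa")
    assert fasta["reference"] == out["reference"]
    sites = sites_from_table(dio.read_table(tmp_path / "sites.tsv"))
    assert sites == list(out["layout"].sites)
    tpm = dio.read_expression_matrix(tmp_path / "expression_tpm.tsv")
    assert np.allclose(tpm.values, out["expression"].values)
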