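"""Synthetic-data generator for palindrome-mediated DUP-TRP/INV-DUP studies.

Builds a reference locus containing a large inverted-repeat (palindrome)
pair whose arms carry two paralog-distinguishing cis-morphism sites, plants
a rearrangement on one homolog, and derives every kind of downstream
evidence with known truth: binned read depth (Poisson or negative-binomial
noise, optional mosaicism), junction-supporting read pairs (BEDPE),
long reads with per-site allele observations, an expression cohort with a
dosage effect on the triplicated gene, and a population CNV call table.

Reference layout (0-based, contiguous)::

    flank_L | arm1 | spacer | arm2 | dup_left | trp | dup_right | flank_R
            `------ palindrome -----'

The four inverted duplication-triplication architectures share one pair of
proximal breakpoints (p1, p2) at paralogous positions inside the palindrome
arms, midway between the cis-morphism sites, and one pair of distal
breakpoints (a2 = trp end, a1 = dup_right end).  Each rearranged haplotype
is three runs: ``ref[0:e1] + revcomp(ref[s2:e2]) + ref[s3:]`` with
``{e1, e2} = {a1, a2}`` and ``{s2, s3} = {p1, p2}`` -- the four assignments
are the four structures that explain identical short-read evidence.  The
proximal transition is homology-mediated and sequence-seamless (arm 2 is
the near-perfect reverse complement of arm 1), which is exactly why long
reads crossing it show chimeric cis-morphism phase while short-read mapping
leaves the breakpoint ambiguous between the arms.  The resulting total
copy-number profile is the stepped 2-3-4-3-2: the proximal CN-3 shoulder
``[p1, p2)`` lies inside the palindrome, and the triplicated core
``[p2, a2)`` spans the distal arm-2 portion, ``dup_left`` and ``trp``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .architecture import FORWARD, INVERTED, HaplotypeWalk, Segment
from .cohort import Interval
from .io import BEDPE_COLUMNS, DEPTH_COLUMNS
from .junctions import Breakend, JunctionCall
from .palindrome import COMPLEMENT, CisMorphismSite, InvertedRepeat, revcomp

ARCHITECTURES = ("REF", "TANDEM_DUP", "DUPTRP_1", "DUPTRP_2", "DUPTRP_3",
                 "DUPTRP_4", "DEL_INV")
BASES = np.array(list("ACGT"))
DEFAULT_CHROM = "chr16_sim"


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-scale simulation parameters.

    Defaults are desk scale: 50 kb flanks, 20 kb palindrome arms of 99.8%
    identity with cis-morphisms 4.2 kb apart, 30/40/30 kb dup/trp/dup
    segments, 500 bp depth bins and ~20 kb long reads.

    ``haploid_depth`` is the mean number of sequenced fragments per bin per
    haploid copy.  The default 60 corresponds to 36x total short-read
    coverage: 18x per haploid copy x 500 bp bin / 150 bp reads = 60
    fragments.
    """

    seed: int = 0
    flank_len: int = 50_000
    dup_left_len: int = 30_000
    trp_len: int = 40_000
    dup_right_len: int = 30_000
    palindrome_arm_len: int = 20_000
    palindrome_spacer_len: int = 2_000
    arm_identity: float = 0.998
    cis_morphism_offsets: tuple[int, int] | None = (7_900, 12_100)
    architecture_id: str = "DUPTRP_1"
    mosaic_fraction: float = 1.0
    haploid_depth: float = 60.0
    bin_size: int = 500
    n_junction_pairs: int = 10
    position_jitter: int = 50
    long_read_len_mean: int = 20_000
    n_long_reads: int = 200
    long_read_error_rate: float = 0.01
    expression_cohort_n: int = 100
    dosage_fc: float = 2.0
    expression_cv: float = 0.1
    chrom: str = DEFAULT_CHROM

    def validate(self) -> None:
        lengths = dict(flank_len=self.flank_len, dup_left_len=self.dup_left_len,
                       trp_len=self.trp_len, dup_right_len=self.dup_right_len,
                       palindrome_arm_len=self.palindrome_arm_len,
                       bin_size=self.bin_size)
        for name, value in lengths.items():
            if value <= 0:
                raise SimConfigError(f"{name} must be > 0")
        if self.palindrome_spacer_len < 0:
            raise SimConfigError("palindrome_spacer_len must be >= 0")
        if not 0 <= self.mosaic_fraction <= 1:
            raise SimConfigError("mosaic_fraction must be in [0, 1]")
        if not 0 < self.arm_identity <= 1:
            raise SimConfigError("arm_identity must be in (0, 1]")
        if self.architecture_id not in ARCHITECTURES:
            raise SimConfigError(
                f"unknown architecture {self.architecture_id!r}")
        if self.haploid_depth <= 0:
            raise SimConfigError("haploid_depth must be > 0")
        offsets = self.cis_morphism_offsets
        if offsets is not None:
            a, b = offsets
            if not (0 < a < b < self.palindrome_arm_len):
                raise SimConfigError(
                    "cis_morphism_offsets must be strictly inside the arm "
                    "and increasing")
        n_sites = 0 if offsets is None else 2
        n_div = round((1 - self.arm_identity) * self.palindrome_arm_len)
        if n_div < n_sites:
            raise SimConfigError(
                "arm_identity incompatible with arm length: fewer divergent "
                "positions than cis-morphism sites")


@dataclass(frozen=True)
class SegmentRecord:
    id: str
    start: int
    end: int
    role: str  # flank | dup | trp | palindrome_arm_1 | palindrome_arm_2 | spacer


@dataclass(frozen=True)
class ReferenceLayout:
    """Interval structure of the simulated reference locus."""

    chrom: str
    records: tuple[SegmentRecord, ...]
    palindrome: InvertedRepeat
    sites: tuple[CisMorphismSite, ...]
    proximal_breakpoints: tuple[int, int]  # (p1 in arm1, p2 in arm2)

    def record(self, rid: str) -> SegmentRecord:
        return next(r for r in self.records if r.id == rid)

    @property
    def length(self) -> int:
        return self.records[-1].end

    def to_bed(self) -> pd.DataFrame:
        rows = [[self.chrom, r.start, r.end, f"{r.id}:{r.role}"]
                for r in self.records]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated rearranged haplotype."""

    architecture_id: str
    pieces: tuple[tuple[int, int, str], ...]  # (ref_start, ref_end, orient)
    sv_segments: tuple[Segment, ...]
    rearranged_walk: HaplotypeWalk
    truth_junctions: tuple[JunctionCall, ...]
    truth_cn_profile: tuple[tuple[int, int, int], ...]  # (start, end, total CN)


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _random_seq(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(BASES, size=n)


def build_reference(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[str, ReferenceLayout]:
    """Generate the reference sequence and its layout.

    Arm 2 is the reverse complement of arm 1 except at planted divergent
    positions: the total number of mismatches between arm 1 and
    revcomp(arm 2) equals ``round((1 - arm_identity) * arm_len)``, of which
    the cis-morphism sites account for two; the remainder are placed
    uniformly at random excluding the sites.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    A = config.palindrome_arm_len
    F = config.flank_len
    S = config.palindrome_spacer_len

    flank_l = _random_seq(F, rng)
    arm1 = _random_seq(A, rng)
    spacer = _random_seq(S, rng)
    arm2 = np.array(list(revcomp("".join(arm1))))
    dup_l = _random_seq(config.dup_left_len, rng)
    trp = _random_seq(config.trp_len, rng)
    dup_r = _random_seq(config.dup_right_len, rng)
    flank_r = _random_seq(F, rng)

    offsets = config.cis_morphism_offsets
    site_offsets = [] if offsets is None else list(offsets)
    n_div = round((1 - config.arm_identity) * A)
    n_random = n_div - len(site_offsets)
    eligible = np.setdiff1d(np.arange(A), np.array(site_offsets, dtype=int))
    random_offsets = rng.choice(eligible, size=n_random, replace=False) \
        if n_random > 0 else np.array([], dtype=int)

    def _mutate_arm2(t: int) -> None:
        """Substitute arm 2 at the position paralogous to arm-1 offset t."""
        j = A - 1 - t
        alternatives = [b for b in "ACGT" if b != arm2[j]]
        arm2[j] = rng.choice(alternatives)

    for t in random_offsets:
        _mutate_arm2(int(t))

    arm1_start = F
    arm2_start = F + A + S
    sites = []
    for i, t in enumerate(site_offsets):
        _mutate_arm2(t)
        g1 = arm1_start + t
        g2 = arm2_start + (A - 1 - t)
        arm1_allele = str(arm1[t])
        arm2_allele = str(arm2[A - 1 - t]).translate(COMPLEMENT)
        # site must remain paralog-distinguishing after projection
        assert arm1_allele != arm2_allele
        sites.append(CisMorphismSite(
            site_id=f"cm{chr(ord('A') + i)}",
            arm1_pos=g1, arm2_pos=g2,
            arm1_allele=arm1_allele, arm2_allele=arm2_allele))

    seq = "".join(["".join(flank_l), "".join(arm1), "".join(spacer),
                   "".join(arm2), "".join(dup_l), "".join(trp),
                   "".join(dup_r), "".join(flank_r)])

    p = arm2_start + A  # palindrome end
    records = (
        SegmentRecord("flank_L", 0, F, "flank"),
        SegmentRecord("arm1", F, F + A, "palindrome_arm_1"),
        SegmentRecord("spacer", F + A, F + A + S, "spacer"),
        SegmentRecord("arm2", arm2_start, p, "palindrome_arm_2"),
        SegmentRecord("dup_left", p, p + config.dup_left_len, "dup"),
        SegmentRecord("trp", p + config.dup_left_len,
                      p + config.dup_left_len + config.trp_len, "trp"),
        SegmentRecord("dup_right", p + config.dup_left_len + config.trp_len,
                      p + config.dup_left_len + config.trp_len
                      + config.dup_right_len, "dup"),
        SegmentRecord("flank_R", p + config.dup_left_len + config.trp_len
                      + config.dup_right_len,
                      p + config.dup_left_len + config.trp_len
                      + config.dup_right_len + F, "flank"),
    )

    # proximal breakpoint pair: paralogous boundaries midway between sites
    if site_offsets:
        t_mid = (site_offsets[0] + site_offsets[1]) // 2
    else:
        t_mid = A // 2
    p1 = arm1_start + t_mid
    p2 = arm2_start + (A - t_mid)

    n_mismatch = len(site_offsets) + len(random_offsets)
    layout = ReferenceLayout(
        chrom=config.chrom,
        records=records,
        palindrome=InvertedRepeat(
            arm1=(arm1_start, arm1_start + A),
            arm2=(arm2_start, arm2_start + A),
            identity=1.0 - n_mismatch / A),
        sites=tuple(sites),
        proximal_breakpoints=(p1, p2),
    )
    return seq, layout


# ---------------------------------------------------------------------------
# Architectures
# ---------------------------------------------------------------------------

def _breakpoints(layout: ReferenceLayout) -> tuple[int, int, int, int]:
    p1, p2 = layout.proximal_breakpoints
    a2 = layout.record("trp").end
    a1 = layout.record("dup_right").end
    return p1, p2, a2, a1


_DUPTRP_RUNS = {
    # architecture -> (e1, s2, e2, s3) indices into (p1, p2, a2, a1)
    "DUPTRP_1": ("a1", "p2", "a2", "p1"),
    "DUPTRP_2": ("a1", "p1", "a2", "p2"),
    "DUPTRP_3": ("a2", "p2", "a1", "p1"),
    "DUPTRP_4": ("a2", "p1", "a1", "p2"),
}


def _pieces_to_walk(pieces, segments: tuple[Segment, ...]) -> HaplotypeWalk:
    """Decompose three-run pieces into a segment walk."""
    by_span = {(s.start, s.end): s for s in segments}
    order = sorted(segments, key=lambda s: s.start)
    steps: list[tuple[str, str]] = []
    for start, end, orient in pieces:
        covered = [s for s in order if s.start >= start and s.end <= end]
        if orient == INVERTED:
            covered = covered[::-1]
        steps.extend((s.id, orient) for s in covered)
    return HaplotypeWalk(tuple(steps))


def apply_architecture(
    ref_seq: str,
    layout: ReferenceLayout,
    architecture_id: str,
) -> tuple[str, TruthRecord]:
    """Construct the rearranged haplotype and its ground truth.

    Every ``DUPTRP_k`` yields the same stepped 2-3-4-3-2 total CN profile
    (against a diploid background with one intact homolog), the same
    tail-to-tail (-/-) distal junction spanning ``dup_right`` and the same
    head-to-head (+/+) proximal junction at the paralogous breakpoint pair
    inside the palindrome; the four differ only in which segments the
    central inverted run covers.  ``REF`` returns the reference haplotype.
    """
    L = layout.length
    chrom = layout.chrom
    p1, p2, a2, a1 = _breakpoints(layout)

    if architecture_id == "REF":
        pieces = ((0, L, FORWARD),)
        segments = (Segment("LOCUS", 0, L, 1),)
        truth = TruthRecord(
            architecture_id=architecture_id,
            pieces=pieces,
            sv_segments=segments,
            rearranged_walk=HaplotypeWalk((("LOCUS", FORWARD),)),
            truth_junctions=(),
            truth_cn_profile=((0, L, 2),),
        )
    elif architecture_id in _DUPTRP_RUNS:
        pos = {"p1": p1, "p2": p2, "a2": a2, "a1": a1}
        e1, s2, e2, s3 = (pos[k] for k in _DUPTRP_RUNS[architecture_id])
        pieces = ((0, e1, FORWARD), (s2, e2, INVERTED), (s3, L, FORWARD))
        segments = (
            Segment("FL", 0, p1, 1),
            Segment("DUP_P", p1, p2, 2),
            Segment("TRP", p2, a2, 3),
            Segment("DUP_D", a2, a1, 2),
            Segment("FR", a1, L, 1),
        )
        junctions = (
            JunctionCall(a=Breakend(chrom, p1, "+"),
                         b=Breakend(chrom, p2, "+"), name="proximal"),
            JunctionCall(a=Breakend(chrom, a2, "-"),
                         b=Breakend(chrom, a1, "-"), name="distal"),
        )
        truth = TruthRecord(
            architecture_id=architecture_id,
            pieces=pieces,
            sv_segments=segments,
            rearranged_walk=_pieces_to_walk(pieces, segments),
            truth_junctions=junctions,
            truth_cn_profile=((0, p1, 2), (p1, p2, 3), (p2, a2, 4),
                              (a2, a1, 3), (a1, L, 2)),
        )
    elif architecture_id == "TANDEM_DUP":
        t = layout.record("trp")
        pieces = ((0, t.end, FORWARD), (t.start, L, FORWARD))
        segments = (
            Segment("FL", 0, t.start, 1),
            Segment("TRP", t.start, t.end, 2),
            Segment("FR", t.end, L, 1),
        )
        junctions = (
            JunctionCall(a=Breakend(chrom, t.start, "-"),
                         b=Breakend(chrom, t.end, "+"), name="tandem"),
        )
        truth = TruthRecord(
            architecture_id=architecture_id,
            pieces=pieces,
            sv_segments=segments,
            rearranged_walk=HaplotypeWalk(
                (("FL", FORWARD), ("TRP", FORWARD), ("TRP", FORWARD),
                 ("FR", FORWARD))),
            truth_junctions=junctions,
            truth_cn_profile=((0, t.start, 2), (t.start, t.end, 3),
                              (t.end, L, 2)),
        )
    elif architecture_id == "DEL_INV":
        d = a2  # distal breakpoint of the inverted, retained segment
        pieces = ((0, p1, FORWARD), (p2, d, INVERTED), (d, L, FORWARD))
        segments = (
            Segment("FL", 0, p1, 1),
            Segment("DEL", p1, p2, 0),
            Segment("INV", p2, d, 1),
            Segment("FR", d, L, 1),
        )
        junctions = (
            JunctionCall(a=Breakend(chrom, p1, "-"),
                         b=Breakend(chrom, d, "-"), name="del_inv_distal"),
            JunctionCall(a=Breakend(chrom, p2, "+"),
                         b=Breakend(chrom, d, "+"), name="del_inv_proximal"),
        )
        truth = TruthRecord(
            architecture_id=architecture_id,
            pieces=pieces,
            sv_segments=segments,
            rearranged_walk=HaplotypeWalk(
                (("FL", FORWARD), ("INV", INVERTED), ("FR", FORWARD))),
            truth_junctions=junctions,
            truth_cn_profile=((0, p1, 2), (p1, p2, 1), (p2, L, 2)),
        )
    else:
        raise SimConfigError(f"unknown architecture {architecture_id!r}")

    hap = "".join(
        ref_seq[s:e] if o == FORWARD else revcomp(ref_seq[s:e])
        for s, e, o in truth.pieces)
    return hap, truth


# ---------------------------------------------------------------------------
# Depth
# ---------------------------------------------------------------------------

def simulate_depth(
    truth_cn_profile,
    haploid_depth: float,
    bin_size: int,
    mosaic_fraction: float = 1.0,
    rng: np.random.Generator | None = None,
    noise: str = "poisson",
    nb_dispersion: float = 10.0,
    chrom: str = DEFAULT_CHROM,
) -> pd.DataFrame:
    """Draw binned read counts from the true copy-number profile.

    The expected count of a bin whose rearranged-homolog copy number is
    ``m`` (total CN = m + 1) in a carrier fraction ``f`` is
    ``haploid_depth x (2 + f(m - 1))``: every cell contributes the intact
    homolog plus either the normal (1) or the rearranged (m) allele.  At
    f = 1 this is the constitutional ``haploid_depth x CN``.

    ``noise``: "poisson" (default), "nb" (gamma-Poisson with dispersion
    ``nb_dispersion``; smaller = noisier) or "none" (exact means, for
    deterministic round-trip checks).
    """
    if haploid_depth <= 0:
        raise ValueError("haploid_depth must be > 0")
    if rng is None:
        rng = np.random.default_rng()
    profile = list(truth_cn_profile)
    lo, hi = profile[0][0], profile[-1][1]
    smallest = min(e - s for s, e, _ in profile)
    if bin_size > smallest:
        warnings.warn("bin_size exceeds the smallest CN segment; steps may "
                      "be unresolvable")
    starts = np.arange(lo, hi, bin_size)
    ends = np.minimum(starts + bin_size, hi)
    if len(starts) == 0:
        raise ValueError("zero bins: locus shorter than one bin")

    f = mosaic_fraction
    means = np.zeros(len(starts))
    for s, e, cn in profile:
        m = cn - 1
        seg_mean = haploid_depth * (2 + f * (m - 1))
        overlap = (np.minimum(ends, e) - np.maximum(starts, s)).clip(min=0)
        means += overlap / (ends - starts) * seg_mean

    if noise == "poisson":
        counts = rng.poisson(means).astype(float)
    elif noise == "nb":
        lam = rng.gamma(shape=nb_dispersion, scale=means / nb_dispersion)
        counts = rng.poisson(lam).astype(float)
    elif noise == "none":
        counts = means
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                         "count": counts})[DEPTH_COLUMNS]


# ---------------------------------------------------------------------------
# Junction evidence
# ---------------------------------------------------------------------------

def simulate_junction_evidence(
    truth_junctions,
    n_junction_pairs: int,
    position_jitter: int = 50,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Emit BEDPE read-pair rows for each truth junction.

    Each junction emits ``n_junction_pairs`` rows carrying its strand pair,
    with both breakend positions jittered independently and uniformly within
    ``+/- position_jitter``.  No truth junctions (the REF architecture)
    yields an empty table.
    """
    if truth_junctions and n_junction_pairs < 1:
        raise ValueError("n_junction_pairs must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for j, call in enumerate(truth_junctions):
        for k in range(n_junction_pairs):
            ja = int(rng.integers(-position_jitter, position_jitter + 1)) \
                if position_jitter else 0
            jb = int(rng.integers(-position_jitter, position_jitter + 1)) \
                if position_jitter else 0
            pa = max(0, call.a.pos + ja)
            pb = max(0, call.b.pos + jb)
            rows.append([call.a.chrom, pa, pa + 1, call.b.chrom, pb, pb + 1,
                         f"{call.name or 'junction'}_{j}_{k}", 1,
                         call.a.strand, call.b.strand])
    return pd.DataFrame(rows, columns=BEDPE_COLUMNS)


# ---------------------------------------------------------------------------
# Long reads and allele observations
# ---------------------------------------------------------------------------

def _piece_hap_offsets(pieces) -> list[int]:
    offs = [0]
    for s, e, _ in pieces:
        offs.append(offs[-1] + (e - s))
    return offs


def _site_instances(pieces, sites) -> list[tuple[str, int, str]]:
    """All haplotype positions carrying a cis-morphism site.

    Returns (site_id, hap_pos, arm) with arm in {"arm1", "arm2"} naming the
    source arm of the material (which determines the observed allele in the
    arm-1 reading frame, regardless of piece orientation).
    """
    offs = _piece_hap_offsets(pieces)
    out = []
    for (s, e, o), base in zip(pieces, offs):
        for site in sites:
            for g, arm in ((site.arm1_pos, "arm1"), (site.arm2_pos, "arm2")):
                if s <= g < e:
                    hap_pos = base + (g - s if o == FORWARD else e - 1 - g)
                    out.append((site.site_id, hap_pos, arm))
    return sorted(out, key=lambda t: t[1])


def proximal_junction_hap_position(truth: TruthRecord) -> int | None:
    """Haplotype coordinate of the junction preceding the last forward run."""
    if len(truth.pieces) < 2:
        return None
    return _piece_hap_offsets(truth.pieces)[-2]


def simulate_long_reads(
    ref_seq: str,
    layout: ReferenceLayout,
    truth: TruthRecord,
    n_reads: int,
    length_mean: int = 20_000,
    rng: np.random.Generator | None = None,
    error_rate: float = 0.0,
    span_hap_positions: list[tuple[int, int]] | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Sample long reads and report their cis-morphism allele observations.

    Reads are drawn from the normal (reference) and rearranged haplotypes in
    proportion to haplotype length (one copy of each per cell).  For every
    cis-morphism site position a read covers, the observed allele is
    reported as a base in the arm-1 forward frame: material derived from
    arm 1 shows the arm-1 allele and material from arm 2 the arm-2 allele,
    whichever orientation the material is traversed in.  A per-base error
    rate substitutes a uniformly random different base.

    ``span_hap_positions`` optionally targets reads: each entry is
    (haplotype index, haplotype position); reads are centered on entries
    drawn uniformly, emulating targeted examination of junction-spanning
    reads.  Haplotype index 0 is the normal homolog, 1 the rearranged one.

    Returns (reads, observations): FASTA-ready (name, sequence) pairs and a
    table with columns read_id / site_id / allele.
    """
    if rng is None:
        rng = np.random.default_rng()
    sites = layout.sites
    if sites and length_mean < abs(sites[1].arm1_pos - sites[0].arm1_pos):
        warnings.warn("mean read length below the inter-site distance; "
                      "two-site phasing will be impossible")
    normal_pieces = ((0, len(ref_seq), FORWARD),)
    haplotypes = [normal_pieces, truth.pieces]
    hap_seqs = ["".join(ref_seq[s:e] if o == FORWARD else revcomp(ref_seq[s:e])
                        for s, e, o in pieces) for pieces in haplotypes]
    hap_lens = np.array([len(s) for s in hap_seqs], dtype=float)
    site_maps = [_site_instances(pieces, sites) for pieces in haplotypes]

    reads: list[tuple[str, str]] = []
    obs_rows: list[tuple[str, str, str]] = []
    for ri in range(n_reads):
        rl = max(200, int(rng.gamma(shape=10.0, scale=length_mean / 10.0)))
        if span_hap_positions:
            hap_idx, center = span_hap_positions[
                int(rng.integers(len(span_hap_positions)))]
            start = int(np.clip(center - rl // 2, 0,
                                max(0, int(hap_lens[hap_idx]) - rl)))
        else:
            hap_idx = int(rng.choice(2, p=hap_lens / hap_lens.sum()))
            start = int(rng.integers(0, max(1, int(hap_lens[hap_idx]) - rl + 1)))
        end = min(start + rl, int(hap_lens[hap_idx]))
        name = f"read_{ri:05d}_h{hap_idx}"
        reads.append((name, hap_seqs[hap_idx][start:end]))
        for site_id, hap_pos, arm in site_maps[hap_idx]:
            if start <= hap_pos < end:
                site = next(s for s in sites if s.site_id == site_id)
                base = site.arm1_allele if arm == "arm1" else site.arm2_allele
                if error_rate and rng.random() < error_rate:
                    base = str(rng.choice([b for b in "ACGT" if b != base]))
                obs_rows.append((name, site_id, base))
    obs = pd.DataFrame(obs_rows, columns=["read_id", "site_id", "allele"])
    return reads, obs


# ---------------------------------------------------------------------------
# Expression cohort
# ---------------------------------------------------------------------------

TARGET_GENE = "ATP6V0C"
HOUSEKEEPING_GENES = ("GAPDH", "ACTB")


def simulate_expression(
    cohort_n: int = 100,
    dosage_fc: float = 2.0,
    cv: float = 0.1,
    rng: np.random.Generator | None = None,
    n_background_genes: int = 47,
    index_sample: str = "INDEX",
) -> pd.DataFrame:
    """TPM matrix (genes x samples) with a dosage effect in one index sample.

    ``cohort_n`` control samples plus the index sample.  Each gene has a
    fixed baseline; per-sample values are mean-one log-normal deviates with
    coefficient of variation ``cv`` around the baseline.  The index sample's
    target gene is scaled by ``dosage_fc``; housekeeping genes are never
    scaled.  ``dosage_fc = 2`` is the naive constitutional-triplication
    (CN 4) expectation.
    """
    if cohort_n < 3:
        raise ValueError("cohort_n must be >= 3")
    if dosage_fc <= 0 or cv < 0:
        raise ValueError("dosage_fc must be > 0 and cv >= 0")
    if rng is None:
        rng = np.random.default_rng()
    genes = [TARGET_GENE, *HOUSEKEEPING_GENES,
             *(f"BG{i:03d}" for i in range(n_background_genes))]
    baselines = np.concatenate([
        [50.0, 1500.0, 2000.0],
        10 ** rng.uniform(0.5, 3.0, size=n_background_genes),
    ])
    samples = [f"S{i + 1:04d}" for i in range(cohort_n)] + [index_sample]
    sigma = np.sqrt(np.log1p(cv ** 2))
    noise = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma,
                          size=(len(genes), len(samples)))
    values = baselines[:, None] * noise
    values[0, -1] *= dosage_fc  # target gene, index sample
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                        columns=samples)


# ---------------------------------------------------------------------------
# Population CNV table
# ---------------------------------------------------------------------------

def simulate_population_cnv(
    n_samples: int,
    target: Interval,
    n_overlapping_dups: int = 19,
    rng: np.random.Generator | None = None,
    locus_span: tuple[int, int] = (0, 10_000_000),
    dup_size_range: tuple[int, int] = (15_000, 3_000_000),
    ratio_mean: float = 1.5,
    ratio_sd: float = 0.08,
    n_background_calls: int = 200,
    n_subthreshold_calls: int = 5,
) -> pd.DataFrame:
    """Population CNV call table with planted target-overlapping duplications.

    Exactly ``n_overlapping_dups`` qualifying duplications overlapping the
    target interval are planted directly (not per-sample Bernoulli), with
    sizes log-uniform in ``dup_size_range`` and copy ratios drawn around the
    constitutional duplication expectation (normal(1.5, 0.08) truncated to
    the duplication regime -- no triplications unless configured otherwise).
    Background calls avoid the target, and a few sub-threshold (<10 kb)
    target-overlapping calls exercise the size filter.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    sample_ids = rng.choice(n_samples,
                            size=n_overlapping_dups + n_background_calls
                            + n_subthreshold_calls, replace=False)
    idx = 0

    def _ratio():
        return float(np.clip(rng.normal(ratio_mean, ratio_sd), 1.2, 1.74))

    lo, hi = locus_span
    for _ in range(n_overlapping_dups):
        size = int(np.exp(rng.uniform(np.log(dup_size_range[0]),
                                      np.log(dup_size_range[1]))))
        # position to overlap the target by at least 1 bp
        start = int(rng.integers(max(lo, target.start - size + 1),
                                 target.end))
        rows.append([f"UKB{sample_ids[idx]:06d}", start, start + size,
                     _ratio()])
        idx += 1
    for _ in range(n_background_calls):
        size = int(np.exp(rng.uniform(np.log(dup_size_range[0]),
                                      np.log(dup_size_range[1]))))
        while True:
            start = int(rng.integers(lo, hi - size))
            if start + size <= target.start or start >= target.end:
                break
        rows.append([f"UKB{sample_ids[idx]:06d}", start, start + size,
                     _ratio()])
        idx += 1
    for _ in range(n_subthreshold_calls):
        size = int(rng.integers(1_000, 9_999))
        start = int(rng.integers(max(lo, target.start - size + 1),
                                 target.end))
        rows.append([f"UKB{sample_ids[idx]:06d}", start, start + size,
                     _ratio()])
        idx += 1
    return pd.DataFrame(rows, columns=["sample", "start", "end",
                                       "copy_ratio"])


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def default_genes(layout: ReferenceLayout) -> pd.DataFrame:
    """A small gene annotation: one gene inside the triplicated core, one in
    the left flank, one straddling the distal junction."""
    trp = layout.record("trp")
    flank = layout.record("flank_L")
    dup_r = layout.record("dup_right")
    third = (trp.end - trp.start) // 3
    rows = [
        [layout.chrom, trp.start + third, trp.end - third, TARGET_GENE],
        [layout.chrom, flank.start + 1000, flank.start + 6000, "FLANK_GENE"],
        [layout.chrom, dup_r.end - 3000, dup_r.end + 3000, "DISTAL_GENE"],
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def simulate_dataset(config: SimConfig, outdir) -> dict:
    """Run the full generator and write every evidence file to ``outdir``.

    Returns a dict of the in-memory objects (layout, truth, tables) so the
    caller can compare downstream inference against ground truth.
    """
    from pathlib import Path

    from . import io as dio
    from .palindrome import sites_to_table

    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ref_seq, layout = build_reference(config, rng)
    hap_seq, truth = apply_architecture(ref_seq, layout,
                                        config.architecture_id)
    depth = simulate_depth(truth.truth_cn_profile, config.haploid_depth,
                           config.bin_size, config.mosaic_fraction, rng,
                           chrom=config.chrom)
    evidence = simulate_junction_evidence(truth.truth_junctions,
                                          config.n_junction_pairs,
                                          config.position_jitter, rng)
    reads, obs = simulate_long_reads(ref_seq, layout, truth,
                                     config.n_long_reads,
                                     config.long_read_len_mean, rng,
                                     error_rate=config.long_read_error_rate)
    tpm = simulate_expression(config.expression_cohort_n, config.dosage_fc,
                              config.expression_cv, rng)
    genes = default_genes(layout)

    dio.write_fasta({"reference": ref_seq}, outdir / "reference.fa")
    dio.write_fasta({"rearranged": hap_seq}, outdir / "haplotype.fa")
    dio.write_bed(layout.to_bed(), outdir / "layout.bed")
    dio.write_bed(genes, outdir / "genes.bed")
    dio.write_depth_bins(depth, outdir / "depth.tsv")
    dio.write_bedpe(evidence, outdir / "junction_evidence.bedpe")
    dio.write_fasta(reads, outdir / "long_reads.fa")
    dio.write_table(obs, outdir / "allele_observations.tsv")
    dio.write_table(sites_to_table(list(layout.sites)), outdir / "sites.tsv")
    dio.write_expression_matrix(tpm, outdir / "expression_tpm.tsv")
    truth_cn = pd.DataFrame(list(truth.truth_cn_profile),
                            columns=["start", "end", "cn"])
    truth_cn.insert(0, "chrom", config.chrom)
    dio.write_table(truth_cn, outdir / "truth_cn.tsv")
    from .junctions import calls_to_bedpe
    dio.write_bedpe(calls_to_bedpe(list(truth.truth_junctions)),
                    outdir / "truth_junctions.bedpe")
    return {"layout": layout, "truth": truth, "depth": depth,
            "junction_evidence": evidence, "reads": reads,
            "observations": obs, "expression": tpm, "genes": genes,
            "reference": ref_seq, "haplotype": hap_seq}
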