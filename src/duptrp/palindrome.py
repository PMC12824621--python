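"""Inverted-repeat detection and cis-morphism breakpoint phasing.

Large genomic palindromes -- two highly identical sequences in inverted
orientation separated by a short spacer -- promote double-strand breaks and
recurrent complex rearrangements, and simultaneously defeat breakpoint
mapping: a breakend inside one arm maps equally well to the other.  The two
arms of a real palindrome are, however, rarely perfectly identical.  A
*cis-morphism* is a paralog-distinguishing difference between the arms:
after projecting both arms onto a common reading frame, the two arms carry
different bases at the site, so any read overlapping the site can be
assigned to an arm.

When a rearrangement's proximal junction is a homology-mediated strand
switch between paralogous positions in the two arms, long reads that span
two cis-morphism sites straddling the switch show a *chimeric* allele
pattern -- one arm's allele at the first site and the other arm's allele at
the second -- which localizes the breakpoint to the open interval between
the sites.

Allele conventions: each site stores its genomic position in both arms and
both alleles expressed in the arm-1 forward reading frame (the arm-2 allele
is the complement of the base on the reference forward strand at the arm-2
position, because arm 2 is the reverse complement of arm 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")

DEFAULT_MIN_INFORMATIVE_READS = 5
DEFAULT_CONFIDENCE_THRESHOLD = 0.8


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class InvertedRepeat:
    """A pair of equal-length inverted arms with their percent identity."""

    arm1: tuple[int, int]
    arm2: tuple[int, int]
    identity: float

    def __post_init__(self):
        (s1, e1), (s2, e2) = self.arm1, self.arm2
        if e1 - s1 != e2 - s2:
            raise ValueError("arm lengths differ")
        if s2 < e1:
            raise ValueError("arm2 must begin after arm1 ends")
        if not 0 < self.identity <= 1:
            raise ValueError("identity must be in (0, 1]")

    @property
    def arm_len(self) -> int:
        return self.arm1[1] - self.arm1[0]

    @property
    def spacer_len(self) -> int:
        return self.arm2[0] - self.arm1[1]


@dataclass(frozen=True)
class CisMorphismSite:
    """A paralog-distinguishing site, alleles in the arm-1 forward frame."""

    site_id: str
    arm1_pos: int
    arm2_pos: int
    arm1_allele: str
    arm2_allele: str

    def __post_init__(self):
        if self.arm1_allele == self.arm2_allele:
            raise ValueError("alleles must differ between arms")


@dataclass(frozen=True)
class PhasingResult:
    """Two-site phase counts and the inferred breakpoint interval."""

    n_arm1_arm1: int
    n_arm2_arm2: int
    n_arm1_arm2: int  # arm1 allele at the first site, arm2 at the second
    n_arm2_arm1: int
    breakpoint_interval: tuple[int, int] | None
    confidence: float
    called: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# Inverted-repeat detection
# ---------------------------------------------------------------------------

def find_inverted_repeats(
    seq: str,
    min_arm: int = 500,
    max_spacer: int = 20000,
    max_mismatch_fraction: float = 0.01,
    seed_k: int = 16,
) -> list[InvertedRepeat]:
    """Detect inverted repeats by exact seed matching plus banded extension.

    Every ``seed_k``-mer of the sequence is compared against the reverse
    complement; a hit between position i and a reverse-complement match whose
    forward-strand interval starts at j (i < j) lies on the anti-diagonal
    ``c = i + j + seed_k``, which is constant across a perfect inverted
    repeat.  Hits are grouped by anti-diagonal, merged into candidate arm
    spans, extended outwards while the overall mismatch fraction stays within
    ``max_mismatch_fraction``, and trimmed back to matching ends.  Reported
    repeats are non-overlapping (longest kept first) and sorted.

    Suitable for desk-scale sequences (well under a megabase); no suffix
    machinery is needed at that size.
    """
    if min_arm < 8:
        raise ValueError("min_arm must be >= 8")
    n = len(seq)
    if n < 2 * min_arm:
        return []
    seq = seq.upper()
    k = min(seed_k, min_arm)

    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)

    # anti-diagonal -> seed start positions on the left arm
    diags: dict[int, list[int]] = {}
    for i in range(n - k + 1):
        kmer_rc = revcomp(seq[i:i + k])
        for j in index.get(kmer_rc, ()):
            if j >= i + k:  # left arm strictly before its inverted partner
                diags.setdefault(i + j + k, []).append(i)

    def _match(i: int, c: int) -> bool:
        j = c - 1 - i  # base paired with i on anti-diagonal c
        return 0 <= j < n and seq[j] == seq[i].translate(COMPLEMENT)

    candidates = []
    for c, starts in diags.items():
        starts = sorted(set(starts))
        # chain nearby seeds into one candidate per gap-free-ish cluster
        clusters = []
        cur = [starts[0]]
        for s in starts[1:]:
            if s - cur[-1] <= min_arm:
                cur.append(s)
            else:
                clusters.append(cur)
                cur = [s]
        clusters.append(cur)
        for cl in clusters:
            s1, e1 = cl[0], cl[-1] + k  # left-arm span covered by seeds
            # X-drop extension: +1 per match, -3 per mismatch; stop when the
            # running score falls xdrop below its maximum and keep the
            # best-scoring end, which pins the arm at the homology boundary.
            xdrop, mismatch_penalty = 20, 3
            lo = s1
            score = best = 0
            i = s1 - 1
            while i >= 0 and c - 1 - i < n and c - 1 - i >= e1:
                score += 1 if _match(i, c) else -mismatch_penalty
                if score > best:
                    best, lo = score, i
                if score < best - xdrop:
                    break
                i -= 1
            hi = e1
            score = best = 0
            i = e1
            while c - 1 - i >= i + 1:
                score += 1 if _match(i, c) else -mismatch_penalty
                if score > best:
                    best, hi = score, i + 1
                if score < best - xdrop:
                    break
                i += 1
            mism = sum(not _match(i, c) for i in range(lo, hi))
            arm_len = hi - lo
            if arm_len < min_arm:
                continue
            arm2 = (c - hi, c - lo)
            spacer = arm2[0] - hi
            if spacer < 0 or spacer > max_spacer:
                continue
            identity = 1.0 - mism / arm_len
            if identity < 1.0 - max_mismatch_fraction:
                continue
            candidates.append(InvertedRepeat((lo, hi), arm2, identity))

    # keep longest, non-overlapping
    candidates.sort(key=lambda r: (-r.arm_len, r.arm1[0]))
    kept: list[InvertedRepeat] = []
    for cand in candidates:
        span = (cand.arm1[0], cand.arm2[1])
        if all(span[1] <= r.arm1[0] or span[0] >= r.arm2[1] for r in kept):
            kept.append(cand)
    kept.sort(key=lambda r: r.arm1[0])
    return kept


# ---------------------------------------------------------------------------
# Cis-morphism phasing
# ---------------------------------------------------------------------------

def _classify_allele(base: str, site: CisMorphismSite) -> str | None:
    if base == site.arm1_allele:
        return "arm1"
    if base == site.arm2_allele:
        return "arm2"
    return None  # third allele: sequencing error, ignored


def phase_breakpoint(
    observations: pd.DataFrame,
    sites: list[CisMorphismSite],
    min_informative_reads: int = DEFAULT_MIN_INFORMATIVE_READS,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> PhasingResult:
    """Localize a palindrome-internal breakpoint from two-site allele phase.

    ``observations`` has columns read_id / site_id / allele (the observed
    base in the arm-1 forward frame).  Reads with exactly one observation at
    each of the two sites are *informative*; reads observing a site more than
    once (e.g. a read spanning the whole palindrome) or carrying a third
    allele are ignored.  If one chimeric pattern is supported by at least
    ``min_informative_reads`` reads and by at least ``confidence_threshold``
    of all chimeric reads, the breakpoint is localized to the open interval
    between the two sites' arm-1 positions (the paralogous arm-2 interval is
    implied by the palindrome symmetry).  Too little evidence yields a
    no-call result, not an exception.
    """
    if len(sites) != 2:
        raise ValueError("two-site phasing requires exactly two sites")
    first, second = sorted(sites, key=lambda s: s.arm1_pos)
    by_id = {s.site_id: s for s in (first, second)}

    counts = {("arm1", "arm1"): 0, ("arm2", "arm2"): 0,
              ("arm1", "arm2"): 0, ("arm2", "arm1"): 0}
    for read_id, group in observations.groupby("read_id"):
        calls: dict[str, str] = {}
        ok = True
        for row in group.itertuples(index=False):
            sid = str(row.site_id)
            if sid not in by_id:
                continue
            if sid in calls:
                ok = False  # multiple instances of one site: ambiguous read
                break
            arm = _classify_allele(str(row.allele), by_id[sid])
            if arm is None:
                ok = False
                break
            calls[sid] = arm
        if ok and len(calls) == 2:
            counts[(calls[first.site_id], calls[second.site_id])] += 1

    n11 = counts[("arm1", "arm1")]
    n22 = counts[("arm2", "arm2")]
    n12 = counts[("arm1", "arm2")]
    n21 = counts[("arm2", "arm1")]
    chimeric = n12 + n21
    informative = n11 + n22 + chimeric

    interval = None
    called = False
    confidence = 0.0
    reason = ""
    if informative < min_informative_reads:
        reason = (f"only {informative} informative reads "
                  f"(< {min_informative_reads})")
    elif chimeric == 0:
        reason = "no chimeric reads: both arms phase-pure"
    else:
        dominant = max(n12, n21)
        confidence = dominant / chimeric
        if dominant < min_informative_reads:
            reason = (f"dominant chimeric pattern has {dominant} reads "
                      f"(< {min_informative_reads})")
        elif confidence < confidence_threshold:
            reason = (f"chimeric patterns conflict "
                      f"(confidence {confidence:.2f})")
        else:
            called = True
            interval = (first.arm1_pos, second.arm1_pos)
    return PhasingResult(
        n_arm1_arm1=n11, n_arm2_arm2=n22,
        n_arm1_arm2=n12, n_arm2_arm1=n21,
        breakpoint_interval=interval, confidence=confidence,
        called=called, reason=reason)


def sites_to_table(sites: list[CisMorphismSite]) -> pd.DataFrame:
    rows = [[s.site_id, s.arm1_pos, s.arm2_pos, s.arm1_allele, s.arm2_allele]
            for s in sites]
    return pd.DataFrame(rows, columns=["site_id", "arm1_pos", "arm2_pos",
                                       "arm1_allele", "arm2_allele"])


def sites_from_table(df: pd.DataFrame) -> list[CisMorphismSite]:
    return [CisMorphismSite(str(r.site_id), int(r.arm1_pos), int(r.arm2_pos),
                            str(r.arm1_allele), str(r.arm2_allele))
            for r in df.itertuples(index=False)]
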