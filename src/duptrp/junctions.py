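"""Breakpoint-junction evidence: parsing, clustering and orientation classes.

A structural-variant junction is described by two breakends, each a
(chromosome, position, strand) triple where the strand is the mapping strand
of the supporting read/segment end at the junction.  With breakends ordered
``a <= b`` in genome order, the strand pair determines the junction class:

=============  ==================  ======================================
strand pair    class               typical event
=============  ==================  ======================================
(+, -)         DEL_LIKE            deletion (or any direct-orientation
                                   jump forward)
(-, +)         TANDEM_DUP_LIKE     tandem duplication
(+, +)         INV_HEAD_HEAD       inverted junction joining two segment
                                   heads (5' ends)
(-, -)         INV_TAIL_TAIL       inverted junction joining two segment
                                   tails (3' ends); the hallmark distal
                                   junction of a DUP-TRP/INV-DUP
=============  ==================  ======================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import pandas as pd

from .io import BEDPE_COLUMNS

JCLASSES = ("DEL_LIKE", "TANDEM_DUP_LIKE", "INV_HEAD_HEAD", "INV_TAIL_TAIL",
            "INTERCHROM")

DEFAULT_MAX_CLUSTER_DISTANCE = 500
DEFAULT_MIN_SUPPORT = 3


@dataclass(frozen=True, order=True)
class Breakend:
    """One side of a junction: chromosome, 0-based position, mapping strand."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.pos < 0:
            raise ValueError(f"negative breakend position {self.pos}")


@dataclass(frozen=True)
class JunctionCall:
    """A consolidated junction with ordered breakends and a class label."""

    a: Breakend
    b: Breakend
    support: int = 1
    jclass: str = field(default="")
    name: str = ""

    def __post_init__(self):
        if (self.a.chrom, self.a.pos) > (self.b.chrom, self.b.pos):
            raise ValueError("breakends must be ordered a <= b")
        if not self.jclass:
            object.__setattr__(
                self, "jclass",
                classify_junction(self.a.strand, self.b.strand,
                                  same_chrom=self.a.chrom == self.b.chrom))

    @property
    def strand_pair(self) -> tuple[str, str]:
        return (self.a.strand, self.b.strand)


def classify_junction(strand1: str, strand2: str, same_chrom: bool = True) -> str:
    """Map an ordered strand pair to a junction class.

    Breakends are assumed ordered ``a <= b`` in genome order; breakends on
    different chromosomes are ``INTERCHROM`` regardless of strands.
    """
    if strand1 not in "+-" or strand2 not in "+-":
        raise ValueError(f"invalid strand pair ({strand1!r}, {strand2!r})")
    if not same_chrom:
        return "INTERCHROM"
    return {
        ("+", "+"): "INV_HEAD_HEAD",
        ("-", "-"): "INV_TAIL_TAIL",
        ("+", "-"): "DEL_LIKE",
        ("-", "+"): "TANDEM_DUP_LIKE",
    }[(strand1, strand2)]


def _bedpe_row_to_breakends(row) -> tuple[Breakend, Breakend]:
    a = Breakend(row.chrom1, int(row.start1), row.strand1)
    b = Breakend(row.chrom2, int(row.start2), row.strand2)
    if (a.chrom, a.pos) > (b.chrom, b.pos):
        a, b = b, a
    return a, b


def cluster_junctions(
    bedpe: pd.DataFrame,
    max_cluster_distance: int = DEFAULT_MAX_CLUSTER_DISTANCE,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[JunctionCall]:
    """Consolidate raw BEDPE junction evidence into junction calls.

    Rows sharing a strand pair and chromosome pair whose breakends both lie
    within ``max_cluster_distance`` of a cluster's running median are merged
    into a single call placed at the median positions.  Calls supported by
    fewer than ``min_support`` rows are dropped.  Input order does not matter:
    rows are sorted before clustering, so the result is permutation-invariant.

    Parameters
    ----------
    bedpe:
        A 10-column BEDPE table (see :data:`duptrp.io.BEDPE_COLUMNS`).
    max_cluster_distance:
        Maximum distance of both breakends from the cluster medians, bp.
    min_support:
        Minimum number of supporting rows per reported call.
    """
    if max_cluster_distance < 0:
        raise ValueError("max_cluster_distance must be >= 0")
    pairs = [_bedpe_row_to_breakends(row) for row in bedpe.itertuples(index=False)]
    pairs.sort()
    clusters: list[dict] = []
    for a, b in pairs:
        key = (a.chrom, b.chrom, a.strand, b.strand)
        placed = False
        for cl in clusters:
            if cl["key"] != key:
                continue
            if (abs(a.pos - median(cl["apos"])) <= max_cluster_distance
                    and abs(b.pos - median(cl["bpos"])) <= max_cluster_distance):
                cl["apos"].append(a.pos)
                cl["bpos"].append(b.pos)
                placed = True
                break
        if not placed:
            clusters.append({"key": key, "apos": [a.pos], "bpos": [b.pos]})

    calls = []
    for i, cl in enumerate(clusters):
        support = len(cl["apos"])
        if support < min_support:
            continue
        chrom1, chrom2, s1, s2 = cl["key"]
        a = Breakend(chrom1, int(median(cl["apos"])), s1)
        b = Breakend(chrom2, int(median(cl["bpos"])), s2)
        if (a.chrom, a.pos) > (b.chrom, b.pos):  # medians may reorder
            a, b = b, a
        calls.append(JunctionCall(a=a, b=b, support=support,
                                  name=f"junction_{i}"))
    calls.sort(key=lambda c: (c.a.chrom, c.a.pos, c.b.chrom, c.b.pos))
    return calls


def calls_to_bedpe(calls: list[JunctionCall]) -> pd.DataFrame:
    """Render junction calls back to a 10-column BEDPE table."""
    rows = []
    for c in calls:
        rows.append([
            c.a.chrom, c.a.pos, c.a.pos + 1,
            c.b.chrom, c.b.pos, c.b.pos + 1,
            c.name or c.jclass, c.support, c.a.strand, c.b.strand,
        ])
    return pd.DataFrame(rows, columns=BEDPE_COLUMNS)
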