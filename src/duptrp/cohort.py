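"""Cross-individual interval analytics and population CNV screening.

The minimal region of overlap (MRO) of the triplicated segments across
affected individuals nominates the critical dosage-sensitive gene; size
summaries describe the cohort; and a population screen classifies CNV calls
overlapping the target interval by copy ratio (a constitutional duplication
sits near r = 1.5, a constitutional triplication near r = 2.0).

Printed coordinates (HGVS-style ``g.start-end``) are 1-based inclusive and
are converted to the internal 0-based half-open convention on input and back
on output.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import pandas as pd

DEFAULT_MIN_SIZE = 10_000
DEFAULT_DUP_BAND = (1.15, 1.75)
DEFAULT_TRIP_THRESHOLD = 1.75


@dataclass(frozen=True)
class Interval:
    """A half-open genomic interval, optionally flagged approximate."""

    start: int
    end: int
    approximate: bool = False

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("empty interval")

    def __len__(self):
        return self.end - self.start

    @staticmethod
    def from_one_based(start: int, end: int,
                       approximate: bool = False) -> "Interval":
        """Build from 1-based inclusive printed coordinates."""
        return Interval(start - 1, end, approximate)

    def to_one_based(self) -> tuple[int, int]:
        return self.start + 1, self.end


@dataclass(frozen=True)
class IndividualSV:
    """One individual's duplication and (nested) triplication intervals."""

    individual: str
    dup: Interval | None
    trp: Interval | None
    inheritance: str = "unknown"

    def __post_init__(self):
        if self.inheritance not in ("de_novo", "inherited", "mosaic_parent",
                                    "unknown"):
            raise ValueError(f"unknown inheritance {self.inheritance!r}")
        if self.dup is not None and self.trp is not None:
            if not (self.dup.start <= self.trp.start
                    and self.trp.end <= self.dup.end):
                raise ValueError("triplication must lie within the duplication")


@dataclass(frozen=True)
class ScreenHit:
    sample: str
    interval: Interval
    copy_ratio: float
    cls: str  # DUP | TRIP | AMBIGUOUS


def minimal_region_of_overlap(intervals: list[Interval]) -> Interval | None:
    """Intersection of all intervals; ``None`` if they are disjoint.

    Order-invariant and associative; adding an interval can only shrink the
    result.  The output is flagged approximate if any input is.
    """
    if not intervals:
        raise ValueError("need at least one interval")
    start = max(iv.start for iv in intervals)
    end = min(iv.end for iv in intervals)
    if start >= end:
        return None
    return Interval(start, end,
                    approximate=any(iv.approximate for iv in intervals))


def interval_length_kb(interval: Interval, decimals: int = 1) -> float:
    """Interval length in kb, rounded to ``decimals``.

    Lengths follow the printed 1-based inclusive convention
    (end - start + 1 on printed coordinates, which equals the half-open
    ``end - start`` internally); inclusive and exclusive arithmetic agree at
    the precisions typically printed.
    """
    return round(len(interval) / 1000.0, decimals)


def size_summary(sizes_kb: list[float]) -> dict[str, float]:
    """Exact min / max / median of per-individual sizes."""
    if not sizes_kb:
        raise ValueError("need at least one size")
    return {"min": min(sizes_kb), "max": max(sizes_kb),
            "median": median(sizes_kb)}


def classify_copy_ratio(
    copy_ratio: float,
    dup_band: tuple[float, float] = DEFAULT_DUP_BAND,
    trip_threshold: float = DEFAULT_TRIP_THRESHOLD,
) -> str:
    """DUP if the ratio falls in ``dup_band`` (half-open), TRIP at or above
    ``trip_threshold``, otherwise AMBIGUOUS.  The classes partition the axis:
    every ratio gets exactly one label."""
    if copy_ratio >= trip_threshold:
        return "TRIP"
    if dup_band[0] <= copy_ratio < dup_band[1]:
        return "DUP"
    return "AMBIGUOUS"


def screen_population(
    cnv_table: pd.DataFrame,
    target: Interval,
    min_size: int = DEFAULT_MIN_SIZE,
    dup_band: tuple[float, float] = DEFAULT_DUP_BAND,
    trip_threshold: float = DEFAULT_TRIP_THRESHOLD,
) -> tuple[list[ScreenHit], dict[str, int]]:
    """Screen a population CNV call table against a target interval.

    Keeps calls of length >= ``min_size`` overlapping the target by at least
    one base pair (the overlap criterion is deliberately permissive and
    configurable), classifies each by copy ratio, and returns the hits plus
    per-class counts.

    ``cnv_table`` columns: sample, start, end (0-based half-open),
    copy_ratio.
    """
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    hits = []
    counts = {"DUP": 0, "TRIP": 0, "AMBIGUOUS": 0}
    for i, row in enumerate(cnv_table.itertuples(index=False), start=1):
        try:
            iv = Interval(int(row.start), int(row.end))
            ratio = float(row.copy_ratio)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed CNV row at line {i}: {exc}") from exc
        if len(iv) < min_size:
            continue
        if iv.end <= target.start or iv.start >= target.end:
            continue
        cls = classify_copy_ratio(ratio, dup_band, trip_threshold)
        hits.append(ScreenHit(str(row.sample), iv, ratio, cls))
        counts[cls] += 1
    return hits, counts


def cohort_from_table(df: pd.DataFrame) -> list[IndividualSV]:
    """Parse a cohort TSV with 1-based inclusive dup/trp coordinates.

    Expected columns: individual, dup_start, dup_end, trp_start, trp_end,
    inheritance.  Missing interval coordinates may be left as NA.
    """
    out = []
    for row in df.itertuples(index=False):
        def _iv(a, b):
            if pd.isna(a) or pd.isna(b):
                return None
            return Interval.from_one_based(int(a), int(b))
        out.append(IndividualSV(
            individual=str(row.individual),
            dup=_iv(row.dup_start, row.dup_end),
            trp=_iv(row.trp_start, row.trp_end),
            inheritance=str(getattr(row, "inheritance", "unknown")),
        ))
    return out
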