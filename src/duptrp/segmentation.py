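"""Read-depth copy-number segmentation and mosaic-fraction estimation.

Binned read counts are normalized to a diploid baseline, segmented into
integer total copy-number states 0..6 by a maximum a-posteriori Viterbi path
under per-bin Poisson emissions, and non-integer copy ratios on gained
segments are converted into an estimate of the fraction of cells carrying
the rearranged allele.

The model: a bin overlapping a region of total copy number ``cn`` has
expected count ``cn/2 x diploid_mean`` where ``diploid_mean`` is the mean
count of a diploid bin.  State changes are penalized by a uniform
``transition_penalty`` in log space; ties are broken toward the lower copy
number, so the output is deterministic.

For a mosaic carrier, a fraction ``f`` of cells carries a rearranged
homolog with ``k`` extra copies of the segment (k=1 in a duplication-only
region, k=2 in the triplicated region) on top of the intact homolog, giving
the depth ratio r = 1 + f*k/2 and hence the estimator f = 2(r-1)/k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MAX_CN = 6
DEFAULT_TRANSITION_PENALTY = math.log(1e4)
MIN_SEGMENT_BINS = 3
_ZERO_CN_MEAN = 0.05  # emission mean (in haploid units) used for CN 0 bins

BASELINE_STRATEGIES = ("global_median", "flank_median", "fixed_value")


@dataclass(frozen=True)
class CNSegment:
    """A maximal run of bins assigned one integer total copy number."""

    chrom: str
    start: int
    end: int
    cn: int
    mean_ratio: float
    n_bins: int


@dataclass(frozen=True)
class MosaicEstimate:
    """Estimated fraction of cells carrying the rearranged allele."""

    f: float
    ci_low: float
    ci_high: float
    k: int


def diploid_baseline(
    bins: pd.DataFrame,
    strategy: str = "global_median",
    fixed_value: float | None = None,
    flank_fraction: float = 0.25,
) -> float:
    """Estimate the mean count of a diploid bin.

    ``global_median`` takes the median of all bins (self-normalizing: a
    constitutional gain covering most of the window shifts the baseline);
    ``flank_median`` uses only the first and last ``flank_fraction`` of bins,
    appropriate when the rearrangement sits in the middle of the window;
    ``fixed_value`` uses a caller-supplied diploid mean.
    """
    if strategy not in BASELINE_STRATEGIES:
        raise ValueError(f"unknown baseline strategy {strategy!r}")
    if len(bins) == 0:
        raise ValueError("no bins")
    counts = np.asarray(bins["count"], dtype=float)
    if strategy == "fixed_value":
        if fixed_value is None or fixed_value <= 0:
            raise ValueError("fixed_value baseline requires a positive value")
        return float(fixed_value)
    if strategy == "flank_median":
        k = max(1, int(round(flank_fraction * len(counts))))
        counts = np.concatenate([counts[:k], counts[-k:]])
    baseline = float(np.median(counts))
    if baseline <= 0:
        raise ValueError("estimated diploid baseline is zero")
    return baseline


def normalize_depth(
    bins: pd.DataFrame,
    baseline_strategy: str = "global_median",
    fixed_value: float | None = None,
    flank_fraction: float = 0.25,
) -> np.ndarray:
    """Per-bin copy ratio r = count / diploid baseline (r=1 is diploid)."""
    baseline = diploid_baseline(bins, baseline_strategy, fixed_value,
                                flank_fraction)
    return np.asarray(bins["count"], dtype=float) / baseline


def _emission_loglik(counts: np.ndarray, diploid_mean: float,
                     states: np.ndarray) -> np.ndarray:
    """Poisson log-likelihood of each bin count under each CN state.

    Constant terms (log k!) are dropped; they cancel across states.
    """
    mu = np.maximum(states, _ZERO_CN_MEAN) / 2.0 * diploid_mean
    # shape (n_bins, n_states)
    return counts[:, None] * np.log(mu)[None, :] - mu[None, :]


def viterbi_path(
    counts: np.ndarray,
    diploid_mean: float,
    states: np.ndarray | None = None,
    transition_penalty: float = DEFAULT_TRANSITION_PENALTY,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """MAP integer-CN state per bin under Poisson emissions.

    Ties are broken toward the lower copy-number state at every step, making
    the path unique and deterministic.  Masked bins contribute no emission
    term (their state is interpolated by the transition structure alone).
    """
    if transition_penalty <= 0:
        raise ValueError("transition_penalty must be > 0")
    if states is None:
        states = np.arange(MAX_CN + 1)
    states = np.asarray(states)
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    if n == 0:
        raise ValueError("empty input")
    emis = _emission_loglik(counts, diploid_mean, states)
    if mask is not None:
        emis[np.asarray(mask, dtype=bool)] = 0.0

    n_states = len(states)
    score = emis[0].copy()
    back = np.zeros((n, n_states), dtype=np.int64)
    for i in range(1, n):
        # best previous state for each current state, lower-CN tie-break
        stay = score
        jump = score.max() - transition_penalty
        jump_from = int(np.argmax(score))  # argmax takes lowest index on ties
        prev_best = np.where(stay >= jump, stay, jump)
        back[i] = np.where(stay >= jump, np.arange(n_states), jump_from)
        score = emis[i] + prev_best
    path = np.zeros(n, dtype=np.int64)
    path[-1] = int(np.argmax(score))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return states[path]


def _runs(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (start_idx, end_idx_exclusive, value)."""
    runs = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            runs.append((start, i, int(values[start])))
            start = i
    return runs


def segment_cn(
    bins: pd.DataFrame,
    diploid_mean: float,
    transition_penalty: float = DEFAULT_TRANSITION_PENALTY,
    states: np.ndarray | None = None,
    min_segment_bins: int = MIN_SEGMENT_BINS,
    mask: np.ndarray | None = None,
) -> list[CNSegment]:
    """Segment binned depth into integer total-copy-number segments.

    Runs of identical Viterbi states are merged into segments; segments
    shorter than ``min_segment_bins`` are absorbed into the neighbor whose
    mean copy ratio is closer, suppressing single-bin flickers such as the
    mapping-quality patchiness seen over repeats.

    Parameters
    ----------
    bins:
        Depth table with columns chrom/start/end/count, sorted,
        non-overlapping, single chromosome.
    diploid_mean:
        Expected count of a diploid bin (see :func:`diploid_baseline`).
    """
    if len(bins) == 0:
        raise ValueError("empty input")
    counts = np.asarray(bins["count"], dtype=float)
    path = viterbi_path(counts, diploid_mean, states, transition_penalty, mask)
    runs = _runs(path)

    # absorb short runs into the neighbor with the closer mean ratio
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for idx, (s, e, cn) in enumerate(runs):
            if e - s >= min_segment_bins:
                continue
            ratio = counts[s:e].mean() / diploid_mean
            left = runs[idx - 1] if idx > 0 else None
            right = runs[idx + 1] if idx + 1 < len(runs) else None

            def _dist(run):
                rs, re, _ = run
                return abs(counts[rs:re].mean() / diploid_mean - ratio)

            target = None
            if left is not None and right is not None:
                target = left if _dist(left) <= _dist(right) else right
            else:
                target = left or right
            if target is None:
                break
            merged_cn = target[2]
            runs[idx] = (s, e, merged_cn)
            # re-merge adjacent equal-cn runs
            merged: list[tuple[int, int, int]] = []
            for run in runs:
                if merged and merged[-1][2] == run[2] and merged[-1][1] == run[0]:
                    merged[-1] = (merged[-1][0], run[1], run[2])
                else:
                    merged.append(run)
            runs = merged
            changed = True
            break

    chrom = str(bins["chrom"].iloc[0])
    starts = np.asarray(bins["start"])
    ends = np.asarray(bins["end"])
    segments = []
    for s, e, cn in runs:
        segments.append(CNSegment(
            chrom=chrom,
            start=int(starts[s]),
            end=int(ends[e - 1]),
            cn=cn,
            mean_ratio=float(counts[s:e].mean() / diploid_mean),
            n_bins=e - s,
        ))
    return segments


def segments_to_bed(segments: list[CNSegment]) -> pd.DataFrame:
    rows = [[s.chrom, s.start, s.end, f"CN{s.cn}", s.cn,
             round(s.mean_ratio, 4), s.n_bins] for s in segments]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "cn", "mean_ratio", "n_bins"])


def estimate_mosaic_fraction(
    mean_ratio: float,
    k: int,
    n_bins: int,
    diploid_mean: float,
    z: float = 1.96,
) -> MosaicEstimate:
    """Estimate the mosaic fraction from a gained segment's depth ratio.

    ``f = 2(r - 1)/k`` where r is the segment's mean copy ratio and k the
    extra allele multiplicity on the rearranged homolog (1 for the
    duplication-only shoulders, 2 for the triplicated core).  The confidence
    interval propagates the Poisson standard error of the segment mean:
    SE(r) = sqrt(r / (n_bins * diploid_mean)).  A constitutional carrier
    (r = 1 + k/2) returns f = 1.

    Ratios below 1 (no gain) are clipped to f = 0 with a warning.
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 (dup-only segment) or 2 (trp segment)")
    if n_bins < 1 or diploid_mean <= 0:
        raise ValueError("n_bins and diploid_mean must be positive")
    r = float(mean_ratio)
    if r < 1.0:
        warnings.warn("segment ratio < 1: not a gain; clipping f to 0")
    f = 2.0 * (r - 1.0) / k
    se_r = math.sqrt(max(r, 1e-12) / (n_bins * diploid_mean))
    se_f = 2.0 * se_r / k
    lo = min(max(f - z * se_f, 0.0), 1.0)
    hi = min(max(f + z * se_f, 0.0), 1.0)
    f = min(max(f, 0.0), 1.0)
    return MosaicEstimate(f=f, ci_low=lo, ci_high=hi, k=k)
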