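"""Migration-time bins: the scoreable marker characters.

Replicate runs of the same material place the same protein at slightly
different migration times (technical jitter, on the order of 0.14 s after
alignment). Clustering replicate apex times and taking their spread yields a
migration-time interval — a *bin* — that is treated as one presence/absence
character ("marker") across all samples, exactly as AFLP fragments are
binned by size. Per-sample or per-group bin sets are then overlapped and
merged into one reference set, and any peak falling inside a bin scores that
marker present.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .trace import PeakCall

logger = logging.getLogger(__name__)

DEFAULT_K_SD = 3.0
DEFAULT_MIN_HALF_WIDTH_S = 0.15
DEFAULT_GAP_S = 0.5
DEFAULT_MIN_SUPPORT = 2
#: bins wider than the single-linkage gap would contradict the clustering
#: that produced them, so half-widths are capped at the gap by default
DEFAULT_MAX_HALF_WIDTH_S = 0.5


@dataclass(frozen=True)
class MarkerBin:
    """One marker: a closed migration-time interval [lo, hi].

    ``center`` is the (support-weighted) mean replicate time and names the
    bin; after merging, the interval is the union span of the merged members
    and need not be symmetric about the center. ``sd`` is the replicate
    standard deviation the width was derived from; ``support`` counts the
    replicate runs contributing.
    """

    label: str
    center: float
    lo: float
    hi: float
    sd: float
    support: int

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValidationError(f"bin {self.label}: empty interval [{self.lo}, {self.hi}]")

    @property
    def half_width(self) -> float:
        return (self.hi - self.lo) / 2.0

    def contains(self, time: float) -> bool:
        return self.lo <= time <= self.hi


def _make_label(center: float) -> str:
    return f"P{center:.1f}"


def _assign_labels(bins: list[dict]) -> list[MarkerBin]:
    """Label bins "P"+center rounded to 0.1 s; collisions get "a","b",... suffixes."""
    out: list[MarkerBin] = []
    seen: dict[str, int] = {}
    for b in bins:
        base = _make_label(b["center"])
        n = seen.get(base, 0)
        seen[base] = n + 1
        label = base if n == 0 else base + "abcdefghijklmnopqrstuvwxyz"[n - 1]
        out.append(MarkerBin(label=label, **b))
    return out


@dataclass(frozen=True)
class BinSet:
    """Ordered collection of marker bins (sorted by center, unique labels)."""

    bins: tuple

    def __post_init__(self) -> None:
        bins = tuple(sorted(self.bins, key=lambda b: b.center))
        object.__setattr__(self, "bins", bins)
        labels = [b.label for b in bins]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate bin labels in BinSet")

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bins]

    def find(self, time: float) -> MarkerBin | None:
        """Bin containing `time`; ties among overlapping bins go to the nearest center."""
        hits = [b for b in self.bins if b.contains(time)]
        if not hits:
            return None
        return min(hits, key=lambda b: abs(b.center - time))


# ---------------------------------------------------------------------------
# replicate-time clustering


def _peak_time(p) -> float:
    return p.time if isinstance(p, PeakCall) else float(p)


def _split_replicate_conflicts(cluster: list[tuple[int, float]]) -> list[list[tuple[int, float]]]:
    """Enforce <=1 peak per replicate per cluster by splitting at the largest
    internal gap (recursively)."""
    reps = [r for r, _ in cluster]
    if len(set(reps)) == len(reps) or len(cluster) < 2:
        return [cluster]
    times = np.array([t for _, t in cluster])
    gaps = np.diff(times)
    if gaps.max() > 0:
        cut = int(np.argmax(gaps)) + 1
    else:
        # coincident times from one replicate; split off the first duplicate
        seen = set()
        cut = 1
        for i, r in enumerate(reps):
            if r in seen:
                cut = i
                break
            seen.add(r)
        cut = max(cut, 1)
    left, right = cluster[:cut], cluster[cut:]
    return _split_replicate_conflicts(left) + _split_replicate_conflicts(right)


def cluster_replicate_peaks(
    replicate_peak_lists: list[list],
    gap: float = DEFAULT_GAP_S,
) -> list[list[tuple[int, float]]]:
    """Single-linkage clustering of aligned apex times across replicates.

    Peaks from all replicates are pooled and chained wherever consecutive
    sorted times differ by <= ``gap``. A cluster may hold at most one peak
    per replicate — two peaks of the same run cannot be the same protein —
    so violating clusters are split at their largest internal gap. Clusters
    are returned ordered by mean time as lists of ``(replicate_index, time)``.
    """
    pooled = [
        (rep_idx, _peak_time(p))
        for rep_idx, peaks in enumerate(replicate_peak_lists)
        for p in peaks
    ]
    pooled.sort(key=lambda rt: rt[1])
    clusters: list[list[tuple[int, float]]] = []
    for item in pooled:
        if clusters and item[1] - clusters[-1][-1][1] <= gap:
            clusters[-1].append(item)
        else:
            clusters.append([item])
    split = [c for cluster in clusters for c in _split_replicate_conflicts(cluster)]
    split.sort(key=lambda c: float(np.mean([t for _, t in c])))
    return split


def build_bins(
    clusters: list[list[tuple[int, float]]],
    k_sd: float = DEFAULT_K_SD,
    min_half_width: float = DEFAULT_MIN_HALF_WIDTH_S,
    min_support: int = DEFAULT_MIN_SUPPORT,
    max_half_width: float | None = DEFAULT_MAX_HALF_WIDTH_S,
) -> BinSet:
    """Turn replicate-time clusters into marker bins.

    Each cluster with support >= ``min_support`` becomes a bin centered on
    the mean time with half-width ``max(k_sd * sd, min_half_width)``, where
    sd is the sample standard deviation of the member times (k_sd = 3 covers
    ~99.7% of Gaussian jitter; the floor guards degenerate spreads, and the
    ``max_half_width`` cap guards the opposite failure — a noisy SD estimate
    from few replicates inflating one bin until it swallows its neighbours).
    Under-supported clusters are discarded with a warning.
    """
    raw = []
    for cluster in clusters:
        times = np.array([t for _, t in cluster])
        if times.size < min_support:
            logger.warning(
                "discarding cluster at %.2f s with support %d < %d",
                times.mean(), times.size, min_support,
            )
            continue
        sd = float(times.std(ddof=1)) if times.size > 1 else 0.0
        center = float(times.mean())
        hw = max(k_sd * sd, min_half_width)
        if max_half_width is not None:
            hw = min(hw, max_half_width)
        raw.append(
            dict(center=center, lo=center - hw, hi=center + hw, sd=sd, support=times.size)
        )
    raw.sort(key=lambda b: b["center"])
    return BinSet(bins=tuple(_assign_labels(raw)))


def merge_bin_sets(bin_sets: list[BinSet]) -> BinSet:
    """Overlap and merge bin sets into one non-overlapping reference set.

    Overlapping or touching intervals are merged transitively; a merged bin
    spans the union of its members, is centered at their support-weighted
    mean center, pools the supports, and carries the support-weighted RMS of
    the member sds. Labels are regenerated from the merged centers. Merging
    is idempotent and independent of input order.
    """
    every = sorted(
        (b for bs in bin_sets for b in bs), key=lambda b: (b.lo, b.hi, b.center)
    )
    merged: list[list[MarkerBin]] = []
    for b in every:
        if merged and b.lo <= max(m.hi for m in merged[-1]):
            merged[-1].append(b)
        else:
            merged.append([b])
    raw = []
    for group in merged:
        support = sum(m.support for m in group)
        w = np.array([m.support for m in group], dtype=float)
        if w.sum() == 0:
            w = np.ones(len(group))
        centers = np.array([m.center for m in group])
        sds = np.array([m.sd for m in group])
        raw.append(
            dict(
                center=float(np.average(centers, weights=w)),
                lo=min(m.lo for m in group),
                hi=max(m.hi for m in group),
                sd=float(math.sqrt(np.average(sds**2, weights=w))),
                support=support,
            )
        )
    raw.sort(key=lambda b: b["center"])
    return BinSet(bins=tuple(_assign_labels(raw)))


def score_profile(
    peaks: list[PeakCall], bins: BinSet
) -> tuple[dict[str, int], list[PeakCall]]:
    """Score aligned, range-restricted peaks against a bin set.

    A marker is present (1) iff at least one peak time lies in its interval;
    a peak covered by several (pre-merge) bins goes to the nearest center.
    Peaks in no bin are returned as ``unassigned`` — candidates for a
    confirmed re-run and bin extension.
    """
    row = {label: 0 for label in bins.labels}
    unassigned: list[PeakCall] = []
    for p in peaks:
        hit = bins.find(p.time)
        if hit is None:
            unassigned.append(p)
        else:
            row[hit.label] = 1
    return row, unassigned


def extend_bins(
    bins: BinSet,
    confirmed_peak: PeakCall,
    min_half_width: float = DEFAULT_MIN_HALF_WIDTH_S,
) -> BinSet:
    """Add a bin for a peak confirmed (by re-running the sample) to fall
    outside every existing bin, then re-merge.

    The caller is responsible for the confirmation step; a peak already
    inside a bin is a no-op with a warning.
    """
    if bins.find(confirmed_peak.time) is not None:
        logger.warning(
            "peak at %.2f s already falls in bin %s; bin set unchanged",
            confirmed_peak.time, bins.find(confirmed_peak.time).label,
        )
        return bins
    t = confirmed_peak.time
    new = MarkerBin(
        label=_make_label(t) + "_new",
        center=t,
        lo=t - min_half_width,
        hi=t + min_half_width,
        sd=0.0,
        support=1,
    )
    return merge_bin_sets([bins, BinSet(bins=(new,))])
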