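"""Electropherogram traces: alignment, peak detection and sizing.

An on-chip electrophoresis run yields a *trace* — fluorescence intensity (FU)
against migration time (s). Every sample is co-loaded with two internal
standards of known mass (by default a 1.6 kDa "lower" and a 95 kDa "upper"
marker). Their apexes anchor a two-point affine time alignment between runs
and, together with a ladder, a log-linear size calibration in kDa.

The scoreable region of a trace lies strictly between the two standards:
peaks migrating past the upper standard (i.e. above 95 kDa) and the
standards' own peaks are never scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .exceptions import (
    CalibrationError,
    DegenerateStandardsError,
    StandardsNotFoundError,
    ValidationError,
)

#: Fluorescence threshold below which peaks are not scored.
DEFAULT_MIN_HEIGHT_FU = 20.0
#: Default prominence floor, suppressing baseline ripple.
DEFAULT_MIN_PROMINENCE_FU = 5.0
#: Default minimum apex separation; the taller apex wins a conflict.
DEFAULT_MIN_SEPARATION_S = 0.2

LOWER_STANDARD_KDA = 1.6
UPPER_STANDARD_KDA = 95.0


@dataclass(frozen=True)
class StandardPair:
    """Apex times of the two internal standards on one trace."""

    lower_time: float
    upper_time: float
    lower_mass: float = LOWER_STANDARD_KDA
    upper_mass: float = UPPER_STANDARD_KDA

    def __post_init__(self) -> None:
        if not self.lower_time < self.upper_time:
            raise ValidationError(
                f"lower standard at {self.lower_time} s must precede upper at "
                f"{self.upper_time} s"
            )


@dataclass
class Trace:
    """One electropherogram: strictly increasing times, finite fluorescence."""

    sample_id: str
    times: np.ndarray
    fluorescence: np.ndarray
    metadata: dict = field(default_factory=dict)
    standards: StandardPair | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.shape != self.fluorescence.shape or self.times.ndim != 1:
            raise ValidationError("times and fluorescence must be equal-length 1-D arrays")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("trace times must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValidationError("fluorescence contains non-finite values")

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass
class PeakCall:
    """A detected peak apex, on the aligned time scale.

    ``flags`` may contain ``"out_of_range"`` (outside the scoreable window)
    and ``"extrapolated_mass"`` (sized outside the ladder span).
    """

    time: float
    height: float
    prominence: float
    mass: float | None = None
    flags: set = field(default_factory=set)


@dataclass(frozen=True)
class LadderTable:
    """Calibration points (migration time s, mass kDa), both strictly increasing."""

    points: tuple

    def __post_init__(self) -> None:
        pts = tuple((float(t), float(m)) for t, m in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 2:
            raise CalibrationError("ladder needs at least 2 points")
        times = np.array([p[0] for p in pts])
        masses = np.array([p[1] for p in pts])
        if not (np.all(np.diff(times) > 0) and np.all(np.diff(masses) > 0)):
            raise CalibrationError("ladder times and masses must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def masses(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


def default_windows(trace: Trace, fraction: float = 0.25) -> tuple[tuple[float, float], tuple[float, float]]:
    """Default standard-search windows: first and last `fraction` of the span."""
    lo, hi = trace.span
    w = (hi - lo) * fraction
    return (lo, lo + w), (hi - w, hi)


def _tallest_apex_in_window(
    trace: Trace, window: tuple[float, float], min_height: float
) -> float | None:
    lo, hi = window
    mask = (trace.times >= lo) & (trace.times <= hi)
    if mask.sum() < 3:
        return None
    f = trace.fluorescence[mask]
    t = trace.times[mask]
    idx, _ = find_peaks(f, height=min_height)
    if idx.size == 0:
        return None
    best = idx[np.argmax(f[idx])]
    return float(t[best])


def locate_internal_standards(
    trace: Trace,
    lower_window: tuple[float, float] | None = None,
    upper_window: tuple[float, float] | None = None,
    min_height: float = DEFAULT_MIN_HEIGHT_FU,
) -> StandardPair:
    """Find the lower/upper internal-standard apexes as the tallest local
    maximum in each search window.

    Raises :class:`StandardsNotFoundError` when a window holds no local
    maximum above ``min_height`` — the chip run must be repeated, mirroring
    the manual check done in the vendor software.
    """
    if lower_window is None or upper_window is None:
        default_lo, default_hi = default_windows(trace)
        lower_window = lower_window or default_lo
        upper_window = upper_window or default_hi
    if lower_window[1] > upper_window[0]:
        raise ValidationError("standard search windows must be disjoint and ordered")
    lower = _tallest_apex_in_window(trace, lower_window, min_height)
    upper = _tallest_apex_in_window(trace, upper_window, min_height)
    if lower is None or upper is None:
        which = "lower" if lower is None else "upper"
        raise StandardsNotFoundError(
            f"{trace.sample_id}: no {which} internal standard above "
            f"{min_height} FU in its window"
        )
    return StandardPair(lower_time=lower, upper_time=upper)


def align_to_reference(trace: Trace, own: StandardPair, reference: StandardPair) -> Trace:
    """Affinely map a trace's time axis so its standards land on the reference's.

    The map is ``t' = a*t + b`` with ``a`` the ratio of standard spacings and
    ``b`` fixing the lower standard; fluorescence is untouched. Aligning a
    trace already on the reference scale is the identity.
    """
    own_span = own.upper_time - own.lower_time
    if own_span == 0:
        raise DegenerateStandardsError(f"{trace.sample_id}: coincident internal standards")
    a = (reference.upper_time - reference.lower_time) / own_span
    b = reference.lower_time - a * own.lower_time
    new_times = a * trace.times + b
    aligned_standards = StandardPair(
        lower_time=a * own.lower_time + b,
        upper_time=a * own.upper_time + b,
        lower_mass=own.lower_mass,
        upper_mass=own.upper_mass,
    )
    return replace(trace, times=new_times, standards=aligned_standards)


def detect_peaks(
    trace: Trace,
    min_height: float = DEFAULT_MIN_HEIGHT_FU,
    min_prominence: float = DEFAULT_MIN_PROMINENCE_FU,
    min_separation: float = DEFAULT_MIN_SEPARATION_S,
) -> list[PeakCall]:
    """Detect peak apexes above the fluorescence threshold.

    An apex is a local maximum with height >= ``min_height`` and prominence
    >= ``min_prominence``; apexes closer than ``min_separation`` are thinned
    greedily, tallest first (ties broken by earlier time). Returned sorted by
    time. The apex time is the time of the maximal sample — no sub-sample
    refinement, which is far finer than any bin width.
    """
    idx, props = find_peaks(
        trace.fluorescence, height=min_height, prominence=min_prominence
    )
    if idx.size == 0:
        return []
    times = trace.times[idx]
    heights = props["peak_heights"]
    proms = props["prominences"]
    # greedy non-maximum suppression on the time axis
    order = np.lexsort((times, -heights))
    kept: list[int] = []
    for j in order:
        if all(abs(times[j] - times[k]) >= min_separation for k in kept):
            kept.append(j)
    kept.sort(key=lambda j: times[j])
    return [
        PeakCall(time=float(times[j]), height=float(heights[j]), prominence=float(proms[j]))
        for j in kept
    ]


def restrict_to_scoreable_range(
    peaks: list[PeakCall],
    standards: StandardPair,
    margin: float = DEFAULT_MIN_SEPARATION_S,
) -> list[PeakCall]:
    """Keep only peaks inside the scoreable window between the standards.

    The window is the half-open interval ``[lower_time + margin, upper_time)``:
    the closed upper cut drops everything at or past the upper standard
    (masses above 95 kDa are not scored) and the margin excludes the lower
    standard's own flank. Excluded peaks are flagged ``out_of_range``.
    """
    kept = []
    for p in peaks:
        if standards.lower_time + margin <= p.time < standards.upper_time:
            kept.append(p)
        else:
            p.flags.add("out_of_range")
    return kept


def size_peak(ladder: LadderTable, time: float) -> tuple[float, bool]:
    """Size a migration time in kDa against the ladder.

    log10(mass) is interpolated linearly in time between bracketing ladder
    points — the standard calibration form for gel/chip migration. Outside
    the ladder span the nearest segment is extended linearly and the result
    is flagged (second return value True).
    """
    t = ladder.times
    logm = np.log10(ladder.masses)
    if t[0] <= time <= t[-1]:
        return float(10 ** np.interp(time, t, logm)), False
    if time < t[0]:
        seg = (0, 1)
    else:
        seg = (-2, -1)
    slope = (logm[seg[1]] - logm[seg[0]]) / (t[seg[1]] - t[seg[0]])
    val = logm[seg[0]] + slope * (time - t[seg[0]])
    return float(10**val), True


def assign_masses(peaks: list[PeakCall], ladder: LadderTable) -> list[PeakCall]:
    """Annotate each peak in place with its ladder-interpolated mass."""
    for p in peaks:
        mass, extrapolated = size_peak(ladder, p.time)
        p.mass = mass
        if extrapolated:
            p.flags.add("extrapolated_mass")
    return peaks
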