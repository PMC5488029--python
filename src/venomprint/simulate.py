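"""Ground-truth-annotated synthetic electropherogram datasets.

No raw chip data accompany the protocol, so every pipeline stage is
exercised on simulated traces that carry the same statistical structure the
method assumes: group-structured marker presence probabilities, Gaussian
peaks at marker-specific migration times, per-run Gaussian migration jitter
(default SD 0.14 s, the magnitude observed on real duplicates), per-run
affine injection warps that the two internal standards correct, lognormal
peak heights over a 20 FU detection threshold, baseline noise, replicate
dropout and spurious peaks.

Biological presence is drawn once per *individual* and shared by its
replicates, so duplicate discordance measures technical scoring error only
— the quantity the QC stage estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinSet
from .exceptions import ValidationError
from .matrix import BinaryMatrix
from .trace import LadderTable, StandardPair, Trace

logger = __import__("logging").getLogger(__name__)


@dataclass(frozen=True)
class GroupSpec:
    """One simulated population: its size and per-marker presence probabilities."""

    name: str
    n_individuals: int
    presence_probs: tuple

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.presence_probs)
        object.__setattr__(self, "presence_probs", probs)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError(f"group {self.name}: probabilities outside [0, 1]")


def _default_ladder(lower_time: float, upper_time: float) -> LadderTable:
    """Ladder linear in log10(mass) between the two system peaks."""
    masses = np.array([1.6, 3.5, 6.5, 15.0, 28.0, 46.0, 63.0, 95.0])
    logm = np.log10(masses)
    times = lower_time + (upper_time - lower_time) * (logm - logm[0]) / (
        logm[-1] - logm[0]
    )
    return LadderTable(points=tuple(zip(times, masses)))


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic dataset.

    Defaults mirror the measured properties of real runs: 0.14 s replicate
    jitter, small affine injection warps (slope SD 1%, offset SD 0.5 s)
    corrected by the 1.6/95 kDa standards, lognormal heights with median
    100 FU, 0.08 s Gaussian peak shapes, 1 FU baseline noise, 2% per-peak
    replicate dropout and 0.3 expected spurious peaks per trace.
    """

    groups: tuple
    true_marker_times: tuple
    jitter_sd: float = 0.14
    warp_slope_sd: float = 0.01
    warp_offset_sd: float = 0.5
    height_log_mean: float = float(np.log(100.0))
    height_log_sd: float = 0.5
    #: detector saturation ceiling for sample peaks; keeps them below the
    #: system peaks, as on the real instrument
    height_max: float = 500.0
    peak_shape_sd: float = 0.08
    baseline_noise_sd: float = 1.0
    detection_floor: float = 25.0
    dropout_prob: float = 0.02
    spurious_rate: float = 0.3
    n_replicates: int = 2
    #: individuals run in replicate (allocated proportionally across groups);
    #: None = all. The remaining individuals get a single run, as in a survey
    #: where only a QC subset is duplicated.
    n_duplicated_individuals: int | None = None
    lower_time: float = 15.0
    upper_time: float = 45.0
    standard_height: float = 600.0
    sampling_step: float = 0.02
    seed: int = 0
    ladder: LadderTable | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(
            self, "true_marker_times", tuple(float(t) for t in self.true_marker_times)
        )
        n_markers = len(self.true_marker_times)
        for g in self.groups:
            if len(g.presence_probs) != n_markers:
                raise ValidationError(
                    f"group {g.name}: {len(g.presence_probs)} probabilities for "
                    f"{n_markers} markers"
                )
        times = np.array(self.true_marker_times)
        if times.size and not (
            (times > self.lower_time).all() and (times < self.upper_time).all()
        ):
            raise ValidationError("true marker times must lie between the standards")
        if times.size > 1 and np.diff(np.sort(times)).min() < 2 * self.jitter_sd:
            logger.warning(
                "some true marker times are closer than 2 x jitter_sd; "
                "adjacent markers may be confounded"
            )
        if self.ladder is None:
            object.__setattr__(
                self, "ladder", _default_ladder(self.lower_time, self.upper_time)
            )

    @property
    def n_markers(self) -> int:
        return len(self.true_marker_times)

    @property
    def reference_standards(self) -> StandardPair:
        return StandardPair(lower_time=self.lower_time, upper_time=self.upper_time)

    def marker_gaps(self) -> np.ndarray:
        """Pairwise gaps between adjacent true times — recorded for test design."""
        return np.diff(np.sort(np.array(self.true_marker_times)))


@dataclass
class SimulatedDataset:
    """Traces plus manifest plus the generating truth."""

    traces: list[Trace]
    manifest: pd.DataFrame  # sample_id, individual_id, replicate_id, group
    ladder: LadderTable
    truth_matrix: BinaryMatrix  # individuals x true markers
    true_intervals: list[tuple[float, float]]  # scoring interval per true marker
    peak_identities: dict[str, list[tuple[int, float]]]  # sample -> (marker idx, apex)
    config: SimConfig


def _true_marker_labels(config: SimConfig) -> list[str]:
    labels = []
    for i, t in enumerate(config.true_marker_times):
        labels.append(f"T{t:.1f}" if f"T{t:.1f}" not in labels else f"T{t:.1f}_{i}")
    return labels


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Draw a complete synthetic dataset, deterministically from the seed.

    Per individual: presence of each marker is one Bernoulli draw from its
    group's probabilities. Per replicate run: an affine warp (slope ~
    N(1, warp_slope_sd), offset ~ N(0, warp_offset_sd)) is applied to all
    true times *including the standards*; each present, non-dropped peak
    appears at warped(true time + jitter) with a lognormal height clipped at
    the detection floor; spurious low peaks (Poisson count, uniform times,
    20-40 FU) and Gaussian baseline noise are added.
    """
    rng = np.random.default_rng(config.seed)
    times = np.array(config.true_marker_times)
    labels = _true_marker_labels(config)

    manifest_rows = []
    traces: list[Trace] = []
    truth_rows: dict[str, dict[str, int]] = {}
    identities: dict[str, list[tuple[int, float]]] = {}

    total = sum(g.n_individuals for g in config.groups)
    for group in config.groups:
        probs = np.array(group.presence_probs)
        if config.n_duplicated_individuals is None:
            n_dup = group.n_individuals
        else:
            n_dup = round(config.n_duplicated_individuals * group.n_individuals / total)
        for i in range(group.n_individuals):
            individual = f"{group.name}_{i + 1:03d}"
            present = rng.random(config.n_markers) < probs
            truth_rows[individual] = {
                lab: int(p) for lab, p in zip(labels, present)
            }
            n_reps = config.n_replicates if i < n_dup else 1
            for rep in range(1, n_reps + 1):
                sample_id = f"{individual}_r{rep}"
                trace, ids = _simulate_trace(sample_id, present, config, rng)
                traces.append(trace)
                identities[sample_id] = ids
                manifest_rows.append(
                    dict(
                        sample_id=sample_id,
                        individual_id=individual,
                        replicate_id=rep,
                        group=group.name,
                    )
                )

    half = max(3 * config.jitter_sd, 0.15)
    intervals = [(t - half, t + half) for t in times]
    truth = BinaryMatrix.from_rows(truth_rows, marker_labels=labels)
    return SimulatedDataset(
        traces=traces,
        manifest=pd.DataFrame(manifest_rows),
        ladder=config.ladder,
        truth_matrix=truth,
        true_intervals=intervals,
        peak_identities=identities,
        config=config,
    )


def _simulate_trace(
    sample_id: str,
    present: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[Trace, list[tuple[int, float]]]:
    slope = rng.normal(1.0, config.warp_slope_sd)
    offset = rng.normal(0.0, config.warp_offset_sd)
    warp = lambda t: slope * t + offset  # noqa: E731

    span = config.upper_time - config.lower_time
    t0 = warp(config.lower_time - 0.12 * span)
    t1 = warp(config.upper_time + 0.12 * span)
    grid = np.arange(t0, t1, config.sampling_step)
    signal = np.zeros_like(grid)

    def add_peak(apex: float, height: float) -> None:
        sd = config.peak_shape_sd
        nearby = np.abs(grid - apex) < 6 * sd
        signal[nearby] += height * np.exp(
            -0.5 * ((grid[nearby] - apex) / sd) ** 2
        )

    # internal standards, warped like everything else
    add_peak(warp(config.lower_time), config.standard_height)
    add_peak(warp(config.upper_time), config.standard_height)

    identities: list[tuple[int, float]] = []
    for m, t_true in enumerate(config.true_marker_times):
        if not present[m]:
            continue
        if rng.random() < config.dropout_prob:
            continue
        apex = warp(t_true + rng.normal(0.0, config.jitter_sd))
        height = float(
            np.clip(
                rng.lognormal(config.height_log_mean, config.height_log_sd),
                config.detection_floor,
                config.height_max,
            )
        )
        add_peak(apex, height)
        identities.append((m, apex))

    n_spurious = rng.poisson(config.spurious_rate)
    for _ in range(n_spurious):
        apex = warp(rng.uniform(config.lower_time + 1.0, config.upper_time - 1.0))
        add_peak(apex, rng.uniform(20.0, 40.0))

    if config.baseline_noise_sd > 0:
        signal = signal + rng.normal(0.0, config.baseline_noise_sd, size=grid.size)

    trace = Trace(sample_id=sample_id, times=grid, fluorescence=signal)
    return trace, identities


# ---------------------------------------------------------------------------
# truth comparison


@dataclass
class ConfusionReport:
    """Cell-level agreement between a scored matrix and the simulator truth."""

    per_marker: pd.DataFrame  # TP/FP/FN/TN, sensitivity, specificity per true marker
    tp: int
    fp: int
    fn: int
    tn: int
    unmapped_markers: list[str]  # scored markers overlapping no true interval

    @property
    def fn_rate(self) -> float:
        return self.fn / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fp_rate(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0


def map_scored_to_true(
    scored_bins: BinSet, true_intervals: list[tuple[float, float]]
) -> tuple[dict[str, int], list[str]]:
    """Map each scored bin to the true marker whose interval overlaps it most.

    Bins overlapping no true interval are unmappable — spurious-peak bins —
    and are reported as false-positive sources.
    """
    mapping: dict[str, int] = {}
    unmapped: list[str] = []
    for b in scored_bins:
        overlaps = []
        for m, (lo, hi) in enumerate(true_intervals):
            ov = min(b.hi, hi) - max(b.lo, lo)
            if ov > 0:
                overlaps.append((ov, -abs(b.center - (lo + hi) / 2), m))
        if overlaps:
            mapping[b.label] = max(overlaps)[2]
        else:
            unmapped.append(b.label)
    return mapping, unmapped


def evaluate_against_truth(
    scored: BinaryMatrix,
    truth: BinaryMatrix,
    scored_bins: BinSet,
    true_intervals: list[tuple[float, float]],
) -> ConfusionReport:
    """Confusion counts of a scored matrix against the simulator's truth.

    Scored markers are first mapped to true markers by interval overlap;
    several scored bins mapping to one true marker are OR-combined. Presence
    in an unmappable marker counts as a false positive.
    """
    if set(scored.individual_ids) != set(truth.individual_ids):
        raise ValidationError("scored and truth matrices cover different individuals")
    mapping, unmapped = map_scored_to_true(scored_bins, true_intervals)
    order = truth.individual_ids
    scored_df = scored.data.loc[order]
    truth_df = truth.data.loc[order]

    rows = []
    tp = fp = fn = tn = 0
    for m, true_label in enumerate(truth.marker_labels):
        cols = [lab for lab, idx in mapping.items() if idx == m and lab in scored_df]
        pred = (
            scored_df[cols].max(axis=1)
            if cols
            else pd.Series(0, index=scored_df.index, dtype="int8")
        )
        actual = truth_df[true_label]
        m_tp = int(((pred == 1) & (actual == 1)).sum())
        m_fp = int(((pred == 1) & (actual == 0)).sum())
        m_fn = int(((pred == 0) & (actual == 1)).sum())
        m_tn = int(((pred == 0) & (actual == 0)).sum())
        tp, fp, fn, tn = tp + m_tp, fp + m_fp, fn + m_fn, tn + m_tn
        rows.append(
            dict(
                marker=true_label,
                tp=m_tp,
                fp=m_fp,
                fn=m_fn,
                tn=m_tn,
                sensitivity=m_tp / (m_tp + m_fn) if m_tp + m_fn else np.nan,
                specificity=m_tn / (m_tn + m_fp) if m_tn + m_fp else np.nan,
            )
        )
    # presences in unmappable scored markers are pure false positives
    for lab in unmapped:
        if lab in scored_df:
            fp += int(scored_df[lab].sum())
    return ConfusionReport(
        per_marker=pd.DataFrame(rows).set_index("marker"),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        unmapped_markers=unmapped,
    )


# ---------------------------------------------------------------------------
# the paper-like demonstration preset


def two_group_preset(
    seed: int = 0,
    n_individuals: tuple[int, int] = (78, 20),
    **overrides,
) -> SimConfig:
    """A demonstration dataset shaped like a real intraspecific survey.

    98 individuals in two venom-type groups (a majority A-like and a
    minority B-like population), 28 true markers of which 4 are fixed
    (probability 1 everywhere) and 3 are strongly group-diagnostic
    (present in B-like, nearly absent in A-like, |dp| >= 0.8); the rest
    vary at intermediate, weakly differentiated frequencies. Structure only
    — the real study's venoms and values are not claimed.
    """
    n_markers = 28
    times = np.round(np.linspace(16.0, 44.0, n_markers), 2)
    rng = np.random.default_rng(seed)
    # frequency structure of real venom panels is bimodal: most polymorphic
    # proteins are expressed at low frequency, a minority at intermediate
    base = np.where(
        rng.random(n_markers) < 2 / 3,
        rng.uniform(0.05, 0.35, size=n_markers),
        rng.uniform(0.35, 0.65, size=n_markers),
    )
    p_a = base.copy()
    p_b = np.clip(base + rng.uniform(-0.08, 0.08, size=n_markers), 0.05, 0.95)
    fixed_idx = [3, 10, 17, 24]
    diagnostic_idx = [6, 13, 20]
    for i in fixed_idx:
        p_a[i] = p_b[i] = 1.0
    for i in diagnostic_idx:
        p_a[i] = 0.05
        p_b[i] = 0.92
    groups = (
        GroupSpec("typeA", n_individuals[0], tuple(p_a)),
        GroupSpec("typeB", n_individuals[1], tuple(p_b)),
    )
    cfg = SimConfig(
        groups=groups, true_marker_times=tuple(times), seed=seed, **overrides
    )
    return cfg


#: true-marker indices of the preset's diagnostic and fixed markers
PRESET_DIAGNOSTIC_IDX = (6, 13, 20)
PRESET_FIXED_IDX = (3, 10, 17, 24)
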