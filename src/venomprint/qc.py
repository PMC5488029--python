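"""Duplicate-based quality control and marker filtering.

Every individual is run at least twice; a marker scored present in one
duplicate and absent in the other is a *mismatch*, exactly as in AFLP
genotyping QC. Markers accumulating mismatches across individuals are prone
to scoring error and are discarded (default threshold: 3 mismatches), and
the overall mismatch error rate — mismatches over total marker x pair
comparisons — is reported before and after that exclusion so readers can
judge data quality.

Markers with frequency exactly 1 (fixed) carry no information about
variation and are dropped before diversity analysis; frequency-0 markers
are dropped by the same argument (they only arise in externally supplied
matrices).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import pandas as pd

from .exceptions import UndefinedRateError
from .matrix import BinaryMatrix

logger = logging.getLogger(__name__)

DEFAULT_MISMATCH_THRESHOLD = 3


@dataclass
class QCReport:
    """Result of duplicate-comparison QC on a scored matrix."""

    mismatches_per_marker: dict[str, int]
    n_pairs: int
    discarded_markers: list[str]
    error_rate_before: float
    error_rate_after: float
    mismatch_threshold: int
    excluded_individuals: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "QCReport":
        return cls(**d)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def consensus_profile(replicate_rows: pd.DataFrame | list) -> pd.Series:
    """Majority consensus across an individual's replicate rows.

    A marker is called present when present in more than half of the
    replicates; exact ties are called present. The tie rule favours
    detection — the protocol re-runs doubtful absences rather than doubting
    presences — and is logged whenever it decides a call.
    """
    df = pd.DataFrame(replicate_rows)
    n = len(df)
    counts = df.sum(axis=0)
    consensus = (2 * counts >= n).astype("int8")
    if n % 2 == 0:
        tied = counts[2 * counts == n]
        for marker in tied.index:
            logger.info("consensus tie at marker %s: called present", marker)
    return consensus


def duplicate_pairs(replicates: pd.DataFrame) -> dict[str, tuple[pd.Series, pd.Series]]:
    """Designated duplicate pair (replicates 1 and 2) per individual.

    Individuals with fewer than two replicates are excluded from QC with a
    warning.
    """
    pairs: dict[str, tuple[pd.Series, pd.Series]] = {}
    for individual, group in replicates.groupby(level=0, sort=False):
        rows = group.droplevel(0)
        if len(rows) < 2:
            logger.info("individual %s has <2 replicates; excluded from QC", individual)
            continue
        rows = rows.sort_index()
        pairs[str(individual)] = (rows.iloc[0], rows.iloc[1])
    return pairs


def count_mismatches(
    pairs: dict[str, tuple[pd.Series, pd.Series]], markers: list[str]
) -> pd.Series:
    """Per-marker count of duplicate pairs with discordant calls."""
    counts = pd.Series(0, index=pd.Index(markers), dtype=int)
    for a, b in pairs.values():
        counts += (a[markers] != b[markers]).astype(int)
    return counts


def mismatch_error_rate(counts: pd.Series, n_pairs: int, n_markers: int) -> float:
    """Total mismatches over total comparisons (pairs x markers)."""
    total = n_pairs * n_markers
    if total == 0:
        raise UndefinedRateError("error rate undefined over zero comparisons")
    return float(counts.sum()) / total


def discard_error_prone(
    matrix: BinaryMatrix,
    counts: pd.Series,
    threshold: int = DEFAULT_MISMATCH_THRESHOLD,
) -> BinaryMatrix:
    """Remove markers with >= `threshold` mismatches, preserving marker order."""
    keep = [m for m in matrix.marker_labels if counts.get(m, 0) < threshold]
    return matrix.select_markers(keep)


def run_qc(
    matrix: BinaryMatrix,
    threshold: int = DEFAULT_MISMATCH_THRESHOLD,
) -> tuple[BinaryMatrix, QCReport]:
    """Full duplicate-QC pass: count mismatches, discard error-prone markers,
    report error rates before and after the exclusion."""
    if matrix.replicates is None:
        raise ValueError("matrix carries no replicate rows; QC needs duplicates")
    pairs = duplicate_pairs(matrix.replicates)
    all_individuals = matrix.replicates.index.get_level_values(0).unique()
    excluded = [str(i) for i in all_individuals if str(i) not in pairs]
    markers = matrix.marker_labels
    counts = count_mismatches(pairs, markers)
    rate_before = mismatch_error_rate(counts, len(pairs), len(markers))
    filtered = discard_error_prone(matrix, counts, threshold)
    discarded = [m for m in markers if m not in filtered.marker_labels]
    kept_counts = counts[filtered.marker_labels]
    if filtered.n_markers:
        rate_after = mismatch_error_rate(kept_counts, len(pairs), filtered.n_markers)
    else:
        rate_after = 0.0
    report = QCReport(
        mismatches_per_marker={m: int(c) for m, c in counts.items()},
        n_pairs=len(pairs),
        discarded_markers=discarded,
        error_rate_before=rate_before,
        error_rate_after=rate_after,
        mismatch_threshold=threshold,
        excluded_individuals=excluded,
    )
    return filtered, report


def drop_fixed_markers(matrix: BinaryMatrix) -> BinaryMatrix:
    """Drop non-polymorphic markers (frequency exactly 1, and frequency 0).

    Fixed markers say nothing about variation among individuals; all-absent
    markers are uninformative for the same reason and are logged separately
    since they only occur in matrices scored elsewhere.
    """
    freq = matrix.data.mean(axis=0)
    fixed = [m for m in matrix.marker_labels if freq[m] == 1.0]
    absent = [m for m in matrix.marker_labels if freq[m] == 0.0]
    if fixed:
        logger.info("dropping %d fixed markers: %s", len(fixed), fixed)
    if absent:
        logger.info("dropping %d all-absent markers: %s", len(absent), absent)
    keep = [m for m in matrix.marker_labels if m not in set(fixed) | set(absent)]
    return matrix.select_markers(keep)
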