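"""Diversity statistics and pairwise dissimilarity of venom profiles.

On a binary matrix the informative statistics are marker frequencies,
per-individual richness (peak counts), a Shannon-type information index,
the table of distinct phenotypes (unique profiles), and pairwise
Bray-Curtis dissimilarity, which for presence/absence data reduces to the
Sorensen dissimilarity 1 - 2a/(2a+b+c).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .exceptions import UndefinedDistanceError
from .matrix import BinaryMatrix


def marker_frequencies(matrix: BinaryMatrix) -> pd.Series:
    """Fraction of individuals carrying each marker."""
    if matrix.n_individuals == 0:
        raise ValueError("frequencies need at least one individual")
    return matrix.data.mean(axis=0)


def richness(matrix: BinaryMatrix) -> pd.Series:
    """Per-individual venom richness: the number of peaks present."""
    return matrix.data.sum(axis=1)


def shannon_marker_index(p) -> np.ndarray | float:
    """Two-state Shannon information index of a marker frequency, in nats.

    I(p) = -(p ln p + (1-p) ln(1-p)) with 0 ln 0 := 0 — the diversity index
    used for dominant (band-presence) markers in population-genetics
    software. Maximal (ln 2) at p = 0.5, zero for fixed or absent markers,
    and symmetric in p and 1-p.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0) + np.where(
            p < 1, (1 - p) * np.log(1 - p), 0.0
        )
    out = -terms
    return float(out) if out.ndim == 0 else out


def shannon_summary(matrix: BinaryMatrix) -> dict:
    """Shannon diversity on both supported bases, labelled explicitly.

    ``per_marker``/``mean_marker_index`` is the two-state index above
    averaged over markers (the primary statistic); ``log_richness`` is the
    per-individual ln(richness) that the classical index degenerates to on
    a single binary profile — exposed as a secondary value.
    """
    p = marker_frequencies(matrix)
    per_marker = pd.Series(shannon_marker_index(p.to_numpy()), index=p.index)
    rich = richness(matrix)
    with np.errstate(divide="ignore"):
        log_rich = pd.Series(
            np.where(rich > 0, np.log(rich.to_numpy(dtype=float)), 0.0), index=rich.index
        )
    return {
        "per_marker": per_marker,
        "mean_marker_index": float(per_marker.mean()) if len(per_marker) else 0.0,
        "log_richness": log_rich,
    }


@dataclass
class PhenotypeTable:
    """Distinct binary profiles (phenotypes) and their multiplicities."""

    phenotypes: list[tuple]
    counts: list[int]
    n_phenotypes: int
    n_singletons: int

    def to_frame(self, marker_labels: list[str]) -> pd.DataFrame:
        df = pd.DataFrame(self.phenotypes, columns=marker_labels)
        df.insert(0, "count", self.counts)
        return df


def phenotype_table(matrix: BinaryMatrix) -> PhenotypeTable:
    """Tabulate unique venom profiles; singletons are profiles seen once."""
    rows = [tuple(int(v) for v in row) for row in matrix.data.to_numpy()]
    counter = Counter(rows)
    # order phenotypes by decreasing count, then lexicographically, for stable output
    items = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    phenotypes = [k for k, _ in items]
    counts = [v for _, v in items]
    return PhenotypeTable(
        phenotypes=phenotypes,
        counts=counts,
        n_phenotypes=len(phenotypes),
        n_singletons=sum(1 for c in counts if c == 1),
    )


def bray_curtis(matrix: BinaryMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between individuals.

    Computed with the general abundance formula (so a future quantitative
    matrix works unchanged); on 0/1 data it equals Sorensen dissimilarity
    1 - 2a/(2a+b+c). Undefined when two all-zero profiles meet; such pairs
    raise, naming the individuals.
    """
    values = matrix.data.to_numpy(dtype=float)
    zero_rows = np.flatnonzero(values.sum(axis=1) == 0)
    if zero_rows.size >= 2:
        ids = [matrix.individual_ids[i] for i in zero_rows[:2]]
        raise UndefinedDistanceError(
            f"Bray-Curtis undefined between all-zero profiles {ids[0]} and {ids[1]}"
        )
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=matrix.individual_ids)


def group_distance_summary(dm: DistanceMatrix, groups: pd.Series) -> dict:
    """Mean within-group and between-group dissimilarity.

    ``groups`` maps individual id -> group label over the matrix ids.
    """
    ids = list(dm.ids)
    labels = np.array([groups[i] for i in ids])
    d = dm.data
    iu = np.triu_indices(len(ids), k=1)
    same = labels[iu[0]] == labels[iu[1]]
    vals = d[iu]
    return {
        "mean_within": float(vals[same].mean()) if same.any() else float("nan"),
        "mean_between": float(vals[~same].mean()) if (~same).any() else float("nan"),
    }
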