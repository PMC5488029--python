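"""Non-metric multidimensional scaling and marker-vector fitting.

NMDS embeds the Bray-Curtis dissimilarities in k dimensions so that the
configuration distances reproduce the *rank order* of the input
dissimilarities as well as possible. Goodness of fit is Kruskal's stress-1,

    stress = sqrt( sum (D_ij - dhat_ij)^2 / sum D_ij^2 ),

where D are configuration distances and dhat the monotone (isotonic)
regression of D on the rank order of the dissimilarities; ties are treated
as *primary* (tied dissimilarities impose no order constraint among
themselves). The minimiser alternates the isotonic fit with a Guttman
configuration update, safeguarded by step-halving so the stress sequence is
non-increasing, and runs from a principal-coordinates start plus seeded
random restarts, keeping the lowest-stress solution.

Markers are then fitted onto the ordination envfit-style: each marker
column is regressed on the coordinates, giving an arrow direction, a
squared correlation r^2, and a permutation p-value obtained by shuffling
the marker over individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa

from .exceptions import ValidationError
from .matrix import BinaryMatrix

DEFAULT_N_STARTS = 20
DEFAULT_MAX_ITER = 300
DEFAULT_TOL = 1e-7
DEFAULT_N_PERM = 999


@dataclass
class OrdinationResult:
    """A fitted NMDS configuration."""

    coordinates: pd.DataFrame  # individuals x axes, centered, principal orientation
    stress: float
    k: int
    n_iterations: int
    converged: bool
    seed: int
    n_starts: int
    stress_history: list[float] = field(default_factory=list)
    start_stresses: list[float] = field(default_factory=list)


@dataclass
class MarkerVectorFit:
    """Direction, fit strength and permutation significance of one marker."""

    marker: str
    direction: np.ndarray
    r2: float
    p_perm: float
    n_perm: int
    degenerate: bool = False


def monotone_disparities(d: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Isotonic regression of configuration distances D on the rank order of
    the dissimilarities d, with primary tie treatment.

    Within a block of tied dissimilarities the distances are pre-sorted
    ascending, so the pool-adjacent-violators fit imposes no constraint
    among the ties beyond what their neighbours force.
    """
    order = np.lexsort((D, d))
    fitted = isotonic_regression(D[order]).x
    dhat = np.empty_like(D)
    dhat[order] = fitted
    return dhat


def kruskal_stress(d: np.ndarray, D: np.ndarray) -> float:
    """Kruskal stress-1 of configuration distances D against dissimilarities d."""
    denom = float(np.sum(D**2))
    if denom == 0:
        return 0.0
    dhat = monotone_disparities(d, D)
    return float(np.sqrt(np.sum((D - dhat) ** 2) / denom))


def _guttman_update(X: np.ndarray, dhat: np.ndarray, D: np.ndarray) -> np.ndarray:
    """One Guttman-transform step toward distances matching the disparities."""
    n = X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(D > 0, dhat / D, 0.0)
    R = squareform(ratio)
    B = -R
    np.fill_diagonal(B, R.sum(axis=1))
    return B @ X / n


def _single_start(
    d: np.ndarray, X0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list[float], bool]:
    """Minimise stress-1 from one starting configuration.

    After each Guttman step the move is accepted only if stress did not
    increase; otherwise the step is halved toward the previous configuration
    (up to 20 times), which keeps the recorded stress sequence non-increasing.
    """
    X = X0 - X0.mean(axis=0)
    D = pdist(X)
    stress = kruskal_stress(d, D)
    history = [stress]
    converged = False
    for _ in range(max_iter):
        dhat = monotone_disparities(d, D)
        X_new = _guttman_update(X, dhat, D)
        D_new = pdist(X_new)
        s_new = kruskal_stress(d, D_new)
        if s_new > stress:
            improved = False
            for _halve in range(20):
                X_new = 0.5 * (X_new + X)
                D_new = pdist(X_new)
                s_new = kruskal_stress(d, D_new)
                if s_new <= stress:
                    improved = True
                    break
            if not improved:
                converged = True
                break
        delta = stress - s_new
        X, D, stress = X_new, D_new, s_new
        history.append(stress)
        if delta < tol:
            converged = True
            break
    return X, stress, history, converged


def _principal_orientation(X: np.ndarray) -> np.ndarray:
    """Center, rotate to principal axes and fix signs so that, on each axis,
    the largest-|coordinate| entry is positive. Removes the rotation and
    reflection indeterminacy of NMDS for reproducible output."""
    X = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    for j in range(X.shape[1]):
        i = int(np.argmax(np.abs(X[:, j])))
        if X[i, j] < 0:
            X[:, j] = -X[:, j]
    return X


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_starts: int = DEFAULT_N_STARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS of a dissimilarity matrix, minimising Kruskal stress-1.

    Runs from one principal-coordinates start plus ``n_starts - 1`` random
    starts with a deterministic seed schedule (``seed + start_index``), and
    returns the lowest-stress configuration, centered and rotated to
    principal axes. Fixed seed and input give bit-identical output.
    """
    if not isinstance(dist, DistanceMatrix):
        dist = DistanceMatrix(np.asarray(dist, dtype=float))
    n = dist.shape[0]
    if k >= n - 1:
        raise ValidationError(f"k={k} too large for n={n} objects")
    d = dist.condensed_form()
    scale = d.max() if d.max() > 0 else 1.0

    starts: list[np.ndarray] = []
    pc = pcoa(dist, number_of_dimensions=min(k, n - 1)).samples.to_numpy()[:, :k]
    if pc.shape[1] < k:
        pc = np.pad(pc, ((0, 0), (0, k - pc.shape[1])))
    starts.append(pc)
    for i in range(1, n_starts):
        rng = np.random.default_rng((seed + i) % 2**31)
        starts.append(rng.normal(scale=scale, size=(n, k)))

    best = None
    start_stresses: list[float] = []
    for X0 in starts:
        X, stress, history, converged = _single_start(d, X0, max_iter, tol)
        start_stresses.append(stress)
        if best is None or stress < best[1]:
            best = (X, stress, history, converged)

    X, stress, history, converged = best
    X = _principal_orientation(X)
    coords = pd.DataFrame(
        X, index=list(dist.ids), columns=[f"axis{j + 1}" for j in range(k)]
    )
    return OrdinationResult(
        coordinates=coords,
        stress=stress,
        k=k,
        n_iterations=len(history) - 1,
        converged=converged,
        seed=seed,
        n_starts=n_starts,
        stress_history=history,
        start_stresses=start_stresses,
    )


def fit_marker_vectors(
    ordination: OrdinationResult,
    matrix: BinaryMatrix,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> list[MarkerVectorFit]:
    """Fit each marker onto the ordination (envfit-style).

    Each marker column y is regressed on the centered coordinate columns;
    r^2 = 1 - RSS/TSS measures how much of the marker's variation the
    ordination explains, and the coefficient vector (normalised to unit
    length) gives the arrow direction of increasing marker frequency. The
    p-value is the permutation tail probability
    ``(1 + #{permuted r^2 >= observed}) / (1 + n_perm)``, using one shared
    set of row permutations drawn from ``seed`` for all markers. A constant
    marker has r^2 = 0, no direction, p = 1.
    """
    X = ordination.coordinates.to_numpy()
    ids = list(ordination.coordinates.index)
    if list(matrix.individual_ids) != ids:
        raise ValidationError("matrix rows must match ordination rows (same ids, same order)")
    Xc = X - X.mean(axis=0)
    Q, _ = np.linalg.qr(Xc)
    n = Xc.shape[0]
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    fits: list[MarkerVectorFit] = []
    for marker in matrix.marker_labels:
        y = matrix.data[marker].to_numpy(dtype=float)
        yc = y - y.mean()
        tss = float(yc @ yc)
        if tss == 0:
            fits.append(
                MarkerVectorFit(
                    marker=marker,
                    direction=np.full(Xc.shape[1], np.nan),
                    r2=0.0,
                    p_perm=1.0,
                    n_perm=n_perm,
                    degenerate=True,
                )
            )
            continue
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        r2 = float((Q.T @ yc) @ (Q.T @ yc) / tss)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else np.full_like(beta, np.nan)
        Yp = yc[perms.T]  # n x n_perm matrix of permuted, centered marker values
        r2_perm = np.sum((Q.T @ Yp) ** 2, axis=0) / tss
        p = (1 + int(np.sum(r2_perm >= r2))) / (1 + n_perm)
        fits.append(
            MarkerVectorFit(
                marker=marker, direction=direction, r2=r2, p_perm=p, n_perm=n_perm
            )
        )
    return fits


def vector_fits_frame(fits: list[MarkerVectorFit]) -> pd.DataFrame:
    """Tabulate vector fits (marker, direction components, r2, p)."""
    k = len(fits[0].direction) if fits else 0
    rows = []
    for f in fits:
        row = {"marker": f.marker}
        for j in range(k):
            row[f"dir{j + 1}"] = f.direction[j]
        row["r2"] = f.r2
        row["p_perm"] = f.p_perm
        rows.append(row)
    return pd.DataFrame(rows)
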