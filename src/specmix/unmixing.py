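"""Linear spectral unmixing with an optional binary-label constraint.

The standard model is y = F @ x: an observed m-channel spectrum y is a
non-negative mixture of the n reference spectra in the columns of F.  The
solver policy follows a two-stage scheme: ordinary least squares first, and
only if any abundance comes back negative is the slower non-negativity-
constrained problem solved.

The binary label constraint encodes the a priori knowledge that every object
carries exactly two fluorophores.  For each of the C(n, 2) unordered pairs
{i, j} the model

    y = f_i * x_i + f_j * x_j + b,      x_i >= 0, x_j >= 0

is fitted by (non-negative) least squares after subtracting the fixed
background vector b, and the pair with the smallest sum of squared residuals
wins.  With 16 fluorophores this enumerates 120 candidate label types —
more distinguishable types than spectral channels would allow in a plain
linear unmixing.

Confidence in an assignment is the Pearson correlation between the observed
spectrum and the reconstructed model spectrum of the winning fit.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .segmentation import SegmentationMask, average_object_spectra
from .spectra import ReferenceMatrix

__all__ = [
    "UnmixingResult",
    "BinaryAssignment",
    "unmix_unconstrained",
    "unmix_nonnegative",
    "unmix_with_fallback",
    "enumerate_pairs",
    "fit_binary_pair",
    "binary_constrained_unmix",
    "confidence_pearson",
    "classify_image",
]

# condition threshold on the 2x2 Gram matrix above which a pair of columns
# is considered effectively parallel
DEGENERATE_GRAM_CONDITION = 1e8


@dataclass(frozen=True)
class UnmixingResult:
    """Abundance vector x, sum of squared residuals, and which solver ran."""

    abundances: np.ndarray
    residual_ss: float
    method_used: str  # "unconstrained" | "nonnegative"


@dataclass(frozen=True)
class BinaryAssignment:
    """The winning fluorophore pair for one particle."""

    pair: tuple[int, int]  # i < j
    abundances: tuple[float, float]
    residual_ss: float
    confidence: float
    all_pair_residuals: np.ndarray | None = None


def _as_array(F: ReferenceMatrix | np.ndarray) -> np.ndarray:
    if isinstance(F, ReferenceMatrix):
        return F.matrix
    return np.asarray(F, dtype=float)


def unmix_unconstrained(
    y: np.ndarray, F: ReferenceMatrix | np.ndarray
) -> UnmixingResult:
    """Ordinary least squares; abundances may come back negative."""
    A = _as_array(F)
    y = np.asarray(y, dtype=float)
    x, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(
            "reference matrix is rank-deficient; minimum-norm solution returned",
            stacklevel=2,
        )
    resid = y - A @ x
    return UnmixingResult(x, float(resid @ resid), "unconstrained")


def unmix_nonnegative(
    y: np.ndarray, F: ReferenceMatrix | np.ndarray
) -> UnmixingResult:
    """Least squares subject to x >= 0 (active-set NNLS)."""
    A = _as_array(F)
    y = np.asarray(y, dtype=float)
    try:
        x, rnorm = scipy.optimize.nnls(A, y)
    except RuntimeError as err:  # pragma: no cover - solver non-convergence
        raise RuntimeError(f"non-negative unmixing failed to converge: {err}")
    return UnmixingResult(x, float(rnorm**2), "nonnegative")


def unmix_with_fallback(
    y: np.ndarray, F: ReferenceMatrix | np.ndarray
) -> UnmixingResult:
    """Unconstrained solve, falling back to NNLS if any abundance is negative.

    The unconstrained solution is accepted only if physically feasible
    (all abundances non-negative); otherwise it is rejected and the
    constrained problem is solved.
    """
    res = unmix_unconstrained(y, F)
    if np.all(res.abundances >= 0):
        return res
    return unmix_nonnegative(y, F)


def enumerate_pairs(n: int) -> list[tuple[int, int]]:
    """All unordered index pairs {i, j}, i < j, in lexicographic order.

    16 fluorophores give the 120 binary label types of the full experiment.
    """
    if n < 2:
        raise ValueError("need at least 2 fluorophores to form pairs")
    return list(itertools.combinations(range(n), 2))


def _nnls_2col(
    gii: float, gjj: float, gij: float, ci: float, cj: float, rss0: float
) -> tuple[float, float, float]:
    """Closed-form active-set solution of a 2-variable NNLS.

    Minimizes ||r - f_i x_i - f_j x_j||^2 over x >= 0 given the Gram entries
    g = f.f, the correlations c = f.r and rss0 = r.r.  Tries the interior
    (unconstrained) solution first; if infeasible, the optimum lies on a
    face, i.e. one of the two single-variable fits (or the origin).
    """
    det = gii * gjj - gij * gij
    if det > 0:
        xi = (gjj * ci - gij * cj) / det
        xj = (gii * cj - gij * ci) / det
        if xi >= 0 and xj >= 0:
            return xi, xj, rss0 - (xi * ci + xj * cj)
    xi1 = max(ci / gii, 0.0) if gii > 0 else 0.0
    xj1 = max(cj / gjj, 0.0) if gjj > 0 else 0.0
    rss_i = rss0 - xi1 * ci
    rss_j = rss0 - xj1 * cj
    if rss_i <= rss_j:
        return xi1, 0.0, rss_i
    return 0.0, xj1, rss_j


def fit_binary_pair(
    y: np.ndarray,
    F: ReferenceMatrix | np.ndarray,
    pair: tuple[int, int],
    b: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Fit y = f_i x_i + f_j x_j + b for one candidate pair.

    The fixed background vector b is subtracted from y and the two
    abundances are solved by non-negative least squares (negative fluorophore
    abundances are not physical).  Returns ``(x_i, x_j, residual_ss)``.
    Near-parallel reference columns are flagged with a warning but still
    fitted (the best feasible fit is well defined even then).
    """
    A = _as_array(F)
    y = np.asarray(y, dtype=float)
    i, j = int(pair[0]), int(pair[1])
    if i == j:
        raise ValueError("pair must contain two distinct fluorophores")
    r = y if b is None else y - np.asarray(b, dtype=float)
    fi, fj = A[:, i], A[:, j]
    gii, gjj, gij = float(fi @ fi), float(fj @ fj), float(fi @ fj)
    eigs = np.linalg.eigvalsh([[gii, gij], [gij, gjj]])
    if eigs[0] <= 0 or eigs[1] / eigs[0] > DEGENERATE_GRAM_CONDITION:
        warnings.warn(
            f"reference spectra {i} and {j} are nearly parallel; "
            "pair fit is degenerate",
            stacklevel=2,
        )
    xi, xj, rss = _nnls_2col(
        gii, gjj, gij, float(fi @ r), float(fj @ r), float(r @ r)
    )
    return xi, xj, max(rss, 0.0)


def _fit_all_pairs(
    A: np.ndarray, r: np.ndarray, pairs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized 2-variable NNLS over every candidate pair.

    Identical arithmetic to :func:`_nnls_2col`, evaluated for all pairs at
    once.  Returns ``(xi, xj, rss)`` arrays of length C(n, 2).
    """
    G = A.T @ A
    c = A.T @ r
    rss0 = float(r @ r)
    ii, jj = pairs[:, 0], pairs[:, 1]
    gii, gjj, gij = G[ii, ii], G[jj, jj], G[ii, jj]
    ci, cj = c[ii], c[jj]
    det = gii * gjj - gij * gij

    with np.errstate(divide="ignore", invalid="ignore"):
        xi_u = (gjj * ci - gij * cj) / det
        xj_u = (gii * cj - gij * ci) / det
        xi_1 = np.where(gii > 0, np.maximum(ci / gii, 0.0), 0.0)
        xj_1 = np.where(gjj > 0, np.maximum(cj / gjj, 0.0), 0.0)
    interior = (det > 0) & (xi_u >= 0) & (xj_u >= 0)
    rss_i = rss0 - xi_1 * ci
    rss_j = rss0 - xj_1 * cj
    edge_i = rss_i <= rss_j
    xi = np.where(interior, xi_u, np.where(edge_i, xi_1, 0.0))
    xj = np.where(interior, xj_u, np.where(edge_i, 0.0, xj_1))
    rss = np.where(
        interior,
        rss0 - (xi_u * ci + xj_u * cj),
        np.where(edge_i, rss_i, rss_j),
    )
    return xi, xj, np.maximum(rss, 0.0)


def confidence_pearson(y: np.ndarray, model: np.ndarray) -> float:
    """Pearson correlation between an observed and a reconstructed spectrum.

    Returns NaN when either vector has zero variance (correlation undefined).
    """
    y = np.asarray(y, dtype=float)
    model = np.asarray(model, dtype=float)
    if y.shape != model.shape:
        raise ValueError("spectra must have the same length")
    dy = y - y.mean()
    dm = model - model.mean()
    denom = np.sqrt((dy @ dy) * (dm @ dm))
    if denom == 0:
        return float("nan")
    return float(np.clip((dy @ dm) / denom, -1.0, 1.0))


def binary_constrained_unmix(
    y: np.ndarray,
    F: ReferenceMatrix | np.ndarray,
    b: np.ndarray | None = None,
    keep_all_residuals: bool = False,
) -> BinaryAssignment:
    """Exhaustively fit every fluorophore pair and keep the minimum-SSR one.

    All C(n, 2) binary subsets are fitted in series; the pair producing the
    overall smallest sum of squared residuals is chosen.  Ties are broken by
    lexicographic pair order (first minimum wins).
    """
    A = _as_array(F)
    if A.shape[1] < 2:
        raise ValueError("binary unmixing needs at least 2 fluorophores")
    y = np.asarray(y, dtype=float)
    r = y if b is None else y - np.asarray(b, dtype=float)
    pairs = np.array(enumerate_pairs(A.shape[1]))
    xi, xj, rss = _fit_all_pairs(A, r, pairs)
    best = int(np.argmin(rss))
    i, j = int(pairs[best, 0]), int(pairs[best, 1])
    model = A[:, i] * xi[best] + A[:, j] * xj[best]
    if b is not None:
        model = model + np.asarray(b, dtype=float)
    return BinaryAssignment(
        pair=(i, j),
        abundances=(float(xi[best]), float(xj[best])),
        residual_ss=float(rss[best]),
        confidence=confidence_pearson(y, model),
        all_pair_residuals=rss.copy() if keep_all_residuals else None,
    )


def classify_image(
    image: np.ndarray,
    mask: SegmentationMask,
    F: ReferenceMatrix,
    b: np.ndarray | None = None,
) -> pd.DataFrame:
    """Binary-constrained assignment for every segmented particle.

    Averages pixel spectra per particle, then runs the binary-constrained
    unmixer on each averaged spectrum.  Per-particle failures are recorded in
    the ``error`` column rather than aborting the batch.

    Returns a DataFrame with one row per particle: particle identity and
    geometry, the winning pair (indices and names), abundances, residual sum
    of squares, and Pearson confidence.
    """
    particles = average_object_spectra(image, mask)
    names = F.names
    rows = []
    for p in particles:
        row = {
            "particle_id": p.particle_id,
            "centroid_row": p.centroid[0],
            "centroid_col": p.centroid[1],
            "pixel_count": p.pixel_count,
        }
        try:
            a = binary_constrained_unmix(p.spectrum, F, b)
            row.update(
                pair_i=a.pair[0],
                pair_j=a.pair[1],
                fluor_i=names[a.pair[0]],
                fluor_j=names[a.pair[1]],
                x_i=a.abundances[0],
                x_j=a.abundances[1],
                residual_ss=a.residual_ss,
                confidence=a.confidence,
                error="",
            )
        except Exception as err:  # per-particle failure is not fatal
            row.update(
                pair_i=-1, pair_j=-1, fluor_i="", fluor_j="",
                x_i=np.nan, x_j=np.nan, residual_ss=np.nan,
                confidence=np.nan, error=str(err),
            )
        rows.append(row)
    columns = [
        "particle_id", "centroid_row", "centroid_col", "pixel_count",
        "pair_i", "pair_j", "fluor_i", "fluor_j", "x_i", "x_j",
        "residual_ss", "confidence", "error",
    ]
    return pd.DataFrame(rows, columns=columns)


def unmix_pixels(
    image: np.ndarray,
    F: ReferenceMatrix | np.ndarray,
    nonnegative_fallback: bool = True,
) -> np.ndarray:
    """Per-pixel unmixing of a whole image; returns an (n, H, W) abundance map.

    All pixels are first solved by one batched ordinary least squares; pixels
    with any negative abundance are re-solved by NNLS when
    ``nonnegative_fallback`` is set.
    """
    A = _as_array(F)
    image = np.asarray(image, dtype=float)
    m, H, W = image.shape
    Y = image.reshape(m, -1)
    X, _, _, _ = np.linalg.lstsq(A, Y, rcond=None)
    if nonnegative_fallback:
        bad = np.where((X < 0).any(axis=0))[0]
        for k in bad:
            X[:, k] = scipy.optimize.nnls(A, Y[:, k])[0]
    return X.reshape(A.shape[1], H, W)
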