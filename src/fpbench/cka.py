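"""Linear-kernel HSIC and centered kernel alignment between fingerprint matrices.

Two fingerprint matrices X (m x x) and Y (m x y) over the same m compounds are
compared after column centering.  The unnormalized linear-kernel HSIC is

    HSIC_feature(X, Y) = ||Y^T X||_F^2        (feature-similarity route)
    HSIC_sample(X, Y)  = trace(X X^T Y Y^T)   (Gram-matrix route)

which coincide for centered matrices.  CKA normalizes HSIC to [0, 1]:

    CKA(X, Y) = HSIC(X, Y) / sqrt(HSIC(X, X) * HSIC(Y, Y))

With the linear kernel this equals the classical RV coefficient.  The default
estimator is the U-statistic unbiased HSIC (Song et al. 2012), which operates
on Gram matrices and can be slightly negative for independent data; the biased
(plug-in) estimator is kept for the feature/sample identity checks, choosing
the feature route whenever m exceeds both widths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .rulefp import FingerprintMatrix


class UndefinedSimilarityError(ValueError):
    """CKA is undefined: a matrix is constant (zero self-HSIC)."""


@dataclass
class SimilarityResult:
    hsic_xy: float
    hsic_xx: float
    hsic_yy: float
    cka: float
    mode: str         # "feature" | "sample"
    estimator: str    # "biased" | "unbiased"


def center_columns(x: np.ndarray) -> np.ndarray:
    """Subtract each column's mean; idempotent."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("centering requires a 2-D matrix with at least 2 rows")
    return x - x.mean(axis=0, keepdims=True)


def _check_rows(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"row-count mismatch: {x.shape[0]} vs {y.shape[0]}")


def hsic_feature(x: np.ndarray, y: np.ndarray) -> float:
    """``||Y^T X||_F^2`` on centered inputs (biased, feature route)."""
    _check_rows(x, y)
    return float(np.linalg.norm(y.T @ x, "fro") ** 2)


def hsic_sample(x: np.ndarray, y: np.ndarray) -> float:
    """``trace(X X^T Y Y^T)`` on centered inputs (biased, Gram route)."""
    _check_rows(x, y)
    return float(np.trace((x @ x.T) @ (y @ y.T)))


def hsic_unbiased(kx: np.ndarray, ky: np.ndarray) -> float:
    """U-statistic unbiased HSIC on two m x m Gram matrices (m >= 4).

    Diagonals are zeroed; the three-term estimator with 1/(m(m-3)) prefactor
    is used.  May be slightly negative for independent data.
    """
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    m = kx.shape[0]
    if kx.shape != (m, m) or ky.shape != (m, m):
        raise ValueError("Gram matrices must be square and equally sized")
    if m < 4:
        raise ValueError(f"unbiased HSIC requires at least 4 samples, got {m}")
    kt = kx - np.diag(np.diag(kx))
    lt = ky - np.diag(np.diag(ky))
    ones = np.ones(m)
    term1 = float(np.sum(kt * lt))
    term2 = float(kt.sum() * lt.sum()) / ((m - 1) * (m - 2))
    term3 = 2.0 / (m - 2) * float(ones @ kt @ (lt @ ones))
    return (term1 + term2 - term3) / (m * (m - 3))


def cka(
    x: np.ndarray,
    y: np.ndarray,
    estimator: str = "unbiased",
    mode: str = "auto",
) -> SimilarityResult:
    """Linear-kernel CKA between two data matrices over the same samples.

    Inputs are column-centered internally.  ``mode`` applies to the biased
    estimator only: "auto" picks the feature route when m > max(n_x, n_y),
    the Gram route otherwise; the unbiased estimator always uses Gram
    matrices.  A constant matrix (zero self-HSIC) raises
    :class:`UndefinedSimilarityError` rather than returning NaN.
    """
    xc = center_columns(np.asarray(x, dtype=float))
    yc = center_columns(np.asarray(y, dtype=float))
    _check_rows(xc, yc)
    m = xc.shape[0]

    if estimator == "biased":
        if mode == "auto":
            mode = "feature" if m > max(xc.shape[1], yc.shape[1]) else "sample"
        fn = hsic_feature if mode == "feature" else hsic_sample
        hxy, hxx, hyy = fn(xc, yc), fn(xc, xc), fn(yc, yc)
    elif estimator == "unbiased":
        mode = "sample"
        kx, ky = xc @ xc.T, yc @ yc.T
        hxy = hsic_unbiased(kx, ky)
        hxx = hsic_unbiased(kx, kx)
        hyy = hsic_unbiased(ky, ky)
    else:
        raise ValueError(f"estimator must be 'biased' or 'unbiased', got {estimator!r}")

    if hxx <= 0 or hyy <= 0:
        raise UndefinedSimilarityError(
            "zero or negative self-HSIC (constant matrix?): CKA undefined"
        )
    value = max(hxy, 0.0) / np.sqrt(hxx * hyy)
    return SimilarityResult(
        hsic_xy=hxy, hsic_xx=hxx, hsic_yy=hyy, cka=float(value),
        mode=mode, estimator=estimator,
    )


def pairwise_cka(
    fps: list[FingerprintMatrix], estimator: str = "unbiased"
) -> tuple[np.ndarray, list[str], list[int]]:
    """Pairwise CKA similarity across fingerprint types of the same compounds.

    Returns ``(similarity, names, order)`` where ``similarity`` is symmetric
    with unit diagonal, and ``order`` is a display ordering from
    average-linkage hierarchical clustering of the distance ``1 - CKA``.
    """
    if len(fps) < 2:
        raise ValueError("pairwise CKA needs at least two fingerprint matrices")
    ref = fps[0].compound_ids
    for fp in fps[1:]:
        if fp.compound_ids != ref:
            missing = sorted(set(ref) ^ set(fp.compound_ids))
            raise ValueError(
                f"fingerprint matrices are not aligned on the same compounds; "
                f"mismatched ids (symmetric difference): {missing[:10]}"
            )
    k = len(fps)
    sim = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            sim[i, j] = sim[j, i] = cka(fps[i].values, fps[j].values, estimator).cka
    names = [fp.name or f"fp{i}" for i, fp in enumerate(fps)]
    dist = np.clip(1.0 - sim, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    order = list(leaves_list(average(squareform(dist, checks=False))))
    return sim, names, order
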