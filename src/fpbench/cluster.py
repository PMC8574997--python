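"""Class-based clustering evaluation of fingerprint matrices.

Each fingerprint matrix over class-labeled compounds is preprocessed three
ways — z-score normalization alone, z-score + PCA keeping the leading
components that explain >0.95 of the variance, and z-score + PLS with the
one-hot class labels as the multi-response target — then scored by
one-versus-all linear discriminant analysis: for every class a binary
(class vs rest) discriminant axis is fitted, all compounds are projected
onto it, and the mean Silhouette coefficient

    s(i) = (b(i) - a(i)) / max(a(i), b(i))

and the variance ratio criterion (Calinski-Harabasz index)

    VRC = [SSB / (K - 1)] / [SSW / (n - K)]

are computed on that 1-D projection with the binary labels as clusters,
then averaged over the classes.  Across fingerprints, each (regime, metric)
column is min-max scaled to [0, 1] and fingerprints are ranked by their
scores on the plain z-scored regime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

logger = logging.getLogger("fpbench.cluster")

REGIMES = ("z", "z+PCA", "z+PLS")
METRICS = ("silhouette", "vrc")


@dataclass
class ClusterScore:
    fingerprint: str
    preprocessing: str
    silhouette_raw: float
    vrc_raw: float
    silhouette_scaled: float = np.nan
    vrc_scaled: float = np.nan
    rank: int = 0


def zscore_normalize(x: np.ndarray) -> np.ndarray:
    """Column z-scores (population sd); constant columns dropped with a warning."""
    x = np.asarray(x, float)
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns are constant; z-scoring undefined")
    if not keep.all():
        logger.warning("dropping %d constant column(s) before z-scoring", (~keep).sum())
    xk = x[:, keep]
    return (xk - xk.mean(axis=0)) / sd[keep]


def pca_reduce(xz: np.ndarray, var_threshold: float = 0.95) -> np.ndarray:
    """Smallest set of leading components exceeding the variance threshold."""
    pca = PCA(svd_solver="full", random_state=0).fit(xz)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, var_threshold) + 1)
    k = min(k, cum.size)
    return pca.transform(xz)[:, :k]


def pls_reduce(xz: np.ndarray, labels: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """PLS score matrix with one-hot labels as the multi-response target."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if n_components is None:
        n_components = max(len(classes) - 1, 1)
    if n_components > min(xz.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(m, n)={min(xz.shape)}"
        )
    onehot = (labels[:, None] == classes[None, :]).astype(float)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(xz, onehot)
    return pls.transform(xz)


def lda_one_vs_all(x: np.ndarray, labels: np.ndarray, ridge: float = 1e-8) -> dict:
    """Per-class binary discriminant projections.

    For each class k the within-class scatter of the (k vs rest) problem is
    inverted against the mean difference to give the discriminant axis
    ``w = S_w^{-1}(mu_k - mu_rest)``; all points are projected onto it.  A
    singular scatter matrix is ridge-regularized with a warning.  Returns
    ``{class: 1-D projection over all points}``.
    """
    x = np.asarray(x, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if any((labels == c).sum() < 2 for c in classes):
        raise ValueError("every class needs at least 2 members")
    projections = {}
    for c in classes:
        mask = labels == c
        xa, xb = x[mask], x[~mask]
        sw = np.cov(xa, rowvar=False, bias=True) * len(xa) + \
             np.cov(xb, rowvar=False, bias=True) * len(xb)
        sw = np.atleast_2d(sw)
        diff = xa.mean(axis=0) - xb.mean(axis=0)
        lam = ridge * max(np.trace(sw) / sw.shape[0], 1.0)
        try:
            w = np.linalg.solve(sw + lam * np.eye(sw.shape[0]), diff)
        except np.linalg.LinAlgError:
            logger.warning("singular within-class scatter for class %r; using pinv", c)
            w = np.linalg.pinv(sw) @ diff
        norm = np.linalg.norm(w)
        if norm > 0:
            w = w / norm
        projections[c] = x @ w
    return projections


def silhouette_mean(projection: np.ndarray, labels: np.ndarray) -> float:
    """Mean Silhouette coefficient of a 1-D projection under Euclidean distance.

    Singleton-cluster points and points with ``max(a, b) == 0`` score 0.
    """
    p = np.asarray(projection, float).ravel()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    dist = np.abs(p[:, None] - p[None, :])
    svals = np.empty(p.size)
    for i in range(p.size):
        own = labels == labels[i]
        if own.sum() == 1:
            svals[i] = 0.0
            continue
        a = dist[i, own].sum() / (own.sum() - 1)
        b = min(dist[i, labels == c].mean() for c in classes if c != labels[i])
        denom = max(a, b)
        svals[i] = 0.0 if denom == 0.0 else (b - a) / denom
    return float(svals.mean())


def vrc(projection: np.ndarray, labels: np.ndarray) -> float:
    """Variance ratio criterion [SSB/(K-1)] / [SSW/(n-K)]; +inf when SSW = 0."""
    p = np.asarray(projection, float).ravel()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    k, n = classes.size, p.size
    if k < 2 or n <= k:
        raise ValueError("VRC requires K >= 2 clusters and n > K points")
    grand = p.mean()
    ssb = ssw = 0.0
    for c in classes:
        pc = p[labels == c]
        ssb += pc.size * (pc.mean() - grand) ** 2
        ssw += ((pc - pc.mean()) ** 2).sum()
    if ssw == 0.0:
        return float("inf")
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def evaluate_fingerprint(
    x: np.ndarray, labels: np.ndarray, pls_components: int | None = None
) -> dict[str, dict[str, float]]:
    """Raw per-regime scores: one-vs-all LDA then silhouette/VRC, class-averaged."""
    labels = np.asarray(labels)
    xz = zscore_normalize(x)
    regimes = {
        "z": xz,
        "z+PCA": pca_reduce(xz),
        "z+PLS": pls_reduce(xz, labels, pls_components),
    }
    out: dict[str, dict[str, float]] = {}
    for name, xr in regimes.items():
        projections = lda_one_vs_all(xr, labels)
        sils, vrcs = [], []
        for c, proj in projections.items():
            binary = (labels == c).astype(int)
            sils.append(silhouette_mean(proj, binary))
            vrcs.append(vrc(proj, binary))
        out[name] = {
            "silhouette": float(np.mean(sils)),
            "vrc": float(np.mean([v for v in vrcs if np.isfinite(v)]) if
                         any(np.isfinite(vrcs)) else np.inf),
        }
    return out


def _minmax(col: np.ndarray) -> np.ndarray:
    lo, hi = np.min(col), np.max(col)
    if hi == lo:
        return np.ones_like(col)
    return (col - lo) / (hi - lo)


def score_table(
    fps: dict[str, np.ndarray], labels: np.ndarray, pls_components: int | None = None
) -> pd.DataFrame:
    """Ranked table of min-max-scaled clustering scores across fingerprints.

    Per (regime, metric) column the best fingerprint scores 1.0 and the worst
    0.0; ranks follow the combined scaled scores of the plain z regime.
    """
    if len(fps) < 2:
        raise ValueError("min-max scaling needs at least 2 fingerprints")
    raw = {name: evaluate_fingerprint(x, labels, pls_components) for name, x in fps.items()}
    names = list(raw)
    rows = []
    for name in names:
        row: dict[str, float | str] = {"fingerprint": name}
        for regime in REGIMES:
            for metric in METRICS:
                row[f"{regime}:{metric}_raw"] = raw[name][regime][metric]
        rows.append(row)
    df = pd.DataFrame(rows)
    for regime in REGIMES:
        for metric in METRICS:
            col = df[f"{regime}:{metric}_raw"].to_numpy(float)
            if np.isinf(col).any():  # +inf sentinel (zero within-scatter) tops the scale
                finite = col[np.isfinite(col)]
                cap = finite.max() + 1.0 if finite.size else 1.0
                col = np.where(np.isposinf(col), cap, col)
            df[f"{regime}:{metric}"] = _minmax(col)
    df["rank_score"] = df["z:silhouette"] + df["z:vrc"]
    df["rank"] = df["rank_score"].rank(ascending=False, method="min").astype(int)
    return df.sort_values("rank").reset_index(drop=True)
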