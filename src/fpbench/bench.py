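"""Drug-combination regression benchmark.

Combination tables (drug_a, drug_b, cell_line, replicate, five response
scores) are aggregated to one row per unordered pair x cell line, featurized
by concatenating the two drugs' fingerprints (sorted-id order; path-based
fingerprints are bit-averaged instead) with a one-hot cell-line block, and
fed to a pluggable regressor under repeated cross-validation: 10-fold
partitions for the 90:10 split and repeated shuffled holdouts for 60:40.

Reported per (fingerprint x score): the Pearson correlation of pooled
test-fold predictions with a 95% confidence interval from a Student-t
estimate on Fisher z-transformed fold PCCs (normality of the z values is
checked by a Shapiro-Wilk gate, warning only), and the RMSE normalized by
the target's population standard deviation with a symmetric 95% empirical
bootstrap interval (1000 resamples).  With the population-sd convention a
constant mean predictor scores a normalized RMSE of exactly 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold, ShuffleSplit

from .rulefp import FingerprintMatrix

logger = logging.getLogger("fpbench.bench")

SCORES = ("css", "bliss", "hsa", "loewe", "zip")
KEY_COLS = ("drug_a", "drug_b", "cell_line")


@dataclass
class BenchResult:
    fingerprint: str
    score: str
    split: str
    pcc_mean: float
    pcc_ci_halfwidth: float
    nrmse: float
    nrmse_ci_halfwidth: float
    folds: int
    repeats: int
    seed: int
    shapiro_p: float
    degenerate: bool = False


def make_regressor(name: str = "gbdt", **kwargs):
    """Shipped regressors: 'gbdt' (histogram gradient boosting) or 'ridge'."""
    if name == "gbdt":
        return HistGradientBoostingRegressor(random_state=0, **kwargs)
    if name == "ridge":
        return Ridge(**kwargs)
    raise ValueError(f"unknown regressor {name!r}; use 'gbdt' or 'ridge'")


def aggregate_tuples(raw: pd.DataFrame, average_pair_orders: bool = True) -> pd.DataFrame:
    """One row per (unordered drug pair, cell line); replicates averaged.

    Pair keys are canonicalized to sorted id order, so (A,B) and (B,A) rows
    collapse together when ``average_pair_orders`` (the default).
    """
    df = raw.copy()
    score_cols = [c for c in df.columns if c not in (*KEY_COLS, "replicate")]
    for c in score_cols:
        df[c] = pd.to_numeric(df[c], errors="raise")
    if average_pair_orders:
        a = df[["drug_a", "drug_b"]].min(axis=1)
        b = df[["drug_a", "drug_b"]].max(axis=1)
        df["drug_a"], df["drug_b"] = a, b
    out = (
        df.groupby(list(KEY_COLS), as_index=False)[score_cols]
        .mean()
        .sort_values(list(KEY_COLS))
        .reset_index(drop=True)
    )
    return out


def featurize_combination(
    fp_a: np.ndarray,
    fp_b: np.ndarray,
    cell_onehot: np.ndarray,
    fp_subtype: str = "circular-2D",
) -> np.ndarray:
    """Single combination feature vector.

    Default: concat(fp_a, fp_b, cell one-hot) with drugs already in canonical
    order -> length 2n + n_cells.  Path-based ("path") fingerprints are
    bit-averaged instead -> length n + n_cells.
    """
    fp_a, fp_b = np.asarray(fp_a, float), np.asarray(fp_b, float)
    if fp_a.shape != fp_b.shape:
        raise ValueError(f"fingerprint length mismatch: {fp_a.shape} vs {fp_b.shape}")
    if fp_subtype == "path":
        drug_block = 0.5 * (fp_a + fp_b)
    else:
        drug_block = np.concatenate([fp_a, fp_b])
    return np.concatenate([drug_block, np.asarray(cell_onehot, float)])


def build_design(
    tuples_df: pd.DataFrame, fp: FingerprintMatrix, cell_lines: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix + score targets for an aggregated combination table."""
    if cell_lines is None:
        cell_lines = sorted(tuples_df["cell_line"].unique())
    cell_index = {c: i for i, c in enumerate(cell_lines)}
    idx = {cid: i for i, cid in enumerate(fp.compound_ids)}
    missing = sorted(
        (set(tuples_df["drug_a"]) | set(tuples_df["drug_b"])) - set(idx)
    )
    if missing:
        raise ValueError(f"drugs absent from fingerprint matrix: {missing[:10]}")
    unknown_cells = set(tuples_df["cell_line"]) - set(cell_lines)
    if unknown_cells:
        raise ValueError(f"unknown cell lines: {sorted(unknown_cells)[:10]}")
    rows = []
    for a, b, cell in zip(tuples_df["drug_a"], tuples_df["drug_b"], tuples_df["cell_line"]):
        a, b = sorted((a, b))
        onehot = np.zeros(len(cell_lines))
        onehot[cell_index[cell]] = 1.0
        rows.append(
            featurize_combination(fp.values[idx[a]], fp.values[idx[b]], onehot, fp.fp_subtype)
        )
    x = np.stack(rows)
    y = tuples_df[list(SCORES)].to_numpy(dtype=float)
    return x, y, list(cell_lines)


# ---------------------------------------------------------------------------
# cross-validation


def _splitter(split: str, k: int, seed: int):
    if split == "90:10":
        return KFold(n_splits=k, shuffle=True, random_state=seed)
    if split == "60:40":
        # k disjoint folds cannot leave 40% aside; use k repeated shuffled
        # 60:40 holdouts instead
        return ShuffleSplit(n_splits=k, test_size=0.4, random_state=seed)
    raise ValueError(f"split must be '90:10' or '60:40', got {split!r}")


def run_cv(
    x: np.ndarray,
    y: np.ndarray,
    regressor,
    split: str = "90:10",
    k: int = 10,
    repeats: int = 1,
    seed: int = 0,
) -> list[dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Fold-wise (y_true, y_pred) per score; one regressor clone per score/fold."""
    y = np.atleast_2d(np.asarray(y, float))
    if y.shape[0] != x.shape[0]:
        y = y.T
    n_scores = y.shape[1]
    names = list(SCORES[:n_scores]) if n_scores <= len(SCORES) else [
        f"y{i}" for i in range(n_scores)
    ]
    folds = []
    for rep in range(repeats):
        rep_seed = (seed + 1000003 * rep) % (2**31)
        for train, test in _splitter(split, k, rep_seed).split(x):
            fold: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for j, name in enumerate(names):
                yt = y[:, j]
                if np.ptp(yt[train]) == 0.0:
                    logger.warning("degenerate fold: constant target %s", name)
                model = clone(regressor)
                model.fit(x[train], yt[train])
                fold[name] = (yt[test], np.asarray(model.predict(x[test]), float))
            folds.append(fold)
    return folds


# ---------------------------------------------------------------------------
# metrics


def pcc_ci(fold_pccs: Sequence[float], confidence: float = 0.95) -> tuple[float, float, bool]:
    """Mean PCC and 95% CI half-width via a t-interval on Fisher z values.

    Each fold PCC is z-transformed (arctanh); a Student-t interval with
    df = folds - 1 is formed on the z scale and its endpoints transformed
    back.  Returns ``(mean, halfwidth, degenerate)`` where the mean is the
    back-transformed mean z; |r| = 1 folds make the interval degenerate.
    """
    r = np.asarray(fold_pccs, float)
    if r.size < 2:
        raise ValueError("need at least 2 fold PCCs")
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("fold PCC of +/-1: Fisher z is infinite, interval degenerate")
        return float(np.mean(r)), float("inf"), True
    z = np.arctanh(r)
    zm = z.mean()
    se = z.std(ddof=1) / np.sqrt(z.size)
    if se == 0.0:
        return float(np.tanh(zm)), 0.0, False
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=z.size - 1)
    lo, hi = np.tanh(zm - tcrit * se), np.tanh(zm + tcrit * se)
    return float(np.tanh(zm)), float((hi - lo) / 2.0), False


def nrmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """RMSE normalized by the population (n-denominator) sd of the target."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    sd = y_true.std()
    if sd == 0.0:
        raise ValueError("target has zero standard deviation")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)) / sd)


def nrmse_ci(
    y_true: np.ndarray, y_pred: np.ndarray, b: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Normalized RMSE with a symmetric 95% empirical bootstrap interval.

    Paired resamples; the half-width is the 97.5th percentile of the absolute
    bootstrap deviations from the point estimate.
    """
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.size != y_pred.size or y_true.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    point = nrmse(y_true, y_pred)
    rng = np.random.default_rng(seed)
    devs = np.empty(b)
    for i in range(b):
        idx = rng.integers(y_true.size, size=y_true.size)
        yt = y_true[idx]
        if yt.std() == 0.0:
            devs[i] = 0.0
            continue
        devs[i] = nrmse(yt, y_pred[idx]) - point
    half = float(np.percentile(np.abs(devs), 97.5))
    return point, half


def shapiro_gate(values: Sequence[float], alpha: float = 0.05) -> tuple[float, bool]:
    """Shapiro-Wilk normality check; warns below alpha but never blocks."""
    v = np.asarray(values, float)
    if not 3 <= v.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0.0:
        warnings.warn("constant input to normality gate: degenerate")
        return 0.0, False
    p = float(stats.shapiro(v).pvalue)
    if p < alpha:
        warnings.warn(f"normality gate: Shapiro-Wilk p={p:.3g} < {alpha}")
    return p, p >= alpha


# ---------------------------------------------------------------------------
# benchmark driver


def benchmark(
    fps: Mapping[str, FingerprintMatrix],
    tuples: pd.DataFrame,
    regressor=None,
    splits: Sequence[str] = ("90:10",),
    k: int = 10,
    repeats: int = 1,
    seed: int = 0,
    bootstrap: int = 1000,
) -> pd.DataFrame:
    """One result row per (fingerprint x score x split); best-per-score flagged."""
    if regressor is None:
        regressor = make_regressor("gbdt")
    agg = aggregate_tuples(tuples)
    results: list[BenchResult] = []
    for split in splits:
        for name, fp in fps.items():
            x, y, _ = build_design(agg, fp)
            folds = run_cv(x, y, regressor, split=split, k=k, repeats=repeats, seed=seed)
            for j, score in enumerate(SCORES[: y.shape[1]]):
                fold_pccs = [
                    stats.pearsonr(f[score][0], f[score][1]).statistic for f in folds
                ]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sp, _ = shapiro_gate(np.arctanh(np.clip(fold_pccs, -0.999999, 0.999999)))
                mean_pcc, pcc_half, degen = pcc_ci(fold_pccs)
                yt = np.concatenate([f[score][0] for f in folds])
                yp = np.concatenate([f[score][1] for f in folds])
                point, half = nrmse_ci(yt, yp, b=bootstrap, seed=seed)
                results.append(BenchResult(
                    fingerprint=name, score=score, split=split,
                    pcc_mean=mean_pcc, pcc_ci_halfwidth=pcc_half,
                    nrmse=point, nrmse_ci_halfwidth=half,
                    folds=k, repeats=repeats, seed=seed, shapiro_p=sp,
                    degenerate=degen,
                ))
    df = pd.DataFrame([r.__dict__ for r in results])
    df["best"] = False
    for (split, score), grp in df.groupby(["split", "score"]):
        df.loc[grp["pcc_mean"].idxmax(), "best"] = True
    return df
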