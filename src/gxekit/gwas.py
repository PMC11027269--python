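"""Mixed-linear-model association scan.

Model per tested marker x_j:

    y = C b + x_j beta + u + e,   u ~ N(0, sigma2_g K),  e ~ N(0, sigma2_e I)

with C the fixed covariates (intercept + principal components) and K a
VanRaden-style genomic relationship matrix built from the full expanded
genotype (additive plus interactive columns). Variance components are
estimated once under the null by REML on the eigendecomposition of K
(EMMA-style 1-D search over delta = sigma2_e/sigma2_g) and reused for every
marker (P3D); each marker's coefficient is tested with a two-sided t
statistic on the GLS estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

EIG_FLOOR = 1e-8


@dataclass
class Kinship:
    """Genomic relationship matrix (VanRaden centered cross-product)."""

    K: np.ndarray
    builder: str = "vanraden"
    source: str = "gbye_full"


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    delta: float  # sigma2_e / sigma2_g
    loglik: float


def compute_kinship(X: np.ndarray, source: str = "gbye_full") -> Kinship:
    """K = Z Z' / c with Z column-centered X and c the summed column variances.

    The scaling makes the mean diagonal exactly 1 on polymorphic data;
    zero-variance columns contribute nothing.
    """
    X = np.asarray(X, dtype=float)
    Z = X - X.mean(axis=0)
    c = float((Z * Z).mean(axis=0).sum())
    if c == 0:
        raise ValueError("all columns have zero variance; kinship undefined")
    K = (Z @ Z.T) / c
    K = 0.5 * (K + K.T)
    return Kinship(K, source=source)


def compute_pcs(X: np.ndarray, k: int = 3) -> np.ndarray:
    """First k principal-component scores of the column-centered matrix.

    Sign convention: each component's largest-magnitude loading is positive.
    """
    X = np.asarray(X, dtype=float)
    if k >= X.shape[0]:
        raise ValueError(f"k={k} must be < number of rows {X.shape[0]}")
    Z = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] *= -1
    return scores


def _floor_eigh(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d, U = np.linalg.eigh(K)
    return np.maximum(d, EIG_FLOOR), U


def _reml_neg_loglik(log_delta, yt, Xt, d, logdet_xtx):
    """-2x restricted log-likelihood profiled over b and sigma2_g."""
    delta = np.exp(log_delta)
    w = d + delta
    Xw = Xt / w[:, None]
    A = Xt.T @ Xw
    b = np.linalg.solve(A, Xw.T @ yt)
    r = yt - Xt @ b
    nq = len(yt) - Xt.shape[1]
    rss = float(r @ (r / w))
    sign, logdet_a = np.linalg.slogdet(A)
    ll = -0.5 * (
        nq * (np.log(2 * np.pi * rss / nq) + 1)
        + np.log(w).sum()
        + logdet_a
        - logdet_xtx
    )
    return -ll


def fit_null_reml(y: np.ndarray, covariates: np.ndarray, K: np.ndarray) -> VarianceComponents:
    """EMMA-style REML: eigendecompose K once, 1-D search over delta.

    ``covariates`` should include the intercept column. The search runs a
    log-spaced grid over delta in [1e-5, 1e5] followed by bounded refinement
    around the best grid point.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    d, U = _floor_eigh(np.asarray(K, dtype=float))
    yt = U.T @ y
    Xt = U.T @ X
    _, logdet_xtx = np.linalg.slogdet(X.T @ X)

    grid = np.log(np.logspace(-5, 5, 61))
    vals = [_reml_neg_loglik(g, yt, Xt, d, logdet_xtx) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), method="bounded",
        args=(yt, Xt, d, logdet_xtx), options={"xatol": 1e-8},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"REML delta search failed to converge: {res}")
    log_delta = res.x if res.fun <= vals[i] else grid[i]
    delta = float(np.exp(log_delta))
    w = d + delta
    Xw = Xt / w[:, None]
    A = Xt.T @ Xw
    b = np.linalg.solve(A, Xw.T @ yt)
    r = yt - Xt @ b
    nq = len(y) - X.shape[1]
    sigma2_g = float(r @ (r / w)) / nq
    return VarianceComponents(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_g * delta,
        delta=delta,
        loglik=-_reml_neg_loglik(np.log(delta), yt, Xt, d, logdet_xtx),
    )


def mlm_scan(
    y: np.ndarray,
    markers: np.ndarray,
    marker_ids=None,
    effect_classes=None,
    covariates: np.ndarray | None = None,
    K: np.ndarray | None = None,
    p3d: bool = True,
    vc: VarianceComponents | None = None,
) -> pd.DataFrame:
    """Scan every marker column with a GLS t-test at fixed variance ratio.

    ``covariates`` excludes the intercept (added internally). With K=None or
    sigma2_g=0 the scan reduces exactly to OLS t-tests. Monomorphic or
    covariate-collinear markers are skipped (p=1, ``skipped``=True).
    Returns a DataFrame with one row per marker: marker_id, effect_class,
    beta, se, t, df, p, skipped.
    """
    y = np.asarray(y, dtype=float)
    markers = np.asarray(markers, dtype=float)
    N, M = markers.shape
    if marker_ids is None:
        marker_ids = [f"m{j}" for j in range(M)]
    if effect_classes is None:
        effect_classes = ["additive"] * M
    X0 = np.ones((N, 1))
    if covariates is not None and np.size(covariates):
        X0 = np.hstack([X0, np.atleast_2d(np.asarray(covariates, dtype=float))])

    if K is not None and (vc is None or vc.sigma2_g > 0):
        if vc is None:
            vc = fit_null_reml(y, X0, K)
        if not p3d:
            return _exact_scan(y, markers, marker_ids, effect_classes, X0, K)
        d, U = _floor_eigh(np.asarray(K, dtype=float))
        w = d + vc.delta
        sw = 1.0 / np.sqrt(w)
        yt = (U.T @ y) * sw
        X0t = (U.T @ X0) * sw[:, None]
        Mt = (U.T @ markers) * sw[:, None]
    else:
        yt, X0t, Mt = y, X0, markers

    q = X0t.shape[1]
    p_cols = q + 1
    df = N - p_cols
    rows = []
    # Precompute pieces of the blockwise normal equations for speed.
    A00 = X0t.T @ X0t
    A00_inv = np.linalg.inv(A00)
    X0ty = X0t.T @ yt
    for j in range(M):
        x = Mt[:, j]
        if markers[:, j].std() == 0:
            rows.append((marker_ids[j], effect_classes[j], np.nan, np.nan, np.nan, df, 1.0, True))
            continue
        a01 = X0t.T @ x
        a11 = float(x @ x)
        schur = a11 - float(a01 @ A00_inv @ a01)
        if schur <= 1e-10 * a11:
            rows.append((marker_ids[j], effect_classes[j], np.nan, np.nan, np.nan, df, 1.0, True))
            continue
        xty = float(x @ yt)
        beta = (xty - float(a01 @ A00_inv @ X0ty)) / schur
        b0 = A00_inv @ (X0ty - a01 * beta)
        r = yt - X0t @ b0 - x * beta
        s2 = float(r @ r) / df
        se = np.sqrt(s2 / schur)
        t = beta / se
        p = 2 * stats.t.sf(abs(t), df)
        rows.append((marker_ids[j], effect_classes[j], beta, se, t, df, max(p, np.finfo(float).tiny), False))
    return pd.DataFrame(
        rows, columns=["marker_id", "effect_class", "beta", "se", "t", "df", "p", "skipped"]
    )


def _exact_scan(y, markers, marker_ids, effect_classes, X0, K):
    """Per-marker REML re-estimation (slow; the `--exact` path)."""
    N, M = markers.shape
    rows = []
    for j in range(M):
        x = markers[:, j]
        if x.std() == 0:
            rows.append((marker_ids[j], effect_classes[j], np.nan, np.nan, np.nan, N - X0.shape[1] - 1, 1.0, True))
            continue
        Xj = np.hstack([X0, x[:, None]])
        vc = fit_null_reml(y, Xj, K)
        sub = mlm_scan(
            y, x[:, None], [marker_ids[j]], [effect_classes[j]],
            covariates=X0[:, 1:] if X0.shape[1] > 1 else None, K=K, vc=vc,
        )
        rows.append(tuple(sub.iloc[0]))
    return pd.DataFrame(
        rows, columns=["marker_id", "effect_class", "beta", "se", "t", "df", "p", "skipped"]
    )


def collapse_pvalues(results: pd.DataFrame, mode: str = "min") -> pd.DataFrame:
    """Collapse the s tests per original marker to one row.

    GbyE produces one additive and s-1 interactive tests per marker;
    ``mode="min"`` keeps the smallest p (recording the winning effect
    class), ``mode="bonf-min"`` multiplies it by the number of copies,
    capped at 1.
    """
    if mode not in ("min", "bonf-min"):
        raise ValueError(f"unknown collapse mode {mode!r}")
    if "marker_id" not in results.columns:
        raise ValueError("results must carry a marker_id column for grouping")
    out = []
    for marker, grp in results.groupby("marker_id", sort=False):
        i = grp["p"].idxmin()
        row = grp.loc[i].copy()
        if mode == "bonf-min":
            row["p"] = min(1.0, row["p"] * len(grp))
        out.append(row)
    df = pd.DataFrame(out).reset_index(drop=True)
    return df


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """alpha / (number of tests); with GbyE, n_tests counts all s*m columns."""
    return alpha / n_tests


def write_results(results: pd.DataFrame, marker_map: pd.DataFrame, path, sep: str = "\t"):
    """Write the scan table joined with chromosome/position."""
    mm = marker_map.rename(columns={"id": "marker_id"})
    out = results.merge(mm, on="marker_id", how="left")
    cols = ["marker_id", "chrom", "pos", "effect_class", "beta", "se", "t", "df", "p", "skipped"]
    out[cols].to_csv(path, sep=sep, index=False)
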