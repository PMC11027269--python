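"""Genomic prediction engines.

Two families:

* :func:`gblup_fit` — kinship-based mixed model y = 1*mu + u + e with
  u ~ N(0, sigma2_u K), variance components by REML or ML on the
  eigendecomposition of the training-block kinship; gEBVs for unobserved
  individuals come from the kinship cross-block. Equivalent to ridge
  regression on centered markers (rrBLUP) when K = ZZ'/c and
  lambda = c * sigma2_e / sigma2_u.

* :func:`gibbs_fit` — single-site Gibbs samplers for whole-genome
  regression with separate marker blocks (e.g. additive and interactive):
  BRR (Gaussian, one variance per block), BayesA (marker-specific scaled-t
  variances), BayesB (point-mass mixture, fixed pi), BayesCpi (common slab
  variance, pi sampled), and BL (Bayesian LASSO, double-exponential via
  exponential scale mixture). Hyper-prior scales follow the R2-rule with
  R2 = 0.5 and df = 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

KINSHIP_RIDGE = 1e-8


@dataclass
class GBLUPFit:
    mu: float
    u_hat: np.ndarray  # gEBV for all N rows of K
    sigma2_u: float
    sigma2_e: float
    method: str
    loglik: float

    def predictions(self) -> np.ndarray:
        return self.mu + self.u_hat


def _gblup_neg_loglik(log_delta, yt, ot, d, reml: bool):
    """-loglik profiled over mu and sigma2_u; delta = sigma2_e/sigma2_u."""
    delta = np.exp(log_delta)
    w = d + delta
    n = len(yt)
    a = float(ot @ (ot / w))
    b = float(ot @ (yt / w)) / a
    r = yt - ot * b
    rss = float(r @ (r / w))
    if reml:
        nq = n - 1
        ll = -0.5 * (nq * (np.log(2 * np.pi * rss / nq) + 1) + np.log(w).sum() + np.log(a))
    else:
        ll = -0.5 * (n * (np.log(2 * np.pi * rss / n) + 1) + np.log(w).sum())
    return -ll


def gblup_fit(
    y: np.ndarray,
    K: np.ndarray,
    method: str = "REML",
    var_components: tuple[float, float] | None = None,
) -> GBLUPFit:
    """Fit GBLUP on the non-missing rows of ``y`` and predict every row.

    ``y`` has NaN at rows to predict (the inference set); K covers all rows.
    ``var_components`` = (sigma2_u, sigma2_e) skips estimation (used by the
    ridge-equivalence oracle). A small ridge (1e-8 I) regularizes the
    training kinship before solving.
    """
    method = method.upper()
    if method not in ("REML", "ML"):
        raise ValueError(f"method must be REML or ML, got {method!r}")
    y = np.asarray(y, dtype=float)
    K = np.asarray(K, dtype=float)
    train = ~np.isnan(y)
    if train.sum() < 3:
        raise ValueError("need at least 3 observed phenotypes to train")
    ytr = y[train]
    Ktr = K[np.ix_(train, train)] + KINSHIP_RIDGE * np.eye(int(train.sum()))
    d, U = np.linalg.eigh(Ktr)
    d = np.maximum(d, 1e-10)
    yt = U.T @ ytr
    ot = U.T @ np.ones(len(ytr))

    if var_components is None:
        reml = method == "REML"
        grid = np.log(np.logspace(-5, 5, 61))
        vals = [_gblup_neg_loglik(g, yt, ot, d, reml) for g in grid]
        i = int(np.argmin(vals))
        res = optimize.minimize_scalar(
            _gblup_neg_loglik,
            bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
            method="bounded", args=(yt, ot, d, reml), options={"xatol": 1e-8},
        )
        log_delta = res.x if res.fun <= vals[i] else grid[i]
        delta = float(np.exp(log_delta))
        w = d + delta
        a = float(ot @ (ot / w))
        mu = float(ot @ (yt / w)) / a
        r = yt - ot * mu
        dof = len(ytr) - 1 if reml else len(ytr)
        sigma2_u = float(r @ (r / w)) / dof
        sigma2_e = sigma2_u * delta
        loglik = -_gblup_neg_loglik(np.log(delta), yt, ot, d, reml)
    else:
        sigma2_u, sigma2_e = var_components
        if sigma2_u <= 0:
            raise ValueError("sigma2_u must be positive")
        delta = sigma2_e / sigma2_u
        w = d + delta
        a = float(ot @ (ot / w))
        mu = float(ot @ (yt / w)) / a
        loglik = -_gblup_neg_loglik(np.log(delta), yt, ot, d, method == "REML")

    # BLUP of u for all rows: u = sigma2_u * K[:, train] V^{-1} (y - mu)
    # with V = sigma2_u * Ktr + sigma2_e * I, done in the eigenbasis.
    resid = yt - ot * mu
    vinv_r = U @ (resid / (d + delta))  # = (Ktr + delta I)^{-1} (ytr - mu)
    u_hat = K[:, train] @ vinv_r
    # training rows use the regularized Ktr (consistent with the solve)
    u_hat[train] = Ktr @ vinv_r
    return GBLUPFit(mu, u_hat, float(sigma2_u), float(sigma2_e), method, float(loglik))


@dataclass
class BayesFit:
    model: str
    mu: float
    beta_mean: list[np.ndarray]       # posterior-mean effects per block
    block_means: list[np.ndarray]     # column means used for centering
    hyper_draws: dict[str, np.ndarray] = field(default_factory=dict)
    niter: int = 0
    burnin: int = 0
    thin: int = 1
    seed: int | None = None


def _scaled_inv_chi2(rng, df: float, scale: float) -> float:
    """Draw from scaled-inv-chi2(df, scale): df*scale / chi2_df."""
    return df * scale / rng.chisquare(df)


def gibbs_fit(
    y: np.ndarray,
    X_blocks: list[np.ndarray],
    model: str = "BRR",
    niter: int = 1500,
    burnin: int = 500,
    thin: int = 1,
    seed: int | None = None,
    pi0: float = 0.5,
    R2: float = 0.5,
    df_prior: float = 5.0,
    fix_resid_var: float | None = None,
    fix_block_var: float | None = None,
) -> BayesFit:
    """Single-site Gibbs sampler for block-structured whole-genome regression.

    ``y`` may contain NaN (those rows are dropped from training; centering
    means are stored for prediction). ``fix_resid_var``/``fix_block_var``
    clamp the variances (conjugate-ridge validation mode, BRR only).
    """
    model = model.upper()
    if model not in ("BRR", "BAYESA", "BAYESB", "BAYESCPI", "BL"):
        raise ValueError(f"unknown model {model!r}")
    if niter <= burnin:
        raise ValueError("niter must exceed burnin")
    rng = np.random.default_rng(seed)
    train = ~np.isnan(np.asarray(y, dtype=float))
    yt = np.asarray(y, dtype=float)[train]
    n = len(yt)
    blocks, means = [], []
    for X in X_blocks:
        X = np.asarray(X, dtype=float)[train]
        mu_cols = X.mean(axis=0)
        blocks.append(X - mu_cols)
        means.append(mu_cols)
    nb = len(blocks)
    p_b = [X.shape[1] for X in blocks]
    xx = [np.einsum("ij,ij->j", X, X) for X in blocks]

    vy = yt.var(ddof=1) if n > 1 else 1.0
    # R2-rule prior scales (genetic R2 split evenly across blocks)
    S_e = vy * (1.0 - R2)
    msx = [max(v.sum() / 1.0, 1e-12) for v in [np.var(X, axis=0) for X in blocks]]
    S_b = [vy * R2 / nb / m for m in msx]

    mu = float(yt.mean())
    e = yt - mu
    beta = [np.zeros(p) for p in p_b]
    sigma2_e = fix_resid_var if fix_resid_var is not None else max(vy * (1 - R2), 1e-8)
    sigma2_b = [fix_block_var if fix_block_var is not None else max(s, 1e-8) for s in S_b]
    var_marker = [np.full(p, sb) for p, sb in zip(p_b, sigma2_b)]  # BayesA/B
    tau2 = [np.ones(p) for p in p_b]  # BL
    lam2 = [1.0] * nb  # BL lambda^2 per block
    pi = [pi0] * nb  # inclusion probability (BayesB fixed, BayesCpi sampled)
    incl = [np.ones(p, dtype=bool) for p in p_b]

    n_keep = (niter - burnin) // thin
    beta_sum = [np.zeros(p) for p in p_b]
    mu_sum = 0.0
    draws: dict[str, list] = {f"sigma2_block{b}": [] for b in range(nb)}
    draws["sigma2_e"] = []
    if model == "BAYESCPI":
        for b in range(nb):
            draws[f"pi_block{b}"] = []

    kept = 0
    for it in range(niter):
        # intercept
        e += mu
        mu = rng.normal(e.mean(), np.sqrt(sigma2_e / n))
        e -= mu
        for b in range(nb):
            X, bb = blocks[b], beta[b]
            if model == "BRR":
                vb = sigma2_b[b]
                for j in range(p_b[b]):
                    xj = X[:, j]
                    old = bb[j]
                    rhs = xj @ e + xx[b][j] * old
                    prec = xx[b][j] / sigma2_e + 1.0 / vb
                    mean = (rhs / sigma2_e) / prec
                    new = rng.normal(mean, np.sqrt(1.0 / prec))
                    e += xj * (old - new)
                    bb[j] = new
                if fix_block_var is None:
                    ss = float(bb @ bb)
                    sigma2_b[b] = _scaled_inv_chi2(
                        rng, df_prior + p_b[b], (df_prior * S_b[b] + ss) / (df_prior + p_b[b])
                    )
            elif model in ("BAYESA", "BAYESB"):
                vm = var_marker[b]
                for j in range(p_b[b]):
                    xj = X[:, j]
                    old = bb[j]
                    rhs = xj @ e + xx[b][j] * old
                    if model == "BAYESB":
                        # marginal log-odds of inclusion at current variances
                        v1 = xx[b][j] * sigma2_e + xx[b][j] ** 2 * vm[j]
                        v0 = xx[b][j] * sigma2_e
                        if v1 <= 0 or v0 <= 0:
                            keep_in = False
                        else:
                            log_bf = 0.5 * (np.log(v0) - np.log(v1)) + 0.5 * rhs**2 * (
                                1.0 / v0 - 1.0 / v1
                            )
                            log_odds = np.log(pi[b] / (1 - pi[b])) + log_bf if pi[b] < 1 else np.inf
                            keep_in = np.log(rng.uniform()) < -np.logaddexp(0.0, -log_odds)
                        if not keep_in:
                            e += xj * old
                            bb[j] = 0.0
                            incl[b][j] = False
                            vm[j] = _scaled_inv_chi2(rng, df_prior, S_b[b])
                            continue
                        incl[b][j] = True
                    prec = xx[b][j] / sigma2_e + 1.0 / vm[j]
                    mean = (rhs / sigma2_e) / prec
                    new = rng.normal(mean, np.sqrt(1.0 / prec))
                    e += xj * (old - new)
                    bb[j] = new
                    vm[j] = _scaled_inv_chi2(
                        rng, df_prior + 1, (df_prior * S_b[b] + new**2) / (df_prior + 1)
                    )
                sigma2_b[b] = float(vm.mean())
            elif model == "BAYESCPI":
                vb = sigma2_b[b]
                for j in range(p_b[b]):
                    xj = X[:, j]
                    old = bb[j]
                    rhs = xj @ e + xx[b][j] * old
                    v1 = xx[b][j] * sigma2_e + xx[b][j] ** 2 * vb
                    v0 = xx[b][j] * sigma2_e
                    log_bf = 0.5 * (np.log(v0) - np.log(v1)) + 0.5 * rhs**2 * (
                        1.0 / v0 - 1.0 / v1
                    )
                    log_odds = (
                        np.inf if pi[b] >= 1 else np.log(pi[b] / (1 - pi[b])) + log_bf
                    )
                    if np.log(rng.uniform()) < -np.logaddexp(0.0, -log_odds):
                        incl[b][j] = True
                        prec = xx[b][j] / sigma2_e + 1.0 / vb
                        mean = (rhs / sigma2_e) / prec
                        new = rng.normal(mean, np.sqrt(1.0 / prec))
                    else:
                        incl[b][j] = False
                        new = 0.0
                    e += xj * (old - new)
                    bb[j] = new
                k_in = int(incl[b].sum())
                ss = float(bb @ bb)
                sigma2_b[b] = _scaled_inv_chi2(
                    rng, df_prior + k_in, (df_prior * S_b[b] + ss) / (df_prior + k_in)
                )
                pi[b] = rng.beta(k_in + 1, p_b[b] - k_in + 1)
            else:  # BL — Park & Casella scale mixture
                t2 = tau2[b]
                for j in range(p_b[b]):
                    xj = X[:, j]
                    old = bb[j]
                    rhs = xj @ e + xx[b][j] * old
                    prec = xx[b][j] / sigma2_e + 1.0 / (t2[j] * sigma2_e)
                    mean = (rhs / sigma2_e) / prec
                    new = rng.normal(mean, np.sqrt(1.0 / prec))
                    e += xj * (old - new)
                    bb[j] = new
                    b2 = max(new**2, 1e-12)
                    inv_tau2 = rng.wald(np.sqrt(lam2[b] * sigma2_e / b2), lam2[b])
                    t2[j] = 1.0 / max(inv_tau2, 1e-12)
                # lambda^2 ~ Gamma(shape, rate) update (BGLR-style)
                lam2[b] = rng.gamma(p_b[b] + 1.2, 1.0 / (t2.sum() / 2.0 + 1.2))
                sigma2_b[b] = float((t2 * sigma2_e).mean())
        if fix_resid_var is None:
            ss_e = float(e @ e)
            if model == "BL":
                # residual variance also scales the BL prior; include beta term
                ss_beta = sum(float(beta[b] @ (beta[b] / tau2[b])) for b in range(nb))
                ptot = sum(p_b)
                sigma2_e = _scaled_inv_chi2(
                    rng, df_prior + n + ptot,
                    (df_prior * S_e + ss_e + ss_beta) / (df_prior + n + ptot),
                )
            else:
                sigma2_e = _scaled_inv_chi2(
                    rng, df_prior + n, (df_prior * S_e + ss_e) / (df_prior + n)
                )
        if not np.isfinite(sigma2_e) or sigma2_e <= 0:
            raise RuntimeError(f"residual variance diverged at iteration {it}")
        if it >= burnin and (it - burnin) % thin == 0:
            kept += 1
            mu_sum += mu
            for b in range(nb):
                beta_sum[b] += beta[b]
                draws[f"sigma2_block{b}"].append(sigma2_b[b])
                if model == "BAYESCPI":
                    draws[f"pi_block{b}"].append(pi[b])
            draws["sigma2_e"].append(sigma2_e)

    return BayesFit(
        model=model,
        mu=mu_sum / kept,
        beta_mean=[s / kept for s in beta_sum],
        block_means=means,
        hyper_draws={k: np.asarray(v) for k, v in draws.items()},
        niter=niter, burnin=burnin, thin=thin, seed=seed,
    )


def predict_gebv(fit: BayesFit, X_blocks: list[np.ndarray]) -> np.ndarray:
    """intercept + sum over blocks of (X - training column means) @ beta."""
    if len(X_blocks) != len(fit.beta_mean):
        raise ValueError("block count mismatch with fitted model")
    out = None
    for X, beta, mu_cols in zip(X_blocks, fit.beta_mean, fit.block_means):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(beta):
            raise ValueError("column count mismatch with fitted block")
        term = (X - mu_cols) @ beta
        out = term if out is None else out + term
    return fit.mu + out


@dataclass
class PredictionAccuracy:
    r: float
    n_test: int
    env: str | None = None
    undefined: bool = False


def accuracy(pred: np.ndarray, observed: np.ndarray, env: str | None = None) -> PredictionAccuracy:
    """Pearson correlation between predictions and observed phenotypes.

    Pairs with a missing value in either vector are dropped; fewer than 3
    pairs or zero variance flags the result undefined (r = NaN).
    """
    pred = np.asarray(pred, dtype=float)
    observed = np.asarray(observed, dtype=float)
    ok = ~(np.isnan(pred) | np.isnan(observed))
    p, o = pred[ok], observed[ok]
    if len(p) < 3 or p.std() == 0 or o.std() == 0:
        return PredictionAccuracy(np.nan, int(len(p)), env, undefined=True)
    r = float(np.corrcoef(p, o)[0, 1])
    return PredictionAccuracy(r, int(len(p)), env)
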