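"""Cross-validated genomic prediction: expanded G-by-E encoding vs the
environment-mean comparator, with missing-environment masking schemes.

Folds are drawn at the individual level so both environment rows of one
individual share a fold. Masking schemes on the stacked phenotype:

* ``standard`` / ``double_env_missing`` — every environment row of an
  inference individual is masked (prediction from marker/kinship
  information only).
* ``single_env_missing`` — only the chosen environment's row is masked;
  the other environment's phenotype stays in training, so prediction can
  borrow strength through the kinship between an individual's two rows.

Accuracy is the Pearson correlation between predicted gEBV and the
observed (normalized) phenotype of the masked cells, overall and per
environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import encoding, gs, gwas
from .data_io import GenotypeMatrix, PhenotypeTable

SCHEMES = ("standard", "single_env_missing", "double_env_missing")
METHODS = ("gbye", "mean", "additive", "interactive")


@dataclass
class CVScheme:
    k: int = 5
    reps: int = 10
    masking: str = "standard"
    missing_env: int = 1  # 0-based env index masked in single_env mode
    seed: int | None = None

    def __post_init__(self):
        if self.masking not in SCHEMES:
            raise ValueError(f"unknown masking scheme {self.masking!r}")


@dataclass
class CVResult:
    records: pd.DataFrame  # rep, fold, method, env, accuracy, n_test
    scheme: CVScheme
    n_failed: int = 0

    def summary(self) -> pd.DataFrame:
        grp = self.records[self.records["env"] == "all"].groupby("method")["accuracy"]
        return pd.DataFrame({"mean": grp.mean(), "sd": grp.std()}).reset_index()


def kfold_split(n_or_ids, k: int, seed=None) -> np.ndarray:
    """Random near-equal partition; returns a fold label (0..k-1) per individual."""
    n = n_or_ids if isinstance(n_or_ids, int) else len(n_or_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds number of individuals {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        labels[chunk] = f
    return labels


def apply_masking(
    y_stacked: np.ndarray,
    inference: np.ndarray,
    scheme: str,
    s: int,
    missing_env: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Mask phenotype cells of inference individuals on the stacked vector.

    ``inference`` is a boolean vector over individuals (length n); the
    stacked vector is environment-major of length s*n. Returns the masked
    copy and the boolean mask of blanked cells.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown masking scheme {scheme!r}")
    n = len(inference)
    if len(y_stacked) != s * n:
        raise ValueError("stacked phenotype length must be s * n")
    mask = np.zeros(s * n, dtype=bool)
    if scheme == "single_env_missing":
        if not 0 <= missing_env < s:
            raise ValueError(f"missing_env {missing_env} out of range")
        mask[missing_env * n:(missing_env + 1) * n] = inference
    else:
        for e in range(s):
            mask[e * n:(e + 1) * n] = inference
    y = np.asarray(y_stacked, dtype=float).copy()
    y[mask] = np.nan
    return y, mask


def _env_of_cells(mask: np.ndarray, s: int, env_names: list[str]) -> np.ndarray:
    n = len(mask) // s
    return np.repeat(env_names, n)[mask]


def _fit_predict(y_masked, K, X_blocks, engine, engine_params):
    """Return predictions for all rows from the requested engine."""
    if engine == "gblup":
        fit = gs.gblup_fit(y_masked, K, **engine_params)
        return fit.predictions()
    fit = gs.gibbs_fit(y_masked, X_blocks, model=engine, **engine_params)
    return gs.predict_gebv(fit, X_blocks)


def run_cv(
    G: GenotypeMatrix,
    pheno: PhenotypeTable,
    scheme: CVScheme | None = None,
    engine: str = "gblup",
    engine_params: dict | None = None,
    methods=("gbye", "mean"),
    standardize: bool = True,
) -> CVResult:
    """k-fold x repeated CV comparing encoding strategies on shared folds.

    Methods: ``gbye`` (full expanded kinship / both marker blocks),
    ``additive`` / ``interactive`` (single block), ``mean``
    (environment-average phenotype with the plain genotype kinship).
    ``standardize=False`` skips the per-environment z-score (raw phenotypes
    stacked as-is).
    """
    scheme = scheme or CVScheme()
    engine_params = dict(engine_params or {})
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    design = encoding.build_env_design(pheno.s, env_names=list(pheno.env_names))
    X = encoding.expand_genotypes(G, design)
    if standardize:
        y_stack = encoding.normalize_stack_phenotypes(pheno, design).y
    else:
        y_stack = np.concatenate([pheno.values[:, e] for e in range(pheno.s)])
    add_block, int_block = X.additive, X.interactive

    needs_marker_engine = engine != "gblup"
    K_by_method, blocks_by_method = {}, {}
    for m in methods:
        if m == "gbye":
            blocks_by_method[m] = [add_block, int_block]
        elif m == "additive":
            blocks_by_method[m] = [add_block]
        elif m == "interactive":
            blocks_by_method[m] = [int_block]
        else:
            blocks_by_method[m] = [G.values.astype(float)]
        if not needs_marker_engine:
            K_by_method[m] = gwas.compute_kinship(np.hstack(blocks_by_method[m]), source=m).K

    y_mean = encoding.mean_phenotype(pheno)
    n, s = G.n, pheno.s
    rng = np.random.default_rng(scheme.seed)
    records = []
    n_failed = 0
    for rep in range(scheme.reps):
        folds = kfold_split(n, scheme.k, rng)
        for f in range(scheme.k):
            inference = folds == f
            y_masked, cell_mask = apply_masking(
                y_stack, inference, scheme.masking, s, scheme.missing_env
            )
            for m in methods:
                try:
                    if m == "mean":
                        ym = y_mean.copy()
                        ym[inference] = np.nan
                        pred = _fit_predict(
                            ym, K_by_method.get(m), blocks_by_method[m], engine, engine_params
                        )
                        obs = y_mean[inference]
                        p_inf = pred[inference]
                        acc = gs.accuracy(p_inf, obs)
                        records.append((rep, f, m, "all", acc.r, acc.n_test))
                        # per-environment: same gEBV against each env's phenotype
                        for e, env in enumerate(pheno.env_names):
                            if scheme.masking == "single_env_missing" and e != scheme.missing_env:
                                continue
                            col = y_stack[e * n:(e + 1) * n][inference]
                            a = gs.accuracy(p_inf, col, env=env)
                            records.append((rep, f, m, env, a.r, a.n_test))
                    else:
                        pred = _fit_predict(
                            y_masked, K_by_method.get(m), blocks_by_method[m], engine, engine_params
                        )
                        obs = y_stack[cell_mask]
                        p_inf = pred[cell_mask]
                        acc = gs.accuracy(p_inf, obs)
                        records.append((rep, f, m, "all", acc.r, acc.n_test))
                        cell_envs = _env_of_cells(cell_mask, s, list(pheno.env_names))
                        for env in pheno.env_names:
                            sel = cell_envs == env
                            if sel.sum() == 0:
                                continue
                            a = gs.accuracy(p_inf[sel], obs[sel], env=env)
                            records.append((rep, f, m, env, a.r, a.n_test))
                except (np.linalg.LinAlgError, RuntimeError):
                    n_failed += 1
    df = pd.DataFrame(
        records, columns=["rep", "fold", "method", "env", "accuracy", "n_test"]
    )
    return CVResult(df, scheme, n_failed)


def compare_methods(result: CVResult, baseline: str = "mean") -> pd.DataFrame:
    """Per-method summary with relative change vs the baseline method.

    Relative change = (mean_method - mean_baseline) / mean_baseline on the
    overall accuracies; significance from a paired two-sided t-test on
    per-rep mean accuracies (methods share fold assignments by design).
    """
    df = result.records[result.records["env"] == "all"]
    if baseline not in set(df["method"]):
        raise ValueError(f"baseline method {baseline!r} not present in results")
    per_rep = df.groupby(["method", "rep"])["accuracy"].mean().unstack(level="rep")
    base = per_rep.loc[baseline]
    rows = []
    for m in per_rep.index:
        vals = per_rep.loc[m]
        rel = (vals.mean() - base.mean()) / abs(base.mean()) if base.mean() != 0 else np.nan
        if m == baseline or len(vals) < 2:
            p = 1.0 if m == baseline else np.nan
        else:
            ok = ~(vals.isna() | base.isna())
            d = (vals[ok] - base[ok]).to_numpy()
            if ok.sum() < 2 or np.allclose(d, 0):
                p = 1.0
            elif d.std(ddof=1) < 1e-12:
                p = 0.0  # constant nonzero paired difference
            else:
                p = float(stats.ttest_rel(vals[ok], base[ok]).pvalue)
        rows.append((m, vals.mean(), vals.std(), rel, p))
    return pd.DataFrame(
        rows, columns=["method", "mean_accuracy", "sd", "relative_change_vs_baseline", "paired_p"]
    )
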