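"""Multi-environment phenotype simulation.

Phenotypes for s environments are generated from a shared set of QTNs
(quantitative trait nucleotides): per-QTN effect vectors are drawn from a
mean-zero multivariate normal with compound-symmetric correlation r (the
genetic correlation between environments), genetic values are G[:, qtn] @
effects, and i.i.d. normal residuals are added per environment with SD
scaled from the realized sample genetic variance so that
var(g)/(var(g)+var(e)) targets the requested heritability h2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import GenotypeMatrix, PhenotypeTable


@dataclass
class SimTruth:
    """Ground truth of a simulation: QTN positions and per-env effect sizes."""

    qtn_indices: np.ndarray  # NQTN marker column indices into the genotype
    effects: np.ndarray      # NQTN x s
    h2: float
    r: float
    seed: int | None = None

    @property
    def nqtn(self) -> int:
        return len(self.qtn_indices)


@dataclass
class SimResult:
    phenotypes: PhenotypeTable
    truth: SimTruth
    genetic_values: np.ndarray  # n x s
    realized_h2: np.ndarray     # per environment


def sample_qtn(G: GenotypeMatrix, nqtn: int, seed=None) -> np.ndarray:
    """Draw ``nqtn`` distinct QTN indices uniformly from polymorphic markers."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    poly = np.flatnonzero(~G.monomorphic)
    if not 1 <= nqtn <= poly.size:
        raise ValueError(f"nqtn={nqtn} outside [1, {poly.size}] polymorphic markers")
    return np.sort(rng.choice(poly, size=nqtn, replace=False))


def sample_effects(nqtn: int, s: int, r: float, seed=None) -> np.ndarray:
    """Draw QTN effects: rows i.i.d. MVN(0, Sigma), Sigma compound-symmetric.

    Sigma has unit diagonal and off-diagonals r; it is positive
    semi-definite only for r in (-1/(s-1), 1].
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if s == 1:
        return rng.standard_normal((nqtn, 1))
    if not (-1.0 / (s - 1) < r <= 1.0):
        raise ValueError(f"correlation r={r} makes the covariance non-PSD for s={s}")
    if r == 1.0:
        z = rng.standard_normal((nqtn, 1))
        return np.repeat(z, s, axis=1)
    sigma = np.full((s, s), r) + (1.0 - r) * np.eye(s)
    chol = np.linalg.cholesky(sigma)
    return rng.standard_normal((nqtn, s)) @ chol.T


def simulate_phenotypes(
    G: GenotypeMatrix,
    qtn_indices: np.ndarray,
    effects: np.ndarray,
    h2: float,
    seed=None,
    env_names: list[str] | None = None,
) -> SimResult:
    """Add residual noise scaled to the realized genetic variance.

    Residual SD per environment e is sqrt(var(g_e) * (1-h2)/h2) with var the
    sample variance of the realized genetic values, so the realized
    heritability matches the target in expectation even at small n.
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = effects.shape[1]
    if env_names is None:
        env_names = [f"env{j+1}" for j in range(s)]
    g = G.values[:, qtn_indices].astype(float) @ effects  # n x s
    var_g = g.var(axis=0, ddof=1)
    if np.any(var_g == 0):
        raise ValueError("zero genetic variance (all selected QTNs monomorphic?)")
    sd_e = np.sqrt(var_g * (1.0 - h2) / h2)
    resid = rng.standard_normal(g.shape) * sd_e
    phen = g + resid
    realized = g.var(axis=0, ddof=1) / phen.var(axis=0, ddof=1)
    table = PhenotypeTable(phen, env_names, list(G.individual_ids))
    truth = SimTruth(np.asarray(qtn_indices), effects, h2, np.nan)
    return SimResult(table, truth, g, realized)


def simulate(
    G: GenotypeMatrix,
    nqtn: int = 20,
    h2: float = 0.5,
    r: float = 0.5,
    s: int = 2,
    seed=None,
    env_names: list[str] | None = None,
) -> SimResult:
    """One-call simulation: sample QTNs, effects, and phenotypes.

    Defaults mirror the study grid: 20 QTNs, two environments, h2 and r each
    chosen from {0.2, 0.5, 0.8}.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    qtn = sample_qtn(G, nqtn, rng)
    effects = sample_effects(nqtn, s, r, rng)
    result = simulate_phenotypes(G, qtn, effects, h2, rng, env_names)
    result.truth.h2 = h2
    result.truth.r = r
    result.truth.seed = seed if isinstance(seed, int) else None
    return result


def write_truth(truth: SimTruth, G: GenotypeMatrix, path, sep: str = "\t"):
    """Write the QTN truth table (id, chrom, pos, per-env effects)."""
    import pandas as pd

    mm = G.marker_map.iloc[truth.qtn_indices].reset_index(drop=True)
    out = mm.copy()
    for e in range(truth.effects.shape[1]):
        out[f"effect_env{e+1}"] = truth.effects[:, e]
    out.insert(0, "qtn_index", truth.qtn_indices)
    out.to_csv(path, sep=sep, index=False)
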