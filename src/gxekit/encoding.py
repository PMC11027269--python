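"""Genotype-by-environment encoding.

The core construction: given genotypes G (n x m) and s environments, build
the environment design E (s x s, column 1 all ones = additive, column j>=2
an indicator for environment j) and expand

    GbyE = E (x) G        (Kronecker product, environment-major rows)

so that for s = 2 the expanded matrix is [[G, 0], [G, G]]: the stacked
[G; G] columns carry the additive (environment-average) effect and the
[0; G] columns carry the interaction — the environment-specific deviation
from the baseline environment. Phenotypes are z-scored per environment and
stacked in the same row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix, PhenotypeTable

ADDITIVE = "additive"


@dataclass
class EnvDesign:
    """Environment design matrix E (s x s), baseline environment first.

    Invariants: column 0 is all ones; column j >= 1 has a single 1 in row j;
    E is lower-triangular and invertible. For s = 2, E = [[1,0],[1,1]].
    """

    E: np.ndarray
    env_names: list[str]
    baseline: str

    @property
    def s(self) -> int:
        return self.E.shape[0]


def build_env_design(s: int, baseline: int = 0, env_names: list[str] | None = None) -> EnvDesign:
    """Build the s x s design: additive column plus s-1 interaction indicators.

    ``baseline`` picks which environment is the reference (row 1); the
    environment order is permuted so the baseline comes first.
    """
    if s < 2:
        raise ValueError("need at least 2 environments (s >= 2)")
    if env_names is None:
        env_names = [f"env{j+1}" for j in range(s)]
    if len(env_names) != s:
        raise ValueError("env_names length must equal s")
    if not 0 <= baseline < s:
        raise ValueError(f"baseline index {baseline} out of range")
    order = [baseline] + [j for j in range(s) if j != baseline]
    names = [env_names[j] for j in order]
    E = np.zeros((s, s), dtype=int)
    E[:, 0] = 1
    for j in range(1, s):
        E[j, j] = 1
    return EnvDesign(E, names, names[0])


@dataclass
class GbyEGenotype:
    """Expanded (s*n) x (s*m) genotype with additive and interactive blocks."""

    values: np.ndarray
    row_index: pd.DataFrame  # columns: individual_id, env (environment-major)
    col_index: pd.DataFrame  # columns: marker_id, effect_class
    n: int
    m: int
    s: int
    marker_map: pd.DataFrame
    env_names: list[str]

    @property
    def additive(self) -> np.ndarray:
        return self.values[:, : self.m]

    @property
    def interactive(self) -> np.ndarray:
        return self.values[:, self.m:]

    def env_rows(self, e: int) -> slice:
        """Row slice of environment ``e`` (0-based, baseline = 0)."""
        return slice(e * self.n, (e + 1) * self.n)


def expand_genotypes(G: GenotypeMatrix, design: EnvDesign | int) -> GbyEGenotype:
    """Kronecker-expand genotypes: block (e, j) of the result is E[e,j] * G.

    Columns are ordered additive block first (m columns), then one
    interactive block per non-baseline environment; rows are
    environment-major (all individuals of the baseline environment, then
    environment 2, ...).
    """
    if isinstance(design, int):
        design = build_env_design(design)
    s, n, m = design.s, G.n, G.m
    values = np.kron(design.E, G.values.astype(np.int16))
    row_index = pd.DataFrame(
        {
            "individual_id": np.tile(G.individual_ids, s),
            "env": np.repeat(design.env_names, n),
        }
    )
    classes = [ADDITIVE] + [f"interactive:{e}" for e in design.env_names[1:]]
    col_index = pd.DataFrame(
        {
            "marker_id": np.tile(G.marker_ids, s),
            "effect_class": np.repeat(classes, m),
        }
    )
    return GbyEGenotype(values, row_index, col_index, n, m, s, G.marker_map, design.env_names)


def split_effects(X: GbyEGenotype) -> tuple[np.ndarray, np.ndarray]:
    """Partition columns into (additive, interactive) submatrices."""
    return X.additive.copy(), X.interactive.copy()


@dataclass
class GbyEPhenotype:
    """Stacked per-environment z-scored phenotype vector (length s*n).

    Missing cells are NaN; ``norms`` records each environment's (mean, sd)
    used for the z-score, computed over non-missing values with sample SD.
    """

    y: np.ndarray
    row_index: pd.DataFrame
    env_names: list[str]
    norms: pd.DataFrame  # columns: env, mean, sd

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.y)

    def env_segment(self, e: int) -> np.ndarray:
        n = len(self.y) // len(self.env_names)
        return self.y[e * n:(e + 1) * n]


def _zscore_column(col: np.ndarray, name: str) -> tuple[np.ndarray, float, float]:
    obs = col[~np.isnan(col)]
    if obs.size < 2:
        raise ValueError(f"environment {name!r} has fewer than 2 non-missing values")
    mu = obs.mean()
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValueError(f"environment {name!r} has zero phenotypic variance")
    return (col - mu) / sd, mu, sd


def normalize_stack_phenotypes(Y: PhenotypeTable, design: EnvDesign) -> GbyEPhenotype:
    """Z-score each environment column and stack environment-major.

    The stacking follows the design's environment order (baseline first) so
    rows align with :func:`expand_genotypes`.
    """
    if Y.s != design.s:
        raise ValueError("phenotype table and design disagree on environment count")
    order = [Y.env_names.index(e) for e in design.env_names]
    segments, records = [], []
    for e in order:
        z, mu, sd = _zscore_column(Y.values[:, e], Y.env_names[e])
        segments.append(z)
        records.append((Y.env_names[e], mu, sd))
    y = np.concatenate(segments)
    row_index = pd.DataFrame(
        {
            "individual_id": np.tile(Y.individual_ids, design.s),
            "env": np.repeat(design.env_names, Y.n),
        }
    )
    norms = pd.DataFrame(records, columns=["env", "mean", "sd"])
    return GbyEPhenotype(y, row_index, design.env_names, norms)


def mean_phenotype(Y: PhenotypeTable) -> np.ndarray:
    """Comparator phenotype: per-environment z-score, then row-wise mean.

    Normalizing first puts every environment on the same scale so the
    average is not dominated by the environment with the largest variance.
    Missing entries are skipped; an individual missing everywhere yields NaN.
    """
    cols = []
    for e in range(Y.s):
        z, _, _ = _zscore_column(Y.values[:, e], Y.env_names[e])
        cols.append(z)
    Z = np.column_stack(cols)
    with np.errstate(invalid="ignore"):
        return np.nanmean(Z, axis=1)


def write_gbye_genotype(X: GbyEGenotype, path, sep: str = "\t"):
    """Write the expanded matrix with (marker, effect_class) column headers."""
    cols = [f"{m}|{c}" for m, c in zip(X.col_index["marker_id"], X.col_index["effect_class"])]
    rows = [f"{i}|{e}" for i, e in zip(X.row_index["individual_id"], X.row_index["env"])]
    pd.DataFrame(X.values, index=rows, columns=cols).to_csv(path, sep=sep, index_label="row")


def write_gbye_phenotype(y: GbyEPhenotype, path, sep: str = "\t"):
    rows = [f"{i}|{e}" for i, e in zip(y.row_index["individual_id"], y.row_index["env"])]
    pd.DataFrame({"y": y.y}, index=rows).to_csv(path, sep=sep, index_label="row")
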