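"""Genotype and phenotype input/output.

Genotypes are held as an ``n x m`` integer matrix coded 0/1/2 (copies of the
minor allele; heterozygote = 1) with a marker map (id, chromosome, position).
This module reads HapMap text and plain numeric matrices, writes numeric
matrices, and generates synthetic genotype panels so the rest of the package
is testable without external downloads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: IUPAC ambiguity codes for heterozygous single-letter calls.
_IUPAC = {
    "A": "AA", "C": "CC", "G": "GG", "T": "TT",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
}
_MISSING_CALLS = {"NN", "N", "--", "-", "00", "0", "./.", "NA", ""}

#: Standard HapMap leading metadata columns.
HAPMAP_META_COLUMNS = (
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
)


def _natural_chrom_key(chrom: str):
    """Sort key placing numeric chromosome names in natural order (1,2,...,10)."""
    s = str(chrom)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


@dataclass
class GenotypeMatrix:
    """Numeric genotypes for ``n`` individuals at ``m`` markers.

    values[i, j] is the minor-allele dosage of individual i at marker j,
    in {0, 1, 2}. ``marker_map`` has one row per marker with columns
    ``id``, ``chrom``, ``pos`` (bp), aligned to the columns of ``values``.
    """

    values: np.ndarray
    individual_ids: list[str]
    marker_map: pd.DataFrame
    monomorphic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        n, m = self.values.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length must match rows of values")
        if len(self.individual_ids) != len(set(self.individual_ids)):
            raise ValueError("individual_ids must be unique")
        if len(self.marker_map) != m:
            raise ValueError("marker_map length must match columns of values")
        bad = ~np.isin(self.values, (0, 1, 2))
        if bad.any():
            raise ValueError("genotype values must be in {0,1,2}")
        if self.monomorphic is None:
            self.monomorphic = self.values.std(axis=0) == 0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return list(self.marker_map["id"])

    def sorted_by_position(self) -> "GenotypeMatrix":
        """Return a copy with markers sorted by (chrom, pos), natural order."""
        keys = [
            (_natural_chrom_key(c), int(p))
            for c, p in zip(self.marker_map["chrom"], self.marker_map["pos"])
        ]
        order = sorted(range(self.m), key=lambda j: keys[j])
        mm = self.marker_map.iloc[order].reset_index(drop=True)
        return GenotypeMatrix(
            self.values[:, order], list(self.individual_ids), mm,
            monomorphic=self.monomorphic[order],
        )


@dataclass
class PhenotypeTable:
    """Per-environment phenotypes: ``n`` individuals x ``s`` environments.

    Missing values are NaN; ``mask`` is True where a value is missing.
    """

    values: np.ndarray
    env_names: list[str]
    individual_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape != (len(self.individual_ids), len(self.env_names)):
            raise ValueError("values shape must be (n individuals, s environments)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def s(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.values)


def _impute_mode(column: np.ndarray, missing: np.ndarray) -> tuple[np.ndarray, int]:
    """Fill missing entries with the most frequent observed value (ties: smaller)."""
    n_missing = int(missing.sum())
    if n_missing == 0:
        return column, 0
    observed = column[~missing]
    if observed.size == 0:
        fill = 0
    else:
        counts = np.bincount(observed.astype(int), minlength=3)
        fill = int(np.argmax(counts))  # argmax takes the smaller value on ties
    out = column.copy()
    out[missing] = fill
    return out, n_missing


def read_hapmap(path) -> GenotypeMatrix:
    """Read a HapMap text file into 0/1/2 coding (major-allele homozygote = 0).

    The file must carry the 11 standard metadata columns followed by one
    column per individual; calls may be two-letter ("AA", "AT") or IUPAC
    single letters. Markers with more than two observed alleles are dropped
    with a warning; missing calls are imputed with the marker mode.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 12:
        raise ValueError(
            f"malformed HapMap header: expected >=12 columns, got {df.shape[1]}"
        )
    first = df.columns[0].lstrip("#").replace("rs#", "rs").lower()
    if first not in ("rs", "rs#", "snpid", "snp", "marker"):
        raise ValueError(f"malformed HapMap header: first column is {df.columns[0]!r}")

    ind_ids = [str(c) for c in df.columns[11:]]
    n = len(ind_ids)
    columns, rows, mono = [], [], []
    n_dropped = 0
    for _, row in df.iterrows():
        calls = [str(v).upper() for v in row.iloc[11:]]
        pairs, missing = [], np.zeros(n, dtype=bool)
        for i, c in enumerate(calls):
            if c in _MISSING_CALLS:
                pairs.append(None)
                missing[i] = True
            elif len(c) == 1:
                if c not in _IUPAC:
                    pairs.append(None)
                    missing[i] = True
                else:
                    pairs.append(_IUPAC[c])
            else:
                pairs.append(c[:2])
        allele_counts: dict[str, int] = {}
        for p in pairs:
            if p is not None:
                for a in p:
                    allele_counts[a] = allele_counts.get(a, 0) + 1
        alleles = sorted(allele_counts)
        if len(alleles) > 2:
            n_dropped += 1
            logger.warning("marker %s has >2 alleles; dropped", row.iloc[0])
            continue
        if len(alleles) == 0:
            n_dropped += 1
            logger.warning("marker %s has no called alleles; dropped", row.iloc[0])
            continue
        if len(alleles) == 1:
            minor = None  # monomorphic: no minor allele, column is all zeros
        else:
            a, b = alleles
            # minor = less frequent allele; alphabetical tie-break at p=0.5
            if allele_counts[a] == allele_counts[b]:
                minor = b
            else:
                minor = a if allele_counts[a] < allele_counts[b] else b
        col = np.zeros(n, dtype=np.int8)
        if minor is not None:
            for i, p in enumerate(pairs):
                if p is not None:
                    col[i] = sum(1 for a in p if a == minor)
        col, n_imp = _impute_mode(col, missing)
        if n_imp:
            logger.info("marker %s: imputed %d missing calls", row.iloc[0], n_imp)
        columns.append(col)
        rows.append((str(row.iloc[0]), str(row.iloc[2]), int(row.iloc[3])))
        mono.append(len(alleles) == 1 or col.std() == 0)
    if n_dropped:
        logger.warning("dropped %d multi-allelic/empty markers", n_dropped)
    values = np.column_stack(columns) if columns else np.zeros((n, 0), dtype=np.int8)
    mm = pd.DataFrame(rows, columns=["id", "chrom", "pos"])
    g = GenotypeMatrix(values, ind_ids, mm, monomorphic=np.asarray(mono))
    return g.sorted_by_position()


def read_numeric(
    path,
    marker_map_path=None,
    orientation: str = "individuals-rows",
    missing_code: str = "NA",
    sep: str = "\t",
) -> GenotypeMatrix:
    """Read a delimited 0/1/2 matrix (header = marker ids, first column = ids).

    ``orientation="markers-rows"`` transposes (header = individual ids,
    first column = marker ids). The marker map, if given, is a 3-column
    delimited file (id, chrom, pos); otherwise positions are invented
    (single chromosome, 1 kb spacing).
    """
    if orientation not in ("individuals-rows", "markers-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=[missing_code])
    if orientation == "markers-rows":
        df = df.T
    ind_ids = [str(i) for i in df.index]
    marker_ids = [str(c) for c in df.columns]
    raw = df.to_numpy(dtype=float)
    missing = np.isnan(raw)
    observed = raw[~missing]
    if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
        bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))][0]
        raise ValueError(f"genotype entry {bad!r} outside {{0,1,2}}")
    values = np.zeros(raw.shape, dtype=np.int8)
    values[~missing] = raw[~missing].astype(np.int8)
    total_imputed = 0
    for j in range(values.shape[1]):
        values[:, j], n_imp = _impute_mode(values[:, j], missing[:, j])
        total_imputed += n_imp
    if total_imputed:
        logger.info("imputed %d missing genotype entries", total_imputed)
    if marker_map_path is not None:
        mm = pd.read_csv(marker_map_path, sep=sep, dtype={"id": str, "chrom": str})
        mm = mm[["id", "chrom", "pos"]]
        mm = mm.set_index("id").loc[marker_ids].reset_index()
    else:
        mm = pd.DataFrame(
            {"id": marker_ids, "chrom": "1", "pos": 1000 * np.arange(1, len(marker_ids) + 1)}
        )
    return GenotypeMatrix(values, ind_ids, mm).sorted_by_position()


def write_numeric(geno: GenotypeMatrix, path, marker_map_path=None, sep: str = "\t"):
    """Write the numeric matrix (and optionally the marker map) to disk."""
    df = pd.DataFrame(geno.values, index=geno.individual_ids, columns=geno.marker_ids)
    df.index.name = "taxa"
    df.to_csv(path, sep=sep)
    if marker_map_path is not None:
        geno.marker_map.to_csv(marker_map_path, sep=sep, index=False)


def read_phenotype(path, genotype: GenotypeMatrix | None = None, sep: str = "\t") -> PhenotypeTable:
    """Read a phenotype table (col 1 = id, remaining columns = environments).

    If a genotype is supplied, rows are re-ordered to the genotype's
    individual order; phenotype-only ids are dropped with a logged count and
    genotype-only ids get all-missing rows.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    env_names = [str(c) for c in df.columns]
    if genotype is None:
        return PhenotypeTable(df.to_numpy(dtype=float), env_names, [str(i) for i in df.index])
    overlap = [i for i in genotype.individual_ids if i in set(df.index)]
    if not overlap:
        raise ValueError("no overlapping individual ids between phenotype and genotype")
    n_dropped = len(set(df.index) - set(genotype.individual_ids))
    if n_dropped:
        logger.warning("dropped %d phenotype ids absent from genotype", n_dropped)
    aligned = df.reindex(genotype.individual_ids)
    return PhenotypeTable(
        aligned.to_numpy(dtype=float), env_names, list(genotype.individual_ids)
    )


def write_phenotype(pheno: PhenotypeTable, path, sep: str = "\t"):
    df = pd.DataFrame(pheno.values, index=pheno.individual_ids, columns=pheno.env_names)
    df.index.name = "taxa"
    df.to_csv(path, sep=sep)


def generate_synthetic_genotypes(
    n: int,
    m: int,
    n_chrom: int = 10,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int | np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Generate an independent-marker synthetic genotype panel.

    Per marker an allele frequency p ~ Uniform(maf_low, maf_high) is drawn
    and genotypes sampled Binomial(2, p) — a panmictic population with no
    linkage disequilibrium or structure. Markers are split evenly across
    ``n_chrom`` chromosomes at 1 kb spacing.
    """
    if n < 2 or m < 2:
        raise ValueError("need n >= 2 and m >= 2")
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=m)
    values = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    ind_ids = [f"ind{i+1:04d}" for i in range(n)]
    chrom_sizes = [len(c) for c in np.array_split(np.arange(m), n_chrom)]
    chroms, positions = [], []
    for c, size in enumerate(chrom_sizes, start=1):
        chroms.extend([str(c)] * size)
        positions.extend(1000 * np.arange(1, size + 1))
    mm = pd.DataFrame(
        {"id": [f"m{j+1:05d}" for j in range(m)], "chrom": chroms, "pos": positions}
    )
    return GenotypeMatrix(values, ind_ids, mm)
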