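"""Reproducible synthetic study grids.

Bundles the synthetic genotype generator with the phenotype simulator to
emit the full heritability x genetic-correlation grid (default 3 x 3:
h2 and r each in {0.2, 0.5, 0.8}, 20 QTNs, two environments) used for
benchmarking, at configurable scale. Each grid cell gets an independent
seed derived deterministically from the master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import data_io, simulate

DEFAULT_LEVELS = (0.2, 0.5, 0.8)


@dataclass
class FixtureSpec:
    n: int = 300
    m: int = 1000
    n_chrom: int = 10
    s: int = 2
    nqtn: int = 20
    h2_grid: tuple = DEFAULT_LEVELS
    r_grid: tuple = DEFAULT_LEVELS
    maf_low: float = 0.05
    maf_high: float = 0.5
    seed: int = 42


def cell_seed(master_seed: int, h2: float, r: float) -> int:
    """Deterministic per-cell seed below 2**31, derived from the master seed."""
    key = f"{master_seed}:{h2}:{r}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31 - 1)


def make_grid(spec: FixtureSpec, outdir, force: bool = False) -> Path:
    """Write one folder per (h2, r) cell: genotype, phenotypes, truth, MANIFEST."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    G = data_io.generate_synthetic_genotypes(
        spec.n, spec.m, spec.n_chrom, spec.maf_low, spec.maf_high, seed=spec.seed
    )
    data_io.write_numeric(G, outdir / "genotype.tsv", outdir / "marker_map.tsv")
    manifest = {"spec": spec.__dict__ | {"h2_grid": list(spec.h2_grid), "r_grid": list(spec.r_grid)},
                "cells": {}}
    for h2 in spec.h2_grid:
        for r in spec.r_grid:
            seed = cell_seed(spec.seed, h2, r)
            cell = outdir / f"h2_{h2}_r_{r}"
            cell.mkdir(exist_ok=True)
            sim = simulate.simulate(G, nqtn=spec.nqtn, h2=h2, r=r, s=spec.s, seed=seed)
            data_io.write_phenotype(sim.phenotypes, cell / "phenotypes.tsv")
            simulate.write_truth(sim.truth, G, cell / "truth.tsv")
            manifest["cells"][cell.name] = {
                "seed": seed, "h2": h2, "r": r,
                "realized_h2": [float(x) for x in sim.realized_h2],
            }
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    return outdir
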