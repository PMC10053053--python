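"""Reference-population designs.

Four sampling schemes for the genomic-prediction reference set are
compared: purebred grandparents (PB, drawn from GP2), random commercial
crossbreds (CB_random, drawn from the DLY generation), two-tailed extreme
crossbreds (CB_extreme, the highest and lowest phenotypes in the DLY
generation), and the combined scheme CCPS (half PB, half CB_extreme).
Candidates are never part of any reference set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .breeding import SystemPopulations
from .founders import ConfigurationError
from .traits import TraitRealization

__all__ = ["ReferenceDesign", "select_extreme", "select_random", "build_design",
           "SCHEMES"]

SCHEMES = ("PB", "CB_random", "CB_extreme", "CCPS")


@dataclass(frozen=True)
class ReferenceDesign:
    scheme: str
    size: int
    indices: np.ndarray           # roster indices into the system population
    phenotypes: np.ndarray
    replicate_seed: int | None = None


def select_extreme(phenotypes: np.ndarray, indices: np.ndarray, n: int
                   ) -> ReferenceDesign:
    """Two-tailed selection: the ceil(n/2) highest and floor(n/2) lowest
    phenotypes.  Ties are broken by index for determinism; the top half
    receives the extra individual when n is odd."""
    phenotypes = np.asarray(phenotypes, dtype=float)
    indices = np.asarray(indices)
    if n < 2:
        raise ConfigurationError("extreme selection needs n >= 2")
    if n > indices.size:
        raise ConfigurationError(f"n={n} exceeds population size {indices.size}")
    order = np.lexsort((indices, phenotypes))  # ascending phenotype, ties by id
    n_top = n - n // 2
    n_bot = n // 2
    pick = np.concatenate([order[:n_bot], order[order.size - n_top:]])
    pick = np.sort(pick)
    return ReferenceDesign(scheme="CB_extreme", size=n, indices=indices[pick],
                           phenotypes=phenotypes[pick])


def select_random(phenotypes: np.ndarray, indices: np.ndarray, n: int,
                  seed: int) -> ReferenceDesign:
    """Uniform draw without replacement, reproducible from ``seed``."""
    indices = np.asarray(indices)
    if n > indices.size:
        raise ConfigurationError(f"n={n} exceeds population size {indices.size}")
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(indices.size, size=n, replace=False))
    return ReferenceDesign(scheme="CB_random", size=n, indices=indices[pick],
                           phenotypes=np.asarray(phenotypes, dtype=float)[pick],
                           replicate_seed=seed)


def build_design(system: SystemPopulations, trait: TraitRealization,
                 scheme: str, n: int, replicate_seed: int = 0,
                 ccps_fraction: float = 0.5) -> ReferenceDesign:
    """Construct a reference design of size ``n`` under the named scheme.

    PB draws purebreds from GP2; the CB schemes draw from the commercial
    DLY generation; CCPS is the union of a PB draw and a CB_extreme draw
    with ``ccps_fraction`` of the individuals coming from CB_extreme.
    Candidate individuals are excluded from every source.
    """
    cand = set(system.candidate_idx.tolist())

    def source(label: str) -> np.ndarray:
        idx = system.membership[label]
        if cand:
            idx = idx[~np.isin(idx, system.candidate_idx)]
        return idx

    pheno_all = trait.phenotype

    if scheme == "PB":
        idx = source("GP2")
        d = select_random(pheno_all[idx], idx, n, replicate_seed)
        return ReferenceDesign("PB", n, d.indices, d.phenotypes, replicate_seed)
    if scheme == "CB_random":
        idx = source("C")
        return select_random(pheno_all[idx], idx, n, replicate_seed)
    if scheme == "CB_extreme":
        idx = source("C")
        return select_extreme(pheno_all[idx], idx, n)
    if scheme == "CCPS":
        n_cb = int(round(n * ccps_fraction))
        n_pb = n - n_cb
        idx_c = source("C")
        cb = select_extreme(pheno_all[idx_c], idx_c, n_cb)
        idx_p = source("GP2")
        pb = select_random(pheno_all[idx_p], idx_p, n_pb, replicate_seed)
        ids = np.concatenate([pb.indices, cb.indices])
        order = np.argsort(ids)
        return ReferenceDesign("CCPS", n, ids[order],
                               np.concatenate([pb.phenotypes, cb.phenotypes])[order],
                               replicate_seed)
    raise ConfigurationError(f"unknown scheme {scheme!r}; one of {SCHEMES}")
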