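"""Quantitative-trait simulation: QTL effects, true breeding values and
phenotypes.

A trait is controlled by ``n_qtl`` loci drawn at random from the markers
segregating in the founder generation.  Absolute effects follow a
Gamma(shape=0.4, scale=1) distribution with a random sign, and are rescaled
by one constant so that the variance of the true breeding value (TBV) over
a stated scaling population (by default every animal in the system) equals
the target genetic variance Vg = 1.  Phenotypes add a normal residual whose
dispersion is set by the heritability h^2 = Vg / (Vg + Ve).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .founders import ConfigurationError, PhasedPopulation

__all__ = [
    "TraitArchitecture",
    "TraitRealization",
    "sample_qtl",
    "rescale_to_vg",
    "compute_tbv",
    "simulate_phenotype",
    "environmental_variance",
]

GAMMA_SHAPE_DEFAULT = 0.4


@dataclass(frozen=True)
class TraitArchitecture:
    """QTL marker indices and signed additive effects."""

    qtl_indices: np.ndarray
    effects: np.ndarray
    gamma_shape: float = GAMMA_SHAPE_DEFAULT
    rescale_factor: float = 1.0
    vg: float | None = None       # realised Var(TBV) on the scaling population

    def __post_init__(self):
        if self.qtl_indices.size != self.effects.size:
            raise ConfigurationError("QTL index/effect length mismatch")
        if np.any(self.effects == 0.0):
            raise ConfigurationError("QTL effects must be nonzero")


@dataclass(frozen=True)
class TraitRealization:
    """One heritability level's phenotypes over a fixed TBV vector."""

    h2: float
    ve: float
    residual_mode: str            # 'variance' | 'sd'
    tbv: np.ndarray
    phenotype: np.ndarray


def sample_qtl(founders: PhasedPopulation, n_qtl: int,
               shape: float = GAMMA_SHAPE_DEFAULT,
               rng: np.random.Generator | None = None) -> TraitArchitecture:
    """Draw QTL uniformly from loci segregating in the founders.

    Effects are |a| ~ Gamma(shape, 1) with sign +/-1 equiprobable.
    """
    rng = rng or np.random.default_rng()
    if n_qtl <= 0:
        raise ConfigurationError("n_qtl must be > 0")
    freq = founders.allele_frequencies()
    segregating = np.flatnonzero((freq > 0.0) & (freq < 1.0))
    if segregating.size < n_qtl:
        raise ConfigurationError(
            f"only {segregating.size} segregating loci for {n_qtl} QTL")
    qtl = np.sort(rng.choice(segregating, size=n_qtl, replace=False))
    mag = rng.gamma(shape, 1.0, size=n_qtl)
    mag = np.maximum(mag, np.finfo(float).tiny)
    sign = rng.choice([-1.0, 1.0], size=n_qtl)
    return TraitArchitecture(qtl_indices=qtl, effects=mag * sign,
                             gamma_shape=shape)


def compute_tbv(dosages: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """TBV_j = sum_i a_i * dosage_ji over the QTL columns.

    ``dosages`` is either the full (individuals x markers) matrix — QTL
    columns are selected by index — or an already-extracted
    (individuals x n_qtl) matrix.
    """
    if dosages.shape[1] == arch.qtl_indices.size:
        q = dosages
    else:
        if dosages.shape[1] <= arch.qtl_indices.max():
            raise ConfigurationError("dosage matrix does not cover all QTL")
        q = dosages[:, arch.qtl_indices]
    return q.astype(np.float64) @ arch.effects


def rescale_to_vg(arch: TraitArchitecture, scaling_dosages: np.ndarray,
                  target_vg: float = 1.0) -> TraitArchitecture:
    """Multiply all effects by the constant making Var(TBV) = ``target_vg``
    over the scaling population."""
    tbv = compute_tbv(scaling_dosages, arch)
    raw_var = float(np.var(tbv))
    if raw_var <= 0.0:
        raise ConfigurationError("raw TBV variance is zero; cannot rescale")
    c = np.sqrt(target_vg / raw_var)
    return replace(arch, effects=arch.effects * c,
                   rescale_factor=arch.rescale_factor * c, vg=target_vg)


def environmental_variance(h2: float, vg: float = 1.0) -> float:
    """Ve from h^2 = Vg / (Vg + Ve)."""
    if not (0.0 < h2 <= 1.0):
        raise ConfigurationError("heritability must be in (0, 1]")
    return vg * (1.0 - h2) / h2


def simulate_phenotype(tbv: np.ndarray, h2: float,
                       rng: np.random.Generator | None = None,
                       mode: str = "variance", vg: float = 1.0
                       ) -> TraitRealization:
    """Phenotype = TBV + residual at heritability ``h2``.

    ``mode='variance'`` (default, internally consistent): residual
    ~ Normal(0, Ve) with Ve = Vg (1 - h2)/h2 a *variance*.
    ``mode='sd'``: residual ~ Normal(0, Ve^2), i.e. the Ve quantity is used
    as a standard deviation — this reproduces the much larger phenotype
    dispersions some summaries report at low heritability.
    """
    rng = rng or np.random.default_rng()
    ve = environmental_variance(h2, vg)
    if mode == "variance":
        sd = np.sqrt(ve)
    elif mode == "sd":
        sd = ve
    else:
        raise ConfigurationError(f"unknown residual mode {mode!r}")
    resid = rng.normal(0.0, sd, size=tbv.shape[0]) if sd > 0 else np.zeros_like(tbv)
    return TraitRealization(h2=h2, ve=ve, residual_mode=mode, tbv=tbv,
                            phenotype=tbv + resid)
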