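"""Relatedness and linkage-disequilibrium machinery.

Implements the genomic relationship matrix (VanRaden method 1), pairwise
identity-by-state sharing, method-of-moments identity-by-descent (PI_HAT),
greedy sliding-window LD pruning and pairwise composite r^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .founders import ConfigurationError, GenomeMap

__all__ = [
    "GenotypeMatrixView",
    "KinshipResult",
    "vanraden_grm",
    "pairwise_ibs",
    "moment_ibd",
    "cross_ibs",
    "ld_prune",
    "pairwise_r2",
]


@dataclass(frozen=True)
class GenotypeMatrixView:
    """Dosage matrix with allele frequencies and their provenance.

    ``frequencies`` are the per-marker alternate-allele frequencies used by
    downstream estimators; ``frequency_source`` records which individuals
    they were computed from (free text, e.g. 'reference+candidates').
    """

    dosages: np.ndarray
    frequencies: np.ndarray
    frequency_source: str = "self"

    @classmethod
    def from_dosages(cls, dosages: np.ndarray,
                     frequency_source: str = "self") -> "GenotypeMatrixView":
        return cls(np.asarray(dosages), np.asarray(dosages).mean(axis=0) / 2.0,
                   frequency_source)

    def __post_init__(self):
        if self.dosages.shape[1] != self.frequencies.shape[0]:
            raise ConfigurationError("frequency vector does not match markers")
        if np.any(self.frequencies < 0) or np.any(self.frequencies > 1):
            raise ConfigurationError("allele frequencies outside [0, 1]")


@dataclass(frozen=True)
class KinshipResult:
    kind: str                    # 'GRM' | 'IBS' | 'IBD'
    matrix: np.ndarray
    marker_count: int


def vanraden_grm(view: GenotypeMatrixView, dtype=np.float64) -> KinshipResult:
    """G = Z Z' / (2 sum p_i q_i) with Z the dosage matrix column-centered
    by twice the allele frequency.

    ``dtype=np.float32`` halves the cost of the large cross-product; the
    result is returned in float64 either way.
    """
    d = view.dosages
    if d.shape[0] < 2:
        raise ConfigurationError("GRM needs at least two individuals")
    p = view.frequencies
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ConfigurationError("all markers monomorphic: zero GRM denominator")
    z = d.astype(dtype) - (2.0 * p).astype(dtype)
    g = (z @ z.T).astype(np.float64) / denom
    return KinshipResult("GRM", g, d.shape[1])


def _ibs_state_counts(da: np.ndarray, db: np.ndarray | None = None):
    """Pairwise IBS-state counts via indicator cross-products.

    Returns (n0, n1) matrices of loci in IBS state 0 and 1 between rows of
    ``da`` and rows of ``db`` (``db=None`` means da vs itself).
    """
    if db is None:
        db = da
    ia = [(da == k).astype(np.float64) for k in (0, 1, 2)]
    ib = [(db == k).astype(np.float64) for k in (0, 1, 2)]
    n0 = ia[0] @ ib[2].T + ia[2] @ ib[0].T
    n1 = ia[1] @ (ib[0] + ib[2]).T + (ia[0] + ia[2]) @ ib[1].T
    return n0, n1


def pairwise_ibs(view: GenotypeMatrixView) -> KinshipResult:
    """IBS(j,k) = (2 N_IBS2 + N_IBS1) / (2 L): the average fraction of
    alleles shared per locus."""
    d = view.dosages
    L = d.shape[1]
    if L == 0:
        raise ConfigurationError("zero markers")
    n0, n1 = _ibs_state_counts(d)
    ibs = 1.0 - (2.0 * n0 + n1) / (2.0 * L)
    return KinshipResult("IBS", ibs, L)


def cross_ibs(view_a: GenotypeMatrixView, view_b: GenotypeMatrixView) -> np.ndarray:
    """Mean IBS between every row of ``view_a`` and every row of ``view_b``
    (used for reference-to-target relatedness summaries)."""
    L = view_a.dosages.shape[1]
    n0, n1 = _ibs_state_counts(view_a.dosages, view_b.dosages)
    return 1.0 - (2.0 * n0 + n1) / (2.0 * L)


def moment_ibd(view: GenotypeMatrixView) -> KinshipResult:
    """Method-of-moments IBD: observed IBS-state counts are equated to
    their expectations given allele frequencies to estimate P(IBD=0,1,2)
    per pair; PI_HAT = P(IBD=2) + P(IBD=1)/2, truncated to [0, 1].

    Negative intermediate state probabilities are truncated to zero and the
    triple renormalised (the standard repair).  Frequencies should come
    from a stated reference panel; an LD-pruned marker set is recommended.
    """
    d = view.dosages
    p = view.frequencies
    q = 1.0 - p
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ConfigurationError("monomorphic panel")
    p, q = p[poly], q[poly]
    dd = d[:, poly]
    L = dd.shape[1]

    # per-locus expected IBS-state probabilities, summed over loci
    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e1_ibd1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))

    n0, n1 = _ibs_state_counts(dd)
    p0 = n0 / e0_ibd0
    p1 = (n1 - p0 * e1_ibd0) / e1_ibd1
    p2 = 1.0 - p0 - p1
    states = np.stack([p0, p1, p2])
    states = np.clip(states, 0.0, None)
    total = states.sum(axis=0)
    total[total == 0.0] = 1.0
    states /= total
    pi_hat = states[2] + 0.5 * states[1]
    np.fill_diagonal(pi_hat, 1.0)
    return KinshipResult("IBD", np.clip(pi_hat, 0.0, 1.0), L)


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns (composite LD)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(), y.var()
    if vx == 0.0 or vy == 0.0:
        raise ConfigurationError("zero variance column in r^2")
    c = np.mean((x - x.mean()) * (y - y.mean()))
    return float(c * c / (vx * vy))


def ld_prune(dosages: np.ndarray, genome: GenomeMap, window: int = 50,
             step: int = 10, r2_max: float = 0.2,
             columns: np.ndarray | None = None) -> np.ndarray:
    """Greedy sliding-window LD pruning (window/step in SNP counts).

    Within each window, for every pair with r^2 above the threshold the
    later-position marker is removed; the window then advances by ``step``
    markers.  ``columns`` maps dosage columns to genome marker indices when
    the matrix covers only a marker subset (default: the full map).
    Returns the surviving *column* indices in map order.
    """
    if window < 2:
        raise ConfigurationError("window must span at least 2 markers")
    m = dosages.shape[1]
    if columns is None:
        if m != genome.n_markers:
            raise ConfigurationError(
                "dosage columns do not match the map; pass `columns`")
        columns = np.arange(m)
    else:
        columns = np.asarray(columns)
        if columns.size != m:
            raise ConfigurationError("`columns` length must match dosages")
    keep = np.ones(m, dtype=bool)
    x = dosages.astype(np.float64)
    sd = x.std(axis=0)
    col_chrom = genome.marker_chrom[columns]
    for c in range(genome.n_chromosomes):
        cols = np.flatnonzero(col_chrom == c)
        start = 0
        while start < cols.size:
            w = cols[start:start + window]
            w = w[keep[w] & (sd[w] > 0)]
            if w.size >= 2:
                xs = x[:, w]
                r = np.corrcoef(xs, rowvar=False)
                r2 = r * r
                for a in range(w.size):
                    if not keep[w[a]]:
                        continue
                    for b in range(a + 1, w.size):
                        if keep[w[b]] and r2[a, b] > r2_max:
                            keep[w[b]] = False
            if start + window >= cols.size:
                break
            start += step
    # markers with zero variance carry no LD information; keep them
    return np.flatnonzero(keep)
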