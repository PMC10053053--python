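"""Mixed-model association testing, SNP-to-QTL linkage assignment and the
phenotypic-variance-explained summary.

Each marker is tested with a Wald test in y = mu + x a + g + e with
g ~ N(0, G sigma_u^2), computed by a single spectral decomposition of G and
generalised least squares at the null-model REML variance ratio.  The
genome-wide significance threshold is Bonferroni (alpha/m); the suggestive
threshold is 1/m.  Markers are assigned to the QTL with which they show the
highest composite r^2; per QTL, the most significant marker within +-500 kb
is the peak, and PVE_i = 2 a_i^2 p_i q_i / (2 a_i^2 p_i q_i +
2 N Se_i^2 p_i q_i); sigPVE sums peak PVE over QTL regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .founders import ConfigurationError, GenomeMap
from .predict import VarianceComponents, reml_fit

__all__ = [
    "GwasResult",
    "QtlRegionReport",
    "lmm_gwas",
    "thresholds",
    "assign_snp_qtl_ld",
    "peak_pve",
    "REGION_HALF_WIDTH",
    "HIGH_LD_R2",
]

REGION_HALF_WIDTH = 500_000   # bp either side of a QTL
HIGH_LD_R2 = 0.6


@dataclass(frozen=True)
class GwasResult:
    effects: np.ndarray
    se: np.ndarray
    statistics: np.ndarray       # squared t (Wald)
    pvalues: np.ndarray
    tested: np.ndarray           # False where monomorphic (skipped)
    n: int
    significant_threshold: float
    suggestive_threshold: float
    components: VarianceComponents

    @property
    def significant(self) -> np.ndarray:
        return self.tested & (self.pvalues < self.significant_threshold)

    @property
    def suggestive(self) -> np.ndarray:
        return self.tested & (self.pvalues < self.suggestive_threshold)


def thresholds(m_tests: int, alpha: float = 0.05) -> tuple[float, float]:
    """(Bonferroni significant, genome-wide suggestive) p-value cutoffs."""
    if m_tests < 1:
        raise ConfigurationError("need at least one test")
    return alpha / m_tests, 1.0 / m_tests


def lmm_gwas(y: np.ndarray, markers: np.ndarray, G: np.ndarray,
             alpha: float = 0.05,
             vc: VarianceComponents | None = None,
             eig: tuple[np.ndarray, np.ndarray] | None = None) -> GwasResult:
    """Per-marker Wald tests under a polygenic mixed model.

    ``markers`` is (n x m) dosages over the tested individuals.  The
    variance ratio is estimated once from the null model (no per-marker
    refit); each marker's effect is then the GLS slope in the whitened
    model.  Monomorphic markers are flagged untested.  P-values use the t
    distribution with n - 2 degrees of freedom.
    """
    y = np.asarray(y, dtype=np.float64)
    n, m = markers.shape
    if eig is None:
        d, U = np.linalg.eigh(G)
        d = np.maximum(d, 0.0)
    else:
        d, U = eig
    if vc is None:
        vc = reml_fit(y, eig=(d, U))
    lam = vc.sigma_u2 / vc.sigma_e2 if vc.sigma_e2 > 0 else 0.0
    w = 1.0 / (lam * d + 1.0)     # whitening weights, up to sigma_e^2

    ys = U.T @ y
    ones_s = U.T @ np.ones(n)
    Xs = U.T @ markers.astype(np.float64)

    sw = float(np.sum(w))
    swx = w @ Xs                   # per marker
    sw1x = (w * ones_s) @ Xs
    sw11 = float(np.sum(w * ones_s * ones_s))
    sw1y = float(np.sum(w * ones_s * ys))
    swxy = (w * ys) @ Xs
    swxx = w @ (Xs * Xs)

    # 2x2 GLS for [intercept, marker] per marker, closed form
    det = sw11 * swxx - sw1x * sw1x
    tested = (markers.max(axis=0) != markers.min(axis=0)) & (det > 1e-12)
    det_safe = np.where(tested, det, 1.0)
    a_hat = (sw11 * swxy - sw1x * sw1y) / det_safe
    mu_hat = (swxx * sw1y - sw1x * swxy) / det_safe

    # residual variance per marker fit
    syy = float(np.sum(w * ys * ys))
    rss = syy - 2 * mu_hat * sw1y - 2 * a_hat * swxy \
        + mu_hat**2 * sw11 + 2 * mu_hat * a_hat * sw1x + a_hat**2 * swxx
    dof = n - 2
    s2 = np.maximum(rss, 0.0) / dof
    var_a = s2 * sw11 / det_safe
    se = np.sqrt(np.maximum(var_a, 1e-300))
    tstat = np.where(tested, a_hat / se, 0.0)
    pvals = np.where(tested, 2.0 * stats.t.sf(np.abs(tstat), dof), 1.0)
    sig, sugg = thresholds(int(tested.sum()), alpha)
    return GwasResult(effects=np.where(tested, a_hat, 0.0), se=se,
                      statistics=tstat**2, pvalues=pvals, tested=tested,
                      n=n, significant_threshold=sig, suggestive_threshold=sugg,
                      components=vc)


def assign_snp_qtl_ld(marker_dosages: np.ndarray, qtl_dosages: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """For each marker, the QTL with maximal composite r^2.

    Returns (best_qtl_index, best_r2) arrays; markers or QTL with zero
    variance yield r^2 = 0 against everything.
    """
    if qtl_dosages.shape[1] == 0:
        raise ConfigurationError("empty QTL set")
    X = marker_dosages.astype(np.float64)
    Q = qtl_dosages.astype(np.float64)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    sx = Xc.std(axis=0)
    sq = Qc.std(axis=0)
    sx[sx == 0] = np.inf
    sq[sq == 0] = np.inf
    R = (Xc / sx).T @ (Qc / sq) / n
    r2 = R * R
    best = np.argmax(r2, axis=1)
    return best, r2[np.arange(r2.shape[0]), best]


@dataclass(frozen=True)
class QtlRegionReport:
    """Per-QTL peak-marker summary within +-500 kb regions."""

    table: pd.DataFrame          # qtl, chrom, start, end, peak marker, p, pve
    sig_pve: float               # sum of peak PVE over QTL with a peak (%)

    @property
    def n_detected(self) -> int:
        return int(self.table["peak_marker"].notna().sum())


def pve_single(a: float, se: float, n: int, p: float) -> float:
    """Phenotypic variance explained by one marker (fraction in [0, 1])."""
    num = 2.0 * a * a * p * (1.0 - p)
    den = num + 2.0 * n * se * se * p * (1.0 - p)
    if den == 0.0:
        return 0.0
    return num / den


def peak_pve(gwas: GwasResult, marker_positions: np.ndarray,
             marker_chrom: np.ndarray, qtl_positions: np.ndarray,
             qtl_chrom: np.ndarray, frequencies: np.ndarray,
             use_suggestive: bool = False) -> QtlRegionReport:
    """Peak-marker PVE within each QTL's +-500 kb window.

    Only markers past the (Bonferroni, or suggestive when requested)
    threshold are eligible; a QTL region without a significant marker
    contributes nothing.  A marker that peaks in two overlapping regions
    contributes to each (regions are per-QTL).  ``sig_pve`` is reported in
    percent, the scale used for scenario summaries.
    """
    flags = gwas.suggestive if use_suggestive else gwas.significant
    rows = []
    total = 0.0
    for k in range(qtl_positions.size):
        lo = qtl_positions[k] - REGION_HALF_WIDTH
        hi = qtl_positions[k] + REGION_HALF_WIDTH
        inwin = (marker_chrom == qtl_chrom[k]) & (marker_positions >= lo) \
            & (marker_positions <= hi) & flags
        idx = np.flatnonzero(inwin)
        if idx.size == 0:
            rows.append((k, qtl_chrom[k], lo, hi, None, np.nan, 0.0))
            continue
        peak = idx[np.argmin(gwas.pvalues[idx])]
        pve = pve_single(gwas.effects[peak], gwas.se[peak], gwas.n,
                         frequencies[peak])
        total += pve
        rows.append((k, qtl_chrom[k], lo, hi, int(peak),
                     float(gwas.pvalues[peak]), pve))
    table = pd.DataFrame(rows, columns=["qtl", "chrom", "start", "end",
                                        "peak_marker", "peak_p", "pve"])
    return QtlRegionReport(table=table, sig_pve=100.0 * total)
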