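"""Factorial experiment runner: scheme x size x heritability x model x
replicate, with accuracy / response-to-selection metrics and per-scenario
GWAS summaries.

The runner wires the whole pipeline together: synthetic founders ->
crossbreeding system -> trait -> reference designs -> predictors (GBLUP /
sparse Bayesian mixture) -> evaluation on the purebred candidate set.
Evaluation follows the study design: prediction accuracy is the Pearson
correlation between GEBV and TBV of the candidates, and Best10%_TBV is the
mean TBV of the top decile of candidates ranked by GEBV; both are also
extracted per breed (Duroc, Landrace, Yorkshire).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .breeding import (BreedingSystemConfig, MeiosisModel, SystemPopulations,
                       desk_scale_config, run_breeding_system)
from .designs import build_design
from .founders import (BreedSpec, ConfigurationError, FounderConfig,
                       PhasedPopulation, generate_founders)
from .gwas import HIGH_LD_R2, assign_snp_qtl_ld, lmm_gwas, peak_pve
from .kinship import GenotypeMatrixView, vanraden_grm
from .predict import BslmmSpec, bslmm_fit, gblup_predict, gebv_from_effects, reml_fit
from .traits import TraitArchitecture, compute_tbv, rescale_to_vg, sample_qtl, \
    simulate_phenotype

log = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "accuracy",
    "best10_tbv",
    "per_breed_metrics",
    "run_experiment",
    "desk_preset",
]


def accuracy(gebv: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation between predicted and true breeding values."""
    gebv = np.asarray(gebv, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    if gebv.size != tbv.size:
        raise ConfigurationError("length mismatch")
    if gebv.size < 3:
        raise ConfigurationError("need at least 3 candidates")
    if gebv.std() == 0.0 or tbv.std() == 0.0:
        raise ConfigurationError("zero variance in GEBV or TBV")
    return float(np.corrcoef(gebv, tbv)[0, 1])


def best10_tbv(gebv: np.ndarray, tbv: np.ndarray) -> float:
    """Mean TBV of the top ceil(n/10) candidates ranked by GEBV
    (descending; ties broken by position for determinism)."""
    gebv = np.asarray(gebv, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    n = gebv.size
    if n < 10:
        raise ConfigurationError("need at least 10 candidates for a decile")
    k = -(-n // 10)
    order = np.lexsort((np.arange(n), -gebv))
    return float(tbv[order[:k]].mean())


def per_breed_metrics(gebv: np.ndarray, tbv: np.ndarray, breeds: np.ndarray
                      ) -> dict[str, dict[str, float]]:
    """Accuracy and Best10%_TBV within each breed's candidate subset."""
    out: dict[str, dict[str, float]] = {}
    for b in pd.unique(np.asarray(breeds)):
        sel = np.asarray(breeds) == b
        if sel.sum() < 3:
            raise ConfigurationError(f"breed {b} has fewer than 3 candidates")
        entry = {"accuracy": accuracy(gebv[sel], tbv[sel])}
        if sel.sum() >= 10:
            entry["best10_tbv"] = best10_tbv(gebv[sel], tbv[sel])
        out[str(b)] = entry
    return out


def desk_preset(seed: int = 0) -> "ExperimentConfig":
    """Reduced-scale preset preserving the design's structure and ratios:
    ~36k animals, 5 chromosomes x 400 markers, 200 QTL, 20,000 DLY,
    1560 candidates, reference sizes up to 2000."""
    founder = FounderConfig(
        breeds=(BreedSpec("Duroc", 6, 30), BreedSpec("Landrace", 6, 60),
                BreedSpec("Yorkshire", 12, 300)),
        n_chromosomes=5, markers_per_chrom=400, pool_size=6,
        mean_segment_bp=20e6, seed=seed,
    )
    return ExperimentConfig(
        founder_config=founder,
        breeding_config=desk_scale_config(seed=seed + 1),
        n_qtl=200,
        sizes=(500, 1000, 2000),
        master_seed=seed,
        bslmm_chain=5000,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    founder_config: FounderConfig
    breeding_config: BreedingSystemConfig
    meiosis: MeiosisModel = MeiosisModel()
    n_qtl: int = 2000
    h2_levels: tuple[float, ...] = (0.1, 0.3, 0.5)
    schemes: tuple[str, ...] = ("PB", "CB_random", "CB_extreme")
    sizes: tuple[int, ...] = (500, 1000, 2000, 3000, 4000, 5000, 6000, 6500)
    models: tuple[str, ...] = ("GBLUP",)
    replicates: int = 50
    master_seed: int = 0
    resample_trait: bool = True   # redraw phenotype residuals per replicate
    run_gwas: bool = False
    bslmm_chain: int = 10_000
    residual_mode: str = "variance"
    target_vg: float = 1.0


@dataclass
class ExperimentResult:
    records: pd.DataFrame         # one row per cell x replicate
    averages: pd.DataFrame        # replicate means per cell
    system: SystemPopulations
    architecture: TraitArchitecture

    def counts(self) -> dict[str, int]:
        return self.system.counts()


def _evaluate_cell(system: SystemPopulations, trait, arch, panel: np.ndarray,
                   scheme: str, size: int, model: str, replicate: int,
                   seed: int, config: ExperimentConfig) -> dict:
    pop = system.population
    design = build_design(system, trait, scheme, size, replicate_seed=seed)
    cand = system.candidate_idx
    ref = design.indices
    joint = np.concatenate([ref, cand])
    dos = pop.dosages(joint, panel)
    freqs = dos.mean(axis=0) / 2.0
    y_ref = design.phenotypes
    tbv_cand = trait.tbv[cand]
    n_ref = ref.size
    ref_rows = np.arange(n_ref)
    cand_rows = np.arange(n_ref, joint.size)

    rec: dict = {"scheme": scheme, "size": size, "h2": trait.h2,
                 "model": model, "replicate": replicate}

    view = GenotypeMatrixView(dos, freqs, frequency_source="reference+candidates")
    if model == "GBLUP":
        G = vanraden_grm(view, dtype=np.float32).matrix
        d, U = np.linalg.eigh(G[np.ix_(ref_rows, ref_rows)])
        d = np.maximum(d, 0.0)
        vc = reml_fit(y_ref, eig=(d, U))
        pred = gblup_predict(y_ref, G, vc, ref_rows, cand_rows)
        gebv = pred.gebv
        rec["sigma_u2"], rec["sigma_e2"] = vc.sigma_u2, vc.sigma_e2
        eig_ref = (d, U)
    elif model == "BSLMM":
        Xc = dos[ref_rows].astype(np.float64) - 2.0 * freqs
        fit = bslmm_fit(y_ref, Xc, BslmmSpec(chain_length=config.bslmm_chain,
                                             seed=seed))
        gebv = gebv_from_effects(fit.beta_mean, dos[cand_rows]).gebv
        rec["pi_mean"] = fit.pi_mean
        rec["sigma_e2"] = fit.resid_var_mean
        eig_ref = None
    else:
        raise ConfigurationError(f"unknown model {model!r}")

    breeds = pop.roster["breed"].to_numpy()[cand]
    rec["accuracy"] = accuracy(gebv, tbv_cand)
    rec["best10_tbv"] = best10_tbv(gebv, tbv_cand)
    for b, metrics in per_breed_metrics(gebv, tbv_cand, breeds).items():
        rec[f"accuracy_{b}"] = metrics["accuracy"]
        if "best10_tbv" in metrics:
            rec[f"best10_tbv_{b}"] = metrics["best10_tbv"]

    if config.run_gwas:
        if model != "GBLUP":
            G = vanraden_grm(view, dtype=np.float32).matrix
            d, U = np.linalg.eigh(G[np.ix_(ref_rows, ref_rows)])
            eig_ref = (np.maximum(d, 0.0), U)
        ref_dos = dos[ref_rows]
        gw = lmm_gwas(y_ref, ref_dos, None, eig=eig_ref)
        qtl_dos = pop.dosages(ref, arch.qtl_indices)
        best, r2 = assign_snp_qtl_ld(ref_dos, qtl_dos)
        sig = gw.significant
        rec["n_significant"] = int(sig.sum())
        rec["n_suggestive"] = int(gw.suggestive.sum())
        rec["n_sig_high_ld"] = int((sig & (r2 > HIGH_LD_R2)).sum())
        g = pop.genome
        report = peak_pve(gw, g.marker_pos[panel], g.marker_chrom[panel],
                          g.marker_pos[arch.qtl_indices],
                          g.marker_chrom[arch.qtl_indices],
                          ref_dos.mean(axis=0) / 2.0)
        rec["sig_pve"] = report.sig_pve
    return rec


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the full factorial experiment.

    Stage seeds are derived from the master seed; replicate ``r`` uses
    ``master_seed + r`` for every random draw it owns (reference sampling
    and, when ``resample_trait``, the phenotype residuals), so a rerun with
    the same master seed reproduces every number.  A failing cell is
    recorded with its error message; remaining cells proceed.
    """
    founders = generate_founders(config.founder_config)
    system = run_breeding_system(founders, config.breeding_config, config.meiosis)
    pop = system.population

    rng_qtl = np.random.default_rng(config.master_seed + 20_011)
    ggp1 = pop.subset(system.membership["GGP1"])
    arch = sample_qtl(ggp1, config.n_qtl, rng=rng_qtl)
    all_dos_qtl = pop.dosages(markers=arch.qtl_indices)
    arch = rescale_to_vg(arch, all_dos_qtl, config.target_vg)
    tbv_all = compute_tbv(all_dos_qtl, arch)
    panel = np.setdiff1d(np.arange(pop.genome.n_markers), arch.qtl_indices)

    records: list[dict] = []
    for r in range(config.replicates):
        seed_r = config.master_seed + r
        for ih, h2 in enumerate(config.h2_levels):
            trait_seed = (config.master_seed + 40_009 + ih * 1000
                          + (r if config.resample_trait else 0))
            trait = simulate_phenotype(
                tbv_all, h2, rng=np.random.default_rng(trait_seed),
                mode=config.residual_mode, vg=config.target_vg)
            for scheme in config.schemes:
                for size in config.sizes:
                    for model in config.models:
                        try:
                            rec = _evaluate_cell(system, trait, arch, panel,
                                                 scheme, size, model, r,
                                                 seed_r, config)
                        except Exception as exc:  # cell fails, run continues
                            log.warning("cell (%s, %d, %.2f, %s, rep %d) "
                                        "failed: %s", scheme, size, h2, model,
                                        r, exc)
                            rec = {"scheme": scheme, "size": size, "h2": h2,
                                   "model": model, "replicate": r,
                                   "error": str(exc)}
                        records.append(rec)
    df = pd.DataFrame(records)
    metric_cols = [c for c in df.columns
                   if c not in {"scheme", "size", "h2", "model", "replicate",
                                "error"}]
    ok = df[df.get("error").isna()] if "error" in df.columns else df
    averages = (ok.groupby(["scheme", "size", "h2", "model"], as_index=False)
                  [metric_cols].mean())
    return ExperimentResult(records=df, averages=averages, system=system,
                            architecture=arch)
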