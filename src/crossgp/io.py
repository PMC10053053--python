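"""Reading and writing phased genotypes and rosters.

Supported formats: phased VCF ("|"-separated GT), the PLINK .ped/.map text
dialect, and a plain haplotype TSV.  Every format is accompanied by a roster
sidecar TSV with columns (id, sex, breed, generation, sire, dam).

Reading applies the panel QC used throughout: markers with call rate
< 0.95 or pooled MAF < 0.01 are dropped; any missing genotype surviving QC
is an error (the internal representation is phased-complete).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .founders import ConfigurationError, GenomeMap, PhasedPopulation, ROSTER_COLUMNS

log = logging.getLogger(__name__)

__all__ = ["read_founders", "write_population", "FormatError", "RosterError"]

CALL_RATE_MIN = 0.95
MAF_MIN = 0.01


class FormatError(ValueError):
    """Genotype file violates the phased-biallelic contract."""


class RosterError(ValueError):
    """Roster does not cover the samples in the genotype file."""


def _read_roster(roster_file) -> pd.DataFrame:
    roster = pd.read_csv(roster_file, sep="\t", dtype={"id": str})
    missing = [c for c in ROSTER_COLUMNS if c not in roster.columns]
    if missing:
        raise RosterError(f"roster missing columns {missing}")
    roster["sire"] = roster["sire"].where(pd.notna(roster["sire"]), None)
    roster["dam"] = roster["dam"].where(pd.notna(roster["dam"]), None)
    return roster[ROSTER_COLUMNS]


def _qc_filter(hap: np.ndarray, missing_mask: np.ndarray, genome: GenomeMap
               ) -> tuple[np.ndarray, GenomeMap]:
    """Drop markers failing call rate or MAF; reject residual missingness.

    ``missing_mask`` is (n_individuals, n_markers) boolean.
    """
    n = missing_mask.shape[0]
    call_rate = 1.0 - missing_mask.mean(axis=0)
    with np.errstate(invalid="ignore"):
        # frequencies over called genotypes only
        called = ~missing_mask
        dos = hap[0::2].astype(np.int32) + hap[1::2]
        freq = np.where(called, dos, 0).sum(axis=0) / np.maximum(
            2 * called.sum(axis=0), 1)
    maf = np.minimum(freq, 1.0 - freq)
    keep = (call_rate >= CALL_RATE_MIN) & (maf >= MAF_MIN)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("QC dropped %d of %d markers (call rate < %.2f or MAF < %.2f)",
                 n_drop, keep.size, CALL_RATE_MIN, MAF_MIN)
    if missing_mask[:, keep].any():
        raise FormatError("missing genotypes remain after QC; input must be "
                          "complete on QC-passing markers")
    kept = np.flatnonzero(keep)
    genome_kept = GenomeMap(
        chromosomes=genome.chromosomes,
        lengths=genome.lengths,
        marker_chrom=genome.marker_chrom[kept],
        marker_pos=genome.marker_pos[kept],
        marker_ids=tuple(genome.marker_ids[i] for i in kept),
        ref_alleles=tuple(genome.ref_alleles[i] for i in kept),
        alt_alleles=tuple(genome.alt_alleles[i] for i in kept),
    )
    return hap[:, kept], genome_kept


def _read_vcf(path: str | Path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms: list[str] = []
    pos, chrom_codes, ids, refs, alts = [], [], [], [], []
    hap_rows, miss_rows = [], []
    chrom_code: dict[str, int] = {}
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(f"non-biallelic record at {rec.CHROM}:{rec.POS}")
        gts = np.asarray(rec.genotype.array())  # (n, 3): a0, a1, phased flag
        missing = (gts[:, 0] < 0) | (gts[:, 1] < 0)
        if np.any((gts[~missing, 2] == 0) & (gts[~missing, 0] != gts[~missing, 1])):
            raise FormatError(f"unphased heterozygote at {rec.CHROM}:{rec.POS}")
        if rec.CHROM not in chrom_code:
            chrom_code[rec.CHROM] = len(chrom_code)
            chroms.append(rec.CHROM)
        chrom_codes.append(chrom_code[rec.CHROM])
        pos.append(rec.POS)
        ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        a = np.clip(gts[:, :2], 0, 1).astype(np.int8)
        hap_rows.append(a)
        miss_rows.append(missing)
    if not pos:
        raise FormatError("VCF contains no records")
    n, m = len(samples), len(pos)
    hap = np.empty((2 * n, m), dtype=np.int8)
    missing_mask = np.empty((n, m), dtype=bool)
    for j, (a, miss) in enumerate(zip(hap_rows, miss_rows)):
        hap[0::2, j] = a[:, 0]
        hap[1::2, j] = a[:, 1]
        missing_mask[:, j] = miss
    genome = GenomeMap(
        chromosomes=tuple(chroms),
        lengths=np.array([max(np.asarray(pos)[np.asarray(chrom_codes) == c].max(), 1)
                          for c in range(len(chroms))], dtype=np.int64),
        marker_chrom=np.asarray(chrom_codes),
        marker_pos=np.asarray(pos, dtype=np.int64),
        marker_ids=tuple(ids),
        ref_alleles=tuple(refs),
        alt_alleles=tuple(alts),
    )
    return samples, hap, missing_mask, genome


def _read_plink(prefix: str | Path):
    prefix = Path(prefix)
    mp = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                     names=["chrom", "id", "cm", "pos"], dtype={"chrom": str})
    chroms = list(dict.fromkeys(mp["chrom"]))
    code = {c: i for i, c in enumerate(chroms)}
    samples, hap_rows, miss_rows = [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            samples.append(parts[1])
            alleles = parts[6:]
            if len(alleles) != 2 * len(mp):
                raise FormatError("ped allele count does not match map")
            a = np.array(alleles).reshape(-1, 2)
            miss = (a == "0").any(axis=1)
            hap_rows.append(a)
            miss_rows.append(miss)
    n, m = len(samples), len(mp)
    # map allele labels to 0/1 using first-seen as reference per marker
    hap = np.zeros((2 * n, m), dtype=np.int8)
    missing_mask = np.vstack(miss_rows)
    ref = np.array([None] * m, dtype=object)
    alt = np.array([None] * m, dtype=object)
    for i, a in enumerate(hap_rows):
        for col in range(2):
            lab = a[:, col]
            for j in np.flatnonzero(~missing_mask[i]):
                s = lab[j]
                if ref[j] is None:
                    ref[j] = s
                elif s != ref[j] and alt[j] is None:
                    alt[j] = s
                hap[2 * i + col, j] = 0 if s == ref[j] else 1
    alt[alt == None] = "G"  # noqa: E711 — monomorphic in file
    genome = GenomeMap(
        chromosomes=tuple(chroms),
        lengths=np.array([max(mp.loc[mp["chrom"] == c, "pos"].max(), 1)
                          for c in chroms], dtype=np.int64),
        marker_chrom=mp["chrom"].map(code).to_numpy(),
        marker_pos=mp["pos"].to_numpy(dtype=np.int64),
        marker_ids=tuple(mp["id"]),
        ref_alleles=tuple(str(x) for x in ref),
        alt_alleles=tuple(str(x) for x in alt),
    )
    return samples, hap, missing_mask, genome


def read_founders(genotype_file: str | Path, roster_file: str | Path
                  ) -> PhasedPopulation:
    """Read a phased founder panel plus roster and apply panel QC.

    ``genotype_file`` may be a ``.vcf`` file or a PLINK prefix (``.ped`` +
    ``.map``).  Markers with call rate < 0.95 or MAF < 0.01 are dropped.
    """
    path = Path(genotype_file)
    if path.suffix == ".vcf":
        samples, hap, missing_mask, genome = _read_vcf(path)
    else:
        prefix = path.with_suffix("") if path.suffix in {".ped", ".map"} else path
        samples, hap, missing_mask, genome = _read_plink(prefix)

    roster = _read_roster(roster_file)
    roster_ids = set(roster["id"])
    absent = [s for s in samples if s not in roster_ids]
    if absent:
        raise RosterError(f"samples missing from roster: {absent[:5]}")
    roster = roster.set_index("id").loc[samples].reset_index()

    hap, genome = _qc_filter(hap, missing_mask, genome)
    return PhasedPopulation(roster=roster, haplotypes=hap, genome=genome)


def _write_roster(pop: PhasedPopulation, path: Path) -> None:
    pop.roster[ROSTER_COLUMNS].to_csv(path, sep="\t", index=False)


def write_population(pop: PhasedPopulation, path: str | Path,
                     format: str = "vcf") -> list[Path]:
    """Write phased genotypes plus a roster sidecar.

    ``path`` is a prefix; suffixes are added per format.  Record order is
    deterministic: roster order for samples, map order for markers.
    Returns the list of files written.
    """
    if pop.n == 0 or pop.genome.n_markers == 0:
        raise ConfigurationError("cannot write an empty population")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = pop.genome
    files: list[Path] = []
    if format == "vcf":
        out = path.with_suffix(".vcf")
        with open(out, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c, L in zip(g.chromosomes, g.lengths):
                fh.write(f"##contig=<ID={c},length={int(L)}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(pop.roster["id"]) + "\n")
            h0, h1 = pop.haplotypes[0::2], pop.haplotypes[1::2]
            for j in range(g.n_markers):
                gts = "\t".join(f"{a}|{b}" for a, b in zip(h0[:, j], h1[:, j]))
                fh.write(f"{g.chromosomes[g.marker_chrom[j]]}\t{g.marker_pos[j]}\t"
                         f"{g.marker_ids[j]}\t{g.ref_alleles[j]}\t{g.alt_alleles[j]}"
                         f"\t.\tPASS\t.\tGT\t{gts}\n")
        files.append(out)
    elif format == "plink":
        ped = path.with_suffix(".ped")
        mp = path.with_suffix(".map")
        with open(mp, "w") as fh:
            for j in range(g.n_markers):
                fh.write(f"{g.chromosomes[g.marker_chrom[j]]}\t{g.marker_ids[j]}"
                         f"\t0\t{g.marker_pos[j]}\n")
        labels = np.stack([np.array(g.ref_alleles), np.array(g.alt_alleles)])
        with open(ped, "w") as fh:
            for i, row in pop.roster.iterrows():
                sex_code = "1" if row["sex"] == "male" else "2"
                a0 = labels[pop.haplotypes[2 * i], np.arange(g.n_markers)]
                a1 = labels[pop.haplotypes[2 * i + 1], np.arange(g.n_markers)]
                geno = " ".join(x + " " + y for x, y in zip(a0, a1))
                fh.write(f"FAM {row['id']} 0 0 {sex_code} -9 {geno}\n")
        files.extend([ped, mp])
    elif format == "tsv":
        out = path.with_suffix(".hap.tsv")
        header = "\t".join(g.marker_ids)
        rows = []
        for i, iid in enumerate(pop.roster["id"]):
            for k in (0, 1):
                rows.append(iid + f".h{k}\t"
                            + "\t".join(map(str, pop.haplotypes[2 * i + k])))
        with open(out, "w") as fh:
            fh.write("haplotype\t" + header + "\n")
            fh.write("\n".join(rows) + "\n")
        files.append(out)
    else:
        raise ConfigurationError(f"unknown format {format!r}")
    roster_path = path.parent / (path.name + ".roster.tsv")
    _write_roster(pop, roster_path)
    files.append(roster_path)
    return files
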