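"""Genotype and metadata I/O plus the panel-level quality filters.

Genotypes are held as an individuals x loci matrix of alternate-allele
dosages (0, 1, 2) with ``-1`` as the missing sentinel.  Loci carry a VCF-style
chromosome + 1-based position and a locus identifier (the GBS read a SNP was
called on), so "one SNP per locus" thinning is possible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "Genotypes",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "read_lake_table",
    "read_population_map",
    "read_stocking_matrix",
    "read_metadata",
    "filter_individuals",
    "filter_snps",
]


class GenotypeIOError(ValueError):
    """Malformed or referentially inconsistent input."""


class EmptyResultError(ValueError):
    """A filter removed everything."""


@dataclass
class Genotypes:
    """Biallelic SNP dosage matrix with locus and sample annotations.

    Attributes
    ----------
    individual_ids : list of str
    locus_ids : list of str
        Identifier of the parent locus (read/tag); not necessarily unique
        before one-per-locus thinning.  ``snp_ids`` are unique per column.
    chrom, pos : per-SNP chromosome and 1-based position.
    dosage : (n_individuals, n_snps) int8 array in {0, 1, 2, MISSING}.
    ref_allele, alt_allele : per-SNP nucleotide.
    """

    individual_ids: list
    snp_ids: list
    locus_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        n, m = self.dosage.shape
        if len(self.individual_ids) != n:
            raise GenotypeIOError("dosage rows != number of individuals")
        for name, arr in (("snp_ids", self.snp_ids), ("locus_ids", self.locus_ids),
                          ("chrom", self.chrom), ("pos", self.pos)):
            if len(arr) != m:
                raise GenotypeIOError(f"{name} length != number of SNPs")
        if len(set(self.snp_ids)) != m:
            raise GenotypeIOError("snp_ids are not unique")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise GenotypeIOError("dosage contains values outside {0,1,2,missing}")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def take_individuals(self, idx) -> "Genotypes":
        idx = np.asarray(idx)
        return replace(
            self,
            individual_ids=[self.individual_ids[i] for i in idx],
            dosage=self.dosage[idx, :],
        )

    def take_snps(self, idx) -> "Genotypes":
        idx = np.asarray(idx)
        return replace(
            self,
            snp_ids=[self.snp_ids[i] for i in idx],
            locus_ids=[self.locus_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            dosage=self.dosage[:, idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
        )


@dataclass
class FilterReport:
    """Attrition accounting: each SNP is charged to the first filter it fails."""

    n_input: int = 0
    n_not_biallelic: int = 0
    n_call_rate: int = 0
    n_maf: int = 0
    n_one_per_locus: int = 0
    n_retained: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path) -> tuple[Genotypes, int]:
    """Read biallelic SNP genotypes from a VCF 4.x file.

    Multi-allelic records are excluded; the count of exclusions is returned
    alongside the genotypes.  Missing GT calls become the missing sentinel.
    Uses cyvcf2 for parsing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise GenotypeIOError(f"{path}: VCF has no samples")
    snp_ids, locus_ids, chroms, poss, refs, alts = [], [], [], [], [], []
    columns = []
    n_multiallelic = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multiallelic += 1
            continue
        gts = var.genotype.array()
        a = gts[:, 0].astype(np.int16)
        b = gts[:, 1].astype(np.int16)
        dose = a + b
        dose[(a < 0) | (b < 0)] = MISSING
        columns.append(dose.astype(np.int8))
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snp_ids.append(vid)
        # GBS convention "locus_pos"; fall back to the chromosome as locus
        locus_ids.append(vid.rsplit("_", 1)[0] if "_" in vid else var.CHROM)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    if not columns:
        raise GenotypeIOError(f"{path}: no biallelic records found")
    g = Genotypes(
        individual_ids=samples,
        snp_ids=snp_ids,
        locus_ids=locus_ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss),
        dosage=np.column_stack(columns),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
    )
    return g, n_multiallelic


def write_vcf(g: Genotypes, path) -> None:
    """Write genotypes as a minimal VCF 4.2 text file (GT field only)."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(g.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.individual_ids)) + "\n")
        for j in range(g.n_snps):
            gts = "\t".join(code[int(d)] for d in g.dosage[:, j])
            fh.write(f"{g.chrom[j]}\t{g.pos[j]}\t{g.snp_ids[j]}\t"
                     f"{g.ref_allele[j]}\t{g.alt_allele[j]}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_lake_table(path) -> pd.DataFrame:
    lakes = pd.read_csv(path)
    required = {"lake_code", "area_ha", "latitude", "longitude", "altitude", "stocked"}
    missing = required - set(lakes.columns)
    if missing:
        raise GenotypeIOError(f"lake table missing columns: {sorted(missing)}")
    if lakes["lake_code"].duplicated().any():
        raise GenotypeIOError("duplicate lake codes")
    if (lakes["area_ha"] <= 0).any():
        raise GenotypeIOError("lake area must be strictly positive")
    if lakes["latitude"].abs().gt(90).any():
        raise GenotypeIOError("latitude outside [-90, 90]")
    if lakes["stocked"].dtype != bool:
        lakes["stocked"] = (
            lakes["stocked"].astype(str).str.strip().str.lower()
            .map({"true": True, "false": False, "stocked": True, "unstocked": False})
        )
        if lakes["stocked"].isna().any():
            raise GenotypeIOError("unparseable 'stocked' column")
    return lakes.set_index("lake_code", drop=False)


def read_population_map(path, lakes: pd.DataFrame) -> pd.Series:
    pm = pd.read_csv(path)
    if not {"individual_id", "lake_code"} <= set(pm.columns):
        raise GenotypeIOError("population map needs individual_id,lake_code columns")
    unknown = sorted(set(pm["lake_code"]) - set(lakes["lake_code"]))
    if unknown:
        raise GenotypeIOError(f"population map references unknown lakes: {unknown}")
    if pm["individual_id"].duplicated().any():
        raise GenotypeIOError("individuals mapped more than once")
    return pm.set_index("individual_id")["lake_code"]


def read_stocking_matrix(path, lakes: pd.DataFrame) -> pd.DataFrame:
    sm = pd.read_csv(path, index_col=0)
    if (sm.values < 0).any():
        raise GenotypeIOError("stocking masses must be non-negative")
    unknown = sorted(set(sm.index) - set(lakes["lake_code"]))
    if unknown:
        raise GenotypeIOError(f"stocking matrix sink lakes not in lake table: {unknown}")
    return sm.astype(float)


def read_metadata(lake_path, popmap_path, stocking_path=None):
    """Load the lake table, population map, and (optionally) stocking matrix."""
    lakes = read_lake_table(lake_path)
    popmap = read_population_map(popmap_path, lakes)
    stocking = None
    if stocking_path is not None:
        stocking = read_stocking_matrix(stocking_path, lakes)
    return lakes, popmap, stocking


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_individuals(g: Genotypes, max_missing: float = 0.30) -> Genotypes:
    """Drop individuals whose fraction of missing genotypes exceeds ``max_missing``."""
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    miss = g.missing_mask().mean(axis=1)
    keep = np.flatnonzero(miss <= max_missing)
    if keep.size == 0:
        raise EmptyResultError("all individuals exceed the missingness threshold")
    return g.take_individuals(keep)


def filter_snps(
    g: Genotypes,
    popmap: pd.Series,
    min_pop_call_rate: float = 0.5,
    min_global_maf: float = 0.05,
    one_per_locus: bool = True,
) -> tuple[Genotypes, FilterReport]:
    """Retain SNPs called in >= ``min_pop_call_rate`` of every population,
    with pooled minor-allele frequency strictly above ``min_global_maf``,
    optionally thinned to one SNP per locus (lowest position wins).

    A SNP failing several filters is charged to the first one (call rate ->
    MAF -> one-per-locus) so attrition counts sum to the input size.
    """
    report = FilterReport(n_input=g.n_snps)
    pops = popmap.reindex(g.individual_ids)
    if pops.isna().any():
        unmapped = [i for i, p in zip(g.individual_ids, pops) if pd.isna(p)]
        raise GenotypeIOError(f"individuals missing from population map: {unmapped[:5]}")
    called = g.dosage != MISSING

    # per-population call rate, all populations must pass
    pass_call = np.ones(g.n_snps, dtype=bool)
    for _, idx in pops.groupby(pops).groups.items():
        rows = [g.individual_ids.index(i) for i in idx]
        rate = called[rows, :].mean(axis=0)
        pass_call &= rate >= min_pop_call_rate

    # pooled MAF over all non-missing genotypes
    n_called = called.sum(axis=0)
    alt = np.where(called, g.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    maf = np.fmin(p, 1 - p)
    pass_maf = np.nan_to_num(maf, nan=0.0) > min_global_maf

    # one SNP per locus: lowest position within each locus id
    pass_locus = np.ones(g.n_snps, dtype=bool)
    if one_per_locus:
        order = np.lexsort((g.pos, np.asarray(g.locus_ids, dtype=object)))
        seen = set()
        keep_idx = set()
        survives = pass_call & pass_maf
        for j in order:
            if not survives[j]:
                continue
            if g.locus_ids[j] not in seen:
                seen.add(g.locus_ids[j])
                keep_idx.add(j)
        pass_locus = np.array([j in keep_idx or not survives[j] for j in range(g.n_snps)])

    report.n_call_rate = int((~pass_call).sum())
    report.n_maf = int((pass_call & ~pass_maf).sum())
    report.n_one_per_locus = int((pass_call & pass_maf & ~pass_locus).sum())
    keep = np.flatnonzero(pass_call & pass_maf & pass_locus)
    report.n_retained = int(keep.size)
    if keep.size == 0:
        raise EmptyResultError(f"no SNPs retained; attrition: {report.as_dict()}")
    return g.take_snps(keep), report
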