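"""Forward Wright–Fisher generator for the full analysis surface.

Each lake is an isolated deme founded from a shared ancestral allele pool and
drifting for G generations; putatively deleterious loci experience viability
selection (genotype fitnesses 1, 1-hs, 1-s against the derived allele), and
stocking is modelled as directional admixture pulses: in a scheduled
generation, a number of breeders in the sink lake proportional to the stocked
mass is replaced by fish drawn from the source lake.  The output mirrors the
real study's inputs — a VCF genotype panel, a population map, a lake table
with 9 never-stocked and 15 stocked lakes, a sink x source stocking-mass
matrix, and a codon-level annotation table with PROVEAN-scale effect scores —
plus a manifest of the true simulation parameters.

Defaults emulate the study conditions: 24 lakes with the published areas and
coordinates, strong drift-driven differentiation (pairwise FST spanning
roughly 0.01-0.50), and three SNP classes (synonymous, nonsynonymous-neutral,
deleterious under purifying selection).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import load_lake_table
from .deleterious import ProteinHit, translate_codon
from .genotype_io import MISSING, Genotypes, write_vcf

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_dataset",
           "codon_pair_pools"]


@dataclass
class SimulationConfig:
    """Parameters of the forward simulation.

    Effective sizes scale sublinearly with lake area (larger lakes hold
    larger populations), clipped to [40, 400]; 60 generations of drift at
    those sizes spans the published range of pairwise differentiation.
    Class fractions follow the observed panel composition at reduced scale
    (roughly 60% synonymous-like background, 20% nonsynonymous-neutral,
    20% deleterious).
    """

    n_loci: int = 600
    frac_synonymous: float = 0.6
    frac_nonsyn_neutral: float = 0.2
    frac_deleterious: float = 0.2
    s: float = 0.05
    h: float = 0.5
    generations: int = 65
    ne_base: float = 10.0          # Ne = clip(ne_base * area_ha**0.3, 40, 250)
    ne_min: int = 40
    ne_max: int = 250
    founder_law: str = "uniform"   # ancestral frequencies: uniform(0.05, 0.95) or beta
    fish_per_kg: float = 2.0
    n_sources: int = 6
    pulses_per_pair: int = 3           # recurrent stocking events per sink-source pair
    stocking_start_frac: float = 0.4   # pulse window as fractions of the run;
    stocking_end_frac: float = 0.8     # selection keeps purging after the last pulse
    missing_rate: float = 0.10
    sample_size: int | None = None     # default: published per-lake sample sizes
    seed: int = 1

    def __post_init__(self):
        total = self.frac_synonymous + self.frac_nonsyn_neutral + self.frac_deleterious
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if not (0 <= self.s <= 1 and 0 <= self.h <= 1):
            raise ValueError("selection parameters out of range")


@dataclass
class SyntheticDataset:
    genotypes: Genotypes
    popmap: pd.Series
    lakes: pd.DataFrame
    stocking: pd.DataFrame
    annotations: list            # list[ProteinHit]
    manifest: dict

    def write(self, outdir) -> None:
        """Write VCF + CSV/TSV metadata + manifest.json under ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(self.genotypes, out / "genotypes.vcf")
        self.lakes.to_csv(out / "lakes.csv", index=False)
        self.popmap.rename("lake_code").rename_axis("individual_id").to_csv(
            out / "popmap.csv")
        self.stocking.rename_axis("lake_code").to_csv(out / "stocking.csv")
        ann = pd.DataFrame([{
            "locus_id": h.locus_id,
            "aligned_aa_length": h.aligned_aa_length,
            "aa_identities": h.aa_identities,
            "percent_identity": h.percent_identity,
            "ref_codon": h.ref_codon,
            "alt_codon": h.alt_codon,
            "effect_score": "" if h.effect_score is None else h.effect_score,
        } for h in self.annotations])
        ann.to_csv(out / "annotations.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def codon_pair_pools():
    """Enumerate single-nucleotide codon pairs by synonymy (stop-free).

    Returns ``(synonymous_pairs, nonsynonymous_pairs)`` in a deterministic
    order, for drawing annotation codons consistent with each SNP class.
    """
    bases = "ACGT"
    syn, nonsyn = [], []
    for c1 in ("".join(t) for t in itertools.product(bases, repeat=3)):
        a1 = translate_codon(c1)
        if a1 == "*":
            continue
        for pos in range(3):
            for b in bases:
                if b == c1[pos]:
                    continue
                c2 = c1[:pos] + b + c1[pos + 1:]
                a2 = translate_codon(c2)
                if a2 == "*":
                    continue
                (syn if a1 == a2 else nonsyn).append((c1, c2))
    return syn, nonsyn


def _effective_sizes(lakes: pd.DataFrame, cfg: SimulationConfig) -> pd.Series:
    ne = (cfg.ne_base * lakes["area_ha"].astype(float) ** 0.3).round()
    return ne.clip(cfg.ne_min, cfg.ne_max).astype(int)


def _make_stocking(lakes: pd.DataFrame, cfg: SimulationConfig, rng) -> pd.DataFrame:
    """Synthetic sink x source mass matrix.

    Each stocked lake draws one (sometimes two) donor lakes from a fixed
    source panel with strongly unequal usage weights — supplementation
    programs rely on a few major donor populations — and the recorded mass
    is the total stocked over the program.  Unstocked lakes are all-zero
    rows.
    """
    stocked = lakes.index[lakes["stocked"]].tolist()
    # donors are wild populations: supplementation here uses fish from
    # unstocked lakes, so each source keeps a distinct gene pool
    wild = lakes.index[~lakes["stocked"]].tolist()
    sources = (lakes.loc[wild].sort_values("area_ha", ascending=False)
               .index[:cfg.n_sources].tolist())
    sm = pd.DataFrame(0.0, index=lakes.index, columns=sources)
    if not sources:               # n_sources = 0 disables stocking entirely
        return sm
    w = 0.5 ** np.arange(len(sources))      # dominant-source usage weights
    for sink in stocked:
        k = 1 if rng.random() < 0.7 else 2
        avail = [s for s in sources if s != sink]
        pw = np.array([w[sources.index(s)] for s in avail])
        donors = rng.choice(avail, size=min(k, len(avail)), replace=False,
                            p=pw / pw.sum())
        for d in donors:
            mass = float(np.round(rng.lognormal(mean=4.0, sigma=0.7), 1))
            sm.loc[sink, d] += mass
    return sm


def _selection_step(p: np.ndarray, sel_mask: np.ndarray, s: float, h: float) -> np.ndarray:
    """Deterministic viability selection on derived-allele frequencies."""
    if s == 0 or not sel_mask.any():
        return p
    q = p[sel_mask]
    num = q * q * (1 - s) + q * (1 - q) * (1 - h * s)
    den = q * q * (1 - s) + 2 * q * (1 - q) * (1 - h * s) + (1 - q) ** 2
    out = p.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out[sel_mask] = np.where(den > 0, num / den, 0.0)
    return out


def simulate_dataset(cfg: SimulationConfig | None = None) -> SyntheticDataset:
    """Run the forward simulation and assemble the full synthetic dataset."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    lakes = load_lake_table()
    L = cfg.n_loci
    ne = _effective_sizes(lakes, cfg)

    # locus classes, ancestral frequencies
    n_del = int(round(cfg.frac_deleterious * L))
    n_nsn = int(round(cfg.frac_nonsyn_neutral * L))
    classes = np.array(["synonymous"] * (L - n_del - n_nsn)
                       + ["nonsyn_neutral"] * n_nsn + ["deleterious"] * n_del)
    rng.shuffle(classes)
    if cfg.founder_law == "uniform":
        p0 = rng.uniform(0.05, 0.95, size=L)
    elif cfg.founder_law == "beta":
        p0 = np.clip(rng.beta(0.8, 0.8, size=L), 0.01, 0.99)
    else:
        raise ValueError(f"unknown founder law {cfg.founder_law!r}")
    # deleterious loci share the founder law; purifying selection during the
    # run is the only asymmetry between classes (drift in small unstocked
    # demes can still fix deleterious alleles against it)
    del_mask = classes == "deleterious"

    stocking = _make_stocking(lakes, cfg, rng)
    # pulse schedule: recurrent events per positive sink-source cell, the
    # recorded mass split evenly across them
    g_start = int(cfg.generations * cfg.stocking_start_frac)
    g_end = max(g_start + 1, int(cfg.generations * cfg.stocking_end_frac))
    schedule = []
    for sink in stocking.index:
        for source in stocking.columns:
            mass = stocking.loc[sink, source]
            if mass <= 0 or sink == source:
                continue
            gens = rng.choice(np.arange(g_start, g_end),
                              size=min(cfg.pulses_per_pair, g_end - g_start),
                              replace=False)
            for gen in sorted(int(x) for x in gens):
                m = int(np.clip(round(mass * cfg.fish_per_kg / len(gens)), 1,
                                min(ne[sink] // 2, ne[source])))
                schedule.append((gen, sink, source, m))
    schedule.sort(key=lambda t: (t[0], t[1], t[2]))

    # founding: binomial sampling from the ancestral pool
    freq = {code: rng.binomial(2 * ne[code], p0) / (2.0 * ne[code])
            for code in lakes.index}

    for gen in range(cfg.generations):
        for code in lakes.index:
            p = _selection_step(freq[code], del_mask, cfg.s, cfg.h)
            freq[code] = rng.binomial(2 * ne[code], p) / (2.0 * ne[code])
        for (g, sink, source, m) in schedule:
            if g != gen:
                continue
            n_res = ne[sink] - m
            counts = (rng.binomial(2 * n_res, freq[sink])
                      + rng.binomial(2 * m, freq[source]))
            freq[sink] = counts / (2.0 * ne[sink])

    # final sampling of diploid individuals under local HWE
    ind_ids, pop_codes, rows = [], [], []
    for code in lakes.index:
        n_k = int(lakes.loc[code, "n_sampled"]) if cfg.sample_size is None \
            else cfg.sample_size
        dose = rng.binomial(2, freq[code], size=(n_k, L)).astype(np.int8)
        for i in range(n_k):
            ind_ids.append(f"{code}_{i+1:03d}")
            pop_codes.append(code)
        rows.append(dose)
    dosage = np.vstack(rows)
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = MISSING

    locus_ids = [f"locus{i:05d}" for i in range(L)]
    pos = rng.integers(5, 76, size=L)
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=L)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref],
                   dtype=object)
    g = Genotypes(
        individual_ids=ind_ids,
        snp_ids=[f"{lid}_{p}" for lid, p in zip(locus_ids, pos)],
        locus_ids=locus_ids,
        chrom=np.array(locus_ids, dtype=object),
        pos=pos,
        dosage=dosage,
        ref_allele=ref.astype(object),
        alt_allele=alt,
    )
    popmap = pd.Series(pop_codes, index=ind_ids, name="lake_code")

    annotations = _make_annotations(locus_ids, classes, rng)
    manifest = {
        "config": asdict(cfg),
        "effective_sizes": {k: int(v) for k, v in ne.items()},
        "locus_classes": {lid: str(c) for lid, c in zip(locus_ids, classes)},
        "stocking_schedule": [
            {"generation": g_, "sink": si, "source": so, "n_migrants": m}
            for (g_, si, so, m) in schedule],
        "ancestral_frequencies": [float(x) for x in np.round(p0, 6)],
    }
    return SyntheticDataset(g, popmap, lakes.reset_index(drop=True),
                            stocking, annotations, manifest)


def _make_annotations(locus_ids, classes, rng) -> list:
    """Annotation rows consistent with each locus class.

    Synonymous loci get a synonymous codon pair and no score; nonsynonymous
    loci get a nonsynonymous pair plus a PROVEAN-scale score: deleterious
    N(-5, 1.2) truncated below -2.5, neutral N(0, 1) truncated above -2.5.
    """
    syn_pairs, nonsyn_pairs = codon_pair_pools()
    hits = []
    for lid, cls in zip(locus_ids, classes):
        if cls == "synonymous":
            c1, c2 = syn_pairs[int(rng.integers(len(syn_pairs)))]
            score = None
        else:
            c1, c2 = nonsyn_pairs[int(rng.integers(len(nonsyn_pairs)))]
            if cls == "deleterious":
                score = -5.0 + 1.2 * rng.standard_normal()
                while score >= -2.5:
                    score = -5.0 + 1.2 * rng.standard_normal()
            else:
                score = rng.standard_normal()
                while score <= -2.5:
                    score = rng.standard_normal()
            score = float(np.round(score, 3))
        hits.append(ProteinHit(lid, 26, 26, 1.0, c1, c2, score))
    return hits
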