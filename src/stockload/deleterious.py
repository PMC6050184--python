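"""Codon-level annotation of SNPs and per-population deleterious-load statistics.

A SNP that falls in a well-supported protein alignment carries a reference and
alternate codon.  Translating both classifies it as synonymous or
nonsynonymous; nonsynonymous changes are further labelled by the
physicochemical category of the two amino acids (directionality preserved)
and by an alignment-based effect score on the PROVEAN scale, where scores
below -2.5 mark putatively deleterious substitutions.

Load statistics per population treat the globally minor allele at each
deleterious SNP as the deleterious allele, so a local frequency of 1 means
the deleterious allele is fixed there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .genotype_io import Genotypes
from .popgen_stats import allele_frequencies

__all__ = [
    "AA_CATEGORY",
    "ProteinHit",
    "AnnotatedLocus",
    "translate_codon",
    "filter_protein_hits",
    "annotate_codon_change",
    "classify_effect",
    "load_ratio",
    "load_summary",
    "class_frequency_table",
]

#: Side-chain category of each amino acid (selenocysteine included).
AA_CATEGORY = {
    "R": "Pos", "H": "Pos", "K": "Pos",
    "D": "Neg", "E": "Neg",
    "S": "Unc", "T": "Unc", "N": "Unc", "Q": "Unc",
    "A": "Hyd", "V": "Hyd", "I": "Hyd", "L": "Hyd",
    "M": "Hyd", "F": "Hyd", "Y": "Hyd", "W": "Hyd",
    "C": "Cys", "U": "Sel", "G": "Gly", "P": "Pro",
}

DELETERIOUS_THRESHOLD = -2.5


@dataclass
class ProteinHit:
    """One SNP's best protein alignment with its codon change."""

    locus_id: str
    aligned_aa_length: int
    aa_identities: int
    percent_identity: float
    ref_codon: str
    alt_codon: str
    effect_score: Optional[float] = None

    def __post_init__(self):
        if self.aa_identities > self.aligned_aa_length:
            raise ValueError(f"{self.locus_id}: identities exceed aligned length")


@dataclass
class AnnotatedLocus:
    locus_id: str
    synonymy: str                      # "synonymous" | "nonsynonymous" | "nonsense"
    aa_from: str
    aa_to: str
    cat_from: Optional[str]
    cat_to: Optional[str]
    directed_class: Optional[tuple]    # (cat_from, cat_to)
    undirected_class: Optional[frozenset]
    effect_score: Optional[float]
    effect_class: str                  # "deleterious" | "neutral" | "unclassified"

    @property
    def is_deleterious(self) -> bool:
        return self.effect_class == "deleterious"


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"not an ACGT codon: {codon!r}")
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


def filter_protein_hits(hits: Iterable[ProteinHit], min_identities: int = 25,
                        min_pct: float = 0.95):
    """Keep hits with >= ``min_identities`` identical residues and
    >= ``min_pct`` percent identity; report rejection reasons."""
    kept, counts = [], {"identities": 0, "percent_identity": 0}
    for h in hits:
        if h.aa_identities < min_identities:
            counts["identities"] += 1
        elif h.percent_identity < min_pct:
            counts["percent_identity"] += 1
        else:
            if not h.ref_codon or not h.alt_codon:
                raise ValueError(f"{h.locus_id}: retained hit lacks codons")
            kept.append(h)
    return kept, counts


def classify_effect(score: Optional[float], threshold: float = DELETERIOUS_THRESHOLD) -> str:
    """Deleterious strictly below the threshold, neutral strictly above;
    missing or exactly-threshold scores cannot be attributed."""
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return "unclassified"
    if score < threshold:
        return "deleterious"
    if score > threshold:
        return "neutral"
    return "unclassified"


def annotate_codon_change(hit: ProteinHit, threshold: float = DELETERIOUS_THRESHOLD) -> AnnotatedLocus:
    """Translate the codon pair and assign synonymy, category classes and the
    effect class.  Codons must differ at exactly one position.  Stop-gain or
    stop-loss changes are flagged "nonsense" and carry no category class.
    """
    ref, alt = hit.ref_codon.upper(), hit.alt_codon.upper()
    ndiff = sum(a != b for a, b in zip(ref, alt))
    if ndiff != 1:
        raise ValueError(f"{hit.locus_id}: codons {ref}->{alt} differ at {ndiff} positions")
    aa_from, aa_to = translate_codon(ref), translate_codon(alt)
    if aa_from == "*" or aa_to == "*":
        return AnnotatedLocus(hit.locus_id, "nonsense", aa_from, aa_to,
                              None, None, None, None, hit.effect_score, "unclassified")
    if aa_from == aa_to:
        cat = AA_CATEGORY[aa_from]
        return AnnotatedLocus(hit.locus_id, "synonymous", aa_from, aa_to,
                              cat, cat, None, None, None, "unclassified")
    cf, ct = AA_CATEGORY[aa_from], AA_CATEGORY[aa_to]
    return AnnotatedLocus(hit.locus_id, "nonsynonymous", aa_from, aa_to,
                          cf, ct, (cf, ct), frozenset((cf, ct)),
                          hit.effect_score,
                          classify_effect(hit.effect_score, threshold))


def read_annotation_table(path) -> list[ProteinHit]:
    """Read the per-locus protein-hit TSV."""
    df = pd.read_csv(path, sep="\t")
    hits = []
    for r in df.itertuples(index=False):
        score = getattr(r, "effect_score", None)
        if score is not None and pd.isna(score):
            score = None
        hits.append(ProteinHit(str(r.locus_id), int(r.aligned_aa_length),
                               int(r.aa_identities), float(r.percent_identity),
                               str(r.ref_codon), str(r.alt_codon), score))
    return hits


def load_ratio(del_proportion: float, n_polymorphic: int, n_total: int) -> float:
    """Proportion of deleterious SNPs present, relative to the proportion of
    polymorphic SNPs: ``del_proportion / (n_polymorphic / n_total)``."""
    if n_total <= 0 or n_polymorphic > n_total:
        raise ValueError("invalid panel counts")
    if n_polymorphic == 0:
        raise ZeroDivisionError("load ratio undefined with zero polymorphic SNPs")
    return del_proportion / (n_polymorphic / n_total)


def _deleterious_allele_freqs(g: Genotypes, popmap, ann_by_id: dict):
    """Local frequency of the globally minor allele at each deleterious SNP.

    Returns a (population x SNP) DataFrame restricted to deleterious loci
    present in the panel.
    """
    freq, _n = allele_frequencies(g, popmap)
    global_p = pd.Series(
        np.nanmean(np.where(g.dosage != -1, g.dosage, np.nan), axis=0) / 2.0,
        index=g.snp_ids)
    del_ids = [s for s, lid in zip(g.snp_ids, g.locus_ids)
               if lid in ann_by_id and ann_by_id[lid].is_deleterious]
    # orient each column to the globally minor allele
    sub = freq[del_ids].copy()
    flip = global_p[del_ids] > 0.5
    sub.loc[:, flip[flip].index] = 1.0 - sub.loc[:, flip[flip].index]
    return sub


def load_summary(g: Genotypes, popmap, annotations: Iterable[AnnotatedLocus],
                 diversity: pd.DataFrame, lowfreq_cutoff: float = 0.05) -> pd.DataFrame:
    """Per-population deleterious-load statistics.

    del_present     number of deleterious SNPs whose (globally minor)
                    deleterious allele is locally present (frequency > 0)
    del_proportion  del_present / number of deleterious SNPs panel-wide
    load_ratio      del_proportion / proportion of polymorphic SNPs
    mean_del_maf    mean local frequency of the deleterious allele over
                    present SNPs
    n_fixed_del     deleterious SNPs locally fixed for the deleterious allele
    prop_lowfreq    fraction of present deleterious SNPs below
                    ``lowfreq_cutoff``
    """
    ann_by_id = {a.locus_id: a for a in annotations}
    n_del_total = sum(1 for a in ann_by_id.values() if a.is_deleterious)
    if n_del_total == 0:
        raise ValueError("no deleterious loci among annotations")
    local = _deleterious_allele_freqs(g, popmap, ann_by_id)
    if local.shape[1] == 0:
        raise ValueError("no deleterious loci present in the genotype panel")
    out = []
    for code in local.index:
        f = local.loc[code].to_numpy(dtype=float)
        present = f > 0
        n_present = int(np.nansum(present))
        del_prop = n_present / local.shape[1]
        prop_poly = float(diversity.loc[code, "prop_polymorphic"])
        out.append({
            "lake_code": code,
            "del_present": n_present,
            "del_proportion": del_prop,
            "load_ratio": (del_prop / prop_poly) if prop_poly > 0 else np.nan,
            "mean_del_maf": float(np.nanmean(f[present])) if n_present else 0.0,
            "n_fixed_del": int(np.nansum(f >= 1.0)),
            "prop_lowfreq": float(np.nanmean(f[present] < lowfreq_cutoff)) if n_present else np.nan,
        })
    return pd.DataFrame(out).set_index("lake_code", drop=False)


def class_frequency_table(g: Genotypes, popmap, annotations: Iterable[AnnotatedLocus]) -> pd.DataFrame:
    """Long table of local minor-allele frequencies stratified by SNP class
    (deleterious / nonsynonymous-neutral / synonymous), for the group tests.

    The frequency reported is that of the globally minor allele, so class
    spectra are comparable across populations.
    """
    ann_by_id = {a.locus_id: a for a in annotations}

    def snp_class(a: AnnotatedLocus):
        if a.synonymy == "synonymous":
            return "synonymous"
        if a.synonymy == "nonsynonymous":
            if a.effect_class == "deleterious":
                return "deleterious"
            if a.effect_class == "neutral":
                return "nonsyn_neutral"
        return None

    freq, _ = allele_frequencies(g, popmap)
    global_p = pd.Series(
        np.nanmean(np.where(g.dosage != -1, g.dosage, np.nan), axis=0) / 2.0,
        index=g.snp_ids)
    recs = []
    for sid, lid in zip(g.snp_ids, g.locus_ids):
        a = ann_by_id.get(lid)
        if a is None:
            continue
        cls = snp_class(a)
        if cls is None:
            continue
        col = freq[sid]
        oriented = 1.0 - col if global_p[sid] > 0.5 else col
        for code, val in oriented.items():
            if not np.isnan(val):
                recs.append({"lake_code": code, "snp_id": sid,
                             "snp_class": cls, "freq": float(val)})
    return pd.DataFrame(recs)
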