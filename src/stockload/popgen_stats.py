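"""Per-population diversity summaries and Weir–Cockerham pairwise FST.

The FST estimator is the WC84 theta built from per-locus variance components
(a: among populations, b: among individuals within populations, c: within
individuals), combined across loci as a ratio of sums.  Significance and
confidence intervals come from bootstrapping loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, Genotypes

__all__ = [
    "allele_frequencies",
    "diversity_summary",
    "wc84_components",
    "pairwise_fst",
    "FstMatrix",
]


def _pop_rows(g: Genotypes, popmap: pd.Series) -> dict[str, np.ndarray]:
    """Row indices of each population, in sorted population order."""
    pops = popmap.reindex(g.individual_ids)
    if pops.isna().any():
        raise ValueError("every genotyped individual must be in the population map")
    out = {}
    for code in sorted(pops.unique()):
        out[code] = np.flatnonzero((pops == code).values)
    return out


def allele_frequencies(g: Genotypes, popmap: pd.Series):
    """Per-population alternate-allele frequencies with per-cell sample sizes.

    Returns ``(freq, n)`` DataFrames of shape (population x SNP); cells with
    zero non-missing calls are NaN in ``freq`` and 0 in ``n``.
    """
    rows = _pop_rows(g, popmap)
    called = g.dosage != MISSING
    freq, size = {}, {}
    for code, idx in rows.items():
        c = called[idx, :]
        n = c.sum(axis=0)
        alt = np.where(c, g.dosage[idx, :], 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2.0 * n), np.nan)
        freq[code] = p
        size[code] = n
    cols = list(g.snp_ids)
    return (pd.DataFrame(freq, index=cols).T, pd.DataFrame(size, index=cols).T)


def diversity_summary(g: Genotypes, popmap: pd.Series, sites_per_locus: int = 1) -> pd.DataFrame:
    """Observed/expected heterozygosity, nucleotide diversity and polymorphism
    counts per population.

    He uses the small-sample (Nei) correction ``2p(1-p) * n/(n-1)`` per SNP
    with n the local number of genotyped individuals; means are taken over
    SNPs genotyped in the population (monomorphic SNPs count as zeros).  Pi is
    the mean corrected heterozygosity over locally variant sites, divided by
    ``sites_per_locus`` to express it per sequenced site when each SNP tags a
    read of known length.
    """
    if sites_per_locus < 1:
        raise ValueError("sites_per_locus must be >= 1")
    rows = _pop_rows(g, popmap)
    called = g.dosage != MISSING
    out = []
    for code, idx in rows.items():
        c = called[idx, :]
        n = c.sum(axis=0)
        genotyped = n > 0
        if not genotyped.any():
            raise ValueError(f"population {code} has zero genotyped SNPs")
        d = g.dosage[idx, :]
        alt = np.where(c, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(genotyped, alt / (2.0 * n), np.nan)
        het = np.where(c, d == 1, False).sum(axis=0)
        ho_site = np.where(genotyped, het / np.maximum(n, 1), np.nan)
        corr = np.where(n > 1, n / np.maximum(n - 1.0, 1.0), 1.0)
        he_site = 2.0 * p * (1.0 - p) * corr
        poly = genotyped & (p > 0) & (p < 1)
        out.append({
            "lake_code": code,
            "genotype_ratio": float(genotyped.mean()),
            "Ho": float(np.nanmean(ho_site[genotyped])),
            "He": float(np.nanmean(he_site[genotyped])),
            "pi": float(he_site[poly].mean() / sites_per_locus) if poly.any() else 0.0,
            "n_polymorphic": int(poly.sum()),
            "prop_polymorphic": float(poly.sum() / g.n_snps),
        })
    return pd.DataFrame(out).set_index("lake_code", drop=False)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta
# ---------------------------------------------------------------------------

def wc84_components(dosage: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-locus WC84 variance components (a, b, c) for r populations.

    ``dosage`` is individuals x loci with the missing sentinel; ``groups``
    lists the row indices of each population.  Loci where fewer than two
    populations have >= 1 genotyped individual (or nc <= 0) get NaN rows.
    Returns an array (loci, 3).
    """
    r = len(groups)
    if r < 2:
        raise ValueError("need at least two populations")
    L = dosage.shape[1]
    ni = np.zeros((r, L))
    pi = np.zeros((r, L))
    hi = np.zeros((r, L))
    for k, idx in enumerate(groups):
        d = dosage[idx, :]
        c = d != MISSING
        n = c.sum(axis=0).astype(float)
        ni[k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            pi[k] = np.where(n > 0, np.where(c, d, 0).sum(axis=0) / (2 * n), np.nan)
            hi[k] = np.where(n > 0, np.where(c, d == 1, False).sum(axis=0) / n, np.nan)

    ok = (ni > 0).sum(axis=0) >= 2
    # treat populations with zero calls as absent: restrict sums to ni > 0
    w = ni > 0
    r_eff = w.sum(axis=0).astype(float)
    nbar = ni.sum(axis=0) / np.maximum(r_eff, 1)
    nsum = ni.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (ni**2).sum(axis=0) / np.maximum(nsum, 1e-12)) / np.maximum(r_eff - 1, 1)
        pbar = np.nansum(np.where(w, ni * pi, 0), axis=0) / np.maximum(nsum, 1e-12)
        s2 = np.nansum(np.where(w, ni * (pi - pbar) ** 2, 0), axis=0) / np.maximum(
            (r_eff - 1) * nbar, 1e-12)
        hbar = np.nansum(np.where(w, ni * hi, 0), axis=0) / np.maximum(nsum, 1e-12)

        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r_eff - 1) / r_eff) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r_eff - 1) / r_eff) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c_ = hbar / 2.0

    comp = np.stack([a, b, c_], axis=1)
    comp[~ok | (nbar <= 1) | (nc <= 0), :] = np.nan
    return comp


def theta_from_components(comp: np.ndarray) -> float:
    """Multi-locus theta as ratio of summed components, clamped to [-1, 1]."""
    ok = ~np.isnan(comp).any(axis=1)
    num = comp[ok, 0].sum()
    den = comp[ok].sum()
    if den == 0:
        return np.nan
    return float(np.clip(num / den, -1.0, 1.0))


@dataclass
class FstMatrix:
    populations: list
    theta: pd.DataFrame           # square, symmetric, zero diagonal
    pvalue: pd.DataFrame          # bootstrap P(theta <= 0)
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame

    @property
    def mean_per_population(self) -> pd.Series:
        t = self.theta.values.copy()
        np.fill_diagonal(t, np.nan)
        return pd.Series(np.nanmean(t, axis=1), index=self.populations)

    def condensed(self) -> pd.DataFrame:
        recs = []
        for i, a in enumerate(self.populations):
            for b in self.populations[i + 1:]:
                recs.append({
                    "pop1": a, "pop2": b,
                    "theta": self.theta.loc[a, b],
                    "p": self.pvalue.loc[a, b],
                    "ci_low": self.ci_low.loc[a, b],
                    "ci_high": self.ci_high.loc[a, b],
                })
        return pd.DataFrame(recs)


def pairwise_fst(g: Genotypes, popmap: pd.Series, n_boot: int = 1000,
                 seed: int = 0) -> FstMatrix:
    """Pairwise WC84 theta for every population pair with locus bootstrap.

    The bootstrap resamples loci with replacement ``n_boot`` times; the
    p-value is the proportion of replicates with theta <= 0 and the CI the
    2.5/97.5 percentiles.  Deterministic given ``seed``; pairs are processed
    in sorted order, each with an independent child generator so results do
    not depend on pair enumeration order.
    """
    rows = _pop_rows(g, popmap)
    pops = list(rows)
    k = len(pops)
    if k < 2:
        raise ValueError("pairwise FST needs at least two populations")
    theta = np.zeros((k, k))
    pval = np.full((k, k), np.nan)
    lo = np.full((k, k), np.nan)
    hi = np.full((k, k), np.nan)
    root = np.random.SeedSequence(seed)
    for i in range(k):
        for j in range(i + 1, k):
            comp = wc84_components(g.dosage, [rows[pops[i]], rows[pops[j]]])
            ok = ~np.isnan(comp).any(axis=1)
            comp = comp[ok]
            if comp.shape[0] == 0:
                raise ValueError(f"pair ({pops[i]},{pops[j]}): no usable loci")
            t = theta_from_components(comp)
            theta[i, j] = theta[j, i] = t
            # canonical locus order so bootstrap draws are order-invariant
            comp = comp[np.lexsort(comp.T)]
            if n_boot > 0:
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=root.entropy, spawn_key=(i, j)))
                L = comp.shape[0]
                idx = rng.integers(0, L, size=(n_boot, L))
                num = comp[idx, 0].sum(axis=1)
                den = comp[idx].sum(axis=(1, 2))
                with np.errstate(invalid="ignore", divide="ignore"):
                    reps = np.clip(num / den, -1, 1)
                pval[i, j] = pval[j, i] = float(np.mean(reps <= 0))
                lo[i, j] = lo[j, i] = float(np.percentile(reps, 2.5))
                hi[i, j] = hi[j, i] = float(np.percentile(reps, 97.5))
    def df(m):
        return pd.DataFrame(m, index=pops, columns=pops)
    np.fill_diagonal(theta, 0.0)
    return FstMatrix(pops, df(theta), df(pval), df(lo), df(hi))
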