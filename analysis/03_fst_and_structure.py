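#!/usr/bin/env python
"""Pairwise differentiation and population structure.

Weir-Cockerham pairwise FST with locus bootstrap over all 24 lakes, plus a
DAPC-style cluster analysis (per-lake imputation, PCA, k-means with BIC
model choice, LDA posteriors) giving the admixture-proxy Q matrix.
"""

import argparse
from pathlib import Path

import numpy as np

from stockload import genotype_io, ordination, popgen_stats

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-boot", type=int, default=200)
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    g, _ = genotype_io.read_vcf(args.out / "filtered.vcf")
    lakes, popmap, _ = genotype_io.read_metadata(
        args.out / "synthetic" / "lakes.csv",
        args.out / "synthetic" / "popmap.csv")

    fst = popgen_stats.pairwise_fst(g, popmap, n_boot=args.n_boot, seed=args.seed)
    fst.theta.to_csv(args.out / "fst_matrix.tsv", sep="\t")
    fst.condensed().to_csv(args.out / "fst_pairs.tsv", sep="\t", index=False)
    t = fst.theta.values[np.triu_indices(len(fst.populations), 1)]
    print(f"pairwise FST: min {t.min():.3f}, median {np.median(t):.3f}, "
          f"max {t.max():.3f}")
    mt = fst.mean_per_population
    print(f"mean per-lake FST: lowest {mt.idxmin()} ({mt.min():.3f}), "
          f"highest {mt.idxmax()} ({mt.max():.3f})")

    gi = ordination.impute_by_population(g, popmap)
    q = ordination.dapc(gi, k_max=30, seed=args.seed)
    q.q.to_csv(args.out / "q_matrix.tsv", sep="\t")
    q.by_population(popmap).to_csv(args.out / "q_by_lake.tsv", sep="\t")
    print(f"DAPC: chose K = {q.k} clusters on {q.n_pcs} PCs "
          f"(BIC minimum band rule)")
    print(f"wrote {args.out / 'fst_matrix.tsv'} and {args.out / 'q_matrix.tsv'}")


if __name__ == "__main__":
    main()
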