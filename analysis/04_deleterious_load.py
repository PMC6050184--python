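#!/usr/bin/env python
"""Deleterious-mutation annotation and per-lake load statistics.

Filters protein hits (>= 25/26 identities, >= 95% identity), classifies
codon changes (synonymy, side-chain category, PROVEAN-scale effect class at
the -2.5 threshold) and computes the per-lake load surface: number and
proportion of deleterious SNPs present, the load ratio (deleterious
proportion over polymorphic proportion), mean deleterious minor-allele
frequency and fixed deleterious counts.
"""

import argparse
from pathlib import Path

from stockload import deleterious, genotype_io, popgen_stats

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "synthetic")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    g, _ = genotype_io.read_vcf(args.out / "filtered.vcf")
    lakes, popmap, _ = genotype_io.read_metadata(
        args.data / "lakes.csv", args.data / "popmap.csv")
    hits = deleterious.read_annotation_table(args.data / "annotations.tsv")
    hits, rejected = deleterious.filter_protein_hits(hits)
    ann = [deleterious.annotate_codon_change(h) for h in hits]
    n_syn = sum(a.synonymy == "synonymous" for a in ann)
    n_non = sum(a.synonymy == "nonsynonymous" for a in ann)
    n_del = sum(a.is_deleterious for a in ann)
    print(f"annotations: {len(ann)} hits kept ({sum(rejected.values())} rejected); "
          f"{n_syn} synonymous, {n_non} nonsynonymous, {n_del} deleterious")

    div = popgen_stats.diversity_summary(g, popmap, sites_per_locus=80)
    load = deleterious.load_summary(g, popmap, ann, div)
    load.to_csv(args.out / "load_summary.tsv", sep="\t", index=False)
    cls = deleterious.class_frequency_table(g, popmap, ann)
    cls.to_csv(args.out / "class_frequencies.tsv", sep="\t", index=False)

    stocked = lakes.index[lakes["stocked"]]
    unstocked = lakes.index[~lakes["stocked"]]
    print(f"mean load ratio: stocked "
          f"{load.loc[stocked, 'load_ratio'].mean():.3f} vs unstocked "
          f"{load.loc[unstocked, 'load_ratio'].mean():.3f}")
    fixed = load[load["n_fixed_del"] > 0]
    print(f"lakes with fixed deleterious alleles: "
          f"{', '.join(fixed['lake_code']) or 'none'}")
    print(f"wrote {args.out / 'load_summary.tsv'}")


if __name__ == "__main__":
    main()
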