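#!/usr/bin/env python
"""Group tests: the published-table reproduction and the synthetic contrasts.

Part 1 recomputes the population-level statistics from the packaged printed
per-lake summary (no genotypes needed): the stocked/unstocked Welch t test
on the load ratio, neutral-He group means, column medians, deleterious-MAF
means and the fixed-allele count.  Part 2 runs the same tests on the
synthetic dataset: load-ratio and He contrasts, class-stratified MAF t
tests, the population-effect MANOVA on deleterious allele frequencies, and
the directed/undirected substitution-class ANOVAs on effect scores.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from stockload import deleterious, genotype_io, group_tests, popgen_stats
from stockload.pipeline import printed_table_statistics, _genotype_group_tests, _result_dict

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "synthetic")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    print("== published per-lake table ==")
    st = printed_table_statistics()
    t = st["load_ratio_ttest"]
    print(f"load ratio, stocked vs unstocked: t = {t.t:.4f}, df = {t.df:.3f}, "
          f"p = {t.p:.3f}; means {st['mean_load_ratio_stocked']:.2f} / "
          f"{st['mean_load_ratio_unstocked']:.2f}")
    print(f"neutral He means: stocked {st['mean_he_neutral_stocked']:.2f}, "
          f"unstocked {st['mean_he_neutral_unstocked']:.2f} "
          f"(t-test p = {st['he_neutral_ttest'].p:.3f})")
    print(f"median deleterious proportion {st['median_del_proportion']:.3f}; "
          f"median Pi {st['median_pi']:.2e}")
    print(f"deleterious MAF means: stocked {st['mean_del_maf_stocked']:.3f}, "
          f"unstocked {st['mean_del_maf_unstocked']:.3f}")
    print(f"populations with fixed deleterious alleles: "
          f"{st['n_pops_with_fixed_deleterious']}")
    print(f"worked TU load ratio: {st['tu_load_ratio']:.2f}")

    print("\n== synthetic dataset ==")
    g, _ = genotype_io.read_vcf(args.out / "filtered.vcf")
    lakes, popmap, _ = genotype_io.read_metadata(
        args.data / "lakes.csv", args.data / "popmap.csv")
    hits = deleterious.read_annotation_table(args.data / "annotations.tsv")
    hits, _rej = deleterious.filter_protein_hits(hits)
    ann = [deleterious.annotate_codon_change(h) for h in hits]
    div = popgen_stats.diversity_summary(g, popmap, sites_per_locus=80)
    load = deleterious.load_summary(g, popmap, ann, div)
    tests = _genotype_group_tests(g, popmap, lakes, ann, div, load)
    for name, res in tests.items():
        d = _result_dict(res)
        stat = d.get("t", d.get("F", d.get("pillai")))
        print(f"{name}: statistic = {stat:.3f}, p = {d['p']:.4f}")

    out = {"published_table": {k: _result_dict(v) for k, v in st.items()},
           "synthetic": {k: _result_dict(v) for k, v in tests.items()}}
    (args.out / "group_tests.json").write_text(json.dumps(out, indent=2, default=float))
    print(f"\nwrote {args.out / 'group_tests.json'}")


if __name__ == "__main__":
    main()
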