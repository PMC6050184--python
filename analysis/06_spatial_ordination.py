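#!/usr/bin/env python
"""Spatially-controlled constrained ordination of differentiation.

Builds the spatial eigenvector basis (db-MEM) from the lake coordinates,
prepares the stocking predictors (area-normalized, Hellinger-transformed
mass matrix; PCA with broken-stick retention), then runs the db-RDA chain
on the FST principal coordinates: forward selection among stocking PCs and
spatial axes, the global model, and the partial db-RDA isolating the
stocking fraction after controlling for space.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from stockload import genotype_io, ordination, spatial

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-perm", type=int, default=499)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "synthetic")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    lakes, popmap, stocking = genotype_io.read_metadata(
        args.data / "lakes.csv", args.data / "popmap.csv",
        args.data / "stocking.csv")
    fst = pd.read_csv(args.out / "fst_matrix.tsv", sep="\t", index_col=0)
    pops = list(fst.index)

    lk = lakes.loc[pops]
    mem = spatial.build_dbmem(spatial.geo_to_meters(
        lk["latitude"], lk["longitude"], lk["altitude"]))
    pd.DataFrame(mem.eigenvectors, index=pops,
                 columns=[f"MEM{i+1}" for i in range(mem.n_axes)]
                 ).to_csv(args.out / "dbmem.tsv", sep="\t")
    print(f"db-MEM: {mem.n_axes} axes, truncation "
          f"{mem.truncation_threshold/1000:.0f} km")

    pco = ordination.pcoa(np.clip(fst.values, 0, None), min_axis_var=0.05)
    y = pco.retained_scores()
    print(f"PCoA of FST: {int(pco.retained.sum())} axes >= 5% "
          f"({pco.proportions[pco.retained].sum():.0%} of variance)")

    hel = ordination.hellinger_stocking(stocking.loc[pops], lakes)
    pca = ordination.pca_broken_stick(hel.values)
    nstock = max(int(pca.retained.sum()), 1)
    print(f"stocking PCA: {nstock} axes retained by broken stick "
          f"({pca.proportions[:nstock].sum():.0%} of variance)")

    cands = {f"stockPC{i+1}": pca.scores[:, [i]] for i in range(nstock)}
    cands.update({f"MEM{i+1}": mem.eigenvectors[:, [i]]
                  for i in range(mem.n_axes)})
    selected, log = ordination.forward_select(
        y, cands, alpha=0.05, n_perm=args.n_perm, seed=args.seed)
    print(f"forward selection kept: {selected or 'nothing'}")

    report = {"pco_retained": int(pco.retained.sum()),
              "stock_pcs": nstock, "mem_axes": mem.n_axes,
              "selected": selected,
              "selection_log": log.to_dict("records")}
    if selected:
        x = np.hstack([cands[s] for s in selected])
        full = ordination.rda(y, x, n_perm=args.n_perm, seed=args.seed)
        print(f"global model: R2 = {full.r2:.3f} (adj {full.adj_r2:.3f}), "
              f"F = {full.F:.2f}, p = {full.p:.4f}, "
              f"max VIF = {full.max_vif if full.max_vif else 1.0:.2f}")
        report["global"] = {"r2": full.r2, "adj_r2": full.adj_r2,
                            "F": full.F, "p": full.p, "max_vif": full.max_vif}
        sstock = [s for s in selected if s.startswith("stock")]
        smem = [s for s in selected if s.startswith("MEM")]
        if sstock and smem:
            part = ordination.partial_rda(
                y, np.hstack([cands[s] for s in sstock]),
                np.hstack([cands[s] for s in smem]),
                n_perm=args.n_perm, seed=args.seed)
            print(f"stocking after space: semipartial R2 = {part.r2:.3f}, "
                  f"p = {part.p:.4f}")
            report["stocking_partial"] = {"r2": part.r2, "adj_r2": part.adj_r2,
                                          "F": part.F, "p": part.p}
    if not any(s.startswith("stock") for s in selected):
        print("note: under the default strong-drift conditions the stocking "
              "fraction of FST variance is small; detection at n = 24 lakes "
              "requires a stronger admixture signal (heavier/later pulses).")
    (args.out / "rda_report.json").write_text(
        json.dumps(report, indent=2, default=float))
    print(f"wrote {args.out / 'rda_report.json'}")


if __name__ == "__main__":
    main()
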