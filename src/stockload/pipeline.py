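"""End-to-end orchestration: filter -> diversity -> FST -> load -> group tests
-> spatial basis -> constrained ordination, with all artifacts written as
TSV/JSON.  Also provides the printed-table mode, which reproduces the
population-level statistics directly from the packaged per-lake summary when
no genotypes are available.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import datasets, deleterious, genotype_io, group_tests, ordination, popgen_stats, spatial

log = logging.getLogger("stockload")

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis",
           "printed_table_statistics"]


@dataclass
class AnalysisConfig:
    vcf: str
    popmap: str
    lakes: str
    stocking: Optional[str] = None
    annotations: Optional[str] = None
    outlier_loci: Optional[str] = None   # one locus id per line; excluded from "neutral"
    outdir: str = "results"
    max_missing: float = 0.30
    min_pop_call_rate: float = 0.5
    min_maf: float = 0.05
    one_per_locus: bool = True
    sites_per_locus: int = 80
    effect_threshold: float = -2.5
    n_boot: int = 200
    n_perm: int = 199
    min_axis_var: float = 0.05
    alpha: float = 0.05
    seed: int = 1

    @classmethod
    def from_yaml(cls, path):
        import yaml
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class AnalysisReport:
    diversity: pd.DataFrame
    load: Optional[pd.DataFrame]
    fst_neutral: popgen_stats.FstMatrix
    fst_deleterious: Optional[popgen_stats.FstMatrix]
    tests: dict
    ordination: dict
    provenance: dict


def _stage(name):
    log.info("stage: %s", name)


def run_full_analysis(cfg: AnalysisConfig) -> AnalysisReport:
    """Run the whole analysis; every artifact lands under ``cfg.outdir``.

    Deterministic given ``cfg.seed``; any stage failure raises with the
    stage name while earlier artifacts remain on disk.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read-inputs"
    try:
        g, n_multi = genotype_io.read_vcf(cfg.vcf)
        lakes, popmap, stocking = genotype_io.read_metadata(
            cfg.lakes, cfg.popmap, cfg.stocking)

        stage = "filter"
        _stage(stage)
        g = genotype_io.filter_individuals(g, cfg.max_missing)
        g, report = genotype_io.filter_snps(
            g, popmap, cfg.min_pop_call_rate, cfg.min_maf, cfg.one_per_locus)
        report.n_not_biallelic = n_multi
        (out / "filter_report.json").write_text(json.dumps(report.as_dict(), indent=2))

        outliers = set()
        if cfg.outlier_loci:
            outliers = {l.strip() for l in Path(cfg.outlier_loci).read_text().split()
                        if l.strip()}
        neutral_idx = [j for j, lid in enumerate(g.locus_ids) if lid not in outliers]
        g_neutral = g.take_snps(neutral_idx) if outliers else g

        stage = "diversity"
        _stage(stage)
        div = popgen_stats.diversity_summary(g, popmap, cfg.sites_per_locus)
        div_neutral = popgen_stats.diversity_summary(g_neutral, popmap, cfg.sites_per_locus)
        div.to_csv(out / "diversity_summary.tsv", sep="\t")
        div_neutral.to_csv(out / "diversity_summary_neutral.tsv", sep="\t")

        stage = "fst"
        _stage(stage)
        fst_neutral = popgen_stats.pairwise_fst(g_neutral, popmap,
                                                n_boot=cfg.n_boot, seed=cfg.seed)
        fst_neutral.theta.to_csv(out / "fst_matrix.tsv", sep="\t")
        fst_neutral.condensed().to_csv(out / "fst_pairs.tsv", sep="\t", index=False)

        ann = None
        load = None
        fst_del = None
        tests: dict = {}
        if cfg.annotations:
            stage = "deleterious-load"
            _stage(stage)
            hits = deleterious.read_annotation_table(cfg.annotations)
            hits, _rej = deleterious.filter_protein_hits(hits)
            ann = [deleterious.annotate_codon_change(h, cfg.effect_threshold)
                   for h in hits]
            load = deleterious.load_summary(g, popmap, ann, div)
            load.to_csv(out / "load_summary.tsv", sep="\t")
            del_loci = {a.locus_id for a in ann if a.is_deleterious}
            del_idx = [j for j, lid in enumerate(g.locus_ids) if lid in del_loci]
            if len(del_idx) >= 2:
                fst_del = popgen_stats.pairwise_fst(
                    g.take_snps(del_idx), popmap, n_boot=cfg.n_boot, seed=cfg.seed)
                fst_del.theta.to_csv(out / "fst_matrix_deleterious.tsv", sep="\t")

            stage = "group-tests"
            _stage(stage)
            tests = _genotype_group_tests(g, popmap, lakes, ann, div_neutral, load)

        stage = "dbmem"
        _stage(stage)
        lk = lakes.loc[sorted(popmap.unique())]
        coords = spatial.geo_to_meters(lk["latitude"], lk["longitude"], lk["altitude"])
        mem = spatial.build_dbmem(coords)
        pd.DataFrame(mem.eigenvectors, index=lk.index,
                     columns=[f"MEM{i+1}" for i in range(mem.n_axes)]
                     ).to_csv(out / "dbmem.tsv", sep="\t")

        stage = "ordination"
        _stage(stage)
        ords = _ordination_block(cfg, g_neutral, popmap, lakes, stocking, mem,
                                 fst_neutral, fst_del)
        (out / "rda_report.json").write_text(json.dumps(ords, indent=2, default=float))

        provenance = {
            "inputs": {"vcf": str(cfg.vcf), "popmap": str(cfg.popmap),
                       "lakes": str(cfg.lakes), "stocking": cfg.stocking,
                       "annotations": cfg.annotations},
            "seed": cfg.seed,
            "thresholds": {"max_missing": cfg.max_missing,
                           "min_pop_call_rate": cfg.min_pop_call_rate,
                           "min_maf": cfg.min_maf,
                           "effect_threshold": cfg.effect_threshold},
            "filter_report": report.as_dict(),
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
        if tests:
            (out / "group_tests.json").write_text(
                json.dumps({k: _result_dict(v) for k, v in tests.items()}, indent=2))
        return AnalysisReport(div, load, fst_neutral, fst_del, tests, ords, provenance)
    except Exception as exc:
        raise RuntimeError(f"analysis failed at stage '{stage}': {exc}") from exc


def _result_dict(r):
    if hasattr(r, "__dict__"):
        return {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in r.__dict__.items()}
    return r


def _genotype_group_tests(g, popmap, lakes, ann, div_neutral, load) -> dict:
    stocked = lakes.loc[lakes["stocked"], "lake_code"]
    unstocked = lakes.loc[~lakes["stocked"], "lake_code"]
    tests = {}
    he = div_neutral["He"]
    tests["he_stocked_vs_unstocked"] = group_tests.welch_t_test(
        he.reindex(stocked).dropna(), he.reindex(unstocked).dropna())
    lr = load["load_ratio"]
    tests["load_ratio_stocked_vs_unstocked"] = group_tests.welch_t_test(
        lr.reindex(stocked).dropna(), lr.reindex(unstocked).dropna())
    cls = deleterious.class_frequency_table(g, popmap, ann)
    for grp, codes in (("stocked", set(stocked)), ("unstocked", set(unstocked))):
        sub = cls[cls["lake_code"].isin(codes) & (cls["freq"] > 0)]
        d = sub.loc[sub["snp_class"] == "deleterious", "freq"]
        n = sub.loc[sub["snp_class"] == "nonsyn_neutral", "freq"]
        s = sub.loc[sub["snp_class"] == "synonymous", "freq"]
        if len(d) > 1 and len(n) > 1:
            tests[f"maf_del_vs_nonsyn_{grp}"] = group_tests.welch_t_test(d, n)
        if len(d) > 1 and len(s) > 1:
            tests[f"maf_del_vs_syn_{grp}"] = group_tests.welch_t_test(d, s)
    # MANOVA: population effect on deleterious allele frequencies (long layout)
    dele = cls[cls["snp_class"] == "deleterious"]
    if dele["lake_code"].nunique() >= 2:
        tests["manova_population"] = group_tests.population_effect_manova(
            dele["freq"].to_numpy(), dele["lake_code"].to_numpy())
    # effect-score class ANOVAs (directed and undirected), nonsense excluded
    nonsyn = [a for a in ann if a.synonymy == "nonsynonymous"
              and a.effect_score is not None]
    if len({a.directed_class for a in nonsyn}) >= 2:
        scores = [a.effect_score for a in nonsyn]
        tests["anova_directed"] = group_tests.one_way_anova(
            scores, ["->".join(a.directed_class) for a in nonsyn])
        tests["anova_undirected"] = group_tests.one_way_anova(
            scores, ["|".join(sorted(a.undirected_class)) for a in nonsyn])
    return tests


def _ordination_block(cfg, g_neutral, popmap, lakes, stocking, mem,
                      fst_neutral, fst_del) -> dict:
    """db-RDA of FST-PCo axes (and, when available, the deleterious FST and
    Q-matrix responses) on stocking PC axes conditioned on db-MEMs."""
    out = {}
    mem_block = {f"MEM{i+1}": mem.eigenvectors[:, [i]]
                 for i in range(mem.n_axes)}
    stock_block = {}
    if stocking is not None:
        hel = ordination.hellinger_stocking(
            stocking.loc[fst_neutral.populations], lakes)
        pca = ordination.pca_broken_stick(hel.values)
        n_keep = max(int(pca.retained.sum()), 1)
        for i in range(n_keep):
            stock_block[f"stockPC{i+1}"] = pca.scores[:, [i]]
        out["stocking_pca"] = {
            "proportions": pca.proportions.tolist(),
            "broken_stick": pca.broken_stick.tolist(),
            "n_retained": int(pca.retained.sum()),
        }

    responses = {"fst_neutral": fst_neutral}
    if fst_del is not None:
        responses["fst_deleterious"] = fst_del
    for name, fst in responses.items():
        pco = ordination.pcoa(np.clip(fst.theta.values, 0, None), cfg.min_axis_var)
        y = pco.retained_scores()
        if y.shape[1] == 0:
            y = pco.scores[:, :1]
        entry = {"n_pco_retained": int(pco.retained.sum()),
                 "pco_proportions": pco.proportions.tolist()}
        candidates = {**stock_block, **mem_block}
        selected, sel_log = ordination.forward_select(
            y, candidates, alpha=cfg.alpha, n_perm=cfg.n_perm, seed=cfg.seed)
        entry["selected"] = selected
        if selected:
            x = np.hstack([candidates[s] for s in selected])
            full = ordination.rda(y, x, n_perm=cfg.n_perm, seed=cfg.seed)
            entry["global"] = {"r2": full.r2, "adj_r2": full.adj_r2,
                               "F": full.F, "p": full.p, "max_vif": full.max_vif}
        sel_stock = [s for s in selected if s.startswith("stockPC")]
        sel_mem = [s for s in selected if s.startswith("MEM")]
        if sel_stock and sel_mem:
            part = ordination.partial_rda(
                y, np.hstack([candidates[s] for s in sel_stock]),
                np.hstack([candidates[s] for s in sel_mem]),
                n_perm=cfg.n_perm, seed=cfg.seed)
            entry["stocking_partial"] = {"r2": part.r2, "adj_r2": part.adj_r2,
                                         "F": part.F, "p": part.p}
        out[name] = entry
    if not stock_block:
        out["stocking"] = "skipped (no stocking matrix)"
    return out


# ---------------------------------------------------------------------------
# Printed-table mode
# ---------------------------------------------------------------------------

def printed_table_statistics(lakes: pd.DataFrame | None = None,
                             summary: pd.DataFrame | None = None) -> dict:
    """Population-level statistics computed from the packaged printed tables
    (no genotypes needed): the stocked/unstocked Welch t tests, column
    medians and means, and the worked load-ratio example for lake TU.
    """
    lakes = datasets.load_lake_table() if lakes is None else lakes
    summary = datasets.load_population_summary() if summary is None else summary
    stocked = lakes.index[lakes["stocked"]]
    unstocked = lakes.index[~lakes["stocked"]]
    lr = summary["load_ratio"]
    he = summary["he_neutral"]
    dm = summary["mean_del_maf"]
    res = {
        # stocked listed first, matching the published statistic's sign
        "load_ratio_ttest": group_tests.welch_t_test(lr[stocked], lr[unstocked]),
        "he_neutral_ttest": group_tests.welch_t_test(he[stocked], he[unstocked]),
        "mean_he_neutral_stocked": float(he[stocked].mean()),
        "mean_he_neutral_unstocked": float(he[unstocked].mean()),
        "mean_load_ratio_stocked": float(lr[stocked].mean()),
        "mean_load_ratio_unstocked": float(lr[unstocked].mean()),
        "median_del_proportion": float(summary["del_proportion"].median()),
        "median_pi": float(summary["pi"].median()),
        "mean_del_maf_stocked": float(dm[stocked].mean()),
        "mean_del_maf_unstocked": float(dm[unstocked].mean()),
        "n_pops_with_fixed_deleterious": int((summary["n_fixed_del"] > 0).sum()),
        "tu_load_ratio": deleterious.load_ratio(
            float(summary.loc["TU", "del_proportion"]),
            int(summary.loc["TU", "n_polymorphic"]),
            datasets.PANEL_SIZE),
    }
    return res
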