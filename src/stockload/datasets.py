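"""Packaged study tables.

Two small CSV fixtures ship with the package: the lake metadata table (24
lakes of the survey — area, sample size, region, coordinates, altitude,
stocking state) and the published per-population genetic summary (genotype
ratio, Pi, heterozygosities for the full and neutral panels, polymorphic SNP
counts, and the deleterious-load columns).  The published panel comprised
4,982 SNPs; group tests on these printed columns reproduce the study's
population-level statistics without the raw genotypes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

PANEL_SIZE = 4982

__all__ = ["PANEL_SIZE", "load_lake_table", "load_population_summary"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("stockload.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_lake_table() -> pd.DataFrame:
    """The 24-lake metadata table, indexed by lake code (9 unstocked, 15 stocked)."""
    df = _read("lake_metadata.csv")
    df["stocked"] = df["stocked"].astype(bool) if df["stocked"].dtype == bool else \
        df["stocked"].astype(str).str.lower().map({"true": True, "false": False})
    return df.set_index("lake_code", drop=False)


def load_population_summary() -> pd.DataFrame:
    """The published per-population summary table, indexed by lake code."""
    return _read("population_summary.csv").set_index("lake_code", drop=False)
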