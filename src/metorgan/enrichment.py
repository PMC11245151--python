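"""Per-gene per-site alteration frequencies and site-vs-kidney enrichment.

A sample counts as altered for a gene when it carries at least one
pathogenic or likely-pathogenic call in that gene; variants of unknown
significance and (likely) benign calls are excluded. Frequencies use
per-gene evaluable denominators. Each metastatic site is compared with the
primary kidney on a 2x2 table (Fisher's exact when any expected count is
below 5, else chi-square), two-sided, with Benjamini-Hochberg adjustment
across the whole screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from metorgan.io import AlterationTable
from metorgan.stats import bh_adjust, compare_2x2


@dataclass(frozen=True)
class FrequencyRecord:
    gene: str
    site: str
    k_altered: int
    n_evaluable: int
    pct: float  # nan when undefined
    undefined: bool = False


@dataclass
class EnrichmentResult:
    gene: str
    site: str
    k_site: int
    n_site: int
    k_kidney: int
    n_kidney: int
    test_used: str  # fisher | chi_square | untestable
    p_raw: float
    q_bh: float
    direction: str  # enriched | depleted
    untestable: bool = False


def _altered_samples(alts: AlterationTable, gene: str) -> set:
    calls = alts.pathogenic_calls()
    return set(calls.loc[calls["gene"] == gene, "sample_id"])


def site_frequency(alts: AlterationTable, samples: pd.DataFrame, gene: str, site: str) -> FrequencyRecord:
    """Alteration frequency of ``gene`` among evaluable samples at ``site``."""
    evaluable = alts.evaluable_samples(gene)
    at_site = set(samples.loc[samples["site"] == site, "sample_id"])
    denom = at_site & evaluable
    n = len(denom)
    k = len(denom & _altered_samples(alts, gene))
    if n == 0:
        return FrequencyRecord(gene, site, 0, 0, float("nan"), undefined=True)
    return FrequencyRecord(gene, site, k, n, 100.0 * k / n)


def compare_site_to_primary(
    alts: AlterationTable, samples: pd.DataFrame, gene: str, site: str
) -> EnrichmentResult:
    """Two-sided site-vs-kidney test of the gene's alteration rate."""
    if site == "kidney":
        raise ValueError("site must be a metastatic site, not 'kidney'")
    fs = site_frequency(alts, samples, gene, site)
    fk = site_frequency(alts, samples, gene, "kidney")
    if fs.undefined or fk.undefined:
        return EnrichmentResult(
            gene, site, fs.k_altered, fs.n_evaluable, fk.k_altered, fk.n_evaluable,
            "untestable", float("nan"), float("nan"), "enriched", untestable=True,
        )
    res = compare_2x2(fs.k_altered, fs.n_evaluable, fk.k_altered, fk.n_evaluable)
    return EnrichmentResult(
        gene, site, fs.k_altered, fs.n_evaluable, fk.k_altered, fk.n_evaluable,
        res.test_used, res.p, float("nan"), res.direction,
        untestable=res.test_used == "untestable",
    )


def enrichment_screen(
    alts: AlterationTable,
    samples: pd.DataFrame,
    genes,
    sites=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen all (gene, metastatic site) pairs against kidney.

    Returns a DataFrame sorted by (gene, site) with raw p, BH q over the
    whole screen, and significance flags at both the raw and BH-adjusted
    alpha.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("genes must be non-empty")
    if sites is None:
        sites = [s for s in samples["site"].unique() if s != "kidney"]
    results = [
        compare_site_to_primary(alts, samples, gene, site)
        for gene in genes
        for site in sites
        if site != "kidney"
    ]
    results.sort(key=lambda r: (r.gene, r.site))
    df = pd.DataFrame([vars(r) for r in results])
    df["q_bh"] = bh_adjust(df["p_raw"].to_numpy())
    df["sig_raw"] = df["p_raw"] < alpha
    df["sig_bh"] = df["q_bh"] < alpha
    return df


def frequency_table(alts: AlterationTable, samples: pd.DataFrame, genes, sites=None) -> pd.DataFrame:
    """Long-format per-(gene, site) frequency table (heatmap substrate)."""
    if sites is None:
        sites = list(samples["site"].unique())
    recs = [site_frequency(alts, samples, g, s) for g in genes for s in sites]
    return pd.DataFrame([vars(r) for r in recs])
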