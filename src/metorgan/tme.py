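"""Marker-gene TME abundance scoring and site-vs-kidney comparison.

Each immune/stromal population is scored per sample as the arithmetic mean
of log2(x+1) over its marker genes (an MCP-counter-style relative abundance:
comparable across samples within a population, not across populations).
Populations and single checkpoint genes are compared per metastatic site
against kidney with two-sided Mann-Whitney tests; significance stars follow
raw p at 0.05 / 0.01 / 0.001 / 0.0001, with BH-adjusted q also reported.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from metorgan.stats import bh_adjust, mann_whitney, star_bucket

log = logging.getLogger(__name__)


def cell_abundance(expr: pd.DataFrame, catalog: dict[str, list[str]]) -> pd.DataFrame:
    """Population x sample abundance: mean log2(x+1) over present markers."""
    seen: dict[str, str] = {}
    for pop, genes in catalog.items():
        if not genes:
            raise ValueError(f"population {pop!r} has an empty marker list")
        for g in genes:
            if g in seen and seen[g] != pop:
                log.warning("marker %s shared between %s and %s", g, seen[g], pop)
            seen.setdefault(g, pop)
    rows = {}
    for pop, genes in catalog.items():
        present = [g for g in genes if g in expr.index]
        if not present:
            raise ValueError(f"population {pop!r} has no markers present in the matrix")
        if len(present) < len(genes):
            log.warning("population %s: dropping %d absent marker(s)", pop, len(genes) - len(present))
        rows[pop] = np.log2(expr.loc[present].to_numpy(dtype=float) + 1.0).mean(axis=0)
    return pd.DataFrame(rows, index=expr.columns).T


def _compare_rows_by_site(scores: pd.DataFrame, samples: pd.DataFrame, alpha_stars: bool = True):
    """Shared harness: per-row per-metastatic-site MW vs kidney + medians."""
    meta = samples.set_index("sample_id")
    cols = [s for s in scores.columns if s in meta.index]
    scores = scores[cols]
    site_of = meta.loc[cols, "site"]
    kidney_cols = site_of.index[site_of == "kidney"]
    if len(kidney_cols) == 0:
        raise ValueError("kidney group is empty")
    sites = [s for s in site_of.unique()]

    medians = pd.DataFrame(
        {site: scores[site_of.index[site_of == site]].median(axis=1) for site in sites}
    )
    stats_rows = []
    kid = scores[kidney_cols].to_numpy(dtype=float)
    for site in sites:
        if site == "kidney":
            continue
        grp_cols = site_of.index[site_of == site]
        grp = scores[grp_cols].to_numpy(dtype=float)
        for i, name in enumerate(scores.index):
            if grp.shape[1] < 2:
                stats_rows.append(
                    {"name": name, "site": site, "n_site": grp.shape[1], "n_kidney": kid.shape[1],
                     "median_site": float("nan"), "median_kidney": float(np.median(kid[i])),
                     "p_raw": float("nan"), "stars": "", "untested": True}
                )
                continue
            p = mann_whitney(grp[i], kid[i])
            stats_rows.append(
                {"name": name, "site": site, "n_site": grp.shape[1], "n_kidney": kid.shape[1],
                 "median_site": float(np.median(grp[i])), "median_kidney": float(np.median(kid[i])),
                 "p_raw": p, "stars": star_bucket(p), "untested": False}
            )
    stats = pd.DataFrame(
        stats_rows,
        columns=["name", "site", "n_site", "n_kidney", "median_site", "median_kidney",
                 "p_raw", "stars", "untested"],
    )
    if len(stats):
        stats["q_bh"] = bh_adjust(stats["p_raw"].to_numpy())
    return medians, stats


def compare_abundance_by_site(abund: pd.DataFrame, samples: pd.DataFrame):
    """Per-(population, site) Mann-Whitney vs kidney with star categories.

    Returns (medians populations x sites, long-format stats DataFrame).
    Sites with fewer than 2 samples are flagged untested, not dropped.
    """
    return _compare_rows_by_site(abund, samples)


def checkpoint_expression_compare(expr: pd.DataFrame, samples: pd.DataFrame, genes):
    """Same site-vs-kidney harness applied to single checkpoint genes.

    Scores are log2(x+1) of each gene. Absent genes are returned in a
    skipped list, not fatal. Returns (medians, stats, skipped_genes).
    """
    present = [g for g in genes if g in expr.index]
    skipped = [g for g in genes if g not in expr.index]
    if skipped:
        log.warning("checkpoint genes absent from matrix: %s", skipped)
    if not present:
        return pd.DataFrame(), pd.DataFrame(), skipped
    scores = pd.DataFrame(
        np.log2(expr.loc[present].to_numpy(dtype=float) + 1.0),
        index=present,
        columns=expr.columns,
    )
    medians, stats = _compare_rows_by_site(scores, samples)
    return medians, stats, skipped
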