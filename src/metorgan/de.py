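"""Differential expression, cross-site DEG overlap, and pathway ORA.

Per-gene two-sided Mann-Whitney U on linear expression between two sample
groups, with log2 fold change computed from group means with a pseudocount
of 1, Benjamini-Hochberg adjustment over genes, and up/down/ns flags at
|log2FC| >= 1 and adjusted p < 0.05 by default. Pathway over-representation
uses the one-sided hypergeometric upper tail against a user-supplied gene
universe and GMT-style gene sets.
"""

from __future__ import annotations

import pandas as pd
import numpy as np
from scipy.stats import hypergeom

from metorgan.stats import bh_adjust, mann_whitney_rows

DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_ALPHA = 0.05


def de_test(
    expr: pd.DataFrame,
    groupA_ids,
    groupB_ids,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Per-gene Mann-Whitney DE of group B over group A.

    log2fc = log2((mean_B + 1) / (mean_A + 1)) on the linear scale. Flags:
    'up' when log2fc >= lfc_threshold and (adjusted) p < alpha, 'down' for
    the mirrored condition, else 'ns'.
    """
    groupA_ids = list(groupA_ids)
    groupB_ids = list(groupB_ids)
    if set(groupA_ids) & set(groupB_ids):
        raise ValueError("groups must be disjoint")
    if len(groupA_ids) < 2 or len(groupB_ids) < 2:
        raise ValueError("each group needs at least 2 samples")
    A = expr[groupA_ids].to_numpy(dtype=float)
    B = expr[groupB_ids].to_numpy(dtype=float)

    log2fc = np.log2((B.mean(axis=1) + 1.0) / (A.mean(axis=1) + 1.0))
    p_raw = mann_whitney_rows(B, A)
    q_adj = bh_adjust(p_raw)

    sig = (q_adj if use_adjusted else p_raw) < alpha
    flag = np.where(
        sig & (log2fc >= lfc_threshold), "up", np.where(sig & (log2fc <= -lfc_threshold), "down", "ns")
    )
    return pd.DataFrame(
        {"gene": expr.index, "log2fc": log2fc, "p_raw": p_raw, "q_adj": q_adj, "flag": flag}
    ).set_index("gene")


def per_site_deg(expr: pd.DataFrame, samples: pd.DataFrame, site: str, **kwargs) -> pd.DataFrame:
    """DE of one metastatic site (group B) against kidney (group A)."""
    if site == "kidney":
        raise ValueError("site must be a metastatic site")
    kidney = samples.loc[samples["site"] == "kidney", "sample_id"]
    at_site = samples.loc[samples["site"] == site, "sample_id"]
    kidney = [s for s in kidney if s in expr.columns]
    at_site = [s for s in at_site if s in expr.columns]
    if len(at_site) < 2:
        raise ValueError(f"site {site!r} has fewer than 2 samples with expression")
    if len(kidney) < 2:
        raise ValueError("kidney group has fewer than 2 samples with expression")
    return de_test(expr, kidney, at_site, **kwargs)


def mets_vs_kidney(expr: pd.DataFrame, samples: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """DE of all pooled metastases (group B) against kidney (group A)."""
    kidney = [s for s in samples.loc[samples["site_class"] == "primary", "sample_id"] if s in expr.columns]
    mets = [s for s in samples.loc[samples["site_class"] == "metastatic", "sample_id"] if s in expr.columns]
    return de_test(expr, kidney, mets, **kwargs)


def deg_overlap(de_by_site: dict[str, pd.DataFrame]) -> dict[str, dict[frozenset, set]]:
    """Venn regions of significant genes across sites, split by direction.

    For each direction ('up', 'down'), maps frozenset-of-sites -> genes
    significant in exactly those sites. Needs >= 2 sites.
    """
    if len(de_by_site) < 2:
        raise ValueError("need at least 2 sites to overlap")
    regions: dict[str, dict[frozenset, set]] = {}
    for direction in ("up", "down"):
        sig = {site: set(df.index[df["flag"] == direction]) for site, df in de_by_site.items()}
        out: dict[frozenset, set] = {}
        all_genes = set().union(*sig.values())
        for gene in all_genes:
            region = frozenset(s for s, genes in sig.items() if gene in genes)
            out.setdefault(region, set()).add(gene)
        regions[direction] = out
    return regions


def ora_hypergeometric(deg_list, universe, pathway_sets: dict[str, list[str]]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a gene list.

    For each pathway: K genes of the universe belong to it, the list has n
    genes of which k are in the pathway; p = P(X >= k) under a
    Hypergeometric(N, K, n) null, BH-adjusted across pathways, sorted by
    ascending p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    deg = set(deg_list)
    stray = deg - universe
    if stray:
        raise ValueError(f"DEG list contains genes outside the universe: {sorted(stray)[:3]}")
    n = len(deg)
    N = len(universe)
    rows = []
    for name, genes in pathway_sets.items():
        members = set(genes) & universe
        K = len(members)
        k = len(deg & members)
        p = float(min(hypergeom.sf(k - 1, N, K, n), 1.0)) if K > 0 else 1.0
        rows.append({"pathway": name, "k": k, "n": n, "K": K, "N": N, "p": p})
    df = pd.DataFrame(rows, columns=["pathway", "k", "n", "K", "N", "p"])
    df["q_bh"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["p", "pathway"], kind="mergesort").reset_index(drop=True)
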