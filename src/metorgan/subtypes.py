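"""Composite z-score molecular subtype classification.

Expression is log2(x+1)-transformed and standardized per gene to z-scores
over the pooled cohort. Per-signature scores are the mean z over the
signature's genes. Each of the 7 molecular subgroups has a coefficient row
over the signatures; a sample's composite score for a subgroup is the
weighted sum of its signature scores, and the sample is assigned the
subgroup with the highest composite score (exact ties break by declared
subgroup order).

The reference coefficient table is a runtime input. The default shipped
here is a synthetic identity-style table (each subgroup weights its own
characteristic signatures, row-normalized), suitable for testing against
the synthetic generator's latent structure; real analyses should load a
coefficient table derived from their reference cohort medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from metorgan.stats import bh_adjust, compare_2x2
from metorgan.synth import DEFAULT_SIGNATURES, SUBGROUP_SIGNATURES, SUBGROUPS

log = logging.getLogger(__name__)


@dataclass
class SubtypeModel:
    signatures: dict[str, list[str]]
    coefficients: pd.DataFrame  # subgroups x signatures
    subgroup_names: tuple[str, ...] = SUBGROUPS

    def validate(self) -> None:
        if len(self.subgroup_names) != 7:
            raise ValueError("exactly 7 subgroups required")
        if set(self.coefficients.index) != set(self.subgroup_names):
            raise ValueError("coefficient rows must match subgroup names")
        missing = set(self.coefficients.columns) - set(self.signatures)
        if missing:
            raise ValueError(f"coefficients reference unknown signatures: {sorted(missing)}")
        if not np.isfinite(self.coefficients.to_numpy(dtype=float)).all():
            raise ValueError("non-finite coefficient in subtype model")


def default_subtype_model(signatures: dict[str, list[str]] | None = None) -> SubtypeModel:
    """Synthetic identity-style model: W[g,s] = 1/k over subgroup g's k signatures."""
    signatures = signatures or {k: list(v) for k, v in DEFAULT_SIGNATURES.items()}
    signames = list(signatures)
    W = pd.DataFrame(0.0, index=list(SUBGROUPS), columns=signames)
    for g, sigs in SUBGROUP_SIGNATURES.items():
        for s in sigs:
            W.loc[g, s] = 1.0 / len(sigs)
    model = SubtypeModel(signatures=signatures, coefficients=W)
    model.validate()
    return model


@dataclass
class CompositeScores:
    scores: pd.DataFrame  # subgroups x samples
    labels: pd.Series  # sample -> subgroup
    margin: pd.Series  # top score minus runner-up


def zscore_log(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores of log2(x+1) expression over the pooled cohort.

    Constant genes map to all-zero rows (logged warning). A single-sample
    matrix is an error: the per-gene SD is undefined.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    values = expr.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression must be non-negative")
    L = np.log2(values + 1.0)
    mu = L.mean(axis=1, keepdims=True)
    sd = L.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        log.warning("%d constant gene(s) mapped to all-zero z rows", int(constant.sum()))
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (L - mu) / sd_safe
    Z[constant, :] = 0.0
    return pd.DataFrame(Z, index=expr.index, columns=expr.columns)


def signature_scores(z: pd.DataFrame, signatures: dict[str, list[str]]) -> pd.DataFrame:
    """Mean z per signature per sample; absent genes dropped with a warning."""
    rows = {}
    for name, genes in signatures.items():
        present = [g for g in genes if g in z.index]
        absent = set(genes) - set(present)
        if not present:
            raise ValueError(f"signature {name!r} has no genes present in the matrix")
        if absent:
            log.warning("signature %s: dropping %d absent gene(s)", name, len(absent))
        rows[name] = z.loc[present].mean(axis=0)
    return pd.DataFrame(rows).T


def composite_and_assign(sigscores: pd.DataFrame, model: SubtypeModel) -> CompositeScores:
    """Composite scores C = W @ S and per-sample argmax subgroup labels."""
    model.validate()
    missing = set(sigscores.index) - set(model.coefficients.columns)
    if missing:
        raise ValueError(f"model lacks coefficients for signatures: {sorted(missing)}")
    W = model.coefficients.loc[list(model.subgroup_names), sigscores.index.tolist()]
    C = pd.DataFrame(
        W.to_numpy(dtype=float) @ sigscores.to_numpy(dtype=float),
        index=list(model.subgroup_names),
        columns=sigscores.columns,
    )
    arr = C.to_numpy()
    top_idx = arr.argmax(axis=0)  # argmax takes the first max: declared-order tie-break
    labels = pd.Series(
        [model.subgroup_names[i] for i in top_idx], index=C.columns, name="subtype"
    )
    sorted_desc = np.sort(arr, axis=0)[::-1]
    margin = pd.Series(sorted_desc[0] - sorted_desc[1], index=C.columns, name="margin")
    return CompositeScores(scores=C, labels=labels, margin=margin)


def classify_expression(expr: pd.DataFrame, model: SubtypeModel) -> CompositeScores:
    """Convenience: z-score, signature-score, and assign in one call."""
    return composite_and_assign(signature_scores(zscore_log(expr), model.signatures), model)


def subtype_metastatic_share(assignments: pd.Series, samples: pd.DataFrame) -> pd.DataFrame:
    """Per subgroup: how many assigned samples are metastatic vs primary.

    Returns a DataFrame indexed by subgroup with n_total, n_metastatic and
    pct_metastatic columns (the 'share of this subgroup that is metastatic').
    """
    meta = samples.set_index("sample_id")
    cls = meta.loc[assignments.index, "site_class"]
    rows = []
    for g in SUBGROUPS:
        mask = assignments == g
        n = int(mask.sum())
        k = int((cls[mask.to_numpy()] == "metastatic").sum())
        rows.append(
            {"subtype": g, "n_total": n, "n_metastatic": k,
             "pct_metastatic": 100.0 * k / n if n else float("nan")}
        )
    return pd.DataFrame(rows).set_index("subtype")


def _mc_contingency_p(table: np.ndarray, rng: np.random.Generator, n_mc: int = 2000) -> float:
    """Monte-Carlo chi-square contingency p with fixed margins (permutation)."""
    from scipy.stats import chi2_contingency

    def stat(t):
        exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            cells = np.where(exp > 0, (t - exp) ** 2 / exp, 0.0)
        return cells.sum()

    obs = stat(table.astype(float))
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1).astype(int))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0).astype(int))
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(cols)
        t = np.zeros_like(table, dtype=float)
        np.add.at(t, (rows, perm), 1.0)
        if stat(t) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def subtype_distribution_by_site(
    assignments: pd.Series,
    samples: pd.DataFrame,
    subgroup_names: tuple[str, ...] = SUBGROUPS,
    seed: int = 0,
    n_mc: int = 2000,
):
    """Per-site subgroup proportions plus site-vs-kidney contingency tests.

    Returns (proportions DataFrame subgroups x sites, full-table tests
    DataFrame, per-subtype 2x2 tests DataFrame). The full 7x2 table per site
    uses chi-square when all expected counts are >= 5, else a seeded
    Monte-Carlo permutation p. Per-subtype 2x2 tests use the usual
    Fisher/chi-square rule.
    """
    from scipy.stats import chi2_contingency

    meta = samples.set_index("sample_id")
    missing = set(assignments.index) - set(meta.index)
    if missing:
        raise ValueError(f"assigned samples missing from metadata: {sorted(missing)[:3]}")
    site_of = meta.loc[assignments.index, "site"]
    counts = (
        pd.crosstab(assignments, site_of)
        .reindex(index=list(subgroup_names), fill_value=0)
    )
    present_sites = [s for s in counts.columns if counts[s].sum() > 0]
    dropped = set(counts.columns) - set(present_sites)
    if dropped:
        log.warning("omitting site(s) with no assigned samples: %s", sorted(dropped))
    counts = counts[present_sites]
    proportions = counts / counts.sum(axis=0)

    rng = np.random.default_rng(seed)
    site_tests = []
    per_subtype = []
    if "kidney" in counts.columns:
        kid = counts["kidney"].to_numpy()
        for site in present_sites:
            if site == "kidney":
                continue
            vec = counts[site].to_numpy()
            table = np.column_stack([vec, kid])
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
            if (expected >= 5).all():
                _, p, _, _ = chi2_contingency(table, correction=False)
                used = "chi_square"
            else:
                p = _mc_contingency_p(table, rng, n_mc=n_mc)
                used = "monte_carlo"
            site_tests.append({"site": site, "test_used": used, "p_raw": float(p)})
            for gi, g in enumerate(subgroup_names):
                r = compare_2x2(int(vec[gi]), int(vec.sum()), int(kid[gi]), int(kid.sum()))
                per_subtype.append(
                    {
                        "site": site,
                        "subtype": g,
                        "k_site": int(vec[gi]),
                        "n_site": int(vec.sum()),
                        "k_kidney": int(kid[gi]),
                        "n_kidney": int(kid.sum()),
                        "test_used": r.test_used,
                        "p_raw": r.p,
                        "direction": r.direction,
                    }
                )
    site_df = pd.DataFrame(site_tests, columns=["site", "test_used", "p_raw"])
    sub_df = pd.DataFrame(
        per_subtype,
        columns=[
            "site", "subtype", "k_site", "n_site", "k_kidney", "n_kidney",
            "test_used", "p_raw", "direction",
        ],
    )
    if len(sub_df):
        sub_df["q_bh"] = bh_adjust(sub_df["p_raw"].to_numpy())
    return proportions, site_df, sub_df
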