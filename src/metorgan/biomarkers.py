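"""Immunotherapy biomarker calling: TMB, PD-L1 positivity, dMMR/MSI consensus.

* **TMB** — nonsynonymous mutations per megabase, counting missense,
  nonsense, in-frame indel, and frameshift calls not previously described as
  germline; splice and promoter variants are excluded. TMB-high at
  >= 10 mutations/Mb.
* **PD-L1 (SP142)** — positive when staining intensity >= 2+ in >= 5% of
  tumor cells (both boundaries inclusive).
* **dMMR/MSI** — consensus over up to three platforms (IHC, fragment
  analysis, NGS): unanimity wins; on discordance the IHC call decides; on
  discordance without IHC the status is indeterminate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from metorgan.stats import bh_adjust, compare_2x2

TMB_QUALIFYING_TYPES = frozenset({"missense", "nonsense", "inframe_indel", "frameshift"})
TMB_HIGH_CUTOFF = 10.0
PDL1_INTENSITY_CUTOFF = 2
PDL1_PCT_CUTOFF = 5.0
MSI_STATES = ("stable", "high", "indeterminate")


def tmb_compute(variants: pd.DataFrame, panel_mb: float) -> float:
    """Mutations per megabase for one sample's variant rows."""
    if panel_mb <= 0:
        raise ValueError("panel_mb must be > 0")
    if len(variants) == 0:
        return 0.0
    mask = variants["variant_type"].isin(TMB_QUALIFYING_TYPES) & ~variants["germline_known"].astype(bool)
    return float(mask.sum()) / panel_mb


def pdl1_call(intensity: int, pct: float) -> bool:
    """SP142 positivity: intensity >= 2+ and >= 5% tumor cells stained."""
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity must be in 0..3, got {intensity!r}")
    if not (0.0 <= pct <= 100.0):
        raise ValueError(f"percent stained must be in [0, 100], got {pct!r}")
    return intensity >= PDL1_INTENSITY_CUTOFF and pct >= PDL1_PCT_CUTOFF


def msi_consensus(ihc=None, fragment_analysis=None, ngs=None) -> str:
    """Multi-platform MSI consensus with IHC override on discordance."""
    calls = {"ihc": ihc, "fragment_analysis": fragment_analysis, "ngs": ngs}
    present = {k: v for k, v in calls.items() if v is not None and not (isinstance(v, float) and np.isnan(v))}
    for k, v in present.items():
        if v not in MSI_STATES:
            raise ValueError(f"platform {k}: unknown MSI state {v!r}")
    if not present:
        raise ValueError("at least one platform call is required")
    values = set(present.values())
    if len(values) == 1:
        return values.pop()
    if "ihc" in present:
        return present["ihc"]
    return "indeterminate"


def biomarker_statuses(
    alterations, samples: pd.DataFrame, msi_ihc: pd.DataFrame, panel_mb: float
) -> pd.DataFrame:
    """Per-sample biomarker table: TMB, PD-L1, MSI consensus and flags."""
    calls = alterations.calls if hasattr(alterations, "calls") else alterations
    by_sample = dict(tuple(calls.groupby("sample_id"))) if len(calls) else {}
    plat = msi_ihc.set_index("sample_id")
    rows = []
    for sid in samples["sample_id"]:
        variants = by_sample.get(sid, calls.iloc[0:0])
        tmb = tmb_compute(variants, panel_mb)
        rec = plat.loc[sid]
        pos = pdl1_call(int(rec["pdl1_intensity"]), float(rec["pdl1_pct"]))
        consensus = msi_consensus(
            ihc=rec.get("msi_ihc"),
            fragment_analysis=rec.get("msi_fragment_analysis"),
            ngs=rec.get("msi_ngs"),
        )
        rows.append(
            {
                "sample_id": sid,
                "tmb": tmb,
                "tmb_high": tmb >= TMB_HIGH_CUTOFF,
                "pdl1_intensity": int(rec["pdl1_intensity"]),
                "pdl1_pct": float(rec["pdl1_pct"]),
                "pdl1_pos": pos,
                "msi_consensus": consensus,
            }
        )
    return pd.DataFrame(rows)


BIOMARKER_FLAGS = {"tmb_high": "tmb_high", "pdl1_pos": "pdl1_pos", "msi_high": "msi_consensus"}


def biomarker_frequencies_by_site(statuses: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-site positive fractions per biomarker with site-vs-kidney tests."""
    merged = statuses.merge(samples[["sample_id", "site"]], on="sample_id", how="inner")
    merged["msi_high"] = merged["msi_consensus"] == "high"
    rows = []
    kidney = merged[merged["site"] == "kidney"]
    for biomarker in ("tmb_high", "pdl1_pos", "msi_high"):
        k_kid = int(kidney[biomarker].sum())
        n_kid = len(kidney)
        for site, grp in merged.groupby("site"):
            k = int(grp[biomarker].sum())
            n = len(grp)
            row = {
                "biomarker": biomarker,
                "site": site,
                "k_positive": k,
                "n": n,
                "pct": 100.0 * k / n if n else float("nan"),
            }
            if site != "kidney" and n_kid > 0 and n > 0:
                res = compare_2x2(k, n, k_kid, n_kid)
                row.update(test_used=res.test_used, p_raw=res.p, direction=res.direction)
            else:
                row.update(test_used="", p_raw=float("nan"), direction="")
            rows.append(row)
    df = pd.DataFrame(rows).sort_values(["biomarker", "site"]).reset_index(drop=True)
    testable = df["p_raw"].notna()
    df["q_bh"] = bh_adjust(df["p_raw"].to_numpy())
    df["sig_raw"] = testable & (df["p_raw"] < 0.05)
    return df
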