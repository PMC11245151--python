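"""Synthetic RCC cohort generator.

Emulates the statistical structure of a real-world profiled cohort of
primary kidney tumors and organ-site metastases: per-site sample counts,
per-(gene, site) pathogenic-alteration probabilities with per-gene evaluable
denominators, a latent 7-subgroup transcriptomic structure driving signature
gene expression, planted metastasis-associated differentially expressed
genes, site-shifted tumor-microenvironment marker expression, per-site
mutational-burden rates, and per-sample PD-L1 staining plus multi-platform
microsatellite-instability calls.

Defaults follow the printed per-site composition and alteration frequencies
of a 657-sample RCC cohort (340 primary kidney, 317 metastatic). Expression
is log-normal: a log2-scale baseline plus additive effects plus Gaussian
noise, exponentiated to linear TPM-like units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from metorgan.io import AlterationTable, HISTOLOGIES, SITES

SUBGROUPS = (
    "angiogenic/stromal",
    "angiogenic",
    "complement/omega-oxidation",
    "T-effector/proliferative",
    "proliferative",
    "stromal/proliferative",
    "snoRNA",
)

# synthetic transcriptional program gene sets (stand-ins for reference
# signature definitions, which are runtime-supplied in real use)
DEFAULT_SIGNATURES: dict[str, list[str]] = {
    "angiogenesis": ["VEGFA", "KDR", "ESM1", "PECAM1", "CD34"],
    "stroma": ["FAP", "FN1", "POSTN", "MMP2", "COL5A1"],
    "complement": ["C3", "C1QA", "C1QB", "CFH", "CYP2J2"],
    "teff": ["CD8A", "GZMA", "GZMB", "PRF1", "IFNG"],
    "cellcycle": ["MKI67", "TOP2A", "CCNB1", "BUB1", "PLK1"],
    "myeloid": ["IL6", "CXCL1", "CXCL2", "CXCL8", "PTGS2"],
    "snoRNA": ["SNORD38A", "SNORD104", "SNORA12", "SNORD46", "SNORA40"],
}

# which transcriptional programs each molecular subgroup elevates
SUBGROUP_SIGNATURES: dict[str, tuple[str, ...]] = {
    "angiogenic/stromal": ("angiogenesis", "stroma"),
    "angiogenic": ("angiogenesis",),
    "complement/omega-oxidation": ("complement",),
    "T-effector/proliferative": ("teff", "cellcycle"),
    "proliferative": ("cellcycle", "myeloid"),
    "stromal/proliferative": ("stroma", "cellcycle"),
    "snoRNA": ("snoRNA",),
}

# synthetic marker-gene catalog for MCP-style TME population scoring
DEFAULT_MARKER_CATALOG: dict[str, list[str]] = {
    "T cells": ["CD3D", "CD3E", "CD2"],
    "CD8+ T cells": ["CD8B", "TRGC2"],
    "cytotoxic lymphocytes": ["GNLY", "KLRD1", "GZMH"],
    "B lineage": ["CD19", "MS4A1", "CD79A"],
    "NK cells": ["NCR1", "KIR2DL3", "NKG7"],
    "monocytic lineage": ["CD14", "CD163", "CSF1R"],
    "myeloid dendritic cells": ["CD1C", "CLEC10A"],
    "neutrophils": ["FCGR3B", "CEACAM3", "S100A12"],
    "endothelial cells": ["VWF", "CDH5", "CLDN5"],
    "fibroblasts": ["COL1A1", "COL3A1", "PDGFRB", "THY1", "LUM"],
}

CHECKPOINT_GENES = ("CTLA4", "TIM3", "LAG3", "PD1", "PDL1", "PDL2")

# the 16 recurrently mutated genes screened for site enrichment
MUTATED_GENES = (
    "VHL",
    "PBRM1",
    "SETD2",
    "KDM5C",
    "BAP1",
    "TP53",
    "PTEN",
    "ASXL1",
    "SPEN",
    "NF1",
    "FAT1",
    "AKT1",
    "TERT",
    "ARID1A",
    "MTOR",
    "KMT2C",
)

# metastasis-associated expression program planted between metastatic and
# primary samples (log2 fold changes): extracellular-matrix reorganization
# genes up in metastases, renin down (kidney-specific expression)
DEFAULT_DEG_EFFECTS: dict[str, float] = {
    "ASPN": 2.0,
    "TTC14": 1.5,
    "DCN": 1.5,
    "COL6A3": 1.2,
    "COL11A1": 1.2,
    "HTRA3": 1.0,
    "REN": -3.0,
}

# per-site cohort composition; kidney..CNS are printed counts, the last
# five are implementer-chosen placeholders summing to the printed total 657
DEFAULT_SITE_COUNTS: dict[str, int] = {
    "kidney": 340,
    "lung": 66,
    "bone": 50,
    "soft tissue": 40,
    "liver": 28,
    "endocrine": 23,
    "CNS": 14,
    "lymph node": 26,
    "pleura": 20,
    "skin": 10,
    "GI tract": 9,
    "other": 31,
}

# overall printed alteration frequencies, used as the per-gene baseline
# rate at every site without a printed site-specific rate
_BASELINE_ALT_PROBS: dict[str, float] = {
    "VHL": 0.619,
    "PBRM1": 0.382,
    "SETD2": 0.206,
    "KDM5C": 0.132,
    "BAP1": 0.107,
    "TP53": 0.06,
    "PTEN": 0.07,
    "ASXL1": 0.02,
    "SPEN": 0.02,
    "NF1": 0.03,
    "FAT1": 0.03,
    "AKT1": 0.01,
    "TERT": 0.05,
    "ARID1A": 0.03,
    "MTOR": 0.05,
    "KMT2C": 0.03,
}

# printed site-specific alteration frequencies (overrides of the baseline)
_SITE_ALT_OVERRIDES: dict[tuple[str, str], float] = {
    ("PBRM1", "lung"): 0.477,
    ("SETD2", "lung"): 0.281,
    ("TP53", "bone"): 0.229,
    ("PBRM1", "bone"): 0.596,
    ("ASXL1", "bone"): 0.071,
    ("KDM5C", "lymph node"): 0.280,
    ("PTEN", "liver"): 0.214,
    ("PBRM1", "endocrine"): 0.591,
    ("KDM5C", "endocrine"): 0.278,
    ("SPEN", "endocrine"): 0.087,
    ("NF1", "endocrine"): 0.125,
    ("FAT1", "soft tissue"): 0.091,
    ("TP53", "CNS"): 0.286,
    ("PTEN", "CNS"): 0.286,
    ("AKT1", "CNS"): 0.071,
}

# per-gene evaluable fraction, matching the varying printed denominators
DEFAULT_EVALUABLE_FRACTION: dict[str, float] = {
    "VHL": 0.999,
    "PBRM1": 0.988,
    "SETD2": 0.970,
    "KDM5C": 0.738,
    "BAP1": 0.963,
    "TP53": 0.960,
    "PTEN": 0.990,
    "ASXL1": 0.560,
    "SPEN": 0.990,
    "NF1": 0.350,
    "FAT1": 0.550,
    "AKT1": 0.990,
    "TERT": 0.900,
    "ARID1A": 0.950,
    "MTOR": 0.950,
    "KMT2C": 0.950,
}

# per-site subgroup prevalence. Kidney entries follow printed proportions;
# metastatic entries encode the printed site enrichments (angiogenic/stromal
# in bone/skin/GI/lung, stromal/proliferative in lung/skin,
# complement/omega-oxidation in liver), remainder chosen to sum to 1
DEFAULT_SUBTYPE_PRIORS: dict[str, tuple[float, ...]] = {
    "kidney": (0.153, 0.262, 0.150, 0.153, 0.156, 0.071, 0.055),
    "lung": (0.244, 0.160, 0.050, 0.120, 0.130, 0.197, 0.099),
    "bone": (0.440, 0.150, 0.060, 0.090, 0.110, 0.100, 0.050),
    "liver": (0.100, 0.080, 0.607, 0.060, 0.060, 0.063, 0.030),
    "skin": (0.400, 0.020, 0.010, 0.030, 0.020, 0.500, 0.020),
    "GI tract": (0.556, 0.100, 0.050, 0.080, 0.080, 0.104, 0.030),
    "endocrine": (0.261, 0.348, 0.080, 0.090, 0.090, 0.091, 0.040),
    "CNS": (0.100, 0.150, 0.070, 0.250, 0.200, 0.180, 0.050),
    "soft tissue": (0.153, 0.262, 0.150, 0.153, 0.156, 0.071, 0.055),
    "lymph node": (0.153, 0.262, 0.150, 0.153, 0.156, 0.071, 0.055),
    "pleura": (0.153, 0.262, 0.150, 0.153, 0.156, 0.071, 0.055),
    "other": (0.153, 0.262, 0.150, 0.153, 0.156, 0.071, 0.055),
}

# TME population / checkpoint-gene shifts by site (log2-scale), encoding the
# fibroblast enrichment across metastatic sites and the reported single-gene
# and population-level site differences
DEFAULT_TME_SHIFTS: dict[tuple[str, str], float] = {
    ("fibroblasts", "liver"): 1.5,
    ("fibroblasts", "lung"): 1.5,
    ("fibroblasts", "bone"): 1.5,
    ("fibroblasts", "pleura"): 1.5,
    ("fibroblasts", "soft tissue"): 1.5,
    ("fibroblasts", "skin"): 1.5,
    ("endothelial cells", "bone"): 1.0,
    ("monocytic lineage", "bone"): 1.0,
    ("B lineage", "lung"): 1.0,
    ("B lineage", "skin"): 1.0,
    ("T cells", "lymph node"): 0.7,
    ("CD8+ T cells", "endocrine"): 0.7,
    ("cytotoxic lymphocytes", "endocrine"): 0.7,
    ("PDL1", "pleura"): 1.0,
    ("PDL2", "lung"): 1.0,
    ("PDL2", "bone"): 1.0,
}

# nonsynonymous mutations per megabase: RCC is a low-TMB tumor type
DEFAULT_TMB_RATES: dict[str, float] = {site: 3.0 for site in SITES}

_HISTOLOGY_PROBS = (0.773, 0.096, 0.046, 0.012, 0.012, 0.012, 0.049)
_DRIVER_TYPE_PROBS = {"missense": 0.5, "nonsense": 0.2, "frameshift": 0.2, "splice": 0.1}
_TMB_QUALIFYING = ("missense", "nonsense", "inframe_indel", "frameshift")


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort generator."""

    site_counts: dict[str, int]
    alt_probs: dict[tuple[str, str], float]
    evaluable_fraction: dict[str, float]
    subtype_priors: dict[str, tuple[float, ...]]
    signature_effect: float = 2.0
    tme_shifts: dict[tuple[str, str], float] = field(default_factory=dict)
    deg_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.5
    tmb_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TMB_RATES))
    panel_mb: float = 1.4
    seed: int = 0
    baseline_log2: float = 5.0
    gene_universe: tuple[str, ...] = ()
    signatures: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_SIGNATURES.items()})
    marker_catalog: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_MARKER_CATALOG.items()})
    sarcomatoid_rate: float = 0.094
    male_fraction: float = 0.706
    panel_assay_fraction: float = 0.571
    msi_high_rate: float = 0.01
    msi_discordance_rate: float = 0.05
    msi_platform_missing_rate: float = 0.05
    msi_ngs_loci_total: int = 2800
    msi_ngs_loci_threshold: int = 46
    pdl1_intensity_probs: tuple[float, ...] = (0.35, 0.20, 0.25, 0.20)

    def __post_init__(self):
        if not self.gene_universe:
            universe = list(MUTATED_GENES)
            for genes in self.signatures.values():
                universe += genes
            for genes in self.marker_catalog.values():
                universe += genes
            universe += list(CHECKPOINT_GENES)
            universe += list(self.deg_effects) if self.deg_effects else list(DEFAULT_DEG_EFFECTS)
            seen: dict[str, None] = {}
            for g in universe:
                seen.setdefault(g)
            self.gene_universe = tuple(seen)

    def validate(self) -> None:
        for (gene, site), p in self.alt_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"alt_probs[{gene},{site}]={p} outside [0,1]")
        for gene, p in self.evaluable_fraction.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"evaluable_fraction[{gene}]={p} outside [0,1]")
        for site, n in self.site_counts.items():
            if n < 0:
                raise ValueError(f"site_counts[{site}]={n} negative")
            if site not in SITES:
                raise ValueError(f"unknown site {site!r}")
        for site, pri in self.subtype_priors.items():
            pri = np.asarray(pri, dtype=float)
            if pri.size != len(SUBGROUPS):
                raise ValueError(f"subtype_priors[{site}] must have {len(SUBGROUPS)} entries")
            if (pri < 0).any() or abs(pri.sum() - 1.0) > 1e-9:
                raise ValueError(f"subtype_priors[{site}] must be a probability vector")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if not self.panel_mb > 0:
            raise ValueError("panel_mb must be > 0")
        universe = set(self.gene_universe)
        for gene, _site in self.alt_probs:
            if gene not in universe:
                raise ValueError(f"alt_probs references gene {gene!r} absent from gene universe")
        for gene in self.deg_effects:
            if gene not in universe:
                raise ValueError(f"deg_effects references gene {gene!r} absent from gene universe")
        for name, genes in self.signatures.items():
            missing = set(genes) - universe
            if missing:
                raise ValueError(f"signature {name!r} references genes absent from universe: {sorted(missing)}")
        for name, genes in self.marker_catalog.items():
            missing = set(genes) - universe
            if missing:
                raise ValueError(f"marker set {name!r} references genes absent from universe: {sorted(missing)}")
        for name, _site in self.tme_shifts:
            if name not in self.marker_catalog and name not in universe:
                raise ValueError(f"tme_shifts key {name!r} is neither a population nor a gene")


@dataclass
class SyntheticCohort:
    samples: pd.DataFrame
    alterations: AlterationTable
    expression: pd.DataFrame
    truth: dict
    config: CohortConfig


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """Config matching the study cohort's printed composition and rates.

    ``site_counts`` holds the printed per-site totals (kidney 340, lung 66,
    bone 50, ...); ``alt_probs`` holds the printed per-site alteration rates
    (e.g. lung PBRM1 0.477) with the overall printed rate as baseline at
    unlisted sites; other fields hold documented stand-in values.
    """
    alt_probs: dict[tuple[str, str], float] = {}
    for gene in MUTATED_GENES:
        for site in SITES:
            alt_probs[(gene, site)] = _SITE_ALT_OVERRIDES.get(
                (gene, site), _BASELINE_ALT_PROBS[gene]
            )
    cfg = CohortConfig(
        site_counts=dict(DEFAULT_SITE_COUNTS),
        alt_probs=alt_probs,
        evaluable_fraction=dict(DEFAULT_EVALUABLE_FRACTION),
        subtype_priors={s: tuple(p) for s, p in DEFAULT_SUBTYPE_PRIORS.items()},
        tme_shifts=dict(DEFAULT_TME_SHIFTS),
        deg_effects=dict(DEFAULT_DEG_EFFECTS),
        seed=seed,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


def _draw_samples(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 0
    for site in SITES:
        n = config.site_counts.get(site, 0)
        for _ in range(n):
            idx += 1
            sid = f"S{idx:05d}"
            rows.append(
                {
                    "sample_id": sid,
                    "patient_id": f"P{idx:05d}",
                    "site": site,
                    "site_class": "primary" if site == "kidney" else "metastatic",
                    "histology": HISTOLOGIES[rng.choice(len(HISTOLOGIES), p=_HISTOLOGY_PROBS)],
                    "sarcomatoid": bool(rng.random() < config.sarcomatoid_rate),
                    "age_years": int(np.clip(round(rng.normal(62, 12)), 14, 90)),
                    "sex": "male" if rng.random() < config.male_fraction else "female",
                    "assay": "panel" if rng.random() < config.panel_assay_fraction else "WES",
                }
            )
    return pd.DataFrame(rows)


def _draw_alterations(
    config: CohortConfig, samples: pd.DataFrame, rng: np.random.Generator
) -> AlterationTable:
    genes = sorted({g for g, _ in config.alt_probs})
    sample_ids = samples["sample_id"].to_numpy()
    sites = samples["site"].to_numpy()
    n = len(samples)

    evaluable: dict[str, frozenset] = {}
    rows = []
    driver_types = list(_DRIVER_TYPE_PROBS)
    driver_p = np.array(list(_DRIVER_TYPE_PROBS.values()))
    qualifying_per_sample = np.zeros(n, dtype=int)

    for gene in genes:
        ev_frac = config.evaluable_fraction.get(gene, 1.0)
        ev_mask = rng.random(n) < ev_frac
        evaluable[gene] = frozenset(sample_ids[ev_mask])
        probs = np.array([config.alt_probs.get((gene, s), 0.0) for s in sites])
        alt_mask = ev_mask & (rng.random(n) < probs)
        for i in np.where(alt_mask)[0]:
            vtype = driver_types[rng.choice(len(driver_types), p=driver_p)]
            rows.append(
                {
                    "sample_id": sample_ids[i],
                    "gene": gene,
                    "variant_type": vtype,
                    "classification": "pathogenic" if rng.random() < 0.7 else "likely_pathogenic",
                    "germline_known": False,
                }
            )
            if vtype in _TMB_QUALIFYING:
                qualifying_per_sample[i] += 1

    # passenger variants (VUS / benign / known-germline) bring each sample's
    # qualifying nonsynonymous count up to its site's mutational-burden rate
    # and exercise the pathogenicity and germline filtering rules downstream
    ev_genes_per_sample = [[] for _ in range(n)]
    for gene in genes:
        evset = evaluable[gene]
        for i, sid in enumerate(sample_ids):
            if sid in evset:
                ev_genes_per_sample[i].append(gene)

    for i, sid in enumerate(sample_ids):
        rate = config.tmb_rates.get(sites[i], 0.0)
        target = rng.poisson(rate * config.panel_mb)
        extra = max(0, target - qualifying_per_sample[i])
        pool = ev_genes_per_sample[i]
        if not pool:
            continue
        for _ in range(extra):
            rows.append(
                {
                    "sample_id": sid,
                    "gene": pool[rng.integers(len(pool))],
                    "variant_type": _TMB_QUALIFYING[rng.integers(len(_TMB_QUALIFYING))],
                    "classification": "VUS",
                    "germline_known": False,
                }
            )
        # a few known-germline and non-qualifying rows, excluded everywhere
        for _ in range(rng.poisson(1.0)):
            rows.append(
                {
                    "sample_id": sid,
                    "gene": pool[rng.integers(len(pool))],
                    "variant_type": _TMB_QUALIFYING[rng.integers(len(_TMB_QUALIFYING))],
                    "classification": "benign",
                    "germline_known": True,
                }
            )
        if rng.random() < 0.2:
            rows.append(
                {
                    "sample_id": sid,
                    "gene": pool[rng.integers(len(pool))],
                    "variant_type": "promoter" if rng.random() < 0.5 else "splice",
                    "classification": "VUS",
                    "germline_known": False,
                }
            )

    calls = pd.DataFrame(
        rows, columns=["sample_id", "gene", "variant_type", "classification", "germline_known"]
    )
    return AlterationTable(calls=calls, evaluable=evaluable)


def _draw_expression(
    config: CohortConfig,
    samples: pd.DataFrame,
    subtype_labels: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    genes = list(config.gene_universe)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes, n_samples = len(genes), len(samples)
    log2 = np.full((n_genes, n_samples), config.baseline_log2, dtype=float)

    sites = samples["site"].to_numpy()
    metastatic = (samples["site_class"] == "metastatic").to_numpy()

    for j in range(n_samples):
        for signame in SUBGROUP_SIGNATURES[subtype_labels[j]]:
            for g in config.signatures.get(signame, ()):
                log2[gene_idx[g], j] += config.signature_effect

    for gene, lfc in config.deg_effects.items():
        log2[gene_idx[gene], metastatic] += lfc

    for (name, site), shift in config.tme_shifts.items():
        cols = sites == site
        if not cols.any():
            continue
        targets = config.marker_catalog.get(name, [name] if name in gene_idx else [])
        for g in targets:
            log2[gene_idx[g], cols] += shift

    log2 += rng.normal(0.0, config.noise_sd, size=log2.shape)
    return pd.DataFrame(np.exp2(log2), index=pd.Index(genes, name="gene"), columns=samples["sample_id"])


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort. Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = _draw_samples(config, rng)
    alterations = _draw_alterations(config, samples, rng)

    labels = np.empty(len(samples), dtype=object)
    kidney_prior = np.asarray(config.subtype_priors["kidney"], dtype=float)
    for i, site in enumerate(samples["site"]):
        prior = np.asarray(config.subtype_priors.get(site, kidney_prior), dtype=float)
        labels[i] = SUBGROUPS[rng.choice(len(SUBGROUPS), p=prior / prior.sum())]

    expression = _draw_expression(config, samples, labels, rng)
    truth = {
        "subtype": pd.Series(labels, index=samples["sample_id"].to_numpy(), name="latent_subtype"),
        "deg_effects": dict(config.deg_effects),
        "tme_shifts": dict(config.tme_shifts),
    }
    return SyntheticCohort(
        samples=samples, alterations=alterations, expression=expression, truth=truth, config=config
    )


_MSI_STATES = ("stable", "high")


def generate_msi_ihc(config: CohortConfig, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-sample PD-L1 staining and three-platform MSI calls.

    Each sample gets a PD-L1 staining intensity (0..3) and percent tumor
    cells stained, plus MSI calls from IHC, fragment analysis and NGS
    (emitted as an unstable-loci count against a loci budget). With
    probability ``msi_discordance_rate`` one randomly chosen platform call
    is flipped; platforms are independently missing with probability
    ``msi_platform_missing_rate``. Deterministic given ``config.seed``.
    """
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(samples)

    intensity = rng.choice(4, size=n, p=np.asarray(config.pdl1_intensity_probs))
    pct = np.where(intensity == 0, 0.0, np.round(rng.beta(1.2, 3.0, size=n) * 100.0, 1))

    truth_high = rng.random(n) < config.msi_high_rate
    calls = np.where(truth_high[:, None], "high", "stable").astype(object)
    calls = np.repeat(calls, 3, axis=1) if calls.shape[1] == 1 else calls
    flip = rng.random(n) < config.msi_discordance_rate
    which = rng.integers(3, size=n)
    for i in np.where(flip)[0]:
        j = which[i]
        calls[i, j] = "high" if calls[i, j] == "stable" else "stable"
    missing = rng.random((n, 3)) < config.msi_platform_missing_rate

    # NGS unstable-loci counts consistent with the NGS call
    thr = config.msi_ngs_loci_threshold
    loci = np.where(
        calls[:, 2] == "high",
        thr + rng.poisson(30, size=n),
        np.minimum(rng.poisson(5, size=n), thr - 1),
    )

    out = pd.DataFrame(
        {
            "sample_id": samples["sample_id"].to_numpy(),
            "pdl1_intensity": intensity,
            "pdl1_pct": pct,
            "msi_ihc": np.where(missing[:, 0], None, calls[:, 0]),
            "msi_fragment_analysis": np.where(missing[:, 1], None, calls[:, 1]),
            "msi_ngs": np.where(missing[:, 2], None, calls[:, 2]),
            "msi_ngs_unstable_loci": loci,
            "msi_ngs_loci_total": config.msi_ngs_loci_total,
        }
    )
    return out
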