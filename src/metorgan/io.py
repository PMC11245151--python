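"""Cohort table schemas, validation, and tab-separated I/O.

Three tables describe a cohort:

* **metadata** — one row per biopsy sample (site, primary/metastatic class,
  histology, demographics, assay type);
* **alterations** — one row per somatic variant call (gene, variant type,
  ACMG-style pathogenicity class, known-germline flag), plus a long-format
  evaluability table saying which samples are assessable for which gene
  (panel vs whole-exome coverage differs by gene);
* **expression** — a dense genes x samples matrix of non-negative linear
  abundances (TPM-like).

All files are UTF-8, tab-separated, with a ``#``-prefixed provenance header
and deterministic row order, so identical cohorts serialize byte-identically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SITES = (
    "kidney",
    "lung",
    "bone",
    "soft tissue",
    "liver",
    "endocrine",
    "CNS",
    "lymph node",
    "pleura",
    "skin",
    "GI tract",
    "other",
)
HISTOLOGIES = (
    "clear cell",
    "papillary",
    "chromophobe",
    "medullary",
    "MiT translocation",
    "collecting duct",
    "other",
)
VARIANT_TYPES = ("missense", "nonsense", "frameshift", "inframe_indel", "splice", "promoter")
CLASSIFICATIONS = ("pathogenic", "likely_pathogenic", "VUS", "likely_benign", "benign")
SEXES = ("male", "female")
ASSAYS = ("panel", "WES")

METADATA_COLUMNS = (
    "sample_id",
    "patient_id",
    "site",
    "site_class",
    "histology",
    "sarcomatoid",
    "age_years",
    "sex",
    "assay",
)
ALTERATION_COLUMNS = ("sample_id", "gene", "variant_type", "classification", "germline_known")


class SchemaError(ValueError):
    """A required column is missing or a field violates its vocabulary."""


class ValidationError(ValueError):
    """A table violates a cohort invariant (ranges, referential integrity)."""


@dataclass
class AlterationTable:
    """Per-variant somatic calls plus the per-gene evaluability map."""

    calls: pd.DataFrame
    evaluable: dict[str, frozenset] = field(default_factory=dict)

    def evaluable_samples(self, gene: str) -> frozenset:
        if gene not in self.evaluable:
            raise KeyError(f"gene {gene!r} not in evaluability map")
        return self.evaluable[gene]

    def pathogenic_calls(self) -> pd.DataFrame:
        """Rows counted as mutations: pathogenic / likely_pathogenic only."""
        mask = self.calls["classification"].isin(["pathogenic", "likely_pathogenic"])
        return self.calls[mask]


def validate_samples(samples: pd.DataFrame) -> None:
    for col in METADATA_COLUMNS:
        if col not in samples.columns:
            raise SchemaError(f"metadata missing required column {col!r}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r}")
    bad_site = ~samples["site"].isin(SITES)
    if bad_site.any():
        raise SchemaError(f"unknown site {samples.loc[bad_site, 'site'].iloc[0]!r}")
    bad_hist = ~samples["histology"].isin(HISTOLOGIES)
    if bad_hist.any():
        raise SchemaError(f"unknown histology {samples.loc[bad_hist, 'histology'].iloc[0]!r}")
    # the kidney is the primary site by definition; everything else is metastatic
    kidney = samples["site"] == "kidney"
    primary = samples["site_class"] == "primary"
    if (kidney != primary).any():
        sid = samples.loc[kidney != primary, "sample_id"].iloc[0]
        raise ValidationError(
            f"sample {sid!r}: site='kidney' must pair with site_class='primary' and vice versa"
        )
    ages = pd.to_numeric(samples["age_years"], errors="coerce")
    out_of_range = ages.notna() & ((ages < 0) | (ages > 120))
    if out_of_range.any():
        sid = samples.loc[out_of_range, "sample_id"].iloc[0]
        raise ValidationError(f"sample {sid!r}: age_years outside [0, 120]")


def validate_alterations(alts: AlterationTable, samples: pd.DataFrame) -> None:
    calls = alts.calls
    for col in ALTERATION_COLUMNS:
        if col not in calls.columns:
            raise SchemaError(f"alterations missing required column {col!r}")
    known = set(samples["sample_id"])
    missing = set(calls["sample_id"]) - known
    if missing:
        raise ValidationError(f"alteration rows reference unknown sample(s): {sorted(missing)[:3]}")
    bad_type = ~calls["variant_type"].isin(VARIANT_TYPES)
    if bad_type.any():
        raise SchemaError(f"unknown variant_type {calls.loc[bad_type, 'variant_type'].iloc[0]!r}")
    bad_cls = ~calls["classification"].isin(CLASSIFICATIONS)
    if bad_cls.any():
        raise SchemaError(f"unknown classification {calls.loc[bad_cls, 'classification'].iloc[0]!r}")
    for gene, sub in calls.groupby("gene"):
        if gene in alts.evaluable:
            stray = set(sub["sample_id"]) - set(alts.evaluable[gene])
            if stray:
                raise ValidationError(
                    f"gene {gene!r}: call in sample(s) {sorted(stray)[:3]} not marked evaluable"
                )


def validate_expression(expr: pd.DataFrame, samples: pd.DataFrame | None = None) -> None:
    if expr.index.duplicated().any():
        raise ValidationError(f"duplicate gene id {expr.index[expr.index.duplicated()][0]!r}")
    if expr.columns.duplicated().any():
        raise ValidationError(
            f"duplicate sample id {expr.columns[expr.columns.duplicated()][0]!r}"
        )
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("expression contains non-finite values")
    if (values < 0).any():
        gene = expr.index[np.where(values < 0)[0][0]]
        raise ValidationError(f"negative expression value for gene {gene!r}")
    if samples is not None:
        unknown = set(expr.columns) - set(samples["sample_id"])
        if unknown:
            raise ValidationError(
                f"expression sample(s) absent from metadata: {sorted(unknown)[:3]}"
            )


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str], index: bool = False) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def write_cohort(cohort, out_dir) -> dict[str, Path]:
    """Write metadata/alterations/evaluability/expression (+truth) TSVs.

    Deterministic: rows sorted on their natural keys, so the same cohort
    always produces byte-identical files. Returns a name -> path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = getattr(getattr(cohort, "config", None), "seed", None)
    prov = [f"generator seed: {seed}"] if seed is not None else ["user-supplied cohort"]

    samples = cohort.samples.sort_values("sample_id").reset_index(drop=True)
    validate_samples(samples)
    paths = {"metadata": out / "metadata.tsv"}
    _write_tsv(samples, paths["metadata"], ["cohort sample metadata"] + prov)

    calls = cohort.alterations.calls.sort_values(
        ["sample_id", "gene", "variant_type", "classification"]
    ).reset_index(drop=True)
    paths["alterations"] = out / "alterations.tsv"
    _write_tsv(calls, paths["alterations"], ["somatic alteration calls"] + prov)

    ev_rows = [
        {"gene": g, "sample_id": s}
        for g in sorted(cohort.alterations.evaluable)
        for s in sorted(cohort.alterations.evaluable[g])
    ]
    ev = pd.DataFrame(ev_rows, columns=["gene", "sample_id"])
    paths["evaluability"] = out / "evaluability.tsv"
    _write_tsv(ev, paths["evaluability"], ["per-gene evaluable samples"] + prov)

    expr = cohort.expression.sort_index()
    expr = expr[sorted(expr.columns)]
    validate_expression(expr, samples)
    paths["expression"] = out / "expression.tsv"
    with open(paths["expression"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# expression matrix, linear TPM-like units\n")
        for line in prov:
            fh.write(f"# {line}\n")
        expr.to_csv(fh, sep="\t", index=True, index_label="gene", lineterminator="\n")

    truth = getattr(cohort, "truth", None)
    if truth is not None and "subtype" in truth:
        tdf = (
            truth["subtype"]
            .rename("latent_subtype")
            .rename_axis("sample_id")
            .reset_index()
            .sort_values("sample_id")
        )
        paths["truth"] = out / "truth.tsv"
        _write_tsv(tdf, paths["truth"], ["latent generator truth"] + prov)
    return paths


def read_cohort(metadata_path, alterations_path, expression_path, evaluability_path=None):
    """Read and validate the three cohort tables.

    Returns (samples DataFrame, AlterationTable, expression DataFrame).
    When no evaluability file is given, every sample is assumed evaluable
    for every gene seen in the alteration table.
    """
    samples = pd.read_csv(metadata_path, sep="\t", comment="#", dtype={"sample_id": str, "patient_id": str})
    validate_samples(samples)

    calls = pd.read_csv(alterations_path, sep="\t", comment="#", dtype={"sample_id": str})
    if calls.empty and "sample_id" not in calls.columns:
        calls = pd.DataFrame(columns=list(ALTERATION_COLUMNS))
    if evaluability_path is not None:
        ev = pd.read_csv(evaluability_path, sep="\t", comment="#", dtype=str)
        evaluable = {
            gene: frozenset(sub["sample_id"]) for gene, sub in ev.groupby("gene")
        }
    else:
        all_ids = frozenset(samples["sample_id"])
        evaluable = {gene: all_ids for gene in calls.get("gene", pd.Series(dtype=str)).unique()}
    alts = AlterationTable(calls=calls, evaluable=evaluable)
    validate_alterations(alts, samples)

    expr = pd.read_csv(expression_path, sep="\t", comment="#", index_col=0)
    expr.index.name = "gene"
    expr.columns.name = "sample_id"
    validate_expression(expr, samples)
    return samples, alts, expr


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format: name <tab> description <tab> gene..."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, "na"] + list(sets[name])) + "\n")


# minimal MAF-dialect import: map the standard variant classifications onto
# this package's vocabulary; unmapped classes are skipped with a warning
_MAF_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
    "In_Frame_Del": "inframe_indel",
    "In_Frame_Ins": "inframe_indel",
    "Splice_Site": "splice",
    "Translation_Start_Site": "missense",
    "5'Flank": "promoter",
}


def read_maf_alterations(path, default_classification: str = "VUS") -> AlterationTable:
    """Import a minimal MAF-dialect table as an AlterationTable.

    Needs Hugo_Symbol, Variant_Classification, Tumor_Sample_Barcode columns;
    an optional ``clinical_significance`` column (values in this package's
    classification vocabulary) overrides the default. All samples seen in
    the file are treated as evaluable for all genes seen.
    """
    maf = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode"):
        if col not in maf.columns:
            raise SchemaError(f"MAF import missing required column {col!r}")
    mapped = maf["Variant_Classification"].map(_MAF_CLASS_MAP)
    skipped = maf.loc[mapped.isna(), "Variant_Classification"].unique()
    if len(skipped):
        warnings.warn(f"skipping unmapped MAF variant classes: {sorted(skipped)}", stacklevel=2)
    keep = maf[mapped.notna()]
    if "clinical_significance" in keep.columns:
        cls = keep["clinical_significance"].fillna(default_classification)
    else:
        cls = pd.Series(default_classification, index=keep.index)
    calls = pd.DataFrame(
        {
            "sample_id": keep["Tumor_Sample_Barcode"].to_numpy(),
            "gene": keep["Hugo_Symbol"].to_numpy(),
            "variant_type": mapped[mapped.notna()].to_numpy(),
            "classification": cls.to_numpy(),
            "germline_known": False,
        }
    )
    all_ids = frozenset(calls["sample_id"])
    evaluable = {gene: all_ids for gene in calls["gene"].unique()}
    return AlterationTable(calls=calls, evaluable=evaluable)
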