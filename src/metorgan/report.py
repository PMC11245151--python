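"""End-to-end orchestration: run every analysis stage, write a report bundle.

``run_all`` executes simulate -> enrich -> classify -> de -> tme ->
biomarkers on a (default or configured) synthetic cohort, writing each
stage's TSV outputs plus a cohort composition summary and a JSON run
manifest with content digests. Analytic TSVs are formatted with 6
significant digits and fixed row order, so identical config+seed produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from metorgan import biomarkers as bm
from metorgan import de as de_mod
from metorgan import enrichment, subtypes, tme
from metorgan.io import write_cohort
from metorgan.synth import (
    CHECKPOINT_GENES,
    MUTATED_GENES,
    CohortConfig,
    default_config,
    generate_cohort,
    generate_msi_ihc,
)

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"
STAGES = ("simulate", "enrich", "classify", "de", "tme", "biomarkers")


def config_from_yaml(path) -> CohortConfig:
    """Build a CohortConfig from a YAML override file over the defaults.

    Scalar fields override directly; mapping fields (site_counts, deg_effects,
    tmb_rates, evaluable_fraction) merge into the defaults. alt_probs,
    subtype_priors and tme_shifts use 'GENE|site'-style compound keys.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = default_config(seed=int(raw.pop("seed", 0)))
    merged: dict = {}
    for key, value in raw.items():
        if key in ("alt_probs", "tme_shifts"):
            base = dict(getattr(cfg, key))
            for ck, v in value.items():
                name, site = ck.split("|", 1)
                base[(name, site)] = float(v)
            merged[key] = base
        elif key == "subtype_priors":
            base = dict(cfg.subtype_priors)
            base.update({s: tuple(v) for s, v in value.items()})
            merged[key] = base
        elif isinstance(value, dict) and isinstance(getattr(cfg, key), dict):
            base = dict(getattr(cfg, key))
            base.update(value)
            merged[key] = base
        else:
            merged[key] = value
    cfg = dataclasses.replace(cfg, **merged)
    cfg.validate()
    return cfg


def _config_digest(config: CohortConfig) -> str:
    def canon(obj):
        if isinstance(obj, dict):
            return sorted((str(k), canon(v)) for k, v in obj.items())
        if isinstance(obj, (list, tuple)):
            return [canon(v) for v in obj]
        return obj

    blob = json.dumps(canon(dataclasses.asdict(config)), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _write_table(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT, lineterminator="\n")


def summarize_cohort(samples: pd.DataFrame) -> pd.DataFrame:
    """Tidy composition table: counts/percents by site, class, histology, sex,
    plus median age with range."""
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    blocks = []
    for block in ("site", "site_class", "histology", "sex"):
        counts = samples[block].value_counts()
        for category, n in counts.items():
            blocks.append(
                {"block": block, "category": category, "n": int(n), "value": 100.0 * n / len(samples)}
            )
    ages = pd.to_numeric(samples["age_years"], errors="coerce").dropna()
    if len(ages):
        blocks.append({"block": "age", "category": "median", "n": len(ages), "value": float(ages.median())})
        blocks.append({"block": "age", "category": "min", "n": len(ages), "value": float(ages.min())})
        blocks.append({"block": "age", "category": "max", "n": len(ages), "value": float(ages.max())})
    blocks.append({"block": "total", "category": "samples", "n": len(samples), "value": 100.0})
    return pd.DataFrame(blocks, columns=["block", "category", "n", "value"])


def run_all(
    out_dir,
    config: CohortConfig | None = None,
    config_path=None,
    skip: tuple[str, ...] = (),
    alpha: float = 0.05,
) -> dict:
    """Run the pipeline end to end; returns the run manifest (also on disk)."""
    if config is None:
        config = config_from_yaml(config_path) if config_path else default_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    executed = []
    outputs: dict[str, Path] = {}

    stage = "simulate"
    try:
        cohort = generate_cohort(config)
        platform = generate_msi_ihc(config, cohort.samples)
        executed.append(stage)
        outputs.update(write_cohort(cohort, out / "cohort"))
        _write_table(summarize_cohort(cohort.samples), out / "cohort_summary.tsv")
        outputs["cohort_summary"] = out / "cohort_summary.tsv"
    except Exception as exc:  # noqa: BLE001 - stage attribution, then re-raise
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    samples, alts, expr = cohort.samples, cohort.alterations, cohort.expression

    if "enrich" not in skip:
        stage = "enrich"
        try:
            screen = enrichment.enrichment_screen(alts, samples, MUTATED_GENES, alpha=alpha)
            freq = enrichment.frequency_table(alts, samples, MUTATED_GENES)
            _write_table(screen, out / "enrichment.tsv")
            _write_table(freq, out / "frequencies.tsv")
            outputs["enrichment"] = out / "enrichment.tsv"
            outputs["frequencies"] = out / "frequencies.tsv"
            executed.append(stage)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    assignments = None
    if "classify" not in skip:
        stage = "classify"
        try:
            model = subtypes.default_subtype_model(config.signatures)
            comp = subtypes.classify_expression(expr, model)
            assignments = comp.labels
            props, site_tests, sub_tests = subtypes.subtype_distribution_by_site(
                comp.labels, samples, seed=config.seed
            )
            sub_out = pd.DataFrame(
                {"sample_id": comp.labels.index, "subtype": comp.labels.to_numpy(),
                 "margin": comp.margin.to_numpy()}
            )
            _write_table(sub_out, out / "subtypes.tsv")
            _write_table(props.rename_axis("subtype"), out / "subtype_distribution.tsv", index=True)
            _write_table(site_tests, out / "subtype_site_tests.tsv")
            _write_table(sub_tests, out / "subtype_per_subtype_tests.tsv")
            for name in ("subtypes", "subtype_distribution", "subtype_site_tests", "subtype_per_subtype_tests"):
                outputs[name] = out / f"{name}.tsv"
            executed.append(stage)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if "de" not in skip:
        stage = "de"
        try:
            pooled = de_mod.mets_vs_kidney(expr, samples, alpha=alpha)
            _write_table(pooled.reset_index(), out / "de_mets_vs_kidney.tsv")
            outputs["de_mets_vs_kidney"] = out / "de_mets_vs_kidney.tsv"
            de_by_site = {}
            for site in ("lung", "bone", "liver"):
                if (samples["site"] == site).sum() >= 2:
                    de_by_site[site] = de_mod.per_site_deg(expr, samples, site, alpha=alpha)
                    _write_table(de_by_site[site].reset_index(), out / f"de_{site}_vs_kidney.tsv")
                    outputs[f"de_{site}"] = out / f"de_{site}_vs_kidney.tsv"
            if len(de_by_site) >= 2:
                regions = de_mod.deg_overlap(de_by_site)
                rows = [
                    {"direction": d, "sites": "&".join(sorted(region)), "genes": ",".join(sorted(genes))}
                    for d, regs in regions.items()
                    for region, genes in sorted(regs.items(), key=lambda kv: sorted(kv[0]))
                ]
                _write_table(pd.DataFrame(rows, columns=["direction", "sites", "genes"]), out / "deg_overlap.tsv")
                outputs["deg_overlap"] = out / "deg_overlap.tsv"
            executed.append(stage)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if "tme" not in skip:
        stage = "tme"
        try:
            abund = tme.cell_abundance(expr, config.marker_catalog)
            med, stats = tme.compare_abundance_by_site(abund, samples)
            _write_table(med.rename_axis("population"), out / "tme_medians.tsv", index=True)
            _write_table(stats, out / "tme_stats.tsv")
            cmed, cstats, skipped = tme.checkpoint_expression_compare(expr, samples, CHECKPOINT_GENES)
            _write_table(cstats, out / "checkpoint_stats.tsv")
            if skipped:
                log.warning("checkpoint genes skipped: %s", skipped)
            for name in ("tme_medians", "tme_stats", "checkpoint_stats"):
                outputs[name] = out / f"{name}.tsv"
            executed.append(stage)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if "biomarkers" not in skip:
        stage = "biomarkers"
        try:
            statuses = bm.biomarker_statuses(alts, samples, platform, config.panel_mb)
            freqs = bm.biomarker_frequencies_by_site(statuses, samples)
            _write_table(statuses, out / "biomarker_statuses.tsv")
            _write_table(freqs, out / "biomarker_frequencies.tsv")
            outputs["biomarker_statuses"] = out / "biomarker_statuses.tsv"
            outputs["biomarker_frequencies"] = out / "biomarker_frequencies.tsv"
            executed.append(stage)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_digest": _config_digest(config),
        "seed": config.seed,
        "stages": executed,
        "outputs": {
            name: {
                "path": str(path.relative_to(out)),
                "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            }
            for name, path in sorted(outputs.items())
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "version": "0.1.0",
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
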