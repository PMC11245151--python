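import numpy as np
import pandas as pd
import pytest

from metorgan.synth import (
    SUBGROUPS,
    CohortConfig,
    default_config,
    generate_cohort,
)


def make_config(site_counts, seed=0, **overrides):
    """Scaled-down config: default parameterization, custom per-site counts."""
    cfg = default_config(seed=seed)
    counts = {s: 0 for s in cfg.site_counts}
    counts.update(site_counts)
    import dataclasses

    cfg = dataclasses.replace(cfg, site_counts=counts, **overrides)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort at the default study composition."""
    return generate_cohort(default_config(seed=11))


@pytest.fixture()
def small_config():
    return make_config({"kidney": 60, "lung": 25, "bone": 25, "liver": 20}, seed=7)


@pytest.fixture()
def small_cohort(small_config):
    return generate_cohort(small_config)


def make_freq_cohort(k, n, gene="VHL", site="lung"):
    """Minimal cohort with exactly k altered of n evaluable samples at a site."""
    from metorgan.io import AlterationTable

    ids = [f"S{i:05d}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "sample_id": ids,
            "patient_id": ids,
            "site": site,
            "site_class": "primary" if site == "kidney" else "metastatic",
            "histology": "clear cell",
            "sarcomatoid": False,
            "age_years": 60,
            "sex": "male",
            "assay": "panel",
        }
    )
    calls = pd.DataFrame(
        {
            "sample_id": ids[:k],
            "gene": gene,
            "variant_type": "missense",
            "classification": "pathogenic",
            "germline_known": False,
        }
    )
    alts = AlterationTable(calls=calls, evaluable={gene: frozenset(ids)})
    return samples, alts
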