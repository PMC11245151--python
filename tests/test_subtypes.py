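"""Composite z-score subtype classification."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_config, make_freq_cohort
from metorgan.subtypes import (
    SubtypeModel,
    classify_expression,
    composite_and_assign,
    default_subtype_model,
    signature_scores,
    subtype_distribution_by_site,
    subtype_metastatic_share,
    zscore_log,
)
from metorgan.synth import SUBGROUPS, generate_cohort


class TestZscoreLog:
    def test_hand_computed_small_matrix(self):
        expr = pd.DataFrame(
            [[0.0, 1.0, 3.0, 7.0], [1.0, 1.0, 1.0, 1.0], [15.0, 3.0, 0.0, 1.0]],
            index=["g1", "g2", "g3"],
            columns=list("abcd"),
        )
        L = np.log2(expr.to_numpy() + 1.0)
        with np.errstate(invalid="ignore"):
            expected = (L - L.mean(axis=1, keepdims=True)) / L.std(
                axis=1, ddof=1, keepdims=True
            )
        expected[1] = 0.0  # constant gene
        z = zscore_log(expr)
        np.testing.assert_allclose(z.to_numpy(), expected, atol=1e-12)

    def test_rows_standardized(self, small_cohort):
        z = zscore_log(small_cohort.expression)
        arr = z.to_numpy()
        nonconst = arr.std(axis=1) > 0
        assert np.abs(arr[nonconst].mean(axis=1)).max() < 1e-8
        assert np.abs(arr[nonconst].std(axis=1, ddof=1) - 1.0).max() < 1e-6

    def test_constant_gene_becomes_zero_row(self):
        expr = pd.DataFrame([[2.0, 2.0, 2.0]], index=["g"], columns=list("abc"))
        assert (zscore_log(expr).to_numpy() == 0).all()

    def test_single_sample_rejected(self):
        expr = pd.DataFrame([[1.0]], index=["g"], columns=["a"])
        with pytest.raises(ValueError):
            zscore_log(expr)


class TestSignatureScores:
    def test_single_gene_signature_is_identity(self, small_cohort):
        z = zscore_log(small_cohort.expression)
        s = signature_scores(z, {"solo": ["VHL"]})
        np.testing.assert_allclose(s.loc["solo"].to_numpy(), z.loc["VHL"].to_numpy())

    def test_opposite_z_values_cancel(self):
        z = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]], index=["g1", "g2"], columns=["a", "b"])
        s = signature_scores(z, {"pair": ["g1", "g2"]})
        np.testing.assert_allclose(s.loc["pair"].to_numpy(), [0.0, 0.0])

    def test_matches_brute_force_mean(self, small_cohort):
        rng = np.random.default_rng(1)
        z = zscore_log(small_cohort.expression)
        genes = list(rng.choice(z.index, size=10, replace=False))
        s = signature_scores(z, {"rand": genes})
        brute = np.mean([z.loc[g].to_numpy() for g in genes], axis=0)
        np.testing.assert_allclose(s.loc["rand"].to_numpy(), brute, atol=1e-12)

    def test_no_present_genes_raises_with_name(self, small_cohort):
        z = zscore_log(small_cohort.expression)
        with pytest.raises(ValueError, match="ghost"):
            signature_scores(z, {"ghost": ["NOPE1", "NOPE2"]})


def _identity_model():
    names = list(SUBGROUPS)
    sigs = {f"sig{i}": [f"G{i}"] for i in range(7)}
    W = pd.DataFrame(np.eye(7), index=names, columns=list(sigs))
    return SubtypeModel(signatures=sigs, coefficients=W)


class TestCompositeAndAssign:
    def test_identity_weighting_picks_elevated_signature(self):
        model = _identity_model()
        S = pd.DataFrame(
            np.zeros((7, 2)), index=list(model.signatures), columns=["a", "b"]
        )
        S.iloc[3, 0] = 2.0
        S.iloc[5, 1] = 1.0
        comp = composite_and_assign(S, model)
        assert comp.labels["a"] == SUBGROUPS[3]
        assert comp.labels["b"] == SUBGROUPS[5]
        assert (comp.margin >= 0).all()

    def test_all_zero_weights_tie_breaks_to_first_subgroup(self):
        model = _identity_model()
        model.coefficients.iloc[:, :] = 0.0
        S = pd.DataFrame(np.ones((7, 3)), index=list(model.signatures), columns=list("abc"))
        comp = composite_and_assign(S, model)
        assert (comp.labels == SUBGROUPS[0]).all()
        assert (comp.scores.to_numpy() == 0).all()

    def test_positive_scaling_of_weights_preserves_labels(self, small_cohort):
        model = default_subtype_model(small_cohort.config.signatures)
        z = zscore_log(small_cohort.expression)
        S = signature_scores(z, model.signatures)
        labels1 = composite_and_assign(S, model).labels
        scaled = SubtypeModel(
            signatures=model.signatures, coefficients=model.coefficients * 7.3
        )
        labels2 = composite_and_assign(S, scaled).labels
        assert (labels1 == labels2).all()

    def test_non_finite_weight_rejected(self):
        model = _identity_model()
        model.coefficients.iloc[0, 0] = np.nan
        S = pd.DataFrame(np.ones((7, 2)), index=list(model.signatures), columns=["a", "b"])
        with pytest.raises(ValueError):
            composite_and_assign(S, model)

    def test_invariant_to_sample_and_gene_order(self, small_cohort):
        model = default_subtype_model(small_cohort.config.signatures)
        expr = small_cohort.expression
        labels1 = classify_expression(expr, model).labels
        rng = np.random.default_rng(0)
        shuffled = expr.iloc[rng.permutation(expr.shape[0]), rng.permutation(expr.shape[1])]
        labels2 = classify_expression(shuffled, model).labels
        assert (labels2.loc[labels1.index] == labels1).all()

    def test_recovers_latent_labels_on_well_separated_cohort(self):
        cfg = make_config(
            {"kidney": 250, "lung": 250}, seed=21, signature_effect=2.0, noise_sd=0.5
        )
        cohort = generate_cohort(cfg)
        model = default_subtype_model(cfg.signatures)
        comp = classify_expression(cohort.expression, model)
        truth = cohort.truth["subtype"]
        acc = (comp.labels.loc[truth.index] == truth).mean()
        assert acc >= 0.9


class TestDistributionBySite:
    def _assignments(self, samples, labels):
        return pd.Series(labels, index=samples["sample_id"].to_numpy(), name="subtype")

    def test_liver_complement_proportion_arithmetic(self):
        liver, _ = make_freq_cohort(0, 28, site="liver")
        kidney, _ = make_freq_cohort(0, 40, site="kidney")
        kidney["sample_id"] = ["K%03d" % i for i in range(40)]
        samples = pd.concat([liver, kidney], ignore_index=True)
        labels = ["complement/omega-oxidation"] * 17 + ["angiogenic"] * 11
        labels += ["angiogenic"] * 40
        props, _, _ = subtype_distribution_by_site(self._assignments(samples, labels), samples)
        assert round(100 * props.loc["complement/omega-oxidation", "liver"], 1) == 60.7
        assert props["liver"].sum() == pytest.approx(1.0)

    def test_metastatic_share_arithmetic(self):
        mets, _ = make_freq_cohort(0, 50, site="lung")
        kid, _ = make_freq_cohort(0, 24, site="kidney")
        kid["sample_id"] = ["K%03d" % i for i in range(24)]
        samples = pd.concat([mets, kid], ignore_index=True)
        labels = ["stromal/proliferative"] * 74
        share = subtype_metastatic_share(self._assignments(samples, labels), samples)
        assert round(share.loc["stromal/proliferative", "pct_metastatic"], 1) == 67.6
        assert share.loc["stromal/proliferative", "n_total"] == 74

    def test_identical_distributions_yield_uniformish_p(self):
        rng = np.random.default_rng(3)
        flags = 0
        reps = 200
        probs = np.array([0.2, 0.2, 0.15, 0.15, 0.1, 0.1, 0.1])
        for _ in range(reps):
            kid, _ = make_freq_cohort(0, 60, site="kidney")
            lung, _ = make_freq_cohort(0, 60, site="lung")
            lung["sample_id"] = ["L%03d" % i for i in range(60)]
            samples = pd.concat([kid, lung], ignore_index=True)
            labels = [SUBGROUPS[i] for i in rng.choice(7, size=120, p=probs)]
            _, site_tests, _ = subtype_distribution_by_site(
                self._assignments(samples, labels), samples, seed=int(rng.integers(2**31))
            )
            flags += site_tests["p_raw"].iloc[0] < 0.05
        rate = flags / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se

    def test_empty_site_omitted(self, small_cohort):
        model = default_subtype_model(small_cohort.config.signatures)
        comp = classify_expression(small_cohort.expression, model)
        props, site_tests, _ = subtype_distribution_by_site(comp.labels, small_cohort.samples)
        present = {s for s in small_cohort.samples["site"].unique()}
        assert set(props.columns) == present
        assert set(site_tests["site"]) == present - {"kidney"}
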