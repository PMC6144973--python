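"""Log transform, correlation PCA, Akaike weights and the selection flow."""

import numpy as np
import pandas as pd
import pytest

from ovoscope import ecostats, eggsim
from ovoscope.ecostats import (
    TRAIT_ORDER,
    akaike_weights,
    check_loadings,
    compare,
    log_traits,
    pca_corr,
    run_selection,
)

# eigenvector listings reported for the museum series (first and second
# principal axis of the 7 log traits, in TRAIT_ORDER)
REPORTED_PC1 = np.array([0.229, -0.360, -0.400, 0.428, 0.390, 0.406, 0.398])
REPORTED_PC2 = np.array([-0.655, 0.523, 0.181, 0.218, 0.295, 0.220, 0.286])


def synthetic_trait_table(rng, n=200, factor_scale=1.0, noise=0.3):
    """7 correlated traits driven by one common factor."""
    f = rng.normal(size=n)
    cols = {}
    for j, name in enumerate(TRAIT_ORDER):
        sign = 1 if j % 2 == 0 else -1
        latent = sign * factor_scale * f + noise * rng.normal(size=n) + 1.0
        # spot_number is log1p-transformed downstream, the rest plain log
        if name == "spot_number":
            cols[name] = np.expm1(latent + 9.0)  # offset keeps counts >= 0
        else:
            cols[name] = np.exp(latent)
    return pd.DataFrame(cols)


class TestLogTraits:
    def test_log_values(self):
        t = synthetic_trait_table(np.random.default_rng(0), n=20)
        t.loc[0, "spottiness"] = 1.0
        t.loc[1, "spottiness"] = np.e
        out = log_traits(t)
        assert out.loc[0, "spottiness"] == pytest.approx(0.0)
        assert out.loc[1, "spottiness"] == pytest.approx(1.0)

    def test_spot_number_uses_log1p(self):
        t = synthetic_trait_table(np.random.default_rng(0), n=20)
        t["spot_number"] = np.arange(20.0)
        out = log_traits(t)
        np.testing.assert_allclose(out["spot_number"],
                                   np.log1p(np.arange(20.0)))

    def test_monotone_order_preserved(self, rng):
        t = synthetic_trait_table(rng, n=50)
        out = log_traits(t)
        for col in TRAIT_ORDER:
            assert (
                t[col].rank().to_numpy() == out[col].rank().to_numpy()
            ).all()

    def test_zero_spottiness_flagged_not_dropped(self):
        t = synthetic_trait_table(np.random.default_rng(0), n=20)
        t.loc[3, "spottiness"] = 0.0
        out = log_traits(t)
        assert out["incomplete"][3]
        assert len(out) == 20

    def test_negative_trait_rejected(self):
        t = synthetic_trait_table(np.random.default_rng(0), n=20)
        t.loc[0, "b_vis"] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            log_traits(t)


class TestPCACorr:
    def test_rank_one_structure(self, rng):
        t = synthetic_trait_table(rng, n=300, factor_scale=2.0, noise=1e-8)
        res = pca_corr(log_traits(t))
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.decomposition import PCA

        t = synthetic_trait_table(rng, n=200)
        logged = log_traits(t)
        res = pca_corr(logged)
        data = logged[list(TRAIT_ORDER)].to_numpy()
        std = (data - data.mean(0)) / data.std(0, ddof=1)
        ref = PCA(n_components=2).fit(std)
        for j in range(2):
            v = ref.components_[j]
            if np.sign(v @ res.loadings[:, j]) < 0:
                v = -v
            np.testing.assert_allclose(res.loadings[:, j], v, atol=1e-8)

    def test_sign_convention(self, trait_truth, rng):
        t = synthetic_trait_table(rng, n=150)
        res = pca_corr(log_traits(t))
        assert res.loadings[TRAIT_ORDER.index("b_vis"), 0] > 0
        assert res.loadings[TRAIT_ORDER.index("spot_size"), 1] > 0

    def test_reconstruction_from_all_components(self, rng):
        t = synthetic_trait_table(rng, n=100)
        logged = log_traits(t)
        data = logged[list(TRAIT_ORDER)].to_numpy()
        std = (data - data.mean(0)) / data.std(0, ddof=1)
        res = pca_corr(logged, n_components=7)
        recon = res.scores @ res.loadings.T
        np.testing.assert_allclose(recon, std, atol=1e-8)

    def test_reported_eigenvectors_pass_validator(self):
        diag = check_loadings(REPORTED_PC1, REPORTED_PC2, tol=0.01)
        assert diag["norm_dev_1"] < 0.01
        assert diag["norm_dev_2"] < 0.01
        assert diag["abs_dot"] < 0.01
        assert diag["ok"]

    def test_orthonormality_validated(self, rng):
        res = pca_corr(log_traits(synthetic_trait_table(rng)))
        res.validate()

    def test_too_few_rows_rejected(self, rng):
        t = synthetic_trait_table(rng, n=7)
        with pytest.raises(ValueError, match="8"):
            pca_corr(log_traits(t))

    def test_constant_column_rejected(self, rng):
        t = synthetic_trait_table(rng, n=50)
        t["b_uv"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            pca_corr(log_traits(t))


class TestAkaikeWeights:
    def test_single_model(self):
        np.testing.assert_allclose(akaike_weights([0.0]), [1.0])

    def test_tied_models_split_evenly(self):
        np.testing.assert_allclose(akaike_weights([0.0, 0.0]), [0.5, 0.5])

    def test_reported_spatiotemporal_block(self):
        """Weights recomputed from the published reflectance-axis delta
        column reproduce the printed weights to 3 decimals."""
        delta = np.array([2.24, 0.00, 4.81, 3.61, 16.12])
        w = akaike_weights(delta)
        np.testing.assert_allclose(
            np.round(w, 3), [0.206, 0.632, 0.057, 0.104, 0.000]
        )

    def test_reported_environmental_blocks(self):
        pc1 = akaike_weights(
            np.array([22.85, 23.38, 20.83, 18.16, 18.83, 13.04, 0.0, 35.14])
        )
        assert round(pc1[6], 3) == 0.998
        assert round(pc1[5], 3) == 0.001
        pc2 = akaike_weights(np.array([6.88, 3.18, 4.35, 0.98, 2.15, 0.0]))
        assert round(pc2[5], 3) == 0.434
        assert round(pc2[3], 3) == 0.266


@pytest.fixture(scope="module")
def selection():
    table = eggsim.make_trait_dataset(seed=42).table
    return run_selection(table, "pc1")


class TestSelectionWorkflow:

    def test_outputs_table2_model_labels(self, selection):
        labels = set(selection["spatio_temporal"].table["model"])
        assert labels == {
            "Year + s(latitude)", "Year + latitude", "Latitude", "Year",
            "Null model",
        }

    def test_weights_sum_to_one(self, selection):
        for key in ("spatio_temporal", "environmental"):
            assert selection[key].table["weight"].sum() == pytest.approx(
                1.0, abs=1e-6
            )
            assert selection[key].table["delta_aicc"].min() == 0.0

    def test_df_bookkeeping_matches_convention(self, selection):
        tbl = selection["spatio_temporal"].table.set_index("model")
        assert tbl.loc["Null model", "df"] == 3
        assert tbl.loc["Year", "df"] == 4
        assert tbl.loc["Year + latitude", "df"] == 5
        assert tbl.loc["Year + s(latitude)", "df"] == 6
        env = selection["environmental"].table.set_index("model")
        assert env.loc["Year + sv + insolation^4", "df"] == 9
        assert env.loc["Year + sv + insolation^3", "df"] == 8
        assert env.loc["Year + sv + s(insolation)", "df"] == 7

    def test_random_effect_assessment_present(self, selection):
        ra = selection["random_effect_assessment"]
        assert set(ra) >= {"aicc_with_site", "aicc_without_site",
                           "delta_aicc", "site_improves"}

    def test_r2_ordering(self, selection):
        tbl = selection["environmental"].table.dropna(subset=["r2m"])
        assert (tbl["r2m"] <= tbl["r2c"] + 1e-9).all()
        assert (tbl["r2c"] <= 1.0).all()

    def test_single_site_refused(self):
        table = eggsim.make_trait_dataset(seed=1).table
        table["site"] = "only"
        with pytest.raises(ValueError, match="2 sites"):
            run_selection(table, "pc1")

    def test_unknown_response_refused(self, trait_truth):
        with pytest.raises(ValueError, match="pc1"):
            run_selection(trait_truth.table, "pc3")

    def test_missing_column_named(self, trait_truth):
        bad = trait_truth.table.drop(columns=["insolation"])
        with pytest.raises(KeyError, match="insolation"):
            run_selection(bad, "pc1")
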