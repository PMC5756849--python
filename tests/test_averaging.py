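import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smoltsurv.averaging import (
    akaike_weights,
    average_models,
    averaged_parameters,
    averaged_predictions,
    confidence_set,
    grouping_weight_table,
)

finite_aicc_lists = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=1, max_size=40
)


class TestAkaikeWeights:
    def test_equal_aicc_uniform(self):
        w = akaike_weights([123.4] * 10)
        np.testing.assert_allclose(w, 0.1)

    def test_two_model_closed_form(self):
        w = akaike_weights([100.0, 102.0])
        e = np.exp(-1.0)
        np.testing.assert_allclose(w, [1 / (1 + e), e / (1 + e)], atol=1e-12)
        assert w[0] == pytest.approx(0.73106, abs=1e-5)
        assert w[1] == pytest.approx(0.26894, abs=1e-5)

    @given(finite_aicc_lists)
    @settings(max_examples=50, deadline=None)
    def test_sum_to_one(self, values):
        assert akaike_weights(values).sum() == pytest.approx(1.0, abs=1e-12)

    @given(finite_aicc_lists, st.floats(min_value=-1e5, max_value=1e5, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_translation_invariance(self, values, shift):
        a = akaike_weights(values)
        b = akaike_weights([v + shift for v in values])
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_nonfinite_gets_zero_weight(self):
        w = akaike_weights([10.0, np.inf, 12.0])
        assert w[1] == 0.0
        assert w.sum() == pytest.approx(1.0)

    def test_monotone_in_delta(self):
        w = akaike_weights([1.0, 3.0, 7.0, 2.0])
        order = np.argsort([1.0, 3.0, 7.0, 2.0])
        assert all(np.diff(w[order]) <= 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            akaike_weights([])


class TestConfidenceSet:
    def test_dominant_model_alone(self):
        mask = confidence_set([0.995, 0.005], level=0.99)
        assert mask.tolist() == [True, False]

    def test_uniform_768(self):
        mask = confidence_set(np.full(768, 1 / 768), level=0.99)
        assert mask.sum() == int(np.ceil(0.99 * 768)) == 761

    def test_crossing_model_included(self):
        mask = confidence_set([0.5, 0.45, 0.05], level=0.99)
        assert mask.tolist() == [True, True, True]
        mask = confidence_set([0.6, 0.4], level=0.99)
        assert mask.tolist() == [True, True]

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_members_dominate_nonmembers(self, raw):
        w = np.asarray(raw) / np.sum(raw)
        mask = confidence_set(w, level=0.9)
        if mask.all() or not mask.any():
            return
        assert w[mask].min() >= w[~mask].max() - 1e-12


class TestAveragedParameters:
    def test_identical_beta_everywhere(self, fit_factory):
        fits = [
            fit_factory(("intercept", "d", "t"), [-1.0, 0.3, 0.7], ses=[0.1, 0.1, 0.1]),
            fit_factory(("intercept", "d", "t", "f"), [-1.0, 0.3, 0.7, 0.2], ses=[0.1] * 4),
        ]
        w = np.array([0.6, 0.4])
        out = averaged_parameters(fits, w, [True, True])
        assert out.loc["t", "averaged_beta"] == pytest.approx(0.7)
        assert out.loc["t", "relative_importance"] == pytest.approx(1.0)

    def test_absent_covariate(self, fit_factory):
        fits = [fit_factory(("intercept", "d"), [-1.0, 0.3], ses=[0.1, 0.1])]
        out = averaged_parameters(fits, [1.0], [True])
        assert out.loc["U", "relative_importance"] == 0.0
        assert np.isnan(out.loc["U", "averaged_beta"])

    def test_three_model_manual_oracle(self, fit_factory):
        # weights .5/.3/.2; 't' present in models 1 and 3 with betas .4/.8, ses .1/.2
        fits = [
            fit_factory(("intercept", "d", "t"), [-1.0, 0.1, 0.4], ses=[0.1, 0.1, 0.1]),
            fit_factory(("intercept", "d"), [-1.0, 0.2], ses=[0.1, 0.1]),
            fit_factory(("intercept", "d", "t"), [-1.0, 0.3, 0.8], ses=[0.1, 0.1, 0.2]),
        ]
        w = np.array([0.5, 0.3, 0.2])
        out = averaged_parameters(fits, w, [True, True, True])
        wc = np.array([0.5, 0.2]) / 0.7
        betas = np.array([0.4, 0.8])
        ses = np.array([0.1, 0.2])
        avg = float(wc @ betas)
        se = float(np.sqrt(wc @ (ses**2 + (betas - avg) ** 2)))
        assert out.loc["t", "averaged_beta"] == pytest.approx(avg)
        assert out.loc["t", "unconditional_se"] == pytest.approx(se)
        assert out.loc["t", "relative_importance"] == pytest.approx(0.7)
        assert out.loc["d", "relative_importance"] == pytest.approx(1.0)

    def test_single_model_with_covariate(self, fit_factory):
        fits = [
            fit_factory(("intercept", "d", "U"), [-1.0, 0.1, -0.9], ses=[0.1, 0.1, 0.3]),
            fit_factory(("intercept", "d"), [-1.0, 0.2], ses=[0.1, 0.1]),
        ]
        out = averaged_parameters(fits, [0.3, 0.7], [True, True])
        assert out.loc["U", "averaged_beta"] == pytest.approx(-0.9)
        assert out.loc["U", "unconditional_se"] == pytest.approx(0.3)

    def test_set_renormalization(self, fit_factory):
        fits = [
            fit_factory(("intercept", "d", "t"), [-1.0, 0.1, 0.5], ses=[0.1] * 3),
            fit_factory(("intercept", "d"), [-1.0, 0.2], ses=[0.1, 0.1]),
            fit_factory(("intercept", "d"), [-1.0, 0.0], ses=[0.1, 0.1]),
        ]
        out = averaged_parameters(fits, [0.5, 0.3, 0.2], [True, True, False])
        assert out.loc["t", "relative_importance"] == pytest.approx(0.5 / 0.8)

    def test_empty_set_rejected(self, fit_factory):
        fits = [fit_factory(("intercept", "d"), [0.0, 0.0])]
        with pytest.raises(ValueError, match="empty confidence set"):
            averaged_parameters(fits, [1.0], [False])


class TestAveragedPredictions:
    def test_unanimous_prediction(self, fit_factory):
        fits = [fit_factory(("intercept", "d"), [0.0, 0.0]) for _ in range(3)]
        grid = pd.DataFrame({"d": [0.0, 1.0]})
        np.testing.assert_allclose(averaged_predictions(fits, [0.2, 0.3, 0.5], grid), 0.5)

    def test_two_model_mean(self, fit_factory):
        from scipy.special import logit

        fits = [
            fit_factory(("intercept", "d"), [float(logit(0.2)), 0.0]),
            fit_factory(("intercept", "d"), [float(logit(0.4)), 0.0]),
        ]
        grid = pd.DataFrame({"d": [0.0]})
        out = averaged_predictions(fits, [0.5, 0.5], grid)
        assert out[0] == pytest.approx(0.3)

    def test_convex_combination_bounds(self, fit_factory):
        rng = np.random.default_rng(8)
        fits = [
            fit_factory(("intercept", "d"), rng.normal(size=2).tolist()) for _ in range(4)
        ]
        w = rng.dirichlet(np.ones(4))
        grid = pd.DataFrame({"d": np.linspace(-2, 2, 9)})
        preds = np.array([averaged_predictions([f], [1.0], grid) for f in fits])
        avg = averaged_predictions(fits, w, grid)
        assert (avg >= preds.min(axis=0) - 1e-12).all()
        assert (avg <= preds.max(axis=0) + 1e-12).all()

    def test_conditional_on_covariate(self, fit_factory):
        fits = [
            fit_factory(("intercept", "d", "t"), [0.0, 0.0, 1.0]),
            fit_factory(("intercept", "d"), [3.0, 0.0]),
        ]
        grid = pd.DataFrame({"d": [0.0], "t": [0.0]})
        out = averaged_predictions(fits, [0.5, 0.5], grid, conditional_covariate="t")
        assert out[0] == pytest.approx(0.5)


class TestGroupingWeightTable:
    def test_partition_sums_to_one(self, fit_factory):
        fits = [
            fit_factory(("intercept", "d"), [0.0, 0.0], loglik=-100.0),
            fit_factory(("intercept", "d", "f"), [0.0, 0.0, 0.0], loglik=-99.0),
            fit_factory(("intercept", "d", "U"), [0.0, 0.0, 0.0], loglik=-98.0),
            fit_factory(("intercept", "d", "I"), [0.0, 0.0, 0.0], loglik=-97.0),
        ]
        w = akaike_weights([f.aicc for f in fits])
        table = grouping_weight_table(fits, w, confidence_set(w))
        assert table["weight_all"].sum() == pytest.approx(1.0, abs=1e-12)
        assert table["n_all"].sum() == 4

    def test_zero_weight_model_removal_invariance(self, fit_factory):
        fits = [
            fit_factory(("intercept", "d"), [0.0, 0.0], loglik=-100.0),
            fit_factory(("intercept", "d", "I"), [0.0, 0.0, 0.0], loglik=-100.0),
            fit_factory(("intercept", "d", "f"), [0.0, 0.0, 0.0], loglik=-1e5),
        ]
        a = np.array([f.aicc for f in fits])
        w = akaike_weights(a)
        assert w[2] == pytest.approx(0.0, abs=1e-300)
        full = grouping_weight_table(fits, w, confidence_set(w))
        reduced = grouping_weight_table(fits[:2], akaike_weights(a[:2]), confidence_set(akaike_weights(a[:2])))
        for g in ("MT", "MT-FW-M-C"):
            assert full.loc[g, "weight_all"] == pytest.approx(reduced.loc[g, "weight_all"], abs=1e-9)


@pytest.fixture(scope="module")
def workflow():
    from tests.conftest import make_fit as fit_factory

    rng = np.random.default_rng(77)
    fits = []
    for name_set, ll in [
        (("intercept", "d"), -105.0),
        (("intercept", "d", "t"), -101.0),
        (("intercept", "d", "I"), -95.0),
        (("intercept", "d", "t", "I"), -94.5),
    ]:
        fits.append(
            fit_factory(name_set, rng.normal(size=len(name_set)).tolist(), ses=[0.1] * len(name_set), loglik=ll)
        )
    return fits, average_models(fits, level=0.99)


class TestAverageModels:

    def test_weights_sum_to_one(self, workflow):
        _, avg = workflow
        assert avg.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_weights_decrease_with_delta(self, workflow):
        _, avg = workflow
        df = avg.models.sort_values("delta_aicc")
        assert all(np.diff(df["weight"]) <= 1e-15)

    def test_confidence_set_mass(self, workflow):
        _, avg = workflow
        assert avg.weights[avg.in_set].sum() >= 0.99

    def test_excludes_nonconverged(self, fit_factory):
        good = fit_factory(("intercept", "d"), [0.0, 0.0], loglik=-100.0)
        bad = fit_factory(("intercept", "d", "t"), [0.0, 0.0, 0.0], loglik=-50.0)
        bad.converged = False
        avg = average_models([good, bad])
        assert len(avg.fits) == 1

    def test_json_round_trip(self, workflow, tmp_path):
        _, avg = workflow
        avg.to_json(tmp_path / "avg.json")
        from smoltsurv.averaging import AveragingResult

        back = AveragingResult.from_json(tmp_path / "avg.json")
        np.testing.assert_allclose(back.weights, avg.weights)
        assert back.in_set.tolist() == avg.in_set.tolist()
        assert len(back.fits) == len(avg.fits)
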