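import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popmarker import (
    LogNormalSpec,
    ParameterMatrix,
    PopulationSpec,
    SingleCellModel,
    lognormal_logscale,
    region_probability,
    sample_parameters,
)


def make_spec(name="p", value=4000.0, cv=0.4, kind="median"):
    return LogNormalSpec(name, value, cv, kind)


class TestLogscale:
    def test_point_mass(self):
        mu, sigma = lognormal_logscale(make_spec(cv=0.0))
        assert sigma == 0.0
        assert math.exp(mu) == pytest.approx(4000.0)

    def test_median_parameterization_closed_form(self):
        mu, sigma = lognormal_logscale(make_spec(value=4000.0, cv=0.4))
        assert sigma == pytest.approx(math.sqrt(math.log(1.16)), abs=1e-12)
        assert sigma == pytest.approx(0.38525, abs=1e-5)
        assert mu == pytest.approx(math.log(4000.0), abs=1e-12)
        assert mu == pytest.approx(8.29405, abs=1e-5)

    def test_mean_parameterization_recovers_mean(self):
        spec = make_spec(value=507.0, cv=0.4, kind="mean")
        mu, sigma = spec.logscale
        assert mu == pytest.approx(math.log(507.0) - math.log(1.16) / 2, abs=1e-12)
        assert spec.mean == pytest.approx(507.0, rel=1e-12)
        # Monte-Carlo moment check at n = 1e6 within 3 standard errors
        rng = np.random.default_rng(42)
        n = 1_000_000
        draws = np.exp(mu + sigma * rng.standard_normal(n))
        se = draws.std() / math.sqrt(n)
        assert abs(draws.mean() - 507.0) < 3 * se

    @given(
        value=st.floats(1e-3, 1e6),
        cv=st.floats(0.0, 2.0),
        kind=st.sampled_from(["mean", "median"]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_parameterization_roundtrip(self, value, cv, kind):
        """Requested location and CV are reproduced exactly by (mu, sigma)."""
        spec = LogNormalSpec("p", value, cv, kind)
        mu, sigma = spec.logscale
        if kind == "median":
            assert math.exp(mu) == pytest.approx(value, rel=1e-9)
        else:
            assert math.exp(mu + sigma**2 / 2) == pytest.approx(value, rel=1e-9)
        if cv > 0:
            got_cv = math.sqrt(math.exp(sigma**2) - 1)
            assert got_cv == pytest.approx(cv, rel=1e-9)

    @pytest.mark.parametrize(
        "value,cv,kind",
        [(-1.0, 0.4, "median"), (0.0, 0.4, "mean"), (10.0, -0.1, "median")],
    )
    def test_validation(self, value, cv, kind):
        with pytest.raises(ValueError):
            LogNormalSpec("p", value, cv, kind)


class TestRegionProbability:
    def test_total_mass(self):
        assert region_probability(make_spec(), 0, np.inf) == pytest.approx(1.0)

    def test_median_splits_mass(self):
        assert region_probability(make_spec(), 4000.0, np.inf) == pytest.approx(0.5)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            region_probability(make_spec(), 10.0, 1.0)

    def test_point_mass_indicator(self):
        spec = make_spec(cv=0.0)
        assert region_probability(spec, 3999, 4001) == 1.0
        assert region_probability(spec, 1, 2) == 0.0

    def test_monte_carlo_frequency(self):
        spec = make_spec()
        p = region_probability(spec, 2000.0, 8000.0)
        rng = np.random.default_rng(7)
        n = 1_000_000
        mu, sigma = spec.logscale
        draws = np.exp(mu + sigma * rng.standard_normal(n))
        freq = ((draws > 2000.0) & (draws < 8000.0)).mean()
        se = math.sqrt(p * (1 - p) / n)
        assert abs(freq - p) < 3 * se

    def test_partition_sums_to_one(self):
        spec = make_spec()
        edges = [0, 1000, 2500, 4000, 7000, 20000, np.inf]
        total = sum(
            region_probability(spec, lo, hi) for lo, hi in zip(edges, edges[1:])
        )
        assert total == pytest.approx(1.0, abs=1e-12)


def two_param_model():
    return SingleCellModel(
        name="null",
        state_names=["x"],
        parameter_names=["a", "b"],
        rhs=lambda x, p: np.zeros(1),
        initial_map=lambda p: np.zeros(1),
    )


def make_pop(varying, fixed, n=10, seed=0, model=None):
    return PopulationSpec(
        model=model or two_param_model(),
        varying=varying,
        fixed=fixed,
        ensemble_size=n,
        seed=seed,
    )


class TestSampling:
    def test_empty_ensemble(self):
        pop = make_pop([make_spec("a"), make_spec("b")], {}, n=0)
        mat = sample_parameters(pop)
        assert mat.values.shape == (0, 2)
        assert mat.parameter_names == ["a", "b"]

    def test_seed_reproducibility(self):
        pop = make_pop([make_spec("a"), make_spec("b")], {}, n=50, seed=123)
        m1, m2 = sample_parameters(pop), sample_parameters(pop)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_column_major_stream_stability(self):
        """Appending a varying parameter leaves earlier columns unchanged."""
        model3 = SingleCellModel(
            name="null3",
            state_names=["x"],
            parameter_names=["a", "b", "c"],
            rhs=lambda x, p: np.zeros(1),
            initial_map=lambda p: np.zeros(1),
        )
        pop2 = make_pop([make_spec("a"), make_spec("b")], {}, n=40, seed=9)
        pop3 = make_pop(
            [make_spec("a"), make_spec("b"), make_spec("c")], {}, n=40, seed=9,
            model=model3,
        )
        m2, m3 = sample_parameters(pop2), sample_parameters(pop3)
        np.testing.assert_array_equal(m2.values, m3.values[:, :2])

    def test_moment_recovery(self):
        pop = make_pop([make_spec("a", 4000, 0.4), make_spec("b", 81.9, 0.4, "mean")],
                       {}, n=100_000, seed=5)
        mat = sample_parameters(pop)
        for j in range(2):
            col = mat.values[:, j]
            assert col.std() / col.mean() == pytest.approx(0.4, rel=0.01)
        assert np.median(mat.values[:, 0]) == pytest.approx(4000, rel=0.01)
        assert mat.values[:, 1].mean() == pytest.approx(81.9, rel=0.01)

    def test_strictly_positive(self):
        pop = make_pop([make_spec("a", 1e-6, 2.0), make_spec("b")], {}, n=1000)
        assert np.all(sample_parameters(pop).values > 0)

    def test_coverage_validation(self):
        with pytest.raises(ValueError, match="cover"):
            make_pop([make_spec("a")], {})
        with pytest.raises(ValueError, match="cover"):
            make_pop([make_spec("a")], {"b": 1.0, "z": 2.0})
        with pytest.raises(ValueError, match="both varying and fixed"):
            make_pop([make_spec("a"), make_spec("b")], {"a": 1.0})

    def test_full_matrix_merges_fixed(self):
        pop = make_pop([make_spec("b")], {"a": 3.14}, n=5)
        sampled = sample_parameters(pop)
        full = pop.full_matrix(sampled)
        assert full.shape == (5, 2)
        np.testing.assert_array_equal(full[:, 0], 3.14)
        np.testing.assert_array_equal(full[:, 1], sampled.values[:, 0])


class TestParameterMatrixIO:
    def test_csv_roundtrip(self, tmp_path):
        mat = ParameterMatrix(
            np.abs(np.random.default_rng(0).lognormal(size=(7, 3))),
            ["α", "beta", "k-8"],
            seed=11,
        )
        path = tmp_path / "params.csv"
        mat.to_csv(path)
        back = ParameterMatrix.from_csv(path)
        assert back.parameter_names == mat.parameter_names
        assert back.seed == 11
        np.testing.assert_allclose(back.values, mat.values, rtol=1e-12)

    def test_npz_roundtrip(self, tmp_path):
        mat = ParameterMatrix(np.ones((2, 2)), ["a", "b"], seed=3)
        path = tmp_path / "params.npz"
        mat.to_npz(path)
        back = ParameterMatrix.from_npz(path)
        assert back.seed == 3
        np.testing.assert_array_equal(back.values, mat.values)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ParameterMatrix(np.array([[1.0, -2.0]]), ["a", "b"])
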