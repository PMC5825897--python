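"""Feature construction: filtering, correlation, Fisher-z, vectorization."""

import numpy as np
import pytest
from scipy import signal

from connclass import (
    ConnectivityMatrix,
    DirectedCouplingSet,
    FeatureVector,
    Network,
    ROITimeSeriesSet,
    correlation_matrix,
    fisher_z,
    model_space_size,
    normalize_subject_vector,
    preprocess_timeseries,
    unvectorize_fc,
    vectorize_coupling,
    vectorize_fc,
)
from connclass.errors import (
    ConfigurationError,
    DegenerateInputError,
    IntegrityError,
    ShapeError,
)


def _ts(series, tr=2.0, names=None):
    series = np.asarray(series, dtype=float)
    names = names or [f"R{i}" for i in range(series.shape[1])]
    return ROITimeSeriesSet("s1", "HC", series, names, tr)


def _band_power(x, freq, tr):
    f, p = signal.periodogram(x, fs=1.0 / tr)
    return p[np.argmin(np.abs(f - freq))]


class TestPreprocess:
    def test_out_of_band_sinusoid_suppressed(self):
        t = np.arange(1000) * 2.0
        slow = np.sin(2 * np.pi * 0.005 * t)
        ts = _ts(np.column_stack([slow, np.random.default_rng(0).normal(size=1000)]))
        out = preprocess_timeseries(ts, 0.01, 0.08)
        assert _band_power(out.series[:, 0], 0.005, 2.0) <= 0.1 * _band_power(
            slow, 0.005, 2.0
        )

    def test_in_band_sinusoid_retained(self):
        t = np.arange(1000) * 2.0
        mid = np.sin(2 * np.pi * 0.04 * t)
        ts = _ts(np.column_stack([mid, np.cos(2 * np.pi * 0.04 * t)]))
        out = preprocess_timeseries(ts, 0.01, 0.08)
        # amplitude loss <= 20% -> power loss <= 36%
        assert _band_power(out.series[:, 0], 0.04, 2.0) >= 0.64 * _band_power(
            mid, 0.04, 2.0
        )

    def test_confound_equal_to_region_zeroes_it(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 3))
        ts = _ts(x)
        detrended = signal.detrend(x, axis=0)
        out_no_filter_proxy = preprocess_timeseries(ts, 0.01, 0.08, confounds=detrended[:, [0]])
        # region 0's variance collapses relative to the unregressed version
        baseline = preprocess_timeseries(ts, 0.01, 0.08)
        assert out_no_filter_proxy.series[:, 0].std() < 1e-8 * baseline.series[:, 0].std()

    def test_band_outside_nyquist_rejected(self):
        ts = _ts(np.random.default_rng(0).normal(size=(50, 2)))
        with pytest.raises(ConfigurationError):
            preprocess_timeseries(ts, 0.01, 0.3)  # Nyquist at tr=2 is 0.25

    def test_confound_row_mismatch_rejected(self):
        ts = _ts(np.random.default_rng(0).normal(size=(50, 2)))
        with pytest.raises(ShapeError):
            preprocess_timeseries(ts, 0.01, 0.08, confounds=np.ones((49, 1)))


class TestCorrelation:
    def test_duplicate_and_negated_regions(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=100)
        c = correlation_matrix(_ts(np.column_stack([a, a, -a])))
        assert c.values[0, 1] == pytest.approx(1.0)
        assert c.values[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(c.values), 1.0)

    def test_matches_direct_covariance_formula(self):
        x = np.array(
            [
                [1.0, 2.0, 0.5], [2.0, 1.5, 0.1], [3.0, 3.5, 0.7], [4.0, 3.0, 0.2],
                [5.0, 5.0, 0.9], [6.0, 4.5, 0.3], [7.0, 7.5, 0.8], [8.0, 6.0, 0.4],
            ]
        )
        c = correlation_matrix(_ts(x))
        for i in range(3):
            for j in range(3):
                xi, xj = x[:, i] - x[:, i].mean(), x[:, j] - x[:, j].mean()
                expect = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert c.values[i, j] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_region_named_in_error(self):
        x = np.random.default_rng(0).normal(size=(20, 3))
        x[:, 1] = 7.0
        with pytest.raises(DegenerateInputError, match="R1"):
            correlation_matrix(_ts(x))

    def test_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(60, 4))
        c1 = correlation_matrix(_ts(x))
        c2 = correlation_matrix(_ts(x * [2.0, 0.5, 10.0, 3.0] + [1, -4, 0, 2]))
        assert np.allclose(c1.values, c2.values, atol=1e-12)


class TestFisherZ:
    def test_known_values_and_clamp(self):
        r = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 1.0], [0.5, 1.0, 1.0]])
        c = ConnectivityMatrix(r, "pearson_r", ["a", "b", "c"])
        z = fisher_z(c, clamp_epsilon=1e-7)
        assert z.scale == "fisher_z"
        assert z.values[0, 1] == 0.0
        assert z.values[0, 2] == pytest.approx(np.arctanh(0.5))
        assert np.isfinite(z.values[1, 2])
        assert z.values[1, 2] == pytest.approx(np.arctanh(1 - 1e-7))
        assert np.all(np.diag(z.values) == 0.0)

    def test_odd_and_monotone(self):
        rs = np.linspace(-0.95, 0.95, 21)
        m = np.eye(2)
        zs = []
        for r in rs:
            m = np.array([[1, r], [r, 1.0]])
            zs.append(fisher_z(ConnectivityMatrix(m, "pearson_r", ["a", "b"])).values[0, 1])
        zs = np.array(zs)
        assert np.all(np.diff(zs) > 0)
        assert np.allclose(zs, -zs[::-1], atol=1e-12)

    def test_wrong_scale_rejected(self):
        z = ConnectivityMatrix(np.zeros((2, 2)), "fisher_z", ["a", "b"])
        with pytest.raises(ConfigurationError):
            fisher_z(z)


class TestVectorize:
    @pytest.mark.parametrize("n_regions,expected", [(2, 1), (15, 105), (116, 6670), (272, 36856)])
    def test_upper_triangle_length(self, n_regions, expected):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(n_regions, n_regions))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        c = ConnectivityMatrix(m, "fisher_z", [f"R{i}" for i in range(n_regions)])
        vec = vectorize_fc(c)
        assert vec.values.size == expected

    def test_round_trip_identity(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=(6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        names = list("abcdef")
        c = ConnectivityMatrix(m, "fisher_z", names)
        back = unvectorize_fc(vectorize_fc(c), names)
        assert np.allclose(back.values, m, atol=1e-15)

    def test_canonical_names_and_order(self):
        m = np.array([[0, 1.0, 2.0], [1.0, 0, 3.0], [2.0, 3.0, 0]])
        c = ConnectivityMatrix(m, "fisher_z", ["A", "B", "C"])
        vec = vectorize_fc(c)
        assert vec.feature_names == ["A--B", "A--C", "B--C"]
        assert list(vec.values) == [1.0, 2.0, 3.0]

    def test_permuted_regions_same_name_value_map(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(80, 4))
        names = ["n1", "n2", "n3", "n4"]
        v1 = vectorize_fc(fisher_z(correlation_matrix(_ts(x, names=names))))
        perm = [2, 0, 3, 1]
        v2 = vectorize_fc(
            fisher_z(correlation_matrix(_ts(x[:, perm], names=[names[i] for i in perm])))
        )
        d1 = dict(zip(v1.feature_names, v1.values))
        d2 = dict(zip(v2.feature_names, v2.values))
        for key, val in d1.items():
            a, b = key.split("--")
            other = d2.get(key, d2.get(f"{b}--{a}"))
            assert other == pytest.approx(val, abs=1e-12)

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(IntegrityError):
            ConnectivityMatrix(m, "fisher_z", ["a", "b"])


class TestNormalize:
    def test_mean_zero_unit_variance(self):
        v = normalize_subject_vector(FeatureVector(np.array([1.0, 2, 3]), ["a", "b", "c"]))
        assert v.values.mean() == pytest.approx(0.0, abs=1e-15)
        assert v.values.std() == pytest.approx(1.0, abs=1e-15)

    def test_idempotent_and_affine_invariant(self):
        rng = np.random.default_rng(7)
        raw = rng.normal(size=30)
        names = [f"f{i}" for i in range(30)]
        v = normalize_subject_vector(FeatureVector(raw, names))
        again = normalize_subject_vector(v)
        assert np.allclose(v.values, again.values, atol=1e-12)
        scaled = normalize_subject_vector(FeatureVector(3.5 * raw - 2.0, names))
        assert np.allclose(v.values, scaled.values, atol=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_subject_vector(FeatureVector(np.ones(5), list("abcde")))


class TestCouplingVectorization:
    def test_two_node_layout_order(self):
        net = Network("N", ["a", "b"], np.array([[1.0, 2.0], [3.0, 4.0]]))
        vec = vectorize_coupling(DirectedCouplingSet("s", [net]))
        assert vec.feature_names == ["N:a->a", "N:a->b", "N:b->a", "N:b->b"]
        assert list(vec.values) == [1.0, 2.0, 3.0, 4.0]

    def test_total_length_is_sum_of_squares(self):
        nets = [
            Network(f"N{i}", [f"N{i}_n{j}" for j in range(s)], np.zeros((s, s)))
            for i, s in enumerate([4, 4, 4, 3])
        ]
        assert vectorize_coupling(DirectedCouplingSet("s", nets)).values.size == 57


class TestModelSpace:
    @pytest.mark.parametrize("n_params,expected", [(16, 256), (20, 256), (9, 512), (1, 2)])
    def test_greedy_cap_rule(self, n_params, expected):
        assert model_space_size(n_params) == expected

    def test_requires_at_least_one_parameter(self):
        with pytest.raises(ConfigurationError):
            model_space_size(0)
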