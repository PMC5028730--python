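"""Fourier features, record aggregation, z-scores and PCA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitmood.errors import (
    ConfigError,
    MissingOrientationError,
    TooShortError,
    ValidationError,
)
from gaitmood.features import (
    FEATURE_NAMES_168,
    SegmentFeatures,
    aggregate_record,
    main_frequency_and_phase,
    pca_apply,
    pca_fit,
    records_to_table,
    segment_features,
    zscore_apply,
    zscore_fit,
)
from gaitmood.preprocess import Segment
from gaitmood.skeleton_io import FeatureTable


def dft_oracle(signal, frame_rate):
    """Main frequency/phase straight from the DFT definition (O(N^2))."""
    x = np.asarray(signal, float)
    n = len(x)
    best_k, best_mag, best_phase = 0, 0.0, 0.0
    for k in range(1, n // 2 + 1):
        coeff = sum(
            x[m] * np.exp(-2j * np.pi * k * m / n) for m in range(n)
        )
        if abs(coeff) > best_mag + 1e-12:
            best_k, best_mag, best_phase = k, abs(coeff), np.angle(coeff)
    if best_mag < 1e-9:
        return 0.0, 0.0
    return best_k * frame_rate / n, best_phase


def make_segment(values, orientation="front"):
    values = np.asarray(values, float)
    return Segment(start=0, stop=values.shape[0], orientation=orientation, values=values)


class TestMainFrequencyAndPhase:
    def test_pure_sinusoid_exact_bin(self):
        t = np.arange(60) / 30.0
        freq, phase = main_frequency_and_phase(np.sin(2 * np.pi * 1.0 * t), 30.0)
        assert freq == pytest.approx(1.0)
        assert phase == pytest.approx(-np.pi / 2, abs=1e-9)

    def test_constant_and_zero_conventions(self):
        assert main_frequency_and_phase(np.zeros(50), 30.0) == (0.0, 0.0)
        assert main_frequency_and_phase(np.full(50, 3.3), 30.0) == (0.0, 0.0)

    def test_dominant_component_wins(self):
        t = np.arange(90) / 30.0
        x = 2.0 * np.sin(2 * np.pi * 1.0 * t) + 1.0 * np.sin(2 * np.pi * 3.0 * t)
        freq, _ = main_frequency_and_phase(x, 30.0)
        assert freq == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [16, 33, 64, 127, 256])
    def test_matches_definition_oracle(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        got = main_frequency_and_phase(x, 30.0)
        want = dft_oracle(x, 30.0)
        assert got[0] == pytest.approx(want[0], abs=1e-9)
        assert got[1] == pytest.approx(want[1], abs=1e-6)

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=80)
        f1, p1 = main_frequency_and_phase(x, 30.0)
        f2, p2 = main_frequency_and_phase(5.0 * x, 30.0)
        assert (f1, p1) == pytest.approx((f2, p2))

    def test_frequency_within_range(self):
        rng = np.random.default_rng(11)
        for n in (40, 41, 100):
            f, p = main_frequency_and_phase(rng.normal(size=n), 30.0)
            assert 0 <= f <= 15.0
            assert -np.pi < p <= np.pi

    def test_too_short_rejected(self):
        with pytest.raises(TooShortError):
            main_frequency_and_phase(np.array([1.0]), 30.0)

    def test_unknown_window_rejected(self):
        with pytest.raises(ConfigError):
            main_frequency_and_phase(np.arange(10.0), 30.0, window="flat-top")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.integers(0, 2**32 - 1),
        st.floats(0.5, 10.0),
        st.integers(48, 200),
    )
    def test_sinusoid_recovered_within_one_bin(self, seed, f_true, n):
        rng = np.random.default_rng(seed)
        phase0 = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / 30.0
        x = np.sin(2 * np.pi * f_true * t + phase0)
        freq, _ = main_frequency_and_phase(x, 30.0)
        assert abs(freq - f_true) <= 30.0 / n + 1e-9


class TestSegmentFeatures:
    def test_yields_42_freqs_and_42_phases(self, rng):
        seg = make_segment(rng.normal(size=(48, 42)))
        sf = segment_features(seg, 30.0)
        assert sf.main_freqs.shape == (42,)
        assert sf.phases.shape == (42,)
        assert sf.orientation == "front"

    def test_zero_columns_give_zero_features(self, rng):
        values = rng.normal(size=(48, 42))
        values[:, 0:3] = 0.0  # SpineBase columns after body-frame transform
        sf = segment_features(make_segment(values), 30.0)
        assert np.all(sf.main_freqs[:3] == 0.0)
        assert np.all(sf.phases[:3] == 0.0)

    def test_deterministic(self, rng):
        values = rng.normal(size=(50, 42))
        a = segment_features(make_segment(values), 30.0)
        b = segment_features(make_segment(values.copy()), 30.0)
        np.testing.assert_array_equal(a.main_freqs, b.main_freqs)
        np.testing.assert_array_equal(a.phases, b.phases)


class TestAggregateRecord:
    def _sf(self, rng, orientation):
        return SegmentFeatures(
            main_freqs=rng.uniform(0, 5, 42),
            phases=rng.uniform(-np.pi, np.pi, 42),
            orientation=orientation,
        )

    def test_one_front_one_back_is_concatenation(self, rng):
        front, back = self._sf(rng, "front"), self._sf(rng, "back")
        fv = aggregate_record([front, back])
        np.testing.assert_allclose(
            fv.values,
            np.concatenate([front.main_freqs, front.phases, back.main_freqs, back.phases]),
        )
        assert fv.values.shape == (168,)
        assert (fv.n_front, fv.n_back) == (1, 1)

    def test_mean_is_idempotent_on_duplicates(self, rng):
        front, back = self._sf(rng, "front"), self._sf(rng, "back")
        once = aggregate_record([front, back])
        twice = aggregate_record([front, front, back])
        np.testing.assert_allclose(once.values, twice.values)

    def test_averages_within_orientation(self, rng):
        f1, f2, back = self._sf(rng, "front"), self._sf(rng, "front"), self._sf(rng, "back")
        fv = aggregate_record([f1, f2, back])
        np.testing.assert_allclose(
            fv.values[:42], (f1.main_freqs + f2.main_freqs) / 2
        )

    def test_missing_orientation_names_record(self, rng):
        with pytest.raises(MissingOrientationError, match="rec9"):
            aggregate_record([self._sf(rng, "front")], provenance="rec9")

    def test_circular_phase_mean_wraps(self):
        near_pi = SegmentFeatures(
            main_freqs=np.zeros(42),
            phases=np.full(42, np.pi - 0.01),
            orientation="front",
        )
        near_minus_pi = SegmentFeatures(
            main_freqs=np.zeros(42),
            phases=np.full(42, -np.pi + 0.01),
            orientation="front",
        )
        back = SegmentFeatures(
            main_freqs=np.zeros(42), phases=np.zeros(42), orientation="back"
        )
        fv = aggregate_record(
            [near_pi, near_minus_pi, back], phase_mean="circular"
        )
        # angles cluster at +/-pi; circular mean stays there, the
        # arithmetic mean would sit at 0
        assert np.all(np.abs(np.abs(fv.values[42:84]) - np.pi) < 0.02)


class TestZScore:
    def _table(self, values):
        values = np.asarray(values, float)
        n, d = values.shape
        return FeatureTable(
            instance_ids=[(f"S{i}", "c", "K1") for i in range(n)],
            values=values,
            feature_names=[f"f{j}" for j in range(d)],
            labels=["c"] * n,
        )

    def test_two_point_column_symmetric(self):
        table = self._table([[1.0], [3.0]])
        means, sds = zscore_fit(table)
        out = zscore_apply(table, means, sds)
        assert out.values[0, 0] == -out.values[1, 0]
        assert out.values[1, 0] > 0
        assert out.values.mean() == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_maps_to_zero(self):
        table = self._table([[2.0, 1.0], [2.0, 5.0], [2.0, 6.0]])
        means, sds = zscore_fit(table)
        out = zscore_apply(table, means, sds)
        assert np.all(out.values[:, 0] == 0.0)

    def test_fit_then_apply_standardizes(self, rng):
        table = self._table(rng.normal(2.0, 3.0, size=(20, 7)))
        means, sds = zscore_fit(table)
        out = zscore_apply(table, means, sds)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.values.std(axis=0), 1.0, atol=1e-9)

    def test_fit_needs_two_instances(self):
        with pytest.raises(ValidationError):
            zscore_fit(self._table(np.ones((1, 3))))


class TestPCA:
    def _table(self, values):
        n, d = values.shape
        return FeatureTable(
            instance_ids=[(f"S{i}", "c", "K1") for i in range(n)],
            values=values,
            feature_names=[f"f{j}" for j in range(d)],
            labels=["c"] * n,
        )

    def test_rank_one_data_keeps_one_component(self, rng):
        direction = rng.normal(size=6)
        coeffs = rng.normal(size=(15, 1))
        values = coeffs * direction + rng.normal(0, 1e-8, size=(15, 6))
        model = pca_fit(self._table(values), variance_threshold=0.95)
        assert model.n_components == 1

    def test_threshold_one_reconstructs(self, rng):
        values = rng.normal(size=(12, 5))
        table = self._table(values)
        model = pca_fit(table, variance_threshold=1.0)
        projected = pca_apply(table, model)
        rebuilt = projected.values @ model.components + model.mean
        np.testing.assert_allclose(rebuilt, values, atol=1e-10)

    def test_matches_covariance_eigendecomposition(self, rng):
        values = rng.normal(size=(20, 8))
        model = pca_fit(self._table(values), variance_threshold=1.0)
        cov = np.cov(values, rowvar=False, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        ratios = eigvals / eigvals.sum()
        np.testing.assert_allclose(
            model.explained_variance_ratio, ratios[: model.n_components], atol=1e-10
        )
        # component subspace agreement: projection matrices coincide
        _, eigvecs = np.linalg.eigh(cov)
        top = eigvecs[:, ::-1][:, : model.n_components]
        np.testing.assert_allclose(
            model.components.T @ model.components, top @ top.T, atol=1e-8
        )

    def test_components_orthonormal_ratios_non_increasing(self, rng):
        values = rng.normal(size=(25, 10))
        model = pca_fit(self._table(values), variance_threshold=0.9)
        k = model.n_components
        np.testing.assert_allclose(
            model.components @ model.components.T, np.eye(k), atol=1e-10
        )
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)
        assert model.explained_variance_ratio.sum() <= 1 + 1e-9

    def test_reconstruction_error_bounded_by_discarded_variance(self, rng):
        values = rng.normal(size=(30, 12))
        table = self._table(values)
        model = pca_fit(table, variance_threshold=0.8)
        rebuilt = pca_apply(table, model).values @ model.components + model.mean
        cov = np.cov(values, rowvar=False, ddof=1)
        discarded = np.sort(np.linalg.eigvalsh(cov))[::-1][model.n_components :].sum()
        mse = np.sum((values - rebuilt) ** 2) / (values.shape[0] - 1)
        assert mse <= discarded + 1e-8

    def test_bad_threshold_rejected(self, rng):
        table = self._table(rng.normal(size=(5, 3)))
        for bad in (0.0, 1.2, -0.5):
            with pytest.raises(ConfigError):
                pca_fit(table, variance_threshold=bad)


def test_feature_names_have_fixed_layout():
    assert len(FEATURE_NAMES_168) == 168
    assert FEATURE_NAMES_168[0] == "front_freq_SpineBase_x"
    assert FEATURE_NAMES_168[42] == "front_phase_SpineBase_x"
    assert FEATURE_NAMES_168[84] == "back_freq_SpineBase_x"
    assert FEATURE_NAMES_168[126] == "back_phase_SpineBase_x"
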