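"""Formula-defined features against brute-force loop oracles, wavelet
energy conservation, co-occurrence texture properties, and LDA."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from ecgwolf.features import (FeatureMatrix, GLCMSpec, WaveletSpec,
                              basic_stats, energy, extract_all, feature_names,
                              glcm_features, lda_reduce, wavelet_features)
from ecgwolf.preprocess import Segment

signals = arrays(np.float64, st.integers(16, 128),
                 elements=st.floats(-50, 50, allow_nan=False, width=64))


def _glcm_oracle(x, spec):
    """Nested-loop co-occurrence features, independent of the implementation."""
    x = np.asarray(x, float)
    lo, hi = x.min(), x.max()
    if hi > lo:
        q = np.minimum(((x - lo) / (hi - lo) * spec.levels).astype(int),
                       spec.levels - 1)
    else:
        q = np.zeros(x.size, int)
    counts = {}
    for t in range(len(q) - spec.lag):
        pair = (q[t], q[t + spec.lag])
        counts[pair] = counts.get(pair, 0) + 1
        if spec.symmetric:
            rev = (q[t + spec.lag], q[t])
            counts[rev] = counts.get(rev, 0) + 1
    total = sum(counts.values())
    P = {k: v / total for k, v in counts.items()}
    contrast = sum(p * (i - j) ** 2 for (i, j), p in P.items())
    energy_ = sum(p ** 2 for p in P.values())
    homogeneity = sum(p / (1 + (i - j) ** 2) for (i, j), p in P.items())
    mu_i = sum(i * p for (i, _), p in P.items())
    mu_j = sum(j * p for (_, j), p in P.items())
    sd_i = np.sqrt(sum((i - mu_i) ** 2 * p for (i, _), p in P.items()))
    sd_j = np.sqrt(sum((j - mu_j) ** 2 * p for (_, j), p in P.items()))
    if sd_i > 0 and sd_j > 0:
        corr = (sum(i * j * p for (i, j), p in P.items()) - mu_i * mu_j) \
               / (sd_i * sd_j)
    else:
        corr = float("nan")
    return {"contrast": contrast, "energy": energy_,
            "homogeneity": homogeneity, "correlation": corr}


class TestEnergy:
    def test_zeros_have_zero_energy(self):
        assert energy(np.zeros(10)) == 0.0

    def test_small_example(self):
        assert energy([1.0, -1.0, 2.0]) == 6.0

    def test_matches_explicit_loop_on_random_vectors(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(1, 60))
            oracle = sum(float(v) ** 2 for v in x)
            assert abs(energy(x) - oracle) <= 1e-12 * max(1.0, oracle)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            energy([])


class TestBasicStats:
    def test_three_point_example(self):
        st_ = basic_stats([1.0, 2.0, 3.0])
        assert st_["mean"] == 2.0
        assert np.isclose(st_["variance"], 2.0 / 3.0)
        assert st_["median"] == 2.0
        assert np.isclose(st_["rms"], np.sqrt(14.0 / 3.0))
        assert st_["max"] == 3.0 and st_["min"] == 1.0

    def test_constant_vector(self):
        st_ = basic_stats([-4.0] * 7)
        assert st_["variance"] == 0.0
        assert st_["rms"] == 4.0

    def test_matches_loop_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            x = rng.normal(size=int(rng.integers(1, 50)))
            n = x.size
            mu = sum(x) / n
            oracle = {
                "mean": mu,
                "variance": sum((v - mu) ** 2 for v in x) / n,
                "median": sorted(x)[n // 2] if n % 2 else
                          (sorted(x)[n // 2 - 1] + sorted(x)[n // 2]) / 2,
                "max": max(x), "min": min(x),
                "rms": (sum(v ** 2 for v in x) / n) ** 0.5,
            }
            got = basic_stats(x)
            for key, val in oracle.items():
                assert abs(got[key] - val) <= 1e-12 * max(1.0, abs(val)), key


class TestWaveletFeatures:
    def test_zero_segment_gives_zero_energies(self):
        feats = wavelet_features(np.zeros(64), WaveletSpec(levels=3))
        assert all(v == 0.0 for k, v in feats.items() if "energy" in k)

    @given(arrays(np.float64, st.integers(2, 16).map(lambda k: 8 * k),
                  elements=st.floats(-50, 50, allow_nan=False, width=64)))
    def test_orthogonal_energy_conservation(self, x):
        # the periodized DWT is orthogonal when 2^levels divides the length
        feats = wavelet_features(x, WaveletSpec("db4", 3))
        total = sum(v for k, v in feats.items() if k.endswith("energy"))
        assert abs(total - energy(x)) <= 1e-8 * max(1.0, energy(x))

    def test_one_level_haar_matches_convolution_oracle(self, rng):
        # Haar filter-and-downsample in closed form:
        #   a[k] = (x[2k] + x[2k+1]) / sqrt(2),  d[k] = (x[2k] - x[2k+1]) / sqrt(2)
        x = rng.normal(size=8)
        a = (x[0::2] + x[1::2]) / np.sqrt(2.0)
        d = (x[0::2] - x[1::2]) / np.sqrt(2.0)
        feats = wavelet_features(x, WaveletSpec("haar", 1))
        assert np.isclose(feats["wl_d1_energy"], np.sum(d ** 2), atol=1e-12)
        assert np.isclose(feats["wl_a1_energy"], np.sum(a ** 2), atol=1e-12)
        assert np.isclose(feats["wl_d1_var"], np.var(d), atol=1e-12)
        assert np.isclose(feats["wl_a1_var"], np.var(a), atol=1e-12)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            wavelet_features(np.zeros(8), WaveletSpec(levels=4))


class TestGLCMFeatures:
    def test_constant_segment_degenerate_values(self):
        feats = glcm_features(np.full(50, 2.7))
        assert feats["contrast"] == 0.0
        assert feats["energy"] == 1.0
        assert feats["homogeneity"] == 1.0
        assert np.isnan(feats["correlation"])

    def test_alternating_two_level_sequence(self):
        x = np.tile([0.0, 1.0], 25)
        feats = glcm_features(x, GLCMSpec(levels=2, lag=1, symmetric=True))
        assert np.isclose(feats["contrast"], 1.0)
        assert np.isclose(feats["energy"], 0.5)
        assert np.isclose(feats["homogeneity"], 0.5)
        assert np.isclose(feats["correlation"], -1.0)

    @pytest.mark.parametrize("spec", [
        GLCMSpec(levels=8, lag=1, symmetric=True),
        GLCMSpec(levels=4, lag=3, symmetric=False),
        GLCMSpec(levels=16, lag=2, symmetric=True),
    ])
    def test_matches_nested_loop_oracle(self, rng, spec):
        for _ in range(40):
            x = rng.normal(size=int(rng.integers(spec.lag + 1, 80)))
            got = glcm_features(x, spec)
            want = _glcm_oracle(x, spec)
            for key in ("contrast", "energy", "homogeneity"):
                assert abs(got[key] - want[key]) <= 1e-12
            if np.isnan(want["correlation"]):
                assert np.isnan(got["correlation"])
            else:
                assert abs(got["correlation"] - want["correlation"]) <= 1e-12

    @given(signals)
    def test_probability_and_range_invariants(self, x):
        got = glcm_features(x, GLCMSpec(levels=8, lag=1, symmetric=True))
        assert got["contrast"] >= 0.0
        assert 0.0 < got["energy"] <= 1.0
        assert 0.0 < got["homogeneity"] <= 1.0
        if not np.isnan(got["correlation"]):
            assert -1.0 - 1e-12 <= got["correlation"] <= 1.0 + 1e-12


class TestExtractAll:
    def test_column_count_from_registry(self, small_dataset):
        segments, _ = small_dataset
        fm = extract_all(segments[:10], WaveletSpec("db4", 4), GLCMSpec())
        # 1 energy + 6 stats + 2*(4 details + 1 approx) + 4 texture = 21
        assert fm.n_features == 21
        assert fm.feature_names == feature_names(WaveletSpec("db4", 4),
                                                 GLCMSpec())

    def test_duplicate_segments_give_identical_rows(self, small_dataset):
        segments, _ = small_dataset
        fm = extract_all([segments[0], segments[0]])
        assert np.array_equal(fm.values[0], fm.values[1])

    def test_column_names_unique_and_stable(self, small_dataset):
        segments, _ = small_dataset
        a = extract_all(segments[:5]).feature_names
        b = extract_all(segments[5:10]).feature_names
        assert a == b
        assert len(set(a)) == len(a)

    def test_constant_segment_dropped_with_count(self, small_dataset, caplog):
        segments, _ = small_dataset
        flat = Segment(np.zeros(segments[0].samples.size), 360.0, label=1)
        with caplog.at_level("WARNING"):
            fm = extract_all([segments[0], flat])
        assert fm.values.shape[0] == 1
        assert "dropped 1" in caplog.text

    def test_unlabeled_segment_rejected(self, small_dataset):
        segments, _ = small_dataset
        bad = Segment(segments[0].samples, 360.0, label=None)
        with pytest.raises(ValueError):
            extract_all([bad])


class TestLDAReduce:
    def _two_class_matrix(self, rng):
        n = 60
        X = rng.normal(size=(2 * n, 5))
        X[:n, 2] += 8.0  # single informative feature
        y = np.array([1] * n + [2] * n)
        return FeatureMatrix(X, [f"f{i}" for i in range(5)], y)

    def test_projection_separates_two_classes(self, rng):
        fm = self._two_class_matrix(rng)
        red = lda_reduce(fm, 1)
        a = red.values[red.labels == 1, 0]
        b = red.values[red.labels == 2, 0]
        assert a.max() < b.min() or b.max() < a.min()
        assert red.feature_names == ["LD1"]

    def test_component_bound_enforced(self, small_features):
        with pytest.raises(ValueError):
            lda_reduce(small_features, 5)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(30, 4))
        fm = FeatureMatrix(X, [f"f{i}" for i in range(4)], np.ones(30, int))
        with pytest.raises(ValueError):
            lda_reduce(fm)

    def test_matches_sklearn_eigen_solver_directions(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        X = rng.normal(size=(200, 6))
        y = rng.integers(1, 5, size=200)
        for c in np.unique(y):
            X[y == c] += rng.normal(scale=2.0, size=6)
        fm = FeatureMatrix(X, [f"f{i}" for i in range(6)], y)
        mine = lda_reduce(fm, 3).values
        other = LinearDiscriminantAnalysis(solver="eigen").fit(X, y)
        theirs = X @ other.scalings_[:, :3]
        # same discriminant directions up to per-component sign and scale
        for k in range(3):
            r = np.corrcoef(mine[:, k], theirs[:, k])[0, 1]
            assert abs(abs(r) - 1.0) < 1e-6
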