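"""Waveform feature extractors: matching pursuit, permutation entropy,
slope chain code, plot rasterization + SIFT descriptor, raw control."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pywt

from p300wave.features import (
    FeatureConfig,
    MPDictionary,
    PEConfig,
    SHCCConfig,
    SIFTConfig,
    build_mp1_dictionary,
    build_mp2_dictionary,
    extract_feature,
    mp1_score,
    mp2_feature,
    mp_decompose,
    ordinal_pattern,
    pe_feature,
    permutation_entropy,
    raw_feature,
    render_plot,
    shcc_feature,
    shcc_resample,
    sift_descriptor,
)

# ---------------------------------------------------------------- matching pursuit


class TestMPDictionaries:
    def test_mp1_one_atom_per_template(self):
        rng = np.random.default_rng(0)
        templates = [rng.standard_normal(16) for _ in range(30)]
        d = build_mp1_dictionary(templates)
        assert d.size == 30
        np.testing.assert_allclose(np.linalg.norm(d.atoms, axis=1), 1.0, atol=1e-12)

    def test_mp1_atom_keeps_template_direction(self):
        t = np.sin(np.arange(16.0))
        d = build_mp1_dictionary([t])
        assert d.atoms[0] @ t == pytest.approx(np.linalg.norm(t))

    def test_zero_norm_template_rejected(self):
        with pytest.raises(ValueError):
            build_mp1_dictionary([np.zeros(16)])

    def test_mp2_atoms_unit_norm_and_supported_inside(self):
        d = build_mp2_dictionary(16)
        np.testing.assert_allclose(np.linalg.norm(d.atoms, axis=1), 1.0, atol=1e-12)
        assert d.atoms.shape[1] == 16          # no wrap-around past the segment

    def test_mp2_size_matches_translation_count(self):
        # independent count: dyadic translations of each atom support
        N = 16
        expected = 0
        level = 1
        supports = []
        while True:
            L = len(pywt.upcoef("d", [1.0], "sym2", level=level))
            if L > N:
                break
            supports.append((level, L))
            level += 1
        top = supports[-1][0]
        La = len(pywt.upcoef("a", [1.0], "sym2", level=top))
        if La <= N:
            supports.append((top, La))
        for lvl, L in supports:
            expected += (N - L) // (2**lvl) + 1
        assert build_mp2_dictionary(N).size == expected

    def test_segment_shorter_than_atom_rejected(self):
        with pytest.raises(ValueError):
            build_mp2_dictionary(2)


class TestMPDecomposition:
    def test_exact_match_atom_selected_first(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(16)
        atoms = np.vstack([rng.standard_normal((5, 16)), x / np.linalg.norm(x)])
        res = mp_decompose(x, MPDictionary(atoms=atoms, source="signal_templates"), m_atoms=1)
        assert res.selected_indices[0] == 5
        assert res.weights[0] == pytest.approx(np.linalg.norm(x))
        assert res.epsilon == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_energy_conservation(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(32)
        d = MPDictionary(atoms=rng.standard_normal((12, 32)), source="signal_templates")
        res = mp_decompose(x, d, m_atoms=6)
        lhs = np.sum(x**2)
        rhs = np.sum(res.weights**2) + res.epsilon**2
        assert abs(lhs - rhs) / lhs < 1e-8

    def test_orthonormal_dictionary_selects_top_coefficients(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(10)
        d = MPDictionary(atoms=np.eye(10), source="signal_templates")
        res = mp_decompose(x, d, m_atoms=4)
        expected = list(np.argsort(-np.abs(x))[:4])
        assert res.selected_indices == expected
        np.testing.assert_allclose(res.weights, x[expected])

    def test_residual_monotone_in_iterations(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(16)
        d = MPDictionary(atoms=rng.standard_normal((8, 16)), source="signal_templates")
        eps = [mp_decompose(x, d, m_atoms=m).epsilon for m in range(1, 6)]
        assert all(a >= b - 1e-12 for a, b in zip(eps, eps[1:]))

    def test_empty_dictionary_rejected(self):
        with pytest.raises(Exception):
            MPDictionary(atoms=np.empty((0, 16)), source="signal_templates")

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_energy_conservation_property(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(12)
        d = MPDictionary(atoms=rng.standard_normal((6, 12)), source="signal_templates")
        res = mp_decompose(x, d, m_atoms=4)
        assert np.sum(x**2) == pytest.approx(np.sum(res.weights**2) + res.epsilon**2, rel=1e-8)


class TestMP1Score:
    def test_signal_in_atom_span_scores_zero(self):
        atom = np.cos(np.arange(16.0))
        d = build_mp1_dictionary([atom])
        assert mp1_score(3.5 * atom, d) == pytest.approx(0.0, abs=1e-10)

    def test_score_non_increasing_in_atoms(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(16)
        d = build_mp1_dictionary([rng.standard_normal(16) for _ in range(10)])
        scores = [mp1_score(x, d, m_atoms=m) for m in range(1, 6)]
        assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_orthogonal_signal_keeps_full_norm(self):
        atoms = np.zeros((3, 16))
        atoms[:, :3] = np.eye(3)
        x = np.zeros(16)
        x[8:] = np.arange(8.0)
        assert mp1_score(x, MPDictionary(atoms=atoms, source="signal_templates")) == (
            pytest.approx(np.linalg.norm(x))
        )


class TestMP2Feature:
    def test_zero_signal_gives_zero_vector(self):
        d = build_mp2_dictionary(16)
        f = mp2_feature(np.zeros(16), d)
        assert f.shape == (d.size,)
        assert not f.any()

    def test_sparsity_and_fixed_length(self):
        rng = np.random.default_rng(7)
        d = build_mp2_dictionary(16)
        for m in (1, 3, 5):
            f = mp2_feature(rng.standard_normal(16), d, m_atoms=m)
            assert f.shape == (d.size,)
            assert np.count_nonzero(f) <= m


# ---------------------------------------------------------------- permutation entropy


def _brute_force_patterns(x, m, tau):
    """Independent pattern counter: descending ranks, earlier-index ties."""
    pats = []
    for s in range(len(x) - (m - 1) * tau):
        w = [x[s + j * tau] for j in range(m)]
        order = sorted(range(m), key=lambda i: (-w[i], i))
        rank = [0] * m
        for r, i in enumerate(order):
            rank[i] = r + 1
        pats.append(tuple(rank))
    return Counter(pats)


def _brute_force_entropy(x, m, tau):
    c = _brute_force_patterns(x, m, tau)
    k = sum(c.values())
    return -sum((n / k) * math.log(n / k) for n in c.values())


class TestOrdinalPatterns:
    def test_documented_examples(self):
        assert ordinal_pattern([3.0, 1.0, 2.0]) == (1, 3, 2)
        assert ordinal_pattern([1.0, 2.0, 3.0]) == (3, 2, 1)

    @pytest.mark.parametrize("m", [3, 4])
    def test_always_a_permutation(self, m):
        for values in itertools.permutations(range(m)):
            assert sorted(ordinal_pattern(np.array(values, float))) == list(range(1, m + 1))

    def test_ties_resolved_to_earlier_index(self):
        assert ordinal_pattern([1.0, 1.0, 0.0]) == (1, 2, 3)


class TestPermutationEntropy:
    def test_monotone_ramp_has_zero_entropy(self):
        assert permutation_entropy(np.arange(10.0), PEConfig(W=10)) == 0.0

    def test_uniform_patterns_reach_log_m_factorial(self):
        # alternating series: the two order-2 patterns occur equally often
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        h = permutation_entropy(x, PEConfig(W=5, m=2, tau=1))
        assert h == pytest.approx(math.log(2))

    def test_frozen_twelve_sample_series(self):
        x = np.array([4, 7, 9, 10, 6, 11, 3, 5, 8, 1, 2, 12], dtype=float)
        h = permutation_entropy(x, PEConfig(W=12, m=3, tau=1))
        assert h == pytest.approx(1.2798542258336676, abs=1e-12)
        assert h == pytest.approx(_brute_force_entropy(list(x), 3, 1), abs=1e-12)

    def test_exhaustive_agreement_with_brute_force(self):
        """All length-8 ternary signals: oracle agreement and entropy bounds."""
        cfg = PEConfig(W=8, m=3, tau=1)
        upper = math.log(math.factorial(3))
        for digits in itertools.product((0.0, 1.0, 2.0), repeat=8):
            h = permutation_entropy(np.array(digits), cfg)
            assert h == pytest.approx(_brute_force_entropy(list(digits), 3, 1), abs=1e-10)
            assert 0.0 <= h <= upper + 1e-12

    def test_window_shorter_than_span_rejected(self):
        with pytest.raises(ValueError):
            PEConfig(W=3, m=3, tau=2)


class TestPEFeature:
    def test_length_formula(self):
        f = pe_feature(np.random.default_rng(0).standard_normal(16), PEConfig(W=8, m=3, tau=1))
        assert len(f) == 16 - (8 + 1 * (3 - 1))

    def test_monotone_signal_gives_zero_feature(self):
        f = pe_feature(np.arange(16.0), PEConfig(W=8))
        assert not f.any()

    def test_entries_match_per_window_calls(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(20)
        cfg = PEConfig(W=8, m=3, tau=2)
        f = pe_feature(x, cfg)
        for u, h in enumerate(f):
            assert h == permutation_entropy(x[u : u + cfg.W], cfg)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            pe_feature(np.arange(10.0), PEConfig(W=8, m=3, tau=1))


# ---------------------------------------------------------------- slope chain code


class TestSHCC:
    def test_resampled_ramp_stays_linear(self):
        x = 2.5 * np.arange(20.0) - 3.0
        grid, values = shcc_resample(x, SHCCConfig(G=19))
        np.testing.assert_allclose(values, 2.5 * grid - 3.0, atol=1e-9)

    def test_resample_length_contract(self):
        _, values = shcc_resample(np.random.default_rng(1).standard_normal(50), SHCCConfig(G=12))
        assert len(values) == 12

    def test_uniform_grid_oracle(self):
        grid, _ = shcc_resample(np.arange(10.0), SHCCConfig(G=4))
        np.testing.assert_allclose(grid, [0.0, 3.0, 6.0, 9.0])

    def test_ramp_encodes_unit_slopes(self):
        f = shcc_feature(np.arange(16.0), SHCCConfig(G=8))
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_feature_length_is_g_minus_one(self):
        f = shcc_feature(np.sin(np.arange(40.0) / 3), SHCCConfig(G=16))
        assert len(f) == 15

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        st.integers(0, 10_000),
        st.floats(0.05, 50.0),
        st.floats(-100.0, 100.0),
    )
    def test_invariant_to_amplitude_scale_and_offset(self, seed, a, b):
        x = np.random.default_rng(seed).standard_normal(24)
        cfg = SHCCConfig(G=10)
        np.testing.assert_allclose(shcc_feature(a * x + b, cfg), shcc_feature(x, cfg), atol=1e-8)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            shcc_feature(np.full(16, 2.0), SHCCConfig(G=8))

    def test_g_not_below_n_rejected(self):
        with pytest.raises(ValueError):
            shcc_resample(np.arange(8.0), SHCCConfig(G=8))


# ---------------------------------------------------------------- plot + SIFT


class TestPlotRendering:
    def test_width_is_delta_times_samples(self):
        img = render_plot(np.sin(np.arange(16.0)), delta=4)
        assert img.width == 64

    def test_pixels_are_binary(self):
        img = render_plot(np.random.default_rng(2).standard_normal(16))
        assert set(np.unique(img.pixels)) <= {0, 255}

    def test_trace_is_eight_connected(self):
        x = np.random.default_rng(3).standard_normal(16)
        img = render_plot(x, delta=4)
        xt = 4 * (x - x.mean()) / x.std()
        h = img.height
        z = img.zero_row
        rows = np.clip(np.round(xt + z).astype(int), 0, h - 1)
        cols = 4 * np.arange(16)
        from skimage.draw import line

        for i in range(15):
            rr, cc = line(rows[i], cols[i], rows[i + 1], cols[i + 1])
            assert np.all(img.pixels[rr, cc] == 255)
            steps = np.abs(np.diff(np.stack([rr, cc]), axis=1))
            assert steps.max() <= 1          # consecutive path pixels 8-adjacent

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            render_plot(np.full(16, 1.0))


class TestSIFTDescriptor:
    @pytest.fixture()
    def image(self):
        return render_plot(np.sin(np.arange(16.0) / 2.0) + 0.1 * np.arange(16.0), delta=4)

    def test_descriptor_length_128(self, image):
        assert sift_descriptor(image).shape == (4 * 4 * 8,)

    def test_unit_norm_or_zero(self, image):
        f = sift_descriptor(image)
        assert np.linalg.norm(f) == pytest.approx(1.0, abs=1e-12)

    def test_clamped_stage_bounded(self, image):
        clamped = sift_descriptor(image, stage="clamped")
        assert clamped.max() <= 0.2 + 1e-15

    def test_uniform_patch_gives_zero_vector(self):
        f = sift_descriptor(np.zeros((20, 20), dtype=np.uint8))
        assert not f.any()

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sift_descriptor(np.empty((0, 0)))


# ---------------------------------------------------------------- control + dispatch


class TestRawFeature:
    def test_zero_mean_unit_variance(self):
        f = raw_feature(np.random.default_rng(4).standard_normal(16) * 7 + 3)
        assert f.mean() == pytest.approx(0.0, abs=1e-9)
        assert f.var() == pytest.approx(1.0, abs=1e-9)
        assert len(f) == 16

    def test_invariant_to_offset_and_positive_scale(self):
        x = np.random.default_rng(5).standard_normal(16)
        np.testing.assert_allclose(raw_feature(3.2 * x + 11.0), raw_feature(x), atol=1e-9)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            raw_feature(np.full(16, 4.0))


@pytest.mark.parametrize("method", ["MP2", "PE", "SHCC", "SIFT", "RAW"])
def test_extractors_deterministic(method, averaged_channel):
    a = extract_feature(averaged_channel, method)
    b = extract_feature(averaged_channel.copy(), method)
    np.testing.assert_array_equal(a, b)


def test_dispatcher_clamps_shcc_blocks_for_short_segments(averaged_channel):
    # 16-sample segment with default G=32: clamped to N-1 = 15 -> 14 slopes
    f = extract_feature(averaged_channel, "SHCC", FeatureConfig())
    assert len(f) == len(averaged_channel) - 2
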