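"""Simulation machinery: noise models, SNR mixing, localization, ROC/AUC."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from recimeg.bem import ChargeOperator
from recimeg.geometry import (ConductivityLayer, HeadModel, SourceSpace,
                              build_icosphere, source_space_from_mesh)
from recimeg.sensors import SensorArray, make_magnetometer
from recimeg.simulate import (NoiseModel, build_noise_model, error_map, localize,
                              mix_to_snr, roc_auc, sample_noise,
                              simulate_dipole_signal, tag_target_region)


@pytest.fixture(scope="module")
def sphere_setup():
    head = HeadModel([ConductivityLayer(build_icosphere(0.09, 2), 0.33, 0.0, "s")])
    op = ChargeOperator(head)
    sites = [np.array(c) for c in ([0, 0, 0.12], [0.08, 0, 0.1], [0, 0.09, 0.09],
                                   [-0.07, 0.05, 0.1], [0.04, -0.08, 0.09])]
    arr = SensorArray([make_magnetometer(f"M{i}", c, c / np.linalg.norm(c), n_elements=8)
                       for i, c in enumerate(sites)])
    src = source_space_from_mesh(build_icosphere(0.06, 1), shift=0.0)
    return head, op, arr, src


class TestSimulateSignal:
    def test_zero_moment_and_unit_normalization(self, sphere_setup):
        head, op, arr, _ = sphere_setup
        b = simulate_dipole_signal(head, arr, np.array([0, 0, 0.05]), np.zeros(3),
                                   operator=op)
        assert np.allclose(b, 0.0)
        b2 = simulate_dipole_signal(head, arr, np.array([0.01, 0, 0.05]),
                                    np.array([1e-8, 0, 0]), operator=op, normalize=True)
        assert np.isclose(np.linalg.norm(b2), 1.0)


class TestNoiseModel:
    def test_deterministic_and_columns_match_forward(self, sphere_setup):
        head, op, arr, src = sphere_setup
        m1 = build_noise_model(head, arr, src, K=6, seed=3, operator=op)
        m2 = build_noise_model(head, arr, src, K=6, seed=3, operator=op)
        assert np.array_equal(m1.noise_leadfield, m2.noise_leadfield)
        j = int(m1.source_indices[0])
        col = simulate_dipole_signal(head, arr, src.positions[j],
                                     1e-8 * src.normals[j], operator=op)
        assert np.allclose(m1.noise_leadfield[:, 0], col)

    def test_K_bounds(self, sphere_setup):
        head, op, arr, src = sphere_setup
        with pytest.raises(ValueError):
            build_noise_model(head, arr, src, K=1, operator=op)
        with pytest.raises(ValueError):
            build_noise_model(head, arr, src, K=src.n_sources + 1, operator=op)


class TestSampleNoise:
    def test_unit_norm_and_determinism(self, rng):
        L = rng.standard_normal((5, 30))
        model = NoiseModel(L, np.zeros((30, 3)), np.arange(30), 0)
        e1 = sample_noise(model, 7)
        e2 = sample_noise(model, 7)
        assert np.isclose(np.linalg.norm(e1), 1.0)
        assert np.array_equal(e1, e2)

    def test_covariance_proportional_to_LLt(self, rng):
        M, K = 4, 50
        L = rng.standard_normal((M, K))
        model = NoiseModel(L, np.zeros((K, 3)), np.arange(K), 0)
        g = np.random.default_rng(0)
        draws = np.array([sample_noise(model, 0, rng=g) for _ in range(10000)])
        emp = draws.T @ draws / len(draws)
        ref = L @ L.T
        emp /= np.trace(emp)
        ref /= np.trace(ref)
        assert np.linalg.norm(emp - ref) <= 0.10 * np.linalg.norm(ref)


class TestMixToSnr:
    def test_snr_one_returns_pure_noise(self, rng):
        b = rng.standard_normal(6)
        b /= np.linalg.norm(b)
        e = rng.standard_normal(6)
        e /= np.linalg.norm(e)
        out = mix_to_snr(b, e, 1.0)
        assert out.eta == 0.0 and np.allclose(out.signal, e)

    def test_below_one_rejected(self, rng):
        v = rng.standard_normal(4)
        v /= np.linalg.norm(v)
        with pytest.raises(ValueError):
            mix_to_snr(v, v, 0.5)

    def test_orthogonal_closed_form(self):
        # zero-mean, orthogonal, equal component variance:
        # SNR^2 = 1 + (eta/(1-eta))^2  =>  eta* = g/(1+g), g = sqrt(SNR^2-1)
        b = np.array([0.0, 0.0, 1.0, -1.0]) / np.sqrt(2)
        e = np.array([1.0, -1.0, 0.0, 0.0]) / np.sqrt(2)
        for snr in (1.5, 3.0, 27.0):
            g = np.sqrt(snr**2 - 1)
            eta_exact = g / (1 + g)
            out = mix_to_snr(b, e, snr)
            assert abs(out.eta - eta_exact) < 1e-3 * eta_exact
            assert abs(out.achieved_snr - snr) <= 1e-3 * snr

    @pytest.mark.parametrize("snr", [81, 27, 9, 3, 2, 1.5])
    def test_round_trip_at_standard_levels(self, snr, rng):
        b = rng.standard_normal(20)
        b /= np.linalg.norm(b)
        e = rng.standard_normal(20)
        e /= np.linalg.norm(e)
        out = mix_to_snr(b, e, snr)
        assert abs(out.achieved_snr - snr) <= 0.01 * snr


class TestLocalize:
    def _src(self):
        pos = np.array([[0, 0, 0], [0.01, 0, 0], [0.02, 0, 0], [0.03, 0, 0]])
        n = np.tile([0, 0, 1.0], (4, 1))
        return SourceSpace(pos, n, np.ones(4), np.arange(4))

    def test_singleton_region(self):
        src = self._src()
        out = localize(np.array([0, 1.0, 0, 0]), src, src.positions[1])
        assert out.peak_distance == 0.0 and out.centroid_distance == 0.0

    def test_two_equal_sources_centroid_midpoint(self):
        src = self._src()
        out = localize(np.array([1.0, 0, 0, 1.0]), src, np.zeros(3), threshold=0.9)
        assert np.allclose(out.centroid_position, [0.015, 0, 0])

    def test_region_matches_bruteforce_threshold_scan(self, rng):
        src = SourceSpace(rng.standard_normal((50, 3)),
                          np.tile([0, 0, 1.0], (50, 1)), np.ones(50), np.arange(50))
        s = rng.standard_normal(50)
        out = localize(s, src, np.zeros(3), threshold=0.6)
        brute = [j for j in range(50) if abs(s[j]) >= 0.6 * np.max(np.abs(s))]
        assert sorted(out.region.tolist()) == brute


class TestTagTargetRegion:
    def test_sphere_has_no_sulci_and_monotone_area(self):
        mesh = build_icosphere(0.07, 3)
        with pytest.raises(ValueError):
            tag_target_region(mesh, np.array([0, 0, 0.07]), curvature_threshold=0.0)
        # with a permissive threshold every face is a candidate
        areas = []
        for frac in (0.2, 0.5, 1.0):
            m = tag_target_region(mesh, np.array([0, 0, 0.07]),
                                  curvature_threshold=1e3, area_fraction=frac)
            areas.append(mesh.face_areas[m].sum())
        assert areas[0] < areas[1] < areas[2]
        full = tag_target_region(mesh, np.array([0, 0, 0.07]),
                                 curvature_threshold=1e3, area_fraction=1.0)
        assert full.all()


class TestRocAuc:
    def test_perfect_and_random_classifiers(self):
        s = np.array([0.9, 0.8, 0.2, 0.1])
        mask = np.array([True, True, False, False])
        assert roc_auc(s, mask).auc == pytest.approx(1.0)
        assert roc_auc(np.full(6, 0.3), np.array([1, 0, 1, 0, 1, 0], bool)).auc \
            == pytest.approx(0.5)

    def test_matches_exhaustive_enumeration(self):
        s = np.array([0.9, 0.4, 0.6, 0.1])
        mask = np.array([True, True, False, False])
        out = roc_auc(s, mask)
        # brute force over all thresholds: pairwise ranking probability
        pos, neg = s[mask], s[~mask]
        pairs = [(1.0 if p > n else 0.5 if p == n else 0.0) for p in pos for n in neg]
        assert out.auc == pytest.approx(np.mean(pairs))

    @given(st.lists(st.floats(0.01, 10), min_size=4, max_size=12))
    def test_invariant_under_monotone_transform(self, vals):
        s = np.array(vals)
        mask = np.zeros(len(s), bool)
        mask[: len(s) // 2] = True
        a1 = roc_auc(s, mask).auc
        a2 = roc_auc(np.log1p(s) ** 2, mask).auc
        assert a1 == pytest.approx(a2)

    def test_curve_monotone(self, rng):
        s = rng.random(40)
        mask = rng.random(40) > 0.5
        if mask.all() or not mask.any():
            mask[0] = ~mask[0]
        out = roc_auc(s, mask)
        # along the threshold sweep both rates are monotone non-increasing
        assert np.all(np.diff(out.fpr) <= 1e-12)
        assert np.all(np.diff(out.tpr) <= 1e-12)
        assert 0.0 <= out.auc <= 1.0

    def test_degenerate_mask_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones(3), np.ones(3, bool))


class TestErrorMap:
    def _setup(self, _rng=None):
        rng = np.random.default_rng(1)  # fixed geometry for reproducible stats
        N = 60
        pos = rng.standard_normal((N, 3)) * 0.03
        src = SourceSpace(pos, np.tile([0, 0, 1.0], (N, 1)), np.ones(N), np.arange(N))
        L = rng.standard_normal((12, N))
        model = NoiseModel(L, pos, np.arange(N), 0)
        inv = np.linalg.pinv(L)
        return src, model, (lambda b: inv @ b)

    def test_zero_noise_degenerate(self, rng):
        src, model, apply_fn = self._setup(rng)
        out = error_map(model, apply_fn, src, noise_level=0.0, seed=1)
        assert np.allclose(out["centroid_std"], 0.0)
        assert np.allclose(out["peak_std"], 0.0)

    def test_deterministic_for_fixed_seed(self, rng):
        src, model, apply_fn = self._setup(rng)
        o1 = error_map(model, apply_fn, src, 0.3, n_samples=10, seed=5)
        o2 = error_map(model, apply_fn, src, 0.3, n_samples=10, seed=5)
        assert np.array_equal(o1["centroid_mean"], o2["centroid_mean"])

    def test_noise_degrades_localization_for_most_dipoles(self, rng):
        src, model, apply_fn = self._setup(rng)
        o0 = error_map(model, apply_fn, src, 0.0, seed=2)
        o3 = error_map(model, apply_fn, src, 0.3, n_samples=100, seed=2)
        frac = np.mean(o3["centroid_mean"] >= o0["centroid_mean"] - 1e-12)
        assert frac >= 0.8

    def test_pure_noise_rejected(self, rng):
        src, model, apply_fn = self._setup(rng)
        with pytest.raises(ValueError):
            error_map(model, apply_fn, src, 1.0)
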