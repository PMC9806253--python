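"""Texture features: hand-computed examples, closed forms, and exact
agreement with brute-force oracles on random masked volumes."""

import numpy as np
import pytest

from radpheno import VolumeWithMask, discretize, extract_rfg, texture_features
from radpheno.features import (
    GLSZM_NAMES,
    OFFSETS_13,
    TEXTURE_NAMES,
    first_order_features,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_zones,
    ngtdm_features,
    ngtdm_table,
    rfg_feature_names,
)
from radpheno.imaging import DiscretizedVolume

from . import oracles
from .conftest import sphere_volume


def _dvol(levels, G):
    return DiscretizedVolume(np.asarray(levels, dtype=np.int64), G)


def _line_volume(values):
    arr = np.asarray(values, dtype=float).reshape(1, -1, 1)
    mask = np.ones(arr.shape, bool)
    return VolumeWithMask(arr, (1, 1, 1), mask)


class TestFirstOrder:
    def test_constant_region_degenerate_conventions(self):
        v = _line_volume([4.0] * 10)
        f = first_order_features(discretize(v, 8), v)
        assert f["fo_variance"] == 0
        assert f["fo_entropy"] == 0
        assert f["fo_uniformity"] == 1
        assert f["fo_range"] == 0
        assert f["fo_skewness"] == 0 and f["fo_kurtosis"] == 0

    def test_hand_computed_four_values(self):
        v = _line_volume([1.0, 2.0, 3.0, 4.0])
        f = first_order_features(discretize(v, 4), v)
        assert f["fo_mean"] == pytest.approx(2.5)
        assert f["fo_variance"] == pytest.approx(1.25)
        assert f["fo_entropy"] == pytest.approx(2.0)  # uniform over 4 levels
        assert f["fo_min"] == 1 and f["fo_max"] == 4 and f["fo_range"] == 3
        assert f["fo_energy"] == pytest.approx(1 + 4 + 9 + 16)
        assert f["fo_rms"] == pytest.approx(np.sqrt(30 / 4))

    def test_order_and_jensen_properties(self, rng):
        for _ in range(10):
            vals = rng.normal(size=50)
            v = _line_volume(vals)
            f = first_order_features(discretize(v, 16), v)
            assert f["fo_min"] <= f["fo_median"] <= f["fo_max"]
            assert f["fo_rms"] ** 2 >= f["fo_mean"] ** 2 - 1e-12


class TestGLCM:
    def test_hand_two_by_two_checker(self):
        # levels [[1,2],[2,1]] with only the two in-plane axis directions:
        # every pair is (1,2) or (2,1)
        lev = np.array([[1, 2], [2, 1]]).reshape(2, 2, 1)
        d = _dvol(lev, 2)
        P = glcm_matrix(d, offsets=[(0, 1, 0), (1, 0, 0)])
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        f = glcm_features(P)
        assert f["glcm_contrast"] == pytest.approx(1.0)
        assert f["glcm_energy"] == pytest.approx(0.5)  # ASM
        assert f["glcm_entropy"] == pytest.approx(1.0)  # 1 bit

    def test_constant_region(self):
        d = _dvol(np.ones((3, 3, 3), dtype=int), 4)
        P = glcm_matrix(d)
        assert P[0, 0] == pytest.approx(1.0)
        f = glcm_features(P)
        assert f["glcm_contrast"] == 0
        assert f["glcm_max_probability"] == 1
        assert f["glcm_homogeneity"] == pytest.approx(1.0)
        assert f["glcm_dissimilarity"] == 0

    def test_matrix_matches_brute_force(self, rng):
        for seed in range(8):
            lev = oracles.random_levels(np.random.default_rng(seed), (6, 5, 4), 4)
            d = _dvol(lev, 4)
            if not (_dvol(lev, 4).mask.sum() > 1):
                continue
            P = glcm_matrix(d)
            B = oracles.brute_glcm(lev, 4)
            assert np.allclose(P, B, atol=1e-12)

    def test_features_match_literal_formulas(self, rng):
        """Each feature agrees with an independent literal-formula pass."""
        lev = oracles.random_levels(rng, (6, 6, 6), 5)
        P = glcm_matrix(_dvol(lev, 5))
        f = glcm_features(P)
        G = 5
        contrast = dissim = asm = ent = maxp = idn = homog = 0.0
        for i in range(1, G + 1):
            for j in range(1, G + 1):
                p = P[i - 1, j - 1]
                contrast += p * (i - j) ** 2
                dissim += p * abs(i - j)
                homog += p / (1 + (i - j) ** 2)
                asm += p * p
                idn += p / (1 + abs(i - j) / G)
                if p > 0:
                    ent -= p * np.log2(p)
                maxp = max(maxp, p)
        assert f["glcm_contrast"] == pytest.approx(contrast)
        assert f["glcm_dissimilarity"] == pytest.approx(dissim)
        assert f["glcm_homogeneity"] == pytest.approx(homog)
        assert f["glcm_energy"] == pytest.approx(asm)
        assert f["glcm_entropy"] == pytest.approx(ent)
        assert f["glcm_max_probability"] == pytest.approx(maxp)
        assert f["glcm_idn"] == pytest.approx(idn)

    def test_single_voxel_roi_is_degenerate(self):
        lev = np.zeros((5, 5, 5), dtype=int)
        lev[2, 2, 2] = 1
        with pytest.raises(ValueError, match="degenerate"):
            glcm_matrix(_dvol(lev, 4))

    def test_relabel_invariance_where_expected(self, rng):
        """ASM/entropy ignore the level identities; contrast does not."""
        lev = oracles.random_levels(rng, (5, 5, 5), 4)
        relabel = np.array([0, 4, 3, 2, 1])  # permute levels 1..4
        lev2 = relabel[lev]
        f1 = glcm_features(glcm_matrix(_dvol(lev, 4)))
        f2 = glcm_features(glcm_matrix(_dvol(lev2, 4)))
        assert f1["glcm_energy"] == pytest.approx(f2["glcm_energy"])
        assert f1["glcm_entropy"] == pytest.approx(f2["glcm_entropy"])


class TestGLRLM:
    def test_single_run_closed_form(self):
        N = 7
        lev = np.ones((1, N, 1), dtype=int)
        R = glrlm_matrix(_dvol(lev, 2), (0, 1, 0))
        assert R[0, N - 1] == 1 and R.sum() == 1
        # features along that single direction: SRE = 1/N^2, LRE = N^2, RP = 1/N
        from radpheno.features import _rl_features_batch

        vals = _rl_features_batch(R[None], N)[0]
        assert vals[0] == pytest.approx(1 / N**2)
        assert vals[1] == pytest.approx(N**2)
        assert vals[6] == pytest.approx(1 / N)

    def test_alternating_line_all_singletons(self):
        lev = np.array([1, 2, 1, 2, 1, 2]).reshape(1, 6, 1)
        R = glrlm_matrix(_dvol(lev, 2), (0, 1, 0))
        assert R[:, 0].sum() == 6 and R[:, 1:].sum() == 0

    def test_matrix_matches_brute_force_all_directions(self):
        for seed in range(6):
            lev = oracles.random_levels(np.random.default_rng(seed), (5, 5, 5), 4)
            d = _dvol(lev, 4)
            for off in OFFSETS_13:
                R = glrlm_matrix(d, off)
                B = oracles.brute_glrlm(lev, 4, tuple(off))
                L = max(R.shape[1], B.shape[1])
                Rp = np.zeros((4, L))
                Bp = np.zeros((4, L))
                Rp[:, : R.shape[1]] = R
                Bp[:, : B.shape[1]] = B
                assert np.array_equal(Rp, Bp), f"direction {off}"

    def test_feature_vector_finite(self, rng):
        lev = oracles.random_levels(rng, (6, 6, 6), 5)
        f = glrlm_features(_dvol(lev, 5))
        assert all(np.isfinite(v) for v in f.values())


class TestGLSZM:
    def test_constant_region_single_zone(self):
        lev = np.ones((3, 3, 3), dtype=int)
        f = glszm_features(_dvol(lev, 2))
        V = 27
        assert f["glszm_zp"] == pytest.approx(1 / V)
        assert f["glszm_sae"] == pytest.approx(1 / V**2)
        assert f["glszm_lae"] == pytest.approx(V**2)

    def test_isolated_voxels_all_singleton_zones(self):
        lev = np.zeros((6, 6, 6), dtype=int)
        lev[::3, ::3, ::3] = 1  # spaced beyond 26-connectivity
        f = glszm_features(_dvol(lev, 2))
        assert f["glszm_sae"] == pytest.approx(1.0)
        assert f["glszm_zp"] == pytest.approx(1.0)

    def test_zones_match_flood_fill_oracle(self):
        for seed in range(8):
            lev = oracles.random_levels(np.random.default_rng(seed), (6, 6, 6), 3)
            mine = sorted(glszm_zones(_dvol(lev, 3)))
            brute = sorted(oracles.brute_zones(lev))
            assert mine == brute


class TestNGTDM:
    def test_constant_region_conventions(self):
        lev = np.ones((3, 3, 3), dtype=int)
        f = ngtdm_features(_dvol(lev, 4))
        assert f["ngtdm_coarseness"] == pytest.approx(1e6)  # 1/eps cap
        assert f["ngtdm_contrast"] == 0
        assert f["ngtdm_busyness"] == 0

    def test_hand_two_level_pattern(self):
        # 2x2x1 checker: each voxel's 3 in-mask neighbors average to
        # (g_other + g_other + g_same)/3, |diff| = 2/3 per voxel
        lev = np.array([[1, 2], [2, 1]]).reshape(2, 2, 1)
        p, s, n = ngtdm_table(_dvol(lev, 2))
        assert np.allclose(p, [0.5, 0.5])
        assert np.allclose(s, [4 / 3, 4 / 3])
        assert np.allclose(n, [2, 2])

    def test_table_matches_brute_force(self):
        for seed in range(8):
            lev = oracles.random_levels(np.random.default_rng(seed), (6, 6, 6), 4)
            p, s, n = ngtdm_table(_dvol(lev, 4))
            bp, bs, bn = oracles.brute_ngtdm(lev, 4)
            assert np.allclose(p, bp)
            assert np.allclose(s, bs, atol=1e-10)
            assert np.allclose(n, bn)


class TestRFG:
    def test_roster_counts(self):
        assert len(TEXTURE_NAMES) == 64
        names = rfg_feature_names()
        assert len(names) == 833
        assert sum(n.startswith("wav_") for n in names) == 768
        assert sum(n.startswith("orig_") for n in names) == 64
        assert len(set(names)) == 833

    def test_sphere_volume_feature(self):
        v = sphere_volume(5.0, (1.0, 1.0, 1.0))
        rng = np.random.default_rng(0)
        v = VolumeWithMask(rng.normal(100, 5, v.shape), v.spacing, v.mask)
        s = extract_rfg(v)
        analytic = 4 / 3 * np.pi * 5.0**3  # 523.6 mm^3
        assert abs(s["volume_mm3"] - analytic) / analytic < 0.05

    def test_determinism_and_finiteness(self, random_volume):
        s1 = extract_rfg(random_volume)
        s2 = extract_rfg(random_volume)
        assert (s1 == s2).all()
        assert np.isfinite(s1.to_numpy()).all()
        assert list(s1.index) == rfg_feature_names()

    def test_all_64_finite_on_degenerate_constant_roi(self):
        v = sphere_volume(4.0, (1.0, 1.0, 1.0), value=9.0)
        f = texture_features(v)
        assert len(f) == 64
        assert all(np.isfinite(val) for val in f.values())

    def test_empty_roi_rejected(self, random_volume):
        v = random_volume.with_mask(np.zeros(random_volume.shape, bool))
        with pytest.raises(ValueError):
            extract_rfg(v)
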