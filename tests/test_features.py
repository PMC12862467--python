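"""Feature definitions checked against independent brute-force oracles.

The oracles below recompute every texture statistic with direct Python
loops over voxels, directions and matrix entries; the implementation
under test uses vectorized/compiled paths.
"""

import numpy as np
import pandas as pd
import pytest

from omrad.errors import DegenerateShapeError, InputError, ParameterError, RegistryError
from omrad.features import (
    SELECTED_FEATURES,
    discretize,
    extract_features,
    extract_features_by_spec,
    firstorder_minimum,
    glcm_features,
    icc_filter,
    ngtdm_busyness,
    shape_elongation,
)
from omrad.filters import logarithm_transform
from omrad.image_io import MaskVolume, VolumeGrid
from omrad.margin import enumerate_band_specs

from conftest import make_ball, make_ellipsoid, random_region

OFFSETS = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1), (1, 0, 0),
    (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1),
]


# ---------------------------------------------------------------------------
# brute-force oracles (direct loops, no shared code with the implementation)


def oracle_glcm(levels, G):
    feats = {"JointEntropy": [], "ClusterShade": [], "Imc1": [], "MCC": []}
    nx, ny, nz = levels.shape
    for off in OFFSETS:
        M = np.zeros((G, G))
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    i = levels[x, y, z]
                    if i == 0:
                        continue
                    x2, y2, z2 = x + off[0], y + off[1], z + off[2]
                    if 0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz:
                        j = levels[x2, y2, z2]
                        if j > 0:
                            M[i - 1, j - 1] += 1
                            M[j - 1, i - 1] += 1
        if M.sum() == 0:
            continue
        p = M / M.sum()
        lv = np.arange(1, G + 1)
        px, py = p.sum(1), p.sum(0)
        nzp = p > 0
        je = float(-(p[nzp] * np.log2(p[nzp])).sum())
        mx, my = (lv * px).sum(), (lv * py).sum()
        cs = sum(
            (i + 1 + j + 1 - mx - my) ** 3 * p[i, j]
            for i in range(G) for j in range(G)
        )
        outer = px[:, None] * py[None, :]
        valid = nzp & (outer > 0)
        hxy1 = float(-(p[valid] * np.log2(outer[valid])).sum())
        hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
        hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
        imc1 = (je - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
        keep = np.nonzero(px > 0)[0]
        if len(keep) < 2:
            mcc = 1.0
        else:
            Q = np.zeros((len(keep), len(keep)))
            for a, ia in enumerate(keep):
                for b, ib in enumerate(keep):
                    Q[a, b] = sum(
                        p[ia, k] * p[ib, k] / (px[ia] * py[k]) for k in keep
                    )
            lam = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
            mcc = float(np.sqrt(np.clip(lam[1], 0, 1)))
        feats["JointEntropy"].append(je)
        feats["ClusterShade"].append(float(cs))
        feats["Imc1"].append(imc1)
        feats["MCC"].append(mcc)
    return {k: float(np.mean(v)) for k, v in feats.items()}


def oracle_busyness(levels, G):
    nx, ny, nz = levels.shape
    s, n = np.zeros(G), np.zeros(G)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                i = levels[x, y, z]
                if i == 0:
                    continue
                n[i - 1] += 1
                neigh = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if dx == dy == dz == 0:
                                continue
                            x2, y2, z2 = x + dx, y + dy, z + dz
                            if 0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz:
                                if levels[x2, y2, z2] > 0:
                                    neigh.append(levels[x2, y2, z2])
                if neigh:
                    s[i - 1] += abs(i - float(np.mean(neigh)))
    p = n / n.sum()
    occ = p > 0
    lv = np.arange(1, G + 1)
    ip = lv[occ] * p[occ]
    den = float(np.abs(ip[:, None] - ip[None, :]).sum())
    return 0.0 if den == 0 else float((p[occ] * s[occ]).sum() / den)


# ---------------------------------------------------------------------------
# discretization


class TestDiscretize:
    def test_constant_region_single_level(self):
        vol = VolumeGrid(np.full((4, 4, 4), 9.0))
        mask = MaskVolume(np.ones((4, 4, 4), dtype=bool))
        reg = discretize(vol, mask, 25.0)
        assert reg.n_levels == 1
        assert set(reg.levels[reg.levels > 0]) == {1}

    def test_hand_worked_levels(self):
        vals = np.array([0.0, 10.0, 25.0, 49.0, 100.0]).reshape(1, 1, 5)
        reg = discretize(
            VolumeGrid(vals), MaskVolume(np.ones((1, 1, 5), dtype=bool)), 25.0
        )
        assert reg.n_levels == 5
        assert list(reg.levels[0, 0]) == [1, 1, 2, 2, 5]

    def test_shift_invariance(self, rng):
        vol, mask = random_region(rng)
        a = discretize(vol, mask, 10.0)
        b = discretize(VolumeGrid(vol.voxels + 137.5), mask, 10.0)
        np.testing.assert_array_equal(a.levels, b.levels)

    def test_errors(self, rng):
        vol, mask = random_region(rng)
        with pytest.raises(ParameterError):
            discretize(vol, mask, 0.0)
        with pytest.raises(InputError):
            discretize(vol, MaskVolume(np.zeros(vol.shape, dtype=bool)), 25.0)


# ---------------------------------------------------------------------------
# texture statistics


class TestGLCM:
    def test_constant_region_degenerate_conventions(self):
        vol = VolumeGrid(np.full((4, 4, 4), 5.0))
        reg = discretize(vol, MaskVolume(np.ones((4, 4, 4), dtype=bool)), 25.0)
        feats = glcm_features(reg)
        assert feats == {"Imc1": 0.0, "MCC": 1.0, "ClusterShade": 0.0, "JointEntropy": 0.0}

    def test_alternating_strip_entropy_one_bit(self):
        # [1,2,1,2,1,2] along the only axis with pairs: all symmetrized
        # mass sits on (1,2) and (2,1) -> joint entropy exactly 1 bit
        vals = np.array([0.0, 25, 0, 25, 0, 25]).reshape(1, 1, 6)
        reg = discretize(VolumeGrid(vals), MaskVolume(np.ones((1, 1, 6), bool)), 25.0)
        assert glcm_features(reg, ("JointEntropy",))["JointEntropy"] == pytest.approx(1.0)

    def test_independent_joint_distribution_gives_imc1_zero(self, rng):
        # checker-free random field: Imc1 <= 0 always, ~0 when joint ~ product
        vol, mask = random_region(rng, shape=(10, 10, 10), density=1.0)
        reg = discretize(vol, mask, 60.0)
        imc1 = glcm_features(reg, ("Imc1",))["Imc1"]
        assert imc1 <= 1e-12
        assert imc1 == pytest.approx(0.0, abs=0.05)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        vol, mask = random_region(rng, shape=(8, 8, 8))
        reg = discretize(vol, mask, 25.0)
        mine = glcm_features(reg)
        ref = oracle_glcm(reg.levels, reg.n_levels)
        for k in mine:
            assert mine[k] == pytest.approx(ref[k], rel=1e-10, abs=1e-10), k

    def test_invariants_on_random_fixtures(self, rng):
        for _ in range(5):
            vol, mask = random_region(rng)
            reg = discretize(vol, mask, 25.0)
            f = glcm_features(reg)
            assert f["JointEntropy"] >= 0
            assert f["Imc1"] <= 1e-12 and f["Imc1"] >= -1 - 1e-12
            assert 0 <= f["MCC"] <= 1 + 1e-9


class TestNGTDM:
    def test_constant_region_zero(self):
        vol = VolumeGrid(np.full((4, 4, 4), 2.0))
        reg = discretize(vol, MaskVolume(np.ones((4, 4, 4), bool)), 25.0)
        assert ngtdm_busyness(reg) == 0.0

    def test_single_voxel_zero(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        reg = discretize(VolumeGrid(np.ones((3, 3, 3))), MaskVolume(m), 25.0)
        assert ngtdm_busyness(reg) == 0.0

    def test_checkerboard_hand_enumeration(self):
        # 3x3x1 two-level checkerboard; the 9 neighbourhood means are
        # enumerable by hand and match oracle_busyness exactly
        vals = np.array([[1, 2, 1], [2, 1, 2], [1, 2, 1]], dtype=float).reshape(3, 3, 1) * 25 - 25
        mask = MaskVolume(np.ones((3, 3, 1), bool))
        reg = discretize(VolumeGrid(vals), mask, 25.0)
        assert reg.n_levels == 2
        # centre voxel (level 1): 8 neighbours all level 2 -> |1-2| = 1, etc.
        assert ngtdm_busyness(reg) == pytest.approx(
            oracle_busyness(reg.levels, reg.n_levels), rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(2000 + seed)
        vol, mask = random_region(rng, shape=(8, 8, 8))
        reg = discretize(vol, mask, 25.0)
        assert ngtdm_busyness(reg) == pytest.approx(
            oracle_busyness(reg.levels, reg.n_levels), rel=1e-10
        )


class TestFirstOrderAndShape:
    def test_minimum_direct_and_brute_force(self, rng):
        vol, mask = random_region(rng)
        assert firstorder_minimum(vol, mask) == float(
            min(vol.voxels[x, y, z] for x, y, z in np.argwhere(mask.voxels))
        )

    def test_minimum_argmin_invariant_under_log(self, rng):
        vol, mask = random_region(rng, mean=100, sd=20)
        vol = VolumeGrid(np.abs(vol.voxels))
        lvol = logarithm_transform(vol)
        inmask = mask.voxels
        assert np.argmin(vol.voxels[inmask]) == np.argmin(lvol.voxels[inmask])

    def test_elongation_ball_near_one(self):
        assert shape_elongation(make_ball(10)) == pytest.approx(1.0, abs=0.05)

    def test_elongation_two_to_one_ellipsoid(self):
        # continuous moments: lambda proportional to semi-axis^2 -> sqrt(1/4) = 0.5
        assert shape_elongation(make_ellipsoid((20, 10, 10))) == pytest.approx(0.5, abs=0.03)

    def test_elongation_rotation_invariant(self):
        from scipy.ndimage import rotate

        mask = make_ellipsoid((16, 8, 8), pad=8)
        rot = rotate(
            mask.voxels.astype(float), 35.0, axes=(0, 1), reshape=True, order=1
        ) > 0.5
        e1 = shape_elongation(mask)
        e2 = shape_elongation(MaskVolume(rot))
        assert e1 == pytest.approx(e2, abs=0.02)

    def test_degenerate_masks_raise(self):
        flat = np.zeros((5, 5, 5), dtype=bool)
        flat[:, :, 2] = True
        with pytest.raises(DegenerateShapeError):
            shape_elongation(MaskVolume(flat))
        tiny = np.zeros((5, 5, 5), dtype=bool)
        tiny[0, 0, 0] = True
        with pytest.raises((DegenerateShapeError, InputError)):
            shape_elongation(MaskVolume(tiny))


# ---------------------------------------------------------------------------
# extraction contract


class TestExtractFeatures:
    def test_seven_features_finite_and_within_invariants(self, rng):
        vol, _ = random_region(rng, shape=(25, 25, 25), density=1.0)
        lesion = make_ball(9, pad=3)
        band = make_ball(9, pad=3)  # original region
        feats = extract_features(vol, lesion, band, SELECTED_FEATURES)
        assert set(feats) == set(SELECTED_FEATURES)
        vals = np.array(list(feats.values()))
        assert np.all(np.isfinite(vals))
        assert 0 < feats["original_shape_Elongation"] <= 1
        assert -1 <= feats["logarithm_glcm_Imc1"] <= 0
        assert 0 <= feats["wavelet_LHL_glcm_MCC"] <= 1
        assert feats["wavelet_HHH_glcm_JointEntropy"] >= 0

    def test_deterministic(self, rng):
        vol, _ = random_region(rng, shape=(25, 25, 25), density=1.0)
        lesion = make_ball(9, pad=3)
        f1 = extract_features(vol, lesion, lesion)
        f2 = extract_features(vol, lesion, lesion)
        assert f1 == f2

    def test_shape_feature_constant_across_all_band_specs(self, rng):
        vol, _ = random_region(rng, shape=(33, 33, 33), density=1.0)
        lesion = make_ball(7, pad=9)
        specs = enumerate_band_specs(10)
        by_spec = extract_features_by_spec(
            vol, lesion, specs, ["original_shape_Elongation"]
        )
        vals = {
            v["original_shape_Elongation"] for v in by_spec.values() if v is not None
        }
        assert len(vals) == 1

    def test_empty_band_raises_and_unknown_name_rejected(self, rng):
        vol, _ = random_region(rng, shape=(13, 13, 13))
        lesion = make_ball(3)
        empty = MaskVolume(np.zeros(vol.shape, dtype=bool))
        with pytest.raises(InputError):
            extract_features(vol, MaskVolume(np.ones(vol.shape, bool)), empty)
        with pytest.raises(RegistryError):
            extract_features(vol, lesion, lesion, ["original_glrlm_RunEntropy"])


# ---------------------------------------------------------------------------
# ICC reproducibility filter


class TestICCFilter:
    def _matrix(self, rng, n=40, p=4):
        return pd.DataFrame(
            rng.normal(size=(n, p)),
            index=[f"P{i}" for i in range(n)],
            columns=[f"f{j}" for j in range(p)],
        )

    def test_identical_raters_all_retained(self, rng):
        a = self._matrix(rng)
        retained, iccs = icc_filter(a, a.copy())
        assert retained == list(a.columns)
        assert np.all(iccs.to_numpy() > 0.999)

    def test_independent_noise_all_dropped(self):
        rng = np.random.default_rng(77)
        n = 100
        idx = [f"P{i}" for i in range(n)]
        a = pd.DataFrame(rng.normal(size=(n, 3)), index=idx, columns=list("abc"))
        b = pd.DataFrame(rng.normal(size=(n, 3)), index=idx, columns=list("abc"))
        retained, iccs = icc_filter(a, b)
        assert retained == []
        assert np.all(np.abs(iccs.to_numpy()) < 0.3)

    def test_threshold_is_strict(self):
        # a feature whose ICC equals the threshold exactly is dropped
        rng = np.random.default_rng(3)
        idx = [f"P{i}" for i in range(50)]
        a = pd.DataFrame(rng.normal(size=(50, 2)), index=idx, columns=list("ab"))
        b = a + rng.normal(scale=0.5, size=(50, 2))
        _, iccs = icc_filter(a, b, threshold=-np.inf)
        at_boundary, _ = icc_filter(a, b, threshold=float(iccs["a"]))
        assert "a" not in at_boundary

    def test_too_few_patients(self, rng):
        a = self._matrix(rng, n=2)
        with pytest.raises(InputError):
            icc_filter(a, a.copy())
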