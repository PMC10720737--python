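"""Tissue volume construction, snapping, symmetry and serialization."""

import numpy as np
import pytest
import yaml

import sfdimc as m
from sfdimc.geometry import TissueVolume


class TestOpticalProperties:
    def test_reduced_scattering_accessor(self):
        p = m.OpticalProperties(mua=0.023, mus=14.2, g=0.9)
        assert p.musp == pytest.approx(1.42, rel=1e-12)

    def test_from_musp_round_trip(self):
        p = m.OpticalProperties.from_musp(mua=0.023, musp=1.42, g=0.9)
        assert p.mus == pytest.approx(14.2, rel=1e-12)
        assert p.musp == pytest.approx(1.42, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mua": -0.1, "mus": 1.0},
            {"mua": 0.1, "mus": -1.0},
            {"mua": 0.1, "mus": 1.0, "g": 1.0},
            {"mua": 0.1, "mus": 1.0, "g": -1.0},
            {"mua": 0.1, "mus": 1.0, "n": 0.5},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            m.OpticalProperties(**kwargs)


class TestHomogeneousVolume:
    def test_dims_and_label_count(self, skin_props):
        vol = m.build_homogeneous_volume(skin_props, (1.0, 1.0, 1.0), 0.5)
        assert vol.dims == (2, 2, 2)
        assert vol.labels.size == 8
        assert len(np.unique(vol.labels)) == 1

    def test_healthy_skin_scattering_stored(self):
        vol = m.build_homogeneous_volume(
            m.OpticalProperties.from_musp(0.023, 1.42, 0.9), (2, 2, 2), 1.0
        )
        assert vol.properties[0].mus == pytest.approx(14.2, rel=1e-12)
        assert vol.properties[0].g == 0.9

    @pytest.mark.parametrize("voxel", [0.0, -0.1])
    def test_bad_voxel_size(self, skin_props, voxel):
        with pytest.raises(ValueError):
            m.build_homogeneous_volume(skin_props, (1, 1, 1), voxel)

    def test_bad_extent(self, skin_props):
        with pytest.raises(ValueError):
            m.build_homogeneous_volume(skin_props, (1, -1, 1), 0.5)

    def test_extents_consistent_with_dims(self, small_homog):
        nx, ny, nz = small_homog.dims
        lx, ly, lz = small_homog.extents
        d = small_homog.voxel_size
        assert (lx, ly, lz) == pytest.approx((nx * d, ny * d, nz * d))


def _wound(width, voxel=0.5, extents=(8.0, 4.0, 8.0), depth=3.0,
           musp_wound=0.71):
    wound = m.OpticalProperties.from_musp(0.023, musp_wound, 0.9)
    return m.build_wound_volume(
        m.SKIN, wound, m.WoundSpec(width=width, depth=depth), extents, voxel
    )


class TestWoundVolume:
    def test_wound_column_indices(self):
        vol = _wound(2.0, voxel=0.5, extents=(8.0, 4.0, 8.0))
        wound_cols = np.unique(np.nonzero(vol.labels == 1)[0])
        assert wound_cols.tolist() == [6, 7, 8, 9]
        assert vol.realized_wound_width == pytest.approx(2.0)

    def test_zero_width_equals_homogeneous(self):
        vol = _wound(0.0)
        ref = m.build_homogeneous_volume(m.SKIN, (8.0, 4.0, 8.0), 0.5)
        assert np.array_equal(vol.labels, ref.labels)
        assert vol.realized_wound_width == 0.0

    def test_skin_below_wound_depth(self):
        # 10 mm deep wound in a 16 mm block: z = 12 mm is skin again
        vol = _wound(2.0, voxel=0.5, extents=(8.0, 4.0, 16.0), depth=10.0)
        iz = int(12.0 / 0.5)
        center = vol.labels.shape[0] // 2
        assert vol.labels[center, 0, iz] == 0
        assert vol.labels[center, 0, iz - 5] == 1  # 9.5 mm: still wound

    def test_too_wide_or_deep(self):
        with pytest.raises(ValueError):
            _wound(9.0)
        with pytest.raises(ValueError):
            _wound(2.0, depth=9.0)

    @pytest.mark.parametrize("width", [0.5, 1.0, 1.5, 2.0, 3.3, 4.0])
    def test_mirror_symmetry(self, width):
        vol = _wound(width, voxel=0.1, extents=(28.0, 4.0, 16.0), depth=10.0)
        assert np.array_equal(vol.labels, vol.labels[::-1])

    @pytest.mark.parametrize("width", [0.5, 2.0, 4.0])
    def test_volume_accounting(self, width):
        voxel = 0.1
        vol = _wound(width, voxel=voxel, extents=(28.0, 4.0, 16.0), depth=10.0)
        n_wound = int((vol.labels == 1).sum())
        ny = vol.dims[1]
        expected = (
            round(vol.realized_wound_width / voxel)
            * ny
            * round(vol.wound_depth / voxel)
        )
        assert n_wound == expected

    def test_missing_property_entry_rejected(self):
        labels = np.zeros((2, 2, 2), dtype=np.int8)
        labels[0, 0, 0] = 3
        with pytest.raises(ValueError, match="no properties entry"):
            TissueVolume(labels=labels, voxel_size=1.0, properties={0: m.SKIN})


class TestSafeDistanceMap:
    """The free-flight bound is an optimization and must not change physics."""

    def test_analytic_bound_never_reaches_other_material(self):
        vol = _wound(2.0, voxel=0.1, extents=(8.0, 4.0, 8.0), depth=3.0)
        safe = vol.safe_distance_map()
        d = vol.voxel_size
        nx, ny, nz = vol.dims
        # sample voxels and verify no differently-labeled voxel lies within
        # the claimed radius (check against voxel-center distances + margin)
        rng = np.random.default_rng(0)
        xs = rng.integers(0, nx, 200)
        ys = rng.integers(0, ny, 200)
        zs = rng.integers(0, nz, 200)
        other = np.array(np.nonzero(vol.labels != vol.labels[xs[0], ys[0], zs[0]]))
        for i, j, k in zip(xs, ys, zs):
            r = safe[i, j, k]
            if r <= 0:
                continue
            diff = np.array(np.nonzero(vol.labels != vol.labels[i, j, k]))
            if diff.size == 0:
                continue
            dist = np.sqrt(
                ((diff[0] - i) * d) ** 2
                + ((diff[1] - j) * d) ** 2
                + ((diff[2] - k) * d) ** 2
            ).min()
            # center-to-center distance exceeds the face-based bound
            assert dist + np.sqrt(3) * d >= r

    def test_physics_identical_without_acceleration(self, skin_props):
        """Zeroing the safe map (pure voxel stepping) must give the same
        reflectance within Monte Carlo tolerance."""
        pattern = m.IlluminationPattern(frequency=0.1)
        cfg = m.SimulationConfig(n_photons=50_000, seed=9, bin_mm=0.1)
        vol_fast = _wound(2.0, voxel=0.1, extents=(14.0, 10.0, 8.0), depth=6.0)
        st_fast = m.run_simulation(vol_fast, pattern, cfg)
        vol_slow = _wound(2.0, voxel=0.1, extents=(14.0, 10.0, 8.0), depth=6.0)
        vol_slow._safe_cache = np.zeros(vol_slow.dims, dtype=np.float32)
        st_slow = m.run_simulation(vol_slow, pattern, cfg)
        rd_fast = st_fast.escaped_total / st_fast.launched_total
        rd_slow = st_slow.escaped_total / st_slow.launched_total
        se = np.sqrt(rd_fast * (1 - rd_fast) / cfg.n_photons)
        assert abs(rd_fast - rd_slow) < 6 * se

    def test_edt_fallback_close_to_analytic(self):
        vol = _wound(2.0, voxel=0.2, extents=(6.0, 3.0, 6.0), depth=3.0)
        analytic = vol.safe_distance_map().copy()
        generic = TissueVolume(
            labels=vol.labels.copy(), voxel_size=vol.voxel_size,
            properties=vol.properties,
        ).safe_distance_map()
        # both are valid lower bounds; the EDT one is more conservative but
        # must never exceed the exact bound by more than a voxel diagonal
        assert np.all(generic <= analytic + np.sqrt(3) * vol.voxel_size + 1e-6)


class TestConfigAndSerialization:
    def test_volume_from_config_mapping(self):
        cfg = {
            "extents_mm": [8.0, 4.0, 8.0],
            "voxel_mm": 0.5,
            "skin": {"mua": 0.023, "musp": 1.42, "g": 0.9},
            "wound": {"mua": 0.023, "musp": 0.71, "g": 0.9,
                      "width_mm": 2.0, "depth_mm": 3.0},
        }
        vol = m.volume_from_config(cfg)
        assert vol.realized_wound_width == pytest.approx(2.0)
        assert vol.properties[0].mus == pytest.approx(14.2, rel=1e-12)
        assert vol.properties[1].mus == pytest.approx(7.1, rel=1e-12)

    def test_volume_from_yaml_file(self, tmp_path):
        path = tmp_path / "vol.yaml"
        path.write_text(yaml.safe_dump({
            "extents_mm": [4.0, 4.0, 4.0],
            "voxel_mm": 1.0,
            "skin": {"mua": 0.01, "musp": 1.0},
        }))
        vol = m.volume_from_config(str(path))
        assert vol.dims == (4, 4, 4)
        assert len(vol.properties) == 1

    def test_hdf5_round_trip(self, tmp_path):
        vol = _wound(2.0)
        path = str(tmp_path / "vol.h5")
        m.save_volume(vol, path)
        back = m.load_volume(path)
        assert np.array_equal(back.labels, vol.labels)
        assert back.voxel_size == vol.voxel_size
        assert back.properties == vol.properties
        assert back.realized_wound_width == vol.realized_wound_width
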