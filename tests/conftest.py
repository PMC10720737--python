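"""Shared fixtures: small volumes and a session-wide simulation cache.

Monte Carlo runs dominate the suite's runtime, so identical runs requested
by different tests (same volume, pattern and budget) are computed once and
shared through ``sim_cache``.
"""

from __future__ import annotations

import numpy as np
import pytest

import sfdimc as m


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231214)


@pytest.fixture(scope="session")
def skin_props():
    return m.SKIN


@pytest.fixture(scope="session")
def small_homog(skin_props):
    """A desk-size homogeneous skin block (10 x 10 x 8 mm, 0.1 mm voxels)."""
    return m.build_homogeneous_volume(skin_props, (10.0, 10.0, 8.0), 0.1)


class _SimCache:
    """Memoizes full-pipeline products keyed by their parameters."""

    def __init__(self):
        self._store = {}

    def wound_profile(self, width, musp, fx, n_photons, seed,
                      voxel_mm=0.1, bin_mm=0.1):
        key = ("profile", width, musp, fx, n_photons, seed, voxel_mm, bin_mm)
        if key not in self._store:
            from sfdimc.experiments import wound_profile

            self._store[key] = wound_profile(
                width, musp, fx, n_photons, seed,
                voxel_mm=voxel_mm, bin_mm=bin_mm,
            )
        return self._store[key]

    def wound_wdown_stack(self, width, musp, n_photons, seed,
                          voxel_mm=0.1, bin_mm=0.1, min_scatters=1):
        """Planar-illumination run recording Weight_down on a wound model."""
        key = ("wdown", width, musp, n_photons, seed, voxel_mm, bin_mm,
               min_scatters)
        if key not in self._store:
            wound = m.OpticalProperties.from_musp(0.023, musp, 0.9)
            vol = m.build_wound_volume(
                m.SKIN, wound, m.WoundSpec(width=width, depth=10.0),
                m.DEFAULT_EXTENTS, voxel_mm,
            )
            cfg = m.SimulationConfig(
                n_photons=n_photons, seed=seed, bin_mm=bin_mm,
                plane_spacing_mm=bin_mm, min_scatters_recorded=min_scatters,
            )
            pattern = m.IlluminationPattern(frequency=0.0, modulation_depth=0.0)
            stack = m.run_simulation(vol, pattern, cfg)
            self._store[key] = (stack, float(vol.realized_wound_width))
        return self._store[key]


@pytest.fixture(scope="session")
def sim_cache():
    return _SimCache()
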