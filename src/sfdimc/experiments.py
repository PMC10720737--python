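"""Config-driven orchestration: three-phase runs, parameter sweeps, fixtures.

A "run" in the width study means: build the wound-in-skin volume, simulate
the three phase-shifted sinusoidal illuminations, demodulate into the AC
image, average along the modulation axis into the across-wound profile,
and measure the apparent wound width at one or more thresholds.  The sweep
iterates this over wound width x wound reduced scattering x spatial
frequency x threshold x seed and emits one table row per cell — flagged,
never dropped, when the width estimate fails (e.g. zero contrast when the
wound matches the skin).
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrology, sfdi
from .geometry import (
    OpticalProperties,
    WoundSpec,
    build_homogeneous_volume,
    build_wound_volume,
    save_volume,
)
from .sfdi import PhaseImageSet, build_lut, demodulate, profile_mean, save_lut
from .transport import (
    THREE_PHASES,
    DetectorStack,
    IlluminationPattern,
    SimulationConfig,
    run_simulation,
)

__all__ = [
    "SweepConfig",
    "simulate_three_phase",
    "run_width_sweep",
    "make_fixture",
    "DEFAULT_EXTENTS",
    "SKIN",
]

log = logging.getLogger("sfdimc")

#: Tissue block of the wound model: lx chosen to make lateral boundaries
#: irrelevant, ly to hold at least two fringe periods at the lowest
#: frequency, lz with a 10 mm wound depth to keep both media semi-infinite.
DEFAULT_EXTENTS = (28.0, 20.0, 16.0)
#: Healthy skin at 617 nm: musp = 1.42 mm^-1, mua = 0.023 mm^-1, g = 0.9.
SKIN = OpticalProperties.from_musp(mua=0.023, musp=1.42, g=0.9)
#: Offset between the per-phase RNG streams of one three-phase acquisition.
_PHASE_SEED_STRIDE = 1_000_003


@dataclass
class SweepConfig:
    """Grid for the width-accuracy study.

    Defaults reproduce the full study grid: widths 0.5-6 mm, the five
    wound reduced-scattering states, frequencies 0.1-0.3 mm^-1 — at a
    desk-scale photon budget and voxel (the production scale of record is
    0.02 mm voxels and 84e6 photons per phase).
    """

    widths_mm: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 4.0, 6.0)
    wound_musp: tuple[float, ...] = (0.473, 0.71, 1.42, 2.84, 4.73)
    frequencies: tuple[float, ...] = (0.1, 0.2, 0.3)
    thresholds_q: tuple[float, ...] = (0.5,)
    n_photons: int = 1_000_000
    seeds: tuple[int, ...] = (1,)
    voxel_mm: float = 0.1
    bin_mm: float = 0.1
    depth_mm: float = 10.0
    wound_mua: float = 0.023
    skin: OpticalProperties = field(default_factory=lambda: SKIN)
    extents_mm: tuple[float, float, float] = DEFAULT_EXTENTS

    def __post_init__(self) -> None:
        for name in ("widths_mm", "wound_musp", "frequencies", "thresholds_q", "seeds"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be nonempty")
        if self.n_photons <= 0:
            raise ValueError("photon budget must be > 0")


def simulate_three_phase(
    volume,
    frequency: float,
    config: SimulationConfig,
    axis: str = "y",
    modulation_depth: float = 1.0,
) -> tuple[PhaseImageSet, list[DetectorStack]]:
    """Simulate the three phase-shifted acquisitions of one frequency.

    Each phase runs an independent RNG stream derived from ``config.seed``.
    Returns the escape images bundled as a :class:`PhaseImageSet` plus the
    raw detector stacks.
    """
    stacks = []
    for k, phase in enumerate(THREE_PHASES):
        pattern = IlluminationPattern(
            frequency=frequency, phase=phase,
            modulation_depth=modulation_depth, axis=axis,
        )
        cfg_k = SimulationConfig(
            n_photons=config.n_photons,
            seed=config.seed + _PHASE_SEED_STRIDE * k,
            roulette_threshold=config.roulette_threshold,
            roulette_chance=config.roulette_chance,
            bin_mm=config.bin_mm,
            plane_spacing_mm=config.plane_spacing_mm,
            min_scatters_recorded=config.min_scatters_recorded,
            boundary_mode=config.boundary_mode,
            tissue_n=config.tissue_n,
        )
        stack = run_simulation(volume, pattern, cfg_k)
        log.info(
            "phase %d: f=%.3g seed=%d photons=%d ledger residual=%.2e",
            k, frequency, cfg_k.seed, cfg_k.n_photons, stack.ledger_residual,
        )
        stacks.append(stack)
    images = tuple(s.escape_image for s in stacks)
    return (
        PhaseImageSet(images=images, frequency=frequency, pixel_mm=config.bin_mm),
        stacks,
    )


def dc_reflectance_map(
    escape_image: np.ndarray,
    n_photons: int,
    extents_mm: tuple[float, float, float],
    bin_mm: float,
) -> np.ndarray:
    """Escape image in absolute diffuse-reflectance units.

    Normalizes the accumulated escaped weight per bin by the mean launched
    weight per bin, ``n_photons * bin^2 / (lx * ly)``.
    """
    lx, ly = extents_mm[0], extents_mm[1]
    launch_per_bin = n_photons * bin_mm**2 / (lx * ly)
    return np.asarray(escape_image, dtype=float) / launch_per_bin


def ac_reflectance_map(
    phase_set: PhaseImageSet,
    n_photons: int,
    extents_mm: tuple[float, float, float],
    modulation_depth: float = 1.0,
) -> np.ndarray:
    """Demodulated AC image in absolute Rd units.

    The modulated component of the launch density has per-bin amplitude
    ``M`` times the mean, so dividing the demodulated amplitude by
    ``M * launch_per_bin`` yields the tissue's modulation transfer
    amplitude Rd_ac.
    """
    if modulation_depth <= 0:
        raise ValueError("modulation_depth must be > 0 for AC normalization")
    ac = demodulate(phase_set).values
    lx, ly = extents_mm[0], extents_mm[1]
    launch_per_bin = n_photons * phase_set.pixel_mm**2 / (lx * ly)
    return ac / (modulation_depth * launch_per_bin)


def measure_rd(
    musp: float,
    mua: float,
    fx: float,
    n_photons: int,
    seed: int,
    g: float = 0.9,
    voxel_mm: float = 0.1,
    bin_mm: float = 0.1,
    extents_mm: tuple[float, float, float] = DEFAULT_EXTENTS,
    margin_mm: float = 6.0,
    boundary_mode: str = "matched",
    tissue_n: float = 1.4,
) -> float:
    """Monte Carlo diffuse reflectance of a homogeneous medium at ``fx``.

    Simulates planar illumination for fx=0 (one run) or the three-phase
    sinusoidal set otherwise, converts to absolute Rd units and averages
    over the central region (``margin_mm`` in from every edge) where the
    absorbing lateral boundaries have no influence.
    """
    props = OpticalProperties.from_musp(mua=mua, musp=musp, g=g)
    volume = build_homogeneous_volume(props, extents_mm, voxel_mm)
    cfg = SimulationConfig(n_photons=n_photons, seed=seed, bin_mm=bin_mm,
                           boundary_mode=boundary_mode, tissue_n=tissue_n)
    lx, ly = extents_mm[0], extents_mm[1]
    launch_per_bin = n_photons * bin_mm**2 / (lx * ly)
    nbx = int(round(lx / bin_mm))
    nby = int(round(ly / bin_mm))
    x = (np.arange(nbx) + 0.5) * bin_mm
    y = (np.arange(nby) + 0.5) * bin_mm
    mx = (x > margin_mm) & (x < lx - margin_mm)
    my = (y > margin_mm) & (y < ly - margin_mm)
    if fx == 0.0:
        pattern = IlluminationPattern(frequency=0.0, modulation_depth=0.0)
        stack = run_simulation(volume, pattern, cfg)
        rd = stack.escape_image / launch_per_bin
        return float(rd[np.ix_(mx, my)].mean())
    # demodulating a noisy map rectifies noise into a positive bias, so
    # average each phase image over the (unmodulated) x band first and
    # demodulate the clean 1D traces along the modulation axis
    phase_set, _ = simulate_three_phase(volume, fx, cfg)
    traces = tuple(im[mx, :].mean(axis=0, keepdims=True) for im in phase_set.images)
    set_1d = PhaseImageSet(images=traces, frequency=fx, pixel_mm=bin_mm)
    ac = demodulate(set_1d).values[0]
    return float(ac[my].mean()) / launch_per_bin


def wound_profile(
    width_mm: float,
    wound_musp: float,
    frequency: float,
    n_photons: int,
    seed: int,
    voxel_mm: float = 0.1,
    bin_mm: float = 0.1,
    depth_mm: float = 10.0,
    wound_mua: float = 0.023,
    skin: OpticalProperties = SKIN,
    extents_mm: tuple[float, float, float] = DEFAULT_EXTENTS,
) -> tuple[sfdi.Profile, float]:
    """One full pipeline pass: returns (AC profile, realized wound width)."""
    wound = OpticalProperties.from_musp(mua=wound_mua, musp=wound_musp, g=skin.g)
    volume = build_wound_volume(
        skin, wound, WoundSpec(width=width_mm, depth=depth_mm),
        extents_mm, voxel_mm,
    )
    cfg = SimulationConfig(n_photons=n_photons, seed=seed, bin_mm=bin_mm)
    phase_set, _ = simulate_three_phase(volume, frequency, cfg)
    ac = demodulate(phase_set)
    profile = profile_mean(ac)
    return profile, float(volume.realized_wound_width)


def run_width_sweep(config: SweepConfig) -> pd.DataFrame:
    """Run the width x musp x fx x q x seed grid; one row per cell.

    Columns: wound_width_mm, realized_width_mm, musp_wound, fx, q,
    measured_width_mm, error_mm, seed, n_photons, status.  Failed width
    estimates carry NaN measurements and a status naming the failure.
    """
    rows = []
    for width in config.widths_mm:
        for musp in config.wound_musp:
            for fx in config.frequencies:
                for seed in config.seeds:
                    profile, realized = wound_profile(
                        width, musp, fx, config.n_photons, seed,
                        voxel_mm=config.voxel_mm, bin_mm=config.bin_mm,
                        depth_mm=config.depth_mm, wound_mua=config.wound_mua,
                        skin=config.skin, extents_mm=config.extents_mm,
                    )
                    for q in config.thresholds_q:
                        row = {
                            "wound_width_mm": width,
                            "realized_width_mm": realized,
                            "musp_wound": musp,
                            "fx": fx,
                            "q": q,
                            "seed": seed,
                            "n_photons": config.n_photons,
                            "measured_width_mm": np.nan,
                            "error_mm": np.nan,
                            "status": "ok",
                        }
                        try:
                            est = metrology.estimate_width(profile, q=q)
                            rec = metrology.width_error(est, realized)
                            row["measured_width_mm"] = rec.measured
                            row["error_mm"] = rec.error
                        except (metrology.FlatProfileError,
                                metrology.CrossingError) as exc:
                            row["status"] = f"{type(exc).__name__}: {exc}"
                        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deterministic test fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, seed: int, outdir: str = ".") -> list[str]:
    """Write tiny deterministic fixture files; returns the paths.

    Kinds: ``volume`` (8x8x8 wound model, HDF5), ``phases`` (64x64
    three-phase sinusoid TIFFs of known amplitude), ``lut`` (10x10 table,
    HDF5), ``all``.
    """
    import tifffile

    os.makedirs(outdir, exist_ok=True)
    paths: list[str] = []
    if kind in ("volume", "all"):
        wound = OpticalProperties.from_musp(mua=0.023, musp=0.71, g=0.9)
        vol = build_wound_volume(
            SKIN, wound, WoundSpec(width=2.0, depth=5.0), (8.0, 8.0, 8.0), 1.0
        )
        p = os.path.join(outdir, "fixture_volume.h5")
        save_volume(vol, p)
        paths.append(p)
    if kind in ("phases", "all"):
        rng = np.random.default_rng(seed)
        ny = nx = 64
        yy = np.arange(ny) * 0.1
        amp = 0.3 + 0.4 * rng.random()
        offset = 1.0 + amp
        for k, ph in enumerate(THREE_PHASES):
            img = offset + amp * np.cos(2 * np.pi * 0.2 * yy[None, :] + ph)
            img = np.broadcast_to(img, (nx, ny)).astype(np.float32)
            p = os.path.join(outdir, f"fixture_phase{k + 1}.tif")
            tifffile.imwrite(p, img)
            paths.append(p)
        np.savetxt(
            os.path.join(outdir, "fixture_phase_amplitude.txt"), [amp]
        )
        paths.append(os.path.join(outdir, "fixture_phase_amplitude.txt"))
    if kind in ("lut", "all"):
        lut = build_lut(
            0.1,
            np.linspace(0.001, 0.05, 10),
            np.linspace(0.3, 5.0, 10),
            n=1.0,
        )
        p = os.path.join(outdir, "fixture_lut.h5")
        save_lut(lut, p)
        paths.append(p)
    if not paths:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return paths


def checksum(path: str) -> str:
    """SHA-256 of a file, for byte-stability checks of fixtures."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
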