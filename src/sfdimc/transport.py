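"""Monte Carlo photon transport through voxelized tissue.

The propagation scheme follows the classic weighted hop-drop-spin random
walk for turbid media: each photon is launched at the top surface with unit
weight heading straight down, travels an optical depth ``tau = -ln(xi)``
consumed at the local ``mut = mua + mus`` per unit length (sub-stepping at
voxel boundaries in heterogeneous volumes), deposits the fraction
``mua/mut`` of its weight at every interaction site, is redirected by
Henyey-Greenstein sampling, and is terminated unbiasedly by Russian
roulette once its weight falls below a threshold.

Detection is twofold:

* the *escape image* accumulates the weight of photons crossing the top
  surface upward, binned on a regular (x, y) grid — the simulated diffuse
  reflectance image;
* optional *nondestructive detector planes* at regular depth intervals
  record the current weight of every downward plane crossing into a
  ``Weight_down(x, y, z)`` volume, without disturbing the photon.

Illumination is a collimated sinusoidal fringe pattern: launch positions
follow the density ``1 + M cos(2 pi f u + phase)`` along the modulation
axis (default y, so the fringes are orthogonal to the wound's long axis)
and are uniform along the other axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from . import _kernel
from .geometry import TissueVolume

__all__ = [
    "IlluminationPattern",
    "SimulationConfig",
    "Photon",
    "DetectorStack",
    "THREE_PHASES",
    "sample_launch",
    "sample_launch_positions",
    "launch_density",
    "hg_scatter",
    "hg_costheta",
    "run_simulation",
    "save_detector_stack",
    "load_detector_stack",
]

TWO_PI = 2.0 * np.pi
#: The canonical three-phase offsets used for demodulation.
THREE_PHASES = (0.0, TWO_PI / 3.0, 2.0 * TWO_PI / 3.0)


@dataclass(frozen=True)
class IlluminationPattern:
    """Sinusoidal fringe illumination.

    Parameters
    ----------
    frequency : float
        Spatial frequency f (mm^-1) of the projected fringes.
    phase : float
        Phase offset (radians).
    modulation_depth : float
        M in [0, 1]; the launch density ``1 + M cos(...)`` must stay
        nonnegative.  M=0 (or frequency 0) is planar illumination.
    axis : str
        Surface axis along which the intensity varies ("x" or "y").
    """

    frequency: float
    phase: float = 0.0
    modulation_depth: float = 1.0
    axis: str = "y"

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise ValueError("frequency must be >= 0")
        if not (0.0 <= self.modulation_depth <= 1.0):
            raise ValueError(
                f"modulation_depth must lie in [0, 1], got {self.modulation_depth}"
            )
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")


@dataclass(frozen=True)
class SimulationConfig:
    """Run-scale knobs for a single Monte Carlo run.

    ``bin_mm`` is the escape-image bin size (the production-scale default
    is 0.02 mm); ``plane_spacing_mm=None`` disables Weight_down recording.
    ``boundary_mode`` "matched" lets every upward surface crossing escape;
    "mismatched" applies unpolarized Fresnel reflection (with total
    internal reflection) for a tissue/ambient index ratio ``tissue_n``.
    """

    n_photons: int
    seed: int = 0
    roulette_threshold: float = 0.01
    roulette_chance: float = 0.1
    bin_mm: float = 0.02
    plane_spacing_mm: float | None = None
    min_scatters_recorded: int = 0
    boundary_mode: str = "matched"
    tissue_n: float = 1.4

    def __post_init__(self) -> None:
        if self.n_photons < 0:
            raise ValueError("n_photons must be >= 0")
        if not (0.0 < self.roulette_chance < 1.0):
            raise ValueError("roulette_chance must lie in (0, 1)")
        if self.bin_mm <= 0:
            raise ValueError("bin_mm must be > 0")
        if self.boundary_mode not in ("matched", "mismatched"):
            raise ValueError("boundary_mode must be 'matched' or 'mismatched'")


@dataclass
class Photon:
    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    n_scatters: int = 0
    alive: bool = True


@dataclass
class DetectorStack:
    """Binned detector output of one run, with the energy ledger.

    ``escape_image`` is indexed ``[x_bin, y_bin]``; ``weight_down`` (if
    recorded) ``[x_bin, y_bin, plane]`` with plane k at depth
    ``(k+1) * plane_spacing_mm``.
    """

    escape_image: np.ndarray
    bin_mm: float
    weight_down: np.ndarray | None
    plane_spacing_mm: float | None
    launched_total: float
    escaped_total: float
    absorbed_total: float
    lost_lateral_total: float
    roulette_killed_total: float
    min_scatters_recorded: int
    seed: int
    n_photons: int
    pattern: IlluminationPattern | None = None
    extents_mm: tuple[float, float, float] | None = None

    @property
    def ledger_residual(self) -> float:
        """(launched - escaped - absorbed - lost) / launched.

        Zero in expectation; the observed value carries only Russian
        roulette noise and shrinks as 1/sqrt(n_photons).
        """
        if self.launched_total == 0:
            return 0.0
        return (
            self.launched_total
            - self.escaped_total
            - self.absorbed_total
            - self.lost_lateral_total
        ) / self.launched_total

    @property
    def x_bin_centers(self) -> np.ndarray:
        return (np.arange(self.escape_image.shape[0]) + 0.5) * self.bin_mm

    @property
    def y_bin_centers(self) -> np.ndarray:
        return (np.arange(self.escape_image.shape[1]) + 0.5) * self.bin_mm

    @property
    def plane_depths(self) -> np.ndarray:
        if self.weight_down is None or self.plane_spacing_mm is None:
            raise ValueError("no Weight_down recorded in this run")
        return (np.arange(self.weight_down.shape[2]) + 1) * self.plane_spacing_mm


# ---------------------------------------------------------------------------
# launch sampling
# ---------------------------------------------------------------------------

def launch_density(pattern: IlluminationPattern, u: np.ndarray) -> np.ndarray:
    """Unnormalized launch density 1 + M cos(2 pi f u + phase)."""
    return 1.0 + pattern.modulation_depth * np.cos(
        TWO_PI * pattern.frequency * np.asarray(u) + pattern.phase
    )


def _launch_cdf_table(
    pattern: IlluminationPattern, length: float, n_knots: int = 32769
) -> np.ndarray:
    """CDF of the sinusoidal launch density on a uniform grid over [0, length].

    Returns an empty array when the density is uniform (M=0 or f=0), which
    the kernel treats as a plain uniform draw.  The CDF is analytic,
    ``F(y) proportional to y + M/(2 pi f) (sin(2 pi f y + phase) - sin(phase))``,
    and is inverted by binary search + linear interpolation; tabulating on
    a uniform *position* grid (rather than uniform quantiles) keeps the
    sampled density accurate where it approaches zero at M=1.
    """
    f, M, ph = pattern.frequency, pattern.modulation_depth, pattern.phase
    if M == 0.0 or f == 0.0:
        return np.empty(0)
    grid = np.linspace(0.0, length, n_knots)
    cdf = grid + (M / (TWO_PI * f)) * (np.sin(TWO_PI * f * grid + ph) - np.sin(ph))
    cdf -= cdf[0]
    cdf /= cdf[-1]
    return np.maximum.accumulate(cdf)  # guard monotonicity against roundoff


def sample_launch_positions(
    pattern: IlluminationPattern,
    volume: TissueVolume,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """n launch positions (x, y, 0) drawn from the fringe pattern density."""
    lx, ly, _ = volume.extents
    mod_len = ly if pattern.axis == "y" else lx
    table = _launch_cdf_table(pattern, mod_len)
    u1 = rng.random(n)
    u2 = rng.random(n)
    if table.size:
        mod = np.interp(u2, table, np.linspace(0.0, mod_len, table.size))
    else:
        mod = u2 * mod_len
    out = np.zeros((n, 3))
    if pattern.axis == "y":
        out[:, 0] = u1 * lx
        out[:, 1] = mod
    else:
        out[:, 0] = mod
        out[:, 1] = u1 * ly
    return out


def sample_launch(
    pattern: IlluminationPattern,
    volume: TissueVolume,
    rng: np.random.Generator,
) -> Photon:
    """One photon at the surface: collimated normal incidence, unit weight."""
    pos = sample_launch_positions(pattern, volume, 1, rng)[0]
    return Photon(position=pos, direction=np.array([0.0, 0.0, 1.0]))


# ---------------------------------------------------------------------------
# Henyey-Greenstein scattering
# ---------------------------------------------------------------------------

def hg_costheta(g: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Deflection cosines from the Henyey-Greenstein inverse transform."""
    if not (-1.0 < g < 1.0):
        raise ValueError(f"g must lie in (-1, 1), got {g}")
    u = rng.random(size)
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return np.clip((1.0 + g * g - tmp * tmp) / (2.0 * g), -1.0, 1.0)


def hg_scatter(
    direction: np.ndarray, g: float, rng: np.random.Generator
) -> np.ndarray:
    """Redirect a unit vector by one Henyey-Greenstein scattering event."""
    ux, uy, uz = direction
    ct = float(hg_costheta(g, 1, rng)[0])
    sth = np.sqrt(max(0.0, 1.0 - ct * ct))
    phi = TWO_PI * rng.random()
    cp, sp = np.cos(phi), np.sin(phi)
    if abs(uz) > 0.99999:
        new = np.array([sth * cp, sth * sp, ct if uz > 0 else -ct])
    else:
        den = np.sqrt(1.0 - uz * uz)
        new = np.array(
            [
                sth * (ux * uz * cp - uy * sp) / den + ux * ct,
                sth * (uy * uz * cp + ux * sp) / den + uy * ct,
                -sth * cp * den + uz * ct,
            ]
        )
    return new / np.linalg.norm(new)


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def run_simulation(
    volume: TissueVolume,
    pattern: IlluminationPattern,
    config: SimulationConfig,
) -> DetectorStack:
    """Trace ``config.n_photons`` photons and return the detector stack.

    Identical (volume, pattern, config) including the seed reproduce the
    detector grids bit-identically; photons use independent RNG substreams
    so the result does not depend on execution order.
    """
    mua_t, mus_t, g_t, _ = volume.property_tables()
    present = np.unique(volume.labels)
    if np.any((mua_t + mus_t)[present] <= 0.0):
        raise ValueError("every material present needs mua + mus > 0")

    lx, ly, lz = volume.extents
    nbx = max(1, int(round(lx / config.bin_mm)))
    nby = max(1, int(round(ly / config.bin_mm)))
    escape = np.zeros((nbx, nby))

    if config.plane_spacing_mm is not None:
        if config.plane_spacing_mm <= 0:
            raise ValueError("plane_spacing_mm must be > 0")
        plane_dz = float(config.plane_spacing_mm)
        npl = int(np.floor(lz / plane_dz - 1e-9))
        wdown = np.zeros((nbx, nby, npl))
    else:
        plane_dz = -1.0
        wdown = np.zeros((1, 1, 1))

    mod_len = ly if pattern.axis == "y" else lx
    inv_cdf = _launch_cdf_table(pattern, mod_len)

    ledger = _kernel.trace_photons(
        volume.labels,
        volume.safe_distance_map(),
        mua_t,
        mus_t,
        g_t,
        float(volume.voxel_size),
        int(config.n_photons),
        int(config.seed),
        1 if pattern.axis == "y" else 0,
        inv_cdf,
        float(config.bin_mm),
        escape,
        plane_dz,
        wdown,
        int(config.min_scatters_recorded),
        float(config.roulette_threshold),
        float(config.roulette_chance),
        config.boundary_mode == "mismatched",
        float(config.tissue_n),
    )

    return DetectorStack(
        escape_image=escape,
        bin_mm=config.bin_mm,
        weight_down=wdown if plane_dz > 0 else None,
        plane_spacing_mm=config.plane_spacing_mm,
        launched_total=ledger[0],
        escaped_total=ledger[1],
        absorbed_total=ledger[2],
        lost_lateral_total=ledger[3],
        roulette_killed_total=ledger[4],
        min_scatters_recorded=config.min_scatters_recorded,
        seed=config.seed,
        n_photons=config.n_photons,
        pattern=pattern,
        extents_mm=(lx, ly, lz),
    )


def save_detector_stack(stack: DetectorStack, path: str) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset(
            "escape_image",
            data=stack.escape_image,
            compression="gzip",
            track_times=False,
        )
        if stack.weight_down is not None:
            fh.create_dataset(
                "weight_down",
                data=stack.weight_down,
                compression="gzip",
                track_times=False,
            )
            fh.attrs["plane_spacing_mm"] = stack.plane_spacing_mm
        fh.attrs["bin_mm"] = stack.bin_mm
        fh.attrs["launched_total"] = stack.launched_total
        fh.attrs["escaped_total"] = stack.escaped_total
        fh.attrs["absorbed_total"] = stack.absorbed_total
        fh.attrs["lost_lateral_total"] = stack.lost_lateral_total
        fh.attrs["roulette_killed_total"] = stack.roulette_killed_total
        fh.attrs["min_scatters_recorded"] = stack.min_scatters_recorded
        fh.attrs["seed"] = stack.seed
        fh.attrs["n_photons"] = stack.n_photons
        if stack.pattern is not None:
            fh.attrs["pattern_frequency"] = stack.pattern.frequency
            fh.attrs["pattern_phase"] = stack.pattern.phase
            fh.attrs["pattern_modulation_depth"] = stack.pattern.modulation_depth
            fh.attrs["pattern_axis"] = stack.pattern.axis
        if stack.extents_mm is not None:
            fh.attrs["extents_mm"] = stack.extents_mm


def load_detector_stack(path: str) -> DetectorStack:
    with h5py.File(path, "r") as fh:
        escape = fh["escape_image"][()]
        wdown = fh["weight_down"][()] if "weight_down" in fh else None
        plane = float(fh.attrs["plane_spacing_mm"]) if wdown is not None else None
        pattern = None
        if "pattern_frequency" in fh.attrs:
            pattern = IlluminationPattern(
                frequency=float(fh.attrs["pattern_frequency"]),
                phase=float(fh.attrs["pattern_phase"]),
                modulation_depth=float(fh.attrs["pattern_modulation_depth"]),
                axis=str(fh.attrs["pattern_axis"]),
            )
        ext = fh.attrs.get("extents_mm")
        return DetectorStack(
            escape_image=escape,
            bin_mm=float(fh.attrs["bin_mm"]),
            weight_down=wdown,
            plane_spacing_mm=plane,
            launched_total=float(fh.attrs["launched_total"]),
            escaped_total=float(fh.attrs["escaped_total"]),
            absorbed_total=float(fh.attrs["absorbed_total"]),
            lost_lateral_total=float(fh.attrs["lost_lateral_total"]),
            roulette_killed_total=float(fh.attrs["roulette_killed_total"]),
            min_scatters_recorded=int(fh.attrs["min_scatters_recorded"]),
            seed=int(fh.attrs["seed"]),
            n_photons=int(fh.attrs["n_photons"]),
            pattern=pattern,
            extents_mm=None if ext is None else tuple(float(v) for v in ext),
        )
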