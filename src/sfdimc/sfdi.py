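"""SFDI processing: demodulation, profiles, forward model, calibration, LUT.

Spatial frequency domain imaging projects sinusoidal fringes at three
phase offsets (0, 2pi/3, 4pi/3), demodulates the three diffuse-reflectance
images into the modulated-amplitude "AC" image, calibrates it against a
reference of known optical properties, and inverts a two-dimensional
lookup table built on the (planar, modulated) diffuse-reflectance pair
(Rd_dc, Rd_ac) to recover per-pixel absorption and reduced scattering.

The demodulation prefactor deserves a note: the canonical identity

    I_AC = (sqrt(2)/3) * sqrt((I1-I2)^2 + (I1-I3)^2 + (I2-I3)^2)

returns exactly the modulation amplitude B for an ideal three-phase
sinusoid A + B cos(theta + phase_i).  A literal prefactor 2/3, which some
of the literature prints, returns sqrt(2)*B instead; it is available via
``convention="literal"``.  Width metrology is invariant to the choice,
being a global scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .geometry import OpticalProperties

__all__ = [
    "PhaseImageSet",
    "ACImage",
    "Profile",
    "LUT",
    "demodulate",
    "dc_demodulate",
    "profile_mean",
    "bin_image",
    "diffusion_rd",
    "calibrate",
    "build_lut",
    "invert_lut",
    "save_lut",
    "load_lut",
]


@dataclass
class PhaseImageSet:
    """Three phase-shifted reflectance images on a common raster."""

    images: tuple[np.ndarray, np.ndarray, np.ndarray]
    frequency: float
    pixel_mm: float
    phases: tuple[float, float, float] = (
        0.0,
        2.0 * np.pi / 3.0,
        4.0 * np.pi / 3.0,
    )

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.images}
        if len(shapes) != 1:
            raise ValueError(f"phase images must share a shape, got {shapes}")


@dataclass
class ACImage:
    """Demodulated amplitude image (nonnegative by construction)."""

    values: np.ndarray
    frequency: float
    pixel_mm: float


@dataclass
class Profile:
    """1D trace across the wound: y-averaged AC intensity or musp."""

    x: np.ndarray
    values: np.ndarray
    n_averaged: int = 1

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.x.shape != self.values.shape:
            raise ValueError("x and values must have equal length")
        if self.x.size > 1 and not np.all(np.diff(self.x) > 0):
            raise ValueError("x must be strictly increasing")


def demodulate(phase_set: PhaseImageSet, convention: str = "amplitude") -> ACImage:
    """Three-phase demodulation into the AC amplitude image.

    ``convention="amplitude"`` uses the sqrt(2)/3 prefactor (an ideal
    sinusoid of amplitude B demodulates to exactly B); ``"literal"`` uses
    2/3 (returns sqrt(2) B), kept for strict comparability with processing
    chains that use that constant.
    """
    i1, i2, i3 = (np.asarray(im, dtype=float) for im in phase_set.images)
    if convention == "amplitude":
        pref = np.sqrt(2.0) / 3.0
    elif convention == "literal":
        pref = 2.0 / 3.0
    else:
        raise ValueError("convention must be 'amplitude' or 'literal'")
    ac = pref * np.sqrt((i1 - i2) ** 2 + (i1 - i3) ** 2 + (i2 - i3) ** 2)
    return ACImage(values=ac, frequency=phase_set.frequency, pixel_mm=phase_set.pixel_mm)


def dc_demodulate(phase_set: PhaseImageSet) -> np.ndarray:
    """Planar (DC) component: the pixelwise mean of the three phases."""
    i1, i2, i3 = (np.asarray(im, dtype=float) for im in phase_set.images)
    return (i1 + i2 + i3) / 3.0


def profile_mean(
    image: np.ndarray | ACImage,
    pixel_mm: float | None = None,
    axis: int = 1,
) -> Profile:
    """Average a 2D map along the modulation axis into a 1D profile.

    For an image indexed ``[x, y]`` the default ``axis=1`` averages over y,
    yielding the across-the-wound trace; ``n_averaged`` reports how many
    rows went into each point.
    """
    if isinstance(image, ACImage):
        pixel_mm = image.pixel_mm
        image = image.values
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a nonempty 2D array")
    if pixel_mm is None:
        pixel_mm = 1.0
    values = arr.mean(axis=axis)
    x = (np.arange(values.size) + 0.5) * pixel_mm
    return Profile(x=x, values=values, n_averaged=arr.shape[axis])


def bin_image(image: np.ndarray, factor: int = 5) -> np.ndarray:
    """Block-average by ``factor`` in both axes (trailing partial blocks
    are dropped), the usual raw-image pre-binning step for camera data."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    arr = np.asarray(image, dtype=float)
    nx, ny = (arr.shape[0] // factor) * factor, (arr.shape[1] // factor) * factor
    if nx == 0 or ny == 0:
        raise ValueError("image smaller than the binning window")
    return (
        arr[:nx, :ny]
        .reshape(nx // factor, factor, ny // factor, factor)
        .mean(axis=(1, 3))
    )


# ---------------------------------------------------------------------------
# diffusion forward model
# ---------------------------------------------------------------------------

def _reff(n: float) -> float:
    """Effective internal reflection coefficient, standard polynomial in n."""
    return 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2


def diffusion_rd(
    mua: float | np.ndarray,
    musp: float | np.ndarray,
    fx: float | np.ndarray,
    n: float = 1.4,
) -> float | np.ndarray:
    """Diffuse reflectance of a homogeneous semi-infinite medium at
    spatial frequency ``fx`` under the standard diffusion approximation.

    With ``mutr = mua + musp``, albedo ``a' = musp/mutr`` and
    ``mueff' = sqrt(3 mua mutr + (2 pi fx)^2)``:

        Rd = 3 A a' / ((mueff'/mutr + 1)(mueff'/mutr + 3A)),
        A = (1 - Reff) / (2 (1 + Reff)).

    For index-matched boundaries (n=1) Reff is ~0 and A ~ 1/2.
    """
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    if np.any(musp <= 0):
        raise ValueError("musp must be > 0")
    if np.any(mua < 0):
        raise ValueError("mua must be >= 0")
    mutr = mua + musp
    ap = musp / mutr
    mueff = np.sqrt(3.0 * mua * mutr + (2.0 * np.pi * np.asarray(fx)) ** 2)
    reff = _reff(n)
    big_a = (1.0 - reff) / (2.0 * (1.0 + reff))
    ratio = mueff / mutr
    rd = 3.0 * big_a * ap / ((ratio + 1.0) * (ratio + 3.0 * big_a))
    return rd if rd.ndim else float(rd)


def calibrate(
    raw_sample: ACImage,
    raw_reference: ACImage,
    reference_props: OpticalProperties,
    fx: float | None = None,
) -> np.ndarray:
    """Convert raw demodulated intensity to diffuse reflectance.

    Ratioing the sample against a homogeneous reference of known optical
    properties, whose Rd is predicted by the diffusion model, removes the
    system's source intensity and transfer function:
    ``Rd_sample = raw_sample / raw_reference * Rd_model(reference)``.
    """
    if raw_sample.values.shape != raw_reference.values.shape:
        raise ValueError("sample and reference must share a raster")
    if fx is None:
        fx = raw_sample.frequency
    bad = int(np.count_nonzero(raw_reference.values <= 0))
    if bad:
        raise ValueError(
            f"reference image has {bad} nonpositive pixel(s); cannot ratio"
        )
    rd_ref = diffusion_rd(
        reference_props.mua, reference_props.musp, fx, reference_props.n
    )
    return raw_sample.values / raw_reference.values * rd_ref


# ---------------------------------------------------------------------------
# lookup-table inversion
# ---------------------------------------------------------------------------

@dataclass
class LUT:
    """Forward table (Rd_dc, Rd_ac) over a (mua, musp) grid at one fx pair.

    Inversion is piecewise-linear in reflectance space: a Delaunay
    triangulation of the forward points carries barycentric interpolation
    of the generating (mua, musp); pixels outside the convex range are
    flagged, never extrapolated.
    """

    fx: float
    mua_grid: np.ndarray
    musp_grid: np.ndarray
    rd_dc: np.ndarray  # shape (len(mua_grid), len(musp_grid))
    rd_ac: np.ndarray
    n: float = 1.4
    _interp: object = field(default=None, repr=False, compare=False)

    def _interpolator(self):
        if self._interp is None:
            from scipy.interpolate import LinearNDInterpolator

            pts = np.column_stack([self.rd_dc.ravel(), self.rd_ac.ravel()])
            mm, ss = np.meshgrid(self.mua_grid, self.musp_grid, indexing="ij")
            vals = np.column_stack([mm.ravel(), ss.ravel()])
            self._interp = LinearNDInterpolator(pts, vals)
        return self._interp


def build_lut(
    fx: float,
    mua_grid: np.ndarray,
    musp_grid: np.ndarray,
    n: float = 1.4,
) -> LUT:
    """Tabulate the diffusion forward model on a strictly increasing grid."""
    mua_grid = np.asarray(mua_grid, dtype=float)
    musp_grid = np.asarray(musp_grid, dtype=float)
    for name, grid in (("mua_grid", mua_grid), ("musp_grid", musp_grid)):
        if grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError(f"{name} must be strictly increasing with >= 2 points")
    mm, ss = np.meshgrid(mua_grid, musp_grid, indexing="ij")
    rd_dc = diffusion_rd(mm, ss, 0.0, n)
    rd_ac = diffusion_rd(mm, ss, fx, n)
    return LUT(fx=fx, mua_grid=mua_grid, musp_grid=musp_grid,
               rd_dc=rd_dc, rd_ac=rd_ac, n=n)


def invert_lut(
    rd_dc: np.ndarray,
    rd_ac: np.ndarray,
    lut: LUT,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel (mua, musp) from measured (Rd_dc, Rd_ac) maps.

    Returns ``(mua, musp, out_of_range)``; out-of-range pixels (outside
    the table's convex span in reflectance space) hold NaN and are flagged
    True.  Raises if *every* pixel falls out of range.
    """
    rd_dc = np.asarray(rd_dc, dtype=float)
    rd_ac = np.asarray(rd_ac, dtype=float)
    if rd_dc.shape != rd_ac.shape:
        raise ValueError("rd_dc and rd_ac must share a shape")
    interp = lut._interpolator()
    res = interp(np.column_stack([rd_dc.ravel(), rd_ac.ravel()]))
    mua = res[:, 0].reshape(rd_dc.shape)
    musp = res[:, 1].reshape(rd_dc.shape)
    flagged = ~np.isfinite(mua)
    if flagged.all():
        raise ValueError("all pixels fall outside the LUT range")
    return mua, musp, flagged


def save_lut(lut: LUT, path: str, provenance: str = "diffusion") -> None:
    with h5py.File(path, "w") as fh:
        for name, data in (
            ("mua_grid", lut.mua_grid),
            ("musp_grid", lut.musp_grid),
            ("rd_dc", lut.rd_dc),
            ("rd_ac", lut.rd_ac),
        ):
            fh.create_dataset(name, data=data, track_times=False)
        fh.attrs["fx"] = lut.fx
        fh.attrs["n"] = lut.n
        fh.attrs["generator"] = provenance


def load_lut(path: str) -> LUT:
    with h5py.File(path, "r") as fh:
        return LUT(
            fx=float(fh.attrs["fx"]),
            mua_grid=fh["mua_grid"][()],
            musp_grid=fh["musp_grid"][()],
            rd_dc=fh["rd_dc"][()],
            rd_ac=fh["rd_ac"][()],
            n=float(fh.attrs["n"]),
        )
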