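"""Voxelized tissue volumes for the surgical-wound imaging model.

The model system is a rectangular block of homogeneous skin with a
rectangular "wound" embedded at its center: the wound spans the full
extent of the block along y (the incision's long axis), has a finite
width along x and a finite depth along z, and presents sharp vertical
optical-property boundaries to the light — the geometry that produces
the partial-volume / edge-response artifacts this package quantifies.

Coordinate convention: x runs across the wound width, y along the wound
long axis, z increases *downward* from the illuminated surface at z=0.
Voxel ``i`` along an axis covers the half-open interval
``[i*voxel, (i+1)*voxel)`` in mm; all indices are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import yaml

__all__ = [
    "OpticalProperties",
    "TissueVolume",
    "WoundSpec",
    "build_homogeneous_volume",
    "build_wound_volume",
    "volume_from_config",
    "save_volume",
    "load_volume",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one tissue type.

    Parameters
    ----------
    mua : float
        Absorption coefficient (mm^-1).
    mus : float
        Scattering coefficient (mm^-1).
    g : float
        Scattering anisotropy, the mean cosine of the single-scattering
        deflection angle; must lie strictly inside (-1, 1).
    n : float
        Refractive index (>= 1).
    """

    mua: float
    mus: float
    g: float = 0.9
    n: float = 1.4

    def __post_init__(self) -> None:
        if self.mua < 0:
            raise ValueError(f"mua must be >= 0, got {self.mua}")
        if self.mus < 0:
            raise ValueError(f"mus must be >= 0, got {self.mus}")
        if not (-1.0 < self.g < 1.0):
            raise ValueError(f"g must lie in (-1, 1), got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def musp(self) -> float:
        """Reduced scattering coefficient mus * (1 - g), in mm^-1."""
        return self.mus * (1.0 - self.g)

    @classmethod
    def from_musp(
        cls, mua: float, musp: float, g: float = 0.9, n: float = 1.4
    ) -> "OpticalProperties":
        """Build from the reduced scattering coefficient (mus = musp/(1-g))."""
        if not (-1.0 < g < 1.0):
            raise ValueError(f"g must lie in (-1, 1), got {g}")
        return cls(mua=mua, mus=musp / (1.0 - g), g=g, n=n)

    def to_dict(self) -> dict:
        return {"mua": self.mua, "mus": self.mus, "g": self.g, "n": self.n}


@dataclass(frozen=True)
class WoundSpec:
    """Geometry of the centered rectangular wound.

    ``width`` is measured along x, ``depth`` along z from the surface.
    The wound spans the full y extent (long axis along y).
    """

    width: float
    depth: float
    skin_label: int = 0
    wound_label: int = 1

    def __post_init__(self) -> None:
        if self.width < 0:
            raise ValueError(f"wound width must be >= 0, got {self.width}")
        if self.depth <= 0:
            raise ValueError(f"wound depth must be > 0, got {self.depth}")
        if self.skin_label == self.wound_label:
            raise ValueError("skin_label and wound_label must differ")


@dataclass
class TissueVolume:
    """A 3D voxel label grid plus the label -> optical-properties table.

    ``labels`` is indexed ``[ix, iy, iz]``; every label value occurring in
    the grid must have an entry in ``properties``.
    """

    labels: np.ndarray
    voxel_size: float
    properties: dict[int, OpticalProperties]
    realized_wound_width: float | None = None
    wound_depth: float | None = None
    _safe_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if min(self.labels.shape) < 1:
            raise ValueError("all dims must be >= 1")
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.properties)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no properties entry")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def extents(self) -> tuple[float, float, float]:
        """Physical lengths (lx, ly, lz) in mm."""
        nx, ny, nz = self.labels.shape
        d = self.voxel_size
        return (nx * d, ny * d, nz * d)

    def property_tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Dense per-label (mua, mus, g, n) arrays indexed by label value."""
        nmax = int(self.labels.max()) + 1
        mua = np.zeros(nmax)
        mus = np.zeros(nmax)
        g = np.zeros(nmax)
        n = np.ones(nmax)
        for lab, p in self.properties.items():
            if 0 <= lab < nmax:
                mua[lab], mus[lab], g[lab], n[lab] = p.mua, p.mus, p.g, p.n
        return mua, mus, g, n

    def safe_distance_map(self) -> np.ndarray:
        """Per-voxel guaranteed free-flight distance (mm, float32).

        From any point inside voxel v, a straight segment shorter than
        ``safe[v]`` is guaranteed to stay in voxels sharing v's label and
        not to leave the volume through a lateral or bottom face.  The top
        surface (z=0) is deliberately *excluded* from the bound: the
        transport kernel treats upward surface crossings analytically, so
        free flights may run right up to the surface.  Cached per volume;
        the wound/homogeneous builders install an exact analytic map, and
        arbitrary label grids fall back to a Euclidean distance transform.
        """
        if self._safe_cache is None:
            from scipy.ndimage import distance_transform_edt

            d = self.voxel_size
            padded = np.pad(self.labels, 1, constant_values=-1)
            # top padding layer mirrors the surface labels: z=0 is not a
            # free-flight barrier (handled analytically in the kernel)
            padded[:, :, 0] = padded[:, :, 1]
            out = np.zeros(self.labels.shape, dtype=np.float32)
            for lab in np.unique(self.labels):
                mask = padded == lab
                dist = distance_transform_edt(mask, sampling=d)
                core = dist[1:-1, 1:-1, 1:-1]
                sel = self.labels == lab
                out[sel] = core[sel]
            # center-to-center distance minus one voxel diagonal is a
            # conservative point-to-point bound
            np.maximum(out - np.sqrt(3.0) * d, 0.0, out=out)
            self._safe_cache = out
        return self._safe_cache


def _dims_from_extents(extents, voxel_size: float) -> tuple[int, int, int]:
    if voxel_size <= 0:
        raise ValueError(f"voxel_size must be > 0, got {voxel_size}")
    dims = []
    for e in extents:
        if e <= 0:
            raise ValueError(f"extents must be positive, got {extents}")
        dims.append(max(1, int(round(e / voxel_size))))
    return tuple(dims)  # type: ignore[return-value]


def _exterior_safe_base(dims: tuple[int, int, int], d: float) -> np.ndarray:
    """Voxel-face distance to the lateral and bottom volume faces (not the
    top), the exact free-flight bound for a homogeneous block."""
    nx, ny, nz = dims
    ix = np.arange(nx, dtype=np.float32)
    iy = np.arange(ny, dtype=np.float32)
    iz = np.arange(nz, dtype=np.float32)
    sx = np.minimum(ix, nx - 1 - ix) * d
    sy = np.minimum(iy, ny - 1 - iy) * d
    sz = (nz - 1 - iz) * d  # bottom only; the top surface is kernel-handled
    return np.minimum(
        np.minimum(sx[:, None, None], sy[None, :, None]), sz[None, None, :]
    ).astype(np.float32)


def build_homogeneous_volume(
    props: OpticalProperties,
    extents: tuple[float, float, float],
    voxel_size: float,
    label: int = 0,
) -> TissueVolume:
    """A single-material block, e.g. healthy skin or a calibration phantom."""
    dims = _dims_from_extents(extents, voxel_size)
    labels = np.full(dims, label, dtype=np.int8)
    vol = TissueVolume(
        labels=labels, voxel_size=voxel_size, properties={label: props}
    )
    vol._safe_cache = _exterior_safe_base(dims, voxel_size)
    return vol


def build_wound_volume(
    skin: OpticalProperties,
    wound: OpticalProperties,
    spec: WoundSpec,
    extents: tuple[float, float, float],
    voxel_size: float,
) -> TissueVolume:
    """Skin block with a centered rectangular wound of given width and depth.

    The wound fills voxels with ``|x - lx/2| < width/2`` (snapped to voxel
    boundaries symmetrically about the center), all of y, and
    ``0 <= z < depth``.  The snapped ("realized") width is reported back on
    the volume and is what width metrology treats as ground truth.
    """
    dims = _dims_from_extents(extents, voxel_size)
    nx, ny, nz = dims
    d = voxel_size
    lx, lz = nx * d, nz * d
    if spec.width > lx:
        raise ValueError(f"wound width {spec.width} exceeds lx={lx}")
    if spec.depth > lz:
        raise ValueError(f"wound depth {spec.depth} exceeds lz={lz}")

    labels = np.full(dims, spec.skin_label, dtype=np.int8)
    # snap each wound boundary to the nearest voxel face; with the wound
    # centered on a voxel face (even nx) round-half-even keeps the pair
    # symmetric about lx/2
    a = int(np.round(nx / 2.0 - spec.width / (2.0 * d)))
    b = int(np.round(nx / 2.0 + spec.width / (2.0 * d)))
    a, b = max(a, 0), min(b, nx)
    kz = min(int(np.round(spec.depth / d)), nz)
    realized = (b - a) * d
    if b > a and kz > 0:
        labels[a:b, :, :kz] = spec.wound_label

    props = {spec.skin_label: skin}
    if b > a and kz > 0:
        props[spec.wound_label] = wound
    vol = TissueVolume(
        labels=labels,
        voxel_size=d,
        properties=props,
        realized_wound_width=realized if b > a else 0.0,
        wound_depth=kz * d if b > a else None,
    )

    # exact analytic free-flight bound for the box-in-block geometry
    safe = _exterior_safe_base(dims, d)
    if b > a and kz > 0:
        ix = np.arange(nx, dtype=np.float32)
        iz = np.arange(nz, dtype=np.float32)
        # skin voxels: Euclidean face distance to the wound box in (x, z)
        dxo = np.maximum(np.maximum(a - ix - 1.0, ix - b), 0.0) * d
        dzo = np.maximum(iz - kz, 0.0) * d
        d_box = np.hypot(dxo[:, None], dzo[None, :]).astype(np.float32)
        np.minimum(safe, d_box[:, None, :], out=safe)
        # wound voxels: distance to the box's own bounding planes
        iy = np.arange(ny, dtype=np.float32)
        wx = np.minimum(ix[a:b] - a, b - 1 - ix[a:b]) * d
        wy = np.minimum(iy, ny - 1 - iy) * d
        wz = (kz - 1 - iz[:kz]) * d
        safe[a:b, :, :kz] = np.minimum(
            np.minimum(wx[:, None, None], wy[None, :, None]),
            wz[None, None, :],
        )
    vol._safe_cache = safe
    return vol


# ---------------------------------------------------------------------------
# configuration files and serialization
# ---------------------------------------------------------------------------

def _props_from_mapping(m: dict) -> OpticalProperties:
    g = float(m.get("g", 0.9))
    n = float(m.get("n", 1.4))
    if "musp" in m:
        return OpticalProperties.from_musp(float(m["mua"]), float(m["musp"]), g=g, n=n)
    return OpticalProperties(float(m["mua"]), float(m["mus"]), g=g, n=n)


def volume_from_config(config: dict | str) -> TissueVolume:
    """Build a volume from a YAML/JSON-style mapping (or path to one).

    Schema::

        extents_mm: [28.0, 20.0, 16.0]
        voxel_mm: 0.1
        skin:  {mua: 0.023, musp: 1.42, g: 0.9, n: 1.4}
        wound: {mua: 0.023, musp: 0.71, g: 0.9, n: 1.4,
                width_mm: 2.0, depth_mm: 10.0}   # optional

    ``musp`` plus ``g`` are given and ``mus`` is derived.
    """
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    extents = tuple(float(v) for v in config["extents_mm"])
    voxel = float(config["voxel_mm"])
    skin = _props_from_mapping(config["skin"])
    if "wound" not in config or config["wound"] is None:
        return build_homogeneous_volume(skin, extents, voxel)
    w = config["wound"]
    wound = _props_from_mapping(w)
    spec = WoundSpec(width=float(w["width_mm"]), depth=float(w["depth_mm"]))
    return build_wound_volume(skin, wound, spec, extents, voxel)


def save_volume(volume: TissueVolume, path: str) -> None:
    """Write a volume to HDF5 (labels + voxel size + JSON properties table)."""
    with h5py.File(path, "w") as fh:
        # track_times=False keeps files byte-stable for fixture checksums
        fh.create_dataset(
            "labels", data=volume.labels, compression="gzip", track_times=False
        )
        fh.attrs["voxel_size_mm"] = volume.voxel_size
        fh.attrs["extents_mm"] = volume.extents
        fh.attrs["properties"] = json.dumps(
            {str(k): p.to_dict() for k, p in volume.properties.items()}
        )
        if volume.realized_wound_width is not None:
            fh.attrs["realized_wound_width_mm"] = volume.realized_wound_width
        if volume.wound_depth is not None:
            fh.attrs["wound_depth_mm"] = volume.wound_depth


def load_volume(path: str) -> TissueVolume:
    with h5py.File(path, "r") as fh:
        labels = fh["labels"][()]
        voxel = float(fh.attrs["voxel_size_mm"])
        props = {
            int(k): OpticalProperties(**v)
            for k, v in json.loads(fh.attrs["properties"]).items()
        }
        rw = fh.attrs.get("realized_wound_width_mm")
        wd = fh.attrs.get("wound_depth_mm")
    return TissueVolume(
        labels=labels,
        voxel_size=voxel,
        properties=props,
        realized_wound_width=None if rw is None else float(rw),
        wound_depth=None if wd is None else float(wd),
    )
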