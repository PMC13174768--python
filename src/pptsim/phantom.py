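"""Voxelized phantoms and emission-source maps.

A :class:`PhantomGrid` holds a per-voxel material index map and an aligned
emission-density map on a right-handed grid whose origin sits at the
phantom center; all lengths are in mm.  Builders cover the homogeneous
calibration cubes and the cylindrical insert phantoms (six-material
inserts, four water rods of graded diameter, and a small-animal style
cylinder with two cold inserts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .nucdata import MATERIALS, get_material

__all__ = [
    "PhantomGrid",
    "CylinderInsert",
    "build_cube",
    "build_cylinder_phantom",
    "sample_emission",
    "CLINICAL_PRESETS",
]


@dataclass
class PhantomGrid:
    """Voxel phantom: material indices plus an emission-density map.

    ``material_map`` stores indices into ``materials`` (a tuple of registry
    names); ``source_map`` is nonnegative and normalized to sum to 1 when a
    source is present.  The world origin is at the grid center; voxel (i,
    j, k) spans ``origin + [i, j, k] * voxel_size`` to ``+ voxel_size``.
    """

    material_map: np.ndarray  # uint8, shape (nx, ny, nz)
    voxel_size: np.ndarray  # mm, shape (3,)
    materials: tuple[str, ...]
    source_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.material_map = np.ascontiguousarray(self.material_map, dtype=np.uint8)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float) * np.ones(3)
        for name in self.materials:
            get_material(name)  # raises for unregistered materials
        if self.material_map.max(initial=0) >= len(self.materials):
            raise ValueError("material_map index outside materials tuple")
        if self.source_map is not None:
            self.source_map = np.asarray(self.source_map, dtype=float)
            if self.source_map.shape != self.material_map.shape:
                raise ValueError("source_map shape must match material_map")
            if np.any(self.source_map < 0):
                raise ValueError("source_map must be nonnegative")
            tot = self.source_map.sum()
            if tot > 0:
                self.source_map = self.source_map / tot

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.material_map.shape

    @property
    def origin(self) -> np.ndarray:
        """World coordinate (mm) of the low corner of voxel (0, 0, 0)."""
        return -0.5 * np.asarray(self.shape) * self.voxel_size

    @property
    def extent(self) -> np.ndarray:
        """Half-size of the grid along each axis, mm."""
        return 0.5 * np.asarray(self.shape) * self.voxel_size

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]

    def voxel_index(self, positions: np.ndarray) -> np.ndarray:
        """Voxel indices (n, 3) of world positions (n, 3); may be out of range."""
        p = np.atleast_2d(positions)
        return np.floor((p - self.origin) / self.voxel_size).astype(np.int64)

    def contains(self, positions: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(positions)
        half = self.extent
        return np.all((p >= -half) & (p < half), axis=1)

    def material_at(self, positions: np.ndarray) -> np.ndarray:
        """Material index at each position (positions must be inside)."""
        idx = self.voxel_index(positions)
        idx = np.clip(idx, 0, np.asarray(self.shape) - 1)
        return self.material_map[idx[:, 0], idx[:, 1], idx[:, 2]]

    def to_nifti(self, path, sidecar: bool = True) -> None:
        """Write the material label map as NIfTI plus a YAML sidecar."""
        import nibabel as nib

        affine = np.diag([*self.voxel_size, 1.0])
        affine[:3, 3] = self.origin + 0.5 * self.voxel_size
        img = nib.Nifti1Image(self.material_map.astype(np.int16), affine)
        nib.save(img, str(path))
        if sidecar:
            meta = {
                "materials": list(self.materials),
                "voxel_size_mm": [float(v) for v in self.voxel_size],
                "has_source": bool(
                    self.source_map is not None and self.source_map.sum() > 0
                ),
            }
            with open(str(path) + ".yaml", "w") as f:
                yaml.safe_dump(meta, f)


@dataclass(frozen=True)
class CylinderInsert:
    """Axial cylindrical insert: center (mm), diameter/length (mm)."""

    center: tuple[float, float, float]
    diameter: float
    length: float
    material: str
    has_source: bool = True


def build_cube(
    side: float,
    material: str = "water",
    source: str = "point",
    voxel_size: float = 1.0,
) -> PhantomGrid:
    """Homogeneous cube of ``side`` mm with a point or uniform source.

    A ``point`` source occupies the single central voxel (the voxel count
    per axis is forced odd so a central voxel exists); ``uniform`` spreads
    the source over the whole cube; ``none`` builds a cold cube.
    """
    if side <= 0:
        raise ValueError("cube side must be positive")
    get_material(material)
    n = max(1, int(round(side / voxel_size)))
    if n % 2 == 0:
        n += 1  # keep a voxel centered on the origin
    vox = side / n
    mat = np.zeros((n, n, n), dtype=np.uint8)
    src = np.zeros((n, n, n))
    if source == "point":
        c = n // 2
        src[c, c, c] = 1.0
    elif source == "uniform":
        src[:] = 1.0
    elif source != "none":
        raise ValueError(f"source must be point|uniform|none, got {source!r}")
    return PhantomGrid(mat, np.full(3, vox), (material,), src)


# clinical cylinder: 20 cm diameter x 20 cm length water background.
# Insert centers are not uniquely fixed by the published figures; these
# presets place them on a 50 mm radius ring, centered axially.
_R_OFFSET = 50.0

CLINICAL_PRESETS: dict[str, list[CylinderInsert]] = {
    "six_insert": [
        CylinderInsert(
            (
                _R_OFFSET * np.cos(np.deg2rad(60.0 * i)),
                _R_OFFSET * np.sin(np.deg2rad(60.0 * i)),
                0.0,
            ),
            20.0,
            38.0,
            m,
        )
        for i, m in enumerate(["water", "adipose", "lung", "brain", "bone", "air"])
    ],
    "four_rod": [
        CylinderInsert(
            (
                _R_OFFSET * np.cos(np.deg2rad(90.0 * i)),
                _R_OFFSET * np.sin(np.deg2rad(90.0 * i)),
                0.0,
            ),
            d,
            38.0,
            "water",
        )
        for i, d in enumerate([8.0, 12.0, 16.0, 25.0])
    ],
}


def build_cylinder_phantom(
    preset,
    voxel_size: float | None = None,
    background: str = "water",
    background_source: bool = False,
) -> PhantomGrid:
    """Water cylinder phantom with cylindrical inserts.

    ``preset`` is ``"six_insert"``, ``"four_rod"``, ``"nu4_small"`` or an
    explicit list of :class:`CylinderInsert`.  The clinical presets use a
    20 cm diameter x 20 cm long water background (2 mm voxels by default)
    surrounded by air; sources are uniform inside the source-flagged
    inserts.  The ``nu4_small`` preset is a 30 mm diameter x 50 mm water
    cylinder with uniform activity and two cold 8 mm x 14 mm inserts
    (water and air), on 1 mm voxels.
    """
    if preset == "nu4_small":
        inserts = [
            CylinderInsert((0.0, 7.0, 0.0), 8.0, 14.0, "water", has_source=False),
            CylinderInsert((0.0, -7.0, 0.0), 8.0, 14.0, "air", has_source=False),
        ]
        bg_d, bg_len = 30.0, 50.0
        vox = 1.0 if voxel_size is None else voxel_size
        background_source = True
    else:
        if isinstance(preset, str):
            if preset not in CLINICAL_PRESETS:
                raise ValueError(
                    f"unknown preset {preset!r}; choose from "
                    f"{sorted(CLINICAL_PRESETS) + ['nu4_small']} or pass inserts"
                )
            inserts = CLINICAL_PRESETS[preset]
        else:
            inserts = list(preset)
        bg_d, bg_len = 200.0, 200.0
        vox = 2.0 if voxel_size is None else voxel_size

    names = [background, "air"]
    for ins in inserts:
        if ins.material not in names:
            names.append(ins.material)
    materials = tuple(names)

    nxy = int(np.ceil(bg_d / vox))
    nz = int(np.ceil(bg_len / vox))
    if nxy % 2 == 0:
        nxy += 1
    if nz % 2 == 0:
        nz += 1
    shape = (nxy, nxy, nz)
    vs = np.full(3, vox)
    origin = -0.5 * np.asarray(shape) * vs
    x = origin[0] + (np.arange(shape[0]) + 0.5) * vox
    y = origin[1] + (np.arange(shape[1]) + 0.5) * vox
    z = origin[2] + (np.arange(shape[2]) + 0.5) * vox
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")

    mat = np.full(shape, names.index("air"), dtype=np.uint8)
    in_bg = (xx**2 + yy**2 <= (bg_d / 2) ** 2) & (np.abs(zz) <= bg_len / 2)
    mat[in_bg] = names.index(background)
    src = np.zeros(shape)
    if background_source:
        src[in_bg] = 1.0

    claimed = np.zeros(shape, dtype=bool)
    for ins in inserts:
        cx, cy, cz = ins.center
        mask = ((xx - cx) ** 2 + (yy - cy) ** 2 <= (ins.diameter / 2) ** 2) & (
            np.abs(zz - cz) <= ins.length / 2
        )
        if np.any(mask & claimed):
            raise ValueError(f"insert at {ins.center} overlaps another insert")
        claimed |= mask
        mat[mask] = names.index(ins.material)
        src[mask] = 1.0 if ins.has_source else 0.0

    return PhantomGrid(mat, vs, materials, src)


def sample_emission(
    grid: PhantomGrid, rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Sample ``n`` emission positions (mm) from the grid's source map.

    Voxels are chosen with probability proportional to the emission
    density; positions are uniform within each chosen voxel.
    """
    if grid.source_map is None or grid.source_map.sum() == 0:
        raise RuntimeError("phantom has no emission source")
    p = grid.source_map.ravel()
    flat = rng.choice(p.size, size=n, p=p)
    idx = np.stack(np.unravel_index(flat, grid.shape), axis=1).astype(float)
    jitter = rng.random((n, 3))
    return grid.origin + (idx + jitter) * grid.voxel_size
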