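"""Synthetic voxel phantoms for BNCT positioning studies.

Two phantom families are provided: a homogeneous PMMA cylinder and an
ellipsoidal head (soft-tissue shell around a brain interior) carrying the
full organ-at-risk set used in single-field posterior BNCT planning.

Coordinate convention (shared by the whole package): right-handed world
frame, the beam travels along +y (posterior to anterior), +x is the
patient's right-to-left axis and +z is inferior-to-superior.  Voxel indices
are 0-based; voxel (i, j, k) owns the half-open box
``[origin + i*d, origin + (i+1)*d)`` and is represented by its centre for
all geometric membership tests.  Depth is measured from the phantom entry
surface along +y.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np
import tifffile

__all__ = [
    "Material",
    "TumorSpec",
    "VoxelPhantom",
    "ROISet",
    "HeadROIGeometry",
    "AIR",
    "PMMA",
    "SOFT_TISSUE",
    "BRAIN",
    "build_cylinder_phantom",
    "build_head_phantom",
    "write_image_stack",
    "read_image_stack",
    "voxelize_to_planning_grid",
]

ROI_NAMES = (
    "tumor",
    "normal_brain",
    "brainstem",
    "circle_of_willis",
    "lens_L",
    "lens_R",
    "eye_L",
    "eye_R",
    "optic_nerve_L",
    "optic_nerve_R",
)


@dataclass(frozen=True)
class Material:
    """A labelled phantom material.

    ``composition`` maps element symbol to mass fraction; it is carried for
    bookkeeping (the transport stand-in only uses densities).
    """

    name: str
    density: float  # g/cm^3
    composition: Mapping[str, float] = field(default_factory=dict)


# Default material palette.  Densities: dry air at NTP, ICRU-like soft
# tissue / brain, and PMMA.
AIR = Material("air", 0.0012, {"N": 0.755, "O": 0.232, "Ar": 0.013})
PMMA = Material("pmma", 1.19, {"H": 0.0805, "C": 0.5998, "O": 0.3196})
SOFT_TISSUE = Material("soft_tissue", 1.03, {"H": 0.105, "C": 0.256, "N": 0.027, "O": 0.602})
BRAIN = Material("brain", 1.04, {"H": 0.107, "C": 0.145, "N": 0.022, "O": 0.712})

AIR_LABEL = 0


@dataclass(frozen=True)
class TumorSpec:
    """Cylindrical tumor: ``diameter`` (cm) across the beam-axis plane,
    ``length`` (cm) along the left-right axis, central axis at ``depth``
    (cm) from the phantom entry surface along the beam."""

    diameter: float = 3.0
    length: float = 5.0
    depth: float = 6.5

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("tumor diameter and length must be positive")
        if self.depth < 0:
            raise ValueError("tumor depth must be non-negative")


@dataclass
class VoxelPhantom:
    """Labelled 3-D material grid with physical spacing.

    ``material_grid`` holds integer labels indexing ``material_table``;
    ``density_grid`` is derived from it and kept in sync.  ``origin`` is the
    world coordinate of the corner of voxel (0, 0, 0).
    """

    material_grid: np.ndarray
    density_grid: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float]
    material_table: Dict[int, Material]

    def __post_init__(self) -> None:
        self.material_grid = np.asarray(self.material_grid)
        self.density_grid = np.asarray(self.density_grid, dtype=float)
        if self.material_grid.ndim != 3:
            raise ValueError("material_grid must be 3-D")
        if self.material_grid.shape != self.density_grid.shape:
            raise ValueError("material and density grids must share dimensions")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        labels = np.unique(self.material_grid)
        missing = [int(l) for l in labels if int(l) not in self.material_table]
        if missing:
            raise ValueError(f"labels {missing} absent from material_table")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.material_grid.shape

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def tissue_mask(self) -> np.ndarray:
        return self.material_grid != AIR_LABEL

    def tissue_centroid(self) -> Tuple[float, float, float]:
        idx = np.argwhere(self.tissue_mask())
        if idx.size == 0:
            raise ValueError("phantom contains no tissue")
        c = idx.mean(axis=0) + 0.5
        return tuple(self.origin[a] + c[a] * self.spacing[a] for a in range(3))

    def densities_from_labels(self) -> np.ndarray:
        lut_size = int(self.material_grid.max()) + 1
        lut = np.zeros(lut_size)
        for label, mat in self.material_table.items():
            if label < lut_size:
                lut[label] = mat.density
        return lut[self.material_grid]


@dataclass
class ROISet:
    """Named boolean masks aligned to a phantom grid."""

    masks: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("ROI masks must share dimensions")
        for name, m in self.masks.items():
            if m.dtype != bool:
                self.masks[name] = m.astype(bool)
        if "tumor" in self.masks:
            if not self.masks["tumor"].any():
                raise ValueError("tumor mask is empty")
            if "normal_brain" in self.masks and (
                self.masks["tumor"] & self.masks["normal_brain"]
            ).any():
                raise ValueError("tumor and normal_brain masks overlap")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self):
        return list(self.masks)


def _grids(shape, spacing, origin):
    axes = [origin[a] + (np.arange(shape[a]) + 0.5) * spacing[a] for a in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _tumor_mask(X, Y, Z, tumor: TumorSpec, center_x: float = 0.0, center_z: float = 0.0):
    # Tumor cylinder axis runs along x; circular cross-section lies in the
    # beam-axis (y) / superior-inferior (z) plane at the requested depth.
    r = tumor.diameter / 2.0
    in_disc = (Y - tumor.depth) ** 2 + (Z - center_z) ** 2 <= r**2
    in_span = np.abs(X - center_x) <= tumor.length / 2.0
    return in_disc & in_span


def build_cylinder_phantom(
    diameter: float = 16.0,
    length: float = 20.0,
    spacing: Tuple[float, float, float] = (0.5, 0.5, 0.5),
    tumor: TumorSpec = TumorSpec(),
    lateral_margin: float = 4.0,
    distal_margin: float = 4.0,
) -> Tuple[VoxelPhantom, ROISet]:
    """Homogeneous PMMA cylinder aligned with the beam axis.

    The flat entry face sits on the aperture plane y=0; the cylinder axis
    coincides with the beam axis (x=z=0).  The lateral margins leave air
    head-room so that the positioning battery (shifts up to 3 cm) never
    clips tissue out of the grid.
    """
    if diameter <= 0 or length <= 0:
        raise ValueError("cylinder diameter and length must be positive")
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing components must be positive")
    radius = diameter / 2.0
    tr = tumor.diameter / 2.0
    if tumor.depth - tr < 0 or tumor.depth + tr > length:
        raise ValueError(
            f"tumor (depth {tumor.depth} cm, diameter {tumor.diameter} cm) "
            f"extends outside the {length} cm cylinder along the beam axis"
        )
    corner = math.hypot(tumor.length / 2.0, tr)
    if corner > radius:
        raise ValueError("tumor extends outside the cylinder radially")

    ext_x = diameter + 2 * lateral_margin
    ext_y = length + distal_margin
    nx = int(round(ext_x / spacing[0]))
    ny = int(round(ext_y / spacing[1]))
    nz = int(round((diameter + 2 * lateral_margin) / spacing[2]))
    origin = (-ext_x / 2.0, 0.0, -(diameter + 2 * lateral_margin) / 2.0)

    X, Y, Z = _grids((nx, ny, nz), spacing, origin)
    in_cyl = (X**2 + Z**2 <= radius**2) & (Y >= 0) & (Y <= length)
    labels = np.where(in_cyl, 1, AIR_LABEL).astype(np.int16)
    table = {AIR_LABEL: AIR, 1: PMMA}
    density = np.where(in_cyl, PMMA.density, AIR.density)
    phantom = VoxelPhantom(labels, density, spacing, origin, table)

    tmask = _tumor_mask(X, Y, Z, tumor) & in_cyl
    rois = ROISet({"tumor": tmask, "normal_brain": in_cyl & ~tmask})
    return phantom, rois


@dataclass(frozen=True)
class HeadROIGeometry:
    """Placement parameters for the head organ set (all cm, relative to the
    head centre unless noted).  The eyes/lenses/optic nerves sit on the
    anterior (+y) side, far from the posterior entry surface."""

    scalp_thickness: float = 0.4
    eye_radius: float = 1.2
    eye_offset: Tuple[float, float, float] = (3.0, 7.5, 0.5)  # (|x|, y, z)
    lens_radius: float = 0.4
    lens_anterior_offset: float = 0.7  # lens centre ahead of eye centre
    optic_nerve_radius: float = 0.3
    optic_nerve_x: float = 2.2
    optic_nerve_z: float = 0.5
    optic_nerve_span: Tuple[float, float] = (3.5, 6.5)  # y range from centre
    brainstem_radius: float = 1.0
    brainstem_span: Tuple[float, float] = (-8.0, -2.0)  # z range from centre
    willis_radius: float = 1.0
    willis_center: Tuple[float, float, float] = (0.0, 0.0, -2.0)


def build_head_phantom(
    head_axes: Tuple[float, float, float] = (9.5, 12.0, 8.0),
    tumor: TumorSpec = TumorSpec(),
    roi_geometry: HeadROIGeometry = HeadROIGeometry(),
    spacing: Tuple[float, float, float] = (0.5, 0.5, 0.5),
    margin: float = 4.0,
) -> Tuple[VoxelPhantom, ROISet]:
    """Ellipsoidal head phantom with the posterior surface on the beam.

    ``head_axes`` are the (AP, SI, LR) semi-axes in cm, i.e. along (y, z, x).
    The posterior pole touches the aperture plane y=0 and the beam axis
    passes through the head centre.
    """
    ay, az, ax = head_axes
    if min(head_axes) <= 0:
        raise ValueError("head semi-axes must be positive")
    g = roi_geometry
    cy = ay  # head centre depth: posterior pole at y = 0

    # Tumor containment is checked against the outer ellipsoid: a shallow
    # (2.5 cm) tumor legitimately grazes the scalp shell.
    tr = tumor.diameter / 2.0
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                px = sx * tumor.length / 2.0
                py = tumor.depth + sy * tr
                pz = sz * tr
                if (px / ax) ** 2 + ((py - cy) / ay) ** 2 + (pz / az) ** 2 > 1.0:
                    raise ValueError(
                        f"tumor at depth {tumor.depth} cm does not fit inside "
                        f"the head (corner ({px:.1f}, {py:.1f}, {pz:.1f}) cm "
                        "lies outside the scalp surface)"
                    )
    if g.lens_anterior_offset + g.lens_radius > g.eye_radius:
        raise ValueError("lens protrudes from the eye: inconsistent lens/eye geometry")

    ext_x = 2 * ax + 2 * margin
    ext_z = 2 * az + 2 * margin
    ny = int(round((2 * ay + 2 * margin) / spacing[1]))
    nx = int(round(ext_x / spacing[0]))
    nz = int(round(ext_z / spacing[2]))
    origin = (-ext_x / 2.0, -margin, -ext_z / 2.0)

    X, Y, Z = _grids((nx, ny, nz), spacing, origin)
    head = (X / ax) ** 2 + ((Y - cy) / ay) ** 2 + (Z / az) ** 2 <= 1.0
    bx, by, bz = ax - g.scalp_thickness, ay - g.scalp_thickness, az - g.scalp_thickness
    brain = (X / bx) ** 2 + ((Y - cy) / by) ** 2 + (Z / bz) ** 2 <= 1.0

    labels = np.full((nx, ny, nz), AIR_LABEL, dtype=np.int16)
    labels[head] = 1
    labels[brain] = 2
    table = {AIR_LABEL: AIR, 1: SOFT_TISSUE, 2: BRAIN}
    density = np.choose(labels, [AIR.density, SOFT_TISSUE.density, BRAIN.density])
    phantom = VoxelPhantom(labels, density, spacing, origin, table)

    def sphere(cx_, cy_, cz_, r_):
        return (X - cx_) ** 2 + (Y - cy_) ** 2 + (Z - cz_) ** 2 <= r_**2

    tmask = _tumor_mask(X, Y, Z, tumor) & head
    masks = {"tumor": tmask, "normal_brain": brain & ~tmask}
    ex, ey, ez = g.eye_offset
    for side, sx in (("L", 1.0), ("R", -1.0)):
        eye_c = (sx * ex, cy + ey, ez)
        masks[f"eye_{side}"] = sphere(*eye_c, g.eye_radius) & head
        masks[f"lens_{side}"] = (
            sphere(eye_c[0], eye_c[1] + g.lens_anterior_offset, eye_c[2], g.lens_radius)
            & head
        )
        on = (
            ((X - sx * g.optic_nerve_x) ** 2 + (Z - g.optic_nerve_z) ** 2
             <= g.optic_nerve_radius**2)
            & (Y >= cy + g.optic_nerve_span[0])
            & (Y <= cy + g.optic_nerve_span[1])
        )
        masks[f"optic_nerve_{side}"] = on & head
    masks["brainstem"] = (
        (X**2 + (Y - cy) ** 2 <= g.brainstem_radius**2)
        & (Z >= g.brainstem_span[0])
        & (Z <= g.brainstem_span[1])
        & brain
    )
    wc = g.willis_center
    masks["circle_of_willis"] = sphere(wc[0], cy + wc[1], wc[2], g.willis_radius) & brain
    return phantom, ROISet(masks)


# ---------------------------------------------------------------------------
# Image-stack input/output


def _gray_mapping(material_table: Dict[int, Material]) -> Dict[int, int]:
    """8-bit gray value per label: air at 0, the rest spread over 1..255 in
    density order (ties broken by lower label)."""
    others = sorted(
        (l for l in material_table if l != AIR_LABEL),
        key=lambda l: (material_table[l].density, l),
    )
    mapping = {AIR_LABEL: 0}
    if len(others) == 1:
        mapping[others[0]] = 255
    elif others:
        for i, label in enumerate(others):
            mapping[label] = int(round(1 + i * 254 / (len(others) - 1)))
    return mapping


def write_image_stack(phantom: VoxelPhantom, roiset: ROISet, directory) -> None:
    """Write one 8-bit grayscale TIFF per axial (z) slice plus per-ROI mask
    stacks and a plain-text ``manifest.txt`` recording spacing, dims, origin
    and the label-to-gray mapping."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gray = _gray_mapping(phantom.material_table)
    nx, ny, nz = phantom.shape
    lut = np.zeros(int(phantom.material_grid.max()) + 1, dtype=np.uint8)
    for label, g in gray.items():
        if label < lut.size:
            lut[label] = g
    for k in range(nz):
        img = lut[phantom.material_grid[:, :, k]]
        tifffile.imwrite(directory / f"slice_{k:04d}.tif", img)
    for name, mask in roiset.masks.items():
        roi_dir = directory / f"roi_{name}"
        roi_dir.mkdir(exist_ok=True)
        for k in range(nz):
            tifffile.imwrite(
                roi_dir / f"slice_{k:04d}.tif",
                (mask[:, :, k].astype(np.uint8) * 255),
            )
    lines = [
        f"nx={nx}", f"ny={ny}", f"nz={nz}",
        f"dx={phantom.spacing[0]!r}", f"dy={phantom.spacing[1]!r}",
        f"dz={phantom.spacing[2]!r}",
        f"axial_extent_cm={nz * phantom.spacing[2]!r}",
        f"ox={phantom.origin[0]!r}", f"oy={phantom.origin[1]!r}",
        f"oz={phantom.origin[2]!r}",
        f"rois={','.join(roiset.masks)}",
    ]
    for label in sorted(phantom.material_table):
        mat = phantom.material_table[label]
        lines.append(f"label_{label}={gray[label]}:{mat.name}:{mat.density!r}")
    (directory / "manifest.txt").write_text("\n".join(lines) + "\n")


def read_manifest(directory) -> Dict[str, str]:
    path = Path(directory) / "manifest.txt"
    if not path.exists():
        raise FileNotFoundError(f"missing manifest.txt in {directory}")
    out: Dict[str, str] = {}
    for line in path.read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_image_stack(directory) -> Tuple[VoxelPhantom, ROISet]:
    """Inverse of :func:`write_image_stack`; exact on labels and masks."""
    directory = Path(directory)
    man = read_manifest(directory)
    nx, ny, nz = int(man["nx"]), int(man["ny"]), int(man["nz"])
    spacing = (float(man["dx"]), float(man["dy"]), float(man["dz"]))
    origin = (float(man["ox"]), float(man["oy"]), float(man["oz"]))
    table: Dict[int, Material] = {}
    gray_to_label: Dict[int, int] = {}
    for key, val in man.items():
        m = re.fullmatch(r"label_(\d+)", key)
        if m:
            label = int(m.group(1))
            g, name, density = val.split(":")
            table[label] = Material(name, float(density))
            gray_to_label[int(g)] = label

    labels = np.empty((nx, ny, nz), dtype=np.int16)
    for k in range(nz):
        img = tifffile.imread(directory / f"slice_{k:04d}.tif")
        if img.shape != (nx, ny):
            raise ValueError(
                f"slice_{k:04d}.tif has shape {img.shape}, expected {(nx, ny)}"
            )
        unknown = set(np.unique(img)) - set(gray_to_label)
        if unknown:
            raise ValueError(
                f"slice_{k:04d}.tif contains gray values {sorted(unknown)} "
                "absent from the manifest"
            )
        lut = np.zeros(256, dtype=np.int16)
        for g, label in gray_to_label.items():
            lut[g] = label
        labels[:, :, k] = lut[img]

    density = np.zeros_like(labels, dtype=float)
    for label, mat in table.items():
        density[labels == label] = mat.density
    phantom = VoxelPhantom(labels, density, spacing, origin, table)

    masks: Dict[str, np.ndarray] = {}
    roi_names = [n for n in man.get("rois", "").split(",") if n]
    for name in roi_names:
        roi_dir = directory / f"roi_{name}"
        mask = np.empty((nx, ny, nz), dtype=bool)
        for k in range(nz):
            img = tifffile.imread(roi_dir / f"slice_{k:04d}.tif")
            if img.shape != (nx, ny):
                raise ValueError(
                    f"roi_{name}/slice_{k:04d}.tif has shape {img.shape}, "
                    f"expected {(nx, ny)}"
                )
            mask[:, :, k] = img > 0
        masks[name] = mask
    return phantom, ROISet(masks)


# ---------------------------------------------------------------------------
# Planning-grid downsampling


def _block_mean(arr: np.ndarray, dims: Tuple[int, int, int]) -> np.ndarray:
    """Average ``arr`` onto a coarse grid of shape ``dims`` (general,
    non-divisible block boundaries handled by index flooring)."""
    src = arr.shape
    idx = [np.minimum((np.arange(src[a]) * dims[a]) // src[a], dims[a] - 1) for a in range(3)]
    flat = (
        idx[0][:, None, None] * (dims[1] * dims[2])
        + idx[1][None, :, None] * dims[2]
        + idx[2][None, None, :]
    )
    sums = np.bincount(flat.ravel(), weights=arr.ravel().astype(float),
                       minlength=dims[0] * dims[1] * dims[2])
    counts = np.bincount(flat.ravel(), minlength=dims[0] * dims[1] * dims[2])
    return (sums / counts).reshape(dims)


def voxelize_to_planning_grid(
    phantom: VoxelPhantom,
    roiset: ROISet,
    dims: Tuple[int, int, int] = (21, 21, 25),
    n_materials: int = 56,
) -> Tuple[VoxelPhantom, ROISet]:
    """Downsample to a coarse planning grid.

    Densities are block-averaged and snapped to material levels: the source
    material densities themselves when the source palette fits within
    ``n_materials``, otherwise ``n_materials`` uniform density bins.  ROI
    masks are downsampled by majority vote; an ROI smaller than one coarse
    voxel keeps the single voxel nearest its centroid.  Physical extent is
    preserved exactly by rescaling the spacing.
    """
    if any(d <= 0 for d in dims):
        raise ValueError("planning grid dims must be positive")
    src = phantom.shape
    if any(dims[a] > src[a] for a in range(3)):
        raise ValueError("planning grid dims must not exceed source dims")

    avg = _block_mean(phantom.density_grid, dims)

    src_mats = sorted(
        phantom.material_table.items(), key=lambda kv: (kv[1].density, kv[0])
    )
    if len(src_mats) <= n_materials:
        levels = np.array([m.density for _, m in src_mats])
        level_mats = [m for _, m in src_mats]
    else:
        dmin, dmax = avg.min(), avg.max()
        edges = np.linspace(dmin, dmax, n_materials + 1)
        levels = 0.5 * (edges[:-1] + edges[1:])
        level_mats = [Material(f"mat_{i:02d}", float(levels[i])) for i in range(n_materials)]

    nearest = np.abs(avg[..., None] - levels[None, None, None, :]).argmin(axis=-1)
    used = np.unique(nearest)
    # Relabel so that labels used match the source labelling when snapping
    # to source materials (identity case stays the identity).
    if len(src_mats) <= n_materials:
        src_labels = [l for l, _ in src_mats]
        labels = np.empty(dims, dtype=np.int16)
        table: Dict[int, Material] = {}
        for i in used:
            labels[nearest == i] = src_labels[i]
            table[src_labels[i]] = level_mats[i]
    else:
        labels = nearest.astype(np.int16)
        table = {int(i): level_mats[i] for i in used}
    density = np.empty(dims)
    for label, mat in table.items():
        density[labels == label] = mat.density
    new_spacing = tuple(phantom.spacing[a] * src[a] / dims[a] for a in range(3))
    coarse = VoxelPhantom(labels, density, new_spacing, phantom.origin, table)

    masks: Dict[str, np.ndarray] = {}
    for name, mask in roiset.masks.items():
        frac = _block_mean(mask.astype(float), dims)
        voted = frac >= 0.5
        if mask.any() and not voted.any():
            centroid = np.argwhere(mask).mean(axis=0)
            coarse_idx = tuple(
                min(int(centroid[a] * dims[a] / src[a]), dims[a] - 1) for a in range(3)
            )
            voted = np.zeros(dims, dtype=bool)
            voted[coarse_idx] = True
        masks[name] = voted
    if "tumor" in masks and "normal_brain" in masks:
        masks["normal_brain"] &= ~masks["tumor"]
    dropped = [n for n, m in roiset.masks.items() if m.any() and not masks[n].any()]
    if dropped:  # cannot happen given the centroid fallback, kept as a guard
        warnings.warn(f"ROIs lost in downsampling: {dropped}")
    return coarse, ROISet(masks)
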