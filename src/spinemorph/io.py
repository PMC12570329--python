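"""Reading and writing of volumes, label maps, tables and skeleton trees.

Conventions
-----------
* In memory, image data is a 4-D array ordered ``(channel, z, y, x)``;
  label maps are 3-D ``(z, y, x)``.
* Voxel spacing is always ``(z, y, x)`` in micrometres and is supplied by
  the caller (config/CLI); TIFF resolution tags are too dialect-dependent
  to be trusted as more than a fallback.
* Voxel indices are 0-based; exported coordinates (SWC, CSV) are physical
  micrometres with the origin at the centre of voxel ``(0, 0, 0)``.
* Multi-page TIFFs are interpreted z-fastest within channel
  (pages ``c0z0, c0z1, ..., c1z0, ...``) unless ``interleaved=True``
  (pages ``z0c0, z0c1, ..., z1c0, ...``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

if TYPE_CHECKING:  # pragma: no cover
    from .morphometry import DendriteSummary, SpineRecord

__all__ = [
    "VolumeImage",
    "SemanticLabelMap",
    "SkeletonTree",
    "CLASS_CODES",
    "read_volume",
    "write_volume",
    "read_label_map",
    "write_label_map",
    "rescale_volume",
    "rescale_label_map",
    "write_swc",
    "read_swc",
    "write_spine_table",
    "write_summary_table",
    "SPINE_TABLE_COLUMNS",
    "SUMMARY_TABLE_COLUMNS",
]

#: Default semantic class codes for segmentation label maps.
CLASS_CODES: dict[int, str] = {
    0: "background",
    1: "dendrite",
    2: "soma",
    3: "spine_head",
    4: "spine_neck",
}


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive values (z, y, x), got {spacing!r}")
    return spacing


@dataclass
class VolumeImage:
    """An n-channel 3-D voxel grid with physical voxel spacing.

    Parameters
    ----------
    voxels
        Array of shape ``(channel, z, y, x)`` with non-negative intensities.
    spacing
        Voxel size ``(z, y, x)`` in micrometres.
    channel_names
        One label per channel; defaults to ``ch0, ch1, ...``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be 4-D (channel, z, y, x), got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise ValueError("every axis must have size >= 1")
        self.spacing = _check_spacing(self.spacing)
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.voxels.shape[0])]
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError("channel_names length must match the channel axis")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class SemanticLabelMap:
    """Integer class volume (z, y, x) sharing a grid with a :class:`VolumeImage`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    class_codes: dict[int, str] = field(default_factory=lambda: dict(CLASS_CODES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3-D (z, y, x), got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.spacing = _check_spacing(self.spacing)
        present = set(np.unique(self.labels).tolist())
        undeclared = present - set(self.class_codes)
        if undeclared:
            raise ValueError(f"label map contains undeclared class codes: {sorted(undeclared)}")

    def code_for(self, name: str) -> int:
        for code, cname in self.class_codes.items():
            if cname == name:
                return code
        raise KeyError(f"no class named {name!r}")

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of the class with the given name."""
        return self.labels == self.code_for(name)

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class SkeletonTree:
    """A forest of skeleton nodes in physical coordinates.

    ``parent[i]`` is the index of node ``i``'s parent, or ``-1`` for roots.
    """

    coords_um: np.ndarray  # (n, 3) float, (z, y, x) micrometres
    radius_um: np.ndarray  # (n,)
    parent: np.ndarray  # (n,) int, -1 for roots

    def __post_init__(self) -> None:
        self.coords_um = np.asarray(self.coords_um, dtype=float).reshape(-1, 3)
        n = len(self.coords_um)
        self.radius_um = np.asarray(self.radius_um, dtype=float).reshape(n)
        self.parent = np.asarray(self.parent, dtype=int).reshape(n)
        self._check_forest()

    def _check_forest(self) -> None:
        n = len(self.parent)
        if np.any((self.parent < -1) | (self.parent >= n)):
            raise ValueError("parent indices out of range")
        # walk each node to a root; a cycle would exceed n steps
        for start in range(n):
            i, steps = start, 0
            while i != -1:
                i = self.parent[i]
                steps += 1
                if steps > n:
                    raise ValueError("parent references contain a cycle")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def roots(self) -> np.ndarray:
        return np.flatnonzero(self.parent == -1)

    def edge_lengths_um(self) -> np.ndarray:
        """Anisotropy-aware Euclidean length of every parent-child edge."""
        child = np.flatnonzero(self.parent != -1)
        if child.size == 0:
            return np.zeros(0)
        d = self.coords_um[child] - self.coords_um[self.parent[child]]
        return np.linalg.norm(d, axis=1)

    def total_length_um(self) -> float:
        return float(self.edge_lengths_um().sum())


# ---------------------------------------------------------------------------
# TIFF volumes


def read_volume(
    path: str | Path,
    spacing: Sequence[float],
    n_channels: int = 1,
    interleaved: bool = False,
    channel_names: list[str] | None = None,
) -> VolumeImage:
    """Read a single- or multi-page TIFF into a ``(channel, z, y, x)`` volume.

    2-D images become single-plane volumes.  For multi-channel stacks the
    page order is channel-major (z-fastest within channel) unless
    ``interleaved`` is set, in which case pages alternate channels within
    each z-plane.
    """
    spacing = _check_spacing(spacing)
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF volume {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[np.newaxis, np.newaxis]
    elif arr.ndim == 3:
        pages = arr.shape[0]
        if pages % n_channels != 0:
            raise ValueError(
                f"{path}: {pages} pages not divisible by n_channels={n_channels}"
            )
        nz = pages // n_channels
        if interleaved:
            arr = arr.reshape(nz, n_channels, *arr.shape[1:]).transpose(1, 0, 2, 3)
        else:
            arr = arr.reshape(n_channels, nz, *arr.shape[1:])
    elif arr.ndim == 4:
        if arr.shape[0] != n_channels and arr.shape[1] == n_channels:
            arr = arr.transpose(1, 0, 2, 3)  # (z, c, y, x) -> (c, z, y, x)
    else:
        raise ValueError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")
    return VolumeImage(arr, spacing, channel_names or [])


def write_volume(v: VolumeImage, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF (channel-major page order)."""
    pages = v.voxels.reshape(-1, *v.voxels.shape[2:])
    tifffile.imwrite(Path(path), pages, software=None, photometric="minisblack")


def read_label_map(
    path: str | Path,
    spacing: Sequence[float],
    class_codes: dict[int, str] | None = None,
) -> SemanticLabelMap:
    """Read a 3-D integer label map from TIFF."""
    spacing = _check_spacing(spacing)
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF label map {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValueError(f"{path}: label map must be 2-D or 3-D, got ndim={arr.ndim}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: label map must contain integers, got {arr.dtype}")
    return SemanticLabelMap(arr, spacing, class_codes or dict(CLASS_CODES))


def write_label_map(m: SemanticLabelMap, path: str | Path) -> None:
    tifffile.imwrite(Path(path), m.labels, software=None)


# ---------------------------------------------------------------------------
# Rescaling


def _target_shape(
    shape: Sequence[int], spacing: Sequence[float], target_spacing: Sequence[float]
) -> tuple[int, ...]:
    out = tuple(
        max(1, int(round(d * s / t)))
        for d, s, t in zip(shape, spacing, target_spacing)
    )
    return out


def rescale_volume(
    v: VolumeImage,
    target_spacing: Sequence[float],
    order: str = "linear",
) -> VolumeImage:
    """Resample a volume onto a grid with the requested voxel spacing.

    ``order`` is ``"linear"`` for images or ``"nearest"`` for label-like
    data.  Output dimensions are ``round(dim * spacing / target_spacing)``,
    clamped to at least 1 voxel.
    """
    target_spacing = _check_spacing(target_spacing)
    if order not in ("nearest", "linear"):
        raise ValueError(f"order must be 'nearest' or 'linear', got {order!r}")
    if tuple(target_spacing) == tuple(v.spacing):
        return VolumeImage(v.voxels.copy(), v.spacing, list(v.channel_names))
    out_shape = _target_shape(v.grid_shape, v.spacing, target_spacing)
    zoom = [o / i for o, i in zip(out_shape, v.grid_shape)]
    k = 0 if order == "nearest" else 1
    out = np.stack(
        [ndi.zoom(v.voxels[c], zoom, order=k, mode="nearest", grid_mode=True)
         for c in range(v.n_channels)]
    )
    return VolumeImage(out, target_spacing, list(v.channel_names))


def rescale_label_map(
    m: SemanticLabelMap, target_spacing: Sequence[float]
) -> SemanticLabelMap:
    """Nearest-neighbour resampling of a label map; never invents class codes."""
    target_spacing = _check_spacing(target_spacing)
    if tuple(target_spacing) == tuple(m.spacing):
        return SemanticLabelMap(m.labels.copy(), m.spacing, dict(m.class_codes))
    out_shape = _target_shape(m.labels.shape, m.spacing, target_spacing)
    zoom = [o / i for o, i in zip(out_shape, m.labels.shape)]
    out = ndi.zoom(m.labels, zoom, order=0, mode="nearest", grid_mode=True)
    return SemanticLabelMap(out, target_spacing, dict(m.class_codes))


def rescale_instance_map(
    labels: np.ndarray, spacing: Sequence[float], target_spacing: Sequence[float]
) -> np.ndarray:
    """Nearest-neighbour resampling of an integer instance map."""
    target_spacing = _check_spacing(target_spacing)
    out_shape = _target_shape(labels.shape, spacing, target_spacing)
    zoom = [o / i for o, i in zip(out_shape, labels.shape)]
    return ndi.zoom(labels, zoom, order=0, mode="nearest", grid_mode=True)


# ---------------------------------------------------------------------------
# SWC skeleton export

_SWC_SOMA, _SWC_DENDRITE = 1, 3


def write_swc(tree: SkeletonTree, path: str | Path) -> None:
    """Write a skeleton forest in SWC format.

    One line per node: ``id type x y z radius parent``.  Ids are contiguous
    from 1 and every parent precedes its children; roots carry the soma
    structure code (1), all other nodes the basal-dendrite code (3).
    Coordinates are micrometres with x/y/x taken from the internal
    (z, y, x) order.
    """
    n = tree.n_nodes
    # topological order: parents before children
    order: list[int] = []
    children: dict[int, list[int]] = {}
    for i, p in enumerate(tree.parent):
        children.setdefault(int(p), []).append(i)
    stack = list(reversed(children.get(-1, [])))
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(reversed(children.get(i, [])))
    if len(order) != n:
        raise ValueError("parent references do not form a forest")
    new_id = {old: k + 1 for k, old in enumerate(order)}
    lines = []
    for old in order:
        p = int(tree.parent[old])
        struct = _SWC_SOMA if p == -1 else _SWC_DENDRITE
        z, y, x = tree.coords_um[old]
        parent_id = -1 if p == -1 else new_id[p]
        lines.append(
            f"{new_id[old]} {struct} {x:.4f} {y:.4f} {z:.4f} "
            f"{tree.radius_um[old]:.4f} {parent_id}"
        )
    Path(path).write_text(
        "# SWC export: id type x y z radius parent (micrometres)\n"
        + "\n".join(lines)
        + "\n"
    )


def read_swc(path: str | Path) -> SkeletonTree:
    """Parse an SWC file back into a :class:`SkeletonTree` (ids remapped to 0-based)."""
    coords, radii, parents, id_map = [], [], [], {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        nid, _struct = int(fields[0]), int(fields[1])
        x, y, z, r = (float(f) for f in fields[2:6])
        parent = int(fields[6])
        id_map[nid] = len(coords)
        coords.append((z, y, x))
        radii.append(r)
        parents.append(parent)
    parent_idx = [(-1 if p == -1 else id_map[p]) for p in parents]
    return SkeletonTree(np.array(coords).reshape(-1, 3), np.array(radii), np.array(parent_idx, dtype=int))


# ---------------------------------------------------------------------------
# Measurement tables

#: Fixed per-spine CSV schema (per-channel intensity columns are appended).
SPINE_TABLE_COLUMNS = [
    "instance_id",
    "volume_um3",
    "head_volume_um3",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "spine_length_um",
    "neck_length_um",
    "head_width_um",
    "distance_to_dendrite_um",
    "soma_distance_euclid_um",
    "soma_distance_geodesic_um",
]

#: Fixed per-dendrite / per-image summary CSV schema.
SUMMARY_TABLE_COLUMNS = [
    "image_id",
    "dendrite_id",
    "skeleton_length_um",
    "spine_count",
    "spine_density_per_um",
    "mean_volume_um3",
    "mean_head_volume_um3",
    "mean_spine_length_um",
    "mean_neck_length_um",
    "mean_head_width_um",
    "mean_distance_to_dendrite_um",
]


def spine_records_frame(records: Iterable["SpineRecord"]) -> pd.DataFrame:
    """Per-spine records as a DataFrame with the fixed schema.

    Missing measurements become NaN, written as empty CSV fields — never 0.
    """
    rows = []
    channels: list[str] = []
    for rec in records:
        row = {
            "instance_id": rec.instance_id,
            "volume_um3": rec.volume_um3,
            "head_volume_um3": rec.head_volume_um3,
            "centroid_z_um": rec.centroid_um[0],
            "centroid_y_um": rec.centroid_um[1],
            "centroid_x_um": rec.centroid_um[2],
            "spine_length_um": rec.spine_length_um,
            "neck_length_um": rec.neck_length_um,
            "head_width_um": rec.head_width_um,
            "distance_to_dendrite_um": rec.distance_to_dendrite_um,
            "soma_distance_euclid_um": rec.soma_distance_euclid_um,
            "soma_distance_geodesic_um": rec.soma_distance_geodesic_um,
        }
        for ch, stats in (rec.intensity_stats or {}).items():
            if ch not in channels:
                channels.append(ch)
            for stat_name, value in stats.items():
                row[f"{stat_name}_intensity_{ch}"] = value
        rows.append(row)
    cols = list(SPINE_TABLE_COLUMNS) + [
        f"{s}_intensity_{ch}" for ch in channels for s in ("mean", "max", "integrated")
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df


def write_spine_table(records: Iterable["SpineRecord"], path: str | Path) -> None:
    """Write the per-spine measurement CSV (one row per spine)."""
    spine_records_frame(records).to_csv(Path(path), index=False)


def summary_frame(summaries: Iterable["DendriteSummary"]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "image_id": s.image_id,
            "dendrite_id": s.dendrite_id,
            "skeleton_length_um": s.skeleton_length_um,
            "spine_count": s.spine_count,
            "spine_density_per_um": s.spine_density_per_um,
            "mean_volume_um3": s.mean_volume_um3,
            "mean_head_volume_um3": s.mean_head_volume_um3,
            "mean_spine_length_um": s.mean_spine_length_um,
            "mean_neck_length_um": s.mean_neck_length_um,
            "mean_head_width_um": s.mean_head_width_um,
            "mean_distance_to_dendrite_um": s.mean_distance_to_dendrite_um,
        })
    return pd.DataFrame(rows, columns=SUMMARY_TABLE_COLUMNS)


def write_summary_table(summaries: Iterable["DendriteSummary"], path: str | Path) -> None:
    """Write per-dendrite / per-image summary rows to CSV."""
    summary_frame(summaries).to_csv(Path(path), index=False)
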