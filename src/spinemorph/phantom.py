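"""Synthetic dendrite+spine phantoms with exact ground truth.

Scenes emulate sparsely labelled dendrites imaged in 3-D fluorescence
microscopy: a tube-like shaft (optionally rooted in a spherical soma)
bearing spines built from a thin cylindrical neck and an ellipsoidal-to-
spherical head, rendered on an anisotropic voxel grid.  Two acquisition
presets are provided: spinning-disk confocal (65 × 65 nm lateral, 150 nm
z-step) and in-vivo two-photon (102 × 102 nm lateral, 1 μm z-step,
~10× axial anisotropy).

The imaging-degradation operator chains an elongated anisotropic Gaussian
PSF blur, Poisson shot noise at a photon-scale knob (the single SNR dial:
lower scale = fewer photons = noisier), and additive Gaussian read noise —
mirroring the paired low/high-SNR acquisition regimes used to train
content-aware restoration models.  Degradation acts on intensities only;
ground-truth labels are generated, never re-derived, so they are exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import CLASS_CODES, SemanticLabelMap, VolumeImage

__all__ = [
    "SPINNING_DISK_SPACING",
    "TWO_PHOTON_SPACING",
    "SpinePlacement",
    "SceneSpec",
    "DegradeSpec",
    "generate_scene",
    "straight_scene_spec",
    "u_shaped_scene_spec",
    "shifted_spec",
    "degrade",
    "augment_pair",
]

#: (z, y, x) voxel size in μm for the spinning-disk confocal preset.
SPINNING_DISK_SPACING = (0.150, 0.065, 0.065)
#: (z, y, x) voxel size in μm for the two-photon preset (~10× z anisotropy).
TWO_PHOTON_SPACING = (1.0, 0.102, 0.102)

_DENDRITE, _SOMA, _HEAD, _NECK = 1, 2, 3, 4


@dataclass
class SpinePlacement:
    """One spine on the dendrite: position along the path plus geometry."""

    position_um: float  # arc length along the dendrite path
    neck_length_um: float = 0.7
    neck_radius_um: float = 0.1
    head_radius_um: float = 0.3
    direction: tuple[float, float, float] | None = None  # unit (z, y, x); None = seeded

    def __post_init__(self) -> None:
        if self.neck_radius_um <= 0 or self.head_radius_um < 0 or self.neck_length_um < 0:
            raise ValueError("spine radii must be positive and lengths non-negative")


@dataclass
class SceneSpec:
    """Full description of a synthetic scene; the seed fixes everything random."""

    shape: tuple[int, int, int] = (48, 192, 192)  # (z, y, x) voxels
    spacing: tuple[float, float, float] = SPINNING_DISK_SPACING
    dendrite_path_um: np.ndarray | None = None  # (k, 3) polyline, (z, y, x) μm
    dendrite_radius_um: float = 0.4
    soma_center_um: tuple[float, float, float] | None = None
    soma_radius_um: float = 1.5
    spines: list[SpinePlacement] = field(default_factory=list)
    foreground_intensity: float = 200.0
    background_intensity: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dendrite_radius_um <= 0 or self.soma_radius_um <= 0:
            raise ValueError("radii must be positive")
        if self.dendrite_path_um is None:
            # default: straight shaft along x through the grid centre
            z, y, _x = (np.array(self.shape) * np.array(self.spacing)) / 2
            x_end = self.shape[2] * self.spacing[2]
            self.dendrite_path_um = np.array([[z, y, 0.0], [z, y, x_end]])
        self.dendrite_path_um = np.asarray(self.dendrite_path_um, dtype=float).reshape(-1, 3)


@dataclass
class DegradeSpec:
    """Imaging degradation: PSF blur, shot noise, read noise.

    ``photon_scale`` is the expected photon count per intensity unit; lower
    values mean stronger Poisson noise.  ``None`` (infinite photons) skips
    shot noise entirely.
    """

    psf_sigma_lateral_um: float = 0.08
    psf_sigma_axial_um: float = 0.25
    photon_scale: float | None = 0.2
    read_noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma_lateral_um < 0 or self.psf_sigma_axial_um < 0:
            raise ValueError("PSF sigmas must be >= 0")
        if self.photon_scale is not None and self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0 (or None to disable)")
        if self.read_noise_sigma < 0:
            raise ValueError("read_noise_sigma must be >= 0")


# ---------------------------------------------------------------------------
# Geometry helpers


def _resample_path(path: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Dense samples along a polyline with cumulative arc length."""
    segs = np.diff(path, axis=0)
    seg_len = np.linalg.norm(segs, axis=1)
    total = float(seg_len.sum())
    if total == 0:
        return path[:1], np.zeros(1)
    n = max(2, int(np.ceil(total / step)) + 1)
    s = np.linspace(0, total, n)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    pts = np.empty((n, 3))
    for d in range(3):
        pts[:, d] = np.interp(s, cum, path[:, d])
    return pts, s


def _path_frame(path: np.ndarray, arc: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and unit tangent of the resampled path at arc length ``s``."""
    s = float(np.clip(s, arc[0], arc[-1]))
    i = int(np.searchsorted(arc, s))
    i = min(max(i, 1), len(arc) - 1)
    t = path[i] - path[i - 1]
    nrm = np.linalg.norm(t)
    tangent = t / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
    frac = (s - arc[i - 1]) / max(arc[i] - arc[i - 1], 1e-12)
    return path[i - 1] + frac * (path[i] - path[i - 1]), tangent


def _perpendicular(tangent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        v -= v.dot(tangent) * tangent
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def _stamp_ball(
    targets, value, inst_map, inst_value, center_um, r_um, spacing, shape, protect=None
):
    spacing = np.asarray(spacing)
    lo = np.maximum(np.floor((center_um - r_um) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center_um + r_um) / spacing).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    d2 = sum(((g * s - c) ** 2 for g, s, c in zip(grids, spacing, center_um)))
    inside = d2 <= r_um**2
    if protect is not None:
        inside = inside & ~protect[sl]
    for arr in targets:
        arr[sl][inside] = value
    if inst_map is not None:
        inst_map[sl][inside] = inst_value


def _stamp_capsule(
    targets, value, inst_map, inst_value, a_um, b_um, r_um, spacing, shape, protect=None
):
    step = min(spacing) / 2.0
    length = np.linalg.norm(b_um - a_um)
    n = max(2, int(np.ceil(length / step)) + 1)
    for frac in np.linspace(0, 1, n):
        c = a_um + frac * (b_um - a_um)
        _stamp_ball(targets, value, inst_map, inst_value, c, r_um, spacing, shape, protect)


# ---------------------------------------------------------------------------
# Scene generation


def generate_scene(
    spec: SceneSpec,
) -> tuple[VolumeImage, SemanticLabelMap, np.ndarray, pd.DataFrame]:
    """Render a scene into image, semantic labels, instance map and gt table.

    Semantic classes overlap with precedence head > neck > dendrite > soma
    (later-painted classes win).  The ground-truth table carries the
    analytic head volume (4/3·π·r³), head width (2r), neck length, spine
    length (neck + head diameter) and the path-measured geodesic distance
    from the soma surface to each spine's attachment point.  Identical
    specs (including seed) produce bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    labels = np.zeros(shape, dtype=np.uint8)
    inst = np.zeros(shape, dtype=np.uint16)

    path, arc = _resample_path(spec.dendrite_path_um, min(spacing) / 2.0)
    total_len = float(arc[-1])

    if spec.soma_center_um is not None:
        _stamp_ball([labels], _SOMA, None, 0, np.asarray(spec.soma_center_um),
                    spec.soma_radius_um, spacing, shape)
    # shaft, plus a protection mask over the shaft and soma interiors so
    # spine voxels stay strictly outside the structure surface (voxel
    # adjacency across the surface keeps them connected to the shaft)
    protect = np.zeros(shape, dtype=bool)
    delta = min(spacing)
    for p in path:
        _stamp_ball([labels], _DENDRITE, None, 0, p, spec.dendrite_radius_um, spacing, shape)
        _stamp_ball([protect], True, None, 0, p, spec.dendrite_radius_um, spacing, shape)
    if spec.soma_center_um is not None:
        _stamp_ball([protect], True, None, 0, np.asarray(spec.soma_center_um),
                    spec.soma_radius_um, spacing, shape)

    # spines: geometry first (seeded directions), then paint necks, then heads
    geo = []
    for k, sp in enumerate(spec.spines, start=1):
        if not (0 <= sp.position_um <= total_len):
            raise ValueError(
                f"spine {k} placed at {sp.position_um} μm, outside the "
                f"{total_len:.2f} μm dendrite path"
            )
        point, tangent = _path_frame(path, arc, sp.position_um)
        direction = (
            np.asarray(sp.direction, dtype=float)
            if sp.direction is not None
            else _perpendicular(tangent, rng)
        )
        direction = direction / np.linalg.norm(direction)
        surface = point + spec.dendrite_radius_um * direction
        neck_end = surface + sp.neck_length_um * direction
        # slight backward overlap keeps the head connected to the neck
        head_center = neck_end + max(sp.head_radius_um - delta, 0.0) * direction
        geo.append((k, sp, surface, neck_end, head_center, direction))

    for k, sp, surface, neck_end, _hc, _d in geo:
        if sp.neck_length_um > 0:
            _stamp_capsule([labels], _NECK, inst, k, surface, neck_end,
                           sp.neck_radius_um, spacing, shape, protect)
        else:
            _stamp_ball([labels], _NECK, inst, k, surface, sp.neck_radius_um,
                        spacing, shape, protect)
    for k, sp, *_rest, head_center, _d in geo:
        if sp.head_radius_um > 0:
            _stamp_ball([labels], _HEAD, inst, k, head_center, sp.head_radius_um,
                        spacing, shape, protect)

    # ground truth table
    soma_exit = 0.0
    if spec.soma_center_um is not None:
        # arc length at which the path leaves the soma ball
        d_to_soma = np.linalg.norm(path - np.asarray(spec.soma_center_um), axis=1)
        outside = np.flatnonzero(d_to_soma > spec.soma_radius_um)
        soma_exit = float(arc[outside[0]]) if outside.size else total_len
    rows = []
    for k, sp, *_r, _hc, _d in geo:
        head_vol = 4.0 / 3.0 * np.pi * sp.head_radius_um**3 if sp.head_radius_um > 0 else None
        # the head ball is rendered overlapping the neck end by delta to
        # guarantee voxel connectivity; the geometric neck (shaft surface to
        # head surface) is therefore shortened by the same delta
        overlap = delta if sp.head_radius_um >= delta else 0.0
        rows.append({
            "spine_id": k,
            "position_um": sp.position_um,
            "neck_length_um": max(sp.neck_length_um - overlap, 0.0),
            "neck_radius_um": sp.neck_radius_um,
            "head_radius_um": sp.head_radius_um,
            "head_volume_um3": head_vol,
            "head_width_um": 2 * sp.head_radius_um if sp.head_radius_um > 0 else None,
            "spine_length_um": sp.neck_length_um + 2 * sp.head_radius_um - overlap,
            "geodesic_soma_distance_um": (
                max(sp.position_um - soma_exit, 0.0)
                if spec.soma_center_um is not None
                else None
            ),
        })
    gt = pd.DataFrame(rows)

    image = np.where(
        labels > 0, spec.foreground_intensity, spec.background_intensity
    ).astype(np.float32)[np.newaxis]
    v = VolumeImage(image, tuple(spacing), ["ch0"])
    m = SemanticLabelMap(labels, tuple(spacing), dict(CLASS_CODES))
    return v, m, inst, gt


def straight_scene_spec(
    n_spines: int = 12,
    shape: tuple[int, int, int] = (48, 192, 192),
    spacing: Sequence[float] = SPINNING_DISK_SPACING,
    with_soma: bool = True,
    seed: int = 0,
    neck_length_range: tuple[float, float] = (0.7, 1.3),
    head_radius_range: tuple[float, float] = (0.25, 0.4),
    neck_radius_um: float = 0.1,
    dendrite_radius_um: float = 0.4,
) -> SceneSpec:
    """A straight shaft along x with evenly spaced, seeded random spines.

    Spine geometry defaults are realistic for cortical pyramidal neurons:
    heads of 0.25–0.4 μm radius (≈0.07–0.27 μm³), necks of 0.7–1.3 μm at
    0.1 μm radius, on a 0.4 μm-radius shaft.  Necks much shorter than
    ~0.5 μm are not planted: at a 150 nm z-step their length sits below
    the voxelization floor and cannot be recovered meaningfully (the same
    resolution limit applies to the real instrument).
    """
    rng = np.random.default_rng(seed)
    shape = tuple(shape)
    spacing = tuple(spacing)
    # the shaft axis sits on a voxel-centre z-plane (an in-focus dendrite)
    zc = round(shape[0] / 2) * spacing[0]
    yc = shape[1] * spacing[1] / 2
    x_end = shape[2] * spacing[2]
    path = np.array([[zc, yc, 0.0], [zc, yc, x_end]])
    soma_center = (zc, yc, 1.2) if with_soma else None
    soma_radius = 1.5
    margin = (soma_radius + 1.2) if with_soma else 1.0
    positions = np.linspace(margin, x_end - 1.0, n_spines)
    # spines projecting along the optical axis are not planted (the coarse
    # z-step cannot resolve their geometry — the same spines are excluded
    # from analysis in real datasets); at z-steps too large to sample the
    # smallest head off-plane, spines stay in the focal plane entirely
    tilt_limit = 0.5 if spacing[0] <= 2 * head_radius_range[0] else 0.0
    spines = []
    for k, p in enumerate(positions):
        # spines alternate sides of the shaft so neighbours never merge
        tilt = rng.uniform(-tilt_limit, tilt_limit)  # radians out of the x-y plane
        side = 1.0 if k % 2 == 0 else -1.0
        direction = (float(np.sin(tilt)), float(side * np.cos(tilt)), 0.0)
        spines.append(
            SpinePlacement(
                position_um=float(p),
                neck_length_um=float(rng.uniform(*neck_length_range)),
                neck_radius_um=neck_radius_um,
                head_radius_um=float(rng.uniform(*head_radius_range)),
                direction=direction,
            )
        )
    return SceneSpec(
        shape=shape,
        spacing=spacing,
        dendrite_radius_um=dendrite_radius_um,
        soma_center_um=soma_center,
        soma_radius_um=soma_radius,
        spines=spines,
        seed=seed,
    )


def u_shaped_scene_spec(
    shape: tuple[int, int, int] = (32, 220, 160),
    spacing: Sequence[float] = SPINNING_DISK_SPACING,
    seed: int = 0,
) -> SceneSpec:
    """A U-shaped dendrite whose far arm runs back toward the soma.

    A spine attached near the end of the return arm is geodesically far
    from the soma (around the U) but Euclideanly close — the canonical
    case separating the two distance definitions.
    """
    shape = tuple(shape)
    spacing = tuple(spacing)
    zc = shape[0] * spacing[0] / 2
    y_lo, y_hi = 2.0, shape[1] * spacing[1] - 2.0
    x_lo, x_hi = 2.0, shape[2] * spacing[2] - 2.0
    path = np.array([
        [zc, y_lo, x_lo],
        [zc, y_lo, x_hi],
        [zc, y_hi, x_hi],
        [zc, y_hi, x_lo],
    ])
    arm = (x_hi - x_lo) + (y_hi - y_lo)  # arc length up to the return arm's start
    spine_pos = arm + (x_hi - x_lo) * 0.9  # near the free end of the return arm
    return SceneSpec(
        shape=shape,
        spacing=spacing,
        dendrite_path_um=path,
        dendrite_radius_um=0.4,
        soma_center_um=(zc, y_lo, x_lo + 0.5),
        soma_radius_um=1.2,
        spines=[
            SpinePlacement(
                position_um=float(spine_pos),
                neck_length_um=0.6,
                head_radius_um=0.3,
                direction=(1.0, 0.0, 0.0),  # out of plane, away from both arms
            )
        ],
        seed=seed,
    )


def shifted_spec(spec: SceneSpec, shift_voxels: Sequence[float]) -> SceneSpec:
    """Translate a whole scene by a (z, y, x) voxel offset (same grid)."""
    dz = np.asarray(shift_voxels, dtype=float) * np.asarray(spec.spacing)
    new_path = spec.dendrite_path_um + dz
    new_soma = (
        tuple(np.asarray(spec.soma_center_um) + dz)
        if spec.soma_center_um is not None
        else None
    )
    return replace(
        spec,
        dendrite_path_um=new_path,
        soma_center_um=new_soma,
        spines=[replace(s) for s in spec.spines],
    )


# ---------------------------------------------------------------------------
# Degradation and augmentation


def degrade(v: VolumeImage, d: DegradeSpec) -> VolumeImage:
    """Blur with an elongated anisotropic PSF, add shot noise, add read noise.

    With zero sigmas, ``photon_scale=None`` and zero read noise this is the
    identity.  Poisson noise is drawn at the scaled intensity and rescaled,
    so ``photon_scale`` is the single SNR knob.
    """
    rng = np.random.default_rng(d.seed)
    out = v.voxels.astype(np.float32).copy()
    sigma_vox = (
        d.psf_sigma_axial_um / v.spacing[0],
        d.psf_sigma_lateral_um / v.spacing[1],
        d.psf_sigma_lateral_um / v.spacing[2],
    )
    for c in range(out.shape[0]):
        if any(s > 0 for s in sigma_vox):
            out[c] = ndi.gaussian_filter(out[c], sigma=sigma_vox)
        if d.photon_scale is not None and np.isfinite(d.photon_scale):
            out[c] = rng.poisson(np.clip(out[c], 0, None) * d.photon_scale) / d.photon_scale
        if d.read_noise_sigma > 0:
            out[c] = out[c] + rng.normal(0.0, d.read_noise_sigma, size=out[c].shape)
    return VolumeImage(out, v.spacing, list(v.channel_names))


_GEOMETRIC_OPS = ("rot90", "flip_z", "flip_y", "flip_x")
_NOISE_OPS = ("shot_noise", "gaussian_blur")


def augment_pair(
    image: VolumeImage,
    labels: SemanticLabelMap,
    ops: Sequence[str],
    seed: int = 0,
) -> list[tuple[VolumeImage, SemanticLabelMap]]:
    """Training-style augmentation of a matched image/label pair.

    Supported ops: right-angle ``rot90`` about z (random k ∈ {1,2,3}),
    per-axis flips, ``shot_noise`` and ``gaussian_blur``.  Geometric ops
    transform image and labels identically (labels stay hard nearest-
    neighbour values); noise and blur touch the image only.  One augmented
    pair is produced per requested op, reproducibly from the seed.
    Arbitrary-angle rotation is rejected: it would force label
    interpolation choices with no principled hard-label answer.
    """
    if image.grid_shape != labels.labels.shape:
        raise ValueError("image and label grids are not congruent")
    rng = np.random.default_rng(seed)
    out: list[tuple[VolumeImage, SemanticLabelMap]] = []
    for op in ops:
        if op == "rot90":
            k = int(rng.integers(1, 4))
            img = np.rot90(image.voxels, k=k, axes=(2, 3)).copy()
            lab = np.rot90(labels.labels, k=k, axes=(1, 2)).copy()
        elif op in ("flip_z", "flip_y", "flip_x"):
            ax = {"flip_z": 0, "flip_y": 1, "flip_x": 2}[op]
            img = np.flip(image.voxels, axis=ax + 1).copy()
            lab = np.flip(labels.labels, axis=ax).copy()
        elif op == "shot_noise":
            scale = 0.5
            img = (
                rng.poisson(np.clip(image.voxels.astype(float), 0, None) * scale) / scale
            ).astype(np.float32)
            lab = labels.labels.copy()
        elif op == "gaussian_blur":
            sigma = rng.uniform(0.5, 1.5)
            img = np.stack([
                ndi.gaussian_filter(image.voxels[c].astype(np.float32), sigma=sigma)
                for c in range(image.n_channels)
            ])
            lab = labels.labels.copy()
        else:
            raise ValueError(
                f"unsupported augmentation {op!r}; only right-angle rotations, "
                f"flips, shot noise and Gaussian blur are available"
            )
        out.append((
            VolumeImage(img, image.spacing, list(image.channel_names)),
            SemanticLabelMap(lab, labels.spacing, dict(labels.class_codes)),
        ))
    return out
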