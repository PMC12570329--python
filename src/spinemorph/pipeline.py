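"""Batch orchestration: configuration, logging, analysis runs, audit images.

The analysis stage consumes precomputed restored volumes and segmentation
label maps (``<stem>.tif`` paired with ``<stem>_labels.tif``); restoration
and segmentation themselves are adapter stages performed by external
tools.  Each image is processed independently — a failure is logged and
the run continues — and all outputs are written at the original
resolution even when analysis runs on a resampled grid.
"""

from __future__ import annotations

import colorsys
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml
from skimage.segmentation import find_boundaries

from . import io as vio
from .instances import FilterSpec, attach_all, extract_spine_instances, filter_spines, instance_label_map
from .io import SemanticLabelMap, VolumeImage
from .morphometry import measure_spines, skeletonize_dendrite, summarize

__all__ = [
    "PipelineConfig",
    "AnalysisResult",
    "run_analysis",
    "mip_overlay",
    "spine_crop_array",
    "instance_colors",
]

logger = logging.getLogger("spinemorph")


@dataclass
class PipelineConfig:
    """All user-facing knobs of an analysis run; loadable from one YAML file."""

    spacing: tuple[float, float, float] = (0.15, 0.065, 0.065)
    class_codes: dict[int, str] = field(default_factory=lambda: dict(vio.CLASS_CODES))
    min_volume_um3: float = 0.035
    max_volume_um3: float = 2.0
    max_distance_to_dendrite_um: float = 1.0
    analysis_spacing: tuple[float, float, float] | None = None
    connectivity: int = 26
    iou_threshold: float = 0.5
    tracking_min_iou: float = 0.3
    channel: int = 0
    n_channels: int = 1
    save_intermediates: bool = False
    save_overlays: bool = True
    save_spine_arrays: bool = False
    crop_size_um: float = 2.0
    seed: int = 0

    @property
    def filter_spec(self) -> FilterSpec:
        return FilterSpec(
            self.min_volume_um3, self.max_volume_um3, self.max_distance_to_dendrite_um
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key in ("spacing", "analysis_spacing") and value is not None:
                value = tuple(float(v) for v in value)
            if key == "class_codes":
                value = {int(k): str(v) for k, v in value.items()}
            setattr(cfg, key, value)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["spacing"] = list(self.spacing)
        if self.analysis_spacing is not None:
            data["analysis_spacing"] = list(self.analysis_spacing)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class AnalysisResult:
    """Per-image status of a batch run."""

    output_dir: Path
    statuses: dict[str, str]  # stem -> "ok" | error message

    @property
    def ok(self) -> bool:
        return all(s == "ok" for s in self.statuses.values())

    @property
    def n_failed(self) -> int:
        return sum(s != "ok" for s in self.statuses.values())


def _setup_run_logging(output_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(output_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler(sys.stderr))
    return handler


def run_analysis(
    input_dir: str | Path, output_dir: str | Path, config: PipelineConfig
) -> AnalysisResult:
    """Analyse every ``<stem>.tif`` / ``<stem>_labels.tif`` pair in a folder.

    Per image: optional rescale to the analysis spacing, instance
    extraction, filtering, morphometry, then per-spine CSV, instance map
    TIFF (at the original resolution), overlay PNG and optional
    intermediates.  Images without a matching label file are skipped with
    a warning; per-image failures do not stop the run.  A combined
    per-image summary CSV and the resolved config are always written.
    """
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(output_dir)
    statuses: dict[str, str] = {}
    summaries = []
    try:
        config.to_yaml(output_dir / "config.yaml")
        stems = sorted(
            p.stem for p in input_dir.glob("*.tif") if not p.stem.endswith("_labels")
        )
        logger.info("analysis run: %d candidate image(s) in %s", len(stems), input_dir)
        for stem in stems:
            label_path = input_dir / f"{stem}_labels.tif"
            if not label_path.exists():
                statuses[stem] = "skipped: no matching label file"
                logger.warning("%s: no matching label file, skipping", stem)
                continue
            try:
                summaries.append(_analyse_one(input_dir, output_dir, stem, config))
                statuses[stem] = "ok"
                logger.info("%s: ok", stem)
            except Exception as exc:  # noqa: BLE001 — isolate per-image failures
                statuses[stem] = f"failed: {exc}"
                logger.error("%s: failed: %s", stem, exc)
        vio.write_summary_table(summaries, output_dir / "summary.csv")
    finally:
        logger.removeHandler(handler)
        handler.close()
    return AnalysisResult(output_dir, statuses)


def _analyse_one(
    input_dir: Path, output_dir: Path, stem: str, config: PipelineConfig
):
    v = vio.read_volume(
        input_dir / f"{stem}.tif", config.spacing, n_channels=config.n_channels
    )
    m = vio.read_label_map(
        input_dir / f"{stem}_labels.tif", config.spacing, dict(config.class_codes)
    )
    if v.grid_shape != m.labels.shape:
        raise ValueError(
            f"image grid {v.grid_shape} does not match label grid {m.labels.shape}"
        )
    original_shape = m.labels.shape
    va, ma = v, m
    if config.analysis_spacing is not None:
        va = vio.rescale_volume(v, config.analysis_spacing, order="linear")
        ma = vio.rescale_label_map(m, config.analysis_spacing)

    instances = extract_spine_instances(ma, connectivity=config.connectivity)
    instances = attach_all(instances, ma)
    kept, rejected = filter_spines(instances, config.filter_spec, ma.spacing)
    records = measure_spines(kept, ma, va)
    tree = skeletonize_dendrite(ma)
    summary = summarize(records, tree, image_id=stem)

    vio.write_spine_table(records, output_dir / f"{stem}_spines.csv")
    inst_map = instance_label_map(kept, ma.labels.shape)
    if inst_map.shape != original_shape:  # analysis ran on a resampled grid
        inst_map = vio.rescale_instance_map(inst_map, ma.spacing, config.spacing)
    tifffile.imwrite(output_dir / f"{stem}_instances.tif", inst_map, software=None)
    if rejected:
        import pandas as pd

        pd.DataFrame(
            [{"instance_id": s.instance_id, "reason": reason} for s, reason in rejected]
        ).to_csv(output_dir / f"{stem}_rejected.csv", index=False)
    if config.save_overlays:
        mip_overlay(
            v, inst_map, output_dir / f"{stem}_overlay.png",
            channel=config.channel, seed=config.seed,
        )
    if config.save_intermediates:
        _save_intermediates(output_dir, stem, ma, tree)
    if config.save_spine_arrays and kept:
        spine_crop_array(
            va, inst_map if inst_map.shape == ma.labels.shape
            else instance_label_map(kept, ma.labels.shape),
            records, config.crop_size_um, output_dir / f"{stem}_spine_array",
            channel=config.channel,
        )
    vio.write_swc(tree, output_dir / f"{stem}_skeleton.swc")
    return summary


def _save_intermediates(output_dir: Path, stem: str, m: SemanticLabelMap, tree) -> None:
    from scipy import ndimage as ndi

    dendrite = m.mask("dendrite")
    dist = ndi.distance_transform_edt(~dendrite, sampling=m.spacing).astype(np.float32)
    tifffile.imwrite(output_dir / f"{stem}_distance_map.tif", dist, software=None)
    skel = np.zeros(m.labels.shape, dtype=np.uint8)
    vox = np.round(tree.coords_um / np.asarray(m.spacing)).astype(int)
    vox = np.clip(vox, 0, np.asarray(m.labels.shape) - 1)
    skel[tuple(vox.T)] = 1
    tifffile.imwrite(output_dir / f"{stem}_skeleton.tif", skel, software=None)


# ---------------------------------------------------------------------------
# Audit visuals


def instance_colors(n: int, seed: int = 0) -> np.ndarray:
    """n visually distinct RGB colours (uint8), stable for a given seed."""
    rng = np.random.default_rng(seed)
    start = rng.uniform(0, 1)
    hues = (start + np.arange(n) * 0.61803398875) % 1.0  # golden-ratio spacing
    return np.array(
        [np.round(np.array(colorsys.hsv_to_rgb(h, 0.9, 1.0)) * 255) for h in hues],
        dtype=np.uint8,
    ).reshape(n, 3)


def mip_overlay(
    v: VolumeImage,
    instance_map: np.ndarray,
    path: str | Path,
    channel: int = 0,
    seed: int = 0,
) -> np.ndarray:
    """Write a z-MIP of the reference channel with coloured instance outlines.

    The raw channel is rendered in grayscale; each instance's projected
    outline gets its own colour (stable across reruns for a fixed seed).
    Returns the RGB array that was written.
    """
    mip = v.voxels[channel].max(axis=0).astype(float)
    lo, hi = mip.min(), mip.max()
    gray = np.zeros_like(mip) if hi == lo else (mip - lo) / (hi - lo)
    rgb = np.repeat((gray * 255).astype(np.uint8)[..., np.newaxis], 3, axis=2)
    label_mip = np.asarray(instance_map).max(axis=0)
    ids = np.unique(label_mip)
    ids = ids[ids > 0]
    if ids.size:
        colors = instance_colors(int(ids.max()), seed=seed)
        for i in ids:
            outline = find_boundaries(label_mip == i, mode="outer")
            rgb[outline] = colors[int(i) - 1]
    iio.imwrite(Path(path), rgb)
    return rgb


def spine_crop_array(
    v: VolumeImage,
    instance_map: np.ndarray,
    records,
    crop_size_um: float,
    path_prefix: str | Path,
    channel: int = 0,
) -> list[bool]:
    """Write per-spine crops as a 2-D montage PNG and a stacked 3-D TIFF.

    Crops are centred on each spine's centroid (rounded to the voxel) and
    ordered by instance id.  Returns one clipped-crop flag per spine, True
    where the crop window extended past the volume border.
    """
    spacing = np.asarray(v.spacing)
    half = np.maximum((np.ceil(crop_size_um / (2 * spacing))).astype(int), 1)
    size = 2 * half + 1
    crops, mask_crops, clipped = [], [], []
    for rec in sorted(records, key=lambda r: r.instance_id):
        center = np.round(np.asarray(rec.centroid_um) / spacing).astype(int)
        lo = center - half
        hi = center + half + 1
        clip = bool(np.any(lo < 0) or np.any(hi > np.asarray(v.grid_shape)))
        clipped.append(clip)
        img_crop = np.zeros(tuple(size), dtype=v.voxels.dtype)
        msk_crop = np.zeros(tuple(size), dtype=np.uint16)
        src_lo = np.maximum(lo, 0)
        src_hi = np.minimum(hi, np.asarray(v.grid_shape))
        dst_lo = src_lo - lo
        dst_hi = dst_lo + (src_hi - src_lo)
        s_src = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
        s_dst = tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))
        img_crop[s_dst] = v.voxels[channel][s_src]
        msk_crop[s_dst] = np.where(
            np.asarray(instance_map)[s_src] == rec.instance_id, rec.instance_id, 0
        )
        crops.append(img_crop)
        mask_crops.append(msk_crop)
    if crops:
        stack = np.stack(crops)
        tifffile.imwrite(f"{path_prefix}_3d.tif", stack, software=None)
        tiles = [c.max(axis=0).astype(float) for c in crops]
        n = len(tiles)
        ncol = int(np.ceil(np.sqrt(n)))
        nrow = int(np.ceil(n / ncol))
        th, tw = tiles[0].shape
        montage = np.zeros((nrow * th, ncol * tw))
        for k, tile in enumerate(tiles):
            r, c = divmod(k, ncol)
            montage[r * th:(r + 1) * th, c * tw:(c + 1) * tw] = tile
        hi = montage.max()
        png = (montage / hi * 255).astype(np.uint8) if hi > 0 else montage.astype(np.uint8)
        iio.imwrite(f"{path_prefix}_montage.png", png)
    return clipped
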