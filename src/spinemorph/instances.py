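"""Spine instance extraction from semantic head/neck labels.

Instances are connected components of the head∪neck foreground.  Touching
spines are not split here: the upstream segmentation model is expected to
separate instances, and watershed-style splitting is a documented
extension point.  Thin necks fragment under 6-connectivity at coarse
z-steps, so 26-connectivity is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .io import SemanticLabelMap

__all__ = [
    "SpineInstance",
    "FilterSpec",
    "extract_spine_instances",
    "attach_to_dendrite",
    "attach_all",
    "filter_spines",
    "instance_label_map",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class SpineInstance:
    """One spine instance: head/neck voxel sets plus dendrite attachment.

    Voxel sets are ``(n, 3)`` integer arrays of (z, y, x) indices.
    ``attachment_point`` and ``distance_to_dendrite_um`` stay ``None``
    until :func:`attach_to_dendrite` fills them.
    """

    instance_id: int
    head_voxels: np.ndarray
    neck_voxels: np.ndarray
    attachment_point: tuple[int, int, int] | None = None
    distance_to_dendrite_um: float | None = None

    def __post_init__(self) -> None:
        self.head_voxels = np.asarray(self.head_voxels, dtype=int).reshape(-1, 3)
        self.neck_voxels = np.asarray(self.neck_voxels, dtype=int).reshape(-1, 3)
        if self.n_voxels == 0:
            raise ValueError("a spine instance must contain at least one voxel")

    @property
    def voxels(self) -> np.ndarray:
        """All instance voxels, head then neck."""
        return np.concatenate([self.head_voxels, self.neck_voxels], axis=0)

    @property
    def n_voxels(self) -> int:
        return len(self.head_voxels) + len(self.neck_voxels)

    def volume_um3(self, spacing: Sequence[float]) -> float:
        return self.n_voxels * float(np.prod(spacing))

    def head_volume_um3(self, spacing: Sequence[float]) -> float | None:
        if len(self.head_voxels) == 0:
            return None
        return len(self.head_voxels) * float(np.prod(spacing))

    def centroid_um(self, spacing: Sequence[float]) -> tuple[float, float, float]:
        c = self.voxels.mean(axis=0) * np.asarray(spacing, dtype=float)
        return tuple(float(v) for v in c)


@dataclass
class FilterSpec:
    """Constraints used to reject spurious spine detections.

    Defaults follow the commonly used 0.035–2 μm³ spine-volume window;
    ``max_distance_to_dendrite_um`` caps how far a detection may float
    from the nearest shaft voxel.
    """

    min_volume_um3: float = 0.035
    max_volume_um3: float = 2.0
    max_distance_to_dendrite_um: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.min_volume_um3 < self.max_volume_um3):
            raise ValueError("need 0 <= min_volume < max_volume")
        if self.max_distance_to_dendrite_um < 0:
            raise ValueError("max_distance_to_dendrite_um must be >= 0")


def extract_spine_instances(
    m: SemanticLabelMap, connectivity: int = 26
) -> list[SpineInstance]:
    """Split the head∪neck foreground into connected-component instances.

    Instance ids are assigned in descending component size; ties are broken
    by the lexicographically smallest (z, y, x) voxel of the component.
    Within each instance, voxels keep their semantic head/neck class.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6, 18, 26, got {connectivity}")
    if m.labels.ndim != 3:
        raise ValueError("expected a 3-D label grid")
    head = m.mask("spine_head")
    neck = m.mask("spine_neck")
    mask = head | neck
    structure = ndi.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    comp, n = ndi.label(mask, structure=structure)
    if n == 0:
        return []
    objects = ndi.find_objects(comp)
    keys = []
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        local = comp[sl] == lab
        size = int(local.sum())
        vox = np.argwhere(local) + [s.start for s in sl]
        # lexicographic minimum voxel for deterministic tie-breaking
        min_vox = vox[np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0]))[0]]
        keys.append((lab, size, tuple(int(v) for v in min_vox), vox))
    keys.sort(key=lambda k: (-k[1], k[2]))
    instances = []
    for new_id, (_lab, _size, _mv, vox) in enumerate(keys, start=1):
        is_head = head[tuple(vox.T)]
        instances.append(
            SpineInstance(
                instance_id=new_id,
                head_voxels=vox[is_head],
                neck_voxels=vox[~is_head],
            )
        )
    return instances


def _dendrite_edt(m: SemanticLabelMap):
    """Distance (μm) to the nearest dendrite voxel, plus that voxel's index."""
    dendrite = m.mask("dendrite")
    if not dendrite.any():
        raise ValueError("label map contains no dendrite voxels; cannot attach spines")
    dist, idx = ndi.distance_transform_edt(
        ~dendrite, sampling=m.spacing, return_indices=True
    )
    return dist, idx


def attach_to_dendrite(
    s: SpineInstance, m: SemanticLabelMap, _edt=None
) -> SpineInstance:
    """Fill in the attachment point and distance to the dendrite shaft.

    The distance is the minimum anisotropic Euclidean distance between any
    spine voxel centre and any dendrite voxel centre; the attachment point
    is the nearest dendrite voxel (ties resolved toward the smallest
    (z, y, x) index).
    """
    dist, idx = _edt if _edt is not None else _dendrite_edt(m)
    vox = s.voxels
    d = dist[tuple(vox.T)]
    dmin = d.min()
    at_min = vox[np.isclose(d, dmin, rtol=0, atol=1e-9)]
    cand = idx[:, at_min[:, 0], at_min[:, 1], at_min[:, 2]].T  # (k, 3) dendrite voxels
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0]))
    attach = tuple(int(v) for v in cand[order[0]])
    return replace(s, attachment_point=attach, distance_to_dendrite_um=float(dmin))


def attach_all(
    instances: list[SpineInstance], m: SemanticLabelMap
) -> list[SpineInstance]:
    """Attach every instance, sharing one distance transform."""
    if not instances:
        return []
    edt = _dendrite_edt(m)
    return [attach_to_dendrite(s, m, _edt=edt) for s in instances]


def filter_spines(
    instances: list[SpineInstance],
    spec: FilterSpec,
    spacing: Sequence[float],
) -> tuple[list[SpineInstance], list[tuple[SpineInstance, str]]]:
    """Apply volume and distance constraints.

    Returns ``(kept, rejected)`` where each rejected entry carries the name
    of the first violated rule (``min_volume``, ``max_volume`` or
    ``max_distance``).  Kept instances are relabelled 1..K preserving
    order.  Idempotent: filtering the kept list again changes nothing.
    """
    kept: list[SpineInstance] = []
    rejected: list[tuple[SpineInstance, str]] = []
    for s in instances:
        vol = s.volume_um3(spacing)
        if vol < spec.min_volume_um3:
            rejected.append((s, "min_volume"))
        elif vol > spec.max_volume_um3:
            rejected.append((s, "max_volume"))
        elif (
            s.distance_to_dendrite_um is not None
            and s.distance_to_dendrite_um > spec.max_distance_to_dendrite_um
        ):
            rejected.append((s, "max_distance"))
        else:
            kept.append(s)
    kept = [replace(s, instance_id=k) for k, s in enumerate(kept, start=1)]
    return kept, rejected


def instance_label_map(
    instances: list[SpineInstance], shape: Sequence[int], dtype=np.uint16
) -> np.ndarray:
    """Render instances into an integer map (0 = background, k = instance k)."""
    out = np.zeros(tuple(shape), dtype=dtype)
    for s in instances:
        vox = s.voxels
        out[tuple(vox.T)] = s.instance_id
    return out
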