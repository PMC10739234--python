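"""Explicit segmentation of CISS into four sub-volumes and of TOF into vessels.

The CISS volume is divided into CSF area, brainstem, cranial nerves and the
remainder. Seeded volume growing extracts the bright CSF of the basal
cisterns; morphological hole filling then pulls the enclosed hypointense
vessel flow voids into the CSF sub-volume (vessels are later delineated
implicitly by the transfer function). The brainstem is grown inside a
bounding box with the CSF as its ventral boundary; cranial nerves are tube
rasterizations of marked centerlines (the scripted stand-in for manual
marking). TOF vessels are grown from seeds placed in the hyperintense lumen.

Volume growing accepts the connected set of voxels whose intensity lies
within a fixed band around the mean of the seed values. The band is fixed
(not adapted while growing), which makes the result independent of the
processing order, monotone in the tolerance, and identical to a brute-force
flood fill.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import (
    BRAINSTEM,
    CSF,
    NERVE,
    REST,
    VESSEL,
    LabelMap,
    Volume,
    log,
)

# ---------------------------------------------------------------------------
# seeded volume growing
# ---------------------------------------------------------------------------


@dataclass
class SeedSet:
    """Seeds plus the homogeneity band and neighborhood of a volume growing run."""

    seeds: list[tuple[int, int, int]]
    tolerance: float                # max |value - mean(seed values)|
    connectivity: int = 6           # 6 or 26

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("seed set must contain at least one seed")
        if not self.tolerance > 0:
            raise ValueError(f"tolerance must be > 0, got {self.tolerance}")
        if self.connectivity not in (6, 26):
            raise ValueError(f"connectivity must be 6 or 26, got {self.connectivity}")
        self.seeds = [tuple(int(i) for i in s) for s in self.seeds]


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def _check_seeds(shape: tuple[int, int, int], seeds) -> None:
    for s in seeds:
        if len(s) != 3 or any(not 0 <= s[d] < shape[d] for d in range(3)):
            raise ValueError(f"seed {s} outside grid of shape {shape}")


def region_grow(v: Volume, s: SeedSet) -> np.ndarray:
    """Voxels reachable from the seeds through the chosen connectivity whose
    intensity deviates from the seed mean by at most the tolerance.

    Every seed must itself satisfy the criterion, otherwise the call errors.
    The result is a boolean mask; it is deterministic, independent of any
    processing order, and never shrinks when the tolerance grows.
    """
    _check_seeds(v.shape, s.seeds)
    idx = tuple(np.asarray(s.seeds).T)
    seed_values = v.values[idx].astype(float)
    mean = float(seed_values.mean())
    worst = float(np.abs(seed_values - mean).max())
    if worst > s.tolerance:
        raise ValueError(
            f"seed violates its own criterion: |value - seed mean| = {worst:.3f}"
            f" > tolerance {s.tolerance:.3f}"
        )
    band = np.abs(v.values.astype(float) - mean) <= s.tolerance
    labels, _ = ndimage.label(band, structure=_structure(s.connectivity))
    wanted = np.unique(labels[idx])
    mask = np.isin(labels, wanted[wanted > 0])
    return mask


# ---------------------------------------------------------------------------
# CISS sub-volumes
# ---------------------------------------------------------------------------


def segment_csf(ciss: Volume, s: SeedSet, hole_seal_mm: float = 0.8) -> np.ndarray:
    """Extract the CSF area of the basal cisterns including all vascular
    structures: bright-CSF volume growing followed by hole filling, so the
    enclosed hypointense flow voids become part of the CSF sub-volume.

    Hole filling is made robust against narrow leaks (dark artifact blobs
    touching the cistern surface can cut thin bright sheets and connect an
    otherwise enclosed flow void to the outside): the grown mask is dilated
    by ``hole_seal_mm``, holes are filled, and the result is eroded back,
    which seals leak channels narrower than twice the sealing radius while
    keeping the outer surface in place.
    """
    grown = region_grow(ciss, s)
    region_mean = float(ciss.values[grown].mean())
    bright_ref = float(np.percentile(ciss.values, 99))
    if region_mean < 0.8 * bright_ref:
        log.warning(
            "CSF seed sanity: grown region mean %.1f is well below the bright "
            "reference %.1f - seeds may sit in the wrong compartment",
            region_mean, bright_ref,
        )
    if hole_seal_mm > 0:
        ball = _ball_structure(hole_seal_mm / ciss.spacing)
        sealed = ndimage.binary_dilation(grown, structure=ball)
        filled = ndimage.binary_fill_holes(sealed)
        return grown | ndimage.binary_erosion(filled, structure=ball)
    return ndimage.binary_fill_holes(grown)


def segment_brainstem(
    ciss: Volume,
    csf_mask: np.ndarray,
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]],
    seed: tuple[int, int, int],
    tolerance: float = 12.0,
) -> np.ndarray:
    """Brainstem growth bounded laterally/dorsally by a box and ventrally by
    the segmented CSF: voxels inside the box, outside the CSF mask, within
    the tolerance band around the seed value, connected to the seed."""
    if not csf_mask.any():
        raise ValueError("empty CSF mask")
    shape = ciss.shape
    (i0, i1), (j0, j1), (k0, k1) = bbox
    if not (0 <= i0 < i1 <= shape[0] and 0 <= j0 < j1 <= shape[1]
            and 0 <= k0 < k1 <= shape[2]):
        raise ValueError(f"bbox {bbox} not inside grid of shape {shape}")
    _check_seeds(shape, [seed])
    box = np.zeros(shape, dtype=bool)
    box[i0:i1, j0:j1, k0:k1] = True
    seed_value = float(ciss.values[tuple(seed)])
    band = box & ~csf_mask & (np.abs(ciss.values - seed_value) <= tolerance)
    labels, _ = ndimage.label(band, structure=_structure(6))
    lab = labels[tuple(seed)]
    if lab == 0:
        raise ValueError("empty segment: seed not inside the brainstem band")
    mask = labels == lab
    if not mask.any():
        raise ValueError("empty segment")
    return mask


def mark_nerves(
    ciss: Volume,
    polylines: list[tuple[np.ndarray, float]],
) -> np.ndarray:
    """Tube rasterization of marked nerve centerlines (world mm, radius mm).

    In phantom studies the truth nerve centerline is passed in, emulating the
    expert's manual marking.
    """
    from .phantom import paint_tube  # local import; phantom depends on volumes only

    mask = np.zeros(ciss.shape, dtype=bool)
    for points, radius in polylines:
        points = np.asarray(points, dtype=float)
        if points.size == 0:
            raise ValueError("empty nerve polyline")
        if not radius > 0:
            raise ValueError("nerve radius must be > 0")
        if points.ndim != 2 or points.shape[1] != 3:
            raise ValueError("nerve polyline must be (N, 3) world points")
        lo = ciss.index(points).min()
        hi = (ciss.index(points) - (np.asarray(ciss.shape) - 1)).max()
        if lo < 0 or hi > 0:
            raise ValueError("nerve polyline outside grid")
        if len(points) == 1:
            points = np.vstack([points, points])
        paint_tube(mask, ciss, points, radius)
    return mask


def segment_tof_vessels(tof: Volume, s: SeedSet) -> np.ndarray:
    """Volume growing over the hyperintense TOF arteries; one seed per named
    trunk suffices on connected trees. Small fragments are reported."""
    _check_seeds(tof.shape, s.seeds)
    # arteries occupy a few tenths of a percent of a TOF volume, so the
    # 99.9th intensity percentile sits inside the bright lumen
    bright_ref = float(np.percentile(tof.values, 99.9))
    seed_values = tof.values[tuple(np.asarray(s.seeds).T)]
    if seed_values.min() < 0.5 * bright_ref:
        raise ValueError(
            "seed violates the vessel criterion: value "
            f"{seed_values.min():.1f} is not hyperintense "
            f"(bright reference {bright_ref:.1f})"
        )
    mask = region_grow(tof, s)
    labels, n = ndimage.label(mask, structure=_structure(s.connectivity))
    if n:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        small = int((sizes < 10).sum())
        if small:
            log.info("TOF vessel mask: %d fragment(s) smaller than 10 voxels", small)
    return mask


# ---------------------------------------------------------------------------
# scripted mask editing (the "-opt" stand-in for expert manual editing)
# ---------------------------------------------------------------------------

_EDIT_OPS = {"add_ball", "remove_ball", "keep_component", "remove_component",
             "fill_holes", "dilate", "erode"}


@dataclass
class MaskEditScript:
    """Ordered, replayable mask edits standing in for expert manual editing.

    Each operation is a mapping with an ``op`` key:
    ``add_ball``/``remove_ball`` (``center_mm``, ``radius_mm``),
    ``keep_component``/``remove_component`` (``seed`` voxel),
    ``fill_holes`` (no arguments), ``dilate``/``erode`` (``radius_mm``).
    """

    ops: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for op in self.ops:
            name = op.get("op")
            if name not in _EDIT_OPS:
                raise ValueError(f"unknown edit op {name!r}")
            if name in ("add_ball", "remove_ball", "dilate", "erode"):
                if not float(op.get("radius_mm", 0)) > 0:
                    raise ValueError(f"edit op {name} needs radius_mm > 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "MaskEditScript":
        return cls(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.ops, indent=1))


def _ball_structure(radius_vox: float) -> np.ndarray:
    r = max(1, int(np.floor(radius_vox)))
    grid = np.mgrid[-r: r + 1, -r: r + 1, -r: r + 1]
    return (grid**2).sum(axis=0) <= radius_vox**2


def _ball_voxels(grid: Volume, center_mm, radius_mm) -> tuple[np.ndarray, ...]:
    center = np.asarray(center_mm, dtype=float)
    r_vox = radius_mm / grid.spacing
    ci = grid.index(center)
    lo = np.maximum(np.floor(ci - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(ci + r_vox).astype(int) + 1, np.asarray(grid.shape))
    if np.any(lo >= hi):
        return (np.empty(0, int),) * 3
    ii, jj, kk = np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)],
                             indexing="ij")
    inside = ((ii - ci[0]) ** 2 + (jj - ci[1]) ** 2 + (kk - ci[2]) ** 2) <= r_vox**2
    return ii[inside], jj[inside], kk[inside]


def apply_edits(mask: np.ndarray, script: MaskEditScript, grid: Volume) -> np.ndarray:
    """Replay an edit script on a mask; balls are clipped to the grid and
    ``fill_holes`` is idempotent."""
    out = mask.copy()
    for op in script.ops:
        name = op["op"]
        if name == "add_ball":
            out[_ball_voxels(grid, op["center_mm"], op["radius_mm"])] = True
        elif name == "remove_ball":
            out[_ball_voxels(grid, op["center_mm"], op["radius_mm"])] = False
        elif name in ("keep_component", "remove_component"):
            seed = tuple(int(i) for i in op["seed"])
            _check_seeds(out.shape, [seed])
            labels, _ = ndimage.label(out, structure=_structure(6))
            lab = labels[seed]
            if name == "keep_component":
                out = labels == lab if lab else np.zeros_like(out)
            elif lab:
                out = out & (labels != lab)
        elif name == "fill_holes":
            out = ndimage.binary_fill_holes(out)
        elif name == "dilate":
            out = ndimage.binary_dilation(
                out, structure=_ball_structure(op["radius_mm"] / grid.spacing))
        elif name == "erode":
            out = ndimage.binary_erosion(
                out, structure=_ball_structure(op["radius_mm"] / grid.spacing))
    return out


# ---------------------------------------------------------------------------
# label assembly
# ---------------------------------------------------------------------------


def assemble_labels(
    csf: np.ndarray,
    brainstem: np.ndarray,
    nerves: np.ndarray,
    vessels: np.ndarray | None,
    grid: Volume,
) -> LabelMap:
    """Combine the binary masks into one partition with precedence
    VESSEL > NERVE > BRAINSTEM > CSF > REST."""
    masks = [m for m in (csf, brainstem, nerves, vessels) if m is not None]
    for m in masks:
        if m.shape != grid.shape:
            raise ValueError("all masks must share the grid geometry")
    labels = np.full(grid.shape, REST, dtype=np.uint8)
    labels[csf] = CSF
    labels[brainstem] = BRAINSTEM
    labels[nerves] = NERVE
    if vessels is not None:
        labels[vessels] = VESSEL
    return LabelMap(labels, grid.spacing, grid.origin.copy())
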