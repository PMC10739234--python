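"""Synthetic posterior-fossa phantoms with ground truth.

Each phantom is a paired CISS-like / TOF-like acquisition of a simplified
posterior fossa: an ellipsoidal basal cistern (bright CSF in CISS), a dorsal
brainstem cylindroid, two thin cranial nerves crossing the cistern, and a
nine-vessel arterial tree (BA, VA, PICA, AICA, SCA; paired vessels left and
right) rendered as dark flow voids in CISS and bright tubes in TOF. The TOF
volume lives in its own, rigidly misaligned frame. Vessels travelling outside
the main cistern carry a snug perivascular CSF sleeve, so every centerline
point lies in CSF and the CSF compartment tightly follows the vasculature.

Ground truth shipped with every phantom: the label map, the named centerline
tree with per-edge radii, the true TOF-to-CISS transform, and the list of
induced flow-void gaps. Artifact models are phenomenological: flow artifacts
replace the flow-void intensity of wide-lumen vessel segments with the CSF
level (the vessel simply vanishes from CISS), and pulsation artifacts add
periodic, geometrically decaying ghost replicas of the flow-void signal along
one grid axis (a stand-in for phase-encode ghosting), confined to the
neighborhood of the CSF compartment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .fusion import RigidTransform
from .volumes import (
    BRAINSTEM,
    CSF,
    NERVE,
    REST,
    VESSEL,
    LabelMap,
    PhantomConfig,
    Volume,
    log,
    write_volume,
)

VESSEL_NAMES = (
    "BA",
    "VA-le", "VA-ri",
    "PICA-le", "PICA-ri",
    "AICA-le", "AICA-ri",
    "SCA-le", "SCA-ri",
)


# ---------------------------------------------------------------------------
# vessel tree
# ---------------------------------------------------------------------------


@dataclass
class Branch:
    """One polyline segment of a named vessel; branch 0 is the trunk."""

    points: np.ndarray              # (N, 3) world mm
    radius: float                   # mm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("branch needs at least two 3D points")
        if not self.radius > 0:
            raise ValueError("branch radius must be > 0")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class VesselTree:
    """Named centerline tree with per-branch radii and scoring anchor points."""

    vessels: dict[str, list[Branch]]
    proximal_points: dict[str, np.ndarray]
    compression_point: np.ndarray
    compression_vessel: str

    def __post_init__(self) -> None:
        self.compression_point = np.asarray(self.compression_point, dtype=float)
        self.proximal_points = {
            k: np.asarray(v, dtype=float) for k, v in self.proximal_points.items()
        }

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.vessels)

    def max_radius(self, name: str) -> float:
        return max(b.radius for b in self.vessels[name])

    def wide_lumen_names(self, threshold_mm: float) -> list[str]:
        return [n for n in self.names if self.max_radius(n) >= threshold_mm]

    def all_branches(self) -> list[tuple[str, int, Branch]]:
        return [
            (name, i, b)
            for name, branches in self.vessels.items()
            for i, b in enumerate(branches)
        ]

    def transformed(self, transform: RigidTransform) -> "VesselTree":
        return VesselTree(
            {
                name: [Branch(transform.apply(b.points), b.radius) for b in branches]
                for name, branches in self.vessels.items()
            },
            {k: transform.apply(v) for k, v in self.proximal_points.items()},
            transform.apply(self.compression_point),
            self.compression_vessel,
        )

    # --- JSON schema: nodes as mm triples; edges as index pairs with radius,
    #     vessel name and branch index -------------------------------------

    def to_dict(self) -> dict:
        nodes: list[list[float]] = []
        edges: list[dict] = []

        def node_id(p: np.ndarray) -> int:
            for i, q in enumerate(nodes):
                if np.allclose(q, p, atol=1e-9):
                    return i
            nodes.append([float(x) for x in p])
            return len(nodes) - 1

        for name, branches in self.vessels.items():
            for bi, br in enumerate(branches):
                ids = [node_id(p) for p in br.points]
                for a, b in zip(ids[:-1], ids[1:]):
                    edges.append(
                        {"i": a, "j": b, "radius": br.radius, "name": name,
                         "branch": bi}
                    )
        return {
            "nodes": nodes,
            "edges": edges,
            "proximal_points": {
                k: [float(x) for x in v] for k, v in self.proximal_points.items()
            },
            "compression_point": [float(x) for x in self.compression_point],
            "compression_vessel": self.compression_vessel,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VesselTree":
        nodes = np.asarray(d["nodes"], dtype=float)
        vessels: dict[str, list[Branch]] = {}
        grouped: dict[tuple[str, int], list[tuple[int, int, float]]] = {}
        for e in d["edges"]:
            grouped.setdefault((e["name"], e["branch"]), []).append(
                (e["i"], e["j"], e["radius"])
            )
        for (name, bi), edge_list in grouped.items():
            pts = [nodes[edge_list[0][0]]]
            for _, j, _ in edge_list:
                pts.append(nodes[j])
            vessels.setdefault(name, []).append(
                Branch(np.asarray(pts), edge_list[0][2])
            )
        return cls(
            vessels,
            {k: np.asarray(v) for k, v in d["proximal_points"].items()},
            np.asarray(d["compression_point"]),
            d["compression_vessel"],
        )


def sample_polyline(points: np.ndarray, step_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample a polyline at fixed arc-length spacing.

    Returns ``(arc_positions_mm, sample_points)``; both endpoints included.
    """
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = max(2, int(np.floor(total / step_mm)) + 1)
    arcs = np.linspace(0.0, total, n)
    samples = np.empty((n, 3))
    for d in range(3):
        samples[:, d] = np.interp(arcs, cum, points[:, d])
    return arcs, samples


# ---------------------------------------------------------------------------
# tube rasterization
# ---------------------------------------------------------------------------


def _segment_distance_field(
    grid_shape: tuple[int, int, int],
    spacing: float,
    origin: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    reach: float,
):
    """Voxel indices within ``reach`` of segment p0-p1 and their distances."""
    lo_w = np.minimum(p0, p1) - reach - spacing
    hi_w = np.maximum(p0, p1) + reach + spacing
    lo = np.maximum(np.floor((lo_w - origin) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((hi_w - origin) / spacing).astype(int) + 1,
                    np.asarray(grid_shape))
    if np.any(lo >= hi):
        return None
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    pts = origin + spacing * np.stack([ii, jj, kk], axis=-1).astype(float)
    v = p1 - p0
    vv = float(v @ v)
    if vv == 0:
        t = np.zeros(pts.shape[:-1])
    else:
        t = np.clip(((pts - p0) @ v) / vv, 0.0, 1.0)
    closest = p0 + t[..., None] * v
    dist = np.linalg.norm(pts - closest, axis=-1)
    return (ii, jj, kk), dist, t


def paint_tube(
    mask: np.ndarray,
    grid: Volume,
    points: np.ndarray,
    radius: float,
) -> None:
    """OR a capsule tube around a polyline into ``mask`` (in place)."""
    points = np.asarray(points, dtype=float)
    for p0, p1 in zip(points[:-1], points[1:]):
        res = _segment_distance_field(mask.shape, grid.spacing, grid.origin,
                                      p0, p1, radius)
        if res is None:
            continue
        (ii, jj, kk), dist, _ = res
        inside = dist <= radius
        mask[ii[inside], jj[inside], kk[inside]] = True


def tube_axial_voxels(
    grid: Volume,
    points: np.ndarray,
    radius: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Lumen voxels of a polyline tube with their arc-length position (mm).

    Returns ``(indices (N, 3), axial_mm (N,))``; voxels near a joint are
    attributed to the segment that contains their closest point.
    """
    points = np.asarray(points, dtype=float)
    seg_len = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    found: dict[tuple[int, int, int], tuple[float, float]] = {}
    for s, (p0, p1) in enumerate(zip(points[:-1], points[1:])):
        res = _segment_distance_field(grid.shape, grid.spacing, grid.origin,
                                      p0, p1, radius)
        if res is None:
            continue
        (ii, jj, kk), dist, t = res
        inside = dist <= radius
        axial = cum[s] + t[inside] * seg_len[s]
        for idx, d, a in zip(
            zip(ii[inside].ravel(), jj[inside].ravel(), kk[inside].ravel()),
            dist[inside].ravel(), axial.ravel(),
        ):
            if idx not in found or d < found[idx][0]:
                found[idx] = (d, a)
    if not found:
        return np.empty((0, 3), dtype=int), np.empty(0)
    idx = np.asarray(list(found), dtype=int)
    ax = np.asarray([v[1] for v in found.values()])
    return idx, ax


# ---------------------------------------------------------------------------
# phantom spec and tree layout
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Study conditions of one phantom: geometry/intensity model, artifact
    settings, true misalignment and the RNG seed."""

    config: PhantomConfig = field(default_factory=PhantomConfig)
    seed: int = 0
    true_transform: RigidTransform | None = None  # None: drawn from the seed

    def __post_init__(self) -> None:
        self.config.validate()
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    def grid(self) -> Volume:
        n = self.config.shape
        return Volume(np.zeros((n, n, n), dtype=np.float32), self.config.spacing)


def _mirror(points: list[tuple[float, float, float]], side: int):
    return [(side * x, y, z) for x, y, z in points]


def build_tree(spec: PhantomSpec) -> VesselTree:
    """Deterministic nine-vessel layout around the grid center.

    The basilar artery (BA) is a midline trunk ending in two terminal
    branches; the vertebral arteries (VA) join it caudally; PICA branches off
    the VAs, AICA and SCA off the BA, each with two distal twigs. Coordinates
    are the grid center plus fixed offsets (mm) with a small seeded jitter on
    non-junction waypoints.
    """
    cfg = spec.config
    grid = spec.grid()
    half_extent = cfg.spacing * (cfg.shape - 1) / 2.0
    if half_extent < 12.6:
        raise ValueError(
            f"grid too small for the vessel layout: half extent {half_extent:.1f} mm"
            " < 12.6 mm"
        )
    c = grid.center
    rng = np.random.default_rng(spec.seed)

    def jit() -> np.ndarray:
        return rng.normal(0.0, 0.15, size=3)

    def P(x: float, y: float, z: float, jitter: bool = True) -> np.ndarray:
        p = c + np.array([x, y, z], dtype=float)
        return p + jit() if jitter else p

    vessels: dict[str, list[Branch]] = {}
    proximal: dict[str, np.ndarray] = {}

    # BA: midline trunk with two terminal (PCA-like) branches
    ba_start = P(0, -6, -8, jitter=False)
    ba_top = P(0, -6, 6, jitter=False)
    vessels["BA"] = [
        Branch([ba_start, P(0, -6, -1), ba_top], 1.7),
        Branch([ba_top, P(-4, -5, 9)], 1.0),
        Branch([ba_top, P(4, -5, 9)], 1.0),
    ]
    proximal["BA"] = ba_start

    for side, suffix in ((-1, "le"), (1, "ri")):
        # VA: enters caudally outside the cistern, joins the BA origin
        va_a = P(side * 5.5, -6, -11.5, jitter=False)
        va_b = P(side * 2.0, -6, -8.7, jitter=False)
        va_mid = (va_a + va_b) / 2.0                       # PICA takeoff
        twig_a0 = va_b + (ba_start - va_b) * 0.5           # on the distal VA
        vessels[f"VA-{suffix}"] = [
            Branch([va_a, va_b, ba_start], 1.4),
            Branch([twig_a0, P(side * 2.5, -7.5, -7)], 0.7),
            Branch([(va_a + va_mid) / 2.0, P(side * 5.5, -7.5, -9.5)], 0.7),
        ]
        proximal[f"VA-{suffix}"] = va_a

        # PICA: off the VA, curving laterally and dorsally
        pica_mid = P(side * 7, -4, -7, jitter=False)
        vessels[f"PICA-{suffix}"] = [
            Branch([va_mid, pica_mid, P(side * 8, -2, -4, jitter=False)], 1.0),
            Branch([pica_mid, P(side * 9, -5.5, -5.5)], 0.6),
            Branch([P(side * 8, -2, -4, jitter=False), P(side * 9, -1, -2)], 0.6),
        ]
        proximal[f"PICA-{suffix}"] = va_mid

        # AICA: off the lower BA
        aica_o = c + np.array([0.0, -6.0, -4.0])
        aica_mid = P(side * 6, -5, -3, jitter=False)
        vessels[f"AICA-{suffix}"] = [
            Branch([aica_o, aica_mid, P(side * 9, -3, -2, jitter=False)], 0.8),
            Branch([aica_mid, P(side * 7, -7, -1)], 0.55),
            Branch([P(side * 9, -3, -2, jitter=False), P(side * 10, -3, 0)], 0.55),
        ]
        proximal[f"AICA-{suffix}"] = aica_o

        # SCA: off the upper BA
        sca_o = c + np.array([0.0, -6.0, 4.0])
        sca_mid = P(side * 6, -5, 5, jitter=False)
        vessels[f"SCA-{suffix}"] = [
            Branch([sca_o, sca_mid, P(side * 8, -2, 6, jitter=False)], 0.8),
            Branch([sca_mid, P(side * 7, -6.5, 7)], 0.55),
            Branch([P(side * 8, -2, 6, jitter=False), P(side * 9, 0, 7)], 0.55),
        ]
        proximal[f"SCA-{suffix}"] = sca_o

    # the simulated syndrome: the left SCA abuts the left cranial nerve; the
    # contact site sits on the SCA surface closest to the nerve tip
    compression_point = c + np.array([-7.2, -3.0, 5.6])
    return VesselTree(vessels, proximal, compression_point, "SCA-le")


def nerve_polylines(spec: PhantomSpec) -> list[tuple[np.ndarray, float]]:
    """Truth cranial-nerve centerlines: thin tubes from the brainstem into
    the cistern; the left one approaches the compression site at the SCA
    (stopping a CSF-filled cleft short of the vessel surface)."""
    c = spec.grid().center
    left = np.array(
        [c + np.array([-5.0, 4.0, 5.0]), c + np.array([-5.5, 0.0, 5.0]),
         c + np.array([-5.7, -1.5, 5.0])]
    )
    right = np.array(
        [c + np.array([5.0, 4.0, 5.0]), c + np.array([5.5, 0.0, 5.0]),
         c + np.array([5.5, -2.0, 5.0])]
    )
    return [(left, 0.6), (right, 0.6)]


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _ellipsoid_mask(grid: Volume, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    shape = grid.shape
    coords = [grid.origin[d] + grid.spacing * np.arange(shape[d]) for d in range(3)]
    xx = (coords[0][:, None, None] - center[0]) / semi[0]
    yy = (coords[1][None, :, None] - center[1]) / semi[1]
    zz = (coords[2][None, None, :] - center[2]) / semi[2]
    return xx**2 + yy**2 + zz**2 <= 1.0


def _brainstem_mask(grid: Volume) -> np.ndarray:
    c = grid.center + np.array([0.0, 6.0, 0.0])
    shape = grid.shape
    coords = [grid.origin[d] + grid.spacing * np.arange(shape[d]) for d in range(3)]
    xx = (coords[0][:, None, None] - c[0]) / 8.0
    yy = (coords[1][None, :, None] - c[1]) / 6.0
    zz = np.abs(coords[2][None, None, :] - c[2]) <= 11.5
    return (xx**2 + yy**2 <= 1.0) & zz


def truth_vessel_mask(grid: Volume, tree: VesselTree,
                      extra_radius: float = 0.0) -> np.ndarray:
    mask = np.zeros(grid.shape, dtype=bool)
    for _, _, br in tree.all_branches():
        paint_tube(mask, grid, br.points, br.radius + extra_radius)
    return mask


def rasterize(
    spec: PhantomSpec, tree: VesselTree
) -> tuple[LabelMap, Volume, Volume]:
    """Rasterize truth labels and the CISS / TOF intensity volumes.

    Label precedence VESSEL > NERVE > BRAINSTEM > CSF > REST. The CSF
    compartment is the cistern ellipsoid united with a perivascular sleeve
    (vessel tube dilated by ``csf_sleeve_mm``). The TOF volume is rendered in
    a frame displaced by the inverse of the true transform.
    """
    cfg = spec.config
    grid = spec.grid()
    c = grid.center

    vessel = truth_vessel_mask(grid, tree)
    sleeve = truth_vessel_mask(grid, tree, extra_radius=cfg.csf_sleeve_mm)
    cistern = _ellipsoid_mask(grid, c + np.array([0.0, -3.5, 0.0]),
                              np.array([8.5, 6.5, 11.0]))
    csf = cistern | sleeve
    brainstem = _brainstem_mask(grid)
    nerve = np.zeros(grid.shape, dtype=bool)
    for pts, radius in nerve_polylines(spec):
        paint_tube(nerve, grid, pts, radius)

    labels = np.full(grid.shape, REST, dtype=np.uint8)
    labels[csf] = CSF
    labels[brainstem] = BRAINSTEM
    labels[nerve] = NERVE
    labels[vessel] = VESSEL
    truth = LabelMap(labels, cfg.spacing, grid.origin.copy())

    rng = np.random.default_rng(spec.seed + 1)
    ciss_means = np.array(
        [cfg.ciss_rest, cfg.ciss_csf, cfg.ciss_brainstem, cfg.ciss_nerve,
         cfg.ciss_vessel], dtype=np.float32,
    )
    ciss_values = ciss_means[labels]
    if cfg.noise_sd > 0:
        ciss_values = ciss_values + rng.normal(
            0.0, cfg.noise_sd, size=grid.shape
        ).astype(np.float32)
    ciss = Volume(ciss_values.astype(np.float32), cfg.spacing, grid.origin.copy())

    true_transform = _true_transform(spec, grid)
    tof_tree = tree.transformed(true_transform.inverse())
    tof_vessel = truth_vessel_mask(grid, tof_tree)
    tof_values = np.full(grid.shape, cfg.tof_background, dtype=np.float32)
    tof_values[tof_vessel] = cfg.tof_vessel
    if cfg.noise_sd > 0:
        tof_values = tof_values + rng.normal(
            0.0, cfg.noise_sd, size=grid.shape
        ).astype(np.float32)
    tof = Volume(tof_values.astype(np.float32), cfg.spacing, grid.origin.copy())
    return truth, ciss, tof


def _true_transform(spec: PhantomSpec, grid: Volume) -> RigidTransform:
    if spec.true_transform is not None:
        t = spec.true_transform
        return RigidTransform(t.rotation, t.translation, grid.center)
    rng = np.random.default_rng(spec.seed + 2)
    cfg = spec.config
    translation = rng.uniform(-cfg.misalign_translation_mm,
                              cfg.misalign_translation_mm, size=3)
    rotation = rng.uniform(-cfg.misalign_rotation_deg,
                           cfg.misalign_rotation_deg, size=3)
    return RigidTransform.from_euler(rotation, translation, grid.center)


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------


@dataclass
class InducedGap:
    vessel: str
    start_mm: float                 # arc position along the trunk
    end_mm: float

    @property
    def length(self) -> float:
        return self.end_mm - self.start_mm

    def to_dict(self) -> dict:
        return {"vessel": self.vessel, "start_mm": float(self.start_mm),
                "end_mm": float(self.end_mm)}


def inject_flow_artifacts(
    ciss: Volume,
    tree: VesselTree,
    spec: PhantomSpec,
    seed: int | None = None,
) -> tuple[Volume, list[InducedGap]]:
    """Erase random flow-void intervals on the configured wide-lumen vessels.

    For each affected vessel, one or more random trunk intervals (length drawn
    from the configured range) have their lumen voxels raised to the CSF
    intensity level, so the vessel segment becomes invisible in CISS.
    """
    cfg = spec.config
    rng = np.random.default_rng(spec.seed + 3 if seed is None else seed)
    out = ciss.copy()
    gaps: list[InducedGap] = []
    if cfg.flow_severity == 0:
        return out, gaps
    for name in cfg.flow_artifact_vessels:
        if name not in tree.vessels:
            raise ValueError(f"flow-artifact vessel {name!r} not in tree")
        trunk = tree.vessels[name][0]
        idx, axial = tube_axial_voxels(ciss, trunk.points,
                                       trunk.radius + 0.25 * ciss.spacing)
        total = trunk.length
        n_gaps = max(1, int(rng.poisson(cfg.flow_severity)))
        lo, hi = cfg.flow_gap_mm
        for _ in range(n_gaps):
            length = float(rng.uniform(lo, min(hi, total - 2.0)))
            start = float(rng.uniform(1.0, total - length - 1.0))
            sel = (axial >= start) & (axial <= start + length)
            vox = idx[sel]
            noise = rng.normal(0.0, cfg.noise_sd, size=len(vox)) if cfg.noise_sd else 0
            out.values[vox[:, 0], vox[:, 1], vox[:, 2]] = (
                cfg.ciss_csf + noise
            ).astype(np.float32)
            gaps.append(InducedGap(name, start, start + length))
    return out, gaps


def inject_pulsation_artifacts(
    ciss: Volume,
    truth: LabelMap,
    spec: PhantomSpec,
    seed: int | None = None,
) -> Volume:
    """Add periodic ghost replicas of the flow-void signal along one axis.

    The deviation of the CSF/vessel compartment from the CSF mean is copied at
    multiples of the ghost period (both directions) with geometrically
    decaying amplitude, producing spurious hypo-/hyper-intense blobs.
    Amplitude 0 is the identity. Ghosts are confined to the interior of the
    CSF compartment (its erosion by one voxel), so every ghost blob is
    strictly surrounded by CSF — it mimics how pulsation ghosting is only
    conspicuous inside the bright cistern.
    """
    cfg = spec.config
    if cfg.pulsation_amplitude == 0:
        return ciss.copy()
    rng = np.random.default_rng(spec.seed + 4 if seed is None else seed)
    amp = cfg.pulsation_amplitude * (1.0 + 0.1 * rng.uniform(-1.0, 1.0))
    support = (truth.values == CSF) | (truth.values == VESSEL)
    source = np.where(support, ciss.values - cfg.ciss_csf, 0.0).astype(np.float32)
    ghost = np.zeros_like(source)
    axis = cfg.pulsation_axis
    period = cfg.pulsation_period_vox
    n_max = ciss.shape[axis] // period
    for k in range(1, n_max + 1):
        weight = amp * cfg.pulsation_decay ** (k - 1)
        for sign in (1, -1):
            shifted = np.zeros_like(source)
            shift = sign * k * period
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if shift > 0:
                src[axis] = slice(0, source.shape[axis] - shift)
                dst[axis] = slice(shift, None)
            else:
                src[axis] = slice(-shift, None)
                dst[axis] = slice(0, source.shape[axis] + shift)
            shifted[tuple(dst)] = source[tuple(src)]
            ghost += weight * shifted
    interior = ndimage.binary_erosion(support)
    ghost[~interior] = 0.0
    out = ciss.copy()
    out.values = (out.values + ghost).astype(np.float32)
    return out


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------


@dataclass
class PhantomBundle:
    """Everything one phantom provides: images, ground truth, provenance."""

    spec: PhantomSpec
    ciss: Volume                    # artifact-laden CISS acquisition
    tof: Volume                     # TOF acquisition, own (misaligned) frame
    truth: LabelMap
    tree: VesselTree                # CISS (truth) frame
    true_transform: RigidTransform  # TOF world -> CISS world
    induced_gaps: list[InducedGap]
    nerves: list[tuple[np.ndarray, float]]
    tof_vessel_truth: np.ndarray    # truth vessel voxels in the TOF frame
    ciss_clean: Volume              # CISS before artifact injection

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_volume(self.ciss, out / "ciss.nii.gz")
        write_volume(self.tof, out / "tof.nii.gz")
        write_volume(self.truth, out / "truth.nii.gz")
        tree_doc = self.tree.to_dict()
        tree_doc["nerves"] = [
            {"points_mm": pts.tolist(), "radius_mm": float(r)}
            for pts, r in self.nerves
        ]
        (out / "tree.json").write_text(json.dumps(tree_doc, indent=1))
        (out / "transform.json").write_text(
            json.dumps(self.true_transform.to_dict(), indent=1)
        )
        (out / "gaps.json").write_text(
            json.dumps([g.to_dict() for g in self.induced_gaps], indent=1)
        )


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build the full phantom bundle for one seed (deterministic)."""
    tree = build_tree(spec)
    truth, ciss_clean, tof = rasterize(spec, tree)
    grid = spec.grid()
    true_transform = _true_transform(spec, grid)
    ciss, gaps = inject_flow_artifacts(ciss_clean, tree, spec)
    ciss = inject_pulsation_artifacts(ciss, truth, spec)
    tof_tree = tree.transformed(true_transform.inverse())
    tof_vessel_truth = truth_vessel_mask(grid, tof_tree)
    log.debug("phantom seed=%d: %d induced gaps, transform t=%s r=%s",
              spec.seed, len(gaps),
              np.round(true_transform.translation, 2),
              np.round(true_transform.angles_deg, 2))
    return PhantomBundle(
        spec=spec, ciss=ciss, tof=tof, truth=truth, tree=tree,
        true_transform=true_transform, induced_gaps=gaps,
        nerves=nerve_polylines(spec), tof_vessel_truth=tof_vessel_truth,
        ciss_clean=ciss_clean,
    )
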