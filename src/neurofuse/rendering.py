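"""Direct volume rendering by orthographic ray casting.

Each of the five sub-volume labels carries its own piecewise-linear transfer
function from intensity to color and opacity; vessels are delineated
implicitly by the CSF table (hypointense flow voids map to opaque red, bright
CSF to fully transparent), nerves render yellow, the brainstem light grey,
and surrounding structures are completely transparent. Compositing is
unshaded front-to-back emission-absorption with early ray termination.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .volumes import (
    BRAINSTEM,
    CSF,
    LABEL_NAMES,
    NERVE,
    REST,
    VESSEL,
    LabelMap,
    RenderingConfig,
    Volume,
)

# ---------------------------------------------------------------------------
# transfer functions
# ---------------------------------------------------------------------------


@dataclass
class TransferFunction:
    """Per-label piecewise-linear map intensity -> (R, G, B, opacity).

    Tables are ``(N, 5)`` arrays of ``[intensity, R, G, B, alpha]`` control
    points sorted by intensity; lookups clamp outside the control range.
    """

    tables: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for label, table in self.tables.items():
            t = np.asarray(table, dtype=float)
            if t.ndim != 2 or t.shape[1] != 5 or len(t) < 1:
                raise ValueError("transfer table must be (N, 5) [x, R, G, B, a]")
            if np.any(np.diff(t[:, 0]) < 0):
                raise ValueError("control points must be sorted by intensity")
            if np.any((t[:, 1:] < 0) | (t[:, 1:] > 1)):
                raise ValueError("channels and opacity must lie in [0, 1]")
            clean[int(label)] = t
        self.tables = clean

    @classmethod
    def default(cls, vessel_level: float = 25.0, csf_level: float = 100.0,
                tissue_alpha: float = 0.15) -> "TransferFunction":
        """Default tables: the CSF table renders flow voids opaque red and
        bright CSF transparent; nerves yellow, brainstem semi-transparent
        light grey, remainder fully transparent."""
        fade = vessel_level + 0.35 * (csf_level - vessel_level)
        return cls({
            REST: np.array([[0.0, 0, 0, 0, 0.0]]),
            CSF: np.array([
                [vessel_level, 1.0, 0.0, 0.0, 1.0],
                [fade, 1.0, 0.0, 0.0, 0.0],
                [csf_level, 0.0, 0.0, 0.0, 0.0],
            ]),
            BRAINSTEM: np.array([[0.0, 0.8, 0.8, 0.8, tissue_alpha]]),
            NERVE: np.array([[0.0, 1.0, 1.0, 0.2, 0.8]]),
            VESSEL: np.array([[0.0, 1.0, 0.0, 0.0, 1.0]]),
        })

    @classmethod
    def from_dict(cls, data: dict) -> "TransferFunction":
        """Build from a mapping of label names to control-point lists."""
        by_name = {v: k for k, v in LABEL_NAMES.items()}
        return cls({by_name[name]: np.asarray(points, dtype=float)
                    for name, points in data.items()})


def classify(
    intensity: np.ndarray,
    label: np.ndarray,
    tf: TransferFunction,
) -> np.ndarray:
    """RGBA (..., 4) for samples: piecewise-linear interpolation in the table
    of each sample's label, clamped outside the control range."""
    intensity = np.asarray(intensity, dtype=float)
    label = np.asarray(label)
    out = np.zeros(intensity.shape + (4,), dtype=float)
    for lab in np.unique(label):
        table = tf.tables.get(int(lab))
        if table is None:
            raise ValueError(f"no transfer table for label {lab}")
        sel = label == lab
        for ch in range(4):
            out[sel, ch] = np.interp(intensity[sel], table[:, 0], table[:, ch + 1])
    return out


# ---------------------------------------------------------------------------
# camera and image
# ---------------------------------------------------------------------------


@dataclass
class Camera:
    """Orthographic camera: parallel rays along ``direction`` through a
    ``width x height`` pixel grid centered on ``eye``."""

    eye: np.ndarray                 # mm
    direction: np.ndarray           # unit, after orthonormalization
    up: np.ndarray
    width: int = 120
    height: int = 120
    pixel_size: float = 0.4         # mm
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.eye = np.asarray(self.eye, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        u = np.asarray(self.up, dtype=float)
        if np.linalg.norm(d) == 0:
            raise ValueError("degenerate camera: zero view direction")
        d = d / np.linalg.norm(d)
        r = np.cross(d, u)
        if np.linalg.norm(r) < 1e-9:
            raise ValueError("degenerate camera: up parallel to view direction")
        r = r / np.linalg.norm(r)
        self.direction = d
        self.right = r
        self.up = np.cross(r, d)
        if self.width < 1 or self.height < 1 or not self.pixel_size > 0:
            raise ValueError("camera needs positive image size and pixel size")

    @classmethod
    def ventral(cls, grid: Volume, config: RenderingConfig | None = None) -> "Camera":
        """Default view onto the phantom: looking dorsally (+y) at the cistern."""
        config = config or RenderingConfig()
        extent = grid.spacing * max(grid.shape)
        eye = grid.center - np.array([0.0, extent, 0.0])
        return cls(eye, np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0]),
                   config.image_size, config.image_size, config.pixel_size_mm,
                   config.background)

    def ray_origins(self) -> np.ndarray:
        """(H, W, 3) world origins of all pixel rays."""
        px = (np.arange(self.width) - (self.width - 1) / 2.0) * self.pixel_size
        py = ((self.height - 1) / 2.0 - np.arange(self.height)) * self.pixel_size
        return (self.eye
                + py[:, None, None] * self.up[None, None, :]
                + px[None, :, None] * self.right[None, None, :])

    def project(self, points: np.ndarray) -> np.ndarray:
        """World points (..., 3) to fractional pixel coordinates (..., 2) (x, y)."""
        rel = np.asarray(points, dtype=float) - self.eye
        x = (rel @ self.right) / self.pixel_size + (self.width - 1) / 2.0
        y = (self.height - 1) / 2.0 - (rel @ self.up) / self.pixel_size
        return np.stack([x, y], axis=-1)


@dataclass
class RenderedImage:
    rgb: np.ndarray                 # (H, W, 3) in [0, 1]
    alpha: np.ndarray               # (H, W) accumulated opacity

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.round(self.rgb * 255.0), 0, 255).astype(np.uint8)

    def save_png(self, path: str | Path) -> None:
        Image.fromarray(self.to_uint8(), mode="RGB").save(str(path), format="PNG")


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------


def composite_front_to_back(
    rgba: np.ndarray, background: np.ndarray | tuple = (0.0, 0.0, 0.0)
) -> np.ndarray:
    """Front-to-back emission-absorption compositing of one ray.

    ``rgba`` is (N, 4) ordered front first; returns the final RGB with the
    background composited under the remaining transparency. This is the exact
    operation the renderer applies per sample:
    ``C += (1 - A) * a * c``; ``A += (1 - A) * a``.
    """
    c = np.zeros(3)
    a = 0.0
    for sample in np.asarray(rgba, dtype=float):
        c = c + (1.0 - a) * sample[3] * sample[:3]
        a = a + (1.0 - a) * sample[3]
    return c + (1.0 - a) * np.asarray(background, dtype=float)


def render(
    v: Volume,
    labels: LabelMap,
    tf: TransferFunction,
    cam: Camera,
    config: RenderingConfig | None = None,
) -> RenderedImage:
    """Cast one orthographic ray per pixel and composite front-to-back.

    Samples are spaced ``step_fraction * spacing`` along the ray; intensity is
    fetched trilinearly, the label nearest-neighbor (labels are categorical),
    classified through the per-label transfer function and accumulated with
    early termination once opacity reaches the configured bound.
    """
    config = config or RenderingConfig()
    if not v.same_geometry(labels):
        raise ValueError("volume and label map must share geometry")
    step = config.step_fraction * v.spacing
    origins = cam.ray_origins().reshape(-1, 3)
    d = cam.direction

    # conservative global parameter range from the volume's corner points
    corners = np.array(
        [v.origin + v.spacing * (np.array(v.shape) - 1) * sel
         for sel in np.ndindex(2, 2, 2)]
    )
    t_all = (corners[None, :, :] - origins[:, None, :]) @ d
    t0 = max(0.0, float(t_all.min()) - v.spacing)
    t1 = float(t_all.max()) + v.spacing
    n_steps = max(1, int(np.ceil((t1 - t0) / step)))

    color = np.zeros((origins.shape[0], 3))
    alpha = np.zeros(origins.shape[0])
    live = np.arange(origins.shape[0])
    for k in range(n_steps):
        t = t0 + k * step
        pts = origins[live] + t * d
        idx = v.index(pts).T
        intensity = ndimage.map_coordinates(v.values, idx, order=1,
                                            mode="constant", cval=0.0)
        lab = ndimage.map_coordinates(labels.values, idx, order=0,
                                      mode="constant", cval=REST)
        rgba = classify(intensity, lab, tf)
        trans = 1.0 - alpha[live]
        color[live] += (trans * rgba[:, 3])[:, None] * rgba[:, :3]
        alpha[live] += trans * rgba[:, 3]
        still = alpha[live] < config.early_exit_alpha
        if not still.all():
            live = live[still]
            if live.size == 0:
                break
    color += (1.0 - alpha)[:, None] * np.asarray(cam.background, dtype=float)
    h, w = cam.height, cam.width
    return RenderedImage(color.reshape(h, w, 3), alpha.reshape(h, w))


def render_variants(
    variants: dict[str, tuple[Volume, LabelMap]],
    tf: TransferFunction,
    cam: Camera,
    config: RenderingConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, RenderedImage]:
    """Render several datasets with one shared camera and transfer function —
    the side-by-side comparison surface of the four visualization variants.

    With ``out_dir`` set, each image is also written as ``<name>.png``.
    """
    images = {name: render(vol, lab, tf, cam, config)
              for name, (vol, lab) in variants.items()}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, img in images.items():
            img.save_png(out / f"{name}.png")
    return images
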