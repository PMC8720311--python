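"""Stack file formats and orientation-map rendering.

Stacks travel as multi-page TIFF (frame order = acquisition order) with an
adjacent JSON sidecar of the same basename carrying the modulation scheme,
pixel pitch, per-frame excitation angles and provenance.  The sidecar is the
single source of truth for angles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
from matplotlib.colors import hsv_to_rgb

from .modulation import DipoleField, ModulationScheme, PolarizationStack
from .orientation import OrientationMap

__all__ = [
    "StackMetadata",
    "RenderOptions",
    "read_stack",
    "write_stack",
    "write_field",
    "read_field",
    "render_orientation",
]

SOFTWARE_VERSION = "polsdom 0.1.0"


@dataclass
class StackMetadata:
    scheme: dict[str, Any]
    pixel_size_nm: float
    frame_angles_deg: list[float]
    acquisition_order: str = "angle-increasing"
    provenance: dict[str, Any] = field(default_factory=dict)
    ground_truth: str | None = None
    software: str = SOFTWARE_VERSION
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=_json_default)

    @classmethod
    def from_json(cls, text: str) -> "StackMetadata":
        d = json.loads(text)
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        return cls(**known)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: PolarizationStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus JSON sidecar; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    meta = StackMetadata(
        scheme=stack.scheme.to_dict(),
        pixel_size_nm=stack.pixel_size_nm,
        frame_angles_deg=[float(a) for a in stack.frame_angles_deg],
        provenance=stack.provenance,
        seed=stack.provenance.get("noise", {}).get("seed") if isinstance(stack.provenance.get("noise"), dict) else None,
    )
    _sidecar_path(path).write_text(meta.to_json())
    return path


def read_stack(path: str | Path) -> PolarizationStack:
    """Read a TIFF + sidecar stack, validating frame count against metadata."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {sidecar}; every stack TIFF needs an "
            "adjacent JSON file of the same basename (see write_stack)"
        )
    frames = np.asarray(tifffile.imread(path))
    if frames.ndim == 2:
        frames = frames[None]
    meta = StackMetadata.from_json(sidecar.read_text())
    scheme = ModulationScheme.from_dict(meta.scheme)
    n_pages = frames.shape[0]
    n_meta = len(meta.frame_angles_deg) if meta.frame_angles_deg else None
    if n_meta is not None and n_meta != n_pages:
        raise ValueError(
            f"sidecar lists {n_meta} frame angles but the TIFF has {n_pages} pages"
        )
    if n_pages not in (scheme.total_N, scheme.samples_per_period_M):
        raise ValueError(
            f"TIFF has {n_pages} pages; scheme expects N={scheme.total_N} or "
            f"M={scheme.samples_per_period_M}"
        )
    return PolarizationStack(
        frames.astype(float), scheme, meta.pixel_size_nm, dict(meta.provenance)
    )


def write_field(field_: DipoleField, path: str | Path) -> Path:
    """Ground truth as a 3-page TIFF (gdc, gac, alpha_deg) + sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.stack([field_.gdc, field_.gac, field_.alpha_deg]), photometric="minisblack")
    _sidecar_path(path).write_text(json.dumps(
        {"pages": ["gdc", "gac", "alpha_deg"], "pixel_size_nm": field_.pixel_size_nm},
        indent=2,
    ))
    return path


def read_field(path: str | Path) -> DipoleField:
    path = Path(path)
    pages = np.asarray(tifffile.imread(path))
    meta = json.loads(_sidecar_path(path).read_text())
    return DipoleField(pages[0], pages[1], pages[2], meta["pixel_size_nm"])


@dataclass(frozen=True)
class RenderOptions:
    mode: str = "hsv"  # 'hsv' or 'glyph'
    glyph_stride: int = 8
    glyph_length_px: float = 6.0
    clip_percentiles: tuple[float, float] = (0.0, 99.5)
    format: str = "png"

    def __post_init__(self) -> None:
        if self.glyph_stride < 1:
            raise ValueError("stride must be >= 1")
        lo, hi = self.clip_percentiles
        if not (0 <= lo < 100 and 0 <= hi < 100 and lo < hi):
            raise ValueError("clip percentiles must be in [0, 100) with lo < hi")


def _normalize_intensity(intensity: np.ndarray, opts: RenderOptions) -> np.ndarray:
    lo, hi = np.percentile(intensity, opts.clip_percentiles)
    if hi <= lo:  # (near-)constant image: full value wherever there is signal
        if hi > 0:
            return (intensity >= hi).astype(float)
        return np.zeros_like(intensity)
    return np.clip((intensity - lo) / (hi - lo), 0.0, 1.0)


def render_orientation(
    omap: OrientationMap,
    intensity: np.ndarray,
    opts: RenderOptions | None = None,
    path: str | Path | None = None,
) -> np.ndarray:
    """HSV composite (hue = alpha over [0,180), saturation = OUF, value =
    normalized intensity) with an optional glyph overlay of line segments
    whose direction is alpha and length is proportional to OUF.  Invalid
    pixels render desaturated.  Returns the RGB array; writes PNG if a path
    is given.  Output is deterministic."""
    opts = opts or RenderOptions()
    if intensity.shape != omap.ouf.shape:
        raise ValueError("intensity and map shapes must match")
    val = _normalize_intensity(np.asarray(intensity, dtype=float), opts)
    if not omap.valid.any():
        import warnings

        warnings.warn("all-invalid orientation map: intensity-only render", stacklevel=2)
        rgb = np.stack([val] * 3, axis=-1)
    else:
        hue = np.where(omap.valid, np.nan_to_num(omap.alpha_deg) / 180.0, 0.0)
        sat = np.where(omap.valid, omap.ouf, 0.0)
        rgb = hsv_to_rgb(np.stack([hue, sat, val], axis=-1))

    if opts.mode == "glyph" and omap.valid.any():
        rgb = rgb.copy()
        _burn_glyphs(rgb, omap, opts)

    if path is not None:
        import imageio.v3 as iio

        iio.imwrite(Path(path), (np.clip(rgb, 0, 1) * 255).astype(np.uint8))
    return rgb


def _burn_glyphs(rgb: np.ndarray, omap: OrientationMap, opts: RenderOptions) -> None:
    """Draw blue line segments (direction alpha, length ~ OUF) in place."""
    h, w = omap.ouf.shape
    stride = opts.glyph_stride
    for cy in range(stride // 2, h, stride):
        for cx in range(stride // 2, w, stride):
            if not omap.valid[cy, cx]:
                continue
            a = np.deg2rad(omap.alpha_deg[cy, cx])
            half = 0.5 * opts.glyph_length_px * omap.ouf[cy, cx]
            # CCW from X-axis with rows increasing downward
            dy, dx = -np.sin(a), np.cos(a)
            n = max(2, int(np.ceil(2 * half)) + 1)
            for t in np.linspace(-half, half, n):
                yy, xx = int(round(cy + t * dy)), int(round(cx + t * dx))
                if 0 <= yy < h and 0 <= xx < w:
                    rgb[yy, xx] = (0.3, 0.5, 1.0)
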