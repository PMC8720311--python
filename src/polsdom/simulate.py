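"""Forward simulator: polarization-modulated stacks from ground-truth fields.

Each frame ``n`` is the PSF-blurred cos^2 dipole response at excitation angle
``theta_n``, optionally attenuated by exponential photobleaching and sampled
with Poisson shot noise plus Gaussian read noise:

    I_n = Poisson(photon_scale * (1-rate)^n * [U * g(., theta_n)] + background)
          + Normal(0, read_sigma)

With ``noise=None`` (or ``photon_scale == 0``) the exact blurred model is
returned, which is what the analytic unit tests rely on.

Ground-truth fixtures (point pairs, filaments, random scatters) accumulate
overlapping emitters as AC phasors ``gac * exp(2j*alpha)`` so that crossing
structures combine exactly as the physics dictates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._conv import ReflectConvolver
from .modulation import DipoleField, ModulationScheme, PolarizationStack, PSFModel

__all__ = [
    "NoiseParams",
    "BleachParams",
    "render_stack",
    "fixture_two_points",
    "fixture_filament",
    "fixture_random_field",
    "apply_photobleaching",
]


@dataclass(frozen=True)
class NoiseParams:
    """Camera noise model: Poisson shot noise at ``photon_scale`` expected
    photons per model-intensity unit, plus Gaussian read noise."""

    photon_scale: float = 1000.0
    read_sigma: float = 2.0
    background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_scale < 0 or self.read_sigma < 0 or self.background < 0:
            raise ValueError("noise parameters must be nonnegative")


@dataclass(frozen=True)
class BleachParams:
    """Exponential photobleaching: frame ``n`` is scaled by ``(1-rate)^n``."""

    rate_per_frame: float = 0.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate_per_frame < 1.0):
            raise ValueError("rate_per_frame must be in [0, 1)")


def render_stack(
    field: DipoleField,
    psf: PSFModel,
    scheme: ModulationScheme,
    noise: NoiseParams | None = None,
    bleach: BleachParams | None = None,
) -> PolarizationStack:
    """Render the N-frame modulated stack for a ground-truth field."""
    if psf.pixel_size_nm != field.pixel_size_nm:
        raise ValueError(
            f"psf pixel size {psf.pixel_size_nm} nm != field pixel size "
            f"{field.pixel_size_nm} nm"
        )
    if min(field.shape) <= 2 * psf.support_radius_px and psf.kind != "delta":
        raise ValueError("PSF support does not fit within the field")

    theta = scheme.angles  # radians, length N
    alpha = np.deg2rad(field.alpha_deg)
    # gdc + gac * cos^2(theta - alpha) = gdc + gac/2 + gac/2 * cos 2(theta-alpha)
    cos2 = np.cos(2.0 * (theta[:, None, None] - alpha[None]))
    response = field.gdc[None] + field.gac[None] * 0.5 * (1.0 + cos2)

    if psf.kind == "delta" or psf.kernel.size == 1:
        blurred = response * psf.kernel.sum()
    else:
        conv = ReflectConvolver(psf.kernel, field.shape)
        blurred = conv.convolve_reflect(response)

    if bleach is not None and bleach.enabled and bleach.rate_per_frame > 0:
        decay = (1.0 - bleach.rate_per_frame) ** np.arange(scheme.total_N)
        blurred = blurred * decay[:, None, None]

    provenance: dict = {"source": "render_stack"}
    if noise is None or noise.photon_scale == 0:
        frames = blurred
        provenance["noise"] = None
    else:
        rng = np.random.default_rng(noise.seed)
        lam = np.clip(noise.photon_scale * blurred + noise.background, 0.0, None)
        frames = rng.poisson(lam).astype(float)
        if noise.read_sigma > 0:
            frames = frames + rng.normal(0.0, noise.read_sigma, size=frames.shape)
        provenance["noise"] = {
            "photon_scale": noise.photon_scale,
            "read_sigma": noise.read_sigma,
            "background": noise.background,
            "seed": noise.seed,
        }
    if bleach is not None:
        provenance["bleach"] = {
            "rate_per_frame": bleach.rate_per_frame,
            "enabled": bleach.enabled,
        }
    return PolarizationStack(frames, scheme, field.pixel_size_nm, provenance)


# ---------------------------------------------------------------------------
# ground-truth fixtures
# ---------------------------------------------------------------------------


class _PhasorAccumulator:
    """Accumulates gdc mass and complex AC phasors gac*exp(2j alpha), then
    collapses to a DipoleField.  Summing cos^2 responses with mixed
    orientations partially cancels the AC amplitude and converts the
    cancelled polarized mass into unpolarized (DC) emission:

        sum_i gac_i cos^2(t - a_i) = (sum gac_i - B)/2 + B cos^2(t - a_hat),

    with B = |sum_i gac_i exp(2j a_i)|; the collapse honours that identity
    exactly, so a combined field renders the same stack as the frame-by-frame
    sum of its parts."""

    def __init__(self, shape: tuple[int, int], pixel_size_nm: float):
        self.gdc = np.zeros(shape)
        self.gac_total = np.zeros(shape)
        self.phasor = np.zeros(shape, dtype=complex)
        self.pixel_size_nm = pixel_size_nm

    def splat(self, y: float, x: float, gdc: float, gac: float, alpha_deg: float) -> None:
        """Bilinear sub-pixel mass splatting (keeps total flux exact)."""
        h, w = self.gdc.shape
        y0, x0 = int(np.floor(y)), int(np.floor(x))
        fy, fx = y - y0, x - x0
        ph = gac * np.exp(2j * np.deg2rad(alpha_deg))
        for dy, wy in ((0, 1 - fy), (1, fy)):
            for dx, wx in ((0, 1 - fx), (1, fx)):
                yy, xx = y0 + dy, x0 + dx
                wgt = wy * wx
                if wgt == 0.0:
                    continue
                if not (0 <= yy < h and 0 <= xx < w):
                    raise ValueError(f"emitter at ({y:.2f}, {x:.2f}) px falls outside the grid")
                self.gdc[yy, xx] += wgt * gdc
                self.gac_total[yy, xx] += wgt * gac
                self.phasor[yy, xx] += wgt * ph

    def smooth(self, sigma_px: float) -> None:
        if sigma_px <= 0:
            return
        from scipy.ndimage import gaussian_filter

        self.gdc = gaussian_filter(self.gdc, sigma_px, mode="constant")
        self.gac_total = gaussian_filter(self.gac_total, sigma_px, mode="constant")
        self.phasor = gaussian_filter(self.phasor.real, sigma_px, mode="constant") + 1j * gaussian_filter(
            self.phasor.imag, sigma_px, mode="constant"
        )

    def to_field(self) -> DipoleField:
        gac = np.abs(self.phasor)
        alpha = np.mod(np.rad2deg(np.angle(self.phasor)) / 2.0, 180.0)
        # cancelled AC mass re-emerges as unpolarized emission
        gdc = self.gdc + 0.5 * np.clip(self.gac_total - gac, 0.0, None)
        return DipoleField(gdc, gac, alpha, self.pixel_size_nm)


def fixture_two_points(
    separation_nm: float,
    mean_alpha_deg: float = 45.0,
    delta_alpha_deg: float = 90.0,
    ouf: float = 1.0,
    peak: float = 1.0,
    shape: tuple[int, int] = (64, 64),
    pixel_size_nm: float = 20.0,
) -> DipoleField:
    """Two point emitters on the horizontal axis through the grid center,
    orientations ``mean_alpha +/- delta_alpha/2``, each of total brightness
    ``peak`` with anisotropy ``ouf``.  ``separation_nm = 0`` merges them."""
    if not (0.0 <= ouf <= 1.0):
        raise ValueError("ouf must be in [0, 1]")
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    half_px = separation_nm / 2.0 / pixel_size_nm
    if cx - half_px < 0 or cx + half_px > w - 1:
        raise ValueError("separation exceeds grid extent")
    acc = _PhasorAccumulator(shape, pixel_size_nm)
    for sgn, da in ((-1.0, -delta_alpha_deg / 2.0), (+1.0, +delta_alpha_deg / 2.0)):
        gac = ouf * peak
        gdc = peak - gac
        acc.splat(cy, cx + sgn * half_px, gdc, gac, mean_alpha_deg + da)
    return acc.to_field()


def fixture_filament(
    shape: tuple[int, int],
    centerline: Sequence[tuple[float, float]],
    width_nm: float = 60.0,
    ouf: float = 1.0,
    tangent_aligned: bool = True,
    constant_alpha_deg: float = 0.0,
    peak: float = 1.0,
    pixel_size_nm: float = 20.0,
) -> DipoleField:
    """A smooth intensity ridge along a polyline of (row, col) pixel points.

    With ``tangent_aligned`` the dipole orientation follows the local tangent
    of the centerline; otherwise it is ``constant_alpha_deg`` everywhere.
    """
    pts = np.asarray(centerline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("centerline must contain at least two points")
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if np.all(seg_len == 0):
        raise ValueError("degenerate polyline")

    acc = _PhasorAccumulator(shape, pixel_size_nm)
    step = 0.25  # px between samples along the ridge
    for (p0, d, length) in zip(pts[:-1], seg, seg_len):
        if length == 0:
            continue
        n_samples = max(2, int(np.ceil(length / step)) + 1)
        t = np.linspace(0.0, 1.0, n_samples)
        ds = length / (n_samples - 1)
        # image rows increase downward, so the CCW-from-X angle uses -dy
        alpha = (
            np.mod(np.rad2deg(np.arctan2(-d[0], d[1])), 180.0)
            if tangent_aligned
            else constant_alpha_deg
        )
        mass = peak * ds
        for ti in t:
            y, x = p0 + ti * d
            acc.splat(y, x, (1.0 - ouf) * mass, ouf * mass, alpha)
    acc.smooth(width_nm / 2.355 / pixel_size_nm)
    return acc.to_field()


def fixture_random_field(
    shape: tuple[int, int] = (64, 64),
    ouf_range: tuple[float, float] = (0.3, 1.0),
    density: float = 0.01,
    seed: int = 0,
    peak: float = 1.0,
    pixel_size_nm: float = 20.0,
    return_emitters: bool = False,
):
    """Reproducible random scatter of emitters with uniform orientations on
    [0, 180) and anisotropy uniform in ``ouf_range``.

    With ``return_emitters`` also returns the drawn per-emitter table
    ``{"y", "x", "alpha_deg", "ouf"}`` (arrays), handy for statistical checks
    that should not be confounded by sub-pixel splatting overlap.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    h, w = shape
    n = max(0, int(round(density * h * w)))
    acc = _PhasorAccumulator(shape, pixel_size_nm)
    margin = 1.0
    ys = rng.uniform(margin, h - 1 - margin, size=n)
    xs = rng.uniform(margin, w - 1 - margin, size=n)
    alphas = rng.uniform(0.0, 180.0, size=n)
    oufs = rng.uniform(ouf_range[0], ouf_range[1], size=n)
    for y, x, alpha, ouf in zip(ys, xs, alphas, oufs):
        acc.splat(y, x, (1.0 - ouf) * peak, ouf * peak, alpha)
    field = acc.to_field()
    if return_emitters:
        return field, {"y": ys, "x": xs, "alpha_deg": alphas, "ouf": oufs}
    return field


def apply_photobleaching(stack: PolarizationStack, bleach: BleachParams) -> PolarizationStack:
    """Multiply frame n by ``(1 - rate)^n``."""
    if not bleach.enabled or bleach.rate_per_frame == 0:
        return stack
    decay = (1.0 - bleach.rate_per_frame) ** np.arange(stack.n_frames)
    frames = stack.frames * decay[:, None, None]
    prov = dict(stack.provenance)
    prov["bleach"] = {"rate_per_frame": bleach.rate_per_frame, "enabled": True}
    return PolarizationStack(frames, stack.scheme, stack.pixel_size_nm, prov)
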