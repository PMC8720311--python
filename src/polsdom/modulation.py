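"""Physical model of polarization-modulated dipole emission.

A fluorophore with in-plane dipole orientation ``alpha`` excited by linearly
polarized light at angle ``theta`` emits

    g(theta) = g_dc + g_ac * cos^2(theta - alpha)

where ``g_dc`` is the polarization-invariant (DC) part and ``g_ac`` the
polarization-variant (AC) amplitude.  Both angles are axial quantities,
defined modulo 180 degrees, measured counterclockwise from the image X-axis
(columns increase along X).  Degrees are used at every public interface;
radians internally.

This module also defines the shared containers: the excitation sampling plan
(:class:`ModulationScheme`), the ground-truth object (:class:`DipoleField`),
the detection PSF (:class:`PSFModel`) and the measurement
(:class:`PolarizationStack`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.special import j1

__all__ = [
    "ModulationScheme",
    "DipoleField",
    "PSFModel",
    "PolarizationStack",
    "make_modulation_scheme",
    "motor_to_polarization",
    "emission_response",
    "anisotropy",
]

#: modulation frequency of the cos^2 response: one cycle per pi radians of
#: excitation polarization angle (the polarization sweeps pi per OLID period)
F_MOD = 1.0 / np.pi


@dataclass(frozen=True)
class ModulationScheme:
    """Excitation-angle sampling plan: ``m`` OLID periods of ``M`` frames.

    One OLID period is a pi sweep of the excitation polarization (one full
    cos^2 modulation cycle).  Frame ``n`` is excited at
    ``theta_n = n * pi / M + phase_offset``.
    """

    periods_m: int = 4
    samples_per_period_M: int = 30
    phase_offset_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.periods_m < 1:
            raise ValueError(f"periods_m must be >= 1, got {self.periods_m}")
        if self.samples_per_period_M < 4:
            raise ValueError(
                "samples_per_period_M must be >= 4 (Nyquist for the 2-theta "
                f"cosine), got {self.samples_per_period_M}"
            )

    @property
    def total_N(self) -> int:
        return self.periods_m * self.samples_per_period_M

    @property
    def delta_theta(self) -> float:
        """Angular step in radians; ``delta_theta * M == pi`` exactly."""
        return np.pi / self.samples_per_period_M

    @property
    def f_mod(self) -> float:
        return F_MOD

    @property
    def angles(self) -> np.ndarray:
        """Excitation polarization angles in radians, length ``total_N``."""
        n = np.arange(self.total_N)
        return n * self.delta_theta + np.deg2rad(self.phase_offset_deg)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.rad2deg(self.angles)

    def single_period(self) -> "ModulationScheme":
        """The same sampling restricted to one OLID period (m = 1)."""
        return replace(self, periods_m=1)

    # -- serialization (embedded in stack metadata sidecars) ---------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "periods": self.periods_m,
            "samples_per_period": self.samples_per_period_M,
            "phase_offset_deg": self.phase_offset_deg,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModulationScheme":
        return cls(
            periods_m=int(d["periods"]),
            samples_per_period_M=int(d["samples_per_period"]),
            phase_offset_deg=float(d.get("phase_offset_deg", 0.0)),
        )


def make_modulation_scheme(
    periods_m: int = 4,
    samples_per_period_M: int = 30,
    phase_offset_deg: float = 0.0,
) -> ModulationScheme:
    """Build a :class:`ModulationScheme` with ``angles[n] = n*pi/M``."""
    return ModulationScheme(periods_m, samples_per_period_M, phase_offset_deg)


def motor_to_polarization(motor_angle_deg):
    """Polarization angle produced by a half-wave plate at ``motor_angle_deg``.

    The HWP rotates linear polarization by twice its own angle, so one full
    motor rotation sweeps the polarization twice around, i.e. the cos^2
    response completes exactly 4 modulation cycles per 360 deg of motor.
    """
    return np.mod(2.0 * np.asarray(motor_angle_deg, dtype=float), 360.0)


def emission_response(gdc, gac, alpha_deg, theta_deg):
    """Emission intensity ``gdc + gac * cos^2(theta - alpha)``.

    All arguments broadcast; angles in degrees.  The excitation intensity
    I0 is absorbed into the units of ``gdc``/``gac``.
    """
    gdc = np.asarray(gdc, dtype=float)
    gac = np.asarray(gac, dtype=float)
    if np.any(gdc < 0) or np.any(gac < 0):
        raise ValueError("gdc and gac must be nonnegative")
    d = np.deg2rad(np.asarray(theta_deg, dtype=float) - np.asarray(alpha_deg, dtype=float))
    return gdc + gac * np.cos(d) ** 2


def anisotropy(gdc, gac):
    """Fluorescence anisotropy ``p = gac / (gac + gdc)`` in [0, 1].

    Where both components are zero the anisotropy is undefined and NaN is
    returned.
    """
    gdc = np.asarray(gdc, dtype=float)
    gac = np.asarray(gac, dtype=float)
    total = gdc + gac
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, gac / np.where(total > 0, total, 1.0), np.nan)
    if p.ndim == 0:
        return float(p)
    return p


@dataclass
class DipoleField:
    """Ground-truth per-pixel dipole populations on a regular grid.

    Pixel centers sit at integer indices; physical position is
    ``index * pixel_size_nm`` with the origin at the top-left pixel center.
    """

    gdc: np.ndarray
    gac: np.ndarray
    alpha_deg: np.ndarray
    pixel_size_nm: float = 20.0

    def __post_init__(self) -> None:
        self.gdc = np.asarray(self.gdc, dtype=float)
        self.gac = np.asarray(self.gac, dtype=float)
        self.alpha_deg = np.mod(np.asarray(self.alpha_deg, dtype=float), 180.0)
        if not (self.gdc.shape == self.gac.shape == self.alpha_deg.shape):
            raise ValueError("gdc, gac and alpha_deg must share a shape")
        if np.any(self.gdc < 0) or np.any(self.gac < 0):
            raise ValueError("gdc and gac must be nonnegative")

    @property
    def height(self) -> int:
        return self.gdc.shape[0]

    @property
    def width(self) -> int:
        return self.gdc.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.gdc.shape

    def anisotropy(self) -> np.ndarray:
        return anisotropy(self.gdc, self.gac)

    @classmethod
    def empty(cls, shape: tuple[int, int], pixel_size_nm: float = 20.0) -> "DipoleField":
        z = np.zeros(shape)
        return cls(z, z.copy(), z.copy(), pixel_size_nm)


def _gaussian_kernel(fwhm_px: float) -> np.ndarray:
    sigma = fwhm_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    radius = max(1, int(np.ceil(3.5 * sigma)))
    x = np.arange(-radius, radius + 1)
    xx, yy = np.meshgrid(x, x)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return k / k.sum()


def _airy_kernel(fwhm_px: float) -> np.ndarray:
    # (2 J1(v)/v)^2 reaches half maximum at v = 1.61633; scale r so the
    # discretized pattern has the requested FWHM.
    v_half = 1.61633
    scale = 2.0 * v_half / fwhm_px  # v per pixel of radius
    radius = max(2, int(np.ceil(2.5 * fwhm_px)))
    x = np.arange(-radius, radius + 1)
    xx, yy = np.meshgrid(x, x)
    r = np.hypot(xx, yy) * scale
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = np.where(r == 0, 1.0, 2.0 * j1(np.where(r == 0, 1.0, r)) / np.where(r == 0, 1.0, r))
    k = amp**2
    return k / k.sum()


@dataclass(frozen=True)
class PSFModel:
    """Detection point spread function U(r), discretized and unit-normalized."""

    kind: str = "gaussian"
    fwhm_nm: float = 200.0
    pixel_size_nm: float = 20.0
    kernel: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "airy", "delta"):
            raise ValueError(f"unknown PSF kind {self.kind!r}")
        if self.kernel is None:
            fwhm_px = self.fwhm_nm / self.pixel_size_nm
            if self.kind == "delta" or fwhm_px == 0:
                k = np.ones((1, 1))
            elif self.kind == "gaussian":
                k = _gaussian_kernel(fwhm_px)
            else:
                k = _airy_kernel(fwhm_px)
            object.__setattr__(self, "kernel", k)

    @property
    def support_radius_px(self) -> int:
        return self.kernel.shape[0] // 2

    @classmethod
    def delta(cls, pixel_size_nm: float = 20.0) -> "PSFModel":
        return cls(kind="delta", fwhm_nm=0.0, pixel_size_nm=pixel_size_nm)

    def with_pixel_size(self, pixel_size_nm: float) -> "PSFModel":
        """Re-discretize the same physical PSF on a different grid pitch."""
        return PSFModel(kind=self.kind, fwhm_nm=self.fwhm_nm, pixel_size_nm=pixel_size_nm)


@dataclass
class PolarizationStack:
    """N-frame image stack I(R, theta_n) with its excitation-angle metadata.

    Noiseless simulated frames are nonnegative; noisy frames may contain
    small negative excursions from Gaussian read noise, which every
    downstream stage tolerates.
    """

    frames: np.ndarray
    scheme: ModulationScheme
    pixel_size_nm: float = 20.0
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be an (N, H, W) array")
        n = self.frames.shape[0]
        if n not in (self.scheme.total_N, self.scheme.samples_per_period_M):
            raise ValueError(
                f"frame count {n} matches neither N={self.scheme.total_N} "
                f"nor M={self.scheme.samples_per_period_M} of the scheme"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def periods_present(self) -> int:
        """m if the full multi-period stack is present, else 1."""
        if self.frames.shape[0] == self.scheme.total_N:
            return self.scheme.periods_m
        return 1

    @property
    def frame_angles(self) -> np.ndarray:
        """Excitation angle (radians) of each stored frame."""
        return self.scheme.angles[: self.n_frames]

    @property
    def frame_angles_deg(self) -> np.ndarray:
        return np.rad2deg(self.frame_angles)
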