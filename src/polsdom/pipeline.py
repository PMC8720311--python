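"""Pipeline orchestration: configuration, run_pipeline, frame rolling.

``run_pipeline`` is a thin functional wrapper over the :class:`~polsdom.model.OLIDSDOM`
facade; ``rolling_reconstruct`` applies it to a sliding window over a
time-lapse acquisition, advancing one OLID period per output so the effective
temporal resolution is one reconstruction per period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .model import OLIDSDOM, OLIDSDOMResults
from .modulation import ModulationScheme, PolarizationStack, PSFModel
from .orientation import DEFAULT_VALIDITY_THRESHOLD, CalibrationCurve
from .reconstruct import DeconvOptions

__all__ = ["PipelineConfig", "run_pipeline", "rolling_reconstruct"]


@dataclass
class PipelineConfig:
    """Per-stage pipeline settings; mirrors the YAML config sections."""

    psf_kind: str = "gaussian"
    psf_fwhm_nm: float = 200.0
    deconvolve: bool = True
    deconv: DeconvOptions = field(default_factory=DeconvOptions)
    validity_threshold: float = DEFAULT_VALIDITY_THRESHOLD
    calibration_offset_deg: float = 0.0
    warm_start: bool = False  # reuse the previous window's result in rolling mode

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        deconv = DeconvOptions(**d.pop("deconv", {}))
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d and k != "deconv"}
        return cls(deconv=deconv, **known)

    def to_dict(self) -> dict[str, Any]:
        out = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "deconv"}
        out["deconv"] = vars(self.deconv).copy()
        return out

    def build_model(self, stack: PolarizationStack) -> OLIDSDOM:
        psf = PSFModel(self.psf_kind, self.psf_fwhm_nm, stack.pixel_size_nm)
        calib = (
            CalibrationCurve(phase_offset_deg=self.calibration_offset_deg)
            if self.calibration_offset_deg
            else None
        )
        return OLIDSDOM(
            stack,
            psf=psf,
            deconv_options=self.deconv,
            calibration=calib,
            validity_threshold=self.validity_threshold,
        )


def run_pipeline(stack: PolarizationStack, config: PipelineConfig | dict | None = None) -> OLIDSDOMResults:
    """OLID filter -> FISTA deconvolution -> FFTPE -> OUF, in that order."""
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    model = config.build_model(stack)
    res = model.fit(deconvolve=config.deconvolve)
    res.report["config"] = config.to_dict()
    return res


def rolling_reconstruct(
    timelapse: np.ndarray,
    scheme: ModulationScheme,
    config: PipelineConfig | dict | None = None,
    pixel_size_nm: float = 20.0,
    step: int | None = None,
) -> list[OLIDSDOMResults]:
    """Sliding-window reconstruction of a T-frame time-lapse.

    The window is one full acquisition (N = m*M frames) advanced by ``step``
    frames (default M, one OLID period), yielding
    ``(T - N) // step + 1`` reconstructions.  Each window's scheme carries
    the excitation phase at which that window starts, so orientation maps
    are consistent across windows.
    """
    timelapse = np.asarray(timelapse, dtype=float)
    window = scheme.total_N
    M = scheme.samples_per_period_M
    step = M if step is None else step
    T = timelapse.shape[0]
    if T < window:
        raise ValueError(f"time-lapse has {T} frames; window needs {window}")
    if window % step:
        raise ValueError("step must divide the window length")

    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)

    results: list[OLIDSDOMResults] = []
    for start in range(0, T - window + 1, step):
        offset = np.rad2deg(start * scheme.delta_theta) % 180.0
        win_scheme = replace(scheme, phase_offset_deg=(scheme.phase_offset_deg + offset) % 180.0)
        stack = PolarizationStack(
            timelapse[start : start + window],
            win_scheme,
            pixel_size_nm,
            {"source": "rolling", "window_start": start},
        )
        results.append(run_pipeline(stack, config))
    return results
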