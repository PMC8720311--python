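"""Optical lock-in detection (OLID): frequency-domain filtering of the
multi-period stack.

Each pixel's N = m*M frame trace is a two-harmonic signal

    a + b * cos(2*theta_n - phi),    theta_n = n*pi/M,

living entirely in DFT bins {0, +m, N-m}.  OLID keeps exactly those bins and
resynthesizes a single M-frame period, so a noiseless trace's first period is
reproduced to machine precision while white noise retains only 3 of N bins —
a noise-variance reduction of 3/N, i.e. 10*log10(N/3) dB on the noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .modulation import PolarizationStack

__all__ = ["OLIDResult", "olid_filter", "snr_gain_db"]


@dataclass
class OLIDResult:
    """Denoised single-period stack plus the retained per-pixel spectrum."""

    single_period: PolarizationStack
    kept_dc: np.ndarray  # complex G(R, 0)
    kept_mod: np.ndarray  # complex G(R, m)
    discarded_power: np.ndarray  # mean squared amplitude of the zeroed bins

    @property
    def kept_spectrum(self) -> dict[str, np.ndarray]:
        """Retained bins: DC, the +m modulation bin and its conjugate."""
        return {"dc": self.kept_dc, "mod": self.kept_mod, "mod_conj": np.conj(self.kept_mod)}


def olid_filter(stack: PolarizationStack, detrend: bool = False) -> OLIDResult:
    """Lock-in filter: retain DFT bins {0, m, N-m}, synthesize one period.

    Scaling is fixed by the contract that a noiseless modulated input's
    first period is reproduced exactly:  with A = G(R,0)/N and the complex
    modulation coefficient c = G(R,m), the output trace is

        y[n] = A + (2|c|/N) * cos(2*n*delta_theta + arg c).

    ``detrend`` optionally removes a linear per-pixel trend (photobleaching
    compensation); off by default since bleaching is treated as negligible.
    """
    scheme = stack.scheme
    m, M, N = scheme.periods_m, scheme.samples_per_period_M, scheme.total_N
    if stack.n_frames != N:
        raise ValueError(
            f"olid_filter needs the full m*M = {N}-frame stack, got {stack.n_frames}"
        )

    frames = stack.frames
    if detrend:
        n = np.arange(N)
        slope = (np.mean(frames * (n - n.mean())[:, None, None], axis=0)) / np.mean(
            (n - n.mean()) ** 2
        )
        frames = frames - slope[None] * (n - n.mean())[:, None, None]

    spec = np.fft.fft(frames, axis=0)  # kernel e^{-j 2 pi k n / N}
    g0 = spec[0]
    gm = spec[m]

    total_power = np.sum(np.abs(spec) ** 2, axis=0)
    kept_power = np.abs(g0) ** 2 + np.abs(gm) ** 2 + np.abs(spec[N - m]) ** 2
    discarded_power = (total_power - kept_power) / N**2

    a = g0.real / N
    amp = 2.0 * np.abs(gm) / N
    phase = np.angle(gm)
    theta_m = np.arange(M) * scheme.delta_theta
    y = a[None] + amp[None] * np.cos(2.0 * theta_m[:, None, None] + phase[None])

    out_scheme = scheme.single_period()
    prov = dict(stack.provenance)
    prov["olid"] = {"periods_m": m, "kept_bins": [0, m, N - m], "detrend": detrend}
    single = PolarizationStack(y, out_scheme, stack.pixel_size_nm, prov)
    return OLIDResult(single, g0, gm, discarded_power)


def snr_gain_db(
    reference_clean: PolarizationStack,
    noisy: PolarizationStack,
    filtered: OLIDResult,
) -> float:
    """SNR improvement of the OLID output over the raw first period, in dB.

    SNR = 10*log10(sum signal^2 / sum (estimate - signal)^2) over one period;
    the gain is SNR(filtered) - SNR(raw).  Returns ``inf`` (saturated) when
    the filtered output matches the reference exactly.
    """
    M = filtered.single_period.n_frames
    ref = reference_clean.frames[:M]
    if ref.shape != filtered.single_period.frames.shape:
        raise ValueError("reference and filtered shapes are incompatible")
    sig_power = float(np.sum(ref**2))
    if sig_power == 0:
        raise ValueError("reference signal power is zero")

    err_filt = float(np.sum((filtered.single_period.frames - ref) ** 2))
    err_raw = float(np.sum((noisy.frames[:M] - ref) ** 2))
    if err_filt == 0:
        return float("inf")
    snr_filt = 10.0 * np.log10(sig_power / err_filt)
    snr_raw = 10.0 * np.log10(sig_power / err_raw) if err_raw > 0 else float("inf")
    return snr_filt - snr_raw
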