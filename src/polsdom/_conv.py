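"""FFT convolution with reflective boundaries, and the exact adjoint pair
used by the deconvolver.

Both the forward simulator and the reconstruction share one operator:
reflect-pad by the kernel radius, convolve circularly on the padded grid,
crop back.  For kernels whose support fits inside the pad this reproduces
``scipy.ndimage.convolve(mode="reflect")`` exactly while keeping every
transform a cached batched FFT.

The deconvolver keeps its unknown on the *padded* grid so that the
forward/adjoint pair (crop o circ-conv, circ-corr o zero-embed) is exactly
adjoint — a requirement for monotone FISTA.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import irfft2, next_fast_len, rfft2


class ReflectConvolver:
    """Convolve (H, W) images (or (..., H, W) batches) with a fixed kernel
    under reflective boundary handling."""

    def __init__(self, kernel: np.ndarray, shape: tuple[int, int]):
        kernel = np.asarray(kernel, dtype=float)
        self.kernel = kernel
        self.shape = tuple(shape)
        self.radius = (kernel.shape[0] // 2, kernel.shape[1] // 2)
        ph = shape[0] + 2 * self.radius[0]
        pw = shape[1] + 2 * self.radius[1]
        self.padded_shape = (ph, pw)
        self.fshape = (next_fast_len(ph), next_fast_len(pw))
        # center the kernel at the origin of the circular domain
        kpad = np.zeros(self.fshape)
        kh, kw = kernel.shape
        kpad[:kh, :kw] = kernel
        kpad = np.roll(kpad, (-self.radius[0], -self.radius[1]), axis=(0, 1))
        self._kfft = rfft2(kpad)
        self._kfft_conj = np.conj(self._kfft)

    # -- circular pieces on the padded grid --------------------------------
    def conv_padded(self, g: np.ndarray) -> np.ndarray:
        """Circular convolution of padded-grid array(s) with the kernel."""
        return self._apply(g, self._kfft)

    def corr_padded(self, g: np.ndarray) -> np.ndarray:
        """Circular correlation (adjoint of :meth:`conv_padded`)."""
        return self._apply(g, self._kfft_conj)

    def _apply(self, g: np.ndarray, kfft: np.ndarray) -> np.ndarray:
        ph, pw = self.padded_shape
        if g.shape[-2:] != self.padded_shape:
            raise ValueError(f"expected padded shape {self.padded_shape}, got {g.shape[-2:]}")
        G = rfft2(g, s=self.fshape)
        out = irfft2(G * kfft, s=self.fshape)
        return np.ascontiguousarray(out[..., :ph, :pw])

    # -- reflect-boundary convolution on the data grid ----------------------
    def pad(self, img: np.ndarray) -> np.ndarray:
        rh, rw = self.radius
        if rh == 0 and rw == 0:
            return np.asarray(img, dtype=float)
        return np.pad(img, [(0, 0)] * (img.ndim - 2) + [(rh, rh), (rw, rw)], mode="reflect")

    def crop(self, padded: np.ndarray) -> np.ndarray:
        rh, rw = self.radius
        return padded[..., rh : rh + self.shape[0], rw : rw + self.shape[1]]

    def embed(self, img: np.ndarray) -> np.ndarray:
        """Zero-embed a data-grid array into the padded grid (adjoint of crop)."""
        rh, rw = self.radius
        out = np.zeros(img.shape[:-2] + self.padded_shape)
        out[..., rh : rh + self.shape[0], rw : rw + self.shape[1]] = img
        return out

    def convolve_reflect(self, img: np.ndarray) -> np.ndarray:
        """Reflect-boundary linear convolution of data-grid image(s)."""
        return self.crop(self.conv_padded(self.pad(img)))


def bin_image(img: np.ndarray, factor: int) -> np.ndarray:
    """Sum-bin the trailing two axes by an integer factor."""
    if factor == 1:
        return img
    *lead, h, w = img.shape
    if h % factor or w % factor:
        raise ValueError("image shape not divisible by binning factor")
    return img.reshape(*lead, h // factor, factor, w // factor, factor).sum(axis=(-3, -1))


def replicate_image(img: np.ndarray, factor: int) -> np.ndarray:
    """Adjoint of :func:`bin_image`: replicate each pixel factor x factor."""
    if factor == 1:
        return img
    return np.repeat(np.repeat(img, factor, axis=-2), factor, axis=-1)
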