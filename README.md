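# polsdom

Super-resolved dipole orientation mapping from polarization-modulated
fluorescence image stacks, with optical lock-in detection (OLID), FISTA
least-squares deconvolution and FFT phase extraction (FFTPE).

## The problem

A fluorophore's absorption/emission dipole has an in-plane orientation
`α ∈ [0°, 180°)`. Under rotating linear-polarized excitation at angle `θ`
its emission modulates as

```
g(θ) = g_dc + g_ac · cos²(θ − α)
```

where `g_dc` is the polarization-invariant part and `g_ac` the modulated
amplitude. In live cells this modulation is often weak — buried under shot
noise, background and the spatial averaging of mixed-orientation dipoles —
so orientation mapping has historically been limited to strongly polarized
samples. The approach implemented here recovers weak modulation by

1. **OLID** — acquiring `m` modulation periods (`N = m·M` frames, one π
   sweep of polarization per period), Fourier-transforming each pixel's
   temporal trace, and keeping only the DC bin and the modulation-frequency
   bins `{0, m, N−m}`. White noise retains 3 of N bins, a
   `10·log10(N/3) ≈ 16 dB` noise-floor reduction at `m=4, M=30`.
2. **Spatial–angular deconvolution** — least-squares FISTA inversion of the
   camera blur on the full M-frame angular stack,
   `min_g Σ_θ ‖U ∗ g(·,θ) − I(·,θ)‖²`, with no sparsity penalty and an
   optional nonnegativity projection. Because emitters with different
   orientations light up in *different frames*, angular difference acts as
   extra separation: orthogonal dipoles can be split well below the 200 nm
   diffraction limit.
3. **FFTPE** — per-pixel DFT of the reconstructed modulation:
   `A = G(0)/N`, `B = 2|G(m)|/N`, `α = −arg G(m)/2 (mod 180°)`, and the
   orientation uniformity factor

```
OUF = 2B / (A + B)  ∈ [0, 1]
```

which equals the anisotropy `p = g_ac/(g_ac+g_dc)` at a single-emitter
pixel: 1 means perfectly uniform dipoles, 0 fully isotropic.

A forward simulator (PSF blur, Poisson + read noise, photobleaching,
point/filament/random-field fixtures) makes every stage testable with no
external data.

## Worked example

```python
import numpy as np
from polsdom import OLIDSDOM, DeconvOptions, fixture_two_points

# a 120 nm "nanoruler": two orthogonal dipoles, fully polarized
field = fixture_two_points(separation_nm=120, mean_alpha_deg=45,
                           delta_alpha_deg=90, ouf=1.0)
model = OLIDSDOM.from_simulation(field, seed=1,
                                 deconv_options=DeconvOptions(upsample=2))
res = model.fit()
print(res.summary())
```

prints

```
OLID-SDOM reconstruction results
==================================
frames              120
scheme (m x M)      4 x 30
pixel size [nm]     20
PSF                 gaussian, FWHM 200 nm
deconvolved         yes
FISTA iterations    200
objective initial   3.23e+04
objective final     1.278e+04
valid pixels        21.1 %
mean OUF (valid)    0.995
median OUF (valid)  1.000
```

The stack has 4 OLID periods of 30 frames; after lock-in filtering and
deconvolution on a 2× upsampled grid the modulated component `G_ac` shows
two distinct peaks ≈120 nm apart (the mean image `G_dc` shows a single
diffraction-limited blob — only the modulated channel separates the pair),
and the valid pixels around each emitter carry OUF near 1 with orientations
near 0° and 90°. `res.plot_orientation("map.png")` renders the HSV
composite (hue = α, saturation = OUF, value = intensity).

The same stages are scriptable from the shell:

```bash
polsdom simulate --separation-nm 120 --delta-alpha 90 --out-dir sim
polsdom pipeline sim/stack.tif --out-dir recon
polsdom render recon/orientation.tif --mode glyph --out-dir fig
polsdom bench --scenario snr-gain --out-dir bench
```

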