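# Methods

## The codec

`framecodec` implements frequency-multiplexed single-exposure videography:
N time-resolved frames are stored simultaneously on one camera image by
giving each frame a unique sinusoidal spatial carrier, and are recovered by
a frequency-sensitive 2D spatial lock-in.

**Encoding.** A frame I(x, y) illuminated with fringe contrast m at carrier
frequency ν = (ν_x, ν_y) (cycles/pixel) becomes

    I(x, y) · [1 + m cos(2π(ν_x x + ν_y y) + φ)]

The multiplicative form `1 + m cos` keeps illumination non-negative; no
renormalization by (1 + m) is applied, since the decoder restores amplitude
with the 2/m factor. In reciprocal space this places a conjugate pair of
copies of the frame spectrum at ±ν, each attenuated by m/2, on top of the
shared unmodulated baseband. Natural images concentrate spectral energy near
DC, so most of reciprocal space is vacant and many copies fit without
overlap. The coordinate convention is row-major, origin top-left, x = column
index, y = row index, fringe phase referenced at pixel (0, 0).

The sensor model scales the multiplexed sum so its maximum fills the
full-well capacity, optionally applies Poisson shot noise and Gaussian read
noise in electrons, and quantizes by floor (ADC truncation) to B bits with
clipping, so a noise-free exposure always peaks at 2^B − 1. Overlapping
frames share the well: N equal-mean copies on a B-bit sensor keep
B − log₂N bits each (8 copies on 16 bits → 13 bits).

**Decoding.** Each frame is recovered by multiplying the exposure with
exp(−i2π ν·x) — an exact transfer of the +ν spectral copy to the origin,
valid for carriers that are not an integer number of cycles across the
image — applying a circular band-pass window of radius r at DC, inverse
transforming, and taking (2/m)·|·|. Only the upper-half-plane sideband is
demodulated; for real images the conjugate sideband is redundant. The
modulus (rather than the real part) makes the result independent of the
unknown absolute fringe phase, at the cost of rectifying any negative
interference residue. By the modulation theorem this is identical, to
machine precision, to convolving the demodulated image with the window's
spatial kernel; the test suite verifies the two routes against each other
at 1e−9.

The window radius sets the decoded resolution: content finer than about
1/(2r) pixels cannot pass the band-pass. Three tapers are provided:

- `gaussian` (default): σ = r/2, truncated at 3σ. Smooth spatial kernel,
  minimal ringing, but the passband is not flat — content at frequency f is
  attenuated by exp(−f²/2σ²), which biases quantitative amplitudes.
- `hard`: exact band-pass. Flat passband (band-limited content passes
  exactly), slowly decaying spatial kernel.
- `tukey`: flat core with a raised-cosine skirt of adjustable width.

Quantitative round-trip measurements in this package use the hard window,
where strictly band-limited content is transmitted with unit gain and the
residual error is the ADC quantization floor (NRMSE ~2·10⁻⁶ at 16 bits).

**Carrier detection.** Carriers can be recovered blind from the exposure:
the Tukey-apodized (taper 0.2) spectrum is searched for 3×3 local maxima
outside a DC exclusion disk that exceed 5× the local spectral background.
The background is the pointwise maximum of the global median, a 7×7 median
and 51-point medians along each frequency axis; the axis medians track the
one-bin-wide ridges of baseband leakage (apodization sidelobes of DC) that
otherwise produce false peaks. Accepted peaks are refined to sub-bin
precision with a 3×3 magnitude centroid. Detection presumes the scene
spectrum is compact, i.e. the spectral copies are isolated peaks; scenes
whose content fills a large fraction of the band (e.g. objects a few pixels
across) yield diffuse copies and detection legitimately refuses rather
than guessing.

**Carrier packing.** Codebooks are planned deterministically on concentric
rings in the annulus between the baseband (r₀ + r) and the optical cutoff
(otf − r), with angles uniform over [0, π) — conjugate symmetry halves the
usable angular range. All separation checks include each carrier's mirror
at −ν. The required spacing is 2r (adjacent windows touching) times a guard
factor of 1.1 for window skirts. The ring construction lower-bounds the
geometric packing optimum but is reproducible and ample for N ≤ 16.

**Commensurate carriers.** A carrier with a non-integer number of fringe
cycles across the detector is not periodic on the grid, and the discrete
transform leaks border energy into every band-pass window (worst for
carriers on a frequency axis, where the leakage collapses onto a single
spectral line; observed round-trip NRMSE up to ~0.1). Real gratings are
incommensurate and the decoder accepts arbitrary carriers, but when the
sensor size is known in advance `packing.snap_codebook` rounds each
frequency to the nearest DFT bin (≤ half a bin per component, re-validated
against the separation constraints), which removes the leakage entirely.
All quantitative synthetic studies here use snapped codebooks.

## The light-in-flight simulator

The synthetic ground-truth generator models the pump–probe Kerr-gate
experiment: a pump pulse crosses a CS₂ cell along x, inducing transient
birefringence; read pulses crossing along z are gated by it between crossed
polarizers, and the camera integrates the transmitted light along z.

- **Pulses** are rigid separable Gaussians: temporal FWHM T (default
  125 fs), speed c/n (n = 1.63 for CS₂, back-derived from the 23 µm per
  125 fs travel of light in the medium), transverse 1/e² radius growing
  linearly with an optional divergence angle. Group-velocity dispersion,
  absorption and pump depletion are neglected — the model is geometric
  propagation at constant speed.
- **Gate.** The birefringence follows the pump intensity low-passed by the
  orientational relaxation of the medium: G = (1/τ) ∫ I(t′) e^{−(t−t′)/τ} dt′,
  normalized so τ → 0 recovers the instantaneous intensity. Because the
  pump intensity at a fixed point is Gaussian in time, G has an
  exponentially-modified-Gaussian closed form, evaluated exactly via the
  scaled complementary error function (`erfcx`, stable for any τ ≥ 0). The
  default τ = 1.6 ps is a typical CS₂ orientational value; results are
  asserted only as limits and monotonicity, never against that number.
  Finite τ drags a trailing skirt of gated signal behind the pump; the
  time-integrated total is conserved up to the sliver of skirt clipped at
  the cell edges.
- **Gate transmission is linearized** (proportional to G): the small-
  retardance regime of a crossed-polarizer Kerr cell. The gate is
  profile-governed, not binary.
- **Frames.** S(x, y) = ∫dz ∫dt I_read · G by midpoint quadrature: the time
  step is min(T_pump, T_read)/10 over the window in which the read pulse is
  inside the cell, and the closed-form gate separates the (x, t) and (y, z)
  dependencies so the integral reduces to small matrix contractions. The z
  and t axes are quadrature axes and must resolve the pulses with at least
  4 samples; x and y are imaging axes where coarse sampling deliberately
  models detector pixelation (at the reference scale of a 7 mm field on
  1002 pixels, the pulse itself spans only ~3 pixels). Read pulses are
  uniform across the (x, y) aperture; fringe coding is applied downstream
  by the codec, matching the separation of coding optics from the gate.

With τ = 0 successive frames are rigid translates and the streak centroid
moves at exactly the pump speed; the simulator reproduces the reference
arithmetic (23 µm per 125 fs = 3 detector pixels; delays of 200 fs/400 fs/
1 ps correspond to 5/2.5/1 THz frame rates; back-to-back 125 fs pulses cap
the rate at 8 THz).

## Interpolation and metrics

`reconstruct_wavefront` interpolates a decoded sequence per-pixel along
time (linear, or monotonicity-limited cubic/PCHIP), exact at sample times
and refusing extrapolation. Intensity-domain interpolation was chosen over
motion-compensated (optical-flow) interpolation, which would inject a
motion model the data does not constrain; the alternative of interpolating
an extracted wave-front surface is noted but not implemented.

`fidelity` reports NRMSE (RMS error over the truth's range) and Pearson r,
excluding a 5-pixel border that absorbs the decoder's circular-convolution
wraparound. `crosstalk_matrix` decomposes each decoded frame on the basis
of the truth frames by least squares (pseudo-inverse, so a blank truth
channel is handled); a perfect decode gives the identity and off-diagonal
entries measure channel mixing.

## Synthetic test patterns and what passing them shows

`synthetic.bandlimited_random_frames` draws white complex noise in the
Fourier domain, masks it below a cutoff, and inverse transforms: the
patterns are periodic on their grid and strictly band-limited, so they
isolate codec behavior from content leakage. They emulate the smooth,
low-frequency structure of real beam-profile images but not their border
discontinuities, shot noise, or out-of-band detail; round-trip figures on
them are therefore the codec's intrinsic (sensor-limited) performance, an
upper bound on what real fringe-projected data can achieve. Noise and
incommensurate-carrier robustness are exercised separately.

## Problem sizes

Quantitative round-trips run on 160×160 frames with N = 4 carriers
(r = 0.03, r₀ = 0.06 cycles/pixel); carrier-detection stress uses 16
carriers on the full 1002×1004 detector grid; simulator checks use a
500–1002 pixel x-axis with a thin (0.2 mm, 40-voxel) cell. These sizes were
chosen so every property is measured at the scale it is quoted while the
whole suite remains interactive.

## Known limitations

- Decoding takes the magnitude, so coherent negative residues (strong
  channel overlap) rectify rather than cancel.
- The planner does not optimize carrier placement against specific image
  spectra (content-adaptive packing is out of scope), and its ring
  construction can undershoot the true packing capacity.
- The simulator has no polarization (Jones-calculus) propagation, no
  aperture diffraction, and represents relaxation-induced blur only as the
  trailing-skirt property.
- Per-frame gain when read-pulse energies differ is exposed as a decode
  option (`gains`) rather than estimated from the data.
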