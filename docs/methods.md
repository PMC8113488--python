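# Methods

## Rendering model

A localization table is a list of positions [xₙ, yₙ] in nm (plus optional
per-localization uncertainty and frame index). All coordinates are
continuous, with the origin at the field-of-view corner, x rightward,
y downward, and every spatial interval half-open on the far edge; image
row = y, column = x. Rendering onto a grid of pixel size p:

* **Histogram**: localization n adds 1 to pixel (⌊xₙ/p⌋, ⌊yₙ/p⌋). The
  flooring discards the sub-pixel position; the round-off error matters
  whenever p is comparable to the localization precision.
* **Bilinear histogram**: the unit mass is split over the four nearest
  pixels with the tent weights w = (1−fy, fy)ᵀ ⊗ (1−fx, fx), where
  fx = xₙ/p − ⌊xₙ/p⌋ (and likewise fy). This is linear interpolation of
  the count density and equals the limit of an average shifted histogram
  as the shift spacing goes to zero (verified against a 1000-shift oracle
  in the tests). Weights addressed outside the grid are dropped and
  accumulated in `spilled_mass` rather than clamped, so
  `values.sum() + spilled_mass == N` holds exactly and edge statistics are
  undistorted.
* **Gaussian** (comparison only): a unit-integral isotropic Gaussian per
  localization, σ fixed or per-localization, sampled at pixel centers,
  truncated at 4σ and renormalized over the truncated support. Gaussian
  rendering injects an assumed correlation length and can bias
  decorrelation-based resolution estimates; it is provided to make that
  comparison possible, not as a default.

## Decorrelation resolution estimation

The estimator assumes the image is a band-limited correlated signal plus
uncorrelated noise. Let F(k) be the DFT of the mean-subtracted image and
Fn(k) = F(k)/|F(k)| (0 where F vanishes) its phase-only normalization,
which equalizes the per-frequency contributions of signal and noise. For an
ideal low-pass cutoff r (radial frequency normalized so Nyquist = 1):

d(r) = Σ_{|k|≤r} Re[F·conj(Fn)] / √( Σ_{|k|≤1} |F|² · Σ_{|k|≤r} |Fn|² )

with the DC bin and all bins beyond Nyquist excluded from every sum, and
d = 0 wherever a denominator factor vanishes. Since Re[F·conj(Fn)] = |F|,
d(r) accumulates spectral amplitude against a √(bin count) penalty: it
rises while the rings at r still carry signal and falls once they hold
mostly noise, so a maximum of d marks the frequency of best noise rejection
with full signal retention. The curve is computed without pre-filtering
and after inverted-Gaussian high-pass filters H(k) = 1 − exp(−|k|²/2σ²)
(σ in normalized frequency units) that progressively suppress
low-frequency dominance and push the detectable cutoff outward; the final
cutoff r_max is the largest accepted peak position over the bank, and

resolution = 2 · pixel_size / r_max.

The FFT evaluation path is exact (not an approximation): a brute-force
double-loop oracle agrees to ~1e-15 on every tested image.

### Peak acceptance rules

The d(r) curves end in one of three ways, and telling them apart is what
makes the estimator parameter-free in practice:

1. **Interior maximum** — the curve later drops more than
   `peak_drop_delta` (default 1e-3, numerical-ripple guard) below the
   maximum: a measured in-band cutoff. Ties in the argmax break toward the
   largest radius.
2. **Plateaued boundary** — the curve levels off and holds its maximum at
   Nyquist (gain over the trailing `boundary_window` = 10% of samples at
   most `boundary_plateau_tol` = 5e-3): the spectrum fills the whole band,
   i.e. the rendering is sampling-limited and the cutoff is pinned at
   Nyquist (resolution = twice the pixel size).
3. **Still climbing at Nyquist** — the signature of a spectrally flat
   image. Any sparse point pattern is of this kind: after phase
   normalization a speckle spectrum yields d(r) ≈ 0.886·√(N_r/N₁), rising
   monotonically to ~0.886 at r = 1 regardless of content. Such a curve
   carries no cutoff information and contributes no peak. Without this
   rejection every sparse rendering would masquerade as "resolution = twice
   the pixel size" at arbitrarily small pixels.

Interior peaks take precedence: plateaued boundary peaks define r_max only
when no curve in the whole bank shows an interior maximum (the result is
then flagged `sampling_limited`). A result with no accepted peak anywhere
is `no_estimate`; `min_amplitude` (default 1e-3) additionally rejects
vanishing peaks from near-empty spectra. These rules were fixed by
simulation: they reproduce simultaneously the twice-the-pixel-size law on
dense data at coarse pixels, clean failure on sparse data, and the
U-shaped resolution-versus-pixel-size curve.

### Procedure

`estimate_resolution` crops the image to the largest centered odd square
(symmetric Fourier grid with an exact DC bin), apodizes it (separable
raised-cosine blend toward the image mean over `apod_border` = 20 edge
pixels, suppressing FFT wrap-around artifacts), computes d on `n_radii`
= 50 cutoffs linear on (0, 1], unfiltered and for `n_filters` = 10
high-pass σ values geometrically spaced from `sigma_max` = 0.5 down to
`sigma_min` = 2/side (about one frequency bin). A refinement pass runs a
second geometric bank between the two σ bracketing the winner (below the
weakest filter if the unfiltered curve won), and re-locates every interior
peak on a locally ~10× finer radius grid — without this polish the
1/n_radii quantization (±2–3% in resolution) dominates the point-to-point
scatter of sweep curves. All curves share one FFT: the filters act as
radial gains on the sorted spectral amplitudes, so a full bank costs one
transform plus cheap cumulative sums.

## The parameter-free workflow

* **Sample area**: bilinear rendering of the full table at 5 nm pixels,
  binarized at 0.5; area = supra-threshold pixel count × pixel area. Both
  values are exposed but fixed by convention — densities are only
  comparable at identical settings. Localization density = N / area.
* **Pixel-size sweep**: render and estimate at each pixel size (default
  grid 2–40 nm) and keep the smallest resolution. Sampling-limited entries
  (cutoff pinned at Nyquist) join the minimum only when no pixel size
  produced an in-band cutoff: "resolution = 2p" asserts only that the
  cutoff lies beyond Nyquist, and letting it undercut measured cutoffs
  would report physically unsupported values at the sparse/sampled
  crossover.
* **Density sweep**: the area is computed once from the full table;
  localization counts run geometrically from max(1000, N/100) to N
  (subsampled by acquisition order when frames exist, which is random
  thinning since frames are unordered; otherwise seeded random).
* **Plateau detection**: the plateau value is the resolution at the
  highest density; the convergence density is the smallest density from
  which every later point has an estimate within `rel_tol` = 10% of it.
  This reads the plateau off the curve directly instead of fitting an
  asymptote, matching how density-sufficiency is judged in practice.

## Synthetic data

The generator emulates a filtered, drift-corrected localization table:
parametric 1D structures (worm-like-chain filaments bouncing off the FOV
walls, rings, line pairs, gratings) decorated by a Poisson process of
emitters uniform in arc length (`emitter_linear_density`, default 0.1/nm —
one binding site per 10 nm of structure), each blinking
Poisson(`mean_locs_per_emitter`, default 20) times, each blink displaced by
isotropic Gaussian error σ_loc (default 6 nm, a state-of-the-art
experimental precision). Reported uncertainties are σ_loc ± a uniform
jitter; frame indices are a random permutation; an optional uniform
background rate defaults to 0. The compound (emitter-then-blinks)
clustering is deliberate: repeat localizations of one emitter add counts
but no structural information, which is what makes the density threshold
behavior realistic.

Not modeled: camera/PSF physics, drift, photophysics kinetics, 3D,
heterogeneous per-blink precision, labeling inhomogeneity. Consequently
passing tests demonstrate the pipeline's behavior under ideal localization
statistics; on real data the plateau sits at worse resolution values and
additional failure modes (drift residues, uncertainty tails) apply.

## Reference study conditions

The end-to-end tests and `scripts/acceptance.py` use a 3 × 3 µm field
holding 14 worm-like filaments of 9 µm contour length (≈126 µm of
structure, ≈30% area coverage — a dense cytoskeleton-like field),
emitter density 0.2/nm, 20 blinks per emitter, σ_loc = 6 nm (5 nm for the
sampling-limited check, keeping 20–40 nm pixels well above the precision),
density sweeps with 12 points, medians over 3 seeds. Under these
conditions the pipeline yields a best resolution of ≈18 nm at 5 nm pixels
(≈3 × σ_loc), a sampling-limited ratio of ≈1.0–1.1, first estimates at
≈4 × 10³ loc/µm² and plateau convergence at ≈1.5–2.5 × 10⁴ loc/µm².

## Numerical choices and limitations

* Half-open pixel/FOV membership everywhere; FOV filtering before
  rendering guarantees valid indices with no clamping.
* d(r) is evaluated on sorted spectral radii with cumulative sums;
  radii whose mask contains no bin give d = 0 by convention.
* The convergence density fluctuates substantially between simulated
  datasets (observed ≈1.5–5 × 10⁴ across seeds): the 10% band around the
  plateau interacts with the slow (roughly logarithmic in N) late-stage
  improvement of the estimate, so single-dataset convergence readings
  should be quoted with the density grid they were measured on.
* Estimates on tiny crops are limited by the apodization border: the
  analyzed square must be at least 2·apod_border + 3 pixels on a side.
* Sectorial/anisotropic resolution, local resolution maps, and Fourier
  ring correlation are out of scope.
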