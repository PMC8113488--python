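"""Decorrelation-analysis resolution estimation for a single 2D image.

The estimator computes cross-correlation coefficients d between an image and
a low-pass-filtered copy of its Fourier-amplitude-normalized version. With
F(k) the DFT of the mean-subtracted (optionally high-pass-filtered) image
and Fn(k) = F(k)/|F(k)| its phase-only normalization, the coefficient at
ideal low-pass cutoff r is

    d(r) = Σ_{|k| ≤ r} Re[F(k) · conj(Fn(k))]
           / sqrt( Σ_{|k| ≤ 1} |F(k)|² · Σ_{|k| ≤ r} |Fn(k)|² ),

with |k| the radial frequency normalized so the Nyquist ring is |k| = 1;
bins beyond Nyquist and the DC bin are excluded from every sum. Because
Re[F·conj(Fn)] = |F|, the numerator accumulates spectral amplitude while the
denominator grows with the number of unmasked bins: d(r) rises as long as
the ring at r carries appreciable signal and falls once it holds mostly
noise, so the position of the last local maximum over a bank of inverted-
Gaussian high-pass pre-filters marks the effective cutoff frequency r_max,
and the resolution is 2 · pixel_size / r_max.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .render import RenderedImage

__all__ = [
    "DecorrConfig",
    "DecorrCurve",
    "DecorrResult",
    "apodize",
    "high_pass",
    "decorr_curve",
    "find_peak",
    "estimate_resolution",
]


@dataclass(frozen=True)
class DecorrConfig:
    """Tuning knobs of the decorrelation estimator.

    n_radii:
        Number of low-pass cutoffs, linearly spaced on (0, 1].
    n_filters:
        High-pass pre-filters per bank (geometric σ series); 0 disables
        pre-filtering.
    sigma_min, sigma_max:
        Range of the high-pass standard deviation in normalized-frequency
        units (Nyquist = 1). ``sigma_min=None`` defaults to 2/side of the
        analyzed square, i.e. about one frequency bin.
    peak_drop_delta:
        A local maximum counts as a peak once the curve drops this far below
        it at a larger radius; guards against numerical ripple.
    min_amplitude:
        Peaks with amplitude below this are rejected; if every curve's peak
        is rejected the estimator reports no estimate.
    boundary_plateau_tol, boundary_window:
        A curve with no interior maximum nominates its endpoint (the
        sampling-limited case, cutoff at Nyquist) only when it has leveled
        off: its total gain over the trailing ``boundary_window`` fraction
        of the samples must not exceed ``boundary_plateau_tol``. A
        curve still climbing at Nyquist is the signature of a spectrally
        flat (sparse/noise-dominated) image and yields no peak.
    apod_border:
        Width (pixels) of the raised-cosine band blending the image edges to
        the mean before the FFT.
    refine:
        Run a second σ bank bracketing the best peak of the first pass.
    """

    n_radii: int = 50
    n_filters: int = 10
    sigma_min: float | None = None
    sigma_max: float = 0.5
    peak_drop_delta: float = 1e-3
    min_amplitude: float = 1e-3
    apod_border: int = 20
    refine: bool = True
    boundary_plateau_tol: float = 5e-3
    boundary_window: float = 0.1

    def __post_init__(self) -> None:
        if self.n_radii < 10:
            raise ValueError("n_radii must be at least 10")
        if self.n_filters < 0:
            raise ValueError("n_filters must be non-negative")
        if self.peak_drop_delta <= 0:
            raise ValueError("peak_drop_delta must be positive")
        if self.min_amplitude < 0:
            raise ValueError("min_amplitude must be non-negative")
        if self.sigma_max <= 0:
            raise ValueError("sigma_max must be positive")
        if self.sigma_min is not None and not (0 < self.sigma_min < self.sigma_max):
            raise ValueError("need 0 < sigma_min < sigma_max")
        if self.boundary_plateau_tol < 0:
            raise ValueError("boundary_plateau_tol must be non-negative")
        if not (0 < self.boundary_window <= 1):
            raise ValueError("boundary_window must be in (0, 1]")


@dataclass(frozen=True)
class DecorrCurve:
    """One d(r) trace: the high-pass σ used (None = unfiltered), radii, d."""

    sigma: float | None
    radii: np.ndarray
    d: np.ndarray


@dataclass(frozen=True)
class DecorrResult:
    """Outcome of :func:`estimate_resolution`.

    ``status`` is ``"estimate"`` (resolution_nm and r_max set, with
    resolution_nm = 2 · pixel_size / r_max) or ``"no_estimate"`` when no
    curve produced an acceptable peak.
    """

    status: str
    resolution_nm: float | None
    r_max: float | None
    pixel_size: float
    sampling_limited: bool = False
    curves: list[DecorrCurve] = field(default_factory=list)
    peaks: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "resolution_nm": self.resolution_nm,
            "r_max": self.r_max,
            "sampling_limited": self.sampling_limited,
            "pixel_size_nm": self.pixel_size,
            "peaks": [[float(r), float(a)] for r, a in self.peaks],
            "curves": [
                {
                    "sigma": c.sigma,
                    "radii": [float(v) for v in c.radii],
                    "d": [float(v) for v in c.d],
                }
                for c in self.curves
            ],
        }


def apodize(image: np.ndarray, border: int) -> np.ndarray:
    """Blend the image toward its global mean over a raised-cosine border.

    The window is a separable product of 1D half-cosine tapers: 1 in the
    interior, 0 at the outermost pixel row/column. Returns
    mean + window · (image − mean).
    """
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    if border < 0 or border > min(ny, nx) / 2:
        raise ValueError("apodization border must be in [0, min(h, w)/2]")
    if border == 0:
        return image.copy()

    def taper(n: int) -> np.ndarray:
        dist = np.minimum(np.arange(n), n - 1 - np.arange(n))
        w = np.ones(n)
        band = dist < border
        w[band] = 0.5 * (1.0 - np.cos(np.pi * dist[band] / border))
        return w

    window = np.outer(taper(ny), taper(nx))
    mean = image.mean()
    return mean + window * (image - mean)


def _radial_freq(ny: int, nx: int) -> np.ndarray:
    """|k| on the FFT grid, normalized so the Nyquist ring is 1."""
    ky = 2.0 * np.fft.fftfreq(ny)[:, None]
    kx = 2.0 * np.fft.fftfreq(nx)[None, :]
    return np.sqrt(ky * ky + kx * kx)


def high_pass(image: np.ndarray, sigma: float) -> np.ndarray:
    """Inverted-Gaussian high-pass filter, σ in normalized frequency units.

    Multiplies the spectrum by H(k) = 1 − exp(−|k|² / (2σ²)) and
    inverse-transforms; the output is real for real input.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    image = np.asarray(image, dtype=float)
    kr = _radial_freq(*image.shape)
    H = 1.0 - np.exp(-(kr * kr) / (2.0 * sigma * sigma))
    return np.real(np.fft.ifft2(np.fft.fft2(image) * H))


def _sorted_spectrum(image: np.ndarray):
    """FFT the mean-subtracted image and sort in-band bins by radius.

    Returns (k_sorted, absF_sorted) over bins with 0 < |k| ≤ 1 (DC and
    beyond-Nyquist bins excluded).
    """
    image = np.asarray(image, dtype=float)
    F = np.fft.fft2(image - image.mean())
    kr = _radial_freq(*image.shape)
    keep = (kr <= 1.0) & (kr > 0.0)
    k = kr[keep]
    a = np.abs(F[keep])
    order = np.argsort(k, kind="stable")
    return k[order], a[order]


def _curve_from_sorted(
    k_sorted: np.ndarray,
    amp_sorted: np.ndarray,
    radii: np.ndarray,
    nonzero_sorted: np.ndarray,
) -> np.ndarray:
    """Evaluate d(r) from radius-sorted spectral amplitudes.

    ``amp_sorted`` is |F| after any high-pass gain; ``nonzero_sorted`` flags
    bins where the normalized spectrum has unit modulus (|F| > 0 and the
    filter gain > 0) — elsewhere Fn is defined as 0.
    """
    cum_amp = np.cumsum(amp_sorted)
    cum_cnt = np.cumsum(nonzero_sorted.astype(float))
    energy = float(np.sum(amp_sorted * amp_sorted))
    idx = np.searchsorted(k_sorted, radii, side="right")
    d = np.zeros(len(radii))
    valid = idx > 0
    if energy > 0:
        num = np.where(valid, cum_amp[np.maximum(idx - 1, 0)], 0.0)
        cnt = np.where(valid, cum_cnt[np.maximum(idx - 1, 0)], 0.0)
        ok = cnt > 0
        d[ok] = num[ok] / np.sqrt(energy * cnt[ok])
    return d


def decorr_curve(
    image: np.ndarray,
    radii: np.ndarray,
    high_pass_sigma: float | None = None,
) -> np.ndarray:
    """d(r) of a single image at the given normalized cutoffs.

    The image is mean-subtracted; if ``high_pass_sigma`` is given the
    inverted-Gaussian high-pass is applied first. Returns one d value per
    radius, each in [0, 1] (0 where the mask is empty or the spectrum
    vanishes).
    """
    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 1 or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    image = np.asarray(image, dtype=float)
    if high_pass_sigma is not None:
        image = high_pass(image, high_pass_sigma)
    k_sorted, amp_sorted = _sorted_spectrum(image)
    return _curve_from_sorted(k_sorted, amp_sorted, radii, amp_sorted > 0)


@dataclass(frozen=True)
class Peak:
    """An accepted d(r) maximum; ``boundary`` marks the sampling-limited case."""

    r: float
    amplitude: float
    boundary: bool = False

    def __iter__(self):
        return iter((self.r, self.amplitude))


def find_peak(
    d: np.ndarray,
    radii: np.ndarray,
    peak_drop_delta: float = 1e-3,
    min_amplitude: float = 1e-3,
    boundary_plateau_tol: float = 5e-3,
    boundary_window: float = 0.1,
) -> Peak | None:
    """Locate the significant maximum of one d(r) trace.

    The global maximum (ties broken toward the largest radius) is an
    interior peak if the curve later drops more than ``peak_drop_delta``
    below it. Without such a drop the maximum sits against the last radius;
    the endpoint then counts as a (boundary) peak only when the curve has
    leveled off — its gain over the trailing ``boundary_window`` fraction of
    the samples is at most ``boundary_plateau_tol``. A trace still climbing at
    the last radius carries no cutoff information (the spectrum is flat up
    to Nyquist) and yields None, as does any peak with amplitude below
    ``min_amplitude``.
    """
    d = np.asarray(d, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if d.shape != radii.shape:
        raise ValueError("d and radii must have the same length")
    if d.size < 3:
        raise ValueError("need at least 3 samples to find a peak")
    m = d.size - 1 - int(np.argmax(d[::-1]))  # ties -> largest radius
    if m < d.size - 1 and np.any(d[m + 1 :] < d[m] - peak_drop_delta):
        r_i, a_i, boundary = radii[m], d[m], False
    else:
        n_tail = max(2, int(round(boundary_window * d.size)))
        if d[-1] - d[-n_tail:].min() > boundary_plateau_tol:
            return None  # still rising at Nyquist: no cutoff in band
        r_i, a_i, boundary = radii[-1], d[-1], True
    if a_i < min_amplitude:
        return None
    return Peak(float(r_i), float(a_i), boundary)


def _odd_center_crop(values: np.ndarray) -> np.ndarray:
    """Largest centered square with odd side length."""
    n = min(values.shape)
    if n % 2 == 0:
        n -= 1
    y0 = (values.shape[0] - n) // 2
    x0 = (values.shape[1] - n) // 2
    return values[y0 : y0 + n, x0 : x0 + n]


def _sigma_bank(sigma_max: float, sigma_min: float, n: int) -> np.ndarray:
    """Geometric σ series from sigma_max down to sigma_min."""
    if n == 1:
        return np.array([sigma_max])
    return np.geomspace(sigma_max, sigma_min, n)


def estimate_resolution(
    image: RenderedImage, config: DecorrConfig = DecorrConfig()
) -> DecorrResult:
    """Full decorrelation resolution estimate of one rendered image.

    The image is cropped to the largest centered odd square, apodized, and
    analyzed with the unfiltered spectrum plus a geometric bank of
    ``n_filters`` high-pass pre-filters (and, when ``refine``, a second bank
    bracketing the best peak). The cutoff r_max is the largest accepted
    interior peak position; plateaued boundary peaks (the sampling-limited
    case, cutoff pinned at Nyquist) are consulted only when no curve in the
    bank shows an interior maximum. resolution_nm = 2 · pixel_size / r_max.
    """
    values = _odd_center_crop(np.asarray(image.values, dtype=float))
    n = values.shape[0]
    if n < 2 * config.apod_border + 3:
        raise ValueError(
            f"image side {n} too small for apodization border "
            f"{config.apod_border}; enlarge the field of view or reduce "
            "apod_border"
        )
    values = apodize(values, config.apod_border)

    radii = np.linspace(1.0 / config.n_radii, 1.0, config.n_radii)
    sigma_min = config.sigma_min if config.sigma_min is not None else 2.0 / n
    sigma_min = min(sigma_min, config.sigma_max / 2)

    k_sorted, abs_sorted = _sorted_spectrum(values)
    nonzero = abs_sorted > 0

    def one_curve(sigma: float | None) -> DecorrCurve:
        if sigma is None:
            amp = abs_sorted
        else:
            gain = 1.0 - np.exp(-(k_sorted * k_sorted) / (2.0 * sigma * sigma))
            amp = abs_sorted * gain
        return DecorrCurve(sigma=sigma, radii=radii,
                           d=_curve_from_sorted(k_sorted, amp, radii, nonzero))

    curves: list[DecorrCurve] = []
    accepted: list[tuple[float | None, Peak]] = []  # (sigma, peak)

    def run_bank(sigmas) -> None:
        for s in sigmas:
            c = one_curve(s)
            curves.append(c)
            pk = find_peak(
                c.d,
                radii,
                config.peak_drop_delta,
                config.min_amplitude,
                config.boundary_plateau_tol,
                config.boundary_window,
            )
            if pk is not None:
                accepted.append((s, pk))

    run_bank([None])
    bank = (
        _sigma_bank(config.sigma_max, sigma_min, config.n_filters)
        if config.n_filters > 0
        else []
    )
    run_bank(bank)

    interior = [(s, p) for s, p in accepted if not p.boundary]
    if config.refine and interior and len(bank) > 0:
        best_sigma = max(interior, key=lambda t: t[1].r)[0]
        lo, hi = _refine_bracket(best_sigma, bank, sigma_min)
        run_bank(_sigma_bank(hi, lo, config.n_filters))
        interior = [(s, p) for s, p in accepted if not p.boundary]

    if config.refine and interior:
        # de-quantize: re-locate each interior maximum on a locally refined
        # radius grid (one coarse step wide, ~10x finer)
        step = radii[1] - radii[0]

        def polish(sigma: float | None, peak: Peak) -> Peak:
            lo_r = max(step * 0.5, peak.r - step)
            hi_r = min(1.0, peak.r + step)
            fine = np.linspace(lo_r, hi_r, 21)
            if sigma is None:
                amp = abs_sorted
            else:
                gain = 1.0 - np.exp(-(k_sorted * k_sorted) / (2.0 * sigma * sigma))
                amp = abs_sorted * gain
            df = _curve_from_sorted(k_sorted, amp, fine, nonzero)
            j = int(np.argmax(df))  # first index of the maximal step
            return Peak(float(fine[j]), float(df[j]), False)

        interior = [(s, polish(s, p)) for s, p in interior]

    # interior maxima carry the actual cutoff; the Nyquist-pinned boundary
    # case stands only when no filter reveals any interior structure
    pool = interior if interior else accepted
    peaks = [(p.r, p.amplitude) for _s, p in pool]
    if not peaks:
        return DecorrResult(
            status="no_estimate",
            resolution_nm=None,
            r_max=None,
            pixel_size=image.pixel_size,
            curves=curves,
            peaks=[],
        )
    r_max = max(r for r, _a in peaks)
    return DecorrResult(
        status="estimate",
        resolution_nm=2.0 * image.pixel_size / r_max,
        r_max=r_max,
        pixel_size=image.pixel_size,
        sampling_limited=not interior,
        curves=curves,
        peaks=peaks,
    )


def _refine_bracket(best_sigma, bank, sigma_min) -> tuple[float, float]:
    """σ interval around the first-pass winner for the refinement bank."""
    bank = np.asarray(bank, dtype=float)  # descending
    step = bank[0] / bank[1] if len(bank) > 1 else 2.0
    if best_sigma is None:
        # the unfiltered curve won: refine just below the weakest filter
        return sigma_min / step, sigma_min
    j = int(np.argmin(np.abs(bank - best_sigma)))
    hi = bank[j - 1] if j > 0 else bank[0] * step
    lo = bank[j + 1] if j < len(bank) - 1 else bank[-1] / step
    return lo, hi
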