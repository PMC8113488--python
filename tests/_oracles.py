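"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized/cumulative-sum code paths:
the decorrelation oracle evaluates the defining sums by explicit loops over
Fourier pixels, and the average-shifted-histogram oracle builds the bilinear
limit by averaging many shifted histograms.
"""

from __future__ import annotations

import numpy as np


def decorr_oracle(image: np.ndarray, radii, sigma: float | None = None) -> np.ndarray:
    """d(r) by direct summation over Fourier pixels.

    Mean subtraction, optional inverted-Gaussian high-pass, phase
    normalization, DC and beyond-Nyquist exclusion — all spelled out
    pixel by pixel.
    """
    img = np.asarray(image, dtype=float)
    ny, nx = img.shape
    ky = 2.0 * np.fft.fftfreq(ny)
    kx = 2.0 * np.fft.fftfreq(nx)
    if sigma is not None:
        H = np.empty((ny, nx))
        for i in range(ny):
            for j in range(nx):
                kr2 = ky[i] ** 2 + kx[j] ** 2
                H[i, j] = 1.0 - np.exp(-kr2 / (2.0 * sigma * sigma))
        img = np.real(np.fft.ifft2(np.fft.fft2(img) * H))
    F = np.fft.fft2(img - img.mean())
    out = []
    for r in radii:
        num = 0.0
        energy = 0.0
        count = 0.0
        for i in range(ny):
            for j in range(nx):
                kr = np.hypot(ky[i], kx[j])
                if kr > 1.0 or kr == 0.0:
                    continue
                aF = abs(F[i, j])
                energy += aF * aF
                if kr <= r and aF > 0.0:
                    Fn = F[i, j] / aF
                    num += (F[i, j] * np.conj(Fn)).real
                    count += 1.0
        den = np.sqrt(energy * count)
        out.append(num / den if den > 0 else 0.0)
    return np.asarray(out)


def shifted_histogram_average(x_nm: float, pixel_size: float, n_pixels: int,
                              n_shifts: int = 1000) -> np.ndarray:
    """1D average shifted histogram evaluated at the grid nodes.

    Averages ``n_shifts`` histograms whose bin edges are offset by uniform
    sub-pixel shifts; in the dense-shift limit this converges to the linear
    (tent) interpolation a bilinear histogram applies along one axis.
    """
    out = np.zeros(n_pixels)
    shifts = (np.arange(n_shifts) + 0.5) / n_shifts
    for s in shifts:
        bin_of_x = np.floor(x_nm / pixel_size - s)
        for j in range(n_pixels):
            if np.floor(j - s) == bin_of_x:
                out[j] += 1.0
    return out / n_shifts
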