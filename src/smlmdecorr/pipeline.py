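"""The parameter-free SMLM resolution workflow.

A localization table has two free rendering choices — pixel size and how
many localizations to include — and the resolution estimate depends on
both. The workflow removes them:

1. estimate the area covered by the structure (binarized 5-nm bilinear
   rendering, threshold 0.5) so localization counts can be normalized to a
   density in loc/µm² comparable across datasets;
2. sweep the rendering pixel size and keep the smallest resolution
   (fine pixels fail from sparsity, coarse pixels are Nyquist-bound at
   twice the pixel size; the minimum sits at the balance point);
3. sweep the number of included localizations to map resolution versus
   density; the presence of a plateau certifies sufficient labeling
   density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decorr import DecorrConfig, DecorrResult, estimate_resolution
from .loc_io import FieldOfView, LocalizationTable, subsample
from .render import bilinear_render

__all__ = [
    "DEFAULT_PIXEL_SIZES",
    "SweepResult",
    "DensityCurve",
    "estimate_sample_area",
    "localization_density",
    "pixel_size_sweep",
    "density_sweep",
    "detect_plateau",
]

# Spans the sparsity-limited (few-nm) to sampling-limited (tens of nm) regimes.
DEFAULT_PIXEL_SIZES: tuple[float, ...] = (2, 3, 4, 5, 7.5, 10, 15, 20, 30, 40)


@dataclass(frozen=True)
class SweepResult:
    """Resolution at each tested pixel size plus the min-resolution pick."""

    entries: tuple[tuple[float, DecorrResult], ...]
    best_resolution_nm: float | None
    best_pixel_size_nm: float | None

    def to_dict(self) -> dict:
        return {
            "best_resolution_nm": self.best_resolution_nm,
            "best_pixel_size_nm": self.best_pixel_size_nm,
            "entries": [
                {"pixel_size_nm": p, **r.to_dict()} for p, r in self.entries
            ],
        }


@dataclass(frozen=True)
class DensityCurve:
    """Best resolution as a function of localization count and density."""

    points: tuple[tuple[int, float, float | None], ...]  # (n, loc/µm², nm)
    area_um2: float

    def to_dict(self) -> dict:
        return {
            "area_um2": self.area_um2,
            "points": [
                {"n_localizations": int(n), "density_per_um2": rho,
                 "best_resolution_nm": res}
                for n, rho, res in self.points
            ],
        }


def estimate_sample_area(
    table: LocalizationTable,
    fov: FieldOfView,
    pixel_size: float = 5.0,
    threshold: float = 0.5,
) -> float:
    """Area (µm²) covered by the structure.

    The full table is rendered with the bilinear histogram at ``pixel_size``
    (5 nm default) and binarized at ``threshold`` (0.5 default); the area is
    the count of supra-threshold pixels times the pixel area. Density
    comparisons across datasets are only meaningful at identical pixel size
    and threshold.
    """
    if len(table) == 0:
        return 0.0
    img = bilinear_render(table, pixel_size, fov)
    n_pix = int(np.count_nonzero(img.values > threshold))
    return n_pix * pixel_size * pixel_size / 1e6


def localization_density(n: int, area_um2: float) -> float:
    """Localizations per µm² of structure."""
    if area_um2 <= 0:
        raise ValueError("sample area is zero — no structure detected")
    return n / area_um2


def pixel_size_sweep(
    table: LocalizationTable,
    fov: FieldOfView,
    pixel_sizes=DEFAULT_PIXEL_SIZES,
    config: DecorrConfig = DecorrConfig(),
) -> SweepResult:
    """Estimate resolution at each pixel size and keep the smallest.

    Each pixel size gets its own bilinear rendering and decorrelation
    estimate; pixel sizes whose rendering is too small for the configured
    apodization border, or that produce no estimate, simply contribute no
    candidate.
    """
    pixel_sizes = [float(p) for p in pixel_sizes]
    if not pixel_sizes or any(p <= 0 for p in pixel_sizes):
        raise ValueError("pixel_sizes must be non-empty and positive")
    entries = []
    for p in pixel_sizes:
        img = bilinear_render(table, p, fov)
        res = estimate_resolution(img, config)
        entries.append((p, res))
    # a sampling-limited verdict only asserts "cutoff beyond Nyquist at this
    # pixel size"; when any rendering measured an actual in-band cutoff,
    # those estimates take precedence in the minimum
    measured = [
        (r.resolution_nm, p)
        for p, r in entries
        if r.status == "estimate" and not r.sampling_limited
    ]
    fallback = [
        (r.resolution_nm, p) for p, r in entries if r.status == "estimate"
    ]
    pool = measured if measured else fallback
    if pool:
        best_res, best_p = min(pool)
    else:
        best_res = best_p = None
    return SweepResult(
        entries=tuple(entries),
        best_resolution_nm=best_res,
        best_pixel_size_nm=best_p,
    )


def density_sweep(
    table: LocalizationTable,
    fov: FieldOfView,
    n_points: int = 8,
    pixel_sizes=DEFAULT_PIXEL_SIZES,
    config: DecorrConfig = DecorrConfig(),
    mode: str | None = None,
    seed: int = 0,
    area_pixel_size: float = 5.0,
    area_threshold: float = 0.5,
) -> DensityCurve:
    """Best resolution versus localization density.

    The sample area is computed once from the full table. Subsample sizes
    are geometrically spaced from max(1000, N/100) up to N; each subsample
    is rendered and swept over ``pixel_sizes``, recording the minimum
    resolution (or None). ``mode`` defaults to first-by-frame when the
    table has frames (acquisition-order truncation) and random otherwise.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    N = len(table)
    if N == 0:
        raise ValueError("cannot sweep an empty table")
    if mode is None:
        mode = "first_by_frame" if table.frame is not None else "random"
    area = estimate_sample_area(table, fov, area_pixel_size, area_threshold)
    if area <= 0:
        raise ValueError("sample area is zero — no structure detected")

    n_min = min(max(1000, N // 100), N)
    counts = np.unique(
        np.round(np.geomspace(n_min, N, n_points)).astype(int)
    )
    counts[-1] = N  # geomspace rounding must not lose the full-table point

    points = []
    for n in counts:
        sub = subsample(table, int(n), mode=mode, seed=seed)
        sweep = pixel_size_sweep(sub, fov, pixel_sizes, config)
        points.append((int(n), localization_density(int(n), area),
                       sweep.best_resolution_nm))
    return DensityCurve(points=tuple(points), area_um2=area)


def detect_plateau(
    curve: DensityCurve, rel_tol: float = 0.1, k: int = 3
) -> tuple[bool, float | None]:
    """Decide whether the density curve has reached a resolution plateau.

    The plateau value is the resolution at the highest density with an
    estimate. The convergence density is the smallest density from which
    every later point has an estimate within ``rel_tol`` (relative) of the
    plateau value. Convergence claimed only when more than the final point
    qualifies. Requires at least ``k`` points with estimates.
    """
    pts = list(curve.points)
    est = [(rho, res) for _n, rho, res in pts if res is not None]
    if len(est) < k:
        raise ValueError(
            f"need at least {k} points with estimates, got {len(est)}"
        )
    plateau = est[-1][1]
    last_idx = len(pts) - 1
    conv_idx = None
    for i in range(len(pts)):
        tail = pts[i:]
        ok = all(
            res is not None and abs(res - plateau) <= rel_tol * plateau
            for _n, _rho, res in tail
        )
        if ok:
            conv_idx = i
            break
    if conv_idx is None:
        return False, None
    converged = conv_idx < last_idx
    return converged, pts[conv_idx][1]
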