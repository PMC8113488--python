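"""Synthetic SMLM data with known ground truth.

Real localization tables are produced by stochastically blinking emitters
decorating an underlying (mostly one-dimensional) structure — filaments,
rings, line pairs — each blink localized with a few-nm Gaussian error. The
generator reproduces exactly that statistical structure and nothing more:

* a :class:`Phantom` is a set of parametric 1D curves (polylines, circles)
  with an exact total arc length;
* emitters are placed by a Poisson process uniform in arc length with linear
  density ``emitter_linear_density`` (per nm of structure);
* each emitter produces a Poisson(``mean_locs_per_emitter``) number of
  localizations — the compound (clustered) statistics matter, because
  repeat localizations of one emitter carry no new structural information;
* every localization is the emitter position plus isotropic Gaussian error
  of standard deviation ``sigma_loc`` (the localization precision).

No camera, PSF, drift or photophysics model is included; the generator
emulates a *filtered, drift-corrected* localization table, which is what
the downstream analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .loc_io import FieldOfView, LocalizationTable

__all__ = [
    "Curve",
    "Polyline",
    "Circle",
    "Phantom",
    "SimConfig",
    "make_phantom",
    "simulate_localizations",
]


class Curve:
    """A parametric 1D curve supporting arc-length sampling."""

    @property
    def length(self) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def sample(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Points at arc lengths ``s`` ∈ [0, length]."""
        raise NotImplementedError

    def distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Euclidean distance from each point to the curve."""
        raise NotImplementedError


@dataclass(frozen=True)
class Polyline(Curve):
    points: np.ndarray  # (M, 2) vertices in nm

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", p)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 2:
            raise ValueError("polyline needs an (M, 2) array with M >= 2")

    @property
    def _seg_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def length(self) -> float:
        return float(self._seg_lengths.sum())

    def sample(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        cum = np.concatenate([[0.0], np.cumsum(self._seg_lengths)])
        s = np.clip(s, 0.0, cum[-1])
        seg = np.clip(np.searchsorted(cum, s, side="right") - 1, 0,
                      len(cum) - 2)
        seg_len = np.maximum(cum[seg + 1] - cum[seg], 1e-300)
        t = (s - cum[seg]) / seg_len
        p0 = self.points[seg]
        p1 = self.points[seg + 1]
        pts = p0 + t[:, None] * (p1 - p0)
        return pts[:, 0], pts[:, 1]

    def distance(self, x, y):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        q = np.stack([x, y], axis=1)[:, None, :]      # (N, 1, 2)
        a = self.points[None, :-1, :]                 # (1, M-1, 2)
        b = self.points[None, 1:, :]
        ab = b - a
        denom = np.maximum((ab * ab).sum(-1), 1e-300)
        t = np.clip(((q - a) * ab).sum(-1) / denom, 0.0, 1.0)
        proj = a + t[..., None] * ab
        return np.sqrt(((q - proj) ** 2).sum(-1)).min(axis=1)


@dataclass(frozen=True)
class Circle(Curve):
    center: tuple[float, float]
    radius: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("circle radius must be positive")

    @property
    def length(self) -> float:
        return float(2.0 * np.pi * self.radius)

    def sample(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        theta = self.phase + s / self.radius
        return (
            self.center[0] + self.radius * np.cos(theta),
            self.center[1] + self.radius * np.sin(theta),
        )

    def distance(self, x, y):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        r = np.hypot(x - self.center[0], y - self.center[1])
        return np.abs(r - self.radius)


@dataclass(frozen=True)
class Phantom:
    """A collection of 1D curves; total_length is the exact arc-length sum."""

    curves: tuple[Curve, ...]
    fov: FieldOfView

    @property
    def total_length(self) -> float:
        return float(sum(c.length for c in self.curves))

    def sample(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map global arc lengths (uniform over the phantom) to points."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        lengths = np.array([c.length for c in self.curves])
        cum = np.concatenate([[0.0], np.cumsum(lengths)])
        s = np.clip(s, 0.0, cum[-1])
        which = np.clip(np.searchsorted(cum, s, side="right") - 1, 0,
                        len(self.curves) - 1)
        x = np.empty_like(s)
        y = np.empty_like(s)
        for ci in np.unique(which):
            sel = which == ci
            x[sel], y[sel] = self.curves[ci].sample(s[sel] - cum[ci])
        return x, y

    def distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Distance from each query point to the nearest curve."""
        dists = np.stack([c.distance(x, y) for c in self.curves])
        return dists.min(axis=0)


@dataclass(frozen=True)
class SimConfig:
    """Stochastic parameters of the localization generator.

    emitter_linear_density:
        Emitters per nm of structure (a well-labeled filament has roughly
        one binding site every 5–20 nm, i.e. 0.05–0.2 /nm).
    mean_locs_per_emitter:
        Mean blinks (= localizations) per emitter.
    sigma_loc:
        Localization precision in nm.
    uncertainty_jitter:
        Relative spread of the reported per-localization uncertainty:
        uncertainty = sigma_loc · (1 + U(−j, +j)).
    background_density:
        Spurious localizations per µm² of FOV, uniform (default 0: the
        analysis targets filtered experimental tables).
    """

    fov: FieldOfView
    emitter_linear_density: float = 0.1
    mean_locs_per_emitter: float = 20.0
    sigma_loc: float = 6.0
    uncertainty_jitter: float = 0.2
    background_density: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("emitter_linear_density", "mean_locs_per_emitter",
                     "sigma_loc", "uncertainty_jitter", "background_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _random_filament(rng, fov: FieldOfView, length: float,
                     persistence_length: float, step: float) -> Polyline:
    """Worm-like-chain-style random walk, reflected at the FOV edges."""
    n_steps = max(int(np.ceil(length / step)), 1)
    x = rng.uniform(fov.x0 + 0.1 * fov.width, fov.x0 + 0.9 * fov.width)
    y = rng.uniform(fov.y0 + 0.1 * fov.height, fov.y0 + 0.9 * fov.height)
    theta = rng.uniform(0, 2 * np.pi)
    sd = np.sqrt(step / max(persistence_length, 1e-9))
    pts = [(x, y)]
    for _ in range(n_steps):
        theta += rng.normal(0.0, sd)
        dx = step * np.cos(theta)
        dy = step * np.sin(theta)
        # bounce off FOV walls by flipping the offending direction
        # component, so every segment keeps exactly length `step`
        if not (fov.x0 <= x + dx < fov.x0 + fov.width):
            dx = -dx
        if not (fov.y0 <= y + dy < fov.y0 + fov.height):
            dy = -dy
        theta = np.arctan2(dy, dx)
        x, y = x + dx, y + dy
        pts.append((x, y))
    return Polyline(np.array(pts))


def make_phantom(kind: str, params: dict | None, fov: FieldOfView,
                 seed: int = 0) -> Phantom:
    """Construct a deterministic test structure inside ``fov``.

    Kinds and their parameters (nm unless noted):

    * ``filaments`` — ``count`` (default 10), ``length`` (default
      4 × FOV width), ``persistence_length`` (default 4000),
      ``step`` (default 10).
    * ``rings`` — ``radius`` (default 55), ``count`` (default 20).
    * ``line_pair`` — ``separation`` (required > 0), ``length`` (default
      0.8 × FOV height): two parallel vertical lines centered in the FOV.
    * ``grating`` — ``period`` (required > 0): vertical lines across the
      full FOV at the given pitch.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    curves: list[Curve] = []
    if kind == "filaments":
        count = int(params.pop("count", 10))
        length = float(params.pop("length", 4.0 * fov.width))
        lp = float(params.pop("persistence_length", 4000.0))
        step = float(params.pop("step", 10.0))
        if count < 1:
            raise ValueError("filaments: count must be >= 1")
        if lp <= 0:
            raise ValueError("filaments: persistence_length must be positive")
        for _ in range(count):
            curves.append(_random_filament(rng, fov, length, lp, step))
    elif kind == "rings":
        radius = float(params.pop("radius", 55.0))
        count = int(params.pop("count", 20))
        if radius <= 0:
            raise ValueError("rings: radius must be positive")
        if count < 1:
            raise ValueError("rings: count must be >= 1")
        margin = radius * 1.01
        for _ in range(count):
            cx = rng.uniform(fov.x0 + margin, fov.x0 + fov.width - margin)
            cy = rng.uniform(fov.y0 + margin, fov.y0 + fov.height - margin)
            curves.append(Circle((cx, cy), radius, phase=rng.uniform(0, 2 * np.pi)))
    elif kind == "line_pair":
        sep = float(params.pop("separation", 0.0))
        if sep <= 0:
            raise ValueError("line_pair: separation must be positive")
        length = float(params.pop("length", 0.8 * fov.height))
        xc = fov.x0 + fov.width / 2
        yc = fov.y0 + fov.height / 2
        for dx in (-sep / 2, sep / 2):
            curves.append(Polyline(np.array([
                [xc + dx, yc - length / 2],
                [xc + dx, yc + length / 2],
            ])))
    elif kind == "grating":
        period = float(params.pop("period", 0.0))
        if period <= 0:
            raise ValueError("grating: period must be positive")
        xs = np.arange(fov.x0 + period / 2, fov.x0 + fov.width, period)
        for x in xs:
            curves.append(Polyline(np.array([
                [x, fov.y0],
                [x, fov.y0 + fov.height * (1 - 1e-12)],
            ])))
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    if params:
        raise ValueError(f"unknown parameters for kind {kind!r}: {sorted(params)}")
    return Phantom(curves=tuple(curves), fov=fov)


def simulate_localizations(phantom: Phantom, config: SimConfig) -> LocalizationTable:
    """Draw a localization table from the compound-Poisson blink model.

    Emitter count ~ Poisson(linear density × total length), positions
    uniform in arc length; blinks per emitter ~ Poisson(mean); each blink is
    displaced by isotropic N(0, sigma_loc²). Localizations landing outside
    the FOV are discarded; frame indices are a random permutation, so
    truncating by frame acts as unbiased random thinning.
    """
    rng = np.random.default_rng(config.seed)
    total = phantom.total_length
    n_emitters = rng.poisson(config.emitter_linear_density * total) if total > 0 else 0

    if n_emitters > 0:
        s = rng.uniform(0.0, total, size=n_emitters)
        ex, ey = phantom.sample(s)
        blinks = rng.poisson(config.mean_locs_per_emitter, size=n_emitters)
        x = np.repeat(ex, blinks)
        y = np.repeat(ey, blinks)
        n = x.size
        x = x + rng.normal(0.0, config.sigma_loc, size=n) if config.sigma_loc > 0 else x
        y = y + rng.normal(0.0, config.sigma_loc, size=n) if config.sigma_loc > 0 else y
    else:
        x = np.empty(0)
        y = np.empty(0)

    if config.background_density > 0:
        fov = config.fov
        area_um2 = fov.width * fov.height / 1e6
        n_bg = rng.poisson(config.background_density * area_um2)
        x = np.concatenate([x, rng.uniform(fov.x0, fov.x0 + fov.width, n_bg)])
        y = np.concatenate([y, rng.uniform(fov.y0, fov.y0 + fov.height, n_bg)])

    keep = config.fov.contains(x, y)
    x, y = x[keep], y[keep]
    n = x.size
    jitter = rng.uniform(-config.uncertainty_jitter, config.uncertainty_jitter, n)
    uncertainty = config.sigma_loc * (1.0 + jitter)
    frame = rng.permutation(n).astype(np.int64)
    return LocalizationTable(x=x, y=y, uncertainty=uncertainty, frame=frame)
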