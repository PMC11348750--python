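"""Soil-line estimation from the depth profile of lateral-root density.

On an excavated, washed maize root crown the soil line is no longer
visible, but lateral roots (hierarchy level >= 2) proliferate almost
exclusively below ground.  Binning total lateral-root length by depth gives
a roughly Gaussian profile; fitting

    f(x) = a * exp(-(x - b)^2 / (2 c^2))

with peak height ``a``, peak depth ``b`` (mm, top-down) and spread ``c``
puts the soil line where the profile starts to rise, at ``b - 2c``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .hierarchy import HierarchyLabeling
from .skeleton import Skeleton, depth_of

__all__ = [
    "DensityProfile",
    "GaussianFit",
    "DegenerateProfileError",
    "FitError",
    "lateral_density_profile",
    "fit_gaussian",
    "soil_line_depth",
    "DEFAULT_BIN_WIDTH_MM",
    "DEFAULT_SIGMA_FACTOR",
]

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH_MM = 2.0
DEFAULT_SIGMA_FACTOR = 2.0


class DegenerateProfileError(ValueError):
    """Profile has too few nonzero bins to support a Gaussian fit."""


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best iterate."""

    def __init__(self, message: str, best: Optional[tuple] = None):
        super().__init__(message)
        self.best = best


@dataclass
class DensityProfile:
    """Total lateral-root length (mm) per uniform depth bin."""

    bin_edges: np.ndarray  # mm, length n+1
    values: np.ndarray  # mm of lateral length, length n

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class GaussianFit:
    a: float  # peak height, profile units
    b: float  # peak depth, mm top-down
    c: float  # standard deviation, mm
    rss: float  # residual sum of squares


def _apportion(depth_lo, depth_hi, length, edges, values) -> None:
    """Split a segment's length across the depth bins it spans, pro rata."""
    width = edges[1] - edges[0]
    if depth_hi < depth_lo:
        depth_lo, depth_hi = depth_hi, depth_lo
    if depth_hi == depth_lo:
        i = int(np.clip((depth_lo - edges[0]) // width, 0, len(values) - 1))
        values[i] += length
        return
    span = depth_hi - depth_lo
    i_lo = int(np.clip((depth_lo - edges[0]) // width, 0, len(values) - 1))
    i_hi = int(np.clip((depth_hi - edges[0]) // width, 0, len(values) - 1))
    for i in range(i_lo, i_hi + 1):
        lo = max(depth_lo, edges[i])
        hi = min(depth_hi, edges[i + 1])
        if hi > lo:
            values[i] += length * (hi - lo) / span


def lateral_density_profile(
    labeling: HierarchyLabeling,
    skeleton: Skeleton,
    top_reference: np.ndarray,
    bin_width_mm: float = DEFAULT_BIN_WIDTH_MM,
    mode: str = "length",
) -> DensityProfile:
    """Depth profile of lateral roots (hierarchy label >= 2).

    ``mode='length'`` (default) apportions each lateral edge's length to
    the depth bins its vertical extent spans; ``mode='count'`` bins lateral
    branch origins instead.  Bin edges are multiples of ``bin_width_mm``
    starting at (or below) depth 0.
    """
    if mode not in ("length", "count"):
        raise ValueError(f"unknown density mode {mode!r}")
    if mode == "length":
        items = [
            (
                depth_of(skeleton.position(a), top_reference),
                depth_of(skeleton.position(b), top_reference),
                skeleton.edge_length((a, b)),
            )
            for a, b in labeling.edges_with_label_at_least(2)
        ]
    else:
        items = []
        for br in labeling.branches:
            if br.label >= 2:
                d = depth_of(skeleton.position(br.vertex_ids[0]), top_reference)
                items.append((d, d, 1.0))

    if not items:
        edges = np.array([0.0, bin_width_mm])
        return DensityProfile(edges, np.zeros(1))
    depths = np.array([[d1, d2] for d1, d2, _ in items])
    lo = min(0.0, np.floor(depths.min() / bin_width_mm) * bin_width_mm)
    hi = np.ceil(depths.max() / bin_width_mm) * bin_width_mm
    if hi <= lo:
        hi = lo + bin_width_mm
    edges = np.arange(lo, hi + 0.5 * bin_width_mm, bin_width_mm)
    values = np.zeros(len(edges) - 1)
    for d1, d2, length in items:
        _apportion(d1, d2, length, edges, values)
    return DensityProfile(edges, values)


def _gauss(x, a, b, c):
    return a * np.exp(-((x - b) ** 2) / (2.0 * c**2))


def fit_gaussian(profile: DensityProfile, max_iter: int = 500) -> GaussianFit:
    """Nonlinear least-squares Gaussian fit of the density profile.

    Initialized at the empirical peak (height and location) and the
    profile's weighted standard deviation.  Fails on profiles with fewer
    than three nonzero bins.
    """
    x = profile.centers
    y = np.asarray(profile.values, float)
    nz = np.count_nonzero(y)
    if nz < 3:
        raise DegenerateProfileError(
            f"Gaussian fit needs >= 3 nonzero bins, got {nz}"
        )
    a0 = float(y.max())
    b0 = float(x[int(np.argmax(y))])
    mean = float((x * y).sum() / y.sum())
    c0 = float(np.sqrt(((x - mean) ** 2 * y).sum() / y.sum()))
    if c0 <= 0:
        c0 = float(profile.bin_edges[1] - profile.bin_edges[0])
    try:
        popt, _ = curve_fit(
            _gauss,
            x,
            y,
            p0=(a0, b0, c0),
            ftol=1e-10,
            xtol=1e-12,
            maxfev=max_iter * 4,
        )
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}", best=(a0, b0, c0))
    a, b, c = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    if not (a > 0 and c > 0):
        raise FitError(
            f"Gaussian fit degenerate (a={a:.3g}, c={c:.3g})", best=(a, b, c)
        )
    rss = float(np.sum((y - _gauss(x, a, b, c)) ** 2))
    return GaussianFit(a=a, b=b, c=c, rss=rss)


def soil_line_depth(
    fit: GaussianFit, sigma_factor: float = DEFAULT_SIGMA_FACTOR
) -> float:
    """Soil-line depth (mm, top-down): ``b - sigma_factor * c``.

    The soil line sits where the lateral-density profile begins to rise,
    a couple of standard deviations above the peak.  A negative result
    (soil line above the stem top) is clamped to 0 with a warning.
    """
    depth = fit.b - sigma_factor * fit.c
    if depth < 0:
        logger.warning(
            "soil line %.2f mm above the stem top; clamping to 0", -depth
        )
        return 0.0
    return float(depth)
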