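"""Traditional shape descriptors for cell and leaf outlines.

Four descriptors summarise an outline: area A, aspect ratio AR = width/length
after principal-axis alignment (1 = isotropic, small = elongate), circularity
C = P^2 / (4 pi A) (1 for a circle, grows with elongation or margin
undulation), and solidity S = A / A_hull (1 = convex, small = undulate or
strongly curved). AR and S are the two near-orthogonal axes of pavement-cell
shape: base-shape anisotropy and margin undulation respectively; C mixes both.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import Outline, convex_hull, perimeter, polygon_area, principal_extents, resample

logger = logging.getLogger("paveshape")

#: All outlines are resampled to this many equally spaced vertices before
#: measurement so that hand-traced vertex density is not a nuisance variable.
RESAMPLE_POINTS = 300


@dataclass(frozen=True)
class ShapeMetrics:
    """The four shape descriptors plus perimeter for one outline."""

    area: float          # um^2 (mm^2 for leaves)
    perimeter: float     # um
    solidity: float      # (0, 1]
    aspect_ratio: float  # (0, 1]
    circularity: float   # >= 1 up to sampling tolerance
    label: str = ""


def solidity(outline: Outline) -> float:
    """Area of the outline divided by the area of its convex hull."""
    return polygon_area(outline) / polygon_area(convex_hull(outline))


def aspect_ratio(outline: Outline, method: str = "covariance") -> float:
    """Width over length of the outline aligned along its long axis."""
    ext = principal_extents(outline, method=method)
    return ext.width / ext.length


def circularity(outline: Outline) -> float:
    """Perimeter squared over area, normalised by 4 pi; 1 for a circle."""
    return perimeter(outline) ** 2 / (4.0 * np.pi * polygon_area(outline))


def measure(outline: Outline, n_points: int = RESAMPLE_POINTS, method: str = "covariance") -> ShapeMetrics:
    """All descriptors from one outline, resampled to ``n_points`` first."""
    o = resample(outline, n_points)
    return ShapeMetrics(
        area=polygon_area(o),
        perimeter=perimeter(o),
        solidity=solidity(o),
        aspect_ratio=aspect_ratio(o, method=method),
        circularity=circularity(o),
        label=outline.label,
    )


@dataclass(frozen=True)
class QuartileClass:
    """Quartile membership of a batch of values for one metric."""

    metric: str
    classes: np.ndarray      # int 1..4 per value
    breakpoints: np.ndarray  # the 0.25 / 0.5 / 0.75 dataset quantiles


def quartile_classify(values, metric: str = "") -> QuartileClass:
    """Assign each value to dataset quartile class 1-4.

    Class i covers (q_{i-1}, q_i] with q_0 = min: ties on a breakpoint fall in
    the lower class. Quantiles use linear (type-7) interpolation.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 4:
        raise ValueError("quartile classification needs at least 4 values")
    breaks = np.quantile(values, [0.25, 0.5, 0.75])
    if values.max() == values.min():
        warnings.warn(f"all values equal for {metric or 'metric'}; quartiles degenerate", stacklevel=2)
    classes = 1 + np.searchsorted(breaks, values, side="left")
    return QuartileClass(metric=metric, classes=classes.astype(int), breakpoints=breaks)
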