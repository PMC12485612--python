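"""Natural-city delineation from nighttime-light rasters.

Urban extents are delineated without administrative boundaries: a
head/tail-breaks threshold splits the heavy-tailed intensity
distribution, bright connected components above the final threshold are
"natural cities", and year-ordered city masks are stacked into
urbanization-gradient rings U1..UT (U1 = oldest core, U_t = cells that
first became urban in year t).  The mean relative expansion rate

    r = 100/(N-1) * sum_{i=1}^{N-1} (A_{i+1} - A_i) / A_i   [% per year]

summarizes a city's area series A_1..A_N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import RasterGrid


class DegenerateRasterError(ValueError):
    """Raised when a raster cannot support head/tail thresholding."""


@dataclass
class ThresholdTrace:
    """Iteration record of a head/tail-breaks run.

    ``thresholds[k]`` is the mean of the subset examined at iteration k;
    ``head_fractions[k]`` is the fraction of *all* finite cells lying
    strictly above that mean.  ``final_threshold`` is the last mean
    computed.  ``converged`` is False only when ``max_iter`` stopped the
    recursion before the head emptied or balanced.
    """

    thresholds: list[float] = field(default_factory=list)
    head_fractions: list[float] = field(default_factory=list)
    final_threshold: float = float("nan")
    converged: bool = True
    n_iter: int = 0


@dataclass
class CityMask:
    member: np.ndarray  # boolean grid aligned to the source raster
    year: int | str | None = None
    cell_area: float = 1.0

    @property
    def n_cells(self) -> int:
        return int(self.member.sum())

    @property
    def area(self) -> float:
        """km^2 (cell count x cell area)."""
        return self.n_cells * self.cell_area


@dataclass
class GradientZones:
    """Integer-labeled grid: 0 = background, t = ring U_t (1-based)."""

    label: np.ndarray
    n_rings: int

    def ring_mask(self, t: int) -> np.ndarray:
        return self.label == t

    def ring_cell_counts(self) -> np.ndarray:
        """Cell count per ring, index 0 -> U1."""
        return np.bincount(self.label.ravel(), minlength=self.n_rings + 1)[1:]


def head_tail_threshold(
    raster: RasterGrid | np.ndarray,
    balance_tol: float = 0.05,
    max_iter: int = 20,
) -> ThresholdTrace:
    """Iterative mean-thresholding for heavy-tailed intensity fields.

    Starting from all finite cells, each iteration computes the mean of
    the current subset and keeps the strictly-above-mean "head" as the
    next subset.  Recursion stops when the head/tail split of the
    current subset is balanced to ``balance_tol``
    (|head - tail| / subset <= tol), when the head is empty, or at
    ``max_iter`` (trace flagged non-converged).  The final threshold is
    the last mean computed.

    Raises
    ------
    DegenerateRasterError
        If the raster has fewer than 2 distinct finite values.
    """
    if not 0 < balance_tol <= 0.5:
        raise ValueError("balance_tol must lie in (0, 0.5]")
    if isinstance(raster, RasterGrid):
        data = raster.values[raster.valid_mask()]
    else:
        data = np.asarray(raster, dtype=float).ravel()
        data = data[np.isfinite(data)]
    if np.unique(data).size < 2:
        raise DegenerateRasterError(
            "head/tail breaks needs >= 2 distinct finite values"
        )

    total = data.size
    trace = ThresholdTrace()
    subset = data
    for _ in range(max_iter):
        mean = float(subset.mean())
        head = subset[subset > mean]
        trace.thresholds.append(mean)
        trace.head_fractions.append(head.size / total)
        trace.n_iter += 1
        balance = abs(head.size - (subset.size - head.size)) / subset.size
        if head.size == 0 or balance <= balance_tol:
            trace.final_threshold = mean
            return trace
        subset = head
    trace.final_threshold = trace.thresholds[-1]
    trace.converged = False
    return trace


def delineate_natural_city(
    raster: RasterGrid,
    threshold: float,
    connectivity: int = 8,
    min_cells: int = 4,
) -> list[CityMask]:
    """Extract bright connected components above ``threshold``.

    Components are strictly-above-threshold cells under 4- or
    8-connectivity, filtered to ``>= min_cells`` cells and sorted by
    area descending.  An empty list (nothing above threshold) is a valid
    result, not an error.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    bright = (raster.values > threshold) & raster.valid_mask()
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels, n = ndimage.label(bright, structure=structure)
    masks = []
    for lab in range(1, n + 1):
        member = labels == lab
        if member.sum() >= min_cells:
            masks.append(CityMask(member=member, cell_area=raster.cell_area()))
    masks.sort(key=lambda m: m.n_cells, reverse=True)
    return masks


def build_gradient_zones(masks: list[CityMask]) -> GradientZones:
    """Stack year-ordered city masks into gradient rings U1..UT.

    Monotone nesting is enforced by cumulative union (noise can shrink a
    raw mask between years); ring t holds cells first urban at year t.
    """
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].member.shape
    for m in masks[1:]:
        if m.member.shape != shape:
            raise ValueError("masks are not spatially aligned")
    label = np.zeros(shape, dtype=np.int32)
    cumulative = np.zeros(shape, dtype=bool)
    for t, m in enumerate(masks, start=1):
        new = m.member & ~cumulative
        label[new] = t
        cumulative |= m.member
    return GradientZones(label=label, n_rings=len(masks))


def expansion_rate(areas: list[float] | np.ndarray) -> float:
    """Mean relative urban land expansion rate in % per year.

    A geometric series with growth factor g gives exactly 100*(g-1).
    """
    A = np.asarray(areas, dtype=float)
    if A.size < 2:
        raise ValueError("need at least two annual areas")
    if np.any(A <= 0):
        raise ValueError("all areas must be positive")
    rel = (A[1:] - A[:-1]) / A[:-1]
    return float(rel.mean() * 100.0)


@dataclass
class ExpansionSeries:
    areas: list[float]
    r: float = field(init=False)

    def __post_init__(self) -> None:
        self.r = expansion_rate(self.areas)
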