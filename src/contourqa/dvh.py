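"""Cumulative dose-volume histograms and the DVH-difference flagging rule.

A cumulative DVH reports, for each dose level d, the fraction of a
structure's volume receiving at least d.  Curves are binned at 1 cGy and
normalized to relative volume, so V(0) = 1 for any non-empty structure and
the curve is monotone non-increasing.

Before sampling dose, the structure mask is refined longitudinally by
slice replication (default factor 3, turning 7.5 mm CT slices into a
2.5 mm DVH grid) so that coarse longitudinal sampling does not dominate
the dose estimate; dose is then read by trilinear interpolation at the
refined voxel centers, at native in-plane resolution.

Two curves are compared with a windowed discrepancy: at each dose level
the other curve may be matched anywhere within a +/-20 cGy dose window,
which forgives small horizontal (dose-axis) displacements in steep
gradients while still catching genuine volume discrepancies.  A pair is
flagged as failing when the windowed discrepancy exceeds 0.05 relative
volume at any dose level >= 20 cGy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    ArgumentError,
    BinningError,
    CoverageError,
    EmptyStructureError,
)
from .grid import ImageGrid, StructureMask, resample_longitudinal

__all__ = [
    "DoseGrid",
    "DVHCurve",
    "DVHDifferenceResult",
    "compute_dvh",
    "dvh_statistic",
    "flag_dvh",
]


@dataclass
class DoseGrid:
    """A non-negative scalar dose field, in cGy, on an :class:`ImageGrid`."""

    grid: ImageGrid
    dose: np.ndarray = field(repr=False)  # cGy

    def __post_init__(self):
        dose = np.asarray(self.dose, dtype=float)
        if dose.shape != tuple(self.grid.shape):
            raise ArgumentError(
                f"dose shape {dose.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(dose)):
            raise ArgumentError("dose must be finite everywhere")
        if dose.size and dose.min() < 0:
            raise ArgumentError("dose must be non-negative")
        self.dose = dose


@dataclass
class DVHCurve:
    """Cumulative relative-volume DVH at fixed dose bins.

    ``values[d]`` is the fraction of structure volume receiving at least
    ``d * bin_width`` cGy.  ``values[0] == 1`` for non-empty structures and
    the array is monotone non-increasing, ending at 0 past the maximum dose.
    """

    structure: str
    values: np.ndarray = field(repr=False)
    bin_width: float = 1.0  # cGy

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 1:
            raise ArgumentError("DVH curve must have at least one bin")
        if self.bin_width <= 0:
            raise ArgumentError("bin width must be positive")
        self.values = v

    def v_at(self, dose_cgy: float) -> float:
        """Relative volume receiving at least ``dose_cgy``."""
        if dose_cgy < 0:
            raise ArgumentError("dose must be non-negative")
        k = int(np.ceil(dose_cgy / self.bin_width - 1e-9))
        return float(self.values[k]) if k < self.values.size else 0.0

    @property
    def max_dose(self) -> float:
        """Largest dose level (cGy) with positive volume."""
        nz = np.nonzero(self.values)[0]
        return float(nz.max() * self.bin_width) if nz.size else 0.0

    @property
    def mean_dose(self) -> float:
        """Integral of the cumulative curve over dose (bin sum x bin width)."""
        return float(self.values[1:].sum() * self.bin_width)

    def d_at(self, p: float) -> float:
        """D(p%): the largest dose level received by at least p% of volume."""
        if not 0 < p <= 100:
            raise ArgumentError(f"volume percentage must lie in (0, 100], got {p}")
        ok = np.nonzero(self.values >= p / 100.0 - 1e-12)[0]
        if ok.size == 0:
            raise ArgumentError(f"no dose level reaches {p}% volume")
        return float(ok.max() * self.bin_width)

    @property
    def is_zero_dose(self) -> bool:
        """True when no part of the structure receives >= 1 bin of dose."""
        return self.max_dose < self.bin_width


@dataclass
class DVHDifferenceResult:
    """Outcome of the windowed DVH-difference flagging rule."""

    discrepancy: np.ndarray = field(repr=False)  # per bin, relative volume
    passed: bool = True
    max_discrepancy: float = 0.0
    first_failing_dose: float | None = None  # cGy
    bin_width: float = 1.0


def compute_dvh(
    mask: StructureMask,
    dose: DoseGrid,
    longitudinal_factor: int = 3,
    bin_width: float = 1.0,
) -> DVHCurve:
    """Cumulative DVH of ``mask`` on ``dose`` at ``bin_width`` cGy bins.

    The mask is first refined longitudinally by ``longitudinal_factor``
    (slice replication, volume-conserving); dose is sampled by trilinear
    interpolation at the refined voxel centers.  The mask and dose grids
    need not coincide, but every occupied voxel center must fall inside
    the dose grid, else a :class:`CoverageError` reports the out-of-grid
    fraction.
    """
    if mask.is_empty:
        raise EmptyStructureError(f"structure '{mask.name}' is empty")
    if bin_width <= 0:
        raise ArgumentError("bin width must be positive")
    fine = resample_longitudinal(mask, longitudinal_factor)
    idx = np.argwhere(fine.data)
    pts = fine.grid.indices_to_physical(idx)
    cont = dose.grid.physical_to_continuous_index(pts)
    shape = np.asarray(dose.grid.shape)
    # the dose field covers its voxel extents, i.e. half a voxel beyond the
    # outermost sample centers; samples there clamp to the edge value
    tol = 1e-6
    outside = np.any((cont < -0.5 - tol) | (cont > shape - 0.5 + tol), axis=1)
    if outside.any():
        frac = outside.mean()
        raise CoverageError(
            f"structure '{mask.name}' extends outside the dose grid "
            f"({frac:.1%} of voxels out of grid)",
            out_of_grid_fraction=float(frac),
        )
    sampled = ndimage.map_coordinates(
        dose.dose, cont.T, order=1, mode="nearest"
    )
    sampled = np.maximum(sampled, 0.0)
    bins = np.floor(sampled / bin_width + 1e-9).astype(np.int64)
    counts = np.bincount(bins)
    # values[d] = fraction with dose >= d*bin_width; one trailing zero bin
    values = np.zeros(counts.size + 1)
    values[: counts.size] = counts[::-1].cumsum()[::-1] / bins.size
    return DVHCurve(structure=mask.name, values=values, bin_width=bin_width)


def dvh_statistic(curve: DVHCurve, which: str) -> float:
    """Named DVH statistic from a curve.

    ``which`` is one of ``"D<p>"`` (dose in cGy to the hottest p% of
    volume, e.g. ``"D50"``), ``"V<d>"`` (relative volume receiving at
    least d cGy, e.g. ``"V1200"``), ``"Dmax"`` or ``"Dmean"`` (cGy).
    """
    w = which.strip()
    lw = w.lower()
    if lw == "dmax":
        return curve.max_dose
    if lw == "dmean":
        return curve.mean_dose
    try:
        if lw.startswith("d"):
            return curve.d_at(float(w[1:]))
        if lw.startswith("v"):
            return curve.v_at(float(w[1:]))
    except ValueError as exc:
        raise ArgumentError(f"cannot parse DVH statistic '{which}'") from exc
    raise ArgumentError(f"unknown DVH statistic '{which}'")


def _windowed_discrepancy(
    v_self: np.ndarray, v_other: np.ndarray, window_bins: int
) -> np.ndarray:
    """min over d' in [d-w, d+w] of |v_self(d) - v_other(d')| per bin d.

    Because a cumulative DVH is monotone, the windowed minimum equals the
    distance from v_self(d) to the interval [min, max] of v_other over the
    window, computed with running min/max filters (edge bins use the
    window clipped to the curve domain).
    """
    if window_bins == 0:
        return np.abs(v_self - v_other)
    size = 2 * window_bins + 1
    lo = ndimage.minimum_filter1d(v_other, size=size, mode="nearest")
    hi = ndimage.maximum_filter1d(v_other, size=size, mode="nearest")
    return np.maximum(0.0, np.maximum(v_self - hi, lo - v_self))


def flag_dvh(
    a: DVHCurve,
    b: DVHCurve,
    vol_tol: float = 0.05,
    dose_window: float = 20.0,
    min_dose: float = 20.0,
) -> DVHDifferenceResult:
    """Flag a clinically significant DVH difference between two curves.

    At each dose level d the discrepancy is the larger of the two directed
    windowed differences (each curve matched against the other anywhere
    within ``dose_window`` cGy); the pair *fails* when the discrepancy
    exceeds ``vol_tol`` relative volume at any dose level >= ``min_dose``.
    Setting ``dose_window=0`` recovers the plain pointwise rule.  The rule
    is symmetric in its two curves.  Curves are compared over the union of
    their supports (the shorter curve is extended with zeros).
    """
    if abs(a.bin_width - b.bin_width) > 1e-12:
        raise BinningError(
            f"curves have different bin widths: {a.bin_width} vs {b.bin_width} cGy"
        )
    if vol_tol < 0 or dose_window < 0 or min_dose < 0:
        raise ArgumentError("tolerances must be non-negative")
    n = max(a.values.size, b.values.size)
    va = np.zeros(n)
    vb = np.zeros(n)
    va[: a.values.size] = a.values
    vb[: b.values.size] = b.values
    w = int(round(dose_window / a.bin_width))
    delta = np.maximum(
        _windowed_discrepancy(va, vb, w), _windowed_discrepancy(vb, va, w)
    )
    k0 = int(np.ceil(min_dose / a.bin_width - 1e-9))
    eligible = delta[k0:] if k0 < n else np.array([])
    failing = np.nonzero(eligible > vol_tol)[0]
    passed = failing.size == 0
    return DVHDifferenceResult(
        discrepancy=delta,
        passed=passed,
        max_discrepancy=float(eligible.max()) if eligible.size else 0.0,
        first_failing_dose=None if passed else float((failing[0] + k0) * a.bin_width),
        bin_width=a.bin_width,
    )
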