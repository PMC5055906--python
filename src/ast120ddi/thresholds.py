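"""Threshold optimization against interaction-study outcomes.

Each interaction-study result carries the theoretical dissolution and
absorption rates (Rd, Ra, in percent) at the moment the adsorbent was
given, and an observed equivalence label: E (exposure unchanged by
co-administration) or NE (significantly changed).  For a candidate
threshold pair (Rdth, Rath) the method predicts

    E      if Rd >= Rdth and Ra >= Rath
    NE     if Rd <  Rdth and Ra <  Rath
    MIXED  otherwise (always counted inconsistent)

and the predictive value is the percentage of results whose prediction
matches the observed label.  The predictive value is piecewise constant in
(Rdth, Rath): it can only change when a threshold crosses an observed Rd
or Ra value, so the exact global maximum — and the full attaining region,
with open/closed boundary flags — is found by enumerating one
representative per constancy cell per axis instead of sweeping a grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import InputDataError


class Prediction(Enum):
    """Predicted equivalence state for one (drug, interval)."""

    EQUIVALENT = "E"
    NON_EQUIVALENT = "NE"
    MIXED = "MIXED"


@dataclass(frozen=True)
class InteractionResult:
    """One interaction-study outcome joined to its Rd/Ra values.

    ``interval_min`` is the dosing interval in minutes between the drug
    and the adsorbent; simultaneous administration is encoded as 1.
    """

    drug_id: str
    interval_min: int
    rd: float
    ra: float
    observed: str  # "E" or "NE"

    def __post_init__(self):
        if self.interval_min < 1:
            raise InputDataError("interval must be >= 1 minute (1 = simultaneous)")
        if not (0 <= self.rd <= 100 and 0 <= self.ra <= 100):
            raise InputDataError("Rd and Ra must lie in [0, 100]")
        if self.observed not in ("E", "NE"):
            raise InputDataError(f"observed must be 'E' or 'NE', got {self.observed!r}")


@dataclass(frozen=True)
class Interval:
    """A one-dimensional threshold interval with boundary flags."""

    low: float
    high: float
    low_open: bool = True
    high_closed: bool = True

    def contains(self, x: float) -> bool:
        lo_ok = x > self.low if self.low_open else x >= self.low
        hi_ok = x <= self.high if self.high_closed else x < self.high
        return lo_ok and hi_ok


@dataclass(frozen=True)
class Box:
    """An axis-aligned rectangle of threshold pairs."""

    rd: Interval
    ra: Interval

    def contains(self, rdth: float, rath: float) -> bool:
        return self.rd.contains(rdth) and self.ra.contains(rath)


@dataclass(frozen=True)
class ThresholdRegion:
    """The set of threshold pairs attaining the maximum predictive value.

    ``boxes`` is an exact decomposition of the attaining set into
    axis-aligned rectangles whose bounds sit at observed data values; the
    top-level ``rdth_*``/``rath_*`` fields summarize its per-axis extent
    (the bounding intervals, which coincide with the single box in the
    common case of a rectangular attaining set).
    """

    max_predictive_value: float
    n_results: int
    n_consistent: int
    boxes: tuple[Box, ...]

    @property
    def rdth_bounds(self) -> Interval:
        return self._bound(axis="rd")

    @property
    def rath_bounds(self) -> Interval:
        return self._bound(axis="ra")

    def _bound(self, axis: str) -> Interval:
        ivs = [getattr(b, axis) for b in self.boxes]
        lo = min(ivs, key=lambda i: (i.low, i.low_open))
        hi = max(ivs, key=lambda i: (i.high, i.high_closed))
        return Interval(lo.low, hi.high, lo.low_open, hi.high_closed)

    def contains(self, rdth: float, rath: float) -> bool:
        return any(b.contains(rdth, rath) for b in self.boxes)

    def to_dict(self) -> dict:
        def iv(i: Interval) -> dict:
            return {
                "low": i.low, "high": i.high,
                "low_open": i.low_open, "high_closed": i.high_closed,
            }

        return {
            "max_predictive_value_pct": round(self.max_predictive_value, 1),
            "n_results": self.n_results,
            "n_consistent": self.n_consistent,
            "rdth": iv(self.rdth_bounds),
            "rath": iv(self.rath_bounds),
            "boxes": [{"rdth": iv(b.rd), "rath": iv(b.ra)} for b in self.boxes],
        }


def predict_equivalence(rd: float, ra: float, rdth: float, rath: float) -> Prediction:
    """Quadrant prediction; equality always falls on the equivalent side."""
    rd_ok, ra_ok = rd >= rdth, ra >= rath
    if rd_ok and ra_ok:
        return Prediction.EQUIVALENT
    if not rd_ok and not ra_ok:
        return Prediction.NON_EQUIVALENT
    return Prediction.MIXED


def is_consistent(prediction: Prediction, observed: str) -> bool:
    """A prediction is consistent iff it equals the observed label;
    MIXED is never consistent."""
    if observed not in ("E", "NE"):
        raise InputDataError(f"observed must be 'E' or 'NE', got {observed!r}")
    return prediction.value == observed


def predictive_value(results, rdth: float, rath: float) -> float:
    """Percent of results whose prediction at (rdth, rath) is consistent."""
    results = list(results)
    if not results:
        raise InputDataError("predictive_value needs at least one result")
    hits = sum(
        is_consistent(predict_equivalence(r.rd, r.ra, rdth, rath), r.observed)
        for r in results
    )
    return 100.0 * hits / len(results)


def surface(results, rd_grid, ra_grid) -> np.ndarray:
    """Predictive value at every (rd_grid[i], ra_grid[j]) pair.

    Returns a len(rd_grid) x len(ra_grid) matrix; used for 3-D/contour
    exports of the threshold landscape.
    """
    results = list(results)
    rd_grid = np.asarray(rd_grid, dtype=float)
    ra_grid = np.asarray(ra_grid, dtype=float)
    for g in (rd_grid, ra_grid):
        if np.any(g < 0) or np.any(g > 100) or np.any(np.diff(g) <= 0):
            raise InputDataError("grids must be ascending within [0, 100]")
    counts = _consistency_counts(results, rd_grid, ra_grid)
    return 100.0 * counts / len(results)


def _consistency_counts(results, rd_cand: np.ndarray, ra_cand: np.ndarray) -> np.ndarray:
    """Consistent-result counts for every candidate pair, vectorized."""
    if not results:
        raise InputDataError("need at least one result")
    rd = np.array([r.rd for r in results])
    ra = np.array([r.ra for r in results])
    is_e = np.array([r.observed == "E" for r in results])
    ge_rd = (rd[None, :] >= rd_cand[:, None]).astype(float)  # (Mr, n)
    ge_ra = (ra[None, :] >= ra_cand[:, None]).astype(float)  # (Ma, n)
    # consistent = (both >=, observed E) or (both <, observed NE)
    return ge_rd @ (ge_ra * is_e).T + (1 - ge_rd) @ ((1 - ge_ra) * ~is_e).T


@dataclass(frozen=True)
class _Cell:
    low: float
    high: float
    low_open: bool
    rep: float  # a threshold value inside the cell


def _axis_cells(values: np.ndarray) -> list[_Cell]:
    """Constancy cells of one threshold axis.

    Thresholds in ``(v_i, v_{i+1}]`` select the same ``>=`` subset, so each
    such interval is one cell represented by its closed right endpoint; the
    cell above the largest value is represented by ``v_max + eps`` with
    eps below half the smallest inter-value gap (capped at 0.05).
    """
    distinct = np.unique(values)
    cells: list[_Cell] = []
    if distinct[0] == 0.0:
        cells.append(_Cell(0.0, 0.0, False, 0.0))
    else:
        cells.append(_Cell(0.0, float(distinct[0]), False, float(distinct[0])))
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cells.append(_Cell(float(lo), float(hi), True, float(hi)))
    top = float(distinct[-1])
    if top < 100.0:
        gaps = np.diff(distinct)
        min_gap = float(gaps.min()) if gaps.size else 100.0
        eps = min(0.05, min_gap / 2.0, (100.0 - top) / 2.0)
        cells.append(_Cell(top, 100.0, True, top + eps))
    return cells


def optimal_region(results) -> ThresholdRegion:
    """Exact maximization of the predictive value over all threshold pairs.

    Enumerates one representative threshold per constancy cell on each
    axis, takes the global maximum of the consistency count, and merges the
    attaining cells into axis-aligned boxes (consecutive Rd-cells with
    identical attaining Ra-patterns collapse, as do consecutive Ra-cells).
    """
    results = list(results)
    if not results:
        raise InputDataError("optimal_region needs at least one result")
    rd_cells = _axis_cells(np.array([r.rd for r in results]))
    ra_cells = _axis_cells(np.array([r.ra for r in results]))
    counts = _consistency_counts(
        results,
        np.array([c.rep for c in rd_cells]),
        np.array([c.rep for c in ra_cells]),
    )
    max_count = int(round(counts.max()))
    attain = np.round(counts).astype(int) == max_count

    boxes: list[Box] = []
    i = 0
    while i < len(rd_cells):
        j = i + 1
        while j < len(rd_cells) and np.array_equal(attain[j], attain[i]):
            j += 1
        row = attain[i]
        k = 0
        while k < len(ra_cells):
            if row[k]:
                k2 = k
                while k2 + 1 < len(ra_cells) and row[k2 + 1]:
                    k2 += 1
                boxes.append(
                    Box(
                        rd=Interval(
                            rd_cells[i].low, rd_cells[j - 1].high,
                            rd_cells[i].low_open, True,
                        ),
                        ra=Interval(
                            ra_cells[k].low, ra_cells[k2].high,
                            ra_cells[k].low_open, True,
                        ),
                    )
                )
                k = k2 + 1
            else:
                k += 1
        i = j

    boxes.sort(
        key=lambda b: (b.rd.high - b.rd.low) * (b.ra.high - b.ra.low), reverse=True
    )
    return ThresholdRegion(
        max_predictive_value=100.0 * max_count / len(results),
        n_results=len(results),
        n_consistent=max_count,
        boxes=tuple(boxes),
    )
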