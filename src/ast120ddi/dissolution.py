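"""Noyes-Whitney dissolution kinetics.

In vitro dissolution profiles (percent of dose dissolved vs time, read in
the two Japanese Pharmacopoeia fluids, pH 1.2 and pH 6.8) are fitted with
the percentage form of the Noyes-Whitney first-order law

    Rd(t) = xe * (1 - exp(-kd * (t - Tlagd)))

where ``kd`` (s^-1) is the apparent dissolution rate constant (the product
of the intrinsic rate constant and the formulation surface area), ``xe``
the percent dissolved at equilibrium and ``Tlagd`` (h) a lag time, defined
operationally as the time to 1 % dissolution (relevant for capsules and
enteric coats).  Drugs that fail to dissolve completely in both fluids are
excluded from interaction scoring; when both fluids give a complete fit the
faster constant governs.  The theoretical dissolution rate used for
interaction prediction evaluates the fitted exponential with ``xe`` pinned
at 100 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import lmfit

from .errors import ExcludedDrugError, FitConvergenceError, InputDataError, NoDissolutionError

MEDIA = ("pH1.2", "pH6.8")

#: fitted xe and the last measured point must both reach this percentage
#: for a medium to count as "complete dissolution" (graph-read data carry a
#: few percent of noise, so 100 % exactly is too strict).
COMPLETENESS_TOLERANCE_PCT = 95.0

_MIN_TO_S = 60.0
_H_TO_S = 3600.0


@dataclass(frozen=True)
class DissolutionCurve:
    """One measured dissolution profile in one test fluid.

    times are minutes since the start of the test, values percent dissolved.
    Small assay overshoot above 100 % is tolerated up to 110 %.
    """

    drug_id: str
    medium: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.medium not in MEDIA:
            raise InputDataError(f"medium must be one of {MEDIA}, got {self.medium!r}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise InputDataError("times and values must be 1-D arrays of equal length")
        if len(self.times) < 3:
            raise InputDataError("a dissolution curve needs at least 3 sampling points")
        if self.times[0] < 0 or np.any(np.diff(self.times) <= 0):
            raise InputDataError("times must be non-negative and strictly increasing")
        if np.any(self.values < 0) or np.any(self.values > 110):
            raise InputDataError("percent dissolved must lie in [0, 110]")


@dataclass(frozen=True)
class DissolutionFit:
    """Fitted Noyes-Whitney parameters for one drug in one medium."""

    kd: float  # s^-1
    tlagd: float  # hours
    xe: float  # percent at equilibrium
    rss: float  # percent^2
    complete: bool
    medium: str
    drug_id: str = ""

    def __post_init__(self):
        if not self.kd > 0:
            raise InputDataError(f"kd must be positive, got {self.kd}")
        if self.tlagd < 0:
            raise InputDataError(f"Tlagd must be non-negative, got {self.tlagd}")
        if not 0 < self.xe <= 110:
            raise InputDataError(f"xe must lie in (0, 110], got {self.xe}")
        if self.rss < 0:
            raise InputDataError("rss must be non-negative")


def estimate_lag_time(curve: DissolutionCurve) -> float:
    """Time to 1 % dissolution, in hours, by linear interpolation.

    Returns 0 when the first sample already sits at or above 1 %.  Raises
    :class:`NoDissolutionError` when the profile never reaches 1 %.
    """
    v = curve.values
    idx = np.nonzero(v >= 1.0)[0]
    if idx.size == 0:
        raise NoDissolutionError(
            f"{curve.drug_id} ({curve.medium}): profile never reaches 1 % dissolved"
        )
    i = int(idx[0])
    if i == 0:
        return 0.0
    t0, t1 = curve.times[i - 1], curve.times[i]
    v0, v1 = v[i - 1], v[i]
    t_cross_min = t0 + (1.0 - v0) / (v1 - v0) * (t1 - t0)
    return float(t_cross_min) / 60.0


def _model(ts: np.ndarray, kd: float, xe: float, tlag_s: float) -> np.ndarray:
    return xe * -np.expm1(-kd * np.maximum(ts - tlag_s, 0.0))


def _initial_kd(ts: np.ndarray, v: np.ndarray, xe0: float, tlag_s: float) -> float:
    """Slope of -log(1 - v/xe0) against time through the origin."""
    tau = ts - tlag_s
    mask = (v > 0) & (v < 0.95 * xe0) & (tau > 0)
    if not mask.any():
        return 1.0 / max(ts[-1], 1.0)
    y = -np.log1p(-v[mask] / (xe0 * 1.001))
    tau = tau[mask]
    denom = float(np.dot(tau, tau))
    kd0 = float(np.dot(y, tau)) / denom if denom > 0 else 1.0 / ts[-1]
    return max(kd0, 1e-9)


def fit_dissolution(curve: DissolutionCurve, use_lag: bool | None = None) -> DissolutionFit:
    """Least-squares fit of the Noyes-Whitney percentage form to a profile.

    ``Tlagd`` is estimated from the measured curve (interpolated 1 %
    crossing) and held fixed; it is not co-estimated with ``kd``, which
    avoids the identifiability ridge between the two.  With
    ``use_lag=None`` the model is fitted both without a lag and, when the
    1 % crossing lies beyond 1 minute, with the estimated lag fixed; the
    lower-residual fit wins (ties go to the lag-free model).  A slow but
    lag-free profile thus never acquires a spurious lag merely because it
    crosses 1 % late.  ``xe`` is free in (0, 110].  Bounded least squares
    with three log-spaced restarts of the ``kd`` start guards against
    local minima.
    """
    if use_lag is None:
        fit0 = fit_dissolution(curve, use_lag=False)
        try:
            lag_h = estimate_lag_time(curve)
        except NoDissolutionError:
            return fit0
        if lag_h * 60.0 <= 1.0:
            return fit0
        fit1 = fit_dissolution(curve, use_lag=True)
        return fit1 if fit1.rss < fit0.rss else fit0

    ts = curve.times * _MIN_TO_S
    v = curve.values

    lag_h = estimate_lag_time(curve) if use_lag else 0.0
    tlag_s = lag_h * _H_TO_S

    xe0 = float(np.clip(max(v[-1], v.max()), 1.0, 110.0))
    kd0 = _initial_kd(ts, v, xe0, tlag_s)

    best = None
    attempts = []
    for factor in (0.2, 1.0, 5.0):
        params = lmfit.Parameters()
        params.add("kd", value=kd0 * factor, min=1e-10, max=10.0)
        params.add("xe", value=xe0, min=1e-3, max=110.0)

        def resid(p):
            return _model(ts, p["kd"].value, p["xe"].value, tlag_s) - v

        try:
            with np.errstate(invalid="ignore", divide="ignore"):
                out = lmfit.minimize(
                    resid, params, method="least_squares",
                    xtol=1e-15, ftol=1e-15, gtol=1e-15, calc_covar=False,
                )
        except Exception as exc:  # pragma: no cover - lmfit rarely raises here
            attempts.append({"start_factor": factor, "error": str(exc)})
            continue
        rss = float(np.sum(out.residual**2))
        attempts.append({"start_factor": factor, "rss": rss, "success": out.success})
        if out.success and (best is None or rss < best[0]):
            best = (rss, out)

    if best is None:
        raise FitConvergenceError(
            f"dissolution fit failed for {curve.drug_id} ({curve.medium})",
            diagnostics={"attempts": attempts, "kd0": kd0, "xe0": xe0},
        )

    rss, out = best
    kd = float(out.params["kd"].value)
    xe = float(out.params["xe"].value)
    complete = xe >= COMPLETENESS_TOLERANCE_PCT and v[-1] >= COMPLETENESS_TOLERANCE_PCT
    return DissolutionFit(
        kd=kd, tlagd=lag_h, xe=xe, rss=rss, complete=complete,
        medium=curve.medium, drug_id=curve.drug_id,
    )


def select_medium_fit(
    fit_ph12: DissolutionFit | None, fit_ph68: DissolutionFit | None
) -> DissolutionFit:
    """Pick the fit that governs interaction prediction.

    Both media complete -> the larger ``kd``; exactly one complete -> that
    one; neither -> the drug is excluded from scoring.
    """
    candidates = [f for f in (fit_ph12, fit_ph68) if f is not None and f.complete]
    if not candidates:
        drug = next(
            (f.drug_id for f in (fit_ph12, fit_ph68) if f is not None), "<unknown>"
        )
        raise ExcludedDrugError(
            f"{drug}: complete dissolution reached in neither fluid; drug excluded"
        )
    return max(candidates, key=lambda f: f.kd)


def dissolution_rate(fit: DissolutionFit, t: float) -> float:
    """Theoretical dissolution rate Rd (%) at ``t`` minutes after intake.

    Only defined for complete fits; ``xe`` is taken as exactly 100 so that
    Rd expresses percent of dose.  Clamped to [0, 100]; times at or before
    the lag give 0.
    """
    if not fit.complete:
        raise ExcludedDrugError(
            f"{fit.drug_id or '<drug>'}: incomplete dissolution; Rd undefined"
        )
    if t <= 0:
        raise InputDataError("dosing interval must be positive")
    tau = t * _MIN_TO_S - fit.tlagd * _H_TO_S
    rd = 100.0 * -math.expm1(-fit.kd * tau) if tau > 0 else 0.0
    return min(max(rd, 0.0), 100.0)
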