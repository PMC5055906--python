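"""Oral absorption kinetics: compartmental fits and the absorption fraction.

Plasma concentration curves after a single oral dose are fitted with the
standard one- or two-compartment disposition models under first-order
absorption with lag:

    one-compartment:  C(t) = A * ka * (e^(-ke*tau) - e^(-ka*tau)) / (ka - ke)
    two-compartment:  C(t) = A * ka * [ f * E(alpha) + (1 - f) * E(beta) ]

with tau = t - Tlaga (zero before the lag), E(r) = (e^(-r*tau) -
e^(-ka*tau)) / (ka - r), ``A`` an apparent dose/volume amplitude, and
``f`` the amplitude fraction of the fast (alpha) disposition phase.  The
degenerate case ka -> r is evaluated by its analytic limit tau*e^(-ka*tau).

The quantity the interaction prediction needs is not the concentration but
the absorption fraction

    Ra(t) = 100 * (1 - exp(-ka * (t - Tlaga)))

the percent of the ultimately absorbed amount that has been absorbed by
time t, which depends only on ``ka`` and ``Tlaga``.

Model order is chosen by the small-sample Akaike criterion (AICc) with a
two-unit tie window favouring the simpler model.  One-compartment fits are
reported in the labelling with ka >= ke; the flip-flop exchange symmetry
(ka <-> ke with a compensating amplitude rescale) leaves the curve, and
hence the residuals, unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import lmfit

from .errors import FitConvergenceError, InputDataError

_DEGENERACY_RTOL = 1e-8
_AICC_TIE_WINDOW = 2.0


@dataclass(frozen=True)
class PlasmaCurve:
    """One plasma-concentration profile after a single oral dose."""

    drug_id: str
    times: np.ndarray  # hours post-dose
    concentrations: np.ndarray  # arbitrary but consistent units

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(
            self, "concentrations", np.asarray(self.concentrations, dtype=float)
        )
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape:
            raise InputDataError("times and concentrations must match in shape")
        if len(self.times) < 5:
            raise InputDataError("a plasma curve needs at least 5 sampling points")
        if self.times[0] < 0 or np.any(np.diff(self.times) <= 0):
            raise InputDataError("times must be non-negative and strictly increasing")
        if np.any(self.concentrations < 0):
            raise InputDataError("concentrations must be non-negative")
        if not np.any(self.concentrations > 0):
            raise InputDataError("at least one concentration must be positive")


@dataclass(frozen=True)
class PKFit:
    """Fitted oral-absorption model for one drug.

    ``disposition`` is ``(ke,)`` for the one-compartment model and
    ``(alpha, beta, alpha_fraction)`` for the two-compartment model.
    ``tlaga_raw`` preserves the optimizer's lag estimate; a negative value
    is clamped to 0 in ``tlaga`` per the reporting rule, and the clamp is
    observable by comparing the two fields.
    """

    model_order: int
    ka: float  # h^-1
    tlaga: float  # hours, clamped >= 0
    disposition: tuple
    scale: float
    rss: float
    aic: float
    n_obs: int
    tlaga_raw: float = 0.0
    drug_id: str = ""

    def __post_init__(self):
        if self.model_order not in (1, 2):
            raise InputDataError("model_order must be 1 or 2")
        if not self.ka > 0:
            raise InputDataError("ka must be positive")
        if self.tlaga < 0:
            raise InputDataError("Tlaga must be non-negative (clamp before building)")
        if any(not d > 0 for d in self.disposition[: self.model_order]):
            raise InputDataError("disposition rate constants must be positive")
        if self.model_order == 2:
            alpha, beta, frac = self.disposition
            if not alpha > beta:
                raise InputDataError("two-compartment fits require alpha > beta")
            if not 0 < frac < 1:
                raise InputDataError("alpha-phase amplitude fraction must be in (0, 1)")

    @property
    def ke(self) -> float:
        if self.model_order != 1:
            raise AttributeError("ke is defined for one-compartment fits only")
        return self.disposition[0]

    @property
    def alpha(self) -> float:
        return self.disposition[0] if self.model_order == 2 else self._no2()

    @property
    def beta(self) -> float:
        return self.disposition[1] if self.model_order == 2 else self._no2()

    @property
    def alpha_fraction(self) -> float:
        return self.disposition[2] if self.model_order == 2 else self._no2()

    def _no2(self):
        raise AttributeError("alpha/beta are defined for two-compartment fits only")


def _exp_term(rate: float, ka: float, tau: np.ndarray) -> np.ndarray:
    """(e^(-rate*tau) - e^(-ka*tau)) / (ka - rate), analytic at ka == rate."""
    if abs(ka - rate) <= _DEGENERACY_RTOL * ka:
        return tau * np.exp(-ka * tau)
    return (np.exp(-rate * tau) - np.exp(-ka * tau)) / (ka - rate)


def _concentration(
    t, ka: float, rates: tuple, fracs: tuple, scale: float, tlaga: float
) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    tau = np.maximum(t - tlaga, 0.0)
    out = np.zeros_like(tau)
    for rate, frac in zip(rates, fracs):
        out += frac * _exp_term(rate, ka, tau)
    return scale * ka * out


def predict_concentration(fit: PKFit, t) -> np.ndarray | float:
    """Model concentration at time(s) ``t`` (hours); 0 at or before the lag."""
    if fit.model_order == 1:
        rates, fracs = (fit.disposition[0],), (1.0,)
    else:
        alpha, beta, f = fit.disposition
        rates, fracs = (alpha, beta), (f, 1.0 - f)
    out = _concentration(t, fit.ka, rates, fracs, fit.scale, fit.tlaga)
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def absorption_fraction(ka: float, tlaga: float, t: float) -> float:
    """Absorption fraction Ra (%) at ``t`` minutes post-dose.

    Ra = 100*(1 - exp(-ka*(t - Tlaga))), clamped to [0, 100]; times at or
    before the lag give 0.
    """
    if not ka > 0:
        raise InputDataError("ka must be positive")
    if tlaga < 0:
        raise InputDataError("Tlaga must be non-negative")
    if t <= 0:
        raise InputDataError("dosing interval must be positive")
    tau = t / 60.0 - tlaga
    ra = 100.0 * -math.expm1(-ka * tau) if tau > 0 else 0.0
    return min(max(ra, 0.0), 100.0)


def _strip_initials(times: np.ndarray, conc: np.ndarray) -> dict:
    """Curve-stripping starting values: terminal slope, method of residuals,
    and the last zero-concentration time as the lag start."""
    pos = conc > 0
    first_pos = int(np.argmax(pos))
    tlag0 = 0.0
    if first_pos > 0:
        zeros_before = np.nonzero(conc[:first_pos] == 0)[0]
        if zeros_before.size:
            tlag0 = float(times[zeros_before[-1]])

    t_pos, c_pos = times[pos], conc[pos]
    m = max(3, len(t_pos) // 3)
    tail_t, tail_c = t_pos[-m:], c_pos[-m:]
    slope, intercept = np.polyfit(tail_t, np.log(tail_c), 1)
    k_term = max(-float(slope), 1e-3)

    i_max = int(np.argmax(conc))
    t_max = max(float(times[i_max]) - tlag0, 1e-3)
    ka0 = None
    head = (times < times[i_max]) & pos
    if head.sum() >= 2:
        extrap = np.exp(intercept + slope * times[head])
        resid = extrap - conc[head]
        if np.all(resid > 0):
            rslope, _ = np.polyfit(times[head], np.log(resid), 1)
            if rslope < 0:
                ka0 = -float(rslope)
    if ka0 is None or ka0 <= k_term:
        ka0 = max(3.0 / t_max, 2.0 * k_term)
    return {"k_term": k_term, "ka0": ka0, "tlag0": tlag0, "cmax": float(conc.max())}


def _fit_order(curve: PlasmaCurve, order: int, resolve_flip_flop: bool = True) -> PKFit:
    times, conc = curve.times, curve.concentrations
    ini = _strip_initials(times, conc)
    k_term, ka0, tlag0 = ini["k_term"], ini["ka0"], ini["tlag0"]
    t_hi = float(times[-1])

    if order == 1:
        starts = [
            {"ka": ka0, "r1": k_term},
            {"ka": 5.0 * k_term, "r1": k_term},
            {"ka": 1.5 * k_term, "r1": 0.5 * k_term},
        ]
    else:
        starts = [
            {"ka": ka0, "r1": 5.0 * k_term, "r2": k_term, "f": 0.5},
            {"ka": max(ka0, 10.0 * k_term), "r1": 10.0 * k_term, "r2": k_term, "f": 0.3},
            {"ka": 3.0 * ka0, "r1": 4.0 * k_term, "r2": k_term, "f": 0.7},
        ]

    best = None
    attempts = []
    for start in starts:
        params = lmfit.Parameters()
        params.add("ka", value=start["ka"], min=1e-6, max=1e3)
        params.add("r1", value=start["r1"], min=1e-6, max=1e3)
        if order == 2:
            params.add("r2", value=start["r2"], min=1e-6, max=1e3)
            params.add("f", value=start["f"], min=1e-6, max=1 - 1e-6)
        params.add("tlag", value=tlag0, min=-5.0, max=t_hi)
        # analytic amplitude start: scale unit-model peak to the observed peak
        unit = _concentration(
            times, start["ka"],
            (start["r1"],) if order == 1 else (start["r1"], start["r2"]),
            (1.0,) if order == 1 else (start["f"], 1.0 - start["f"]),
            1.0, tlag0,
        )
        peak = float(unit.max())
        params.add("scale", value=ini["cmax"] / peak if peak > 0 else 1.0, min=1e-12)

        def resid(p):
            if order == 1:
                rates, fracs = (p["r1"].value,), (1.0,)
            else:
                rates = (p["r1"].value, p["r2"].value)
                fracs = (p["f"].value, 1.0 - p["f"].value)
            return _concentration(
                times, p["ka"].value, rates, fracs, p["scale"].value, p["tlag"].value
            ) - conc

        try:
            with np.errstate(invalid="ignore", divide="ignore"):
                out = lmfit.minimize(
                    resid, params, method="least_squares",
                    xtol=1e-15, ftol=1e-15, gtol=1e-15, calc_covar=False,
                )
        except Exception as exc:  # pragma: no cover
            attempts.append({"start": start, "error": str(exc)})
            continue
        rss = float(np.sum(out.residual**2))
        attempts.append({"start": start, "rss": rss, "success": out.success})
        if out.success and (best is None or rss < best[0]):
            best = (rss, out)

    if best is None:
        raise FitConvergenceError(
            f"{order}-compartment fit failed for {curve.drug_id}",
            diagnostics={"attempts": attempts, "initials": ini},
        )

    rss, out = best
    p = {k: float(v.value) for k, v in out.params.items()}
    ka, scale, tlag_raw = p["ka"], p["scale"], p["tlag"]

    if order == 1:
        ke = p["r1"]
        if resolve_flip_flop and ka < ke:  # flip-flop: report the ka >= ke labelling
            ka, ke, scale = ke, ka, scale * ka / ke
        disposition = (ke,)
    else:
        a, b, f = p["r1"], p["r2"], p["f"]
        if a < b:
            a, b, f = b, a, 1.0 - f
        f = min(max(f, 1e-9), 1 - 1e-9)
        if a <= b:  # exactly equal rates: split infinitesimally
            a = b * (1 + 1e-9)
        disposition = (a, b, f)

    n = len(times)
    k_par = 4 if order == 1 else 6
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * k_par
    aicc = aic + (
        2 * k_par * (k_par + 1) / (n - k_par - 1) if n - k_par - 1 > 0 else math.inf
    )
    return PKFit(
        model_order=order, ka=ka, tlaga=max(tlag_raw, 0.0), disposition=disposition,
        scale=scale, rss=rss, aic=aicc, n_obs=n, tlaga_raw=tlag_raw,
        drug_id=curve.drug_id,
    )


def fit_pk(
    curve: PlasmaCurve, model_order: int, resolve_flip_flop: bool = True
) -> PKFit:
    """Fit the requested compartment model to a plasma curve.

    Unweighted least squares on the linear concentration scale (graph-read
    data; roughly uniform absolute noise).  The lag is free down to -5 h in
    the search and clamped to 0 afterwards so a negative estimate stays
    visible in ``tlaga_raw``.  One-compartment fits are relabelled so that
    ka >= ke (the flip-flop exchange leaves the curve unchanged); pass
    ``resolve_flip_flop=False`` to keep the optimizer's labelling when ka
    is pinned by external knowledge.
    """
    if model_order not in (1, 2):
        raise InputDataError("model_order must be 1 or 2")
    if model_order == 2 and len(curve.times) < 6:
        raise InputDataError("a two-compartment fit needs at least 6 points")
    return _fit_order(curve, model_order, resolve_flip_flop)


def select_model(fit1: PKFit, fit2: PKFit) -> PKFit:
    """Choose between one- and two-compartment fits of the same curve by
    AICc; ties within 2 units go to the one-compartment model."""
    if fit1.model_order != 1 or fit2.model_order != 2:
        raise InputDataError("select_model expects (one-compartment, two-compartment)")
    if math.isfinite(fit2.aic) and fit2.aic < fit1.aic - _AICC_TIE_WINDOW:
        return fit2
    return fit1
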