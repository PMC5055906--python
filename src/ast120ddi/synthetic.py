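"""Synthetic curve generation for parameter-recovery testing.

Curves are drawn from the same models the fitters assume (Noyes-Whitney
dissolution; one-/two-compartment oral absorption) plus additive Gaussian
noise, emulating the dominant error source of the real inputs — reading
values off published graphs, which contributes a roughly uniform absolute
error of a few percent of scale.  Dissolution noise is specified in
percent dissolved; plasma noise as a fraction of the peak concentration.
All randomness flows through a seed carried in the spec, so a generated
curve is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .absorption import PKFit, PlasmaCurve, predict_concentration
from .dissolution import DissolutionCurve
from .errors import InputDataError

#: default dissolution sampling grid, minutes (typical pharmacopoeial points)
DISSOLUTION_TIMES_MIN = (5.0, 10.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0)
#: default plasma sampling grid, hours post-dose; dense over the absorption
#: phase (several points before a typical 1-2 h tmax) so that ka and the
#: lag are jointly identifiable, sparse over the terminal phase
PK_TIMES_H = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)


@dataclass(frozen=True)
class SyntheticDissolutionSpec:
    """Truth parameters for one simulated dissolution profile."""

    kd: float  # s^-1
    xe: float = 100.0  # percent
    tlagd: float = 0.0  # hours
    times_min: tuple = DISSOLUTION_TIMES_MIN
    noise_sd_pct: float = 0.0
    seed: int = 0
    drug_id: str = "synthetic"
    medium: str = "pH1.2"

    def __post_init__(self):
        if self.noise_sd_pct < 0:
            raise InputDataError("noise sd must be non-negative")


@dataclass(frozen=True)
class SyntheticPKSpec:
    """Truth parameters for one simulated plasma curve."""

    fit: PKFit  # the generating model (order, ka, lag, disposition, scale)
    times_h: tuple = PK_TIMES_H
    noise_sd_frac_of_peak: float = 0.0
    seed: int = 0
    drug_id: str = "synthetic"

    def __post_init__(self):
        if self.noise_sd_frac_of_peak < 0:
            raise InputDataError("noise sd must be non-negative")


SyntheticSpec = SyntheticDissolutionSpec | SyntheticPKSpec


def generate_dissolution_curve(spec: SyntheticDissolutionSpec) -> DissolutionCurve:
    """Noyes-Whitney profile plus seeded Gaussian noise, clipped to [0, 110]."""
    t = np.asarray(spec.times_min, dtype=float)
    clean = spec.xe * -np.expm1(-spec.kd * np.maximum(t * 60.0 - spec.tlagd * 3600.0, 0.0))
    rng = np.random.default_rng(spec.seed)
    noisy = clean + rng.normal(0.0, spec.noise_sd_pct, size=t.shape) if spec.noise_sd_pct else clean
    return DissolutionCurve(
        drug_id=spec.drug_id, medium=spec.medium, times=t,
        values=np.clip(noisy, 0.0, 110.0),
    )


def generate_pk_curve(spec: SyntheticPKSpec) -> PlasmaCurve:
    """Compartment-model concentrations plus seeded Gaussian noise, floored at 0."""
    t = np.asarray(spec.times_h, dtype=float)
    clean = np.asarray(predict_concentration(spec.fit, t), dtype=float)
    if spec.noise_sd_frac_of_peak:
        rng = np.random.default_rng(spec.seed)
        sd = spec.noise_sd_frac_of_peak * float(clean.max())
        clean = clean + rng.normal(0.0, sd, size=t.shape)
    return PlasmaCurve(
        drug_id=spec.drug_id, times=t, concentrations=np.maximum(clean, 0.0)
    )
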