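"""Four-group interaction-risk classification.

At a given dosing interval a drug's theoretical dissolution rate Rd and
absorption fraction Ra are compared with the operating thresholds
(Th_Rd, Th_Ra), default (90, 30):

    group 1: Rd >= Th_Rd and Ra >= Th_Ra   (fast dissolution & absorption; lowest risk)
    group 2: Rd <  Th_Rd and Ra >= Th_Ra
    group 3: Rd >= Th_Rd and Ra <  Th_Ra   (dissolved but unabsorbed drug meets the adsorbent)
    group 4: Rd <  Th_Rd and Ra <  Th_Ra   (highest risk)

Because Rd and Ra are non-decreasing in the interval, group-1 membership
is upward-closed: once a drug reaches group 1, every longer interval keeps
it there, which is what makes "minimum interval to a target group" well
defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .absorption import absorption_fraction
from .dissolution import DissolutionFit, dissolution_rate
from .errors import ExcludedDrugError, InputDataError
from .thresholds import ThresholdRegion

DEFAULT_TH_RD = 90.0
DEFAULT_TH_RA = 30.0
DEFAULT_INTERVALS = (1, 30, 60, 90, 120, 240)  # minutes; 1 = simultaneous


@dataclass(frozen=True)
class DrugPKProfile:
    """The rate-constant summary a drug needs for interaction prediction."""

    drug_id: str
    kd: float  # s^-1, governing medium
    tlagd: float  # h
    dissolution_complete: bool
    ka: float  # h^-1
    tlaga: float  # h

    def __post_init__(self):
        if not (self.kd > 0 and self.ka > 0):
            raise InputDataError("kd and ka must be positive")
        if self.tlagd < 0 or self.tlaga < 0:
            raise InputDataError("lag times must be non-negative")


@dataclass(frozen=True)
class RiskAssignment:
    """Classification of one drug at one dosing interval."""

    drug_id: str
    interval_min: int
    rd: float
    ra: float
    group: int


def classify(
    rd: float, ra: float, th_rd: float = DEFAULT_TH_RD, th_ra: float = DEFAULT_TH_RA
) -> int:
    """Quadrant group of an (Rd, Ra) point; equality on the >= side."""
    for name, x in (("Rd", rd), ("Ra", ra), ("Th_Rd", th_rd), ("Th_Ra", th_ra)):
        if not 0 <= x <= 100:
            raise InputDataError(f"{name} must lie in [0, 100], got {x}")
    if rd >= th_rd:
        return 1 if ra >= th_ra else 3
    return 2 if ra >= th_ra else 4


def profile_rates(profile: DrugPKProfile, interval_min: float) -> tuple[float, float]:
    """(Rd, Ra) of a drug at one dosing interval (minutes)."""
    if not profile.dissolution_complete:
        raise ExcludedDrugError(
            f"{profile.drug_id}: incomplete dissolution; cannot be scored"
        )
    fit = DissolutionFit(
        kd=profile.kd, tlagd=profile.tlagd, xe=100.0, rss=0.0,
        complete=True, medium="pH1.2", drug_id=profile.drug_id,
    )
    rd = dissolution_rate(fit, interval_min)
    ra = absorption_fraction(profile.ka, profile.tlaga, interval_min)
    return rd, ra


def classify_profile(
    profile: DrugPKProfile,
    intervals=DEFAULT_INTERVALS,
    th_rd: float = DEFAULT_TH_RD,
    th_ra: float = DEFAULT_TH_RA,
    region: ThresholdRegion | None = None,
) -> list[RiskAssignment]:
    """Classify a drug at each dosing interval.

    When an optimal threshold region is supplied and the operating point
    lies outside it, a warning is issued (the classification still runs).
    """
    if region is not None and not region.contains(th_rd, th_ra):
        warnings.warn(
            f"operating point ({th_rd}, {th_ra}) lies outside the optimal "
            "threshold region",
            stacklevel=2,
        )
    out = []
    for interval in intervals:
        if interval <= 0:
            raise InputDataError("intervals must be positive minutes")
        rd, ra = profile_rates(profile, interval)
        out.append(
            RiskAssignment(
                drug_id=profile.drug_id, interval_min=int(interval),
                rd=rd, ra=ra, group=classify(rd, ra, th_rd, th_ra),
            )
        )
    return out


def min_interval_to_group(
    profile: DrugPKProfile,
    target: int,
    candidates=DEFAULT_INTERVALS,
    th_rd: float = DEFAULT_TH_RD,
    th_ra: float = DEFAULT_TH_RA,
) -> int | None:
    """Smallest candidate interval whose group is within the target risk.

    ``target=1`` requires group 1; ``target=2`` accepts groups 1 and 2.
    Returns None when no candidate qualifies.
    """
    if target not in (1, 2):
        raise InputDataError("target must be 1 or 2")
    candidates = list(candidates)
    if any(b <= a for a, b in zip(candidates, candidates[1:])):
        raise InputDataError("candidate intervals must be ascending")
    acceptable = {1} if target == 1 else {1, 2}
    for assignment in classify_profile(profile, candidates, th_rd, th_ra):
        if assignment.group in acceptable:
            return assignment.interval_min
    return None


def group_counts(assignments) -> dict[int, dict[int, int]]:
    """Per-interval counts of drugs in each group (zeros filled in)."""
    out: dict[int, dict[int, int]] = {}
    for a in assignments:
        per = out.setdefault(a.interval_min, {1: 0, 2: 0, 3: 0, 4: 0})
        per[a.group] += 1
    return out
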