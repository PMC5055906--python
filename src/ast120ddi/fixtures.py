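"""Bundled reference data: six drugs with published interaction studies.

The six drugs (amlodipine, the Bufferin combination tablet, losartan,
metoprolol extended-release, nifedipine, triazolam) are the ones whose
interaction with the adsorbent has been measured in healthy-subject
crossover studies, giving fourteen (drug, dosing-interval) outcomes
labelled E (equivalent exposure) or NE (non-equivalent).  Their published
rate constants and the tabulated Rd/Ra values at the studied intervals are
transcribed here at the printed precision; the threshold optimization
operates on these printed values.
"""

from __future__ import annotations

from dataclasses import dataclass

from .risk import DrugPKProfile
from .thresholds import InteractionResult

#: dissolution rate constants per medium, s^-1 (both fluids reached
#: complete dissolution for all six drugs; the larger value governs)
DISSOLUTION_RATE_CONSTANTS: dict[str, dict[str, float]] = {
    "amlodipine": {"pH1.2": 25.54e-4, "pH6.8": 3.99e-4},
    "bufferin": {"pH1.2": 11.00e-4, "pH6.8": 27.64e-4},
    "losartan": {"pH1.2": 0.6e-4, "pH6.8": 10.5e-4},
    "metoprolol_er": {"pH1.2": 1.03e-4, "pH6.8": 0.76e-4},
    "nifedipine": {"pH1.2": 17.59e-4, "pH6.8": 11.58e-4},
    "triazolam": {"pH1.2": 14.69e-4, "pH6.8": 11.08e-4},
}

# drug_id -> (tlagd_h, ka_per_h, tlaga_h)
_ABSORPTION = {
    "amlodipine": (0.00, 0.62, 0.00),
    "bufferin": (0.00, 1.55, 0.00),
    "losartan": (0.00, 1.43, 0.33),
    "metoprolol_er": (0.00, 0.11, 0.00),
    "nifedipine": (0.00, 2.49, 0.28),
    "triazolam": (0.00, 17.34, 0.44),
}

# (drug_id, interval_min, rd_pct, ra_pct, observed) — printed values;
# interval 1 encodes simultaneous administration
_RESULTS = [
    ("amlodipine", 1, 14.2, 1.0, "NE"),
    ("amlodipine", 30, 99.0, 26.8, "NE"),
    ("amlodipine", 90, 100.0, 60.8, "E"),
    ("amlodipine", 240, 100.0, 91.8, "E"),
    ("bufferin", 1, 15.3, 2.6, "NE"),
    ("bufferin", 60, 100.0, 78.8, "E"),
    ("losartan", 30, 84.8, 21.7, "NE"),
    ("losartan", 60, 97.7, 61.6, "E"),
    ("metoprolol_er", 1, 0.6, 0.2, "NE"),
    ("metoprolol_er", 60, 30.9, 10.7, "NE"),
    ("nifedipine", 1, 10.0, 0.0, "E"),
    ("nifedipine", 30, 95.8, 41.6, "E"),
    ("nifedipine", 120, 99.8, 98.6, "E"),
    ("triazolam", 1, 8.4, 0.0, "NE"),
]


@dataclass(frozen=True)
class FixtureSet:
    """The bundled reference drugs and interaction-study outcomes."""

    profiles: tuple[DrugPKProfile, ...]
    results: tuple[InteractionResult, ...]

    def profile(self, drug_id: str) -> DrugPKProfile:
        for p in self.profiles:
            if p.drug_id == drug_id:
                return p
        raise KeyError(drug_id)


def load_fixtures() -> FixtureSet:
    """Six drug profiles and fourteen interaction-study results."""
    profiles = tuple(
        DrugPKProfile(
            drug_id=drug,
            kd=max(kds.values()),
            tlagd=_ABSORPTION[drug][0],
            dissolution_complete=True,
            ka=_ABSORPTION[drug][1],
            tlaga=_ABSORPTION[drug][2],
        )
        for drug, kds in DISSOLUTION_RATE_CONSTANTS.items()
    )
    results = tuple(
        InteractionResult(drug_id=d, interval_min=i, rd=rd, ra=ra, observed=obs)
        for d, i, rd, ra, obs in _RESULTS
    )
    return FixtureSet(profiles=profiles, results=results)
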