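"""CSV readers and writers for the documented table schemas.

All tables are comma-separated with a header row, UTF-8, "." decimals.
Dosing intervals are integer minutes; the string ``simultaneous`` is
accepted on input as an alias for 1.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .absorption import PKFit, PlasmaCurve
from .dissolution import DissolutionCurve, DissolutionFit
from .errors import InputDataError
from .risk import DrugPKProfile, RiskAssignment
from .thresholds import InteractionResult, ThresholdRegion


def _read_csv(path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InputDataError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = required - set(df.columns)
    if missing:
        raise InputDataError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_dissolution_csv(path) -> list[DissolutionCurve]:
    """`drug_id, medium, time_min, dissolved_pct` -> one curve per (drug, medium)."""
    df = _read_csv(path, {"drug_id", "medium", "time_min", "dissolved_pct"})
    curves = []
    for (drug, medium), grp in df.groupby(["drug_id", "medium"], sort=True):
        grp = grp.sort_values("time_min")
        curves.append(
            DissolutionCurve(
                drug_id=str(drug), medium=str(medium),
                times=grp["time_min"].to_numpy(float),
                values=grp["dissolved_pct"].to_numpy(float),
            )
        )
    return curves


def read_pk_csv(path) -> list[PlasmaCurve]:
    """`drug_id, time_h, conc` -> one plasma curve per drug."""
    df = _read_csv(path, {"drug_id", "time_h", "conc"})
    curves = []
    for drug, grp in df.groupby("drug_id", sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            PlasmaCurve(
                drug_id=str(drug),
                times=grp["time_h"].to_numpy(float),
                concentrations=grp["conc"].to_numpy(float),
            )
        )
    return curves


def _parse_interval(x) -> int:
    if isinstance(x, str) and x.strip().lower() == "simultaneous":
        return 1
    return int(x)


def read_outcomes_csv(path) -> list[dict]:
    """`drug_id, interval_min, observed[, rd_pct, ra_pct]` outcome rows.

    Rd/Ra columns are optional: when present the rows can be turned into
    :class:`InteractionResult` directly, otherwise the rates are computed
    from fitted profiles at join time.
    """
    df = _read_csv(path, {"drug_id", "interval_min", "observed"})
    rows = []
    for _, r in df.iterrows():
        row = {
            "drug_id": str(r["drug_id"]),
            "interval_min": _parse_interval(r["interval_min"]),
            "observed": str(r["observed"]).strip(),
        }
        if row["observed"] not in ("E", "NE"):
            raise InputDataError(
                f"{path}: observed must be E or NE, got {row['observed']!r} "
                f"for {row['drug_id']}"
            )
        for col, key in (("rd_pct", "rd"), ("ra_pct", "ra")):
            if col in df.columns and pd.notna(r[col]):
                row[key] = float(r[col])
        rows.append(row)
    return rows


def outcomes_to_results(rows: list[dict]) -> list[InteractionResult]:
    """Build results from outcome rows that already carry Rd/Ra columns."""
    try:
        return [
            InteractionResult(
                drug_id=r["drug_id"], interval_min=r["interval_min"],
                rd=r["rd"], ra=r["ra"], observed=r["observed"],
            )
            for r in rows
        ]
    except KeyError as exc:
        raise InputDataError(
            "outcome rows lack rd_pct/ra_pct columns; join them against "
            "fitted profiles instead"
        ) from exc


def read_profiles_csv(path) -> list[DrugPKProfile]:
    """`drug_id, kd_per_s, tlagd_h, ka_per_h, tlaga_h, dissolution_complete`."""
    df = _read_csv(
        path,
        {"drug_id", "kd_per_s", "tlagd_h", "ka_per_h", "tlaga_h", "dissolution_complete"},
    )
    return [
        DrugPKProfile(
            drug_id=str(r["drug_id"]), kd=float(r["kd_per_s"]),
            tlagd=float(r["tlagd_h"]),
            dissolution_complete=_parse_bool(r["dissolution_complete"]),
            ka=float(r["ka_per_h"]), tlaga=float(r["tlaga_h"]),
        )
        for _, r in df.iterrows()
    ]


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise InputDataError(f"cannot parse boolean value {x!r}")


def write_profiles_csv(profiles: list[DrugPKProfile], path) -> None:
    pd.DataFrame(
        [
            {
                "drug_id": p.drug_id, "kd_per_s": p.kd, "tlagd_h": p.tlagd,
                "ka_per_h": p.ka, "tlaga_h": p.tlaga,
                "dissolution_complete": p.dissolution_complete,
            }
            for p in profiles
        ]
    ).to_csv(path, index=False)


def write_outcomes_csv(results: list[InteractionResult], path) -> None:
    pd.DataFrame(
        [
            {
                "drug_id": r.drug_id, "interval_min": r.interval_min,
                "rd_pct": r.rd, "ra_pct": r.ra, "observed": r.observed,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def write_dissolution_fits_csv(
    fits: list[DissolutionFit], selected: set[tuple[str, str]], path
) -> None:
    """`selected` holds the (drug_id, medium) pairs chosen to govern prediction."""
    pd.DataFrame(
        [
            {
                "drug_id": f.drug_id, "medium": f.medium, "kd_per_s": f.kd,
                "tlagd_h": f.tlagd, "xe_pct": f.xe, "rss": f.rss,
                "complete": f.complete,
                "selected": (f.drug_id, f.medium) in selected,
            }
            for f in fits
        ]
    ).to_csv(path, index=False)


def write_pk_fits_csv(fits: list[PKFit], path) -> None:
    rows = []
    for f in fits:
        row = {
            "drug_id": f.drug_id, "model_order": f.model_order,
            "ka_per_h": f.ka, "tlaga_h": f.tlaga,
            "ke_per_h": f.disposition[0] if f.model_order == 1 else "",
            "alpha_per_h": f.disposition[0] if f.model_order == 2 else "",
            "beta_per_h": f.disposition[1] if f.model_order == 2 else "",
            "alpha_fraction": f.disposition[2] if f.model_order == 2 else "",
            "scale": f.scale, "rss": f.rss, "aic": f.aic,
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_risk_csv(assignments: list[RiskAssignment], path) -> None:
    pd.DataFrame(
        [
            {
                "drug_id": a.drug_id, "interval_min": a.interval_min,
                "rd_pct": round(a.rd, 1), "ra_pct": round(a.ra, 1),
                "group": a.group,
            }
            for a in assignments
        ]
    ).to_csv(path, index=False)


def write_region_json(region: ThresholdRegion, path, extra: dict | None = None) -> None:
    doc = region.to_dict()
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def write_surface_csv(rd_grid, ra_grid, matrix, path) -> None:
    """Matrix export for threshold-landscape plots: rows Rdth, columns Rath."""
    df = pd.DataFrame(matrix, index=list(rd_grid), columns=list(ra_grid))
    df.index.name = "rdth_pct"
    df.to_csv(path)
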