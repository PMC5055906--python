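"""End-to-end run: fit curves, score thresholds, classify risk, write reports.

Given raw dissolution and plasma-concentration tables (and optionally an
interaction-study outcome table), the pipeline fits every curve, selects
the governing dissolution medium and the better compartment model per
drug, computes Rd/Ra at the configured dosing intervals, classifies each
drug into the four risk groups, and — when outcomes are supplied — joins
them against the computed rates to optimize the equivalence thresholds.

Outputs are deterministic given identical inputs and configuration: files
carry no timestamps and all tables are sorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import io as tables
from .absorption import fit_pk, select_model
from .dissolution import fit_dissolution, select_medium_fit
from .errors import ExcludedDrugError, FitConvergenceError, InputDataError
from .risk import (
    DEFAULT_INTERVALS,
    DEFAULT_TH_RA,
    DEFAULT_TH_RD,
    DrugPKProfile,
    classify_profile,
)
from .thresholds import InteractionResult, optimal_region, predictive_value


@dataclass(frozen=True)
class PipelineConfig:
    th_rd: float = DEFAULT_TH_RD
    th_ra: float = DEFAULT_TH_RA
    intervals: tuple = DEFAULT_INTERVALS
    seed: int = 0  # threaded to any synthetic-data steps; fits are deterministic


@dataclass
class PipelineReport:
    profiles: list[DrugPKProfile]
    assignments: list
    excluded: list[str]
    region: object | None
    operating_predictive_value: float | None
    log: list[str] = field(default_factory=list)


def run_pipeline(
    dissolution_csv,
    pk_csv,
    outcomes_csv=None,
    config: PipelineConfig = PipelineConfig(),
    out_dir=None,
) -> PipelineReport:
    log: list[str] = []

    # --- dissolution fits, medium selection ---------------------------------
    curves = tables.read_dissolution_csv(dissolution_csv)
    by_drug: dict[str, dict[str, object]] = {}
    all_fits = []
    for curve in curves:
        fit = fit_dissolution(curve)
        all_fits.append(fit)
        by_drug.setdefault(curve.drug_id, {})[curve.medium] = fit
        log.append(
            f"dissolution fit {curve.drug_id} {curve.medium}: "
            f"kd={fit.kd:.6e}/s tlagd={fit.tlagd:.4f}h xe={fit.xe:.2f}% "
            f"rss={fit.rss:.4f} complete={fit.complete}"
        )

    selected: dict[str, object] = {}
    excluded: list[str] = []
    for drug in sorted(by_drug):
        fits = by_drug[drug]
        try:
            sel = select_medium_fit(fits.get("pH1.2"), fits.get("pH6.8"))
        except ExcludedDrugError:
            excluded.append(drug)
            log.append(f"excluded {drug}: complete dissolution in neither fluid")
            continue
        selected[drug] = sel
        log.append(f"selected medium for {drug}: {sel.medium} (kd={sel.kd:.6e}/s)")

    # --- pharmacokinetic fits, model selection ------------------------------
    pk_fits: dict[str, object] = {}
    for curve in tables.read_pk_csv(pk_csv):
        fit1 = fit_pk(curve, 1)
        if len(curve.times) >= 6:
            try:
                fit2 = fit_pk(curve, 2)
            except FitConvergenceError:
                # over-parameterized on mono-exponential disposition data
                fit2 = None
            if fit2 is not None:
                best = select_model(fit1, fit2)
                log.append(
                    f"model selection {curve.drug_id}: AICc 1-cpt={fit1.aic:.2f} "
                    f"2-cpt={fit2.aic:.2f} -> order {best.model_order}"
                )
            else:
                best = fit1
                log.append(
                    f"model selection {curve.drug_id}: 2-cpt did not converge; "
                    "order 1 kept"
                )
        else:
            best = fit1
            log.append(f"model selection {curve.drug_id}: only 1-cpt (few points)")
        if best.tlaga_raw < 0:
            log.append(
                f"clamp {curve.drug_id}: fitted Tlaga {best.tlaga_raw:.4f}h -> 0"
            )
        pk_fits[curve.drug_id] = best

    # --- profiles, classification -------------------------------------------
    profiles = []
    for drug in sorted(selected):
        if drug not in pk_fits:
            log.append(f"skipped {drug}: no plasma curve supplied")
            continue
        sel, pk = selected[drug], pk_fits[drug]
        profiles.append(
            DrugPKProfile(
                drug_id=drug, kd=sel.kd, tlagd=sel.tlagd,
                dissolution_complete=True, ka=pk.ka, tlaga=pk.tlaga,
            )
        )

    assignments = []
    for profile in profiles:
        assignments.extend(
            classify_profile(profile, config.intervals, config.th_rd, config.th_ra)
        )

    # --- threshold optimization against supplied outcomes -------------------
    region = None
    op_pv = None
    if outcomes_csv is not None:
        rows = tables.read_outcomes_csv(outcomes_csv)
        if rows:
            from .risk import profile_rates

            by_id = {p.drug_id: p for p in profiles}
            missing = [
                f"{r['drug_id']}@{r['interval_min']}min"
                for r in rows
                if r["drug_id"] not in by_id
            ]
            if missing:
                raise InputDataError(
                    "outcome rows without fitted profiles: " + ", ".join(missing)
                )
            results = []
            for r in rows:
                if "rd" in r and "ra" in r:
                    rd, ra = r["rd"], r["ra"]
                else:
                    rd, ra = profile_rates(by_id[r["drug_id"]], r["interval_min"])
                results.append(
                    InteractionResult(
                        drug_id=r["drug_id"], interval_min=r["interval_min"],
                        rd=rd, ra=ra, observed=r["observed"],
                    )
                )
            region = optimal_region(results)
            op_pv = predictive_value(results, config.th_rd, config.th_ra)
            log.append(
                f"threshold optimization: max predictive value "
                f"{region.max_predictive_value:.1f}% "
                f"({region.n_consistent}/{region.n_results}); operating point "
                f"({config.th_rd}, {config.th_ra}) -> {op_pv:.1f}%"
            )
        else:
            log.append("outcomes file empty: classification-only run")

    report = PipelineReport(
        profiles=profiles, assignments=assignments, excluded=excluded,
        region=region, operating_predictive_value=op_pv, log=log,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sel_keys = {(f.drug_id, f.medium) for f in selected.values()}
        tables.write_dissolution_fits_csv(
            sorted(all_fits, key=lambda f: (f.drug_id, f.medium)),
            sel_keys, out / "dissolution_fits.csv",
        )
        tables.write_pk_fits_csv(
            [pk_fits[d] for d in sorted(pk_fits)], out / "pk_fits.csv"
        )
        tables.write_risk_csv(assignments, out / "risk.csv")
        if region is not None:
            tables.write_region_json(
                region, out / "region.json",
                extra={
                    "operating_point": [config.th_rd, config.th_ra],
                    "operating_predictive_value_pct": round(op_pv, 1),
                },
            )
        (out / "report.log").write_text("\n".join(log) + "\n")

    return report
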