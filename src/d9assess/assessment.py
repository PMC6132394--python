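"""Assessment engine: per-series trend, endpoints and threshold compliance.

For every site x species x tissue x analyte series the engine reports the
sampling span, the linear-trend endpoints (calculated trend-line value in
the last year alongside the measured one), the trend significance, and
compliance flags of both last-year values against every applicable
regulatory threshold — uncorrected and, for mussel soft-body pools with a
known breathing-water share, corrected for breathing-water dilution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .conversions import BasisContext, apply_matrix_correction, breathing_water_factor
from .datamodel import SampleRecord, TimeSeries, build_time_series
from .errors import D9Error, InsufficientDataError
from .thresholds import ComplianceFlag, ThresholdRegistry, check_compliance
from .trend import (
    LinearTrendResult,
    TrendTestResult,
    linear_trend,
    trend_anova,
)

#: (species, tissue) -> threshold matrix class
DEFAULT_MATRIX_MAP = {
    ("Mytilus edulis", "soft body"): "bivalve",
    ("Zoarces viviparus", "fillet"): "fish_muscle",
}

#: breathing-water correction applies to these matrices only
_BREATHING_WATER_TISSUES = {("Mytilus edulis", "soft body")}


@dataclass
class AssessmentConfig:
    alpha: float = 0.05
    window_years: float = 7.0
    divergence_factor: float = 2.0     # flag calc vs measured differing by >= this
    bound: str = "upper"               # censoring convention carried in notes
    censored_substitution: str = "loq"
    matrix_map: dict = field(default_factory=lambda: dict(DEFAULT_MATRIX_MAP))


@dataclass
class ComplianceEntry:
    """One threshold comparison within an assessment row."""

    kind: str
    threshold_value: float
    threshold_unit: str
    threshold_basis: str
    protection_goal: Optional[str]
    which: str        # "measured" | "calculated"
    corrected: bool   # breathing-water corrected value?
    flag: ComplianceFlag


@dataclass
class AssessmentRow:
    site: str
    species: str
    tissue: str
    analyte: str
    unit: str
    basis: str
    n: int
    year_first: int
    year_last: int
    trend: Optional[TrendTestResult]
    linear: Optional[LinearTrendResult]
    value_last_measured: Optional[float]
    value_last_calculated: Optional[float]  # None when trend line < 0 ("not detected")
    breathing_water_factor: Optional[float]
    corrected_last_measured: Optional[float]
    corrected_last_calculated: Optional[float]
    divergence_flag: bool
    compliance: list[ComplianceEntry]
    notes: list[str]
    error: Optional[str] = None


def _compliance_entries(
    value: float,
    which: str,
    corrected: bool,
    series: TimeSeries,
    specs,
    context: BasisContext,
) -> list[ComplianceEntry]:
    out = []
    for spec in specs:
        flag = check_compliance(value, series.key.unit, series.key.basis, spec, context)
        out.append(
            ComplianceEntry(
                kind=spec.kind,
                threshold_value=spec.value,
                threshold_unit=spec.unit,
                threshold_basis=spec.basis,
                protection_goal=spec.protection_goal,
                which=which,
                corrected=corrected,
                flag=flag,
            )
        )
    return out


def assess_series(
    series: TimeSeries,
    context: BasisContext,
    registry: ThresholdRegistry,
    config: Optional[AssessmentConfig] = None,
) -> AssessmentRow:
    """Assess one monitoring series: trend, endpoints, compliance."""
    config = config or AssessmentConfig()
    key = series.key
    notes: list[str] = [f"censored values at {config.censored_substitution} (bound={config.bound})"]

    lin: Optional[LinearTrendResult] = None
    trend_res: Optional[TrendTestResult] = None
    try:
        lin = linear_trend(series, censored_substitution=config.censored_substitution)
    except InsufficientDataError as exc:
        notes.append(f"linear trend skipped: {exc}")
    if len(series) >= 7:
        trend_res = trend_anova(
            series,
            window_years=config.window_years,
            alpha=config.alpha,
            censored_substitution=config.censored_substitution,
        )
    else:
        notes.append("trend ANOVA skipped: fewer than 7 annual pools")

    measured_last = series.values[-1]
    calc_last: Optional[float] = None
    divergence = False
    if lin is not None:
        if lin.last_year_status == "value":
            calc_last = lin.calc_last
            if lin.calc_vs_measured_factor is not None and (
                lin.calc_vs_measured_factor >= config.divergence_factor
            ):
                divergence = True
                notes.append(
                    f"trend-line vs measured last-year values differ by factor "
                    f"{lin.calc_vs_measured_factor:.2f}; assess the measured value too"
                )
        else:
            notes.append("trend-line value in last year < 0: reported as not detected")

    bw_factor: Optional[float] = None
    corr_meas: Optional[float] = None
    corr_calc: Optional[float] = None
    if (key.species, key.tissue) in _BREATHING_WATER_TISSUES and (
        context.breathing_water_fraction is not None
    ):
        bw_factor = breathing_water_factor(context.breathing_water_fraction)
        corr_meas = apply_matrix_correction(measured_last, bw_factor)
        if calc_last is not None:
            corr_calc = apply_matrix_correction(calc_last, bw_factor)
        notes.append(
            f"breathing-water correction x{bw_factor:.4g} "
            f"(b={context.breathing_water_fraction:g})"
        )

    matrix_class = config.matrix_map.get((key.species, key.tissue))
    specs = registry.applicable(key.analyte, matrix_class) if matrix_class else []
    if not specs:
        notes.append("no applicable threshold registered")

    compliance: list[ComplianceEntry] = []
    compliance += _compliance_entries(measured_last, "measured", False, series, specs, context)
    if calc_last is not None:
        compliance += _compliance_entries(calc_last, "calculated", False, series, specs, context)
    if corr_meas is not None:
        compliance += _compliance_entries(corr_meas, "measured", True, series, specs, context)
    if corr_calc is not None:
        compliance += _compliance_entries(corr_calc, "calculated", True, series, specs, context)

    return AssessmentRow(
        site=key.site,
        species=key.species,
        tissue=key.tissue,
        analyte=key.analyte,
        unit=key.unit,
        basis=key.basis,
        n=len(series),
        year_first=series.years[0],
        year_last=series.years[-1],
        trend=trend_res,
        linear=lin,
        value_last_measured=measured_last,
        value_last_calculated=calc_last,
        breathing_water_factor=bw_factor,
        corrected_last_measured=corr_meas,
        corrected_last_calculated=corr_calc,
        divergence_flag=divergence,
        compliance=compliance,
        notes=notes,
    )


def assess_collection(
    records: Sequence[SampleRecord],
    contexts: dict[str, BasisContext],
    registry: ThresholdRegistry,
    config: Optional[AssessmentConfig] = None,
) -> list[AssessmentRow]:
    """Assess every series in a record collection.

    Row order is deterministic (site, species, tissue, analyte).  Per-row
    failures are captured in the row's ``error`` field instead of aborting
    the table.
    """
    config = config or AssessmentConfig()
    rows: list[AssessmentRow] = []
    series_list = build_time_series(records)
    series_list.sort(key=lambda s: (s.key.site, s.key.species, s.key.tissue, s.key.analyte))
    for series in series_list:
        ctx = contexts.get(series.key.site, BasisContext())
        try:
            rows.append(assess_series(series, ctx, registry, config))
        except D9Error as exc:
            rows.append(
                AssessmentRow(
                    site=series.key.site,
                    species=series.key.species,
                    tissue=series.key.tissue,
                    analyte=series.key.analyte,
                    unit=series.key.unit,
                    basis=series.key.basis,
                    n=len(series),
                    year_first=series.years[0],
                    year_last=series.years[-1],
                    trend=None,
                    linear=None,
                    value_last_measured=None,
                    value_last_calculated=None,
                    breathing_water_factor=None,
                    corrected_last_measured=None,
                    corrected_last_calculated=None,
                    divergence_flag=False,
                    compliance=[],
                    notes=["not assessable"],
                    error=str(exc),
                )
            )
    return rows


def _worst_status(row: AssessmentRow, which: str, corrected: bool) -> str:
    entries = [e for e in row.compliance if e.which == which and e.corrected == corrected]
    if not entries:
        return ""
    statuses = [e.flag.status for e in entries]
    if "exceedance" in statuses:
        return "exceedance"
    if all(s == "not_assessable" for s in statuses):
        return "not_assessable"
    return "compliant"


def rows_to_frame(rows: Sequence[AssessmentRow]) -> pd.DataFrame:
    """Flatten assessment rows into the summary table (one line per series)."""
    recs = []
    for r in rows:
        recs.append(
            {
                "site": r.site,
                "species": r.species,
                "tissue": r.tissue,
                "analyte": r.analyte,
                "unit": r.unit,
                "basis": r.basis,
                "n": r.n,
                "year_first": r.year_first,
                "year_last": r.year_last,
                "p_linear": None if r.trend is None else r.trend.p_linear,
                "p_nonlinear": None if r.trend is None else r.trend.p_nonlinear,
                "overall_trend": "" if r.trend is None else r.trend.overall_trend,
                "slope": None if r.linear is None else r.linear.slope,
                "percent_change": None if r.linear is None else r.linear.percent_change,
                "last_measured": r.value_last_measured,
                "last_calculated": (
                    "not_detected" if (r.linear is not None and r.value_last_calculated is None)
                    else r.value_last_calculated
                ),
                "bw_factor": r.breathing_water_factor,
                "last_measured_corrected": r.corrected_last_measured,
                "divergence_flag": r.divergence_flag,
                "status_measured": _worst_status(r, "measured", False),
                "status_measured_corrected": _worst_status(r, "measured", True),
                "status_calculated": _worst_status(r, "calculated", False),
                "error": r.error or "",
            }
        )
    return pd.DataFrame.from_records(recs)
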