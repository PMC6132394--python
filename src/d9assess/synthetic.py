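"""Seeded generators for synthetic monitoring series and congener panels.

The generators emulate the statistical structure of annual pooled biota
monitoring: one value per site x species x analyte x year over one to three
decades, exponential decline (or a hump-shaped excursion) in the mean,
multiplicative lognormal noise and left-censoring at a limit of
quantification.  They also ship a demo dataset mirroring a three-site
mussel + eelpout monitoring design, so the full assessment pipeline runs
without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .conversions import BasisContext
from .datamodel import SampleRecord
from .errors import ValidationError
from .teq import CongenerMeasurement, TEFTable


# ---------------------------------------------------------------------------
# concentration series


@dataclass(frozen=True)
class SeriesGenSpec:
    """Recipe for one synthetic monitoring series.

    The mean follows c(t) = c0 * exp(-k t) plus an optional symmetric hump
    (zero at both ends, peaking mid-series) of height ``nonlinear_amplitude``;
    observations are c(t) times a mean-one lognormal with coefficient of
    variation ``noise_cv``; values falling below ``loq`` are emitted at the
    LOQ with the censoring flag set.
    """

    year_start: int
    year_end: int
    c0: float
    decline_rate: float = 0.0
    nonlinear_amplitude: float = 0.0
    noise_cv: float = 0.0
    loq: float = 0.0
    sampling_interval: int = 1
    seed: int = 0
    site: str = "SYN"
    species: str = "Mytilus edulis"
    tissue: str = "soft body"
    analyte: str = "X"
    unit: str = "µg/kg"
    basis: str = "wet"

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValidationError("c0 must be > 0")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.year_end < self.year_start:
            raise ValidationError("year_end before year_start")
        if self.sampling_interval not in (1, 2):
            raise ValidationError("sampling_interval must be 1 or 2")

    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1, self.sampling_interval)

    def mean_curve(self, years: Optional[np.ndarray] = None) -> np.ndarray:
        """Noise-free mean concentration at each sampling year."""
        if years is None:
            years = self.years()
        t = np.asarray(years, dtype=float) - self.year_start
        span = max(self.year_end - self.year_start, 1)
        s = t / span
        hump = self.nonlinear_amplitude * 4.0 * s * (1.0 - s)
        return self.c0 * np.exp(-self.decline_rate * t) + hump


@dataclass
class SeriesTruth:
    """Generator-side ground truth for one simulated series."""

    years: np.ndarray
    mean: np.ndarray
    true_values: np.ndarray   # noisy values before censoring
    n_censored: int


def lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    mu = -sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def simulate_series(spec: SeriesGenSpec) -> tuple[list[SampleRecord], SeriesTruth]:
    """Simulate one annual-pool series; returns records plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    years = spec.years()
    mean = spec.mean_curve(years)
    noisy = mean * lognormal_noise(rng, spec.noise_cv, len(years))
    censored = noisy < spec.loq
    emitted = np.where(censored, spec.loq, noisy)
    records = [
        SampleRecord(
            site=spec.site,
            species=spec.species,
            tissue=spec.tissue,
            year=int(y),
            analyte=spec.analyte,
            value=float(v),
            unit=spec.unit,
            basis=spec.basis,
            censored=bool(c),
        )
        for y, v, c in zip(years, emitted, censored)
    ]
    truth = SeriesTruth(
        years=years, mean=mean, true_values=noisy, n_censored=int(censored.sum())
    )
    return records, truth


# ---------------------------------------------------------------------------
# congener panels


@dataclass
class PanelTruth:
    """Generator-side bookkeeping of the expected TEQ of a panel,
    computed by direct summation independent of the aggregation code."""

    teq_upper: float
    teq_middle: float
    teq_lower: float
    n_censored: int


def simulate_congener_panel(
    n_congeners: int = 29,
    censor_prob: float = 0.3,
    seed: int = 0,
    tefs: Optional[TEFTable] = None,
    scale_pg_g: float = 0.1,
) -> tuple[list[CongenerMeasurement], PanelTruth]:
    """Simulate a censored congener panel drawn from the TEF table.

    Concentrations are lognormal around ``scale_pg_g``; each congener is
    independently censored with probability ``censor_prob``, in which case
    its recorded value is a drawn LOQ.  Ground-truth upper/middle/lower TEQs
    are accumulated term by term while generating.
    """
    if tefs is None:
        tefs = TEFTable.who2005()
    ids = tefs.congener_ids()
    if not (1 <= n_congeners <= len(ids)):
        raise ValidationError(f"n_congeners must be in [1, {len(ids)}]")
    rng = np.random.default_rng(seed)
    panel: list[CongenerMeasurement] = []
    up = mid = low = 0.0
    n_cens = 0
    for cid in ids[:n_congeners]:
        conc = float(rng.lognormal(mean=math.log(scale_pg_g), sigma=1.0))
        censored = bool(rng.random() < censor_prob)
        if censored:
            loq = float(rng.uniform(0.5, 1.5) * scale_pg_g)
            panel.append(CongenerMeasurement(cid, loq, censored=True))
            tef = tefs.tef(cid)
            up += tef * loq
            mid += tef * loq / 2.0
            n_cens += 1
        else:
            panel.append(CongenerMeasurement(cid, conc, censored=False))
            tef = tefs.tef(cid)
            up += tef * conc
            mid += tef * conc
            low += tef * conc
    return panel, PanelTruth(teq_upper=up, teq_middle=mid, teq_lower=low, n_censored=n_cens)


# ---------------------------------------------------------------------------
# demo monitoring dataset (three sites, mussel + eelpout)


#: site -> matrix composition of mussel soft-body pools
DEMO_CONTEXTS = {
    "NS1": BasisContext(water_fraction=0.906, breathing_water_fraction=0.67),
    "NS2": BasisContext(water_fraction=0.926, breathing_water_fraction=0.58),
    "BS": BasisContext(water_fraction=0.947, breathing_water_fraction=0.67),
}

# analyte -> (unit, c0 scale, decline per year); magnitudes are plausible for
# coastal biota and kept below the food maximum levels, except PAH4 which
# starts high enough that its breathing-water-corrected early values exceed
# the ML, and PBDE6 which sits above its (very low) biota EQS throughout.
_MUSSEL_ANALYTES = {
    "Pb": ("mg/kg", 0.35, 0.035),
    "Cd": ("mg/kg", 0.15, 0.012),
    "Hg": ("mg/kg", 0.006, 0.015),
    "BaP": ("µg/kg", 1.2, 0.05),
    "PAH4": ("µg/kg", 22.0, 0.08),
    "TBT": ("µg/kg", 9.0, 0.12),
}
_EELPOUT_ANALYTES = {
    "Hg": ("mg/kg", 0.04, 0.01),
    "ndl-PCB6": ("µg/kg", 9.0, 0.05),
    "PFOS": ("µg/kg", 1.1, 0.03),
    "PBDE6": ("µg/kg", 0.09, 0.06),
    "HBCDD": ("µg/kg", 0.8, 0.05),
    "TEQ": ("pg/g", 0.9, 0.0),
}

_SITE_LEVEL = {"NS1": 1.0, "NS2": 0.6, "BS": 0.8}  # NS1 the most contaminated


def demo_dataset(seed: int = 0, noise_cv: float = 0.2) -> tuple[list[SampleRecord], dict]:
    """A three-site mussel + eelpout monitoring campaign.

    Mussel soft-body series run 1985-2017 annually (TBT 1988-2013);
    eelpout fillet series run 1994-2017, the organics biennially from 2003
    then annually from 2016, mirroring a retrospective-analysis design.
    Returns the records and the site -> :class:`BasisContext` table.
    """
    rng = np.random.default_rng(seed)
    records: list[SampleRecord] = []
    for si, (site, ctx) in enumerate(DEMO_CONTEXTS.items()):
        lvl = _SITE_LEVEL[site]
        for analyte, (unit, c0, k) in _MUSSEL_ANALYTES.items():
            y0, y1, interval = 1985, 2017, 1
            if analyte == "TBT":
                y0, y1 = 1988, 2013
            spec = SeriesGenSpec(
                year_start=y0,
                year_end=y1,
                c0=c0 * lvl,
                decline_rate=k,
                noise_cv=noise_cv,
                loq=c0 * lvl * 0.01,
                sampling_interval=interval,
                seed=int(rng.integers(2**31 - 1)),
                site=site,
                species="Mytilus edulis",
                tissue="soft body",
                analyte=analyte,
                unit=unit,
            )
            recs, _ = simulate_series(spec)
            records.extend(
                SampleRecord(
                    **{
                        **r.__dict__,
                        "water_fraction": ctx.water_fraction,
                        "breathing_water_fraction": ctx.breathing_water_fraction,
                    }
                )
                for r in recs
            )
        for analyte, (unit, c0, k) in _EELPOUT_ANALYTES.items():
            if analyte in ("Hg",):
                y0, y1, interval = 1994, 2017, 1
            else:
                y0, y1, interval = 2003, 2015, 2
            spec = SeriesGenSpec(
                year_start=y0,
                year_end=y1,
                c0=c0 * lvl,
                decline_rate=k,
                noise_cv=noise_cv,
                loq=c0 * lvl * 0.01,
                sampling_interval=interval,
                seed=int(rng.integers(2**31 - 1)),
                site=site,
                species="Zoarces viviparus",
                tissue="fillet",
                analyte=analyte,
                unit=unit,
            )
            recs, _ = simulate_series(spec)
            records.extend(recs)
            if interval == 2:  # recent annual follow-up years
                spec2 = SeriesGenSpec(
                    year_start=2016,
                    year_end=2017,
                    c0=c0 * lvl * math.exp(-k * (2016 - y0)),
                    decline_rate=k,
                    noise_cv=noise_cv,
                    loq=c0 * lvl * 0.01,
                    seed=int(rng.integers(2**31 - 1)),
                    site=site,
                    species="Zoarces viviparus",
                    tissue="fillet",
                    analyte=analyte,
                    unit=unit,
                )
                recs2, _ = simulate_series(spec2)
                records.extend(recs2)
    return records, dict(DEMO_CONTEXTS)


# ---------------------------------------------------------------------------
# Monte-Carlo studies of the trend machinery


def null_rejection_rate(
    n_reps: int = 2000,
    n_years: int = 15,
    noise_cv: float = 0.2,
    alpha: float = 0.05,
    window_years: float = 7.0,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the linear-component trend test.

    Series of ``n_years`` annual values with constant mean 1 and mean-one
    lognormal noise; returns the fraction of replicates with
    p_linear <= alpha.
    """
    from .trend import trend_anova_arrays

    rng = np.random.default_rng(seed)
    years = np.arange(2000.0, 2000.0 + n_years)
    noise = lognormal_noise(rng, noise_cv, (n_reps, n_years))
    rejections = 0
    for i in range(n_reps):
        res = trend_anova_arrays(years, noise[i], window_years=window_years, alpha=alpha)
        if res.p_linear <= alpha:
            rejections += 1
    return rejections / n_reps


def decline_power(
    n_reps: int = 500,
    n_years: int = 15,
    decline_per_decade: float = 0.5,
    noise_cv: float = 0.2,
    alpha: float = 0.05,
    window_years: float = 7.0,
    seed: int = 0,
) -> float:
    """Power of the linear-component test against an exponential decline.

    ``decline_per_decade`` is the fractional loss over ten years, e.g. 0.5
    for a halving per decade (decline rate k = -ln(1-0.5)/10 per year).
    """
    from .trend import trend_anova_arrays

    k = -math.log(1.0 - decline_per_decade) / 10.0
    rng = np.random.default_rng(seed)
    years = np.arange(2000.0, 2000.0 + n_years)
    mean = np.exp(-k * (years - years[0]))
    noise = lognormal_noise(rng, noise_cv, (n_reps, n_years))
    hits = 0
    for i in range(n_reps):
        res = trend_anova_arrays(years, mean * noise[i], window_years=window_years, alpha=alpha)
        if res.p_linear <= alpha and res.slope < 0:
            hits += 1
    return hits / n_reps
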