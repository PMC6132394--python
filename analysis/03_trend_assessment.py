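#!/usr/bin/env python
"""Trend-test every simulated monitoring series.

For each series with at least seven annual pools: the LOESS/ANOVA
decomposition into linear and non-linear trend components, the least-squares
trend line with its endpoints (negative endpoints reported as not detected),
and a contrast test between the first and last fitted year where the span
allows.
"""

import argparse
from pathlib import Path

import pandas as pd

from d9assess.datamodel import build_time_series, read_samples
from d9assess.trend import contrast_test, linear_trend, loess_fit, trend_anova

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--samples", default=str(RESULTS / "samples.csv"))
    args = ap.parse_args()

    records = read_samples(args.samples)
    rows = []
    for series in build_time_series(records):
        if len(series) < 7:
            continue
        res = trend_anova(series)
        lin = linear_trend(series)
        row = {
            "site": series.key.site,
            "species": series.key.species,
            "analyte": series.key.analyte,
            "n": len(series),
            "year_first": lin.year_first,
            "year_last": lin.year_last,
            "p_linear": res.p_linear,
            "p_nonlinear": res.p_nonlinear,
            "overall_trend": res.overall_trend,
            "slope": lin.slope,
            "calc_last": lin.calc_last,
            "last_year_status": lin.last_year_status,
            "percent_change": lin.percent_change,
        }
        span = lin.year_last - lin.year_first
        if span >= 7:
            c = contrast_test(loess_fit(series), lin.year_first, lin.year_last)
            row["contrast_p"] = c.p
        rows.append(row)

    df = pd.DataFrame(rows).sort_values(["site", "species", "analyte"])
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "trends.csv"
    df.to_csv(out, index=False)

    sig = df[df.overall_trend != "none"]
    print(f"{len(df)} series tested; {len(sig)} with a significant linear trend "
          f"({(sig.overall_trend == 'decreasing').sum()} decreasing, "
          f"{(sig.overall_trend == 'increasing').sum()} increasing)")
    nd = df[df.last_year_status == "not_detected"]
    if len(nd):
        print(f"{len(nd)} trend lines cross zero before the final year "
              "(endpoint reported as not detected)")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
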