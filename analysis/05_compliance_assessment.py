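#!/usr/bin/env python
"""Build the full compliance/trend assessment table.

One row per site x species x tissue x analyte: sampling span, trend
significance, measured and trend-line last-year values, breathing-water
corrected mussel values, and compliance flags against every applicable food
maximum level, biota EQS, OSPAR EAC or national standard.
"""

import argparse
from pathlib import Path

from d9assess.assessment import AssessmentConfig, assess_collection, rows_to_frame
from d9assess.cli import _load_contexts
from d9assess.datamodel import read_samples
from d9assess.thresholds import ThresholdRegistry

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--samples", default=str(RESULTS / "samples.csv"))
    args = ap.parse_args()

    records = read_samples(args.samples)
    contexts = _load_contexts(None)
    registry = ThresholdRegistry.default()
    rows = assess_collection(records, contexts, registry, AssessmentConfig())
    frame = rows_to_frame(rows)

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "assessment.csv"
    frame.to_csv(out, index=False)

    n_exc = (frame.status_measured == "exceedance").sum()
    n_exc_corr = (frame.status_measured_corrected == "exceedance").sum()
    print(f"{len(frame)} series assessed")
    print(f"measured last-year exceedances: {n_exc} "
          f"({', '.join(sorted(set(frame.loc[frame.status_measured == 'exceedance', 'analyte'])))})")
    print(f"breathing-water-corrected exceedances (mussels): {n_exc_corr}")
    div = frame[frame.divergence_flag]
    if len(div):
        print(f"{len(div)} series where trend-line and measured final values "
              "diverge by >= 2x (assess the measured value too)")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
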