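#!/usr/bin/env python
"""Aggregate censored congener panels to WHO-TEQ under all three bound
conventions.

Simulates seeded 29-congener dioxin/furan/dl-PCB panels at increasing
censoring pressure and shows how the gap between lower- and upper-bound TEQ
widens with the censored fraction — the reason assessments report the
conservative upper bound.
"""

import argparse
from pathlib import Path

import pandas as pd

from d9assess.synthetic import simulate_congener_panel
from d9assess.teq import PCDDF_CLASSES, TEFTable, compute_teq

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    tefs = TEFTable.who2005()
    rows = []
    for censor_prob in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
        panel, truth = simulate_congener_panel(
            n_congeners=29, censor_prob=censor_prob, seed=args.seed
        )
        rows.append(
            {
                "censor_prob": censor_prob,
                "n_censored": truth.n_censored,
                "teq_upper": compute_teq(panel, tefs, "upper"),
                "teq_middle": compute_teq(panel, tefs, "middle"),
                "teq_lower": compute_teq(panel, tefs, "lower"),
                "teq_pcddf_only_upper": compute_teq(
                    panel, tefs, "upper", classes=PCDDF_CLASSES
                ),
            }
        )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "teq_bounds.csv"
    df.to_csv(out, index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    spread = df.teq_upper - df.teq_lower
    print(f"\nupper-lower spread grows from {spread.iloc[0]:.4f} (censor-free) "
          f"to {spread.iloc[-1]:.4f} (fully censored) pg/g WHO-TEQ")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
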