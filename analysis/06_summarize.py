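#!/usr/bin/env python
"""Condense the grid results into the study's reporting tables.

Reads the per-replicate tables written by 04/05, recomputes the
median +/- IQR summaries per condition, and prints the trends the study is
about: parameter error and prediction accuracy as functions of SNR, SR and
TR. Writes results/summary_by_snr.csv and summary_by_condition.csv.
"""

from pathlib import Path

import pandas as pd

from gliopred.evaluate import summarize

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    source = OUT / "cohort_metrics.csv"
    if not source.exists():
        source = OUT / "central_metrics.csv"
    if not source.exists():
        raise SystemExit("run 04_central_tumor_grid.py or 05_cohort_grid.py first")
    table = pd.read_csv(source).fillna({"failure": "", "notes": ""})
    by_cond = summarize(table)
    by_cond.to_csv(OUT / "summary_by_condition.csv", index=False)

    ok = table[(table["failure"] == "") & (table["day"] == 10)]
    by_snr = ok.groupby("snr").agg(
        pe_kt_median=("pe_k_t", "median"),
        pe_Dt_median=("pe_D_t0", "median"),
        pe_Dv_median=("pe_D_v0", "median"),
        ccc_tumor_median=("ccc_tumor", "median"),
        ccc_vasc_median=("ccc_vasc", "median"),
        dice_median=("dice_tumor", "median"),
    )
    by_snr.to_csv(OUT / "summary_by_snr.csv")
    print(f"wrote {OUT / 'summary_by_condition.csv'} and summary_by_snr.csv")
    print("\nday-10 medians pooled over SR/TR, by SNR:")
    print(by_snr.round(4).to_string())


if __name__ == "__main__":
    main()
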