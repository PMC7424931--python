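#!/usr/bin/env python
"""Reliability statistics over the per-ROI agreement and density tables.

Reads the tables written by 02 and 03 and computes: Bland–Altman of each
grader's densities against the truth (log10-transformed automatically
when the raw differences fail Shapiro–Wilk normality), the ICC(2,1) of
densities across annotators with its Cicchetti band, a repeated-measures
ANOVA with Bonferroni post hoc paired t-tests over each comparison's
Dice, and the mean per-ROI density CoV.  Writes results/stats_report.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from conemosaic.pipeline import stats_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--ground-truth", default="truth")
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    rates = pd.read_csv(args.out_dir / "agreement_per_roi.csv")
    dens = pd.read_csv(args.out_dir / "density_per_roi.csv")
    report = stats_report(rates, dens, args.ground_truth, alpha=args.alpha)

    out = args.out_dir / "stats_report.json"
    out.write_text(json.dumps(report, indent=2))

    icc = report["icc"]
    print(
        f"density ICC(2,1) across annotators: {icc['icc']:.3f} "
        f"(95% CI {icc['ci_low']:.2f}–{icc['ci_high']:.2f}), {icc['band']}"
    )
    print(f"mean per-ROI density CoV: {report['density_cov_mean']:.3f}")
    for label, ba in report["bland_altman"].items():
        print(
            f"Bland–Altman truth vs {label}: transform={ba['transform']}, "
            f"bias={ba['bias']:.4g}, LoA=[{ba['loa_low']:.4g}, {ba['loa_high']:.4g}]"
        )
    anova = report.get("dice_rm_anova")
    if anova:
        print(
            f"Dice RM-ANOVA: F={anova['F']:.2f}, p={anova['p_omnibus']:.3g}; "
            "Bonferroni post hoc pairs with p<0.05: "
            + str([p["pair"] for p in anova["posthoc"] if p["p_bonferroni"] < 0.05])
        )
    print(f"report: {out}")


if __name__ == "__main__":
    main()
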