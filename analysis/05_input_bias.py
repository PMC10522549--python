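#!/usr/bin/env python
"""Arterial-input bias attribution experiment.

Low-flow MBF is proportional to myocardial uptake divided by the arterial
input, so underestimating the input inflates every estimate.  Finding: the
fraction of scans whose segmental scar flow exceeds the 0.44 mL/min/g gate
grows monotonically as the arterial input is scaled down, while the
unbiased run stays clean — the mechanism behind inter-package upward bias.
"""

import argparse
from pathlib import Path

import pandas as pd

import tmsflow as tf
from tmsflow.benchmark import BenchmarkConfig, run_benchmark

SCALES = (1.0, 0.85, 0.7, 0.6)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-phantoms", type=int, default=20)
    ap.add_argument("--out", type=Path, default=Path("results/input_bias.csv"))
    args = ap.parse_args()

    variants = tuple(
        tf.EstimatorVariant(f"scale_{s}", "retention", "la_aorta", input_scale=s)
        for s in SCALES
    )
    config = BenchmarkConfig(
        n_phantoms=args.n_phantoms, seed=args.seed, variants=variants,
        qa_enabled=False,
    )
    report = run_benchmark(config)

    rows = []
    for s in SCALES:
        summary = report.variant_summary[f"scale_{s}"]
        rows.append(
            {
                "input_scale": s,
                "seg_scar_median_rmbf": summary["seg_scar_rmbf"]["median"],
                "roi_scar_median_rmbf": summary["roi_mean_rmbf"]["median"],
                "pct_scans_seg_gate_exceed": summary["pct_scans_seg_gate_exceed"],
                "pct_scans_roi_gate_fail": summary["pct_scans_roi_gate_fail"],
            }
        )
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    print(df.round(3).to_string(index=False))
    exceed = df.pct_scans_seg_gate_exceed
    print(
        "\ngate exceedance monotone in input underestimation:",
        bool(exceed.is_monotonic_increasing),
    )
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
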