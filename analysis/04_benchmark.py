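#!/usr/bin/env python
"""The full low-flow accuracy benchmark across estimator variants.

Finding: the unbiased individualized-input retention pipeline keeps every
scan's ROI-confined scar flow under the 0.39 mL/min/g literature gate; the
Seg-Scar (segmental) average sits slightly above the ROI mean because
segments admix viable border tissue; variants that read a biased arterial
input, and the fixed-distribution-volume fit with a mismatched constant,
shift scar and normal flows upward, reproducing the upward-bias patterns
seen between clinical software packages.
"""

import argparse
from pathlib import Path

import tmsflow as tf
from tmsflow.benchmark import BenchmarkConfig, run_benchmark


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-phantoms", type=int, default=20)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    config = BenchmarkConfig(n_phantoms=args.n_phantoms, seed=args.seed)
    report = run_benchmark(config)
    args.out.mkdir(parents=True, exist_ok=True)
    report.to_json(args.out / "benchmark_report.json")
    report.to_csv(args.out / "benchmark_detail.csv")

    print(
        f"{report.n_scans_simulated} scans simulated, "
        f"{report.n_scans_excluded} excluded by the quality screen"
    )
    print(report.table())
    ref = report.variant_summary["retention_la"]
    print(
        f"\nretention (unbiased input): ROI-Scar median "
        f"{ref['roi_mean_rmbf']['median']:.2f} "
        f"[{ref['roi_mean_rmbf']['q1']:.2f}-{ref['roi_mean_rmbf']['q3']:.2f}] mL/min/g, "
        f"%RU {ref['roi_mean_ru']['median']:.0f}, "
        f"ROI gate failures {ref['pct_scans_roi_gate_fail']:.0f}% of scans"
    )
    print(f"wrote {args.out}/benchmark_report.json and benchmark_detail.csv")


if __name__ == "__main__":
    main()
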