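#!/usr/bin/env python
"""Render the per-criterion validity table and compare against expectation.

Takes the pipeline outputs from 02_run_pipeline.py plus the generator's
analytic expectations from 01_simulate.py, prints a human-readable validity
table (sensitivity, specificity, LR+, LR- with interpretation bands, "-" for
the undefined sentinels), and reports how far each estimate sits from the
value implied by the generator configuration.

Writes results/validity_report.txt.
"""

import argparse
from pathlib import Path

import pandas as pd

from sihvalid.metrics import format_lr


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--pipeline", type=Path, default=Path("results/pipeline"))
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path,
                    default=Path("results/validity_report.txt"))
    args = ap.parse_args()

    vt = pd.read_csv(args.pipeline / "validity_table.csv")
    expected = pd.read_csv(args.data / "truth_expected_metrics.csv")

    lines = []
    header = (f"{'criterion':22s} {'stratum':8s} {'n_ref+':>6s} {'sens%':>6s} "
              f"{'spec%':>6s} {'LR+':>9s} {'LR-':>6s}  bands")
    lines.append(header)
    lines.append("-" * len(header))
    for _, r in vt.iterrows():
        sens = "-" if pd.isna(r.sens_pct) else f"{r.sens_pct:.1f}"
        spec = "-" if pd.isna(r.spec_pct) else f"{r.spec_pct:.1f}"
        lines.append(
            f"{r.criterion:22s} {r.stratum:8s} {r.n_ref_pos:6d} {sens:>6s} "
            f"{spec:>6s} {format_lr(r.lr_pos, 'pos'):>9s} "
            f"{format_lr(r.lr_neg, 'neg'):>6s}  {r.band_pos or '-'}/{r.band_neg or '-'}")

    est = vt[vt.stratum.isin(("public", "private")) & (vt.n_ref_pos > 0)]
    cmp = est.merge(expected, on=["criterion", "stratum"])
    cmp["sens_gap"] = cmp.sens_pct - 100 * cmp.expected_sens
    cmp["spec_gap"] = cmp.spec_pct - 100 * cmp.expected_spec
    lines.append("")
    lines.append("estimate minus generator expectation (percentage points):")
    lines.append(f"  sensitivity: mean abs gap "
                 f"{cmp.sens_gap.abs().mean():.1f}, max {cmp.sens_gap.abs().max():.1f}")
    lines.append(f"  specificity: mean abs gap "
                 f"{cmp.spec_gap.abs().mean():.1f}, max {cmp.spec_gap.abs().max():.1f}")

    text = "\n".join(lines)
    print(text)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(text + "\n", encoding="utf-8")
    print(f"\nwritten to {args.out}")


if __name__ == "__main__":
    main()
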