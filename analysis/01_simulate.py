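#!/usr/bin/env python
"""Generate the synthetic study dataset.

Draws a reference-standard obstetric hospitalization census (50 public + 28
private hospitals, a 30-day window each) together with the paired claims
tables — the reduced one-row-per-AIH table and the professional-acts table —
under the default error processes: per-condition recording sensitivity and
false-positive rates differing by hospital type, private-sector
under-capture, public-sector over-capture, episode splitting through the
continuing-stay billing reason, and linkage-key corruption.

Writes the three tables plus the ground-truth sidecars to results/synthetic/.
"""

import argparse
from pathlib import Path

from sihvalid.simulate import SimConfig, generate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20210)
    ap.add_argument("--episodes-per-hospital", type=int, default=100)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed, n_hospitals_public=50,
                    n_hospitals_private=28,
                    episodes_per_hospital=args.episodes_per_hospital)
    sim = generate(cfg)
    args.out.mkdir(parents=True, exist_ok=True)
    sim.reference.to_csv(args.out / "reference.csv", index=False)
    sim.reduced.to_csv(args.out / "reduced.csv", index=False)
    sim.acts.to_csv(args.out / "professional_acts.csv", index=False)
    sim.truth.pairing.to_csv(args.out / "truth_pairing.csv", index=False)
    sim.truth.expected.to_csv(args.out / "truth_expected_metrics.csv", index=False)

    n_split = (sim.truth.pairing.groupby("reference_id").size() > 1).sum()
    print(f"reference census : {len(sim.reference):6d} stays "
          f"({(sim.reference.hospital_type == 'public').sum()} public, "
          f"{(sim.reference.hospital_type == 'private').sum()} private)")
    print(f"claims (reduced) : {len(sim.reduced):6d} AIH rows "
          f"({n_split} stays billed as chained AIH pairs)")
    print(f"professional acts: {len(sim.acts):6d} rows")
    print(f"expected coverage: public {sim.truth.expected_coverage['public']:.1f}%, "
          f"private {sim.truth.expected_coverage['private']:.1f}%")
    print(f"written to {args.out}/")


if __name__ == "__main__":
    main()
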