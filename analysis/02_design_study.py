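#!/usr/bin/env python
"""Clustered sampling and the blinded dual-rater assignment plan.

From the simulated classified pool (01_simulate_cohort.py), samples 160
visits evenly across the three EDAC clusters (54/53/53) and assigns each to
two distinct raters: ten first-round batches of 20 visits (composition a
permutation of 7/7/6) plus six second-round batches, i.e. six raters with 40
ratings and four with 20 — 320 ratings total.  The plan CSV carries no EDAC
class (raters stay blinded); the key file retains the class map.
"""

import argparse
import csv
from collections import Counter
from pathlib import Path

from edac.design import build_assignment, stratified_sample
from edac.io import read_class_map


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument(
        "--class-key", type=Path, default=Path("results/synthetic/class_key.csv")
    )
    parser.add_argument("--outdir", type=Path, default=Path("results/design"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    classes = read_class_map(args.class_key)
    sample = stratified_sample(classes, 160, seed=args.seed)
    raters = [f"r{i:02d}" for i in range(1, 11)]
    plan = build_assignment(
        [(v, classes[v]) for v in sample],
        raters_round1=raters,
        raters_round2=raters[:6],
        batch_size=20,
        composition=(7, 7, 6),
        seed=args.seed,
    )

    with (args.outdir / "plan.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rater_id", "visit_id", "round"])
        w.writerows(plan.assignments)

    load = Counter(r for r, _, _ in plan.assignments)
    print(
        f"{len(plan.assignments)} assignments; per-rater loads "
        f"{sorted(load.values())} -> {args.outdir / 'plan.csv'}"
    )


if __name__ == "__main__":
    main()
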