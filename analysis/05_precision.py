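#!/usr/bin/env python
"""Where does the potentially-avoidable class belong?

Rating-level accuracy/sensitivity/specificity of the EDAC under the three
regroupings of the middle class.  Merging it into the avoidable group keeps
accuracy essentially unchanged (83.2% -> 82.8%) while merging it into the
not-avoidable group collapses accuracy and sensitivity (-21.6 and -25.5
points): the middle class behaves like the avoidable one.  Writes
results/precision.json.
"""

import argparse
import json
from pathlib import Path

from edac.precision import scenario_compare
from edac.synthetic import reference_fixture


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/precision.json"))
    args = parser.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)

    block = scenario_compare(reference_fixture())
    args.out.write_text(json.dumps(block, indent=2) + "\n")

    for scen, r in block["results"].items():
        print(
            f"{scen}: accuracy {100 * r['accuracy']:.1f}% "
            f"sensitivity {100 * r['sensitivity_negative_group_ed']:.1f}% "
            f"specificity {100 * r['specificity_positive_group_subacute']:.1f}% "
            f"(n={r['n_ratings']} ratings)"
        )
    d = block["deltas_vs_baseline"]["potential_as_not_avoidable"]
    print(f"merging middle class downward: accuracy {d['accuracy_pp']:+.1f} pp, "
          f"sensitivity {d['sensitivity_pp']:+.1f} pp")
    print(f"-> {args.out}")


if __name__ == "__main__":
    main()
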