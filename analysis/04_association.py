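#!/usr/bin/env python
"""Association between the EDAC and paired physician judgements.

On the reference table the EDAC ordinal correlates with the judgement
concordance ordinal at Spearman 0.64; the odds both physicians judge a
visit subacute-suitable are 80.0 (95% CI 17.1-374.9) times higher for
EDAC-avoidable visits than for not-avoidable ones (7.1, 3.0-16.8 for the
middle class), and the class ordering discriminates outcome levels with a
concordance index of 0.84.  Writes results/association.json.
"""

import argparse
import json
from pathlib import Path

from edac.io import study_report
from edac.synthetic import reference_fixture


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/association.json"))
    args = parser.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)

    pairs = reference_fixture().to_pairs()
    block = study_report(pairs)["association"]
    args.out.write_text(json.dumps(block, indent=2) + "\n")

    print(f"Spearman rank correlation: {block['spearman']:.2f}")
    for cls, d in block["reported_or"].items():
        print(f"  OR[{cls}] = {d['or']:.1f} ({d['ci'][0]:.1f}-{d['ci'][1]:.1f})")
    fit = block["cumulative_logit"]
    print(f"proportional-odds beta: "
          f"{ {k: round(v, 3) for k, v in fit['beta'].items()} } "
          f"(loglik {fit['loglik']:.3f}, {fit['n_iter']} Newton steps)")
    print(f"c-index: {block['cindex']:.2f}")
    print(f"-> {args.out}")


if __name__ == "__main__":
    main()
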