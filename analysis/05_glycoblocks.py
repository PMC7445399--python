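#!/usr/bin/env python
"""Glycoblock decomposition and propensity predictions for all glycoforms.

Decomposes every registered glycoform into its glycoblocks, runs the
propensity rule base, and tabulates the predicted (1-6)-arm direction with
the fired rules and the reference population metadata each rule carries.
Writes results/glycoblocks_table.csv.
"""

import sys
from collections import Counter
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

from glycoarch import model  # noqa: E402
from glycoarch.blocks import compare_decompositions, decompose, predict_propensity  # noqa: E402


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name in model.registry_names():
        tree = model.parse_glycan(name)
        blocks = decompose(tree)
        report = predict_propensity(blocks)
        sigs = Counter(b.signature for b in blocks)
        rows.append(
            {
                "glycoform": name,
                "n_residues": len(tree),
                "blocks": "; ".join(f"{k} x{v}" if v > 1 else k for k, v in sorted(sigs.items())),
                "arm_1_6": report.arm_1_6,
                "chitobiose_psi_shift_deg": report.chitobiose_psi_shift,
                "fired_rules": "+".join(report.fired()),
            }
        )
        print(f"{name:9s} {report.arm_1_6:22s} rules={'+'.join(report.fired())}")
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "glycoblocks_table.csv", index=False)

    diff = compare_decompositions(model.parse_glycan("ng"), model.parse_glycan("ngx"))
    print("\nng -> ngx block diff:", diff["modified"])
    print(f"wrote {RESULTS / 'glycoblocks_table.csv'}")
    print("Directionality: a(1-3)-Fuc and Xyl push plant forms open; "
          "b(1-4)-Gal plus a(1-6)-Fuc closes hybrid arms; LeA termini couple "
          "the two arms.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
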