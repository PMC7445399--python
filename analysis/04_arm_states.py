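#!/usr/bin/env python
"""(1-6)-arm state classification on constructed geometries.

Builds labelled open / front-fold / back-fold scaffolds at known
centroid-centroid distances, classifies them blind, then sweeps the
open/folded boundary d_open to show which frames sit inside the decision
band. Writes results/arm_states_summary.json.
"""

import json
import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

from glycoarch import synth  # noqa: E402
from glycoarch.arms import ArmParams, classify_arm_frames  # noqa: E402


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    summary = {"recovery": {}, "d_open_sweep": {}}

    for state, dist in (("open", 14.0), ("front_fold", 5.0), ("back_fold", 5.0)):
        ens, ci, ai = synth.build_arm_geometry(state, dist, n_frames=200, seed=41, jitter=0.05)
        out = classify_arm_frames(ens.xyz[:, ci], ens.xyz[:, ai])
        acc = float((out.states == state).mean())
        summary["recovery"][state] = {"distance_A": dist, "accuracy": acc}
        print(f"{state:11s} at {dist:4.1f} A -> recovered {acc:.1%}")

    # boundary sensitivity: folded geometries spread across 6-10 A
    rng = np.random.default_rng(42)
    dists = rng.uniform(6.0, 10.0, size=200)
    cores, arms = [], []
    for d in dists:
        ens, ci, ai = synth.build_arm_geometry("front_fold", float(d), n_frames=1)
        cores.append(ens.xyz[0, ci])
        arms.append(ens.xyz[0, ai])
    core, arm = np.stack(cores), np.stack(arms)
    for d_open in (7.5, 8.0, 8.5):
        out = classify_arm_frames(core, arm, ArmParams(d_open=d_open))
        frac_open = float((out.states == "open").mean())
        summary["d_open_sweep"][str(d_open)] = frac_open
        print(f"d_open {d_open:.1f} A -> open fraction {frac_open:.2f}")

    (RESULTS / "arm_states_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    print(f"wrote {RESULTS / 'arm_states_summary.json'}")
    print("Labels flip only for frames whose centroid distance crosses the "
          "shifted boundary — the classifier is a pure distance/plane rule.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
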