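"""End-to-end pipeline orchestration behind the command-line interface.

Three entry points mirror the subcommands:

* :func:`run_simulate` — sample a synthetic torsion ensemble from an
  :class:`~glycoarch.synth.EnsembleSpec` and (when the spec names a small
  fragment) write it out as a multi-model PDB with its ground-truth table;
* :func:`run_analyze` — read an ensemble, measure every glycosidic torsion
  of the given glycan, cluster phi/psi (and omega) landscapes, write
  population tables, KDE grids and the convergence report;
* :func:`run_blocks` — decompose a sequence into glycoblocks and run the
  propensity rule base.

Every run writes a JSON manifest (inputs hashed, parameters, seed, package
version) sufficient to reproduce it; identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from glycoarch import blocks as blocks_mod
from glycoarch import io, landscape, model, synth, torsions
from glycoarch.arms import ArmParams, classify_arm_state, find_arm_terminus

__all__ = ["RunConfig", "run_simulate", "run_analyze", "run_blocks"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run; defaults are the documented ones."""

    out_dir: Path = Path("glycoarch_out")
    glycan: str = ""  # shorthand or condensed sequence
    topology: Path = None
    frames: list = field(default_factory=list)
    dialect: str = "custom"
    spec_path: Path = None  # simulate: EnsembleSpec JSON
    eps: float = 25.0  # clustering neighbourhood, degrees
    min_fraction: float = 0.01
    bandwidth: float = 10.0  # KDE, degrees
    grid_size: int = 90
    d_open: float = 8.0  # arm open/folded boundary, Angstrom
    convergence_threshold: float = 15.0  # degrees
    stride: int = 1
    discard: int = 0
    seed: int = 0

    def params_dict(self) -> dict:
        return {
            "glycan": self.glycan,
            "dialect": self.dialect,
            "eps_deg": self.eps,
            "min_fraction": self.min_fraction,
            "kde_bandwidth_deg": self.bandwidth,
            "kde_grid_size": self.grid_size,
            "d_open_A": self.d_open,
            "convergence_threshold_deg": self.convergence_threshold,
            "stride": self.stride,
            "discard": self.discard,
            "seed": self.seed,
        }


def run_simulate(config: RunConfig) -> dict:
    """Generate a synthetic ensemble from a spec file and write it out."""
    spec = synth.EnsembleSpec.from_json(config.spec_path)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sampled = synth.sample_torsion_mixture(spec)

    outputs = {}
    truth = sampled.truth_frame()
    if spec.fragment:
        tor_values = {
            name: sampled.column(name) for name in sampled.dimensions
        }
        ensemble, build_truth = synth.build_linked_ensemble(
            spec.fragment, tor_values, n_frames=spec.n_frames
        )
        pdb_path = io.write_ensemble_pdb(ensemble, out / "ensemble.pdb")
        outputs["ensemble_pdb"] = str(pdb_path)
        truth = truth.merge(build_truth, on="frame")
    truth_path = out / "truth.csv"
    truth.to_csv(truth_path, index=False, float_format="%.6f")
    outputs["truth_csv"] = str(truth_path)
    spec_path = out / "spec.json"
    spec.to_json(spec_path)
    outputs["spec_json"] = str(spec_path)
    io.write_manifest(
        out / "manifest.json",
        {"subcommand": "simulate", **config.params_dict(), "spec": json.loads(spec.to_json())},
        inputs=[config.spec_path] if config.spec_path else [],
    )
    outputs["manifest"] = str(out / "manifest.json")
    return outputs


def _landscapes_for(series_list, config: RunConfig):
    """Group torsion series into per-linkage landscapes (phi/psi 2D, omega 1D)."""
    by_linkage: dict = {}
    for s in series_list:
        by_linkage.setdefault(s.definition.linkage, {})[s.torsion_name] = s
    out = []
    for lk, group in by_linkage.items():
        tag = f"{lk.child_id}({lk.child_anomeric_carbon}-{lk.parent_position}){lk.parent_id}"
        if "phi" in group and "psi" in group:
            ls = landscape.cluster_torsions(
                [group["phi"], group["psi"]],
                eps=config.eps,
                min_fraction=config.min_fraction,
                label=tag,
            )
            ls.kde = landscape.kde_landscape(
                [group["phi"], group["psi"]],
                bandwidth=config.bandwidth,
                grid_size=config.grid_size,
            )
            out.append(ls)
        if "omega" in group:
            ls = landscape.cluster_torsions(
                group["omega"],
                eps=config.eps,
                min_fraction=config.min_fraction,
                label=tag + ":omega",
            )
            out.append(ls)
    return out


def run_analyze(config: RunConfig) -> dict:
    """Full conformational analysis of one ensemble."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = model.parse_glycan(config.glycan)
    defs = model.torsion_definitions(tree)

    inputs = [config.topology] + list(config.frames)
    ensemble = io.read_ensemble(
        config.topology,
        config.frames or None,
        stride=config.stride,
        discard=config.discard,
    )
    amap = io.map_atoms(tree, ensemble, dialect=config.dialect)
    series = torsions.torsion_series(ensemble, amap, defs)

    outputs = {}
    torsions.write_series_csv(series, out / "torsion_series.csv")
    outputs["torsion_series_csv"] = str(out / "torsion_series.csv")

    pooled = _landscapes_for(series, config)
    io.write_population_table(pooled, out / "populations.csv")
    outputs["populations_csv"] = str(out / "populations.csv")

    # KDE grids as CSV matrices + JSON metadata for external plotting
    kde_dir = out / "kde"
    kde_dir.mkdir(exist_ok=True)
    for ls in pooled:
        if ls.kde is None:
            continue
        stem = ls.label.replace("(", "_").replace(")", "_").replace(":", "_")
        np.savetxt(kde_dir / f"{stem}.csv", ls.kde.density, delimiter=",", fmt="%.8e")
        (kde_dir / f"{stem}.json").write_text(
            json.dumps(
                {
                    "landscape": ls.label,
                    "dimensions": list(ls.dimension_names),
                    "bandwidth_deg": ls.kde.bandwidth,
                    "grid_size": ls.kde.density.shape[0],
                    "range_deg": [-180.0, 180.0],
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
    outputs["kde_dir"] = str(kde_dir)

    # per-trajectory convergence (pooled counts as one trajectory otherwise)
    per_traj: dict = {}
    if len(config.frames) > 1:
        for fpath in config.frames:
            sub = io.read_ensemble(
                config.topology, [fpath], stride=config.stride, discard=config.discard
            )
            sub_series = torsions.torsion_series(sub, amap, defs)
            for ls in _landscapes_for(sub_series, config):
                per_traj[f"{Path(fpath).name}:{ls.label}"] = ls
    else:
        for ls in pooled:
            per_traj[f"pooled:{ls.label}"] = ls
    report = landscape.assess_convergence(
        per_traj, threshold=config.convergence_threshold
    )
    report.rows.to_csv(out / "convergence.csv", index=False, float_format="%.4f")
    (out / "convergence.json").write_text(
        json.dumps(
            {"threshold_deg": report.threshold, "flag": report.flag},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    outputs["convergence"] = str(out / "convergence.json")

    # arm states, when the glycan has a (1-6) arm
    try:
        find_arm_terminus(tree)
        has_arm = True
    except ValueError:
        has_arm = False
    if has_arm:
        arm = classify_arm_state(
            ensemble, amap, tree, params=ArmParams(d_open=config.d_open)
        )
        arm.frame().to_csv(out / "arm_states.csv", index=False, float_format="%.4f")
        (out / "arm_states.json").write_text(
            json.dumps(
                {"fractions": arm.fractions(), "d_open_A": config.d_open},
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        outputs["arm_states"] = str(out / "arm_states.json")

    io.write_manifest(
        out / "manifest.json",
        {"subcommand": "analyze", **config.params_dict()},
        inputs=[p for p in inputs if p],
    )
    outputs["manifest"] = str(out / "manifest.json")
    return outputs


def run_blocks(config: RunConfig) -> dict:
    """Glycoblock decomposition + propensity report for a sequence."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = model.parse_glycan(config.glycan)
    decomposition = blocks_mod.decompose(tree)
    report = blocks_mod.predict_propensity(decomposition)

    payload = {
        "glycan": config.glycan,
        "sequence": model.serialize_glycan(tree),
        "blocks": [
            {
                "block_type": b.block_type,
                "members": list(b.members),
                "modifiers": list(b.modifiers),
                "arm": b.arm,
            }
            for b in decomposition
        ],
        "propensity": {
            "arm_1_6": report.arm_1_6,
            "chitobiose_psi_shift_deg": report.chitobiose_psi_shift,
            "fired_rules": report.fired(),
            "trace": report.trace,
            "reference_populations": report.reference_populations,
        },
    }
    (out / "blocks.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    (out / "blocks.txt").write_text(report.to_text() + "\n")
    io.write_manifest(
        out / "manifest.json", {"subcommand": "blocks", **config.params_dict()}
    )
    return {
        "blocks_json": str(out / "blocks.json"),
        "blocks_txt": str(out / "blocks.txt"),
        "report": report,
    }
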