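# glycoarch

Conformational analysis of N-glycan 3D architecture from atomistic
coordinate ensembles — built for structural glycobiologists studying how
plant and invertebrate sequence motifs (core α(1-3)-fucose, β(1-2)-xylose,
β(1-3)-galactose, Lewis A/X termini) reshape the dynamics of the
biantennary N-glycan scaffold relative to its mammalian counterparts.

N-glycans are intrinsically disordered at room temperature: their 3D
"structure" is an ensemble of conformers defined almost entirely by the
glycosidic torsions φ/ψ (and ω for 1→6 linkages), by pyranose ring puckers
(⁴C₁ ⇌ ¹C₄), and by large-scale arm motions — the (1-6) arm in particular
exchanges between an outstretched *open* state and *front-fold* /
*back-fold* / *rotated-core* closed states. This package provides the
machinery to quantify those ensembles and a rule framework ("glycoblocks")
that predicts the qualitative direction of the (1-6)-arm equilibrium from
sequence alone.

## What it computes

* **Sequence model** — rooted labelled trees for N-glycans, parsed from a
  condensed IUPAC-like dialect or from a registry of shorthand glycoform
  names (`ng`, `gfx`, `lea`, `xFA2G2`, …), with canonical serialization
  and per-linkage torsion definitions
  (φ = O5′–C1′–On–Cn, ψ = C1′–On–Cn–C(n−1), ω = O6–C6–C5–O5 with
  rotamers gg = −60°, gt = +60°, tg = 180°).
* **Torsion statistics** — dihedrals over multi-model PDB / DCD / XTC
  ensembles (MDAnalysis-backed I/O), summarised with circular statistics:
  mean = arg Σe^{iθ}, SD = √(−2 ln R) where R is the mean resultant length.
* **Conformer landscapes** — density-based (DBSCAN-family) clustering under
  the exact toroidal metric, count-based populations with noise reported
  explicitly, wrapped-Gaussian KDE heat-map grids, and a per-trajectory
  convergence rule (flag *extend* when any cluster's circular SD exceeds
  15°).
* **Ring & arm states** — Cremer–Pople pucker classification
  (θ ≤ 45° → ⁴C₁, θ ≥ 135° → ¹C₄) with the two-torsion
  (C1–C2–C3–C4, C2–C3–C4–C5) projection as a cross-check, and geometric
  (1-6)-arm state labelling (open / front-fold / back-fold / rotated-core).
* **Glycoblocks** — decomposition of a glycan tree into self-contained 3D
  units (chitobiose core + fucoses, trimannose core + xylose, arm GlcNAc,
  terminal galactoses, Lewis A/X termini) and a data-driven rule base that
  predicts the (1-6)-arm propensity with a full evidence trace.
* **Synthetic ensembles** — seed-deterministic von Mises torsion mixtures,
  Markov ring-flip series and internal-coordinate Cartesian builders that
  realise requested torsions/puckers exactly, so every analysis can be
  validated against known ground truth (microsecond MD sampling is out of
  scope).

## Worked example

Simulate a two-conformer disaccharide ensemble, analyse it blind, and
compare with the generator's truth:

```bash
cat > spec.json <<'JSON'
{
  "dimensions": ["phi", "psi"],
  "components": [
    {"mean": [60.0, 180.0],  "kappa": 50.0, "weight": 0.7},
    {"mean": [-60.0, -120.0], "kappa": 50.0, "weight": 0.3}
  ],
  "n_frames": 2000, "seed": 11, "fragment": "Gal(b1-3)GlcNAc"
}
JSON
glycoarch simulate --spec spec.json --out sim
glycoarch analyze --glycan "Gal(b1-3)GlcNAc" --topology sim/ensemble.pdb --out ana
head -4 ana/populations.csv
```

prints

```
landscape,dimensions,cluster,population_pct,n_members,mean_phi,mean_psi,sd_phi,sd_psi
2(1-3)1,phi/psi,1,71.5500,1431,60.0071,-179.9208,8.1168,8.0557
2(1-3)1,phi/psi,2,28.4500,569,-59.9344,-120.2970,7.8108,8.2016
2(1-3)1,phi/psi,noise,0.0000,0,,,,
```

— two clusters at the planted (φ, ψ) modes; the populations (71.6 / 28.4 %)
match the labels the generator actually drew for this seed, and the
circular SDs (~8.1°) match the κ = 50 concentration. `ana/convergence.json`
reports `"converged"` because every cluster SD is below the 15° rule.
The sequence-level view of a full glycoform:

```bash
glycoarch blocks --glycan gfx --out blk
```

reports `open_dominant` for the (1-6) arm with the fired rule trace
(core α(1-3)-Fuc rotation of the chitobiose ψ by ≈ −20°, xylose steric
blocking of the front fold, β(1-3)-Gal reinforcement) and the reference
population metadata each rule carries.

The numbered scripts under `analysis/` run these stages as a narrative
(simulate → landscapes → ring flips → arm states → glycoblocks) and write
their tables under `results/`, with large per-frame intermediates under
`scratch/`.

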