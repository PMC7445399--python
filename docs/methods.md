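# Methods

## Scope and model

`glycoarch` treats an N-glycan conformational ensemble as a collection of
periodic degrees of freedom: per-linkage glycosidic torsions (φ, ψ, and ω
for 1→6 linkages), per-residue pyranose puckers, and a coarse (1-6)-arm
state. The package quantifies each of these from Cartesian ensembles and,
separately, predicts the qualitative (1-6)-arm direction from sequence
through a glycoblock rule base. It does not run molecular dynamics, compute
free energies, or enumerate hydrogen-bond networks; reference population
percentages from microsecond-scale MD characterisations of these
glycoforms are carried in the registry and rule base as annotation
metadata only and are never recomputed.

## Torsion conventions

For a linkage X(1→n)Y:

* φ = O5(X)–C1(X)–On(Y)–Cn(Y)
* ψ = C1(X)–On(Y)–Cn(Y)–C(n−1)(Y); for 2-linked substituents (β(1-2)-Xyl,
  arm GlcNAc-β(1-2)) the fourth atom falls back to C1(Y)
* ω (1→6 only) = O6(Y)–C6(Y)–C5(Y)–O5(Y), rotamers gg = −60°, gt = +60°,
  tg = 180°

This is the standard carbohydrate-NMR convention consistent with the
gg/gt/tg rotamer naming. Dihedral signs follow IUPAC (cis = 0°, clockwise
positive looking along the central bond); the implementation is validated
against an independent plane-normal/atan2 construction to < 1e-9° and
against MDAnalysis to single precision. All angles are degrees in
(−180°, 180]; radians exist only inside function bodies.

## Circular statistics

Torsions live on the circle, so summaries use the resultant-vector
formalism: R = |mean e^{iθ}|, circular mean = arg mean e^{iθ}, circular
SD = √(−2 ln R) (Mardia). Reported "mean (SD)" pairs are these quantities.
Whether literature "(±)" values are circular or linear SDs is usually
unstated; circular is used throughout and documented here. The sampler's
SD is validated against the closed form √(−2 ln(I₁(κ)/I₀(κ))) of the
von Mises distribution.

## Conformer clustering

Cluster analysis is density-based (DBSCAN family) under the exact toroidal
metric: per-dimension shortest angular difference, Euclidean combination.
Defaults: eps = 25°, min_samples = 10, min_fraction = 0.01 (clusters below
1 % of frames are folded into noise). Implementation detail: up to 3000
frames are clustered directly via a precomputed toroidal distance matrix;
larger series are clustered on a deterministic stride subsample of ≤ 3000
frames and every frame is then assigned to its nearest clustered frame
within eps using a periodic KD-tree (box size 360°, which realises the
toroidal metric exactly). Populations are exact member counts over *all*
frames, so weight recovery is unbiased by the subsampling; noise frames
are always reported as their own row, never dropped. min_samples applies
to the clustered set unscaled — inside a genuine torsion mode the
neighbourhood counts exceed it by orders of magnitude even on the
subsample, while keeping it high suppresses single-point bridges between
well-separated modes. Cluster labels are 1-based in descending population
order; label 0 marks noise.

Validated properties: two- and three-component von Mises mixtures with
modes ≥ 90° apart (κ = 50, n = 3×10⁴) are recovered with the correct
cluster count and every population within 3 binomial standard errors of
the drawn truth across 20 seeds; a mode centred on ±180° is never split;
rotating all angles by +137° leaves memberships unchanged.

## KDE landscapes

Heat-map grids use a wrapped-Gaussian kernel on the torus, default
bandwidth 10° on a 90×90 grid over (−180°, 180]². The estimate is computed
by histogramming samples on the output grid and circular FFT convolution
with the kernel discretised at the bin centres — the standard fast binned
KDE — then renormalised so the torus integral is exactly 1. At the default
resolution the binning displaces density by at most half a cell (2°),
well below the bandwidth; the argmax of a unimodal sample falls within one
cell of the sample circular mean.

## Convergence rule

Sampling adequacy is judged per trajectory and per cluster: the flag is
*extend* if and only if any cluster's per-dimension circular SD is
strictly greater than 15°. "Strictly" is a deliberate reading of the
threshold — an SD of exactly 15.0° is converged. With multiple trajectory
files the rule is evaluated on each trajectory's own clustering; with a
single (pooled) input it is evaluated on the pooled landscape, and both
views are available.

## Ring pucker

Classification is total and rotation-invariant via Cremer–Pople puckering
coordinates of the six ring atoms ordered O5–C1–C2–C3–C4–C5: amplitude
Q, polar angle θ, phase φ. Thresholds: θ ≤ 45° → ⁴C₁, θ ≥ 135° → ¹C₄,
otherwise (including the boat/twist-boat band near θ = 90° and rings with
Q < 0.1 Å) *other*. The two endocyclic projection torsions
t₁ = C1–C2–C3–C4 and t₂ = C2–C3–C4–C5 are always reported for
projection-style scatter plots, and a sign-quadrant heuristic over
(t₁, t₂) serves as an independent cross-check (≥ 99 % agreement on
synthetic chair-flip ensembles). Note one convention consequence: cyclic
relabelling of the ring origin by an even number of positions leaves the
chair classification unchanged, while an odd shift inverts the alternating
puckering mode and therefore swaps the ⁴C₁/¹C₄ labels — ring atoms must be
supplied in the stated O5-first order.

## Arm states

The (1-6) arm is labelled per frame by a geometric rule with three
parameters:

* `d_open` (default 8.0 Å): the arm is *open* when the distance between
  the arm-terminus ring centroid and the root-GlcNAc ring centroid
  exceeds it. No numeric boundary is printed in the literature for this
  split; 8 Å sits between the constructed outstretched (≈ 14 Å) and folded
  (≈ 5 Å) geometries, is configurable, and is logged in every manifest.
* front vs back fold: the sign of the arm centroid's distance from the
  least-squares plane of the root-GlcNAc ring, with the normal oriented by
  the ring's O5→C1 vector. The literature defines front/back only
  pictorially; this fixes the convention algebraically.
* `psi_reference` / 90°: frames whose core Man-β(1-4)-GlcNAc ψ deviates
  more than 90° from its reference mode are *rotated_core*, taking
  precedence over the distance-based labels (the rotated trimannose is a
  distinct conformer, not a folding state).

An alternative torsion-region assignment (clusters → named states via
`population_of_state`) is provided alongside, since published open/closed
assignments may be cluster-based rather than distance-based; which was
used originally is not determinable.

## Glycoblocks and the rule base

`decompose` partitions a tree by precedence: chitobiose core (absorbing
core fucoses as modifiers) → trimannose core (absorbing β(1-2)-Xyl) →
branched Lewis A/X termini (absorbing their arm GlcNAc) → arm GlcNAc →
unbranched terminal galactoses. Terminal Gal and arm GlcNAc are modelled
as separate block types (the alternative single-block reading is flagged
in the vocabulary). The partition is checked to be disjoint and covering
for every registered glycoform.

The propensity rules live in `data/rules.json`, each with an integer
priority, predicate over decomposition features, an evidence sentence in
the package's own words, and reference population metadata. Rules fire in
ascending priority; the highest-priority fired rule that sets the
(1-6)-arm state wins and overridden rules are logged in the trace. The
encoded findings: core α(1-3)-Fuc rotates the chitobiose ψ by ≈ −20° and
biases the arm open (R1); β(1-2)-Xyl blocks the front fold and restrains
the (1-3) arm (R2); β(1-4)-Gal termini plus core α(1-6)-Fuc close the arm,
overriding open biases (R3); β(1-4)-Gal without α(1-6)-Fuc is
closed-leaning mixed, with or without Xyl (R4/R4x); LeA termini couple the
arms (R5, restrained_interacting); LeX termini leave them independent and
open (R6); β(1-3)-Gal reinforces the R1/R2 open bias (R7); α(1-3)-Fuc and
Xyl together enhance the rotated-trimannose conformer (R8); an unmodified
scaffold defaults to mixed (R0). The xFA2 hybrid is deliberately left to
the generic Xyl rule: the literature narrative for it is internally
ambiguous, and the registry entry carries that note rather than a guess.

## Synthetic data

The generator defines the study conditions for everything the tests
measure:

* **Torsion mixtures** — independent von Mises draws per dimension around
  component means, multinomial component membership. κ = 50 (circular SD
  ≈ 8°) is the default concentration, matching the within-cluster spreads
  of glycosidic torsion wells; mixture weights and n = 3×10⁴ frames for
  recovery studies mirror the well-separated two/three-conformer scenarios.
* **Flip series** — a two-state Markov chain with geometric dwells, mean
  dwells 9 and 3 frames by default (stationary 0.75/0.25). Real ring-flip
  dwell times span far more frames in μs trajectories; the short default
  is the package's scaling choice so that a 10⁴-frame series estimates
  stationary fractions with SE ≈ 0.009. What passing tests show is that
  classification and counting are exact given adequate sampling — not that
  μs kinetics are reproduced.
* **Cartesian builders** — internal-coordinate (bond/angle/torsion) chain
  construction with no force field: rings are built as regular hexagons
  with out-of-plane displacements from the pure m = 2, 3 puckering modes
  (which makes the recovered Cremer–Pople coordinates exact by mode
  orthogonality), and fragments of ≤ 4 residues are chained by
  natural-extension placement so that measured glycosidic torsions equal
  the requested values to < 1e-6°. Bond lengths are near the 1.43–1.52 Å
  nominals (recorded as achieved); anomeric chemistry, hydrogens and
  energetics are not modelled — the geometry only needs to realise the
  requested internal coordinates for the classifiers and the torsion
  engine. Steric clashes (< 0.5 Å) are recorded per frame, never fatal.

Synthetic ensembles differ from real MD in ways that bound what the tests
demonstrate: torsion dimensions are sampled independently (no φ–ψ
correlation within a conformer), frames are i.i.d. or first-order Markov
(no long-time correlation), and solvent, hydrogen bonding and sterics are
absent. The tests therefore validate the *measurement machinery* —
geometry, statistics, clustering, classification, bookkeeping — not the
physics of any particular glycan.

## Numerical choices and degenerate inputs

* Dihedrals: degenerate (collinear/coincident) quadruples raise a
  GeometryError naming the frame; no silent NaN.
* Angle wrapping maps exactly onto (−180°, 180]; −180° inputs become
  +180°.
* KDE grids are renormalised after convolution, so the integral-1 property
  is exact by construction; densities are clipped at 0 before
  normalisation to remove FFT ringing at machine precision.
* Clustering ties (equal populations) break by original DBSCAN label for
  determinism; all generators and the pipeline are seed-deterministic and
  manifests exclude timestamps so identical runs are byte-identical.
* Problem sizes in the tests and the acceptance script (10³–10⁵ frames,
  20-seed sweeps) are chosen to give tight statistical bounds at
  interactive runtimes; they are small relative to production MD analyses
  but large relative to every tolerance asserted.

## Known limitations

* GLYCAM residue-name support covers a representative subset of the
  linkage-code table (extendable in `data/dialects.json`).
* The arm-state classifier uses the root-GlcNAc ring as the chitobiose
  reference plane; heavily distorted cores could misorient the front/back
  sign, though the orientation vector (O5→C1) is robust for chair rings.
* Sialylated sequences parse (`Neu5Ac`/`Sia` tokens) but are flagged
  unsupported for torsion analysis; the Sia placeholder exists only so
  registry extensions can name them.
* The propensity engine is qualitative by design: it predicts directions
  and carries literature percentages as metadata, never quantitative
  populations from sequence.
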