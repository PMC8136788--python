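# Methods

## Model

A nucleobase assembly is a set of rigidly placed planar bases, optionally
with monovalent ions. The sugar–phosphate backbone is not modeled: each
base carries a hydrogen on its glycosidic nitrogen (N9 for purines, N1 for
pyrimidines) in place of C1′. This isolates base–base and base–ion
donor–acceptor interactions from backbone constraints; the price is that
built assemblies relax into geometries a backbone would forbid, which is
exactly what the structure-factor comparison against experimental
structures is designed to expose.

### Base templates

`src/dnastack/data/base_templates.tsv` ships idealized geometries for A, T,
G, C and N3-protonated cytosine (C⁺). They are synthetic: each free base
was force-field-relaxed (MMFF), projected exactly onto its least-squares
plane, and oriented into a standard frame — base plane = xy, glycosidic
anchor at the origin, substituent H along −y. Ring atoms deviate < 0.05 Å
from planarity by construction (exactly 0 after projection). Bond lengths
and angles agree with experimental averages to the few-hundredths-of-an-Å
level, which is sufficient for every geometric quantity computed here;
no claim is made that they reproduce any particular refinement library.

### Pair placement

Pairing places the second base in the plane of the first so that the
requested edge's hydrogen bonds are ideal: linear D–H⋯A with H⋯A = 1.90 Å
(the experimental Watson–Crick mean HBL). Each bond contributes
correspondence points (acceptor position on the fixed donor's D–H line;
for ring-N acceptors also a lone-pair direction point; for bonds donated by
the moving base, the H and D positions on the line through the fixed
acceptor). The in-plane rigid motion minimizing the squared residuals is
found by 2-D Kabsch; bonds donated by the moving base are linearized by a
short fixed-point iteration because a carbonyl acceptor has no single
lone-pair direction. Amino donors try both hydrogens and keep the better
fit. With two or more bonds the placement is over-determined, so realized
HBLs deviate from 1.90 Å by up to a few hundredths of an Å (G–C mean:
1.906 Å) — the templates' internal geometry cannot satisfy all ideals
simultaneously, as in reality.

**Parity.** Each template has a fixed ring-winding sense in its standard
frame, so coplanar placement has two branches: proper rotation (same
winding) and in-plane reflection (opposite winding — for a planar molecule
this is the physical flip about an in-plane axis, not an unphysical
mirroring). Watson–Crick pairs join bases of opposite winding (antiparallel
strands); Hoogsteen pairs in a parallel triplex join bases of equal
winding. The `flipped` flag toggles the branch and produces the
reversed-Hoogsteen ("r") variants, which come out with GVA near 180° as
expected. Reversed variants also engage the other acceptor of the purine
edge (O2 instead of O4 for T·A; N7/O6 swapped for C⁺·G and G·G), which the
bond tables encode explicitly.

### Triads, tetrads, stacks

Triads place the third base against the free Hoogsteen edge of the pair's
purine with the same engine. The G-tetrad constrains the neighbor guanine
to be an exact 90° rotation of the first and solves only for the cycle
center (a linear least-squares problem); both rotation senses are tried
because the N1-H→O6 / N2-H→N7 donation cycle closes in only one of them.
The result is exactly C4-symmetric: 4 NH-N + 4 NH-O bonds, and an ion on
the axis is equidistant from the four O6 (2.26 Å in-plane, matching
observed Na⁺⋯O distances). Stacks translate layer *k* to z = k·rise and
rotate it by k·twist about the vertical axis through its centroid; a
quadruplex ion defaults to the axis midway between layers
(the out-of-plane arrangement), `out_of_plane` on `build_tetrad` covers the
in-plane/offset dichotomy.

## Structure factors

* **HBL** is the hydrogen-to-acceptor distance, not donor-to-acceptor: the
  1.90 Å experimental mean is only consistent with H⋯A. Detection
  criteria: H⋯A ≤ 2.5 Å and D–H⋯A ≥ 120° (overridable); inter-base bonds
  only. X-ray structures carry no hydrogens, so donor hydrogens are rebuilt
  at idealized in-plane positions (ring N–H along the external bisector,
  amino N–H trigonal at 120°, 1.01 Å) — X-ray and NMR data are then
  measured identically.
* **GVA** is the arccos of the dot product of the two unit glycosidic
  vectors (anchor → C1′ when a backbone is present, anchor → substituent H
  otherwise), reported unsigned in [0°, 180°].
* **TA** projects the matched bases' glycosidic vectors onto the plane
  orthogonal to the stacking axis and averages the per-base unsigned
  angles. The stacking axis is the sign-aligned **mean of the two
  per-layer best-fit plane normals**, not the normal of a plane fitted
  through both layers pooled: each layer is nearly flat, so its own normal
  is well-conditioned, whereas at a 3.4 Å rise the pooled cloud's
  inter-layer variance rivals its in-plane minor-axis variance and the
  pooled normal tips over. With the per-layer axis the read-back of a
  built stack is exact to float precision for any twist in [0°, 179°].
  Whether an experimental TA should be averaged over bases or taken from
  one reference base is a genuine choice; averaging is implemented and
  recorded in survey metadata.
* **Planarity** is the RMS distance to the least-squares plane; **rise**
  the centroid separation along the axis; **ion bonds** the ion→O6
  distances within 4.0 Å, with "in-plane" meaning an axial offset < 0.5 Å
  from the nearest layer plane.

All factors depend only on relative geometry and are rotation/translation
equivariant to 1e-6 (tested).

## Energy ledger

The decomposition and counterpoise formulas are in the module docstring of
`dnastack.energy`. Choices worth recording:

* **Units**: kcal/mol throughout; one conversion constant
  (627.509474 kcal/mol per hartree) applied at ingestion from backend logs.
* **Fixture table**: `data/component_energies.csv` transcribes published
  counterpoise-corrected water-phase component energies for all pairs,
  triads, tetrads and two-layer stacks, with per-bond parentheticals as
  printed. A consistency check verifies each parenthetical equals
  total/bond-count within half a unit of its printed precision. The Li⁺
  quadruplex row is flagged, not resolved: its printed per-bond value
  implies eight ionic bonds while the in-plane Li⁺ arrangement is described
  with four Li⁺⋯O bonds. Gas-phase columns are schema-compatible but not
  populated.
* **Rounding**: report rounding is round-half-away-from-zero at the
  table's precision (e.g. −20.26/4 → −5.07), never banker's rounding.
* **Bond counts** come from `structure_metrics` when geometry is at hand,
  else from a bundled lookup (G–C 3, A–T 2, …, C⁺·G 2, tetrad 4,
  quadruplex 8), so fixture-only runs need no geometry.
* **Quadruplex aggregation** uses the G–G pair value (−6.75) as the
  per-pair term, four pairs per tetrad layer; this reproduces the
  out-of-plane Na⁺ aggregate of −106.3 at one decimal. The corresponding
  in-plane Na⁺ aggregate (−105.8) is not reproducible from printed
  components and is excluded from worked examples.
* **Hydration**: `DEFAULT_HYDRATION_ENERGIES` is a synthetic placeholder
  set (Li⁺ −41.00, Na⁺ −34.00, K⁺ −31.78 kcal/mol) chosen once to satisfy
  the two constraints the analysis actually uses — hydration stability
  Li⁺ > Na⁺ > K⁺ and a Na⁺/K⁺ gap of 2.22 kcal/mol. The K⁺-first ordering
  of ΔE_M⁺binding is a property of those constraints, not of the
  particular values (property-tested over random consistent sets). Supply
  measured values for real work.
* **Stability ranking** sorts most-negative-first and chains entries
  within 0.05 kcal/mol into tie groups, reflecting printed precision.

## QM bridge and mock backend

The deck writer emits one dialect (Gaussian-style: `-Bq` ghost suffix,
`Opt=ModRedundant` frozen-dihedral blocks, an SCRF continuum-water keyword
that is overridable because solvent keyword sets vary between codes) behind
a `JobSpec` so other dialects can be added. Decks are byte-deterministic.
The parser takes the last energy in a log. The mock backend fabricates
monomer energies from a CRC of the fragment id (stable across processes),
then shapes complex/ghost/fragment-basis records so the matching ledger
operation returns the planted component exactly at zero noise — the ledger
code is exercised end to end without any electronic-structure run.

## Synthetic data and what passing tests show

The generator builds duplex/triplex/quadruplex stacks at stated rise,
twist and HBL, perturbs every atom with isotropic Gaussian noise
(σ default 0.05 Å, seeded, replicates via spawned child seeds) and writes
PDB text the survey consumes unchanged. Energy noise is additive Gaussian
on the complex record. Neither noise model is physical — real coordinate
error is correlated along the backbone and real DFT error is systematic —
so recovery tests demonstrate that the estimators are unbiased and
correctly plumbed, not that they would be accurate on any particular
experimental ensemble. Survey tests run on pools of ~40 replicates; the
acceptance script uses the same size, which keeps the full pipeline under
a minute on one CPU.

## Survey

Inclusion rules: pure-DNA structures only (standard DA/DT/DG/DC residues
plus Li/Na/K ions and water); protein or RNA chains and non-standard
residues exclude a record with machine-readable reasons. NMR models are
pooled with equal weight (the mean is order-invariant). Layers are
re-inferred from hydrogen-bond connectivity rather than residue numbering,
so files whose numbering does not encode pairing still survey correctly.
Because pooling choices for experimental means are not uniquely defined,
`survey(..., internal_only=True)` reports the variant that drops terminal
layers alongside the all-pairs default. No downloading: accession files
are user-supplied paths.

Stress diagnosis compares a model value to the survey mean: TA below/above
the mean (±2°) is under/overrotation; model HBL below/above (±0.05 Å)
means tensile/compressive stress once a backbone is attached.

## Known limitations

* No sugar/phosphate construction, no syn/anti nucleosides, no A/Z-form
  geometry, no strand directionality — A–T/T–A and T–A/A–T are identical
  here.
* The component-energy table is the single energetic source; the package
  deliberately performs no DFT/CCSD, no solvation model, and no
  free-energy or entropy modeling.
* Template geometries are idealized stand-ins, not a reconstruction of any
  specific reference frame library; absolute GVA values of built pairs
  (e.g. 67.4° for G–C) carry a few degrees of template dependence.
* The survey's base-pair identification (≥ 2 hydrogen bonds between
  different-chain bases) will miss single-bond pairs such as C–C.
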