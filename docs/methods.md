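# Methods

This note documents the models and procedures implemented in
`phspec`, the parameters that matter, the numerical choices, and what
the synthetic-data experiments do and do not demonstrate.

## Physicochemical sequence profiles

A profile assigns each residue the arithmetic mean of a property scale
over an odd window centred on it; windows are truncated at the
sequence ends (the mean runs over the available positions only), so no
values are invented beyond the chain. With window 1 the profile is the
raw scale. The default window is 9 — a common smoothing width for a
~110-residue domain — and is configurable over odd values 1–21.

Four scales ship as editable data files:

| label | property | source | units |
|-------|----------|--------|-------|
| H | hydropathy | Kyte & Doolittle 1982 | kcal/mol-derived index |
| F | flexibility | Vihinen et al. 1994 | normalized B-factor |
| E | electronic charge concentration | Collantes & Dunn 1995 ECI | charge index |
| I | isotropic surface area | Collantes & Dunn 1995 ISA | Å² |

These are the standard literature scales matching the four profile
names; any two-column table can be substituted. Nonstandard letters
(X, B, Z, U, O) evaluate to the scale mean with a warning, which keeps
profiles defined without biasing any residue class. Profiles are
compared across sequences on alignment columns; gap cells carry no
value, and the column→residue maps are strictly increasing by
construction. Average pairwise identity uses the pairwise-deletion
convention (denominator = columns where both rows are non-gap); the
number is convention-dependent, which is why the convention is pinned
here.

## Solvent-accessible surface area

SASA follows the Lee–Richards construction: each atom sphere is
expanded by the probe radius (1.4 Å for water), cut into parallel
slices, and on each slice the exposed arc of the atom's circle against
all intersecting neighbour circles is measured exactly (interval union
on arc angles) and integrated as `2π·R·Δz` per exposed fraction. The
method is deterministic and converges as the slice spacing shrinks;
the default spacing 0.1 Å changes total SASA by <0.2% when halved on a
50-atom fixture. Translation invariance is exact (slices are anchored
per atom); rotation invariance holds to the discretization error of
the slicing direction (relative ~10⁻³ at 0.05 Å spacing), which is the
tolerance the tests use.

Van der Waals radii are a Bondi-style per-element table (C 1.70,
N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å), packaged and overridable.
Hydrogens absent from crystal structures are simply not modelled;
united-atom radii are *not* applied by default but can be supplied as
a replacement table. Exposure fractions divide per-residue SASA by
extended Gly-X-Gly reference maxima (theoretical values of Tien et
al. 2013) and are clipped to [0, 1]. Apo/complex burial is floored at
zero and residues burying more than 1.0 Å² (configurable) are flagged
as binding-site residues; the criterion is a design choice, since
published binding-site markings rarely state one.

NMR ensembles default to the first model — the convention for entries
without an average structure. Alternate locations resolve to the
highest-occupancy conformer (ties: first in file order).

## Contact complementarity

Every atom carries one of five hydropathy classes — hydrophilic
donor, hydrophilic acceptor, donor/acceptor, hydrophobic, neutral —
from a packaged (residue, atom) table for protein atoms and
element/connectivity rules for ligand atoms (phosphate and ester
oxygens are acceptors, hydroxyl oxygens donor/acceptors, carbons
hydrophobic, phosphorus neutral). This is a 5-class simplification of
the original 8-class contact-analysis scheme; the load-bearing
constraint — hydrophilic×hydrophobic contacts are always
illegitimate — is validated whenever a legitimacy table is loaded, so
table edits cannot silently break it. Like-polarity hydrophilic pairs
(donor–donor, acceptor–acceptor) are also illegitimate; neutral atoms
are compatible with everything.

Phosphate groups are inferred by distance (P–O ≤ 1.8 Å; an ester
oxygen bonded to both C and P belongs to the phosphate) rather than
CONECT records, which are unreliable in the wild.

Buried contact surface is measured on a deterministic Fibonacci point
lattice on each ligand atom's probe-expanded sphere: points accessible
on the isolated ligand but occluded by the protein are buried, each
buried point is attributed to the protein atom whose *expanded
surface* is nearest (single-owner attribution), and the class pair
decides legitimate vs illegitimate. Because the same point sets define
both the attribution and the isolated-minus-complexed SASA difference,
the partition conserves the buried area to floating point. The default
lattice is 4096 points/atom (16384 in the validation against the
independent random-sampling oracle, which keeps lattice and sampling
noise below the 2% comparison band; a 0.35 Å² floor covers groups
whose 2% falls below the oracle's own Monte-Carlo noise).

The complementarity of a group is C = S_legit − S_illegit (Å²). The
normalization NC = C / reference area uses the group's accessible
surface on the *isolated* ligand as the reference — the only per-group
normalization that keeps NC on a comparable scale across groups of
similar size. The published table's NC normalization is not defined in
print, so NC values are comparable in ordering but not asserted
bit-for-bit; the C column is pure arithmetic on the printed contact
areas and is reproduced exactly.

## Poisson–Boltzmann electrostatics

The solver discretizes ∇·(ε∇φ) − κ̄²sinh(φ) = −4πC Σqᵢδᵢ on a uniform
cubic-voxel grid, with lengths in Å, charges in e, and φ in kT/e at
298 K (C = e²/4πε₀kT·Å ≈ 560.7, recomputed from physical constants,
never hard-coded). The dielectric is two-valued — solute (default 2)
inside the probe-inflated atom spheres, solvent (default 80) outside,
with face values taken at face midpoints; there is no reentrant
surface, a documented simplification. Ionic screening (default 0.145 M
1:1 salt) acts only in solvent. Charges spread trilinearly to the
eight surrounding nodes. Grid faces carry a single-sphere
Debye–Hückel boundary condition summed over charges. Grid geometry
follows the production convention: spacing set so the longest padded
box edge (default padding 20 Å) spans 123 nodes, other axes covered at
the same spacing.

Relaxation is checkerboard successive over-relaxation with
ω = 2/(1+sin(π/n)); the nonlinear mode Newton-linearizes the sinh term
each sweep (argument clipped at ±30 for overflow safety). Convergence
is declared when the largest update falls below `tol` (default 10⁻⁴
kT/e); non-convergence raises with the residual history. On the
Born-ion fixture (charge-centred sphere, where the exterior solution
is exactly Cq/(ε_out·d)), the 123-node grid is accurate to ~0.5% at
6–12 Å; validation uses grids of 33–123 nodes, trading the published
production resolution against desk-scale runtime. Formal charges
(Lys/Arg +1, Asp/Glu −0.5 per carboxylate oxygen, charged termini, His
neutral) are the default scheme; they reproduce the qualitative
positively-charged β1/β2 binding patch without a force-field
dependency, and per-atom tables can be substituted. Surface potentials
are trilinear interpolations on each atom's solvent-accessible sphere,
reported raw and clamped to ±10 kT/e (the conventional colouring
range).

## Motif scanning and classification

Motif patterns are restricted regular expressions (literals, character
sets, bounded gaps; PROSITE-style `X(n,m)` accepted); unbounded
repeats are rejected so match lengths stay bounded. The shipped
3-phosphate signature default, `K-X-[SG]-X(6,11)-[KR]-X-R`, follows
the basic-residue PtdIns(3,4,5)P₃-binding signature of the cited
literature; since the classifier only requires *some* pattern, the
file is editable data, not code.

The decision flow is fixed in rule order: (1) an in-loop motif hit
sends the sequence to {1,3}, otherwise {2,4}; (2) within {1,3}, a
β1/β2 hydropathy peak ≥ τ_peak means Group 3, else Group 1; (3) within
{2,4}, max loop charge concentration < τ_charge *and* loop
hydrophilicity (negated mean hydropathy) < τ_philic means Group 4,
else Group 2. The ≥/< comparisons make the boundary behaviour
explicit: a tie on rule 3 lands on the lower-numbered group; rule 2
follows its stated ≥ convention. Every prediction carries a structured
rule trace whose replay reproduces the label.

The thresholds are the genuinely open part — the source analysis is
qualitative ("notable hydrophobic peak", "lower" charge). They are
calibrated **once** on the synthetic archetype distributions as the
midpoint between the two relevant group means (200 cases/group, full
effect, calibration seed 12345; `scripts/calibrate_thresholds.py`) and
shipped as config: τ_peak = 0.893, τ_charge = 0.996, τ_philic = 1.655.
The β1/β2 window itself comes from configuration or alignment
annotation, never from computed secondary structure — this keeps the
sequence-only pipeline free of a structure-assignment dependency.

## Synthetic data: what it emulates and what it does not

Sequence cases are ~110 residues of uniform-composition background
(uniform maximizes contrast control; natural frequencies would add
composition biases orthogonal to the planted signal) with a fixed
β1/β2-like window at positions 10–28. Groups 1 and 3 receive a literal
motif instance with probability equal to the archetype strength
`effect`; the motif gap and the rest of the window follow the group
archetype (K/R/N/S for the hydrophilic/basic groups 1 and 2, an
I/L/V/F run for group 3, untouched background for group 4). Groups 2
and 4 are rejection-verified motif-free. At `effect = 0` no signal is
planted and the four groups are statistically identical — an exact
negative control, where recovery sits at chance (~25%). Each case has
its own RNG stream keyed by (master seed, case index), so any case
regenerates bit-identically in isolation.

Toy complexes pack class-labelled pseudo-atoms (realised as
residue/atom identities the packaged class table recognises: Lys NZ
for donors, Asp OD1 for acceptors, Leu CD1 for hydrophobics, …) into a
sphere with a 2.4 Å minimum separation, and place P+4O phosphate
groups at configured burial depths with optional forced pocket
chemistry. They exercise the geometry and attribution machinery with
known ground truth; they do **not** emulate real PH-domain folds,
ligand stereochemistry, or crystallographic artefacts. Passing the
synthetic recovery experiment (≥95% of 400 cases at full effect)
therefore demonstrates that the decision flow, profiles and motif
scan interlock correctly — not that real PH domains are classified at
that accuracy, which depends on real alignments and loop annotations
supplied by the user.

Classification of group 4 is intrinsically the weakest call even on
synthetic data: the group is defined by the *absence* of strong loop
signal, so a background window that drifts charged or hydrophilic is
misread as Group 2. The observed per-group recall reflects this
asymmetry.

## Known limitations

* The dielectric boundary is the probe-inflated sphere union, not a
  molecular (reentrant) surface; potentials very close to crevices are
  smoother than a molecular-surface solver would give.
* NC absolute values depend on the chosen reference area; only
  orderings are asserted.
* The published analysis's exact property scales, smoothing window,
  motif definition and classifier thresholds are not printed in the
  source; all four are shipped as documented, overridable defaults.
* Quantum-chemical ligand descriptors (dipole moments, spatial
  extents, energies) are consumed as a packaged read-only table and
  never recomputed.
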