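# Methods

## Force field

The intermolecular energy is a pair sum over ligand–receptor atoms of a
Lennard-Jones term, an angularly weighted metal coordination term and a
screened Coulomb term. Two LJ forms are used, both normalized so the well
depth is exactly −ε at r = R_min:

* 12-6 (generic van der Waals, and the metal–HD "metal-assisted
  deprotonation" term): `ε[(R_min/r)¹² − 2(R_min/r)⁶]`
* 12-10 (hydrogen-bond-like; used for metal–NA/OA/SA and for donor-H against
  acceptors): `ε[5(R_min/r)¹² − 6(R_min/r)¹⁰]`

Metal pair parameters: R_min = 1.00 / 2.20 / 2.25 / 2.30 Å against
HD / NA / OA / SA, well depths free (fitted); metal–metal ε fixed at
0.010 kcal/mol; all other metal pairs combine Lorentz–Berthelot from an
AutoDock4-lineage like-pair table. Unknown pairs are derived lazily by the
same combination rule, so the table is closed over any metal element.

Electrostatics: `332.06 q_i q_j / (ε(r) r)` with the Mehler–Solmajer
sigmoidal distance-dependent dielectric (ε∞ = 78.4, A = −8.5525,
λ = 0.003627, k = 7.7839). Cutoffs: 8 Å (LJ), 20 Å (electrostatics). The
AutoDock4 desolvation term is omitted: only the ε values are the subject of
fitting here, and the atomic solvation volume is stored but unused. A
consequence worth knowing: without desolvation, dense nonpolar surfaces act
as adsorption sinks; the synthetic pockets are built so no such surface
competes with the specific contacts (see below).

### Coordination directionality

A metal with a vacant site carries a dummy atom (type DD, zero charge, zero
parameters) at `metal + L·v`, default L = 2.0 Å, where v is the normalized
negative sum of the metal→ligator unit vectors. When that sum nearly
vanishes (‖Σ‖ < 0.2 — square planar, octahedral), v falls back to the
best-fit-plane normal of the ligator directions, pointing to the half-space
holding fewer ligand atoms; an exact tie takes the sign making the first
non-zero component positive. A saturated, balanced 6-coordinate sphere has
no vacancy and the placement refuses (use `vacant_site=false`).

The dummy contributes no pair energy. Its sole effect: the attractive term
of each metal–acceptor 12-10 well is multiplied by w = cos²θ (θ = angle
between metal→dummy and metal→acceptor), zero beyond 90°. Without a dummy,
w = 1. The cos² form and the 90° threshold are this package's choice;
anything smooth, monotone in θ and equal to 1 at θ=0 would serve. Repulsion
is left unweighted so a clashing acceptor is never hidden by the angle term.

## Atom typing and torsions

Deterministic rules on the bond graph: H on N/O/S → HD else H; C in a
planar 5/6-ring of C/N/O/S with all members ≤3-coordinate → A else C; N
with no bound H and <3 heavy neighbours → NA else N; O → OA; S → SA;
metals → their element symbol. Bond perception: d < 1.15·(r_i+r_j) Cordero
covalent radii, factor 1.25 for pairs involving a metal (dative bonds are
longer). Rotatable bonds are acyclic single bonds between non-terminal
heavy atoms, excluding amides and every bond touching the metal or its
first coordination sphere — the complex core is assumed geometry-optimized
beforehand and rigid. More than 10 rotatable bonds is refused: the GA's
reliability degrades past that point. The tree root is the atom minimizing
the largest distal subtree (ties → lowest index).

## Pose search

Genome = (root-atom position, unit quaternion, torsion angles). Coordinates
are produced by applying torsions root-outward to the input conformer, then
rotating about the root and translating. Each docking run is an independent
GA from a fresh uniform randomization (position uniform in the box,
orientation from four normal deviates normalized, torsions uniform), so the
input pose cannot bias the result; n_runs (default 10) run bests, sorted by
energy, are the poses.

Desk-scale GA defaults: population 50, 100 generations, two-point crossover
over genome segments at rate 0.8, Gaussian mutation at rate 0.2 with
σ = 1.0 Å translation and 30° rotation/torsion, elitism 1, 10% fresh random
immigrants per generation, tournament selection (k = 2). A Solis–Wets
stochastic descent refines the current best 10% plus three random
individuals each generation — refining only the elite lets narrow deep
basins die before their depth is ever measured. Each run ends with a longer
Solis–Wets descent, a short basin-hopping polish (12 perturb-and-descend
rounds) and a deterministic Powell refinement; near-native minima in these
landscapes are separated by sub-kcal barriers, and the run best should be
the bottom of its basin, not a point on its slope. The wide mutation steps
and the immigrant stream are deliberately more explorative than classic
AutoDock settings; with a 10–20 Å box and ≤10 torsions, exploration is the
binding constraint, not exploitation. An AutoDock-sized preset
(population 150) is available but not default.

The GA objective adds to the intermolecular energy (i) a quadratic penalty
(50 kcal/mol/Ų) on root-atom excursion outside the box — a soft wall keeps
the gradient informative where hard rejection would not — and (ii) the
torsion-dependent intramolecular LJ between atoms of different rigid
fragments more than three bonds apart. Reported pose energies are pure
intermolecular energies, recomputable from the pose coordinates.

## Evaluation

Pose RMSD is computed **in place** — docked poses live in the receptor
frame, so no re-superposition is applied. All atoms present in both
structures count (the vacancy dummy never does); hydrogens can be excluded
on request, which is logged. `element-matched` mode solves an optimal
assignment within each element (Hungarian algorithm; identical to
exhaustive permutation, which the tests use as the oracle) so
symmetry-equivalent atoms do not inflate the value; the fitting default is
plain `ordered`. The fitting objective ("total RMSD") is the flat mean of
the N×M matrix of per-pair, per-pose RMSDs. The resolution report rounds
(mean RMSD − mean resolution) per metal to 3 decimals; a difference near
zero means the docking error is within the experimental uncertainty of the
reference structures.

## Monte Carlo well-depth fitting

Starting from ε = 2 kcal/mol each, the four parameters are swept once in
the fixed order HD → NA → OA → SA; per parameter, 250 candidates are drawn
uniformly from [0, 7] kcal/mol, each evaluated by re-docking the whole
training set (10 poses per pair) and accepted iff the total RMSD does not
exceed the best seen (greedy; RMSD_b is carried across sweeps, not reset).
A Metropolis mode `exp(−ΔRMSD/T)` is available behind `acceptance_mode` for
users who want barrier crossing; greedy is the default because the
objective as a function of one ε is effectively unimodal in the synthetic
problems and the sweep is a single pass. Every docking evaluation derives a
fresh seed recorded in the audit history, so a stochastic docker can be
replayed. A failing pair is skipped with a warning and N adjusts.

## Similarity metrics

Fingerprints: all simple element/bond-order paths of 1–7 atoms, canonical
direction (lexicographic min of the string and its reverse), SHA-1 hashed
and folded to 2048 bits — deterministic and independent of atom numbering.
Any fingerprint with those invariants would be conformant; this one was
chosen for having no dependencies. Tanimoto = |A∩B|/(|A|+|B|−|A∩B|); two
empty prints give 0 with a warning. TM-score uses
d0 = max(0.5, 1.24(L−15)^⅓ − 1.8) with L the reference length, maximizing
Σ 1/(1+(d_i/d0)²)/L by Kabsch superposition seeded from the full length and
sliding half/quarter fragments, each refined by re-superposing on the
residues within a shrinking distance cut. Full structural alignment search
is out of scope; the residue correspondence comes from identical lengths, a
user mapping, or global BLOSUM62 sequence alignment (gap open −10,
extend −0.5). The held-out test entry minimizes the unweighted mean of its
mean off-diagonal Tanimoto and TM-score rows.

## Synthetic problems: what they emulate, and what they do not

**Toy complexes** place a metal at the origin, N ligators at ideal
coordination geometries (2.0 Å), and a heavy-atom zigzag arm on the +x
ligator giving an exact requested number of rotatable bonds; charges are
toy values summing to the formal charge (metal +0.4).

**Pockets** are built around the planted pose so that the pose is, by
construction, the energy optimum: each anchor atom sits exactly at its pair
R_min from its designated ligand atom, where that pair's force vanishes.
The anchors: an axial OA acceptor on the vacancy axis (the coordination
contact; generating well depth 5 kcal/mol — the pocket emulates a complex
docked under an already *fitted* parameter set, not the 2 kcal/mol pre-fit
placeholder — and carboxylate-like charge −0.4, giving the one positive
ligand atom, the metal, an electrostatic funnel), behind which a cap of
carbons enforces the approach direction; an HD donor with a carbon parent
locking the arm's terminal oxygen; carbon walls bracketing one off-axis
ligator and the first arm carbon, which pin the rotation about the vacancy
axis — a mode the arm torsion could otherwise compensate. Donor anchors
always carry parent atoms because a bare H can nestle between several
acceptors at once, something no real donor can do; acceptor anchors carry a
cap for the mirror-image reason. A sparse carbon shell at 8.5 Å supplies
bulk context; it sits beyond the LJ cutoff, so it is energetically inert
and the optimum stays where the anchor construction puts it. A seeded rigid
rotation of the whole problem makes different seeds genuinely different
search problems. At generation time the planted pose is verified to score
below 10⁴ random poses.

These pockets are *abstract typed-atom shells, not proteins*: no backbone,
no rotamers, no desolvation, and an idealized degree of shape
complementarity. Passing the recovery benchmarks therefore shows that the
search machinery finds and ranks a well-defined optimum in a realistic
energy model — it does not certify accuracy on real PDB complexes, which
additionally stresses charge models, protonation and receptor flexibility.

**Fitting problems** probe one metal–protein type per training pair: a
single anchor of that type opposes a like-charge Coulomb repulsion, so the
equilibrium metal–anchor distance r̂(ε) is strictly monotone in the well
depth (solved to 1e-12 by bracketed root finding on dE/dr; a well too
shallow to bind against the repulsion returns a capped distance — the
complex unbinds). References are generated by the same procedure at the
true ε, so the total RMSD is exactly zero at the planted parameters and
strictly increases away from them. The accompanying surrogate docker
re-equilibrates this dominant interaction under the current parameters and
returns its single deterministic minimizer replicated ten times (a
deterministic surrogate has no pose scatter). This isolates the Monte
Carlo machinery from GA stochasticity; the GA-backed path is exercised
separately by the docking benchmarks and by the `fit-params` CLI.

## Numerical choices and limitations

* Benchmarks run at desk scale: 5 pockets × 10 GA runs for pose recovery,
  4 training pairs × 250 samples/parameter × 5 seeds for parameter
  recovery. Box 10 Å for pockets (a pocket-sized search volume), 20 Å in
  the fitting problems.
* Degenerate inputs: zero-length axes and quaternions are rejected;
  `r ≤ 0` in any potential is an error; empty training sets, empty RMSD
  matrices and <2 curation entries are errors, not silent NaNs.
* The balanced-sphere dummy tie-break is frame-dependent by necessity (both
  sides of a symmetric sphere are physically equivalent); equivariance
  under rotation holds wherever the vector-sum rule applies.
* Single-model PDB files only; alternate locations resolve to the highest
  occupancy (first on ties). Protonation states are taken as given — the pH
  option is recorded, never acted on.
* PDBQT atom ordering follows the torsion tree (root fragment first), so a
  ligand file round-trips exactly when its atoms are already in tree order,
  which all generated fixtures are.
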