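# Methods

`dmdnano` simulates and analyzes the aggregation of the 37-residue human
islet amyloid polypeptide (IAPP/amylin) in the presence of three small
molecules — curcumin, resveratrol and aspirin — with an event-driven
discrete molecular dynamics (DMD) engine on a coarse-grained model, and
computes the full aggregation-statistics stack (contacts, clustering,
cluster compositions, radial core/corona profiles, secondary structure).
This note records the model, its assumptions, the parameters that matter,
and the choices made where the design was genuinely open.

## Coarse-grained model

**Peptide.** Two beads per residue: a backbone bead (56 amu) and a
sidechain bead carrying the residue-specific remainder of the average
residue mass; glycines (residues 24 and 33) are a single bead, so an IAPP
chain has 72 beads.  Sidechain classes follow residue identity:
hydrophobic (L, I, V, A), aromatic (F15, H18, F23, Y37), charged (K1,
R11), polar otherwise.  The protonated N-terminus is modelled as a
charged-class bead (pH 7 protonation; His18 neutral, C-terminus amidated).
The Cys2–Cys7 disulfide is a permanent bond-like constraint.  Covalent
geometry is enforced by hard-wall distance windows: consecutive backbone
beads 3.8 Å ± 20 %, backbone–sidechain 2.8 Å ± 25 %, and a backbone
(i, i+2) window of 4.5–7.4 Å that admits both helical (~5.4 Å) and
extended (~6.7 Å) local geometry.  The generous windows are a deliberate
trade: they keep the bond-collision rate low (event-driven cost scales
with it) while preserving connectivity and excluded volume.

**Small molecules.** Bead graphs carrying the interaction features the
nanoassembly mechanism uses: curcumin = 2 phenol-ring beads + 3 linker
beads (one a carbonyl-oxygen acceptor); resveratrol = 2 ring beads (3
hydroxyls total) + 2 bridge beads; aspirin = 1 ring bead + 1 polar-oxygen
bead holding the acetyl/carboxyl groups.  Ring and aliphatic beads carry a
per-species well-depth multiplier (`eps_scale`) — the hydrophobicity
ladder — calibrated so that self-assembly propensity orders curcumin >
resveratrol > aspirin, mirroring their aqueous solubilities (curcumin
~1.6 µM, resveratrol ~131 µM, aspirin ~17 mM).  Shipped values: 1.30,
0.95, 0.55 (`scripts/calibrate_ligands.py` reproduces the calibration).

**Interactions.** All nonbonded pair energies are stepwise in distance.
The shipped table uses a single wide square well per class pair: hard core
at the sum of bead radii (1.7–2.3 Å per class) and depth ε to a 6.5 Å
cutoff.  Depths are expressed in kT at 300 K; hydrophobic–hydrophobic
1.0 kT, aromatic–aromatic (the π-stacking surrogate) 1.2 kT, backbone and
polar surface terms 0.35–0.55 kT, polar–hydrophobic ≈ 0 (the implicit
solvation penalty folded in), ligand–peptide terms 0.4–1.0 kT before the
species multiplier.  Ligand–peptide depths were calibrated upward until
polyphenols bind the peptide nearly continuously, the behaviour the
mechanism requires.  The wide flat bottom is a deliberate numerical
choice: internal shell boundaries multiply the event rate at dense packing
with little thermodynamic gain at this resolution.  The `discretize`
operation (shell-averaged stepping of arbitrary continuous potentials)
remains available for multi-shell tables and is used for electrostatics.

**Electrostatics.** The three charged beads per chain interact through a
Debye–Hückel screened Coulomb term (screening length 10 Å ≙ 100 mM NaCl,
ε_r = 78.4) discretized into 4 shells to a 7 Å cutoff.  Restricting the
electrostatic range keeps the neighbor-search cells small; at 7 Å the
screened unit-charge energy is already below 0.5 kT.

**Hydrogen bonds.** A distance-only reaction rule: an unreacted
donor–acceptor pair crossing its reaction distance inward, with capacity
available on both beads, forms a bond of energy −3.5 kT; the bond breaks
when the pair crosses outward with enough radial kinetic energy.  The
reaction distance is max(4.2 Å, hard core + 0.5 Å) per class pair so it
never coincides with a hard core.  Capacities (backbone 1 donor + 1
acceptor; hydroxyl-bearing sidechains and ligand rings per chemistry) are
enforced greedily; eligibility is re-checked at execution so the registry
is always consistent.  Orientation-dependent criteria are out of scope at
this resolution.

## Engine

Dynamics proceeds exactly between events.  Pair events are boundary
crossings of the step potentials; collisions exchange an impulse along
the line of centers, conserving energy, linear momentum and the pair's
angular momentum about its center of mass; an outward step of height ΔU
is crossed only if ½µv_r² > ΔU, otherwise the pair reflects.  The
implementation (numba-compiled) uses asynchronous per-bead position
timestamps, periodic minimum-image cells at least as wide as the largest
interaction range, per-bead best + runner-up event slots with
collision-counter invalidation, and a rigorous closing-speed prefilter.
Two details matter for exact energy conservation and are worth recording:
resolved pairs are nudged onto the exact boundary radius, and the
"at-boundary" classification window is kept at |r² − d²| ≤ 1e−12 so that
a slot invalidated in the instant a pair sits near a boundary cannot be
re-derived on the wrong side (a window of 1e−6 produced rare,
one-well-depth bookkeeping leaks; the tightened window makes the internal
O(N²) energy audit agree with the incremental tracker to ~1e−11 over
millions of events).

**Temperature.** An Anderson thermostat redraws single-bead velocities
from the Maxwell–Boltzmann distribution at exponentially distributed
intervals.  The rate is a free protocol parameter (the source material
fixes only ~300 K): high rates thermalize quickly but suppress the
center-of-mass diffusion of whole molecules and clusters (D ≈ kT/(2Mν)),
which desk-scale aggregation is limited by.  The package therefore uses a
staged protocol (below) and additionally offers interval-based global
kinetic-energy rescaling to drain the heat of assembly under very weak
stochastic coupling without randomizing transport.

## Simulation protocol (desk scale)

Systems follow the study conditions: cubic periodic boxes at constant
peptide density (63.7 Å edge for one chain, edge × n^(1/3) for n chains,
~6.4 mM), two ligands per peptide when ligands are present, random
overlap-free placement (rejection sampling replaces gradient
minimization, which event-driven dynamics does not define), randomized
Maxwell–Boltzmann velocities at 300 K with zero total momentum, and
independent replicates from distinct seeds analyzed over last-half
windows.

The shipped replicate protocol is two-staged: 2 500 reduced-time units of
thermalization at thermostat rate 0.05 (drains the heat of chain collapse),
then production at rate 1e−4 with kinetic-energy rescaling every 25 time
units.  One reduced time unit is ≈ 48.9 fs nominally, but no quantitative
time mapping is claimed at this resolution.  Production lengths are a
desk-scale choice (see `io.PROTOCOL`): long enough for ligand binding and
oligomer formation to reach a quasi-steady state, short enough for a
replicate set to run on a laptop-class budget.

**Known transport limitation.** With single-bead Anderson kicks, cluster
diffusion falls off as 1/(mass × rate); the final coarsening step of the
peptide-only control (two large oligomers merging into the single octamer
the full-resolution study reports) sits at the edge of the desk-scale
budget.  Control replicates reliably reach one dominant oligomer of 4–7
chains plus a small satellite within the shipped budget; complete
collapse to a single octamer typically requires several-fold longer
production than the default.  The acceptance suite documents this
honestly rather than inflating the budget.

## Analysis

* Contacts: two beads of different molecules closer than 5.5 Å
  (strictly), minimum image; k-d-tree accelerated and verified against an
  O(N²) scan.
* Clusters: connected components of the molecule-level contact graph
  (transitive membership), verified against a union-find oracle.
* Cluster statistics: per-frame counts of peptide-containing clusters,
  mass-weighted size histogram P(s) = ⟨s·n_s⟩/N_peptides, and an
  (n_peptides, n_ligands) composition map that retains ligand-only
  clusters; replicate means and standard deviations.
* Radial profiles: clusters are unwrapped across the periodic boundary by
  walking the contact graph, the mass-weighted center of mass is taken,
  and per-selector distance histograms (1 Å bins) are normalized.
  Selectors: peptide beads, ligand beads, ligand aliphatic carbons,
  ligand oxygens.
* Secondary structure: a pseudo-angle/pseudo-dihedral assignment on the
  backbone-bead trace — helix for θ ∈ [85°, 105°] and τ ∈ [30°, 70°] over
  ≥3 consecutive residues, strand for θ ∈ [110°, 145°] and |τ| ≥ 150°
  over ≥2, short direction reversals (θ < 85°, runs ≤ 3) as turns, else
  coil.  Thresholds are calibrated to ideal template geometries built by
  the fixtures module, not to atomistic assignments; atomistic
  helix/strand counts are out of scope.
* Binding fractions: per-ligand (mean over ligands of the fraction of
  frames with ≥1 peptide contact; the headline mode) and any-ligand.
* Steady-state window: last half of frames (floor split); a
  potential-energy linear-trend plateau detector can be reported
  alongside but never overrides the convention.

## Synthetic fixtures

`fixtures` generates trajectories with *provable* ground truth: cluster
members are chained on a serpentine grid at 3 Å spacing (< 5.5 Å cutoff)
so clusters are contact-connected by construction, and cluster anchors are
separated by more than twice the maximum extent plus the cutoff so they
can never merge; spread and jitter are validated against these bounds.
The generators emulate cluster bookkeeping, not aggregation kinetics —
passing analysis tests on fixtures demonstrates the statistics are
computed correctly, not that the engine's ensembles are realistic.  The
two-body square-well bound fraction has a closed-form configurational
integral oracle used to validate engine sampling end-to-end.

## Numerical choices

* Reduced units Å / amu / kcal·mol⁻¹; k_B = 1.9872e−3 kcal/(mol K).
* Event-time ties break by bead index through the argmin scan order;
  simultaneous events execute deterministically.
* Execution-time boundary mismatch tolerance 1e−5 Å; mismatched records
  are dropped and recomputed.
* Seeds: every stochastic component (placement, velocities, thermostat)
  is deterministic given its seed; replicate seeds are base_seed + k and
  the production stage derives its stream from seed + 7919.
* Frames are emitted on a fixed reduced-time grid, so last-half windows
  weigh all configurations equally regardless of the event rate.

## Limitations

* No hydrodynamics; Anderson kicks give free-draining (Rouse-like)
  cluster mobility, so coarsening kinetics are qualitative.
* The coarse-grained force field is calibrated to qualitative behaviours
  (self-assembly ordering, strong polyphenol binding, peptide
  aggregation), not to any published atomistic energy scale; binding
  percentages and helix residue counts from atomistic studies are not
  reproduction targets.
* Aromatic rings are isotropic beads: stacking has no orientation
  dependence.
* Hydrogen bonding is distance-only with greedy capacities.
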