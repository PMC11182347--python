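# Methods

`ktntools` implements the discrete-path-sampling style of energy-landscape
analysis: build a database of local minima by basin-hopping global
optimisation, connect the minima through index-1 saddle points located by
double-ended (DNEB) and single-ended (hybrid eigenvector-following)
searches, refine the resulting kinetic transition network, and analyse it
with harmonic-superposition thermodynamics, disconnectivity graphs and
fastest-path extraction.  This note records the models, the numerical
choices and the places where the design was genuinely open.

## Potential models

Three built-in systems exercise the machinery at increasing complexity.

**Müller–Brown surface.**  The standard 2-D benchmark (sum of four
exponential-quadratic terms with the conventional parameter set).  Within
the conventional plotting region it has exactly three minima
(−146.70, −108.17, −80.77) and two index-1 saddles (−40.66, −72.25), which
the test suite recovers with an independent dense-grid + descent oracle.
One additional high-energy saddle exists outside that region (near
(−1.60, 0.45), E ≈ +4.6); it is excluded from the census on purpose.  Note
also that the surface *grows* far from the origin (the fourth term has a
positive-definite quadratic form), so there is no flat asymptote.

**Lennard-Jones clusters.**  Pairwise 12-6 potential in reduced units
(ε = σ = 1), the classic benchmark for basin-hopping.  For LJ7 the known
isomer ladder (−16.5054, −15.9350, −15.5932, −15.5331) is reproduced.
Because all atoms are identical, minima that are energy-degenerate within
10⁻⁶ are treated as the same structure (permutational and rotational
isomers); this is the cheap and standard bookkeeping for clusters.

**Titratable bead peptide.**  A one-bead-per-residue chain (default 10
residues) designed so that a compact "helix" and an extended
"strand/hairpin" ensemble compete and respond to protonation:

* harmonic virtual bonds, r₀ = 3.8 Å, k = 25 kcal mol⁻¹ Å⁻²
  (deliberately soft: the Cα–Cα virtual bond carries no physics here and
  a stiff spring only ill-conditions the minimisations);
* harmonic bond angles, θ₀ = 105°, k = 10 kcal mol⁻¹ rad⁻²;
* a backbone dihedral term written as a first + second harmonic Fourier
  series with exactly two wells: a helix well at 60° (depth −3.0
  kcal mol⁻¹, curvature 6 kcal mol⁻¹ rad⁻²) and a strand well at 180°
  shallower by 0.3 kcal mol⁻¹.  The four Fourier coefficients were solved
  once from those conditions and are frozen package constants.  A smooth
  two-well form was chosen over Gaussian wells because Gaussian tails
  leave flat inter-well plateaus on which saddle searches are
  ill-conditioned;
* a cooperative coupling between neighbouring dihedrals,
  −J_H Σ w_H(φ_j) w_H(φ_j+1) − J_S Σ w_S(φ_j) w_S(φ_j+1) with smooth well
  memberships w = ((1+cos(φ−φ₀))/2)⁴, J_H = 0.4 and J_S = 0.65
  kcal mol⁻¹.  This emulates the hydrogen-bond cooperativity of helices
  and the pairing cooperativity of strands: pure secondary structures
  form deep funnels while mixed dihedral strings are pushed up, which is
  what keeps the strand funnel inside the low-energy window sampled by
  the lowest-k seeding.  Without cooperativity the low-energy spectrum is
  a combinatorial flood of mixed strings and no strand funnel survives;
* Lennard-Jones between beads three or more bonds apart
  (ε = 0.25 kcal mol⁻¹, σ = 4.8 Å);
* screened Coulomb between formal bead charges,
  E = (332.06/ε_r)·q_iq_j/r·exp(−r/λ_D) with ε_r = 74 (water near 310 K)
  and λ_D the Debye length of a 1:1 electrolyte computed from physical
  constants (λ_D ≈ 9.6 Å at 0.1 M, 310 K; the default ionic strength is
  0.1 M).

**Protonation presets.**  Three charge patterns emulate a peptide with
three acidic residues, one histidine and two permanent basic residues:
`prot1` (neutral-pH analogue: carboxylates ionised, His neutral, net −1),
`prot2` (mildly acidic: Glu-like sites protonated, His⁺, net +2) and
`prot3` (strongly acidic: everything titratable protonated, net +3).
The sites form an N-terminal acidic block (His at 0, Glu at 1–2, Asp at
3) facing a basic block four residues downstream (Lys/Arg at 6–7 for the
10-residue chain): in the helix the blocks are in contact, so the
ionised acids of `prot1` act as helix-stabilising salt bridges that
acidification removes while adding His⁺ repulsion against the basic
block; extended and hairpin strand structures keep the blocks apart.
This layout was chosen by scoring candidate site placements on a
charge-free structural library for a large, robust preset ordering, then
frozen.  On the ideal geometries the strand−helix potential-energy gap
is 2.015 / 1.755 / 1.354 kcal mol⁻¹ for prot1/2/3, and the sampled
free-energy gap at 310 K preserves the ordering.  Swapping presets
changes the Coulomb term only; the test suite asserts this identity
exactly.

All gradients are analytic; optional numba kernels reproduce the numpy
reference implementation to ~1e-12 and are cross-checked in the tests.
Gradient correctness is verified against central finite differences at
random configurations for every model.

## Stationary points

**Minimisation** is scipy's L-BFGS-B (history 20) run to a loose
gradient max-norm, then polished with a few eigenvalue-regularised Newton
steps (full finite-difference Hessian; all built-in systems have ≤ 100
degrees of freedom) until the RMS gradient is ≤ 10⁻⁶ — the convergence
criterion used throughout.  The polish escapes the slow L-BFGS endgame on
the ill-conditioned bead chain at about half the cost.

**Normal modes** come from a symmetrised central finite-difference
Hessian (step 10⁻⁵) of the analytic gradient, mass-weighted (unit masses
for analytic surfaces, 110 Da per residue for the chain).  Eigenvalues
with |λ| ≤ 10⁻⁶ are classified as zero modes; 3-D bead systems show the
expected six rigid-body zero modes at minima.  Frequencies are
ν_j = √λ_j / 2π in model units.

**Steepest descent** follows the negative gradient with displacement
capped at 0.05 length units (backtracking on any energy increase) and
hands off to the minimiser once the RMS gradient falls below 10⁻³.

## Transition-state searches

**DNEB.**  A doubly-nudged elastic band between two minima: each movable
image feels the perpendicular component of the true gradient, the
parallel spring force, and the doubly-nudged remainder of the
perpendicular spring force; tangents are energy-weighted upwind
estimates.  The second endpoint is first rigid-body superposed onto the
first, without which the straight-line interpolation between conformers
drags beads through each other.  The number of images adapts to the
endpoint separation (≈ 2 per length unit, between 11 and 31); the band
relaxes under FIRE with per-image displacements capped at 0.1.  Interior
images that are local maxima of the relaxed profile become saddle
candidates.

**Hybrid eigenvector-following.**  Candidates are converged by uphill
Newton steps along the lowest non-zero Hessian eigenvector and downhill
Newton steps in the orthogonal complement, every component capped at a
0.2 trust radius.  In convex regions the walk pushes a fixed displacement
along the softest mode with mode-following (largest overlap with the
previous eigenvector) so that near-degenerate soft modes cannot scramble
the walk; a walk that stays convex for 120 consecutive iterations is
abandoned.  Convergence requires RMS gradient ≤ 10⁻⁶ *and* exactly one
negative eigenvalue; anything else raises a saddle-index error.  Full
diagonalisation is used throughout (dimension ≤ 100).

**Connections.**  Each converged saddle is displaced ±10⁻² along its
negative eigenvector and steepest-descent paths identify the two
connected minima.  `connect_pair` iterates band → converge → connect,
each cycle attacking the closest pair of minima in different connected
components of the growing local network (pairs bridging the two endpoint
components first), until the endpoints join or the cycle budget is
spent.

## Kinetic transition networks

Minima are deduplicated by energy (10⁻⁶) then aligned distance (10⁻³,
Kabsch superposition; energy only for identical-particle clusters);
transition states by energy plus unordered minimum pair.  The plain-text
format stores a `[minima]` and a `[ts]` table (id, energy, log frequency
product, zero-mode count / negative eigenvalue, connected ids, order
parameters) with coordinates in a sidecar file keyed by id; all floats
are printed with shortest-round-trip precision so write → read → write is
byte-identical.

**Refinements** (all strictly additive):

* SHORTCUT attempts connections between the endpoints of an existing
  path and between members ⌈n/3⌉ apart along it;
* UNTRAP ranks minima by (energy barrier to the global minimum) /
  (energy above the global minimum) and attempts direct connections for
  the worst offenders;
* CONNECTUNC attempts connections between the closest pairs of minima in
  different components (below a distance gate, ∞ by default).

**Fastest paths** are Dijkstra shortest paths over edge weights
w(i → ts) = ln k_max − ln k_(i→ts) ≥ 0, where k is the harmonic TST rate
(below) at the analysis temperature; minimising the sum maximises the
product of rates.  Ties break deterministically toward the
lexicographically smallest minimum-id sequence.  The integrated path
length sums aligned Euclidean distances between successive stationary
points (rigid-body superposition removes trivial translation/rotation
contributions, which is flagged in the output metadata).

## Thermodynamics

Each minimum contributes a classical harmonic partition function

    ln Z_i = −E_i/kT − Σ_j ln ν_j + (n_vib/2) · ln(kT/2π),

the Gaussian configuration integral of its basin (exact equality with
quadrature is asserted for a 1-D quadratic well); zero modes are
excluded and symmetry numbers are 1.  Occupation probabilities
p_i = Z_i/ΣZ_j are computed with log-sum-exp (no overflow for spans of
hundreds of kT).  Harmonic transition-state-theory rates are

    k_(i→ts) = (1/2π) · exp(L_i − L_ts) · exp(−(E_ts − E_i)/kT)

with L the stored log frequency products; detailed balance
p_i k_ij = p_j k_ji then holds identically and is asserted on random
networks to 10⁻¹².  For minima loaded from files without coordinates the
kT-dependent constant (which needs the dimension) is dropped; it is
common to all minima of a system and cancels in every relative quantity.

**Free-energy regrouping** merges two groups when the free energy of the
connecting transition-state ensemble lies below both group free energies
by less than the threshold (fast interconversion in both directions),
iterated to a fixed point; each group's free energy is −kT ln Σ Z over
members.  The default threshold is 1 kT at 310 K.  Groups are the
operational "funnels" of the free-energy landscape.

## Order parameters

Radius of gyration is the mass-weighted RMS distance from the centre of
mass.  Secondary structure is assigned per dihedral window — helix for
40–80°, strand for 160–200° (synthetic-model constants, not a claim
about real hydrogen-bond-based assignment) — with runs shorter than
three consecutive residues relabelled coil, mimicking the refusal of
real assignment algorithms to call one-residue helices.  The CD-signal
conversion implements [θ] = m°(deg)/(10·l·c) per mole of peptide
(units deg cm² dmol⁻¹), with mean-residue normalisation available
behind a flag since both conventions are common.

## Disconnectivity graphs

Superbasins are connected components of the sub-network whose transition
states lie below each threshold on a descending ladder with spacing ΔE
(default: energy span / 40).  The merge level of any leaf pair equals
the minimax barrier between them quantized up to ΔE; this is asserted
against a brute-force all-paths oracle on small networks.  Rendering
writes plain SVG with fixed-precision coordinates (byte-deterministic);
the energy-to-pixel affine transform is declared in the `<desc>` element
so stem positions can be mapped back to energies.  Leaves may be
coloured by any scalar (linear normalisation, clipped) through a
red→green→blue map; the lowest-energy subtree is placed centrally, a
purely cosmetic choice.

## End-to-end protocol and scale

`run_landscape` follows the standard protocol shape: multi-start
basin-hopping (the default four starts are an ideal helix, an ideal
strand and two randomised chains), keep the lowest k minima per start,
merge, connect into one component, apply SHORTCUT/UNTRAP/CONNECTUNC
rounds, then analyse at 310 K.  Production-scale defaults (60,000 steps,
lowest-200) mirror the protocol's published scale; the shipped
`RunConfig.scaled()` profile (2,000 steps per start, lowest-20) runs the
whole three-preset comparison in a few minutes on one core and is what
the test suite and the acceptance script use.  Everything is driven by a
single integer seed; repeated runs are byte-identical.

**Cross-seeding.**  In the multi-preset comparison
(`run_preset_comparison`) every minimum found under one preset is
re-minimised under each of the others and merged into that preset's
database before the thermodynamic analysis — the protocol's standard
device of seeding one system's searches with another's low-energy
structures.  Without it each preset's strand ensemble is composed of
whatever its own search happened to find, and that composition noise
can exceed the small designed free-energy differences between adjacent
presets; with a common structural library the gap ordering reflects the
designed electrostatics.

With the scaled profile the three-preset comparison gives
ΔF(strand − helix) = 2.45, 1.96, 1.52 kcal mol⁻¹ for prot1/2/3 — the
helix funnel holds the global free-energy minimum in every preset and
the gap is strictly largest for the neutral-pH analogue, the designed
qualitative pH response.  The values are reproducible across seeds to
four decimals because the cross-seeded scaled protocol saturates the
low-energy structural library that dominates the Boltzmann sums.

## What the synthetic model does and does not show

The bead peptide is a designed emulation: its helix/strand competition,
cooperativity and charge response were chosen so that the qualitative
structure of a pH-dependent conformational equilibrium appears at desk
scale.  Passing tests therefore demonstrate that the landscape machinery
(sampling, saddle searches, network thermodynamics, visualisation) is
correct and that the designed physics behaves as designed.  They say
nothing quantitative about any real peptide: there are no side chains,
no hydrogen bonds, no generalized Born solvation, and the charge
patterns are cartoons of titration.  Real-force-field numbers (helix
percentages, lag times, absolute rates) are out of scope.

## Known limitations

* Transition-state searches can fail on very distant or tangled minimum
  pairs; the connection cycle treats failures as exhausted attempts and
  moves on, so sparse databases can remain disconnected (reported, never
  silently patched).
* Harmonic thermodynamics ignores anharmonicity and basin volume beyond
  the Gaussian approximation; at 310 K on this model that is a design
  choice, not an approximation with a controlled error bound.
* The Dijkstra edge weight (−ln TST rate) is one of several defensible
  "fastest path" definitions (branching probabilities and mean waiting
  times being alternatives); it is documented prominently because the
  choice changes the extracted path in general.
* Identical-particle deduplication for clusters is by energy degeneracy,
  which could in principle merge distinct isomers that are accidentally
  degenerate to 10⁻⁶.
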