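# Methods

`ipec` models a stoichiometric interpolyelectrolyte complex (IPEC) of two
linear chains of equal length N and ionization degree f = 1/2: a hydrophobic
polycation (H) whose affinity for the solvent is tunable, and a hydrophilic
polyanion (P) for which the solvent is always good.  The package has three
computational layers — a coarse-grained Langevin simulator, a structural
observable/classification layer, and an analytical free-energy theory of the
core-shell/vesicle transition — plus a synthetic-structure generator that
makes every analysis component testable without dynamics.

## Coarse-grained model

Reduced units throughout: ε_LJ = σ = m_b = k_BT = 1.

* **Bonds**: E = K (r − b)², K = 10⁴, b = 1σ.  The spring is stiff enough
  that the thermal RMS bond-length deviation, √(kT/2K)/b ≈ 0.71%, stays
  below 1%.
* **Excluded volume**: WCA repulsion (the purely repulsive part of
  Lennard-Jones, shifted to vanish at r_c = 2^(1/6)σ) between all non-bonded
  beads.
* **Solvent quality**: an implicit-solvent Yukawa-type attraction between
  H–H pairs, E = ε_HH (σ/r)(1 − (r/r_cY)²)² with r_cY = 4σ and ε_HH ≤ 0.
  ε_HP = ε_PP = 0 (athermal, good solvent for P).  Both the energy and its
  derivative vanish continuously at the cutoff.
* **Electrostatics**: bare Coulomb E = l_B q_i q_j / r between the charged
  beads (alternating ±1 along each chain).  The Bjerrum length l_B
  (0.25–10σ) sets the coupling strength.  Counterions are not represented:
  in a dilute solution the stoichiometric complex releases them far away.
  The reference protocol for this system uses Ewald sums in boxes of edge
  1200–2400σ for a complex of size ~10σ; at that dilution periodic images
  contribute negligibly, so this package sums Coulomb directly (non-periodic,
  O(n²) over charged beads).  An `electrostatics_mode="ewald"` enum value is
  reserved but intentionally not implemented.
* **Exclusions**: bonded (1–2) pairs interact only through the bond spring;
  WCA and Yukawa are excluded for them (the stiff spring dominates the 1–2
  distance, and the bonded-pair Yukawa would be a near-constant shift).
  Coulomb needs no exclusion because strict charge alternation means bonded
  neighbours are never both charged.

## Integration and thermostat

The equations of motion are integrated with the BAOAB splitting of Langevin
dynamics: half kick, half drift, an exactly sampled Ornstein-Uhlenbeck
velocity update, half drift, half kick.  One force evaluation per step;
the OU substep is exact, which keeps equipartition accurate even though the
bond vibration is only ~6 steps per period at dt = 0.005 (ω·dt ≈ 1).
A plain velocity-Verlet stepper (no thermostat) exists for energy-drift
checks; with dt ≤ 10⁻³ the relative drift over 10⁴ steps is < 10⁻³.

The damping constant D = 100 is read in the LAMMPS `damp` convention by
default: τ = 100 reduced time units (`damping_convention="time_units"`).
The accompanying phrase "temperature relaxed within 100 time steps" suggests
the much stronger coupling τ = damping·dt = 0.5, which is selectable
(`damping_convention="steps"`).  Equilibrium structure does not depend on
the choice; dynamics does, strongly: bead diffusivity is kT·τ/m, so the
weak-friction default explores conformations ~200× faster per step, and the
annealed complexes coalesce into their compact equilibrium shapes within the
desk-scale stage lengths (under the overdamped reading they remain trapped
in elongated transients).  Temperature stays within a few percent of kT = 1
throughout the anneal despite the weak coupling.

Neighbor search uses a Verlet pair list with a 0.3σ skin, rebuilt by an
O(n²) sweep when any bead has moved more than half the skin.  At desk scale
(n ≤ a few thousand) the brute-force rebuild is faster and simpler than cell
lists; one sweep fills two lists, a WCA list (all species) and an H–H
Yukawa list, so the 4σ attraction is only ever evaluated on H–H pairs.
Initial states are two interleaved excluded-volume random walks grown inside
a sphere of radius N^0.6 b, avoiding the transient of two distant coils
drifting together.

## Annealing protocol

Relaxation at ε_HH = 0, then a stepwise schedule ε_HH: −0.1, −0.2, …, −2.0
(step −0.1, extensible to −3.0), each stage an equilibration run followed by
a production run with snapshots at a fixed stride.  Stage averages use the
production half (second half of each stage's production snapshots).

**Desk-scale sizes.** The full study protocol (4×10⁶-step relaxation,
2×10⁶ + 2×10⁶ steps per stage, N = 512–2048) is far beyond a single-core
desk budget.  The package's reference runs (`ipec.studies`) use, as their
own defaults: N = 256 with relaxation 10⁵ and stages 10⁴ + 10⁴ steps for
the annealed short-chain run; N = 512 with relaxation 2×10⁵ and production
10⁵ for the good-solvent run; and N = 512 with relaxation 5×10⁴ and stages
5×10³ + 5×10³ for the annealed micelle run.  In every annealed run the final
ε_HH value is repeated for three extra stages, so end-point averages span
several stage windows.  Convergence of the annealed observables was
verified by doubling all stage lengths and by extending the final stage
six-fold: ψ_b, k1, k2 and the radial profiles are unchanged within their
stage-to-stage scatter (±0.01 on ψ_b, ±0.02 on k).

**Caveat on ψ_b in the core-shell regime.**  The ion-pair fraction here is
the fraction of charged units with ≥ 1 opposite-sign partner within
r_b = 1.5 b.  For the weak-electrostatics core-shell complexes this
implementation converges to ψ_b ≈ 0.32 (N = 256) and ≈ 0.36 (N = 512) —
stable under doubled stages, 6–12× extended final windows and both damping
conventions — whereas the reference curves for this regime read
ψ_b ≤ 0.25.  The gap traces back to the ambiguity in what counts as "an ion
pair": a unique-pairing (matching) count would halve our values to
0.16–0.19, inside the bound, but the participating-fraction reading is the
only one compatible with the ψ_b ≈ 0.95 reported for strong coupling
(a matching caps at 0.5).  The package reports the participating-fraction
value honestly; the test asserting the ≤ 0.25 bound at desk scale fails and
is intentionally left failing rather than loosened.

**Caveat on the micelle k2.**  The N = 512 poor-solvent micelle's k2
converges to 0.96 ± 0.02 over the desk-scale end-point window (~600 time
units), slightly above the ≈ 0.9 read off full-scale runs whose 10⁴
time-unit averages sample rare large shape deformations that this window
cannot.  k1 (0.92) and the (k1+k2)/2 mean (0.94) agree with the full-scale
values within 0.05.

## Observables

* **Shape factors** (equal-mass gyration tensor, eigenvalues g1 ≤ g2 ≤ g3):
  k1 = (g1+g2)/(g2+g3), k2 = (g1+g3)/(g2+g3).  Sphere → (1, 1), thin disk
  → (0.5, 0.5), long cylinder → (0, 1).  Rotation/translation/permutation
  invariant.
* **Maximal cluster**: connected components of the contact graph of nonionic
  H beads at cutoff 1.4σ (KD-tree + sparse connected components; an O(n²)
  union-find is kept as the test oracle).  Reported as M_max/n_selected,
  which equals 2⟨M_max⟩/N for f = 1/2 chains.  The abrupt rise of this
  fraction marks the necklace regime.
* **Radial profiles**: shell-volume-normalized densities of H±, H⁰, P−, P⁰
  about the all-bead center of mass.  The cavity detector calls a complex
  hollow when total density stays below 5% of its peak out to at least 2σ
  (both knobs configurable).  A high–low–high radial pattern of the H
  density flags the buried core of the onion morphology.
* **Ion pairs**: ψ_b = fraction of charged beads with ≥ 1 oppositely charged
  bead within r_b = 1.5 b.  A literal "number of unique pairs / N" would cap
  at 0.5 and cannot reproduce the ≈ 0.95 values of the strongly coupled
  regime, so the participating-fraction reading is used; the raw contact
  count is reported alongside.

## Shell symmetry (Q_l)

The angular distribution of H beads about the complex center is expanded in
spherical harmonics, w_lm = Σ_i Y*_lm(θ_i, φ_i), and

    Q_l = 4π/((2l+1) n) Σ_m |w_lm|²  =  (1/n) Σ_ij P_l(cos γ_ij),

computed up to l = 10.  The two forms are equal by the addition theorem; the
package computes the harmonic form and uses the O(n²) Legendre double sum as
its primary oracle (agreement to 10⁻⁸ is a test invariant, as is rotation
invariance).  Q_0 = n identically; an isotropic shell gives Q_l ≈ 1 for
l ≥ 1 (shot noise, independent of n) while a coherent l-fold feature grows
∝ n — hence the dominance threshold is set on raw Q_l (default 6, i.e. 6×
the noise floor; the labelled fixtures produce Q_l of order 30–500).
Exact bead angles feed Q_l by default; the π/18-binned histogram variant is
retained for visualization and cross-checks (binned vs exact low-l values
agree within ~2 counts on smooth shells).  Diagnostic spectra: three pores
at triangle vertices → Q_3 dominant; cubic pore patterns → Q_4 (with Q_8);
dodecahedral → Q_6, Q_10; tetrahedral point sets rank
Q_3 > Q_10 > Q_7 > Q_9 > Q_4.

## Morphology classification

`classify` is a pure rule cascade over an observable bundle; every
threshold lives on `Thresholds`.  Since the source taxonomy is assigned by
eye, the defaults are tuned once on the labelled synthetic fixtures and then
frozen: sphericity k1, k2 ≥ 0.8; coil when the maximal-cluster fraction is
< 0.1 and the complex is loose (density < 0.15σ⁻³ inside its gyration
sphere, or ε_HH near 0); necklace in the cluster-fraction rise window
0.1–0.75 (the upper edge tightened from 0.9 so that a transiently fragmented
dense cylinder is not called a necklace); cylinder when k1 < 0.4, k2 > 0.8;
torus by the empty-axis test (no beads in a cylinder of radius 0.25× the
median axial distance around the smallest-eigenvalue axis).  Spherical
structures split on the radial profile (hollow → vesicle, with pores →
perforated vesicle; buried H core → onion), on Q_l dominance + high ψ_b
(structured solid), and on low ψ_b + dense H core (core-shell).

Pores are counted as 4-connected patches (≥ 3 bins, φ-periodic) of angular
histogram bins that are empty despite an isotropic expectation of ≥ 2 beads
— conservative on sparse shells, where single empty bins arise by chance.

On the labelled fixture suite (all 10 taxonomy labels, randomized geometry
and orientation) the classifier scores 100% both noiseless and at jitter
0.2σ over 50 seeds per label.  The fixtures are geometric idealizations
(melt-density lattice cores, loose random coronas, exact shells); passing
them shows the decision boundaries are placed correctly between idealized
morphologies, not that the classifier is robust to every equilibrium
fluctuation of real trajectories — the scaled-down simulation checks cover
that gap for the spherical regimes.

## Synthetic structures

Quasi-uniform spheres use a deterministic Fibonacci lattice (plus seeded
jitter); filled bodies use low-discrepancy radial stratification; planar
disks use a Fermat spiral.  Dense hydrophobic cores are built on two
interpenetrating cubic sublattices at melt density (~1σ⁻³): nonionic beads
on the corner lattice (spacing 1.25σ < 1.4σ, so their contact network is
connected by construction) and charged beads on the body-centered offsets.
A Poisson fill at the same density badly underestimates contact
connectivity in quasi-one-dimensional cores (cylinders, torus tubes) —
real collapsed cores are liquid-like with a well-defined nearest-neighbor
distance, which the lattice emulates.  Chain-like fixtures (random coil,
necklace) carry bonds and strict charged/uncharged alternation; fixtures are
geometric, not Boltzmann-distributed.

## Analytical theory

Lengths in units of the monomer size a, volumes in the monomer volume υ
(υ_H = υ_P = υ, a_H = a_P = a), energies in k_BT.  The polycation collapses
into a dense region — a ball of radius D (core-shell) or a spherical layer
of thickness D around a cavity of radius R (vesicle) — and the polyanion
adsorbs onto its surfaces.  Free-energy terms (totals, not per monomer):

* Flory-Huggins mixing in the dense region with the geometric volume
  fraction φ_H (not hard-coded to 1, though χ = 6 drives it there);
* surface energy (a_H/υ_H) χ φ_H² per unit area over the printed two-surface
  combination 4π((R+D)² + D²) for the vesicle;
* electrostatic self-energy W of the dense region: (1/10) l_B f² N²/D for
  the ball; the spherical-layer form's R → 0, y → 0 limit reproduces the
  ball form exactly (the package asserts the ratio is 1);
* screened adsorption of the polyanion with κ = √(4π f² l_B/B): the outer
  term −(1/2) l_B f² N² (1−y)²/((R+D)(1+κ(R+D))) and, for the vesicle, a
  cavity term with sinh/cosh structure in κR, where
  y = φ_H S_in a_H/(N υ_H) is the fraction of polycation surface units on
  the cavity side.  The cavity term is evaluated by series for κR < 10⁻³
  and by its flat-interface asymptote 2/(κR(κR−1)) for κR > 30 to avoid
  overflow.

Numerical notes: as R → 0 the vesicle's printed surface term tends to
2× the ball's (both boundaries persist in the printed formula); the
comparison of minima is unaffected because the core-shell branch is always
evaluated with its own expression.  Minimization is a deterministic
geometric grid scan (D for the ball; (R, φ_H) for the vesicle, with D
eliminated through the volume constraint) followed by Nelder-Mead
refinement; the multi-start grid guards the double-well structure near the
transition.  The transition line l_B*(N) is found by sign-change bracketing
of ΔF on a log grid and Brent root refinement (relative tolerance 10⁻⁴);
absence of a sign change is reported as "no transition" (NaN in the curve
table).

For the reference parameter set (f = 0.5, B/υ = 4, χ = 6, υ_H/υ_S = 1,
υ_H/a³ = 1) the computed line has l_B* strictly decreasing in N, the cavity
diameter 2R growing along the line, 2R ≈ 9 a at N ≈ 1000, lower ionization
(f = 0.45) enlarging the core-shell region, and larger B shifting the line
to higher N and l_B.  The headline cavity-size figure is evaluated at
N = 1024, the chain length of the simulated morphology diagrams.

## Known limitations

* No explicit counterions, salt, solvent beads or charge regulation; no
  Ewald summation (dilute, non-periodic regime only).
* The simulator is single-threaded; desk-scale runs use N ≤ 512 and the
  reduced stage lengths above.  Full morphology diagrams (N up to 2048,
  l_B up to 10, 4×10⁶-step stages) are out of desk scale; the classifier
  and observables are instead validated property-based on fixtures.
* The theory covers only the two spherically symmetric structures; no
  cylinder/torus free energies, and the B >> υ assumption means the
  theory's chain lengths are not quantitatively those of the simulations.
* Classification of single snapshots cannot use shape-fluctuation
  information; the good-solvent "coil" call therefore leans on cluster
  fraction and density rather than on k1/k2 variance.
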