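# Methods

## The model

`ampholyte` simulates short flexible peptides that carry both weak-acid
and weak-base side chains, in order to study charge regulation: how the
ionisation state of each group departs from the isolated-group
(Henderson–Hasselbalch) prediction because of electrostatic interactions
with the other groups, and how ionisation couples to chain conformation.

Each amino acid is coarse-grained to two beads: a backbone bead C and a
titratable side-chain bead (A for acids, B for bases) carrying charge 0
in the neutral state and ∓1 e / ±1 e in the ionised state.  The
interaction terms are deliberately minimal:

- **Bonds** — harmonic, U_h(r) = (k_h/2)(r − b)², k_h = 400 k_BT nm⁻²
  for all bonds.  Backbone–backbone bonds have b_CC = 0.382 nm; the
  side-chain bond length is residue-specific (Asp 0.327, Glu 0.436,
  His 0.453, Tyr 0.648, Lys 0.589, hypothetical a/b 0.355 nm — averages
  of all-atom tetramer geometries).  Note the stiffness is stated per
  nm², the only dimensionally consistent reading.
- **Excluded volume** — the WCA (truncated-and-shifted, purely repulsive
  Lennard-Jones) potential between *all* bead pairs including explicit
  ions and bonded neighbours, with ε = 1 k_BT, σ = 0.355 nm, r_cut =
  0.4 nm.  Because 0.4 nm is slightly beyond the Lennard-Jones minimum
  2^(1/6)σ = 0.3985 nm, the literal parameterisation leaves a ~3.5×10⁻⁴
  k_BT step at the cutoff; we reproduce it literally by default and
  provide `exact_wca_cutoff=True` for the continuous variant.  No bonded
  exclusions are applied anywhere (none are part of the model; at the
  C–C rest length 0.382 nm < r_cut the bonded pair feels a small WCA
  contribution).
- **Electrostatics** — U_ij = z_i z_j l_B k_BT / r with Bjerrum length
  l_B = 0.71 nm (water at room temperature), summed over the periodic
  cubic box by a direct Ewald sum with tinfoil boundary conditions.
  Splitting parameter and cutoffs are chosen from the standard
  truncation-error estimates for a target relative rms force error
  (default 10⁻³; measured error on random charge configurations is ~5×
  smaller, and the test suite checks both the error target and agreement
  with an independently coded reference Ewald sum).  At the system sizes
  this package targets (tens to a few hundred particles) a direct sum is
  faster and simpler than a mesh method; the solver contract, not the
  algorithm, is what the rest of the package relies on.

Reduced units: energies in k_BT (temperature enters only through l_B and
the thermostat target), lengths in nm, particle mass m = 1 (static
observables do not depend on it), time in τ = σ√(m/ε).

## Constant-pH sampling

Protonation states are sampled in the constant-pH ensemble.  The two
reactions HA ⇌ A⁻ + H⁺ and BH⁺ ⇌ B + H⁺ are realised as Monte Carlo
moves: a deprotonation lowers the site charge by one and inserts a free
H⁺ at a uniform random position; a protonation raises the site charge by
one and deletes a uniformly chosen free H⁺ (rejected outright when none
exists).  Moves are accepted with

    P_acc = min[1, exp(−βΔU + ξ (pH − pK_A) ln 10)],    ξ = ±1,

where ΔU is the full electrostatic + excluded-volume energy change
(computed incrementally and verified against the total-energy difference
to machine precision in the tests).  In the non-interacting limit this
acceptance rule reproduces the Henderson–Hasselbalch isotherm exactly,
which the test suite uses as an analytic oracle.

Two design choices deserve comment:

- **Proposal scheme.**  A site is chosen uniformly; the reaction
  direction is then drawn 50/50 and the proposal is discarded if the
  site is not in the matching state.  The obvious alternative — letting
  the current state dictate the direction — creates a deterministic
  period-2 chain whenever every compatible proposal is accepted (ΔU = 0
  at pH = pK_A), which aliases with any fixed sampling stride.  The
  symmetric scheme has the same stationary distribution and stays
  aperiodic.
- **Initial state and electroneutrality.**  The box starts from the
  fully protonated state (acids neutral, bases ionised) accompanied by
  one fixed monovalent anion per basic side chain — the counterions that
  a peptide salt brings along in experiment.  Reaction moves conserve
  the box charge exactly, and with this reference state the free-H⁺
  inventory is n_H = (ionised acids) + (neutral bases) ≥ 0, so every
  physical ionisation state is reachable.  (Starting instead from the
  fully ionised state would make the low-pH states unreachable: nothing
  negative would exist to balance a net-positive peptide.)  Added salt —
  100 pairs for the reference box — sits on top of these counterions.

Between Monte Carlo blocks the coordinates evolve by velocity-Verlet
Langevin dynamics (δt = 0.01 τ, γ = 1 τ⁻¹, T = 300 K; friction and the
fluctuation–dissipation-matched random kicks enter the force on both
half steps, so γ = 0 recovers plain velocity Verlet).  A production
cycle is 10 reaction moves followed by 100 MD steps; observables are
recorded once per cycle after the MD block; the first 20 % of cycles are
discarded as equilibration.  Newly inserted ions receive
Maxwell–Boltzmann velocities.  A single seeded generator drives every
stochastic element, making runs bit-reproducible.

## Reference systems

The built-in catalogue holds ten systems: five acid/base pairings
spanning ΔpK_A = pK_A(base) − pK_A(acid) from −4.07 (Tyr/His) through 0
(hypothetical a/b) to +6.89 (Lys/Asp), each as a diblock (e.g.
KKKKKDDDDD) and an alternating (KDKDKDKDKD) decapeptide, with 10 chains,
100 salt pairs and box edge 25.512 nm — i.e. 5 mM of each ionisable
species and 10 mM added salt.  (The printed reference edge, 25.513 nm,
corresponds to a truncated Avogadro constant; with the exact SI value 50
groups at 5 mM give 25.51231 nm.  We keep the exact constant and treat
the two as equal within 10⁻³ nm.)  A chain-length family Lysₙ–Aspₙ /
(Lys–Asp)ₙ rescales the box ∝ N^{1/3} and the salt count ∝ volume so
both concentrations are held fixed; whether the original study rescaled
salt this way is not stated, so it is configurable.

Initial configurations grow each chain as an off-lattice random walk
with all bonds at rest length, rejecting placements closer than 0.8 σ to
any placed bead (where a single WCA pair would exceed ~50 k_BT); ions
are placed uniformly with the same clearance.

## Observables and errors

Net charge per chain, per-species ionisation degrees, end-to-end
distance R_e (first to last backbone bead) and radius of gyration R_g
(all beads of a chain; a backbone-only variant is available since the
convention is not fixed by the model) are computed from unwrapped
coordinates via per-particle periodic image counters.  Monte Carlo
series are strongly autocorrelated, so standard errors are corrected
with the integrated autocorrelation time τ_int (sum of the
autocorrelation function truncated at its first non-positive estimate),
SE = s√(2 τ_int / N); a blocking (batch-means) estimator is provided as
a cross-check and the two agree within 20 % on well-behaved series.
Curves report ±1 SE; acceptance checks use 3 SE.

## Data-reduction formulas

For potentiometric titrations the peptide charge follows from the proton
balance
z = [V_HCl c_HCl − V_NaOH c_NaOH + (c_OH − c_H)(V_HCl + V_NaOH)] /
(c_peptide V_HCl) + z_max x_TFA, with c_H = 10^(−pH), c_OH = 10^(pH−pK_w)
and pK_w = 13.997 at 25 °C by default (user-overridable; the balance is
temperature-sensitive through pK_w and trusted only for 3 < pH < 11).
The trifluoroacetate mole fraction x_TFA enters affinely with slope
z_max, so anchoring the curve to a known charge at one pH (charge at
pH 6, or the +z_max plateau at pH 5) determines it in closed form.
Activities are replaced by concentrations throughout, consistent with
the balance's form.  NMR ionisation degrees are affine in the chemical
shift between the two plateaus, α_base = (δ_max − δ)/(δ_max − δ_min) and
α_acid = 1 − α_base; values leaving [0, 1] through plateau noise are
clipped and flagged.

Synthetic experimental records invert these formulas from a known ground
truth (the balance is linear in V_NaOH), optionally adding Gaussian pH
or shift noise, so both reducers are validated by exact round trips.

## What the synthetic data does and does not emulate

The generators reproduce the *structure* of the real inputs — system
compositions at the stated concentrations, titrant-volume/pH pairs,
chemical-shift series with plateaus — with exactly known ground truth.
They do not emulate electrode drift, CO₂ uptake, activity corrections,
peak overlap in crowded spectra, or pK_A shifts from neighbouring
residues (the study itself reports such shifts between simulated and
measured curves).  Passing round-trip tests therefore validates the
algebra and the pipeline, not instrument physics.

## Desk-scale test protocol

The reference protocol (10 chains, 10⁵ cycles per pH) is the package
default for production use.  The test suite runs scaled-down versions
chosen once as a compromise between statistical resolution and a test
run that completes on one CPU: one chain at the same concentrations
(box rescaled accordingly), 3×10³ cycles for the qualitative
charge-regulation and conformation checks, and 10⁴ cycles for the
non-interacting analytic oracles.  Qualitative findings are asserted as
inequalities with 3 SE slack; at these sizes the directional effects
(suppressed/enhanced ionisation, R_e minimum near the isoelectric
point, alternating chains more stretched than diblocks at extreme pH)
are well resolved, but quantitative curve shapes are noisier than the
reference figures and are not asserted numerically.

## Numerical choices and edge cases

- Isoelectric points are found by bracketing root search (Brent) on
  [min pK_A − 10, max pK_A + 10]; the ideal net charge is strictly
  decreasing in pH so the root is unique; tolerance 10⁻⁸ in |z|.
  Compositions with only acids or only bases have no root and are
  rejected.
- Exact particle overlaps during an insertion proposal are rejected via
  an effectively infinite energy rather than propagating a division by
  zero.
- An MD displacement larger than L/2 in a single step aborts the run
  with a diagnostic (unstable configuration) since minimum-image
  bookkeeping would silently corrupt distances.
- Constant observable series report SE = 0 with τ_int undefined.
- The H⁺ insertion has no volume-scaling factor in the acceptance rule;
  the chemical potential of the proton is wholly absorbed into the
  (pH − pK_A) term, following the standard constant-pH convention.  The
  free "H⁺" is a generic monovalent cation; no H⁺/OH⁻ recombination is
  modelled, and the nominal box pH is an ensemble parameter, not the
  concentration of these ions.

## Known limitations

- No activity corrections or ionic-strength-dependent pK_A; terminal
  groups are treated as capped (no terminal amine/carboxyl titration).
- The constant-pH scheme does not reproduce the true ionic-strength
  contribution of H⁺/OH⁻ at extreme pH; grand-reaction variants exist
  but are out of scope.
- Direct Ewald scales as O(N²)–O(N·N_k); fine for the catalogue systems,
  not intended for thousands of particles.
- Single-chain test runs cannot show inter-chain association effects
  (e.g. coacervate-like clustering of long diblocks at the isoelectric
  point); the catalogue defaults (10 chains) do.
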