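# Methods

## Free-energy analysis of binding kinetics

For a bimolecular association A + B ⇌ AB with association rate constant
k_on and dissociation rate constant k_off, a mutation's effect is expressed
as two free-energy differences (mutant minus wild type, destabilisation
positive):

    ΔΔG_TS = −R T ln(k_on,mut / k_on,wt)
    ΔΔG_Eq =  R T ln(K_d,mut / K_d,wt),   K_d = k_off / k_on

The binding Φ value, Φ_b = ΔΔG_TS / ΔΔG_Eq, estimates the fraction of the
mutated residue's native interaction free energy already present in the
transition state; the Brønsted (Leffler) slope α of ΔΔG_TS against ΔΔG_Eq
over a mutant panel is the global analogue.  Double-mutant-cycle coupling
energies ΔΔΔG_C = ΔΔG_Eq(AB) − ΔΔG_Eq(A) − ΔΔG_Eq(B) quantify energetic
non-additivity between one mutation in each chain.

Conventions and defaults:

* R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹; default temperature 277 K (the
  stopped-flow condition of the packaged dataset), overridable per record.
* Units follow experimental practice: k_on in μM⁻¹ s⁻¹, k_off in s⁻¹, K_d
  in nM, energies in kcal mol⁻¹.
* Φ_b is refused when |ΔΔG_Eq| < 0.18 kcal mol⁻¹ (configurable): the ratio
  of two near-zero numbers is dominated by noise.  Reported Φ_b values are
  binned into low [0, 0.3), intermediate [0.3, 0.6) and high [0.6, 1]
  categories, the resolution Φ analysis actually supports.
* Errors are propagated to first order (delta method) assuming independent
  errors on k_on and K_d; correlations between them are not reported
  experimentally and are ignored.  The test suite validates this
  propagation against 10⁴-draw Monte-Carlo resampling to 10%.
* The Brønsted fit is unweighted with a free intercept.  Weighted and
  through-origin variants exist behind flags, but the headline statistics
  are defined under the default; when the ΔΔG_Eq spread is below
  0.2 kcal mol⁻¹ the slope SE is inflated and a warning raised.

## Kinetic fitting

Traces F(t) = F_∞ + Σ_p A_p e^(−k_p t) (one or two phases) are fitted by
bounded nonlinear least squares; rate initialisation is deterministic
(log-spaced guesses from the trace's 10–90% decay times) so fits are
reproducible.  A fit whose amplitude is indistinguishable from the residual
noise (|A| ≤ 3σ_res) is flagged unidentifiable rather than silently
returned.  k_obs vs concentration uses the reversible bimolecular solution

    k_obs = √(k_on²(A₀−B₀)² + 2 k_on k_off (A₀+B₀) + k_off²)

rather than the pseudo-first-order line, because the standard design here
(~1 μM probe, 1–12 μM titrant) violates strict pseudo-first-order
conditions; the linear fit is available behind a flag.  Displacement
experiments estimate k_off as the mean k_obs over an explicitly supplied
plateau window (the window is experiment-specific and is therefore a
required input), with the standard deviation of those points as the error
and a t-test warning when the plateau still has a slope.

## Native contacts and Φ restraints

A native contact between residues i and j (|i−j| ≥ 2 within a chain; all
inter-chain pairs eligible) is the set of side-chain heavy-atom *pairs* —
one atom from each residue — within 0.65 nm in the native structure.
Counting pairs (rather than atoms) makes the per-residue fraction well
defined; it is the standard restrained-simulation Φ definition.  In a
conformer, a native pair is formed iff the same two atoms are within the
same cutoff (a tolerance multiplier is exposed in config, default 1.0), and

    Φ(residue) = formed native pairs involving it / all its native pairs.

Residues with no side-chain heavy atoms (Gly) have undefined Φ and are
excluded from restraint sums with a warning.  The restraint pseudo-energy
is E = k Σᵢ (Φ_sim,i − Φ_exp,i)², with analytic gradient 2k(Φ_sim−Φ_exp);
only experimental values in [0, 1] are admissible as restraints (outside
that range Φ is not interpretable as a contact fraction).  The force
constant k is not experimentally determined; the default 500 kcal mol⁻¹
per squared Φ unit pins sampled Φ within ~0.05 of the target in the toy
sampler and is a tuning parameter, not a physical claim.

The restraint is applied per conformer (each sampled configuration is
pushed toward the target Φ); an ensemble-averaged-restraint mode is
possible within the same energy interface but is not the default.

## Desk-scale restrained annealing

The original protocol — restrained molecular dynamics with simulated
annealing between 298 and 383 K over 1340 cycles, retaining the
reference-temperature structure of each of the last 1000 cycles — is
reproduced at desk scale by Metropolis Monte Carlo on a coarse-grained
model: one bead per residue at the side-chain centroid, harmonic virtual
bonds (0.38 nm between consecutive beads), soft-sphere excluded volume
(0.35 nm), and an optional square-well attraction on native bead pairs.
Φ for bead models reuses the all-atom contact code path on the centroid
sites with the same 0.65 nm cutoff — an approximation of the all-atom
definition, documented as such.

Schedule semantics are preserved: within each cycle the temperature ramps
piecewise-linearly T_ref → T_max → T_ref (the ramp shape is our choice and
config-exposed; only the endpoints are prescribed), the configuration at
the final reference-temperature step of the cycle is recorded, and the
retained samples of the last `n_retain` post-burn-in cycles form the
ensemble.  A "150 ps" MD cycle has no MC equivalent; `steps_per_cycle` is
an explicit stand-in (default 10⁴ moves).  Moves are single-bead
displacements, crankshaft rotations and rigid-body chain
translations/rotations (weights 0.6/0.2/0.2), all chain-topology
preserving.  Runs are bit-reproducible for a fixed seed.

Sampler correctness is established independently of any annealing result:
a single harmonic coordinate reproduces the equipartition variance
k_B T / k_spring within 10%, variance is linear in T, and a two-state toy
system visits states in Boltzmann proportion.

Test and acceptance runs use a 1/10-scaled schedule (134 cycles, 34
burn-in, retain 100; 300 moves/cycle) on 12-bead two-chain systems — sizes
chosen so the statistical contracts (recovery of Φ_exp = 1 to ensemble
mean ≥ 0.8; strictly larger pairwise-RMSD spread under intermediate
restraints) are well resolved.

## Ensemble analytics

* **Rg**: mass-weighted by default (element masses; unknown elements 12 u).
* **Pairwise RMSD**: optimal superposition by Kabsch SVD with the
  determinant sign fix; the residual is computed from rotated coordinates,
  which avoids the catastrophic cancellation of the singular-value
  shortcut near RMSD 0.  An independent quaternion (Horn) implementation
  serves as the oracle in tests.
* **Contact probability maps**: P(i,j) = fraction of conformers in which
  residues i, j share ≥ 1 side-chain heavy-atom pair within the cutoff,
  over all eligible residue pairs (so non-native contacts appear);
  symmetric, with the native-vs-ensemble split-diagonal view a plotting
  concern only.
* **Helicity**: internal Kabsch–Sander minimal rule.  Backbone hydrogen
  bonds are scored with E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
  kcal/mol (distances in Å), E < −0.5 kcal/mol; the amide H is built
  geometrically (0.101 nm from N, opposite the C(prev)/Cα bisector) when
  absent; a residue is helical inside two consecutive i→i+4 turns.  This
  reproduces full DSSP on ideal geometries, which is what the tests
  assert; the 8-state alphabet and solvent accessibility are out of scope.
* **Clustering**: GROMOS-style greedy leader algorithm on the RMSD matrix;
  the first-half vs full comparison is the convergence diagnostic.

## Synthetic data

Generators provide every input with machine-readable ground truth:

* **Traces**: exponential decays at the reversible-binding k_obs for known
  k_on/k_off with additive Gaussian noise (default 1% of amplitude,
  1–12 μM titration of a 1 μM probe — the standard experimental design).
* **Panels**: background × probe rate tables built so ΔΔG_TS = α·ΔΔG_Eq
  (+ intercept) exactly, realised through k_on/k_off with K_d = k_off/k_on
  exact before noise.  Rate noise is log-normal (multiplicative) because
  rate-constant errors are roughly proportional; σ is set on the log scale.
* **Ensembles**: a two-chain "contact ladder" in which residue i of chain A
  contacts only residue i of chain B (0.45 nm formed / 0.95 nm broken,
  0.5 nm along-chain spacing keeps all other pairs outside the cutoff), so
  prescribed per-pair formation probabilities are realised exactly
  independently and all contact/Φ statistics have closed-form (binomial)
  expectations.  Ideal α-helix and extended-chain builders (NeRF
  construction from standard backbone geometry, φ/ψ = −57/−47 or 180/180)
  supply the secondary-structure tests.

What the generators do **not** emulate: realistic unfolded-state polymer
statistics, correlated contact formation, force-field-quality energetics,
or instrument artefacts (dead time, photobleaching).  Passing tests
therefore demonstrate correctness of the estimators and samplers under
their stated models, not the accuracy of any specific experimental
ensemble.

## Degenerate inputs and numerical choices

Empty or malformed PDB records raise a parse error naming the offending
line; all-Gly structures yield an empty contact set with a warning rather
than an error; undefined Φ is an explicit flag (NaN + mask), never a
silent zero.  Coordinates are stored in nm internally (the contact cutoff
is stated in nm) and converted from/to Å at the PDB boundary; residue
identity is (chain, author residue number), never renumbered.  K_d is
back-filled as k_off/k_on (×10³ for μM→nM) only when a table row omits it;
measured K_d values take precedence when present.

## Known limitations

* The all-atom, explicit-solvent restrained-MD ensemble is out of scope by
  design; the coarse sampler shares restraint and schedule semantics, not
  force-field realism.
* Per-residue Φ in small bead models is a ratio of small integers, so
  intermediate restraint targets may sit between achievable levels; the
  ensemble mean then converges to the nearest achievable value.
* The full published double-mutant kinetic dataset is not redistributable
  here; the per-background Brønsted median analysis runs on it when a user
  supplies `data/supporting_kinetics.csv` (standard rate-table schema) and
  is otherwise exercised on synthetic panels.
* The packaged Φ-restraint table contains only the three main-text values
  and is a synthetic stand-in for the full experimental restraint set.
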