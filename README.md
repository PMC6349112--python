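# tsphi — transition-state analysis of coupled binding and folding

Many intrinsically disordered proteins (IDPs) fold only upon binding a
partner.  The transition state (TS) of such a coupled binding-and-folding
reaction cannot be observed directly; it is characterised kinetically, by
measuring how mutations perturb the association rate constant relative to
the binding equilibrium.  `tsphi` implements that analysis end to end for
two-chain systems such as the ACTR–NCBD complex (two IDP domains that each
form three α-helices on binding):

* **Stopped-flow kinetics** — single/double exponential trace fitting, the
  reversible bimolecular binding fit of k_obs vs concentration
  (`k_obs = √(k_on²(A₀−B₀)² + 2k_on k_off(A₀+B₀) + k_off²)`), and plateau
  k_off from displacement experiments.
* **Linear free-energy relationships** — from rate constants,
  `ΔΔG_TS = −RT ln(k_on,mut/k_on,wt)` and `ΔΔG_Eq = RT ln(K_d,mut/K_d,wt)`;
  the binding Φ value `Φ_b = ΔΔG_TS/ΔΔG_Eq` (fraction of a residue's native
  interaction free energy present in the TS), Brønsted/Leffler slopes α
  across mutant panels, and double-mutant-cycle coupling energies
  `ΔΔΔG_C = ΔΔG_Eq(AB) − ΔΔG_Eq(A) − ΔΔG_Eq(B)`.
* **Φ-restrained ensemble sampling** — native contacts defined as
  side-chain heavy-atom pairs within 0.65 nm (non-nearest-neighbour
  residues), per-residue Φ as the fraction of native contacts formed, a
  squared-deviation restraint pseudo-energy `E = k Σᵢ (Φ_sim,i − Φ_exp,i)²`,
  and a desk-scale Metropolis simulated-annealing sampler (coarse-grained
  bead-per-residue chains, 298→383 K cycles, retain the reference-
  temperature sample of each post-burn-in cycle).
* **Ensemble analytics** — contact probability maps, radius of gyration,
  Kabsch-superposition pairwise RMSD, an internal Kabsch–Sander-style
  α-helix assignment, and GROMOS-style leader clustering with a
  first-half/full convergence check.

A packaged rate-constant table for wild-type and point mutants of the
ACTR–NCBD pair (stopped-flow, 277 K) serves as the worked dataset, and a
synthetic-data module generates every other input with known ground truth.

## Worked example

```python
import tsphi as T

records = T.load_table1()
lut = {(r.actr_variant, r.ncbd_variant, r.condition): r for r in records}

wt_tmao = lut[("WT", "Y2108W", "TMAO")]     # pseudo-wild-type, 0.7 M TMAO
a2098g  = lut[("WT", "A2098G", "TMAO")]     # probes helix 3 of NCBD

ddg = T.ddg_from_rates(wt_tmao, a2098g)     # 277 K
phi = T.phi_b(ddg)
print(f"ddG_TS = {ddg.ddG_TS:.3f} kcal/mol, ddG_Eq = {ddg.ddG_Eq:.3f} kcal/mol")
print(f"Phi_b  = {phi.value:.3f} +- {phi.error:.3f}  ({phi.category})")
```

prints

```
ddG_TS = 0.569 kcal/mol, ddG_Eq = 1.246 kcal/mol
Phi_b  = 0.457 +- 0.057  (intermediate)
```

i.e. the A2098G mutation destabilises the transition state by roughly half
of its equilibrium effect — helix 3 of NCBD is about half-formed at the
rate-limiting barrier.  Running `python analysis/03_phi_values.py` produces
the full table: one more computable Φ_b (T2073A, 0.476, intermediate) and
five mutants excluded by the |ΔΔG_Eq| < 0.18 kcal/mol significance rule.

## Analysis pipeline

The numbered scripts under `analysis/` run the study end to end on packaged
and synthetic inputs, writing tables under `results/`:

1. `01_simulate_kinetics.py` — synthetic stopped-flow titration → k_obs table
2. `02_fit_rate_constants.py` — reversible-binding fit → k_on, k_off, K_d
3. `03_phi_values.py` — mutant table → ΔΔG, Φ_b, significance exclusions
4. `04_bronsted_coupling.py` — double-mutant panel → per-background α,
   Φ_b background comparison, coupling energies
5. `05_ts_ensemble.py` — Φ-restrained annealing → TS-like ensemble and its
   structural descriptors (Rg, RMSD spread, contact map, clusters)

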