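"""Phi-restrained simulated annealing of a coarse-grained chain system.

The transition-state ensemble protocol — anneal between a reference and a
high temperature over many cycles under a force field plus the squared
Phi-deviation pseudo-energy, retaining the reference-temperature sample at
the end of each post-burn-in cycle — is reproduced here on a bead-per-residue
model sampled with Metropolis Monte Carlo.  This is a desk-scale sampler with
the same restraint and schedule semantics, not a replication of all-atom
explicit-solvent dynamics.

The model places one interaction site per residue at the side-chain centroid;
the base potential has harmonic virtual bonds (0.38 nm between consecutive
beads of a chain), soft-sphere excluded volume, and an optional square-well
attraction on native bead pairs.  Phi uses the same native-contact semantics
as the all-atom definition, applied to bead sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .constants import R_KCAL
from .structure import Structure, Ensemble
from .contacts import (NativeContactSet, PhiRestraintSet,
                       build_native_contacts, DEFAULT_CUTOFF)


@dataclass
class SamplerConfig:
    """Annealing schedule and move-set parameters.

    Defaults mirror the full protocol (1340 cycles between 298 and 383 K,
    retaining the reference-temperature samples of the latter 1000 cycles);
    desk-scale runs pass a scaled-down config.
    """

    T_ref: float = 298.0
    T_max: float = 383.0
    n_cycles: int = 1340
    burn_in_cycles: int = 340
    n_retain: int = 1000
    steps_per_cycle: int = 10_000
    seed: int = 0
    move_weights: tuple[float, float, float] = (0.6, 0.2, 0.2)
    # (single-bead, crankshaft, rigid chain translate/rotate)
    bead_step_nm: float = 0.08
    chain_step_nm: float = 0.15
    max_rot_rad: float = 0.3

    def __post_init__(self) -> None:
        if not (self.T_max >= self.T_ref > 0):
            raise ValueError("require T_max >= T_ref > 0")
        if self.n_retain > self.n_cycles - self.burn_in_cycles:
            raise ValueError("n_retain exceeds post-burn-in cycle count")

    def temperature(self, step: int) -> float:
        """Piecewise-linear ramp within one cycle: T_ref -> T_max -> T_ref."""
        n = self.steps_per_cycle
        half = n / 2.0
        frac = step / half if step <= half else (n - step) / half
        return self.T_ref + (self.T_max - self.T_ref) * frac


@dataclass
class CoarseModel:
    """Bead-per-residue model: positions (nm), chain labels, base potential."""

    positions: np.ndarray         # (n, 3) reference/native bead coordinates
    chain_id: np.ndarray          # (n,) str
    res_id: np.ndarray            # (n,) int
    bond_length: float = 0.38
    k_bond: float = 200.0         # kcal/mol/nm^2
    excluded_radius: float = 0.35  # nm
    k_rep: float = 100.0
    native_well_depth: float = 0.0  # kcal/mol; >0 switches on Go-like wells
    contact_cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.chain_id = np.asarray(self.chain_id)
        self.res_id = np.asarray(self.res_id, dtype=int)
        n = len(self.positions)
        if not (len(self.chain_id) == len(self.res_id) == n):
            raise ValueError("length mismatch")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def bonds(self) -> np.ndarray:
        """(m, 2) consecutive bead pairs within each chain."""
        idx = np.arange(self.n_beads - 1)
        same = self.chain_id[idx] == self.chain_id[idx + 1]
        return np.stack([idx[same], idx[same] + 1], axis=1)

    def to_structure(self, positions: np.ndarray | None = None) -> Structure:
        """Bead model as a Structure (one CB pseudo-atom per residue)."""
        pos = self.positions if positions is None else positions
        n = self.n_beads
        return Structure(
            atom_name=np.array(["CB"] * n),
            element=np.array(["C"] * n),
            res_id=self.res_id.copy(),
            res_name=np.array(["ALA"] * n),
            chain_id=self.chain_id.astype(str),
            coords=np.asarray(pos, dtype=float),
        )

    def native_contacts(self, min_separation: int = 2) -> NativeContactSet:
        return build_native_contacts(self.to_structure(),
                                     cutoff=self.contact_cutoff,
                                     min_separation=min_separation)

    @classmethod
    def from_structure(cls, native: Structure, **kwargs) -> "CoarseModel":
        """Side-chain-centroid beads from an all-atom structure.

        Residues without side-chain heavy atoms use CA (or the residue
        centroid) as the site.
        """
        pos, chains, rids = [], [], []
        sc = native.is_sidechain_heavy
        for ch, ri, _ in native.residues():
            idx = native.atom_indices_of(ch, ri)
            sel = idx[sc[idx]]
            if sel.size == 0:
                ca = idx[native.atom_name[idx] == "CA"]
                sel = ca if ca.size else idx
            pos.append(native.coords[sel].mean(axis=0))
            chains.append(ch)
            rids.append(ri)
        return cls(np.array(pos), np.array(chains), np.array(rids), **kwargs)


def metropolis_accept(delta_E: float, T: float, rng: np.random.Generator) -> bool:
    """Standard Metropolis criterion with k_B T in kcal/mol (k_B = R molar)."""
    if delta_E <= 0:
        return True
    return rng.random() < np.exp(-delta_E / (R_KCAL * T))


class _EnergyModel:
    """Base + restraint energy for a bead configuration (full recompute)."""

    def __init__(self, model: CoarseModel, contacts: NativeContactSet,
                 restraints: PhiRestraintSet | None):
        self.model = model
        self.contacts = contacts
        self.bonds = model.bonds()
        n = model.n_beads
        nb = ~np.eye(n, dtype=bool)
        for i, j in self.bonds:
            nb[i, j] = nb[j, i] = False
        self.nonbonded = np.triu(nb, k=1)
        self.totals = contacts.per_residue_totals().astype(float)
        if restraints is not None:
            rkeys = contacts.residue_keys
            self.r_idx = []
            self.r_target = []
            for ch, ri, phi in restraints.entries:
                key = (str(ch), int(ri))
                if key not in rkeys:
                    raise ValueError(f"restraint on missing residue {key}")
                b = rkeys.index(key)
                if self.totals[b] == 0:
                    warnings.warn(f"residue {key} has no native contacts; "
                                  "restraint skipped")
                    continue
                self.r_idx.append(b)
                self.r_target.append(phi)
            self.r_idx = np.array(self.r_idx, dtype=int)
            self.r_target = np.array(self.r_target, dtype=float)
            self.k_restraint = restraints.k
        else:
            self.r_idx = np.zeros(0, dtype=int)
            self.r_target = np.zeros(0)
            self.k_restraint = 0.0

    def phi_per_bead(self, dist: np.ndarray) -> np.ndarray:
        formed = np.zeros(self.model.n_beads)
        if self.contacts.n_pairs:
            pr = self.contacts.pair_res
            f = (dist[self.contacts.pair_atoms[:, 0],
                      self.contacts.pair_atoms[:, 1]]
                 <= self.contacts.cutoff).astype(float)
            np.add.at(formed, pr[:, 0], f)
            np.add.at(formed, pr[:, 1], f)
        with np.errstate(invalid="ignore"):
            return np.where(self.totals > 0, formed / np.maximum(self.totals, 1),
                            np.nan)

    def energy(self, pos: np.ndarray) -> float:
        m = self.model
        dist = squareform(pdist(pos))
        e = 0.0
        if len(self.bonds):
            db = dist[self.bonds[:, 0], self.bonds[:, 1]]
            e += m.k_bond * np.sum((db - m.bond_length) ** 2)
        dn = dist[self.nonbonded]
        overlap = m.excluded_radius - dn
        e += m.k_rep * np.sum(np.clip(overlap, 0, None) ** 2)
        if m.native_well_depth > 0 and self.contacts.n_pairs:
            dc = dist[self.contacts.pair_atoms[:, 0],
                      self.contacts.pair_atoms[:, 1]]
            e -= m.native_well_depth * np.count_nonzero(dc <= m.contact_cutoff)
        if len(self.r_idx):
            phi = self.phi_per_bead(dist)[self.r_idx]
            e += self.k_restraint * np.sum((phi - self.r_target) ** 2)
        return float(e)


def _propose(pos: np.ndarray, model: CoarseModel, cfg: SamplerConfig,
             rng: np.random.Generator) -> np.ndarray:
    new = pos.copy()
    w = np.asarray(cfg.move_weights, dtype=float)
    kind = rng.choice(3, p=w / w.sum())
    n = len(pos)
    if kind == 0:  # single-bead displacement
        i = rng.integers(n)
        new[i] += rng.normal(scale=cfg.bead_step_nm, size=3)
    elif kind == 1:  # crankshaft: rotate interior bead about neighbour axis
        interior = [i for i in range(1, n - 1)
                    if model.chain_id[i - 1] == model.chain_id[i] ==
                    model.chain_id[i + 1]]
        if not interior:
            i = rng.integers(n)
            new[i] += rng.normal(scale=cfg.bead_step_nm, size=3)
        else:
            i = interior[rng.integers(len(interior))]
            a, b = pos[i - 1], pos[i + 1]
            axis = b - a
            norm = np.linalg.norm(axis)
            if norm < 1e-9:
                new[i] += rng.normal(scale=cfg.bead_step_nm, size=3)
            else:
                axis /= norm
                theta = rng.uniform(-cfg.max_rot_rad, cfg.max_rot_rad)
                v = pos[i] - a
                new[i] = a + (v * np.cos(theta)
                              + np.cross(axis, v) * np.sin(theta)
                              + axis * np.dot(axis, v) * (1 - np.cos(theta)))
    else:  # rigid-body move of one chain
        chains = np.unique(model.chain_id)
        ch = chains[rng.integers(len(chains))]
        sel = model.chain_id == ch
        if rng.random() < 0.5:
            new[sel] += rng.normal(scale=cfg.chain_step_nm, size=3)
        else:
            theta = rng.uniform(-cfg.max_rot_rad, cfg.max_rot_rad)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            Rm = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * K @ K
            com = new[sel].mean(axis=0)
            new[sel] = (new[sel] - com) @ Rm.T + com
    return new


def anneal(model: CoarseModel, restraints: PhiRestraintSet | None,
           config: SamplerConfig,
           start_positions: np.ndarray | None = None,
           ) -> tuple[Ensemble, dict]:
    """Simulated-annealing MC under base potential + Phi restraint.

    Runs ``n_cycles`` annealing cycles; within each cycle the temperature
    ramps T_ref -> T_max -> T_ref and the configuration at the final
    (reference-temperature) step is recorded.  The samples of the last
    ``n_retain`` post-burn-in cycles form the returned ensemble.  Bit
    reproducible for a fixed seed.

    Returns (ensemble, diagnostics) where diagnostics carries per-cycle
    acceptance rates, energies, and the per-cycle mean Phi trace.
    """
    contacts = model.native_contacts()
    em = _EnergyModel(model, contacts, restraints)
    rng = np.random.default_rng(config.seed)
    pos = (model.positions if start_positions is None
           else np.asarray(start_positions, dtype=float)).copy()
    e_curr = em.energy(pos)
    retained: list[Structure] = []
    acc_rates, cycle_energies, phi_trace = [], [], []
    first_retained_cycle = config.n_cycles - config.n_retain
    for cycle in range(config.n_cycles):
        n_acc = 0
        for step in range(config.steps_per_cycle):
            T = config.temperature(step + 1)
            cand = _propose(pos, model, config, rng)
            e_new = em.energy(cand)
            if metropolis_accept(e_new - e_curr, T, rng):
                pos, e_curr = cand, e_new
                n_acc += 1
        rate = n_acc / config.steps_per_cycle
        acc_rates.append(rate)
        cycle_energies.append(e_curr)
        dist = squareform(pdist(pos))
        phi = em.phi_per_bead(dist)
        phi_trace.append(float(np.nanmean(phi)))
        if rate == 0.0:
            warnings.warn(f"cycle {cycle}: zero acceptance "
                          f"(E={e_curr:.2f} kcal/mol)")
        if cycle >= max(config.burn_in_cycles, first_retained_cycle):
            retained.append(model.to_structure(pos.copy()))
    ens = Ensemble(retained[-config.n_retain:], label="TS")
    diag = {"acceptance": np.array(acc_rates),
            "energy": np.array(cycle_energies),
            "mean_phi": np.array(phi_trace)}
    return ens, diag


def boltzmann_check(k_spring: float, T: float, n_steps: int,
                    seed: int = 0, step_nm: float | None = None) -> float:
    """Sample variance of a single harmonic coordinate at temperature T.

    Correct canonical sampling gives variance ~ k_B T / k_spring
    (equipartition); used as a correctness harness for the MC engine.
    """
    rng = np.random.default_rng(seed)
    kBT = R_KCAL * T
    sigma = np.sqrt(kBT / k_spring) if kBT > 0 else 1e-3
    step = step_nm if step_nm is not None else 2.0 * sigma
    x = 0.0
    e = 0.0
    samples = np.empty(n_steps)
    for i in range(n_steps):
        xn = x + rng.normal(scale=step)
        en = 0.5 * k_spring * xn ** 2
        if en - e <= 0 or (kBT > 0 and rng.random() < np.exp(-(en - e) / kBT)):
            x, e = xn, en
        samples[i] = x
    return float(np.var(samples))
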