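"""Synthetic data with known ground truth for every pipeline stage.

Three generators mirror the experimental inputs:

* :func:`gen_traces` — stopped-flow fluorescence traces whose observed rates
  follow the reversible bimolecular binding law for known k_on/k_off, with
  additive Gaussian noise;
* :func:`gen_panel` — rate tables for background x probe mutant panels built
  so that ddG_TS = alpha_true * ddG_Eq (+ intercept), realised through
  k_on/k_off consistent with K_d, with optional log-normal rate noise
  (rate-constant errors are roughly proportional, so noise is multiplicative);
* :func:`gen_ensembles` — toy two-chain "contact ladder" ensembles in which
  each native contact forms independently with a prescribed probability, so
  contact-map and Phi statistics have closed-form expectations.

Ideal-geometry chain builders (:func:`make_ideal_helix`,
:func:`make_extended_chain`) provide backbone coordinates for the secondary
structure assignment tests.  Every generator is bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import PhysicalConstants, T_DEFAULT, kd_nM
from .io import RateConstants
from .kinetics import KineticTrace, ObservedRates, kobs_reversible
from .structure import Structure, Ensemble

_PC = PhysicalConstants()


# ---------------------------------------------------------------------------
# Kinetic traces
# ---------------------------------------------------------------------------

@dataclass
class KineticsScenario:
    """Ground truth for one variant pair's stopped-flow experiment.

    Defaults emulate the standard design: ~1 uM probe, titrant 1-12 uM,
    1% amplitude noise.
    """

    kon: float = 21.3          # uM^-1 s^-1
    koff: float = 2.2          # s^-1
    probe_uM: float = 1.0
    conc_uM: tuple = (1, 2, 4, 6, 8, 10, 12)
    noise_sigma: float = 0.01  # fraction of amplitude
    amplitude: float = 1.0
    offset: float = 0.1
    n_points: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kon <= 0 or self.koff <= 0:
            raise ValueError("rate constants must be positive")


def gen_traces(scenario: KineticsScenario,
               ) -> tuple[list[KineticTrace], ObservedRates]:
    """Synthetic traces plus the ground-truth observed rates."""
    rng = np.random.default_rng(scenario.seed)
    conc = np.asarray(scenario.conc_uM, dtype=float)
    kobs = kobs_reversible(conc, scenario.kon, scenario.koff, scenario.probe_uM)
    traces = []
    for c, k in zip(conc, kobs):
        t = np.linspace(0, 5.0 / k, scenario.n_points)
        signal = scenario.offset + scenario.amplitude * np.exp(-k * t)
        signal += rng.normal(scale=scenario.noise_sigma * scenario.amplitude,
                             size=t.size)
        traces.append(KineticTrace(t, signal, meta={"conc_uM": float(c),
                                                    "kobs_true": float(k)}))
    return traces, ObservedRates(conc, kobs)


# ---------------------------------------------------------------------------
# Mutant panels
# ---------------------------------------------------------------------------

@dataclass
class PanelScenario:
    """Background x probe panel with a prescribed Bronsted slope.

    ``backgrounds`` and ``probes`` map variant name -> true ddG_Eq
    (kcal/mol); contributions are additive in free energy.  ``side`` names
    the protein carrying the background mutations.  ``noise_sigma_log`` is
    the s.d. of multiplicative log-normal noise applied to both rate
    constants after construction.
    """

    backgrounds: dict = field(default_factory=lambda: {"WTB": 0.0})
    probes: dict = field(default_factory=lambda: {
        "M1": 0.4, "M2": 0.8, "M3": 1.2, "M4": 1.6, "M5": -0.5})
    alpha: float = 0.23
    intercept: float = 0.0
    side: str = "ncbd"
    kon0: float = 21.3
    koff0: float = 2.2
    noise_sigma_log: float = 0.0
    temperature: float = T_DEFAULT
    seed: int = 0
    probe_ref: str = "WT"
    background_ref: str = "WTB"


def gen_panel(scenario: PanelScenario) -> tuple[list[RateConstants], dict]:
    """Full cross rate table plus the truth sidecar.

    Every (probe, background) combination — including the references — gets
    a record whose noise-free rates satisfy ddG_TS = alpha * ddG_Eq +
    intercept relative to the reference pair, with K_d = k_off/k_on exact
    before noise.
    """
    rng = np.random.default_rng(scenario.seed)
    RT = _PC.RT(scenario.temperature)
    records = []
    truth = {"alpha": scenario.alpha, "intercept": scenario.intercept,
             "pairs": {}}
    probes = {scenario.probe_ref: 0.0, **scenario.probes}
    backgrounds = {scenario.background_ref: 0.0, **scenario.backgrounds}
    for bg, ddg_bg in backgrounds.items():
        for probe, ddg_pr in probes.items():
            ddg_eq = ddg_bg + ddg_pr
            ddg_ts = scenario.alpha * ddg_eq + (
                scenario.intercept if ddg_eq != 0.0 else 0.0)
            kon = scenario.kon0 * np.exp(-ddg_ts / RT)
            kd = kd_nM(scenario.kon0, scenario.koff0) * np.exp(ddg_eq / RT)
            koff = kon * kd / 1e3  # nM -> uM
            if scenario.noise_sigma_log > 0:
                kon *= np.exp(rng.normal(scale=scenario.noise_sigma_log))
                koff *= np.exp(rng.normal(scale=scenario.noise_sigma_log))
            actr, ncbd = (probe, bg) if scenario.side == "ncbd" else (bg, probe)
            rel = scenario.noise_sigma_log
            records.append(RateConstants(
                actr_variant=actr, ncbd_variant=ncbd,
                kon=float(kon), koff=float(koff),
                kd=kd_nM(float(kon), float(koff)),
                kon_err=float(kon) * rel, koff_err=float(koff) * rel,
                kd_err=kd_nM(float(kon), float(koff)) * rel * np.sqrt(2),
                temperature=scenario.temperature))
            truth["pairs"][(actr, ncbd)] = {"ddG_Eq": ddg_eq, "ddG_TS": ddg_ts}
    return records, truth


# ---------------------------------------------------------------------------
# Chain geometry (NeRF construction from internal coordinates)
# ---------------------------------------------------------------------------

# bond lengths (nm) and angles (deg), standard peptide geometry
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 0.1458, 0.1525, 0.1329, 0.1231, 0.1530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position a fourth atom from bond length, angle b-c-d, dihedral a-b-c-d."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    u = c - b
    u /= np.linalg.norm(u)
    n = np.cross(b - a, u)
    n /= np.linalg.norm(n)
    m = np.cross(n, u)
    return c + bond * (-np.cos(theta) * u
                       + np.sin(theta) * (np.cos(chi) * m + np.sin(chi) * n))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees (IUPAC convention)."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def make_chain(n_res: int, phi: float, psi: float, chain_id: str = "A",
               first_res_id: int = 1, with_cb: bool = True,
               translate: np.ndarray | None = None) -> Structure:
    """Poly-residue chain with uniform backbone torsions (omega = 180)."""
    names, coords = [], []
    n = np.array([0.0, 0.0, 0.0])
    ca = n + np.array([_B_N_CA, 0.0, 0.0])
    th = np.deg2rad(_A_N_CA_C)
    c = ca + _B_CA_C * np.array([-np.cos(th), np.sin(th), 0.0])
    res_atoms = []
    for i in range(n_res):
        atoms = {"N": n, "CA": ca, "C": c}
        if with_cb:
            atoms["CB"] = _place(c, n, ca, _B_CA_CB, 110.5, 122.5)
        if i < n_res - 1:
            n_next = _place(n, ca, c, _B_C_N, _A_CA_C_N, psi)
            atoms["O"] = _place(n, ca, c, _B_C_O, _A_CA_C_O, psi + 180.0)
            ca_next = _place(ca, c, n_next, _B_N_CA, _A_C_N_CA, 180.0)
            c_next = _place(c, n_next, ca_next, _B_CA_C, _A_N_CA_C, phi)
            n, ca, c = n_next, ca_next, c_next
        else:
            atoms["O"] = _place(atoms["N"], atoms["CA"], atoms["C"],
                                _B_C_O, _A_CA_C_O, psi + 180.0)
        res_atoms.append(atoms)
    order = ["N", "CA", "C", "O"] + (["CB"] if with_cb else [])
    atom_name, element, res_id, res_name, xyz = [], [], [], [], []
    for i, atoms in enumerate(res_atoms):
        for name in order:
            atom_name.append(name)
            element.append(name[0])
            res_id.append(first_res_id + i)
            res_name.append("ALA" if with_cb else "GLY")
            xyz.append(atoms[name])
    xyz = np.array(xyz)
    if translate is not None:
        xyz = xyz + np.asarray(translate)
    return Structure(np.array(atom_name), np.array(element),
                     np.array(res_id, dtype=int), np.array(res_name),
                     np.array([chain_id] * len(atom_name)), xyz)


def make_ideal_helix(n_res: int, chain_id: str = "A", first_res_id: int = 1,
                     with_cb: bool = True,
                     translate: np.ndarray | None = None) -> Structure:
    """Ideal alpha-helix (phi = -57, psi = -47)."""
    return make_chain(n_res, -57.0, -47.0, chain_id, first_res_id, with_cb,
                      translate)


def make_extended_chain(n_res: int, chain_id: str = "A", first_res_id: int = 1,
                        with_cb: bool = True,
                        translate: np.ndarray | None = None) -> Structure:
    """Fully extended chain (phi = psi = 180)."""
    return make_chain(n_res, 180.0, 180.0, chain_id, first_res_id, with_cb,
                      translate)


def concat_structures(*parts: Structure) -> Structure:
    """Concatenate chains into one multi-chain Structure."""
    return Structure(
        np.concatenate([p.atom_name for p in parts]),
        np.concatenate([p.element for p in parts]),
        np.concatenate([p.res_id for p in parts]),
        np.concatenate([p.res_name for p in parts]),
        np.concatenate([p.chain_id for p in parts]),
        np.vstack([p.coords for p in parts]),
    )


# ---------------------------------------------------------------------------
# Toy two-chain contact-ladder ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleScenario:
    """Two parallel chains whose residue-i/residue-i contacts form independently.

    Geometry is chosen so that residue i of chain A can contact only residue
    i of chain B (0.45 nm apart when formed, ~0.95 nm when broken; 0.5 nm
    along-chain spacing keeps every other pair outside the 0.65 nm cutoff),
    making the prescribed per-pair formation probabilities exactly
    independent.
    """

    n_res: int = 10
    probs: tuple | float = 0.5
    n_conformers: int = 200
    seed: int = 0
    spacing: float = 0.5          # nm along the chain axis
    formed_distance: float = 0.45
    broken_distance: float = 0.95
    jitter: float = 0.02

    def prob_array(self) -> np.ndarray:
        p = np.full(self.n_res, self.probs) if np.isscalar(self.probs) \
            else np.asarray(self.probs, dtype=float)
        if p.shape != (self.n_res,):
            raise ValueError("probs length must equal n_res")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("formation probabilities must lie in [0, 1]")
        return p


def _ladder_structure(scn: EnsembleScenario,
                      b_offsets: np.ndarray) -> Structure:
    """Two CA+CB chains; chain B side-chain sites displaced by b_offsets (nm)."""
    n = scn.n_res
    names, elems, rids, rnames, chains, xyz = [], [], [], [], [], []
    for i in range(n):  # chain A: CB fixed, pointing toward B (+y)
        x = scn.spacing * i
        for name, pos in (("CA", (x, -0.15, 0.0)), ("CB", (x, 0.0, 0.0))):
            names.append(name); elems.append("C"); rids.append(i + 1)
            rnames.append("ALA"); chains.append("A"); xyz.append(pos)
    for i in range(n):  # chain B: CB at formed_distance + offset from A's CB
        x = scn.spacing * i
        y_cb = scn.formed_distance + b_offsets[i]
        for name, pos in (("CA", (x, y_cb + 0.15, 0.0)), ("CB", (x, y_cb, 0.0))):
            names.append(name); elems.append("C"); rids.append(i + 1)
            rnames.append("ALA"); chains.append("B"); xyz.append(pos)
    return Structure(np.array(names), np.array(elems),
                     np.array(rids, dtype=int), np.array(rnames),
                     np.array(chains), np.array(xyz, dtype=float))


def gen_ensembles(scenario: EnsembleScenario,
                  ) -> tuple[Structure, Ensemble, dict]:
    """(native structure, ensemble, truth) for a contact-ladder scenario.

    In each conformer, ladder pair i is formed (chain-B site at the native
    separation) with probability ``probs[i]`` and broken (displaced past the
    cutoff) otherwise, with small uniform jitter that never crosses the
    cutoff.
    """
    p = scenario.prob_array()
    if scenario.formed_distance + scenario.jitter >= 0.65:
        raise ValueError("formed distance + jitter crosses the contact cutoff")
    if scenario.broken_distance - scenario.jitter <= 0.65:
        raise ValueError("broken distance - jitter crosses the contact cutoff")
    rng = np.random.default_rng(scenario.seed)
    native = _ladder_structure(scenario, np.zeros(scenario.n_res))
    conformers = []
    formed_draws = rng.random((scenario.n_conformers, scenario.n_res)) < p
    jit = rng.uniform(-scenario.jitter, scenario.jitter,
                      size=(scenario.n_conformers, scenario.n_res))
    for m in range(scenario.n_conformers):
        offsets = np.where(
            formed_draws[m], jit[m],
            scenario.broken_distance - scenario.formed_distance + jit[m])
        conformers.append(_ladder_structure(scenario, offsets))
    truth = {"probs": p, "formed": formed_draws}
    return native, Ensemble(conformers, label="synthetic"), truth
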