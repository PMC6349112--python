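"""Native contacts, per-residue Phi values, and the Phi-restraint energy.

A *native contact* between two residues that are not nearest neighbours in
sequence is the set of side-chain heavy-atom pairs (one atom from each
residue) within the cutoff (0.65 nm by default) in the native structure.  The
Phi value of a residue in a conformer is the fraction of its native atom
pairs that remain within the cutoff in that conformer — 1 for fully native
packing, 0 for none.  Restraining sampled conformers by the squared
difference between simulated and experimental Phi values turns measured
binding Phi values into an effective potential that biases a simulation
toward the transition-state ensemble.

Inter-chain residue pairs are always eligible: the nearest-neighbour
exclusion removes trivially-formed covalent neighbours, which cannot occur
across chains.  Residues without side-chain heavy atoms (Gly) have no native
contacts and carry an *undefined* Phi rather than a number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure import Structure, Ensemble

DEFAULT_CUTOFF = 0.65  # nm
DEFAULT_MIN_SEPARATION = 2  # same-chain |i-j| >= 2


@dataclass
class NativeContactSet:
    """Atom-pair level native contacts of one reference structure.

    ``pair_atoms[p]`` holds the two atom indices (into the native topology)
    of native pair ``p``; ``pair_res[p]`` the indices of the two residues in
    ``residue_keys``.  The per-residue-pair contact *count* of the field's
    definition is the number of atom pairs stored for that residue pair.
    """

    cutoff: float
    min_sequence_separation: int
    residue_keys: list[tuple[str, int]]
    pair_atoms: np.ndarray  # (P, 2) int
    pair_res: np.ndarray    # (P, 2) int, canonical i < j
    atom_signature: tuple = ()  # (atom_name, chain, res_id) per native atom

    @property
    def n_pairs(self) -> int:
        return len(self.pair_atoms)

    def residue_pair_counts(self) -> dict[tuple[tuple[str, int], tuple[str, int]], int]:
        out: dict = {}
        for i, j in self.pair_res:
            key = (self.residue_keys[i], self.residue_keys[j])
            out[key] = out.get(key, 0) + 1
        return out

    def per_residue_totals(self) -> np.ndarray:
        """Number of native atom pairs involving each residue."""
        tot = np.zeros(len(self.residue_keys), dtype=int)
        if self.n_pairs:
            np.add.at(tot, self.pair_res[:, 0], 1)
            np.add.at(tot, self.pair_res[:, 1], 1)
        return tot

    def formed_mask(self, conformer: Structure, scale: float = 1.0) -> np.ndarray:
        """Boolean mask over native pairs formed in ``conformer``.

        A native atom pair counts as formed iff the *same* atoms are within
        ``scale * cutoff`` (scale defaults to 1.0: no tolerance multiplier).
        """
        if self.n_pairs == 0:
            return np.zeros(0, dtype=bool)
        d = np.linalg.norm(conformer.coords[self.pair_atoms[:, 0]]
                           - conformer.coords[self.pair_atoms[:, 1]], axis=1)
        return d <= scale * self.cutoff


@dataclass
class PhiProfile:
    """Per-residue Phi values for one conformer or an ensemble mean.

    ``phi`` is NaN where undefined (residue has no native contacts); the
    ``defined`` mask makes the distinction explicit.
    """

    residue_keys: list[tuple[str, int]]
    native_total: np.ndarray
    formed: np.ndarray
    phi: np.ndarray
    scope: str = "conformer"

    @property
    def defined(self) -> np.ndarray:
        return self.native_total > 0

    def value(self, chain: str, res_id: int) -> float:
        i = self.residue_keys.index((chain, res_id))
        return float(self.phi[i])

    def as_dict(self) -> dict[tuple[str, int], float]:
        return {k: float(p) for k, p, d in
                zip(self.residue_keys, self.phi, self.defined) if d}


@dataclass
class PhiRestraintSet:
    """Experimental binding Phi values and the restraint force constant.

    ``k`` (kcal mol^-1 per squared Phi unit) sets how strongly sampled
    conformers are pinned to the experimental values; default 500.
    """

    entries: list[tuple[str, int, float]]
    k: float = 500.0

    def __post_init__(self) -> None:
        for ch, ri, phi in self.entries:
            if not 0.0 <= phi <= 1.0:
                raise ValueError(
                    f"restraint ({ch}, {ri}): Phi {phi} outside [0, 1]; only "
                    "values in [0, 1] are interpretable as contact fractions")

    def keys(self) -> list[tuple[str, int]]:
        return [(ch, ri) for ch, ri, _ in self.entries]

    def targets(self) -> np.ndarray:
        return np.array([phi for _, _, phi in self.entries])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_native_contacts(native: Structure,
                          cutoff: float = DEFAULT_CUTOFF,
                          min_separation: int = DEFAULT_MIN_SEPARATION,
                          ) -> NativeContactSet:
    """Enumerate all native side-chain heavy-atom contact pairs.

    Exhaustive over every eligible residue pair: different residues, and for
    same-chain pairs ``|res_id_i - res_id_j| >= min_separation``.
    """
    rkeys = native.residue_keys()
    if len(rkeys) < 2:
        raise ValueError("need at least 2 residues")
    rindex = {k: i for i, k in enumerate(rkeys)}

    sc = np.flatnonzero(native.is_sidechain_heavy)
    if sc.size == 0:
        warnings.warn("no side-chain heavy atoms (all-Gly input?); "
                      "returning empty contact set")
        return NativeContactSet(cutoff, min_separation, rkeys,
                                np.zeros((0, 2), int), np.zeros((0, 2), int),
                                _atom_signature(native))

    res_of = np.array([rindex[(str(c), int(r))]
                       for c, r in zip(native.chain_id[sc], native.res_id[sc])])
    chain_of = native.chain_id[sc]
    seq_of = native.res_id[sc].astype(int)

    d = cdist(native.coords[sc], native.coords[sc])
    same_chain = chain_of[:, None] == chain_of[None, :]
    sep = np.abs(seq_of[:, None] - seq_of[None, :])
    eligible = (res_of[:, None] != res_of[None, :]) & \
               (~same_chain | (sep >= min_separation))
    ai, aj = np.nonzero(eligible & (d <= cutoff))
    keep = ai < aj  # each unordered atom pair once
    ai, aj = ai[keep], aj[keep]

    ri, rj = res_of[ai], res_of[aj]
    swap = ri > rj
    ri2 = np.where(swap, rj, ri)
    rj2 = np.where(swap, ri, rj)
    a1 = np.where(swap, aj, ai)
    a2 = np.where(swap, ai, aj)
    order = np.lexsort((a2, a1, rj2, ri2))
    pair_atoms = np.stack([sc[a1[order]], sc[a2[order]]], axis=1)
    pair_res = np.stack([ri2[order], rj2[order]], axis=1)
    if len(pair_atoms) == 0:
        warnings.warn("no native contacts found under cutoff")
    return NativeContactSet(cutoff, min_separation, rkeys,
                            pair_atoms.astype(int), pair_res.astype(int),
                            _atom_signature(native))


def _atom_signature(s: Structure) -> tuple:
    return tuple(zip(s.atom_name.tolist(),
                     s.chain_id.astype(str).tolist(),
                     s.res_id.astype(int).tolist()))


def _check_topology(conformer: Structure, native: NativeContactSet) -> None:
    if conformer.residue_keys() != native.residue_keys:
        raise ValueError("conformer topology does not match native contact set")
    if native.atom_signature:
        sig = _atom_signature(conformer)
        if len(sig) != len(native.atom_signature):
            raise ValueError(
                f"atom count differs: {len(sig)} vs {len(native.atom_signature)}")
        for i, (a, b) in enumerate(zip(sig, native.atom_signature)):
            if a != b:
                raise ValueError(f"topology mismatch at atom {i}: {a} vs {b}")


def phi_profile(conformer: Structure, native: NativeContactSet,
                formed_scale: float = 1.0) -> PhiProfile:
    """Per-residue fraction of native atom pairs formed in ``conformer``."""
    _check_topology(conformer, native)
    total = native.per_residue_totals()
    formed = np.zeros_like(total, dtype=float)
    mask = native.formed_mask(conformer, scale=formed_scale)
    if native.n_pairs:
        np.add.at(formed, native.pair_res[:, 0], mask.astype(float))
        np.add.at(formed, native.pair_res[:, 1], mask.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(total > 0, formed / np.maximum(total, 1), np.nan)
    return PhiProfile(native.residue_keys, total, formed, phi, scope="conformer")


def ensemble_phi(ensemble: Ensemble, native: NativeContactSet,
                 formed_scale: float = 1.0) -> PhiProfile:
    """Per-residue mean of per-conformer Phi over the ensemble."""
    profiles = [phi_profile(c, native, formed_scale) for c in ensemble]
    total = native.per_residue_totals()
    phis = np.stack([p.phi for p in profiles])
    formed = np.stack([p.formed for p in profiles]).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        phi = np.nanmean(phis, axis=0)
    return PhiProfile(native.residue_keys, total, formed, phi,
                      scope="ensemble mean")


def restraint_energy(phi_sim: PhiProfile, restraints: PhiRestraintSet,
                     ) -> tuple[float, np.ndarray]:
    """Pseudo-energy ``k * sum_i (Phi_sim,i - Phi_exp,i)^2`` and its gradient.

    Returns the energy (kcal mol^-1) and dE/dPhi_sim,i for each restrained
    residue, in restraint order.  Restrained residues whose simulated Phi is
    undefined are an error (they cannot contribute a deviation).
    """
    keys = restraints.keys()
    idx = []
    missing, undefined = [], []
    for key in keys:
        try:
            i = phi_sim.residue_keys.index(key)
        except ValueError:
            missing.append(key)
            continue
        if not phi_sim.defined[i]:
            undefined.append(key)
        idx.append(i)
    if missing:
        raise ValueError(f"restrained residues absent from topology: {missing}")
    if undefined:
        raise ValueError(
            f"restrained residues with undefined simulated Phi: {undefined}")
    dev = phi_sim.phi[idx] - restraints.targets()
    energy = restraints.k * float(np.sum(dev ** 2))
    grad = 2.0 * restraints.k * dev
    return energy, grad
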