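"""Structural descriptors of conformational ensembles.

Covers the analytics used to characterise a transition-state ensemble
against a native reference: residue-residue contact probability maps, radius
of gyration, optimal-superposition pairwise RMSD, per-residue helical
content, and GROMOS-style leader clustering with a first-half/full
convergence check.

Secondary structure uses an internal Kabsch-Sander minimal rule: a backbone
hydrogen bond is scored with the classic electrostatic energy
``E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)`` (distances in
Angstrom) with E < -0.5 kcal/mol, the amide hydrogen built geometrically
when absent, and a residue assigned alpha-helix when it sits in two
consecutive i -> i+4 turns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure import Structure, Ensemble
from .contacts import NativeContactSet, DEFAULT_CUTOFF, DEFAULT_MIN_SEPARATION

_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
           "P": 30.974}

HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_HB_FACTOR = 0.084 * 332.0  # kcal/mol * Angstrom


# ---------------------------------------------------------------------------
# Rg and RMSD
# ---------------------------------------------------------------------------

def radius_of_gyration(conformer: Structure, mass_weighted: bool = True) -> float:
    """Rg in nm: sqrt(sum m_i |r_i - r_cm|^2 / sum m_i)."""
    xyz = conformer.coords
    if mass_weighted:
        m = np.array([_MASSES.get(e.upper(), 12.0) for e in conformer.element])
    else:
        m = np.ones(len(xyz))
    cm = np.average(xyz, axis=0, weights=m)
    return float(np.sqrt(np.average(np.sum((xyz - cm) ** 2, axis=1), weights=m)))


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD of P onto Q after optimal rotation/translation (SVD)."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    # residual computed from rotated coordinates (avoids the cancellation of
    # the singular-value shortcut near RMSD 0)
    return float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))


def pairwise_rmsd(ensemble: Ensemble,
                  selection: np.ndarray | None = None) -> np.ndarray:
    """Symmetric matrix of optimal-superposition RMSDs (nm).

    ``selection`` is a boolean atom mask or index array; default all atoms.
    At least 3 selected atoms are required (superposition is
    underdetermined below that).
    """
    if len(ensemble) < 2:
        raise ValueError("need >= 2 conformers")
    coords = ensemble.coords_array()
    if selection is not None:
        coords = coords[:, np.asarray(selection)]
    if coords.shape[1] < 3:
        raise ValueError("need >= 3 selected atoms for superposition")
    n = len(coords)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = kabsch_rmsd(coords[i], coords[j])
    return out


# ---------------------------------------------------------------------------
# Contact probability map
# ---------------------------------------------------------------------------

@dataclass
class ContactProbMap:
    """Symmetric residue-pair contact-formation probabilities over an ensemble."""

    residue_keys: list[tuple[str, int]]
    matrix: np.ndarray
    n_conformers: int
    cutoff: float
    min_separation: int

    def prob(self, key_i: tuple[str, int], key_j: tuple[str, int]) -> float:
        i = self.residue_keys.index(key_i)
        j = self.residue_keys.index(key_j)
        return float(self.matrix[i, j])

    def support(self, threshold: float = 0.0) -> set:
        """Residue pairs with probability > threshold (canonical order)."""
        out = set()
        ii, jj = np.nonzero(self.matrix > threshold)
        for i, j in zip(ii, jj):
            if i < j:
                out.add((self.residue_keys[i], self.residue_keys[j]))
        return out


def _residue_contact_matrix(conformer: Structure, cutoff: float,
                            min_separation: int) -> np.ndarray:
    """Boolean matrix: residues share >= 1 side-chain heavy-atom pair in cutoff."""
    rkeys = conformer.residue_keys()
    rindex = {k: i for i, k in enumerate(rkeys)}
    sc = np.flatnonzero(conformer.is_sidechain_heavy)
    nres = len(rkeys)
    mat = np.zeros((nres, nres), dtype=bool)
    if sc.size == 0:
        return mat
    res_of = np.array([rindex[(str(c), int(r))]
                       for c, r in zip(conformer.chain_id[sc],
                                       conformer.res_id[sc])])
    chain_of = conformer.chain_id[sc]
    seq_of = conformer.res_id[sc].astype(int)
    d = cdist(conformer.coords[sc], conformer.coords[sc])
    same_chain = chain_of[:, None] == chain_of[None, :]
    sep = np.abs(seq_of[:, None] - seq_of[None, :])
    eligible = (res_of[:, None] != res_of[None, :]) & \
               (~same_chain | (sep >= min_separation))
    ai, aj = np.nonzero(eligible & (d <= cutoff))
    mat[res_of[ai], res_of[aj]] = True
    return mat | mat.T


def contact_probability_map(ensemble: Ensemble,
                            native: NativeContactSet | None = None,
                            cutoff: float = DEFAULT_CUTOFF,
                            min_separation: int = DEFAULT_MIN_SEPARATION,
                            ) -> ContactProbMap:
    """P(i, j) = fraction of conformers in which residues i, j are in contact.

    With ``native`` given, the contact definition parameters (cutoff,
    separation rule) are taken from it; contacts are still evaluated over
    all eligible residue pairs, so non-native contacts appear too.
    """
    if native is not None:
        cutoff = native.cutoff
        min_separation = native.min_sequence_separation
    rkeys = ensemble[0].residue_keys()
    acc = np.zeros((len(rkeys), len(rkeys)))
    for c in ensemble:
        acc += _residue_contact_matrix(c, cutoff, min_separation)
    return ContactProbMap(rkeys, acc / len(ensemble), len(ensemble),
                          cutoff, min_separation)


# ---------------------------------------------------------------------------
# Helical content (internal Kabsch-Sander minimal rule)
# ---------------------------------------------------------------------------

@dataclass
class SSProfile:
    """Per-residue alpha-helix fraction over an ensemble; NaN = unassignable."""

    residue_keys: list[tuple[str, int]]
    helix_fraction: np.ndarray

    def value(self, chain: str, res_id: int) -> float:
        return float(self.helix_fraction[self.residue_keys.index((chain, res_id))])


def _backbone_table(conformer: Structure) -> dict:
    """Per residue: positions of N, CA, C, O (nm) where present."""
    table: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for i in range(conformer.n_atoms):
        name = conformer.atom_name[i]
        if name in ("N", "CA", "C", "O", "H"):
            key = (str(conformer.chain_id[i]), int(conformer.res_id[i]))
            table.setdefault(key, {})[name] = conformer.coords[i]
    return table


def _amide_h(bb: dict, prev_bb: dict | None) -> np.ndarray | None:
    """Geometric amide H: 0.101 nm from N, opposite the C(prev)/CA bisector."""
    if "H" in bb:
        return bb["H"]
    if prev_bb is None or "C" not in prev_bb or "N" not in bb or "CA" not in bb:
        return None
    n = bb["N"]
    u1 = n - prev_bb["C"]
    u2 = n - bb["CA"]
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    d = u1 + u2
    nrm = np.linalg.norm(d)
    if nrm < 1e-9:
        return None
    return n + 0.101 * d / nrm


def _hbond_energy(donor_n: np.ndarray, donor_h: np.ndarray,
                  acc_c: np.ndarray, acc_o: np.ndarray) -> float:
    # classic electrostatic model; distances converted nm -> Angstrom
    r_on = np.linalg.norm(acc_o - donor_n) * 10.0
    r_ch = np.linalg.norm(acc_c - donor_h) * 10.0
    r_oh = np.linalg.norm(acc_o - donor_h) * 10.0
    r_cn = np.linalg.norm(acc_c - donor_n) * 10.0
    if min(r_on, r_ch, r_oh, r_cn) < 0.1:
        return 0.0
    return _HB_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_helix(conformer: Structure) -> dict[tuple[str, int], bool | None]:
    """Alpha-helix assignment per residue; None where backbone incomplete.

    A residue is helical when it lies inside two consecutive i -> i+4 turns
    (CO of residue i hydrogen-bonded to NH of residue i+4, E < -0.5
    kcal/mol).
    """
    bb = _backbone_table(conformer)
    rkeys = conformer.residue_keys()
    by_chain: dict[str, list[tuple[str, int]]] = {}
    for key in rkeys:
        by_chain.setdefault(key[0], []).append(key)
    result: dict[tuple[str, int], bool | None] = {}
    for key in rkeys:
        have = bb.get(key, {})
        result[key] = False if all(a in have for a in ("N", "CA", "C", "O")) \
            else None
    for chain, keys in by_chain.items():
        nres = len(keys)
        turn = np.zeros(nres, dtype=bool)
        for i in range(nres - 4):
            acc = bb.get(keys[i], {})
            don = bb.get(keys[i + 4], {})
            prev = bb.get(keys[i + 3], {})
            if not {"C", "O"} <= set(acc) or not {"N", "CA"} <= set(don):
                continue
            h = _amide_h(don, prev)
            if h is None:
                continue
            if _hbond_energy(don["N"], h, acc["C"], acc["O"]) < HB_ENERGY_CUTOFF:
                turn[i] = True
        for i in range(1, nres - 4):
            if turn[i - 1] and turn[i]:
                for j in range(i, i + 4):
                    if result[keys[j]] is not None:
                        result[keys[j]] = True
    return result


def helical_content(ensemble: Ensemble) -> SSProfile:
    """Per-residue fraction of conformers assigned alpha-helix."""
    rkeys = ensemble[0].residue_keys()
    counts = np.zeros(len(rkeys))
    defined = np.zeros(len(rkeys))
    for c in ensemble:
        assign = assign_helix(c)
        for i, key in enumerate(rkeys):
            v = assign.get(key)
            if v is not None:
                defined[i] += 1
                counts[i] += bool(v)
    with np.errstate(invalid="ignore"):
        frac = np.where(defined > 0, counts / np.maximum(defined, 1), np.nan)
    return SSProfile(rkeys, frac)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    assignments: np.ndarray
    n_clusters: int
    rmsd_cutoff: float
    subset: str

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignments)


def cluster_ensemble(ensemble: Ensemble, rmsd_cutoff: float,
                     subset: str = "all",
                     selection: np.ndarray | None = None,
                     rmsd_matrix: np.ndarray | None = None) -> ClusterResult:
    """Greedy leader (GROMOS-style) clustering on pairwise RMSD.

    Iteratively picks the conformer with the most neighbours within the
    cutoff as a cluster centre, assigns and removes that cluster, and
    repeats until every conformer is assigned exactly once.  ``subset``
    restricts to the first half of the ensemble ('first_half') for the
    convergence check against the full set.
    """
    if subset not in ("all", "first_half"):
        raise ValueError("subset must be 'all' or 'first_half'")
    n_total = len(ensemble)
    n_use = n_total // 2 if subset == "first_half" else n_total
    if rmsd_matrix is None:
        sub = Ensemble(ensemble.conformers[:n_use], label=ensemble.label)
        rmsd_matrix = pairwise_rmsd(sub, selection)
    else:
        rmsd_matrix = rmsd_matrix[:n_use, :n_use]
    within = rmsd_matrix <= rmsd_cutoff
    assignments = np.full(n_use, -1, dtype=int)
    remaining = np.ones(n_use, dtype=bool)
    cluster = 0
    while remaining.any():
        counts = (within & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))
        members = within[center] & remaining
        members[center] = True
        assignments[members] = cluster
        remaining &= ~members
        cluster += 1
    return ClusterResult(assignments, cluster, rmsd_cutoff, subset)
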