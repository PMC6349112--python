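import numpy as np
import pytest

import tsphi as T


@pytest.fixture(scope="session")
def table1():
    return T.load_table1()


@pytest.fixture(scope="session")
def table1_lookup(table1):
    return {(r.actr_variant, r.ncbd_variant, r.condition): r for r in table1}


def dense_ladder_model(n_res: int = 6, spacing: float = 0.4,
                       **kwargs) -> T.CoarseModel:
    """Two parallel bead rows 0.45 nm apart; interior beads have 3 native
    contacts (across plus both diagonals), so per-residue Phi can take
    intermediate values."""
    xs = spacing * np.arange(n_res)
    pos = np.concatenate([
        np.stack([xs, np.zeros(n_res), np.zeros(n_res)], axis=1),
        np.stack([xs, np.full(n_res, 0.45), np.zeros(n_res)], axis=1)])
    chains = np.array(["A"] * n_res + ["B"] * n_res)
    rids = np.concatenate([np.arange(1, n_res + 1)] * 2)
    return T.CoarseModel(pos, chains, rids, **kwargs)


@pytest.fixture
def ladder_model():
    return dense_ladder_model()


def random_toy_structure(rng: np.random.Generator, n_res: int,
                         n_chains: int = 2, box: float = 1.5) -> T.Structure:
    """Random multi-chain structure with 1-3 side-chain heavy atoms/residue."""
    names, elems, rids, rnames, chains, xyz = [], [], [], [], [], []
    chain_labels = "ABCD"[:n_chains]
    res = 0
    for ch in chain_labels:
        n_in_chain = max(1, n_res // n_chains)
        for i in range(n_in_chain):
            res += 1
            center = rng.uniform(0, box, size=3)
            names.append("CA"); elems.append("C")
            rids.append(i + 1); rnames.append("ALA"); chains.append(ch)
            xyz.append(center)
            for k in range(rng.integers(1, 4)):
                names.append(f"C{'BGD'[k]}"); elems.append("C")
                rids.append(i + 1); rnames.append("ALA"); chains.append(ch)
                xyz.append(center + rng.normal(scale=0.15, size=3))
    return T.Structure(np.array(names), np.array(elems),
                       np.array(rids, dtype=int), np.array(rnames),
                       np.array(chains), np.array(xyz))


def brute_force_contacts(s: T.Structure, cutoff: float, min_sep: int):
    """Independent O(N^2) scan over every side-chain heavy-atom pair.

    Returns {((chain_i, res_i), (chain_j, res_j)): count} with canonical
    residue ordering.
    """
    rkeys = s.residue_keys()
    order = {k: i for i, k in enumerate(rkeys)}
    counts = {}
    heavy = [i for i in range(s.n_atoms)
             if s.element[i].upper() != "H"
             and s.atom_name[i] not in ("N", "CA", "C", "O")]
    for a in heavy:
        for b in heavy:
            if a >= b:
                continue
            ka = (str(s.chain_id[a]), int(s.res_id[a]))
            kb = (str(s.chain_id[b]), int(s.res_id[b]))
            if ka == kb:
                continue
            if ka[0] == kb[0] and abs(ka[1] - kb[1]) < min_sep:
                continue
            d = np.linalg.norm(s.coords[a] - s.coords[b])
            if d <= cutoff:
                key = (ka, kb) if order[ka] < order[kb] else (kb, ka)
                counts[key] = counts.get(key, 0) + 1
    return counts
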