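"""Molecular structures and conformational ensembles.

A :class:`Structure` is a flat, array-backed record of atoms (name, element,
residue, chain, position in nm).  An :class:`Ensemble` is an ordered list of
conformers sharing one topology, e.g. the retained transition-state samples of
an annealing run.  PDB reading/writing is delegated to :mod:`biotite`;
coordinates are converted to nm on read (the native-contact cutoff is stated
in nm) and back to Angstrom on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .constants import ANG_TO_NM

BACKBONE_NAMES = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed; carries the offending line."""


@dataclass
class Structure:
    """One conformer: per-atom arrays plus derived residue bookkeeping.

    Residue identity is the pair ``(chain_id, res_id)`` with author numbering
    preserved (e.g. NCBD 2098 stays 2098).  Hydrogens are retained but
    excluded from heavy-atom selections by element.
    """

    atom_name: np.ndarray
    element: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    coords: np.ndarray  # (n_atoms, 3), nm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for name in ("atom_name", "element", "res_id", "res_name", "chain_id"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (self.n_atoms,):
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)
        # residue indices must be non-decreasing within each chain
        for ch in np.unique(self.chain_id):
            ids = self.res_id[self.chain_id == ch].astype(int)
            starts = ids[np.r_[True, np.diff(ids) != 0]]
            if np.any(np.diff(starts) <= 0):
                raise ValueError(f"residue indices not increasing in chain {ch!r}")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    # -- masks -------------------------------------------------------------
    @property
    def is_hydrogen(self) -> np.ndarray:
        return np.char.upper(self.element.astype(str)) == "H"

    @property
    def is_backbone(self) -> np.ndarray:
        return np.isin(self.atom_name, BACKBONE_NAMES)

    @property
    def is_sidechain_heavy(self) -> np.ndarray:
        """Non-hydrogen atoms excluding backbone N, CA, C, O."""
        return ~self.is_hydrogen & ~self.is_backbone

    # -- residues ----------------------------------------------------------
    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique ``(chain_id, res_id, res_name)`` triples."""
        seen: dict[tuple[str, int], str] = {}
        for ch, ri, rn in zip(self.chain_id, self.res_id, self.res_name):
            seen.setdefault((str(ch), int(ri)), str(rn))
        return [(ch, ri, rn) for (ch, ri), rn in seen.items()]

    def residue_keys(self) -> list[tuple[str, int]]:
        return [(ch, ri) for ch, ri, _ in self.residues()]

    def atom_indices_of(self, chain: str, res: int) -> np.ndarray:
        return np.flatnonzero((self.chain_id == chain) & (self.res_id == res))

    # -- geometry ----------------------------------------------------------
    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Structure":
        """Copy with a rigid-body transform applied to every atom."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation).T
        if translation is not None:
            xyz = xyz + np.asarray(translation)
        return Structure(self.atom_name.copy(), self.element.copy(),
                         self.res_id.copy(), self.res_name.copy(),
                         self.chain_id.copy(), xyz)

    def same_topology(self, other: "Structure") -> str | None:
        """None if topologies match, else a message naming the first mismatch."""
        if self.n_atoms != other.n_atoms:
            return f"atom count differs: {self.n_atoms} vs {other.n_atoms}"
        for i in range(self.n_atoms):
            a = (self.atom_name[i], self.chain_id[i], self.res_id[i])
            b = (other.atom_name[i], other.chain_id[i], other.res_id[i])
            if a != b:
                return f"atom {i}: {a} vs {b}"
        return None


@dataclass
class Ensemble:
    """Ordered conformers sharing a single topology."""

    conformers: list[Structure]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("ensemble must contain at least one conformer")
        ref = self.conformers[0]
        for k, c in enumerate(self.conformers[1:], start=1):
            msg = ref.same_topology(c)
            if msg is not None:
                raise ValueError(f"conformer {k} topology mismatch: {msg}")

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i: int) -> Structure:
        return self.conformers[i]

    def coords_array(self) -> np.ndarray:
        """(n_conformers, n_atoms, 3) stacked coordinates, nm."""
        return np.stack([c.coords for c in self.conformers])


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _locate_bad_line(path: str) -> tuple[int, str] | None:
    """Best-effort scan for the first malformed ATOM/HETATM record."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    return lineno, line.rstrip("\n")
    return None


def _read_stack(path: str) -> bst.AtomArrayStack:
    with open(path) as fh:
        if not fh.read().strip():
            raise PDBParseError(f"{path}: empty PDB file")
    try:
        pdb = PDBFile.read(path)
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # locate the line for a useful message
        bad = _locate_bad_line(path)
        if bad is not None:
            raise PDBParseError(
                f"{path}: malformed record at line {bad[0]}: {bad[1]!r}") from exc
        raise PDBParseError(f"{path}: {exc}") from exc
    if stack.array_length() == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")
    return stack


def _from_atom_array(arr: bst.AtomArray) -> Structure:
    return Structure(
        atom_name=arr.atom_name.astype(str),
        element=arr.element.astype(str),
        res_id=arr.res_id.astype(int),
        res_name=arr.res_name.astype(str),
        chain_id=arr.chain_id.astype(str),
        coords=arr.coord * ANG_TO_NM,
    )


def _to_atom_array(s: Structure) -> bst.AtomArray:
    arr = bst.AtomArray(s.n_atoms)
    arr.atom_name = s.atom_name.astype(str)
    arr.element = s.element.astype(str)
    arr.res_id = s.res_id.astype(int)
    arr.res_name = s.res_name.astype(str)
    arr.chain_id = s.chain_id.astype(str)
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    arr.coord = np.asarray(s.coords, dtype=np.float32) / ANG_TO_NM
    return arr


def read_structure(path: str) -> Structure:
    """Read the first model of a PDB file."""
    return _from_atom_array(_read_stack(path)[0])


def read_ensemble(path: str, label: str = "") -> Ensemble:
    """Read a (possibly multi-model) PDB file as an :class:`Ensemble`."""
    stack = _read_stack(path)
    return Ensemble([_from_atom_array(stack[i])
                     for i in range(stack.stack_depth())], label=label)


def write_structure(s: Structure, path: str) -> None:
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(s))
    pdb.write(path)


def write_ensemble(ens: Ensemble, path: str) -> None:
    """Write as multi-model PDB (MODEL/ENDMDL blocks)."""
    stack = bst.stack([_to_atom_array(c) for c in ens.conformers])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)
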