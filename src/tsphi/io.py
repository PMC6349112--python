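"""Rate-constant and restraint tables.

The central record is :class:`RateConstants`: association/dissociation rate
constants for one (ACTR variant, NCBD variant) pair under one condition.
Units follow the experimental convention: k_on in uM^-1 s^-1, k_off in s^-1,
K_d in nM.  When a table row omits K_d it is back-filled as k_off/k_on
(times 1e3 for uM -> nM).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import T_DEFAULT, kd_nM

REQUIRED_COLUMNS = ("actr_variant", "ncbd_variant", "kon", "koff")
OPTIONAL_COLUMNS = ("kd", "kon_err", "koff_err", "kd_err", "condition",
                    "temperature")


class SchemaError(ValueError):
    """Missing or malformed table columns."""


class ValidationError(ValueError):
    """A row violates a physical invariant (e.g. non-positive rate)."""


@dataclass(frozen=True)
class RateConstants:
    """Binding rate constants for one variant pair.

    Attributes
    ----------
    kon, koff : float
        Association (uM^-1 s^-1) and dissociation (s^-1) rate constants.
    kd : float
        Dissociation constant in nM; ``koff/kon * 1e3`` when not measured
        independently.
    condition : str
        Free-text buffer tag, e.g. ``"buffer"`` or ``"0.7 M TMAO"``.
    """

    actr_variant: str
    ncbd_variant: str
    kon: float
    koff: float
    kd: float
    kon_err: float = 0.0
    koff_err: float = 0.0
    kd_err: float = 0.0
    condition: str = "buffer"
    temperature: float = T_DEFAULT

    def __post_init__(self) -> None:
        if not (self.kon > 0 and self.koff > 0):
            raise ValidationError(
                f"{self.actr_variant}/{self.ncbd_variant}: "
                f"rate constants must be positive (kon={self.kon}, koff={self.koff})")
        if not self.kd > 0:
            raise ValidationError("K_d must be positive")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.actr_variant, self.ncbd_variant)

    @property
    def kd_from_rates(self) -> float:
        """k_off/k_on expressed in nM."""
        return kd_nM(self.kon, self.koff)


def _row_to_record(row: pd.Series) -> RateConstants:
    kon, koff = float(row["kon"]), float(row["koff"])
    if not (kon > 0 and koff > 0):
        raise ValidationError(
            f"{row['actr_variant']}/{row['ncbd_variant']}: rate constants "
            f"must be positive (kon={kon}, koff={koff})")
    kd = row.get("kd")
    if kd is None or (isinstance(kd, float) and np.isnan(kd)):
        kd = kd_nM(float(row["kon"]), float(row["koff"]))

    def opt(name: str, default: float = 0.0) -> float:
        v = row.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return default
        return float(v)

    cond = row.get("condition")
    if cond is None or (isinstance(cond, float) and np.isnan(cond)):
        cond = "buffer"
    return RateConstants(
        actr_variant=str(row["actr_variant"]),
        ncbd_variant=str(row["ncbd_variant"]),
        kon=float(row["kon"]),
        koff=float(row["koff"]),
        kd=float(kd),
        kon_err=opt("kon_err"),
        koff_err=opt("koff_err"),
        kd_err=opt("kd_err"),
        condition=str(cond),
        temperature=opt("temperature", T_DEFAULT),
    )


def read_rate_table(path: str | Path) -> list[RateConstants]:
    """Read a CSV/TSV rate table into validated records.

    The header must contain ``actr_variant, ncbd_variant, kon, koff``;
    ``kd`` (nM) and per-quantity errors are optional.  K_d is filled from
    k_off/k_on when absent.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return [_row_to_record(row) for _, row in df.iterrows()]


def write_rate_table(records: list[RateConstants], path: str | Path) -> None:
    df = pd.DataFrame([r.__dict__ for r in records])
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False)


def rate_lookup(records: list[RateConstants],
                condition: str | None = None) -> dict[tuple[str, str], RateConstants]:
    """Index records by (ACTR, NCBD) variant pair, optionally filtering."""
    out: dict[tuple[str, str], RateConstants] = {}
    for r in records:
        if condition is not None and r.condition != condition:
            continue
        out[r.pair] = r
    return out


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("tsphi") / "data" / name)


def load_table1() -> list[RateConstants]:
    """The packaged wild-type/mutant rate-constant table (stopped-flow, 277 K)."""
    return read_rate_table(_data_path("table1.csv"))


def read_restraint_table(path: str | Path) -> list[tuple[str, int, float]]:
    """Read a TSV of experimental binding Phi values: chain, res_id, phi.

    Values must lie in [0, 1] (only that range is interpretable as a
    fraction of native contacts and usable as a structural restraint).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for c in ("chain", "res_id", "phi"):
        if c not in df.columns:
            raise SchemaError(f"{path}: missing column {c!r}")
    entries = []
    for _, row in df.iterrows():
        phi = float(row["phi"])
        if not 0.0 <= phi <= 1.0:
            raise ValidationError(f"experimental Phi {phi} outside [0, 1]")
        entries.append((str(row["chain"]), int(row["res_id"]), phi))
    return entries


def load_phi_restraints() -> list[tuple[str, int, float]]:
    """Packaged main-text binding Phi values (synthetic stand-in table).

    Only the three values printed in the main text are packaged; the full
    experimental restraint set is user-replaceable via
    :func:`read_restraint_table`.
    """
    return read_restraint_table(_data_path("phi_restraints_synthetic.tsv"))
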