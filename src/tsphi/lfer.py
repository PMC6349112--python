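"""Linear free-energy relationships from binding rate constants.

From wild-type and mutant rate constants:

* ``ddG_TS = -R T ln(k_on,mut / k_on,wt)`` — mutational change in the
  activation free energy for association,
* ``ddG_Eq = R T ln(K_d,mut / K_d,wt)`` — change in equilibrium binding free
  energy (destabilising mutation positive in both),
* ``Phi_b = ddG_TS / ddG_Eq`` — fraction of the residue's native interaction
  free energy already present in the transition state,
* the Bronsted (Leffler) slope alpha of ddG_TS vs ddG_Eq across a mutant
  panel — global native-likeness of the transition state,
* the double-mutant-cycle coupling energy
  ``dddG_C = ddG_Eq(AB) - ddG_Eq(A) - ddG_Eq(B)``.

Errors are propagated to first order assuming independent errors on the rate
constants (correlations are not reported experimentally).  Phi_b is refused
when |ddG_Eq| falls below a significance threshold (default 0.18 kcal/mol):
the ratio of two near-zero numbers carries no structural information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import PhysicalConstants
from .io import RateConstants, rate_lookup

_PC = PhysicalConstants()

#: Minimum |ddG_Eq| (kcal/mol) for a meaningful Phi_b.
DEFAULT_SIGNIFICANCE = 0.18

#: Phi_b category bins: low [0, 0.3), intermediate [0.3, 0.6), high [0.6, 1].
CATEGORY_EDGES = (0.3, 0.6)


class PhiBUndetermined(ValueError):
    """|ddG_Eq| too small to compute a meaningful Phi_b."""


class ConditionMismatch(ValueError):
    """Rate constants measured under different buffer conditions."""


@dataclass(frozen=True)
class DDG:
    """Mutational free-energy changes (kcal/mol), mutant minus wild type."""

    ddG_TS: float
    ddG_Eq: float
    ddG_TS_err: float
    ddG_Eq_err: float
    temperature: float
    pair: tuple[str, str]
    ref_pair: tuple[str, str]


@dataclass(frozen=True)
class PhiB:
    value: float
    error: float
    category: str
    background: str = ""

    @staticmethod
    def categorise(value: float) -> str:
        lo, hi = CATEGORY_EDGES
        if value < lo:
            return "low"
        if value < hi:
            return "intermediate"
        return "high"


@dataclass(frozen=True)
class BronstedFit:
    alpha: float
    alpha_se: float
    intercept: float
    n: int
    background: str
    pairs: tuple


@dataclass(frozen=True)
class CouplingEnergy:
    dddG_C: float
    error: float
    pair_a: str
    pair_b: str


# ---------------------------------------------------------------------------

def _rel_err(value: float, err: float) -> float:
    return err / value if value > 0 else 0.0


def ddg_from_rates(wt: RateConstants, mut: RateConstants,
                   T: float | None = None,
                   allow_condition_mismatch: bool = False) -> DDG:
    """ddG_TS and ddG_Eq (kcal/mol) for ``mut`` relative to ``wt``.

    K_d values carried by the records (measured, or back-filled from
    k_off/k_on) define ddG_Eq.  Records must share a condition tag unless
    explicitly overridden.
    """
    if wt.condition != mut.condition and not allow_condition_mismatch:
        raise ConditionMismatch(
            f"conditions differ: {wt.condition!r} vs {mut.condition!r}")
    if T is None:
        T = mut.temperature
    if T <= 0:
        raise ValueError("temperature must be positive")
    RT = _PC.RT(T)
    ddG_TS = -RT * np.log(mut.kon / wt.kon)
    ddG_Eq = RT * np.log(mut.kd / wt.kd)
    ts_err = RT * np.hypot(_rel_err(mut.kon, mut.kon_err),
                           _rel_err(wt.kon, wt.kon_err))
    eq_err = RT * np.hypot(_rel_err(mut.kd, mut.kd_err),
                           _rel_err(wt.kd, wt.kd_err))
    return DDG(float(ddG_TS), float(ddG_Eq), float(ts_err), float(eq_err),
               float(T), mut.pair, wt.pair)


def phi_b(ddg: DDG, significance: float = DEFAULT_SIGNIFICANCE,
          background: str = "") -> PhiB:
    """Phi_b = ddG_TS / ddG_Eq with first-order error propagation.

    Raises :class:`PhiBUndetermined` when |ddG_Eq| < ``significance``: such
    mutants perturb binding too little for the ratio to be meaningful.
    """
    if abs(ddg.ddG_Eq) < significance:
        raise PhiBUndetermined(
            f"|ddG_Eq| = {abs(ddg.ddG_Eq):.3f} kcal/mol < {significance}: "
            f"too small to compute Phi_b for {ddg.pair}")
    value = ddg.ddG_TS / ddg.ddG_Eq
    err = np.hypot(ddg.ddG_TS_err / ddg.ddG_Eq,
                   ddg.ddG_TS * ddg.ddG_Eq_err / ddg.ddG_Eq ** 2)
    return PhiB(float(value), float(abs(err)), PhiB.categorise(value), background)


def bronsted(points: list[DDG], background: str = "") -> BronstedFit:
    """Unweighted least-squares slope of ddG_TS on ddG_Eq (free intercept)."""
    if len(points) < 3:
        raise ValueError("need >= 3 mutants for a Bronsted fit")
    x = np.array([p.ddG_Eq for p in points])
    y = np.array([p.ddG_TS for p in points])
    res = stats.linregress(x, y)
    se = res.stderr if np.isfinite(res.stderr) else np.inf
    if np.ptp(x) < 0.2:
        warnings.warn(
            f"ddG_Eq spread {np.ptp(x):.2f} kcal/mol < 0.2: slope poorly "
            "determined, SE inflated")
        se = max(se, abs(res.slope))
    return BronstedFit(float(res.slope), float(se), float(res.intercept),
                       len(points), background, tuple(p.pair for p in points))


def coupling_energy(wt_wt: RateConstants, mutA_wt: RateConstants,
                    wt_mutB: RateConstants, mutA_mutB: RateConstants,
                    T: float | None = None) -> CouplingEnergy:
    """Double-mutant-cycle coupling energy (kcal/mol).

    ``dddG_C = ddG_Eq(A.B) - ddG_Eq(A) - ddG_Eq(B)``, all relative to the
    wild-type/wild-type corner; zero for energetically additive mutations.
    Symmetric under relabelling which single mutant is "first".
    """
    corners = {"wt/wt": wt_wt, "mutA/wt": mutA_wt,
               "wt/mutB": wt_mutB, "mutA/mutB": mutA_mutB}
    for name, rec in corners.items():
        if rec is None:
            raise ValueError(f"missing double-mutant-cycle corner: {name}")
    dd_ab = ddg_from_rates(wt_wt, mutA_mutB, T)
    dd_a = ddg_from_rates(wt_wt, mutA_wt, T)
    dd_b = ddg_from_rates(wt_wt, wt_mutB, T)
    val = dd_ab.ddG_Eq - dd_a.ddG_Eq - dd_b.ddG_Eq
    err = float(np.sqrt(dd_ab.ddG_Eq_err ** 2 + dd_a.ddG_Eq_err ** 2
                        + dd_b.ddG_Eq_err ** 2))
    return CouplingEnergy(float(val), err,
                          mutA_wt.actr_variant, wt_mutB.ncbd_variant)


# ---------------------------------------------------------------------------
# Panel analyses (per-background Bronsted fits, Phi_b background comparison)
# ---------------------------------------------------------------------------

def _sides(side: str) -> tuple[str, str]:
    if side not in ("actr", "ncbd"):
        raise ValueError("side must be 'actr' or 'ncbd'")
    return ("actr_variant", "ncbd_variant") if side == "ncbd" else \
           ("ncbd_variant", "actr_variant")


def bronsted_by_background(records: list[RateConstants],
                           side: str,
                           ref_actr: str, ref_ncbd: str,
                           min_points: int = 3) -> list[BronstedFit]:
    """One Bronsted fit per background variant on the given side.

    ``side='ncbd'`` fits, for each NCBD variant b, ddG_TS vs ddG_Eq across
    the ACTR probe mutants measured against b (and vice versa for
    ``side='actr'``).  The reference corner for each fit is (reference probe,
    b), so the fit reflects probe perturbations within that background.
    """
    table = rate_lookup(records)
    probe_ref = ref_actr if side == "ncbd" else ref_ncbd
    fits = []
    backgrounds = sorted({getattr(r, _sides(side)[1]) for r in records})
    for b in backgrounds:
        def key(probe: str) -> tuple[str, str]:
            return (probe, b) if side == "ncbd" else (b, probe)
        wt_rec = table.get(key(probe_ref))
        if wt_rec is None:
            continue
        pts = []
        for r in records:
            if getattr(r, _sides(side)[1]) != b:
                continue
            probe = getattr(r, _sides(side)[0])
            if probe == probe_ref:
                continue
            pts.append(ddg_from_rates(wt_rec, r))
        if len(pts) >= min_points:
            fits.append(bronsted(pts, background=b))
    return fits


def phi_background_comparison(records: list[RateConstants],
                              side: str,
                              ref_actr: str, ref_ncbd: str,
                              significance: float = DEFAULT_SIGNIFICANCE,
                              ddg_eq_filter: float | None = None,
                              ) -> pd.DataFrame:
    """Compare Phi_b of each probe mutation across background variants.

    For ``side='ncbd'``: each NCBD background variant b yields Phi_b values
    for ACTR probe mutations measured in that background; these are paired
    with the same probe's Phi_b in the reference background.  Returns a tidy
    frame (background, probe, phi_ref, phi_mut, background ddG_Eq, category
    flags).  ``ddg_eq_filter`` restricts to backgrounds whose own |ddG_Eq|
    is below the given value (kcal/mol).
    """
    table = rate_lookup(records)
    probe_col, bg_col = _sides(side)
    probe_ref = ref_actr if side == "ncbd" else ref_ncbd
    bg_ref = ref_ncbd if side == "ncbd" else ref_actr

    def key(probe: str, bg: str) -> tuple[str, str]:
        return (probe, bg) if side == "ncbd" else (bg, probe)

    ref_wt = table.get(key(probe_ref, bg_ref))
    if ref_wt is None:
        raise ValueError("reference pair absent from table")

    rows = []
    backgrounds = sorted({getattr(r, bg_col) for r in records} - {bg_ref})
    probes = sorted({getattr(r, probe_col) for r in records} - {probe_ref})
    for b in backgrounds:
        bg_wt = table.get(key(probe_ref, b))
        if bg_wt is None:
            continue
        bg_ddg = ddg_from_rates(ref_wt, bg_wt)
        for m in probes:
            rec_ref = table.get(key(m, bg_ref))
            rec_bg = table.get(key(m, b))
            if rec_ref is None or rec_bg is None:
                continue
            try:
                p_ref = phi_b(ddg_from_rates(ref_wt, rec_ref), significance)
                p_bg = phi_b(ddg_from_rates(bg_wt, rec_bg), significance)
            except PhiBUndetermined:
                continue
            rows.append({
                "background": b, "probe": m,
                "phi_ref": p_ref.value, "phi_bg": p_bg.value,
                "phi_ref_err": p_ref.error, "phi_bg_err": p_bg.error,
                "abs_diff": abs(p_bg.value - p_ref.value),
                "bg_ddG_Eq": bg_ddg.ddG_Eq,
                "category_changed": p_ref.category != p_bg.category,
            })
    df = pd.DataFrame(rows)
    if ddg_eq_filter is not None and not df.empty:
        df = df[df["bg_ddG_Eq"].abs() < ddg_eq_filter].reset_index(drop=True)
    return df


def mean_abs_phi_difference(comparison: pd.DataFrame) -> float:
    """Mean |Phi_b(background) - Phi_b(reference)| over all paired probes."""
    if comparison.empty:
        return float("nan")
    return float(comparison["abs_diff"].mean())
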