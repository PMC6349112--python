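"""Stopped-flow kinetics: exponential trace fits and k_obs analysis.

Binding between the probe (held at ~1 uM) and an excess titrant produces
fluorescence relaxations fitted to one or two exponential phases; the
concentration dependence of the observed rate constant k_obs is then fitted
to the solution for reversible bimolecular binding

    k_obs = sqrt( k_on^2 (A0 - B0)^2 + 2 k_on k_off (A0 + B0) + k_off^2 )

which reduces to the familiar pseudo-first-order line k_obs = k_on*A0 + k_off
when A0 >> B0.  Dissociation rate constants come from displacement
experiments: at high competitor concentration k_obs plateaus at k_off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


@dataclass
class KineticTrace:
    """One averaged stopped-flow trace: time (s) vs fluorescence (a.u.)."""

    time: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size < 10:
            raise ValueError("trace must have at least 10 points")
        if self.time.shape != self.signal.shape:
            raise ValueError("time/signal length mismatch")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class ObservedRates:
    """k_obs per titrant concentration for one (or two) kinetic phases."""

    conc_uM: np.ndarray
    kobs: np.ndarray
    kobs_err: np.ndarray | None = None
    phase: str = "linear"  # "linear" (concentration-dependent) | "constant"

    def __post_init__(self) -> None:
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        self.kobs = np.asarray(self.kobs, dtype=float)
        if np.any(self.conc_uM <= 0) or np.any(self.kobs <= 0):
            raise ValueError("concentrations and k_obs must be positive")
        if self.kobs_err is not None:
            self.kobs_err = np.asarray(self.kobs_err, dtype=float)


@dataclass
class ExpFit:
    """Result of a 1- or 2-phase exponential fit F(t) = F_inf + sum A_p e^{-k_p t}.

    Rates are sorted in decreasing order for two-phase fits.  ``converged``
    is False when the optimiser failed or a rate/amplitude is unidentifiable;
    the result is still returned with diagnostics, never silently dropped.
    """

    n_phases: int
    amplitudes: np.ndarray
    rates: np.ndarray
    offset: float
    rate_errors: np.ndarray
    amplitude_errors: np.ndarray
    residuals: np.ndarray
    converged: bool
    message: str = ""

    @property
    def kobs(self) -> float:
        """Observed rate of the dominant (largest-amplitude) phase."""
        return float(self.rates[int(np.argmax(np.abs(self.amplitudes)))])

    def rss(self) -> float:
        return float(np.sum(self.residuals ** 2))


def _multi_exp(t: np.ndarray, offset: float, *params: float) -> np.ndarray:
    n = len(params) // 2
    out = np.full_like(t, offset, dtype=float)
    for p in range(n):
        out += params[2 * p] * np.exp(-params[2 * p + 1] * t)
    return out


def _initial_rates(trace: KineticTrace, n_phases: int) -> np.ndarray:
    """Deterministic rate guesses from the trace's 10-90% decay times."""
    s = trace.signal
    span = s[0] - s[-1]
    if span == 0:
        return np.array([1.0 / trace.time[-1]] * n_phases)
    frac = (s - s[-1]) / span
    def t_at(level: float) -> float:
        below = np.flatnonzero(frac <= level)
        return trace.time[below[0]] if below.size else trace.time[-1]
    t10, t90 = t_at(0.9), t_at(0.1)
    t10 = max(t10, trace.time[1])
    t90 = max(t90, 2 * t10)
    k_fast = np.log(10) / t10
    k_slow = np.log(10) / t90
    if n_phases == 1:
        return np.array([np.sqrt(k_fast * k_slow)])
    return np.geomspace(k_fast, k_slow, n_phases)


def fit_trace(trace: KineticTrace, n_phases: int = 1) -> ExpFit:
    """Nonlinear least-squares exponential fit of a kinetic trace.

    Parameter standard errors come from the covariance of the fit;
    residuals are exposed for inspection.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t, s = trace.time, trace.signal
    k0 = _initial_rates(trace, n_phases)
    amp0 = (s[0] - s[-1]) / n_phases
    p0 = [s[-1]]
    for k in k0:
        p0 += [amp0, k]
    lower = [-np.inf] + [-np.inf, 0.0] * n_phases
    upper = [np.inf] + [np.inf, np.inf] * n_phases
    try:
        popt, pcov = optimize.curve_fit(
            _multi_exp, t, s, p0=p0, bounds=(lower, upper), maxfev=20000)
        ok = np.all(np.isfinite(pcov))
        msg = "" if ok else "covariance not estimable"
    except RuntimeError as exc:
        popt = np.asarray(p0, dtype=float)
        pcov = np.full((len(p0), len(p0)), np.inf)
        ok, msg = False, f"fit did not converge: {exc}"
    perr = np.sqrt(np.abs(np.diag(pcov)))
    amps = popt[1::2]
    rates = popt[2::2]
    amp_err = perr[1::2]
    rate_err = perr[2::2]
    order = np.argsort(rates)[::-1]
    residuals = s - _multi_exp(t, popt[0], *popt[1:])
    # unidentifiable rate: amplitude indistinguishable from residual noise
    noise = np.std(residuals) if residuals.size else 0.0
    if ok and np.any(np.abs(amps) <= 3 * noise + 1e-30 * np.abs(s).max()):
        ok = False
        msg = "amplitude consistent with zero; rate unidentifiable"
    if ok and np.any(rates <= 1e-9 / (t[-1] - t[0])):
        warnings.warn("fitted rate at lower bound")
    return ExpFit(n_phases, amps[order], rates[order], float(popt[0]),
                  rate_err[order], amp_err[order], residuals, ok, msg)


# ---------------------------------------------------------------------------
# k_obs vs concentration
# ---------------------------------------------------------------------------

def kobs_reversible(conc_uM: np.ndarray, kon: float, koff: float,
                    probe_uM: float) -> np.ndarray:
    """Relaxation rate for reversible bimolecular binding (square-root form)."""
    a = np.asarray(conc_uM, dtype=float)
    return np.sqrt(kon ** 2 * (a - probe_uM) ** 2
                   + 2.0 * kon * koff * (a + probe_uM) + koff ** 2)


def fit_binding_curve(obs: ObservedRates, probe_uM: float,
                      pseudo_first_order: bool = False,
                      ) -> tuple[float, float, float, float]:
    """Fit k_obs(concentration) for k_on (uM^-1 s^-1) and k_off (s^-1).

    Uses the reversible-binding square-root expression by default (the
    standard designs here, ~1 uM probe titrated with 1-12 uM partner, are not
    strictly pseudo-first-order); set ``pseudo_first_order`` for a plain
    linear fit.  Returns (k_on, k_off, SE(k_on), SE(k_off)).
    """
    a, y = obs.conc_uM, obs.kobs
    if a.size < 4 or a.max() / a.min() < 3.0:
        raise ValueError("need >= 4 concentrations spanning >= 3-fold range")
    sigma = obs.kobs_err if obs.kobs_err is not None and np.all(obs.kobs_err > 0) \
        else None
    slope0 = (y[-1] - y[0]) / (a[-1] - a[0])
    kon0 = max(slope0, 1e-6)
    koff0 = max(y.min() - kon0 * a.min(), 1e-3 * y.min())
    if pseudo_first_order:
        model = lambda c, kon, koff: kon * c + koff
    else:
        model = lambda c, kon, koff: kobs_reversible(c, kon, koff, probe_uM)
    popt, pcov = optimize.curve_fit(
        model, a, y, p0=[kon0, koff0], sigma=sigma, absolute_sigma=sigma is not None,
        bounds=([0, 0], [np.inf, np.inf]), maxfev=20000)
    kon, koff = popt
    if koff <= 0:
        warnings.warn("fitted k_off non-positive; bounded at 0")
    se = np.sqrt(np.abs(np.diag(pcov)))
    return float(kon), float(koff), float(se[0]), float(se[1])


def koff_displacement(obs: ObservedRates,
                      plateau_window: tuple[float, float],
                      ) -> tuple[float, float]:
    """k_off from the plateau of a displacement series.

    The mean k_obs over the plateau window (a concentration interval chosen
    by the experimenter) approximates k_off; the standard deviation of those
    points is taken as the error.  Warns if the plateau still has a
    significant slope (t-test at 5%).
    """
    lo, hi = plateau_window
    sel = (obs.conc_uM >= lo) & (obs.conc_uM <= hi)
    if np.count_nonzero(sel) < 3:
        raise ValueError("need >= 3 points inside the plateau window")
    c, y = obs.conc_uM[sel], obs.kobs[sel]
    res = stats.linregress(c, y)
    if res.pvalue < 0.05:
        warnings.warn(
            f"plateau slope significantly non-zero (p={res.pvalue:.3g}); "
            "k_off may be underestimated")
    return float(np.mean(y)), float(np.std(y, ddof=1))
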