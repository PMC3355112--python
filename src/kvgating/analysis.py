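"""ON-charge integration, Boltzmann fits, decay kinetics and derived
voltage-dependence curves.

All fitters are deterministic: multistart grids are fixed and
scipy.optimize.least_squares is run with fixed tolerances
(xtol/ftol/gtol 1e-8, max 200 iterations per start).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import PhysicalConstants, DEFAULT_CONSTANTS
from .protocol import CurrentTrace

__all__ = [
    "QVCurve",
    "BoltzmannFit",
    "DoubleBoltzmannFit",
    "DecayFit",
    "ColeMooreResult",
    "GVCurve",
    "FitError",
    "boltzmann",
    "integrate_on_charge",
    "build_qv",
    "fit_boltzmann",
    "fit_double_boltzmann",
    "charge_from_slope",
    "fit_decay",
    "tau_voltage_curve",
    "local_maxima",
    "detect_crossings",
    "cole_moore_delay",
    "cole_moore_shift",
    "build_gv",
]

_LSQ_OPTS = dict(xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=200)


class FitError(RuntimeError):
    pass


def boltzmann(V, Q_half, slope_k):
    """y = 1 / (1 + exp(-(V - Q_half)/slope_k))."""
    V = np.asarray(V, dtype=float)
    x = np.clip(-(V - Q_half) / slope_k, -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(x))


@dataclass
class QVCurve:
    voltages: np.ndarray
    normalized_charge: np.ndarray
    raw_charge: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.normalized_charge = np.asarray(self.normalized_charge, dtype=float)
        if self.voltages.shape != self.normalized_charge.shape:
            raise ValueError("voltages/charge length mismatch")


@dataclass
class BoltzmannFit:
    Q_half: float
    slope_k: float
    amplitude: float
    residual_sse: float
    degenerate: bool = False

    def __call__(self, V):
        return self.amplitude * boltzmann(V, self.Q_half, self.slope_k)


@dataclass
class DoubleBoltzmannFit:
    fraction_1: float
    Q_half_1: float
    slope_k_1: float
    Q_half_2: float
    slope_k_2: float
    residual_sse: float
    flagged: bool = False

    def __call__(self, V):
        return (self.fraction_1 * boltzmann(V, self.Q_half_1, self.slope_k_1)
                + (1 - self.fraction_1) * boltzmann(V, self.Q_half_2, self.slope_k_2))


@dataclass
class DecayFit:
    amplitudes: tuple[float, ...]
    taus: tuple[float, ...]
    weighted_tau: float
    n_components: int
    residual_sse: float


@dataclass
class ColeMooreResult:
    prepulses: tuple[float, ...]
    delays: tuple[float, ...]
    shift: float


@dataclass
class GVCurve:
    voltages: np.ndarray
    normalized_conductance: np.ndarray
    midpoint: float
    slope_k: float


# ---------------------------------------------------------------------------
# charge integration and Q-V construction

def integrate_on_charge(trace: CurrentTrace,
                        window: tuple[float, float]) -> float:
    """Trapezoidal integral of the current over ``window``.

    Units follow the trace: pA*ms = fC, or e0 for per-channel gating
    flux in e0/ms.
    """
    sl = trace.window_slice(window)
    return float(np.trapezoid(trace.current[sl], trace.time[sl]))


def _default_window(trace: CurrentTrace) -> tuple[float, float]:
    bounds = trace.metadata.get("segment_bounds")
    if bounds:
        return tuple(bounds[-1])
    return (float(trace.time[0]), float(trace.time[-1]))


def build_qv(traces: Sequence[CurrentTrace],
             window: tuple[float, float] | None = None) -> QVCurve:
    """Integrate ON charge per episode and normalize to the maximum."""
    if len(traces) < 3:
        raise ValueError("need at least 3 episodes for a Q-V curve")
    charges, volts = [], []
    for tr in traces:
        w = window if window is not None else _default_window(tr)
        charges.append(integrate_on_charge(tr, w))
        volts.append(tr.step_voltage)
    charges = np.asarray(charges)
    qmax = charges.max()
    if qmax <= 0:
        raise ValueError("all integrated charges are <= 0; cannot normalize")
    return QVCurve(voltages=np.asarray(volts),
                   normalized_charge=charges / qmax,
                   raw_charge=charges)


# ---------------------------------------------------------------------------
# Boltzmann fitting

def _run_multistart(residual, starts, bounds):
    best = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            res = least_squares(residual, x0, bounds=bounds, **_LSQ_OPTS)
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    if best is None:
        raise FitError("no multistart converged")
    return best


def fit_boltzmann(qv: QVCurve, free_amplitude: bool = False) -> BoltzmannFit:
    """Least-squares single-Boltzmann fit of a normalized Q-V curve.

    By default the asymptotes are constrained to 0 and 1 (amplitude
    fixed at 1). A flat curve (unidentifiable slope) is flagged
    ``degenerate`` rather than silently returned.
    """
    V, y = qv.voltages, qv.normalized_charge
    if len(V) < 4:
        raise ValueError("need at least 4 points")
    if np.ptp(y) < 1e-3:
        return BoltzmannFit(Q_half=float("nan"), slope_k=float("nan"),
                            amplitude=float(np.mean(y)),
                            residual_sse=0.0, degenerate=True)
    span = max(np.ptp(V), 1.0)
    q_grid = np.quantile(V, [0.15, 0.3, 0.5, 0.7, 0.85])
    k_grid = [span / 40, span / 15, span / 6, span / 3]
    lo = [V.min() - span, 1e-3] + ([1e-6] if free_amplitude else [])
    hi = [V.max() + span, 10 * span] + ([10.0] if free_amplitude else [])
    starts = []
    for q0 in q_grid:
        for k0 in k_grid:
            starts.append([q0, k0] + ([1.0] if free_amplitude else []))

    if free_amplitude:
        def residual(p):
            return p[2] * boltzmann(V, p[0], p[1]) - y
    else:
        def residual(p):
            return boltzmann(V, p[0], p[1]) - y

    best = _run_multistart(residual, starts, (lo, hi))
    amp = best.x[2] if free_amplitude else 1.0
    return BoltzmannFit(Q_half=float(best.x[0]), slope_k=float(best.x[1]),
                        amplitude=float(amp),
                        residual_sse=float(2 * best.cost))


def fit_double_boltzmann(qv: QVCurve) -> DoubleBoltzmannFit:
    """Weighted two-component Boltzmann fit A*B1 + (1-A)*B2.

    Multistart guesses include the single-Boltzmann solution split by
    +/-40 mV. The ordering Q_half_1 < Q_half_2 is enforced after the
    fit (label-switch resolution); a mixing fraction pinned at its
    bounds is flagged.
    """
    V, y = qv.voltages, qv.normalized_charge
    if len(V) < 6:
        raise ValueError("need at least 6 points")

    def residual(p):
        A, q1, k1, q2, k2 = p
        return (A * boltzmann(V, q1, k1)
                + (1 - A) * boltzmann(V, q2, k2) - y)

    span = max(np.ptp(V), 1.0)
    lo = [1e-3, V.min() - span, 0.2, V.min() - span, 0.2]
    hi = [1 - 1e-3, V.max() + span, 10 * span, V.max() + span, 10 * span]
    starts = []
    try:
        single = fit_boltzmann(qv)
        if not single.degenerate:
            for d in (20.0, 40.0, 70.0):
                starts.append([0.2, single.Q_half - d, single.slope_k,
                               single.Q_half + d / 4, single.slope_k])
                starts.append([0.5, single.Q_half - d / 2, single.slope_k,
                               single.Q_half + d / 2, single.slope_k])
    except (FitError, ValueError):
        pass
    for A0 in (0.15, 0.3, 0.5):
        for q1 in np.quantile(V, [0.1, 0.3]):
            for q2 in np.quantile(V, [0.6, 0.85]):
                starts.append([A0, q1, span / 15, q2, span / 20])
    best = _run_multistart(residual, starts, (lo, hi))
    A, q1, k1, q2, k2 = best.x
    if q1 > q2:
        A, q1, k1, q2, k2 = 1 - A, q2, k2, q1, k1
    flagged = bool(A <= 2e-3 or A >= 1 - 2e-3)
    return DoubleBoltzmannFit(fraction_1=float(A), Q_half_1=float(q1),
                              slope_k_1=float(k1), Q_half_2=float(q2),
                              slope_k_2=float(k2),
                              residual_sse=float(2 * best.cost),
                              flagged=flagged)


def charge_from_slope(slope_k: float,
                      pc: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Apparent charge z = k_B*T/(slope*e0), in e0 units."""
    if not slope_k > 0:
        raise ValueError(f"slope_k must be > 0, got {slope_k}")
    return pc.thermal_voltage / slope_k


# ---------------------------------------------------------------------------
# decay kinetics

def _fit_exponentials(t, y, n_comp, tau0):
    """Fit sum of n_comp decaying exponentials with positive amplitudes."""
    scale = max(np.abs(y).max(), 1e-30)

    def model(p):
        out = np.zeros_like(t)
        for i in range(n_comp):
            out = out + p[2 * i] * np.exp(-t / p[2 * i + 1])
        return out

    starts = []
    if n_comp == 1:
        for f in (0.3, 1.0, 3.0):
            starts.append([y[0] if y[0] > 0 else scale, tau0 * f])
    else:
        for f in (0.2, 1.0):
            for g in (1.0, 5.0):
                a = max(y[0], scale) / 2
                starts.append([a, tau0 * f, a, tau0 * f * g])
    t_span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    lo = [0.0, 1e-6] * n_comp
    hi = [10 * scale, 100 * t_span] * n_comp
    best = _run_multistart(lambda p: model(p) - y, starts, (lo, hi))
    return best


def fit_decay(trace: CurrentTrace,
              fit_window: tuple[float, float] | None = None,
              improvement_threshold: float = 0.05) -> DecayFit:
    """Fit the post-peak current decay with 1 or 2 exponentials.

    The window defaults to [peak of the final segment, end of trace].
    A second component is kept only when it lowers the SSE by at least
    ``improvement_threshold`` (relative). The weighted time constant is
    sum(A_i tau_i)/sum(A_i).
    """
    if fit_window is None:
        w0, w1 = _default_window(trace)
        sl = trace.window_slice((w0, w1))
        seg_t = trace.time[sl]
        seg_i = trace.current[sl]
        ipk = int(np.argmax(seg_i))
        fit_window = (float(seg_t[ipk]), float(w1))
    sl = trace.window_slice(fit_window)
    t = trace.time[sl] - trace.time[sl][0]
    y = trace.current[sl]
    if len(t) < 5:
        raise FitError("decay window too short")
    # crude tau guess: time to fall to 1/e of the initial value
    below = np.nonzero(y < y[0] / math.e)[0]
    tau0 = float(t[below[0]]) if len(below) else float(t[-1] / 2)
    tau0 = max(tau0, float(t[1]))

    res1 = _fit_exponentials(t, y, 1, tau0)
    sse1 = 2 * res1.cost
    res2 = _fit_exponentials(t, y, 2, tau0)
    sse2 = 2 * res2.cost
    if sse2 < (1 - improvement_threshold) * sse1:
        p = res2.x
        amps, taus = (p[0], p[2]), (p[1], p[3])
        # drop a vanishing component
        if min(amps) < 1e-6 * max(amps):
            keep = int(np.argmax(amps))
            amps, taus = (amps[keep],), (taus[keep],)
        sse = sse2
    else:
        amps, taus = (res1.x[0],), (res1.x[1],)
        sse = sse1
    wt = float(np.dot(amps, taus) / np.sum(amps))
    return DecayFit(amplitudes=tuple(float(a) for a in amps),
                    taus=tuple(float(x) for x in taus),
                    weighted_tau=wt, n_components=len(amps),
                    residual_sse=float(sse))


def tau_voltage_curve(traces: Sequence[CurrentTrace],
                      fit_window: tuple[float, float] | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Weighted decay time constant per episode vs step voltage."""
    volts, taus = [], []
    for tr in traces:
        fit = fit_decay(tr, fit_window)
        volts.append(tr.step_voltage)
        taus.append(fit.weighted_tau)
    return np.asarray(volts), np.asarray(taus)


def local_maxima(voltages: np.ndarray, values: np.ndarray) -> list[float]:
    """Voltages of strict interior local maxima (endpoints count when
    they dominate their single neighbour)."""
    v = np.asarray(voltages)
    y = np.asarray(values)
    order = np.argsort(v)
    v, y = v[order], y[order]
    out = []
    for i in range(len(v)):
        left_ok = i == 0 or y[i] > y[i - 1]
        right_ok = i == len(v) - 1 or y[i] > y[i + 1]
        if left_ok and right_ok and 0 < i < len(v) - 1:
            out.append(float(v[i]))
    return out


# ---------------------------------------------------------------------------
# trace crossings, Cole-Moore, G-V

def detect_crossings(traces: Sequence[CurrentTrace],
                     fit_window: tuple[float, float] | None = None,
                     rel_tol: float = 1e-3,
                     ) -> list[tuple[float, float, bool]]:
    """For consecutive episode pairs, report whether the traces cross
    during the post-peak decay.

    A crossing requires a sign change of (later - earlier) after both
    peak times, with an excursion beyond ``rel_tol`` of the pair's peak
    amplitude on both sides (guards against numerical dithering).
    """
    out = []
    for a, b in zip(traces[:-1], traces[1:]):
        w = fit_window
        if w is None:
            w = _default_window(a)
        sla, slb = a.window_slice(w), b.window_slice(w)
        ya, yb = a.current[sla], b.current[slb]
        n = min(len(ya), len(yb))
        ya, yb = ya[:n], yb[:n]
        start = max(int(np.argmax(ya)), int(np.argmax(yb))) + 1
        diff = (yb - ya)[start:]
        tol = rel_tol * max(ya.max(), yb.max(), 1e-30)
        crossed = bool(len(diff) and diff.max() > tol and diff.min() < -tol)
        out.append((a.step_voltage, b.step_voltage, crossed))
    return out


def cole_moore_delay(trace: CurrentTrace,
                     window: tuple[float, float] | None = None) -> float:
    """Activation delay from a delayed mono-exponential rise fit.

    Fits I(t) = A*(1 - exp(-(t - t0)/tau)) for t >= t0 (zero before)
    over the test-step window and returns t0 relative to the step
    onset, clamped at >= 0.
    """
    if window is None:
        window = _default_window(trace)
    sl = trace.window_slice(window)
    t = trace.time[sl] - window[0]
    y = trace.current[sl]
    ymax = np.abs(y).max()
    if ymax <= 0:
        raise FitError("no activating current in window")

    def model(p):
        A, t0, tau = p
        out = A * (1.0 - np.exp(-np.maximum(t - t0, 0.0) / tau))
        return out

    t_span = float(t[-1])
    # tau guess from time to half maximum
    half = np.nonzero(y > 0.5 * y[-1])[0]
    tau0 = float(t[half[0]]) if len(half) else t_span / 5
    tau0 = max(tau0, t_span / 200)
    starts = [[y[-1], t0g, tau0 * f]
              for t0g in (0.0, tau0 / 2, tau0) for f in (0.5, 1.0, 2.0)]
    lo = [0.0, -t_span, 1e-6]
    hi = [10 * ymax, t_span, 100 * t_span]
    best = _run_multistart(lambda p: model(p) - y, starts, (lo, hi))
    t0 = float(best.x[1])
    return max(t0, 0.0)


def cole_moore_shift(traces: Sequence[CurrentTrace],
                     prepulses: Sequence[float],
                     window: tuple[float, float] | None = None) -> ColeMooreResult:
    """Delay per prepulse level and the shift deep-minus-shallow.

    The shift is delay(most hyperpolarized prepulse) - delay(least
    hyperpolarized prepulse).
    """
    delays = [cole_moore_delay(tr, window) for tr in traces]
    deep = int(np.argmin(prepulses))
    shallow = int(np.argmax(prepulses))
    return ColeMooreResult(prepulses=tuple(float(p) for p in prepulses),
                           delays=tuple(delays),
                           shift=float(delays[deep] - delays[shallow]))


def build_gv(traces: Sequence[CurrentTrace],
             window: tuple[float, float] | None = None) -> GVCurve:
    """Normalized peak ionic current vs step voltage with a Boltzmann
    fit for the midpoint."""
    peaks, volts = [], []
    for tr in traces:
        w = window if window is not None else _default_window(tr)
        sl = tr.window_slice(w)
        peaks.append(tr.current[sl].max())
        volts.append(tr.step_voltage)
    peaks = np.asarray(peaks, dtype=float)
    volts = np.asarray(volts, dtype=float)
    pmax = peaks.max()
    if pmax <= 0:
        raise ValueError("no positive peak currents; cannot normalize")
    norm = peaks / pmax
    fit = fit_boltzmann(QVCurve(voltages=volts, normalized_charge=norm))
    return GVCurve(voltages=volts, normalized_conductance=norm,
                   midpoint=fit.Q_half, slope_k=fit.slope_k)
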