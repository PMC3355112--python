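"""Synthetic patch-clamp recordings: model current + noise + recording
artifacts, with the generating ground truth attached.

The acquisition chain mirrors a whole-cell rig: Gaussian current noise
added to the model current, a causal 4-pole low-pass Bessel filter
(-3 dB at the cutoff, monotone step response), optional decimation to
the recording sample rate, linear leak, capacitive transients, and P/8
subtraction.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .constants import PhysicalConstants, DEFAULT_CONSTANTS
from .kinetics import ChannelAssembly, build_state_space
from .protocol import (
    CurrentTrace,
    VoltageProtocol,
    gating_current_trace,
    ionic_current_trace,
    propagate_occupancy,
)
from .analysis import QVCurve, build_qv

__all__ = [
    "NoiseModel",
    "SyntheticRecording",
    "generate_recording",
    "add_leak_and_capacitance",
    "make_p8_protocol",
    "p_over_8_subtract",
    "mixed_population_qv",
    "noise_bandwidth_factor",
]


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian noise + acquisition filter parameters.

    rms_noise in pA (pre-filter), cutoff and sample rate in kHz.
    """

    rms_noise: float = 2.0
    filter_cutoff: float = 1.0
    sample_rate: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rms_noise < 0:
            raise ValueError("rms_noise must be >= 0")
        if self.filter_cutoff is not None and self.filter_cutoff > self.sample_rate / 2:
            raise ValueError("filter cutoff must be <= Nyquist (sample_rate/2)")


def _bessel_sos(noise: NoiseModel):
    return signal.bessel(4, noise.filter_cutoff, btype="low", output="sos",
                         fs=noise.sample_rate, norm="mag")


def noise_bandwidth_factor(noise: NoiseModel, n: int = 1 << 16) -> float:
    """sqrt of the filter's mean power gain over the sampled band.

    White noise of standard deviation s has standard deviation
    ``s * noise_bandwidth_factor(noise)`` after the filter.
    """
    sos = _bessel_sos(noise)
    w, h = signal.sosfreqz(sos, worN=n, fs=noise.sample_rate)
    return float(np.sqrt(np.mean(np.abs(h) ** 2)))


def apply_filter(current: np.ndarray, noise: NoiseModel) -> np.ndarray:
    """Causal low-pass Bessel filter (DC gain 1, -3 dB at cutoff)."""
    sos = _bessel_sos(noise)
    return signal.sosfilt(sos, current)


@dataclass
class SyntheticRecording:
    traces: list[CurrentTrace]
    ground_truth: dict
    subtracted: bool = False


def _model_traces(asm: ChannelAssembly, prot: VoltageProtocol,
                  pc: PhysicalConstants, kind: str) -> list[CurrentTrace]:
    space = build_state_space(asm)
    out = []
    for ep in range(prot.n_episodes):
        traj = propagate_occupancy(asm, prot, ep, pc, space)
        if kind == "gating":
            out.append(gating_current_trace(traj, space, asm, pc, in_pA=True))
        else:
            out.append(ionic_current_trace(traj, asm, space))
    return out


def generate_recording(asm: ChannelAssembly | Sequence[tuple[float, ChannelAssembly]],
                       prot: VoltageProtocol, noise: NoiseModel,
                       pc: PhysicalConstants = DEFAULT_CONSTANTS,
                       kind: str = "gating",
                       filter_enabled: bool = True) -> SyntheticRecording:
    """Simulate, add Gaussian noise, filter, and resample.

    ``asm`` may be a single assembly or a list of (weight, assembly)
    pairs for a mixed channel population; weights are channel-count
    fractions.

    Randomness is fully determined by ``noise.seed``.
    """
    if isinstance(asm, ChannelAssembly):
        population = [(1.0, asm)]
    else:
        population = list(asm)
    traces: list[CurrentTrace] | None = None
    for w, a in population:
        part = _model_traces(a, prot, pc, kind)
        if traces is None:
            traces = part
            for tr in traces:
                tr.current = w * tr.current
        else:
            for tr, p in zip(traces, part):
                tr.current = tr.current + w * p.current
    assert traces is not None

    rng = np.random.default_rng(noise.seed)
    sim_rate = 1.0 / prot.sample_interval  # kHz
    decim = max(int(round(sim_rate / noise.sample_rate)), 1)
    # sample indices of command discontinuities (segment boundaries)
    boundary_idx = np.cumsum([int(round(d / prot.sample_interval))
                              for d, _ in prot.segments(0)])[:-1]
    out = []
    for tr in traces:
        y = tr.current.copy()
        if filter_enabled and noise.filter_cutoff is not None:
            # the model current jumps at step onsets; a discrete filter
            # weights every sample fully, so split the discontinuity
            # sample (trapezoid convention) to preserve charge
            for k in boundary_idx:
                y[k] = 0.5 * (y[k - 1] + y[k])
        if noise.rms_noise > 0:
            y = y + rng.normal(0.0, noise.rms_noise, size=y.shape)
        if filter_enabled and noise.filter_cutoff is not None:
            nm = NoiseModel(rms_noise=noise.rms_noise,
                            filter_cutoff=noise.filter_cutoff,
                            sample_rate=sim_rate, seed=noise.seed)
            y = apply_filter(y, nm)
        time = tr.time
        if decim > 1:
            y = y[::decim]
            time = time[::decim]
        out.append(CurrentTrace(time=time.copy(), current=y,
                                step_voltage=tr.step_voltage, kind=tr.kind,
                                command=None if tr.command is None
                                else tr.command[::decim].copy(),
                                metadata=dict(tr.metadata)))
    gt = {
        "population": [(w, a.to_dict()) for w, a in population],
        "noise": {"rms_noise": noise.rms_noise,
                  "filter_cutoff": noise.filter_cutoff,
                  "sample_rate": noise.sample_rate, "seed": noise.seed},
        "protocol": prot.to_dict(),
        "kind": kind,
        "filter_enabled": filter_enabled,
        "temperature": pc.temperature,
    }
    return SyntheticRecording(traces=out, ground_truth=gt, subtracted=True)


def add_leak_and_capacitance(trace: CurrentTrace, leak_conductance: float,
                             leak_reversal: float, cap: float,
                             series_tau: float) -> CurrentTrace:
    """Add linear leak g*(V - E_leak) and exponential capacitive
    transients cap*dV/series_tau * exp(-(t-ts)/series_tau) at every
    command step. Units: nS, mV, pF, ms -> pA.
    """
    if trace.command is None:
        raise ValueError("trace carries no command voltage")
    t, v = trace.time, trace.command
    y = trace.current + leak_conductance * (v - leak_reversal)
    jumps = np.nonzero(np.diff(v) != 0)[0] + 1
    for j in jumps:
        dv = v[j] - v[j - 1]
        ts = t[j]
        tail = t >= ts - 1e-12
        y = y + np.where(tail,
                         cap * dv / series_tau * np.exp(-(t - ts) / series_tau),
                         0.0)
    out = copy.copy(trace)
    out.current = y
    out.metadata = dict(trace.metadata)
    out.metadata["leak"] = {"g": leak_conductance, "E": leak_reversal,
                            "cap": cap, "series_tau": series_tau}
    return out


def make_p8_protocol(prot: VoltageProtocol, episode: int,
                     subtraction_holding: float | None = None,
                     n_subpulses: int = 8) -> VoltageProtocol:
    """Build the P/8 companion protocol for one test episode.

    Each of the 8 subpulse episodes follows the same segment sequence
    with voltage deviations from the subtraction holding scaled by 1/8.
    """
    if subtraction_holding is None:
        subtraction_holding = prot.holding_potential
    segs = prot.segments(episode)
    sub_segs = tuple(
        (dur, subtraction_holding + (v - prot.holding_potential) / n_subpulses)
        for dur, v in segs)
    return VoltageProtocol(
        episodes=tuple(sub_segs for _ in range(n_subpulses)),
        episode_labels=tuple(float(i) for i in range(n_subpulses)),
        holding_potential=subtraction_holding,
        sample_interval=prot.sample_interval)


def _baseline(trace: CurrentTrace) -> float:
    """Mean current over the initial holding segment (first 80%)."""
    bounds = trace.metadata.get("segment_bounds")
    if bounds:
        t0, t1 = bounds[0]
    else:
        t0, t1 = trace.time[0], trace.time[0] + 0.1 * (trace.time[-1] - trace.time[0])
    sl = trace.window_slice((t0, t0 + 0.8 * (t1 - t0)))
    return float(trace.current[sl].mean())


def p_over_8_subtract(raw: CurrentTrace,
                      subpulses: Sequence[CurrentTrace]) -> CurrentTrace:
    """Subtract the scaled average of the 8 subpulse responses.

    Both the raw episode and the subpulses are baseline-aligned on
    their initial holding segment first; linear (leak + capacitive)
    components then cancel exactly.
    """
    for sp in subpulses:
        if sp.time.shape != raw.time.shape or not np.allclose(sp.time, raw.time):
            raise ValueError("subpulse grid does not match the raw episode")
    n = len(subpulses)
    avg = np.mean([sp.current - _baseline(sp) for sp in subpulses], axis=0)
    corrected = (raw.current - _baseline(raw)) - n * avg
    out = copy.copy(raw)
    out.current = corrected
    out.metadata = dict(raw.metadata)
    out.metadata["p_over_n_subtracted"] = n
    return out


def mixed_population_qv(frac_hetero: float, asm_homo: ChannelAssembly,
                        asm_hetero: ChannelAssembly, prot: VoltageProtocol,
                        pc: PhysicalConstants = DEFAULT_CONSTANTS,
                        ) -> tuple[QVCurve, list[CurrentTrace], dict]:
    """Q-V of a mixed homo/heterotetramer population.

    The population gating current is the channel-fraction-weighted sum
    of the per-channel currents of the two assemblies.
    """
    if not 0.0 <= frac_hetero <= 1.0:
        raise ValueError("frac_hetero must be in [0, 1]")
    parts = []
    for w, a in ((1.0 - frac_hetero, asm_homo), (frac_hetero, asm_hetero)):
        if w > 0:
            parts.append((w, _model_traces(a, prot, pc, "gating")))
    traces = []
    for ep in range(prot.n_episodes):
        base = parts[0][1][ep]
        cur = sum(w * p[ep].current for w, p in parts)
        tr = copy.copy(base)
        tr.current = cur
        tr.metadata = dict(base.metadata)
        traces.append(tr)
    qv = build_qv(traces)
    gt = {"frac_hetero": frac_hetero, "homo": asm_homo.to_dict(),
          "hetero": asm_hetero.to_dict()}
    return qv, traces, gt
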