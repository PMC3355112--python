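"""Voltage protocols, deterministic propagation, and current synthesis.

Occupancies are propagated segment by segment with the matrix
exponential of the (constant) generator; samples sit on a uniform grid
that includes both endpoints of every episode, with segment boundaries
sharing a sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .constants import PhysicalConstants, DEFAULT_CONSTANTS
from .kinetics import (
    ChannelAssembly,
    StateSpace,
    build_state_space,
    equilibrium_distribution,
    generator_at_voltage,
    transition_rates,
)

__all__ = [
    "VoltageProtocol",
    "CurrentTrace",
    "OccupancyTrajectory",
    "PropagationError",
    "make_gating_protocol",
    "make_cole_moore_protocol",
    "propagate_occupancy",
    "gating_current_trace",
    "ionic_current_trace",
    "gillespie_simulate",
]

E0_PER_MS_TO_PA = 1.602176634e-4  # 1 e0/ms expressed in pA


class PropagationError(RuntimeError):
    pass


@dataclass(frozen=True)
class VoltageProtocol:
    """Episodic piecewise-constant command voltage.

    episodes : one list of (duration_ms, voltage_mV) segments per sweep.
    episode_labels : one label per sweep (typically the varied voltage).
    """

    episodes: tuple[tuple[tuple[float, float], ...], ...]
    episode_labels: tuple[float, ...]
    holding_potential: float
    sample_interval: float

    def __post_init__(self) -> None:
        if len(self.episodes) != len(self.episode_labels):
            raise ValueError("one label per episode required")
        if not self.sample_interval > 0:
            raise ValueError("sample_interval must be > 0")
        for segs in self.episodes:
            for dur, _ in segs:
                if dur <= 0:
                    raise ValueError("segment durations must be > 0")
                if self.sample_interval > dur + 1e-12:
                    raise ValueError(
                        "sample_interval must not exceed the shortest segment")

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)

    def segments(self, episode: int) -> tuple[tuple[float, float], ...]:
        return self.episodes[episode]

    def time_grid(self, episode: int) -> np.ndarray:
        total = sum(d for d, _ in self.episodes[episode])
        n = int(round(total / self.sample_interval))
        return np.arange(n + 1) * self.sample_interval

    def command_voltage(self, episode: int) -> np.ndarray:
        """Voltage at each sample; boundary samples take the new segment."""
        t = self.time_grid(episode)
        v = np.empty_like(t)
        start = 0.0
        v[:] = self.episodes[episode][-1][1]
        for dur, volt in self.episodes[episode]:
            v[(t >= start - 1e-9) & (t < start + dur - 1e-9)] = volt
            start += dur
        v[-1] = self.episodes[episode][-1][1]
        return v

    def segment_window(self, episode: int, index: int) -> tuple[float, float]:
        """(start, end) time of segment ``index`` (negative allowed)."""
        segs = self.episodes[episode]
        starts = np.concatenate([[0.0], np.cumsum([d for d, _ in segs])])
        if index < 0:
            index += len(segs)
        return float(starts[index]), float(starts[index + 1])

    def to_dict(self) -> dict:
        return {
            "episodes": [[list(s) for s in segs] for segs in self.episodes],
            "episode_labels": list(self.episode_labels),
            "holding_potential": self.holding_potential,
            "sample_interval": self.sample_interval,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageProtocol":
        return cls(
            episodes=tuple(tuple((float(a), float(b)) for a, b in segs)
                           for segs in d["episodes"]),
            episode_labels=tuple(float(x) for x in d["episode_labels"]),
            holding_potential=float(d["holding_potential"]),
            sample_interval=float(d["sample_interval"]),
        )


@dataclass
class CurrentTrace:
    """One sampled current episode.

    current is in pA for ionic traces and, by default, in e0/ms per
    channel for gating traces (see ``gating_current_trace``).
    """

    time: np.ndarray
    current: np.ndarray
    step_voltage: float
    kind: str  # 'gating' | 'ionic'
    command: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape:
            raise ValueError("time and current must have equal length")
        dt = np.diff(self.time)
        if len(dt) and (np.any(dt <= 0)
                        or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12)):
            raise ValueError("time grid must be strictly increasing and uniform")

    @property
    def sample_interval(self) -> float:
        return float(self.time[1] - self.time[0])

    def window_slice(self, window: tuple[float, float]) -> slice:
        t0, t1 = window
        if t0 < self.time[0] - 1e-9 or t1 > self.time[-1] + 1e-9:
            raise ValueError(f"window {window} outside trace span "
                             f"[{self.time[0]}, {self.time[-1]}]")
        i0 = int(np.searchsorted(self.time, t0 - 1e-9))
        i1 = int(np.searchsorted(self.time, t1 + 1e-9))  # end sample included
        return slice(i0, i1)


@dataclass
class OccupancyTrajectory:
    """Per-state occupancy along one protocol episode."""

    time: np.ndarray
    probabilities: np.ndarray  # (n_time, n_states)
    voltages: np.ndarray       # command at each sample
    step_voltage: float
    segment_bounds: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.probabilities.shape[0] != self.time.shape[0]:
            raise ValueError("time/probability length mismatch")


def make_gating_protocol(start: float = -140.0, stop: float = 40.0,
                         increment: float = 10.0, step_ms: float = 60.0,
                         prepulse_mV: float = -140.0, prepulse_ms: float = 20.0,
                         holding_mV: float = -100.0, holding_ms: float = 10.0,
                         sample_interval_ms: float = 0.1) -> VoltageProtocol:
    """Standard ON-gating protocol: holding, prepulse, then one test
    step per sweep from ``start`` to ``stop`` in ``increment`` steps."""
    if increment <= 0:
        raise ValueError("increment must be > 0")
    if start > stop:
        raise ValueError("start must be <= stop")
    n = int(round((stop - start) / increment)) + 1
    steps = [start + i * increment for i in range(n)]
    episodes = tuple(
        ((holding_ms, holding_mV), (prepulse_ms, prepulse_mV), (step_ms, v))
        for v in steps
    )
    return VoltageProtocol(episodes=episodes, episode_labels=tuple(steps),
                           holding_potential=holding_mV,
                           sample_interval=sample_interval_ms)


def make_cole_moore_protocol(prepulse_mVs: Sequence[float],
                             prepulse_ms: float = 100.0,
                             test_mV: float = 40.0, test_ms: float = 60.0,
                             holding_mV: float = -100.0,
                             holding_ms: float = 10.0,
                             sample_interval_ms: float = 0.01) -> VoltageProtocol:
    """Identical test step after a family of conditioning prepulses.

    Labels carry the prepulse voltage.
    """
    if len(prepulse_mVs) < 1:
        raise ValueError("at least one prepulse level required")
    episodes = tuple(
        ((holding_ms, holding_mV), (prepulse_ms, v), (test_ms, test_mV))
        for v in prepulse_mVs
    )
    return VoltageProtocol(episodes=episodes,
                           episode_labels=tuple(float(v) for v in prepulse_mVs),
                           holding_potential=holding_mV,
                           sample_interval=sample_interval_ms)


def propagate_occupancy(asm: ChannelAssembly, prot: VoltageProtocol,
                        episode: int,
                        pc: PhysicalConstants = DEFAULT_CONSTANTS,
                        space: StateSpace | None = None) -> OccupancyTrajectory:
    """Solve the master equation along one episode.

    The initial condition is the equilibrium at the holding potential;
    within each segment the constant generator is propagated by powers
    of expm(Q*dt), which is exact for piecewise-constant commands.
    """
    if not 0 <= episode < prot.n_episodes:
        raise IndexError(f"episode {episode} out of range")
    if space is None:
        space = build_state_space(asm)
    dt = prot.sample_interval
    segs = prot.segments(episode)
    t = prot.time_grid(episode)
    p = equilibrium_distribution(asm, prot.holding_potential, pc, space)
    probs = np.empty((len(t), space.n_states))
    probs[0] = p
    k = 0
    bounds = []
    t_cursor = 0.0
    for dur, volt in segs:
        n_steps = int(round(dur / dt))
        if abs(n_steps * dt - dur) > 1e-6 * max(dt, dur):
            raise PropagationError(
                f"segment duration {dur} is not a multiple of dt={dt}")
        Q = generator_at_voltage(asm, volt, pc, space).entries
        P = expm(Q * dt)
        for _ in range(n_steps):
            p = p @ P
            k += 1
            probs[k] = p
        bounds.append((t_cursor, t_cursor + dur))
        t_cursor += dur
    if np.any(probs < -1e-9) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-8):
        raise PropagationError("occupancy left the probability simplex")
    probs = np.clip(probs, 0.0, None)
    return OccupancyTrajectory(time=t, probabilities=probs,
                               voltages=prot.command_voltage(episode),
                               step_voltage=prot.episode_labels[episode],
                               segment_bounds=tuple(bounds))


def gating_current_trace(traj: OccupancyTrajectory, space: StateSpace,
                         asm: ChannelAssembly,
                         pc: PhysicalConstants = DEFAULT_CONSTANTS,
                         per_channel: bool = True,
                         in_pA: bool = False) -> CurrentTrace:
    """Gating current from net charge flux over every transition.

    I_Q(t) = sum over forward edges of charge * (p_src*k_fwd - p_tgt*k_bwd),
    positive for outward (activating) charge movement. Units are e0/ms
    per channel by default; set ``in_pA=True`` (implies population
    scaling by ``asm.n_channels``) for picoamperes.
    """
    if traj.probabilities.shape[1] != space.n_states:
        raise ValueError("trajectory/state-space dimension mismatch")
    current = np.zeros(len(traj.time))
    # rates change only at segment boundaries: group samples by voltage
    for volt in np.unique(traj.voltages):
        mask = traj.voltages == volt
        rates = transition_rates(space, asm, float(volt), pc)
        p = traj.probabilities[mask]
        flux = np.zeros(mask.sum())
        for t_edge, r in zip(space.transitions, rates):
            if not t_edge.forward:
                continue
            rev = next(rr for te, rr in zip(space.transitions, rates)
                       if te.source == t_edge.target and te.target == t_edge.source
                       and te.kind == t_edge.kind)
            flux += t_edge.charge * (p[:, t_edge.source] * r
                                     - p[:, t_edge.target] * rev)
        current[mask] = flux
    scale = 1.0
    if not per_channel or in_pA:
        scale *= asm.n_channels
    if in_pA:
        scale *= E0_PER_MS_TO_PA
    return CurrentTrace(time=traj.time.copy(), current=current * scale,
                        step_voltage=traj.step_voltage, kind="gating",
                        command=traj.voltages.copy(),
                        metadata={"units": "pA" if in_pA else "e0/ms",
                                  "per_channel": per_channel and not in_pA,
                                  "segment_bounds": list(traj.segment_bounds)})


def ionic_current_trace(traj: OccupancyTrajectory, asm: ChannelAssembly,
                        space: StateSpace | None = None) -> CurrentTrace:
    """Ohmic ionic current through the open state, in pA."""
    if space is None:
        n_states = traj.probabilities.shape[1]
        open_idx = n_states - 1
    else:
        if traj.probabilities.shape[1] != space.n_states:
            raise ValueError("trajectory/state-space dimension mismatch")
        open_idx = space.open_index
    p_open = traj.probabilities[:, open_idx]
    current = (asm.n_channels * asm.single_channel_conductance
               * p_open * (traj.voltages - asm.reversal_potential))
    return CurrentTrace(time=traj.time.copy(), current=current,
                        step_voltage=traj.step_voltage, kind="ionic",
                        command=traj.voltages.copy(),
                        metadata={"units": "pA",
                                  "segment_bounds": list(traj.segment_bounds)})


def gillespie_simulate(asm: ChannelAssembly, prot: VoltageProtocol,
                       episode: int, n_channels: int, seed: int,
                       pc: PhysicalConstants = DEFAULT_CONSTANTS,
                       space: StateSpace | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Exact-jump stochastic simulation of ``n_channels`` independent
    channels along one episode.

    Piecewise-constant rates are handled by discarding any putative jump
    that would land beyond the current segment boundary and redrawing
    from the boundary (valid because the exponential clock is memoryless
    within a segment).

    Returns (time_grid, counts) where counts[t, s] is the number of
    channels in state s at each sample time.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if space is None:
        space = build_state_space(asm)
    rng = np.random.default_rng(seed)
    dt = prot.sample_interval
    t_grid = prot.time_grid(episode)
    segs = prot.segments(episode)
    n_states = space.n_states
    # per-voltage jump tables
    seg_tables = []
    t_cursor = 0.0
    for dur, volt in segs:
        rates = transition_rates(space, asm, float(volt), pc)
        out_rates = np.zeros(n_states)
        targets: list[list[int]] = [[] for _ in range(n_states)]
        probs: list[list[float]] = [[] for _ in range(n_states)]
        for tr, r in zip(space.transitions, rates):
            out_rates[tr.source] += r
            targets[tr.source].append(tr.target)
            probs[tr.source].append(r)
        cum = [np.cumsum(p) for p in probs]
        seg_tables.append((t_cursor, t_cursor + dur, out_rates, targets, cum))
        t_cursor += dur
    p0 = equilibrium_distribution(asm, prot.holding_potential, pc, space)
    init = rng.choice(n_states, size=n_channels, p=p0)
    counts = np.zeros((len(t_grid), n_states), dtype=np.int64)
    for ch in range(n_channels):
        s = int(init[ch])
        t = 0.0
        sample_idx = 0
        for (seg_start, seg_end, out_rates, targets, cum) in seg_tables:
            while t < seg_end - 1e-12:
                rate = out_rates[s]
                t_jump = seg_end if rate == 0 else t + rng.exponential(1.0 / rate)
                t_next = min(t_jump, seg_end)
                # record samples passed before this jump/boundary
                last = min(int(np.floor(t_next / dt + 1e-9)), len(t_grid) - 1)
                while sample_idx <= last:
                    counts[sample_idx, s] += 1
                    sample_idx += 1
                if t_jump >= seg_end:
                    t = seg_end
                else:
                    t = t_jump
                    u = rng.random() * cum[s][-1]
                    s = targets[s][int(np.searchsorted(cum[s], u))]
        while sample_idx < len(t_grid):
            counts[sample_idx, s] += 1
            sample_idx += 1
    return t_grid, counts
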