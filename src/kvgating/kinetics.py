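"""Subunit rate laws, channel state space, and generator matrices.

The channel is a tetramer: three identical "common" voltage-sensor
subunits plus one "distinct" subunit (equal to the common one for a
homotetramer). Each subunit switches between a closed (C) and an
activated (A) conformation with exponentially voltage-dependent rates

    alpha(V) = alpha0 * exp(+z_alpha_delta * V / V_T)
    beta(V)  = beta0  * exp(-z_beta_delta  * V / V_T)

where V_T = k_B*T/e0. Once all four sensors are activated, a final
voltage-independent concerted step opens the pore.

The aggregated state space has 9 states: (n, d) with n in {0..3}
activated common subunits and d in {C, A} for the distinct subunit,
plus a single open state O reachable only from (3, A). States are
ordered lexicographically (n ascending, C before A) with O last.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import PhysicalConstants, DEFAULT_CONSTANTS

__all__ = [
    "SubunitKinetics",
    "ChannelAssembly",
    "StateSpace",
    "Transition",
    "GeneratorMatrix",
    "rate_alpha",
    "rate_beta",
    "build_state_space",
    "generator_at_voltage",
    "equilibrium_distribution",
    "calibrate_from_boltzmann",
    "CalibrationError",
]

SCHEMA_VERSION = 1


class CalibrationError(ValueError):
    """Raised when Boltzmann/tau constraints cannot be met."""


@dataclass(frozen=True)
class SubunitKinetics:
    """Rate-law parameters of one voltage sensor.

    alpha0, beta0 : forward/backward rates at 0 mV (1/ms).
    z_alpha_delta, z_beta_delta : charge-distance products (e0 units)
        entering the forward and backward exponents; their sum is the
        total charge displaced by one C->A transition.
    """

    alpha0: float
    beta0: float
    z_alpha_delta: float
    z_beta_delta: float

    def __post_init__(self) -> None:
        if not (self.alpha0 > 0 and self.beta0 > 0):
            raise ValueError("alpha0 and beta0 must be > 0")
        if self.z_alpha_delta < 0 or self.z_beta_delta < 0:
            raise ValueError("charge-distance products must be >= 0")
        if self.z_alpha_delta + self.z_beta_delta <= 0:
            raise ValueError("total charge per transition must be > 0")

    @property
    def total_charge(self) -> float:
        """Charge displaced by one full C->A transition (e0)."""
        return self.z_alpha_delta + self.z_beta_delta

    def v_half(self, pc: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
        """Voltage (mV) at which alpha(V) == beta(V)."""
        return (
            pc.thermal_voltage
            * math.log(self.beta0 / self.alpha0)
            / self.total_charge
        )

    def to_dict(self) -> dict:
        return {
            "alpha0": self.alpha0,
            "beta0": self.beta0,
            "z_alpha_delta": self.z_alpha_delta,
            "z_beta_delta": self.z_beta_delta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubunitKinetics":
        return cls(**{k: float(d[k]) for k in
                      ("alpha0", "beta0", "z_alpha_delta", "z_beta_delta")})


def rate_alpha(kin: SubunitKinetics, V: float,
               pc: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Forward (activation) rate at voltage V in 1/ms."""
    if not np.isfinite(V):
        raise ValueError(f"voltage must be finite, got {V}")
    return kin.alpha0 * math.exp(kin.z_alpha_delta * V / pc.thermal_voltage)


def rate_beta(kin: SubunitKinetics, V: float,
              pc: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Backward (deactivation) rate at voltage V in 1/ms."""
    if not np.isfinite(V):
        raise ValueError(f"voltage must be finite, got {V}")
    return kin.beta0 * math.exp(-kin.z_beta_delta * V / pc.thermal_voltage)


@dataclass(frozen=True)
class ChannelAssembly:
    """A tetrameric channel: 3 common subunits + 1 distinct subunit.

    For a homotetramer set ``distinct == common`` (field-wise); the
    :meth:`homotetramer` constructor does this for you.

    The final opening step is voltage independent and displaces no
    charge. ``single_channel_conductance`` is in nS and
    ``reversal_potential`` in mV, so ionic currents come out in pA per
    channel.
    """

    common: SubunitKinetics
    distinct: SubunitKinetics
    opening_rate: float = 1.0
    closing_rate: float = 5.0
    single_channel_conductance: float = 0.01
    reversal_potential: float = -85.0
    n_channels: int = 1

    def __post_init__(self) -> None:
        if not (self.opening_rate > 0 and self.closing_rate > 0):
            raise ValueError("opening and closing rates must be > 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")

    @classmethod
    def homotetramer(cls, kin: SubunitKinetics, **kwargs) -> "ChannelAssembly":
        return cls(common=kin, distinct=kin, **kwargs)

    @property
    def is_homotetramer(self) -> bool:
        return self.common == self.distinct

    @property
    def total_gating_charge(self) -> float:
        """Total charge moved by full activation: 3*z_common + z_distinct."""
        return 3.0 * self.common.total_charge + self.distinct.total_charge

    # -- JSON model file ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "common": self.common.to_dict(),
            "distinct": self.distinct.to_dict(),
            "opening_rate": self.opening_rate,
            "closing_rate": self.closing_rate,
            "single_channel_conductance": self.single_channel_conductance,
            "reversal_potential": self.reversal_potential,
            "n_channels": self.n_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelAssembly":
        schema = d.get("schema", SCHEMA_VERSION)
        if schema != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {schema!r}")
        return cls(
            common=SubunitKinetics.from_dict(d["common"]),
            distinct=SubunitKinetics.from_dict(d["distinct"]),
            opening_rate=float(d["opening_rate"]),
            closing_rate=float(d["closing_rate"]),
            single_channel_conductance=float(d["single_channel_conductance"]),
            reversal_potential=float(d["reversal_potential"]),
            n_channels=int(d["n_channels"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChannelAssembly":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def with_(self, **kwargs) -> "ChannelAssembly":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Transition:
    """One directed edge of the state graph.

    kind : 'common', 'distinct' or 'opening'
    multiplicity : combinatorial factor multiplying the unit rate
    charge : signed charge displacement (e0) in this direction
    """

    source: int
    target: int
    kind: str
    forward: bool
    multiplicity: int
    charge: float


@dataclass(frozen=True)
class StateSpace:
    """The 9-state aggregated graph with per-edge charge displacements."""

    labels: tuple[str, ...]
    states: tuple[tuple[int, int, bool], ...]  # (n_common_active, distinct_active, open)
    transitions: tuple[Transition, ...]

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def open_index(self) -> int:
        return self.n_states - 1

    def index(self, n_common: int, distinct_active: int, is_open: bool = False) -> int:
        return self.states.index((n_common, distinct_active, is_open))

    def charge_vector(self) -> np.ndarray:
        """Cumulative activated charge of each state relative to (0, C)."""
        out = np.empty(self.n_states)
        # charges are consistent along every path of the tree, so walk
        # from the transitions themselves
        zc = next(t.charge for t in self.transitions
                  if t.kind == "common" and t.forward)
        zd = next(t.charge for t in self.transitions
                  if t.kind == "distinct" and t.forward)
        for i, (n, d, _) in enumerate(self.states):
            out[i] = n * zc + d * zd
        return out


def build_state_space(asm: ChannelAssembly) -> StateSpace:
    """Assemble the 9-state ladder with multiplicities and edge charges.

    Ordering: (n ascending, distinct C before A), open state last.
    """
    states: list[tuple[int, int, bool]] = []
    labels: list[str] = []
    for n in range(4):
        for d in (0, 1):
            states.append((n, d, False))
            labels.append(f"C{3 - n}A{n}" + ("*A" if d else "*C"))
    states.append((3, 1, True))
    labels.append("O")

    idx = {s: i for i, s in enumerate(states)}
    zc = asm.common.total_charge
    zd = asm.distinct.total_charge

    transitions: list[Transition] = []
    for n in range(4):
        for d in (0, 1):
            i = idx[(n, d, False)]
            if n < 3:
                j = idx[(n + 1, d, False)]
                transitions.append(Transition(i, j, "common", True, 3 - n, zc))
                transitions.append(Transition(j, i, "common", False, n + 1, -zc))
            if d == 0:
                j = idx[(n, 1, False)]
                transitions.append(Transition(i, j, "distinct", True, 1, zd))
                transitions.append(Transition(j, i, "distinct", False, 1, -zd))
    i, j = idx[(3, 1, False)], idx[(3, 1, True)]
    transitions.append(Transition(i, j, "opening", True, 1, 0.0))
    transitions.append(Transition(j, i, "opening", False, 1, 0.0))

    return StateSpace(tuple(labels), tuple(states), tuple(transitions))


@dataclass(frozen=True)
class GeneratorMatrix:
    """Rate (generator) matrix of the master equation at one voltage."""

    entries: np.ndarray  # (9, 9), 1/ms
    voltage: float

    def __post_init__(self) -> None:
        q = self.entries
        if q.shape[0] != q.shape[1]:
            raise ValueError("generator must be square")


def _unit_rates(asm: ChannelAssembly, V: float, pc: PhysicalConstants) -> dict[str, tuple[float, float]]:
    """(forward, backward) unit rates per transition kind at voltage V."""
    return {
        "common": (rate_alpha(asm.common, V, pc), rate_beta(asm.common, V, pc)),
        "distinct": (rate_alpha(asm.distinct, V, pc), rate_beta(asm.distinct, V, pc)),
        "opening": (asm.opening_rate, asm.closing_rate),
    }


def transition_rates(space: StateSpace, asm: ChannelAssembly, V: float,
                     pc: PhysicalConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Rate of every directed transition (same order as space.transitions)."""
    unit = _unit_rates(asm, V, pc)
    return np.array([t.multiplicity * unit[t.kind][0 if t.forward else 1]
                     for t in space.transitions])


def generator_at_voltage(asm: ChannelAssembly, V: float,
                         pc: PhysicalConstants = DEFAULT_CONSTANTS,
                         space: StateSpace | None = None) -> GeneratorMatrix:
    """Build the 9x9 generator matrix at a fixed voltage.

    Convention: Q[i, j] for i != j is the i->j rate; rows sum to zero.
    Occupancy row-vectors evolve as dp/dt = p @ Q.
    """
    if space is None:
        space = build_state_space(asm)
    rates = transition_rates(space, asm, V, pc)
    n = space.n_states
    Q = np.zeros((n, n))
    for t, r in zip(space.transitions, rates):
        Q[t.source, t.target] += r
    Q[np.diag_indices(n)] -= Q.sum(axis=1)
    return GeneratorMatrix(entries=Q, voltage=float(V))


def equilibrium_distribution(asm: ChannelAssembly, V: float,
                             pc: PhysicalConstants = DEFAULT_CONSTANTS,
                             space: StateSpace | None = None) -> np.ndarray:
    """Stationary distribution of the generator at voltage V.

    The graph is a tree, so the stationary law satisfies detailed
    balance and has a product form; it is computed here by propagating
    equilibrium constants edge by edge, which is exact and robust for
    extreme voltages.
    """
    if space is None:
        space = build_state_space(asm)
    vt = pc.thermal_voltage
    # log equilibrium constants, written from the raw parameters so
    # extreme voltages cannot overflow
    log_ka = (math.log(asm.common.alpha0 / asm.common.beta0)
              + asm.common.total_charge * V / vt)
    log_kd = (math.log(asm.distinct.alpha0 / asm.distinct.beta0)
              + asm.distinct.total_charge * V / vt)
    log_ko = math.log(asm.opening_rate / asm.closing_rate)
    log_w = np.array([
        math.log(math.comb(3, n)) + n * log_ka
        + (log_kd if d else 0.0) + (log_ko if is_open else 0.0)
        for (n, d, is_open) in space.states
    ])
    log_w -= log_w.max()
    w = np.exp(log_w)
    return w / w.sum()


def calibrate_from_boltzmann(Q_half: float, slope_k: float,
                             tau_ref: float, V_tau_ref: float,
                             pc: PhysicalConstants = DEFAULT_CONSTANTS) -> SubunitKinetics:
    """Build subunit kinetics from measured Boltzmann and tau values.

    The total charge is taken from the slope, z = V_T / slope_k, and is
    split symmetrically between the forward and backward exponents, so
    the relaxation time 1/(alpha+beta) is maximal at the midpoint. The
    absolute rate scale is fixed by requiring
    ``1/(alpha(V_tau_ref) + beta(V_tau_ref)) == tau_ref``.

    Parameters
    ----------
    Q_half : midpoint of the single-sensor charge-voltage curve, mV.
    slope_k : Boltzmann slope factor, mV (> 0).
    tau_ref : relaxation time constant at ``V_tau_ref``, ms (> 0).
    V_tau_ref : voltage at which ``tau_ref`` was measured, mV.
    """
    if not slope_k > 0:
        raise CalibrationError(f"slope_k must be > 0, got {slope_k}")
    if not tau_ref > 0:
        raise CalibrationError(f"tau_ref must be > 0, got {tau_ref}")
    vt = pc.thermal_voltage
    z = vt / slope_k
    za = zb = z / 2.0
    # beta0/alpha0 from V_half = vt*ln(beta0/alpha0)/z == Q_half
    log_ratio = z * Q_half / vt
    # alpha(V) + beta(V) = alpha0*(exp(za*V/vt) + ratio*exp(-zb*V/vt))
    denom = math.exp(za * V_tau_ref / vt) + math.exp(log_ratio - zb * V_tau_ref / vt)
    alpha0 = 1.0 / (tau_ref * denom)
    beta0 = alpha0 * math.exp(log_ratio)
    if not (alpha0 > 0 and beta0 > 0 and math.isfinite(alpha0) and math.isfinite(beta0)):
        raise CalibrationError(
            f"calibration produced non-positive/non-finite rates "
            f"(alpha0={alpha0}, beta0={beta0})")
    return SubunitKinetics(alpha0=alpha0, beta0=beta0,
                           z_alpha_delta=za, z_beta_delta=zb)
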