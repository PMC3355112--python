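"""Physical constants and the thermal voltage.

All voltages in this package are millivolts, times are milliseconds,
rates are 1/ms, and charges are multiples of the elementary charge e0.
"""

from __future__ import annotations

from dataclasses import dataclass

import scipy.constants as _const

__all__ = ["PhysicalConstants", "DEFAULT_CONSTANTS"]


@dataclass(frozen=True)
class PhysicalConstants:
    """Temperature and the derived thermal voltage k_B*T/e0.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Must be positive.
    """

    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def thermal_voltage(self) -> float:
        """k_B*T/e0 in mV (~25.693 mV at 298.15 K)."""
        return _const.k * self.temperature / _const.e * 1e3

    def to_dict(self) -> dict:
        return {"temperature": self.temperature}

    @classmethod
    def from_dict(cls, d: dict) -> "PhysicalConstants":
        return cls(temperature=float(d["temperature"]))


DEFAULT_CONSTANTS = PhysicalConstants()
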