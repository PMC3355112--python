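"""Published whole-cell fit parameters used as calibration targets.

These are the measured Boltzmann midpoints/slopes of the normalized
Q-V curves and weighted decay time constants for the homotetrameric
channel and the two components resolved in the 3:1 heterotetramer,
used to pin down the subunit rate laws (see
:func:`kvgating.kinetics.calibrate_from_boltzmann`).
"""

from __future__ import annotations

from .constants import PhysicalConstants, DEFAULT_CONSTANTS
from .kinetics import ChannelAssembly, calibrate_from_boltzmann

__all__ = [
    "HOMO_QV_MIDPOINT",
    "HOMO_QV_SLOPE",
    "HOMO_PEAK_TAU",
    "HET1_QV_MIDPOINT",
    "HET1_QV_SLOPE",
    "HET1_TAU",
    "HET1_TAU_VOLTAGE",
    "HET2_QV_MIDPOINT",
    "HET2_QV_SLOPE",
    "HET2_TAU",
    "HET2_TAU_VOLTAGE",
    "APPARENT_CHARGE_HOMO",
    "default_homotetramer",
    "default_heterotetramer",
]

# homotetramer: single-component Q-V and its peak weighted tau. The
# tau-V bell peaks at the Q-V midpoint under the symmetric charge split,
# so the peak tau is referenced at the midpoint.
HOMO_QV_MIDPOINT = -26.5   # mV
HOMO_QV_SLOPE = 4.6        # mV
HOMO_PEAK_TAU = 16.5       # ms

# heterotetramer, hyperpolarized (component 1, the distinct subunit)
# and depolarized (component 2, the common subunits) Q-V components,
# with weighted taus quoted at the voltages they were measured.
HET1_QV_MIDPOINT = -93.2
HET1_QV_SLOPE = 9.4
HET1_TAU = 5.8
HET1_TAU_VOLTAGE = -70.0

HET2_QV_MIDPOINT = -21.8
HET2_QV_SLOPE = 5.8
HET2_TAU = 14.5
HET2_TAU_VOLTAGE = -20.0

# per-subunit apparent charge quoted for the homotetramer (e0); note
# this is lower than thermal_voltage/slope evaluated at room
# temperature (see README, "apparent charge discrepancy").
APPARENT_CHARGE_HOMO = 3.8


def default_homotetramer(pc: PhysicalConstants = DEFAULT_CONSTANTS,
                         **kwargs) -> ChannelAssembly:
    """Homotetramer calibrated to the published Q-V and peak tau."""
    kin = calibrate_from_boltzmann(HOMO_QV_MIDPOINT, HOMO_QV_SLOPE,
                                   HOMO_PEAK_TAU, HOMO_QV_MIDPOINT, pc)
    return ChannelAssembly.homotetramer(kin, **kwargs)


def default_heterotetramer(pc: PhysicalConstants = DEFAULT_CONSTANTS,
                           **kwargs) -> ChannelAssembly:
    """3:1 assembly: common subunits from component 2, the distinct
    subunit from component 1."""
    common = calibrate_from_boltzmann(HET2_QV_MIDPOINT, HET2_QV_SLOPE,
                                      HET2_TAU, HET2_TAU_VOLTAGE, pc)
    distinct = calibrate_from_boltzmann(HET1_QV_MIDPOINT, HET1_QV_SLOPE,
                                        HET1_TAU, HET1_TAU_VOLTAGE, pc)
    return ChannelAssembly(common=common, distinct=distinct, **kwargs)


def matched_pair(pc: PhysicalConstants = DEFAULT_CONSTANTS,
                 **kwargs) -> tuple[ChannelAssembly, ChannelAssembly]:
    """(homotetramer, heterotetramer) sharing the same common subunit.

    For side-by-side ionic-current comparisons (activation delay,
    Cole-Moore, G-V shift) the two assemblies must differ only in the
    fourth subunit; both use the homotetramer calibration for the
    common subunit and component 1 for the distinct one.
    """
    common = calibrate_from_boltzmann(HOMO_QV_MIDPOINT, HOMO_QV_SLOPE,
                                      HOMO_PEAK_TAU, HOMO_QV_MIDPOINT, pc)
    distinct = calibrate_from_boltzmann(HET1_QV_MIDPOINT, HET1_QV_SLOPE,
                                        HET1_TAU, HET1_TAU_VOLTAGE, pc)
    homo = ChannelAssembly.homotetramer(common, **kwargs)
    het = ChannelAssembly(common=common, distinct=distinct, **kwargs)
    return homo, het
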