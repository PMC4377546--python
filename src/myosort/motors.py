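"""Motor species definitions and load-dependent dwell-time sampling.

A processive dimeric myosin is summarised by four mechanochemical numbers:
its stall force, its unloaded mean dwell time between steps, its step size,
and the direction it walks on a polar actin filament.  Myosin V walks toward
the barbed (plus) end and is the stronger motor of the antagonistic pair
studied here; myosin VI walks toward the pointed (minus) end and is slightly
weaker.  Dwell times are exponentially distributed; under load the mean dwell
grows as the reciprocal of the linear force-velocity relation
``v = v0 * (1 - T / F_stall)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Fraction of the stall force beyond which a motor is considered stalled.
STALL_EPS = 1e-6


@dataclass(frozen=True)
class MotorSpec:
    """One motor species of a tug-of-war pair.

    Parameters
    ----------
    label : str
        Identifier, e.g. ``"myosinV"``.
    stall_force : float
        Stall force in pN (or in units of ``F_low`` for normalized runs).
    unloaded_dwell : float
        Mean dwell time between steps at zero load, in ms.
    step_size : float
        Step size in nm.
    polarity : int
        +1 for plus-end (barbed-end) directed motors, -1 for minus-end.
    """

    label: str
    stall_force: float
    unloaded_dwell: float
    step_size: float
    polarity: int

    def __post_init__(self) -> None:
        if self.stall_force <= 0:
            raise ValueError("stall_force must be positive")
        if self.unloaded_dwell <= 0:
            raise ValueError("unloaded_dwell must be positive")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")


#: Myosin V: ~3 pN stall, 170 ms mean dwell, 36 nm steps, plus-end directed.
MYOSIN_V = MotorSpec("myosinV", stall_force=3.0, unloaded_dwell=170.0,
                     step_size=36.0, polarity=+1)

#: Myosin VI: ~2 pN stall, 215 ms mean dwell, 30 nm steps, minus-end directed.
MYOSIN_VI = MotorSpec("myosinVI", stall_force=2.0, unloaded_dwell=215.0,
                      step_size=30.0, polarity=-1)


def is_stalled(tension: float, motor: MotorSpec) -> bool:
    """True when the inter-motor tension leaves no forward-stepping capacity."""
    return 1.0 - tension / motor.stall_force <= STALL_EPS


def sample_dwell(tension: float, motor: MotorSpec,
                 rng: np.random.Generator) -> float:
    """Draw one dwell time (ms) for ``motor`` under inter-motor tension.

    The dwell is exponential with mean ``unloaded_dwell / (1 - T/F_stall)``.
    At or beyond stall the mean dwell diverges and ``inf`` is returned: a
    stalled motor never wins the dwell race.

    Raises
    ------
    ValueError
        If ``tension`` is negative.
    """
    if tension < 0:
        raise ValueError("tension must be non-negative")
    factor = 1.0 - tension / motor.stall_force
    if factor <= STALL_EPS:
        return float("inf")
    return float(rng.exponential(motor.unloaded_dwell / factor))
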