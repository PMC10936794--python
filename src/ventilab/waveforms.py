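"""Per-breath reference signals for volume-controlled, CPAP and PAV modes.

Volume-controlled operation tracks a square flow pulse: the reference
flow is the set inspiratory flow ``gamma`` while the delivered volume is
still below the tidal volume and the cycle is inside the inspiratory
window, and zero otherwise.

The pressure modes have no published waveform equations, so the package
fixes two conventions: CPAP is a constant set pressure, and PAV is PEEP
plus a gain-scaled half-sine surrogate of the patient's inspiratory
effort.  Their role is to produce distinguishable mode signatures for the
downstream classifier benchmark, not clinical fidelity.

Within-cycle time uses t_cycle in [0, T_resp); the cycle boundary belongs
to the next cycle, and the strict inequalities of the volume rule are
honored exactly (flow is zero at t_cycle = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ventilab.errors import ConfigurationError, ParameterError


@dataclass(frozen=True)
class BreathTiming:
    """Inspiratory/expiratory durations of one breath cycle, s."""

    t_insp: float = 1.33
    t_exp: float = 2.67

    def __post_init__(self) -> None:
        if not self.t_insp > 0:
            raise ParameterError(f"t_insp must be > 0, got {self.t_insp!r}")
        if not self.t_exp > 0:
            raise ParameterError(f"t_exp must be > 0, got {self.t_exp!r}")

    @property
    def T_resp(self) -> float:
        """Cycle period t_insp + t_exp, s."""
        return self.t_insp + self.t_exp

    @property
    def ie_ratio(self) -> float:
        """Inspiratory-to-expiratory duration ratio."""
        return self.t_insp / self.t_exp


@dataclass(frozen=True)
class VolumeReference:
    """Volume-mode settings: inspiratory flow gamma (ml/s), tidal volume VT (ml)."""

    gamma: float
    VT: float

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ParameterError(f"gamma must be > 0, got {self.gamma!r}")
        if not self.VT > 0:
            raise ParameterError(f"VT must be > 0, got {self.VT!r}")


@dataclass(frozen=True)
class PressureReference:
    """Pressure-mode settings for CPAP or PAV.

    ``target`` is the set pressure in cm H2O (study levels 20 and 40).
    PAV additionally needs the dimensionless assist gain ``pav_gain`` in
    [0, 1) and the peak ``effort_amplitude`` (cm H2O) of the simulated
    patient-effort half-sine.
    """

    mode: str
    target: float
    PEEP: float = 0.0
    pav_gain: Optional[float] = None
    effort_amplitude: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("CPAP", "PAV"):
            raise ConfigurationError(f"mode must be 'CPAP' or 'PAV', got {self.mode!r}")
        if self.PEEP < 0:
            raise ParameterError(f"PEEP must be >= 0, got {self.PEEP!r}")
        if not self.target > self.PEEP:
            raise ParameterError(
                f"target ({self.target!r}) must exceed PEEP ({self.PEEP!r})"
            )
        if self.mode == "PAV":
            if self.pav_gain is None or self.effort_amplitude is None:
                raise ConfigurationError(
                    "PAV requires both pav_gain and effort_amplitude"
                )
            if not (0.0 <= self.pav_gain < 1.0):
                raise ParameterError(
                    f"pav_gain must lie in [0, 1), got {self.pav_gain!r}"
                )
            if self.effort_amplitude < 0:
                raise ParameterError(
                    f"effort_amplitude must be >= 0, got {self.effort_amplitude!r}"
                )


def cycle_time(t: float, timing: BreathTiming) -> float:
    """Map absolute time onto the current cycle: t mod T_resp in [0, T_resp)."""
    return float(t) % timing.T_resp


def flow_reference(t: float, ref: VolumeReference, timing: BreathTiming) -> float:
    """Volume-mode reference flow at time t, ml/s.

    Returns ``gamma`` when both ``gamma * t_cycle < VT`` (the tidal volume
    is not yet delivered) and ``0 < t_cycle < t_insp`` (inside the
    inspiratory window); zero otherwise.
    """
    tc = cycle_time(t, timing)
    if ref.gamma * tc < ref.VT and 0.0 < tc < timing.t_insp:
        return ref.gamma
    return 0.0


def pressure_reference(t: float, ref: PressureReference, timing: BreathTiming) -> float:
    """Pressure-mode reference at time t, cm H2O.

    CPAP holds the set ``target`` at every instant.  PAV returns PEEP plus
    ``pav_gain * effort_amplitude * sin(pi * t_cycle / t_insp)`` during
    inspiration and PEEP during expiration; the reference never drops
    below PEEP.
    """
    if ref.mode == "CPAP":
        return ref.target
    tc = cycle_time(t, timing)
    if 0.0 < tc < timing.t_insp:
        effort = ref.effort_amplitude * math.sin(math.pi * tc / timing.t_insp)
        return ref.PEEP + ref.pav_gain * max(effort, 0.0)
    return ref.PEEP


def reference_series(
    scenario_ref, timing: BreathTiming, dt: float, n_samples: int, t0: float = 0.0
) -> np.ndarray:
    """Sample a reference (flow or pressure) on a uniform grid of n_samples."""
    t = t0 + np.arange(n_samples) * dt
    if isinstance(scenario_ref, VolumeReference):
        return np.array([flow_reference(ti, scenario_ref, timing) for ti in t])
    if isinstance(scenario_ref, PressureReference):
        return np.array([pressure_reference(ti, scenario_ref, timing) for ti in t])
    raise ConfigurationError(
        f"unsupported reference type {type(scenario_ref).__name__}"
    )


def delivered_volume_per_cycle(ref: VolumeReference, timing: BreathTiming) -> float:
    """Analytic integral of the reference flow over one cycle, ml.

    Flow is gamma until either the tidal volume VT is reached (at
    t = VT/gamma) or inspiration ends, whichever is first, so the
    delivered volume is min(VT, gamma * t_insp).
    """
    return min(ref.VT, ref.gamma * timing.t_insp)
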