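"""Lumped ventilator-patient plant model.

The ventilator circuit plus the patient's airway is reduced to a
first-order-plus-dead-time transfer function

    G(s) = b0 / (a1*s + a0) * exp(-delay*s)

relating the commanded volume rate to the delivered air-flow rate.  In
symbolic form the coefficients follow from the lumped compliances and the
load-branch resistance,

    b0 = Cc,    a1 = Cc*C2*R2c,    a0 = Cc + C2,

with the transport delay fixed at 45% of the breathing-cycle period.  The
package also carries a *canonical* coefficient set (b0=0.07425, a1=0.022,
a0=0.54) used as the reference plant throughout: its denominator constant
equals the sum of the compliances, but its numerator and lag are not
reproduced by the symbolic assembly from the published parameter table, so
the two assemblies are kept side by side and never silently reconciled.

Discretization is exact for zero-order-hold inputs: the state update uses
the closed-form exponential of the continuous lag, and the dead time is an
integer-sample ring buffer (delay rounded to the nearest sample).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ventilab.errors import ParameterError

logger = logging.getLogger(__name__)

#: Canonical reference-plant coefficients (flow-rate transfer function).
CANONICAL_B0 = 0.07425
CANONICAL_A1 = 0.022
CANONICAL_A0 = 0.54

#: Default breathing-cycle period, s (~15 breaths/min adult).
DEFAULT_T_RESP = 4.0

#: Transport delay as a fraction of the breathing-cycle period.
DELAY_FRACTION = 0.45


@dataclass(frozen=True)
class PlantParameters:
    """Physical parameters of the lumped ventilator-patient model.

    Parameters
    ----------
    Cc : float
        Pulmonary compliance, ml/cm H2O.
    C2 : float
        Load-reservoir compliance, ml/cm H2O.
    R2c : float
        Load-branch resistance, cm H2O/(ml/s).
    Rc : float
        Patient airway resistance, cm H2O/(ml/s).
    Rv2min : float
        Minimum valve resistance, cm H2O/(ml/s).
    T_resp : float
        Breathing-cycle period, s.
    PEEP : float
        End-expiratory pressure, cm H2O.
    circuit_info : dict, optional
        Free-form record of the remaining circuit elements (valves,
        sources, auxiliary resistances).  Documentation only; never used
        in simulation.
    """

    Cc: float = 0.075
    C2: float = 0.465
    R2c: float = 0.377
    Rc: float = 0.377
    Rv2min: float = 1.062e-4
    T_resp: float = DEFAULT_T_RESP
    PEEP: float = 0.0
    circuit_info: Optional[dict] = None

    def __post_init__(self) -> None:
        for name, value, strict in [
            ("Cc", self.Cc, True),
            ("C2", self.C2, False),
            ("R2c", self.R2c, True),
            ("Rc", self.Rc, True),
            ("T_resp", self.T_resp, True),
            ("PEEP", self.PEEP, False),
        ]:
            if strict and not value > 0:
                raise ParameterError(f"{name} must be > 0, got {value!r}")
            if not strict and value < 0:
                raise ParameterError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class FirstOrderDelayPlant:
    """First-order-plus-dead-time plant b0/(a1*s + a0) * exp(-delay*s)."""

    b0: float
    a1: float
    a0: float
    delay: float = 0.0

    def __post_init__(self) -> None:
        for name, value in [("b0", self.b0), ("a1", self.a1), ("a0", self.a0)]:
            if not value > 0:
                raise ParameterError(f"{name} must be > 0, got {value!r}")
        if self.delay < 0:
            raise ParameterError(f"delay must be >= 0, got {self.delay!r}")
        if not math.isfinite(self.b0 / self.a0):
            raise ParameterError("dc_gain b0/a0 is not finite")

    @property
    def dc_gain(self) -> float:
        """Steady-state gain b0/a0 (output per unit input)."""
        return self.b0 / self.a0

    @property
    def time_constant(self) -> float:
        """Lag time constant a1/a0, s."""
        return self.a1 / self.a0

    @property
    def cutoff(self) -> float:
        """-3 dB cutoff frequency a0/a1 of the lag, rad/s."""
        return self.a0 / self.a1

    def frequency_response(self, omega: np.ndarray) -> np.ndarray:
        """Complex frequency response G(j*omega), including the dead time."""
        omega = np.asarray(omega, dtype=float)
        lag = self.b0 / (self.a1 * 1j * omega + self.a0)
        return lag * np.exp(-1j * omega * self.delay)

    def replace_delay(self, delay: float) -> "FirstOrderDelayPlant":
        return FirstOrderDelayPlant(self.b0, self.a1, self.a0, delay)


@dataclass
class Trajectory:
    """Uniformly sampled closed- or open-loop record of one simulation.

    Series share one length; ``t`` is uniform with spacing ``dt``.  Units
    of ``reference``/``output`` are cm H2O or ml/s depending on the
    scenario; ``control`` is the actuation input in plant input units.
    """

    dt: float
    t: np.ndarray
    reference: np.ndarray
    output: np.ndarray
    control: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.output = np.asarray(self.output, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        n = len(self.t)
        if not (len(self.reference) == len(self.output) == len(self.control) == n):
            raise ParameterError("trajectory series must share one length")
        if n >= 2:
            steps = np.diff(self.t)
            if np.any(steps <= 0) or not np.allclose(steps, self.dt, rtol=0, atol=1e-9):
                raise ParameterError("t must increase uniformly with spacing dt")

    def __len__(self) -> int:
        return len(self.t)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "reference": self.reference,
                "output": self.output,
                "control": self.control,
            }
        )

    def to_csv(self, path) -> None:
        """Write the fixed-order ``t,reference,output,control`` CSV."""
        self.to_dataframe().to_csv(path, index=False)


def assemble_transfer_function(
    params: PlantParameters, use_canonical: bool = True
) -> FirstOrderDelayPlant:
    """Assemble the lumped plant from physical parameters.

    In symbolic mode the coefficients are built from the compliances and
    the load-branch resistance (b0=Cc, a1=Cc*C2*R2c, a0=Cc+C2).  In
    canonical mode (default) the published reference coefficients are used
    verbatim; a warning notes that the symbolic assembly does not
    reproduce the canonical numerator and lag, so the two must not be
    treated as interchangeable beyond the shared denominator constant.
    The transport delay is 0.45*T_resp in either mode.
    """
    delay = DELAY_FRACTION * params.T_resp
    if use_canonical:
        logger.warning(
            "canonical plant requested: symbolic assembly from the physical "
            "parameter table yields b0=%.5g, a1=%.5g which do not reproduce "
            "the canonical b0=%.5g, a1=%.5g; only a0=Cc+C2=%.5g is shared",
            params.Cc,
            params.Cc * params.C2 * params.R2c,
            CANONICAL_B0,
            CANONICAL_A1,
            params.Cc + params.C2,
        )
        return FirstOrderDelayPlant(CANONICAL_B0, CANONICAL_A1, CANONICAL_A0, delay)
    return FirstOrderDelayPlant(
        b0=params.Cc,
        a1=params.Cc * params.C2 * params.R2c,
        a0=params.Cc + params.C2,
        delay=delay,
    )


def canonical_plant(delay: float = 0.0) -> FirstOrderDelayPlant:
    """The canonical reference plant with a caller-chosen transport delay."""
    return FirstOrderDelayPlant(CANONICAL_B0, CANONICAL_A1, CANONICAL_A0, delay)


class PlantSimulator:
    """Stateful sample-by-sample simulator of a FirstOrderDelayPlant.

    Uses the exact zero-order-hold discretization of the lag,

        y[k+1] = alpha*y[k] + K*(1 - alpha)*u[k - n_delay],
        alpha  = exp(-dt/tau),   K = b0/a0,   tau = a1/a0,

    with the dead time realized as an integer-sample ring buffer
    pre-filled with the initial input (zero), so the output is identically
    the initial value for all t < delay.
    """

    def __init__(
        self, plant: FirstOrderDelayPlant, dt: float, initial_output: float = 0.0
    ):
        if dt <= 0:
            raise ParameterError(f"dt must be > 0, got {dt!r}")
        tau = plant.time_constant
        if dt >= tau:
            raise ParameterError(
                f"dt={dt:g} s is not smaller than the plant lag time constant "
                f"a1/a0={tau:g} s; choose a smaller integration step"
            )
        self.plant = plant
        self.dt = dt
        self._alpha = math.exp(-dt / tau)
        self._gain = plant.dc_gain
        self._y = float(initial_output)
        n_delay = int(round(plant.delay / dt))
        if abs(n_delay * dt - plant.delay) > 1e-12:
            logger.info(
                "transport delay %.6g s rounded to %d samples (%.6g s) at dt=%.6g",
                plant.delay,
                n_delay,
                n_delay * dt,
                dt,
            )
        self._buffer = [0.0] * n_delay

    @property
    def output(self) -> float:
        return self._y

    def step(self, u: float) -> float:
        """Advance one sample with held input ``u``; return the new output."""
        if self._buffer:
            self._buffer.append(float(u))
            u_eff = self._buffer.pop(0)
        else:
            u_eff = float(u)
        self._y = self._alpha * self._y + self._gain * (1.0 - self._alpha) * u_eff
        return self._y

    def reset(self, initial_output: float = 0.0) -> None:
        self._y = float(initial_output)
        self._buffer = [0.0] * len(self._buffer)


def simulate_response(
    plant: FirstOrderDelayPlant, control: np.ndarray, dt: float
) -> Trajectory:
    """Open-loop response to an arbitrary sampled input, zero initial state.

    ``control[k]`` is held over [k*dt, (k+1)*dt); ``output[k]`` is the
    state at time k*dt (so ``output[0] == 0``).
    """
    control = np.asarray(control, dtype=float)
    sim = PlantSimulator(plant, dt)
    n = len(control)
    y = np.zeros(n)
    for k in range(1, n):
        y[k] = sim.step(control[k - 1])
    t = np.arange(n) * dt
    return Trajectory(dt=dt, t=t, reference=control.copy(), output=y, control=control)


def step_response(
    plant: FirstOrderDelayPlant, amplitude: float, dt: float, horizon: float
) -> Trajectory:
    """Response to a step of the given amplitude applied at t=0."""
    if dt <= 0:
        raise ParameterError(f"dt must be > 0, got {dt!r}")
    if horizon < dt:
        raise ParameterError(f"horizon must be >= dt, got {horizon!r}")
    n = int(round(horizon / dt)) + 1
    u = np.full(n, float(amplitude))
    return simulate_response(plant, u, dt)


def read_plant_config(path) -> PlantParameters:
    """Read plant parameters from a flat key-value (YAML) config file.

    Keys match the physical symbol names (``Cc``, ``C2``, ``R2c``, ``Rc``,
    ``Rv2min``, ``T_resp``, ``PEEP``); unknown keys are collected into
    ``circuit_info``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"Cc", "C2", "R2c", "Rc", "Rv2min", "T_resp", "PEEP"}
    kwargs = {k: float(v) for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    if extra:
        kwargs["circuit_info"] = extra
    return PlantParameters(**kwargs)
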