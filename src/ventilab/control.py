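"""PID and current-cycle-feedback ILC-PID control laws.

The per-sample feedback law is the classical three-term controller

    u = Kp*e + Ki * integral(e) + Kd * d/dt e,

discretized with backward Euler for both the integral and the
derivative, with output clamping and conditional-integration anti-windup
(the integrator is frozen on any sample whose raw output exceeds the
actuation limits).

Between breath cycles the iterative-learning layer refines a stored
control trajectory:

    u_{i+1} = Q[u_i] + L[e_i] + C[e_{i+1}]

where Q is a robustness low-pass, L a learning operator and C the
current-cycle PID feedback.  Because the inverse operator implied by the
closed-form ILC-PID expression is not realizable causally sample by
sample, the learning terms Q[u_i] + L[e_i] are applied offline to whole
stored cycles between breaths (the lifted-iteration domain), while the C
term runs online within the cycle.  Q is a zero-phase (forward-backward)
first-order low-pass whose default cutoff is the plant cutoff a0/a1; L is
the same low-pass scaled by l_gain over the plant DC gain, so the
frequency-domain contraction factor |Q(w)| * |1 - L(w)G(w)| stays below
one over the learnable band.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from ventilab.errors import AlignmentError, ParameterError, SignalError
from ventilab.plant import FirstOrderDelayPlant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PIDGains:
    """PID gains, sample interval and actuation clamps.

    Units: Kp maps error units to actuation units; Ki is Kp-like per
    second; Kd is Kp-like times seconds; dt in s.
    """

    Kp: float
    Ki: float = 0.0
    Kd: float = 0.0
    dt: float = 0.005
    u_min: float = -np.inf
    u_max: float = np.inf

    def __post_init__(self) -> None:
        for name, value in [("Kp", self.Kp), ("Ki", self.Ki), ("Kd", self.Kd)]:
            if value < 0:
                raise ParameterError(f"{name} must be >= 0, got {value!r}")
        if not self.dt > 0:
            raise ParameterError(f"dt must be > 0, got {self.dt!r}")
        if not self.u_min < self.u_max:
            raise ParameterError(
                f"u_min ({self.u_min!r}) must be below u_max ({self.u_max!r})"
            )


def imc_pid_gains(
    plant: FirstOrderDelayPlant,
    dt: float = 0.005,
    u_min: float = 0.0,
    u_max: float = 1e4,
) -> PIDGains:
    """Internal-model-control PI tuning on the first-order(-plus-dead-time) lag.

    For a plant K/(tau*s + 1)*exp(-theta*s) the IMC rule with the
    closed-loop time constant set equal to the plant lag gives
    Kp = tau / (K * (tau + theta)) and Ki = Kp/tau; with no dead time
    this reduces to Kp = 1/K.  The derivative term is not needed on a
    first-order plant.
    """
    K = plant.dc_gain
    tau = plant.time_constant
    kp = tau / (K * (tau + plant.delay))
    return PIDGains(Kp=kp, Ki=kp / tau, Kd=0.0, dt=dt, u_min=u_min, u_max=u_max)


@dataclass
class PIDState:
    """Integrator and backward-difference memory of one PID instance."""

    integral: float = 0.0
    prev_error: float = 0.0

    def reset(self) -> None:
        self.integral = 0.0
        self.prev_error = 0.0


def pid_step(error: float, state: PIDState, gains: PIDGains) -> float:
    """One sample of the PID law; mutates ``state``.

    Backward-Euler integral and derivative (derivative acts on the error,
    not the measurement).  Output is clamped to [u_min, u_max]; on a
    clamped sample the integrator update is discarded (anti-windup).
    """
    if not math.isfinite(error):
        raise SignalError(f"non-finite error sample: {error!r}")
    integral_new = state.integral + error * gains.dt
    derivative = (error - state.prev_error) / gains.dt
    u_raw = gains.Kp * error + gains.Ki * integral_new + gains.Kd * derivative
    if u_raw > gains.u_max:
        u = gains.u_max
    elif u_raw < gains.u_min:
        u = gains.u_min
    else:
        u = u_raw
        state.integral = integral_new
    state.prev_error = error
    return u


def pid_series(errors: np.ndarray, gains: PIDGains) -> np.ndarray:
    """Apply the PID law to a whole error series from a zero initial state."""
    state = PIDState()
    return np.array([pid_step(float(e), state, gains) for e in errors])


@dataclass(frozen=True)
class ILCConfig:
    """Design knobs of the iterative-learning layer.

    q_cutoff: Q-filter cutoff, rad/s (None -> plant cutoff a0/a1).
    l_gain: dimensionless learning gain; the realized L operator is
        l_gain / dc_gain times a low-pass, so l_gain in (0, 2) keeps the
        DC contraction |1 - l_gain| below one.
    n_iterations: breath cycles to learn over.
    use_current_cycle: enable the within-cycle C (PID feedback) term.
    dt: controller sample interval, s.
    """

    q_cutoff: Optional[float] = None
    l_gain: float = 0.8
    n_iterations: int = 10
    use_current_cycle: bool = True
    dt: float = 0.005

    def __post_init__(self) -> None:
        if self.q_cutoff is not None and not self.q_cutoff > 0:
            raise ParameterError(f"q_cutoff must be > 0, got {self.q_cutoff!r}")
        if self.n_iterations < 1:
            raise ParameterError(
                f"n_iterations must be >= 1, got {self.n_iterations!r}"
            )
        if not math.isfinite(self.l_gain):
            raise ParameterError(f"l_gain must be finite, got {self.l_gain!r}")
        if not self.dt > 0:
            raise ParameterError(f"dt must be > 0, got {self.dt!r}")


@dataclass
class IterationMemory:
    """Stored control and error series of one learned breath cycle."""

    cycle_index: int
    u: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.e = np.asarray(self.e, dtype=float)
        if self.u.shape != self.e.shape:
            raise AlignmentError(
                f"stored control ({len(self.u)}) and error ({len(self.e)}) "
                "series must share one length"
            )

    @property
    def rms_error(self) -> float:
        return float(np.sqrt(np.mean(self.e**2)))


@dataclass
class ILCFilters:
    """Realized Q and L operators plus their contraction estimate.

    ``q_cutoff = inf`` makes Q the identity.  ``l_lowpass=False`` makes L
    a pure scalar (useful for desk checks); the default applies the same
    zero-phase low-pass as Q before scaling by ``l_scale``.
    """

    dt: float
    q_cutoff: float
    l_scale: float
    l_lowpass: bool = True
    lead_samples: int = 0
    contraction_estimate: float = np.nan
    plant_cutoff: float = np.nan

    def _lowpass(self, series: np.ndarray, cutoff: float) -> np.ndarray:
        series = np.asarray(series, dtype=float)
        if not np.isfinite(cutoff):
            return series.copy()
        # first-order Butterworth, forward-backward => zero phase,
        # reflection ("even") padding against cycle-edge transients
        nyq = math.pi / self.dt
        wn = min(cutoff / nyq, 0.999)
        b, a = sps.butter(1, wn, btype="low")
        padlen = min(len(series) - 1, 3 * max(len(a), len(b)))
        if padlen <= 0:
            return series.copy()
        return sps.filtfilt(b, a, series, padtype="even", padlen=padlen)

    def apply_q(self, series: np.ndarray) -> np.ndarray:
        """Zero-phase low-pass of a stored control cycle."""
        return self._lowpass(series, self.q_cutoff)

    def apply_l(self, series: np.ndarray) -> np.ndarray:
        """Learning operator on a stored error cycle.

        Besides the gain and optional low-pass, L advances the stored
        error by the plant dead time (``lead_samples``): acting on the
        whole previous cycle, this non-causal shift cancels the delay's
        phase in the learning loop, which sample-by-sample feedback can
        never do.  The vacated tail is padded with the edge value.
        """
        out = np.asarray(series, dtype=float)
        if self.l_lowpass:
            out = self._lowpass(out, self.q_cutoff)
        else:
            out = out.copy()
        k = self.lead_samples
        if 0 < k < len(out):
            out = np.r_[out[k:], np.full(k, out[-1])]
        return self.l_scale * out


def design_filters(plant: FirstOrderDelayPlant, cfg: ILCConfig) -> ILCFilters:
    """Design the Q and L operators from the plant cutoff.

    The plant cutoff w_c = a0/a1 sets the default Q cutoff.  L is scaled
    by the inverse DC gain so l_gain directly controls the DC contraction
    |1 - l_gain|.  The returned contraction estimate is
    sup_w |Q(w)| * |1 - L(w) G(jw)| on a frequency grid; a value >= 1 logs
    a warning (learning may diverge) but is not a hard error.
    """
    omega_c = plant.cutoff
    q_cutoff = cfg.q_cutoff if cfg.q_cutoff is not None else omega_c
    l_scale = cfg.l_gain / plant.dc_gain
    if not abs(1.0 - cfg.l_gain) < 1.0:
        logger.warning(
            "l_gain=%.4g puts the DC contraction |1 - l_gain| at %.4g >= 1",
            cfg.l_gain,
            abs(1.0 - cfg.l_gain),
        )
    omega = np.linspace(1e-3, 50.0 * q_cutoff, 4096)
    # zero-phase first-order low-pass: real response 1/(1 + (w/wq)^2)
    q_mag = 1.0 / (1.0 + (omega / q_cutoff) ** 2)
    l_resp = l_scale * q_mag
    # L's time-advance cancels the dead-time phase in the learning loop,
    # so the contraction is evaluated against the delay-free lag
    g = plant.replace_delay(0.0).frequency_response(omega)
    contraction = float(np.max(q_mag * np.abs(1.0 - l_resp * g)))
    if contraction >= 1.0:
        logger.warning(
            "ILC contraction estimate %.4g >= 1: learning may diverge", contraction
        )
    return ILCFilters(
        dt=cfg.dt,
        q_cutoff=q_cutoff,
        l_scale=l_scale,
        l_lowpass=True,
        lead_samples=int(round(plant.delay / cfg.dt)),
        contraction_estimate=contraction,
        plant_cutoff=omega_c,
    )


def ilc_feedforward(memory: IterationMemory, filters: ILCFilters) -> np.ndarray:
    """Offline learning update Q[u_i] + L[e_i] for the next cycle."""
    return filters.apply_q(memory.u) + filters.apply_l(memory.e)


def ilc_update(
    memory: IterationMemory,
    current_error: Optional[np.ndarray],
    filters: ILCFilters,
    pid: Optional[PIDGains] = None,
    u_min: float = -np.inf,
    u_max: float = np.inf,
) -> np.ndarray:
    """Full iteration update u_{i+1} = Q[u_i] + L[e_i] + C[e_{i+1}].

    ``current_error`` is the e_{i+1} series the C term acts on; pass
    ``None`` (or ``pid=None``) to disable the current-cycle feedback term.
    The result is clamped to the actuation limits.  In closed-loop use the
    C term instead runs online inside the cycle (see
    :func:`ilc_feedforward` and the engine); this offline form applies the
    same PID law to a supplied error series.
    """
    u_next = ilc_feedforward(memory, filters)
    if current_error is not None and pid is not None:
        current_error = np.asarray(current_error, dtype=float)
        if current_error.shape != memory.e.shape:
            raise AlignmentError(
                f"current-cycle error length {len(current_error)} does not "
                f"match stored cycle length {len(memory.e)}"
            )
        u_next = u_next + pid_series(current_error, pid)
        u_min = max(u_min, pid.u_min)
        u_max = min(u_max, pid.u_max)
    return np.clip(u_next, u_min, u_max)
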