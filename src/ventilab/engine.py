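"""Closed-loop multi-breath simulation scenarios.

A scenario couples the lumped plant, a per-breath reference (flow for
volume-controlled operation, pressure for CPAP/PAV) and one of three
controller choices: none (open loop, the reference fed straight into the
plant), PID, or ILC-PID (PID feedback plus the between-cycle learning
update).

Each breath cycle is simulated as an independent repetition from a zero
plant state — the iteration-invariant initial condition that iterative
learning assumes — so cycles differ only through the learned control.
Volume trajectories are obtained by integrating the plant's flow output
within the cycle, reset at each cycle start.  Disturbances, when enabled,
are seeded Gaussian noise added to the measured output; everything is
deterministic given the seed.

The shipped default scenarios are "paper-style": they assert controller
orderings and saturation behaviour (uncontrolled error >= PID error >=
ILC-PID final-cycle error), not any particular printed endpoint, because
the study's excitation and gains are not published.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from ventilab.control import (
    ILCConfig,
    ILCFilters,
    IterationMemory,
    PIDGains,
    PIDState,
    design_filters,
    ilc_feedforward,
    imc_pid_gains,
    pid_step,
)
from ventilab.errors import ConfigurationError, DivergenceError, ParameterError
from ventilab.plant import (
    FirstOrderDelayPlant,
    PlantParameters,
    PlantSimulator,
    Trajectory,
    assemble_transfer_function,
    canonical_plant,
)
from ventilab.waveforms import (
    BreathTiming,
    PressureReference,
    VolumeReference,
    reference_series,
)

CONTROLLERS = ("none", "pid", "ilcpid")


@dataclass
class BreathScenario:
    """One multi-breath simulation configuration.

    ``plant_params=None`` with ``use_canonical=True`` selects the
    canonical reference plant.  ``delay`` is the transport delay in s
    (default 0; the nominal physical value is 0.45 * T_resp, but the
    package's default scenarios run delay-free since the published
    curves are not reproducible either way).
    """

    reference: Union[VolumeReference, PressureReference]
    timing: BreathTiming = field(default_factory=BreathTiming)
    controller: str = "pid"
    n_cycles: int = 10
    dt: float = 0.005
    seed: int = 0
    disturbance: float = 0.0
    delay: float = 0.0
    plant_params: Optional[PlantParameters] = None
    use_canonical: bool = True
    pid: Optional[PIDGains] = None
    ilc: Optional[ILCConfig] = None

    def __post_init__(self) -> None:
        if self.controller not in CONTROLLERS:
            raise ConfigurationError(
                f"controller must be one of {CONTROLLERS}, got {self.controller!r}"
            )
        if self.n_cycles < 1:
            raise ParameterError(f"n_cycles must be >= 1, got {self.n_cycles!r}")
        if not self.dt > 0:
            raise ParameterError(f"dt must be > 0, got {self.dt!r}")
        if self.disturbance < 0:
            raise ParameterError(
                f"disturbance must be >= 0, got {self.disturbance!r}"
            )

    def build_plant(self) -> FirstOrderDelayPlant:
        if self.plant_params is not None:
            base = assemble_transfer_function(
                self.plant_params, use_canonical=self.use_canonical
            )
        else:
            base = canonical_plant()
        return base.replace_delay(self.delay)

    def resolve_pid(self, plant: FirstOrderDelayPlant) -> PIDGains:
        if self.pid is not None:
            return self.pid
        return imc_pid_gains(plant, dt=self.dt)

    def resolve_ilc(self) -> ILCConfig:
        if self.ilc is not None:
            return self.ilc
        return ILCConfig(dt=self.dt)


@dataclass
class ScenarioResult:
    """Per-cycle trajectories and summary statistics of one scenario run."""

    scenario: BreathScenario
    trajectories: list
    rms_error: np.ndarray
    max_error: np.ndarray
    peak_output: np.ndarray
    peak_volume: np.ndarray
    contraction_estimate: float = np.nan

    @property
    def final_rms(self) -> float:
        return float(self.rms_error[-1])

    @property
    def steady_state_error(self) -> float:
        """Mean |reference - output| over the last 20% of the final cycle."""
        traj = self.trajectories[-1]
        tail = max(1, len(traj) // 5)
        e = traj.reference[-tail:] - traj.output[-tail:]
        return float(np.mean(np.abs(e)))

    def summary_row(self) -> dict:
        return {
            "controller": self.scenario.controller,
            "n_cycles": self.scenario.n_cycles,
            "final_rms": self.final_rms,
            "final_max_error": float(self.max_error[-1]),
            "peak_output": float(self.peak_output[-1]),
            "peak_volume": float(self.peak_volume[-1]),
            "steady_state_error": self.steady_state_error,
        }

    def diagnostics(self) -> pd.DataFrame:
        """Per-iteration learning diagnostics table."""
        return pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.rms_error) + 1),
                "rms_error": self.rms_error,
                "max_error": self.max_error,
                "contraction_estimate": self.contraction_estimate,
            }
        )


def _simulate_cycle(
    plant: FirstOrderDelayPlant,
    ref: np.ndarray,
    dt: float,
    controller: str,
    pid: Optional[PIDGains],
    feedforward: Optional[np.ndarray],
    noise: Optional[np.ndarray],
    divergence_bound: float,
    cycle_index: int,
) -> Trajectory:
    """One breath cycle from zero plant state; returns the logged trajectory."""
    n = len(ref)
    sim = PlantSimulator(plant, dt)
    y = np.zeros(n)
    u = np.zeros(n)
    state = PIDState()
    y_meas = 0.0
    for k in range(n):
        e_k = ref[k] - y_meas
        if controller == "none":
            u_k = ref[k]
        else:
            u_k = pid_step(e_k, state, pid)
            if feedforward is not None:
                u_k = float(np.clip(u_k + feedforward[k], pid.u_min, pid.u_max))
        u[k] = u_k
        if k < n - 1:
            y_next = sim.step(u_k)
            y_meas = y_next + (noise[k + 1] if noise is not None else 0.0)
            y[k + 1] = y_meas
            if abs(y_meas) > divergence_bound:
                raise DivergenceError(
                    f"output {y_meas:.4g} exceeded 10x the reference bound "
                    f"in cycle {cycle_index + 1}"
                )
    t = np.arange(n) * dt
    return Trajectory(dt=dt, t=t, reference=ref.copy(), output=y, control=u)


def run_scenario(scenario: BreathScenario) -> ScenarioResult:
    """Simulate ``n_cycles`` closed-loop breaths.

    With ``controller='ilcpid'`` the iteration memory carries across
    cycles: after each breath the stored control and error are turned
    into the next cycle's feedforward via the designed Q/L operators,
    while the PID term keeps running inside every cycle.
    """
    plant = scenario.build_plant()
    pid = scenario.resolve_pid(plant) if scenario.controller != "none" else None
    dt = scenario.dt
    n = int(round(scenario.timing.T_resp / dt))
    ref = reference_series(scenario.reference, scenario.timing, dt, n)
    ref_bound = float(np.max(np.abs(ref)))
    divergence_bound = 10.0 * ref_bound if ref_bound > 0 else np.inf

    filters: Optional[ILCFilters] = None
    if scenario.controller == "ilcpid":
        ilc_cfg = scenario.resolve_ilc()
        ilc_cfg = replace(ilc_cfg, dt=dt)
        filters = design_filters(plant, ilc_cfg)

    rng = np.random.default_rng(scenario.seed)
    trajectories = []
    rms = np.zeros(scenario.n_cycles)
    max_err = np.zeros(scenario.n_cycles)
    peak_out = np.zeros(scenario.n_cycles)
    peak_vol = np.zeros(scenario.n_cycles)
    feedforward = None
    for i in range(scenario.n_cycles):
        noise = (
            rng.normal(0.0, scenario.disturbance, size=n)
            if scenario.disturbance > 0
            else None
        )
        traj = _simulate_cycle(
            plant,
            ref,
            dt,
            scenario.controller,
            pid,
            feedforward,
            noise,
            divergence_bound,
            i,
        )
        e = traj.reference - traj.output
        rms[i] = np.sqrt(np.mean(e**2))
        max_err[i] = np.max(np.abs(e))
        peak_out[i] = np.max(np.abs(traj.output))
        # within-cycle volume: integral of the flow output, reset at cycle start
        peak_vol[i] = np.max(np.cumsum(traj.output) * dt)
        trajectories.append(traj)
        if scenario.controller == "ilcpid":
            # memory holds the learned feedforward trajectory; the PID
            # (C) contribution stays online-only, so the iteration map is
            # u_ff[i+1] = Q[u_ff[i]] + L[e_i] — contractive and monotone,
            # unlike learning on the total (feedback-inclusive) input
            prev_ff = feedforward if feedforward is not None else np.zeros(n)
            memory = IterationMemory(cycle_index=i, u=prev_ff, e=e)
            feedforward = np.clip(
                ilc_feedforward(memory, filters), pid.u_min, pid.u_max
            )
    return ScenarioResult(
        scenario=scenario,
        trajectories=trajectories,
        rms_error=rms,
        max_error=max_err,
        peak_output=peak_out,
        peak_volume=peak_vol,
        contraction_estimate=(
            filters.contraction_estimate if filters is not None else np.nan
        ),
    )


def compare_controllers(
    scenario: BreathScenario, controllers=("none", "pid", "ilcpid")
) -> tuple:
    """Run the same scenario under several controllers with identical seeds.

    Returns ``(results, summary)`` where ``results`` maps controller name
    to its :class:`ScenarioResult` and ``summary`` is a one-row-per-
    controller DataFrame (final RMS, peak output/volume, settling error).
    """
    results = {}
    rows = []
    for name in controllers:
        res = run_scenario(replace(scenario, controller=name))
        results[name] = res
        rows.append(res.summary_row())
    return results, pd.DataFrame(rows)


def default_pressure_scenario(
    controller: str = "pid",
    target: float = 20.0,
    n_cycles: int = 10,
    seed: int = 0,
) -> BreathScenario:
    """Paper-style CPAP pressure scenario on the canonical delay-free plant."""
    return BreathScenario(
        reference=PressureReference(mode="CPAP", target=target, PEEP=0.0),
        controller=controller,
        n_cycles=n_cycles,
        seed=seed,
    )


def default_volume_scenario(
    controller: str = "pid",
    VT: float = 500.0,
    gamma: float = 500.0,
    n_cycles: int = 10,
    seed: int = 0,
    dt: float = 0.005,
) -> BreathScenario:
    """Paper-style volume scenario: square flow pulse delivering VT per breath.

    The flow servo is proportional-only (Kp = 2/K, so the closed-loop
    pulse gain is 2/3; Ki = 0): integral action in a flow loop keeps
    pushing flow after the inspiratory window closes, over-delivering the
    breath late, so within-cycle control is kept proportional and the
    volume deficit is left for the cycle-to-cycle learning layer to
    correct — which is exactly the comparison the scenario exists to
    show.  Gains are stated here and echoed in every summary.
    """
    kp = 2.0 / canonical_plant().dc_gain
    pid = PIDGains(Kp=kp, Ki=0.0, Kd=0.0, dt=dt, u_min=0.0, u_max=1e4)
    return BreathScenario(
        reference=VolumeReference(gamma=gamma, VT=VT),
        controller=controller,
        n_cycles=n_cycles,
        seed=seed,
        dt=dt,
        pid=pid,
    )
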