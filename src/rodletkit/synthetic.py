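"""Synthetic inputs for the analysis stages.

Generates two-state (dwell/step) end trajectories with exponentially
distributed phase durations and step sizes, sigmoidal precursor-height
traces, and dye-fluorescence curves driven by the saturating elongation
model, so that every downstream stage is testable without microscopy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .docklock import DockLockModel, Scenario, ThTCurve, simulate_interface_switch
from .errors import ValidationError
from .kinetics import EndTrajectory, HeightTrace, Phase

__all__ = [
    "TrajectoryParams",
    "PrecursorParams",
    "SimulatedTrajectory",
    "gen_end_trajectory",
    "gen_precursor_traces",
    "gen_tht_curve",
]


@dataclass(frozen=True)
class TrajectoryParams:
    """Parameters of the two-state renewal growth process.

    Dwell durations, step durations and step sizes are drawn independently
    from exponential distributions with the configured means; each step
    ramps linearly over its duration. Positions are sampled every
    ``frame_interval`` seconds with additive i.i.d. Gaussian noise.
    """

    tau_dwell: float
    tau_step: float
    mean_step_size: float
    frame_interval: float = 12.75
    duration: float = 1785.0
    noise_sigma: float = 0.3
    start_in_dwell: bool = True
    seed: int = 0

    def __post_init__(self):
        if not self.tau_dwell > 0:
            raise ValidationError("tau_dwell must be positive")
        if not self.tau_step > 0:
            raise ValidationError("tau_step must be positive")
        if not self.mean_step_size > 0:
            raise ValidationError("mean_step_size must be positive")
        if not self.frame_interval > 0:
            raise ValidationError("frame_interval must be positive")
        if not self.duration > 0:
            raise ValidationError("duration must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class PrecursorParams:
    """Parameters of precursor height traces (logistic rise or constant)."""

    plateau_height: float = 2.3
    midpoint_time: float = 600.0
    rise_width: float = 120.0
    noise_sigma: float = 0.2
    converts: bool = True
    constant_height: float = 3.1
    n_traces: int = 1
    frame_interval: float = 12.75
    t_max: float = 1800.0
    seed: int = 0

    def __post_init__(self):
        if not self.plateau_height > 0:
            raise ValidationError("plateau_height must be positive")
        if not self.rise_width > 0:
            raise ValidationError("rise_width must be positive")
        if self.n_traces < 1:
            raise ValidationError("n_traces must be >= 1")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class SimulatedTrajectory:
    """Sampled trajectory together with its latent ground-truth phases."""

    trajectory: EndTrajectory
    latent_phases: tuple[Phase, ...]
    params: TrajectoryParams


def gen_end_trajectory(
    params: TrajectoryParams,
    rodlet_id: str = "sim-0",
    end_label: str = "unassigned",
    category: str = "preexisting",
    context: str = "single",
    min_phases: int = 0,
) -> SimulatedTrajectory:
    """Simulate one end trajectory.

    Alternating dwell (flat) and step (linear rise by an exponential
    increment over an exponential duration) phases are generated until the
    configured total time is covered (and at least ``min_phases`` phases
    were drawn), sampled at the frame interval, then Gaussian noise is
    added. The latent phase sequence is returned alongside the samples;
    with zero noise the sampled track is exactly piecewise linear and
    nondecreasing.
    """
    rng = np.random.default_rng(params.seed)
    phases: list[Phase] = []
    t = 0.0
    in_dwell = params.start_in_dwell
    knot_t = [0.0]
    knot_y = [0.0]
    while t < params.duration or len(phases) < min_phases:
        if in_dwell:
            dur = float(rng.exponential(params.tau_dwell))
            phases.append(Phase("dwell", t, dur, 0.0))
            knot_t.append(t + dur)
            knot_y.append(knot_y[-1])
        else:
            dur = float(rng.exponential(params.tau_step))
            size = float(rng.exponential(params.mean_step_size))
            phases.append(Phase("step", t, dur, size))
            knot_t.append(t + dur)
            knot_y.append(knot_y[-1] + size)
        t += dur
        in_dwell = not in_dwell

    n = int(np.floor(params.duration / params.frame_interval)) + 1
    times = np.arange(n) * params.frame_interval
    positions = np.interp(times, knot_t, knot_y)
    if params.noise_sigma > 0:
        positions = positions + rng.normal(0.0, params.noise_sigma, size=n)
    traj = EndTrajectory(
        rodlet_id=rodlet_id,
        end_label=end_label,
        category=category,
        context=context,
        times=times,
        positions=positions,
    )
    return SimulatedTrajectory(traj, tuple(phases), params)


def gen_precursor_traces(params: PrecursorParams) -> list[HeightTrace]:
    """Generate precursor height traces.

    Converting precursors rise along ``plateau * logistic((t - midpoint) /
    width)``; non-converting ones stay at ``constant_height``. Independent
    Gaussian noise is added per sample.
    """
    rng = np.random.default_rng(params.seed)
    n = int(np.floor(params.t_max / params.frame_interval)) + 1
    times = np.arange(n) * params.frame_interval
    traces = []
    for _ in range(params.n_traces):
        if params.converts:
            clean = params.plateau_height / (
                1.0 + np.exp(-(times - params.midpoint_time) / params.rise_width)
            )
        else:
            clean = np.full(n, params.constant_height)
        noise = rng.normal(0.0, params.noise_sigma, size=n) if params.noise_sigma > 0 else 0.0
        traces.append(HeightTrace(times, clean + noise, converts=params.converts))
    return traces


def gen_tht_curve(
    model: DockLockModel,
    schedule: Scenario,
    times,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> ThTCurve:
    """Generate a dye-fluorescence curve from the elongation model.

    Fluorescence is ``alpha * M(t) + beta`` plus Gaussian noise, where M(t)
    integrates the saturating elongation ODE. Before interface introduction
    the growth rate is zero unless seed material is present (``M0 > 0``).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValidationError("times must be a strictly increasing 1-D grid")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    mass = simulate_interface_switch(model, schedule.interface_on_at, times)
    fl = model.alpha * mass + model.beta
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        fl = fl + rng.normal(0.0, noise_sigma, size=times.size)
    return ThTCurve(
        times=times,
        fluorescence=fl,
        interface_on_at=schedule.interface_on_at,
        seeded=model.M0 > 0,
    )
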