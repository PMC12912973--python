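import numpy as np
import pytest

from rodletkit.kinetics import EndTrajectory, KineticEvents, Phase
from rodletkit.synthetic import TrajectoryParams, gen_end_trajectory

#: per-condition means printed in the study: (tau_dwell s, tau_step s, step size nm)
PRINTED_SETS = {
    "preexisting": (61.0, 29.7, 26.5),
    "de_novo": (75.6, 27.3, 19.2),
    "fast": (57.6, 27.6, 21.7),
    "slow": (95.7, 25.9, 18.8),
    "bundled": (43.6, 20.6, 36.4),
    "single": (67.1, 31.2, 22.2),
}


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_trajectory(positions, dt=12.75, **kw):
    positions = np.asarray(positions, dtype=float)
    defaults = dict(
        rodlet_id="r0", end_label="unassigned", category="preexisting", context="single"
    )
    defaults.update(kw)
    return EndTrajectory(
        times=np.arange(positions.size) * dt, positions=positions, **defaults
    )


def make_events(phases, censored_first=False, censored_last=False):
    return KineticEvents(
        tuple(Phase(*p) for p in phases),
        censored_first=censored_first,
        censored_last=censored_last,
    )


def simulate_set(tau_dwell, tau_step, mean_step_size, n, seed, duration=3000.0, noise=0.3,
                 **traj_kw):
    """Generate n trajectories for one parameter set (seed-spawned streams)."""
    ss = np.random.SeedSequence(seed)
    sims = []
    for k, child in enumerate(ss.spawn(n)):
        params = TrajectoryParams(
            tau_dwell=tau_dwell,
            tau_step=tau_step,
            mean_step_size=mean_step_size,
            duration=duration,
            noise_sigma=noise,
            seed=int(child.generate_state(1)[0]),
        )
        sims.append(gen_end_trajectory(params, rodlet_id=f"r{k:03d}", **traj_kw))
    return sims
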