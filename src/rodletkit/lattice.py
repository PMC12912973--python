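"""Two-dimensional lattice Monte Carlo of rodlet nucleation and growth.

Each cell holds -1 (vertical rodlet), 0 (empty) or +1 (horizontal rodlet).
Dynamics are insertion-only: at every step one empty cell is drawn
uniformly, an attempt-probability gate is applied (high when an
extension-direction placement is geometrically available, low otherwise),
the orientation is Boltzmann-sampled from the neighbor interaction
energies, and the insertion is Metropolis-accepted. Aligned
extension-direction contacts contribute ``eps_elongation`` each, aligned
side contacts ``eps_lateral``; opposite orientations contribute nothing.
A placement gaining both contact types is classed as surface-catalyzed
elongation.

The inner loop is compiled with numba when available and falls back to the
identical pure-Python code path otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


__all__ = [
    "LatticeConfig",
    "LatticeState",
    "SimulationResult",
    "CorrelationProfile",
    "ElongationEventCounts",
    "TipExperimentResult",
    "EVENT_CLASSES",
    "interaction_energy",
    "choose_orientation",
    "metropolis_accept",
    "run_simulation",
    "angle_pair_correlation",
    "count_elongation_events",
    "run_tip_experiment",
    "render_grid",
]

EVENT_CLASSES = (
    "nucleation",
    "elongation_independent",
    "elongation_surface_catalyzed",
    "lateral_attachment",
    "misaligned",
)

EPS_LATERAL_SWEEP = (0.0, -0.01, -0.1, -0.2, -0.5, -1.0)


@dataclass(frozen=True)
class LatticeConfig:
    """Simulation parameters (see module docstring for the rules)."""

    L: int = 100
    P_iso: float = 0.005
    P_ext: float = 0.1
    P_other: float = 0.005
    eps_elongation: float = -1.0
    eps_lateral: float = -0.5
    kBT: float = 0.1
    max_steps: int = 1_000_000
    seed: int = 0
    snapshot_every: int = 10_000
    periodic: bool = False
    apply_metropolis: bool = True

    def __post_init__(self):
        if self.L < 2:
            raise ValidationError("L must be >= 2")
        for name in ("P_iso", "P_ext", "P_other"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if not self.kBT > 0:
            raise ValidationError("kBT must be positive")
        if self.eps_elongation > 0 or self.eps_lateral > 0:
            raise ValidationError("energy depths must be <= 0")
        if self.max_steps < 1:
            raise ValidationError("max_steps must be >= 1")


@dataclass(frozen=True)
class LatticeState:
    """Final grid plus the log of every gate-passed insertion attempt."""

    grid: np.ndarray
    step_count: int
    event_log: pd.DataFrame


@dataclass(frozen=True)
class SimulationResult:
    state: LatticeState
    snapshots: tuple[tuple[int, np.ndarray], ...]
    config: LatticeConfig


@dataclass(frozen=True)
class CorrelationProfile:
    """Distance-binned orientational pair correlation ``<cos 2(dtheta)>``."""

    r_bins: np.ndarray
    G2: np.ndarray
    pair_counts: np.ndarray

    def mean_up_to(self, r_max: float) -> float:
        """Pair-weighted mean of G2 over bins with centre <= r_max."""
        mask = self.r_bins <= r_max
        w = self.pair_counts[mask]
        return float(np.sum(self.G2[mask] * w) / np.sum(w))


@dataclass(frozen=True)
class ElongationEventCounts:
    n_surface_catalyzed: int
    n_independent: int
    n_nucleation: int
    n_lateral: int


# ---------------------------------------------------------------------------
# local rules (reference implementations, also used by tests as oracles)
# ---------------------------------------------------------------------------

_NEIGH = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _neighbor_counts(grid: np.ndarray, i: int, j: int, v: int, periodic: bool):
    """Counts of occupied / elongation-aligned / laterally-aligned neighbors."""
    rows, cols = grid.shape
    n_occ = n_elong = n_lat = 0
    for di, dj in _NEIGH:
        ii, jj = i + di, j + dj
        if periodic:
            ii %= rows
            jj %= cols
        elif not (0 <= ii < rows and 0 <= jj < cols):
            continue  # outside counts as empty
        w = grid[ii, jj]
        if w == 0:
            continue
        n_occ += 1
        if w == v:
            # joint vector b = (j - jj, i - ii); horizontal (+1) is parallel
            # to b when the neighbor shares the row, vertical (-1) when it
            # shares the column
            along_axis = (di == 0) if v == 1 else (dj == 0)
            if along_axis:
                n_elong += 1
            else:
                n_lat += 1
    return n_occ, n_elong, n_lat


def interaction_energy(
    grid: np.ndarray,
    cell: tuple[int, int],
    v: int,
    eps_elongation: float,
    eps_lateral: float,
    periodic: bool = False,
) -> tuple[float, str]:
    """Insertion energy and event class for orientation ``v`` at ``cell``.

    Each aligned extension-direction neighbor contributes
    ``eps_elongation``; each aligned side neighbor ``eps_lateral``;
    opposite orientations contribute 0. A placement with both contact
    types is surface-catalyzed elongation.
    """
    i, j = cell
    if grid[i, j] != 0:
        raise ValidationError("target cell is occupied")
    if v not in (-1, 1):
        raise ValidationError("orientation must be -1 or +1")
    n_occ, n_elong, n_lat = _neighbor_counts(grid, i, j, v, periodic)
    energy = n_elong * eps_elongation + n_lat * eps_lateral
    if n_occ == 0:
        cls = "nucleation"
    elif n_elong > 0 and n_lat > 0:
        cls = "elongation_surface_catalyzed"
    elif n_elong > 0:
        cls = "elongation_independent"
    elif n_lat > 0:
        cls = "lateral_attachment"
    else:
        cls = "misaligned"
    return float(energy), cls


def choose_orientation(
    grid: np.ndarray,
    cell: tuple[int, int],
    kBT: float,
    rng: np.random.Generator,
    eps_elongation: float,
    eps_lateral: float,
    periodic: bool = False,
) -> int:
    """Sample the orientation of a new rodlet.

    Isolated cells draw -1/+1 with probability 1/2 each; otherwise the
    orientation is Boltzmann-sampled from the two insertion energies.
    """
    i, j = cell
    n_occ, ne_p, nl_p = _neighbor_counts(grid, i, j, 1, periodic)
    if n_occ == 0:
        return 1 if rng.random() < 0.5 else -1
    _, ne_m, nl_m = _neighbor_counts(grid, i, j, -1, periodic)
    e_plus = ne_p * eps_elongation + nl_p * eps_lateral
    e_minus = ne_m * eps_elongation + nl_m * eps_lateral
    p_plus = 1.0 / (1.0 + math.exp((e_plus - e_minus) / kBT))
    return 1 if rng.random() < p_plus else -1


def metropolis_accept(delta_E: float, kBT: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-delta_E / kBT))."""
    if not kBT > 0:
        raise ValidationError("kBT must be positive")
    if delta_E <= 0:
        return True
    return bool(rng.random() < math.exp(-delta_E / kBT))


# ---------------------------------------------------------------------------
# compiled inner loop
# ---------------------------------------------------------------------------


@njit(cache=True)
def _terms(grid, rows, cols, i, j, v, periodic):
    n_occ = 0
    n_elong = 0
    n_lat = 0
    for k in range(4):
        if k == 0:
            di, dj = -1, 0
        elif k == 1:
            di, dj = 1, 0
        elif k == 2:
            di, dj = 0, -1
        else:
            di, dj = 0, 1
        ii = i + di
        jj = j + dj
        if periodic:
            ii = ii % rows
            jj = jj % cols
        elif ii < 0 or ii >= rows or jj < 0 or jj >= cols:
            continue
        w = grid[ii, jj]
        if w == 0:
            continue
        n_occ += 1
        if w == v:
            if v == 1:
                along = di == 0
            else:
                along = dj == 0
            if along:
                n_elong += 1
            else:
                n_lat += 1
    return n_occ, n_elong, n_lat


@njit(cache=True)
def _run_kernel(
    grid,
    max_steps,
    p_iso,
    p_ext,
    p_other,
    eps_e,
    eps_l,
    kbt,
    seed,
    periodic,
    apply_metropolis,
):
    np.random.seed(seed)
    rows, cols = grid.shape
    ncell = rows * cols
    empties = np.empty(ncell, np.int64)
    slot = np.full(ncell, -1, np.int64)
    n_empty = 0
    for flat in range(ncell):
        if grid[flat // cols, flat % cols] == 0:
            empties[n_empty] = flat
            slot[flat] = n_empty
            n_empty += 1

    ev_step = np.empty(max_steps, np.int64)
    ev_i = np.empty(max_steps, np.int32)
    ev_j = np.empty(max_steps, np.int32)
    ev_v = np.empty(max_steps, np.int8)
    ev_cls = np.empty(max_steps, np.int8)
    ev_de = np.empty(max_steps, np.float64)
    ev_acc = np.empty(max_steps, np.uint8)
    n_ev = 0

    step = 0
    while step < max_steps and n_empty > 0:
        idx = np.random.randint(0, n_empty)
        flat = empties[idx]
        i = flat // cols
        j = flat % cols

        n_occ, ne_p, nl_p = _terms(grid, rows, cols, i, j, 1, periodic)
        _, ne_m, nl_m = _terms(grid, rows, cols, i, j, -1, periodic)

        if n_occ == 0:
            p_att = p_iso
        elif ne_p > 0 or ne_m > 0:
            p_att = p_ext
        else:
            p_att = p_other

        if np.random.random() < p_att:
            if n_occ == 0:
                v = 1 if np.random.random() < 0.5 else -1
            else:
                e_plus = ne_p * eps_e + nl_p * eps_l
                e_minus = ne_m * eps_e + nl_m * eps_l
                p_plus = 1.0 / (1.0 + np.exp((e_plus - e_minus) / kbt))
                v = 1 if np.random.random() < p_plus else -1
            if v == 1:
                ne, nl = ne_p, nl_p
            else:
                ne, nl = ne_m, nl_m
            energy = ne * eps_e + nl * eps_l
            if n_occ == 0:
                cls = 0
            elif ne > 0 and nl > 0:
                cls = 2
            elif ne > 0:
                cls = 1
            elif nl > 0:
                cls = 3
            else:
                cls = 4
            accepted = True
            if apply_metropolis and energy > 0.0:
                accepted = np.random.random() < np.exp(-energy / kbt)
            ev_step[n_ev] = step
            ev_i[n_ev] = i
            ev_j[n_ev] = j
            ev_v[n_ev] = v
            ev_cls[n_ev] = cls
            ev_de[n_ev] = energy
            ev_acc[n_ev] = 1 if accepted else 0
            n_ev += 1
            if accepted:
                grid[i, j] = v
                last = empties[n_empty - 1]
                empties[idx] = last
                slot[last] = idx
                slot[flat] = -1
                n_empty -= 1
        step += 1

    return step, n_ev, ev_step, ev_i, ev_j, ev_v, ev_cls, ev_de, ev_acc


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------


def _events_frame(n_ev, ev_step, ev_i, ev_j, ev_v, ev_cls, ev_de, ev_acc) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "step": ev_step[:n_ev],
            "i": ev_i[:n_ev],
            "j": ev_j[:n_ev],
            "orientation": ev_v[:n_ev].astype(int),
            "event_class": pd.Categorical.from_codes(ev_cls[:n_ev], categories=EVENT_CLASSES),
            "delta_E": ev_de[:n_ev],
            "accepted": ev_acc[:n_ev].astype(bool),
        }
    )


def run_simulation(
    config: LatticeConfig, initial_grid: np.ndarray | None = None
) -> SimulationResult:
    """Run the insertion Monte Carlo until full occupancy or ``max_steps``.

    Returns the final state (grid plus full attempt log) and grid
    snapshots taken every ``snapshot_every`` steps, reconstructed from the
    insertion log.
    """
    if initial_grid is None:
        grid = np.zeros((config.L, config.L), dtype=np.int8)
    else:
        grid = np.asarray(initial_grid, dtype=np.int8).copy()
        if not np.isin(grid, (-1, 0, 1)).all():
            raise ValidationError("grid values must be in {-1, 0, 1}")
    start = grid.copy()
    out = _run_kernel(
        grid,
        config.max_steps,
        config.P_iso,
        config.P_ext,
        config.P_other,
        config.eps_elongation,
        config.eps_lateral,
        config.kBT,
        config.seed,
        config.periodic,
        config.apply_metropolis,
    )
    steps, n_ev = out[0], out[1]
    log = _events_frame(n_ev, *out[2:])
    snapshots = []
    if config.snapshot_every > 0:
        acc = log[log["accepted"]]
        for s in range(config.snapshot_every, steps + 1, config.snapshot_every):
            snap = start.copy()
            sel = acc[acc["step"] < s]
            snap[sel["i"].to_numpy(), sel["j"].to_numpy()] = sel["orientation"].to_numpy()
            snapshots.append((s, snap))
    state = LatticeState(grid=grid, step_count=int(steps), event_log=log)
    return SimulationResult(state=state, snapshots=tuple(snapshots), config=config)


def angle_pair_correlation(
    grid: np.ndarray, max_r: float = 20.0, bin_width: float = 1.0
) -> CorrelationProfile:
    """Orientational pair correlation G2(r) = <cos 2(theta_i - theta_j)>.

    Horizontal rods have angle 0, vertical rods 90 degrees, so the cosine
    term is +1 for equal and -1 for orthogonal orientations: exactly the
    product of the +/-1 cell values. Pairs are averaged in Euclidean
    distance bins of ``bin_width``; only populated bins are returned.
    """
    g = np.asarray(grid)
    if not np.isin(g, (-1, 0, 1)).all():
        raise ValidationError("grid values must be in {-1, 0, 1}")
    if int(np.count_nonzero(g)) < 2:
        raise ValidationError("need at least 2 occupied cells")
    s = g.astype(np.int64)
    occ = (g != 0).astype(np.int64)
    nbins = int(np.ceil(max_r / bin_width)) + 1
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    span = int(math.floor(max_r))
    for di in range(0, span + 1):
        for dj in range(-span, span + 1):
            if di == 0 and dj <= 0:
                continue  # count each unordered pair once
            r = math.hypot(di, dj)
            if r > max_r:
                continue
            b = int(r / bin_width)
            if dj >= 0:
                a1, a2 = s[: s.shape[0] - di, : s.shape[1] - dj], s[di:, dj:]
                o1, o2 = occ[: s.shape[0] - di, : s.shape[1] - dj], occ[di:, dj:]
            else:
                a1, a2 = s[: s.shape[0] - di, -dj:], s[di:, : s.shape[1] + dj]
                o1, o2 = occ[: s.shape[0] - di, -dj:], occ[di:, : s.shape[1] + dj]
            sums[b] += int((a1 * a2).sum())
            counts[b] += int((o1 * o2).sum())
    keep = counts > 0
    centers = (np.arange(nbins) + 0.5) * bin_width
    return CorrelationProfile(
        r_bins=centers[keep], G2=sums[keep] / counts[keep], pair_counts=counts[keep]
    )


def count_elongation_events(event_log: pd.DataFrame) -> ElongationEventCounts:
    """Tally accepted events by class (empty log gives all zeros)."""
    if len(event_log) == 0:
        return ElongationEventCounts(0, 0, 0, 0)
    acc = event_log[event_log["accepted"]]
    tally = acc["event_class"].value_counts()
    return ElongationEventCounts(
        n_surface_catalyzed=int(tally.get("elongation_surface_catalyzed", 0)),
        n_independent=int(tally.get("elongation_independent", 0)),
        n_nucleation=int(tally.get("nucleation", 0)),
        n_lateral=int(tally.get("lateral_attachment", 0)),
    )


# ---------------------------------------------------------------------------
# simplified tip-elongation experiment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TipExperimentResult:
    """Right-tip advance of each tracked rodlet front.

    ``extents`` holds the final contiguous advance (cells) of every tip
    beyond its initial column; bundled tips track the fastest row of the
    long-rodlet/short-rodlet pair, single tips the long rodlet's own row.
    """

    kinds: tuple[str, ...]  # "bundled" | "single" per tip
    extents: np.ndarray
    steps_run: int
    event_log: pd.DataFrame
    initial_grid: np.ndarray
    final_grid: np.ndarray

    def mean_increment_per_step(self, kind: str) -> float:
        sel = np.array([k == kind for k in self.kinds])
        return float(np.mean(self.extents[sel]) / self.steps_run)


def run_tip_experiment(
    config: LatticeConfig | None = None,
    n_long: int = 10,
    long_len: int = 100,
    short_len: int = 2,
    spacing: int = 6,
    margin: int = 30,
    max_steps: int = 1_500_000,
    seed: int | None = None,
) -> TipExperimentResult:
    """Compare tip elongation of laterally-contacted vs isolated rodlets.

    ``n_long`` horizontal rodlets of ``long_len`` cells are laid out at
    equal row intervals; alternate rodlets get a ``short_len`` rodlet in
    lateral contact flush with their right tip. Nucleation is switched off
    (isolated and purely-lateral placements are disabled) so only
    elongation-direction insertions occur, isolating tip growth. The
    advance of each tip front is measured as the longest contiguous
    occupied run beyond the initial tip column over the rows belonging to
    that front.
    """
    if config is None:
        config = LatticeConfig()
    if spacing < 3:
        raise ValidationError("spacing must be >= 3 to keep fronts independent")
    rows = n_long * spacing
    cols = long_len + 2 * margin
    grid = np.zeros((rows, cols), dtype=np.int8)
    tip_col = margin + long_len - 1
    tip_rows: list[tuple[str, tuple[int, ...]]] = []
    for k in range(n_long):
        r = spacing // 2 + k * spacing
        grid[r, margin : margin + long_len] = 1
        if k % 2 == 0:
            grid[r - 1, tip_col - short_len + 1 : tip_col + 1] = 1
            tip_rows.append(("bundled", (r, r - 1)))
        else:
            tip_rows.append(("single", (r,)))
    if tip_col + 1 >= cols:
        raise ValidationError("geometry leaves no room to elongate")

    cfg = replace(
        config,
        P_iso=0.0,  # nucleation off
        P_other=0.0,  # purely-lateral seeding is nucleation on a surface
        max_steps=max_steps,
        seed=config.seed if seed is None else seed,
        snapshot_every=0,
    )
    result = run_simulation(cfg, initial_grid=grid)
    final = result.state.grid

    extents = np.zeros(len(tip_rows))
    for n, (_kind, rws) in enumerate(tip_rows):
        best = 0
        for r in rws:
            e = 0
            c = tip_col + 1
            while c < cols and final[r, c] == 1:
                e += 1
                c += 1
            best = max(best, e)
        extents[n] = best
    return TipExperimentResult(
        kinds=tuple(k for k, _ in tip_rows),
        extents=extents,
        steps_run=result.state.step_count,
        event_log=result.state.event_log,
        initial_grid=grid,
        final_grid=final,
    )


def render_grid(grid: np.ndarray, path: str) -> None:
    """Write a three-color PNG of the grid (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    cmap = ListedColormap(["#1f77b4", "#f5f5f5", "#d62728"])  # vertical/empty/horizontal
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(grid, cmap=cmap, vmin=-1, vmax=1, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
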