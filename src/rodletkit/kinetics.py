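"""Dwell/step kinetics of fibril-end position trajectories.

This module segments end-position tracks into alternating pause ("dwell")
and growth ("step") phases, fits exponential distributions to phase
durations and step sizes, derives per-end elongation rates and the
pause/growth equilibrium constant, fits sigmoid plateaus to precursor
height traces, and provides the nonparametric statistical comparisons used
for group contrasts (Brunner-Munzel test, paired sign-flip permutation).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    DegenerateTestError,
    FitFailureError,
    UndefinedRateError,
    ValidationError,
)

__all__ = [
    "EndTrajectory",
    "Phase",
    "KineticEvents",
    "ExponentialFit",
    "EndKinetics",
    "HeightTrace",
    "BrunnerMunzelResult",
    "PairedComparisonResult",
    "KineticsEstimate",
    "detect_phases",
    "fit_exponential",
    "fit_exponential_counts",
    "apparent_elongation_rate",
    "step_rate",
    "equilibrium_constant",
    "fit_sigmoid_plateau",
    "mean_window_height",
    "brunner_munzel",
    "paired_end_comparison",
    "summarize_group",
    "pooled_interior_phases",
    "correct_missed_events",
    "recalibrate_kinetics",
]

_END_LABELS = {"fast", "slow", "unassigned"}
_CATEGORIES = {"preexisting", "de_novo"}
_CONTEXTS = {"single", "bundled"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EndTrajectory:
    """Position-versus-time track of one rodlet end.

    Parameters
    ----------
    rodlet_id : str
        Identifier of the parent rodlet.
    end_label : {"fast", "slow", "unassigned"}
    category : {"preexisting", "de_novo"}
    context : {"single", "bundled"}
    times : ndarray
        Sample times in seconds; strictly increasing, uniformly spaced.
    positions : ndarray
        End position along the growth axis in nm; finite.
    """

    rodlet_id: str
    end_label: str
    category: str
    context: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", y)
        if self.end_label not in _END_LABELS:
            raise ValidationError(f"unknown end_label {self.end_label!r}")
        if self.category not in _CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.context not in _CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}")
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValidationError("times and positions must be 1-D and equal length")
        if t.size < 3:
            raise ValidationError("trajectory needs at least 3 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValidationError("times must be uniformly spaced")
        if not np.all(np.isfinite(y)):
            raise ValidationError("positions must be finite")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class Phase:
    """One dwell or step phase: kind, onset (s), duration (s), length change (nm)."""

    kind: str  # "dwell" | "step"
    start: float
    duration: float
    delta: float

    def __post_init__(self):
        if self.kind not in ("dwell", "step"):
            raise ValidationError(f"unknown phase kind {self.kind!r}")
        if not self.duration > 0:
            raise ValidationError("phase duration must be positive")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class KineticEvents:
    """Alternating dwell/step segmentation of one trajectory.

    ``censored_first``/``censored_last`` flag the phases touching the record
    boundaries; their durations are lower bounds and are excluded from
    distribution fits by downstream code.
    """

    phases: tuple[Phase, ...]
    censored_first: bool
    censored_last: bool

    def __post_init__(self):
        for a, b in zip(self.phases, self.phases[1:]):
            if a.kind == b.kind:
                raise ValidationError("phases must alternate in kind")

    def is_censored(self, index: int) -> bool:
        index = index % len(self.phases)
        if index == 0 and self.censored_first:
            return True
        if index == len(self.phases) - 1 and self.censored_last:
            return True
        return False

    def _select(self, kind: str, include_censored: bool) -> list[Phase]:
        return [
            p
            for i, p in enumerate(self.phases)
            if p.kind == kind and (include_censored or not self.is_censored(i))
        ]

    def dwell_phases(self, include_censored: bool = False) -> list[Phase]:
        return self._select("dwell", include_censored)

    def step_phases(self, include_censored: bool = False) -> list[Phase]:
        return self._select("step", include_censored)

    def dwell_durations(self, include_censored: bool = False) -> np.ndarray:
        return np.array([p.duration for p in self.dwell_phases(include_censored)])

    def step_durations(self, include_censored: bool = False) -> np.ndarray:
        return np.array([p.duration for p in self.step_phases(include_censored)])

    def step_sizes(self, include_censored: bool = False) -> np.ndarray:
        return np.array([p.delta for p in self.step_phases(include_censored)])


@dataclass(frozen=True)
class ExponentialFit:
    """Exponential distribution fit: mean ``tau`` plus fit metadata.

    ``method='mle'`` gives tau equal to the arithmetic sample mean with an
    exact chi-square confidence interval; ``method='histogram_lsq'`` mirrors
    the display-style least-squares fit of binned counts to A*exp(-t/tau).
    """

    tau: float
    A: float | None
    n: int
    method: str
    ci95: tuple[float, float]

    def __post_init__(self):
        if not self.tau > 0:
            raise ValidationError("tau must be positive")
        if self.n < 2:
            raise ValidationError("fit needs at least 2 observations")


@dataclass(frozen=True)
class EndKinetics:
    """Per-group kinetic summary (rates in nm/min, times in s)."""

    group: str
    n_ends: int
    apparent_rate: float
    apparent_rate_se: float
    step_rate_mean: float
    step_rate_se: float
    tau_dwell: float
    tau_step: float
    mean_step_size: float
    k_open: float
    k_close: float
    K_d: float


@dataclass(frozen=True)
class HeightTrace:
    """Height-versus-time record of one spherical precursor."""

    times: np.ndarray
    heights: np.ndarray
    converts: bool

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "heights", h)
        if t.ndim != 1 or h.ndim != 1 or t.size != h.size:
            raise ValidationError("times and heights must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(h)):
            raise ValidationError("heights must be finite")


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _runs(labels: np.ndarray) -> list[list]:
    """Run-length encode a boolean array into [value, first, last] triples."""
    out = []
    start = 0
    for k in range(1, len(labels) + 1):
        if k == len(labels) or labels[k] != labels[start]:
            out.append([bool(labels[start]), start, k - 1])
            start = k
    return out


def _merge_adjacent(runs: list[list]) -> list[list]:
    merged = [runs[0]]
    for r in runs[1:]:
        if r[0] == merged[-1][0]:
            merged[-1][2] = r[2]
        else:
            merged.append(r)
    return merged


def detect_phases(
    traj: EndTrajectory,
    threshold_nm: float,
    min_frames: int = 2,
    hysteresis: float = 2.0,
    refine: bool = True,
    min_dwell_s: float | None = None,
) -> KineticEvents:
    """Segment a trajectory into alternating dwell and step phases.

    Frame intervals are classified as growth when the forward displacement
    over ``min_frames`` frames exceeds ``threshold_nm``; runs of like
    intervals are merged into phases. Candidate step runs whose net rise
    does not exceed ``hysteresis * threshold_nm`` are treated as noise and
    folded back into the surrounding dwell. With ``refine=True``, phase
    boundaries are localized to sub-frame precision by intersecting a line
    fit of the ramp with the flanking dwell levels; on noiseless data this
    recovers the true piecewise-linear breakpoints exactly whenever the
    ramp spans at least two interior frames, and within one frame
    otherwise.

    Parameters
    ----------
    traj : EndTrajectory
    threshold_nm : float
        Displacement threshold; a sensible default is twice the position
        noise standard deviation.
    min_frames : int
        Look-ahead window (frames) for the displacement classification.
    hysteresis : float
        Multiple of ``threshold_nm`` a step run's net rise must exceed.
    refine : bool
        Enable sub-frame boundary refinement.
    min_dwell_s : float, optional
        If set, interior dwell phases shorter than this are folded into
        the surrounding steps after segmentation. Using the frame interval
        here gives the detection a sharp dead time, which the missed-event
        correction (`correct_missed_events`) assumes.

    Returns
    -------
    KineticEvents
    """
    if threshold_nm <= 0:
        raise ValidationError("threshold_nm must be positive")
    if min_frames < 1:
        raise ValidationError("min_frames must be >= 1")
    t = traj.times
    y = traj.positions
    n = t.size
    dt = traj.frame_interval

    k = np.arange(n - 1)
    fwd = y[np.minimum(k + min_frames, n - 1)] - y[k]
    is_step = fwd > threshold_nm

    runs = _runs(is_step)
    # hysteresis: a step run must achieve a net rise clearly above threshold
    for r in runs:
        if r[0] and (y[r[2] + 1] - y[r[1]]) <= hysteresis * threshold_nm:
            r[0] = False
    runs = _merge_adjacent(runs)

    step_runs = [r for r in runs if r[0]]
    if not step_runs:
        phase = Phase("dwell", float(t[0]), float(t[-1] - t[0]), float(y[-1] - y[0]))
        return KineticEvents((phase,), censored_first=True, censored_last=True)

    run_index = {id(r): i for i, r in enumerate(runs)}
    tiny = dt * 1e-9

    def _dwell_level(run) -> float:
        a, b = run[1], run[2]
        return float(np.mean(y[a : b + 2]))

    boundaries = []  # (onset, term, prev_level, next_level, a, b)
    for r in step_runs:
        i = run_index[id(r)]
        a, b = r[1], r[2]
        prev_run = runs[i - 1] if i > 0 else None
        next_run = runs[i + 1] if i < len(runs) - 1 else None
        prev_level = _dwell_level(prev_run) if prev_run is not None else None
        next_level = _dwell_level(next_run) if next_run is not None else None

        onset, term = float(t[a]), float(t[b + 1])
        m = b - a + 1  # run length in intervals
        # frames strictly inside the ramp; the first min_frames-1 frames of a
        # run can predate the ramp because of the look-ahead classification
        interior = np.arange(a + min_frames, b + 1)
        if refine:
            if interior.size >= 2:
                slope, icept = np.polyfit(t[interior], y[interior], 1)
                if slope > 0:
                    if prev_level is not None:
                        onset = (prev_level - icept) / slope
                        onset = float(np.clip(onset, t[max(a - 1, 0)], t[a + 1]))
                    if next_level is not None:
                        term = (next_level - icept) / slope
                        term = float(np.clip(term, t[b], t[min(b + 2, n - 1)]))
            else:
                # too short for a line fit; use an expectation-centred span
                if prev_level is not None and next_level is not None:
                    if m == 1:
                        onset = float(t[a] + 0.25 * dt)
                        term = float(t[a] + 0.75 * dt)
                    else:
                        onset = float(t[a] + 0.5 * dt)
                        term = float(t[b + 1] - 0.5 * dt)
        if prev_run is None:
            onset = float(t[0])
        if next_run is None:
            term = float(t[-1])
        if term <= onset:  # degenerate refinement; fall back to raw frames
            onset, term = float(t[a]), float(t[b + 1])
        boundaries.append((onset, term, prev_level, next_level, a, b))

    # enforce strictly increasing, non-overlapping step windows
    for j in range(1, len(boundaries)):
        onset, term, pl, nl, a, b = boundaries[j]
        prev_term = boundaries[j - 1][1]
        if onset <= prev_term:
            onset = prev_term + tiny
        if term <= onset:
            term = onset + tiny
        boundaries[j] = (onset, term, pl, nl, a, b)
    # keep room for the flanking dwells when the record starts/ends with one
    if not runs[0][0]:
        onset, term, pl, nl, a, b = boundaries[0]
        onset = max(onset, float(t[0]) + tiny)
        term = max(term, onset + tiny)
        boundaries[0] = (onset, term, pl, nl, a, b)
    if not runs[-1][0]:
        onset, term, pl, nl, a, b = boundaries[-1]
        term = min(term, float(t[-1]) - tiny)
        onset = min(onset, term - tiny)
        boundaries[-1] = (onset, term, pl, nl, a, b)

    pos = _interp1d(t, y)
    phases: list[Phase] = []
    first_is_step = runs[0][0]
    if not first_is_step:
        onset0 = boundaries[0][0]
        phases.append(Phase("dwell", float(t[0]), onset0 - t[0], float(pos(onset0) - y[0])))
    for j, (onset, term, prev_level, next_level, a, b) in enumerate(boundaries):
        if prev_level is not None and next_level is not None:
            delta = next_level - prev_level
        else:
            delta = float(y[b + 1] - y[a])
        delta = max(delta, tiny)  # step phases rise by construction
        phases.append(Phase("step", onset, term - onset, delta))
        if j < len(boundaries) - 1:
            nxt_onset = boundaries[j + 1][0]
            nxt_prev_level = boundaries[j + 1][2]
            d_delta = (
                nxt_prev_level - next_level
                if (next_level is not None and nxt_prev_level is not None)
                else float(pos(nxt_onset) - pos(term))
            )
            phases.append(Phase("dwell", term, nxt_onset - term, d_delta))
    last_term = boundaries[-1][1]
    if not runs[-1][0]:
        phases.append(
            Phase("dwell", last_term, float(t[-1]) - last_term, float(y[-1] - pos(last_term)))
        )

    if min_dwell_s is not None:
        phases = _enforce_min_dwell(phases, min_dwell_s)
    return KineticEvents(tuple(phases), censored_first=True, censored_last=True)


def _enforce_min_dwell(phases: list[Phase], min_dwell_s: float) -> list[Phase]:
    """Fold interior dwells shorter than ``min_dwell_s`` into surrounding steps."""
    n = len(phases)
    records = []
    for idx, p in enumerate(phases):
        kind = p.kind
        if kind == "dwell" and 0 < idx < n - 1 and p.duration < min_dwell_s:
            kind = "step"
        records.append([kind, p.start, p.duration, p.delta])
    merged = [records[0]]
    for rec in records[1:]:
        if rec[0] == merged[-1][0]:
            merged[-1][2] += rec[2]
            merged[-1][3] += rec[3]
        else:
            merged.append(rec)
    return [Phase(k, s, d, x) for k, s, d, x in merged]


def _interp1d(t, y):
    def f(x):
        return float(np.interp(x, t, y))

    return f


# ---------------------------------------------------------------------------
# exponential fitting
# ---------------------------------------------------------------------------


def fit_exponential(
    values, method: str = "mle", bin_width: float | None = None
) -> ExponentialFit:
    """Fit an exponential distribution (count curve N = A*exp(-t/tau)).

    ``mle`` returns tau equal to the sample mean with the exact chi-square
    95% interval. ``histogram_lsq`` bins the data (default width 10 units)
    and least-squares fits the decaying count curve, mirroring the usual
    display fit of duration/size histograms.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValidationError("need at least 2 observations")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValidationError("all observations must be positive and finite")
    n = v.size
    if method == "mle":
        tau = float(np.mean(v))
        lo = 2 * n * tau / stats.chi2.ppf(0.975, 2 * n)
        hi = 2 * n * tau / stats.chi2.ppf(0.025, 2 * n)
        return ExponentialFit(tau=tau, A=None, n=n, method="mle", ci95=(lo, hi))
    if method == "histogram_lsq":
        width = 10.0 if bin_width is None else float(bin_width)
        edges = np.arange(0.0, v.max() + width, width)
        counts, edges = np.histogram(v, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        fit = fit_exponential_counts(centers[keep], counts[keep])
        return ExponentialFit(tau=fit.tau, A=fit.A, n=n, method="histogram_lsq", ci95=fit.ci95)
    raise ValidationError(f"unknown method {method!r}")


def fit_exponential_counts(t, counts) -> ExponentialFit:
    """Least-squares fit of A*exp(-t/tau) to an observed count curve."""
    t = np.asarray(t, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if t.size < 2:
        raise ValidationError("need at least 2 histogram points")
    a0 = float(counts.max())
    pos = counts > 0
    tau0 = float(np.sum(t[pos] * counts[pos]) / np.sum(counts[pos])) or 1.0
    tau0 = max(tau0, 1e-9)
    try:
        popt, pcov = optimize.curve_fit(
            lambda x, A, tau: A * np.exp(-x / tau),
            t,
            counts,
            p0=(a0, tau0),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise FitFailureError(f"exponential count fit failed: {exc}") from exc
    A, tau = float(popt[0]), float(popt[1])
    err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.inf
    return ExponentialFit(
        tau=tau, A=A, n=t.size, method="histogram_lsq", ci95=(tau - 1.96 * err, tau + 1.96 * err)
    )


# ---------------------------------------------------------------------------
# rates and equilibrium
# ---------------------------------------------------------------------------


def apparent_elongation_rate(events: KineticEvents) -> float:
    """Endpoint slope of growth: first step onset to last step termination.

    Returns nm/min. Positions are reconstructed from the phase deltas, so
    intervening dwells contribute their (near-zero) drift only.
    """
    steps = events.step_phases(include_censored=True)
    if not steps:
        raise UndefinedRateError("trajectory contains no step phase")
    onset = steps[0].start
    term = steps[-1].end
    rise = sum(p.delta for p in events.phases if p.start >= onset - 1e-12 and p.start < term)
    return rise / (term - onset) * 60.0


def step_rate(events: KineticEvents) -> tuple[float, float]:
    """Mean and SE over steps of per-step rate (size/time), in nm/min."""
    steps = events.step_phases(include_censored=False)
    if not steps:
        raise UndefinedRateError("no uncensored step phase")
    rates = np.array([p.delta / p.duration * 60.0 for p in steps])
    mean = float(np.mean(rates))
    se = float(np.std(rates, ddof=1) / np.sqrt(rates.size)) if rates.size > 1 else 0.0
    return mean, se


def equilibrium_constant(tau_dwell: float, tau_step: float) -> float:
    """Pause/growth equilibrium constant from mean dwell and step times.

    Computed as ``tau_dwell / tau_step``, the convention that reproduces
    the reported per-condition values from the mean times.
    """
    if not (tau_dwell > 0 and tau_step > 0):
        raise ValidationError("tau_dwell and tau_step must be positive")
    return tau_dwell / tau_step


# ---------------------------------------------------------------------------
# precursor heights
# ---------------------------------------------------------------------------


def _logistic(t, base, plateau, midpoint, width):
    return base + (plateau - base) / (1.0 + np.exp(-(t - midpoint) / width))


def fit_sigmoid_plateau(trace: HeightTrace) -> float:
    """Upper asymptote of a 4-parameter logistic least-squares fit."""
    t = trace.times
    h = trace.heights
    if t.size < 5:
        raise ValidationError("need at least 5 samples for a sigmoid fit")
    spread = float(np.ptp(h))
    if spread < 1e-12:  # degenerate constant trace
        return float(h[0])
    mid0 = float(t[np.argmin(np.abs(h - (h.min() + h.max()) / 2.0))])
    p0 = (float(h.min()), float(h.max()), mid0, float(np.ptp(t)) / 10.0)
    try:
        popt, _ = optimize.curve_fit(_logistic, t, h, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitFailureError(
            "sigmoid fit did not converge",
            diagnostics={"p0": p0, "n": int(t.size), "spread": spread},
        ) from exc
    return float(popt[1])


def mean_window_height(trace: HeightTrace, t0: float, t1: float) -> float:
    """Arithmetic mean of heights with ``t0 <= t <= t1``."""
    mask = (trace.times >= t0) & (trace.times <= t1)
    if not np.any(mask):
        raise ValidationError("window does not overlap the trace")
    return float(np.mean(trace.heights[mask]))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BrunnerMunzelResult:
    statistic: float
    df: float
    p_value: float
    relative_effect: float  # P(X < Y) + 0.5 P(X = Y)


def brunner_munzel(x, y) -> BrunnerMunzelResult:
    """Rank-based Brunner-Munzel two-sample test with Welch-type df.

    The relative effect is P(X < Y) + 0.5*P(X = Y); 0.5 means stochastic
    equality. Identical samples yield statistic 0 and p = 1; a fully
    separated zero-variance configuration yields an infinite statistic and
    p = 0 rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValidationError("both samples need at least 2 observations")
    combined = np.concatenate([x, y])
    rk = stats.rankdata(combined)
    r1, r2 = rk[:n1], rk[n1:]
    r1_in = stats.rankdata(x)
    r2_in = stats.rankdata(y)
    m1, m2 = r1.mean(), r2.mean()
    effect = (m2 - (n2 + 1) / 2.0) / n1
    s1 = np.sum((r1 - r1_in - m1 + (n1 + 1) / 2.0) ** 2) / (n1 - 1)
    s2 = np.sum((r2 - r2_in - m2 + (n2 + 1) / 2.0) ** 2) / (n2 - 1)
    var = n1 * s1 + n2 * s2
    if var <= 0:
        if np.isclose(effect, 0.5):
            return BrunnerMunzelResult(0.0, float(n1 + n2 - 2), 1.0, 0.5)
        stat = math.inf if effect > 0.5 else -math.inf
        return BrunnerMunzelResult(stat, float(n1 + n2 - 2), 0.0, float(effect))
    stat = n1 * n2 * (m2 - m1) / ((n1 + n2) * np.sqrt(var))
    df = var**2 / ((n1 * s1) ** 2 / (n1 - 1) + (n2 * s2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(stat), df)
    return BrunnerMunzelResult(float(stat), float(df), float(p), float(effect))


@dataclass(frozen=True)
class PairedComparisonResult:
    mean_difference: float
    p_value: float
    n_pairs: int
    n_permutations: int
    exact: bool


def paired_end_comparison(
    pairs, *, max_exact: int = 20, n_resamples: int = 100_000, seed: int | None = None
) -> PairedComparisonResult:
    """Two-sided sign-flip permutation test of the within-rodlet difference.

    ``pairs`` is a sequence of (fast, slow) apparent-rate pairs, one per
    rodlet. With one observation per end per rodlet this is the exact
    paired reduction of a random-intercept model for the end effect. The
    null distribution enumerates all 2^n sign flips when n <= ``max_exact``
    and is sampled otherwise.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be an (n, 2) array of (fast, slow) values")
    n = arr.shape[0]
    if n < 5:
        raise ValidationError("need at least 5 complete pairs")
    d = arr[:, 0] - arr[:, 1]
    observed = float(np.mean(d))
    if np.allclose(d, 0.0):
        return PairedComparisonResult(0.0, 1.0, n, 0, True)
    if n <= max_exact:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        null = signs @ d / n
        p = float(np.mean(np.abs(null) >= abs(observed) - 1e-12))
        return PairedComparisonResult(observed, p, n, signs.shape[0], True)
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(n_resamples, n))
    null = signs @ d / n
    hits = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    p = (hits + 1) / (n_resamples + 1)
    return PairedComparisonResult(observed, float(p), n, n_resamples, False)


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

_GROUPINGS = {"category", "context", "end_label"}


def summarize_group(
    trajs,
    grouping: str = "context",
    threshold_nm: float = 0.6,
    min_frames: int = 2,
    refine: bool = True,
) -> pd.DataFrame:
    """Segment, fit and summarize trajectories per group.

    Censored phases are excluded from the exponential fits. Returns one
    row per group with rates (nm/min), mean times (s), mean step size (nm),
    the open/close rate constants and the equilibrium constant K_d.
    """
    trajs = list(trajs)
    if not trajs:
        raise ValidationError("no trajectories supplied")
    if grouping not in _GROUPINGS:
        raise ValidationError(f"grouping must be one of {sorted(_GROUPINGS)}")

    rows = []
    groups: dict[str, list[EndTrajectory]] = {}
    for tr in trajs:
        groups.setdefault(getattr(tr, grouping), []).append(tr)
    for name in sorted(groups):
        members = groups[name]
        dwells, steps, sizes, rates = [], [], [], []
        for tr in members:
            ev = detect_phases(tr, threshold_nm, min_frames=min_frames, refine=refine)
            dwells.append(ev.dwell_durations())
            steps.append(ev.step_durations())
            sizes.append(ev.step_sizes())
            try:
                rates.append(apparent_elongation_rate(ev))
            except UndefinedRateError:
                pass
        dwells = np.concatenate(dwells) if dwells else np.array([])
        steps = np.concatenate(steps) if steps else np.array([])
        sizes = np.concatenate(sizes) if sizes else np.array([])
        if dwells.size < 2 or steps.size < 2:
            raise ValidationError(f"group {name!r} has too few uncensored phases")
        tau_dwell = fit_exponential(dwells).tau
        tau_step = fit_exponential(steps).tau
        mean_size = float(np.mean(sizes))
        per_step = sizes / steps * 60.0
        rates = np.asarray(rates)
        rows.append(
            EndKinetics(
                group=name,
                n_ends=len(members),
                apparent_rate=float(np.mean(rates)),
                apparent_rate_se=(
                    float(np.std(rates, ddof=1) / np.sqrt(rates.size)) if rates.size > 1 else 0.0
                ),
                step_rate_mean=float(np.mean(per_step)),
                step_rate_se=(
                    float(np.std(per_step, ddof=1) / np.sqrt(per_step.size))
                    if per_step.size > 1
                    else 0.0
                ),
                tau_dwell=tau_dwell,
                tau_step=tau_step,
                mean_step_size=mean_size,
                k_open=1.0 / tau_dwell,
                k_close=1.0 / tau_step,
                K_d=equilibrium_constant(tau_dwell, tau_step),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("group")


# ---------------------------------------------------------------------------
# missed-event (dead-time) correction
#
# At frame interval dt, a pause shorter than one frame can never produce a
# frame-to-frame displacement below threshold, so adjacent growth phases
# merge; symmetric arguments give a linear detection window on [dt, 2*dt].
# The estimators below invert the first-moment equations of that
# observation model; they are standard single-molecule missed-event
# corrections specialized to this segmentation.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticsEstimate:
    """Dead-time-corrected kinetic parameters of the two-state process."""

    tau_dwell: float
    tau_step: float
    mean_step_size: float
    n_dwells: int
    n_steps: int
    details: dict = field(default_factory=dict)

    @property
    def K_d(self) -> float:
        return equilibrium_constant(self.tau_dwell, self.tau_step)


def pooled_interior_phases(events_list) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Pool uncensored phase durations/sizes across trajectories.

    Returns (dwell durations, step durations, step sizes, total interior
    time). The interior time is the exact sum of uncensored phase
    durations, which telescopes to the measured span and is therefore free
    of per-boundary measurement error.
    """
    dwells, steps, sizes = [], [], []
    total = 0.0
    for ev in events_list:
        for i, p in enumerate(ev.phases):
            if ev.is_censored(i):
                continue
            total += p.duration
            if p.kind == "dwell":
                dwells.append(p.duration)
            else:
                steps.append(p.duration)
                sizes.append(p.delta)
    return np.array(dwells), np.array(steps), np.array(sizes), total


def _window_quants(tau: float, dt: float):
    """Moments of the linear dwell-detection window w(d)=clip((d-dt)/dt,0,1)."""
    e1 = math.exp(-dt / tau)
    p_detect = (tau / dt) * e1 * (1.0 - e1)
    mean_detected = (2.0 * tau + dt - 2.0 * e1 * (dt + tau)) / (1.0 - e1)
    mu_missed = (tau - p_detect * mean_detected) / (1.0 - p_detect)
    return p_detect, mean_detected, mu_missed


_FFT_N = 1 << 15
_FFT_DX = 0.25


def _observed_dwell_tail_mean(
    tau_dwell: float, tau_step: float, p_strong: float, dt: float, t_cut: float, j_max: int = 4
) -> float:
    """Model tail mean (above ``t_cut``) of observed dwell durations.

    An observed dwell is a chain of detected dwells joined by weak
    (sub-threshold) steps; the chain density is built by FFT convolution
    of the window-weighted dwell density with the step-duration density.
    """
    x = np.arange(_FFT_N) * _FFT_DX
    f_d = np.exp(-x / tau_dwell) / tau_dwell
    w = np.clip((x - dt) / dt, 0.0, 1.0)
    g1 = w * f_d
    g1 /= g1.sum() * _FFT_DX
    f_s = np.exp(-x / tau_step) / tau_step
    fs_hat = np.fft.rfft(f_s) * _FFT_DX
    g1_hat = np.fft.rfft(g1) * _FFT_DX
    mix = np.zeros(_FFT_N)
    for j in range(j_max + 1):
        gj = np.fft.irfft(g1_hat * (fs_hat * g1_hat) ** j, _FFT_N) / _FFT_DX
        mix += p_strong * (1.0 - p_strong) ** j * gj
    mask = x > t_cut
    return float(np.sum(x[mask] * mix[mask]) / np.sum(mix[mask]) - t_cut)


def _pair_low_table(threshold: float, sigma: float, n: int = 120):
    """P(two adjacent frame displacements both fall below c) vs c.

    Adjacent frame-to-frame noise differences share one sample, so they
    are bivariate normal with correlation -1/2.
    """
    from scipy.stats import multivariate_normal

    sd = sigma * math.sqrt(2.0)
    cov = [[sd**2, -0.5 * sd**2], [-0.5 * sd**2, sd**2]]
    cs = np.linspace(threshold - 12.0 * sd, threshold, n)
    ps = np.array([multivariate_normal.cdf([c, c], mean=[0.0, 0.0], cov=cov) for c in cs])
    return cs, ps


def _split_probability(
    tau_step: float,
    mean_step_size: float,
    dt: float,
    threshold: float,
    sigma: float,
    rng: np.random.Generator,
    table,
    n_mc: int = 6000,
) -> float:
    """Forward-model probability that noise splits a true step in two.

    A split needs two consecutive within-ramp intervals whose observed
    rise falls below threshold; slow shallow ramps dominate.
    """
    if sigma <= 0:
        return 0.0
    t = rng.exponential(tau_step, n_mc)
    s = rng.exponential(mean_step_size, n_mc)
    n_interior = np.floor(t / dt).astype(int) - 1
    c = threshold - (s / t) * dt
    cs, ps = table
    p2 = np.interp(c, cs, ps, left=0.0, right=float(ps[-1]))
    ok = n_interior >= 2
    out = np.zeros(n_mc)
    out[ok] = 1.0 - (1.0 - p2[ok]) ** (n_interior[ok] - 1)
    return float(out.mean())


def correct_missed_events(
    dwell_durations,
    step_durations,
    step_sizes,
    total_time: float,
    frame_interval: float = 12.75,
    threshold_nm: float = 0.6,
    noise_sigma: float = 0.3,
    min_step_delta: float | None = None,
    n_iter: int = 10,
    seed: int = 0,
) -> KineticsEstimate:
    """Invert the observation model for the underlying kinetic parameters.

    Combines (i) a chain-aware tail fit of the dwell durations, immune to
    sub-frame boundary errors, (ii) the detection-window chain multiplicity
    for step merging, (iii) a forward-model noise-split rate, and (iv) the
    exact time-budget identity, iterated to a fixed point.

    ``total_time`` must be the summed duration of the pooled uncensored
    phases (see `pooled_interior_phases`). ``min_step_delta`` defaults to
    the hysteresis level ``2 * threshold_nm``.
    """
    dw = np.asarray(dwell_durations, dtype=float)
    st = np.asarray(step_durations, dtype=float)
    sz = np.asarray(step_sizes, dtype=float)
    if dw.size < 10 or st.size < 10:
        raise ValidationError("need at least 10 dwell and 10 step phases")
    dt = frame_interval
    b = 2.0 * threshold_nm if min_step_delta is None else min_step_delta
    t_cut = 2.0 * dt
    tail = dw[dw > t_cut]
    if tail.size < 5:
        raise ValidationError("too few dwell durations above the dead-time window")
    tail_obs = float(tail.mean() - t_cut)
    table = _pair_low_table(threshold_nm, noise_sigma) if noise_sigma > 0 else None
    rng = np.random.default_rng(seed)

    tau_d, tau_s, msz = tail_obs, float(st.mean()), float(sz.mean())
    n_s = sz.size
    for _ in range(n_iter):
        p_strong = math.exp(-b / msz)
        lo, hi = dt / 4.0, 100.0 * dt
        for _ in range(36):
            mid = 0.5 * (lo + hi)
            if _observed_dwell_tail_mean(mid, tau_s, p_strong, dt, t_cut) < tail_obs:
                lo = mid
            else:
                hi = mid
        tau_d = 0.5 * (lo + hi)
        p_detect = _window_quants(tau_d, dt)[0]
        chain_len = 1.0 / p_detect
        p_split = (
            _split_probability(tau_s, msz, dt, threshold_nm, noise_sigma, rng, table)
            if table is not None
            else 0.0
        )
        n_chains = n_s / (1.0 + chain_len * p_split)
        n_true = n_chains * chain_len
        msz = max(float(sz.mean()) * n_s / n_true, 1e-9)
        tau_s = max(total_time / n_true - tau_d, 1e-9)
    return KineticsEstimate(
        tau_dwell=float(tau_d),
        tau_step=float(tau_s),
        mean_step_size=float(msz),
        n_dwells=int(dw.size),
        n_steps=int(n_s),
        details={
            "p_detect_dwell": p_detect,
            "chain_multiplicity": chain_len,
            "split_probability": p_split,
            "implied_true_steps": n_true,
        },
    )


def recalibrate_kinetics(
    estimate: KineticsEstimate,
    duration: float,
    frame_interval: float = 12.75,
    noise_sigma: float = 0.3,
    threshold_nm: float = 0.6,
    min_frames: int = 1,
    n_sim: int = 150,
    rounds: int = 1,
    seed: int = 0,
) -> KineticsEstimate:
    """Remove residual estimator bias by parametric-bootstrap recalibration.

    Simulates the full generate-detect-correct pipeline at the current
    estimate, compares the re-estimated parameters with the input ones,
    and rescales (indirect inference). One round removes the first-order
    systematic bias at the cost of Monte Carlo noise of order
    ``1/sqrt(n_sim * phases)``.
    """
    from .synthetic import TrajectoryParams, gen_end_trajectory

    target = np.array([estimate.tau_dwell, estimate.tau_step, estimate.mean_step_size])
    theta = target.copy()
    ss = np.random.SeedSequence(seed)
    for _ in range(rounds):
        events = []
        for child in ss.spawn(n_sim):
            params = TrajectoryParams(
                tau_dwell=theta[0],
                tau_step=theta[1],
                mean_step_size=theta[2],
                frame_interval=frame_interval,
                duration=duration,
                noise_sigma=noise_sigma,
                seed=int(child.generate_state(1)[0]),
            )
            sim = gen_end_trajectory(params)
            events.append(
                detect_phases(
                    sim.trajectory,
                    threshold_nm,
                    min_frames=min_frames,
                    min_dwell_s=frame_interval,
                )
            )
        dw, st, sz, total = pooled_interior_phases(events)
        sim_est = correct_missed_events(
            dw, st, sz, total,
            frame_interval=frame_interval,
            threshold_nm=threshold_nm,
            noise_sigma=noise_sigma,
            seed=int(ss.generate_state(1)[0]),
        )
        sim_vec = np.array([sim_est.tau_dwell, sim_est.tau_step, sim_est.mean_step_size])
        theta = theta * target / sim_vec
    return KineticsEstimate(
        tau_dwell=float(theta[0]),
        tau_step=float(theta[1]),
        mean_step_size=float(theta[2]),
        n_dwells=estimate.n_dwells,
        n_steps=estimate.n_steps,
        details={**estimate.details, "recalibration_rounds": rounds, "n_sim": n_sim},
    )
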