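"""Saturating two-step ("dock-lock") bulk elongation model.

The aggregate mass M(t) obeys

    dM/dt = kappa * m / (1 + m / K_M),        m = m_total - M,

where ``kappa`` is the combined rate (elongation rate constant times the
constant number of open ends, times two for bidirectional growth) and
``K_M`` is the Michaelis constant of elongation. Mass conservation closes
the system. The module integrates the ODE, simulates interface-switch and
seeding scenarios, and fits the model to fluorescence curves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp

from .errors import FitFailureError, ValidationError

__all__ = [
    "DockLockModel",
    "ThTCurve",
    "Scenario",
    "DockLockFitResult",
    "integrate_dock_lock",
    "simulate_interface_switch",
    "fit_dock_lock",
]


@dataclass(frozen=True)
class DockLockModel:
    """Model parameters; ``kappa`` is identifiable only as a product.

    The elongation rate constant and the number of open ends cannot be
    separated from a single curve, so the model carries their product.
    ``alpha``/``beta`` map mass to fluorescence affinely.
    """

    kappa: float
    K_M: float
    m_total: float
    M0: float = 0.0
    alpha: float = 1.0
    beta: float = 0.0

    def __post_init__(self):
        if self.kappa < 0:
            raise ValidationError("kappa must be >= 0")
        if not self.K_M > 0:
            raise ValidationError("K_M must be positive")
        if not self.m_total > 0:
            raise ValidationError("m_total must be positive")
        if not 0 <= self.M0 <= self.m_total:
            raise ValidationError("M0 must lie in [0, m_total]")
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")


@dataclass(frozen=True)
class ThTCurve:
    """Time-fluorescence record with its interface/seed provenance."""

    times: np.ndarray
    fluorescence: np.ndarray
    interface_on_at: float | None = 0.0
    seeded: bool = False

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fluorescence", f)
        if t.size != f.size or t.ndim != 1:
            raise ValidationError("times and fluorescence must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise ValidationError("fluorescence must be finite")


@dataclass(frozen=True)
class Scenario:
    """Interface schedule: ``interface_on_at=None`` means never introduced."""

    interface_on_at: float | None = 0.0


def _rate(kappa: float, K_M: float, m_total: float):
    def f(_t, M):
        m = m_total - M
        return kappa * m / (1.0 + m / K_M)

    return f


def integrate_dock_lock(model: DockLockModel, times, rtol: float = 1e-8) -> np.ndarray:
    """Integrate the elongation ODE on the given time grid.

    Uses adaptive Runge-Kutta (RK45). The returned mass series is
    nondecreasing and bounded by ``m_total``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0):
        raise ValidationError("times must be a strictly increasing 1-D grid")
    if model.kappa == 0 or times.size == 1:
        return np.full(times.size, model.M0)
    sol = solve_ivp(
        _rate(model.kappa, model.K_M, model.m_total),
        (times[0], times[-1]),
        [model.M0],
        t_eval=times,
        method="RK45",
        rtol=rtol,
        atol=model.m_total * 1e-12,
    )
    if not sol.success:
        raise FitFailureError(f"integration failed: {sol.message}")
    mass = np.minimum(sol.y[0], model.m_total)
    # clamp integrator wiggle (~rtol) so the monotonicity invariant is exact
    return np.maximum.accumulate(mass)


def simulate_interface_switch(
    model: DockLockModel, t_switch: float | None, times, rtol: float = 1e-8
) -> np.ndarray:
    """Mass series with the interface introduced at ``t_switch``.

    Before ``t_switch`` there are no interface-generated open ends, so
    growth only occurs if seed material is present (``M0 > 0``); after the
    switch the configured ``kappa`` applies. ``t_switch=None`` (or a value
    beyond the grid) means the interface is never introduced. M is
    continuous at the switch.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0):
        raise ValidationError("times must be a strictly increasing 1-D grid")
    never = t_switch is None or t_switch >= times[-1]
    if t_switch is not None and not never and t_switch < times[0]:
        t_switch = float(times[0])
    pre_model = model if model.M0 > 0 else replace(model, kappa=0.0)
    if never:
        return integrate_dock_lock(pre_model, times, rtol=rtol)
    if t_switch <= times[0]:
        return integrate_dock_lock(model, times, rtol=rtol)
    before = times[times <= t_switch]
    after = times[times > t_switch]
    grid_pre = before if before[-1] == t_switch else np.append(before, t_switch)
    mass_pre = integrate_dock_lock(pre_model, grid_pre, rtol=rtol)
    m_switch = float(mass_pre[-1])
    grid_post = np.concatenate([[t_switch], after])
    post_model = replace(model, M0=m_switch)
    mass_post = integrate_dock_lock(post_model, grid_post, rtol=rtol)
    return np.concatenate([mass_pre[: before.size], mass_post[1:]])


@dataclass(frozen=True)
class DockLockFitResult:
    model: DockLockModel
    rss: float
    residuals: np.ndarray
    ci95: dict[str, tuple[float, float]] | None = None


def fit_dock_lock(
    curve: ThTCurve,
    init: DockLockModel,
    fit_m_total: bool = False,
    n_bootstrap: int = 0,
    seed: int | None = None,
    rtol: float = 1e-8,
) -> DockLockFitResult:
    """Nonlinear least-squares fit of the model to a fluorescence curve.

    Fits (kappa, K_M, alpha, beta), optionally co-fitting ``m_total``.
    Confidence intervals, when requested, are percentile bootstrap over
    residuals with ``n_bootstrap`` replicates.
    """
    t = curve.times
    f = curve.fluorescence
    if t.size < 10:
        raise ValidationError("need at least 10 time points to fit")

    names = ["kappa", "K_M", "alpha", "beta"] + (["m_total"] if fit_m_total else [])

    def predict(params: np.ndarray) -> np.ndarray:
        kappa, K_M, alpha, beta = params[:4]
        m_total = params[4] if fit_m_total else init.m_total
        model = DockLockModel(
            kappa=max(kappa, 0.0),
            K_M=max(K_M, 1e-12),
            m_total=max(m_total, 1e-12),
            M0=min(init.M0, max(m_total, 1e-12)),
            alpha=max(alpha, 0.0),
            beta=beta,
        )
        return model.alpha * integrate_dock_lock(model, t, rtol=rtol) + model.beta

    def residual(params: np.ndarray, target: np.ndarray) -> np.ndarray:
        return predict(params) - target

    p0 = [init.kappa, init.K_M, init.alpha, init.beta] + ([init.m_total] if fit_m_total else [])
    lower = [0.0, 1e-12, 0.0, -np.inf] + ([1e-12] if fit_m_total else [])
    upper = [np.inf] * len(p0)
    res = optimize.least_squares(
        residual, p0, args=(f,), bounds=(lower, upper), xtol=1e-12, ftol=1e-12
    )
    if not res.success:
        raise FitFailureError(
            "dock-lock fit did not converge",
            diagnostics={"message": res.message, "x": res.x.tolist()},
        )
    best = res.x
    fitted = DockLockModel(
        kappa=float(best[0]),
        K_M=float(best[1]),
        m_total=float(best[4]) if fit_m_total else init.m_total,
        M0=init.M0,
        alpha=float(best[2]),
        beta=float(best[3]),
    )
    residuals = res.fun
    rss = float(np.sum(residuals**2))

    ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        fit_curve = f - residuals
        samples = {name: [] for name in names}
        for _ in range(n_bootstrap):
            boot = fit_curve + rng.choice(residuals, size=residuals.size, replace=True)
            try:
                bres = optimize.least_squares(
                    residual, best, args=(boot,), bounds=(lower, upper)
                )
            except Exception:  # pragma: no cover - rare numeric failure
                continue
            for name, val in zip(names, bres.x):
                samples[name].append(float(val))
        ci = {
            name: (
                float(np.percentile(vals, 2.5)),
                float(np.percentile(vals, 97.5)),
            )
            for name, vals in samples.items()
            if vals
        }
    return DockLockFitResult(model=fitted, rss=rss, residuals=residuals, ci95=ci)
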