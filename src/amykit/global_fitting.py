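"""Global fitting of dose-series aggregation kinetics and AICc model selection.

A dose series holds replicate normalized ThT curves at several inhibitor (or
monomer) concentrations.  Mechanism-of-inhibition analysis fits all curves
simultaneously under perturbation scenarios in which exactly one microscopic
process — primary nucleation, secondary nucleation, or elongation — is
allowed to vary with inhibitor concentration while the others are shared
globally.  Scenarios are ranked by the small-sample corrected Akaike
information criterion (AICc).

Normalized fibril-mass curves constrain only the macroscopic rates λ and κ
(products of the normalized process rates), so fits are parameterized at the
(λ, κ) level:

* ``primary_only``    — λ free per condition, κ shared,
* ``secondary_only``  — κ free per condition, λ shared,
* ``elongation_only`` — κ free per condition, λ/κ ratio shared (elongation
  scales λ and κ together, both as the square root of ν₊),
* ``none_vary``       — one shared (λ, κ).

Every scenario for an n-condition series then has n + 1 free parameters and
a well-conditioned Jacobian.  Reported normalized rates pin ν₊ = 1 h⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .kinetic_models import (
    KineticCurve,
    MacroscopicRates,
    half_time,
    oosawa_curve,
    rg_curve,
)

__all__ = [
    "Condition",
    "DoseSeries",
    "Scenario",
    "SCENARIOS",
    "ScenarioFit",
    "MacroscopicDoseResponse",
    "aicc",
    "fit_scenario",
    "compare_scenarios",
    "extract_macroscopic",
    "fit_monomer_series",
    "FitError",
]

LOG_BOUNDS = (-6.0, 4.0)  # log10 bounds on rates in 1/h
DEFAULT_THETA = 0.323
MAX_POINTS_PER_WELL = 300


class FitError(RuntimeError):
    """Raised when a global fit fails to converge within the start budget."""


@dataclass
class Condition:
    """Replicate curves at one concentration (inhibitor or monomer)."""

    label: str
    concentration: float
    m0: float
    times: np.ndarray
    curves: np.ndarray  # shape (n_replicates, n_times)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        if self.curves.shape[1] != self.times.size:
            raise ValueError(
                f"condition {self.label!r}: curves have {self.curves.shape[1]} "
                f"columns but the time grid has {self.times.size} points"
            )


@dataclass
class DoseSeries:
    """An ordered set of conditions sharing experiment metadata."""

    conditions: List[Condition]
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.conditions) < 1:
            raise ValueError("a dose series needs at least one condition")


@dataclass(frozen=True)
class Scenario:
    """A perturbation hypothesis: which process varies with concentration."""

    name: str
    free_process: Optional[str]  # 'nu_n' | 'nu_2' | 'nu_plus' | None
    theta: float = DEFAULT_THETA


SCENARIOS: Dict[str, Scenario] = {
    "primary_only": Scenario("primary_only", "nu_n"),
    "secondary_only": Scenario("secondary_only", "nu_2"),
    "elongation_only": Scenario("elongation_only", "nu_plus"),
    "none_vary": Scenario("none_vary", None),
}


@dataclass
class ScenarioFit:
    """Result of one global scenario fit."""

    scenario: str
    params: Dict[str, float]
    stderr: Dict[str, float]
    rss: float
    n_obs: int
    k_params: int
    aicc: float
    r2: float
    delta_aicc: float = 0.0
    at_bounds: List[str] = field(default_factory=list)
    n_starts_used: int = 1
    success: bool = True
    message: str = ""

    #: per-condition macroscopic rates implied by the fit
    lam: Dict[str, float] = field(default_factory=dict)
    kappa: Dict[str, float] = field(default_factory=dict)


@dataclass
class MacroscopicDoseResponse:
    """Per-condition λ and κ with asymptotic fitting errors."""

    labels: List[str]
    concentrations: np.ndarray
    lam: np.ndarray
    lam_err: np.ndarray
    kappa: np.ndarray
    kappa_err: np.ndarray


def aicc(rss: float, n_obs: int, k_params: int) -> float:
    """Corrected Akaike criterion under the least-squares Gaussian likelihood.

    AICc = n·ln(rss/n) + 2k + 2k(k+1)/(n−k−1).
    """
    if n_obs <= k_params + 1:
        raise ValueError(
            f"AICc undefined: n_obs={n_obs} must exceed k_params+1={k_params + 1}"
        )
    if rss <= 0:
        rss = np.finfo(float).tiny
    n, k = n_obs, k_params
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _downsample(times: np.ndarray, curves: np.ndarray, max_points: int):
    if max_points and times.size > max_points:
        idx = np.unique(np.linspace(0, times.size - 1, max_points).round().astype(int))
        return times[idx], curves[:, idx]
    return times, curves


def _stack_series(series: DoseSeries, max_points: int):
    """Per-condition (times, curves) after optional down-sampling."""
    return [
        _downsample(c.times, c.curves, max_points) for c in series.conditions
    ]


def _heuristic_rates(times: np.ndarray, curves: np.ndarray, theta: float) -> Tuple[float, float]:
    """Rough (λ, κ) from the pooled mean curve's half-time and rise width."""
    mean = curves.mean(axis=0)
    curve = KineticCurve(times, mean)
    t50 = half_time(curve)
    if t50 is None or t50 <= 0:
        t50 = max(times[-1] / 2.0, 1e-3)
    plateau = np.mean(mean[-max(1, mean.size // 10):])
    lo = np.searchsorted(mean >= 0.1 * plateau, True)
    hi = np.searchsorted(mean >= 0.9 * plateau, True)
    hi = min(hi, times.size - 1)
    width = max(times[hi] - times[lo], times[1] - times[0] if times.size > 1 else 0.1)
    kappa0 = 4.0 / width
    # invert the large-κt half-time relation for λ
    arg = 2.0 * theta * (2.0 ** (1.0 / theta) - 1.0) * kappa0 ** 2
    lam0 = math.sqrt(arg * math.exp(-kappa0 * t50))
    lam0 = min(max(lam0, 10.0 ** LOG_BOUNDS[0]), 10.0 ** LOG_BOUNDS[1])
    kappa0 = min(max(kappa0, 10.0 ** LOG_BOUNDS[0]), 10.0 ** LOG_BOUNDS[1])
    return lam0, kappa0


def _scenario_rates(theta: float):
    """Map a log10-parameter vector to per-condition (λ, κ) for a scenario."""

    def build(scenario: Scenario, n_cond: int):
        if scenario.free_process == "nu_n":
            names = [f"log_lam_{i}" for i in range(n_cond)] + ["log_kap"]

            def rates(x):
                lam = 10.0 ** x[:n_cond]
                kap = np.full(n_cond, 10.0 ** x[n_cond])
                return lam, kap

        elif scenario.free_process == "nu_2":
            names = [f"log_kap_{i}" for i in range(n_cond)] + ["log_lam"]

            def rates(x):
                kap = 10.0 ** x[:n_cond]
                lam = np.full(n_cond, 10.0 ** x[n_cond])
                return lam, kap

        elif scenario.free_process == "nu_plus":
            # elongation scales λ and κ together: λ_c = r·κ_c with shared r
            names = [f"log_kap_{i}" for i in range(n_cond)] + ["log_ratio"]

            def rates(x):
                kap = 10.0 ** x[:n_cond]
                lam = kap * 10.0 ** x[n_cond]
                return lam, kap

        elif scenario.free_process is None:
            names = ["log_lam", "log_kap"]

            def rates(x):
                lam = np.full(n_cond, 10.0 ** x[0])
                kap = np.full(n_cond, 10.0 ** x[1])
                return lam, kap

        else:
            raise ValueError(f"unknown free process {scenario.free_process!r}")
        return names, rates

    return build


def _residuals_factory(stacked, rates_fn, theta: float):
    def residuals(x):
        lam, kap = rates_fn(x)
        out = []
        for i, (t, curves) in enumerate(stacked):
            model = rg_curve(MacroscopicRates(lam[i], kap[i], theta), t).fraction_fibrillar
            out.append((curves - model[None, :]).ravel())
        return np.concatenate(out)

    return residuals


def _multistart(
    residuals,
    x0: np.ndarray,
    bounds: Tuple[np.ndarray, np.ndarray],
    n_starts: int,
    seed: int,
    stall: int = 3,
    min_starts: int = 4,
):
    """Deterministic multi-start least squares over log-parameter space.

    The heuristic start runs first, then Latin-hypercube starts; the loop
    stops early once the best RSS has not improved by >0.1% for ``stall``
    consecutive starts (after at least ``min_starts``).
    """
    lo, hi = bounds
    starts = [np.clip(x0, lo, hi)]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=x0.size, seed=seed)
        unit = sampler.random(n_starts - 1)
        starts.extend(lo + unit * (hi - lo))
    best = None
    best_rss = np.inf
    since_improved = 0
    used = 0
    for x_start in starts:
        used += 1
        sol = least_squares(residuals, x_start, bounds=(lo, hi), method="trf")
        rss = float(2.0 * sol.cost)
        if rss < best_rss * (1.0 - 1e-3):
            best, best_rss = sol, rss
            since_improved = 0
        else:
            since_improved += 1
            if best is None or rss < best_rss:
                best, best_rss = sol, rss
        if used >= min_starts and since_improved >= stall:
            break
    return best, used


def _stderr_from_jac(sol, n_obs: int) -> np.ndarray:
    """Asymptotic standard errors of the log10 parameters."""
    J = sol.jac
    k = J.shape[1]
    dof = max(n_obs - k, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.pinv(J.T @ J) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(k, np.nan)


def _finish_fit(
    scenario_name: str,
    names: Sequence[str],
    sol,
    rates_fn,
    stacked,
    labels: Sequence[str],
    n_starts_used: int,
) -> ScenarioFit:
    n_obs = sum(c.size for _, c in stacked)
    k = len(names)
    rss = float(2.0 * sol.cost)
    y = np.concatenate([c.ravel() for _, c in stacked])
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    log_err = _stderr_from_jac(sol, n_obs)
    params = {}
    stderr = {}
    at_bounds = []
    for name, val, err in zip(names, sol.x, log_err):
        lin = 10.0 ** val
        params[name.replace("log_", "")] = lin
        stderr[name.replace("log_", "")] = lin * math.log(10.0) * err
        if min(val - LOG_BOUNDS[0], LOG_BOUNDS[1] - val) < 1e-6:
            at_bounds.append(name)
    lam, kap = rates_fn(sol.x)
    return ScenarioFit(
        scenario=scenario_name,
        params=params,
        stderr=stderr,
        rss=rss,
        n_obs=n_obs,
        k_params=k,
        aicc=aicc(rss, n_obs, k),
        r2=r2,
        at_bounds=at_bounds,
        n_starts_used=n_starts_used,
        success=sol.success,
        message=str(sol.message),
        lam={lab: float(l) for lab, l in zip(labels, lam)},
        kappa={lab: float(kv) for lab, kv in zip(labels, kap)},
    )


def fit_scenario(
    series: DoseSeries,
    scenario: Scenario,
    theta: Optional[float] = None,
    n_starts: int = 16,
    seed: int = 0,
    max_points: int = MAX_POINTS_PER_WELL,
) -> ScenarioFit:
    """Globally fit a dose series under one perturbation scenario.

    θ is held fixed (default 0.323) and residuals are pooled over all
    replicates and conditions, unweighted.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    if theta is None:
        theta = scenario.theta
    if len(series.conditions) < 2 and scenario.free_process is not None:
        raise ValueError("perturbation scenarios need at least 2 conditions")
    stacked = _stack_series(series, max_points)
    labels = [c.label for c in series.conditions]
    n_cond = len(series.conditions)
    names, rates_fn = _scenario_rates(theta)(scenario, n_cond)
    residuals = _residuals_factory(stacked, rates_fn, theta)

    # heuristic start from per-condition half-times
    lam0s, kap0s = zip(*(_heuristic_rates(t, c, theta) for t, c in stacked))
    if scenario.free_process == "nu_n":
        x0 = np.log10(np.r_[lam0s, np.median(kap0s)])
    elif scenario.free_process == "nu_2":
        x0 = np.log10(np.r_[kap0s, np.median(lam0s)])
    elif scenario.free_process == "nu_plus":
        x0 = np.log10(np.r_[kap0s, np.median(np.array(lam0s) / np.array(kap0s))])
    else:
        x0 = np.log10([np.median(lam0s), np.median(kap0s)])

    lo = np.full(x0.size, LOG_BOUNDS[0])
    hi = np.full(x0.size, LOG_BOUNDS[1])
    if scenario.free_process == "nu_plus":
        lo[-1], hi[-1] = -8.0, 2.0  # λ/κ ratio spans a different range
    sol, used = _multistart(residuals, x0, (lo, hi), n_starts, seed)
    if sol is None or not np.isfinite(2.0 * sol.cost):
        raise FitError(
            f"scenario {scenario.name!r} did not converge after {used} starts"
        )
    return _finish_fit(scenario.name, names, sol, rates_fn, stacked, labels, used)


def compare_scenarios(
    series: DoseSeries,
    scenarios: Sequence = ("primary_only", "secondary_only", "elongation_only"),
    theta: float = DEFAULT_THETA,
    n_starts: int = 16,
    seed: int = 0,
    max_points: int = MAX_POINTS_PER_WELL,
) -> List[ScenarioFit]:
    """Fit several scenarios and rank them by AICc (ascending).

    Individual fit failures are reported in-place (success=False) and the
    ranking proceeds on the successes.
    """
    if len(scenarios) < 1:
        raise ValueError("need at least one scenario")
    fits: List[ScenarioFit] = []
    for sc in scenarios:
        name = sc if isinstance(sc, str) else sc.name
        try:
            fits.append(
                fit_scenario(series, sc, theta=theta, n_starts=n_starts, seed=seed,
                             max_points=max_points)
            )
        except (FitError, ValueError) as exc:
            fits.append(
                ScenarioFit(
                    scenario=name, params={}, stderr={}, rss=np.inf, n_obs=0,
                    k_params=0, aicc=np.inf, r2=-np.inf, success=False,
                    message=str(exc),
                )
            )
    fits.sort(key=lambda f: f.aicc)
    best = fits[0].aicc
    for f in fits:
        f.delta_aicc = f.aicc - best if np.isfinite(f.aicc) else np.inf
    return fits


def extract_macroscopic(
    series: DoseSeries,
    theta: float = DEFAULT_THETA,
    n_starts: int = 8,
    seed: int = 0,
    max_points: int = MAX_POINTS_PER_WELL,
) -> MacroscopicDoseResponse:
    """Fit (λ, κ) independently per condition, with asymptotic errors."""
    labels, concs, lams, lam_errs, kaps, kap_errs = [], [], [], [], [], []
    for cond in series.conditions:
        sub = DoseSeries([cond], metadata=series.metadata)
        fit = fit_scenario(
            sub, SCENARIOS["none_vary"], theta=theta, n_starts=n_starts,
            seed=seed, max_points=max_points,
        )
        labels.append(cond.label)
        concs.append(cond.concentration)
        lams.append(fit.params["lam"])
        lam_errs.append(fit.stderr["lam"])
        kaps.append(fit.params["kap"])
        kap_errs.append(fit.stderr["kap"])
    return MacroscopicDoseResponse(
        labels=labels,
        concentrations=np.asarray(concs, dtype=float),
        lam=np.asarray(lams),
        lam_err=np.asarray(lam_errs),
        kappa=np.asarray(kaps),
        kappa_err=np.asarray(kap_errs),
    )


# --- monomer-dependence model comparison -----------------------------------

_MONOMER_MODELS = ("oosawa", "fragmentation", "secondary_single", "secondary_multistep")


def _monomer_model_factory(model: str, m0s: np.ndarray, nc: float, n2: float):
    """Parameter names and per-condition curve builder for one mechanism.

    Microscopic constants are shared across monomer concentrations; only
    identifiable products are fitted: A = 2·k₊·kₙ (λ_c² = A·m0^nc),
    B = 2·k₊·k₂ (κ_c² = B·m0^(n2+1), saturating for multistep) and
    C = 2·k₊·k_f (κ_c² = C·m0).  θ is free for the secondary models.
    """
    if model == "oosawa":
        names = ["log_A"]

        def curves(x, times_list):
            lam = np.sqrt(10.0 ** x[0] * m0s ** nc)
            return [
                oosawa_curve(MacroscopicRates(lam[i], 0.0), nc, t).fraction_fibrillar
                for i, t in enumerate(times_list)
            ]

    elif model == "fragmentation":
        names = ["log_A", "log_C", "theta"]

        def curves(x, times_list):
            lam = np.sqrt(10.0 ** x[0] * m0s ** nc)
            kap = np.sqrt(10.0 ** x[1] * m0s)
            return [
                rg_curve(MacroscopicRates(lam[i], kap[i], x[2]), t).fraction_fibrillar
                for i, t in enumerate(times_list)
            ]

    elif model == "secondary_single":
        names = ["log_A", "log_B", "theta"]

        def curves(x, times_list):
            lam = np.sqrt(10.0 ** x[0] * m0s ** nc)
            kap = np.sqrt(10.0 ** x[1] * m0s ** (n2 + 1.0))
            return [
                rg_curve(MacroscopicRates(lam[i], kap[i], x[2]), t).fraction_fibrillar
                for i, t in enumerate(times_list)
            ]

    elif model == "secondary_multistep":
        names = ["log_A", "log_B", "log_K2", "theta"]

        def curves(x, times_list):
            lam = np.sqrt(10.0 ** x[0] * m0s ** nc)
            sat = 1.0 + (m0s / 10.0 ** x[2]) ** n2
            kap = np.sqrt(10.0 ** x[1] * m0s ** (n2 + 1.0) / sat)
            return [
                rg_curve(MacroscopicRates(lam[i], kap[i], x[3]), t).fraction_fibrillar
                for i, t in enumerate(times_list)
            ]

    else:
        raise ValueError(f"unknown mechanism {model!r}")
    return names, curves


def fit_monomer_series(
    series: DoseSeries,
    models: Sequence[str] = _MONOMER_MODELS,
    nc: float = 2.0,
    n2: float = 2.0,
    n_starts: int = 16,
    seed: int = 0,
    max_points: int = MAX_POINTS_PER_WELL,
) -> List[ScenarioFit]:
    """Globally fit an uninhibited monomer dilution series under each
    candidate mechanism and rank the mechanisms by AICc."""
    stacked = _stack_series(series, max_points)
    labels = [c.label for c in series.conditions]
    m0s = np.array([c.m0 for c in series.conditions], dtype=float)
    times_list = [t for t, _ in stacked]
    fits: List[ScenarioFit] = []
    for model in models:
        names, curve_fn = _monomer_model_factory(model, m0s, nc, n2)

        def residuals(x):
            model_curves = curve_fn(x, times_list)
            return np.concatenate(
                [(c - mc[None, :]).ravel() for (_, c), mc in zip(stacked, model_curves)]
            )

        lam0, kap0 = _heuristic_rates(*stacked[0], DEFAULT_THETA)
        m0_ref = m0s[0]
        x0 = [math.log10(max(lam0 ** 2 / m0_ref ** nc, 1e-12))]
        lo = [LOG_BOUNDS[0] * 2]
        hi = [LOG_BOUNDS[1]]
        if model != "oosawa":
            if model == "fragmentation":
                x0.append(math.log10(max(kap0 ** 2 / m0_ref, 1e-12)))
            else:
                x0.append(math.log10(max(kap0 ** 2 / m0_ref ** (n2 + 1.0), 1e-12)))
            lo.append(LOG_BOUNDS[0] * 2)
            hi.append(LOG_BOUNDS[1])
        if model == "secondary_multistep":
            x0.append(math.log10(np.median(m0s)))
            lo.append(-3.0)
            hi.append(5.0)
        if model != "oosawa":
            x0.append(DEFAULT_THETA)
            lo.append(0.05)
            hi.append(3.0)
        sol, used = _multistart(
            residuals, np.asarray(x0, dtype=float),
            (np.asarray(lo), np.asarray(hi)), n_starts, seed,
        )
        if sol is None:
            fits.append(
                ScenarioFit(scenario=model, params={}, stderr={}, rss=np.inf,
                            n_obs=0, k_params=0, aicc=np.inf, r2=-np.inf,
                            success=False, message="no convergence")
            )
            continue

        n_obs = sum(c.size for _, c in stacked)
        rss = float(2.0 * sol.cost)
        y = np.concatenate([c.ravel() for _, c in stacked])
        tss = float(np.sum((y - y.mean()) ** 2))
        log_err = _stderr_from_jac(sol, n_obs)
        params, stderr = {}, {}
        for name, val, err in zip(names, sol.x, log_err):
            if name.startswith("log_"):
                params[name[4:]] = 10.0 ** val
                stderr[name[4:]] = 10.0 ** val * math.log(10.0) * err
            else:
                params[name] = float(val)
                stderr[name] = float(err)
        fits.append(
            ScenarioFit(
                scenario=model, params=params, stderr=stderr, rss=rss,
                n_obs=n_obs, k_params=len(names),
                aicc=aicc(rss, n_obs, len(names)),
                r2=1.0 - rss / tss if tss > 0 else 1.0,
                n_starts_used=used, success=sol.success, message=str(sol.message),
            )
        )
    fits.sort(key=lambda f: f.aicc)
    best = fits[0].aicc
    for f in fits:
        f.delta_aicc = f.aicc - best if np.isfinite(f.aicc) else np.inf
    return fits
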