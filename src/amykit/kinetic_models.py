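"""Closed-form kinetic models of amyloid fibril mass accumulation.

The models describe nucleated polymerization of an amyloidogenic peptide
(e.g. IAPP) in terms of microscopic processes: primary nucleation of new
fibrils from free monomer (rate constant ``kn``, reaction order ``nc``),
elongation of fibril ends by monomer addition (``kplus``), and a secondary
pathway that multiplies growing ends in a fibril-dependent manner — either
fragmentation (``kf``) or secondary nucleation on the fibril surface
(``k2``, order ``n2``, optionally saturating with Michaelis constant
``K2``).

Two macroscopic rates summarize the microscopic constants:

* ``lambda = sqrt(2 * nu_plus * nu_n / m0)`` — rate of monomer-to-fibril
  conversion through the primary pathway,
* ``kappa = sqrt(2 * nu_plus * nu_2)`` (or ``sqrt(2 * nu_plus * kf)``) —
  rate of the secondary pathway,

where ``nu_n = kn * m0**nc``, ``nu_plus = kplus * m0`` and ``nu_2`` are the
normalized process rates at the initial monomer concentration ``m0``.

Units are hours and micromolar throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "MECHANISMS",
    "ConfigurationError",
    "KineticParameters",
    "NormalizedRates",
    "MacroscopicRates",
    "KineticCurve",
    "normalized_rates",
    "macroscopic_rates",
    "params_from_macroscopic",
    "theta_from_order",
    "oosawa_curve",
    "rg_curve",
    "moment_ode_oracle",
    "half_time",
]

MECHANISMS = ("oosawa", "fragmentation", "secondary_single", "secondary_multistep")

#: Both fibril ends grow, so elongation contributes 2*kplus*m*P to dM/dt.
ELONGATION_ENDS = 2.0


class ConfigurationError(ValueError):
    """A mechanism-specific rate constant is missing or invalid."""


@dataclass(frozen=True)
class KineticParameters:
    """Microscopic rate constants defining one assembly mechanism.

    Parameters
    ----------
    m0 : initial free monomer concentration (μM).
    nc : effective reaction order of primary nucleation (≥ 1).
    kn : primary nucleation rate constant (μM**(1-nc) / h).
    kplus : elongation rate constant (1 / (μM h)).
    mechanism : one of :data:`MECHANISMS`.
    kf : fragmentation rate constant (1/h), required iff mechanism is
        ``fragmentation``.
    k2 : secondary nucleation rate constant (μM**(-n2) / h), required for
        the two secondary-nucleation mechanisms.
    n2 : effective reaction order of secondary nucleation.
    K2 : effective Michaelis constant for saturating (multistep) secondary
        nucleation (μM).
    theta : dimensionless sensitivity of the secondary pathway to monomer
        depletion in the late growth phase.
    """

    m0: float
    nc: float = 2.0
    kn: float = 0.0
    kplus: float = 0.0
    mechanism: str = "secondary_single"
    kf: Optional[float] = None
    k2: Optional[float] = None
    n2: Optional[float] = None
    K2: Optional[float] = None
    theta: float = 0.323

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(
                f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}"
            )
        if not self.m0 > 0:
            raise ConfigurationError("m0 must be > 0")
        if self.nc < 1:
            raise ConfigurationError("nc must be >= 1")
        for name in ("kn", "kplus"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.theta < 0:
            raise ConfigurationError("theta must be >= 0")
        if self.mechanism == "fragmentation":
            if self.kf is None:
                raise ConfigurationError("mechanism 'fragmentation' requires kf")
            if self.kf < 0:
                raise ConfigurationError("kf must be >= 0")
        if self.mechanism in ("secondary_single", "secondary_multistep"):
            if self.k2 is None:
                raise ConfigurationError(f"mechanism {self.mechanism!r} requires k2")
            if self.n2 is None:
                raise ConfigurationError(f"mechanism {self.mechanism!r} requires n2")
            if self.k2 < 0 or self.n2 < 0:
                raise ConfigurationError("k2 and n2 must be >= 0")
        if self.mechanism == "secondary_multistep":
            if self.K2 is None:
                raise ConfigurationError("mechanism 'secondary_multistep' requires K2")
            if not self.K2 > 0:
                raise ConfigurationError("K2 must be > 0")


@dataclass(frozen=True)
class NormalizedRates:
    """Process rates evaluated at the initial monomer concentration.

    ``nu_n = kn*m0**nc`` (μM/h), ``nu_plus = kplus*m0`` (1/h) and
    ``nu_2`` (1/h) is zero for mechanisms without secondary nucleation.
    """

    nu_n: float
    nu_plus: float
    nu_2: float


@dataclass(frozen=True)
class MacroscopicRates:
    """Macroscopic primary (λ) and secondary (κ) pathway rates, in 1/h."""

    lam: float
    kappa: float
    theta: float = 0.323

    def __post_init__(self) -> None:
        if self.lam < 0 or self.kappa < 0:
            raise ValueError("lam and kappa must be >= 0")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")


@dataclass(frozen=True)
class KineticCurve:
    """A fibrillar mass-fraction time course M(t)/m0 on a fixed time grid."""

    times: np.ndarray
    fraction_fibrillar: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.fraction_fibrillar, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("times and fraction_fibrillar must be matching 1-D arrays")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fraction_fibrillar", y)


def normalized_rates(p: KineticParameters) -> NormalizedRates:
    """Evaluate the per-process rate laws at the initial monomer concentration."""
    nu_n = p.kn * p.m0 ** p.nc
    nu_plus = p.kplus * p.m0
    if p.mechanism == "secondary_single":
        nu_2 = p.k2 * p.m0 ** p.n2
    elif p.mechanism == "secondary_multistep":
        nu_2 = p.k2 * p.m0 ** p.n2 / (1.0 + (p.m0 / p.K2) ** p.n2)
    else:
        nu_2 = 0.0
    return NormalizedRates(nu_n=nu_n, nu_plus=nu_plus, nu_2=nu_2)


def macroscopic_rates(p: KineticParameters) -> MacroscopicRates:
    """Combine normalized rates into the macroscopic λ and κ.

    λ² = 2·ν₊·νₙ/m0 and κ² = 2·ν₊·ν₂ (secondary nucleation) or
    κ² = 2·ν₊·k_f (fragmentation); κ = 0 for the primary-only mechanism.
    """
    nu = normalized_rates(p)
    lam = math.sqrt(2.0 * nu.nu_plus * nu.nu_n / p.m0)
    if p.mechanism == "oosawa":
        kappa = 0.0
    elif p.mechanism == "fragmentation":
        kappa = math.sqrt(2.0 * nu.nu_plus * p.kf)
    else:
        kappa = math.sqrt(2.0 * nu.nu_plus * nu.nu_2)
    return MacroscopicRates(lam=lam, kappa=kappa, theta=p.theta)


def theta_from_order(n2: float) -> float:
    """Late-phase depletion sensitivity implied by a secondary-nucleation order.

    Matching the closed-form late-time relaxation rate θκ to the moment-ODE
    value κ·sqrt(2/(n2(n2+1))) gives θ = sqrt(2/(n2(n2+1))).
    """
    if n2 <= 0:
        raise ValueError("n2 must be > 0")
    return math.sqrt(2.0 / (n2 * (n2 + 1.0)))


def params_from_macroscopic(
    rates: MacroscopicRates,
    m0: float,
    nc: float = 2.0,
    n2: float = 2.0,
    mechanism: str = "secondary_single",
    K2: Optional[float] = None,
    nu_plus: float = 1.0,
) -> KineticParameters:
    """Construct microscopic constants that realize given macroscopic rates.

    The normalized fibril-mass curve depends on the microscopic constants
    only through λ and κ (the third degree of freedom rescales the fibril
    number), so ``nu_plus`` (= kplus·m0, 1/h) may be pinned arbitrarily.
    """
    kplus = nu_plus / m0
    kn = rates.lam ** 2 / (2.0 * nu_plus * m0 ** (nc - 1.0))
    kw = dict(m0=m0, nc=nc, kn=kn, kplus=kplus, mechanism=mechanism, theta=rates.theta)
    if mechanism == "oosawa":
        if rates.kappa != 0:
            raise ValueError("mechanism 'oosawa' requires kappa == 0")
    elif mechanism == "fragmentation":
        kw["kf"] = rates.kappa ** 2 / (2.0 * nu_plus)
    elif mechanism == "secondary_single":
        kw.update(k2=rates.kappa ** 2 / (2.0 * nu_plus * m0 ** n2), n2=n2)
    elif mechanism == "secondary_multistep":
        if K2 is None:
            raise ConfigurationError("mechanism 'secondary_multistep' requires K2")
        sat = 1.0 + (m0 / K2) ** n2
        kw.update(k2=rates.kappa ** 2 * sat / (2.0 * nu_plus * m0 ** n2), n2=n2, K2=K2)
    else:
        raise ConfigurationError(f"unknown mechanism {mechanism!r}")
    return KineticParameters(**kw)


def _check_times(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    return t


def oosawa_curve(rates: MacroscopicRates, nc: float, times) -> KineticCurve:
    """Exact primary-nucleation/elongation (Oosawa) solution.

    M(t)/m0 = 1 − sech**(2/nc)(sqrt(nc/2)·λ·t), evaluated in log space so
    large λ·t does not overflow.
    """
    t = _check_times(times)
    if rates.kappa != 0:
        raise ValueError("oosawa_curve requires kappa == 0")
    if rates.lam == 0:
        return KineticCurve(t, np.zeros_like(t))
    x = math.sqrt(nc / 2.0) * rates.lam * t
    # log sech(x) = ln2 − x − log1p(exp(−2x))
    log_sech = math.log(2.0) - x - np.log1p(np.exp(-2.0 * x))
    frac = -np.expm1((2.0 / nc) * log_sech)
    return KineticCurve(t, frac)


def rg_curve(rates: MacroscopicRates, times) -> KineticCurve:
    """Closed-form solution with primary and secondary pathways.

    M(t)/m0 = 1 − [1 + (λ²/(θκ²))·(cosh(κt) − 1)]^(−θ).  The expression
    interpolates between the exact linearized early-time solution
    (λ²/κ²)(cosh κt − 1) and exponential late-time relaxation at rate θκ.
    Evaluated via log1p/expm1 so large κ·t never overflows.
    """
    t = _check_times(times)
    lam, kap, th = rates.lam, rates.kappa, rates.theta
    if lam == 0:
        return KineticCurve(t, np.zeros_like(t))
    if th <= 0:
        raise ValueError("rg_curve requires theta > 0")
    if kap == 0:
        # κ→0 limit: cosh(κt)−1 → (κt)²/2
        big_l = np.log1p(lam ** 2 * t ** 2 / (2.0 * th))
    else:
        x = kap * t / 2.0
        with np.errstate(divide="ignore"):
            log_c = np.where(
                x < 20.0,
                math.log(2.0) + 2.0 * np.log(np.sinh(np.minimum(x, 20.0))),
                2.0 * x + 2.0 * np.log1p(-np.exp(-2.0 * np.maximum(x, 20.0))) - math.log(2.0),
            )
        log_q = math.log(lam ** 2 / (th * kap ** 2))
        big_l = np.logaddexp(0.0, log_q + log_c)  # log(1 + q·c), exact at t=0
    frac = -np.expm1(-th * big_l)
    return KineticCurve(t, frac)


def moment_ode_oracle(
    p: KineticParameters,
    times,
    rtol: float = 1e-9,
    atol: Optional[float] = None,
    return_conservation: bool = False,
):
    """Brute-force numerical integration of the moment equations.

    Integrates fibril number P, fibril mass M and free monomer m as
    independent state variables (so monomer conservation m + M = m0 is a
    genuine integrator check, not an identity):

        dP/dt = kn·m^nc + secondary source (kf·M, or k2·m^n2·M with
                optional Michaelis saturation)
        dM/dt = 2·kplus·m·P
        dm/dt = −2·kplus·m·P

    Returns the normalized mass curve; with ``return_conservation`` also the
    maximal |m + M − m0| over the grid.
    """
    t = _check_times(times)
    m0 = p.m0
    if atol is None:
        atol = 1e-12 * m0

    kn, kp, nc = p.kn, p.kplus, p.nc

    if p.mechanism == "fragmentation":
        kf = p.kf

        def secondary(m, M):
            return kf * M

    elif p.mechanism == "secondary_single":
        k2, n2 = p.k2, p.n2

        def secondary(m, M):
            return k2 * m ** n2 * M

    elif p.mechanism == "secondary_multistep":
        k2, n2, K2 = p.k2, p.n2, p.K2

        def secondary(m, M):
            return k2 * m ** n2 / (1.0 + (m / K2) ** n2) * M

    else:

        def secondary(m, M):
            return 0.0

    def rhs(_t, y):
        P, M, m = y
        mc = max(m, 0.0)
        growth = ELONGATION_ENDS * kp * mc * P
        return (kn * mc ** nc + secondary(mc, M), growth, -growth)

    t_span = (0.0, float(t[-1]) if t[-1] > 0 else 1.0)
    sol = solve_ivp(
        rhs,
        t_span,
        [0.0, 0.0, m0],
        method="LSODA",
        t_eval=t,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"moment ODE integration failed ({sol.message}) for parameters {p!r}"
        )
    M = sol.y[1]
    m = sol.y[2]
    curve = KineticCurve(t, M / m0)
    if return_conservation:
        return curve, float(np.max(np.abs(m + M - m0)))
    return curve


def half_time(
    curve: KineticCurve,
    plateau_frac: float = 0.1,
    smooth: int = 0,
) -> Optional[float]:
    """Earliest time at which the signal crosses half its plateau value.

    The plateau is estimated as the mean over the final ``plateau_frac`` of
    samples; the crossing is located by linear interpolation between the
    bracketing samples.  Returns ``None`` when the curve never reaches half
    its plateau (e.g. a flat failed well), rather than a number.

    ``smooth`` > 0 applies a centered moving average of that window before
    the crossing search (off by default).
    """
    t = curve.times
    y = np.asarray(curve.fraction_fibrillar, dtype=float)
    if y.size < 2:
        return None
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        y = np.convolve(y, kernel, mode="same")
    n_tail = max(1, int(round(plateau_frac * y.size)))
    plateau = float(np.mean(y[-n_tail:]))
    if plateau <= 0:
        return None
    half = 0.5 * plateau
    above = y >= half
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    return float(t[i - 1] + (half - y0) * (t[i] - t[i - 1]) / (y1 - y0))
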