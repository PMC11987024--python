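"""Auxiliary biophysical fits: Taylor dispersion, SPR kinetics, NMR CSP,
copelleting fractions, protein extinction coefficients and buffer capacity.

These are the orthogonal measurements used to characterize inhibitor
candidates: molecular sizing by Taylor dispersion analysis (TDA), binding
kinetics by surface plasmon resonance (SPR), residue-level binding by NMR
chemical shift perturbation, and the fraction of compound removed with
pelleted fibrils from UV absorbance spectra.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "BOLTZMANN_JK",
    "LAMBDA_MAX_NM",
    "Taylorgram",
    "TaylorFit",
    "Sensorgram",
    "BiexpFit",
    "LangmuirFit",
    "taylor_peak",
    "fit_taylorgram",
    "stokes_einstein",
    "fit_spr_biexponential",
    "fit_spr_1to1",
    "csp",
    "copelleting_fraction",
    "extinction_coefficient_280",
    "buffer_capacity",
]

log = logging.getLogger(__name__)

BOLTZMANN_JK = 1.380649e-23  # J/K

#: Absorbance maxima (nm) of the screened compounds, for copelleting analysis.
LAMBDA_MAX_NM = {
    "YX-I-1": 252.0,
    "canagliflozin": 291.0,
    "doxazosin": 340.0,
    "dapagliflozin": 276.0,
}


# --- Taylor dispersion ------------------------------------------------------


@dataclass
class Taylorgram:
    """A TDA elution trace with instrument configuration.

    Defaults: capillary radius a = 37.5 μm, T = 303 K, η = 0.797 mPa·s.
    """

    times: np.ndarray  # s
    intensities: np.ndarray
    a: float = 37.5e-6  # m
    temperature: float = 303.0  # K
    viscosity: float = 0.797e-3  # Pa·s

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not (self.a > 0 and self.temperature > 0 and self.viscosity > 0):
            raise ValueError("a, temperature and viscosity must be > 0")


@dataclass
class TaylorFit:
    A: float  # peak area
    t_R: float  # s
    D: float  # m²/s
    R_h: float  # m
    rss: float
    r2: float


def taylor_peak(times, A: float, t_R: float, D: float, a: float) -> np.ndarray:
    """Gaussian Taylor dispersion peak with temporal variance a²·t_R/(24·D)."""
    t = np.asarray(times, dtype=float)
    sigma2 = a ** 2 * t_R / (24.0 * D)
    return A / np.sqrt(2.0 * math.pi * sigma2) * np.exp(-((t - t_R) ** 2) / (2.0 * sigma2))


def fit_taylorgram(tg: Taylorgram) -> TaylorFit:
    """Least-squares fit of (A, t_R, D) to a single dominant peak."""
    t, y = tg.times, tg.intensities
    i_max = int(np.argmax(y))
    t_r0 = float(t[i_max])
    if t_r0 <= 0:
        t_r0 = float(t[-1]) / 2.0
    # moment-based width for the initial D
    w = np.clip(y, 0.0, None)
    if w.sum() > 0:
        mu = float((t * w).sum() / w.sum())
        var = float(((t - mu) ** 2 * w).sum() / w.sum())
    else:
        var = (t[-1] - t[0]) ** 2 / 16.0
    var = max(var, (t[1] - t[0]) ** 2)
    d0 = tg.a ** 2 * t_r0 / (24.0 * var)
    area0 = float(np.trapezoid(w, t))
    x0 = np.log10([max(area0, 1e-12), t_r0, max(d0, 1e-14)])

    def residuals(x):
        A, t_r, D = 10.0 ** x
        return taylor_peak(t, A, t_r, D, tg.a) - y

    sol = least_squares(residuals, x0, method="lm")
    if not sol.success:
        raise RuntimeError(
            f"taylorgram fit failed to converge (initial guess A={area0:g}, "
            f"t_R={t_r0:g}, D={d0:g}): {sol.message}"
        )
    A, t_r, D = 10.0 ** sol.x
    rss = float(2.0 * sol.cost)
    tss = float(np.sum((y - y.mean()) ** 2))
    return TaylorFit(
        A=A, t_R=t_r, D=D,
        R_h=stokes_einstein(D, tg.temperature, tg.viscosity),
        rss=rss, r2=1.0 - rss / tss if tss > 0 else 1.0,
    )


def stokes_einstein(D: float, temperature: float = 303.0,
                    viscosity: float = 0.797e-3) -> float:
    """Hydrodynamic radius R_h = k_B·T / (6π·η·D), in meters."""
    if D <= 0:
        raise ValueError("D must be > 0")
    return BOLTZMANN_JK * temperature / (6.0 * math.pi * viscosity * D)


# --- SPR --------------------------------------------------------------------


@dataclass
class Sensorgram:
    """An SPR response trace at one analyte concentration (μM)."""

    times: np.ndarray  # s
    response: np.ndarray  # RU
    concentration: float  # μM
    tau: float = 60.0  # s, start of the dissociation phase

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if not (self.times[0] <= self.tau <= self.times[-1]):
            raise ValueError("tau must lie within the time range")


@dataclass
class BiexpFit:
    k1: float  # s⁻¹, fast phase
    k2: float  # s⁻¹, slow phase
    A1: float  # RU
    A2: float  # RU
    rss: float
    effectively_monoexponential: bool = False

    @property
    def plateau(self) -> float:
        return self.A1 + self.A2


@dataclass
class LangmuirFit:
    B_max: float  # RU
    k_on: float  # μM⁻¹ s⁻¹
    k_off: float  # s⁻¹
    rss: float
    status: str = "ok"  # or 'KD >> max [A]'
    B_max_pinned: bool = False

    @property
    def K_D(self) -> float:
        return self.k_off / self.k_on


def fit_spr_biexponential(sg: Sensorgram) -> BiexpFit:
    """Fit R(t) = A1(1−e^{−k1 t}) + A2(1−e^{−k2 t}) to the association phase.

    Phases are reported fast-first (k1 ≥ k2); nearly equal rates are flagged
    as effectively monoexponential rather than treated as an error.
    """
    mask = sg.times <= sg.tau
    t, y = sg.times[mask], sg.response[mask]
    if t.size < 5:
        raise ValueError("association window contains too few points")
    plateau0 = max(float(np.percentile(y, 95)), 1e-9)
    k_fast0 = 5.0 / max(sg.tau, 1e-9)
    k_slow0 = 0.5 / max(sg.tau, 1e-9)
    x0 = np.array([math.log10(k_fast0), math.log10(k_slow0),
                   plateau0 / 2.0, plateau0 / 2.0])

    def residuals(x):
        k1, k2 = 10.0 ** x[0], 10.0 ** x[1]
        a1, a2 = x[2], x[3]
        return a1 * -np.expm1(-k1 * t) + a2 * -np.expm1(-k2 * t) - y

    lo = np.array([-6.0, -6.0, -np.inf, -np.inf])
    hi = np.array([3.0, 3.0, np.inf, np.inf])
    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
    k1, k2 = 10.0 ** sol.x[0], 10.0 ** sol.x[1]
    a1, a2 = float(sol.x[2]), float(sol.x[3])
    if k1 < k2:  # canonical order: fast phase first
        k1, k2, a1, a2 = k2, k1, a2, a1
    mono = abs(k1 - k2) <= 1e-3 * max(k1, k2)
    return BiexpFit(k1=k1, k2=k2, A1=a1, A2=a2, rss=float(2.0 * sol.cost),
                    effectively_monoexponential=mono)


def _langmuir_model(t, conc, b_max, k_on, k_off, tau):
    if conc == 0:
        return np.zeros_like(t)
    kd = k_off / k_on
    req = b_max * conc / (conc + kd)
    kobs = k_on * conc + k_off
    assoc = req * -np.expm1(-kobs * np.minimum(t, tau))
    r_tau = req * -np.expm1(-kobs * tau)
    return np.where(t <= tau, assoc, r_tau * np.exp(-k_off * np.maximum(t - tau, 0.0)))


def fit_spr_1to1(
    sensorgrams: Sequence[Sensorgram],
    b_max: Optional[float] = None,
    linearity_r2: float = 0.999,
) -> LangmuirFit:
    """Global 1:1 kinetic fit across analyte concentrations.

    R(t) = B_max·[A]/([A]+K_D)·(1−e^{−(k_on[A]+k_off)t}) during association
    (t ≤ τ), then exponential dissociation at k_off.  Pass ``b_max`` to pin
    the saturation response (e.g. 1e4 RU).  When the plateau response is
    linear in [A] throughout (R² above ``linearity_r2``) and the fitted K_D
    exceeds 10× the highest concentration, K_D is unidentifiable and the fit
    is returned with status ``'KD >> max [A]'``.
    """
    if len(sensorgrams) < 2:
        raise ValueError("global 1:1 fit needs sensorgrams at >= 2 concentrations")
    concs = np.array([sg.concentration for sg in sensorgrams])
    max_conc = float(concs.max())

    pin = b_max is not None

    def unpack(x):
        if pin:
            return b_max, 10.0 ** x[0], 10.0 ** x[1]
        return 10.0 ** x[0], 10.0 ** x[1], 10.0 ** x[2]

    def residuals(x):
        bm, kon, koff = unpack(x)
        return np.concatenate(
            [
                _langmuir_model(sg.times, sg.concentration, bm, kon, koff, sg.tau)
                - sg.response
                for sg in sensorgrams
            ]
        )

    r_max = max(float(np.percentile(sg.response, 95)) for sg in sensorgrams)
    kon0 = 1e-3
    koff0 = 0.05
    if pin:
        x0 = np.log10([kon0, koff0])
        lo, hi = np.array([-8.0, -5.0]), np.array([2.0, 2.0])
    else:
        x0 = np.log10([max(2.0 * r_max, 1.0), kon0, koff0])
        lo, hi = np.array([-2.0, -8.0, -5.0]), np.array([9.0, 2.0, 2.0])
    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
    bm, kon, koff = unpack(sol.x)
    fit = LangmuirFit(B_max=float(bm), k_on=float(kon), k_off=float(koff),
                      rss=float(2.0 * sol.cost), B_max_pinned=pin)

    # unidentifiability check: plateau response linear in concentration
    plateaus = np.array(
        [
            float(np.mean(sg.response[(sg.times > 0.8 * sg.tau) & (sg.times <= sg.tau)]))
            for sg in sensorgrams
        ]
    )
    if concs.size >= 2 and np.ptp(concs) > 0:
        slope = float((concs * plateaus).sum() / (concs ** 2).sum())
        pred = slope * concs
        ss_res = float(((plateaus - pred) ** 2).sum())
        ss_tot = float(((plateaus - plateaus.mean()) ** 2).sum())
        r2_lin = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        if r2_lin > linearity_r2 and fit.K_D > 10.0 * max_conc:
            fit.status = "KD >> max [A]"
    return fit


# --- NMR --------------------------------------------------------------------

#: ¹⁵N shift weighting in the combined CSP (Williamson convention).
CSP_N_WEIGHT = 0.14


def csp(reference: pd.DataFrame, ligand: pd.DataFrame) -> pd.DataFrame:
    """Per-residue chemical shift perturbation and intensity ratio.

    Both tables need columns ``residue``, ``dH``, ``dN``, ``intensity``.
    CSP = sqrt((ΔδH² + (0.14·ΔδN)²)/2); I/I0 uses raw peak heights.
    Residues present in only one state are excluded and logged.
    """
    for name, df in (("reference", reference), ("ligand", ligand)):
        missing = {"residue", "dH", "dN", "intensity"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} peak table lacks columns {sorted(missing)}")
    merged = reference.merge(ligand, on="residue", suffixes=("_0", "_1"), how="outer",
                             indicator=True)
    unmatched = merged.loc[merged["_merge"] != "both", "residue"].tolist()
    if unmatched:
        log.warning("residues excluded (present in one state only): %s", unmatched)
    both = merged[merged["_merge"] == "both"].copy()
    d_h = both["dH_1"] - both["dH_0"]
    d_n = both["dN_1"] - both["dN_0"]
    both["csp"] = np.sqrt((d_h ** 2 + (CSP_N_WEIGHT * d_n) ** 2) / 2.0)
    both["intensity_ratio"] = both["intensity_1"] / both["intensity_0"]
    return both[["residue", "csp", "intensity_ratio"]].reset_index(drop=True)


# --- copelleting ------------------------------------------------------------


def _interp(spectrum: pd.DataFrame, wavelength: float) -> float:
    wl = spectrum.iloc[:, 0].to_numpy(dtype=float)
    ab = spectrum.iloc[:, 1].to_numpy(dtype=float)
    if not (wl.min() <= wavelength <= wl.max()):
        raise ValueError(f"spectrum does not cover {wavelength} nm")
    return float(np.interp(wavelength, wl, ab))


def copelleting_fraction(
    sample_before: pd.DataFrame,
    sample_after: pd.DataFrame,
    reference_before: pd.DataFrame,
    reference_after: pd.DataFrame,
    lambda_max: float,
    baseline_nm: float = 400.0,
) -> Dict[str, float]:
    """Percent of compound remaining free vs copelleted with fibrils.

    Each spectrum is reference-subtracted (fibrils without compound) and
    baselined at 400 nm; the free fraction is the after/before fold-change
    of the corrected absorbance at the compound's λ_max.
    """

    def corrected(sample, reference):
        peak = _interp(sample, lambda_max) - _interp(reference, lambda_max)
        base = _interp(sample, baseline_nm) - _interp(reference, baseline_nm)
        return peak - base

    before = corrected(sample_before, reference_before)
    after = corrected(sample_after, reference_after)
    if before <= 0:
        raise ValueError(
            f"corrected absorbance before pelleting is nonpositive ({before:g})"
        )
    free = 100.0 * after / before
    return {"percent_free": free, "percent_copelleted": 100.0 - free}


# --- composition calculations ----------------------------------------------

# ProtParam residue extinction coefficients at 280 nm (M⁻¹cm⁻¹)
_EPS_TRP = 5500.0
_EPS_TYR = 1490.0
_EPS_CYSTINE = 125.0


def extinction_coefficient_280(n_trp: int, n_tyr: int, n_cystine: int) -> float:
    """Molar extinction coefficient at 280 nm from residue composition.

    ε = 5500·nTrp + 1490·nTyr + 125·n(cystine), the standard
    Expasy/ProtParam rule (cystine = disulfide-bonded cysteine pair).
    """
    if min(n_trp, n_tyr, n_cystine) < 0:
        raise ValueError("residue counts must be >= 0")
    return _EPS_TRP * n_trp + _EPS_TYR * n_tyr + _EPS_CYSTINE * n_cystine


# pKw of water vs temperature (°C), CRC values; linear interpolation between.
_PKW_TABLE = (
    (0.0, 14.94), (5.0, 14.73), (10.0, 14.53), (15.0, 14.35), (20.0, 14.17),
    (25.0, 13.996), (30.0, 13.83), (35.0, 13.68), (40.0, 13.53), (50.0, 13.26),
)


def buffer_capacity(
    total_conc_mm: float,
    pka_list: Sequence[float],
    ph: float,
    temperature_c: float = 25.0,
) -> float:
    """Van Slyke buffer capacity β = dC/dpH, in mM.

    β = ln(10)·(Kw/[H⁺] + [H⁺] + Σᵢ C·Kaᵢ·[H⁺]/(Kaᵢ+[H⁺])²), with the water
    autoionization constant interpolated at the given temperature.  Protolytic
    groups are treated as independent; activity corrections are not applied,
    so printed capacities computed with other conventions may differ slightly.
    """
    if total_conc_mm <= 0:
        raise ValueError("buffer concentration must be > 0")
    if len(pka_list) == 0:
        raise ValueError("pka_list must not be empty")
    temps, pkws = zip(*_PKW_TABLE)
    pkw = float(np.interp(temperature_c, temps, pkws))
    h = 10.0 ** (-ph)
    kw = 10.0 ** (-pkw)
    c_molar = total_conc_mm * 1e-3
    beta = kw / h + h
    for pka in pka_list:
        ka = 10.0 ** (-pka)
        beta += c_molar * ka * h / (ka + h) ** 2
    return math.log(10.0) * beta * 1e3  # mM
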