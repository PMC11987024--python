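"""Seeded generators for every input the analysis pipeline consumes.

Each generator emulates one of the study's measurement modalities — ThT
plate-reader kinetics, inhibitor dose series, taylorgrams, SPR sensorgrams
and microfluidic elugrams — from a known ground truth that is returned
alongside the data, so every pipeline stage can be tested end to end
without instrument data.

Defaults mirror typical assay conditions: 10 μM monomer aggregating with a
dominant secondary pathway (λ = 0.02 h⁻¹, κ = 1.0 h⁻¹, θ = 0.323), readings
every 5 min, 3 replicate and 3 blank wells, and additive Gaussian noise of
σ = 0.01 on the normalized signal.  Noise is additive on the normalized
signal; per-well gain and baseline are drawn once per well.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .biophysics import Sensorgram, Taylorgram, taylor_peak
from .capflex import Elugram
from .global_fitting import Condition, DoseSeries
from .kinetic_models import MacroscopicRates, rg_curve
from .tht_screening import Plate

__all__ = [
    "DEFAULT_RATES",
    "gen_tht_plate",
    "gen_dose_series",
    "gen_monomer_series",
    "gen_taylorgram",
    "gen_spr_trace",
    "gen_spr_series",
    "gen_elugram",
]

DEFAULT_RATES = MacroscopicRates(lam=0.02, kappa=1.0, theta=0.323)
DEFAULT_DT_H = 5.0 / 60.0  # plate-reader sampling: one read every 5 min


def _time_grid(t_max: float, dt: float) -> np.ndarray:
    n = int(round(t_max / dt)) + 1
    return np.arange(n) * dt


def gen_tht_plate(
    seed: int,
    conditions: Optional[Dict[str, MacroscopicRates]] = None,
    n_replicates: int = 3,
    n_blanks: int = 3,
    t_max: float = 24.0,
    dt: float = DEFAULT_DT_H,
    noise_sigma: float = 0.01,
    gain: float = 1000.0,
    gain_cv: float = 0.05,
    baseline: float = 100.0,
    baseline_sd: float = 2.0,
) -> Tuple[Plate, Dict]:
    """Simulate a raw ThT plate: gain·model + baseline + noise, plus blanks.

    Each well draws its gain and baseline once (well-to-well variability);
    Gaussian read noise (σ as a fraction of the well gain) is added per time
    point.  Returns the plate and a ground-truth record with the generating
    rates and noise-free curves.
    """
    rng = np.random.default_rng(seed)
    if conditions is None:
        conditions = {"control": DEFAULT_RATES}
    times = _time_grid(t_max, dt)
    wells: Dict[str, np.ndarray] = {}
    layout_rows = []
    truth: Dict = {"rates": {}, "noise_sigma": noise_sigma, "seed": seed}
    w = 0
    for label, rates in conditions.items():
        model = rg_curve(rates, times).fraction_fibrillar
        truth["rates"][label] = {
            "lam": rates.lam, "kappa": rates.kappa, "theta": rates.theta,
        }
        for _ in range(n_replicates):
            well = f"W{w:02d}"
            w += 1
            g = gain * (1.0 + gain_cv * rng.standard_normal())
            b = baseline + baseline_sd * rng.standard_normal()
            trace = g * model + b + g * noise_sigma * rng.standard_normal(times.size)
            wells[well] = trace
            role = "control_no_compound" if label == "control" else "sample"
            layout_rows.append({"well": well, "role": role, "condition": label})
    for _ in range(n_blanks):
        well = f"B{w:02d}"
        w += 1
        b = baseline + baseline_sd * rng.standard_normal()
        wells[well] = b + gain * noise_sigma * rng.standard_normal(times.size)
        layout_rows.append({"well": well, "role": "blank", "condition": "blank"})
    data = pd.DataFrame(wells, index=times)
    layout = pd.DataFrame(layout_rows).set_index("well")
    return Plate(times=times, data=data, layout=layout), truth


def _scaled_rates(base: MacroscopicRates, process: str, factor: float) -> MacroscopicRates:
    """Scale one normalized process rate; λ and κ respond as square roots.

    λ² ∝ ν₊·νₙ and κ² ∝ ν₊·ν₂, so scaling νₙ by f scales λ by √f, scaling
    ν₂ by f scales κ by √f, and scaling ν₊ by f scales both by √f.
    """
    s = math.sqrt(factor)
    if process == "nu_n":
        return MacroscopicRates(base.lam * s, base.kappa, base.theta)
    if process == "nu_2":
        return MacroscopicRates(base.lam, base.kappa * s, base.theta)
    if process == "nu_plus":
        return MacroscopicRates(base.lam * s, base.kappa * s, base.theta)
    raise ValueError(f"unknown process {process!r}; expected nu_n, nu_2 or nu_plus")


def gen_dose_series(
    seed: int,
    process: str = "nu_n",
    factors: Sequence[float] = (1.0, 0.7, 0.4, 0.2, 0.1),
    concentrations: Optional[Sequence[float]] = None,
    base: MacroscopicRates = DEFAULT_RATES,
    m0: float = 10.0,
    n_replicates: int = 3,
    t_max: float = 48.0,
    dt: float = DEFAULT_DT_H,
    noise_sigma: float = 0.01,
) -> Tuple[DoseSeries, Dict]:
    """Simulate a normalized inhibitor dose series.

    Exactly one normalized process rate is multiplied by the per-condition
    factor (1.0 = uninhibited control); all conditions share the monomer
    concentration and time grid.  Returns the series plus ground truth
    (factors and per-condition λ, κ).
    """
    rng = np.random.default_rng(seed)
    if concentrations is None:
        concentrations = np.linspace(0.0, 100.0, len(factors))
    if len(concentrations) != len(factors):
        raise ValueError("concentrations and factors must have equal length")
    times = _time_grid(t_max, dt)
    conds: List[Condition] = []
    truth: Dict = {
        "process": process, "factors": list(factors), "seed": seed,
        "noise_sigma": noise_sigma, "lam": [], "kappa": [],
        "base": {"lam": base.lam, "kappa": base.kappa, "theta": base.theta},
    }
    for conc, f in zip(concentrations, factors):
        rates = _scaled_rates(base, process, f)
        truth["lam"].append(rates.lam)
        truth["kappa"].append(rates.kappa)
        model = rg_curve(rates, times).fraction_fibrillar
        curves = model[None, :] + noise_sigma * rng.standard_normal(
            (n_replicates, times.size)
        )
        conds.append(
            Condition(
                label=f"{conc:g}uM", concentration=float(conc), m0=m0,
                times=times, curves=curves,
            )
        )
    series = DoseSeries(conds, metadata={"m0": m0, "seed": seed})
    return series, truth


def gen_monomer_series(
    seed: int,
    m0s: Sequence[float] = (8.0, 12.0, 16.0, 22.0, 30.0),
    mechanism: str = "secondary_multistep",
    A: float = 4.0e-5,
    B: float = 8.0e-3,
    K2: float = 15.0,
    theta: float = 0.323,
    nc: float = 2.0,
    n2: float = 2.0,
    n_replicates: int = 3,
    t_max: float = 48.0,
    dt: float = DEFAULT_DT_H,
    noise_sigma: float = 0.01,
) -> Tuple[DoseSeries, Dict]:
    """Simulate an uninhibited monomer dilution series under one mechanism.

    A = 2·k₊·kₙ and B = 2·k₊·k₂ (or 2·k₊·k_f for fragmentation) set
    λ_c = √(A·m0^nc) and the mechanism-appropriate κ_c per concentration.
    """
    rng = np.random.default_rng(seed)
    times = _time_grid(t_max, dt)
    conds: List[Condition] = []
    truth: Dict = {
        "mechanism": mechanism, "A": A, "B": B, "K2": K2, "theta": theta,
        "nc": nc, "n2": n2, "seed": seed, "lam": [], "kappa": [],
    }
    for m0 in m0s:
        lam = math.sqrt(A * m0 ** nc)
        if mechanism == "oosawa":
            kap = 0.0
        elif mechanism == "fragmentation":
            kap = math.sqrt(B * m0)
        elif mechanism == "secondary_single":
            kap = math.sqrt(B * m0 ** (n2 + 1.0))
        elif mechanism == "secondary_multistep":
            kap = math.sqrt(B * m0 ** (n2 + 1.0) / (1.0 + (m0 / K2) ** n2))
        else:
            raise ValueError(f"unknown mechanism {mechanism!r}")
        truth["lam"].append(lam)
        truth["kappa"].append(kap)
        if mechanism == "oosawa":
            from .kinetic_models import oosawa_curve

            model = oosawa_curve(MacroscopicRates(lam, 0.0), nc, times).fraction_fibrillar
        else:
            model = rg_curve(MacroscopicRates(lam, kap, theta), times).fraction_fibrillar
        curves = model[None, :] + noise_sigma * rng.standard_normal(
            (n_replicates, times.size)
        )
        conds.append(
            Condition(label=f"{m0:g}uM", concentration=float(m0), m0=float(m0),
                      times=times, curves=curves)
        )
    return DoseSeries(conds, metadata={"seed": seed}), truth


def gen_taylorgram(
    seed: int,
    A: float = 50.0,
    t_R: float = 120.0,
    D: float = 4.0e-10,
    a: float = 37.5e-6,
    t_max: float = 240.0,
    dt: float = 0.2,
    noise_sigma: float = 0.0,
) -> Tuple[Taylorgram, Dict]:
    """Simulate a Taylor dispersion peak with optional Gaussian noise.

    ``noise_sigma`` is expressed as a fraction of the peak height.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max + dt / 2, dt)
    signal = taylor_peak(times, A, t_R, D, a)
    peak = float(signal.max())
    signal = signal + noise_sigma * peak * rng.standard_normal(times.size)
    tg = Taylorgram(times=times, intensities=signal, a=a)
    return tg, {"A": A, "t_R": t_R, "D": D, "a": a, "seed": seed,
                "noise_sigma": noise_sigma}


def _langmuir_trace(times, conc, b_max, k_on, k_off, tau):
    if conc == 0:
        return np.zeros_like(times)
    kd = k_off / k_on
    req = b_max * conc / (conc + kd)
    kobs = k_on * conc + k_off
    assoc = req * -np.expm1(-kobs * np.minimum(times, tau))
    r_tau = req * -np.expm1(-kobs * tau)
    dissoc = r_tau * np.exp(-k_off * np.maximum(times - tau, 0.0))
    return np.where(times <= tau, assoc, dissoc)


def gen_spr_trace(
    seed: int,
    kind: str = "biexp",
    concentration: float = 50.0,
    t_max: float = 180.0,
    dt: float = 0.5,
    tau: float = 60.0,
    noise_sigma: float = 1.0,
    A1: float = 30.0,
    A2: float = 20.0,
    k1: float = 0.5,
    k2: float = 0.05,
    b_max: float = 100.0,
    k_on: float = 1.0e-3,
    k_off: float = 0.05,
) -> Tuple[Sensorgram, Dict]:
    """Simulate a single sensorgram, biexponential or 1:1 Langmuir.

    Rates in s⁻¹ (k_on in μM⁻¹s⁻¹), amplitudes/responses in RU, noise in RU.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max + dt / 2, dt)
    if kind == "biexp":
        assoc = A1 * -np.expm1(-k1 * np.minimum(times, tau)) + A2 * -np.expm1(
            -k2 * np.minimum(times, tau)
        )
        r_tau = A1 * -np.expm1(-k1 * tau) + A2 * -np.expm1(-k2 * tau)
        signal = np.where(times <= tau, assoc, r_tau)
        truth = {"A1": A1, "A2": A2, "k1": k1, "k2": k2, "plateau": A1 + A2}
    elif kind == "langmuir":
        signal = _langmuir_trace(times, concentration, b_max, k_on, k_off, tau)
        truth = {"b_max": b_max, "k_on": k_on, "k_off": k_off,
                 "K_D": k_off / k_on, "concentration": concentration}
    else:
        raise ValueError(f"unknown sensorgram kind {kind!r}")
    signal = signal + noise_sigma * rng.standard_normal(times.size)
    sg = Sensorgram(times=times, response=signal, concentration=concentration, tau=tau)
    truth.update({"seed": seed, "noise_sigma": noise_sigma})
    return sg, truth


def gen_spr_series(
    seed: int,
    concentrations: Sequence[float] = (10.0, 50.0, 150.0),
    b_max: float = 100.0,
    k_on: float = 1.0e-3,
    k_off: float = 0.05,
    tau: float = 60.0,
    t_max: float = 180.0,
    dt: float = 0.5,
    noise_sigma: float = 1.0,
) -> Tuple[List[Sensorgram], Dict]:
    """Simulate a 1:1 Langmuir concentration series for global fitting."""
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max + dt / 2, dt)
    sgs = []
    for conc in concentrations:
        signal = _langmuir_trace(times, conc, b_max, k_on, k_off, tau)
        signal = signal + noise_sigma * rng.standard_normal(times.size)
        sgs.append(Sensorgram(times=times, response=signal,
                              concentration=float(conc), tau=tau))
    truth = {"b_max": b_max, "k_on": k_on, "k_off": k_off,
             "K_D": k_off / k_on, "seed": seed, "noise_sigma": noise_sigma}
    return sgs, truth


def gen_elugram(
    seed: int,
    plateau: float = 1.0,
    baseline: float = 0.0,
    step_start: float = 15.0,
    step_end: float = 30.0,
    n_spikes: int = 5,
    spike_height: Tuple[float, float] = (0.02, 0.1),
    t_max: float = 80.0,
    dt: float = 0.1,
    noise_sigma: float = 0.002,
) -> Tuple[Elugram, Dict]:
    """Simulate a microfluidic elugram: baseline, plateau step, planted spikes.

    Spikes are single-sample excursions planted at distinct times in the
    plateau region (> ``step_end``), with heights drawn uniformly from
    ``spike_height`` (normalized fluorescence units above the local signal).
    Spike times and heights are recorded in the ground truth.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max + dt / 2, dt)
    # smooth sigmoidal step between baseline and plateau
    center = 0.5 * (step_start + step_end)
    width = max((step_end - step_start) / 6.0, dt)
    signal = baseline + (plateau - baseline) / (1.0 + np.exp(-(times - center) / width))
    eligible = np.flatnonzero(times > step_end + 2.0)
    # jittered even placement with a minimum gap of one median window
    # between spikes, so each planted spike is a distinct detectable event
    min_gap = 16
    if n_spikes > 0:
        if n_spikes * min_gap > eligible.size:
            raise ValueError("too many spikes for the plateau window")
        slot = eligible.size / n_spikes
        jitter = (slot - min_gap) / 2.0
        centers = (np.arange(n_spikes) + 0.5) * slot
        offsets = rng.uniform(-jitter, jitter, size=n_spikes) if jitter > 0 else 0.0
        idx = eligible[np.clip((centers + offsets).astype(int), 0, eligible.size - 1)]
        idx = np.sort(idx)
    else:
        idx = np.empty(0, dtype=int)
    heights = rng.uniform(*spike_height, size=n_spikes)
    signal[idx] += heights
    signal = signal + noise_sigma * rng.standard_normal(times.size)
    e = Elugram(times=times, fluorescence=signal)
    truth = {
        "plateau": plateau, "baseline": baseline,
        "spike_indices": idx.tolist(), "spike_times": times[idx].tolist(),
        "spike_heights": heights.tolist(), "seed": seed,
        "noise_sigma": noise_sigma,
    }
    return e, truth
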