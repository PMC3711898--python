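"""Physiological metric extraction from batch-culture time series.

Given a sampled trajectory (biomass, extracellular metabolites,
cumulative off-gas) this module computes the quantities used to compare
yeast carbon metabolism across species:

* the exponential growth window on glucose and the maximum specific
  growth rate mu (slope of ln biomass vs time),
* the evaluation endpoint — ethanol maximum for Crabtree-positive runs,
  glucose depletion for negative runs,
* endpoint yields Y_p/S = delta(product) / delta(glucose) in g/g,
* exponential-phase specific rates q_p = (delta c_p / delta X) * mu in
  g/gDW/h,
* the respiration ratio (mol CO2 evolved per mol O2 consumed during
  growth on glucose),
* the C-mole carbon balance (products + biomass + CO2 over consumed
  glucose), the standard closure check for a well-run reactor.

Between-sample values (endpoint concentrations, gas totals at the
glucose-phase end) are obtained by linear interpolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .simulator import (
    CultureTimeSeries,
    MW_ACETATE_C,
    MW_BIOMASS_C,
    MW_ETHANOL_C,
    MW_GLUCOSE_C,
    MW_GLYCEROL_C,
)

__all__ = [
    "Basis",
    "EndpointRule",
    "ExponentialWindow",
    "Endpoint",
    "PhenotypeMetrics",
    "ExtractionConfig",
    "detect_exponential_window",
    "fit_growth_rate",
    "determine_endpoint",
    "compute_yields",
    "compute_specific_rates",
    "respiration_ratio",
    "carbon_balance",
    "extract_metrics",
    "metrics_frame",
    "PRODUCT_COLUMNS",
    "CARBON_MASS",
]

#: Product name -> time-series column.
PRODUCT_COLUMNS = {
    "ethanol": "ethanol_gL",
    "glycerol": "glycerol_gL",
    "acetate": "acetate_gL",
    "pyruvate": "pyruvate_gL",
    "succinate": "succinate_gL",
    "lactate": "lactate_gL",
}

#: Grams per C-mole for the carbon balance.
CARBON_MASS = {
    "glucose": MW_GLUCOSE_C,
    "ethanol": MW_ETHANOL_C,
    "glycerol": MW_GLYCEROL_C,
    "acetate": MW_ACETATE_C,
    "pyruvate": 29.35,
    "succinate": 29.52,
    "lactate": 30.03,
    "biomass": MW_BIOMASS_C,
}

#: Glucose concentration treated as "depleted" (HPLC detection scale), g/L.
GLUCOSE_DEPLETED_GL = 0.1
#: Ethanol concentration above which a run counts as Crabtree positive, g/L.
ETHANOL_DETECT_GL = 0.5


class Basis(str, Enum):
    DW = "DW"
    OD600 = "OD600"


class EndpointRule(str, Enum):
    ETHANOL_MAX = "ETHANOL_MAX"
    GLUCOSE_DEPLETED = "GLUCOSE_DEPLETED"


@dataclass(frozen=True)
class ExponentialWindow:
    t_start_h: float
    t_end_h: float
    mu_per_h: float
    fit_r2: float
    n_points: int
    basis: Basis = Basis.DW

    def __post_init__(self) -> None:
        if not self.t_start_h < self.t_end_h:
            raise ValueError("t_start_h must precede t_end_h")
        if self.n_points < 3:
            raise ValueError("a growth-rate fit needs >= 3 points")


@dataclass(frozen=True)
class Endpoint:
    t_end_h: float
    rule: EndpointRule
    crabtree_positive: bool
    mixed_metabolism: bool = False

    def __post_init__(self) -> None:
        if self.crabtree_positive != (self.rule is EndpointRule.ETHANOL_MAX):
            raise ValueError("rule ETHANOL_MAX iff crabtree_positive")


@dataclass
class PhenotypeMetrics:
    """Per-run derived physiology: yields, q-rates, mu, RQ, C-balance."""

    yields: dict[str, float]          # product -> g/g; includes "biomass"
    rates: dict[str, float]           # "glucose", products -> g/gDW/h
    mu_per_h: float
    respiration_ratio: float          # mol CO2 / mol O2 (inf if no O2)
    carbon_balance: float             # C-mol out / C-mol in
    endpoint: Endpoint
    window: ExponentialWindow
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class ExtractionConfig:
    """Tunable thresholds of the extraction pipeline (defaults are the
    package-wide design values)."""

    basis: Basis = Basis.DW
    min_points: int = 4
    r2_min: float = 0.995
    window_glucose_min_gL: float = 1.0
    ethanol_detect_gL: float = ETHANOL_DETECT_GL
    glucose_depleted_gL: float = GLUCOSE_DEPLETED_GL
    manual_window: Optional[tuple[float, float]] = None
    median_filter_ethanol: bool = False  # optional 3-point median filter


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _signal_column(basis: Basis | str) -> str:
    basis = Basis(basis)
    return "dw_gL" if basis is Basis.DW else "od600"


def _interp(ts: CultureTimeSeries, column: str, t: float) -> float:
    s = ts.samples
    return float(np.interp(t, s["time_h"].to_numpy(), s[column].to_numpy()))


def _loglinear_fit(t: np.ndarray, signal: np.ndarray) -> tuple[float, float]:
    """OLS of ln(signal) on t -> (slope, r_squared)."""
    y = np.log(signal)
    slope, intercept = np.polyfit(t, y, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(slope), r2


def _ethanol_series(ts: CultureTimeSeries, config: ExtractionConfig) -> np.ndarray:
    eth = ts.samples["ethanol_gL"].to_numpy(dtype=float)
    if config.median_filter_ethanol and len(eth) >= 3:
        smoothed = eth.copy()
        for i in range(1, len(eth) - 1):
            smoothed[i] = np.median(eth[i - 1:i + 2])
        return smoothed
    return eth


# ---------------------------------------------------------------------------
# Exponential window and growth rate
# ---------------------------------------------------------------------------

def detect_exponential_window(
    ts: CultureTimeSeries,
    basis: Basis | str = Basis.DW,
    min_points: int = 4,
    r2_min: float = 0.995,
    *,
    glucose_min_gL: float = 1.0,
    ethanol_detect_gL: float = ETHANOL_DETECT_GL,
) -> ExponentialWindow:
    """Locate the exponential growth phase on glucose.

    Candidate samples must have positive biomass, glucose above
    ``glucose_min_gL`` and lie before any ethanol decline (i.e. not past
    the ethanol maximum of a fermenting run).  Among all contiguous
    candidate stretches of at least ``min_points`` samples whose
    log-linear biomass fit reaches ``r2_min``, the longest is returned;
    ties go to the higher fitted growth rate.
    """
    basis = Basis(basis)
    s = ts.samples
    t = s["time_h"].to_numpy(dtype=float)
    signal = s[_signal_column(basis)].to_numpy(dtype=float)
    glucose = s["glucose_gL"].to_numpy(dtype=float)
    eth = s["ethanol_gL"].to_numpy(dtype=float)

    eligible = (signal > 0) & (glucose > glucose_min_gL)
    if eth.max() >= ethanol_detect_gL:
        eligible &= t <= t[int(np.argmax(eth))]

    best: Optional[tuple[int, float, float, int, int]] = None  # (len, mu, r2, i, j)
    idx = np.flatnonzero(eligible)
    if idx.size:
        # split eligible indices into contiguous segments
        breaks = np.flatnonzero(np.diff(idx) > 1)
        segments = np.split(idx, breaks + 1)
        for seg in segments:
            n = len(seg)
            for length in range(n, min_points - 1, -1):
                if best is not None and length < best[0]:
                    break
                for start in range(0, n - length + 1):
                    window = seg[start:start + length]
                    mu, r2 = _loglinear_fit(t[window], signal[window])
                    if r2 < r2_min:
                        continue
                    key = (length, mu)
                    if best is None or key > (best[0], best[1]):
                        best = (length, mu, r2, window[0], window[-1])
    if best is None:
        raise ValueError(
            "no exponential window found (need >= "
            f"{min_points} samples with glucose > {glucose_min_gL} g/L and "
            f"log-linear r^2 >= {r2_min}); supply a manual window"
        )
    length, mu, r2, i, j = best
    return ExponentialWindow(
        t_start_h=float(t[i]), t_end_h=float(t[j]), mu_per_h=mu,
        fit_r2=r2, n_points=length, basis=basis,
    )


def fit_growth_rate(
    ts: CultureTimeSeries,
    window: tuple[float, float],
    basis: Basis | str = Basis.DW,
) -> float:
    """OLS slope of ln(biomass signal) vs time over samples inside
    ``window`` (inclusive), 1/h."""
    basis = Basis(basis)
    s = ts.samples
    t0, t1 = window
    mask = (s["time_h"] >= t0) & (s["time_h"] <= t1)
    if int(mask.sum()) < 3:
        raise ValueError("growth-rate window must contain >= 3 samples")
    signal = s.loc[mask, _signal_column(basis)].to_numpy(dtype=float)
    if np.any(signal <= 0):
        raise ValueError("nonpositive biomass values inside the fit window")
    slope, _ = _loglinear_fit(s.loc[mask, "time_h"].to_numpy(dtype=float),
                              signal)
    return slope


# ---------------------------------------------------------------------------
# Endpoint
# ---------------------------------------------------------------------------

def determine_endpoint(
    ts: CultureTimeSeries,
    ethanol_detect_gL: float = ETHANOL_DETECT_GL,
    glucose_depleted_gL: float = GLUCOSE_DEPLETED_GL,
    *,
    median_filter_ethanol: bool = False,
) -> Endpoint:
    """Evaluation endpoint of a run.

    Fermenting runs (max ethanol >= ``ethanol_detect_gL``) end at the
    earliest sample attaining the ethanol maximum; respiratory runs end
    when glucose first reaches ``glucose_depleted_gL``, linearly
    interpolated between the bracketing samples.  A fermenting run whose
    ethanol peak occurs while glucose is still present is flagged as
    mixed metabolism.
    """
    s = ts.samples
    if "glucose_gL" not in s.columns:
        raise ValueError("time series lacks a glucose column")
    t = s["time_h"].to_numpy(dtype=float)
    glucose = s["glucose_gL"].to_numpy(dtype=float)
    eth = _ethanol_series(
        ts, ExtractionConfig(median_filter_ethanol=median_filter_ethanol)
    )

    if eth.max() >= ethanol_detect_gL:
        i = int(np.argmax(eth))  # argmax returns the earliest maximum
        mixed = bool(glucose[i] > glucose_depleted_gL)
        if mixed:
            warnings.warn(
                "ethanol maximum reached while glucose is still present "
                f"({glucose[i]:.2f} g/L): mixed fermentative/respiratory "
                "metabolism",
                stacklevel=2,
            )
        return Endpoint(float(t[i]), EndpointRule.ETHANOL_MAX, True, mixed)

    below = np.flatnonzero(glucose <= glucose_depleted_gL)
    if below.size == 0:
        raise ValueError(
            "culture not finished: glucose never depleted and no ethanol "
            "detected"
        )
    i = int(below[0])
    if i == 0:
        t_end = float(t[0])
    else:
        g0, g1 = glucose[i - 1], glucose[i]
        frac = (g0 - glucose_depleted_gL) / (g0 - g1) if g0 > g1 else 1.0
        t_end = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return Endpoint(t_end, EndpointRule.GLUCOSE_DEPLETED, False)


# ---------------------------------------------------------------------------
# Yields and rates
# ---------------------------------------------------------------------------

def compute_yields(ts: CultureTimeSeries, endpoint: Endpoint) -> dict[str, float]:
    """Endpoint yields Y_p/S in g/g (``"biomass"`` uses dry weight).

    Concentrations at the endpoint are linearly interpolated; negative
    numerators (measurement noise) clip to zero.
    """
    s = ts.samples
    t0 = float(s["time_h"].iloc[0])
    t_end = endpoint.t_end_h
    if not (t0 <= t_end <= float(s["time_h"].iloc[-1])):
        raise ValueError("endpoint lies outside the sampled range")
    consumed = float(s["glucose_gL"].iloc[0]) - _interp(ts, "glucose_gL", t_end)
    if consumed <= 0:
        raise ValueError("no glucose consumed up to the endpoint")
    out: dict[str, float] = {}
    for product, column in PRODUCT_COLUMNS.items():
        delta = _interp(ts, column, t_end) - float(s[column].iloc[0])
        out[product] = max(delta, 0.0) / consumed
    delta_x = _interp(ts, "dw_gL", t_end) - float(s["dw_gL"].iloc[0])
    out["biomass"] = max(delta_x, 0.0) / consumed
    return out


def compute_specific_rates(
    ts: CultureTimeSeries, window: ExponentialWindow, mu: float | None = None
) -> dict[str, float]:
    """Exponential-phase specific rates in g/gDW/h.

    ``q_S = (dS/dX) * mu`` and ``q_p = (dc_p/dX) * mu`` evaluated
    between the first and last samples of the window — equivalently the
    exponential-phase yield ratios times mu.
    """
    mu = window.mu_per_h if mu is None else mu
    s = ts.samples
    mask = (s["time_h"] >= window.t_start_h) & (s["time_h"] <= window.t_end_h)
    sub = s.loc[mask]
    if len(sub) < 2:
        raise ValueError("window must contain >= 2 samples")
    delta_x = float(sub["dw_gL"].iloc[-1] - sub["dw_gL"].iloc[0])
    if delta_x <= 0:
        raise ValueError("biomass not increasing over the window")
    rates = {
        "glucose": (float(sub["glucose_gL"].iloc[0] - sub["glucose_gL"].iloc[-1])
                    / delta_x) * mu
    }
    for product, column in PRODUCT_COLUMNS.items():
        delta = float(sub[column].iloc[-1] - sub[column].iloc[0])
        rates[product] = max(delta, 0.0) / delta_x * mu
    rates["glucose"] = max(rates["glucose"], 0.0)
    return rates


# ---------------------------------------------------------------------------
# Off-gas: respiration ratio and carbon balance
# ---------------------------------------------------------------------------

def _glucose_phase_end(
    ts: CultureTimeSeries,
    endpoint: Optional[Endpoint],
    glucose_depleted_gL: float = GLUCOSE_DEPLETED_GL,
) -> float:
    """Time at which growth on glucose alone ends."""
    if endpoint is not None and endpoint.rule is EndpointRule.GLUCOSE_DEPLETED:
        return endpoint.t_end_h
    s = ts.samples
    t = s["time_h"].to_numpy(dtype=float)
    glucose = s["glucose_gL"].to_numpy(dtype=float)
    below = np.flatnonzero(glucose <= glucose_depleted_gL)
    if below.size == 0:
        return float(t[-1])
    i = int(below[0])
    if i == 0:
        return float(t[0])
    g0, g1 = glucose[i - 1], glucose[i]
    frac = (g0 - glucose_depleted_gL) / (g0 - g1) if g0 > g1 else 1.0
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def respiration_ratio(
    ts: CultureTimeSeries,
    endpoint: Optional[Endpoint] = None,
    glucose_depleted_gL: float = GLUCOSE_DEPLETED_GL,
) -> float:
    """Mol CO2 evolved per mol O2 consumed during growth on glucose.

    Near 1 for purely respiratory growth; far above 1 when fermentation
    adds CO2 without O2 uptake.  Returns ``inf`` when essentially no O2
    was consumed (fermentation-only data).
    """
    s = ts.samples
    for col in ("co2_cum_mol_per_L", "o2_cum_mol_per_L"):
        if col not in s.columns:
            raise ValueError(f"time series lacks gas column {col!r}")
    t_end = _glucose_phase_end(ts, endpoint, glucose_depleted_gL)
    dco2 = _interp(ts, "co2_cum_mol_per_L", t_end) - float(
        s["co2_cum_mol_per_L"].iloc[0])
    do2 = _interp(ts, "o2_cum_mol_per_L", t_end) - float(
        s["o2_cum_mol_per_L"].iloc[0])
    if do2 < 1e-6:
        return math.inf
    return dco2 / do2


def carbon_balance(ts: CultureTimeSeries, endpoint: Endpoint) -> float:
    """C-mol of products (metabolites + biomass + CO2) per C-mol of
    glucose consumed, both measured from the first sample to the
    endpoint.  Close to 1.0 for a carbon-closed experiment."""
    s = ts.samples
    if "co2_cum_mol_per_L" not in s.columns:
        raise ValueError("time series lacks the cumulative CO2 column")
    t_end = endpoint.t_end_h
    consumed = float(s["glucose_gL"].iloc[0]) - _interp(ts, "glucose_gL", t_end)
    if consumed <= 0:
        raise ValueError("no glucose consumed up to the endpoint")
    cmol_in = consumed / CARBON_MASS["glucose"]
    cmol_out = 0.0
    for product, column in PRODUCT_COLUMNS.items():
        delta = _interp(ts, column, t_end) - float(s[column].iloc[0])
        cmol_out += max(delta, 0.0) / CARBON_MASS[product]
    delta_x = _interp(ts, "dw_gL", t_end) - float(s["dw_gL"].iloc[0])
    cmol_out += max(delta_x, 0.0) / CARBON_MASS["biomass"]
    cmol_out += _interp(ts, "co2_cum_mol_per_L", t_end) - float(
        s["co2_cum_mol_per_L"].iloc[0])
    return cmol_out / cmol_in


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def extract_metrics(
    ts: CultureTimeSeries, config: ExtractionConfig | None = None
) -> PhenotypeMetrics:
    """Run the full extraction: window, mu, endpoint, yields, rates,
    respiration ratio and carbon balance, with QC flags."""
    config = config or ExtractionConfig()

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ValueError as exc:
            raise ValueError(f"{name}: {exc}") from exc

    if config.manual_window is not None:
        t0, t1 = config.manual_window
        mu = _stage("growth-rate fit", fit_growth_rate, ts, (t0, t1),
                    config.basis)
        n = int(((ts.samples["time_h"] >= t0)
                 & (ts.samples["time_h"] <= t1)).sum())
        window = ExponentialWindow(t0, t1, mu, math.nan, n,
                                   Basis(config.basis))
    else:
        window = _stage(
            "window detection", detect_exponential_window, ts, config.basis,
            config.min_points, config.r2_min,
            glucose_min_gL=config.window_glucose_min_gL,
            ethanol_detect_gL=config.ethanol_detect_gL,
        )
        mu = window.mu_per_h

    endpoint = _stage(
        "endpoint", determine_endpoint, ts, config.ethanol_detect_gL,
        config.glucose_depleted_gL,
        median_filter_ethanol=config.median_filter_ethanol,
    )
    yields = _stage("yields", compute_yields, ts, endpoint)
    rates = _stage("rates", compute_specific_rates, ts, window, mu)
    rq = _stage("respiration ratio", respiration_ratio, ts, endpoint,
                config.glucose_depleted_gL)
    balance = _stage("carbon balance", carbon_balance, ts, endpoint)

    flags: list[str] = []
    if not 0.9 <= balance <= 1.1:
        flags.append(f"carbon balance {balance:.3f} outside [0.9, 1.1]")
    if endpoint.mixed_metabolism:
        flags.append("mixed metabolism at ethanol maximum")
    return PhenotypeMetrics(
        yields=yields, rates=rates, mu_per_h=mu,
        respiration_ratio=rq, carbon_balance=balance,
        endpoint=endpoint, window=window, qc_flags=flags,
    )


def metrics_frame(named_metrics: dict[str, PhenotypeMetrics]) -> pd.DataFrame:
    """Tabulate extracted metrics (one row per run) in the layout of the
    packaged reference table, plus QC columns."""
    rows = []
    for name, m in named_metrics.items():
        rows.append({
            "species": name,
            "ethanol_yield": m.yields["ethanol"],
            "biomass_yield": m.yields["biomass"],
            "glc_cons_rate": m.rates["glucose"],
            "etoh_prod_rate": m.rates["ethanol"],
            "growth_rate": m.mu_per_h,
            "respiration_ratio": m.respiration_ratio,
            "carbon_balance": m.carbon_balance,
            "endpoint_h": m.endpoint.t_end_h,
            "endpoint_rule": m.endpoint.rule.value,
            "crabtree_positive": m.endpoint.crabtree_positive,
            "qc_flags": ";".join(m.qc_flags),
        })
    return pd.DataFrame(rows)
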