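"""Overflow-metabolism batch-culture simulator (synthetic data generator).

Generates aerobic batch fermentation time series with the structure seen
in real multi-species yeast screens: exponential growth on 2% glucose,
ethanol accumulation for Crabtree-positive phenotypes (respiratory
bottleneck + overflow), a diauxic shift to ethanol consumption, and
carbon-closed cumulative off-gas (CO2 produced, O2 consumed).

The model is a Sonnleitner–Käppeli-style respiratory-bottleneck model.
During growth on glucose the specific uptake follows Monod kinetics,
``q_S = qs_max * S / (Ks + S)``.  Uptake up to the respiratory capacity
``resp_cap`` is oxidized (biomass yield ``Yxs_ox``, respiratory quotient
fixed at 1.0); the excess overflows into fermentation (biomass yield
``Yxs_ferm``, ethanol yield ``Yes_ferm`` <= 0.511 g/g, one CO2 per
ethanol, no O2).  CO2 is computed as the carbon not fixed in biomass or
excreted products, so the model is carbon-closed by construction.  After
glucose depletion, phenotypes with ``ethanol_growth`` respire the
accumulated ethanol (Monod in ethanol, O2 from an electron balance on
ethanol and biomass).

Integration is fixed-step RK4 (default 0.01 h) with the glucose-depletion
event handled by linear sub-step blending, which keeps carbon closure to
well under 1%.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "BatchSimParams",
    "CultureTimeSeries",
    "TIMESERIES_COLUMNS",
    "PRESETS",
    "make_preset",
    "simulate_batch",
    "add_measurement_noise",
    "glucose_phase_mu",
    "glucose_phase_yields",
    "endpoint_yields",
    "ethanol_phase_mu",
    "write_timeseries_csv",
    "read_timeseries_csv",
]

# ---------------------------------------------------------------------------
# Shared stoichiometric constants (g per C-mol unless noted).
# Biomass is the standard ash-free yeast composition CH1.8O0.5N0.2.
# ---------------------------------------------------------------------------
MW_GLUCOSE_C = 30.03
MW_ETHANOL_C = 23.03
MW_GLYCEROL_C = 30.70
MW_ACETATE_C = 30.03
MW_BIOMASS_C = 24.6
MW_ETHANOL = 46.07         # g/mol
#: Degrees of reduction per C-mol (electrons transferable to O2).
GAMMA_ETHANOL = 6.0
GAMMA_BIOMASS = 4.2
#: Maximum theoretical ethanol yield on glucose, 2*46.07/180.16 g/g.
MAX_ETHANOL_YIELD = 0.511

TIMESERIES_COLUMNS = [
    "time_h", "dw_gL", "od600",
    "glucose_gL", "ethanol_gL", "glycerol_gL", "acetate_gL",
    "pyruvate_gL", "succinate_gL", "lactate_gL",
    "co2_cum_mol_per_L", "o2_cum_mol_per_L",
]

_CONC_COLUMNS = [
    "dw_gL", "od600", "glucose_gL", "ethanol_gL", "glycerol_gL",
    "acetate_gL", "pyruvate_gL", "succinate_gL", "lactate_gL",
]
_GAS_COLUMNS = ["co2_cum_mol_per_L", "o2_cum_mol_per_L"]

#: Glucose concentration below which the culture switches to the
#: ethanol (diauxic) phase, g/L.
GLUCOSE_SWITCH_GL = 0.05


@dataclass(frozen=True)
class BatchSimParams:
    """Kinetic parameters of one simulated batch fermentation."""

    qs_max: float          # max specific glucose uptake, g/gDW/h
    Ks: float              # glucose half-saturation, g/L
    resp_cap: float        # respiratory glucose capacity, g/gDW/h
    Yxs_ox: float          # respiratory biomass yield, gDW/g glucose
    Yxs_ferm: float        # fermentative biomass yield, gDW/g glucose
    Yes_ferm: float        # ethanol yield on overflowed glucose, g/g
    qe_max: float          # max specific ethanol uptake, g/gDW/h
    Ke: float              # ethanol half-saturation, g/L
    Yxe: float             # biomass yield on ethanol, gDW/g
    ethanol_growth: bool   # make-accumulate-consume vs no diauxic phase
    S0: float = 20.0       # initial glucose, g/L (2% w/v)
    X0: float = 0.02       # initial biomass, gDW/L
    duration_h: float = 48.0
    sample_interval_h: float = 0.5
    od_per_dw: float = 2.0  # OD600 units per gDW/L
    # Optional small by-product fluxes (g product per g overflowed
    # glucose) for robustness tests; real screens see only traces.
    Ygs_ferm: float = 0.0  # glycerol
    Yas_ferm: float = 0.0  # acetate
    dt_h: float = 0.01     # RK4 step

    def __post_init__(self) -> None:
        for name in ("qs_max", "Ks", "resp_cap", "Yxs_ox", "Yxs_ferm",
                     "Yes_ferm", "qe_max", "Ke", "Yxe", "S0", "X0",
                     "duration_h", "sample_interval_h", "od_per_dw",
                     "Ygs_ferm", "Yas_ferm", "dt_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.Yes_ferm > MAX_ETHANOL_YIELD:
            raise ValueError(
                f"Yes_ferm {self.Yes_ferm} exceeds the stoichiometric "
                f"maximum {MAX_ETHANOL_YIELD}"
            )
        # Carbon sanity on the fermentative branch: biomass + ethanol +
        # by-product carbon cannot exceed the glucose carbon.
        ferm_c = (self.Yxs_ferm / MW_BIOMASS_C
                  + self.Yes_ferm / MW_ETHANOL_C
                  + self.Ygs_ferm / MW_GLYCEROL_C
                  + self.Yas_ferm / MW_ACETATE_C)
        if ferm_c > 1.0 / MW_GLUCOSE_C + 1e-12:
            raise ValueError("fermentative yields exceed glucose carbon")
        if self.Yxs_ox / MW_BIOMASS_C > 1.0 / MW_GLUCOSE_C + 1e-12:
            raise ValueError("Yxs_ox exceeds glucose carbon")
        if self.Yxe / MW_BIOMASS_C > 1.0 / MW_ETHANOL_C + 1e-12:
            raise ValueError("Yxe exceeds ethanol carbon")


@dataclass
class CultureTimeSeries:
    """Sampled batch-culture trajectory plus provenance metadata."""

    samples: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TIMESERIES_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"time series is missing columns: {missing}")
        t = self.samples["time_h"].to_numpy()
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("time_h must be strictly increasing")

    def copy(self) -> "CultureTimeSeries":
        return CultureTimeSeries(self.samples.copy(), dict(self.metadata))

    def __len__(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# Presets: parameter sets whose extracted metrics fall in the three
# phenotype ranges seen across the Saccharomycetaceae screen.
# ---------------------------------------------------------------------------

def _preset_params() -> dict[str, BatchSimParams]:
    common = dict(Ks=0.1, Ke=0.1, S0=20.0, duration_h=48.0,
                  sample_interval_h=0.5)
    return {
        # S. cerevisiae-like: strong overflow, Y_E/S ~ 0.40, Y_X/S ~ 0.15.
        "strong_positive": BatchSimParams(
            qs_max=1.9, resp_cap=0.25, Yxs_ox=0.50, Yxs_ferm=0.10,
            Yes_ferm=0.46, qe_max=0.20, Yxe=0.55, ethanol_growth=True,
            X0=20.0 * 0.50 / 500.0, **common,
        ),
        # Lachancea-like: moderate overflow, Y_X/S ~ 0.29, Y_E/S ~ 0.25.
        "intermediate": BatchSimParams(
            qs_max=1.1, resp_cap=0.50, Yxs_ox=0.50, Yxs_ferm=0.12,
            Yes_ferm=0.45, qe_max=0.20, Yxe=0.55, ethanol_growth=True,
            X0=20.0 * 0.50 / 500.0, **common,
        ),
        # K. lactis-like: fully respiratory, no ethanol, Y_X/S ~ 0.55.
        "negative": BatchSimParams(
            qs_max=0.55, resp_cap=0.55, Yxs_ox=0.55, Yxs_ferm=0.0,
            Yes_ferm=0.0, qe_max=0.0, Yxe=0.0, ethanol_growth=False,
            X0=20.0 * 0.55 / 500.0, duration_h=36.0,
            Ks=0.1, Ke=0.1, S0=20.0, sample_interval_h=0.5,
        ),
    }


PRESETS = _preset_params()


def make_preset(phenotype: str) -> BatchSimParams:
    """Parameter preset for ``strong_positive``, ``intermediate`` or
    ``negative`` Crabtree phenotypes.

    Inocula follow standard screen practice: roughly 500-fold below the
    final biomass (``X0 = S0 * Yxs_ox / 500``) on 2% glucose.
    """
    try:
        return PRESETS[phenotype]
    except KeyError:
        raise ValueError(
            f"unknown phenotype {phenotype!r}; "
            f"expected one of {sorted(PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# Closed-form glucose/ethanol-phase quantities (used as oracles by the
# extraction tests and the acceptance checks).
# ---------------------------------------------------------------------------

def glucose_phase_mu(params: BatchSimParams) -> float:
    """Analytic specific growth rate on glucose at substrate saturation."""
    qs_ox = min(params.qs_max, params.resp_cap)
    qs_ferm = params.qs_max - qs_ox
    return params.Yxs_ox * qs_ox + params.Yxs_ferm * qs_ferm


def glucose_phase_yields(params: BatchSimParams) -> dict[str, float]:
    """Analytic instantaneous yields on glucose at saturation (g/g)."""
    qs_ox = min(params.qs_max, params.resp_cap)
    qs_ferm = params.qs_max - qs_ox
    qs = params.qs_max
    return {
        "biomass": glucose_phase_mu(params) / qs,
        "ethanol": params.Yes_ferm * qs_ferm / qs,
        "glycerol": params.Ygs_ferm * qs_ferm / qs,
        "acetate": params.Yas_ferm * qs_ferm / qs,
    }


def endpoint_yields(params: BatchSimParams, s_end: float) -> dict[str, float]:
    """Exact closed-form glucose-phase yields between ``S0`` and
    ``s_end`` (g/g), obtained by integrating the yield odes in the
    substrate coordinate.

    With ``r = resp_cap / qs_max`` and Monod uptake, the oxidized
    fraction of a unit of consumed glucose is ``r (Ks + S) / S``, so the
    per-product integrals reduce to ``dS`` and ``Ks ln(S0/s_end)``
    terms.  Valid while uptake exceeds the respiratory capacity down to
    ``s_end`` (true for the packaged fermentative presets); a fully
    respiratory parameterization returns the constant yields.
    """
    if s_end <= 0 or s_end >= params.S0:
        raise ValueError("s_end must lie strictly between 0 and S0")
    ds = params.S0 - s_end
    if params.resp_cap >= params.qs_max:  # never overflows
        return {"biomass": params.Yxs_ox, "ethanol": 0.0}
    r = params.resp_cap / params.qs_max
    log_term = params.Ks * math.log(params.S0 / s_end)
    oxidized_fraction = r * (ds + log_term) / ds
    ethanol = params.Yes_ferm * (1.0 - oxidized_fraction)
    biomass = (params.Yxs_ferm
               + (params.Yxs_ox - params.Yxs_ferm) * oxidized_fraction)
    return {"biomass": biomass, "ethanol": ethanol}


def ethanol_phase_mu(params: BatchSimParams) -> float:
    """Analytic specific growth rate on ethanol at saturation."""
    if not params.ethanol_growth:
        return 0.0
    return params.Yxe * params.qe_max


# ---------------------------------------------------------------------------
# ODE right-hand side and RK4 integration.
# State vector: (X biomass gDW/L, S glucose g/L, E ethanol g/L,
#                G glycerol g/L, A acetate g/L,
#                CO2 cumulative mol/L, O2 cumulative mol/L).
# ---------------------------------------------------------------------------

def _rates(params: BatchSimParams, state: tuple) -> tuple:
    X, S, E = state[0], state[1], state[2]
    if X <= 0.0:
        return (0.0,) * 7
    if S > GLUCOSE_SWITCH_GL:
        qs = params.qs_max * S / (params.Ks + S)
        qs_ox = min(qs, params.resp_cap)
        qs_ferm = qs - qs_ox
        mu = params.Yxs_ox * qs_ox + params.Yxs_ferm * qs_ferm
        qe_prod = params.Yes_ferm * qs_ferm
        qg = params.Ygs_ferm * qs_ferm
        qa = params.Yas_ferm * qs_ferm
        # All substrate carbon not fixed in biomass or excreted products
        # leaves as CO2 (C-mol == mol).
        co2 = (qs / MW_GLUCOSE_C - mu / MW_BIOMASS_C
               - qe_prod / MW_ETHANOL_C - qg / MW_GLYCEROL_C
               - qa / MW_ACETATE_C)
        # Fermentation adds one CO2 per ethanol and consumes no O2; the
        # respiratory remainder runs at RQ 1.0 (pure carbohydrate
        # oxidation), so O2 uptake equals the respiratory CO2.
        o2 = co2 - qe_prod / MW_ETHANOL
        return (mu * X, -qs * X, qe_prod * X, qg * X, qa * X,
                co2 * X, o2 * X)
    if params.ethanol_growth and E > 0.0:
        qe = params.qe_max * E / (params.Ke + E)
        mu = params.Yxe * qe
        co2 = qe / MW_ETHANOL_C - mu / MW_BIOMASS_C
        # Electron balance: electrons in consumed ethanol minus electrons
        # fixed in biomass go to O2 (4 electrons per O2).
        o2 = (qe / MW_ETHANOL_C * GAMMA_ETHANOL
              - mu / MW_BIOMASS_C * GAMMA_BIOMASS) / 4.0
        return (mu * X, 0.0, -qe * X, 0.0, 0.0, co2 * X, o2 * X)
    return (0.0,) * 7


def _rk4_step(params: BatchSimParams, state: tuple, dt: float) -> tuple:
    k1 = _rates(params, state)
    s2 = tuple(y + 0.5 * dt * k for y, k in zip(state, k1))
    k2 = _rates(params, s2)
    s3 = tuple(y + 0.5 * dt * k for y, k in zip(state, k2))
    k3 = _rates(params, s3)
    s4 = tuple(y + dt * k for y, k in zip(state, k3))
    k4 = _rates(params, s4)
    return tuple(
        y + dt / 6.0 * (a + 2.0 * b + 2.0 * c + d)
        for y, a, b, c, d in zip(state, k1, k2, k3, k4)
    )


def _integrate(params: BatchSimParams) -> Iterator[tuple[float, tuple]]:
    """Yield (time, state) at every RK4 step, handling the
    glucose-depletion event by linear sub-step blending."""
    dt = params.dt_h
    state = (params.X0, params.S0, 0.0, 0.0, 0.0, 0.0, 0.0)
    t = 0.0
    yield t, state
    n_steps = int(round(params.duration_h / dt))
    for i in range(n_steps):
        new = _rk4_step(params, state, dt)
        if not all(math.isfinite(v) for v in new):
            raise ArithmeticError(
                f"non-finite state at integration step {i} (t={t:.3f} h)"
            )
        if new[1] < 0.0:
            # Blend to the point where glucose hits zero, then continue
            # from the depleted state for the remainder of the step.
            prev_s = state[1]
            frac = prev_s / (prev_s - new[1]) if prev_s > new[1] else 0.0
            blended = tuple(
                y0 + frac * (y1 - y0) for y0, y1 in zip(state, new)
            )
            blended = (blended[0], 0.0) + blended[2:]
            rest = (1.0 - frac) * dt
            new = _rk4_step(params, blended, rest) if rest > 0 else blended
            if new[1] < 0.0:
                new = (new[0], 0.0) + new[2:]
        if new[2] < 0.0:  # ethanol exhausted within the step
            new = new[:2] + (0.0,) + new[3:]
        t += dt
        state = new
        yield t, state


def simulate_batch(params: BatchSimParams, seed: int = 0) -> CultureTimeSeries:
    """Integrate the batch model and sample it at ``sample_interval_h``.

    The trajectory itself is deterministic; ``seed`` is recorded in the
    metadata so noisy replicates derived from this run are traceable.
    """
    every = max(1, int(round(params.sample_interval_h / params.dt_h)))
    rows = []
    for i, (t, state) in enumerate(_integrate(params)):
        if i % every:
            continue
        X, S, E, G, A, CO2, O2 = state
        rows.append((t, X, params.od_per_dw * X, S, E, G, A,
                     0.0, 0.0, 0.0, CO2, O2))
    samples = pd.DataFrame(rows, columns=TIMESERIES_COLUMNS)
    meta = {"strain": "synthetic", "seed": int(seed), "noise_cv": 0.0,
            "params": params}
    return CultureTimeSeries(samples, meta)


def add_measurement_noise(
    ts: CultureTimeSeries, cv: float, seed: int = 0
) -> CultureTimeSeries:
    """Multiplicative lognormal measurement noise, mean 1, coefficient of
    variation ``cv``, independent per sample and channel.

    Concentration and biomass channels are perturbed directly; the
    cumulative off-gas channels stay smooth — noise is applied to their
    increments, which are then re-accumulated (gas analyzers integrate,
    they do not resample).  Deterministic given ``seed``; ``cv = 0``
    returns an identical copy.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    out = ts.copy()
    out.metadata["noise_cv"] = float(cv)
    out.metadata["noise_seed"] = int(seed)
    if cv == 0.0:
        return out
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv * cv))
    mu_ln = -0.5 * sigma * sigma  # mean-1 lognormal
    df = out.samples
    for col in _CONC_COLUMNS:
        factors = rng.lognormal(mu_ln, sigma, size=len(df))
        df[col] = np.clip(df[col].to_numpy() * factors, 0.0, None)
    for col in _GAS_COLUMNS:
        cum = df[col].to_numpy()
        inc = np.diff(cum, prepend=0.0)
        factors = rng.lognormal(mu_ln, sigma, size=len(inc))
        df[col] = np.cumsum(inc * factors)
    return out


# ---------------------------------------------------------------------------
# CSV dialect: "#"-prefixed metadata comments, then the canonical header.
# ---------------------------------------------------------------------------

def write_timeseries_csv(ts: CultureTimeSeries, path: str | Path | io.TextIOBase,
                         extra_header: dict | None = None) -> None:
    """Write the culture time series in the package's CSV dialect."""
    meta = dict(ts.metadata)
    meta.update(extra_header or {})
    lines = []
    for key, value in meta.items():
        if key == "params" and isinstance(value, BatchSimParams):
            value = ";".join(
                f"{f}={getattr(value, f)}" for f in value.__dataclass_fields__
            )
        lines.append(f"# {key}: {value}")
    body = ts.samples.to_csv(index=False, float_format="%.6g")
    text = "\n".join(lines) + ("\n" if lines else "") + body
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        Path(path).write_text(text)


def read_timeseries_csv(path: str | Path | io.TextIOBase) -> CultureTimeSeries:
    """Read a culture time-series CSV (comment headers allowed)."""
    if isinstance(path, io.TextIOBase):
        text = path.read()
    else:
        text = Path(path).read_text()
    meta: dict = {}
    data_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, value = stripped.partition(":")
                meta[key.strip()] = value.strip()
        elif line.strip():
            data_lines.append(line)
    frame = pd.read_csv(io.StringIO("\n".join(data_lines)))
    missing = [c for c in TIMESERIES_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(
            f"time-series CSV is missing columns: {', '.join(missing)}"
        )
    return CultureTimeSeries(frame[TIMESERIES_COLUMNS].astype(float), meta)
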