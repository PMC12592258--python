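"""Closed-form steady-state pharmacokinetics for periodic oral dosing.

The structural model is a linear two-compartment disposition model with
first-order absorption from a depot (no lag time), parameterized by apparent
(oral, dose-normalized) clearance and volumes.  Its single-dose solution is a
sum of exponentials ("macro-constants"); exact periodic steady state under any
repeating dose schedule follows by summing the geometric series of each
exponential term, so no ODE integration or run-in is ever needed.

With ``Q = 0`` (or a vanishing peripheral volume) the model reduces exactly to
the one-compartment Bateman form, which is kept as a first-class limit for
testing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StructuralParams",
    "DoseEvent",
    "Regimen",
    "ConcentrationGrid",
    "macro_constants",
    "single_dose_concentration",
    "css_concentrations",
    "css_profile",
    "steady_state_metrics_batch",
    "REGIMEN_PRESETS",
    "get_regimen",
    "load_regimen",
]

#: Relative gap below which the absorption rate constant is considered
#: degenerate with a disposition eigenvalue (removable singularity of the
#: macro-constant decomposition).
KA_MIN_REL_GAP = 1e-6

#: Available tablet strengths, mg.  240 = 3 x 80, so composable amounts are
#: exactly the positive multiples of 80 mg.
TABLET_STRENGTHS = (80.0, 240.0)


@dataclass(frozen=True)
class StructuralParams:
    """Apparent (oral-scale) PK parameters of one individual.

    cl : apparent clearance CL/F, L/h
    v1 : apparent central volume V1/F, L
    q  : apparent inter-compartmental clearance Q/F, L/h (0 -> one-compartment)
    v2 : apparent peripheral volume V2/F, L (0 -> one-compartment)
    ka : first-order absorption rate constant, 1/h
    f  : relative bioavailability fraction (fixed 1.0; only apparent
         parameters are identifiable from oral data)
    """

    cl: float
    v1: float
    q: float
    v2: float
    ka: float
    f: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "ka", "f"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"StructuralParams.{name} must be strictly positive")
        for name in ("q", "v2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"StructuralParams.{name} must be non-negative")

    @property
    def one_compartment(self) -> bool:
        """True when the peripheral compartment is absent (Q=0 or V2=0)."""
        return self.q == 0.0 or self.v2 == 0.0


@dataclass(frozen=True)
class DoseEvent:
    """A single oral dose inside one dosing period."""

    time_h: float
    amount_mg: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.amount_mg) or self.amount_mg <= 0:
            raise ValueError("dose amount must be strictly positive")
        if not np.isfinite(self.time_h) or self.time_h < 0:
            raise ValueError("dose time must be non-negative")

    @property
    def tablet_compatible(self) -> bool:
        """Whether the amount is composable from 80/240 mg tablets."""
        return abs(self.amount_mg / 80.0 - round(self.amount_mg / 80.0)) < 1e-9


@dataclass(frozen=True)
class Regimen:
    """A periodic dose schedule: `events` repeat every `period_h` hours."""

    period_h: float
    events: tuple[DoseEvent, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.period_h) or self.period_h <= 0:
            raise ValueError("regimen period must be strictly positive")
        if len(self.events) == 0:
            raise ValueError("regimen must contain at least one dose event")
        object.__setattr__(self, "events", tuple(self.events))
        times = [e.time_h for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose event times must be strictly increasing")
        if times[-1] >= self.period_h:
            raise ValueError("dose event times must lie in [0, period)")

    @property
    def dose_per_period_mg(self) -> float:
        return float(sum(e.amount_mg for e in self.events))

    @property
    def daily_dose_mg(self) -> float:
        """Average dose per 24 h."""
        return self.dose_per_period_mg * 24.0 / self.period_h

    @property
    def dosing_days_fraction(self) -> float:
        """Fraction of calendar days on which at least one dose is taken."""
        period_days = self.period_h / 24.0
        days_with_dose = len({int(e.time_h // 24.0) for e in self.events})
        return days_with_dose / period_days

    def scaled(self, alpha: float, label: str | None = None) -> "Regimen":
        """Return the regimen with every dose amount multiplied by `alpha`."""
        return Regimen(
            self.period_h,
            tuple(DoseEvent(e.time_h, e.amount_mg * alpha) for e in self.events),
            label if label is not None else f"{self.label}x{alpha:g}",
        )


#: Named regimens used throughout: the approved dose and the genotype-guided
#: alternatives (including the alternating-day first dose reduction).
REGIMEN_PRESETS: dict[str, Regimen] = {
    "240QD": Regimen(24.0, (DoseEvent(0.0, 240.0),), "240QD"),
    "160QD": Regimen(24.0, (DoseEvent(0.0, 160.0),), "160QD"),
    "240QOD": Regimen(48.0, (DoseEvent(0.0, 240.0),), "240QOD"),
    "80_160_ALT": Regimen(48.0, (DoseEvent(0.0, 80.0), DoseEvent(24.0, 160.0)), "80_160_ALT"),
}


def get_regimen(label: str) -> Regimen:
    try:
        return REGIMEN_PRESETS[label]
    except KeyError:
        raise KeyError(
            f"unknown regimen {label!r}; available presets: {sorted(REGIMEN_PRESETS)}"
        ) from None


def load_regimen(path: str | Path) -> Regimen:
    """Read a regimen from a YAML/JSON config: {period: h, doses: [{time, amount}], label}."""
    import yaml

    text = Path(path).read_text()
    doc = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    events = tuple(DoseEvent(float(d["time"]), float(d["amount"])) for d in doc["doses"])
    return Regimen(float(doc["period"]), events, str(doc.get("label", Path(path).stem)))


@dataclass
class ConcentrationGrid:
    """A sampled steady-state concentration-time profile (mg/L over hours)."""

    times: np.ndarray
    concentrations: np.ndarray
    period_h: float

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"time_h": self.times, "conc_mg_per_L": self.concentrations}
        ).to_csv(path, index=False)


def _resolve_ka(ka: float, rates: Iterable[float]) -> float:
    """Nudge ka off a disposition eigenvalue (removable singularity)."""
    for lam in rates:
        if abs(ka - lam) / lam < KA_MIN_REL_GAP:
            warnings.warn(
                f"ka={ka:g} within {KA_MIN_REL_GAP:g} of eigenvalue {lam:g}; "
                "perturbing ka to avoid the degenerate (confluent) form",
                RuntimeWarning,
                stacklevel=3,
            )
            ka = ka * (1.0 + 2.0 * KA_MIN_REL_GAP)
    return ka


def macro_constants(params: StructuralParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit-dose exponential decomposition of the single-dose profile.

    Returns (coefficients, rates) such that after a dose D at t=0

        C(t) = D * F * sum_i coefficients[i] * exp(-rates[i] * t).

    Coefficients sum to zero (oral input: C(0)=0) and all rates are positive.
    For a one-compartment model (Q=0 or V2=0) exactly two terms are returned
    (the Bateman equation); otherwise three.
    """
    if params.one_compartment:
        ke = params.cl / params.v1
        ka = _resolve_ka(params.ka, (ke,))
        a = ka / (params.v1 * (ka - ke))
        return np.array([a, -a]), np.array([ke, ka])

    k10 = params.cl / params.v1
    k12 = params.q / params.v1
    k21 = params.q / params.v2
    s = k10 + k12 + k21
    disc = np.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = k10 * k21 / alpha  # product form: stable as the roots separate
    ka = _resolve_ka(params.ka, (alpha, beta))
    a = ka / params.v1 * (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    b = ka / params.v1 * (k21 - beta) / ((ka - beta) * (alpha - beta))
    c = ka / params.v1 * (k21 - ka) / ((alpha - ka) * (beta - ka))
    return np.array([a, b, c]), np.array([alpha, beta, ka])


def single_dose_concentration(
    params: StructuralParams, dose_mg: float, times: np.ndarray
) -> np.ndarray:
    """Concentration (mg/L) after a single oral dose at t=0."""
    coefs, rates = macro_constants(params)
    t = np.asarray(times, dtype=float)
    return dose_mg * params.f * np.einsum("i,it->t", coefs, np.exp(-np.outer(rates, t)))


def css_concentrations(
    params: StructuralParams, regimen: Regimen, times: np.ndarray
) -> np.ndarray:
    """Exact periodic steady-state concentration at arbitrary times.

    Each dose event contributes its single-dose exponentials accumulated over
    the infinite dosing history: a term A*exp(-lam*tau) becomes
    A*exp(-lam*((t - t_event) mod T)) / (1 - exp(-lam*T)).
    """
    coefs, rates = macro_constants(params)
    t = np.asarray(times, dtype=float)
    acc = 1.0 - np.exp(-rates * regimen.period_h)
    out = np.zeros_like(t)
    for ev in regimen.events:
        tau = np.mod(t - ev.time_h, regimen.period_h)
        out += ev.amount_mg * params.f * np.einsum(
            "i,it->t", coefs / acc, np.exp(-np.outer(rates, tau))
        )
    return out


def _profile_times(regimen: Regimen, window_h: float, grid_step_h: float) -> np.ndarray:
    grid = np.arange(0.0, window_h + 0.5 * grid_step_h, grid_step_h)
    event_times = [
        k * regimen.period_h + ev.time_h
        for ev in regimen.events
        for k in range(int(np.ceil(window_h / regimen.period_h)) + 1)
    ]
    event_times = [t for t in event_times if t <= window_h]
    return np.unique(np.concatenate([grid, np.asarray(event_times)]))


def css_profile(
    params: StructuralParams,
    regimen: Regimen,
    window_h: float = 168.0,
    grid_step_h: float = 0.1,
) -> ConcentrationGrid:
    """Steady-state profile over a weekly window.

    The time grid always includes the exact scheduled dose times, where the
    (continuous) concentration equals the pre-dose value, so troughs read off
    the profile are not grid-limited.
    """
    if grid_step_h <= 0:
        raise ValueError("grid_step_h must be positive")
    times = _profile_times(regimen, window_h, grid_step_h)
    return ConcentrationGrid(times, css_concentrations(params, regimen, times), regimen.period_h)


def steady_state_metrics_batch(
    cl: np.ndarray,
    v1: np.ndarray,
    q: np.ndarray,
    v2: np.ndarray,
    ka: np.ndarray,
    regimen: Regimen,
    f: float = 1.0,
    grid_step_h: float = 0.25,
    chunk: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (Ctrough, Caverage) at steady state for arrays of individuals.

    Ctrough is the minimum of the periodic profile over one period evaluated on
    a grid that includes the exact pre-dose times (where the minimum of an
    absorption-elimination profile lies); by periodicity this equals the
    weekly minimum.  Caverage is the exact per-period time average
    (dose per period) * F / (CL * period).
    """
    cl, v1, q, v2, ka = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (cl, v1, q, v2, ka))
    )
    if np.any(q <= 0.0) or np.any(v2 <= 0.0):
        raise ValueError("batch path requires a peripheral compartment (q, v2 > 0)")
    T = regimen.period_h
    times = _profile_times(regimen, T, grid_step_h)

    n = cl.shape[0]
    trough = np.empty(n)
    for lo in range(0, n, chunk):
        sl = slice(lo, min(lo + chunk, n))
        k10 = cl[sl] / v1[sl]
        k12 = q[sl] / v1[sl]
        k21 = q[sl] / v2[sl]
        s = k10 + k12 + k21
        disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
        alpha = 0.5 * (s + disc)
        beta = k10 * k21 / alpha
        kab = ka[sl].copy()
        for lam in (alpha, beta):
            bad = np.abs(kab - lam) / lam < KA_MIN_REL_GAP
            if np.any(bad):
                kab[bad] *= 1.0 + 2.0 * KA_MIN_REL_GAP
        a = kab / v1[sl] * (k21 - alpha) / ((kab - alpha) * (beta - alpha))
        b = kab / v1[sl] * (k21 - beta) / ((kab - beta) * (alpha - beta))
        c = kab / v1[sl] * (k21 - kab) / ((alpha - kab) * (beta - kab))
        coefs = np.stack([a, b, c])  # (3, m)
        rates = np.stack([alpha, beta, kab])
        acc = coefs / (1.0 - np.exp(-rates * T))  # (3, m)
        conc = np.zeros((sl.stop - sl.start, times.size))
        for ev in regimen.events:
            tau = np.mod(times - ev.time_h, T)  # (t,)
            # (m, t) accumulation: sum_i acc[i, m] * exp(-rates[i, m] * tau[t])
            conc += ev.amount_mg * f * np.einsum(
                "im,imt->mt", acc, np.exp(-rates[:, :, None] * tau[None, None, :])
            )
        trough[sl] = conc.min(axis=1)
    caverage = regimen.dose_per_period_mg * f / (cl * T)
    return trough, caverage
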