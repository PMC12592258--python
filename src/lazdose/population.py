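"""Virtual-cohort generation for the lazertinib dosing simulation.

Patients are sampled with log-normal body weight (geometric mean 70 kg, 20%
arithmetic CV), a 1:1 sex ratio, a fixed GSTM1 genotype per scenario, and
log-normal inter-individual random effects on PK parameters.  Individual
structural parameters follow a conventional allometric covariate model on the
population-typical values, with the GSTM1-null genotype acting as a fractional
multiplier on clearance.  Sex, ethnicity, and pretreatment hooks exist but
default to neutral (reference) multipliers: only non-Japanese treatment-naive
patients are simulated, and no effect magnitudes are available for the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .pk import StructuralParams

__all__ = [
    "GENOTYPES",
    "CovariateModel",
    "IIVModel",
    "TypicalModel",
    "VirtualPatient",
    "individualize",
    "sample_cohort",
    "sample_cohort_arrays",
    "cohort_frame",
]

GENOTYPES = ("null", "non-null")


def _check_genotype(genotype: str) -> str:
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown GSTM1 genotype {genotype!r}; expected one of {GENOTYPES}")
    return genotype


def lognormal_sigma(cv: float) -> float:
    """Log-scale SD of a log-normal with the given arithmetic CV."""
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass(frozen=True)
class CovariateModel:
    """Covariate distribution of the simulated population."""

    weight_gm: float = 70.0       # kg, geometric mean
    weight_cv: float = 0.20       # arithmetic CV of log-normal weight
    sex_prob_female: float = 0.5
    ethnicity: str = "non-Japanese"
    pretreatment: str = "treatment-naive"

    def __post_init__(self) -> None:
        if self.weight_gm <= 0:
            raise ValueError("weight_gm must be positive")
        if self.weight_cv < 0:
            raise ValueError("weight_cv must be non-negative")
        if not 0.0 <= self.sex_prob_female <= 1.0:
            raise ValueError("sex_prob_female must lie in [0, 1]")


@dataclass(frozen=True)
class IIVModel:
    """Log-normal inter-individual variability (SDs of log-scale random effects).

    omega_cl acts on clearance, omega_v on central volume, omega_q on
    inter-compartmental clearance.  omega_q carries the disposition-shape
    variability that trough concentrations exhibit on top of the clearance
    variability shared with Caverage (see docs/methods.md).
    """

    omega_cl: float = 0.0
    omega_v: float = 0.0
    omega_q: float = 0.0
    corr_cl_v: float = 0.0

    def __post_init__(self) -> None:
        for name in ("omega_cl", "omega_v", "omega_q"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not -1.0 <= self.corr_cl_v <= 1.0:
            raise ValueError("corr_cl_v must lie in [-1, 1]")

    def covariance(self) -> np.ndarray:
        """2x2 covariance of (eta_CL, eta_V); must be positive semi-definite."""
        c = self.corr_cl_v * self.omega_cl * self.omega_v
        return np.array(
            [[self.omega_cl**2, c], [c, self.omega_v**2]]
        )


@dataclass(frozen=True)
class TypicalModel:
    """Population-typical PK parameters plus covariate and variability model."""

    tvcl_nonnull: float           # L/h, typical CL/F for GSTM1 non-null, 70 kg
    gstm1_cl_fraction: float      # multiplier on CL for the null genotype (<1)
    tvv1: float                   # L
    tvq: float                    # L/h
    tvv2: float                   # L
    tvka: float                   # 1/h
    allo_cl: float = 0.75         # allometric exponent, clearances
    allo_v: float = 1.0           # allometric exponent, volumes
    ref_weight: float = 70.0      # kg
    sex_effect_female: float = 1.0        # multiplicative hook, neutral
    ethnicity_effect: float = 1.0         # multiplicative hook, neutral
    pretreatment_effect: float = 1.0      # multiplicative hook, neutral
    iiv: IIVModel = field(default_factory=IIVModel)

    def __post_init__(self) -> None:
        for name in ("tvcl_nonnull", "tvv1", "tvq", "tvv2", "tvka", "ref_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.gstm1_cl_fraction < 1.0:
            raise ValueError("gstm1_cl_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "tvcl_nonnull", "gstm1_cl_fraction", "tvv1", "tvq", "tvv2", "tvka",
                "allo_cl", "allo_v", "ref_weight",
                "sex_effect_female", "ethnicity_effect", "pretreatment_effect",
            )
        }
        d["iiv"] = {
            "omega_cl": self.iiv.omega_cl,
            "omega_v": self.iiv.omega_v,
            "omega_q": self.iiv.omega_q,
            "corr_cl_v": self.iiv.corr_cl_v,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TypicalModel":
        d = dict(d)
        iiv = IIVModel(**d.pop("iiv"))
        return cls(iiv=iiv, **d)


@dataclass(frozen=True)
class VirtualPatient:
    """One sampled individual with derived structural parameters."""

    patient_id: int
    weight: float
    sex: str                      # "F" or "M"
    genotype: str                 # "null" or "non-null"
    eta_cl: float
    eta_v: float
    eta_q: float
    params: StructuralParams


def individualize(
    typical: TypicalModel,
    weight: float,
    sex: str,
    genotype: str,
    eta_cl: float = 0.0,
    eta_v: float = 0.0,
    eta_q: float = 0.0,
) -> StructuralParams:
    """Map covariates and random effects to one individual's parameters.

    CL = TVCL * (W/70)^0.75 * gstm1_fraction[genotype] * covariate hooks * e^eta_CL
    V1 = TVV1 * (W/70)^1.0 * e^eta_V ; Q = TVQ * (W/70)^0.75 * e^eta_Q ;
    V2 = TVV2 * (W/70)^1.0 ; ka = TVKA.
    """
    _check_genotype(genotype)
    if weight <= 0:
        raise ValueError("weight must be positive")
    w = weight / typical.ref_weight
    gen_frac = typical.gstm1_cl_fraction if genotype == "null" else 1.0
    sex_frac = typical.sex_effect_female if sex == "F" else 1.0
    cl = (
        typical.tvcl_nonnull
        * w**typical.allo_cl
        * gen_frac
        * sex_frac
        * typical.ethnicity_effect
        * typical.pretreatment_effect
        * np.exp(eta_cl)
    )
    v1 = typical.tvv1 * w**typical.allo_v * np.exp(eta_v)
    q = typical.tvq * w**typical.allo_cl * np.exp(eta_q)
    v2 = typical.tvv2 * w**typical.allo_v
    return StructuralParams(cl=cl, v1=v1, q=q, v2=v2, ka=typical.tvka)


def sample_cohort_arrays(
    n: int,
    rng: np.random.Generator | int,
    cov: CovariateModel,
    genotype: str,
    typical: TypicalModel,
) -> dict[str, np.ndarray]:
    """Vectorized cohort draw; returns covariates, etas, and parameter arrays.

    Weights are i.i.d. log-normal with geometric mean ``weight_gm`` and
    arithmetic CV ``weight_cv``; sexes i.i.d. Bernoulli; (eta_CL, eta_V) from
    the IIV covariance and eta_Q independent.  Draws are made in a fixed order
    so that identical seeds give bitwise-identical cohorts.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    _check_genotype(genotype)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    weight = cov.weight_gm * np.exp(
        rng.normal(0.0, lognormal_sigma(cov.weight_cv), n)
    )
    female = rng.random(n) < cov.sex_prob_female
    # explicit Cholesky-style construction (robust to zero omegas)
    z1, z2 = rng.standard_normal(n), rng.standard_normal(n)
    rho = typical.iiv.corr_cl_v
    eta_clv = np.column_stack(
        [
            typical.iiv.omega_cl * z1,
            typical.iiv.omega_v * (rho * z1 + np.sqrt(1.0 - rho * rho) * z2),
        ]
    )
    eta_q = (
        rng.normal(0.0, typical.iiv.omega_q, n)
        if typical.iiv.omega_q > 0
        else np.zeros(n)
    )

    w = weight / typical.ref_weight
    gen_frac = typical.gstm1_cl_fraction if genotype == "null" else 1.0
    sex_frac = np.where(female, typical.sex_effect_female, 1.0)
    cl = (
        typical.tvcl_nonnull
        * w**typical.allo_cl
        * gen_frac
        * sex_frac
        * typical.ethnicity_effect
        * typical.pretreatment_effect
        * np.exp(eta_clv[:, 0])
    )
    return {
        "weight": weight,
        "female": female,
        "eta_cl": eta_clv[:, 0],
        "eta_v": eta_clv[:, 1],
        "eta_q": eta_q,
        "cl": cl,
        "v1": typical.tvv1 * w**typical.allo_v * np.exp(eta_clv[:, 1]),
        "q": typical.tvq * w**typical.allo_cl * np.exp(eta_q),
        "v2": typical.tvv2 * w**typical.allo_v,
        "ka": np.full(n, typical.tvka),
    }


def sample_cohort(
    n: int,
    seed: int | np.random.Generator,
    cov: CovariateModel,
    genotype: str,
    typical: TypicalModel,
) -> list[VirtualPatient]:
    """Sample `n` virtual patients of one genotype (object API over the arrays)."""
    arr = sample_cohort_arrays(n, seed, cov, genotype, typical)
    return [
        VirtualPatient(
            patient_id=i,
            weight=float(arr["weight"][i]),
            sex="F" if arr["female"][i] else "M",
            genotype=genotype,
            eta_cl=float(arr["eta_cl"][i]),
            eta_v=float(arr["eta_v"][i]),
            eta_q=float(arr["eta_q"][i]),
            params=StructuralParams(
                cl=float(arr["cl"][i]),
                v1=float(arr["v1"][i]),
                q=float(arr["q"][i]),
                v2=float(arr["v2"][i]),
                ka=float(arr["ka"][i]),
            ),
        )
        for i in range(n)
    ]


def cohort_frame(patients: Sequence[VirtualPatient]) -> pd.DataFrame:
    """Patient-level table (CSV-exportable) of covariates and parameters."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "weight_kg": [p.weight for p in patients],
            "sex": [p.sex for p in patients],
            "genotype": [p.genotype for p in patients],
            "eta_CL": [p.eta_cl for p in patients],
            "eta_V": [p.eta_v for p in patients],
            "eta_Q": [p.eta_q for p in patients],
            "CL": [p.params.cl for p in patients],
            "V1": [p.params.v1 for p in patients],
            "Q": [p.params.q for p in patients],
            "V2": [p.params.v2 for p in patients],
            "ka": [p.params.ka for p in patients],
        }
    )
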