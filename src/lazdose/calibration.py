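"""Recover a working population model from published exposure summaries.

The regulatory lazertinib population-PK model's parameter values are not
public; only simulated exposure summaries are (geometric mean and %CV of
steady-state Ctrough and Caverage per genotype/regimen, from Monte Carlo
cohorts of 70-kg-centred virtual patients).  This module inverts those
summaries into a working :class:`~lazdose.population.TypicalModel`:

1. Typical clearances come in closed form from the Caverage geometric means
   (Caverage = dose rate / CL), giving the non-null CL/F and the GSTM1-null
   clearance fraction.
2. The clearance IIV comes in closed form from the Caverage %CV by log-variance
   subtraction of the allometric weight contribution.
3. Disposition parameters (V1, Q, V2, ka) are fitted by bounded multi-start
   least squares to three trough geometric means (non-null 240 QD, null 240 QD,
   null 240 QOD); the null 160 QD column is held out as a pure prediction.
4. Shape variability (omega_V, omega_Q) is fitted by Monte Carlo to the four
   trough %CVs with common random numbers.
5. Because the trough is nonlinear in the random effects, the cohort geometric
   mean sits a few percent below the typical-individual trough; an outer loop
   re-adjusts the typical-scale trough targets until the *simulated population*
   geometric means match the published ones.

Only the predicted exposure surface is identifiable — not the disposition
parameters themselves, which are known to be non-unique along a V1/V2 tradeoff.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.optimize import least_squares, minimize

from .pk import Regimen, StructuralParams, css_concentrations, _profile_times, get_regimen
from .population import CovariateModel, IIVModel, TypicalModel, lognormal_sigma
from . import pk

__all__ = [
    "ScenarioTarget",
    "CalibrationTargets",
    "CalibrationResult",
    "CalibrationError",
    "load_targets",
    "clearances_from_caverage",
    "typical_trough",
    "fit_disposition",
    "fit_iiv",
    "calibrate",
]

#: Bounded search region for the disposition fit (apparent units).
DISPOSITION_BOUNDS = {
    "v1": (20.0, 1000.0),
    "q": (1.0, 100.0),
    "v2": (100.0, 50000.0),
    "ka": (0.05, 3.0),
}

#: Scenarios whose trough geometric means are calibration inputs; the null
#: 160 QD trough is dose-linear in the null 240 QD one and is held out.
CALIBRATION_TROUGH_SCENARIOS = (
    ("non-null", "240QD"),
    ("null", "240QD"),
    ("null", "240QOD"),
)


class CalibrationError(RuntimeError):
    """Calibration failed to converge; carries optimizer diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class ScenarioTarget:
    """Published GM/%CV pair for both metrics in one genotype x regimen cell."""

    genotype: str
    regimen: str
    ctrough_gm: float
    ctrough_cv_pct: float
    caverage_gm: float
    caverage_cv_pct: float

    def __post_init__(self) -> None:
        for name in ("ctrough_gm", "ctrough_cv_pct", "caverage_gm", "caverage_cv_pct"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"target cell {name} for ({self.genotype}, {self.regimen}) "
                    f"must be positive, got {v!r}"
                )


@dataclass(frozen=True)
class CalibrationTargets:
    """The full calibration surface: four scenario cells plus the threshold."""

    scenarios: tuple[ScenarioTarget, ...]
    threshold_mg_per_l: float = 0.0568
    price_per_dosing_day_usd: float = 728.0

    def __post_init__(self) -> None:
        if self.threshold_mg_per_l <= 0:
            raise ValueError("threshold must be positive")
        object.__setattr__(self, "scenarios", tuple(self.scenarios))
        for s in self.scenarios:
            get_regimen(s.regimen)  # must resolve

    def cell(self, genotype: str, regimen: str) -> ScenarioTarget:
        for s in self.scenarios:
            if s.genotype == genotype and s.regimen == regimen:
                return s
        raise KeyError(f"no target cell for ({genotype}, {regimen})")

    def sha256(self) -> str:
        doc = [
            [s.genotype, s.regimen, s.ctrough_gm, s.ctrough_cv_pct, s.caverage_gm, s.caverage_cv_pct]
            for s in self.scenarios
        ]
        payload = json.dumps([doc, self.threshold_mg_per_l], sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def load_targets(path: str | Path | None = None) -> CalibrationTargets:
    """Load targets from JSON (default: the packaged reference values)."""
    if path is None:
        text = resources.files("lazdose.data").joinpath("exposure_targets.json").read_text()
    else:
        text = Path(path).read_text()
    try:
        doc = json.loads(text)
        scenarios = tuple(
            ScenarioTarget(
                genotype=s["genotype"],
                regimen=s["regimen"],
                ctrough_gm=float(s["ctrough_gm"]),
                ctrough_cv_pct=float(s["ctrough_cv_pct"]),
                caverage_gm=float(s["caverage_gm"]),
                caverage_cv_pct=float(s["caverage_cv_pct"]),
            )
            for s in doc["scenarios"]
        )
        return CalibrationTargets(
            scenarios=scenarios,
            threshold_mg_per_l=float(doc["threshold_mg_per_l"]),
            price_per_dosing_day_usd=float(doc.get("price_per_dosing_day_usd", 728.0)),
        )
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed targets file: {exc}") from exc


@dataclass
class CalibrationResult:
    """Calibrated model plus residuals and provenance."""

    typical: TypicalModel
    residuals: dict[str, float]
    diagnostics: dict

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "model": self.typical.to_dict(),
            "residuals": self.residuals,
            "diagnostics": _jsonable(self.diagnostics),
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationResult":
        doc = json.loads(Path(path).read_text())
        return cls(
            typical=TypicalModel.from_dict(doc["model"]),
            residuals=doc["residuals"],
            diagnostics=doc["diagnostics"],
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def clearances_from_caverage(daily_dose_mg: float, caverage_gm: float) -> float:
    """Closed-form apparent clearance (L/h) from Caverage = daily dose / (CL * 24)."""
    if daily_dose_mg <= 0 or caverage_gm <= 0:
        raise ValueError("daily dose and Caverage must be positive")
    return daily_dose_mg / (24.0 * caverage_gm)


def typical_trough(
    cl: float, v1: float, q: float, v2: float, ka: float, regimen: Regimen,
    grid_step_h: float = 0.25,
) -> float:
    """Steady-state trough of one individual: periodic minimum over one period
    on a grid that includes the exact pre-dose times."""
    params = StructuralParams(cl=cl, v1=v1, q=q, v2=v2, ka=ka)
    times = _profile_times(regimen, regimen.period_h, grid_step_h)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.min(css_concentrations(params, regimen, times)))


def fit_disposition(
    trough_targets: dict[tuple[str, str], float],
    cl_by_genotype: dict[str, float],
    seed: int = 0,
    n_starts: int = 12,
    x0: np.ndarray | None = None,
    one_compartment: bool = False,
    ka_penalty_weight: float = 0.003,
    ka_penalty_center: float = 0.4,
    anchor_weight: float = 0.0,
    strict: bool = True,
) -> tuple[dict[str, float], dict]:
    """Bounded multi-start least squares of (V1, Q, V2, ka) on log-troughs.

    ``trough_targets`` maps (genotype, regimen label) to the typical-scale
    trough target in mg/L.  Clearances are fixed inputs.  A weak penalty keeps
    ka away from the bounds where the fit is otherwise indifferent.  With
    ``one_compartment=True`` the peripheral compartment is removed (used only
    to demonstrate infeasibility of the reduced model).

    The fit is underdetermined (four unknowns, three targets); a positive
    ``anchor_weight`` adds a weak pull toward ``x0`` in log space so that
    warm-started refits select the nearest solution on the feasible manifold
    instead of hopping between equivalent basins.
    """
    keys = sorted(trough_targets)
    regs = {k: get_regimen(k[1]) for k in keys}
    log_targets = np.log([trough_targets[k] for k in keys])

    if one_compartment:
        names = ["v1", "ka"]
        lb = np.log([DISPOSITION_BOUNDS["v1"][0], DISPOSITION_BOUNDS["ka"][0]])
        ub = np.log([20000.0, DISPOSITION_BOUNDS["ka"][1]])
    else:
        names = ["v1", "q", "v2", "ka"]
        lb = np.log([DISPOSITION_BOUNDS[n][0] for n in names])
        ub = np.log([DISPOSITION_BOUNDS[n][1] for n in names])

    def residuals(x: np.ndarray) -> np.ndarray:
        vals = dict(zip(names, np.exp(x)))
        q = 0.0 if one_compartment else vals["q"]
        v2 = 0.0 if one_compartment else vals["v2"]
        preds = []
        for k in keys:
            genotype, _ = k
            tr = typical_trough(
                cl_by_genotype[genotype], vals["v1"], q, v2, vals["ka"], regs[k]
            )
            preds.append(tr)
        preds = np.asarray(preds)
        if np.any(~np.isfinite(preds)) or np.any(preds <= 0):
            return np.full(len(keys) + 1, 1e3)
        pen = [ka_penalty_weight * (np.log(vals["ka"]) - np.log(ka_penalty_center))]
        if anchor_weight > 0.0 and x0 is not None:
            pen.extend(anchor_weight * (x - np.log(np.asarray(x0, dtype=float))))
        return np.concatenate([np.log(preds) - log_targets, pen])

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    if x0 is not None:
        starts.append(np.clip(np.log(np.asarray(x0, dtype=float)), lb, ub))
    while len(starts) < n_starts:
        starts.append(rng.uniform(lb, ub))

    trace = []
    best = None
    for i, s0 in enumerate(starts):
        try:
            sol = least_squares(residuals, s0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
        except Exception as exc:  # pragma: no cover - optimizer hiccups
            trace.append({"start": i, "error": str(exc)})
            continue
        fit_cost = float(np.sum(sol.fun[: len(keys)] ** 2))
        trace.append({"start": i, "cost": fit_cost, "x": np.exp(sol.x).tolist()})
        if best is None or fit_cost < best[0]:
            best = (fit_cost, sol)

    if best is None:
        raise CalibrationError("disposition fit failed from every start", {"trace": trace})
    _, sol = best
    vals = dict(zip(names, np.exp(sol.x)))
    rel_err = np.abs(np.exp(sol.fun[: len(keys)]) - 1.0)
    bounds_hit = {
        n: bool(np.isclose(sol.x[j], lb[j], atol=1e-6) or np.isclose(sol.x[j], ub[j], atol=1e-6))
        for j, n in enumerate(names)
    }
    diag = {
        "targets": {f"{g}:{r}": trough_targets[(g, r)] for g, r in keys},
        "max_rel_err": float(rel_err.max()),
        "rel_err": {f"{g}:{r}": float(e) for (g, r), e in zip(keys, rel_err)},
        "bounds_hit": bounds_hit,
        "seed": seed,
        "trace": trace,
    }
    if strict and not one_compartment and rel_err.max() > 0.02:
        raise CalibrationError(
            f"no disposition start converged: max trough residual "
            f"{rel_err.max():.2%} exceeds 2%",
            diag,
        )
    result = {"v1": float(vals["v1"]), "ka": float(vals["ka"])}
    result["q"] = 0.0 if one_compartment else float(vals["q"])
    result["v2"] = 0.0 if one_compartment else float(vals["v2"])
    return result, diag


def solve_omega_cl(caverage_cv_pct: float, weight_cv: float, allo_cl: float = 0.75) -> float:
    """Closed-form clearance IIV from the Caverage %CV.

    Log-variances add for the product of independent log-normals:
    ln(1+CV_total^2) = omega_CL^2 + allo_cl^2 * ln(1+CV_weight^2).
    """
    total = np.log1p((caverage_cv_pct / 100.0) ** 2)
    weight_part = allo_cl**2 * np.log1p(weight_cv**2)
    if total <= weight_part:
        raise ValueError(
            "Caverage CV target is smaller than the weight-allometry contribution"
        )
    return float(np.sqrt(total - weight_part))


def _trough_samples(
    typical: TypicalModel,
    cov: CovariateModel,
    genotype: str,
    regimen: Regimen,
    draws: dict[str, np.ndarray],
    omega_v: float | None = None,
    omega_q: float | None = None,
) -> np.ndarray:
    """Vectorized trough draw reusing common random numbers in `draws`."""
    ov = typical.iiv.omega_v if omega_v is None else omega_v
    oq = typical.iiv.omega_q if omega_q is None else omega_q
    w = cov.weight_gm * np.exp(lognormal_sigma(cov.weight_cv) * draws["z_w"]) / typical.ref_weight
    gen_frac = typical.gstm1_cl_fraction if genotype == "null" else 1.0
    cl = typical.tvcl_nonnull * gen_frac * w**typical.allo_cl * np.exp(
        typical.iiv.omega_cl * draws["z_cl"]
    )
    v1 = typical.tvv1 * w**typical.allo_v * np.exp(ov * draws["z_v"])
    q = typical.tvq * w**typical.allo_cl * np.exp(oq * draws["z_q"])
    v2 = typical.tvv2 * w**typical.allo_v
    ka = np.full(w.shape, typical.tvka)
    trough, _ = pk.steady_state_metrics_batch(cl, v1, q, v2, ka, regimen)
    return trough


def fit_iiv(
    trough_cv_targets: dict[tuple[str, str], float],
    typical: TypicalModel,
    cov: CovariateModel,
    draws: dict[str, np.ndarray],
    max_cv_err_pp: float | None = 5.0,
    ridge_omega_v: float = 2.0,
    x0: tuple[float, float] = (0.1, 0.8),
) -> tuple[IIVModel, dict]:
    """Fit shape-variability components (omega_V, omega_Q) to the trough %CVs.

    omega_CL must already be set on ``typical`` (closed form from the Caverage
    CV).  The objective is the summed squared %CV error over all scenarios,
    evaluated by Monte Carlo with common random numbers, plus a small ridge on
    omega_V (to which the trough surface is nearly indifferent in the
    calibrated flip-flop regime).  Raises if the best fit leaves any scenario
    more than ``max_cv_err_pp`` percentage points off.
    """
    keys = sorted(trough_cv_targets)
    regs = {k: get_regimen(k[1]) for k in keys}
    targets = np.array([trough_cv_targets[k] for k in keys])

    def cvs(ov: float, oq: float) -> np.ndarray:
        out = []
        for k in keys:
            tr = _trough_samples(typical, cov, k[0], regs[k], draws, omega_v=ov, omega_q=oq)
            out.append(100.0 * tr.std(ddof=1) / tr.mean())
        return np.asarray(out)

    def objective(x: np.ndarray) -> float:
        err = cvs(x[0], x[1]) - targets
        return float(np.sum(err**2) + ridge_omega_v * x[0] ** 2)

    res = minimize(
        objective,
        x0=np.asarray(x0, dtype=float),
        method="Nelder-Mead",
        bounds=[(0.0, 1.5), (0.0, 1.5)],
        options={"xatol": 1e-3, "fatol": 1e-3, "maxiter": 200},
    )
    ov, oq = float(res.x[0]), float(res.x[1])
    final_cvs = cvs(ov, oq)
    errs = final_cvs - targets
    diag = {
        "cv_targets": {f"{g}:{r}": trough_cv_targets[(g, r)] for g, r in keys},
        "cv_fitted": {f"{g}:{r}": float(c) for (g, r), c in zip(keys, final_cvs)},
        "cv_err_pp": {f"{g}:{r}": float(e) for (g, r), e in zip(keys, errs)},
        "max_abs_cv_err_pp": float(np.max(np.abs(errs))),
        "n_mc": int(draws["z_w"].size),
        "optimizer_iterations": int(res.nit),
    }
    if max_cv_err_pp is not None and np.max(np.abs(errs)) > max_cv_err_pp:
        raise CalibrationError(
            f"no shape-IIV in bounds brings all trough CVs within "
            f"{max_cv_err_pp} percentage points (worst {np.max(np.abs(errs)):.1f} pp)",
            diag,
        )
    iiv = IIVModel(omega_cl=typical.iiv.omega_cl, omega_v=ov, omega_q=oq)
    return iiv, diag


def calibrate(
    targets: CalibrationTargets | None = None,
    seed: int = 2025,
    n_mc: int = 20000,
    cov: CovariateModel | None = None,
    max_outer_iter: int = 12,
    gm_tol: float = 0.005,
    n_starts: int = 12,
) -> CalibrationResult:
    """Full calibration pipeline; deterministic given ``seed``.

    The outer loop alternates the disposition fit, the shape-IIV fit, and a
    population-GM correction: typical-scale trough targets are rescaled by the
    ratio of published to simulated population geometric means until the
    simulated cohort reproduces the published GMs (tolerance ``gm_tol``).
    """
    targets = targets if targets is not None else load_targets()
    cov = cov if cov is not None else CovariateModel()

    nn240 = targets.cell("non-null", "240QD")
    null240 = targets.cell("null", "240QD")
    cl_nn = clearances_from_caverage(240.0, nn240.caverage_gm)
    cl_null = clearances_from_caverage(240.0, null240.caverage_gm)
    gstm1_fraction = cl_null / cl_nn

    omega_cl = solve_omega_cl(nn240.caverage_cv_pct, cov.weight_cv)

    printed_troughs = {
        k: targets.cell(*k).ctrough_gm for k in CALIBRATION_TROUGH_SCENARIOS
    }
    cv_targets = {
        (s.genotype, s.regimen): s.ctrough_cv_pct for s in targets.scenarios
    }
    cl_by_genotype = {"non-null": cl_nn, "null": cl_null}

    ss = np.random.SeedSequence(seed)
    fit_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(ss.spawn(2)[1])
    draws = {name: rng.standard_normal(n_mc) for name in ("z_w", "z_cl", "z_v", "z_q")}

    adjusted = dict(printed_troughs)
    history: list[dict] = []
    disp_diag: dict = {}
    iiv_diag: dict = {}

    def build_typical(disp: dict[str, float], iiv: IIVModel) -> TypicalModel:
        return TypicalModel(
            tvcl_nonnull=cl_nn,
            gstm1_cl_fraction=gstm1_fraction,
            tvv1=disp["v1"],
            tvq=disp["q"],
            tvv2=disp["v2"],
            tvka=disp["ka"],
            iiv=iiv,
        )

    def gm_ratios(typical: TypicalModel) -> dict[tuple[str, str], float]:
        out = {}
        for k in CALIBRATION_TROUGH_SCENARIOS:
            tr = _trough_samples(typical, cov, k[0], get_regimen(k[1]), draws)
            out[k] = printed_troughs[k] / float(np.exp(np.mean(np.log(tr))))
        return out

    # stage 1: disposition at printed targets
    disp, disp_diag = fit_disposition(
        adjusted, cl_by_genotype, seed=fit_seed, n_starts=n_starts
    )
    iiv = IIVModel(omega_cl=omega_cl)

    # stage 2: two rounds of [shape-IIV fit -> frozen-IIV population-GM
    # correction loop].  The IIV is fitted once at the initial disposition and
    # refreshed once at the GM-corrected one (further refreshes only creep
    # omega_Q upward with negligible CV gain while destabilizing the GM loop);
    # warm refits are anchored so the correction map stays local.
    converged = False
    damping = 0.8
    n_rounds = 2
    for round_ in range(n_rounds):
        iiv, iiv_diag = fit_iiv(
            cv_targets, build_typical(disp, iiv), cov, draws,
            max_cv_err_pp=None,
            x0=(iiv.omega_v, iiv.omega_q) if round_ else (0.1, 0.8),
        )
        for it in range(max_outer_iter):
            ratios = gm_ratios(build_typical(disp, iiv))
            max_dev = max(abs(r - 1.0) for r in ratios.values())
            history.append(
                {
                    "round": round_,
                    "iteration": it,
                    "disposition": dict(disp),
                    "omega_v": iiv.omega_v,
                    "omega_q": iiv.omega_q,
                    "gm_ratio_dev": {f"{g}:{r}": float(v - 1.0) for (g, r), v in ratios.items()},
                    "max_gm_dev": float(max_dev),
                }
            )
            if max_dev < gm_tol:
                converged = True
                break
            converged = False
            adjusted = {k: adjusted[k] * ratios[k] ** damping for k in adjusted}
            disp, disp_diag = fit_disposition(
                adjusted,
                cl_by_genotype,
                seed=fit_seed,
                n_starts=1,
                x0=np.array([disp["v1"], disp["q"], disp["v2"], disp["ka"]]),
                anchor_weight=0.02,
                strict=False,
            )
    typical = build_typical(disp, iiv)
    # the last GM loop may have nudged disposition; verify the CV surface of
    # the final model without refitting
    final_cv_errs = {}
    for k in sorted(cv_targets):
        tr = _trough_samples(typical, cov, k[0], get_regimen(k[1]), draws)
        cv = 100.0 * tr.std(ddof=1) / tr.mean()
        final_cv_errs[f"{k[0]}:{k[1]}"] = float(cv - cv_targets[k])
    iiv_diag["final_cv_err_pp"] = final_cv_errs
    if max(abs(v) for v in final_cv_errs.values()) > 5.0:
        raise CalibrationError(
            "fitted shape-IIV leaves a trough %CV more than 5 percentage "
            "points from its target",
            {"iiv_fit": iiv_diag, "history": history},
        )

    # residual report: simulated population GMs / CVs vs every published cell
    residuals: dict[str, float] = {}
    for s in targets.scenarios:
        reg = get_regimen(s.regimen)
        tr = _trough_samples(typical, cov, s.genotype, reg, draws)
        gm = float(np.exp(np.mean(np.log(tr))))
        cv = float(100.0 * tr.std(ddof=1) / tr.mean())
        residuals[f"ctrough_gm:{s.genotype}:{s.regimen}"] = gm / s.ctrough_gm - 1.0
        residuals[f"ctrough_cv_pp:{s.genotype}:{s.regimen}"] = cv - s.ctrough_cv_pct
        gen_frac = gstm1_fraction if s.genotype == "null" else 1.0
        cav_gm_pred = reg.daily_dose_mg / (24.0 * cl_nn * gen_frac)
        residuals[f"caverage_gm:{s.genotype}:{s.regimen}"] = cav_gm_pred / s.caverage_gm - 1.0

    diagnostics = {
        "seed": seed,
        "n_mc": n_mc,
        "targets_sha256": targets.sha256(),
        "cl_nonnull": cl_nn,
        "cl_null": cl_null,
        "gstm1_fraction": gstm1_fraction,
        "omega_cl_closed_form": omega_cl,
        "outer_iterations": len(history),
        "history": history,
        "disposition_fit": disp_diag,
        "iiv_fit": iiv_diag,
        "converged": bool(converged),
        "adjusted_trough_targets": {f"{g}:{r}": v for (g, r), v in adjusted.items()},
    }
    if not converged:
        raise CalibrationError(
            "population-GM correction did not converge", diagnostics
        )
    return CalibrationResult(typical=typical, residuals=residuals, diagnostics=diagnostics)
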