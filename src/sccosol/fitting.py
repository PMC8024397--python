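"""Coefficient estimation by seeded multi-start global optimization.

Every registered correlation is linear in its coefficients on its response
transform's scale, so an ordinary least-squares solve in that transformed
space gives a cheap, deterministic starting point. The fit then minimizes
the requested objective on the mole-fraction scale — by default the
degrees-of-freedom AARD, the same criterion the fits are ranked by — with a
multi-start scheme: a derivative-free simplex polish of the least-squares
start, plus seeded differential-evolution searches inside per-coefficient
bounds, each polished again. The best start wins; ties go to the lowest
start index, and identical seeds and inputs reproduce bit-identical results.

Parameter vectors whose predictions overflow or leave the (0, 1) mole
fraction range are mapped to a large finite penalty instead of raising, so
the global search can traverse them.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution, minimize

from sccosol import models as _m
from sccosol.data import Dataset
from sccosol.metrics import aard_percent, r_adjusted, r_squared

_PENALTY = 1.0e8
_DE_SEED_KW = (
    "rng" if "rng" in inspect.signature(differential_evolution).parameters else "seed"
)


class FittingError(RuntimeError):
    """Fit could not be carried out (too few records, all starts diverged)."""


@dataclass
class FitResult:
    """Fitted coefficients plus the statistics the model is judged by."""

    model: str
    params: np.ndarray
    aard_percent: float  # N-Z normalized (degrees-of-freedom form)
    aard_percent_plain: float  # N normalized
    r2: float
    r_adj: float
    residuals: np.ndarray  # per-record relative deviations (calc - exp)/exp
    n_records: int
    objective: str
    normalization: str
    seed: int
    n_starts: int
    converged: bool
    start_objectives: tuple[float, ...] = ()
    pressure_unit: str = "bar"
    conc_mode: str = "dilute"

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": [float(a) for a in self.params],
            "metrics": {
                "aard_percent": self.aard_percent,
                "aard_percent_plain": self.aard_percent_plain,
                "r2": self.r2,
                "r_adj": self.r_adj,
            },
            "residuals": [float(r) for r in self.residuals],
            "n_records": self.n_records,
            "objective": self.objective,
            "normalization": self.normalization,
            "seed": self.seed,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "start_objectives": [float(v) for v in self.start_objectives],
            "pressure_unit": self.pressure_unit,
            "conc_mode": self.conc_mode,
        }


def _make_objective(spec, data, objective, normalization, pressure_unit, conc_mode):
    ctx = _m._context(spec, data, pressure_unit, conc_mode)
    X = _m._features(spec, ctx)
    y_exp = data.y2
    log_y = np.log(y_exp)
    n, z = y_exp.size, spec.Z
    denom = (n - z) if normalization == "n_minus_z" else n
    if objective == "aard_s":
        # score against the dataset's independently recorded g/L solubility
        # column (it can differ from rho*y2*M2/M1 through separate rounding)
        s_vals = [r.S for r in data.records]
        if any(v is None for v in s_vals):
            raise FittingError("objective 'aard_s' requires every record to carry S")
        S_exp = np.array(s_vals, dtype=float)
        s_factor = data.rho * data.solute_mw / data.solvent_mw

    def f(p):
        lp = X @ np.asarray(p, dtype=float)
        y_pred = _m._inverse_response(spec, ctx, lp)
        bad = ~np.isfinite(y_pred) | (y_pred <= 0) | (y_pred >= 1)
        if bad.any():
            return _PENALTY * (1.0 + bad.mean())
        if objective == "aard":
            return 100.0 * float(np.sum(np.abs(y_pred - y_exp) / y_exp)) / denom
        if objective == "aard_s":
            return 100.0 * float(np.sum(np.abs(y_pred * s_factor - S_exp) / S_exp)) / denom
        if objective == "sse_log":
            return float(np.sum((np.log(y_pred) - log_y) ** 2))
        raise FittingError(f"unknown objective {objective!r}")

    return f, X


def least_squares_start(
    model,
    data: Dataset,
    *,
    pressure_unit: str = "bar",
    conc_mode: str = "dilute",
) -> np.ndarray:
    """Ordinary least-squares coefficients in the model's transformed space.

    Exact for noiseless model-generated data; the standard deterministic
    starting point for the global AARD search.
    """
    spec = _m.get_model(model)
    X = _m.design_matrix(spec, data, pressure_unit=pressure_unit, conc_mode=conc_mode)
    r = _m.response_value(spec, data, pressure_unit=pressure_unit, conc_mode=conc_mode)
    coef, *_ = np.linalg.lstsq(X, r, rcond=None)
    return coef


def objective_value(
    model,
    params,
    data: Dataset,
    objective: str = "aard",
    *,
    normalization: str = "n_minus_z",
    pressure_unit: str = "bar",
    conc_mode: str = "dilute",
) -> float:
    """Objective for a given coefficient vector (penalty for non-finite fits)."""
    spec = _m.get_model(model)
    f, _ = _make_objective(spec, data, objective, normalization, pressure_unit, conc_mode)
    return f(np.asarray(params, dtype=float))


def default_bounds(p_center: np.ndarray) -> list[tuple[float, float]]:
    """Per-coefficient search box centered on the least-squares start."""
    half = 5.0 * np.abs(p_center) + 10.0
    return [(float(c - h), float(c + h)) for c, h in zip(p_center, half)]


def _polish(f, x0):
    res = minimize(
        f,
        np.asarray(x0, dtype=float),
        method="Nelder-Mead",
        options={
            "maxfev": 40000,
            "xatol": 1e-10,
            "fatol": 1e-12,
            "adaptive": True,
        },
    )
    return res.x, float(res.fun)


def fit(
    model,
    data: Dataset,
    objective: str = "aard",
    n_starts: int = 8,
    seed: int = 0,
    bounds: list[tuple[float, float]] | None = None,
    *,
    normalization: str = "n_minus_z",
    pressure_unit: str = "bar",
    conc_mode: str = "dilute",
) -> FitResult:
    """Fit one correlation to a dataset and package the result.

    Start 0 polishes the transformed-space least-squares solution with a
    Nelder-Mead simplex; starts 1..n_starts-1 run seeded differential
    evolution within ``bounds`` (default: a data-driven box around the
    least-squares start) followed by the same polish. The best-of-starts
    coefficients are returned together with AARD (both normalizations),
    R^2, the adjusted correlation coefficient and per-record residuals.
    """
    spec = _m.get_model(model)
    if data.n <= spec.Z:
        raise FittingError(
            f"{spec.name!r} has Z = {spec.Z} coefficients but only {data.n} records given"
        )
    f, _X = _make_objective(spec, data, objective, normalization, pressure_unit, conc_mode)
    p0 = least_squares_start(spec, data, pressure_unit=pressure_unit, conc_mode=conc_mode)
    if not np.all(np.isfinite(p0)):
        raise FittingError("least-squares start is non-finite; check the dataset")
    box = bounds if bounds is not None else default_bounds(p0)

    candidates: list[tuple[float, np.ndarray]] = []
    x, fx = _polish(f, p0)
    candidates.append((fx, x))
    for k in range(1, max(1, n_starts)):
        de_kwargs = {
            "maxiter": 300,
            "popsize": 15,
            "tol": 0.005,
            "mutation": (0.5, 1.0),
            "recombination": 0.7,
            "polish": False,
            "init": "latinhypercube",
            _DE_SEED_KW: int(seed + 1_000_003 * k) % (2**31 - 1),
        }
        res = differential_evolution(f, box, **de_kwargs)
        x, fx = _polish(f, res.x)
        candidates.append((fx, x))

    start_objectives = tuple(c[0] for c in candidates)
    best_idx = int(np.argmin(start_objectives))  # lowest index wins ties
    best_f, best_p = candidates[best_idx]
    if not np.isfinite(best_f) or best_f >= _PENALTY:
        raise FittingError("all starts diverged (no finite predictions found)")

    y_calc = _m.predict(spec, best_p, data, pressure_unit=pressure_unit, conc_mode=conc_mode)
    y_exp = data.y2
    return FitResult(
        model=spec.name,
        params=np.asarray(best_p, dtype=float),
        aard_percent=aard_percent(y_exp, y_calc, spec.Z, "n_minus_z"),
        aard_percent_plain=aard_percent(y_exp, y_calc, spec.Z, "n"),
        r2=r_squared(y_exp, y_calc),
        r_adj=r_adjusted(y_exp, y_calc, spec.Q),
        residuals=(y_calc - y_exp) / y_exp,
        n_records=data.n,
        objective=objective,
        normalization=normalization,
        seed=int(seed),
        n_starts=int(n_starts),
        converged=bool(np.isfinite(best_f) and best_f < _PENALTY),
        start_objectives=start_objectives,
        pressure_unit=pressure_unit,
        conc_mode=conc_mode,
    )
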