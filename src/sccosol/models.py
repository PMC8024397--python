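"""Registry and evaluation of the density-based solubility correlations.

Twelve semi-empirical correlations relate the solute mole fraction ``y2`` to
the solvent density ``rho`` (kg/m3), temperature ``T`` (K) and pressure
``P``: eight for the binary (solute + SC-CO2) system — Chrastil,
Kumar-Johnston (K-J), Bartle, Mendez-Santiago-Teja (MST), Sparks, Bian,
Jouyban and Sodeifian — and four for the ternary (cosolvent) system — a
cosolvent-extended MST, Sodeifian-Sajadian, Gonzalez and Soltani-Mazloumi,
which add the cosolvent mole fraction ``y3`` as a state variable.

Every registered correlation is linear in its adjustable coefficients after
its response transform (ln c, ln y2, T ln(y2 P), ...), which the fitting
module exploits for least-squares starting points; predictions are always
mapped back to the mole fraction y2 so that models with different response
scales are compared on a common footing.

Pressure enters the formulas in bar by default (P_ref = 1 bar for the
Bartle-type enhancement ratio); the convention is configurable and is
absorbed by the coefficients of any model with an intercept degree of
freedom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from sccosol.data import (
    Dataset,
    RHO_CRITICAL,
    SolubilityDataError,
    T_CRITICAL,
    mass_conc_to_mole_fraction,
    mole_fraction_to_mass_conc,
)

_P_SCALES = {"bar": 10.0, "MPa": 1.0}  # multiplier applied to P given in MPa


class ModelError(ValueError):
    """Unknown model or a record that a formula cannot evaluate."""


@dataclass(frozen=True)
class ModelSpec:
    """A registered correlation.

    ``Z`` is the number of adjustable coefficients, ``Q`` the number of
    independent state variables the formula uses (for the adjusted
    correlation coefficient), ``response`` identifies the transformed
    quantity the formula is linear in, and ``constants`` the physical
    reference values the formula needs.
    """

    name: str
    system: str
    Z: int
    Q: int
    response: str
    formula: str
    constants: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "system": self.system,
            "Z": self.Z,
            "Q": self.Q,
            "response": self.response,
            "formula": self.formula,
            "constants": dict(self.constants),
        }


@dataclass
class _Context:
    """Per-dataset state variables on the model's unit convention."""

    T: np.ndarray
    P: np.ndarray  # scaled (bar by default)
    rho: np.ndarray
    y3: np.ndarray | None
    p_ref: float  # scaled like P
    solute_mw: float
    solvent_mw: float
    conc_mode: str


def _context(spec: ModelSpec, data: Dataset, pressure_unit: str, conc_mode: str) -> _Context:
    if pressure_unit not in _P_SCALES:
        raise ModelError(f"unknown pressure unit {pressure_unit!r}")
    if spec.system != data.system:
        raise ModelError(
            f"model {spec.name!r} is a {spec.system} correlation but the dataset is {data.system}"
        )
    scale = _P_SCALES[pressure_unit]
    y3 = data.y3 if data.system == "ternary" else None
    p_ref = spec.constants.get("P_ref_MPa", 0.1) * scale
    return _Context(
        T=data.T,
        P=data.P * scale,
        rho=data.rho,
        y3=y3,
        p_ref=p_ref,
        solute_mw=data.solute_mw,
        solvent_mw=data.solvent_mw,
        conc_mode=conc_mode,
    )


# --- feature matrices (design in the coefficient-linear transformed space) --


def _features(spec: ModelSpec, c: _Context) -> np.ndarray:
    T, P, rho, y3 = c.T, c.P, c.rho, c.y3
    one = np.ones_like(T)
    name = spec.name
    if name == "chrastil":
        cols = [np.log(rho), 1.0 / T, one]
    elif name == "kumar_johnston":
        cols = [one, rho, 1.0 / T]
    elif name == "bartle":
        cols = [one, 1.0 / T, rho - spec.constants["rho_ref"]]
    elif name == "mst":
        cols = [one, rho, T]
    elif name == "sparks":
        rho_r = rho / spec.constants["rho_c"]
        T_r = T / spec.constants["T_c"]
        cols = [np.log(rho_r), rho_r * np.log(rho_r), one, 1.0 / T_r]
    elif name == "bian":
        cols = [np.log(rho), rho * np.log(rho), 1.0 / T, rho / T, one]
    elif name == "jouyban":
        cols = [one, rho, P**2, P * T, T / P, np.log(rho)]
    elif name == "sodeifian":
        cols = [one, P**2 / T, np.log(rho * T), rho * np.log(rho), P * np.log(T),
                np.log(rho) / T]
    elif name == "mst_ternary":
        cols = [one, rho, T, y3]
    elif name == "sodeifian_sajadian":
        cols = [np.log(rho), (rho / T) * np.log(rho), rho, np.log(y3 * P)]
    elif name == "gonzalez":
        cols = [np.log(rho), np.log(y3), 1.0 / T, one]
    elif name == "soltani_mazloumi":
        cols = [one, 1.0 / T, rho / T, -np.log(P), np.log(y3 * rho * T)]
    else:  # pragma: no cover - registry and dispatch are kept in sync
        raise ModelError(f"no feature builder for {name!r}")
    return np.column_stack(cols)


# --- response transforms and their inverses ---------------------------------


def _observed_response(spec: ModelSpec, c: _Context, y2: np.ndarray) -> np.ndarray:
    if np.any(y2 <= 0):
        raise ModelError("response transform requires positive mole fractions")
    resp = spec.response
    if resp == "ln_c":
        conc = mole_fraction_to_mass_conc(y2, c.rho, c.solute_mw, c.solvent_mw, c.conc_mode)
        return np.log(conc)
    if resp == "ln_y2":
        return np.log(y2)
    if resp == "ln_y2P_over_Pref":
        return np.log(y2 * c.P / c.p_ref)
    if resp == "T_ln_y2P":
        return c.T * np.log(y2 * c.P)
    if resp == "T_ln_y2P_over_Pref":
        return c.T * np.log(y2 * c.P / c.p_ref)
    raise ModelError(f"unknown response transform {resp!r}")  # pragma: no cover


def _inverse_response(spec: ModelSpec, c: _Context, lp: np.ndarray) -> np.ndarray:
    """Map the linear predictor back to a predicted mole fraction."""
    resp = spec.response
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if resp == "ln_c":
            conc = np.exp(lp)
            out = np.where(
                np.isfinite(conc),
                conc * c.solvent_mw / (c.rho * c.solute_mw)
                if c.conc_mode == "dilute"
                else conc * c.solvent_mw
                / (c.rho * c.solute_mw - conc * (c.solute_mw - c.solvent_mw)),
                np.nan,
            )
        elif resp == "ln_y2":
            out = np.exp(lp)
        elif resp == "ln_y2P_over_Pref":
            out = c.p_ref * np.exp(lp) / c.P
        elif resp == "T_ln_y2P":
            out = np.exp(lp / c.T) / c.P
        elif resp == "T_ln_y2P_over_Pref":
            out = c.p_ref * np.exp(lp / c.T) / c.P
        else:  # pragma: no cover
            raise ModelError(f"unknown response transform {resp!r}")
    return out


# --- registry ---------------------------------------------------------------

_REGISTRY: dict[str, ModelSpec] = {
    m.name: m
    for m in [
        ModelSpec("chrastil", "binary", 3, 2, "ln_c",
                  "c = rho^a0 * exp(a1/T + a2)"),
        ModelSpec("kumar_johnston", "binary", 3, 2, "ln_y2",
                  "ln(y2) = a0 + a1*rho + a2/T"),
        ModelSpec("bartle", "binary", 3, 3, "ln_y2P_over_Pref",
                  "ln(y2*P/Pref) = a0 + a1/T + a2*(rho - rho_ref)",
                  {"P_ref_MPa": 0.1, "rho_ref": 700.0}),
        ModelSpec("mst", "binary", 3, 3, "T_ln_y2P",
                  "T*ln(y2*P) = a0 + a1*rho + a2*T"),
        ModelSpec("sparks", "binary", 4, 2, "ln_c",
                  "c = rho_r^(a0 + a1*rho_r) * exp(a2 + a3/T_r)",
                  {"rho_c": RHO_CRITICAL, "T_c": T_CRITICAL}),
        ModelSpec("bian", "binary", 5, 2, "ln_y2",
                  "y2 = rho^(a0 + a1*rho) * exp(a2/T + a3*rho/T + a4)"),
        ModelSpec("jouyban", "binary", 6, 3, "ln_y2",
                  "ln(y2) = a0 + a1*rho + a2*P^2 + a3*P*T + a4*T/P + a5*ln(rho)"),
        ModelSpec("sodeifian", "binary", 6, 3, "ln_y2",
                  "ln(y2) = a0 + a1*P^2/T + a2*ln(rho*T) + a3*rho*ln(rho)"
                  " + a4*P*ln(T) + a5*ln(rho)/T"),
        ModelSpec("mst_ternary", "ternary", 4, 4, "T_ln_y2P_over_Pref",
                  "T*ln(y2'*P/Pref) = a0 + a1*rho1 + a2*T + a3*y3",
                  {"P_ref_MPa": 0.1}),
        ModelSpec("sodeifian_sajadian", "ternary", 4, 4, "ln_y2",
                  "ln(y2') = (a0 + a1*rho1/T)*ln(rho1) + a2*rho1 + a3*ln(y3*P)"),
        ModelSpec("gonzalez", "ternary", 4, 3, "ln_y2",
                  "ln(y2') = a0*ln(rho1) + a1*ln(y3) + a2/T + a3"),
        ModelSpec("soltani_mazloumi", "ternary", 5, 4, "ln_y2",
                  "ln(y2') = a0 + a1/T + (a2/T)*rho1 - a3*ln(P)"
                  " + a4*ln(y3*rho1*T)"),
    ]
}


def list_models(system: str | None = None) -> tuple[ModelSpec, ...]:
    """All registered correlations, optionally filtered by system kind."""
    specs = tuple(_REGISTRY.values())
    if system is None:
        return specs
    if system not in ("binary", "ternary"):
        raise ModelError(f"unknown system kind {system!r}")
    return tuple(s for s in specs if s.system == system)


def get_model(name: str | ModelSpec) -> ModelSpec:
    if isinstance(name, ModelSpec):
        return name
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ModelError(
            f"unknown model {name!r}; available: {', '.join(sorted(_REGISTRY))}"
        ) from None


def registry_json() -> str:
    """Machine-readable listing of the registry (name, Z, response, constants)."""
    return json.dumps([s.to_dict() for s in _REGISTRY.values()], indent=2, sort_keys=True)


# --- evaluation -------------------------------------------------------------


def design_matrix(
    model: str | ModelSpec,
    data: Dataset,
    *,
    pressure_unit: str = "bar",
    conc_mode: str = "dilute",
) -> np.ndarray:
    """N x Z matrix of the coefficient-linear predictors of the model."""
    spec = get_model(model)
    return _features(spec, _context(spec, data, pressure_unit, conc_mode))


def response_value(
    model: str | ModelSpec,
    data: Dataset,
    *,
    pressure_unit: str = "bar",
    conc_mode: str = "dilute",
) -> np.ndarray:
    """Observed transformed response of each record (e.g. ln c, T ln(y2 P))."""
    spec = get_model(model)
    c = _context(spec, data, pressure_unit, conc_mode)
    return _observed_response(spec, c, data.y2)


def predict(
    model: str | ModelSpec,
    params,
    data: Dataset,
    *,
    pressure_unit: str = "bar",
    conc_mode: str = "dilute",
) -> np.ndarray:
    """Predicted solute mole fraction at each record of ``data``.

    Raises :class:`ModelError` when any prediction is non-finite (the fitting
    objective instead maps such parameter vectors to a penalty).
    """
    y2 = predict_allow_nonfinite(model, params, data,
                                 pressure_unit=pressure_unit, conc_mode=conc_mode)
    if not np.all(np.isfinite(y2)) or np.any(y2 <= 0):
        raise ModelError(f"model {get_model(model).name!r} produced a non-finite or "
                         "non-positive mole fraction")
    return y2


def predict_allow_nonfinite(
    model: str | ModelSpec,
    params,
    data: Dataset,
    *,
    pressure_unit: str = "bar",
    conc_mode: str = "dilute",
) -> np.ndarray:
    """Like :func:`predict` but returning NaN/inf instead of raising."""
    spec = get_model(model)
    params = np.asarray(params, dtype=float)
    if params.shape != (spec.Z,):
        raise ModelError(f"model {spec.name!r} takes {spec.Z} coefficients, "
                         f"got shape {params.shape}")
    c = _context(spec, data, pressure_unit, conc_mode)
    lp = _features(spec, c) @ params
    return _inverse_response(spec, c, lp)
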