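"""Post-fit physical analysis: enthalpies, cosolvent effect, crossover pressure.

The temperature coefficients of the density-based correlations carry the
thermal effects of dissolution. In the Chrastil (and Sparks) picture the
1/T coefficient is -dH_total/R with dH_total the total dissolution
(solvation + vaporization) enthalpy; in the Bartle picture, where density
effects are separated out, the 1/T coefficient gives the solute vaporization
enthalpy dH_vap. Their difference is the solvation enthalpy,
dH_sol = dH_total - dH_vap (negative when vaporization outweighs the total,
i.e. solvation is exothermic).

The cosolvent effect e = y2'(T, P, y3) / y2(T, P) quantifies the solubility
enhancement by the cosolvent at matched conditions, and the crossover
pressure is the region where solubility isotherms intersect: below it the
density effect dominates (solubility falls with temperature), above it the
vapor-pressure effect dominates (solubility rises with temperature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from sccosol.data import Dataset, R_GAS, SolubilityDataError, _condition_key


@dataclass(frozen=True)
class EnthalpyReport:
    """Enthalpies in kJ/mol derived from fitted temperature coefficients."""

    dH_total: float
    dH_vap: float
    dH_sol: float
    source_models: tuple[str, str]

    def to_dict(self) -> dict:
        return {
            "dH_total_kJ_mol": round(self.dH_total, 2),
            "dH_vap_kJ_mol": round(self.dH_vap, 2),
            "dH_sol_kJ_mol": round(self.dH_sol, 2),
            "source_models": list(self.source_models),
        }


@dataclass(frozen=True)
class CosolventEffectRecord:
    """Enhancement factor e = y2'/y2 at one shared (T, P) condition."""

    T: float
    P: float
    e: float

    def __post_init__(self) -> None:
        if not self.e > 0:
            raise SolubilityDataError(f"enhancement factor must be positive, got {self.e}")


@dataclass(frozen=True)
class PairCrossing:
    """Intersection of two adjacent-temperature isotherms."""

    T_low: float
    T_high: float
    P_cross: float  # interpolated intersection pressure, MPa
    bracket: tuple[float, float]  # grid segment containing the intersection


@dataclass(frozen=True)
class CrossoverResult:
    window: tuple[float, float]  # MPa
    crossings: tuple[PairCrossing, ...]
    pairs_without_crossing: tuple[tuple[float, float], ...]
    method: str


def enthalpy_from_temperature_coefficient(
    model: str, coeff: float, Tc: float | None = None
) -> float:
    """Enthalpy in kJ/mol from a fitted temperature coefficient.

    ``chrastil`` / ``bartle``: the coefficient multiplies 1/T (units K), so
    dH = -R * a1. ``sparks``: the coefficient multiplies 1/T_r = Tc/T
    (dimensionless), so dH = -R * Tc * a3 and ``Tc`` is required.
    """
    if not np.isfinite(coeff):
        raise SolubilityDataError("temperature coefficient must be finite")
    if model in ("chrastil", "bartle"):
        return -R_GAS * float(coeff) / 1000.0
    if model == "sparks":
        if Tc is None:
            raise SolubilityDataError("sparks enthalpy requires the critical temperature Tc")
        return -R_GAS * float(Tc) * float(coeff) / 1000.0
    raise SolubilityDataError(
        f"no enthalpy interpretation registered for model {model!r}"
    )


def solvation_enthalpy(dH_total: float, dH_vap: float) -> float:
    """dH_sol = dH_total - dH_vap (kJ/mol)."""
    if not (np.isfinite(dH_total) and np.isfinite(dH_vap)):
        raise SolubilityDataError("enthalpies must be finite")
    return float(dH_total) - float(dH_vap)


def enthalpy_report(
    dH_total: float, dH_vap: float, source_models: tuple[str, str] = ("chrastil", "bartle")
) -> EnthalpyReport:
    """Bundle total/vaporization enthalpies with the derived solvation term."""
    return EnthalpyReport(
        dH_total=float(dH_total),
        dH_vap=float(dH_vap),
        dH_sol=solvation_enthalpy(dH_total, dH_vap),
        source_models=tuple(source_models),
    )


def cosolvent_effect(binary: Dataset, ternary: Dataset) -> list[CosolventEffectRecord]:
    """Enhancement factors at every (T, P) condition the two datasets share.

    Conditions are matched after rounding to 0.1 K / 0.1 MPa; unmatched
    conditions are skipped with a warning.
    """
    bmap = {rec.condition: rec for rec in binary.records}
    out: list[CosolventEffectRecord] = []
    unmatched = []
    for rec in ternary.records:
        mate = bmap.get(rec.condition)
        if mate is None:
            unmatched.append(rec.condition)
            continue
        out.append(CosolventEffectRecord(T=rec.T, P=rec.P, e=rec.y2 / mate.y2))
    if unmatched:
        warnings.warn(f"skipped conditions with no binary mate: {unmatched}", stacklevel=2)
    if not out:
        raise SolubilityDataError("the two datasets share no (T, P) conditions")
    return out


def _isotherm_table(data: Dataset) -> tuple[np.ndarray, dict[float, np.ndarray], np.ndarray]:
    temps = np.sort(data.temperatures())
    if temps.size < 2:
        raise SolubilityDataError("crossover analysis requires at least two isotherms")
    by_T = {}
    pressures = None
    for T in temps:
        iso = data.isotherm(T)
        if iso.n < 2:
            raise SolubilityDataError(f"isotherm {T} K has fewer than two pressures")
        P = iso.P
        if pressures is None:
            pressures = P
        elif not np.array_equal(P, pressures):
            raise SolubilityDataError("isotherms must share a common pressure grid")
        by_T[float(T)] = np.log(iso.y2)
    return temps, by_T, pressures


def crossover_window(data: Dataset, method: str = "bracket") -> CrossoverResult:
    """Locate the crossover pressure region from the measured isotherms.

    For each adjacent-temperature isotherm pair the difference of the
    piecewise-linear ln y2 vs P curves is scanned for sign changes; each sign
    change yields an interpolated intersection pressure and the grid segment
    bracketing it. ``method="bracket"`` (default) reports the crossover
    *area*: the union of all bracketing segments, acknowledging that a
    crossing interpolated between measured pressures is only localized to its
    segment. ``method="interpolated"`` reports the tighter min/max of the
    interpolated intersection pressures themselves.
    """
    if method not in ("bracket", "interpolated"):
        raise SolubilityDataError(f"unknown crossover method {method!r}")
    temps, by_T, P = _isotherm_table(data)
    return _scan_crossings(temps, by_T, P, method)


def _scan_crossings(temps, lny_by_T, P, method: str) -> CrossoverResult:
    crossings: list[PairCrossing] = []
    empty_pairs: list[tuple[float, float]] = []
    for T_lo, T_hi in zip(temps[:-1], temps[1:]):
        d = lny_by_T[float(T_lo)] - lny_by_T[float(T_hi)]  # cold minus hot, ln y2
        found = False
        for j in range(d.size - 1):
            if d[j] == 0.0:
                crossings.append(PairCrossing(T_lo, T_hi, float(P[j]), (float(P[j]), float(P[j]))))
                found = True
            elif d[j] * d[j + 1] < 0:
                frac = d[j] / (d[j] - d[j + 1])
                p_cross = float(P[j] + frac * (P[j + 1] - P[j]))
                crossings.append(
                    PairCrossing(T_lo, T_hi, p_cross, (float(P[j]), float(P[j + 1])))
                )
                found = True
        if not found:
            empty_pairs.append((float(T_lo), float(T_hi)))
    if not crossings:
        raise SolubilityDataError("no isotherm pair intersects: no crossover in range")
    if method == "bracket":
        lo = min(c.bracket[0] for c in crossings)
        hi = max(c.bracket[1] for c in crossings)
    else:
        lo = min(c.P_cross for c in crossings)
        hi = max(c.P_cross for c in crossings)
    return CrossoverResult(
        window=(lo, hi),
        crossings=tuple(crossings),
        pairs_without_crossing=tuple(empty_pairs),
        method=method,
    )


def crossover_window_from_model(
    model,
    params,
    data: Dataset,
    n_pressure: int = 200,
    method: str = "interpolated",
) -> CrossoverResult:
    """Model-based crossover estimate on a fine pressure grid.

    Evaluates the fitted correlation along each measured isotherm on a dense
    pressure grid (densities from the smooth interpolated surface) and runs
    the same intersection scan; gives smooth crossover estimates instead of
    segment-limited ones.
    """
    from types import SimpleNamespace

    from sccosol.data import parametric_density
    from sccosol.models import get_model, predict

    if method not in ("bracket", "interpolated"):
        raise SolubilityDataError(f"unknown crossover method {method!r}")
    spec = get_model(model)
    temps = np.sort(data.temperatures())
    if temps.size < 2:
        raise SolubilityDataError("crossover analysis requires at least two isotherms")
    P_grid = np.linspace(data.P.min(), data.P.max(), n_pressure)
    lny_by_T: dict[float, np.ndarray] = {}
    for T in temps:
        iso = data.isotherm(T)
        # state-variable view of the dense grid (finer than the 0.1 MPa
        # condition-matching resolution of a measured Dataset)
        view = SimpleNamespace(
            system=spec.system,
            T=np.full_like(P_grid, T),
            P=P_grid,
            rho=parametric_density(np.full_like(P_grid, T), P_grid),
            y3=np.interp(P_grid, iso.P, iso.y3) if spec.system == "ternary" else None,
            y2=np.full_like(P_grid, np.nan),
            solute_mw=data.solute_mw,
            solvent_mw=data.solvent_mw,
        )
        lny_by_T[float(T)] = np.log(predict(spec, params, view))
    return _scan_crossings(temps, lny_by_T, P_grid, method)
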