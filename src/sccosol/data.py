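"""Domain types, dataset I/O, unit conversions and the packaged solubility tables.

Solubility data are isothermal measurements of the equilibrium mole fraction
``y2`` of a solid solute in supercritical CO2 at a set of (T, P) conditions,
with the CO2 density at each condition. Ternary (cosolvent) datasets carry in
addition the cosolvent mole fraction ``y3``. Two curated datasets ship with
the package: ketoconazole in SC-CO2 (``ktz_binary``, 28 conditions over
308-338 K and 12-30 MPa) and ketoconazole in SC-CO2 + menthol
(``ktz_ternary``, same grid).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

# Physico-chemical constants for the shipped system
MW_KETOCONAZOLE = 531.0  # g/mol
MW_CO2 = 44.01  # g/mol
MW_MENTHOL = 156.26  # g/mol
T_CRITICAL = 304.1  # K, CO2
P_CRITICAL = 7.38  # MPa, CO2
RHO_CRITICAL = 467.6  # kg/m3, CO2
R_GAS = 8.314  # J mol-1 K-1

BUILTIN_DATASETS = ("ktz_binary", "ktz_ternary")

_REQUIRED_COLUMNS = {"binary": ("T_K", "P_MPa", "y2"), "ternary": ("T_K", "P_MPa", "y2", "y3")}


class SolubilityDataError(ValueError):
    """Invalid solubility data (failed invariant, malformed stream, bad key)."""


def _condition_key(T: float, P: float) -> tuple[float, float]:
    # match conditions after rounding to the instrument resolution (0.1 K, 0.1 MPa)
    return (round(float(T), 1), round(float(P), 1))


@dataclass(frozen=True)
class SolubilityRecord:
    """One equilibrium measurement at a single (T, P) condition.

    Parameters
    ----------
    T : float
        Temperature in K; must lie above the CO2 critical temperature.
    P : float
        Pressure in MPa; must lie above the CO2 critical pressure.
    rho : float
        Density of the supercritical CO2 phase in kg/m3.
    y2 : float
        Solute mole fraction in the fluid phase (0 < y2 < 1).
    y3 : float, optional
        Cosolvent mole fraction; present only for ternary records.
    S : float, optional
        Solubility in grams of solute per liter of fluid; derivable from
        (y2, rho) via :func:`mole_fraction_to_mass_conc`.
    """

    T: float
    P: float
    rho: float
    y2: float
    y3: float | None = None
    S: float | None = None

    def __post_init__(self) -> None:
        if not self.T > T_CRITICAL:
            raise SolubilityDataError(
                f"T = {self.T} K is not supercritical (requires T > {T_CRITICAL} K)"
            )
        if not self.P > P_CRITICAL:
            raise SolubilityDataError(
                f"P = {self.P} MPa is not supercritical (requires P > {P_CRITICAL} MPa)"
            )
        if not self.rho > 0:
            raise SolubilityDataError(f"density must be positive, got {self.rho}")
        if not 0.0 < self.y2 < 1.0:
            raise SolubilityDataError(f"solute mole fraction must be in (0, 1), got {self.y2}")
        if self.y3 is not None:
            if not 0.0 < self.y3 < 1.0:
                raise SolubilityDataError(
                    f"cosolvent mole fraction must be in (0, 1), got {self.y3}"
                )
            if not self.y2 + self.y3 < 1.0:
                raise SolubilityDataError("y2 + y3 must be below 1")

    @property
    def condition(self) -> tuple[float, float]:
        return _condition_key(self.T, self.P)


@dataclass(frozen=True)
class Dataset:
    """A validated collection of solubility records for one system.

    All records must share the system kind (binary records carry no ``y3``,
    ternary records all do) and (T, P) conditions must be unique.
    """

    system: str
    records: tuple[SolubilityRecord, ...]
    solute_mw: float = MW_KETOCONAZOLE
    solvent_mw: float = MW_CO2
    cosolvent_mw: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.system not in ("binary", "ternary"):
            raise SolubilityDataError(f"unknown system kind {self.system!r}")
        if not self.records:
            raise SolubilityDataError("no records")
        object.__setattr__(self, "records", tuple(self.records))
        for i, rec in enumerate(self.records):
            has_y3 = rec.y3 is not None
            if self.system == "ternary" and not has_y3:
                raise SolubilityDataError(f"record {i}: ternary dataset requires y3")
            if self.system == "binary" and has_y3:
                raise SolubilityDataError(f"record {i}: binary dataset must not carry y3")
        keys = [rec.condition for rec in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise SolubilityDataError(f"duplicate (T, P) conditions: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def T(self) -> np.ndarray:
        return np.array([r.T for r in self.records], dtype=float)

    @property
    def P(self) -> np.ndarray:
        return np.array([r.P for r in self.records], dtype=float)

    @property
    def rho(self) -> np.ndarray:
        return np.array([r.rho for r in self.records], dtype=float)

    @property
    def y2(self) -> np.ndarray:
        return np.array([r.y2 for r in self.records], dtype=float)

    @property
    def y3(self) -> np.ndarray:
        if self.system != "ternary":
            raise SolubilityDataError("binary dataset has no cosolvent mole fractions")
        return np.array([r.y3 for r in self.records], dtype=float)

    def temperatures(self) -> np.ndarray:
        return np.unique(self.T)

    def isotherm(self, T: float) -> "Dataset":
        recs = [r for r in self.records if _condition_key(r.T, 0)[0] == round(float(T), 1)]
        if not recs:
            raise SolubilityDataError(f"no records at T = {T} K")
        return Dataset(self.system, tuple(sorted(recs, key=lambda r: r.P)), self.solute_mw,
                       self.solvent_mw, self.cosolvent_mw, f"{self.label}@{T}K")

    def to_frame(self) -> pd.DataFrame:
        cols = {"T_K": self.T, "P_MPa": self.P, "rho_kg_m3": self.rho, "y2": self.y2}
        if self.system == "ternary":
            cols["y3"] = self.y3
        s = [r.S for r in self.records]
        if all(v is not None for v in s):
            cols["S_g_per_L"] = np.array(s, dtype=float)
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class ReplicateSet:
    """Repeated mole-fraction measurements of one condition (n >= 2)."""

    values: tuple[float, ...]
    n: int = -1

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if self.n == -1:
            object.__setattr__(self, "n", len(self.values))
        if self.n != len(self.values):
            raise SolubilityDataError(
                f"replicate count n = {self.n} does not match {len(self.values)} values"
            )
        if self.n < 2:
            raise SolubilityDataError("replicate statistics require at least two measurements")


# ---------------------------------------------------------------------------
# Dataset I/O


def load_dataset(
    source,
    system: str,
    *,
    solute_mw: float = MW_KETOCONAZOLE,
    solvent_mw: float = MW_CO2,
    cosolvent_mw: float | None = None,
    label: str = "",
) -> Dataset:
    """Read a CSV stream/path into a validated :class:`Dataset`.

    The stream must carry a header with columns ``T_K``, ``P_MPa``, ``y2``
    (plus ``y3`` for a ternary system); ``rho_kg_m3`` is optional and is
    filled from the packaged density table when absent. Rows violating the
    record invariants are reported with their (0-based) row index.
    """
    if system not in _REQUIRED_COLUMNS:
        raise SolubilityDataError(f"unknown system kind {system!r}")
    try:
        frame = pd.read_csv(source)
    except pd.errors.EmptyDataError as exc:
        raise SolubilityDataError("no records: empty stream") from exc
    missing = [c for c in _REQUIRED_COLUMNS[system] if c not in frame.columns]
    if missing:
        raise SolubilityDataError(f"missing mandatory column(s): {', '.join(missing)}")
    if frame.empty:
        raise SolubilityDataError("no records")

    records: list[SolubilityRecord] = []
    problems: list[str] = []
    for i, row in frame.iterrows():
        try:
            rho = float(row["rho_kg_m3"]) if "rho_kg_m3" in frame.columns else density_at(
                float(row["T_K"]), float(row["P_MPa"])
            )
            records.append(
                SolubilityRecord(
                    T=float(row["T_K"]),
                    P=float(row["P_MPa"]),
                    rho=rho,
                    y2=float(row["y2"]),
                    y3=float(row["y3"]) if system == "ternary" else None,
                    S=float(row["S_g_per_L"]) if "S_g_per_L" in frame.columns else None,
                )
            )
        except (SolubilityDataError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise SolubilityDataError("invalid rows:\n" + "\n".join(problems))
    if cosolvent_mw is None and system == "ternary":
        cosolvent_mw = MW_MENTHOL
    return Dataset(system, tuple(records), solute_mw, solvent_mw, cosolvent_mw, label)


def builtin_table(name: str) -> pd.DataFrame:
    """Raw packaged table (all printed columns, descaled SI values)."""
    if name not in BUILTIN_DATASETS:
        raise SolubilityDataError(
            f"unknown dataset {name!r}; available: {', '.join(BUILTIN_DATASETS)}"
        )
    ref = resources.files("sccosol").joinpath(f"datasets/{name}.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def builtin_dataset(name: str) -> Dataset:
    """Load one of the packaged datasets (``ktz_binary`` or ``ktz_ternary``)."""
    frame = builtin_table(name)
    system = "ternary" if "y3" in frame.columns else "binary"
    buf = io.StringIO()
    frame.to_csv(buf, index=False)
    buf.seek(0)
    return load_dataset(buf, system, label=name)


# ---------------------------------------------------------------------------
# Density providers

_external_density_backend: Callable[[float, float], float] | None = None
_density_table: dict[tuple[float, float], float] | None = None


def register_density_backend(fn: Callable[[float, float], float] | None) -> None:
    """Register a pure-CO2 property backend ``fn(T_K, P_MPa) -> kg/m3``.

    Any callable computing the density of pure CO2 (for example a wrapper
    around a reference equation-of-state library) can serve as the
    ``external`` provider of :func:`density_at`.
    """
    global _external_density_backend
    _external_density_backend = fn


def _table() -> dict[tuple[float, float], float]:
    global _density_table
    if _density_table is None:
        frame = builtin_table("ktz_binary")
        _density_table = {
            _condition_key(t, p): rho
            for t, p, rho in zip(frame["T_K"], frame["P_MPa"], frame["rho_kg_m3"])
        }
    return _density_table


def density_at(T: float, P: float, provider: str = "table") -> float:
    """CO2 density (kg/m3) at (T in K, P in MPa).

    ``table`` looks the condition up on the packaged measurement grid;
    ``external`` delegates to the backend installed with
    :func:`register_density_backend`.
    """
    if provider == "table":
        key = _condition_key(T, P)
        try:
            return _table()[key]
        except KeyError:
            raise SolubilityDataError(
                f"condition not tabulated: (T = {T} K, P = {P} MPa)"
            ) from None
    if provider == "external":
        if _external_density_backend is None:
            raise SolubilityDataError(
                "no external density backend registered; see register_density_backend"
            )
        return float(_external_density_backend(float(T), float(P)))
    raise SolubilityDataError(f"unknown density provider {provider!r}")


def parametric_density(T, P):
    """Smooth density surface interpolating the packaged (T, P, rho) grid.

    Tensor PCHIP interpolation: monotone-preserving along each axis, so the
    surface increases with P and decreases with T wherever the underlying
    grid does. Valid over the grid hull (308-338 K, 12-30 MPa).
    """
    from scipy.interpolate import PchipInterpolator

    frame = builtin_table("ktz_binary")
    piv = frame.pivot(index="T_K", columns="P_MPa", values="rho_kg_m3")
    T_grid = piv.index.to_numpy(dtype=float)
    P_grid = piv.columns.to_numpy(dtype=float)
    T_in = np.asarray(T, dtype=float)
    scalar = T_in.ndim == 0 and np.asarray(P).ndim == 0
    T_arr, P_arr = np.broadcast_arrays(np.atleast_1d(T_in), np.atleast_1d(np.asarray(P, float)))
    if (
        np.any(T_arr < T_grid[0])
        or np.any(T_arr > T_grid[-1])
        or np.any(P_arr < P_grid[0])
        or np.any(P_arr > P_grid[-1])
    ):
        raise SolubilityDataError(
            f"parametric density surface is defined on "
            f"[{T_grid[0]}, {T_grid[-1]}] K x [{P_grid[0]}, {P_grid[-1]}] MPa"
        )
    # interpolate along P within each measured isotherm, then along T,
    # grouped by unique temperature so grid-shaped queries stay fast
    rows = piv.to_numpy(dtype=float)
    along_p = np.array([PchipInterpolator(P_grid, row)(P_arr) for row in rows])
    out = np.empty_like(T_arr, dtype=float)
    for t_val in np.unique(T_arr):
        sel = T_arr == t_val
        out[sel] = PchipInterpolator(T_grid, along_p[:, sel], axis=0)(t_val)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Unit conversions


def mole_fraction_to_mass_conc(
    y2,
    rho,
    solute_mw: float = MW_KETOCONAZOLE,
    solvent_mw: float = MW_CO2,
    mode: str = "dilute",
):
    """Convert solute mole fraction to solubility in g per liter of fluid.

    ``dilute`` uses S = rho * y2 * M2 / M1 (valid for y2 << 1, the convention
    used for the packaged tables); ``exact`` uses the full mixture molar mass
    S = rho * y2 * M2 / (y2 * M2 + (1 - y2) * M1).
    """
    y2 = np.asarray(y2, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(y2 < 0) or np.any(y2 >= 1):
        raise SolubilityDataError("mole fraction must satisfy 0 <= y2 < 1")
    if np.any(rho <= 0) or solute_mw <= 0 or solvent_mw <= 0:
        raise SolubilityDataError("density and molecular weights must be positive")
    if mode == "dilute":
        out = rho * y2 * solute_mw / solvent_mw
    elif mode == "exact":
        out = rho * y2 * solute_mw / (y2 * solute_mw + (1.0 - y2) * solvent_mw)
    else:
        raise SolubilityDataError(f"unknown conversion mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def mass_conc_to_mole_fraction(
    S,
    rho,
    solute_mw: float = MW_KETOCONAZOLE,
    solvent_mw: float = MW_CO2,
    mode: str = "dilute",
):
    """Exact inverse of :func:`mole_fraction_to_mass_conc` in the same mode."""
    S = np.asarray(S, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(S < 0):
        raise SolubilityDataError("solubility must be non-negative")
    if np.any(rho <= 0) or solute_mw <= 0 or solvent_mw <= 0:
        raise SolubilityDataError("density and molecular weights must be positive")
    if mode == "dilute":
        out = S * solvent_mw / (rho * solute_mw)
    elif mode == "exact":
        out = S * solvent_mw / (rho * solute_mw - S * (solute_mw - solvent_mw))
    else:
        raise SolubilityDataError(f"unknown conversion mode {mode!r}")
    if np.any(np.asarray(out) >= 1.0):
        raise SolubilityDataError("solubility implies a mole fraction >= 1")
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Replicate statistics and uncertainty combination


def replicate_stats(replicates: ReplicateSet | Sequence[float]):
    """(mean, sd, sd_of_mean, relative standard uncertainty) of replicates.

    The standard deviation uses the n-1 denominator; the relative standard
    uncertainty is sd / mean.
    """
    if not isinstance(replicates, ReplicateSet):
        replicates = ReplicateSet(tuple(replicates))
    vals = np.array(replicates.values, dtype=float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    sd_of_mean = sd / math.sqrt(replicates.n)
    if mean == 0:
        raise SolubilityDataError("relative uncertainty undefined for zero mean")
    return mean, sd, sd_of_mean, sd / mean


def expanded_uncertainty(
    relative_components: Iterable[float], y: float, k: float = 2.0
) -> float:
    """Expanded uncertainty U = k * y * sqrt(sum of squared relative components).

    ``relative_components`` are the sensitivity-weighted relative standard
    uncertainties of the input estimates; ``k`` is the coverage factor
    (default 2, ~95 % confidence).
    """
    comps = np.array(list(relative_components), dtype=float)
    if comps.size == 0:
        raise SolubilityDataError("at least one uncertainty component is required")
    if not k > 0:
        raise SolubilityDataError("coverage factor must be positive")
    return float(k * abs(y) * math.sqrt(float(np.sum(comps**2))))
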