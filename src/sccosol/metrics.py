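"""Goodness-of-fit statistics used to rank the correlations.

The headline accuracy criterion is the average absolute relative deviation
(AARD) normalized by N - Z, i.e. the residual degrees of freedom after
fitting Z adjustable coefficients:

    AARD% = 100 / (N - Z) * sum_i |y_calc_i - y_exp_i| / y_exp_i

which penalizes heavily-parameterized models relative to the plain 100/N
mean (available as the ``"n"`` normalization; the two differ exactly by the
factor N / (N - Z)).

The adjusted correlation coefficient follows the unconventional
absolute-value square-root form used alongside these correlations,

    R_adj = sqrt(| R^2 - Q (1 - R^2) / (N - Q - 1) |)

with Q the number of independent state variables of the model; the familiar
adjusted R^2 (1 - (1 - R^2)(N - 1)/(N - Q - 1)) is available behind
``form="conventional"``.
"""

from __future__ import annotations

import math

import numpy as np


class MetricError(ValueError):
    """Degenerate metric input (too few points, zero variance, ...)."""


def _validate(y_exp, y_model) -> tuple[np.ndarray, np.ndarray]:
    y_exp = np.asarray(y_exp, dtype=float)
    y_model = np.asarray(y_model, dtype=float)
    if y_exp.shape != y_model.shape or y_exp.ndim != 1:
        raise MetricError("observed and predicted vectors must be 1-D and equally long")
    return y_exp, y_model


def aard_percent(y_exp, y_calc, Z: int = 0, normalization: str = "n_minus_z") -> float:
    """Average absolute relative deviation in percent.

    ``normalization="n_minus_z"`` divides the summed relative deviations by
    N - Z (degrees-of-freedom form); ``"n"`` divides by N.
    """
    y_exp, y_calc = _validate(y_exp, y_calc)
    if np.any(y_exp <= 0):
        raise MetricError("AARD requires strictly positive observed values")
    n = y_exp.size
    rel = np.abs(y_calc - y_exp) / y_exp
    if normalization == "n_minus_z":
        if n <= Z:
            raise MetricError(f"N = {n} must exceed Z = {Z} for the N-Z normalization")
        return float(100.0 * rel.sum() / (n - Z))
    if normalization == "n":
        return float(100.0 * rel.sum() / n)
    raise MetricError(f"unknown AARD normalization {normalization!r}")


def r_squared(y_exp, y_model) -> float:
    """R^2 = 1 - SS_E / SS_T with the uncentered-minus-correction SS_T form.

    SS_T = sum(y_exp^2) - (sum y_exp)^2 / N, which is algebraically the
    centered sum of squares; SS_E = sum((y_exp - y_model)^2).
    """
    y_exp, y_model = _validate(y_exp, y_model)
    n = y_exp.size
    if n < 2:
        raise MetricError("R^2 requires at least two observations")
    ss_t = float(np.sum(y_exp**2) - np.sum(y_exp) ** 2 / n)
    ss_e = float(np.sum((y_exp - y_model) ** 2))
    scale = float(np.sum(y_exp**2))
    if ss_t <= 0 or (scale > 0 and ss_t < 1e-14 * scale):
        raise MetricError("R^2 undefined for constant observations (SS_T = 0)")
    return 1.0 - ss_e / ss_t


def r_adjusted(y_exp, y_model, Q: int, form: str = "paper") -> float:
    """Adjusted correlation coefficient penalizing the Q state variables.

    ``form="paper"`` returns sqrt(|R^2 - Q(1-R^2)/(N-Q-1)|); ``"conventional"``
    returns the textbook adjusted R^2.
    """
    y_exp, y_model = _validate(y_exp, y_model)
    n = y_exp.size
    if n <= Q + 1:
        raise MetricError(f"N = {n} must exceed Q + 1 = {Q + 1}")
    r2 = r_squared(y_exp, y_model)
    if form == "paper":
        return math.sqrt(abs(r2 - Q * (1.0 - r2) / (n - Q - 1)))
    if form == "conventional":
        return 1.0 - (1.0 - r2) * (n - 1) / (n - Q - 1)
    raise MetricError(f"unknown adjusted-R form {form!r}")
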