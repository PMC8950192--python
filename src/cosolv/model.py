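"""Jouyban-Acree cosolvency model: regression, fitting, and prediction.

The model expresses the log saturated solubility in a binary solvent
mixture as the composition-weighted mean of the mono-solvent log
solubilities plus a temperature-scaled interaction polynomial::

    ln x_m(T) = w1*ln x1(T) + w2*ln x2(T)
                + (w1*w2/T) * sum_{i=0}^{np} J_i * (w1 - w2)**i

with w2 = 1 - w1 the solute-free composition of the second solvent and
J_i coefficients in kelvin.  The J terms are estimated by ordinary least
squares of the excess-log response ``ln x_m - w1*ln x1 - w2*ln x2``
against the regressors ``w1*w2*(w1-w2)**i / T``, no intercept.  With all
J_i = 0 the model reduces to the Yalkowsky log-linear mixing rule.

Pure-solvent records (w1*w2 = 0) carry identically-zero regressors and
response; they are excluded from the regression rows but retained in
back-calculation, where the model returns the experimental anchors
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import statsmodels.api as sm

from cosolv.datamodel import UnitCode
from cosolv.units import ConvertedDataset

__all__ = [
    "FitError",
    "UnderdeterminedError",
    "JouybanAcreeFit",
    "BackCalculation",
    "build_regression",
    "fit_ja",
    "predict_ln_solubility",
    "back_calculate",
    "yalkowsky_predict",
]

MAX_NP = 4


class FitError(ValueError):
    """The regression cannot be estimated."""


class UnderdeterminedError(FitError):
    """Fewer usable regression rows than coefficients."""


@dataclass
class JouybanAcreeFit:
    """Estimated interaction coefficients J_0..J_np (kelvin) and inference.

    ``retained`` marks terms kept by significance pruning; pruned
    coefficients are exactly 0 and their standard errors / p-values NaN.
    """

    coefficients: np.ndarray  # length np+1, kelvin
    standard_errors: np.ndarray
    p_values: np.ndarray
    retained: np.ndarray  # bool mask
    np_index: int  # highest power of (w1 - w2)
    n_regression_points: int
    code: Optional[UnitCode] = None
    dataset_label: str = ""
    alpha: Optional[float] = None  # pruning level, None = pruning disabled

    @property
    def n_terms(self) -> int:
        return self.np_index + 1

    def to_dict(self) -> dict:
        return {
            "coefficients_K": [float(c) for c in self.coefficients],
            "standard_errors_K": [float(s) for s in self.standard_errors],
            "p_values": [float(p) for p in self.p_values],
            "retained": [bool(r) for r in self.retained],
            "np": self.np_index,
            "n_regression_points": self.n_regression_points,
            "code": None if self.code is None else int(self.code),
            "dataset_label": self.dataset_label,
            "alpha": self.alpha,
        }


@dataclass
class BackCalculation:
    """Experimental vs back-calculated solubilities, one pair per record."""

    x_exp: np.ndarray
    x_cal: np.ndarray

    def __post_init__(self) -> None:
        self.x_exp = np.asarray(self.x_exp, dtype=float)
        self.x_cal = np.asarray(self.x_cal, dtype=float)
        if self.x_exp.shape != self.x_cal.shape:
            raise ValueError("x_exp and x_cal must have the same length")

    def __len__(self) -> int:
        return len(self.x_exp)


def _validate_np(np_index: int) -> None:
    if not (0 <= np_index <= MAX_NP):
        raise ValueError(f"np must be in 0..{MAX_NP}, got {np_index}")


def build_regression(
    conv: ConvertedDataset, np_index: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the OLS system (response vector, design matrix).

    One row per mixed-composition record (0 < w1 < 1).  The response is
    the excess-log solubility ``ln x_m - w1*ln x1_T - w2*ln x2_T``;
    design column i (i = 0..np) is ``w1*w2*(w1-w2)**i / T``.
    """
    _validate_np(np_index)
    w1 = np.asarray(conv.w1, dtype=float)
    mask = (w1 > 0.0) & (w1 < 1.0)
    n_rows = int(mask.sum())
    if n_rows < np_index + 1:
        raise UnderdeterminedError(
            f"{n_rows} mixed-composition rows but {np_index + 1} coefficients"
        )
    w1 = w1[mask]
    w2 = 1.0 - w1
    T = conv.temperature[mask]
    y = (
        np.log(conv.x_m[mask])
        - w1 * np.log(conv.x1_T[mask])
        - w2 * np.log(conv.x2_T[mask])
    )
    base = w1 * w2 / T
    X = np.column_stack([base * (w1 - w2) ** i for i in range(np_index + 1)])
    return y, X


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS without intercept; returns (coef, se, two-sided p)."""
    res = sm.OLS(y, X).fit()
    return res.params, res.bse, res.pvalues


def _check_rank(X: np.ndarray, np_index: int) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise FitError(
            f"rank-deficient design (rank {rank} < {X.shape[1]} columns): "
            f"powers of (w1-w2) up to {np_index} are collinear on this grid"
        )


def fit_ja(
    conv: ConvertedDataset,
    np_index: int = 2,
    prune: bool = False,
    alpha: float = 0.05,
) -> JouybanAcreeFit:
    """Estimate J_0..J_np by OLS, optionally pruning insignificant terms.

    Pruning is one-at-a-time backward elimination: repeatedly drop the
    single retained term with the largest two-sided p-value exceeding
    ``alpha`` and refit, until every retained term has p <= alpha or only
    one term remains.  Ties are broken by dropping the higher-order term.
    Pruned coefficients are reported as exactly 0.
    """
    y, X = build_regression(conv, np_index)
    _check_rank(X, np_index)
    k = np_index + 1
    retained = np.ones(k, dtype=bool)

    coef_r, se_r, p_r = _ols(y, X)
    if prune:
        while retained.sum() > 1:
            over = (p_r > alpha) | np.isnan(p_r)
            if not over.any():
                break
            # index (within retained set) of the worst term; ties -> higher order
            p_cmp = np.where(np.isnan(p_r), np.inf, p_r)
            worst_local = int(np.max(np.flatnonzero(p_cmp == p_cmp.max())))
            drop_global = int(np.flatnonzero(retained)[worst_local])
            retained[drop_global] = False
            coef_r, se_r, p_r = _ols(y, X[:, retained])

    coefficients = np.zeros(k)
    standard_errors = np.full(k, np.nan)
    p_values = np.full(k, np.nan)
    idx = np.flatnonzero(retained)
    coefficients[idx] = coef_r
    standard_errors[idx] = se_r
    p_values[idx] = p_r
    return JouybanAcreeFit(
        coefficients=coefficients,
        standard_errors=standard_errors,
        p_values=p_values,
        retained=retained,
        np_index=np_index,
        n_regression_points=X.shape[0],
        code=conv.code,
        dataset_label=conv.source.label,
        alpha=alpha if prune else None,
    )


def predict_ln_solubility(
    fit: Union[JouybanAcreeFit, Sequence[float]],
    w1: float,
    T: float,
    ln_x1: float,
    ln_x2: float,
) -> float:
    """Evaluate the model at one condition, returning ln solubility.

    ``fit`` may be a :class:`JouybanAcreeFit` or a bare J-coefficient
    sequence.  At w1 = 1 (resp. 0) returns ``ln_x1`` (``ln_x2``) exactly.
    """
    J = fit.coefficients if isinstance(fit, JouybanAcreeFit) else np.asarray(fit, float)
    if w1 == 1.0:
        return ln_x1
    if w1 == 0.0:
        return ln_x2
    w2 = 1.0 - w1
    diff = w1 - w2
    interaction = sum(J[i] * diff**i for i in range(len(J)))
    return w1 * ln_x1 + w2 * ln_x2 + (w1 * w2 / T) * interaction


def yalkowsky_predict(w1: float, ln_x1: float, ln_x2: float) -> float:
    """Ideal log-linear mixing rule: ln x_m = w1*ln_x1 + w2*ln_x2.

    The special case of the full model with every J term zero.
    """
    if w1 == 1.0:
        return ln_x1
    if w1 == 0.0:
        return ln_x2
    return w1 * ln_x1 + (1.0 - w1) * ln_x2


def back_calculate(fit: JouybanAcreeFit, conv: ConvertedDataset) -> BackCalculation:
    """Back-calculate every record (pure-solvent points included).

    Uses the experimental mono-solvent anchors at each record's
    temperature; anchor records therefore reproduce their experimental
    values exactly.
    """
    n = len(conv)
    x_cal = np.empty(n)
    for i in range(n):
        w1 = conv.w1[i]
        if w1 == 1.0:
            x_cal[i] = conv.x1_T[i]
        elif w1 == 0.0:
            x_cal[i] = conv.x2_T[i]
        else:
            ln_pred = predict_ln_solubility(
                fit,
                w1,
                conv.temperature[i],
                np.log(conv.x1_T[i]),
                np.log(conv.x2_T[i]),
            )
            x_cal[i] = np.exp(ln_pred)
    return BackCalculation(x_exp=conv.x_m.copy(), x_cal=x_cal)
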