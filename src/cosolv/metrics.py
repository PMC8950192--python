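"""Accuracy criteria for back-calculated solubilities.

Five criteria: percentage mean relative deviation (MRD%), root-mean-square
deviation on the arithmetic (RMSD1) and logarithmic (RMSD2) scales, and
mean absolute deviation on the arithmetic (E1) and logarithmic (E2)
scales.  MRD%, RMSD2, and E2 are invariant under uniform positive scaling
of both solubility vectors; RMSD1 and E1 are homogeneous of degree 1 (so
the g/L-unit values of a dataset are exactly the molar-unit values times
the drug's molar mass).

MRD% and E1 are defined with absolute deviations: the printed formulas
omit the bars, but signed means could cancel to zero for bias-free fits,
which would contradict their use as fit-quality criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cosolv.model import BackCalculation

__all__ = [
    "MetricsReport",
    "mrd_percent",
    "rmsd_arith",
    "rmsd_log",
    "e_arith",
    "e_log",
    "metrics_report",
    "correlate_metrics",
    "METRIC_NAMES",
]

METRIC_NAMES = ("mrd_percent", "rmsd_arith", "rmsd_log", "e_arith", "e_log")

#: conventional presentation scalings (reporting layer only; stored values
#: are never scaled)
PRESENTATION_SCALE = {"rmsd_arith": 1e5, "rmsd_log": 100.0}


def _vectors(bc: BackCalculation) -> tuple[np.ndarray, np.ndarray]:
    if len(bc) == 0:
        raise ValueError("empty back-calculation: no data points")
    return bc.x_cal, bc.x_exp


def mrd_percent(bc: BackCalculation) -> float:
    """Percentage mean relative deviation: (100/N) sum |xCal-xExp|/xExp."""
    cal, exp = _vectors(bc)
    if not np.all(exp > 0):
        raise ValueError("experimental solubilities must be > 0")
    return float(100.0 * np.mean(np.abs(cal - exp) / exp))


def rmsd_arith(bc: BackCalculation) -> float:
    """Arithmetic-scale RMSD: sqrt(sum (xCal-xExp)^2 / N)."""
    cal, exp = _vectors(bc)
    return float(np.sqrt(np.mean((cal - exp) ** 2)))


def rmsd_log(bc: BackCalculation) -> float:
    """Log-scale RMSD: sqrt(sum (ln xCal - ln xExp)^2 / N)."""
    cal, exp = _vectors(bc)
    return float(np.sqrt(np.mean((np.log(cal) - np.log(exp)) ** 2)))


def e_arith(bc: BackCalculation) -> float:
    """Arithmetic-scale mean absolute deviation: sum |xCal-xExp| / N."""
    cal, exp = _vectors(bc)
    return float(np.mean(np.abs(cal - exp)))


def e_log(bc: BackCalculation) -> float:
    """Log-scale mean absolute deviation: sum |ln xCal - ln xExp| / N."""
    cal, exp = _vectors(bc)
    return float(np.mean(np.abs(np.log(cal) - np.log(exp))))


@dataclass
class MetricsReport:
    """The five error criteria for one back-calculation plus N."""

    mrd_percent: float
    rmsd_arith: float
    rmsd_log: float
    e_arith: float
    e_log: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "mrd_percent": self.mrd_percent,
            "rmsd_arith": self.rmsd_arith,
            "rmsd_log": self.rmsd_log,
            "e_arith": self.e_arith,
            "e_log": self.e_log,
            "n_points": self.n_points,
        }

    def values(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in METRIC_NAMES])


def metrics_report(bc: BackCalculation) -> MetricsReport:
    """Compute all five criteria over every record of a back-calculation."""
    return MetricsReport(
        mrd_percent=mrd_percent(bc),
        rmsd_arith=rmsd_arith(bc),
        rmsd_log=rmsd_log(bc),
        e_arith=e_arith(bc),
        e_log=e_log(bc),
        n_points=len(bc),
    )


def correlate_metrics(
    reports: Sequence[MetricsReport], reference: str = "mrd_percent"
) -> pd.DataFrame:
    """Correlate each criterion against a reference criterion across datasets.

    Returns a frame indexed by metric name with Pearson and Spearman
    coefficients versus ``reference``.  A constant metric vector makes the
    correlation undefined; such rows are flagged (``degenerate=True``,
    NaN coefficients) rather than dropped.
    """
    if reference not in METRIC_NAMES:
        raise ValueError(f"unknown reference metric {reference!r}")
    if len(reports) < 3:
        raise ValueError("need >= 3 reports to correlate metrics")
    table = {m: np.array([getattr(r, m) for r in reports]) for m in METRIC_NAMES}
    ref = table[reference]
    rows = []
    ref_constant = np.ptp(ref) == 0
    for m in METRIC_NAMES:
        vec = table[m]
        degenerate = ref_constant or np.ptp(vec) == 0
        if degenerate:
            pearson = spearman = np.nan
        else:
            pearson = stats.pearsonr(vec, ref).statistic
            spearman = stats.spearmanr(vec, ref).statistic
        rows.append(
            {
                "metric": m,
                "pearson": pearson,
                "spearman": spearman,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("metric")
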