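"""Comparative study orchestration.

Runs the nine-code fitting over a batch of datasets, aggregates the error
criteria per code and per drug, computes composition-skew diagnostics,
correlates criteria against MRD%, and performs single-record outlier
perturbation experiments.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from cosolv.datamodel import SolubilityDataset, SolventBasis, UnitCode
from cosolv.metrics import (
    METRIC_NAMES,
    MetricsReport,
    correlate_metrics,
    metrics_report,
)
from cosolv.model import JouybanAcreeFit, back_calculate, fit_ja
from cosolv.synth import inject_outlier
from cosolv.units import convert_dataset

__all__ = [
    "CodeResult",
    "StudySummary",
    "PerturbationResult",
    "run_code_analysis",
    "run_full_study",
    "composition_skew",
    "perturb_and_compare",
]

logger = logging.getLogger("cosolv")


@dataclass
class CodeResult:
    """Outcome of analysing one dataset under one unit code."""

    dataset_label: str
    drug_name: str
    code: int
    fit: Optional[JouybanAcreeFit] = None
    metrics: Optional[MetricsReport] = None
    error: Optional[str] = None

    @property
    def failed(self) -> bool:
        return self.error is not None


@dataclass
class PerturbationResult:
    """Metric values before and after a single-record perturbation + refit."""

    dataset_label: str
    record_index: int
    original_value: float
    perturbed_value: float
    code: int
    before: MetricsReport
    after: MetricsReport
    anchor_perturbed: bool = False

    def deltas(self) -> dict:
        return {
            m: getattr(self.after, m) - getattr(self.before, m) for m in METRIC_NAMES
        }


def _as_code(code: Union[int, UnitCode]) -> UnitCode:
    return code if isinstance(code, UnitCode) else UnitCode(int(code))


def run_code_analysis(
    dataset: SolubilityDataset,
    code: Union[int, UnitCode],
    np_index: int = 2,
    prune: bool = False,
    alpha: float = 0.05,
) -> tuple[JouybanAcreeFit, MetricsReport]:
    """Convert -> fit -> back-calculate -> metrics for one dataset/code pair."""
    code = _as_code(code)
    conv = convert_dataset(dataset, code)
    fit = fit_ja(conv, np_index=np_index, prune=prune, alpha=alpha)
    bc = back_calculate(fit, conv)
    report = metrics_report(bc)
    logger.info(
        "fit %s %s: retained=%s MRD%%=%.3f",
        dataset.label,
        code,
        list(np.flatnonzero(fit.retained)),
        report.mrd_percent,
    )
    return fit, report


@dataclass
class StudySummary:
    """Per-(dataset, code) fits and metrics plus study-level aggregates."""

    results: list[CodeResult]
    skew: pd.DataFrame  # per dataset: mean w1 in each basis

    def summary_frame(self) -> pd.DataFrame:
        """One row per (dataset, code) with coefficients and all metrics."""
        rows = []
        for r in self.results:
            row = {
                "dataset": r.dataset_label,
                "drug": r.drug_name,
                "code": r.code,
                "failed": r.failed,
                "error": r.error or "",
            }
            if r.fit is not None:
                for i, c in enumerate(r.fit.coefficients):
                    row[f"J{i}"] = c
                row["n_regression_points"] = r.fit.n_regression_points
            if r.metrics is not None:
                row.update(r.metrics.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def overall_frame(self) -> pd.DataFrame:
        """Per code: unweighted mean MRD% across datasets and its sample SD."""
        ok = [r for r in self.results if not r.failed]
        rows = []
        for code in sorted({r.code for r in ok}):
            vals = np.array([r.metrics.mrd_percent for r in ok if r.code == code])
            rows.append(
                {
                    "code": code,
                    "n_datasets": len(vals),
                    "overall_mrd_percent": vals.mean(),
                    "sd_mrd_percent": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def per_drug_frame(self) -> pd.DataFrame:
        """Per (drug, code): unweighted mean E1 and mean MRD%."""
        ok = [r for r in self.results if not r.failed]
        rows = []
        for drug in sorted({r.drug_name for r in ok}):
            for code in sorted({r.code for r in ok if r.drug_name == drug}):
                sel = [r for r in ok if r.drug_name == drug and r.code == code]
                rows.append(
                    {
                        "drug": drug,
                        "code": code,
                        "n_datasets": len(sel),
                        "overall_e_arith": np.mean([r.metrics.e_arith for r in sel]),
                        "overall_mrd_percent": np.mean(
                            [r.metrics.mrd_percent for r in sel]
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def correlations_frame(self, code: int = 4, reference: str = "mrd_percent") -> pd.DataFrame:
        """Metric correlations vs a reference across datasets, for one code."""
        reports = [
            r.metrics for r in self.results if r.code == code and not r.failed
        ]
        return correlate_metrics(reports, reference=reference)

    @property
    def failures(self) -> list[CodeResult]:
        return [r for r in self.results if r.failed]


def run_full_study(
    datasets: Sequence[SolubilityDataset],
    codes: Iterable[Union[int, UnitCode]] = range(1, 10),
    np_index: int = 2,
    prune: bool = False,
    alpha: float = 0.05,
) -> StudySummary:
    """Analyse every dataset under every requested code.

    A failed (dataset, code) pair is recorded with its error message and
    never aborts the batch.  Identical inputs and options give identical
    summaries.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no datasets supplied")
    codes = [_as_code(c) for c in codes]
    results = []
    for ds in datasets:
        for code in codes:
            try:
                fit, report = run_code_analysis(
                    ds, code, np_index=np_index, prune=prune, alpha=alpha
                )
                results.append(
                    CodeResult(ds.label, ds.drug.name, code.code, fit, report)
                )
            except Exception as exc:  # recorded, not raised
                logger.warning("dataset %s %s failed: %s", ds.label, code, exc)
                results.append(
                    CodeResult(ds.label, ds.drug.name, code.code, error=str(exc))
                )
    skew_rows = []
    for ds in datasets:
        row = {"dataset": ds.label}
        row.update(
            {f"mean_w1_{b.value}": v for b, v in composition_skew(ds).items()}
        )
        skew_rows.append(row)
    return StudySummary(results=results, skew=pd.DataFrame(skew_rows))


def composition_skew(dataset: SolubilityDataset) -> dict[SolventBasis, float]:
    """Mean solvent-1 fraction after conversion to each of the three bases.

    A mean well below 0.5 on a grid that is uniform in another basis
    signals composition skew (the usual case for mole fractions when the
    cosolvent is much heavier than water).
    """
    dataset.validate()
    out = {}
    for basis in SolventBasis:
        code = UnitCode.from_basis_unit(basis, dataset.solubility_unit)
        conv = convert_dataset(dataset, code)
        out[basis] = float(np.mean(conv.w1))
    return out


def perturb_and_compare(
    dataset: SolubilityDataset,
    record_index: int,
    code: Union[int, UnitCode],
    factor: Optional[float] = None,
    new_value: Optional[float] = None,
    np_index: int = 2,
    prune: bool = False,
    alpha: float = 0.05,
) -> PerturbationResult:
    """Refit after multiplying one record's solubility by a factor.

    Exactly one of ``factor`` / ``new_value`` must be given.  Perturbing a
    mono-solvent anchor is permitted but flagged (and warned), since it
    shifts the model's anchor solubilities as well.
    """
    if (factor is None) == (new_value is None):
        raise ValueError("give exactly one of factor or new_value")
    rec = dataset.records[record_index]
    if new_value is not None:
        if new_value <= 0:
            raise ValueError("perturbed value must be > 0")
        factor = new_value / rec.solubility_value
    anchor = rec.solvent_fraction_1 in (0.0, 1.0)
    if anchor:
        warnings.warn(
            f"perturbing a mono-solvent anchor (record {record_index}): "
            "this changes the model's anchor solubilities",
            stacklevel=2,
        )
    code = _as_code(code)
    _, before = run_code_analysis(dataset, code, np_index, prune, alpha)
    perturbed = inject_outlier(dataset, record_index, factor)
    _, after = run_code_analysis(perturbed, code, np_index, prune, alpha)
    return PerturbationResult(
        dataset_label=dataset.label,
        record_index=record_index,
        original_value=rec.solubility_value,
        perturbed_value=perturbed.records[record_index].solubility_value,
        code=code.code,
        before=before,
        after=after,
        anchor_perturbed=anchor,
    )
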