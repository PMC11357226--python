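"""RSM-vs-ANN model comparison.

Each model proposes optimum extraction conditions and a predicted yield; a
confirmatory wet-lab extraction at those conditions supplies the measured
yield.  The verification error is the absolute difference between measured
and predicted yield in response units (mg g-1) — the definition under which
the study's printed values (2.85 for the RSM, 0.79 for the ANN) are exact
arithmetic; a true percentage error is reported alongside under its own
name.  Each model's global fit is summarized by R^2 of its predictions over
the full design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ann import SurrogateModel, predict_ann
from .design import DesignTable
from .optimize import Optimum
from .rsm import QuadraticFit, fit_metrics

logger = logging.getLogger("extraopt.compare")


def verification_error(actual: float, predicted: float) -> float:
    """Absolute difference |measured - predicted| in response units."""
    if not (np.isfinite(actual) and np.isfinite(predicted)):
        raise ValueError("actual and predicted yields must be finite")
    return abs(float(actual) - float(predicted))


def percent_error(actual: float, predicted: float) -> float:
    """Percentage error 100 |measured - predicted| / measured."""
    return 100.0 * verification_error(actual, predicted) / abs(float(actual))


@dataclass
class ModelRecord:
    label: str
    optimum: Optimum
    predicted_yield: float
    verification_yield: float | None
    error: float | None          # |measured - predicted|, mg g-1
    error_percent: float | None
    r_squared: float


@dataclass
class ComparisonReport:
    models: list[ModelRecord]
    preferred: str | None     # model with the lower verification error

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.models:
            row = {"model": m.label}
            for j, v in enumerate(m.optimum.actual):
                row[f"x{j+1}_opt"] = float(v)
            row.update({
                "predicted_yield": m.predicted_yield,
                "verification_yield": m.verification_yield,
                "error": m.error,
                "error_percent": m.error_percent,
                "r_squared": m.r_squared,
            })
            rows.append(row)
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [f"{'Model':<8}{'Conditions':<34}{'Measured':>10}"
                 f"{'Predicted':>11}{'Error':>8}{'R^2':>9}"]
        for m in self.models:
            cond = ", ".join(f"{v:.6g}" for v in m.optimum.actual)
            meas = f"{m.verification_yield:.2f}" if m.verification_yield is not None else ""
            err = f"{m.error:.2f}" if m.error is not None else ""
            lines.append(f"{m.label:<8}{cond:<34}{meas:>10}"
                         f"{m.predicted_yield:>11.2f}{err:>8}{m.r_squared:>9.4f}")
        if self.preferred:
            lines.append(f"Preferred model (lower verification error): {self.preferred}")
        return "\n".join(lines)


def build_report(rsm_optimum: Optimum, ann_optimum: Optimum,
                 design: DesignTable, rsm_fit: QuadraticFit,
                 ann_model: SurrogateModel,
                 verification_yields: dict[str, float] | None = None,
                 ) -> ComparisonReport:
    """Assemble the two-model comparison.

    ``verification_yields`` maps model label ("RSM"/"ANN") to the measured
    confirmatory yield; entries may be missing (wet-lab input), in which
    case the error cells stay blank and a warning is logged.
    """
    verification_yields = verification_yields or {}
    mask = design.has_response
    records = []
    for label, opt, preds in (
        ("RSM", rsm_optimum, rsm_fit.predict(design.coded)),
        ("ANN", ann_optimum, predict_ann(ann_model, design.coded)),
    ):
        r2 = fit_metrics(design, np.asarray(preds))["r_squared"]
        meas = verification_yields.get(label)
        if meas is None:
            logger.warning("no verification yield supplied for %s; "
                           "error cells left blank", label)
            err = errp = None
        else:
            err = verification_error(meas, opt.predicted_response)
            errp = percent_error(meas, opt.predicted_response)
        records.append(ModelRecord(
            label=label, optimum=opt,
            predicted_yield=float(opt.predicted_response),
            verification_yield=meas, error=err, error_percent=errp,
            r_squared=r2,
        ))
    with_err = [m for m in records if m.error is not None]
    preferred = min(with_err, key=lambda m: m.error).label if len(with_err) == len(records) and records else None
    return ComparisonReport(models=records, preferred=preferred)
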