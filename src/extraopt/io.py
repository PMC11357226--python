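"""File formats and packaged fixtures.

Design CSV dialect: comma-separated UTF-8 with header ``run,
x1_actual,...,xk_actual[,x1_coded,...,xk_coded][,response]``.  Coded
columns are emitted by the writer but recomputed from the factor specs on
load (the specs are authoritative); a missing response cell marks a
design-only run.

Packaged fixtures (``extraopt/data``): the 29-run design/response table of
the reference extraction experiment (``table1.csv``), its factor levels
(``table4_factors.json``) and a frozen trained surrogate network
(``ann_fixture.json``).
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .ann import SurrogateModel, load_model
from .design import DesignTable, FactorSpec

logger = logging.getLogger("extraopt.io")

#: tolerance beyond [-1, +1] before a loaded coded level draws a warning
CODED_RANGE_TOL = 1e-6


class ParseError(ValueError):
    """A file does not conform to the declared dialect."""


# -- factor specs ----------------------------------------------------------

def load_factor_specs(path) -> list[FactorSpec]:
    """Factor spec JSON: a list of {name, unit, low, center, high}."""
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(raw, list) or not raw:
        raise ParseError(f"{path}: expected a non-empty list of factor objects")
    return [FactorSpec.from_dict(d) for d in raw]


def write_factor_specs(factors: list[FactorSpec], path) -> None:
    Path(path).write_text(json.dumps([f.to_dict() for f in factors], indent=1))


# -- design CSV ------------------------------------------------------------

def write_design_csv(design: DesignTable, path, header_comment: str | None = None) -> None:
    """Write run ids, actual levels, coded levels and responses.

    ``header_comment`` (without '#') is emitted as a leading comment line,
    used by the pipeline to stamp artifacts with their config hash/seed.
    """
    frame = design.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False, na_rep="")


def load_design_csv(path, factors: list[FactorSpec]) -> DesignTable:
    """Parse a design CSV against the given factor specs.

    Actual levels are read; coded levels are recomputed.  A malformed
    numeric cell raises :class:`ParseError` naming the row and column;
    coded levels outside [-1, +1] beyond tolerance draw a range warning.
    Missing responses are allowed and flagged.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    k = len(factors)
    actual_cols = [f"x{j+1}_actual" for j in range(k)]
    missing = [c for c in ["run", *actual_cols] if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")

    def cell(col: str, row: int, allow_blank=False) -> float:
        v = raw[col].iloc[row]
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
            if allow_blank:
                return np.nan
            raise ParseError(f"{path}: blank cell at row {row + 2}, column {col!r}")
        try:
            return float(v)
        except ValueError as exc:
            raise ParseError(
                f"{path}: malformed numeric cell {v!r} at row {row + 2}, column {col!r}"
            ) from exc

    n = len(raw)
    if n == 0:
        raise ParseError(f"{path}: no data rows")
    run_ids = np.array([int(cell("run", i)) for i in range(n)])
    actual = np.array([[cell(c, i) for c in actual_cols] for i in range(n)])
    if "response" in raw.columns:
        response = np.array([cell("response", i, allow_blank=True) for i in range(n)])
        n_missing = int(np.isnan(response).sum())
        if n_missing:
            logger.info("%s: %d run(s) without a response", path, n_missing)
    else:
        response = np.full(n, np.nan)
    design = DesignTable.from_actual(factors, actual, response, run_ids)
    coded = design.coded
    if np.any(np.abs(coded) > 1.0 + CODED_RANGE_TOL):
        worst = np.unravel_index(np.argmax(np.abs(coded)), coded.shape)
        logger.warning(
            "%s: coded level %.4f (run %d, factor %r) outside [-1, +1]",
            path, coded[worst], run_ids[worst[0]], factors[worst[1]].name,
        )
    return design


# -- packaged fixtures -----------------------------------------------------

def _data_path(name: str):
    return resources.files("extraopt").joinpath("data", name)


def fixture_factors() -> list[FactorSpec]:
    """The reference experiment's four factors and levels."""
    with resources.as_file(_data_path("table4_factors.json")) as p:
        return load_factor_specs(p)


def fixture_design() -> DesignTable:
    """The packaged 29-run design/response table."""
    with resources.as_file(_data_path("table1.csv")) as p:
        return load_design_csv(p, fixture_factors())


def fixture_ann() -> SurrogateModel:
    """The frozen trained surrogate network."""
    with resources.as_file(_data_path("ann_fixture.json")) as p:
        return load_model(p)


# -- misc ------------------------------------------------------------------

def config_hash(obj) -> str:
    """Stable SHA-256 of a JSON-serializable configuration."""
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
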