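"""Factor coding and Box-Behnken designs.

A response-surface experiment varies each process factor over three levels,
rescaled ("coded") so that the low/center/high experimental settings map to
-1/0/+1.  All model fitting downstream happens in coded units; this module
owns the coding map and the construction of the Box-Behnken design (BBD)
lattice: for every pair of factors, the four (+-1, +-1) combinations with the
remaining factors held at their centers, plus replicated all-center runs.
For four factors that is 24 edge runs plus the center replicates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("extraopt.design")

#: relative tolerance (on the factor range) for the center-vs-midpoint check
MIDPOINT_RTOL = 1e-8


class DesignError(ValueError):
    """Base class for experimental-design errors."""


class InvalidFactorError(DesignError):
    """A factor specification is degenerate or inconsistent."""


class UnsupportedDesignError(DesignError):
    """The requested design does not exist for this number of factors."""


@dataclass(frozen=True)
class FactorSpec:
    """One process factor and its three experimental levels.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"ethanol"``.
    low, center, high : float
        Actual values at coded -1, 0 and +1.  ``low < center < high`` is
        required.  If ``center`` is not the midpoint of ``low`` and ``high``
        a warning is logged (the coding scale is ``(high - low)/2`` either
        way, the standard coded-factor convention).
    unit : str
        Unit text for reports, e.g. ``"%"`` or ``"mL g-1"``.
    """

    name: str
    low: float
    center: float
    high: float
    unit: str = ""

    def __post_init__(self) -> None:
        if self.high == self.low:
            raise InvalidFactorError(
                f"factor {self.name!r}: degenerate range (high == low == {self.high})"
            )
        if not (self.low < self.center < self.high):
            raise InvalidFactorError(
                f"factor {self.name!r}: require low < center < high, got "
                f"({self.low}, {self.center}, {self.high})"
            )
        midpoint = 0.5 * (self.low + self.high)
        if abs(self.center - midpoint) > MIDPOINT_RTOL * (self.high - self.low):
            logger.warning(
                "factor %r: center %g is not the midpoint %g of (low, high); "
                "coding scale remains (high - low)/2",
                self.name, self.center, midpoint,
            )

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, actual):
        """Map actual units to coded level: ``2 (actual - center) / (high - low)``."""
        actual = np.asarray(actual, dtype=float)
        coded = 2.0 * (actual - self.center) / (self.high - self.low)
        return float(coded) if coded.ndim == 0 else coded

    def decode(self, coded):
        """Inverse of :meth:`code`: ``center + coded * (high - low) / 2``.

        Values beyond +-1 are allowed (extrapolation) but flagged in the log.
        """
        coded = np.asarray(coded, dtype=float)
        if np.any(np.abs(coded) > 1.0 + 1e-9):
            logger.warning(
                "factor %r: decoding coded level(s) outside [-1, +1] (extrapolation)",
                self.name,
            )
        actual = self.center + coded * self.half_range
        return float(actual) if actual.ndim == 0 else actual

    def to_dict(self) -> dict:
        return {"name": self.name, "unit": self.unit,
                "low": self.low, "center": self.center, "high": self.high}

    @classmethod
    def from_dict(cls, d: dict) -> "FactorSpec":
        return cls(name=d["name"], low=float(d["low"]), center=float(d["center"]),
                   high=float(d["high"]), unit=d.get("unit", ""))


def code_levels(spec: FactorSpec, actual):
    """Functional alias for :meth:`FactorSpec.code`."""
    return spec.code(actual)


def decode_levels(spec: FactorSpec, coded):
    """Functional alias for :meth:`FactorSpec.decode`."""
    return spec.decode(coded)


@dataclass
class DesignTable:
    """An experimental design: factors, runs and (optionally) responses.

    Coded and actual levels are kept mutually consistent by construction:
    the table stores actual levels and derives coded ones through the factor
    specs (and vice versa for :meth:`from_coded`).  Responses may be missing
    (NaN) for design-only export.
    """

    factors: list[FactorSpec]
    run_ids: np.ndarray          # (n,) int
    actual: np.ndarray           # (n, k) float
    response: np.ndarray         # (n,) float, NaN = missing

    def __post_init__(self) -> None:
        self.run_ids = np.asarray(self.run_ids, dtype=int)
        self.actual = np.atleast_2d(np.asarray(self.actual, dtype=float))
        self.response = np.asarray(self.response, dtype=float)
        n, k = self.actual.shape
        if k != len(self.factors):
            raise DesignError(f"{k} level columns for {len(self.factors)} factors")
        if len(self.run_ids) != n or len(self.response) != n:
            raise DesignError("run_ids, levels and response lengths disagree")
        if len(np.unique(self.run_ids)) != n:
            raise DesignError("run ids are not unique")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_actual(cls, factors: Sequence[FactorSpec], actual, response=None,
                    run_ids=None) -> "DesignTable":
        actual = np.atleast_2d(np.asarray(actual, dtype=float))
        n = actual.shape[0]
        if response is None:
            response = np.full(n, np.nan)
        if run_ids is None:
            run_ids = np.arange(1, n + 1)
        return cls(list(factors), np.asarray(run_ids), actual,
                   np.asarray(response, dtype=float))

    @classmethod
    def from_coded(cls, factors: Sequence[FactorSpec], coded, response=None,
                   run_ids=None) -> "DesignTable":
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        actual = np.column_stack([f.decode(coded[:, j])
                                  for j, f in enumerate(factors)])
        return cls.from_actual(factors, actual, response, run_ids)

    # -- views -------------------------------------------------------------
    @property
    def n_runs(self) -> int:
        return self.actual.shape[0]

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def coded(self) -> np.ndarray:
        return np.column_stack([f.code(self.actual[:, j])
                                for j, f in enumerate(self.factors)])

    @property
    def has_response(self) -> np.ndarray:
        return ~np.isnan(self.response)

    def with_response(self, response) -> "DesignTable":
        return replace(self, response=np.asarray(response, dtype=float))

    def replicate_groups(self, decimals: int = 6) -> list[np.ndarray]:
        """Row-index groups sharing identical coded levels (rounded).

        Groups with at least two members carry the pure-error information of
        the design; for a standard BBD that is the block of center replicates.
        """
        key = np.round(self.coded, decimals)
        groups: dict[tuple, list[int]] = {}
        for i, row in enumerate(key):
            groups.setdefault(tuple(row), []).append(i)
        return [np.asarray(ix) for ix in groups.values()]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: run id, actual levels, coded levels, response."""
        data: dict = {"run": self.run_ids}
        coded = self.coded
        for j in range(self.k):
            data[f"x{j+1}_actual"] = self.actual[:, j]
        for j in range(self.k):
            data[f"x{j+1}_coded"] = coded[:, j]
        data["response"] = self.response
        return pd.DataFrame(data)


def generate_bbd(factors: Sequence[FactorSpec], n_center: int = 5) -> DesignTable:
    """Construct the Box-Behnken design for ``k >= 3`` factors.

    Runs are emitted pair-block by pair-block in factor-index order — for
    each factor pair (i, j), i < j, the four (+-1, +-1) combinations with all
    other factors at 0 — followed by ``n_center`` all-center runs.  Run order
    is deterministic; no randomization schedule is applied.

    For four factors this yields ``6 pairs x 4 + n_center`` runs, the
    29-run matrix of the reference experiment when ``n_center = 5``.
    """
    k = len(factors)
    if k < 3:
        raise UnsupportedDesignError(
            f"Box-Behnken designs require at least 3 factors, got {k}"
        )
    if n_center < 1:
        raise DesignError("n_center must be >= 1")
    rows: list[np.ndarray] = []
    for i, j in itertools.combinations(range(k), 2):
        for si in (-1.0, 1.0):
            for sj in (-1.0, 1.0):
                row = np.zeros(k)
                row[i], row[j] = si, sj
                rows.append(row)
    rows.extend(np.zeros(k) for _ in range(n_center))
    return DesignTable.from_coded(factors, np.vstack(rows))
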