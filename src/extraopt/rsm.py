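"""Second-order response-surface regression and ANOVA.

Fits the full quadratic polynomial in coded factors

    y = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i^2

by ordinary least squares (normal equations) and partitions the variation
into the response-surface ANOVA: the 14 single-degree-of-freedom terms with
partial (Type III) sums of squares, the residual, and — when the design
contains replicated runs — its split into lack of fit and pure error.  The
lack-of-fit F ratio MS(LOF)/MS(PE) tests model adequacy against the
replicate-measured noise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .design import DesignTable, FactorSpec

logger = logging.getLogger("extraopt.rsm")


class SingularDesignError(ValueError):
    """Model matrix is rank deficient; ``columns`` names the collinear terms."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"rank-deficient model matrix; collinear columns: {columns}")


class UndefinedRSquaredError(ValueError):
    """R^2 is undefined because the response has zero total variance."""


def term_names(k: int) -> list[str]:
    """Coefficient keys in model order: b0, b1..bk, b12.., b11..bkk."""
    names = ["b0"] + [f"b{i+1}" for i in range(k)]
    names += [f"b{i+1}{j+1}" for i, j in itertools.combinations(range(k), 2)]
    names += [f"b{i+1}{i+1}" for i in range(k)]
    return names


def model_matrix(coded: np.ndarray) -> np.ndarray:
    """Full quadratic model matrix: intercept, linear, interactions, squares."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    n, k = coded.shape
    cols = [np.ones(n)]
    cols += [coded[:, i] for i in range(k)]
    cols += [coded[:, i] * coded[:, j] for i, j in itertools.combinations(range(k), 2)]
    cols += [coded[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


@dataclass
class QuadraticFit:
    """A fitted full second-order polynomial in coded factors.

    ``beta`` holds the ``1 + k + k(k-1)/2 + k`` coefficients in the order of
    :func:`term_names`; ``xtx_inv`` is (X'X)^-1, the unscaled coefficient
    covariance; ``ms_residual`` the residual mean square.
    """

    factors: list[FactorSpec]
    beta: np.ndarray
    xtx_inv: np.ndarray
    ms_residual: float
    n_obs: int

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def names(self) -> list[str]:
        return term_names(self.k)

    @property
    def n_terms(self) -> int:
        return len(self.beta)

    @property
    def df_residual(self) -> int:
        return self.n_obs - self.n_terms

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    @property
    def linear(self) -> np.ndarray:
        return self.beta[1:1 + self.k]

    @property
    def interaction(self) -> np.ndarray:
        return self.beta[1 + self.k:1 + self.k + self.k * (self.k - 1) // 2]

    @property
    def quadratic(self) -> np.ndarray:
        return self.beta[-self.k:]

    def quadratic_matrix(self) -> np.ndarray:
        """Symmetric matrix B with b_ii on the diagonal and b_ij/2 off it.

        The fitted surface is ``b0 + b'x + x'Bx``.
        """
        k = self.k
        B = np.diag(self.quadratic.astype(float))
        for (i, j), bij in zip(itertools.combinations(range(k), 2), self.interaction):
            B[i, j] = B[j, i] = bij / 2.0
        return B

    def predict(self, points) -> np.ndarray | float:
        """Evaluate the fitted polynomial at coded point(s)."""
        pts = np.asarray(points, dtype=float)
        scalar = pts.ndim == 1
        out = model_matrix(np.atleast_2d(pts)) @ self.beta
        return float(out[0]) if scalar else out

    def coefficient_se(self) -> np.ndarray:
        """Standard errors: sqrt(MS_residual * diag((X'X)^-1))."""
        return np.sqrt(self.ms_residual * np.diag(self.xtx_inv))

    def coefficients(self) -> dict[str, float]:
        return {name: float(b) for name, b in zip(self.names, self.beta)}

    def to_dict(self) -> dict:
        return {
            "factors": [f.to_dict() for f in self.factors],
            "coefficients": self.coefficients(),
            "ms_residual": self.ms_residual,
            "n_obs": self.n_obs,
            "xtx_inv": self.xtx_inv.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticFit":
        factors = [FactorSpec.from_dict(f) for f in d["factors"]]
        names = term_names(len(factors))
        beta = np.array([d["coefficients"][n] for n in names], dtype=float)
        return cls(factors=factors, beta=beta,
                   xtx_inv=np.asarray(d["xtx_inv"], dtype=float),
                   ms_residual=float(d["ms_residual"]), n_obs=int(d["n_obs"]))


def _observed(design: DesignTable) -> tuple[np.ndarray, np.ndarray]:
    mask = design.has_response
    return design.coded[mask], design.response[mask]


def fit_quadratic(design: DesignTable) -> QuadraticFit:
    """Least-squares fit of the full quadratic model on coded levels.

    Requires more runs with responses than model terms; a rank-deficient
    model matrix raises :class:`SingularDesignError` naming the collinear
    columns (identified by QR column pivoting).
    """
    coded, y = _observed(design)
    X = model_matrix(coded)
    n, p = X.shape
    if n <= p:
        raise ValueError(
            f"need more than {p} runs with responses to fit {p} terms, got {n}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        names = term_names(coded.shape[1])
        raise SingularDesignError([names[j] for j in sorted(piv[rank:])])
    xtx = X.T @ X
    beta = scipy.linalg.solve(xtx, X.T @ y, assume_a="pos")
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    return QuadraticFit(
        factors=list(design.factors),
        beta=beta,
        xtx_inv=scipy.linalg.inv(xtx),
        ms_residual=ss_res / (n - p),
        n_obs=n,
    )


def predict(fit: QuadraticFit, point) -> np.ndarray | float:
    """Functional alias for :meth:`QuadraticFit.predict`."""
    return fit.predict(point)


@dataclass
class AnovaRow:
    source: str
    ss: float
    df: int
    ms: float | None
    f: float | None
    p: float | None


@dataclass
class AnovaTable:
    """Response-surface ANOVA: per-source SS/df/MS/F/p plus R^2 statistics."""

    rows: list[AnovaRow]
    r_squared: float
    adj_r_squared: float

    def __getitem__(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"source": r.source, "ss": r.ss, "df": r.df, "ms": r.ms,
              "f": r.f, "p": r.p} for r in self.rows]
        )

    def to_text(self) -> str:
        """Aligned rendering with p below 1e-4 shown as '<0.0001'."""
        lines = [f"{'Source':<14}{'SS':>12}{'df':>5}{'MS':>12}{'F':>10}{'p':>10}"]
        for r in self.rows:
            ms = f"{r.ms:.2f}" if r.ms is not None else ""
            fv = f"{r.f:.2f}" if r.f is not None else ""
            if r.p is None:
                pv = ""
            elif r.p < 1e-4:
                pv = "<0.0001"
            else:
                pv = f"{r.p:.4f}"
            lines.append(f"{r.source:<14}{r.ss:>12.2f}{r.df:>5}{ms:>12}{fv:>10}{pv:>10}")
        lines.append(f"R-squared = {self.r_squared:.4f}   "
                     f"adj R-squared = {self.adj_r_squared:.4f}")
        return "\n".join(lines)


def _term_labels(factors: Sequence[FactorSpec]) -> list[str]:
    k = len(factors)
    labels = [f"X{i+1}" for i in range(k)]
    labels += [f"X{i+1}X{j+1}" for i, j in itertools.combinations(range(k), 2)]
    labels += [f"X{i+1}^2" for i in range(k)]
    return labels


def anova(design: DesignTable, fit: QuadraticFit,
          ss_type: str = "partial") -> AnovaTable:
    """Build the quadratic-model ANOVA table.

    Single-df term sums of squares are partial (Type III) by default:
    ``SS_j = b_j^2 / [(X'X)^-1]_jj`` — each term adjusted for all others,
    the convention under which the quadratic-term SS of the reference
    software are reproduced.  ``ss_type="sequential"`` gives Type I SS in
    model order instead.

    Pure error comes from replicate groups (identical coded rows after
    rounding to 6 decimals); lack of fit is the remainder of the residual.
    Without replicates the lack-of-fit partition is omitted with a warning.
    """
    if ss_type not in ("partial", "sequential"):
        raise ValueError(f"unknown ss_type {ss_type!r}")
    coded, y = _observed(design)
    X = model_matrix(coded)
    n, p = X.shape
    resid = y - X @ fit.beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_mod = ss_tot - ss_res
    df_mod, df_res = p - 1, n - p
    ms_res = ss_res / df_res
    ms_mod = ss_mod / df_mod

    if ss_type == "partial":
        term_ss = [float(fit.beta[j] ** 2 / fit.xtx_inv[j, j]) for j in range(1, p)]
    else:
        term_ss = []
        ss_prev_res = ss_tot  # residual about the intercept-only fit
        for j in range(2, p + 1):
            bj = np.linalg.lstsq(X[:, :j], y, rcond=None)[0]
            rj = y - X[:, :j] @ bj
            ss_j_res = float(rj @ rj)
            term_ss.append(ss_prev_res - ss_j_res)
            ss_prev_res = ss_j_res

    rows = [AnovaRow("Model", ss_mod, df_mod, ms_mod,
                     ms_mod / ms_res, float(stats.f.sf(ms_mod / ms_res, df_mod, df_res)))]
    for label, ss in zip(_term_labels(design.factors), term_ss):
        f_val = ss / ms_res
        rows.append(AnovaRow(label, ss, 1, ss,
                             f_val, float(stats.f.sf(f_val, 1, df_res))))
    rows.append(AnovaRow("Residual", ss_res, df_res, ms_res, None, None))

    mask = design.has_response
    groups = [g for g in DesignTable(design.factors, design.run_ids[mask],
                                     design.actual[mask], design.response[mask]
                                     ).replicate_groups() if len(g) > 1]
    if groups:
        ss_pe = 0.0
        df_pe = 0
        for g in groups:
            yg = y[g]
            ss_pe += float(((yg - yg.mean()) ** 2).sum())
            df_pe += len(g) - 1
        ss_lof = ss_res - ss_pe
        if ss_lof < 0:
            logger.warning("negative lack-of-fit SS (%g) clamped to 0", ss_lof)
            ss_lof = 0.0
        df_lof = df_res - df_pe
        if df_lof > 0 and df_pe > 0:
            ms_lof, ms_pe = ss_lof / df_lof, ss_pe / df_pe
            f_lof = ms_lof / ms_pe if ms_pe > 0 else np.inf
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
            rows.append(AnovaRow("Lack of Fit", ss_lof, df_lof, ms_lof, f_lof, p_lof))
            rows.append(AnovaRow("Pure Error", ss_pe, df_pe, ms_pe, None, None))
        else:
            rows.append(AnovaRow("Lack of Fit", ss_lof, df_lof, None, None, None))
            rows.append(AnovaRow("Pure Error", ss_pe, df_pe,
                                 ss_pe / df_pe if df_pe else None, None, None))
    else:
        logger.warning("no replicated runs: lack-of-fit/pure-error rows omitted")

    rows.append(AnovaRow("Cor Total", ss_tot, n - 1, None, None, None))

    r2 = ss_mod / ss_tot if ss_tot > 0 else np.nan
    adj = 1.0 - (ss_res / df_res) / (ss_tot / (n - 1)) if ss_tot > 0 else np.nan
    return AnovaTable(rows=rows, r_squared=float(r2), adj_r_squared=float(adj))


def fit_metrics(design: DesignTable, predictions) -> dict[str, float]:
    """R^2, RMSE and MAE of arbitrary predictions against the responses.

    ``R^2 = 1 - SS(residual about predictions) / SS(corrected total)``; an
    all-constant response makes R^2 undefined and raises
    :class:`UndefinedRSquaredError`.
    """
    mask = design.has_response
    y = design.response[mask]
    yhat = np.asarray(predictions, dtype=float)
    if yhat.shape[0] == design.n_runs:
        yhat = yhat[mask]
    if yhat.shape != y.shape:
        raise ValueError("predictions not aligned with design runs")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise UndefinedRSquaredError("response has zero total variance")
    err = y - yhat
    return {
        "r_squared": 1.0 - float(err @ err) / ss_tot,
        "rmse": float(np.sqrt(np.mean(err ** 2))),
        "mae": float(np.mean(np.abs(err))),
    }
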