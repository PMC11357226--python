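"""Box-constrained maximization of a fitted quadratic surface.

For a quadratic ``y = b0 + b'x + x'Bx`` the maximum over an axis-aligned box
is attained either at the interior stationary point ``x* = -B^{-1} b / 2``
(when B is negative definite and x* lies inside) or on a face of the box.
Every face of a box is itself a box for a lower-dimensional quadratic, so
enumerating the stationary points of all 3^k fixed/free patterns (each
factor at its lower bound, upper bound, or free) together with the corners
gives the exact global maximum — no iterative search is required.  A local
polish step is still run from the best candidate as a numerical safeguard.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .rsm import QuadraticFit

logger = logging.getLogger("extraopt.optimize")


class RidgeSystemError(ValueError):
    """The quadratic has a singular curvature matrix (stationary ridge)."""


@dataclass
class Optimum:
    """An optimization result on the coded box, reported in both unit systems."""

    coded: np.ndarray
    actual: np.ndarray
    predicted_response: float
    method: str
    converged: bool = True
    trajectory: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "coded": [float(v) for v in self.coded],
            "actual": [float(v) for v in self.actual],
            "predicted_response": float(self.predicted_response),
            "method": self.method,
            "converged": bool(self.converged),
        }
        return d

    def rounded_conditions(self, factors) -> dict[str, float]:
        """Actual-unit conditions at report precision (2 decimals for '%'
        factors, integers otherwise) — presentation only, internals keep
        full precision."""
        out = {}
        for f, v in zip(factors, self.actual):
            out[f.name] = round(float(v), 2) if f.unit == "%" else round(float(v))
        return out


def stationary_point(fit: QuadraticFit) -> tuple[np.ndarray, str]:
    """Solve grad y = 0 for the fitted quadratic and classify the point.

    Returns ``(x*, kind)`` with ``x* = -B^{-1} b / 2`` and kind one of
    ``"maximum"``, ``"minimum"``, ``"saddle"`` from the eigenvalue signs of
    the curvature matrix B.
    """
    B = fit.quadratic_matrix()
    b = fit.linear.astype(float)
    try:
        x = scipy.linalg.solve(-2.0 * B, b)
    except scipy.linalg.LinAlgError as exc:
        raise RidgeSystemError("singular curvature matrix") from exc
    if not np.all(np.isfinite(x)):
        raise RidgeSystemError("singular curvature matrix")
    eig = scipy.linalg.eigvalsh(B)
    if np.all(eig < 0):
        kind = "maximum"
    elif np.all(eig > 0):
        kind = "minimum"
    else:
        kind = "saddle"
    return x, kind


def _face_candidates(B: np.ndarray, b: np.ndarray, bounds: np.ndarray) -> list[np.ndarray]:
    """Stationary points of every fixed/free face pattern, plus corners."""
    k = len(b)
    cands: list[np.ndarray] = []
    for pattern in itertools.product((0, 1, 2), repeat=k):
        fixed = [i for i, s in enumerate(pattern) if s != 2]
        free = [i for i, s in enumerate(pattern) if s == 2]
        x = np.zeros(k)
        for i in fixed:
            x[i] = bounds[i, pattern[i]]
        if not free:
            cands.append(x)
            continue
        Bff = B[np.ix_(free, free)]
        # gradient on the face: b_f + 2 B_ff x_f + 2 B_f,fixed x_fixed = 0
        rhs = -(b[free] + 2.0 * B[np.ix_(free, fixed)] @ x[fixed]) if fixed \
            else -b[free]
        try:
            xf = scipy.linalg.solve(2.0 * Bff, rhs)
        except scipy.linalg.LinAlgError:
            continue
        if not np.all(np.isfinite(xf)):
            continue
        if np.all(xf >= bounds[free, 0] - 1e-12) and np.all(xf <= bounds[free, 1] + 1e-12):
            x[free] = np.clip(xf, bounds[free, 0], bounds[free, 1])
            cands.append(x)
    return cands


def maximize_in_box(fit: QuadraticFit, bounds=None) -> Optimum:
    """Exact global maximum of the fitted quadratic over a coded box.

    ``bounds`` is a (k, 2) array of per-factor coded intervals; the default
    is the experimental region ``[-1, +1]^k`` (optimizing outside it is
    extrapolation and must be requested explicitly via wider bounds).  Ties
    are broken toward the lexicographically smallest coded point.
    """
    k = fit.k
    bounds = np.tile([-1.0, 1.0], (k, 1)) if bounds is None \
        else np.atleast_2d(np.asarray(bounds, dtype=float))
    if bounds.shape != (k, 2) or not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be a finite (k, 2) array")
    if np.any(bounds[:, 0] > bounds[:, 1]):
        raise ValueError("each bound must satisfy low <= high")

    B = fit.quadratic_matrix()
    b = fit.linear.astype(float)
    cands = _face_candidates(B, b, bounds)
    values = np.array([fit.predict(x) for x in cands])
    best = max(range(len(cands)),
               key=lambda i: (values[i], tuple(-cands[i])))  # lexicographic tie-break
    x_best, v_best = cands[best], values[best]

    # numerical safeguard: local polish from the best candidate
    res = scipy.optimize.minimize(
        lambda x: -fit.predict(x), x_best, method="L-BFGS-B",
        bounds=[tuple(bd) for bd in bounds],
        jac=lambda x: -(b + 2.0 * B @ x),
    )
    if res.success and -res.fun > v_best + 1e-12:
        x_best, v_best = np.clip(res.x, bounds[:, 0], bounds[:, 1]), -res.fun

    actual = np.array([f.decode(x) for f, x in zip(fit.factors, x_best)])
    return Optimum(coded=x_best, actual=actual,
                   predicted_response=float(fit.predict(x_best)),
                   method="RSM", converged=True)


def response_grid(fit: QuadraticFit, i: int, j: int, fixed,
                  n: int = 21, bounds=(-1.0, 1.0)) -> pd.DataFrame:
    """Predicted-response grid over factors i and j with the rest held fixed.

    The data behind surface/contour plots: one row per (x_i, x_j) grid node
    with coded levels, actual levels and the prediction.
    """
    fixed = np.asarray(fixed, dtype=float)
    grid = np.linspace(bounds[0], bounds[1], n)
    rows = []
    for gi in grid:
        for gj in grid:
            x = fixed.copy()
            x[i], x[j] = gi, gj
            rows.append({
                f"x{i+1}_coded": gi,
                f"x{j+1}_coded": gj,
                f"x{i+1}_actual": fit.factors[i].decode(gi),
                f"x{j+1}_actual": fit.factors[j].decode(gj),
                "predicted": fit.predict(x),
            })
    return pd.DataFrame(rows)
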