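"""Synthetic design/response data with the structure the analysis assumes.

Generates Box-Behnken experiments whose responses follow a known quadratic
truth plus homoscedastic Gaussian noise — the implicit OLS noise model —
and, optionally, a smooth cubic perturbation (``amplitude * x1^2 x2``) that
lies outside the quadratic model's column span on the BBD support, so it
induces genuine lack of fit without touching pure error.

Defaults reproduce the study conditions: the printed quadratic coefficients
as ground truth, a 29-run four-factor BBD with 5 center replicates, and a
noise standard deviation of 3.78 mg g-1 (the square root of the study's
pure-error mean square, 14.29).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .design import DesignTable, FactorSpec, generate_bbd
from .rsm import anova, fit_quadratic, model_matrix

logger = logging.getLogger("extraopt.simulate")

#: the study's fitted quadratic, in term order b0, b1..b4, b12..b34, b11..b44
DEFAULT_TRUTH = np.array([
    121.52, 1.80, -2.98, 13.01, 6.78,
    1.09, 0.26, 5.04, -1.20, -0.115, 16.47,
    -25.23, -18.44, -23.29, -15.80,
])


def default_factors() -> list[FactorSpec]:
    """The four extraction factors at the study's experimental ranges."""
    return [
        FactorSpec("ethanol", 40, 60, 80, "%"),
        FactorSpec("temperature", 70, 80, 90, "degC"),
        FactorSpec("ratio", 20, 25, 30, "mL g-1"),
        FactorSpec("time", 60, 90, 120, "min"),
    ]


@dataclass
class SyntheticSpec:
    """Ground truth and noise structure for one simulated experiment."""

    coefficients: np.ndarray = field(default_factory=lambda: DEFAULT_TRUTH.copy())
    noise_sd: float = 3.78
    n_center: int = 5
    seed: int = 0
    perturbation: float = 0.0   # amplitude of the lack-of-fit term x1^2 x2

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.perturbation < 0:
            raise ValueError("perturbation amplitude must be >= 0")


def _lof_term(coded: np.ndarray) -> np.ndarray:
    """Smooth cubic perturbation x1^2 x2, off-span on the BBD support."""
    return coded[:, 0] ** 2 * coded[:, 1]


def generate(spec: SyntheticSpec,
             factors: list[FactorSpec] | None = None) -> DesignTable:
    """One seeded synthetic experiment on a fresh BBD."""
    factors = factors or default_factors()
    design = generate_bbd(factors, n_center=spec.n_center)
    coded = design.coded
    mean = model_matrix(coded) @ spec.coefficients
    if spec.perturbation:
        mean = mean + spec.perturbation * _lof_term(coded)
    rng = np.random.default_rng(spec.seed)
    y = mean + rng.normal(0.0, spec.noise_sd, size=design.n_runs)
    return design.with_response(y)


def pure_error_calibration(spec: SyntheticSpec, n_reps: int,
                           alpha: float = 0.05,
                           factors: list[FactorSpec] | None = None) -> dict:
    """Monte-Carlo check of the pure-error estimator and the lack-of-fit test.

    Runs ``n_reps`` seeded replicates of :func:`generate`, fits the quadratic
    and its ANOVA on each, and summarizes: the mean pure-error mean square
    (unbiased for ``noise_sd**2`` under the model) and the fraction of
    replicates in which the lack-of-fit F exceeds its upper ``alpha``
    critical value (the type-I error rate when ``perturbation == 0``).
    """
    if spec.n_center < 2:
        raise ValueError("pure-error calibration needs n_center >= 2")
    rep_seeds = np.random.default_rng(spec.seed).integers(2 ** 31, size=n_reps)
    pe_ms = np.empty(n_reps)
    lof_f = np.empty(n_reps)
    lof_reject = np.zeros(n_reps, dtype=bool)
    from dataclasses import replace
    for r, s in enumerate(rep_seeds):
        d = generate(replace(spec, seed=int(s)), factors)
        fit = fit_quadratic(d)
        tab = anova(d, fit)
        pe_ms[r] = tab["Pure Error"].ms
        row = tab["Lack of Fit"]
        lof_f[r] = row.f
        lof_reject[r] = row.p is not None and row.p < alpha
    return {
        "n_reps": n_reps,
        "noise_sd": spec.noise_sd,
        "mean_pure_error_ms": float(pe_ms.mean()),
        "sd_pure_error_ms": float(pe_ms.std(ddof=1)) if n_reps > 1 else 0.0,
        "mean_lof_f": float(lof_f.mean()),
        "lof_rejection_rate": float(lof_reject.mean()),
        "alpha": alpha,
    }
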