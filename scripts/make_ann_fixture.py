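"""Regenerate the frozen surrogate fixture `src/extraopt/data/ann_fixture.json`.

The fixture is a synthetic stand-in for the study's trained network, which
is documented only through its fit statistics and its GA optimum
(ethanol 61.00%, 77 degC, 26 mL g-1, 103 min).  Reconstruction rule, fixed
before freezing: train the default 4-9-1 configuration on all 29 runs
(split (1, 0, 0), 20000 epochs) for seeds 0..19 — every seed converges to
R^2 = 0.995 on the full design — and freeze the seed whose box-constrained
argmax (41-per-axis grid) is closest in coded Euclidean distance to the
study's reported optimum.

Run from the repository root:  python scripts/make_ann_fixture.py
"""

import itertools
import json
from pathlib import Path

import numpy as np

from extraopt import (AnnConfig, fit_metrics, fit_surrogate, fixture_design,
                      predict_ann, save_model)

REPORTED_OPTIMUM_ACTUAL = np.array([61.00, 77.0, 26.0, 103.0])

design = fixture_design()
reported_coded = np.array([f.code(v) for f, v in
                           zip(design.factors, REPORTED_OPTIMUM_ACTUAL)])

axis = np.linspace(-1.0, 1.0, 41)
grid = np.array(list(itertools.product(axis, repeat=4)))

best = None
for seed in range(20):
    cfg = AnnConfig(seed=seed, split=(1.0, 0.0, 0.0), max_epochs=20000)
    model = fit_surrogate(design, cfg)
    r2 = fit_metrics(design, predict_ann(model, design.coded))["r_squared"]
    vals = predict_ann(model, grid)
    argmax = grid[int(np.argmax(vals))]
    dist = float(np.linalg.norm(argmax - reported_coded))
    print(f"seed {seed:2d}  R2 {r2:.4f}  argmax {np.round(argmax, 3)}  "
          f"coded distance {dist:.3f}")
    if best is None or dist < best[0]:
        best = (dist, seed, model, r2)

dist, seed, model, r2 = best
out = Path(__file__).resolve().parents[1] / "src/extraopt/data/ann_fixture.json"
save_model(model, out)
print(f"froze seed {seed} (R2 {r2:.4f}, coded distance {dist:.3f}) -> {out}")
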