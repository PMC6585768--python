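"""Recompute the headline simulation outcomes from scratch.

Three quantities summarize the model's main claims:

* the location of the positive mode of the within-channel D1-D1 / D2-D2
  correlation histograms under background-only drive,
* the mode of the recruitment-distance histogram in the GABA-antagonist
  experiment with the non-monotonic kernel (in channel-distance units), and
* the maximum linear velocity commanded over a full bilateral-D1 run.

Each entry reports {"value": ..., "n": problem size used}.
"""

from __future__ import annotations

import numpy as np

from . import analysis
from .workflows import (background_correlation_summary,
                        recruitment_experiment, run_paradigm)

__all__ = ["run_acceptance"]


def run_acceptance(seed: int = 1, fast: bool = False,
                   correlation_duration_ms: float | None = None,
                   n_trials: int | None = None) -> dict:
    """Run the three headline computations and return the report dict.

    ``correlation_duration_ms`` defaults to 50 s (a scaled-down version of
    the full 200 s correlation run; 20 s under ``fast``); the recruitment
    experiment uses 5 trials (2 under ``fast``).
    """
    seed = int(seed) % (2**31)
    if correlation_duration_ms is None:
        correlation_duration_ms = 20_000.0 if fast else 50_000.0
    if n_trials is None:
        n_trials = 2 if fast else 5

    # within-channel co-activation: positive correlation mode (background only)
    summary = background_correlation_summary(
        duration=correlation_duration_ms, seed=seed)
    within = np.concatenate([summary.coefficients[("D1-D1", "within")],
                             summary.coefficients[("D2-D2", "within")]])
    t1 = analysis.positive_mode(within)

    # recruitment-distance mode, non-monotonic kernel, trial-averaged
    _, _, t2 = recruitment_experiment("non_monotonic", n_trials=n_trials,
                                      seed=seed)

    # motor bound over a full bilateral D1 run
    run = run_paradigm("bilateral_D1", seed=seed)
    t5 = float(run.trajectory["v"].max())

    return {
        "t1": {"value": float(t1), "n": int(len(within))},
        "t2": {"value": float(t2), "n": int(n_trials)},
        "t5": {"value": t5, "n": int(len(run.trajectory))},
    }
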