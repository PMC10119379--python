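import numpy as np
import pandas as pd
import pytest

from attnwarp import design_experiment
from attnwarp.synthetic_observer import ObserverParams, p_choose_target


@pytest.fixture(scope="session")
def designs():
    """One deterministic design per experiment, shared across tests."""
    return {e: design_experiment(e, seed=123) for e in ("E1", "E2", "E3", "E4")}


def binomial_summaries(rng, deltas, n_per_cell, bias, sigma, D=30.0,
                       directions=("away",), lapse=0.0):
    """Cell summaries with counts drawn straight from the closed-form model.

    Used as a fast generative source for fitting tests; independent of
    simulate_dataset's trial-level path.
    """
    rows = []
    params = ObserverParams(bias=bias, sigma=sigma, lapse=lapse)
    for delta in deltas:
        for direction in directions:
            p = p_choose_target(delta, direction, params)
            k = int(rng.binomial(n_per_cell, p))
            rows.append(
                {
                    "D": D,
                    "delta": float(delta),
                    "foil_direction": direction,
                    "n_trials": n_per_cell,
                    "n_target_chosen": k,
                }
            )
    return pd.DataFrame(rows)
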