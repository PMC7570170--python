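import itertools

import numpy as np
import pandas as pd
import pytest

from diallelkit.io import TrialTable
from diallelkit.simulate import SimulationConfig, simulate_diallel


def make_trial(
    parents=("A", "B", "C"),
    n_envs=1,
    n_reps=1,
    n_planted=100,
    counts=None,
    rng=None,
):
    """Hand-rolled balanced trial table with controllable counts.

    ``counts`` maps (female, male) -> (n_male_fertile, n_seed_set) applied
    to every plot of that cross; otherwise counts are drawn binomially.
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    for k, m, (f, ma) in itertools.product(
        range(n_envs), range(n_reps), itertools.product(parents, parents)
    ):
        if counts is not None:
            n_mf, n_ss = counts[(f, ma)]
        else:
            n_mf = int(rng.binomial(n_planted, 0.3))
            n_ss = int(rng.binomial(n_mf, 0.5))
        rows.append(
            {
                "env": f"E{k + 1}",
                "rep": m + 1,
                "female": f,
                "male": ma,
                "n_planted": n_planted,
                "n_at_anthesis": n_planted,
                "n_male_fertile": n_mf,
                "n_seed_set": n_ss,
            }
        )
    return TrialTable.from_records(pd.DataFrame(rows), parents=list(parents))


@pytest.fixture
def default_trial():
    """Study-dimensioned synthetic trial (8 parents, 2 env x 2 rep)."""
    trial, truth = simulate_diallel(SimulationConfig(seed=11))
    return trial, truth


def sequential_anova_oracle(df, trait, term_columns):
    """Type I sums of squares by explicit projection onto growing spans.

    ``term_columns`` is an ordered mapping name -> categorical Series;
    each step adds the full dummy block and charges the SS drop to the
    term.  Independent of the fitting route under test.
    """
    y = df[trait].to_numpy(dtype=float)
    X = np.ones((len(df), 1))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(((y - X @ beta) ** 2).sum())

    prev = rss(X)
    out = {}
    for name, series in term_columns.items():
        X = np.hstack([X, pd.get_dummies(series).to_numpy(dtype=float)])
        cur = rss(X)
        out[name] = prev - cur
        prev = cur
    out["Error"] = prev
    return out
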