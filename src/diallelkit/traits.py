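"""Spontaneous chromosome-doubling traits from haploid plot counts.

Two traits describe how readily a genotype's haploids become fertile
without chemical doubling agents:

HMF (haploid male fertility)
    percent of haploid plants in a plot that shed pollen.
HF (haploid fertility)
    percent of haploid plants in a plot that set seed upon selfing; the
    operational success rate for doubled-haploid line production.

Both are simple plot proportions on the denominator of haploid plants
surviving at anthesis (configurable to planted kernels).  A plot with a
zero denominator yields a missing value, never a zero.
"""

from __future__ import annotations

import math
import warnings

from .errors import IntegrityError
from .io import TrialTable


def _fertility_percent(n_haploid: int, n_event: int, what: str) -> float:
    if n_haploid < 0 or n_event < 0:
        raise IntegrityError(f"negative count in {what} computation")
    if n_event > n_haploid:
        raise IntegrityError(
            f"{what}: event count {n_event} exceeds haploid plant count {n_haploid}"
        )
    if n_haploid == 0:
        return math.nan
    return 100.0 * n_event / n_haploid


def compute_hmf(n_haploid_plants: int, n_male_fertile: int) -> float:
    """Haploid male fertility (%): pollen-producing / haploid plants."""
    return _fertility_percent(n_haploid_plants, n_male_fertile, "HMF")


def compute_hf(n_haploid_plants: int, n_seed_set: int) -> float:
    """Haploid fertility (%): seed-producing / haploid plants."""
    return _fertility_percent(n_haploid_plants, n_seed_set, "HF")


def add_trait_columns(trial: TrialTable, denominator: str = "n_at_anthesis") -> TrialTable:
    """Append ``hmf`` and ``hf`` columns to a trial table.

    Parameters
    ----------
    trial
        Validated plot records.
    denominator
        ``"n_at_anthesis"`` (default: haploid plants recorded at flowering)
        or ``"n_planted"`` (putative haploid kernels planted).

    Returns a new :class:`~diallelkit.io.TrialTable`; the input is not
    modified.  Values are carried at full float precision — rounding is a
    reporting concern only.
    """
    if denominator not in ("n_at_anthesis", "n_planted"):
        raise ValueError("denominator must be 'n_at_anthesis' or 'n_planted'")
    records = trial.records.copy()
    denom = records[denominator].to_numpy()
    records["hmf"] = [
        compute_hmf(d, e) for d, e in zip(denom, records["n_male_fertile"])
    ]
    records["hf"] = [
        compute_hf(d, e) for d, e in zip(denom, records["n_seed_set"])
    ]
    exceeds = records["hf"] > records["hmf"]
    if exceeds.any():
        warnings.warn(
            f"HF exceeds HMF on {int(exceeds.sum())} plot(s); "
            "seed set without recorded tassel fertility",
            stacklevel=2,
        )
    return TrialTable(
        records=records,
        parents=list(trial.parents),
        environments=list(trial.environments),
        n_reps=trial.n_reps,
    )
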