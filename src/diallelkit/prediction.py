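"""Hybrid performance prediction from parent per se values and GCA sums.

For a cross i x j the mid-parent value MPV = (P_i + P_j) / 2 predicts F1
performance when inheritance is mostly additive; the sum g_i + g_j of the
parents' general-combining-ability effects is the corresponding
design-based predictor.  Pearson correlations of each predictor with the
observed F1 values (over the unordered crosses, parents excluded)
quantify how far a breeder can go on parental data alone.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import EstimationError, FixtureLookupError
from . import fixtures

CLASS_ORDER = ("High", "Medium", "Low")


def _lookup(values: Mapping[str, float], parent: str, what: str) -> float:
    try:
        return float(values[parent])
    except KeyError as exc:
        raise FixtureLookupError(f"unknown parent {parent!r} in {what}") from exc


def midparent_values(
    parent_means: Mapping[str, float] | pd.Series,
    crosses: Iterable[tuple[str, str]],
) -> np.ndarray:
    """MPV = (P_i + P_j) / 2 for each cross; symmetric in the parents."""
    return np.array(
        [
            (_lookup(parent_means, a, "parent means") + _lookup(parent_means, b, "parent means")) / 2
            for a, b in crosses
        ]
    )


def gca_sums(
    gca: Mapping[str, float] | pd.Series, crosses: Iterable[tuple[str, str]]
) -> np.ndarray:
    """g_i + g_j for each cross."""
    return np.array(
        [
            _lookup(gca, a, "GCA effects") + _lookup(gca, b, "GCA effects")
            for a, b in crosses
        ]
    )


def group_label(class_a: str, class_b: str) -> str:
    """Unordered-pair label like ``"High × Low"`` (High before Low)."""
    pair = sorted((class_a, class_b), key=CLASS_ORDER.index)
    return f"{pair[0]} × {pair[1]}"


def build_predictions(
    parent_means: Mapping[str, float] | pd.Series,
    f1: pd.DataFrame,
    gca: Mapping[str, float] | pd.Series | None = None,
    classification: Mapping[str, str] | None = None,
    trait_col: str = "f1p",
) -> pd.DataFrame:
    """Assemble the per-cross prediction frame.

    ``f1`` needs columns ``parent1, parent2`` and ``trait_col`` (observed
    F1 performance).  Adds ``mpv``, optionally ``gca_sum`` and ``group``.
    """
    crosses = list(zip(f1["parent1"], f1["parent2"]))
    out = f1[["parent1", "parent2", trait_col]].rename(columns={trait_col: "f1p"}).copy()
    out["mpv"] = midparent_values(parent_means, crosses)
    if gca is not None:
        out["gca_sum"] = gca_sums(gca, crosses)
    if classification is not None:
        out["group"] = [
            group_label(
                _class(classification, a), _class(classification, b)
            )
            for a, b in crosses
        ]
    return out


def _class(classification: Mapping[str, str], parent: str) -> str:
    try:
        return classification[parent]
    except KeyError as exc:
        raise FixtureLookupError(f"parent {parent!r} has no class assigned") from exc


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3:
        raise EstimationError("need at least 3 hybrids for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise EstimationError("correlation undefined: zero variance")
    return float(pearsonr(x, y)[0])


def prediction_correlations(predictions: pd.DataFrame) -> tuple[float, float | None]:
    """(r(MPV:F1P), r(GCA-sum:F1P)); the second is None without GCA."""
    r_mpv = _pearson(predictions["mpv"].to_numpy(), predictions["f1p"].to_numpy())
    r_gca = None
    if "gca_sum" in predictions.columns:
        r_gca = _pearson(
            predictions["gca_sum"].to_numpy(), predictions["f1p"].to_numpy()
        )
    return r_mpv, r_gca


def group_summaries(
    predictions: pd.DataFrame,
    classification: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per hybrid-group and overall mean F1 performance.

    Uses the ``group`` column if present, otherwise derives labels from
    ``classification``.  Returns rows (group, n, mean_f1p) ordered High ×
    High first, plus an ``Overall`` row.
    """
    df = predictions.copy()
    if "group" not in df.columns:
        if classification is None:
            raise EstimationError("no group column and no classification supplied")
        df["group"] = [
            group_label(_class(classification, a), _class(classification, b))
            for a, b in zip(df["parent1"], df["parent2"])
        ]

    def _key(label: str) -> tuple[int, int]:
        a, b = label.split(" × ")
        return CLASS_ORDER.index(a), CLASS_ORDER.index(b)

    rows = [
        {"group": grp, "n": len(sub), "mean_f1p": float(sub["f1p"].mean())}
        for grp, sub in df.groupby("group")
    ]
    rows.sort(key=lambda r: _key(r["group"]))
    rows.append({"group": "Overall", "n": len(df), "mean_f1p": float(df["f1p"].mean())})
    return pd.DataFrame(rows)


def predictions_from_fixtures(experiment: str, trait: str) -> pd.DataFrame:
    """Prediction frame for one published diallel experiment and trait.

    Combines the parent per se means, the 28 combined-reciprocal F1 BLUEs
    and the published GCA effects into the standard prediction frame.
    """
    trait = trait.lower()
    if trait not in ("hmf", "hf"):
        raise FixtureLookupError(f"unknown trait {trait!r}; use 'hmf' or 'hf'")
    parents = fixtures.parent_means(experiment)[trait]
    hybrids = fixtures.hybrid_blues(experiment)
    gca = fixtures.gca_effects(experiment)[f"gca_{trait}"]
    out = build_predictions(parents, hybrids, gca=gca, trait_col=trait)
    # keep the published group labels verbatim rather than re-deriving them
    out["group"] = hybrids["group_label"].to_numpy()
    return out
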