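"""Packaged reference tables from the source field study.

Two 8-parent full diallels of CIMMYT maize lines (CMLs) were evaluated for
spontaneous-doubling traits; the published summary tables are shipped as
CSV fixtures so the prediction and variance-ratio analyses can run without
the unreleased plot data:

``table1_diallel1`` / ``table1_diallel2``
    Parent per se means for HMF and HF (%), with pedigree, adaptation and
    the narrative High/Medium/Low doubling class.
``table2_diallel1`` / ``table2_diallel2``
    The 28 F1 hybrid BLUEs (%) per diallel with their printed hybrid-group
    labels (High × High … Low × Low).  Reciprocals are combined.
``table4``
    Published variance-component estimates (σ²P, σ²A, σ²D, σ²e) and the
    derived ratios per experiment × trait.
``table5_diallel1`` / ``table5_diallel2``
    Published GCA effect estimates per parent (%) with significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import FixtureLookupError

FIXTURE_IDS: tuple[str, ...] = (
    "table1_diallel1",
    "table1_diallel2",
    "table2_diallel1",
    "table2_diallel2",
    "table4",
    "table5_diallel1",
    "table5_diallel2",
)

EXPERIMENTS: tuple[str, ...] = ("diallel1", "diallel2")


@dataclass(frozen=True)
class PaperFixture:
    """One published table, parsed to a DataFrame."""

    identifier: str
    data: pd.DataFrame


def load_fixture(identifier: str) -> PaperFixture:
    """Load a packaged fixture by identifier.

    Raises
    ------
    FixtureLookupError
        If the identifier is not one of :data:`FIXTURE_IDS`.
    """
    if identifier not in FIXTURE_IDS:
        raise FixtureLookupError(
            f"unknown fixture {identifier!r}; choose from {FIXTURE_IDS}"
        )
    ref = resources.files("diallelkit.data").joinpath(f"{identifier}.csv")
    with ref.open("r", encoding="utf-8") as fh:
        data = pd.read_csv(fh)
    return PaperFixture(identifier=identifier, data=data)


def _check_experiment(experiment: str) -> None:
    if experiment not in EXPERIMENTS:
        raise FixtureLookupError(
            f"unknown experiment {experiment!r}; choose from {EXPERIMENTS}"
        )


def parent_means(experiment: str) -> pd.DataFrame:
    """Parent per se HMF/HF means (%), indexed by parent."""
    _check_experiment(experiment)
    df = load_fixture(f"table1_{experiment}").data
    return df.set_index("parent")[["hmf", "hf"]]


def parent_classification(experiment: str) -> dict[str, str]:
    """High/Medium/Low spontaneous-doubling class per parent."""
    _check_experiment(experiment)
    df = load_fixture(f"table1_{experiment}").data
    return dict(zip(df["parent"], df["doubling_class"]))


def hybrid_blues(experiment: str) -> pd.DataFrame:
    """The 28 combined-reciprocal F1 BLUEs with printed group labels."""
    _check_experiment(experiment)
    return load_fixture(f"table2_{experiment}").data.copy()


def gca_effects(experiment: str) -> pd.DataFrame:
    """Published GCA effects (%), indexed by parent."""
    _check_experiment(experiment)
    df = load_fixture(f"table5_{experiment}").data
    return df.set_index("parent")[["gca_hmf", "gca_hf"]]


def variance_table() -> pd.DataFrame:
    """Published variance components/ratios, indexed by component name."""
    return load_fixture("table4").data.set_index("component")
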