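"""Trial-table and entry-mean-table containers and their CSV round trips.

A *trial table* holds one row per field plot of a full diallel evaluated in
one or more environments with replicates: the cross identity (female ×
male, parents on the diagonal when female == male) and the raw haploid
plant counts from which the fertility traits are computed.  An *entry-mean
table* is the p × p grid of per-cross trait means x_ij (row = mother,
column = father) that the combining-ability closed forms consume.

Files are plain CSV, UTF-8, one header row.  Trial tables use the fixed
column set ``env, rep, female, male, n_planted, n_at_anthesis,
n_male_fertile, n_seed_set``; entry-mean tables are wide, with a leading
``female`` column and one column per male parent.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError, IntegrityError

TRIAL_COLUMNS: tuple[str, ...] = (
    "env",
    "rep",
    "female",
    "male",
    "n_planted",
    "n_at_anthesis",
    "n_male_fertile",
    "n_seed_set",
)
COUNT_COLUMNS: tuple[str, ...] = TRIAL_COLUMNS[4:]
KEY_COLUMNS: tuple[str, ...] = TRIAL_COLUMNS[:4]


@dataclass
class TrialTable:
    """Plot-level records of a diallel trial.

    Parameters
    ----------
    records
        One row per plot with the ``TRIAL_COLUMNS`` schema (plus any trait
        columns appended later).
    parents
        Ordered parent identifiers; every ``female``/``male`` value must be
        a member.  All downstream matrices index rows and columns in this
        single order.
    environments
        Environment labels in order of appearance.
    n_reps
        Replicates per environment (the nominal design value).
    """

    records: pd.DataFrame
    parents: list[str]
    environments: list[str]
    n_reps: int

    @property
    def p(self) -> int:
        return len(self.parents)

    @classmethod
    def from_records(
        cls, records: pd.DataFrame, parents: list[str] | None = None
    ) -> "TrialTable":
        """Validate a raw record frame and wrap it.

        Parent order defaults to lexicographic so that every matrix built
        from the same records is indexed identically.
        """
        records = records.copy()
        missing = [c for c in TRIAL_COLUMNS if c not in records.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        records["env"] = records["env"].astype(str)
        records["female"] = records["female"].astype(str)
        records["male"] = records["male"].astype(str)
        _validate_counts(records)
        dup = records.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            rows = (records.index[dup] + 1).tolist()
            raise IntegrityError(
                f"duplicate (env, rep, female, male) key at data row(s) {rows}"
            )
        seen = sorted(set(records["female"]) | set(records["male"]))
        if parents is None:
            parents = seen
        else:
            unknown = sorted(set(seen) - set(parents))
            if unknown:
                raise IntegrityError(f"parents not in parent list: {unknown}")
        envs = list(dict.fromkeys(records["env"]))
        n_reps = int(records.groupby("env")["rep"].nunique().max())
        return cls(records=records, parents=list(parents), environments=envs, n_reps=n_reps)


def _validate_counts(records: pd.DataFrame) -> None:
    for col in COUNT_COLUMNS:
        vals = records[col]
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals), equal_nan=False):
                raise IntegrityError(f"column {col} contains non-integer counts")
            records[col] = vals.astype(int)
        neg = records.index[records[col] < 0]
        if len(neg):
            raise IntegrityError(
                f"negative count in column {col} at data row(s) {(neg + 1).tolist()}"
            )
    bad_mf = records.index[records["n_male_fertile"] > records["n_at_anthesis"]]
    if len(bad_mf):
        raise IntegrityError(
            "n_male_fertile exceeds n_at_anthesis at data row(s) "
            f"{(bad_mf + 1).tolist()}"
        )
    bad_ss = records.index[records["n_seed_set"] > records["n_at_anthesis"]]
    if len(bad_ss):
        raise IntegrityError(
            "n_seed_set exceeds n_at_anthesis at data row(s) "
            f"{(bad_ss + 1).tolist()}"
        )
    bad_surv = records.index[records["n_at_anthesis"] > records["n_planted"]]
    if len(bad_surv):
        raise IntegrityError(
            "n_at_anthesis exceeds n_planted at data row(s) "
            f"{(bad_surv + 1).tolist()}"
        )
    # Seed set without tassel fertility is biologically odd (selfing targets
    # fertile tassels) but not impossible in field records: warn, don't fail.
    odd = records.index[records["n_seed_set"] > records["n_male_fertile"]]
    if len(odd):
        warnings.warn(
            "n_seed_set exceeds n_male_fertile at data row(s) "
            f"{(odd + 1).tolist()}; check field records",
            stacklevel=3,
        )


def read_trial_table(path: str | Path) -> TrialTable:
    """Read a plot-level trial CSV and validate it."""
    path = Path(path)
    try:
        records = pd.read_csv(path, dtype={"env": str, "female": str, "male": str})
    except pd.errors.ParserError as exc:  # pragma: no cover - passthrough
        raise FormatError(str(exc)) from exc
    return TrialTable.from_records(records)


def write_trial_table(trial: TrialTable, path: str | Path) -> None:
    """Write a trial table as CSV; inverse of :func:`read_trial_table`."""
    cols = [c for c in trial.records.columns if c in TRIAL_COLUMNS]
    cols += [c for c in trial.records.columns if c not in TRIAL_COLUMNS]
    trial.records[cols].to_csv(path, index=False, lineterminator="\n")


def trial_to_csv_bytes(trial: TrialTable) -> bytes:
    """Serialize a trial table to CSV bytes (used for determinism audits)."""
    buf = _io.StringIO()
    write_trial_table(trial, buf)  # type: ignore[arg-type]
    return buf.getvalue().encode()


@dataclass
class EntryMeanTable:
    """p × p grid of trait means x_ij: row = female (mother), column = male.

    Diagonal cells are parents per se; off-diagonal cells are the F1 of
    mother i × father j, so the grid carries both reciprocals.  Missing
    cells are NaN and are never imputed; Griffing Method 1 closed forms
    require a complete grid and reject incomplete ones.
    """

    trait: str
    parents: list[str]
    values: np.ndarray
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.parents)
        if self.values.shape != (p, p):
            raise DesignError(
                f"values grid {self.values.shape} does not match {p} parents"
            )
        if self.counts is None:
            self.counts = np.where(np.isnan(self.values), 0, 1).astype(int)
        else:
            self.counts = np.asarray(self.counts, dtype=int)

    @property
    def p(self) -> int:
        return len(self.parents)

    @property
    def is_complete(self) -> bool:
        return bool(np.isfinite(self.values).all())

    def cell(self, female: str, male: str) -> float:
        return float(
            self.values[self.parents.index(female), self.parents.index(male)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.parents, columns=self.parents)


def read_entry_table(path: str | Path, trait: str) -> EntryMeanTable:
    """Read a wide p × p entry-mean CSV (leading ``female`` column)."""
    df = pd.read_csv(path, index_col=0)
    parents = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != parents:
        raise FormatError("row and column parent labels differ or are misordered")
    return EntryMeanTable(trait=trait, parents=parents, values=df.to_numpy(dtype=float))


def write_entry_table(table: EntryMeanTable, path: str | Path) -> None:
    df = table.to_frame()
    df.index.name = "female"
    df.to_csv(path, lineterminator="\n")


def env_subset(trial: TrialTable, env: str) -> TrialTable:
    """Restrict a trial table to one environment (same parent order)."""
    sub = trial.records[trial.records["env"] == str(env)].reset_index(drop=True)
    if sub.empty:
        raise DesignError(f"no records for environment {env!r}")
    return TrialTable(
        records=sub, parents=list(trial.parents), environments=[str(env)],
        n_reps=trial.n_reps,
    )


def per_environment_means(trial: TrialTable, trait: str) -> list[EntryMeanTable]:
    """One entry-mean table per environment, in environment order."""
    return [means_to_entry_table(env_subset(trial, e), trait) for e in trial.environments]


def means_to_entry_table(trial: TrialTable, trait: str) -> EntryMeanTable:
    """Aggregate per-plot trait values to the p × p entry-mean grid.

    Cell x_ij is the plain mean over environments and replicates of the
    trait for cross female-i × male-j; the per-cell observation count
    excludes missing plot values.  Cells with no observations are NaN.
    """
    if trait not in trial.records.columns:
        raise DesignError(
            f"trait column {trait!r} not present; run traits.add_trait_columns first"
        )
    p = trial.p
    idx = {name: k for k, name in enumerate(trial.parents)}
    values = np.full((p, p), np.nan)
    counts = np.zeros((p, p), dtype=int)
    grouped = trial.records.groupby(["female", "male"])[trait]
    for (female, male), vals in grouped:
        i, j = idx[str(female)], idx[str(male)]
        ok = vals.dropna()
        counts[i, j] = len(ok)
        if len(ok):
            values[i, j] = float(ok.mean())
    return EntryMeanTable(trait=trait, parents=list(trial.parents), values=values, counts=counts)
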