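"""Combined-environment fixed-effects ANOVA and entry BLUEs.

The plot model for a trait y observed on genotype (entry) ij in
replicate m of environment k is

    y_ijkm = mu + g_ij + l_k + (gl)_ijk + r_mk + e_ijkm

with every effect fixed.  Sums of squares are sequential (Type I) on the
order Env, Rep(Env), Genotype, Genotype × Env; with balanced data this
coincides with Type III and with the textbook between-group sums.  The
environment row is tested against Rep(Env); Rep(Env), Genotype and
Genotype × Env against the residual.

Entry BLUEs come from the additive model (entry + env + rep-in-env): under
balance they are the plain entry means, and with missing plots they are
the least-squares adjusted means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import DesignError
from .io import TrialTable

ENTRY_SEP = ":"


@dataclass
class AnovaTable:
    """ANOVA rows (source, df, ss, ms, F, p) plus the residual summary."""

    table: pd.DataFrame
    error_ms: float
    error_df: int
    n_environments: int
    n_reps: int

    def row(self, source: str) -> pd.Series:
        return self.table.set_index("source").loc[source]


def _prepare(trial: TrialTable, trait: str) -> pd.DataFrame:
    if trait not in trial.records.columns:
        raise DesignError(
            f"trait column {trait!r} not present; run traits.add_trait_columns first"
        )
    df = trial.records.copy()
    df["entry"] = df["female"].astype(str) + ENTRY_SEP + df["male"].astype(str)
    df["rep"] = df["rep"].astype(str)
    df = df.dropna(subset=[trait])
    expected = {
        f"{f}{ENTRY_SEP}{m}" for f in trial.parents for m in trial.parents
    }
    absent = sorted(expected - set(df["entry"]))
    if absent:
        raise DesignError(
            f"entries with no observed plots: {absent}; design is rank-deficient"
        )
    return df


def fit_combined_anova(trial: TrialTable, trait: str) -> AnovaTable:
    """Fit the plot model and return the ANOVA table.

    With a single environment the Env and Genotype × Env rows are absent
    and replicate is a plain blocking term.
    """
    df = _prepare(trial, trait)
    n_env = df["env"].nunique()
    if n_env > 1:
        # rep is coded nested in env (no free-standing rep main effect), so
        # the Rep(Env) row carries e*(r-1) df as the model requires
        formula = f"{trait} ~ C(env) + C(env):C(rep) + C(entry) + C(env):C(entry)"
        names = {
            "C(env)": "Env",
            "C(env):C(rep)": "Rep(Env)",
            "C(entry)": "Genotype",
            "C(env):C(entry)": "Genotype x Env",
        }
    else:
        formula = f"{trait} ~ C(rep) + C(entry)"
        names = {"C(rep)": "Rep", "C(entry)": "Genotype"}
    fit = smf.ols(formula, data=df).fit()
    raw = anova_lm(fit, typ=1)
    rows = []
    for term, label in names.items():
        rows.append(
            {
                "source": label,
                "df": int(raw.loc[term, "df"]),
                "ss": float(raw.loc[term, "sum_sq"]),
            }
        )
    error_ss = float(raw.loc["Residual", "sum_sq"])
    error_df = int(raw.loc["Residual", "df"])
    rows.append({"source": "Error", "df": error_df, "ss": error_ss})
    table = pd.DataFrame(rows)
    table["ms"] = table["ss"] / table["df"].where(table["df"] > 0)

    error_ms = error_ss / error_df if error_df > 0 else np.nan
    ms = table.set_index("source")["ms"]
    dfree = table.set_index("source")["df"]

    def ftest(source: str, denom: str) -> tuple[float, float]:
        if error_df == 0 and denom == "Error":
            return (np.nan, np.nan)
        F = ms[source] / ms[denom]
        p = scipy.stats.f.sf(F, dfree[source], dfree[denom])
        return float(F), float(p)

    fvals, pvals = {}, {}
    if n_env > 1:
        fvals["Env"], pvals["Env"] = ftest("Env", "Rep(Env)")
        for src in ("Rep(Env)", "Genotype", "Genotype x Env"):
            fvals[src], pvals[src] = ftest(src, "Error")
    else:
        for src in ("Rep", "Genotype"):
            fvals[src], pvals[src] = ftest(src, "Error")
    table["F"] = table["source"].map(fvals)
    table["p"] = table["source"].map(pvals)
    return AnovaTable(
        table=table,
        error_ms=error_ms,
        error_df=error_df,
        n_environments=n_env,
        n_reps=trial.n_reps,
    )


def compute_blues(trial: TrialTable, trait: str) -> pd.DataFrame:
    """Least-squares entry means across environments, with standard errors.

    Returns a frame with columns female, male, entry, blue, se.  Each BLUE
    is the model prediction for the entry averaged over the full env × rep
    grid, so balanced data give arithmetic means exactly.
    """
    df = _prepare(trial, trait)
    n_env = df["env"].nunique()
    if n_env > 1:
        formula = f"{trait} ~ C(entry) + C(env) + C(env):C(rep)"
    else:
        formula = f"{trait} ~ C(entry) + C(rep)"
    fit = smf.ols(formula, data=df).fit()
    design_info = fit.model.data.design_info
    cov = np.asarray(fit.cov_params())
    beta = np.asarray(fit.params)

    env_rep = df[["env", "rep"]].drop_duplicates()
    out = []
    for female in trial.parents:
        for male in trial.parents:
            entry = f"{female}{ENTRY_SEP}{male}"
            grid = env_rep.copy()
            grid["entry"] = entry
            (X,) = patsy.build_design_matrices([design_info], grid)
            L = np.asarray(X).mean(axis=0)
            blue = float(L @ beta)
            se = float(np.sqrt(L @ cov @ L))
            out.append(
                {"female": female, "male": male, "entry": entry, "blue": blue, "se": se}
            )
    return pd.DataFrame(out)


def genotype_ss_oracle_basis(trial: TrialTable, trait: str) -> float:
    """Genotype sum of squares for balanced data via cell means.

    Convenience used by the diallel partition closure check: for a
    balanced trial, SS(Genotype) = n_obs_per_entry * sum((entry mean -
    grand mean)^2).
    """
    df = _prepare(trial, trait)
    counts = df.groupby("entry")[trait].count()
    if counts.nunique() != 1:
        raise DesignError("balanced design required")
    n = int(counts.iloc[0])
    means = df.groupby("entry")[trait].mean()
    return float(n * ((means - df[trait].mean()) ** 2).sum())
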