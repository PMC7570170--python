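"""Griffing Method 1, Model I diallel analysis.

Method 1 uses the complete p x p table of entry means x_ij — parents on
the diagonal, both reciprocals off it — and decomposes each cell as

    x_ij = mu + g_i + g_j + s_ij + r_ij            (r_ii = 0)

with general combining ability g_i, specific combining ability s_ij
(symmetric), and reciprocal effect r_ij (antisymmetric), which further
splits into a parent-level maternal effect m_i and a pair-level
nonmaternal remainder n_ij:  r_ij = (m_i - m_j) + n_ij.

Closed-form estimators (x_i. = row sum, x_.i = column sum, x.. = total):

    mu    = x.. / p^2
    g_i   = (x_i. + x_.i) / 2p - x.. / p^2
    s_ij  = (x_ij + x_ji)/2 - (x_i. + x_.i + x_j. + x_.j)/2p + x../p^2
    r_ij  = (x_ij - x_ji)/2
    m_i   = (x_i. - x_.i) / 2p
    n_ij  = r_ij - (m_i - m_j)

The effects satisfy sum(g) = 0, sum_j s_ij = 0 for every i, r antisymmetric,
sum(m) = 0, sum_j n_ij = 0, and the decomposition is saturated: it
reproduces every input cell exactly (1 + (p-1) + p(p-1)/2 + p(p-1)/2 = p^2
degrees of freedom).

Because the components are mutually orthogonal over the p^2 cells, their
sums of squares on the entry-mean basis are plain quadratic forms of the
estimates; multiplying by the observations per cell puts them on the plot
basis of the stage-one ANOVA, where SS(GCA) + SS(SCA) + SS(Reciprocal)
equals the genotype sum of squares.

Model I treats the parents as the population of interest (fixed effects);
the "variance components" derived from the mean-square chain are the
descriptive quantities breeders quote — Baker's ratio, the GCA/SCA
variance ratio, and narrow/broad-sense heritabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DesignError, EstimationError
from .io import EntryMeanTable


# ---------------------------------------------------------------------------
# effects


@dataclass
class GriffingEffects:
    """Estimated Method 1 effects for one trait.

    Arrays are indexed by ``parents`` order: ``gca`` and ``maternal`` are
    length p; ``sca`` is symmetric p x p (diagonal = parental s_ii);
    ``reciprocal`` and ``nonmaternal`` are antisymmetric p x p with zero
    diagonals.  ``se_*``/``t_*``/``p_*`` are populated when an error
    variance was supplied.
    """

    parents: list[str]
    trait: str
    mu: float
    gca: np.ndarray
    sca: np.ndarray
    reciprocal: np.ndarray
    maternal: np.ndarray
    nonmaternal: np.ndarray
    error_variance: float | None = None
    error_df: int | None = None
    se_gca: np.ndarray | None = None
    se_sca: np.ndarray | None = None
    se_reciprocal: np.ndarray | None = None
    se_maternal: np.ndarray | None = None
    se_nonmaternal: np.ndarray | None = None

    @property
    def p(self) -> int:
        return len(self.parents)

    def reconstruct(self) -> np.ndarray:
        """Fitted cell means; equals the input table (saturated design)."""
        g = self.gca
        return self.mu + g[:, None] + g[None, :] + self.sca + self.reciprocal

    def gca_series(self) -> pd.Series:
        return pd.Series(self.gca, index=self.parents, name=f"gca_{self.trait}")

    def to_frame(self) -> pd.DataFrame:
        """Long-format effects with t tests where available."""
        rows = []

        def trow(kind, p1, p2, est, se):
            t = pv = np.nan
            if se is not None and np.isfinite(se) and se > 0 and self.error_df:
                t = est / se
                pv = 2 * scipy.stats.t.sf(abs(t), self.error_df)
            rows.append(
                {
                    "effect_type": kind,
                    "parent_1": p1,
                    "parent_2": p2,
                    "estimate": est,
                    "se": np.nan if se is None else se,
                    "t": t,
                    "p": pv,
                    "stars": _stars(pv),
                }
            )

        for i, a in enumerate(self.parents):
            trow("gca", a, "", self.gca[i], _at(self.se_gca, i))
            trow("maternal", a, "", self.maternal[i], _at(self.se_maternal, i))
        for i, a in enumerate(self.parents):
            for j, b in enumerate(self.parents):
                if i <= j:
                    trow("sca", a, b, self.sca[i, j], _at(self.se_sca, (i, j)))
                if i < j:
                    trow(
                        "reciprocal", a, b, self.reciprocal[i, j],
                        _at(self.se_reciprocal, (i, j)),
                    )
                    trow(
                        "nonmaternal", a, b, self.nonmaternal[i, j],
                        _at(self.se_nonmaternal, (i, j)),
                    )
        return pd.DataFrame(rows)


def _at(arr, idx):
    return None if arr is None else float(arr[idx])


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _closed_form(x: np.ndarray) -> dict[str, np.ndarray | float]:
    p = x.shape[0]
    row = x.sum(axis=1)
    col = x.sum(axis=0)
    tot = x.sum()
    mu = tot / p**2
    g = (row + col) / (2 * p) - tot / p**2
    s = (
        (x + x.T) / 2
        - (row[:, None] + col[:, None] + row[None, :] + col[None, :]) / (2 * p)
        + tot / p**2
    )
    r = (x - x.T) / 2
    m = (row - col) / (2 * p)
    n = r - (m[:, None] - m[None, :])
    np.fill_diagonal(n, 0.0)
    return {"mu": float(mu), "g": g, "s": s, "r": r, "m": m, "n": n}


def _effect_standard_errors(p: int, c: float) -> dict[str, np.ndarray]:
    """Exact SEs of each effect as a linear functional of cell means.

    Every estimator above is linear in the p^2 independent cell means,
    each with variance ``c`` (the mean-basis error variance).  Applying
    the closed forms to the identity basis yields the coefficient of every
    cell in every effect; the variance is c * sum(coef^2).  This is exact
    and sidesteps transcribing the per-effect variance formulas.
    """
    sums = {k: 0.0 for k in ("g", "s", "r", "m", "n")}
    acc = {k: None for k in sums}
    for a in range(p):
        for b in range(p):
            basis = np.zeros((p, p))
            basis[a, b] = 1.0
            eff = _closed_form(basis)
            for k in sums:
                contrib = np.asarray(eff[k]) ** 2
                acc[k] = contrib if acc[k] is None else acc[k] + contrib
    return {k: np.sqrt(c * v) for k, v in acc.items()}


def estimate_effects(
    means: EntryMeanTable,
    error_ms: float | None = None,
    n_obs_per_cell: int | None = None,
    error_df: int | None = None,
) -> GriffingEffects:
    """Estimate Method 1 effects from a complete entry-mean table.

    Parameters
    ----------
    means
        Complete p x p table (p >= 3) of entry means.
    error_ms, n_obs_per_cell, error_df
        Plot-basis residual mean square, observations per cell and
        residual df from the stage-one ANOVA; when given, effect standard
        errors and two-sided t tests use the mean-basis error variance
        error_ms / n_obs_per_cell.
    """
    if not means.is_complete:
        raise DesignError(
            "entry-mean table has missing cells; Method 1 requires the full "
            "p x p grid (parents and both reciprocals)"
        )
    if means.p < 3:
        raise DesignError(f"Method 1 needs at least 3 parents, got {means.p}")
    eff = _closed_form(means.values)
    ses = {}
    edf = None
    if error_ms is not None:
        n_obs = 1 if n_obs_per_cell is None else n_obs_per_cell
        c = error_ms / n_obs
        ses = _effect_standard_errors(means.p, c)
        edf = error_df
    return GriffingEffects(
        parents=list(means.parents),
        trait=means.trait,
        mu=eff["mu"],
        gca=eff["g"],
        sca=eff["s"],
        reciprocal=eff["r"],
        maternal=eff["m"],
        nonmaternal=eff["n"],
        error_variance=None if error_ms is None else error_ms / (n_obs_per_cell or 1),
        error_df=edf,
        se_gca=ses.get("g"),
        se_sca=ses.get("s"),
        se_reciprocal=ses.get("r"),
        se_maternal=ses.get("m"),
        se_nonmaternal=ses.get("n"),
    )


# ---------------------------------------------------------------------------
# sums of squares / diallel ANOVA


def component_df(p: int) -> dict[str, int]:
    return {
        "GCA": p - 1,
        "SCA": p * (p - 1) // 2,
        "Reciprocal": p * (p - 1) // 2,
        "Maternal": p - 1,
        "NonMaternal": (p - 1) * (p - 2) // 2,
    }


def _component_ss_mean_basis(x: np.ndarray) -> dict[str, float]:
    """Orthogonal component SS over the p^2 cells of one mean table."""
    eff = _closed_form(x)
    p = x.shape[0]
    g, s, r, m, n = eff["g"], eff["s"], eff["r"], eff["m"], eff["n"]
    ss = {
        "GCA": 2 * p * float(g @ g),
        "SCA": float((s**2).sum()),
        "Reciprocal": float((r**2).sum()),
        "Maternal": 2 * p * float(m @ m),
        "NonMaternal": float((n**2).sum()),
    }
    return ss


@dataclass
class DiallelAnovaTable:
    """Combining-ability ANOVA: components, their x Env rows, and Error."""

    table: pd.DataFrame
    p: int
    n_environments: int
    n_obs_per_cell: int

    def ms(self, source: str) -> float:
        return float(self.table.set_index("source").loc[source, "ms"])

    def row(self, source: str) -> pd.Series:
        return self.table.set_index("source").loc[source]


def partition_anova(
    means: EntryMeanTable,
    per_env_means: list[EntryMeanTable] | None = None,
    error_ms: float | None = None,
    error_df: int | None = None,
    n_obs_per_cell: int = 1,
    n_reps: int = 1,
) -> DiallelAnovaTable:
    """Partition the genotype variation into combining-ability components.

    SS are computed on the entry-mean basis and scaled to the plot basis
    by ``n_obs_per_cell`` (environments x replicates per cell).  With
    per-environment mean tables, each component's x Env SS is the same
    partition applied within environments (scaled by ``n_reps``) minus
    the across-environment component SS; each main component is then
    F-tested against its own x Env mean square, and the x Env rows
    against the pooled error.  With a single environment, components are
    tested directly against the pooled error.
    """
    if not means.is_complete:
        raise DesignError("entry-mean table has missing cells")
    p = means.p
    dfs = component_df(p)
    main = {
        k: v * n_obs_per_cell for k, v in _component_ss_mean_basis(means.values).items()
    }
    multi_env = per_env_means is not None and len(per_env_means) >= 2
    inter = None
    if multi_env:
        n_env = len(per_env_means)
        within = {k: 0.0 for k in dfs}
        for t in per_env_means:
            if list(t.parents) != list(means.parents):
                raise DesignError("per-environment tables must share parent order")
            for k, v in _component_ss_mean_basis(t.values).items():
                within[k] += v * n_reps
        inter = {k: within[k] - main[k] for k in dfs}
    else:
        n_env = 1

    rows = []
    for k in ("GCA", "SCA", "Reciprocal", "Maternal", "NonMaternal"):
        rows.append({"source": k, "df": dfs[k], "ss": main[k]})
        if multi_env:
            rows.append(
                {"source": f"{k} x Env", "df": dfs[k] * (n_env - 1), "ss": inter[k]}
            )
    if error_ms is not None:
        rows.append(
            {
                "source": "Error",
                "df": error_df if error_df is not None else np.nan,
                "ss": error_ms * error_df if error_df else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    table["ms"] = np.where(
        table["source"] == "Error",
        error_ms if error_ms is not None else np.nan,
        table["ss"] / table["df"],
    )
    ms = table.set_index("source")["ms"]
    dff = table.set_index("source")["df"]

    fvals, pvals = {}, {}
    for k in ("GCA", "SCA", "Reciprocal", "Maternal", "NonMaternal"):
        if multi_env:
            denom, ddf = ms[f"{k} x Env"], dff[f"{k} x Env"]
        elif error_ms is not None:
            denom, ddf = error_ms, error_df
        else:
            denom = None
        if denom and denom > 0 and ddf:
            fvals[k] = ms[k] / denom
            pvals[k] = scipy.stats.f.sf(fvals[k], dff[k], ddf)
        if multi_env and error_ms is not None and error_df:
            src = f"{k} x Env"
            fvals[src] = ms[src] / error_ms
            pvals[src] = scipy.stats.f.sf(fvals[src], dff[src], error_df)
    table["F"] = table["source"].map(fvals)
    table["p"] = table["source"].map(pvals)
    table["stars"] = table["p"].map(lambda v: _stars(v) if np.isfinite(v) else "")
    return DiallelAnovaTable(
        table=table, p=p, n_environments=n_env, n_obs_per_cell=n_obs_per_cell
    )


# ---------------------------------------------------------------------------
# variance components, Baker's ratio, heritability


@dataclass
class VarianceComponents:
    """Descriptive variance components and the ratios derived from them.

    All variances are on the percent^2 scale of the trait.  ``sigma2_a``
    = 2 sigma2_gca and ``sigma2_d`` = sigma2_sca under the usual diallel
    reading.  ``baker_ratio`` = 2 sigma2_gca / (2 sigma2_gca + sigma2_sca)
    in [0, 1]: values near 1 mean additive (GCA) control.  ``h2`` and
    ``H2`` are narrow- and broad-sense heritabilities on the chosen
    phenotypic variance ``sigma2_p``.
    """

    sigma2_gca: float
    sigma2_sca: float
    sigma2_rec: float
    sigma2_e: float
    sigma2_p: float
    sigma2_a: float
    sigma2_d: float
    gca_sca_ratio: float
    baker_ratio: float
    h2: float
    H2: float
    clamped: list[str] = field(default_factory=list)

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "sigma2_GCA": self.sigma2_gca,
                "sigma2_SCA": self.sigma2_sca,
                "sigma2_REC": self.sigma2_rec,
                "sigma2_A": self.sigma2_a,
                "sigma2_D": self.sigma2_d,
                "sigma2_e": self.sigma2_e,
                "sigma2_P": self.sigma2_p,
                "gca_sca_ratio": self.gca_sca_ratio,
                "baker_ratio": self.baker_ratio,
                "h2": self.h2,
                "H2": self.H2,
            }
        )


def _ratios(
    sigma2_a: float,
    sigma2_d: float,
    sigma2_p: float,
    sigma2_gca: float,
    sigma2_sca: float,
) -> tuple[float, float, float, float]:
    if sigma2_p <= 0:
        raise EstimationError(f"non-positive phenotypic variance {sigma2_p}")
    denom = sigma2_a + sigma2_d
    baker = sigma2_a / denom if denom > 0 else np.nan
    gsr = sigma2_gca / sigma2_sca if sigma2_sca > 0 else np.inf
    h2 = sigma2_a / sigma2_p
    H2 = (sigma2_a + sigma2_d) / sigma2_p
    return gsr, baker, h2, H2


def components_from_variances(
    sigma2_a: float,
    sigma2_d: float,
    sigma2_p: float | None = None,
    sigma2_e: float = 0.0,
    sigma2_rec: float = 0.0,
) -> VarianceComponents:
    """Build the ratio set directly from additive/dominance variances.

    This is the identity route used with published variance estimates:
    sigma2_gca = sigma2_a / 2, sigma2_sca = sigma2_d, Baker's ratio
    = sigma2_a / (sigma2_a + sigma2_d), h2 = sigma2_a / sigma2_p,
    H2 = (sigma2_a + sigma2_d) / sigma2_p.  When ``sigma2_p`` is omitted
    it defaults to sigma2_a + sigma2_d + sigma2_rec + sigma2_e.
    """
    if sigma2_p is None:
        sigma2_p = sigma2_a + sigma2_d + sigma2_rec + sigma2_e
    gca, sca = sigma2_a / 2, sigma2_d
    gsr, baker, h2, H2 = _ratios(sigma2_a, sigma2_d, sigma2_p, gca, sca)
    return VarianceComponents(
        sigma2_gca=gca,
        sigma2_sca=sca,
        sigma2_rec=sigma2_rec,
        sigma2_e=sigma2_e,
        sigma2_p=sigma2_p,
        sigma2_a=sigma2_a,
        sigma2_d=sigma2_d,
        gca_sca_ratio=gsr,
        baker_ratio=baker,
        h2=h2,
        H2=H2,
    )


def estimate_variance_components(
    anova: DiallelAnovaTable,
    error_ms: float,
    gca_divisor: float | None = None,
    sca_divisor: float = 1.0,
    sigma2_p: float | None = None,
    include_reciprocal_in_p: bool = True,
) -> VarianceComponents:
    """Variance components from the diallel mean-square chain.

    Mean squares are taken on the entry-mean basis (the plot-basis MS
    divided by observations per cell), and

        sigma2_GCA = (MS_GCA - MS_SCA) / gca_divisor      (default 2p)
        sigma2_SCA = (MS_SCA - MS_e) / sca_divisor
        sigma2_REC = (MS_REC - MS_e) / 2

    The divisors are configurable because fixed-model packages differ in
    convention; the derived ratios (Baker, GCA/SCA, h2, H2) are the
    quantities of record.  Negative raw estimates are clamped to zero and
    recorded in ``clamped`` — never silently.
    """
    n = anova.n_obs_per_cell
    p = anova.p
    if gca_divisor is None:
        gca_divisor = 2 * p
    ms_gca = anova.ms("GCA") / n
    ms_sca = anova.ms("SCA") / n
    ms_rec = anova.ms("Reciprocal") / n
    ms_e = error_ms / n

    raw = {
        "sigma2_GCA": (ms_gca - ms_sca) / gca_divisor,
        "sigma2_SCA": (ms_sca - ms_e) / sca_divisor,
        "sigma2_REC": (ms_rec - ms_e) / 2,
    }
    clamped = [k for k, v in raw.items() if v < 0]
    if clamped:
        warnings.warn(
            f"negative variance component estimate(s) clamped to 0: {clamped}",
            stacklevel=2,
        )
    gca = max(raw["sigma2_GCA"], 0.0)
    sca = max(raw["sigma2_SCA"], 0.0)
    rec = max(raw["sigma2_REC"], 0.0)
    sigma2_a = 2 * gca
    sigma2_d = sca
    if sigma2_p is None:
        sigma2_p = sigma2_a + sigma2_d + (rec if include_reciprocal_in_p else 0.0) + ms_e
    gsr, baker, h2, H2 = _ratios(sigma2_a, sigma2_d, sigma2_p, gca, sca)
    return VarianceComponents(
        sigma2_gca=gca,
        sigma2_sca=sca,
        sigma2_rec=rec,
        sigma2_e=ms_e,
        sigma2_p=sigma2_p,
        sigma2_a=sigma2_a,
        sigma2_d=sigma2_d,
        gca_sca_ratio=gsr,
        baker_ratio=baker,
        h2=h2,
        H2=H2,
        clamped=clamped,
    )


def heritabilities(vc: VarianceComponents) -> tuple[float, float]:
    """(narrow-sense h2, broad-sense H2) from a component set."""
    if vc.sigma2_p <= 0:
        raise EstimationError("non-positive phenotypic variance")
    return vc.sigma2_a / vc.sigma2_p, (vc.sigma2_a + vc.sigma2_d) / vc.sigma2_p
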