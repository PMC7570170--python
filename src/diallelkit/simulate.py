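"""Synthetic full-diallel trials with known genetic architecture.

The generator mirrors the design of the field study the package analyzes:
p = 8 parents crossed in all p^2 combinations (selfs plus both
reciprocals), evaluated in 2 environments x 2 replicates with ~100
putative haploid kernels per plot.  A latent per-plot tassel-fertility
percentage is assembled additively from drawn GCA, SCA, maternal,
nonmaternal, environment, G x E, replicate and plot effects, mapped to a
probability, and the observed counts are binomial:

    n_male_fertile ~ Binomial(n_at_anthesis, p_tassel)
    n_seed_set     ~ Binomial(n_male_fertile, seed_set_rate)

so the count conservation n_seed_set <= n_male_fertile <= n_at_anthesis
<= n_planted holds by construction, and E[HF] = p_tassel * seed_set_rate
(roughly the 2:1 HMF:HF pattern of the real lines at the default rate of
0.5).

Randomness is split per plot by a counter-based scheme (the seed sequence
is keyed on root seed, environment, replicate and cross indices), so the
draws never depend on record order; the same seed yields a byte-identical
trial table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import DesignError
from .io import TrialTable
from . import fixtures

#: latent percentages are clamped to this open interval before becoming
#: binomial probabilities, so no plot is deterministically 0% or 100%.
CLAMP = (0.5, 99.5)


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of a synthetic diallel trial.

    Variances are on the latent percent^2 scale (logit^2 under the logit
    link).  Defaults reproduce the study conditions: 8 parents, 2
    environments, 2 replicates, 100 kernels per plot; genetic variance
    magnitudes are set at the scale reported for a high-variance
    male-fertility trait (additive dominating non-additive, small
    reciprocal structure), with mu near the observed hybrid mean.
    """

    p: int = 8
    parents: tuple[str, ...] | None = None
    n_environments: int = 2
    n_replicates: int = 2
    n_plants: int = 100
    mu: float = 25.0
    sigma2_gca: float = 85.0
    sigma2_sca: float = 60.0
    sigma2_mat: float = 3.0
    sigma2_nonm: float = 3.0
    sigma2_env: float = 10.0
    sigma2_gxe: float = 10.0
    sigma2_rep: float = 3.0
    sigma2_plot: float = 100.0
    seed_set_rate: float = 0.5
    link: str = "identity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 3:
            raise DesignError("need at least 3 parents")
        for name in (
            "sigma2_gca", "sigma2_sca", "sigma2_mat", "sigma2_nonm",
            "sigma2_env", "sigma2_gxe", "sigma2_rep", "sigma2_plot",
        ):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be non-negative")
        if not 0 <= self.seed_set_rate <= 1:
            raise DesignError("seed_set_rate must be in [0, 1]")
        if self.link not in ("identity", "logit"):
            raise DesignError("link must be 'identity' or 'logit'")
        if self.parents is not None and len(self.parents) != self.p:
            raise DesignError("parents list length must equal p")

    @property
    def parent_names(self) -> list[str]:
        if self.parents is not None:
            return list(self.parents)
        return [f"P{i + 1}" for i in range(self.p)]


@dataclass
class SimulationTruth:
    """The drawn generating effects, for parameter-recovery assertions."""

    config: SimulationConfig
    parents: list[str]
    mu: float
    gca: np.ndarray
    sca: np.ndarray
    maternal: np.ndarray
    nonmaternal: np.ndarray
    env_effects: np.ndarray
    gxe: np.ndarray  # (n_env, p, p)
    rep_effects: np.ndarray  # (n_env, n_reps)
    latent_cell_means: np.ndarray  # p x p, genetic part only
    plot_probabilities: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    n_clamped: int = 0


def _draw_centered(rng: np.random.Generator, n: int, var: float) -> np.ndarray:
    if var == 0:
        return np.zeros(n)
    x = rng.normal(0.0, np.sqrt(var), n)
    return x - x.mean()


def _draw_symmetric_centered(rng: np.random.Generator, p: int, var: float) -> np.ndarray:
    """Symmetric matrix with every row (hence column) summing to zero."""
    if var == 0:
        return np.zeros((p, p))
    a = rng.normal(0.0, np.sqrt(var), (p, p))
    s = (a + a.T) / np.sqrt(2)
    s = s - s.mean(axis=1, keepdims=True) - s.mean(axis=0, keepdims=True) + s.mean()
    return s


def _draw_antisymmetric(rng: np.random.Generator, p: int, var: float) -> np.ndarray:
    if var == 0:
        return np.zeros((p, p))
    a = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    a[iu] = rng.normal(0.0, np.sqrt(var), len(iu[0]))
    return a - a.T


def _to_probability(latent_percent: np.ndarray, link: str, mu: float) -> tuple[np.ndarray, int]:
    if link == "identity":
        clamped = int(
            np.sum((latent_percent < CLAMP[0]) | (latent_percent > CLAMP[1]))
        )
        return np.clip(latent_percent, *CLAMP) / 100.0, clamped
    # logit: effects act on the log-odds scale around logit(mu / 100),
    # scaled so that a one-percent latent deviation is one-percent-ish
    # near mu; no clamping is needed.
    base = logit(np.clip(mu, *CLAMP) / 100.0)
    slope = 1.0 / (mu * (1 - mu / 100.0))  # d logit / d percent at mu
    return expit(base + (latent_percent - mu) * slope), 0


def simulate_diallel(
    config: SimulationConfig,
    latent_cell_means: np.ndarray | None = None,
) -> tuple[TrialTable, SimulationTruth]:
    """Generate one full diallel trial.

    When ``latent_cell_means`` is given (p x p), it replaces mu + the
    drawn genetic effects as the genetic layer (used by
    :func:`simulate_paperlike`); environment, replicate and plot layers
    are still drawn from the config.
    """
    cfg = config
    p = cfg.p
    parents = cfg.parent_names
    root = np.random.default_rng(cfg.seed)

    gca = _draw_centered(root, p, cfg.sigma2_gca)
    sca = _draw_symmetric_centered(root, p, cfg.sigma2_sca)
    mat = _draw_centered(root, p, cfg.sigma2_mat)
    nonm = _draw_antisymmetric(root, p, cfg.sigma2_nonm)
    env_eff = _draw_centered(root, cfg.n_environments, cfg.sigma2_env)
    gxe = np.stack(
        [
            _draw_symmetric_centered(root, p, cfg.sigma2_gxe)
            for _ in range(cfg.n_environments)
        ]
    )
    gxe -= gxe.mean(axis=0, keepdims=True)  # center over environments per cell
    rep_eff = np.stack(
        [
            _draw_centered(root, cfg.n_replicates, cfg.sigma2_rep)
            for _ in range(cfg.n_environments)
        ]
    )

    if latent_cell_means is None:
        recip = mat[:, None] - mat[None, :] + nonm
        genetic = cfg.mu + gca[:, None] + gca[None, :] + sca + recip
        np.fill_diagonal(
            genetic, cfg.mu + 2 * gca + np.diag(sca)
        )  # selfs carry no reciprocal part
    else:
        genetic = np.asarray(latent_cell_means, dtype=float)
        if genetic.shape != (p, p):
            raise DesignError("latent_cell_means must be p x p")

    records = []
    probs = []
    n_clamped = 0
    for k in range(cfg.n_environments):
        for m in range(cfg.n_replicates):
            for i in range(p):
                for j in range(p):
                    plot_rng = np.random.default_rng([cfg.seed, k, m, i, j])
                    noise = (
                        plot_rng.normal(0.0, np.sqrt(cfg.sigma2_plot))
                        if cfg.sigma2_plot > 0
                        else 0.0
                    )
                    latent = genetic[i, j] + env_eff[k] + gxe[k, i, j] + rep_eff[k, m] + noise
                    p_t, nc = _to_probability(np.array([latent]), cfg.link, cfg.mu)
                    n_clamped += nc
                    p_tassel = float(p_t[0])
                    n_at = cfg.n_plants
                    n_mf = int(plot_rng.binomial(n_at, p_tassel))
                    n_ss = int(plot_rng.binomial(n_mf, cfg.seed_set_rate))
                    records.append(
                        {
                            "env": f"E{k + 1}",
                            "rep": m + 1,
                            "female": parents[i],
                            "male": parents[j],
                            "n_planted": cfg.n_plants,
                            "n_at_anthesis": n_at,
                            "n_male_fertile": n_mf,
                            "n_seed_set": n_ss,
                        }
                    )
                    probs.append(
                        {
                            "env": f"E{k + 1}",
                            "rep": m + 1,
                            "female": parents[i],
                            "male": parents[j],
                            "p_tassel": p_tassel,
                            "p_seed": p_tassel * cfg.seed_set_rate,
                        }
                    )
    trial = TrialTable.from_records(pd.DataFrame(records), parents=parents)
    truth = SimulationTruth(
        config=cfg,
        parents=parents,
        mu=cfg.mu,
        gca=gca,
        sca=sca,
        maternal=mat,
        nonmaternal=nonm,
        env_effects=env_eff,
        gxe=gxe,
        rep_effects=rep_eff,
        latent_cell_means=genetic,
        plot_probabilities=pd.DataFrame(probs),
        n_clamped=n_clamped,
    )
    return trial, truth


def simulate_paperlike(
    experiment: str,
    seed: int,
    **overrides,
) -> tuple[TrialTable, SimulationTruth]:
    """Diallel trial anchored to the published parent per se means.

    The diagonal of the latent genetic grid is set to the published HMF
    means of the chosen experiment's parents; each hybrid cell is the
    mid-parent value plus drawn SCA and reciprocal deviations.  Design
    dimensions are the study's: 8 parents x 2 environments x 2 replicates
    x 100 kernels.
    """
    parent_df = fixtures.parent_means(experiment)
    parents = tuple(parent_df.index)
    per_se = parent_df["hmf"].to_numpy()
    cfg = SimulationConfig(
        p=len(parents),
        parents=parents,
        mu=float(per_se.mean()),
        seed=seed,
    )
    cfg = replace(cfg, **overrides)

    # draw SCA/reciprocal deviations around the MPV surface
    rng = np.random.default_rng([seed, 2**16 + 1])
    p = cfg.p
    sca = _draw_symmetric_centered(rng, p, cfg.sigma2_sca)
    mat = _draw_centered(rng, p, cfg.sigma2_mat)
    nonm = _draw_antisymmetric(rng, p, cfg.sigma2_nonm)
    mpv = (per_se[:, None] + per_se[None, :]) / 2
    genetic = mpv + sca + (mat[:, None] - mat[None, :] + nonm)
    np.fill_diagonal(genetic, per_se)

    trial, truth = simulate_diallel(cfg, latent_cell_means=genetic)
    truth.sca = sca
    truth.maternal = mat
    truth.nonmaternal = nonm
    truth.gca = per_se / 2 - per_se.mean() / 2  # additive surface equivalent
    return trial, truth
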