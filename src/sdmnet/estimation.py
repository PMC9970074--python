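"""Node-wise Bayesian multilevel estimation of the skills network.

For each of the nine skills, a Bayesian multilevel linear regression is
fitted with that skill as the outcome and the other eight as predictors,
with the intercept and all slopes varying between physicians. The
physician-specific coefficient for predictor k in the model for outcome j
is the population coefficient plus that physician's deviation, formed
draw-by-draw, and becomes the k -> j edge weight of the physician's
skills network. Predictors enter on the raw 0-5 scale (no
standardization); an optional grand-mean-centering flag is provided.

Priors are weakly informative by default: zero-mean Normal priors on the
population intercept and slopes with scales wide relative to the 0-5
item range, half-t-type priors on the residual and random-effect scales,
and (optionally) an unstructured correlation structure among the random
effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .samplers import McmcConfig, GibbsDraws, sample_multilevel, split_rhat
from .skills import N_SKILLS, SKILL_COLUMNS, skill_column

__all__ = [
    "McmcConfig",
    "PriorSpec",
    "NodewiseFit",
    "ConvergenceReport",
    "fit_nodewise",
    "fit_all_nodes",
    "check_convergence",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PriorSpec:
    """Prior specification for a regression model.

    ``coef_mean``/``coef_sd`` may be scalars (applied to every slope) or
    per-coefficient vectors (informative priors imported from a previous
    study's posterior). Scales must be strictly positive.
    """

    intercept_mean: float = 0.0
    intercept_sd: float = 10.0
    coef_mean: float | np.ndarray = 0.0
    coef_sd: float | np.ndarray = 5.0
    resid_scale: float = 10.0
    ranef_scale: float = 2.5
    correlated_ranef: bool = True
    provenance: str = "weakly_informative_default"

    def __post_init__(self) -> None:
        for name in ("intercept_sd", "resid_scale", "ranef_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if np.any(np.asarray(self.coef_sd, dtype=float) <= 0):
            raise ValueError("coef_sd must be > 0")

    def design_prior(self, n_coef: int) -> tuple[np.ndarray, np.ndarray]:
        """Prior mean/sd vectors for [intercept, slopes...]."""
        mean = np.concatenate(
            [[self.intercept_mean], np.broadcast_to(np.asarray(self.coef_mean, float), (n_coef,))]
        )
        sd = np.concatenate(
            [[self.intercept_sd], np.broadcast_to(np.asarray(self.coef_sd, float), (n_coef,))]
        )
        return mean, sd

    @classmethod
    def from_file(cls, path: str | Path) -> "PriorSpec":
        """Load a prior file (YAML or JSON mapping of the fields above)."""
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("coef_mean", "coef_sd"):
            if isinstance(raw.get(key), list):
                raw[key] = np.asarray(raw[key], dtype=float)
        raw.setdefault("provenance", "file")
        return cls(**raw)


@dataclass
class NodewiseFit:
    """Posterior of one skill's regression on the other eight.

    ``beta`` rows are retained draws of [intercept, slopes for
    ``predictor_skills``]; ``physician_beta`` has shape (S, P, 9) holding
    the physician-specific coefficients (population + deviation, summed
    per retained iteration); ``rhat`` maps parameter names to split R-hat.
    """

    outcome_skill: int
    predictor_skills: list[int]
    physician_ids: list[str]
    draws: GibbsDraws
    physician_beta: np.ndarray
    rhat: dict[str, float]
    centered: bool = False

    @property
    def n_draws(self) -> int:
        return self.draws.n_draws

    def population_slope_draws(self, predictor_skill: int) -> np.ndarray:
        idx = self.predictor_skills.index(predictor_skill)
        return self.draws.beta[:, idx + 1]

    def physician_slope_draws(self, physician_id: str, predictor_skill: int) -> np.ndarray:
        p = self.physician_ids.index(physician_id)
        idx = self.predictor_skills.index(predictor_skill)
        return self.physician_beta[:, p, idx + 1]

    def summary(self) -> pd.DataFrame:
        """Posterior summary table (mean, sd, 95% CI, R-hat) for the
        population-level parameters."""
        names = ["intercept"] + [
            f"b_skill{k}" for k in self.predictor_skills
        ]
        rows = []
        for i, name in enumerate(names):
            d = self.draws.beta[:, i]
            rows.append(
                {
                    "parameter": name,
                    "mean": d.mean(),
                    "sd": d.std(ddof=1),
                    "q2.5": np.quantile(d, 0.025),
                    "q97.5": np.quantile(d, 0.975),
                    "rhat": self.rhat.get(name, np.nan),
                }
            )
        d = self.draws.sigma
        rows.append(
            {
                "parameter": "sigma",
                "mean": d.mean(),
                "sd": d.std(ddof=1),
                "q2.5": np.quantile(d, 0.025),
                "q97.5": np.quantile(d, 0.975),
                "rhat": self.rhat.get("sigma", np.nan),
            }
        )
        return pd.DataFrame(rows)


def _compute_rhat(fit_draws: GibbsDraws, predictor_skills: list[int],
                  physician_ids: list[str], physician_beta: np.ndarray) -> dict[str, float]:
    names = ["intercept"] + [f"b_skill{k}" for k in predictor_skills]
    rhat: dict[str, float] = {}
    for i, name in enumerate(names):
        rhat[name] = split_rhat(fit_draws.by_chain(fit_draws.beta[:, i]))
    rhat["sigma"] = split_rhat(fit_draws.by_chain(fit_draws.sigma))
    if fit_draws.sd_u is not None and len(physician_ids) > 1:
        for i, name in enumerate(names):
            rhat[f"sd_u[{name}]"] = split_rhat(fit_draws.by_chain(fit_draws.sd_u[:, i]))
        for p, pid in enumerate(physician_ids):
            for i, name in enumerate(names):
                rhat[f"b[{pid},{name}]"] = split_rhat(
                    fit_draws.by_chain(physician_beta[:, p, i])
                )
    return rhat


def fit_nodewise(
    ratings: pd.DataFrame,
    outcome_skill: int,
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    center: bool = False,
) -> NodewiseFit:
    """Fit the multilevel regression of one skill on the other eight.

    ``ratings`` must be complete (post-imputation). With a single
    physician the hierarchy collapses to a pooled Bayesian regression.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcConfig()
    skill_column(outcome_skill)
    cols = ratings[SKILL_COLUMNS]
    if cols.isna().any().any():
        raise ValueError("ratings contain missing values; run imputation first")

    predictor_skills = [k for k in range(1, N_SKILLS + 1) if k != outcome_skill]
    y = ratings[skill_column(outcome_skill)].to_numpy(dtype=float)
    Xs = ratings[[skill_column(k) for k in predictor_skills]].to_numpy(dtype=float)
    if center:
        Xs = Xs - Xs.mean(axis=0, keepdims=True)
    X = np.column_stack([np.ones(len(y)), Xs])

    physician_ids = sorted(ratings["physician_id"].astype(str).unique().tolist())
    code = {pid: i for i, pid in enumerate(physician_ids)}
    groups = ratings["physician_id"].astype(str).map(code).to_numpy()

    prior_mean, prior_sd = priors.design_prior(len(predictor_skills))
    draws = sample_multilevel(
        y,
        X,
        groups,
        prior_mean,
        prior_sd,
        mcmc,
        resid_scale=priors.resid_scale,
        ranef_scale=priors.ranef_scale,
        correlated=priors.correlated_ranef,
    )
    # Physician-specific coefficients: population + deviation, per draw.
    physician_beta = draws.beta[:, None, :] + draws.u
    rhat = _compute_rhat(draws, predictor_skills, physician_ids, physician_beta)
    return NodewiseFit(
        outcome_skill=outcome_skill,
        predictor_skills=predictor_skills,
        physician_ids=physician_ids,
        draws=draws,
        physician_beta=physician_beta,
        rhat=rhat,
        centered=center,
    )


def fit_all_nodes(
    ratings: pd.DataFrame,
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    center: bool = False,
) -> dict[int, NodewiseFit]:
    """Fit all nine node-wise models with per-node seeds derived from the
    master seed."""
    mcmc = mcmc or McmcConfig()
    node_seeds = np.random.SeedSequence(mcmc.seed).generate_state(N_SKILLS) % (2**31)
    fits = {}
    for j in range(1, N_SKILLS + 1):
        node_mcmc = McmcConfig(
            n_chains=mcmc.n_chains,
            iterations=mcmc.iterations,
            burn_in=mcmc.burn_in,
            thinning=mcmc.thinning,
            seed=int(node_seeds[j - 1]),
        )
        log.info("fitting node-wise model for skill %d", j)
        fits[j] = fit_nodewise(ratings, j, priors, node_mcmc, center=center)
    return fits


@dataclass
class ConvergenceReport:
    outcome_skill: int
    threshold: float
    rhat: pd.DataFrame  # parameter, rhat
    flagged: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return not self.flagged


def check_convergence(fit: NodewiseFit, threshold: float = 1.01) -> ConvergenceReport:
    """Flag parameters whose split Gelman-Rubin R-hat exceeds the threshold."""
    n_chains = int(fit.draws.chain.max()) + 1
    if n_chains < 2:
        raise ValueError("convergence check requires at least 2 chains")
    df = pd.DataFrame(
        {"parameter": list(fit.rhat), "rhat": list(fit.rhat.values())}
    )
    flagged = df.loc[df["rhat"] > threshold, "parameter"].tolist()
    return ConvergenceReport(
        outcome_skill=fit.outcome_skill, threshold=threshold, rhat=df, flagged=flagged
    )
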