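"""Predicting observer-rated competence from skills-network parameters.

Two analysis modes mirror the study design:

* **Confirmatory**: a fixed predictor set — activation, instrength and
  outstrength of the skills "focusing the decision" (1), "eliciting
  preferences" (6) and "deliberating the decision" (7) — with informative
  Gaussian priors supplied from the posterior of an earlier analysis.

* **Exploratory**: a two-stage selection. Stage 1 fits, per parameter
  type (activation / instrength / outstrength) and per instrument, a
  regression on that type for all nine skills. Any skill with at least
  one significant stage-1 coefficient (95% CI excluding zero, any type,
  any instrument) enters the final model, which includes all three
  parameter types of the selected skills, per instrument, under weakly
  informative priors.

Reported per fit: posterior medians and 95% equal-tailed credible
intervals per coefficient with significance flags, the posterior of the
multiple correlation R (correlation between the linear predictor and the
observed responses, computed draw by draw and floored at zero) and of
R^2, and per-physician posterior-mean predictions for calibration plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import PriorSpec
from .networks import SkillsNetwork
from .samplers import McmcConfig, GibbsDraws, sample_linear
from .skills import PARAM_TYPES

__all__ = [
    "CONFIRMATORY_SKILLS",
    "default_prediction_priors",
    "SmallSampleError",
    "PredictionFit",
    "ExploratoryResult",
    "assemble_predictors",
    "fit_prediction",
    "confirmatory_model",
    "exploratory_procedure",
    "calibration_pairs",
]

log = logging.getLogger(__name__)

#: Skill subset of the confirmatory model (focusing the decision,
#: eliciting preferences, deliberating the decision).
CONFIRMATORY_SKILLS = (1, 6, 7)


def default_prediction_priors() -> PriorSpec:
    """Weakly informative priors matched to the 0-100 competence scale.

    The intercept scale must dwarf the response scale; a tight intercept
    prior would drag correlated slope posteriors away from zero and
    distort their significance under the null.
    """
    return PriorSpec(
        intercept_sd=100.0, coef_sd=50.0, resid_scale=25.0,
        provenance="weakly_informative_default",
    )


class SmallSampleError(ValueError):
    """Too few physicians with responses to fit the requested model."""


def predictor_name(skill: int, ptype: str) -> str:
    return f"skill{skill}_{ptype}"


def assemble_predictors(
    networks: dict[str, SkillsNetwork],
    skills: tuple[int, ...] | list[int],
    types: tuple[str, ...] = PARAM_TYPES,
) -> pd.DataFrame:
    """Physician-by-parameter predictor matrix.

    Column order is deterministic: skill-major, parameter-type-minor
    (e.g. skill1_activation, skill1_instrength, skill1_outstrength,
    skill6_activation, ...). Values are copied from the built networks.
    """
    for t in types:
        if t not in PARAM_TYPES:
            raise ValueError(f"unknown parameter type {t!r}")
    cols = [predictor_name(s, t) for s in skills for t in types]
    index = pd.Index(sorted(networks), name="physician_id")
    df = pd.DataFrame(index=index, columns=cols, dtype=float)
    for pid in index:
        net = networks[pid]
        for s in skills:
            for t in types:
                if t == "activation":
                    val = net.activation[s - 1]
                elif t == "instrength":
                    val = net.instrength[s - 1]
                else:
                    val = net.outstrength[s - 1]
                df.loc[pid, predictor_name(s, t)] = float(val)
    return df


@dataclass
class PredictionFit:
    """Posterior of a Bayesian linear regression of one observer measure
    on network parameters."""

    instrument: str
    predictor_names: list[str]
    physician_ids: list[str]
    draws: GibbsDraws
    observed: np.ndarray
    fitted: np.ndarray  # posterior-mean linear predictor per physician
    r_draws: np.ndarray
    priors: PriorSpec

    @property
    def n(self) -> int:
        return len(self.physician_ids)

    @property
    def r2_draws(self) -> np.ndarray:
        return self.r_draws**2

    def coefficient_table(self) -> pd.DataFrame:
        """Posterior medians, 95% CIs and significance flags (CI excludes
        zero), intercept first."""
        names = ["Intercept"] + self.predictor_names
        rows = []
        for i, name in enumerate(names):
            d = self.draws.beta[:, i]
            lo, hi = np.quantile(d, [0.025, 0.975])
            rows.append(
                {
                    "predictor": name,
                    "estimate": float(np.median(d)),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "significant": bool(lo > 0 or hi < 0),
                }
            )
        return pd.DataFrame(rows)

    def fit_statistics(self) -> pd.DataFrame:
        """Posterior median and 95% CI of R and R^2 (same draw set)."""
        rows = []
        for name, d in (("R", self.r_draws), ("R2", self.r2_draws)):
            lo, hi = np.quantile(d, [0.025, 0.975])
            rows.append(
                {
                    "statistic": name,
                    "estimate": float(np.median(d)),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
        return pd.DataFrame(rows)

    def significant_predictors(self) -> list[str]:
        tab = self.coefficient_table()
        return tab.loc[
            (tab["significant"]) & (tab["predictor"] != "Intercept"), "predictor"
        ].tolist()


def _check_design(X: np.ndarray, names: list[str], on_collinear: str = "error") -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Identify offending columns via QR with pivoting.
        from scipy.linalg import qr

        _, R, piv = qr(X, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag.max()]
        bad += [names[p] for p in piv[len(diag):]]
        msg = f"rank-deficient design; collinear columns: {sorted(set(bad))}"
        if on_collinear == "error":
            raise ValueError(msg)
        # With proper Gaussian priors the posterior remains well-defined;
        # degenerate columns (e.g. a strength pruned to zero for every
        # physician) are kept so the report surface stays complete.
        log.warning("%s; proceeding under proper priors", msg)


def fit_prediction(
    table: pd.DataFrame,
    response: pd.Series,
    instrument: str,
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    on_collinear: str = "error",
) -> PredictionFit:
    """Fit one observer measure on the predictor table.

    Physicians with a missing response are dropped for this instrument
    only. Requires at least (number of predictors + 2) responding
    physicians. Rank-deficient designs are rejected with the collinear
    columns named unless ``on_collinear="allow"``, in which case the fit
    proceeds (the proper Gaussian priors keep the posterior well-defined)
    with a logged warning.
    """
    priors = priors or default_prediction_priors()
    mcmc = mcmc or McmcConfig()
    resp = response.reindex(table.index)
    keep = resp.notna()
    y = resp[keep].to_numpy(dtype=float)
    Xs = table.loc[keep].to_numpy(dtype=float)
    names = list(table.columns)
    n, p = Xs.shape
    if n < p + 2:
        raise SmallSampleError(
            f"{instrument}: {n} physicians with responses cannot support "
            f"{p} predictors (need at least {p + 2})"
        )
    X = np.column_stack([np.ones(n), Xs])
    _check_design(X, ["Intercept"] + names, on_collinear)

    prior_mean, prior_sd = priors.design_prior(p)
    draws = sample_linear(
        y, X, prior_mean, prior_sd, mcmc, resid_scale=priors.resid_scale
    )

    linpred = draws.beta @ X.T  # (S, n)
    fitted = linpred.mean(axis=0)
    sd_lp = linpred.std(axis=1, ddof=1)
    sd_y = y.std(ddof=1)
    if sd_y < 1e-12:
        r = np.zeros(draws.n_draws)
    else:
        yc = y - y.mean()
        lc = linpred - linpred.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (lc @ yc) / ((n - 1) * sd_lp * sd_y)
        r = np.where(sd_lp < 1e-12, 0.0, r)
    r = np.clip(r, 0.0, 1.0)

    return PredictionFit(
        instrument=instrument,
        predictor_names=names,
        physician_ids=[str(i) for i in table.index[keep]],
        draws=draws,
        observed=y,
        fitted=fitted,
        r_draws=r,
        priors=priors,
    )


def _responses(scores: pd.DataFrame, instrument: str) -> pd.Series:
    if instrument not in scores.columns:
        raise KeyError(f"instrument {instrument!r} absent from competence scores")
    return scores[instrument]


def confirmatory_model(
    networks: dict[str, SkillsNetwork],
    scores: pd.DataFrame,
    prior_file: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    instruments: tuple[str, ...] | None = None,
) -> dict[str, PredictionFit]:
    """Confirmatory prediction on the fixed skill subset {1, 6, 7}.

    ``prior_file`` carries informative per-coefficient Gaussian priors
    (means/SDs estimated from an earlier study's posterior); when absent
    the fit falls back to weakly informative defaults with a warning.
    """
    if prior_file is None:
        log.warning(
            "no informative prior file supplied; confirmatory model falls "
            "back to weakly informative defaults"
        )
        prior_file = default_prediction_priors()
    table = assemble_predictors(networks, CONFIRMATORY_SKILLS, PARAM_TYPES)
    insts = instruments or tuple(
        c for c in scores.columns if not str(c).startswith("n_")
    )
    fits = {}
    for i, inst in enumerate(insts):
        inst_mcmc = _offset_mcmc(mcmc or McmcConfig(), i + 1)
        fits[inst] = fit_prediction(
            table, _responses(scores, inst), inst, prior_file, inst_mcmc,
            on_collinear="allow",
        )
    return fits


def _offset_mcmc(mcmc: McmcConfig, offset: int) -> McmcConfig:
    sub = np.random.SeedSequence(mcmc.seed).generate_state(offset + 1) % (2**31)
    return McmcConfig(
        n_chains=mcmc.n_chains,
        iterations=mcmc.iterations,
        burn_in=mcmc.burn_in,
        thinning=mcmc.thinning,
        seed=int(sub[offset]),
    )


@dataclass
class ExploratoryResult:
    stage1: dict[tuple[str, str], PredictionFit]  # (ptype, instrument) -> fit
    selected_skills: list[int]
    final: dict[str, PredictionFit] = field(default_factory=dict)

    def stage1_report(self) -> pd.DataFrame:
        rows = []
        for (ptype, inst), fit in self.stage1.items():
            tab = fit.coefficient_table()
            tab.insert(0, "parameter_type", ptype)
            tab.insert(1, "instrument", inst)
            rows.append(tab)
        return pd.concat(rows, ignore_index=True)


def exploratory_procedure(
    networks: dict[str, SkillsNetwork],
    scores: pd.DataFrame,
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    instruments: tuple[str, ...] | None = None,
    selected_skills: list[int] | None = None,
) -> ExploratoryResult:
    """Two-stage exploratory prediction with weakly informative priors.

    ``selected_skills`` overrides stage-1 selection (useful for refitting
    a previously selected set); stage-1 fits are still produced and
    reported for audit.
    """
    priors = priors or default_prediction_priors()
    mcmc = mcmc or McmcConfig()
    insts = instruments or tuple(
        c for c in scores.columns if not str(c).startswith("n_")
    )
    all_skills = tuple(range(1, 10))

    stage1: dict[tuple[str, str], PredictionFit] = {}
    chosen: set[int] = set()
    counter = 0
    for ptype in PARAM_TYPES:
        table = assemble_predictors(networks, all_skills, (ptype,))
        for inst in insts:
            counter += 1
            fit = fit_prediction(
                table,
                _responses(scores, inst),
                inst,
                priors,
                _offset_mcmc(mcmc, counter),
                on_collinear="allow",
            )
            stage1[(ptype, inst)] = fit
            for name in fit.significant_predictors():
                chosen.add(int(name.split("_")[0].removeprefix("skill")))

    selection = sorted(selected_skills) if selected_skills is not None else sorted(chosen)
    result = ExploratoryResult(stage1=stage1, selected_skills=selection)

    if not selection:
        log.info("no skill selected in stage 1; final model is intercept-only")
    table = assemble_predictors(networks, selection, PARAM_TYPES)
    for inst in insts:
        counter += 1
        result.final[inst] = fit_prediction(
            table, _responses(scores, inst), inst, priors,
            _offset_mcmc(mcmc, counter), on_collinear="allow",
        )
    return result


def calibration_pairs(fit: PredictionFit, smooth: bool = False) -> pd.DataFrame:
    """Per-physician (predicted, observed) pairs for calibration plots.

    With ``smooth`` a lowess curve over the pairs is appended as extra
    columns (``smooth_x``, ``smooth_y``; NaN-padded).
    """
    df = pd.DataFrame(
        {
            "physician_id": fit.physician_ids,
            "predicted": fit.fitted,
            "observed": fit.observed,
        }
    )
    if smooth and len(df) >= 4:
        try:
            from statsmodels.nonparametric.smoothers_lowess import lowess

            sm = lowess(df["observed"], df["predicted"], frac=0.8, return_sorted=True)
            df["smooth_x"] = pd.Series(sm[:, 0]).reindex(df.index)
            df["smooth_y"] = pd.Series(sm[:, 1]).reindex(df.index)
        except ImportError:  # pragma: no cover - statsmodels is optional here
            pass
    return df
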