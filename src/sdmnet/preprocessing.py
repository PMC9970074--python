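"""Input handling: rating/observer tables, missingness rule, EM imputation.

The consultation-level missingness rule follows the measurement protocol:
consultations with more than two of the nine skills missing are excluded;
one or two missing ratings per consultation are imputed with the
expectation-maximization (EM) algorithm under a pooled multivariate
Gaussian, and the imputed values are left continuous.

Observer instrument scores are affinely rescaled to 0-100 and averaged
across each physician's rated consultations to give one competence score
per physician and instrument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .skills import SKILL_COLUMNS, ID_COLUMNS, RATING_MIN, RATING_MAX

__all__ = [
    "load_ratings",
    "save_ratings",
    "load_observer",
    "filter_missing",
    "ExclusionReport",
    "impute_em",
    "ImputationResult",
    "EmError",
    "rescale_score",
    "aggregate_observer",
]

log = logging.getLogger(__name__)

OBSERVER_COLUMNS = ["physician_id", "consultation_id", "instrument", "score"]


class EmError(RuntimeError):
    """EM failed to converge; carries the log-likelihood trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def _validate_ratings(
    df: pd.DataFrame, source: str = "ratings", check_range: bool = True
) -> pd.DataFrame:
    missing_cols = [c for c in ID_COLUMNS + SKILL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{source}: missing columns {missing_cols}")
    df = df[ID_COLUMNS + SKILL_COLUMNS].copy()
    dup = df.duplicated(subset=ID_COLUMNS)
    if dup.any():
        pairs = df.loc[dup, ID_COLUMNS].values.tolist()
        raise ValueError(f"{source}: duplicate (physician, consultation) keys {pairs}")
    for col in SKILL_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_numeric = vals.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad_numeric.any():
            row = df.index[bad_numeric][0]
            raise ValueError(f"{source}: non-numeric rating in column {col}, row {row}")
        out_of_range = vals.notna() & ((vals < RATING_MIN) | (vals > RATING_MAX))
        if check_range and out_of_range.any():
            row = df.index[out_of_range][0]
            raise ValueError(
                f"{source}: rating out of [0, 5] in column {col}, row {row} "
                f"(value {vals[out_of_range].iloc[0]})"
            )
        df[col] = vals
    return df.reset_index(drop=True)


def load_ratings(path: str | Path, missing_sentinel: str | None = None) -> pd.DataFrame:
    """Read and validate a rating table CSV.

    Empty cells (and optionally a sentinel string) are treated as missing,
    never as zero. Out-of-range or non-numeric ratings raise with the
    offending row and column named.
    """
    na = ["", "NA", "nan"] if missing_sentinel is None else ["", missing_sentinel]
    df = pd.read_csv(path, na_values=na, keep_default_na=True, dtype={c: str for c in ID_COLUMNS})
    return _validate_ratings(df, source=str(path))


def save_ratings(ratings: pd.DataFrame, path: str | Path) -> None:
    ratings.to_csv(path, index=False)


def load_observer(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"physician_id": str})
    missing = [c for c in ("physician_id", "instrument") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    score_col = "score" if "score" in df.columns else "raw_score"
    if score_col not in df.columns:
        raise ValueError(f"{path}: need a 'score' or 'raw_score' column")
    return df


@dataclass
class ExclusionReport:
    """Consultations removed by the >2-missing-skills rule."""

    excluded: pd.DataFrame  # physician_id, consultation_id, n_missing
    n_input: int
    n_kept: int

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def filter_missing(ratings: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop consultations with three or more missing skill ratings.

    Consultations with one or two missing items are retained (for EM
    imputation); the report lists each excluded (physician, consultation)
    pair with its missing count. Idempotent.
    """
    ratings = _validate_ratings(ratings, check_range=False)
    n_missing = ratings[SKILL_COLUMNS].isna().sum(axis=1)
    drop = n_missing > 2
    excluded = ratings.loc[drop, ID_COLUMNS].copy()
    excluded["n_missing"] = n_missing[drop].values
    kept = ratings.loc[~drop].reset_index(drop=True)
    report = ExclusionReport(
        excluded=excluded.reset_index(drop=True), n_input=len(ratings), n_kept=len(kept)
    )
    if report.n_excluded:
        log.info(
            "excluded %d of %d consultations with >2 missing skills",
            report.n_excluded,
            report.n_input,
        )
    return kept, report


@dataclass
class ImputationResult:
    ratings: pd.DataFrame
    mean: np.ndarray
    cov: np.ndarray
    loglik_trace: list[float]
    n_iter: int
    converged: bool


def _observed_loglik(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Observed-data log-likelihood under MVN with row-wise missingness."""
    total = 0.0
    for row in X:
        obs = ~np.isnan(row)
        if not obs.any():
            continue
        x = row[obs] - mu[obs]
        S = sigma[np.ix_(obs, obs)]
        sign, logdet = np.linalg.slogdet(S)
        total += -0.5 * (
            obs.sum() * np.log(2 * np.pi) + logdet + x @ np.linalg.solve(S, x)
        )
    return float(total)


def impute_em(
    ratings: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 500,
    ridge: float = 1e-9,
) -> ImputationResult:
    """Impute missing skill ratings by EM under a pooled multivariate Gaussian.

    All consultations are pooled into a single Gaussian (the small number
    of rows per physician makes per-physician fits unstable). Missing
    cells are replaced by their conditional expectations given the
    observed items at the converged parameters; observed cells are left
    bit-identical and imputed values stay continuous. Convergence is
    declared when successive observed-data log-likelihoods differ by less
    than ``tol``; non-convergence raises :class:`EmError` with the trace.
    """
    ratings = _validate_ratings(ratings, check_range=False)
    X = ratings[SKILL_COLUMNS].to_numpy(dtype=float)
    n, k = X.shape
    miss = np.isnan(X)
    if (miss.sum(axis=1) > 2).any():
        raise ValueError("apply filter_missing first: a consultation has >2 missing skills")

    mu = np.nanmean(X, axis=0)
    Xc = np.where(miss, mu[None, :], X)
    sigma = np.cov(Xc, rowvar=False) + ridge * np.eye(k)

    trace: list[float] = [_observed_loglik(X, mu, sigma)]
    if not miss.any():
        out = ratings.copy()
        return ImputationResult(out, mu, sigma, trace, 0, True)

    # Group rows by missingness pattern so each E-step solves one system.
    patterns: dict[bytes, np.ndarray] = {}
    for key in np.unique(miss, axis=0):
        rows = np.where((miss == key[None, :]).all(axis=1))[0]
        patterns[key.tobytes()] = rows

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step: expected sufficient statistics.
        EX = X.copy()
        C = np.zeros((k, k))  # sum of conditional covariances
        for key, rows in patterns.items():
            m = np.frombuffer(key, dtype=bool)
            if not m.any():
                continue
            o = ~m
            S_oo = sigma[np.ix_(o, o)]
            S_mo = sigma[np.ix_(m, o)]
            S_mm = sigma[np.ix_(m, m)]
            B = linalg.solve(S_oo, S_mo.T, assume_a="pos").T  # regression of miss on obs
            cond_cov = S_mm - B @ S_mo.T
            diff = X[np.ix_(rows, np.where(o)[0])] - mu[o][None, :]
            EX[np.ix_(rows, np.where(m)[0])] = mu[m][None, :] + diff @ B.T
            C[np.ix_(m, m)] += len(rows) * cond_cov

        # M-step.
        mu = EX.mean(axis=0)
        centered = EX - mu[None, :]
        sigma = (centered.T @ centered + C) / n + ridge * np.eye(k)

        ll = _observed_loglik(X, mu, sigma)
        trace.append(ll)
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    if not converged:
        raise EmError(
            f"EM did not converge within {max_iter} iterations "
            f"(last change {abs(trace[-1] - trace[-2]):.3g})",
            trace,
        )

    # Final imputation at the converged parameters.
    X_imp = X.copy()
    for key, rows in patterns.items():
        m = np.frombuffer(key, dtype=bool)
        if not m.any():
            continue
        o = ~m
        B = linalg.solve(sigma[np.ix_(o, o)], sigma[np.ix_(m, o)].T, assume_a="pos").T
        diff = X[np.ix_(rows, np.where(o)[0])] - mu[o][None, :]
        X_imp[np.ix_(rows, np.where(m)[0])] = mu[m][None, :] + diff @ B.T

    out = ratings.copy()
    out[SKILL_COLUMNS] = X_imp
    return ImputationResult(out, mu, sigma, trace, n_iter, True)


def rescale_score(
    raw: float | np.ndarray, instrument_min: float, instrument_max: float
) -> float | np.ndarray:
    """Affine rescaling of an instrument score to the 0-100 scale."""
    if instrument_max <= instrument_min:
        raise ValueError("instrument_max must exceed instrument_min")
    raw_arr = np.asarray(raw, dtype=float)
    if ((raw_arr < instrument_min) | (raw_arr > instrument_max)).any():
        raise ValueError("raw score outside the instrument range")
    scaled = 100.0 * (raw_arr - instrument_min) / (instrument_max - instrument_min)
    return float(scaled) if np.isscalar(raw) else scaled


def aggregate_observer(scores: pd.DataFrame) -> pd.DataFrame:
    """Average rescaled observer scores per physician and instrument.

    Returns a physician-indexed frame with one column per instrument plus
    ``n_<instrument>`` consultation counts. Physicians without any rated
    consultation for an instrument are absent (NaN) in that column, never
    zero-filled.
    """
    if "score" not in scores.columns:
        raise ValueError("expected a rescaled 'score' column (0-100)")
    if ((scores["score"] < 0) | (scores["score"] > 100)).any():
        raise ValueError("scores must already be rescaled to [0, 100]")
    g = scores.groupby(["physician_id", "instrument"])["score"]
    means = g.mean().unstack("instrument")
    counts = g.count().unstack("instrument")
    out = means.copy()
    for inst in counts.columns:
        out[f"n_{inst}"] = counts[inst]
    out.index.name = "physician_id"
    return out
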