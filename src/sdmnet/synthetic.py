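"""Synthetic rating and observer data with known ground truth.

The generator mirrors the data situation of a consultation study: each of
P physicians rates their own use of nine SDM skills (0-5 Likert scale)
after every consultation, and external observers score a subset of
physicians on up to three competence instruments (0-100 scale).

The joint generative model for the nine ratings of one physician is a
multivariate Gaussian parameterized by a precision matrix. This choice is
deliberate: the node-wise regressions the estimation pipeline fits are
exactly the conditionals of such a joint, so every estimated edge has an
analytic truth. The true directed edge weight from skill k to skill j for
physician p is

    beta_{p,jk} = -omega_jk / omega_jj

of that physician's precision matrix (zero when omega_jk = 0), which is
the population regression coefficient of predictor k in the conditional
model for outcome j. Physician heterogeneity enters as (a) an additive
symmetric perturbation of the off-diagonal precision entries, with an
eigenvalue-floor shrink-and-retry repair, and (b) physician-specific item
means around the population means, which give the "activation" parameters
genuine between-physician variance.

Observer competence scores are linear in the true per-physician network
parameters (activation, instrength, outstrength of selected skills) plus
Gaussian noise, clipped to [0, 100].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .skills import (
    N_SKILLS,
    SKILL_COLUMNS,
    PARAM_TYPES,
    INSTRUMENTS,
    RATING_MIN,
    RATING_MAX,
)

__all__ = [
    "GeneratorConfig",
    "TrueModel",
    "sample_true_model",
    "simulate_ratings",
    "inject_missingness",
    "simulate_observer_scores",
    "true_edge_weights",
    "true_network_parameters",
    "study_structure_partials",
]


def study_structure_partials() -> np.ndarray:
    """Population partial-correlation template shaped like the field's
    replicated skills-network topology.

    Skills 1-2 form a strongly tied pair disconnected from the rest; a
    dense cluster links 3, 4, 6, 8 around the hub 7; skills 5 and 9 hang
    peripherally off 4 and 8.
    """
    edges = {
        (1, 2): 0.40,
        (3, 4): 0.25,
        (3, 7): 0.20,
        (4, 7): 0.22,
        (6, 7): 0.25,
        (7, 8): 0.20,
        (3, 6): 0.15,
        (4, 6): 0.15,
        (6, 8): 0.15,
        (4, 5): 0.25,
        (8, 9): 0.30,
    }
    R = np.zeros((N_SKILLS, N_SKILLS))
    for (j, k), rho in edges.items():
        R[j - 1, k - 1] = R[k - 1, j - 1] = rho
    return R


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings of the synthetic study.

    Defaults emulate the scale of the motivating study: 28 physicians,
    11 consultations each (308 rows), audio recordings for 24 physicians,
    and observer scores available for 22/24/22 physicians on the three
    instruments.
    """

    n_physicians: int = 28
    n_skills: int = N_SKILLS
    consultations_per_physician: int = 11
    structure: str = "study"  # "study" | "random"
    sparsity: float = 0.6  # random structure: fraction of absent edges
    partial_range: tuple[float, float] = (0.15, 0.30)
    heterogeneity: float = 0.08  # SD of precision off-diagonal perturbation
    mean_heterogeneity: float = 0.4  # SD of physician-level item means
    item_mean_range: tuple[float, float] = (2.8, 4.2)
    perturb_all_offdiag: bool = False  # else perturb the support only
    diag_range: tuple[float, float] = (0.7, 1.5)  # item conditional precisions
    eig_floor: float = 0.05
    max_repair_retries: int = 50
    n_recorded: int = 24
    instrument_coverage: dict[str, int] = field(
        default_factory=lambda: {"OPTION-12": 22, "OPTION-5": 24, "4HCS": 22}
    )
    n_observer_consultations: int = 3
    observer_intercepts: dict[str, float] = field(
        default_factory=lambda: {"OPTION-12": 30.0, "OPTION-5": 25.0, "4HCS": 40.0}
    )
    observer_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "OPTION-12": {"6:activation": 12.0, "7:outstrength": -5.0, "1:activation": 3.0},
            "OPTION-5": {"6:activation": 15.0, "6:instrength": 3.0},
            "4HCS": {"6:outstrength": 5.0, "6:activation": 6.0, "1:instrength": 2.0},
        }
    )
    observer_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"OPTION-12": 8.0, "OPTION-5": 8.0, "4HCS": 8.0}
    )


@dataclass
class TrueModel:
    """Ground truth of one synthetic study."""

    n_physicians: int
    n_skills: int
    population_precision: np.ndarray  # (K, K)
    physician_precisions: np.ndarray  # (P, K, K)
    item_means: np.ndarray  # (K,)
    physician_means: np.ndarray  # (P, K)
    observer_intercepts: dict[str, float]
    observer_effects: dict[str, dict[str, float]]
    observer_noise_sd: dict[str, float]
    recorded_physicians: list[str]
    instrument_physicians: dict[str, list[str]]
    seed: int

    @property
    def physician_ids(self) -> list[str]:
        return [f"phys_{p + 1:02d}" for p in range(self.n_physicians)]

    def validate(self) -> None:
        for name, mat in [("population", self.population_precision)] + [
            (f"physician {p}", self.physician_precisions[p])
            for p in range(self.n_physicians)
        ]:
            if not np.allclose(mat, mat.T):
                raise ValueError(f"{name} precision not symmetric")
            eig = np.linalg.eigvalsh(mat)
            if eig.min() <= 0:
                raise ValueError(f"{name} precision not positive definite")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_physicians": self.n_physicians,
            "n_skills": self.n_skills,
            "population_precision": self.population_precision.tolist(),
            "physician_precisions": self.physician_precisions.tolist(),
            "item_means": self.item_means.tolist(),
            "physician_means": self.physician_means.tolist(),
            "observer_intercepts": self.observer_intercepts,
            "observer_effects": self.observer_effects,
            "observer_noise_sd": self.observer_noise_sd,
            "recorded_physicians": self.recorded_physicians,
            "instrument_physicians": self.instrument_physicians,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrueModel":
        d = json.loads(Path(path).read_text())
        return cls(
            n_physicians=d["n_physicians"],
            n_skills=d["n_skills"],
            population_precision=np.array(d["population_precision"]),
            physician_precisions=np.array(d["physician_precisions"]),
            item_means=np.array(d["item_means"]),
            physician_means=np.array(d["physician_means"]),
            observer_intercepts=d["observer_intercepts"],
            observer_effects=d["observer_effects"],
            observer_noise_sd=d["observer_noise_sd"],
            recorded_physicians=d["recorded_physicians"],
            instrument_physicians=d["instrument_physicians"],
            seed=d["seed"],
        )


def true_edge_weights(precision: np.ndarray) -> np.ndarray:
    """Directed edge weights implied by a precision matrix.

    Returns W with ``W[k, j] = -omega_jk / omega_jj`` (edge k -> j, i.e. the
    coefficient of predictor k in the conditional regression for outcome j);
    the diagonal is zero. Note k->j and j->k generally differ.
    """
    omega = np.asarray(precision, dtype=float)
    W = -omega / np.diag(omega)[None, :]
    np.fill_diagonal(W, 0.0)
    return W


def _repair_spd(mat: np.ndarray, base: np.ndarray, floor: float, retries: int) -> np.ndarray:
    """Shrink the perturbation (mat - base) toward base until SPD."""
    cur = mat.copy()
    for _ in range(retries):
        if np.linalg.eigvalsh(cur).min() > floor:
            return cur
        cur = base + 0.7 * (cur - base)
    if np.linalg.eigvalsh(cur).min() > floor:
        return cur
    raise ValueError(
        "could not repair precision matrix to positive definiteness; "
        "reduce heterogeneity or sparsify the structure"
    )


def sample_true_model(config: GeneratorConfig, seed: int) -> TrueModel:
    """Draw a ground-truth model: population structure, physician
    precisions and means, observer-score coefficients.

    Deterministic given (config, seed); heterogeneity 0 yields identical
    physician precisions.
    """
    rng = np.random.default_rng(seed)
    K = config.n_skills

    if config.structure == "study":
        if K != N_SKILLS:
            raise ValueError("study structure requires 9 skills")
        partials = study_structure_partials()
    elif config.structure == "random":
        lo, hi = config.partial_range
        partials = np.zeros((K, K))
        iu = np.triu_indices(K, 1)
        present = rng.random(len(iu[0])) >= config.sparsity
        vals = rng.uniform(lo, hi, len(iu[0])) * rng.choice([-1.0, 1.0], len(iu[0]))
        # Negative partial correlations are allowed but kept in the minority,
        # as questionnaire items are predominantly positively associated.
        vals = np.where(rng.random(len(vals)) < 0.8, np.abs(vals), vals)
        partials = np.zeros((K, K))
        partials[iu] = np.where(present, vals, 0.0)
        partials = partials + partials.T
    else:
        raise ValueError(f"unknown structure {config.structure!r}")

    # Precision built from partial correlations (omega_jk proportional to
    # -rho_jk) with item-specific conditional precisions on the diagonal:
    # unequal diagonals make the k->j and j->k conditional coefficients
    # genuinely asymmetric, as they are for real questionnaire items.
    lo_d, hi_d = config.diag_range
    root = np.sqrt(rng.uniform(lo_d, hi_d, K))
    base = _repair_spd(
        np.eye(K) - partials, np.eye(K), config.eig_floor, config.max_repair_retries
    )
    pop = root[:, None] * base * root[None, :]

    phys = np.empty((config.n_physicians, K, K))
    support = (pop != 0) & ~np.eye(K, dtype=bool)
    phys_floor = min(config.eig_floor, 0.5 * float(np.linalg.eigvalsh(pop).min()))
    for p in range(config.n_physicians):
        if config.heterogeneity == 0:
            phys[p] = pop
            continue
        noise = rng.normal(0.0, config.heterogeneity, (K, K))
        noise = (noise + noise.T) / 2.0
        np.fill_diagonal(noise, 0.0)
        if not config.perturb_all_offdiag:
            noise = np.where(support, noise, 0.0)
        # mild physician-specific variation in the item conditional
        # precisions; without it, single-neighbour skills would have
        # exactly proportional true in- and outstrength across physicians
        diag_jitter = np.exp(rng.normal(0.0, 0.5 * config.heterogeneity, K))
        np.fill_diagonal(noise, np.diag(pop) * (diag_jitter - 1.0))
        phys[p] = _repair_spd(
            pop + noise, pop, phys_floor, config.max_repair_retries
        )

    lo, hi = config.item_mean_range
    item_means = rng.uniform(lo, hi, K)
    physician_means = item_means[None, :] + rng.normal(
        0.0, config.mean_heterogeneity, (config.n_physicians, K)
    )
    physician_means = np.clip(physician_means, RATING_MIN, RATING_MAX)

    ids = [f"phys_{p + 1:02d}" for p in range(config.n_physicians)]
    n_rec = min(config.n_recorded, config.n_physicians)
    recorded = sorted(rng.choice(ids, size=n_rec, replace=False).tolist())
    instrument_physicians = {}
    for inst in INSTRUMENTS:
        cov = min(config.instrument_coverage.get(inst, n_rec), n_rec)
        instrument_physicians[inst] = sorted(
            rng.choice(recorded, size=cov, replace=False).tolist()
        )

    model = TrueModel(
        n_physicians=config.n_physicians,
        n_skills=K,
        population_precision=pop,
        physician_precisions=phys,
        item_means=item_means,
        physician_means=physician_means,
        observer_intercepts=dict(config.observer_intercepts),
        observer_effects={k: dict(v) for k, v in config.observer_effects.items()},
        observer_noise_sd=dict(config.observer_noise_sd),
        recorded_physicians=recorded,
        instrument_physicians=instrument_physicians,
        seed=seed,
    )
    model.validate()
    return model


def simulate_ratings(
    model: TrueModel,
    consultations_per_physician: int | list[int] | np.ndarray = 11,
    discretize: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw consultation-level skill ratings.

    Each consultation row is a draw from the physician's multivariate
    Gaussian (mean = physician item means, covariance = inverse precision).
    In discretize mode values are clipped to [0, 5] and rounded to the
    Likert grid; continuous mode is kept for exact-recovery tests.
    """
    rng = np.random.default_rng(seed)
    P = model.n_physicians
    counts = np.broadcast_to(np.asarray(consultations_per_physician), (P,))
    if (counts < 1).any():
        raise ValueError("every physician needs at least one consultation")

    rows = []
    for p, pid in enumerate(model.physician_ids):
        cov = np.linalg.inv(model.physician_precisions[p])
        draws = rng.multivariate_normal(
            model.physician_means[p], cov, size=int(counts[p]), method="cholesky"
        )
        if discretize:
            draws = np.clip(np.rint(np.clip(draws, RATING_MIN, RATING_MAX)), 0, 5)
        for c in range(int(counts[p])):
            rows.append([pid, f"cons_{c + 1:03d}", *draws[c]])
    return pd.DataFrame(
        rows, columns=["physician_id", "consultation_id", *SKILL_COLUMNS]
    )


def inject_missingness(
    ratings: pd.DataFrame, item_missing_rate: float, seed: int = 0
) -> pd.DataFrame:
    """Set each skill cell to missing independently with the given rate."""
    if not 0.0 <= item_missing_rate < 1.0:
        raise ValueError("item_missing_rate must be in [0, 1)")
    out = ratings.copy()
    if item_missing_rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random((len(out), len(SKILL_COLUMNS))) < item_missing_rate
    vals = out[SKILL_COLUMNS].to_numpy(dtype=float)
    vals[mask] = np.nan
    out[SKILL_COLUMNS] = vals
    return out


def true_network_parameters(model: TrueModel) -> pd.DataFrame:
    """Ground-truth per-physician network parameters.

    Activation is the physician's true item mean; in/outstrength sum the
    true (unpruned) directed edge weights of the physician's precision.
    """
    rows = {}
    for p, pid in enumerate(model.physician_ids):
        W = true_edge_weights(model.physician_precisions[p])
        row = {}
        for j in range(model.n_skills):
            row[f"skill{j + 1}_activation"] = model.physician_means[p, j]
            row[f"skill{j + 1}_instrength"] = W[:, j].sum()
            row[f"skill{j + 1}_outstrength"] = W[j, :].sum()
        rows[pid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "physician_id"
    return df


def _linear_predictor(
    model: TrueModel, params: pd.DataFrame, instrument: str
) -> pd.Series:
    lin = pd.Series(model.observer_intercepts[instrument], index=params.index)
    for key, coef in model.observer_effects.get(instrument, {}).items():
        skill, ptype = key.split(":")
        if ptype not in PARAM_TYPES:
            raise ValueError(f"unknown parameter type {ptype!r}")
        lin = lin + coef * params[f"skill{int(skill)}_{ptype}"]
    return lin


def simulate_observer_scores(
    model: TrueModel,
    true_params: pd.DataFrame | None = None,
    seed: int = 0,
    n_consultations: int = 3,
) -> pd.DataFrame:
    """Generate observer-rated competence scores on the 0-100 scale.

    For each instrument and each covered physician,
    ``score = intercept + sum(coef * true parameter) + noise``, clipped to
    [0, 100], once per rated consultation.
    """
    if true_params is None:
        true_params = true_network_parameters(model)
    rng = np.random.default_rng(seed)
    rows = []
    for inst in model.instrument_physicians:
        covered = model.instrument_physicians[inst]
        lin = _linear_predictor(model, true_params.loc[covered], inst)
        sd = model.observer_noise_sd.get(inst, 0.0)
        for pid in covered:
            for c in range(n_consultations):
                score = lin[pid] + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                rows.append([pid, f"rec_{c + 1:02d}", inst, float(np.clip(score, 0.0, 100.0))])
    return pd.DataFrame(
        rows, columns=["physician_id", "consultation_id", "instrument", "score"]
    )
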