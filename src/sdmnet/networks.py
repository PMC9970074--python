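"""Directed skills networks from coefficient posteriors.

Each physician's network is a directed weighted 9-node graph: the edge
k -> j carries that physician's posterior-mean coefficient of predictor
skill k in the node-wise model for outcome skill j. Edges whose 95%
equal-tailed credible interval includes zero are pruned to avoid
spurious associations. Three node parameters are derived per skill:

* activation — the physician's mean rating of the skill across their
  consultations;
* outstrength — sum of the retained outgoing edge weights (how strongly
  the skill influences other skills);
* instrength — sum of the retained incoming edge weights (how strongly
  the skill is influenced by other skills).

A population network uses the population-level (fixed-effect) posterior
means and credible intervals, with activation averaged across physicians
with equal weight. Node positions come from the Fruchterman-Reingold
force-directed layout with absolute edge weights as attraction strengths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .estimation import NodewiseFit
from .skills import N_SKILLS, SKILL_NAMES, skill_column

__all__ = [
    "SkillsNetwork",
    "prune_edges",
    "build_physician_network",
    "build_population_network",
    "layout_network",
    "export_network",
    "import_network",
]


def prune_edges(draws: np.ndarray, level: float = 0.95) -> np.ndarray | bool:
    """Edge retention by equal-tailed credible interval.

    ``draws`` holds the posterior sample along the last axis; an edge is
    retained iff the equal-tailed interval at ``level`` excludes zero
    (empirical quantiles). Returns a boolean with the leading shape of
    ``draws``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    draws = np.asarray(draws, dtype=float)
    if draws.shape[-1] < 500:
        raise ValueError("need at least 500 draws per edge for stable intervals")
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(draws, alpha, axis=-1)
    hi = np.quantile(draws, 1.0 - alpha, axis=-1)
    retained = (lo > 0.0) | (hi < 0.0)
    return retained if retained.ndim else bool(retained)


def _ci_bounds(draws: np.ndarray, level: float) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(draws, alpha)), float(np.quantile(draws, 1.0 - alpha))


@dataclass
class SkillsNetwork:
    """A directed weighted 9-node skills network.

    ``weights[k-1, j-1]`` is the k -> j edge weight (posterior mean);
    ``mask`` marks retained edges after credible-interval pruning; the
    diagonal is undefined and kept at zero/False. Strength vectors are
    computed from retained edges only; raw (unpruned) strengths are kept
    for sensitivity analyses.
    """

    label: str  # physician id or "population"
    weights: np.ndarray  # (9, 9)
    mask: np.ndarray  # (9, 9) bool
    ci_low: np.ndarray
    ci_high: np.ndarray
    activation: np.ndarray  # (9,)
    level: float
    coordinates: np.ndarray | None = None  # (9, 2)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        np.fill_diagonal(self.weights, 0.0)
        np.fill_diagonal(self.mask, False)

    @property
    def retained_weights(self) -> np.ndarray:
        return np.where(self.mask, self.weights, 0.0)

    @property
    def outstrength(self) -> np.ndarray:
        """o_k = sum over j of retained W[k -> j].

        Accumulated in plain index order so a brute-force re-summation
        reproduces the stored values bit for bit.
        """
        W = self.retained_weights
        out = np.zeros(W.shape[0])
        for k in range(W.shape[0]):
            acc = 0.0
            for j in range(W.shape[1]):
                acc += W[k, j]
            out[k] = acc
        return out

    @property
    def instrength(self) -> np.ndarray:
        """i_j = sum over k of retained W[k -> j]."""
        W = self.retained_weights
        out = np.zeros(W.shape[1])
        for j in range(W.shape[1]):
            acc = 0.0
            for k in range(W.shape[0]):
                acc += W[k, j]
            out[j] = acc
        return out

    @property
    def raw_outstrength(self) -> np.ndarray:
        W = self.weights.copy()
        np.fill_diagonal(W, 0.0)
        return W.sum(axis=1)

    @property
    def raw_instrength(self) -> np.ndarray:
        W = self.weights.copy()
        np.fill_diagonal(W, 0.0)
        return W.sum(axis=0)

    def parameters(self) -> pd.DataFrame:
        """Per-skill activation / instrength / outstrength table."""
        return pd.DataFrame(
            {
                "skill": np.arange(1, N_SKILLS + 1),
                "name": [SKILL_NAMES[j] for j in range(1, N_SKILLS + 1)],
                "activation": self.activation,
                "instrength": self.instrength,
                "outstrength": self.outstrength,
            }
        )

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph(label=self.label, level=self.level)
        for j in range(1, N_SKILLS + 1):
            attrs = {"label": SKILL_NAMES[j], "activation": float(self.activation[j - 1])}
            if self.coordinates is not None:
                attrs["x"] = float(self.coordinates[j - 1, 0])
                attrs["y"] = float(self.coordinates[j - 1, 1])
            g.add_node(j, **attrs)
        for k in range(1, N_SKILLS + 1):
            for j in range(1, N_SKILLS + 1):
                if k == j:
                    continue
                g.add_edge(
                    k,
                    j,
                    weight=float(self.weights[k - 1, j - 1]),
                    retained=bool(self.mask[k - 1, j - 1]),
                    ci_low=float(self.ci_low[k - 1, j - 1]),
                    ci_high=float(self.ci_high[k - 1, j - 1]),
                )
        return g


def _assemble(
    fits: dict[int, NodewiseFit],
    slope_draws: "callable",
    level: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    W = np.zeros((N_SKILLS, N_SKILLS))
    mask = np.zeros((N_SKILLS, N_SKILLS), dtype=bool)
    lo = np.zeros((N_SKILLS, N_SKILLS))
    hi = np.zeros((N_SKILLS, N_SKILLS))
    for j, fit in fits.items():
        for k in fit.predictor_skills:
            d = slope_draws(fit, k)
            W[k - 1, j - 1] = d.mean()
            lo[k - 1, j - 1], hi[k - 1, j - 1] = _ci_bounds(d, level)
            mask[k - 1, j - 1] = prune_edges(d, level)
    return W, mask, lo, hi


def build_physician_network(
    fits: dict[int, NodewiseFit],
    ratings: pd.DataFrame,
    physician_id: str,
    level: float = 0.95,
) -> SkillsNetwork:
    """One physician's network from their coefficient posteriors.

    Pruning uses the physician-specific draws (population + deviation per
    iteration); activation is the physician's mean post-imputation rating
    per skill.
    """
    if len(fits) != N_SKILLS:
        raise ValueError("need all nine node-wise fits")
    own = ratings.loc[ratings["physician_id"].astype(str) == str(physician_id)]
    if own.empty:
        raise ValueError(f"physician {physician_id!r} absent from ratings")
    for fit in fits.values():
        if str(physician_id) not in fit.physician_ids:
            raise ValueError(f"physician {physician_id!r} absent from fit {fit.outcome_skill}")

    W, mask, lo, hi = _assemble(
        fits, lambda fit, k: fit.physician_slope_draws(str(physician_id), k), level
    )
    activation = np.array(
        [own[skill_column(j)].mean() for j in range(1, N_SKILLS + 1)]
    )
    return SkillsNetwork(
        label=str(physician_id),
        weights=W,
        mask=mask,
        ci_low=lo,
        ci_high=hi,
        activation=activation,
        level=level,
        meta={"kind": "physician", "n_consultations": int(len(own))},
    )


def build_population_network(
    fits: dict[int, NodewiseFit],
    ratings: pd.DataFrame,
    level: float = 0.95,
) -> SkillsNetwork:
    """Population network from the fixed-effect posteriors.

    Edge weights and pruning come from the population-level coefficient
    draws; activation is the mean over physicians of each physician's
    mean rating (equal weight per physician, not per consultation).
    """
    if len(fits) != N_SKILLS:
        raise ValueError("need all nine node-wise fits")
    W, mask, lo, hi = _assemble(
        fits, lambda fit, k: fit.population_slope_draws(k), level
    )
    per_phys = ratings.groupby(ratings["physician_id"].astype(str))[
        [skill_column(j) for j in range(1, N_SKILLS + 1)]
    ].mean()
    activation = per_phys.mean(axis=0).to_numpy()
    return SkillsNetwork(
        label="population",
        weights=W,
        mask=mask,
        ci_low=lo,
        ci_high=hi,
        activation=activation,
        level=level,
        meta={"kind": "population", "n_physicians": int(per_phys.shape[0])},
    )


def average_physician_network(
    networks: list[SkillsNetwork], level: float = 0.95
) -> SkillsNetwork:
    """Alternative population summary: the element-wise mean of physician
    networks (weights averaged over physicians; an edge is retained when
    it is retained for a majority of physicians)."""
    W = np.mean([n.weights for n in networks], axis=0)
    mask = np.mean([n.mask for n in networks], axis=0) > 0.5
    lo = np.mean([n.ci_low for n in networks], axis=0)
    hi = np.mean([n.ci_high for n in networks], axis=0)
    activation = np.mean([n.activation for n in networks], axis=0)
    return SkillsNetwork(
        label="population_mean_of_physicians",
        weights=W,
        mask=mask,
        ci_low=lo,
        ci_high=hi,
        activation=activation,
        level=level,
        meta={"kind": "population_average", "n_physicians": len(networks)},
    )


def layout_network(network: SkillsNetwork, seed: int = 0) -> np.ndarray:
    """Fruchterman-Reingold node coordinates, deterministic given seed.

    Absolute retained edge weights act as attraction strengths, so
    strongly associated skills are placed close together.
    """
    g = nx.Graph()
    g.add_nodes_from(range(1, N_SKILLS + 1))
    absw = np.abs(network.retained_weights)
    for k in range(1, N_SKILLS + 1):
        for j in range(1, N_SKILLS + 1):
            if k < j and (absw[k - 1, j - 1] > 0 or absw[j - 1, k - 1] > 0):
                g.add_edge(k, j, weight=float(absw[k - 1, j - 1] + absw[j - 1, k - 1]))
    pos = nx.spring_layout(g, weight="weight", seed=seed)
    coords = np.array([pos[j] for j in range(1, N_SKILLS + 1)])
    network.coordinates = coords
    return coords


def export_network(
    network: SkillsNetwork, path: str | Path, format: str = "json"
) -> Path:
    """Write a network to disk.

    ``json`` is the lossless bundle (weights, mask, CIs, activation,
    coordinates, metadata); ``graphml`` embeds node/edge attributes via
    networkx; ``csv`` is an edge list of the retained edges only.
    """
    path = Path(path)
    if format == "json":
        payload = {
            "label": network.label,
            "level": network.level,
            "weights": network.weights.tolist(),
            "mask": network.mask.tolist(),
            "ci_low": network.ci_low.tolist(),
            "ci_high": network.ci_high.tolist(),
            "activation": network.activation.tolist(),
            "coordinates": None
            if network.coordinates is None
            else network.coordinates.tolist(),
            "meta": network.meta,
            "skill_names": {str(j): SKILL_NAMES[j] for j in range(1, N_SKILLS + 1)},
        }
        path.write_text(json.dumps(payload, indent=1))
    elif format == "graphml":
        nx.write_graphml(network.to_graph(), path)
    elif format == "csv":
        rows = []
        for k in range(1, N_SKILLS + 1):
            for j in range(1, N_SKILLS + 1):
                if k != j and network.mask[k - 1, j - 1]:
                    rows.append(
                        {
                            "source_skill": k,
                            "target_skill": j,
                            "weight": network.weights[k - 1, j - 1],
                            "retained": True,
                            "ci_low": network.ci_low[k - 1, j - 1],
                            "ci_high": network.ci_high[k - 1, j - 1],
                        }
                    )
        pd.DataFrame(
            rows,
            columns=[
                "source_skill",
                "target_skill",
                "weight",
                "retained",
                "ci_low",
                "ci_high",
            ],
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def import_network(path: str | Path, format: str = "json") -> SkillsNetwork:
    """Read a network back; ``json`` and ``graphml`` round-trip losslessly
    (graphml does not carry activation-free metadata beyond attributes)."""
    path = Path(path)
    if format == "json":
        d = json.loads(path.read_text())
        return SkillsNetwork(
            label=d["label"],
            weights=np.array(d["weights"]),
            mask=np.array(d["mask"], dtype=bool),
            ci_low=np.array(d["ci_low"]),
            ci_high=np.array(d["ci_high"]),
            activation=np.array(d["activation"]),
            level=d["level"],
            coordinates=None if d["coordinates"] is None else np.array(d["coordinates"]),
            meta=d.get("meta", {}),
        )
    if format == "graphml":
        g = nx.read_graphml(path)
        K = N_SKILLS
        W = np.zeros((K, K))
        mask = np.zeros((K, K), dtype=bool)
        lo = np.zeros((K, K))
        hi = np.zeros((K, K))
        activation = np.zeros(K)
        coords = np.zeros((K, 2))
        has_coords = True
        for node, attrs in g.nodes(data=True):
            j = int(node)
            activation[j - 1] = attrs["activation"]
            if "x" in attrs:
                coords[j - 1] = (attrs["x"], attrs["y"])
            else:
                has_coords = False
        for u, v, attrs in g.edges(data=True):
            k, j = int(u), int(v)
            W[k - 1, j - 1] = attrs["weight"]
            mask[k - 1, j - 1] = bool(attrs["retained"])
            lo[k - 1, j - 1] = attrs["ci_low"]
            hi[k - 1, j - 1] = attrs["ci_high"]
        return SkillsNetwork(
            label=g.graph.get("label", path.stem),
            weights=W,
            mask=mask,
            ci_low=lo,
            ci_high=hi,
            activation=activation,
            level=float(g.graph.get("level", 0.95)),
            coordinates=coords if has_coords else None,
        )
    raise ValueError(f"unknown import format {format!r}")
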