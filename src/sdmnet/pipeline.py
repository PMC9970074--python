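"""End-to-end orchestration with file handoffs between stages.

Stages (mirroring the CLI subcommands):

* ``simulate``      — synthetic study: ratings CSV, observer CSV, truth JSON
* ``fit-networks``  — preprocessing, nine node-wise fits, physician and
                      population networks, convergence report
* ``predict``       — confirmatory and exploratory competence prediction
                      reports plus calibration pairs
* ``report``        — calibration and network figures

Each stage writes a manifest (config hash, seeds, package versions) so a
run can be reproduced exactly; identical config and seeds produce
identical output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimation import McmcConfig, PriorSpec, check_convergence, fit_all_nodes
from .networks import (
    SkillsNetwork,
    build_physician_network,
    build_population_network,
    export_network,
    import_network,
    layout_network,
)
from .prediction import (
    CONFIRMATORY_SKILLS,
    PredictionFit,
    calibration_pairs,
    confirmatory_model,
    exploratory_procedure,
)
from .preprocessing import (
    aggregate_observer,
    filter_missing,
    impute_em,
    load_observer,
    load_ratings,
    rescale_score,
    save_ratings,
)
from .skills import INSTRUMENTS, PARAM_TYPES
from .synthetic import (
    GeneratorConfig,
    inject_missingness,
    sample_true_model,
    simulate_observer_scores,
    simulate_ratings,
)

__all__ = [
    "PipelineConfig",
    "default_config",
    "run_simulate",
    "run_fit_networks",
    "run_predict",
    "run_report",
]

log = logging.getLogger(__name__)

_DEFAULTS: dict[str, Any] = {
    "output_dir": "sdmnet_output",
    "seed": 2023,
    "ratings_path": None,  # default: <output_dir>/ratings.csv
    "observer_path": None,  # default: <output_dir>/observer.csv
    "prior_file": None,
    "prune_level": 0.95,
    "confirmatory_skills": list(CONFIRMATORY_SKILLS),
    "instruments": {inst: {"min": 0.0, "max": 100.0} for inst in INSTRUMENTS},
    "missing": {"item_missing_rate": 0.02, "em_tol": 1e-6, "em_max_iter": 500},
    "mcmc": {
        "n_chains": 4,
        "iterations": 8000,
        "burn_in": 3000,
        "thinning": 10,
    },
    "simulate": {
        "n_physicians": 28,
        "consultations_per_physician": 11,
        "structure": "study",
        "heterogeneity": 0.08,
        "mean_heterogeneity": 0.4,
        "discretize": True,
        "n_observer_consultations": 3,
    },
    "fail_on_nonconvergence": False,
    "rhat_threshold": 1.05,
}


class PipelineConfig(dict):
    """Validated pipeline configuration (a dict with defaults filled in)."""

    @classmethod
    def from_mapping(cls, raw: dict[str, Any]) -> "PipelineConfig":
        cfg = cls(json.loads(json.dumps(_DEFAULTS)))
        for key, value in raw.items():
            if key not in _DEFAULTS:
                raise ValueError(f"unknown configuration key: {key!r}")
            if isinstance(value, dict) and isinstance(cfg[key], dict):
                for sub, sval in value.items():
                    if key != "instruments" and sub not in cfg[key]:
                        raise ValueError(f"unknown configuration key: {key}.{sub}")
                    cfg[key][sub] = sval
            else:
                cfg[key] = value
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_mapping(raw)

    @property
    def output_dir(self) -> Path:
        out = Path(self["output_dir"])
        out.mkdir(parents=True, exist_ok=True)
        return out

    def path(self, key: str, default_name: str) -> Path:
        return Path(self[key]) if self[key] else self.output_dir / default_name

    def mcmc_config(self, offset: int = 0) -> McmcConfig:
        sub = np.random.SeedSequence(int(self["seed"])).generate_state(offset + 1)
        return McmcConfig(seed=int(sub[offset] % (2**31)), **self["mcmc"])

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self, sort_keys=True, default=str).encode()
        ).hexdigest()


def default_config(**overrides: Any) -> PipelineConfig:
    return PipelineConfig.from_mapping(overrides)


def _write_manifest(cfg: PipelineConfig, stage: str, extra: dict[str, Any]) -> Path:
    manifest = {
        "stage": stage,
        "config_hash": cfg.hash(),
        "seed": cfg["seed"],
        "versions": {
            "sdmnet": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        **extra,
    }
    path = cfg.output_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def run_simulate(cfg: PipelineConfig) -> dict[str, Path]:
    """Generate a synthetic study and write its files."""
    sim = cfg["simulate"]
    gen = GeneratorConfig(
        n_physicians=sim["n_physicians"],
        consultations_per_physician=sim["consultations_per_physician"],
        structure=sim["structure"],
        heterogeneity=sim["heterogeneity"],
        mean_heterogeneity=sim["mean_heterogeneity"],
    )
    seed = int(cfg["seed"])
    model = sample_true_model(gen, seed)
    ratings = simulate_ratings(
        model,
        consultations_per_physician=sim["consultations_per_physician"],
        discretize=sim["discretize"],
        seed=seed + 1,
    )
    rate = float(cfg["missing"]["item_missing_rate"])
    if rate > 0:
        ratings = inject_missingness(ratings, rate, seed=seed + 2)
    observer = simulate_observer_scores(
        model, seed=seed + 3, n_consultations=sim["n_observer_consultations"]
    )

    out = cfg.output_dir
    paths = {
        "ratings": cfg.path("ratings_path", "ratings.csv"),
        "observer": cfg.path("observer_path", "observer.csv"),
        "true_model": out / "true_model.json",
    }
    save_ratings(ratings, paths["ratings"])
    observer.to_csv(paths["observer"], index=False)
    model.to_json(paths["true_model"])
    _write_manifest(
        cfg,
        "simulate",
        {
            "n_physicians": model.n_physicians,
            "n_consultations": int(len(ratings)),
            "n_observer_rows": int(len(observer)),
        },
    )
    return paths


def run_fit_networks(
    cfg: PipelineConfig,
    priors: PriorSpec | None = None,
) -> dict[str, Any]:
    """Preprocess ratings, fit the nine node-wise models, build networks."""
    ratings = load_ratings(cfg.path("ratings_path", "ratings.csv"))
    kept, report = filter_missing(ratings)
    for _, row in report.excluded.iterrows():
        log.info(
            "excluded consultation (%s, %s): %d missing skills",
            row["physician_id"],
            row["consultation_id"],
            row["n_missing"],
        )
    imputation = impute_em(
        kept,
        tol=float(cfg["missing"]["em_tol"]),
        max_iter=int(cfg["missing"]["em_max_iter"]),
    )
    complete = imputation.ratings

    out = cfg.output_dir
    report.excluded.to_csv(out / "excluded_consultations.csv", index=False)
    save_ratings(complete, out / "ratings_imputed.csv")

    fits = fit_all_nodes(complete, priors=priors, mcmc=cfg.mcmc_config())
    conv_rows = []
    all_converged = True
    for j, fit in fits.items():
        rep = check_convergence(fit, threshold=float(cfg["rhat_threshold"]))
        all_converged &= rep.converged
        frame = rep.rhat.copy()
        frame.insert(0, "outcome_skill", j)
        conv_rows.append(frame)
    convergence = pd.concat(conv_rows, ignore_index=True)
    convergence.to_csv(out / "convergence.csv", index=False)
    if not all_converged:
        msg = "some parameters exceeded the R-hat threshold (see convergence.csv)"
        if cfg["fail_on_nonconvergence"]:
            raise RuntimeError(msg)
        log.warning(msg)

    level = float(cfg["prune_level"])
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    physician_ids = sorted(complete["physician_id"].astype(str).unique())
    networks: dict[str, SkillsNetwork] = {}
    for pid in physician_ids:
        net = build_physician_network(fits, complete, pid, level=level)
        layout_network(net, seed=int(cfg["seed"]))
        export_network(net, net_dir / f"{pid}.json", "json")
        networks[pid] = net
    population = build_population_network(fits, complete, level=level)
    layout_network(population, seed=int(cfg["seed"]))
    export_network(population, out / "population.json", "json")
    export_network(population, out / "population.graphml", "graphml")
    export_network(population, out / "population_edges.csv", "csv")

    n_pruned = int((~population.mask).sum() - population.mask.shape[0])
    log.info(
        "fit %d physicians, %d consultations; population network retains %d edges",
        len(physician_ids),
        len(complete),
        int(population.mask.sum()),
    )
    _write_manifest(
        cfg,
        "fit_networks",
        {
            "n_physicians": len(physician_ids),
            "n_consultations_kept": report.n_kept,
            "n_consultations_excluded": report.n_excluded,
            "em_iterations": imputation.n_iter,
            "population_retained_edges": int(population.mask.sum()),
            "population_pruned_edges": n_pruned,
            "converged": bool(all_converged),
        },
    )
    return {
        "fits": fits,
        "networks": networks,
        "population": population,
        "exclusions": report,
        "imputation": imputation,
        "convergence": convergence,
    }


def _load_networks(cfg: PipelineConfig) -> dict[str, SkillsNetwork]:
    net_dir = cfg.output_dir / "networks"
    if not net_dir.is_dir():
        raise FileNotFoundError(
            f"{net_dir} not found; run the fit-networks stage first"
        )
    networks = {}
    for path in sorted(net_dir.glob("*.json")):
        net = import_network(path, "json")
        networks[net.label] = net
    return networks


def _competence_scores(cfg: PipelineConfig) -> pd.DataFrame:
    observer = load_observer(cfg.path("observer_path", "observer.csv"))
    if "raw_score" in observer.columns and "score" not in observer.columns:
        ranges = cfg["instruments"]
        scaled = []
        for inst, grp in observer.groupby("instrument"):
            rng = ranges.get(inst, {"min": 0.0, "max": 100.0})
            grp = grp.copy()
            grp["score"] = rescale_score(
                grp["raw_score"].to_numpy(), float(rng["min"]), float(rng["max"])
            )
            scaled.append(grp)
        observer = pd.concat(scaled, ignore_index=True)
    return aggregate_observer(observer)


def _report_order(tab: pd.DataFrame) -> pd.DataFrame:
    """Order coefficient rows type-major (activation, instrength,
    outstrength blocks, skills ascending), intercept first, the way the
    study's tables are laid out."""
    def key(name: str) -> tuple[int, int]:
        if name == "Intercept":
            return (-1, 0)
        skill, ptype = name.split("_")
        return (PARAM_TYPES.index(ptype), int(skill.removeprefix("skill")))

    tab = tab.copy()
    tab["_key"] = tab["predictor"].map(key)
    tab = tab.sort_values("_key").drop(columns="_key").reset_index(drop=True)
    return tab


def _write_fit(out: Path, prefix: str, inst: str, fit: PredictionFit) -> None:
    safe = inst.replace("/", "_")
    _report_order(fit.coefficient_table()).to_csv(
        out / f"{prefix}_{safe}_coefficients.csv", index=False
    )
    fit.fit_statistics().to_csv(out / f"{prefix}_{safe}_fitstats.csv", index=False)
    calibration_pairs(fit).to_csv(out / f"{prefix}_{safe}_calibration.csv", index=False)


def run_predict(
    cfg: PipelineConfig, instruments: tuple[str, ...] | None = None
) -> dict[str, Any]:
    """Confirmatory and exploratory prediction from the network bundle."""
    networks = _load_networks(cfg)
    scores = _competence_scores(cfg)
    scored = scores.index.astype(str)
    networks = {pid: net for pid, net in networks.items() if pid in set(scored)}
    if not networks:
        raise ValueError("no overlap between networks and observer-scored physicians")
    scores = scores.loc[sorted(networks)]

    prior_file = None
    if cfg["prior_file"]:
        prior_file = PriorSpec.from_file(cfg["prior_file"])

    mcmc = cfg.mcmc_config(offset=1)
    insts = instruments or tuple(
        c for c in scores.columns if not str(c).startswith("n_")
    )
    out = cfg.output_dir

    confirmatory = confirmatory_model(
        networks, scores, prior_file=prior_file, mcmc=mcmc, instruments=insts
    )
    for inst, fit in confirmatory.items():
        _write_fit(out, "confirmatory", inst, fit)

    exploratory = exploratory_procedure(
        networks, scores, mcmc=cfg.mcmc_config(offset=2), instruments=insts
    )
    exploratory.stage1_report().to_csv(out / "exploratory_stage1.csv", index=False)
    for inst, fit in exploratory.final.items():
        _write_fit(out, "exploratory", inst, fit)

    _write_manifest(
        cfg,
        "predict",
        {
            "instruments": list(insts),
            "selected_skills": exploratory.selected_skills,
            "n_networks": len(networks),
        },
    )
    return {"confirmatory": confirmatory, "exploratory": exploratory, "scores": scores}


def run_report(cfg: PipelineConfig) -> list[Path]:
    """Static figures: population network and calibration plots."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = cfg.output_dir
    written: list[Path] = []

    pop_path = out / "population.json"
    if pop_path.exists():
        net = import_network(pop_path, "json")
        if net.coordinates is None:
            layout_network(net, seed=int(cfg["seed"]))
        fig, ax = plt.subplots(figsize=(6, 6))
        g = net.to_graph()
        pos = {j: net.coordinates[j - 1] for j in g.nodes}
        retained = [
            (u, v) for u, v, d in g.edges(data=True) if d["retained"]
        ]
        widths = [3.0 * abs(g.edges[e]["weight"]) for e in retained]
        import networkx as nx

        nx.draw_networkx_nodes(
            g, pos, ax=ax, node_size=500, node_color="#c6dbef", edgecolors="k"
        )
        nx.draw_networkx_labels(g, pos, ax=ax, font_size=9)
        nx.draw_networkx_edges(
            g, pos, ax=ax, edgelist=retained, width=widths, arrows=True,
            connectionstyle="arc3,rad=0.08",
        )
        ax.set_title("Population skills network (retained edges)")
        ax.axis("off")
        fig.tight_layout()
        path = out / "population_network.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)

    for cal in sorted(out.glob("*_calibration.csv")):
        pairs = pd.read_csv(cal)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(pairs["predicted"], pairs["observed"], color="k", s=18)
        lims = [
            min(pairs["predicted"].min(), pairs["observed"].min()) - 2,
            max(pairs["predicted"].max(), pairs["observed"].max()) + 2,
        ]
        ax.plot(lims, lims, color="grey", lw=1, ls="--")
        ax.set_xlabel("predicted competence (0-100)")
        ax.set_ylabel("observed competence (0-100)")
        ax.set_title(cal.stem.replace("_calibration", ""))
        fig.tight_layout()
        path = cal.with_suffix(".png")
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)

    _write_manifest(cfg, "report", {"figures": [str(p) for p in written]})
    return written
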