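"""End-to-end orchestration: CLAM -> fit -> predict -> change -> similarity.

``run_all`` reproduces the whole analysis sequence on one set of input
files and writes tidy CSV outputs, the posterior archive, a log file and a
machine-readable manifest.  Species groups used in predictions and
similarities are the CLAM-derived collapsed groups (also fed into the
model's trait matrix) unless an explicit trait table is configured.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clam import clam_from_captures
from .config import RunConfig
from .core_data import (TraitTable, build_model_data, load_capture_table,
                        load_covariates, load_traits,
                        phylo_correlation_from_tree)
from .gibbs import fit as gibbs_fit
from .model import PosteriorSamples
from .prediction import (build_prediction_grid, change_summary,
                         expected_individuals, expected_richness, predict_set)
from .turnover import assemblage_similarity, similarity_increase_probability

__all__ = ["run_all", "predictions_table", "change_table", "similarity_table"]

log = logging.getLogger(__name__)

_PAIRS = (("continuous", "fragment"), ("continuous", "secondary"))


def _groups(traits: TraitTable, species_ids) -> dict[str, list[str]]:
    amap = traits.affinity_map()
    return {
        "all": list(species_ids),
        "specialist": [s for s in species_ids if amap.get(s) == "specialist"],
        "generalist": [s for s in species_ids if amap.get(s) == "generalist"],
    }


def predictions_table(samples: PosteriorSamples, grid, traits: TraitTable,
                      marginal: bool = True) -> pd.DataFrame:
    """Standardized-effort richness and individuals per habitat x period x
    group (the per-visit expectation surface)."""
    groups = _groups(traits, samples.species_ids)
    rows = []
    for r in grid.table.itertuples(index=False):
        pred = predict_set(samples, r._asdict(), marginal=marginal)
        for gname, members in groups.items():
            if not members:
                continue
            rich = expected_richness(pred, members)
            indiv = expected_individuals(pred, members)
            for stat, (mean, sd) in (("richness", rich),
                                     ("individuals", indiv)):
                rows.append({"habitat": r.habitat, "period": r.period,
                             "group": gname, "statistic": stat,
                             "posterior_mean": mean, "posterior_sd": sd})
    return pd.DataFrame(rows)


def change_table(samples: PosteriorSamples, grid,
                 marginal: bool = True) -> pd.DataFrame:
    """Per-species period-2 minus period-1 differences with posterior
    support, for every habitat."""
    out = []
    for habitat in ("continuous", "fragment", "secondary"):
        p1 = predict_set(samples, grid.row(habitat, 1), marginal=marginal)
        p2 = predict_set(samples, grid.row(habitat, 2), marginal=marginal)
        tab = change_summary(p1, p2)
        tab.insert(0, "habitat", habitat)
        out.append(tab)
    return pd.concat(out, ignore_index=True)


def similarity_table(samples: PosteriorSamples, grid, traits: TraitTable,
                     marginal: bool = True, per_draw: bool = True,
                     floor: float = 1e-12) -> pd.DataFrame:
    """Assemblage similarity between continuous forest and each modified
    habitat, per period, with the posterior probability that similarity was
    lower in period 1 than in period 2."""
    groups = _groups(traits, samples.species_ids)
    preds = {(h, p): predict_set(samples, grid.row(h, p), marginal=marginal)
             for h in ("continuous", "fragment", "secondary")
             for p in (1, 2)}
    rows = []
    for gname, members in groups.items():
        if len(members) < 3:
            continue
        for ref, other in _PAIRS:
            for scale in ("occupancy", "abundance"):
                sims = {}
                for period in (1, 2):
                    sims[period] = assemblage_similarity(
                        preds[(ref, period)], preds[(other, period)],
                        scale=scale, species_subset=members, floor=floor,
                        posterior_mean_inputs=not per_draw,
                        labels=(f"{ref}-P{period}", f"{other}-P{period}"))
                rows.append({
                    "group": gname, "pair": f"{ref}:{other}", "scale": scale,
                    "sim_period1": sims[1].posterior_mean,
                    "sim_period2": sims[2].posterior_mean,
                    "prob_increase": similarity_increase_probability(
                        sims[1], sims[2]),
                })
    return pd.DataFrame(rows)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> Path:
    """Execute every pipeline stage; returns the artifact directory.

    Any stage failure aborts with the stage name prepended to the message.
    """
    config.require_paths()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("batjsdm")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t_start = time.time()
    stage = "load"
    try:
        captures = load_capture_table(config.captures,
                                      species_filter=config.species_filter)
        covars = load_covariates(config.covariates)
        phylo = phylo_correlation_from_tree(Path(config.tree).read_text())
        log.info("loaded %d sessions, %d species", captures.n_sessions,
                 len(captures.species_ids))

        stage = "clam"
        clam = clam_from_captures(captures, covars, K=config.clam_K,
                                  alpha=config.clam_alpha,
                                  coverage_limit=config.clam_coverage_limit)
        clam.to_frame().to_csv(out / "clam.csv", index=False)
        log.info("CLAM groups: %s", clam.group_sizes())
        if config.traits:
            traits = load_traits(config.traits)
        else:
            traits = TraitTable(pd.DataFrame({
                "species_id": clam.species_ids,
                "affinity": clam.collapsed}))

        stage = "fit"
        data = build_model_data(captures, covars, traits, phylo)
        spec = config.model_spec()

        def progress(it, info):
            log.info("sweep %d: rho1=%.2f rho2=%.2f |lambda1|=%.2f "
                     "|lambda2|=%.2f", it, info["rho1"], info["rho2"],
                     info["lambda1_norm"], info["lambda2_norm"])

        samples = gibbs_fit(data, spec, progress=progress)
        samples.save(out / "posterior.npz", out / "posterior.json")

        stage = "predict"
        grid = build_prediction_grid(covars, captures.sessions)
        grid.table.to_csv(out / "prediction_grid.csv", index=False)
        predictions_table(samples, grid, traits,
                          marginal=config.marginal_predictions
                          ).to_csv(out / "predictions.csv", index=False)

        stage = "change"
        change_table(samples, grid,
                     marginal=config.marginal_predictions
                     ).to_csv(out / "change.csv", index=False)

        stage = "similarity"
        similarity_table(samples, grid, traits,
                         marginal=config.marginal_predictions,
                         per_draw=config.similarity_per_draw,
                         floor=config.similarity_floor
                         ).to_csv(out / "similarity.csv", index=False)

        stage = "manifest"
        outputs = ["clam.csv", "posterior.npz", "prediction_grid.csv",
                   "predictions.csv", "change.csv", "similarity.csv"]
        manifest = {
            "package": "batjsdm",
            "version": __version__,
            "seed": config.seed,
            "spec_hash": spec.spec_hash(),
            "config": config.to_jsonable(),
            "outputs": {name: _file_hash(out / name) for name in outputs},
            "elapsed_s": round(time.time() - t_start, 1),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
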