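"""End-to-end orchestration: survey file in, report bundle out.

``run`` reads and validates a survey, builds the nine network layers
(seven trust dimensions, combined trust, collaboration), and writes:

* ``nets/<layer>.csv`` — nine weighted edge lists;
* ``pearson_r.csv`` / ``pearson_p.csv`` — the survey-item correlation matrix;
* ``measures.csv`` — the network-level statistic battery, one row per layer;
* ``envelopes.csv`` — observed value vs 95% null envelope for every
  (layer, measure, null model) triple;
* ``rank_correlations.csv`` — top-k Spearman agreement of weighted
  in-degree and betweenness rankings between trust layers;
* ``manifest.json`` — seed, configuration hash and package version, so any
  number in the bundle can be recomputed by calling the underlying
  operation directly.

The run is deterministic under its master seed.  Any stage failure aborts
the run with the stage name; partially written outputs are removed.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .correlations import dyad_matrix, pearson_matrix, top_k_spearman
from .layers import (
    COLLABORATION_LABEL,
    COMBINED_LABEL,
    DIMENSION_LABELS,
    build_all_layers,
    write_edgelist,
)
from .metrics import all_weighted_in_degrees, betweenness, measure_table
from .nulls import MODELS, NullConfig, envelope
from .survey import node_universe, read_roster, read_survey

log = logging.getLogger("trustnet")

TRUST_LAYER_LABELS = DIMENSION_LABELS + (COMBINED_LABEL,)


@dataclass(frozen=True)
class RunConfig:
    """Settings for one full analysis run."""

    survey: str
    out_dir: str
    roster: str | None = None  # full member list; keeps non-respondent isolates
    seed: int = 0
    null_models: tuple[str, ...] = MODELS
    null_iterations: int = 1000
    rank_k: int = 20
    lenient_missing: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "null_models" in raw:
            raw["null_models"] = tuple(raw["null_models"])
        return cls(**raw)


class PipelineError(RuntimeError):
    """A stage of the analysis failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _float_csv(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, float_format="%.10g", **kw)
    return path


def run(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the paths of every artifact."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    artifacts: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "read_survey"
        log.info("reading survey %s", cfg.survey)
        known = read_roster(cfg.roster) if cfg.roster else None
        roster, records = read_survey(
            cfg.survey, roster=known, lenient_missing=cfg.lenient_missing
        )
        universe = node_universe(roster, records)

        stage = "build_layers"
        layers = build_all_layers(records, universe=universe)
        nets_dir = out / "nets"
        nets_dir.mkdir(exist_ok=True)
        for label, layer in layers.items():
            p = write_edgelist(layer, nets_dir / f"{label}.csv")
            written.append(p)
            artifacts[f"edgelist:{label}"] = p
        log.info("built %d layers over %d nodes", len(layers), len(universe))

        stage = "pearson"
        r, p = pearson_matrix(dyad_matrix(records))
        artifacts["pearson_r"] = _float_csv(r, out / "pearson_r.csv")
        artifacts["pearson_p"] = _float_csv(p, out / "pearson_p.csv")
        written += [artifacts["pearson_r"], artifacts["pearson_p"]]

        stage = "measures"
        rows = [measure_table(layers[label]) for label in layers]
        measures = pd.DataFrame(
            [{"layer": t.label, "n_nodes": t.n_nodes, **t.as_dict()} for t in rows]
        ).set_index("layer")
        artifacts["measures"] = _float_csv(measures, out / "measures.csv")
        written.append(artifacts["measures"])

        stage = "envelopes"
        env_rows = []
        for mi, model in enumerate(cfg.null_models):
            for li, label in enumerate(layers):
                ncfg = NullConfig(
                    iterations=cfg.null_iterations,
                    seed=cfg.seed + 1000 * mi + li,
                    n_nodes=len(universe),
                    n_respondents=max(1, len(records)),
                )
                log.info("envelope: %s model, %s layer (%d iterations)",
                         model, label, ncfg.iterations)
                env_rows += envelope(layers[label], model, ncfg)
        env = pd.DataFrame([asdict(e) for e in env_rows])
        artifacts["envelopes"] = _float_csv(env, out / "envelopes.csv", index=False)
        written.append(artifacts["envelopes"])

        stage = "rank_correlations"
        scores = {
            label: {
                "weighted_in_degree": all_weighted_in_degrees(layers[label]),
                "betweenness": betweenness(layers[label]),
            }
            for label in TRUST_LAYER_LABELS
        }
        rc_rows = []
        for measure in ("weighted_in_degree", "betweenness"):
            for a, b in itertools.combinations(TRUST_LAYER_LABELS, 2):
                rep = top_k_spearman(scores[a][measure], scores[b][measure], k=cfg.rank_k)
                rc_rows.append(
                    {"measure": measure, "layer_a": a, "layer_b": b,
                     "rho": rep.rho, "pvalue": rep.pvalue,
                     "n_common": rep.n_common, "included": rep.included,
                     "note": rep.note}
                )
        artifacts["rank_correlations"] = _float_csv(
            pd.DataFrame(rc_rows), out / "rank_correlations.csv", index=False
        )
        written.append(artifacts["rank_correlations"])

        stage = "manifest"
        cfg_dict = asdict(cfg)
        cfg_dict["null_models"] = list(cfg.null_models)
        manifest = {
            "seed": cfg.seed,
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()
            ).hexdigest(),
            "trustnet_version": __version__,
            "n_nodes": len(universe),
            "n_respondents": len(records),
        }
        mp = out / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        artifacts["manifest"] = mp
        written.append(mp)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    return artifacts
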