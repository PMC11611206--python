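"""End-to-end pipeline with configuration and provenance capture.

``run_pipeline`` wires the stages together — profile (parse + correct +
scale + filter), ratings, per-indicator ensemble, index construction
(per-indicator + overall), and statistical evaluation — into one run
directory, and writes a machine-readable manifest recording the config
hash, seeds, and a SHA-256 checksum of every artifact.  Identical config
plus master seed reproduces the manifest byte for byte (single-threaded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import evaluate, index, profile, ratings
from .ensemble import EnsembleConfig, make_splits, run_ensemble, table1_summary
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters; defaults follow the published study design."""

    contrib_path: str | None = None
    marker_path: str | None = None
    ratings_path: str | None = None
    metadata_path: str | None = None     # TSV with sample_id + zone column
    zone_column: str = "zone"
    transform_ratings: bool = False
    pathway_mapping_path: str | None = None
    nsti_max: float = 2.0
    min_prevalence: float = 1 / 3
    n_runs: int = 25
    test_fraction: float = 0.2
    cv_folds: int = 3
    tuning_budget: int = 25
    objective: str = "regression"
    presence_min: int = 13
    k_grid: tuple[int, ...] = index.DEFAULT_K_GRID
    k_per_indicator: int = 50
    alpha: float = 0.05
    seed: int = 0
    indicators: list[str] | None = None  # default: all rating columns
    version: str = "0.1.0"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "k_grid" in doc:
            doc["k_grid"] = tuple(doc["k_grid"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_grid"] = list(self.k_grid)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    definitions: dict[str, index.MishDefinition] = field(default_factory=dict)
    scores: pd.DataFrame | None = None


def run_pipeline(config: RunConfig, out_dir: str | Path) -> PipelineResult:
    """Execute profile -> ratings -> ensemble -> index -> evaluate.

    Outputs land in ``out_dir``; a failure in any stage raises with the
    stage name while earlier outputs are preserved.  The manifest
    (manifest.json) lists the config, its hash, and per-artifact SHA-256
    checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage = "configure"
    try:
        for attr in ("contrib_path", "marker_path", "ratings_path",
                     "metadata_path"):
            p = getattr(config, attr)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{attr} does not exist: {p}")
        if (config.contrib_path is None or config.marker_path is None
                or config.ratings_path is None):
            raise ConfigurationError(
                "contrib_path, marker_path and ratings_path are required")

        stage = "profile"
        contribs = profile.parse_stratified_contributions(config.contrib_path)
        markers = profile.parse_marker_predictions(config.marker_path)
        raw = profile.compute_ec_relative_abundance(
            contribs, markers, nsti_max=config.nsti_max)
        scaled = profile.minmax_scale(raw)
        feats, report = profile.prevalence_filter(
            scaled, min_fraction=config.min_prevalence)
        feats.write(out / "features.tsv", out / "scaling_params.json")
        artifacts += [out / "features.tsv", out / "scaling_params.json"]
        logger.info("profile: %d samples x %d features (%d filtered out)",
                    len(feats.sample_ids), len(feats.feature_ids),
                    len(report.removed))

        stage = "ratings"
        rated = ratings.load_ratings(config.ratings_path,
                                     transform=config.transform_ratings)
        rated = ratings.IndicatorRatings(
            ratings=rated.ratings.loc[feats.sample_ids])
        rated.write(out / "ratings.tsv")
        artifacts.append(out / "ratings.tsv")

        stage = "strata"
        if config.metadata_path:
            meta = pd.read_csv(config.metadata_path, sep="\t", index_col=0)
            meta.index = meta.index.astype(str)
            strata = meta[config.zone_column].astype(str)
        else:
            strata = pd.Series("all", index=pd.Index(feats.sample_ids))

        ens_config = EnsembleConfig(
            n_runs=config.n_runs, test_fraction=config.test_fraction,
            cv_folds=config.cv_folds, tuning_budget=config.tuning_budget,
            objective=config.objective, seed=config.seed)
        indicators = config.indicators or rated.indicator_ids
        definitions: dict[str, index.MishDefinition] = {}
        all_scores = {}
        for pos, ind in enumerate(indicators):
            stage = f"ensemble[{ind}]"
            plans = make_splits(feats.sample_ids, strata,
                                n_runs=config.n_runs,
                                test_fraction=config.test_fraction,
                                seed=config.seed + 1000 * (pos + 1))
            rating = rated.ratings[ind]
            results, summary = run_ensemble(feats, rating, plans, ens_config)
            summary.table.to_csv(out / f"ensemble_{ind}.tsv", sep="\t",
                                 index_label="ec", float_format="%.12g")
            table1_summary(results).to_frame("value").to_csv(
                out / f"runstats_{ind}.tsv", sep="\t", float_format="%.12g")
            artifacts += [out / f"ensemble_{ind}.tsv",
                          out / f"runstats_{ind}.tsv"]

            stage = f"index[{ind}]"
            sweep = index.sweep_k(summary, feats, rating,
                                  k_grid=config.k_grid,
                                  presence_min=config.presence_min)
            sweep.to_frame().to_csv(out / f"sweep_{ind}.tsv", sep="\t",
                                    index=False, float_format="%.12g")
            artifacts.append(out / f"sweep_{ind}.tsv")
            definition = index.build_indicator_index(
                summary, feats, rating, presence_min=config.presence_min,
                k=config.k_per_indicator, seed=config.seed)
            definition.to_json(out / f"mish_{ind}.json")
            artifacts.append(out / f"mish_{ind}.json")
            definitions[ind] = definition
            all_scores[ind] = index.score(definition, feats)

        stage = "index[overall]"
        overall = index.build_overall_index(
            list(definitions.values()),
            k_per_indicator=config.k_per_indicator)
        overall.to_json(out / "mish_overall.json")
        artifacts.append(out / "mish_overall.json")
        definitions["overall"] = overall
        all_scores["overall"] = index.score(overall, feats)
        scores = pd.DataFrame(all_scores)
        scores.to_csv(out / "scores.tsv", sep="\t", index_label="sample_id",
                      float_format="%.12g")
        artifacts.append(out / "scores.tsv")

        stage = "evaluate"
        eval_rows = []
        for ind in indicators:
            bins = rated.bins[ind]
            gt = evaluate.group_test(scores[ind], bins, alpha=config.alpha)
            reg = evaluate.fit_rating_regression(
                scores[ind].to_numpy(), rated.ratings[ind].to_numpy())
            eval_rows.append({
                "indicator": ind, "kruskal_H": gt.kruskal_H,
                "kruskal_p": gt.kruskal_p,
                "letters": json.dumps(gt.letters, sort_keys=True),
                "adj_r2": reg.adj_r2, "rmse": reg.rmse, "aic": reg.aic,
                "p_value": reg.p_value})
        pd.DataFrame(eval_rows).to_csv(out / "evaluation.tsv", sep="\t",
                                       index=False, float_format="%.12g")
        artifacts.append(out / "evaluation.tsv")

        if config.pathway_mapping_path:
            stage = "pathways"
            mapping = evaluate.load_pathway_mapping(config.pathway_mapping_path)
            ecs_per = {ind: [e.ec for e in d.entries]
                       for ind, d in definitions.items()}
            evaluate.summarize_pathways(ecs_per, mapping).to_csv(
                out / "pathways.tsv", sep="\t", index=False,
                float_format="%.12g")
            artifacts.append(out / "pathways.tsv")
    except Exception as exc:
        raise DataError(f"pipeline failed at stage '{stage}': {exc}") from exc

    stage = "manifest"
    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return PipelineResult(out_dir=out, manifest=manifest,
                          definitions=definitions, scores=scores)
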