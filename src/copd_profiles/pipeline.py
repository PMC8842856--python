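"""End-to-end pipeline: simulate -> discover -> annotate -> tree -> stability.

Every stage writes delimited-text or JSON artifacts into the output directory
and the run is summarised in a manifest recording the seed, a configuration
hash and the artifact list. All randomness flows from a single root seed via
per-stage spawn keys, so a rerun with the same configuration reproduces every
stochastic stage bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path


from copd_profiles import cohort as cohort_mod
from copd_profiles import classification, discovery, stability, tree

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Settings for one full pipeline run."""

    seed: int = 1
    output_dir: str = "copd_run"
    cohort: cohort_mod.CohortConfig | None = None
    # discovery
    k: int | None = None            # fixed k; None -> gap statistic
    k_max: int = 8
    n_references: int = 100
    variance_threshold: float | None = None  # None -> Kaiser rule
    # decision tree
    train_fraction: float = 0.7
    max_depth: int = 3
    n_top_variables: int = 3
    n_importance_trees: int = 100
    leaf_map: dict | None = None
    # stability
    fev1_source: str = "baseline"

    def resolved_cohort(self) -> cohort_mod.CohortConfig:
        if self.cohort is not None:
            return self.cohort
        return cohort_mod.default_config(seed=self.seed)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["cohort"] = cohort_mod.config_to_dict(self.resolved_cohort())
        return data


def _config_hash(config: RunConfig) -> str:
    data = config.to_dict()
    data.pop("output_dir", None)  # where artifacts land is not a setting
    canonical = json.dumps(data, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest.

    On a stage failure the manifest is still written with the failing stage
    named and a failure marker, and the exception re-raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_config = config.resolved_cohort()
    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "artifacts": [],
        "status": "running",
        "failed_stage": None,
    }

    def emit(name: str) -> Path:
        manifest["artifacts"].append(name)
        return out / name

    stage = "simulate"
    try:
        cohort_mod.write_config(cohort_config, emit("cohort_config.json"))
        cohort = cohort_mod.sample_cohort(cohort_config, seed=config.seed)
        cohort_mod.write_cohort(cohort, emit("cohort.csv"))
        longitudinal = cohort_mod.sample_trajectories(
            cohort_config, cohort=cohort, seed=config.seed, include_baseline=True
        )
        cohort_mod.write_cohort(longitudinal, emit("longitudinal.csv"))
        logger.info(
            "simulate: %d participants (%d longitudinal over %d timepoints)",
            cohort_config.total_n, cohort_config.longitudinal_n, cohort_config.timepoints,
        )

        stage = "discover"
        result = discovery.discover_profiles(
            cohort,
            k=config.k,
            k_max=config.k_max,
            n_references=config.n_references,
            variance_threshold=config.variance_threshold,
            seed=config.seed,
        )
        result.assignments.to_csv(emit("assignments.csv"), index=False)
        if result.gap is not None:
            result.gap.as_frame().to_csv(emit("gap_curve.csv"), index=False)
        logger.info(
            "discover: %d components retained, k=%d",
            result.n_components, result.cluster_model.k,
        )

        stage = "annotate"
        traits = classification.annotate_cohort(cohort)
        traits.to_csv(emit("traits.csv"), index=False)
        prevalence = classification.trait_prevalence(cohort, result.assignments)
        prevalence.to_csv(emit("trait_prevalence.csv"), index=False)

        stage = "tree"
        labels = result.assignments["profile"].to_numpy()
        importance = tree.rank_importance(
            cohort[discovery.CLUSTERING_VARIABLES],
            labels,
            n_trees=config.n_importance_trees,
            seed=config.seed,
        )
        importance.to_csv(emit("variable_importance.csv"), index=False)
        top = list(importance["variable"].head(config.n_top_variables))
        train_idx, val_idx = tree.split_data(
            cohort, labels, train_fraction=config.train_fraction, seed=config.seed
        )
        model = tree.induce_tree(
            cohort.iloc[train_idx],
            labels[train_idx],
            top,
            max_depth=config.max_depth,
            validation=(cohort.iloc[val_idx], labels[val_idx]),
        )
        emit("tree.json").write_text(model.to_json(), encoding="utf-8")
        predicted = tree.predict(model, cohort.iloc[val_idx])
        agreement = tree.cohens_kappa(predicted, labels[val_idx])
        emit("agreement.json").write_text(
            json.dumps(agreement.to_dict(), indent=2), encoding="utf-8"
        )
        logger.info(
            "tree: top variables %s, validation accuracy %.3f, kappa %.3f (%s)",
            top, agreement.accuracy, agreement.kappa, agreement.band,
        )

        stage = "stability"
        if config.leaf_map is None:
            logger.info("stability: no leaf map supplied, using the default reconstruction")
        allocation = tree.published_tree_model(config.leaf_map)
        trajectories, excluded = stability.assign_over_time(
            allocation, longitudinal, fev1_source=config.fev1_source
        )
        stability.trajectories_frame(trajectories).to_csv(
            emit("trajectories.csv"), index=False
        )
        summary = stability.cohort_stability_summary(trajectories)
        payload = summary.to_dict()
        payload["excluded_participants"] = excluded
        emit("stability_summary.json").write_text(
            json.dumps(payload, indent=2), encoding="utf-8"
        )
        logger.info(
            "stability: %.1f%% fully stable, mean stability %.1f%%",
            100 * summary.proportion_fully_stable, summary.mean_stability_pct,
        )
    except Exception:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
        raise

    manifest["status"] = "complete"
    manifest["artifacts"].append("manifest.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
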