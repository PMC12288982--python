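"""End-to-end orchestration of the two analysis arms.

The biomarker arm: complete-case filtering, univariate screening, PCA,
inflamed-outlier flagging, ensemble random-forest ranking, and 70:30 logistic
evaluation of the top features.  The microbiome arm, per time point:
alpha/beta diversity with NMDS and PERMANOVA, class-level contrasts, and the
LASSO-OPLS-DA classifier with VIP scores, repeated CV, permutation test and
correlation edges; optionally a cross-cohort transfer step on multi-level
composition matrices.

A single top-level seed expands deterministically into per-stage seeds; every
run writes a manifest (config, seeds, stages) so reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anthropometry, composition, data_io, ensemble_rf, oplsda, screening
from .errors import ConfigurationError
from .synthetic import EffectSpec, SyntheticCohort, generate_cohort


@dataclass
class RunConfig:
    """Inputs and stage parameters for a pipeline run.

    Exactly one of ``input_paths`` (biomarkers/asv/taxonomy/growth/labels
    file paths) or ``generator_spec`` must be provided.
    """

    output_dir: str | Path
    seed: int = 0
    input_paths: dict | None = None
    generator_spec: EffectSpec | None = None

    timepoint: int = 9
    rf_iterations: int = 20
    rf_trees: int = 1000
    top_k: int = 9
    cv_folds: int = 5
    cv_repetitions: int = 50
    n_permutations: int = 100
    nested_selection: bool = True
    n_ortho: int = 1
    permanova_permutations: int = 999
    r_threshold: float = 0.7

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.generator_spec is None):
            raise ConfigurationError(
                "provide exactly one of input_paths or generator_spec"
            )


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, children)}


def _load(config: RunConfig) -> SyntheticCohort:
    if config.generator_spec is not None:
        return generate_cohort(config.generator_spec, config.seed)
    paths = config.input_paths
    required = {"biomarkers", "asv", "taxonomy", "growth", "labels"}
    missing = required - set(paths)
    if missing:
        raise ConfigurationError(f"input_paths lacks: {sorted(missing)}")
    labels = pd.read_csv(paths["labels"], sep="\t", index_col=0, dtype={0: str})
    if "inflamed" not in labels.columns:
        labels["inflamed"] = False
    labels["inflamed"] = labels["inflamed"].astype(bool)
    return SyntheticCohort(
        biomarkers=data_io.read_feature_table(paths["biomarkers"], "biomarker"),
        asv=data_io.read_feature_table(paths["asv"], "asv"),
        taxonomy=data_io.read_taxonomy(paths["taxonomy"]),
        growth=anthropometry.read_growth_records(paths["growth"]),
        labels=labels,
        spec=config.generator_spec or EffectSpec(),
        seed=config.seed,
    )


def _write_manifest(config: RunConfig, seeds: dict[str, int], stages: list[str], outdir: Path) -> None:
    def _plain(obj):
        if isinstance(obj, dict):
            return {str(k): _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        return obj if isinstance(obj, (int, float, bool, str, type(None))) else str(obj)

    doc = {
        "config": {
            k: _plain(v)
            for k, v in dataclasses.asdict(config).items()
            if k != "generator_spec"
        },
        "generator_spec": (
            {k: str(v) for k, v in dataclasses.asdict(config.generator_spec).items()}
            if config.generator_spec is not None
            else None
        ),
        "stage_seeds": seeds,
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(doc, indent=1, sort_keys=True))


def run_biomarker_arm(config: RunConfig) -> dict:
    """Biomarker arm: filtering -> screening/PCA/outliers -> ensemble RF -> logistic."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["partition", "forest", "logistic"])
    cohort = _load(config)

    filtered, report = data_io.filter_complete_cases(cohort.biomarkers)
    wasted = filtered.data[
        cohort.labels["group"]
        .reindex(filtered.data.index.get_level_values("subject_id"))
        .isin(["responder", "nonresponder"])
        .to_numpy()
    ]
    y = (
        cohort.labels["group"]
        .reindex(wasted.index.get_level_values("subject_id"))
        .to_numpy()
    )

    screen = screening.wilcoxon_bh(wasted, y)
    screening.write_screen_result(screen, outdir / "biomarker_screen.tsv")
    pca = screening.pca_features(filtered.data, standardize=True)
    pca.scores.to_csv(outdir / "biomarker_pca_scores.tsv", sep="\t")
    all_labels = cohort.labels_for(filtered.data.index)
    outliers = screening.flag_inflamed_outliers(filtered, all_labels)
    pd.DataFrame(
        {
            "inflamed_flag": outliers.flags,
            "composite": outliers.composite_score,
            "distance": outliers.distance_score,
        }
    ).to_csv(outdir / "inflamed_outliers.tsv", sep="\t")

    partition = ensemble_rf.make_partition(len(wasted), config.rf_iterations, seeds["partition"])
    summary = ensemble_rf.ensemble_importance(
        wasted, y, partition, n_trees=config.rf_trees, seed=seeds["forest"]
    )
    summary.importance.to_csv(outdir / "rf_importance.tsv", sep="\t")
    top = ensemble_rf.select_top_features(summary, config.top_k)
    eval_result = ensemble_rf.train_test_logistic(wasted, y, top, seed=seeds["logistic"])

    metrics = {
        "n_samples_after_filter": int(filtered.n_samples),
        "n_markers_after_filter": len(filtered.markers),
        "dropped_markers": report.dropped_markers,
        "mean_oob_error": float(np.mean(summary.oob_errors)),
        "top_features": top,
        "n_inflamed_flagged": int(outliers.flags.sum()),
        "logistic_train_accuracy": eval_result.train_accuracy,
        "logistic_test_accuracy": eval_result.test_accuracy,
    }
    (outdir / "biomarker_metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True))
    _write_manifest(config, seeds, ["filter", "screen", "pca", "outliers", "rf", "logistic"], outdir)
    return metrics


def run_microbiome_arm(config: RunConfig, transfer_cohort: SyntheticCohort | None = None) -> dict:
    """Microbiome arm at one time point: diversity -> ordination -> OPLS-DA."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["nmds", "permanova", "lasso", "cv", "perm", "transfer"])
    cohort = _load(config)

    tp = config.timepoint
    available = set(cohort.asv.data.index.get_level_values("timepoint"))
    if tp not in available:
        raise ConfigurationError(f"time point {tp} months absent from ASV table")
    counts = cohort.asv.at_timepoint(tp)
    wasted_mask = (
        cohort.labels["group"]
        .reindex(counts.data.index.get_level_values("subject_id"))
        .isin(["responder", "nonresponder"])
        .to_numpy()
    )
    counts = type(counts)(counts.data[wasted_mask])
    y = (
        cohort.labels["group"]
        .reindex(counts.data.index.get_level_values("subject_id"))
        .to_numpy()
    )

    alpha = composition.alpha_diversity(counts)
    alpha.to_csv(outdir / f"alpha_diversity_t{tp}.tsv", sep="\t")
    dmat = composition.bray_curtis(counts)
    dmat.to_csv(outdir / f"bray_curtis_t{tp}.tsv", sep="\t")
    ordination = composition.nmds(dmat, seed=seeds["nmds"])
    coords = ordination.coordinates.copy()
    coords["stress"] = ordination.stress
    coords.to_csv(outdir / f"nmds_t{tp}.tsv", sep="\t")
    perma = composition.permanova(
        dmat, y, n_perm=config.permanova_permutations, seed=seeds["permanova"]
    )

    class_counts = composition.aggregate_taxa(counts, cohort.taxonomy, "class")
    class_screen = screening.wilcoxon_bh(
        composition.relative_abundance(class_counts), y
    )
    class_screen.to_csv(outdir / f"class_screen_t{tp}.tsv", sep="\t", index=False)

    rel = composition.relative_abundance(counts)
    selected = oplsda.lasso_select(rel, y, seed=seeds["lasso"])
    model = oplsda.fit_oplsda(rel[selected], y, n_ortho=config.n_ortho, unit_variance=False)
    vip = oplsda.vip_scores(model)
    vip.to_csv(outdir / f"vip_t{tp}.tsv", sep="\t", index=False)
    model.to_json(outdir / f"oplsda_model_t{tp}.json")
    cv = oplsda.repeated_cv(
        rel,
        y,
        folds=config.cv_folds,
        repetitions=config.cv_repetitions,
        seed=seeds["cv"],
        nested_selection=config.nested_selection,
        unit_variance=False,
        n_ortho=config.n_ortho,
    )
    perm = oplsda.permutation_test(
        rel,
        y,
        n_perm=config.n_permutations,
        seed=seeds["perm"],
        folds=config.cv_folds,
        nested_selection=False,
        unit_variance=False,
        n_ortho=config.n_ortho,
    )
    edges = composition.correlation_edges(rel, selected, config.r_threshold)
    edges.to_csv(outdir / f"correlation_edges_t{tp}.tsv", sep="\t", index=False)

    metrics = {
        "timepoint": tp,
        "nmds_stress": ordination.stress,
        "permanova_pseudo_f": perma.pseudo_f,
        "permanova_p": perma.p_value,
        "n_selected_asvs": len(selected),
        "cv_mean_accuracy": cv.mean_accuracy,
        "permutation_p": perm.p_value,
        "permutation_observed_accuracy": perm.observed_accuracy,
        "n_correlation_edges": int(len(edges)),
    }

    if transfer_cohort is not None:
        multi_train = composition.multilevel_composition(counts, cohort.taxonomy)
        model_t = _fit_multilevel(multi_train, y, config, seeds["lasso"])
        other_counts = transfer_cohort.asv.at_timepoint(tp)
        other_mask = (
            transfer_cohort.labels["group"]
            .reindex(other_counts.data.index.get_level_values("subject_id"))
            .isin(["responder", "nonresponder"])
            .to_numpy()
        )
        other_counts = type(other_counts)(other_counts.data[other_mask])
        y_other = (
            transfer_cohort.labels["group"]
            .reindex(other_counts.data.index.get_level_values("subject_id"))
            .to_numpy()
        )
        multi_other = composition.multilevel_composition(other_counts, transfer_cohort.taxonomy)
        res = oplsda.transfer_predict(model_t, multi_other, y_other)
        metrics["transfer_accuracy"] = res.accuracy
        metrics["transfer_feature_overlap"] = res.feature_overlap

    (outdir / f"microbiome_metrics_t{tp}.json").write_text(
        json.dumps(metrics, indent=1, sort_keys=True)
    )
    _write_manifest(
        config,
        seeds,
        ["alpha", "bray_curtis", "nmds", "permanova", "class_screen", "oplsda", "edges"],
        outdir,
    )
    return metrics


def _fit_multilevel(multi: pd.DataFrame, y: np.ndarray, config: RunConfig, seed: int):
    selected = oplsda.lasso_select(multi, y, seed=seed)
    return oplsda.fit_oplsda(multi[selected], y, n_ortho=config.n_ortho, unit_variance=False)
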