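"""End-to-end study pipeline.

For each scene of a balanced five-grade panel: train the supervised
reference classifier on its train ROIs, derive the reference mask and FVC
(V_sup), then for each vegetation index segment the scene with Otsu,
compute the index FVC (V_vi) and score OA/kappa on the validation ROIs and
RE against V_sup.  Grade-level means, ANOVA tables and Duncan letters are
assembled from the balanced 19-indices x 6-images layout.

All randomness flows from a single root seed, split deterministically per
scene and stage.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accuracy as acc
from . import fvc as fvcmod
from . import segmentation as seg
from .indices import INDEX_NAMES, compute_all_indices, normalize_chromatic
from .reference import DEFAULT_ROI_COUNTS, PixelClassifier, extract_training_samples
from .stats import anova_frame, duncan_frame, replicate_study
from .synthetic import SceneSpec, SyntheticScene, generate_grade_panel, panel_manifest, sample_rois

logger = logging.getLogger("desertfvc")

__all__ = ["RunConfig", "StudyResult", "run_full_study", "evaluate_scene"]


@dataclass
class RunConfig:
    """Settings of a full study run; defaults reproduce the study design."""

    seed: int = 0
    indices: tuple[str, ...] = INDEX_NAMES
    otsu_bins: int = 256
    svm_gamma: float = 0.333
    svm_c: float = 1.0
    chromatic_features: bool = False
    roi_counts: dict = field(default_factory=lambda: dict(DEFAULT_ROI_COUNTS))
    validation_fraction: float = 0.12
    alpha: float = 0.05
    n_per_grade: int = 6
    scene_height: int = 512
    scene_width: int = 512
    spectral_overlap: float = 0.15
    non_desertification_overlap: float = 0.45
    palette_sd: float = 4.0
    noise_sd: float = 2.0
    shadow_fraction: float = 0.0
    cive_green: float = 0.881
    polarity_overrides: dict = field(default_factory=dict)
    skip_degenerate: bool = False
    out_dir: str | None = None
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["indices"] = list(self.indices)
        data["roi_counts"] = {k: list(v) for k, v in self.roi_counts.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "indices" in data:
            data["indices"] = tuple(data["indices"])
        if "roi_counts" in data:
            data["roi_counts"] = {k: tuple(v) for k, v in data["roi_counts"].items()}
        return cls(**data)


@dataclass
class StudyResult:
    """All outputs of one full study run."""

    manifest: pd.DataFrame          # per-scene panel manifest
    reference: pd.DataFrame         # per-scene reference OA/kappa/V_sup
    metric_table: pd.DataFrame      # per (index, scene, grade, metric) values
    grade_report: pd.DataFrame      # mean per (grade, metric, index)
    anova: dict                     # (grade, metric) -> (AnovaTable, DuncanResult)
    thresholds: pd.DataFrame        # Otsu diagnostics per scene/index
    confusion: pd.DataFrame         # validation-ROI TP/FN/FP/TN per scene/index


def _scene_base_spec(config: RunConfig) -> SceneSpec:
    return SceneSpec(
        target_fvc=30.0,
        height=config.scene_height,
        width=config.scene_width,
        spectral_overlap=config.spectral_overlap,
        palette_sd=config.palette_sd,
        noise_sd=config.noise_sd,
        shadow_fraction=config.shadow_fraction,
    )


def evaluate_scene(
    scene: SyntheticScene,
    config: RunConfig,
    scene_id: int,
    roi_seed: int,
) -> tuple[dict, list[dict], list[dict], list[dict]]:
    """Reference-classify and index-evaluate one scene.

    Returns (reference record, per-index metric rows, threshold rows,
    confusion rows).
    """
    rois = sample_rois(
        scene,
        counts=config.roi_counts,
        seed=roi_seed,
        validation_fraction=config.validation_fraction,
    )
    X, y = extract_training_samples(scene.image, rois, "train")
    clf = PixelClassifier(
        gamma=config.svm_gamma,
        c=config.svm_c,
        chromatic_features=config.chromatic_features,
        seed=roi_seed,
    ).fit(X, y)
    ref_mask = clf.classify_image(scene.image)
    v_sup = fvcmod.compute_fvc(ref_mask).fvc

    test_labels = rois.label_array("test")
    test_conf = acc.confusion_from_rois(ref_mask, test_labels)
    ref_record = dict(
        scene_id=scene_id,
        grade=scene.intended_grade,
        truth_fvc=scene.achieved_fvc,
        v_sup=v_sup,
        ref_grade=fvcmod.assign_grade(v_sup),
        test_oa_percent=100.0 * acc.overall_accuracy(test_conf),
        test_kappa=acc.kappa(test_conf),
    )

    chromatic = normalize_chromatic(scene.image)
    validation_labels = rois.label_array("validation")
    constants = {"green": config.cive_green} if config.cive_green != 0.881 else None
    index_maps = compute_all_indices(scene.image, names=config.indices)
    if constants is not None and "CIVE" in index_maps:
        from .indices import compute_index

        index_maps["CIVE"] = compute_index(
            scene.image, "CIVE", chromatic=chromatic, constants=constants
        )

    metric_rows: list[dict] = []
    threshold_rows: list[dict] = []
    confusion_rows: list[dict] = []
    for name, index_map in index_maps.items():
        try:
            mask, tres = seg.binarize(
                index_map,
                chromatic,
                n_bins=config.otsu_bins,
                polarity_override=config.polarity_overrides.get(name),
            )
        except seg.DegenerateInputError:
            if not config.skip_degenerate:
                raise
            logger.warning("scene %d index %s: degenerate Otsu input, skipped",
                           scene_id, name)
            continue
        v_vi = fvcmod.compute_fvc(mask).fvc
        conf = acc.confusion_from_rois(mask, validation_labels)
        re, abs_re = acc.relative_error(v_sup, v_vi)
        result = acc.AccuracyResult(
            oa=acc.overall_accuracy(conf), kappa=acc.kappa(conf), re=re, abs_re=abs_re
        )
        threshold_rows.append(dict(
            scene_id=scene_id, index=name, threshold=tres.threshold,
            between_class_variance=tres.between_class_variance,
            polarity=tres.polarity,
        ))
        confusion_rows.append(dict(
            scene_id=scene_id, index=name,
            tp=conf.tp, fn=conf.fn, fp=conf.fp, tn=conf.tn,
        ))
        base = dict(index=name, image_id=scene_id, grade=scene.intended_grade)
        metric_rows.extend([
            dict(base, metric="oa_percent", value=result.oa_percent),
            dict(base, metric="kappa", value=result.kappa),
            dict(base, metric="abs_re", value=result.abs_re),
            dict(base, metric="re", value=result.re),
            dict(base, metric="v_vi", value=v_vi),
        ])
    return ref_record, metric_rows, threshold_rows, confusion_rows


def run_full_study(config: RunConfig) -> StudyResult:
    """Run the complete replication: panel, reference, indices, statistics."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    root = np.random.SeedSequence(config.seed)
    panel_seed, roi_root = root.spawn(2)
    panel = generate_grade_panel(
        n_per_grade=config.n_per_grade,
        base_spec=_scene_base_spec(config),
        seed=panel_seed,
        non_desertification_overlap=config.non_desertification_overlap,
    )
    manifest = panel_manifest(panel)

    roi_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in roi_root.spawn(len(panel))]
    ref_records, metric_rows, threshold_rows, confusion_rows = [], [], [], []
    for i, scene in enumerate(panel):
        ref, metrics, thresholds, confusions = evaluate_scene(scene, config, i + 1, roi_seeds[i])
        ref_records.append(ref)
        metric_rows.extend(metrics)
        threshold_rows.extend(thresholds)
        confusion_rows.extend(confusions)
        logger.info("scene %d/%d (%s) done", i + 1, len(panel), scene.intended_grade)

    reference = pd.DataFrame(ref_records)
    metric_table = pd.DataFrame(metric_rows)
    stat_table = metric_table[metric_table["metric"].isin(["oa_percent", "kappa", "abs_re"])]
    anova = replicate_study(stat_table, alpha=config.alpha)
    grade_report = (
        stat_table.groupby(["grade", "metric", "index"], sort=False)["value"]
        .mean()
        .reset_index(name="mean")
    )
    result = StudyResult(
        manifest=manifest,
        reference=reference,
        metric_table=metric_table,
        grade_report=grade_report,
        anova=anova,
        thresholds=pd.DataFrame(threshold_rows),
        confusion=pd.DataFrame(confusion_rows),
    )
    if config.out_dir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: StudyResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.manifest.to_csv(out / "panel_manifest.csv", index=False)
    result.reference.to_csv(out / "reference.csv", index=False)
    result.metric_table.to_csv(out / "metrics.csv", index=False)
    result.grade_report.to_csv(out / "grade_report.csv", index=False)
    result.thresholds.to_csv(out / "thresholds.csv", index=False)
    result.confusion.to_csv(out / "confusion.csv", index=False)
    anova_frame(result.anova).to_csv(out / "anova.csv", index=False)
    duncan_frame(result.anova).to_csv(out / "duncan.csv", index=False)
    config.to_yaml(out / "run_config.yaml")
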