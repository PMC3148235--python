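"""End-to-end workflow: simulate (or load), build, validate, compare, score.

``run_pipeline`` wires the stages in study order: signature building with
leave-one-out cross-validation for each dose, cross-dose prediction
(dose specificity), persistence profiles at the recovery bleed, direction
decomposition and overlap, pathway activity scoring with the group ANOVA,
and gene-set overlap annotation.  Every stage writes its artifacts under
the output directory and is recorded in a JSON run manifest together with
the parameters and seeds, so map-mode runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from pathlib import Path

import pandas as pd

from . import __version__
from .composition import compare_signatures
from .enrichment import annotate_signature
from .formats import (
    ExpressionMatrix,
    GeneSetCollection,
    load_annotations,
    load_expression,
    load_gene_sets,
    save_annotations,
    save_cls,
    save_expression,
)
from .pathway import PathwayTrainingSet, one_way_anova_bonferroni, score_pathway
from .recovery import persistence_profile
from .signature import (
    cross_predict,
    fit_metagene_model,
    labels_from_groups,
    loocv,
    roc_summary,
)
from .simulate import (
    EXPOSURE,
    PlantConfig,
    StudyDesign,
    generate_pathway_training,
    generate_study,
    plant_pathway_effect,
)

__all__ = ["PipelineConfig", "run_pipeline", "StageError", "write_simulated_study"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclasses.dataclass
class PipelineConfig:
    """Paths and parameters for one run; mirrors the CLI flags."""

    out_dir: str = "pbsig_run"
    gct: str | None = None
    annotations: str | None = None
    gmt: str | None = None
    k: int = 250
    m: int = 2
    mode: str = "map"
    threshold: float = 0.5
    effect_size: float = 3.0
    reversion: float = 0.0
    seed: int = 42
    pathway_effect: float = 2.0
    stages: tuple[str, ...] = (
        "simulate",
        "signatures",
        "crosspredict",
        "recovery",
        "compare",
        "pathways",
        "enrich",
    )

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat key=value config file (one pair per line, '#' comments)."""
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip().strip("\"'")
            if key == "stages":
                kwargs[key] = tuple(s.strip() for s in value.split(",") if s.strip())
            elif key in {"k", "m", "seed"}:
                kwargs[key] = int(value)
            elif key in {"threshold", "effect_size", "reversion", "pathway_effect"}:
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        kwargs.update(overrides)
        return cls(**kwargs)


def _log(msg: str, verbose: bool) -> None:
    if verbose:
        print(msg, file=sys.stderr)


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def write_simulated_study(
    out_dir: str | Path,
    effect_size: float = 3.0,
    reversion: float = 0.0,
    seed: int = 42,
) -> dict[str, Path]:
    """Generate the default synthetic study and write GCT/CLS/TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plant = PlantConfig(effect_size=effect_size, reversion=reversion, seed=seed)
    matrix, truth = generate_study(StudyDesign(), plant)
    paths = {
        "gct": out / "study.gct",
        "cls": out / "study.cls",
        "annotations": out / "study_annotations.tsv",
        "truth": out / "study_truth.tsv",
    }
    save_expression(matrix, paths["gct"])
    labels = [0 if g == "control" else 1 for g in matrix.groups()]
    save_cls(labels, ["control", "exposed"], paths["cls"])
    save_annotations(matrix.annotations, paths["annotations"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def run_pipeline(config: PipelineConfig, verbose: bool = False) -> dict:
    """Execute the enabled stages; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "stages"
        },
        "stages": {},
        "inputs": {},
    }
    stages = set(config.stages)

    # ---- input acquisition -------------------------------------------
    truth = None
    if "simulate" in stages:
        _log("[simulate] generating synthetic study", verbose)
        plant = PlantConfig(
            effect_size=config.effect_size, reversion=config.reversion, seed=config.seed
        )
        matrix, truth = generate_study(StudyDesign(), plant)
        paths = write_simulated_study(
            out / "simulated", config.effect_size, config.reversion, config.seed
        )
        manifest["stages"]["simulate"] = {str(k): str(v) for k, v in paths.items()}
    else:
        if not config.gct or not Path(config.gct).exists():
            raise StageError("input", f"GCT not found: {config.gct!r} (simulate disabled)")
        if not config.annotations:
            raise StageError("input", "annotation TSV required when simulate is disabled")
        matrix = load_expression(config.gct, annotation_path=config.annotations)
        manifest["inputs"]["gct"] = {"path": config.gct, "md5": _md5(Path(config.gct))}

    exposure = matrix.select_samples(timepoint=EXPOSURE)
    doses = [g for g in pd.unique(matrix.groups()) if g != "control"]

    # ---- per-dose signatures + LOOCV ---------------------------------
    models: dict = {}
    cohorts: dict = {}
    if "signatures" in stages:
        sig_summary = {}
        for dose in doses:
            _log(f"[signatures] {dose} vs control", verbose)
            cohort = exposure.select_samples(group=["control", dose])
            y = labels_from_groups(cohort, dose)
            model = fit_metagene_model(
                cohort, y, k=config.k, m=config.m, mode=config.mode, seed=config.seed
            )
            preds = loocv(
                cohort, y, k=config.k, m=config.m, mode=config.mode, seed=config.seed
            )
            roc = roc_summary(preds, config.threshold)
            model.signature.save_tsv(out / f"signature_{dose}.tsv")
            model.to_json(out / f"model_{dose}.json")
            preds.save_tsv(out / f"loocv_{dose}.tsv")
            (out / f"roc_{dose}.json").write_text(
                json.dumps(roc.to_dict(), indent=1) + "\n"
            )
            models[dose] = model
            cohorts[dose] = (cohort, y)
            sig_summary[dose] = {"k": model.signature.k, "loocv_auc": roc.auc}
        manifest["stages"]["signatures"] = sig_summary

    # ---- dose specificity --------------------------------------------
    if "crosspredict" in stages and len(doses) >= 2 and models:
        cross = {}
        for dose_model in doses:
            for dose_test in doses:
                if dose_model == dose_test:
                    continue
                cohort, y = cohorts[dose_test]
                preds, roc = cross_predict(
                    models[dose_model], cohort, y, config.threshold
                )
                tag = f"{dose_model}_model_on_{dose_test}_cohort"
                preds.save_tsv(out / f"crosspredict_{tag}.tsv")
                cross[tag] = roc.to_dict()
        (out / "crosspredict_roc.json").write_text(json.dumps(cross, indent=1) + "\n")
        manifest["stages"]["crosspredict"] = {t: r["auc"] for t, r in cross.items()}

    # ---- persistence --------------------------------------------------
    if "recovery" in stages and models:
        rec = {}
        for dose in doses:
            prof = persistence_profile(models[dose].signature, matrix, dose)
            prof.save_tsv(out / f"persistence_{dose}.tsv")
            rec[dose] = {
                "mean_abs_exposure": prof.mean_abs_exposure,
                "mean_abs_recovery": prof.mean_abs_recovery,
                "reversion_ratio": prof.reversion_ratio,
            }
        manifest["stages"]["recovery"] = rec

    # ---- composition ---------------------------------------------------
    if "compare" in stages and len(models) >= 2:
        a, b = doses[0], doses[1]
        cmp_ab = compare_signatures(models[a].signature, models[b].signature)
        cmp_ab.save_json(out / f"comparison_{a}_vs_{b}.json")
        manifest["stages"]["compare"] = cmp_ab.counts

    # ---- pathway scoring ----------------------------------------------
    if "pathways" in stages:
        _log("[pathways] scoring synthetic perturbation signatures", verbose)
        n_train_probes = min(2000, matrix.n_probes)
        train_mx, planted = generate_pathway_training(
            n_probes=n_train_probes, seed=config.seed,
            effect_size=config.pathway_effect,
            probe_ids=matrix.probe_ids[:n_train_probes],
        )
        training = PathwayTrainingSet(
            name="synthetic_pathway",
            matrix=train_mx,
            labels=(train_mx.groups() == "activated").to_numpy().astype(float),
        )
        # plant the pathway in the high-dose exposure samples of a copy
        test = plant_pathway_effect(
            exposure, planted, group=doses[-1], effect=config.pathway_effect
        )
        activity = score_pathway(
            training, test, k=config.k, m=config.m, mode=config.mode, seed=config.seed
        )
        activity.save_tsv(out / "pathway_activity.tsv")
        comparison = one_way_anova_bonferroni(
            activity.table["probability"], activity.table["group"]
        )
        comparison.save_json(out / "pathway_anova.json")
        manifest["stages"]["pathways"] = {
            "pathway": activity.pathway,
            "group_means": activity.group_means().to_dict(),
            "anova_f": comparison.f_statistic,
            "anova_p": comparison.p_value,
        }

    # ---- enrichment ----------------------------------------------------
    if "enrich" in stages and models:
        collection = _enrichment_collection(config, matrix, truth)
        enr_summary = {}
        for dose in doses:
            results = annotate_signature(
                models[dose].signature, collection, universe_size=matrix.n_probes
            )
            for part, res in results.items():
                res.save_tsv(out / f"enrichment_{dose}_{part}.tsv")
            enr_summary[dose] = {
                part: res.table.iloc[0]["set_name"] for part, res in results.items()
            }
        manifest["stages"]["enrich"] = enr_summary

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


def _enrichment_collection(
    config: PipelineConfig, matrix: ExpressionMatrix, truth: pd.DataFrame | None
) -> GeneSetCollection:
    if config.gmt:
        return load_gene_sets(config.gmt)
    if truth is None:
        raise StageError("enrich", "no GMT supplied and no simulated ground truth")
    sets: dict[str, dict] = {}
    for cat, sub in truth.groupby("category"):
        sets[f"planted_{cat}"] = {
            "description": "simulated ground-truth block",
            "members": sub["probe_id"].tolist(),
        }
    return GeneSetCollection(sets)
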