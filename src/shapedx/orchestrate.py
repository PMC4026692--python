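"""End-to-end orchestration: feature extraction → classification → evaluation.

Ties the feature extractors and the classification protocol into
reproducible runs over a cohort (synthetic or loaded from disk), with every
random step seeded from a single master seed.  Feature extraction and
classification communicate through plain tables, so precomputed features
from an external pipeline can be injected at the classification stage.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import evaluation, pipeline, volumetry
from .displacement import (
    CorrespondencePair,
    displacement_field,
    partition_surface,
    patch_features,
)
from .pipeline import FeatureTable, ModelSelectionGrid
from .spectral import spectral_descriptor
from .synthetic import SyntheticCohort

__all__ = ["RunConfig", "extract_features", "run_threeclass", "run_pairwise",
           "run_partition_sweep"]

DEFAULT_SWEEP = (5, 10, 20, 50, 100, 200, 300)


@dataclass
class RunConfig:
    """Settings for an end-to-end run; defaults follow the study protocol."""

    feature_sets: tuple[str, ...] = ("volume", "invariants", "displacement")
    spectral_family: str = "F2"
    n_eigenvalues: int = 100
    n_patches: int = 300
    sweep_patches: tuple[int, ...] = DEFAULT_SWEEP
    k_features: int = 5
    grid: ModelSelectionGrid = field(default_factory=ModelSelectionGrid)
    classifier: str = "rbf_svm"
    train_fraction: float = 0.75
    n_reps: int = 10
    seed: int = 42
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "grid" in raw:
            raw["grid"] = ModelSelectionGrid(
                log10_C=tuple(raw["grid"]["log10_C"]),
                log10_gamma=tuple(raw["grid"]["log10_gamma"]),
            )
        for key in ("feature_sets", "sweep_patches"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def provenance(self) -> dict:
        d = asdict(self)
        d["grid"] = {"log10_C": list(self.grid.log10_C),
                     "log10_gamma": list(self.grid.log10_gamma)}
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return {"config": d, "config_hash": hashlib.sha256(blob).hexdigest()[:12]}


def _seed_for(master: int, tag: str) -> int:
    """Derive a stage seed deterministically from the master seed."""
    h = hashlib.sha256(f"{master}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def extract_features(
    cohort: SyntheticCohort, config: RunConfig, min_voxels: int = 200
) -> dict[str, FeatureTable]:
    """Per-biomarker feature tables for one structure.

    volume — the ICV-normalized structure volume (one column);
    invariants — the spectral family (n−1 columns);
    displacement — patch-averaged displacement magnitudes (n_patches columns).
    """
    labels = cohort.labels
    out: dict[str, FeatureTable] = {}

    if "volume" in config.feature_sets:
        masks = {s.subject_id: s.mask for s in cohort.subjects}
        vol, _model = volumetry.cohort_volumes(cohort.cohort_table, masks)
        feats = vol.set_index("subject_id")[["v_norm_mm3"]]
        out["volume"] = FeatureTable(feats, labels, name="volume")

    if "invariants" in config.feature_sets:
        rows = {}
        for s in cohort.subjects:
            desc = spectral_descriptor(
                s.mask, family=config.spectral_family, n=config.n_eigenvalues,
                min_voxels=min_voxels, seed=_seed_for(config.seed, "spectral"),
            )
            rows[s.subject_id] = desc.features
        feats = pd.DataFrame.from_dict(rows, orient="index")
        feats.columns = [f"f_{i:03d}" for i in range(1, feats.shape[1] + 1)]
        out["invariants"] = FeatureTable(feats, labels, name="invariants")

    if "displacement" in config.feature_sets:
        vertex_fields = vertex_displacements(cohort)
        out["displacement"] = patch_feature_table(
            cohort, vertex_fields, config.n_patches,
            seed=_seed_for(config.seed, "kmeans"),
        )
    return out


def vertex_displacements(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-vertex displacement magnitudes for every subject (subjects × vertices)."""
    rows = {}
    for s in cohort.subjects:
        pair = CorrespondencePair(template=cohort.template, target=s.mesh)
        rows[s.subject_id] = displacement_field(pair, prealign=True).magnitudes
    return pd.DataFrame.from_dict(rows, orient="index")


def patch_feature_table(
    cohort: SyntheticCohort, vertex_fields: pd.DataFrame, n_patches: int,
    seed: int,
) -> FeatureTable:
    """Reduce vertex-level fields to patch averages on the template partition."""
    part = partition_surface(cohort.template, n_patches=n_patches, seed=seed)
    feats = pd.DataFrame(
        np.stack([patch_features(vertex_fields.loc[sid].to_numpy(), part)
                  for sid in vertex_fields.index]),
        index=vertex_fields.index,
        columns=[f"patch_{p:03d}" for p in range(n_patches)],
    )
    return FeatureTable(feats, cohort.labels, name=f"displacement_N{n_patches}")


def _write_bundle(out_dir: str | None, name: str, payload: dict) -> None:
    if out_dir is None:
        return
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, f"{name}.json"), "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def run_threeclass(
    features: dict[str, FeatureTable], config: RunConfig
) -> dict:
    """Three-class hold-out evaluation per biomarker (single seeded split).

    Returns per-biomarker weighted AUC, per-class AUCs, confusion counts and
    cobweb axes, plus provenance.
    """
    t0 = time.time()
    results = {}
    for name, table in features.items():
        plan = pipeline.stratified_split(
            table.labels.to_numpy(), config.train_fraction,
            _seed_for(config.seed, f"split:{name}"),
        )
        model = pipeline.grid_search_train(
            table.subset(plan.train_idx), grid=config.grid,
            classifier=config.classifier, k_features=config.k_features,
            seed=_seed_for(config.seed, f"train:{name}"),
        )
        test = table.subset(plan.test_idx)
        scores = pipeline.predict_scores(model, test.features)
        report = evaluation.evaluate_multiclass(scores, test.labels)
        results[name] = {
            "report": report,
            "weighted_auc": report.weighted_auc,
            "selected_features": model.selected_features,
            "params": model.params,
        }
    bundle = {
        "results": {k: {"weighted_auc": v["weighted_auc"],
                        "per_class_auc": v["report"].per_class_auc,
                        "cobweb_axes": dict(v["report"].cobweb_axes),
                        "selected_features": v["selected_features"],
                        "params": v["params"]}
                    for k, v in results.items()},
        "elapsed_s": time.time() - t0,
        **config.provenance(),
    }
    _write_bundle(config.out_dir, "threeclass", bundle)
    bundle["reports"] = {k: v["report"] for k, v in results.items()}
    return bundle


def run_pairwise(
    features: dict[str, FeatureTable], config: RunConfig,
    include_loocv: bool = True,
) -> dict:
    """Pairwise evaluation: LOOCV and hold-out AUC/sensitivity/specificity
    for each pair of classes and each biomarker."""
    t0 = time.time()
    out: dict = {}
    for name, table in features.items():
        classes = sorted(table.labels.unique())
        pairs = [(a, b) for i, a in enumerate(classes) for b in classes[i + 1:]]
        out[name] = {}
        for a, b in pairs:
            keep = np.flatnonzero(table.labels.isin([a, b]).to_numpy())
            sub = table.subset(keep)
            entry = {}
            plan = pipeline.stratified_split(
                sub.labels.to_numpy(), config.train_fraction,
                _seed_for(config.seed, f"pair:{name}:{a}:{b}"),
            )
            model = pipeline.grid_search_train(
                sub.subset(plan.train_idx), grid=config.grid,
                classifier=config.classifier, k_features=config.k_features,
                seed=_seed_for(config.seed, f"pairtrain:{name}:{a}:{b}"),
            )
            test = sub.subset(plan.test_idx)
            scores = pipeline.predict_scores(model, test.features)
            entry["holdout"] = evaluation.binary_metrics(
                scores, test.labels.to_numpy(), positive=a)
            if include_loocv:
                _, loo_scores = pipeline.loocv(
                    sub, grid=config.grid, classifier=config.classifier,
                    k_features=config.k_features,
                    seed=_seed_for(config.seed, f"loo:{name}:{a}:{b}"),
                )
                entry["loocv"] = evaluation.binary_metrics(
                    loo_scores, sub.labels.to_numpy(), positive=a)
            out[name][f"{a}_vs_{b}"] = entry
    bundle = {"results": out, "elapsed_s": time.time() - t0,
              **config.provenance()}
    _write_bundle(config.out_dir, "pairwise", bundle)
    return bundle


def run_partition_sweep(
    cohort: SyntheticCohort,
    config: RunConfig,
    vertex_fields: pd.DataFrame | None = None,
    n_seeds: int = 5,
) -> pd.DataFrame:
    """Weighted AUC of the displacement biomarker vs number of patches.

    For each sweep value, patch features are rebuilt from the vertex-level
    displacement fields and evaluated with ``n_seeds`` seeded hold-out runs;
    the mean and SD of the weighted AUC are reported per sweep value.
    """
    if not config.sweep_patches:
        raise ValueError("sweep list is empty")
    if vertex_fields is None:
        vertex_fields = vertex_displacements(cohort)
    rows = []
    for n_patches in config.sweep_patches:
        table = patch_feature_table(
            cohort, vertex_fields, n_patches,
            seed=_seed_for(config.seed, f"kmeans:{n_patches}"),
        )
        aucs = []
        for rep in range(n_seeds):
            plan = pipeline.stratified_split(
                table.labels.to_numpy(), config.train_fraction,
                _seed_for(config.seed, f"sweep:{n_patches}:{rep}"),
            )
            model = pipeline.grid_search_train(
                table.subset(plan.train_idx), grid=config.grid,
                classifier=config.classifier, k_features=config.k_features,
                seed=_seed_for(config.seed, f"sweeptrain:{n_patches}:{rep}"),
            )
            test = table.subset(plan.test_idx)
            scores = pipeline.predict_scores(model, test.features)
            _, _, weighted = evaluation.weighted_multiclass_auc(
                scores, test.labels.to_numpy())
            aucs.append(weighted)
        rows.append({"n_patches": n_patches,
                     "weighted_auc_mean": float(np.mean(aucs)),
                     "weighted_auc_sd": float(np.std(aucs, ddof=1)) if n_seeds > 1 else 0.0})
    result = pd.DataFrame(rows)
    if config.out_dir is not None:
        os.makedirs(config.out_dir, exist_ok=True)
        result.to_csv(os.path.join(config.out_dir, "partition_sweep.csv"),
                      index=False)
    return result
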