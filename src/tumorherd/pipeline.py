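"""End-to-end experiment orchestration.

Three experiment modes mirror the study design:

* ``individual`` — one deep extractor, EHA-reduced, classified alone;
* ``dual_deep``  — two deep extractors, each EHA-reduced, serially fused;
* ``dl_ml``      — one EHA-reduced deep extractor fused with the 25 GLCM
  and 3 Hu features mined from the watershed tumor mask.

Reduction happens per extractor before fusion.  Noise robustness is a
config flag: ``noise_sigma`` corrupts the slices before feature extraction.
When segmentation returns an empty mask the slice's GLCM/Hu block is
imputed as zeros and the slice is flagged in the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify, eha, features, fusion, metrics, phantom, segmentation

__all__ = ["ExperimentConfig", "validate_config", "run_experiment"]

logger = logging.getLogger("tumorherd")

MODES = ("individual", "dual_deep", "dl_ml")

_KNOWN_KEYS = {
    "mode", "extractor_seeds", "n_per_class", "split", "skull", "noise_sigma",
    "image_size", "eha", "classifiers", "folds", "seed", "output_dir",
}
_EHA_KEYS = {f.name for f in dataclasses.fields(eha.EHAParams)}


@dataclass
class ExperimentConfig:
    mode: str = "dl_ml"
    extractor_seeds: list[int] = field(default_factory=lambda: [0])
    n_per_class: int = 150
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    skull: bool = False
    noise_sigma: float = 0.0
    image_size: int = 224
    eha: dict = field(default_factory=dict)
    classifiers: list[str] = field(default_factory=lambda: list(classify.CLASSIFIERS))
    folds: int = 3
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        errors = self.validate()
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))

    def validate(self) -> list[str]:
        errors = []
        if self.mode not in MODES:
            errors.append(f"mode must be one of {MODES}, got {self.mode!r}")
        n_ext = len(self.extractor_seeds)
        if self.mode == "dual_deep" and n_ext != 2:
            errors.append(f"dual_deep requires exactly 2 extractors, got {n_ext}")
        if self.mode in ("individual", "dl_ml") and n_ext != 1:
            errors.append(f"{self.mode} requires exactly 1 extractor, got {n_ext}")
        for c in self.classifiers:
            if c not in classify.CLASSIFIERS:
                errors.append(f"unknown classifier {c!r}")
        if self.folds != 3:
            logger.warning("folds=%d; the reference protocol fixes 3-fold CV", self.folds)
        unknown_eha = set(self.eha) - _EHA_KEYS
        if unknown_eha:
            errors.append(f"unknown eha keys {sorted(unknown_eha)}")
        if self.noise_sigma < 0:
            errors.append("noise_sigma must be >= 0")
        return errors


def validate_config(path: str | Path) -> ExperimentConfig:
    """Parse, default and validate a YAML experiment config.

    All schema violations are collected and raised together.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    errors = [f"unknown key {k!r}" for k in raw if k not in _KNOWN_KEYS]
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    if "split" in raw:
        raw["split"] = tuple(raw["split"])
    return ExperimentConfig(**raw)


def _eha_params(config: ExperimentConfig, seed: int) -> eha.EHAParams:
    kwargs = dict(config.eha)
    kwargs.setdefault("seed", seed)
    kwargs.setdefault("bounds", (0.0, 1.0))
    return eha.EHAParams(**kwargs)


def _extract_handcrafted(slices, params=None):
    """Per-slice GLCM+Hu block (28 values); zeros + flag for empty masks."""
    glcm_names = hu_names = None
    rows, flagged = [], []
    for i, slc in enumerate(slices):
        tm = segmentation.segment_slice(slc.pixels, params)
        if tm.empty:
            rows.append(None)
            flagged.append(i)
            continue
        g = features.glcm_features(slc.pixels, tm)
        h = features.hu_features(tm)
        glcm_names, hu_names = g.names, h.names
        rows.append(np.concatenate([g.values, h.values]))
    if glcm_names is None:
        raise RuntimeError("segmentation produced no usable mask on any slice")
    width = len(glcm_names) + len(hu_names)
    mat = np.vstack([r if r is not None else np.zeros(width) for r in rows])
    return mat, glcm_names + hu_names, flagged


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one end-to-end experiment; returns (and optionally writes) the report."""
    rng = np.random.default_rng(config.seed)
    logger.info("mode=%s n_per_class=%d seed=%d", config.mode, config.n_per_class, config.seed)

    ds = phantom.generate_dataset(
        n_per_class=config.n_per_class, split=config.split,
        seed=int(rng.integers(2**31 - 1)), skull=config.skull,
        image_size=config.image_size,
    )
    slices = ds.slices
    if config.noise_sigma > 0:
        noise_seeds = rng.integers(2**31 - 1, size=len(slices))
        slices = [phantom.add_gaussian_noise(s, config.noise_sigma, int(ns))
                  for s, ns in zip(slices, noise_seeds)]
    labels = np.array([s.label for s in slices])

    report: dict = {"config": {**dataclasses.asdict(config)}, "stages": {}}

    # deep features, one matrix per extractor, each EHA-reduced
    reduced_blocks: list[fusion.FeatureVector] = []
    deep_mats = []
    for ext_seed in config.extractor_seeds:
        ext = features.stub_extractor(ext_seed)
        mat = np.vstack([features.deep_features(s, ext).values for s in slices])
        names = features.deep_features(slices[0], ext).names
        sel_seed = int(rng.integers(2**31 - 1))
        sel = eha.select_features(mat, labels, _eha_params(config, sel_seed))
        idx = sel.selected_indices
        deep_mats.append(mat[:, idx])
        reduced_blocks.append((ext.name, idx, names, sel))
        logger.info("extractor %s: 1000 -> %d features (q=%.3f, rho=%.2f)",
                    ext.name, idx.size, sel.threshold_quantile, sel.redundancy_cutoff)
        report["stages"][f"select_{ext.name}"] = {
            "selected": int(idx.size),
            "quantile": round(sel.threshold_quantile, 4),
            "redundancy_cutoff": sel.redundancy_cutoff,
            "fitness": round(sel.fitness, 4),
            "indices": idx.tolist(),
        }

    per_slice_vectors = []
    handcrafted = None
    if config.mode == "dl_ml":
        hand_mat, hand_names, flagged = _extract_handcrafted(slices)
        report["stages"]["segmentation"] = {
            "n_slices": len(slices), "empty_masks": flagged,
        }
        handcrafted = (hand_mat, hand_names)

    # assemble fused per-slice vectors
    fused_rows = []
    for i in range(len(slices)):
        blocks = []
        for (ext_name, idx, names, _), mat in zip(reduced_blocks, deep_mats):
            blocks.append(features.FeatureVector(
                mat[i], [names[j] for j in idx], ext_name))
        if handcrafted is not None:
            hand_mat, hand_names = handcrafted
            blocks.append(features.FeatureVector(
                hand_mat[i, :25], hand_names[:25], "GLCM"))
            blocks.append(features.FeatureVector(
                hand_mat[i, 25:], hand_names[25:], "Hu"))
        fused_rows.append(fusion.fuse(blocks))

    X = np.vstack([f.values for f in fused_rows])
    fused_dim = fused_rows[0].dim
    report["fused_dim"] = int(fused_dim)
    report["fused_parts"] = fused_rows[0].parts
    logger.info("fused dimension: %d (%s)", fused_dim, fused_rows[0].parts)

    cv_seed = int(rng.integers(2**31 - 1))
    table_rows = []
    report["classification"] = {}
    for clf in config.classifiers:
        cv = classify.train_eval_cv(X, labels, clf, seed=cv_seed, folds=config.folds)
        report["classification"][clf] = cv.to_dict()
        table_rows.append((clf, cv.pooled))
        logger.info("%s: pooled AC=%.4f best fold=%d", clf,
                    cv.pooled_metrics.ac, cv.best_fold)
    report["metrics_table"] = metrics.metrics_table(table_rows).to_dict(orient="records")

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        metrics.metrics_table(table_rows).to_csv(out / "metrics.csv", index=False)
    return report
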