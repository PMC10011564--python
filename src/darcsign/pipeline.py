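"""End-to-end orchestration: filter -> features -> train -> explain.

The pipeline consumes per-sample variant and segment tables plus a label
sheet and cytoband file, and produces a feature matrix, one model
artifact per target label, per-sample probabilities, metrics and feature
impact rankings.  Every artifact is stamped with the configuration hash
and seed; deterministic stages are bit-identical under rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classifier as clf
from .copynumber_features import DEFAULT_SCHEMA, CnFeatureSchema
from .io_formats import read_cytobands, read_segments, read_variants
from .mutation_features import build_catalog
from .profiles import build_profile
from .somatic_filters import ErrorModel, FilterConfig, call_somatic
from .types import ValidationError

log = logging.getLogger(__name__)

DEFAULT_TARGETS = ("BRCA2d", "CDK12d", "MMRd")


@dataclass
class RunConfig:
    variants_dir: Path
    segments_dir: Path
    labels_path: Path
    cytobands_path: Path
    out_dir: Path
    targets: tuple[str, ...] = DEFAULT_TARGETS
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    schema: CnFeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)
    train_config: clf.TrainConfig | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("variants_dir", "segments_dir", "labels_path", "cytobands_path"):
            path = Path(getattr(self, name))
            if not path.exists():
                raise ValidationError(f"{name} does not exist: {path}")

    def digest(self) -> str:
        payload = json.dumps(
            {
                "targets": list(self.targets),
                "filter": vars(self.filter_config),
                "seed": self.seed,
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def extract_features(config: RunConfig, error_model: ErrorModel | None = None
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Filter each sample's variants and build its 224-feature profile."""
    arm_map = read_cytobands(config.cytobands_path)
    labels = pd.read_csv(config.labels_path, sep="\t", index_col="sample")["label"]
    error_model = error_model or ErrorModel(rates={}, panel_size=1)
    rows = []
    for sid in labels.index:
        variants = read_variants(Path(config.variants_dir) / f"{sid}.tsv")
        verdicts = call_somatic(variants, error_model, config.filter_config)
        passing = [v.record for v in verdicts if v.passed]
        log.info("sample %s: %d/%d variants pass filters", sid, len(passing), len(variants))
        solution = read_segments(Path(config.segments_dir) / f"{sid}.tsv")
        catalog = build_catalog(passing, sid)
        rows.append(build_profile(catalog, solution.segments, arm_map, config.schema))
    X = pd.DataFrame(rows)
    return X, labels.loc[X.index]


def run_pipeline(config: RunConfig) -> Path:
    """Run the full pipeline; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train_config = config.train_config or clf.TrainConfig.test_profile(config.seed)

    X, labels = extract_features(config)
    X.rename_axis("sample").to_csv(out / "feature_matrix.tsv", sep="\t")

    metrics: dict[str, dict] = {}
    probabilities = pd.DataFrame(index=X.index)
    for target in config.targets:
        y = clf.binarize_labels(labels.values, target)
        train_idx, test_idx = clf.stratified_split(y, train_config.test_fraction,
                                                   config.seed)
        model = clf.grid_search_train(X.iloc[train_idx], y[train_idx], target,
                                      train_config)
        p_all = clf.predict_proba(model, X)
        model.threshold = clf.derive_threshold(y[train_idx], p_all[train_idx])
        clf.save_model(model, out / "models" / target)
        probabilities[target] = p_all
        held_out = clf.evaluate(y[test_idx], p_all[test_idx])
        metrics[target] = {
            "threshold": model.threshold,
            "held_out_auc": held_out["auc"],
            "held_out_f1": held_out["f1"],
            "n_train": int(len(train_idx)),
            "n_test": int(len(test_idx)),
        }
        impact = clf.feature_impact(model, X)
        impact.rename("impact").rename_axis("feature").to_csv(
            out / f"impact_{target}.tsv", sep="\t"
        )

    probabilities.rename_axis("sample").to_csv(out / "probabilities.tsv", sep="\t")
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    (out / "run_manifest.json").write_text(
        json.dumps({"config_hash": config.digest(), "seed": config.seed}, indent=2)
    )
    return out
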