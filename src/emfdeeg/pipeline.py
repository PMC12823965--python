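"""End-to-end orchestration: data -> decomposition -> features -> evaluation.

A single :class:`RunConfig` (expressible as YAML) drives synthetic-data
generation or delimited-file loading, feature extraction, and overall
plus lobe-wise cross-validated classification.  One top-level seed
deterministically derives every stage seed, so the same config produces
byte-identical report tables.
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

from .classify_eval import (CVResult, ModelSpec, bayesian_optimize,
                            learning_curve, permutation_test,
                            stratified_kfold_cv)
from .entropy_features import (META_COLUMNS, EntropyFeaturizer, EntropyParams,
                               FeatureReducer, split_features_meta)
from .io_preprocess import read_delimited, preprocess, segment_record
from .lobe_montage import build_montage, select_lobe_features
from .synth_eeg import SynthConfig, generate_dataset

logger = logging.getLogger(__name__)

METRIC_ORDER = ["Ac", "Se", "Sp", "Pr", "Fs"]


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    synth: SynthConfig | None = None
    data_dir: str | None = None  # delimited recordings + sidecars
    dataset_preset: str = "stew"
    filter_low: float | None = None   # used with dataset_preset="custom"
    filter_high: float | None = None
    filter_order: int = 4
    window_s: float = 4.0
    overlap_s: float = 0.0
    n_modes: int = 5
    entropy_params: EntropyParams = field(default_factory=EntropyParams)
    montage_id: str = "stew14"
    classifiers: list[str] = field(default_factory=lambda: ["boosted_trees"])
    optimize: bool = False
    opt_budget: int = 30
    folds: int = 10
    group_by_subject: bool = False
    reduce_features: bool = False
    permutations: int = 0
    learning_fractions: list[float] = field(default_factory=list)
    lobes: str | list[str] = "all"
    out_dir: str = "emfd_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synth" in raw and raw["synth"] is not None:
            raw["synth"] = SynthConfig(**raw["synth"])
        if "entropy_params" in raw:
            raw["entropy_params"] = EntropyParams(**raw["entropy_params"])
        return cls(**raw)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def derive_seed(seed: int, *tags: str) -> int:
    """Stable stage seed below 2^31 derived from the run seed and a tag."""
    digest = hashlib.sha256(("/".join([str(seed), *tags])).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def load_segments(config: RunConfig):
    """Materialize labeled segments from the configured source."""
    if config.synth is not None:
        segs = generate_dataset(config.synth, window_s=config.window_s)
        logger.info("synth stage: %d segments, %d channels",
                    len(segs), len(segs[0].labels) if segs else 0)
        return segs
    if config.data_dir is None:
        raise ValueError("RunConfig needs either a synth config or a data_dir")
    segs = []
    for path in sorted(Path(config.data_dir).glob("*.csv")):
        rec = read_delimited(path)
        rec = preprocess(rec, preset=config.dataset_preset,
                         low=config.filter_low, high=config.filter_high,
                         order=config.filter_order)
        segs.extend(segment_record(rec, window_s=config.window_s,
                                   overlap_s=config.overlap_s))
    logger.info("load stage: %d segments from %s", len(segs), config.data_dir)
    if not segs:
        raise ValueError(f"no recordings found under {config.data_dir}")
    return segs


def extract_features(config: RunConfig, segments) -> pd.DataFrame:
    feat = EntropyFeaturizer(config.n_modes, config.entropy_params)
    matrix = feat.fit_transform(segments)
    logger.info("feature stage: %d rows x %d columns",
                matrix.shape[0], matrix.shape[1])
    return matrix


def _evaluate_matrix(config: RunConfig, matrix: pd.DataFrame,
                     family: str, tag: str) -> tuple[ModelSpec, CVResult]:
    feats, meta = split_features_meta(matrix)
    y = meta["condition"].to_numpy()
    groups = meta["subject_id"].to_numpy() if config.group_by_subject else None
    seed = derive_seed(config.seed, family, tag)
    reducer = FeatureReducer() if config.reduce_features else None
    if config.optimize:
        spec, _ = bayesian_optimize(family, feats, y,
                                    budget=config.opt_budget, seed=seed)
    else:
        spec = ModelSpec(family, seed=seed)
    result = stratified_kfold_cv(spec, feats, y, k=config.folds, seed=seed,
                                 groups=groups, reduce=reducer)
    return spec, result


def _result_row(family: str, lobe: str, res: CVResult) -> dict:
    row = {"classifier": family, "lobe": lobe}
    row.update({m: (round(res.pooled[m], 2) if res.pooled[m] is not None else None)
                for m in METRIC_ORDER})
    row.update({"mean_Ac": round(res.mean_accuracy, 2),
                "sd_Ac": round(res.sd_accuracy, 3),
                "ci95_low": round(res.ci95[0], 2),
                "ci95_high": round(res.ci95[1], 2),
                "AUC": round(res.auc, 4)})
    return row


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write the report bundle.

    Emits the overall metrics table (one row per classifier), the
    lobe-wise table (one row per classifier per lobe), pooled
    out-of-fold ROC points, optional permutation and learning-curve
    outputs, and a manifest (seed, config hash) sufficient to re-run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        segments = load_segments(config)
        stage = "features"
        matrix = extract_features(config, segments)
        montage = build_montage(config.montage_id)
        lobes = montage.lobes if config.lobes == "all" else (
            [] if config.lobes == "overall" else list(config.lobes))

        stage = "evaluate"
        rows, roc_frames = [], []
        results: dict[tuple[str, str], CVResult] = {}
        for family in config.classifiers:
            spec, res = _evaluate_matrix(config, matrix, family, "overall")
            results[(family, "overall")] = res
            rows.append(_result_row(family, "overall", res))
            roc_frames.append(pd.DataFrame(res.roc_points,
                                           columns=["fpr", "tpr"])
                              .assign(classifier=family, lobe="overall"))
            for lobe in lobes:
                sub = select_lobe_features(matrix, montage, lobe)
                spec_l, res_l = _evaluate_matrix(config, sub, family, lobe)
                results[(family, lobe)] = res_l
                rows.append(_result_row(family, lobe, res_l))

        report = pd.DataFrame(rows)
        report.to_csv(out / "metrics.csv", index=False)
        pd.concat(roc_frames).to_csv(out / "roc.csv", index=False)

        extras = {}
        if config.permutations > 0:
            stage = "permutation"
            feats, meta = split_features_meta(matrix)
            y = meta["condition"].to_numpy()
            family = config.classifiers[0]
            perm = permutation_test(ModelSpec(family, seed=derive_seed(config.seed, "perm")),
                                    feats, y, n_perm=config.permutations,
                                    k=min(config.folds, 5),
                                    seed=derive_seed(config.seed, "perm"))
            extras["permutation"] = {"observed": perm.observed,
                                     "p_value": perm.p_value}
            pd.DataFrame({"permuted_accuracy": perm.permuted}).to_csv(
                out / "permutation.csv", index=False)
        if config.learning_fractions:
            stage = "learning_curve"
            feats, meta = split_features_meta(matrix)
            y = meta["condition"].to_numpy()
            family = config.classifiers[0]
            lc = learning_curve(ModelSpec(family, seed=derive_seed(config.seed, "lc")),
                                feats, y, fractions=config.learning_fractions,
                                seed=derive_seed(config.seed, "lc"))
            lc.to_csv(out / "learning_curve.csv", index=False)
            extras["learning_curve"] = lc.to_dict("records")

        manifest = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_segments": len(segments),
            "n_features": int(matrix.shape[1] - len(META_COLUMNS)),
            "classifiers": config.classifiers,
            "folds": config.folds,
            "lobes": lobes,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return {"report": report, "results": results, "manifest": manifest,
                **extras}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
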