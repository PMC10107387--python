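"""End-to-end experiment orchestration, PCA coordinates, and table export.

``run_experiment`` drives one signal kind through the whole pipeline —
cohort generation, windowing, LSDL threshold search, feature extraction
(raw and decomposed arms), the supervised suite, the clustering
comparison, and 2-D PCA coordinates — and writes every artifact as CSV or
JSON under the configured output directory. All randomness descends from
one master seed through a per-stage hash, so a config plus seed reproduces
every file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from . import io as record_io
from .balance import BalanceConfig
from .features import FEATURE_NAMES, FeatureConfig, featurize_cohort
from .lsdl import search_optimal
from .preprocess import select_records, window_disjoint
from .supervised import MODEL_NAMES, ModelSpec, run_model_suite
from .synth import CohortParams, generate_cohort
from .unsupervised import (
    ClusteringError,
    evaluate_clusters,
    gmm_partition,
    kmeans_partition,
)

__all__ = ["ExperimentConfig", "stage_seed", "run_experiment", "pca_coords"]

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of the stage name mixed with the master."""
    return int(zlib.crc32(f"{stage}:{master_seed}".encode()) % (2**31))


@dataclass
class ExperimentConfig:
    cohort: CohortParams = field(default_factory=CohortParams)
    n_windows: int = 10
    min_record_len: int = 80
    lsdl_max_iterations: int = 4
    lsdl_min_samples: int = 16
    features: FeatureConfig = field(default_factory=FeatureConfig)
    balance: BalanceConfig = field(default_factory=BalanceConfig)
    model_names: tuple = MODEL_NAMES
    k_folds: int = 10
    grouped_folds: bool = False
    clustering_restarts: int = 5
    clustering_selection: str = "accuracy"
    gmm_reg: float = 0.1
    pca_components: int = 2
    output_dir: str = "pretermsig_out"
    master_seed: int = 0


def pca_coords(
    features: pd.DataFrame | np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Standardised-PCA coordinates and explained-variance fractions.

    Features are z-scored first (the ensemble mixes units spanning orders
    of magnitude); zero-variance columns are dropped with a warning. Sign
    convention: the largest-magnitude loading of each component is positive.
    """
    if isinstance(features, pd.DataFrame):
        cols = [c for c in FEATURE_NAMES if c in features.columns]
        X = features[cols].to_numpy(dtype=float) if cols else features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need at least 3 rows and 2 features")
    finite_X = np.where(np.isfinite(X), X, np.nan)
    col_means = np.nanmean(finite_X, axis=0)
    X = np.where(np.isfinite(X), X, col_means)
    variances = X.var(axis=0)
    keep = variances > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance feature(s) before PCA",
                       int((~keep).sum()))
    X = X[:, keep]
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 informative features remain")
    Z = StandardScaler().fit_transform(X)
    n_components = min(n_components, Z.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(Z)
    for k in range(n_components):
        loading = pca.components_[k]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, k] *= -1.0
    return coords, pca.explained_variance_ratio_


def _clustering_table(feat: pd.DataFrame, cfg: ExperimentConfig, seed: int) -> pd.DataFrame:
    X = StandardScaler().fit_transform(
        np.nan_to_num(feat[list(FEATURE_NAMES)].to_numpy(dtype=float))
    )
    y = feat["label"].to_numpy()
    rows = []
    for model, fn, kwargs in (
        ("GMM", gmm_partition, {"reg": cfg.gmm_reg}),
        ("K-Means", kmeans_partition, {}),
    ):
        try:
            assignments = fn(
                X, restarts=cfg.clustering_restarts, seed=seed,
                selection=cfg.clustering_selection, labels=y, **kwargs,
            )
            rep = evaluate_clusters(assignments, y, model=model)
            rows.append(
                {
                    "Model": model,
                    "Preterm (%)": round(rep.preterm_acc, 1),
                    "Term (%)": round(rep.term_acc, 1),
                    "Overall accuracy (%)": rep.overall_acc,
                }
            )
        except (ClusteringError, ValueError) as exc:
            logger.warning("%s clustering failed: %s", model, exc)
            rows.append(
                {
                    "Model": model,
                    "Preterm (%)": "n/a",
                    "Term (%)": "n/a",
                    "Overall accuracy (%)": "n/a",
                }
            )
    return pd.DataFrame(rows)


def _candidate_table(model) -> pd.DataFrame:
    """Candidate J values laid out as the threshold-search tables: one row
    per region, one column per iteration, failures printed as n/a."""
    iters = sorted({c.iteration for c in model.candidates})
    data = {}
    for region, label in (("upper", "Upper threshold"), ("lower", "Lower threshold")):
        row = []
        for i in iters:
            cand = next(
                c for c in model.candidates if c.region == region and c.iteration == i
            )
            row.append(round(cand.cost, 4) if cand.valid else "n/a")
        data[label] = row
    table = pd.DataFrame(data, index=[f"Iteration {i}" for i in iters]).T
    table.index.name = "Region"
    return table


def run_experiment(config: ExperimentConfig) -> dict[str, str]:
    """Run the full pipeline for one signal kind; returns the artifact manifest."""
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict[str, str] = {}

    # 1. cohort
    params = replace(config.cohort, seed=stage_seed(config.master_seed, "cohort"))
    cohort = generate_cohort(params)
    cohort_dir = os.path.join(out, "cohort")
    manifest["cohort_manifest"] = record_io.write_cohort(cohort, cohort_dir)

    # 2. preprocessing: down-selection and disjoint windows
    kept = select_records(cohort, config.min_record_len)
    if not kept:
        raise RuntimeError("preprocess: no records survive down-selection")
    window_sets = [window_disjoint(r, config.n_windows) for r in kept]

    # 3. LSDL threshold search
    model = search_optimal(
        window_sets,
        feature_config=config.features,
        max_iterations=config.lsdl_max_iterations,
        min_samples=config.lsdl_min_samples,
    )
    model_path = os.path.join(out, "lsdl_model.json")
    model.to_json(model_path)
    manifest["lsdl_model"] = model_path
    cand_path = os.path.join(out, "lsdl_candidates.csv")
    _candidate_table(model).to_csv(cand_path)
    manifest["lsdl_candidates"] = cand_path

    # 4. feature tables, raw and decomposed arms
    feat_raw = featurize_cohort(window_sets, config.features)
    feat_lsdl = featurize_cohort(window_sets, config.features, lsdl=model)
    for arm, table in (("raw", feat_raw), ("lsdl", feat_lsdl)):
        path = os.path.join(out, f"features_{arm}.csv")
        table.to_csv(path, index=False)
        manifest[f"features_{arm}"] = path

    # 5. supervised suite
    sup_table, _ = run_model_suite(
        feat_raw, feat_lsdl,
        seed=stage_seed(config.master_seed, "supervised"),
        specs=[ModelSpec(n) for n in config.model_names],
        k_folds=config.k_folds,
        balance=config.balance,
        grouped=config.grouped_folds,
    )
    sup_path = os.path.join(out, "supervised_report.csv")
    sup_table.to_csv(sup_path, index=False)
    manifest["supervised_report"] = sup_path

    # 6. clustering (decomposed arm)
    clu = _clustering_table(
        feat_lsdl, config, stage_seed(config.master_seed, "clustering")
    )
    clu_path = os.path.join(out, "clustering_report.csv")
    clu.to_csv(clu_path, index=False)
    manifest["clustering_report"] = clu_path

    # 7. PCA coordinates for both arms
    pca_rows = []
    for arm, table in (("Raw", feat_raw), ("LSDL", feat_lsdl)):
        coords, evr = pca_coords(table, config.pca_components)
        for (pid, lab), (pc1, pc2) in zip(
            table[["patient_id", "label"]].itertuples(index=False), coords[:, :2]
        ):
            pca_rows.append(
                {"arm": arm, "patient_id": pid, "label": lab,
                 "PC1": pc1, "PC2": pc2,
                 "evr1": round(float(evr[0]), 6), "evr2": round(float(evr[1]), 6)}
            )
    pca_path = os.path.join(out, "pca_coords.csv")
    pd.DataFrame(pca_rows).to_csv(pca_path, index=False)
    manifest["pca_coords"] = pca_path

    # 8. run log + manifest
    log = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "stage_seeds": {
            s: stage_seed(config.master_seed, s)
            for s in ("cohort", "supervised", "clustering")
        },
        "config": _config_to_jsonable(config),
        "lsdl_best": {
            "region": model.best.region,
            "iteration": model.best.iteration,
            "threshold": model.best.threshold,
            "cost": model.best.cost,
        },
    }
    log_path = os.path.join(out, "run_log.json")
    with open(log_path, "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    manifest["run_log"] = log_path

    manifest_path = os.path.join(out, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["manifest"] = manifest_path
    return manifest


def _config_to_jsonable(config: ExperimentConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    return convert(config)
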