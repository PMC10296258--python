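"""Pipeline orchestration and the top-level model object.

`PrognosticSubtypeModel` is built from the four study inputs (replicate
feature table, clinical table, identification library, pathway map); its
``fit()`` runs preprocessing, hierarchical model selection, differential
ranking, pathway enrichment and the stratified survival analysis, and
returns a `SubtypeResults` carrying every stage's output plus a
``summary()`` table. `run_pipeline` wraps the model with file IO, stage
logging and a JSON report for shell use.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import differential as _diff
from . import enrichment as _enr
from . import survival as _surv
from .preprocess import (
    CV_THRESHOLD, KNN_K, MAX_MISSING, PPM_TOL, RT_TOL_S,
    preprocess as _preprocess,
)
from .config import SimulationConfig
from .containers import MetaboliteLibrary, MetaboliteMatrix, RawFeatureTable
from .simulate import generate_cohort, write_cohort


@dataclass
class PipelineConfig:
    outdir: str = "metabotype_run"
    seed: int = 0
    # inputs: either simulate, or read the four files below
    simulate: bool = True
    sim_config: SimulationConfig = field(default_factory=SimulationConfig)
    clinical_path: str | None = None
    features_path: str | None = None
    library_path: str | None = None
    pathways_path: str | None = None
    # stage parameters
    cv_threshold: float = CV_THRESHOLD
    max_missing: float = MAX_MISSING
    knn_k: int = KNN_K
    ppm_tol: float = PPM_TOL
    rt_tol_s: float = RT_TOL_S
    kmin: int = _cluster.K_RANGE[0]
    kmax: int = _cluster.K_RANGE[1]
    adj_p_threshold: float = _diff.ADJ_P_THRESHOLD
    method: str = "hierarchical"  # hierarchical | kmeans | rf
    sensitivity: bool = False
    horizon: float = _surv.HORIZON_YEARS

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim_config"] = self.sim_config.to_dict()
        return d


class SubtypeResults:
    """Fitted results: subtype labels, model-selection table, differential
    ranking, enrichment table and the stratified survival report."""

    def __init__(self, *, matrix, processing_log, models, k, votes, labels,
                 differential, enrichment, survival_report, method,
                 sensitivity=None):
        self.matrix: MetaboliteMatrix = matrix
        self.processing_log = processing_log
        self.models = models
        self.k = k
        self.votes = votes
        self.labels: pd.Series = labels
        self.differential: pd.DataFrame = differential
        self.enrichment: pd.DataFrame = enrichment
        self.survival_report: dict = survival_report
        self.method = method
        self.sensitivity = sensitivity or {}

    @property
    def subtype_sizes(self) -> dict:
        return self.labels.value_counts().sort_index().to_dict()

    def metric_table(self) -> pd.DataFrame:
        rows = {m.k: m.metrics for m in self.models}
        return pd.DataFrame(rows).T.rename_axis("k")

    def summary(self) -> str:
        lines = [
            "Prognostic metabolic subtype analysis",
            "=" * 42,
            f"samples: {self.matrix.n_samples}   "
            f"metabolites: {self.matrix.n_metabolites}",
            f"chosen k: {self.k} (votes: {self.votes})",
            f"subtype sizes: {self.subtype_sizes}",
            f"selected metabolites: {self.differential['selected'].sum()}"
            f" of {len(self.differential)}",
        ]
        if len(self.enrichment):
            lines.append("top enriched pathways:")
            for _, r in self.enrichment.head(4).iterrows():
                lines.append(
                    f"  {r['pathway']}: k={r['k']}/m={r['m']} "
                    f"chi2={r['chi2']:.2f} p={r['p']:.3g} ({r['direction']})")
        for stratum in ("full", "ever_smokers", "never_smokers"):
            entry = self.survival_report.get(stratum, {})
            cox = entry.get("os", {}).get("cox", {})
            adj = cox.get("adjusted", {})
            if "hr" in adj:
                lo, hi = adj["ci"]
                lines.append(
                    f"OS HR A vs B, {stratum} (adjusted): "
                    f"{adj['hr']:.2f} ({lo:.2f}, {hi:.2f}), p={adj['p']:.3g}")
        return "\n".join(lines)


class PrognosticSubtypeModel:
    """Discover and evaluate metabolic subtypes in one cohort.

    Parameters mirror the study inputs: ``raw`` replicate-level feature
    intensities, ``clinical`` the baseline + outcome table, ``library`` the
    level-1 identification library and ``pathway_map`` the pathway
    membership sets.
    """

    def __init__(self, raw: RawFeatureTable, clinical: pd.DataFrame,
                 library: MetaboliteLibrary, pathway_map: dict,
                 config: PipelineConfig | None = None):
        self.raw = raw
        self.clinical = clinical
        self.library = library
        self.pathway_map = pathway_map
        self.config = config or PipelineConfig()

    @classmethod
    def from_files(cls, clinical_path, features_path, library_path,
                   pathways_path, config: PipelineConfig | None = None):
        return cls(
            RawFeatureTable.from_tsv(features_path),
            pd.read_csv(clinical_path),
            MetaboliteLibrary.from_tsv(library_path),
            _enr.read_gmt(pathways_path),
            config=config,
        )

    # ------------------------------------------------------------- stages
    def _cluster_stage(self, matrix: MetaboliteMatrix, cfg: PipelineConfig):
        X = matrix.data.to_numpy(float)
        if cfg.method == "hierarchical":
            models = _cluster.hierarchical_models(X, cfg.kmin, cfg.kmax)
            k, votes = _cluster.select_k(models)
            chosen = next(m for m in models if m.k == k)
        elif cfg.method in ("kmeans", "rf"):
            fit = _cluster.kmeans_cluster if cfg.method == "kmeans" \
                else _cluster.rf_proximity_cluster
            models = [fit(X, k, seed=cfg.seed)
                      for k in range(cfg.kmin, cfg.kmax + 1)]
            k, votes = _cluster.select_k(models)
            chosen = next(m for m in models if m.k == k)
        else:
            raise ValueError(f"unknown clustering method: {cfg.method!r}")
        letters = _letter_labels(X, chosen.labels)
        labels = pd.Series(letters, index=matrix.data.index, name="subtype")
        return models, k, votes, labels

    def fit(self) -> SubtypeResults:
        cfg = self.config
        matrix, plog = _preprocess(
            self.raw, self.library, cv_threshold=cfg.cv_threshold,
            max_missing=cfg.max_missing, knn_k=cfg.knn_k,
            ppm_tol=cfg.ppm_tol, rt_tol_s=cfg.rt_tol_s)
        models, k, votes, labels = self._cluster_stage(matrix, cfg)

        # differential ranking between the two largest subtypes
        ranked = _diff.rank_metabolites(matrix, labels.to_numpy(),
                                        group_a="A", group_b="B")
        ranked = _diff.rank_and_select(ranked, cfg.adj_p_threshold)
        selected = set(ranked.index[ranked["selected"]])
        background = set(matrix.data.columns)
        if 0 < len(selected) < len(background):
            enr = _enr.enrich_all(selected, background, self.pathway_map)
        else:
            enr = pd.DataFrame()
            enr.attrs["skipped"] = list(self.pathway_map)

        clinical = self.clinical.set_index("id")
        joined = clinical.join(labels.rename("subtype"), how="inner")
        surv = _surv.stratified_analysis(joined, horizon=cfg.horizon)

        sensitivity = {}
        if cfg.sensitivity:
            X = matrix.data.to_numpy(float)
            for name, fn in (("kmeans", _cluster.kmeans_cluster),
                             ("rf", _cluster.rf_proximity_cluster)):
                model = fn(X, 2, seed=cfg.seed)
                letters = _letter_labels(X, model.labels)
                agree = float(np.mean(letters == labels.to_numpy()))
                sensitivity[name] = {
                    "labels": pd.Series(letters, index=matrix.data.index),
                    "agreement_with_primary": agree,
                }
        return SubtypeResults(
            matrix=matrix, processing_log=plog, models=models, k=k,
            votes=votes, labels=labels, differential=ranked, enrichment=enr,
            survival_report=surv, method=cfg.method, sensitivity=sensitivity)


def _letter_labels(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Name clusters A, B, ... by descending grand-mean standardized level,
    so the metabolically elevated cluster is always subtype A."""
    means = {}
    for lab in np.unique(labels):
        means[lab] = float(X[labels == lab].mean())
    order = sorted(means, key=lambda lab: -means[lab])
    letter = {lab: chr(ord("A") + i) for i, lab in enumerate(order)}
    return np.array([letter[lab] for lab in labels])


# ------------------------------------------------------------ validation

def validate_inputs(paths: dict) -> list[str]:
    """Schema and cross-file checks for the four input files.

    ``paths`` maps clinical/features/library/pathways to file paths.
    Returns a list of human-readable issues (empty = valid).
    """
    issues: list[str] = []
    loaded: dict = {}
    for key in ("clinical", "features", "library", "pathways"):
        p = paths.get(key)
        if p is None or not Path(p).exists():
            issues.append(f"{key}: file missing ({p})")
    if issues:
        return issues
    try:
        loaded["clinical"] = pd.read_csv(paths["clinical"])
        needed = {"id", "smoking", "hpv_status", "os_time", "os_event",
                  "pfs_time", "pfs_event"}
        missing = needed - set(loaded["clinical"].columns)
        if missing:
            issues.append(f"clinical: missing columns {sorted(missing)}")
    except Exception as exc:
        issues.append(f"clinical: unreadable ({exc})")
    try:
        raw = RawFeatureTable.from_tsv(paths["features"])
        raw.validate()
        loaded["features"] = raw
    except Exception as exc:
        issues.append(f"features: {exc}")
    try:
        loaded["library"] = MetaboliteLibrary.from_tsv(paths["library"])
    except Exception as exc:
        issues.append(f"library: {exc}")
    try:
        loaded["pathways"] = _enr.read_gmt(paths["pathways"])
    except Exception as exc:
        issues.append(f"pathways: {exc}")
    if issues:
        return issues

    raw = loaded["features"]
    bad = raw.intensities.apply(
        lambda col: ~(pd.to_numeric(col, errors="coerce").notna()
                      | col.isna())).to_numpy()
    if bad.any():
        f, c = np.argwhere(bad)[0]
        issues.append(
            f"features: non-numeric intensity at feature "
            f"{raw.feature_ids[f]}, column {raw.intensities.columns[c]}")
    clin_ids = set(loaded["clinical"]["id"])
    feat_ids = set(raw.sample_ids)
    for sid in sorted(clin_ids - feat_ids):
        issues.append(f"cross-check: clinical sample {sid} absent from "
                      f"feature table")
    for sid in sorted(feat_ids - clin_ids):
        issues.append(f"cross-check: feature-table sample {sid} absent "
                      f"from clinical table")
    lib_acc = set(loaded["library"].entries["hmdb_id"])
    for name, members in loaded["pathways"].items():
        stray = members - lib_acc
        if stray:
            issues.append(
                f"cross-check: pathway {name!r} references accessions not "
                f"in the library: {sorted(stray)[:5]}")
    return issues


# --------------------------------------------------------------- pipeline

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> preprocess -> cluster -> rank -> enrich ->
    survive, writing per-stage artifacts and an aggregated JSON report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: list = []
    t0 = time.time()

    def log_stage(name, **info):
        run_log.append({"stage": name, "elapsed_s": round(time.time() - t0, 3),
                        **info})

    if config.simulate:
        sim_cfg = dataclasses.replace(config.sim_config, seed=config.seed)
        cohort = generate_cohort(sim_cfg)
        paths = write_cohort(cohort, outdir / "inputs")
        model = PrognosticSubtypeModel(
            cohort.raw, cohort.clinical, cohort.library, cohort.pathway_map,
            config=config)
        log_stage("simulate", n_patients=len(cohort.clinical),
                  n_features=cohort.raw.n_features, paths=paths)
    else:
        model = PrognosticSubtypeModel.from_files(
            config.clinical_path, config.features_path, config.library_path,
            config.pathways_path, config=config)
        log_stage("load_inputs")

    res = model.fit()
    log_stage("preprocess", **{k: v for k, v in res.processing_log.items()
                               if k != "modes"})
    log_stage("cluster", k=res.k, votes=res.votes,
              sizes=res.subtype_sizes, method=res.method)
    log_stage("rank", n_selected=int(res.differential["selected"].sum()))
    log_stage("enrich", n_pathways=len(res.enrichment))
    log_stage("survive", strata=list(res.survival_report.keys()))

    # artifacts
    res.labels.rename("subtype").to_csv(outdir / "labels.csv",
                                        index_label="sample_id")
    res.metric_table().to_csv(outdir / "metrics.csv")
    res.differential.to_csv(outdir / "differential.csv",
                            index_label="metabolite_id")
    if len(res.enrichment):
        res.enrichment.to_csv(outdir / "enrichment.csv", index=False)
    _write_km_coordinates(res.survival_report, outdir / "km_coordinates.csv")

    report = {
        "config": config.to_dict(),
        "k": res.k,
        "votes": res.votes,
        "subtype_sizes": res.subtype_sizes,
        "n_selected": int(res.differential["selected"].sum()),
        "selected_fraction": res.differential.attrs["selected_fraction"],
        "processing_log": res.processing_log,
        "enrichment": res.enrichment.to_dict(orient="records")
        if len(res.enrichment) else [],
        "survival": res.survival_report,
        "run_log": run_log,
    }
    report = _jsonify(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(_jsonify(run_log), fh, indent=2)
    return report


def _write_km_coordinates(report: dict, path) -> None:
    rows = []
    for stratum, entry in report.items():
        if not isinstance(entry, dict):
            continue
        for outcome in ("os", "pfs"):
            curves = entry.get(outcome, {}).get("curves", {})
            for subtype, curve in curves.items():
                for t, s in zip(curve.times, curve.survival):
                    rows.append((stratum, outcome, subtype, t, s))
    pd.DataFrame(rows, columns=["stratum", "outcome", "subtype", "time",
                                "survival"]).to_csv(path, index=False)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_dict())
    if isinstance(obj, _surv.KMCurve):
        return {"times": obj.times.tolist(),
                "survival": obj.survival.tolist()}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
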