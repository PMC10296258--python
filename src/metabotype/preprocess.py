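"""Post-extraction feature processing.

Fixed stage order (each stage operates per chromatography mode, the two
modes are pooled at the end):

1. replicate-CV filter (median technical-replicate CV >= 0.75 removed),
2. median summarization across the sample triplicates (>= 2 observed
   replicates required, else the cell is missing),
3. log2 transform and empirical-Bayes batch correction,
4. missingness filter (features missing in > 20% of samples removed),
5. k-nearest-neighbor imputation over samples,
6. Z-score standardization (metabolite mean 0, unit sample SD),
7. library matching (m/z within 10 ppm, retention time within 30 s) and
   restriction to identified metabolites,
8. pooling of the HILIC-positive and C18-negative matrices.

Every operation here is deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .combat import combat
from .containers import (
    MODES, MetaboliteLibrary, MetaboliteMatrix, RawFeatureTable,
)

CV_THRESHOLD = 0.75
MAX_MISSING = 0.20
KNN_K = 10
PPM_TOL = 10.0
RT_TOL_S = 30.0


# ----------------------------------------------------------- CV filtering

def replicate_cv(raw: RawFeatureTable) -> pd.Series:
    """Median within-sample technical-replicate CV per feature.

    The CV of a (feature, sample) cell is the sample SD over its observed
    replicates divided by their mean; cells with fewer than two observed
    replicates contribute no CV. Features with no computable CV at all get
    NaN (treated as failing the filter downstream).
    """
    arr = _replicate_array(raw)  # (features, samples, 3)
    n_obs = np.sum(~np.isnan(arr), axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=2)
        sd = np.nanstd(arr, axis=2, ddof=1)
        cv = np.where(n_obs >= 2, sd / mean, np.nan)
        med = np.nanmedian(cv, axis=1)
    return pd.Series(med, index=raw.feature_ids, name="median_cv")


def filter_by_cv(raw: RawFeatureTable, threshold: float = CV_THRESHOLD
                 ) -> tuple[RawFeatureTable, list]:
    """Drop features whose median replicate CV is >= ``threshold``
    (inclusive bound) or undefined. Returns (table, removed feature ids)."""
    med = replicate_cv(raw)
    fails = med.isna() | (med >= threshold)
    removed = list(med.index[fails])
    keep = ~fails
    out = RawFeatureTable(raw.features.loc[keep],
                          raw.intensities.loc[keep], raw.batches)
    return out, removed


# -------------------------------------------------------- summarization

def summarize_triplicates(raw: RawFeatureTable) -> pd.DataFrame:
    """Median over observed replicates per (feature, sample); missing when
    fewer than 2 of the 3 replicates were observed."""
    arr = _replicate_array(raw)
    n_obs = np.sum(~np.isnan(arr), axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(arr, axis=2)
    med = np.where(n_obs >= 2, med, np.nan)
    return pd.DataFrame(med, index=raw.feature_ids, columns=raw.sample_ids)


def _replicate_array(raw: RawFeatureTable) -> np.ndarray:
    samples = raw.sample_ids
    cols = pd.MultiIndex.from_product([samples, [1, 2, 3]])
    vals = raw.intensities.reindex(columns=cols).to_numpy(float)
    return vals.reshape(raw.n_features, len(samples), 3)


# ------------------------------------------------------ batch correction

def correct_batches(log2_matrix: pd.DataFrame,
                    batches: pd.Series) -> pd.DataFrame:
    """Empirical-Bayes location/scale batch adjustment of a features x
    samples log2 table (see :mod:`metabotype.combat`)."""
    return combat(log2_matrix, batches)


# --------------------------------------------------- missingness / impute

def filter_missingness(matrix: pd.DataFrame, max_missing: float = MAX_MISSING
                       ) -> tuple[pd.DataFrame, list]:
    """Drop features missing in strictly more than ``max_missing`` of the
    samples (a feature missing in exactly 20% is retained)."""
    frac = matrix.isna().mean(axis=1)
    removed = list(matrix.index[frac > max_missing])
    return matrix.loc[frac <= max_missing], removed


def impute_knn(matrix: pd.DataFrame, k: int = KNN_K) -> pd.DataFrame:
    """Fill missing cells from the k nearest samples.

    Sample-to-sample distances are Euclidean over the features observed in
    both samples, computed once on the pre-imputation matrix. A missing
    (feature, sample) cell becomes the mean of that feature over the k
    nearest samples in which it was observed. If no sample shares any
    observed feature (or no donor exists), the feature median is used and a
    warning issued.
    """
    X = matrix.to_numpy(float)
    if not np.isnan(X).any():
        return matrix.copy()
    obs = ~np.isnan(X)
    n_feat, n_samp = X.shape
    Xs = X.T  # samples x features
    Ms = obs.T
    dist2 = np.full((n_samp, n_samp), np.inf)
    X0 = np.where(Ms, Xs, 0.0)
    for i in range(n_samp):
        shared = Ms[i][None, :] & Ms
        diff = (X0[i][None, :] - X0) * shared
        d2 = np.einsum("ij,ij->i", diff, diff)
        any_shared = shared.any(axis=1)
        dist2[i] = np.where(any_shared, d2, np.inf)
    np.fill_diagonal(dist2, np.inf)

    out = X.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        feat_median = np.nanmedian(X, axis=1)
    fallback = []
    for f, s in zip(*np.where(~obs)):
        donors = np.flatnonzero(obs[f] & np.isfinite(dist2[s]))
        if donors.size == 0:
            out[f, s] = feat_median[f]
            fallback.append((matrix.index[f], matrix.columns[s]))
            continue
        nearest = donors[np.argsort(dist2[s, donors], kind="stable")[:k]]
        out[f, s] = X[f, nearest].mean()
    if fallback:
        warnings.warn(
            f"kNN imputation fell back to the feature median for "
            f"{len(fallback)} cells with no usable neighbor")
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ------------------------------------------------------- standardization

def log2_zscore(matrix: pd.DataFrame, log_input: bool = False
                ) -> pd.DataFrame:
    """log2-transform (unless ``log_input``) then Z-score per feature.

    Input is features x samples with no missing values; output is samples x
    features with each column mean 0 and unit sample SD (n-1 denominator).
    A zero-variance feature raises an error naming it.
    """
    X = matrix.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("standardization requires a complete matrix")
    if not log_input:
        if (X <= 0).any():
            raise ValueError("intensities must be positive for log2")
        X = np.log2(X)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = np.ravel(sd)
    if (flat == 0).any():
        bad = [str(matrix.index[i]) for i in np.flatnonzero(flat == 0)]
        raise ValueError(f"zero-variance metabolites: {bad}")
    z = (X - mean) / sd
    return pd.DataFrame(z.T, index=matrix.columns, columns=matrix.index)


# ------------------------------------------------------- library matching

def match_library(features: pd.DataFrame, library: MetaboliteLibrary,
                  ppm_tol: float = PPM_TOL, rt_tol_s: float = RT_TOL_S
                  ) -> pd.DataFrame:
    """Annotate features against a level-1 library.

    A feature matches an entry of the same mode when |dmz| / mz_library *
    1e6 <= ppm_tol and |drt| <= rt_tol_s (both bounds inclusive). The entry
    with the smallest ppm error wins; residual ties go to the smallest rt
    error. When several features hit the same library entry, only the one
    with the smallest ppm error is kept, so metabolite identities stay
    unique. Returns a DataFrame indexed by feature_id with the library
    annotation columns plus ppm_error / rt_error.
    """
    lib = library.entries
    rows = []
    for fid, feat in features.iterrows():
        cand = lib[lib["mode"] == feat["mode"]]
        if cand.empty:
            continue
        ppm = (feat["mz"] - cand["mz"]).abs() / cand["mz"] * 1e6
        drt = (feat["rt"] - cand["rt"]).abs()
        ok = (ppm <= ppm_tol) & (drt <= rt_tol_s)
        if not ok.any():
            continue
        sub = cand[ok].assign(ppm_error=ppm[ok], rt_error=drt[ok])
        best = sub.sort_values(["ppm_error", "rt_error"], kind="stable").iloc[0]
        rows.append({
            "feature_id": fid, "name": best["name"], "mz": best["mz"],
            "rt": best["rt"], "mode": best["mode"], "adduct": best["adduct"],
            "hmdb_id": best["hmdb_id"], "ppm_error": best["ppm_error"],
            "rt_error": best["rt_error"],
        })
    if not rows:
        return pd.DataFrame(
            columns=["name", "mz", "rt", "mode", "adduct", "hmdb_id",
                     "ppm_error", "rt_error"],
            index=pd.Index([], name="feature_id"))
    out = pd.DataFrame(rows).set_index("feature_id")
    out = (out.sort_values("ppm_error", kind="stable")
           .groupby("hmdb_id", sort=False).head(1))
    return out.loc[[f for f in features.index if f in out.index]]


# --------------------------------------------------------------- merging

def merge_modes(a: MetaboliteMatrix, b: MetaboliteMatrix) -> MetaboliteMatrix:
    """Pool two per-mode matrices column-wise (same samples required)."""
    if len(b.data.columns) == 0:
        return a
    if not a.data.index.equals(b.data.index):
        only_a = set(a.data.index) - set(b.data.index)
        only_b = set(b.data.index) - set(a.data.index)
        raise ValueError(
            f"sample sets differ between modes: only in first={sorted(only_a)},"
            f" only in second={sorted(only_b)}")
    dup = set(a.data.columns) & set(b.data.columns)
    if dup:
        raise ValueError(f"duplicate metabolite ids across modes: {sorted(dup)}")
    data = pd.concat([a.data, b.data], axis=1)
    ann = pd.concat([a.annotations, b.annotations], axis=0)
    return MetaboliteMatrix(data, ann)


# ------------------------------------------------------------ full stage

def preprocess(raw: RawFeatureTable, library: MetaboliteLibrary,
               cv_threshold: float = CV_THRESHOLD,
               max_missing: float = MAX_MISSING, knn_k: int = KNN_K,
               ppm_tol: float = PPM_TOL, rt_tol_s: float = RT_TOL_S,
               ) -> tuple[MetaboliteMatrix, dict]:
    """Run the full per-mode pipeline and pool the modes.

    Returns the standardized samples x metabolites matrix (columns = HMDB
    accessions) and a processing log with per-stage counts.
    """
    raw.validate()
    log: dict = {"modes": {}, "order": [
        "cv_filter", "summarize", "log2", "batch_correct",
        "missingness_filter", "impute_knn", "zscore", "match_library",
        "merge_modes"]}
    merged: MetaboliteMatrix | None = None
    for mode in MODES:
        sub = raw.subset_mode(mode)
        if sub.n_features == 0:
            continue
        stage: dict = {"n_features_in": sub.n_features}
        filtered, removed_cv = filter_by_cv(sub, cv_threshold)
        stage["removed_cv"] = len(removed_cv)
        summarized = summarize_triplicates(filtered)
        logged = pd.DataFrame(
            np.log2(summarized.to_numpy(float)),
            index=summarized.index, columns=summarized.columns)
        corrected = correct_batches(logged, raw.batches)
        kept, removed_miss = filter_missingness(corrected, max_missing)
        stage["removed_missingness"] = len(removed_miss)
        n_missing_cells = int(kept.isna().to_numpy().sum())
        stage["imputed_cells"] = n_missing_cells
        stage["cells"] = int(kept.size)
        stage["imputed_fraction"] = n_missing_cells / max(kept.size, 1)
        complete = impute_knn(kept, k=knn_k)
        z = log2_zscore(complete, log_input=True)
        ann = match_library(filtered.features.loc[z.columns], library,
                            ppm_tol, rt_tol_s)
        stage["matched"] = len(ann)
        z = z.loc[:, ann.index]
        z.columns = ann["hmdb_id"].to_numpy()
        ann_out = ann.reset_index().set_index("hmdb_id")
        matrix = MetaboliteMatrix(z, ann_out)
        log["modes"][mode] = stage
        merged = matrix if merged is None else merge_modes(merged, matrix)
    if merged is None:
        raise ValueError("no features in any chromatography mode")
    # restandardize: pooling preserves per-mode standardization, but assert it
    merged.validate_standardized(atol=1e-6)
    log["n_metabolites"] = merged.n_metabolites
    log["n_samples"] = merged.n_samples
    total_cells = sum(s["imputed_cells"] for s in log["modes"].values())
    total_size = sum(s["cells"] for s in log["modes"].values())
    log["imputed_fraction"] = total_cells / total_size if total_size else 0.0
    return merged, log
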