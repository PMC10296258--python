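"""Post-hoc differential-metabolite ranking between two subtypes.

Each metabolite is tested with a two-sided Wilcoxon rank-sum (Mann-Whitney)
test between the subtypes, p-values are Benjamini-Hochberg adjusted, and
metabolites with adjusted p below a threshold are selected as the
pathway-analysis input set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MetaboliteMatrix

ADJ_P_THRESHOLD = 1e-5
EXACT_MAX_N = 12


def wilcoxon_rank_sum(x, y, method: str | None = None) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U statistic of x, p).

    By default uses exact enumeration when the combined sample size is at
    most 12 and the data have no ties, otherwise the normal approximation
    with midranks, tie-corrected variance, and a continuity correction.
    ``method`` ('exact' / 'asymptotic') overrides the automatic choice.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if method is None:
        method = "exact" if (len(pooled) <= EXACT_MAX_N and no_ties) \
            else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvals, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def rank_metabolites(matrix: MetaboliteMatrix, labels,
                     group_a=0, group_b=1) -> pd.DataFrame:
    """Per-metabolite rank-sum tests between two cluster labels.

    Returns a DataFrame indexed by metabolite with columns statistic, p,
    adj_p, rank (by adjusted then raw p), mean_z_a, mean_z_b, and the
    library annotations where available.
    """
    labels = np.asarray(labels)
    in_a = labels == group_a
    in_b = labels == group_b
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValueError("both clusters must be non-empty")
    X = matrix.data.to_numpy(float)
    stats_, ps = [], []
    for j in range(X.shape[1]):
        s, p = wilcoxon_rank_sum(X[in_a, j], X[in_b, j])
        stats_.append(s)
        ps.append(p)
    out = pd.DataFrame({
        "statistic": stats_,
        "p": ps,
        "adj_p": bh_adjust(ps),
        "mean_z_a": X[in_a].mean(axis=0),
        "mean_z_b": X[in_b].mean(axis=0),
    }, index=matrix.data.columns)
    order = np.lexsort((out["p"].to_numpy(), out["adj_p"].to_numpy()))
    ranks = np.empty(len(out), dtype=int)
    ranks[order] = np.arange(1, len(out) + 1)
    out["rank"] = ranks
    if not matrix.annotations.empty:
        ann_cols = [c for c in ("name", "mz", "rt", "mode", "adduct")
                    if c in matrix.annotations.columns]
        out = out.join(matrix.annotations[ann_cols], how="left")
    return out.sort_values("rank")


def rank_and_select(results: pd.DataFrame,
                    adj_p_threshold: float = ADJ_P_THRESHOLD,
                    top_fraction: float | None = None) -> pd.DataFrame:
    """Flag the selected metabolite set.

    Selection is adjusted-p driven (``adj_p < adj_p_threshold``); when
    ``top_fraction`` is given instead, the top fraction by rank is taken.
    The implied selected fraction is attached as ``results.attrs``.
    """
    out = results.copy()
    if top_fraction is not None:
        n_sel = int(round(top_fraction * len(out)))
        out["selected"] = out["rank"] <= n_sel
    else:
        out["selected"] = out["adj_p"] < adj_p_threshold
    out.attrs["n_selected"] = int(out["selected"].sum())
    out.attrs["selected_fraction"] = float(out["selected"].mean()) if len(out) \
        else 0.0
    return out
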