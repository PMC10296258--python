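"""Background-constrained pathway over-representation by Pearson chi-squared.

A selected metabolite set of size T drawn from an assayed background of N
metabolites is tested, pathway by pathway, against the 2x2 table

    [[k, m - k], [T - k, N - m - T + k]]

where m is the pathway's membership within the background and k its overlap
with the selected set. The statistic is the uncorrected Pearson chi-squared
with one degree of freedom and an upper-tail p; the enrichment direction
(enriched vs depleted relative to the expected hit count m*T/N) is reported
separately from the two-sided p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PathwayMap


@dataclass
class EnrichmentRow:
    pathway: str
    N: int
    T: int
    m: int
    k: int
    chi2: float
    df: int
    p: float
    direction: str
    expected: float
    low_count: bool


# ------------------------------------------------------------------- GMT IO

def read_gmt(path) -> PathwayMap:
    """Read a GMT file (pathway<TAB>description<TAB>member...)."""
    pmap: PathwayMap = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member")
            name, members = parts[0], [m for m in parts[2:] if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: pathway {name!r} is empty")
            pmap[name] = set(members)
    return pmap


def write_gmt(pmap: PathwayMap, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in pmap.items():
            desc = (descriptions or {}).get(name, "synthetic")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ------------------------------------------------------------------ testing

def enrichment_chisq(N: int, T: int, m: int, k: int
                     ) -> tuple[float, int, float, str, bool]:
    """Pearson chi-squared (no continuity correction) for one pathway.

    Returns (chi2, df, upper-tail p, direction, low_count flag); the flag is
    set when any expected cell count falls below 1.
    """
    if not 0 < m < N:
        raise ValueError("need 0 < m < N (pathway margin degenerate)")
    if not 0 < T < N:
        raise ValueError("need 0 < T < N (selected-set margin degenerate)")
    if k > min(m, T) or k < max(0, m + T - N):
        raise ValueError("impossible hit count for the given margins")
    table = np.array([[k, m - k], [T - k, N - m - T + k]], float)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    expected = rowsum * colsum / N
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    exp_hits = m * T / N
    direction = "enriched" if k > exp_hits else (
        "depleted" if k < exp_hits else "as-expected")
    low_count = bool((expected < 1).any())
    return chi2, 1, p, direction, low_count


def enrich_all(selected, background, pathway_map: PathwayMap) -> pd.DataFrame:
    """Chi-squared enrichment of every pathway with background members.

    ``selected`` must be a subset of ``background``; pathways with no
    member inside the background are skipped (listed in ``attrs``). Rows
    are sorted by ascending p.
    """
    selected = set(selected)
    background = set(background)
    stray = selected - background
    if stray:
        raise ValueError(
            f"selected metabolites outside the background: {sorted(stray)}")
    N, T = len(background), len(selected)
    rows, skipped = [], []
    for name, members in pathway_map.items():
        m = len(members & background)
        if m == 0:
            skipped.append(name)
            continue
        k = len(members & selected)
        chi2, df, p, direction, low = enrichment_chisq(N, T, m, k)
        rows.append(EnrichmentRow(name, N, T, m, k, chi2, df, p, direction,
                                  m * T / N, low))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if len(out):
        out = out.sort_values(["p", "pathway"], kind="stable",
                              ignore_index=True)
    out.attrs["skipped"] = skipped
    return out
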