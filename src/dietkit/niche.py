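"""Bivariate (δ13C, δ15N) isotopic niche metrics and lipid screening.

The six Eltonian niche characteristics (ENCs) summarise a population's
scatter in δ13C–δ15N space:

* CR, NR — carbon and nitrogen ranges (max − min, ‰);
* TA — total area of the convex hull (‰²), the occupied niche space;
* CD — mean Euclidean distance of individuals to the group centroid (‰),
  a measure of trophic diversity;
* MNND — mean distance from each individual to its nearest neighbour (‰),
  and SDNND its sample standard deviation, describing packing/evenness.

High lipid content biases δ13C, so tissue samples whose C:N weight ratio
exceeds 3.5 are screened out before computing the metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .data import IsotopeRecord

__all__ = [
    "ENCResult",
    "lipid_filter",
    "convex_hull_area",
    "layman_metrics",
    "group_enc_table",
]


@dataclass
class ENCResult:
    """Six niche metrics for one group of fish."""

    group: tuple
    n: int
    CR: float
    NR: float
    TA: float | None  # None when n < 3 leaves the hull undefined
    CD: float
    MNND: float
    SDNND: float


def lipid_filter(
    records: list[IsotopeRecord], cn_max: float = 3.5, strict: bool = False
) -> tuple[list[IsotopeRecord], pd.DataFrame]:
    """Screen out lipid-biased samples: C:N ratio strictly greater than ``cn_max``.

    A sample at exactly the threshold is retained.  Records lacking a C:N
    ratio are retained with a warning (rejected when ``strict``).  Returns
    (retained records, per-group exclusion report).
    """
    retained, rows = [], {}
    for rec in records:
        key = rec.group
        rows.setdefault(key, {"group": key, "n_in": 0, "n_excluded": 0, "n_missing_cn": 0})
        rows[key]["n_in"] += 1
        if rec.cn_ratio is None:
            rows[key]["n_missing_cn"] += 1
            if strict:
                rows[key]["n_excluded"] += 1
                continue
            warnings.warn(f"fish {rec.fish_id}: missing C:N ratio; retained", stacklevel=2)
            retained.append(rec)
        elif rec.cn_ratio > cn_max:
            rows[key]["n_excluded"] += 1
        else:
            retained.append(rec)
    return retained, pd.DataFrame(rows.values())


def convex_hull_area(points: np.ndarray) -> float:
    """Area of the planar convex hull; 0 for fewer than 3 points or collinear sets."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # in 2-D, .volume is the area
    except QhullError:
        return 0.0  # degenerate (collinear / coincident) point sets


def layman_metrics(points: np.ndarray, group: tuple = ()) -> ENCResult:
    """The six ENCs for one set of (δ13C, δ15N) points; requires n ≥ 2.

    TA is None for n < 3 (the hull is undefined, not zero-area by sampling).
    SDNND uses the n−1 sample standard deviation of nearest-neighbour
    distances (0 when n = 2).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points")
    cr = float(pts[:, 0].max() - pts[:, 0].min())
    nr = float(pts[:, 1].max() - pts[:, 1].min())
    ta = convex_hull_area(pts) if n >= 3 else None
    centroid = pts.mean(axis=0)
    cd = float(np.linalg.norm(pts - centroid, axis=1).mean())
    d = squareform(pdist(pts))
    np.fill_diagonal(d, np.inf)  # a point is never its own neighbour
    nnd = d.min(axis=1)
    mnnd = float(nnd.mean())
    sdnnd = float(np.std(nnd, ddof=1)) if n > 2 else 0.0
    return ENCResult(group=group, n=n, CR=cr, NR=nr, TA=ta, CD=cd, MNND=mnnd, SDNND=sdnnd)


def group_enc_table(
    records: list[IsotopeRecord], grouping: tuple[str, ...] = ("location", "year")
) -> pd.DataFrame:
    """One row of ENCs per group (e.g. location × year); TA is NaN when n < 3."""
    df = pd.DataFrame(
        {
            "d13C": [r.d13C for r in records],
            "d15N": [r.d15N for r in records],
            **{k: [getattr(r, k) for r in records] for k in grouping},
        }
    )
    rows = []
    for key, sub in df.groupby(list(grouping), dropna=False, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        pts = sub[["d13C", "d15N"]].to_numpy()
        if len(pts) < 2:
            warnings.warn(f"group {key}: fewer than 2 samples; skipped", stacklevel=2)
            continue
        enc = layman_metrics(pts, group=key)
        rows.append(
            {
                **dict(zip(grouping, key)),
                "n": enc.n,
                "CR": enc.CR,
                "NR": enc.NR,
                "TA": np.nan if enc.TA is None else enc.TA,
                "CD": enc.CD,
                "MNND": enc.MNND,
                "SDNND": enc.SDNND,
            }
        )
    return pd.DataFrame(rows)
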