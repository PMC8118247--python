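"""Distance-based multivariate analysis of diet composition.

Implements the McArdle–Anderson distance-based linear-model family on a
Bray-Curtis (or Euclidean) dissimilarity matrix:

* PERMANOVA with sequential (Type I) sums of squares over an ordered list of
  model terms, pseudo-F statistics, and permutation p-values obtained by free
  permutation of observation labels;
* forward stepwise model building (largest pseudo-F among candidates whose
  permutation p-value clears the entry threshold);
* PERMDISP — permutation test of homogeneity of multivariate group
  dispersions (distances to group centroids in principal-coordinate space);
* CAP / db-RDA — constrained ordination of the principal coordinates on an
  explanatory design, with per-axis eigenvalues, permutation tests, and
  biplot scores.

The machinery works on the Gower-centered matrix G = −½ J D² J (J the
centering projector).  For any hat matrix H of a design, the explained sum of
squares is tr(HG); permuting observation labels permutes G symmetrically.
Bray-Curtis is non-Euclidean, so G can have negative eigenvalues; axes with
negative eigenvalues are discarded for PERMDISP and CAP and the discarded
share of inertia is logged.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

logger = logging.getLogger("dietkit")

__all__ = [
    "DistanceMatrix",
    "PermanovaTable",
    "ForwardSelectionResult",
    "PermdispResult",
    "CapResult",
    "bray_curtis",
    "euclidean_distance",
    "covariate_screen",
    "permanova",
    "forward_select",
    "permdisp",
    "cap",
]

_EIG_TOL = 1e-8


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with observation ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValueError("distance matrix must be square and match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = d

    @property
    def n(self) -> int:
        return len(self.ids)


def bray_curtis(composition: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between composition rows (e.g. per-stomach %N).

    d_ij = Σ|x_i − x_j| / Σ(x_i + x_j) over prey categories; 0 for identical
    rows, 1 for disjoint prey spectra.
    """
    x = composition.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if np.any(x.sum(axis=1) == 0):
        bad = composition.index[x.sum(axis=1) == 0][0]
        raise ValueError(f"all-zero composition row {bad!r}; exclude empty records first")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(ids=[str(i) for i in composition.index], values=d)


def euclidean_distance(data: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances; mainly for closed-form cross-checks against ANOVA."""
    d = squareform(pdist(data.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(ids=[str(i) for i in data.index], values=d)


def gower_center(d: np.ndarray) -> np.ndarray:
    """G = −½ J D² J with J = I − 11'/n; tr(G) is the total sum of squares."""
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


# ---------------------------------------------------------------------------
# design matrices


def _encode_variable(col: pd.Series) -> np.ndarray:
    """Main-effect coding: treatment dummies (drop first level) or the numeric column."""
    if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
        return col.to_numpy(dtype=float).reshape(-1, 1)
    levels = sorted(col.astype(str).unique())
    return np.column_stack([(col.astype(str) == lv).astype(float) for lv in levels[1:]]) if len(
        levels
    ) > 1 else np.zeros((len(col), 0))


def term_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Model-matrix columns for a term; ``a:b`` denotes an interaction."""
    parts = term.split(":")
    blocks = []
    for p in parts:
        if p not in metadata.columns:
            raise KeyError(f"term {term!r}: variable {p!r} not in metadata")
        blocks.append(_encode_variable(metadata[p]))
    cols = blocks[0]
    for b in blocks[1:]:
        cols = np.concatenate(
            [cols[:, i : i + 1] * b for i in range(cols.shape[1])], axis=1
        ) if cols.shape[1] and b.shape[1] else np.zeros((len(metadata), 0))
    return cols


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal-projection (hat) matrix onto col span of [1, x]; returns (H, rank)."""
    n = x.shape[0]
    full = np.column_stack([np.ones(n), x])
    q, r = np.linalg.qr(full)
    keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


# ---------------------------------------------------------------------------
# covariate screening


def covariate_screen(
    metadata: pd.DataFrame,
    candidates: list[str] | None = None,
    r_threshold: float = 0.65,
    alpha: float = 0.05,
    priority: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop one of each highly correlated covariate pair (|r| > threshold, p < alpha).

    For a flagged pair the variable appearing *later* in ``priority`` (default:
    the candidate order) is dropped.  Constant covariates are dropped with a
    warning.  Returns (retained, report) where the report lists every pairwise
    decision.
    """
    if candidates is None:
        candidates = [c for c in metadata.columns if pd.api.types.is_numeric_dtype(metadata[c])]
    priority = priority or list(candidates)
    rank = {c: priority.index(c) if c in priority else len(priority) for c in candidates}

    retained = []
    for c in candidates:
        if metadata[c].nunique() <= 1:
            warnings.warn(f"covariate {c!r} is constant; dropped", stacklevel=2)
        else:
            retained.append(c)

    rows = []
    dropped: set[str] = set()
    for a, b in itertools.combinations(sorted(retained, key=lambda c: rank[c]), 2):
        r, p = pearsonr(metadata[a].to_numpy(float), metadata[b].to_numpy(float))
        flagged = abs(r) > r_threshold and p < alpha
        action = ""
        if flagged and a not in dropped and b not in dropped:
            loser = b if rank[a] <= rank[b] else a
            dropped.add(loser)
            action = f"dropped {loser}"
        rows.append({"var_a": a, "var_b": b, "r": r, "p": p, "flagged": flagged, "action": action})
    report = pd.DataFrame(rows, columns=["var_a", "var_b", "r", "p", "flagged", "action"])
    return [c for c in retained if c not in dropped], report


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaTable:
    """Sequential-SS pseudo-F table with permutation p-values."""

    table: pd.DataFrame  # index: terms + Residual + Total; columns df, SS, F, r2, p
    permutations: int
    seed: int | None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string()


def _sequential_ss(g: np.ndarray, hats: list[np.ndarray]) -> np.ndarray:
    """tr(H_t G) − tr(H_{t−1} G) for the nested hat sequence (H_0 = intercept ⇒ 0)."""
    traces = np.array([(h * g).sum() for h in hats])
    prev = np.concatenate([[0.0], traces[:-1]])
    return traces - prev


def _permutation_indices(
    n: int, permutations: int | str, rng: np.random.Generator
) -> list[np.ndarray]:
    if permutations == "exact":
        if n > 8:
            raise ValueError("exact enumeration only supported for n <= 8")
        return [np.array(p) for p in itertools.permutations(range(n))]
    return [rng.permutation(n) for _ in range(int(permutations))]


def permanova(
    dist: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str],
    permutations: int | str = 999,
    seed: int | None = None,
) -> PermanovaTable:
    """PERMANOVA with sequential sums of squares over ordered ``terms``.

    ``permutations="exact"`` enumerates all n! label orderings (small n only)
    and reports p = #{F* ≥ F}/n!; otherwise p = (b + 1)/(m + 1) over m random
    free permutations of observation labels, b the count of permuted pseudo-F
    values at or above the observed one.
    """
    n = dist.n
    meta = metadata.loc[[i for i in dist.ids]] if set(dist.ids) <= set(
        map(str, metadata.index)
    ) else metadata
    if len(meta) != n or meta.isna().any().any():
        raise ValueError("metadata must match the distance matrix with no missing values")
    g = gower_center(dist.values)
    ss_total = float(np.trace(g))

    hats, dfs = [], []
    x: np.ndarray | None = None
    prev_rank = 1  # intercept
    for t in terms:
        cols = term_columns(meta, t)
        x = cols if x is None else np.column_stack([x, cols])
        h, rank = _hat(x)
        df_t = rank - prev_rank
        if df_t == 0:
            raise ValueError(f"term {t!r} is aliased with earlier terms (singular design)")
        hats.append(h)
        dfs.append(df_t)
        prev_rank = rank
    df_res = n - prev_rank
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    ss = _sequential_ss(g, hats)
    ss_res = ss_total - float((hats[-1] * g).sum())
    f_obs = (ss / np.array(dfs)) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    perms = _permutation_indices(n, permutations, rng)
    exceed = np.zeros(len(terms))
    for p in perms:
        gp = g[np.ix_(p, p)]
        ss_p = _sequential_ss(gp, hats)
        ss_res_p = ss_total - float((hats[-1] * gp).sum())
        f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_res)
        exceed += f_p >= f_obs - 1e-12
    if permutations == "exact":
        pvals = exceed / len(perms)
        m = len(perms)
    else:
        pvals = (exceed + 1) / (len(perms) + 1)
        m = len(perms)

    table = pd.DataFrame(
        {
            "df": dfs + [df_res, n - 1],
            "SS": list(ss) + [ss_res, ss_total],
            "F": list(f_obs) + [np.nan, np.nan],
            "r2": list(ss / ss_total) + [ss_res / ss_total, 1.0],
            "p": list(pvals) + [np.nan, np.nan],
        },
        index=terms + ["Residual", "Total"],
    )
    return PermanovaTable(table=table, permutations=m, seed=seed)


@dataclass
class ForwardSelectionResult:
    order: list[str]
    steps: pd.DataFrame  # per-step candidate F and p
    table: pd.DataFrame | None  # final PERMANOVA table re-ranked by F
    permutations: int
    seed: int | None


def forward_select(
    dist: DistanceMatrix,
    metadata: pd.DataFrame,
    candidates: list[str],
    permutations: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    max_terms: int | None = None,
) -> ForwardSelectionResult:
    """Forward stepwise PERMANOVA model building.

    At each step every remaining candidate is tested conditional on the terms
    already entered (its sequential SS when added last); the candidate with
    the largest pseudo-F among those with permutation p ≤ ``alpha`` enters
    (ties broken alphabetically).  Stops when no candidate qualifies or after
    ``max_terms`` entries.  The final table is the sequential PERMANOVA of the
    selected terms, re-ranked by descending F.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    n = dist.n
    g = gower_center(dist.values)
    ss_total = float(np.trace(g))
    rng = np.random.default_rng(seed)

    selected: list[str] = []
    x_sel: np.ndarray | None = None
    h_sel = np.full((n, n), 1.0 / n)
    rank_sel = 1
    step_rows = []

    while candidates and (max_terms is None or len(selected) < max_terms):
        perms = [rng.permutation(n) for _ in range(permutations)]
        gps = [g[np.ix_(p, p)] for p in perms]
        best: tuple[float, str] | None = None
        tr_sel = float((h_sel * g).sum())
        tr_sel_p = [float((h_sel * gp).sum()) for gp in gps]
        for cand in sorted(candidates):
            cols = term_columns(metadata, cand)
            x_c = cols if x_sel is None else np.column_stack([x_sel, cols])
            h_c, rank_c = _hat(x_c)
            df_c = rank_c - rank_sel
            if df_c == 0:
                step_rows.append(
                    {"step": len(selected) + 1, "candidate": cand, "F": 0.0, "p": 1.0,
                     "entered": False, "note": "aliased"}
                )
                continue
            df_res = n - rank_c
            ss_c = float((h_c * g).sum()) - tr_sel
            ss_res = ss_total - float((h_c * g).sum())
            f_obs = (ss_c / df_c) / (ss_res / df_res)
            exceed = 0
            for gp, tsp in zip(gps, tr_sel_p):
                ss_cp = float((h_c * gp).sum()) - tsp
                ss_rp = ss_total - float((h_c * gp).sum())
                if (ss_cp / df_c) / (ss_rp / df_res) >= f_obs - 1e-12:
                    exceed += 1
            p_c = (exceed + 1) / (permutations + 1)
            step_rows.append(
                {"step": len(selected) + 1, "candidate": cand, "F": f_obs, "p": p_c,
                 "entered": False, "note": ""}
            )
            if p_c <= alpha and (best is None or f_obs > best[0]):
                best = (f_obs, cand)
        if best is None:
            break
        _, chosen = best
        for row in step_rows:
            if row["step"] == len(selected) + 1 and row["candidate"] == chosen:
                row["entered"] = True
        selected.append(chosen)
        candidates = [c for c in candidates if c != chosen]
        cols = term_columns(metadata, chosen)
        x_sel = cols if x_sel is None else np.column_stack([x_sel, cols])
        h_sel, rank_sel = _hat(x_sel)

    table = None
    if selected:
        final = permanova(dist, metadata, selected, permutations=permutations, seed=seed)
        terms_ranked = (
            final.table.drop(index=["Residual", "Total"]).sort_values("F", ascending=False).index
        )
        table = final.table.loc[list(terms_ranked) + ["Residual", "Total"]]
    return ForwardSelectionResult(
        order=selected,
        steps=pd.DataFrame(step_rows),
        table=table,
        permutations=permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# principal coordinates, PERMDISP, CAP


def pcoa_coordinates(dist: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding retaining positive-eigenvalue axes.

    Returns (coordinates n×m, eigenvalues m).  The share of inertia carried by
    discarded negative eigenvalues is logged (Bray-Curtis is non-Euclidean).
    """
    g = gower_center(dist.values)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > _EIG_TOL * max(1.0, eigval.max())
    neg_share = float(np.abs(eigval[eigval < 0]).sum() / np.abs(eigval).sum()) if np.abs(
        eigval
    ).sum() > 0 else 0.0
    if neg_share > 0:
        logger.info("PCoA: discarding %.1f%% of inertia on negative eigenvalues", 100 * neg_share)
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    return coords, eigval[pos]


@dataclass
class PermdispResult:
    f: float
    p: float
    group_dispersion: pd.Series
    permutations: int
    seed: int | None


def permdisp(
    dist: DistanceMatrix,
    grouping: pd.Series | np.ndarray,
    permutations: int = 999,
    seed: int | None = None,
) -> PermdispResult:
    """Permutation test of homogeneity of multivariate group dispersions.

    Dispersion of an observation is its distance to its group centroid in the
    positive principal-coordinate space; the test statistic is the one-way
    ANOVA F on those distances, with p from permutation of group labels.
    Groups of size 1 are excluded with a warning.
    """
    groups = np.asarray(pd.Series(grouping).astype(str))
    coords, _ = pcoa_coordinates(dist)
    sizes = pd.Series(groups).value_counts()
    small = sizes[sizes < 2].index
    if len(small):
        warnings.warn(f"groups of size 1 excluded: {list(small)}", stacklevel=2)
        keep = ~np.isin(groups, small)
        coords, groups = coords[keep], groups[keep]
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")

    def distances_to_centroids(lab: np.ndarray) -> np.ndarray:
        out = np.empty(len(lab))
        for lv in np.unique(lab):
            mask = lab == lv
            cent = coords[mask].mean(axis=0)
            out[mask] = np.linalg.norm(coords[mask] - cent, axis=1)
        return out

    def anova_f(z: np.ndarray, lab: np.ndarray) -> float:
        grand = z.mean()
        ss_b = sum(
            (lab == lv).sum() * (z[lab == lv].mean() - grand) ** 2 for lv in np.unique(lab)
        )
        ss_w = sum(((z[lab == lv] - z[lab == lv].mean()) ** 2).sum() for lv in np.unique(lab))
        df_b, df_w = len(np.unique(lab)) - 1, len(z) - len(np.unique(lab))
        return float((ss_b / df_b) / (ss_w / df_w))

    z_obs = distances_to_centroids(groups)
    f_obs = anova_f(z_obs, groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        lab_p = groups[rng.permutation(len(groups))]
        # betadisper-style: recompute centroids and distances under permuted labels
        z_p = distances_to_centroids(lab_p)
        if anova_f(z_p, lab_p) >= f_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (permutations + 1)
    disp = pd.Series(
        {lv: float(z_obs[groups == lv].mean()) for lv in labels}, name="mean_dispersion"
    )
    return PermdispResult(f=f_obs, p=p, group_dispersion=disp, permutations=permutations, seed=seed)


@dataclass
class CapResult:
    eigenvalues: np.ndarray
    pct_variance: np.ndarray  # per canonical axis, of total inertia
    explained_pct: float  # whole model, of total inertia
    overall_f: float
    overall_p: float
    axis_f: np.ndarray
    axis_p: np.ndarray
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame | None
    variable_scores: pd.DataFrame
    permutations: int
    seed: int | None


def cap(
    dist: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str],
    permutations: int = 999,
    seed: int | None = None,
    composition: pd.DataFrame | None = None,
    n_axes: int | None = None,
) -> CapResult:
    """Constrained ordination (CAP / db-RDA) of a distance matrix on a design.

    Principal coordinates are regressed on the design; canonical axes are the
    eigenvectors of the fitted values' covariance.  Axis percent variance is
    the canonical eigenvalue over total (positive) inertia; overall and
    per-axis pseudo-F values get p-values by free permutation of observation
    labels.  Biplot scores: correlations of composition columns (prey
    categories) and continuous design variables with the site scores, and
    level centroids for factors.
    """
    coords, _ = pcoa_coordinates(dist)
    n, m = coords.shape
    x = np.column_stack([term_columns(metadata, t) for t in terms])
    h, rank = _hat(x)
    q = rank - 1  # constrained df (intercept excluded; coords are centered)
    if n - q - 1 <= 0:
        raise ValueError("more design columns than observations leave no residual df")
    if q < 1:
        raise ValueError("design has no non-constant columns")

    total_inertia = float((coords**2).sum())

    def canonical(coords_: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        fitted = h @ coords_
        cov = fitted.T @ fitted
        lam, vec = np.linalg.eigh(cov)
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
        keep = lam > _EIG_TOL * max(1.0, lam.max())
        return lam[np.where(keep)[0][: min(q, keep.sum())]], vec[:, np.where(keep)[0][: min(q, keep.sum())]]

    lam, vec = canonical(coords)
    if n_axes is not None:
        lam, vec = lam[:n_axes], vec[:, :n_axes]
    ss_constrained = float(lam.sum())
    ss_resid = total_inertia - ss_constrained
    df_res = n - q - 1
    overall_f = (ss_constrained / q) / (ss_resid / df_res)
    axis_f = lam / (ss_resid / df_res)

    rng = np.random.default_rng(seed)
    exceed_overall = 0
    exceed_axis = np.zeros(len(lam))
    for _ in range(permutations):
        perm = rng.permutation(n)
        lam_p, _ = canonical(coords[perm])
        ss_c_p = float(lam_p.sum())
        f_p = (ss_c_p / q) / ((total_inertia - ss_c_p) / df_res)
        if f_p >= overall_f - 1e-12:
            exceed_overall += 1
        k = min(len(lam), len(lam_p))
        resid_p = (total_inertia - ss_c_p) / df_res
        exceed_axis[:k] += (lam_p[:k] / resid_p) >= (axis_f[:k] - 1e-12)
    overall_p = (exceed_overall + 1) / (permutations + 1)
    axis_p = (exceed_axis + 1) / (permutations + 1)

    site = coords @ vec  # weighted-sums site scores
    axis_names = [f"CAP{i + 1}" for i in range(site.shape[1])]
    site_scores = pd.DataFrame(site, index=dist.ids, columns=axis_names)

    species_scores = None
    if composition is not None:
        comp = composition.loc[[i for i in dist.ids]] if set(dist.ids) <= set(
            map(str, composition.index)
        ) else composition
        cc = comp.to_numpy(float)
        species_scores = pd.DataFrame(
            _corr_columns(cc, site), index=comp.columns, columns=axis_names
        )

    var_rows = {}
    for t in terms:
        for p_ in t.split(":"):
            if p_ in var_rows:
                continue
            col = metadata[p_]
            if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
                var_rows[p_] = _corr_columns(col.to_numpy(float).reshape(-1, 1), site)[0]
            else:
                for lv in sorted(col.astype(str).unique()):
                    mask = (col.astype(str) == lv).to_numpy()
                    var_rows[f"{p_}={lv}"] = site[mask].mean(axis=0)
    variable_scores = pd.DataFrame(var_rows, index=axis_names).T

    return CapResult(
        eigenvalues=lam,
        pct_variance=100.0 * lam / total_inertia,
        explained_pct=100.0 * ss_constrained / total_inertia,
        overall_f=overall_f,
        overall_p=overall_p,
        axis_f=axis_f,
        axis_p=axis_p,
        site_scores=site_scores,
        species_scores=species_scores,
        variable_scores=variable_scores,
        permutations=permutations,
        seed=seed,
    )


def _corr_columns(x: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of x with each score axis (0 for constants)."""
    out = np.zeros((x.shape[1], scores.shape[1]))
    for i in range(x.shape[1]):
        xi = x[:, i]
        if xi.std() == 0:
            continue
        for a in range(scores.shape[1]):
            sa = scores[:, a]
            if sa.std() == 0:
                continue
            out[i, a] = np.corrcoef(xi, sa)[0, 1]
    return out
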