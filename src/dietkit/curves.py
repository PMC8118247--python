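"""Randomized cumulative prey curves and the endpoint-slope sufficiency test.

A cumulative prey curve plots the expected number of distinct prey categories
against the number of stomachs examined, averaging over random orderings of
the stomachs.  When the curve flattens, additional sampling yields few new
prey types and the sample is judged sufficient to describe the diet.  The
criterion used here is the ordinary-least-squares slope over the last five
points of the mean curve: b ≤ 0.05 prey categories per stomach counts as
having reached an asymptote.

The exact expectation of richness after k of n stomachs has the classical
hypergeometric closed form

    E[S_k] = S_obs − Σ_i C(n − n_i, k) / C(n, k),

where n_i is the number of stomachs containing prey i — the same quantity the
randomized curve estimates, available here both as an analytic option and as
the oracle the randomized estimator is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .data import DietDataset

__all__ = [
    "AccumulationCurve",
    "accumulation_curve",
    "expected_richness_exact",
    "endpoint_slope",
    "sufficiency",
]


@dataclass
class AccumulationCurve:
    """Mean ± sd prey richness as a function of stomachs sampled."""

    mean_richness: np.ndarray
    sd_richness: np.ndarray
    permutations: int
    seed: int | None

    @property
    def n_points(self) -> int:
        return len(self.mean_richness)


def _presence_matrix(dataset: DietDataset) -> np.ndarray:
    counts, weights = dataset.to_frames(full_only=True)
    present = ((counts.values > 0) | (weights.values > 0))
    return present[:, present.any(axis=0)]  # drop never-seen prey


def accumulation_curve(
    dataset: DietDataset, permutations: int = 999, seed: int | None = None
) -> AccumulationCurve:
    """Randomized cumulative prey curve over ``permutations`` stomach orderings.

    Deterministic given (seed, permutations).  The final mean equals the
    observed richness exactly: every ordering ends with all stomachs included.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    present = _presence_matrix(dataset)
    n = present.shape[0]
    if n < 2:
        raise ValueError("need at least 2 full stomachs")
    rng = np.random.default_rng(seed)
    richness = np.empty((permutations, n))
    for p in range(permutations):
        order = rng.permutation(n)
        seen = np.maximum.accumulate(present[order], axis=0)
        richness[p] = seen.sum(axis=1)
    return AccumulationCurve(
        mean_richness=richness.mean(axis=0),
        sd_richness=richness.std(axis=0, ddof=1),
        permutations=permutations,
        seed=seed,
    )


def expected_richness_exact(dataset: DietDataset) -> np.ndarray:
    """Analytic mean curve: hypergeometric expectation of richness at each k."""
    present = _presence_matrix(dataset)
    n = present.shape[0]
    n_i = present.sum(axis=0)  # stomachs containing each prey
    k = np.arange(1, n + 1)

    def log_comb(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.empty(n)
    for idx, kk in enumerate(k):
        miss = n - n_i  # stomachs not containing prey i
        valid = miss >= kk
        p_absent = np.zeros_like(n_i, dtype=float)
        p_absent[valid] = np.exp(log_comb(miss[valid], kk) - log_comb(np.array(n), kk))
        out[idx] = (1.0 - p_absent).sum()
    return out


def endpoint_slope(curve: AccumulationCurve | np.ndarray, k_last: int = 5) -> float:
    """OLS slope (prey categories per stomach) over the final ``k_last`` mean points."""
    mean = curve.mean_richness if isinstance(curve, AccumulationCurve) else np.asarray(curve)
    if len(mean) < k_last:
        raise ValueError(f"curve has {len(mean)} points; need at least k_last={k_last}")
    y = mean[-k_last:]
    x = np.arange(k_last, dtype=float)
    x = x - x.mean()
    return float((x * (y - y.mean())).sum() / (x * x).sum())


def sufficiency(b: float, threshold: float = 0.05) -> bool:
    """Sample sufficiency: True iff the endpoint slope b ≤ threshold (inclusive)."""
    if not np.isfinite(b):
        raise ValueError("slope must be finite")
    return bool(b <= threshold)
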