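"""Prey-specific diet index family: %N, %W, %PN, %PW, %FO, %PSIRI.

All six indices are computed over the *full* stomachs of a stratum (empty
stomachs never enter a denominator).  For prey category *i*:

* %FO_i  — percentage of full stomachs in which *i* occurs (by count or weight);
* %PN_i, %PW_i — mean per-stomach percentage of *i* by number / weight, averaged
  over only the stomachs that contain *i* ("prey-specific" abundance);
* %N_i, %W_i — the same means taken over all full stomachs (zeros included),
  so %N_i = %PN_i × %FO_i / 100 exactly, and likewise for weight;
* %PSIRI_i = %FO_i × (%PN_i + %PW_i) / 200 = (%N_i + %W_i) / 2.

%N, %W and %PSIRI each sum to 100 over prey categories and are additive under
category merging, which makes %PSIRI comparable across taxonomic levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .data import DietDataset, PreyCategory

__all__ = [
    "DietMetricsTable",
    "per_stomach_proportions",
    "frequency_of_occurrence",
    "prey_specific_abundance",
    "mean_percent_abundance",
    "psiri",
    "psiri_by_stratum",
    "additivity_check",
    "round_half_away",
    "pct_n_from_identity",
    "psiri_from_identity",
]

Basis = Literal["number", "weight"]

_IDENTITY_TOL = 1e-9


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used for display tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def pct_n_from_identity(pct_pn: float, pct_fo: float) -> float:
    """Reconstruct mean percent abundance from its prey-specific form: %PN × %FO / 100."""
    return pct_pn * pct_fo / 100.0


def psiri_from_identity(pct_pn: float, pct_pw: float, pct_fo: float) -> float:
    """Reconstruct %PSIRI from prey-specific abundances: (%PN + %PW) × %FO / 200."""
    return (pct_pn + pct_pw) * pct_fo / 200.0


@dataclass
class DietMetricsTable:
    """Per-prey diet indices for one stratum, sorted by descending %PSIRI."""

    stratum: str
    n_stomachs: int
    table: pd.DataFrame  # columns pctN, pctPN, pctW, pctPW, pctFO, pctPSIRI
    taxonomy: list[PreyCategory] = field(default_factory=list)

    def rounded(self, decimals: int = 1) -> pd.DataFrame:
        """Display form: half-away-from-zero rounding of the unrounded values."""
        return self.table.map(lambda v: round_half_away(v, decimals))


def _basis_frame(dataset: DietDataset, basis: Basis) -> pd.DataFrame:
    counts, weights = dataset.to_frames(full_only=True)
    if basis == "number":
        return counts
    if basis == "weight":
        return weights
    raise ValueError(f"unknown basis {basis!r}")


def per_stomach_proportions(dataset: DietDataset, basis: Basis) -> pd.DataFrame:
    """Per-stomach composition in percent; every retained row sums to 100.

    Full stomachs whose total is zero on the chosen basis (possible for the
    weight basis when all item weights round to 0) are dropped with a warning.
    """
    x = _basis_frame(dataset, basis)
    totals = x.sum(axis=1)
    zero = totals == 0
    if zero.any():
        import warnings

        warnings.warn(
            f"{int(zero.sum())} record(s) with zero total on basis={basis}; excluded",
            stacklevel=2,
        )
        x, totals = x[~zero], totals[~zero]
    return x.div(totals, axis=0) * 100.0


def frequency_of_occurrence(dataset: DietDataset) -> pd.Series:
    """%FO per prey: share of full stomachs where the prey is present.

    Presence means count > 0 OR weight > 0, so heavily digested items counted
    only by weight still register an occurrence.
    """
    counts, weights = dataset.to_frames(full_only=True)
    present = (counts > 0) | (weights > 0)
    n_full = len(counts)
    if n_full == 0:
        raise ValueError("no full stomachs in dataset")
    fo = present.sum(axis=0) / n_full * 100.0
    fo.name = "pctFO"
    return fo


def prey_specific_abundance(dataset: DietDataset, basis: Basis) -> pd.Series:
    """%PN or %PW: mean per-stomach percentage over only stomachs containing the prey."""
    props = per_stomach_proportions(dataset, basis)
    counts, weights = dataset.to_frames(full_only=True)
    present = ((counts > 0) | (weights > 0)).loc[props.index]
    out = props.where(present).mean(axis=0).fillna(0.0)
    out.name = "pctPN" if basis == "number" else "pctPW"
    return out


def mean_percent_abundance(dataset: DietDataset, basis: Basis) -> pd.Series:
    """%N or %W: mean per-stomach percentage over ALL full stomachs (zeros included).

    Computed directly and via the prey-specific identity %PN × %FO / 100; the
    two routes must agree to within numerical tolerance.
    """
    props = per_stomach_proportions(dataset, basis)
    counts, weights = dataset.to_frames(full_only=True)
    n_full = len(counts)
    direct = props.sum(axis=0) / n_full
    # independent route via the prey-specific identity %PN × %FO / 100, with
    # occurrence restricted to the rows that entered the proportions
    present = ((counts > 0) | (weights > 0)).loc[props.index]
    pn = props.where(present).mean(axis=0).fillna(0.0)
    fo = present.sum(axis=0) / n_full * 100.0
    via_identity = pct_n_from_identity(pn, fo)
    if not np.allclose(direct.values, via_identity.values, atol=_IDENTITY_TOL):
        raise AssertionError("direct and prey-specific routes to %N/%W disagree")
    direct.name = "pctN" if basis == "number" else "pctW"
    return direct


def psiri(dataset: DietDataset, stratum: str = "pooled") -> DietMetricsTable:
    """Full diet-index table for one stratum.

    Rows are sorted by descending %PSIRI (ties broken alphabetically by prey
    code); prey occurring in no stomach are dropped.  Values are unrounded;
    use :meth:`DietMetricsTable.rounded` for the 1-decimal display form.
    """
    counts, weights = dataset.to_frames(full_only=True)
    if counts.empty:
        raise ValueError("no full stomachs in dataset")
    if (counts.sum().sum() == 0) or (weights.sum().sum() == 0):
        raise ValueError(
            "psiri needs both counts and weights; use basis-specific metrics "
            "(mean_percent_abundance / prey_specific_abundance) for one-basis data"
        )
    fo = frequency_of_occurrence(dataset)
    pn = prey_specific_abundance(dataset, "number")
    pw = prey_specific_abundance(dataset, "weight")
    n = mean_percent_abundance(dataset, "number")
    w = mean_percent_abundance(dataset, "weight")
    table = pd.DataFrame(
        {
            "pctN": n,
            "pctPN": pn,
            "pctW": w,
            "pctPW": pw,
            "pctFO": fo,
            "pctPSIRI": (n + w) / 2.0,
        }
    )
    table = table[fo > 0]
    # descending %PSIRI; ties broken alphabetically by prey code via a stable
    # sort on a code-presorted frame
    table = table.sort_index(kind="mergesort").sort_values(
        "pctPSIRI", ascending=False, kind="mergesort"
    )
    return DietMetricsTable(
        stratum=stratum, n_stomachs=len(counts), table=table, taxonomy=list(dataset.taxonomy)
    )


def psiri_by_stratum(
    dataset: DietDataset, stratify: tuple[str, ...] = ("location", "year")
) -> dict[tuple, DietMetricsTable]:
    """One diet-index table per (location, year) stratum."""
    out = {}
    for key, sub in dataset.strata(stratify).items():
        if sub.n_full == 0:
            continue
        label = "-".join(str(k) for k in key)
        out[key] = psiri(sub, stratum=label)
    return out


def additivity_check(
    table_lowest: DietMetricsTable,
    table_generalized: DietMetricsTable,
    tol: float = 0.1,
) -> pd.DataFrame:
    """Verify that %N and %W aggregate additively from lowest to generalized level.

    For each generalized category, the sums of member-category %N and %W must
    match the generalized values within ``tol``, and generalized %FO must be at
    least the maximum member %FO (a stomach containing a member contains the
    group).  Returns a report frame with an ``ok`` column; never raises.
    """
    parent = {
        c.code: c.parent for c in table_lowest.taxonomy if c.level == "lowest" and c.parent
    }
    rows = []
    low = table_lowest.table
    gen = table_generalized.table
    for gcode in gen.index:
        members = [c for c in low.index if parent.get(c) == gcode or c == gcode]
        sum_n = float(low.loc[members, "pctN"].sum())
        sum_w = float(low.loc[members, "pctW"].sum())
        max_fo = float(low.loc[members, "pctFO"].max()) if members else 0.0
        ok = (
            abs(sum_n - gen.loc[gcode, "pctN"]) <= tol
            and abs(sum_w - gen.loc[gcode, "pctW"]) <= tol
            and gen.loc[gcode, "pctFO"] >= max_fo - 1e-9
        )
        rows.append(
            {
                "generalized": gcode,
                "members": ",".join(members),
                "sum_pctN": sum_n,
                "gen_pctN": float(gen.loc[gcode, "pctN"]),
                "sum_pctW": sum_w,
                "gen_pctW": float(gen.loc[gcode, "pctW"]),
                "max_member_pctFO": max_fo,
                "gen_pctFO": float(gen.loc[gcode, "pctFO"]),
                "ok": ok,
            }
        )
    return pd.DataFrame(rows)
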