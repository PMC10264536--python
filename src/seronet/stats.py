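"""Per-analyte toxicity-group comparison.

Abundances are natural-log transformed, each analyte is compared between
the cumulative-toxicity groups with a two-sided Mann-Whitney U test, and
p-values are adjusted across the analyte family with the
Benjamini-Hochberg step-up procedure. Shapiro-Wilk normality is recorded
descriptively and never switches the test.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .cohort import MIN_GROUP_OBS, CohortError, CohortTable

ALPHA = 0.05

#: Exact Mann-Whitney null distribution is used when n0*n1 is at most this
#: and there are no ties; larger problems use the tie- and
#: continuity-corrected normal approximation.
EXACT_MAX_PRODUCT = 400


class Direction(str, enum.Enum):
    UP_IN_TOXICITY = "up_in_toxicity"
    DOWN_IN_TOXICITY = "down_in_toxicity"
    NONE = "none"


@dataclass(frozen=True)
class NormalityResult:
    analyte_id: str
    w_statistic: float
    p_raw: float
    scope: str = "pooled"  # "pooled", "group0" or "group1"


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float  # U for group 1 vs group 0
    p_raw: float
    degenerate: bool = False  # all values tied across both groups


@dataclass(frozen=True)
class DifferentialResult:
    analyte_id: str
    n0: int
    n1: int
    u_statistic: float
    p_raw: float
    p_adjusted: float
    direction: Direction
    median0: float  # log scale
    median1: float


def shapiro_wilk(values: Sequence[float], analyte_id: str = "", scope: str = "pooled") -> NormalityResult:
    """Shapiro-Wilk W and p for a vector without missing values."""
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values must be removed before the normality test")
    if x.size < 3 or x.size > 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("W is undefined for a constant vector")
    res = scipy.stats.shapiro(x)
    return NormalityResult(analyte_id, float(res.statistic), float(res.pvalue), scope)


def mann_whitney(values0: Sequence[float], values1: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test; U reported for group 1 vs group 0.

    The exact null distribution is used when the group-size product is at
    most ``EXACT_MAX_PRODUCT`` and the pooled sample has no ties;
    otherwise the normal approximation with tie correction and continuity
    correction. A fully tied sample returns p = 1 with a degeneracy flag.
    """
    x0 = np.asarray(values0, dtype=float)
    x1 = np.asarray(values1, dtype=float)
    if np.isnan(x0).any() or np.isnan(x1).any():
        raise ValueError("missing values must be removed before the group test")
    if x0.size < MIN_GROUP_OBS or x1.size < MIN_GROUP_OBS:
        raise ValueError(
            f"each group needs >= {MIN_GROUP_OBS} observations, "
            f"got n0={x0.size}, n1={x1.size}"
        )
    pooled = np.concatenate([x0, x1])
    if np.ptp(pooled) == 0:
        return MannWhitneyResult(x0.size * x1.size / 2.0, 1.0, degenerate=True)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x0.size * x1.size <= EXACT_MAX_PRODUCT and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x1, x0, alternative="two-sided", method=method)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_profile(cohort: CohortTable, *, alpha: float = ALPHA) -> list[DifferentialResult]:
    """Mann-Whitney comparison of every usable analyte between toxicity groups.

    Requires a log-transformed cohort with at least ``MIN_GROUP_OBS``
    patients per group. Adjustment is over the family of analytes tested
    in this run; records are sorted by adjusted p.
    """
    if not cohort.log_scale:
        raise CohortError("differential_profile requires a log-transformed cohort")
    n0_total, n1_total = cohort.group_sizes()
    if n0_total < MIN_GROUP_OBS or n1_total < MIN_GROUP_OBS:
        raise CohortError(
            f"each toxicity group needs >= {MIN_GROUP_OBS} patients, "
            f"got {n0_total}/{n1_total}"
        )
    frame0 = cohort.group_frame(0)
    frame1 = cohort.group_frame(1)
    rows: list[dict] = []
    for analyte in cohort.usable_analytes():
        v0 = frame0[analyte].dropna().to_numpy()
        v1 = frame1[analyte].dropna().to_numpy()
        if v0.size < MIN_GROUP_OBS or v1.size < MIN_GROUP_OBS:
            continue
        mw = mann_whitney(v0, v1)
        rows.append(
            dict(
                analyte_id=analyte,
                n0=v0.size,
                n1=v1.size,
                u_statistic=mw.u_statistic,
                p_raw=mw.p_raw,
                median0=float(np.median(v0)),
                median1=float(np.median(v1)),
            )
        )
    if not rows:
        return []
    adjusted = benjamini_hochberg([r["p_raw"] for r in rows])
    results = []
    for row, p_adj in zip(rows, adjusted):
        if p_adj <= alpha and row["median1"] > row["median0"]:
            direction = Direction.UP_IN_TOXICITY
        elif p_adj <= alpha and row["median1"] < row["median0"]:
            direction = Direction.DOWN_IN_TOXICITY
        else:
            direction = Direction.NONE
        results.append(
            DifferentialResult(p_adjusted=float(p_adj), direction=direction, **row)
        )
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.analyte_id))
    return results


def normality_profile(cohort: CohortTable) -> list[NormalityResult]:
    """Descriptive Shapiro-Wilk on pooled log-values, per usable analyte."""
    if not cohort.log_scale:
        raise CohortError("normality_profile requires a log-transformed cohort")
    out = []
    for analyte in cohort.usable_analytes():
        values = cohort.abundance[analyte].dropna().to_numpy()
        if values.size < 3 or np.ptp(values) == 0:
            continue
        out.append(shapiro_wilk(values, analyte_id=analyte))
    return out


def differential_to_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                analyte_id=r.analyte_id,
                n0=r.n0,
                n1=r.n1,
                u_statistic=r.u_statistic,
                p_raw=r.p_raw,
                p_adjusted=r.p_adjusted,
                direction=r.direction.value,
                median0=r.median0,
                median1=r.median1,
            )
            for r in results
        ]
    )


def write_differential_tsv(results: Sequence[DifferentialResult], path: str | Path) -> None:
    differential_to_frame(results).to_csv(path, sep="\t", index=False)
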