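"""Spearman connectivity.

Connectivity between two analytes is the Spearman rank correlation of
their abundance profiles across patients, computed on pairwise-complete
observations. Two surfaces are provided: per-analyte association with
the binary cumulative-toxicity indicator, and the full analyte x analyte
matrix within one toxicity group. Each surface is its own
multiple-testing family and is BH-adjusted independently: the analyte
family (up to 34 hypotheses) for toxicity associations, the C(m,2) pair
family (561 for a 34-analyte panel) for each group matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .cohort import CohortError, CohortTable
from .stats import ALPHA, benjamini_hochberg

#: Minimum pairwise-complete observations for a correlation to be defined.
MIN_PAIR_OBS = 4

#: Largest n for which the exact permutation p-value may be requested.
EXACT_PERMUTATION_MAX_N = 10


class UndefinedCorrelationError(ValueError):
    """A correlation is undefined (constant vector or too few pairs)."""


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_raw: float
    n_used: int


@dataclass(frozen=True)
class ToxicityAssociation:
    analyte_id: str
    rho: float
    p_raw: float
    p_adjusted: float
    n_used: int

    @property
    def significant(self) -> bool:
        return self.p_adjusted <= ALPHA


@dataclass
class ConnectivityMatrix:
    """Pairwise Spearman rho / p / adjusted-p over panel analytes.

    All matrices are symmetric DataFrames in panel order; the rho diagonal
    is exactly 1 and the p diagonals are 0. ``undefined_pairs`` lists
    analyte pairs whose correlation could not be computed (too few
    pairwise-complete observations or a constant vector); their cells are
    NaN and they are excluded from the adjustment family.
    """

    group_label: str  # "toxicity0", "toxicity1" or "all"
    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    n_used: pd.DataFrame
    undefined_pairs: set[frozenset] = field(default_factory=set)

    @property
    def analytes(self) -> list[str]:
        return list(self.rho.columns)

    def __post_init__(self) -> None:
        for name in ("rho", "p_raw", "p_adjusted", "n_used"):
            m = getattr(self, name).to_numpy(dtype=float)
            if not np.allclose(m, m.T, equal_nan=True):
                raise ValueError(f"{name} matrix must be symmetric")
        rho = self.rho.to_numpy(dtype=float)
        if not np.all(np.diag(rho) == 1.0):
            raise ValueError("rho diagonal must be exactly 1")
        off = rho[~np.eye(rho.shape[0], dtype=bool)]
        if np.nanmax(np.abs(off), initial=0.0) > 1.0 + 1e-12:
            raise ValueError("|rho| must not exceed 1")

    def pair_frame(self) -> pd.DataFrame:
        """Long-format upper triangle: one row per unordered analyte pair."""
        rows = []
        ids = self.analytes
        for i, j in itertools.combinations(range(len(ids)), 2):
            rows.append(
                dict(
                    analyte_a=ids[i],
                    analyte_b=ids[j],
                    rho=self.rho.iat[i, j],
                    p_raw=self.p_raw.iat[i, j],
                    p_adjusted=self.p_adjusted.iat[i, j],
                    n_used=int(self.n_used.iat[i, j]),
                )
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.pair_frame().to_csv(path, sep="\t", index=False)


def _t_approx_p(rho: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p for Spearman rho via the t approximation with n-2 dof."""
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.full(rho.shape, np.nan)
    ok = ~np.isnan(rho) & (n > 2)
    perfect = ok & (np.abs(rho) >= 1.0)
    p[perfect] = 0.0
    reg = ok & ~perfect
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho[reg] * np.sqrt((n[reg] - 2) / ((1 - rho[reg]) * (1 + rho[reg])))
    p[reg] = 2.0 * scipy.stats.t.sf(np.abs(t), n[reg] - 2)
    return np.minimum(p, 1.0, out=p, where=~np.isnan(p))


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p by full enumeration (n <= EXACT_PERMUTATION_MAX_N)."""
    n = x.size
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    a = rx - rx.mean()
    a /= np.linalg.norm(a)
    b = ry - ry.mean()
    b /= np.linalg.norm(b)
    count = 0
    total = 0
    chunk: list[tuple] = []
    threshold = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            rhos = np.take(b, np.array(chunk)) @ a
            count += int((np.abs(rhos) >= threshold).sum())
            total += len(chunk)
            chunk = []
    if chunk:
        rhos = np.take(b, np.array(chunk)) @ a
        count += int((np.abs(rhos) >= threshold).sum())
        total += len(chunk)
    return count / total


def spearman(x: Sequence[float], y: Sequence[float], *, exact: bool = False) -> SpearmanResult:
    """Tie-aware Spearman correlation on pairwise-complete observations.

    rho is the Pearson correlation of average ranks; the two-sided p uses
    the t approximation with n-2 degrees of freedom, or, with
    ``exact=True`` and n <= 10, full enumeration of the permutation
    distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    xc, yc = x[mask], y[mask]
    n = int(xc.size)
    if n < MIN_PAIR_OBS:
        raise UndefinedCorrelationError(
            f"need >= {MIN_PAIR_OBS} pairwise-complete observations, got {n}"
        )
    if np.ptp(xc) == 0 or np.ptp(yc) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    rho = float(scipy.stats.spearmanr(xc, yc).statistic)
    if exact:
        if n > EXACT_PERMUTATION_MAX_N:
            raise ValueError(
                f"exact permutation p limited to n <= {EXACT_PERMUTATION_MAX_N}"
            )
        p = _exact_permutation_p(xc, yc, rho)
    else:
        p = float(_t_approx_p(np.array([rho]), np.array([n]))[0])
    return SpearmanResult(rho, p, n)


def toxicity_associations(cohort: CohortTable, *, alpha: float = ALPHA) -> list[ToxicityAssociation]:
    """Spearman association of each analyte's log-level with toxicity 0/1.

    Both toxicity groups must be present. BH adjustment is over the
    analyte family; output follows panel (functional-group block) order.
    """
    if not cohort.log_scale:
        raise CohortError("toxicity_associations requires a log-transformed cohort")
    n0, n1 = cohort.group_sizes()
    if n0 == 0 or n1 == 0:
        raise CohortError("both toxicity groups must be present")
    tox = cohort.toxicity.to_numpy(dtype=float)
    rows = []
    for analyte in cohort.usable_analytes():
        values = cohort.abundance[analyte].to_numpy(dtype=float)
        try:
            res = spearman(values, tox)
        except UndefinedCorrelationError:
            continue
        rows.append((analyte, res))
    if not rows:
        return []
    adjusted = benjamini_hochberg([r.p_raw for _, r in rows])
    return [
        ToxicityAssociation(analyte, res.rho, res.p_raw, float(p_adj), res.n_used)
        for (analyte, res), p_adj in zip(rows, adjusted)
    ]


def group_connectivity(cohort: CohortTable, group: int | str) -> ConnectivityMatrix:
    """All-pairs Spearman matrix within one toxicity group (or the whole cohort).

    Correlations use pairwise-complete log-values; BH adjustment is over
    this matrix's own C(m,2) family of defined pairs.
    """
    if not cohort.log_scale:
        raise CohortError("group_connectivity requires a log-transformed cohort")
    if group == "all":
        frame = cohort.abundance
        label = "all"
    else:
        frame = cohort.group_frame(int(group))
        label = f"toxicity{int(group)}"
    if len(frame) < MIN_PAIR_OBS:
        raise CohortError(
            f"group {group!r} has {len(frame)} patients; need >= {MIN_PAIR_OBS}"
        )
    ids = list(frame.columns)
    m = len(ids)
    # tie-aware pairwise-complete rank correlation (Pearson of average ranks)
    rho = frame.corr(method="spearman", min_periods=MIN_PAIR_OBS)
    obs = frame.notna().to_numpy(dtype=float)
    n_used = obs.T @ obs
    rho_arr = rho.to_numpy(dtype=float)
    np.fill_diagonal(rho_arr, 1.0)
    undefined = {
        frozenset((ids[i], ids[j]))
        for i, j in itertools.combinations(range(m), 2)
        if np.isnan(rho_arr[i, j]) or n_used[i, j] < MIN_PAIR_OBS
    }
    for pair in undefined:
        i, j = (ids.index(a) for a in pair)
        rho_arr[i, j] = rho_arr[j, i] = np.nan

    p_raw = _t_approx_p(rho_arr, n_used)
    np.fill_diagonal(p_raw, 0.0)

    iu = np.triu_indices(m, k=1)
    flat_p = p_raw[iu]
    defined = ~np.isnan(flat_p)
    p_adj_flat = np.full(m * (m - 1) // 2, np.nan)
    if defined.any():
        p_adj_flat[defined] = benjamini_hochberg(flat_p[defined])
    p_adj = np.full((m, m), np.nan)
    p_adj[iu] = p_adj_flat
    p_adj.T[iu] = p_adj_flat
    np.fill_diagonal(p_adj, 0.0)

    def df(a: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(a, index=ids, columns=ids)

    return ConnectivityMatrix(
        group_label=label,
        rho=df(rho_arr),
        p_raw=df(p_raw),
        p_adjusted=df(p_adj),
        n_used=df(n_used),
        undefined_pairs=undefined,
    )


def associations_to_frame(associations: Sequence[ToxicityAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                analyte_id=a.analyte_id,
                rho=a.rho,
                p_raw=a.p_raw,
                p_adjusted=a.p_adjusted,
                n_used=a.n_used,
                significant=a.significant,
            )
            for a in associations
        ]
    )
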