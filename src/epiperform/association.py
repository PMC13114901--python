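"""Tie-aware rank correlation, tertile stratification and the DMP scan.

Spearman's rho is the Pearson correlation of mid-ranks (average ranks on
ties).  The two-sided p-value uses the t approximation
``t = rho * sqrt((n-2)/(1-rho^2))`` on n−2 degrees of freedom; for small
samples (n < 10) or degenerate |rho| = 1 the t formula is unreliable, so a
permutation p-value is substituted — exact enumeration when n ≤ 7,
otherwise a fixed-seed Monte-Carlo permutation null.

Subjects are stratified into tertiles either by fixed year boundaries
(chronological age: ≤55 / 56–64 / ≥65) or by ranking on the variable and
cutting into three near-equal groups, with whole tied-value runs moved to
the later (higher-value) group so a tie never straddles a boundary.

The differentially-methylated-position (DMP) scan regresses each CpG's
M-value on a continuous phenotype by ordinary least squares, with
Benjamini–Hochberg control of the false discovery rate across all CpGs
tested; a CpG is called significant at q < 0.01.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "TertileSplit",
    "spearman",
    "tertile_split",
    "chronological_tertiles",
    "stratified_correlation",
    "dmp_scan",
    "bh_fdr",
]

DMP_Q_THRESHOLD = 0.01
_PERMUTATION_SEED = 987654321
_N_MC_PERMUTATIONS = 10_000


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    rho: float
    p_value: float
    n: int
    method: str  # "t_approx" or "permutation"


def _midranks(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def _rank_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = _midranks(x), _midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Tie-aware Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho = _rank_rho(x, y)
    if n < 10 or abs(rho) >= 1.0 - 1e-14:
        p, method = _permutation_p(x, y, rho), "permutation"
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        method = "t_approx"
    return CorrelationResult(x_name=x_name, y_name=y_name, rho=rho,
                             p_value=min(p, 1.0), n=n, method=method)


def _permutation_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p for |rho|; exact for n ≤ 7, else Monte-Carlo."""
    n = len(x)
    tol = 1e-12
    if n <= 7:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_rank_rho(x, y[list(perm)])) >= abs(rho_obs) - tol:
                count += 1
        return count / total
    rng = np.random.default_rng(_PERMUTATION_SEED)
    count = 1  # identity permutation
    for _ in range(_N_MC_PERMUTATIONS):
        if abs(_rank_rho(x, rng.permutation(y))) >= abs(rho_obs) - tol:
            count += 1
    return count / (_N_MC_PERMUTATIONS + 1)


@dataclass(frozen=True)
class TertileSplit:
    """Per-subject tertile labels (1 = lowest values, 3 = highest)."""

    labels: pd.Series  # index: subject ids, values in {1, 2, 3}
    basis: str

    @property
    def sizes(self) -> tuple[int, int, int]:
        return tuple(int((self.labels == g).sum()) for g in (1, 2, 3))

    def value_ranges(self, values: pd.Series) -> dict[int, tuple[float, float]]:
        out = {}
        for g in (1, 2, 3):
            member = values[self.labels[self.labels == g].index]
            if len(member):
                out[g] = (float(member.min()), float(member.max()))
        return out


def tertile_split(values, ids=None, basis: str = "value") -> TertileSplit:
    """Rank subjects and cut into three near-equal ordered groups.

    Base group sizes differ by at most one (larger groups first).  When a
    run of tied values straddles a cut, the whole run moves to the later
    (higher-value) group, so a tie never splits across groups.
    """
    values = pd.Series(np.asarray(values, dtype=float),
                       index=ids if ids is not None else range(len(np.atleast_1d(values))))
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 subjects for tertiles")
    order = np.argsort(values.to_numpy(), kind="stable")
    sorted_vals = values.to_numpy()[order]
    base = n // 3
    extra = n % 3
    sizes = [base + (1 if i < extra else 0) for i in range(3)]
    cuts = [sizes[0], sizes[0] + sizes[1]]  # cut AFTER these sorted positions
    adj = []
    for c in cuts:
        # retreat the cut to the start of any tie run straddling it
        while c > 0 and c < n and sorted_vals[c] == sorted_vals[c - 1]:
            c -= 1
        adj.append(c)
    if adj[1] < adj[0]:
        adj[0] = adj[1]
    labels_sorted = np.empty(n, dtype=int)
    labels_sorted[: adj[0]] = 1
    labels_sorted[adj[0]: adj[1]] = 2
    labels_sorted[adj[1]:] = 3
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    if adj[0] == 0 and adj[1] == 0:
        warnings.warn(f"tertile split on {basis!r}: all values tied, "
                      "every subject assigned to group 3", stacklevel=2)
    return TertileSplit(labels=pd.Series(labels, index=values.index),
                        basis=basis)


def chronological_tertiles(ages, ids=None) -> TertileSplit:
    """Fixed-boundary age tertiles: ≤55 → 1, 56–64 → 2, ≥65 → 3."""
    ages = pd.Series(np.asarray(ages, dtype=float),
                     index=ids if ids is not None else range(len(np.atleast_1d(ages))))
    labels = pd.Series(np.where(ages <= 55, 1, np.where(ages < 65, 2, 3)),
                       index=ages.index)
    return TertileSplit(labels=labels, basis="chronological_age")


def stratified_correlation(x, y, split: TertileSplit,
                           x_name: str = "x", y_name: str = "y",
                           ) -> dict[int, CorrelationResult | None]:
    """Spearman within each tertile; groups with n < 3 come back as None."""
    x = pd.Series(np.asarray(x, dtype=float), index=split.labels.index)
    y = pd.Series(np.asarray(y, dtype=float), index=split.labels.index)
    out: dict[int, CorrelationResult | None] = {}
    for g in (1, 2, 3):
        members = split.labels[split.labels == g].index
        if len(members) < 3:
            out[g] = None
            continue
        try:
            out[g] = spearman(x[members], y[members],
                              x_name=f"{x_name}[tertile {g}]", y_name=y_name)
        except ValueError:
            out[g] = None  # constant within the group
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j ≥ i} m·p_(j)/j over the sorted p's, mapped back to the
    input order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def dmp_scan(m_matrix: pd.DataFrame, phenotype,
             q_threshold: float = DMP_Q_THRESHOLD) -> pd.DataFrame:
    """Per-CpG OLS of M-values on a continuous phenotype, BH-corrected.

    ``m_matrix`` is CpG × sample; ``phenotype`` is aligned to the sample
    columns.  Returns a DataFrame indexed by cpg_id with slope, t, p, q
    and the significance call at ``q < q_threshold``.
    """
    if hasattr(m_matrix, "values") and not isinstance(m_matrix, pd.DataFrame):
        m_matrix = m_matrix.values  # accept an MValue/BetaMatrix wrapper
    x = np.asarray(phenotype, dtype=float)
    n = m_matrix.shape[1]
    if len(x) != n:
        raise ValueError("phenotype length must match the number of samples")
    if n < 4:
        raise ValueError("need at least 4 samples for the DMP scan")
    if np.ptp(x) == 0:
        raise ValueError("phenotype has zero variance")
    ym = m_matrix.to_numpy(dtype=float)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = ym - ym.mean(axis=1, keepdims=True)
    slope = (yc @ xc) / sxx
    resid = yc - np.outer(slope, xc)
    dof = n - 2
    sigma2 = (resid ** 2).sum(axis=1) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / sxx)
        # se == 0: a perfect linear fit (t = ±inf) or a constant CpG (t = 0)
        t = np.where(se > 0, slope / se,
                     np.where(slope == 0, 0.0, np.inf * np.sign(slope)))
    p = 2.0 * stats.t.sf(np.abs(t), df=dof)
    q = bh_fdr(p)
    return pd.DataFrame({
        "slope": slope, "t_stat": t, "p_value": p, "q_value": q,
        "significant": q < q_threshold,
    }, index=m_matrix.index.rename("cpg_id"))
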