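"""Nonparametric inference chain: Friedman, Conover post hoc, Spearman.

Implemented from first principles on mid-ranks so the algebra the
pipeline relies on is explicit and auditable.

Notation: ``n`` blocks (participants) × ``k`` treatments (indexes);
``r_ij`` the within-block mid-rank of treatment j in block i; ``R_j``
the rank sum of treatment j; ``A = Σ r_ij²``; ``C = n k (k+1)² / 4``.

* Friedman omnibus (tie-corrected form):
  ``Q = (k−1) Σ_j (R_j − n(k+1)/2)² / (A − C)``,
  chi-squared with k−1 df. Without ties this reduces to the classic
  ``12/(n k (k+1)) Σ R_j² − 3 n (k+1)``.
* Conover all-pairs post hoc:
  ``t = (R_a − R_b) / sqrt(2 n (A − C) (1 − Q/(n(k−1))) / ((n−1)(k−1)))``,
  referred to Student's t with (n−1)(k−1) df — algebraically Fisher's
  LSD from the two-way (block + treatment) ANOVA of the ranks.
* Spearman's rho: Pearson correlation of mid-ranks, two-sided p from the
  t approximation with n−2 df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateProfileError, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlockMatrix:
    """n blocks × k treatments of real values, no missing cells."""

    values: np.ndarray
    block_labels: tuple[str, ...] = ()
    treatment_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise InputError(f"block matrix must be at least 2×2, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise InputError("block matrix contains non-finite values (listwise-delete upstream)")
        object.__setattr__(self, "values", v)
        if not self.block_labels:
            object.__setattr__(self, "block_labels", tuple(f"b{i + 1}" for i in range(v.shape[0])))
        if not self.treatment_labels:
            object.__setattr__(
                self, "treatment_labels", tuple(f"t{j + 1}" for j in range(v.shape[1]))
            )
        if len(self.block_labels) != v.shape[0] or len(self.treatment_labels) != v.shape[1]:
            raise InputError("label lengths do not match matrix shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    p_value: float
    n: int
    k: int
    tie_corrected: bool


@dataclass(frozen=True)
class PosthocPair:
    treatment_a: str
    treatment_b: str
    statistic: float
    p_unadjusted: float
    p_adjusted: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def midrank(x: np.ndarray) -> np.ndarray:
    """Mid-ranks (average ranks for ties) of a 1-D vector, from 1."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0  # average of positions i..j, 1-based
        i = j + 1
    return ranks


def rank_within_blocks(m: BlockMatrix) -> np.ndarray:
    """Mid-rank each block's row; every row sums to k(k+1)/2."""
    return np.apply_along_axis(midrank, 1, m.values)


def _rank_sums(m: BlockMatrix) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Ranks, treatment rank sums, A = Σr² and C = nk(k+1)²/4."""
    r = rank_within_blocks(m)
    n, k = m.n, m.k
    return r, r.sum(axis=0), float((r**2).sum()), n * k * (k + 1) ** 2 / 4.0


def friedman_test(m: BlockMatrix, tie_corrected: bool = True) -> FriedmanResult:
    """Friedman rank test for k related treatments over n blocks.

    With ``tie_corrected`` (default) the statistic uses the A − C
    divisor, matching mainstream software; without it, the classic
    formula assumes no ties. A fully tied matrix yields Q = 0, p = 1.
    """
    r, R, A, C = _rank_sums(m)
    n, k = m.n, m.k
    ss_treat = float(((R - n * (k + 1) / 2.0) ** 2).sum())
    if tie_corrected:
        denom = A - C
        stat = 0.0 if denom <= 0 else (k - 1) * ss_treat / denom
    else:
        stat = 12.0 * ss_treat / (n * k * (k + 1))
    df = k - 1
    p = 1.0 if stat == 0.0 else float(sps.chi2.sf(stat, df))
    return FriedmanResult(
        statistic=float(stat), df=df, p_value=p, n=n, k=k, tie_corrected=tie_corrected
    )


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment of a vector of p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m, dtype=float)
    running = 0.0
    for rank_idx, idx in enumerate(order):
        running = max(running, (m - rank_idx) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def conover_posthoc(m: BlockMatrix, adjust: str = "none") -> list[PosthocPair]:
    """All-pairs Conover post hoc following a Friedman test.

    The pairwise statistic divides the difference of treatment rank sums
    by its standard error derived from the within-block rank sum of
    squares and is referred to Student's t with (n−1)(k−1) df.

    Raises
    ------
    DegenerateProfileError
        If every block is fully tied (zero rank variance).
    """
    if adjust not in ("none", "holm"):
        raise InputError(f"unknown adjustment {adjust!r}; use 'none' or 'holm'")
    r, R, A, C = _rank_sums(m)
    n, k = m.n, m.k
    if A - C <= 0:
        raise DegenerateProfileError("all blocks fully tied: post hoc comparisons are undefined")
    q = friedman_test(m, tie_corrected=True).statistic
    df = (n - 1) * (k - 1)
    # 1 − Q/(n(k−1)) can hit 0 to rounding when every block is perfectly
    # concordant; clip so the t statistic becomes ±inf rather than NaN.
    se2 = 2.0 * n * (A - C) * max(1.0 - q / (n * (k - 1)), 0.0) / df
    pairs: list[PosthocPair] = []
    stats_: list[float] = []
    for a in range(k):
        for b in range(a + 1, k):
            diff = R[a] - R[b]
            if se2 > 0:
                t = diff / np.sqrt(se2)
            else:
                t = 0.0 if diff == 0 else np.inf * np.sign(diff)
            stats_.append(float(t))
            pairs.append((a, b, float(t)))
    p_un = np.array([2.0 * sps.t.sf(abs(t), df) for t in stats_])
    p_adj = holm_adjust(p_un) if adjust == "holm" else [None] * len(pairs)
    return [
        PosthocPair(
            treatment_a=m.treatment_labels[a],
            treatment_b=m.treatment_labels[b],
            statistic=t,
            p_unadjusted=float(pu),
            p_adjusted=None if pa is None else float(pa),
        )
        for (a, b, t), pu, pa in zip(pairs, p_un, p_adj)
    ]


def spearman_correlation(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Spearman rank correlation with mid-rank ties and t-approximation p.

    A constant vector has undefined rank correlation; rho = 0 with p = 1
    is returned with a warning in that case.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError(f"x and y must be equal-length 1-D vectors, got {x.shape} and {y.shape}")
    n = x.size
    if n < 3:
        raise InputError(f"need at least 3 paired observations, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("missing or non-finite values in correlation input")
    rx, ry = midrank(x), midrank(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        logger.warning("constant vector in spearman_correlation; returning rho=0, p=1")
        return CorrelationResult(rho=0.0, p_value=1.0, n=n)
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p_value=p, n=n)


def summarize_median_iqr(values: np.ndarray) -> tuple[float, float]:
    """Median and IQR (Q3 − Q1) under linear interpolation (quantile type 7)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InputError("empty vector")
    if not np.isfinite(v).all():
        raise InputError("non-finite values")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # numpy default = type 7
    return float(med), float(q3 - q1)
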