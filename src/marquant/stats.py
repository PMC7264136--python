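"""Statistical comparison layer for edge-count data.

Slice counts from different acquisitions form unbalanced groups (each
prosthesis/protocol yields a different number of usable axial slices), so
all omnibus and pairwise machinery here is heteroscedasticity-robust:
Welch's one-way ANOVA, the Games-Howell post hoc test on the studentized
range scale, and Welch (Satterthwaite) t-tests.  Shapiro-Wilk normality is
always computed and reported as advisory output rather than used as a
behavioural switch.  All tests are two-sided; sample variance uses the n-1
denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "NormalityResult",
    "AnovaResult",
    "PairwiseComparison",
    "TTestResult",
    "DegenerateSampleError",
    "IncompleteDesignError",
    "shapiro_wilk",
    "welch_anova",
    "games_howell",
    "welch_t_test",
    "compare_conditions",
    "SHAPIRO_GATE_N",
]

#: advisory gate: normality testing is conventional for groups up to this size
SHAPIRO_GATE_N = 30


class DegenerateSampleError(ValueError):
    """A sample has zero variance (or too few values) for the requested test."""


class IncompleteDesignError(ValueError):
    """The factorial design is missing one or more cells."""


@dataclass(frozen=True)
class GroupSample:
    """A labelled group of per-slice values (ratios or count differences)."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 2:
            raise ValueError(f"group {self.label!r} needs n >= 2")
        if not np.isfinite(vals).all():
            raise ValueError(f"group {self.label!r} has non-finite values")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def var(self) -> float:
        return float(np.var(self.values, ddof=1))


@dataclass(frozen=True)
class NormalityResult:
    W: float
    p_value: float
    n: int
    #: True when n is within the conventional small-sample gate (advisory)
    within_gate: bool


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: float
    df2: float
    p_value: float


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    q: float
    df: float
    p_adjusted: float
    significant_at_05: bool


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float


def shapiro_wilk(values: Sequence[float]) -> NormalityResult:
    """Shapiro-Wilk W and p (Royston AS R94 approximation, via SciPy)."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 3:
        raise DegenerateSampleError("Shapiro-Wilk needs at least 3 values")
    if arr.size > 5000:
        raise DegenerateSampleError("Shapiro-Wilk approximation valid only for n <= 5000")
    if np.ptp(arr) == 0:
        raise DegenerateSampleError("Shapiro-Wilk undefined for zero-variance samples")
    res = sps.shapiro(arr)
    return NormalityResult(
        W=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(arr.size),
        within_gate=arr.size <= SHAPIRO_GATE_N,
    )


def _group_stats(groups: Sequence[GroupSample]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = np.array([g.n for g in groups], dtype=np.float64)
    mean = np.array([g.mean for g in groups])
    var = np.array([g.var for g in groups])
    return n, mean, var


def welch_anova(groups: Sequence[GroupSample]) -> AnovaResult:
    """Welch's heteroscedastic one-way ANOVA.

    With weights w_i = n_i / s_i^2, W = sum(w_i) and weighted grand mean
    x_w, the statistic is

        F* = [sum w_i (x_i - x_w)^2 / (k-1)]
             / [1 + 2(k-2)/(k^2-1) * sum (1 - w_i/W)^2 / (n_i - 1)]

    with df1 = k-1 and df2 = (k^2-1) / [3 sum (1 - w_i/W)^2 / (n_i - 1)].
    """
    if len(groups) < 2:
        raise ValueError("Welch ANOVA needs at least 2 groups")
    n, mean, var = _group_stats(groups)
    if (var <= 0).any():
        raise DegenerateSampleError("Welch ANOVA requires positive variance in every group")
    k = len(groups)
    w = n / var
    W = w.sum()
    grand = (w * mean).sum() / W
    a = (w * (mean - grand) ** 2).sum() / (k - 1)
    lam = ((1 - w / W) ** 2 / (n - 1)).sum()
    b = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    F = a / b
    df1 = float(k - 1)
    df2 = (k**2 - 1) / (3 * lam)
    p = float(sps.f.sf(F, df1, df2))
    return AnovaResult(F=float(F), df1=df1, df2=float(df2), p_value=p)


def games_howell(groups: Sequence[GroupSample], alpha: float = 0.05) -> tuple[PairwiseComparison, ...]:
    """Games-Howell pairwise comparisons for unequal variances and sizes.

    Each pair gets its own Welch-Satterthwaite degrees of freedom; the
    statistic q = |mean_a - mean_b| / sqrt((s_a^2/n_a + s_b^2/n_b) / 2) is
    referred to the studentized-range distribution with k groups.
    """
    if len(groups) < 2:
        raise ValueError("Games-Howell needs at least 2 groups")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    for g in groups:
        if g.var <= 0:
            raise DegenerateSampleError(f"group {g.label!r} has zero variance")
    k = len(groups)
    out = []
    for a, b in combinations(groups, 2):
        sa, sb = a.var / a.n, b.var / b.n
        se2 = sa + sb
        df = se2**2 / (sa**2 / (a.n - 1) + sb**2 / (b.n - 1))
        diff = a.mean - b.mean
        q = abs(diff) / np.sqrt(se2 / 2.0)
        p = float(sps.studentized_range.sf(q, k, df))
        p = min(max(p, 0.0), 1.0)
        out.append(
            PairwiseComparison(
                group_a=a.label,
                group_b=b.label,
                mean_diff=float(diff),
                q=float(q),
                df=float(df),
                p_adjusted=p,
                significant_at_05=p < alpha,
            )
        )
    return tuple(out)


def welch_t_test(a: GroupSample, b: GroupSample, pooled: bool = False) -> TTestResult:
    """Two-sided independent t-test; Welch/Satterthwaite df by default.

    ``pooled=True`` gives the classic Student test with the pooled-variance
    estimator (offered for sensitivity checks only).
    """
    if a.var == 0 and b.var == 0:
        raise DegenerateSampleError("both samples have zero variance")
    if pooled:
        sp2 = ((a.n - 1) * a.var + (b.n - 1) * b.var) / (a.n + b.n - 2)
        se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
        df = float(a.n + b.n - 2)
    else:
        sa, sb = a.var / a.n, b.var / b.n
        se = np.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa**2 / (a.n - 1) + sb**2 / (b.n - 1))
    t = (a.mean - b.mean) / se
    p = float(2 * sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p_value=p)


def compare_conditions(
    table: Mapping[tuple[float, float], Sequence[float]],
    voxels: Sequence[float] = (0.2, 0.3),
    kvps: Sequence[float] = (70.0, 100.0),
    pooled: bool = False,
) -> dict[str, TTestResult]:
    """Margin tests of a full 2x2 voxel-size x tube-voltage design.

    ``table`` maps (voxel_mm, kvp) to the per-slice MAR_off - MAR_on count
    differences of that cell.  For each voxel size the two tube voltages
    are compared, and for each tube voltage the two voxel sizes, giving
    exactly four tests for a full design.  Keys of the result read e.g.
    ``"voxel0.2: 70 vs 100 kVp"`` and ``"70kVp: 0.2 vs 0.3 mm"``.
    """
    if len(voxels) != 2 or len(kvps) != 2:
        raise IncompleteDesignError("the factorial design needs exactly 2 levels per factor")
    missing = [
        (v, k) for v in voxels for k in kvps if (v, k) not in table
    ]
    if missing:
        raise IncompleteDesignError(f"missing design cells: {missing}")
    cells = {
        (v, k): GroupSample(label=f"voxel{v}_kvp{k:g}", values=tuple(table[(v, k)]))
        for v in voxels
        for k in kvps
    }
    results: dict[str, TTestResult] = {}
    for v in voxels:
        results[f"voxel{v}: {kvps[0]:g} vs {kvps[1]:g} kVp"] = welch_t_test(
            cells[(v, kvps[0])], cells[(v, kvps[1])], pooled=pooled
        )
    for k in kvps:
        results[f"{k:g}kVp: {voxels[0]} vs {voxels[1]} mm"] = welch_t_test(
            cells[(voxels[0], k)], cells[(voxels[1], k)], pooled=pooled
        )
    return results
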