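"""Edge counting and the edge-reduction-ratio metric.

An "edge" is one connected component of edge pixels in the binary Canny
output — a continuous line with no breaks.  Components are 8-connected by
default so that diagonal pixel runs count as a single line; 4-connectivity
is available for sensitivity checks.  The MAR-efficacy metric is

    reduction ratio (%) = 100 * (edges_off - edges_on) / edges_off

computed on the summed counts of a paired MAR_off / MAR_on stack, with
per-slice count differences (off - on) summarized as mean +/- sample SD for
condition-level comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .canny import EdgeMap, EdgeParams, detect_edges
from .types import ImageStack, PairingError, StackLabel, StackPair

__all__ = [
    "EdgeCountSeries",
    "ReductionReport",
    "UndefinedRatioError",
    "count_edges",
    "count_stack",
    "reduction_ratio",
    "slice_differences",
    "analyze_pair",
]

_STRUCTURES = {
    8: np.ones((3, 3), dtype=bool),
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
}


class UndefinedRatioError(ZeroDivisionError):
    """The MAR_off stack has zero edges; the ratio denominator vanishes."""


@dataclass(frozen=True)
class EdgeCountSeries:
    """Per-slice edge counts for one acquisition, in slice order."""

    counts: tuple[int, ...]
    stack_label: StackLabel

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if any(c < 0 for c in counts):
            raise ValueError("edge counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class ReductionReport:
    """Paired counts, per-slice differences and the reduction ratio."""

    off_counts: EdgeCountSeries
    on_counts: EdgeCountSeries
    per_slice_diff: tuple[int, ...]
    total_off: int
    total_on: int
    reduction_ratio_pct: float
    mean_diff: float
    sd_diff: float

    def __post_init__(self) -> None:
        n = len(self.off_counts)
        if not (len(self.on_counts) == n == len(self.per_slice_diff)):
            raise PairingError("count series and differences must share length")
        if self.total_off != self.off_counts.total or self.total_on != self.on_counts.total:
            raise ValueError("totals inconsistent with per-slice counts")


def count_edges(edge_map: EdgeMap | np.ndarray, connectivity: int = 8) -> int:
    """Number of connected components of edge pixels (one component = one edge)."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    pixels = edge_map.pixels if isinstance(edge_map, EdgeMap) else np.asarray(edge_map)
    _, n = ndimage.label(pixels.astype(bool), structure=_STRUCTURES[connectivity])
    return int(n)


def count_stack(
    stack: ImageStack,
    params: EdgeParams = EdgeParams(),
    connectivity: int = 8,
    min_component_size: int = 1,
) -> EdgeCountSeries:
    """Detect edges and count components on every slice, in slice order.

    ``min_component_size`` optionally drops components smaller than a pixel
    floor before counting (default keeps everything, single pixels included).
    """
    counts = []
    for s in stack:
        emap = detect_edges(s, params)
        if min_component_size > 1:
            labels, n = ndimage.label(emap.pixels, structure=_STRUCTURES[connectivity])
            if n:
                sizes = np.bincount(labels.ravel())[1:]
                counts.append(int((sizes >= min_component_size).sum()))
            else:
                counts.append(0)
        else:
            counts.append(count_edges(emap, connectivity))
    return EdgeCountSeries(counts=tuple(counts), stack_label=stack.label)


def reduction_ratio(total_off: int, total_on: int) -> float:
    """100 * (off - on) / off; negative when MAR adds edges."""
    if total_off == 0:
        raise UndefinedRatioError("reduction ratio undefined: MAR_off has zero edges")
    if total_off < 0 or total_on < 0:
        raise ValueError("edge totals must be non-negative")
    return 100.0 * (total_off - total_on) / total_off


def slice_differences(
    off: EdgeCountSeries | Sequence[int], on: EdgeCountSeries | Sequence[int]
) -> tuple[tuple[int, ...], float, float]:
    """Per-slice (off - on) differences with mean and sample SD (n-1).

    With a single slice the SD is reported as 0.0.
    """
    off_c = off.counts if isinstance(off, EdgeCountSeries) else tuple(int(x) for x in off)
    on_c = on.counts if isinstance(on, EdgeCountSeries) else tuple(int(x) for x in on)
    if len(off_c) != len(on_c):
        raise PairingError(
            f"cannot pair count series of lengths {len(off_c)} and {len(on_c)}"
        )
    diffs = tuple(a - b for a, b in zip(off_c, on_c))
    arr = np.asarray(diffs, dtype=np.float64)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return diffs, mean, sd


def analyze_pair(
    pair: StackPair,
    params: EdgeParams = EdgeParams(),
    connectivity: int = 8,
    min_component_size: int = 1,
) -> ReductionReport:
    """Full pairwise analysis: counts, differences, totals and the ratio."""
    off_counts = count_stack(pair.off_stack, params, connectivity, min_component_size)
    on_counts = count_stack(pair.on_stack, params, connectivity, min_component_size)
    diffs, mean, sd = slice_differences(off_counts, on_counts)
    total_off, total_on = off_counts.total, on_counts.total
    return ReductionReport(
        off_counts=off_counts,
        on_counts=on_counts,
        per_slice_diff=diffs,
        total_off=total_off,
        total_on=total_on,
        reduction_ratio_pct=reduction_ratio(total_off, total_on),
        mean_diff=mean,
        sd_diff=sd,
    )
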