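"""Multi-factor target-set overlap, peak-to-peak distances, and ChIP-qPCR arithmetic."""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Peak
from .linking import PeakGeneLink


@dataclass
class OverlapResult:
    """Set sizes, intersections, percentages, hypergeometric expectations.

    ``expected`` is |X|*|Y|/N per pair; ``p`` is the upper-tail
    hypergeometric probability of observing at least the actual overlap.
    """

    labels: "tuple[str, ...]"
    universe: int
    sizes: "dict[str, int]"
    intersections: "dict[str, int]"
    percentages: "dict[str, float]"  # keyed "X&Y|X" = % of X shared with Y
    expected: "dict[str, float]"
    p: "dict[str, float]"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": f"|{k}|", "value": v} for k, v in self.sizes.items()
        ]
        rows += [
            {"quantity": f"|{k}|", "value": v}
            for k, v in self.intersections.items()
        ]
        rows += [
            {"quantity": f"%({k})", "value": v}
            for k, v in self.percentages.items()
        ]
        rows += [
            {"quantity": f"expected({k})", "value": v}
            for k, v in self.expected.items()
        ]
        rows += [{"quantity": f"p({k})", "value": v} for k, v in self.p.items()]
        rows.append({"quantity": "N", "value": self.universe})
        return pd.DataFrame(rows)


def target_overlap(set_a: "set[str]", set_b: "set[str]",
                   set_c: "Optional[set[str]]" = None, *,
                   universe_size: int,
                   labels: "tuple[str, ...]" = ("A", "B", "C")) -> OverlapResult:
    """All 2- and 3-way intersections with expected overlaps and p-values.

    ``universe_size`` is an explicit required parameter; it must be at
    least the size of the union of the sets.
    """
    sets = {labels[0]: set(set_a), labels[1]: set(set_b)}
    if set_c is not None:
        sets[labels[2]] = set(set_c)
    union = set().union(*sets.values())
    if universe_size < len(union):
        raise ValueError(
            f"universe size {universe_size} smaller than union {len(union)}"
        )
    sizes = {k: len(v) for k, v in sets.items()}
    intersections: "dict[str, int]" = {}
    percentages: "dict[str, float]" = {}
    expected: "dict[str, float]" = {}
    pvals: "dict[str, float]" = {}
    for x, y in combinations(sets, 2):
        k = len(sets[x] & sets[y])
        key = f"{x}&{y}"
        intersections[key] = k
        for member in (x, y):
            percentages[f"{key}|{member}"] = (
                100.0 * k / sizes[member] if sizes[member] else 0.0
            )
        expected[key] = sizes[x] * sizes[y] / universe_size
        pvals[key] = float(
            stats.hypergeom.sf(k - 1, universe_size, sizes[x], sizes[y])
        )
    if set_c is not None:
        names = list(sets)
        k3 = len(sets[names[0]] & sets[names[1]] & sets[names[2]])
        key = "&".join(names)
        intersections[key] = k3
        for member in names:
            percentages[f"{key}|{member}"] = (
                100.0 * k3 / sizes[member] if sizes[member] else 0.0
            )
    return OverlapResult(
        labels=tuple(sets),
        universe=universe_size,
        sizes=sizes,
        intersections=intersections,
        percentages=percentages,
        expected=expected,
        p=pvals,
    )


@dataclass
class DistanceResult:
    """Per-gene minimum summit-to-summit distances between two factors."""

    distances: "dict[str, int]"
    histogram: pd.DataFrame
    n_skipped: int


def peak_distance_distribution(peaks_a: Sequence[Peak],
                               peaks_b: Sequence[Peak],
                               links: Sequence[PeakGeneLink],
                               common_genes: Sequence[str],
                               bin_width: int = 100,
                               max_distance: int = 2000) -> DistanceResult:
    """Min |summitA - summitB| per common gene, histogrammed.

    Genes missing peaks from either factor are skipped and counted.
    The final histogram row collects distances beyond ``max_distance``.
    """
    summit_a = {p.peak_id: p.summit for p in peaks_a}
    summit_b = {p.peak_id: p.summit for p in peaks_b}
    gene_a: "dict[str, list[int]]" = defaultdict(list)
    gene_b: "dict[str, list[int]]" = defaultdict(list)
    for link in links:
        if link.peak_id in summit_a:
            gene_a[link.gene_id].append(summit_a[link.peak_id])
        if link.peak_id in summit_b:
            gene_b[link.gene_id].append(summit_b[link.peak_id])

    distances: "dict[str, int]" = {}
    n_skipped = 0
    for gene in common_genes:
        sa, sb = gene_a.get(gene), gene_b.get(gene)
        if not sa or not sb:
            n_skipped += 1
            continue
        arr_a = np.array(sa, dtype=np.int64)
        arr_b = np.array(sb, dtype=np.int64)
        distances[gene] = int(np.abs(arr_a[:, None] - arr_b[None, :]).min())

    vals = np.array(list(distances.values()), dtype=int)
    edges = list(range(0, max_distance + bin_width, bin_width))
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        count = int(((vals >= lo) & (vals < hi)).sum()) if vals.size else 0
        rows.append({"distance_lo": lo, "distance_hi": hi - 1, "count": count})
    overflow = int((vals >= max_distance).sum()) if vals.size else 0
    rows.append(
        {"distance_lo": max_distance, "distance_hi": -1, "count": overflow}
    )
    return DistanceResult(distances, pd.DataFrame(rows), n_skipped)


def qpcr_enrichment(target_test: float, ref_test: float,
                    target_ctrl: float, ref_ctrl: float) -> float:
    """(target_test/ref_test) / (target_ctrl/ref_ctrl); inputs must be > 0."""
    vals = (target_test, ref_test, target_ctrl, ref_ctrl)
    if any(v <= 0 for v in vals):
        raise ValueError(f"all qPCR quantities must be positive, got {vals}")
    return (target_test / ref_test) / (target_ctrl / ref_ctrl)
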