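"""Differential-expression calling and cross-pathway dependence statistics.

The DE rule is a fold-change threshold (default 1.5) on CPM-normalized
means combined with a raw Welch-t p-value threshold (default 0.01); no
multiple-testing adjustment.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DE_COLUMNS = ["log2fc", "p", "de_flag"]

_OPPOSITE = {"up": "down", "down": "up"}


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million per library; errors on a zero-total library."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero total counts in libraries: {list(zero.index)}")
    return counts * 1e6 / totals


def _parse_contrast(contrast) -> "tuple[str, str]":
    if isinstance(contrast, str):
        parts = contrast.split(":")
        if len(parts) != 2:
            raise ValueError(f"contrast must be 'test:ref', got {contrast!r}")
        return parts[0], parts[1]
    test, ref = contrast
    return test, ref


def call_differential(counts: pd.DataFrame, design: pd.DataFrame, contrast,
                      fc_threshold: float = 1.5,
                      alpha: float = 0.01) -> pd.DataFrame:
    """Per-gene log2fc, Welch-t p, and DE flag for ``test:ref``.

    counts: gene x library matrix of nonnegative integers.
    design: table with ``library`` and ``condition`` columns.
    Genes with zero counts in every library are dropped.  Flags follow
    |log2fc| >= log2(fc_threshold) and p < alpha.
    """
    test, ref = _parse_contrast(contrast)
    libs = {}
    for cond in (test, ref):
        sel = design.loc[design["condition"] == cond, "library"].tolist()
        if len(sel) < 2:
            raise ValueError(
                f"condition {cond!r} has {len(sel)} replicate(s); need >= 2"
            )
        missing = [l for l in sel if l not in counts.columns]
        if missing:
            raise ValueError(f"libraries missing from counts: {missing}")
        libs[cond] = sel
    if (counts < 0).any().any():
        raise ValueError("counts must be nonnegative")

    norm = cpm(counts)
    keep = counts.sum(axis=1) > 0
    norm = norm.loc[keep]

    a = norm[libs[test]].to_numpy(dtype=float)
    b = norm[libs[ref]].to_numpy(dtype=float)
    log2fc = np.log2((a.mean(axis=1) + 1.0) / (b.mean(axis=1) + 1.0))

    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    # Degenerate zero-variance groups: equal means -> no evidence (p=1),
    # different means with literally zero noise -> p=0.
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)

    thr = math.log2(fc_threshold)
    flag = np.where(
        (log2fc >= thr) & (p < alpha),
        "up",
        np.where((log2fc <= -thr) & (p < alpha), "down", "ns"),
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "de_flag": flag}, index=norm.index
    )


def fc_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame,
                   gene_subset: Optional[Sequence[str]] = None
                   ) -> "tuple[float, int]":
    """Pearson r of log2fc vectors over a shared gene subset.

    Default subset: genes DE (flag != ns) in both tables.  Requires at
    least 3 genes and nonzero variance in both vectors.
    """
    shared = table_a.index.intersection(table_b.index)
    if gene_subset is None:
        de_a = table_a.loc[shared, "de_flag"] != "ns"
        de_b = table_b.loc[shared, "de_flag"] != "ns"
        genes = shared[de_a.to_numpy() & de_b.to_numpy()]
    else:
        genes = pd.Index(gene_subset).intersection(shared)
    x = table_a.loc[genes, "log2fc"].to_numpy(dtype=float)
    y = table_b.loc[genes, "log2fc"].to_numpy(dtype=float)
    finite = np.isfinite(x) & np.isfinite(y)
    x, y = x[finite], y[finite]
    if x.size < 3:
        raise ValueError(f"need >= 3 shared genes with finite log2fc, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a log2fc vector")
    r, _ = stats.pearsonr(x, y)
    return float(r), int(x.size)


@dataclass
class CoregulationSummary:
    """Sign patterns of DE flags across contrasts over a gene set."""

    counts: "dict[str, int]"
    fractions: "dict[str, float]"
    n: int
    concordant_opposing_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"pattern": k, "count": self.counts[k],
                 "fraction": self.fractions[k]}
                for k in sorted(self.counts)
            ]
        )


def coregulation_pattern(tables: Sequence[pd.DataFrame],
                         gene_set: Sequence[str]) -> CoregulationSummary:
    """Per-gene DE-flag tuples across >= 2 contrasts, as pattern fractions.

    Genes flagged ns in any contrast form the single pattern class
    ``ns_any``.  With >= 3 contrasts, the concordant-opposing fraction
    counts genes whose first two flags agree and whose third opposes.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 contrast tables")
    counts: "dict[str, int]" = {}
    n_conc = 0
    genes = list(gene_set)
    for g in genes:
        flags = []
        for t in tables:
            if g not in t.index:
                raise KeyError(f"gene {g!r} missing from a contrast table")
            flags.append(str(t.loc[g, "de_flag"]))
        key = "ns_any" if "ns" in flags else ",".join(flags)
        counts[key] = counts.get(key, 0) + 1
        if (
            len(flags) >= 3
            and "ns" not in flags
            and flags[0] == flags[1]
            and flags[2] == _OPPOSITE[flags[0]]
        ):
            n_conc += 1
    n = len(genes)
    fractions = {k: v / n for k, v in counts.items()} if n else {}
    return CoregulationSummary(
        counts=counts,
        fractions=fractions,
        n=n,
        concordant_opposing_fraction=(n_conc / n if n else 0.0),
    )


@dataclass
class RetentionResult:
    n_wt: int
    n_retained: int
    percent: Optional[float]  # None when n_wt == 0
    direction: str

    @property
    def undefined(self) -> bool:
        return self.percent is None


def response_retention(table_wt: pd.DataFrame, table_mut: pd.DataFrame,
                       direction: str) -> RetentionResult:
    """Genes DE in ``direction`` in WT that stay so in the mutant.

    percent = 100 * n_retained / n_wt rounded to one decimal; defined
    result with percent=None when n_wt is 0.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    wt_genes = table_wt.index[table_wt["de_flag"] == direction]
    mut_genes = set(table_mut.index[table_mut["de_flag"] == direction])
    n_wt = len(wt_genes)
    n_retained = sum(1 for g in wt_genes if g in mut_genes)
    percent = round(100.0 * n_retained / n_wt, 1) if n_wt else None
    return RetentionResult(n_wt, n_retained, percent, direction)


def rtqpcr_relative_expression(quant_target: float, quant_ref: float,
                               baseline_target: float,
                               baseline_ref: float) -> float:
    """(target/ref) / (baseline_target/baseline_ref); inputs must be > 0."""
    vals = (quant_target, quant_ref, baseline_target, baseline_ref)
    if any(v <= 0 for v in vals):
        raise ValueError(f"all quantities must be positive, got {vals}")
    return (quant_target / quant_ref) / (baseline_target / baseline_ref)


def ratio_treated_mock(level_treated: float, level_mock: float) -> float:
    if level_treated <= 0 or level_mock <= 0:
        raise ValueError("levels must be positive")
    return level_treated / level_mock
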