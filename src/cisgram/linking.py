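"""Assign binding peaks to target genes and classify peak positions.

A peak links to a gene iff its summit lies in the strand-aware union
of the promoter window [TSS - promoter_bp, TSS), the gene body, and the
downstream window (3' end, 3' end + downstream_bp].  Membership is
decided by the summit, not by interval overlap.
"""
from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import GeneModel, Peak

LINK_COLUMNS = ["peak_id", "gene_id", "factor", "region_class", "signed_distance"]


@dataclass(frozen=True)
class PeakGeneLink:
    peak_id: str
    gene_id: str
    factor: str
    region_class: str
    signed_distance: int


def signed_distance(summit: int, gene: GeneModel) -> int:
    """Strand-aware bp from summit to TSS (negative = upstream)."""
    return summit - gene.tss if gene.strand == "+" else gene.tss - summit


def classify_region(summit: int, gene: GeneModel, promoter_bp: int,
                    downstream_bp: int) -> Optional[str]:
    """Region label for a summit relative to one gene, or None if outside.

    Upstream positions fall into 1-kb bins u1000, u2000, ... out to
    ``promoter_bp``; the gene body is d0; the downstream window is
    labelled d<downstream_bp>.
    """
    if gene.start <= summit < gene.end:
        return "d0"
    d = signed_distance(summit, gene)
    if -promoter_bp <= d < 0:
        return f"u{1000 * math.ceil(-d / 1000)}"
    if gene.strand == "+":
        e = summit - gene.three_prime_end
    else:
        e = gene.three_prime_end - summit
    if 0 < e <= downstream_bp:
        return f"d{downstream_bp}"
    return None


def _gene_arrays(genes: Sequence[GeneModel]):
    tss = np.array([g.tss for g in genes], dtype=np.int64)
    start = np.array([g.start for g in genes], dtype=np.int64)
    end = np.array([g.end for g in genes], dtype=np.int64)
    tpe = np.array([g.three_prime_end for g in genes], dtype=np.int64)
    plus = np.array([g.strand == "+" for g in genes])
    return tss, start, end, tpe, plus


def _membership(summits: np.ndarray, genes: Sequence[GeneModel],
                promoter_bp: int, downstream_bp: int):
    """Vectorized summit-in-window test; returns (member, d) matrices."""
    tss, start, end, tpe, plus = _gene_arrays(genes)
    s = summits[:, None]
    d = np.where(plus[None, :], s - tss[None, :], tss[None, :] - s)
    body = (s >= start[None, :]) & (s < end[None, :])
    upstream = (d >= -promoter_bp) & (d < 0)
    e = np.where(plus[None, :], s - tpe[None, :], tpe[None, :] - s)
    downstream = (e > 0) & (e <= downstream_bp)
    return body | upstream | downstream, d


def assign_peaks_to_genes(peaks: Sequence[Peak], genes: Sequence[GeneModel],
                          promoter_bp: int = 3000,
                          downstream_bp: int = 1000) -> "list[PeakGeneLink]":
    """All (peak, gene) links under the summit-membership rule.

    Links are sorted by (gene_id, peak_id).  Peaks on contigs absent
    from the annotation raise a ValueError listing the offenders.
    """
    genes_by_contig: "dict[str, list[GeneModel]]" = defaultdict(list)
    for g in genes:
        genes_by_contig[g.contig].append(g)
    unknown = [p.peak_id for p in peaks if p.contig not in genes_by_contig]
    if unknown:
        raise ValueError(
            f"peaks on contigs absent from the gene annotation: {unknown}"
        )

    links: "list[PeakGeneLink]" = []
    peaks_by_contig: "dict[str, list[Peak]]" = defaultdict(list)
    for p in peaks:
        peaks_by_contig[p.contig].append(p)

    for contig, contig_peaks in peaks_by_contig.items():
        contig_genes = genes_by_contig[contig]
        summits = np.array([p.summit for p in contig_peaks], dtype=np.int64)
        member, d = _membership(summits, contig_genes, promoter_bp, downstream_bp)
        for i, j in np.argwhere(member):
            peak, gene = contig_peaks[i], contig_genes[j]
            region = classify_region(peak.summit, gene, promoter_bp, downstream_bp)
            links.append(
                PeakGeneLink(
                    peak_id=peak.peak_id,
                    gene_id=gene.gene_id,
                    factor=peak.factor,
                    region_class=region,
                    signed_distance=int(d[i, j]),
                )
            )
    links.sort(key=lambda l: (l.gene_id, l.peak_id))
    return links


def target_genes(links: Sequence[PeakGeneLink]) -> "dict[str, set[str]]":
    """Deduplicated target-gene sets keyed by factor."""
    out: "dict[str, set[str]]" = defaultdict(set)
    for link in links:
        out[link.factor].add(link.gene_id)
    return dict(out)


@dataclass
class PositionDistribution:
    """Per-region-bin peak counts and fractions (fractions over binned peaks)."""

    counts: "dict[str, int]"
    fractions: "dict[str, float]"
    n_binned: int
    n_intergenic: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": k, "count": self.counts[k], "fraction": self.fractions[k]}
            for k in self.counts
        ]
        rows.append(
            {"region": "intergenic", "count": self.n_intergenic,
             "fraction": float("nan")}
        )
        return pd.DataFrame(rows)


def peak_position_distribution(peaks: Sequence[Peak],
                               genes: Sequence[GeneModel],
                               upstream_bp: int = 5000,
                               downstream_bp: int = 1000) -> PositionDistribution:
    """Descriptive distribution of summits over gene-anchored region bins.

    Each peak is assigned to exactly one bin by its summit and its
    nearest gene (smallest absolute signed distance to a TSS; ties
    broken by lexicographically smaller gene_id).  Peaks outside every
    gene's extended window are counted as intergenic.
    """
    bins = [f"u{1000 * k}" for k in range(upstream_bp // 1000, 0, -1)]
    bins += ["d0", f"d{downstream_bp}"]
    counts = {b: 0 for b in bins}
    n_intergenic = 0

    genes_by_contig: "dict[str, list[GeneModel]]" = defaultdict(list)
    for g in genes:
        genes_by_contig[g.contig].append(g)
    for contig in genes_by_contig:
        genes_by_contig[contig].sort(key=lambda g: g.gene_id)

    peaks_by_contig: "dict[str, list[Peak]]" = defaultdict(list)
    for p in peaks:
        peaks_by_contig[p.contig].append(p)

    for contig, contig_peaks in peaks_by_contig.items():
        contig_genes = genes_by_contig.get(contig, [])
        if not contig_genes:
            n_intergenic += len(contig_peaks)
            continue
        summits = np.array([p.summit for p in contig_peaks], dtype=np.int64)
        member, d = _membership(summits, contig_genes, upstream_bp, downstream_bp)
        absd = np.where(member, np.abs(d), np.iinfo(np.int64).max)
        nearest = np.argmin(absd, axis=1)  # first minimum = smallest gene_id
        for i, peak in enumerate(contig_peaks):
            if not member[i].any():
                n_intergenic += 1
                continue
            gene = contig_genes[nearest[i]]
            region = classify_region(peak.summit, gene, upstream_bp, downstream_bp)
            counts[region] += 1

    n_binned = sum(counts.values())
    fractions = {
        b: (counts[b] / n_binned if n_binned else 0.0) for b in bins
    }
    return PositionDistribution(counts, fractions, n_binned, n_intergenic)


def links_to_frame(links: Sequence[PeakGeneLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peak_id": l.peak_id,
                "gene_id": l.gene_id,
                "factor": l.factor,
                "region_class": l.region_class,
                "signed_distance": l.signed_distance,
            }
            for l in links
        ],
        columns=LINK_COLUMNS,
    )


def links_from_frame(df: pd.DataFrame) -> "list[PeakGeneLink]":
    return [
        PeakGeneLink(
            peak_id=str(r.peak_id),
            gene_id=str(r.gene_id),
            factor=str(r.factor),
            region_class=str(r.region_class),
            signed_distance=int(r.signed_distance),
        )
        for r in df.itertuples(index=False)
    ]
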