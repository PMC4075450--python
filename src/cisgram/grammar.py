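"""Motif scanning in peak windows and cis-element grammar statistics.

Exact IUPAC string matching on both strands (N bases in the genome
never match); co-occurrence classes over a core element and an E-box
set; enrichment against genomic background windows; footprint-gap
spacing; activation association; and score-by-class comparison.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    DEFAULT_MOTIFS,
    Genome,
    IUPAC,
    Motif,
    Peak,
    reverse_complement,
)

CORE_NAME = "AuxRE-core"
EBOX_NAMES = ("G-box", "HUD")
CLASSES = ("both", "auxre_only", "ebox_only", "neither")


@dataclass(frozen=True)
class MotifHit:
    """One motif match; offset is relative to the scanned window start."""

    motif: str
    offset: int
    strand: str
    length: int

    @property
    def footprint(self) -> "tuple[int, int]":
        return (self.offset, self.offset + self.length)


def _pattern_regex(pattern: str) -> re.Pattern:
    # Lookahead so overlapping occurrences are all reported; IUPAC codes
    # expand to character classes that exclude N, so N never matches.
    parts = []
    for c in pattern:
        exp = IUPAC[c]
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    return re.compile(f"(?=({''.join(parts)}))")


def find_matches(seq: str, motif: Motif) -> "list[MotifHit]":
    """All forward and reverse-complement matches of one motif in ``seq``.

    Reverse-complement matches are reported on the - strand at forward
    coordinates; palindromic patterns yield exactly one hit per position.
    """
    n = len(motif.pattern)
    hits = [
        MotifHit(motif.name, m.start(), "+", n)
        for m in _pattern_regex(motif.pattern).finditer(seq)
    ]
    if not motif.is_palindrome:
        rc = reverse_complement(motif.pattern)
        hits += [
            MotifHit(motif.name, m.start(), "-", n)
            for m in _pattern_regex(rc).finditer(seq)
        ]
    hits.sort(key=lambda h: (h.offset, h.motif, h.strand))
    return hits


def scan_sequence(seq: str,
                  motifs: Sequence[Motif] = DEFAULT_MOTIFS) -> "list[MotifHit]":
    hits: "list[MotifHit]" = []
    for motif in motifs:
        hits.extend(find_matches(seq, motif))
    hits.sort(key=lambda h: (h.offset, h.motif, h.strand))
    return hits


def extract_window(genome: Genome, contig: str, center: int,
                   halfwidth: int = 100) -> "tuple[int, str]":
    """Window [center - halfwidth, center + halfwidth + 1) clipped to the contig."""
    seq = genome.contigs[contig]
    if not (0 <= center < len(seq)):
        raise ValueError(f"center {center} outside contig {contig!r}")
    lo = max(0, center - halfwidth)
    hi = min(len(seq), center + halfwidth + 1)
    return lo, seq[lo:hi]


def scan_window(genome: Genome, contig: str, center: int,
                halfwidth: int = 100,
                motifs: Sequence[Motif] = DEFAULT_MOTIFS) -> "list[MotifHit]":
    """Scan the clipped window around ``center``; offsets are window-relative."""
    _, window = extract_window(genome, contig, center, halfwidth)
    return scan_sequence(window, motifs)


def footprint_gap(a: "tuple[int, int]", b: "tuple[int, int]") -> int:
    """Bases strictly between two match footprints; overlapping -> 0."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


def _classify_hits(hits: Sequence[MotifHit], core: str,
                   ebox: Sequence[str]) -> "tuple[str, Optional[int]]":
    core_hits = [h for h in hits if h.motif == core]
    ebox_hits = [h for h in hits if h.motif in ebox]
    if core_hits and ebox_hits:
        gap = min(
            footprint_gap(c.footprint, e.footprint)
            for c in core_hits
            for e in ebox_hits
        )
        return "both", gap
    if core_hits:
        return "auxre_only", None
    if ebox_hits:
        return "ebox_only", None
    return "neither", None


def profile_sequence(seq: str, motifs: Sequence[Motif] = DEFAULT_MOTIFS,
                     core: str = CORE_NAME,
                     ebox: Sequence[str] = EBOX_NAMES):
    """(class, min_gap, hits) for a raw window sequence."""
    hits = scan_sequence(seq, motifs)
    cls, gap = _classify_hits(hits, core, ebox)
    return cls, gap, hits


@dataclass(frozen=True)
class PeakMotifProfile:
    peak_id: str
    hits: "tuple[MotifHit, ...]"
    cooccurrence_class: str
    min_gap: Optional[int]


def build_profiles(genome: Genome, peaks: Sequence[Peak],
                   halfwidth: int = 100,
                   motifs: Sequence[Motif] = DEFAULT_MOTIFS,
                   core: str = CORE_NAME,
                   ebox: Sequence[str] = EBOX_NAMES) -> "list[PeakMotifProfile]":
    """Per-peak motif hits within +/- ``halfwidth`` bp of the summit."""
    profiles = []
    for p in peaks:
        hits = scan_window(genome, p.contig, p.summit, halfwidth, motifs)
        cls, gap = _classify_hits(hits, core, ebox)
        profiles.append(PeakMotifProfile(p.peak_id, tuple(hits), cls, gap))
    return profiles


def classify_cooccurrence(profiles: Sequence[PeakMotifProfile]):
    """(peak_id -> class, class fractions).  Fractions sum to 1 when n > 0."""
    classes = {p.peak_id: p.cooccurrence_class for p in profiles}
    n = len(profiles)
    fractions = {
        c: (sum(1 for p in profiles if p.cooccurrence_class == c) / n if n else 0.0)
        for c in CLASSES
    }
    return classes, fractions


def sample_background_windows(genome: Genome, n: int, halfwidth: int,
                              exclude: Sequence["tuple[str, int, int]"],
                              rng: np.random.Generator) -> "list[str]":
    """``n`` windows drawn uniformly from the genome, avoiding ``exclude``.

    ``exclude`` is a list of (contig, start, end) intervals (typically
    the peak windows themselves); candidate centers falling inside any
    are rejected and redrawn.
    """
    contigs = list(genome.contigs)
    lengths = np.array([genome.length(c) for c in contigs], dtype=float)
    probs = lengths / lengths.sum()
    excl: "dict[str, list[tuple[int, int]]]" = {}
    for contig, s, e in exclude:
        excl.setdefault(contig, []).append((s, e))
    windows: "list[str]" = []
    attempts = 0
    while len(windows) < n:
        attempts += 1
        if attempts > 1000 * max(n, 1):
            raise RuntimeError("background sampling failed; exclusion too dense")
        ci = rng.choice(len(contigs), p=probs)
        contig = contigs[ci]
        L = genome.length(contig)
        if L < 2 * halfwidth + 1:
            continue
        center = int(rng.integers(halfwidth, L - halfwidth))
        if any(s <= center < e for s, e in excl.get(contig, [])):
            continue
        windows.append(genome.contigs[contig][center - halfwidth:
                                              center + halfwidth + 1])
    return windows


def motif_enrichment(peak_windows: Sequence[str],
                     background_windows: Sequence[str],
                     motifs: Sequence[Motif] = DEFAULT_MOTIFS) -> pd.DataFrame:
    """Per-motif presence/absence enrichment of peaks over background.

    fold = (peak fraction + 0.5/n_peak) / (background fraction + 0.5/n_bg);
    p from a two-sided Fisher exact test on the 2x2 presence table.
    """
    if not background_windows:
        raise ValueError("empty background window set")
    if not peak_windows:
        raise ValueError("empty peak window set")
    n_p, n_b = len(peak_windows), len(background_windows)
    eps_p, eps_b = 0.5 / n_p, 0.5 / n_b
    rows = []
    for motif in motifs:
        a = sum(1 for w in peak_windows if find_matches(w, motif))
        b = sum(1 for w in background_windows if find_matches(w, motif))
        fold = (a / n_p + eps_p) / (b / n_b + eps_b)
        _, p = stats.fisher_exact([[a, n_p - a], [b, n_b - b]],
                                  alternative="two-sided")
        rows.append(
            {
                "motif": motif.name,
                "pattern": motif.pattern,
                "n_peak": n_p,
                "n_peak_with": a,
                "n_background": n_b,
                "n_background_with": b,
                "peak_fraction": a / n_p,
                "background_fraction": b / n_b,
                "fold": fold,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SpacingResult:
    observed_gaps: np.ndarray
    background_gaps: np.ndarray
    histogram: pd.DataFrame
    observed_frac_within_20: float
    background_frac_within_20: float


def _gap_histogram(observed: np.ndarray, background: np.ndarray,
                   bin_width: int) -> pd.DataFrame:
    top = 0
    for arr in (observed, background):
        if arr.size:
            top = max(top, int(arr.max()))
    edges = np.arange(0, top + bin_width + 1, bin_width)
    obs_counts, _ = np.histogram(observed, bins=edges)
    bg_counts, _ = np.histogram(background, bins=edges)
    return pd.DataFrame(
        {
            "gap_lo": edges[:-1],
            "gap_hi": edges[1:] - 1,
            "observed_count": obs_counts,
            "observed_fraction": obs_counts / observed.size if observed.size else 0.0,
            "background_count": bg_counts,
            "background_fraction": (
                bg_counts / background.size if background.size else 0.0
            ),
        }
    )


def spacing_distribution(profiles: Sequence[PeakMotifProfile],
                         background_windows: Sequence[str],
                         motifs: Sequence[Motif] = DEFAULT_MOTIFS,
                         core: str = CORE_NAME,
                         ebox: Sequence[str] = EBOX_NAMES,
                         bin_width: int = 5) -> SpacingResult:
    """Gap histogram (observed vs background) over class-"both" windows.

    The gap is measured edge-to-edge between the nearest core-element
    and E-box match footprints; overlapping footprints count as 0.
    """
    observed = np.array(
        [p.min_gap for p in profiles if p.cooccurrence_class == "both"],
        dtype=int,
    )
    bg = []
    for w in background_windows:
        cls, gap, _ = profile_sequence(w, motifs, core, ebox)
        if cls == "both":
            bg.append(gap)
    background = np.array(bg, dtype=int)
    hist = _gap_histogram(observed, background, bin_width)
    return SpacingResult(
        observed_gaps=observed,
        background_gaps=background,
        histogram=hist,
        observed_frac_within_20=(
            float((observed <= 20).mean()) if observed.size else 0.0
        ),
        background_frac_within_20=(
            float((background <= 20).mean()) if background.size else 0.0
        ),
    )


@dataclass
class AssociationResult:
    n_both: int
    n_both_activated: int
    n_auxre_only: int
    n_auxre_only_activated: int
    pct_both: float
    pct_auxre_only: float
    p: float
    stars: str
    warning: bool


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def activation_association(classes: Mapping[str, str],
                           activated: Mapping[str, bool]) -> AssociationResult:
    """% activated among class "both" vs "auxre_only", with Fisher p.

    If either class is empty the result is defined with p = 1 and a
    warning flag.
    """
    both = [pid for pid, c in classes.items() if c == "both"]
    aux = [pid for pid, c in classes.items() if c == "auxre_only"]
    a = sum(1 for pid in both if activated.get(pid, False))
    b = sum(1 for pid in aux if activated.get(pid, False))
    warning = not both or not aux
    if warning:
        p = 1.0
    else:
        _, p = stats.fisher_exact(
            [[a, len(both) - a], [b, len(aux) - b]], alternative="two-sided"
        )
    return AssociationResult(
        n_both=len(both),
        n_both_activated=a,
        n_auxre_only=len(aux),
        n_auxre_only_activated=b,
        pct_both=100.0 * a / len(both) if both else 0.0,
        pct_auxre_only=100.0 * b / len(aux) if aux else 0.0,
        p=float(p),
        stars=_stars(p),
        warning=warning,
    )


@dataclass
class ScoreByClassResult:
    summary: pd.DataFrame
    u_statistic: Optional[float]
    p: Optional[float]


def score_by_class(peaks: Sequence[Peak],
                   profiles: Sequence[PeakMotifProfile]) -> ScoreByClassResult:
    """Score quartiles per co-occurrence class + Mann-Whitney "both" vs "auxre_only".

    Classes with fewer than 2 peaks get a summary but no test.
    """
    cls_by_peak = {p.peak_id: p.cooccurrence_class for p in profiles}
    scores: "dict[str, list[float]]" = {c: [] for c in CLASSES}
    for peak in peaks:
        if peak.peak_id in cls_by_peak:
            scores[cls_by_peak[peak.peak_id]].append(peak.score)
    rows = []
    for c in CLASSES:
        vals = np.array(scores[c], dtype=float)
        if vals.size:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
        else:
            q1 = med = q3 = float("nan")
        rows.append({"class": c, "n": vals.size, "q1": q1, "median": med, "q3": q3})
    summary = pd.DataFrame(rows)
    x, y = scores["both"], scores["auxre_only"]
    if len(x) < 2 or len(y) < 2:
        return ScoreByClassResult(summary, None, None)
    method = "exact" if (
        len(x) <= 30 and len(y) <= 30 and len(set(x + y)) == len(x) + len(y)
    ) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ScoreByClassResult(summary, float(res.statistic), float(res.pvalue))
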