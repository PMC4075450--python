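"""Domain types, coordinate conventions, and text-format I/O.

All internal coordinates are 0-based half-open on the forward strand.
GFF3 (1-based inclusive) is converted only at the I/O boundary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


class ConfigError(ValueError):
    """An invalid configuration value or combination."""


# IUPAC nucleotide codes -> the set of concrete bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B",
}

# Genome alphabet after normalization.
_GENOME_ALPHABET = frozenset("ACGTN")
_AMBIGUITY = frozenset("RYSWKMBDHV")
_AMBIGUITY_TO_N = str.maketrans({c: "N" for c in _AMBIGUITY})


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


@dataclass
class Genome:
    """Ordered mapping of contig name -> uppercase A/C/G/T/N sequence."""

    contigs: "dict[str, str]"

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(seq) - _GENOME_ALPHABET
            if bad:
                raise ValueError(
                    f"contig {name!r} has characters outside ACGTN: {sorted(bad)}"
                )

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self.contigs == other.contigs


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene; the coordinate anchor for all peak linking.

    ``start``/``end`` form a 0-based half-open interval on the forward
    strand.  ``tss`` and ``three_prime_end`` are strand-aware base
    positions lying inside [start, end).
    """

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime_end(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class Peak:
    """One binding region with its summit and caller score."""

    peak_id: str
    factor: str
    contig: str
    start: int
    end: int
    summit: int
    score: float
    fdr: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.peak_id}: summit {self.summit} outside "
                f"[{self.start}, {self.end})"
            )
        if self.score < 0:
            raise ValueError(f"peak {self.peak_id}: negative score")
        if self.fdr is not None and not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"peak {self.peak_id}: fdr outside [0, 1]")


@dataclass(frozen=True)
class Motif:
    """A named IUPAC pattern matched as an exact (expanded) string."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) < 4:
            raise ValueError(f"motif {self.name}: pattern shorter than 4")
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.name}: non-IUPAC characters {sorted(bad)}")

    @property
    def is_palindrome(self) -> bool:
        return self.pattern == reverse_complement(self.pattern)


DEFAULT_MOTIFS: "tuple[Motif, ...]" = (
    Motif("AuxRE-core", "TGTC"),
    Motif("AuxRE", "TGTCTC"),
    Motif("AuxRE-alt", "TGTCGG"),
    Motif("G-box", "CACGTG"),
    Motif("HUD", "CACATG"),
    Motif("control", "GATCG"),
)


# ---------------------------------------------------------------------------
# FASTA

def parse_fasta(path) -> Genome:
    """Read a multi-record FASTA into a :class:`Genome`.

    Header text up to the first whitespace is the contig name.  Sequence
    is uppercased; IUPAC ambiguity codes are normalized to N; any other
    character is a parse error naming the line.
    """
    path = Path(path)
    contigs: "dict[str, str]" = {}
    name: Optional[str] = None
    chunks: "list[str]" = []
    header_line = 0

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}:{header_line}: empty record {name!r}")
        contigs[name] = seq

    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                new_name = line[1:].split()[0] if line[1:].split() else ""
                if not new_name:
                    raise ParseError(f"{path}:{line_no}: FASTA header without a name")
                if new_name in contigs or new_name == name:
                    raise ParseError(
                        f"{path}:{line_no}: duplicate contig name {new_name!r}"
                    )
                name = new_name
                header_line = line_no
                chunks = []
            else:
                if name is None:
                    raise ParseError(f"{path}:{line_no}: sequence before first header")
                up = line.upper()
                bad = set(up) - _GENOME_ALPHABET - _AMBIGUITY
                if bad:
                    raise ParseError(
                        f"{path}:{line_no}: non-IUPAC character(s) {sorted(bad)}"
                    )
                chunks.append(up.translate(_AMBIGUITY_TO_N))
    flush()
    if not contigs:
        raise ParseError(f"{path}: no FASTA records")
    return Genome(contigs)


def write_fasta(genome: Genome, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (gene features only)

def parse_gff3_genes(path) -> "list[GeneModel]":
    """Read ``gene`` features from a GFF3 file.

    1-based inclusive coordinates are converted to 0-based half-open;
    the minus-strand TSS is the record's end coordinate.
    """
    path = Path(path)
    genes: "list[GeneModel]" = []
    seen: "set[str]" = set()
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ParseError(f"{path}:{line_no}: expected >= 8 GFF3 columns")
            if cols[2] != "gene":
                continue
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{line_no}: non-integer coordinates") from exc
            if start1 > end1:
                raise ParseError(f"{path}:{line_no}: start > end")
            strand = cols[6]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{line_no}: unknown strand {strand!r}")
            gene_id = f"gene{line_no}"
            if len(cols) >= 9:
                for item in cols[8].split(";"):
                    if item.startswith("ID="):
                        gene_id = item[3:]
                        break
            if gene_id in seen:
                raise ParseError(f"{path}:{line_no}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            genes.append(
                GeneModel(gene_id, cols[0], strand, start=start1 - 1, end=end1)
            )
    return genes


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.contig,
                        "cisgram",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Peak tables

PEAK_COLUMNS = ["contig", "start", "end", "peak_id", "score", "summit_offset"]


def parse_peaks(path, factor: Optional[str] = None,
                fdr_threshold: Optional[float] = 0.01) -> "list[Peak]":
    """Read a 6-7 column peak TSV (header required).

    ``summit = start + summit_offset``.  When an ``fdr`` column is
    present, peaks with fdr >= ``fdr_threshold`` are dropped (pass
    ``fdr_threshold=None`` to keep everything).  A ``factor`` column,
    when present, overrides the ``factor`` argument.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    has_fdr = "fdr" in df.columns
    has_factor = "factor" in df.columns
    peaks: "list[Peak]" = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        start, end = int(row.start), int(row.end)
        offset = int(row.summit_offset)
        if not (0 <= offset < end - start):
            raise ParseError(
                f"{path}:{line_no}: summit offset {offset} outside peak of "
                f"width {end - start}"
            )
        fdr = None
        if has_fdr and not pd.isna(row.fdr):
            fdr = float(row.fdr)
        if fdr is not None and fdr_threshold is not None and fdr >= fdr_threshold:
            continue
        fac = str(row.factor) if has_factor else (factor or "NA")
        peaks.append(
            Peak(
                peak_id=str(row.peak_id),
                factor=fac,
                contig=str(row.contig),
                start=start,
                end=end,
                summit=start + offset,
                score=float(row.score),
                fdr=fdr,
            )
        )
    return peaks


def write_peaks(peaks: Sequence[Peak], path) -> None:
    rows = []
    any_fdr = any(p.fdr is not None for p in peaks)
    for p in peaks:
        row = {
            "contig": p.contig,
            "start": p.start,
            "end": p.end,
            "peak_id": p.peak_id,
            "score": p.score,
            "summit_offset": p.summit - p.start,
            "factor": p.factor,
        }
        if any_fdr:
            row["fdr"] = p.fdr if p.fdr is not None else math.nan
        rows.append(row)
    cols = PEAK_COLUMNS + ["factor"] + (["fdr"] if any_fdr else [])
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.10g", lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Generic TSV tables

def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g",
              lineterminator="\n")
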