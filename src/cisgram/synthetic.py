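"""Synthetic genomes, Venn-structured peak sets with planted motifs, and
replicate expression counts with configurable dependence structure.

Every planted quantity (Venn fractions, motif class probabilities,
spacing-law parameters, retention fraction, target correlation,
coregulation pattern mix) is written to ground-truth tables so the
analysis modules can be tested by parameter recovery.  All randomness
flows from a single seed through per-stage substreams, so identical
configs give byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    ConfigError,
    Genome,
    GeneModel,
    Peak,
    write_fasta,
    write_gff3,
    write_peaks,
    write_table,
)
from . import grammar

VENN_REGIONS = ("A", "B", "C", "AB", "AC", "BC", "ABC", "none")
MOTIF_CLASSES = ("both", "auxre_only", "ebox_only", "neither")
_STAGES = ("genome", "peaks", "expression", "coregulation")

# Sign patterns over three contrasts; the first two are the
# concordant-opposing patterns (first two agree, third opposes).
_CONCORDANT_OPPOSING = (("up", "up", "down"), ("down", "down", "up"))
_OTHER_PATTERNS = tuple(
    (a, b, c)
    for a in ("up", "down")
    for b in ("up", "down")
    for c in ("up", "down")
    if (a, b, c) not in _CONCORDANT_OPPOSING
)

_EBOX_PATTERNS = ("CACGTG", "CACATG")
# Patterns scrubbed from planted windows (both strands covered by the
# scanner); GATCG is deliberately left alone so it stays a clean control.
_SCRUB_MOTIFS = tuple(
    m for m in grammar.DEFAULT_MOTIFS
    if m.name in ("AuxRE-core", "G-box", "HUD")
)


def _default_venn() -> "dict[str, float]":
    return {
        "A": 0.10, "B": 0.10, "C": 0.10,
        "AB": 0.05, "AC": 0.10, "BC": 0.05,
        "ABC": 0.15, "none": 0.35,
    }


def _default_motif_probs() -> "dict[str, float]":
    return {"both": 0.5, "auxre_only": 0.4, "ebox_only": 0.05, "neither": 0.05}


@dataclass
class SyntheticConfig:
    seed: int = 0
    genome_length: int = 2_000_000
    n_genes: int = 200
    gc_content: float = 0.36
    promoter_window: int = 3000
    factors: "tuple[str, ...]" = ("ARF6", "BZR1", "PIF4")
    venn_fractions: "dict[str, float]" = field(default_factory=_default_venn)
    peak_width: "tuple[int, int]" = (200, 400)
    gene_length: "tuple[int, int]" = (800, 2000)
    motif_class_probs: "dict[str, float]" = field(
        default_factory=_default_motif_probs
    )
    spacing_law: "tuple" = ("uniform", 0, 20)
    score_shift_both: float = 2.0
    n_replicates: int = 3
    lfc_mean: float = 3.0
    lfc_sd: float = 0.5
    responsive_fraction: float = 0.3
    retention_fraction: float = 0.2
    target_corr: float = -0.6
    nb_dispersion: float = 0.05
    pattern_fraction: float = 0.7
    coregulated_fraction: float = 0.4

    def validate(self) -> None:
        if len(self.factors) != 3:
            raise ConfigError("exactly 3 factors required")
        if set(self.venn_fractions) != set(VENN_REGIONS):
            raise ConfigError(f"venn_fractions must have keys {VENN_REGIONS}")
        total = sum(self.venn_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"venn_fractions sum to {total}, expected 1")
        if set(self.motif_class_probs) != set(MOTIF_CLASSES):
            raise ConfigError(f"motif_class_probs must have keys {MOTIF_CLASSES}")
        ptot = sum(self.motif_class_probs.values())
        if abs(ptot - 1.0) > 1e-9:
            raise ConfigError(f"motif_class_probs sum to {ptot}, expected 1")
        for name, probs in (
            ("venn_fractions", self.venn_fractions),
            ("motif_class_probs", self.motif_class_probs),
        ):
            if any(not (0.0 <= v <= 1.0) for v in probs.values()):
                raise ConfigError(f"{name} values must lie in [0, 1]")
        if not (0.0 < self.gc_content < 1.0):
            raise ConfigError("gc_content must be in (0, 1)")
        if abs(self.target_corr) > 1.0:
            raise ConfigError("|target_corr| must be <= 1")
        for frac_name in ("responsive_fraction", "retention_fraction",
                          "pattern_fraction", "coregulated_fraction"):
            v = getattr(self, frac_name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{frac_name} must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if self.spacing_law[0] == "uniform":
            _, lo, hi = self.spacing_law
            if not (0 <= lo <= hi):
                raise ConfigError("uniform spacing law needs 0 <= lo <= hi")
        elif self.spacing_law[0] == "geometric":
            if not (0.0 < self.spacing_law[1] <= 1.0):
                raise ConfigError("geometric spacing law needs p in (0, 1]")
        else:
            raise ConfigError(f"unknown spacing law {self.spacing_law[0]!r}")

    def rng_for(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage substream derived from the config seed."""
        idx = _STAGES.index(stage)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,))
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["factors"] = list(self.factors)
        d["peak_width"] = list(self.peak_width)
        d["gene_length"] = list(self.gene_length)
        d["spacing_law"] = list(self.spacing_law)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        kwargs = dict(d)
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown synthetic config keys: {sorted(unknown)}")
        for key in ("factors", "peak_width", "gene_length", "spacing_law"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Planted parameters of one synthetic bundle, one row per gene/peak."""

    targets: pd.DataFrame  # gene_id, region, is_<factor> flags
    peak_motifs: pd.DataFrame  # peak_id, gene_id, motif_class, planted_gap
    expression: Optional[pd.DataFrame] = None
    patterns: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# Genome + annotation

def generate_genome(config: SyntheticConfig) -> "tuple[Genome, list[GeneModel]]":
    """I.i.d. bases at the configured GC; non-overlapping genes with
    >= promoter_window + 1000 bp gaps between and around them."""
    config.validate()
    rng = config.rng_for("genome")
    gl0, gl1 = config.gene_length
    gap = config.promoter_window + 1000
    lengths = rng.integers(gl0, gl1 + 1, size=config.n_genes)
    needed = int(lengths.sum()) + gap * (config.n_genes + 1)
    if needed > config.genome_length:
        raise ConfigError(
            f"cannot pack {config.n_genes} genes with {gap} bp flanks into "
            f"{config.genome_length} bp (need >= {needed})"
        )
    slack = config.genome_length - needed
    extra = (
        rng.multinomial(slack, [1.0 / (config.n_genes + 1)] * (config.n_genes + 1))
        if slack > 0
        else np.zeros(config.n_genes + 1, dtype=int)
    )
    strands = rng.choice(np.array(["+", "-"]), size=config.n_genes)

    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=config.genome_length, p=probs)
    seq = (
        np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode("ascii")
    )
    genome = Genome({"chr1": seq})

    genes: "list[GeneModel]" = []
    cursor = 0
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        cursor += gap + int(extra[i])
        start = cursor
        end = start + int(lengths[i])
        cursor = end
        genes.append(
            GeneModel(
                gene_id=f"g{i:0{max(width, 4)}d}",
                contig="chr1",
                strand=str(strands[i]),
                start=start,
                end=end,
            )
        )
    return genome, genes


# ---------------------------------------------------------------------------
# Peaks with planted motifs

def _draw_gap(config: SyntheticConfig, rng: np.random.Generator) -> int:
    law = config.spacing_law
    if law[0] == "uniform":
        return int(rng.integers(law[1], law[2] + 1))
    return int(rng.geometric(law[1]) - 1)


def _scrub(chars: "list[str]", rng: np.random.Generator,
           protect: "set[int]" = frozenset()) -> None:
    """Destroy all scrub-motif occurrences in-place by random base edits.

    Positions in ``protect`` are never touched (planted motifs live there).
    """
    bases = "ACGT"
    for _ in range(200):
        hits = grammar.scan_sequence("".join(chars), _SCRUB_MOTIFS)
        dirty = False
        for h in hits:
            span = [
                i for i in range(h.offset, h.offset + h.length)
                if i not in protect
            ]
            if not span:
                continue  # fully protected = a planted motif
            dirty = True
            pos = span[len(span) // 2]
            old = chars[pos]
            choices = [b for b in bases if b != old]
            chars[pos] = choices[int(rng.integers(len(choices)))]
        if not dirty:
            return
    raise RuntimeError("window scrubbing did not converge")


def _plant_window(chars: "list[str]", cls: str, gap: int,
                  rng: np.random.Generator) -> bool:
    """Plant motifs for one class into a window; True when the final
    window classifies exactly as intended (and measures the planted gap)."""
    wlen = len(chars)
    protect: "set[int]" = set()
    if cls == "both":
        ebox = _EBOX_PATTERNS[int(rng.integers(2))]
        core = "TGTC"
        total = len(core) + gap + len(ebox)
        if total > wlen:
            return False
        left = int(rng.integers(0, wlen - total + 1))
        first, second = (core, ebox) if rng.integers(2) == 0 else (ebox, core)
        for i, c in enumerate(first):
            chars[left + i] = c
        off2 = left + len(first) + gap
        for i, c in enumerate(second):
            chars[off2 + i] = c
        protect = set(range(left, left + len(first))) | set(
            range(off2, off2 + len(second))
        )
    elif cls == "auxre_only":
        left = int(rng.integers(0, wlen - 4 + 1))
        for i, c in enumerate("TGTC"):
            chars[left + i] = c
        protect = set(range(left, left + 4))
    elif cls == "ebox_only":
        ebox = _EBOX_PATTERNS[int(rng.integers(2))]
        left = int(rng.integers(0, wlen - len(ebox) + 1))
        for i, c in enumerate(ebox):
            chars[left + i] = c
        protect = set(range(left, left + len(ebox)))
    # "neither": nothing planted.

    _scrub(chars, rng, protect)
    got_cls, got_gap, _ = grammar.profile_sequence("".join(chars))
    if got_cls != cls:
        return False
    if cls == "both" and got_gap != gap:
        return False
    return True


def plant_peaks(config: SyntheticConfig, genome: Genome,
                genes: Sequence[GeneModel]
                ) -> "tuple[dict[str, list[Peak]], Genome, GroundTruth]":
    """One peak per (factor, target gene); motifs planted for the first
    factor's peaks by overwriting sequence in place.

    Target genes are drawn per ``venn_fractions``; summits are uniform
    in [TSS-1000, TSS); co-bound summits sit within 200 bp of each
    other.  Returns the (modified) genome alongside peaks and truth.
    """
    config.validate()
    rng = config.rng_for("peaks")
    chars = list(genome.contigs["chr1"])
    L = len(chars)

    region_probs = [config.venn_fractions[r] for r in VENN_REGIONS]
    region_idx = rng.choice(len(VENN_REGIONS), size=len(genes), p=region_probs)

    letter_of = {config.factors[0]: "A", config.factors[1]: "B",
                 config.factors[2]: "C"}
    peaks: "dict[str, list[Peak]]" = {f: [] for f in config.factors}
    target_rows = []
    motif_rows = []
    w0, w1 = config.peak_width
    halfw = 100

    for gene, ridx in zip(genes, region_idx):
        region = VENN_REGIONS[ridx]
        bound = [f for f in config.factors if letter_of[f] in region]
        target_rows.append(
            {
                "gene_id": gene.gene_id,
                "region": region,
                **{f"is_{f}": (f in bound) for f in config.factors},
            }
        )
        if not bound:
            continue
        tss = gene.tss
        sign = 1 if gene.strand == "+" else -1
        u0 = int(rng.integers(1, 1001))  # primary summit: TSS-1000 .. TSS-1
        s0 = tss - sign * u0
        for factor in bound:
            if factor == bound[0]:
                summit = s0
            else:
                delta = int(rng.integers(-100, 101))
                summit = s0 + delta
                lo_s = min(tss - sign * 1000, tss - sign * 1)
                hi_s = max(tss - sign * 1000, tss - sign * 1)
                summit = int(np.clip(summit, lo_s, hi_s))
            width = int(rng.integers(w0, w1 + 1))
            start = max(0, summit - width // 2)
            end = min(L, start + width)
            score = float(rng.lognormal(mean=2.0, sigma=0.5))
            peak_id = f"{factor}_{gene.gene_id}"

            if factor == config.factors[0]:
                cls = MOTIF_CLASSES[
                    int(
                        rng.choice(
                            len(MOTIF_CLASSES),
                            p=[config.motif_class_probs[c] for c in MOTIF_CLASSES],
                        )
                    )
                ]
                gap = _draw_gap(config, rng) if cls == "both" else None
                wlo = max(0, summit - halfw)
                whi = min(L, summit + halfw + 1)
                for attempt in range(50):
                    wchars = chars[wlo:whi]
                    if _plant_window(wchars, cls, gap if gap is not None else 0,
                                     rng):
                        chars[wlo:whi] = wchars
                        break
                else:
                    raise RuntimeError(
                        f"motif planting failed for peak {peak_id}"
                    )
                if cls == "both":
                    score += config.score_shift_both
                motif_rows.append(
                    {
                        "peak_id": peak_id,
                        "gene_id": gene.gene_id,
                        "motif_class": cls,
                        "planted_gap": gap if gap is not None else np.nan,
                    }
                )
            peaks[factor].append(
                Peak(
                    peak_id=peak_id,
                    factor=factor,
                    contig="chr1",
                    start=start,
                    end=end,
                    summit=summit,
                    score=score,
                )
            )

    new_genome = Genome({"chr1": "".join(chars)})
    truth = GroundTruth(
        targets=pd.DataFrame(target_rows),
        peak_motifs=pd.DataFrame(
            motif_rows,
            columns=["peak_id", "gene_id", "motif_class", "planted_gap"],
        ),
    )
    return peaks, new_genome, truth


# ---------------------------------------------------------------------------
# Expression counts

CONDITIONS = ("WT_mock", "WT_BL", "mut_mock", "mut_BL")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray,
               dispersion: float) -> np.ndarray:
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _equalize_depth(means: "dict[str, np.ndarray]") -> "dict[str, np.ndarray]":
    """Scale per-condition mean vectors to a common expected total.

    Mimics fixed sequencing depth, so CPM normalization recovers the
    planted fold changes without composition bias.
    """
    totals = {k: v.sum() for k, v in means.items()}
    target = np.mean(list(totals.values()))
    return {k: v * (target / totals[k]) for k, v in means.items()}


def simulate_expression(config: SyntheticConfig,
                        ground_truth: Optional[GroundTruth] = None
                        ) -> "tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]":
    """Negative-binomial replicate counts for WT/mut x mock/BL.

    True contrast effects by construction:
      WT_BL vs WT_mock   = e1 (responsive genes only),
      mut_BL vs mut_mock = e1 * retained,
      mut_BL vs WT_BL    = e2, where corr(e1, e2) = target_corr exactly
                           at the population level.

    Returns (counts, design, expression truth).  Gene ids come from the
    ground truth when given, else ``g00000``-style ids over n_genes.
    """
    config.validate()
    rng = config.rng_for("expression")
    if ground_truth is not None:
        gene_ids = list(ground_truth.targets["gene_id"])
    else:
        gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    n = len(gene_ids)

    responsive = rng.random(n) < config.responsive_fraction
    magnitude = np.abs(config.lfc_mean + config.lfc_sd * rng.standard_normal(n))
    retained = responsive & (rng.random(n) < config.retention_fraction)
    base = rng.lognormal(mean=6.5, sigma=1.0, size=n)

    # Assign up/down so the multiplicative mass of the planted effects
    # balances (sum base*2^e ~= sum base).  CPM normalization measures
    # relative abundance, so unbalanced mass would shift every gene's
    # apparent fold change; balancing makes planted effects recoverable.
    sign = np.zeros(n)
    resp_idx = np.flatnonzero(responsive)
    up_mass = base[resp_idx] * (2.0 ** magnitude[resp_idx] - 1.0)
    dn_mass = base[resp_idx] * (1.0 - 2.0 ** -magnitude[resp_idx])
    order = resp_idx[np.argsort(-np.maximum(up_mass, dn_mass))]
    imbalance = 0.0
    for i in order:
        if imbalance > 0:
            sign[i] = -1.0
            imbalance -= base[i] * (1.0 - 2.0 ** -magnitude[i])
        else:
            sign[i] = 1.0
            imbalance += base[i] * (2.0 ** magnitude[i] - 1.0)
    e1 = np.where(responsive, sign * magnitude, 0.0)

    rho = config.target_corr
    z1 = (e1 - e1.mean()) / e1.std() if e1.std() > 0 else np.zeros(n)
    noise = rng.standard_normal(n)
    e2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho ** 2)) * noise

    means = _equalize_depth(
        {
            "WT_mock": base,
            "WT_BL": base * 2.0 ** e1,
            "mut_BL": base * 2.0 ** (e1 + e2),
            "mut_mock": base * 2.0 ** (e1 + e2 - e1 * retained),
        }
    )

    cols = {}
    design_rows = []
    for cond in CONDITIONS:
        genotype, treatment = cond.split("_")
        for k in range(1, config.n_replicates + 1):
            lib = f"{cond}_r{k}"
            cols[lib] = _nb_counts(rng, means[cond], config.nb_dispersion)
            design_rows.append(
                {
                    "library": lib,
                    "genotype": genotype,
                    "treatment": treatment,
                    "replicate": k,
                    "condition": cond,
                }
            )
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    design = pd.DataFrame(design_rows)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "responsive": responsive,
            "retained": retained,
            "lfc_wt": e1,
            "lfc_geno": e2,
            "lfc_mut": e1 * retained,
        }
    )
    return counts, design, truth


# ---------------------------------------------------------------------------
# Coregulation patterns (three contrasts against a shared reference)

def simulate_coregulation(config: SyntheticConfig,
                          n_genes: Optional[int] = None
                          ) -> "tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]":
    """Counts for conditions {ref, c1, c2, c3} with planted sign patterns.

    A ``coregulated_fraction`` of genes is DE in all three contrasts; of
    those, ``pattern_fraction`` get a concordant-opposing pattern (the
    first two contrasts agree, the third opposes), the rest one of the
    six other full sign patterns.  Remaining genes are null.
    """
    config.validate()
    rng = config.rng_for("coregulation")
    n = n_genes if n_genes is not None else config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]

    n_coreg = int(round(config.coregulated_fraction * n))
    if 2 * n_coreg > n:
        raise ConfigError(
            "coregulated_fraction too high to place ballast genes"
        )
    coreg = np.zeros(n, dtype=bool)
    coreg[rng.choice(n, size=n_coreg, replace=False)] = True
    use_conc = rng.random(n) < config.pattern_fraction
    conc_pick = rng.integers(0, len(_CONCORDANT_OPPOSING), size=n)
    other_pick = rng.integers(0, len(_OTHER_PATTERNS), size=n)
    base = rng.lognormal(mean=6.5, sigma=1.0, size=n)

    # Every coregulated gene gets a high-expression ballast partner whose
    # small compensating effects cancel the planted multiplicative mass
    # per contrast exactly, so CPM normalization does not shift the null
    # genes.  Ballast effects are -1 (opposite an "up") or ~+0.06
    # (opposite a "down"): always below the fold threshold in at least
    # one contrast, so ballast genes never enter a DE-in-all gene set.
    m = config.lfc_mean
    alpha = 2.0 * (2.0 ** m - 1.0)  # ballast base multiple; gives e' = -1
    ballast_up = np.log2(1.0 - (2.0 ** m - 1.0) / alpha)  # compensates "up"
    ballast_dn = np.log2(1.0 + (1.0 - 2.0 ** -m) / alpha)  # compensates "down"

    coreg_idx = np.flatnonzero(coreg)
    pool = np.flatnonzero(~coreg)
    ballast_idx = rng.choice(pool, size=len(coreg_idx), replace=False)

    effects = np.zeros((n, 3))
    patterns = ["ns"] * n
    roles = ["null"] * n
    for i, k in zip(coreg_idx, ballast_idx):
        pat = (
            _CONCORDANT_OPPOSING[conc_pick[i]]
            if use_conc[i]
            else _OTHER_PATTERNS[other_pick[i]]
        )
        patterns[i] = ",".join(pat)
        roles[i] = "coregulated"
        roles[k] = "ballast"
        base[k] = alpha * base[i]
        for j, direction in enumerate(pat):
            effects[i, j] = m if direction == "up" else -m
            effects[k, j] = ballast_up if direction == "up" else ballast_dn
    means = _equalize_depth(
        {
            cond: (base if cond == "ref" else base * 2.0 ** effects[:, j - 1])
            for j, cond in enumerate(["ref", "c1", "c2", "c3"])
        }
    )
    cols = {}
    design_rows = []
    for cond in ("ref", "c1", "c2", "c3"):
        mu = means[cond]
        for k in range(1, config.n_replicates + 1):
            lib = f"{cond}_r{k}"
            cols[lib] = _nb_counts(rng, mu, config.nb_dispersion)
            design_rows.append(
                {"library": lib, "genotype": "NA", "treatment": cond,
                 "replicate": k, "condition": cond}
            )
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    design = pd.DataFrame(design_rows)
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "coregulated": coreg, "role": roles,
         "pattern": patterns}
    )
    return counts, design, truth


# ---------------------------------------------------------------------------
# Bundle writer

def write_bundle(config: SyntheticConfig, outdir) -> "dict[str, Path]":
    """Generate everything and write the full text bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    genome, genes = generate_genome(config)
    peaks, genome, truth = plant_peaks(config, genome, genes)
    counts, design, expr_truth = simulate_expression(config, truth)
    coreg_counts, coreg_design, coreg_truth = simulate_coregulation(config)
    truth.expression = expr_truth
    truth.patterns = coreg_truth

    paths: "dict[str, Path]" = {}

    def _path(key: str, name: str) -> Path:
        paths[key] = outdir / name
        return paths[key]

    write_fasta(genome, _path("genome", "genome.fa"))
    write_gff3(genes, _path("genes", "genes.gff3"))
    for factor in config.factors:
        write_peaks(peaks[factor], _path(f"peaks_{factor}",
                                         f"peaks_{factor}.tsv"))
    write_table(counts, _path("counts", "counts.tsv"), index=True)
    write_table(design, _path("design", "design.tsv"))
    write_table(coreg_counts, _path("coreg_counts", "coreg_counts.tsv"),
                index=True)
    write_table(coreg_design, _path("coreg_design", "coreg_design.tsv"))
    write_table(truth.targets, _path("truth_targets", "truth/targets.tsv"))
    write_table(truth.peak_motifs,
                _path("truth_peak_motifs", "truth/peak_motifs.tsv"))
    write_table(expr_truth, _path("truth_expression", "truth/expression.tsv"))
    write_table(coreg_truth, _path("truth_patterns", "truth/patterns.tsv"))
    with open(_path("config", "config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return paths
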