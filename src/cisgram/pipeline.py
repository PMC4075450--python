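"""End-to-end orchestration: config validation, stage wiring, report tables.

Stages communicate via files under the run directory; every number in a
report table comes from exactly one module operation.  Identical config
plus seed produces byte-identical outputs.
"""
from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import (
    ConfigError,
    parse_fasta,
    parse_gff3_genes,
    parse_peaks,
    read_table,
    write_table,
)
from . import cobinding, expression, grammar, linking
from .synthetic import SyntheticConfig, write_bundle

log = logging.getLogger("cisgram")

DEFAULT_PARAMS = {
    "promoter_bp": 3000,
    "downstream_bp": 1000,
    "halfwidth": 100,
    "fc_threshold": 1.5,
    "alpha": 0.01,
    "universe": None,
    "spacing_bin": 5,
    "distance_bin": 100,
    "max_distance": 2000,
    "background_multiple": 10,
    "fdr_threshold": 0.01,
}

REPORT_TABLES = [
    "position_distribution.tsv",
    "overlap_venn.tsv",
    "motif_enrichment.tsv",
    "cooccurrence_fractions.tsv",
    "spacing_histogram.tsv",
    "activation_association.tsv",
    "score_by_class.tsv",
    "de_summary.tsv",
    "fc_correlation.tsv",
    "pattern_fractions.tsv",
    "retention.tsv",
]

_REQUIRED_KEYS = ("seed", "outdir")
_KNOWN_KEYS = {"seed", "outdir", "synthetic", "inputs", "params", "log_level"}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def validate_config(cfg: dict) -> "list[str]":
    """Diagnostics for a run config; empty list means valid."""
    diags: "list[str]" = []
    if not isinstance(cfg, dict):
        return ["config must be a mapping"]
    for key in _REQUIRED_KEYS:
        if key not in cfg:
            diags.append(f"missing required key: {key}")
    if "synthetic" not in cfg and "inputs" not in cfg:
        diags.append("one of 'synthetic' or 'inputs' is required")
    for key in cfg:
        if key not in _KNOWN_KEYS:
            diags.append(f"unused key: {key}")
    params = {**DEFAULT_PARAMS, **(cfg.get("params") or {})}
    for key in params:
        if key not in DEFAULT_PARAMS:
            diags.append(f"unused params key: {key}")
    alpha = params.get("alpha")
    if alpha is not None and not (0 < alpha < 1):
        diags.append(f"alpha out of range (0, 1): {alpha}")
    fc = params.get("fc_threshold")
    if fc is not None and fc <= 1:
        diags.append(f"fc_threshold must be > 1: {fc}")
    for key in ("promoter_bp", "downstream_bp", "halfwidth",
                "spacing_bin", "distance_bin", "background_multiple"):
        v = params.get(key)
        if v is not None and (not isinstance(v, int) or v <= 0):
            diags.append(f"{key} must be a positive integer: {v}")
    if "synthetic" in cfg:
        try:
            syn = dict(cfg["synthetic"] or {})
            syn.setdefault("seed", cfg.get("seed", 0))
            SyntheticConfig.from_dict(syn)
        except (ConfigError, TypeError) as exc:
            diags.append(f"synthetic config invalid: {exc}")
    if "inputs" in cfg:
        inputs = cfg["inputs"] or {}
        for key in ("genome", "genes", "counts", "design"):
            if key not in inputs:
                diags.append(f"inputs missing key: {key}")
            elif not Path(inputs[key]).exists():
                diags.append(f"input path does not exist: {inputs[key]}")
        for factor, path in (inputs.get("peaks") or {}).items():
            if not Path(path).exists():
                diags.append(f"peak file for {factor} does not exist: {path}")
    return diags


def _stage(name: str, outdir: Path):
    """Context manager logging stage timing and writing a FAILED marker."""

    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (outdir / "FAILED").write_text(f"stage: {name}\ncause: {exc}\n")
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def run_pipeline(cfg: dict) -> dict:
    """Execute simulate -> link -> express -> grammar -> cobind -> integrate.

    Writes one TSV per report panel plus a machine-readable manifest.
    Returns the manifest as a dict.
    """
    diags = validate_config(cfg)
    if diags:
        raise ConfigError("invalid config: " + "; ".join(diags))

    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    seed = int(cfg["seed"])
    params = {**DEFAULT_PARAMS, **(cfg.get("params") or {})}
    manifest: "dict[str, object]" = {
        "version": __version__,
        "seed": seed,
    }
    for k in sorted(params):
        manifest[f"param.{k}"] = params[k]

    # -- simulate (optional) or load inputs ---------------------------------
    with _stage("simulate" if "synthetic" in cfg else "load", outdir):
        if "synthetic" in cfg:
            syn = dict(cfg["synthetic"] or {})
            syn.setdefault("seed", seed)
            syn_cfg = SyntheticConfig.from_dict(syn)
            bundle_dir = outdir / "bundle"
            paths = write_bundle(syn_cfg, bundle_dir)
            factors = list(syn_cfg.factors)
            genome_path = paths["genome"]
            genes_path = paths["genes"]
            peaks_paths = {f: paths[f"peaks_{f}"] for f in factors}
            counts_path, design_path = paths["counts"], paths["design"]
            coreg = (paths["coreg_counts"], paths["coreg_design"])
            activated_path = None
            manifest["mode"] = "synthetic"
        else:
            inputs = cfg["inputs"]
            genome_path = Path(inputs["genome"])
            genes_path = Path(inputs["genes"])
            peaks_paths = {f: Path(p) for f, p in (inputs.get("peaks") or {}).items()}
            factors = list(peaks_paths)
            counts_path, design_path = Path(inputs["counts"]), Path(inputs["design"])
            coreg = None
            activated_path = inputs.get("activated")
            manifest["mode"] = "inputs"
        genome = parse_fasta(genome_path)
        genes = parse_gff3_genes(genes_path)
        peaks = {
            f: parse_peaks(p, factor=f, fdr_threshold=params["fdr_threshold"])
            for f, p in peaks_paths.items()
        }
        def _rel(p) -> str:
            try:
                return str(Path(p).relative_to(outdir))
            except ValueError:
                return str(p)

        manifest["input.genome"] = _rel(genome_path)
        manifest["input.genes"] = _rel(genes_path)
        manifest["n_genes"] = len(genes)
        for f in factors:
            manifest[f"n_peaks.{f}"] = len(peaks[f])

    # -- link ---------------------------------------------------------------
    with _stage("link", outdir):
        all_peaks = [p for f in factors for p in peaks[f]]
        links = linking.assign_peaks_to_genes(
            all_peaks, genes,
            promoter_bp=params["promoter_bp"],
            downstream_bp=params["downstream_bp"],
        )
        write_table(linking.links_to_frame(links), outdir / "links.tsv")
        posdist = linking.peak_position_distribution(
            peaks[factors[0]], genes, upstream_bp=5000,
            downstream_bp=params["downstream_bp"],
        )
        write_table(posdist.to_frame(), outdir / "position_distribution.tsv")
        targets = linking.target_genes(links)
        manifest["n_links"] = len(links)
        for f in factors:
            manifest[f"n_targets.{f}"] = len(targets.get(f, set()))

    # -- express ------------------------------------------------------------
    with _stage("express", outdir):
        counts = read_table(counts_path).set_index("gene_id")
        design = read_table(design_path)
        de_wt = expression.call_differential(
            counts, design, "WT_BL:WT_mock",
            fc_threshold=params["fc_threshold"], alpha=params["alpha"],
        )
        de_mut = expression.call_differential(
            counts, design, "mut_BL:mut_mock",
            fc_threshold=params["fc_threshold"], alpha=params["alpha"],
        )
        de_geno = expression.call_differential(
            counts, design, "mut_BL:WT_BL",
            fc_threshold=params["fc_threshold"], alpha=params["alpha"],
        )
        for name, table in (("de_wt", de_wt), ("de_mut", de_mut),
                            ("de_geno", de_geno)):
            out = table.reset_index().rename(columns={"index": "gene_id"})
            out.columns = ["gene_id"] + list(table.columns)
            write_table(out, outdir / f"{name}.tsv")
        summary_rows = []
        for name, table in (("WT_BL:WT_mock", de_wt),
                            ("mut_BL:mut_mock", de_mut),
                            ("mut_BL:WT_BL", de_geno)):
            vc = table["de_flag"].value_counts()
            summary_rows.append(
                {
                    "contrast": name,
                    "n_up": int(vc.get("up", 0)),
                    "n_down": int(vc.get("down", 0)),
                    "n_ns": int(vc.get("ns", 0)),
                }
            )
        write_table(pd.DataFrame(summary_rows), outdir / "de_summary.tsv")
        manifest["n_expressed_genes"] = len(de_wt)

    # -- grammar ------------------------------------------------------------
    with _stage("grammar", outdir):
        focus = peaks[factors[0]]
        halfw = params["halfwidth"]
        profiles = grammar.build_profiles(genome, focus, halfwidth=halfw)
        classes, fractions = grammar.classify_cooccurrence(profiles)
        write_table(
            pd.DataFrame(
                [{"class": c, "fraction": fractions[c]} for c in grammar.CLASSES]
            ),
            outdir / "cooccurrence_fractions.tsv",
        )
        profile_rows = [
            {
                "peak_id": p.peak_id,
                "cooccurrence_class": p.cooccurrence_class,
                "min_gap": p.min_gap if p.min_gap is not None else np.nan,
                "n_hits": len(p.hits),
            }
            for p in profiles
        ]
        write_table(pd.DataFrame(profile_rows), outdir / "peak_profiles.tsv")

        rng = np.random.default_rng(seed)
        exclude = [(p.contig, p.summit - halfw, p.summit + halfw + 1)
                   for p in focus]
        background = grammar.sample_background_windows(
            genome, params["background_multiple"] * len(focus), halfw,
            exclude, rng,
        )
        peak_windows = [
            grammar.extract_window(genome, p.contig, p.summit, halfw)[1]
            for p in focus
        ]
        enrich = grammar.motif_enrichment(peak_windows, background)
        write_table(enrich, outdir / "motif_enrichment.tsv")

        spacing = grammar.spacing_distribution(
            profiles, background, bin_width=params["spacing_bin"]
        )
        write_table(spacing.histogram, outdir / "spacing_histogram.tsv")

        if activated_path is not None:
            activated_genes = set(
                Path(activated_path).read_text().split()
            )
        else:
            activated_genes = set(de_wt.index[de_wt["de_flag"] == "up"])
        focus_links = [l for l in links if l.factor == factors[0]]
        activated_peaks: "dict[str, bool]" = {p.peak_id: False for p in focus}
        for l in focus_links:
            if l.gene_id in activated_genes:
                activated_peaks[l.peak_id] = True
        assoc = grammar.activation_association(classes, activated_peaks)
        write_table(
            pd.DataFrame(
                [
                    {"class": "both", "n": assoc.n_both,
                     "n_activated": assoc.n_both_activated,
                     "pct_activated": assoc.pct_both},
                    {"class": "auxre_only", "n": assoc.n_auxre_only,
                     "n_activated": assoc.n_auxre_only_activated,
                     "pct_activated": assoc.pct_auxre_only},
                    {"class": "fisher_p", "n": np.nan, "n_activated": np.nan,
                     "pct_activated": assoc.p},
                ]
            ),
            outdir / "activation_association.tsv",
        )
        sbc = grammar.score_by_class(focus, profiles)
        sbc_table = sbc.summary.copy()
        sbc_table["mannwhitney_p"] = sbc.p if sbc.p is not None else np.nan
        write_table(sbc_table, outdir / "score_by_class.tsv")
        manifest["n_profiles"] = len(profiles)
        manifest["n_background_windows"] = len(background)

    # -- cobind -------------------------------------------------------------
    with _stage("cobind", outdir):
        universe = params["universe"] or len(genes)
        sets = [targets.get(f, set()) for f in factors[:3]]
        overlap = cobinding.target_overlap(
            sets[0], sets[1], sets[2] if len(sets) > 2 else None,
            universe_size=universe, labels=tuple(factors[:3]),
        )
        write_table(overlap.to_frame(), outdir / "overlap_venn.tsv")
        if len(factors) >= 3:
            common = sorted(sets[0] & sets[1] & sets[2])
            dist_frames = []
            for other in (factors[1], factors[2]):
                dist = cobinding.peak_distance_distribution(
                    peaks[factors[0]], peaks[other], links, common,
                    bin_width=params["distance_bin"],
                    max_distance=params["max_distance"],
                )
                frame = dist.histogram.copy()
                frame.insert(0, "pair", f"{factors[0]}-{other}")
                dist_frames.append(frame)
            write_table(pd.concat(dist_frames, ignore_index=True),
                        outdir / "distance_histogram.tsv")
        manifest["universe"] = universe

    # -- integrate ----------------------------------------------------------
    with _stage("integrate", outdir):
        corr_rows = []
        try:
            r_de, n_de = expression.fc_correlation(de_wt, de_geno)
            corr_rows.append({"subset": "de_in_both", "r": r_de, "n": n_de})
        except ValueError as exc:
            log.warning("fc_correlation (de_in_both) undefined: %s", exc)
        shared = list(de_wt.index.intersection(de_geno.index))
        r_all, n_all = expression.fc_correlation(de_wt, de_geno,
                                                 gene_subset=shared)
        corr_rows.append({"subset": "all_shared", "r": r_all, "n": n_all})
        write_table(pd.DataFrame(corr_rows), outdir / "fc_correlation.tsv")

        retention_rows = []
        for direction in ("up", "down"):
            ret = expression.response_retention(de_wt, de_mut, direction)
            retention_rows.append(
                {
                    "direction": direction,
                    "n_wt": ret.n_wt,
                    "n_retained": ret.n_retained,
                    "percent": ret.percent if ret.percent is not None else np.nan,
                }
            )
        write_table(pd.DataFrame(retention_rows), outdir / "retention.tsv")

        if coreg is not None:
            coreg_counts = read_table(coreg[0]).set_index("gene_id")
            coreg_design = read_table(coreg[1])
            tables = [
                expression.call_differential(
                    coreg_counts, coreg_design, f"{c}:ref",
                    fc_threshold=params["fc_threshold"], alpha=params["alpha"],
                )
                for c in ("c1", "c2", "c3")
            ]
            de_all = tables[0].index
            for t in tables[1:]:
                de_all = de_all.intersection(t.index)
            mask = np.ones(len(de_all), dtype=bool)
            for t in tables:
                mask &= (t.loc[de_all, "de_flag"] != "ns").to_numpy()
            gene_set = list(de_all[mask])
            summary = expression.coregulation_pattern(tables, gene_set)
            frame = summary.to_frame()
            frame.loc[len(frame)] = {
                "pattern": "concordant_opposing_total",
                "count": round(summary.concordant_opposing_fraction * summary.n),
                "fraction": summary.concordant_opposing_fraction,
            }
            write_table(frame, outdir / "pattern_fractions.tsv")
            manifest["n_coregulated_set"] = summary.n
        else:
            write_table(
                pd.DataFrame(columns=["pattern", "count", "fraction"]),
                outdir / "pattern_fractions.tsv",
            )

    # -- manifest -----------------------------------------------------------
    for table in REPORT_TABLES:
        path = outdir / table
        with open(path) as fh:
            manifest[f"rows.{table}"] = sum(1 for _ in fh) - 1
    manifest_df = pd.DataFrame(
        [{"key": k, "value": manifest[k]} for k in manifest]
    )
    write_table(manifest_df, outdir / "manifest.tsv")
    return manifest
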