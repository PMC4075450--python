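import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from cisgram.core_io import DEFAULT_MOTIFS, Genome, Motif, Peak, reverse_complement
from cisgram import grammar
from cisgram.grammar import (
    activation_association,
    build_profiles,
    classify_cooccurrence,
    find_matches,
    footprint_gap,
    motif_enrichment,
    profile_sequence,
    sample_background_windows,
    scan_window,
    score_by_class,
    spacing_distribution,
)

GBOX = Motif("G-box", "CACGTG")
HUD = Motif("HUD", "CACATG")
CORE = Motif("AuxRE-core", "TGTC")
AUXRE = Motif("AuxRE", "TGTCTC")


# ---------------------------------------------------------------------------
# Scanning

def test_palindrome_counted_once():
    hits = find_matches("AAACACGTGAAA", GBOX)
    assert len(hits) == 1
    assert (hits[0].offset, hits[0].strand) == (3, "+")


def test_reverse_complement_hit():
    # CATGTG is the reverse complement of CACATG
    hits = find_matches("CATGTG", HUD)
    assert len(hits) == 1
    assert (hits[0].offset, hits[0].strand) == (0, "-")


def test_substring_containment_both_hit():
    seq = "TGTCTC"
    assert len(find_matches(seq, CORE)) == 1
    assert len(find_matches(seq, AUXRE)) == 1
    assert find_matches(seq, CORE)[0].offset == 0
    assert find_matches(seq, AUXRE)[0].offset == 0


def test_n_bases_never_match():
    assert find_matches("TGNC", CORE) == []
    assert find_matches("NNNNNN", GBOX) == []


def test_overlapping_matches_reported():
    assert [h.offset for h in find_matches("TGTCTGTC", CORE)
            if h.strand == "+"] == [0, 4]


def test_scan_window_clipping_and_center_bounds():
    genome = Genome({"chr1": "TGTC" + "A" * 500})
    hits = scan_window(genome, "chr1", 2, halfwidth=100)
    assert any(h.motif == "AuxRE-core" and h.offset == 0 for h in hits)
    with pytest.raises(ValueError):
        scan_window(genome, "chr1", 504)
    with pytest.raises(ValueError):
        scan_window(genome, "chr1", -1)


@given(st.text(alphabet="ACGT", min_size=10, max_size=80))
@settings(max_examples=60, deadline=None)
def test_scan_strand_symmetry(seq):
    # scanning the reverse complement yields the mirrored hit set
    fwd = grammar.scan_sequence(seq, DEFAULT_MOTIFS)
    rev = grammar.scan_sequence(reverse_complement(seq), DEFAULT_MOTIFS)
    mirrored = {
        (h.motif, len(seq) - h.offset - h.length) for h in rev
    }
    assert {(h.motif, h.offset) for h in fwd} == mirrored


# ---------------------------------------------------------------------------
# Co-occurrence classification

def test_classify_both_and_neither():
    cls, gap, _ = profile_sequence("CACGTGAAAAATGTCAAA")
    assert cls == "both"
    cls2, _, _ = profile_sequence("A" * 40)
    assert cls2 == "neither"


def test_classify_single_classes():
    assert profile_sequence("AATGTCAAAAAAAAA")[0] == "auxre_only"
    assert profile_sequence("AACACGTGAAAAAAA")[0] == "ebox_only"


def test_class_fractions_sum_to_one(default_bundle):
    cfg, genome, genes, peaks, truth = default_bundle
    profiles = build_profiles(genome, peaks[cfg.factors[0]])
    _, fractions = classify_cooccurrence(profiles)
    assert abs(sum(fractions.values()) - 1.0) < 1e-12


def test_cooccurrence_recovery_on_planted_truth(default_bundle):
    cfg, genome, genes, peaks, truth = default_bundle
    profiles = build_profiles(genome, peaks[cfg.factors[0]])
    planted = truth.peak_motifs.set_index("peak_id")
    for prof in profiles:
        assert prof.cooccurrence_class == planted.loc[prof.peak_id, "motif_class"]
        if prof.cooccurrence_class == "both":
            assert prof.min_gap == planted.loc[prof.peak_id, "planted_gap"]


def test_cooccurrence_fraction_within_3se(default_bundle):
    cfg, genome, genes, peaks, truth = default_bundle
    profiles = build_profiles(genome, peaks[cfg.factors[0]])
    _, fractions = classify_cooccurrence(profiles)
    n = len(profiles)
    for cls, p in cfg.motif_class_probs.items():
        se = np.sqrt(p * (1 - p) / n)
        assert abs(fractions[cls] - p) <= 3 * se + 1e-12


# ---------------------------------------------------------------------------
# Enrichment

def test_enrichment_fold_arithmetic():
    with_motif = "AACACGTGAA"
    without = "A" * 10
    peak_windows = [with_motif] * 30 + [without] * 70
    bg_windows = [with_motif] * 10 + [without] * 90
    df = motif_enrichment(peak_windows, bg_windows, motifs=[GBOX])
    row = df.iloc[0]
    assert row.n_peak_with == 30 and row.n_background_with == 10
    assert row.fold == pytest.approx(3.0, abs=0.2)


def test_enrichment_null_case():
    with_motif = "AACACGTGAA"
    without = "A" * 10
    windows = [with_motif] * 10 + [without] * 90
    df = motif_enrichment(windows, list(windows), motifs=[GBOX])
    assert df.iloc[0].fold == pytest.approx(1.0, abs=1e-9)
    assert df.iloc[0].p == pytest.approx(1.0)


def test_enrichment_p_matches_enumeration():
    with_motif = "AACACGTGAA"
    without = "A" * 10
    peak_windows = [with_motif] * 8 + [without] * 2
    bg_windows = [with_motif] * 2 + [without] * 8
    df = motif_enrichment(peak_windows, bg_windows, motifs=[GBOX])
    expected = oracles.fisher_exact_two_sided(8, 2, 2, 8)
    assert df.iloc[0].p == pytest.approx(expected, rel=1e-9)


def test_enrichment_empty_background_errors():
    with pytest.raises(ValueError):
        motif_enrichment(["ACGTACGT"], [], motifs=[GBOX])


def test_control_motif_not_enriched(default_bundle):
    cfg, genome, genes, peaks, truth = default_bundle
    focus = peaks[cfg.factors[0]]
    rng = np.random.default_rng(0)
    exclude = [(p.contig, p.summit - 100, p.summit + 101) for p in focus]
    bg = sample_background_windows(genome, 10 * len(focus), 100, exclude, rng)
    windows = [
        grammar.extract_window(genome, p.contig, p.summit, 100)[1] for p in focus
    ]
    df = motif_enrichment(windows, bg).set_index("motif")
    row = df.loc["control"]
    p_hat = row.background_fraction
    se = np.sqrt(p_hat * (1 - p_hat) * (1 / row.n_peak + 1 / row.n_background))
    assert abs(row.peak_fraction - row.background_fraction) <= 3 * se + 1e-12


# ---------------------------------------------------------------------------
# Spacing

def test_footprint_gap_definition():
    assert footprint_gap((0, 4), (6, 12)) == 2
    assert footprint_gap((6, 12), (0, 4)) == 2
    assert footprint_gap((0, 6), (5, 9)) == 0  # overlap -> 0
    assert footprint_gap((0, 4), (4, 10)) == 0  # adjacent -> 0


def test_gap_from_sequence():
    # TGTC at [0,4), CACGTG at [6,12): two bases strictly between
    cls, gap, _ = profile_sequence("TGTCAACACGTGAAA")
    assert cls == "both"
    assert gap == 2


def test_spacing_uniform_law_recovery(default_bundle):
    cfg, genome, genes, peaks, truth = default_bundle
    profiles = build_profiles(genome, peaks[cfg.factors[0]])
    result = spacing_distribution(profiles, [], bin_width=5)
    gaps = result.observed_gaps
    assert result.observed_frac_within_20 == 1.0
    lo, hi = cfg.spacing_law[1], cfg.spacing_law[2]
    assert gaps.min() >= lo and gaps.max() <= hi
    # chi-square GOF against the planted uniform law
    from scipy import stats

    observed = np.bincount(gaps, minlength=hi + 1)
    stat, p = stats.chisquare(observed)
    assert p > 0.01


def test_spacing_background_measured_same_way():
    windows = ["TGTCAACACGTGAAA"] * 5  # gap 2 windows
    result = spacing_distribution([], windows)
    assert list(result.background_gaps) == [2] * 5


# ---------------------------------------------------------------------------
# Activation association

def test_association_percentages():
    classes = {}
    activated = {}
    for i in range(100):
        classes[f"b{i}"] = "both"
        activated[f"b{i}"] = i < 60
        classes[f"a{i}"] = "auxre_only"
        activated[f"a{i}"] = i < 30
    res = activation_association(classes, activated)
    assert res.pct_both == 60.0
    assert res.pct_auxre_only == 30.0
    assert not res.warning
    assert res.p < 0.01 and res.stars == "**"


def test_association_null():
    classes = {f"b{i}": "both" for i in range(10)}
    classes.update({f"a{i}": "auxre_only" for i in range(10)})
    activated = {k: k.endswith(("1", "2", "3")) for k in classes}
    res = activation_association(classes, activated)
    assert res.p == pytest.approx(1.0)


def test_association_small_table_matches_enumeration():
    classes = {}
    activated = {}
    for i in range(8):
        classes[f"b{i}"] = "both"
        activated[f"b{i}"] = i < 6
        classes[f"a{i}"] = "auxre_only"
        activated[f"a{i}"] = i < 2
    res = activation_association(classes, activated)
    assert res.p == pytest.approx(
        oracles.fisher_exact_two_sided(6, 2, 2, 6), rel=1e-9
    )


def test_association_empty_class_warns():
    classes = {"a1": "auxre_only", "a2": "auxre_only"}
    res = activation_association(classes, {"a1": True, "a2": False})
    assert res.warning and res.p == 1.0


# ---------------------------------------------------------------------------
# Score by class

def _mk_peaks(scores_by_class):
    peaks, profiles = [], []
    i = 0
    for cls, scores in scores_by_class.items():
        for s in scores:
            pid = f"p{i}"
            peaks.append(Peak(pid, "TF", "chr1", 0, 100, 50, float(s)))
            profiles.append(
                grammar.PeakMotifProfile(pid, (), cls, 0 if cls == "both" else None)
            )
            i += 1
    return peaks, profiles


def test_score_identical_distributions():
    peaks, profiles = _mk_peaks({"both": [1, 2, 3], "auxre_only": [1, 2, 3]})
    res = score_by_class(peaks, profiles)
    s = res.summary.set_index("class")
    assert s.loc["both", "median"] == s.loc["auxre_only", "median"]


def test_score_u_statistic_matches_enumeration():
    peaks, profiles = _mk_peaks({"both": [1, 2, 3], "auxre_only": [4, 5, 6]})
    res = score_by_class(peaks, profiles)
    u_oracle = oracles.mannwhitney_u([1, 2, 3], [4, 5, 6])
    assert u_oracle == 0.0
    assert res.u_statistic == u_oracle
    assert res.p == pytest.approx(
        oracles.mannwhitney_two_sided([1, 2, 3], [4, 5, 6]), rel=1e-9
    )


def test_score_shift_detected():
    rng = np.random.default_rng(8)
    base = rng.normal(10, 1, size=50)
    shifted = rng.normal(12, 1, size=50)
    peaks, profiles = _mk_peaks({"both": shifted, "auxre_only": base})
    res = score_by_class(peaks, profiles)
    assert res.p < 0.01


def test_score_small_class_no_test():
    peaks, profiles = _mk_peaks({"both": [1], "auxre_only": [1, 2, 3]})
    res = score_by_class(peaks, profiles)
    assert res.p is None
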