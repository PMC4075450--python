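import numpy as np
import pandas as pd
import pytest

from cisgram.expression import (
    call_differential,
    coregulation_pattern,
    fc_correlation,
    ratio_treated_mock,
    response_retention,
    rtqpcr_relative_expression,
)


def _design(conditions, reps=3):
    rows = []
    for cond in conditions:
        for k in range(1, reps + 1):
            rows.append({"library": f"{cond}_r{k}", "condition": cond})
    return pd.DataFrame(rows)


def _counts(gene_rows, conditions, reps=3):
    cols = {}
    for cond in conditions:
        for k in range(1, reps + 1):
            cols[f"{cond}_r{k}"] = [row[cond] for row in gene_rows]
    return pd.DataFrame(cols, index=[f"g{i}" for i in range(len(gene_rows))])


def test_twofold_up_called():
    # signal genes 800 vs 400 with equal library sizes (one ballast gene
    # balances the mass) and tiny replicate noise
    rng = np.random.default_rng(0)
    genes = [{"t": 800, "r": 400} for _ in range(10)]
    genes.append({"t": 2000, "r": 6000})  # ballast: totals 10000 vs 10000
    counts = _counts(genes, ["t", "r"])
    noise = rng.integers(-3, 4, size=counts.shape)
    counts = counts + noise
    table = call_differential(counts, _design(["t", "r"]), "t:r")
    signal = table.iloc[:10]
    assert np.allclose(signal.log2fc, 1.0, atol=0.1)
    assert (signal.de_flag == "up").all()


def test_identical_replicates_ns():
    genes = [{"t": 500, "r": 500} for _ in range(5)]
    counts = _counts(genes, ["t", "r"])
    table = call_differential(counts, _design(["t", "r"]), "t:r")
    assert (table.log2fc == 0).all()
    assert (table.de_flag == "ns").all()
    assert (table.p == 1.0).all()


def test_flag_rule_thresholds():
    # log2fc just below log2(1.5) -> ns regardless of p
    rng = np.random.default_rng(1)
    counts = _counts([{"t": 140, "r": 100} for _ in range(20)], ["t", "r"])
    counts = counts + rng.integers(-2, 3, size=counts.shape)
    table = call_differential(counts, _design(["t", "r"]), "t:r")
    assert (table.de_flag == "ns").all()  # 1.4-fold < 1.5


def test_zero_count_genes_dropped():
    counts = _counts([{"t": 100, "r": 50}, {"t": 0, "r": 0}], ["t", "r"])
    table = call_differential(counts, _design(["t", "r"]), "t:r")
    assert list(table.index) == ["g0"]


def test_too_few_replicates_errors():
    counts = _counts([{"t": 10, "r": 10}], ["t", "r"], reps=1)
    with pytest.raises(ValueError, match="replicate"):
        call_differential(counts, _design(["t", "r"], reps=1), "t:r")


def test_zero_library_errors():
    counts = _counts([{"t": 10, "r": 10}], ["t", "r"])
    counts["t_r1"] = 0
    with pytest.raises(ValueError, match="zero total"):
        call_differential(counts, _design(["t", "r"]), "t:r")


def test_cpm_invariance_under_library_rescaling():
    rng = np.random.default_rng(3)
    genes = [{"t": int(m), "r": int(m * f)}
             for m, f in zip(rng.integers(50, 5000, 100),
                             rng.choice([0.3, 1.0, 3.0], 100))]
    counts = _counts(genes, ["t", "r"])
    counts = counts + rng.integers(0, 10, size=counts.shape)
    t1 = call_differential(counts, _design(["t", "r"]), "t:r")
    scaled = counts.copy()
    scaled["t_r2"] = scaled["t_r2"] * 7  # uniform rescale of one library
    t2 = call_differential(scaled, _design(["t", "r"]), "t:r")
    assert (t1.de_flag == t2.de_flag).all()


def test_type_i_error_calibration():
    from cisgram.synthetic import SyntheticConfig, simulate_expression

    cfg = SyntheticConfig(seed=101, n_genes=2000, responsive_fraction=0.0)
    counts, design, _ = simulate_expression(cfg)
    table = call_differential(counts, design, "WT_BL:WT_mock")
    frac = float((table.p < 0.01).mean())
    se = np.sqrt(0.01 * 0.99 / len(table))
    assert abs(frac - 0.01) <= 3 * se


def test_planted_effect_sensitivity(expression_bundle):
    cfg, counts, design, truth = expression_bundle
    table = call_differential(counts, design, "WT_BL:WT_mock")
    t = truth.set_index("gene_id")
    strong = t.index[(t.lfc_wt.abs() >= np.log2(1.5)) & t.responsive]
    called = (table.loc[table.index.intersection(strong), "de_flag"] != "ns")
    assert called.mean() >= 0.8


# ---------------------------------------------------------------------------
# fc_correlation

def _table(lfc, flags=None, genes=None):
    lfc = np.asarray(lfc, dtype=float)
    genes = genes or [f"g{i}" for i in range(len(lfc))]
    flags = flags or ["up" if x > 0 else "down" for x in lfc]
    return pd.DataFrame(
        {"log2fc": lfc, "p": 0.001, "de_flag": flags}, index=genes
    )


def test_fc_correlation_exact_anticorrelation():
    a = _table([1.0, 2.0, -1.5, 0.5])
    b = _table(-a.log2fc.to_numpy())
    r, n = fc_correlation(a, b)
    assert r == pytest.approx(-1.0)
    assert n == 4


def test_fc_correlation_identity():
    a = _table([1.0, 2.0, -1.5, 0.5])
    r, _ = fc_correlation(a, a)
    assert r == pytest.approx(1.0)


def test_fc_correlation_zero_variance_errors():
    a = _table([1.0, 1.0, 1.0])
    b = _table([1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="variance"):
        fc_correlation(a, b)


def test_fc_correlation_too_few_genes_errors():
    a = _table([1.0, 2.0])
    with pytest.raises(ValueError, match=">= 3"):
        fc_correlation(a, a)


def test_fc_correlation_recovers_target(expression_bundle):
    cfg, counts, design, truth = expression_bundle
    a = _table(truth.lfc_wt.to_numpy(), genes=list(truth.gene_id),
               flags=["ns"] * len(truth))
    b = _table(truth.lfc_geno.to_numpy(), genes=list(truth.gene_id),
               flags=["ns"] * len(truth))
    r, n = fc_correlation(a, b, gene_subset=list(truth.gene_id))
    assert n == len(truth)
    assert r == pytest.approx(cfg.target_corr, abs=0.05)


# ---------------------------------------------------------------------------
# coregulation_pattern

def test_pattern_degenerate_all_concordant_opposing():
    a = _table([1.0] * 10)
    b = _table([1.0] * 10)
    c = _table([-1.0] * 10)
    summary = coregulation_pattern([a, b, c], list(a.index))
    assert summary.concordant_opposing_fraction == 1.0
    assert summary.fractions["up,up,down"] == 1.0


def test_pattern_fractions_sum_to_one():
    rng = np.random.default_rng(4)
    tables = [
        _table(rng.normal(size=50),
               flags=list(rng.choice(["up", "down", "ns"], 50)))
        for _ in range(3)
    ]
    summary = coregulation_pattern(tables, list(tables[0].index))
    assert abs(sum(summary.fractions.values()) - 1.0) < 1e-12


def test_pattern_ns_class():
    a = _table([1.0, 1.0], flags=["up", "ns"])
    b = _table([1.0, 1.0], flags=["up", "up"])
    c = _table([-1.0, -1.0], flags=["down", "down"])
    summary = coregulation_pattern([a, b, c], list(a.index))
    assert summary.counts["ns_any"] == 1
    assert summary.counts["up,up,down"] == 1
    assert summary.concordant_opposing_fraction == 0.5


def test_pattern_recovery_from_counts():
    from cisgram.synthetic import SyntheticConfig, simulate_coregulation

    cfg = SyntheticConfig(seed=42)
    counts, design, truth = simulate_coregulation(cfg, n_genes=1500)
    tables = [
        call_differential(counts, design, f"{c}:ref") for c in ("c1", "c2", "c3")
    ]
    idx = tables[0].index
    mask = np.ones(len(idx), dtype=bool)
    for t in tables:
        mask &= (t.loc[idx, "de_flag"] != "ns").to_numpy()
    gene_set = list(idx[mask])
    summary = coregulation_pattern(tables, gene_set)
    se = np.sqrt(cfg.pattern_fraction * (1 - cfg.pattern_fraction) / summary.n)
    assert abs(
        summary.concordant_opposing_fraction - cfg.pattern_fraction
    ) <= 3 * se


# ---------------------------------------------------------------------------
# response_retention

def test_retention_worked_example():
    # 276 retained of 1616 -> 17.1%
    wt = _table([1.0] * 1616 + [0.0] * 100,
                flags=["up"] * 1616 + ["ns"] * 100)
    mut_flags = ["up"] * 276 + ["ns"] * (1616 - 276) + ["ns"] * 100
    mut = _table([1.0] * 1716, flags=mut_flags)
    res = response_retention(wt, mut, "up")
    assert (res.n_wt, res.n_retained) == (1616, 276)
    assert res.percent == 17.1


def test_retention_identity_and_degenerate():
    wt = _table([1.0] * 10)
    assert response_retention(wt, wt, "up").percent == 100.0
    mut = _table([0.0] * 10, flags=["ns"] * 10)
    assert response_retention(wt, mut, "up").percent == 0.0


def test_retention_zero_wt_is_defined():
    wt = _table([0.0] * 5, flags=["ns"] * 5)
    res = response_retention(wt, wt, "up")
    assert res.n_wt == 0
    assert res.percent is None
    assert res.undefined


def test_retention_recovery(expression_bundle):
    cfg, counts, design, truth = expression_bundle
    de_wt = call_differential(counts, design, "WT_BL:WT_mock")
    de_mut = call_differential(counts, design, "mut_BL:mut_mock")
    for direction in ("up", "down"):
        res = response_retention(de_wt, de_mut, direction)
        p = cfg.retention_fraction
        se = np.sqrt(p * (1 - p) / res.n_wt)
        assert abs(res.percent / 100.0 - p) <= 3 * se


# ---------------------------------------------------------------------------
# qRT-PCR arithmetic

def test_rtqpcr_identity():
    assert rtqpcr_relative_expression(2, 4, 2, 4) == pytest.approx(1.0)


def test_rtqpcr_ratio():
    assert ratio_treated_mock(6.0, 2.0) == pytest.approx(3.0)


def test_rtqpcr_scale_invariance():
    a = rtqpcr_relative_expression(3, 5, 2, 7)
    b = rtqpcr_relative_expression(30, 50, 20, 70)
    assert a == pytest.approx(b)


def test_rtqpcr_nonpositive_errors():
    with pytest.raises(ValueError):
        rtqpcr_relative_expression(0, 1, 1, 1)
    with pytest.raises(ValueError):
        ratio_treated_mock(1.0, 0.0)
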