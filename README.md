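# cisgram

Desk-scale cistrome/transcriptome integration: peak-to-gene target
calling, cis-element grammar statistics (motif enrichment, co-occurrence
classes, spacing, activation association, score-by-class), multi-factor
target-set overlap, differential-expression calling with cross-pathway
dependence statistics, and a fully deterministic synthetic-data
generator that plants every parameter the analysis modules recover.

## Layout

| module                  | role |
|-------------------------|------|
| `cisgram.core_io`       | domain types (Genome, GeneModel, Peak, Motif) and FASTA/GFF3/peak-TSV readers and writers; 0-based half-open coordinates internally |
| `cisgram.synthetic`     | toy genomes, Venn-structured 3-factor peak sets with planted motifs at configurable spacing, negative-binomial expression counts with configurable retention/correlation/pattern structure, ground-truth tables |
| `cisgram.linking`       | summit-based peak→gene assignment (promoter −3 kb / gene body / +1 kb downstream), target-gene sets, peak position distribution |
| `cisgram.grammar`       | exact IUPAC motif scanning (both strands, ±100 bp of summit), enrichment vs genomic background (Fisher), co-occurrence classes, footprint-gap spacing, activation association, Mann–Whitney score comparison |
| `cisgram.cobinding`     | 2/3-set target overlap with hypergeometric expectation and p-value, peak-to-peak distance histograms, ChIP-qPCR enrichment arithmetic |
| `cisgram.expression`    | CPM + Welch-t differential calling (1.5-fold, p<0.01 rule), fold-change correlation, sign-pattern co-regulation, response retention, qRT-PCR relative quantification |
| `cisgram.pipeline`/`cli`| config validation, end-to-end orchestration, report tables, manifest |

## CLI

Full run from a YAML config (synthetic mode shown):

```sh
cat > run.yaml <<EOF
seed: 1
outdir: out/
synthetic:
  n_genes: 200
params:
  promoter_bp: 3000
  alpha: 0.01
EOF
cisgram validate --config run.yaml
cisgram run --config run.yaml
```

`out/` then contains one TSV per report panel (position distribution,
overlap Venn, motif enrichment, co-occurrence fractions, spacing
histogram, activation association, score-by-class, DE summary,
correlation, pattern fractions, retention) plus `manifest.tsv`.
Identical config + seed ⇒ byte-identical outputs.

Per-stage subcommands: `simulate`, `link`, `grammar`, `cobind`,
`express`, `express-integrate`, `report` — see `cisgram <cmd> --help`.
Real data goes in through an `inputs:` section (genome FASTA, gene GFF3,
per-factor peak TSVs, counts + design TSVs) instead of `synthetic:`.

## Notes

- Peak files are 6–7 column TSVs with header
  `contig start end peak_id score summit_offset [fdr]`; peaks with
  fdr ≥ 0.01 are dropped by default.
- The DE rule is deliberately simple (CPM, log2 mean fold change with
  +1 pseudocount, Welch t, raw p) and configurable via
  `fc_threshold`/`alpha`.
- Test oracles (exhaustive Fisher/Mann–Whitney enumeration, all-pairs
  interval membership, Monte-Carlo overlap) live in `tests/oracles.py`,
  independent of the package code paths they check.
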