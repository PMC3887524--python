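# poiarray

Parent-of-origin differential expression analysis for two-color spotted
microarrays.

When two genotypes carry identical nuclear genomes but inherited their sex
chromosomes from different parents, any expression difference between them
is an imprinting (parent-of-origin) effect.  `poiarray` implements the
complete analysis for direct dye-swap comparisons of such genotypes on
spotted arrays, plus a synthetic-data generator with planted ground truth
so the whole pipeline is testable without any external data:

- **spot QC** — the three pixel-summary criteria (≥70% of foreground
  pixels above background + 2 SD in some channel; foreground ≥ 3×
  background in some channel; > 30 foreground pixels);
- **normalization** — per-array M = log2(ch1/ch2) ratios detrended by a
  loess fit of M on A (span 0.3) and then by a local-regression surface
  over the slide coordinates (span 0.002 of the spots);
- **differential expression** — per-gene orientation-corrected mean
  log2 fold-change, empirical-Bayes moderated t-statistics
  (s̃²_g = (d0·s0² + d_g·s²_g)/(d0 + d_g) with (d0, s0²) estimated by
  moment-matching log s² against a scaled-F model), Benjamini–Hochberg
  q-values, and an empirical FDR from a dye-orientation sign-flip
  permutation null; a median-based fold-change estimator is always
  computed alongside as a cross-check;
- **tissue specificity** — τ = Σ(1 − x̂ᵢ)/(N − 1) over a 20-tissue
  atlas (absent calls floored at 1, strongest probe set per gene),
  specific iff τ > 0.9, plus a quantitative per-tissue enrichment score;
- **statistics** — chromosomal distribution χ² tests with mapped-only
  denominators, odds-ratio/Fisher direction tables, Mann–Whitney group
  shifts, Spearman concordance, standard major axis regression, and
  exact binomial direction-bias tests.

See `docs/methods.md` for the model details and design choices.

## Worked example

Run the default synthetic contrast (8 dye-swapped arrays, 21,487 genes,
12% testis-specific genes planted at a median log2 shift of +0.24, 0.8%
midgut-specific at −0.23, background at −0.03) end to end:

```sh
poiarray run-all --seed 1 --outdir run1
```

which prints

```
21487 genes tested, 15016 significant; outputs in run1
```

and writes `genes.tsv` (per-gene log2FC, moderated t, p, q, permutation
FDR), `qc_report.tsv`, per-array normalized MA tables, `specificity.tsv`
and `stats_report.tsv`.  The statistics report contains, among others:

```
testis_direction_bias   frac_down=0.9877  odds_ratio=140.0
midgut_median_shift     median_difference=-0.2136  p=8.6e-64
estimator_concordance   rho=0.9931
```

i.e. virtually all significant testis-specific genes are downregulated in
the genotype with reversed sex-chromosome inheritance, midgut-specific
genes shift the opposite way, and the two fold-change estimators agree to
rank correlation 0.993.  The same stages are available individually
(`poiarray simulate / qc / normalize / de / specificity / stats`), each
reading and writing plain tab-delimited tables, so real spot tables — for
example GenePix-style exports, via the column-mapping hook in
`poiarray.array_io.read_spot_table` — can be substituted at any stage.

From Python:

```python
import poiarray as pa

cfg = pa.SimulationConfig(seed=1)
catalog, truth, atlas, hybs = pa.simulate_experiment(cfg)
kept = [pa.filter_hybridization(h)[0] for h in hybs]
mas = [pa.normalize_hybridization(h) for h in kept]
matrix = pa.assemble_matrix(mas, kept)
result = pa.contrast_result(matrix, n_perm=200, seed=1)
cls = truth.tissue_class.reindex(result.index)
print(result.loc[cls == "testis", "log2fc"].median())   # 0.2387
print(result.loc[cls == "midgut", "log2fc"].median())   # -0.2233
```

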