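# swathcomp

Cross-species comparison of proteomes from SWATH/DIA (data-independent
acquisition) mass spectrometry: conserved-peptide quantification,
empirical-Bayes differential abundance, gene-set enrichment, co-expression
and quality control — with a synthetic-data generator that provides ground
truth for every stage.

## The problem

Label-free intensities of *different* peptide sequences are not comparable:
ionization efficiency varies across sequences by orders of magnitude. When
comparing synaptic (or any) proteomes **across species**, the only safely
comparable signals come from tryptic peptides whose amino-acid sequence is
identical in every species compared. `swathcomp` implements that comparison
end to end, starting from a peptide-level targeted-extraction report (one
row per sample × precursor, where a precursor is a (sequence, modifications,
charge) triple with a normalized peak area and a Q-value):

1. **Conserved-peptide selection** — in-silico tryptic digestion (cleave
   after K/R unless followed by P; length ≥ 6; ≤ 2 missed cleavages) of each
   species' protein database, and an index of which peptide occurs in which
   species. Only peptides present in *all* compared species survive.
2. **Confidence filtering** — a precursor is kept when its Q-value is
   ≤ 10⁻⁴ over all samples of either contrast group, allowing one outlier
   sample per species (technical-replicate QC uses the stricter any-sample
   rule at 10⁻³). Precursors mapping to more than one gene are discarded.
3. **Rollup and normalization** — protein abundance = sum of its peptides'
   peak areas, after per-run total-area rescaling; the protein matrix is
   then normalized by 10 iterations of *fast cyclic loess* (each sample's
   log-ratio M against the mean log profile A is loess-smoothed and
   subtracted; span 0.7).
4. **Differential abundance** — per gene, a two-group linear model with
   empirical-Bayes variance shrinkage. With per-gene residual variance s²
   on d degrees of freedom and a prior (d₀, s₀²) estimated from all genes
   by method of moments on log s² (digamma/trigamma identities, Newton
   inversion of the trigamma function), the posterior variance is
   s̃² = (d₀s₀² + d·s²)/(d₀ + d) and the moderated statistic
   t = log₂FC / (s̃·√(1/n_A + 1/n_B)) is referred to a t distribution with
   d + d₀ df. P-values are Benjamini–Hochberg adjusted and called at
   FDR ≤ 0.005.
5. **Enrichment, co-expression, QC** — 2×2 Pearson chi-square (df = 1,
   optional continuity correction) of gene-set membership against DE
   status; gene–gene Pearson correlation of log₂ abundances; per-species
   coefficients of variation, pairwise R², and average-linkage sample
   clustering on correlation distance. iBAQ (intensity / number of
   theoretically observable tryptic peptides, default 7–30 residues) is
   provided for absolute-abundance estimates from discovery data.

The moderated-t fit and the fast cyclic loess are verified in the test
suite against the reference R implementations (limma's `eBayes` and
`normalizeCyclicLoess`) to ~10⁻⁶ or better, and the digestion against
brute-force enumeration and pyteomics.

## Worked example

Every capability has a narrative script under `examples/`. Differential
abundance on a synthetic 1000-gene dataset
(`python examples/04_differential_abundance.py`) prints:

```
prior df d0 = 15.49, prior variance s0^2 = 0.0106
calls at FDR 0.005: {'unchanged': 901, 'higher_in_primate': 50, 'higher_in_rodent': 49}
log2FC recovery among 100 true-DE genes: Pearson r = 0.999
smallest detected fold change: 1.129 (high replicate precision resolves sub-1.3-fold differences)
```

The generator planted 100 differentially abundant genes of 1000; the
pipeline makes 99 calls (98 true positives, 1 false positive — consistent
with the 0.005 false-discovery target), the estimated log₂ fold
changes track the true ones at r = 0.999, and the smallest detected change
is ~1.13-fold — the precision regime in which targeted-extraction
proteomics resolves sub-1.3-fold species differences. The enrichment script
(`examples/05_enrichment_and_techrep_qc.py`) reproduces the worked
chi-square example: a 340-protein synaptic-plasticity set with 188 DE
members inside a 1642-protein universe with 779 DE gives χ² = 10.60,
p = 1.13 × 10⁻³ (1.40 × 10⁻³ with continuity correction), odds ratio 1.49.

A thin CLI mirrors the library (`swathcomp simulate|digest|filter|quantify|
diffexp|enrich|qc|run`); `swathcomp run --config config.yaml` executes the
whole workflow and writes result tables plus a manifest with parameters,
input checksums and per-filter survival counts.

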