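# Methods

This note documents the statistical model behind `swathcomp`, the choices
made where the design was genuinely open, what the synthetic data emulate
(and what they do not), and the numerical details a maintainer needs.

## Comparison model

The pipeline compares protein abundance between two groups of species
(e.g. rodent = {mouse, rat} vs primate = {marmoset, human}) from a
peptide-level targeted-extraction report. Its central assumption is that
only sequence-identical peptides are quantitatively comparable across
samples from different species: ionization efficiency is a property of the
sequence, so identical sequences cancel it, while species-specific
sequences confound abundance with response. Conservation is therefore
decided by *exact string equality* of the bare peptide sequence (I and L
distinct; modifications ignored for this test only) against the in-silico
digest of every species' database. Precursor identity everywhere else is
the full (sequence, modifications, charge) triple: the same sequence with a
different charge or modification is a distinct measurement unit.

### Digestion

Trypsin cleaves after K or R; the default rule suppresses cleavage before
proline (`trypsin_blocked_by_proline`), with `trypsin_p` selectable. The
identification/conservation digest uses minimum length 6 and up to two
missed cleavages — the same limits a typical database search applies, so
any reported peptide can be tested for membership in every species'
digest. The iBAQ denominator counts distinct fully-tryptic peptides of
7–30 residues at 0 missed cleavages; the length window is configurable
since the canonical method fixes no bounds. A protein with no observable
peptide yields an explicit "undefined" iBAQ, never a division by zero.

### Confidence rules

Two Q-value rules serve two workflows:

* technical replicates: drop a precursor if Q > 10⁻³ in *any* sample;
* group comparisons: keep a precursor if, in either contrast group, every
  species has at most one sample with Q > 10⁻⁴.

The outlier allowance is evaluated per species, per precursor; group
qualification is OR-combined across the two groups (`either`), with `both`
available. All samples of a kept precursor enter quantification, including
the outlier sample — the allowance concerns identification confidence, not
the measured area. Because targeted extraction yields complete matrices, a
precursor observed in only some samples is treated as corrupt input and
raises, rather than being silently dropped (silent drops would bias the
summed rollup).

### Normalization

Per-run total-area rescaling (each column scaled so totals equal the mean
of the original totals — the target is a convention; mean was chosen and is
trivially changeable) is applied at the peptide level, then proteins are
formed by summation and normalized by **fast cyclic loess** on log₂
values: per iteration, each sample's log-ratio M = x_j − rowmean(X) is
smoothed against the mean profile A = rowmean(X) by robust locally weighted
regression (span 0.7, 3 robustness iterations, interpolation delta 1 % of
the A range) and the fit subtracted; 10 iterations by default. This
reproduces the reference R implementation (limma `normalizeCyclicLoess`,
`method="fast"`) to ~10⁻¹⁰, which the test suite checks directly via
Rscript when available.

One property worth knowing: the fast variant is **not a fixed-point map**.
Robust local fits of the residual scatter keep drifting at the ~10⁻²-log₂
level per iteration, and very long iteration counts (hundreds) visibly
drift — in the reference implementation as much as in this one. Ten
iterations remove constant offsets essentially completely (residual median
pairwise log-ratio < 0.01) while leaving rank order within samples intact
for monotone distortions; there is nothing to gain from iterating further.

### Moderated t

For each gene, a two-group model gives means x̄_A, x̄_B and pooled residual
variance s² on d = n_A + n_B − 2 df. Across genes, s² is assumed scaled
inverse-chi-square with prior df d₀ and scale s₀². Writing z = log s²,

    E[z]   = log s₀² + ψ(d/2) − log(d/2) − ψ(d₀/2) + log(d₀/2)
    Var[z] = ψ′(d/2) + ψ′(d₀/2)

so d₀ follows by inverting ψ′ (Newton iteration, with the asymptotic
branches 1/√x for x > 10⁷ and 1/x for x < 10⁻⁶) on the excess sample
variance of z, and s₀² from the mean. If the excess variance is ≤ 0 the
prior is infinite: every gene gets s̃² = s₀² and the statistic is referred
to a standard normal. Otherwise s̃² = (d₀s₀² + d·s²)/(d₀ + d) and
t = (x̄_A − x̄_B)/(s̃·√(1/n_A + 1/n_B)) has d + d₀ df. Genes with s² = 0
(possible in noise-free synthetic data) are excluded from the moment fit
and shrink toward the prior as d₀s₀²·d⁻¹-weighted averages, exactly as the
formula dictates. `prior_df=0` recovers the classical pooled t-test;
`prior_df=inf` the z-limit; both limits are tested numerically. No
intensity-dependent variance trend is fitted (the reference default).
Agreement with limma `eBayes` on the shipped 50×20 fixture is ~10⁻¹³ in
d₀, s₀², t and p.

Species are pooled within groups — species is not modeled as a nested
random effect. This matches the study design being emulated and keeps the
contrast a two-group comparison; within-group species differences inflate
the residual variance and make the test conservative rather than invalid.

Multiple testing uses Benjamini–Hochberg step-up (delegated to
statsmodels); a gene is called significant when adjusted p ≤ α = 0.005,
*inclusive* at the boundary. Fold changes are reported as
max(r, 1/r) with a direction label.

### Enrichment

Gene-set enrichment is a Pearson chi-square on the 2×2 table
(set∩DE, set∩nonDE, nonset∩DE, nonset∩nonDE), df = 1, *without* continuity
correction by default; the Yates-corrected variant is available by flag
because published analyses frequently leave the choice unstated — for the
margins used in the worked example the two straddle the published value,
so both are reported. Odds ratios use the Haldane +0.5 correction only
when a cell is zero. The universe is the set of quantified genes with the
gene set's margin disjoint from its complement.

### Co-expression and QC

Correlations are Pearson on log₂ abundances. Sample clustering uses
1 − r as the distance with average linkage; columns are sorted by sample
id before clustering, making the dendrogram invariant to input order, and
the tree is exported as Newick. CoV is the unbiased SD divided by the mean
of *linear*-scale values, reported in percent; pairwise R² is squared
Pearson correlation of log₂ values (linear-scale R² would be dominated by
the top abundance decade).

## Synthetic data

The generator produces, from one master seed, per-species protein FASTAs,
a complete long-format peptide report, a design table and the full ground
truth. Independent pseudo-random streams are derived per logical entity
(sequences, abundances, noise, Q-values, charges), so the same seed gives
byte-identical output.

What it emulates, with defaults chosen to mirror the study conditions:

* 4 species in 2 groups, n = 5/5/6/5 samples;
* 2000 genes, 2–8 peptides each; protein sequences are concatenations of
  tryptic blocks (length 6–20, terminal K/R, no internal K/R/P) so a
  0-missed digest recovers exactly the generated peptides;
* 70 % of peptides identical in all species; the rest carry ≥ 1
  substitution in ≥ 1 non-reference species, substitutions never touching
  K/R/P so the cleavage structure stays aligned across species;
* gene abundances log-normal with log₁₀ SD 0.8 — with peptide response
  factors of log₁₀ SD 1.0 the observed peptide intensities span roughly
  six orders of magnitude or more;
* 10 % of genes differentially abundant with |log₂FC| ~ U(0.2, 2.0),
  applied ±half to each contrast group;
* multiplicative log-normal observation noise with mean 1 and CV 10 %
  (4 % in the technical-replicate emulation);
* 2 % of observations drawn as low-confidence (Q in a log-uniform band
  above 10⁻⁴), preferentially at low intensities via a weighted
  without-replacement (Gumbel top-k) draw; confident observations get
  Q ≤ 10⁻⁵.

An optional `species_effect_sd` (default 0) adds per-gene per-species log₂
offsets beyond the group contrast. It is off by default so that the no-DE
configuration is an exact null for FDR-control experiments; the clustering
tests switch it on to create species structure dominating the noise.

What it does **not** emulate: retention time and fragment-level signals,
interference/background, missing rows (targeted extraction is assumed
complete), shared peptides between genes (library maps are unambiguous by
construction), modified-peptide variants, and any intensity-dependent
noise trend. Consequently, passing tests demonstrate the correctness and
calibration of the statistical machinery under the stated generative
model — not robustness to interference, missingness or annotation
ambiguity in real extractions. The Q-value model in particular is a
structural stand-in, not calibrated to any real extraction software.

## Problem sizes and tolerances

The validation suite uses 2000-gene simulations (≈ 10 000 peptides,
210 000 observations) for calibration checks, 20 replicates for the null
false-positive experiment, and 150–500-gene datasets for unit tests —
sizes at which all binomial/Monte-Carlo tolerances used (±5 percentage
points on conservation, ±25 % relative on noise CV, 3 Monte-Carlo SEs on
the null FDR) are comfortably wider than sampling error. The sensitivity
experiment fixes the true fold change at 1.25 and uses observation CV 13 %,
which lands the median protein-level CoV in the 8–12 % window
characteristic of the emulated workflow's biological comparisons.
Numerical comparisons against independent oracles use 10⁻⁶ relative
tolerance; comparisons against the R reference implementations 10⁻⁶ or
tighter. Degenerate inputs — zero variances, zero observable peptides,
empty gene sets, zero column totals, incomplete matrices — raise or return
explicit markers rather than propagating NaN/inf silently.

## Known limitations

* Only two-group contrasts; no moderated F-tests over > 2 groups.
* No imputation: the complete-matrix contract is enforced, not worked
  around.
* iBAQ values are relative within an experiment; no calibration to copy
  numbers is attempted.
* The CLI is a thin convenience layer; programmatic use through the
  library API is the primary interface.
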