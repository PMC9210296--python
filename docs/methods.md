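# Methods

## Study design being modeled

Four crosses — two intraspecific parental controls (`dom`, `mus`) and the
reciprocal F1 hybrids (`musXdom`, `domXmus`, named mother × father) — by
three FACS-enriched spermatogenesis stages: leptotene/zygotene (LZ, before
MSCI), diplotene (DIP, after MSCI is established), and round spermatids (RS,
postmeiotic), with three replicates each (36 libraries). The contrast panel
compares each hybrid with the parent that shares its X chromosome (the X is
maternal, so `musXdom` vs `mus` and `domXmus` vs `dom`), plus the two hybrids
against each other, within each stage.

## Negative-binomial differential expression

Counts are modeled NB with variance μ + φμ² (φ = BCV²). For a two-group
contrast the null model fits one log-mean with per-sample log-library-size
offsets, the alternative one log-mean per group; both are one-dimensional
concave problems solved by damped Newton iteration, vectorized across genes
(all-zero genes take the boundary MLE μ→0). The LRT statistic 2·ΔlogLik is
referred to χ²(1). log₂FC uses offset-adjusted group totals with a 0.5-count
prior per group so it is always finite.

**Dispersion.** Per-gene moment estimates φ̂ = Σ(v−m)/Σm² pooled over
replicate groups, with the across-gene median corrected for the χ² skew of
the pooled sample variance (median(χ²_df)/df < 1; at 4 residual df the
uncorrected median runs ~16% low, enough to break null p-value uniformity).
Tagwise values shrink φ̂ toward the common value with prior weight w
(default 10); `prior_weight=inf` collapses to the common value.

**Filtering.** FPKM = count / (exonic kb × library millions); a gene is
expressed when FPKM > 1 (strict) in ≥ 3 samples of the scope — all samples
for the global list, the contrast's six samples for per-cell-type DE calls.
Both scopes are available because published gene counts do not pin down
which was used for the genome-wide list. BH adjustment is applied within
contrast over the genes passing the cell-type filter; unfiltered genes carry
p_adj = 1 and are never DE.

**Pipeline analysis settings.** The end-to-end pipeline estimates one
dispersion from all 12 design groups and uses full shrinkage
(tagwise ≡ common): with 3 replicates per group the per-gene moment estimate
is noise-dominated, and its selection effect (genes with lucky small
within-group variance get both a small dispersion and a large
between-group gap) inflates the far p-tail about six-fold. It also uses
trimmed-mean library scaling rather than raw totals: planted X de-repression
adds counts to hybrid libraries, and pure total-count offsets would push a
systematic apparent logFC onto every null gene (classic composition bias).
Both alternatives remain available (`prior_weight`, `normalization`
arguments). Measured on the generator defaults over 10 seeds: sensitivity
0.95 and observed FDR 0.077 for planted logFC = 2 disruption at FDR 5%.

## X-vs-autosome asymmetry

Among expressed genes of a contrast, up means logFC > 0; exact zeros count
in neither direction (direction undefined; only degenerate synthetic cases
are affected). Pearson's χ² without continuity correction on
[[X_up, X_down], [A_up, A_down]] (continuity correction available behind a
flag); a zero marginal makes the test undefined and it is flagged rather
than computed. The BH family is every test emitted in one run (all contrasts
× cell types × scopes); both the all-expressed and DE-only scopes are
computed since figure-level summaries can be read either way.

## Sliding gene-window scan

Genes ordered along each chromosome; windows of W = 250 expressed genes
advance by step 25 (W/10 — the stride is not prescribed anywhere, so a fine,
bounded default was chosen; configurable). λ_d = genome-wide rate of
direction d × W, computed over the scanned (autosomal by default)
chromosomes; a per-chromosome rate is available behind a flag. The flagging
threshold is the smallest k with P(Poisson(λ) ≤ k) ≥ 0.99 and windows flag
strictly above it (conservative). The final partial window is dropped and
windows never span chromosomes; chromosomes with fewer than W expressed
genes are skipped with a warning.

## Ampliconic copy number

Ampliconic families collapse onto few reference loci, so copy number is read
from depth relative to the diploid background, halved because the sex
chromosomes of males are haploid.

* **Paralog discovery:** exact 31-mer seeds vote for ungapped offsets; each
  candidate locus is scored by full-span identity and kept at ≥ 97% identity
  over ≥ 90% of the query, both strands, overlaps merged keeping the higher
  identity. This replaces an external aligner so results are deterministic;
  the contract is the match counts, not any tool's behavior.
* **Region coverage:** Σ per-region mean depth ÷ (background/2). Summing
  *mean* region depths (not per-base totals) makes a single-copy region
  contribute exactly 1 haploid unit, dimensionally consistent with the
  halved-mean denominator.
* **Informative sites:** all 101-bp query kmers are exact-mapped (both
  strands, capped at 500 hits); m is the modal positive multiplicity,
  smaller value on ties (conservative: fewer assumed reference copies);
  kmers mapping exactly m times are retained, and every ≤ 2-mismatch
  location (pigeonhole: one of three 33-bp thirds must match exactly, then
  Hamming verification) becomes a site. The estimate is the mean over kmers
  of summed relative window depths.
* **Background depth:** length-weighted mean excluding the family's own
  intervals (region method) or the union of all query kmers'
  mismatch-tolerant windows (site method). On a real genome the family is a
  negligible fraction and this equals the genome-wide average; on a
  desk-scale toy genome the amplicon pile-up (up to 20% of the backbone)
  would otherwise inflate its own denominator.
* **GC correction:** window depths divided by the per-2%-GC-bin median
  relative depth of 1000 randomly sampled genome windows, normalized to the
  global median so an unbiased genome is untouched (< 2% shift on
  GC-neutral simulations). The correction is optional.
* **Family ratio:** Sly/(Slx+Slxl1), the two X families pooled; returned at
  full precision with optional significant-digit rounding.

## Synthetic data: what it does and does not emulate

* **Expression:** per-gene lognormal baselines (median 500 counts) times
  per-gene stage multipliers (lognormal, σ=0.5, so samples cluster by cell
  type), NB noise at φ = 0.1748² (BCV 0.175). MSCI multiplies X-gene DIP
  means by 0.02 in all crosses; hybrid disruption multiplies a configurable
  fraction of X genes by 2^logFC (default logFC 2) — defaults plant DIP+RS
  disruption in `musXdom` (0.4/0.3 of X genes) and DIP-only in `domXmus`
  (0.2/0), mirroring the asymmetry between the reciprocal hybrids. Exonic
  lengths are log-uniform in [500, 5000] bp so FPKM filtering is
  non-trivial. Truth rows are per gene × stage × hybrid because disruption
  is hybrid-specific. Autosomes use 5 chromosomes so each holds more than
  one 250-gene window at the default 3000 genes. Not emulated: mapping
  bias, multi-mapped counting, batch effects, cross-specific baselines.
* **Amplicons:** R copies of a random query planted without overlap on a
  200-kb backbone at 99.9% per-base identity — the near-perfect internal
  identity that defines ampliconic repeats and that a 2-mismatch/101-bp
  tolerance is matched to (at 99% identity a window exceeds 2 mismatches
  8% of the time and the site estimator would be structurally ~10% low) —
  plus one 92% decoy exercising the 97% filter's lower side. Depth is
  Poisson: 2× haploid mean on the diploid backbone, (N/R)× haploid inside
  planted copies (N sample copies piling onto R reference loci), background
  over the decoy. Not emulated: read-level mapping, indels, GC bias.
* **Phenotypes:** per-cross Gaussian traits and a 4-category morphology
  multinomial per 100 sperm; defaults order the crosses as in the study
  (fertile parents ≈ 3.0 index; hybrids small-testes/low-count, `musXdom`
  most severe ≈ 0.7).
* **Zinc fingers:** 28-residue C2H2 repeats with requested −1/3/6 residues
  (helix positions ≡ H₁−7/H₁−4/H₁−1, the canonical recognition-helix
  numbering given the fixed 12-residue spacer); finger 1 is the invariant
  finger the typing step discards. Spacer-length variants are rejected, not
  aligned — adequate for PRDM9's highly regular array, not for general ZF
  proteins.

Passing tests on these generators demonstrate calibration and truth
recovery under the stated statistical model; they do not certify behavior
under real-data pathologies the generators omit (mapping bias, outlier
samples, assembly gaps).

## Phenotype statistics

Morphology categories 1→3, 2→2, 3→1, 4→0 (forced by the stated 3-to-0 range
and category order). Wilcoxon rank-sum is two-sided (direction is flagged
post hoc from medians, not tested one-sided); the normal approximation with
tie correction is used, with constant-data comparisons set to p = 1 with a
warning. SE of the median is a seeded bootstrap (default 1000 resamples).
All BH corrections in the package share one implementation
(`hybridx.stats.bh_adjust`).

## Numerical choices and problem sizes

Newton tolerance 1e−12 on the log-mean step, 100 iterations, steps clipped
to ±5; LRT clipped at 0 (the alternative nests the null, so negatives are
numerical). Dispersions floored at 1e−6. Calibration checks use 2000-gene
null matrices (5 seeds), truth recovery the 3000-gene default design (10
seeds), copy-number recovery 10 seeds per (N, R), window calibration 100
seeds, and the asymmetry null panel 200 seeds — sizes at which every Monte
Carlo bound tested has comfortable binomial margin while the whole suite
runs in about a minute.

## Known limitations

* The NB test is the two-group LRT reduction of the single-factor design;
  no quasi-likelihood F-test, exact test, or batch covariates.
* Copy-number identity scoring is ungapped; diverged paralogs with indels
  would be missed (irrelevant at ampliconic identity levels).
* The window scan reports flagged windows only; adjacent flags are not
  merged into regions.
* Allele matching is exact on the −1/3/6 signature; it does not align
  arrays of unequal finger count beyond counting the length difference.
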