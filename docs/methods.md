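# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic benchmark does and does not demonstrate,
and the numerical conventions adopted where the design was genuinely open.

## Coordinates and tags

All coordinates are 0-based half-open; BED input is taken verbatim and GTF
start positions are shifted by −1. A sequencing tag is reduced to its 5′
position (start for +/unstranded records, end−1 for − records); no
fragment-shift or extension is applied. This is the simplest defensible
convention when the fragment-size distribution is unknown, and it biases
summit positions by at most half a fragment length — irrelevant at the
200-bp window resolution used downstream.

## Island calling

The caller follows the SICER design: tile each chromosome into windows of
`window_w` bp (default 200), mark a window *eligible* when its tag count
clears the Poisson tail threshold c\* = min{c : P(X ≥ c | λ_bg) < p₀}, and
link eligible windows across gaps of at most `gap_g` ineligible windows.

- λ_bg = total_treatment_tags × w / (G × f_eff), with
  `effective_genome_fraction` f_eff = 0.74 (the conventional mappable
  fraction for a mammalian genome at short reads).
- `eligibility_p0` = 0.2, SICER's window-level convention. It only shapes
  the candidate set; error control happens at the island level.
- `gap_g` = 1 window for sharp (TF-like) marks, 3 windows for broad
  domains. These are the published SICER conventions; parity with any
  particular SICER release is not a goal.
- Island significance: the treatment count over the island span (gap
  windows included) is tested against Poisson(max(scaled control count,
  λ_bg × n_windows)), where the control count is scaled by the
  treatment/control library-size ratio. Flooring at the background rate
  keeps near-empty control spans from manufacturing significance. A
  zero-tag control degrades to the background expectation with a logged
  warning.
- Multiple testing: Benjamini–Hochberg across all candidate islands
  genome-wide, retained at q < `fdr_threshold` (default 10⁻⁴). This
  replaces SICER's random-background E-value with an equally standard and
  more directly testable criterion exposing the same interface (an FDR
  threshold).
- The summit is the center of the maximal-count window (ties → leftmost).
  Window quantization means summits are resolved to w/2; sequence
  extraction for motif discovery uses summit ± 200 bp with truncation at
  chromosome ends.
- The island score Σ −ln Poisson(count; λ_bg) over eligible windows is
  reported for ranking and is monotone in any count above λ_bg; it plays
  no role in retention.

Calibration, measured by the test suite and `scripts/acceptance.py`: on
matched 20k-tag treatment/control pairs over 10 Mb the mean number of
called islands across 100 seeded runs is ~0 (≤ 0.1 required); 5-kb domains
planted at 8-fold enrichment (≈400 expected tags each) are recovered at
≥ 50% reciprocal overlap in ≥ 95% of cases. Recovery is benchmarked on
multi-window domains because a called island is quantized to whole
windows, which makes 50% reciprocal overlap ill-posed for features
narrower than about two windows.

## Co-occupancy, signal matrices, chromatin mode

Co-occupancy is plain interval intersection: an A peak is co-occupied iff
it shares ≥ 1 bp with any B peak, each side counted once. TSS-proximal
restriction keeps peaks whose alignment center (A summit for A groups, B
summit for solo-B) lies within ±10 kb of any TSS, retaining every
qualifying gene (many-to-many).

Feature classes: promoter = TSS ± 1 kb of any gene; gene body = TSS + 1 kb
strand-ward through the TES; intergenic otherwise. Promoter takes
precedence when a summit satisfies both for different genes, reflecting
the promoter-centric question the classification serves.

Signal matrices cover center ± 5 kb in 100-bp bins with value
log2(RPKM + 1), RPKM = count / (bin_kb × total_tags/10⁶). The log base is
a display convention and configurable; log2 is the heatmap norm. Bins that
fall outside the chromosome read 0. Row ordering sorts by me3 row mean
ascending, breaking ties (equal within 10⁻⁹, implemented by quantizing to
a 10⁻⁹ grid) by ac row mean descending, and is stable thereafter.

A peak's chromatin mode is defined by ≥ 1 bp overlap with called mark
islands at the same FDR as the peaks themselves: me3_marked, ac_marked,
dual, or unmarked. Operationalizing "associated with a mark" as overlap
with a *called* island keeps the definition self-consistent with the rest
of the pipeline rather than introducing a second, arbitrary signal
threshold.

## Differential expression

FPKM = count / (length_kb × total/10⁶). Calls follow fixed filtering
rules: up = KO/WT ≥ 2 ∧ q < 0.05 ∧ mean KO FPKM ≥ 1; down mirrored with
WT; band_1p5 = fold in [1.5, 2) ∧ q < 0.05. Fold changes are ratios of
mean FPKM without pseudocount — the FPKM ≥ 1 gate is what protects against
near-zero denominators, matching the stated rules exactly.

Significance is a two-sample t statistic on log2(FPKM + 1). With two
replicates per genotype a per-gene Welch test has essentially no power
after FDR correction (the df ≈ 2 null has very fat tails), so by default
each genotype's per-gene variance is shrunk toward the grand mean variance
across genes with `prior_df` = 10 pseudo-observations, and the t statistic
uses df = 2(1 + prior_df). Under the generator's homoscedastic
log-multiplicative noise this is close to a known-variance z-test and is
well calibrated: across 100 null simulations of 2,000 genes the false-call
rate is ≤ the nominal 5%, and sensitivity at a planted 4-fold effect with
CV 0.2 and n = 2 is ≥ 90% (measured ≈ 100%). On real data with
heteroscedastic dispersion this moderated test is a transparent stand-in,
not a replacement for a count-model DE method; `prior_df=0` gives plain
Welch, and externally computed p-values can be passed through untouched.

## GSEA

The enrichment score is the signed maximal deviation of the weighted
running sum: hits increment by |metric|^p / Σ_set |metric|^p (p = 1, the
standard weighted statistic), misses decrement by 1/(N − k). A set whose
members' metrics are all exactly zero falls back to equal hit weights.
ES ∈ [−1, 1] by construction; a single top-ranked member gives ES = +1 and
a single bottom-ranked member gives ES = −1 (the running minimum −1 is
reached just before the final hit).

The ranking metric is log2((mean WT FPKM + ε)/(mean KO FPKM + ε)), ε =
0.01, ties broken lexicographically. With two replicates per genotype,
phenotype permutation is degenerate (only three distinct relabelings), so
the null redraws the gene set uniformly without replacement —
*gene-set permutation* — which is the appropriate scheme at this design
size. Nominal p uses the (k+1)/(n+1) convention over same-sign null
scores; NES divides ES by the mean same-sign null magnitude; the FDR q is
the standard NES-based ratio pooled over all sets tested. Calibration:
nominal p for random sets on a null ranking is uniform (KS test at
α = 0.01 over 200 sets × 1,000 permutations), and a set planted in the top
decile of the ranking is detected at q < 0.05. The leading edge comprises
set members at or before the extremum for ES > 0, at or after it for
ES < 0.

## Integration

The mode-of-action report records, per gene, its DE call, leading-edge
membership, and the chromatin modes of every peak whose summit lies within
±10 kb of its TSS; summary counts are recomputed from the per-gene records
and checked for consistency. "Up" and "down" are knockout-relative
throughout. The contingency table counts genes that are (ac-marked, down)
versus (me3-marked, up), with Haldane's 0.5 added to every cell when any
cell is zero. The mark–expression check is a Spearman correlation between
promoter-window (TSS ± 1 kb) mark RPKM and mean FPKM; a constant vector
yields NaN ("undefined") rather than an arbitrary number. Reported gene
universes are stated explicitly in the report summary because fractions
over "peaks" versus "TSS-proximal peaks" differ.

## qPCR arithmetic

Histone marks: (ChIP/input) ÷ (negative-control ChIP/input), then divided
by the wild-type reference so WT = 1. Factor binding: (target Ezh2/IgG) ÷
(Hprt Ezh2/IgG). Transcripts: 2^(−ΔΔCt) with a configurable reference
gene; the ΔΔCt method is the standard choice where no amplification-
efficiency calibration is available. All enrichment formulas are invariant
under rescaling all quantities, and non-positive quantities are rejected.

## Synthetic-data generator

The generator is the package's study design, not a tuning knob. Defaults:
2 chromosomes × 5 Mb; 300 genes placed uniformly with ≥ 25 kb TSS spacing
and random strands; 40% of promoters bound by factor A; factor B
co-occupies each A site with probability 0.45 (so the expected co-binding
fraction is a known planted quantity) and additionally binds 15% of non-A
promoters so that solo-B sites exist; 15% of A-bound genes are planted as
repressed targets (10-kb repressive-mark domains), the rest as activated
targets (2-kb active-mark promoter domains); a gene is never both. TF
peaks are 300 bp at 8-fold enrichment, domains 8-fold; each library
(A, B, me3, ac, input) totals ~200,000 tags sampled from a
piecewise-constant intensity normalized so the expected total equals the
target (Poisson-distributed actual totals).

The fraction of repressed targets is defined relative to *A-bound* genes
(not all genes) so that every planted class carries an A peak and the
chromatin-mode truth is unambiguous.

Expression: baseline log2 FPKM ~ Normal(4, 1.5), with repressed targets
shifted −3 (a silenced locus is lowly expressed in the wild type) and
activated targets +1; knockout multiplies activated targets by 1/4 and
repressed targets by 4; replicate noise is multiplicative log-normal at
CV 0.2, two replicates per genotype. The −3/+1 baseline shifts are what
give the mark–expression correlations their planted signs.

What the benchmark does **not** emulate: fragment-length structure, GC and
mappability bias, duplicate reads, overdispersed (non-Poisson) background,
gene-dependent expression dispersion, isoforms, and partial or graded
binding. Passing the suite therefore demonstrates the correctness and
calibration of the algorithms under their stated models — it does not
certify performance on real libraries, where peak callers and DE methods
confront all of the above.

## Problem sizes and determinism

The shipped benchmarks use a 10-Mb genome, 100 seeded null runs, 200
planted domains, 200 random gene sets × 1,000 permutations, and 100 null
expression tables of 2,000 genes — sizes at which every calibration
quantity is stable across seeds while the whole suite runs in well under a
minute per stage. Every stochastic routine takes an explicit seed or
generator; the generator's artifacts are bit-identical under a fixed seed,
and acceptance quantities are reproducible given `--seed`.

## Known limitations

- The island caller's per-island Poisson test ignores overdispersion;
  on real input libraries the FDR is nominal only under the Poisson
  background model.
- The moderated DE test assumes roughly shared variance on the log scale
  across genes; strongly heteroscedastic data calls for an external DE
  model whose q-values can be passed through.
- GSEA's gene-set permutation answers a different null than phenotype
  permutation (gene exchangeability rather than label exchangeability);
  with larger designs phenotype permutation would be preferable.
- Full-scale peak or DE counts from any particular published dataset
  depend on unpublished tool parameters and are not reproduction targets
  at this scale.
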