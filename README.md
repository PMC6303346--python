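# chromode

Integrative ChIP-seq / RNA-seq analysis of a chromatin regulator's mode of
action. The package asks, for a factor that can both activate and repress
transcription: *which of its binding sites sit in activating (H3K27ac) versus
repressive (H3K27me3) chromatin, which are co-occupied by a recruiting
transcription factor, and do the nearby genes lose or gain expression when
the factor is knocked out?*

It is aimed at computational biologists analyzing matched ChIP-seq (factor,
co-factor, histone marks, input) and two-genotype RNA-seq, and at anyone who
wants a compact, fully tested reference implementation of the underlying
statistics.

## What it implements

- **Island calling** (`chromode.islands`) — SICER-style enriched-region
  detection. The genome is tiled into *w*-bp windows (default 200); a window
  with count *c* is *eligible* when the Poisson tail
  P(X ≥ c | λ_bg) < p₀ for the background rate
  λ_bg = N·w / (G·f_eff); eligible windows separated by ≤ *g* ineligible
  windows are linked into islands scored by Σ −ln Poisson(count; λ_bg).
  Each island's treatment count is tested against the library-size-scaled
  control count (floored at λ_bg), with Benjamini–Hochberg control at
  q < 10⁻⁴ and a max-window summit.
- **Co-occupancy and chromatin mode** (`chromode.cooccupancy`) — grouping of
  two peak sets into co-occupied/solo groups by ≥1 bp overlap, TSS-proximal
  restriction (±10 kb), promoter / gene-body / intergenic annotation,
  summit-centered log2(RPKM+1) signal matrices (±5 kb, 100-bp bins) with the
  me3-ascending / ac-descending-on-ties row ordering, and classification of
  each peak as me3-marked, ac-marked, dual or unmarked.
- **Differential expression** (`chromode.expression`) — FPKM arithmetic and
  the fold ≥ 2 ∧ q < 0.05 ∧ FPKM ≥ 1 calling rules (plus the 1.5–2-fold
  band), with a variance-moderated two-sample test on log2(FPKM+1) suited to
  two replicates per genotype.
- **GSEA** (`chromode.gsea`) — weighted running-sum enrichment score
  ES ∈ [−1, 1], gene-set permutation null, NES = ES / mean |same-sign null|,
  nominal p with the (k+1)/(n+1) convention, NES-based FDR, and leading-edge
  extraction. GMT/RNK I/O included.
- **Integration** (`chromode.integration`) — peak–gene cross-referencing
  (genes with peaks within ±10 kb of the TSS, unique target genes), the
  mode × DE-direction contingency table with Haldane-corrected odds ratio,
  and the promoter mark-vs-expression Spearman correlation.
- **ChIP-qPCR arithmetic** (`chromode.qpcr`) — double normalization of
  histone-mark signals (input, then negative-control region, then WT = 1),
  factor-binding enrichment relative to IgG and the *Hprt* promoter, and
  2^(−ΔΔCt) relative transcript quantification.
- **Synthetic data** (`chromode.simulate`) — a seeded generator that plants
  TF peaks, co-occupied sites, activating/repressive mark domains and
  genotype-dependent expression effects, and emits every artifact with a
  ground-truth manifest. All statistical guarantees in the test suite are
  measured against this planted truth.

## Worked example

```python
from chromode import (SimConfig, simulate, call_islands, IslandParams,
                      classify_cooccupancy, call_de, build_report)
from chromode.expression import ExpressionTable

res = simulate(SimConfig(seed=1))                 # 300 genes, 10-Mb genome
inp = res.libraries["input"]
tfA = call_islands(res.libraries["tfA"], inp, res.layout, IslandParams(gap_g=1))
tfB = call_islands(res.libraries["tfB"], inp, res.layout, IslandParams(gap_g=1))
me3 = call_islands(res.libraries["me3"], inp, res.layout, IslandParams(gap_g=3))
ac  = call_islands(res.libraries["ac"],  inp, res.layout, IslandParams(gap_g=3))

assignments, frac = classify_cooccupancy(tfA, tfB)
de = call_de(ExpressionTable(res.fpkm, res.design))
report = build_report(res.genes, tfA, me3, ac, de)
print(len(tfA), f"{frac:.2f}", report.summary["peak_mode_counts"])
```

prints

```
120 0.49 {'me3_marked': 18, 'ac_marked': 102, 'dual': 0, 'unmarked': 0}
```

— all 120 planted factor-A peaks are called; 49% overlap factor-B peaks
(the generator plants co-occupancy at rate 0.45); 102 peaks sit in
activating chromatin and 18 in repressive domains, exactly the planted
split. The same stages are available from the shell via the `chromode`
command (`simulate`, `call-islands`, `cooccupancy`, `de`, `gsea`, `qpcr`,
`report`).

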