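# bimodalseed

Analysis toolkit for **non-canonical miRNA seed targeting**: does a miRNA
repress transcripts through an *internal seed* (IS) — perfect
complementarity to guide positions 6–12 — in addition to the canonical seed
(CS) at positions 2–8?

The package is written for computational biologists who have (or can
simulate) the typical evidence set around a miRNA overexpression
experiment: replicate expression arrays, 3′UTR sequences, AGO-CLIP
libraries, small-RNA reads over the miRNA locus, and a qPCR tumour panel.
It provides every analysis stage as a library module, a `bimodalseed` CLI,
and a synthetic-data generator with ground truth so the whole chain is
testable end to end.

## What it computes

For a guide g (5′→3′) and seed window positions a…a+k−1, the **target
word** is the reverse complement of g[a…a+k−1] in DNA. A 5′-truncated
isomiR of s nt shifts every window by +s (CS+1, IS+1, …); which shifts are
active is read off the small-RNA 5′-offset profile.

* **seedscan** — exact word scanning of 3′UTRs, seed-class annotation
  (CS-only / IS-only / both / neither), site-context position frequency
  matrices.
* **expression** — Welch t per gene on log2 replicate matrices,
  Benjamini–Hochberg adjustment, ranking, top-N/down strata; qPCR CNRQ
  normalisation (geometric-mean reference scaling) and Spearman correlation
  on complete cases.
* **enrichment** — Sylamer-style landscapes: for every k-mer w present in K
  of N ranked genes and a leading bin of n genes containing x of them, the
  signed value ±log10 of the exact one-sided hypergeometric tail
  P(X ≥ x | N, K, n) (positive = over-represented). Computed in log space,
  so p ≈ 10⁻³⁰⁰ words do not saturate.
* **ecdf** — Grimson-style seed-class ECDF comparison of log2 fold changes,
  KS tests, mean shifts and a bootstrap additivity gap
  (both − CS − IS shifts).
* **duplex** — intermolecular minimum-free-energy hybrids by
  nearest-neighbor dynamic programming (WC + G·U, bulges/internal loops,
  kcal/mol), contiguous-pairing run analysis, and the down-vs-unaffected
  energy screen of IS-site windows.
* **clip** — seed-anchored peak calling: seed match ± 10 nt windows,
  any-overlap read counting, library-normalised treatment/control
  enrichment, UTR5/CDS/UTR3 annotation, overlap with the down-regulated set.
* **isomir** — 5′-offset spectra of a miRNA locus and selection of active
  seed shifts.
* **simulate** — generates all of the above inputs with planted truth
  (sites, effect sizes, read piles, offset proportions, rank correlation).

## Worked example

Generate a small cohort with planted IS/CS sites (IS effect −0.40 log2
units, CS effect −0.25, σ = 0.3), rank genes, and ask which 7-mer word is
most enriched among down-regulated genes:

```python
from bimodalseed import simulate, expression, enrichment

cfg = simulate.small()                      # 300 genes, 10%/10%/5% classes
utrs, truth = simulate.gen_utrs(cfg, seed=7)
matrix = simulate.gen_expression(truth, cfg, seed=7)
records = expression.per_gene_stats(matrix, simulate.group_labels(cfg))
ranked = expression.rank_by_downregulation(records)

index = enrichment.build_word_index(utrs, k=7)
for word, bin_, peak in enrichment.top_words(ranked, index, m=3):
    print(f"{word}  peak {peak:.1f} at leading bin {bin_}")
```

prints

```
GAGGTCA  peak 29.9 at leading bin 57
AGAGGTC  peak 12.1 at leading bin 51
AGGTCAC  peak 10.9 at leading bin 48
```

`GAGGTCA` is the planted internal-seed word (reverse complement of guide
positions 6–12): its peak, −log10 p ≈ 30 among the ~57 most down-regulated
genes, towers over the rest of the 7-mer vocabulary — the runners-up are
its own 1-shifted neighbours. On the full-size preset the same analysis
separates the IS word from the CS word by hundreds of log units.

The whole chain (isomiR profile → seed set → scan → statistics →
enrichment → ECDF → duplex screen → CLIP → correlation) runs as:

```bash
bimodalseed run-all --preset paperlike --seed 1 --outdir results/run1
```

which writes per-stage TSV/JSON outputs, landscape and ECDF figures, and a
manifest; reruns with the same seed are byte-identical.

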