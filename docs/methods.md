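# Methods

`bimodalseed` implements the computational side of an analysis that asks
whether a miRNA represses transcripts through a *shifted* seed window — an
"internal seed" (IS) at guide positions 6–12 — in addition to, and
independently of, the canonical seed (CS) at positions 2–8. This note
documents the models, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices.

## Seed model and coordinates

A seed is a window on the mature guide described by a 1-based anchor
(position of its first nucleotide on the canonical mature sequence), a word
size k ∈ [5, 9], and an isomiR shift s ≥ 0. The target word is the reverse
complement of the window written in the DNA alphabet, and a 5′ truncation of
the guide by s nt moves every window s positions toward the 3′ end (CS+1,
IS+1, …). Defaults are the 7-mers CS = positions 2–8 and IS = positions
6–12. UTR matches use 0-based half-open intervals; overlapping occurrences
are all counted, though every downstream consumer is presence-based
(≥ 1 occurrence), so multiplicity only shows up in the per-gene counts.
Scanning is exact string matching on the mRNA sense strand; `N` matches
nothing.

## Word-enrichment landscapes

Genes are ranked from most down- to most up-regulated (ascending Welch t,
ties broken by gene id). For a word present in K of N genes, and a leading
bin of the first n genes containing x word-genes, the landscape value is the
signed −log10 of the smaller one-sided hypergeometric tail (positive =
over-represented). The full-list bin is identically zero. The default bin
step is max(1, N/100).

Counting is presence-based rather than occurrence-based with a Markov
background correction: the seed-class factor downstream is itself
presence-based, and presence keeps the exact hypergeometric model. This is a
deliberate divergence from occurrence-counting enrichment engines; on
composition-biased real data it is more sensitive to GC/length confounding
than a composition-corrected statistic would be.

Tails are computed exactly in log space: the pmf is summed from x in the
direction in which it decays (decided against the distribution mode), using
the pmf ratio recurrence with a relative truncation of 1e-18; the fat tail
comes from the exact complement 1 − short + pmf(x). A vectorised
implementation of the same algorithm scans the whole 4^k vocabulary
(`top_words`); a test pins the vectorised path to the scalar engine at
1e-9 and the scalar engine to exhaustive rational enumeration at 1e-12 for
all parameterisations with N ≤ 12.

## Differential expression, strata, ECDFs

Per-gene statistics are Welch two-sample t on log2 values with
Welch–Satterthwaite degrees of freedom (zero-variance equal-mean rows get
t = 0, p = 1), Benjamini–Hochberg adjustment, and two strata used downstream:
the top-250 down-regulated set restricted to adjusted p < 0.01, and the
t < −4 "down" / t ≥ −4 "unaffected" split. For the latter, the mirror
reading (unaffected = t ≥ +4) is preserved behind
`stratify_by_t(..., unaffected="t_ge_4")` because a threshold printed as
"≥ 4" admits both readings; the complement is the default since the
mirror stratum would exclude almost every gene.

The seed-class ECDF analysis partitions genes into CS-only / IS-only /
both / neither by the word content of their 3′UTRs (word sets include all
active shifted variants) and compares log2 fold-change distributions. The
scalar summary is the mean shift against the "neither" background (median
optional); the two-sample KS test (D plus asymptotic Kolmogorov p; exact
label-permutation enumeration available for tiny samples) accompanies the
curves. Additivity of CS and IS repression is tested as
gap = shift(both) − shift(CS-only) − shift(IS-only) with a seeded
percentile bootstrap CI (1000 resamples): under additive planted effects
the CI covers 0.

## Duplex energy model

The duplex module finds the minimum-free-energy *intermolecular* pairing of
guide and target window under a nearest-neighbor model: Watson–Crick + G·U
pairs, non-crossing antiparallel pairings, energy = initiation (+4.09
kcal/mol) + tabulated stacks + bulge/internal-loop penalties by size, capped
at 10 nt per side with a linear 0.3 kcal/mol/nt extension beyond the table.
There is no intramolecular structure, no dangling ends, no temperature
scaling, and no partition function.

The embedded parameter table (`data/nn_params.json`, version
`bimodalseed-nn-1`) is a simplified pair-strength table: stack(p1, p2) =
−(s(p1) + s(p2)) with s(GC) = 1.6, s(AU) = 0.6, s(GU) = 0.25 kcal/mol. It
reproduces the qualitative ordering of real stacking energies (GC-rich
stacks ≈ −3.2, AU/AU ≈ −1.2) and guarantees the monotonicity invariants
(WC stacks ≤ 0; substituting G·C for A·U never destabilises). Numeric
agreement with external folding programs is explicitly not a goal; the DP is
validated instead against exhaustive enumeration of all non-crossing
pairings (exact energy match on random pairs up to length 8). The table is a
data file so a fuller Turner set can be swapped in.

Traceback ties break toward more pairs, then the smallest gap pair, making
results deterministic. The target window for screening is the seed match
± 15 nt (configurable); the per-gene statistic is the minimum energy over a
gene's IS windows (per-site mode available). Hybrids whose MFE structure
carries ≥ 10 uninterrupted pairs covering the IS window are flagged as
long-motif candidates.

## CLIP peak calling

Candidate regions are seed matches extended 10 nt in both directions in
transcript coordinates, clipped at transcript bounds, with overlapping
same-type windows merged (CS and IS windows are kept separate even when
they overlap). Reads count toward a window on any ≥ 1-base overlap,
weighted by their collapsed-duplicate count. A window is a positive peak
when n_treat ≥ 5 and the pseudocount-regularised, library-size-normalised
fold change ≥ 2; a one-sided Poisson test (`test="poisson"`) is an
alternative criterion. These defaults are documented choices, not a claim
to reproduce any particular published peak count. Peaks are annotated
UTR5/CDS/UTR3 by midpoint against a per-transcript span model, and
positive 3′UTR peak genes are intersected with the down-regulated set per
seed type.

## isomiR profiling

Read 5′ offsets are measured against the canonical mature 5′ end in mature
orientation (plus strand: read.start − locus.start; minus strand:
locus.end − read.end; positive = truncated), weighted by read count, with
|offset| > 5 pooled into an "other" bucket. Shifts whose locus fraction
reaches `min_fraction` (default 0.10) become active seed shifts and feed the
scanner's shifted word sets. Negative offsets (5′ extensions) and 3′
heterogeneity are recorded but never shift seeds.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
an explicit truth manifest:

* **UTR cohort** — i.i.d. nucleotides at GC 0.45, lengths uniform 200–2000
  nt, 5000 genes; 10% CS-only, 10% IS-only, 5% both (one planted site per
  seed type, non-overlapping). Any chance occurrence of an active word
  (shifts 0–2) triggers a resample, so class labels are exact.
* **Non-pairing flanks** — the two bases flanking a planted site are chosen
  so they cannot pair (WC or G·U) with the adjacent guide bases; contiguous
  guide–target complementarity at a planted site therefore equals the seed
  length. Without this, roughly one random-flank site in seven extends to
  ≥ 10 contiguous pairs by chance and the long-hybrid screen's ground truth
  would be ill-defined. Deliberate long hybrids are planted separately
  (`plant_long_hybrids`) as perfect 12-nt complements centred on the IS
  site; note that a perfect complement over guide positions 3–14
  necessarily embeds the shifted-seed words, so classification should be
  read before planting.
* **Expression** — control replicates ~ N(8, 0.3²) on the log2 scale,
  treatment shifted by δ_CS·[CS] + δ_IS·[IS] + interaction·[both] with
  δ_CS = −0.25, δ_IS = −0.40, interaction 0, six replicates per group.
  Effect sizes are in the range such seed classes show in transfection
  arrays, with the IS effect deliberately stronger than CS to mirror the
  motivating observation.
* **CLIP** — each planted site receives a treatment read pile (Poisson mean
  30 reads, 30-nt reads, starts jittered ± 5 nt) with probability 0.6; the
  other sites are decoys. Both libraries carry uniform background at 0.01
  reads/nt over transcripts modelled as 100 nt UTR5 + 500 nt CDS + the
  generated 3′UTR. All planted sites are 3′UTR sites; CDS/UTR5 annotation
  is exercised by hand-built fixtures.
* **isomiRs** — multinomial 5′ offsets (0, 1, 2) at (0.6, 0.3, 0.1) over
  5000 locus reads: two major isoforms and a minor third, the structure the
  shift-selection rule is designed around.
* **qPCR** — a Gaussian copula plants Spearman ρ = −0.5 between the miRNA
  and target latent log2 quantities across 19 samples (the per-group tumour
  panel size), Pearson latent correlation 2·sin(πρ/6); three reference
  genes constant up to 0.05 cycles of noise; Cq = 25 − log2(quantity) +
  N(0, 0.1). With noise set to 0, CNRQ inverts the construction exactly.

All streams derive from a master seed via named `SeedSequence` spawns;
identical config + seed reproduce outputs byte-identically.

What the generator does **not** emulate: real transcriptome composition
(GC/length biases that confound presence-based enrichment), probe-level
array noise and probe-to-gene multiplicity, crosslink-induced truncations
or mutations in CLIP reads, multi-site target architecture (single site per
class by default), and correlated biological replicates. Passing recovery
tests therefore demonstrates the correctness of the machinery under the
stated statistical model, not robustness to those real-data artefacts.

## Scenario sizes and specific choices

* The duplex screen recovery scenario uses 400 genes with δ_IS = −1.2: at
  the default effect size the expected per-gene t is about −2.3
  (|δ|/(σ·√(2/6))), so a t < −4 down stratum would be nearly empty; the
  stronger planted effect populates it, which is the point of that
  scenario.
* Spearman recovery at n = 19 is asserted as: the planted ρ lies in the
  central 95% of 200 estimates, and the mean estimate is within 0.05 of the
  truth. The 0.05 allowance is the known small-sample attenuation of the
  rank correlation (Moran's expectation formula gives E[r_s] ≈ −0.477 for a
  planted −0.5 at n = 19), not an empirical tolerance.
* Unit tests on the 300-gene cohort assert recoveries at 3·SE (n ≈ 30 per
  class); the 5000-gene validation asserts at 2·SE.
* `run-all` computes 7-mer landscapes by default (6/7/8-mers via `--k`),
  uses isomiR `min_fraction` 0.10, and writes a manifest without timestamps
  so reruns are byte-identical.

## Known limitations

* Presence-based enrichment has no composition correction (see above).
* The duplex parameter table is internally consistent but simplified; MFE
  values are comparable within this package only.
* The peak caller's enrichment criterion is a normalised fold change with a
  pseudocount; scale invariance is exact only with the pseudocount off.
* Exact Spearman p values (n ≤ 10) enumerate all pairings and are
  exponential in n; larger samples use the t approximation.
* Genome-space CLIP (liftover from transcript coordinates) and CLASH-style
  chimera parsing are out of scope.
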