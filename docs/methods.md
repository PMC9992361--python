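# Methods

## Substitution calling

Input is a stream of uniquely mapped, tagged reads (cell barcode, UMI, gene,
gene strand). Reads are kept when their mapping quality strictly exceeds 10
and all three tags are present; rejections are tallied per category, never
raised. Reads sharing one (cell, gene, UMI) are collapsed to a consensus by
majority vote at each covered reference position. Three rules govern the
vote:

* a base participates only when its Phred quality strictly exceeds 27 —
  below that it is treated as *missing*, not merely excluded from
  substitution calls, so low-quality reads cannot dominate a site;
* a tie resolves to the reference base (conservative: ties never create a
  substitution), which also makes the consensus independent of read order;
* UMI groups with fewer than 2 reads are discarded — a single read cannot be
  error-corrected by voting.

On the consensus, `n` counts positions whose *sense-strand* reference base
is T (reference T on plus-strand genes, reference A complemented on
minus-strand genes — the conversion chemistry acts on the transcript, so all
calls are defined on the transcript sense strand) and `y` the subset read as
sense-strand C. Sites carrying T-to-C signal in an unlabeled control sample
are masked from **both** counts: removing a site from `y` but not `n` would
bias the per-site conversion probability the mixture model estimates.
Consensus sites are those covered by *any* read of the group; the stricter
alternative (sites covered by every read) discards information without
changing the per-site error model, since sub-threshold bases are already
missing. Coordinates are 0-based internally; non-ACGT reference bases are
excluded from `n`.

A molecule is *labeled* iff `y ≥ 1`. Labeled and unlabeled molecules are
tallied into sparse cell × gene matrices L and U; duplicated
(cell, gene, UMI) keys keep the first record and log the rest. Barcodes are
matched exactly — barcode error correction belongs to the upstream
demultiplexer.

## Mixture model

Each record contributes (n_i, y_i) to

    f(θ, p, q) = θ·Binom(y_i; p, n_i) + (1 − θ)·Binom(y_i; q, n_i),

the two components being genuine labeling (rate p) and background (rate q).
The log-likelihood is computed with log-sum-exp stabilization, after
collapsing records to unique (n, y) pairs with multiplicities — an exact
rewrite that makes each evaluation O(distinct pairs) instead of O(records).
Records with n = 0 carry no likelihood information and are excluded (they
remain in U for matrix totals).

**Global fit.** Up to 100,000 records are subsampled without replacement
(seeded); Nelder–Mead runs from 100 random interior starts drawn as
θ ~ U(0.05, 0.5), p ~ U(0.005, 0.08), q ~ U(10⁻⁴, 0.01) — spanning
plausible 4sU-incorporation and background regimes — in logit space, which
enforces (0, 1) bounds without constraints. Convergence: absolute function
tolerance 1e-8, at most 2,000 iterations per restart (the problem is a
cheap 3-D surface). The best restart wins; the label-switching symmetry
(θ, p, q) ↔ (1−θ, q, p) is broken by swapping components so p ≥ q. A sample
with no substitutions at all leaves the mixture unidentifiable: the
boundary fit (θ = 0, rates at 0) is returned with a structured warning.
Note the mixture *nests* the single binomial, so on data generated with
p = q its maximum likelihood is marginally above the single-binomial
optimum in any finite sample; tests treat that gap as a likelihood-ratio
statistic, not a defect.

**Per-gene θ.** With (p, q) fixed, θ_gene maximizes the same likelihood over
θ alone (bounded scalar optimization, tolerance 1e-10, explicit boundary
checks — the function is concave in θ). Records are pooled across all cells
of one sample: the per-cell alternative is data-starved at typical UMI
depths. Genes with fewer than 5 usable records fall back to the sample-level
θ̂ and are flagged; so does the degenerate case p ≤ q.

**Detection rate and correction.** α_cell = L_cell / Σ_g θ_g (L_g + U_g)
divides observed labeled molecules by model-estimated new molecules.
α is deliberately not clamped to 1 — the min() in
N_g = min(L_g / α_cell, L_g + U_g) is the sole guard, and old counts are
(L + U) − N, which the clamp keeps non-negative. α = 0 exactly when the
cell has no labeled molecules (then every N is 0); a zero denominator with
a nonzero numerator cannot arise from self-consistent inputs and raises.
Note α's numerator counts *observed* labeled molecules, which at q > 0
includes background-labeled old molecules; α therefore exceeds the
labeled-given-new probability 1 − (1−p)^n whenever q > 0, and equals it
only in the no-background limit — the regime the detection-rate consistency
test uses.

## Simulator

The generator draws exactly the structure the model assumes, so every
estimator is testable by parameter recovery. Per sample: gene abundance
weights from a symmetric Dirichlet (concentration 0.5 — skewed expression,
which exercises the sparse-gene fallback); per-gene θ from U(0.05, 0.35)
(mean 0.2) unless given; per cell a Poisson(1000) number of molecules. Per
molecule: gene ~ weights, new ~ Bernoulli(θ_gene), uridine count
n ~ Poisson(50) clipped to ≥ 1 (or fixed), conversions
y ~ Binom(n, p if new else q). Defaults p = 0.02, q = 0.001 reproduce the
regime of roughly 15% labeled UMIs at n ≈ 50 and θ ≈ 0.15–0.2 reported for
2 h 4sU labeling; they are simulator choices, not fitted values. Everything
is parameterized in `SimConfig`; the seed is mandatory and the output is
byte-deterministic given it.

The read-level path places each gene on its own 300-nt random locus
(strands alternate), gives each molecule a random 100-nt window, applies
conversions **once per molecule** (chemistry precedes amplification — all
reads of a UMI share them; this ordering is what makes consensus voting
effective), then applies sequencing errors independently per read and base.
Reads per UMI default to 1 + Geometric (mean 3, minimum 2); a fixed count
can be forced, e.g. 1 to exercise the min-reads filter. Truth (n, y) refers
to the molecule, so with zero sequencing error the calling pipeline must
recover it exactly — a lossless-channel contract the tests assert per UMI.

Not emulated: transcript structure (introns, splicing), ambient RNA,
doublets, barcode errors, PCR duplication bias, or coverage that varies
along the transcript. Passing tests therefore validate the statistical
machinery under the model's own assumptions, not robustness to artifacts
real libraries add on top.

## Normalization and differential expression

Counts are scaled to transcripts-per-10,000 per cell and transformed as
ln(TP10K + 1); optional per-gene z-scaling standardizes over retained cells
(cells with zero totals are dropped with a warning; constant genes stay at
0). The transform inverts exactly (expm1, rescale) when not z-scaled.

Differential testing of corrected new counts compares each treated group
with the control per gene using the two-sided Wilcoxon rank-sum test
(normal approximation with tie correction) on the log-normalized values; a
gene constant across both groups gets p = 1 by convention. Fold changes are
ratios of group means on the linear TP10K scale — matching "fold change of
expression" semantics; the log-space alternative is one normalization flag
away. Significance requires absolute fold change > 1.5 (the ratio or its
inverse) **and** Bonferroni-adjusted p < 0.05, where the Bonferroni
denominator is the number of genes tested per comparison after exclusions;
a gene is reported significant when it passes in at least one treated
comparison (union rule). Mitochondrial (MT-) and ribosomal-protein
(RPL/RPS) gene names are excluded before testing; the patterns are
arguments, since the categories, not the prefixes, are the convention.

## Problem sizes used in tests and the acceptance script

Parameter recovery runs 20 (tests) or 10 (script) independent samples of
~100,000 records at θ = 0.2, p = 0.02, q = 0.001, n = 50 — enough that the
MLE's sampling error is well inside the asserted tolerances (mean |θ̂ − θ|
≤ 0.03, p̂ within 15%, q̂ within 50%). The grid-search oracle uses a 21³
lattice over [0,1] × [0,0.1] × [0,0.01]. Detection-rate consistency uses 15
cells of ~4,000 UMIs at q = 0, so the comparator's own binomial noise
(SE ≈ 0.017) sits inside the ±0.05 band. The channel comparison calls
~4,000 UMIs at 0.1% per-base error with 3 reads each. The DE power test
uses 200 cells per group, 100 genes, 20 of them shifted 2× in mean.

## Known limitations

* θ_gene is a point estimate; no posterior uncertainty is propagated into α
  or N (credible-interval machinery is out of scope).
* Each sample (time point) is fit independently; there is no joint
  multi-sample model.
* α assumes the detection rate is shared across a cell's genes; genes with
  atypical uridine content violate this mildly (longer transcripts are more
  often labeled at equal p).
* Only T-to-C conversions are called; other chemistries (e.g. G-to-A) would
  need a second base-pair convention.
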