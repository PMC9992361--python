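# slamkit

New-RNA quantification for nucleotide-conversion single-cell RNA-seq.

Metabolic labeling with 4-thiouridine (4sU) followed by iodoacetamide
alkylation leaves T-to-C substitutions in reads that come from RNA
transcribed during the labeling window. `slamkit` turns tagged alignments
(cell barcode, UMI, gene) into per-molecule substitution calls, separates
genuine labeling from background with a binomial mixture model, and corrects
the resulting new-RNA counts for incomplete labeling — producing the paired
"new" and "old" expression matrices that time-resolved single-cell analyses
(RNA velocity, response kinetics, regulon dynamics) are built on.

It is aimed at computational biologists processing SLAM/TimeLapse-chemistry
scRNA-seq data who need the statistical core — consensus calling, mixture
fitting, detection-rate correction — as a library and a small CLI, without
an alignment or barcoding pipeline attached.

## The model

For molecule *i*, let *n_i* be the number of sense-strand uridine positions
observed on its UMI-consensus sequence and *y_i* the number read as C.
A fraction θ of molecules is newly transcribed; new molecules convert each
uridine with probability *p* (incomplete 4sU incorporation keeps *p* ≪ 1),
old molecules with background probability *q* (SNPs, residual errors):

    f(θ, p, q) = θ·Binom(y_i; p, n_i) + (1 − θ)·Binom(y_i; q, n_i)

Global (θ, p, q) are maximum-likelihood estimates over a random subsample of
consensus records (multi-restart Nelder–Mead in logit space). With (p, q)
fixed, a per-gene fraction θ_gene is a bounded 1-D maximization. Because a
new molecule shows no conversion with probability (1−p)^n, observed labeled
counts underestimate new RNA; the per-cell detection rate

    α_cell = L_cell / Σ_g θ_gene (L_g + U_g)

(observed labeled molecules over model-estimated new molecules) corrects
them: N_gene = min(L_gene / α_cell, L_gene + U_gene), and old counts are
(L + U) − N.

Calling conventions: reads kept at mapping quality > 10; bases vote in the
consensus only at Phred > 27; UMIs need ≥ 2 supporting reads; sites with
T-to-C signal in an unlabeled control are masked; a molecule is *labeled*
iff its consensus carries ≥ 1 sense-strand T-to-C.

## Worked example

Simulate a sample, fit the mixture, and correct the counts:

```python
import slamkit as sk

cfg = sk.SimConfig(n_cells=100, n_genes=100, umis_per_cell=1000,
                   theta_gene=0.2, n_sites_fixed=50, p=0.02, q=0.001, seed=11)
records, truth = sk.simulate_records(cfg)
fit = sk.fit_global_pq([(r.n, r.y) for r in records], seed=11)
print(f"theta={fit.theta:.3f} p={fit.p:.4f} q={fit.q:.5f}")

matrices = sk.assemble_matrices(records)
thetas = sk.estimate_all_gene_thetas(records, fit)
alphas = sk.correct_matrices(matrices, thetas)
print(f"mean alpha = {sum(a.alpha for a in alphas)/len(alphas):.3f}")
```

prints

```
theta=0.193 p=0.0204 q=0.00107
mean alpha = 0.861
```

i.e. from ~100,000 simulated molecules the fit recovers the true new
fraction 0.20 within 0.01, the conversion rate 0.02 within 2%, and the
background rate 0.001 within 10%. The detection rate is well below 1
because at p = 0.02 and 50 uridines per molecule only 1 − 0.98⁵⁰ ≈ 64% of
new molecules carry a visible conversion; background conversions on old
molecules push the observed-labeled numerator back up, landing the mean
α near 0.86 — `correct_matrices` divides each labeled count by its cell's
α, clamped at the total observed.

The same flow from a shell:

```
slamkit simulate --seed 11 --out-dir sim/
slamkit fit --records sim/records.tsv --seed 11 --out fit.json
slamkit correct --fit-json fit.json --records sim/records.tsv --out-dir corrected/
slamkit deg --new-matrix corrected/ --groups groups.tsv --control day0 --out de.tsv
```

`slamkit call --bam sample.bam --fasta ref.fa --control-bam ctrl.bam
--out-dir out/` runs consensus substitution calling on real tagged
alignments (Drop-seq style XC/XM/GE tags).

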