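"""Synthetic nucleotide-conversion scRNA-seq data with known ground truth.

The generator mirrors the statistical structure the mixture model assumes:
every captured molecule belongs to a gene drawn from skewed abundance
weights, is newly transcribed with probability theta_gene, and accumulates
T-to-C conversions per uridine site at rate p (new) or q (old).  Conversion
happens at the molecule level — all reads of a UMI inherit the same
converted sites, because the chemistry acts on the transcript before
amplification — while sequencing errors are drawn independently per read and
base.  That ordering is exactly what makes UMI-consensus voting effective.

Two entry points:

* :func:`simulate_records` draws consensus-level records (n, y) directly —
  the fast path for testing the mixture model;
* :func:`simulate_reads` expands every molecule into tagged reads against a
  generated toy reference, exercising the full consensus-calling pipeline.

Both are deterministic given ``SimConfig.seed`` and return a
:class:`SimTruth` with every latent variable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .calling import COMPLEMENT, ConsensusRecord, TaggedRead

BASES = np.array(["A", "C", "G", "T"])

# toy reference geometry: one locus per gene, reads cover a fixed-width window
LOCUS_LEN = 300
READ_LEN = 100


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    Defaults mimic the regime reported for 2 h 4sU labeling: conversion rate
    p = 0.02 and background q = 0.001 give roughly 15% labeled UMIs at
    ~50 uridine sites per molecule and new fractions around 0.2.  Gene
    abundances are symmetric-Dirichlet (concentration 0.5) to produce the
    skewed expression typical of real libraries, which also exercises the
    sparse-gene theta fallback.  ``theta_gene`` may be a scalar, a per-gene
    array, or None to draw Uniform(0.05, 0.35) per gene (mean 0.2).
    """

    n_cells: int = 200
    n_genes: int = 100
    seed: int = 0
    gene_abundance: Optional[np.ndarray] = None
    dirichlet_conc: float = 0.5
    umis_per_cell: float = 1000.0
    theta_gene: Optional[float | np.ndarray] = None
    p: float = 0.02
    q: float = 0.001
    n_sites_mean: float = 50.0
    n_sites_fixed: Optional[int] = None
    reads_per_umi_mean: float = 3.0
    reads_per_umi_fixed: Optional[int] = None
    seq_error: float = 0.0

    def validate(self) -> None:
        rates = {"p": self.p, "q": self.q, "seq_error": self.seq_error}
        for name, r in rates.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name} = {r} outside [0, 1]")
        if not self.p > self.q:
            raise ValueError(f"need p > q, got p = {self.p}, q = {self.q}")
        th = self.theta_gene
        if th is not None:
            arr = np.atleast_1d(np.asarray(th, dtype=float))
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("theta_gene values must lie in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


@dataclass
class SimTruth:
    """Every latent variable of one simulation, per record and aggregated."""

    genes: list[str]
    cells: list[str]
    theta_gene: np.ndarray
    p: float
    q: float
    cell_of: np.ndarray   # record -> cell index
    gene_of: np.ndarray   # record -> gene index
    is_new: np.ndarray    # record -> bool
    n: np.ndarray         # record -> uridine sites
    y: np.ndarray         # record -> conversions

    def n_records(self) -> int:
        return int(self.n.size)

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "theta_gene": self.theta_gene})

    def cell_table(self) -> pd.DataFrame:
        """Per-cell new-molecule totals and the realized detection rate.

        The realized rate is the fraction of truly new molecules that carry at
        least one conversion — what the model's alpha_cell estimates.
        """
        n_cells = len(self.cells)
        new = np.bincount(self.cell_of, weights=self.is_new, minlength=n_cells)
        labeled_new = np.bincount(
            self.cell_of, weights=self.is_new & (self.y >= 1), minlength=n_cells
        )
        total = np.bincount(self.cell_of, minlength=n_cells)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(new > 0, labeled_new / np.maximum(new, 1), 0.0)
        return pd.DataFrame(
            {
                "cell": self.cells,
                "total_umis": total.astype(int),
                "true_new": new.astype(int),
                "labeled_new": labeled_new.astype(int),
                "realized_detection_rate": rate,
            }
        )

    def record_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": [self.cells[i] for i in self.cell_of],
                "gene": [self.genes[j] for j in self.gene_of],
                "is_new": self.is_new.astype(int),
                "n": self.n,
                "y": self.y,
            }
        )


# ---------------------------------------------------------------------------
# shared latent draws
# ---------------------------------------------------------------------------

def _draw_latents(config: SimConfig, rng: np.random.Generator):
    """Draw weights, thetas, and per-record (cell, gene, new) assignments."""
    G, C = config.n_genes, config.n_cells
    genes = [f"G{j:04d}" for j in range(G)]
    cells = [f"CELL{i:05d}" for i in range(C)]

    if config.gene_abundance is not None:
        w = np.asarray(config.gene_abundance, dtype=float)
        w = w / w.sum()
    else:
        w = rng.dirichlet(np.full(G, config.dirichlet_conc))

    if config.theta_gene is None:
        theta = rng.uniform(0.05, 0.35, size=G)
    else:
        theta = np.broadcast_to(
            np.asarray(config.theta_gene, dtype=float), (G,)
        ).copy()

    umis = rng.poisson(config.umis_per_cell, size=C)
    M = int(umis.sum())
    cell_of = np.repeat(np.arange(C), umis)
    gene_of = rng.choice(G, size=M, p=w)
    is_new = rng.random(M) < theta[gene_of]
    return genes, cells, theta, cell_of, gene_of, is_new


def _draw_n_sites(config: SimConfig, rng: np.random.Generator, m: int) -> np.ndarray:
    if config.n_sites_fixed is not None:
        return np.full(m, config.n_sites_fixed, dtype=np.int64)
    return np.maximum(rng.poisson(config.n_sites_mean, size=m), 1)


# ---------------------------------------------------------------------------
# consensus-record path
# ---------------------------------------------------------------------------

def simulate_records(config: SimConfig) -> tuple[list[ConsensusRecord], SimTruth]:
    """Draw consensus records straight from the mixture's generative model.

    Per molecule: gene ~ abundance weights, new ~ Bernoulli(theta_gene),
    n ~ n_sites distribution (min 1), y ~ Binomial(n, p if new else q).
    Byte-identical output for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, cells, theta, cell_of, gene_of, is_new = _draw_latents(config, rng)
    m = cell_of.size
    n = _draw_n_sites(config, rng, m)
    rate = np.where(is_new, config.p, config.q)
    y = rng.binomial(n, rate)

    records = [
        ConsensusRecord(
            cell_barcode=cells[cell_of[i]],
            gene=genes[gene_of[i]],
            umi=f"U{i:08d}",
            n=int(n[i]),
            y=int(y[i]),
            read_support=2,
        )
        for i in range(m)
    ]
    truth = SimTruth(
        genes=genes, cells=cells, theta_gene=theta, p=config.p, q=config.q,
        cell_of=cell_of, gene_of=gene_of, is_new=is_new, n=n, y=y,
    )
    return records, truth


# ---------------------------------------------------------------------------
# read-level path
# ---------------------------------------------------------------------------

def _make_reference(config: SimConfig, rng: np.random.Generator, genes: list[str]):
    """One random locus per gene; strands alternate so both are exercised."""
    reference: dict[str, str] = {}
    strands: dict[str, str] = {}
    for j, gene in enumerate(genes):
        chrom = f"locus_{gene}"
        reference[chrom] = "".join(rng.choice(BASES, size=LOCUS_LEN))
        strands[gene] = "+" if j % 2 == 0 else "-"
    return reference, strands


def simulate_reads(
    config: SimConfig,
) -> tuple[list[TaggedRead], SimTruth, dict[str, str]]:
    """Expand molecules into tagged reads against a generated toy reference.

    Each molecule occupies a random read-length window of its gene's locus;
    its uridine sites are the sense-strand T positions in that window.
    Conversions are drawn once per molecule and shared by all of its reads;
    sequencing errors hit each read independently at ``seq_error`` per base.
    Truth (n, y) refers to the molecule, so with seq_error = 0 the consensus
    caller recovers it exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, cells, theta, cell_of, gene_of, is_new = _draw_latents(config, rng)
    reference, strands = _make_reference(config, rng, genes)
    m = cell_of.size

    if config.reads_per_umi_fixed is not None:
        reads_per_umi = np.full(m, config.reads_per_umi_fixed, dtype=np.int64)
    else:
        # 1 + geometric: at least one read, mean = reads_per_umi_mean
        reads_per_umi = 1 + rng.geometric(1.0 / (config.reads_per_umi_mean - 1.0), size=m)

    reads: list[TaggedRead] = []
    n_true = np.zeros(m, dtype=np.int64)
    y_true = np.zeros(m, dtype=np.int64)

    for i in range(m):
        gene = genes[gene_of[i]]
        chrom = f"locus_{gene}"
        strand = strands[gene]
        locus = reference[chrom]
        start = int(rng.integers(0, LOCUS_LEN - READ_LEN + 1))
        window = locus[start : start + READ_LEN]

        # sense-strand T positions within the window (genome coordinates)
        if strand == "+":
            t_sites = [start + k for k, b in enumerate(window) if b == "T"]
        else:
            t_sites = [start + k for k, b in enumerate(window) if b == "A"]
        n_true[i] = len(t_sites)

        rate = config.p if is_new[i] else config.q
        converted = [pos for pos in t_sites if rng.random() < rate]
        y_true[i] = len(converted)

        # molecule sequence on the genome strand: T->C on +, A->G on -
        mol = list(window)
        for pos in converted:
            mol[pos - start] = "C" if strand == "+" else "G"

        umi = f"U{i:08d}"
        for _r in range(int(reads_per_umi[i])):
            read_seq = list(mol)
            if config.seq_error > 0:
                err = rng.random(READ_LEN) < config.seq_error
                for k in np.flatnonzero(err):
                    alternatives = [b for b in "ACGT" if b != read_seq[k]]
                    read_seq[k] = alternatives[int(rng.integers(3))]
            pairs = [
                (k, start + k, read_seq[k], window[k], 37) for k in range(READ_LEN)
            ]
            reads.append(
                TaggedRead(
                    cell_barcode=cells[cell_of[i]],
                    umi=umi,
                    gene=gene,
                    mapq=60,
                    aligned_pairs=pairs,
                    gene_strand=strand,
                    chrom=chrom,
                )
            )

    truth = SimTruth(
        genes=genes, cells=cells, theta_gene=theta, p=config.p, q=config.q,
        cell_of=cell_of, gene_of=gene_of, is_new=is_new, n=n_true, y=y_true,
    )
    return reads, truth, reference


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_truth(truth: SimTruth, out_dir: str | Path) -> None:
    """Write ground-truth tables (TSV) and global parameters (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.gene_table().to_csv(out / "truth_gene_theta.tsv", sep="\t", index=False)
    truth.cell_table().to_csv(out / "truth_cells.tsv", sep="\t", index=False)
    truth.record_table().to_csv(out / "truth_records.tsv", sep="\t", index=False)
    (out / "truth_params.json").write_text(
        json.dumps({"p": truth.p, "q": truth.q}, indent=2) + "\n"
    )


def read_truth_gene_theta(out_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(out_dir) / "truth_gene_theta.tsv", sep="\t")


def write_reference_fasta(reference: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(reference):
            fh.write(f">{chrom}\n")
            seq = reference[chrom]
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")


def write_sam(
    reads: list[TaggedRead],
    reference: dict[str, str],
    path: str | Path,
) -> None:
    """Write tagged reads as a plain-text SAM with Drop-seq style tags."""
    import pysam

    chroms = sorted(reference)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": len(reference[c])} for c in chroms],
        }
    )
    tid = {c: k for k, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for idx, read in enumerate(reads):
            a = pysam.AlignedSegment(header)
            a.query_name = f"read{idx:09d}"
            a.reference_id = tid[read.chrom]
            a.reference_start = read.aligned_pairs[0][1]
            a.mapping_quality = read.mapq
            a.query_sequence = "".join(p[2] for p in read.aligned_pairs)
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(p[4] + 33) for p in read.aligned_pairs)
            )
            a.cigarstring = f"{len(read.aligned_pairs)}M"
            a.flag = 0
            a.set_tag("XC", read.cell_barcode)
            a.set_tag("XM", read.umi)
            a.set_tag("GE", read.gene)
            a.set_tag("GS", read.gene_strand)
            out.write(a)


# ---------------------------------------------------------------------------
# group-comparison count simulator (for differential-expression testing)
# ---------------------------------------------------------------------------

def simulate_de_counts(
    n_genes: int = 100,
    n_cells_per_group: int = 200,
    frac_shifted: float = 0.2,
    effect: float = 2.0,
    base_mean: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """Two-group Poisson counts with a known set of mean-shifted genes.

    Gene base means are log-normal around ``base_mean``; a ``frac_shifted``
    subset is multiplied by ``effect`` in the treated group.  Returns
    (counts cells x genes, gene names, group labels, shifted gene names).
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{j:04d}" for j in range(n_genes)]
    mu = base_mean * rng.lognormal(0.0, 0.5, size=n_genes)
    n_shift = int(round(frac_shifted * n_genes))
    shifted_idx = rng.choice(n_genes, size=n_shift, replace=False)
    mu_treated = mu.copy()
    mu_treated[shifted_idx] *= effect

    counts_ctrl = rng.poisson(mu, size=(n_cells_per_group, n_genes))
    counts_trt = rng.poisson(mu_treated, size=(n_cells_per_group, n_genes))
    counts = np.vstack([counts_ctrl, counts_trt])
    groups = ["control"] * n_cells_per_group + ["treated"] * n_cells_per_group
    shifted = [genes[j] for j in sorted(shifted_idx)]
    return counts, genes, groups, shifted
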