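"""Per-UMI consensus construction and T-to-C substitution calling.

Metabolic labeling with 4-thiouridine followed by iodoacetamide alkylation
leaves T-to-C substitutions in sequencing reads of newly transcribed RNA.
This module turns tagged alignment records (cell barcode, UMI, gene) into
per-UMI consensus records: for every captured molecule it reports the number
of sense-strand uridine positions observed (``n``) and how many of them read
as C (``y``).  A molecule is called *labeled* when at least one substitution
survives consensus voting.

Filtering conventions (all strict inequalities):

* reads are kept when their mapping quality exceeds ``min_mapq`` (default 10)
  and they carry cell, UMI and gene tags;
* a base participates in consensus voting only when its Phred quality exceeds
  ``min_phred`` (default 27) — lower-quality bases are treated as missing;
* UMI groups supported by fewer than ``min_reads`` reads (default 2) are
  discarded;
* genomic sites that show T-to-C signal in an unlabeled control sample are
  masked out of both the numerator and the denominator.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("slamkit")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# Drop-seq tag convention
DEFAULT_CELL_TAG = "XC"
DEFAULT_UMI_TAG = "XM"
DEFAULT_GENE_TAG = "GE"
DEFAULT_STRAND_TAG = "GS"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

#: one aligned, quality-scored base:
#: (read_position, reference_position, read_base, reference_base, base_quality)
AlignedBase = tuple[int, int, str, str, int]


@dataclass
class TaggedRead:
    """A uniquely mapped read annotated with cell barcode, UMI and gene.

    ``aligned_pairs`` holds genome-strand bases; strand handling happens at
    substitution-calling time.  ``gene_strand`` is the strand of the annotated
    gene the read was assigned to.
    """

    cell_barcode: str
    umi: str
    gene: str
    mapq: int
    aligned_pairs: list[AlignedBase]
    gene_strand: str
    chrom: str = ""

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.cell_barcode, self.gene, self.umi)


@dataclass
class BackgroundMask:
    """Genomic sites with T-to-C signal in an unlabeled control sample.

    Sites are (chromosome, 0-based position, gene strand).  Membership is an
    exact set test; the empty mask is valid and masks nothing.
    """

    sites: set[tuple[str, int, str]] = field(default_factory=set)

    def __contains__(self, site: tuple[str, int, str]) -> bool:
        return site in self.sites

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class ConsensusRecord:
    """Error-corrected summary of one captured molecule (one UMI).

    ``n`` counts sense-strand uridine sites with a defined consensus base and
    ``y`` the subset whose consensus base is C — the sufficient statistics of
    the binomial mixture model.
    """

    cell_barcode: str
    gene: str
    umi: str
    n: int
    y: int
    read_support: int

    def __post_init__(self) -> None:
        if not (0 <= self.y <= self.n):
            raise ValueError(f"invalid record: y={self.y} outside [0, n={self.n}]")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.cell_barcode, self.gene, self.umi)


@dataclass
class LabelMatrices:
    """Paired sparse cell x gene count matrices.

    ``L`` counts labeled UMIs, ``U`` unlabeled UMIs; ``N`` holds corrected
    new-RNA counts and is zero until filled in by the mixture model.  Rows are
    cells, columns genes, in the stored order.
    """

    cells: list[str]
    genes: list[str]
    L: sp.csr_matrix
    U: sp.csr_matrix
    N: sp.csr_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.cells), len(self.genes))

    def old(self) -> sp.csr_matrix:
        """Pre-existing RNA counts: (L + U) - N."""
        return (self.L + self.U - self.N).tocsr()


# ---------------------------------------------------------------------------
# read-level filtering
# ---------------------------------------------------------------------------

def filter_read(
    read: TaggedRead,
    min_mapq: int = 10,
    rejections: Optional[Counter] = None,
) -> bool:
    """Keep a read iff mapq strictly exceeds ``min_mapq`` and all tags are set.

    Rejected reads are tallied by category in ``rejections`` when given;
    missing tags never raise.
    """
    if read.mapq <= min_mapq:
        if rejections is not None:
            rejections["low_mapq"] += 1
        return False
    if not read.cell_barcode:
        if rejections is not None:
            rejections["missing_cell_tag"] += 1
        return False
    if not read.umi:
        if rejections is not None:
            rejections["missing_umi_tag"] += 1
        return False
    if not read.gene:
        if rejections is not None:
            rejections["missing_gene_tag"] += 1
        return False
    return True


def build_background_mask(
    control_reads: Iterable[TaggedRead],
    min_phred: int = 27,
    min_mapq: int = 10,
) -> BackgroundMask:
    """Collect sites showing sense-strand T-to-C in an unlabeled control.

    Any single control read with a sense-strand T-to-C mismatch at base
    quality strictly above ``min_phred`` puts the site into the mask; reads
    are pre-filtered with the same mapq rule as experimental samples.  These
    sites (SNPs, recurrent errors) are excluded from substitution calling.
    """
    sites: set[tuple[str, int, str]] = set()
    n_reads = 0
    for read in control_reads:
        if not filter_read(read, min_mapq=min_mapq):
            continue
        n_reads += 1
        strand = read.gene_strand
        for _qpos, rpos, base, ref, qual in read.aligned_pairs:
            if qual is None or qual <= min_phred:
                continue
            sense_ref = ref if strand == "+" else COMPLEMENT.get(ref, "N")
            sense_base = base if strand == "+" else COMPLEMENT.get(base, "N")
            if sense_ref == "T" and sense_base == "C":
                sites.add((read.chrom, rpos, strand))
    if n_reads == 0:
        logger.warning("background mask built from an empty control stream")
    return BackgroundMask(sites=sites)


# ---------------------------------------------------------------------------
# UMI consensus
# ---------------------------------------------------------------------------

def collapse_umi(
    reads: Sequence[TaggedRead],
    min_reads: int = 2,
    min_phred: int = 27,
) -> Optional[dict[int, tuple[str, str]]]:
    """Majority-vote consensus over reads sharing one (cell, gene, UMI).

    Returns ``{reference_position: (reference_base, consensus_base)}`` on the
    genome strand, or ``None`` when the group has fewer than ``min_reads``
    reads.  Bases at or below ``min_phred`` are treated as missing and do not
    vote; a site where every base is missing is dropped.  Ties resolve to the
    reference base, so the result is independent of read order.
    """
    if len(reads) < min_reads:
        return None
    votes: dict[int, Counter] = defaultdict(Counter)
    refbase: dict[int, str] = {}
    for read in reads:
        for _qpos, rpos, base, ref, qual in read.aligned_pairs:
            if qual is None or qual <= min_phred:
                continue
            votes[rpos][base] += 1
            refbase[rpos] = ref
    consensus: dict[int, tuple[str, str]] = {}
    for rpos, counter in votes.items():
        top = counter.most_common()
        best, best_count = top[0]
        tied = [b for b, c in top if c == best_count]
        if len(tied) > 1:
            best = refbase[rpos]
        consensus[rpos] = (refbase[rpos], best)
    return consensus


def count_substitutions(
    consensus: dict[int, tuple[str, str]],
    chrom: str,
    gene_strand: str,
    mask: Optional[BackgroundMask] = None,
) -> tuple[int, int]:
    """Count uridine sites (n) and T-to-C substitutions (y) on the sense strand.

    For genes on the minus strand the genome-strand bases are complemented, so
    a reference A read as G counts as a sense T-to-C.  Masked sites and sites
    with a non-ACGT reference base contribute to neither count.
    """
    n = 0
    y = 0
    for rpos, (ref, base) in consensus.items():
        sense_ref = ref if gene_strand == "+" else COMPLEMENT.get(ref, "N")
        if sense_ref != "T":
            continue
        if mask is not None and (chrom, rpos, gene_strand) in mask:
            continue
        n += 1
        sense_base = base if gene_strand == "+" else COMPLEMENT.get(base, "N")
        if sense_base == "C":
            y += 1
    return n, y


def classify_umi(record: ConsensusRecord) -> str:
    """A molecule is 'labeled' (newly transcribed) iff it has >= 1 T-to-C."""
    return "labeled" if record.y >= 1 else "unlabeled"


# ---------------------------------------------------------------------------
# sample-level pipeline
# ---------------------------------------------------------------------------

def process_sample(
    reads: Iterable[TaggedRead],
    mask: Optional[BackgroundMask] = None,
    min_mapq: int = 10,
    min_phred: int = 27,
    min_reads: int = 2,
) -> tuple[list[ConsensusRecord], Counter]:
    """Run filter -> group by (cell, gene, UMI) -> consensus -> count.

    Returns the retained consensus records plus a per-category rejection log.
    """
    rejections: Counter = Counter()
    groups: dict[tuple[str, str, str], list[TaggedRead]] = defaultdict(list)
    for read in reads:
        if filter_read(read, min_mapq=min_mapq, rejections=rejections):
            groups[read.key].append(read)

    records: list[ConsensusRecord] = []
    for (cell, gene, umi), group in groups.items():
        consensus = collapse_umi(group, min_reads=min_reads, min_phred=min_phred)
        if consensus is None:
            rejections["umi_too_few_reads"] += 1
            continue
        n, y = count_substitutions(
            consensus, group[0].chrom, group[0].gene_strand, mask
        )
        records.append(
            ConsensusRecord(
                cell_barcode=cell, gene=gene, umi=umi,
                n=n, y=y, read_support=len(group),
            )
        )
    if rejections:
        logger.info("read/UMI rejections: %s", dict(rejections))
    return records, rejections


def assemble_matrices(records: Iterable[ConsensusRecord]) -> LabelMatrices:
    """Tally labeled and unlabeled UMIs into sparse cell x gene matrices.

    Duplicate (cell, gene, umi) keys keep the first record seen; duplicates
    are logged, never raised.  The empty stream yields valid 0 x 0 matrices.
    """
    seen: set[tuple[str, str, str]] = set()
    kept: list[ConsensusRecord] = []
    n_dup = 0
    for rec in records:
        key = (rec.cell_barcode, rec.gene, rec.umi)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        kept.append(rec)
    if n_dup:
        logger.warning("%d duplicate (cell, gene, umi) records dropped", n_dup)

    cells = sorted({r.cell_barcode for r in kept})
    genes = sorted({r.gene for r in kept})
    cell_idx = {c: i for i, c in enumerate(cells)}
    gene_idx = {g: j for j, g in enumerate(genes)}
    shape = (len(cells), len(genes))

    rows_l, cols_l, rows_u, cols_u = [], [], [], []
    for rec in kept:
        i, j = cell_idx[rec.cell_barcode], gene_idx[rec.gene]
        if rec.y >= 1:
            rows_l.append(i)
            cols_l.append(j)
        else:
            rows_u.append(i)
            cols_u.append(j)

    L = sp.coo_matrix(
        (np.ones(len(rows_l), dtype=np.int64), (rows_l, cols_l)), shape=shape
    ).tocsr()
    U = sp.coo_matrix(
        (np.ones(len(rows_u), dtype=np.int64), (rows_u, cols_u)), shape=shape
    ).tocsr()
    N = sp.csr_matrix(shape, dtype=np.float64)
    return LabelMatrices(cells=cells, genes=genes, L=L, U=U, N=N)


# ---------------------------------------------------------------------------
# alignment-file input
# ---------------------------------------------------------------------------

def reads_from_alignments(
    path: str | Path,
    fasta_path: Optional[str | Path] = None,
    cell_tag: str = DEFAULT_CELL_TAG,
    umi_tag: str = DEFAULT_UMI_TAG,
    gene_tag: str = DEFAULT_GENE_TAG,
    strand_tag: str = DEFAULT_STRAND_TAG,
) -> Iterator[TaggedRead]:
    """Stream TaggedReads from a SAM/BAM file.

    Reference bases come from the indexed FASTA when given, otherwise from the
    MD tag.  Unmapped, secondary and supplementary alignments are skipped.
    """
    import pysam

    fasta = pysam.FastaFile(str(fasta_path)) if fasta_path else None
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for aln in af:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                yield _tagged_read_from_alignment(
                    aln, fasta, cell_tag, umi_tag, gene_tag, strand_tag
                )
    finally:
        if fasta is not None:
            fasta.close()


def _tagged_read_from_alignment(
    aln, fasta, cell_tag: str, umi_tag: str, gene_tag: str, strand_tag: str
) -> TaggedRead:
    def tag(name: str) -> str:
        return aln.get_tag(name) if aln.has_tag(name) else ""

    gene_strand = tag(strand_tag) or ("-" if aln.is_reverse else "+")
    seq = aln.query_sequence or ""
    quals = aln.query_qualities
    chrom = aln.reference_name or ""

    pairs: list[AlignedBase] = []
    if fasta is not None and chrom:
        ref_seq = fasta.fetch(chrom, aln.reference_start, aln.reference_end).upper()
        for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
            ref = ref_seq[rpos - aln.reference_start]
            qual = quals[qpos] if quals is not None else None
            pairs.append((qpos, rpos, seq[qpos].upper(), ref, qual))
    else:
        for qpos, rpos, ref in aln.get_aligned_pairs(matches_only=True, with_seq=True):
            qual = quals[qpos] if quals is not None else None
            pairs.append((qpos, rpos, seq[qpos].upper(), (ref or "N").upper(), qual))

    return TaggedRead(
        cell_barcode=tag(cell_tag),
        umi=tag(umi_tag),
        gene=tag(gene_tag),
        mapq=aln.mapping_quality,
        aligned_pairs=pairs,
        gene_strand=gene_strand,
        chrom=chrom,
    )


# ---------------------------------------------------------------------------
# text I/O: consensus records, matrices, mask
# ---------------------------------------------------------------------------

RECORD_COLUMNS = ["cell", "gene", "umi", "n", "y", "read_support"]


def write_records(records: Iterable[ConsensusRecord], path: str | Path) -> None:
    """Write consensus records to a tab-separated file with a header line."""
    df = pd.DataFrame(
        [
            (r.cell_barcode, r.gene, r.umi, r.n, r.y, r.read_support)
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_records(path: str | Path) -> list[ConsensusRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"cell": str, "gene": str, "umi": str})
    return [
        ConsensusRecord(
            cell_barcode=row.cell, gene=row.gene, umi=row.umi,
            n=int(row.n), y=int(row.y), read_support=int(row.read_support),
        )
        for row in df.itertuples(index=False)
    ]


def write_matrices(matrices: LabelMatrices, out_dir: str | Path) -> None:
    """Write L/U/N as Matrix Market triplets (genes x cells) plus axis files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "L.mtx", matrices.L.T.tocoo())
    scipy.io.mmwrite(out / "U.mtx", matrices.U.T.tocoo())
    scipy.io.mmwrite(out / "N.mtx", matrices.N.T.tocoo())
    (out / "barcodes.tsv").write_text("".join(c + "\n" for c in matrices.cells))
    (out / "features.tsv").write_text("".join(g + "\n" for g in matrices.genes))


def read_matrices(in_dir: str | Path) -> LabelMatrices:
    d = Path(in_dir)
    cells = d.joinpath("barcodes.tsv").read_text().split()
    genes = d.joinpath("features.tsv").read_text().split()
    L = sp.csr_matrix(scipy.io.mmread(d / "L.mtx").T)
    U = sp.csr_matrix(scipy.io.mmread(d / "U.mtx").T)
    n_path = d / "N.mtx"
    if n_path.exists():
        N = sp.csr_matrix(scipy.io.mmread(n_path).T, dtype=np.float64)
    else:
        N = sp.csr_matrix(L.shape, dtype=np.float64)
    return LabelMatrices(cells=cells, genes=genes, L=L, U=U, N=N)


def write_mask(mask: BackgroundMask, path: str | Path) -> None:
    """Write the mask as a 3-column TSV: chrom, 0-based position, strand."""
    with open(path, "w") as fh:
        for chrom, pos, strand in sorted(mask.sites):
            fh.write(f"{chrom}\t{pos}\t{strand}\n")


def read_mask(path: str | Path) -> BackgroundMask:
    sites = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, pos, strand = line.rstrip("\n").split("\t")
            sites.add((chrom, int(pos), strand))
    return BackgroundMask(sites=sites)
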