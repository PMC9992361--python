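"""Shared builders for toy tagged reads."""

from __future__ import annotations

import pytest

from slamkit import TaggedRead


def make_read(
    ref: str,
    seq: str,
    quals=None,
    cell: str = "CELL1",
    gene: str = "GENE1",
    umi: str = "U1",
    mapq: int = 60,
    chrom: str = "chr1",
    strand: str = "+",
    start: int = 0,
) -> TaggedRead:
    """Build a TaggedRead from aligned reference/read strings.

    ``quals`` may be a single int applied to every base or a per-base list.
    """
    if quals is None:
        quals = 37
    if isinstance(quals, int):
        quals = [quals] * len(seq)
    assert len(ref) == len(seq) == len(quals)
    pairs = [(i, start + i, seq[i], ref[i], quals[i]) for i in range(len(seq))]
    return TaggedRead(
        cell_barcode=cell,
        umi=umi,
        gene=gene,
        mapq=mapq,
        aligned_pairs=pairs,
        gene_strand=strand,
        chrom=chrom,
    )


@pytest.fixture
def read_builder():
    return make_read
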