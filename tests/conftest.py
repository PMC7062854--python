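"""Shared fixtures: a hand-built two-exon gene, SAM writers, simulations."""

from __future__ import annotations

import numpy as np
import pytest

from spliceburden.annotation import GeneIndex, Transcript, build_gene_model
from spliceburden.counting import FragmentAlignment
from spliceburden.intervals import GenomicInterval

CHROM = "chrT"
CHROM_LEN = 100_000


def make_gene(
    gene_id: str,
    exons: list[tuple[int, int]],
    gene_span: tuple[int, int] | None = None,
    strand: str = "+",
    chrom: str = CHROM,
    transcripts: list[list[tuple[int, int]]] | None = None,
):
    """Build a GeneModel from raw exon coordinates."""
    chains = transcripts if transcripts is not None else [exons]
    txs = [
        Transcript(f"{gene_id}.t{i + 1}", [GenomicInterval(chrom, s, e, strand) for s, e in chain])
        for i, chain in enumerate(chains)
    ]
    feature = (
        GenomicInterval(chrom, gene_span[0], gene_span[1], strand)
        if gene_span
        else None
    )
    return build_gene_model(gene_id, "protein_coding", 2, txs, feature)


def make_fragment(
    blocks: list[tuple[int, int]],
    junctions: set[tuple[int, int]] | None = None,
    strand: str | None = None,
    chrom: str = CHROM,
    fragment_id: str = "frag",
) -> FragmentAlignment:
    return FragmentAlignment(
        fragment_id=fragment_id,
        chrom=chrom,
        blocks=sorted(blocks),
        junctions=junctions or set(),
        strand=strand,
    )


def blocks_to_cigar(blocks: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def write_sam(
    path,
    fragments: list[list[tuple[int, int]]],
    chrom: str = CHROM,
    chrom_len: int = CHROM_LEN,
    names: list[str] | None = None,
) -> str:
    """Write single-end SAM records, one per fragment block list."""
    lines = [f"@HD\tVN:1.6\tSO:unknown", f"@SQ\tSN:{chrom}\tLN:{chrom_len}"]
    for i, blocks in enumerate(fragments):
        blocks = sorted(blocks)
        name = names[i] if names else f"r{i}"
        seq_len = sum(e - s for s, e in blocks)
        lines.append(
            f"{name}\t0\t{chrom}\t{blocks[0][0] + 1}\t255\t{blocks_to_cigar(blocks)}"
            f"\t*\t0\t0\t{'A' * seq_len}\t{'#' * seq_len}"
        )
    path = str(path)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


@pytest.fixture
def f1_gene():
    """Fixture F1: exons [100,200) and [400,500), gene extent [100,1000)."""
    return make_gene("F1", [(100, 200), (400, 500)], gene_span=(100, 1000))


@pytest.fixture
def f1_index(f1_gene):
    return GeneIndex([f1_gene])


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
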