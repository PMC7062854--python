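"""Strict-containment fragment counting at the exon and gene level.

A fragment (read pair) is assigned to a gene only when every aligned block of
both mates lies entirely within the target feature set of exactly one
strand-compatible gene — the intersection-strict rule. Exonic counting tests
containment in the flattened exon union; genic counting tests containment in
the gene extent. The per-gene intronic count is the difference genic − exonic:
a conservative estimate of reads touching intronic sequence, because any
fragment that leaves the exon union while staying inside the gene is genic
but not exonic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import GeneIndex, GeneModel
from .design import SampleDesign

ASSIGNED = "assigned"
NO_FEATURE = "no_feature"
AMBIGUOUS = "ambiguous"
NOT_CONTAINED = "not_contained"

PROTOCOLS = ("unstranded", "forward", "reverse")


@dataclass
class FragmentAlignment:
    """One sequenced fragment: the union of both mates' aligned blocks."""

    fragment_id: str
    chrom: str
    blocks: list[tuple[int, int]]  # sorted, merged, half-open
    junctions: set[tuple[int, int]]  # (donor_end, acceptor_start) from N gaps
    sample_id: str = ""
    strand: str | None = None  # library-inferred fragment strand

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


def _merge_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    blocks.sort()
    merged = [list(blocks[0])]
    for s, e in blocks[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _read_junctions(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    juncs = []
    pos = read.reference_start
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8, 2):  # M/=/X/D consume reference
            pos += length
        elif op == 3:  # N
            juncs.append((pos, pos + length))
            pos += length
    return juncs


def fragment_from_reads(
    reads: Sequence[pysam.AlignedSegment],
    sample_id: str = "",
    protocol: str = "reverse",
) -> FragmentAlignment:
    """Build a FragmentAlignment from one or two mates of a pair."""
    blocks: list[tuple[int, int]] = []
    junctions: set[tuple[int, int]] = set()
    for r in reads:
        blocks.extend(r.get_blocks())
        junctions.update(_read_junctions(r))
    strand = _infer_strand(reads, protocol)
    return FragmentAlignment(
        fragment_id=reads[0].query_name,
        chrom=reads[0].reference_name,
        blocks=_merge_blocks(blocks),
        junctions=junctions,
        sample_id=sample_id,
        strand=strand,
    )


def _infer_strand(reads: Sequence[pysam.AlignedSegment], protocol: str) -> str | None:
    """Fragment strand under the library protocol.

    ``forward``: read 1 carries the transcript strand; ``reverse`` (dUTP):
    read 2 carries it. ``unstranded`` infers nothing.
    """
    if protocol == "unstranded":
        return None
    read = reads[0]
    is_read2 = read.is_paired and read.is_read2
    sense = "-" if read.is_reverse else "+"
    flip = (protocol == "reverse") != is_read2
    if flip:
        sense = "+" if sense == "-" else "-"
    return sense


def _candidates(
    fragment: FragmentAlignment, index: GeneIndex
) -> list[GeneModel]:
    start, end = fragment.span
    genes = index.overlapping_extent(fragment.chrom, start, end)
    if fragment.strand is not None:
        genes = [g for g in genes if g.strand in (fragment.strand, ".")]
    return genes


def _assign(
    fragment: FragmentAlignment, index: GeneIndex, layer: str
) -> tuple[str | None, str]:
    """Strict assignment on one layer ('exonic' or 'genic')."""
    cands = _candidates(fragment, index)
    if not cands:
        return None, NO_FEATURE
    containing = []
    for g in cands:
        iset = g.exon_set() if layer == "exonic" else g.extent_set()
        if all(iset.contains_block(s, e) for s, e in fragment.blocks):
            containing.append(g)
    if len(containing) == 1:
        return containing[0].gene_id, ASSIGNED
    if len(containing) > 1:
        return None, AMBIGUOUS
    return None, NOT_CONTAINED


def assign_exonic(fragment: FragmentAlignment, index: GeneIndex) -> tuple[str | None, str]:
    """Gene whose flattened exon union strictly contains every block, if unique."""
    return _assign(fragment, index, "exonic")


def assign_genic(fragment: FragmentAlignment, index: GeneIndex) -> tuple[str | None, str]:
    """Gene whose extent strictly contains every block, if unique."""
    return _assign(fragment, index, "genic")


@dataclass
class SampleCounts:
    sample_id: str
    exonic: dict[str, int]
    genic: dict[str, int]
    reasons: dict[str, dict[str, int]]  # layer -> reason code -> tally
    n_fragments: int = 0
    n_singletons: int = 0


def iter_fragments(
    alignments: Iterable[pysam.AlignedSegment],
    sample_id: str = "",
    protocol: str = "reverse",
) -> Iterable[tuple[FragmentAlignment, bool]]:
    """Pair mates by read name; yield (fragment, is_singleton).

    Secondary, supplementary and unmapped records are skipped; duplicates are
    kept. Unpaired leftovers are emitted as singletons at the end.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    for read in alignments:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if not read.is_paired:
            yield fragment_from_reads([read], sample_id, protocol), False
            continue
        mate = pending.pop(read.query_name, None)
        if mate is None:
            pending[read.query_name] = read
        else:
            yield fragment_from_reads([mate, read], sample_id, protocol), False
    for read in pending.values():
        yield fragment_from_reads([read], sample_id, protocol), True


def count_sample(
    alignments: str | Iterable[pysam.AlignedSegment],
    genes: Sequence[GeneModel],
    protocol: str = "reverse",
    sample_id: str = "",
    index: GeneIndex | None = None,
) -> SampleCounts:
    """Count exonic and genic fragments for one sample.

    ``alignments`` is a SAM path or an iterable of pysam records. Each
    fragment is counted at most once per layer.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"protocol must be one of {PROTOCOLS}")
    if index is None:
        index = GeneIndex(genes)
    exonic = {g.gene_id: 0 for g in genes}
    genic = {g.gene_id: 0 for g in genes}
    reasons = {
        "exonic": {NO_FEATURE: 0, AMBIGUOUS: 0, NOT_CONTAINED: 0},
        "genic": {NO_FEATURE: 0, AMBIGUOUS: 0, NOT_CONTAINED: 0},
    }
    handle: pysam.AlignmentFile | None = None
    if isinstance(alignments, str):
        handle = pysam.AlignmentFile(alignments, "r", check_sq=False)
        records: Iterable[pysam.AlignedSegment] = handle
    else:
        records = alignments
    n_fragments = 0
    n_singletons = 0
    try:
        for fragment, is_singleton in iter_fragments(records, sample_id, protocol):
            n_fragments += 1
            n_singletons += is_singleton
            gene, reason = assign_exonic(fragment, index)
            if gene is not None:
                exonic[gene] += 1
            else:
                reasons["exonic"][reason] += 1
            gene, reason = assign_genic(fragment, index)
            if gene is not None:
                genic[gene] += 1
            else:
                reasons["genic"][reason] += 1
    finally:
        if handle is not None:
            handle.close()
    return SampleCounts(
        sample_id=sample_id,
        exonic=exonic,
        genic=genic,
        reasons=reasons,
        n_fragments=n_fragments,
        n_singletons=n_singletons,
    )


@dataclass
class CountMatrix:
    """Genes × samples counts on the exonic, genic and intronic layers.

    ``intronic = genic - exonic``; entries where genic < exonic are kept as
    negative values but flagged, never clamped — the retention-stage gene
    filter acts on the flags.
    """

    genes: list[str]
    samples: list[str]
    exonic: np.ndarray
    genic: np.ndarray
    design: list[SampleDesign] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exonic = np.asarray(self.exonic, dtype=np.int64)
        self.genic = np.asarray(self.genic, dtype=np.int64)
        expected = (len(self.genes), len(self.samples))
        if self.exonic.shape != expected or self.genic.shape != expected:
            raise ValueError("count matrix shape mismatch with gene/sample labels")

    @property
    def intronic(self) -> np.ndarray:
        return self.genic - self.exonic

    @property
    def flagged(self) -> np.ndarray:
        """Boolean genes×samples mask where genic < exonic."""
        return self.genic < self.exonic

    def subset(self, keep: np.ndarray) -> "CountMatrix":
        genes = [g for g, k in zip(self.genes, keep) if k]
        return CountMatrix(genes, self.samples, self.exonic[keep], self.genic[keep], self.design)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for layer in ("exonic", "genic", "intronic"):
            df = pd.DataFrame(getattr(self, layer), index=self.genes, columns=self.samples)
            df["layer"] = layer
            frames.append(df.reset_index(names="gene_id"))
        return pd.concat(frames, ignore_index=True)


def build_count_matrix(
    per_sample: Sequence[SampleCounts], design: Sequence[SampleDesign] | None = None
) -> CountMatrix:
    """Align per-sample counts on a common (gene, sample) grid."""
    if not per_sample:
        return CountMatrix([], [], np.zeros((0, 0)), np.zeros((0, 0)), list(design or []))
    gene_sets = [set(sc.exonic) for sc in per_sample]
    if any(gs != gene_sets[0] for gs in gene_sets[1:]):
        raise ValueError("inconsistent gene sets across samples")
    genes = sorted(gene_sets[0])
    samples = [sc.sample_id for sc in per_sample]
    exonic = np.array([[sc.exonic[g] for sc in per_sample] for g in genes], dtype=np.int64)
    genic = np.array([[sc.genic[g] for sc in per_sample] for g in genes], dtype=np.int64)
    if design is not None:
        order = {s.sample_id: s for s in design}
        design = [order[s] for s in samples if s in order]
    return CountMatrix(genes, samples, exonic, genic, list(design or []))
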