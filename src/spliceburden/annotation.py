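"""Gene-model construction from GTF annotation.

Builds, per retained gene, the flattened exon union (the most comprehensive
exonic definition: every annotated exon of every transcript contributes),
the derived introns (complement of the union within the gene extent) and the
gene extent itself. Retention is restricted by biotype and annotation level;
the default mirrors a protein-coding, level 1-2 restriction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

from intervaltree import IntervalTree

from .intervals import GenomicInterval, IntervalSet, complement_within, merge_intervals

log = logging.getLogger(__name__)

# Gencode dialect: values are usually quoted, but e.g. `level 2;` is not
_ATTR_RE = re.compile(r'(\w+)\s+(?:"([^"]*)"|([^";\s]+))\s*;')


class GtfParseError(ValueError):
    pass


@dataclass
class Transcript:
    transcript_id: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def finalize(self) -> None:
        """Sort exons and check the single-chrom / non-overlap invariants."""
        self.exons.sort(key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.chrom != b.chrom:
                raise GtfParseError(
                    f"transcript {self.transcript_id} spans chromosomes "
                    f"{a.chrom} and {b.chrom}"
                )
            if b.start < a.end:
                raise GtfParseError(
                    f"transcript {self.transcript_id} has overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def span(self) -> GenomicInterval:
        first, last = self.exons[0], self.exons[-1]
        return GenomicInterval(first.chrom, first.start, last.end, first.strand)

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    biotype: str
    level: int | None
    transcripts: list[Transcript]
    exon_union: list[GenomicInterval]
    introns: list[GenomicInterval]
    extent: GenomicInterval

    # lazily built O(log n) containment helpers, used by the counters
    _exon_set: IntervalSet | None = None
    _extent_set: IntervalSet | None = None

    @property
    def chrom(self) -> str:
        return self.extent.chrom

    @property
    def strand(self) -> str:
        return self.extent.strand

    @property
    def exonic_length(self) -> int:
        return sum(len(iv) for iv in self.exon_union)

    @property
    def intronic_length(self) -> int:
        return sum(len(iv) for iv in self.introns)

    def exon_set(self) -> IntervalSet:
        if self._exon_set is None:
            self._exon_set = IntervalSet(self.exon_union)
        return self._exon_set

    def extent_set(self) -> IntervalSet:
        if self._extent_set is None:
            self._extent_set = IntervalSet([self.extent])
        return self._extent_set


def flatten_exons(transcripts: Sequence[Transcript]) -> list[GenomicInterval]:
    """Union of all exons of all transcripts, merged where overlapping or bookended."""
    exons = [e for t in transcripts for e in t.exons]
    return merge_intervals(exons)


def build_gene_model(
    gene_id: str,
    biotype: str,
    level: int | None,
    transcripts: list[Transcript],
    gene_feature: GenomicInterval | None = None,
    extent_from_gene_feature: bool = True,
) -> GeneModel:
    """Assemble the derived fields of a gene model.

    The extent comes from the annotated *gene* feature when present (and
    ``extent_from_gene_feature`` is set), else from the span of the exons.
    """
    for t in transcripts:
        t.finalize()
    exon_union = flatten_exons(transcripts)
    span = GenomicInterval(
        exon_union[0].chrom, exon_union[0].start, exon_union[-1].end, exon_union[0].strand
    )
    if gene_feature is not None and extent_from_gene_feature:
        extent = GenomicInterval(
            gene_feature.chrom,
            min(gene_feature.start, span.start),
            max(gene_feature.end, span.end),
            gene_feature.strand,
        )
    else:
        extent = span
    introns = complement_within(exon_union, extent)
    return GeneModel(gene_id, biotype, level, transcripts, exon_union, introns, extent)


def _parse_attributes(text: str) -> dict[str, str]:
    return {k: quoted or bare for k, quoted, bare in _ATTR_RE.findall(text)}


def iter_gtf_records(
    stream: Iterable[str],
) -> Iterator[tuple[int, str, str, int, int, str, dict[str, str]]]:
    """Yield (lineno, feature, chrom, start0, end, strand, attributes)."""
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"GTF line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
        try:
            start0 = int(start) - 1  # GTF is 1-based inclusive
            end0 = int(end)
        except ValueError as exc:
            raise GtfParseError(f"GTF line {lineno}: non-integer coordinates") from exc
        if start0 < 0 or end0 <= start0:
            raise GtfParseError(f"GTF line {lineno}: invalid interval {start}-{end}")
        yield lineno, feature, chrom, start0, end0, strand, _parse_attributes(attrs)


def read_gene_models(
    stream: Iterable[str] | IO[str],
    biotypes: set[str] | frozenset[str] = frozenset({"protein_coding"}),
    max_level: int | None = 2,
    extent_from_gene_feature: bool = True,
) -> list[GeneModel]:
    """Parse a Gencode-style GTF into gene models, applying the study filters.

    Only *gene* and *exon* features are consulted; other feature types are
    ignored. A gene is retained iff its ``gene_type`` is in ``biotypes`` and,
    when ``max_level`` is set, its ``level`` attribute is present and at most
    ``max_level`` (an absent level cannot be verified and is excluded).
    Genes with zero exons are dropped with a warning.
    """
    if not biotypes:
        raise ValueError("biotypes must be non-empty")
    gene_meta: dict[str, dict[str, str]] = {}
    gene_feature: dict[str, GenomicInterval] = {}
    gene_transcripts: dict[str, dict[str, Transcript]] = {}
    order: list[str] = []

    for lineno, feature, chrom, start, end, strand, attrs in iter_gtf_records(stream):
        if feature not in ("gene", "exon"):
            continue
        gene_id = attrs.get("gene_id")
        if not gene_id:
            raise GtfParseError(f"GTF line {lineno}: missing gene_id attribute")
        if gene_id not in gene_meta:
            gene_meta[gene_id] = attrs
            order.append(gene_id)
        if feature == "gene":
            gene_feature[gene_id] = GenomicInterval(chrom, start, end, strand)
            gene_meta[gene_id] = {**attrs, **gene_meta[gene_id]}
        else:
            tid = attrs.get("transcript_id")
            if not tid:
                raise GtfParseError(
                    f"GTF line {lineno}: exon record without transcript_id"
                )
            tx = gene_transcripts.setdefault(gene_id, {}).setdefault(
                tid, Transcript(tid)
            )
            tx.exons.append(GenomicInterval(chrom, start, end, strand))

    models: list[GeneModel] = []
    for gene_id in order:
        attrs = gene_meta[gene_id]
        biotype = attrs.get("gene_type", "")
        if biotype not in biotypes:
            continue
        level_str = attrs.get("level")
        level: int | None = None
        if level_str is not None:
            try:
                level = int(level_str)
            except ValueError:
                level = None
        if max_level is not None and (level is None or level > max_level):
            continue
        txs = list(gene_transcripts.get(gene_id, {}).values())
        if not any(t.exons for t in txs):
            log.warning("gene %s has no exons; excluded", gene_id)
            continue
        models.append(
            build_gene_model(
                gene_id,
                biotype,
                level,
                txs,
                gene_feature.get(gene_id),
                extent_from_gene_feature=extent_from_gene_feature,
            )
        )
    return models


class GeneIndex:
    """Interval index over gene extents, with per-gene exon containment tests."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for i, g in enumerate(self.genes):
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree.addi(g.extent.start, g.extent.end, i)

    def overlapping_extent(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [self.genes[hit.data] for hit in tree.overlap(start, end)]

    def overlapping_exons(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        query = GenomicInterval(chrom, start, end)
        return [
            g
            for g in self.overlapping_extent(chrom, start, end)
            if any(iv.overlaps(query) for iv in g.exon_union)
        ]


def build_gene_index(genes: Sequence[GeneModel]) -> GeneIndex:
    return GeneIndex(genes)
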