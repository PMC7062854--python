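"""Alternative-splicing event enumeration and inclusion-level (ψ) estimation.

Events of five categories — skipped exon (SE), retained intron (RI),
alternative 5′/3′ splice site (A5SS/A3SS) and mutually exclusive exons
(MXE) — are derived by pairwise comparison of annotated transcripts within a
gene. Inclusion and skipping forms are quantified from fragments overlapping
the defining junctions plus fragments whose blocks are unique to the
inclusion form ("junctions + reads on target"), and ψ is the
length-normalized inclusion fraction (I/lI) / (I/lI + S/lS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneModel, Transcript
from .counting import iter_fragments
from .intervals import GenomicInterval
from .design import SampleDesign, condition_label

log = logging.getLogger(__name__)

CATEGORIES = ("SE", "RI", "A5SS", "A3SS", "MXE")


@dataclass(frozen=True)
class SpliceEvent:
    event_id: str
    category: str
    gene_id: str
    chrom: str
    strand: str
    inclusion_junctions: frozenset[tuple[int, int]]
    skipping_junctions: frozenset[tuple[int, int]]
    inclusion_body: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category}")
        if self.inclusion_junctions & self.skipping_junctions:
            raise ValueError("inclusion and skipping junction sets must be disjoint")


def _junctions(tx: Transcript) -> set[tuple[int, int]]:
    return {
        (a.end, b.start) for a, b in zip(tx.exons, tx.exons[1:])
    }


def _covers_contiguously(tx: Transcript, start: int, end: int) -> bool:
    return any(e.start <= start and end <= e.end for e in tx.exons)


def _overlaps_any(tx: Transcript, start: int, end: int) -> bool:
    return any(e.start < end and start < e.end for e in tx.exons)


def enumerate_events(genes: Sequence[GeneModel]) -> list[SpliceEvent]:
    """Derive SE/RI/A5SS/A3SS/MXE events from transcript structures.

    Every unordered pair of transcripts within a gene is compared; duplicate
    events (same category and junction sets) are reported once.
    """
    events: dict[tuple, SpliceEvent] = {}
    for gene in genes:
        txs = gene.transcripts
        for i in range(len(txs)):
            for j in range(len(txs)):
                if i == j:
                    continue
                for ev in _compare_pair(gene, txs[i], txs[j]):
                    key = (ev.category, ev.inclusion_junctions, ev.skipping_junctions)
                    events.setdefault(key, ev)
    return sorted(events.values(), key=lambda e: e.event_id)


def _compare_pair(
    gene: GeneModel, inc: Transcript, skp: Transcript
) -> Iterable[SpliceEvent]:
    """Events where ``inc`` carries the inclusion form and ``skp`` the skipping form."""
    j_inc, j_skp = _junctions(inc), _junctions(skp)
    chrom, strand = gene.chrom, gene.strand

    # SE: exon bounded by two junctions in inc, bridged by one junction in skp
    for k, exon in enumerate(inc.exons[1:-1], start=1):
        left = (inc.exons[k - 1].end, exon.start)
        right = (exon.end, inc.exons[k + 1].start)
        bridge = (left[0], right[1])
        if bridge in j_skp and not _overlaps_any(skp, exon.start, exon.end):
            yield SpliceEvent(
                f"SE:{gene.gene_id}:{exon.start}-{exon.end}",
                "SE",
                gene.gene_id,
                chrom,
                strand,
                frozenset({left, right}),
                frozenset({bridge}),
                (exon,),
            )

    # RI: a junction of skp contiguously covered by an exon of inc
    for d, a in j_skp:
        if _covers_contiguously(inc, d, a):
            yield SpliceEvent(
                f"RI:{gene.gene_id}:{d}-{a}",
                "RI",
                gene.gene_id,
                chrom,
                strand,
                frozenset(),
                frozenset({(d, a)}),
                (GenomicInterval(chrom, d, a, strand),),
            )

    # A5SS / A3SS: junction pairs sharing one end; inclusion = shorter intron
    for d1, a1 in j_inc:
        for d2, a2 in j_skp:
            if (d1, a1) == (d2, a2):
                continue
            if a1 == a2 and d1 > d2:  # shared acceptor, inc has longer upstream exon
                cat = "A5SS" if strand != "-" else "A3SS"
                body = GenomicInterval(chrom, d2, d1, strand)
                # the extension must be contiguously exonic in the inclusion
                # form and absent from the skipping form
                if _overlaps_any(skp, d2, d1) or not _covers_contiguously(inc, d2, d1):
                    continue
                yield SpliceEvent(
                    f"{cat}:{gene.gene_id}:{d2}-{d1}@{a1}",
                    cat,
                    gene.gene_id,
                    chrom,
                    strand,
                    frozenset({(d1, a1)}),
                    frozenset({(d2, a2)}),
                    (body,),
                )
            elif d1 == d2 and a1 < a2:  # shared donor, inc has longer downstream exon
                cat = "A3SS" if strand != "-" else "A5SS"
                body = GenomicInterval(chrom, a1, a2, strand)
                if _overlaps_any(skp, a1, a2) or not _covers_contiguously(inc, a1, a2):
                    continue
                yield SpliceEvent(
                    f"{cat}:{gene.gene_id}:{a1}-{a2}@{d1}",
                    cat,
                    gene.gene_id,
                    chrom,
                    strand,
                    frozenset({(d1, a1)}),
                    frozenset({(d2, a2)}),
                    (body,),
                )

    # MXE: exclusive exon in each form, shared flanking donor/acceptor
    for k, e1 in enumerate(inc.exons[1:-1], start=1):
        up = inc.exons[k - 1].end
        down = inc.exons[k + 1].start
        for m, e2 in enumerate(skp.exons[1:-1], start=1):
            if e1.end <= e2.start or e2.end <= e1.start:
                if (
                    skp.exons[m - 1].end == up
                    and skp.exons[m + 1].start == down
                    and not _overlaps_any(skp, e1.start, e1.end)
                    and not _overlaps_any(inc, e2.start, e2.end)
                    and e1.start < e2.start  # leftmost exon defines inclusion
                ):
                    yield SpliceEvent(
                        f"MXE:{gene.gene_id}:{e1.start}-{e1.end}|{e2.start}-{e2.end}",
                        "MXE",
                        gene.gene_id,
                        chrom,
                        strand,
                        frozenset({(up, e1.start), (e1.end, down)}),
                        frozenset({(up, e2.start), (e2.end, down)}),
                        (e1,),
                    )


# ---------------------------------------------------------------------------
# support counting


@dataclass
class EventCounts:
    event_id: str
    sample_id: str
    inclusion: int = 0
    skipping: int = 0
    conflicted: int = 0  # fragments supporting both forms; discarded


def psi(I: int, S: int, lI: float, lS: float) -> float | None:
    """Length-normalized inclusion level; None when no supporting reads."""
    if I < 0 or S < 0:
        raise ValueError("counts must be non-negative")
    if lI < 1 or lS < 1:
        raise ValueError("effective lengths must be >= 1")
    if I + S == 0:
        return None
    ni = I / lI
    return ni / (ni + S / lS)


def count_event_support(
    alignments: str | Iterable[pysam.AlignedSegment],
    events: Sequence[SpliceEvent],
    sample_id: str = "",
) -> dict[str, EventCounts]:
    """Tally inclusion/skipping support per event for one sample.

    A fragment supports inclusion when any of its junctions equals an
    inclusion junction exactly or any aligned block lies entirely within an
    inclusion-body interval; it supports skipping when any junction equals a
    skipping junction. Fragments supporting both forms of an event are
    discarded and tallied as conflicted.
    """
    by_junction: dict[tuple[str, int, int], list[tuple[int, str]]] = {}
    bodies: dict[str, list[tuple[int, int, int]]] = {}
    counts = {ev.event_id: EventCounts(ev.event_id, sample_id) for ev in events}
    for idx, ev in enumerate(events):
        for j in ev.inclusion_junctions:
            by_junction.setdefault((ev.chrom, *j), []).append((idx, "I"))
        for j in ev.skipping_junctions:
            by_junction.setdefault((ev.chrom, *j), []).append((idx, "S"))
        for body in ev.inclusion_body:
            bodies.setdefault(ev.chrom, []).append((body.start, body.end, idx))
    for chrom in bodies:
        bodies[chrom].sort()

    handle: pysam.AlignmentFile | None = None
    if isinstance(alignments, str):
        handle = pysam.AlignmentFile(alignments, "r", check_sq=False)
        records: Iterable[pysam.AlignedSegment] = handle
    else:
        records = alignments
    try:
        for fragment, _single in iter_fragments(records, sample_id, "unstranded"):
            inc: set[int] = set()
            skp: set[int] = set()
            for j in fragment.junctions:
                for idx, role in by_junction.get((fragment.chrom, *j), ()):
                    (inc if role == "I" else skp).add(idx)
            chrom_bodies = bodies.get(fragment.chrom)
            if chrom_bodies:
                for bs, be, idx in chrom_bodies:
                    for s, e in fragment.blocks:
                        if bs <= s and e <= be:
                            inc.add(idx)
                            break
            for idx in inc | skp:
                ec = counts[events[idx].event_id]
                if idx in inc and idx in skp:
                    ec.conflicted += 1
                elif idx in inc:
                    ec.inclusion += 1
                else:
                    ec.skipping += 1
    finally:
        if handle is not None:
            handle.close()
    return counts


# ---------------------------------------------------------------------------
# effective lengths

JUNCTION_CONVENTION = {  # inclusion-specific / skipping-specific junction counts
    "SE": (2, 1),
    "RI": (1, 1),
    "A5SS": (1, 1),
    "A3SS": (1, 1),
    "MXE": (2, 2),
}


def _representative(gene: GeneModel, ev: SpliceEvent, form: str) -> Transcript:
    """A transcript carrying all defining junctions (and body) of one form."""
    want = ev.inclusion_junctions if form == "I" else ev.skipping_junctions
    for tx in gene.transcripts:
        j = _junctions(tx)
        if want <= j:
            if form == "I" and not all(
                _covers_contiguously(tx, b.start, b.end) for b in ev.inclusion_body
            ):
                continue
            return tx
    raise ValueError(f"no transcript carries the {form} form of {ev.event_id}")


def _placement_support(
    tx: Transcript, ev: SpliceEvent, read_length: int, fragment_length: int
) -> tuple[int, int]:
    """Count fragment placements on ``tx`` supporting inclusion / skipping.

    Exhaustive enumeration over all start positions at the nominal fragment
    length, applying the same support predicate as ``count_event_support``.
    """
    exons = [(e.start, e.end) for e in tx.exons]
    cum = [0]
    for s, e in exons:
        cum.append(cum[-1] + (e - s))
    M = cum[-1]
    F = min(fragment_length, M)
    F = max(F, read_length)
    juncs_tx = _junctions(tx)
    inc_j = ev.inclusion_junctions & juncs_tx
    skp_j = ev.skipping_junctions & juncs_tx
    body = [(b.start, b.end) for b in ev.inclusion_body]

    def mate_blocks(ms: int, me: int) -> list[tuple[int, int]]:
        out = []
        i = np.searchsorted(cum, ms, side="right") - 1
        pos = ms
        while pos < me:
            gs = exons[i][0] + (pos - cum[i])
            take = min(me, cum[i + 1]) - pos
            out.append((gs, gs + take))
            pos += take
            i += 1
        return out

    n_inc = n_skp = 0
    for s in range(0, M - F + 1):
        b1 = mate_blocks(s, s + read_length)
        b2 = mate_blocks(s + F - read_length, s + F)
        blocks = b1 + b2
        juncs = set()
        for mate in (b1, b2):
            for (s1, e1), (s2, e2) in zip(mate, mate[1:]):
                juncs.add((e1, s2))
        hit_inc = bool(juncs & inc_j) or any(
            bs <= s0 and e0 <= be for bs, be in body for s0, e0 in blocks
        )
        hit_skp = bool(juncs & skp_j)
        if hit_inc and not hit_skp:
            n_inc += 1
        elif hit_skp and not hit_inc:
            n_skp += 1
    return n_inc, n_skp


def effective_lengths(
    ev: SpliceEvent,
    gene: GeneModel | None = None,
    read_length: int = 73,
    fragment_length: int = 250,
    mode: str = "placement",
) -> tuple[float, float]:
    """Effective inclusion/skipping lengths (lI, lS) for ψ normalization.

    ``placement`` (default): exact enumeration of supporting fragment
    placements on representative transcripts of each form, expressed in units
    of one junction's worth of placements (2·(read_length−1) for a read pair).
    ``junction-count``: the fixed per-category junction counts, with the
    inclusion body contributing body_length/read_length.
    """
    if mode == "junction-count":
        lI, lS = JUNCTION_CONVENTION[ev.category]
        body_len = sum(b.end - b.start for b in ev.inclusion_body)
        if ev.category == "RI":
            lI = 1 + body_len / read_length
        return float(lI), float(lS)
    if mode != "placement":
        raise ValueError(f"unknown effective-length mode {mode!r}")
    if gene is None:
        raise ValueError("placement mode requires the gene model")
    tx_inc = _representative(gene, ev, "I")
    tx_skp = _representative(gene, ev, "S")
    a_inc, _ = _placement_support(tx_inc, ev, read_length, fragment_length)
    _, a_skp = _placement_support(tx_skp, ev, read_length, fragment_length)
    unit = 2 * (read_length - 1)
    return max(a_inc / unit, 1.0), max(a_skp / unit, 1.0)


# ---------------------------------------------------------------------------
# per-sample PSI and comparisons


def psi_table(
    counts_by_sample: dict[str, dict[str, EventCounts]],
    events: Sequence[SpliceEvent],
    genes: Sequence[GeneModel] | None = None,
    read_length: int = 73,
    fragment_length: int = 250,
    mode: str = "placement",
) -> pd.DataFrame:
    """Tidy per-event per-sample table of I, S counts and ψ."""
    gene_by_id = {g.gene_id: g for g in genes} if genes else {}
    lens = {}
    for ev in events:
        lens[ev.event_id] = effective_lengths(
            ev, gene_by_id.get(ev.gene_id), read_length, fragment_length, mode
        )
    rows = []
    for sample_id, counts in counts_by_sample.items():
        for ev in events:
            ec = counts[ev.event_id]
            lI, lS = lens[ev.event_id]
            rows.append(
                {
                    "event_id": ev.event_id,
                    "category": ev.category,
                    "gene_id": ev.gene_id,
                    "sample_id": sample_id,
                    "I": ec.inclusion,
                    "S": ec.skipping,
                    "conflicted": ec.conflicted,
                    "lI": lI,
                    "lS": lS,
                    "psi": psi(ec.inclusion, ec.skipping, lI, lS),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class EventComparison:
    event_id: str
    category: str
    mean_psi_a: float
    mean_psi_b: float
    delta_psi: float
    p: float
    q: float = np.nan
    significant: bool = False


def compare_events(
    psi_df: pd.DataFrame,
    design: Sequence[SampleDesign],
    condition_a: str,
    condition_b: str,
    alpha: float = 0.05,
    min_delta: float = 0.20,
) -> pd.DataFrame:
    """Two-condition event comparison with BH correction.

    ΔΨ is the difference of replicate-mean ψ (B − A); the p-value is a
    two-sided Fisher exact test on the condition-pooled inclusion/skipping
    counts. An event is significant when FDR q < ``alpha`` and
    |ΔΨ| ≥ ``min_delta``.
    """
    cond_of = {d.sample_id: condition_label(d) for d in design}
    df = psi_df.copy()
    df["condition"] = df["sample_id"].map(cond_of)
    df = df[df["condition"].isin([condition_a, condition_b])]
    rows = []
    for event_id, g in df.groupby("event_id", sort=True):
        a = g[g["condition"] == condition_a]
        b = g[g["condition"] == condition_b]
        psi_a = a["psi"].dropna()
        psi_b = b["psi"].dropna()
        if psi_a.empty or psi_b.empty:
            continue
        table = [
            [int(a["I"].sum()), int(a["S"].sum())],
            [int(b["I"].sum()), int(b["S"].sum())],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "event_id": event_id,
                "category": g["category"].iloc[0],
                "gene_id": g["gene_id"].iloc[0],
                "mean_psi_a": psi_a.mean(),
                "mean_psi_b": psi_b.mean(),
                "delta_psi": psi_b.mean() - psi_a.mean(),
                "p": p,
            }
        )
    if not rows:
        log.warning("no evaluable events for %s vs %s", condition_a, condition_b)
        return pd.DataFrame(
            columns=["event_id", "category", "gene_id", "mean_psi_a", "mean_psi_b",
                     "delta_psi", "p", "q", "significant"]
        )
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["q"] = q
    out["significant"] = (out["q"] < alpha) & (out["delta_psi"].abs() >= min_delta)
    return out


def category_summary(comparison: pd.DataFrame) -> pd.DataFrame:
    """Per-category 'total (lower:higher)' summary of a comparison."""
    rows = []
    for cat in CATEGORIES:
        sub = comparison[comparison["category"] == cat]
        sig = sub[sub["significant"]]
        rows.append(
            {
                "category": cat,
                "total": len(sub),
                "lower": int((sig["delta_psi"] < 0).sum()),
                "higher": int((sig["delta_psi"] > 0).sum()),
            }
        )
    return pd.DataFrame(rows)
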