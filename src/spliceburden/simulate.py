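"""Spliced paired-end read simulation with known ground truth.

Emulates the structure of a 2×2 (shRNA depletion × cisplatin) design with
three replicates per condition: protein-coding gene models on one synthetic
chromosome, negative-binomial expression, per-gene intron-retention
fractions and per-event inclusion levels, and N-gapped paired-end SAM
alignments (73-nt mates by default). Every latent quantity is recorded in a
truth table so downstream estimators can be checked against it.

The condition effect on retention is additive: depletion raises every
gene's retention fraction by ``retention_delta_depletion`` without drug and
by the larger ``retention_delta_depletion_cisplatin`` under cisplatin.

Three named gene presets reproduce candidate-gene topologies: ``sat1``
(7 exons, skippable exon 4 carrying a premature stop), ``nupr1`` (2 exons,
retainable intron 1) and ``noxa1`` (11 exons, retainable introns 9 and 10).
"""

from __future__ import annotations

import io
import os
import zlib
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .design import (
    CONDITIONS,
    SampleDesign,
    condition_label,
    default_design,
    samples_of,
    validate_design,
)

#: Cisplatin induction of NUPR1 expression: 5.6-fold in control cells,
#: collapsing to 1.5-fold under RNF113A depletion (candidate-gene presets).
NUPR1_CONTROL_CISPLATIN_FOLD = 5.6
NUPR1_DEPLETED_CISPLATIN_FOLD = 1.5

PRESETS = ("sat1", "nupr1", "noxa1")


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_genes: int = 200
    read_length: int = 73
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 30.0
    library_size: int = 200_000
    nb_dispersion: float = 0.05
    expression_sigma: float = 1.0  # lognormal sd of relative gene abundance
    retention_base: float = 0.05
    retention_delta_depletion: float = 0.05
    retention_delta_depletion_cisplatin: float = 0.10
    psi_base: float = 0.5
    event_fraction: float = 0.0  # fraction of background genes given an SE event
    include_presets: tuple[str, ...] = ()
    nested_pair: bool = False
    exon_count_range: tuple[int, int] = (2, 8)
    exon_length_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (200, 800)
    intergenic_gap_range: tuple[int, int] = (1000, 2000)
    chrom: str = "chrSim1"
    seed: int = 0
    retention_overrides: dict = field(default_factory=dict)  # (gene_id, condition) -> r
    psi_overrides: dict = field(default_factory=dict)  # (event_id, condition) -> psi
    expression_overrides: dict = field(default_factory=dict)  # (gene_id, condition) -> fold

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not (0 < self.read_length < self.fragment_length_mean):
            raise ConfigError("require 0 < read_length < fragment_length_mean")
        for name in ("retention_base", "psi_base", "event_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        for p in self.include_presets:
            if p not in PRESETS:
                raise ConfigError(f"unknown preset {p!r}; expected one of {PRESETS}")
        min_exonic = self.exon_count_range[0] * self.exon_length_range[0]
        if min_exonic < self.read_length:
            raise ConfigError("shortest possible isoform cannot fit a read")

    def retention(self, gene_id: str, condition: str) -> float:
        r = self.retention_overrides.get((gene_id, condition))
        if r is None:
            r = self.retention_base
            if condition == "D":
                r += self.retention_delta_depletion
            elif condition == "Dcis":
                r += self.retention_delta_depletion_cisplatin
        return float(np.clip(r, 0.0, 1.0))

    def psi(self, event_id: str, condition: str) -> float:
        return float(self.psi_overrides.get((event_id, condition), self.psi_base))


# ---------------------------------------------------------------------------
# isoform geometry


class Isoform:
    """Exon chain with mature→genomic coordinate mapping."""

    __slots__ = ("exons", "cum", "length")

    def __init__(self, exons: Sequence[tuple[int, int]]):
        self.exons = list(exons)
        cum = [0]
        for s, e in self.exons:
            cum.append(cum[-1] + (e - s))
        self.cum = cum
        self.length = cum[-1]

    def blocks(self, ms: int, me: int) -> list[tuple[int, int]]:
        """Genomic blocks covered by mature interval [ms, me)."""
        out = []
        i = bisect_right(self.cum, ms) - 1
        pos = ms
        while pos < me:
            gs = self.exons[i][0] + (pos - self.cum[i])
            take = min(me, self.cum[i + 1]) - pos
            out.append((gs, gs + take))
            pos += take
            i += 1
        return out


def _merge_intron(exons: list[tuple[int, int]], k: int) -> list[tuple[int, int]]:
    """Exon chain with intron k (between exons k and k+1) retained."""
    out = list(exons)
    out[k] = (out[k][0], out[k + 1][1])
    del out[k + 1]
    return out


@dataclass
class GeneBlueprint:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # canonical (fully spliced) chain
    # annotated transcripts: (transcript_id, exon chain)
    transcripts: list[tuple[str, list[tuple[int, int]]]] = field(default_factory=list)
    # events: (event_id, kind, [isoform index within `variants`])
    se_exon_index: int | None = None
    ri_intron_indices: list[int] = field(default_factory=list)
    annotate_retained: bool = True

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def event_ids(self) -> list[str]:
        ids = []
        if self.se_exon_index is not None:
            s, e = self.exons[self.se_exon_index]
            ids.append(f"SE:{self.gene_id}:{s}-{e}")
        for k in self.ri_intron_indices:
            d, a = self.exons[k][1], self.exons[k + 1][0]
            ids.append(f"RI:{self.gene_id}:{d}-{a}")
        return ids

    def flattened_introns(self) -> list[tuple[int, int]]:
        """Introns left after flattening all annotated transcripts."""
        if self.annotate_retained:
            spliced = set(self.ri_intron_indices)
        else:
            spliced = set()
        return [
            (self.exons[k][1], self.exons[k + 1][0])
            for k in range(len(self.exons) - 1)
            if k not in spliced
        ]


def _build_background_gene(
    gene_id: str, chrom: str, strand: str, start: int, rng: np.random.Generator,
    config: SimulationConfig, with_se: bool,
) -> GeneBlueprint:
    lo_n, hi_n = config.exon_count_range
    n_exons = int(rng.integers(max(lo_n, 3 if with_se else lo_n), hi_n + 1))
    exon_lens = rng.integers(*config.exon_length_range, size=n_exons, endpoint=True)
    intron_lens = rng.integers(*config.intron_length_range, size=n_exons - 1, endpoint=True)
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    bp = GeneBlueprint(gene_id, chrom, strand, exons)
    bp.transcripts.append((f"{gene_id}.t1", exons))
    if with_se:
        k = int(rng.integers(1, n_exons - 1))
        bp.se_exon_index = k
        bp.transcripts.append((f"{gene_id}.t2", exons[:k] + exons[k + 1 :]))
    return bp


def _build_preset(name: str, chrom: str, start: int) -> GeneBlueprint:
    if name == "sat1":
        # 7 exons; exon 4 (index 3) skippable
        exon_lens = [300, 300, 300, 100, 300, 300, 300]
        intron_len = 400
        exons, pos = [], start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el + (intron_len if i < 6 else 0)
        bp = GeneBlueprint("SAT1SIM", chrom, "+", exons, se_exon_index=3)
        bp.transcripts.append(("SAT1SIM.t1", exons))
        bp.transcripts.append(("SAT1SIM.t2", exons[:3] + exons[4:]))
        return bp
    if name == "nupr1":
        # 2 exons; retainable intron 1
        exons = [(start, start + 400), (start + 900, start + 1500)]
        bp = GeneBlueprint("NUPR1SIM", chrom, "+", exons, ri_intron_indices=[0])
        bp.transcripts.append(("NUPR1SIM.t1", exons))
        bp.transcripts.append(("NUPR1SIM.t2", _merge_intron(exons, 0)))
        return bp
    if name == "noxa1":
        # 11 exons; retainable introns 9 and 10 (indices 8 and 9)
        exons, pos = [], start
        for i in range(11):
            exons.append((pos, pos + 200))
            pos += 200 + (300 if i < 10 else 0)
        bp = GeneBlueprint("NOXA1SIM", chrom, "+", exons, ri_intron_indices=[8, 9])
        bp.transcripts.append(("NOXA1SIM.t1", exons))
        bp.transcripts.append(("NOXA1SIM.t2", _merge_intron(exons, 8)))
        bp.transcripts.append(("NOXA1SIM.t3", _merge_intron(exons, 9)))
        return bp
    raise ConfigError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# annotation


@dataclass
class SimulatedAnnotation:
    gtf: str
    genes: list  # list[GeneModel]
    events: list  # list[SpliceEvent]
    blueprints: list[GeneBlueprint]
    chrom: str
    chrom_length: int


def _gtf_lines(bp: GeneBlueprint, level: int = 2) -> list[str]:
    gs, ge = bp.span
    attrs = f'gene_id "{bp.gene_id}"; gene_type "protein_coding"; level {level};'
    lines = [
        f"{bp.chrom}\tsim\tgene\t{gs + 1}\t{ge}\t.\t{bp.strand}\t.\t{attrs}"
    ]
    for tid, exons in bp.transcripts:
        for s, e in exons:
            a = (
                f'gene_id "{bp.gene_id}"; transcript_id "{tid}"; '
                f'gene_type "protein_coding"; level {level};'
            )
            lines.append(f"{bp.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{bp.strand}\t.\t{a}")
    return lines


def simulate_annotation(config: SimulationConfig) -> SimulatedAnnotation:
    """Generate non-overlapping gene models (plus optional presets and an
    engineered nested pair), returning the GTF, parsed models and events."""
    from .annotation import read_gene_models
    from .events import enumerate_events

    rng = np.random.default_rng([config.seed, 17])
    blueprints: list[GeneBlueprint] = []
    pos = 10_000
    for name in config.include_presets:
        bp = _build_preset(name, config.chrom, pos)
        blueprints.append(bp)
        pos = bp.span[1] + int(rng.integers(*config.intergenic_gap_range, endpoint=True))
    n_background = config.n_genes - len(blueprints)
    for i in range(max(n_background, 0)):
        strand = "+" if rng.random() < 0.5 else "-"
        with_se = rng.random() < config.event_fraction
        bp = _build_background_gene(
            f"G{i + 1:05d}", config.chrom, strand, pos, rng, config, with_se
        )
        blueprints.append(bp)
        pos = bp.span[1] + int(rng.integers(*config.intergenic_gap_range, endpoint=True))
    if config.nested_pair:
        # outer gene with one long intron hosting a smaller same-strand gene
        outer_exons = [(pos, pos + 500), (pos + 5500, pos + 6000)]
        outer = GeneBlueprint("NESTOUTER", config.chrom, "+", outer_exons)
        outer.transcripts.append(("NESTOUTER.t1", outer_exons))
        inner_exons = [(pos + 1500, pos + 1900), (pos + 2600, pos + 3100)]
        inner = GeneBlueprint("NESTINNER", config.chrom, "+", inner_exons)
        inner.transcripts.append(("NESTINNER.t1", inner_exons))
        blueprints.extend([outer, inner])
        pos += 6000 + int(rng.integers(*config.intergenic_gap_range, endpoint=True))

    lines = []
    for bp in blueprints:
        lines.extend(_gtf_lines(bp))
    gtf = "\n".join(lines) + "\n"
    genes = read_gene_models(io.StringIO(gtf))
    events = enumerate_events(genes)
    return SimulatedAnnotation(gtf, genes, events, blueprints, config.chrom, pos + 10_000)


# ---------------------------------------------------------------------------
# alignments


@dataclass
class TruthTable:
    genes: pd.DataFrame  # gene_id, condition, mean_expression, retention
    events: pd.DataFrame  # event_id, condition, psi
    samples: pd.DataFrame  # sample_id, n_fragments


@dataclass
class SimulationResult:
    sam_paths: dict[str, str]
    truth: TruthTable


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode()) & 0x7FFFFFFF])


def _isoform_menu(
    bp: GeneBlueprint, config: SimulationConfig, condition: str, fragment_nominal: int
) -> tuple[list[Isoform], np.ndarray, list[Isoform]]:
    """Spliced-form isoforms with sampling weights, plus per-intron retained copies.

    Transcript fractions follow the event inclusion levels; sampling weights
    are fraction × number of fragment placements, so read support is
    proportional to abundance × insert capacity.
    """
    eids = bp.event_ids()
    forms: list[tuple[list[tuple[int, int]], float]] = []
    if bp.se_exon_index is not None:
        f = config.psi(eids[0], condition)
        k = bp.se_exon_index
        forms = [(bp.exons, f), (bp.exons[:k] + bp.exons[k + 1 :], 1.0 - f)]
    elif bp.ri_intron_indices:
        fracs = [config.psi(e, condition) for e in eids]
        spliced_frac = max(1.0 - sum(fracs), 0.0)
        forms = [(bp.exons, spliced_frac)]
        for k, f in zip(bp.ri_intron_indices, fracs):
            forms.append((_merge_intron(bp.exons, k), f))
    else:
        forms = [(bp.exons, 1.0)]
    isoforms = [Isoform(e) for e, _ in forms]
    weights = np.array(
        [
            frac * max(iso.length - fragment_nominal + 1, 1)
            for iso, (_, frac) in zip(isoforms, forms)
        ],
        dtype=float,
    )
    if weights.sum() <= 0:
        weights = np.ones(len(isoforms))
    weights /= weights.sum()
    retained = [Isoform(_merge_intron(bp.exons, k)) for k in range(len(bp.exons) - 1)]
    return isoforms, weights, retained


def _cigar(blocks: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def _write_fragment(
    out, qname: str, chrom: str, strand: str, iso: Isoform, s: int, frag_len: int,
    read_length: int, seq: str, qual: str,
) -> None:
    left = iso.blocks(s, s + read_length)
    right = iso.blocks(s + frag_len - read_length, s + frag_len)
    lpos, rpos = left[0][0] + 1, right[0][0] + 1
    tlen = right[-1][1] - left[0][0]
    lc, rc = _cigar(left), _cigar(right)
    if strand == "+":
        # dUTP library: read 2 carries the transcript strand (left, forward)
        lflag, rflag = 163, 83
    else:
        lflag, rflag = 99, 147
    out.write(
        f"{qname}\t{lflag}\t{chrom}\t{lpos}\t255\t{lc}\t=\t{rpos}\t{tlen}\t{seq}\t{qual}\n"
        f"{qname}\t{rflag}\t{chrom}\t{rpos}\t255\t{rc}\t=\t{lpos}\t{-tlen}\t{seq}\t{qual}\n"
    )


def simulate_alignments(
    annotation: SimulatedAnnotation,
    config: SimulationConfig,
    design: Sequence[SampleDesign] | None = None,
    out_dir: str = ".",
) -> SimulationResult:
    """Draw per-sample fragments and write one SAM file per sample.

    Per gene and sample, fragment counts are negative-binomial via the
    Poisson–Gamma construction; per fragment, an isoform is chosen (a
    retained-intron copy with the condition's retention probability, else an
    annotated form weighted by inclusion level × placement count), the
    fragment length is Normal(mean, sd) truncated to [read_length, isoform
    length], and the start is uniform over valid placements.
    """
    if design is None:
        design = default_design()
    design = list(design)
    validate_design(design)
    os.makedirs(out_dir, exist_ok=True)
    rng_expr = np.random.default_rng([config.seed, 29])
    bps = annotation.blueprints
    weights = rng_expr.lognormal(mean=0.0, sigma=config.expression_sigma, size=len(bps))
    rel = weights / weights.sum()

    frag_nominal = int(round(config.fragment_length_mean))
    L = config.read_length
    seq, qual = "A" * L, "#" * L

    gene_truth_rows = []
    event_truth_rows = []
    mu_by_condition: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        mult = np.array(
            [
                config.expression_overrides.get((bp.gene_id, cond), 1.0)
                for bp in bps
            ]
        )
        mu_by_condition[cond] = config.library_size * rel * mult
        for bp, mu in zip(bps, mu_by_condition[cond]):
            gene_truth_rows.append(
                {
                    "gene_id": bp.gene_id,
                    "condition": cond,
                    "mean_expression": mu,
                    "retention": config.retention(bp.gene_id, cond)
                    if bp.flattened_introns()
                    else 0.0,
                }
            )
            for eid in bp.event_ids():
                event_truth_rows.append(
                    {"event_id": eid, "condition": cond, "psi": config.psi(eid, cond)}
                )

    # per-gene menus are condition dependent; cache them
    menu_cache: dict[tuple[int, str], tuple] = {}

    sam_paths: dict[str, str] = {}
    sample_rows = []
    alpha = config.nb_dispersion
    for sample in design:
        cond = condition_label(sample)
        rng = _sample_rng(config.seed, sample.sample_id)
        mu = mu_by_condition[cond]
        if alpha > 0:
            lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
        else:
            lam = mu
        counts = rng.poisson(lam)
        path = os.path.join(out_dir, f"{sample.sample_id}.sam")
        sam_paths[sample.sample_id] = path
        n_total = 0
        with open(path, "w") as out:
            out.write("@HD\tVN:1.6\tSO:unknown\n")
            out.write(f"@SQ\tSN:{annotation.chrom}\tLN:{annotation.chrom_length}\n")
            for gi, bp in enumerate(bps):
                n = int(counts[gi])
                if n == 0:
                    continue
                key = (gi, cond)
                if key not in menu_cache:
                    menu_cache[key] = _isoform_menu(bp, config, cond, frag_nominal)
                isoforms, w, retained_isos = menu_cache[key]
                introns = bp.flattened_introns()
                r = config.retention(bp.gene_id, cond) if introns else 0.0
                retained_mask = rng.random(n) < r
                iso_idx = rng.choice(len(isoforms), size=n, p=w)
                intron_idx = (
                    rng.integers(0, len(introns), size=n) if introns else np.zeros(n, int)
                )
                frag_lens = rng.normal(
                    config.fragment_length_mean, config.fragment_length_sd, size=n
                )
                starts_u = rng.random(n)
                # map flattened-intron index to canonical intron index
                if introns:
                    canon = [
                        k
                        for k in range(len(bp.exons) - 1)
                        if (bp.exons[k][1], bp.exons[k + 1][0]) in set(introns)
                    ]
                for i in range(n):
                    if retained_mask[i]:
                        iso = retained_isos[canon[intron_idx[i]]]
                    else:
                        iso = isoforms[iso_idx[i]]
                    F = int(round(frag_lens[i]))
                    F = max(L, min(F, iso.length))
                    s = int(starts_u[i] * (iso.length - F + 1))
                    n_total += 1
                    _write_fragment(
                        out,
                        f"{sample.sample_id}.{bp.gene_id}.{i}",
                        bp.chrom,
                        bp.strand,
                        iso,
                        s,
                        F,
                        L,
                        seq,
                        qual,
                    )
        sample_rows.append({"sample_id": sample.sample_id, "n_fragments": n_total})

    truth = TruthTable(
        genes=pd.DataFrame(gene_truth_rows),
        events=pd.DataFrame(event_truth_rows),
        samples=pd.DataFrame(sample_rows),
    )
    return SimulationResult(sam_paths=sam_paths, truth=truth)


# ---------------------------------------------------------------------------
# count-level simulation (for normalization / fold-change recovery)


def simulate_count_matrix(
    design: Sequence[SampleDesign],
    n_background: int = 1000,
    target_gene: str = "TARGET",
    target_base_mean: float = 500.0,
    condition_fold: dict[str, float] | None = None,
    background_log_mean: float = 4.0,
    background_sigma: float = 1.0,
    dispersion: float = 0.05,
    library_variation: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene × sample NB count matrix with a fold-perturbed target gene.

    Background genes have condition-constant lognormal means; the target
    gene's mean is multiplied by ``condition_fold[condition]``. Per-sample
    depth varies uniformly within ±``library_variation``; median-of-ratios
    size factors should recover it.
    """
    validate_design(list(design))
    rng = np.random.default_rng(seed)
    condition_fold = condition_fold or {}
    base = rng.lognormal(mean=background_log_mean, sigma=background_sigma, size=n_background)
    genes = [target_gene] + [f"BG{i + 1:05d}" for i in range(n_background)]
    cols = {}
    for sample in design:
        cond = condition_label(sample)
        depth = rng.uniform(1.0 - library_variation, 1.0 + library_variation)
        mu = np.concatenate(
            [[target_base_mean * condition_fold.get(cond, 1.0)], base]
        ) * depth
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        else:
            lam = mu
        cols[sample.sample_id] = rng.poisson(lam)
    return pd.DataFrame(cols, index=genes)


def simulate_nupr1_counts(
    seed: int = 0,
    n_background: int = 1000,
    control_fold: float = NUPR1_CONTROL_CISPLATIN_FOLD,
    depleted_fold: float = NUPR1_DEPLETED_CISPLATIN_FOLD,
    **kwargs,
) -> tuple[pd.DataFrame, list[SampleDesign]]:
    """NB counts for the NUPR1 candidate-gene scenario over the full design.

    The cisplatin induction of the target is ``control_fold`` in control
    cells and ``depleted_fold`` in depleted cells; the interaction ratio is
    therefore depleted_fold / control_fold.
    """
    design = default_design()
    counts = simulate_count_matrix(
        design,
        n_background=n_background,
        target_gene="NUPR1SIM",
        condition_fold={"C": 1.0, "Ccis": control_fold, "D": 1.0, "Dcis": depleted_fold},
        seed=seed,
        **kwargs,
    )
    return counts, design
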