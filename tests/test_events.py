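"""Event enumeration, support counting, ψ estimation and comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from spliceburden.design import default_design
from spliceburden.events import (
    category_summary,
    compare_events,
    count_event_support,
    enumerate_events,
    psi,
    psi_table,
)
from spliceburden.simulate import (
    SimulationConfig,
    simulate_alignments,
    simulate_annotation,
)

from conftest import make_gene, write_sam


class TestEnumerateEvents:
    def test_sat1_preset_yields_single_se(self):
        ann = simulate_annotation(
            SimulationConfig(n_genes=3, include_presets=("sat1",))
        )
        evs = [e for e in ann.events if e.gene_id == "SAT1SIM"]
        assert len(evs) == 1 and evs[0].category == "SE"
        # skipped exon is exon 4 of seven
        sat = next(g for g in ann.genes if g.gene_id == "SAT1SIM")
        exon4 = sat.exon_union[3]
        assert evs[0].inclusion_body[0].start == exon4.start

    def test_nupr1_preset_yields_single_ri(self):
        ann = simulate_annotation(
            SimulationConfig(n_genes=3, include_presets=("nupr1",))
        )
        evs = [e for e in ann.events if e.gene_id == "NUPR1SIM"]
        assert [e.category for e in evs] == ["RI"]

    def test_noxa1_preset_yields_two_ri(self):
        ann = simulate_annotation(
            SimulationConfig(n_genes=3, include_presets=("noxa1",))
        )
        evs = [e for e in ann.events if e.gene_id == "NOXA1SIM"]
        assert [e.category for e in evs] == ["RI", "RI"]

    def test_single_transcript_gene_has_no_events(self):
        g = make_gene("solo", [(100, 200), (400, 500)])
        assert enumerate_events([g]) == []

    def test_a5ss_and_a3ss(self):
        # two transcripts differing at the donor side of one junction ('+')
        g = make_gene(
            "alt5",
            [(0, 100), (300, 400)],
            transcripts=[[(0, 100), (300, 400)], [(0, 150), (300, 400)]],
        )
        evs = enumerate_events([g])
        assert [e.category for e in evs] == ["A5SS"]
        assert evs[0].inclusion_junctions == frozenset({(150, 300)})
        assert evs[0].skipping_junctions == frozenset({(100, 300)})
        # acceptor-side difference
        g3 = make_gene(
            "alt3",
            [(0, 100), (300, 400)],
            transcripts=[[(0, 100), (300, 400)], [(0, 100), (250, 400)]],
        )
        evs3 = enumerate_events([g3])
        assert [e.category for e in evs3] == ["A3SS"]

    def test_mxe(self):
        t1 = [(0, 100), (200, 300), (600, 700)]
        t2 = [(0, 100), (400, 500), (600, 700)]
        g = make_gene("mxe", [(0, 100), (600, 700)], transcripts=[t1, t2])
        evs = enumerate_events([g])
        assert [e.category for e in evs] == ["MXE"]
        assert evs[0].inclusion_junctions == frozenset({(100, 200), (300, 600)})
        assert evs[0].skipping_junctions == frozenset({(100, 400), (500, 600)})

    def test_duplicate_events_deduplicated(self):
        # three transcripts where two pairs imply the same SE event
        full = [(0, 100), (200, 300), (500, 600), (800, 900)]
        skip = [(0, 100), (500, 600), (800, 900)]
        skip2 = [(0, 100), (500, 600), (800, 950)]
        g = make_gene("dup", full, transcripts=[full, skip, skip2])
        ses = [e for e in enumerate_events([g]) if e.category == "SE"]
        assert len(ses) == 1


class TestPsi:
    def test_boundary_values(self):
        assert psi(0, 10, 1, 1) == 0.0
        assert psi(10, 0, 1, 1) == 1.0
        assert psi(0, 0, 1, 1) is None

    def test_length_normalization(self):
        assert psi(30, 10, 2, 1) == pytest.approx(15 / 25)

    def test_scale_invariance_and_monotonicity(self):
        base = psi(30, 10, 2, 1)
        assert psi(300, 100, 2, 1) == pytest.approx(base)
        assert psi(31, 10, 2, 1) > base

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            psi(-1, 5, 1, 1)


class TestCountEventSupport:
    def _sat1(self):
        ann = simulate_annotation(
            SimulationConfig(n_genes=3, include_presets=("sat1",))
        )
        ev = next(e for e in ann.events if e.category == "SE")
        sat = next(g for g in ann.genes if g.gene_id == "SAT1SIM")
        return ann, ev, sat

    def test_junction_reads_counted_per_form(self, tmp_path):
        ann, ev, sat = self._sat1()
        [left, right] = sorted(ev.inclusion_junctions)
        [bridge] = ev.skipping_junctions
        frags = [
            [(left[0] - 20, left[0]), (left[1], left[1] + 20)],  # inclusion
            [(right[0] - 20, right[0]), (right[1], right[1] + 20)],  # inclusion
            [(bridge[0] - 20, bridge[0]), (bridge[1], bridge[1] + 20)],  # skipping
            [(sat.exon_union[0].start, sat.exon_union[0].start + 40)],  # neither
        ]
        sam = write_sam(tmp_path / "ev.sam", frags, chrom=sat.chrom,
                        chrom_len=10**6)
        counts = count_event_support(sam, ann.events, "s1")
        ec = counts[ev.event_id]
        assert (ec.inclusion, ec.skipping, ec.conflicted) == (2, 1, 0)

    def test_body_read_supports_inclusion(self, tmp_path):
        ann, ev, sat = self._sat1()
        body = ev.inclusion_body[0]
        sam = write_sam(
            tmp_path / "body.sam", [[(body.start + 5, body.start + 60)]],
            chrom=sat.chrom, chrom_len=10**6,
        )
        ec = count_event_support(sam, ann.events, "s1")[ev.event_id]
        assert ec.inclusion == 1 and ec.skipping == 0

    def test_conflicting_fragment_discarded_and_tallied(self, tmp_path):
        ann, ev, sat = self._sat1()
        [left, _] = sorted(ev.inclusion_junctions)
        [bridge] = ev.skipping_junctions
        # discordant mates: mate 1 spans an inclusion junction, mate 2 the
        # skipping junction of the same event
        gap1 = left[1] - left[0]
        gap2 = bridge[1] - bridge[0]
        lines = [
            "@HD\tVN:1.6",
            f"@SQ\tSN:{sat.chrom}\tLN:1000000",
            (
                f"x\t65\t{sat.chrom}\t{left[0] - 20 + 1}\t255\t20M{gap1}N20M"
                f"\t=\t{bridge[0] - 20 + 1}\t0\t{'A' * 40}\t{'#' * 40}"
            ),
            (
                f"x\t129\t{sat.chrom}\t{bridge[0] - 20 + 1}\t255\t20M{gap2}N20M"
                f"\t=\t{left[0] - 20 + 1}\t0\t{'A' * 40}\t{'#' * 40}"
            ),
        ]
        sam = tmp_path / "conf.sam"
        sam.write_text("\n".join(lines) + "\n")
        ec = count_event_support(str(sam), ann.events, "s1")[ev.event_id]
        assert (ec.inclusion, ec.skipping, ec.conflicted) == (0, 0, 1)


@pytest.mark.parametrize("psi_true", [0.0, 0.25, 0.5, 0.75, 1.0])
def test_psi_recovery_across_grid(tmp_path, psi_true):
    """Estimated ψ is within 0.03 of truth at ~50k fragments on the skipped
    exon preset (length-normalized placement mode)."""
    cfg = SimulationConfig(
        n_genes=3, include_presets=("sat1",), library_size=150_000,
        expression_sigma=0.0, seed=31,
        retention_base=0.0, retention_delta_depletion=0.0,
        retention_delta_depletion_cisplatin=0.0,
        psi_base=psi_true,
    )
    ann = simulate_annotation(cfg)
    design = default_design()[:1]
    res = simulate_alignments(ann, cfg, design, str(tmp_path))
    counts = {
        design[0].sample_id: count_event_support(
            res.sam_paths[design[0].sample_id], ann.events, design[0].sample_id
        )
    }
    df = psi_table(counts, ann.events, ann.genes)
    est = df.loc[df["category"] == "SE", "psi"].iloc[0]
    if psi_true in (0.0, 1.0):
        # no reads support the absent form at all
        assert est == psi_true
    else:
        assert est == pytest.approx(psi_true, abs=0.03)


class TestCompareEvents:
    def _psi_df(self, rows):
        return pd.DataFrame(
            rows,
            columns=["event_id", "category", "gene_id", "sample_id", "I", "S",
                     "conflicted", "lI", "lS", "psi"],
        )

    def _design(self):
        return default_design()

    def test_identical_tables_not_significant(self):
        rows = []
        for s in ("Ccis_1", "Dcis_1"):
            rows.append(["e1", "SE", "g", s, 10, 10, 0, 1, 1, 0.5])
        out = compare_events(self._psi_df(rows), self._design(), "Ccis", "Dcis")
        assert out.loc[0, "delta_psi"] == 0
        assert out.loc[0, "p"] == pytest.approx(1.0)
        assert not out.loc[0, "significant"]

    def test_extreme_flip_matches_hypergeometric_enumeration(self):
        """Pooled (I=10,S=0) vs (I=0,S=10): the two-sided Fisher p equals the
        exhaustively enumerated hypergeometric tail, ~1.1e-5."""
        rows = [
            ["e1", "SE", "g", "Ccis_1", 10, 0, 0, 1, 1, 1.0],
            ["e1", "SE", "g", "Dcis_1", 0, 10, 0, 1, 1, 0.0],
        ]
        out = compare_events(self._psi_df(rows), self._design(), "Ccis", "Dcis")
        assert out.loc[0, "delta_psi"] == pytest.approx(-1.0)
        # enumeration over all 2x2 tables with the same margins
        margins_p = [
            stats.hypergeom.pmf(k, 20, 10, 10) for k in range(11)
        ]
        p_obs = stats.hypergeom.pmf(10, 20, 10, 10)
        p_exact = sum(p for p in margins_p if p <= p_obs * (1 + 1e-9))
        assert out.loc[0, "p"] == pytest.approx(p_exact, rel=1e-6)
        assert out.loc[0, "p"] == pytest.approx(1.1e-5, rel=0.05)

    def test_shifted_events_detected_with_bh_control(self, rng):
        """200 events, 20 truly shifted 0.5→0.1 at deep coverage: at least 18
        are flagged and false positives stay near the BH expectation."""
        rows = []
        design = self._design()
        depth = 400
        for i in range(200):
            shifted = i < 20
            for d in design:
                cond = d.sample_id.split("_")[0]
                p_true = {"Ccis": 0.5, "Dcis": 0.1 if shifted else 0.5}.get(cond, 0.5)
                I = rng.binomial(depth, p_true)
                rows.append(
                    [f"e{i:03d}", "SE", f"g{i}", d.sample_id, I, depth - I, 0,
                     1, 1, I / depth]
                )
        out = compare_events(self._psi_df(rows), design, "Ccis", "Dcis")
        sig = out[out["significant"]]
        true_ids = {f"e{i:03d}" for i in range(20)}
        assert len(true_ids & set(sig["event_id"])) >= 18
        assert len(set(sig["event_id"]) - true_ids) <= 2

    def test_category_summary_shape(self, rng):
        rows = [
            ["e1", "SE", "g", "Ccis_1", 50, 50, 0, 1, 1, 0.5],
            ["e1", "SE", "g", "Dcis_1", 5, 95, 0, 1, 1, 0.05],
            ["e2", "RI", "g", "Ccis_1", 5, 95, 0, 1, 1, 0.05],
            ["e2", "RI", "g", "Dcis_1", 50, 50, 0, 1, 1, 0.5],
        ]
        out = compare_events(self._psi_df(rows), self._design(), "Ccis", "Dcis")
        summary = category_summary(out).set_index("category")
        assert list(summary.columns) == ["total", "lower", "higher"]
        assert summary.loc["SE", "total"] == 1
        assert summary.loc["SE", "lower"] == int(out.set_index("event_id").loc["e1", "significant"])
        assert summary.loc["RI", "higher"] == int(out.set_index("event_id").loc["e2", "significant"])

    def test_empty_input_warns_and_returns_empty(self):
        out = compare_events(self._psi_df([]), self._design(), "Ccis", "Dcis")
        assert out.empty


def test_bh_matches_brute_force_step_up(rng):
    """BH q-values agree with a direct step-up computation on random p-vectors."""
    for _ in range(20):
        p = rng.uniform(size=int(rng.integers(1, 60)))
        _, q, _, _ = multipletests(p, method="fdr_bh")
        # brute force: q_i = min over j with p_j >= p_i of m*p_j/rank_j
        m = len(p)
        order = np.argsort(p)
        q_ref = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, m * p[i] / rank)
            q_ref[i] = prev
        assert np.allclose(q, q_ref)
        # step-up decision rule: reject 1..k where k = max rank with
        # p_(rank) <= alpha*rank/m
        for alpha in (0.01, 0.05, 0.2):
            ks = [r for r in range(1, m + 1) if p[order[r - 1]] <= alpha * r / m]
            n_reject = max(ks) if ks else 0
            assert int((q <= alpha).sum()) == n_reject
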