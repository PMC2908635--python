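import math

import numpy as np
import pytest

import _oracles
from conftest import make_gene, random_seq
from probesieve.genome_io import ProbeRecord
from probesieve.scoring import (
    ScoreCard,
    classify_intron_relation,
    hairpin_delta_g,
    intron_class_score,
    rescore_after_reannotation,
    score_chi,
    score_fold,
    score_position,
    select_round1,
    select_round2,
    total_score,
)


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestCriterionBands:
    @pytest.mark.parametrize("chi,expected", [
        (0, 0), (60, 0), (60.5, 1), (72, 1), (84.9, 1), (85, 4), (90, 4), (100, 4),
    ])
    def test_chi_bands(self, chi, expected):
        assert score_chi(chi) == expected

    def test_chi_out_of_range(self):
        with pytest.raises(ValueError):
            score_chi(101)

    @pytest.mark.parametrize("dg,expected", [(-7.9, 0), (-8.0, 1), (-20, 1), (5, 0)])
    def test_fold_bands(self, dg, expected):
        assert score_fold(dg) == expected

    @pytest.mark.parametrize("d,expected", [
        (1, 0), (300, 0), (500, 0), (501, 1), (800, 1), (1000, 1), (1001, 4), (1200, 4),
    ])
    def test_position_bands(self, d, expected):
        assert score_position(d) == expected

    def test_band_monotonicity(self):
        """Worse inputs never improve a criterion score."""
        chis = np.linspace(0, 100, 201)
        assert all(score_chi(a) <= score_chi(b) for a, b in zip(chis, chis[1:]))
        dists = range(1, 1500, 7)
        assert all(score_position(a) <= score_position(b)
                   for a, b in zip(dists, list(dists)[1:]))
        dgs = np.linspace(-30, 5, 100)
        assert all(score_fold(a) >= score_fold(b) for a, b in zip(dgs, dgs[1:]))


class TestHairpin:
    def test_homopolymer_cannot_fold(self):
        dg = hairpin_delta_g("A" * 60)
        assert dg > 0
        assert score_fold(dg) == 0

    def test_strong_stem_folds_below_cutoff(self):
        rng = np.random.default_rng(20)
        stem = "GCGGCCGCGGCGCAT"  # 15-mer, GC-rich
        probe = random_seq(rng, 20) + stem + "AAAA" + _revcomp(stem) + random_seq(rng, 6)
        dg = hairpin_delta_g(probe)
        assert dg <= -8.0
        assert score_fold(dg) == 1
        # the fast search agrees with exhaustive structure enumeration
        assert dg == pytest.approx(_oracles.enumerate_hairpin_mfe(probe), abs=1e-9)

    def test_matches_enumeration_on_random_30mers(self):
        """MFE equals the exhaustive oracle on a batch of random sequences."""
        rng = np.random.default_rng(21)
        for _ in range(40):
            seq = random_seq(rng, 30)
            fast = hairpin_delta_g(seq)
            slow = _oracles.enumerate_hairpin_mfe(seq)
            if math.isinf(slow):
                assert math.isinf(fast)
            else:
                assert fast == pytest.approx(slow, abs=1e-9)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            hairpin_delta_g("ACGTN" * 8)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            hairpin_delta_g("ACGTACG")


class TestIntronClass:
    def _gene_with_intron(self, seed=22, left=300, intron=120, right=300):
        rng = np.random.default_rng(seed)
        parts = [("exon", random_seq(rng, left)), ("intron", random_seq(rng, intron)),
                 ("exon", random_seq(rng, right))]
        gene, contig = make_gene(parts, contig_pad=0)
        return gene, contig

    def test_exonic_probe_is_class1(self):
        gene, _ = self._gene_with_intron()
        probe = ProbeRecord("p", "gene1", 100, gene.spliced[99:159])
        assert classify_intron_relation(probe, gene) == 1
        assert intron_class_score(1) == 0

    def test_footprint_into_intron_is_class3(self):
        """A probe whose genomic footprint includes base x+1 overlaps the intron."""
        gene, _ = self._gene_with_intron()
        (intron,) = gene.introns
        # 30 exon bases + 30 intron bases, taken from the unspliced strand
        g0 = gene.span[0]
        start_unspliced = intron.x - 30 - (g0 - 1)
        seq = gene.unspliced[start_unspliced : start_unspliced + 60]
        probe = ProbeRecord("p", "gene1", intron.x - 29, seq)
        assert classify_intron_relation(probe, gene) == 3
        assert intron_class_score(3) == 4

    def test_probe_starting_at_y_is_class2(self):
        gene, _ = self._gene_with_intron()
        (intron,) = gene.introns
        cds_start = 301  # first base of exon 2 == y in CDS coordinates
        probe = ProbeRecord("p", "gene1", cds_start, gene.spliced[300:360])
        assert gene.cds_to_coding(cds_start) == intron.y
        assert classify_intron_relation(probe, gene) == 2
        assert intron_class_score(2) == 1

    def test_adjacency_window_boundary(self):
        gene, _ = self._gene_with_intron()
        for offset, expected in [(0, 2), (9, 2), (10, 1)]:
            start = 301 + offset
            probe = ProbeRecord("p", "gene1", start, gene.spliced[start - 1 : start + 59])
            assert classify_intron_relation(probe, gene, adjacency_window=10) == expected

    def test_unmapped_probe_is_error(self):
        gene, _ = self._gene_with_intron()
        probe = ProbeRecord("p", "gene1", 10, "A" * 60)
        with pytest.raises(ValueError, match="matches neither"):
            classify_intron_relation(probe, gene)


def card(pid, cds="cds1", chi=0, fold=0, pos=0, intron=0, match=0, d3=200,
         chi_pct=0.0, klass=1, est_ok=True):
    return ScoreCard(
        probe_id=pid, cds_id=cds, chi_percent=chi_pct, chi_score=chi,
        delta_g=math.inf, fold_score=fold, distance_3p=d3, pos_score=pos,
        intron_class=klass, intron_score=intron, match_score=match, est_ok=est_ok,
    )


class TestTotals:
    @pytest.mark.parametrize("scores,expected", [
        ((0, 0, 0, 0, 0), 0), ((1, 1, 1, 1, 0), 4), ((0, 0, 0, 0, 20), 20),
    ])
    def test_final_is_sum(self, scores, expected):
        chi, fold, pos, intron, match = scores
        c = card("p", chi=chi, fold=fold, pos=pos, intron=intron, match=match)
        assert total_score(c) == c.final_score == expected


class TestRound1:
    def test_admits_scores_below_four(self):
        cards = [card(f"p{i}", chi=min(i, 4), fold=max(0, i - 4), d3=150 + 10 * i)
                 for i in range(6)]
        for i, c in enumerate(cards):  # final scores 0..5
            assert c.final_score == i
        out = select_round1(cards)
        assert sorted(out.round1_panel) == ["p0", "p1", "p2", "p3"]

    def test_keeps_four_closest_to_3prime(self):
        cards = [card(f"p{d}", d3=d) for d in (150, 200, 250, 300, 350, 400)]
        out = select_round1(cards)
        assert out.round1_panel == ["p150", "p200", "p250", "p300"]

    def test_excludes_last_100_nt(self):
        out = select_round1([card("p", d3=90)])
        assert out.round1_panel == []
        assert "last 100" in out.exclusions["p"]

    def test_panel_ordered_by_distance_with_total_tiebreak(self):
        cards = [card("b", d3=200), card("a", d3=200), card("c", d3=150)]
        out = select_round1(cards)
        assert out.round1_panel == ["c", "a", "b"]

    def test_mixed_cds_rejected(self):
        with pytest.raises(ValueError, match="one CDS"):
            select_round1([card("p1", cds="x"), card("p2", cds="y")])


class TestRound2:
    def test_est_confirmed_intron_probe_recovered(self):
        r1 = select_round1([card("p1", d3=150)])
        probe = card("p2", chi=1, pos=1, intron=4, d3=1200, chi_pct=80.0,
                     klass=3, est_ok=True)
        assert probe.final_score == 6
        out = select_round2([card("p1", d3=150), probe], r1)
        assert out.round2_additions == ["p2"]
        assert not out.deficient

    def test_unconfirmed_intron_probe_stays_out(self):
        r1 = select_round1([card("p1", d3=150)])
        probe = card("p2", chi=1, pos=1, intron=4, d3=1200, chi_pct=80.0,
                     klass=3, est_ok=False)
        out = select_round2([card("p1", d3=150), probe], r1)
        assert out.round2_additions == []
        assert "EST" in out.exclusions["p2"]

    def test_chi_above_85_excluded(self):
        r1 = select_round1([card("p1", d3=150)])
        probe = card("p2", chi=4, d3=1200, chi_pct=86.0)
        out = select_round2([card("p1", d3=150), probe], r1)
        assert out.round2_additions == []
        assert "CHI" in out.exclusions["p2"]

    def test_distance_beyond_1500_excluded(self):
        r1 = select_round1([card("p1", d3=150)])
        probe = card("p2", chi=1, pos=4, d3=1600, chi_pct=70.0)
        out = select_round2([card("p1", d3=150), probe], r1)
        assert out.round2_additions == []
        assert "1500" in out.exclusions["p2"]

    def test_deficient_flag_below_two_probes(self):
        r1 = select_round1([card("p1", d3=150)])
        out = select_round2([card("p1", d3=150)], r1)
        assert out.panel == ["p1"]
        assert out.deficient is True

    def test_error_on_full_panel(self):
        cards = [card(f"p{i}", d3=150 + i) for i in range(4)]
        r1 = select_round1(cards)
        with pytest.raises(ValueError, match="already full"):
            select_round2(cards, r1)

    def test_no_probe_admitted_twice(self):
        cards = [card("p1", d3=150), card("p2", chi=1, d3=300, chi_pct=70.0)]
        r1 = select_round1(cards)
        out = select_round2(cards, r1)
        panel = out.panel
        assert len(panel) == len(set(panel))
        assert set(r1.round1_panel) <= set(panel)


class TestReannotation:
    def _setup(self):
        rng = np.random.default_rng(30)
        cds = random_seq(rng, 600)
        probe = ProbeRecord("p1", "cdsA", 401, cds[400:460])
        cards = {"p1": card("p1", cds="cdsA")}
        return cds, probe, cards

    def test_perfect_match_keeps_score(self):
        cds, probe, cards = self._setup()
        updated, deficient = rescore_after_reannotation([probe], cards, {"cdsA": cds})
        assert updated["p1"].match_score == 0
        assert updated["p1"].final_score == cards["p1"].final_score
        assert deficient == []

    def test_substitution_in_footprint_scores_20(self):
        cds, probe, cards = self._setup()
        mutated = cds[:430] + ("A" if cds[430] != "A" else "C") + cds[431:]
        updated, deficient = rescore_after_reannotation([probe], cards, {"cdsA": mutated})
        assert updated["p1"].match_score == 20
        assert updated["p1"].final_score >= 20
        assert deficient == ["cdsA"]

    def test_deleted_cds_orphans_probes(self):
        cds, probe, cards = self._setup()
        updated, deficient = rescore_after_reannotation([probe], cards, {"cdsB": cds})
        assert updated["p1"].orphaned
        assert updated["p1"].match_score == 20
        assert "cdsB" in deficient


from hypothesis import given, settings, strategies as st

score_values = dict(
    chi=st.sampled_from([0, 1, 4]),
    fold=st.sampled_from([0, 1]),
    pos=st.sampled_from([0, 1, 4]),
    intron=st.sampled_from([0, 1, 4]),
    match=st.sampled_from([0, 20]),
    d3=st.integers(min_value=1, max_value=2000),
)


class TestSelectionProperties:
    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.fixed_dictionaries(score_values), min_size=1, max_size=10))
    def test_round1_admission_is_exactly_the_rule(self, specs):
        cards = [card(f"p{i:02d}", **kw) for i, kw in enumerate(specs)]
        out = select_round1(cards)
        eligible = sorted(
            (c for c in cards if c.final_score < 4 and c.distance_3p > 100),
            key=lambda c: (c.distance_3p, c.probe_id),
        )
        assert out.round1_panel == [c.probe_id for c in eligible[:4]]
        # additivity holds for every generated card
        for c, kw in zip(cards, specs):
            assert c.final_score == kw["chi"] + kw["fold"] + kw["pos"] + kw["intron"] + kw["match"]

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.fixed_dictionaries(score_values), min_size=1, max_size=10))
    def test_round2_never_duplicates_and_respects_bounds(self, specs):
        cards = [card(f"p{i:02d}", **kw) for i, kw in enumerate(specs)]
        # chi_percent consistent with the chi band actually drawn
        for c in cards:
            c.chi_percent = {0: 50.0, 1: 70.0, 4: 90.0}[c.chi_score]
        out = select_round1(cards)
        if len(out.round1_panel) >= 4:
            return
        out = select_round2(cards, out)
        panel = out.panel
        assert len(panel) == len(set(panel)) <= 4
        by_id = {c.probe_id: c for c in cards}
        for pid in out.round2_additions:
            c = by_id[pid]
            assert c.final_score <= 8
            assert c.chi_percent <= 85.0
            assert c.distance_3p <= 1500
        assert out.deficient == (len(panel) < 2)
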