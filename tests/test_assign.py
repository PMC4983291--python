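"""Link assembly: matching, ambiguity, proline bridging, chains, scoring."""

import numpy as np
import pytest

from conconnmr import assign
from conconnmr.assign import (Pick, Strip, assemble_chains, build_links,
                              pair_complementary_picks, score_links,
                              strips_from_peaklist)
from conconnmr.mixing import MixingModel
from conconnmr.peaks import eligible_pairs, enumerate_peaks, project_to_4d
from conconnmr.shiftgen import generate_shifts, random_idp_sequence
from conconnmr.smft import AnchorPeak


def perfect_strips(sequence, seed=3):
    shifts = generate_shifts(sequence, seed)
    pl = enumerate_peaks("HACACONCOCONH_5D", shifts, MixingModel())
    return shifts, strips_from_peaklist(pl, shifts)


class TestBuildLinks:
    def test_noiseless_completeness_proline_free(self):
        shifts, strips = perfect_strips("AEKQGLSDVTRINHMFYWCA")
        graph = build_links(strips, tol_co=0.05, tol_n=0.3)
        stats = score_links(graph, shifts, "HACACONCOCONH_5D", 0.05, 0.3)
        assert stats.forward_matched == stats.forward_eligible == 19
        assert stats.backward_matched == stats.backward_eligible == 19
        assert stats.forward_row == "100 % (19/19)"

    def test_proline_bridge_in_aapaa(self):
        shifts, strips = perfect_strips("AAPAA", seed=11)
        graph = build_links(strips)
        virtuals = [n for n in graph.nodes.values() if n.kind == "virtual"]
        assert len(virtuals) == 1
        v = virtuals[0]
        assert v.co_ppm == pytest.approx(shifts.shift(2, "CO"), abs=1e-6)
        assert v.n_ppm == pytest.approx(shifts.shift(3, "N"), abs=1e-6)
        # links into and out of the bridged proline node
        sources = {e.source for e in graph.edges_to(v.label)}
        assert sources == {shifts.label(2), shifts.label(4)}
        chains = assemble_chains(graph)
        assert len(chains) == 1 and len(chains[0]) == 4  # A2, P-pair, A4, A5

    def test_identical_anchors_are_ambiguous(self):
        a1 = AnchorPeak("X1", 8.3, 120.0, 176.0, truth_residue=2)
        a2 = AnchorPeak("X2", 8.1, 120.05, 176.01, truth_residue=5)
        a3 = AnchorPeak("X3", 8.2, 112.0, 174.0, truth_residue=9)
        s3 = Strip(a3, [Pick(174.0, 112.0, 1.0), Pick(176.0, 120.0, 0.5)])
        graph = build_links([Strip(a1, []), Strip(a2, []), Strip(a3, s3.picks)])
        assert len(graph.edges) == 0
        assert len(graph.ambiguities) == 1
        assert set(graph.ambiguities[0][2]) == {"X1", "X2"}

    def test_strip_without_diagonal_is_flagged(self):
        a1 = AnchorPeak("X1", 8.3, 120.0, 176.0, truth_residue=2)
        graph = build_links([Strip(a1, [Pick(170.0, 105.0, 1.0)])])
        assert graph.flagged_strips == ["X1"]

    def test_missing_strip_is_not_bridged_like_a_proline(self):
        """Orphan picks around a missing non-proline strip carry an ordinary
        amide nitrogen and must not form a virtual bridge."""
        shifts, strips = perfect_strips("AEKQGLSDVTRINHMFYWCA")
        strips = [s for s in strips if s.anchor.truth_residue != 10]
        graph = build_links(strips)
        assert not any(n.kind == "virtual" for n in graph.nodes.values())


class TestChains:
    def test_perfect_50mer_single_chain(self):
        seq = random_idp_sequence(50, 0, seed=3)
        shifts, strips = perfect_strips(seq, seed=3)
        chains = assemble_chains(build_links(strips))
        assert len(chains) == 1
        assert len(chains[0]) == 49  # one CON-pair transition per anchor

    def test_deleting_internal_strip_splits_chain_in_two(self):
        seq = random_idp_sequence(50, 0, seed=3)
        shifts, strips = perfect_strips(seq, seed=3)
        strips = [s for s in strips if s.anchor.truth_residue != 25]
        chains = assemble_chains(build_links(strips))
        assert len(chains) == 2
        assert sorted(len(c) for c in chains) == [23, 25]

    def test_swapped_near_degenerate_anchors_break_consistency(self):
        """Swapping the pairs of two near-degenerate anchors must not silently
        produce a full-length chain: the damage is visible in the output."""
        seq = random_idp_sequence(20, 0, seed=6)
        shifts, strips = perfect_strips(seq, seed=6)
        i, j = 8, 14
        si = next(s for s in strips if s.anchor.truth_residue == i)
        sj = next(s for s in strips if s.anchor.truth_residue == j)
        ai, aj = si.anchor, sj.anchor
        si.anchor = AnchorPeak(ai.label, ai.hn_ppm, aj.n_ppm, aj.co_ppm, i)
        sj.anchor = AnchorPeak(aj.label, aj.hn_ppm, ai.n_ppm, ai.co_ppm, j)
        graph = build_links(strips)
        chains = assemble_chains(graph)
        stats = score_links(graph, shifts, "HACACONCOCONH_5D")
        intact = len(chains) == 1 and len(chains[0]) == 19
        assert (not intact) or stats.forward_matched < stats.forward_eligible

    def test_deterministic_output(self):
        seq = random_idp_sequence(30, 3, seed=9)
        shifts, strips = perfect_strips(seq, seed=9)
        a = assemble_chains(build_links(strips))
        b = assemble_chains(build_links(strips))
        assert a == b


class TestScoring:
    def test_row_format(self):
        shifts, strips = perfect_strips("AAPAA", seed=11)
        stats = score_links(build_links(strips), shifts, "HACACONCOCONH_5D")
        assert stats.forward_row == "100 % (4/4)"
        assert stats.backward_row == "100 % (4/4)"

    def test_proline_reduces_hn_start_eligible_count(self):
        seq = random_idp_sequence(60, 6, seed=4)
        e_hn = len(eligible_pairs("HNCOCONH_5D", seq))
        e_haca = len(eligible_pairs("HACACONCOCONH_5D", seq))
        assert e_hn < e_haca

    def test_random_deletions_match_brute_force_recount(self):
        """Deleting 20 % of cross-peaks: accepted counts equal an independent
        per-pair recount done directly on the surviving picks."""
        seq = random_idp_sequence(40, 0, seed=8)
        shifts, strips = perfect_strips(seq, seed=8)
        rng = np.random.default_rng(15)
        kept_strips = []
        for s in strips:
            diag_pair = s.own_pair
            picks = []
            for p in s.picks:
                is_diag = (abs(p.co_ppm - diag_pair[0]) < 1e-9
                           and abs(p.n_ppm - diag_pair[1]) < 1e-9)
                if is_diag or rng.random() > 0.20:
                    picks.append(p)
            kept_strips.append(Strip(s.anchor, picks))
        graph = build_links(kept_strips)
        stats = score_links(graph, shifts, "HACACONCOCONH_5D")

        # independent recount: pair (j-1, j) is forward-linked iff the strip
        # of residue j-1 still holds a pick at the pair's true shifts (or the
        # carrier is structurally absent and the diagonal of j survives).
        by_res = {s.anchor.truth_residue: s for s in kept_strips}
        n = len(seq)

        def has_pick(res, j):
            s = by_res.get(res)
            if s is None:
                return False
            tco, tn = shifts.shift(j - 1, "CO"), shifts.shift(j, "N")
            return any(abs(p.co_ppm - tco) < 1e-9 and abs(p.n_ppm - tn) < 1e-9
                       for p in s.picks)

        fwd = bwd = 0
        for j in range(2, n + 1):
            fwd += has_pick(j - 1, j) if j - 1 >= 2 else (by_res.get(j) is not None)
            bwd += has_pick(j + 1, j) if j + 1 <= n else (by_res.get(j) is not None)
        assert stats.forward_matched == fwd
        assert stats.backward_matched == bwd


class TestComplementary4d:
    def test_4d_pairing_equals_5d_linking(self, idp30_shifts, lossless_model):
        pl5 = enumerate_peaks("HACACONCOCONH_5D", idp30_shifts, lossless_model)
        strips5 = strips_from_peaklist(pl5, idp30_shifts)
        by_co, by_n = {}, {}
        for p in project_to_4d(pl5, "CO"):
            by_co.setdefault(p.anchor_res, []).append((p.positions["COres"], p.amplitude))
        for p in project_to_4d(pl5, "N"):
            by_n.setdefault(p.anchor_res, []).append((p.positions["Nres"], p.amplitude))
        strips4 = [Strip(s.anchor, pair_complementary_picks(
            by_co[s.anchor.truth_residue], by_n[s.anchor.truth_residue]))
            for s in strips5]
        g5, g4 = build_links(strips5), build_links(strips4)
        s5 = score_links(g5, idp30_shifts, "HACACONCOCONH_5D")
        s4 = score_links(g4, idp30_shifts, "HACACONCOCONH_5D")
        assert (s5.forward_row, s5.backward_row) == (s4.forward_row, s4.backward_row)

        def canon(g, chains):
            return [tuple((round(g.nodes[l].co_ppm, 4), round(g.nodes[l].n_ppm, 4))
                          for l in c) for c in chains]

        assert canon(g5, assemble_chains(g5)) == canon(g4, assemble_chains(g4))
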