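import numpy as np
import pytest

from ibdthread.ibdio import IBDSegment
from ibdthread.placement import (PlacementState, place_segment,
                                 select_source_max_prob,
                                 select_source_min_path,
                                 transmission_probability,
                                 transmission_sides)
from ibdthread.pedigree import Individual, Pedigree
from ibdthread.sources import find_sources


def chain_pedigree(k: int) -> tuple[Pedigree, frozenset]:
    """k meioses from a founder couple down a single lineage to one
    genotyped leaf, plus a genotyped sibling at the top to make a cohort."""
    ped = Pedigree()
    ped.add(Individual("a0", None, None, "M"))
    ped.add(Individual("b0", None, None, "F"))
    ped.add(Individual("sib", "a0", "b0", "M", genotyped=True))
    prev = ("a0", "b0")
    for i in range(1, k + 1):
        ident = f"c{i}"
        spouse = f"s{i}"
        ped.add(Individual(ident, prev[0], prev[1], "M",
                           genotyped=(i == k)))
        if i < k:
            ped.add(Individual(spouse, None, None, "F"))
            prev = (ident, spouse)
    return ped, frozenset({"sib", f"c{k}"})


class TestSelectors:
    def test_min_path_order_and_rejection(self, looped_example):
        ped, cohort = looped_example
        cands = find_sources(ped, cohort)
        assert select_source_min_path(cands, set()).members == ("g", "h")
        assert select_source_min_path(cands, {("g", "h")}).members == ("l",)
        allk = {c.key for c in cands}
        assert select_source_min_path(cands, allk) is None

    def test_max_prob_single_and_rejected(self, looped_example):
        ped, cohort = looped_example
        cands = find_sources(ped, cohort)
        only = [cands[0]]
        assert select_source_max_prob(ped, only, cohort, 0.1, set()) is cands[0]
        best = select_source_max_prob(ped, cands, cohort, 0.1, set())
        second = select_source_max_prob(ped, cands, cohort, 0.1, {best.key})
        assert second is not None and second.key != best.key

    def test_max_prob_is_exhaustively_maximal(self, looped_example):
        ped, cohort = looped_example
        cands = find_sources(ped, cohort)
        probs = {c.key: transmission_probability(ped, c, cohort, 0.05)
                 for c in cands}
        best = select_source_max_prob(ped, cands, cohort, 0.05, set())
        assert probs[best.key] == max(probs.values())


class TestTransmissionProbability:
    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_zero_length_chain(self, k):
        ped, cohort = chain_pedigree(k)
        cands = find_sources(ped, cohort)
        couple = next(c for c in cands if c.members == ("a0", "b0"))
        # k meioses to the deep leaf + 1 to the sibling
        assert transmission_probability(ped, couple, cohort, 0.0) == \
            pytest.approx(0.5 ** (k + 1))

    @pytest.mark.parametrize("length", [0.0, 0.2, 0.5])
    def test_single_path_closed_form(self, length):
        ped, cohort = chain_pedigree(3)
        couple = find_sources(ped, cohort)[0]
        q = 0.5 * np.exp(-length)
        assert transmission_probability(ped, couple, cohort, length) == \
            pytest.approx(q ** 4)

    def test_matches_monte_carlo_gene_drop(self):
        """Chain transmission frequency from simulated meioses (coin for
        the starting strand, Poisson crossovers) matches the analytic
        value within 3 standard errors."""
        ped, cohort = chain_pedigree(2)
        couple = find_sources(ped, cohort)[0]
        length = 0.3  # Morgans
        p = transmission_probability(ped, couple, cohort, length)
        rng = np.random.default_rng(5)
        reps = 100_000
        # three independent meioses: couple->sib, couple->c1, c1->c2
        intact = np.ones(reps, dtype=bool)
        for _ in range(3):
            coin = rng.random(reps) < 0.5
            no_xo = rng.poisson(length, reps) == 0
            intact &= coin & no_xo
        p_hat = intact.mean()
        se = np.sqrt(p_hat * (1 - p_hat) / reps)
        assert abs(p - p_hat) <= 3 * se

    def test_probabilities_are_probabilities(self, looped_example):
        ped, cohort = looped_example
        for c in find_sources(ped, cohort):
            p = transmission_probability(ped, c, cohort, 0.1)
            assert 0 < p < 1


def make_segment(seg_id, start, end, consensus, cohort=()):
    consensus = np.asarray(consensus, dtype=np.int8)
    return IBDSegment(id=seg_id, chrom="1", start=start, end=end,
                      start_bp=start * 1000 + 1, end_bp=end * 1000,
                      cm=float(end - start) / 10,
                      cohort=frozenset(cohort), consensus=consensus)


class TestPlacement:
    def test_looped_example_places_into_b_c_d(self, looped_example):
        ped, cohort = looped_example
        cand = find_sources(ped, cohort)[0]
        state = PlacementState()
        seg = make_segment("s1", 0, 100, np.ones(100))
        assert place_segment(state, seg, cand, reconstructions={}, ped=ped)
        assert set(state.placed) == {"b", "c", "d"}
        assert state.chosen["s1"] == ("g", "h")

    def test_no_reconstructed_targets_always_succeeds(self, looped_example):
        ped, cohort = looped_example
        cand = find_sources(ped, cohort)[1]
        state = PlacementState()
        seg = make_segment("s1", 0, 100, np.zeros(100))
        assert place_segment(state, seg, cand, reconstructions={})

    def test_conflicting_reconstruction_rejects_candidate(self, looped_example):
        ped, cohort = looped_example
        cand = find_sources(ped, cohort)[0]   # places into b, c, d
        hap = np.zeros(100, dtype=np.int8)
        recon = {"c": (hap, hap)}             # c is fixed all-zero
        seg = make_segment("s1", 0, 100, np.ones(100))  # all-one consensus
        state = PlacementState()
        assert not place_segment(state, seg, cand, recon,
                                 agreement=0.98, min_snps=50)
        assert state.is_rejected("s1", cand.key)
        assert state.placed == {}
        # a matching segment is accepted
        seg2 = make_segment("s2", 0, 100, np.zeros(100))
        assert place_segment(state, seg2, cand, recon)

    def test_sides_recorded(self, looped_example):
        ped, cohort = looped_example
        cands = find_sources(ped, cohort)
        (l_cand,) = [c for c in cands if c.members == ("l",)]
        sides = transmission_sides(ped, l_cand, l_cand.on_all_paths)
        # b, c are children of g+h; only h descends from l
        assert sides["b"] == {"h"} and sides["c"] == {"h"}
        (pq,) = [c for c in cands if c.members == ("p", "q")]
        sides_pq = transmission_sides(ped, pq, pq.on_all_paths)
        assert sides_pq["b"] == {"g"}
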