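import numpy as np
import pytest

from ibdthread.grouping import (HaplotypeGroup, StrongGroupPolicy, classify,
                                consensus_haplotypes,
                                detect_homozygous_regions, group_segments,
                                is_strong)
from ibdthread.ibdio import IBDSegment
from ibdthread.metrics import individual_similarity
from ibdthread.pedigree import assign_generations

S = 1000
POSITIONS = np.arange(1, S + 1) * 10_000  # 10 kb spacing


def seg(seg_id, start, end, consensus):
    consensus = np.asarray(consensus, dtype=np.int8)
    assert len(consensus) == end - start
    return IBDSegment(id=seg_id, chrom="1", start=start, end=end,
                      start_bp=int(POSITIONS[start]),
                      end_bp=int(POSITIONS[end - 1]),
                      cm=(end - start) * 0.02,
                      cohort=frozenset(), consensus=consensus)


def group_with(n_segments, coverage, n_sites=S):
    g = HaplotypeGroup(n_sites)
    covered = int(round(coverage * n_sites))
    g.votes1[:covered] = 1
    g.members = [f"m{i}" for i in range(n_segments)]
    return g


class TestHomozygousRegions:
    def test_identical_overlapping_segments_declare_region(self):
        alleles = np.ones(500, dtype=np.int8)
        segs = [seg("a", 0, 500, alleles), seg("b", 0, 500, alleles)]
        regions = detect_homozygous_regions(segs, POSITIONS)
        assert regions == [(0, 500)]

    def test_heterozygous_site_splits_region(self):
        a = np.ones(500, dtype=np.int8)
        b = np.ones(500, dtype=np.int8)
        b[250] = 0
        regions = detect_homozygous_regions(
            [seg("a", 0, 500, a), seg("b", 0, 500, b)], POSITIONS)
        assert regions == [(0, 250), (251, 500)]

    def test_single_coverage_is_not_evidence(self):
        segs = [seg("a", 0, 500, np.ones(500))]
        assert detect_homozygous_regions(segs, POSITIONS) == []

    def test_thresholds(self):
        alleles = np.ones(99, dtype=np.int8)
        segs = [seg("a", 0, 99, alleles), seg("b", 0, 99, alleles)]
        # 99 SNPs < 100 SNP floor even though the bp span is wide enough
        assert detect_homozygous_regions(segs, POSITIONS,
                                         min_bp=300_000, min_snps=100) == []


class TestStrongTiers:
    @pytest.mark.parametrize("n,cov,setting,gen,expected", [
        (2, 0.91, "default", 9, True),
        (2, 0.89, "default", 9, False),
        (3, 0.70, "default", 9, True),
        (9, 0.69, "default", 9, False),
        (10, 0.50, "default", 9, True),
        (10, 0.49, "default", 9, False),
        # Setting A tightens the middle tier for ancient generations
        (3, 0.70, "A", 7, False),
        (3, 0.90, "A", 7, True),
        (14, 0.70, "A", 7, True),
        (15, 0.50, "A", 7, True),
        (3, 0.70, "A", 9, True),     # recent generations keep the default
        # Setting B relaxes the coverage floors for ancient generations
        (2, 0.70, "B", 7, True),
        (2, 0.69, "B", 7, False),
        (5, 0.60, "B", 7, True),
        (15, 0.50, "B", 7, True),
        (2, 0.70, "B", 9, False),    # recent generations keep the default
    ])
    def test_tiers(self, n, cov, setting, gen, expected):
        policy = StrongGroupPolicy.from_setting(setting)
        assert is_strong(group_with(n, cov), S, policy, gen) is expected

    def test_zero_coverage_never_strong(self):
        assert not is_strong(group_with(5, 0.0), S)


class TestClassification:
    def make_asm(self, groups):
        from ibdthread.grouping import IndividualAssembly
        asm = IndividualAssembly(individual="x", n_sites=S)
        asm.groups = groups
        return asm

    def test_two_strong_groups_reconstructed(self):
        asm = self.make_asm([group_with(5, 0.8), group_with(5, 0.8)])
        classify(asm)
        assert asm.status == "reconstructed"
        assert asm.retained == (0, 1)

    def test_oversized_extra_group_blocks(self):
        extra = group_with(3, 0.48)  # 60% of the weaker strong group
        weaker = group_with(5, 0.8)
        asm = self.make_asm([group_with(8, 0.9), weaker, extra])
        classify(asm)
        assert asm.status != "reconstructed"

    def test_small_extra_groups_are_rejected_and_ok(self):
        extra = group_with(2, 0.2)  # half the count and a quarter the length
        asm = self.make_asm([group_with(8, 0.9), group_with(5, 0.8), extra])
        classify(asm)
        assert asm.status == "reconstructed"
        assert set(asm.rejected_segments) == set(extra.members)

    def test_no_groups_unresolved(self):
        asm = self.make_asm([])
        classify(asm)
        assert asm.status == "unresolved"

    def test_single_strong_group_partial(self):
        asm = self.make_asm([group_with(5, 0.8), group_with(1, 0.2)])
        classify(asm)
        assert asm.status == "partial"

    def test_same_parent_side_pair_is_invalid(self):
        g1 = group_with(8, 0.9)
        g2 = group_with(5, 0.8)
        g1.allowed = frozenset({"dad"})
        g2.allowed = frozenset({"dad"})
        asm = self.make_asm([g1, g2])
        classify(asm)
        assert asm.status == "partial"
        assert set(asm.rejected_segments) == set(g2.members)

    def test_consensus_requires_reconstructed(self):
        asm = self.make_asm([group_with(1, 0.2)])
        classify(asm)
        with pytest.raises(ValueError, match="not reconstructed"):
            consensus_haplotypes(asm)


class TestGrouping:
    def test_single_segment_single_group(self):
        asm = group_segments("x", [seg("a", 0, 300, np.ones(300))],
                             S, POSITIONS)
        assert len(asm.groups) == 1
        assert asm.groups[0].members == ["a"]

    def test_conflicting_segment_rejected(self):
        """A segment disagreeing with both established haplotype groups is
        reported for re-sourcing, not forced into either."""
        rng = np.random.default_rng(0)
        hap1 = rng.integers(0, 2, S).astype(np.int8)
        hap2 = 1 - hap1
        rogue = rng.integers(0, 2, S).astype(np.int8)
        segs = [seg("a1", 0, 600, hap1[:600]), seg("a2", 400, S, hap1[400:]),
                seg("b1", 0, 600, hap2[:600]), seg("b2", 400, S, hap2[400:]),
                seg("r", 200, 800, rogue[200:800])]
        asm = group_segments("x", segs, S, POSITIONS)
        assert asm.rejected_segments == {"r"}
        assert len(asm.groups) == 2

    def test_opposite_haplotype_opens_second_group(self):
        rng = np.random.default_rng(1)
        hap1 = rng.integers(0, 2, S).astype(np.int8)
        hap2 = 1 - hap1
        asm = group_segments("x", [seg("a", 0, S, hap1), seg("b", 0, S, hap2)],
                             S, POSITIONS)
        assert len(asm.groups) == 2

    def test_genotyped_individuals_recover_true_haplotypes(self, small_sim):
        """Grouping an individual's true segments yields two retained
        haplotypes nearly identical to the simulated truth."""
        _, ped, truth, segments = small_sim
        gens = assign_generations(ped)
        sims = []
        for ind in sorted(ped.genotyped_ids()):
            mine = [s for s in segments
                    if ind in {h[0] for h in s.cohort}]
            if not mine:
                continue
            asm = group_segments(ind, mine, truth.positions.size,
                                 truth.positions, generation=gens[ind])
            if asm.status == "reconstructed":
                sims.append(individual_similarity(
                    consensus_haplotypes(asm),
                    (truth.haplotypes[(ind, 0)], truth.haplotypes[(ind, 1)]),
                    missing_as_mismatch=False))
        assert len(sims) >= 10
        assert np.mean(sims) >= 0.98

    def test_deterministic(self, small_sim):
        _, ped, truth, segments = small_sim
        ind = sorted(ped.genotyped_ids())[0]
        mine = [s for s in segments if ind in {h[0] for h in s.cohort}]
        a1 = group_segments(ind, mine, truth.positions.size, truth.positions)
        a2 = group_segments(ind, mine, truth.positions.size, truth.positions)
        assert a1.status == a2.status
        assert [g.members for g in a1.groups] == [g.members for g in a2.groups]
        for g1, g2 in zip(a1.groups, a2.groups):
            assert np.array_equal(g1.consensus(), g2.consensus())
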