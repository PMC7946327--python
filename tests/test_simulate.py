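import json

import numpy as np
import pytest

from ibdthread.ibdio import build_cohorts, read_match, read_phased_vcf, \
    read_plink_map
from ibdthread.pedigree import inbreeding, parse_pedigree
from ibdthread.simulate import (SimConfig, example_pedigree, gene_drop,
                                meiosis_selector, simulate_pedigree,
                                true_ibd_segments, true_pairwise_matches,
                                write_fixtures)


class TestPedigreeSimulation:
    def test_quota_zero_is_loop_free(self):
        cfg = SimConfig(generations=3, couples_per_generation=6,
                        quota_second=0, quota_third=0, quota_fourth=0,
                        n_snps=0, chrom_cm=1.0, seed=4)
        ped = simulate_pedigree(cfg)
        assert all(inbreeding(ped, i) == 0.0 for i in ped.individuals)

    def test_same_seed_identical(self):
        cfg = SimConfig(generations=5, couples_per_generation=6, n_snps=0,
                        chrom_cm=1.0, seed=9)
        p1 = simulate_pedigree(cfg)
        p2 = simulate_pedigree(cfg)
        assert p1.individuals == p2.individuals
        assert p1.sim_marriages == p2.sim_marriages

    def test_consanguinity_quotas_realized(self):
        """Realized fractions of first-/second-/third-cousin marriages stay
        within two percentage points of the quotas, pooled over seeds."""
        counts = {2: 0, 3: 0, 4: 0}
        total = 0
        for seed in range(10):
            ped = simulate_pedigree(SimConfig(n_snps=0, chrom_cm=1.0,
                                              seed=seed))
            for _a, _b, band, gen in ped.sim_marriages:
                if gen >= 2:
                    total += 1
                    if band in counts:
                        counts[band] += 1
        cfg = SimConfig()
        for band, quota in [(2, cfg.quota_second), (3, cfg.quota_third),
                            (4, cfg.quota_fourth)]:
            assert abs(counts[band] / total - quota) <= 0.02

    def test_expected_scale(self, default_sim):
        cfg, ped, _, _ = default_sim
        assert 250 <= ped.t <= 350
        # bottom three generations carry the genotypes
        assert ped.n >= 80


class TestGeneDrop:
    def test_zero_length_chromosome_transmits_whole_haplotypes(self):
        cfg = SimConfig(generations=3, couples_per_generation=3, n_snps=50,
                        chrom_cm=0.0, seed=2)
        ped = simulate_pedigree(cfg)
        truth = gene_drop(ped, cfg)
        for ident, ind in ped.individuals.items():
            if ind.is_founder:
                continue
            for k, parent in ((0, ind.father), (1, ind.mother)):
                child = truth.haplotypes[(ident, k)]
                assert any(np.array_equal(child, truth.haplotypes[(parent, j)])
                           for j in (0, 1))

    def test_crossover_count_is_poisson_with_map_length(self):
        rng = np.random.default_rng(12)
        cm = np.linspace(0, 250, 2000)
        counts = []
        for _ in range(10_000):
            sel = meiosis_selector(cm, 250.0, rng)
            counts.append(int((np.diff(sel) != 0).sum()))
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        # crossovers between the first and last SNP ~ Poisson(2.5 Morgans)
        assert abs(mean - 2.5) <= 3 * se

    def test_determinism(self):
        cfg = SimConfig(generations=4, couples_per_generation=4, n_snps=300,
                        chrom_cm=50.0, seed=6)
        ped = simulate_pedigree(cfg)
        t1, t2 = gene_drop(ped, cfg), gene_drop(ped, cfg)
        for h in t1.haplotypes:
            assert np.array_equal(t1.haplotypes[h], t2.haplotypes[h])
            assert np.array_equal(t1.ancestry[h], t2.ancestry[h])

    def test_kinship_matches_realized_sharing(self, small_sim):
        """Pedigree kinship predicts the realized fraction of the genome at
        which random haplotypes of two individuals share founder origin."""
        from ibdthread.pedigree import kinship
        cfg, ped, truth, _ = small_sim
        rng = np.random.default_rng(3)
        geno = sorted(ped.genotyped_ids())
        pairs = [(geno[i], geno[j]) for i, j in
                 zip(rng.integers(0, len(geno), 12),
                     rng.integers(0, len(geno), 12)) if geno[i] != geno[j]]
        for a, b in pairs[:6]:
            shared = np.mean([
                (truth.ancestry[(a, i)] == truth.ancestry[(b, j)]).mean()
                for i in (0, 1) for j in (0, 1)])
            phi = kinship(ped, a, b)
            # one chromosome realization: allow a generous band around phi
            assert abs(shared - phi) <= max(3 * np.sqrt(phi * (1 - phi) / 8),
                                            0.1)


class TestTrueIbd:
    def test_cohorts_byte_identical(self, small_sim):
        _, ped, truth, segments = small_sim
        for seg in segments[::11]:
            for h in seg.cohort:
                assert np.array_equal(truth.haplotypes[h][seg.start:seg.end],
                                      seg.consensus)

    def test_minimum_length_respected(self, small_sim):
        cfg, _, _, segments = small_sim
        assert segments
        assert min(s.cm for s in segments) >= cfg.min_cm

    def test_sibling_pairs_share_half_the_chromosome(self):
        """Mean pairwise sharing between full siblings is ~50% per parental
        haplotype (averaged over seeds)."""
        fracs = []
        for seed in range(6):
            cfg = SimConfig(generations=2, couples_per_generation=2,
                            children_range=(2, 2), n_snps=800,
                            chrom_cm=150.0, genotyped_generations=1,
                            seed=seed)
            ped = simulate_pedigree(cfg)
            truth = gene_drop(ped, cfg)
            for couple in {(i.father, i.mother)
                           for i in ped.individuals.values()
                           if not i.is_founder}:
                kids = sorted(ped.shared_children(*couple))
                a, b = kids[:2]
                for k in (0, 1):  # paternal then maternal haplotypes
                    fracs.append(
                        (truth.ancestry[(a, k)] == truth.ancestry[(b, k)])
                        .mean())
        assert abs(np.mean(fracs) - 0.5) <= 0.05

    def test_pairwise_matches_consistent_with_rectangles(self, small_sim):
        _, ped, truth, segments = small_sim
        matches = true_pairwise_matches(truth, ped, min_cm=3.0)
        assert matches
        # every cohort pair of every segment is covered by a pairwise match
        by_pair = {}
        for m in matches:
            by_pair.setdefault(frozenset((m.hap1, m.hap2)), []).append(m)
        for seg in segments[::17]:
            cohort = sorted(seg.cohort)
            for i in range(len(cohort)):
                for j in range(i + 1, len(cohort)):
                    if cohort[i][0] == cohort[j][0]:
                        continue  # autozygous pair within one individual
                    key = frozenset((cohort[i], cohort[j]))
                    assert any(m.start_bp <= seg.start_bp
                               and m.end_bp >= seg.end_bp
                               for m in by_pair.get(key, []))

    def test_build_cohorts_recovers_truth(self, small_sim):
        _, ped, truth, segments = small_sim
        panel = truth.to_panel(ped)
        sample = segments[::7]
        matches = [m for s in sample for m in s.to_matches()]
        segs, _ = build_cohorts(matches, panel, min_overlap_frac=0.9)
        got = {(s.start, s.end, s.cohort) for s in segs}
        want = {(s.start, s.end, s.cohort) for s in sample}
        assert len(got & want) / len(want) >= 0.9


class TestFixtures:
    def test_write_and_reread(self, tmp_path, small_sim):
        cfg, ped, truth, segments = small_sim
        paths = write_fixtures(ped, truth, cfg, tmp_path)
        with open(paths["pedigree"]) as fh:
            ped2 = parse_pedigree(fh)
        assert ped2.individuals == ped.individuals
        panel = read_phased_vcf(paths["vcf"])
        assert set(panel.samples) == ped.genotyped_ids()
        for s in panel.samples:
            for k in (0, 1):
                assert np.array_equal(panel.get((s, k)),
                                      truth.haplotypes[(s, k)])
        with open(paths["match"]) as fh:
            matches = read_match(fh)
        assert len(matches) == sum(
            len(s.cohort) * (len(s.cohort) - 1) // 2 for s in segments)
        bp, cm = read_plink_map(paths["map"])
        assert np.array_equal(bp, truth.positions)
        doc = json.loads(paths["truth"].read_text())
        assert doc["chrom"] == truth.chrom
        assert len(doc["segments"]) == len(segments)
        first = sorted(doc["haplotypes"])[0]
        sample, k = first.rsplit(".", 1)
        assert doc["haplotypes"][first] == \
            "".join(map(str, truth.haplotypes[(sample, int(k))]))

    def test_example_pedigree_quantities(self):
        from ibdthread.sources import enumerate_paths, find_sources
        ped, cohort = example_pedigree()
        cands = find_sources(ped, cohort)
        assert len(cands) == 3
        assert sorted(c.d for c in cands) == [1, 2, 8]
        assert sum(len(enumerate_paths(ped, c, cohort)) for c in cands) == 11
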