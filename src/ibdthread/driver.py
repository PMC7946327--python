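"""Outer reconstruction loop: alternate source selection and grouping
until no further individuals are reconstructed.

Iteration 0 seeds the reconstructed list with the genotyped individuals
(whose haplotypes come from the panel and never change).  Each iteration
(re-)sources the pending segments — initially all of them, later only
those whose source was rejected — places each into the individuals on all
descendance paths from its chosen source, then regroups every ungenotyped
individual that has placed segments.  Individuals assembling into two
strong haplotypes join the reconstructed list and their haplotypes are
fixed; segments falling in discarded weak groups (or conflicting with
both haplotypes) have their source rejected and are re-sourced in the
next iteration.  The loop stops when an iteration reconstructs nobody and
re-sources nothing, or at the iteration cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grouping import (IndividualAssembly, StrongGroupPolicy,
                       consensus_haplotypes, group_segments)
from .ibdio import HaplotypePanel, IBDSegment, write_phased_vcf
from .pedigree import Pedigree, assign_generations
from .placement import (PlacementState, place_segment, select_source_max_prob,
                        select_source_min_path)
from .sources import SourceCandidate, find_sources

__all__ = ["ThreadConfig", "ReconstructionResult", "run_thread", "emit_outputs"]


@dataclass(frozen=True)
class ThreadConfig:
    """All tunables of the reconstruction, with the documented defaults."""

    source_method: str = "min_path"       # or "max_prob"
    strong_setting: str = "default"       # or "A" / "B"
    conflict_agreement: float = 0.98
    conflict_min_snps: int = 50
    group_agreement: float = 0.98
    group_min_snps: int = 50
    lineup_max_gap: int = 50
    hom_min_bp: int = 300_000
    hom_min_snps: int = 100
    prob_config_cap: int = 10_000
    max_iter: int = 25
    accept_full_homozygous: bool = False
    # reconstruct the most recent ancestral generations first: individuals
    # older than the moving frontier are not declared reconstructed until
    # the frontier reaches them, so that recent (well-constrained)
    # reconstructions can veto wrong sources for older ones
    generation_frontier: bool = True

    def policy(self) -> StrongGroupPolicy:
        return StrongGroupPolicy.from_setting(self.strong_setting)


@dataclass
class ReconstructionResult:
    """Everything the run produced, sufficient to write all outputs."""

    assemblies: dict[str, IndividualAssembly] = field(default_factory=dict)
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    iterations: int = 0
    converged: bool = True
    history: list[tuple[int, int]] = field(default_factory=list)  # (new, re-sourced)
    skipped_segments: list[str] = field(default_factory=list)
    n_segments: int = 0
    n_pairs: int = 0
    state: PlacementState = field(default_factory=PlacementState)
    config: ThreadConfig = field(default_factory=ThreadConfig)
    generations: dict[str, int] = field(default_factory=dict)

    @property
    def reconstructed_ids(self) -> list[str]:
        return sorted(self.haplotypes)

    @property
    def n_reconstructed(self) -> int:
        return len(self.haplotypes)


def run_thread(ped: Pedigree, panel: HaplotypePanel,
               segments: list[IBDSegment],
               config: ThreadConfig | None = None) -> ReconstructionResult:
    """Run the full reconstruction for one chromosome.

    Returns a result whose ``haplotypes`` contains only the *ancestral*
    (ungenotyped) reconstructions; genotyped haplotypes are taken from the
    panel and are used for conflict checks but are not re-derived.
    """
    config = config or ThreadConfig()
    gens = assign_generations(ped)
    policy = config.policy()
    genotyped = {s for s in panel.samples
                 if s in ped.individuals and ped.individuals[s].genotyped}
    reconstructions: dict[str, tuple[np.ndarray, np.ndarray]] = {
        s: (panel.get((s, 0)), panel.get((s, 1))) for s in genotyped
    }

    seg_by_id = {seg.id: seg for seg in segments}
    candidates: dict[str, list[SourceCandidate]] = {}
    skipped: set[str] = set()
    for seg in segments:
        cohort = seg.cohort_individuals()
        cands = find_sources(ped, cohort, gens) if len(cohort) >= 2 else []
        if not cands:
            skipped.add(seg.id)
        else:
            candidates[seg.id] = cands

    result = ReconstructionResult(config=config, n_segments=len(segments),
                                  generations=gens)
    result.n_pairs = sum(len(s.cohort) * (len(s.cohort) - 1) // 2
                         for s in segments)
    state = result.state
    assemblies = result.assemblies

    def seg_order(sid: str):
        seg = seg_by_id[sid]
        return (-seg.cm, seg.start, seg.id)

    pending: set[str] = {s.id for s in segments if s.id not in skipped}
    ancestral_gens = sorted(
        {gens.get(i, 0) for i in ped.individuals
         if not ped.individuals[i].genotyped}, reverse=True)
    frontier = ancestral_gens[0] if (config.generation_frontier
                                     and ancestral_gens) else 0
    min_gen = ancestral_gens[-1] if ancestral_gens else 0
    iteration = 0
    while iteration < config.max_iter:
        iteration += 1
        n_resourced = len(pending) if iteration > 1 else 0

        for sid in sorted(pending, key=seg_order):
            seg = seg_by_id[sid]
            cohort = seg.cohort_individuals()
            state.unplace(sid)
            while True:
                rejected = state.rejected.get(sid, set())
                if config.source_method == "min_path":
                    cand = select_source_min_path(candidates[sid], rejected)
                else:
                    cand = select_source_max_prob(
                        ped, candidates[sid], cohort, seg.cm / 100.0,
                        rejected, config.prob_config_cap)
                if cand is None:
                    skipped.add(sid)
                    break
                if place_segment(state, seg, cand, reconstructions,
                                 config.conflict_agreement,
                                 config.conflict_min_snps, ped=ped):
                    break
        pending = set()

        new_recon = 0
        frontier_blocked = False
        for ind in sorted(state.placed):
            if ind in reconstructions or ind in genotyped:
                continue
            if ind in ped.individuals and ped.individuals[ind].genotyped:
                continue
            segs_here = [seg_by_id[s] for s in sorted(state.placed[ind])]
            if not segs_here:
                continue
            asm = group_segments(
                ind, segs_here, panel.n_snps, panel.positions,
                policy=policy, generation=gens.get(ind),
                agreement=config.group_agreement,
                min_snps=config.group_min_snps,
                lineup_max_gap=config.lineup_max_gap,
                hom_min_bp=config.hom_min_bp,
                hom_min_snps=config.hom_min_snps,
                accept_full_homozygous=config.accept_full_homozygous,
                sides={sid: state.sides[(ind, sid)]
                       for sid in state.placed[ind]
                       if (ind, sid) in state.sides},
            )
            assemblies[ind] = asm
            for sid in asm.rejected_segments:
                if sid in state.chosen:
                    state.reject(sid, state.chosen[sid])
                    pending.add(sid)
            if asm.status == "reconstructed":
                if gens.get(ind, 0) >= frontier:
                    result.haplotypes[ind] = consensus_haplotypes(asm)
                    reconstructions[ind] = result.haplotypes[ind]
                    new_recon += 1
                else:
                    frontier_blocked = True

        result.history.append((new_recon, n_resourced))
        if new_recon == 0 and not pending:
            if frontier_blocked and frontier > min_gen:
                frontier -= 1
                continue
            break
    else:
        result.converged = False

    result.iterations = iteration
    result.skipped_segments = sorted(skipped)
    return result


# ---------------------------------------------------------------------------
# Outputs
# ---------------------------------------------------------------------------

def emit_outputs(result: ReconstructionResult, panel: HaplotypePanel,
                 out_dir: str | Path,
                 prefix: str = "ibdthread") -> dict[str, Path]:
    """Write the reconstructed haplotypes (phased VCF over the panel sites,
    missing where uncovered), the per-individual group report, and a
    one-row run summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / f"{prefix}.reconstructed.vcf",
        "groups": out / f"{prefix}.groups.tsv",
        "summary": out / f"{prefix}.summary.tsv",
    }

    haps = {(s, k): panel.get((s, k)) for s in panel.samples for k in (0, 1)}
    samples = list(panel.samples)
    for ind in result.reconstructed_ids:
        h0, h1 = result.haplotypes[ind]
        haps[(ind, 0)] = np.asarray(h0, dtype=np.int8)
        haps[(ind, 1)] = np.asarray(h1, dtype=np.int8)
        samples.append(ind)
    out_panel = HaplotypePanel(
        chrom=panel.chrom, positions=panel.positions.copy(),
        haplotypes=haps, samples=samples, cm=panel.cm.copy(),
        ref=panel.ref, alt=panel.alt, snp_ids=panel.snp_ids,
    )
    with open(paths["vcf"], "w") as fh:
        write_phased_vcf(out_panel, fh)

    with open(paths["groups"], "w") as fh:
        fh.write("individual\tchrom\tstart_bp\tend_bp\tgroup\t"
                 "n_segments\tcoverage\tstrong\tstatus\n")
        for ind in sorted(result.assemblies):
            asm = result.assemblies[ind]
            for gi, grp in enumerate(asm.groups):
                s, e = grp.span()
                if e <= s:
                    continue
                fh.write(
                    f"{ind}\t{panel.chrom}\t{panel.positions[s]}\t"
                    f"{panel.positions[e - 1]}\t{gi}\t{grp.n_segments}\t"
                    f"{grp.coverage():.4f}\t{int(grp.strong)}\t{asm.status}\n"
                )

    with open(paths["summary"], "w") as fh:
        fh.write("chrom\tibd_pairs\tunique_ibds\titerations\treconstructed\n")
        fh.write(f"{panel.chrom}\t{result.n_pairs}\t{result.n_segments}\t"
                 f"{result.iterations}\t{result.n_reconstructed}\n")
    return paths
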