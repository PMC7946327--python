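"""Evaluation procedures: sequence similarity, similarity-vs-kinship,
leave-one-out reconstruction, lost-region scan, cross-chromosome Jaccard
consistency, and the well-reconstructed prediction filter."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .driver import ReconstructionResult, ThreadConfig, run_thread
from .ibdio import HaplotypePanel
from .pedigree import Pedigree, genotyped_descendants, kinship
from .simulate import SimConfig, TruthSet, true_ibd_segments

__all__ = [
    "sequence_similarity",
    "individual_similarity",
    "similarity_vs_kinship",
    "leave_one_out",
    "lost_regions",
    "jaccard_consistency",
    "prediction_filter",
    "mean_ibd_coverage",
]


def sequence_similarity(hap_a: np.ndarray, hap_b: np.ndarray,
                        mask: np.ndarray | None = None,
                        missing_as_mismatch: bool = True) -> float:
    """Fraction of genotyped sites at which the two haplotypes agree.

    ``mask`` restricts the comparison to a subset of sites (default: all).
    Missing calls count as mismatches by default (conservative); set
    ``missing_as_mismatch=False`` to exclude them from the denominator.
    """
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    if a.shape != b.shape:
        raise ValueError("haplotypes must have equal length")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    a, b = a[mask], b[mask]
    ok = (a >= 0) & (b >= 0)
    if missing_as_mismatch:
        return float(((a == b) & ok).sum()) / len(a)
    if not ok.any():
        return 0.0
    return float((a[ok] == b[ok]).sum()) / int(ok.sum())


def individual_similarity(recon: tuple[np.ndarray, np.ndarray],
                          truth: tuple[np.ndarray, np.ndarray],
                          mask: np.ndarray | None = None,
                          missing_as_mismatch: bool = True) -> float:
    """Mean haplotype similarity under the best of the two pairings."""
    def pair(i: int, j: int) -> float:
        return 0.5 * (
            sequence_similarity(recon[0], truth[i], mask, missing_as_mismatch)
            + sequence_similarity(recon[1], truth[j], mask, missing_as_mismatch)
        )
    return max(pair(0, 1), pair(1, 0))


def similarity_vs_kinship(ped: Pedigree,
                          panels: Sequence[HaplotypePanel]) -> list[dict]:
    """Per-pair genetic similarity (SNP-count-weighted across chromosomes)
    against the pedigree kinship coefficient."""
    samples = sorted(set.intersection(
        *[set(p.samples) for p in panels])) if panels else []
    genotyped = [s for s in samples
                 if s in ped.individuals and ped.individuals[s].genotyped]
    rows: list[dict] = []
    weights = np.array([p.n_snps for p in panels], dtype=float)
    for i in range(len(genotyped)):
        for j in range(i + 1, len(genotyped)):
            a, b = genotyped[i], genotyped[j]
            sims = []
            for p in panels:
                sims.append(individual_similarity(
                    (p.get((a, 0)), p.get((a, 1))),
                    (p.get((b, 0)), p.get((b, 1)))))
            sim = float(np.average(sims, weights=weights))
            rows.append({"a": a, "b": b,
                         "kinship": kinship(ped, a, b),
                         "similarity": sim})
    return rows


@dataclass
class LeaveOneOutOutcome:
    target: str
    reconstructed: bool
    similarity: float | None
    status: str


def leave_one_out(ped: Pedigree, truth: TruthSet, cfg: SimConfig,
                  target: str,
                  config: ThreadConfig | None = None) -> LeaveOneOutOutcome:
    """Withhold one genotyped individual, rebuild the true-IBD input
    without them, reconstruct, and score against the withheld truth.

    The withheld haplotypes are consulted only for the final similarity.
    Refuses targets without genotyped descendants (nothing downstream
    could vouch for them).
    """
    if not ped.individuals[target].genotyped:
        raise ValueError(f"target {target!r} is not genotyped")
    if not genotyped_descendants(ped, target):
        raise ValueError(
            f"target {target!r} has no genotyped descendants; refusing"
        )
    keep = sorted(ped.genotyped_ids() - {target})
    panel = truth.to_panel(ped, genotyped_only=True).drop_samples([target])
    segments = true_ibd_segments(truth, ped, min_cm=cfg.min_cm, genotyped=keep)
    # hide the genotyped flag of the target from the run
    import copy
    from dataclasses import replace as dc_replace
    ped2 = copy.deepcopy(ped)
    ped2.individuals[target] = dc_replace(ped2.individuals[target],
                                          genotyped=False)
    ped2._invalidate()
    result = run_thread(ped2, panel, segments, config)
    asm = result.assemblies.get(target)
    status = asm.status if asm is not None else "unresolved"
    if target in result.haplotypes:
        sim = individual_similarity(
            result.haplotypes[target],
            (truth.haplotypes[(target, 0)], truth.haplotypes[(target, 1)]))
        return LeaveOneOutOutcome(target, True, sim, status)
    return LeaveOneOutOutcome(target, False, None, status)


def lost_regions(coverage_masks: Sequence[np.ndarray], positions: np.ndarray,
                 window: int = 50, frac: float = 0.4,
                 ) -> list[dict]:
    """Windowed scan for regions reconstructed in unusually few individuals.

    ``coverage_masks`` holds one boolean array per target individual (True
    where that individual's reconstruction covers the SNP).  A
    non-overlapping window of ``window`` SNPs is flagged when the fraction
    of individuals whose reconstruction covers it (majority of its sites)
    is below ``frac``; adjacent flagged windows are merged and telomeric
    (chromosome-end) regions are annotated.
    """
    if not coverage_masks:
        raise ValueError("need at least one reconstruction")
    S = len(positions)
    n_win = (S + window - 1) // window
    flagged: list[tuple[int, int, float]] = []
    for w in range(n_win):
        s, e = w * window, min((w + 1) * window, S)
        fracs = [float(m[s:e].mean()) for m in coverage_masks]
        covered = np.mean([f >= 0.5 for f in fracs])
        if covered < frac:
            flagged.append((s, e, float(covered)))
    merged: list[dict] = []
    for s, e, cov in flagged:
        if merged and merged[-1]["end"] == s:
            merged[-1]["end"] = e
            merged[-1]["fraction"] = min(merged[-1]["fraction"], cov)
        else:
            merged.append({"start": s, "end": e, "fraction": cov})
    for region in merged:
        region["start_bp"] = int(positions[region["start"]])
        region["end_bp"] = int(positions[region["end"] - 1])
        region["telomeric"] = region["start"] == 0 or region["end"] == S
    return merged


def jaccard_consistency(flags: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Pairwise Jaccard coefficients between per-chromosome reconstructed
    flags (equal-length binary vectors over the same individuals)."""
    keys = sorted(flags)
    out: dict[tuple[str, str], float] = {}
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a = np.asarray(flags[keys[i]], dtype=bool)
            b = np.asarray(flags[keys[j]], dtype=bool)
            if a.shape != b.shape:
                raise ValueError("flag vectors must have equal length")
            union = int((a | b).sum())
            inter = int((a & b).sum())
            out[(keys[i], keys[j])] = inter / union if union else 1.0
    return out


def mean_ibd_coverage(segments: Iterable, individual_targets: dict[str, set[str]],
                      n_snps: int) -> dict[str, float]:
    """Average per-base (per-SNP) depth of placed IBD segments per individual."""
    seg_by_id = {s.id: s for s in segments}
    out: dict[str, float] = {}
    for ind, seg_ids in individual_targets.items():
        depth = 0
        for sid in seg_ids:
            seg = seg_by_id[sid]
            depth += seg.n_snps
        out[ind] = depth / n_snps if n_snps else 0.0
    return out


def prediction_filter(generation: int, coverage: float,
                      g_min: int = 8, c_min: float = 1.0) -> bool:
    """Heuristic predictor of a well-reconstructed individual: recent
    generation and high average per-base IBD coverage."""
    return generation >= g_min and coverage >= c_min
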