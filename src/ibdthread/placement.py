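"""Source selection and IBD segment placement.

Two selectors choose a source for a segment among the candidates: the
greedy "min path" rule (fewest descendance paths first) and the
probabilistic "max prob" rule, which ranks candidates by the probability
that the segment is transmitted intact from the source to every cohort
member.  The per-meiosis factor is q = exp(-l) / 2 for a segment of
genetic length l Morgans (a fair strand coin times the Haldane no-crossover
probability); multiple routes are combined exactly by summing over
transmission outcomes on the descent DAG, with a best-single-path lower
bound when the DAG is too large.  Non-cohort carriers are deliberately not
penalised, so this is a transmission probability, not a configuration
likelihood.

Placement gives the segment to every individual on all descendance paths
from the chosen source; if any such individual already has fixed
haplotypes and the segment disagrees with both, the source is rejected.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .ibdio import IBDSegment
from .pedigree import Pedigree
from .sources import SourceCandidate, _source_children

__all__ = [
    "PlacementState",
    "select_source_min_path",
    "select_source_max_prob",
    "transmission_probability",
    "place_segment",
]

CandidateKey = tuple[str, ...]


@dataclass
class PlacementState:
    """Mutable record of segment-to-source assignments and per-individual
    placed segments; rejected sets only ever grow (the termination
    argument of the outer loop)."""

    chosen: dict[str, CandidateKey] = field(default_factory=dict)
    rejected: dict[str, set[CandidateKey]] = field(default_factory=dict)
    placed: dict[str, set[str]] = field(default_factory=dict)   # individual -> seg ids
    targets: dict[str, frozenset[str]] = field(default_factory=dict)  # seg -> individuals
    # per (individual, segment): through which of the individual's parents
    # the segment can have arrived from its chosen source
    sides: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    def reject(self, seg_id: str, key: CandidateKey) -> None:
        self.rejected.setdefault(seg_id, set()).add(key)

    def is_rejected(self, seg_id: str, key: CandidateKey) -> bool:
        return key in self.rejected.get(seg_id, set())

    def unplace(self, seg_id: str) -> None:
        for ind in self.targets.pop(seg_id, frozenset()):
            self.placed.get(ind, set()).discard(seg_id)
            self.sides.pop((ind, seg_id), None)
        self.chosen.pop(seg_id, None)

    def place(self, seg_id: str, key: CandidateKey,
              targets: frozenset[str],
              sides: dict[str, frozenset[str]] | None = None) -> None:
        self.chosen[seg_id] = key
        self.targets[seg_id] = targets
        for ind in targets:
            self.placed.setdefault(ind, set()).add(seg_id)
            if sides and ind in sides:
                self.sides[(ind, seg_id)] = sides[ind]


def select_source_min_path(cands: list[SourceCandidate],
                           rejected: set[CandidateKey]) -> SourceCandidate | None:
    """First non-rejected candidate in (d, generation desc, id) order;
    None when exhausted (the caller skips the segment)."""
    for cand in cands:
        if cand.key not in rejected:
            return cand
    return None


# ---------------------------------------------------------------------------
# Transmission probability
# ---------------------------------------------------------------------------

def _descent_dag(ped: Pedigree, cand: SourceCandidate,
                 cohort: frozenset[str]) -> tuple[list[str], list[tuple[str, str]]]:
    """Nodes and edges of the union of all descent chains from the source
    to the cohort.  The source is the virtual node ''."""
    allowed: set[str] = set()
    for c in cohort:
        allowed |= ped.ancestors(c)
        allowed.add(c)
    roots = [r for r in _source_children(ped, cand.members) if r in allowed]
    # keep only vertices that can still reach a cohort member
    reach_cohort: set[str] = set()

    def reaches(v: str) -> bool:
        if v in reach_cohort:
            return True
        if v in cohort:
            reach_cohort.add(v)
            return True
        ok = any(reaches(ch) for ch in ped.children(v) if ch in allowed)
        if ok:
            reach_cohort.add(v)
        return ok

    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    stack = [r for r in roots if reaches(r)]
    for r in stack:
        edges.add(("", r))
    while stack:
        v = stack.pop()
        if v in nodes:
            continue
        nodes.add(v)
        if v in cohort:
            continue
        for ch in ped.children(v):
            if ch in allowed and reaches(ch):
                edges.add((v, ch))
                stack.append(ch)
    return sorted(nodes), sorted(edges)


def transmission_probability(ped: Pedigree, cand: SourceCandidate,
                             cohort: frozenset[str] | set[str],
                             seg_len_morgans: float,
                             config_cap: int = 10_000) -> float:
    """Probability that every cohort member inherits the intact segment
    from the candidate source through at least one descendance path.

    Each parent-to-child transmission succeeds independently with
    q = exp(-l)/2; an individual carries the segment when at least one of
    its carrying parents transmits it.  Computed exactly by summing over
    all edge outcomes when 2^|E| <= ``config_cap``; otherwise falls back
    to the largest single-path product (a lower bound).
    """
    if seg_len_morgans < 0:
        raise ValueError("segment length must be non-negative")
    q = 0.5 * math.exp(-seg_len_morgans)
    cohort = frozenset(cohort)
    nodes, edges = _descent_dag(ped, cand, cohort)
    if not edges:
        return 0.0
    if 2 ** len(edges) > config_cap:
        return _best_single_path(ped, cand, cohort, q)

    children_of: dict[str, list[int]] = {}
    for idx, (u, _v) in enumerate(edges):
        children_of.setdefault(u, []).append(idx)
    # topological order over nodes starting from the virtual source
    order = [""]
    remaining = set(nodes)
    while remaining:
        progressed = False
        for v in sorted(remaining):
            parents = [u for (u, w) in edges if w == v]
            if all(u not in remaining for u in parents):
                order.append(v)
                remaining.discard(v)
                progressed = True
        if not progressed:  # pragma: no cover - DAG guaranteed upstream
            raise RuntimeError("cycle in descent DAG")

    total = 0.0
    E = len(edges)
    for outcome in itertools.product((True, False), repeat=E):
        carriers = {""}
        for v in order[1:]:
            for idx, (u, w) in enumerate(edges):
                if w == v and outcome[idx] and u in carriers:
                    carriers.add(v)
                    break
        if cohort <= carriers:
            s = sum(outcome)
            total += (q ** s) * ((1 - q) ** (E - s))
    return total


def _best_single_path(ped: Pedigree, cand: SourceCandidate,
                      cohort: frozenset[str], q: float) -> float:
    """q ** |edge union of the shortest chain per member| (lower bound)."""
    from .sources import _chains_to

    roots = _source_children(ped, cand.members)
    edges: set[tuple[str, str]] = set()
    for c in sorted(cohort):
        chains = _chains_to(ped, roots, c)
        if not chains:
            return 0.0
        best = min(chains, key=len)
        edges.add(("", best[0]))
        edges.update(zip(best, best[1:]))
    return q ** len(edges)


def select_source_max_prob(ped: Pedigree, cands: list[SourceCandidate],
                           cohort: frozenset[str] | set[str],
                           seg_len_morgans: float,
                           rejected: set[CandidateKey],
                           config_cap: int = 10_000) -> SourceCandidate | None:
    """Highest transmission-probability non-rejected candidate; ties break
    by (generation descending, id)."""
    best: tuple[float, int, CandidateKey] | None = None
    best_cand: SourceCandidate | None = None
    for cand in cands:
        if cand.key in rejected:
            continue
        p = transmission_probability(ped, cand, cohort, seg_len_morgans,
                                     config_cap)
        key = (-p, -cand.generation, cand.key)
        if best is None or key < best:
            best = key
            best_cand = cand
    return best_cand


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

def _conflicts_with_both(seg: IBDSegment, haps: tuple[np.ndarray, np.ndarray],
                         agreement: float, min_snps: int) -> bool:
    """True when the segment consensus disagrees with both fixed haplotypes
    over a sufficiently informative overlap."""
    best = -1.0
    informative = False
    for hap in haps:
        window = hap[seg.start:seg.end]
        ok = (window >= 0) & (seg.consensus >= 0)
        n = int(ok.sum())
        if n < min_snps:
            continue
        informative = True
        frac = float((window[ok] == seg.consensus[ok]).sum()) / n
        best = max(best, frac)
    return informative and best < agreement


def transmission_sides(ped: Pedigree, cand: SourceCandidate,
                       targets: Iterable[str]) -> dict[str, frozenset[str]]:
    """For each target individual, the subset of its parents through whom
    the segment can have arrived from the candidate source.

    A segment reaches an individual through a parent that is the source
    itself (couple member) or a descendant of it; a segment whose source
    is an ancestor only on the paternal side must lie on the paternal
    haplotype.  Used by grouping as a Mendelian consistency constraint.
    """
    reach: set[str] = set(cand.members)
    for m in cand.members:
        reach |= ped.descendants(m)
    out: dict[str, frozenset[str]] = {}
    for ind in targets:
        out[ind] = frozenset(p for p in ped.parents(ind) if p in reach)
    return out


def place_segment(state: PlacementState, seg: IBDSegment,
                  cand: SourceCandidate,
                  reconstructions: dict[str, tuple[np.ndarray, np.ndarray]],
                  agreement: float = 0.98, min_snps: int = 50,
                  ped: Pedigree | None = None) -> bool:
    """Place ``seg`` under ``cand`` into every individual on all paths.

    If a target already has fixed haplotypes and the segment conflicts
    with both, the candidate is added to the segment's rejected set and
    nothing is placed; returns False in that case.  When ``ped`` is
    given, the parental side of each placement is recorded for the
    grouping stage.
    """
    if state.is_rejected(seg.id, cand.key):
        raise ValueError(f"candidate {cand.label()} already rejected for {seg.id}")
    targets = frozenset(cand.on_all_paths)
    for ind in sorted(targets):
        fixed = reconstructions.get(ind)
        if fixed is not None and _conflicts_with_both(seg, fixed,
                                                      agreement, min_snps):
            state.reject(seg.id, cand.key)
            return False
    sides = transmission_sides(ped, cand, targets) if ped is not None else None
    state.place(seg.id, cand.key, targets, sides)
    return True
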