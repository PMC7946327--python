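"""Enumerate possible sources of an IBD segment shared by a cohort.

An IBD segment shared by a cohort of genotyped individuals must descend
from a common ancestor (individual or couple).  The number of distinct
*descendance paths* — sets of parent->child transmissions carrying the
segment from the source to every cohort member — grows exponentially with
pedigree depth, so candidates are found with a multiset sweep rather than
explicit enumeration: each ancestor ``p`` carries a multiset over cohort
members whose multiplicity ``m_p(c)`` is the number of distinct descent
chains from ``p`` down to member ``c`` (the concatenation of the children's
multisets).  An ancestor whose multiset contains every member is a
candidate source, with path count

    d(s) = prod over members c of m_s(c).

Two post-processing passes follow: (1) *trimming* — an ancestor whose
multiset cardinality equals the maximum cardinality among its children's
multisets contributes no route absent from that child and is redundant;
(2) *couple merging* — spouses with identical multisets are collapsed into
a single couple source (remarriage makes the cardinalities differ, in
which case the individual source is kept).

Explicit path enumeration is retained as a bounded facility and as the
oracle for the multiset arithmetic.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .pedigree import Pedigree

__all__ = [
    "SourceCandidate",
    "DescentPath",
    "find_sources",
    "count_paths",
    "enumerate_paths",
    "individuals_on_all_paths",
    "individuals_on_all_paths_all_sources",
    "PathCapExceeded",
]


class PathCapExceeded(RuntimeError):
    """Raised when explicit enumeration would exceed the requested cap."""


@dataclass(frozen=True)
class SourceCandidate:
    """A putative source: one individual or a couple, with its route multiset."""

    members: tuple[str, ...]              # one id, or two ids sorted
    multiset: tuple[tuple[str, int], ...]  # sorted (member -> multiplicity)
    d: int                                 # product of multiplicities
    on_all_paths: frozenset[str]           # intermediates on every descendance path
    generation: int = 0

    @property
    def key(self) -> tuple[str, ...]:
        return self.members

    @property
    def is_couple(self) -> bool:
        return len(self.members) == 2

    def multiplicity(self, member: str) -> int:
        return dict(self.multiset).get(member, 0)

    def label(self) -> str:
        return "+".join(self.members)


@dataclass(frozen=True)
class DescentPath:
    """One way a segment reaches every cohort member: a set of transmissions."""

    source: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    @property
    def individuals(self) -> frozenset[str]:
        virtual = "+".join(self.source) if len(self.source) > 1 else None
        nodes = set(self.source)
        for u, v in self.edges:
            if u != virtual:
                nodes.add(u)
            nodes.add(v)
        return frozenset(nodes)


# ---------------------------------------------------------------------------
# Multiset sweep
# ---------------------------------------------------------------------------

def _chain_multisets(ped: Pedigree, cohort: frozenset[str]) -> dict[str, Counter]:
    """For every ancestor of the cohort, the Counter of descent-chain counts
    to each cohort member (cohort members count one chain to themselves)."""
    relevant = set(cohort)
    for c in cohort:
        relevant |= ped.ancestors(c)

    multi: dict[str, Counter] = {}

    def resolve(ident: str) -> Counter:
        if ident in multi:
            return multi[ident]
        stack = [ident]
        while stack:
            cur = stack[-1]
            if cur in multi:
                stack.pop()
                continue
            kids = [ch for ch in ped.children(cur)
                    if ch in relevant or ch in cohort]
            pending = [ch for ch in kids if ch not in multi]
            if pending:
                stack.extend(pending)
                continue
            stack.pop()
            acc: Counter = Counter()
            if cur in cohort:
                acc[cur] += 1
            for ch in kids:
                acc.update(multi[ch])
            multi[cur] = acc
        return multi[ident]

    for ident in relevant:
        resolve(ident)
    return multi


def _source_children(ped: Pedigree, members: tuple[str, ...]) -> list[str]:
    """The children through whom a source's descent chains start."""
    if len(members) == 1:
        return sorted(ped.children(members[0]))
    a, b = members
    return sorted(ped.shared_children(a, b))


def _downward_counts(ped: Pedigree, roots: Iterable[str],
                     relevant: set[str]) -> dict[str, int]:
    """Number of descent chains from a virtual source (with children
    ``roots``) to each reachable relevant individual."""
    counts: dict[str, int] = {}
    order = _topo_down(ped, roots, relevant)
    root_set = set(roots)
    for v in order:
        base = 1 if v in root_set else 0
        total = base + sum(counts.get(u, 0) for u in ped.parents(v)
                           if u in counts)
        counts[v] = total
    return counts


def _topo_down(ped: Pedigree, roots: Iterable[str],
               relevant: set[str]) -> list[str]:
    """Topological order (parents before children) of relevant individuals
    reachable downward from ``roots``."""
    reach: set[str] = set()
    stack = [r for r in roots if r in relevant]
    while stack:
        v = stack.pop()
        if v in reach:
            continue
        reach.add(v)
        stack.extend(ch for ch in ped.children(v) if ch in relevant)
    out: list[str] = []
    seen: set[str] = set()

    def visit(v: str) -> None:
        stk = [(v, False)]
        while stk:
            node, done = stk.pop()
            if done:
                out.append(node)
                continue
            if node in seen:
                continue
            seen.add(node)
            stk.append((node, True))
            for p in ped.parents(node):
                if p in reach and p not in seen:
                    stk.append((p, False))

    for v in sorted(reach):
        visit(v)
    return out


def _on_all_paths(ped: Pedigree, members: tuple[str, ...],
                  cohort: frozenset[str],
                  multi: dict[str, Counter]) -> frozenset[str]:
    """Intermediates present on every descendance path from the source.

    A vertex v lies on all paths iff, for some cohort member c, every
    descent chain source->c passes through v; which holds exactly when
    chains(source->v) * chains(v->c) == chains(source->c) (exact integer
    counts; a chain cannot visit v twice in a DAG).
    """
    roots = _source_children(ped, members)
    relevant = set(multi)
    down = _downward_counts(ped, roots, relevant)
    src_multi = _merged_multiset(ped, members, multi)
    out: set[str] = set()
    for c in cohort:
        total = src_multi.get(c, 0)
        if total == 0:
            continue
        for v, dv in down.items():
            if v in cohort or v in members:
                continue
            mv = multi.get(v, Counter()).get(c, 0)
            if mv and dv * mv == total:
                out.add(v)
    return frozenset(out)


def _merged_multiset(ped: Pedigree, members: tuple[str, ...],
                     multi: dict[str, Counter]) -> Counter:
    """The source's own multiset: for couples, chains run through the
    shared children only (the spouses' multisets are identical under the
    merge criterion, so this normally equals either one)."""
    if len(members) == 1:
        return multi[members[0]]
    acc: Counter = Counter()
    for ch in _source_children(ped, members):
        if ch in multi:
            acc.update(multi[ch])
    return acc


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def find_sources(ped: Pedigree, cohort: Iterable[str],
                 generations: dict[str, int] | None = None
                 ) -> list[SourceCandidate]:
    """All possible sources (individuals or couples) of a segment shared by
    ``cohort``, after trimming redundant ancestors and merging couples.

    Returns candidates sorted by (d ascending, generation descending, id),
    the order in which the greedy "min path" selector consumes them.
    Returns an empty list when the cohort has no common ancestor.
    """
    cohort = frozenset(cohort)
    if len(cohort) < 2:
        raise ValueError("cohort must contain at least two individuals")
    for c in cohort:
        ped[c]

    multi = _chain_multisets(ped, cohort)

    # candidate individuals: multiset covers the whole cohort; never cohort
    # members themselves, never descendants of a cohort member
    cands: list[str] = []
    for ident, ms in multi.items():
        if ident in cohort:
            continue
        if all(ms.get(c, 0) >= 1 for c in cohort):
            if any(ident in ped.descendants(c) for c in cohort):
                continue
            cands.append(ident)

    # (1) trim redundant ancestors
    surviving: list[str] = []
    for ident in cands:
        kid_cards = [sum(multi[ch].values()) for ch in ped.children(ident)
                     if ch in multi and multi[ch]]
        if kid_cards and sum(multi[ident].values()) == max(kid_cards):
            continue
        surviving.append(ident)

    # (2) merge couples with identical multisets
    surv = set(surviving)
    merged: list[tuple[str, ...]] = []
    used: set[str] = set()
    for ident in sorted(surv):
        if ident in used:
            continue
        partner = None
        for sp in sorted(ped.spouses(ident)):
            if sp in surv and sp not in used and multi[sp] == multi[ident]:
                partner = sp
                break
        if partner is not None:
            used.add(ident)
            used.add(partner)
            merged.append(tuple(sorted((ident, partner))))
        else:
            used.add(ident)
            merged.append((ident,))

    gens = generations if generations is not None else {}
    out: list[SourceCandidate] = []
    for members in merged:
        ms = _merged_multiset(ped, members, multi)
        d = 1
        for c in cohort:
            d *= ms[c]
        on_all = _on_all_paths(ped, members, cohort, multi)
        gen = max((gens.get(m, 0) for m in members), default=0)
        out.append(SourceCandidate(
            members=members,
            multiset=tuple(sorted((c, ms[c]) for c in cohort)),
            d=d,
            on_all_paths=on_all,
            generation=gen,
        ))
    out.sort(key=lambda s: (s.d, -s.generation, s.members))
    return out


def count_paths(cand: SourceCandidate) -> int:
    """Total number of descendance paths from the source to the cohort."""
    d = 1
    for _, mult in cand.multiset:
        d *= mult
    return d


def _chains_to(ped: Pedigree, roots: list[str], member: str) -> list[tuple[str, ...]]:
    """All descent chains from a virtual source (children ``roots``) to
    ``member``, as node tuples ending at the member."""
    chains: list[tuple[str, ...]] = []

    allowed = ped.ancestors(member) | {member}

    def dfs(node: str, acc: list[str]) -> None:
        acc.append(node)
        if node == member:
            chains.append(tuple(acc))
        else:
            for ch in sorted(ped.children(node)):
                if ch in allowed:
                    dfs(ch, acc)
        acc.pop()

    for r in roots:
        if r in allowed:
            dfs(r, [])
    return chains


def enumerate_paths(ped: Pedigree, cand: SourceCandidate,
                    cohort: Iterable[str], cap: int = 10_000
                    ) -> list[DescentPath]:
    """Explicitly enumerate descendance paths (cross-product of per-member
    descent chains, deduplicated as transmission-edge sets).

    Raises :class:`PathCapExceeded` when d exceeds ``cap``.
    """
    cohort = frozenset(cohort)
    if cand.d > cap:
        raise PathCapExceeded(
            f"source {cand.label()} has {cand.d} paths, exceeding cap {cap}"
        )
    roots = _source_children(ped, cand.members)
    per_member: list[list[tuple[str, ...]]] = []
    for c in sorted(cohort):
        chains = _chains_to(ped, roots, c)
        if not chains:
            return []
        per_member.append(chains)

    src = cand.members
    paths: set[frozenset[tuple[str, str]]] = set()
    ordered: list[DescentPath] = []
    for combo in itertools.product(*per_member):
        edges: set[tuple[str, str]] = set()
        for chain in combo:
            edges.add((src[0] if len(src) == 1 else "+".join(src), chain[0]))
            edges.update(zip(chain, chain[1:]))
        fs = frozenset(edges)
        if fs not in paths:
            paths.add(fs)
            ordered.append(DescentPath(source=src, edges=fs))
    return ordered


def individuals_on_all_paths(ped: Pedigree, cand: SourceCandidate,
                             cohort: Iterable[str]) -> set[str]:
    """Intermediate individuals lying on every descendance path from the
    candidate (excluding the cohort and the source members themselves)."""
    cohort = frozenset(cohort)
    multi = _chain_multisets(ped, cohort)
    return set(_on_all_paths(ped, cand.members, cohort, multi))


def individuals_on_all_paths_all_sources(cands: list[SourceCandidate]) -> set[str]:
    """Individuals on all paths from *all* sources: the intersection across
    candidates of on-all-paths sets (counting a couple's own members as on
    all of that couple's paths)."""
    if not cands:
        raise ValueError("need at least one source candidate")
    acc: set[str] | None = None
    for cand in cands:
        s = set(cand.on_all_paths) | set(cand.members)
        acc = s if acc is None else acc & s
    return acc or set()
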