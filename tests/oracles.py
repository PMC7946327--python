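"""Independent brute-force oracles for source finding.

Path counts are obtained by explicitly enumerating every descent chain
with a DFS (no multiset arithmetic), and on-all-paths sets by
intersecting the node sets of fully enumerated descendance paths — the
slow, obviously-correct counterpart of the production implementation.
"""

from __future__ import annotations

import itertools
from math import prod

from ibdthread.pedigree import Pedigree


def chains_down(ped: Pedigree, start: str, member: str) -> list[tuple[str, ...]]:
    """All child-edge chains from ``start`` (exclusive) ending at ``member``."""
    out: list[tuple[str, ...]] = []

    def dfs(node: str, acc: list[str]) -> None:
        if node == member:
            out.append(tuple(acc))
            return
        for ch in sorted(ped.children(node)):
            acc.append(ch)
            dfs(ch, acc)
            acc.pop()

    dfs(start, [])
    return out


def member_chains(ped: Pedigree, roots: list[str],
                  member: str) -> list[tuple[str, ...]]:
    chains = []
    for r in roots:
        if r == member:
            chains.append((r,))
        else:
            chains.extend((r,) + c for c in chains_down(ped, r, member))
    return chains


def oracle_sources(ped: Pedigree, cohort: frozenset[str], path_cap: int = 4000):
    """Candidate sources with path counts and on-all-paths sets, from
    explicit enumeration.  Returns (dict members->d, dict members->on_all)
    or None when some candidate exceeds ``path_cap`` paths."""
    counts: dict[str, dict[str, int]] = {}
    for ident in ped.individuals:
        if ident in cohort:
            continue
        if any(ident in ped.descendants(c) for c in cohort):
            continue
        per = {c: len(member_chains(ped, sorted(ped.children(ident)), c))
               for c in cohort}
        if all(v >= 1 for v in per.values()):
            counts[ident] = per

    def card(x: str) -> int:
        # multiset cardinality: total number of chains from x to the cohort
        # (a cohort member counts one chain to itself)
        return sum(len(member_chains(ped, [x], c)) for c in cohort)

    # trim: cardinality equal to the max cardinality among children
    surviving = []
    for ident in counts:
        kid_cards = [card(ch) for ch in ped.children(ident)]
        kid_cards = [k for k in kid_cards if k > 0]
        if kid_cards and sum(counts[ident].values()) == max(kid_cards):
            continue
        surviving.append(ident)

    # merge couples with identical per-member counts
    merged: list[tuple[str, ...]] = []
    used: set[str] = set()
    surv = set(surviving)
    for ident in sorted(surv):
        if ident in used:
            continue
        partner = None
        for sp in sorted(ped.spouses(ident)):
            if sp in surv and sp not in used and counts[sp] == counts[ident] \
                    and sum(counts[sp].values()) == sum(counts[ident].values()):
                partner = sp
                break
        if partner is not None:
            used.update((ident, partner))
            merged.append(tuple(sorted((ident, partner))))
        else:
            used.add(ident)
            merged.append((ident,))

    d_map: dict[tuple[str, ...], int] = {}
    on_all: dict[tuple[str, ...], set[str]] = {}
    for members in merged:
        if len(members) == 1:
            roots = sorted(ped.children(members[0]))
        else:
            roots = sorted(ped.shared_children(*members))
        per_member = {c: member_chains(ped, roots, c) for c in sorted(cohort)}
        d = prod(len(v) for v in per_member.values())
        if d > path_cap:
            return None
        d_map[members] = d
        inter: set[str] | None = None
        for combo in itertools.product(*per_member.values()):
            nodes = set(itertools.chain.from_iterable(combo))
            inter = nodes if inter is None else inter & nodes
        assert inter is not None
        on_all[members] = inter - cohort - set(members)
    return d_map, on_all
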