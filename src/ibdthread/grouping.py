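"""Assemble the IBD segments placed in one individual into haplotype groups.

The segments placed in an individual should, if correctly sourced, split
into two internally consistent groups — the individual's two chromosome
copies.  Assembly is deterministic: homozygous regions are detected first
and seeded into both haplotypes, the remaining segments are assigned
greedily from longest to shortest (joining the best-agreeing overlapping
group, merging groups bridged by one segment), and finally groups that
line up end-to-end (separated by an ancestral recombination) are merged.
Groups are then graded as *strong* on a sliding scale of IBD count versus
SNP coverage, and the individual is classified reconstructed, partial, or
unresolved.  Segments that conflict with both haplotypes were mis-sourced
and are reported for re-sourcing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ibdio import IBDSegment, MISSING

__all__ = [
    "HaplotypeGroup",
    "IndividualAssembly",
    "StrongGroupPolicy",
    "DEFAULT_TIERS",
    "SETTING_A_TIERS",
    "SETTING_B_TIERS",
    "detect_homozygous_regions",
    "group_segments",
    "is_strong",
    "classify",
    "consensus_haplotypes",
]

# (min number of IBD segments, required coverage fraction); evaluated from
# the largest min_ibd_count downward
DEFAULT_TIERS = ((10, 0.50), (3, 0.70), (1, 0.90))
SETTING_A_TIERS = ((15, 0.50), (4, 0.70), (1, 0.90))
SETTING_B_TIERS = ((15, 0.50), (4, 0.60), (1, 0.70))


@dataclass(frozen=True)
class StrongGroupPolicy:
    """Coverage thresholds by IBD count, optionally stricter/looser for
    ancient generations (generation number <= ``ancient_max_generation``)."""

    tiers: tuple[tuple[int, float], ...] = DEFAULT_TIERS
    ancient_tiers: tuple[tuple[int, float], ...] | None = None
    ancient_max_generation: int = 7

    @classmethod
    def from_setting(cls, setting: str) -> "StrongGroupPolicy":
        if setting == "default":
            return cls()
        if setting == "A":
            return cls(ancient_tiers=SETTING_A_TIERS)
        if setting == "B":
            return cls(ancient_tiers=SETTING_B_TIERS)
        raise ValueError(f"unknown strong-group setting {setting!r}")

    def tiers_for(self, generation: int | None) -> tuple[tuple[int, float], ...]:
        if (self.ancient_tiers is not None and generation is not None
                and generation <= self.ancient_max_generation):
            return self.ancient_tiers
        return self.tiers


def _combine_sides(a: frozenset[str] | None,
                   b: frozenset[str] | None) -> frozenset[str] | None:
    if a is None:
        return b
    if b is None:
        return a
    return a & b


def _sides_compatible(a: frozenset[str] | None,
                      b: frozenset[str] | None) -> bool:
    combined = _combine_sides(a, b)
    return combined is None or len(combined) > 0


@dataclass
class HaplotypeGroup:
    """A set of mutually consistent segments with a per-site consensus."""

    n_sites: int
    members: list[str] = field(default_factory=list)
    votes0: np.ndarray | None = None
    votes1: np.ndarray | None = None
    strong: bool = False
    # the twin copy of a duplicated homozygous region; the two copies
    # stand for the two chromosomes and must never be merged together
    partner: "HaplotypeGroup | None" = None
    # which parents of the individual this group's segments can have come
    # through (None = unconstrained); a haplotype has a single parental
    # origin, so members' sides must share at least one parent
    allowed: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.votes0 is None:
            self.votes0 = np.zeros(self.n_sites, dtype=np.int32)
        if self.votes1 is None:
            self.votes1 = np.zeros(self.n_sites, dtype=np.int32)

    @property
    def covered(self) -> np.ndarray:
        return (self.votes0 + self.votes1) > 0

    @property
    def n_covered(self) -> int:
        return int(self.covered.sum())

    @property
    def n_segments(self) -> int:
        return len(self.members)

    def coverage(self) -> float:
        return self.n_covered / self.n_sites if self.n_sites else 0.0

    def consensus(self) -> np.ndarray:
        out = np.full(self.n_sites, MISSING, dtype=np.int8)
        out[self.votes1 > self.votes0] = 1
        out[(self.votes0 >= self.votes1) & (self.votes0 > 0)] = 0
        return out

    def span(self) -> tuple[int, int]:
        idx = np.nonzero(self.covered)[0]
        if idx.size == 0:
            return (0, 0)
        return int(idx[0]), int(idx[-1]) + 1

    def add(self, seg: IBDSegment,
            side: frozenset[str] | None = None) -> None:
        self.members.append(seg.id)
        sl = slice(seg.start, seg.end)
        self.votes0[sl] += (seg.consensus == 0)
        self.votes1[sl] += (seg.consensus == 1)
        self.allowed = _combine_sides(self.allowed, side)

    def add_region(self, start: int, end: int, consensus: np.ndarray) -> None:
        self.votes0[start:end] += (consensus == 0)
        self.votes1[start:end] += (consensus == 1)

    def absorb(self, other: "HaplotypeGroup") -> None:
        self.members.extend(other.members)
        self.votes0 += other.votes0
        self.votes1 += other.votes1
        self.allowed = _combine_sides(self.allowed, other.allowed)
        if other.partner is not None and other.partner is not self:
            if self.partner is None:
                self.partner = other.partner
            other.partner.partner = self

    def agreement(self, seg: IBDSegment) -> tuple[float, int]:
        """(agreeing fraction, #comparable SNPs) of a segment against the
        current group consensus."""
        cons = self.consensus()[seg.start:seg.end]
        ok = (cons >= 0) & (seg.consensus >= 0)
        n = int(ok.sum())
        if n == 0:
            return 0.0, 0
        return float((cons[ok] == seg.consensus[ok]).sum()) / n, n

    def agrees_with_group(self, other: "HaplotypeGroup",
                          agreement: float) -> bool:
        a, b = self.consensus(), other.consensus()
        ok = (a >= 0) & (b >= 0)
        n = int(ok.sum())
        if n == 0:
            return True
        return float((a[ok] == b[ok]).sum()) / n >= agreement


@dataclass
class IndividualAssembly:
    individual: str
    n_sites: int
    groups: list[HaplotypeGroup] = field(default_factory=list)
    status: str = "unresolved"   # reconstructed | partial | unresolved | homozygous
    rejected_segments: set[str] = field(default_factory=set)
    retained: tuple[int, int] | None = None   # indices of the two kept groups


# ---------------------------------------------------------------------------
# Homozygosity
# ---------------------------------------------------------------------------

def detect_homozygous_regions(segments: list[IBDSegment],
                              positions: np.ndarray,
                              min_bp: int = 300_000,
                              min_snps: int = 100) -> list[tuple[int, int]]:
    """Maximal SNP intervals covered by the pooled segments with a single
    allele at every site, spanning more than ``min_bp`` and at least
    ``min_snps``.  Each such region belongs on both chromosome copies."""
    S = len(positions)
    has0 = np.zeros(S, dtype=bool)
    has1 = np.zeros(S, dtype=bool)
    depth = np.zeros(S, dtype=np.int32)
    for seg in segments:
        sl = slice(seg.start, seg.end)
        has0[sl] |= (seg.consensus == 0)
        has1[sl] |= (seg.consensus == 1)
        depth[sl] += (seg.consensus >= 0)
    # one allele per site is only evidence of homozygosity where at least
    # two placed segments actually overlap
    mono = (has0 ^ has1) & (depth >= 2)
    out: list[tuple[int, int]] = []
    i = 0
    while i < S:
        if not mono[i]:
            i += 1
            continue
        j = i
        while j < S and mono[j]:
            j += 1
        span = int(positions[j - 1] - positions[i])
        if span > min_bp and (j - i) >= min_snps:
            out.append((i, j))
        i = j
    return out


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def group_segments(individual: str, segments: list[IBDSegment],
                   n_sites: int, positions: np.ndarray,
                   policy: StrongGroupPolicy | None = None,
                   generation: int | None = None,
                   agreement: float = 0.98, min_snps: int = 50,
                   lineup_max_gap: int = 50,
                   hom_min_bp: int = 300_000, hom_min_snps: int = 100,
                   accept_full_homozygous: bool = False,
                   sides: dict[str, frozenset[str]] | None = None,
                   ) -> IndividualAssembly:
    """Deterministically assemble placed segments into haplotype groups and
    classify the individual (see module docstring for the stages)."""
    policy = policy or StrongGroupPolicy()
    asm = IndividualAssembly(individual=individual, n_sites=n_sites)
    if not segments:
        classify(asm, policy, generation, accept_full_homozygous)
        return asm

    hom = detect_homozygous_regions(segments, positions, hom_min_bp, hom_min_snps)
    groups: list[HaplotypeGroup] = []
    withheld: set[str] = set()
    if hom:
        pooled0 = np.zeros(n_sites, dtype=np.int32)
        pooled1 = np.zeros(n_sites, dtype=np.int32)
        for seg in segments:
            sl = slice(seg.start, seg.end)
            pooled0[sl] += (seg.consensus == 0)
            pooled1[sl] += (seg.consensus == 1)
        cons = np.full(n_sites, MISSING, dtype=np.int8)
        cons[pooled1 > pooled0] = 1
        cons[(pooled0 >= pooled1) & (pooled0 > 0)] = 0
        g1 = HaplotypeGroup(n_sites)
        g2 = HaplotypeGroup(n_sites)
        g1.partner = g2
        g2.partner = g1
        for (s, e) in hom:
            g1.add_region(s, e, cons[s:e])
            g2.add_region(s, e, cons[s:e])
        for seg in segments:
            if any(seg.start >= s and seg.end <= e for (s, e) in hom):
                withheld.add(seg.id)
                g1.members.append(seg.id)
                g2.members.append(seg.id)
        groups.extend([g1, g2])

    sides = sides or {}
    order = sorted(segments,
                   key=lambda g: (-(g.end_bp - g.start_bp), g.start, g.id))
    for seg in order:
        if seg.id in withheld:
            continue
        side = sides.get(seg.id)
        qualifying: list[int] = []
        conflicting = 0
        for gi, grp in enumerate(groups):
            frac, n = grp.agreement(seg)
            if n >= min_snps:
                if frac >= agreement:
                    if _sides_compatible(grp.allowed, side):
                        qualifying.append(gi)
                    # a sequence-consistent but side-incompatible group is
                    # simply the other chromosome; neither join nor conflict
                else:
                    conflicting += 1
        if not qualifying:
            if conflicting >= 2:
                # conflicts with both putative haplotypes: mis-sourced
                asm.rejected_segments.add(seg.id)
            else:
                # disagreeing with at most one group, it may simply be the
                # other chromosome: open a new group
                grp = HaplotypeGroup(n_sites)
                grp.add(seg, side)
                groups.append(grp)
            continue
        if len(qualifying) > 1:
            # bridge: merge the groups this segment is consistent with,
            # provided they do not contradict each other and are not the
            # two copies of a duplicated homozygous region
            keep = qualifying[0]
            for gi in qualifying[1:]:
                if groups[gi] is groups[keep].partner:
                    continue
                if groups[keep].agrees_with_group(groups[gi], agreement) \
                        and _sides_compatible(groups[keep].allowed,
                                              groups[gi].allowed):
                    groups[keep].absorb(groups[gi])
                    groups[gi] = None  # type: ignore[call-overload]
            groups[keep].add(seg, side)
            groups = [g for g in groups if g is not None]
        else:
            groups[qualifying[0]].add(seg, side)

    groups = _lineup_merge(groups, agreement, lineup_max_gap)
    groups = [g for g in groups if g.n_covered > 0]
    groups.sort(key=lambda g: (-g.n_covered, -g.n_segments, g.span()))
    asm.groups = groups
    classify(asm, policy, generation, accept_full_homozygous)
    return asm


def _lineup_merge(groups: list[HaplotypeGroup], agreement: float,
                  max_gap: int) -> list[HaplotypeGroup]:
    """Merge non-overlapping groups whose covered ranges are adjacent
    (at most ``max_gap`` genotyped SNPs in between) — segments separated
    by an ancestral recombination event."""
    changed = True
    while changed:
        changed = False
        groups = sorted(groups, key=lambda g: g.span())
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                si, ei = groups[i].span()
                sj, ej = groups[j].span()
                if ei <= sj:
                    gap = sj - ei
                elif ej <= si:
                    gap = si - ej
                else:
                    continue
                if gap <= max_gap and groups[j] is not groups[i].partner \
                        and _sides_compatible(groups[i].allowed,
                                              groups[j].allowed) \
                        and groups[i].agrees_with_group(groups[j], agreement):
                    groups[i].absorb(groups[j])
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return groups


def is_strong(group: HaplotypeGroup, n_sites: int,
              policy: StrongGroupPolicy | None = None,
              generation: int | None = None) -> bool:
    """Apply the sliding IBD-count / coverage scale."""
    policy = policy or StrongGroupPolicy()
    n = group.n_segments
    if n == 0 or n_sites == 0:
        return False
    cov = group.n_covered / n_sites
    for min_count, required in policy.tiers_for(generation):
        if n >= min_count:
            return cov >= required
    return False


def classify(asm: IndividualAssembly, policy: StrongGroupPolicy | None = None,
             generation: int | None = None,
             accept_full_homozygous: bool = False) -> IndividualAssembly:
    """Grade groups and set the assembly status.

    Reconstructed requires exactly two strong groups, or two strong groups
    plus only weak ones each having at most half the IBD count or half the
    covered length of the weaker strong group; the weak groups' segments
    are rejected for re-sourcing.  One strong group is partial; a single
    group covering everything is flagged homozygous (a distinct status
    unless ``accept_full_homozygous``).
    """
    policy = policy or StrongGroupPolicy()
    for g in asm.groups:
        g.strong = is_strong(g, asm.n_sites, policy, generation)
    strong = [i for i, g in enumerate(asm.groups) if g.strong]
    weak = [i for i, g in enumerate(asm.groups) if not g.strong]

    if len(asm.groups) == 1 and asm.n_sites and \
            asm.groups[0].n_covered == asm.n_sites:
        asm.status = "reconstructed" if accept_full_homozygous else "homozygous"
        asm.retained = (0, 0) if accept_full_homozygous else None
        return asm

    if len(strong) == 2:
        g1, g2 = asm.groups[strong[0]], asm.groups[strong[1]]
        a, b = g1.allowed, g2.allowed
        if a is not None and b is not None and len(a | b) < 2:
            # both strong groups can only be the same parent's haplotype:
            # one of them must be mis-sourced — discard the weaker
            drop = strong[1] if (g2.n_covered, g2.n_segments) <= \
                (g1.n_covered, g1.n_segments) else strong[0]
            asm.rejected_segments.update(asm.groups[drop].members)
            asm.groups[drop].strong = False
            asm.status = "partial"
            return asm
        weaker = min((asm.groups[i] for i in strong),
                     key=lambda g: (g.n_covered, g.n_segments))
        ok = all(
            asm.groups[i].n_segments * 2 <= weaker.n_segments
            or asm.groups[i].n_covered * 2 <= weaker.n_covered
            for i in weak
        )
        if ok:
            asm.status = "reconstructed"
            asm.retained = (strong[0], strong[1])
            for i in weak:
                asm.rejected_segments.update(asm.groups[i].members)
            return asm
        asm.status = "unresolved"
        return asm
    if len(strong) == 1:
        asm.status = "partial"
    else:
        asm.status = "unresolved"
    return asm


def consensus_haplotypes(asm: IndividualAssembly
                         ) -> tuple[np.ndarray, np.ndarray]:
    """The two retained haplotype sequences (missing where uncovered)."""
    if asm.status != "reconstructed" or asm.retained is None:
        raise ValueError(
            f"individual {asm.individual} is not reconstructed "
            f"(status {asm.status!r})"
        )
    i, j = asm.retained
    return asm.groups[i].consensus(), asm.groups[j].consensus()
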