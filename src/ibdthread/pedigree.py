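"""Pedigree structure, structural queries, and kinship/inbreeding coefficients.

The pedigree file dialect is a whitespace/tab-delimited table with five
columns per row::

    id  father_id  mother_id  sex  genotyped

where ``0`` denotes an unknown parent (founders and married-in individuals
have both parents unknown), ``sex`` is ``M``/``F``/``U`` (or ``1``/``2``/``0``),
and ``genotyped`` is ``0``/``1``.  This is a superset of PLINK ``.fam``
semantics with an explicit genotyped flag.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "parse_pedigree",
    "write_pedigree",
    "assign_generations",
    "kinship",
    "inbreeding",
    "genotyped_descendants",
]

MALE, FEMALE, UNKNOWN = "M", "F", "U"

_SEX_CODES = {
    "m": MALE, "1": MALE, "M": MALE,
    "f": FEMALE, "2": FEMALE, "F": FEMALE,
    "u": UNKNOWN, "0": UNKNOWN, "U": UNKNOWN,
}


class PedigreeError(ValueError):
    """Raised for malformed pedigree input (dangling parents, cycles, duplicates)."""


@dataclass(frozen=True)
class Individual:
    id: str
    father: str | None
    mother: str | None
    sex: str = UNKNOWN
    genotyped: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """A set of individuals with parent links forming a DAG.

    Loops (cycles in the undirected marriage graph, e.g. cousin marriages)
    are allowed and expected; cycles in the *directed* parent graph are not.
    """

    individuals: dict[str, Individual] = field(default_factory=dict)
    children_index: dict[str, set[str]] = field(default_factory=dict)

    # -- construction ------------------------------------------------------

    def add(self, ind: Individual) -> None:
        if ind.id in self.individuals:
            raise PedigreeError(f"duplicated individual id {ind.id!r}")
        self.individuals[ind.id] = ind
        self.children_index.setdefault(ind.id, set())
        for parent in (ind.father, ind.mother):
            if parent is not None:
                self.children_index.setdefault(parent, set()).add(ind.id)
        self._invalidate()

    def _invalidate(self) -> None:
        self.__dict__.pop("_depth_cache", None)
        self.__dict__.pop("_kinship_cache", None)

    def validate(self) -> None:
        for ind in self.individuals.values():
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self.individuals:
                    raise PedigreeError(
                        f"individual {ind.id!r} references unknown parent {parent!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Kahn's algorithm on parent->child edges.
        indeg = {i: 0 for i in self.individuals}
        for ind in self.individuals.values():
            n = sum(1 for p in (ind.father, ind.mother)
                    if p is not None and p in self.individuals)
            indeg[ind.id] = n
        queue = deque(i for i, d in indeg.items() if d == 0)
        seen = 0
        while queue:
            i = queue.popleft()
            seen += 1
            for ch in self.children_index.get(i, ()):
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if seen != len(self.individuals):
            cyclic = sorted(i for i, d in indeg.items() if d > 0)
            raise PedigreeError(f"cycle in parent graph involving {cyclic[:5]}")

    # -- queries -----------------------------------------------------------

    def __contains__(self, ident: str) -> bool:
        return ident in self.individuals

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, ident: str) -> Individual:
        try:
            return self.individuals[ident]
        except KeyError:
            raise KeyError(f"unknown individual id {ident!r}") from None

    def parents(self, ident: str) -> tuple[str, ...]:
        ind = self[ident]
        return tuple(p for p in (ind.father, ind.mother) if p is not None)

    def children(self, ident: str) -> set[str]:
        self[ident]
        return self.children_index.get(ident, set())

    def spouses(self, ident: str) -> set[str]:
        """Co-parents: individuals sharing at least one child with ``ident``."""
        out: set[str] = set()
        for ch in self.children(ident):
            for p in self.parents(ch):
                if p != ident:
                    out.add(p)
        return out

    def shared_children(self, a: str, b: str) -> set[str]:
        return self.children(a) & self.children(b)

    def ancestors(self, ident: str) -> set[str]:
        """All strict ancestors of ``ident``."""
        out: set[str] = set()
        stack = list(self.parents(ident))
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents(p))
        return out

    def descendants(self, ident: str) -> set[str]:
        """All strict descendants of ``ident``."""
        out: set[str] = set()
        stack = list(self.children(ident))
        while stack:
            c = stack.pop()
            if c not in out:
                out.add(c)
                stack.extend(self.children(c))
        return out

    def is_ancestor(self, a: str, b: str) -> bool:
        """True if ``a`` is a strict ancestor of ``b``."""
        return b in self.descendants(a)

    def founders(self) -> list[str]:
        return [i for i, ind in self.individuals.items() if ind.is_founder]

    def genotyped_ids(self) -> set[str]:
        return {i for i, ind in self.individuals.items() if ind.genotyped}

    # -- counts (t / n / m) ------------------------------------------------

    @property
    def t(self) -> int:
        """Total number of individuals."""
        return len(self.individuals)

    @property
    def n(self) -> int:
        """Number of genotyped individuals."""
        return sum(1 for ind in self.individuals.values() if ind.genotyped)

    @property
    def m(self) -> int:
        """Number of ungenotyped individuals with at least one genotyped descendant."""
        count = 0
        for ident, ind in self.individuals.items():
            if not ind.genotyped and genotyped_descendants(self, ident):
                count += 1
        return count

    # -- depth (max distance from a founder), used by kinship --------------

    def _depth(self, ident: str) -> int:
        cache: dict[str, int] = self.__dict__.setdefault("_depth_cache", {})
        if ident in cache:
            return cache[ident]
        # iterative post-order to avoid recursion limits on deep pedigrees
        stack = [ident]
        while stack:
            cur = stack[-1]
            parents = self.parents(cur)
            pending = [p for p in parents if p not in cache]
            if pending:
                stack.extend(pending)
                continue
            stack.pop()
            cache[cur] = 1 + max((cache[p] for p in parents), default=-1)
        return cache[ident]


# ---------------------------------------------------------------------------
# Parsing / writing
# ---------------------------------------------------------------------------

def parse_pedigree(stream: IO[str] | Iterable[str]) -> Pedigree:
    """Parse the 5-column pedigree dialect; ``0`` means unknown parent.

    Raises :class:`PedigreeError` on duplicated ids, dangling parent
    references, or directed cycles among parent edges.
    """
    ped = Pedigree()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 5:
            raise PedigreeError(f"line {lineno}: expected 5 columns, got {len(fields)}")
        ident, father, mother, sex, geno = fields[:5]
        ped.add(Individual(
            id=ident,
            father=None if father == "0" else father,
            mother=None if mother == "0" else mother,
            sex=_SEX_CODES.get(sex, UNKNOWN),
            genotyped=geno not in ("0", "", "-"),
        ))
    ped.validate()
    return ped


def write_pedigree(ped: Pedigree, stream: IO[str]) -> None:
    """Emit the identical 5-column dialect accepted by :func:`parse_pedigree`."""
    for ind in ped.individuals.values():
        stream.write(
            f"{ind.id}\t{ind.father or 0}\t{ind.mother or 0}\t"
            f"{ind.sex}\t{1 if ind.genotyped else 0}\n"
        )


# ---------------------------------------------------------------------------
# Generations
# ---------------------------------------------------------------------------

def assign_generations(ped: Pedigree) -> dict[str, int]:
    """Assign a positive generation number to every individual.

    Founders are generation 1; a non-founder's generation is one more than
    the maximum of its parents' generations; married-in individuals (no
    recorded parents but with a spouse) carry the generation of their
    spouse (ties resolve to the maximum).  Computed by fixed-point
    iteration, which handles chains of married-in individuals.
    """
    gen: dict[str, int] = {}
    for ident, ind in ped.individuals.items():
        if ind.is_founder and not ped.spouses(ident) and not ped.children(ident):
            warnings.warn(
                f"individual {ident!r} has no parents, spouse or children; "
                "assigned generation 1"
            )
            gen[ident] = 1

    changed = True
    while changed:
        changed = False
        for ident, ind in ped.individuals.items():
            if ind.is_founder:
                spouse_gens = [gen[s] for s in ped.spouses(ident) if s in gen
                               and not ped.individuals[s].is_founder]
                new = max(spouse_gens) if spouse_gens else 1
            else:
                parent_gens = [gen[p] for p in ped.parents(ident) if p in gen]
                if len(parent_gens) < len(ped.parents(ident)):
                    continue
                new = 1 + max(parent_gens)
            if gen.get(ident) != new:
                gen[ident] = new
                changed = True
    return gen


# ---------------------------------------------------------------------------
# Kinship / inbreeding
# ---------------------------------------------------------------------------

def kinship(ped: Pedigree, a: str, b: str) -> float:
    """Kinship coefficient phi(a, b): the probability that one allele sampled
    from ``a`` and one from ``b`` at a single autosomal locus are IBD.

    Uses the standard recursion (distinct founders are unrelated):
    phi(a, a) = (1 + F_a) / 2 and, recursing on the individual farther from
    the founders, phi(a, b) = (phi(father_a, b) + phi(mother_a, b)) / 2.
    Memoised on the unordered pair; results survive repeated queries.
    """
    ped[a], ped[b]
    cache: dict[frozenset[str], float] = ped.__dict__.setdefault("_kinship_cache", {})

    def phi(x: str, y: str) -> float:
        key = frozenset((x, y))
        if key in cache:
            return cache[key]
        # ensure a well-founded recursion: recurse on the deeper individual,
        # which can never be an ancestor of the shallower one
        if ped._depth(x) < ped._depth(y):
            x, y = y, x
        if x == y:
            parents = ped.parents(x)
            f = phi(parents[0], parents[1]) if len(parents) == 2 else 0.0
            val = 0.5 * (1.0 + f)
        else:
            parents = ped.parents(x)
            if not parents:
                val = 0.0
            else:
                val = 0.5 * sum(phi(p, y) for p in parents)
                if len(parents) == 1:
                    # single recorded parent: the unknown parent is unrelated
                    pass
        cache[key] = val
        return val

    return phi(a, b)


def inbreeding(ped: Pedigree, a: str) -> float:
    """Inbreeding coefficient F_a = kinship between a's parents (0 for founders)."""
    parents = ped.parents(a)
    if len(parents) < 2:
        return 0.0
    return kinship(ped, parents[0], parents[1])


def genotyped_descendants(ped: Pedigree, a: str) -> set[str]:
    """All genotyped individuals reachable from ``a`` by child edges (excluding a)."""
    return {d for d in ped.descendants(a) if ped.individuals[d].genotyped}


def generation_table(ped: Pedigree) -> "Iterator[tuple[int, int, int]]":
    """Yield (generation, n_individuals, n_genotyped) rows, sorted by generation."""
    gens = assign_generations(ped)
    by_gen: dict[int, list[str]] = {}
    for ident, g in gens.items():
        by_gen.setdefault(g, []).append(ident)
    for g in sorted(by_gen):
        ids = by_gen[g]
        yield g, len(ids), sum(1 for i in ids if ped.individuals[i].genotyped)
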