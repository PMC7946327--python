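"""Self-contained synthetic data: endogamous pedigrees, gene-drop meiosis,
and true IBD segments.

The generator emulates the validation setting the package targets: a
generation-stratified endogamous population in which a configurable
fraction of marriages is constrained to be between close relatives
(second-degree = first cousins, third-degree = second cousins,
fourth-degree = third cousins, classified by the depth of the closest
shared ancestral couple), with the most recent generations genotyped.
Founder haplotypes are i.i.d. Bernoulli per site with allele frequencies
drawn uniformly; meiosis places a Poisson number of crossovers uniformly
on the genetic map (Haldane model: no interference, sex-averaged map).
Because every allele is labelled with its founder haplotype of origin,
true IBD segments and their full carrier cohorts are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from .ibdio import HapId, HaplotypePanel, IBDSegment, PairwiseMatch, \
    write_match, write_phased_vcf, write_plink_map
from .pedigree import FEMALE, MALE, Individual, Pedigree, write_pedigree

__all__ = [
    "SimConfig",
    "TruthSet",
    "simulate_pedigree",
    "gene_drop",
    "true_ibd_segments",
    "true_pairwise_matches",
    "write_fixtures",
    "example_pedigree",
    "meiosis_selector",
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic pedigree and gene drop."""

    generations: int = 8
    couples_per_generation: int = 12
    children_range: tuple[int, int] = (2, 4)      # inclusive
    quota_second: float = 0.05    # first-cousin marriages
    quota_third: float = 0.10     # second-cousin marriages
    quota_fourth: float = 0.10    # third-cousin marriages
    n_snps: int = 5000
    chrom_cm: float = 100.0
    bp_per_cm: float = 1_000_000.0
    chrom_label: str = "1"
    maf_low: float = 0.05
    maf_high: float = 0.5
    genotyped_generations: int = 3  # bottom-most generations carry genotypes
    min_cm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.quota_second + self.quota_third + self.quota_fourth > 1:
            raise ValueError("consanguinity quotas must sum to at most 1")
        if self.chrom_cm <= 0 and self.n_snps > 0:
            if self.chrom_cm < 0:
                raise ValueError("chromosome length must be non-negative")


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def _ancestor_depths(ped: Pedigree, ident: str,
                     cache: dict[str, dict[str, int]]) -> dict[str, int]:
    """Minimum number of meiosis steps up to each ancestor."""
    if ident in cache:
        return cache[ident]
    out: dict[str, int] = {}
    for p in ped.parents(ident):
        out[p] = 1
        for anc, d in _ancestor_depths(ped, p, cache).items():
            if anc not in out or d + 1 < out[anc]:
                out[anc] = d + 1
    cache[ident] = out
    return out


def relationship_degree(ped: Pedigree, a: str, b: str,
                        cache: dict[str, dict[str, int]] | None = None
                        ) -> int | None:
    """Depth of the closest shared ancestor: 1 = siblings, 2 = first
    cousins, 3 = second cousins, 4 = third cousins; None if unrelated."""
    cache = cache if cache is not None else {}
    da = _ancestor_depths(ped, a, cache)
    db = _ancestor_depths(ped, b, cache)
    shared = set(da) & set(db)
    if not shared:
        return None
    return min(max(da[s], db[s]) for s in shared)


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Generate an endogamous, generation-stratified pedigree.

    Marriages within each generation are allocated to consanguinity bands
    by the quotas (fractional targets carried across generations so the
    realized fractions track the quotas); remaining marriages avoid
    relatives of fourth degree or closer when possible, taking a
    married-in founder spouse otherwise.  Fully reproducible under the
    config seed.  The realized marriages are recorded on the returned
    pedigree as ``ped.sim_marriages`` (list of (a, b, band, generation)).
    """
    rng = np.random.default_rng(cfg.seed)
    ped = Pedigree()
    counter = [0]

    def new_ind(gen: int, sex: str, father=None, mother=None) -> str:
        counter[0] += 1
        ident = f"G{gen}I{counter[0]:04d}"
        geno = gen > cfg.generations - cfg.genotyped_generations
        ped.add(Individual(ident, father, mother, sex, genotyped=geno))
        return ident

    def breed(couples: list[tuple[str, str]], child_gen: int) -> list[str]:
        kids: list[str] = []
        lo, hi = cfg.children_range
        for father, mother in couples:
            k = int(rng.integers(lo, hi + 1))
            for _ in range(k):
                sex = MALE if rng.random() < 0.5 else FEMALE
                kids.append(new_ind(child_gen, sex, father, mother))
        return kids

    marriages: list[tuple[str, str, int | None, int]] = []

    # generation 1: founder couples
    couples = [(new_ind(1, MALE), new_ind(1, FEMALE))
               for _ in range(cfg.couples_per_generation)]
    for f, m in couples:
        marriages.append((f, m, None, 1))
    pool = breed(couples, 2) if cfg.generations >= 2 else []

    carry = {2: 0.0, 3: 0.0, 4: 0.0}
    # the final generation does not marry (its members are the leaves)
    for gen in range(2, cfg.generations):
        anc_cache: dict[str, dict[str, int]] = {}
        males = [i for i in pool if ped[i].sex == MALE]
        females = [i for i in pool if ped[i].sex == FEMALE]
        rng.shuffle(males)
        rng.shuffle(females)
        taken: set[str] = set()
        new_couples: list[tuple[str, str]] = []

        def degree(a: str, b: str) -> int | None:
            return relationship_degree(ped, a, b, anc_cache)

        # banded (consanguineous) marriages first
        for band in (2, 3, 4):
            quota = {2: cfg.quota_second, 3: cfg.quota_third,
                     4: cfg.quota_fourth}[band]
            want = quota * cfg.couples_per_generation + carry[band]
            n_want = int(want)
            carry[band] = want - n_want
            made = 0
            for a in males:
                if made >= n_want:
                    break
                if a in taken:
                    continue
                for b in females:
                    if b in taken:
                        continue
                    if degree(a, b) == band:
                        taken.update((a, b))
                        new_couples.append((a, b))
                        marriages.append((a, b, band, gen))
                        made += 1
                        break
            carry[band] += n_want - made  # unmet demand rolls forward

        # remaining marriages: unrelated within the pool when possible,
        # otherwise a married-in founder spouse
        while len(new_couples) < cfg.couples_per_generation:
            a = next((i for i in males if i not in taken), None)
            if a is None:
                a = new_ind(gen, MALE)
            else:
                taken.add(a)
            b = None
            for cand in females:
                if cand in taken:
                    continue
                deg = degree(a, cand) if a in pool else None
                if deg is None or deg > 4:
                    b = cand
                    break
            if b is None:
                b = new_ind(gen, FEMALE)
            else:
                taken.add(b)
            new_couples.append((a, b))
            marriages.append((a, b, None, gen))

        if gen < cfg.generations:
            pool = breed(new_couples, gen + 1)
        couples = new_couples

    ped.validate()
    ped.sim_marriages = marriages  # type: ignore[attr-defined]
    return ped


# ---------------------------------------------------------------------------
# Gene drop
# ---------------------------------------------------------------------------

def meiosis_selector(cm_positions: np.ndarray, chrom_cm: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Which parental haplotype (0/1) the gamete copies at each SNP.

    Crossover count is Poisson in the map length (Morgans), positions
    uniform in cM, and the starting strand is a fair coin — the Haldane
    model with no interference.
    """
    k = int(rng.poisson(chrom_cm / 100.0)) if chrom_cm > 0 else 0
    start = int(rng.integers(2))
    if k == 0:
        return np.full(len(cm_positions), start, dtype=np.int8)
    xo = np.sort(rng.uniform(0.0, chrom_cm, size=k))
    flips = np.searchsorted(xo, cm_positions, side="right")
    return ((start + flips) % 2).astype(np.int8)


@dataclass
class TruthSet:
    """Complete haplotypes and founder-origin labels for every individual."""

    chrom: str
    positions: np.ndarray
    cm: np.ndarray
    haplotypes: dict[HapId, np.ndarray]       # alleles, int8
    ancestry: dict[HapId, np.ndarray]         # founder-haplotype label, int32
    founder_haps: dict[int, HapId]            # label -> founder haplotype
    crossovers: dict[HapId, np.ndarray] = field(default_factory=dict)
    allele_freq: np.ndarray | None = None

    def to_panel(self, ped: Pedigree, genotyped_only: bool = True
                 ) -> HaplotypePanel:
        ids = sorted(i for i in ped.individuals
                     if ped.individuals[i].genotyped or not genotyped_only)
        haps = {(s, k): self.haplotypes[(s, k)].copy()
                for s in ids for k in (0, 1)}
        return HaplotypePanel(chrom=self.chrom, positions=self.positions.copy(),
                              haplotypes=haps, samples=ids, cm=self.cm.copy())


def gene_drop(ped: Pedigree, cfg: SimConfig,
              rng: np.random.Generator | None = None) -> TruthSet:
    """Drop founder haplotypes through the pedigree, one meiosis per
    parent-child transmission, recording the founder origin of every allele."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    S = cfg.n_snps
    total_bp = max(cfg.chrom_cm, 1e-9) * cfg.bp_per_cm
    positions = np.unique(
        (np.arange(1, S + 1) * (total_bp / (S + 1))).astype(np.int64))
    if len(positions) < S:  # collision guard for tiny spans
        positions = np.arange(1, S + 1, dtype=np.int64)
    cm = (positions / positions[-1]) * cfg.chrom_cm if S else positions * 0.0

    freq = rng.uniform(cfg.maf_low, cfg.maf_high, size=S)
    haplotypes: dict[HapId, np.ndarray] = {}
    ancestry: dict[HapId, np.ndarray] = {}
    crossovers: dict[HapId, np.ndarray] = {}
    founder_haps: dict[int, HapId] = {}
    label = [0]

    # process in parent-before-child order
    order: list[str] = []
    seen: set[str] = set()

    def visit(i: str) -> None:
        stack = [(i, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if node in seen:
                continue
            seen.add(node)
            stack.append((node, True))
            for p in ped.parents(node):
                stack.append((p, False))

    for i in sorted(ped.individuals):
        visit(i)

    for ident in order:
        ind = ped.individuals[ident]
        if ind.is_founder:
            for k in (0, 1):
                hap = (rng.random(S) < freq).astype(np.int8)
                haplotypes[(ident, k)] = hap
                ancestry[(ident, k)] = np.full(S, label[0], dtype=np.int32)
                founder_haps[label[0]] = (ident, k)
                label[0] += 1
        else:
            for k, parent in ((0, ind.father), (1, ind.mother)):
                sel = meiosis_selector(cm, cfg.chrom_cm, rng)
                h = np.where(sel == 0, haplotypes[(parent, 0)],
                             haplotypes[(parent, 1)]).astype(np.int8)
                a = np.where(sel == 0, ancestry[(parent, 0)],
                             ancestry[(parent, 1)]).astype(np.int32)
                haplotypes[(ident, k)] = h
                ancestry[(ident, k)] = a
                flip = np.nonzero(np.diff(sel))[0]
                crossovers[(ident, k)] = cm[flip] if len(flip) else \
                    np.empty(0, dtype=float)

    return TruthSet(chrom=cfg.chrom_label, positions=positions, cm=cm,
                    haplotypes=haplotypes, ancestry=ancestry,
                    founder_haps=founder_haps, crossovers=crossovers,
                    allele_freq=freq)


# ---------------------------------------------------------------------------
# True IBD extraction
# ---------------------------------------------------------------------------

def true_ibd_segments(truth: TruthSet, ped: Pedigree,
                      min_cm: float = 3.0,
                      genotyped: Iterable[str] | None = None
                      ) -> list[IBDSegment]:
    """True IBD segments among the genotyped haplotypes.

    For each founder haplotype, every *maximal* pair (carrier set,
    interval) is emitted: the carrier set (at least two distinct
    individuals) all descend from that founder haplotype over the whole
    interval, and neither the interval can be extended nor the set
    enlarged without breaking that.  This yields IBD sharing at every
    scale — long segments for close relatives nested over shorter,
    deeper-cohort segments — mirroring what an IBD detector reports.
    Cohort members are byte-identical over their interval by construction.
    """
    ids = sorted(genotyped) if genotyped is not None else \
        sorted(ped.genotyped_ids())
    haps: list[HapId] = [(s, k) for s in ids for k in (0, 1)]
    if not haps or truth.positions.size == 0:
        return []
    S = truth.positions.size

    # run-length encode every haplotype's founder-origin labels
    by_fid: dict[int, list[tuple[int, int, int]]] = {}  # fid -> (row, s, e)
    for row, h in enumerate(haps):
        anc = truth.ancestry[h]
        change = np.nonzero(anc[1:] != anc[:-1])[0]
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [S]))
        for s, e in zip(starts, ends):
            by_fid.setdefault(int(anc[s]), []).append((row, int(s), int(e)))

    def n_individuals(rows: frozenset[int]) -> int:
        return len({haps[r][0] for r in rows})

    rects: set[tuple[frozenset[int], int, int]] = set()
    for fid, intervals in by_fid.items():
        if len(intervals) < 2:
            continue
        events = sorted({x for _, s, e in intervals for x in (s, e)})
        blocks: list[tuple[int, int, frozenset[int]]] = []
        for bs, be in zip(events, events[1:]):
            rows = frozenset(r for r, s, e in intervals if s <= bs and e >= be)
            blocks.append((bs, be, rows))
        B = len(blocks)
        for i in range(B):
            cur: frozenset[int] | None = None
            start = blocks[i][0]
            j = i
            while j < B:
                nxt = blocks[j][2] if cur is None else cur & blocks[j][2]
                if n_individuals(nxt) < 2:
                    break
                if nxt != cur:
                    if cur is not None and not (
                            i > 0 and cur <= blocks[i - 1][2]):
                        rects.add((cur, start, blocks[j - 1][1]))
                    cur = nxt
                j += 1
            if cur is not None and not (i > 0 and cur <= blocks[i - 1][2]):
                rects.add((cur, start, blocks[j - 1][1]))
    # consensus comes from any carrier (all are identical over the interval)
    segments: list[IBDSegment] = []
    ordered = sorted(rects, key=lambda t: (t[1], t[2], sorted(t[0])))
    n = 0
    for rows, s, e in ordered:
        if e <= s:
            continue
        length = float(truth.cm[e - 1] - truth.cm[s])
        if length < min_cm:
            continue
        n += 1
        cohort = frozenset(haps[r] for r in rows)
        any_row = min(rows)
        consensus = truth.haplotypes[haps[any_row]][s:e].copy()
        segments.append(IBDSegment(
            id=f"true{n}", chrom=truth.chrom, start=s, end=e,
            start_bp=int(truth.positions[s]), end_bp=int(truth.positions[e - 1]),
            cm=length, cohort=cohort, consensus=consensus,
        ))
    return segments


def true_pairwise_matches(truth: TruthSet, ped: Pedigree,
                          min_cm: float = 3.0,
                          genotyped: Iterable[str] | None = None
                          ) -> list[PairwiseMatch]:
    """Maximal pairwise true IBD segments, as GERMLINE-dialect matches.

    For every pair of genotyped haplotypes (distinct individuals) and every
    founder haplotype both descend from, the maximal interval over which
    both carry it, kept when at least ``min_cm`` long.  This is the
    pairwise view an IBD detector reports; feed it through
    :func:`ibdthread.ibdio.build_cohorts` to obtain the cohort segments
    the reconstruction consumes.
    """
    ids = sorted(genotyped) if genotyped is not None else \
        sorted(ped.genotyped_ids())
    haps: list[HapId] = [(s, k) for s in ids for k in (0, 1)]
    if not haps or truth.positions.size == 0:
        return []
    S = truth.positions.size
    by_fid: dict[int, list[tuple[int, int, int]]] = {}
    for row, h in enumerate(haps):
        anc = truth.ancestry[h]
        change = np.nonzero(anc[1:] != anc[:-1])[0]
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [S]))
        for s, e in zip(starts, ends):
            by_fid.setdefault(int(anc[s]), []).append((row, int(s), int(e)))

    matches: list[PairwiseMatch] = []
    for fid, intervals in sorted(by_fid.items()):
        for i in range(len(intervals)):
            r1, s1, e1 = intervals[i]
            for j in range(i + 1, len(intervals)):
                r2, s2, e2 = intervals[j]
                if haps[r1][0] == haps[r2][0]:
                    continue
                s, e = max(s1, s2), min(e1, e2)
                if e <= s:
                    continue
                length = float(truth.cm[e - 1] - truth.cm[s])
                if length < min_cm:
                    continue
                h1, h2 = sorted((haps[r1], haps[r2]))
                matches.append(PairwiseMatch(
                    hap1=h1, hap2=h2, chrom=truth.chrom,
                    start_bp=int(truth.positions[s]),
                    end_bp=int(truth.positions[e - 1]),
                    n_markers=e - s, length=length, unit="cM",
                ))
    matches.sort(key=lambda m: (m.start_bp, m.end_bp, m.hap1, m.hap2))
    return matches


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_fixtures(ped: Pedigree, truth: TruthSet, cfg: SimConfig,
                   out_dir: str | Path) -> dict[str, Path]:
    """Write pedigree, phased VCF (genotyped individuals), pairwise .match,
    PLINK .map and a truth JSON; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": out / "pedigree.txt",
        "vcf": out / "panel.vcf",
        "match": out / "true.match",
        "map": out / "chrom.map",
        "truth": out / "truth.json",
    }
    with open(paths["pedigree"], "w") as fh:
        write_pedigree(ped, fh)
    panel = truth.to_panel(ped, genotyped_only=True)
    with open(paths["vcf"], "w") as fh:
        write_phased_vcf(panel, fh)
    segments = true_ibd_segments(truth, ped, min_cm=cfg.min_cm)
    with open(paths["match"], "w") as fh:
        for seg in segments:
            write_match(seg.to_matches(), fh)
    with open(paths["map"], "w") as fh:
        write_plink_map(panel, fh)
    truth_doc = {
        "chrom": truth.chrom,
        "positions": truth.positions.tolist(),
        "haplotypes": {f"{s}.{k}": "".join(map(str, truth.haplotypes[(s, k)]))
                       for (s, k) in sorted(truth.haplotypes)},
        "segments": [
            {"id": seg.id, "start": seg.start, "end": seg.end,
             "start_bp": seg.start_bp, "end_bp": seg.end_bp, "cm": seg.cm,
             "cohort": sorted(f"{s}.{k}" for s, k in seg.cohort)}
            for seg in segments
        ],
        "config": asdict(cfg),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh)
    return paths


# ---------------------------------------------------------------------------
# Worked-example pedigree
# ---------------------------------------------------------------------------

def example_pedigree() -> tuple[Pedigree, frozenset[str]]:
    """A 21-individual looped pedigree with eight genotyped descendants and
    the five-member cohort used throughout the documentation.

    Structure: founder couple p+q has children g, f and m; founder couple
    k+l has child h; l's remarriage to m yields e; couple g+h has children
    b, c and d; b (with married-in founder a) has children 1 and 2; couple
    c+f has children 7 and 8; couple d+e has child 5.  The two marriage
    loops are c/f (both descend from p+q) and d/e (both descend from l).
    Genotyped individuals are 1-8; the cohort is {1, 2, 5, 7, 8}.
    """
    rows = [
        # id, father, mother, sex
        ("p", None, None, MALE), ("q", None, None, FEMALE),
        ("k", None, None, FEMALE), ("l", None, None, MALE),
        ("a", None, None, MALE),
        ("g", "p", "q", MALE), ("f", "p", "q", FEMALE),
        ("m", "p", "q", FEMALE),
        ("h", "l", "k", FEMALE),
        ("e", "l", "m", FEMALE),
        ("b", "g", "h", FEMALE), ("c", "g", "h", MALE),
        ("d", "g", "h", MALE),
        ("1", "a", "b", MALE), ("2", "a", "b", FEMALE),
        ("3", "a", "b", MALE),
        ("7", "c", "f", MALE), ("8", "c", "f", FEMALE),
        ("4", "c", "f", MALE),
        ("5", "d", "e", MALE), ("6", "d", "e", FEMALE),
    ]
    ped = Pedigree()
    genotyped = {str(i) for i in range(1, 9)}
    for ident, fa, mo, sex in rows:
        ped.add(Individual(ident, fa, mo, sex, genotyped=ident in genotyped))
    ped.validate()
    return ped, frozenset({"1", "2", "5", "7", "8"})
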