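"""Haplotype panels, pairwise IBD matches, and multi-individual IBD cohorts.

Readers and writers for the standard interchange formats: phased VCF 4.2
(read through cyvcf2), GERMLINE ``.match`` files, and PLINK ``.map`` genetic
maps.  Coordinates are 1-based inclusive base pairs at the I/O boundary and
0-based half-open SNP indices internally; conversion happens only here.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np

__all__ = [
    "HapId",
    "HaplotypePanel",
    "PairwiseMatch",
    "IBDSegment",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_match",
    "write_match",
    "read_plink_map",
    "build_cohorts",
]

MISSING = np.int8(-1)

HapId = tuple[str, int]  # (sample id, 0 or 1)

_HAP_SUFFIX_RE = re.compile(r"^(?P<sample>.+)\.(?P<hap>[01])$")


def hap_str(h: HapId) -> str:
    return f"{h[0]}.{h[1]}"


def parse_hap(s: str, pattern: re.Pattern = _HAP_SUFFIX_RE) -> HapId:
    m = pattern.match(s)
    if not m:
        raise ValueError(f"cannot parse haplotype identifier {s!r}")
    return (m.group("sample"), int(m.group("hap")))


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotypes over an ordered set of SNPs on one chromosome.

    ``haplotypes`` maps (sample, 0|1) -> int8 array of length S with -1
    for missing calls.  ``cm`` gives the genetic-map position of every SNP
    (piecewise-linear interpolation of the supplied map).
    """

    chrom: str
    positions: np.ndarray            # bp, strictly increasing, int64
    haplotypes: dict[HapId, np.ndarray]
    samples: list[str] = field(default_factory=list)
    cm: np.ndarray | None = None
    ref: list[str] | None = None
    alt: list[str] | None = None
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("SNP positions must be strictly increasing")
        if not self.samples:
            self.samples = sorted({s for s, _ in self.haplotypes})
        if self.cm is None:
            # default uniform map: 1 cM per Mbp
            self.cm = self.positions.astype(float) * 1e-6
        for h, arr in self.haplotypes.items():
            if len(arr) != self.n_snps:
                raise ValueError(f"haplotype {hap_str(h)} has wrong length")

    @property
    def n_snps(self) -> int:
        return len(self.positions)

    def hap_ids(self) -> list[HapId]:
        return [(s, k) for s in self.samples for k in (0, 1)]

    def get(self, h: HapId) -> np.ndarray:
        return self.haplotypes[h]

    def attach_map(self, map_bp: np.ndarray, map_cm: np.ndarray) -> None:
        self.cm = np.interp(self.positions.astype(float), map_bp, map_cm)

    def cm_length(self, start: int, end: int) -> float:
        """Genetic length of the half-open SNP interval [start, end)."""
        if end <= start:
            return 0.0
        return float(self.cm[end - 1] - self.cm[start])

    def bp_span(self, start: int, end: int) -> tuple[int, int]:
        return int(self.positions[start]), int(self.positions[end - 1])

    def snp_interval(self, start_bp: int, end_bp: int) -> tuple[int, int]:
        """Half-open SNP index interval covering inclusive [start_bp, end_bp]."""
        s = int(np.searchsorted(self.positions, start_bp, side="left"))
        e = int(np.searchsorted(self.positions, end_bp, side="right"))
        return s, e

    def drop_samples(self, remove: Iterable[str]) -> "HaplotypePanel":
        remove = set(remove)
        keep = [s for s in self.samples if s not in remove]
        haps = {h: a for h, a in self.haplotypes.items() if h[0] not in remove}
        return replace(self, haplotypes=haps, samples=keep)


def read_phased_vcf(path: str | Path) -> HaplotypePanel:
    """Read a single-chromosome, biallelic, fully phased VCF into a panel.

    Multiallelic records are skipped with a warning; unphased genotypes are
    an error (missing genotypes are allowed and encoded as -1).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    ids: list[str] = []
    rows: list[np.ndarray] = []
    chrom: str | None = None
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multiallelic record at {var.CHROM}:{var.POS}")
            continue
        if chrom is None:
            chrom = str(var.CHROM)
        elif str(var.CHROM) != chrom:
            raise ValueError("panel VCF must contain a single chromosome")
        alleles = np.full(2 * len(samples), MISSING, dtype=np.int8)
        for j, gt in enumerate(var.genotypes):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a >= 0 and b >= 0 and not phased:
                raise ValueError(
                    f"unphased genotype for sample {samples[j]} at "
                    f"{var.CHROM}:{var.POS}"
                )
            alleles[2 * j] = a if a >= 0 else MISSING
            alleles[2 * j + 1] = b if b >= 0 else MISSING
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        ids.append(var.ID or f"snp{len(positions)}")
        rows.append(alleles)
    vcf.close()
    if chrom is None:
        raise ValueError("empty VCF")
    mat = np.vstack(rows)  # S x 2N
    haps = {
        (s, k): np.ascontiguousarray(mat[:, 2 * j + k])
        for j, s in enumerate(samples) for k in (0, 1)
    }
    return HaplotypePanel(
        chrom=chrom, positions=np.asarray(positions, dtype=np.int64),
        haplotypes=haps, samples=samples, ref=refs, alt=alts, snp_ids=ids,
    )


def write_phased_vcf(panel: HaplotypePanel, stream: IO[str],
                     samples: Sequence[str] | None = None) -> None:
    """Write the panel (or a subset of its samples) as phased VCF 4.2 text.

    Missing alleles are emitted as ``.``, so reconstructions with gaps
    round-trip through :func:`read_phased_vcf`.
    """
    samples = list(samples) if samples is not None else list(panel.samples)
    stream.write("##fileformat=VCFv4.2\n")
    stream.write(f"##contig=<ID={panel.chrom}>\n")
    stream.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    stream.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
    ref = panel.ref or ["A"] * panel.n_snps
    alt = panel.alt or ["G"] * panel.n_snps
    ids = panel.snp_ids or [f"snp{i + 1}" for i in range(panel.n_snps)]

    def code(v: int) -> str:
        return "." if v < 0 else str(int(v))

    cols = [(panel.haplotypes[(s, 0)], panel.haplotypes[(s, 1)]) for s in samples]
    for i in range(panel.n_snps):
        gts = "\t".join(f"{code(h0[i])}|{code(h1[i])}" for h0, h1 in cols)
        stream.write(
            f"{panel.chrom}\t{panel.positions[i]}\t{ids[i]}\t{ref[i]}\t{alt[i]}"
            f"\t.\tPASS\t.\tGT\t{gts}\n"
        )


def read_plink_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a PLINK .map file (chrom, id, cM, bp); returns (bp, cM) arrays."""
    import pandas as pd

    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "id", "cm", "bp"])
    order = np.argsort(df["bp"].to_numpy())
    return df["bp"].to_numpy()[order].astype(np.int64), \
        df["cm"].to_numpy()[order].astype(float)


def write_plink_map(panel: HaplotypePanel, stream: IO[str]) -> None:
    ids = panel.snp_ids or [f"snp{i + 1}" for i in range(panel.n_snps)]
    for i in range(panel.n_snps):
        stream.write(f"{panel.chrom}\t{ids[i]}\t{panel.cm[i]:.6f}\t"
                     f"{panel.positions[i]}\n")


# ---------------------------------------------------------------------------
# GERMLINE matches
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseMatch:
    """One GERMLINE match line: a pairwise IBD segment between two haplotypes."""

    hap1: HapId
    hap2: HapId
    chrom: str
    start_bp: int
    end_bp: int
    start_snp_id: str = "."
    end_snp_id: str = "."
    n_markers: int = 0
    length: float = 0.0
    unit: str = "cM"
    mismatches: int = 0
    fam1: str = "0"
    fam2: str = "0"

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("match start after end")


def read_match(stream: IO[str] | Iterable[str],
               known_samples: set[str] | None = None,
               hap_pattern: re.Pattern = _HAP_SUFFIX_RE) -> list[PairwiseMatch]:
    """Parse GERMLINE ``.match`` lines (the ``-haploid`` dialect, where the
    sample id carries a ``.0``/``.1`` haplotype suffix).

    Matches naming samples absent from ``known_samples`` (when given) are
    dropped with a warning; malformed lines raise with their line number.
    """
    out: list[PairwiseMatch] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        f = line.split()
        if len(f) < 12:
            raise ValueError(f".match line {lineno}: expected >=12 fields, got {len(f)}")
        try:
            h1 = parse_hap(f[1], hap_pattern)
            h2 = parse_hap(f[3], hap_pattern)
            match = PairwiseMatch(
                hap1=h1, hap2=h2, chrom=f[4],
                start_bp=int(f[5]), end_bp=int(f[6]),
                start_snp_id=f[7], end_snp_id=f[8],
                n_markers=int(f[9]), length=float(f[10]), unit=f[11],
                mismatches=int(f[12]) if len(f) > 12 else 0,
                fam1=f[0], fam2=f[2],
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f".match line {lineno}: {exc}") from exc
        if known_samples is not None and (
                h1[0] not in known_samples or h2[0] not in known_samples):
            warnings.warn(f".match line {lineno}: unknown sample, dropped")
            continue
        out.append(match)
    return out


def write_match(matches: Iterable[PairwiseMatch], stream: IO[str]) -> None:
    for m in matches:
        stream.write(
            f"{m.fam1}\t{hap_str(m.hap1)}\t{m.fam2}\t{hap_str(m.hap2)}\t"
            f"{m.chrom}\t{m.start_bp}\t{m.end_bp}\t{m.start_snp_id}\t"
            f"{m.end_snp_id}\t{m.n_markers}\t{m.length:.6g}\t{m.unit}\t"
            f"{m.mismatches}\t0\t0\n"
        )


# ---------------------------------------------------------------------------
# IBD segments (cohort level)
# ---------------------------------------------------------------------------

@dataclass
class IBDSegment:
    """A segment interval plus the cohort of haplotypes sharing it."""

    id: str
    chrom: str
    start: int                 # SNP index, half-open [start, end)
    end: int
    start_bp: int
    end_bp: int
    cm: float
    cohort: frozenset[HapId]
    consensus: np.ndarray      # int8 over [start, end), -1 missing

    @property
    def n_snps(self) -> int:
        return self.end - self.start

    @property
    def bp_length(self) -> int:
        return self.end_bp - self.start_bp + 1

    def cohort_individuals(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.cohort)

    def to_matches(self) -> list[PairwiseMatch]:
        """All pairwise GERMLINE-dialect lines implied by the cohort."""
        haps = sorted(self.cohort)
        out = []
        for i in range(len(haps)):
            for j in range(i + 1, len(haps)):
                out.append(PairwiseMatch(
                    hap1=haps[i], hap2=haps[j], chrom=self.chrom,
                    start_bp=self.start_bp, end_bp=self.end_bp,
                    n_markers=self.n_snps, length=self.cm, unit="cM",
                ))
        return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _consensus(panel: HaplotypePanel, cohort: Iterable[HapId],
               start: int, end: int) -> np.ndarray:
    """Majority allele per site among cohort haplotypes (ties -> 0)."""
    stack = [panel.get(h)[start:end] for h in cohort if h in panel.haplotypes]
    if not stack:
        return np.full(end - start, MISSING, dtype=np.int8)
    mat = np.vstack(stack)
    ones = (mat == 1).sum(axis=0)
    zeros = (mat == 0).sum(axis=0)
    cons = np.full(end - start, MISSING, dtype=np.int8)
    cons[ones > zeros] = 1
    cons[(zeros >= ones) & (zeros > 0)] = 0
    return cons


def _agreement(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    """(#agreeing, #comparable) over sites where both are non-missing."""
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    return int((a[ok] == b[ok]).sum()), n


def build_cohorts(matches: Sequence[PairwiseMatch], panel: HaplotypePanel,
                  min_overlap_frac: float = 0.5, min_cm: float = 3.0,
                  epsilon: float = 0.02) -> tuple[list[IBDSegment], int]:
    """Merge pairwise matches into multi-haplotype IBD cohorts.

    Each match contributes two (haplotype, interval) claims joined by an
    edge; claims on the same haplotype are additionally joined when their
    reciprocal bp overlap is at least ``min_overlap_frac``.  Each connected
    component becomes one segment whose interval is the intersection of the
    member intervals; components whose intersection falls below ``min_cm``
    are split greedily by interval similarity, and unsplittable remainders
    are dropped.  Returns (segments, n_dropped_matches).
    """
    if not matches:
        return [], 0
    claims: list[tuple[HapId, int, int, int]] = []  # hap, start_bp, end_bp, match idx
    for k, m in enumerate(matches):
        claims.append((m.hap1, m.start_bp, m.end_bp, k))
        claims.append((m.hap2, m.start_bp, m.end_bp, k))
    uf = _UnionFind(len(claims))
    for k in range(len(matches)):
        uf.union(2 * k, 2 * k + 1)
    by_hap: dict[HapId, list[int]] = {}
    for idx, (h, *_rest) in enumerate(claims):
        by_hap.setdefault(h, []).append(idx)

    def recip_overlap(i: int, j: int) -> float:
        _, s1, e1, _ = claims[i]
        _, s2, e2, _ = claims[j]
        ov = min(e1, e2) - max(s1, s2) + 1
        if ov <= 0:
            return 0.0
        return min(ov / (e1 - s1 + 1), ov / (e2 - s2 + 1))

    for idxs in by_hap.values():
        idxs.sort(key=lambda i: claims[i][1])
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                if claims[idxs[b]][1] > claims[idxs[a]][2]:
                    break
                if recip_overlap(idxs[a], idxs[b]) >= min_overlap_frac:
                    uf.union(idxs[a], idxs[b])

    comps: dict[int, list[int]] = {}
    for idx in range(len(claims)):
        comps.setdefault(uf.find(idx), []).append(idx)

    segments: list[IBDSegment] = []
    dropped_matches: set[int] = set()
    seg_no = 0

    def emit(idx_list: list[int]) -> bool:
        nonlocal seg_no
        start_bp = max(claims[i][1] for i in idx_list)
        end_bp = min(claims[i][2] for i in idx_list)
        if start_bp > end_bp:
            return False
        s, e = panel.snp_interval(start_bp, end_bp)
        if e <= s or panel.cm_length(s, e) < min_cm:
            return False
        cohort = frozenset(claims[i][0] for i in idx_list)
        if len({h[0] for h in cohort}) < 2:
            return False
        cons = _consensus(panel, cohort, s, e)
        kept = []
        for h in sorted(cohort):
            if h not in panel.haplotypes:
                kept.append(h)
                continue
            agree, n = _agreement(panel.get(h)[s:e], cons)
            if n == 0 or agree / n >= 1.0 - epsilon:
                kept.append(h)
        if len({h[0] for h in kept}) < 2:
            return False
        cohort = frozenset(kept)
        seg_no += 1
        segments.append(IBDSegment(
            id=f"seg{seg_no}", chrom=panel.chrom, start=s, end=e,
            start_bp=start_bp, end_bp=end_bp, cm=panel.cm_length(s, e),
            cohort=cohort, consensus=_consensus(panel, cohort, s, e),
        ))
        return True

    for comp in sorted(comps.values(), key=lambda c: claims[c[0]][1]):
        if emit(comp):
            continue
        # greedy split by interval similarity: sweep claims by start and
        # open a new cluster whenever the running intersection would vanish
        comp_sorted = sorted(comp, key=lambda i: (claims[i][1], claims[i][2]))
        clusters: list[list[int]] = []
        bounds: list[tuple[int, int]] = []
        for i in comp_sorted:
            _, s_bp, e_bp, _ = claims[i]
            placed = False
            for ci, (cs, ce) in enumerate(bounds):
                ns, ne = max(cs, s_bp), min(ce, e_bp)
                if ns <= ne and recip_overlap_bounds(ns, ne, s_bp, e_bp) \
                        >= min_overlap_frac:
                    clusters[ci].append(i)
                    bounds[ci] = (ns, ne)
                    placed = True
                    break
            if not placed:
                clusters.append([i])
                bounds.append((s_bp, e_bp))
        for cl in clusters:
            if not emit(cl):
                dropped_matches.update(claims[i][3] for i in cl)
                warnings.warn("dropped unsplittable/short IBD component")
    return segments, len(dropped_matches)


def recip_overlap_bounds(s1: int, e1: int, s2: int, e2: int) -> float:
    ov = min(e1, e2) - max(s1, s2) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (e1 - s1 + 1), ov / (e2 - s2 + 1))
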