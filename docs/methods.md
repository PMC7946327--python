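# Methods

This note documents the model behind `ibdthread`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the known limits of the approach.

## Problem and assumptions

Given a pedigree whose recent generations are genotyped and phased, every
IBD segment shared by a cohort of genotyped haplotypes is assumed to descend
from a single common ancestor (or ancestral couple) without recombination
breaking it on the way down. The method is combinatorial, not
likelihood-based: it never computes the probability of the full observed
sharing configuration, only per-segment transmission probabilities, and it
deliberately does not penalise non-cohort carriers. It is designed for
endogamous pedigrees where loops (marriages between relatives) are common
and IBD is abundant; in outbred pedigrees there is usually too little IBD
for the coverage thresholds to be met.

## Stages

**Cohorts.** Pairwise matches become cohorts by connected-component
clustering: two (haplotype, interval) claims are joined when a match links
them or when they sit on the same haplotype with reciprocal overlap ≥ 0.5.
The cohort interval is the *intersection* of member intervals, so every
member carries the whole reported segment — which the source-finding stage
assumes. Components whose intersection falls under the 3 cM floor are split
greedily by interval similarity and dropped if unsplittable (the dropped
count is reported).

**Source finding.** The multiset sweep computes, for every ancestor, the
number of descent chains to each cohort member; the per-member counts
multiply into the path count `d(s)`. Ancestors whose multiset cardinality
equals the largest cardinality among their children contribute no route of
their own and are trimmed; spouses with identical multisets merge into a
couple source (remarriage yields different cardinalities, in which case the
individual source is kept — never the couple). Cohort members themselves are
never candidates, so a cohort in which one member is an ancestor of all the
others has no external source and the segment is skipped. The individuals on
*all* descendance paths are computed without enumeration: `v` is on every
path iff for some member `c`, `chains(s→v)·chains(v→c) = chains(s→c)`
(exact integer arithmetic); explicit enumeration is retained as a bounded
facility and as the test oracle.

**Placement.** "min path" takes the candidate with the fewest paths (ties:
most recent generation, then id). "max prob" ranks candidates by the
probability that every cohort member receives the intact segment: each
meiosis transmits it with `q = ½·e^(−ℓ)` (fair strand choice times the
Haldane no-crossover probability for genetic length `ℓ` Morgans), edges are
independent, and the probability that all members are reached through at
least one route is summed exactly over edge outcomes while `2^|E|` stays
within `prob_config_cap`, falling back to the best single-path product (a
lower bound) beyond it. The chosen source's segment is deposited in every
on-all-paths individual; if one of them already has fixed haplotypes and the
segment agrees with neither (best agreement < 98 % over ≥ 50 comparable
SNPs), the source is rejected and the next candidate tried.

Each deposit also records through which parents of the target the segment
can have arrived (those that are the source or descend from it). Since a
haplotype comes from exactly one parent, this *parental side* is carried
into grouping as a Mendelian constraint: a group's feasible sides are the
intersection of its members' sides, side-incompatible segments never join
the same group, and the two retained haplotype groups must be assignable to
different parents (otherwise the weaker one is discarded and re-sourced).
This constraint is pure bookkeeping on information placement already has; it
never uses genotype data.

**Grouping.** Homozygous regions are detected first: maximal runs where the
pooled deposits show a single allele at every site, span > 300 kbp and
≥ 100 SNPs, *and* have deposit depth ≥ 2 (one lone segment is no evidence).
Each region is duplicated into two seed groups — one per chromosome copy —
that are marked as partners and may never be merged with each other.
Remaining segments are assigned longest-first: a segment joins the
best-agreeing group (agreement ≥ 98 % over ≥ 50 shared SNPs), bridges and
merges multiple agreeing groups, opens a new group when it overlaps at most
one group insufficiently, and is reported as mis-sourced when it disagrees
with two or more groups (the "conflicts with both haplotypes" situation). A
final line-up pass merges groups with disjoint covered ranges separated by
at most 50 genotyped SNPs — fragments split by an ancestral recombination.

**Strength and classification.** A group is strong when its coverage meets
the count-dependent scale (default 1–2 IBDs → 90 %, 3–9 → 70 %, ≥ 10 →
50 %; Settings A and B override the scale for generations ≤ 7, A stricter,
B looser). Reconstructed = exactly two strong groups, or two strong groups
plus only weak ones each having at most half the IBD count *or* half the
covered length (in SNPs) of the weaker strong group; those weak groups'
segments are rejected for re-sourcing. One strong group is `partial`; a
single group covering every SNP is flagged `homozygous` (accepted as
reconstructed only with `accept_full_homozygous`).

**Iteration.** Genotyped individuals seed the reconstructed list; each round
re-sources pending segments (all of them initially, later only those whose
source was rejected), regroups the unreconstructed individuals, and fixes
the haplotypes of newly reconstructed ones (they never change afterwards).
Ancestral generations are released to reconstruction through a moving
frontier, most recent first, so that fixed recent haplotypes can veto wrong
sources for older individuals before those are attempted. The loop stops
when a round adds nothing, or at `max_iter` (25); termination is guaranteed
because rejected-source sets only grow and candidate lists are finite.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `min_cm` | 3.0 cM | minimum IBD segment length (matches the usual detector floor) |
| `min_overlap_frac` | 0.5 | reciprocal overlap joining claims into cohorts |
| `conflict_agreement` / `conflict_min_snps` | 0.98 / 50 | "conflicts with both haplotypes" test |
| `group_agreement` / `group_min_snps` | 0.98 / 50 | joining a segment to a group |
| `lineup_max_gap` | 50 SNPs | largest gap bridged by the line-up merge |
| `hom_min_bp` / `hom_min_snps` | 300 kbp / 100 | homozygous-region floor |
| `prob_config_cap` | 10⁴ | exact-summation budget for "max prob" |
| `max_iter` | 25 | iteration cap (runs converge in ~5–20) |

The 98 %/50-SNP agreement thresholds tolerate sparse genotyping error
without admitting wrong lineages (two unrelated haplotypes agree at ~60 %
of sites under the default allele-frequency law). The 50-SNP line-up gap
(1 cM at the default SNP density) exists because the 3 cM floor erodes
segment ends near recombination junctions: with a gap of zero, haplotypes
fragment into groups that never reach the coverage tiers; 50 SNPs bridges
those erosion gaps while opposite-haplotype groups — whose covered ranges
almost always overlap — remain ineligible for line-up merging.

## The simulator

`simulate_pedigree` builds a generation-stratified population: a fixed
number of couples per generation (12), children per couple uniform on 2–4,
and marriage quotas binding 5 % of unions to first cousins, 10 % to second
cousins and 10 % to third cousins (degree = depth of the closest shared
ancestral couple, classified structurally). Quota demand unmet in early
generations (cousins of the required depth do not exist yet) rolls forward,
so realized fractions track the quotas over the whole pedigree. Remaining
unions avoid relatives of fourth degree or closer, taking a married-in
founder spouse when the pool has no eligible partner; the final generation
does not marry. The default scenario is 8 generations (~300 individuals)
with the bottom three generations genotyped.

`gene_drop` assigns founder haplotypes i.i.d. per site with minor-allele
frequency uniform on (0.05, 0.5) and simulates each meiosis with a Poisson
crossover count (mean = map length in Morgans), uniform crossover positions
and a fair starting strand — the Haldane model, deliberately matching the
placement stage's transmission probability so the Monte-Carlo oracles close.
Every allele carries its founder-haplotype label, so true IBD is exact:
`true_ibd_segments` emits every *maximal (carrier set, interval) rectangle*
per founder haplotype (at least two distinct individuals, ≥ 3 cM). This
multi-scale truth contains the long pairwise segments of close relatives
together with the shorter, deeper-cohort segments nested inside them — the
information an IBD detector's pairwise output carries. (A cohort-constant
segmentation was evaluated instead and rejected: carrier sets of common
founder haplotypes change every few cM, so constant runs fragment below the
3 cM floor and starve the reconstruction.)

What the generator does **not** emulate: linkage disequilibrium and
coalescent structure among founder haplotypes, genotyping and phasing
error, IBS masquerading as IBD, detector boundary noise, crossover
interference, sex-specific maps, and multiple chromosomes. Passing tests
therefore demonstrate the combinatorial machinery and its calibration under
clean input; they do not bound performance on array data with phasing
error, where the agreement thresholds and the conflict test carry the load.

## Numerical and determinism notes

All stages are deterministic given the input: candidate order is
(d, generation desc, id); segments are processed by descending cM (ties:
start, id); group consensus ties break to allele 0; couples sort by the
ordered id pair. Reruns with the same seed and configuration are
bit-identical, including emitted files. The only randomness is the
simulator's, driven entirely by the config seed.

## Limitations

* Source confusion is the dominant error: in looped pedigrees many
  candidates are genuine common ancestors of a cohort, and both selection
  heuristics sometimes choose a source whose bottleneck individuals did not
  actually carry the segment. Conflict resolution removes part of this, but
  segments from a single wrong lineage are mutually consistent and can
  assemble into a clean-looking wrong haplotype.
* At desk scale (one 100 cM chromosome, a few hundred true segments), the
  coverage tiers for ancestors are typically met only with the help of
  homozygous-region duplication, which copies regions covered on one
  chromosome onto both. Where the individual is actually heterozygous this
  caps the attainable identity of reconstructed ancestors (observed
  plateau ≈ 0.75–0.82 in the end-to-end tests, against ≥ 0.98 for genotyped
  individuals' grouping); disabling the duplication removes ancestral
  reconstructions entirely at this segment density. With genome-scale
  input the tiers are met by genuine two-sided coverage and the mechanism
  matters less.
* A segment whose cohort member is an ancestor of all other members has no
  external source and is skipped; its information is not used.
* Reconstructed haplotypes are frozen when declared; an early wrong
  reconstruction can reject later correct segments. The generation frontier
  mitigates but does not eliminate this.
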