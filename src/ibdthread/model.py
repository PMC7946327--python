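"""Model/Results interface over the reconstruction pipeline.

`AncestralReconstruction` bundles the data (pedigree, phased panel, IBD
segments) with the configuration; `fit()` runs the iterative
reconstruction and returns `ReconstructionResults`, which carries the
per-individual assemblies, the reconstructed haplotypes, diagnostics and
a `summary()` table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .driver import ReconstructionResult, ThreadConfig, emit_outputs, run_thread
from .ibdio import (HaplotypePanel, IBDSegment, build_cohorts, read_match,
                    read_phased_vcf, read_plink_map)
from .metrics import individual_similarity
from .pedigree import Pedigree, parse_pedigree

__all__ = ["AncestralReconstruction", "ReconstructionResults"]


class AncestralReconstruction:
    """Reconstruct ancestral haplotypes from IBD sharing among genotyped
    descendants of an extended (possibly looped) pedigree.

    Parameters
    ----------
    pedigree : Pedigree
        Family structure; genotyped flags mark the panel individuals.
    panel : HaplotypePanel
        Phased biallelic haplotypes for the genotyped individuals
        (one chromosome).
    segments : list of IBDSegment
        Multi-individual IBD cohorts; build them from pairwise matches
        with :func:`ibdthread.ibdio.build_cohorts` or use
        :meth:`from_files`.
    """

    def __init__(self, pedigree: Pedigree, panel: HaplotypePanel,
                 segments: Sequence[IBDSegment],
                 config: ThreadConfig | None = None) -> None:
        self.pedigree = pedigree
        self.panel = panel
        self.segments = list(segments)
        self.config = config or ThreadConfig()

    @classmethod
    def from_files(cls, pedigree_path: str | Path, vcf_path: str | Path,
                   match_path: str | Path, map_path: str | Path | None = None,
                   config: ThreadConfig | None = None,
                   ) -> "AncestralReconstruction":
        """Build the model from a pedigree file, phased VCF, GERMLINE
        .match file and optional PLINK .map genetic map."""
        with open(pedigree_path) as fh:
            ped = parse_pedigree(fh)
        panel = read_phased_vcf(vcf_path)
        if map_path is not None:
            panel.attach_map(*read_plink_map(map_path))
        with open(match_path) as fh:
            matches = read_match(fh, known_samples=set(panel.samples))
        segments, _ = build_cohorts(matches, panel)
        return cls(ped, panel, segments, config)

    def fit(self, source_method: str | None = None) -> "ReconstructionResults":
        config = self.config
        if source_method is not None:
            from dataclasses import replace
            config = replace(config, source_method=source_method)
        raw = run_thread(self.pedigree, self.panel, self.segments, config)
        return ReconstructionResults(self, raw)


class ReconstructionResults:
    """Fitted reconstruction: haplotypes, assemblies and diagnostics."""

    def __init__(self, model: AncestralReconstruction,
                 raw: ReconstructionResult) -> None:
        self.model = model
        self.raw = raw

    # -- convenience views -------------------------------------------------

    @property
    def haplotypes(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        return self.raw.haplotypes

    @property
    def reconstructed_ids(self) -> list[str]:
        return self.raw.reconstructed_ids

    @property
    def n_reconstructed(self) -> int:
        return self.raw.n_reconstructed

    @property
    def iterations(self) -> int:
        return self.raw.iterations

    @property
    def converged(self) -> bool:
        return self.raw.converged

    def coverage(self, individual: str) -> float:
        """Fraction of panel SNPs covered by the two retained haplotypes
        (mean of the two)."""
        h0, h1 = self.raw.haplotypes[individual]
        return float(((h0 >= 0).mean() + (h1 >= 0).mean()) / 2)

    def similarity_to(self, truth: dict[str, tuple[np.ndarray, np.ndarray]]
                      ) -> pd.DataFrame:
        """Score every reconstructed individual against known haplotypes."""
        rows = []
        for ind in self.reconstructed_ids:
            if ind not in truth:
                continue
            rows.append({
                "individual": ind,
                "generation": self.raw.generations.get(ind),
                "similarity": individual_similarity(self.raw.haplotypes[ind],
                                                    truth[ind]),
                "coverage": self.coverage(ind),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable run summary (counts, iterations, convergence)."""
        statuses = pd.Series(
            {i: a.status for i, a in self.raw.assemblies.items()})
        counts = statuses.value_counts().to_dict() if len(statuses) else {}
        lines = [
            "Ancestral haplotype reconstruction",
            "==================================",
            f"chromosome:            {self.model.panel.chrom}",
            f"panel SNPs:            {self.model.panel.n_snps}",
            f"IBD segments:          {self.raw.n_segments} "
            f"(pairs {self.raw.n_pairs}, skipped {len(self.raw.skipped_segments)})",
            f"iterations:            {self.raw.iterations} "
            f"({'converged' if self.raw.converged else 'iteration cap reached'})",
            f"reconstructed:         {self.raw.n_reconstructed} ancestral individuals",
        ]
        for status in ("partial", "unresolved", "homozygous"):
            if counts.get(status):
                lines.append(f"  {status:<20} {counts[status]}")
        if self.raw.n_reconstructed:
            covs = [self.coverage(i) for i in self.reconstructed_ids]
            lines.append(f"mean haplotype coverage: {np.mean(covs):.3f}")
        return "\n".join(lines)

    def to_files(self, out_dir: str | Path, prefix: str = "ibdthread"):
        return emit_outputs(self.raw, self.model.panel, out_dir, prefix)
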