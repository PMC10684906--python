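"""Binned heterozygosity scanning from variant calls.

Loss of one parental chromosome (or of a whole parental genome) erases
heterozygosity over the affected region.  This module applies the
variant post-filters (QUAL > 140, DP <= 50, SCBZ <= 0), retains only
heterozygous genotypes, counts them in the shared 250 kb bins, and
compares a sample's per-bin counts against outbred controls to call
chromosome- or genome-wide heterozygosity loss.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from .errors import KaryoscreenError
from .layout import BinGrid

QUAL_MIN_EXCLUSIVE = 140.0
DP_MAX = 50
SCBZ_MAX = 0.0


@dataclass(frozen=True)
class VariantRecord:
    """One VCF site reduced to the fields the filters need.

    ``scbz`` may be None when the caller did not emit the soft-clip-bias
    annotation; see ``filter_variants`` for how that is handled.
    """

    chrom: str
    pos: int  # 1-based
    qual: float
    dp: int
    scbz: float | None
    genotype: str  # hom_ref | het | hom_alt | missing


@dataclass
class VariantFilterStats:
    """Discard tallies per filter clause (first failing clause wins)."""

    retained: int = 0
    low_qual: int = 0
    high_dp: int = 0
    positive_scbz: int = 0
    not_het: int = 0
    missing_scbz_passed: int = 0


def _genotype_from_gt(gt: tuple) -> str:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return "missing"
    if len(set(alleles)) > 1:
        return "het"
    return "hom_ref" if alleles[0] == 0 else "hom_alt"


def read_variants(path) -> Iterator[VariantRecord]:
    """Stream a single-sample VCF as VariantRecord."""
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise KaryoscreenError(
                f"expected a single-sample VCF, found {len(samples)} samples in {path}"
            )
        for rec in vcf:
            gt = rec.samples[samples[0]].get("GT", (None,))
            dp = rec.info.get("DP", 0)
            scbz = rec.info.get("SCBZ", None)
            yield VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                qual=float(rec.qual) if rec.qual is not None else 0.0,
                dp=int(dp) if dp is not None else 0,
                scbz=float(scbz) if scbz is not None else None,
                genotype=_genotype_from_gt(gt),
            )


def filter_variants(
    records: Iterable[VariantRecord],
    stats: VariantFilterStats | None = None,
    strict_scbz: bool = False,
) -> Iterator[VariantRecord]:
    """Retain heterozygous calls passing QUAL > 140, DP <= 50, SCBZ <= 0.

    Records lacking SCBZ pass that clause with a warning tally by
    default (many callers do not emit it); ``strict_scbz=True`` drops
    them instead.  Filtering is idempotent: a retained stream passes
    unchanged through a second application.
    """
    stats = stats if stats is not None else VariantFilterStats()
    for rec in records:
        if rec.qual <= QUAL_MIN_EXCLUSIVE:
            stats.low_qual += 1
            continue
        if rec.dp > DP_MAX:
            stats.high_dp += 1
            continue
        if rec.scbz is None:
            if strict_scbz:
                stats.positive_scbz += 1
                continue
            stats.missing_scbz_passed += 1
        elif rec.scbz > SCBZ_MAX:
            stats.positive_scbz += 1
            continue
        if rec.genotype != "het":
            stats.not_het += 1
            continue
        stats.retained += 1
        yield rec


@dataclass
class HetProfile:
    """Per-bin heterozygous-SNP counts for one sample."""

    sample_id: str
    counts: dict[str, np.ndarray]
    grid: BinGrid

    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def to_tsv(self, path) -> None:
        rows = []
        for chrom in self.grid.chromosomes:
            for b in range(self.grid.n_bins(chrom)):
                start, end = self.grid.bin_bounds(chrom, b)
                rows.append(
                    {"chrom": chrom, "bin_start": start, "bin_end": end, "het_count": int(self.counts[chrom][b])}
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def bin_het_snps(records: Iterable[VariantRecord], grid: BinGrid, sample_id: str = "sample") -> HetProfile:
    """Count retained het SNPs per bin by mapped position (1-based)."""
    counts = grid.zero_counts()
    for rec in records:
        if rec.chrom not in counts:
            raise KeyError(f"contig {rec.chrom!r} not present in the bin grid")
        counts[rec.chrom][grid.bin_index(rec.chrom, rec.pos - 1)] += 1
    return HetProfile(sample_id, counts, grid)


@dataclass
class HetLossCall:
    """Per-chromosome and genome-wide heterozygosity verdicts."""

    sample_id: str
    chromosome_verdicts: dict[str, str]  # normal | reduced
    genome_wide: str  # normal | genome_wide_reduction
    uninformative: list[str] = field(default_factory=list)

    def reduced_chromosomes(self) -> list[str]:
        return [c for c, v in self.chromosome_verdicts.items() if v == "reduced"]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "sample_id": self.sample_id,
                "chromosome_verdicts": self.chromosome_verdicts,
                "genome_wide": self.genome_wide,
                "uninformative_chromosomes": self.uninformative,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def detect_het_loss(
    sample: HetProfile,
    controls: list[HetProfile],
    threshold_fraction: float = 0.10,
) -> HetLossCall:
    """Flag chromosomes whose het density collapsed relative to controls.

    A chromosome is "reduced" when the sample's median per-bin het count
    falls below ``threshold_fraction`` of the controls' median per-bin
    count for that chromosome (controls pooled).  Chromosomes where the
    control median itself is zero carry no information and stay
    "normal" with an uninformative flag.  Genome-wide reduction requires
    every chromosome to be reduced.
    """
    if len(controls) < 2:
        raise KaryoscreenError(f"need >= 2 control profiles, got {len(controls)}")
    for ctrl in controls:
        if not ctrl.grid.same_grid(sample.grid):
            raise KaryoscreenError("control profile built on a different bin grid")
    verdicts: dict[str, str] = {}
    uninformative: list[str] = []
    for chrom in sample.grid.chromosomes:
        ctrl_bins = np.concatenate([c.counts[chrom] for c in controls])
        ctrl_median = float(np.median(ctrl_bins))
        if ctrl_median == 0:
            verdicts[chrom] = "normal"
            uninformative.append(chrom)
            warnings.warn(f"control het median is zero on {chrom}; chromosome uninformative", stacklevel=2)
            continue
        sample_median = float(np.median(sample.counts[chrom]))
        verdicts[chrom] = "reduced" if sample_median < threshold_fraction * ctrl_median else "normal"
    genome_wide = (
        "genome_wide_reduction"
        if verdicts and all(v == "reduced" for v in verdicts.values())
        else "normal"
    )
    return HetLossCall(sample.sample_id, verdicts, genome_wide, uninformative)


def het_pipeline(
    sample_path,
    control_paths: list,
    grid: BinGrid,
    sample_id: str = "sample",
    threshold_fraction: float = 0.10,
) -> tuple[HetProfile, HetLossCall, VariantFilterStats]:
    """Full heterozygosity workflow on VCF files: filter, bin, compare."""
    stats = VariantFilterStats()
    sample = bin_het_snps(filter_variants(read_variants(sample_path), stats), grid, sample_id)
    controls = [
        bin_het_snps(filter_variants(read_variants(p)), grid, f"control_{i}")
        for i, p in enumerate(control_paths)
    ]
    return sample, detect_het_loss(sample, controls, threshold_fraction), stats
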