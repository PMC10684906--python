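"""Synthetic haploid-inducer cross simulator.

Emulates a cross between a *cenh3* mutant plant (maternal parent) and a
*CENH3* wild-type plant, producing offspring of four karyotype classes:

``self``
    Self-pollination of the mutant parent: two mutant-parent genome
    copies, homozygous for the edited allele at the target locus.
``f1``
    True outcross: one genome copy from each parent, heterozygous at
    the target locus and at every site where the parents differ.
``aneuploid_mono7``
    An F1 that lost the maternal (mutant-parent) copy of chromosome 7:
    chromosome 7 is in a single, wild-type-parent copy; all other
    chromosomes are disomic and biparental.
``eliminated_tetraploid``
    Uniparental genome elimination followed by two rounds of spontaneous
    chromosome doubling: four identical wild-type-parent copies of every
    chromosome and zero heterozygous sites.

For each offspring the simulator can write the raw inputs that the
downstream pipeline consumes: a coordinate-sorted SAM of paired-end
alignments with Poisson per-bin coverage proportional to local copy
number, a VCF 4.2 call set with filterable QUAL/DP/SCBZ fields, an
endpoint-fluorescence (PACE) table, and a per-nucleus flow-cytometry
table whose peak location scales linearly with ploidy.

Parents are modelled as fully homozygous (inbred) at every simulated SNP
site, with each site's alternate allele carried by exactly one parent.
This makes an offspring's genotype a deterministic function of which
parent contributed each chromosome copy, which is exactly the structure
the heterozygosity and lineage analyses exploit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .layout import BinGrid, GenomeLayout

MUTANT_PARENT = "cenh3_mutant"
WILDTYPE_PARENT = "wildtype"

CLASS_LABELS = ("self", "f1", "aneuploid_mono7", "eliminated_tetraploid")

#: SAM FLAG values of a properly paired, mapped read (fwd/rev mate
#: combinations of first/second in pair).
PROPER_PAIR_FLAGS = (99, 147, 83, 163)

_UNIQUE_MAPQ = 60
_READ_SPAN = 150
_TEMPLATE_LEN = 300


def _rng(seed: int, *tags: str) -> np.random.Generator:
    """Derive an independent child generator from the master seed."""
    return np.random.default_rng([seed] + [zlib.crc32(t.encode()) for t in tags])


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cross.

    Parameters
    ----------
    seed
        Master seed; every output stream derives its own child seed from
        it, so identical configs reproduce identical files byte-for-byte.
    depth_per_copy
        Expected retained read *pairs* per bin per chromosome copy.
    read_length
        Read length in bp (both mates).
    variant_density_per_kb
        SNP sites per kilobase of genome. Each site is homozygous within
        each parent and polymorphic between them.
    genotyping_error
        Probability that an emitted genotype call is flipped
        (hom -> het or het -> hom).
    fluorescence_cv
        Multiplicative (log-scale) noise on PACE and flow intensities.
    nuclei_per_sample
        Flow-cytometry events simulated per sample.
    decoy_fraction
        Fraction of extra SAM records that deliberately fail one of the
        three alignment filters (improper flag / low MAPQ / mate on
        another contig).
    filter_fail_fraction
        Per-clause probability that a VCF record is planted with a
        failing QUAL, DP or SCBZ value.
    """

    seed: int = 0
    depth_per_copy: float = 30.0
    read_length: int = _READ_SPAN
    variant_density_per_kb: float = 0.2
    genotyping_error: float = 0.0
    fluorescence_cv: float = 0.05
    nuclei_per_sample: int = 5000
    decoy_fraction: float = 0.0
    filter_fail_fraction: float = 0.05
    flow_base_intensity: float = 100.0

    def __post_init__(self) -> None:
        for name in ("genotyping_error", "decoy_fraction", "filter_fail_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.depth_per_copy <= 0:
            raise ConfigError("depth_per_copy must be positive")
        if self.variant_density_per_kb < 0:
            raise ConfigError("variant_density_per_kb must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class ParentalGenome:
    """One parent of the cross.

    ``snp_alleles`` maps ``(chromosome, position)`` to the parent's
    diploid genotype over ``{"ref", "alt"}``; in this simulator parents
    are homozygous at every site.  ``marker_haplotypes`` holds the
    homozygous allele at each diagnostic marker locus, and
    ``mito_haplotype`` the organellar haplotype string.
    """

    parent_id: str
    snp_alleles: dict[tuple[str, int], tuple[str, str]]
    marker_haplotypes: dict[str, str]
    mito_haplotype: str

    def allele_at(self, chrom: str, pos: int) -> str:
        gt = self.snp_alleles[(chrom, pos)]
        return gt[0]


@dataclass(frozen=True)
class OffspringSpec:
    """Ground truth for one progeny seedling.

    ``origins`` lists, per chromosome, the parent contributing each copy;
    its length is the chromosome copy number.  ``segment_overrides`` may
    replace the copy number on a run of bins (used to emulate partial
    chromosome duplication); overrides affect read coverage only.
    """

    offspring_id: str
    class_label: str
    origins: dict[str, tuple[str, ...]]
    edited_locus_genotype: str  # hom_edited | het | hom_wildtype
    nominal_ploidy: int
    segment_overrides: tuple[tuple[str, int, int, int], ...] = ()

    def copy_number(self, chrom: str) -> int:
        return len(self.origins[chrom])

    def copy_number_for_bin(self, chrom: str, bin_index: int) -> int:
        for c, lo, hi, n in self.segment_overrides:
            if c == chrom and lo <= bin_index < hi:
                return n
        return self.copy_number(chrom)


def _make_parents(layout: GenomeLayout, config: SimulationConfig) -> tuple[ParentalGenome, ParentalGenome]:
    rng = _rng(config.seed, "sites")
    mut_snps: dict[tuple[str, int], tuple[str, str]] = {}
    wt_snps: dict[tuple[str, int], tuple[str, str]] = {}
    for chrom in layout.names:
        length = layout.lengths[chrom]
        n_sites = int(round(config.variant_density_per_kb * length / 1000))
        if n_sites == 0:
            continue
        positions = np.sort(rng.choice(np.arange(1, length + 1), size=n_sites, replace=False))
        carriers = rng.random(n_sites) < 0.5  # True -> mutant parent carries alt
        for pos, mut_is_carrier in zip(positions, carriers):
            site = (chrom, int(pos))
            mut_snps[site] = ("alt", "alt") if mut_is_carrier else ("ref", "ref")
            wt_snps[site] = ("ref", "ref") if mut_is_carrier else ("alt", "alt")

    # Two diagnostic marker loci per chromosome, homozygous and divergent.
    mut_markers: dict[str, str] = {}
    wt_markers: dict[str, str] = {}
    bases = "ACGT"
    for i, chrom in enumerate(layout.names):
        for j in (1, 2):
            locus = f"M{chrom[3:] if chrom.startswith('chr') else chrom}_{j}"
            a = bases[(2 * i + j) % 4]
            b = bases[(2 * i + j + 1) % 4]
            mut_markers[locus] = a
            wt_markers[locus] = b

    mut = ParentalGenome(MUTANT_PARENT, mut_snps, mut_markers, mito_haplotype="ATCGGATCCGTA")
    wt = ParentalGenome(WILDTYPE_PARENT, wt_snps, wt_markers, mito_haplotype="ATCGGATCCGGA")
    return mut, wt


def marker_positions(layout: GenomeLayout) -> list[tuple[str, str]]:
    """(locus_id, chromosome) pairs for the two markers per chromosome."""
    out = []
    for chrom in layout.names:
        for j in (1, 2):
            out.append((f"M{chrom[3:] if chrom.startswith('chr') else chrom}_{j}", chrom))
    return out


def _offspring_origins(class_label: str, layout: GenomeLayout) -> tuple[dict[str, tuple[str, ...]], str, int]:
    chroms = layout.names
    if class_label == "self":
        origins = {c: (MUTANT_PARENT, MUTANT_PARENT) for c in chroms}
        return origins, "hom_edited", 2
    if class_label == "f1":
        origins = {c: (MUTANT_PARENT, WILDTYPE_PARENT) for c in chroms}
        return origins, "het", 2
    if class_label == "aneuploid_mono7":
        origins = {c: (MUTANT_PARENT, WILDTYPE_PARENT) for c in chroms}
        chrom7 = chroms[6]
        origins[chrom7] = (WILDTYPE_PARENT,)
        # CENH3 sits on chromosome 7: losing the maternal copy leaves
        # only the wild-type allele visible at the edited locus.
        return origins, "hom_wildtype", 2
    if class_label == "eliminated_tetraploid":
        origins = {c: (WILDTYPE_PARENT,) * 4 for c in chroms}
        return origins, "hom_wildtype", 4
    raise ConfigError(f"unknown offspring class label: {class_label!r}")


def simulate_cross(
    layout: GenomeLayout,
    config: SimulationConfig,
    class_mix: dict[str, int],
) -> tuple[ParentalGenome, ParentalGenome, list[OffspringSpec]]:
    """Build the two parental genomes and the requested progeny.

    Returns ``(mutant_parent, wildtype_parent, offspring)`` with exactly
    ``class_mix[label]`` offspring per class, deterministically under a
    fixed seed.  The mutant parent is always the maternal parent, as in
    the crossing scheme the pipeline is designed for.
    """
    for label, count in class_mix.items():
        if label not in CLASS_LABELS:
            raise ConfigError(f"unknown offspring class label: {label!r}")
        if count < 0:
            raise ConfigError(f"negative count for class {label!r}")
    mut, wt = _make_parents(layout, config)
    offspring: list[OffspringSpec] = []
    for label in CLASS_LABELS:
        for i in range(class_mix.get(label, 0)):
            origins, edited_gt, ploidy = _offspring_origins(label, layout)
            offspring.append(
                OffspringSpec(
                    offspring_id=f"{label}_{i:03d}",
                    class_label=label,
                    origins=origins,
                    edited_locus_genotype=edited_gt,
                    nominal_ploidy=ploidy,
                )
            )
    return mut, wt, offspring


def marker_loci_for(
    offspring: OffspringSpec,
    mut: ParentalGenome,
    wt: ParentalGenome,
    layout: GenomeLayout,
):
    """Diagnostic marker genotypes of one offspring, as MarkerLocus records.

    The alleles observed in the progeny are the union over its
    chromosome copies of the contributing parents' (homozygous) marker
    alleles — a presence-based genotype, as in Sanger/PCR assays.
    """
    from .lineage import MarkerLocus

    parents = {MUTANT_PARENT: mut, WILDTYPE_PARENT: wt}
    loci = []
    for locus_id, chrom in marker_positions(layout):
        alleles = frozenset(
            parents[p].marker_haplotypes[locus_id] for p in offspring.origins[chrom]
        )
        loci.append(
            MarkerLocus(
                locus_id=locus_id,
                chrom=chrom,
                parent_a_allele=mut.marker_haplotypes[locus_id],
                parent_b_allele=wt.marker_haplotypes[locus_id],
                progeny_alleles=alleles,
            )
        )
    return loci


def write_marker_table(
    offspring: OffspringSpec,
    mut: ParentalGenome,
    wt: ParentalGenome,
    layout: GenomeLayout,
    path,
) -> pd.DataFrame:
    """Write the lineage-assignment input CSV for one offspring."""
    rows = []
    for locus in marker_loci_for(offspring, mut, wt, layout):
        rows.append(
            {
                "locus_id": locus.locus_id,
                "chrom": locus.chrom,
                "parentA_gt": locus.parent_a_allele,
                "parentB_gt": locus.parent_b_allele,
                "progeny_gt": "/".join(sorted(locus.progeny_alleles)),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def write_mito_table(mut: ParentalGenome, wt: ParentalGenome, path) -> pd.DataFrame:
    """Write the organellar haplotype CSV (the mutant parent is maternal)."""
    df = pd.DataFrame(
        [
            {"parent_id": mut.parent_id, "haplotype": mut.mito_haplotype},
            {"parent_id": wt.parent_id, "haplotype": wt.mito_haplotype},
            {"parent_id": "progeny", "haplotype": mut.mito_haplotype},
        ]
    )
    df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# SAM emission


def _sam_header(layout: GenomeLayout) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for chrom in layout.names:
        lines.append(f"@SQ\tSN:{chrom}\tLN:{layout.lengths[chrom]}")
    return lines


def write_alignments(
    offspring: OffspringSpec,
    layout: GenomeLayout,
    config: SimulationConfig,
    path,
) -> int:
    """Write a coordinate-sorted SAM for one offspring; returns pair count.

    Retained read pairs per bin are Poisson with mean
    ``copy_number x depth_per_copy``; both mates of a pair have their mid
    position inside the same bin, so each pair contributes exactly two
    records to that bin's count downstream.  ``decoy_fraction`` adds
    records that each violate exactly one of the three alignment filters.
    """
    grid = BinGrid(layout)
    rng = _rng(config.seed, "sam", offspring.offspring_id)
    rl = config.read_length
    records: dict[str, list[tuple[int, str]]] = {c: [] for c in layout.names}
    n_pairs = 0
    for chrom in layout.names:
        for b in range(grid.n_bins(chrom)):
            copy = offspring.copy_number_for_bin(chrom, b)
            if copy == 0:
                continue
            start, end = grid.bin_bounds(chrom, b)
            # leftmost 0-based position such that both mate mid positions
            # (pos0 + rl//2 and pos0 + rl + rl//2) stay inside the bin
            hi = end - (rl + rl // 2 + 1)
            if hi <= start:
                continue
            k = rng.poisson(copy * config.depth_per_copy)
            if k == 0:
                continue
            pos0 = rng.integers(start, hi, size=k)
            orient = rng.random(k) < 0.5
            for i in range(k):
                qname = f"{offspring.offspring_id}.{chrom}.{b}.{i}"
                p1 = int(pos0[i]) + 1  # SAM is 1-based
                p2 = p1 + rl
                f1, f2 = (99, 147) if orient[i] else (83, 163)
                records[chrom].append(
                    (p1, _sam_line(qname, f1, chrom, p1, _UNIQUE_MAPQ, rl, "=", p2, _TEMPLATE_LEN))
                )
                records[chrom].append(
                    (p2, _sam_line(qname, f2, chrom, p2, _UNIQUE_MAPQ, rl, "=", p1, -_TEMPLATE_LEN))
                )
                n_pairs += 1

    n_proper = 2 * n_pairs
    n_decoy = int(round(config.decoy_fraction * n_proper))
    for i in range(n_decoy):
        chrom = layout.names[int(rng.integers(len(layout.names)))]
        pos = int(rng.integers(1, layout.lengths[chrom] - rl))
        kind = i % 3
        qname = f"{offspring.offspring_id}.decoy.{i}"
        if kind == 0:  # paired but not in a proper pair (flag 97)
            line = _sam_line(qname, 97, chrom, pos, _UNIQUE_MAPQ, rl, "=", pos + rl, _TEMPLATE_LEN)
        elif kind == 1:  # non-unique mapping quality
            line = _sam_line(qname, 99, chrom, pos, 30, rl, "=", pos + rl, _TEMPLATE_LEN)
        else:  # mate on another contig
            other = layout.names[(layout.names.index(chrom) + 1) % len(layout.names)]
            line = _sam_line(qname, 99, chrom, pos, _UNIQUE_MAPQ, rl, other, pos + rl, 0)
        records[chrom].append((pos, line))

    with open(path, "w") as fh:
        for line in _sam_header(layout):
            fh.write(line + "\n")
        for chrom in layout.names:
            for _, line in sorted(records[chrom], key=lambda t: t[0]):
                fh.write(line + "\n")
    return n_pairs


def _sam_line(qname, flag, rname, pos, mapq, rl, rnext, pnext, tlen) -> str:
    return "\t".join(
        [qname, str(flag), rname, str(pos), str(mapq), f"{rl}M", rnext, str(pnext), str(tlen), "*", "*"]
    )


# ---------------------------------------------------------------------------
# VCF emission


def _true_genotype(offspring: OffspringSpec, mut: ParentalGenome, wt: ParentalGenome, chrom: str, pos: int) -> str:
    parents = {MUTANT_PARENT: mut, WILDTYPE_PARENT: wt}
    alleles = {parents[p].allele_at(chrom, pos) for p in offspring.origins[chrom]}
    if alleles == {"ref"}:
        return "hom_ref"
    if alleles == {"alt"}:
        return "hom_alt"
    return "het"


def write_variant_calls(
    offspring: OffspringSpec,
    mut: ParentalGenome,
    wt: ParentalGenome,
    layout: GenomeLayout,
    config: SimulationConfig,
    path,
) -> int:
    """Write a single-sample VCF 4.2 call set; returns record count.

    Emits one record per simulated SNP site at which the (possibly
    miscalled) genotype is non-reference.  With probability
    ``genotyping_error`` a call is flipped hom<->het.  A
    ``filter_fail_fraction`` of records is planted, per clause, with
    QUAL <= 140, DP > 50 or SCBZ > 0 so the downstream filters have
    something to remove.
    """
    rng = _rng(config.seed, "vcf", offspring.offspring_id)
    sites = sorted(mut.snp_alleles)
    chrom_order = {c: i for i, c in enumerate(layout.names)}
    sites.sort(key=lambda s: (chrom_order[s[0]], s[1]))

    n = 0
    lines: list[str] = []
    for chrom, pos in sites:
        gt = _true_genotype(offspring, mut, wt, chrom, pos)
        if config.genotyping_error > 0 and rng.random() < config.genotyping_error:
            if gt == "het":
                gt = "hom_alt" if rng.random() < 0.5 else "hom_ref"
            else:
                gt = "het"
        if gt == "hom_ref":
            continue
        qual = 150.0 + 250.0 * rng.random()
        dp = min(int(rng.poisson(30)), 50)
        scbz = -abs(rng.normal(1.0, 0.5))
        f = config.filter_fail_fraction
        if f > 0:
            if rng.random() < f:
                qual = 20.0 + 120.0 * rng.random()  # QUAL <= 140
            if rng.random() < f:
                dp = int(rng.integers(51, 101))  # DP > 50
            if rng.random() < f:
                scbz = 0.1 + 2.0 * rng.random()  # SCBZ > 0
        gt_field = {"het": "0/1", "hom_alt": "1/1"}[gt]
        lines.append(
            f"{chrom}\t{pos}\t.\tA\tC\t{qual:.1f}\t.\tDP={dp};SCBZ={scbz:.3f}\tGT\t{gt_field}"
        )
        n += 1

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in layout.names:
            fh.write(f"##contig=<ID={chrom},length={layout.lengths[chrom]}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">\n')
        fh.write('##INFO=<ID=SCBZ,Number=1,Type=Float,Description="Soft-clip length bias z-score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{offspring.offspring_id}\n")
        for line in lines:
            fh.write(line + "\n")
    return n


# ---------------------------------------------------------------------------
# Fluorescence tables

#: Endpoint-fluorescence archetypes at the edited locus. The HEX primer
#: reads the edited allele, the FAM primer the wild-type allele, so
#: self-pollinations are HEX-only, F1s show both channels equally, and
#: genome-elimination candidates are FAM-only.
_PACE_ARCHETYPE = {
    "hom_edited": (0.0, 1.0),
    "het": (0.5, 0.5),
    "hom_wildtype": (1.0, 0.0),
}


def write_fluorescence_tables(
    offspring: list[OffspringSpec],
    config: SimulationConfig,
    pace_path,
    flow_path,
    include_reference: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write the PACE (seedling_id,fam,hex) and flow (sample_id,fluorescence) CSVs.

    PACE intensities are the class archetype under multiplicative
    log-normal noise.  Flow events are drawn per nucleus around
    ``flow_base_intensity x ploidy``, again with multiplicative noise, so
    peak medians scale linearly with ploidy.  When ``include_reference``
    is set, a diploid reference sample is appended to the flow table.
    """
    if not offspring:
        raise ConfigError("offspring list is empty")
    cv = config.fluorescence_cv

    pace_rng = _rng(config.seed, "pace")
    pace_rows = []
    for o in offspring:
        fam0, hex0 = _PACE_ARCHETYPE[o.edited_locus_genotype]
        noise = np.exp(pace_rng.normal(0.0, cv, size=2)) if cv > 0 else np.ones(2)
        pace_rows.append({"seedling_id": o.offspring_id, "fam": fam0 * noise[0], "hex": hex0 * noise[1]})
    pace = pd.DataFrame(pace_rows, columns=["seedling_id", "fam", "hex"])
    pace.to_csv(pace_path, index=False)

    flow_rng = _rng(config.seed, "flow")
    flow_frames = []
    samples = [(o.offspring_id, o.nominal_ploidy) for o in offspring]
    if include_reference:
        samples.append(("diploid_reference", 2))
    for sample_id, ploidy in samples:
        loc = config.flow_base_intensity * ploidy
        if cv > 0:
            values = loc * np.exp(flow_rng.normal(0.0, cv, size=config.nuclei_per_sample))
        else:
            values = np.full(config.nuclei_per_sample, loc)
        flow_frames.append(pd.DataFrame({"sample_id": sample_id, "fluorescence": values}))
    flow = pd.concat(flow_frames, ignore_index=True)
    flow.to_csv(flow_path, index=False)
    return pace, flow
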