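# karyoscreen

Detection of **uniparental genome elimination, aneuploidy and ploidy
change** in progeny of haploid-inducer crosses.

Crossing a *cenh3* mutant plant (centromeric histone H3) with a
*CENH3* wild-type plant can trigger missegregation of the mutant
parent's chromosomes in the young embryo, producing progeny that lost a
single chromosome (aneuploids) or an entire parental genome (the basis
of *in vivo* haploid induction, and — after spontaneous doubling —
of "instant inbred" doubled haploids). `karyoscreen` implements the
complete screening workflow used to find and characterize such progeny
in a carrot cenh3 × wild-type crossing scheme, plus a cross simulator
that generates every raw input with known ground truth, so the whole
pipeline is testable at desk scale.

## The analyses

Let a genome have chromosomes divided into 250 kb bins.

**Progeny classification** (`karyoscreen.genotyping`) — at the edited
CENH3 locus, the allele fraction from endpoint fluorescence,
*r* = FAM/(FAM+HEX), classifies each seedling: *r* ≈ 0 →
self-pollination (`self`), *r* ≈ ½ → outcross (`f1`), *r* ≈ 1 →
genome-elimination `candidate` (only the wild-type allele present).
Per-cross summaries report the self-pollination rate
100·*self*/(*surveyed* − *no-calls*), rounded half-up to one decimal.

**Dosage analysis** (`karyoscreen.dosage`) — reads with
FLAG ∈ {83, 99, 147, 163}, RNEXT `=` and MAPQ = 60 are counted per bin by
mid position; each bin count is divided by the sample's total retained
reads (percent depth), divided by the mean percent depth of ≥ 2
wild-type controls, and multiplied by 2. A euploid bin sits at ~2;
a monosomic chromosome oscillates around 1, a trisomic segment around 3.
Being a *relative* measure, whole-genome duplication is invisible here
— that is the flow module's job.

**Heterozygosity scan** (`karyoscreen.hetscan`) — variant calls pass
QUAL > 140, DP ≤ 50, SCBZ ≤ 0; only heterozygous genotypes are kept and
counted per bin. A chromosome whose median per-bin het count falls
below 10% of the controls' median is called reduced; reduction on every
chromosome is the genome-elimination signature.

**Lineage assignment** (`karyoscreen.lineage`) — eighteen diagnostic
marker loci (two per chromosome) where the parents are homozygous for
different alleles: a progeny carrying only one parent's allele at every
informative locus is uniparental; the maternal parent is identified
from a mitochondrial polymorphism (organelles are inherited
maternally regardless of nuclear karyotype).

**Flow cytometry** (`karyoscreen.flow`) — relative nuclear DNA content
is the ratio of the sample's propidium-iodide G1-peak median to a
diploid reference's, in separate or mixed preparations; nominal ploidy
= round(ratio × 2).

**Simulator** (`karyoscreen.simulate`) — generates two polymorphic
parental genomes and offspring of four classes (`self`, `f1`,
`aneuploid_mono7`, `eliminated_tetraploid`), then writes
coordinate-sorted SAM (per-bin read pairs ~ Poisson(copy × depth), with
optional decoy records that fail each alignment filter), single-sample
VCF 4.2 (het sites exactly where the offspring carries both parental
alleles, with configurable miscall rate and planted filter failures),
and PACE/flow CSVs. Identical seeds give byte-identical files.

## Worked example

```python
from pathlib import Path
import numpy as np
from karyoscreen import *
from karyoscreen.flow import read_flow_csv
from karyoscreen.layout import GenomeLayout, BinGrid

layout = GenomeLayout.default()        # 9 chromosomes x 5 Mb, 250 kb bins
grid = BinGrid(layout)
cfg = SimulationConfig(seed=7)
mut, wt, offspring = simulate_cross(
    layout, cfg, {"f1": 4, "aneuploid_mono7": 1, "eliminated_tetraploid": 1}
)
out = Path("demo"); out.mkdir(exist_ok=True)
for o in offspring:
    write_alignments(o, layout, cfg, out / f"{o.offspring_id}.sam")
    write_variant_calls(o, mut, wt, layout, cfg, out / f"{o.offspring_id}.vcf")
write_fluorescence_tables(offspring, cfg, out / "pace.csv", out / "flow.csv")

controls = [out / f"f1_{i:03d}.sam" for i in range(4)]
profile, call, stats = dosage_pipeline(out / "aneuploid_mono7_000.sam", controls, grid, "mono7")
print("chr7 mean normalized:", round(float(np.nanmean(profile.chromosome_values("chr7"))), 3))
print("dosage states:", call.states)

vcf_controls = [out / f"f1_{i:03d}.vcf" for i in range(4)]
_, het_call, _ = het_pipeline(out / "eliminated_tetraploid_000.vcf", vcf_controls, grid, "elim")
print("het verdict:", het_call.genome_wide)

loci = marker_loci_for(offspring[-1], mut, wt, layout)
calls = [call_marker_origin(l) for l in loci]
print("lineage:", infer_nuclear_lineage(calls).verdict, "| wild-type-only loci:", calls.count("b_only"))

samples = read_flow_csv(out / "flow.csv")
pc = ploidy_separate(samples["eliminated_tetraploid_000"], samples["diploid_reference"])
print("flow ratio:", round(pc.ratio, 3), "nominal ploidy:", pc.nominal_ploidy)
```

prints

```
chr7 mean normalized: 1.054
dosage states: {'chr1': 'disomic', 'chr2': 'disomic', 'chr3': 'disomic', 'chr4': 'disomic', 'chr5': 'disomic', 'chr6': 'disomic', 'chr7': 'monosomic', 'chr8': 'disomic', 'chr9': 'disomic'}
het verdict: genome_wide_reduction
lineage: uniparental_b | wild-type-only loci: 18
flow ratio: 2.0 nominal ploidy: 4
```

The monosomic-7 offspring's chromosome 7 sits near one copy (slightly
above 1 because losing a chromosome shrinks the percent-depth
denominator) and is called monosomic; the genome-eliminated offspring
shows heterozygosity loss on every chromosome, carries the wild-type
parent's allele at all 18 diagnostic loci (`b_only` = wild-type-parent
only), and has twice the reference DNA content — a tetraploid whose
four chromosome sets all trace to one parent.

The same workflow is available from a shell via the `karyoscreen` CLI
(`simulate`, `classify`, `dosage`, `het`, `lineage`, `flow`); run
`karyoscreen --help`.

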