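# Methods

This note documents the models behind `karyoscreen`, the parameters
that matter, the design choices made where the design was genuinely
open, and what the simulation-based tests do and do not demonstrate.

## The screening problem

In a cenh3-mutant × wild-type cross, the mutant parent's centromeres
can fail in the early embryo, producing progeny with a missing
chromosome (aneuploidy) or with the mutant genome eliminated entirely.
Elimination followed by spontaneous doubling yields a plant whose
chromosome sets are all copies of the wild-type parent's gametic
genome: no heterozygosity anywhere, uniparental marker alleles, and —
after two doubling rounds — four identical chromosome sets. The
pipeline detects each signature independently (locus genotype, read
dosage, heterozygosity, marker lineage, DNA content) so that the
conclusions cross-check each other.

## Shared binning

All per-position counting uses one grid: 0-based half-open bins
`[start, start + 250000)` tiling each chromosome, last bin truncated.
A read is assigned by its mid coordinate `(pos − 1) + span/2` (each
mate counts as one read; a template-midpoint rule would double-weight
pairs), a SNP by its mapped position. Using a single grid object in
every module guarantees bin-boundary arithmetic can never drift
between the dosage and heterozygosity tracks.

## Dosage model

Retained reads are exactly those with FLAG ∈ {83, 99, 147, 163}, mate
on the same contig, and MAPQ equal to 60 (the aligner's unique-mapping
value; strict equality, not ≥). Percent depth divides each bin by the
sample's **whole-genome** retained total. A per-chromosome denominator
is also implemented (`per_chromosome_denominator=True`) for audit, but
it normalizes away exactly the whole-chromosome signal the method
exists to detect, so it is not the default.

Normalization divides by the mean percent depth of ≥ 2 euploid
controls and multiplies by 2. Bins where the control mean is zero are
masked (NaN), not dropped, so bin indices stay aligned across samples.
Consequences worth knowing:

- **The measure is relative.** A whole-genome duplication rescales
  every bin identically; a simulated tetraploid profiles at median 2,
  indistinguishable from a diploid. Absolute DNA content comes from
  flow cytometry.
- **A lost chromosome biases the rest upward.** With 9 chromosomes,
  a monosomic chromosome leaves 17 of 18 chromosome copies in the
  denominator, so its expected normalized value is 18/17 ≈ 1.059 and
  every disomic chromosome sits at 36/17 ≈ 2.118. Tests therefore
  compare against these analytic expectations, not against exactly
  1 and 2.

Copy-state calling uses the median of a chromosome's bins with bands
<1.5 → monosomic, [1.5, 2.5) → disomic, [2.5, 3.5) → trisomic, else
"other" (all configurable; the original analysis called states by
visual inspection, so fixed bands are an artifact decision that makes
the procedure testable). Segmental anomalies are maximal runs of ≥ 8
consecutive bins deviating from the chromosome's nominal value by
> 0.4, after closing isolated single-bin gaps. The gap closing is
deliberate: at desk-scale depths a single Poisson-noisy bin would
split a true 8-bin run into two sub-threshold runs and segment
recovery would be a coin flip; repairing one-bin interruptions (never
longer gaps) restores deterministic behaviour without changing the
run-length or deviation thresholds.

## Heterozygosity model

The variant filter retains records with QUAL > 140, DP ≤ 50, SCBZ ≤ 0
and a heterozygous genotype. Two reading notes: the quality clause
filters site QUAL (the executable filter expression is authoritative
over looser prose describing it as mapping quality), and records
lacking SCBZ — many callers do not emit it — pass that clause with a
warning tally by default (`strict_scbz=True` drops them instead), so
the scanner runs on third-party VCFs. Multi-allelic records are used
only through the GT field's het/hom status; allele identities never
enter the count.

A chromosome is "reduced" when its median per-bin het count is below
10% of the pooled controls' median for that chromosome. The 10%
default is chosen so that an outbred control never trips it under
Poisson fluctuation at the simulated SNP densities (control medians
are ~40–50 het SNPs per bin; 10% of that is ~12 standard deviations
below). Genome-wide reduction requires **every** chromosome to be
reduced; a chromosome whose control median is zero is uninformative,
stays "normal", and therefore blocks the genome-wide verdict — a
conservative choice: with uninformative controls the data cannot
support the claim.

## Lineage rules

Marker input is a genotype table (allele labels), not chromatograms:
the decision procedure, not trace deconvolution, is the method. A
uniparental verdict demands unanimity over informative loci; a single
heterozygous locus makes the verdict biparental, and a single
inconsistent call (allele matching neither parent) withholds any
verdict. Genotyping is presence-based, so four identical copies are
indistinguishable from two — matching the underlying assay. Organellar
maternity is an exact haplotype match, decoupled from the nuclear
karyotype.

## Flow-cytometry model

Events below 10% of the global histogram mode are gated out as debris
(the gating procedure was open; this minimal rule is declared and
configurable). Peaks are modes of a 64-bin log-spaced histogram
(intensities span decades) smoothed with a 3-bin moving average;
candidate modes shorter than 10% of the tallest are rejected as
histogram noise, and accepted modes must be separated by more than the
±20% peak window, otherwise the result is flagged `merged`. Each
peak's median is computed over raw events within ±20% of the mode, so
the statistic does not depend on bin placement. G2/S-phase nuclei are
not modelled by default. The mixed-preparation mode assumes the sample
peak is the upper of the two — correct for the
tetraploid-versus-diploid use case; a sub-diploid sample in a mixture
would need the separate mode.

## Simulator: what it emulates, and what it does not

Defaults (all in `SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| genome | 9 chromosomes × 5 Mb | 20 bins of 250 kb each; only bin counts matter for relative dosage, so realistic chromosome lengths add runtime, not information |
| `depth_per_copy` | 30 pairs/bin/copy | per-bin read pairs ~ Poisson(copy × depth); Poisson is the minimal read-sampling noise model |
| `read_length` | 150 bp | paired, template 300 bp, both mate mids kept inside the pair's bin |
| `variant_density_per_kb` | 0.2 | ~9,000 SNP sites genome-wide; parents homozygous, each site's alternate allele carried by exactly one parent |
| `genotyping_error` | 0 | per-site probability of a hom↔het miscall |
| `filter_fail_fraction` | 0.05 | per-clause probability of planting a failing QUAL/DP/SCBZ value |
| `fluorescence_cv` | 0.05 | multiplicative log-normal noise on PACE and flow intensities |
| `nuclei_per_sample` | 5,000 | flow events per sample |

One master seed; each output stream (sites, per-offspring SAM, VCF,
PACE, flow) derives an independent child generator from it, so outputs
are byte-identical under a fixed config.

Modelling choices and their limits:

- **Inbred-homozygous parents.** Every SNP site is homozygous within
  each parent and divergent between them. This makes offspring
  genotypes deterministic in the parental origin of each chromosome
  copy (an F1 is het at every site, an eliminated offspring at none)
  and is what the lineage and het analyses exploit. Real outbred
  parents are themselves heterozygous, which dilutes but does not
  remove these signatures; passing tests therefore demonstrate
  correctness of the decision procedures, not their power on weakly
  divergent crosses.
- **Decoy reads are planted per failure category** (improper flag,
  MAPQ 30, mate on another contig), not produced by simulating a
  mis-mapping aligner: the filters, not the aligner, are under test.
- **SCBZ is synthetic**: a negative half-normal for clean sites,
  positive for planted failures; it is only ever a filter field.
- **No read sequences, base errors, indels or structural variants**
  beyond whole-chromosome/segment copy-number changes; SEQ/QUAL are
  `*`. Segment-level copy overrides affect coverage only, not
  genotypes (adequate for dosage tests; a real duplication would also
  shift allele balance).
- **Flow distributions are unimodal log-normal** scaling linearly
  with ploidy; no debris tail or G2 peak by default.

## Problem sizes in tests and the acceptance script

The default suite simulates the toy genome at 30 read pairs per
bin-copy (≈ 10,000 pairs per diploid sample). Seeded-recovery suites
use 20 runs each: karyotype recovery at 60 pairs/bin-copy (so that a
9-bin trisomic segment clears the deviation threshold with ~2 sigma
margin per bin), and monosomy-7 recovery at 150 pairs/bin-copy, at
which the Monte-Carlo standard error of a 20-bin chromosome mean is
≈ 0.017 copy units and the analytic expectation 18/17 can be asserted
within ± 4 sigma. The acceptance script uses the same 150
pairs/bin-copy dosage run — still ~500-fold below the per-bin depth of
a real whole-genome sequencing screen, whose estimates are
correspondingly tighter.

## Known limitations

- Thresholded state calling has no confidence measure; borderline
  medians (e.g. a 50% mosaic) fall into whichever band they land in.
- The segment caller reports runs, not breakpoints; it is not a
  substitute for change-point segmentation when breakpoint resolution
  matters.
- Self-pollination rates exclude no-calls from the denominator; when
  unclassifiable samples were handled differently upstream, printed
  rates from other sources may differ in the last decimal.
- GC-content and mappability correction are out of scope; on real
  data, systematic coverage bias shared by sample and controls cancels
  in the ratio, but sample-specific bias does not.
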