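"""Parent-of-origin assignment from diagnostic marker loci.

A progeny produced by uniparental genome elimination carries, at every
informative nuclear marker (two per chromosome, eighteen in all for a
nine-chromosome genome), only the alleles of one parent.  This module
scores each marker locus, combines the per-locus calls into a lineage
verdict, and identifies the maternal parent from an organellar
(mitochondrial) polymorphism, which is inherited uniparentally from the
mother regardless of what happened to the nuclear genome.

Marker input is allele labels (a genotype table), not raw chromatograms:
the decision procedure operates downstream of trace interpretation.
Genotyping here is presence-based, so a tetraploid with four identical
copies is indistinguishable from a diploid homozygote — which is exactly
the assay's behaviour.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .errors import KaryoscreenError, NoInformativeMarkersError

ORIGIN_CALLS = ("a_only", "b_only", "both", "inconsistent", "uninformative")


@dataclass(frozen=True)
class MarkerLocus:
    """One diagnostic locus: homozygous parental alleles plus the progeny genotype.

    ``progeny_alleles`` is the unordered set of alleles observed in the
    progeny (one element for an apparent homozygote, two for a
    heterozygote).
    """

    locus_id: str
    chrom: str
    parent_a_allele: str
    parent_b_allele: str
    progeny_alleles: frozenset[str]

    def informative(self) -> bool:
        return self.parent_a_allele != self.parent_b_allele


@dataclass(frozen=True)
class LineageVerdict:
    """Combined verdict over all marker loci, with supporting counts."""

    verdict: str  # uniparental_a | uniparental_b | biparental | mixed
    counts: dict[str, int]

    def to_json(self, path=None) -> str:
        payload = json.dumps({"verdict": self.verdict, "counts": self.counts}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def call_marker_origin(locus: MarkerLocus) -> str:
    """Assign one locus to a parental origin category.

    Homozygous for parent A's allele -> ``a_only`` (symmetric for B);
    both parental alleles present -> ``both``; any allele matching
    neither parent -> ``inconsistent``; identical parental alleles ->
    ``uninformative``.
    """
    if not locus.progeny_alleles:
        raise ValueError(f"locus {locus.locus_id!r} has no progeny alleles")
    if not locus.informative():
        return "uninformative"
    parental = {locus.parent_a_allele, locus.parent_b_allele}
    if locus.progeny_alleles - parental:
        return "inconsistent"
    has_a = locus.parent_a_allele in locus.progeny_alleles
    has_b = locus.parent_b_allele in locus.progeny_alleles
    if has_a and has_b:
        return "both"
    return "a_only" if has_a else "b_only"


def infer_nuclear_lineage(calls: list[str]) -> LineageVerdict:
    """Combine per-locus origin calls into a lineage verdict.

    A uniparental verdict demands unanimity: every informative locus
    must carry only the one parent's allele.  A single heterozygous
    locus makes the genome biparental; a single inconsistent call, or
    conflicting uniparental calls, withholds any verdict (``mixed``).
    """
    unknown = set(calls) - set(ORIGIN_CALLS)
    if unknown:
        raise ValueError(f"unknown origin calls: {sorted(unknown)}")
    counts = dict(Counter(calls))
    informative = [c for c in calls if c != "uninformative"]
    if not informative:
        raise NoInformativeMarkersError("no informative markers")
    if "inconsistent" in informative:
        verdict = "mixed"
    elif "both" in informative:
        verdict = "biparental"
    elif all(c == "a_only" for c in informative):
        verdict = "uniparental_a"
    elif all(c == "b_only" for c in informative):
        verdict = "uniparental_b"
    else:
        verdict = "mixed"
    for key in ORIGIN_CALLS:
        counts.setdefault(key, 0)
    return LineageVerdict(verdict, counts)


def infer_maternal_parent(progeny_haplotype: str, parent_haplotypes: dict[str, str]) -> str:
    """Identify the maternal parent from an organellar haplotype match.

    Organellar genomes are inherited uniparentally from the mother, so
    the parent whose haplotype exactly matches the progeny is maternal.
    """
    if len(parent_haplotypes) != 2:
        raise KaryoscreenError("exactly two parental haplotypes required")
    (id_a, hap_a), (id_b, hap_b) = parent_haplotypes.items()
    if hap_a == hap_b:
        raise KaryoscreenError("uninformative organellar marker: parental haplotypes identical")
    if progeny_haplotype == hap_a:
        return id_a
    if progeny_haplotype == hap_b:
        return id_b
    raise KaryoscreenError("maternity indeterminate: progeny matches neither parent")


def read_marker_csv(path) -> list[MarkerLocus]:
    """Read `locus_id,chrom,parentA_gt,parentB_gt,progeny_gt` rows.

    Genotypes are allele strings, with heterozygotes written as
    `X/Y`; parents are expected homozygous (a single allele or `X/X`).
    """
    df = pd.read_csv(path)
    loci = []
    for r in df.itertuples():
        pa = _single_allele(str(r.parentA_gt), "parentA", r.locus_id)
        pb = _single_allele(str(r.parentB_gt), "parentB", r.locus_id)
        prog = frozenset(str(r.progeny_gt).split("/"))
        loci.append(MarkerLocus(str(r.locus_id), str(r.chrom), pa, pb, prog))
    return loci


def _single_allele(gt: str, which: str, locus_id) -> str:
    alleles = set(gt.split("/"))
    if len(alleles) != 1:
        raise KaryoscreenError(
            f"{which} is not homozygous at locus {locus_id!r}: {gt!r}"
        )
    return alleles.pop()
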