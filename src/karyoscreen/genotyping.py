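"""Progeny classification at the edited CENH3 locus and cross summaries.

Seedlings from a cenh3-mutant x wild-type cross are classified from an
endpoint-fluorescence (PACE/KASP-style) assay or from a Sanger genotype
of the target window into one of: ``self`` (self-pollination of the
mutant parent), ``f1`` (true outcross), ``candidate`` (genome-elimination
candidate: only the wild-type allele detected), or ``no_call``.

The PACE rule works on the allele fraction r = FAM / (FAM + HEX), where
the FAM primer reads the wild-type allele and the HEX primer the edited
allele: r near 1 is a candidate, r near 0 a self-pollination, r near 1/2
an F1.  Thresholds are explicit, with no-call gaps between the bands so
that mis-set thresholds surface as no-calls instead of silent misclassification.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .errors import ConfigError, KaryoscreenError

PROGENY_CLASSES = ("self", "f1", "candidate", "no_call")

SANGER_GENOTYPES = ("hom_edited", "het", "hom_wildtype", "ambiguous")

#: Sanger genotype -> progeny class. A homozygous wild-type sequence in
#: progeny of a cenh3/cenh3 mother is the genome-elimination signature.
_SANGER_MAP = {
    "hom_edited": "self",
    "het": "f1",
    "hom_wildtype": "candidate",
    "ambiguous": "no_call",
}


@dataclass(frozen=True)
class PaceSignal:
    """Endpoint fluorescence of one seedling (arbitrary units, >= 0)."""

    seedling_id: str
    fam: float
    hex: float

    def __post_init__(self) -> None:
        if self.fam < 0 or self.hex < 0:
            raise ValueError("fluorescence intensities must be non-negative")


@dataclass(frozen=True)
class PaceThresholds:
    """Allele-fraction cutoffs for the three genotype clusters.

    r <= t_low -> self; r >= t_high -> candidate; f1_low <= r <= f1_high
    -> f1; anything between the bands -> no_call.
    """

    t_low: float = 0.15
    t_high: float = 0.85
    f1_low: float = 0.30
    f1_high: float = 0.70

    def __post_init__(self) -> None:
        if not (0 < self.t_low < 0.5 < self.t_high < 1):
            raise ConfigError("need 0 < t_low < 0.5 < t_high < 1")
        if not (self.t_low <= self.f1_low < 0.5 < self.f1_high <= self.t_high):
            raise ConfigError("F1 band must sit between t_low and t_high around 0.5")


@dataclass(frozen=True)
class Classification:
    """A progeny class plus bookkeeping flags."""

    seedling_id: str
    label: str
    signal_absent: bool = False


@dataclass(frozen=True)
class CrossSummary:
    """Per-cross screening totals in the layout of the study's cross table."""

    cross_id: str
    total_surveyed: int
    f1_count: int
    candidate_count: int
    self_count: int
    no_call_count: int
    self_pollination_rate: float
    germination_rate: float | None = None


def _round_half_up(value: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(value)).quantize(Decimal(f"1e-{ndigits}"), rounding=ROUND_HALF_UP))


def classify_pace(signal: PaceSignal, thresholds: PaceThresholds | None = None) -> Classification:
    """Classify one seedling from its FAM/HEX endpoint fluorescence.

    A dead reaction (both channels zero) yields ``no_call`` with the
    ``signal_absent`` flag set rather than an exception.
    """
    t = thresholds or PaceThresholds()
    total = signal.fam + signal.hex
    if total == 0:
        return Classification(signal.seedling_id, "no_call", signal_absent=True)
    r = signal.fam / total
    if r >= t.t_high:
        label = "candidate"
    elif r <= t.t_low:
        label = "self"
    elif t.f1_low <= r <= t.f1_high:
        label = "f1"
    else:
        label = "no_call"
    return Classification(signal.seedling_id, label)


def classify_sanger(seedling_id: str, genotype: str) -> Classification:
    """Map a Sanger genotype of the edited window onto a progeny class."""
    if genotype not in _SANGER_MAP:
        raise ValueError(f"unknown Sanger genotype {genotype!r}")
    return Classification(seedling_id, _SANGER_MAP[genotype])


def summarize_cross(
    classes: list[Classification | str],
    cross_id: str,
    seeds_planted: int | None = None,
    seeds_germinated: int | None = None,
) -> CrossSummary:
    """Tally one cross's progeny classes and compute its rates.

    The self-pollination rate is ``100 x self / (surveyed - no_calls)``,
    rounded half-up to one decimal; no-calls are excluded from the
    denominator because they carry no information about the pollen
    source.  The germination rate is computed only when seed counts are
    supplied.
    """
    if not classes:
        raise KaryoscreenError(f"no progeny supplied for cross {cross_id!r}")
    labels = [c if isinstance(c, str) else c.label for c in classes]
    bad = set(labels) - set(PROGENY_CLASSES)
    if bad:
        raise ValueError(f"unknown progeny class labels: {sorted(bad)}")
    counts = Counter(labels)
    total = len(labels)
    callable_n = total - counts["no_call"]
    rate = _round_half_up(100.0 * counts["self"] / callable_n) if callable_n else 0.0
    germ = None
    if seeds_planted is not None and seeds_germinated is not None:
        if seeds_planted <= 0:
            raise ValueError("seeds_planted must be positive")
        germ = _round_half_up(100.0 * seeds_germinated / seeds_planted)
    return CrossSummary(
        cross_id=cross_id,
        total_surveyed=total,
        f1_count=counts["f1"],
        candidate_count=counts["candidate"],
        self_count=counts["self"],
        no_call_count=counts["no_call"],
        self_pollination_rate=rate,
        germination_rate=germ,
    )


def aggregate_screen(summaries: list[CrossSummary]) -> dict[str, int]:
    """Whole-screen totals over all crosses.

    Returns total progeny surveyed, total F1s and total candidates;
    duplicate cross identifiers are rejected, as each cross must be
    counted once.
    """
    if not summaries:
        raise KaryoscreenError("no cross summaries supplied")
    ids = [s.cross_id for s in summaries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate cross ids: {dupes}")
    return {
        "total_surveyed": sum(s.total_surveyed for s in summaries),
        "total_f1": sum(s.f1_count for s in summaries),
        "total_candidates": sum(s.candidate_count for s in summaries),
        "total_self": sum(s.self_count for s in summaries),
        "total_no_call": sum(s.no_call_count for s in summaries),
    }


def read_pace_csv(path) -> list[PaceSignal]:
    """Read a `seedling_id,fam,hex` CSV into PaceSignal records."""
    df = pd.read_csv(path)
    return [PaceSignal(str(r.seedling_id), float(r.fam), float(r.hex)) for r in df.itertuples()]


def read_sanger_csv(path) -> list[tuple[str, str]]:
    """Read a `seedling_id,genotype` CSV."""
    df = pd.read_csv(path)
    return [(str(r.seedling_id), str(r.genotype)) for r in df.itertuples()]


def summary_frame(summaries: list[CrossSummary]) -> pd.DataFrame:
    """CrossSummary list -> a tidy frame mirroring the screening table."""
    return pd.DataFrame(
        {
            "cross_id": [s.cross_id for s in summaries],
            "total_surveyed": [s.total_surveyed for s in summaries],
            "f1": [s.f1_count for s in summaries],
            "candidates": [s.candidate_count for s in summaries],
            "self": [s.self_count for s in summaries],
            "no_call": [s.no_call_count for s in summaries],
            "self_pollination_rate": [s.self_pollination_rate for s in summaries],
            "germination_rate": [s.germination_rate for s in summaries],
        }
    )
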