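"""Relative chromosome copy number from binned read depth.

The estimator follows the standard binned-coverage recipe for detecting
aneuploidy from whole-genome sequencing of an individual against a panel
of euploid controls:

1. keep only uniquely mapped, properly paired reads whose mate is on the
   same contig (FLAG in {83, 99, 147, 163}, RNEXT '=', MAPQ = 60);
2. count retained reads in 250 kb bins by read mid position;
3. divide each bin by the sample's total retained reads (percent depth);
4. divide by the mean percent depth of >= 2 wild-type controls in the
   same bin and multiply by two, so a euploid bin sits at 2.0.

The result is *relative* dosage: a whole-genome duplication rescales
every bin identically and is invisible here by construction (flow
cytometry covers absolute DNA content).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from .errors import GridMismatchError, KaryoscreenError
from .layout import BinGrid

RETAINED_FLAGS = frozenset({83, 99, 147, 163})
UNIQUE_MAPQ = 60


@dataclass(frozen=True)
class AlignedReadPair:
    """The alignment fields the dosage filters need, for one record."""

    chrom: str
    flag: int
    mapq: int
    mate_same_contig: bool
    pos: int  # 1-based leftmost
    span: int  # aligned reference span in bp

    @property
    def mid(self) -> int:
        """0-based mid-position coordinate used for bin assignment."""
        return (self.pos - 1) + self.span // 2


@dataclass
class ReadFilterStats:
    """Tally of retained and discarded records, by first failing clause."""

    retained: int = 0
    improper_flag: int = 0
    bad_mate_contig: int = 0
    non_unique_mapq: int = 0
    malformed: int = 0

    @property
    def discarded(self) -> int:
        return self.improper_flag + self.bad_mate_contig + self.non_unique_mapq


def read_alignments(path, stats: ReadFilterStats | None = None) -> Iterator[AlignedReadPair]:
    """Stream mapped records of a SAM/BAM file as AlignedReadPair.

    Records that cannot be interpreted are counted as malformed and
    skipped rather than aborting the file.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            try:
                if rec.is_unmapped or rec.reference_name is None:
                    # unmapped lines can never pass the proper-pair filter
                    yield AlignedReadPair("*", rec.flag, rec.mapping_quality, False, 1, 0)
                    continue
                span = rec.reference_length or 0
                same = rec.next_reference_id == rec.reference_id
                yield AlignedReadPair(
                    rec.reference_name, rec.flag, rec.mapping_quality, same, rec.reference_start + 1, span
                )
            except (ValueError, TypeError):
                if stats is not None:
                    stats.malformed += 1
                warnings.warn("skipping malformed alignment record", stacklevel=2)


def filter_reads(
    records: Iterable[AlignedReadPair], stats: ReadFilterStats | None = None
) -> Iterator[AlignedReadPair]:
    """Retain properly paired, same-contig, uniquely mapped records.

    Order is preserved; discards are tallied by the first failing clause.
    """
    stats = stats if stats is not None else ReadFilterStats()
    for rec in records:
        if rec.flag not in RETAINED_FLAGS:
            stats.improper_flag += 1
            continue
        if not rec.mate_same_contig:
            stats.bad_mate_contig += 1
            continue
        if rec.mapq != UNIQUE_MAPQ:
            stats.non_unique_mapq += 1
            continue
        stats.retained += 1
        yield rec


def bin_reads(records: Iterable[AlignedReadPair], grid: BinGrid) -> dict[str, np.ndarray]:
    """Count records per bin by mid position; totals are conserved.

    Raises KeyError naming the contig if a record maps to a chromosome
    absent from the grid.
    """
    counts = grid.zero_counts()
    for rec in records:
        if rec.chrom not in counts:
            raise KeyError(f"contig {rec.chrom!r} not present in the bin grid")
        counts[rec.chrom][grid.bin_index(rec.chrom, rec.mid)] += 1
    return counts


@dataclass
class DosageProfile:
    """Per-bin raw counts, percent depth and normalized dosage for one sample."""

    sample_id: str
    frame: pd.DataFrame  # chrom, bin_start, bin_end, raw, percent, normalized

    def chromosome_values(self, chrom: str) -> np.ndarray:
        return self.frame.loc[self.frame["chrom"] == chrom, "normalized"].to_numpy()

    def genome_median(self) -> float:
        return float(np.nanmedian(self.frame["normalized"].to_numpy()))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _percent_depth(counts: dict[str, np.ndarray], grid: BinGrid, per_chromosome: bool) -> dict[str, np.ndarray]:
    if per_chromosome:
        return {
            c: counts[c] / counts[c].sum() if counts[c].sum() > 0 else np.zeros_like(counts[c], dtype=float)
            for c in grid.chromosomes
        }
    total = sum(int(counts[c].sum()) for c in grid.chromosomes)
    if total == 0:
        raise KaryoscreenError("sample has zero retained reads")
    return {c: counts[c] / total for c in grid.chromosomes}


def normalize_dosage(
    sample_counts: dict[str, np.ndarray],
    control_counts: list[dict[str, np.ndarray]],
    grid: BinGrid,
    sample_id: str = "sample",
    per_chromosome_denominator: bool = False,
) -> DosageProfile:
    """Percent-depth normalize a sample against euploid controls.

    ``normalized = 2 x sample_percent / mean(control_percents)`` per bin;
    bins where the control mean is zero are masked (NaN), not divided, so
    bin indices stay aligned across samples.  At least two controls are
    required.  ``per_chromosome_denominator`` switches the percent-depth
    denominator from the whole sample to each chromosome (an audit
    option; it erases whole-chromosome dosage signal).
    """
    if len(control_counts) < 2:
        raise KaryoscreenError(f"need >= 2 control profiles, got {len(control_counts)}")
    for cc in control_counts + [sample_counts]:
        if set(cc) != set(grid.chromosomes) or any(
            len(cc[c]) != grid.n_bins(c) for c in grid.chromosomes
        ):
            raise GridMismatchError("profile does not match the bin grid")
        if sum(int(cc[c].sum()) for c in grid.chromosomes) == 0:
            raise KaryoscreenError("a profile has zero total reads")

    sample_pct = _percent_depth(sample_counts, grid, per_chromosome_denominator)
    ctrl_pcts = [_percent_depth(cc, grid, per_chromosome_denominator) for cc in control_counts]

    rows = []
    for chrom in grid.chromosomes:
        ctrl_mean = np.mean([cp[chrom] for cp in ctrl_pcts], axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            norm = 2.0 * sample_pct[chrom] / ctrl_mean
        norm[ctrl_mean == 0] = np.nan
        for b in range(grid.n_bins(chrom)):
            start, end = grid.bin_bounds(chrom, b)
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": start,
                    "bin_end": end,
                    "raw": int(sample_counts[chrom][b]),
                    "percent": sample_pct[chrom][b],
                    "normalized": norm[b],
                }
            )
    return DosageProfile(sample_id, pd.DataFrame(rows))


@dataclass(frozen=True)
class DosageThresholds:
    """Cutoffs for turning normalized bin values into copy-state calls.

    Chromosome state comes from the median of its bins: below
    ``monosomic_below`` -> monosomic, then disomic / trisomic bands, else
    "other".  Segmental anomalies are maximal runs of at least
    ``min_run_bins`` consecutive bins deviating from the chromosome's
    nominal value by more than ``segment_deviation``.
    """

    monosomic_below: float = 1.5
    disomic_below: float = 2.5
    trisomic_below: float = 3.5
    min_run_bins: int = 8
    segment_deviation: float = 0.4


_STATE_NOMINAL = {"monosomic": 1.0, "disomic": 2.0, "trisomic": 3.0}


@dataclass
class DosageCall:
    """Per-chromosome copy states plus any segmental anomalies."""

    sample_id: str
    states: dict[str, str]
    segments: list[dict] = field(default_factory=list)
    uninformative: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "sample_id": self.sample_id,
                "states": self.states,
                "segments": self.segments,
                "uninformative_chromosomes": self.uninformative,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def _classify_state(median: float, t: DosageThresholds) -> str:
    if median < t.monosomic_below:
        return "monosomic"
    if median < t.disomic_below:
        return "disomic"
    if median < t.trisomic_below:
        return "trisomic"
    return "other"


def call_dosage(profile: DosageProfile, thresholds: DosageThresholds | None = None) -> DosageCall:
    """Call a copy state per chromosome and flag deviating segments."""
    t = thresholds or DosageThresholds()
    states: dict[str, str] = {}
    segments: list[dict] = []
    uninformative: list[str] = []
    for chrom in profile.frame["chrom"].unique():
        values = profile.chromosome_values(chrom)
        if np.all(np.isnan(values)):
            states[chrom] = "other"
            uninformative.append(chrom)
            continue
        median = float(np.nanmedian(values))
        state = _classify_state(median, t)
        states[chrom] = state
        nominal = _STATE_NOMINAL.get(state, median)
        deviating = np.abs(values - nominal) > t.segment_deviation
        deviating &= ~np.isnan(values)
        # close isolated single-bin gaps so one noisy bin cannot split a
        # true segment into two sub-threshold runs
        for i in range(1, len(deviating) - 1):
            if not deviating[i] and deviating[i - 1] and deviating[i + 1]:
                deviating[i] = True
        # maximal runs of deviating bins
        run_start = None
        for i, flag in enumerate(list(deviating) + [False]):
            if flag and run_start is None:
                run_start = i
            elif not flag and run_start is not None:
                if i - run_start >= t.min_run_bins:
                    segments.append(
                        {
                            "chrom": str(chrom),
                            "start_bin": run_start,
                            "end_bin": i,
                            "mean_normalized": float(np.nanmean(values[run_start:i])),
                        }
                    )
                run_start = None
    return DosageCall(profile.sample_id, states, segments, uninformative)


def dosage_pipeline(
    sample_path,
    control_paths: list,
    grid: BinGrid,
    sample_id: str = "sample",
    thresholds: DosageThresholds | None = None,
) -> tuple[DosageProfile, DosageCall, ReadFilterStats]:
    """Full dosage workflow on SAM files: filter, bin, normalize, call."""
    stats = ReadFilterStats()
    sample_counts = bin_reads(filter_reads(read_alignments(sample_path, stats), stats), grid)
    control_counts = [
        bin_reads(filter_reads(read_alignments(p)), grid) for p in control_paths
    ]
    profile = normalize_dosage(sample_counts, control_counts, grid, sample_id=sample_id)
    return profile, call_dosage(profile, thresholds), stats
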