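"""Genome layout and the shared binning grid.

Every stage of the pipeline (read-depth dosage, heterozygosity scanning,
the simulator) counts events in fixed-width genomic bins.  The grid is
defined once here so that bin boundary arithmetic is identical everywhere:
bins are 0-based half-open intervals ``[start, start + bin_size)`` tiling
each chromosome, with the final bin truncated at the chromosome end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_BIN_SIZE = 250_000

#: Toy genome used throughout the test-bed: nine chromosomes of 5 Mb each,
#: i.e. 20 bins per chromosome at the default 250 kb bin size.  Carrot has
#: nine chromosomes; the real lengths are irrelevant to any relative-dosage
#: quantity, only the bin count per chromosome matters.
DEFAULT_CHROM_LENGTH = 5_000_000
N_CHROMOSOMES = 9


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names, their lengths, and the bin width.

    Parameters
    ----------
    names
        Ordered chromosome identifiers.
    lengths
        Mapping from chromosome name to length in base pairs.
    bin_size
        Width of the analysis bins in base pairs (default 250 kb).
    """

    names: tuple[str, ...]
    lengths: dict[str, int] = field(hash=False)
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if set(self.names) != set(self.lengths):
            raise ValueError("names and lengths must cover the same chromosomes")
        for name in self.names:
            if self.lengths[name] < 2 * self.bin_size:
                raise ValueError(
                    f"chromosome {name!r} shorter than two bins "
                    f"({self.lengths[name]} < {2 * self.bin_size})"
                )

    @classmethod
    def default(cls, bin_size: int = DEFAULT_BIN_SIZE) -> "GenomeLayout":
        names = tuple(f"chr{i}" for i in range(1, N_CHROMOSOMES + 1))
        return cls(names, {n: DEFAULT_CHROM_LENGTH for n in names}, bin_size)

    def n_bins(self, chrom: str) -> int:
        return -(-self.lengths[chrom] // self.bin_size)  # ceil division


@dataclass(frozen=True)
class BinGrid:
    """Per-chromosome half-open bins of width ``layout.bin_size``.

    A genomic coordinate is assigned to a bin by integer division of its
    0-based position by the bin width; a 1-based position ``p`` therefore
    lands in bin ``(p - 1) // bin_size``.
    """

    layout: GenomeLayout

    @property
    def bin_size(self) -> int:
        return self.layout.bin_size

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return self.layout.names

    def n_bins(self, chrom: str) -> int:
        return self.layout.n_bins(chrom)

    def bin_index(self, chrom: str, pos0: int) -> int:
        """Bin index of a 0-based coordinate; raises on unknown contig."""
        if chrom not in self.layout.lengths:
            raise KeyError(f"contig {chrom!r} not present in the bin grid")
        return pos0 // self.bin_size

    def bin_bounds(self, chrom: str, index: int) -> tuple[int, int]:
        """(start, end) of a bin, 0-based half-open, end clipped to length."""
        start = index * self.bin_size
        end = min(start + self.bin_size, self.layout.lengths[chrom])
        return start, end

    def zero_counts(self) -> dict[str, np.ndarray]:
        return {c: np.zeros(self.n_bins(c), dtype=np.int64) for c in self.chromosomes}

    def same_grid(self, other: "BinGrid") -> bool:
        return (
            self.layout.names == other.layout.names
            and self.layout.lengths == other.layout.lengths
            and self.layout.bin_size == other.layout.bin_size
        )
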