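"""Relative ploidy from flow-cytometry fluorescence distributions.

Propidium-iodide fluorescence of a nucleus is proportional to its DNA
content, so the ratio of a sample's G1-peak median to that of a diploid
reference estimates relative ploidy.  Two preparation modes are
supported, mirroring common practice: *separate* (sample and reference
stained in separate preps, one peak each) and *mixed* (tissues pooled
before nuclei isolation, giving one histogram with up to two peaks — the
lower peak is the diploid reference).

Peaks are located on a smoothed log-spaced histogram; each peak's median
is then computed over the raw events within +/-20% of the mode, which
makes the statistic insensitive to histogram binning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import KaryoscreenError

MIN_EVENTS = 200
DEBRIS_GATE_FRACTION = 0.10
PEAK_WINDOW_FRACTION = 0.20
DEFAULT_HIST_BINS = 64
SMOOTHING_WINDOW = 3
#: candidate modes shorter than this fraction of the tallest mode are
#: treated as histogram noise, not nuclei populations
MIN_PEAK_HEIGHT_FRACTION = 0.10


@dataclass(frozen=True)
class FlowSample:
    """Per-nucleus fluorescence values for one preparation."""

    sample_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if np.any(values <= 0):
            raise ValueError("fluorescence values must be positive")


@dataclass(frozen=True)
class PeakEstimate:
    """One fluorescence peak: its median, event count and bounds."""

    median: float
    count: int
    low: float
    high: float
    merged: bool = False


def gate_debris(values: np.ndarray, fraction: float = DEBRIS_GATE_FRACTION) -> np.ndarray:
    """Drop low-fluorescence debris: events below ``fraction`` of the global mode."""
    hist, edges = _log_histogram(values, DEFAULT_HIST_BINS)
    mode = _bin_centers(edges)[int(np.argmax(hist))]
    return values[values >= fraction * mode]


def _log_histogram(values: np.ndarray, bins: int) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = values.min(), values.max()
    if lo == hi:  # degenerate noise-free sample: one point mass
        lo, hi = lo * 0.99, hi * 1.01
    edges = np.geomspace(lo, hi, bins + 1)
    hist, _ = np.histogram(values, bins=edges)
    return hist, edges


def _bin_centers(edges: np.ndarray) -> np.ndarray:
    return np.sqrt(edges[:-1] * edges[1:])  # geometric centers for log bins


def find_peaks(
    sample: FlowSample,
    expected: int = 1,
    hist_bins: int = DEFAULT_HIST_BINS,
) -> list[PeakEstimate]:
    """Locate the requested number of fluorescence modes (1 or 2).

    The histogram uses ``hist_bins`` log-spaced bins smoothed with a
    moving average of window 3; local maxima are ranked by height and
    greedily accepted when separated from already-accepted modes by more
    than the peak window.  If fewer separable modes than requested are
    found, the found peaks are returned flagged ``merged``.  Each peak's
    median and bounds come from the raw events within +/-20% of its mode.
    """
    if expected not in (1, 2):
        raise KaryoscreenError("expected peak count must be 1 or 2")
    values = gate_debris(sample.values)
    if values.size == 0:
        raise KaryoscreenError(f"no events left after gating in sample {sample.sample_id!r}")
    if values.size < MIN_EVENTS:
        raise KaryoscreenError(
            f"sample {sample.sample_id!r} has {values.size} gated events (< {MIN_EVENTS})"
        )
    hist, edges = _log_histogram(values, hist_bins)
    kernel = np.ones(SMOOTHING_WINDOW) / SMOOTHING_WINDOW
    smooth = np.convolve(hist, kernel, mode="same")
    centers = _bin_centers(edges)

    # local maxima (plateau-tolerant at the strict side)
    floor = MIN_PEAK_HEIGHT_FRACTION * smooth.max()
    candidates = [
        i
        for i in range(len(smooth))
        if smooth[i] >= floor
        and (i == 0 or smooth[i] >= smooth[i - 1])
        and (i == len(smooth) - 1 or smooth[i] > smooth[i + 1])
    ]
    candidates.sort(key=lambda i: smooth[i], reverse=True)
    modes: list[float] = []
    for i in candidates:
        pos = centers[i]
        if all(
            abs(pos - m) > PEAK_WINDOW_FRACTION * max(pos, m) for m in modes
        ):
            modes.append(pos)
        if len(modes) == expected:
            break
    merged = len(modes) < expected

    peaks = []
    for mode in sorted(modes):
        lo, hi = (1 - PEAK_WINDOW_FRACTION) * mode, (1 + PEAK_WINDOW_FRACTION) * mode
        window = values[(values >= lo) & (values <= hi)]
        peaks.append(
            PeakEstimate(
                median=float(np.median(window)),
                count=int(window.size),
                low=float(lo),
                high=float(hi),
                merged=merged,
            )
        )
    return peaks


@dataclass(frozen=True)
class PloidyCall:
    """Relative DNA content of a sample against a diploid reference."""

    sample_id: str
    ratio: float
    nominal_ploidy: int
    mode: str  # separate | mixed

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "sample_id": self.sample_id,
                "ratio": self.ratio,
                "nominal_ploidy": self.nominal_ploidy,
                "mode": self.mode,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def estimate_ploidy(
    sample_peaks: list[PeakEstimate],
    reference_peaks: list[PeakEstimate],
    reference_ploidy: int = 2,
    mode: str = "separate",
    sample_id: str = "sample",
) -> PloidyCall:
    """Ploidy from the ratio of sample to reference peak medians.

    ``nominal_ploidy = round(ratio x reference_ploidy)``.  In mixed mode
    the two inputs are the two peaks of one histogram, the reference
    being the lower.
    """
    if not sample_peaks or not reference_peaks:
        raise KaryoscreenError("missing peak estimate for sample or reference")
    ref = reference_peaks[0]
    if ref.median <= 0:
        raise KaryoscreenError("reference peak median must be positive")
    sample = sample_peaks[-1] if mode == "mixed" else sample_peaks[0]
    ratio = sample.median / ref.median
    nominal = max(1, round(ratio * reference_ploidy))
    return PloidyCall(sample_id, float(ratio), int(nominal), mode)


def ploidy_separate(sample: FlowSample, reference: FlowSample, reference_ploidy: int = 2) -> PloidyCall:
    """Separate-preparation workflow: one peak per sample."""
    sp = find_peaks(sample, expected=1)
    rp = find_peaks(reference, expected=1)
    return estimate_ploidy(sp, rp, reference_ploidy, mode="separate", sample_id=sample.sample_id)


def ploidy_mixed(mixture: FlowSample, reference_ploidy: int = 2) -> PloidyCall:
    """Mixed-preparation workflow: sample and reference nuclei in one tube.

    Two separable peaks -> the upper is the sample, the lower the
    reference.  A single (merged) peak means the sample's DNA content is
    indistinguishable from the reference, giving ratio 1.
    """
    peaks = find_peaks(mixture, expected=2)
    if len(peaks) == 1:
        return PloidyCall(mixture.sample_id, 1.0, reference_ploidy, "mixed")
    return estimate_ploidy(peaks, peaks[:1], reference_ploidy, mode="mixed", sample_id=mixture.sample_id)


def read_flow_csv(path) -> dict[str, FlowSample]:
    """Read a `sample_id,fluorescence` CSV (one event per row)."""
    df = pd.read_csv(path)
    return {
        str(sid): FlowSample(str(sid), grp["fluorescence"].to_numpy())
        for sid, grp in df.groupby("sample_id")
    }


def histogram_frame(sample: FlowSample, bins: int = DEFAULT_HIST_BINS) -> pd.DataFrame:
    """Gated log-binned histogram of a sample (plotting substrate)."""
    values = gate_debris(sample.values)
    hist, edges = _log_histogram(values, bins)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": hist}
    )
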