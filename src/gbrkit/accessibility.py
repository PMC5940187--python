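"""ATAC-seq characterization: open-chromatin overlap and summit-centered metaprofiles.

Accessibility status of a binding region is decided by overlap with called
open-chromatin peaks; the quantitative metaprofile averages library-normalized
coverage (reads per million per bin) in fixed-width bins across a window
centered on each region's summit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from gbrkit.intervals import Peak, PeakSet


@dataclass
class CoverageTrack:
    """Run-length encoded per-base read coverage, one (starts, ends, values)
    triple per chromosome, plus the library size used for RPM scaling."""

    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    total_reads: float

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        for chrom, (s, e, v) in self.runs.items():
            if not (len(s) == len(e) == len(v)):
                raise ValueError(f"{chrom}: run arrays differ in length")
            if (np.asarray(v) < 0).any():
                raise ValueError(f"{chrom}: coverage values must be nonnegative")

    def window_coverage(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base coverage over [start, end); bases beyond the track are zero."""
        out = np.zeros(end - start, dtype=float)
        if chrom not in self.runs or end <= start:
            return out
        starts, ends, values = self.runs[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return out
        a = np.clip(starts[lo:hi] - start, 0, end - start)
        b = np.clip(ends[lo:hi] - start, 0, end - start)
        keep = b > a
        delta = np.zeros(end - start + 1, dtype=float)
        np.add.at(delta, a[keep], values[lo:hi][keep])
        np.add.at(delta, b[keep], -values[lo:hi][keep])
        out += np.cumsum(delta[:-1])
        return out


@dataclass
class AccessProfile:
    """Mean accessibility profile: ordered bin means in RPM per bin across
    ``n_regions`` summit-centered windows."""

    values: np.ndarray
    bin_width: int
    flank: int
    n_regions: int
    condition: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != 2 * self.flank // self.bin_width:
            raise ValueError("profile length must equal 2*flank/bin_width")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")

    def bin_offsets(self) -> np.ndarray:
        """Center offset of each bin relative to the summit, in bp."""
        return np.arange(-self.flank, self.flank, self.bin_width) + self.bin_width / 2.0


def fraction_open(gbr: Iterable[Peak], atac_peaks: PeakSet, min_bp: int = 1) -> tuple[int, int, float]:
    """(n_open, n_total, pct): regions overlapping any open-chromatin peak by >= min_bp bp."""
    peaks = list(gbr)
    if not peaks:
        raise ValueError("empty region set")
    n_open = sum(1 for p in peaks if atac_peaks.overlaps_peak(p, min_bp))
    return n_open, len(peaks), 100.0 * n_open / len(peaks)


def newly_accessible(
    gbr: Iterable[Peak],
    atac_with: PeakSet,
    atac_depleted: PeakSet,
    min_bp: int = 1,
) -> tuple[set[str], float]:
    """Regions open (ATAC peak overlap) only after depletion: open in the
    depleted-condition peak set and closed in the coregulator-containing one.
    Returns the peak_id subset and its fraction of the input."""
    peaks = list(gbr)
    if not peaks:
        return set(), 0.0
    newly = {
        p.peak_id
        for p in peaks
        if atac_depleted.overlaps_peak(p, min_bp) and not atac_with.overlaps_peak(p, min_bp)
    }
    return newly, len(newly) / len(peaks)


def aggregate_profile(
    gbr: Iterable[Peak],
    track: CoverageTrack,
    flank: int = 1000,
    bin_width: int = 10,
    condition: str = "",
) -> AccessProfile:
    """Mean RPM-per-bin profile over summit-centered windows [summit-flank, summit+flank).

    Per region, per-base coverage is summed within consecutive ``bin_width``-bp
    bins and scaled by 1e6 / total_reads; bins are then averaged region-wise.
    Windows running past a chromosome start are zero-padded with a warning.
    """
    if flank % bin_width != 0:
        raise ValueError("flank must be divisible by bin_width")
    n_bins = 2 * flank // bin_width
    acc = np.zeros(n_bins, dtype=float)
    n = 0
    clipped = 0
    for p in gbr:
        s = p.summit()
        w_start = s - flank
        cov = np.zeros(2 * flank, dtype=float)
        if w_start < 0:
            clipped += 1
            cov[-w_start:] = track.window_coverage(p.chrom, 0, s + flank)
        else:
            cov[:] = track.window_coverage(p.chrom, w_start, s + flank)
        acc += cov.reshape(n_bins, bin_width).sum(axis=1)
        n += 1
    if n == 0:
        raise ValueError("empty region set")
    if clipped:
        warnings.warn(f"{clipped} window(s) extended past the chromosome start; zero-padded", stacklevel=2)
    values = acc / n * 1e6 / track.total_reads
    return AccessProfile(values=values, bin_width=bin_width, flank=flank, n_regions=n, condition=condition)


def coverage_from_arrays(per_chrom: Mapping[str, np.ndarray], total_reads: float) -> CoverageTrack:
    """Build an RLE track from dense per-base coverage arrays (testing helper)."""
    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, arr in per_chrom.items():
        arr = np.asarray(arr, dtype=float)
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(arr)]))
        values = arr[starts]
        keep = values != 0
        runs[chrom] = (starts[keep].astype(np.int64), ends[keep].astype(np.int64), values[keep])
    return CoverageTrack(runs=runs, total_reads=total_reads)
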