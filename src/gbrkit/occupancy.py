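"""Consensus peaks, CPM normalization, and negative-binomial differential occupancy.

The differential test models per-peak counts as negative binomial with a
per-peak dispersion estimated by method-of-moments and shrunk 50/50 toward a
mean-dispersion trend, then applies a Wald test on the log2 fold change and
Benjamini-Hochberg correction across peaks. Significance gating combines the
FDR threshold with a fold-change cutoff (the MA-plot classification rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from gbrkit.intervals import Peak, PeakSet

PSEUDOCOUNT = 0.5
MIN_DISPERSION = 1e-6
MAX_DISPERSION = 10.0


@dataclass
class CountMatrix:
    """Per-peak read counts across samples.

    ``counts`` is indexed by peak_id with one column per sample; ``samples``
    has one row per sample with columns (sample, condition, replicate,
    library_size).
    """

    peaks: list[Peak]
    samples: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "condition", "replicate", "library_size"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"samples sheet missing columns: {sorted(missing)}")
        if list(self.counts.columns) != list(self.samples["sample"]):
            raise ValueError("counts columns must match the samples sheet order")
        if len(self.peaks) != len(self.counts):
            raise ValueError("peaks and count rows differ in length")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.samples["library_size"].to_numpy() <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def peak_ids(self) -> list[str]:
        return list(self.counts.index)

    def library_sizes(self) -> np.ndarray:
        return self.samples["library_size"].to_numpy(dtype=float)

    def condition_samples(self, condition: str) -> list[str]:
        return list(self.samples.loc[self.samples["condition"] == condition, "sample"])


@dataclass
class DiffResult:
    """Per-peak differential-occupancy statistics for one contrast.

    ``table`` columns: mean_log2_cpm (MA x-axis), log2_fc (MA y-axis, contrast
    condition over reference), p_value, fdr, significant.
    """

    contrast: tuple[str, str]
    table: pd.DataFrame
    alpha: float | None = None
    min_fold: float | None = None

    def significant_ids(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


def build_consensus(per_sample_peaks: Sequence[PeakSet], min_samples: int = 2) -> PeakSet:
    """Merged regions supported by peak calls in at least ``min_samples`` input sets.

    The pooled intervals (each set merged internally first) are segmented at
    every breakpoint; segments supported by >= min_samples sets are kept and
    contiguous kept segments are fused. The summit of each consensus region is
    the support-weighted centroid, i.e. the balance point of the per-base
    number of supporting samples.
    """
    if len(per_sample_peaks) < 2:
        raise ValueError("need at least 2 input peak sets")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if min_samples > len(per_sample_peaks):
        warnings.warn(
            f"min_samples={min_samples} exceeds the number of input sets "
            f"({len(per_sample_peaks)}); consensus is empty",
            stacklevel=2,
        )
        return PeakSet("consensus", [])

    merged_per_set = [s.merged_intervals() for s in per_sample_peaks]
    chroms = sorted({c for m in merged_per_set for c in m})
    out: list[Peak] = []
    n = 0
    for chrom in chroms:
        events: list[tuple[int, int]] = []
        for m in merged_per_set:
            for s, e in m.get(chrom, np.empty((0, 2), dtype=np.int64)):
                events.append((int(s), 1))
                events.append((int(e), -1))
        if not events:
            continue
        events.sort()
        # segments of constant support between consecutive breakpoints
        segments: list[tuple[int, int, int]] = []
        support = 0
        prev = events[0][0]
        i = 0
        while i < len(events):
            pos = events[i][0]
            if pos > prev and support >= min_samples:
                segments.append((prev, pos, support))
            while i < len(events) and events[i][0] == pos:
                support += events[i][1]
                i += 1
            prev = pos
        # fuse contiguous kept segments into consensus regions
        region: list[tuple[int, int, int]] = []
        for seg in segments + [(-1, -1, 0)]:
            if region and seg[0] != region[-1][1]:
                out.append(_segments_to_peak(chrom, region, f"cons_{n}"))
                n += 1
                region = []
            if seg[0] >= 0:
                region.append(seg)
    return PeakSet("consensus", out)


def _segments_to_peak(chrom: str, segments: list[tuple[int, int, int]], peak_id: str) -> Peak:
    start, end = segments[0][0], segments[-1][1]
    w = np.array([(e - s) * sup for s, e, sup in segments], dtype=float)
    mid = np.array([(s + e) / 2.0 for s, e, _ in segments])
    centroid = int(round(float((w * mid).sum() / w.sum())))
    offset = min(max(centroid - start, 0), end - start - 1)
    return Peak(chrom, start, end, summit_offset=offset, score=max(s[2] for s in segments), peak_id=peak_id)


def normalize_cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million mapped reads: count / library_size * 1e6."""
    libs = cm.library_sizes()
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    return cm.counts / libs * 1e6


def mean_log2_cpm(cm: CountMatrix, pseudocount: float = PSEUDOCOUNT) -> pd.Series:
    """log2(mean CPM across all samples + pseudocount) — the MA-plot x-axis."""
    return np.log2(normalize_cpm(cm).mean(axis=1) + pseudocount)


def _dispersion_trend(mean_counts: np.ndarray, disp_mom: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Smooth dispersion-vs-mean trend: binned means of the raw MoM estimates."""
    ok = mean_counts > 0
    if ok.sum() < 2:
        return np.full_like(disp_mom, 0.1)
    lm = np.log(mean_counts[ok])
    d = disp_mom[ok]
    qs = np.quantile(lm, np.linspace(0, 1, min(n_bins, max(2, ok.sum() // 10)) + 1))
    qs = np.unique(qs)
    centers, levels = [], []
    for lo, hi in zip(qs[:-1], qs[1:]):
        sel = (lm >= lo) & (lm <= hi)
        if sel.sum() >= 3:
            centers.append(lm[sel].mean())
            levels.append(float(np.mean(d[sel])))
    if not centers:
        return np.full_like(disp_mom, max(float(np.mean(d)), MIN_DISPERSION))
    trend = np.interp(np.log(np.maximum(mean_counts, 1e-8)), centers, levels)
    return np.clip(trend, MIN_DISPERSION, MAX_DISPERSION)


def nb_differential(
    cm: CountMatrix,
    contrast: tuple[str, str],
    pseudocount: float = PSEUDOCOUNT,
    shrink_weight: float = 0.5,
) -> DiffResult:
    """Negative-binomial Wald test of the contrast condition over the reference.

    Counts are normalized to a common library size; per-peak dispersions are
    method-of-moments estimates pooled over the two groups and shrunk
    ``shrink_weight``/(1-``shrink_weight``) toward a mean-dispersion trend.
    The Wald statistic is log2_fc over its delta-method standard error, with a
    two-sided normal p and BH correction across peaks.
    """
    cond, ref = contrast
    for c in (cond, ref):
        if c not in set(cm.samples["condition"]):
            raise ValueError(f"condition {c!r} missing from samples sheet")
    s_cond = cm.condition_samples(cond)
    s_ref = cm.condition_samples(ref)
    if len(s_cond) < 2 or len(s_ref) < 2:
        warnings.warn("fewer than 2 replicates in a contrast group; test will be unstable", stacklevel=2)

    libs = cm.library_sizes()
    mean_lib = float(libs.mean())
    # counts rescaled to a common (mean) library size
    y = (cm.counts / libs * mean_lib).to_numpy(dtype=float)
    cols = list(cm.counts.columns)
    ia = [cols.index(s) for s in s_cond]
    ib = [cols.index(s) for s in s_ref]
    ya, yb = y[:, ia], y[:, ib]
    na, nb = len(ia), len(ib)

    ma_, mb_ = ya.mean(axis=1), yb.mean(axis=1)
    va = ya.var(axis=1, ddof=1) if na > 1 else np.zeros_like(ma_)
    vb = yb.var(axis=1, ddof=1) if nb > 1 else np.zeros_like(mb_)

    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = ((va - ma_) + (vb - mb_)) / (ma_**2 + mb_**2)
    disp_mom = np.nan_to_num(disp_mom, nan=0.0, posinf=MAX_DISPERSION, neginf=0.0)
    disp_mom = np.clip(disp_mom, 0.0, MAX_DISPERSION)

    overall_mean = y.mean(axis=1)
    trend = _dispersion_trend(overall_mean, disp_mom)
    disp = np.clip(shrink_weight * disp_mom + (1.0 - shrink_weight) * trend, MIN_DISPERSION, MAX_DISPERSION)

    log2_fc = np.log2((ma_ + pseudocount) / (mb_ + pseudocount))
    var_log2 = (
        (ma_ + disp * ma_**2) / (na * (ma_ + pseudocount) ** 2)
        + (mb_ + disp * mb_**2) / (nb * (mb_ + pseudocount) ** 2)
    ) / np.log(2.0) ** 2
    se = np.sqrt(var_log2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2_fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "mean_log2_cpm": mean_log2_cpm(cm, pseudocount),
            "log2_fc": log2_fc,
            "p_value": p,
            "fdr": fdr,
            "significant": False,
        },
        index=cm.counts.index,
    )
    return DiffResult(contrast=contrast, table=table)


def ma_classify(dr: DiffResult, alpha: float = 0.01, min_fold: float = 3.0) -> set[str]:
    """Significant peaks: FDR <= alpha and |log2_fc| >= log2(min_fold).

    ``min_fold = 1`` disables the fold gate (pure FDR thresholding, as used for
    the chromatin-remodeler contrasts).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if min_fold < 1.0:
        raise ValueError("min_fold must be >= 1")
    t = dr.table
    sig = (t["fdr"] <= alpha) & (t["log2_fc"].abs() >= np.log2(min_fold))
    dr.table["significant"] = sig
    dr.alpha = alpha
    dr.min_fold = min_fold
    return set(t.index[sig])
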