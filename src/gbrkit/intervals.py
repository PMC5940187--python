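"""Genomic interval algebra: overlaps, Venn partitioning, summit windows, TSS distances.

All coordinates are 0-based half-open (BED convention). Peaks carry an optional
summit as an offset from the interval start (``-1`` = unknown; the interval
midpoint is used as a fallback wherever a summit is needed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

INF_DISTANCE = math.inf


@dataclass(frozen=True)
class Peak:
    """A called peak: a genomic interval with an optional summit.

    ``summit_offset`` is in bp from ``start``; ``-1`` means unknown, in which
    case :meth:`summit` falls back to ``floor((start + end) / 2)``.
    """

    chrom: str
    start: int
    end: int
    summit_offset: int = -1
    score: float = 0.0
    peak_id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"peak {self.peak_id!r}: start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"peak {self.peak_id!r}: end must exceed start ({self.start}-{self.end})")
        if self.summit_offset != -1 and not (0 <= self.summit_offset < self.end - self.start):
            raise ValueError(
                f"peak {self.peak_id!r}: summit_offset {self.summit_offset} outside [0, {self.end - self.start})"
            )
        if self.score < 0:
            raise ValueError(f"peak {self.peak_id!r}: score must be nonnegative")

    def summit(self) -> int:
        """Absolute summit coordinate (midpoint when the summit is unknown)."""
        if self.summit_offset == -1:
            return (self.start + self.end) // 2
        return self.start + self.summit_offset

    @property
    def length(self) -> int:
        return self.end - self.start


def overlaps(a: Peak, b: Peak, min_bp: int = 1) -> bool:
    """True iff *a* and *b* share at least ``min_bp`` bases.

    Different chromosomes never overlap; half-open adjacency (a.end == b.start)
    is not overlap.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_bp


def summit_window(p: Peak, flank: int) -> tuple[str, int, int]:
    """Half-open window of ``2 * flank`` bp centered at the peak summit, clipped at 0."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    s = p.summit()
    return (p.chrom, max(0, s - flank), s + flank)


def tss_distance(p: Peak, g) -> float:
    """Strand-agnostic |summit - TSS| distance in bp; +inf across chromosomes."""
    if p.chrom != g.chrom:
        return INF_DISTANCE
    return abs(p.summit() - g.tss)


class PeakSet:
    """A named, sorted collection of peaks with unique ids.

    Peaks are kept sorted by (chrom, start, end). ``metadata`` typically carries
    the condition/treatment labels of the sample the peaks were called from.
    """

    def __init__(self, name: str, peaks: Iterable[Peak], metadata: Mapping[str, str] | None = None):
        self.name = name
        self.peaks: list[Peak] = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
        self.metadata: dict[str, str] = dict(metadata or {})
        ids = [p.peak_id for p in self.peaks if p.peak_id]
        if len(ids) != len(set(ids)):
            raise ValueError(f"peak set {name!r}: duplicate peak_ids")
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def by_id(self) -> dict[str, Peak]:
        return {p.peak_id: p for p in self.peaks}

    def chroms(self) -> list[str]:
        return sorted({p.chrom for p in self.peaks})

    # -- merged-interval index for fast overlap queries -------------------

    def merged_intervals(self) -> dict[str, np.ndarray]:
        """Per-chromosome (n, 2) arrays of the set's intervals merged at >=1 bp overlap."""
        out: dict[str, np.ndarray] = {}
        for chrom, ivals in _group_by_chrom(self.peaks).items():
            out[chrom] = merge_intervals(ivals)
        return out

    def _ensure_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if self._index is None:
            self._index = {
                chrom: (arr[:, 0].copy(), arr[:, 1].copy())
                for chrom, arr in self.merged_intervals().items()
            }
        return self._index

    def overlaps_interval(self, chrom: str, start: int, end: int, min_bp: int = 1) -> bool:
        """True iff [start, end) on *chrom* overlaps this set by >= min_bp bases."""
        idx = self._ensure_index()
        if chrom not in idx:
            return False
        starts, ends = idx[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            if min(end, ends[i]) - max(start, starts[i]) >= min_bp:
                return True
        return False

    def overlaps_peak(self, p: Peak, min_bp: int = 1) -> bool:
        return self.overlaps_interval(p.chrom, p.start, p.end, min_bp)


def _group_by_chrom(peaks: Sequence[Peak]) -> dict[str, np.ndarray]:
    groups: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        groups.setdefault(p.chrom, []).append((p.start, p.end))
    return {c: np.asarray(v, dtype=np.int64) for c, v in groups.items()}


def merge_intervals(ivals: np.ndarray) -> np.ndarray:
    """Merge (n, 2) intervals overlapping by >=1 bp; adjacency is not merged."""
    if len(ivals) == 0:
        return ivals.reshape(0, 2)
    order = np.lexsort((ivals[:, 1], ivals[:, 0]))
    ivals = ivals[order]
    merged = [[int(ivals[0, 0]), int(ivals[0, 1])]]
    for s, e in ivals[1:]:
        if s < merged[-1][1]:  # strict: touching intervals stay separate
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])
    return np.asarray(merged, dtype=np.int64)


@dataclass
class VennPartition:
    """Partition of the union of 2-3 peak sets into membership compartments.

    Each atomic union region (connected component of the pooled, per-set-merged
    intervals) is assigned exactly one signature: the subset of input sets it
    overlaps. Signatures are frozensets of set names; ``counts`` maps each
    signature to the number of union regions carrying it, ``compartments`` to
    their region identifiers (``chrom:start-end``).
    """

    set_names: list[str]
    compartments: dict[frozenset, list[str]]
    counts: dict[frozenset, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {sig: len(ids) for sig, ids in self.compartments.items()}

    def count(self, *names: str) -> int:
        """Count of regions whose signature is exactly the given set names."""
        return self.counts.get(frozenset(names), 0)

    def member_total(self, name: str) -> int:
        """Number of union regions that include the named set."""
        return sum(n for sig, n in self.counts.items() if name in sig)

    def signature_label(self, sig: frozenset) -> str:
        return "&".join(n for n in self.set_names if n in sig) or "(none)"

    def to_dict(self) -> dict[str, int]:
        return {self.signature_label(sig): n for sig, n in sorted(self.counts.items(), key=lambda kv: self.signature_label(kv[0]))}


def reproducible_peaks(replicates: Sequence[PeakSet], name: str = "reproducible", min_bp: int = 1) -> PeakSet:
    """Replicate-overlap reproducibility filter.

    Returns the union regions of the pooled replicate calls that are supported
    by every replicate (>= ``min_bp`` overlap with each) — a deterministic
    stand-in for model-based irreproducible-discovery-rate filtering.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    merged = [s.merged_intervals() for s in replicates]
    chroms = sorted({c for m in merged for c in m})
    out: list[Peak] = []
    n = 0
    for chrom in chroms:
        present = [m.get(chrom, np.empty((0, 2), dtype=np.int64)) for m in merged]
        if any(len(iv) == 0 for iv in present):
            continue
        regions = merge_intervals(np.vstack(present))
        for start, end in regions:
            ok = True
            for ivals in present:
                ov = np.minimum(end, ivals[:, 1]) - np.maximum(start, ivals[:, 0])
                need = np.minimum(min_bp, ivals[:, 1] - ivals[:, 0])
                if not (ov >= need).any():
                    ok = False
                    break
            if ok:
                out.append(Peak(chrom, int(start), int(end), peak_id=f"{name}_{n}"))
                n += 1
    return PeakSet(name, out)


def venn_partition(sets: Sequence[PeakSet], min_bp: int = 1) -> VennPartition:
    """Venn-partition 2-3 peak sets into atomic union regions with one signature each.

    Within-set overlapping peaks are merged first; the pooled intervals are then
    flattened into connected union regions, and each region is assigned the
    signature of the input sets that overlap it by >= ``min_bp`` bp. Multiple
    peaks of one set falling in one region count once.
    """
    if not (2 <= len(sets) <= 3):
        raise ValueError("venn_partition takes 2 or 3 peak sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate set names: {names}")
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")

    merged = {s.name: s.merged_intervals() for s in sets}
    chroms = sorted({c for m in merged.values() for c in m})
    compartments: dict[frozenset, list[str]] = {}
    for chrom in chroms:
        pooled = np.vstack([m[chrom] for m in merged.values() if chrom in m])
        regions = merge_intervals(pooled)
        for start, end in regions:
            sig = set()
            for s in sets:
                ivals = merged[s.name].get(chrom)
                if ivals is None or len(ivals) == 0:
                    continue
                ov = np.minimum(end, ivals[:, 1]) - np.maximum(start, ivals[:, 0])
                # member if >= min_bp overlap; peaks shorter than min_bp count
                # when fully contained (their whole length overlaps)
                need = np.minimum(min_bp, ivals[:, 1] - ivals[:, 0])
                if (ov >= need).any():
                    sig.add(s.name)
            compartments.setdefault(frozenset(sig), []).append(f"{chrom}:{start}-{end}")
    return VennPartition(set_names=names, compartments=compartments)
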