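"""PWM scanning in summit-centered windows, motif enrichment, and co-occurrence.

Known position-weight matrices (a GRE, an AP-1, and an ETS-family model) are
scanned over fixed-width windows centered on peak summits; per-peak presence
feeds a hypergeometric enrichment test of a foreground peak class against a
background class, positional distributions of hits relative to the summit,
and three-way motif co-occurrence summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
DEFAULT_THRESHOLD_FRACTION = 0.8
NEG_INF = -1e12  # effective -inf for N bases


@dataclass
class Pwm:
    """Position probability matrix (4 x L, rows A/C/G/T) with a log-odds threshold.

    ``score_threshold`` defaults to ``DEFAULT_THRESHOLD_FRACTION`` of the
    maximum achievable log-odds score.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    score_threshold: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError(f"PWM {self.name}: matrix must be 4 x L with L >= 4")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x L log2(p / background); zero-probability cells score -inf."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.matrix / self.background[:, None])
        return np.where(np.isfinite(lo), lo, NEG_INF)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def threshold(self) -> float:
        if self.score_threshold is not None:
            return self.score_threshold
        return DEFAULT_THRESHOLD_FRACTION * self.max_score()

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            name=self.name,
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            score_threshold=self.score_threshold,
        )


@dataclass(frozen=True)
class MotifHit:
    peak_id: str
    motif: str
    offset: float  # bp from hit center to window center (signed)
    strand: str
    score: float


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def _encode(seq: str) -> np.ndarray:
    """Map A/C/G/T to 0..3 and anything else (N) to 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    idx = np.full(len(arr), 4, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        idx[arr == ord(b)] = i
    return idx


def _scores(idx: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Log-odds score at every start position; N bases contribute -inf."""
    L = lo.shape[1]
    if len(idx) < L:
        return np.empty(0)
    lo5 = np.vstack([lo, np.full(L, NEG_INF)])  # row 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    return lo5[windows, np.arange(L)].sum(axis=1)


def scan_pwm(sequence: str, pwm: Pwm, flank: int = 500, peak_id: str = "") -> list[MotifHit]:
    """All positions on either strand scoring >= the PWM threshold.

    ``sequence`` must be the 2*flank window centered on the summit; hit offsets
    are measured from hit center to window center (exact, so the hit set of a
    reverse-complemented window mirrors with negated offsets).
    """
    if len(sequence) != 2 * flank:
        raise ValueError(f"sequence length {len(sequence)} != 2*flank ({2 * flank})")
    idx = _encode(sequence)
    thr = pwm.threshold()
    L = pwm.length
    center = (len(sequence) - 1) / 2.0
    hits: list[MotifHit] = []
    for strand, lo in (("+", pwm.log_odds()), ("-", pwm.reverse_complement().log_odds())):
        sc = _scores(idx, lo)
        for pos in np.flatnonzero(sc >= thr):
            offset = pos + (L - 1) / 2.0 - center
            hits.append(MotifHit(peak_id=peak_id, motif=pwm.name, offset=float(offset), strand=strand, score=float(sc[pos])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def peaks_with_motif(sequences: Mapping[str, str], pwm: Pwm, flank: int = 500) -> set[str]:
    """Peak ids whose window carries at least one hit."""
    return {pid for pid, seq in sequences.items() if scan_pwm(seq, pwm, flank, pid)}


@dataclass
class EnrichmentResult:
    motif: str
    n_fore_with: int
    n_fore: int
    n_back_with: int
    n_back: int
    prevalence_pct: float
    p_value: float


def motif_enrichment(
    fore_sequences: Mapping[str, str],
    back_sequences: Mapping[str, str],
    pwm: Pwm,
    flank: int = 500,
) -> EnrichmentResult:
    """Hypergeometric upper-tail enrichment of motif presence in the foreground.

    A peak counts "with motif" when its window has >= 1 hit; the test draws
    ``n_fore`` peaks from the pooled foreground+background population and asks
    for P(X >= n_fore_with).
    """
    if not fore_sequences or not back_sequences:
        raise ValueError("foreground and background must both be non-empty")
    if set(fore_sequences) & set(back_sequences):
        raise ValueError("foreground and background must be disjoint")
    fore_with = peaks_with_motif(fore_sequences, pwm, flank)
    back_with = peaks_with_motif(back_sequences, pwm, flank)
    return enrichment_from_presence(
        pwm.name, len(fore_with), len(fore_sequences), len(back_with), len(back_sequences)
    )


def enrichment_from_presence(
    motif: str, n_fore_with: int, n_fore: int, n_back_with: int, n_back: int
) -> EnrichmentResult:
    """Hypergeometric upper-tail test from precomputed with-motif counts."""
    if n_fore <= 0 or n_back <= 0:
        raise ValueError("foreground and background must both be non-empty")
    p = float(stats.hypergeom.sf(n_fore_with - 1, n_fore + n_back, n_fore_with + n_back_with, n_fore))
    return EnrichmentResult(
        motif=motif,
        n_fore_with=n_fore_with,
        n_fore=n_fore,
        n_back_with=n_back_with,
        n_back=n_back,
        prevalence_pct=100.0 * n_fore_with / n_fore,
        p_value=p,
    )


def positional_distribution(
    hits: Iterable[MotifHit],
    bin_width: int = 50,
    flank: int = 500,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Histogram of hit offsets plus (mean, SD) of |offset| over per-peak best hits.

    Returns (bin_edges, counts, mean_abs_offset, sd_abs_offset). The histogram
    uses every hit; the summary statistics use the best-scoring hit per peak.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    hits = list(hits)
    edges = np.arange(-flank, flank + bin_width, bin_width, dtype=float)
    counts, _ = np.histogram([h.offset for h in hits], bins=edges)
    best: dict[str, MotifHit] = {}
    for h in hits:
        if h.peak_id not in best or h.score > best[h.peak_id].score:
            best[h.peak_id] = h
    if best:
        abs_off = np.array([abs(h.offset) for h in best.values()])
        mean, sd = float(abs_off.mean()), float(abs_off.std(ddof=0))
    else:
        mean, sd = float("nan"), float("nan")
    return edges, counts, mean, sd


def motif_cooccurrence(
    per_motif_presence: Mapping[str, set[str]],
    universe: set[str],
) -> dict:
    """Three-way Venn counts and conditional percentages of motif presence.

    Returns {"venn": {signature: count}, "conditional_pct": {"X|Y": pct},
    "pct_any": pct of universe with >= 1 motif}.
    """
    names = list(per_motif_presence)
    for name, ids in per_motif_presence.items():
        if not ids <= universe:
            raise ValueError(f"{name}: presence set not contained in universe")
    venn: dict[str, int] = {}
    from itertools import product

    for mask in product([False, True], repeat=len(names)):
        if not any(mask):
            continue
        sel = universe.copy()
        for name, inc in zip(names, mask):
            sel = sel & per_motif_presence[name] if inc else sel - per_motif_presence[name]
        venn["&".join(n for n, inc in zip(names, mask) if inc)] = len(sel)
    cond: dict[str, float] = {}
    for x in names:
        for y in names:
            if x == y:
                continue
            ny = len(per_motif_presence[y])
            cond[f"{x}|{y}"] = 100.0 * len(per_motif_presence[x] & per_motif_presence[y]) / ny if ny else 0.0
    any_ids = set().union(*per_motif_presence.values()) if names else set()
    pct_any = 100.0 * len(any_ids) / len(universe) if universe else 0.0
    return {"venn": venn, "conditional_pct": cond, "pct_any": pct_any}


# -- PWM text format ------------------------------------------------------


def parse_jaspar(text: str) -> list[Pwm]:
    """Parse JASPAR-style count/probability matrices.

    Format per record: a ``>name`` header then four lines ``A [ n n ... ]``
    (C, G, T). Columns are normalized to probabilities.
    """
    pwms: list[Pwm] = []
    name = None
    rows: dict[str, list[float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                pwms.append(_finish_pwm(name, rows))
            name = line[1:].split()[0]
            rows = {}
        else:
            base = line[0].upper()
            if base not in _BASE_INDEX:
                raise ValueError(f"unexpected matrix row: {line!r}")
            nums = line[1:].replace("[", " ").replace("]", " ").split()
            rows[base] = [float(x) for x in nums]
    if name is not None:
        pwms.append(_finish_pwm(name, rows))
    return pwms


def _finish_pwm(name: str, rows: dict[str, list[float]]) -> Pwm:
    if set(rows) != set(BASES):
        raise ValueError(f"PWM {name}: need A, C, G and T rows")
    mat = np.array([rows[b] for b in BASES], dtype=float)
    mat = mat / mat.sum(axis=0, keepdims=True)
    return Pwm(name=name, matrix=mat)


def write_jaspar(pwms: Sequence[Pwm], path: str | Path, counts_scale: float = 100.0) -> None:
    lines = []
    for pwm in pwms:
        lines.append(f">{pwm.name}")
        for i, b in enumerate(BASES):
            vals = " ".join(f"{v * counts_scale:.2f}" for v in pwm.matrix[i])
            lines.append(f"{b} [ {vals} ]")
    Path(path).write_text("\n".join(lines) + "\n")


def load_pwms(path: str | Path | None = None) -> dict[str, Pwm]:
    """Load PWMs from a JASPAR-style file, or the package's bundled GRE/AP-1/ETS models."""
    if path is not None:
        text = Path(path).read_text()
    else:
        text = resources.files("gbrkit.data").joinpath("core_motifs.jaspar").read_text()
    return {p.name: p for p in parse_jaspar(text)}
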