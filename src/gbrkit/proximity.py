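"""TSS-window proximity of blocked/non-blocked regions to gene classes, with chi-square tests.

Genes carry a regulatory-response class label — ``block`` (hormone-regulated
only after coregulator depletion), ``ind`` (regulated independently of the
coregulator), ``mod`` (regulation modulated by it) — and binding regions are
tallied per class within nested windows around the TSS. Ratios of blocked to
non-blocked regions are compared between classes by Pearson chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GENE_CLASSES = ("block", "ind", "mod")
DEFAULT_WINDOWS = (10_000, 50_000, 100_000, 1_000_000)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"
    gene_class: str = "none"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


def _tss_by_chrom(genes: list[GeneRecord]) -> dict[str, np.ndarray]:
    groups: dict[str, list[int]] = {}
    for g in genes:
        groups.setdefault(g.chrom, []).append(g.tss)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in groups.items()}


def gbr_near_genes(classification, genes: list[GeneRecord], window: int) -> dict[str, dict[str, set[str]]]:
    """Peak ids near each gene class, split by blocked/non-blocked label.

    A region belongs to a gene class when its summit lies within ``window`` bp
    of any TSS of that class (strand-agnostic, summit-to-TSS distance). A
    region may belong to several classes; within a class it counts once.
    Returns {gene_class: {"blocked": ids, "non_blocked": ids}}.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t = classification.table
    out: dict[str, dict[str, set[str]]] = {}
    for cls in GENE_CLASSES:
        tss_idx = _tss_by_chrom([g for g in genes if g.gene_class == cls])
        hits: dict[str, set[str]] = {"blocked": set(), "non_blocked": set()}
        sub = t[t["label"].isin(["blocked", "non_blocked"])]
        for pid, row in sub.iterrows():
            tss = tss_idx.get(row["chrom"])
            if tss is None or len(tss) == 0:
                continue
            s = row["summit"]
            i = int(np.searchsorted(tss, s))
            near = (i < len(tss) and abs(int(tss[i]) - s) <= window) or (
                i > 0 and abs(int(tss[i - 1]) - s) <= window
            )
            if near:
                hits[row["label"]].add(pid)
        out[cls] = hits
    return out


def chi_square_ratio(
    counts_a: tuple[int, int],
    counts_b: tuple[int, int],
    yates: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square (1 df) comparing two blocked/non-blocked ratios.

    Computed by the textbook sum over cells of (O - E)^2 / E on the 2x2 table
    with rows (counts_a, counts_b); no continuity correction unless ``yates``.
    """
    obs = np.asarray([counts_a, counts_b], dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row <= 0).any() or (col <= 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    expected = np.outer(row, col) / obs.sum()
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p


def proportion_table(
    classification,
    genes: list[GeneRecord],
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    reference_class: str = "block",
    yates: bool = False,
) -> pd.DataFrame:
    """Per (gene class, window) blocked/non-blocked counts, percentage blocked,
    and chi-square versus the reference class's ratio at the same window.

    Rows with an all-zero margin (no regions, or a class with no genes) are
    flagged ``defined = False`` with NaN statistics.
    """
    rows = []
    per_window = {w: gbr_near_genes(classification, genes, w) for w in windows}
    for w in windows:
        near = per_window[w]
        ref = near.get(reference_class, {"blocked": set(), "non_blocked": set()})
        ref_counts = (len(ref["blocked"]), len(ref["non_blocked"]))
        for cls in GENE_CLASSES:
            nb = len(near[cls]["blocked"])
            nn = len(near[cls]["non_blocked"])
            total = nb + nn
            row = {
                "gene_class": cls,
                "window": w,
                "n_blocked": nb,
                "n_nonblocked": nn,
                "pct_blocked": 100.0 * nb / total if total else np.nan,
                "defined": total > 0,
                "chi2": np.nan,
                "p": np.nan,
                "significant_0.001": False,
            }
            if cls != reference_class and total > 0 and sum(ref_counts) > 0:
                try:
                    chi2, p = chi_square_ratio((nb, nn), ref_counts, yates=yates)
                    row.update({"chi2": chi2, "p": p, "significant_0.001": p < 0.001})
                except ValueError:
                    row["defined"] = False
            rows.append(row)
    return pd.DataFrame(rows)
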