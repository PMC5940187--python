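"""Blocked / non-blocked classification of binding regions and remodeler dependency.

A consensus binding region is *blocked* when its occupancy increases
significantly upon coregulator depletion (FDR- and fold-gated differential
call) and it is present in the depleted-cell reproducible peak set;
*non-blocked* when it is reproducibly called both with and without the
coregulator and shows no significant occupancy change. Chromatin-remodeler
dependency is assessed two ways: by disappearance of the called peak upon
remodeler co-depletion (peak-set route), or by a significant directional drop
in occupancy (differential route).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from gbrkit.intervals import Peak, PeakSet
from gbrkit.occupancy import DiffResult

LABELS = ("blocked", "non_blocked", "hic5_dependent", "shared_nonsig", "other")


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (report-parity rounding)."""
    return int(Decimal(x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class GbrClassification:
    """Per-consensus-peak labels plus the evidence flags behind them.

    ``table`` is indexed by peak_id with columns: chrom, start, end, summit,
    label, blocked_subtype, in_idr_control, in_idr_depleted, diff_significant.
    """

    table: pd.DataFrame
    peaks: PeakSet

    def ids_with_label(self, label: str) -> set[str]:
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
        return set(self.table.index[self.table["label"] == label])

    def peaks_with_label(self, label: str) -> list[Peak]:
        ids = self.ids_with_label(label)
        return [p for p in self.peaks if p.peak_id in ids]

    def counts(self) -> dict[str, int]:
        return {lab: int((self.table["label"] == lab).sum()) for lab in LABELS}


def classify_gbr(
    consensus: PeakSet,
    idr_control: PeakSet,
    idr_depleted: PeakSet,
    significant: set[str],
    min_bp: int = 1,
) -> GbrClassification:
    """Assign each consensus peak one label from the blocked/non-blocked scheme.

    Labels (mutually exclusive, assigned in this priority):

    - ``blocked``: significant gain upon depletion and present in the
      depleted-cell reproducible set. Subtype ``depletion_only`` when absent
      from the control set, else ``shared_but_differential``.
    - ``hic5_dependent``: present only in the control reproducible set
      (binding lost upon depletion).
    - ``non_blocked``: present in both reproducible sets, not significant.
    - ``shared_nonsig``: present only in the depleted set, not significant.
    - ``other``: remaining cases (significant but absent from the depleted
      reproducible set, or reproducible in neither condition).
    """
    ids = {p.peak_id for p in consensus}
    orphans = significant - ids
    if orphans:
        raise ValueError(f"{len(orphans)} significant peak_ids absent from consensus (e.g. {sorted(orphans)[:3]})")

    rows = []
    for p in consensus:
        in_ctrl = idr_control.overlaps_peak(p, min_bp)
        in_depl = idr_depleted.overlaps_peak(p, min_bp)
        sig = p.peak_id in significant
        subtype = "n/a"
        if sig and in_depl:
            label = "blocked"
            subtype = "shared_but_differential" if in_ctrl else "depletion_only"
        elif in_ctrl and not in_depl:
            label = "hic5_dependent"
        elif in_ctrl and in_depl and not sig:
            label = "non_blocked"
        elif in_depl and not in_ctrl and not sig:
            label = "shared_nonsig"
        else:
            label = "other"
        rows.append(
            {
                "peak_id": p.peak_id,
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "summit": p.summit(),
                "label": label,
                "blocked_subtype": subtype,
                "in_idr_control": in_ctrl,
                "in_idr_depleted": in_depl,
                "diff_significant": sig,
            }
        )
    table = pd.DataFrame(rows).set_index("peak_id")
    return GbrClassification(table=table, peaks=consensus)


@dataclass
class DependencyCompartments:
    """Joint remodeler-dependency compartments for one class of binding regions."""

    dep_both: int
    dep_chd9_only: int
    dep_brm_only: int
    dep_neither: int

    @property
    def total(self) -> int:
        return self.dep_both + self.dep_chd9_only + self.dep_brm_only + self.dep_neither


def dependency_by_peaksets(
    regions: list[Peak],
    peaks_chd9_codepletion: PeakSet,
    peaks_brm_codepletion: PeakSet,
    min_bp: int = 1,
) -> DependencyCompartments:
    """Dependency by peak presence: a region is remodeler-dependent iff no peak
    is called there in the corresponding co-depletion set."""
    both = c_only = b_only = neither = 0
    for p in regions:
        dep_c = not peaks_chd9_codepletion.overlaps_peak(p, min_bp)
        dep_b = not peaks_brm_codepletion.overlaps_peak(p, min_bp)
        if dep_c and dep_b:
            both += 1
        elif dep_c:
            c_only += 1
        elif dep_b:
            b_only += 1
        else:
            neither += 1
    return DependencyCompartments(dep_both=both, dep_chd9_only=c_only, dep_brm_only=b_only, dep_neither=neither)


def dependency_by_diff(
    region_ids: set[str],
    diff_chd9: DiffResult,
    diff_brm: DiffResult,
    alpha: float = 0.01,
) -> DependencyCompartments:
    """Dependency by differential statistics: FDR <= alpha AND reduced occupancy
    (log2_fc < 0) in the co-depletion-versus-single-depletion contrast."""

    def dependent(dr: DiffResult) -> set[str]:
        t = dr.table
        sel = (t["fdr"] <= alpha) & (t["log2_fc"] < 0)
        return set(t.index[sel]) & region_ids

    dep_c = dependent(diff_chd9)
    dep_b = dependent(diff_brm)
    both = len(dep_c & dep_b)
    return DependencyCompartments(
        dep_both=both,
        dep_chd9_only=len(dep_c) - both,
        dep_brm_only=len(dep_b) - both,
        dep_neither=len(region_ids) - len(dep_c | dep_b),
    )


def summarize_dependency(dc: DependencyCompartments) -> dict[str, int]:
    """Integer percentages of regions dependent on each remodeler, both, either, neither."""
    if dc.total <= 0:
        raise ValueError("total must be positive")
    t = dc.total
    return {
        "pct_chd9": round_half_up(100.0 * (dc.dep_chd9_only + dc.dep_both) / t),
        "pct_brm": round_half_up(100.0 * (dc.dep_brm_only + dc.dep_both) / t),
        "pct_both": round_half_up(100.0 * dc.dep_both / t),
        "pct_either": round_half_up(100.0 * (t - dc.dep_neither) / t),
        "pct_neither": round_half_up(100.0 * dc.dep_neither / t),
    }
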