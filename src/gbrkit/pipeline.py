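"""Pipeline configuration and stage orchestration.

Stages: consensus -> reproducible sets -> differential occupancy ->
blocked/non-blocked classification -> remodeler dependency -> TSS proximity ->
chromatin accessibility -> motif enrichment -> summary report. Each stage
persists its outputs as TSV/JSON under the configured output directory; the
summary records every threshold used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gbrkit import io as gio
from gbrkit.accessibility import aggregate_profile, fraction_open, newly_accessible
from gbrkit.classify import classify_gbr, dependency_by_diff, dependency_by_peaksets, summarize_dependency
from gbrkit.intervals import PeakSet, reproducible_peaks
from gbrkit.motifs import (
    enrichment_from_presence,
    load_pwms,
    motif_cooccurrence,
    peaks_with_motif,
    positional_distribution,
    scan_pwm,
)
from gbrkit.occupancy import build_consensus, ma_classify, nb_differential
from gbrkit.proximity import chi_square_ratio, proportion_table

log = logging.getLogger("gbrkit")

DEFAULT_WINDOWS = (10_000, 50_000, 100_000, 1_000_000)


@dataclass
class PipelineConfig:
    """Input paths, condition names, and the analysis thresholds.

    Threshold defaults are the study's cutoffs: differential FDR 0.01 with a
    3-fold gate for the depletion contrast, FDR 0.01 with no fold gate for the
    remodeler contrasts, nested TSS windows of 10 kb to 1 Mb, a 1-kb motif
    window (flank 500) and a +/-1 kb, 10-bp-binned accessibility profile.
    """

    replicate_peaks: dict = field(default_factory=dict)  # condition -> [paths]
    counts: str = ""
    samples: str = ""
    genes: str = ""
    atac_peaks: dict = field(default_factory=dict)  # atac condition -> path
    atac_coverage: dict = field(default_factory=dict)
    sequences: str = ""
    pwms: str | None = None
    outdir: str = "results"
    # condition names
    control_condition: str = "siNS/siNS"
    depleted_condition: str = "siHic5/siNS"
    chd9_codepletion: str = "siCHD9/siHic5"
    brm_codepletion: str = "siBRM/siHic5"
    atac_conditions: tuple = ("siNS_etoh", "siNS_dex", "siHic5_etoh", "siHic5_dex")
    # thresholds
    alpha: float = 0.01
    min_fold: float = 3.0
    dependency_alpha: float = 0.01
    windows: tuple = DEFAULT_WINDOWS
    min_bp: int = 1
    yates: bool = False
    min_samples: int = 2
    motif_flank: int = 500
    profile_flank: int = 1000
    profile_bin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_fold < 1 or self.min_bp < 1 or self.profile_bin <= 0:
            raise ValueError("thresholds must be positive (min_fold >= 1)")

    @classmethod
    def from_manifest(cls, manifest_path: str | Path, outdir: str | Path | None = None, **overrides) -> "PipelineConfig":
        m = json.loads(Path(manifest_path).read_text())
        kwargs = {
            "replicate_peaks": m["replicate_peaks"],
            "counts": m["counts"],
            "samples": m["samples"],
            "genes": m["genes"],
            "atac_peaks": m["atac_peaks"],
            "atac_coverage": m["atac_coverage"],
            "sequences": m["sequences"],
            "seed": m.get("seed", 0),
        }
        if outdir is not None:
            kwargs["outdir"] = str(outdir)
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("windows", "atac_conditions"):
            if key in data:
                data[key] = tuple(data[key])
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class Pipeline:
    """Stage runner holding intermediate objects; each ``stage_*`` persists its outputs."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.state: dict = {}

    # -- helpers ----------------------------------------------------------

    def _replicate_sets(self) -> dict[str, list[PeakSet]]:
        if "replicates" not in self.state:
            self.state["replicates"] = {
                cond: [gio.read_narrowpeak(p, name=f"{cond}_rep{i + 1}") for i, p in enumerate(paths)]
                for cond, paths in self.cfg.replicate_peaks.items()
            }
        return self.state["replicates"]

    # -- stages -----------------------------------------------------------

    def stage_consensus(self):
        reps = self._replicate_sets()
        all_sets = [s for sets in reps.values() for s in sets]
        consensus = build_consensus(all_sets, min_samples=self.cfg.min_samples)
        gio.write_narrowpeak(consensus, self.out / "consensus.narrowPeak")
        self.state["consensus"] = consensus
        log.info("consensus: %d regions from %d samples (min_samples=%d)", len(consensus), len(all_sets), self.cfg.min_samples)
        return consensus

    def stage_reproducible(self):
        reps = self._replicate_sets()
        repro = {}
        pooled = {}
        (self.out / "reproducible").mkdir(exist_ok=True)
        for cond, sets in reps.items():
            r = reproducible_peaks(sets, name=f"idr_{cond.replace('/', '_')}", min_bp=self.cfg.min_bp)
            repro[cond] = r
            gio.write_narrowpeak(r, self.out / "reproducible" / f"{cond.replace('/', '_')}.narrowPeak")
            pooled[cond] = PeakSet(f"pooled_{cond.replace('/', '_')}", [p for s in sets for p in s], {"condition": cond})
        self.state["reproducible"] = repro
        self.state["pooled"] = pooled
        return repro

    def stage_diff(self):
        cm = gio.read_count_matrix(self.cfg.counts, self.cfg.samples)
        self.state["count_matrix"] = cm
        contrasts = {
            "hic5": (self.cfg.depleted_condition, self.cfg.control_condition),
            "chd9": (self.cfg.chd9_codepletion, self.cfg.depleted_condition),
            "brm": (self.cfg.brm_codepletion, self.cfg.depleted_condition),
        }
        diffs = {}
        for key, contrast in contrasts.items():
            dr = nb_differential(cm, contrast)
            if key == "hic5":
                ma_classify(dr, self.cfg.alpha, self.cfg.min_fold)
            else:
                ma_classify(dr, self.cfg.dependency_alpha, 1.0)
            gio.write_diff_result(dr, self.out / f"diff_{key}.tsv")
            diffs[key] = dr
        self.state["diffs"] = diffs
        return diffs

    def stage_classify(self):
        consensus = self.state.get("consensus") or self.stage_consensus()
        repro = self.state.get("reproducible") or self.stage_reproducible()
        diffs = self.state.get("diffs") or self.stage_diff()
        significant = diffs["hic5"].significant_ids()
        classification = classify_gbr(
            consensus,
            idr_control=repro[self.cfg.control_condition],
            idr_depleted=repro[self.cfg.depleted_condition],
            significant=significant,
            min_bp=self.cfg.min_bp,
        )
        classification.table.to_csv(self.out / "classification.tsv", sep="\t")
        self.state["classification"] = classification
        log.info("classification: %s", classification.counts())
        return classification

    def stage_dependency(self):
        classification = self.state.get("classification") or self.stage_classify()
        pooled = self.state.get("pooled") or (self.stage_reproducible(), self.state["pooled"])[1]
        diffs = self.state.get("diffs") or self.stage_diff()
        result = {}
        for label in ("blocked", "non_blocked"):
            regions = classification.peaks_with_label(label)
            ids = classification.ids_with_label(label)
            entry = {}
            if regions:
                dc = dependency_by_peaksets(
                    regions, pooled[self.cfg.chd9_codepletion], pooled[self.cfg.brm_codepletion], self.cfg.min_bp
                )
                entry["peakset"] = {**dataclasses.asdict(dc), "total": dc.total, **summarize_dependency(dc)}
                dd = dependency_by_diff(ids, diffs["chd9"], diffs["brm"], self.cfg.dependency_alpha)
                entry["diff"] = {**dataclasses.asdict(dd), "total": dd.total, **summarize_dependency(dd)}
            result[label] = entry
        gio.write_json(result, self.out / "dependency.json")
        self.state["dependency"] = result
        return result

    def stage_proximity(self):
        classification = self.state.get("classification") or self.stage_classify()
        genes = gio.read_genes(self.cfg.genes)
        table = proportion_table(classification, genes, windows=tuple(self.cfg.windows), yates=self.cfg.yates)
        table.to_csv(self.out / "proximity.tsv", sep="\t", index=False, float_format="%.6g")
        self.state["proximity"] = table
        self.state["genes"] = genes
        return table

    def stage_access(self):
        classification = self.state.get("classification") or self.stage_classify()
        atac = {cond: gio.read_bed6(path, name=f"atac_{cond}") for cond, path in self.cfg.atac_peaks.items()}
        rows = []
        frac = {}
        for label in ("blocked", "non_blocked"):
            regions = classification.peaks_with_label(label)
            if not regions:
                continue
            for cond in self.cfg.atac_conditions:
                n_open, n_total, pct = fraction_open(regions, atac[cond], self.cfg.min_bp)
                rows.append({"label": label, "condition": cond, "n_open": n_open, "n_total": n_total, "pct_open": pct})
                frac[(label, cond)] = (n_open, n_total)
        open_df = pd.DataFrame(rows)
        for cond in self.cfg.atac_conditions:
            if ("blocked", cond) in frac and ("non_blocked", cond) in frac:
                nb_open, nb_tot = frac[("blocked", cond)]
                nn_open, nn_tot = frac[("non_blocked", cond)]
                chi2, p = chi_square_ratio((nb_open, nb_tot - nb_open), (nn_open, nn_tot - nn_open), self.cfg.yates)
                open_df.loc[open_df["condition"] == cond, "chi2_vs_other_class"] = chi2
                open_df.loc[open_df["condition"] == cond, "p_vs_other_class"] = p
        open_df.to_csv(self.out / "open_fractions.tsv", sep="\t", index=False, float_format="%.6g")

        etoh_pair = (self.cfg.atac_conditions[0], self.cfg.atac_conditions[2])
        dex_pair = (self.cfg.atac_conditions[1], self.cfg.atac_conditions[3])
        newly = {}
        for label in ("blocked", "non_blocked"):
            regions = classification.peaks_with_label(label)
            if not regions:
                continue
            for treat, (with_c, depl_c) in (("etoh", etoh_pair), ("dex", dex_pair)):
                ids, fraction = newly_accessible(regions, atac[with_c], atac[depl_c], self.cfg.min_bp)
                newly[f"{label}_{treat}"] = {"n": len(ids), "fraction": fraction, "pct": 100.0 * fraction}
        gio.write_json(newly, self.out / "newly_accessible.json")

        prof_rows = []
        profiles = {}
        for cond in self.cfg.atac_conditions:
            track = gio.read_bedgraph(self.cfg.atac_coverage[cond])
            for label in ("blocked", "non_blocked"):
                regions = classification.peaks_with_label(label)
                if not regions:
                    continue
                prof = aggregate_profile(regions, track, self.cfg.profile_flank, self.cfg.profile_bin, condition=cond)
                profiles[(label, cond)] = prof
                for off, v in zip(prof.bin_offsets(), prof.values):
                    prof_rows.append({"label": label, "condition": cond, "bin_center_offset": off, "mean_rpm": v})
        pd.DataFrame(prof_rows).to_csv(self.out / "profiles.tsv", sep="\t", index=False, float_format="%.6g")
        self.state["open_fractions"] = open_df
        self.state["newly_accessible"] = newly
        self.state["profiles"] = profiles
        return open_df, newly, profiles

    def stage_motifs(self):
        classification = self.state.get("classification") or self.stage_classify()
        sequences = gio.read_fasta(self.cfg.sequences)
        pwms = load_pwms(self.cfg.pwms)
        flank = self.cfg.motif_flank
        fore = {pid: sequences[pid] for pid in classification.ids_with_label("blocked") if pid in sequences}
        back = {pid: sequences[pid] for pid in classification.ids_with_label("non_blocked") if pid in sequences}
        enr_rows = []
        presence = {}
        pos_rows = []
        for name, pwm in pwms.items():
            fore_hits = {pid: scan_pwm(seq, pwm, flank, pid) for pid, seq in fore.items()}
            back_with = len(peaks_with_motif(back, pwm, flank))
            presence[name] = {pid for pid, h in fore_hits.items() if h}
            for direction, kf, nf, kb_, nb_ in (
                ("blocked_vs_nonblocked", len(presence[name]), len(fore), back_with, len(back)),
                ("nonblocked_vs_blocked", back_with, len(back), len(presence[name]), len(fore)),
            ):
                r = enrichment_from_presence(name, kf, nf, kb_, nb_)
                enr_rows.append(
                    {
                        "motif": name, "foreground": direction,
                        "n_fore_with": r.n_fore_with, "n_fore": r.n_fore,
                        "n_back_with": r.n_back_with, "n_back": r.n_back,
                        "prevalence_pct": r.prevalence_pct, "p_value": r.p_value,
                    }
                )
            hits = [h for hs in fore_hits.values() for h in hs]
            edges, counts, mean_abs, sd_abs = positional_distribution(hits, bin_width=50, flank=flank)
            pos_rows.append({"motif": name, "mean_abs_offset": mean_abs, "sd_abs_offset": sd_abs, "n_hits": len(hits)})
        enr_df = pd.DataFrame(enr_rows)
        enr_df.to_csv(self.out / "motif_enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        pos_df = pd.DataFrame(pos_rows)
        pos_df.to_csv(self.out / "motif_positions.tsv", sep="\t", index=False, float_format="%.6g")
        cooc = motif_cooccurrence(presence, set(fore))
        gio.write_json(cooc, self.out / "motif_cooccurrence.json")
        self.state["motif_enrichment"] = enr_df
        self.state["motif_positions"] = pos_df
        self.state["motif_cooccurrence"] = cooc
        return enr_df, pos_df, cooc

    def stage_report(self) -> dict:
        classification = self.state["classification"]
        diffs = self.state["diffs"]
        hic5 = diffs["hic5"].table
        sig = hic5[hic5["significant"]]
        counts = classification.counts()
        n_bl, n_nb = counts["blocked"], counts["non_blocked"]
        summary = {
            "thresholds": {
                "alpha": self.cfg.alpha,
                "min_fold": self.cfg.min_fold,
                "dependency_alpha": self.cfg.dependency_alpha,
                "windows": list(self.cfg.windows),
                "min_bp": self.cfg.min_bp,
                "min_samples": self.cfg.min_samples,
                "motif_flank": self.cfg.motif_flank,
                "profile_flank": self.cfg.profile_flank,
                "profile_bin": self.cfg.profile_bin,
                "seed": self.cfg.seed,
            },
            "n_consensus": len(self.state["consensus"]),
            "classification_counts": counts,
            "n_significant": int(len(sig)),
            "pct_significant_increased": (100.0 * float((sig["log2_fc"] > 0).mean()) if len(sig) else float("nan")),
            "pct_blocked_of_classified": (100.0 * n_bl / (n_bl + n_nb) if (n_bl + n_nb) else float("nan")),
            "dependency": self.state.get("dependency"),
            "proximity": (
                self.state["proximity"].to_dict(orient="records") if "proximity" in self.state else None
            ),
            "open_fractions": (
                self.state["open_fractions"].to_dict(orient="records") if "open_fractions" in self.state else None
            ),
            "newly_accessible": self.state.get("newly_accessible"),
            "profile_means": {
                f"{label}_{cond}": float(np.mean(p.values)) for (label, cond), p in self.state.get("profiles", {}).items()
            },
            "motif_enrichment": (
                self.state["motif_enrichment"].to_dict(orient="records") if "motif_enrichment" in self.state else None
            ),
            "motif_positions": (
                self.state["motif_positions"].to_dict(orient="records") if "motif_positions" in self.state else None
            ),
            "motif_cooccurrence": self.state.get("motif_cooccurrence"),
        }
        gio.write_json(summary, self.out / "summary.json")
        self.state["summary"] = summary
        return summary

    STAGES = ("consensus", "reproducible", "diff", "classify", "dependency", "proximity", "access", "motifs", "report")

    def run_all(self) -> dict:
        for stage in self.STAGES:
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        return self.state["summary"]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the summary dict (also written as JSON)."""
    return Pipeline(cfg).run_all()
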