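"""Seeded synthetic dataset generator with planted blocked/non-blocked structure.

The generator emulates the study design the analysis expects: six siRNA
conditions (control, coregulator depletion, two remodeler depletions, two
remodeler+coregulator co-depletions) with two replicate ChIP peak sets each,
negative-binomial occupancy counts over the consensus regions, open-chromatin
peak sets and coverage for four ATAC conditions (± depletion x ± hormone), a
gene annotation with block/ind/mod class labels, and summit-window sequences
with planted GRE/AP-1/ETS motif instances at class-specific prevalence. Every
planted fact is recorded in a ground-truth table keyed by consensus peak id,
so that downstream recovery can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gbrkit import io as gio
from gbrkit.accessibility import CoverageTrack
from gbrkit.intervals import Peak, PeakSet, reproducible_peaks
from gbrkit.motifs import load_pwms, reverse_complement
from gbrkit.occupancy import CountMatrix, build_consensus
from gbrkit.proximity import GeneRecord

CONDITIONS = ("siNS/siNS", "siHic5/siNS", "siCHD9/siNS", "siCHD9/siHic5", "siBRM/siNS", "siBRM/siHic5")
ATAC_CONDITIONS = ("siNS_etoh", "siNS_dex", "siHic5_etoh", "siHic5_dex")


def condition_safe(cond: str) -> str:
    return cond.replace("/", "_")


@dataclass
class SyntheticConfig:
    """Defaults encode the study conditions the analysis is designed for.

    Gene-class sizes, proximity proportions, dependency splits, accessibility
    direction and motif prevalences follow the structure of the real
    experiment; scale parameters (genome size, region count, occupancy level)
    are desk-scale choices documented in the methods note.
    """

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 30_000_000),
        ("chr2", 30_000_000),
        ("chr3", 30_000_000),
        ("chr4", 30_000_000),
    )
    n_genes: dict = field(default_factory=lambda: {"block": 534, "ind": 105, "mod": 364})
    n_gbr: int = 5000
    blocked_fraction: float = 0.55  # blocked probability for background regions
    proximal_rate: float = 2.0  # mean regions planted within 10 kb of each gene
    proximal_blocked_prob: dict = field(default_factory=lambda: {"block": 0.67, "ind": 0.39, "mod": 0.44})
    proximal_span: int = 8000
    peak_width: int = 400
    min_gbr_spacing: int = 3000
    min_gene_spacing: int = 25_000
    shared_blocked_fraction: float = 0.10  # blocked regions also called in control cells
    dropout: float = 0.025  # per-replicate peak-call dropout
    coordinate_jitter: int = 30
    nb_dispersion: float = 0.05
    mu_occupied: float = 300.0
    fold_change_blocked: float = 8.0
    codepletion_fold: float = 0.2
    dependency_probs: dict = field(
        default_factory=lambda: {
            # (both, chd9_only, brm_only, neither)
            "blocked": (0.68, 0.12, 0.04, 0.16),
            "non_blocked": (0.13, 0.22, 0.03, 0.62),
        }
    )
    library_size: int = 20_000_000
    atac_library_size: int = 20_000_000  # fixed ATAC library size for RPM scaling
    # ATAC: probability a region is open in control cells, and the fraction of
    # the class that becomes newly open upon depletion, per treatment
    atac_open_control: dict = field(default_factory=lambda: {"blocked": 0.25, "non_blocked": 0.70})
    atac_newly_open: dict = field(
        default_factory=lambda: {
            "blocked": {"etoh": 0.15, "dex": 0.22},
            "non_blocked": {"etoh": 0.08, "dex": 0.13},
        }
    )
    atac_peak_halfwidth: int = 300
    n_background_atac: int = 2000
    atac_background_width: int = 500
    # coverage amplitude (mean reads per bp at the summit) per label x condition
    atac_amplitude: dict = field(
        default_factory=lambda: {
            "blocked": {"siNS_etoh": 1.0, "siNS_dex": 1.05, "siHic5_etoh": 1.6, "siHic5_dex": 4.0},
            "non_blocked": {"siNS_etoh": 2.5, "siNS_dex": 5.0, "siHic5_etoh": 2.2, "siHic5_dex": 6.0},
        }
    )
    closed_amplitude_factor: float = 0.4
    profile_sigma: float = 300.0
    coverage_bin: int = 10
    coverage_flank: int = 1000
    motif_flank: int = 500
    motif_prevalence: dict = field(
        default_factory=lambda: {
            "GRE": {"blocked": 0.44, "non_blocked": 0.50},
            "ETS": {"blocked": 0.52, "non_blocked": 0.03},
            "AP-1": {"blocked": 0.32, "non_blocked": 0.32},
        }
    )
    motif_offset_sd: dict = field(default_factory=lambda: {"GRE": 60.0, "ETS": 140.0, "AP-1": 220.0})

    def validate(self) -> None:
        if self.fold_change_blocked < 3:
            raise ValueError("fold_change_blocked must be >= 3")
        if self.n_gbr <= 0 or any(v <= 0 for v in self.n_genes.values()):
            raise ValueError("n_gbr and gene counts must be positive")
        total = sum(length for _, length in self.genome)
        if self.n_gbr * self.min_gbr_spacing > 0.8 * total:
            raise ValueError("genome too small for the requested number of regions")
        for d in (self.proximal_blocked_prob, self.atac_open_control):
            if any(not (0.0 <= v <= 1.0) for v in d.values()):
                raise ValueError("probabilities must lie in [0, 1]")
        for probs in self.dependency_probs.values():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("dependency probabilities must sum to 1")


@dataclass
class GroundTruth:
    """Planted facts per consensus region (table keyed by consensus peak_id)."""

    table: pd.DataFrame

    def label_ids(self, label: str) -> set[str]:
        return set(self.table.index[self.table["label"] == label])


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _place_genes(cfg: SyntheticConfig, rng: np.random.Generator) -> list[GeneRecord]:
    chrom_names = [c for c, _ in cfg.genome]
    lengths = np.array([l for _, l in cfg.genome], dtype=float)
    weights = lengths / lengths.sum()
    taken: dict[str, list[int]] = {c: [] for c in chrom_names}
    genes: list[GeneRecord] = []
    for cls in ("block", "ind", "mod"):
        for i in range(cfg.n_genes[cls]):
            for _ in range(1000):
                ci = int(rng.choice(len(chrom_names), p=weights))
                chrom = chrom_names[ci]
                margin = min(2_000_000, cfg.genome[ci][1] // 10)
                pos = int(rng.integers(margin, cfg.genome[ci][1] - margin))
                lst = taken[chrom]
                j = bisect_left(lst, pos)
                if (j > 0 and pos - lst[j - 1] < cfg.min_gene_spacing) or (
                    j < len(lst) and lst[j] - pos < cfg.min_gene_spacing
                ):
                    continue
                insort(lst, pos)
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GeneRecord(f"g_{cls}_{i}", chrom, pos, strand, cls))
                break
            else:
                raise ValueError("genome too small to place genes at the requested spacing")
    return genes


def _place_gbr(cfg: SyntheticConfig, genes: list[GeneRecord], rng: np.random.Generator) -> pd.DataFrame:
    chrom_len = dict(cfg.genome)
    tss_by_chrom = {
        chrom: np.sort(np.array([g.tss for g in genes if g.chrom == chrom], dtype=np.int64))
        for chrom in chrom_len
    }
    rows = []
    for g in genes:
        for _ in range(int(rng.poisson(cfg.proximal_rate))):
            summit = g.tss + int(rng.integers(-cfg.proximal_span, cfg.proximal_span + 1))
            blocked = rng.random() < cfg.proximal_blocked_prob[g.gene_class]
            rows.append((g.chrom, summit, "blocked" if blocked else "non_blocked"))
    n_background = max(cfg.n_gbr - len(rows), 0)
    names = [c for c, _ in cfg.genome]
    lengths = np.array([chrom_len[c] for c in names], dtype=float)
    weights = lengths / lengths.sum()
    # background regions stay out of the innermost TSS window so the planted
    # class-proximal proportions are not diluted at 10 kb; wider windows still
    # accumulate background (the dilution the 1 Mb window is meant to show)
    clear = cfg.proximal_span + 4000
    placed = 0
    while placed < n_background:
        ci = int(rng.choice(len(names), p=weights))
        summit = int(rng.integers(10_000, lengths[ci] - 10_000))
        tss = tss_by_chrom[names[ci]]
        if len(tss):
            j = int(np.searchsorted(tss, summit))
            if (j < len(tss) and abs(int(tss[j]) - summit) < clear) or (
                j > 0 and abs(int(tss[j - 1]) - summit) < clear
            ):
                continue
        blocked = rng.random() < cfg.blocked_fraction
        rows.append((names[ci], summit, "blocked" if blocked else "non_blocked"))
        placed += 1
    df = pd.DataFrame(rows, columns=["chrom", "summit", "label"])
    df["summit"] = df["summit"].clip(10_000, df["chrom"].map(chrom_len) - 10_000)
    df = df.sort_values(["chrom", "summit"], kind="mergesort").reset_index(drop=True)
    # enforce minimum spacing so regions stay atomic through merging
    keep = []
    last: dict[str, int] = {}
    for i, r in df.iterrows():
        if r["chrom"] not in last or r["summit"] - last[r["chrom"]] >= cfg.min_gbr_spacing:
            keep.append(i)
            last[r["chrom"]] = int(r["summit"])
    df = df.loc[keep].reset_index(drop=True)
    half = cfg.peak_width // 2
    df["start"] = df["summit"] - half
    df["end"] = df["start"] + cfg.peak_width
    return df


def generate(cfg: SyntheticConfig, outdir: str | Path) -> tuple[dict, GroundTruth]:
    """Generate the full dataset bundle under ``outdir``; returns (manifest, truth).

    Deterministic given ``cfg.seed``: per-component random streams are spawned
    from the seed so adding a component does not perturb the others.
    """
    cfg.validate()
    outdir = Path(outdir)
    for sub in ("peaks", "reproducible", "atac"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    (rng_genes, rng_gbr, rng_dep, rng_calls, rng_counts, rng_atac, rng_cov, rng_seq) = _spawn(cfg.seed, 8)

    genes = _place_genes(cfg, rng_genes)
    gio.write_genes(genes, outdir / "genes.tsv")

    truth = _place_gbr(cfg, genes, rng_gbr)
    n = len(truth)
    blocked = (truth["label"] == "blocked").to_numpy()

    # remodeler dependency categories and shared-with-control flags
    cats = np.empty(n, dtype=object)
    for lab in ("blocked", "non_blocked"):
        sel = truth["label"] == lab
        cats[sel.to_numpy()] = rng_dep.choice(
            ["both", "chd9_only", "brm_only", "neither"], size=int(sel.sum()), p=cfg.dependency_probs[lab]
        )
    truth["dep_chd9"] = np.isin(cats, ["both", "chd9_only"])
    truth["dep_brm"] = np.isin(cats, ["both", "brm_only"])
    truth["shared"] = blocked & (rng_dep.random(n) < cfg.shared_blocked_fraction)

    present = _presence_matrix(truth)

    # replicate peak calls with dropout and coordinate jitter
    replicate_files: dict[str, list[str]] = {}
    replicate_sets: list[PeakSet] = []
    for cond in CONDITIONS:
        safe = condition_safe(cond)
        paths = []
        reps = []
        for rep in (1, 2):
            called = present[cond] & (rng_calls.random(n) >= cfg.dropout)
            peaks = []
            for i in np.flatnonzero(called):
                j0 = int(rng_calls.integers(-cfg.coordinate_jitter, cfg.coordinate_jitter + 1))
                j1 = int(rng_calls.integers(-cfg.coordinate_jitter, cfg.coordinate_jitter + 1))
                start = int(truth.at[i, "start"]) + j0
                end = int(truth.at[i, "end"]) + j1
                summit = int(truth.at[i, "summit"])
                offset = min(max(summit - start, 0), end - start - 1)
                peaks.append(Peak(truth.at[i, "chrom"], start, end, offset, 100.0, f"{safe}_r{rep}_{i}"))
            ps = PeakSet(f"{safe}_rep{rep}", peaks, {"condition": cond, "replicate": str(rep), "treatment": "dex"})
            reps.append(ps)
            p = outdir / "peaks" / f"{safe}_rep{rep}.narrowPeak"
            gio.write_narrowpeak(ps, p)
            paths.append(str(p))
        replicate_files[cond] = paths
        replicate_sets.extend(reps)
        repro = reproducible_peaks(reps, name=f"idr_{safe}")
        gio.write_narrowpeak(repro, outdir / "reproducible" / f"{safe}.narrowPeak")

    # consensus regions and the mapping back to planted truth
    consensus = build_consensus(replicate_sets, min_samples=2)
    truth_idx = _map_consensus_to_truth(consensus, truth)
    kept = [i is not None for i in truth_idx]
    consensus = PeakSet("consensus", [p for p, k in zip(consensus.peaks, kept) if k])
    truth_idx = [i for i in truth_idx if i is not None]

    counts = _draw_counts(cfg, truth, truth_idx, consensus, rng_counts)
    gio.write_count_matrix(counts, outdir / "counts.tsv", outdir / "samples.tsv")

    truth_out = truth.iloc[truth_idx].copy()
    truth_out.index = pd.Index([p.peak_id for p in consensus], name="peak_id")

    _draw_atac(cfg, truth_out, rng_atac)
    atac_peak_files, atac_cov_files = _emit_atac(cfg, truth_out, consensus, outdir, rng_atac, rng_cov)

    sequences, motif_records = _plant_motifs(cfg, truth_out, rng_seq)
    gio.write_fasta(sequences, outdir / "sequences.fasta")
    truth_out["motifs"] = [
        ";".join(f"{m}:{o:+.1f}{s}" for m, o, s in motif_records.get(pid, [])) for pid in truth_out.index
    ]
    truth_out.to_csv(outdir / "truth.tsv", sep="\t")

    manifest = {
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "genes": str(outdir / "genes.tsv"),
        "replicate_peaks": replicate_files,
        "reproducible": {
            cond: str(outdir / "reproducible" / f"{condition_safe(cond)}.narrowPeak") for cond in CONDITIONS
        },
        "counts": str(outdir / "counts.tsv"),
        "samples": str(outdir / "samples.tsv"),
        "atac_peaks": atac_peak_files,
        "atac_coverage": atac_cov_files,
        "sequences": str(outdir / "sequences.fasta"),
        "truth": str(outdir / "truth.tsv"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest, GroundTruth(table=truth_out)


def _config_dict(cfg: SyntheticConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["genome"] = [list(g) for g in cfg.genome]
    return d


def _presence_matrix(truth: pd.DataFrame) -> dict[str, np.ndarray]:
    blocked = (truth["label"] == "blocked").to_numpy()
    shared = truth["shared"].to_numpy()
    dep_c = truth["dep_chd9"].to_numpy()
    dep_b = truth["dep_brm"].to_numpy()
    in_control = ~blocked | shared
    return {
        "siNS/siNS": in_control,
        "siHic5/siNS": np.ones(len(truth), dtype=bool),
        "siCHD9/siNS": in_control,
        "siBRM/siNS": in_control,
        "siCHD9/siHic5": ~dep_c,
        "siBRM/siHic5": ~dep_b,
    }


def _map_consensus_to_truth(consensus: PeakSet, truth: pd.DataFrame) -> list[int | None]:
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in truth.groupby("chrom"):
        by_chrom[chrom] = (grp["summit"].to_numpy(), grp.index.to_numpy())
    out: list[int | None] = []
    for p in consensus:
        summits, idx = by_chrom.get(p.chrom, (np.empty(0), np.empty(0)))
        j = np.searchsorted(summits, p.start)
        hit = None
        for k in (j, j - 1):
            if 0 <= k < len(summits) and p.start <= summits[k] < p.end:
                hit = int(idx[k])
                break
        out.append(hit)
    return out


def _draw_counts(
    cfg: SyntheticConfig,
    truth: pd.DataFrame,
    truth_idx: list[int],
    consensus: PeakSet,
    rng: np.random.Generator,
) -> CountMatrix:
    n = len(consensus)
    blocked = (truth["label"].iloc[truth_idx] == "blocked").to_numpy()
    mu_low = cfg.mu_occupied / cfg.fold_change_blocked
    mu = np.empty((n, len(CONDITIONS)), dtype=float)
    for j, cond in enumerate(CONDITIONS):
        if cond == "siHic5/siNS":
            # depletion unblocks every region; blocked regions rise from the
            # sub-threshold control level by fold_change_blocked
            base = np.full(n, cfg.mu_occupied)
        elif cond in ("siCHD9/siHic5", "siBRM/siHic5"):
            dep = truth["dep_chd9" if "CHD9" in cond else "dep_brm"].iloc[truth_idx].to_numpy()
            base = np.where(dep, cfg.mu_occupied * cfg.codepletion_fold, cfg.mu_occupied)
        else:
            base = np.where(blocked, mu_low, cfg.mu_occupied)
        mu[:, j] = base
    disp = cfg.nb_dispersion
    samples = []
    data = {}
    for j, cond in enumerate(CONDITIONS):
        for rep in (1, 2):
            name = f"{condition_safe(cond)}_rep{rep}"
            draws = rng.negative_binomial(1.0 / disp, 1.0 / (1.0 + disp * mu[:, j]), size=n)
            data[name] = draws.astype(np.int64)
            samples.append({"sample": name, "condition": cond, "replicate": rep, "library_size": cfg.library_size})
    counts = pd.DataFrame(data, index=pd.Index([p.peak_id for p in consensus], name="peak_id"))
    return CountMatrix(peaks=list(consensus.peaks), samples=pd.DataFrame(samples), counts=counts)


def _draw_atac(cfg: SyntheticConfig, truth_out: pd.DataFrame, rng: np.random.Generator) -> None:
    n = len(truth_out)
    blocked = (truth_out["label"] == "blocked").to_numpy()
    p_open = np.where(blocked, cfg.atac_open_control["blocked"], cfg.atac_open_control["non_blocked"])
    open_ctrl = rng.random(n) < p_open
    truth_out["open_siNS_etoh"] = open_ctrl
    truth_out["open_siNS_dex"] = open_ctrl
    for treat in ("etoh", "dex"):
        frac_new = np.where(
            blocked,
            cfg.atac_newly_open["blocked"][treat],
            cfg.atac_newly_open["non_blocked"][treat],
        )
        p_closed = 1.0 - p_open
        with np.errstate(divide="ignore", invalid="ignore"):
            flip = np.where(p_closed > 0, np.minimum(frac_new / p_closed, 1.0), 0.0)
        newly = ~open_ctrl & (rng.random(n) < flip)
        truth_out[f"open_siHic5_{treat}"] = open_ctrl | newly
        truth_out[f"newly_{treat}"] = newly


def _emit_atac(
    cfg: SyntheticConfig,
    truth_out: pd.DataFrame,
    consensus: PeakSet,
    outdir: Path,
    rng_atac: np.random.Generator,
    rng_cov: np.random.Generator,
) -> tuple[dict[str, str], dict[str, str]]:
    chrom_len = dict(cfg.genome)
    summits_by_chrom: dict[str, np.ndarray] = {
        chrom: np.sort(grp["summit"].to_numpy()) for chrom, grp in truth_out.groupby("chrom")
    }
    # background open regions, kept clear of the planted regions, shared by all conditions
    names = [c for c, _ in cfg.genome]
    lengths = np.array([chrom_len[c] for c in names], dtype=float)
    weights = lengths / lengths.sum()
    background: list[tuple[str, int]] = []
    while len(background) < cfg.n_background_atac:
        ci = int(rng_atac.choice(len(names), p=weights))
        pos = int(rng_atac.integers(10_000, lengths[ci] - 10_000))
        s = summits_by_chrom.get(names[ci])
        if s is not None and len(s):
            j = int(np.searchsorted(s, pos))
            near = (j < len(s) and abs(int(s[j]) - pos) < 3000) or (j > 0 and abs(int(s[j - 1]) - pos) < 3000)
            if near:
                continue
        background.append((names[ci], pos))

    summit = truth_out["summit"].to_numpy()
    chroms = truth_out["chrom"].to_numpy()
    labels = truth_out["label"].to_numpy()
    hw = cfg.atac_peak_halfwidth
    bw = cfg.atac_background_width

    peak_files: dict[str, str] = {}
    cov_files: dict[str, str] = {}
    n_bins = 2 * cfg.coverage_flank // cfg.coverage_bin
    d = np.arange(-cfg.coverage_flank, cfg.coverage_flank, cfg.coverage_bin) + cfg.coverage_bin / 2.0
    shape = np.exp(-0.5 * (d / cfg.profile_sigma) ** 2)
    for cond in ATAC_CONDITIONS:
        open_flag = truth_out[f"open_{cond}"].to_numpy()
        peaks = [
            Peak(chroms[i], int(summit[i]) - hw, int(summit[i]) + hw, hw, 50.0, f"atac_{cond}_{i}")
            for i in np.flatnonzero(open_flag)
        ]
        peaks += [
            Peak(c, pos - bw // 2, pos + bw // 2, bw // 2, 50.0, f"atac_{cond}_bg{k}")
            for k, (c, pos) in enumerate(background)
        ]
        ps = PeakSet(f"atac_{cond}", peaks, {"condition": cond})
        path = outdir / "atac" / f"atac_{cond}.bed"
        gio.write_bed6(ps, path)
        peak_files[cond] = str(path)

        amp = np.array(
            [cfg.atac_amplitude[lab][cond] * (1.0 if op else cfg.closed_amplitude_factor)
             for lab, op in zip(labels, open_flag)]
        )
        lam = amp[:, None] * shape[None, :] * cfg.coverage_bin
        cov = rng_cov.poisson(lam).astype(np.int64)
        # RPM scaling uses a fixed library size: the emitted coverage spans
        # only the analyzed windows, while a real library's reads fall mostly
        # elsewhere in the genome
        total = float(cfg.atac_library_size)
        runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        order = np.argsort(chroms, kind="mergesort")
        for chrom in sorted(set(chroms)):
            sel = order[chroms[order] == chrom]
            starts = (summit[sel, None] - cfg.coverage_flank + np.arange(n_bins)[None, :] * cfg.coverage_bin).ravel()
            vals = cov[sel].ravel()
            keep = vals > 0
            s = starts[keep]
            srt = np.argsort(s, kind="mergesort")
            runs[chrom] = (s[srt], s[srt] + cfg.coverage_bin, vals[keep][srt].astype(float))
        track = CoverageTrack(runs=runs, total_reads=total)
        cpath = outdir / "atac" / f"coverage_{cond}.bedgraph"
        gio.write_bedgraph(track, cpath)
        cov_files[cond] = str(cpath)
    return peak_files, cov_files


def plant_motifs(sequences: dict[str, str], labels: dict[str, str], cfg: SyntheticConfig, rng: np.random.Generator):
    """Plant consensus motif instances into existing windows (in-place semantics).

    For each region, each motif is planted with its label-specific prevalence
    at an offset drawn from a center-concentrated normal (GRE tightest, ETS
    intermediate, AP-1 broadest), on a random strand, avoiding previously
    planted instances. Returns (sequences, records) where records maps peak_id
    to a list of (motif, offset, strand).
    """
    pwms = load_pwms()
    flank = cfg.motif_flank
    W = 2 * flank
    out: dict[str, str] = {}
    records: dict[str, list[tuple[str, float, str]]] = {}
    for pid, seq in sequences.items():
        lab = labels[pid]
        seq_list = list(seq)
        placed: list[tuple[int, int]] = []
        recs: list[tuple[str, float, str]] = []
        for mname in ("GRE", "ETS", "AP-1"):
            prev = cfg.motif_prevalence[mname].get(lab, 0.0)
            if rng.random() >= prev:
                continue
            pwm = pwms[mname]
            L = pwm.length
            inst = pwm.consensus()
            # uniform columns (spacers) are sampled rather than fixed
            uniform = np.isclose(pwm.matrix.max(axis=0), pwm.matrix.min(axis=0))
            inst = "".join(
                "ACGT"[rng.integers(4)] if uniform[i] else b for i, b in enumerate(inst)
            )
            sd = cfg.motif_offset_sd[mname]
            for _ in range(30):
                offset = float(np.clip(rng.normal(0.0, sd), -(flank - L), flank - L))
                start = int(round(offset - (L - 1) / 2.0 + (W - 1) / 2.0))
                start = min(max(start, 0), W - L)
                if any(start < e and start + L > s for s, e in placed):
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                word = inst if strand == "+" else reverse_complement(inst)
                seq_list[start : start + L] = list(word)
                placed.append((start, start + L))
                center = start + (L - 1) / 2.0 - (W - 1) / 2.0
                recs.append((mname, center, strand))
                break
        out[pid] = "".join(seq_list)
        records[pid] = recs
    return out, records


def _plant_motifs(cfg: SyntheticConfig, truth_out: pd.DataFrame, rng: np.random.Generator):
    n = len(truth_out)
    W = 2 * cfg.motif_flank
    mat = rng.integers(0, 4, size=(n, W))
    alphabet = np.array(list("ACGT"))
    sequences = {pid: "".join(alphabet[row]) for pid, row in zip(truth_out.index, mat)}
    labels = dict(zip(truth_out.index, truth_out["label"]))
    return plant_motifs(sequences, labels, cfg, rng)
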