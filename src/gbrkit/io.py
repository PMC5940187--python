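"""Readers and writers for the plain-text genomics formats the pipeline consumes.

Supported: ENCODE narrowPeak (10-column) and broadPeak (9-column), BED6,
bedGraph coverage, FASTA (via Biopython), gene-annotation TSV, count-matrix
TSV with a samples sheet, and the pipeline's own result tables.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from gbrkit.accessibility import CoverageTrack
from gbrkit.intervals import Peak, PeakSet, VennPartition
from gbrkit.occupancy import CountMatrix, DiffResult
from gbrkit.proximity import GeneRecord


def _parse_peak_line(fields: list[str], lineno: int, path, n_cols: int) -> Peak:
    if len(fields) < n_cols:
        raise ValueError(f"{path}:{lineno}: expected {n_cols} columns, got {len(fields)}")
    try:
        start, end = int(fields[1]), int(fields[2])
        signal = float(fields[6]) if len(fields) > 6 else float(fields[4])
        summit = int(fields[9]) if n_cols == 10 else -1
        return Peak(
            chrom=fields[0], start=start, end=end,
            summit_offset=summit, score=max(signal, 0.0), peak_id=fields[3],
        )
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: {exc}") from exc


def _read_peaks(path: str | Path, n_cols: int, name: str | None) -> PeakSet:
    path = Path(path)
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            peaks.append(_parse_peak_line(line.split("\t"), lineno, path, n_cols))
    keys = [(p.chrom, p.start, p.end) for p in peaks]
    if keys != sorted(keys):
        warnings.warn(f"{path}: peaks not coordinate-sorted; sorting on load", stacklevel=2)
    return PeakSet(name or path.stem, peaks)


def read_narrowpeak(path: str | Path, name: str | None = None) -> PeakSet:
    """Read a 10-column ENCODE narrowPeak file (summit offset in column 10)."""
    return _read_peaks(path, 10, name)


def read_broadpeak(path: str | Path, name: str | None = None) -> PeakSet:
    return _read_peaks(path, 9, name)


def read_bed6(path: str | Path, name: str | None = None) -> PeakSet:
    return _read_peaks(path, 6, name)


def write_narrowpeak(ps: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in ps:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t"
                f"{min(int(round(p.score)), 1000)}\t.\t{p.score:.4f}\t-1\t-1\t{p.summit_offset}\n"
            )


def write_bed6(ps: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in ps:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{min(int(round(p.score)), 1000)}\t.\n")


# -- bedGraph coverage -----------------------------------------------------


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write an RLE coverage track; total_reads is kept on the track line."""
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph total_reads={track.total_reads:.0f}\n")
        for chrom in sorted(track.runs):
            starts, ends, values = track.runs[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:g}\n")


def read_bedgraph(path: str | Path, total_reads: float | None = None) -> CoverageTrack:
    """Read a bedGraph file into an RLE coverage track.

    ``total_reads`` falls back to a ``total_reads=`` attribute on the track
    line, then to the sum of all coverage values.
    """
    runs: dict[str, list[tuple[int, int, float]]] = {}
    header_total = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(("track", "browser")):
                for tok in line.split():
                    if tok.startswith("total_reads="):
                        header_total = float(tok.split("=", 1)[1])
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            runs.setdefault(f[0], []).append((int(f[1]), int(f[2]), float(f[3])))
    arrs = {}
    grand = 0.0
    for chrom, rows in runs.items():
        rows.sort()
        s = np.array([r[0] for r in rows], dtype=np.int64)
        e = np.array([r[1] for r in rows], dtype=np.int64)
        v = np.array([r[2] for r in rows], dtype=float)
        arrs[chrom] = (s, e, v)
        grand += float((v * (e - s)).sum())
    total = total_reads if total_reads is not None else (header_total if header_total is not None else grand)
    return CoverageTrack(runs=arrs, total_reads=total)


# -- FASTA -----------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# -- gene annotation -------------------------------------------------------


def read_genes(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "tss", "strand", "gene_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        GeneRecord(
            gene_id=str(r.gene_id), chrom=str(r.chrom), tss=int(r.tss),
            strand=str(r.strand), gene_class=str(r.gene_class),
        )
        for r in df.itertuples()
    ]


def write_genes(genes: Sequence[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "tss": g.tss, "strand": g.strand, "gene_class": g.gene_class}
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


# -- count matrix ----------------------------------------------------------


def write_count_matrix(cm: CountMatrix, counts_path: str | Path, samples_path: str | Path) -> None:
    coords = pd.DataFrame(
        {
            "peak_id": [p.peak_id for p in cm.peaks],
            "chrom": [p.chrom for p in cm.peaks],
            "start": [p.start for p in cm.peaks],
            "end": [p.end for p in cm.peaks],
            "summit_offset": [p.summit_offset for p in cm.peaks],
        }
    ).set_index("peak_id")
    counts = cm.counts.copy()
    counts.index = coords.index
    pd.concat([coords, counts], axis=1).to_csv(counts_path, sep="\t")
    cm.samples.to_csv(samples_path, sep="\t", index=False)


def read_count_matrix(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col="peak_id", dtype={"chrom": str})
    samples = pd.read_csv(samples_path, sep="\t")
    peaks = [
        Peak(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
             summit_offset=int(r.summit_offset), peak_id=str(pid))
        for pid, r in zip(df.index, df.itertuples())
    ]
    counts = df[list(samples["sample"])].astype(np.int64)
    return CountMatrix(peaks=peaks, samples=samples, counts=counts)


# -- result tables ---------------------------------------------------------


def write_diff_result(dr: DiffResult, path: str | Path) -> None:
    out = dr.table.copy()
    for col in ("mean_log2_cpm", "log2_fc"):
        out[col] = out[col].map(lambda x: float(f"{x:.6g}"))
    out.to_csv(path, sep="\t", float_format="%.6g", index_label="peak_id")


def read_diff_result(path: str | Path, contrast: tuple[str, str] = ("", "")) -> DiffResult:
    table = pd.read_csv(path, sep="\t", index_col="peak_id")
    table["significant"] = table["significant"].astype(bool)
    return DiffResult(contrast=contrast, table=table)


def write_venn(vp: VennPartition, json_path: str | Path, tsv_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(vp.to_dict(), indent=2, sort_keys=True) + "\n")
    if tsv_path is not None:
        rows = []
        for sig, ids in vp.compartments.items():
            label = vp.signature_label(sig)
            rows.extend({"region": rid, "signature": label} for rid in ids)
        pd.DataFrame(rows).sort_values("region").to_csv(tsv_path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
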