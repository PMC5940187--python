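import pathlib

import numpy as np
import pandas as pd
import pytest

from gbrkit.intervals import Peak
from gbrkit.occupancy import CountMatrix
from gbrkit.pipeline import Pipeline, PipelineConfig
from gbrkit.simulate import SyntheticConfig, generate


def small_config(seed: int = 11, **overrides) -> SyntheticConfig:
    """A desk-scale generator config used across the unit tests."""
    kwargs = dict(
        seed=seed,
        n_gbr=600,
        genome=(("chr1", 6_000_000), ("chr2", 6_000_000)),
        n_genes={"block": 60, "ind": 15, "mod": 40},
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Generated small dataset plus a completed pipeline run over it."""
    root = tmp_path_factory.mktemp("bundle")
    manifest, truth = generate(small_config(), root / "data")
    pipe = Pipeline(PipelineConfig.from_manifest(root / "data" / "manifest.json", outdir=root / "res"))
    summary = pipe.run_all()
    return {
        "root": root,
        "manifest": manifest,
        "truth": truth,
        "pipeline": pipe,
        "summary": summary,
        "outdir": pathlib.Path(root / "res"),
        "datadir": pathlib.Path(root / "data"),
    }


def make_count_matrix(counts: np.ndarray, conditions, library_sizes=None, peak_ids=None) -> CountMatrix:
    """Assemble a CountMatrix from a (peaks x samples) array and condition labels."""
    counts = np.asarray(counts)
    n, m = counts.shape
    peak_ids = peak_ids or [f"p{i}" for i in range(n)]
    library_sizes = library_sizes if library_sizes is not None else [1_000_000] * m
    reps = {}
    names = []
    for c in conditions:
        reps[c] = reps.get(c, 0) + 1
        names.append(f"{c}_r{reps[c]}")
    samples = pd.DataFrame(
        {
            "sample": names,
            "condition": list(conditions),
            "replicate": [int(n.rsplit("_r", 1)[1]) for n in names],
            "library_size": library_sizes,
        }
    )
    peaks = [Peak("chr1", 1000 * i, 1000 * i + 400, 200, 1.0, pid) for i, pid in enumerate(peak_ids)]
    return CountMatrix(peaks=peaks, samples=samples, counts=pd.DataFrame(counts, index=peak_ids, columns=names))


def random_peaks(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"), span=10_000, max_len=400, prefix="p"):
    """Random possibly-overlapping peaks for oracle comparisons."""
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        peaks.append(Peak(chrom, start, start + length, peak_id=f"{prefix}{i}"))
    return peaks
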