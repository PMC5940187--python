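"""Consensus construction, CPM normalization, and the NB differential test."""

import numpy as np
import pandas as pd
import pytest

from gbrkit.intervals import Peak, PeakSet
from gbrkit.occupancy import build_consensus, ma_classify, mean_log2_cpm, nb_differential, normalize_cpm

from conftest import make_count_matrix, random_peaks


def brute_consensus_regions(sets, min_samples):
    """Oracle: per-base support counting over all sets."""
    support = {}
    for s in sets:
        seen = set()
        for p in s:
            for base in range(p.start, p.end):
                seen.add((p.chrom, base))
        for key in seen:
            support[key] = support.get(key, 0) + 1
    kept = sorted(k for k, v in support.items() if v >= min_samples)
    regions = []
    for chrom, base in kept:
        if regions and regions[-1][0] == chrom and regions[-1][2] == base:
            regions[-1][2] = base + 1
        else:
            regions.append([chrom, base, base + 1])
    return [(c, s, e) for c, s, e in regions]


class TestBuildConsensus:
    def test_region_in_two_of_three_sets_retained(self):
        sets = [
            PeakSet("s1", [Peak("chr1", 100, 500, peak_id="a")]),
            PeakSet("s2", [Peak("chr1", 200, 600, peak_id="b")]),
            PeakSet("s3", [Peak("chr1", 5000, 5400, peak_id="c")]),
        ]
        cons = build_consensus(sets, min_samples=2)
        assert [(p.start, p.end) for p in cons] == [(200, 500)]

    def test_region_in_one_of_six_dropped(self):
        sets = [PeakSet(f"s{i}", []) for i in range(5)]
        sets.append(PeakSet("s5", [Peak("chr1", 100, 500, peak_id="a")]))
        assert len(build_consensus(sets, min_samples=2)) == 0

    def test_min_samples_above_set_count_warns_empty(self):
        sets = [PeakSet("s1", [Peak("chr1", 0, 10)]), PeakSet("s2", [Peak("chr1", 0, 10)])]
        with pytest.warns(UserWarning, match="exceeds"):
            assert len(build_consensus(sets, min_samples=3)) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_support_counting(self, seed):
        rng = np.random.default_rng(seed)
        sets = [
            PeakSet(f"s{k}", random_peaks(rng, int(rng.integers(1, 20)), span=4000, max_len=300, prefix=f"s{k}_"))
            for k in range(int(rng.integers(2, 6)))
        ]
        min_samples = int(rng.integers(1, len(sets) + 1))
        cons = build_consensus(sets, min_samples)
        assert [(p.chrom, p.start, p.end) for p in cons] == brute_consensus_regions(sets, min_samples)

    def test_summit_is_support_weighted_centroid(self):
        # support 2 on [100,200), support 3 on [200,300): centroid at
        # (150*100*2 + 250*100*3) / 500 = 210
        sets = [
            PeakSet("s1", [Peak("chr1", 100, 300, peak_id="a")]),
            PeakSet("s2", [Peak("chr1", 100, 300, peak_id="b")]),
            PeakSet("s3", [Peak("chr1", 200, 300, peak_id="c")]),
        ]
        cons = build_consensus(sets, min_samples=2)
        assert cons.peaks[0].summit() == 210


class TestNormalization:
    def test_cpm_arithmetic(self):
        cm = make_count_matrix([[50, 100]], ["A", "B"], library_sizes=[1_000_000, 2_000_000])
        cpm = normalize_cpm(cm)
        assert cpm.iloc[0, 0] == 50.0 and cpm.iloc[0, 1] == 50.0

    def test_zero_count_row_gives_log2_pseudocount(self):
        cm = make_count_matrix([[0, 0], [10, 10]], ["A", "B"])
        assert mean_log2_cpm(cm).iloc[0] == np.log2(0.5)

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError, match="library"):
            make_count_matrix([[1, 1]], ["A", "B"], library_sizes=[0, 10])

    def test_scaling_one_sample_leaves_cpm_unchanged(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 1000, size=(50, 4))
        cm1 = make_count_matrix(counts, ["A", "A", "B", "B"], library_sizes=[1e6] * 4)
        scaled = counts.copy()
        scaled[:, 2] *= 3
        cm2 = make_count_matrix(scaled, ["A", "A", "B", "B"], library_sizes=[1e6, 1e6, 3e6, 1e6])
        assert np.allclose(normalize_cpm(cm1).to_numpy(), normalize_cpm(cm2).to_numpy())


class TestNbDifferential:
    def test_identical_counts_give_null_result(self):
        counts = np.tile([[120, 120, 120, 120]], (20, 1))
        cm = make_count_matrix(counts, ["A", "A", "B", "B"])
        dr = nb_differential(cm, ("A", "B"))
        assert np.allclose(dr.table["log2_fc"], 0.0)
        assert (dr.table["p_value"] > 0.99).all()

    def test_missing_condition_rejected(self):
        cm = make_count_matrix([[1, 1, 1, 1]], ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="missing"):
            nb_differential(cm, ("A", "C"))

    def test_fold_change_recovery_on_simulated_counts(self):
        # 2000 peaks, 10% with a true 8-fold difference, NB dispersion 0.05
        rng = np.random.default_rng(7)
        n, mu, disp = 2000, 100.0, 0.05
        tp = rng.random(n) < 0.1
        mu_a = np.where(tp, 8 * mu, mu)
        draw = lambda m: rng.negative_binomial(1 / disp, 1 / (1 + disp * m))
        counts = np.column_stack([draw(mu_a), draw(mu_a), draw(np.full(n, mu)), draw(np.full(n, mu))])
        cm = make_count_matrix(counts, ["A", "A", "B", "B"])
        dr = nb_differential(cm, ("A", "B"))
        median_fc = np.median(dr.table["log2_fc"].to_numpy()[tp])
        assert abs(median_fc - 3.0) <= 0.5

    def test_bh_adjusted_values_are_monotone_in_p(self):
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(20, 0.1, size=(300, 4))
        cm = make_count_matrix(counts, ["A", "A", "B", "B"])
        t = nb_differential(cm, ("A", "B")).table.sort_values("p_value")
        assert (np.diff(t["fdr"].to_numpy()) >= -1e-12).all()
        assert (t["fdr"] >= t["p_value"] - 1e-12).all()


class TestMaClassify:
    def _diff(self, fdr, log2_fc):
        from gbrkit.occupancy import DiffResult

        table = pd.DataFrame(
            {"mean_log2_cpm": 5.0, "log2_fc": log2_fc, "p_value": fdr, "fdr": fdr, "significant": False},
            index=[f"p{i}" for i in range(len(fdr))],
        )
        return DiffResult(contrast=("A", "B"), table=table)

    def test_fold_gate(self):
        dr = self._diff([0.005, 0.005], [np.log2(3.2), np.log2(2.5)])
        assert ma_classify(dr, 0.01, 3.0) == {"p0"}

    def test_min_fold_one_disables_gate(self):
        rng = np.random.default_rng(0)
        fdr = rng.random(100)
        dr = self._diff(fdr, rng.normal(0, 0.2, 100))
        assert ma_classify(dr, 0.05, 1.0) == {f"p{i}" for i in np.flatnonzero(fdr <= 0.05)}

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        dr = self._diff(rng.random(200), rng.normal(0, 2, 200))
        loose = ma_classify(dr, 0.01, 1.0)
        strict = ma_classify(dr, 0.01, 3.0)
        assert strict <= loose
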