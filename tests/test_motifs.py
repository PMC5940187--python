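"""PWM scanning, enrichment, positional statistics, and co-occurrence."""

import math

import numpy as np
import pytest

from gbrkit.motifs import (
    Pwm,
    load_pwms,
    motif_cooccurrence,
    motif_enrichment,
    parse_jaspar,
    positional_distribution,
    reverse_complement,
    scan_pwm,
    write_jaspar,
)

ALPHABET = np.array(list("ACGT"))


def sharp_pwm(consensus: str, name: str = "test", p: float = 0.97) -> Pwm:
    mat = np.full((4, len(consensus)), (1 - p) / 3)
    for j, b in enumerate(consensus):
        mat["ACGT".index(b), j] = p
    return Pwm(name=name, matrix=mat)


def random_seq(rng, n):
    return "".join(ALPHABET[rng.integers(0, 4, n)])


def brute_scan(seq: str, pwm: Pwm):
    """Oracle: explicit per-position, per-strand log-odds scoring."""
    thr = pwm.threshold()
    hits = []
    for strand in ("+", "-"):
        mat = pwm.matrix if strand == "+" else pwm.matrix[::-1, ::-1]
        L = mat.shape[1]
        for pos in range(len(seq) - L + 1):
            score = 0.0
            for j, base in enumerate(seq[pos : pos + L]):
                if base not in "ACGT":
                    score = -math.inf
                    break
                score += math.log2(mat["ACGT".index(base), j] / 0.25)
            if score >= thr:
                offset = pos + (L - 1) / 2.0 - (len(seq) - 1) / 2.0
                hits.append((round(offset, 6), strand, round(score, 9)))
    return sorted(hits)


class TestPwm:
    def test_columns_must_sum_to_one(self):
        bad = np.full((4, 6), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            Pwm(name="bad", matrix=bad)

    def test_consensus_and_threshold(self):
        pwm = sharp_pwm("ACGTAC")
        assert pwm.consensus() == "ACGTAC"
        assert pwm.threshold() == pytest.approx(0.8 * pwm.max_score())

    def test_jaspar_roundtrip(self, tmp_path):
        pwms = list(load_pwms().values())
        path = tmp_path / "m.jaspar"
        write_jaspar(pwms, path)
        back = parse_jaspar(path.read_text())
        for a, b in zip(pwms, back):
            assert a.name == b.name
            assert np.allclose(a.matrix, b.matrix, atol=1e-3)

    def test_builtin_models(self):
        pwms = load_pwms()
        assert set(pwms) == {"GRE", "AP-1", "ETS"}
        assert pwms["GRE"].length == 15


class TestScanPwm:
    def test_planted_consensus_found_once(self):
        rng = np.random.default_rng(0)
        pwm = sharp_pwm("ACGTGACGTA")
        seq = list(random_seq(rng, 400))
        seq[137 : 137 + 10] = list("ACGTGACGTA")
        hits = scan_pwm("".join(seq), pwm, flank=200)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) >= 1
        expected = 137 + 4.5 - 199.5
        assert any(h.offset == expected for h in plus)

    def test_all_n_sequence_has_no_hits(self):
        pwm = sharp_pwm("ACGTAC")
        assert scan_pwm("N" * 100, pwm, flank=50) == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            scan_pwm("ACGT", sharp_pwm("ACGTAC"), flank=100)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pwm = sharp_pwm("ACGTAC", p=0.7)  # permissive: plenty of hits
        pwm.score_threshold = 0.5 * pwm.max_score()
        seq = random_seq(rng, 200)
        got = sorted((round(h.offset, 6), h.strand, round(h.score, 9)) for h in scan_pwm(seq, pwm, flank=100))
        assert got == brute_scan(seq, pwm)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(9)
        pwm = sharp_pwm("ACGGTAC", p=0.7)
        pwm.score_threshold = 0.5 * pwm.max_score()
        seq = random_seq(rng, 300)
        fwd = scan_pwm(seq, pwm, flank=150)
        rev = scan_pwm(reverse_complement(seq), pwm, flank=150)
        assert sorted((-h.offset, h.score) for h in rev) == sorted((h.offset, h.score) for h in fwd)


class TestEnrichment:
    def _seqs(self, rng, ids, motif=None, flank=100):
        out = {}
        for pid in ids:
            seq = list(random_seq(rng, 2 * flank))
            if motif:
                pos = int(rng.integers(0, 2 * flank - len(motif)))
                seq[pos : pos + len(motif)] = list(motif)
            out[pid] = "".join(seq)
        return out

    def test_motif_everywhere_gives_p_one(self):
        rng = np.random.default_rng(1)
        pwm = sharp_pwm("ACGTGACGTA")
        fore = self._seqs(rng, [f"f{i}" for i in range(10)], pwm.consensus())
        back = self._seqs(rng, [f"b{i}" for i in range(10)], pwm.consensus())
        r = motif_enrichment(fore, back, pwm, flank=100)
        assert r.p_value == pytest.approx(1.0)
        assert r.prevalence_pct == 100.0

    def test_tiny_sets_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        pwm = sharp_pwm("ACGTGACGTA")
        fore = self._seqs(rng, [f"f{i}" for i in range(5)], pwm.consensus())
        back = self._seqs(rng, [f"b{i}" for i in range(5)])
        r = motif_enrichment(fore, back, pwm, flank=100)
        # enumerate: of C(10, 5) draws from a pool with K carriers, how many
        # put >= k carriers in the foreground
        K = r.n_fore_with + r.n_back_with
        total = math.comb(10, 5)
        favourable = sum(
            math.comb(K, x) * math.comb(10 - K, 5 - x) for x in range(r.n_fore_with, min(K, 5) + 1)
        )
        assert r.p_value == pytest.approx(favourable / total)

    def test_p_monotone_in_foreground_carriers(self):
        from gbrkit.motifs import enrichment_from_presence

        ps = [enrichment_from_presence("m", k, 50, 10, 50).p_value for k in range(10, 40)]
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_overlapping_fore_back_rejected(self):
        rng = np.random.default_rng(3)
        pwm = sharp_pwm("ACGTGACGTA")
        seqs = self._seqs(rng, ["x"])
        with pytest.raises(ValueError, match="disjoint"):
            motif_enrichment(seqs, seqs, pwm, flank=100)


class TestPositionalDistribution:
    def _hits(self, offsets, scores=None, peak_ids=None):
        from gbrkit.motifs import MotifHit

        scores = scores or [1.0] * len(offsets)
        peak_ids = peak_ids or [f"p{i}" for i in range(len(offsets))]
        return [MotifHit(pid, "m", o, "+", s) for pid, o, s in zip(peak_ids, offsets, scores)]

    def test_all_hits_at_center(self):
        _, counts, mean, sd = positional_distribution(self._hits([0.0, 0.0, 0.0]), 50, 500)
        assert mean == 0.0 and sd == 0.0

    def test_symmetric_offsets(self):
        _, _, mean, sd = positional_distribution(self._hits([100.0, -100.0]), 50, 500)
        assert mean == 100.0 and sd == 0.0

    def test_best_hit_per_peak_used_for_summary(self):
        hits = self._hits([10.0, 400.0], scores=[5.0, 1.0], peak_ids=["p0", "p0"])
        _, _, mean, _ = positional_distribution(hits, 50, 500)
        assert mean == 10.0

    def test_matches_direct_arithmetic(self):
        rng = np.random.default_rng(4)
        offsets = rng.uniform(-500, 500, 200)
        _, counts, mean, sd = positional_distribution(self._hits(list(offsets)), 50, 500)
        assert counts.sum() == 200
        assert mean == pytest.approx(np.abs(offsets).mean())
        assert sd == pytest.approx(np.abs(offsets).std())


class TestCooccurrence:
    def test_disjoint_sets_zero_conditionals(self):
        res = motif_cooccurrence({"A": {"1"}, "B": {"2"}, "C": {"3"}}, {"1", "2", "3", "4"})
        assert all(v == 0.0 for v in res["conditional_pct"].values())
        assert res["pct_any"] == 75.0

    def test_subset_conditional_is_hundred(self):
        res = motif_cooccurrence({"AP-1": {"1", "2", "3"}, "ETS": {"2", "3"}}, {"1", "2", "3", "4"})
        assert res["conditional_pct"]["AP-1|ETS"] == 100.0
        assert res["conditional_pct"]["ETS|AP-1"] == pytest.approx(200 / 3)

    def test_union_bound(self):
        rng = np.random.default_rng(6)
        universe = {f"p{i}" for i in range(100)}
        presence = {
            name: {pid for pid in universe if rng.random() < q}
            for name, q in (("A", 0.4), ("B", 0.5), ("C", 0.3))
        }
        res = motif_cooccurrence(presence, universe)
        sum_prev = sum(100.0 * len(s) / 100 for s in presence.values())
        assert res["pct_any"] <= sum_prev + 1e-9

    def test_presence_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            motif_cooccurrence({"A": {"zzz"}}, {"1"})
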