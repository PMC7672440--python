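"""PWM scoring, promoter scanning, distance conventions, pair construction."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import random_pwm, random_seq
from regcouple import synthdata
from regcouple.annotation import PromoterSet
from regcouple.pairs import (
    MotifPWM,
    build_pairs,
    closest_promoter_hits,
    pwm_log_odds_score,
    revcomp,
    scan_promoter,
    scan_promoters,
    scan_sequence,
    signed_offset_distance,
    tfbs_distance,
    tfbs_distance_stats,
)


def one_hot_pwm(motif: str) -> MotifPWM:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    probs = np.zeros((len(motif), 4))
    for i, b in enumerate(motif):
        probs[i, idx[b]] = 1.0
    return MotifPWM(tf_id="tf1", probs=probs)


class TestLogOddsScore:
    def test_one_hot_consensus_hand_value(self):
        pwm = one_hot_pwm("ACGTA")
        score = pwm_log_odds_score(pwm, "ACGTA")
        assert score == pytest.approx(5 * math.log2(1.0001 / 0.25), abs=1e-9)

    def test_uniform_pwm_scores_near_zero(self):
        pwm = MotifPWM(tf_id="u", probs=np.full((4, 4), 0.25))
        assert pwm_log_odds_score(pwm, "ACGT") == pytest.approx(4 * math.log2(1.0004), abs=1e-9)

    def test_score_within_per_column_bounds(self, rng):
        for _ in range(20):
            pwm = random_pwm(rng, int(rng.integers(2, 7)))
            window = random_seq(rng, pwm.length)
            lo, hi = pwm.score_range()
            assert lo - 1e-9 <= pwm_log_odds_score(pwm, window) <= hi + 1e-9

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            pwm_log_odds_score(one_hot_pwm("ACG"), "ANG")


def brute_force_hits(pwm, seq, rel_threshold):
    """Independent oracle: score every forward and reverse window explicitly."""
    smin, smax = pwm.score_range()
    span = smax - smin
    found = set()
    L = pwm.length
    for p in range(len(seq) - L + 1):
        fwd = pwm_log_odds_score(pwm, seq[p : p + L])
        if (fwd - smin) / span >= rel_threshold:
            found.add((p, "+"))
        rev = pwm_log_odds_score(pwm, revcomp(seq[p : p + L]))
        if (rev - smin) / span >= rel_threshold:
            found.add((p, "-"))
    return found


class TestScanner:
    def test_planted_consensus_found_at_relative_score_one(self, rng):
        pwm = one_hot_pwm("ACGTACGT")
        seq = random_seq(rng, 50) + "ACGTACGT" + random_seq(rng, 42)
        hits = scan_sequence(pwm, seq, rel_threshold=1.0)
        fwd = hits[hits.strand == "+"]
        assert 50 in set(fwd.start)
        assert (fwd.rel_score >= 1.0 - 1e-12).all()

    @pytest.mark.parametrize("case", range(200))
    def test_scanner_matches_brute_force_enumeration(self, case):
        rng = np.random.default_rng(5000 + case)
        pwm = random_pwm(rng, int(rng.integers(2, 7)))
        seq = random_seq(rng, int(rng.integers(pwm.length, 31)))
        thr = float(rng.uniform(0.3, 1.0))
        hits = scan_sequence(pwm, seq, rel_threshold=thr)
        got = set(zip(hits.start, hits.strand))
        assert got == brute_force_hits(pwm, seq, thr)

    def test_threshold_one_without_consensus_gives_empty(self):
        pwm = one_hot_pwm("AAAAAA")
        hits = scan_sequence(pwm, "CCCCCCCCCCCC", rel_threshold=1.0)
        assert len(hits) == 0

    def test_relative_score_invariant_to_per_column_shift(self, rng):
        # adding a constant to every entry of a log-odds column rescales the
        # raw score but leaves the relative score (hence the hit set) unchanged
        from regcouple.pairs import _strand_scores

        pwm = random_pwm(rng, 5)
        seq_codes = np.array([0, 1, 2, 3] * 5, dtype=np.uint8)
        lut = pwm.log_odds()
        shifted = lut + rng.normal(size=(5, 1))
        s0 = _strand_scores(lut, seq_codes)
        s1 = _strand_scores(shifted, seq_codes)
        rel0 = (s0 - lut.min(axis=1).sum()) / (lut.max(axis=1).sum() - lut.min(axis=1).sum())
        rel1 = (s1 - shifted.min(axis=1).sum()) / (
            shifted.max(axis=1).sum() - shifted.min(axis=1).sum()
        )
        np.testing.assert_allclose(rel0, rel1, atol=1e-9)

    def test_short_sequence_yields_empty(self):
        assert len(scan_sequence(one_hot_pwm("ACGTACGT"), "ACG")) == 0

    def test_batch_scan_equals_per_sequence_scan(self, rng):
        pwms = [random_pwm(rng, int(rng.integers(3, 6))) for _ in range(3)]
        for k, p in enumerate(pwms):
            p.tf_id = f"tf{k}"
        seqs = {f"g{i}": random_seq(rng, 40) for i in range(5)}
        batch = scan_promoters(pwms, seqs, tss_offset=30, rel_threshold=0.7)
        singles = []
        for p in pwms:
            for g, s in seqs.items():
                h = scan_promoter(p, s, tss_offset=30, rel_threshold=0.7)
                h.insert(0, "gene_id", g)
                h.insert(0, "tf_id", p.tf_id)
                singles.append(h)
        single = (
            pd.concat(singles, ignore_index=True)
            .sort_values(["tf_id", "gene_id", "start", "strand"])
            .reset_index(drop=True)
        )
        batch = batch.sort_values(["tf_id", "gene_id", "start", "strand"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            batch[["tf_id", "gene_id", "start", "end", "strand", "distance"]],
            single[["tf_id", "gene_id", "start", "end", "strand", "distance"]],
        )


class TestDistanceConvention:
    def test_upstream_hit_uses_nearest_boundary(self):
        # hit [TSS-60, TSS-50) on a + strand gene
        assert tfbs_distance(940, 950, 1000, "+") == -50

    def test_hit_covering_tss_is_zero(self):
        assert tfbs_distance(995, 1005, 1000, "+") == 0

    def test_minus_strand_mirrors_plus_strand(self):
        # same geometry upstream of a - strand gene (upstream = higher coords)
        assert tfbs_distance(1051, 1061, 1000, "-") == -50

    def test_downstream_hit_positive(self):
        assert signed_offset_distance(10, 20) == 10


class TestBuildPairs:
    def test_planted_pairs_all_recovered(self, small_dataset):
        ds = small_dataset
        pairs, _ = build_pairs(ds.annotations, ds.promoters, ds.pwms)
        got = set(zip(pairs.tf_id, pairs.tg_id))
        planted = ds.ground_truth.planted_pairs()
        assert planted <= got

    def test_gene_without_utr5_excluded(self, small_dataset):
        ds = small_dataset
        no_utr5 = {a.gene_id for a in ds.annotations if a.max_utr5_len() == 0}
        assert no_utr5, "fixture should contain 5'UTR-less genes"
        pairs, _ = build_pairs(ds.annotations, ds.promoters, ds.pwms)
        assert not (set(pairs.tg_id) | set(pairs.tf_id)) & no_utr5

    def test_missing_pwm_raises(self, small_dataset):
        ds = small_dataset
        with pytest.raises(ValueError, match="TFs with no PWM"):
            build_pairs(ds.annotations, ds.promoters, ds.pwms[1:])

    def test_absent_consensus_at_threshold_one_gives_no_pairs(self, small_dataset):
        ds = small_dataset
        probs = np.zeros((20, 4))
        probs[:, 1] = 1.0  # poly-C motif of length 20: absent from promoters
        pwms = [
            p if p.tf_id != ds.pwms[0].tf_id else MotifPWM(ds.pwms[0].tf_id, probs)
            for p in ds.pwms
        ]
        pairs, _ = build_pairs(ds.annotations, ds.promoters, pwms, rel_threshold=1.0)
        assert ds.pwms[0].tf_id not in set(pairs.tf_id)

    def test_planted_offset_round_trip(self, small_config):
        cfg = small_config.replace(seed=77)
        annotations, promoters = synthdata.generate_genome(cfg)
        pwms = synthdata.generate_pwms(cfg)
        pair = ("TF001", annotations[-1].gene_id)
        promoters = synthdata.plant_motifs(pwms, promoters, {pair: -60})
        pwm = [p for p in pwms if p.tf_id == "TF001"][0]
        hits = scan_promoter(pwm, promoters[pair[1]], promoters.tss_offset)
        assert -60 in set(hits.distance)

    def test_planted_offset_outside_window_raises(self, small_dataset):
        ds = small_dataset
        with pytest.raises(ValueError, match="TF000.*outside promoter"):
            synthdata.plant_motifs(
                ds.pwms, ds.promoters, {("TF000", ds.annotations[-1].gene_id): 2000}
            )


class TestDistanceStats:
    def test_hand_computed_mean_and_sd(self):
        hits = pd.DataFrame(
            {
                "tf_id": ["t", "t"],
                "gene_id": ["g1", "g2"],
                "start": [0, 0],
                "end": [8, 8],
                "strand": "+",
                "rel_score": 1.0,
                "distance": [-100, -300],
            }
        )
        tf_stats, _ = tfbs_distance_stats(hits)
        assert tf_stats.loc["t", "mean"] == pytest.approx(-200)
        assert tf_stats.loc["t", "sd"] == pytest.approx(141.42, abs=0.01)

    def test_single_hit_sd_is_zero(self):
        hits = pd.DataFrame(
            {"tf_id": ["t"], "gene_id": ["g"], "start": [0], "end": [8],
             "strand": "+", "rel_score": 1.0, "distance": [-100]}
        )
        tf_stats, _ = tfbs_distance_stats(hits)
        assert tf_stats.loc["t", "sd"] == 0.0

    def test_out_of_window_hit_excluded(self):
        hits = pd.DataFrame(
            {"tf_id": ["t", "t"], "gene_id": ["g", "g"], "start": [0, 0], "end": [8, 8],
             "strand": "+", "rel_score": 1.0, "distance": [-1200, -100]}
        )
        tf_stats, _ = tfbs_distance_stats(hits)
        assert tf_stats.loc["t", "mean"] == pytest.approx(-100)

    def test_closest_hit_prefers_min_abs_then_upstream(self):
        hits = pd.DataFrame(
            {"tf_id": ["t"] * 3, "gene_id": ["g"] * 3, "start": [0, 0, 0],
             "end": [8, 8, 8], "strand": "+", "rel_score": 1.0,
             "distance": [-300, -50, 50]}
        )
        best = closest_promoter_hits(hits, tss_offset=0, promoter_window=(-500, 500))
        assert best.loc[0, "distance"] == -50


class TestPlantedRecallProperty:
    def test_full_recall_with_low_entropy_in_window(self):
        cfg = synthdata.SimConfig(
            n_tf=5, n_gene=60, n_sample=10, targets_per_tf=8,
            entropy_levels=(0.05, 0.2, 0.3), frac_coupled_pairs=0.5, seed=99,
        )
        ds = synthdata.generate_all(cfg)
        pairs, _ = build_pairs(ds.annotations, ds.promoters, ds.pwms)
        got = set(zip(pairs.tf_id, pairs.tg_id))
        assert ds.ground_truth.planted_pairs() <= got
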