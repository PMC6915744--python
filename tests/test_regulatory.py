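"""PWM scanning, annotation-track overlaps and splice-site scoring."""

import numpy as np
import pandas as pd
import pytest

import _oracles
from conftest import make_window, random_dna
from methsig.preprocess import DMSRecord
from methsig.regulatory import (
    AnnotationTrack,
    PositionFrequencyMatrix,
    count_track_overlaps,
    load_jaspar_pfms,
    pfm_to_pwm,
    restrict_to_regions,
    scan_pwm,
    ss_score,
    find_splice_sites,
    tfbs_count,
)
from methsig.seqcontext import reverse_complement
from methsig.simulate import TF_CONSENSUS, fixture_pfm

JASPAR_TEXT = """\
>MA0001.1 MOTIF_A
A  [ 10  2  0 14  1 ]
C  [  2  1  0  0 12 ]
G  [  1 11 14  0  1 ]
T  [  1  0  0  0  0 ]
>MA0002.1 MOTIF_B
A  [ 1 1 9 1 ]
C  [ 9 1 1 1 ]
G  [ 1 9 1 1 ]
T  [ 1 1 1 9 ]
"""


class TestJasparLoading:
    def test_fixture_round_trip(self, tmp_path):
        p = tmp_path / "motifs.jaspar"
        p.write_text(JASPAR_TEXT)
        pfms = load_jaspar_pfms(p)
        assert [m.motif_id for m in pfms] == ["MA0001.1", "MA0002.1"]
        assert pfms[0].length == 5 and pfms[1].length == 4
        assert pfms[1].consensus == "CGAT"

    def test_labeled_rows_reordered(self, tmp_path):
        scrambled = (
            ">MA0003.1 SCRAMBLED\n"
            "C  [ 9 1 1 1 ]\n"
            "A  [ 1 1 9 1 ]\n"
            "T  [ 1 1 1 9 ]\n"
            "G  [ 1 9 1 1 ]\n"
        )
        p = tmp_path / "s.jaspar"
        p.write_text(scrambled)
        (m,) = load_jaspar_pfms(p)
        assert m.consensus == "CGAT"

    def test_all_zero_column_rejected(self):
        counts = np.ones((4, 5))
        counts[:, 2] = 0
        with pytest.raises(ValueError, match="no positive count"):
            PositionFrequencyMatrix("BAD", "bad", counts)


class TestPfmToPwm:
    def test_equal_counts_uniform_background_is_zero(self):
        pfm = PositionFrequencyMatrix("EQ", "eq", np.full((4, 5), 3.0))
        pwm = pfm_to_pwm(pfm)
        assert np.allclose(pwm.matrix, 0.0)

    def test_single_base_columns_are_column_maxima(self):
        pwm = pfm_to_pwm(fixture_pfm())
        base_idx = {b: i for i, b in enumerate("ACGT")}
        for j, b in enumerate(TF_CONSENSUS):
            assert pwm.matrix[:, j].argmax() == base_idx[b]

    def test_max_score_is_best_kmer_score_exhaustively(self):
        # enumerate all k-mers of a short motif and compare with max_score
        pfm = PositionFrequencyMatrix(
            "X", "x", np.array([[8, 1, 3, 1], [1, 8, 3, 1],
                                [0.5, 0.5, 3, 8], [0.5, 0.5, 3, 1]]))
        pwm = pfm_to_pwm(pfm)
        best = max(
            sum(pwm.matrix["ACGT".index(c), j] for j, c in enumerate(kmer))
            for kmer in map("".join, __import__("itertools").product("ACGT", repeat=4))
        )
        assert pwm.max_score == pytest.approx(best, abs=1e-12)

    def test_background_validation(self):
        pfm = fixture_pfm()
        with pytest.raises(ValueError):
            pfm_to_pwm(pfm, background=[0.5, 0.5, 0.0, 0.0])
        with pytest.raises(ValueError):
            pfm_to_pwm(pfm, background=[0.4, 0.4, 0.4, 0.4])


class TestScanPwm:
    def test_planted_consensus_scores_relative_one(self, fixture_pwm):
        rng = np.random.default_rng(8)
        flanks = random_dna(rng, 40), random_dna(rng, 40)
        seq = flanks[0] + TF_CONSENSUS + flanks[1]
        hits = scan_pwm(seq, fixture_pwm, min_rel_score=0.99)
        assert any(h.start == 40 and h.rel_score == 1.0 and h.strand == "+"
                   for h in hits)

    def test_threshold_one_keeps_only_exact_consensus(self, fixture_pwm):
        seq = "A" * 20 + TF_CONSENSUS + "A" * 20
        hits = scan_pwm(seq, fixture_pwm, min_rel_score=1.0)
        assert [h.start for h in hits if h.strand == "+"] == [20]

    def test_n_placements_skipped(self, fixture_pwm):
        seq = TF_CONSENSUS[:4] + "N" + TF_CONSENSUS[5:]
        assert scan_pwm(seq, fixture_pwm, min_rel_score=0.0) == []

    def test_matches_per_offset_rescoring_oracle(self, fixture_pwm):
        rng = np.random.default_rng(21)
        for _ in range(60):
            seq = random_dna(rng, 60)
            got = sorted((h.start, h.strand, round(h.score, 9))
                         for h in scan_pwm(seq, fixture_pwm, min_rel_score=0.6))
            exp = [(s, st, round(sc, 9)) for s, st, sc in _oracles.pwm_scan_oracle(
                seq, fixture_pwm.matrix, fixture_pwm.min_score,
                fixture_pwm.max_score, 0.6)]
            assert got == exp

    def test_strand_mirroring(self, fixture_pwm):
        rng = np.random.default_rng(31)
        seq = random_dna(rng, 50) + TF_CONSENSUS + random_dna(rng, 50)
        fwd = {(h.start, h.strand) for h in scan_pwm(seq, fixture_pwm, 0.8)}
        rc = {(len(seq) - h.start - fixture_pwm.length,
               "+" if h.strand == "-" else "-")
              for h in scan_pwm(reverse_complement(seq), fixture_pwm, 0.8)}
        assert fwd == rc

    def test_threshold_monotonicity(self, fixture_pwm):
        rng = np.random.default_rng(41)
        seq = random_dna(rng, 80)
        loose = {(h.start, h.strand) for h in scan_pwm(seq, fixture_pwm, 0.5)}
        tight = {(h.start, h.strand) for h in scan_pwm(seq, fixture_pwm, 0.7)}
        assert tight <= loose

    def test_invalid_threshold(self, fixture_pwm):
        with pytest.raises(ValueError):
            scan_pwm("ACGT" * 10, fixture_pwm, min_rel_score=1.5)

    def test_tfbs_count_sums_over_motifs(self, fixture_pwm):
        seq = "T" * 10 + TF_CONSENSUS + "T" * 10
        assert tfbs_count(seq, [fixture_pwm, fixture_pwm], 1.0) == \
            2 * len(scan_pwm(seq, fixture_pwm, 1.0))


def _track(intervals, kind="conserved_tfbs"):
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    df["label"] = "."
    return AnnotationTrack(intervals=df, kind=kind)


class TestTracks:
    def test_empty_track_keeps_nothing(self):
        track = _track([], kind="promoter")
        sites = [DMSRecord("chr1", 150, 151)]
        assert restrict_to_regions(sites, track) == []

    def test_containment(self):
        track = _track([("chr1", 100, 200)], kind="promoter")
        kept = restrict_to_regions(
            [DMSRecord("chr1", 150, 151), DMSRecord("chr1", 250, 251),
             DMSRecord("chr2", 150, 151)], track)
        assert [(s.chrom, s.start) for s in kept] == [("chr1", 150)]

    def test_restrict_requires_region_kind(self):
        track = _track([("chr1", 0, 10)], kind="conserved_tfbs")
        with pytest.raises(ValueError, match="promoter"):
            restrict_to_regions([DMSRecord("chr1", 5, 6)], track)

    def test_count_hand_placed(self):
        w = make_window("A" * 100, origin=1000, chrom="chr1")
        track = _track([("chr1", 990, 1010), ("chr1", 1050, 1060),
                        ("chr1", 2000, 2100), ("chr2", 1000, 1100)])
        assert count_track_overlaps(w, track) == 2

    def test_count_matches_quadratic_oracle(self):
        rng = np.random.default_rng(99)
        intervals = [("chr1", int(s), int(s) + int(l))
                     for s, l in zip(rng.integers(0, 5000, 400),
                                     rng.integers(1, 120, 400))]
        track = _track(intervals)
        for _ in range(50):
            start = int(rng.integers(0, 4900))
            w = make_window("A" * 100, origin=start, chrom="chr1")
            exp = _oracles.overlap_count_oracle(
                start, start + 100, [(s, e) for _, s, e in intervals])
            assert count_track_overlaps(w, track) == exp

    def test_restrict_matches_quadratic_oracle_on_shuffled_input(self):
        rng = np.random.default_rng(13)
        intervals = [("chr1", int(s), int(s) + int(l))
                     for s, l in zip(rng.integers(0, 2000, 100),
                                     rng.integers(5, 50, 100))]
        rng.shuffle(intervals)
        track = _track(intervals, kind="cpg_island")
        sites = [DMSRecord("chr1", int(p), int(p) + 1)
                 for p in rng.integers(0, 2100, 200)]
        kept = {s.start for s in restrict_to_regions(sites, track)}
        exp = {s.start for s in sites
               if any(a <= s.start < b for _, a, b in intervals)}
        assert kept == exp


class TestSpliceSites:
    def test_consensus_and_anticonsensus_bounds(self, donor, acceptor):
        for model in (donor, acceptor):
            assert ss_score(model.consensus, model) == pytest.approx(100.0)
            anti = "".join("ACGT"[j] for j in model.freq.argmin(axis=0))
            assert ss_score(anti, model) == pytest.approx(0.0)

    def test_hand_summed_mixed_kmer(self, donor):
        kmer = "AAGGTAAGT"
        t = sum(donor.freq["ACGT".index(c), j] for j, c in enumerate(kmer))
        t_min = donor.freq.min(axis=0).sum()
        t_max = donor.freq.max(axis=0).sum()
        expected = 100 * (t - t_min) / (t_max - t_min)
        assert ss_score(kmer, donor) == pytest.approx(expected)

    def test_length_mismatch_and_n_rejected(self, donor):
        with pytest.raises(ValueError):
            ss_score("ACGT", donor)
        with pytest.raises(ValueError):
            ss_score("CAGGTNAGT", donor)

    def test_score_always_within_bounds(self, donor, acceptor):
        rng = np.random.default_rng(6)
        for model in (donor, acceptor):
            for _ in range(100):
                s = ss_score(random_dna(rng, model.length), model)
                assert 0.0 <= s <= 100.0

    def test_all_a_window_has_no_hits(self, donor, acceptor):
        found, hits = find_splice_sites("A" * 60, donor, acceptor)
        assert not found and hits == []

    def test_planted_donor_consensus_found(self, donor, acceptor):
        rng = np.random.default_rng(61)
        seq = random_dna(rng, 30) + donor.consensus + random_dna(rng, 30)
        found, hits = find_splice_sites(seq, donor, acceptor, min_score=95)
        assert found
        assert any(h.site_type == "donor" and h.start == 30 and h.strand == "+"
                   for h in hits)

    def test_matches_rescoring_oracle(self, donor, acceptor):
        rng = np.random.default_rng(71)
        for _ in range(30):
            seq = random_dna(rng, 70)
            _, hits = find_splice_sites(seq, donor, acceptor, min_score=70)
            for model in (donor, acceptor):
                got = sorted((h.start, h.strand, round(h.score, 9))
                             for h in hits if h.site_type == model.site_type)
                assert got == _oracles.splice_scan_oracle(seq, model.freq, 70)

    def test_lowering_min_score_never_removes_hits(self, donor, acceptor):
        rng = np.random.default_rng(81)
        seq = random_dna(rng, 80)
        _, tight = find_splice_sites(seq, donor, acceptor, min_score=85)
        _, loose = find_splice_sites(seq, donor, acceptor, min_score=75)
        assert {(h.site_type, h.start, h.strand) for h in tight} <= \
            {(h.site_type, h.start, h.strand) for h in loose}
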