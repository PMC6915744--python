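"""Input loading, beta/M conversions and differential filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bh_oracle
from methsig.preprocess import (
    BetaMatrix,
    BisulfiteCounts,
    DMSRecord,
    beta_from_counts,
    beta_from_intensities,
    beta_to_m,
    bh_fdr,
    differential_filter,
    load_beta_matrix,
    load_dms_bed,
    m_to_beta,
    subsample_dms,
    write_dms_bed,
)


class TestDMSRecord:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DMSRecord("chr1", 10, 10)
        with pytest.raises(ValueError):
            DMSRecord("", 0, 1)
        with pytest.raises(ValueError):
            DMSRecord("chr1", 0, 1, delta_beta=1.5)

    def test_hyper_hypo_orientation(self):
        assert DMSRecord("chr1", 0, 1, delta_beta=0.4).is_hyper
        assert not DMSRecord("chr1", 0, 1, delta_beta=-0.4).is_hyper


class TestBedIO:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "dms.bed"
        p.write_text("chr1\t100\t101\t0.4\nchr1\t200\t201\t-0.35\nchr2\t50\t51\t0.1\n")
        recs = load_dms_bed(p)
        assert [r.delta_beta for r in recs] == [0.4, -0.35, 0.1]
        assert [(r.chrom, r.start, r.end) for r in recs] == [
            ("chr1", 100, 101), ("chr1", 200, 201), ("chr2", 50, 51)]
        out = tmp_path / "out.bed"
        write_dms_bed(recs, out)
        assert [r.delta_beta for r in load_dms_bed(out)] == [0.4, -0.35, 0.1]

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        with pytest.warns(UserWarning, match="no DMS records"):
            assert load_dms_bed(p) == []

    def test_malformed_lines_skipped_with_line_numbers(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text(
            "chr1\t100\t101\t0.4\n"
            "chr1\t300\t200\t0.2\n"      # start >= end
            "chr1\t400\t401\tnotnum\n"   # non-numeric score
            "chr1\t500\t501\t-0.2\n"
        )
        with pytest.warns(UserWarning, match="line 2"):
            recs = load_dms_bed(p)
        assert [(r.start, r.delta_beta) for r in recs] == [(100, 0.4), (500, -0.2)]

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_dms_bed(tmp_path / "nope.bed")

    def test_m_diff_dialect_keeps_raw_score(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text("chr1\t100\t101\t-2.7\n")
        recs = load_dms_bed(p, score_scale="m_diff")
        assert recs[0].score == -2.7 and recs[0].delta_beta is None


class TestConversions:
    @pytest.mark.parametrize(
        "meth,unmeth,expected",
        [(0, 0, 0.0), (900, 0, 0.9), (1000, 1000, 1000 / 2100)],
    )
    def test_beta_from_intensities(self, meth, unmeth, expected):
        assert beta_from_intensities(meth, unmeth) == pytest.approx(expected)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            beta_from_intensities(-1, 0)

    @pytest.mark.parametrize("m,expected", [(0.0, 0.5), (1.0, 2 / 3)])
    def test_m_to_beta_values(self, m, expected):
        assert m_to_beta(m) == pytest.approx(expected, abs=1e-12)

    def test_beta_to_m_undefined_at_bounds(self):
        for b in (0.0, 1.0):
            with pytest.raises(ValueError):
                beta_to_m(b)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=-20, max_value=20, allow_nan=False))
    def test_m_beta_round_trip_and_monotonicity(self, m):
        b = m_to_beta(m)
        assert 0 < b < 1
        assert beta_to_m(b) == pytest.approx(m, abs=1e-9)
        assert m_to_beta(m + 0.5) > b  # strictly increasing

    def test_round_trip_tight_at_moderate_m(self):
        assert beta_to_m(m_to_beta(-2.7)) == pytest.approx(-2.7, abs=1e-12)

    @pytest.mark.parametrize(
        "meth,total,min_depth,expected",
        [(5, 10, 5, 0.5), (3, 4, 5, np.nan), (0, 0, 1, np.nan)],
    )
    def test_beta_from_counts(self, meth, total, min_depth, expected):
        counts = BisulfiteCounts(
            sites=pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1]},
                               index=["s0"]),
            meth_reads=np.array([meth]),
            total_reads=np.array([total]),
        )
        out = beta_from_counts(counts, min_depth=min_depth)
        if np.isnan(expected):
            assert np.isnan(out[0])
        else:
            assert out[0] == pytest.approx(expected)

    def test_counts_invariant(self):
        with pytest.raises(ValueError):
            BisulfiteCounts(sites=pd.DataFrame(), meth_reads=np.array([5]),
                            total_reads=np.array([4]))


class TestBHFDR:
    def test_hand_computed_example(self):
        # 4 p-values 0.01..0.04: step-up gives q = 0.04 everywhere
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_step_up_definition_on_seeded_grid(self):
        rng = np.random.default_rng(42)
        for n in range(1, 13):
            for _ in range(30):
                p = rng.random(n)
                assert np.allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)
            # ties and degenerate vectors
            assert np.allclose(bh_fdr(np.full(n, 0.02)), bh_oracle(np.full(n, 0.02)))
            p = np.round(rng.random(n), 1)
            assert np.allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_monotone_over_sorted_pvalues(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.random(50))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-12).all()


def _matrix_from_arrays(case, ctrl):
    n_sites = case.shape[0]
    ids = [f"s{i}" for i in range(n_sites)]
    vals = pd.DataFrame(
        np.hstack([case, ctrl]), index=ids,
        columns=[f"a{j}" for j in range(case.shape[1])]
        + [f"b{j}" for j in range(ctrl.shape[1])],
    )
    groups = pd.Series(["tumor"] * case.shape[1] + ["normal"] * ctrl.shape[1],
                       index=vals.columns)
    sites = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(n_sites) * 10,
         "end": np.arange(n_sites) * 10 + 1}, index=ids)
    return BetaMatrix(values=vals, groups=groups, sites=sites, case_group="tumor")


class TestDifferentialFilter:
    def test_identical_groups_pass_nothing(self):
        rng = np.random.default_rng(1)
        x = rng.beta(2, 2, size=(20, 10))
        mat = _matrix_from_arrays(x, x.copy())
        assert differential_filter(mat) == []

    def test_planted_site_recovered_among_nulls(self):
        # one site with group means 0.2 vs 0.8 (sd ~0.02) among 99 null sites
        rng = np.random.default_rng(7)
        case = rng.beta(5, 5, size=(100, 10))
        ctrl = rng.beta(5, 5, size=(100, 10))
        case[0] = np.clip(rng.normal(0.8, 0.02, 10), 0, 1)
        ctrl[0] = np.clip(rng.normal(0.2, 0.02, 10), 0, 1)
        mat = _matrix_from_arrays(case, ctrl)
        recs = differential_filter(mat)
        assert [r.site_id for r in recs] == ["s0"]
        assert recs[0].is_hyper and recs[0].delta_beta == pytest.approx(0.6, abs=0.05)

    def test_thresholds_off_returns_every_testable_site(self):
        rng = np.random.default_rng(3)
        mat = _matrix_from_arrays(rng.beta(2, 2, size=(30, 5)),
                                  rng.beta(2, 2, size=(30, 5)))
        recs = differential_filter(mat, min_abs_delta=0, max_p=1.0, max_fdr=1.0)
        assert len(recs) == 30

    def test_small_groups_excluded_with_warning(self):
        rng = np.random.default_rng(5)
        case = rng.beta(2, 2, size=(10, 4))
        ctrl = rng.beta(2, 2, size=(10, 4))
        case[0, :3] = np.nan  # one usable sample left in the case group
        mat = _matrix_from_arrays(case, ctrl)
        with pytest.warns(UserWarning, match="excluded"):
            recs = differential_filter(mat, min_abs_delta=0, max_p=1, max_fdr=1)
        assert len(recs) == 9

    def test_mannwhitney_switch(self):
        rng = np.random.default_rng(9)
        case = rng.beta(8, 2, size=(5, 10))
        ctrl = rng.beta(2, 8, size=(5, 10))
        recs = differential_filter(mat := _matrix_from_arrays(case, ctrl),
                                   test="mannwhitney")
        assert len(recs) == 5
        assert all(r.is_hyper for r in recs)


class TestSubsample:
    def test_no_op_below_limit(self):
        recs = [DMSRecord("chr1", i, i + 1) for i in range(500)]
        assert subsample_dms(recs, n_max=1000, seed=1) == recs

    def test_deterministic_subset_without_duplicates(self):
        recs = [DMSRecord("chr1", i, i + 1, site_id=str(i)) for i in range(2000)]
        a = subsample_dms(recs, n_max=1000, seed=123)
        b = subsample_dms(recs, n_max=1000, seed=123)
        assert a == b and len(a) == 1000
        ids = [r.site_id for r in a]
        assert len(set(ids)) == 1000 and set(ids) <= {r.site_id for r in recs}
        assert subsample_dms(recs, n_max=1000, seed=124) != a


class TestBetaMatrixIO:
    def test_tsv_round_trip_with_coordinate_parsing(self, tmp_path):
        vals = pd.DataFrame(
            {"s1": [0.1, 0.9], "s2": [0.2, 0.8], "s3": [0.15, 0.85],
             "s4": [0.12, 0.88]},
            index=["chr1:100", "chr1:200"],
        )
        vp = tmp_path / "beta.tsv"
        vals.to_csv(vp, sep="\t")
        gp = tmp_path / "groups.tsv"
        gp.write_text("s1\ttumor\ns2\ttumor\ns3\tnormal\ns4\tnormal\n")
        mat = load_beta_matrix(vp, gp)
        assert mat.case_group == "tumor"
        assert mat.sites is not None
        assert mat.sites.loc["chr1:100", "start"] == 100

    def test_two_group_invariant(self):
        vals = pd.DataFrame({"s1": [0.5], "s2": [0.5]}, index=["x"])
        groups = pd.Series({"s1": "a", "s2": "a"})
        with pytest.raises(ValueError, match="two group"):
            BetaMatrix(values=vals, groups=groups)

    def test_beta_range_invariant(self):
        vals = pd.DataFrame({"s1": [1.5], "s2": [0.5]}, index=["x"])
        groups = pd.Series({"s1": "a", "s2": "b"})
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            BetaMatrix(values=vals, groups=groups)
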