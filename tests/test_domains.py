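"""Insulation scores, boundary/TAD calling, sharing and variability."""

import numpy as np
import pandas as pd
import pytest

import hicscape as hs
from hicscape.domains import InsulationTrack


def _uniform_balanced(n=60, bin_size=50_000):
    bins = hs.GenomeBins({"c": n * bin_size}, bin_size)
    cmap = hs.ContactMap.empty(bins)
    cmap.counts["c"] = np.ones((n, n))
    return hs.kr_balance(cmap)


class TestInsulationScore:
    def test_uniform_matrix_scores_near_zero(self):
        track = hs.insulation_score(_uniform_balanced(), window=250_000)
        s = track.score["c"]
        assert np.nanmax(np.abs(s)) < 1e-6

    def test_planted_boundary_is_local_minimum(self):
        spec = hs.make_tad_spec(n_bins=100, n_boundaries=1, tad_factor=3.0)
        bal = hs.kr_balance(hs.expected_rate_map(spec))
        track = hs.insulation_score(bal)
        b = spec.tad_boundaries["chr1"][0]
        s = track.score["chr1"]
        assert s[b] < -0.5
        assert abs(np.nanargmin(s) - b) <= 1  # symmetric tie with b+1

    def test_window_must_divide_and_span(self, small_bins):
        bal = _uniform_balanced()
        with pytest.raises(ValueError, match="multiple"):
            hs.insulation_score(bal, window=75_000)
        with pytest.raises(ValueError, match="2 bins"):
            hs.insulation_score(bal, window=50_000)

    def test_masked_region_stays_missing_without_leakage(self):
        n = 80
        bins = hs.GenomeBins({"c": n * 50_000}, 50_000)
        cmap = hs.ContactMap.empty(bins)
        cmap.counts["c"] = np.ones((n, n))
        cmap.counts["c"][35:45, :] = 0
        cmap.counts["c"][:, 35:45] = 0
        bal = hs.kr_balance(cmap)
        track = hs.insulation_score(bal, window=250_000)
        s = track.score["c"]
        assert np.isnan(s[38:42]).all()          # inside the hole
        assert np.isfinite(s[10:25]).all()       # far away unaffected
        assert np.nanmax(np.abs(s[10:25])) < 0.5

    def test_depth_invariance_on_downsampled_map(self, tad_map_balanced):
        spec, bal = tad_map_balanced
        cmap = hs.simulate_contact_map(spec, seed=31)
        half = hs.downsample(cmap, int(cmap.total()) // 2, seed=1)
        t_full = hs.insulation_score(hs.kr_balance(cmap))
        t_half = hs.insulation_score(hs.kr_balance(half))
        both = np.isfinite(t_full.score["chr1"]) & np.isfinite(t_half.score["chr1"])
        diff = t_full.score["chr1"][both] - t_half.score["chr1"][both]
        assert np.abs(diff).mean() < 0.2


class TestCallBoundaries:
    def test_noiseless_recovery_exact(self):
        spec = hs.make_tad_spec(n_boundaries=9, tad_factor=3.0)
        bal = hs.kr_balance(hs.expected_rate_map(spec))
        track = hs.call_boundaries(hs.insulation_score(bal))
        called = track.boundaries["chr1"]
        planted = spec.tad_boundaries["chr1"]
        assert len(called) == len(planted)
        assert all(np.min(np.abs(planted - b)) <= 1 for b in called)

    def test_infinite_strength_threshold_gives_one_tad(self):
        spec = hs.make_tad_spec(n_boundaries=9)
        bal = hs.kr_balance(hs.expected_rate_map(spec))
        track = hs.call_boundaries(hs.insulation_score(bal),
                                   strength_min=np.inf)
        assert track.boundaries["chr1"].size == 0
        assert len(track.tads["chr1"]) == 1

    def test_close_boundaries_leave_no_sub_minimum_tad(self):
        # hand-built score with two sharp minima 2 bins apart
        n = 40
        score = np.zeros(n)
        score[10] = score[12] = -2.0
        bins = hs.GenomeBins({"c": n * 50_000}, 50_000)
        track = InsulationTrack(bins=bins, score={"c": score}, window=250_000)
        called = hs.call_boundaries(track, delta_window=2, strength_min=0.1)
        for start, end in called.tads["c"]:
            assert end - start >= 3
        covered = set()
        for start, end in called.tads["c"]:
            covered.update(range(start, end))
        assert not covered & set(called.boundaries["c"])  # disjoint

    def test_boundaries_and_tads_partition(self, tad_map_balanced):
        _spec, bal = tad_map_balanced
        track = hs.call_boundaries(hs.insulation_score(bal))
        bd = set(track.boundaries["chr1"])
        tad_bins = set()
        for start, end in track.tads["chr1"]:
            assert not bd & set(range(start, end))
            tad_bins.update(range(start, end))
        assert len(tad_bins) + len(bd) <= 400


class TestAggregation:
    def test_profile_minimum_at_planted_boundaries(self, tad_map_balanced):
        spec, bal = tad_map_balanced
        track = hs.insulation_score(bal)
        prof = hs.aggregate_boundary_profile(
            track, {"chr1": spec.tad_boundaries["chr1"]}, flank=5)
        assert abs(np.nanargmin(prof) - 5) <= 1

    def test_random_positions_are_flat(self, tad_map_balanced, rng):
        _spec, bal = tad_map_balanced
        track = hs.insulation_score(bal)
        rand = {"chr1": rng.integers(20, 380, size=50)}
        prof = hs.aggregate_boundary_profile(track, rand, flank=5)
        assert np.nanmax(np.abs(prof)) < 0.2

    def test_zero_flank_is_mean_boundary_score(self, tad_map_balanced):
        spec, bal = tad_map_balanced
        track = hs.insulation_score(bal)
        bd = {"chr1": spec.tad_boundaries["chr1"]}
        prof = hs.aggregate_boundary_profile(track, bd, flank=0)
        direct = np.nanmean(track.score["chr1"][bd["chr1"]])
        assert prof[0] == pytest.approx(direct)

    def test_matrix_corners_intra_exceeds_inter(self, tad_map_balanced):
        spec, bal = tad_map_balanced
        oe = hs.observed_over_expected(bal)
        _mean, corners = hs.aggregate_boundary_matrix(
            oe, {"chr1": spec.tad_boundaries["chr1"]}, flank=10)
        assert corners["intra_tad"] > corners["inter_tad"]


class TestSharedTads:
    def _frame(self, ivs):
        return pd.DataFrame(ivs, columns=["chrom", "start", "end"])

    def test_identical_sets_all_shared(self):
        a = self._frame([("c", 0, 1000), ("c", 1000, 3000)])
        res = hs.shared_tads(a, a.copy())
        assert res["n_shared"] == 2 and not res["a_specific"]

    def test_seventy_percent_overlap_not_shared(self):
        a = self._frame([("c", 0, 1000)])
        b = self._frame([("c", 300, 1300)])  # reciprocal overlap 0.7
        assert hs.shared_tads(a, b)["n_shared"] == 0
        b2 = self._frame([("c", 200, 1200)])  # 0.8 both ways
        assert hs.shared_tads(a, b2)["n_shared"] == 1

    def test_nested_half_length_not_shared(self):
        a = self._frame([("c", 0, 1000)])
        b = self._frame([("c", 250, 750)])  # covered 100% but covers only 50%
        assert hs.shared_tads(a, b)["n_shared"] == 0

    def test_symmetric(self):
        a = self._frame([("c", 0, 1000), ("c", 2000, 2800)])
        b = self._frame([("c", 50, 1050), ("c", 2100, 2900)])
        assert (hs.shared_tads(a, b)["n_shared"]
                == hs.shared_tads(b, a)["n_shared"])

    def test_one_to_one_matching(self):
        a = self._frame([("c", 0, 1000)])
        b = self._frame([("c", 10, 1010), ("c", 20, 1020)])
        res = hs.shared_tads(a, b)
        assert res["n_shared"] == 1 and len(res["b_specific"]) == 1


class TestBoundaryVariability:
    def _track(self, scores, boundaries, n=100):
        bins = hs.GenomeBins({"c": n * 50_000}, 50_000)
        return InsulationTrack(bins=bins, score={"c": scores},
                               window=500_000,
                               boundaries={"c": np.asarray(boundaries)})

    def test_identical_tracks_zero_sd_tie_break_by_order(self):
        s = np.zeros(100)
        s[[10, 50, 90]] = -1.0
        tr = self._track(s, [10, 50, 90])
        df = hs.boundary_variability([tr, tr, tr], top_k=2)
        assert (df["sd"] == 0).all()
        assert df["bin"].tolist() == [10, 50]  # genome order on ties

    def test_variable_boundaries_dominate_ranking(self, rng):
        base = rng.normal(0, 0.01, size=100)
        s1, s2, s3 = base.copy(), base.copy(), base.copy()
        stable = [20, 40, 60, 80]
        variable = [10, 30, 50, 70, 90]
        for s in (s1, s2, s3):
            s[stable] = -1.0
        s1[variable] = -1.0  # present only in stage 1
        tracks = [self._track(s, stable + variable) for s in (s1, s2, s3)]
        df = hs.boundary_variability(tracks, top_k=5)
        assert set(df["bin"]) == set(variable)

    def test_cluster_recovery_of_planted_patterns(self, rng):
        n = 400
        patterns = {1: (-2, 0, 0), 2: (0, -2, 0), 3: (0, 0, -2), 4: (-2, -2, 0)}
        truth, scores = [], [np.zeros(n), np.zeros(n), np.zeros(n)]
        bns = []
        for k, b in enumerate(range(10, 390, 4)):
            pat = (k % 4) + 1
            truth.append(pat)
            bns.append(b)
            for s, v in zip(scores, patterns[pat]):
                s[b] = v + rng.normal(0, 0.05)
        tracks = [self._track(s, bns, n=n) for s in scores]
        df = hs.boundary_variability(tracks, top_k=len(bns), n_clusters=4)
        got = df.set_index("bin").loc[bns, "cluster"].to_numpy()
        from scipy.special import comb

        def rand_index(x, y):
            same_x = np.equal.outer(x, x)
            same_y = np.equal.outer(y, y)
            iu = np.triu_indices(len(x), k=1)
            agree = (same_x[iu] == same_y[iu]).sum()
            return agree / comb(len(x), 2)

        assert rand_index(np.array(truth), got) >= 0.8

    def test_requires_two_stages(self):
        tr = self._track(np.zeros(100), [10])
        with pytest.raises(ValueError, match="two stages"):
            hs.boundary_variability([tr])
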