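"""Compartment calling, strength, saddle, switches and overlaps."""

import numpy as np
import pandas as pd
import pytest

import hicscape as hs
from hicscape.compartments import MASKED


def _density_for(spec, a_mean=2.0, b_mean=0.5):
    return {c: np.where(lab == "A", a_mean, b_mean)
            for c, lab in spec.compartment_labels.items()}


def _uniform_oe(n=120, bin_size=100_000):
    bins = hs.GenomeBins({"c": n * bin_size}, bin_size)
    return hs.OEMatrix(bins=bins, values={"c": np.ones((n, n))})


class TestCallCompartments:
    def test_noiseless_checkerboard_recovered(self, checkerboard_oe):
        spec, oe = checkerboard_oe
        prof = hs.call_compartments(oe, _density_for(spec))
        agree = np.mean(prof.label["chr1"] == spec.compartment_labels["chr1"])
        assert agree >= 0.99

    def test_orientation_follows_gene_density(self, checkerboard_oe):
        spec, oe = checkerboard_oe
        straight = hs.call_compartments(oe, _density_for(spec))
        flipped = hs.call_compartments(oe, _density_for(spec, 0.5, 2.0))
        a, b = straight.label["chr1"], flipped.label["chr1"]
        swap = {"A": "B", "B": "A", MASKED: MASKED}
        assert all(b[i] == swap[a[i]] for i in range(len(a)))

    def test_structureless_map_has_small_e1(self):
        spec = hs.make_checkerboard_spec(n_bins=200, contrast=0.0, depth=1e6)
        cmap = hs.simulate_contact_map(spec, seed=3)
        oe = hs.observed_over_expected(hs.kr_balance(cmap))
        prof = hs.call_compartments(oe, _density_for(spec))
        frac_a = np.mean(prof.label["chr1"] == "A")
        assert 0.2 < frac_a < 0.8  # no stable majority class

    def test_tiny_chromosome_fully_masked(self, small_bins):
        oe = hs.OEMatrix(bins=small_bins,
                         values={c: np.ones((small_bins.n_bins(c),) * 2)
                                 for c in small_bins.chroms})
        dens = {c: np.zeros(small_bins.n_bins(c)) for c in small_bins.chroms}
        prof = hs.call_compartments(oe, dens, min_bins=100)
        assert (prof.label["chr1"] == MASKED).all()


class TestStrength:
    def test_uniform_matrix_scores_half(self):
        oe = _uniform_oe()
        labels = np.array(["A", "B"] * 60)
        prof = hs.CompartmentProfile(bins=oe.bins, e1={"c": np.ones(120)},
                                     label={"c": labels})
        assert hs.compartment_strength(oe, prof, "c") == pytest.approx(0.5)

    def test_monotone_in_contrast_noiseless(self):
        scores = []
        for c in (0.1, 0.3, 0.6):
            spec = hs.make_checkerboard_spec(n_bins=200, contrast=c)
            oe = hs.observed_over_expected(
                hs.kr_balance(hs.expected_rate_map(spec)))
            prof = hs.call_compartments(oe, _density_for(spec))
            scores.append(hs.compartment_strength(oe, prof, "chr1"))
        assert scores[0] > scores[1] > scores[2]

    def test_true_labels_minimize_score(self, checkerboard_oe, rng):
        spec, oe = checkerboard_oe
        labels = spec.compartment_labels["chr1"]
        prof = hs.CompartmentProfile(bins=oe.bins,
                                     e1={"chr1": np.ones(labels.size)},
                                     label={"chr1": labels})
        true_score = hs.compartment_strength(oe, prof, "chr1")
        for _ in range(5):
            perm = hs.CompartmentProfile(
                bins=oe.bins, e1=prof.e1,
                label={"chr1": rng.permutation(labels)})
            assert hs.compartment_strength(oe, perm, "chr1") >= true_score

    def test_absent_class_flagged(self):
        oe = _uniform_oe()
        prof = hs.CompartmentProfile(bins=oe.bins, e1={"c": np.ones(120)},
                                     label={"c": np.array(["A"] * 120)})
        with pytest.warns(UserWarning, match="absent"):
            assert np.isnan(hs.compartment_strength(oe, prof, "c"))


class TestSaddle:
    def test_uniform_oe_gives_flat_saddle(self):
        oe = _uniform_oe()
        prof = hs.CompartmentProfile(
            bins=oe.bins, e1={"c": np.linspace(-1, 1, 120)},
            label={"c": np.where(np.linspace(-1, 1, 120) > 0, "A", "B")})
        sad = hs.saddle(oe, prof, ngroups=10)
        assert np.allclose(sad.values, 1.0)

    def test_corners_separate_with_contrast(self, checkerboard_oe):
        spec, oe = checkerboard_oe
        prof = hs.call_compartments(oe, _density_for(spec))
        sad = hs.saddle(oe, prof, ngroups=50)
        c = sad.corner_summaries
        assert c["AA"] * c["BB"] > c["AB"] ** 2

    def test_saddle_mean_near_oe_mean(self, checkerboard_oe):
        spec, oe = checkerboard_oe
        prof = hs.call_compartments(oe, _density_for(spec))
        sad = hs.saddle(oe, prof, ngroups=20)
        assert np.nanmean(sad.values) == pytest.approx(1.0, abs=0.15)

    def test_requires_enough_bins(self, checkerboard_oe):
        spec, oe = checkerboard_oe
        prof = hs.call_compartments(oe, _density_for(spec))
        with pytest.raises(ValueError, match="fewer"):
            hs.saddle(oe, prof, ngroups=10_000)


class TestSwitches:
    def test_identical_profiles_never_switch(self, checkerboard_oe):
        spec, oe = checkerboard_oe
        prof = hs.call_compartments(oe, _density_for(spec))
        sw = hs.compartment_switches(prof, prof)
        assert hs.switch_fractions(sw)["switched"] == 0.0

    def test_planted_block_flips_recovered(self):
        base = hs.make_checkerboard_spec(n_bins=400, contrast=0.6)
        flipped_bins = list(range(100, 120)) + list(range(300, 320))
        edited = hs.StageEdit(label_flips={"chr1": flipped_bins}).apply(base)
        dens = _density_for(base)
        profs = []
        for spec in (base, edited):
            oe = hs.observed_over_expected(
                hs.kr_balance(hs.expected_rate_map(spec)))
            profs.append(hs.call_compartments(oe, dens))
        sw = hs.compartment_switches(profs[0], profs[1])["chr1"]
        hit = np.isin(sw[flipped_bins], ("A2B", "B2A")).mean()
        assert hit >= 0.9
        other = np.ones(400, dtype=bool)
        other[flipped_bins] = False
        assert np.isin(sw[other], ("A2A", "B2B")).mean() >= 0.95

    def test_categories_partition_unmasked(self, checkerboard_oe):
        spec, oe = checkerboard_oe
        prof = hs.call_compartments(oe, _density_for(spec))
        sw = hs.compartment_switches(prof, prof)
        fr = hs.switch_fractions(sw)
        assert fr["A2A"] + fr["B2B"] + fr["A2B"] + fr["B2A"] == pytest.approx(1.0)

    def test_mismatched_bins_rejected(self, checkerboard_oe, small_bins):
        spec, oe = checkerboard_oe
        prof = hs.call_compartments(oe, _density_for(spec))
        other = hs.CompartmentProfile(
            bins=small_bins,
            e1={c: np.zeros(small_bins.n_bins(c)) for c in small_bins.chroms},
            label={c: np.full(small_bins.n_bins(c), "A") for c in small_bins.chroms})
        with pytest.raises(ValueError, match="binning"):
            hs.compartment_switches(prof, other)


class TestSwitchExpression:
    def _setup(self, rng, b2a_mult=2.0, n_genes=200):
        bins = hs.GenomeBins({"c": 40_000_000}, 100_000)
        n = 400
        half = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        sw = {"c": np.where(np.arange(n) % 4 == 0,
                            np.where(half == "A", "A2B", "B2A"),
                            np.char.add(np.char.add(half, "2"), half))}
        pos = rng.integers(0, 40_000_000, size=n_genes)
        tss = pd.DataFrame({"chrom": "c", "start": pos, "end": pos + 1,
                            "name": [f"g{i}" for i in range(n_genes)]})
        cat = sw["c"][pos // 100_000]
        lfc = rng.normal(0, 0.5, size=n_genes)
        lfc[cat == "B2A"] += np.log2(b2a_mult)
        lfc[cat == "A2B"] -= np.log2(b2a_mult)
        delta = pd.Series(lfc, index=tss["name"])
        return sw, delta, tss, bins

    def test_planted_upregulation_detected(self, rng):
        sw, delta, tss, bins = self._setup(rng, b2a_mult=2.0)
        res = hs.switch_expression_association(sw, delta, tss, bins)
        assert res["medians"]["B2A"] > res["medians"]["A2B"]
        assert res["b2a_vs_a2b_p"] < 0.05

    def test_null_effect_not_significant(self, rng):
        sw, delta, tss, bins = self._setup(rng, b2a_mult=1.0)
        res = hs.switch_expression_association(sw, delta, tss, bins)
        assert res["b2a_vs_a2b_p"] > 0.05

    def test_empty_category_no_crash(self, rng):
        sw, delta, tss, bins = self._setup(rng)
        sw = {"c": np.where(sw["c"] == "B2A", "B2B", sw["c"])}
        res = hs.switch_expression_association(sw, delta, tss, bins)
        assert res["distributions"]["B2A"].size == 0
        assert np.isnan(res["b2a_vs_a2b_p"])

    def test_unmappable_genes_counted(self, rng):
        sw, delta, tss, bins = self._setup(rng)
        delta["ghost"] = 1.0
        res = hs.switch_expression_association(sw, delta, tss, bins)
        assert res["dropped_genes"] == 1


class TestPeakOverlap:
    def _profile(self):
        bins = hs.GenomeBins({"c": 1_000_000}, 100_000)
        labels = np.array(["A", "B"] * 5)
        return hs.CompartmentProfile(bins=bins, e1={"c": np.ones(10)},
                                     label={"c": labels})

    def test_peak_inside_one_label(self):
        prof = self._profile()
        peaks = pd.DataFrame({"chrom": ["c"], "start": [10_000], "end": [20_000]})
        counts = hs.peak_compartment_overlap(peaks, prof)
        assert counts == {"A": 1, "B": 0}

    def test_straddling_peak_counts_both(self):
        prof = self._profile()
        peaks = pd.DataFrame({"chrom": ["c"], "start": [95_000], "end": [105_000]})
        assert hs.peak_compartment_overlap(peaks, prof) == {"A": 1, "B": 1}

    def test_touching_boundary_is_not_overlap(self):
        prof = self._profile()
        peaks = pd.DataFrame({"chrom": ["c"], "start": [100_000], "end": [110_000]})
        assert hs.peak_compartment_overlap(peaks, prof) == {"A": 0, "B": 1}

    def test_planted_density_ratio_recovered(self, rng):
        prof = self._profile()
        a_starts = rng.integers(0, 5, size=400) * 200_000 + rng.integers(0, 90_000, 400)
        b_starts = a_starts[:100] + 100_000
        peaks = pd.DataFrame({
            "chrom": "c",
            "start": np.concatenate([a_starts, b_starts]),
            "end": np.concatenate([a_starts, b_starts]) + 1_000})
        counts = hs.peak_compartment_overlap(peaks, prof)
        assert counts["A"] / counts["B"] == pytest.approx(4.0, rel=0.1)

    def test_unknown_chromosome_dropped_with_warning(self):
        prof = self._profile()
        peaks = pd.DataFrame({"chrom": ["c", "chrX"], "start": [0, 0],
                              "end": [1000, 1000]})
        with pytest.warns(UserWarning, match="unknown"):
            counts = hs.peak_compartment_overlap(peaks, prof)
        assert counts["A"] == 1
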