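"""CPT normalization, entry proportions, aggregate profiles, and the exact
paired signed-rank test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cenlandscape as cl
from cenlandscape.classify import ClassLabel, ClassifiedTranscript
from cenlandscape.quantify import (QuantifyError, aggregate_profile,
                                   compute_cpt, count_table,
                                   entry_proportions, fold_change,
                                   median_entry_proportion,
                                   orientation_preference,
                                   paired_signed_rank,
                                   pooled_entry_proportion, replicate_mean)


def _fake(cen, side, label, read, read_id="x"):
    return ClassifiedTranscript(read_id, cen, label, side,
                                1 if label in cl.ENTERING_SET else 0,
                                0 if side else None, read)


class TestCpt:
    def test_arithmetic(self):
        assert compute_cpt(76, 1000) == 76.0
        assert compute_cpt(0, 123) == 0.0

    def test_zero_library_rejected(self):
        with pytest.raises(QuantifyError):
            compute_cpt(3, 0)

    def test_scale_invariance(self):
        assert compute_cpt(10, 500) == compute_cpt(20, 1000)

    def test_replicate_mean_of_identical_replicates(self):
        assert replicate_mean([7.5, 7.5]) == 7.5


class TestEntryProportions:
    def test_sixty_percent_cell(self, make_read):
        r = make_read(0, 10)
        cls = [_fake("CEN1", "CDEI", ClassLabel.CEN_ENTERING, r, f"e{i}")
               for i in range(60)]
        cls += [_fake("CEN1", "CDEI", ClassLabel.CONVERGING_PERICEN, r,
                      f"p{i}") for i in range(40)]
        tab = entry_proportions(cls)
        assert tab.loc[0, "proportion"] == pytest.approx(0.60)
        assert tab.loc[0, "n_pericen_total"] == 100

    def test_spanning_counts_in_both_numerator_and_denominator(self,
                                                               make_read):
        r = make_read(0, 10)
        cls = [_fake("CEN1", "CDEI", ClassLabel.CEN_SPANNING, r, "s"),
               _fake("CEN1", "CDEI", ClassLabel.CONVERGING_PERICEN, r, "p")]
        tab = entry_proportions(cls)
        assert tab.loc[0, "n_entering"] == 1
        assert tab.loc[0, "n_pericen_total"] == 2

    def test_median_of_constant_cells(self, make_read):
        r = make_read(0, 10)
        cls = []
        for cen in ("CEN1", "CEN2"):
            for side in ("CDEI", "CDEIII"):
                cls.append(_fake(cen, side, ClassLabel.CEN_ENTERING, r,
                                 f"{cen}{side}e"))
                cls.append(_fake(cen, side, ClassLabel.CONVERGING_PERICEN, r,
                                 f"{cen}{side}p"))
        tab = entry_proportions(cls)
        assert median_entry_proportion(tab) == pytest.approx(0.5)

    def test_empty_cells_flagged_and_excluded_from_median(self, make_cen,
                                                          make_read):
        r = make_read(0, 10)
        cls = [_fake("CEN1", "CDEI", ClassLabel.CEN_ENTERING, r)]
        tab = entry_proportions(cls, cens=[make_cen(cen_id="CEN1"),
                                           make_cen(cen_id="CEN2",
                                                    chrom="chrU")])
        assert len(tab) == 4
        assert tab["proportion"].isna().sum() == 3
        assert median_entry_proportion(tab) == 1.0

    def test_pooled_equals_weighted_mean_of_cells(self, small_genome):
        import dataclasses

        cfg = dataclasses.replace(small_genome.config, p_enter=0.3, seed=23)
        reads = cl.simulate_library(cfg, small_genome, n_per_cell=300)
        out = cl.classify_library(reads, small_genome.centromeres)
        tab = entry_proportions(out, small_genome.centromeres)
        pooled = pooled_entry_proportion(tab)
        nonzero = tab[tab["n_pericen_total"] > 0]
        weighted = (nonzero["proportion"] * nonzero["n_pericen_total"]).sum() \
            / nonzero["n_pericen_total"].sum()
        assert pooled == pytest.approx(weighted)


class TestAggregateProfile:
    def _uniform_cls(self, cens, depth, lo, hi, make_read):
        out = []
        for c in cens:
            b = c.span.start
            for i in range(depth):
                r = make_read(b + lo, b + hi, "+", chrom=c.chrom,
                              read_id=f"{c.cen_id}_{i}")
                out.append(ClassifiedTranscript(
                    r.read_id, c.cen_id, ClassLabel.CONVERGING_PERICEN,
                    c.border_side("left"), 0, 0, r))
        return out

    def test_constant_tracks_give_constant_median(self, make_cen, make_read):
        cens = [make_cen(chrom=f"c{i}", cen_id=f"CEN{i}", start=1000)
                for i in range(16)]
        cls = self._uniform_cls(cens, 5, -100, 60, make_read)
        prof = aggregate_profile(cls, cens, anchor="CDEI_start", flank=50)
        assert np.all(prof.values == 5)

    def test_even_count_median_averages_middle_pair(self, make_cen,
                                                    make_read):
        cens = [make_cen(chrom=f"c{i}", cen_id=f"CEN{i}", start=1000)
                for i in range(16)]
        cls = self._uniform_cls(cens[:8], 10, -100, 60, make_read)
        prof = aggregate_profile(cls, cens, anchor="CDEI_start", flank=50)
        assert np.all(prof.values == 5)  # 8 tracks of 10, 8 of 0

    def test_minus_orientation_track_is_mirror_of_plus(self, make_cen,
                                                       make_read):
        plus = make_cen(chrom="cp", cen_id="P", start=1000, orientation="+")
        minus = make_cen(chrom="cm", cen_id="M", start=1000, orientation="-")
        flank = 60
        # same geometry relative to the approached CDEI border on each
        rp = make_read(1000 - 40, 1000 + 10, "+", chrom="cp", read_id="rp")
        rm = make_read(1117 - 10, 1117 + 40, "-", chrom="cm", read_id="rm")
        cls = [
            ClassifiedTranscript("rp", "P", ClassLabel.CEN_ENTERING, "CDEI",
                                 10, 10, rp),
            ClassifiedTranscript("rm", "M", ClassLabel.CEN_ENTERING, "CDEI",
                                 10, 10, rm),
        ]
        prof = aggregate_profile(cls, [plus, minus], anchor="CDEI_start",
                                 flank=flank)
        assert np.array_equal(prof.per_centromere["P"],
                              prof.per_centromere["M"])

    def test_track_sum_conserves_aligned_bases(self, small_cfg,
                                               small_genome):
        reads = cl.simulate_library(small_cfg, small_genome, n_per_cell=40)
        out = cl.classify_library(reads, small_genome.centromeres)
        flank = 400
        prof = aggregate_profile(out, small_genome.centromeres,
                                 anchor="CDEI_start", flank=flank)
        for c in small_genome.centromeres:
            side = "CDEI"
            b0 = c.outer_edge(side)
            direction = 1 if b0 == c.span.start else -1
            expected = 0
            for x in out:
                if x.entry_side != side or x.centromere_id != c.cen_id or \
                        x.termination_offset is None:
                    continue
                for s, e in x.alignment.blocks:
                    for g in range(s, e):
                        pos = (g - b0) * direction
                        if -flank <= pos <= flank:
                            expected += 1
            assert prof.per_centromere[c.cen_id].sum() == expected


class TestOrientation:
    def test_fractions(self, make_read):
        r = make_read(0, 10)
        cls = [_fake("CEN1", "CDEIII", ClassLabel.CEN_ENTERING, r, f"a{i}")
               for i in range(9)]
        cls += [_fake("CEN1", "CDEI", ClassLabel.CEN_ENTERING, r, "b")]
        tab = orientation_preference(cls)
        assert tab.loc[0, "frac_cdeI"] == pytest.approx(0.1)
        assert tab.loc[0, "frac_cdeIII"] == pytest.approx(0.9)

    def test_all_one_side(self, make_read):
        r = make_read(0, 10)
        cls = [_fake("CEN1", "CDEI", ClassLabel.CEN_ENTERING, r, f"{i}")
               for i in range(4)]
        tab = orientation_preference(cls)
        assert (tab.loc[0, "frac_cdeI"], tab.loc[0, "frac_cdeIII"]) == (1, 0)

    def test_zero_entering_flagged_missing(self, make_cen):
        tab = orientation_preference([], cens=[make_cen(cen_id="CEN9")])
        assert np.isnan(tab.loc[0, "frac_cdeI"])

    def test_symmetric_simulator_is_balanced(self, small_genome):
        import dataclasses

        cfg = dataclasses.replace(small_genome.config, p_enter=0.5, seed=31)
        reads = cl.simulate_library(cfg, small_genome, n_per_cell=1500)
        out = cl.classify_library(reads, small_genome.centromeres)
        tab = orientation_preference(out, small_genome.centromeres)
        for _, row in tab.iterrows():
            n = row["n_entering"]
            se = math.sqrt(0.25 / n)
            assert abs(row["frac_cdeIII"] - 0.5) < 3 * se


class TestFoldChange:
    def test_ratio_and_identity(self):
        assert fold_change(46.0, 1.0) == 46.0
        assert fold_change(3.3, 3.3) == 1.0

    def test_zero_denominator_flagged_infinite(self):
        with pytest.warns(UserWarning):
            assert math.isinf(fold_change(5.0, 0.0))


def oracle_signed_rank(x, y):
    """Full 2^n sign enumeration of the signed-rank null (test oracle)."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=n)]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestPairedSignedRank:
    def test_identical_vectors(self):
        with pytest.warns(UserWarning):
            assert paired_signed_rank([1, 2, 3], [1, 2, 3]) == 1.0

    def test_five_uniform_positive_shifts(self):
        p = paired_signed_rank([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
        assert p == pytest.approx(0.0625)

    def test_32_uniform_shifts_reach_below_1e4(self):
        x = np.arange(32) + 1.0
        p = paired_signed_rank(x + 0.5, x)
        assert p == pytest.approx(2.0 * 2.0 ** -32, rel=1e-9)
        assert p < 1e-4

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_full_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        x = rng.normal(size=n)
        y = x + rng.normal(scale=0.8, size=n)
        # occasionally force ties in |d|
        if seed % 2:
            y[1] = x[1] - (y[0] - x[0])
        assert paired_signed_rank(x, y) == \
            pytest.approx(oracle_signed_rank(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_exact_without_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        expected = stats.wilcoxon(x, y, mode="exact",
                                  alternative="two-sided").pvalue
        assert paired_signed_rank(x, y) == pytest.approx(expected, rel=1e-10)

    def test_normal_approximation_for_large_n(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        y = x + rng.normal(scale=1.0, size=200) + 0.1
        p_approx = paired_signed_rank(x, y, method="approx")
        expected = stats.wilcoxon(x, y, mode="approx", correction=True,
                                  alternative="two-sided").pvalue
        assert p_approx == pytest.approx(expected, rel=1e-6)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(QuantifyError):
            paired_signed_rank([1, 2], [1, 2, 3])


class TestCountTable:
    def test_counts_and_cpt(self, make_read):
        r = make_read(0, 10)
        cls = [_fake("CEN1", "CDEI", ClassLabel.CEN_ENTERING, r, f"{i}")
               for i in range(10)]
        tab = count_table(cls, "libA", library_size=1000)
        row = tab.iloc[0]
        assert row["count"] == 10 and row["cpt"] == 10.0
        assert row["library"] == "libA"
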