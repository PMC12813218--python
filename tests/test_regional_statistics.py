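"""Median normalization, the mixed RM-ANOVA and the Δavg.PSC convention."""

import numpy as np
import pytest

from plf.digest_mapping import RegionMatrix
from plf.regional_statistics import (AllTotalsZero, bonferroni, delta_avg_psc,
                                     median_normalize,
                                     mixed_anova_decomposition,
                                     pooled_contrast_error, region_anova,
                                     star_level)

from oracles import oracle_mixed_anova


def matrix_from(values, sample_ids, region_size=50, protein_length=200):
    values = np.asarray(values, dtype=float)
    return RegionMatrix("P1", list(sample_ids), values,
                        values.sum(axis=1), region_size, protein_length)


SIDS = [f"{g}_male_{i}" for g in ("juvenile", "adult") for i in (1, 2, 3)]


class TestMedianNormalize:
    def test_equal_totals_is_identity(self):
        m = matrix_from([[3, 7], [5, 5], [1, 9], [9, 1], [2, 8], [4, 6]], SIDS)
        nm = median_normalize(m)
        assert np.allclose(nm.scale_factors, 1.0)
        assert np.array_equal(nm.norm_values, m.values)

    def test_factor_arithmetic(self):
        m = matrix_from([[10, 0], [20, 0], [40, 0], [40, 0]], SIDS[:4])
        nm = median_normalize(m)
        assert np.allclose(nm.scale_factors, [3.0, 1.5, 0.75, 0.75])
        assert np.allclose(nm.norm_values[:, 0], 30.0)

    def test_zero_total_sample_excluded_and_listed(self):
        m = matrix_from([[4, 4], [0, 0], [3, 5], [6, 2]], SIDS[:4])
        nm = median_normalize(m)
        assert nm.excluded_samples == [SIDS[1]]
        assert nm.sample_ids == [SIDS[0], SIDS[2], SIDS[3]]

    def test_all_totals_zero_raises(self):
        m = matrix_from(np.zeros((4, 2)), SIDS[:4])
        with pytest.raises(AllTotalsZero):
            median_normalize(m)

    def test_abundance_multiplier_invariance(self):
        """Scaling one sample's counts leaves its normalized row unchanged
        while >=3 other samples pin the median."""
        rng = np.random.default_rng(11)
        base = rng.integers(1, 30, size=(5, 6)).astype(float)
        m = matrix_from(base, [f"s{i}" for i in range(5)])
        nm = median_normalize(m)
        for c in (0.5, 2.0, 7.0):
            scaled = base.copy()
            scaled[2] *= c
            m2 = matrix_from(scaled, [f"s{i}" for i in range(5)])
            nm2 = median_normalize(m2)
            if np.median(m2.totals) == np.median(m.totals):
                assert np.allclose(nm2.norm_values[2], nm.norm_values[2])


class TestMixedAnova:
    def _fixture(self, seed=2024, n_per=3, K=4):
        rng = np.random.default_rng(seed)
        Y = rng.normal(10, 3, size=(2 * n_per, K))
        groups = np.array(["juvenile"] * n_per + ["adult"] * n_per)
        return Y, groups

    def test_decomposition_matches_first_principles_oracle(self):
        """Sums of squares, omnibus F and contrast p agree to 1e-8."""
        for seed in (2024, 2025, 77):
            Y, groups = self._fixture(seed)
            table = mixed_anova_decomposition(Y, groups)
            ora = oracle_mixed_anova(Y, groups)
            for name in ("ss_group", "ss_subjects_within", "ss_region",
                         "ss_interaction", "ss_error"):
                assert getattr(table, name) == pytest.approx(
                    ora[name], rel=1e-8)
            assert table.F_group == pytest.approx(ora["F_group"], rel=1e-8)
            assert table.F_region == pytest.approx(ora["F_region"], rel=1e-8)
            assert table.F_interaction == pytest.approx(
                ora["F_interaction"], rel=1e-8)

    def test_omnibus_matches_pingouin(self):
        """Independent library cross-check of the mixed ANOVA table."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        Y, groups = self._fixture(31, n_per=4, K=5)
        table = mixed_anova_decomposition(Y, groups)
        long = pd.DataFrame([
            {"subject": i, "group": groups[i], "region": k, "y": Y[i, k]}
            for i in range(Y.shape[0]) for k in range(Y.shape[1])])
        pg = pingouin.mixed_anova(long, dv="y", within="region",
                                  subject="subject", between="group")
        pg = pg.set_index("Source")
        assert table.F_group == pytest.approx(pg.loc["group", "F"], rel=1e-6)
        assert table.F_region == pytest.approx(pg.loc["region", "F"], rel=1e-6)
        assert table.F_interaction == pytest.approx(
            pg.loc["Interaction", "F"], rel=1e-6)

    def test_region_anova_contrasts_match_oracle(self, design_3v3):
        Y, groups = self._fixture(99)
        m = matrix_from(Y, SIDS, protein_length=200)
        nm = median_normalize(m)
        res = region_anova(nm, design_3v3, "male", transform="none")
        ora = oracle_mixed_anova(nm.norm_values, groups)
        assert len(res.regions) == 4
        for r, (F, p) in zip(res.regions, ora["contrasts"]):
            assert r.F_stat == pytest.approx(F, rel=1e-8)
            assert r.p_raw == pytest.approx(p, rel=1e-8)
            assert r.p_adjusted == pytest.approx(min(1.0, 4 * p), rel=1e-8)

    def test_identical_groups_null_identity(self, design_3v3):
        vals = np.tile([4.0, 9.0, 2.0, 7.0], (6, 1))
        nm = median_normalize(matrix_from(vals, SIDS, protein_length=200))
        res = region_anova(nm, design_3v3, "male")
        assert all(r.F_stat == 0 for r in res.regions)
        assert all(r.p_adjusted == 1.0 for r in res.regions)

    def test_unobserved_regions_excluded_from_m(self, design_3v3):
        rng = np.random.default_rng(4)
        vals = np.column_stack([rng.normal(10, 2, 6), np.zeros(6),
                                rng.normal(8, 2, 6)])
        nm = median_normalize(matrix_from(vals, SIDS, protein_length=150))
        res = region_anova(nm, design_3v3, "male")
        assert res.tested_regions == [0, 2]
        assert all(r.m == 2 for r in res.regions)

    def test_too_few_samples_per_group_raises(self, design_3v3):
        vals = np.random.default_rng(1).normal(10, 1, (6, 3))
        nm = median_normalize(matrix_from(vals, SIDS, protein_length=150))
        with pytest.raises(ValueError, match="need >="):
            region_anova(nm, design_3v3, "male", min_per_group=5)

    def test_planted_shift_recovered_only_there(self, design_3v3):
        """A 10-sigma mean shift in one region is the only discovery.

        Totals are held equal across samples so the fixture probes the
        contrast machinery itself, not the normalization's response to the
        totals shift such a large single-region effect would induce.
        """
        rng = np.random.default_rng(12)
        hits, false = 0, 0
        reps = 200
        for _ in range(reps):
            Y = rng.normal(20, 1, size=(6, 8))
            Y[:3, 5] += 10.0
            m = RegionMatrix("P1", SIDS, Y, np.full(6, 100.0), 50, 400)
            res = region_anova(median_normalize(m), design_3v3, "male",
                               transform="none")
            sig = {r.region_index for r in res.regions if r.p_adjusted <= 0.05}
            hits += 5 in sig
            false += bool(sig - {5})
        assert hits / reps >= 0.95
        assert false / reps <= 0.10


class TestDeltaAvgPsc:
    def test_arithmetic(self, design_3v3):
        vals = np.array([[2, 0], [4, 0], [3, 0], [0, 0], [0, 0], [0, 0]],
                        dtype=float)
        m = RegionMatrix("P1", SIDS, vals, np.ones(6), 50, 100)
        nm = median_normalize(m)
        d = delta_avg_psc(nm, design_3v3, "male")
        assert np.allclose(d, [3.0, 0.0])

    def test_antisymmetry_under_group_swap(self, design_3v3):
        """Exchanging which samples carry each group label negates Δ."""
        from plf.io_formats import SampleMeta, StudyDesign

        rng = np.random.default_rng(8)
        vals = rng.integers(1, 40, (6, 5)).astype(float)
        m = RegionMatrix("P1", SIDS, vals, vals.sum(1), 50, 250)
        nm = median_normalize(m)
        d = delta_avg_psc(nm, design_3v3, "male")
        # same samples, group labels exchanged; sample order arranged so the
        # (juvenile, adult) level ordering of the design is preserved
        flipped = {"juvenile": "adult", "adult": "juvenile"}
        swapped_design = StudyDesign(tuple(
            SampleMeta(s.sample_id, flipped[s.group], s.stratum)
            for s in list(design_3v3.samples)[3:] + list(design_3v3.samples)[:3]))
        d2 = delta_avg_psc(nm, swapped_design, "male")
        assert np.allclose(d, -d2)

    def test_equals_two_pass_mean_difference(self, design_3v3):
        rng = np.random.default_rng(13)
        vals = rng.integers(0, 25, (6, 7)).astype(float)
        m = RegionMatrix("P1", SIDS, vals, vals.sum(1) + 1, 50, 350)
        nm = median_normalize(m)
        d = delta_avg_psc(nm, design_3v3, "male")
        expect = nm.norm_values[:3].mean(0) - nm.norm_values[3:].mean(0)
        assert np.allclose(d, expect)


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [
        (0.01, 3, 0.03),
        (0.5, 5, 1.0),
        (0.2, 1, 0.2),
    ])
    def test_examples(self, p, m, expected):
        assert bonferroni([p], m)[0] == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], 2)
        with pytest.raises(ValueError):
            bonferroni([0.5], 0)

    def test_star_convention(self):
        assert star_level(0.05) == "*"
        assert star_level(0.01) == "**"
        assert star_level(0.001) == "***"
        assert star_level(0.0501) == ""
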