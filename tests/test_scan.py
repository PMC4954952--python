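"""Haley-Knott scans, permutation thresholds, stepwise models, intervals."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rilmap._rng import substream
from rilmap.mapping import (
    A,
    B,
    GeneticMap,
    GenotypeMatrix,
    build_scan_grid,
    genotype_probabilities,
)
from rilmap.scan import (
    ScanConfig,
    drop_one_refine,
    fit_multiqtl_stepwise,
    hk_scan,
    lod_support_interval,
    permutation_max_lods,
    permutation_threshold,
    scan_value_matrix,
    standardized_additive_effect,
)
from rilmap.simulate import (
    simulate_ril_genotypes,
)


def _marker_regression_lod(y, x01):
    """Independent two-group oracle: LOD from class-mean regression."""
    y = np.asarray(y, float)
    rss0 = np.sum((y - y.mean()) ** 2)
    rss1 = 0.0
    for g in (0, 1):
        sub = y[x01 == g]
        if sub.size:
            rss1 += np.sum((sub - sub.mean()) ** 2)
    n = y.size
    if rss1 <= 0:
        return 300.0
    return (n / 2.0) * np.log10(rss0 / rss1)


def _tiny_map():
    return GeneticMap(
        pd.DataFrame(
            {"marker": ["m0", "m1"], "chromosome": [1, 1], "position_cm": [0.0, 20.0]}
        )
    )


class TestHKScan:
    def test_hand_computed_lod(self):
        """Four lines split A,A,B,B with trait 1,2,3,4: RSS0=5, RSS1=1."""
        gmap = _tiny_map()
        geno = GenotypeMatrix(["l1", "l2", "l3", "l4"], [[A, A], [A, B], [B, A], [B, B]])
        grid = build_scan_grid(gmap, 20.0)
        probs = genotype_probabilities(gmap, geno, grid)
        y = np.array([1.0, 2.0, 3.0, 4.0])
        prof = hk_scan(y, probs, grid, min_lines=4)
        assert prof.lod[0] == pytest.approx(2 * np.log10(5.0), abs=1e-10)
        assert prof.lod[0] == pytest.approx(1.39794, abs=1e-5)

    def test_constant_trait_zero_profile(self, template_probs):
        _, grid, probs = template_probs
        with pytest.warns(UserWarning, match="zero-variance"):
            prof = hk_scan(np.full(probs.shape[0], 3.0), probs, grid)
        assert np.all(prof.lod == 0.0)

    def test_hk_equals_marker_regression_at_markers(self, template_map, template_probs):
        geno, grid, probs = template_probs
        rng = substream(21, "hk_oracle")
        y = 10 + rng.normal(0, 1, probs.shape[0])
        j = template_map.marker_index(template_map.nearest_marker(2, 40.0))
        y += 0.6 * np.where(geno.calls[:, j] == A, 1.0, -1.0)
        prof = hk_scan(y, probs, grid)
        mk = grid.marker_positions()
        for col in mk[:: len(mk) // 40]:
            x01 = (probs[:, col] < 0.5).astype(int)
            assert prof.lod[col] == pytest.approx(
                _marker_regression_lod(y, x01), abs=1e-8
            )

    def test_affine_invariance(self, template_probs):
        _, grid, probs = template_probs
        rng = substream(22, "affine")
        y = rng.normal(0, 1, probs.shape[0])
        a = hk_scan(y, probs, grid).lod
        b = hk_scan(-2.5 * y + 7.0, probs, grid).lod
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_fitted_class_means(self):
        gmap = _tiny_map()
        geno = GenotypeMatrix(["l1", "l2", "l3", "l4"], [[A, A], [A, B], [B, A], [B, B]])
        grid = build_scan_grid(gmap, 20.0)
        probs = genotype_probabilities(gmap, geno, grid)
        prof = hk_scan(np.array([1.0, 2.0, 3.0, 4.0]), probs, grid, min_lines=4)
        mean_a, mean_b = prof.class_means(0)
        assert mean_a == pytest.approx(1.5)
        assert mean_b == pytest.approx(3.5)

    def test_too_few_lines_rejected(self, template_probs):
        _, grid, probs = template_probs
        y = np.full(probs.shape[0], np.nan)
        y[:5] = [1, 2, 3, 4, 5]
        with pytest.raises(ValueError, match="lines"):
            hk_scan(y, probs, grid)


class TestPermutationThreshold:
    def test_exhaustive_enumeration_oracle(self):
        """n=4 lines, 2 markers: the sampled threshold must sit at the
        exhaustive 24-permutation quantile."""
        gmap = _tiny_map()
        geno = GenotypeMatrix(["l1", "l2", "l3", "l4"], [[A, A], [A, B], [B, A], [B, B]])
        grid = build_scan_grid(gmap, 20.0)
        probs = genotype_probabilities(gmap, geno, grid)
        y = np.array([1.0, 2.0, 3.0, 4.0])
        exhaustive = []
        for perm in itertools.permutations(range(4)):
            yp = y[list(perm)]
            exhaustive.append(
                max(
                    _marker_regression_lod(yp, (probs[:, c] < 0.5).astype(int))
                    for c in range(probs.shape[1])
                )
            )
        exhaustive = np.sort(exhaustive)
        alpha = 0.25
        sampled = np.sort(permutation_max_lods(y, probs, 4000, substream(23, "ex")))
        k = int(np.ceil((1 - alpha) * 4000)) - 1
        k_ex = int(np.ceil((1 - alpha) * 24)) - 1
        assert sampled[k] == pytest.approx(exhaustive[k_ex], abs=1e-8)

    def test_threshold_monotone_in_alpha(self, template_probs):
        _, grid, probs = template_probs
        y = substream(24, "mono").normal(0, 1, probs.shape[0])
        t_strict = permutation_threshold(y, probs, 500, 0.02, substream(24, "p"))
        t_loose = permutation_threshold(y, probs, 500, 0.20, substream(24, "p"))
        assert t_strict >= t_loose

    def test_small_n_perm_rejected(self, template_probs):
        _, grid, probs = template_probs
        y = np.arange(probs.shape[0], dtype=float)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_threshold(y, probs, 10, 0.05)

    def test_reproducible_under_fixed_seed(self, template_probs):
        _, grid, probs = template_probs
        y = substream(25, "rep").normal(0, 1, probs.shape[0])
        a = permutation_threshold(y, probs, 200, 0.05, substream(25, "p"))
        b = permutation_threshold(y, probs, 200, 0.05, substream(25, "p"))
        assert a == b

    def test_null_max_lod_grows_with_marker_count(self, template_probs):
        """Genome-wide max LOD null stochastically increases with the
        number of tested positions."""
        _, grid, probs = template_probs
        y = substream(26, "grow").normal(0, 1, probs.shape[0])
        few = permutation_max_lods(y, probs[:, :40], 400, substream(26, "p"))
        many = permutation_max_lods(y, probs, 400, substream(26, "p"))
        assert many.mean() > few.mean()


class TestStepwise:
    def test_two_unlinked_qtls_recovered(self, template_map):
        hits = 0
        sims = 6
        for s in range(sims):
            geno = simulate_ril_genotypes(template_map, 250, substream(s, "two"))
            grid = build_scan_grid(template_map, 2.0)
            probs = genotype_probabilities(template_map, geno, grid)
            truth = [(3, 50.0), (8, 60.0)]
            x = np.zeros(250)
            for c, p in truth:
                j = template_map.marker_index(template_map.nearest_marker(c, p))
                x += 0.5 * np.where(geno.calls[:, j] == A, 1.0, -1.0)
            y = 10 + x + substream(s, "noise").normal(0, 1, 250)
            thr = permutation_threshold(y, probs, 200, 0.05, substream(s, "perm"))
            model = fit_multiqtl_stepwise(y, probs, grid, main_penalty=thr)
            model = drop_one_refine(model, y, probs, thr)
            found = []
            for c, p in truth:
                ok = any(
                    grid.chromosome[q] == c and abs(grid.positions[q] - p) <= 15.0
                    for q in model.positions
                )
                found.append(ok)
            hits += all(found)
        assert hits >= int(0.8 * sims)

    def test_pure_interaction_found_by_pair_search(self, template_map):
        geno = simulate_ril_genotypes(template_map, 300, substream(31, "epi"))
        grid = build_scan_grid(template_map, 2.0)
        probs = genotype_probabilities(template_map, geno, grid)
        j1 = template_map.marker_index(template_map.nearest_marker(2, 60.0))
        j2 = template_map.marker_index(template_map.nearest_marker(9, 40.0))
        x1 = np.where(geno.calls[:, j1] == A, 1.0, -1.0)
        x2 = np.where(geno.calls[:, j2] == A, 1.0, -1.0)
        y = 10 + 1.2 * x1 * x2 + substream(31, "noise").normal(0, 1, 300)
        thr = permutation_threshold(y, probs, 200, 0.05, substream(31, "perm"))
        no_pairs = fit_multiqtl_stepwise(y, probs, grid, main_penalty=thr)
        model = fit_multiqtl_stepwise(
            y, probs, grid, main_penalty=thr, int_penalty=thr, pair_search=True
        )
        assert len(model.interactions) == 1
        chroms = sorted(grid.chromosome[q] for q in model.positions)
        assert chroms == [2, 9]
        assert len(no_pairs.interactions) == 0  # single-locus moves cannot see it

    def test_null_traits_mostly_empty_models(self, template_probs):
        _, grid, probs = template_probs
        empty = 0
        sims = 12
        for s in range(sims):
            y = substream(s, "nullmodel").normal(0, 1, probs.shape[0])
            thr = permutation_threshold(y, probs, 200, 0.05, substream(s, "np"))
            model = fit_multiqtl_stepwise(y, probs, grid, main_penalty=thr)
            empty += len(model.positions) == 0
        assert empty >= 10

    def test_single_qtl_drop_one_equals_scan_lod(self, template_map, template_probs):
        geno, grid, probs = template_probs
        j = template_map.marker_index(template_map.nearest_marker(4, 50.0))
        x = np.where(geno.calls[:, j] == A, 1.0, -1.0)
        y = 10 + 0.8 * x + substream(33, "noise").normal(0, 1, probs.shape[0])
        prof = hk_scan(y, probs, grid)
        thr = permutation_threshold(y, probs, 200, 0.05, substream(33, "p"))
        model = fit_multiqtl_stepwise(y, probs, grid, main_penalty=thr, max_qtl=1)
        model = drop_one_refine(model, y, probs, thr)
        assert len(model.positions) == 1
        q = model.positions[0]
        assert model.drop_one_lod[q] == pytest.approx(prof.lod[q], abs=1e-8)

    def test_duplicate_qtl_pruned(self, template_map, template_probs):
        from rilmap.scan import MultiQTLModel

        geno, grid, probs = template_probs
        j = template_map.marker_index(template_map.nearest_marker(4, 50.0))
        x = np.where(geno.calls[:, j] == A, 1.0, -1.0)
        y = 10 + 0.8 * x + substream(34, "noise").normal(0, 1, probs.shape[0])
        sl = grid.chrom_slice(4)
        q = sl.start + int(
            np.argmin(np.abs(grid.positions[sl] - 50.0))
        )
        model = MultiQTLModel(positions=[q, q])
        model = drop_one_refine(model, y, probs, threshold=2.0)
        assert model.positions == [q]

    def test_linked_qtls_partial_lods(self, template_map):
        """Two linked QTLs 10 cM apart: each drop-one LOD below the joint
        model LOD (shared signal)."""
        geno = simulate_ril_genotypes(template_map, 400, substream(35, "link"))
        grid = build_scan_grid(template_map, 2.0)
        probs = genotype_probabilities(template_map, geno, grid)
        j1 = template_map.marker_index(template_map.nearest_marker(1, 80.0))
        j2 = template_map.marker_index(template_map.nearest_marker(1, 90.0))
        x1 = np.where(geno.calls[:, j1] == A, 1.0, -1.0)
        x2 = np.where(geno.calls[:, j2] == A, 1.0, -1.0)
        y = 10 + 0.7 * x1 + 0.7 * x2 + substream(35, "noise").normal(0, 1, 400)
        sl = grid.chrom_slice(1)
        pos = grid.positions[sl]
        q1 = sl.start + int(np.argmin(np.abs(pos - 80.0)))
        q2 = sl.start + int(np.argmin(np.abs(pos - 90.0)))
        from rilmap.scan import MultiQTLModel

        model = drop_one_refine(MultiQTLModel(positions=[q1, q2]), y, probs, 0.0)
        assert set(model.positions) == {q1, q2}
        for q in (q1, q2):
            assert 0 < model.drop_one_lod[q] < model.lod


class TestSupportInterval:
    def test_symmetric_tent_profile(self):
        pos = np.arange(0.0, 21.0)
        lods = 10.0 - 0.375 * np.abs(pos - 10.0)  # crosses -1.5 at +-4 cM
        lo, hi, li, hi_i = lod_support_interval(pos, lods, 10, drop=1.5)
        assert (lo, hi) == (6.0, 14.0)

    def test_flat_profile_whole_chromosome(self):
        pos = np.arange(0.0, 11.0)
        lods = np.full(11, 4.0)
        lo, hi, *_ = lod_support_interval(pos, lods, 5, drop=1.5)
        assert (lo, hi) == (0.0, 10.0)

    def test_peak_at_chromosome_end_one_sided(self):
        pos = np.arange(0.0, 11.0)
        lods = 8.0 - 0.5 * pos
        lo, hi, *_ = lod_support_interval(pos, lods, 0, drop=1.5)
        assert lo == 0.0
        assert hi == 3.0


class TestStandardizedEffect:
    def test_arithmetic_example(self):
        y = np.array([12.0, 12.0, 8.0, 8.0])
        p = np.array([1.0, 1.0, 0.0, 0.0])
        effect, se = standardized_additive_effect(y, p)
        assert effect == pytest.approx(0.4)

    def test_equal_means_zero(self):
        y = np.array([5.0, 7.0, 5.0, 7.0])
        p = np.array([1.0, 1.0, 0.0, 0.0])
        assert standardized_additive_effect(y, p)[0] == pytest.approx(0.0)

    def test_label_swap_antisymmetry(self):
        rng = substream(36, "swap")
        y = rng.normal(10, 2, 40)
        p = (rng.random(40) > 0.5).astype(float)
        e1, _ = standardized_additive_effect(y, p)
        e2, _ = standardized_additive_effect(y, 1.0 - p)
        assert e1 == pytest.approx(-e2, abs=1e-12)

    def test_zero_grand_mean_rejected(self):
        y = np.array([-1.0, 1.0, -1.0, 1.0])
        p = np.array([1.0, 1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="grand mean"):
            standardized_additive_effect(y, p)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            standardized_additive_effect(np.ones(4), np.ones(4))


class TestPanelScan:
    def test_identical_traits_identical_results(self, template_map, template_probs):
        geno, grid, probs = template_probs
        j = template_map.marker_index(template_map.nearest_marker(5, 60.0))
        x = np.where(geno.calls[:, j] == A, 1.0, -1.0)
        y = 10 + 0.8 * x + substream(37, "dup").normal(0, 1, probs.shape[0])
        values = pd.DataFrame({"t1": y, "t2": y.copy()}, index=geno.line_ids)
        cfg = ScanConfig(step=2.0, n_perm=200)
        qtls, _ = scan_value_matrix(values, geno, template_map, cfg, seed=99)
        a = qtls[qtls["trait"] == "t1"].drop(columns="trait").reset_index(drop=True)
        b = qtls[qtls["trait"] == "t2"].drop(columns="trait").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) >= 1

    def test_interval_contains_peak_and_markers_flank(self, template_map, template_probs):
        geno, grid, probs = template_probs
        j = template_map.marker_index(template_map.nearest_marker(7, 50.0))
        x = np.where(geno.calls[:, j] == A, 1.0, -1.0)
        y = 10 + 0.7 * x + substream(38, "ci").normal(0, 1, probs.shape[0])
        values = pd.DataFrame({"t": y}, index=geno.line_ids)
        qtls, _ = scan_value_matrix(
            values, geno, template_map, ScanConfig(step=2.0, n_perm=200), seed=5
        )
        assert len(qtls) >= 1
        row = qtls.iloc[0]
        assert row["ci_low_cM"] <= row["position_cM"] <= row["ci_high_cM"]
        assert 0.0 <= row["pve"] <= 100.0
        assert row["effect"] == pytest.approx(2 * 0.7 / 10, rel=0.5)
        markers = set(template_map.markers_on(row["chromosome"])["marker"])
        assert {row["ci_low_marker"], row["ci_high_marker"]} <= markers

    def test_sparse_trait_skipped(self, template_map, template_probs):
        geno, grid, probs = template_probs
        y = np.full(probs.shape[0], np.nan)
        y[:5] = 1.0
        values = pd.DataFrame({"sparse": y}, index=geno.line_ids)
        qtls, _ = scan_value_matrix(
            values, geno, template_map, ScanConfig(step=2.0, n_perm=100), seed=6
        )
        assert len(qtls) == 0
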