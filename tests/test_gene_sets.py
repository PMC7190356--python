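"""Threshold panels, symmetry statistics and the overlap permutation test."""

import numpy as np
import pytest
from scipy import stats

from dediff import (
    GenePanel,
    InputError,
    classify_changing_genes,
    define_aggregation_panel,
    define_early_induced,
    direction_over_window,
    log2fc,
    overlap_permutation_test,
    symmetry_overlap,
)
from conftest import make_timecourse
from oracles import (
    aggregation_panel_loops,
    changing_genes_loops,
    early_induced_loops,
)

DEV_TIMES = [0, 2, 4, 6, 8, 10, 12, 14]


class TestLog2FC:
    @pytest.mark.parametrize(
        "vt, v0, pc, want",
        [
            (100, 100, 1, 0.0),
            (401, 100, 1, np.log2(402 / 101)),
            (0, 0, 1, 0.0),
        ],
    )
    def test_examples(self, vt, v0, pc, want):
        assert log2fc(vt, v0, pc) == pytest.approx(want, abs=1e-12)


class TestChangingGenes:
    def test_rule_application(self):
        tc = make_timecourse(
            [
                [200, 500, 450],  # in: max>100 and l2fc(500 vs 200) > 1
                [40, 90, 85],  # out: never above 100
                [200, 350, 300],  # out: max |l2fc| ~ 0.80
            ],
            times=[0, 2, 4],
        )
        panel = classify_changing_genes(tc, "dediff-bacteria")
        assert panel.genes == {"g0"}

    def test_missing_zero_hour_is_error(self):
        tc = make_timecourse([[1, 2]], times=[1, 2])
        with pytest.raises(InputError):
            classify_changing_genes(tc, "dediff-bacteria")

    def test_matches_loop_oracle(self, rng):
        vals = rng.lognormal(4.5, 1.2, size=(80, 8))
        tc = make_timecourse(vals, times=DEV_TIMES)
        got = classify_changing_genes(tc, "dediff-bacteria").genes
        assert got == changing_genes_loops(tc.condition_timecourse("dediff-bacteria"))


class TestDirectionOverWindow:
    def test_up_down_flat(self):
        tc = make_timecourse(
            [[100, 450], [400, 150], [100, 150]], times=[0.5, 4]
        )
        labels = direction_over_window(tc, "dediff-bacteria", (0.5, 4))
        assert list(labels) == ["up", "down", "flat"]

    def test_unsampled_endpoint_is_error(self):
        tc = make_timecourse([[1, 2]], times=[0, 4])
        with pytest.raises(InputError, match="no interpolation"):
            direction_over_window(tc, "dediff-bacteria", (0, 3))


class TestSymmetryOverlap:
    def test_fraction_and_counts(self):
        a = GenePanel("a", {"A", "B", "C"})
        b = GenePanel("b", {"A", "B"})
        res = symmetry_overlap(a, b)
        assert (res.overlap, res.size) == (2, 3)
        assert res.fraction == pytest.approx(2 / 3)

    def test_disjoint_and_empty(self):
        assert symmetry_overlap(GenePanel("a", {"A"}), GenePanel("b", {"B"})).fraction == 0
        with pytest.raises(InputError):
            symmetry_overlap(GenePanel("a", set()), GenePanel("b", {"B"}))

    def test_overlap_times_size_is_integer(self, rng):
        genes = [f"g{i}" for i in range(50)]
        a = GenePanel("a", rng.choice(genes, 20, replace=False))
        b = GenePanel("b", rng.choice(genes, 25, replace=False))
        res = symmetry_overlap(a, b)
        assert res.fraction * res.size == pytest.approx(round(res.fraction * res.size))


class TestAggregationPanel:
    def test_rule_application(self):
        rows = [
            [10, 10, 60, 60, 60, 20, 20, 20],  # in: 60 > 20 and 60 > 40
            [10, 10, 60, 60, 60, 35, 35, 35],  # out: 60 < 70
        ]
        tc = make_timecourse(rows, condition="development", times=DEV_TIMES)
        assert define_aggregation_panel(tc).genes == {"g0"}

    def test_missing_timepoint_is_error(self):
        tc = make_timecourse([[1] * 7], condition="development", times=DEV_TIMES[:-1])
        with pytest.raises(InputError, match="missing timepoints"):
            define_aggregation_panel(tc)

    def test_matches_loop_oracle(self, rng):
        vals = rng.lognormal(3.5, 1.0, size=(100, 8))
        tc = make_timecourse(vals, condition="development", times=DEV_TIMES)
        assert define_aggregation_panel(tc).genes == aggregation_panel_loops(
            tc.condition_timecourse("development")
        )


class TestEarlyInduced:
    TIMES = [0, 0.5, 1, 2, 4, 6, 8, 12]

    def test_rule_application(self):
        rows = [
            [100, 120, 160, 150, 140, 120, 100, 90],  # in: max 160 at 1 hr, 1.59x
            [100, 120, 130, 150, 200, 150, 100, 90],  # out: global max at 4 hr
            [100, 110, 120, 140, 130, 120, 100, 90],  # out: 1.39x < 1.5x
        ]
        tc = make_timecourse(rows, times=self.TIMES)
        panel = define_early_induced(tc, "dediff-bacteria")
        assert panel.genes == {"g0"}

    def test_any_rise_mode_ignores_late_maximum(self):
        # rises 1.6x by 1 hr but peaks globally at 4 hr: only any_rise takes it
        tc = make_timecourse([[100, 120, 160, 150, 200, 150, 100, 90]], times=self.TIMES)
        assert define_early_induced(tc, "dediff-bacteria").genes == set()
        got = define_early_induced(tc, "dediff-bacteria", mode="any_rise")
        assert got.genes == {"g0"}

    def test_matches_loop_oracle(self, rng):
        vals = rng.lognormal(4.0, 0.8, size=(120, 8))
        tc = make_timecourse(vals, times=self.TIMES)
        got = define_early_induced(tc, "dediff-bacteria").genes
        assert got == early_induced_loops(tc.condition_timecourse("dediff-bacteria"))


class TestOverlapPermutationTest:
    def _tiny(self):
        universe = [f"g{i}" for i in range(6)]
        panel = GenePanel("panel", universe[:2])
        induced = GenePanel("induced", universe[:3])
        return panel, induced, universe

    def test_exhaustive_null_enumeration(self):
        panel, induced, universe = self._tiny()
        res = overlap_permutation_test(panel, induced, universe, method="exhaustive")
        values, counts = np.unique(res.null_overlaps, return_counts=True)
        assert dict(zip(values.tolist(), counts.tolist())) == {0: 3, 1: 9, 2: 3}
        assert np.median(res.null_overlaps) == 1
        assert res.exhaustive and res.n_permutations == 15

    def test_auto_switches_to_exhaustive_on_small_universe(self):
        panel, induced, universe = self._tiny()
        assert overlap_permutation_test(panel, induced, universe, method="auto").exhaustive

    def test_empirical_p_with_zero_exceedances(self):
        universe = [f"g{i}" for i in range(200)]
        panel = GenePanel("panel", universe[:10])
        induced = GenePanel("induced", universe[:10])
        res = overlap_permutation_test(
            panel, induced, universe, n_permutations=1000, seed=7, method="sample"
        )
        assert res.observed_overlap == 10
        assert (res.null_overlaps < 10).all()
        assert res.empirical_p == pytest.approx(1 / 1001)

    def test_null_mean_matches_hypergeometric(self):
        universe = [f"g{i}" for i in range(300)]
        rng = np.random.default_rng(11)
        panel = GenePanel("panel", rng.choice(universe, 40, replace=False))
        induced = GenePanel("induced", rng.choice(universe, 60, replace=False))
        res = overlap_permutation_test(
            panel, induced, universe, n_permutations=4000, seed=5, method="sample"
        )
        want_mean = 40 * 60 / 300
        sd = stats.hypergeom(300, 60, 40).std()
        assert abs(res.null_overlaps.mean() - want_mean) < 3 * sd / np.sqrt(4000)

    def test_determinism_under_fixed_seed(self):
        universe = [f"g{i}" for i in range(100)]
        panel = GenePanel("p", universe[:15])
        induced = GenePanel("i", universe[10:40])
        a = overlap_permutation_test(panel, induced, universe, 500, seed=3, method="sample")
        b = overlap_permutation_test(panel, induced, universe, 500, seed=3, method="sample")
        assert (a.null_overlaps == b.null_overlaps).all()

    def test_panel_exceeding_universe_is_error(self):
        with pytest.raises(InputError):
            overlap_permutation_test(
                GenePanel("p", {"a", "b"}), GenePanel("i", {"a"}), ["a"], 10
            )
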