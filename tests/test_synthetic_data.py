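"""The synthetic-cohort generator: determinism, truth recovery, scaling."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import small_scenario
from panelburden import (
    FilterConfig,
    PopulationSpec,
    ScenarioConfig,
    read_regions,
    read_vcf,
    run_cascade,
    simulate_burden_grid,
    simulate_cohort,
    simulate_null_grid,
)
from panelburden.io_formats import ConfigurationError
from panelburden.synthetic_data import build_layout


class TestScenarioConfig:
    def test_panel_larger_than_exome_is_infeasible(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(exome_size=10_000, panel_size=20_000)

    def test_bad_dropout_range(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(coverage_dropout=(0.5, 0.2))

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_scenario(seed=3)
        path = tmp_path / "scenario.yaml"
        cfg.to_yaml(path)
        again = ScenarioConfig.from_yaml(path)
        assert again.seed == 3
        assert [p.label for p in again.populations] == ["White", "Black"]
        assert again.panel_size == cfg.panel_size


class TestLayout:
    def test_panel_is_subset_of_capture_and_masks_are_off_panel(self):
        layout = build_layout(small_scenario())
        capture, panel = layout["capture"], layout["panel"]
        assert panel.intersect(capture).total_length == panel.total_length
        assert panel.total_length == 40_000
        masks = layout["tandem_repeat"].union(layout["segdup"])
        assert masks.intersect(panel).total_length == 0
        assert masks.intersect(capture).total_length == masks.total_length
        assert layout["ccds"].total_length < capture.total_length


class TestSimulatedCohort:
    def test_same_seed_is_byte_identical(self, tmp_path):
        s1 = simulate_cohort(small_scenario(), tmp_path / "a")
        s2 = simulate_cohort(small_scenario(), tmp_path / "b")
        assert s1.vcf_path.read_bytes() == s2.vcf_path.read_bytes()
        assert s1.truth_path.read_bytes() == s2.truth_path.read_bytes()
        sample = next(iter(s1.coverage_paths))
        assert (
            s1.coverage_paths[sample].read_bytes()
            == s2.coverage_paths[sample].read_bytes()
        )

    def test_different_seed_differs(self, tmp_path):
        s1 = simulate_cohort(small_scenario(seed=1), tmp_path / "a")
        s2 = simulate_cohort(small_scenario(seed=2), tmp_path / "b")
        assert s1.vcf_path.read_bytes() != s2.vcf_path.read_bytes()

    def test_files_parse_and_decoys_are_caught_exactly(self, small_cohort):
        regions = {
            name: read_regions(path, name=name)
            for name, path in small_cohort.region_paths.items()
        }
        variants = list(read_vcf(small_cohort.vcf_path, check_against=regions["capture"]))
        truth = small_cohort.manifest.variant_truth
        assert len(variants) == len(truth)
        _, report = run_cascade(variants, FilterConfig(), regions)
        for key, entry in truth.items():
            want = (
                None
                if entry["expected_disposition"] == "pass"
                else entry["expected_disposition"]
            )
            assert report.dispositions[key] == want
        report.check_conservation()

    def test_true_events_survive_and_match_sample_truth(self, small_cohort):
        regions = {
            name: read_regions(path, name=name)
            for name, path in small_cohort.region_paths.items()
        }
        variants = list(read_vcf(small_cohort.vcf_path))
        surviving, _ = run_cascade(variants, FilterConfig(), regions)
        panel = regions["panel"].intersect(regions["capture"])
        counts_exome: dict[str, int] = {}
        counts_panel: dict[str, int] = {}
        for v in surviving:
            for s in v.carriers():
                counts_exome[s] = counts_exome.get(s, 0) + 1
                if panel.contains(v.chrom, v.pos0):
                    counts_panel[s] = counts_panel.get(s, 0) + 1
        for sid, entry in small_cohort.manifest.sample_truth.items():
            assert counts_exome.get(sid, 0) == entry["exome_events"]
            assert counts_panel.get(sid, 0) == entry["panel_events"]


class TestCountLevelSimulators:
    def test_single_replicate_p_is_valid(self):
        cal = simulate_null_grid(ScenarioConfig(), 1, seed=5)
        assert cal.pvalues.shape == (1,)
        assert 0.0 < cal.pvalues[0] <= 1.0

    def test_enrichment_is_forced_to_one_under_the_null(self):
        cfg = ScenarioConfig(
            populations=[PopulationSpec("pop1", 40, 1.5e-6, 5.0)]
        )
        cal = simulate_null_grid(cfg, 400, seed=9)
        # a five-fold enrichment would reject nearly always; the null grid must not
        assert cal.rejection_rate < 0.12

    def test_doubling_rate_doubles_mean_event_count(self):
        base = ScenarioConfig(
            populations=[PopulationSpec("pop1", 40, 1.5e-6, 1.0)], seed=0
        )
        doubled = ScenarioConfig(
            populations=[PopulationSpec("pop1", 40, 3.0e-6, 1.0)], seed=0
        )
        g1 = simulate_burden_grid(base, 50, seed=17, keep_counts=True)["pop1"]
        g2 = simulate_burden_grid(doubled, 50, seed=18, keep_counts=True)["pop1"]
        ratio = g2["M"].mean() / g1["M"].mean()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_p_values_are_valid_under_null(self):
        # with a small expected panel count the exact p-value is discrete and
        # conservative, so test validity (P(p <= a) <= a) rather than exact
        # uniformity, plus a floor ruling out degenerate over-conservatism
        cal = simulate_null_grid(ScenarioConfig(), 2000, seed=23)
        for alpha in (0.05, 0.1, 0.25, 0.5, 0.75):
            frac = (cal.pvalues <= alpha).mean()
            assert frac <= alpha + 0.03
            assert frac >= alpha / 3.0

    def test_lambda_estimates_center_on_truth(self):
        cfg = ScenarioConfig(populations=[PopulationSpec("pop1", 40, 1.5e-6, 1.0)])
        g = simulate_burden_grid(cfg, 200, seed=31)["pop1"]
        assert np.median(g["lambda_hat"]) == pytest.approx(1.5e-6, rel=0.05)
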