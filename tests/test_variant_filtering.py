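"""The rare-truncating filter cascade: thresholds, order, accounting."""

from __future__ import annotations

import pytest

from panelburden import FilterConfig, RegionSet, run_cascade
from panelburden.io_formats import (
    DataError,
    HET,
    MISSING,
    SampleCall,
    Variant,
)
from panelburden.variant_filtering import (
    ConfigurationError,
    apply_genotype_missingness,
    apply_maf_filter,
    apply_structural_filters,
    classify_truncating,
)


def make_variant(
    pos=100,
    ref="G",
    alt="A",
    consequence="stopgain",
    freqs=None,
    depths=(30,) * 10,
    carrier_index=0,
    carrier_depth=None,
):
    calls = {}
    for i, d in enumerate(depths):
        gt = HET if i == carrier_index else "hom_ref"
        calls[f"S{i}"] = SampleCall(gt, d)
    if carrier_depth is not None:
        calls[f"S{carrier_index}"] = SampleCall(HET, carrier_depth)
    return Variant("chr1", pos, ref, alt, consequence, dict(freqs or {}), calls)


CFG = FilterConfig()


class TestMissingness:
    def test_two_low_depth_calls_in_ten_removes_site(self):
        v = make_variant(depths=(30,) * 8 + (2, 2))
        assert apply_genotype_missingness(v, CFG) is None

    def test_exactly_at_threshold_is_retained(self):
        # missing rate 0.1 is not > 0.1
        v = make_variant(depths=(30,) * 9 + (2,))
        out = apply_genotype_missingness(v, CFG)
        assert out is not None
        assert out.sample_calls["S9"].genotype == MISSING

    def test_all_depths_adequate_is_identity(self):
        v = make_variant()
        out = apply_genotype_missingness(v, CFG)
        assert out is not None
        assert all(c.genotype != MISSING for c in out.sample_calls.values())

    def test_zero_samples_is_an_error(self):
        v = Variant("chr1", 100, "G", "A", "stopgain")
        with pytest.raises(DataError):
            apply_genotype_missingness(v, CFG)


class TestConsequenceClass:
    @pytest.mark.parametrize(
        "consequence,expected",
        [
            ("stopgain", True),
            ("stoploss", True),
            ("splice_site", True),
            ("frameshift_indel", True),
            ("other", False),
        ],
    )
    def test_truncating_classes(self, consequence, expected):
        v = make_variant(consequence=consequence)
        assert classify_truncating(v, CFG) is expected

    def test_long_frameshift_is_still_classified_truncating(self):
        # the length filter is a separate, later concern
        v = make_variant(ref="G" + "A" * 25, alt="G", consequence="frameshift_indel")
        assert classify_truncating(v, CFG)


class TestMafFilter:
    @pytest.mark.parametrize(
        "freqs,retained",
        [
            ({"1000g": 0.05}, False),
            ({"1000g": 0.001, "exac": 0.015}, True),
            ({}, True),  # unknown frequency passes
            ({"esp": 0.02}, True),  # boundary: cutoff is exclusive
            ({"esp": 0.0201}, False),
        ],
    )
    def test_any_source_above_cutoff_removes(self, freqs, retained):
        v = make_variant(freqs=freqs)
        assert apply_maf_filter(v, CFG) is retained


class TestStructuralFilters:
    def test_indel_length_boundary(self):
        long_del = make_variant(ref="G" + "A" * 21, alt="G", consequence="frameshift_indel")
        ok_del = make_variant(ref="G" + "A" * 20, alt="G", consequence="frameshift_indel")
        assert not apply_structural_filters(long_del, CFG)
        assert apply_structural_filters(ok_del, CFG)

    def test_carrier_depth_boundary(self):
        assert not apply_structural_filters(make_variant(carrier_depth=14), CFG)
        assert apply_structural_filters(make_variant(carrier_depth=15), CFG)

    def test_depth_rule_is_per_carrier(self):
        # two carriers, one under-covered: the site survives via the other
        v = make_variant()
        v.sample_calls["S1"] = SampleCall(HET, 10)
        assert apply_structural_filters(v, CFG)

    def test_mask_and_restriction_membership(self):
        mask = RegionSet([("chr1", 90, 110)], name="segdup")
        v = make_variant(pos=100)  # anchor 99 in [90,110)
        assert not apply_structural_filters(v, CFG, masks=[mask])
        capture = RegionSet([("chr1", 0, 50)], name="capture")
        assert not apply_structural_filters(v, CFG, restrict=[capture])


class TestCascade:
    REGIONS = {
        "capture": RegionSet([("chr1", 0, 10_000)], name="capture"),
        "tandem_repeat": RegionSet([("chr1", 5_000, 5_100)], name="tandem_repeat"),
        "segdup": RegionSet([("chr1", 6_000, 6_100)], name="segdup"),
    }

    def engineered_variants(self):
        """One variant per removal cause plus survivors; returns (variants, want)."""
        cases = [
            ("surv_snv", make_variant(pos=101), None),
            ("surv_fs", make_variant(pos=201, ref="GA", alt="G",
                                     consequence="frameshift_indel"), None),
            ("missing", make_variant(pos=301, depths=(30,) * 8 + (2, 2)), "missingness"),
            ("missense", make_variant(pos=401, consequence="other"), "non_truncating"),
            ("common", make_variant(pos=501, freqs={"1000g": 0.3}), "common_maf"),
            ("long", make_variant(pos=601, ref="G" + "A" * 21, alt="G",
                                  consequence="frameshift_indel"), "long_indel"),
            ("lowdp", make_variant(pos=701, carrier_depth=10), "low_depth"),
            ("masked", make_variant(pos=5_050), "masked_region"),
            ("offtarget", make_variant(pos=20_000), "outside_restriction"),
        ]
        return [v for _, v, _ in cases], {v.key: d for _, v, d in cases}

    def test_dispositions_match_engineered_design(self):
        variants, want = self.engineered_variants()
        surviving, report = run_cascade(variants, CFG, self.REGIONS)
        assert report.dispositions == want
        assert len(surviving) == 2
        assert report.n_input == len(variants)
        report.check_conservation()
        # each filter removed exactly its engineered variant
        removed = {d for d in want.values() if d is not None}
        for stage in removed:
            assert report.removed_by(stage) == 1

    def test_cascade_is_idempotent(self):
        variants, _ = self.engineered_variants()
        once, _ = run_cascade(variants, CFG, self.REGIONS)
        twice, report2 = run_cascade(once, CFG, self.REGIONS)
        assert [v.key for v in twice] == [v.key for v in once]
        assert all(s.n_removed == 0 for s in report2.stages)

    def test_neutralized_config_returns_input_unchanged(self):
        variants, _ = self.engineered_variants()
        neutral = FilterConfig(
            genotype_depth_min=0,
            site_missing_rate_max=1.0,
            maf_max=1.0,
            indel_length_max=None,
            variant_depth_min=0,
            truncating_classes=frozenset(
                {"stopgain", "stoploss", "splice_site", "frameshift_indel", "other"}
            ),
            masks=(),
            restrict_to=(),
        )
        surviving, report = run_cascade(variants, neutral, {})
        assert [v.key for v in surviving] == [v.key for v in variants]
        assert report.n_surviving == report.n_input

    def test_partial_neutralization_leaves_other_filters_active(self):
        variants, want = self.engineered_variants()
        cfg = FilterConfig(maf_max=1.0, masks=(), restrict_to=("capture",))
        _, report = run_cascade(variants, cfg, self.REGIONS)
        assert report.removed_by("common_maf") == 0
        assert report.removed_by("masked_region") == 0
        assert report.removed_by("non_truncating") == 1

    def test_missing_region_is_configuration_error(self):
        variants, _ = self.engineered_variants()
        with pytest.raises(ConfigurationError, match="tandem_repeat"):
            run_cascade(variants, CFG, {"capture": self.REGIONS["capture"],
                                        "segdup": self.REGIONS["segdup"]})

    def test_removed_variants_have_exactly_one_reason(self):
        variants, _ = self.engineered_variants()
        surviving, report = run_cascade(variants, CFG, self.REGIONS)
        surviving_keys = {v.key for v in surviving}
        for key, reason in report.dispositions.items():
            assert (reason is None) == (key in surviving_keys)


class TestFilterConfigValidation:
    def test_rejects_out_of_range_thresholds(self):
        with pytest.raises(ConfigurationError):
            FilterConfig(maf_max=0.0)
        with pytest.raises(ConfigurationError):
            FilterConfig(site_missing_rate_max=1.5)
        with pytest.raises(ConfigurationError):
            FilterConfig(genotype_depth_min=-1)

    def test_from_mapping_rejects_unknown_keys(self):
        with pytest.raises(ConfigurationError):
            FilterConfig.from_mapping({"maf_cutoff": 0.02})

    def test_round_trips_through_dict(self):
        cfg = FilterConfig(maf_max=0.01, masks=("segdup",))
        again = FilterConfig.from_mapping(
            {**cfg.to_dict(), "truncating_classes": sorted(cfg.truncating_classes)}
        )
        assert again.maf_max == 0.01
        assert again.masks == ("segdup",)
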