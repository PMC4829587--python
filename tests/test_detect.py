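"""The three-rule heteroplasmy filter and its frequency arithmetic."""

import numpy as np
import pytest

from mitodrift import (
    FilterThresholds,
    LineProfile,
    SitePileup,
    call_heteroplasmies,
    classify_variant,
    line_variant_stats,
    per_site_nonref_frequency,
    site_variant_frequency,
)


class TestSiteVariantFrequency:
    @pytest.mark.parametrize(
        "ref,ref_n,var,var_n,expected",
        [
            ("G", 495, "A", 21, 0.041),  # low-frequency progenitor heteroplasmy
            ("G", 259, "T", 155, 0.374),  # mid-frequency segregating variant
            ("G", 0, "T", 447, 1.000),  # fixed (homoplasmic) variant
            ("C", 292, "A", 18, 0.058),
        ],
    )
    def test_count_ratios_reproduce_published_frequencies(
        self, ref, ref_n, var, var_n, expected
    ):
        p = SitePileup(1, ref, {ref: ref_n, var: var_n})
        assert round(site_variant_frequency(p, var), 3) == expected

    def test_zero_variant_count_is_zero(self):
        p = SitePileup(1, "G", {"G": 100})
        assert site_variant_frequency(p, "A") == 0.0

    def test_denominator_includes_third_alleles_and_indels(self):
        p = SitePileup(1, "G", {"G": 80, "A": 10, "T": 5}, {"G": 5})
        assert site_variant_frequency(p, "A") == pytest.approx(0.1)

    def test_indel_frequency_uses_informative_reads(self):
        p = SitePileup(1, "A", {"A": 113}, {"A": 441})
        assert round(site_variant_frequency(p, "A", "deletion"), 3) == 0.796

    def test_zero_coverage_rejected(self):
        with pytest.raises(ZeroDivisionError):
            site_variant_frequency(SitePileup(1, "G"), "A")

    def test_var_equal_to_ref_rejected(self):
        with pytest.raises(ValueError):
            site_variant_frequency(SitePileup(1, "G", {"G": 10}), "G")


class TestNonRefFrequency:
    def test_pure_reference_site(self):
        assert per_site_nonref_frequency(SitePileup(1, "A", {"A": 50})) == 0.0

    def test_two_alt_alleles_sum(self):
        p = SitePileup(1, "A", {"A": 90, "C": 5, "G": 5})
        assert per_site_nonref_frequency(p) == pytest.approx(0.1)

    def test_fully_non_reference_site(self):
        p = SitePileup(1, "G", {"G": 0, "T": 447})
        assert per_site_nonref_frequency(p) == 1.0


def test_line_variant_stats_hand_computed():
    piles = [
        SitePileup(1, "A", {"A": 100}),
        SitePileup(2, "A", {"A": 80, "C": 20}),
    ]
    mean, sd = line_variant_stats(piles)
    assert mean == pytest.approx(0.1)
    assert sd == pytest.approx(np.sqrt(0.02), rel=1e-12)  # 0.1414...


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "ref,var,expected",
        [("G", "T", "SNP"), ("A", "-", "deletion"), ("-", "T", "insertion")],
    )
    def test_allele_shapes(self, ref, var, expected):
        assert classify_variant(ref, var) == expected

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            classify_variant("A", "A")

    def test_multi_base_substitution_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            classify_variant("AC", "GT")


def profile_with_variant(var_count=30, site_cov=300, n_sites=60, base_cov=300):
    """A line whose background is clean except one candidate site."""
    piles = [SitePileup(i + 1, "A", {"A": base_cov}) for i in range(n_sites)]
    piles[10] = SitePileup(11, "A", {"A": site_cov - var_count, "T": var_count})
    return LineProfile("L", piles)


class TestFilterRules:
    def test_clean_planted_variant_passes_all_rules(self):
        calls = call_heteroplasmies(profile_with_variant())
        (c,) = [c for c in calls if c.var_count]
        assert c.passed and c.filter_label == "PASS"
        assert c.frequency == pytest.approx(0.1)

    def test_five_supporting_reads_fail_the_count_rule_only(self):
        calls = call_heteroplasmies(profile_with_variant(var_count=5))
        (c,) = [c for c in calls if c.var_count]
        assert not c.filter_flags["min_count"]
        assert c.filter_flags["vf_thresh"]
        assert c.filter_label == "min_count"

    def test_six_reads_is_the_inclusive_boundary(self):
        calls = call_heteroplasmies(profile_with_variant(var_count=6))
        (c,) = [c for c in calls if c.var_count]
        assert c.filter_flags["min_count"]

    def test_site_two_sd_above_mean_coverage_fails_the_window_rule(self):
        prof = profile_with_variant()
        target = prof.cov_mean + 2 * prof.cov_sd + 1
        calls = call_heteroplasmies(profile_with_variant(site_cov=int(target)))
        (c,) = [c for c in calls if c.var_count]
        assert not c.filter_flags["cov_window"]

    def test_coverage_window_is_two_sided(self):
        # a coverage trough fails just like a spike
        prof = profile_with_variant(site_cov=100)
        calls = call_heteroplasmies(prof)
        (c,) = [c for c in calls if c.var_count]
        assert not c.filter_flags["cov_window"]

    def test_frequency_rule_is_strict_inequality(self):
        # two-site line where the variant frequency equals the threshold
        piles = [
            SitePileup(1, "A", {"A": 100}),
            SitePileup(2, "A", {"A": 100}),
            SitePileup(3, "A", {"A": 90, "T": 10}),
        ]
        prof = LineProfile("L", piles)
        floor = prof.vf_mean + 2 * prof.vf_sd
        calls = call_heteroplasmies(prof)
        (c,) = [c for c in calls if c.var_count]
        assert c.frequency <= floor  # construction: 0.1 vs floor ~0.148
        assert not c.filter_flags["vf_thresh"]

    def test_allele_fixed_in_baseline_is_excluded(self):
        baseline = LineProfile(
            "N2",
            [
                SitePileup(i + 1, "A", {"A": 300} if i != 10 else {"A": 3, "T": 297})
                for i in range(60)
            ],
        )
        calls = call_heteroplasmies(profile_with_variant(), baseline_profiles=[baseline])
        (c,) = [c for c in calls if c.var_count]
        assert c.baseline_excluded and not c.filter_flags["baseline"]
        assert c.filter_label == "baseline"

    def test_segregating_baseline_allele_is_not_excluded(self):
        baseline = LineProfile(
            "N2",
            [
                SitePileup(i + 1, "A", {"A": 300} if i != 10 else {"A": 150, "T": 150})
                for i in range(60)
            ],
        )
        calls = call_heteroplasmies(profile_with_variant(), baseline_profiles=[baseline])
        (c,) = [c for c in calls if c.var_count]
        assert c.filter_flags["baseline"]

    def test_masked_sites_are_never_called(self):
        from mitodrift import RegionMask

        piles = [SitePileup(i + 1, "A", {"A": 300}) for i in range(40)]
        piles[5] = SitePileup(6, "A", {"A": 200, "T": 100})
        prof = LineProfile("L", piles, mask=RegionMask([(6, 6)]))
        assert call_heteroplasmies(prof) == []


def random_profile(rng):
    n = 40
    piles = []
    for i in range(n):
        cov = int(rng.integers(100, 500))
        var = int(rng.integers(0, 30))
        piles.append(SitePileup(i + 1, "A", {"A": cov - var, "T": var}))
    return LineProfile("L", piles)


def test_tightening_any_threshold_never_grows_the_pass_set():
    rng = np.random.default_rng(42)
    base = FilterThresholds()
    tighter = [
        FilterThresholds(min_var_count=10),
        FilterThresholds(cov_sd_window=0.5),
        FilterThresholds(vf_sd_multiple=3.0),
        FilterThresholds(baseline_fixed_cutoff=0.90),
    ]
    for _ in range(25):
        prof = random_profile(rng)
        baseline = random_profile(rng)
        passed = {
            (c.position, c.var_allele)
            for c in call_heteroplasmies(prof, base, [baseline])
            if c.passed
        }
        for th in tighter:
            tightened = {
                (c.position, c.var_allele)
                for c in call_heteroplasmies(prof, th, [baseline])
                if c.passed
            }
            assert tightened <= passed
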