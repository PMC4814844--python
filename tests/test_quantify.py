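"""Subset Poisson estimators, frequencies, merging, background subtraction."""

import math

import numpy as np
import pytest

from dropquant import (
    ClusterCounts,
    SaturatedWellError,
    TemplateMix,
    assign_clusters,
    frequencies_from_copies,
    merge_wells,
    poisson_lambda,
    quantify_classes,
    simulate_well,
    subtract_background,
)


class TestPoissonLambda:
    def test_all_negative_is_zero_rate(self):
        rate = poisson_lambda(10_000, 10_000)
        assert rate.lam == 0.0
        assert rate.ci_low == 0.0
        assert rate.ci_high == 0.0

    def test_e_minus_one_fraction(self):
        rate = poisson_lambda(3679, 10_000)
        assert abs(rate.lam - 1.0) < 1e-3
        assert rate.ci_low < rate.lam < rate.ci_high

    def test_monte_carlo_recovery(self, quiet_model):
        lam_true = 0.5
        well = simulate_well(TemplateMix(lambda_wt=lam_true), 10**6, quiet_model, seed=8)
        n_neg = int(np.sum(well.truth[:, 0] == 0))
        rate = poisson_lambda(n_neg, 10**6)
        assert abs(rate.lam - lam_true) < 3 * rate.se

    def test_saturated_and_invalid(self):
        with pytest.raises(SaturatedWellError):
            poisson_lambda(0, 100)
        with pytest.raises(ValueError):
            poisson_lambda(101, 100)


def oracle_quantify(e, n, w, h):
    """Direct composition of the subset definitions with the base formula;
    kept independent of the implementation under test."""
    lam = lambda neg, tot: -math.log(neg / tot)
    return (
        lam(e + n, e + n + w),          # WT
        lam(e + n + w, e + n + w + h),  # HDR
        lam(e, e + n),                  # NHEJ
    )


class TestQuantifyClasses:
    def test_closed_form_wt_only(self):
        est = quantify_classes(ClusterCounts(9000, 0, 1000, 0))
        assert est.wt.rate.lam == pytest.approx(math.log(10_000 / 9_000))
        assert est.hdr.rate.lam == 0.0
        assert est.nhej.rate.lam == 0.0
        assert est.wt.frequency == pytest.approx(100.0)

    def test_all_empty_flagged_undefined(self):
        est = quantify_classes(ClusterCounts(5000, 0, 0, 0))
        assert est.wt.rate.lam == 0.0
        assert all(math.isnan(f) for f in est.frequencies)

    def test_saturated_well_rejected(self):
        with pytest.raises(SaturatedWellError):
            quantify_classes(ClusterCounts(0, 10, 100, 5))

    def test_exhaustive_small_count_oracle_equivalence(self):
        """All cluster-count compositions with n_total <= 50 match the
        direct subset-formula evaluation."""
        checked = 0
        for total in range(1, 51):
            for e in range(1, total + 1):
                for n in range(total - e + 1):
                    for w in range(total - e - n + 1):
                        h = total - e - n - w
                        est = quantify_classes(ClusterCounts(e, n, w, h))
                        lw, lh, ln = oracle_quantify(e, n, w, h)
                        assert est.wt.rate.lam == pytest.approx(lw, abs=1e-12)
                        assert est.hdr.rate.lam == pytest.approx(lh, abs=1e-12)
                        assert est.nhej.rate.lam == pytest.approx(ln, abs=1e-12)
                        checked += 1
        assert checked > 100_000

    @pytest.mark.parametrize("lam", [0.01, 0.1, 0.5, 1.0, 2.0])
    def test_subset_estimators_consistent(self, lam, quiet_model):
        """Recovered per-class rates fall within 3 SE of truth at 10^6
        droplets, across the rate grid, with all three classes loaded."""
        mix = TemplateMix(lam, lam / 2, lam / 4)
        well = simulate_well(mix, 10**6, quiet_model, seed=int(lam * 100))
        counts, _ = assign_clusters(well)
        est = quantify_classes(counts)
        for cls, truth in (("wt", lam), ("hdr", lam / 2), ("nhej", lam / 4)):
            rate = getattr(est, cls).rate
            assert abs(rate.lam - truth) < 3 * rate.se, cls

    def test_frequencies_normalize(self, spike_well):
        counts, _ = assign_clusters(spike_well)
        est = quantify_classes(counts)
        assert sum(est.frequencies) == pytest.approx(100.0, abs=1e-9)

    def test_nhej_rate_monotone_in_nhej_count(self):
        prev = -1.0
        for n_nhej in (10, 50, 200, 1000):
            est = quantify_classes(ClusterCounts(5000, n_nhej, 4000, 20))
            assert est.nhej.rate.lam > prev
            prev = est.nhej.rate.lam


class TestFrequenciesFromCopies:
    def test_worked_example(self):
        hdr, nhej, wt = frequencies_from_copies(79, 677, 11_971)
        assert round(hdr, 1) == 0.6
        assert round(nhej, 1) == 5.3
        assert round(wt, 1) == 94.1

    def test_pure_wt(self):
        assert frequencies_from_copies(0, 0, 1234)[2] == 100.0

    def test_symmetry(self):
        assert frequencies_from_copies(5, 5, 5) == pytest.approx((100 / 3,) * 3)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            frequencies_from_copies(0, 0, 0)


class TestMergeWells:
    def test_merge_scales_counts_not_rates(self):
        a = ClusterCounts(9000, 100, 900, 10)
        merged = merge_wells([a, a])
        assert merged.n_empty == 18_000
        est_a, est_m = quantify_classes(a), quantify_classes(merged)
        for cls in ("wt", "hdr", "nhej"):
            assert getattr(est_m, cls).rate.lam == pytest.approx(
                getattr(est_a, cls).rate.lam)

    def test_single_well_identity(self):
        a = ClusterCounts(10, 1, 2, 3, 4)
        assert merge_wells([a]) == a

    def test_merged_se_shrinks_like_sqrt2(self, quiet_model):
        mix = TemplateMix(1.8, 0.02, 0.02)
        counts = []
        for seed in (1, 2):
            w = simulate_well(mix, 15_000, quiet_model, seed=seed)
            counts.append(assign_clusters(w)[0])
        se_single = quantify_classes(counts[0]).nhej.rate.se
        se_merged = quantify_classes(merge_wells(counts)).nhej.rate.se
        assert se_merged == pytest.approx(se_single / math.sqrt(2), rel=0.15)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            merge_wells([])


@pytest.mark.parametrize("edited,control,expected", [
    (0.5, 0.1, 0.4),
    (0.05, 0.1, 0.0),
    (0.37, 0.0, 0.37),
])
def test_subtract_background(edited, control, expected):
    assert subtract_background(edited, control) == pytest.approx(expected)
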