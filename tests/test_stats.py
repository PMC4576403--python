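"""Fisher, likelihood ratios, Kruskal-Wallis, Youden cutoffs, stratification."""

import itertools
import math

import numpy as np
import pytest
from conftest import fisher_oracle, youden_oracle

from cytogi.clinical import PatientRecord
from cytogi.stats import (
    ABOVE_FLAGS_POSITIVE,
    BELOW_FLAGS_POSITIVE,
    ContingencyTable2x2,
    crossover_detected,
    derive_band_cutoffs,
    derive_gi_cutoffs,
    fisher_exact_two_tailed,
    kruskal_wallis_two_sample,
    likelihood_ratio,
    pearson_r2,
    profiled_projection,
    stratify,
    youden_cutoff,
)


def patients(groups):
    """groups: list of (n, arm, n_remissions, gi)."""
    out, k = [], 0
    for n, arm, rem, gi in groups:
        for i in range(n):
            out.append(
                PatientRecord(
                    f"P{k + i}", arm, "remission" if i < rem else "failure", gi=gi
                )
            )
        k += n
    return out


class TestFisher:
    def test_low_band_comparison_reproduces_printed_p(self):
        assert fisher_exact_two_tailed([[16, 8], [6, 14]]) == pytest.approx(
            0.033, abs=5e-4
        )

    def test_symmetric_table_is_one(self):
        assert fisher_exact_two_tailed([[1, 1], [1, 1]]) == 1.0

    def test_perfect_separation_enumeration(self):
        assert fisher_exact_two_tailed([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_empty_margin_gives_one_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert fisher_exact_two_tailed([[0, 0], [3, 4]]) == 1.0
        assert "margin" in caplog.text

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)

    def test_matches_independent_implementation_on_random_tables(self, rng):
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(0, 40, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            mine = fisher_exact_two_tailed([[a, b], [c, d]])
            assert mine == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)


class TestLikelihoodRatio:
    @pytest.mark.parametrize(
        "a,m,b,n,lr,lo,hi",
        [
            (14, 34, 6, 60, 4.12, 1.74, 9.72),
            (10, 34, 2, 60, 8.82, 2.05, 37.95),
            (25, 60, 5, 34, 2.83, 1.20, 6.72),
            (18, 45, 9, 48, 2.13, 1.07, 4.25),
        ],
    )
    def test_printed_rows_reproduced_at_two_decimals(self, a, m, b, n, lr, lo, hi):
        res = likelihood_ratio(a, m, b, n)
        assert round(res.lr, 2) == lr
        assert round(res.ci_low, 2) == lo
        assert round(res.ci_high, 2) == hi

    def test_identical_proportions_give_unity(self):
        for k, m in [(1, 5), (3, 7), (10, 10)]:
            assert likelihood_ratio(k, m, k, m).lr == 1.0

    def test_ci_brackets_the_estimate(self, rng):
        for _ in range(30):
            m, n = (int(v) for v in rng.integers(2, 80, size=2))
            a = int(rng.integers(1, m + 1))
            b = int(rng.integers(1, n + 1))
            res = likelihood_ratio(a, m, b, n)
            assert res.ci_low <= res.lr <= res.ci_high
            assert res.ci_low > 0

    def test_boundary_counts_flagged_not_raised(self, caplog):
        with caplog.at_level("WARNING"):
            res = likelihood_ratio(0, 34, 6, 60)
        assert res.lr == 0.0 and math.isnan(res.ci_low)
        res = likelihood_ratio(6, 34, 0, 60)
        assert math.isinf(res.lr)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio(5, 4, 1, 10)


class TestKruskalWallis:
    def test_identical_groups_give_zero_statistic(self):
        h, p = kruskal_wallis_two_sample([1, 2, 3], [3, 1, 2])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_values_give_p_one(self):
        assert kruskal_wallis_two_sample([5, 5], [5, 5, 5]) == (0.0, 1.0)

    def test_chi_square_p_near_exact_permutation_p_on_complete_separation(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        h_obs, p = kruskal_wallis_two_sample(x, y)
        # exhaustive permutation oracle over all C(6,3)=20 splits
        values = x + y
        hs = []
        for comb in itertools.combinations(range(6), 3):
            xs = [values[i] for i in comb]
            ys = [values[i] for i in range(6) if i not in comb]
            hs.append(kruskal_wallis_two_sample(xs, ys)[0])
        exact_p = np.mean([h >= h_obs - 1e-12 for h in hs])
        assert exact_p == pytest.approx(0.1)  # the two extreme splits
        assert abs(p - exact_p) <= 0.06  # chi-square approximation error

    def test_power_against_one_sd_shift(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(500 + s)
            x = rng.normal(0, 1, 200)
            y = rng.normal(1, 1, 200)
            hits += kruskal_wallis_two_sample(x, y)[1] < 0.01
        assert hits >= 19

    def test_h_is_monotone_in_squared_rank_sum_deviation(self, rng):
        # without ties, H is proportional to (W - E[W])^2 for fixed sizes
        from scipy.stats import rankdata

        n1, n2 = 12, 17
        stats = []
        for _ in range(30):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            ranks = rankdata(np.concatenate([x, y]))
            w = ranks[:n1].sum()
            dev = (w - n1 * (n1 + n2 + 1) / 2) ** 2
            stats.append((dev, kruskal_wallis_two_sample(x, y)[0]))
        stats.sort()
        hs = [h for _, h in stats]
        assert hs == sorted(hs)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_two_sample([], [1.0])


class TestPearsonR2:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        assert pearson_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_constructed_zero_covariance(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = x**2  # symmetric about 0 -> cov(x, y) = 0
        assert pearson_r2(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_known_correlation_recovered(self):
        rng = np.random.default_rng(77)
        n = 10_000
        x = rng.normal(size=n)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=n)
        assert pearson_r2(x, y) == pytest.approx(0.64, abs=0.03)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pearson_r2([1.0, 2.0], [1.0, 2.0])


class TestYouden:
    def test_perfect_separation(self):
        res = youden_cutoff([1, 2, 3, 4], [True, True, False, False],
                            BELOW_FLAGS_POSITIVE)
        assert res.threshold == 2.5
        assert res.youden_j == pytest.approx(1.0)
        assert res.sensitivity == res.specificity == 1.0

    @pytest.mark.parametrize("direction", [BELOW_FLAGS_POSITIVE, ABOVE_FLAGS_POSITIVE])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_threshold_search(self, direction, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        values = rng.normal(size=n)
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        res = youden_cutoff(values, labels, direction)
        j_star, flagged_star, _ = youden_oracle(values, labels, direction)
        assert res.youden_j == pytest.approx(j_star, abs=1e-12)
        assert res.n_flagged == flagged_star

    def test_j_small_under_label_permutation(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(900 + s)
            values = rng.normal(size=200)
            labels = rng.permutation([True] * 80 + [False] * 120)
            res = youden_cutoff(values, labels, BELOW_FLAGS_POSITIVE)
            hits += res.youden_j < 0.25
        assert hits >= 18

    def test_invariant_j_equals_sens_plus_spec_minus_one(self, rng):
        values = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        labels[0], labels[1] = True, False
        res = youden_cutoff(values, labels, ABOVE_FLAGS_POSITIVE)
        assert res.youden_j == pytest.approx(res.sensitivity + res.specificity - 1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_cutoff([1.0, 2.0], [True, True], BELOW_FLAGS_POSITIVE)

    def test_same_arm_failure_and_success_sweeps_are_mirror_images(self, rng):
        """Maximizing J for 'low GI flags failure' and 'high GI flags
        success' on the same patients is the same optimization; with a
        unique maximum both return the same threshold."""
        pats = patients([(40, "RTX", 0, None)])
        gis = rng.normal(20, 35, size=40)
        for i, p in enumerate(pats):
            pats[i] = PatientRecord(
                p.subject_id, "RTX",
                "remission" if rng.random() < 0.4 + 0.005 * gis[i] else "failure",
                gi=float(gis[i]),
            )
        if len({p.outcome for p in pats}) < 2:
            pytest.skip("degenerate draw")
        fail_cut, success_cut = derive_gi_cutoffs(pats)
        assert fail_cut.youden_j == pytest.approx(success_cut.youden_j, abs=1e-12)
        assert fail_cut.threshold == success_cut.threshold


class TestStratify:
    # printed low/middle/high composition: (n, arm, remissions, gi placed in band)
    PAPER_GROUPS = [
        (20, "RTX", 6, -20.0),
        (24, "CYC", 16, -20.0),
        (44, "RTX", 29, 10.0),
        (42, "CYC", 23, 10.0),
        (30, "RTX", 25, 60.0),
        (27, "CYC", 9, 60.0),
    ]

    def test_band_sizes_and_rates_match_printed_stratification(self):
        strata = stratify(patients(self.PAPER_GROUPS), -9.25, 47.6)
        by = {s.band: s for s in strata}
        assert (by["low"].n, by["middle"].n, by["high"].n) == (44, 86, 57)
        assert round(100 * by["low"].rate_cyc) == 67
        assert round(100 * by["low"].rate_rtx) == 30
        assert round(100 * by["high"].rate_rtx) == 83
        assert round(100 * by["high"].rate_cyc) == 33
        assert round(100 * by["middle"].rate_rtx) == 66
        assert round(100 * by["middle"].rate_cyc) == 55

    def test_between_arm_p_values_match_printed(self):
        by = {s.band: s for s in stratify(patients(self.PAPER_GROUPS), -9.25, 47.6)}
        assert by["low"].p_value == pytest.approx(0.033, abs=5e-4)
        assert by["high"].p_value == pytest.approx(0.0002, abs=5e-5)
        assert by["middle"].p_value == pytest.approx(0.38, abs=5e-3)

    def test_band_boundaries_are_inclusive(self):
        pats = patients([(2, "RTX", 1, -9.25), (2, "CYC", 1, 47.6), (2, "RTX", 1, 0.0)])
        by = {s.band: s for s in stratify(pats, -9.25, 47.6)}
        assert by["low"].n == 2 and by["high"].n == 2 and by["middle"].n == 2

    def test_conservation_of_patients_and_remissions(self, rng):
        pats = patients(
            [
                (int(rng.integers(1, 30)), arm, 0, float(g))
                for arm in ("RTX", "CYC")
                for g in rng.normal(10, 40, size=4)
            ]
        )
        pats = [
            PatientRecord(
                p.subject_id, p.arm,
                "remission" if rng.random() < 0.5 else "failure", gi=p.gi,
            )
            for p in pats
        ]
        strata = stratify(pats, -9.25, 47.6)
        assert sum(s.n for s in strata) == len(pats)
        assert sum(s.remissions for s in strata) == sum(p.remitted for p in pats)

    def test_infinite_cuts_reduce_to_unstratified_comparison(self):
        pats = patients([(20, "RTX", 12, 5.0), (20, "CYC", 8, 5.0)])
        strata = stratify(pats, -1e9, 1e9)
        by = {s.band: s for s in strata}
        assert by["middle"].n == 40
        assert by["low"].n == by["high"].n == 0
        assert by["low"].p_value is None
        unstrat = fisher_exact_two_tailed([[8, 12], [12, 8]])
        assert by["middle"].p_value == pytest.approx(unstrat)

    def test_cuts_must_be_ordered(self):
        with pytest.raises(ValueError):
            stratify(patients([(4, "RTX", 2, 0.0)]), 5.0, 5.0)


class TestCrossoverAndBandCutoffs:
    def test_crossover_detected_on_printed_pattern(self):
        strata = stratify(patients(TestStratify.PAPER_GROUPS), -9.25, 47.6)
        assert crossover_detected(strata)

    def test_no_crossover_when_bands_agree(self):
        pats = patients(
            [(30, "RTX", 25, -20.0), (30, "CYC", 5, -20.0),
             (30, "RTX", 25, 60.0), (30, "CYC", 5, 60.0),
             (10, "RTX", 5, 10.0), (10, "CYC", 5, 10.0)]
        )
        assert not crossover_detected(stratify(pats, -9.25, 47.6))

    def test_band_cutoffs_bracket_opposed_arm_signals(self):
        rng = np.random.default_rng(4)
        pats = []
        for i in range(300):
            gi = float(rng.normal(20, 35))
            arm = "RTX" if i % 2 else "CYC"
            p_rem = 1 / (1 + np.exp(-(0.05 if arm == "RTX" else -0.05) * (gi - 20)))
            pats.append(
                PatientRecord(
                    f"P{i}", arm,
                    "remission" if rng.random() < p_rem else "failure", gi=gi,
                )
            )
        lo, hi = derive_band_cutoffs(pats)
        assert lo <= hi
        assert -40 < lo and hi < 80  # near the true crossover at GI ~ 20


class TestProjection:
    def test_printed_projection_reproduced(self):
        strata = stratify(patients(TestStratify.PAPER_GROUPS), -9.25, 47.6)
        proj = profiled_projection(strata)
        assert proj.projected_remissions == 129
        assert proj.observed_remissions == 108
        assert round(100 * proj.projected_rate) == 69
        assert round(100 * proj.observed_rate) == 58
        assert proj.p_value == pytest.approx(0.0317, abs=5e-5)

    def test_empty_outer_bands_project_observed_totals(self):
        pats = patients([(20, "RTX", 12, 5.0), (20, "CYC", 8, 5.0)])
        proj = profiled_projection(stratify(pats, -1e9, 1e9))
        assert proj.projected_remissions == proj.observed_remissions == 20
        assert proj.p_value == 1.0

    def test_projection_monotone_in_high_band_rtx_rate(self):
        base = patients(TestStratify.PAPER_GROUPS)
        proj1 = profiled_projection(stratify(base, -9.25, 47.6))
        better = [
            PatientRecord(p.subject_id, p.arm, "remission", gi=p.gi)
            if p.arm == "RTX" and p.gi == 60.0
            else p
            for p in base
        ]
        proj2 = profiled_projection(stratify(better, -9.25, 47.6))
        assert proj2.projected_remissions >= proj1.projected_remissions

    def test_populated_band_with_empty_favored_arm_is_an_error(self):
        pats = patients([(10, "RTX", 5, -20.0), (20, "RTX", 10, 10.0),
                         (10, "RTX", 8, 60.0), (10, "CYC", 5, 10.0)])
        with pytest.raises(ValueError, match="CYC arm empty"):
            profiled_projection(stratify(pats, -9.25, 47.6))
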