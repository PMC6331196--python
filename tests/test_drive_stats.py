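"""Exact tests, loss-rate estimation and mechanism discrimination."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octadrive.cross_simulator import CrossConfig, with_fixed_female
from octadrive.drive_stats import (
    binomial_drive_test,
    contingency_test,
    discriminate_mechanisms,
    estimate_loss_rate,
    label_counts_from_records,
    loss_percentage,
    predict_patterns,
    randomize_one_per_ascus,
    significance_stars,
)
from octadrive.errors import DegenerateTableError, NoDataError
from octadrive.segregation_classifier import classify_octad
from octadrive.tetrad_qc import verify_ascus


def binomial_pvalue_by_enumeration(k: int, n: int) -> float:
    """Independent oracle: sum the point probabilities of all outcomes no
    more likely than k under Binomial(n, 1/2)."""
    probs = [comb(n, i) / 2**n for i in range(n + 1)]
    p_obs = probs[k]
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-12)))


def fisher_pvalue_by_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Independent 2x2 oracle: hypergeometric enumeration over all tables
    with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = comb(r1, x) * comb(r2, c1 - x) / denom
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


class TestBinomialDriveTest:
    def test_null_expectation_gives_p_one(self):
        assert binomial_drive_test(12, 24).p_value == pytest.approx(1.0)

    def test_six_of_twentyfour(self):
        # 2 * sum_{i<=6} C(24,i) / 2^24
        expected = 2 * sum(comb(24, i) for i in range(7)) / 2**24
        assert binomial_drive_test(6, 24).p_value == pytest.approx(expected)
        assert expected == pytest.approx(0.0227, abs=5e-5)

    def test_extreme_point(self):
        assert binomial_drive_test(24, 24).p_value == pytest.approx(2 * 0.5**24)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binomial_drive_test(5, 4)
        with pytest.raises(ValueError):
            binomial_drive_test(0, 0)

    def test_matches_enumeration_for_all_small_n(self):
        for n in range(1, 31):
            for k in range(n + 1):
                assert binomial_drive_test(k, n).p_value == pytest.approx(
                    binomial_pvalue_by_enumeration(k, n), rel=1e-9
                ), (k, n)


class TestContingencyTest:
    def test_diagonal_two_by_two(self):
        result = contingency_test([[5, 0], [0, 5]])
        assert result.statistic_name == "fisher_exact"
        assert result.p_value == pytest.approx(2 / 252)

    def test_identical_rows_give_p_one(self):
        assert contingency_test([[7, 3], [7, 3]]).p_value == pytest.approx(1.0)

    def test_large_table_switches_to_chi_squared(self):
        small = contingency_test([[5, 2], [2, 5]])
        big = contingency_test([[5000, 2000], [2000, 5000]])
        assert small.statistic_name == "fisher_exact"
        assert big.statistic_name == "chi_squared"

    def test_degenerate_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            contingency_test([[0, 0], [3, 4]])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.integers(0, 10), b=st.integers(0, 10),
        c=st.integers(0, 10), d=st.integers(0, 10),
    )
    def test_fisher_matches_hypergeometric_enumeration(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            return  # degenerate margins are rejected, tested above
        result = contingency_test([[a, b], [c, d]])
        assert result.statistic_name == "fisher_exact"
        assert result.p_value == pytest.approx(
            fisher_pvalue_by_enumeration(a, b, c, d), rel=1e-6
        )


class TestRandomizeOnePerAscus:
    def _table(self, n_asci=24, spores_per=8):
        rows = []
        for a in range(n_asci):
            for s in range(spores_per):
                rows.append({"ascus_id": f"A{a:03d}", "spore_id": f"A{a:03d}.s{s}"})
        return pd.DataFrame(rows)

    def test_one_row_per_ascus(self):
        table = self._table()
        picked = randomize_one_per_ascus(table, seed=3)
        assert len(picked) == 24
        assert picked["ascus_id"].is_unique

    def test_singleton_input_unchanged(self):
        table = self._table(spores_per=1)
        picked = randomize_one_per_ascus(table, seed=3)
        assert picked.reset_index(drop=True).equals(table)

    def test_reproducible(self):
        table = self._table()
        a = randomize_one_per_ascus(table, seed=11)
        b = randomize_one_per_ascus(table, seed=11)
        assert a.equals(b)


class TestLossRate:
    def _records(self, loss_rate, n_asci, seed, parents, pairing):
        config = CrossConfig(
            parent1=parents[0], parent2=parents[1], loss_rate=loss_rate,
            n_asci=n_asci, seed=seed,
        )
        octads = with_fixed_female(config, 0)
        return [r for o in octads for r in classify_octad(o, pairing)]

    def test_zero_loss_gives_zero_rate(self, parents, pairing):
        est = estimate_loss_rate(self._records(0.0, 30, 41, parents, pairing))
        assert est.rate == 0.0
        assert est.heterogeneity is None

    def test_recovers_rate_within_99pct_binomial_interval(self, parents, pairing):
        """At ~10,078 paired instances and loss probability 0.037 the
        estimate must fall inside the exact 99% binomial interval."""
        p = 0.037
        records = self._records(p, 840, 43, parents, pairing)
        paired = [r for r in records if r.pairing_status == "paired"]
        est = estimate_loss_rate(paired)
        assert est.instances == 2 * len(paired) == 10080
        from scipy.stats import binom

        lo = binom.ppf(0.005, est.instances, p) / est.instances
        hi = binom.ppf(0.995, est.instances, p) / est.instances
        assert lo <= est.rate <= hi

    def test_equal_proportions_give_null_heterogeneity(self):
        # constructed records: every chromosome with identical loss counts
        rows = []
        for chrom in ("chr14", "chr15", "chr16"):
            for i in range(50):
                deficient = i < 5
                rows.append(
                    {
                        "ascus_id": f"A{i}",
                        "chromosome": chrom,
                        "pairing_status": "paired",
                        "carriers_p1": 2 if deficient else 4,
                        "carriers_p2": 4,
                        "disomic_spores": 0,
                        "absent_spores": 2 if deficient else 0,
                        "label": "loss_deviation" if deficient else "mendelian_4_4",
                        "expected_carriers": 4,
                        "n_spores": 8,
                    }
                )
        est = estimate_loss_rate(pd.DataFrame(rows))
        assert est.heterogeneity is not None
        assert est.heterogeneity.p_value == pytest.approx(1.0)

    def test_no_paired_records_rejected(self):
        with pytest.raises(NoDataError):
            estimate_loss_rate(pd.DataFrame())

    def test_worked_percentage(self):
        assert loss_percentage(377, 10078) == 3.7


class TestPredictPatterns:
    def test_closed_forms(self):
        assert predict_patterns("mendelian", "female_unpaired").carrier_count_distribution == {4: 1.0}
        assert predict_patterns("female_drive", "female_unpaired").carrier_count_distribution == {8: 1.0}
        assert predict_patterns("female_drive", "male_unpaired").carrier_count_distribution == {4: 1.0}
        half = predict_patterns(
            "female_drive", "female_unpaired", drive_penetrance=0.25
        ).carrier_count_distribution
        assert half == {8: 0.25, 4: 0.75}

    def test_preferential_support_never_exceeds_four(self):
        for bias in (0.5, 0.8, 1.0):
            pred = predict_patterns(
                "preferential_segregation", "female_unpaired",
                preferential_bias=bias, loss_rate=0.1, n_sim=300, seed=2,
            )
            assert max(pred.carrier_count_distribution) <= 4
            assert sum(pred.carrier_count_distribution.values()) == pytest.approx(1.0)

    def test_spore_killing_prediction_incomplete(self):
        pred = predict_patterns("spore_killing", "female_unpaired")
        assert pred.octad_complete is False

    def test_monte_carlo_matches_analytic_mendelian(self):
        r, d = 0.2, 0.3
        pred = predict_patterns(
            "mendelian", "female_unpaired", loss_rate=r,
            nondisjunction_rate=d, n_sim=3000, seed=5,
        )
        assert pred.mc_stderr is not None
        assert pred.carrier_count_distribution[4] == pytest.approx(
            (1 - r) * (1 - d), abs=4 * pred.mc_stderr
        )


class TestDiscriminateMechanisms:
    def _labels(self, mechanism, parents, pairing, **kwargs):
        config = CrossConfig(
            parent1=parents[0], parent2=parents[1], mechanism=mechanism,
            n_asci=200, seed=59, **kwargs,
        )
        octads = with_fixed_female(config, 0)
        complete = np.mean([verify_ascus(o).valid for o in octads])
        records = [r for o in octads for r in classify_octad(o, pairing)]
        return label_counts_from_records(records), complete

    def test_drive_data_leaves_only_female_drive(self, parents, pairing):
        counts, complete = self._labels("female_drive", parents, pairing)
        result = discriminate_mechanisms(counts, complete)
        assert result.consistent == {"female_drive"}
        assert set(result.excluded) == {
            "mendelian",
            "preferential_segregation",
            "premeiotic_amplification",
            "spore_killing",
        }

    def test_mendelian_data_keeps_mendelian(self, parents, pairing):
        counts, complete = self._labels("mendelian", parents, pairing)
        result = discriminate_mechanisms(counts, complete)
        assert "mendelian" in result.consistent
        assert "spore_killing" in result.excluded
        assert result.notes  # zero-penetrance indistinguishability is flagged

    def test_recovery_of_generating_mechanism(self, parents, pairing):
        cases = [
            ("mendelian", {}),
            ("female_drive", {}),
            ("preferential_segregation", {}),
            ("premeiotic_amplification", {"premeiotic_copy_loss": False}),
            ("spore_killing", {"killer_chromosome": "chr18"}),
        ]
        for mechanism, kwargs in cases:
            counts, complete = self._labels(mechanism, parents, pairing, **kwargs)
            result = discriminate_mechanisms(counts, complete)
            assert mechanism in result.consistent, mechanism

    def test_premeiotic_disomy_excess_excludes_meiotic_drive(self, parents, pairing):
        counts, complete = self._labels(
            "premeiotic_amplification", parents, pairing,
            premeiotic_copy_loss=False,
        )
        result = discriminate_mechanisms(counts, complete)
        assert result.consistent == {"premeiotic_amplification"}
        assert "female_drive" in result.excluded

    def test_empty_counts_rejected(self):
        with pytest.raises(NoDataError):
            discriminate_mechanisms({}, True)


def test_significance_stars_thresholds():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(0.0004) == "***"
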