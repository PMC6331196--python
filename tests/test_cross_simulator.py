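"""Cross layout, sexual roles and the meiosis/octad generator."""

import numpy as np
import pytest
from scipy import stats as sps

from octadrive.cross_simulator import (
    CrossConfig,
    assign_sexual_roles,
    build_cross,
    female_probability,
    simulate_experiment,
    simulate_octad,
    with_fixed_female,
)
from octadrive.errors import ConfigError, IncompatibleCrossError
from octadrive.strains import ipo323, ipo323_deletion, ipo94269


class TestBuildCross:
    def test_reference_cross_partition(self, parents):
        pm = build_cross(*parents)
        assert pm.unpaired_from_p1 == {"chr18", "chr20"}
        assert pm.unpaired_from_p2 == set()
        assert pm.paired == {"chr14", "chr15", "chr16", "chr17", "chr19", "chr21"}

    def test_deletion_strain_creates_reciprocal_unpaired(self):
        pm = build_cross(ipo323_deletion("chr14"), ipo94269())
        assert pm.unpaired_from_p2 == {"chr14"}
        assert pm.unpaired_from_p1 == {"chr18", "chr20"}
        assert "chr14" not in pm.paired

    def test_same_mating_type_is_incompatible(self):
        with pytest.raises(IncompatibleCrossError):
            build_cross(ipo323(), ipo323_deletion("chr14"))

    def test_partition_is_disjoint_and_complete(self, parents):
        pm = build_cross(*parents)
        sets = [pm.paired, pm.unpaired_from_p1, pm.unpaired_from_p2]
        assert sum(len(s) for s in sets) == len(set().union(*sets))
        assert set().union(*sets) == (
            parents[0].supernumerary_complement
            | parents[1].supernumerary_complement
        )

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ConfigError):
            ipo323_deletion("chr99")


class TestSexualRoles:
    def test_equal_density_is_symmetric(self):
        assert female_probability(1e7, 1e7) == pytest.approx(0.5)

    def test_lower_density_parent_favoured_as_female(self):
        # parent 1 at the lower density must be female more often than not
        for d1, d2 in [(1e5, 1e7), (1e6, 1e7), (0.5, 1.0)]:
            assert female_probability(d1, d2) > 0.5

    def test_closed_form_matches_monte_carlo(self, rng):
        p = female_probability(1e5, 1e7, 1.0)
        assert p == pytest.approx(1e7 / (1e5 + 1e7))
        n = 100_000
        hits = sum(
            assign_sexual_roles(1e5, 1e7, 1.0, rng)[0] == 0 for _ in range(n)
        )
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ConfigError):
            female_probability(0.0, 1e7)


class TestSimulateOctad:
    def test_mendelian_zero_rates_expectations(self, mendelian_config, pairing, rng):
        octad = simulate_octad(pairing, 0, mendelian_config, rng)
        assert len(octad.spores) == 8
        # unpaired chromosomes in exactly 4 of 8 spores
        for chrom in ("chr18", "chr20"):
            assert octad.carrier_count(chrom) == 4
        # each parental homolog of every paired chromosome in exactly 4
        for chrom in pairing.paired:
            assert octad.carrier_count(chrom, 0) == 4
            assert octad.carrier_count(chrom, 1) == 4
        # four twin pairs
        assert len({s.twin_id for s in octad.spores}) == 4

    def test_female_drive_transmits_to_all_eight(self, drive_config, pairing, rng):
        octad = simulate_octad(pairing, 0, drive_config, rng)
        assert octad.carrier_count("chr18") == 8
        assert octad.carrier_count("chr20") == 8
        # paired chromosomes stay Mendelian under the drive
        for chrom in pairing.paired:
            assert octad.carrier_count(chrom, 0) == 4

    def test_drive_spares_male_unpaired(self, drive_config, pairing, rng):
        octad = simulate_octad(pairing, 1, drive_config, rng)  # IPO94269 female
        assert octad.carrier_count("chr18") == 4
        assert octad.carrier_count("chr20") == 4

    def test_penetrance_zero_restores_mendelian(self, parents, pairing, rng):
        config = CrossConfig(
            parent1=parents[0], parent2=parents[1], mechanism="female_drive",
            drive_penetrance={"chr18": 0.0}, n_asci=0, seed=1,
        )
        octad = simulate_octad(pairing, 0, config, rng)
        assert octad.carrier_count("chr18") == 4  # chr14-style exception
        assert octad.carrier_count("chr20") == 8

    def test_forced_nondisjunction_paired_pattern(self, parents, pairing):
        """One chromatid crossing poles: 2 biparental disomic spores, their
        sister-product twins empty, 4 single-copy spores."""
        config = CrossConfig(
            parent1=parents[0], parent2=parents[1],
            nondisjunction_rate=1.0, n_asci=0, seed=1,
        )
        rng = np.random.default_rng(33)
        octad = simulate_octad(pairing, 0, config, rng)
        pattern = sorted(s.copies["chr21"] for s in octad.spores)
        assert pattern.count((1, 1)) == 2
        assert pattern.count((0, 0)) == 2
        assert pattern.count((1, 0)) + pattern.count((0, 1)) == 4

    def test_forced_nondisjunction_unpaired_gives_same_parent_double(
        self, parents, pairing
    ):
        config = CrossConfig(
            parent1=parents[0], parent2=parents[1],
            nondisjunction_rate=1.0, n_asci=0, seed=1,
        )
        rng = np.random.default_rng(33)
        octad = simulate_octad(pairing, 0, config, rng)
        counts = sorted(s.copies["chr18"] for s in octad.spores)
        assert counts.count((2, 0)) == 2
        assert counts.count((0, 0)) == 6

    def test_mito_uniparental(self, mendelian_config, pairing, rng):
        for female, expected in [(0, "mtIPO323"), (1, "mtIPO94269")]:
            octad = simulate_octad(pairing, female, mendelian_config, rng)
            assert {s.mito for s in octad.spores} == {expected}

    def test_twins_identical_in_every_field(self, parents, pairing):
        """Twin identity holds under every mechanism and nuisance rate."""
        for mechanism, kwargs in [
            ("mendelian", {}),
            ("female_drive", {}),
            ("preferential_segregation", {}),
            ("premeiotic_amplification", {"premeiotic_copy_loss": False}),
            ("spore_killing", {"killer_chromosome": "chr18"}),
        ]:
            config = CrossConfig(
                parent1=parents[0], parent2=parents[1], mechanism=mechanism,
                loss_rate=0.1, nondisjunction_rate=0.1, n_asci=0, seed=1,
                **kwargs,
            )
            rng = np.random.default_rng(7)
            for _ in range(20):
                octad = simulate_octad(pairing, 0, config, rng)
                by_twin = {}
                for spore in octad.spores:
                    by_twin.setdefault(spore.twin_id, []).append(spore)
                for twins in by_twin.values():
                    assert len(twins) <= 2
                    if len(twins) == 2:
                        a, b = twins
                        assert a.core_alleles == b.core_alleles
                        assert a.mito == b.mito
                        assert a.copies == b.copies

    def test_copy_conservation(self, parents, pairing, rng):
        mend = CrossConfig(parent1=parents[0], parent2=parents[1], seed=1)
        octad = simulate_octad(pairing, 0, mend, rng)
        for chrom in pairing.paired:
            assert sum(s.copies[chrom][0] for s in octad.spores) == 4
            assert sum(s.copies[chrom][1] for s in octad.spores) == 4
        for chrom in ("chr18", "chr20"):
            assert sum(s.copies[chrom][0] for s in octad.spores) == 4
        drive = CrossConfig(
            parent1=parents[0], parent2=parents[1], mechanism="female_drive",
            seed=1,
        )
        octad = simulate_octad(pairing, 0, drive, rng)
        for chrom in ("chr18", "chr20"):
            assert sum(s.copies[chrom][0] for s in octad.spores) == 8

    def test_preferential_segregation_never_exceeds_four(self, parents, pairing):
        config = CrossConfig(
            parent1=parents[0], parent2=parents[1],
            mechanism="preferential_segregation", preferential_bias=1.0,
            n_asci=0, seed=1,
        )
        rng = np.random.default_rng(11)
        for _ in range(50):
            octad = simulate_octad(pairing, 0, config, rng)
            assert octad.carrier_count("chr18") <= 4
            assert octad.carrier_count("chr20") <= 4

    def test_spore_killing_leaves_incomplete_octads(self, parents, pairing):
        config = CrossConfig(
            parent1=parents[0], parent2=parents[1], mechanism="spore_killing",
            killer_chromosome="chr18", n_asci=0, seed=1,
        )
        rng = np.random.default_rng(13)
        octad = simulate_octad(pairing, 0, config, rng)
        assert len(octad.spores) == 4
        assert all(s.has("chr18") for s in octad.spores)

    def test_carrier_count_distribution_matches_enumeration(self, parents, pairing):
        """Single unpaired chromosome: simulated carrier counts follow the
        exhaustively enumerated MI x MII outcome space.

        With loss probability r and non-disjunction probability d, the
        enumeration over {no event, loss, non-disjunction, both} gives
        P(4 carriers) = (1-r)(1-d) and P(2 carriers) = r + d - r*d
        (a loss removes one chromatid -> 2 carrier spores; non-disjunction
        sends both chromatids to one product -> 2 carrier spores).
        """
        r, d = 0.2, 0.3
        config = CrossConfig(
            parent1=parents[0], parent2=parents[1], loss_rate=r,
            nondisjunction_rate=d, n_asci=0, seed=1,
        )
        rng = np.random.default_rng(99)
        observed = {0: 0, 2: 0, 4: 0}
        n = 10_000
        for _ in range(n):
            octad = simulate_octad(pairing, 0, config, rng)
            observed[octad.carrier_count("chr18")] += 1
        assert observed[0] == 0
        expected = {2: n * (r + d - r * d), 4: n * (1 - r) * (1 - d)}
        chi2 = sps.chisquare(
            [observed[2], observed[4]], [expected[2], expected[4]]
        )
        assert chi2.pvalue > 0.01


class TestSimulateExperiment:
    def test_zero_asci_gives_empty_collection(self, parents):
        config = CrossConfig(parent1=parents[0], parent2=parents[1], n_asci=0, seed=1)
        assert simulate_experiment(config) == []

    def test_unpaired_carrier_fraction_is_exactly_half(self, single_unpaired_config):
        from dataclasses import replace

        config = replace(single_unpaired_config, n_asci=1000)
        octads = simulate_experiment(config)
        carriers = sum(o.carrier_count("chr18") for o in octads)
        assert carriers / (8 * len(octads)) == 0.5

    def test_same_seed_reproduces_octads(self, mendelian_config):
        from octadrive.io_tables import octads_to_frame

        a = octads_to_frame(simulate_experiment(mendelian_config))
        b = octads_to_frame(simulate_experiment(mendelian_config))
        assert a.equals(b)

    def test_counter_substreams_stable_under_n_asci_change(self, mendelian_config):
        from dataclasses import replace

        from octadrive.io_tables import octads_to_frame

        short = octads_to_frame(simulate_experiment(replace(mendelian_config, n_asci=5)))
        long = octads_to_frame(simulate_experiment(replace(mendelian_config, n_asci=10)))
        assert short.equals(long.iloc[: len(short)].reset_index(drop=True))

    def test_fixed_female_pins_mito(self, drive_config):
        octads = with_fixed_female(drive_config, 1)
        assert all(o.female_parent == "IPO94269" for o in octads)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"loss_rate": 1.2},
            {"nondisjunction_rate": -0.1},
            {"preferential_bias": 0.3},
            {"density_exponent": 0.0},
            {"n_asci": -1},
            {"mechanism": "telepathy"},
            {"mechanism": "spore_killing"},  # no killer chromosome
            {"drive_penetrance": 1.5},
        ],
    )
    def test_invalid_config_rejected(self, parents, kwargs):
        with pytest.raises(ConfigError):
            CrossConfig(parent1=parents[0], parent2=parents[1], seed=1, **kwargs)
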