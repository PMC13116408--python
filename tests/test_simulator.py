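import math

import numpy as np
import pytest

from twinsnv.core import Genotype, ReadSupport
from twinsnv.simulate import (
    SimulationConfig,
    genotype_quality_from_counts,
    sample_read_support,
    select_control_loci,
    simulate_panel,
    simulate_twin_pair,
    write_simulation,
)


class TestSimulationConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(p_het=0.9, p_hom_alt=0.5),
            dict(somatic_fraction_low=0.3, somatic_fraction_high=0.1),
            dict(mean_depth_trace=0),
            dict(error_rate=1.5),
            dict(n_replicates=1),
            dict(undesignable_rate=2.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_dict_round_trip(self):
        config = SimulationConfig(n_loci=100, n_postzygotic=(3, 4), seed=9)
        assert SimulationConfig.from_dict(config.to_dict()) == config

    def test_overfull_postzygotic_request_rejected(self):
        config = SimulationConfig(n_loci=10, p_het=0.5, p_hom_alt=0.4,
                                  n_postzygotic=(50, 0), n_somatic=0)
        with pytest.raises(ValueError, match="post-zygotic"):
            simulate_twin_pair(config)


class TestSampleReadSupport:
    def test_symmetric_fraction_mean_hb(self):
        rng = np.random.default_rng(42)
        n = 10_000
        balances = []
        for _ in range(n):
            support = sample_read_support(0.5, 30.0, 0.0, rng)
            if support.allelic_depth > 0:
                balances.append(support.alt_count / support.allelic_depth)
        mean = float(np.mean(balances))
        se = float(np.std(balances) / math.sqrt(len(balances)))
        assert abs(mean - 0.5) <= 3 * se

    def test_expected_alt_count_at_fixed_depth(self):
        rng = np.random.default_rng(43)
        n = 10_000
        alts = [
            sample_read_support(0.125, 40.0, 0.0, rng, fixed_depth=40).alt_count
            for _ in range(n)
        ]
        mean = float(np.mean(alts))
        se = float(np.std(alts) / math.sqrt(n))
        assert abs(mean - 5.0) <= 3 * se  # 40 x 0.125

    def test_error_reads_land_on_alt_at_one_third(self):
        rng = np.random.default_rng(44)
        n = 2_000
        alts = [
            sample_read_support(0.0, 1000.0, 0.003, rng, fixed_depth=1000).alt_count
            for _ in range(n)
        ]
        mean = float(np.mean(alts))
        se = float(np.std(alts) / math.sqrt(n))
        assert abs(mean - 1.0) <= 3 * se  # 1000 x eps / 3

    def test_depth_is_poisson_with_requested_mean(self):
        rng = np.random.default_rng(45)
        depths = [sample_read_support(0.5, 39.7, 0.002, rng).dp for _ in range(5_000)]
        mean = float(np.mean(depths))
        se = float(np.std(depths) / math.sqrt(len(depths)))
        assert abs(mean - 39.7) <= 3 * se

    def test_invalid_fraction_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_read_support(1.5, 30.0, 0.0, rng)


class TestGenotypeCaller:
    def test_overwhelming_hom_alt_capped_gq(self):
        genotype, gq = genotype_quality_from_counts(ReadSupport(0, 50, 0), 0.001)
        assert genotype is Genotype.HOM_ALT
        assert gq == 99

    def test_balanced_counts_call_het(self):
        genotype, gq = genotype_quality_from_counts(ReadSupport(25, 25, 0), 0.001)
        assert genotype is Genotype.HET
        assert gq > 0

    def test_two_read_het_gq_matches_binomial_oracle(self):
        # independent oracle: explicit binomial likelihoods for 1 alt of 2 reads
        eps = 0.001
        likelihood_het = 2 * 0.5 * 0.5
        p_hom_ref = eps / 3
        likelihood_hom_ref = 2 * p_hom_ref * (1 - p_hom_ref)
        p_hom_alt = 1 - eps
        likelihood_hom_alt = 2 * p_hom_alt * (1 - p_hom_alt)
        second = max(likelihood_hom_ref, likelihood_hom_alt)
        expected_gq = round(10 * math.log10(likelihood_het / second))

        genotype, gq = genotype_quality_from_counts(ReadSupport(1, 1, 0), eps)
        assert genotype is Genotype.HET
        assert gq == expected_gq

    def test_zero_depth_is_missing(self):
        genotype, gq = genotype_quality_from_counts(ReadSupport(0, 0, 0), 0.001)
        assert genotype is Genotype.MISSING
        assert gq == 0

    def test_clear_hom_ref(self):
        genotype, _ = genotype_quality_from_counts(ReadSupport(40, 0, 0), 0.002)
        assert genotype is Genotype.HOM_REF

    def test_skewed_somatic_fraction_low_quality_or_hom(self):
        # 2 alt reads of 40: neither a confident het nor able to displace hom_ref
        genotype, gq = genotype_quality_from_counts(ReadSupport(38, 2, 0), 0.002)
        assert genotype is not Genotype.HOM_ALT
        if genotype is Genotype.HET:
            assert gq < 10


class TestSimulateTwinPair:
    def test_identical_source_zero_true_differences(self):
        config = SimulationConfig(
            n_loci=300, n_postzygotic=(0, 0), n_somatic=0,
            trace_twin=0, reference_twin=0, error_rate=0.0, seed=5,
        )
        sim = simulate_twin_pair(config)
        np.testing.assert_array_equal(
            sim.sample_alt_fraction["trace"], sim.sample_alt_fraction["reference"]
        )
        assert not any(t.category.startswith("post_zygotic") for t in sim.truth)

    def test_distinct_twins_without_mutations_are_identical(self):
        config = SimulationConfig(
            n_loci=300, n_postzygotic=(0, 0), n_somatic=0, seed=6,
        )
        sim = simulate_twin_pair(config)
        np.testing.assert_array_equal(sim.twin_genotypes[0], sim.twin_genotypes[1])

    def test_category_conservation(self, small_sim):
        config = small_sim.config
        counts = {"germline": 0, "post_zygotic_twin1": 0,
                  "post_zygotic_twin2": 0, "somatic": 0}
        for record in small_sim.truth:
            counts[record.category] += 1
        assert counts["post_zygotic_twin1"] == config.n_postzygotic[0]
        assert counts["post_zygotic_twin2"] == config.n_postzygotic[1]
        assert counts["somatic"] == 2 * config.n_somatic
        n_variant = int((small_sim.twin_genotypes[0] != 0).sum())
        assert counts["germline"] == n_variant - config.n_postzygotic[0]

    def test_postzygotic_het_in_exactly_one_twin(self, small_sim):
        for record in small_sim.truth:
            if record.category.startswith("post_zygotic"):
                genotypes = (record.twin1_genotype, record.twin2_genotype)
                assert sorted(g.value for g in genotypes) == ["het", "hom_ref"]

    def test_germline_records_identical_between_twins(self, small_sim):
        for record in small_sim.truth:
            if record.category == "germline":
                assert record.twin1_genotype == record.twin2_genotype

    def test_somatic_fractions_in_configured_range(self, small_sim):
        config = small_sim.config
        for record in small_sim.truth:
            if record.category == "somatic":
                assert record.sample_id in ("trace", "reference")
                assert (
                    config.somatic_fraction_low
                    <= record.alt_fraction
                    <= config.somatic_fraction_high
                )

    def test_replicate_count_respected(self, small_sim):
        assert len(small_sim.callsets["trace"]) == small_sim.config.n_replicates
        assert len(small_sim.callsets["reference"]) == small_sim.config.n_replicates

    def test_determinism_in_memory(self):
        config = SimulationConfig(n_loci=200, seed=99)
        first = simulate_twin_pair(config)
        second = simulate_twin_pair(config)
        for sample in ("trace", "reference"):
            for cs1, cs2 in zip(first.callsets[sample], second.callsets[sample]):
                assert cs1.calls == cs2.calls


class TestWriteSimulation:
    def test_default_layout(self, tmp_path, small_sim):
        out = tmp_path / "sim"
        written = write_simulation(small_sim, out)
        names = sorted(p.name for p in written)
        assert names == [
            "reference_rep1.vcf", "reference_rep2.vcf", "simulation_config.json",
            "trace_rep1.vcf", "trace_rep2.vcf", "truth.tsv",
        ]

    def test_three_replicates_give_six_vcfs(self, tmp_path):
        config = SimulationConfig(n_loci=100, n_replicates=3, n_somatic=2,
                                  n_postzygotic=(1, 1), seed=2)
        sim = simulate_twin_pair(config)
        written = write_simulation(sim, tmp_path / "sim3")
        assert sum(1 for p in written if p.suffix == ".vcf") == 6

    def test_byte_identical_under_fixed_seed(self, tmp_path):
        config = SimulationConfig(n_loci=150, n_somatic=5, seed=17)
        for name in ("a", "b"):
            write_simulation(simulate_twin_pair(config), tmp_path / name)
        for path_a in sorted((tmp_path / "a").iterdir()):
            path_b = tmp_path / "b" / path_a.name
            assert path_a.read_bytes() == path_b.read_bytes()

    def test_truth_table_matches_truth_records(self, tmp_path, small_sim):
        write_simulation(small_sim, tmp_path / "sim")
        lines = (tmp_path / "sim" / "truth.tsv").read_text().splitlines()
        assert len(lines) == len(small_sim.truth) + 1


class TestSimulatePanel:
    def test_panel_restricted_to_requested_loci(self, small_sim):
        loci = [t.locus for t in small_sim.truth[:5]]
        panel = simulate_panel(small_sim, loci, depth=500)
        for replicates in panel.values():
            for callset in replicates:
                assert set(callset.calls) == set(loci)

    def test_unknown_locus_rejected(self, small_sim):
        from twinsnv.core import Locus

        with pytest.raises(ValueError, match="panel locus"):
            simulate_panel(small_sim, [Locus("chrX", 1, "A", "G")])

    def test_panel_depth_applied(self, small_sim):
        loci = [t.locus for t in small_sim.truth[:20]]
        panel = simulate_panel(small_sim, loci, depth=500)
        depths = [
            call.support.dp
            for replicates in panel.values()
            for callset in replicates
            for call in callset.calls.values()
        ]
        assert 450 < float(np.mean(depths)) < 550

    def test_controls_are_shared_hets(self, small_sim):
        controls = select_control_loci(small_sim, 10)
        index = small_sim.locus_index
        for locus in controls:
            i = index[locus]
            assert small_sim.twin_genotypes[0, i] == 1
            assert small_sim.twin_genotypes[1, i] == 1

    def test_too_many_controls_rejected(self, clean_sim):
        with pytest.raises(ValueError, match="control"):
            select_control_loci(clean_sim, 10_000)
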