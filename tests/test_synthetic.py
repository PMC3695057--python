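import numpy as np
import pytest

from mirhub.expression import differential_expression, significant_genes
from mirhub.synthetic import (
    HubSpec,
    ScenarioConfig,
    generate_hub_scenario,
    generate_mirna_set,
    generate_promoter_set,
    generate_utr_set,
    plant_seed_sites,
    write_scenario,
)
from mirhub.targets import MiRNASequence, find_seed_sites, predict_targets, site_words


class TestGenerateUtrs:
    def test_deterministic_fasta(self, tmp_path, small_config):
        a = generate_utr_set(small_config)
        b = generate_utr_set(small_config)
        pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
        a.to_fasta(pa)
        b.to_fasta(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_gc_one_gives_only_gc(self):
        cfg = ScenarioConfig(n_genes=20, gc_fraction=1.0, hubs=[], rng_seed=1)
        utrs = generate_utr_set(cfg)
        assert all(set(s) <= {"G", "C"} for s in utrs.sequences.values())

    def test_length_distribution(self):
        cfg = ScenarioConfig(
            n_genes=1000, utr_length_mean=800, utr_length_sd=200, hubs=[], rng_seed=2
        )
        lengths = np.array([len(s) for s in generate_utr_set(cfg).sequences.values()])
        se = 200 / np.sqrt(1000)
        assert abs(lengths.mean() - 800) < 3 * se
        assert lengths.min() >= 30

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError, match="gc_fraction"):
            ScenarioConfig(gc_fraction=1.5)

    def test_conservation_of_counts(self, small_config):
        assert len(generate_utr_set(small_config)) == small_config.n_genes
        assert len(generate_mirna_set(small_config)) == small_config.n_mirnas


class TestPlantSites:
    @pytest.fixture
    def utrs(self, small_config):
        return generate_utr_set(small_config)

    @pytest.fixture
    def mirna(self, small_config):
        return list(generate_mirna_set(small_config).values())[0]

    def test_fraction_zero_is_noop(self, utrs, mirna):
        out, truth = plant_seed_sites(utrs, mirna, 0.0, "8mer", 1)
        assert truth == {}
        assert out.sequences == utrs.sequences

    def test_fraction_one_all_detected(self, utrs, mirna):
        out, truth = plant_seed_sites(utrs, mirna, 1.0, "8mer", 1)
        assert len(truth) == len(utrs)
        targets = set(predict_targets(mirna, out).members)
        assert targets == set(utrs.gene_ids)

    def test_rounding_nearest_ties_up(self, mirna):
        cfg = ScenarioConfig(n_genes=200, hubs=[], rng_seed=3)
        utrs = generate_utr_set(cfg)
        _, truth = plant_seed_sites(utrs, mirna, 0.3, "8mer", 1)
        assert len(truth) == 60
        # 0.5 tie rounds up: 0.0025 * 200 = 0.5 -> 1 recipient
        _, truth2 = plant_seed_sites(utrs, mirna, 0.0025, "8mer", 1)
        assert len(truth2) == 1

    def test_lengths_unchanged(self, utrs, mirna):
        out, _ = plant_seed_sites(utrs, mirna, 0.5, "8mer", 4)
        for g in utrs.gene_ids:
            assert len(out.sequences[g]) == len(utrs.sequences[g])

    def test_planted_site_found_at_recorded_position(self, utrs, mirna):
        out, truth = plant_seed_sites(utrs, mirna, 0.3, "7mer-m8", 5)
        word = site_words(mirna)["7mer-m8"]
        for gene, pos in truth.items():
            assert out.sequences[gene][pos:pos + len(word)] == word
            sites = find_seed_sites(
                mirna, out.sequences[gene], site_types=frozenset({"7mer-m8"})
            )
            assert any(s.start == pos for s in sites)

    def test_bad_fraction_rejected(self, utrs, mirna):
        with pytest.raises(ValueError, match="fraction"):
            plant_seed_sites(utrs, mirna, 1.2, "8mer", 1)

    def test_word_longer_than_shortest_utr_rejected(self, mirna):
        from mirhub.targets import UTRSet

        utrs = UTRSet({"g": "ACGTA"})
        with pytest.raises(ValueError, match="shortest"):
            plant_seed_sites(utrs, mirna, 1.0, "8mer", 1)


class TestHubScenario:
    def test_determinism(self, small_config):
        a = generate_hub_scenario(small_config)
        b = generate_hub_scenario(small_config)
        assert a.expression.values.equals(b.expression.values)
        assert a.mirna_counts.counts.equals(b.mirna_counts.counts)
        assert a.utrs.sequences == b.utrs.sequences

    def test_truth_targets_carry_sites(self, small_config):
        bundle = generate_hub_scenario(small_config)
        for hub in small_config.hubs:
            mirna = bundle.mirnas[hub.mirna_id]
            for gene in bundle.truth.targets_by_hub[hub.mirna_id]:
                sites = find_seed_sites(
                    mirna, bundle.utrs.sequences[gene],
                    site_types=frozenset({hub.site_type}),
                )
                assert sites, f"no planted site in {gene}"

    def test_planted_effect_recovered_in_group_means(self, small_config):
        bundle = generate_hub_scenario(small_config)
        hub = small_config.hubs[0]  # cond1 hub, miRNA down -> targets up
        targets = bundle.truth.targets_by_hub[hub.mirna_id]
        em = bundle.expression
        cond = em.values[em.samples_in_group("cond1")].loc[targets].mean(axis=1)
        ref = em.values[em.samples_in_group("naive")].loc[targets].mean(axis=1)
        observed = (cond - ref).mean()
        assert observed == pytest.approx(hub.target_log2_effect, abs=0.05)

    def test_unknown_hub_mirna_rejected(self):
        cfg = ScenarioConfig(
            n_mirnas=3,
            hubs=[HubSpec("cond1", "mir-999", "down")],
        )
        with pytest.raises(ValueError, match="mir-999"):
            generate_hub_scenario(cfg)

    def test_zero_effect_scenarios_yield_empty_de_sets(self):
        flat_hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = ScenarioConfig(
                n_genes=300, n_mirnas=5,
                hubs=[HubSpec("cond1", "mir-001", "down", 0.3, 0.0, "8mer", 0.0)],
                rng_seed=seed,
            )
            bundle = generate_hub_scenario(cfg)
            de = differential_expression(bundle.expression, "cond1", "naive")
            flat_hits += len(significant_genes(de))
        # empirical FDR sanity: with no signal almost no gene passes the gate
        assert flat_hits / (n_seeds * 300) < 0.01

    def test_library_sizes_positive_and_recorded(self, small_config):
        bundle = generate_hub_scenario(small_config)
        assert (bundle.mirna_counts.library_sizes > 0).all()
        assert list(bundle.mirna_counts.library_sizes.index) == small_config.sample_ids

    def test_replicate_minimum_enforced(self):
        with pytest.raises(ValueError, match="replicates"):
            ScenarioConfig(groups=(("naive", 1), ("cond1", 4)))

    def test_write_scenario_files(self, tmp_path, small_config):
        bundle = generate_hub_scenario(small_config)
        paths = write_scenario(bundle, tmp_path / "scen")
        for path in paths.values():
            assert path.exists() and path.stat().st_size > 0


class TestPromoterSet:
    def test_plant_fraction_zero(self, rich_pwm):
        seqs, truth = generate_promoter_set(10, rich_pwm, 0.0, rng_seed=1)
        assert truth == {}
        assert len(seqs) == 10

    def test_full_plant_recovered_by_scan(self, rich_pwm):
        from mirhub.promoter import PromoterRegion, scan_promoter

        seqs, truth = generate_promoter_set(15, rich_pwm, 1.0, rng_seed=2)
        assert len(truth) == 15
        for pid, (pos, strand) in truth.items():
            prom = PromoterRegion(pid, "c", "+", 0, 1500, seqs[pid])
            hits = scan_promoter(rich_pwm, prom, p_max=5e-6)
            assert any(h.offset == pos and h.strand == strand for h in hits)

    def test_minus_strand_plant_word(self, rich_pwm):
        from mirhub.seq import revcomp

        seqs, truth = generate_promoter_set(40, rich_pwm, 1.0, rng_seed=3)
        minus = [(p, pos) for p, (pos, s) in truth.items() if s == "-"]
        assert minus  # at ~50% strand probability some minus plants exist
        for pid, pos in minus:
            w = rich_pwm.width
            assert seqs[pid][pos:pos + w] == revcomp(rich_pwm.consensus)

    def test_bad_fraction_rejected(self, rich_pwm):
        with pytest.raises(ValueError, match="plant_fraction"):
            generate_promoter_set(5, rich_pwm, -0.1, rng_seed=1)
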