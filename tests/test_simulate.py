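"""Synthetic-data generators: determinism, calibration and recovery."""

import numpy as np
import pytest
from scipy import stats

from tfbench.bias import oligo_contains_seed
from tfbench.pbm import kmer_intensity_scores
from tfbench.pwm import PWMSet, consensus_kmer, occupancy_score
from tfbench.selex import kmer_frequency_table, nucleotide_composition, top_k_kmers
from tfbench.simulate import (
    SimulationConfig,
    gen_chip_experiment,
    gen_contaminant_oligos,
    gen_pbm_experiment,
    gen_pwm,
    gen_selex_experiment,
    kmer_affinity_table,
)

SMALL = dict(n_probes=2000, pool_size=20_000, reads_per_cycle=2000, n_cycles=3)


class TestGenPWM:
    def test_deterministic_under_seed(self):
        a = gen_pwm(8, 0.1, 42)
        b = gen_pwm(8, 0.1, 42)
        assert np.array_equal(a.probs, b.probs)

    def test_low_concentration_limit_is_near_one_hot(self):
        # columns approach one-hot as concentration -> 0 (in distribution)
        maxima = np.concatenate(
            [gen_pwm(8, 0.002, seed).probs.max(axis=0) for seed in range(10)]
        )
        assert maxima.mean() > 0.95
        assert (maxima > 0.9).mean() > 0.8

    def test_entropy_decreases_with_concentration(self):
        def mean_entropy(conc):
            vals = []
            for seed in range(20):
                p = gen_pwm(8, conc, seed, consensus_margin=0.0).probs
                with np.errstate(divide="ignore", invalid="ignore"):
                    h = -np.where(p > 0, p * np.log2(p), 0).sum(axis=0)
                vals.append(h.mean())
            return np.mean(vals)

        assert mean_entropy(0.05) < mean_entropy(0.5) < mean_entropy(2.0)

    def test_consensus_margin_enforced(self):
        for seed in range(10):
            p = gen_pwm(8, 0.1, seed).probs
            top2 = np.sort(p, axis=0)[-2:]
            assert (top2[1] - top2[0] >= 0.2).all()

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            gen_pwm(3, 0.1, 0)
        with pytest.raises(ValueError):
            gen_pwm(8, 0.0, 0)


class TestGenPBM:
    def test_deterministic(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        pwm = gen_pwm(8, 0.1, 5)
        t1, _ = gen_pbm_experiment(pwm, cfg)
        t2, _ = gen_pbm_experiment(pwm, cfg)
        assert t1.sequences == t2.sequences
        assert np.array_equal(t1.intensities, t2.intensities)

    def test_zero_noise_preserves_occupancy_ranking(self):
        cfg = SimulationConfig(seed=2, noise_sigma=0.0, **SMALL)
        pwm = gen_pwm(8, 0.1, 2)
        table, truth = gen_pbm_experiment(pwm, cfg)
        affinities = [truth.affinities[s] for s in table.sequences]
        rho = stats.spearmanr(affinities, table.intensities).statistic
        assert rho == pytest.approx(1.0)

    def test_zero_scale_gives_chance_auc(self):
        from tfbench.pbm import evaluate_pbm

        aucs = []
        for seed in range(4):
            cfg = SimulationConfig(seed=seed, intensity_scale=0.0, **SMALL)
            pwm = gen_pwm(8, 0.1, seed)
            table, _ = gen_pbm_experiment(pwm, cfg)
            aucs.append(evaluate_pbm(table, PWMSet([pwm])).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_ground_truth_matches_recomputed_occupancy(self):
        cfg = SimulationConfig(seed=7, **SMALL)
        pwm = gen_pwm(8, 0.1, 7)
        table, truth = gen_pbm_experiment(pwm, cfg)
        for seq in table.sequences[:20]:
            assert truth.affinities[seq] == pytest.approx(
                occupancy_score(pwm, seq, "both")
            )


class TestGenSelex:
    def test_deterministic(self):
        cfg = SimulationConfig(seed=3, **SMALL)
        pwm = gen_pwm(8, 0.1, 3)
        e1, _ = gen_selex_experiment(pwm, cfg)
        e2, _ = gen_selex_experiment(pwm, cfg)
        for c1, c2 in zip(e1.cycles, e2.cycles):
            assert c1.counts == c2.counts

    def test_seeds_are_consensus(self):
        cfg = SimulationConfig(seed=3, **SMALL)
        pwm = gen_pwm(8, 0.1, 3)
        exp, _ = gen_selex_experiment(pwm, cfg)
        assert exp.seeds == [consensus_kmer(pwm)]

    def test_null_model_composition_stable(self):
        """No selection, no bias: base composition is statistically flat
        across cycles (chi-square on base counts, alpha 0.01)."""
        cfg = SimulationConfig(seed=11, selection_strength=0.0, **SMALL)
        pwm = gen_pwm(8, 0.1, 11)
        exp, _ = gen_selex_experiment(pwm, cfg)
        n0 = cfg.reads_per_cycle * cfg.oligo_length
        comp0 = nucleotide_composition(exp.cycles[0])
        comp3 = nucleotide_composition(exp.cycles[-1])
        table = np.array(
            [[comp0[b] * n0 for b in "ACGT"], [comp3[b] * n0 for b in "ACGT"]]
        )
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_consensus_frequency_increases_across_cycles(self):
        """Affinity-driven enrichment: the consensus word's frequency rises
        monotonically through the cycles in nearly every run."""
        rising = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed)
            pwm = gen_pwm(8, cfg.pwm_concentration, seed)
            exp, _ = gen_selex_experiment(pwm, cfg)
            cons = consensus_kmer(pwm)
            freqs = [
                kmer_frequency_table(c).scores.get(cons, 0.0) for c in exp.cycles
            ]
            rising += all(a < b for a, b in zip(freqs, freqs[1:]))
        assert rising >= 0.9 * n_seeds

    def test_ground_truth_affinities_consistent(self):
        cfg = SimulationConfig(seed=9, **SMALL)
        pwm = gen_pwm(8, 0.1, 9)
        exp, truth = gen_selex_experiment(pwm, cfg)
        some = list(exp.cycles[0].counts)[:20]
        for oligo in some:
            assert truth.affinities[oligo] == pytest.approx(
                occupancy_score(pwm, oligo, "both")
            )

    def test_contaminant_generator_avoids_seeds(self):
        seeds = ["ACGTGCAT"]
        oligos = gen_contaminant_oligos(10, 16, seeds, seed=4)
        assert len(oligos) == 10
        assert not any(oligo_contains_seed(o, seeds, 1) for o in oligos)

    def test_contaminants_grow_into_late_cycles(self):
        pwm = gen_pwm(8, 0.1, 6)
        conts = gen_contaminant_oligos(5, 16, [consensus_kmer(pwm)], seed=6)
        cfg = SimulationConfig(seed=6, contaminant_oligos=conts, **SMALL)
        exp, truth = gen_selex_experiment(pwm, cfg)
        assert truth.contaminants == list(conts)
        last = exp.last_cycle.counts
        first = exp.cycles[0].counts
        assert sum(last.get(o, 0) for o in conts) > sum(
            first.get(o, 0) for o in conts
        )


class TestGenChip:
    def test_deterministic(self):
        cfg = SimulationConfig(seed=4, n_peaks=20)
        pwm = gen_pwm(8, 0.1, 4)
        p1, g1, _ = gen_chip_experiment(pwm, cfg, 60_000)
        p2, g2, _ = gen_chip_experiment(pwm, cfg, 60_000)
        assert g1 == g2
        assert p1 == p2

    def test_planted_sites_written_into_genome(self):
        cfg = SimulationConfig(seed=4, n_peaks=20, plant_prob=1.0)
        pwm = gen_pwm(8, 0.02, 4)
        peaks, genome, truth = gen_chip_experiment(pwm, cfg, 60_000)
        assert all(pos is not None for pos in truth.planted_positions)
        for chrom, pos in truth.planted_positions:
            site = genome[chrom][pos : pos + pwm.k]
            # every base of the written site has positive probability
            for j, b in enumerate(site):
                assert pwm.probs["ACGT".index(b), j] > 0

    def test_no_planting_leaves_no_records(self):
        cfg = SimulationConfig(seed=4, n_peaks=10, plant_prob=0.0)
        pwm = gen_pwm(8, 0.1, 4)
        _, _, truth = gen_chip_experiment(pwm, cfg, 40_000)
        assert all(pos is None for pos in truth.planted_positions)

    def test_planted_pvalues_smaller(self):
        cfg = SimulationConfig(seed=4, n_peaks=40, plant_prob=0.5)
        pwm = gen_pwm(8, 0.1, 4)
        peaks, _, truth = gen_chip_experiment(pwm, cfg, 100_000)
        planted = [p.pvalue for p, t in zip(peaks, truth.planted_positions) if t]
        unplanted = [p.pvalue for p, t in zip(peaks, truth.planted_positions) if not t]
        assert max(planted) < min(unplanted)

    def test_geometry_errors(self):
        cfg = SimulationConfig(seed=0, n_peaks=10)
        pwm = gen_pwm(8, 0.1, 0)
        with pytest.raises(ValueError):
            gen_chip_experiment(pwm, cfg, 10_000)


class TestEndToEnd:
    def test_low_noise_matched_pair_correlates_strongly(self):
        """Idealized deep-coverage regime: a large pool, deep sequencing,
        short oligos and noise-free intensities push the best grid
        correlation above 0.9."""
        from tfbench.compare import run_comparison_grid

        cfg = SimulationConfig(
            seed=0,
            noise_sigma=0.0,
            pool_size=500_000,
            reads_per_cycle=50_000,
            oligo_length=14,
            n_cycles=3,
        )
        pwm = gen_pwm(8, cfg.pwm_concentration, cfg.seed)
        table, _ = gen_pbm_experiment(pwm, cfg)
        exp, _ = gen_selex_experiment(pwm, cfg)
        pbm_kmers = kmer_intensity_scores(table, statistic="median")
        result = run_comparison_grid(exp, pbm_kmers)
        assert result.best.pearson > 0.9

    def test_fewer_reads_degrade_selex_top_correlations(self):
        """Cutting sequencing depth hurts the SELEX-sourced top-100 pick."""
        from tfbench.compare import run_comparison_grid

        deep_means, shallow_means = [], []
        for seed in range(6):
            base = dict(seed=seed, n_probes=10_000)
            pwm = gen_pwm(8, 0.1, seed)
            table, _ = gen_pbm_experiment(
                pwm, SimulationConfig(**base)
            )
            pbm_kmers = kmer_intensity_scores(table)
            for reads, sink in ((5000, deep_means), (500, shallow_means)):
                cfg = SimulationConfig(reads_per_cycle=reads, **base)
                exp, _ = gen_selex_experiment(pwm, cfg)
                grid = run_comparison_grid(exp, pbm_kmers)
                vals = [
                    e.pearson for e in grid.entries if e.source == "selex_top"
                ]
                sink.append(np.mean(vals))
        assert np.mean(deep_means) > np.mean(shallow_means)
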