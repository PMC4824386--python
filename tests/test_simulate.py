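"""Tests for the clonal-expansion and sequencing simulators."""

import numpy as np
import pytest

from clonerate.rate_model import molecule_lambda
from clonerate.simulate import (
    EXACT_GENERATION_CAP,
    GenerationCapError,
    SimulatedReadPair,
    TruthVariant,
    simulate_amplicon,
    simulate_catalog,
    simulate_expansion,
    simulate_expansion_counts,
    simulate_lineage_mutations,
    simulate_read_pairs,
    truth_table,
)


class TestExpansion:
    def test_no_mutation_process_gives_founder_set_only(self):
        tree = simulate_expansion(mu=0, generations=5, founder_mutations=3, seed=0)
        assert tree.n_mutations == 3
        for leaf in tree.leaves():
            assert tree.leaf_mutations(leaf) == {0, 1, 2}
        for v in tree.truth_variants():
            assert v.molecule_fraction == 0.5

    def test_carrier_count_forced_by_binary_division(self):
        tree = simulate_expansion(mu=1.5, generations=10, seed=42)
        origin2 = [m for m, n in tree.mutation_origin.items() if n == 2]
        assert origin2, "expected some generation-2 mutations at mu=1.5"
        for m in origin2:
            assert len(tree.carrier_leaves(m)) == 2 ** 8
            assert TruthVariant(m, 2).molecule_fraction == 1 / 8

    def test_mean_total_mutations_matches_poisson_expectation(self):
        # expectation: mu * (2**(G+1) - 2) daughters over all divisions
        mu, gens, reps = 14, 8, 500
        totals = [
            simulate_expansion(mu, gens, seed=s).n_mutations for s in range(reps)
        ]
        expected = mu * (2 ** (gens + 1) - 2)
        se = np.sqrt(expected / reps)  # Poisson variance of the replicate mean
        assert abs(np.mean(totals) - expected) < 4 * se

    def test_conservation_of_mutation_counts(self):
        tree = simulate_expansion(mu=2, generations=6, founder_mutations=5, seed=3)
        branch_total = sum(len(v) for v in tree.branch_mutations.values())
        assert tree.n_mutations == tree.founder_mutations + branch_total

    def test_molecule_fraction_is_exact_halving(self):
        tree = simulate_expansion(mu=1, generations=6, seed=9)
        for v in tree.truth_variants():
            assert v.molecule_fraction == 2.0 ** -(v.origin_generation + 1)
            assert v.cell_fraction == 2 * v.molecule_fraction

    def test_deterministic_under_fixed_seed(self):
        a = simulate_expansion(3, 5, seed=11)
        b = simulate_expansion(3, 5, seed=11)
        assert a.mutation_origin == b.mutation_origin
        assert a.branch_mutations == b.branch_mutations

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_expansion(-1, 4)
        with pytest.raises(ValueError):
            simulate_expansion(1, -1)

    def test_generation_cap_raises_capability_error(self):
        with pytest.raises(GenerationCapError, match="simulate_expansion_counts"):
            simulate_expansion(1, EXACT_GENERATION_CAP + 1)

    def test_count_approximation_matches_exact_in_expectation(self):
        mu, gens = 0.5, 6
        exact = [simulate_expansion(mu, gens, seed=s).n_mutations for s in range(300)]
        approx = [
            len(simulate_expansion_counts(mu, gens, seed=10_000 + s))
            for s in range(300)
        ]
        expected = mu * (2 ** (gens + 1) - 2)
        se = np.sqrt(expected / 300)
        assert abs(np.mean(exact) - expected) < 4 * se
        assert abs(np.mean(approx) - expected) < 4 * se

    def test_lineage_mutation_count_is_poisson_mu_per_division(self):
        counts = [
            len(simulate_lineage_mutations(14, 24, seed=s)) for s in range(200)
        ]
        expected = 14 * 24
        se = np.sqrt(expected / 200)
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_truth_table_round_trips_fields(self):
        tree = simulate_expansion(1, 4, founder_mutations=2, seed=5)
        df = truth_table(tree.truth_variants())
        assert list(df.columns) == [
            "mutation_id", "origin_generation", "cell_fraction", "molecule_fraction",
        ]
        assert (df.molecule_fraction == 2.0 ** -(df.origin_generation + 1)).all()


class TestAmplicon:
    def test_absent_variant_error_free_gives_zero_alt(self):
        for depth in (0, 100, 10_000):
            ref, alt = simulate_amplicon(None, 1500, depth, 0.0, seed=1)
            assert alt == 0 and ref == depth

    def test_clonal_variant_converges_to_half(self):
        # at large depth the residual spread is the Poisson template sampling,
        # sd = sqrt(750)/1500 per replicate; average over 50 replicates
        truth = TruthVariant(0, 0)  # clonal: molecule fraction 1/2
        fracs = []
        for s in range(50):
            ref, alt = simulate_amplicon(truth, 1500, 50_000, 0.0, seed=s)
            fracs.append(alt / (ref + alt))
        se = np.sqrt(750) / 1500 / np.sqrt(50)
        assert abs(np.mean(fracs) - 0.5) < 4 * se

    @pytest.mark.parametrize("lam", [0.1, 0.5, 1.0, 2.0])
    def test_detection_frequency_matches_poisson_complement(self, lam):
        # choose the generation whose lambda equals the target via N = lam * 2^(n+1)
        n = 3
        n_molecules = int(round(lam * 2 ** (n + 1)))
        lam_actual = molecule_lambda(n_molecules, n)
        truth = TruthVariant(0, n)
        reps = 3000
        hits = sum(
            simulate_amplicon(truth, n_molecules, 500, 0.0, seed=s)[1] > 0
            for s in range(reps)
        )
        p = 1 - np.exp(-lam_actual)
        se = np.sqrt(p * (1 - p) / reps)
        # depth 500 over <= 32 template molecules: a single mutant template
        # is sampled into at least one read with probability ~1
        assert abs(hits / reps - p) < 3 * se + 0.01

    def test_error_rate_validated(self):
        with pytest.raises(ValueError):
            simulate_amplicon(None, 1500, 100, 1.5)
        with pytest.raises(ValueError):
            simulate_amplicon(None, 0, 100, 0.0)


class TestReadPairs:
    def test_error_free_reads_equal_template(self):
        template = "ACGT" * 25
        for pair in simulate_read_pairs(template, overlap=30, n_pairs=3, seed=0):
            assert pair.read1 == template[pair.offset1:pair.offset1 + len(pair.read1)]
            assert pair.read2 == template[pair.offset2:pair.offset2 + len(pair.read2)]

    def test_per_read_mismatch_fraction_matches_error_rate(self, rng):
        template = "".join(rng.choice(list("ACGT"), 100))
        pairs = simulate_read_pairs(
            template, overlap=40, error_rate=0.01, n_pairs=5000, seed=1
        )
        mismatches = sum(
            sum(a != b for a, b in zip(p.read1, p.truth[p.offset1:]))
            for p in pairs
        )
        total = sum(len(p.read1) for p in pairs)
        rate = mismatches / total
        se = np.sqrt(0.01 * 0.99 / total)
        assert abs(rate - 0.01) < 4 * se

    def test_consensus_collision_rate_is_squared(self, rng):
        # both reads wrong with the same base at one overlap position:
        # 3 * (e/3)^2 per site, far below the single-read rate e
        template = "".join(rng.choice(list("ACGT"), 60))
        e = 0.05  # inflated to make collisions observable
        pairs = simulate_read_pairs(
            template, overlap=60, error_rate=e, n_pairs=20_000, seed=2, read_length=60
        )
        collisions = sites = 0
        for p in pairs:
            start, end = p.overlap_interval
            for pos in range(start, end):
                b1 = p.read1[pos - p.offset1]
                b2 = p.read2[pos - p.offset2]
                t = p.truth[pos]
                sites += 1
                if b1 == b2 != t:
                    collisions += 1
        expected = 3 * (e / 3) ** 2
        se = np.sqrt(expected / sites)
        assert abs(collisions / sites - expected) < 4 * se
        assert collisions / sites < e / 10

    def test_overlap_longer_than_read_rejected(self):
        with pytest.raises(ValueError):
            simulate_read_pairs("A" * 100, overlap=80, read_length=60)

    def test_quality_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimulatedReadPair(
                read1="AC", read2="AC",
                qual1=np.array([50, 30]), qual2=np.array([30, 30]),
                offset1=0, offset2=0, truth="AC",
            )


class TestCatalog:
    def test_single_signature_large_n_converges(self, two_signatures):
        sig = two_signatures[0]
        counts = simulate_catalog([sig], [1.0], 200_000, seed=0)
        assert np.max(np.abs(counts / counts.sum() - sig)) < 0.01

    def test_two_channel_mixture_means(self):
        a = np.zeros(96); a[0] = 1.0
        b = np.zeros(96); b[95] = 1.0
        counts = simulate_catalog([a, b], [0.7, 0.3], 10_000, seed=1)
        assert abs(counts[0] - 7000) < 200
        assert abs(counts[95] - 3000) < 200
        assert counts.sum() == 10_000

    def test_dimension_and_weight_validation(self):
        with pytest.raises(ValueError):
            simulate_catalog([np.ones(95) / 95], [1.0], 10)
        with pytest.raises(ValueError):
            simulate_catalog([np.ones(96) / 96], [0.5], 10)
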