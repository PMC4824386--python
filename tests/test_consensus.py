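"""Tests for paired-read consensus merging and error-rate estimation."""

import itertools

import numpy as np
import pytest

from clonerate.consensus import (
    MASK,
    ConsensusRead,
    PairRejection,
    RejectionReason,
    compare_error_distributions,
    count_bases,
    error_rate_summary,
    merge_pair,
)
from clonerate.simulate import SimulatedReadPair, simulate_read_pairs


def make_pair(read1, read2, q1, q2, offset2=0, truth=None):
    q1 = np.full(len(read1), q1) if np.isscalar(q1) else np.asarray(q1)
    q2 = np.full(len(read2), q2) if np.isscalar(q2) else np.asarray(q2)
    return SimulatedReadPair(
        read1=read1, read2=read2, qual1=q1, qual2=q2,
        offset1=0, offset2=offset2, truth=truth or read1,
    )


class TestMergePair:
    def test_agreeing_high_quality_base_accepted(self):
        result = merge_pair(make_pair("A", "A", 30, 30))
        assert isinstance(result, ConsensusRead)
        assert result.bases == "A"

    def test_summed_quality_exactly_40_is_masked(self):
        # acceptance requires Q1 + Q2 strictly above 40
        result = merge_pair(make_pair("A", "A", 20, 20))
        assert result.bases == MASK
        assert merge_pair(make_pair("A", "A", 20, 21)).bases == "A"

    def test_pair_discarded_above_ten_percent_mismatch(self):
        r1 = "A" * 20
        r2 = "C" * 3 + "A" * 17  # 15% mismatch
        result = merge_pair(make_pair(r1, r2, 30, 30))
        assert isinstance(result, PairRejection)
        assert result.reason is RejectionReason.HIGH_MISMATCH
        assert result.mismatch_fraction == pytest.approx(0.15)

    def test_exactly_ten_percent_mismatch_kept(self):
        r1 = "A" * 20
        r2 = "C" * 2 + "A" * 18  # 10% exactly: "more than 10%" is strict
        result = merge_pair(make_pair(r1, r2, 30, 30))
        assert isinstance(result, ConsensusRead)
        assert result.bases == MASK * 2 + "A" * 18

    def test_disagreeing_bases_masked_never_guessed(self):
        # one mismatch in 20 (5%) keeps the pair; the position is masked
        result = merge_pair(make_pair("A" * 19 + "C", "A" * 19 + "G", 40, 40))
        assert result.bases == "A" * 19 + MASK

    def test_n_bases_masked(self):
        result = merge_pair(make_pair("AN", "AA", 40, 40))
        assert result.bases == "A" + MASK

    def test_empty_overlap_rejected_with_reason(self):
        pair = make_pair("AAAA", "CCCC", 30, 30, offset2=10, truth="A" * 14)
        result = merge_pair(pair)
        assert isinstance(result, PairRejection)
        assert result.reason is RejectionReason.EMPTY_OVERLAP

    def test_error_free_input_identity_no_masking(self):
        template = "ACGTACGTACGTACGTACGT"
        for pair in simulate_read_pairs(template, overlap=12, n_pairs=5, seed=0):
            result = merge_pair(pair)
            start, end = pair.overlap_interval
            assert result.bases == template[start:end]
            assert result.n_masked == 0

    def test_order_independence(self, rng):
        template = "".join(rng.choice(list("ACGT"), 80))
        pairs = simulate_read_pairs(
            template, overlap=40, error_rate=0.02, n_pairs=50, seed=1
        )
        forward = [merge_pair(p) for p in pairs]
        backward = [merge_pair(p) for p in reversed(pairs)]
        for a, b in zip(forward, reversed(backward)):
            assert type(a) is type(b)
            if isinstance(a, ConsensusRead):
                assert a.bases == b.bases

    def test_length_mismatch_raises(self):
        pair = make_pair("ACG", "ACG", 30, 30)
        pair.qual1 = np.array([30, 30])
        with pytest.raises(ValueError):
            merge_pair(pair)


class TestCountBases:
    def test_uniform_reference_counts(self):
        reads = [ConsensusRead(bases="C", start=0, pair_id=i) for i in range(100)]
        sites, qc = count_bases(reads, "C")
        assert sites[0].counts == {"A": 0, "C": 100, "G": 0, "T": 0}
        assert sites[0].error_fraction == 0.0
        assert qc["reads_counted"] == 100

    def test_small_nonreference_fraction(self):
        reads = [ConsensusRead(bases="C", start=0, pair_id=i) for i in range(9999)]
        reads.append(ConsensusRead(bases="T", start=0, pair_id=9999))
        sites, _ = count_bases(reads, "C")
        assert sites[0].error_fraction == pytest.approx(1e-4)

    def test_masked_positions_excluded(self):
        reads = [ConsensusRead(bases="A" + MASK + "G", start=0)]
        sites, _ = count_bases(reads, "ACG")
        assert sites[1].total == 0
        assert sites[0].counts["A"] == 1 and sites[2].counts["G"] == 1

    def test_unknown_amplicon_skipped_and_logged(self):
        reads = [ConsensusRead(bases="A", start=0, pair_id=0)]
        sites, qc = count_bases(
            reads, {"amp1": "A"}, amplicon_of=lambda pid: "missing"
        )
        assert qc["reads_skipped_unknown_amplicon"] == 1
        assert qc["reads_counted"] == 0

    def test_consensus_suppresses_error_below_single_read(self, rng):
        """Merged reads beat first-read-only counting on nearly every amplicon."""
        wins = 0
        n_amplicons = 30
        for a in range(n_amplicons):
            template = "".join(rng.choice(list("ACGT"), 60))
            pairs = simulate_read_pairs(
                template, overlap=60, error_rate=1e-3, n_pairs=400,
                seed=a, read_length=60,
            )
            merged = [p for p in (merge_pair(q) for q in pairs)
                      if isinstance(p, ConsensusRead)]
            single = [ConsensusRead(bases=p.read1, start=p.offset1, pair_id=p.pair_id)
                      for p in pairs]
            err_cons = np.nanmean(
                [s.error_fraction for s in count_bases(merged, template)[0]]
            )
            err_single = np.nanmean(
                [s.error_fraction for s in count_bases(single, template)[0]]
            )
            if err_cons < err_single:
                wins += 1
        assert wins >= 0.99 * n_amplicons


class TestErrorSummary:
    def _sites(self, fractions, amplicon="amp"):
        from clonerate.consensus import SiteCounts

        sites = []
        for i, f in enumerate(fractions):
            total = 10_000
            nonref = int(round(f * total))
            sites.append(
                SiteCounts(
                    amplicon_id=amplicon, offset=i, ref_base="C",
                    counts={"A": nonref, "C": total - nonref, "G": 0, "T": 0},
                )
            )
        return sites

    def test_zero_error_median(self):
        summary = error_rate_summary(self._sites([0.0, 0.0, 0.0]))
        assert summary.loc["amp", "median"] == 0.0

    def test_median_is_middle_value(self):
        summary = error_rate_summary(self._sites([0.0001, 0.0002, 0.0009]))
        assert summary.loc["amp", "median"] == pytest.approx(0.0002)

    def test_excluded_variant_sites_ignored(self):
        sites = self._sites([0.0001, 0.5, 0.0003])
        summary = error_rate_summary(sites, exclude_sites=[("amp", 1)])
        assert summary.loc["amp", "median"] == pytest.approx(0.0002)
        assert summary.loc["amp", "n_sites"] == 2

    def test_no_covered_sites_raises(self):
        with pytest.raises(ValueError):
            error_rate_summary([])

    def test_consensus_median_strictly_lower_on_simulated_q30(self, rng):
        template = "".join(rng.choice(list("ACGT"), 80))
        # Q30 -> per-base error 1e-3
        pairs = simulate_read_pairs(
            template, overlap=80, error_rate=1e-3, n_pairs=2000,
            seed=7, read_length=80, quality_profile=30,
        )
        merged = [p for p in (merge_pair(q) for q in pairs)
                  if isinstance(p, ConsensusRead)]
        single = [ConsensusRead(bases=p.read1, start=p.offset1, pair_id=p.pair_id)
                  for p in pairs]
        med_cons = error_rate_summary(count_bases(merged, template)[0]).loc["amplicon", "median"]
        med_single = error_rate_summary(count_bases(single, template)[0]).loc["amplicon", "median"]
        assert med_cons < med_single


class TestMannWhitney:
    def test_identical_samples_give_central_u(self):
        a = [0.1, 0.2, 0.3, 0.4]
        u, p = compare_error_distributions(a, a)
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p > 0.99

    def test_matches_exact_enumeration_oracle(self):
        """Fully separated n=(3,3) samples: enumerate all C(6,3)=20 rank splits."""
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        u, p = compare_error_distributions(a, b)
        # brute-force null distribution of U over all assignments of ranks
        ranks = range(1, 7)
        u_null = []
        for combo in itertools.combinations(ranks, 3):
            r1 = sum(combo)
            u_null.append(r1 - 3 * 4 / 2)
        u_obs = sum((1, 2, 3)) - 3 * 4 / 2  # ranks of sample a
        p_exact = np.mean([
            min(x, 9 - x) <= min(u_obs, 9 - u_obs) for x in u_null
        ])
        assert u == pytest.approx(0.0)
        assert p == pytest.approx(p_exact) == pytest.approx(0.1)

    def test_power_on_shifted_distributions(self, rng):
        significant = 0
        reps = 40
        for _ in range(reps):
            a = rng.normal(0.0, 1.0, 200)
            b = rng.normal(0.7, 1.0, 200)
            _, p = compare_error_distributions(a, b)
            significant += p < 0.001
        assert significant >= 0.95 * reps

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_error_distributions([], [1.0])
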