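"""Motif scanning, shuffle nulls and the Gumbel-mixture fit."""

import itertools
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reptation import motif_scan as ms

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=0, max_size=60)


def oracle_all_pairs(seq, min_gap=2, max_gap=10, anchors="FW"):
    pos = [i for i, c in enumerate(seq) if c in anchors]
    return [(i, j + 1) for i, j in itertools.combinations(pos, 2)
            if min_gap <= j - i - 1 <= max_gap]


def oracle_leftmost(seq, min_gap=2, max_gap=10):
    """Independent oracle: lazy regex gives leftmost-shortest matches."""
    return [(m.start(), m.end())
            for m in re.finditer(r"[FW].{2,10}?[FW]", seq)]


class TestFindMotifs:
    def test_simple_match(self):
        matches = ms.find_motifs("FAGF")
        assert len(matches) == 1
        assert matches[0].span == "FAGF"
        assert (matches[0].start, matches[0].end) == (0, 4)

    def test_gap_below_minimum_rejected(self):
        assert ms.find_motifs("FAF") == []

    def test_gap_above_maximum_rejected(self):
        assert ms.find_motifs("F" + "A" * 11 + "F") == []

    def test_invalid_characters_listed(self):
        with pytest.raises(ValueError, match="positions 1"):
            ms.find_motifs("AXA")

    def test_default_mode_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(202)
        letters = np.array(list(AA))
        weights = np.full(len(letters), 0.03)
        weights[letters == "F"] = 0.2
        weights[letters == "W"] = 0.26
        weights /= weights.sum()
        for _ in range(200):
            seq = "".join(rng.choice(letters, rng.integers(4, 40), p=weights))
            got = [(m.start, m.end) for m in ms.find_motifs(seq)]
            assert got == oracle_leftmost(seq), seq

    def test_all_pairs_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        letters = np.array(list("FWAGPL"))
        for _ in range(100):
            seq = "".join(rng.choice(letters, rng.integers(4, 30)))
            got = [(m.start, m.end) for m in ms.find_motifs(seq, mode="all_pairs")]
            assert sorted(got) == sorted(oracle_all_pairs(seq)), seq

    @given(sequences)
    @settings(max_examples=200, deadline=None)
    def test_all_pairs_count_at_least_leftmost(self, seq):
        n_all = len(ms.find_motifs(seq, mode="all_pairs"))
        n_left = len(ms.find_motifs(seq))
        assert n_all >= n_left

    @given(sequences)
    @settings(max_examples=200, deadline=None)
    def test_group_count_reversal_invariant_in_all_pairs(self, seq):
        assert ms.group_count(seq, mode="all_pairs") == \
            ms.group_count(seq[::-1], mode="all_pairs")


class TestDestabilizingCount:
    def test_simple_span(self):
        matches = ms.find_motifs("FAGF")
        assert ms.destabilizing_count("FAGF", matches) == 2  # A and G

    def test_overlapping_spans_count_positions_once(self):
        seq = "FAGPFAAGW"  # all-pairs spans share the middle P
        matches = ms.find_motifs(seq, mode="all_pairs")
        count = ms.destabilizing_count(seq, matches)
        by_union = sum(c in "AGPVC" for c in seq)  # whole string covered
        assert count == by_union

    def test_gpvc_inside_tryptophan_bracket(self):
        # destabilizing core flanked by aromatic anchors scores 4
        seq = "LLWGPVCWLL"
        matches = ms.find_motifs(seq)
        assert len(matches) == 1
        assert ms.destabilizing_count(seq, matches) == 4


class TestShuffle:
    def test_single_residue_fixed_point(self):
        assert ms.shuffle_seq("A", 0) == "A"

    @given(sequences.filter(lambda s: len(s) > 1))
    @settings(max_examples=100, deadline=None)
    def test_composition_preserved(self, seq):
        assert sorted(ms.shuffle_seq(seq, 3)) == sorted(seq)

    def test_mean_group_count_matches_exact_permutation_average(self):
        """Shuffle mean approaches the exact average over all permutations."""
        seq = "FAGFWPA"
        perms = {"".join(p) for p in itertools.permutations(seq)}
        exact = np.mean([ms.group_count(p, mode="all_pairs") for p in perms])
        rng = np.random.default_rng(11)
        sampled = np.mean([
            ms.group_count(ms.shuffle_seq(seq, rng), mode="all_pairs")
            for _ in range(1000)
        ])
        assert sampled == pytest.approx(exact, rel=0.05)

    def test_iid_sequences_match_shuffle_null(self):
        """For i.i.d. sequences the observed and shuffle-null count
        distributions agree (chi-square)."""
        rng = np.random.default_rng(5)
        letters = np.array(list(AA))
        records = [
            (f"s{i}", "".join(rng.choice(letters, 80))) for i in range(500)
        ]
        result = ms.scan_cohort(records, n_shuffles=1, rng=rng)
        observed = result["distribution"]
        null = result["null_distribution"]
        support = observed.index.union(null.index)
        obs = observed.reindex(support, fill_value=0.0) * 500
        exp = null.reindex(support, fill_value=0.0) * 500
        # pool sparse bins so chi-square expectations are reasonable
        keep = (obs + exp) / 2 >= 5
        obs_binned = np.append(obs[keep], obs[~keep].sum())
        exp_binned = np.append(exp[keep], exp[~keep].sum())
        from scipy.stats import chisquare
        stat = chisquare(obs_binned, exp_binned * obs_binned.sum() / exp_binned.sum())
        assert stat.pvalue > 0.01


class TestCountDistribution:
    def test_single_value_mass_one(self):
        dist = ms.count_distribution([4, 4, 4])
        assert dist.loc[4] == pytest.approx(1.0)

    def test_two_values_half_half(self):
        dist = ms.count_distribution([1, 2])
        assert dist.loc[1] == pytest.approx(0.5)

    @given(st.lists(st.integers(0, 30), min_size=1, max_size=100))
    @settings(max_examples=100, deadline=None)
    def test_sums_to_one(self, counts):
        assert ms.count_distribution(counts).sum() == pytest.approx(1.0)


class TestGumbelMixture:
    def test_density_at_location_is_rate_over_e(self):
        lam = 0.7
        value = ms.gumbel_mixture_density(5.0, 1.0, lam, 5.0, 2.0, 30.0)
        assert value == pytest.approx(lam * np.exp(-1.0))

    def test_single_component_recovery(self):
        rng = np.random.default_rng(0)
        x = np.round(rng.gumbel(10.0, 2.0, 5000)).astype(int)
        fit = ms.fit_double_gumbel(ms.count_distribution(x))
        assert fit.converged
        # dominant component carries the mass
        if fit.S >= 0.5:
            mu, lam, weight = fit.mu1, fit.lambda1, fit.S
        else:
            mu, lam, weight = fit.mu2, fit.lambda2, 1.0 - fit.S
        assert weight > 0.8
        assert mu == pytest.approx(10.0, abs=0.5)
        assert lam == pytest.approx(0.5, rel=0.15)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(7)
        n = 5000
        pop1 = rng.random(n) < 0.46
        x = np.where(pop1, rng.gumbel(7.0, 2.0, n), rng.gumbel(16.0, 2.0, n))
        fit = ms.fit_double_gumbel(ms.count_distribution(np.round(x).astype(int)))
        assert fit.converged
        assert fit.S == pytest.approx(0.46, abs=0.1)
        assert fit.mu1 == pytest.approx(7.0, abs=0.5)
        assert fit.mu2 == pytest.approx(16.0, abs=0.5)

    def test_parameter_recovery_across_replicates(self):
        """Median relative parameter error < 15 % over replicates."""
        rng = np.random.default_rng(1)
        true = dict(S=0.4, lam1=0.5, mu1=6.0, lam2=0.4, mu2=15.0)
        rel_errors = []
        for _ in range(8):
            n = 5000
            pop1 = rng.random(n) < true["S"]
            x = np.where(pop1,
                         rng.gumbel(true["mu1"], 1 / true["lam1"], n),
                         rng.gumbel(true["mu2"], 1 / true["lam2"], n))
            fit = ms.fit_double_gumbel(ms.count_distribution(np.round(x).astype(int)))
            rel_errors.append(np.median([
                abs(fit.S - true["S"]) / true["S"],
                abs(fit.mu1 - true["mu1"]) / true["mu1"],
                abs(fit.mu2 - true["mu2"]) / true["mu2"],
                abs(fit.lambda1 - true["lam1"]) / true["lam1"],
                abs(fit.lambda2 - true["lam2"]) / true["lam2"],
            ]))
        assert np.median(rel_errors) < 0.15

    def test_explicit_init_used(self):
        rng = np.random.default_rng(3)
        x = np.round(rng.gumbel(8.0, 2.0, 3000)).astype(int)
        fit = ms.fit_double_gumbel(ms.count_distribution(x),
                                   init=(0.9, 0.5, 8.0, 0.5, 12.0))
        assert fit.converged

    def test_too_few_support_points_raise(self):
        with pytest.raises(ValueError):
            ms.fit_double_gumbel(ms.count_distribution([1, 1, 2, 2, 3]))


class TestFasta:
    def test_round_trip(self, tmp_path):
        records = [("p1", "MKLVFW" * 10), ("p2", "ACDEFG")]
        path = ms.write_fasta(records, tmp_path / "cohort.fasta")
        assert ms.read_fasta(path) == records

    def test_empty_file_raises(self, tmp_path):
        empty = tmp_path / "empty.fasta"
        empty.write_text("\n")
        with pytest.raises(ValueError):
            ms.read_fasta(empty)
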