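import itertools

import numpy as np
import pytest

from mitoevo.diversity import (diagnosability, diversity_stats,
                               focal_substitutions,
                               four_gamete_compatibility,
                               recombination_blocks)
from mitoevo.synthetic import simulate_species_loci


def naive_pi(rows):
    """Double-loop oracle: average pairwise difference per comparable site,
    over columns where >=2 sequences carry a nucleotide."""
    nucs = set("ACGT")
    L = len(rows[0])
    l_eff = sum(1 for c in range(L)
                if sum(r[c] in nucs for r in rows) >= 2)
    total = 0
    for a, b in itertools.combinations(rows, 2):
        total += sum(1 for x, y in zip(a, b)
                     if x in nucs and y in nucs and x != y)
    n_pairs = len(rows) * (len(rows) - 1) // 2
    return total / (n_pairs * l_eff) if l_eff else 0.0


class TestDiversityStats:
    def test_identical_sequences(self):
        aln = {"a": "ACGTACGTAC", "b": "ACGTACGTAC"}
        r = diversity_stats(aln, window=10)
        assert r.pi == 0.0 and r.S == 0

    def test_single_pair_two_mismatches(self):
        r = diversity_stats({"a": "ACGTACGTAC", "b": "ACGTACGTGG"}, window=10)
        assert r.pi == pytest.approx(0.2)
        assert r.S == 2

    def test_four_sequences_hand_case(self):
        # pairwise differences {1,1,2,2,3,3}, 100 gap-free columns:
        # pi = (12/6)/100 = 0.02
        base = "A" * 100
        s2 = "G" + base[1:]
        s3 = base[:1] + "G" + base[2:]
        s4 = base[:3] + "CC" + base[5:]
        aln = {"s1": base, "s2": s2, "s3": s3, "s4": s4}
        diffs = sorted(sum(x != y for x, y in zip(a, b))
                       for a, b in itertools.combinations(aln.values(), 2))
        assert diffs == [1, 1, 2, 2, 3, 3]
        r = diversity_stats(aln, window=100)
        assert r.pi == pytest.approx(0.02)

    def test_matches_naive_oracle_with_gaps(self, rng):
        chars = np.array(list("ACGT-"))
        for _ in range(10):
            rows = ["".join(rng.choice(chars, size=60,
                                       p=[.22, .22, .22, .22, .12]))
                    for _ in range(5)]
            aln = {f"s{i}": r for i, r in enumerate(rows)}
            assert diversity_stats(aln).pi == pytest.approx(naive_pi(rows))

    def test_sequence_order_irrelevant(self, rng):
        aln, _, _ = simulate_species_loci(n_species=3, strains_per_species=3,
                                          seed=8)
        shuffled = dict(reversed(list(aln.items())))
        a, b = diversity_stats(aln), diversity_stats(shuffled)
        assert a.pi == b.pi and a.S == b.S

    def test_windows_cover_alignment(self):
        aln = {"a": "A" * 200, "b": "A" * 200}
        r = diversity_stats(aln, window=100, step=25)
        assert r.windows[0][:2] == (1, 100)
        assert r.windows[-1][1] == 200

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            diversity_stats({"a": "ACGT", "b": "ACG"})


class TestFourGamete:
    def test_all_four_gametes_incompatible(self):
        aln = {"s1": "AG", "s2": "AC", "s3": "TG", "s4": "TC",
               "s5": "AG", "s6": "TC"}
        m = four_gamete_compatibility(aln)
        assert m.positions == [0, 1]
        assert not m.compatible[0, 1]

    def test_three_gametes_compatible(self):
        aln = {"s1": "AG", "s2": "AG", "s3": "TG", "s4": "TC",
               "s5": "TC", "s6": "TG"}
        m = four_gamete_compatibility(aln)
        assert m.compatible[0, 1]

    def test_matrix_symmetric_diag_true(self):
        aln, _, _ = simulate_species_loci(n_species=4, strains_per_species=4,
                                          crossovers=1, seed=3)
        m = four_gamete_compatibility(aln)
        assert (m.compatible == m.compatible.T).all()
        assert m.compatible.diagonal().all()

    def test_crossover_creates_spanning_incompatibility(self):
        aln, _, truth = simulate_species_loci(
            n_species=4, strains_per_species=4, theta_within=0.0,
            fixed_diffs_per_pair=4, indel_rate=0.0, crossovers=1, seed=2)
        m = four_gamete_compatibility(aln)
        bp = truth.data["crossover_breakpoints"][0]
        assert any(a < bp <= b for a, b in m.incompatible_pairs)

    def test_no_crossover_no_incompatibility(self):
        aln, _, _ = simulate_species_loci(
            n_species=4, strains_per_species=4, theta_within=0.0,
            fixed_diffs_per_pair=4, indel_rate=0.0, crossovers=0, seed=2)
        assert four_gamete_compatibility(aln).incompatible_pairs == []


class TestRecombinationBlocks:
    def test_all_compatible_no_signal(self):
        aln, _, _ = simulate_species_loci(
            n_species=4, strains_per_species=4, theta_within=0.0,
            fixed_diffs_per_pair=4, indel_rate=0.0, seed=2)
        res = recombination_blocks(four_gamete_compatibility(aln), seed=0)
        assert res.blocks == [] and res.verdict == "no recombination signal"

    def test_two_block_mosaic_found_at_boundary(self):
        aln, _, truth = simulate_species_loci(
            n_species=4, strains_per_species=4, theta_within=0.0,
            fixed_diffs_per_pair=4, indel_rate=0.0, crossovers=1, seed=2)
        res = recombination_blocks(four_gamete_compatibility(aln), seed=0)
        bp = truth.data["crossover_breakpoints"][0]
        assert res.verdict == "blocks" and len(res.blocks) == 2
        assert res.blocks[0][1] < bp <= res.blocks[1][0]

    def test_scattered_homoplasy_gives_no_blocks(self):
        aln, _, _ = simulate_species_loci(
            n_species=4, strains_per_species=4, theta_within=0.01,
            fixed_diffs_per_pair=4, indel_rate=0.0, seed=7)
        m = four_gamete_compatibility(aln)
        assert m.incompatible_pairs  # homoplasy present within & between loci
        res = recombination_blocks(m, seed=0)
        assert res.blocks == []


class TestFocalSubstitutions:
    def test_identical_focal_is_zero(self):
        aln, smap, _ = simulate_species_loci(n_species=2,
                                             strains_per_species=3,
                                             theta_within=0.0, indel_rate=0.0,
                                             seed=1)
        assert focal_substitutions(aln, smap, "sp1_s1") == 0

    def test_planted_private_substitutions_counted(self):
        aln, smap, _ = simulate_species_loci(n_species=2,
                                             strains_per_species=5,
                                             theta_within=0.0, indel_rate=0.0,
                                             seed=9)
        row = list(aln["sp1_s1"])
        other = {"A": "G", "G": "A", "C": "T", "T": "C"}
        for pos in (10, 50, 90):
            row[pos] = other[row[pos]]
        row[120] = "-"   # indel excluded from the count
        aln["sp1_s1"] = "".join(row)
        assert focal_substitutions(aln, smap, "sp1_s1") == 3

    def test_bounded_by_segregating_sites(self):
        aln, smap, _ = simulate_species_loci(seed=12)
        S = diversity_stats(aln).S
        for strain in list(aln)[:6]:
            assert focal_substitutions(aln, smap, strain) <= S

    def test_absent_focal_rejected(self):
        aln, smap, _ = simulate_species_loci(n_species=2, seed=1)
        with pytest.raises(ValueError):
            focal_substitutions(aln, smap, "nope")


class TestDiagnosability:
    def test_monomorphic_species_counted(self):
        aln = {"a1": "AAAAA", "a2": "AAAAA", "b1": "CCCCC", "b2": "CCCCC"}
        smap = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        rep = diagnosability(aln, smap)
        assert rep.fixed_differences[("A", "B")] == 5
        assert rep.locus_diagnostic

    def test_shared_polymorphism_breaks_fixity(self):
        aln = {"a1": "A", "a2": "C", "b1": "C", "b2": "C"}
        smap = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        rep = diagnosability(aln, smap)
        assert rep.fixed_differences[("A", "B")] == 0
        assert not rep.locus_diagnostic

    def test_planted_panel_diagnostic_until_sites_removed(self):
        aln, smap, truth = simulate_species_loci(
            n_species=8, strains_per_species=4, theta_within=0.0,
            fixed_diffs_per_pair=2, indel_rate=0.0, seed=4)
        assert diagnosability(aln, smap).locus_diagnostic
        drop = sorted({s for sites in truth.data["fixed_sites"].values()
                       for s in sites}, reverse=True)
        stripped = {sid: "".join(ch for i, ch in enumerate(row)
                                 if i not in set(drop))
                    for sid, row in aln.items()}
        assert not diagnosability(stripped, smap).locus_diagnostic
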