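import numpy as np
import pytest

from mitoevo.annotation import reverse_complement
from mitoevo.duplication import (characterize_duplication, find_repeats,
                                 merge_colinear_pairs, RepeatPair)
from mitoevo.io_formats import GenomeRecord
from mitoevo.synthetic import synthesize_genome


def genome_with_planted_copies(seed=0, length=12000, seg_len=386,
                               a0=3000, b0=7000, mismatches=0):
    """Random genome with an exact segment planted twice; the bases flanking
    each copy are forced to differ so the maximal repeat is exactly the
    planted segment."""
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=length))
    seg = list(rng.choice(list("ACGT"), size=seg_len))
    other = {"A": "C", "C": "G", "G": "T", "T": "A"}
    seq[a0:a0 + seg_len] = seg
    seq[b0:b0 + seg_len] = seg
    # break homology immediately outside both copies
    seq[b0 - 1] = other[seq[a0 - 1]]
    seq[b0 + seg_len] = other[seq[a0 + seg_len]]
    for k in range(mismatches):
        pos = b0 + 50 + 97 * k
        seq[pos] = other[seq[pos]]
    return GenomeRecord(id="g", sequence="".join(seq), circular=False)


class TestFindRepeats:
    def test_random_genome_is_empty(self, random_genome):
        assert find_repeats(random_genome, min_length=100) == []

    def test_exact_planted_copy_found_once(self):
        g = genome_with_planted_copies()
        pairs = find_repeats(g, min_length=100, min_identity=90)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.a_start, p.a_end) == (3001, 3386)
        assert (p.b_start, p.b_end) == (7001, 7386)
        assert p.length == 386 and p.identity == 100.0 and not p.inverted

    def test_two_mismatches_give_expected_identity(self):
        g = genome_with_planted_copies(mismatches=2)
        (p,) = find_repeats(g, min_length=100, min_identity=90)
        assert p.length == 386
        assert p.identity == pytest.approx(100 * 384 / 386, abs=0.05)

    def test_inverted_repeat_flagged(self):
        rng = np.random.default_rng(3)
        seq = list(rng.choice(list("ACGT"), size=8000))
        seg = "".join(rng.choice(list("ACGT"), size=300))
        seq[2000:2300] = list(seg)
        seq[5000:5300] = list(reverse_complement(seg))
        g = GenomeRecord(id="g", sequence="".join(seq), circular=False)
        pairs = find_repeats(g, min_length=100)
        assert any(p.inverted for p in pairs)
        assert not any(not p.inverted for p in pairs)

    def test_reverse_complement_mirrors_direct_pairs(self):
        g = genome_with_planted_copies(seed=5)
        rc = GenomeRecord(id="rc", sequence=reverse_complement(g.sequence),
                          circular=False)
        fwd = find_repeats(g, min_length=100)
        bwd = find_repeats(rc, min_length=100)
        L = len(g)
        assert {(p.length, p.identity) for p in fwd} == \
            {(p.length, p.identity) for p in bwd}
        (p,), (q,) = fwd, bwd
        assert {L - p.a_end + 1, L - p.b_end + 1} == {q.a_start, q.b_start}

    def test_multiple_planted_duplications_all_recovered(self):
        rng = np.random.default_rng(9)
        seq = list(rng.choice(list("ACGT"), size=20000))
        planted = [(1000, 5000, 250), (8000, 12000, 150), (14000, 17000, 400)]
        for a0, b0, n in planted:
            seg = rng.choice(list("ACGT"), size=n)
            seq[a0:a0 + n] = seg
            seq[b0:b0 + n] = seg
        g = GenomeRecord(id="g", sequence="".join(seq), circular=False)
        pairs = find_repeats(g, min_length=100)
        assert len(pairs) >= len(planted)
        for a0, b0, n in planted:
            overlap = max(
                (min(p.a_end, a0 + n) - max(p.a_start, a0 + 1) + 1)
                for p in pairs)
            assert overlap >= 0.95 * n

    def test_short_genome_rejected(self):
        g = GenomeRecord(id="s", sequence="ACGT" * 10)
        with pytest.raises(ValueError):
            find_repeats(g, min_length=100)


class TestCharacterize:
    def test_perfect_copies(self):
        g = genome_with_planted_copies()
        (p,) = find_repeats(g, min_length=100)
        rep = characterize_duplication(g, p)
        assert rep.duplicated_length == 386
        assert rep.insertions == [] and rep.deletions == []
        assert rep.identity == 100.0

    def test_interrupting_insertion_recovered(self):
        g, _, truth = synthesize_genome(
            length=15000, seed=21, circular=False,
            duplication_plan={"copy_a_start": 4001, "copy_b_start": 9001,
                              "insert_len": 488, "insert_after": 138})
        merged = merge_colinear_pairs(find_repeats(g), max_gap=600)
        direct = [p for p in merged if not p.inverted]
        rep = characterize_duplication(g, direct[0])
        assert [(c, ln) for c, _s, ln in rep.insertions] == [("B", 488)]
        # detection boundaries carry a little chance-homology fuzz; the
        # planted coordinates give the exact structure
        assert abs(rep.duplicated_length - 386) <= 20
        a1, a2 = truth.data["duplication"]["copy_a"]
        b1, b2 = truth.data["duplication"]["copy_b"]
        exact = characterize_duplication(
            g, RepeatPair(a_start=a1, a_end=a2, b_start=b1, b_end=b2,
                          identity=100.0, length=a2 - a1 + 1))
        assert exact.duplicated_length == 386
        assert [(c, ln) for c, _s, ln in exact.insertions] == [("B", 488)]

    def test_deletion_recovered(self):
        g, _, _ = synthesize_genome(
            length=15000, seed=22, circular=False,
            duplication_plan={"copy_a_start": 4001, "copy_b_start": 9001,
                              "deletion_len": 118, "deletion_at": 140})
        merged = merge_colinear_pairs(find_repeats(g), max_gap=600)
        rep = characterize_duplication(g, merged[0])
        assert [(c, ln) for c, _s, ln in rep.deletions] == [("B", 118)]

    def test_length_conservation_invariant(self):
        g, _, _ = synthesize_genome(
            length=15000, seed=23, circular=False,
            duplication_plan={"copy_a_start": 4001, "copy_b_start": 9001,
                              "insert_len": 200, "insert_after": 100})
        merged = merge_colinear_pairs(find_repeats(g), max_gap=600)
        p = merged[0]
        rep = characterize_duplication(g, p)
        span_a = p.a_end - p.a_start + 1
        span_b = p.b_end - p.b_start + 1
        ins = {"A": 0, "B": 0}
        for copy, _s, ln in rep.insertions:
            ins[copy] += ln
        assert span_a == rep.duplicated_length + ins["A"] \
            + rep.small_indel_bases["A"]
        assert span_b == rep.duplicated_length + ins["B"] \
            + rep.small_indel_bases["B"]

    def test_unrelated_spans_rejected(self, random_genome):
        pair = RepeatPair(a_start=1, a_end=300, b_start=5001, b_end=5300,
                          identity=100.0, length=300)
        with pytest.raises(ValueError, match="not a duplication pair"):
            characterize_duplication(random_genome, pair)
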