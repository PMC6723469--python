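"""RBH pairing, perfect/imperfect/unpaired classification, redundancy exclusion."""

import itertools

import numpy as np
import pytest

from annoconcord._aligner import encode, sw_score
from annoconcord.annotation_io import AnnotationRecord, Source
from annoconcord.pairs import (
    PairCategory,
    PairRecord,
    classify_pairs,
    exclude_redundant_unpaired,
    merge_final,
    read_pair_table,
    reciprocal_best_hits,
    write_pair_table,
)
from annoconcord.search import Enzyme, SearchParams


def _rec(gene, seq, source=Source.SOURCE_A, species="sp"):
    return AnnotationRecord(gene, gene, gene, species, source, seq)


def _mutate(seq, n, rng):
    s = list(seq)
    for i in rng.choice(len(seq), n, replace=False):
        s[i] = rng.choice([c for c in "ACGT" if c != s[i]])
    return "".join(s)


class TestReciprocalBestHits:
    def test_single_mutual_best(self):
        a = [_rec("x", "ACGT" * 100)]
        b = [_rec("xp", "ACGT" * 100, Source.SOURCE_B)]
        assert reciprocal_best_hits(a, b) == [("x", "xp")]

    def test_empty_side(self):
        assert reciprocal_best_hits([_rec("x", "ACGT" * 80)], []) == []

    def test_matches_bruteforce_on_diverged_families(self, rng):
        base = ["".join(rng.choice(list("ACGT"), 600)) for _ in range(4)]
        set_a = [_rec(f"a{i}", _mutate(base[i], 20, rng)) for i in range(4)]
        set_b = [_rec(f"b{i}", _mutate(base[i], 20, rng), Source.SOURCE_B) for i in range(4)]
        pairs = reciprocal_best_hits(set_a, set_b)
        # brute force: full score table, mutual argmax
        params = SearchParams()
        table = {}
        for ra, rb in itertools.product(set_a, set_b):
            table[(ra.gene_id, rb.gene_id)] = sw_score(
                encode(ra.sequence), encode(rb.sequence), 1.0, -1.0, 5.0, 2.0
            )
        expected = []
        for ra in set_a:
            best_b = max((rb.gene_id for rb in set_b), key=lambda g: table[(ra.gene_id, g)])
            best_a = max((x.gene_id for x in set_a), key=lambda g: table[(g, best_b)])
            if best_a == ra.gene_id:
                expected.append((ra.gene_id, best_b))
        assert sorted(pairs) == sorted(expected)
        assert sorted(pairs) == [(f"a{i}", f"b{i}") for i in range(4)]

    def test_identical_groups_fully_matched(self):
        seq = "ACGTAA" * 80
        set_a = [_rec("g1", seq), _rec("g2", seq)]
        set_b = [_rec("h1", seq, Source.SOURCE_B), _rec("h2", seq, Source.SOURCE_B)]
        pairs = reciprocal_best_hits(set_a, set_b)
        assert len(pairs) == 2
        assert {p[0] for p in pairs} == {"g1", "g2"}
        assert {p[1] for p in pairs} == {"h1", "h2"}


class TestClassifyPairs:
    def test_identical_sequences_perfect(self):
        seq = "ATG" + "CCG" * 398 + "TAA"
        a = [_rec("x", seq)]
        b = [_rec("y", seq, Source.SOURCE_B)]
        records = classify_pairs([("x", "y")], a, b, Enzyme.CHS, "sp")
        (pr,) = records
        assert pr.category is PairCategory.PERFECT
        assert pr.identity == 100.0
        assert pr.length_ratio == 1.0

    def test_five_prime_extension_imperfect_with_length_ratio(self):
        core = "TCG" * 400  # 1200 nt
        ext = "AGC" * 20 + core  # 1260 nt
        a = [_rec("x", ext)]
        b = [_rec("y", core, Source.SOURCE_B)]
        (pr,) = classify_pairs([("x", "y")], a, b, Enzyme.DFR, "sp")
        assert pr.category is PairCategory.IMPERFECT
        assert pr.length_ratio == pytest.approx(1260 / 1200)

    def test_leftovers_unpaired(self):
        a = [_rec("x", "ACG" * 200), _rec("z", "TTG" * 200)]
        b = [_rec("y", "ACG" * 200, Source.SOURCE_B)]
        records = classify_pairs([("x", "y")], a, b, Enzyme.CHI, "sp")
        cats = {r.category for r in records}
        assert PairCategory.UNPAIRED_A in cats
        unpaired = [r for r in records if r.category is PairCategory.UNPAIRED_A]
        assert unpaired[0].member_a == "z"


class TestExcludeRedundant:
    def _records(self):
        seq1 = "AAC" * 150
        seq2 = "GGT" * 150
        full = [
            _rec("a1", seq1),
            _rec("a2", seq1),  # within-source duplicate of a1
            _rec("a3", seq2),
            _rec("b1", seq1, Source.SOURCE_B),
        ]
        records = [
            PairRecord(Enzyme.CHS, "sp", "a1", "b1", PairCategory.PERFECT, 100.0, 1.0, 450, 450),
            PairRecord(Enzyme.CHS, "sp", "a2", None, PairCategory.UNPAIRED_A, length_a=450),
            PairRecord(Enzyme.CHS, "sp", "a3", None, PairCategory.UNPAIRED_A, length_a=450),
        ]
        return records, full

    def test_duplicate_unpaired_excluded(self):
        records, full = self._records()
        out = exclude_redundant_unpaired(records, full)
        by_gene = {r.member_a: r.category for r in out if r.member_a}
        assert by_gene["a2"] is PairCategory.EXCLUDED_REDUNDANT
        assert by_gene["a3"] is PairCategory.UNPAIRED_A
        assert by_gene["a1"] is PairCategory.PERFECT

    def test_noop_without_duplicates(self):
        records, full = self._records()
        unique_full = [r for r in full if r.gene_id != "a2"]
        out = exclude_redundant_unpaired(records, unique_full)
        assert [r.category for r in out if r.member_a == "a3"] == [PairCategory.UNPAIRED_A]

    def test_planted_duplicates_all_recategorised(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 450)) for _ in range(5)]
        full = [_rec(f"g{i}", s) for i, s in enumerate(seqs)]
        k = 3
        full += [_rec(f"g{i}dup", seqs[i]) for i in range(k)]
        records = [
            PairRecord(Enzyme.DFR, "sp", r.gene_id, None, PairCategory.UNPAIRED_A, length_a=450)
            for r in full
        ]
        out = exclude_redundant_unpaired(records, full)
        excluded = [r for r in out if r.category is PairCategory.EXCLUDED_REDUNDANT]
        # each planted duplicate and its original are both redundant
        assert len(excluded) == 2 * k


class TestMergeFinal:
    def test_union_with_source_a_preference(self):
        records = [
            PairRecord(Enzyme.CHS, "sp", "a1", "b1", PairCategory.PERFECT, 100.0, 1.0),
            PairRecord(Enzyme.CHS, "sp", "a2", "b2", PairCategory.PERFECT, 100.0, 1.0),
            PairRecord(Enzyme.CHS, "sp", None, "b3", PairCategory.UNPAIRED_B),
            PairRecord(Enzyme.CHS, "sp", "a4", None, PairCategory.EXCLUDED_REDUNDANT),
        ]
        final = merge_final(records)
        assert final[(Enzyme.CHS, "sp")] == {"a1", "a2", "b3"}


class TestPartitionInvariant:
    def test_every_gene_in_exactly_one_slot(self, rng):
        base = ["".join(rng.choice(list("ACGT"), 500)) for _ in range(6)]
        set_a = [_rec(f"a{i}", _mutate(base[i], 15, rng)) for i in range(5)]
        set_b = [
            _rec(f"b{i}", _mutate(base[i], 15, rng), Source.SOURCE_B) for i in [0, 1, 2, 5]
        ]
        rbh = reciprocal_best_hits(set_a, set_b)
        records = classify_pairs(rbh, set_a, set_b, Enzyme.F3H, "sp")
        records = exclude_redundant_unpaired(records, set_a + set_b)
        slots_a = [r.member_a for r in records if r.member_a]
        slots_b = [r.member_b for r in records if r.member_b]
        assert sorted(slots_a) == sorted(r.gene_id for r in set_a)
        assert sorted(slots_b) == sorted(r.gene_id for r in set_b)


def test_pair_table_roundtrip(tmp_path):
    records = [
        PairRecord(Enzyme.ANS, "sp1", "a1", "b1", PairCategory.PERFECT, 100.0, 1.0, 900, 900),
        PairRecord(Enzyme.ANS, "sp1", "a2", "b2", PairCategory.IMPERFECT, 98.5, 1.05, 945, 900, rescued_by_tree=True),
        PairRecord(Enzyme.ANS, "sp2", "a3", None, PairCategory.UNPAIRED_A, length_a=600),
    ]
    path = tmp_path / "pairs.tsv"
    write_pair_table(records, path)
    back = read_pair_table(path)
    assert [(r.member_a, r.member_b, r.category, r.rescued_by_tree) for r in back] == [
        (r.member_a, r.member_b, r.category, r.rescued_by_tree) for r in records
    ]
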