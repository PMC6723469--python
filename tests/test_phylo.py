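"""Alignment, codon-block trimming, NJ/GTR trees, rescue and rooting."""

from io import StringIO

import numpy as np
import pytest
from skbio import TreeNode

from annoconcord.phylo import (
    GeneTree,
    MultipleAlignment,
    TrimParams,
    align_family,
    build_tree,
    codon_column_is_good,
    gtr_distance_matrix,
    rescue_unpaired,
    root_with_outgroup,
    trim_codon_blocks,
)
from annoconcord.pairs import PairCategory, PairRecord
from annoconcord.search import Enzyme, SearchParams
from annoconcord.simulate import (
    SubstitutionModel,
    evolve_along_branch,
    random_root_cds,
)

DEC = np.array(list("ACGT"), dtype="U1")


def _dec(codes):
    return "".join(DEC[codes])


class TestAlignFamily:
    def test_identical_sequences_gap_free(self):
        seq = "ATGCCC" * 50
        aln = align_family([("a", seq), ("b", seq)])
        assert aln.column_count == len(seq)
        assert aln.rows["a"] == seq
        assert aln.rows["b"] == seq

    def test_three_nt_insertion_yields_single_gap_run(self):
        base = "ATGCAT" * 60
        ins = base[:180] + "GGG" + base[180:]
        aln = align_family([("short", base), ("long", ins)])
        assert aln.column_count == len(ins)
        row = aln.rows["short"]
        gap_runs = [len(x) for x in row.replace("A", "N").replace("C", "N").replace("G", "N").replace("T", "N").split("N") if x]
        assert gap_runs == [3]
        assert aln.rows["long"] == ins

    def test_input_order_invariance(self, rng):
        root = random_root_cds(300, rng)
        seqs = []
        for i in range(5):
            child = evolve_along_branch(root, 0.1, SubstitutionModel.JC, 1.0, rng)
            seqs.append((f"t{i}", _dec(child)))
        aln1 = align_family(seqs)
        aln2 = align_family(list(reversed(seqs)))
        assert aln1.rows == aln2.rows

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            align_family([("a", "ACGT")])


class TestTrimCodonBlocks:
    def test_identical_alignment_untouched(self):
        rows = {f"s{i}": "ATGAAACCCGGGTTTCATCACGAGTGGTAA" for i in range(4)}
        aln = MultipleAlignment(ids=sorted(rows), rows=rows, codon_frame=True)
        trimmed, ranges = trim_codon_blocks(aln)
        assert trimmed.column_count == aln.column_count
        assert ranges == [(0, 10)]

    def test_four_codon_run_discarded_under_b4_of_five(self):
        # 4 conserved codons flanked by columns that fail the majority rule
        good = "ATGAAACCCGGG"
        rows = {}
        variants = ["TTT", "GGG", "CCC", "AAA"]
        for i in range(4):
            rows[f"s{i}"] = variants[i] + good + variants[(i + 1) % 4]
        aln = MultipleAlignment(ids=sorted(rows), rows=rows, codon_frame=True)
        with pytest.raises(ValueError, match="relax"):
            trim_codon_blocks(aln)

    def test_survivors_match_independent_column_rule(self, rng):
        # random alignment mixing conserved and noisy codon columns
        n_rows, n_codons = 8, 60
        conserved = rng.random(n_codons) < 0.6
        rows = {f"s{i}": [] for i in range(n_rows)}
        base_codons = ["".join(rng.choice(list("ACGT"), 3)) for _ in range(n_codons)]
        for c in range(n_codons):
            for i in range(n_rows):
                if conserved[c] or i < 5:
                    rows[f"s{i}"].append(base_codons[c])
                else:
                    rows[f"s{i}"].append("".join(rng.choice(list("ACGT"), 3)))
        rows = {k: "".join(v) for k, v in rows.items()}
        aln = MultipleAlignment(ids=sorted(rows), rows=rows, codon_frame=True)
        params = TrimParams()
        trimmed, ranges = trim_codon_blocks(aln, params)
        # independent per-column re-evaluation
        codes = aln.codes()
        good = [codon_column_is_good(codes, c, params) for c in range(n_codons)]
        expected_cols = []
        run = []
        for c, g in enumerate(good + [False]):
            if g:
                run.append(c)
            else:
                if len(run) >= params.b4_min_block_codons:
                    expected_cols.extend(run)
                run = []
        got_cols = [c for s, e in ranges for c in range(s, e)]
        assert got_cols == expected_cols
        assert trimmed.column_count == 3 * len(expected_cols)

    def test_gap_heavy_columns_fail_b5(self):
        rows = {
            "s1": "ATG" * 10,
            "s2": "ATG" * 10,
            "s3": "---" + "ATG" * 9,
            "s4": "---" + "ATG" * 9,
            "s5": "---" + "ATG" * 9,
        }
        aln = MultipleAlignment(ids=sorted(rows), rows=rows, codon_frame=True)
        codes = aln.codes()
        assert not codon_column_is_good(codes, 0, TrimParams())  # 60% gapped > b5=0.5
        assert codon_column_is_good(codes, 1, TrimParams())


class TestBuildTree:
    def test_three_taxon_closed_form(self, rng):
        root = random_root_cds(900, rng)
        rows = {}
        for name, t in (("a", 0.05), ("b", 0.10), ("c", 0.20)):
            rows[name] = _dec(evolve_along_branch(root, t, SubstitutionModel.JC, 1.0, rng))
        aln = MultipleAlignment(ids=sorted(rows), rows=rows, codon_frame=True)
        gt = build_tree(aln, bootstraps=0, gamma_shape=None)
        d = gtr_distance_matrix(aln.codes(), gamma_shape=None)
        expected = {
            "a": (d[0, 1] + d[0, 2] - d[1, 2]) / 2,
            "b": (d[0, 1] + d[1, 2] - d[0, 2]) / 2,
            "c": (d[0, 2] + d[1, 2] - d[0, 1]) / 2,
        }
        for tip in gt.tree.tips():
            assert tip.length == pytest.approx(expected[tip.name], abs=1e-9)

    def test_five_taxon_topology_recovery(self, rng):
        newick = "((A:0.08,B:0.08):0.05,(C:0.06,D:0.06):0.07,E:0.2);"
        sp = TreeNode.read(StringIO(newick))
        root = random_root_cds(3000, rng)
        rows = {}

        def rec(node, codes):
            ev = evolve_along_branch(codes, node.length or 0.0, SubstitutionModel.JC, 1.0, rng)
            if node.is_tip():
                rows[node.name] = _dec(ev)
            else:
                for ch in node.children:
                    rec(ch, ev)

        for ch in sp.children:
            rec(ch, root)
        aln = MultipleAlignment(ids=sorted(rows), rows=rows, codon_frame=True)
        gt = build_tree(aln, bootstraps=0, seed=0)
        from annoconcord.phylo import _splits

        splits = _splits(gt.tree, frozenset("ABCDE"))
        assert frozenset("CD") in splits or frozenset("ABE") in splits
        assert frozenset("AB") in splits or frozenset("CDE") in splits

    def test_identical_rows_distance_zero(self, rng):
        seq = _dec(random_root_cds(600, rng))
        other = _dec(evolve_along_branch(random_root_cds(600, rng), 0.0, SubstitutionModel.JC, 1.0, rng))
        rows = {"x": seq, "y": seq, "z": other}
        aln = MultipleAlignment(ids=sorted(rows), rows=rows, codon_frame=True)
        d = gtr_distance_matrix(aln.codes())
        xi, yi = sorted(rows).index("x"), sorted(rows).index("y")
        assert d[xi, yi] == pytest.approx(0.0, abs=1e-9)
        gt = build_tree(aln, bootstraps=0)
        tx = gt.tree.find("x")
        ty = gt.tree.find("y")
        assert tx.distance(ty) == pytest.approx(0.0, abs=1e-9)

    def test_all_gap_row_rejected(self):
        rows = {"a": "ATGTAA", "b": "ATGTAA", "c": "------"}
        aln = MultipleAlignment(ids=sorted(rows), rows=rows, codon_frame=True)
        with pytest.raises(ValueError, match="all-gap"):
            build_tree(aln, bootstraps=0)

    def test_bootstrap_deterministic_given_seed(self, rng):
        root = random_root_cds(600, rng)
        rows = {
            f"t{i}": _dec(evolve_along_branch(root, 0.05 * (i + 1), SubstitutionModel.JC, 1.0, rng))
            for i in range(5)
        }
        aln = MultipleAlignment(ids=sorted(rows), rows=rows, codon_frame=True)
        gt1 = build_tree(aln, bootstraps=50, seed=9)
        gt2 = build_tree(aln, bootstraps=50, seed=9)
        assert gt1.supports == gt2.supports


def _pair(enzyme, species, a, b, cat, **kw):
    return PairRecord(enzyme, species, a, b, cat, **kw)


class TestRescue:
    def _tree(self, newick):
        return GeneTree(tree=TreeNode.read(StringIO(newick)))

    def test_cross_source_cherry_merged(self):
        gt = self._tree("((x|A:0.01,y|B:0.01):0.4,(p|A:0.1,q|B:0.1):0.2,z|A:0.3);")
        records = [
            _pair(Enzyme.DFR, "s1", "x", None, PairCategory.UNPAIRED_A, length_a=900),
            _pair(Enzyme.DFR, "s1", None, "y", PairCategory.UNPAIRED_B, length_b=870),
            _pair(Enzyme.DFR, "s1", "p", "q", PairCategory.IMPERFECT, identity=99.0, length_ratio=1.0),
            _pair(Enzyme.DFR, "s1", "z", None, PairCategory.UNPAIRED_A, length_a=900),
        ]
        out = rescue_unpaired(gt, records)
        rescued = [r for r in out if r.rescued_by_tree]
        assert len(rescued) == 1
        assert (rescued[0].member_a, rescued[0].member_b) == ("x", "y")
        assert rescued[0].category is PairCategory.IMPERFECT

    def test_gene_count_conserved(self):
        gt = self._tree("((x|A:0.01,y|B:0.01):0.4,(p|A:0.1,q|B:0.1):0.2,z|A:0.3);")
        records = [
            _pair(Enzyme.DFR, "s1", "x", None, PairCategory.UNPAIRED_A),
            _pair(Enzyme.DFR, "s1", None, "y", PairCategory.UNPAIRED_B),
            _pair(Enzyme.DFR, "s1", "p", "q", PairCategory.IMPERFECT, identity=99.0, length_ratio=1.0),
            _pair(Enzyme.DFR, "s1", "z", None, PairCategory.UNPAIRED_A),
        ]
        out = rescue_unpaired(gt, records)
        genes = sorted(g for r in out for g in r.genes)
        assert genes == sorted(g for r in records for g in r.genes)

    def test_no_unpaired_leaves_noop(self):
        gt = self._tree("((p|A:0.1,q|B:0.1):0.2,(r|A:0.1,s|B:0.1):0.2);")
        records = [
            _pair(Enzyme.CHI, "s1", "p", "q", PairCategory.PERFECT, identity=100.0, length_ratio=1.0),
            _pair(Enzyme.CHI, "s1", "r", "s", PairCategory.IMPERFECT, identity=98.0, length_ratio=1.0),
        ]
        assert rescue_unpaired(gt, records) == records

    def test_same_source_cherry_untouched(self):
        gt = self._tree("((x|A:0.01,z|A:0.01):0.4,(p|A:0.1,q|B:0.1):0.2,y|B:0.3);")
        records = [
            _pair(Enzyme.ANS, "s1", "x", None, PairCategory.UNPAIRED_A),
            _pair(Enzyme.ANS, "s1", "z", None, PairCategory.UNPAIRED_A),
            _pair(Enzyme.ANS, "s1", None, "y", PairCategory.UNPAIRED_B),
            _pair(Enzyme.ANS, "s1", "p", "q", PairCategory.PERFECT, identity=100.0, length_ratio=1.0),
        ]
        out = rescue_unpaired(gt, records)
        assert not any(r.rescued_by_tree for r in out)

    def test_cross_species_cherry_untouched(self):
        gt = self._tree("((x|A:0.01,y|B:0.01):0.4,(p|A:0.1,q|B:0.1):0.2,z|A:0.3);")
        records = [
            _pair(Enzyme.ANS, "s1", "x", None, PairCategory.UNPAIRED_A),
            _pair(Enzyme.ANS, "s2", None, "y", PairCategory.UNPAIRED_B),
            _pair(Enzyme.ANS, "s1", "p", "q", PairCategory.PERFECT, identity=100.0, length_ratio=1.0),
            _pair(Enzyme.ANS, "s1", "z", None, PairCategory.UNPAIRED_A),
        ]
        out = rescue_unpaired(gt, records)
        assert not any(r.rescued_by_tree for r in out)


class TestRooting:
    def test_single_outgroup_roots_on_pendant_edge(self):
        gt = GeneTree(tree=TreeNode.read(StringIO("((a:1,b:1):1,(c:1,d:1):1);")))
        rooted = root_with_outgroup(gt, ["d"])
        kids = rooted.tree.children
        names = [k.name for k in kids]
        assert "d" in names

    def test_nonmonophyletic_outgroup_best_agreement(self):
        # exhaustive edge scan oracle on a small tree
        newick = "((a:1,(b:1,o1:1):1):1,((c:1,o2:1):1,o3:1):1);"
        tree = TreeNode.read(StringIO(newick))
        outgroup = {"o1", "o2", "o3"}
        ingroup = {"a", "b", "c"}
        leaves = outgroup | ingroup

        def agreement(side):
            agree = len(outgroup & side) + len(ingroup - side)
            return max(agree, len(leaves) - agree)

        best = 0
        for node in tree.traverse(include_self=False):
            side = {node.name} if node.is_tip() else {t.name for t in node.tips()}
            best = max(best, agreement(side))
        rooted = root_with_outgroup(GeneTree(tree=tree), sorted(outgroup))
        sides = [
            {child.name} if child.is_tip() else {t.name for t in child.tips()}
            for child in rooted.tree.children
        ]
        assert max(agreement(s) for s in sides) == best

    def test_empty_outgroup_error(self):
        gt = GeneTree(tree=TreeNode.read(StringIO("((a:1,b:1):1,c:1);")))
        with pytest.raises(ValueError):
            root_with_outgroup(gt, [])

    def test_absent_outgroup_error(self):
        gt = GeneTree(tree=TreeNode.read(StringIO("((a:1,b:1):1,c:1);")))
        with pytest.raises(ValueError, match="absent"):
            root_with_outgroup(gt, ["zz"])
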