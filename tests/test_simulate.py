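"""Birth-death family simulation, sequence evolution, corruption channel."""

import math
from io import StringIO

import numpy as np
import pytest
from skbio import TreeNode

from annoconcord.annotation_io import longest_orf
from annoconcord.pairs import PairCategory
from annoconcord.simulate import (
    CorruptionConfig,
    SimulationConfig,
    SubstitutionModel,
    TrueGene,
    clean_corruption,
    corrupt_annotations,
    evolve_along_branch,
    generate,
    random_root_cds,
    simulate_family,
    write_source_files,
)


class TestSimulateFamily:
    def test_no_events_gives_one_gene_per_species(self, rng, tree10):
        tree = TreeNode.read(StringIO(tree10))
        gt = simulate_family(tree, 0.0, 0.0, rng)
        species = sorted(l.species for l in gt.leaves())
        assert species == sorted(t.name for t in tree.tips())

    def test_birth_process_mean_matches_expectation(self, rng):
        # pure birth on a two-species clock tree of depth 1
        tree = TreeNode.read(StringIO("(sp1:1.0,sp2:1.0);"))
        lam = 0.5
        sizes = np.array(
            [
                sum(1 for l in simulate_family(tree, lam, 0.0, rng).leaves() if l.species == "sp1")
                for _ in range(2000)
            ]
        )
        expected = math.exp(lam)
        se = sizes.std(ddof=1) / math.sqrt(len(sizes))
        assert abs(sizes.mean() - expected) < 3 * se

    def test_heavy_loss_produces_zero_copy_species(self, rng, tree10):
        tree = TreeNode.read(StringIO(tree10))
        seen_zero = False
        for _ in range(20):
            gt = simulate_family(tree, 0.1, 5.0, rng)
            present = set() if gt is None else {l.species for l in gt.leaves()}
            if len(present) < len(list(tree.tips())):
                seen_zero = True
                break
        assert seen_zero

    def test_expected_size_cap_enforced(self, rng):
        tree = TreeNode.read(StringIO("(sp1:1.0,sp2:1.0);"))
        with pytest.raises(ValueError, match="cap"):
            simulate_family(tree, 10.0, 0.0, rng, cap=100)


class TestEvolveSequences:
    def test_zero_branch_identical(self, rng):
        root = random_root_cds(600, rng)
        child = evolve_along_branch(root, 0.0, SubstitutionModel.JC, 1.0, rng)
        assert np.array_equal(root, child)

    def test_jc_mismatch_fraction_closed_form(self, rng):
        root = random_root_cds(2001, rng)
        t = 0.1
        child = evolve_along_branch(root, t, SubstitutionModel.JC, 1.0, rng)
        p = float((root != child).mean())
        expected = 0.75 * (1 - math.exp(-4 * t / 3))
        se = math.sqrt(expected * (1 - expected) / len(root))
        assert abs(p - expected) < 3 * se

    def test_hky_transition_bias(self, rng):
        root = random_root_cds(9000, rng)
        child = evolve_along_branch(root, 0.3, SubstitutionModel.HKY, 4.0, rng)
        diff = root != child
        pairs = set(map(frozenset, [(0, 2), (1, 3)]))
        ts = sum(1 for a, b in zip(root[diff], child[diff]) if frozenset((int(a), int(b))) in pairs)
        tv = int(diff.sum()) - ts
        assert ts > tv

    def test_protected_evolution_keeps_valid_orf(self, rng, tree6):
        cfg = SimulationConfig(
            species_tree_newick=tree6,
            duplication_rate=1.0,
            loss_rate=0.2,
            corruption=clean_corruption(),
            seed=5,
        )
        ds = generate(cfg)
        for gene in ds.true_genes:
            span = longest_orf(gene.cds)
            assert span is not None
            assert gene.cds[span[0] : span[1]] == gene.cds
            assert len(gene.cds) % 3 == 0


def _true_genes(n, rng, species="sp01", family="DFR"):
    return [
        TrueGene(f"{species}_{family}_g{i:04d}", species, family, "".join(
            np.array(list("ACGT"))[random_root_cds(900, rng)]
        ))
        for i in range(n)
    ]


class TestCorruption:
    def test_clean_channel_all_perfect(self, rng):
        genes = _true_genes(50, rng)
        out_a, out_b, truth = corrupt_annotations(genes, clean_corruption(), rng)
        assert len(out_a) == len(out_b) == 50
        cats = set(truth.implied_categories().values())
        assert cats == {PairCategory.PERFECT}
        assert [e.sequence for e in out_a] == [g.cds for g in genes]

    def test_miss_rate_binomial(self, rng):
        genes = _true_genes(1000, rng)
        cfg = CorruptionConfig(
            miss_prob=0.1,
            utr_extend_prob=0.0,
            truncation_prob=0.0,
            variant_rate=0.0,
            identical_duplicate_prob=0.0,
        )
        out_a, _, truth = corrupt_annotations(genes, cfg, rng)
        dropped = 1000 - len(out_a)
        se = math.sqrt(1000 * 0.1 * 0.9)
        assert abs(dropped - 100) < 3 * se

    def test_single_coding_extension_implies_imperfect_longer(self, rng):
        genes = _true_genes(200, rng)
        cfg = CorruptionConfig(
            miss_prob=0.0,
            utr_extend_prob=0.5,
            coding_extension_prob=1.0,
            truncation_prob=0.0,
            variant_rate=0.0,
            identical_duplicate_prob=0.0,
        )
        _, _, truth = corrupt_annotations(genes, cfg, rng)
        imperfect = [r for r in truth.rows if r.implied_a is PairCategory.IMPERFECT]
        assert imperfect, "some genes must be extended at these rates"
        for r in imperfect:
            assert max(len(r.cds_a), len(r.cds_b)) > min(len(r.cds_a), len(r.cds_b)) or r.cds_a != r.cds_b
        # extension events change only one side in most cases -> length ratio > 1
        one_sided = [
            r for r in imperfect if ("coding_ext" in r.events_a) != ("coding_ext" in r.events_b)
        ]
        for r in one_sided:
            assert len(r.cds_a) != len(r.cds_b)

    def test_utr_only_extension_is_invisible_after_orf_inference(self, rng):
        genes = _true_genes(100, rng)
        cfg = CorruptionConfig(
            miss_prob=0.0,
            utr_extend_prob=1.0,
            coding_extension_prob=0.0,
            truncation_prob=0.0,
            variant_rate=0.0,
            identical_duplicate_prob=0.0,
        )
        out_a, out_b, truth = corrupt_annotations(genes, cfg, rng)
        # every transcript carries UTRs but the implied CDS equals the true CDS
        for row, gene in zip(truth.rows, genes):
            assert row.cds_a == gene.cds
            assert row.implied_a is PairCategory.PERFECT
        for e in out_a:
            assert len(e.sequence) > 900
            span = longest_orf(e.sequence)
            assert e.sequence[span[0] : span[1]] in {g.cds for g in genes}

    def test_duplicates_implied_excluded(self, rng):
        genes = _true_genes(300, rng)
        cfg = CorruptionConfig(
            miss_prob=0.0,
            utr_extend_prob=0.0,
            truncation_prob=0.0,
            variant_rate=0.0,
            identical_duplicate_prob=0.2,
        )
        out_a, out_b, truth = corrupt_annotations(genes, cfg, rng)
        dup_rows = [r for r in truth.rows if r.kind == "duplicate"]
        assert dup_rows
        for r in dup_rows:
            cat = r.implied_a or r.implied_b
            assert cat is PairCategory.EXCLUDED_REDUNDANT


class TestDeterminism:
    def test_identical_seed_byte_identical_fasta(self, tmp_path, tree6):
        cfg = SimulationConfig(
            species_tree_newick=tree6, duplication_rate=1.0, loss_rate=0.3, seed=77
        )
        files = []
        for run in ("one", "two"):
            ds = generate(cfg)
            fasta = tmp_path / f"{run}.fasta"
            write_source_files(ds.source_a, fasta, tmp_path / f"{run}.tsv")
            files.append(fasta.read_bytes())
        assert files[0] == files[1]

    def test_different_seeds_differ(self, tree6):
        base = dict(species_tree_newick=tree6, duplication_rate=1.0, loss_rate=0.3)
        d1 = generate(SimulationConfig(seed=1, **base))
        d2 = generate(SimulationConfig(seed=2, **base))
        assert d1.seeds != d2.seeds
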