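# annoconcord

Annotation-concordance and gene-family copy-number analysis for the
anthocyanin branch of the flavonoid biosynthesis pathway (FBP), with a
ground-truthed dual-source annotation simulator.

## The problem

Gene copy number is only as reliable as the gene annotation it is counted
from. For many plant genomes two independent annotations coexist — one from
the NCBI eukaryotic annotation pipeline, one from a genome-specific pipeline —
and they disagree: genes missed by one source, coding boundaries placed
differently (UTR handling), redundant transcript variants, identical duplicate
entries. This package implements a workflow that quantifies that disagreement
for the seven core anthocyanin-pathway enzymes (CHS, CHI, F3H, F3′H, F3′5′H,
DFR, ANS):

1. **normalize** — reduce each source's transcripts to one CDS per locus
   (longest-ORF inference with a 300 nt floor, longest-variant-per-locus);
2. **mine** — assign genes to enzyme families by relaxed local similarity
   search (Smith–Waterman, +1/−1, Karlin–Altschul E ≤ 1e−50 against per-enzyme
   seed queries);
3. **classify** — per species and enzyme, match the two sources by reciprocal
   best hits (RBH) and label each gene a *perfect pair* (identical CDS
   strings), *imperfect pair* (RBH with differences), or *unpaired*; unpaired
   genes duplicating another same-source CDS are *excluded* as redundant;
4. **tree + rescue** — build per-enzyme gene trees (progressive alignment,
   codon-mode block trimming with b2/b4/b5, neighbor joining on GTR+Γ
   distances, codon bootstrap) and reclassify cross-source unpaired genes that
   form a same-species cherry as imperfect pairs;
5. **report** — concordance accounting (with the identity
   totalₐ = perfect + imperfect + unpairedₐ + excludedₐ), per-enzyme ×
   per-species copy-number matrices with discrepancy/zero flags, and
   mean ± SD CDS lengths per category.

Real dual-source annotation bundles are too large to ship, so the package
carries a first-class simulator: gene families evolve by a birth–death process
along a 21-taxon eudicot species tree, sequences evolve under JC/HKY, and two
annotation sources are derived from the same truth through independent
corruption channels (missed genes, UTR extensions with and without coding
boundary shifts, in-frame truncations, transcript variants, identical
duplicates). The simulator writes a truth table with the pair category each
corruption implies, so every pipeline claim is tested as a recovery statement.
See `docs/methods.md` for models, parameters and limitations.

## Worked example

The analysis drivers under `analysis/` run the whole study end to end and
write artifacts under `results/analysis/`:

```bash
cd analysis
python 01_simulate_annotations.py --seed 1
python 02_normalize_annotations.py --seed 1
python 03_mine_homologs.py       --seed 1
python 04_classify_pairs.py      --seed 1
python 05_build_trees_and_rescue.py --seed 1
python 06_summarize_concordance.py  --seed 1
python 07_evaluate_against_truth.py --seed 1
```

With seed 1 the simulator produces 1258 true genes across the seven families;
after corruption the two sources annotate 1493 and 1509 transcripts, which
normalisation reduces to 1170 and 1197 CDS. Classification then prints (step
04, pre-rescue):

```
pre-rescue concordance accounting:
  total_a        1170
  total_b        1197
  shared_pairs   1001
  perfect         574
  imperfect       427
  unpaired_a      109
  unpaired_b      127
  excluded_a       60
  excluded_b       69
identity check: 574+427+109+60 = 1170 (source A)
```

i.e. every normalised gene lands in exactly one category and the per-source
totals decompose exactly — the accounting identity that real dual-source
comparisons rely on. Step 05 builds the six gene trees (the two CYP75
hydroxylases jointly) and rescues cross-source unpaired genes that cluster as
same-species cherries:

```
rescued 8 cross-source unpaired pairs into imperfect pairs
  F3p5pH Vivin: Vivin_F3p5pH_g024.1 ~ Vivin_F3p5pH_g024.1 (identity 100.0%)
  ...
```

Step 06 writes the final report (574 perfect / 435 imperfect after rescue),
the 147-cell copy-number matrix (89 cells discrepant between sources, 6 with
zeros) and per-category length statistics, and step 07 scores the run against
the simulator's truth:

```
category recovery: 2328/2367 = 98.35%
tree-rescued pairs: 8
```

so ~98% of emitted annotations received exactly the category their corruption
history implies, and 8 boundary-shifted gene models that RBH alone left
unpaired were recovered by the phylogenetic rescue.

## Command line

The same stages are exposed as a CLI over a JSON configuration:

```bash
annoconcord all --outdir results/run --seed 7
annoconcord simulate --config cfg.json --outdir results/run --seed 7
```

Each stage writes a `manifest.json` (inputs, parameters, seed, output
checksums), so every artifact is regenerable from its manifest.
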