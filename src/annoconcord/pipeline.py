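"""End-to-end orchestration: simulate -> normalize -> mine -> classify -> tree
-> rescue -> report.

Two layers:

* an in-memory API (``normalize_sources``, ``mine_homologs``, ``classify_all``,
  ``build_family_trees``, ``rescue_all``, ``summarize``) used by tests and the
  acceptance script, and
* file-based stages with manifests (inputs, parameters, seed, checksums) for
  the command line and the analysis drivers; every artifact is regenerable
  from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO

from annoconcord.annotation_io import (
    AnnotationRecord,
    Source,
    SourceDialect,
    VariantPolicy,
    normalize_annotation_set,
    read_normalized,
    write_normalized,
)
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
from annoconcord.phylo import (
    GeneTree,
    MultipleAlignment,
    TrimParams,
    align_family,
    build_tree,
    rescue_unpaired,
    trim_codon_blocks,
)
from annoconcord.search import (
    CYP75_ENZYMES,
    Enzyme,
    EnzymeSpec,
    KEGG_CODES,
    SearchParams,
    identify_homologs,
)
from annoconcord.simulate import (
    SimulationConfig,
    emitted_to_records,
    generate,
    read_seed_fasta,
    species_of_gene_id,
    write_seed_fasta,
    write_source_files,
)
from annoconcord.summary import (
    concordance_report,
    copy_number_matrix,
    length_stats,
    write_tables,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "mine", "classify", "tree", "rescue", "report")

#: tree groups: the CYP75 hydroxylases are analysed jointly
TREE_GROUPS: dict[str, tuple[Enzyme, ...]] = {
    "CHS": (Enzyme.CHS,),
    "CHI": (Enzyme.CHI,),
    "F3H": (Enzyme.F3H,),
    "CYP75": CYP75_ENZYMES,
    "DFR": (Enzyme.DFR,),
    "ANS": (Enzyme.ANS,),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: Path = Path("results/pipeline")
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    search: SearchParams = field(default_factory=SearchParams)
    pair_search: SearchParams = field(default_factory=lambda: SearchParams(evalue_max=10.0))
    # profile-alignment scoring: +2/-1 keeps homologous columns positive down
    # to ~33% identity (deep CYP75 joint alignments), with stiffer gap costs
    msa_search: SearchParams = field(
        default_factory=lambda: SearchParams(
            match_reward=2, mismatch_penalty=-1, gap_open=10, gap_extend=2, evalue_max=10.0
        )
    )
    trim: TrimParams = field(default_factory=TrimParams)
    tree_bootstraps: int = 0
    rescue_min_support: int = 0
    rescue_cluster_mode: str = "cherry"
    dialect_a: SourceDialect = field(
        default_factory=lambda: SourceDialect("ncbi-style", VariantPolicy.LONGEST_PER_LOCUS)
    )
    dialect_b: SourceDialect = field(
        default_factory=lambda: SourceDialect(
            "genome-specific", VariantPolicy.LONGEST_PER_LOCUS_FROM_FEATURE_TABLE
        )
    )

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, tuple):
                return list(obj)
            if hasattr(obj, "value"):
                return obj.value
            return obj

        return json.dumps(enc(self), indent=2, default=str)


# ---------------------------------------------------------------------------
# in-memory pipeline


def normalize_sources(
    raw_a: Sequence[AnnotationRecord],
    raw_b: Sequence[AnnotationRecord],
    config: PipelineConfig,
) -> tuple[list[AnnotationRecord], list[AnnotationRecord]]:
    """Normalise both sources per species (CDS inference, variant removal)."""

    def norm(raw: Sequence[AnnotationRecord], dialect: SourceDialect) -> list[AnnotationRecord]:
        by_species: dict[str, list[AnnotationRecord]] = {}
        for r in raw:
            by_species.setdefault(r.species, []).append(r)
        out: list[AnnotationRecord] = []
        for sp in sorted(by_species):
            out.extend(normalize_annotation_set(by_species[sp], dialect))
        return out

    return norm(raw_a, config.dialect_a), norm(raw_b, config.dialect_b)


def make_enzyme_specs(seeds: dict[str, str]) -> list[EnzymeSpec]:
    specs = []
    for fam, seq in seeds.items():
        enzyme = Enzyme(fam)
        specs.append(
            EnzymeSpec(
                enzyme=enzyme,
                seed_queries=((f"seed_{fam}", seq),),
                kegg_code=KEGG_CODES[enzyme],
            )
        )
    return specs


def mine_homologs(
    norm_a: Sequence[AnnotationRecord],
    norm_b: Sequence[AnnotationRecord],
    seeds: dict[str, str],
    config: PipelineConfig,
) -> dict[Source, dict[Enzyme, dict[str, set[str]]]]:
    """Per source: enzyme -> species -> assigned gene ids."""
    specs = make_enzyme_specs(seeds)
    out: dict[Source, dict[Enzyme, dict[str, set[str]]]] = {}
    for source, records in ((Source.SOURCE_A, norm_a), (Source.SOURCE_B, norm_b)):
        assignment, _cyp75 = identify_homologs(specs, records, config.search)
        species_of = {r.gene_id: r.species for r in records}
        nested: dict[Enzyme, dict[str, set[str]]] = {}
        for enz, gids in assignment.items():
            for gid in gids:
                nested.setdefault(enz, {}).setdefault(species_of[gid], set()).add(gid)
        out[source] = nested
    return out


def classify_all(
    norm_a: Sequence[AnnotationRecord],
    norm_b: Sequence[AnnotationRecord],
    assignments: dict[Source, dict[Enzyme, dict[str, set[str]]]],
    config: PipelineConfig,
) -> list[PairRecord]:
    """RBH classification per (species, enzyme), then redundancy exclusion."""
    rec_a = {r.gene_id: r for r in norm_a}
    rec_b = {r.gene_id: r for r in norm_b}
    records: list[PairRecord] = []
    keys = set()
    for source, nested in assignments.items():
        for enz, by_sp in nested.items():
            for sp in by_sp:
                keys.add((enz, sp))
    for enz, sp in sorted(keys, key=lambda k: (k[0].value, k[1])):
        gids_a = assignments.get(Source.SOURCE_A, {}).get(enz, {}).get(sp, set())
        gids_b = assignments.get(Source.SOURCE_B, {}).get(enz, {}).get(sp, set())
        set_a = [rec_a[g] for g in sorted(gids_a)]
        set_b = [rec_b[g] for g in sorted(gids_b)]
        rbh = reciprocal_best_hits(set_a, set_b, config.pair_search)
        records.extend(classify_pairs(rbh, set_a, set_b, enz, sp, config.pair_search))
    full_sets = list(norm_a) + list(norm_b)
    return exclude_redundant_unpaired(records, full_sets)


def build_family_trees(
    records: Sequence[PairRecord],
    seq_a: dict[str, str],
    seq_b: dict[str, str],
    config: PipelineConfig,
    seed: Optional[int] = None,
) -> dict[str, GeneTree]:
    """One tree per enzyme group over all non-excluded genes of both sources.

    Leaves are named ``<gene_id>|<A/B>`` since ids may repeat across sources.
    """
    seed = config.seed if seed is None else seed
    trees: dict[str, GeneTree] = {}
    for group, enzymes in TREE_GROUPS.items():
        leaf_meta: dict[str, dict] = {}
        seqs: list[tuple[str, str]] = []
        for pr in records:
            if pr.enzyme not in enzymes:
                continue
            if pr.category is PairCategory.EXCLUDED_REDUNDANT:
                continue
            for gid, side, pool in ((pr.member_a, "A", seq_a), (pr.member_b, "B", seq_b)):
                if gid is not None and gid in pool:
                    leaf = f"{gid}|{side}"
                    seqs.append((leaf, pool[gid]))
                    leaf_meta[leaf] = {
                        "species": pr.species,
                        "source": side,
                        "category": pr.category.value,
                    }
        if len(seqs) < 3:
            continue
        aln = align_family(seqs, config.msa_search)
        aln = _pad_to_codon_frame(aln)
        try:
            trimmed, _ranges = trim_codon_blocks(aln, config.trim)
        except ValueError as exc:
            logger.warning("%s: %s; building tree from untrimmed alignment", group, exc)
            trimmed = aln
        trees[group] = build_tree(
            trimmed,
            bootstraps=config.tree_bootstraps,
            seed=seed + zlib.crc32(group.encode()) % 10_000,
            leaf_meta=leaf_meta,
        )
    return trees


def _pad_to_codon_frame(aln: MultipleAlignment) -> MultipleAlignment:
    pad = (-aln.column_count) % 3
    if pad == 0:
        aln.codon_frame = True
        return aln
    rows = {gid: row + "-" * pad for gid, row in aln.rows.items()}
    return MultipleAlignment(ids=list(aln.ids), rows=rows, codon_frame=True)


def rescue_all(
    records: Sequence[PairRecord],
    trees: dict[str, GeneTree],
    seq_a: dict[str, str],
    seq_b: dict[str, str],
    config: PipelineConfig,
) -> list[PairRecord]:
    qualified = {f"{g}|A": s for g, s in seq_a.items()}
    qualified.update({f"{g}|B": s for g, s in seq_b.items()})
    out = list(records)
    for group in sorted(trees):
        out = rescue_unpaired(
            trees[group],
            out,
            sequences=qualified,
            params=config.pair_search,
            min_support=config.rescue_min_support,
            cluster_mode=config.rescue_cluster_mode,
        )
    return out


def run_in_memory(config: PipelineConfig, dataset=None):
    """Full pipeline on a simulated dataset; returns a results namespace."""
    if dataset is None:
        dataset = generate(config.simulation)
    raw_a = emitted_to_records(dataset.source_a, Source.SOURCE_A)
    raw_b = emitted_to_records(dataset.source_b, Source.SOURCE_B)
    # sources annotate transcripts that may carry UTRs: run full normalisation
    raw_a = [dataclasses.replace(r, is_cds=False) for r in raw_a]
    raw_b = [dataclasses.replace(r, is_cds=False) for r in raw_b]
    norm_a, norm_b = normalize_sources(raw_a, raw_b, config)
    assignments = mine_homologs(norm_a, norm_b, dataset.seeds, config)
    records = classify_all(norm_a, norm_b, assignments, config)
    seq_a = {r.gene_id: r.sequence for r in norm_a}
    seq_b = {r.gene_id: r.sequence for r in norm_b}
    trees = build_family_trees(records, seq_a, seq_b, config)
    records = rescue_all(records, trees, seq_a, seq_b, config)
    final = merge_final(records)
    report = concordance_report(records)
    matrix = copy_number_matrix(
        {
            src: {
                enz: {sp: set(gids) for sp, gids in by_sp.items()}
                for enz, by_sp in nested.items()
            }
            for src, nested in assignments.items()
        },
        final,
    )
    lengths = length_stats(records, seq_a, seq_b)
    sequences = {**{f"{g}|A": s for g, s in seq_a.items()}, **{f"{g}|B": s for g, s in seq_b.items()}}

    @dataclass
    class Results:
        dataset: object
        norm_a: list
        norm_b: list
        assignments: dict
        records: list
        trees: dict
        final: dict
        report: object
        matrix: object
        lengths: object
        sequences: dict

    return Results(
        dataset, norm_a, norm_b, assignments, records, trees, final, report, matrix, lengths, sequences
    )


# ---------------------------------------------------------------------------
# file-based stages


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(stage_dir: Path, stage: str, config: PipelineConfig, inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "inputs": [str(p) for p in inputs],
        "outputs": {str(p): _sha256(p) for p in outputs},
        "config": json.loads(config.to_json()),
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path}; run the '{producing_stage}' stage first"
        )
    return path


def _stage_dir(config: PipelineConfig, stage: str) -> Path:
    d = Path(config.outdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def stage_simulate(config: PipelineConfig):
    d = _stage_dir(config, "simulate")
    sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
    dataset = generate(sim_cfg)
    write_source_files(dataset.source_a, d / "source_A.fasta", d / "source_A.features.tsv")
    write_source_files(dataset.source_b, d / "source_B.fasta", d / "source_B.features.tsv")
    write_seed_fasta(dataset.seeds, d / "seeds.fasta")
    dataset.truth.write(d / "truth.tsv")
    outputs = [
        d / "source_A.fasta",
        d / "source_A.features.tsv",
        d / "source_B.fasta",
        d / "source_B.features.tsv",
        d / "seeds.fasta",
        d / "truth.tsv",
    ]
    _write_manifest(d, "simulate", config, [], outputs)
    return dataset


def _load_raw_source(fasta: Path, features: Path, source: Source) -> list[AnnotationRecord]:
    feature_map = {}
    for line in features.read_text().splitlines():
        tid, locus = line.split("\t")
        feature_map[tid] = locus
    records = []
    for entry in SeqIO.parse(str(fasta), "fasta"):
        locus = feature_map.get(entry.id, entry.id)
        records.append(
            AnnotationRecord(
                gene_id=entry.id,
                locus_id=locus,
                transcript_id=entry.id,
                species=species_of_gene_id(locus),
                source=source,
                sequence=str(entry.seq).upper(),
                is_cds=False,
            )
        )
    return records


def stage_normalize(config: PipelineConfig):
    sim = Path(config.outdir) / "simulate"
    raw_a = _load_raw_source(
        _require(sim / "source_A.fasta", "simulate"),
        _require(sim / "source_A.features.tsv", "simulate"),
        Source.SOURCE_A,
    )
    raw_b = _load_raw_source(
        _require(sim / "source_B.fasta", "simulate"),
        _require(sim / "source_B.features.tsv", "simulate"),
        Source.SOURCE_B,
    )
    norm_a, norm_b = normalize_sources(raw_a, raw_b, config)
    d = _stage_dir(config, "normalize")
    write_normalized(norm_a, d / "normalized_A.fasta", d / "normalized_A.tsv")
    write_normalized(norm_b, d / "normalized_B.fasta", d / "normalized_B.tsv")
    outputs = [d / f"normalized_{s}.{ext}" for s in "AB" for ext in ("fasta", "tsv")]
    _write_manifest(d, "normalize", config, [sim / "source_A.fasta", sim / "source_B.fasta"], outputs)
    return norm_a, norm_b


def _load_normalized(config: PipelineConfig):
    d = Path(config.outdir) / "normalize"
    norm_a = read_normalized(
        _require(d / "normalized_A.fasta", "normalize"), _require(d / "normalized_A.tsv", "normalize")
    )
    norm_b = read_normalized(
        _require(d / "normalized_B.fasta", "normalize"), _require(d / "normalized_B.tsv", "normalize")
    )
    return norm_a, norm_b


def stage_mine(config: PipelineConfig):
    norm_a, norm_b = _load_normalized(config)
    seeds = read_seed_fasta(_require(Path(config.outdir) / "simulate" / "seeds.fasta", "simulate"))
    assignments = mine_homologs(norm_a, norm_b, seeds, config)
    d = _stage_dir(config, "mine")
    path = d / "assignments.tsv"
    with open(path, "w") as fh:
        fh.write("gene_id\tsource\tenzyme\tspecies\n")
        for source, nested in assignments.items():
            for enz, by_sp in sorted(nested.items(), key=lambda kv: kv[0].value):
                for sp in sorted(by_sp):
                    for gid in sorted(by_sp[sp]):
                        fh.write(f"{gid}\t{source.value}\t{enz.value}\t{sp}\n")
    _write_manifest(d, "mine", config, [], [path])
    return assignments


def _load_assignments(config: PipelineConfig):
    path = _require(Path(config.outdir) / "mine" / "assignments.tsv", "mine")
    out: dict[Source, dict[Enzyme, dict[str, set[str]]]] = {}
    for line in path.read_text().splitlines()[1:]:
        gid, src, enz, sp = line.split("\t")
        out.setdefault(Source(src), {}).setdefault(Enzyme(enz), {}).setdefault(sp, set()).add(gid)
    return out


def stage_classify(config: PipelineConfig):
    norm_a, norm_b = _load_normalized(config)
    assignments = _load_assignments(config)
    records = classify_all(norm_a, norm_b, assignments, config)
    d = _stage_dir(config, "classify")
    write_pair_table(records, d / "pairs.tsv")
    _write_manifest(d, "classify", config, [], [d / "pairs.tsv"])
    return records


def stage_tree(config: PipelineConfig):
    norm_a, norm_b = _load_normalized(config)
    records = read_pair_table(_require(Path(config.outdir) / "classify" / "pairs.tsv", "classify"))
    seq_a = {r.gene_id: r.sequence for r in norm_a}
    seq_b = {r.gene_id: r.sequence for r in norm_b}
    trees = build_family_trees(records, seq_a, seq_b, config)
    d = _stage_dir(config, "tree")
    outputs = []
    for group, gtree in trees.items():
        path = d / f"{group}.nwk"
        path.write_text(gtree.to_newick() + "\n")
        outputs.append(path)
    _write_manifest(d, "tree", config, [], outputs)
    return trees


def stage_rescue(config: PipelineConfig):
    norm_a, norm_b = _load_normalized(config)
    records = read_pair_table(_require(Path(config.outdir) / "classify" / "pairs.tsv", "classify"))
    seq_a = {r.gene_id: r.sequence for r in norm_a}
    seq_b = {r.gene_id: r.sequence for r in norm_b}
    # trees are rebuilt rather than parsed: leaf metadata and supports live in
    # memory, and the manifest guarantees identical inputs
    _require(Path(config.outdir) / "tree" / "manifest.json", "tree")
    trees = build_family_trees(records, seq_a, seq_b, config)
    rescued = rescue_all(records, trees, seq_a, seq_b, config)
    d = _stage_dir(config, "rescue")
    write_pair_table(rescued, d / "pairs_rescued.tsv")
    _write_manifest(d, "rescue", config, [], [d / "pairs_rescued.tsv"])
    return rescued


def stage_report(config: PipelineConfig):
    norm_a, norm_b = _load_normalized(config)
    records = read_pair_table(
        _require(Path(config.outdir) / "rescue" / "pairs_rescued.tsv", "rescue")
    )
    assignments = _load_assignments(config)
    seq_a = {r.gene_id: r.sequence for r in norm_a}
    seq_b = {r.gene_id: r.sequence for r in norm_b}
    final = merge_final(records)
    report = concordance_report(records)
    matrix = copy_number_matrix(
        {
            src: {enz: dict(by_sp) for enz, by_sp in nested.items()}
            for src, nested in assignments.items()
        },
        final,
    )
    lengths = length_stats(records, seq_a, seq_b)
    d = _stage_dir(config, "report")
    write_tables(d, concordance=report.to_series(), copy_number=matrix, length_stats=lengths)
    outputs = [d / "concordance.tsv", d / "copy_number.tsv", d / "length_stats.tsv"]
    _write_manifest(d, "report", config, [], outputs)
    return report, matrix, lengths


def run_subcommand(name: str, config: PipelineConfig):
    """Dispatch one stage, or chain all of them with ``all``."""
    if name == "all":
        results = None
        for stage in STAGES:
            results = run_subcommand(stage, config)
        return results
    stages = {
        "simulate": stage_simulate,
        "normalize": stage_normalize,
        "mine": stage_mine,
        "classify": stage_classify,
        "tree": stage_tree,
        "rescue": stage_rescue,
        "report": stage_report,
    }
    if name not in stages:
        raise PipelineError(f"unknown stage {name!r}; choose from {STAGES + ('all',)}")
    logger.info("running stage %s", name)
    return stages[name](config)
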