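"""Ground-truthed dual-source annotation simulator.

Gene families evolve by a birth-death process (duplication rate lambda, loss
rate mu, events per unit branch length) along a species tree; coding sequences
evolve along the resulting gene trees under JC or HKY substitution models with
codon-aware guards (no internal in-frame stops; start and stop codons held
fixed).  Each surviving tip lineage is one *true gene*.

Two annotation sources are then derived from the same true gene set through
independent corruption channels that emulate real annotation discrepancies:

* missed genes (``miss_prob``),
* UTR additions that do not change the inferred CDS (``utr_extend_prob`` with
  probability ``1 - coding_extension_prob``),
* coding-boundary shifts: an in-frame N-terminal extension starting at an
  upstream ATG, so the longest-ORF rule recovers a longer CDS
  (``utr_extend_prob`` with probability ``coding_extension_prob``),
* in-frame truncations (``truncation_prob``),
* redundant transcript variants per locus (removed by normalisation), and
* identical within-source duplicate genes (``identical_duplicate_prob``).

A :class:`TruthTable` records every event and the cross-source pair category
each gene should receive, derived deterministically from the corruption events
by the same rules the classifier states (string-identical CDS = perfect pair,
both present otherwise = imperfect, one side = unpaired, unpaired duplicating
another same-source CDS = excluded).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from io import StringIO
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from annoconcord.annotation_io import AnnotationRecord, Source, longest_orf
from annoconcord.pairs import PairCategory

_BASES = np.array(list("ACGT"), dtype="U1")
_STOPS = {"TAA", "TAG", "TGA"}

# 21 sampled eudicots: 8 Solanaceae, Ipomoea (Convolvulaceae), 3 Lamiales,
# Coffea (Gentianales), 4 campanulids and 4 rosid outgroups.  Synthetic
# ultrametric topology/depths assembled from the taxonomy of the sampled
# clades (tip depth 0.3 substitutions/site).
DEFAULT_SPECIES_TREE = (
    "(((Arath:0.20,Glyma:0.20):0.06,(Vivin:0.18,Potri:0.18):0.08):0.04,"
    "((Dacar:0.18,(Cycar:0.13,(Heann:0.08,Lasat:0.08):0.05):0.05):0.07,"
    "((Cocan:0.19,(Migut:0.15,(Sesin:0.10,Oleur:0.10):0.05):0.04):0.03,"
    "(Ipnil:0.12,(Pethy:0.09,((Nitab:0.03,(Nisyl:0.02,Nitom:0.02):0.01):0.04,"
    "(Capan:0.05,(Soltu:0.03,(Solly:0.02,Solme:0.02):0.01):0.02):0.02):0.02):0.03):0.10):0.03):0.05);"
)

DEFAULT_FAMILIES = ("CHS", "CHI", "F3H", "F3pH", "F3p5pH", "DFR", "ANS")


class SubstitutionModel(str, Enum):
    JC = "JC"
    HKY = "HKY"


@dataclass(frozen=True)
class CorruptionConfig:
    """Per-source corruption channel; probabilities are per gene and source."""

    miss_prob: float = 0.1
    utr_extend_prob: float = 0.3
    coding_extension_prob: float = 0.5  # given an extension, P(it shifts the CDS start)
    utr_min_len: int = 30
    utr_max_len: int = 180
    coding_ext_max_codons: int = 10
    truncation_prob: float = 0.1
    truncation_max_codons: int = 20
    variant_rate: float = 0.3  # Poisson mean of extra transcript variants per locus
    identical_duplicate_prob: float = 0.05

    def __post_init__(self) -> None:
        for p in (
            self.miss_prob,
            self.utr_extend_prob,
            self.coding_extension_prob,
            self.truncation_prob,
            self.identical_duplicate_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    species_tree_newick: str = DEFAULT_SPECIES_TREE
    families: tuple[str, ...] = DEFAULT_FAMILIES
    duplication_rate: float = 7.0  # events per unit branch length
    loss_rate: float = 0.6
    root_sequence_length: int = 900  # nt, codon multiple, incl. start/stop
    model: SubstitutionModel = SubstitutionModel.HKY
    kappa: float = 2.0
    # the two CYP75 hydroxylase families descend from a shared ancestor; each
    # family root sits this far (subs/site) from it
    cyp75_divergence: float = 0.10
    corruption: CorruptionConfig = field(default_factory=CorruptionConfig)
    family_size_cap: int = 100  # cap on expected tip copies per species
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.root_sequence_length % 3 or self.root_sequence_length < 300:
            raise ValueError("root_sequence_length must be a codon multiple >= 300")


def clean_corruption() -> CorruptionConfig:
    """All-zero corruption: both sources reproduce the true gene set exactly."""
    return CorruptionConfig(
        miss_prob=0.0,
        utr_extend_prob=0.0,
        truncation_prob=0.0,
        variant_rate=0.0,
        identical_duplicate_prob=0.0,
    )


# ---------------------------------------------------------------------------
# gene-family birth-death simulation


class GNode:
    """Gene-tree node; leaves carry the species they landed in."""

    __slots__ = ("length", "children", "species", "name")

    def __init__(self, length: float, children: Optional[list] = None, species: Optional[str] = None):
        self.length = length
        self.children = children or []
        self.species = species
        self.name: Optional[str] = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["GNode"]:
        if self.is_leaf():
            return [self]
        out = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf():
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out


def _bd_along_branch(duration: float, lam: float, mu: float, rng: np.random.Generator):
    """Birth-death of one lineage over ``duration``; leaves of the returned
    subtree are surviving lineage endpoints at the branch bottom (species None).
    Returns None if all sublineages die."""
    total = lam + mu
    if total == 0.0:
        return GNode(duration)
    t = 0.0
    wait = rng.exponential(1.0 / total)
    if wait >= duration:
        return GNode(duration)
    # event strictly inside the branch
    if rng.random() < lam / total:
        left = _bd_along_branch(duration - wait, lam, mu, rng)
        right = _bd_along_branch(duration - wait, lam, mu, rng)
        kids = [k for k in (left, right) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length += wait
            return kids[0]
        return GNode(wait, children=kids)
    return None


def _max_root_tip_depth(tree: TreeNode) -> float:
    def depth(node) -> float:
        own = node.length or 0.0
        if node.is_tip():
            return own
        return own + max(depth(c) for c in node.children)

    return max(depth(c) for c in tree.children)


def simulate_family(
    species_tree: TreeNode,
    lam: float,
    mu: float,
    rng: np.random.Generator,
    cap: int = 100,
) -> Optional[GNode]:
    """Simulate one gene family along a species tree.

    Returns the gene-tree root (leaves carry ``species``), or None when the
    family went extinct everywhere.  Expected per-species family size is
    exp((lam - mu) * depth); configurations exceeding ``cap`` are refused.
    """
    depth = _max_root_tip_depth(species_tree)
    if math.exp((lam - mu) * depth) > cap:
        raise ValueError(
            f"expected family size exp((lam-mu)*depth) exceeds cap {cap}"
        )

    def descend(species_node: TreeNode) -> Optional[GNode]:
        """One lineage entering the branch above species_node."""
        sub = _bd_along_branch(species_node.length or 0.0, lam, mu, rng)
        if sub is None:
            return None
        for endpoint in sub.leaves():
            if species_node.is_tip():
                endpoint.species = species_node.name
            else:
                kids = [descend(c) for c in species_node.children]
                kids = [k for k in kids if k is not None]
                if not kids:
                    endpoint.species = "__dead__"
                else:
                    endpoint.children = kids
        return _prune(sub)

    def _prune(node: GNode) -> Optional[GNode]:
        if node.is_leaf():
            return None if node.species == "__dead__" else node
        kids = [_prune(k) for k in node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length += node.length
            return kids[0]
        node.children = kids
        return node

    root_kids = [descend(c) for c in species_tree.children]
    root_kids = [k for k in root_kids if k is not None]
    if not root_kids:
        return None
    if len(root_kids) == 1:
        return root_kids[0]
    return GNode(0.0, children=root_kids)


# ---------------------------------------------------------------------------
# sequence evolution


def _rate_matrix(model: SubstitutionModel, kappa: float) -> np.ndarray:
    """HKY rate matrix with uniform base frequencies, scaled to 1 sub/site/unit."""
    k = kappa if model is SubstitutionModel.HKY else 1.0
    Q = np.ones((4, 4))
    # transitions: A<->G (0,2), C<->T (1,3)
    Q[0, 2] = Q[2, 0] = k
    Q[1, 3] = Q[3, 1] = k
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -0.25 * np.trace(Q)
    return Q / rate


def transition_matrix(model: SubstitutionModel, kappa: float, t: float) -> np.ndarray:
    from scipy.linalg import expm

    return expm(_rate_matrix(model, kappa) * t)


def evolve_along_branch(
    codes: np.ndarray,
    t: float,
    model: SubstitutionModel,
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve encoded bases (0..3) for branch length t (substitutions/site)."""
    if t <= 0:
        return codes.copy()
    P = transition_matrix(model, kappa, t)
    cum = np.cumsum(P, axis=1)
    u = rng.random(len(codes))
    out = np.empty_like(codes)
    for b in range(4):
        mask = codes == b
        if mask.any():
            out[mask] = np.searchsorted(cum[b], u[mask]).astype(codes.dtype)
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def _fix_internal_stops(
    child: np.ndarray, parent: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Resample codons that became stops (positions 1..n-2); start/stop codons
    are copied from the parent unchanged."""
    child = child.copy()
    child[:3] = parent[:3]
    child[-3:] = parent[-3:]
    n_codons = len(child) // 3
    for _ in range(20):
        view = child.reshape(n_codons, 3)
        codon_strs = ["".join(_BASES[c]) for c in view[1:-1]]
        bad = [i + 1 for i, c in enumerate(codon_strs) if c in _STOPS]
        if not bad:
            return child
        for ci in bad:
            # redraw the codon uniformly among non-stop codons
            while True:
                cand = rng.integers(0, 4, size=3)
                if "".join(_BASES[cand]) not in _STOPS:
                    child[3 * ci : 3 * ci + 3] = cand
                    break
    return child


def random_root_cds(length: int, rng: np.random.Generator) -> np.ndarray:
    """ATG + random non-stop codons + TAA, encoded 0..3."""
    n_codons = length // 3 - 2
    body = np.empty((n_codons, 3), dtype=np.uint8)
    for i in range(n_codons):
        while True:
            cand = rng.integers(0, 4, size=3)
            if "".join(_BASES[cand]) not in _STOPS:
                body[i] = cand
                break
    start = np.array([0, 3, 2], dtype=np.uint8)  # ATG
    stop = np.array([3, 0, 0], dtype=np.uint8)  # TAA
    return np.concatenate([start, body.ravel(), stop])


def evolve_sequences(
    gene_tree: GNode,
    root_codes: np.ndarray,
    model: SubstitutionModel,
    kappa: float,
    rng: np.random.Generator,
    protect_orf: bool = True,
) -> dict[int, np.ndarray]:
    """Evolve the root CDS down a gene tree; returns {id(leaf GNode): codes}."""
    out: dict[int, np.ndarray] = {}

    def rec(node: GNode, codes: np.ndarray) -> None:
        evolved = evolve_along_branch(codes, node.length, model, kappa, rng)
        if protect_orf:
            evolved = _fix_internal_stops(evolved, codes, rng)
        if node.is_leaf():
            out[id(node)] = evolved
        else:
            for child in node.children:
                rec(child, evolved)

    rec(gene_tree, root_codes)
    return out


# ---------------------------------------------------------------------------
# corruption channel


@dataclass(frozen=True)
class TrueGene:
    gene_id: str  # base id shared by both sources
    species: str
    family: str
    cds: str


@dataclass
class TruthRow:
    gene_id: str
    species: str
    family: str
    kind: str  # "gene" or "duplicate"
    present_a: bool
    present_b: bool
    id_a: Optional[str]
    id_b: Optional[str]
    cds_a: Optional[str]  # CDS after corruption, as the pipeline should infer it
    cds_b: Optional[str]
    events_a: str
    events_b: str
    implied_a: Optional[PairCategory] = None
    implied_b: Optional[PairCategory] = None
    duplicate_of: Optional[str] = None


@dataclass
class TruthTable:
    rows: list[TruthRow]

    def family_sizes(self) -> dict[tuple[str, str], int]:
        """(species, family) -> number of true genes (emitted or not)."""
        out: dict[tuple[str, str], int] = {}
        for r in self.rows:
            if r.kind == "gene":
                key = (r.species, r.family)
                out[key] = out.get(key, 0) + 1
        return out

    def implied_categories(self) -> dict[tuple[str, str], PairCategory]:
        """(source letter, emitted gene id) -> implied category."""
        out = {}
        for r in self.rows:
            if r.present_a and r.implied_a is not None:
                out[("A", r.id_a)] = r.implied_a
            if r.present_b and r.implied_b is not None:
                out[("B", r.id_b)] = r.implied_b
        return out

    def write(self, path: Path | str) -> None:
        with open(Path(path), "w") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                [
                    "gene_id",
                    "species",
                    "family",
                    "kind",
                    "present_a",
                    "present_b",
                    "id_a",
                    "id_b",
                    "cds_a",
                    "cds_b",
                    "events_a",
                    "events_b",
                    "implied_a",
                    "implied_b",
                    "duplicate_of",
                ]
            )
            for r in self.rows:
                w.writerow(
                    [
                        r.gene_id,
                        r.species,
                        r.family,
                        r.kind,
                        int(r.present_a),
                        int(r.present_b),
                        r.id_a or "",
                        r.id_b or "",
                        r.cds_a or "",
                        r.cds_b or "",
                        r.events_a,
                        r.events_b,
                        r.implied_a.value if r.implied_a else "",
                        r.implied_b.value if r.implied_b else "",
                        r.duplicate_of or "",
                    ]
                )

    @classmethod
    def read(cls, path: Path | str) -> "TruthTable":
        rows = []
        with open(Path(path)) as fh:
            for rec in csv.DictReader(fh, delimiter="\t"):
                rows.append(
                    TruthRow(
                        gene_id=rec["gene_id"],
                        species=rec["species"],
                        family=rec["family"],
                        kind=rec["kind"],
                        present_a=bool(int(rec["present_a"])),
                        present_b=bool(int(rec["present_b"])),
                        id_a=rec["id_a"] or None,
                        id_b=rec["id_b"] or None,
                        cds_a=rec["cds_a"] or None,
                        cds_b=rec["cds_b"] or None,
                        events_a=rec["events_a"],
                        events_b=rec["events_b"],
                        implied_a=PairCategory(rec["implied_a"]) if rec["implied_a"] else None,
                        implied_b=PairCategory(rec["implied_b"]) if rec["implied_b"] else None,
                        duplicate_of=rec["duplicate_of"] or None,
                    )
                )
        return cls(rows)


_PYRIMIDINES = np.array([1, 3], dtype=np.uint8)  # C, T


def _utr_flank(length: int, rng: np.random.Generator) -> str:
    """Pyrimidine-only flank: cannot create start or stop codons anywhere."""
    return _decode(_PYRIMIDINES[rng.integers(0, 2, size=length)])


def _nonstop_codons(n: int, rng: np.random.Generator) -> str:
    out = []
    for _ in range(n):
        while True:
            cand = rng.integers(0, 4, size=3)
            c = "".join(_BASES[cand])
            if c not in _STOPS:
                out.append(c)
                break
    return "".join(out)


@dataclass
class EmittedTranscript:
    transcript_id: str
    locus_id: str
    sequence: str
    is_cds: bool


def _corrupt_one(
    gene: TrueGene,
    cfg: CorruptionConfig,
    rng: np.random.Generator,
) -> tuple[Optional[str], Optional[str], list[str]]:
    """Corrupt one gene for one source.

    Returns (inferred_cds, transcript, events); (None, None, ['miss']) when the
    gene is dropped.  ``transcript`` is what the source annotates; the inferred
    CDS is what normalisation recovers from it.
    """
    events: list[str] = []
    if rng.random() < cfg.miss_prob:
        return None, None, ["miss"]
    cds = gene.cds
    if rng.random() < cfg.truncation_prob:
        max_k = (len(cds) - 300) // 3
        if max_k >= 1:
            k = int(rng.integers(1, min(max_k, cfg.truncation_max_codons) + 1))
            cds = cds[:3] + cds[3 + 3 * k :]
            events.append(f"truncate:{k}")
    transcript = cds
    if rng.random() < cfg.utr_extend_prob:
        if rng.random() < cfg.coding_extension_prob:
            j = int(rng.integers(1, cfg.coding_ext_max_codons + 1))
            ext = "ATG" + _nonstop_codons(j, rng)
            cds = ext + cds
            transcript = cds
            events.append(f"coding_ext:{j}")
        five = _utr_flank(int(rng.integers(cfg.utr_min_len, cfg.utr_max_len + 1)), rng)
        three = _utr_flank(int(rng.integers(cfg.utr_min_len, cfg.utr_max_len + 1)), rng)
        transcript = five + cds + three
        events.append(f"utr:{len(five)}+{len(three)}")
        span = longest_orf(transcript)
        assert span is not None and transcript[span[0] : span[1]] == cds, (
            "UTR construction must leave the intended CDS as the longest ORF"
        )
    if not events:
        events.append("none")
    return cds, transcript, events


def corrupt_annotations(
    true_genes: Sequence[TrueGene],
    cfg: CorruptionConfig,
    rng: np.random.Generator,
    variant_sources: Sequence[Source] = (Source.SOURCE_A, Source.SOURCE_B),
) -> tuple[list[EmittedTranscript], list[EmittedTranscript], TruthTable]:
    """Derive both corrupted sources and the ground-truth table.

    Transcript ids are ``<gene>.1`` (primary) and ``.2``... (variants), so the
    default locus-resolution rule groups them; injected duplicates get fresh
    loci with a ``d`` suffix that sorts after the original (RBH ties then keep
    the original paired, leaving the duplicate to the redundancy exclusion).
    """
    out_a: list[EmittedTranscript] = []
    out_b: list[EmittedTranscript] = []
    rows: list[TruthRow] = []
    dup_rows: list[TruthRow] = []
    for gene in true_genes:
        per_source: dict[Source, tuple[Optional[str], Optional[str], list[str]]] = {}
        for source in (Source.SOURCE_A, Source.SOURCE_B):
            per_source[source] = _corrupt_one(gene, cfg, rng)
        row = TruthRow(
            gene_id=gene.gene_id,
            species=gene.species,
            family=gene.family,
            kind="gene",
            present_a=per_source[Source.SOURCE_A][0] is not None,
            present_b=per_source[Source.SOURCE_B][0] is not None,
            id_a=gene.gene_id if per_source[Source.SOURCE_A][0] is not None else None,
            id_b=gene.gene_id if per_source[Source.SOURCE_B][0] is not None else None,
            cds_a=per_source[Source.SOURCE_A][0],
            cds_b=per_source[Source.SOURCE_B][0],
            events_a=",".join(per_source[Source.SOURCE_A][2]),
            events_b=",".join(per_source[Source.SOURCE_B][2]),
        )
        rows.append(row)
        for source, out in ((Source.SOURCE_A, out_a), (Source.SOURCE_B, out_b)):
            cds, transcript, _ = per_source[source]
            if cds is None:
                continue
            out.append(
                EmittedTranscript(
                    transcript_id=f"{gene.gene_id}.1",
                    locus_id=gene.gene_id,
                    sequence=transcript,
                    is_cds=(transcript == cds),
                )
            )
            if source in variant_sources and cfg.variant_rate > 0:
                n_var = int(rng.poisson(cfg.variant_rate))
                for v in range(n_var):
                    max_k = (len(cds) - 300) // 3
                    if max_k < 1:
                        break
                    k = int(rng.integers(1, max_k + 1))
                    var_cds = cds[:3] + cds[3 + 3 * k :]
                    out.append(
                        EmittedTranscript(
                            transcript_id=f"{gene.gene_id}.{v + 2}",
                            locus_id=gene.gene_id,
                            sequence=var_cds,
                            is_cds=True,
                        )
                    )
            if rng.random() < cfg.identical_duplicate_prob:
                dup_id = f"{gene.gene_id}d"
                out.append(
                    EmittedTranscript(
                        transcript_id=f"{dup_id}.1",
                        locus_id=dup_id,
                        sequence=transcript,
                        is_cds=(transcript == cds),
                    )
                )
                dup_rows.append(
                    TruthRow(
                        gene_id=dup_id,
                        species=gene.species,
                        family=gene.family,
                        kind="duplicate",
                        present_a=source is Source.SOURCE_A,
                        present_b=source is Source.SOURCE_B,
                        id_a=dup_id if source is Source.SOURCE_A else None,
                        id_b=dup_id if source is Source.SOURCE_B else None,
                        cds_a=cds if source is Source.SOURCE_A else None,
                        cds_b=cds if source is Source.SOURCE_B else None,
                        events_a="duplicate" if source is Source.SOURCE_A else "",
                        events_b="duplicate" if source is Source.SOURCE_B else "",
                        duplicate_of=gene.gene_id,
                    )
                )
    rows.extend(dup_rows)
    _imply_categories(rows)
    return out_a, out_b, TruthTable(rows)


def _imply_categories(rows: list[TruthRow]) -> None:
    """Fill implied_a/implied_b from presence patterns and CDS identity."""
    # per (species, source): emitted CDS per gene id, for the redundancy rule
    pool_a: dict[str, dict[str, str]] = {}
    pool_b: dict[str, dict[str, str]] = {}
    for r in rows:
        if r.present_a:
            pool_a.setdefault(r.species, {})[r.id_a] = r.cds_a
        if r.present_b:
            pool_b.setdefault(r.species, {})[r.id_b] = r.cds_b

    def redundant(species: str, gid: str, cds: str, pool: dict) -> bool:
        return any(
            seq == cds for g, seq in pool.get(species, {}).items() if g != gid
        )

    for r in rows:
        if r.present_a and r.present_b:
            cat = PairCategory.PERFECT if r.cds_a == r.cds_b else PairCategory.IMPERFECT
            r.implied_a = cat
            r.implied_b = cat
        elif r.present_a:
            if redundant(r.species, r.id_a, r.cds_a, pool_a):
                r.implied_a = PairCategory.EXCLUDED_REDUNDANT
            else:
                r.implied_a = PairCategory.UNPAIRED_A
        elif r.present_b:
            if redundant(r.species, r.id_b, r.cds_b, pool_b):
                r.implied_b = PairCategory.EXCLUDED_REDUNDANT
            else:
                r.implied_b = PairCategory.UNPAIRED_B


# ---------------------------------------------------------------------------
# top-level generation and serialisation


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    seeds: dict[str, str]  # family -> root CDS (used as search seed queries)
    true_genes: list[TrueGene]
    source_a: list[EmittedTranscript]
    source_b: list[EmittedTranscript]
    truth: TruthTable


def generate(config: SimulationConfig) -> SimulatedDataset:
    """Run the full simulator: families, sequences, corruption, truth table."""
    rng = np.random.default_rng(config.seed)
    species_tree = TreeNode.read(StringIO(config.species_tree_newick))
    seeds: dict[str, str] = {}
    true_genes: list[TrueGene] = []
    cyp75 = {"F3pH", "F3p5pH"}
    cyp75_ancestor = None
    if cyp75 <= set(config.families) and config.cyp75_divergence > 0:
        cyp75_ancestor = random_root_cds(config.root_sequence_length, rng)
    for family in config.families:
        if cyp75_ancestor is not None and family in cyp75:
            evolved = evolve_along_branch(
                cyp75_ancestor, config.cyp75_divergence, config.model, config.kappa, rng
            )
            root = _fix_internal_stops(evolved, cyp75_ancestor, rng)
        else:
            root = random_root_cds(config.root_sequence_length, rng)
        seeds[family] = _decode(root)
        gtree = simulate_family(
            species_tree,
            config.duplication_rate,
            config.loss_rate,
            rng,
            cap=config.family_size_cap,
        )
        if gtree is None:
            continue
        leaf_seqs = evolve_sequences(
            gtree, root, config.model, config.kappa, rng, protect_orf=True
        )
        counters: dict[str, int] = {}
        for leaf in gtree.leaves():
            sp = leaf.species
            counters[sp] = counters.get(sp, 0) + 1
            gid = f"{sp}_{family}_g{counters[sp]:03d}"
            true_genes.append(
                TrueGene(
                    gene_id=gid,
                    species=sp,
                    family=family,
                    cds=_decode(leaf_seqs[id(leaf)]),
                )
            )
    out_a, out_b, truth = corrupt_annotations(true_genes, config.corruption, rng)
    return SimulatedDataset(
        config=config,
        seeds=seeds,
        true_genes=true_genes,
        source_a=out_a,
        source_b=out_b,
        truth=truth,
    )


def species_of_gene_id(gene_id: str) -> str:
    return gene_id.split("_", 1)[0]


def planted_rescue_dataset(
    n_pairs: int = 20,
    n_background: int = 10,
    divergence: float = 0.04,
    seed: int = 0,
    enzyme_name: str = "DFR",
    n_species: int = 5,
):
    """Dataset with planted cross-source unpaired pairs for the tree-rescue stage.

    Each planted pair is one true gene annotated in both sources with shifted
    coding boundaries and <= ``divergence`` substitution divergence, but left
    UNPAIRED in the classification (emulating an RBH miss); background genes
    are ordinary imperfect pairs.  Genes are mutually well separated (star
    radiation from one family root), so each planted pair should form a
    same-species cross-source cherry in the gene tree.

    Returns (records, seq_a, seq_b, planted id pairs).
    """
    from annoconcord.search import Enzyme

    enzyme = Enzyme(enzyme_name)
    rng = np.random.default_rng(seed)
    root = random_root_cds(900, rng)
    records = []
    seq_a: dict[str, str] = {}
    seq_b: dict[str, str] = {}
    planted: list[tuple[str, str]] = []
    for i in range(n_pairs):
        sp = f"sp{i % n_species + 1:02d}"
        base = _fix_internal_stops(
            evolve_along_branch(root, 0.15, SubstitutionModel.JC, 1.0, rng), root, rng
        )
        ida, idb = f"{sp}_plant{i:02d}a", f"{sp}_plant{i:02d}b"
        other = _fix_internal_stops(
            evolve_along_branch(base, divergence, SubstitutionModel.JC, 1.0, rng), base, rng
        )
        k = int(rng.integers(1, 6))  # shift the annotated start by 1-5 codons
        seq_a[ida] = _decode(base)
        seq_b[idb] = _decode(other)[: 3] + _decode(other)[3 + 3 * k :]
        records.append(
            PairRecordProxy(enzyme, sp, ida, None, PairCategory.UNPAIRED_A, len(seq_a[ida]), None)
        )
        records.append(
            PairRecordProxy(enzyme, sp, None, idb, PairCategory.UNPAIRED_B, None, len(seq_b[idb]))
        )
        planted.append((ida, idb))
    for j in range(n_background):
        sp = f"sp{j % n_species + 1:02d}"
        base = _fix_internal_stops(
            evolve_along_branch(root, 0.15, SubstitutionModel.JC, 1.0, rng), root, rng
        )
        ida, idb = f"{sp}_bg{j:02d}a", f"{sp}_bg{j:02d}b"
        seq_a[ida] = _decode(base)
        seq_b[idb] = _decode(
            _fix_internal_stops(
                evolve_along_branch(base, 0.01, SubstitutionModel.JC, 1.0, rng), base, rng
            )
        )
        records.append(
            PairRecordProxy(
                enzyme, sp, ida, idb, PairCategory.IMPERFECT, len(seq_a[ida]), len(seq_b[idb])
            )
        )
    return records, seq_a, seq_b, planted


def PairRecordProxy(enzyme, species, member_a, member_b, category, length_a, length_b):
    from annoconcord.pairs import PairRecord

    identity = None
    ratio = None
    if category is PairCategory.IMPERFECT:
        identity = 99.0
        ratio = 1.0
    return PairRecord(
        enzyme=enzyme,
        species=species,
        member_a=member_a,
        member_b=member_b,
        category=category,
        identity=identity,
        length_ratio=ratio,
        length_a=length_a,
        length_b=length_b,
    )


def category_recovery(truth: TruthTable, records: Sequence) -> tuple[float, int, int]:
    """Fraction of emitted annotations whose pipeline category matches the
    implied one.

    Each emitted gene (per source) counts once; genes the pipeline lost
    entirely count as mismatches.  Returns (fraction, matched, total).
    The pipeline's record ids carry the ``.1`` primary-transcript suffix;
    truth ids do not, so ids are compared on their locus stem.
    """
    pipeline_cat: dict[tuple[str, str], str] = {}
    for pr in records:
        for gid, side in ((pr.member_a, "A"), (pr.member_b, "B")):
            if gid is None:
                continue
            stem = gid.rsplit(".", 1)[0] if "." in gid else gid
            pipeline_cat[(side, stem)] = pr.category.value
    implied = truth.implied_categories()
    total = len(implied)
    matched = sum(
        1 for key, cat in implied.items() if pipeline_cat.get(key) == cat.value
    )
    return (matched / total if total else 1.0, matched, total)


def emitted_to_records(
    emitted: Sequence[EmittedTranscript], source: Source
) -> list[AnnotationRecord]:
    """Adapt emitted transcripts to annotation records (per species)."""
    return [
        AnnotationRecord(
            gene_id=e.transcript_id,
            locus_id=e.locus_id,
            transcript_id=e.transcript_id,
            species=species_of_gene_id(e.locus_id),
            source=source,
            sequence=e.sequence,
            is_cds=e.is_cds,
        )
        for e in emitted
    ]


def write_source_files(
    emitted: Sequence[EmittedTranscript], fasta_path: Path | str, features_path: Path | str
) -> None:
    """FASTA + 2-column (transcript, locus) feature table for one source."""
    SeqIO.write(
        [SeqRecord(Seq(e.sequence), id=e.transcript_id, description="") for e in emitted],
        str(fasta_path),
        "fasta",
    )
    with open(features_path, "w") as fh:
        for e in emitted:
            fh.write(f"{e.transcript_id}\t{e.locus_id}\n")


def write_seed_fasta(seeds: dict[str, str], path: Path | str) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=f"seed_{fam}", description="") for fam, s in seeds.items()],
        str(path),
        "fasta",
    )


def read_seed_fasta(path: Path | str) -> dict[str, str]:
    return {
        e.id.removeprefix("seed_"): str(e.seq).upper()
        for e in SeqIO.parse(str(path), "fasta")
    }
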