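"""Gene-tree construction and tree-based rescue of unpaired annotations.

The internal reference backend is fully deterministic:

* progressive multiple alignment guided by a k-mer (k=6) neighbor-joining tree,
  profile-profile alignment under the search scoring scheme with free end gaps
  (annotated CDS of one family differ mostly at their boundaries);
* codon-mode block trimming with the b2 (flank conservation), b4 (minimum block
  length, in codons) and b5 (allowed gap fraction) parameters;
* neighbor joining on pairwise GTR distances (empirical base frequencies,
  eigen-decomposition of the divergence matrix) with an optional gamma
  rate-heterogeneity correction, and nonparametric bootstrap over codon columns
  for branch supports.

External aligner/tree programs can be substituted behind the same contracts;
everything in this package runs against the internal backend.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from io import StringIO
from typing import Optional, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from annoconcord._aligner import encode, nw_profile_ops, pair_count_matrices
from annoconcord.pairs import PairCategory, PairRecord
from annoconcord.search import SearchParams

logger = logging.getLogger(__name__)

_GAP = 4  # encoded gap / ambiguous state
_DIST_CAP = 10.0


@dataclass
class MultipleAlignment:
    """Gapped rows over a common coordinate system."""

    ids: list[str]
    rows: dict[str, str]
    codon_frame: bool = False

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def column_count(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def codes(self) -> np.ndarray:
        """(n_rows, n_cols) uint8 matrix; gaps and ambiguous bases encode as 4."""
        out = np.empty((len(self.ids), self.column_count), dtype=np.uint8)
        for i, gid in enumerate(self.ids):
            out[i] = encode(self.rows[gid])
        return out


@dataclass(frozen=True)
class TrimParams:
    """Codon-mode trimming thresholds.

    b2: minimum fraction of non-gap rows sharing the majority codon for a
    column to count as conserved; b4: minimum run of good codon columns, in
    codons; b5: maximum fraction of rows gapped in a good codon column.
    """

    b2_min_flank_fraction: float = 0.5
    b4_min_block_codons: int = 5
    b5_max_gap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.b2_min_flank_fraction <= 1 and 0 < self.b5_max_gap_fraction <= 1):
            raise ValueError("fractions must be in (0, 1]")
        if self.b4_min_block_codons < 1:
            raise ValueError("b4 must be >= 1")


@dataclass
class GeneTree:
    """Leaf-labelled tree with bootstrap supports and per-leaf metadata."""

    tree: TreeNode
    supports: dict[frozenset, int] = field(default_factory=dict)
    leaf_meta: dict[str, dict] = field(default_factory=dict)

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def to_newick(self) -> str:
        t = self.tree.copy()
        for node in t.non_tips():
            split = frozenset(tip.name for tip in node.tips())
            if split in self.supports:
                node.name = str(self.supports[split])
        buf = StringIO()
        t.write(buf, format="newick")
        return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# alignment


def _kmer_sets(seqs: Sequence[str], k: int = 6) -> list[set]:
    return [{s[i : i + k] for i in range(len(s) - k + 1)} for s in seqs]


def kmer_distance_matrix(seqs: Sequence[str], k: int = 6) -> np.ndarray:
    """1 - shared-kmer fraction (relative to the smaller k-mer set)."""
    sets = _kmer_sets(seqs, k)
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j]))
            shared = len(sets[i] & sets[j]) / denom if denom else 0.0
            d[i, j] = d[j, i] = 1.0 - shared
    return d


def _profile(rows: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Column base-frequency profile (L, 4) and occupancy (non-gap fraction)."""
    arr = np.stack(rows)
    L = arr.shape[1]
    freq = np.zeros((L, 4))
    for b in range(4):
        freq[:, b] = (arr == b).mean(axis=0)
    occ = freq.sum(axis=1)
    return freq, occ


def _merge_profiles(
    rows_a: dict[str, np.ndarray],
    rows_b: dict[str, np.ndarray],
    params: SearchParams,
) -> dict[str, np.ndarray]:
    fa, occa = _profile(list(rows_a.values()))
    fb, occb = _profile(list(rows_b.values()))
    match = float(params.match_reward)
    mismatch = float(params.mismatch_penalty)
    S = (match - mismatch) * (fa @ fb.T) + mismatch * np.outer(occa, occb)
    ops = nw_profile_ops(
        S.astype(np.float64),
        float(params.gap_open),
        float(params.gap_extend),
        True,
    )
    out: dict[str, np.ndarray] = {}
    take_a = np.array([op != 2 for op in ops])
    take_b = np.array([op != 1 for op in ops])
    L = len(ops)
    for gid, row in rows_a.items():
        new = np.full(L, _GAP, dtype=np.uint8)
        new[take_a] = row
        out[gid] = new
    for gid, row in rows_b.items():
        new = np.full(L, _GAP, dtype=np.uint8)
        new[take_b] = row
        out[gid] = new
    return out


_DECODE = np.array(list("ACGT-"), dtype="U1")


def align_family(
    seqs: Sequence[tuple[str, str]],
    params: SearchParams = SearchParams(),
    k: int = 6,
) -> MultipleAlignment:
    """Deterministic progressive alignment of one gene family.

    Guide tree: neighbor joining on k-mer distances; merges follow the guide
    tree bottom-up with profile-profile alignment.  Input order does not affect
    the result (sequences are processed in sorted-id order).
    """
    if len(seqs) < 2:
        raise ValueError("align_family needs at least 2 sequences")
    items = sorted(seqs)
    ids = [gid for gid, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    enc = {gid: encode(s) for gid, s in items}
    if len(items) == 2:
        merged = _merge_profiles({ids[0]: enc[ids[0]]}, {ids[1]: enc[ids[1]]}, params)
    else:
        dmat = kmer_distance_matrix([s for _, s in items], k)
        # nj needs positive-ish distances; add tiny jitter-free epsilon on ties
        dm = DistanceMatrix(dmat, ids)
        guide = nj(dm)
        merged = _progressive(guide, enc, params)
    rows = {gid: "".join(_DECODE[row]) for gid, row in merged.items()}
    ncols = len(next(iter(rows.values())))
    return MultipleAlignment(ids=ids, rows=rows, codon_frame=(ncols % 3 == 0))


def _progressive(
    guide: TreeNode, enc: dict[str, np.ndarray], params: SearchParams
) -> dict[str, np.ndarray]:
    def rec(node: TreeNode) -> dict[str, np.ndarray]:
        if node.is_tip():
            return {node.name: enc[node.name]}
        children = list(node.children)
        # deterministic merge order: by smallest leaf name under each child
        children.sort(key=lambda c: min(t.name for t in c.tips()) if not c.is_tip() else c.name)
        cur = rec(children[0])
        for child in children[1:]:
            cur = _merge_profiles(cur, rec(child), params)
        return cur

    return rec(guide)


# ---------------------------------------------------------------------------
# trimming


def codon_column_is_good(
    codes: np.ndarray, codon_idx: int, params: TrimParams
) -> bool:
    """Apply the per-codon-column rule: gap fraction <= b5 and majority codon
    frequency >= b2 among non-gap rows."""
    cols = codes[:, 3 * codon_idx : 3 * codon_idx + 3]
    gapped = (cols >= 4).any(axis=1)
    n = codes.shape[0]
    if gapped.mean() > params.b5_max_gap_fraction:
        return False
    clean = cols[~gapped]
    if clean.shape[0] == 0:
        return False
    codons = clean[:, 0] * 16 + clean[:, 1] * 4 + clean[:, 2]
    _, counts = np.unique(codons, return_counts=True)
    return counts.max() / clean.shape[0] >= params.b2_min_flank_fraction


def trim_codon_blocks(
    aln: MultipleAlignment, params: TrimParams = TrimParams()
) -> tuple[MultipleAlignment, list[tuple[int, int]]]:
    """Keep maximal runs of >= b4 good codon columns; returns (alignment, kept ranges).

    Ranges are half-open codon-column intervals into the input alignment.
    """
    if not aln.codon_frame:
        raise ValueError("codon-mode trimming requires a codon-frame alignment")
    codes = aln.codes()
    n_codons = aln.column_count // 3
    good = np.array(
        [codon_column_is_good(codes, c, params) for c in range(n_codons)], dtype=bool
    )
    kept_ranges: list[tuple[int, int]] = []
    c = 0
    while c < n_codons:
        if good[c]:
            start = c
            while c < n_codons and good[c]:
                c += 1
            if c - start >= params.b4_min_block_codons:
                kept_ranges.append((start, c))
        else:
            c += 1
    if not kept_ranges:
        raise ValueError(
            "all codon columns were trimmed; relax b2/b4/b5 or check the alignment"
        )
    col_idx = np.concatenate(
        [np.arange(3 * s, 3 * e) for s, e in kept_ranges]
    )
    rows = {gid: "".join(np.array(list(aln.rows[gid]))[col_idx]) for gid in aln.ids}
    return MultipleAlignment(ids=list(aln.ids), rows=rows, codon_frame=True), kept_ranges


# ---------------------------------------------------------------------------
# distances and trees


def _gtr_distance_from_counts(C: np.ndarray, gamma_shape: Optional[float]) -> float:
    """GTR distance from a 4x4 substitution-count matrix.

    d = -tr(Pi log(Pi^-1 F)) with F the symmetrised divergence matrix and Pi the
    average base composition of the pair; with a gamma shape alpha, -log(x) is
    replaced by alpha*(x^(-1/alpha) - 1) on the eigenvalues.
    """
    total = C.sum()
    if total == 0:
        return _DIST_CAP
    F = (C + C.T) / (2.0 * total)
    pi = F.sum(axis=1)
    if np.any(pi <= 0):
        # a base absent from the pair: fall back to proportional distance
        p = 1.0 - np.trace(C) / total
        return min(_DIST_CAP, -0.75 * np.log(max(1e-9, 1 - 4 * p / 3.0)))
    M = F / pi[:, None]
    try:
        w, V = np.linalg.eig(M)
    except np.linalg.LinAlgError:  # pragma: no cover
        return _DIST_CAP
    w = np.real(w)
    if np.any(w <= 1e-9):
        return _DIST_CAP
    if gamma_shape is None:
        g = -np.log(w)
    else:
        a = float(gamma_shape)
        g = a * (w ** (-1.0 / a) - 1.0)
    logM = np.real(V @ np.diag(g) @ np.linalg.inv(V))
    d = float(np.trace(np.diag(pi) @ logM))
    if not np.isfinite(d) or d < 0:
        return 0.0 if abs(d) < 1e-12 else _DIST_CAP
    return min(d, _DIST_CAP)


def gtr_distance_matrix(
    codes: np.ndarray,
    columns: Optional[np.ndarray] = None,
    gamma_shape: Optional[float] = 1.0,
) -> np.ndarray:
    """Pairwise GTR(+Gamma) distances over selected alignment columns."""
    n = codes.shape[0]
    if columns is None:
        columns = np.arange(codes.shape[1], dtype=np.int64)
    pairs = np.array(list(itertools.combinations(range(n), 2)), dtype=np.int64)
    if len(pairs) == 0:
        return np.zeros((n, n))
    counts = pair_count_matrices(codes, pairs, columns.astype(np.int64))
    d = np.zeros((n, n))
    for (i, j), C in zip(pairs, counts):
        dij = _gtr_distance_from_counts(C, gamma_shape)
        d[i, j] = d[j, i] = dij
    return d


def _nj_tree(dist: np.ndarray, ids: Sequence[str]) -> TreeNode:
    if len(ids) == 2:
        half = dist[0, 1] / 2.0
        return TreeNode.read(StringIO(f"({ids[0]}:{half:.8f},{ids[1]}:{half:.8f});"))
    dm = DistanceMatrix(dist, list(ids))
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0  # NJ can produce small negative branches
    return tree


def _splits(tree: TreeNode, leaf_set: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions, each canonicalised to the side not containing
    the lexicographically smallest leaf."""
    anchor = min(leaf_set)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= len(leaf_set) - 1:
            continue
        if anchor in side:
            side = leaf_set - side
        out.add(side)
    return out


def build_tree(
    aln: MultipleAlignment,
    bootstraps: int = 1000,
    seed: int = 0,
    gamma_shape: Optional[float] = 1.0,
    leaf_meta: Optional[dict[str, dict]] = None,
) -> GeneTree:
    """Neighbor-joining GTR(+Gamma) tree with codon-column bootstrap supports.

    Deterministic given ``seed``.  Supports are percentages of replicates
    containing each internal bipartition of the point-estimate tree.
    """
    if len(aln.ids) < 3:
        raise ValueError("build_tree needs at least 3 rows")
    codes = aln.codes()
    if ((codes >= 4).all(axis=1)).any():
        raise ValueError("alignment contains an all-gap row")
    dist = gtr_distance_matrix(codes, gamma_shape=gamma_shape)
    tree = _nj_tree(dist, aln.ids)
    leaf_set = frozenset(aln.ids)
    supports: dict[frozenset, int] = {}
    if bootstraps > 0:
        target = _splits(tree, leaf_set)
        hit_counts = {s: 0 for s in target}
        rng = np.random.default_rng(seed)
        ncols = aln.column_count
        n_codons = ncols // 3
        for _ in range(bootstraps):
            if n_codons > 0:
                cod = rng.integers(0, n_codons, size=n_codons)
                cols = (3 * cod[:, None] + np.arange(3)[None, :]).ravel()
            else:  # pragma: no cover - degenerate tiny alignment
                cols = rng.integers(0, ncols, size=ncols)
            bdist = gtr_distance_matrix(codes, columns=cols, gamma_shape=gamma_shape)
            btree = _nj_tree(bdist, aln.ids)
            for s in _splits(btree, leaf_set) & target:
                hit_counts[s] += 1
        supports = {
            s: int(round(100.0 * c / bootstraps)) for s, c in hit_counts.items()
        }
    return GeneTree(tree=tree, supports=supports, leaf_meta=dict(leaf_meta or {}))


# ---------------------------------------------------------------------------
# rescue and rooting


def _cherries(tree: TreeNode) -> list[tuple[str, str]]:
    out = []
    for node in tree.non_tips(include_self=True):
        kids = node.children
        if len(kids) == 2 and all(k.is_tip() for k in kids):
            out.append((kids[0].name, kids[1].name))
    return out


def rescue_unpaired(
    gtree: GeneTree,
    records: Sequence[PairRecord],
    sequences: Optional[dict[str, str]] = None,
    params: SearchParams = SearchParams(),
    min_support: int = 0,
    cluster_mode: str = "cherry",
) -> list[PairRecord]:
    """Reclassify cross-source unpaired genes that form a unique cluster.

    Tree leaves are named ``<gene_id>|<source letter>`` because the two sources
    may annotate a gene under the same id.  In ``cherry`` mode (default,
    strictest reading) a rescue happens for every two-leaf sister clade
    consisting of exactly one unpaired SOURCE_A and one unpaired SOURCE_B gene
    of the same species; ``clade`` mode widens this to any minimal clade
    containing exactly one unpaired leaf per source and no paired leaves.
    Merged records become imperfect pairs with ``rescued_by_tree=True``.  Gene
    count is conserved: only categories change.
    """
    by_gene: dict[str, PairRecord] = {}
    for pr in records:
        if pr.member_a is not None:
            by_gene[f"{pr.member_a}|A"] = pr
        if pr.member_b is not None:
            by_gene[f"{pr.member_b}|B"] = pr

    def unpaired_side(gid: str) -> Optional[str]:
        pr = by_gene.get(gid)
        if pr is None:
            return None
        if pr.category is PairCategory.UNPAIRED_A:
            return "A"
        if pr.category is PairCategory.UNPAIRED_B:
            return "B"
        return None

    candidates: list[tuple[str, str]] = []
    if cluster_mode == "cherry":
        groups = [list(pair) for pair in _cherries(gtree.tree)]
    elif cluster_mode == "clade":
        groups = []
        for node in gtree.tree.non_tips(include_self=True):
            leaves = [t.name for t in node.tips()]
            sides = [unpaired_side(g) for g in leaves]
            if None in sides:
                continue
            if sorted(sides) == ["A", "B"]:
                groups.append(leaves)
        # keep minimal clades only
        groups = [
            g
            for g in groups
            if not any(set(h) < set(g) for h in groups if h is not g)
        ]
    else:
        raise ValueError(f"unknown cluster_mode {cluster_mode!r}")

    for leaves in groups:
        if len(leaves) != 2:
            continue
        x, y = leaves
        sx, sy = unpaired_side(x), unpaired_side(y)
        if sx is None or sy is None or sx == sy:
            continue
        if sx == "B":
            x, y = y, x
        prx, pry = by_gene[x], by_gene[y]
        if prx.species != pry.species or prx.enzyme != pry.enzyme:
            continue
        if min_support > 0:
            split = frozenset(leaves)
            if gtree.supports.get(split, 0) < min_support:
                # cherry splits are trivial bipartitions on 4-taxon trees etc.;
                # missing support entries fail a positive threshold
                continue
        candidates.append((x, y))

    merged_genes: set[str] = set()
    merged_objs: set[int] = set()
    out: list[PairRecord] = []
    merged_records: list[PairRecord] = []
    for ga, gb in candidates:
        if ga in merged_genes or gb in merged_genes:
            continue
        merged_genes.update((ga, gb))
        pra, prb = by_gene[ga], by_gene[gb]
        merged_objs.update((id(pra), id(prb)))
        ident = None
        ratio = None
        if sequences and ga in sequences and gb in sequences:
            sa, sb = sequences[ga], sequences[gb]
            from annoconcord.pairs import _identity  # local to avoid cycle at import

            ident = 100.0 if sa == sb else _identity(encode(sa), encode(sb), params)
            ratio = max(len(sa), len(sb)) / min(len(sa), len(sb))
        merged_records.append(
            PairRecord(
                enzyme=pra.enzyme,
                species=pra.species,
                member_a=ga.rsplit("|", 1)[0],
                member_b=gb.rsplit("|", 1)[0],
                category=PairCategory.IMPERFECT,
                identity=ident,
                length_ratio=ratio,
                length_a=pra.length_a,
                length_b=prb.length_b,
                rescued_by_tree=True,
            )
        )
    for pr in records:
        if id(pr) in merged_objs:
            continue
        out.append(pr)
    out.extend(merged_records)
    return out


def root_with_outgroup(gtree: GeneTree, outgroup_labels: Sequence[str]) -> GeneTree:
    """Root on the edge subtending the smallest clade holding all outgroup leaves.

    If the outgroup is not monophyletic in the unrooted tree, the edge whose
    bipartition best agrees with the outgroup/ingroup partition is chosen and a
    warning logged.
    """
    outgroup = set(outgroup_labels)
    if not outgroup:
        raise ValueError("empty outgroup set")
    leaves = set(gtree.leaf_names())
    missing = outgroup - leaves
    if missing:
        raise ValueError(f"outgroup labels absent from tree: {sorted(missing)}")
    tree = gtree.tree.copy()
    best_node = None
    best_score = -1
    best_size = None
    n_leaves = len(leaves)

    def leafset(node) -> set:
        return {node.name} if node.is_tip() else {t.name for t in node.tips()}

    for node in tree.traverse(include_self=False):
        side = leafset(node)
        agree = len(outgroup & side) + len((leaves - outgroup) - side)
        agree = max(agree, n_leaves - agree)  # orientation-free
        size_penalty = min(len(side), n_leaves - len(side))
        if agree > best_score or (agree == best_score and (best_size is None or size_penalty < best_size)):
            best_node = node
            best_score = agree
            best_size = size_penalty
    side = leafset(best_node)
    if side not in (outgroup, leaves - outgroup):
        logger.warning("outgroup not monophyletic; rooting on best-agreement edge")
    rooted = tree.root_at(best_node, above=True, reset=True, branch_attrs=[])
    return GeneTree(tree=rooted, supports=dict(gtree.supports), leaf_meta=dict(gtree.leaf_meta))
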