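"""Cross-source pair classification: perfect / imperfect / unpaired.

Within one species and one enzyme family, annotations from the two sources are
matched by reciprocal best hits (RBH).  A pair is *perfect* when the two coding
sequences are identical strings (the symmetric reading of "100% identity over
100% of the length"); every other RBH pair is *imperfect*, with alignment
identity and a length ratio recorded.  Genes with no RBH partner are *unpaired*
unless their CDS duplicates another gene of the same source, in which case they
are excluded as redundant.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from annoconcord._aligner import encode, sw_align, sw_score
from annoconcord.annotation_io import AnnotationRecord, Source
from annoconcord.search import Enzyme, SearchParams


class PairCategory(str, Enum):
    PERFECT = "perfect"
    IMPERFECT = "imperfect"
    UNPAIRED_A = "unpaired_a"
    UNPAIRED_B = "unpaired_b"
    EXCLUDED_REDUNDANT = "excluded_redundant"


@dataclass(frozen=True)
class PairRecord:
    enzyme: Enzyme
    species: str
    member_a: Optional[str]
    member_b: Optional[str]
    category: PairCategory
    identity: Optional[float] = None  # percent, [0, 100]
    length_ratio: Optional[float] = None  # longer/shorter, >= 1
    length_a: Optional[int] = None
    length_b: Optional[int] = None
    rescued_by_tree: bool = False

    def __post_init__(self) -> None:
        both = self.member_a is not None and self.member_b is not None
        if self.category in (PairCategory.PERFECT, PairCategory.IMPERFECT) and not both:
            raise ValueError("paired categories need both members")
        if self.category is PairCategory.UNPAIRED_A and (
            self.member_a is None or self.member_b is not None
        ):
            raise ValueError("unpaired_a needs exactly member_a")
        if self.category is PairCategory.UNPAIRED_B and (
            self.member_b is None or self.member_a is not None
        ):
            raise ValueError("unpaired_b needs exactly member_b")
        if self.category is PairCategory.PERFECT:
            if self.identity != 100.0 or self.length_ratio != 1.0:
                raise ValueError("perfect pairs have identity 100 and length ratio 1")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g in (self.member_a, self.member_b) if g is not None)


def _score(a_enc, b_enc, params: SearchParams) -> float:
    return sw_score(
        a_enc,
        b_enc,
        float(params.match_reward),
        float(params.mismatch_penalty),
        float(params.gap_open),
        float(params.gap_extend),
    )


def _identity(a_enc, b_enc, params: SearchParams) -> float:
    _, _, _, _, _, matches, aln_len, _, _ = sw_align(
        a_enc,
        b_enc,
        float(params.match_reward),
        float(params.mismatch_penalty),
        float(params.gap_open),
        float(params.gap_extend),
    )
    return 100.0 * matches / aln_len if aln_len else 0.0


def reciprocal_best_hits(
    set_a: Sequence[AnnotationRecord],
    set_b: Sequence[AnnotationRecord],
    params: SearchParams = SearchParams(),
) -> list[tuple[str, str]]:
    """RBH pairs between two same-species, same-family gene sets.

    (a, b) is returned iff b is among a's best-scoring hits in set_b and a is
    among b's best in set_a.  "Best" means highest alignment score; ties break
    by lower E-value (equivalent at fixed lengths), then higher identity.
    Remaining exact ties (typically identical-sequence groups) are resolved by
    a deterministic matching: queries in id order each take the smallest
    still-unused tied partner, so a group of k identical genes on both sides
    yields k pairs instead of collapsing onto one partner.  Each gene appears
    in at most one pair.
    """
    if not set_a or not set_b:
        return []
    enc_a = {r.gene_id: encode(r.sequence) for r in set_a}
    enc_b = {r.gene_id: encode(r.sequence) for r in set_b}
    ids_a = sorted(enc_a)
    ids_b = sorted(enc_b)
    scores: dict[tuple[str, str], float] = {}
    for ga in ids_a:
        for gb in ids_b:
            scores[(ga, gb)] = _score(enc_a[ga], enc_b[gb], params)

    def tied_best(gid: str, partners: list[str], is_a: bool) -> set[str]:
        key = lambda p: (gid, p) if is_a else (p, gid)
        top = max(scores[key(p)] for p in partners)
        tied = [p for p in partners if scores[key(p)] == top]
        if len(tied) > 1:
            enc_self = enc_a[gid] if is_a else enc_b[gid]
            enc_other = enc_b if is_a else enc_a
            idents = {p: _identity(enc_self, enc_other[p], params) for p in tied}
            best_ident = max(idents.values())
            tied = [p for p in tied if idents[p] == best_ident]
        return set(tied)

    best_a = {ga: tied_best(ga, ids_b, True) for ga in ids_a}
    best_b = {gb: tied_best(gb, ids_a, False) for gb in ids_b}
    used_b: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for ga in ids_a:
        mutual = [gb for gb in best_a[ga] if ga in best_b[gb] and gb not in used_b]
        if mutual:
            gb = min(mutual)
            used_b.add(gb)
            pairs.append((ga, gb))
    return pairs


def classify_pairs(
    rbh: Sequence[tuple[str, str]],
    set_a: Sequence[AnnotationRecord],
    set_b: Sequence[AnnotationRecord],
    enzyme: Enzyme,
    species: str,
    params: SearchParams = SearchParams(),
) -> list[PairRecord]:
    """Turn RBH pairs into perfect/imperfect records; leftovers become unpaired."""
    seq_a = {r.gene_id: r.sequence for r in set_a}
    seq_b = {r.gene_id: r.sequence for r in set_b}
    records: list[PairRecord] = []
    paired_a: set[str] = set()
    paired_b: set[str] = set()
    for ga, gb in rbh:
        sa, sb = seq_a[ga], seq_b[gb]
        paired_a.add(ga)
        paired_b.add(gb)
        if sa == sb:
            records.append(
                PairRecord(
                    enzyme=enzyme,
                    species=species,
                    member_a=ga,
                    member_b=gb,
                    category=PairCategory.PERFECT,
                    identity=100.0,
                    length_ratio=1.0,
                    length_a=len(sa),
                    length_b=len(sb),
                )
            )
        else:
            ident = _identity(encode(sa), encode(sb), params)
            ratio = max(len(sa), len(sb)) / min(len(sa), len(sb))
            records.append(
                PairRecord(
                    enzyme=enzyme,
                    species=species,
                    member_a=ga,
                    member_b=gb,
                    category=PairCategory.IMPERFECT,
                    identity=ident,
                    length_ratio=ratio,
                    length_a=len(sa),
                    length_b=len(sb),
                )
            )
    for r in set_a:
        if r.gene_id not in paired_a:
            records.append(
                PairRecord(
                    enzyme=enzyme,
                    species=species,
                    member_a=r.gene_id,
                    member_b=None,
                    category=PairCategory.UNPAIRED_A,
                    length_a=r.length,
                )
            )
    for r in set_b:
        if r.gene_id not in paired_b:
            records.append(
                PairRecord(
                    enzyme=enzyme,
                    species=species,
                    member_a=None,
                    member_b=r.gene_id,
                    category=PairCategory.UNPAIRED_B,
                    length_b=r.length,
                )
            )
    return records


def exclude_redundant_unpaired(
    records: Sequence[PairRecord],
    full_source_sets: Sequence[AnnotationRecord],
) -> list[PairRecord]:
    """Recategorise unpaired genes that duplicate another gene of their source.

    An unpaired annotation whose CDS is string-identical to a *different*
    gene_id in the same (species, source) set carries no independent evidence
    and is excluded as redundant.
    """
    by_source: dict[tuple[str, Source], dict[str, str]] = {}
    for rec in full_source_sets:
        by_source.setdefault((rec.species, rec.source), {})[rec.gene_id] = rec.sequence
    out: list[PairRecord] = []
    for pr in records:
        if pr.category is PairCategory.UNPAIRED_A:
            gid, source = pr.member_a, Source.SOURCE_A
        elif pr.category is PairCategory.UNPAIRED_B:
            gid, source = pr.member_b, Source.SOURCE_B
        else:
            out.append(pr)
            continue
        pool = by_source.get((pr.species, source), {})
        seq = pool.get(gid)
        redundant = seq is not None and any(
            other_seq == seq for other_gid, other_seq in pool.items() if other_gid != gid
        )
        if redundant:
            out.append(replace(pr, category=PairCategory.EXCLUDED_REDUNDANT))
        else:
            out.append(pr)
    return out


def merge_final(records: Sequence[PairRecord]) -> dict[tuple[Enzyme, str], set[str]]:
    """Final non-redundant gene set per (enzyme, species).

    One representative per pair, preferring the SOURCE_A (NCBI-style) member,
    plus all remaining unpaired genes from either source; excluded-redundant
    records contribute nothing.
    """
    final: dict[tuple[Enzyme, str], set[str]] = {}
    for pr in records:
        key = (pr.enzyme, pr.species)
        final.setdefault(key, set())
        if pr.category in (PairCategory.PERFECT, PairCategory.IMPERFECT):
            final[key].add(pr.member_a)
        elif pr.category is PairCategory.UNPAIRED_A:
            final[key].add(pr.member_a)
        elif pr.category is PairCategory.UNPAIRED_B:
            final[key].add(pr.member_b)
    return final


def write_pair_table(records: Iterable[PairRecord], path: Path | str) -> None:
    with open(Path(path), "w") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "enzyme",
                "species",
                "member_a",
                "member_b",
                "category",
                "identity",
                "length_a",
                "length_b",
                "rescued_by_tree",
            ]
        )
        for pr in records:
            writer.writerow(
                [
                    pr.enzyme.value,
                    pr.species,
                    pr.member_a or "",
                    pr.member_b or "",
                    pr.category.value,
                    f"{pr.identity:.2f}" if pr.identity is not None else "",
                    pr.length_a if pr.length_a is not None else "",
                    pr.length_b if pr.length_b is not None else "",
                    int(pr.rescued_by_tree),
                ]
            )


def read_pair_table(path: Path | str) -> list[PairRecord]:
    records = []
    with open(Path(path)) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            cat = PairCategory(row["category"])
            ident = float(row["identity"]) if row["identity"] else None
            la = int(row["length_a"]) if row["length_a"] else None
            lb = int(row["length_b"]) if row["length_b"] else None
            ratio = None
            if la and lb:
                ratio = max(la, lb) / min(la, lb)
            records.append(
                PairRecord(
                    enzyme=Enzyme(row["enzyme"]),
                    species=row["species"],
                    member_a=row["member_a"] or None,
                    member_b=row["member_b"] or None,
                    category=cat,
                    identity=ident,
                    length_ratio=ratio,
                    length_a=la,
                    length_b=lb,
                    rescued_by_tree=bool(int(row["rescued_by_tree"])),
                )
            )
    return records
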