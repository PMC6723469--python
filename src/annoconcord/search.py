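"""Relaxed nucleotide local-similarity search for enzyme homolog mining.

The reference backend is an in-package Smith-Waterman aligner with +1/-1
match/mismatch scoring and affine gaps, thresholded on Karlin-Altschul
E-values (E = K*m*n*exp(-lambda*S)).  For the +1/-1 scheme on uniform base
composition lambda = ln 3 exactly; K is fixed at 0.333, the conventional
ungapped value for this scheme, and applied to gapped scores as a documented
approximation.  Downstream logic relies on thresholding behaviour (a relaxed
cutoff of 1e-50 keeps genuine family members and rejects unrelated CDS by tens
of orders of magnitude), not on exact E-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from annoconcord._aligner import encode, sw_align, sw_score
from annoconcord.annotation_io import AnnotationRecord

logger = logging.getLogger(__name__)

KA_LAMBDA = math.log(3.0)
KA_K = 0.333
MIN_QUERY_WARN_LEN = 50


class Enzyme(str, Enum):
    """The seven core anthocyanin-branch FBP enzymes, in pathway order."""

    CHS = "CHS"
    CHI = "CHI"
    F3H = "F3H"
    F3pH = "F3pH"  # flavonoid 3'-hydroxylase
    F3p5pH = "F3p5pH"  # flavonoid 3',5'-hydroxylase
    DFR = "DFR"
    ANS = "ANS"


#: KEGG orthology codes for the seven enzymes.
KEGG_CODES: dict[Enzyme, str] = {
    Enzyme.CHS: "K00660",
    Enzyme.CHI: "K01859",
    Enzyme.F3H: "K00475",
    Enzyme.F3pH: "K05280",
    Enzyme.F3p5pH: "K13083",
    Enzyme.DFR: "K13082",
    Enzyme.ANS: "K05277",
}

#: CYP75 subfamily members analysed jointly downstream.
CYP75_ENZYMES = (Enzyme.F3pH, Enzyme.F3p5pH)

_ENZYME_ORDER = {e: i for i, e in enumerate(Enzyme)}


@dataclass(frozen=True)
class SearchParams:
    """Scoring scheme and E-value cutoff of the similarity search.

    Defaults follow relaxed nucleotide search practice: +1/-1 with a strict
    1e-50 cutoff for homolog mining.  Gap costs are conventional for +-1
    scoring (a gap of length k costs gap_open + k*gap_extend).
    """

    match_reward: int = 1
    mismatch_penalty: int = -1
    gap_open: int = 5
    gap_extend: int = 2
    evalue_max: float = 1e-50

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if not (self.match_reward > 0 > self.mismatch_penalty):
            raise ValueError("need match_reward > 0 > mismatch_penalty")


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int  # 1-based inclusive
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    score: float
    query_coverage: float


@dataclass(frozen=True)
class EnzymeSpec:
    enzyme: Enzyme
    seed_queries: tuple[tuple[str, str], ...]  # (query_id, sequence)
    kegg_code: str = ""

    def __post_init__(self) -> None:
        if not self.seed_queries:
            raise ValueError(f"{self.enzyme}: at least one seed query required")


def evalue_from_score(score: float, m: int, n: int) -> float:
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def bit_score_from_score(score: float) -> float:
    return (KA_LAMBDA * score - math.log(KA_K)) / math.log(2.0)


def min_score_for_evalue(evalue_max: float, m: int, n: int) -> float:
    """Smallest raw score whose E-value is <= evalue_max in an m x n search space."""
    return (math.log(KA_K * m * n) - math.log(evalue_max)) / KA_LAMBDA


def local_search(
    queries: Sequence[tuple[str, str]],
    subjects: Sequence[tuple[str, str]],
    params: SearchParams = SearchParams(),
) -> list[SimilarityHit]:
    """All query-subject local alignments passing the E-value cutoff.

    ``queries`` and ``subjects`` are (id, sequence) pairs.  The search space for
    each query is query length x total subject length.  Deterministic: hits are
    ordered by (query, descending score, subject id).
    """
    subjects = list(subjects)
    n_total = sum(len(s) for _, s in subjects)
    if n_total == 0:
        return []
    enc_subjects = [(sid, s, encode(s)) for sid, s in subjects]
    hits: list[SimilarityHit] = []
    for qid, qseq in queries:
        if len(qseq) < MIN_QUERY_WARN_LEN:
            logger.warning("query %s is shorter than %d nt", qid, MIN_QUERY_WARN_LEN)
        qenc = encode(qseq)
        m = len(qseq)
        smin = min_score_for_evalue(params.evalue_max, m, n_total)
        qhits = []
        for sid, sseq, senc in enc_subjects:
            score = sw_score(
                qenc,
                senc,
                float(params.match_reward),
                float(params.mismatch_penalty),
                float(params.gap_open),
                float(params.gap_extend),
            )
            if score < smin:
                continue
            (
                score,
                qs,
                qe,
                ss,
                se,
                matches,
                aln_len,
                gaps,
                gap_opens,
            ) = sw_align(
                qenc,
                senc,
                float(params.match_reward),
                float(params.mismatch_penalty),
                float(params.gap_open),
                float(params.gap_extend),
            )
            ev = evalue_from_score(score, m, n_total)
            if ev > params.evalue_max:
                continue
            qhits.append(
                SimilarityHit(
                    query_id=qid,
                    subject_id=sid,
                    percent_identity=100.0 * matches / aln_len if aln_len else 0.0,
                    alignment_length=aln_len,
                    mismatches=aln_len - gaps - matches,
                    gap_opens=gap_opens,
                    q_start=qs + 1,
                    q_end=qe,
                    s_start=ss + 1,
                    s_end=se,
                    evalue=ev,
                    bit_score=bit_score_from_score(score),
                    score=score,
                    query_coverage=(qe - qs) / m,
                )
            )
        qhits.sort(key=lambda h: (-h.score, h.subject_id))
        hits.extend(qhits)
    return hits


def write_hit_table(hits: Iterable[SimilarityHit], path: Path | str) -> None:
    """12-column tab-separated hit summary (blast outfmt-6 layout)."""
    with open(Path(path), "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.3f}",
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:.3g}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


def identify_homologs(
    specs: Sequence[EnzymeSpec],
    annotation: Sequence[AnnotationRecord],
    params: SearchParams = SearchParams(),
) -> tuple[dict[Enzyme, set[str]], set[str]]:
    """Assign each annotated gene to the enzyme whose seeds hit it best.

    Every gene with at least one passing hit is assigned to exactly one enzyme,
    the one providing its best raw alignment score (ties broken by enzyme
    order).  Returns (per-enzyme gene-id sets, merged CYP75 set): the F3'H and
    F3'5'H hydroxylases are additionally pooled for joint analysis.
    """
    subjects = [(r.gene_id, r.sequence) for r in annotation]
    best: dict[str, tuple[float, int]] = {}
    assignment: dict[Enzyme, set[str]] = {spec.enzyme: set() for spec in specs}
    for spec in specs:
        hits = local_search(list(spec.seed_queries), subjects, params)
        order = _ENZYME_ORDER[spec.enzyme]
        for h in hits:
            key = (h.score, -order)
            cur = best.get(h.subject_id)
            if cur is None or key > cur[0]:
                best[h.subject_id] = (key, order)
    inv_order = {i: e for e, i in _ENZYME_ORDER.items()}
    for gid, (_, order) in best.items():
        assignment[inv_order[order]].add(gid)
    cyp75 = set().union(*(assignment.get(e, set()) for e in CYP75_ENZYMES))
    return assignment, cyp75
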