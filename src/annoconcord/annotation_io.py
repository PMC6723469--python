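"""Reading, normalising and filtering annotated CDS sets.

Two annotation sources are compared throughout the package: an "NCBI-style"
source (``SOURCE_A``) and a "genome-specific" source (``SOURCE_B``).  Each source
delivers one nucleotide FASTA of annotated transcripts or coding sequences per
species, optionally accompanied by a feature table mapping transcripts to loci.
Normalisation turns these into one representative CDS per locus:

1. coding-sequence inference by a deterministic longest-ORF rule with a 300 nt
   floor (transcripts that may carry UTRs only),
2. transcript-variant removal, keeping the longest sequence per locus,
3. removal of records whose CDS is more than 10% ambiguous (N).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_STOPS = frozenset({"TAA", "TAG", "TGA"})

DEFAULT_MIN_CDS_LEN = 300
DEFAULT_MAX_N_FRACTION = 0.10


class Source(str, Enum):
    """Annotation provenance: A = NCBI-style pipeline, B = genome-specific pipeline."""

    SOURCE_A = "A"
    SOURCE_B = "B"


class VariantPolicy(str, Enum):
    PREFILTERED_PRIMARY = "prefiltered_primary"
    LONGEST_PER_LOCUS = "longest_per_locus"
    LONGEST_PER_LOCUS_FROM_FEATURE_TABLE = "longest_per_locus_from_feature_table"


@dataclass(frozen=True)
class SourceDialect:
    """How one annotation source packages transcript variants."""

    name: str
    variant_policy: VariantPolicy

    @property
    def requires_feature_table(self) -> bool:
        return self.variant_policy is VariantPolicy.LONGEST_PER_LOCUS_FROM_FEATURE_TABLE


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated transcript or CDS from one source.

    ``gene_id`` is unique within (species, source); ``locus_id`` groups transcript
    variants of the same locus; ``is_cds`` is False when the sequence may still
    carry UTRs and needs ORF inference.
    """

    gene_id: str
    locus_id: str
    transcript_id: str
    species: str
    source: Source
    sequence: str
    is_cds: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for {self.gene_id}")

    @property
    def length(self) -> int:
        return len(self.sequence)


class AnnotationParseError(RuntimeError):
    pass


def _locus_from_transcript_id(transcript_id: str) -> str:
    """Strip one trailing '.<int>' version/isoform suffix (e.g. 'Soltu.1.2' -> 'Soltu.1')."""
    stem, dot, tail = transcript_id.rpartition(".")
    if dot and tail.isdigit():
        return stem
    return transcript_id


def _read_feature_map(feature_path: Path) -> dict[str, str]:
    """Read transcript -> locus mapping from a 2-column TSV or a GFF3.

    GFF3 support is minimal on purpose: mRNA/transcript features provide
    (ID, Parent) pairs, everything else is ignored.
    """
    feature_path = Path(feature_path)
    mapping: dict[str, str] = {}
    with open(feature_path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith("##gff") or first.count("\t") >= 8:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    continue
                ftype = fields[2].lower()
                if ftype not in {"mrna", "transcript"}:
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                tid = attrs.get("ID")
                parent = attrs.get("Parent")
                if tid and parent:
                    mapping[tid] = parent.split(",")[0]
        else:
            for row in csv.reader(fh, delimiter="\t"):
                if len(row) >= 2 and row[0] and not row[0].startswith("#"):
                    mapping[row[0]] = row[1]
    return mapping


def parse_annotation_set(
    cds_path: Path | str,
    feature_path: Optional[Path | str],
    species: str,
    source: Source,
    dialect: SourceDialect,
    is_cds: bool = True,
) -> list[AnnotationRecord]:
    """Load one (species, source) annotation set from FASTA (+ optional feature table).

    Locus ids come from the feature table when given; otherwise a trailing
    '.<int>' suffix of the transcript id is stripped.  FASTA entries missing from
    the feature table are retained with locus_id = transcript_id and a warning.
    """
    cds_path = Path(cds_path)
    if not cds_path.exists():
        raise AnnotationParseError(f"FASTA not found: {cds_path}")
    if dialect.requires_feature_table and feature_path is None:
        raise AnnotationParseError(
            f"dialect {dialect.name!r} requires a feature table but none was given"
        )
    feature_map = _read_feature_map(Path(feature_path)) if feature_path else None

    records: list[AnnotationRecord] = []
    seen: set[str] = set()
    try:
        entries = list(SeqIO.parse(str(cds_path), "fasta"))
    except Exception as exc:  # pragma: no cover - malformed files are rare in practice
        raise AnnotationParseError(f"cannot parse FASTA {cds_path}: {exc}") from exc
    for entry in entries:
        tid = entry.id
        if tid in seen:
            raise AnnotationParseError(f"duplicate FASTA id {tid!r} in {cds_path}")
        seen.add(tid)
        seq = str(entry.seq).upper()
        if feature_map is not None:
            locus = feature_map.get(tid)
            if locus is None:
                logger.warning(
                    "%s/%s: %s absent from feature table; using transcript id as locus",
                    species,
                    source.value,
                    tid,
                )
                locus = tid
        else:
            locus = _locus_from_transcript_id(tid)
        records.append(
            AnnotationRecord(
                gene_id=tid,
                locus_id=locus,
                transcript_id=tid,
                species=species,
                source=source,
                sequence=seq,
                is_cds=is_cds,
            )
        )
    return records


def _validate_alphabet(record: AnnotationRecord) -> None:
    bad = set(record.sequence) - _VALID_BASES
    if bad:
        raise ValueError(
            f"{record.gene_id}: invalid characters {sorted(bad)} (alphabet is A,C,G,T,N)"
        )


def longest_orf(sequence: str) -> Optional[tuple[int, int]]:
    """Return (start, end) of the longest forward-strand ORF, or None.

    An ORF is ATG..stop in one of the three forward frames of the given
    transcript, standard genetic code; ``end`` is exclusive and includes the stop
    codon.  Codons containing N are treated as non-stop (and NTG etc. never
    counts as a start).  Ties go to the leftmost ORF.
    """
    best: Optional[tuple[int, int]] = None
    n = len(sequence)
    for frame in range(3):
        start: Optional[int] = None
        for pos in range(frame, n - 2, 3):
            codon = sequence[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOPS:
                length = pos + 3 - start
                if best is None or length > best[1] - best[0]:
                    best = (start, pos + 3)
                start = None
        # an unterminated run (no in-frame stop) is not an ORF
    return best


def infer_cds(
    record: AnnotationRecord, min_len: int = DEFAULT_MIN_CDS_LEN
) -> Optional[AnnotationRecord]:
    """Replace a transcript by its longest ORF; reject if that ORF is < min_len.

    Emulates stripping UTRs from transcript-level annotations before length and
    identity comparison; 300 nt is the conventional floor for a credible FBP
    coding sequence.  Returns None on rejection.
    """
    if record.is_cds:
        raise ValueError(f"{record.gene_id} is already a CDS")
    _validate_alphabet(record)
    span = longest_orf(record.sequence)
    if span is None:
        return None
    start, end = span
    if end - start < min_len:
        return None
    return replace(record, sequence=record.sequence[start:end], is_cds=True)


def dedup_variants(
    records: Sequence[AnnotationRecord], dialect: SourceDialect
) -> list[AnnotationRecord]:
    """Collapse transcript variants to one representative per locus.

    PREFILTERED_PRIMARY sets pass through unchanged; the other policies keep the
    longest sequence per locus_id (ties: lexicographically smallest
    transcript_id).  Output preserves input order of the survivors.
    """
    if dialect.variant_policy is VariantPolicy.PREFILTERED_PRIMARY:
        return list(records)
    if records:
        tags = {(r.species, r.source) for r in records}
        if len(tags) > 1:
            raise ValueError(f"mixed (species, source) in dedup_variants: {tags}")
    best: dict[str, AnnotationRecord] = {}
    for rec in records:
        cur = best.get(rec.locus_id)
        if (
            cur is None
            or rec.length > cur.length
            or (rec.length == cur.length and rec.transcript_id < cur.transcript_id)
        ):
            best[rec.locus_id] = rec
    keep = set(id(r) for r in best.values())
    return [r for r in records if id(r) in keep]


def drop_ambiguous(
    records: Sequence[AnnotationRecord], max_n_fraction: float = DEFAULT_MAX_N_FRACTION
) -> list[AnnotationRecord]:
    """Drop records whose CDS is more than ``max_n_fraction`` N, with a warning."""
    kept = []
    for rec in records:
        if rec.sequence.count("N") / rec.length > max_n_fraction:
            logger.warning("dropping %s: >%d%% N", rec.gene_id, int(100 * max_n_fraction))
        else:
            kept.append(rec)
    return kept


def normalize_annotation_set(
    records: Sequence[AnnotationRecord],
    dialect: SourceDialect,
    min_len: int = DEFAULT_MIN_CDS_LEN,
    max_n_fraction: float = DEFAULT_MAX_N_FRACTION,
) -> list[AnnotationRecord]:
    """Full normalisation: CDS inference (when needed), variant removal, N filter."""
    inferred: list[AnnotationRecord] = []
    for rec in records:
        if rec.is_cds:
            _validate_alphabet(rec)
            if rec.length >= min_len:
                inferred.append(rec)
        else:
            out = infer_cds(rec, min_len=min_len)
            if out is not None:
                inferred.append(out)
    deduped = dedup_variants(inferred, dialect)
    return drop_ambiguous(deduped, max_n_fraction)


def write_normalized(
    records: Sequence[AnnotationRecord], fasta_path: Path | str, manifest_path: Path | str
) -> None:
    """Write normalized FASTA plus a TSV manifest (gene, locus, species, source, length)."""
    fasta_path = Path(fasta_path)
    manifest_path = Path(manifest_path)
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description="") for r in records
    ]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    with open(manifest_path, "w") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "locus_id", "species", "source", "length"])
        for r in records:
            writer.writerow([r.gene_id, r.locus_id, r.species, r.source.value, r.length])


def read_normalized(
    fasta_path: Path | str, manifest_path: Path | str
) -> list[AnnotationRecord]:
    """Inverse of :func:`write_normalized`."""
    seqs = {e.id: str(e.seq).upper() for e in SeqIO.parse(str(fasta_path), "fasta")}
    records = []
    with open(manifest_path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(
                AnnotationRecord(
                    gene_id=row["gene_id"],
                    locus_id=row["locus_id"],
                    transcript_id=row["gene_id"],
                    species=row["species"],
                    source=Source(row["source"]),
                    sequence=seqs[row["gene_id"]],
                    is_cds=True,
                )
            )
    return records
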