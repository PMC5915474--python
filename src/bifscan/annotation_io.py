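"""Transcript annotation and genome-sequence input.

Transcript models are read from UCSC genePred / refFlat tables or from GTF
and normalised to a single internal convention: 0-based, half-open exon
intervals on the forward genomic strand.  Each transcript carries a coding
flag derived from its CDS columns when present, cross-checked against the
RefSeq accession prefix (NM_/XM_ coding, NR_/XR_ non-coding).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable

log = logging.getLogger(__name__)

_IUPAC = set("ACGTRYSWKMBDHVN")


class CodingClass(str, Enum):
    CODING = "coding"
    NONCODING = "noncoding"
    UNKNOWN = "unknown"


class AnnotationError(ValueError):
    """Malformed annotation input."""


class FastaError(ValueError):
    """Malformed FASTA input."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript isoform.

    exons are 0-based half-open genomic intervals, sorted ascending and
    pairwise disjoint.  ``cds`` is the genomic CDS span (start, end) or None
    for non-coding transcripts.  ``predicted`` marks XM_/XR_ accessions.
    """

    accession: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None = None
    coding: bool = False
    predicted: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.accession}: strand must be + or -")
        if not self.exons:
            raise AnnotationError(f"{self.accession}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise AnnotationError(f"{self.accession}: empty exon [{s},{e})")
            if s < prev_end:
                raise AnnotationError(f"{self.accession}: exons overlap or unsorted")
            prev_end = e
        if self.cds is not None and not self.coding:
            raise AnnotationError(f"{self.accession}: CDS present but coding=False")

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GenomeSequence:
    """Chromosome name -> uppercase nucleotide string."""

    chroms: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> str:
        return self.chroms[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chroms

    def validate_transcript(self, t: TranscriptRecord) -> None:
        if t.chrom not in self.chroms:
            raise FastaError(f"{t.accession}: chromosome {t.chrom!r} absent from genome")
        if t.tx_end > len(self.chroms[t.chrom]):
            raise FastaError(
                f"{t.accession}: exon end {t.tx_end} beyond {t.chrom} "
                f"length {len(self.chroms[t.chrom])}"
            )


_PREFIX_RE = re.compile(r"^(NM|NR|XM|XR)_")


def classify_accession(accession: str) -> CodingClass:
    """Classify a RefSeq-style accession by its prefix.

    NM_/XM_ -> coding, NR_/XR_ -> noncoding, anything else -> unknown.
    A trailing version suffix (``.N``) is ignored; the function is total.
    """
    if not accession:
        raise ValueError("empty accession")
    m = _PREFIX_RE.match(accession)
    if m is None:
        return CodingClass.UNKNOWN
    return CodingClass.CODING if m.group(1) in ("NM", "XM") else CodingClass.NONCODING


def is_predicted_accession(accession: str) -> bool:
    return accession.startswith(("XM_", "XR_"))


def _split_int_list(s: str, n_expected: int, what: str, lineno: int) -> list[int]:
    parts = [p for p in s.strip().split(",") if p != ""]
    if len(parts) != n_expected:
        raise AnnotationError(
            f"line {lineno}: {what} has {len(parts)} entries, expected {n_expected}"
        )
    return [int(p) for p in parts]


def _make_record(
    accession: str,
    gene_symbol: str,
    chrom: str,
    strand: str,
    cds_start: int,
    cds_end: int,
    exons: tuple[tuple[int, int], ...],
    lineno: int | None = None,
) -> TranscriptRecord:
    where = f"line {lineno}: " if lineno is not None else ""
    has_cds = cds_end > cds_start
    prefix_class = classify_accession(accession)
    if has_cds and prefix_class is CodingClass.NONCODING:
        # CDS columns win over the accession prefix for the coding flag.
        log.warning(
            "%s%s has a non-coding prefix but a CDS; treating as coding", where, accession
        )
    return TranscriptRecord(
        accession=accession,
        gene_symbol=gene_symbol,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds=(cds_start, cds_end) if has_cds else None,
        coding=has_cds,
        predicted=is_predicted_accession(accession),
    )


def read_genepred(stream: IO[str] | Iterable[str]) -> list[TranscriptRecord]:
    """Read genePred or refFlat (auto-detected by column count).

    genePred rows start with the transcript name; refFlat rows carry a
    leading gene-symbol column.  Coordinates are kept 0-based half-open;
    ``cdsStart == cdsEnd`` signals a non-coding transcript.
    """
    records: list[TranscriptRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 11:  # refFlat: geneName + 10 genePred columns
            gene_symbol, fields = fields[0], fields[1:]
        elif len(fields) == 10:
            gene_symbol = ""
        else:
            raise AnnotationError(
                f"line {lineno}: expected 10 (genePred) or 11 (refFlat) fields, "
                f"got {len(fields)}"
            )
        (name, chrom, strand, _tx_start, _tx_end, cds_start, cds_end,
         exon_count, exon_starts, exon_ends) = fields
        n = int(exon_count)
        starts = _split_int_list(exon_starts, n, "exonStarts", lineno)
        ends = _split_int_list(exon_ends, n, "exonEnds", lineno)
        exons = tuple(zip(starts, ends))
        try:
            rec = _make_record(
                name, gene_symbol, chrom, strand,
                int(cds_start), int(cds_end), exons, lineno,
            )
        except AnnotationError as exc:
            raise AnnotationError(f"line {lineno}: {exc}") from None
        records.append(rec)
    return records


def write_genepred(records: Iterable[TranscriptRecord], stream: IO[str]) -> None:
    """Write refFlat rows (gene symbol first) with trailing-comma exon lists."""
    for t in records:
        cds_start, cds_end = t.cds if t.cds is not None else (t.tx_end, t.tx_end)
        starts = "".join(f"{s}," for s, _ in t.exons)
        ends = "".join(f"{e}," for _, e in t.exons)
        stream.write(
            "\t".join(
                [t.gene_symbol, t.accession, t.chrom, t.strand,
                 str(t.tx_start), str(t.tx_end), str(cds_start), str(cds_end),
                 str(len(t.exons)), starts, ends]
            )
            + "\n"
        )


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(stream: IO[str] | Iterable[str]) -> list[TranscriptRecord]:
    """Read GTF exon/CDS features into transcript records.

    GTF coordinates are 1-based closed; they are converted to 0-based
    half-open on read so that the same gene models written as genePred and
    GTF parse identically.  Transcripts are grouped by ``transcript_id``.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    order: list[str] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationError(f"line {lineno}: expected 9 GTF fields")
        chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
        if feature not in ("exon", "CDS"):
            continue
        attr = dict(_GTF_ATTR_RE.findall(attrs))
        tid = attr.get("transcript_id")
        if not tid:
            raise AnnotationError(f"line {lineno}: {feature} without transcript_id")
        gene = attr.get("gene_id", attr.get("gene_name", ""))
        iv = (int(start) - 1, int(end))
        if tid not in meta:
            meta[tid] = (gene, chrom, strand)
            order.append(tid)
        (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)
    records = []
    for tid in order:
        gene, chrom, strand = meta[tid]
        ex = tuple(sorted(exons.get(tid, [])))
        if not ex:
            raise AnnotationError(f"transcript {tid}: CDS features but no exons")
        if tid in cds:
            spans = sorted(cds[tid])
            cds_start, cds_end = spans[0][0], spans[-1][1]
            for s, e in spans:
                if not any(es <= s and e <= ee for es, ee in ex):
                    raise AnnotationError(f"transcript {tid}: CDS outside exon union")
        else:
            cds_start = cds_end = ex[-1][1]
        records.append(_make_record(tid, gene, chrom, strand, cds_start, cds_end, ex))
    return records


def read_fasta(stream: IO[str] | Iterable[str]) -> GenomeSequence:
    """Read FASTA into a chromosome map; sequences are upper-cased.

    The header token up to the first whitespace names the chromosome.
    Duplicate chromosome names and non-IUPAC characters are errors.
    """
    chroms: dict[str, str] = {}
    name: str | None = None
    parts: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(parts).upper()
        bad = set(seq) - _IUPAC
        if bad:
            raise FastaError(f"{name}: non-IUPAC characters {sorted(bad)}")
        chroms[name] = seq

    for raw in stream:
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0] if len(line) > 1 else ""
            if not name:
                raise FastaError("empty FASTA header")
            if name in chroms:
                raise FastaError(f"duplicate chromosome {name!r}")
            parts = []
        else:
            if name is None:
                raise FastaError("sequence before first header")
            parts.append(line)
    flush()
    if not chroms:
        raise FastaError("empty FASTA")
    return GenomeSequence(chroms)


def write_fasta(genome: GenomeSequence, stream: IO[str], width: int = 70) -> None:
    for name in genome.chroms:
        stream.write(f">{name}\n")
        seq = genome.chroms[name]
        for i in range(0, len(seq), width):
            stream.write(seq[i : i + width] + "\n")


def census_eligible(records: Iterable[TranscriptRecord],
                    include_predicted: bool = False) -> list[TranscriptRecord]:
    """Filter transcripts to those entering the coding/non-coding census.

    Predicted (XM_/XR_) accessions and unknown-prefix transcripts without
    CDS columns are excluded by default; the excluded count is logged.
    """
    kept, dropped = [], 0
    for t in records:
        if t.predicted and not include_predicted:
            dropped += 1
            continue
        if not t.coding and classify_accession(t.accession) is CodingClass.UNKNOWN:
            # no CDS evidence and no recognised prefix: class is undecidable
            dropped += 1
            continue
        kept.append(t)
    if dropped:
        log.info("census: excluded %d transcripts (predicted or unclassifiable)", dropped)
    return kept
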