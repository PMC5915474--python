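"""Three-way census of gene loci by isoform coding content.

Transcripts are grouped by gene symbol (the locus key) and each locus is
labelled coding-only, non-coding-only, or bifunctional (at least one coding
and one non-coding isoform).  The census summary reports counts and
percentages rounded half-away-from-zero to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import IO, Iterable

from .annotation_io import TranscriptRecord


class LocusClass(str, Enum):
    CODING_ONLY = "coding_only"
    NONCODING_ONLY = "noncoding_only"
    BIFUNCTIONAL = "bifunctional"


@dataclass(frozen=True)
class LocusPartition:
    gene_symbol: str
    n_coding_isoforms: int
    n_noncoding_isoforms: int

    def __post_init__(self) -> None:
        if self.n_coding_isoforms < 0 or self.n_noncoding_isoforms < 0:
            raise ValueError("negative isoform count")
        if self.n_coding_isoforms + self.n_noncoding_isoforms < 1:
            raise ValueError(f"{self.gene_symbol}: locus with no isoforms")

    @property
    def klass(self) -> LocusClass:
        if self.n_coding_isoforms > 0 and self.n_noncoding_isoforms > 0:
            return LocusClass.BIFUNCTIONAL
        if self.n_coding_isoforms > 0:
            return LocusClass.CODING_ONLY
        return LocusClass.NONCODING_ONLY


@dataclass(frozen=True)
class CensusSummary:
    counts: dict[LocusClass, int]
    total: int
    percentages: dict[LocusClass, float]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (not banker's rounding)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def partition_loci(transcripts: Iterable[TranscriptRecord]) -> list[LocusPartition]:
    """One LocusPartition per distinct gene symbol, sorted lexicographically.

    Every transcript must carry a non-empty gene symbol; offenders are
    reported together in the raised error.
    """
    transcripts = list(transcripts)
    missing = [t.accession for t in transcripts if not t.gene_symbol]
    if missing:
        raise ValueError(f"transcripts without gene symbol: {', '.join(missing)}")
    tally: dict[str, list[int]] = {}
    for t in transcripts:
        counts = tally.setdefault(t.gene_symbol, [0, 0])
        counts[0 if t.coding else 1] += 1
    return [
        LocusPartition(gene, c, nc)
        for gene, (c, nc) in sorted(tally.items())
    ]


def summarize_census(partition: list[LocusPartition]) -> CensusSummary:
    counts = {k: 0 for k in LocusClass}
    for p in partition:
        counts[p.klass] += 1
    return summarize_counts(
        counts[LocusClass.CODING_ONLY],
        counts[LocusClass.NONCODING_ONLY],
        counts[LocusClass.BIFUNCTIONAL],
    )


def summarize_counts(n_coding_only: int, n_noncoding_only: int,
                     n_bifunctional: int) -> CensusSummary:
    """Census summary from the three class counts.

    Percentage = 100 * count / total, rounded half-away-from-zero to one
    decimal; percentages are derived from counts, never stored independently.
    """
    counts = {
        LocusClass.CODING_ONLY: n_coding_only,
        LocusClass.NONCODING_ONLY: n_noncoding_only,
        LocusClass.BIFUNCTIONAL: n_bifunctional,
    }
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty partition: nothing to summarize")
    percentages = {k: round_half_up(100.0 * v / total) for k, v in counts.items()}
    return CensusSummary(counts=counts, total=total, percentages=percentages)


def write_partition_tsv(partition: list[LocusPartition], stream: IO[str]) -> None:
    stream.write("gene\tn_coding\tn_noncoding\tclass\n")
    for p in partition:
        stream.write(
            f"{p.gene_symbol}\t{p.n_coding_isoforms}\t{p.n_noncoding_isoforms}"
            f"\t{p.klass.value}\n"
        )


def write_census_tsv(summary: CensusSummary, stream: IO[str]) -> None:
    stream.write("class\tcount\tpercent\n")
    for k in LocusClass:
        stream.write(f"{k.value}\t{summary.counts[k]}\t{summary.percentages[k]}\n")
    stream.write(f"total\t{summary.total}\t100.0\n")
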