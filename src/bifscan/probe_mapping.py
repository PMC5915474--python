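"""Probe-to-isoform exact matching and discriminability.

A 25-nt expression-array probe "hits" a transcript when it occurs as an
exact, ungapped, full-length substring of the spliced transcript sequence
(optionally in reverse complement).  A probe is *ambiguous* when its hit set
contains both coding and non-coding isoforms, i.e. the probe cannot tell
the two isoform classes of a locus apart.

Matching is done with a k-mer hash over the spliced sequences (one index
per distinct probe length), which is exactly equivalent to a naive full
scan but linear in total transcript length.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Literal

from Bio.Seq import reverse_complement

from .annotation_io import GenomeSequence, TranscriptRecord
from .locus_partition import LocusClass, LocusPartition, round_half_up

log = logging.getLogger(__name__)

SenseMode = Literal["sense", "antisense", "both"]


class Verdict(str, Enum):
    CODING_SPECIFIC = "coding_specific"
    NONCODING_SPECIFIC = "noncoding_specific"
    AMBIGUOUS = "ambiguous"
    NO_HIT = "no_hit"


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    probeset_id: str
    declared_gene: str
    sequence: str


@dataclass
class ProbeHitReport:
    probe_id: str
    hits: set[tuple[str, int]] = field(default_factory=set)  # (accession, offset)
    hit_coding: bool = False
    hit_noncoding: bool = False

    @property
    def verdict(self) -> Verdict:
        if not self.hits:
            return Verdict.NO_HIT
        if self.hit_coding and self.hit_noncoding:
            return Verdict.AMBIGUOUS
        return Verdict.CODING_SPECIFIC if self.hit_coding else Verdict.NONCODING_SPECIFIC


@dataclass
class GeneDiscriminability:
    gene_symbol: str
    n_probes: int
    n_ambiguous: int

    @property
    def any_ambiguous(self) -> bool:
        return self.n_ambiguous > 0

    @property
    def all_ambiguous(self) -> bool:
        return self.n_probes > 0 and self.n_ambiguous == self.n_probes


def spliced_sequence(t: TranscriptRecord, genome: GenomeSequence) -> str:
    """Spliced transcript sequence: exon substrings concatenated in genomic
    order, reverse-complemented for minus-strand transcripts."""
    genome.validate_transcript(t)
    chrom = genome[t.chrom]
    seq = "".join(chrom[s:e] for s, e in t.exons)
    return reverse_complement(seq) if t.strand == "-" else seq


def read_probe_table(stream: IO[str] | Iterable[str]) -> list[ProbeRecord]:
    """Read the probe TSV (header: probe_id, probeset_id, gene, sequence)."""
    probes: list[ProbeRecord] = []
    seen: set[str] = set()
    header_skipped = False
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if not header_skipped:
            header_skipped = True
            if fields[0].lower() in ("probe_id", "probe"):
                continue
        if len(fields) != 4:
            raise ValueError(f"probe table line {lineno}: expected 4 fields")
        probe_id, probeset_id, gene, seq = fields
        if probe_id in seen:
            raise ValueError(f"probe table line {lineno}: duplicate probe_id {probe_id}")
        seen.add(probe_id)
        probes.append(ProbeRecord(probe_id, probeset_id, gene, seq.upper()))
    return probes


def write_probe_table(probes: Iterable[ProbeRecord], stream: IO[str]) -> None:
    stream.write("probe_id\tprobeset_id\tgene\tsequence\n")
    for p in probes:
        stream.write(f"{p.probe_id}\t{p.probeset_id}\t{p.declared_gene}\t{p.sequence}\n")


def _build_kmer_index(
    spliced: dict[str, str], k: int
) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for acc, seq in spliced.items():
        for i in range(len(seq) - k + 1):
            index[seq[i : i + k]].append((acc, i))
    return index


def match_probes(
    probes: list[ProbeRecord],
    transcripts: list[TranscriptRecord],
    genome: GenomeSequence,
    sense_mode: SenseMode = "both",
) -> list[ProbeHitReport]:
    """Match every probe exactly against every spliced transcript.

    ``sense_mode`` controls which orientation(s) of the probe are searched:
    array probes are antisense to the mRNA, but the default ``both`` makes
    the matcher annotation-agnostic.  Probes containing non-ACGT characters
    are skipped with a warning (their report is absent from the output).
    """
    spliced = {t.accession: spliced_sequence(t, genome) for t in transcripts}
    coding = {t.accession: t.coding for t in transcripts}

    by_len: dict[int, list[ProbeRecord]] = defaultdict(list)
    reports: list[ProbeHitReport] = []
    for p in probes:
        if set(p.sequence) - set("ACGT"):
            log.warning("probe %s contains non-ACGT characters; skipped", p.probe_id)
            continue
        by_len[len(p.sequence)].append(p)

    for k, group in sorted(by_len.items()):
        index = _build_kmer_index(spliced, k)
        for p in group:
            queries = []
            if sense_mode in ("sense", "both"):
                queries.append(p.sequence)
            if sense_mode in ("antisense", "both"):
                rc = reverse_complement(p.sequence)
                if rc != p.sequence or sense_mode == "antisense":
                    queries.append(rc)
            report = ProbeHitReport(probe_id=p.probe_id)
            for q in queries:
                for acc, off in index.get(q, ()):
                    report.hits.add((acc, off))
                    if coding[acc]:
                        report.hit_coding = True
                    else:
                        report.hit_noncoding = True
            reports.append(report)
    # restore the input probe order (index building groups by length)
    order = {p.probe_id: i for i, p in enumerate(probes)}
    reports.sort(key=lambda r: order[r.probe_id])
    return reports


def match_probes_naive(
    probes: list[ProbeRecord],
    transcripts: list[TranscriptRecord],
    genome: GenomeSequence,
    sense_mode: SenseMode = "both",
) -> list[ProbeHitReport]:
    """Reference matcher: direct scan of every (probe, transcript, offset).

    Quadratic; used as the correctness oracle for :func:`match_probes`.
    """
    spliced = {t.accession: spliced_sequence(t, genome) for t in transcripts}
    coding = {t.accession: t.coding for t in transcripts}
    reports = []
    for p in probes:
        if set(p.sequence) - set("ACGT"):
            continue
        queries = {p.sequence} if sense_mode == "sense" else (
            {reverse_complement(p.sequence)} if sense_mode == "antisense"
            else {p.sequence, reverse_complement(p.sequence)}
        )
        report = ProbeHitReport(probe_id=p.probe_id)
        for acc, seq in spliced.items():
            for q in queries:
                for off in range(len(seq) - len(q) + 1):
                    if seq[off : off + len(q)] == q:
                        report.hits.add((acc, off))
                        if coding[acc]:
                            report.hit_coding = True
                        else:
                            report.hit_noncoding = True
        reports.append(report)
    return reports


@dataclass
class DiscriminabilitySummary:
    n_bifunctional_genes_probed: int
    n_probes_on_bifunctional: int
    n_ambiguous_probes: int
    percent_ambiguous: float
    n_genes_any_ambiguous: int
    n_genes_all_ambiguous: int
    n_probes_no_hit: int


def gene_discriminability(
    reports: list[ProbeHitReport],
    partition: list[LocusPartition],
    transcripts: list[TranscriptRecord],
    probes: list[ProbeRecord] | None = None,
    gene_assignment: Literal["declared", "by_hit"] = "by_hit",
) -> tuple[list[GeneDiscriminability], DiscriminabilitySummary]:
    """Per-gene probe tallies and the array-level ambiguity headline.

    The headline counts probes hitting bifunctional loci and the fraction of
    those that are ambiguous; no-hit probes are excluded from the
    denominator and counted separately.  ``gene_assignment`` chooses between
    the probe table's declared gene and the gene(s) of the hit transcripts
    (a probe hitting several genes is tallied once per gene and flagged).
    """
    gene_of = {t.accession: t.gene_symbol for t in transcripts}
    klass = {p.gene_symbol: p.klass for p in partition}
    declared = {p.probe_id: p.declared_gene for p in probes} if probes else {}

    tallies: dict[str, list[int]] = {}  # gene -> [n_probes, n_ambiguous]
    n_no_hit = n_probes_bif = n_ambig = 0
    genes_probed: set[str] = set()
    for r in reports:
        if r.verdict is Verdict.NO_HIT:
            n_no_hit += 1
            continue
        if gene_assignment == "declared":
            genes = {declared.get(r.probe_id, "")} - {""}
        else:
            genes = {gene_of[acc] for acc, _ in r.hits}
            if len(genes) > 1:
                log.info("probe %s hits %d genes", r.probe_id, len(genes))
        for g in genes:
            t = tallies.setdefault(g, [0, 0])
            t[0] += 1
            ambiguous = r.verdict is Verdict.AMBIGUOUS
            t[1] += ambiguous
            if klass.get(g) is LocusClass.BIFUNCTIONAL:
                genes_probed.add(g)
        # probe-level headline counts a probe once if any hit gene is bifunctional
        if any(klass.get(g) is LocusClass.BIFUNCTIONAL for g in genes):
            n_probes_bif += 1
            n_ambig += r.verdict is Verdict.AMBIGUOUS

    rows = [
        GeneDiscriminability(g, n, a) for g, (n, a) in sorted(tallies.items())
    ]
    percent = round_half_up(100.0 * n_ambig / n_probes_bif) if n_probes_bif else 0.0
    summary = DiscriminabilitySummary(
        n_bifunctional_genes_probed=len(genes_probed),
        n_probes_on_bifunctional=n_probes_bif,
        n_ambiguous_probes=n_ambig,
        percent_ambiguous=percent,
        n_genes_any_ambiguous=sum(r.any_ambiguous for r in rows),
        n_genes_all_ambiguous=sum(r.all_ambiguous for r in rows),
        n_probes_no_hit=n_no_hit,
    )
    return rows, summary


def write_verdicts_tsv(reports: list[ProbeHitReport], stream: IO[str]) -> None:
    stream.write("probe_id\tn_hits\thit_coding\thit_noncoding\tverdict\n")
    for r in reports:
        stream.write(
            f"{r.probe_id}\t{len(r.hits)}\t{int(r.hit_coding)}"
            f"\t{int(r.hit_noncoding)}\t{r.verdict.value}\n"
        )
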