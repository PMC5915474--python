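"""Synthetic genome / annotation / array / expression / gene-set generator.

Emits the five inputs the pipeline consumes — genome FASTA, refFlat
annotation, probe table, expression matrix, GMT library — with full ground
truth, so that every stage (locus census, probe discriminability, rank
test, enrichment) can be verified without any external download.

Bifunctional loci are realised as alternative-isoform structures: a run of
shared exons plus one exon unique to the coding (NM_) isoform and one
unique to the non-coding (NR_) isoform.  Probes are 25-mers cut from the
spliced isoform sequences, placed either wholly inside a shared exon
(intended ambiguous) or inside an isoform-specific exon (intended
specific).  Expression values are log-scale intensities with equal means
for coding- and non-coding-specific probe groups unless a shift delta is
planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .annotation_io import (
    GenomeSequence,
    TranscriptRecord,
    read_fasta,
    read_genepred,
    write_fasta,
    write_genepred,
)
from .enrichment import GeneSetLibrary, write_gmt
from .locus_partition import LocusClass, partition_loci
from .probe_mapping import (
    ProbeRecord,
    Verdict,
    gene_discriminability,
    match_probes,
    read_probe_table,
    spliced_sequence,
    write_probe_table,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator.

    Defaults mirror the real-data setting the pipeline emulates: a
    bifunctional-locus fraction of 9.2%, 11 probes per gene (one array
    probe set), 25-nt probes, two thirds of bifunctional-gene probes on
    shared exons, 60 samples, and no coding/non-coding expression shift.
    """

    n_genes: int = 2000
    frac_bifunctional: float = 0.092
    frac_coding_only: float = 0.602
    frac_noncoding_only: float = 0.306
    # isoform counts per locus class (inclusive ranges)
    coding_isoforms: tuple[int, int] = (1, 2)
    noncoding_isoforms: tuple[int, int] = (1, 2)
    # gene architecture
    n_shared_exons: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (80, 160)
    intron_length: tuple[int, int] = (60, 140)
    # array
    probe_length: int = 25
    probes_per_gene: int = 11
    frac_probes_on_shared_exons: float = 0.667
    # expression
    n_samples: int = 60
    expr_gene_mean: float = 7.0
    expr_gene_sd: float = 1.0
    expr_noise_sd: float = 0.5
    delta: float = 0.0  # planted coding-minus-noncoding shift, log-scale units
    # gene-set library
    n_gene_sets: int = 20
    gene_set_size: tuple[int, int] = (5, 30)
    genes_per_chrom: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.frac_bifunctional, self.frac_coding_only, self.frac_noncoding_only)
        if any(f < 0 or f > 1 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("class fractions must lie in [0,1] and sum to 1")
        if self.n_genes < 1 or self.probes_per_gene < 0 or self.n_samples < 1:
            raise ValueError("counts must be positive")
        if self.exon_length[0] < self.probe_length:
            raise ValueError("exons must be at least one probe long")
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")


@dataclass
class ProbeTruth:
    gene: str
    intended_verdict: Verdict
    isoform: str   # transcript whose spliced sequence the probe was cut from
    offset: int    # offset of the probe within that spliced sequence


@dataclass
class GroundTruth:
    gene_class: dict[str, LocusClass]
    transcript_coding: dict[str, bool]
    probes: dict[str, ProbeTruth]

    def expression_groups(self) -> tuple[list[str], list[str]]:
        """Probe ids of all-coding-specific vs all-noncoding-specific
        bifunctional genes (the default expression selection rule)."""
        by_gene: dict[str, list[tuple[str, Verdict]]] = {}
        for pid, t in self.probes.items():
            by_gene.setdefault(t.gene, []).append((pid, t.intended_verdict))
        a, b = [], []
        for g, items in by_gene.items():
            if self.gene_class[g] is not LocusClass.BIFUNCTIONAL:
                continue
            verdicts = {v for _, v in items}
            if verdicts == {Verdict.CODING_SPECIFIC}:
                a += [pid for pid, _ in items]
            elif verdicts == {Verdict.NONCODING_SPECIFIC}:
                b += [pid for pid, _ in items]
        return sorted(a), sorted(b)


@dataclass
class SynthBundle:
    config: SynthConfig
    genome: GenomeSequence
    transcripts: list[TranscriptRecord]
    probes: list[ProbeRecord]
    expression: pd.DataFrame
    library: GeneSetLibrary
    truth: GroundTruth


@dataclass
class _Locus:
    gene: str
    klass: LocusClass
    chrom: str
    strand: str
    transcripts: list[TranscriptRecord]
    shared_exons: list[tuple[int, int]]
    coding_exon: tuple[int, int] | None
    noncoding_exon: tuple[int, int] | None


def _rint(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def _gene_classes(cfg: SynthConfig, rng: np.random.Generator) -> list[LocusClass]:
    """Per-gene class by independent draws from the class fractions."""
    classes = rng.choice(
        np.array([LocusClass.BIFUNCTIONAL, LocusClass.CODING_ONLY,
                  LocusClass.NONCODING_ONLY], dtype=object),
        size=cfg.n_genes,
        p=[cfg.frac_bifunctional, cfg.frac_coding_only, cfg.frac_noncoding_only],
    )
    return list(classes)


def _build_locus(
    gene: str, klass: LocusClass, chrom: str, offset: int,
    cfg: SynthConfig, rng: np.random.Generator,
) -> tuple[_Locus, int]:
    """Lay the locus's exons on the chromosome starting at ``offset``.

    Bifunctional layout interleaves one coding-specific and one
    noncoding-specific exon among the shared exons, so the NM_ and NR_
    isoforms differ in internal structure but share flanking exons.
    Returns the locus and the next free genomic position.
    """
    strand = "+" if rng.random() < 0.5 else "-"
    n_shared = _rint(rng, cfg.n_shared_exons)

    def next_exon(pos: int) -> tuple[tuple[int, int], int]:
        pos += _rint(rng, cfg.intron_length)
        length = _rint(rng, cfg.exon_length)
        return (pos, pos + length), pos + length

    pos = offset
    shared: list[tuple[int, int]] = []
    coding_exon = noncoding_exon = None
    if klass is LocusClass.BIFUNCTIONAL:
        # genomic order: S1 [C] S2..  [N] S_last  (specific exons internal)
        first, pos = next_exon(pos)
        coding_exon, pos = next_exon(pos)
        mid = []
        for _ in range(max(0, n_shared - 2)):
            e, pos = next_exon(pos)
            mid.append(e)
        noncoding_exon, pos = next_exon(pos)
        last, pos = next_exon(pos)
        shared = [first, *mid, last]
    else:
        for _ in range(max(2, n_shared)):
            e, pos = next_exon(pos)
            shared.append(e)

    transcripts: list[TranscriptRecord] = []

    def mk(accession: str, exons: list[tuple[int, int]], coding: bool) -> TranscriptRecord:
        exons = sorted(exons)
        cds = None
        if coding:
            # CDS trimmed inside the first and last exon to leave UTRs
            cds = (exons[0][0] + 5, exons[-1][1] - 5)
        return TranscriptRecord(
            accession=accession, gene_symbol=gene, chrom=chrom, strand=strand,
            exons=tuple(exons), cds=cds, coding=coding,
        )

    serial = int("".join(ch for ch in gene if ch.isdigit()) or "0")
    if klass is LocusClass.BIFUNCTIONAL:
        n_nm = _rint(rng, cfg.coding_isoforms)
        n_nr = _rint(rng, cfg.noncoding_isoforms)
        nm_exons = [*shared, coding_exon]
        nr_exons = [*shared, noncoding_exon]
        for i in range(n_nm):
            ex = nm_exons if i == 0 or len(shared) < 3 else nm_exons[:-2] + [nm_exons[-1]]
            transcripts.append(mk(f"NM_{serial}{i}.1", ex, True))
        for i in range(n_nr):
            ex = nr_exons if i == 0 or len(shared) < 3 else nr_exons[:-2] + [nr_exons[-1]]
            transcripts.append(mk(f"NR_{serial}{i}.1", ex, False))
    elif klass is LocusClass.CODING_ONLY:
        for i in range(_rint(rng, cfg.coding_isoforms)):
            ex = shared if i == 0 or len(shared) < 3 else shared[:1] + shared[2:]
            transcripts.append(mk(f"NM_{serial}{i}.1", ex, True))
    else:
        for i in range(_rint(rng, cfg.noncoding_isoforms)):
            ex = shared if i == 0 or len(shared) < 3 else shared[:1] + shared[2:]
            transcripts.append(mk(f"NR_{serial}{i}.1", ex, False))

    locus = _Locus(gene, klass, chrom, strand, transcripts, shared,
                   coding_exon, noncoding_exon)
    return locus, pos + _rint(rng, cfg.intron_length)


def generate_models(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[list[_Locus], dict[str, int]]:
    """Gene models only (no sequence): loci plus chromosome lengths.

    This is the cheap path used for large-scale census simulations; the
    full :func:`generate` builds on it.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    classes = _gene_classes(cfg, rng)
    loci: list[_Locus] = []
    chrom_len: dict[str, int] = {}
    width = len(str(cfg.n_genes))
    pos, chrom = 0, None
    for i, klass in enumerate(classes):
        if i % cfg.genes_per_chrom == 0:
            if chrom is not None:
                chrom_len[chrom] = pos + 50
            chrom = f"chr{i // cfg.genes_per_chrom + 1}"
            pos = 0
        gene = f"G{i + 1:0{width}d}"
        locus, pos = _build_locus(gene, klass, chrom, pos, cfg, rng)
        loci.append(locus)
    chrom_len[chrom] = pos + 50
    return loci, chrom_len


def _tx_intervals(t: TranscriptRecord) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """(genomic exon, transcript-coordinate interval) pairs in transcript order."""
    exons = list(t.exons) if t.strand == "+" else list(t.exons)[::-1]
    out, pos = [], 0
    for ex in exons:
        length = ex[1] - ex[0]
        out.append((ex, (pos, pos + length)))
        pos += length
    return out


def _place_probes(
    loci: list[_Locus], genome: GenomeSequence,
    cfg: SynthConfig, rng: np.random.Generator,
) -> tuple[list[ProbeRecord], dict[str, ProbeTruth]]:
    probes: list[ProbeRecord] = []
    truth: dict[str, ProbeTruth] = {}
    L = cfg.probe_length
    for locus in loci:
        spliced = {t.accession: spliced_sequence(t, genome) for t in locus.transcripts}
        probeset = f"{locus.gene}_at"
        for j in range(cfg.probes_per_gene):
            pid = f"{locus.gene}:{j + 1}"
            if locus.klass is LocusClass.BIFUNCTIONAL:
                on_shared = rng.random() < cfg.frac_probes_on_shared_exons
                if on_shared:
                    target_exons = locus.shared_exons
                    verdict = Verdict.AMBIGUOUS
                    iso = locus.transcripts[0]  # the NM_ isoform carries the shared exon too
                elif rng.random() < 0.5:
                    target_exons = [locus.coding_exon]
                    verdict = Verdict.CODING_SPECIFIC
                    iso = next(t for t in locus.transcripts if t.coding)
                else:
                    target_exons = [locus.noncoding_exon]
                    verdict = Verdict.NONCODING_SPECIFIC
                    iso = next(t for t in locus.transcripts if not t.coding)
            else:
                iso = locus.transcripts[0]
                target_exons = list(iso.exons)
                verdict = (Verdict.CODING_SPECIFIC if iso.coding
                           else Verdict.NONCODING_SPECIFIC)
            # pick an exon long enough, then a window wholly inside it
            candidates = [e for e in target_exons if e[1] - e[0] >= L]
            exon = candidates[int(rng.integers(len(candidates)))]
            tx_iv = dict(_tx_intervals(iso))[exon]
            off = int(rng.integers(tx_iv[0], tx_iv[1] - L + 1))
            seq = spliced[iso.accession][off : off + L]
            probes.append(ProbeRecord(pid, probeset, locus.gene, seq))
            truth[pid] = ProbeTruth(locus.gene, verdict, iso.accession, off)
    return probes, truth


def _expression_matrix(
    probes: list[ProbeRecord], truth: dict[str, ProbeTruth],
    cfg: SynthConfig, rng: np.random.Generator,
) -> pd.DataFrame:
    genes = sorted({t.gene for t in truth.values()})
    gene_mu = {
        g: cfg.expr_gene_mean + cfg.expr_gene_sd * rng.standard_normal()
        for g in genes
    }
    shift = {
        Verdict.CODING_SPECIFIC: +cfg.delta / 2.0,
        Verdict.NONCODING_SPECIFIC: -cfg.delta / 2.0,
        Verdict.AMBIGUOUS: 0.0,
    }
    rows = np.empty((len(probes), cfg.n_samples))
    for i, p in enumerate(probes):
        t = truth[p.probe_id]
        mu = gene_mu[t.gene] + shift[t.intended_verdict]
        rows[i] = mu + cfg.expr_noise_sd * rng.standard_normal(cfg.n_samples)
    samples = [f"S{j + 1:02d}" for j in range(cfg.n_samples)]
    return pd.DataFrame(rows.round(4), index=[p.probe_id for p in probes],
                        columns=samples)


def _gene_set_library(
    loci: list[_Locus], cfg: SynthConfig, rng: np.random.Generator
) -> GeneSetLibrary:
    universe = sorted(l.gene for l in loci)
    sets = {}
    for i in range(cfg.n_gene_sets):
        size = min(_rint(rng, cfg.gene_set_size), len(universe))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"SET{i + 1:03d}"] = frozenset(members)
    return GeneSetLibrary(sets=sets, universe=frozenset(universe))


def generate(cfg: SynthConfig) -> SynthBundle:
    """Generate the full synthetic study; reproducible from ``rng_seed``."""
    rng = np.random.default_rng(cfg.rng_seed)
    loci, chrom_len = generate_models(cfg, rng)
    genome = GenomeSequence({
        name: "".join(rng.choice(_BASES, size=length))
        for name, length in chrom_len.items()
    })
    probes, probe_truth = _place_probes(loci, genome, cfg, rng)
    expression = _expression_matrix(probes, probe_truth, cfg, rng)
    library = _gene_set_library(loci, cfg, rng)
    transcripts = [t for l in loci for t in l.transcripts]
    truth = GroundTruth(
        gene_class={l.gene: l.klass for l in loci},
        transcript_coding={t.accession: t.coding for t in transcripts},
        probes=probe_truth,
    )
    return SynthBundle(cfg, genome, transcripts, probes, expression, library, truth)


def write_bundle(bundle: SynthBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write genome.fa, annotation.refFlat, probes.tsv, expression.tsv,
    library.gmt into ``out_dir``; returns the path of each."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "annotation": out / "annotation.refFlat",
        "probes": out / "probes.tsv",
        "expression": out / "expression.tsv",
        "library": out / "library.gmt",
    }
    with open(paths["genome"], "w") as fh:
        write_fasta(bundle.genome, fh)
    with open(paths["annotation"], "w") as fh:
        write_genepred(bundle.transcripts, fh)
    with open(paths["probes"], "w") as fh:
        write_probe_table(bundle.probes, fh)
    bundle.expression.to_csv(paths["expression"], sep="\t", index_label="probe_id")
    with open(paths["library"], "w") as fh:
        write_gmt(bundle.library, fh)
    return paths


@dataclass
class VerifyReport:
    n_genes_checked: int
    n_probes_checked: int
    mismatches: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.mismatches


def verify(paths: dict[str, Path], truth: GroundTruth) -> VerifyReport:
    """Re-run the pipeline on freshly written files and compare against truth.

    Checks locus classes from the annotation and per-probe verdicts from
    sequence matching; every mismatch is enumerated in the report.
    """
    with open(paths["annotation"]) as fh:
        transcripts = read_genepred(fh)
    with open(paths["genome"]) as fh:
        genome = read_fasta(fh)
    with open(paths["probes"]) as fh:
        probes = read_probe_table(fh)

    report = VerifyReport(n_genes_checked=0, n_probes_checked=0)
    partition = partition_loci(transcripts)
    for p in partition:
        report.n_genes_checked += 1
        want = truth.gene_class.get(p.gene_symbol)
        if want is None:
            report.mismatches.append(f"unexpected gene {p.gene_symbol}")
        elif p.klass is not want:
            report.mismatches.append(
                f"gene {p.gene_symbol}: recovered {p.klass.value}, truth {want.value}"
            )
    seen = {p.gene_symbol for p in partition}
    for g in sorted(set(truth.gene_class) - seen):
        report.mismatches.append(f"gene {g} missing from partition")

    reports = match_probes(probes, transcripts, genome, sense_mode="both")
    for r in reports:
        report.n_probes_checked += 1
        want = truth.probes[r.probe_id].intended_verdict
        if r.verdict is not want:
            report.mismatches.append(
                f"probe {r.probe_id}: recovered {r.verdict.value}, truth {want.value}"
            )
    return report


def constructed_ambiguous_percent(truth: GroundTruth) -> float:
    """Percent of bifunctional-gene probes the generator placed on shared
    exons — the ground-truth counterpart of the matcher's headline."""
    on_bif = [
        t for t in truth.probes.values()
        if truth.gene_class[t.gene] is LocusClass.BIFUNCTIONAL
    ]
    if not on_bif:
        return 0.0
    n_amb = sum(t.intended_verdict is Verdict.AMBIGUOUS for t in on_bif)
    from .locus_partition import round_half_up

    return round_half_up(100.0 * n_amb / len(on_bif))
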