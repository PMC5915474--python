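"""Gene-set overrepresentation against a GMT library.

The statistic is the one-sided hypergeometric upper tail (Fisher-exact
enrichment): for a query of n genes drawn from a universe of N, the
probability of observing at least k members of a set of size m,

    p = sum_{i=k}^{min(m,n)} C(m,i) C(N-m, n-i) / C(N,n),

accumulated in log space for numerical stability, with Benjamini-Hochberg
adjustment across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


class GmtError(ValueError):
    """Malformed GMT input."""


@dataclass
class GeneSetLibrary:
    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise GmtError(f"set {name!r} is empty")
            extra = genes - self.universe
            if extra:
                raise GmtError(f"set {name!r} has genes outside the universe: {sorted(extra)[:5]}")


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    universe_size: int  # N
    set_size: int       # m
    query_size: int     # n
    overlap: int        # k
    p_hyper: float
    q_bh: float


def read_gmt(stream: IO[str] | Iterable[str],
             universe: Iterable[str] | None = None) -> GeneSetLibrary:
    """Read a GMT library (set name, description, tab-separated genes).

    Gene symbols are upper-cased and deduplicated within each set.  The
    universe defaults to the union of all library genes; an explicit
    universe must cover every set.
    """
    sets: dict[str, frozenset[str]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise GmtError(f"line {lineno}: GMT line needs name, description, >=1 gene")
        name = fields[0]
        if name in sets:
            raise GmtError(f"line {lineno}: duplicate set name {name!r}")
        genes = frozenset(g.upper() for g in fields[2:] if g)
        if not genes:
            raise GmtError(f"line {lineno}: set {name!r} has no genes")
        sets[name] = genes
    if not sets:
        raise GmtError("empty GMT")
    if universe is None:
        uni = frozenset().union(*sets.values())
    else:
        uni = frozenset(g.upper() for g in universe)
    return GeneSetLibrary(sets=sets, universe=uni)


def write_gmt(library: GeneSetLibrary, stream: IO[str]) -> None:
    for name, genes in library.sets.items():
        stream.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def _log_hyper_pmf(i: np.ndarray, N: int, m: int, n: int) -> np.ndarray:
    """log C(m,i) + log C(N-m, n-i) - log C(N,n) via log-gamma."""

    def lchoose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return lchoose(m, i) + lchoose(N - m, n - i) - lchoose(N, n)


def hypergeom_upper_tail(k: int, N: int, m: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, m, n), summed in log space."""
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError("require 0 <= m, n <= N")
    hi = min(m, n)
    lo_support = max(0, m + n - N)
    if k <= lo_support:
        return 1.0
    if k > hi:
        return 0.0
    i = np.arange(k, hi + 1)
    return float(np.exp(logsumexp(_log_hyper_pmf(i, N, m, n))))


def enrich(query: Iterable[str], library: GeneSetLibrary) -> list[EnrichmentRow]:
    """Overrepresentation of the query in every library set, sorted by p.

    Query genes outside the universe are dropped with a logged count; a
    query disjoint from the universe is an error.  Ties in p are broken by
    set name so output order is deterministic.
    """
    q = {g.upper() for g in query}
    dropped = q - library.universe
    if dropped:
        log.info("dropped %d query genes outside the universe", len(dropped))
    q &= library.universe
    if not q:
        raise ValueError("query has no genes in the universe")
    N, n = len(library.universe), len(q)
    names = sorted(library.sets)
    ps, ks, ms = [], [], []
    for name in names:
        genes = library.sets[name]
        m, k = len(genes), len(genes & q)
        ps.append(hypergeom_upper_tail(k, N, m, n))
        ks.append(k)
        ms.append(m)
    qs = multipletests(ps, method="fdr_bh")[1]
    rows = [
        EnrichmentRow(name, N, m, n, k, p, float(qv))
        for name, m, k, p, qv in zip(names, ms, ks, ps, qs)
    ]
    rows.sort(key=lambda r: (r.p_hyper, r.set_name))
    return rows


def write_enrichment_tsv(rows: list[EnrichmentRow], stream: IO[str]) -> None:
    stream.write("set\tN\tm\tn\tk\tp\tq\n")
    for r in rows:
        stream.write(
            f"{r.set_name}\t{r.universe_size}\t{r.set_size}\t{r.query_size}"
            f"\t{r.overlap}\t{r.p_hyper:.6g}\t{r.q_bh:.6g}\n"
        )
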