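"""Expression comparison of coding- vs non-coding-specific probes.

The core statistic is a Wilcoxon–Mann–Whitney rank-sum test implemented
here from first principles: the U statistic from midranks, an exact p-value
by complete enumeration of group labelings when that is feasible, and
otherwise a tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb, erfc, sqrt
from typing import IO, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .locus_partition import LocusClass, LocusPartition
from .probe_mapping import ProbeHitReport, Verdict

log = logging.getLogger(__name__)

EXACT_ENUMERATION_CAP = 200_000  # max C(N, n1) for the exact method


@dataclass(frozen=True)
class RankTestResult:
    n1: int
    n2: int
    U: float
    z: float
    p_two_sided: float
    method: Literal["exact", "normal_approx"]
    degenerate: bool = False


def read_expression_tsv(stream: IO[str]) -> pd.DataFrame:
    """Expression matrix: first column row ids, header of sample names.

    Rows with no finite value are dropped; duplicate row or column ids are
    errors.
    """
    df = pd.read_csv(stream, sep="\t", index_col=0, na_values=["NA", ""])
    if df.index.has_duplicates:
        raise ValueError("duplicate row ids in expression matrix")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample names in expression matrix")
    all_na = df.isna().all(axis=1)
    if all_na.any():
        log.info("dropping %d all-NA expression rows", int(all_na.sum()))
        df = df.loc[~all_na]
    return df


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return rankdata(pooled, method="average")


def _u_from_ranks(ranks1: np.ndarray, n1: int, n2: int) -> float:
    r1 = float(ranks1.sum())
    return r1 - n1 * (n1 + 1) / 2.0


def _tie_corrected_variance(pooled: np.ndarray, n1: int, n2: int) -> float:
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    return n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    exact_cap: int = EXACT_ENUMERATION_CAP,
) -> RankTestResult:
    """Two-sided Wilcoxon–Mann–Whitney test.

    U is computed from midranks of the pooled sample.  When
    ``C(n1+n2, n1) <= exact_cap`` the p-value is exact: every assignment of
    pooled values to the first group is enumerated and the two-sided p is
    ``min(1, 2 * min(P(U' <= U), P(U' >= U)))``.  Otherwise a normal
    approximation with tie-corrected variance

        Var(U) = n1 n2 / 12 * [(N+1) - sum(t^3 - t) / (N (N-1))]

    and a 0.5 continuity correction is used.  All values tied across both
    groups yield p = 1 with ``degenerate=True``.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u = _u_from_ranks(ranks[:n1], n1, n2)

    if np.unique(pooled).size == 1:
        return RankTestResult(n1, n2, u, 0.0, 1.0, "normal_approx", degenerate=True)

    if comb(n1 + n2, n1) <= exact_cap:
        lo, hi = _exact_tails(ranks, n1, u)
        p = min(1.0, 2.0 * min(lo, hi))
        return RankTestResult(n1, n2, u, float("nan"), p, "exact")

    var = _tie_corrected_variance(pooled, n1, n2)
    mean = n1 * n2 / 2.0
    diff = u - mean
    # continuity correction shrinks |diff| by 0.5
    cc = 0.5 if diff != 0 else 0.0
    z = (diff - np.sign(diff) * cc) / sqrt(var)
    p = min(1.0, erfc(abs(z) / sqrt(2.0)))
    return RankTestResult(n1, n2, u, float(z), p, "normal_approx")


def _exact_tails(ranks: np.ndarray, n1: int, u_obs: float) -> tuple[float, float]:
    """P(U <= u_obs) and P(U >= u_obs) over all C(N, n1) group assignments."""
    n = ranks.size
    offset = n1 * (n1 + 1) / 2.0
    total = comb(n, n1)
    le = ge = 0
    eps = 1e-9
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if u <= u_obs + eps:
            le += 1
        if u >= u_obs - eps:
            ge += 1
    return le / total, ge / total


@dataclass(frozen=True)
class FiveNumberSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    lower_fence: float
    upper_fence: float
    outliers: tuple[float, ...]


def boxplot_summary(v: Sequence[float]) -> FiveNumberSummary:
    """Tukey five-number summary with 1.5*IQR fences.

    Quartiles use linear interpolation between order statistics (the
    convention matplotlib and R's default quantile share).
    """
    x = np.asarray(v, dtype=float)
    if x.size < 1:
        raise ValueError("empty vector")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = tuple(float(o) for o in np.sort(x[(x < lo) | (x > hi)]))
    return FiveNumberSummary(
        float(x.min()), float(q1), float(med), float(q3), float(x.max()),
        float(lo), float(hi), outliers,
    )


def select_groups(
    matrix: pd.DataFrame,
    reports: list[ProbeHitReport],
    partition: list[LocusPartition],
    probe_gene: dict[str, str],
    rule: Literal["exclusive_within_bifunctional", "locus_class"] =
        "exclusive_within_bifunctional",
    reduce: Literal["median", "mean", "none"] = "median",
) -> tuple[np.ndarray, np.ndarray]:
    """Build the two expression vectors for the coding vs non-coding test.

    Default rule: among bifunctional loci, take genes whose probes are all
    coding-specific (group A) or all non-coding-specific (group B); each
    probe contributes its across-sample median (``reduce``).  The
    alternative ``locus_class`` rule takes probes of plain coding-only vs
    non-coding-only loci.  Probes absent from the matrix are dropped with a
    logged count.
    """
    klass = {p.gene_symbol: p.klass for p in partition}
    by_gene: dict[str, list[ProbeHitReport]] = {}
    for r in reports:
        if r.verdict is Verdict.NO_HIT:
            continue
        g = probe_gene.get(r.probe_id)
        if g:
            by_gene.setdefault(g, []).append(r)

    probes_a: list[str] = []
    probes_b: list[str] = []
    if rule == "exclusive_within_bifunctional":
        for g, rs in by_gene.items():
            if klass.get(g) is not LocusClass.BIFUNCTIONAL:
                continue
            verdicts = {r.verdict for r in rs}
            if verdicts == {Verdict.CODING_SPECIFIC}:
                probes_a += [r.probe_id for r in rs]
            elif verdicts == {Verdict.NONCODING_SPECIFIC}:
                probes_b += [r.probe_id for r in rs]
    else:
        for g, rs in by_gene.items():
            if klass.get(g) is LocusClass.CODING_ONLY:
                probes_a += [r.probe_id for r in rs]
            elif klass.get(g) is LocusClass.NONCODING_ONLY:
                probes_b += [r.probe_id for r in rs]

    def values(ids: list[str]) -> np.ndarray:
        present = [i for i in ids if i in matrix.index]
        if len(present) < len(ids):
            log.info("dropped %d probes absent from matrix", len(ids) - len(present))
        sub = matrix.loc[present]
        if reduce == "median":
            out = sub.median(axis=1, skipna=True).to_numpy()
        elif reduce == "mean":
            out = sub.mean(axis=1, skipna=True).to_numpy()
        else:
            out = sub.to_numpy().ravel()
        return out[np.isfinite(out)]

    va, vb = values(probes_a), values(probes_b)
    if va.size == 0 or vb.size == 0:
        raise ValueError(
            "one selection group is empty; relax the selection rule "
            "(try rule='locus_class') or check probe/gene assignments"
        )
    return va, vb


def write_rank_test_json(result: RankTestResult, stream: IO[str]) -> None:
    import json

    z = None if result.method == "exact" else result.z
    json.dump(
        {
            "n1": result.n1, "n2": result.n2, "U": result.U, "z": z,
            "p_two_sided": result.p_two_sided, "method": result.method,
            "degenerate": result.degenerate,
        },
        stream, indent=2,
    )
    stream.write("\n")
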