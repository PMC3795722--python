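"""Diploid genotype calling and cohort statistics.

Per-fibre repeat counts from integrity-gated fibres are clustered into at
most two alleles per individual; genotypes aggregate into an allele table
(occurrences and frequencies over the flagged unrelated chromosomes),
observed heterozygosity, and distance summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import NoCallError, Rnu2CombError

logger = logging.getLogger(__name__)


@dataclass
class Genotype:
    individual_id: str
    allele_low: int
    allele_high: int
    support_low: int
    support_high: int
    heterozygous: bool
    confidence_note: str = ""


@dataclass
class AlleleTable:
    rows: list[tuple[int, int, float]]   # (repeat_units, occurrences, freq)
    chromosomes: int
    distinct_alleles: int


def _clusters(counts: Sequence[int], merge_tol: int) -> list[list[int]]:
    """Single-linkage clusters of integer counts (linkage <= merge_tol)."""
    out: list[list[int]] = []
    for c in sorted(counts):
        if out and c - out[-1][-1] <= merge_tol:
            out[-1].append(c)
        else:
            out.append([c])
    return out


def _representative(cluster: Sequence[int]) -> int:
    """Cluster representative: median, ties broken to the lower value."""
    s = sorted(cluster)
    return s[(len(s) - 1) // 2]


def call_genotype(counts: Sequence[int], individual_id: str = "",
                  min_support: int = 2, merge_tol: int = 1,
                  low_coverage_note_below: int = 6) -> Genotype:
    """Call a diploid genotype from per-fibre repeat counts.

    Counts must come from integrity-full fibres.  Single-linkage clusters
    (within ``merge_tol`` copies) are ranked by support; a second allele is
    called iff the runner-up cluster has support >= ``min_support`` and its
    representative differs from the leader's by more than ``merge_tol``.
    """
    counts = [int(c) for c in counts]
    if len(counts) < min_support:
        raise NoCallError(
            f"{individual_id or 'individual'}: {len(counts)} fibre counts "
            f"< min_support {min_support}")
    clusters = _clusters(counts, merge_tol)
    # rank by support, then by lower representative for determinism
    ranked = sorted(clusters, key=lambda cl: (-len(cl), _representative(cl)))
    top = ranked[0]
    second = None
    for cl in ranked[1:]:
        if (len(cl) >= min_support
                and abs(_representative(cl) - _representative(top)) > merge_tol):
            second = cl
            break
    note = ""
    if second is None:
        if len(counts) < low_coverage_note_below:
            note = ("single cluster from few intact fibres; a second allele "
                    "may have been missed")
        a = _representative(top)
        return Genotype(individual_id, a, a, len(top), len(top), False, note)
    a, b = _representative(top), _representative(second)
    sa, sb = len(top), len(second)
    if a > b:
        a, b, sa, sb = b, a, sb, sa
    return Genotype(individual_id, a, b, sa, sb, True, note)


def genotype_cohort(calls, min_support: int = 2, merge_tol: int = 1):
    """Group countable fibre calls by individual and call genotypes.

    Returns ``(genotypes, no_calls)``; individuals with too few countable
    fibres land in ``no_calls`` rather than raising.
    """
    per_ind: dict[str, list[int]] = {}
    for c in calls:
        if c.repeat_count is not None:
            per_ind.setdefault(c.individual_id, []).append(c.repeat_count)
    genotypes, no_calls = [], []
    for ind in sorted(per_ind):
        try:
            genotypes.append(call_genotype(per_ind[ind], ind,
                                           min_support=min_support,
                                           merge_tol=merge_tol))
        except NoCallError:
            no_calls.append(ind)
    if no_calls:
        logger.warning("no genotype call for %d individuals: %s",
                       len(no_calls), ", ".join(no_calls))
    return genotypes, no_calls


def _round2(x: float) -> float:
    return float(Decimal(x).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def build_allele_table(genotypes: Sequence[Genotype],
                       unrelated: Optional[dict] = None) -> AlleleTable:
    """Tally allele occurrences over the included (unrelated) chromosomes.

    ``unrelated`` maps individual_id -> (include_chrom1, include_chrom2);
    missing individuals default to fully included.  Frequencies are
    occurrences / chromosomes rounded half-away-from-zero to 2 dp.
    """
    if not genotypes:
        raise Rnu2CombError("empty genotype list")
    occ: dict[int, int] = {}
    total = 0
    for g in genotypes:
        inc = (unrelated or {}).get(g.individual_id, (True, True))
        for allele, keep in ((g.allele_low, inc[0]), (g.allele_high, inc[1])):
            if keep:
                occ[allele] = occ.get(allele, 0) + 1
                total += 1
    rows = [(a, n, _round2(n / total)) for a, n in sorted(occ.items())]
    return AlleleTable(rows=rows, chromosomes=total, distinct_alleles=len(rows))


def observed_heterozygosity(genotypes: Sequence[Genotype]) -> tuple[float, float]:
    """Fraction of individuals with two distinct alleles: (raw, 2-dp)."""
    if not genotypes:
        raise Rnu2CombError("empty genotype list")
    raw = sum(g.heterozygous for g in genotypes) / len(genotypes)
    return raw, _round2(raw)


def summarize_distances(calls) -> dict:
    """Sample mean ± sd (n-1 denominator) of the per-fibre distance outputs.

    Quantities with fewer than two values are omitted.
    """
    pools: dict[str, list[float]] = {"brca1_to_array_kb": [],
                                     "signal_length_kb": [],
                                     "gap_length_kb": []}
    n_fibres = 0
    for c in calls:
        d = getattr(c, "distances", {}) or {}
        if d:
            n_fibres += 1
        if "brca1_to_array_kb" in d:
            pools["brca1_to_array_kb"].append(d["brca1_to_array_kb"])
        pools["signal_length_kb"].extend(d.get("signal_lengths_kb", []))
        pools["gap_length_kb"].extend(d.get("gap_lengths_kb", []))
    out: dict = {"n_fibres": n_fibres}
    for name, values in pools.items():
        if len(values) >= 2:
            arr = np.asarray(values, dtype=float)
            out[name] = {"mean": float(arr.mean()),
                         "sd": float(arr.std(ddof=1)),
                         "n": int(arr.size)}
    return out
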