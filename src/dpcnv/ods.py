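"""Overlapping density score (ODS) for comparing CNV call sets.

When no ground truth exists (real tumor samples), callers are compared by
mutual concordance.  For method A against k other methods,

    overlap_total = sum over other methods B of the number of A's calls
                    that overlap at least one call of B,
    m_cnv  = overlap_total / k          (mean overlap count per method)
    m'_cnv = overlap_total / n_detected (overlap fraction of A's own calls)
    ODS    = m_cnv * m'_cnv.

A high ODS needs both many overlaps and a call set not inflated with calls
nobody else reproduces.  Overlap is status-agnostic single-base by default;
a reciprocal-fraction rule is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["Interval", "OdsResult", "ods_compare", "read_bed_intervals"]


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int


@dataclass
class OdsResult:
    method: str
    n_detected: int
    overlap_total: int
    m_cnv: float
    m_cnv_prime: float
    ods: float


def read_bed_intervals(path) -> list[Interval]:
    """First three columns of a BED-like file; '#' lines skipped."""
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(Interval(f[0], int(f[1]), int(f[2])))
    return out


def _overlaps(a: Interval, b: Interval, reciprocal: float) -> bool:
    if a.chrom != b.chrom:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    if reciprocal <= 0:
        return True
    return ov >= reciprocal * (a.end - a.start) and ov >= reciprocal * (b.end - b.start)


def ods_compare(
    call_sets: dict[str, list[Interval]],
    reciprocal: float = 0.0,
    denominator_includes_self: bool = False,
) -> dict[str, OdsResult]:
    """ODS per method over >= 2 named call sets.

    ``reciprocal`` > 0 switches from any-base overlap to a reciprocal
    overlap fraction.  The m_cnv denominator is the count of *other*
    methods; set ``denominator_includes_self`` for the k+1 variant.
    """
    if len(call_sets) < 2:
        raise ValueError("ODS needs at least 2 call sets")
    names = list(call_sets)
    results: dict[str, OdsResult] = {}
    for a in names:
        calls_a = call_sets[a]
        others = [b for b in names if b != a]
        k = len(others) + (1 if denominator_includes_self else 0)
        overlap_total = 0
        for b in others:
            calls_b = call_sets[b]
            overlap_total += sum(
                1 for ca in calls_a if any(_overlaps(ca, cb, reciprocal) for cb in calls_b)
            )
        if len(calls_a) == 0:
            warnings.warn(f"method {a!r} has no calls; ODS reported as 0")
            results[a] = OdsResult(a, 0, 0, 0.0, 0.0, 0.0)
            continue
        m_cnv = overlap_total / k
        m_prime = overlap_total / len(calls_a)
        results[a] = OdsResult(a, len(calls_a), overlap_total, m_cnv, m_prime, m_cnv * m_prime)
    return results
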