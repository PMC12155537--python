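"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from natedit.io import EditingCall, GenomicInterval, IntervalSet, SampleCallSet

settings.register_profile(
    "natedit",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("natedit")


# ---------------------------------------------------------------------------
# builders


def make_call(
    start: int,
    substitution: str = "A>G",
    strand: str = "+",
    chrom: str = "chrS",
    supporting: int = 5,
    total: int = 20,
) -> EditingCall:
    ref, _, alt = substitution.partition(">")
    return EditingCall(chrom, start, ref, alt, strand, supporting, total)


def make_callset(
    calls,
    sample_id: str = "S1",
    group: str | None = "tumor",
    subtype: str | None = "ER+",
    mapped_reads: int | None = 10_000_000,
) -> SampleCallSet:
    return SampleCallSet(
        sample_id=sample_id,
        calls=tuple(calls),
        group=group,
        subtype=subtype,
        mapped_reads=mapped_reads,
    )


def cohort_from_k_table(k_table, n_tumor: int, n_adjacent: int, chrom: str = "chrS"):
    """Call sets realizing exact per-site detection counts.

    ``k_table``: {start: (k_tumor, k_adjacent)}. Site ``start`` appears in
    the first k samples of each group, as an A>G '+' call.
    """
    sets = []
    for group, n, k_idx in (("tumor", n_tumor, 0), ("adjacent", n_adjacent, 1)):
        for i in range(n):
            calls = [
                make_call(start, chrom=chrom)
                for start, ks in k_table.items()
                if i < ks[k_idx]
            ]
            sets.append(
                make_callset(
                    calls,
                    sample_id=f"{group[0].upper()}{i + 1:02d}",
                    group=group,
                )
            )
    return sets


# ---------------------------------------------------------------------------
# independent oracles


def mw_u_statistic(x, y) -> float:
    """U for x: number of (x, y) pairs with x > y, ties counting 1/2."""
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def mw_null_distribution(n1: int, n2: int) -> Counter:
    """Exact null distribution of U by enumerating all rank splits."""
    n = n1 + n2
    dist: Counter = Counter()
    for idx in itertools.combinations(range(n), n1):
        chosen = set(idx)
        x = [r for r in range(n) if r in chosen]
        y = [r for r in range(n) if r not in chosen]
        dist[mw_u_statistic(x, y)] += 1
    return dist


def mw_enumeration_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of rank splits.

    Tie-free inputs only: p = P(U <= lo) + P(U >= n1*n2 - lo) with
    lo = min(U, n1*n2 - U), capped at 1.
    """
    n1, n2 = len(x), len(y)
    u_obs = mw_u_statistic(x, y)
    lo = min(u_obs, n1 * n2 - u_obs)
    hi = n1 * n2 - lo
    dist = mw_null_distribution(n1, n2)
    total = sum(dist.values())
    count = sum(c for u, c in dist.items() if u <= lo or u >= hi)
    return min(1.0, count / total)


def brute_force_overlap(call: EditingCall, intervals: IntervalSet) -> bool:
    """All-pairs half-open overlap scan, independent of interval trees."""
    return any(
        iv.chrom == call.chrom and iv.start <= call.start < iv.end
        for iv in intervals.intervals
    )


def random_filter_fixture(rng: np.random.Generator, n_calls=200, n_intervals=50):
    """Random call set + Alu/SNP annotations for oracle comparisons."""
    span = 5_000
    starts = rng.choice(span, size=n_calls, replace=False)
    subs = rng.choice(["A>G", "T>C", "C>T", "G>A", "A>C"], size=n_calls,
                      p=[0.4, 0.3, 0.1, 0.1, 0.1])
    strands = rng.choice(["+", "-"], size=n_calls)
    calls = [
        make_call(int(s), substitution=str(sub), strand=str(st))
        for s, sub, st in zip(starts, subs, strands)
    ]
    alu_ivs = []
    for i in range(n_intervals):
        a = int(rng.integers(0, span))
        b = a + int(rng.integers(1, 60))
        alu_ivs.append(GenomicInterval("chrS", a, b, f"Alu{i}", "+"))
    snp_ivs = []
    snp_pos = rng.choice(span, size=n_intervals // 2, replace=False)
    snp_names = rng.choice(["A>G", "T>C", "C>T"], size=n_intervals // 2)
    for p, nm in zip(snp_pos, snp_names):
        snp_ivs.append(GenomicInterval("chrS", int(p), int(p) + 1, str(nm), "."))
    return (
        make_callset(calls),
        IntervalSet("alu", tuple(alu_ivs)),
        IntervalSet("snp", tuple(snp_ivs)),
    )
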