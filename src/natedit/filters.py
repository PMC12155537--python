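"""Editing-call filter chain.

Three stages, applied per sample and in this order:

1. ``editing_type`` — keep only calls consistent with A-to-I editing:
   A>G on the plus strand or T>C on the minus strand (hydrolytic
   deamination of adenosine reads as guanosine; the reverse-strand
   signature is T>C).
2. ``alu_overlap`` — keep only calls inside annotated Alu repeats, where
   inverted-repeat dsRNA concentrates genuine A-to-I editing.
3. ``snp_overlap`` — drop calls coinciding with a known A>G or T>C SNP,
   which would mimic an editing signature genomically.

Every stage reports input/retained/excluded counts; counts are conserved
and the chain is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import IntervalSet, SampleCallSet

__all__ = [
    "FilterStage",
    "FilterReport",
    "filter_editing_type",
    "filter_alu_overlap",
    "filter_snp_overlap",
    "apply_filter_chain",
]

# (ref>alt, strand) pairs consistent with A-to-I editing, strict strand rule
_AG_TC_STRICT = {("A>G", "+"), ("T>C", "-")}
_AG_TC_SNP = {"A>G", "T>C"}


@dataclass(frozen=True)
class FilterStage:
    """Audit record of one filter stage."""

    stage: str
    input_count: int
    retained_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.retained_count <= self.input_count:
            raise ValueError(
                f"stage {self.stage}: retained {self.retained_count} "
                f"outside [0, {self.input_count}]"
            )

    @property
    def excluded_count(self) -> int:
        return self.input_count - self.retained_count

    @property
    def excluded_fraction(self) -> float:
        if self.input_count == 0:
            return 0.0
        return self.excluded_count / self.input_count


@dataclass(frozen=True)
class FilterReport:
    """Per-stage audit of one filter-chain run."""

    stages: tuple[FilterStage, ...]

    def __post_init__(self) -> None:
        for prev, cur in zip(self.stages, self.stages[1:]):
            if cur.input_count != prev.retained_count:
                raise ValueError(
                    f"stage {cur.stage} input {cur.input_count} != "
                    f"previous stage retained {prev.retained_count}"
                )

    @property
    def input_count(self) -> int:
        return self.stages[0].input_count if self.stages else 0

    @property
    def retained_count(self) -> int:
        return self.stages[-1].retained_count if self.stages else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.stage, s.input_count, s.retained_count, s.excluded_count, s.excluded_fraction)
                for s in self.stages
            ],
            columns=["stage", "input_count", "retained_count", "excluded_count", "excluded_fraction"],
        )


def filter_editing_type(callset: SampleCallSet, *, lenient: bool = False) -> SampleCallSet:
    """Retain A-to-I-consistent calls.

    Strict (default): (A>G, '+') and (T>C, '-') only. With ``lenient=True``
    any A>G or T>C call is kept regardless of strand.
    """
    if lenient:
        kept = [c for c in callset if c.substitution in _AG_TC_SNP]
    else:
        kept = [c for c in callset if (c.substitution, c.strand) in _AG_TC_STRICT]
    return callset.with_calls(kept)


def filter_alu_overlap(callset: SampleCallSet, alu: IntervalSet) -> SampleCallSet:
    """Retain calls whose single-base interval intersects >= 1 Alu interval.

    Overlap is strand-agnostic and half-open: a call at position p is kept
    iff some Alu interval [s, e) has s <= p < e.
    """
    if alu.kind != "alu":
        raise ValueError(f"expected alu IntervalSet, got kind {alu.kind!r}")
    kept = [c for c in callset if alu.covers(c.chrom, c.start)]
    return callset.with_calls(kept)


def filter_snp_overlap(
    callset: SampleCallSet,
    snps: IntervalSet,
    *,
    allele_specific: bool = True,
) -> tuple[SampleCallSet, FilterStage]:
    """Remove calls coinciding with a known SNP.

    With ``allele_specific=True`` (default) only positions carrying an A>G
    or T>C SNP trigger removal — other SNP types at the position do not.
    With ``allele_specific=False`` any SNP at the position removes the call.
    """
    if snps.kind != "snp":
        raise ValueError(f"expected snp IntervalSet, got kind {snps.kind!r}")
    kept = []
    for c in callset:
        names = snps.names_at(c.chrom, c.start)
        if allele_specific:
            hit = any(n in _AG_TC_SNP for n in names)
        else:
            hit = bool(names)
        if not hit:
            kept.append(c)
    stage = FilterStage("snp_overlap", input_count=len(callset), retained_count=len(kept))
    return callset.with_calls(kept), stage


def apply_filter_chain(
    callset: SampleCallSet,
    alu: IntervalSet,
    snps: IntervalSet,
    *,
    lenient_strand: bool = False,
    allele_specific_snp: bool = True,
) -> tuple[SampleCallSet, FilterReport]:
    """Apply editing-type -> Alu-overlap -> SNP-exclusion, with audit."""
    after_type = filter_editing_type(callset, lenient=lenient_strand)
    stage_type = FilterStage("editing_type", len(callset), len(after_type))

    after_alu = filter_alu_overlap(after_type, alu)
    stage_alu = FilterStage("alu_overlap", len(after_type), len(after_alu))

    after_snp, stage_snp = filter_snp_overlap(after_alu, snps, allele_specific=allele_specific_snp)

    return after_snp, FilterReport(stages=(stage_type, stage_alu, stage_snp))
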