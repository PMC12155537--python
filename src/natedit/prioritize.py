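"""Candidate-site prioritization from cross-cohort detection prevalence.

For every edited site, detection is binary per sample: the site either
appears in the sample's filtered call file or it does not. Within one
breast-cancer subtype the statistic chain is:

1. per-site prevalence per group: ``prev = k / n`` (fraction of samples
   with the site detected);
2. keep sites detected in at least 40% of either group;
3. tumor/adjacent prevalence ratio (zero-prevalence denominators are
   guarded with a half-count, Haldane-style);
4. Z-score of the ratios across sites; retain ``|Z| > 1.96``;
5. keep only sites overlapped by a natural antisense transcript (NAT);
6. intersect the candidate lists of the two subtypes.

Two standardizations are provided. ``classical`` is the textbook
``z = (v - mean) / sd`` (sd with denominator n-1) over the post-filter
record set. ``robust`` uses median and normal-consistent MAD, by default
estimated over the full detected-site roster: in an outlier screen the
candidates themselves inflate a mean/sd scale estimate and the 40% filter
preselects noise-extreme sites, both of which destroy sensitivity. The
high-level :func:`prioritize` pipeline therefore defaults to the robust
form on raw ratios with Haldane-shrunk prevalences; the classical form is
exposed for the literal textbook computation.

No multiple-testing correction is applied: selection uses the fixed
``|Z| > 1.96`` cutoff, not an FDR procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import IntervalSet, SampleCallSet, to_report_position

__all__ = [
    "CandidateList",
    "PrioritizationResult",
    "site_prevalence",
    "prevalence_filter",
    "prevalence_ratio",
    "zscore_ratios",
    "select_candidates",
    "intersect_subtypes",
    "prioritize",
]

PREVALENCE_COLUMNS = [
    "chrom",
    "start",
    "k_tumor",
    "n_tumor",
    "k_adjacent",
    "n_adjacent",
    "prev_tumor",
    "prev_adjacent",
]


@dataclass(frozen=True)
class CandidateList:
    """Ordered candidate sites of one subtype plus selection parameters."""

    subtype: str | None
    records: pd.DataFrame
    min_prevalence: float
    z_threshold: float

    def __len__(self) -> int:
        return len(self.records)

    def sites(self) -> set[tuple[str, int]]:
        return set(zip(self.records["chrom"], self.records["start"]))


@dataclass(frozen=True)
class PrioritizationResult:
    """Full per-site roster (all flags and intermediates) plus the
    selected candidates."""

    subtype: str | None
    roster: pd.DataFrame
    candidates: CandidateList


def site_prevalence(
    call_sets: Iterable[SampleCallSet],
    subtype: str | None = None,
) -> pd.DataFrame:
    """Per-site detection counts and prevalences across the two groups.

    The roster is the union of sites observed in any sample; a site absent
    from a sample counts 0 for that sample regardless of coverage. With
    ``subtype`` given, only samples of that subtype enter.
    """
    sets = [cs for cs in call_sets if subtype is None or cs.subtype == subtype]
    tumor = [cs for cs in sets if cs.group == "tumor"]
    adjacent = [cs for cs in sets if cs.group == "adjacent"]
    if not tumor or not adjacent:
        raise ValueError(
            f"need >= 1 sample per group, got {len(tumor)} tumor / {len(adjacent)} adjacent"
            + (f" for subtype {subtype}" if subtype else "")
        )
    n_t, n_a = len(tumor), len(adjacent)
    counts: dict[tuple[str, int], list[int]] = {}
    for group_idx, group in enumerate((tumor, adjacent)):
        for cs in group:
            for site in cs.sites():
                counts.setdefault(site, [0, 0])[group_idx] += 1
    rows = [
        (chrom, start, kt, n_t, ka, n_a, kt / n_t, ka / n_a)
        for (chrom, start), (kt, ka) in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=PREVALENCE_COLUMNS)


def prevalence_filter(records: pd.DataFrame, min_prevalence: float = 0.40) -> pd.DataFrame:
    """Keep sites detected in at least ``min_prevalence`` of either group.

    The boundary is inclusive ("at least 40%").
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError(f"min_prevalence must be in [0, 1], got {min_prevalence}")
    mask = (records["prev_tumor"] >= min_prevalence) | (records["prev_adjacent"] >= min_prevalence)
    out = records[mask].copy()
    out["passes_prevalence_filter"] = True
    return out


def prevalence_ratio(
    records: pd.DataFrame,
    zero_guard: float | None = None,
    shrinkage: str | None = None,
) -> pd.DataFrame:
    """Tumor/adjacent prevalence ratio with log2.

    Default: ``ratio = prev_tumor / prev_adjacent``; a zero count in
    either group is replaced by the half-count prevalence ``0.5 / n``
    (``zero_guard`` overrides the denominator guard) so the ratio and its
    log2 stay finite. With ``shrinkage="haldane"`` both prevalences are
    shrunk to ``(k + 0.5) / (n + 1)`` unconditionally, which stabilizes
    small counts and is the pipeline default.
    """
    out = records.copy()
    if shrinkage not in (None, "haldane"):
        raise ValueError(f"unknown shrinkage {shrinkage!r}")
    if shrinkage == "haldane":
        num = (out["k_tumor"] + 0.5) / (out["n_tumor"] + 1)
        den = (out["k_adjacent"] + 0.5) / (out["n_adjacent"] + 1)
    else:
        guard_den = zero_guard if zero_guard is not None else 0.5 / out["n_adjacent"]
        num = out["prev_tumor"].where(out["k_tumor"] > 0, 0.5 / out["n_tumor"])
        den = out["prev_adjacent"].where(out["k_adjacent"] > 0, guard_den)
    out["ratio"] = num / den
    out["log2_ratio"] = np.log2(out["ratio"])
    return out


def zscore_ratios(
    records: pd.DataFrame,
    scale: str = "log2",
    method: str = "classical",
    reference_values: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Standardize prevalence ratios across sites.

    ``scale`` picks the standardized variable: ``log2`` (log2_ratio
    column, symmetric for enrichment/depletion) or ``raw`` (the ratio
    itself). ``method="classical"`` centers on the mean and scales by the
    sample standard deviation (denominator n-1), so over the record set
    mean(z) = 0 and sd(z) = 1. ``method="robust"`` centers on the median
    and scales by 1.4826*MAD. ``reference_values`` standardizes against an
    external value set (e.g. the full detected-site roster) instead of the
    records' own values.

    Requires >= 3 reference values; a zero scale estimate yields z = 0
    everywhere with a warning.
    """
    if scale not in ("log2", "raw"):
        raise ValueError(f"scale must be 'log2' or 'raw', got {scale!r}")
    col = "log2_ratio" if scale == "log2" else "ratio"
    out = records.copy()
    v = out[col].to_numpy(dtype=float)
    ref = v if reference_values is None else np.asarray(reference_values, dtype=float)
    if ref.size < 3:
        raise ValueError(f"need >= 3 records to standardize, got {ref.size}")
    if method == "classical":
        loc, spread = float(np.mean(ref)), float(np.std(ref, ddof=1))
    elif method == "robust":
        loc = float(np.median(ref))
        spread = float(stats.median_abs_deviation(ref, scale="normal"))
    else:
        raise ValueError(f"method must be 'classical' or 'robust', got {method!r}")
    if spread == 0.0:
        warnings.warn("all ratios equal; z-scores set to 0")
        out["z"] = 0.0
    else:
        out["z"] = (v - loc) / spread
    return out


def select_candidates(
    records: pd.DataFrame,
    nat: IntervalSet,
    z_threshold: float = 1.96,
    *,
    subtype: str | None = None,
    min_prevalence: float = 0.40,
) -> CandidateList:
    """Retain sites with ``|z| > z_threshold`` (strict) that lie inside a
    NAT interval, ordered by |z| descending (ties by coordinate).

    NAT overlap is positional and strand-agnostic: an antisense transcript
    by construction lies opposite the edited transcript, so its annotated
    strand carries no extra information for a single-base overlap.
    """
    if nat.kind != "nat":
        raise ValueError(f"expected nat IntervalSet, got kind {nat.kind!r}")
    out = records.copy()
    out["in_nat"] = [
        nat.covers(chrom, start) for chrom, start in zip(out["chrom"], out["start"])
    ]
    out["passes_z"] = out["z"].abs() > z_threshold
    sel = out[out["passes_z"] & out["in_nat"]].copy()
    sel["abs_z"] = sel["z"].abs()
    sel = sel.sort_values(
        ["abs_z", "chrom", "start"], ascending=[False, True, True]
    ).drop(columns="abs_z").reset_index(drop=True)
    return CandidateList(
        subtype=subtype, records=sel, min_prevalence=min_prevalence, z_threshold=z_threshold
    )


def intersect_subtypes(a: CandidateList, b: CandidateList) -> list[tuple[str, int]]:
    """Sites (chrom, 0-based start) present in both candidate lists."""
    return sorted(a.sites() & b.sites())


def format_sites_report(sites: Iterable[tuple[str, int]]) -> list[str]:
    """Render sites 1-based for human-readable reports."""
    return [f"{chrom}:{to_report_position(start)}" for chrom, start in sorted(sites)]


def prioritize(
    call_sets: Iterable[SampleCallSet],
    nat: IntervalSet,
    *,
    subtype: str | None = None,
    min_prevalence: float = 0.40,
    z_threshold: float = 1.96,
    ratio_scale: str = "raw",
    z_method: str = "robust",
    z_reference: str = "roster",
    shrinkage: str | None = "haldane",
) -> PrioritizationResult:
    """Run the full prioritization chain for one subtype.

    ``z_reference`` chooses the standardization reference set: ``roster``
    (all detected sites; default) or ``postfilter`` (only sites passing
    the prevalence filter). See the module docstring for why the defaults
    are robust/raw/roster/haldane rather than the classical textbook form.
    """
    if z_reference not in ("roster", "postfilter"):
        raise ValueError(f"z_reference must be 'roster' or 'postfilter', got {z_reference!r}")
    roster = site_prevalence(call_sets, subtype=subtype)
    roster = prevalence_ratio(roster, shrinkage=shrinkage)
    passed = prevalence_filter(roster, min_prevalence=min_prevalence)
    col = "log2_ratio" if ratio_scale == "log2" else "ratio"
    ref = (roster if z_reference == "roster" else passed)[col].to_numpy(dtype=float)
    passed = zscore_ratios(passed, scale=ratio_scale, method=z_method, reference_values=ref)
    candidates = select_candidates(
        passed, nat, z_threshold, subtype=subtype, min_prevalence=min_prevalence
    )
    # roster with flags for reporting
    roster["passes_prevalence_filter"] = (
        (roster["prev_tumor"] >= min_prevalence) | (roster["prev_adjacent"] >= min_prevalence)
    )
    return PrioritizationResult(subtype=subtype, roster=roster, candidates=candidates)
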