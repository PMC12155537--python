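"""qPCR relative expression (2^-ddCt) and transcript-decay kinetics.

Relative expression follows the standard 2^-ddCt scheme: technical
replicates are averaged on the Ct scale, dCt = Ct_target - Ct_reference,
ddCt = dCt_condition - dCt_calibrator, fold change = 2^-ddCt.

Transcript stability after transcription shutoff (actinomycin D chase) is
modelled as first-order decay, N(t) = N0 * exp(-lambda * t). The decay
rate is estimated by ordinary least squares of ln(expression) on time;
the half-life is ln(2) / lambda. Biological replicates are fitted
separately so that conditions can be compared with a Welch t-test on the
replicate half-life estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RelativeExpression",
    "DecayFit",
    "DecayComparison",
    "ddct",
    "relative_expression_timecourse",
    "fit_decay",
    "fit_decay_replicates",
    "compare_decay",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit of one transcript in one condition/replicate.

    ``rate_per_hour`` is the decay constant lambda (floored at 0);
    ``t_half_hours`` is ln2/lambda, infinite when no decay is detected.
    """

    gene: str
    condition: str
    rate_per_hour: float
    t_half_hours: float
    intercept: float
    r_squared: float
    n_points: int
    replicate: int | None = None


@dataclass(frozen=True)
class DecayComparison:
    difference_t_half_hours: float
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int


def _average_technical(ct: pd.DataFrame) -> pd.DataFrame:
    """Average duplicate Ct rows (same sample/condition/timepoint/gene/
    replicate) on the Ct scale."""
    keys = ["sample_label", "condition", "timepoint_hours", "gene", "replicate"]
    return ct.groupby(keys, as_index=False)["ct"].mean()


def ddct(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_condition: str,
) -> pd.DataFrame:
    """Relative expression of ``target_gene`` by the 2^-ddCt method.

    Replicates are averaged on the Ct scale per (sample_label, condition,
    timepoint); dCt is formed against ``reference_gene``; ddCt against the
    mean dCt of ``calibrator_condition`` (per sample_label when the
    calibrator was run for that sample, otherwise the global calibrator
    mean). Returns one row per (sample_label, condition, timepoint) with
    delta_ct, delta_delta_ct and fold_change.
    """
    averaged = _average_technical(ct)
    keys = ["sample_label", "condition", "timepoint_hours"]
    merged = averaged.groupby(keys + ["gene"], as_index=False)["ct"].mean()
    target = merged[merged["gene"] == target_gene].rename(columns={"ct": "ct_target"})
    reference = merged[merged["gene"] == reference_gene].rename(columns={"ct": "ct_reference"})
    if target.empty:
        raise ValueError(f"no rows for target gene {target_gene!r}")
    joined = target.drop(columns="gene").merge(
        reference.drop(columns="gene"), on=keys, how="left"
    )
    if joined["ct_reference"].isna().any():
        bad = joined[joined["ct_reference"].isna()].iloc[0]
        raise ValueError(
            f"missing reference-gene ({reference_gene}) rows for "
            f"{bad['sample_label']}/{bad['condition']}/t={bad['timepoint_hours']}"
        )
    joined["delta_ct"] = joined["ct_target"] - joined["ct_reference"]
    cal = joined[joined["condition"] == calibrator_condition]
    if cal.empty:
        raise ValueError(f"calibrator condition {calibrator_condition!r} absent from table")
    cal_by_sample = cal.groupby("sample_label")["delta_ct"].mean()
    global_cal = float(cal["delta_ct"].mean())
    joined["delta_ct_calibrator"] = (
        joined["sample_label"].map(cal_by_sample).fillna(global_cal)
    )
    joined["delta_delta_ct"] = joined["delta_ct"] - joined["delta_ct_calibrator"]
    joined["fold_change"] = np.power(2.0, -joined["delta_delta_ct"])
    return joined[
        keys + ["delta_ct", "delta_delta_ct", "fold_change"]
    ].reset_index(drop=True)


# kept for symmetry with the domain model; ddct returns a DataFrame
RelativeExpression = pd.DataFrame


def relative_expression_timecourse(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
) -> pd.DataFrame:
    """Per-replicate 2^-ddCt time course, calibrated to t = 0.

    The ``replicate`` column is treated as the biological replicate;
    duplicate rows within a replicate (technical replicates) are averaged
    on the Ct scale first. Each replicate's t = 0 sample is its own
    calibrator, so the returned rel_expression is 1 at t = 0 by
    construction. Returns (sample_label, condition, replicate,
    timepoint_hours, rel_expression).
    """
    averaged = _average_technical(ct)
    keys = ["sample_label", "condition", "replicate", "timepoint_hours"]
    target = averaged[averaged["gene"] == target_gene].rename(columns={"ct": "ct_target"})
    reference = averaged[averaged["gene"] == reference_gene].rename(columns={"ct": "ct_reference"})
    if target.empty:
        raise ValueError(f"no rows for target gene {target_gene!r}")
    joined = target.drop(columns="gene").merge(reference.drop(columns="gene"), on=keys, how="left")
    if joined["ct_reference"].isna().any():
        bad = joined[joined["ct_reference"].isna()].iloc[0]
        raise ValueError(
            f"missing reference-gene ({reference_gene}) rows for "
            f"{bad['condition']}/rep {bad['replicate']}/t={bad['timepoint_hours']}"
        )
    joined["delta_ct"] = joined["ct_target"] - joined["ct_reference"]
    rep_keys = ["sample_label", "condition", "replicate"]
    t0 = (
        joined[joined["timepoint_hours"] == 0.0]
        .rename(columns={"delta_ct": "delta_ct_t0"})[rep_keys + ["delta_ct_t0"]]
    )
    if t0.empty:
        raise ValueError("time course lacks a t = 0 calibrator timepoint")
    joined = joined.merge(t0, on=rep_keys, how="left")
    if joined["delta_ct_t0"].isna().any():
        raise ValueError("some replicates lack a t = 0 calibrator timepoint")
    joined["delta_delta_ct"] = joined["delta_ct"] - joined["delta_ct_t0"]
    joined["rel_expression"] = np.power(2.0, -joined["delta_delta_ct"])
    out = joined[keys + ["rel_expression"]]
    return out.sort_values(keys).reset_index(drop=True)


def fit_decay(
    timepoints: Sequence[float],
    expression: Sequence[float],
    *,
    gene: str = "",
    condition: str = "",
    replicate: int | None = None,
) -> DecayFit:
    """OLS fit of ln(expression) on time; lambda = -slope, floored at 0.

    Requires >= 3 timepoints including 0 and strictly positive expression
    values (relative to t = 0). A constant series yields lambda = 0 and an
    infinite half-life ("not reached" within the chase).
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(expression, dtype=float)
    if t.size != y.size:
        raise ValueError("timepoints and expression differ in length")
    if t.size < 3:
        raise ValueError(f"need >= 3 timepoints, got {t.size}")
    if not np.any(t == 0.0):
        raise ValueError("time course must include t = 0")
    if np.any(y <= 0.0):
        raise ValueError("expression values must be > 0 for a log-linear fit")
    logy = np.log(y)
    if np.allclose(logy, logy[0]):
        # flat series: no measurable decay
        return DecayFit(gene, condition, 0.0, math.inf, float(logy[0]), 1.0, int(t.size), replicate)
    res = stats.linregress(t, logy)
    lam = max(0.0, -float(res.slope))
    t_half = math.inf if lam == 0.0 else LN2 / lam
    return DecayFit(
        gene=gene,
        condition=condition,
        rate_per_hour=lam,
        t_half_hours=t_half,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_points=int(t.size),
        replicate=replicate,
    )


def fit_decay_replicates(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    condition: str | None = None,
) -> list[DecayFit]:
    """One decay fit per (condition, biological replicate) of a Ct table."""
    rel = relative_expression_timecourse(ct, target_gene, reference_gene)
    if condition is not None:
        rel = rel[rel["condition"] == condition]
        if rel.empty:
            raise ValueError(f"condition {condition!r} absent from table")
    fits = []
    for (cond, rep), grp in rel.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("timepoint_hours")
        fits.append(
            fit_decay(
                grp["timepoint_hours"],
                grp["rel_expression"],
                gene=target_gene,
                condition=str(cond),
                replicate=int(rep),
            )
        )
    return fits


def compare_decay(fits_a: Sequence[DecayFit], fits_b: Sequence[DecayFit]) -> DecayComparison:
    """Welch two-sample t-test on replicate half-life estimates.

    Requires >= 2 finite-half-life replicates per condition. Degenerate
    zero-variance inputs: identical means give p = 1, differing means
    p = 0.
    """
    a = np.array([f.t_half_hours for f in fits_a], dtype=float)
    b = np.array([f.t_half_hours for f in fits_b], dtype=float)
    for name, arr in (("first", a), ("second", b)):
        if arr.size < 2:
            raise ValueError(f"{name} condition has {arr.size} replicate fits (< 2)")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} condition contains a non-decaying replicate (infinite t1/2)")
    diff = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
        tstat = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        tstat, p = float(res.statistic), float(res.pvalue)
    return DecayComparison(
        difference_t_half_hours=diff,
        t_statistic=tstat,
        p_value=p,
        n_a=int(a.size),
        n_b=int(b.size),
    )
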