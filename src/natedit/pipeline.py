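"""One reproducible run: simulate/load -> filter -> burden -> prioritize
(-> kinetics), with a machine-readable JSON summary.

The run config comes from a YAML file with exactly one of a ``simulation``
block (cohort simulator conditions) or an ``inputs`` block (paths to a
manifest and annotation files). All parameters are echoed verbatim into
the summary; outputs carry no timestamps, so identical config + seed
gives byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .burden import burden_counts, compare_burden
from .filters import FilterReport, apply_filter_chain
from .io import (
    IntervalSet,
    read_interval_bed,
    read_sample_manifest,
    read_snp_vcf,
    to_report_position,
)
from .kinetics import compare_decay, fit_decay_replicates
from .prioritize import intersect_subtypes, prioritize
from .simulate import CohortSimConfig, simulate_cohort

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("natedit")

PRIORITIZE_DEFAULTS = {
    "min_prevalence": 0.40,
    "z_threshold": 1.96,
    "ratio_scale": "raw",
    "z_method": "robust",
    "z_reference": "roster",
    "shrinkage": "haldane",
}
FILTER_DEFAULTS = {"lenient_strand": False, "allele_specific_snp": True}


@dataclass
class RunConfig:
    """Validated run configuration; exactly one input source."""

    simulation: CohortSimConfig | None = None
    inputs: dict[str, str] | None = None
    filter: dict[str, Any] = field(default_factory=dict)
    prioritization: dict[str, Any] = field(default_factory=dict)
    kinetics: dict[str, Any] | None = None
    seed: int | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("config must provide exactly one of 'simulation' or 'inputs'")
        if self.inputs is not None:
            missing = [k for k in ("manifest", "alu", "nat", "snps") if k not in self.inputs]
            if missing:
                raise ValueError(f"inputs block missing keys {missing}")
        unknown = set(self.filter) - set(FILTER_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown filter options {sorted(unknown)}")
        unknown = set(self.prioritization) - set(PRIORITIZE_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown prioritization options {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.get("simulation")
        return cls(
            simulation=CohortSimConfig.from_dict(sim) if sim is not None else None,
            inputs=raw.get("inputs"),
            filter=raw.get("filter") or {},
            prioritization=raw.get("prioritization") or {},
            kinetics=raw.get("kinetics"),
            seed=raw.get("seed"),
            out_dir=raw.get("out_dir"),
        )

    def parameters(self) -> dict[str, Any]:
        """All effective parameters, for verbatim echo into the summary."""
        return {
            "simulation": self.simulation.to_dict() if self.simulation else None,
            "inputs": self.inputs,
            "filter": {**FILTER_DEFAULTS, **self.filter},
            "prioritization": {**PRIORITIZE_DEFAULTS, **self.prioritization},
            "kinetics": self.kinetics,
            "seed": self.seed,
        }


def _stage(name: str, **counts: Any) -> dict[str, Any]:
    logger.info("stage %s: %s", name, counts)
    return {"stage": name, **counts}


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Execute the full pipeline; returns (and writes) the run summary.

    ``seed``/``out_dir`` arguments override the config values. Any stage
    failure propagates with the stage named in the log.
    """
    out = Path(out_dir or config.out_dir or "natedit_run")
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = config.seed
    stages: list[dict[str, Any]] = []

    # --- stage 1: obtain inputs -------------------------------------------
    if config.simulation is not None:
        sim_config = config.simulation
        if seed is not None:
            sim_config = CohortSimConfig.from_dict({**sim_config.to_dict(), "seed": int(seed)})
        sim = simulate_cohort(sim_config)
        sim.write(out / "inputs")
        call_sets, alu, nat, snps = sim.call_sets, sim.alu, sim.nat, sim.snps
        stages.append(
            _stage(
                "simulate",
                n_samples=len(call_sets),
                n_sites=sim_config.n_sites,
                output_calls=sum(len(cs) for cs in call_sets),
            )
        )
    else:
        manifest_path = Path(config.inputs["manifest"])
        cohort = read_sample_manifest(manifest_path)
        call_sets = cohort.load_call_sets(base_dir=manifest_path.parent)
        alu = read_interval_bed(config.inputs["alu"], kind="alu")
        nat = read_interval_bed(config.inputs["nat"], kind="nat")
        snps_path = str(config.inputs["snps"])
        if snps_path.endswith((".vcf", ".vcf.gz")):
            snps = read_snp_vcf(snps_path)
        else:
            snps = read_interval_bed(snps_path, kind="snp")
        stages.append(
            _stage(
                "load",
                n_samples=len(call_sets),
                output_calls=sum(len(cs) for cs in call_sets),
            )
        )

    # --- stage 2: filter chain --------------------------------------------
    filter_opts = {**FILTER_DEFAULTS, **config.filter}
    filtered: list = []
    report_rows = []
    for cs in call_sets:
        fcs, report = apply_filter_chain(
            cs,
            alu,
            snps,
            lenient_strand=filter_opts["lenient_strand"],
            allele_specific_snp=filter_opts["allele_specific_snp"],
        )
        filtered.append(fcs)
        for st in report.stages:
            report_rows.append(
                (cs.sample_id, st.stage, st.input_count, st.retained_count,
                 st.excluded_count, st.excluded_fraction)
            )
    import pandas as pd

    report_df = pd.DataFrame(
        report_rows,
        columns=["sample_id", "stage", "input_count", "retained_count",
                 "excluded_count", "excluded_fraction"],
    )
    report_df.to_csv(out / "filter_report.tsv", sep="\t", index=False)
    total_in = sum(len(cs) for cs in call_sets)
    total_out = sum(len(cs) for cs in filtered)
    stages.append(_stage("filter", input_calls=total_in, output_calls=total_out))

    # --- stage 3: burden ---------------------------------------------------
    counts = burden_counts(filtered)
    counts.to_csv(out / "burden.tsv", sep="\t", index=False)
    subtypes = sorted({cs.subtype for cs in filtered if cs.subtype})
    burden_results = {}
    for st in subtypes:
        sub = counts[counts["subtype"] == st]
        if (sub["group"] == "tumor").sum() >= 2 and (sub["group"] == "adjacent").sum() >= 2:
            cmp = compare_burden(counts, st)
            burden_results[st] = {
                "n_tumor": cmp.n_tumor,
                "n_adjacent": cmp.n_adjacent,
                "median_tumor": cmp.median_tumor,
                "median_adjacent": cmp.median_adjacent,
                "u": cmp.u,
                "p_value": cmp.p_value,
                "method": cmp.method,
            }
    stages.append(_stage("burden", input_calls=total_out, n_samples=len(filtered)))

    # --- stage 4: prioritization ------------------------------------------
    pri_opts = {**PRIORITIZE_DEFAULTS, **config.prioritization}
    candidate_lists = {}
    prioritization_summary = {}
    for st in subtypes:
        result = prioritize(filtered, nat, subtype=st, **pri_opts)
        roster = result.roster.copy()
        roster["position_1based"] = roster["start"].map(to_report_position)
        roster.to_csv(out / f"prevalence_{st}.tsv", sep="\t", index=False)
        cand = result.candidates.records.copy()
        cand["position_1based"] = cand["start"].map(to_report_position)
        cand.to_csv(out / f"candidates_{st}.tsv", sep="\t", index=False)
        candidate_lists[st] = result.candidates
        prioritization_summary[st] = {
            "roster_sites": int(len(roster)),
            "postfilter_sites": int(roster["passes_prevalence_filter"].sum()),
            "candidates": int(len(cand)),
        }
        stages.append(
            _stage(
                f"prioritize[{st}]",
                roster_sites=int(len(roster)),
                candidates=int(len(cand)),
            )
        )

    intersection = None
    if len(subtypes) >= 2:
        a, b = (candidate_lists[s] for s in subtypes[:2])
        shared = intersect_subtypes(a, b)
        intersection = [f"{chrom}:{to_report_position(s)}" for chrom, s in shared]
        pd.DataFrame(
            [(c, to_report_position(s)) for c, s in shared],
            columns=["chrom", "position_1based"],
        ).to_csv(out / "intersection.tsv", sep="\t", index=False)
        stages.append(_stage("intersect", shared_sites=len(shared)))

    # --- stage 5: kinetics (optional) -------------------------------------
    kinetics_summary = None
    if config.kinetics:
        from .io import read_ct_table

        kcfg = config.kinetics
        ct = read_ct_table(kcfg["ct"])
        fits = fit_decay_replicates(ct, kcfg["target_gene"], kcfg["reference_gene"])
        fits_df = pd.DataFrame(
            [
                (f.gene, f.condition, f.replicate, f.rate_per_hour, f.t_half_hours,
                 f.r_squared, f.n_points)
                for f in fits
            ],
            columns=["gene", "condition", "replicate", "rate_per_hour", "t_half_hours",
                     "r_squared", "n_points"],
        )
        fits_df.to_csv(out / "decay_fits.tsv", sep="\t", index=False)
        kinetics_summary = {"n_fits": len(fits)}
        compare = kcfg.get("compare_conditions")
        if compare:
            cond_a, cond_b = compare
            res = compare_decay(
                [f for f in fits if f.condition == cond_a],
                [f for f in fits if f.condition == cond_b],
            )
            kinetics_summary["comparison"] = {
                "conditions": [cond_a, cond_b],
                "difference_t_half_hours": res.difference_t_half_hours,
                "p_value": res.p_value,
            }
        stages.append(_stage("kinetics", n_fits=len(fits)))

    summary = {
        "natedit_version": __version__,
        "seed": seed,
        "parameters": config.parameters(),
        "stages": stages,
        "burden": burden_results,
        "prioritization": prioritization_summary,
        "intersection": intersection,
        "kinetics": kinetics_summary,
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
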