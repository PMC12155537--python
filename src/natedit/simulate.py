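"""Synthetic cohorts, annotations and qPCR tables with ground truth.

The cohort simulator emulates the statistical structure of a per-sample
RNA-editing call dataset: each site has a per-group detection prevalence
(binary presence/absence per sample — the prioritization statistic uses
detection, not editing fraction), background sites share one prevalence
drawn from a Beta distribution, and planted sites carry a configured
tumor/adjacent prevalence gap. Read counts, sequencing depths and
annotation membership (Alu, NAT, SNP decoys) are generated so parsers and
filters see realistic input, and everything is recorded in a truth table.

Sites live on a single pseudo-chromosome on a fixed grid with jitter, so
per-site annotation intervals never bleed onto a neighboring site and the
truth table stays exactly consistent with the emitted interval files.

One integer seed drives a named child generator per artifact (positions,
depths, detections, read counts, ...), so extending one stream never
shifts another.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    Cohort,
    EditingCall,
    GenomicInterval,
    IntervalSet,
    SampleCallSet,
    SampleInfo,
    write_editing_calls,
    write_interval_bed,
    write_sample_manifest,
    write_snp_vcf,
)

__all__ = [
    "CohortSimConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_decay_series",
    "simulate_normalized_burden",
    "child_rng",
]

LN2 = math.log(2.0)

TRUTH_COLUMNS = [
    "chrom",
    "start",
    "planted",
    "true_prevalence_tumor",
    "true_prevalence_adjacent",
    "in_alu",
    "is_snp",
    "in_nat",
]


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic named child generator of one global seed."""
    return np.random.default_rng([zlib.crc32(name.encode()) & 0x7FFFFFFF, int(seed)])


@dataclass(frozen=True)
class CohortSimConfig:
    """Study conditions for one simulated two-group cohort.

    Depth is lognormal in raw mapped reads (defaults centered near 3e7,
    the scale of a bulk RNA-seq run). ``burden_per_million`` optionally
    thins detections so the expected per-sample site count tracks
    sequencing depth (Figure-1-style normalization becomes testable);
    when None, detection follows site prevalence exactly. Coverage at a
    detected site is negative-binomial; the per-site editing fraction is
    Beta so supporting-read counts look like real calls.
    """

    n_tumor: int = 20
    n_adjacent: int = 15
    n_sites: int = 1000
    n_planted: int = 20
    background_beta: tuple[float, float] = (2.0, 8.0)
    planted_prevalence_tumor: float = 0.8
    planted_prevalence_adjacent: float = 0.1
    depth_lognormal: tuple[float, float] = (math.log(3.0e7), 0.4)
    burden_per_million: float | None = None
    fraction_alu: float = 0.85
    fraction_snp_decoy: float = 0.03
    fraction_nat: float = 0.25
    planted_in_nat: bool = True
    subtype: str = "ER+"
    chrom: str = "chrS"
    site_spacing: int = 150
    coverage_nb: tuple[float, float] = (30.0, 5.0)  # (mean, dispersion r)
    editing_beta: tuple[float, float] = (2.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_sites:
            raise ValueError(f"n_planted {self.n_planted} > n_sites {self.n_sites}")
        if min(self.n_tumor, self.n_adjacent, self.n_sites) <= 0:
            raise ValueError("n_tumor, n_adjacent and n_sites must be positive")
        for name in (
            "planted_prevalence_tumor",
            "planted_prevalence_adjacent",
            "fraction_alu",
            "fraction_snp_decoy",
            "fraction_nat",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("background_beta", "depth_lognormal", "coverage_nb", "editing_beta"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSimConfig":
        d = dict(d)
        for key in ("background_beta", "depth_lognormal", "coverage_nb", "editing_beta"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimulatedCohort:
    """In-memory simulation result; ``write`` materializes the on-disk
    cohort (call files, manifest, annotations, truth table)."""

    config: CohortSimConfig
    call_sets: list[SampleCallSet]
    cohort: Cohort
    alu: IntervalSet
    nat: IntervalSet
    snps: IntervalSet
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        calls_dir = out / "calls"
        calls_dir.mkdir(exist_ok=True)
        for cs in self.call_sets:
            write_editing_calls(cs, calls_dir / f"{cs.sample_id}.bed")
        samples = [
            SampleInfo(
                sample_id=s.sample_id,
                subtype=s.subtype,
                group=s.group,
                mapped_reads=s.mapped_reads,
                calls_path=f"calls/{s.sample_id}.bed",
            )
            for s in self.cohort
        ]
        write_sample_manifest(Cohort(tuple(samples)), out / "manifest.tsv")
        write_interval_bed(self.alu, out / "alu.bed")
        write_interval_bed(self.nat, out / "nat.bed")
        write_snp_vcf(self.snps, out / "snps.vcf")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        return out


def _site_layout(config: CohortSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_sites
    spacing = config.site_spacing
    jitter = rng.integers(0, max(1, spacing // 4), size=n)
    starts = spacing * (np.arange(n) + 1) + jitter
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    planted = np.zeros(n, dtype=bool)
    planted[rng.choice(n, size=config.n_planted, replace=False)] = True
    a, b = config.background_beta
    prev_bg = rng.beta(a, b, size=n)
    prev_t = np.where(planted, config.planted_prevalence_tumor, prev_bg)
    prev_a = np.where(planted, config.planted_prevalence_adjacent, prev_bg)
    in_alu = np.where(planted, True, rng.random(n) < config.fraction_alu)
    is_snp = np.where(planted, False, rng.random(n) < config.fraction_snp_decoy)
    in_nat = np.where(
        planted, config.planted_in_nat, rng.random(n) < config.fraction_nat
    )
    return pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": starts.astype(int),
            "strand": strands,
            "planted": planted,
            "true_prevalence_tumor": prev_t,
            "true_prevalence_adjacent": prev_a,
            "in_alu": in_alu.astype(bool),
            "is_snp": is_snp.astype(bool),
            "in_nat": in_nat.astype(bool),
        }
    )


def _annotations(config: CohortSimConfig, sites: pd.DataFrame) -> tuple[IntervalSet, IntervalSet, IntervalSet]:
    # widths stay below half the site spacing so intervals of one site can
    # never cover a neighboring site
    alu_ivs, nat_ivs, snp_ivs = [], [], []
    for i, row in enumerate(sites.itertuples(index=False)):
        start = int(row.start)
        if row.in_alu:
            alu_ivs.append(
                GenomicInterval(row.chrom, max(0, start - 20), start + 21, f"AluSim{i}", "+")
            )
        if row.in_nat:
            nat_strand = "-" if row.strand == "+" else "+"
            nat_ivs.append(
                GenomicInterval(row.chrom, max(0, start - 40), start + 41, f"NATSim{i}", nat_strand)
            )
        if row.is_snp:
            name = "A>G" if row.strand == "+" else "T>C"
            snp_ivs.append(GenomicInterval(row.chrom, start, start + 1, name, "."))
    return (
        IntervalSet("alu", tuple(alu_ivs)),
        IntervalSet("nat", tuple(nat_ivs)),
        IntervalSet("snp", tuple(snp_ivs)),
    )


def _sample_calls(
    config: CohortSimConfig,
    sites: pd.DataFrame,
    prevalence: np.ndarray,
    mapped_reads: int,
    rng_detect: np.random.Generator,
    rng_reads: np.random.Generator,
    editing_fraction: np.ndarray,
) -> list[EditingCall]:
    detected = rng_detect.random(len(sites)) < prevalence
    if config.burden_per_million is not None:
        target = config.burden_per_million * mapped_reads / 1e6
        expected = float(prevalence.sum())
        keep_prob = min(1.0, target / expected) if expected > 0 else 0.0
        detected &= rng_detect.random(len(sites)) < keep_prob
    idx = np.flatnonzero(detected)
    mean_cov, disp = config.coverage_nb
    p_nb = disp / (disp + mean_cov)
    totals = 2 + rng_reads.negative_binomial(disp, p_nb, size=idx.size)
    calls = []
    for j, i in enumerate(idx):
        row = sites.iloc[i]
        total = int(totals[j])
        supporting = 1 + int(rng_reads.binomial(total - 1, editing_fraction[i]))
        ref, alt = ("A", "G") if row.strand == "+" else ("T", "C")
        calls.append(
            EditingCall(
                chrom=row.chrom,
                start=int(row.start),
                ref_base=ref,
                alt_base=alt,
                strand=row.strand,
                supporting_reads=supporting,
                total_reads=total,
            )
        )
    return calls


def simulate_cohort(config: CohortSimConfig) -> SimulatedCohort:
    """Simulate a full two-group cohort under the configured conditions.

    Detection is independent per (site, sample) with the group's
    prevalence; per-sample mapped reads are lognormal; annotation interval
    sets are emitted mutually consistent with the truth table. The same
    config and seed reproduce the result bit for bit.
    """
    seed = config.seed
    sites = _site_layout(config, child_rng(seed, "sites"))
    alu, nat, snps = _annotations(config, sites)
    rng_depth = child_rng(seed, "depths")
    rng_detect = child_rng(seed, "detections")
    rng_reads = child_rng(seed, "reads")
    ea, eb = config.editing_beta
    editing_fraction = child_rng(seed, "editing").beta(ea, eb, size=len(sites))

    prev_t = sites["true_prevalence_tumor"].to_numpy()
    prev_a = sites["true_prevalence_adjacent"].to_numpy()
    mean_log, sd_log = config.depth_lognormal

    call_sets: list[SampleCallSet] = []
    infos: list[SampleInfo] = []
    width = max(2, len(str(max(config.n_tumor, config.n_adjacent))))
    for group, n, prev, prefix in (
        ("tumor", config.n_tumor, prev_t, "T"),
        ("adjacent", config.n_adjacent, prev_a, "A"),
    ):
        for i in range(n):
            sample_id = f"{prefix}{i + 1:0{width}d}"
            mapped = int(rng_depth.lognormal(mean_log, sd_log))
            mapped = max(mapped, 1)
            calls = _sample_calls(
                config, sites, prev, mapped, rng_detect, rng_reads, editing_fraction
            )
            call_sets.append(
                SampleCallSet(
                    sample_id=sample_id,
                    calls=tuple(calls),
                    group=group,
                    subtype=config.subtype,
                    mapped_reads=mapped,
                )
            )
            infos.append(
                SampleInfo(
                    sample_id=sample_id,
                    subtype=config.subtype,
                    group=group,
                    mapped_reads=mapped,
                    calls_path=f"calls/{sample_id}.bed",
                )
            )
    truth = sites[TRUTH_COLUMNS].copy()
    return SimulatedCohort(
        config=config,
        call_sets=call_sets,
        cohort=Cohort(tuple(infos)),
        alu=alu,
        nat=nat,
        snps=snps,
        truth=truth,
    )


def simulate_normalized_burden(
    n_tumor: int = 20,
    n_adjacent: int = 15,
    fold_change: float = 2.0,
    base_rate: float = 250.0,
    sd_log: float = 0.4,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Depth-normalized burden draws (sites per million) for two groups.

    Lognormal with multiplicative spread ``sd_log`` around
    ``base_rate * fold_change`` (tumor) and ``base_rate`` (adjacent);
    ``fold_change=1`` gives a null cohort. A direct generator for
    burden-comparison power and calibration studies, bypassing site-level
    simulation.
    """
    if fold_change <= 0 or base_rate <= 0:
        raise ValueError("fold_change and base_rate must be positive")
    rng = child_rng(seed, "burden")
    tumor = rng.lognormal(math.log(base_rate * fold_change), sd_log, size=n_tumor)
    adjacent = rng.lognormal(math.log(base_rate), sd_log, size=n_adjacent)
    return tumor, adjacent


def simulate_decay_series(
    t_half_hours: float,
    timepoints: Sequence[float] = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0),
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    *,
    gene: str = "UGGT1",
    reference_gene: str = "GAPDH",
    condition: str = "WT",
    sample_label: str = "S1",
    reference_ct: float = 20.0,
    baseline_delta_ct: float = 5.0,
) -> pd.DataFrame:
    """Ct table of a transcription-shutoff time course.

    Target abundance follows exp(-lambda*t) with lambda = ln2/t_half,
    with multiplicative log-normal noise of sd ``noise_sd`` (natural-log
    scale). Encoded as target/reference Ct pairs: the reference gene's Ct
    is constant, and the target's Ct rises by t/t_half cycles (one cycle
    per halving), so 2^-ddCt against t = 0 recovers the decay curve.
    """
    if t_half_hours <= 0:
        raise ValueError(f"t_half_hours must be > 0, got {t_half_hours}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    timepoints = [float(t) for t in timepoints]
    if not timepoints or 0.0 not in timepoints:
        raise ValueError("timepoints must be non-empty and include 0")
    rng = child_rng(seed, "decay")
    rows = []
    for rep in range(1, n_replicates + 1):
        for t in timepoints:
            decay_ct = t / t_half_hours  # -log2(exp(-lambda t))
            noise_ct = rng.normal(0.0, noise_sd / LN2) if noise_sd > 0 else 0.0
            rows.append(
                (sample_label, condition, t, gene, rep,
                 reference_ct + baseline_delta_ct + decay_ct + noise_ct)
            )
            rows.append((sample_label, condition, t, reference_gene, rep, reference_ct))
    return pd.DataFrame(
        rows, columns=["sample_label", "condition", "timepoint_hours", "gene", "replicate", "ct"]
    )
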