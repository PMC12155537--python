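"""Readers and writers for every on-disk format the pipeline touches.

All coordinates are held 0-based half-open internally (BED-native).
Human-readable reports render 1-based inclusive positions; use
:func:`to_report_position` / :func:`from_report_position` to convert.
VCF input (1-based) is converted on read.

Formats
-------
editing calls
    7-column tab-separated, BED-like:
    ``chrom  start  end  REF>ALT  supporting_reads  strand  total_reads``.
    One file per sample; sample metadata (group, subtype, sequencing depth)
    lives in the manifest, never in the call file.
annotations
    BED3/BED6 for Alu repeats and natural antisense transcript (NAT) spans.
SNPs
    sites-only VCF (``CHROM POS ID REF ALT ...``), or single-base BED6 whose
    name field is ``REF>ALT``.
manifest / Ct tables
    TSV with mandatory header.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "ParseError",
    "EditingCall",
    "SampleCallSet",
    "GenomicInterval",
    "IntervalSet",
    "SampleInfo",
    "Cohort",
    "read_editing_calls",
    "write_editing_calls",
    "read_interval_bed",
    "write_interval_bed",
    "read_snp_vcf",
    "write_snp_vcf",
    "read_sample_manifest",
    "write_sample_manifest",
    "read_ct_table",
    "write_ct_table",
    "to_report_position",
    "from_report_position",
]

BASES = frozenset("ACGT")
GROUPS = ("tumor", "adjacent")
SUBTYPES = ("ER+", "TNBC")
INTERVAL_KINDS = ("alu", "nat", "snp")

CT_COLUMNS = ["sample_label", "condition", "timepoint_hours", "gene", "replicate", "ct"]
MANIFEST_COLUMNS = ["sample_id", "subtype", "group", "mapped_reads", "calls_path"]


class ParseError(ValueError):
    """Malformed input row; message carries file path and line number."""


def to_report_position(start: int) -> int:
    """0-based internal start -> 1-based inclusive position for reports."""
    return start + 1


def from_report_position(position: int) -> int:
    """1-based report position -> 0-based internal start."""
    return position - 1


# ---------------------------------------------------------------------------
# editing calls


@dataclass(frozen=True)
class EditingCall:
    """One candidate edited site observed in one sample.

    ``start`` is 0-based; the site spans ``[start, start + 1)``.
    ``supporting_reads`` counts reads carrying the edit at a coverage of
    ``total_reads``.
    """

    chrom: str
    start: int
    ref_base: str
    alt_base: str
    strand: str
    supporting_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.ref_base not in BASES or self.alt_base not in BASES:
            raise ValueError(f"bases must be one of ACGT, got {self.ref_base}>{self.alt_base}")
        if self.ref_base == self.alt_base:
            raise ValueError(f"ref and alt base identical: {self.ref_base}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.supporting_reads < 0:
            raise ValueError("supporting_reads must be >= 0")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be > 0")
        if self.supporting_reads > self.total_reads:
            raise ValueError(
                f"supporting_reads {self.supporting_reads} > total_reads {self.total_reads}"
            )

    @property
    def end(self) -> int:
        return self.start + 1

    @property
    def substitution(self) -> str:
        return f"{self.ref_base}>{self.alt_base}"

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.start)

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.ref_base, self.alt_base)


@dataclass(frozen=True)
class SampleCallSet:
    """All editing calls of one sample plus its design metadata.

    Calls are kept sorted by coordinate; duplicate
    (chrom, start, ref, alt) entries are rejected. Group/subtype/depth come
    from the manifest and may be absent when a call file is read standalone.
    """

    sample_id: str
    calls: tuple[EditingCall, ...]
    group: str | None = None
    subtype: str | None = None
    mapped_reads: int | None = None

    def __post_init__(self) -> None:
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.subtype is not None and self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}; expected one of {SUBTYPES}")
        if self.mapped_reads is not None and self.mapped_reads <= 0:
            raise ValueError("mapped_reads must be positive")
        ordered = tuple(sorted(self.calls, key=EditingCall.sort_key))
        keys = [c.sort_key() for c in ordered]
        if len(set(keys)) != len(keys):
            dup = next(k for i, k in enumerate(keys) if k in keys[:i])
            raise ValueError(f"duplicate call {dup[0]}:{dup[1]} {dup[2]}>{dup[3]}")
        object.__setattr__(self, "calls", ordered)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[EditingCall]:
        return iter(self.calls)

    def sites(self) -> set[tuple[str, int]]:
        """Distinct (chrom, start) keys present in this sample."""
        return {c.site for c in self.calls}

    def with_calls(self, calls: Iterable[EditingCall]) -> "SampleCallSet":
        """Same sample metadata, different call collection."""
        return replace(self, calls=tuple(calls))


def _split_row(raw: str) -> list[str]:
    return raw.rstrip("\n").rstrip("\r").split("\t")


def read_editing_calls(
    path: str | Path,
    *,
    sample_id: str | None = None,
    group: str | None = None,
    subtype: str | None = None,
    mapped_reads: int | None = None,
    column_map: Mapping[str, int] | None = None,
) -> SampleCallSet:
    """Read one sample's 7-column editing-call file.

    Lines starting with ``#`` are headers and skipped. ``column_map`` maps
    field names (chrom, start, end, substitution, supporting_reads, strand,
    total_reads) to 0-based column indices for non-default dialects.

    Raises :class:`ParseError` naming the offending line on any malformed
    row; rows are never silently dropped.
    """
    path = Path(path)
    cmap = {
        "chrom": 0,
        "start": 1,
        "end": 2,
        "substitution": 3,
        "supporting_reads": 4,
        "strand": 5,
        "total_reads": 6,
    }
    if column_map:
        cmap.update(column_map)
    ncol = max(cmap.values()) + 1

    calls: list[EditingCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = _split_row(raw)
            if len(fields) < ncol:
                raise ParseError(f"{path}:{lineno}: expected {ncol} columns, got {len(fields)}")
            try:
                chrom = fields[cmap["chrom"]]
                start = int(fields[cmap["start"]])
                end = int(fields[cmap["end"]])
                sub = fields[cmap["substitution"]]
                supporting = int(fields[cmap["supporting_reads"]])
                strand = fields[cmap["strand"]]
                total = int(fields[cmap["total_reads"]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if end != start + 1:
                raise ParseError(f"{path}:{lineno}: end {end} != start + 1 ({start + 1})")
            if ">" not in sub:
                raise ParseError(f"{path}:{lineno}: substitution {sub!r} is not 'REF>ALT'")
            ref, _, alt = sub.partition(">")
            try:
                call = EditingCall(chrom, start, ref, alt, strand, supporting, total)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            calls.append(call)
    try:
        return SampleCallSet(
            sample_id=sample_id or path.stem,
            calls=tuple(calls),
            group=group,
            subtype=subtype,
            mapped_reads=mapped_reads,
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_editing_calls(callset: SampleCallSet, path: str | Path) -> Path:
    """Write a call set in the 7-column dialect; inverse of the reader."""
    path = Path(path)
    lines = ["#chrom\tstart\tend\tsubstitution\tsupporting_reads\tstrand\ttotal_reads"]
    for c in callset.calls:
        lines.append(
            f"{c.chrom}\t{c.start}\t{c.end}\t{c.substitution}\t"
            f"{c.supporting_reads}\t{c.strand}\t{c.total_reads}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# intervals


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open, optionally stranded interval; strand '.' means unknown."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")


@dataclass
class IntervalSet:
    """Strand-aware interval collection with point/range overlap queries.

    ``kind`` is one of ``alu`` (repeat annotation), ``nat`` (antisense
    transcript spans) or ``snp`` (single-base, name carries ``REF>ALT``).
    Lookups go through per-chromosome interval trees.
    """

    kind: str
    intervals: tuple[GenomicInterval, ...]
    _trees: dict[str, IntervalTree] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in INTERVAL_KINDS:
            raise ValueError(f"unknown interval kind {self.kind!r}; expected {INTERVAL_KINDS}")
        self.intervals = tuple(
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.name))
        )
        if self.kind == "snp":
            for iv in self.intervals:
                if iv.end - iv.start != 1:
                    raise ValueError(f"snp interval must be single-base: {iv}")
                ref, _, alt = iv.name.partition(">")
                if ref not in BASES or alt not in BASES or ref == alt:
                    raise ValueError(f"snp name must be 'REF>ALT', got {iv.name!r}")
        trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._trees = trees

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """All intervals intersecting [start, end) on chrom (half-open)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(start, end)]
        return sorted(hits, key=lambda iv: (iv.start, iv.end, iv.name))

    def covers(self, chrom: str, start: int, end: int | None = None) -> bool:
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return bool(tree.overlap(start, start + 1 if end is None else end))

    def names_at(self, chrom: str, start: int) -> list[str]:
        return [iv.name for iv in self.overlapping(chrom, start, start + 1)]


def read_interval_bed(path: str | Path, kind: str) -> IntervalSet:
    """Read a BED3/BED6 file; BED3 rows get strand '.' and name '.'."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            fields = _split_row(raw)
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, name, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    try:
        return IntervalSet(kind=kind, intervals=tuple(intervals))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_interval_bed(intervals: IntervalSet, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}"
        for iv in intervals
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_snp_vcf(path: str | Path) -> IntervalSet:
    """Read a sites-only VCF into a snp-kind IntervalSet.

    POS is converted 1-based -> 0-based. Multi-allelic ALT fields yield one
    single-base interval per (POS, REF, ALT) pair, named ``REF>ALT``.
    Non-SNV records and records with REF == ALT are skipped with a warning.
    """
    import pysam

    path = Path(path)
    intervals: list[GenomicInterval] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch():
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                    warnings.warn(
                        f"{path}: skipping non-SNV record at {rec.chrom}:{rec.pos} ({ref}>{alt})"
                    )
                    continue
                if ref == alt:
                    warnings.warn(
                        f"{path}: skipping record with REF == ALT at {rec.chrom}:{rec.pos}"
                    )
                    continue
                intervals.append(
                    GenomicInterval(rec.chrom, rec.start, rec.start + 1, f"{ref}>{alt}", ".")
                )
    return IntervalSet(kind="snp", intervals=tuple(intervals))


def write_snp_vcf(snps: IntervalSet, path: str | Path) -> Path:
    """Write a snp IntervalSet as a minimal sites-only VCF (1-based POS)."""
    if snps.kind != "snp":
        raise ValueError(f"expected snp IntervalSet, got kind {snps.kind!r}")
    path = Path(path)
    chroms = sorted({iv.chrom for iv in snps})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for iv in snps:
        ref, _, alt = iv.name.partition(">")
        lines.append(f"{iv.chrom}\t{iv.start + 1}\t.\t{ref}\t{alt}\t.\t.\t.")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# manifest


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    subtype: str
    group: str
    mapped_reads: int
    calls_path: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}; expected one of {SUBTYPES}")
        if self.mapped_reads <= 0:
            raise ValueError(f"mapped_reads must be > 0, got {self.mapped_reads}")


@dataclass(frozen=True)
class Cohort:
    """The study design: one row per sample, the single source of group
    labels and sequencing depth."""

    samples: tuple[SampleInfo, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = next(i for n, i in enumerate(ids) if i in ids[:n])
            raise ValueError(f"duplicate sample_id {dup!r} in manifest")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SampleInfo]:
        return iter(self.samples)

    def group_sizes(self) -> dict[tuple[str, str], int]:
        """(subtype, group) -> number of samples."""
        sizes: dict[tuple[str, str], int] = {}
        for s in self.samples:
            key = (s.subtype, s.group)
            sizes[key] = sizes.get(key, 0) + 1
        return sizes

    def subtypes(self) -> list[str]:
        return sorted({s.subtype for s in self.samples})

    def load_call_sets(self, base_dir: str | Path | None = None) -> list[SampleCallSet]:
        """Read every sample's call file, joining manifest metadata."""
        out = []
        for s in self.samples:
            p = Path(s.calls_path)
            if base_dir is not None and not p.is_absolute():
                p = Path(base_dir) / p
            out.append(
                read_editing_calls(
                    p,
                    sample_id=s.sample_id,
                    group=s.group,
                    subtype=s.subtype,
                    mapped_reads=s.mapped_reads,
                )
            )
        return out


def read_sample_manifest(path: str | Path) -> Cohort:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment=None)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: manifest missing columns {missing}")
    samples = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            samples.append(
                SampleInfo(
                    sample_id=str(row.sample_id),
                    subtype=str(row.subtype),
                    group=str(row.group),
                    mapped_reads=int(row.mapped_reads),
                    calls_path=str(row.calls_path),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    try:
        return Cohort(samples=tuple(samples))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_sample_manifest(cohort: Cohort, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            (s.sample_id, s.subtype, s.group, s.mapped_reads, s.calls_path)
            for s in cohort
        ],
        columns=MANIFEST_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Ct tables


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table (TSV with the mandatory header).

    Columns: sample_label, condition, timepoint_hours, gene, replicate, ct.
    Validates ct > 0 and timepoint_hours >= 0; reference-gene completeness
    is checked where the reference gene is actually named (kinetics.ddct).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: Ct table missing columns {missing}")
    df = df[CT_COLUMNS].copy()
    df["timepoint_hours"] = df["timepoint_hours"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    df["ct"] = df["ct"].astype(float)
    if (df["ct"] <= 0).any():
        bad = df.index[df["ct"] <= 0][0]
        raise ParseError(f"{path}: non-positive ct value in data row {bad + 1}")
    if (df["timepoint_hours"] < 0).any():
        bad = df.index[df["timepoint_hours"] < 0][0]
        raise ParseError(f"{path}: negative timepoint in data row {bad + 1}")
    return df


def write_ct_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df[CT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path
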