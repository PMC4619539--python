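"""Typed records and readers/writers for every table the pipeline touches.

Coordinate convention: 1-based, fully inclusive, everywhere in memory and in
every TSV this package writes.  Interval length is ``end - start + 1``.
BED input (0-based half-open) is converted on read; GFF3 (1-based inclusive)
is taken as-is.  Chromosome names are normalized to ``chrN`` on read and
compared case-sensitively afterwards.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._meta import version_header as _version_header


class ValidationError(ValueError):
    """A record violates an invariant of its type."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome name to the ``chrN`` form (``1`` -> ``chr1``)."""
    c = str(chrom).strip()
    if not c:
        raise ValidationError("empty chromosome name")
    if c.lower().startswith("chr"):
        c = c[3:]
    return "chr" + c


_CHROM_NUM = re.compile(r"^chr(\d+)$")


def chrom_sort_key(chrom: str) -> tuple:
    """Natural ordering: chr1 < chr2 < ... < chr10 < chrX < chrY."""
    m = _CHROM_NUM.match(chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome span, 1-based inclusive."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class SegmentRecord:
    """One segmented copy-number call: a span with its mean log2 ratio."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self):
        if not self.sample_id:
            raise ValidationError("empty sample_id")
        if not self.chrom:
            raise ValidationError("empty chromosome")
        if self.start >= self.end:
            raise ValidationError(
                f"segment start {self.start} >= end {self.end} "
                f"({self.sample_id} {self.chrom})"
            )

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


VALID_CT_ROLES = ("sample", "calibrator", "dilution")


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: a cycle-threshold reading with its experimental role."""

    sample_id: str
    assay: str
    role: str
    dilution_factor: float | None
    experiment_id: str
    replicate_id: str
    ct: float

    def __post_init__(self):
        if self.role not in VALID_CT_ROLES:
            raise ValidationError(f"unknown Ct role {self.role!r}")
        if self.ct <= 0:
            raise ValidationError(f"non-positive Ct {self.ct} ({self.sample_id}/{self.assay})")
        if self.role == "dilution":
            if self.dilution_factor is None or not self.dilution_factor > 0:
                raise ValidationError(
                    f"dilution well without positive dilution_factor "
                    f"({self.sample_id}/{self.assay})"
                )
        elif self.dilution_factor is not None:
            raise ValidationError(
                f"dilution_factor given for role={self.role} "
                f"({self.sample_id}/{self.assay})"
            )


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient covariates: Breslow thickness and follow-up."""

    sample_id: str
    thickness_mm: float
    mfs_time: float
    mfs_event: int
    os_time: float
    os_event: int

    def __post_init__(self):
        if self.thickness_mm <= 0:
            raise ValidationError(f"{self.sample_id}: non-positive thickness")
        if self.mfs_time < 0 or self.os_time < 0:
            raise ValidationError(f"{self.sample_id}: negative follow-up time")
        if self.mfs_event not in (0, 1) or self.os_event not in (0, 1):
            raise ValidationError(f"{self.sample_id}: event flags must be 0/1")


# ---------------------------------------------------------------------------
# readers

_SEGMENT_COLS = ["sample_id", "chrom", "start", "end", "log2_ratio"]
_CT_COLS = [
    "sample_id",
    "assay",
    "role",
    "dilution_factor",
    "experiment_id",
    "replicate_id",
    "ct",
]
_CLINICAL_COLS = [
    "sample_id",
    "thickness_mm",
    "mfs_time",
    "mfs_event",
    "os_time",
    "os_event",
]


def _read_table(path, required_cols) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def _to_int(value: str, path, line: int, col: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ParseError(f"{path}, line {line}: bad {col} {value!r}") from None


def _to_float(value: str, path, line: int, col: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(f"{path}, line {line}: bad {col} {value!r}") from None


def read_segments(path) -> list[SegmentRecord]:
    """Read a segment table (TSV: sample_id, chrom, start, end, log2_ratio).

    Records are validated, sorted by (sample, chrom, start); overlapping
    segments of one sample on one chromosome are an error.
    """
    df = _read_table(path, _SEGMENT_COLS)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        records.append(
            SegmentRecord(
                sample_id=str(row.sample_id),
                chrom=normalize_chrom(row.chrom),
                start=_to_int(row.start, path, i, "start"),
                end=_to_int(row.end, path, i, "end"),
                log2_ratio=_to_float(row.log2_ratio, path, i, "log2_ratio"),
            )
        )
    records.sort(key=lambda r: (r.sample_id, chrom_sort_key(r.chrom), r.start))
    for a, b in zip(records, records[1:]):
        if a.sample_id == b.sample_id and a.chrom == b.chrom and b.start <= a.end:
            raise ValidationError(
                f"{path}: overlapping segments for {a.sample_id} on {a.chrom}: "
                f"[{a.start},{a.end}] and [{b.start},{b.end}]"
            )
    return records


def read_gene_annotation(path) -> list[GeneRecord]:
    """Read gene annotation from BED4+ (0-based half-open) or GFF3 (1-based).

    Both are converted to the internal 1-based inclusive convention.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        return _read_bed(path)
    if suffix in {".gff", ".gff3"}:
        return _read_gff3(path)
    raise ParseError(f"{path}: unrecognized annotation extension {suffix!r}")


def _read_bed(path: Path) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}, line {i}: BED4+ needs >=4 columns")
            chrom = normalize_chrom(parts[0])
            start0 = _to_int(parts[1], path, i, "start")
            end0 = _to_int(parts[2], path, i, "end")
            if end0 <= start0:
                raise ParseError(f"{path}, line {i}: BED end {end0} <= start {start0}")
            strand = parts[5] if len(parts) > 5 and parts[5] in {"+", "-"} else "."
            # BED half-open [start0, end0) -> 1-based inclusive [start0+1, end0]
            genes.append(GeneRecord(parts[3], chrom, start0 + 1, end0, strand))
    return genes


_GFF_ID = re.compile(r"(?:^|;)\s*(?:ID|gene_id|Name)=([^;]+)")


def _read_gff3(path: Path) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}, line {i}: GFF3 needs 9 columns")
            chrom = normalize_chrom(parts[0])
            start = _to_int(parts[3], path, i, "start")
            end = _to_int(parts[4], path, i, "end")
            if end < start:
                raise ParseError(f"{path}, line {i}: GFF end {end} < start {start}")
            strand = parts[6] if parts[6] in {"+", "-"} else "."
            m = _GFF_ID.search(parts[8])
            gene_id = m.group(1).strip() if m else f"{chrom}:{start}-{end}"
            genes.append(GeneRecord(gene_id, chrom, start, end, strand))
    return genes


def read_ct_table(path) -> list[CtRecord]:
    """Read a qPCR Ct table (TSV/CSV with the seven CtRecord columns).

    Duplicated (sample, assay, role, dilution, experiment, replicate) wells
    are an error, never silently averaged.
    """
    df = _read_table(path, _CT_COLS)
    records = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        dil = row.dilution_factor
        dil_value = (
            None
            if dil is None or (isinstance(dil, float) and pd.isna(dil)) or str(dil) in {"", "NA", "nan", "."}
            else _to_float(dil, path, i, "dilution_factor")
        )
        rec = CtRecord(
            sample_id=str(row.sample_id),
            assay=str(row.assay),
            role=str(row.role),
            dilution_factor=dil_value,
            experiment_id=str(row.experiment_id),
            replicate_id=str(row.replicate_id),
            ct=_to_float(row.ct, path, i, "ct"),
        )
        key = (rec.sample_id, rec.assay, rec.role, rec.dilution_factor,
               rec.experiment_id, rec.replicate_id)
        if key in seen:
            raise ValidationError(f"{path}, line {i}: duplicated Ct well {key}")
        seen.add(key)
        records.append(rec)
    return records


def read_clinical_table(path) -> list[ClinicalRecord]:
    """Read a clinical table (TSV/CSV with the six ClinicalRecord columns)."""
    df = _read_table(path, _CLINICAL_COLS)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        records.append(
            ClinicalRecord(
                sample_id=str(row.sample_id),
                thickness_mm=_to_float(row.thickness_mm, path, i, "thickness_mm"),
                mfs_time=_to_float(row.mfs_time, path, i, "mfs_time"),
                mfs_event=_to_int(row.mfs_event, path, i, "mfs_event"),
                os_time=_to_float(row.os_time, path, i, "os_time"),
                os_event=_to_int(row.os_event, path, i, "os_event"),
            )
        )
    return records


# ---------------------------------------------------------------------------
# writers


def _header_comment(params: dict | None = None) -> str:
    items = "; ".join(f"{k}={v}" for k, v in (params or {}).items())
    line = _version_header()
    if items:
        line += " | " + items
    return "# " + line + "\n"


def write_tsv(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a DataFrame as TSV with a commented provenance header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_comment(params))
        df.to_csv(fh, sep="\t", index=False)


def write_segments(records: Sequence[SegmentRecord], path, params=None) -> None:
    df = pd.DataFrame(
        [(r.sample_id, r.chrom, r.start, r.end, r.log2_ratio) for r in records],
        columns=_SEGMENT_COLS,
    )
    write_tsv(df, path, params)


def write_ct_table(records: Sequence[CtRecord], path, params=None) -> None:
    df = pd.DataFrame(
        [
            (r.sample_id, r.assay, r.role,
             "" if r.dilution_factor is None else r.dilution_factor,
             r.experiment_id, r.replicate_id, r.ct)
            for r in records
        ],
        columns=_CT_COLS,
    )
    write_tsv(df, path, params)


def write_clinical_table(records: Sequence[ClinicalRecord], path, params=None) -> None:
    df = pd.DataFrame(
        [
            (r.sample_id, r.thickness_mm, r.mfs_time, r.mfs_event,
             r.os_time, r.os_event)
            for r in records
        ],
        columns=_CLINICAL_COLS,
    )
    write_tsv(df, path, params)


def write_hotspot_report(hotspots, path, params: dict | None = None) -> None:
    """Write one row per hotspot: chrom, start, end, length, support, samples,
    genes.  Coordinates 1-based inclusive; deterministic (chrom, start) order.
    """
    rows = []
    for h in sorted(hotspots, key=lambda h: (chrom_sort_key(h.interval.chrom), h.interval.start)):
        rows.append(
            (
                h.interval.chrom,
                h.interval.start,
                h.interval.end,
                h.length_bp,
                h.support,
                ",".join(sorted(h.supporting_samples)),
                ",".join(h.genes),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "length_bp", "support", "samples", "genes"],
    )
    write_tsv(df, path, params)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for output headers."""
    canon = repr(sorted(_flatten(config)))
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _flatten(d, prefix=""):
    items = []
    for k, v in d.items():
        key = f"{prefix}.{k}" if prefix else str(k)
        if isinstance(v, dict):
            items.extend(_flatten(v, key))
        else:
            items.append((key, repr(v)))
    return items
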