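"""Reading isomiR quantification files and sample manifests.

Input files follow the TCGA ``isoform.quantification.txt`` dialect: one row
per sequenced isoform with a genomic coordinate string
``assembly:chrom:start-end:strand``, a raw read count, an RPM value
(reads per million miRNA-mapped reads), a cross-mapping flag and a region
annotation.  Coordinates are 1-based inclusive and are kept that way
internally.

Sample identity and tumor-type labels come from a tab-separated manifest
(``sample_id  barcode  tumor_type  file_path``).  Sample-type filtering uses
the TCGA barcode infix: primary solid tumors carry ``01``; acute myeloid
leukemia (LAML) samples are blood-derived and carry ``03`` instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "IsomiRRecord",
    "FivePrimeLocus",
    "SampleMeta",
    "ParserDialect",
    "parse_quantification_file",
    "five_prime_locus",
    "filter_samples",
    "retained_samples",
    "read_manifest",
]

_STRANDS = ("+", "-")


@dataclass(frozen=True)
class FivePrimeLocus:
    """Strand-aware identity of a 5'isomiR.

    All isoforms sharing the same genomic 5'-end base collapse to one locus,
    regardless of their 3' ends.  On the minus strand transcription runs from
    high to low coordinate, so the 5'-most base is the interval's *end*.
    """

    chromosome: str
    strand: str
    five_prime_pos: int

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def sort_key(self) -> tuple[str, str, int]:
        # Chromosome strings compare lexicographically (chr10 < chr2); this is
        # a deterministic ordering, not a karyotype ordering.
        return (self.chromosome, self.strand, self.five_prime_pos)

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.strand}:{self.five_prime_pos}"


@dataclass(frozen=True)
class IsomiRRecord:
    """One parsed quantification line."""

    mirna_id: str
    assembly: str
    chromosome: str
    start: int
    end: int
    strand: str
    read_count: int
    rpm: float
    cross_mapped: bool
    region: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.read_count < 0 or self.rpm < 0:
            raise ValueError("read_count and rpm must be non-negative")


@dataclass
class SampleMeta:
    """One manifest row, with the exclusion verdict filled in by filtering."""

    sample_id: str
    barcode: str
    tumor_type: str
    file_path: str
    excluded: bool = False
    reason: str = ""


@dataclass(frozen=True)
class ParserDialect:
    """Column layout of a quantification file.

    ``columns`` maps the logical fields to 0-based column indices; the default
    is the TCGA order (miRNA_ID, isoform_coords, read_count,
    reads_per_million_miRNA_mapped, cross-mapped, miRNA_region).
    """

    mirna_id: int = 0
    coords: int = 1
    read_count: int = 2
    rpm: int = 3
    cross_mapped: int = 4
    region: int = 5
    n_columns: int = 6
    has_header: bool = True

    def indices(self) -> tuple[int, ...]:
        return (self.mirna_id, self.coords, self.read_count, self.rpm, self.cross_mapped, self.region)


DEFAULT_DIALECT = ParserDialect()


def _parse_coords(text: str) -> tuple[str, str, int, int, str]:
    """Split ``assembly:chrom:start-end:strand`` into its parts."""
    parts = text.split(":")
    if len(parts) != 4:
        raise ValueError(f"bad coordinate string {text!r}")
    assembly, chrom, span, strand = parts
    if strand not in _STRANDS:
        raise ValueError(f"bad strand in {text!r}")
    lo, sep, hi = span.partition("-")
    if not sep:
        raise ValueError(f"bad span in {text!r}")
    return assembly, chrom, int(lo), int(hi), strand


def parse_quantification_file(
    path: str | Path,
    dialect: ParserDialect = DEFAULT_DIALECT,
) -> list[IsomiRRecord]:
    """Parse one quantification file into records.

    Well-formed lines become one :class:`IsomiRRecord` each.  Malformed lines
    (wrong column count, unparseable coordinates or numbers) are skipped and
    reported with their line numbers in a single summary warning.  An
    unreadable file raises.
    """
    path = Path(path)
    records: list[IsomiRRecord] = []
    bad_lines: list[int] = []
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if lineno == 1 and dialect.has_header:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != dialect.n_columns:
                bad_lines.append(lineno)
                continue
            try:
                assembly, chrom, start, end, strand = _parse_coords(fields[dialect.coords])
                record = IsomiRRecord(
                    mirna_id=fields[dialect.mirna_id],
                    assembly=assembly,
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    read_count=int(fields[dialect.read_count]),
                    rpm=float(fields[dialect.rpm]),
                    cross_mapped=fields[dialect.cross_mapped].strip().upper() in ("Y", "YES", "TRUE", "1"),
                    region=fields[dialect.region],
                )
            except (ValueError, IndexError):
                bad_lines.append(lineno)
                continue
            records.append(record)
    if bad_lines:
        warnings.warn(
            f"{path.name}: skipped {len(bad_lines)} malformed line(s) "
            f"at {bad_lines[:20]}{'...' if len(bad_lines) > 20 else ''}",
            stacklevel=2,
        )
    return records


def five_prime_locus(record: IsomiRRecord) -> FivePrimeLocus:
    """Derive the strand-aware 5' locus of a record.

    Plus strand: the 5'-most transcribed base is ``start``.  Minus strand:
    transcription runs high-to-low coordinate, so it is ``end``.
    """
    pos = record.start if record.strand == "+" else record.end
    return FivePrimeLocus(record.chromosome, record.strand, pos)


def _barcode_infix(barcode: str) -> str | None:
    """Extract the two-digit sample-type code from a TCGA barcode.

    TCGA-XX-YYYY-01A-... -> "01".  Returns None when the barcode does not
    carry a fourth dash-separated field with at least two characters.
    """
    parts = barcode.split("-")
    if len(parts) < 4 or len(parts[3]) < 2 or not parts[3][:2].isdigit():
        return None
    return parts[3][:2]


def filter_samples(
    manifest: Sequence[SampleMeta],
    problematic_ids: Iterable[str] = (),
    laml_label: str = "LAML",
) -> list[SampleMeta]:
    """Apply the sample-type and problematic-sample filters.

    Retains primary solid tumor samples (barcode infix ``01``), except for
    the LAML class where the blood-derived infix ``03`` is required instead.
    Samples listed in ``problematic_ids`` (by sample_id or barcode) are
    dropped.  Returns a new list covering every input sample; dropped samples
    carry ``excluded=True`` and a reason, so retained + dropped partitions
    the input.
    """
    problematic = set(problematic_ids)
    out: list[SampleMeta] = []
    n_bad = 0
    for meta in manifest:
        if meta.sample_id in problematic or meta.barcode in problematic:
            out.append(replace(meta, excluded=True, reason="potentially_problematic"))
            continue
        infix = _barcode_infix(meta.barcode)
        if infix is None:
            n_bad += 1
            out.append(replace(meta, excluded=True, reason="bad_barcode"))
            continue
        required = "03" if meta.tumor_type == laml_label else "01"
        if infix != required:
            out.append(replace(meta, excluded=True, reason=f"sample_type_infix_{infix}"))
            continue
        if not meta.tumor_type:
            out.append(replace(meta, excluded=True, reason="missing_tumor_type"))
            continue
        out.append(replace(meta, excluded=False, reason=""))
    if n_bad:
        warnings.warn(f"{n_bad} sample(s) excluded for unparseable barcodes", stacklevel=2)
    return out


def retained_samples(manifest: Sequence[SampleMeta]) -> list[SampleMeta]:
    """The non-excluded subset of a filtered manifest."""
    return [m for m in manifest if not m.excluded]


def read_manifest(path: str | Path) -> list[SampleMeta]:
    """Read a tab-separated manifest: sample_id, barcode, tumor_type, file_path.

    A header line starting with ``sample_id`` is skipped.  File paths are
    interpreted relative to the manifest's directory when not absolute.
    """
    path = Path(path)
    out: list[SampleMeta] = []
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("sample_id"):
                continue
            sample_id, barcode, tumor_type, file_path = line.split("\t")
            fp = Path(file_path)
            if not fp.is_absolute():
                fp = path.parent / fp
            out.append(SampleMeta(sample_id, barcode, tumor_type, str(fp)))
    return out
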