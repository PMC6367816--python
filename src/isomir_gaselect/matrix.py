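"""Building the samples x 5'isomiR expression matrix.

Per sample, every record mapping to the same strand-aware 5' locus is summed
on the RPM scale.  Loci are then filtered for expression (summed RPM >= 10 in
strictly more than 10 samples, both configurable), values below 1 RPM are
floored to 1 (treated as noise) and the matrix holds log2 of the floored RPM.
Columns are sorted deterministically by (chromosome string, strand, position)
so feature IDs are reproducible; chromosome strings compare lexicographically
(chr10 < chr2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_DIALECT,
    FivePrimeLocus,
    IsomiRRecord,
    ParserDialect,
    SampleMeta,
    filter_samples,
    five_prime_locus,
    parse_quantification_file,
    read_manifest,
    retained_samples,
)

__all__ = [
    "ExpressionMatrix",
    "aggregate_profiles",
    "filter_loci",
    "log_transform",
    "floored_log2",
    "build_matrix_from_manifest",
]


@dataclass
class ExpressionMatrix:
    """Samples x loci matrix of floored log2(RPM) values with class labels.

    ``values[i, j]`` is log2(max(RPM, 1)) for sample ``sample_ids[i]`` at
    locus ``loci[j]``.  Feature IDs are the column indices under the
    deterministic locus sort, stable for the lifetime of the matrix.
    """

    values: np.ndarray
    sample_ids: list[str]
    labels: list[str]
    loci: list[FivePrimeLocus]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError("matrix shape does not match sample_ids x loci")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels must align with sample rows")
        if np.any(self.values < 0):
            raise ValueError("entries must be >= 0 (floored log2 RPM)")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate loci")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def class_order(self) -> list[str]:
        return sorted(set(self.labels))

    def feature_id(self, locus: FivePrimeLocus) -> int:
        return self.loci.index(locus)

    def subset_features(self, feature_ids: Iterable[int]) -> "ExpressionMatrix":
        ids = sorted(feature_ids)
        return ExpressionMatrix(
            self.values[:, ids],
            list(self.sample_ids),
            list(self.labels),
            [self.loci[j] for j in ids],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=[str(l) for l in self.loci])

    def write_tsv(self, path: str | Path, labels_path: str | Path | None = None) -> None:
        """Serialize as TSV with a two-line header (feature IDs, locus descriptors)."""
        path = Path(path)
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("feature_id\t" + "\t".join(str(j) for j in range(self.n_features)) + "\n")
            handle.write("locus\t" + "\t".join(str(l) for l in self.loci) + "\n")
            for i, sid in enumerate(self.sample_ids):
                row = "\t".join(format(v, ".10g") for v in self.values[i])
                handle.write(f"{sid}\t{row}\n")
        if labels_path is not None:
            with open(labels_path, "w", encoding="utf-8") as handle:
                handle.write("sample_id\ttumor_type\n")
                for sid, lab in zip(self.sample_ids, self.labels):
                    handle.write(f"{sid}\t{lab}\n")


def aggregate_profiles(
    records_by_sample: Mapping[str, Sequence[IsomiRRecord]],
    drop_cross_mapped: bool = True,
) -> dict[str, dict[FivePrimeLocus, float]]:
    """Collapse records to per-sample 5'-locus RPM totals.

    Each locus value is the exact sum of RPM over the sample's records mapping
    to that locus; loci absent from a sample are implicitly 0.  Cross-mapped
    records are dropped by default to avoid counting reads at several loci.
    Mixing genome assemblies within one run is a fatal error.
    """
    assemblies = {r.assembly for records in records_by_sample.values() for r in records}
    if len(assemblies) > 1:
        raise ValueError(f"mixed genome assemblies in one run: {sorted(assemblies)}")
    profiles: dict[str, dict[FivePrimeLocus, float]] = {}
    for sample_id, records in records_by_sample.items():
        acc: dict[FivePrimeLocus, float] = {}
        for record in records:
            if drop_cross_mapped and record.cross_mapped:
                continue
            locus = five_prime_locus(record)
            acc[locus] = acc.get(locus, 0.0) + record.rpm
        profiles[sample_id] = acc
    return profiles


def filter_loci(
    profiles: Mapping[str, Mapping[FivePrimeLocus, float]],
    min_rpm: float = 10.0,
    min_samples: int = 10,
) -> set[FivePrimeLocus]:
    """Retain loci expressed at >= ``min_rpm`` in strictly more than ``min_samples`` samples."""
    if not profiles:
        raise ValueError("empty profiles")
    counts: dict[FivePrimeLocus, int] = {}
    for sample_profile in profiles.values():
        for locus, rpm in sample_profile.items():
            if rpm >= min_rpm:
                counts[locus] = counts.get(locus, 0) + 1
    retained = {locus for locus, n in counts.items() if n > min_samples}
    if not retained:
        warnings.warn("expression filter retained no loci", stacklevel=2)
    return retained


def floored_log2(rpm: np.ndarray) -> np.ndarray:
    """log2 after flooring values below 1 RPM to 1 (noise floor)."""
    return np.log2(np.maximum(np.asarray(rpm, dtype=float), 1.0))


def log_transform(
    profiles: Mapping[str, Mapping[FivePrimeLocus, float]],
    retained: Iterable[FivePrimeLocus],
    labels: Mapping[str, str] | None = None,
    sample_order: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Build the floored log2 matrix over the retained loci.

    Loci absent from a sample are 0 RPM, hence 0 after the floor-and-log
    transform.  Column order is the deterministic locus sort; row order is
    ``sample_order`` when given, else sorted sample IDs.
    """
    loci = sorted(retained, key=FivePrimeLocus.sort_key)
    samples = list(sample_order) if sample_order is not None else sorted(profiles)
    rpm = np.zeros((len(samples), len(loci)))
    for i, sid in enumerate(samples):
        profile = profiles[sid]
        for j, locus in enumerate(loci):
            rpm[i, j] = profile.get(locus, 0.0)
    lab = [labels[s] for s in samples] if labels is not None else [""] * len(samples)
    return ExpressionMatrix(floored_log2(rpm), samples, lab, loci)


def build_matrix_from_manifest(
    manifest_path: str | Path,
    problematic_ids: Iterable[str] = (),
    min_rpm: float = 10.0,
    min_samples: int = 10,
    drop_cross_mapped: bool = True,
    dialect: ParserDialect = DEFAULT_DIALECT,
) -> tuple[ExpressionMatrix, list[SampleMeta]]:
    """End-to-end: manifest -> sample filter -> parse -> aggregate -> filter -> matrix.

    Returns the matrix over retained samples and loci, plus the full filtered
    manifest (retained and dropped, with reasons).
    """
    manifest = filter_samples(read_manifest(manifest_path), problematic_ids)
    kept = retained_samples(manifest)
    if not kept:
        raise ValueError("no samples retained after filtering")
    records_by_sample = {
        m.sample_id: parse_quantification_file(m.file_path, dialect) for m in kept
    }
    profiles = aggregate_profiles(records_by_sample, drop_cross_mapped=drop_cross_mapped)
    retained = filter_loci(profiles, min_rpm=min_rpm, min_samples=min_samples)
    labels = {m.sample_id: m.tumor_type for m in kept}
    order = [m.sample_id for m in kept]
    matrix = log_transform(profiles, retained, labels=labels, sample_order=order)
    return matrix, manifest
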