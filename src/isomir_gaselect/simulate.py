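"""Synthetic multi-class 5'isomiR expression data with known ground truth.

The generator emulates the statistical shape of a TCGA-style isomiR corpus:
several tumor classes with unequal sample counts, many candidate 5' loci of
which most are uninformative, class-specific planted markers (a log2-scale
mean shift in the marker's signal class), collinear blocks of loci standing
in for miRNA families/clusters with shared expression, and a long tail of
low-expressed loci below the 10-RPM regime.  Expression is log-normal on the
RPM scale: log2-RPM = locus baseline + a shared within-block Gaussian factor
(weighted by the block correlation) + independent noise (+ the planted
effect), then exponentiated.  The matrix the generator returns is passed
through the same floor-at-1-RPM log2 transform as the real pipeline, so it
is distribution-compatible with matrices built from files.

Data can be emitted both as a ready matrix and as per-sample quantification
files (each locus split into 1-3 records sharing the 5' end but differing at
the 3' end) so the parser and aggregator are exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FivePrimeLocus
from .matrix import ExpressionMatrix, floored_log2

__all__ = ["SyntheticConfig", "GroundTruth", "generate_matrix", "emit_quantification_files"]

_DEFAULT_LABELS = [
    "BRCA", "LAML", "COAD", "KIRC", "LUAD", "PRAD",
    "THCA", "STAD", "HNSC", "LGG", "OV", "SKCM",
]

_FILE_HEADER = (
    "miRNA_ID\tisoform_coords\tread_count\treads_per_million_miRNA_mapped\t"
    "cross-mapped\tmiRNA_region\n"
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the tiny desk-scale study profile.

    Six classes with unbalanced sizes (8-40 samples, echoing the order-of-
    magnitude imbalance of real tumor cohorts), 300 candidate loci in
    collinear blocks of 3, 12 planted markers with a 4 log2-unit (16-fold)
    shift in their signal class — the scale of strong tissue-specific miRNA
    markers, chosen so a set containing all markers is close to
    Bayes-separable — and 40% of loci in the low-expression regime below
    10 RPM.
    """

    n_classes: int = 6
    samples_per_class: tuple[int, ...] = (8, 10, 12, 14, 20, 40)
    n_loci: int = 300
    n_informative: int = 12
    effect_size: float = 4.0
    block_size: int = 3
    block_correlation: float = 0.5
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.0
    low_expression_fraction: float = 0.4
    low_log2_mean: float = 1.0
    seed: int = 0
    class_labels: tuple[str, ...] | None = None
    informative_assignment: str = "round_robin"  # "round_robin" | "grouped"
    include_decoy: bool = True

    def __post_init__(self) -> None:
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class length must equal n_classes")
        if self.n_informative > self.n_loci:
            raise ValueError("n_informative cannot exceed n_loci")
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block_correlation must lie in [0, 1)")
        if self.informative_assignment not in ("round_robin", "grouped"):
            raise ValueError(f"unknown informative_assignment {self.informative_assignment!r}")

    def labels_list(self) -> list[str]:
        if self.class_labels is not None:
            if len(self.class_labels) != self.n_classes:
                raise ValueError("class_labels length must equal n_classes")
            return list(self.class_labels)
        if self.n_classes <= len(_DEFAULT_LABELS):
            return _DEFAULT_LABELS[: self.n_classes]
        return _DEFAULT_LABELS + [f"T{i:02d}" for i in range(len(_DEFAULT_LABELS), self.n_classes)]


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset, keyed by final feature IDs."""

    informative: dict[str, set[int]]  # class label -> feature IDs carrying its signal
    blocks: dict[int, int]  # feature ID -> block ID

    def informative_ids(self) -> set[int]:
        return set().union(*self.informative.values()) if self.informative else set()


def _make_loci(config: SyntheticConfig) -> list[FivePrimeLocus]:
    """Syntactically valid placeholder coordinates, one per raw locus index.

    Loci of a block share a chromosome and strand and sit close together,
    like a clustered miRNA family.  Positions are globally unique so every
    (chromosome, strand, position) triple is distinct.
    """
    loci = []
    for raw in range(config.n_loci):
        block = raw // config.block_size
        chrom = f"chr{(block % 9) + 1}"
        strand = "+" if block % 2 == 0 else "-"
        pos = 100_000 + raw * 1_000
        loci.append(FivePrimeLocus(chrom, strand, pos))
    return loci


def _assign_informative(
    config: SyntheticConfig, expressed: np.ndarray
) -> dict[int, int]:
    """Map raw locus index -> class index for the planted markers.

    ``round_robin`` spreads markers over distinct blocks and cycles through
    the classes, so every class gets markers and no block holds two.
    ``grouped`` gives each class a contiguous run of markers inside a single
    block, creating redundant same-class, same-block marker copies (classes
    earlier in the order receive the extra markers when counts are uneven).
    """
    expressed_set = set(expressed.tolist())
    by_block: dict[int, list[int]] = {}
    for raw in sorted(expressed_set):
        by_block.setdefault(raw // config.block_size, []).append(raw)
    blocks = sorted(by_block)
    assignment: dict[int, int] = {}
    if config.informative_assignment == "round_robin":
        i = 0
        for b in blocks:
            if i >= config.n_informative:
                break
            assignment[by_block[b][0]] = i % config.n_classes
            i += 1
        if i < config.n_informative:  # more markers than blocks: reuse blocks
            pool = [raw for b in blocks for raw in by_block[b][1:]]
            for raw in pool[: config.n_informative - i]:
                assignment[raw] = i % config.n_classes
                i += 1
    else:
        base = config.n_informative // config.n_classes
        extra = config.n_informative % config.n_classes
        counts = [base + (1 if c < extra else 0) for c in range(config.n_classes)]
        # Each class's markers come from a single block so same-class copies
        # are genuinely collinear; blocks too small for the class are skipped.
        block_iter = iter(blocks)
        for cls, need in enumerate(counts):
            members: list[int] = []
            while len(members) < need:
                members = by_block[next(block_iter)]
            for raw in members[:need]:
                assignment[raw] = cls
    if len(assignment) != config.n_informative:
        raise ValueError("not enough expressed loci/blocks to place the planted markers")
    return assignment


def _generate_raw(config: SyntheticConfig):
    """Sample the RPM matrix in the deterministic sorted-locus column order.

    Returns (rpm array samples x loci, sample_ids, labels, sorted loci,
    ground truth keyed by final feature IDs).
    """
    rng = np.random.default_rng(config.seed)
    labels_by_class = config.labels_list()
    labels: list[str] = []
    for cls, n in enumerate(config.samples_per_class):
        labels.extend([labels_by_class[cls]] * n)
    n_samples = len(labels)
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]

    n_low = int(round(config.low_expression_fraction * config.n_loci))
    low = rng.choice(config.n_loci, size=n_low, replace=False)
    mu = rng.normal(config.baseline_log2_mean, 1.0, size=config.n_loci)
    mu[low] = rng.normal(config.low_log2_mean, 0.75, size=n_low)
    expressed = np.setdiff1d(np.arange(config.n_loci), low)

    assignment = _assign_informative(config, expressed)

    n_blocks = -(-config.n_loci // config.block_size)
    z_block = rng.normal(size=(n_samples, n_blocks))
    eps = rng.normal(size=(n_samples, config.n_loci))
    rho = config.block_correlation
    block_of = np.arange(config.n_loci) // config.block_size
    noise = np.sqrt(rho) * z_block[:, block_of] + np.sqrt(1.0 - rho) * eps
    x = mu[None, :] + config.baseline_log2_sd * noise
    class_index = {lab: i for i, lab in enumerate(labels_by_class)}
    sample_class = np.array([class_index[lab] for lab in labels])
    for raw, cls in assignment.items():
        x[sample_class == cls, raw] += config.effect_size
    rpm = np.exp2(x)

    raw_loci = _make_loci(config)
    order = sorted(range(config.n_loci), key=lambda j: raw_loci[j].sort_key())
    rank = {raw: fid for fid, raw in enumerate(order)}
    loci = [raw_loci[j] for j in order]
    rpm = rpm[:, order]
    informative: dict[str, set[int]] = {lab: set() for lab in labels_by_class}
    for raw, cls in assignment.items():
        informative[labels_by_class[cls]].add(rank[raw])
    truth = GroundTruth(
        informative=informative,
        blocks={rank[raw]: int(raw // config.block_size) for raw in range(config.n_loci)},
    )
    return rpm, sample_ids, labels, loci, truth


def generate_matrix(config: SyntheticConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the ready expression matrix (floored log2 RPM) and its truth."""
    rpm, sample_ids, labels, loci, truth = _generate_raw(config)
    return ExpressionMatrix(floored_log2(rpm), sample_ids, labels, loci), truth


def _split_rpm(r: float, n_parts: int, rng: np.random.Generator) -> list[float]:
    """Split an RPM total into parts whose float sum recovers it to ~1 ulp."""
    if n_parts == 1:
        return [r]
    fracs = rng.uniform(0.2, 0.4, size=n_parts - 1)
    parts = [r * f for f in fracs]
    rest = r
    for p in parts:
        rest -= p
    parts.append(rest)
    return parts


def emit_quantification_files(config: SyntheticConfig, out_dir: str | Path) -> Path:
    """Write per-sample quantification files plus a manifest; returns the manifest path.

    Each locus's RPM is split into 1-3 records with the same 5' end and
    different 3' ends, so re-aggregating through the real parser reproduces
    the generated profile.  LAML-labelled samples get the blood-derived
    barcode infix ``03``, everything else ``01``; when ``include_decoy`` is
    set, one extra normal-tissue sample (infix ``11``) is written to exercise
    the sample-type filter.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rpm, sample_ids, labels, loci, _truth = _generate_raw(config)
    # Separate stream so record splitting never perturbs matrix generation.
    split_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 81]))
    manifest_rows = []
    for i, (sid, lab) in enumerate(zip(sample_ids, labels)):
        infix = "03" if lab == "LAML" else "01"
        barcode = f"TCGA-SY-{i:04d}-{infix}A-01R-0001-13"
        fname = f"{sid}.isoform.quantification.txt"
        _write_sample_file(out_dir / fname, rpm[i], loci, split_rng)
        manifest_rows.append((sid, barcode, lab, fname))
    if config.include_decoy:
        fname = "DECOY01.isoform.quantification.txt"
        _write_sample_file(out_dir / fname, rpm[0], loci, split_rng)
        manifest_rows.append(("DECOY01", "TCGA-SY-9999-11A-01R-0001-13", labels[0], fname))
    manifest_path = out_dir / "manifest.tsv"
    with open(manifest_path, "w", encoding="utf-8") as handle:
        handle.write("sample_id\tbarcode\ttumor_type\tfile_path\n")
        for row in manifest_rows:
            handle.write("\t".join(row) + "\n")
    return manifest_path


def _write_sample_file(
    path: Path,
    sample_rpm: np.ndarray,
    loci: list[FivePrimeLocus],
    rng: np.random.Generator,
) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(_FILE_HEADER)
        for j, locus in enumerate(loci):
            parts = _split_rpm(float(sample_rpm[j]), int(rng.integers(1, 4)), rng)
            for part_idx, part in enumerate(parts):
                length = 21 + part_idx
                if locus.strand == "+":
                    start, end = locus.five_prime_pos, locus.five_prime_pos + length
                else:
                    start, end = locus.five_prime_pos - length, locus.five_prime_pos
                coords = f"hg19:{locus.chromosome}:{start}-{end}:{locus.strand}"
                read_count = max(1, int(round(part * 10.0)))
                # 17 significant digits round-trips a double exactly.
                handle.write(
                    f"syn-mir-{j}\t{coords}\t{read_count}\t{float(part):.17g}\tN\tmature\n"
                )
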