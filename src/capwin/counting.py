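"""Read counting from BAM alignments into windows.

Counting rule: an alignment contributes to every window it overlaps by at
least 1 bp (any-overlap). Alignments that are unmapped, secondary,
supplementary, duplicate, or below the MAPQ cutoff are skipped. In paired
mode, properly paired reads are counted once per fragment using the fragment
interval (leftmost read start to leftmost start + |TLEN|); non-proper reads
still count individually.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
from intervaltree import IntervalTree

from .errors import ValidationError
from .experiment import ExperimentMatrix, SampleInfo
from .windows import WindowSet

DEFAULT_MIN_MAPQ = 10


def _passes_filters(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.mapping_quality < min_mapq
    )


def _read_interval(
    read: pysam.AlignedSegment, paired: bool
) -> tuple[int, int] | None:
    """Interval this record contributes, or None if deferred to its mate."""
    if paired and read.is_proper_pair and not read.mate_is_unmapped:
        # count each fragment once, from its leftmost read only
        if read.template_length < 0:
            return None
        if read.template_length == 0 and read.is_read2:
            return None
        start = read.reference_start
        return start, start + abs(read.template_length)
    return read.reference_start, read.reference_end


def count_reads(
    bam_path: str | Path,
    windows: WindowSet,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    paired: bool = False,
) -> np.ndarray:
    """Count qualifying alignments per window for one BAM.

    Returns one non-negative integer per window, in window order. Windows on
    chromosomes absent from the BAM header get zero counts with a warning.
    Requires a BAM index.
    """
    if len(windows) == 0:
        raise ValidationError("cannot count into an empty window set")
    trees: dict[str, IntervalTree] = {}
    index_of = {w.window_id: i for i, w in enumerate(windows)}
    for w in windows:
        trees.setdefault(w.chrom, IntervalTree())[w.start : w.end] = w.window_id
    counts = np.zeros(len(windows), dtype=np.int64)
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if not bam.has_index():
            raise IOError(f"{bam_path}: BAM index (.bai) required")
        header_chroms = set(bam.references)
        missing = [c for c in trees if c not in header_chroms]
        if missing:
            warnings.warn(
                f"{bam_path}: chromosomes absent from BAM header get zero "
                f"counts: {missing}",
                stacklevel=2,
            )
        for chrom, tree in trees.items():
            if chrom not in header_chroms:
                continue
            for read in bam.fetch(chrom):
                if not _passes_filters(read, min_mapq):
                    continue
                interval = _read_interval(read, paired)
                if interval is None:
                    continue
                start, end = interval
                if end <= start:
                    continue
                for hit in tree.overlap(start, end):
                    counts[index_of[hit.data]] += 1
    return counts


def build_experiment(
    samples: Sequence[SampleInfo],
    windows: WindowSet,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    paired: bool = False,
) -> ExperimentMatrix:
    """Assemble the window × sample count matrix from per-sample BAMs."""
    if len(windows) == 0:
        raise ValidationError("window set is empty")
    if not samples:
        raise ValidationError("no samples given")
    columns = []
    for s in samples:
        try:
            columns.append(count_reads(s.bam_path, windows, min_mapq, paired))
        except Exception as exc:
            raise type(exc)(f"sample {s.sample_id!r}: {exc}") from exc
    return ExperimentMatrix(
        windows=windows,
        samples=samples,
        counts=np.column_stack(columns),
    )
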