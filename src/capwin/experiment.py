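"""The central window × sample count container.

An :class:`ExperimentMatrix` holds an integer count matrix indexed by an
ordered :class:`~capwin.windows.WindowSet` (rows) and an ordered list of
:class:`SampleInfo` (columns), plus named derived layers of identical shape
(e.g. ``"normalized"``). Raw counts are never modified in place; processing
steps add layers.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .windows import GenomicWindow, TargetClass, WindowSet

SubsetBy = Literal["all", "on_target", "off_target", "control"]


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one sequenced sample."""

    sample_id: str
    treatment: str
    replicate: int
    bam_path: str = ""

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be >= 1"
            )


def read_sample_sheet(
    path: str | Path, check_bams: bool = True
) -> list[SampleInfo]:
    """Read a CSV sample sheet with columns sample_id, treatment, replicate, bam_path."""
    required = {"sample_id", "treatment", "replicate", "bam_path"}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            have = set(reader.fieldnames or [])
            raise SchemaError(
                f"{path}: sample sheet missing columns "
                f"{sorted(required - have)}"
            )
        samples = [
            SampleInfo(
                sample_id=row["sample_id"],
                treatment=row["treatment"],
                replicate=int(row["replicate"]),
                bam_path=row["bam_path"],
            )
            for row in reader
        ]
    _check_unique_samples(samples)
    if check_bams:
        for s in samples:
            if s.bam_path and not Path(s.bam_path).exists():
                raise IOError(
                    f"sample {s.sample_id!r}: BAM not found: {s.bam_path}"
                )
    return samples


def _check_unique_samples(samples: Sequence[SampleInfo]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample_id values: {dupes}")
    pairs = [(s.treatment, s.replicate) for s in samples]
    if len(set(pairs)) != len(pairs):
        raise ValidationError("duplicate (treatment, replicate) pairs")


class ExperimentMatrix:
    """Window × sample count matrix with annotations and derived layers."""

    def __init__(
        self,
        windows: WindowSet,
        samples: Sequence[SampleInfo],
        counts: np.ndarray,
        layers: dict[str, np.ndarray] | None = None,
        norm_factors=None,
    ):
        counts = np.asarray(counts)
        if counts.shape != (len(windows), len(samples)):
            raise ValidationError(
                f"counts shape {counts.shape} != "
                f"({len(windows)} windows, {len(samples)} samples)"
            )
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        _check_unique_samples(samples)
        self.windows = windows
        self.samples = list(samples)
        self.counts = counts.astype(np.int64, copy=False)
        self.layers: dict[str, np.ndarray] = {}
        for name, layer in (layers or {}).items():
            self.add_layer(name, layer)
        self.norm_factors = norm_factors

    # -- basic accessors ---------------------------------------------------

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def treatments(self) -> list[str]:
        return sorted({s.treatment for s in self.samples})

    def sample_index(self, sample_id: str) -> int:
        for i, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return i
        raise ValidationError(f"unknown sample {sample_id!r}")

    def treatment_columns(self, treatment: str) -> list[int]:
        cols = [i for i, s in enumerate(self.samples) if s.treatment == treatment]
        if not cols:
            raise ValidationError(f"unknown treatment {treatment!r}")
        return cols

    def add_layer(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != self.counts.shape:
            raise ValidationError(
                f"layer {name!r} shape {values.shape} != {self.counts.shape}"
            )
        if name in self.layers:
            warnings.warn(f"overwriting existing layer {name!r}", stacklevel=2)
        self.layers[name] = values

    def working_counts(self) -> np.ndarray:
        """The normalized layer if present, else the raw counts as float."""
        if "normalized" in self.layers:
            return self.layers["normalized"]
        return self.counts.astype(float)

    # -- subsetting --------------------------------------------------------

    def subset_by(self, by: SubsetBy = "all") -> "ExperimentMatrix":
        """Restrict to windows of one target class; ``all`` copies."""
        if by == "all":
            mask = np.ones(self.n_windows, dtype=bool)
        else:
            cls = TargetClass(by)
            mask = np.array(
                [w.target_class == cls for w in self.windows], dtype=bool
            )
        if not mask.any():
            raise ValidationError(f"no windows with target class {by!r}")
        sub_windows = WindowSet(
            w for w, keep in zip(self.windows, mask) if keep
        )
        return ExperimentMatrix(
            windows=sub_windows,
            samples=self.samples,
            counts=self.counts[mask],
            layers={k: v[mask] for k, v in self.layers.items()},
            norm_factors=self.norm_factors,
        )

    # -- pandas / disk interop --------------------------------------------

    def to_frame(self, layer: str | None = None) -> pd.DataFrame:
        values = self.counts if layer is None else self.layers[layer]
        return pd.DataFrame(
            values, index=self.windows.ids, columns=self.sample_ids
        )

    def to_tsv(self, path: str | Path, layer: str | None = None) -> None:
        df = self.to_frame(layer)
        df.index.name = "window_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        samples: Sequence[SampleInfo],
        windows: WindowSet | None = None,
    ) -> "ExperimentMatrix":
        """Build from a window_id × sample_id DataFrame.

        Without explicit windows, placeholder single-bp windows on a dummy
        chromosome are created so count-only workflows (e.g. normalize/detect
        on a saved TSV) do not require the original BED.
        """
        sample_ids = [s.sample_id for s in samples]
        missing = [s for s in sample_ids if s not in df.columns]
        if missing:
            raise SchemaError(f"count table missing sample columns {missing}")
        if windows is None:
            windows = WindowSet(
                GenomicWindow("unknown", i, i + 1, wid)
                for i, wid in enumerate(df.index.astype(str))
            )
        else:
            if list(df.index.astype(str)) != windows.ids:
                df = df.reindex(windows.ids)
                if df.isna().any().any():
                    raise ValidationError(
                        "count table rows do not match the window set"
                    )
        counts = df[sample_ids].to_numpy()
        if not np.allclose(counts, np.round(counts)):
            raise ValidationError("count table contains non-integer values")
        return cls(windows=windows, samples=samples, counts=counts.astype(np.int64))

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        samples: Sequence[SampleInfo],
        windows: WindowSet | None = None,
    ) -> "ExperimentMatrix":
        df = pd.read_csv(path, sep="\t", index_col="window_id")
        return cls.from_frame(df, samples, windows)
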