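"""Between-sample normalization for windowed capture-seq counts.

Four strategies are provided, all returning geometric-mean-centered
per-sample factors (product of factors = 1, so normalization changes
relative, not absolute, scale):

``library_size``
    factor_s = total_s / geometric mean of totals. Appropriate only when
    mean counts are reasonably high and few windows change.
``gof``
    Dynamic selection of the least-variable windows by a Pearson
    goodness-of-fit statistic across samples, then median-of-ratios factors
    over the selected windows. The recommended default: it finds stable
    anchor windows automatically regardless of how many windows change.
``control_windows``
    Median-of-ratios over user-nominated control windows assumed not to
    change.
``custom``
    User-supplied per-sample factors, centered on read.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .experiment import ExperimentMatrix
from .windows import WindowSet

GOF_QUANTILE = 0.25

# library-size heuristics: advisory only
_LIBSIZE_MIN_MEAN = 20.0
_LIBSIZE_MAX_CHANGING = 0.10


@dataclass(frozen=True)
class NormFactors:
    """Per-sample positive scale factors with provenance."""

    factors: np.ndarray
    method: str
    sample_ids: tuple[str, ...]
    windows_used: tuple[str, ...] = ()
    gof_quantile: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "factors", np.asarray(self.factors, dtype=float)
        )
        if np.any(self.factors <= 0) or not np.all(np.isfinite(self.factors)):
            raise ValidationError("normalization factors must be positive finite")

    def as_series(self) -> pd.Series:
        return pd.Series(self.factors, index=list(self.sample_ids))

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"sample_id": self.sample_ids, "factor": self.factors}
        )
        df.to_csv(path, index=False)


def _center(factors: np.ndarray) -> np.ndarray:
    """Divide by the geometric mean so the product of factors is 1."""
    factors = np.asarray(factors, dtype=float)
    return factors / np.exp(np.mean(np.log(factors)))


def library_size_factors(exp: ExperimentMatrix) -> NormFactors:
    """Factors proportional to total counts, geometric-mean centered."""
    totals = exp.counts.sum(axis=0).astype(float)
    if np.any(totals <= 0):
        bad = [s for s, t in zip(exp.sample_ids, totals) if t <= 0]
        raise ValidationError(f"samples with zero total count: {bad}")
    if totals.mean() / exp.n_windows < _LIBSIZE_MIN_MEAN:
        warnings.warn(
            "library-size normalization is unreliable at low mean counts "
            f"(< {_LIBSIZE_MIN_MEAN:g} per window); consider the GoF method",
            stacklevel=2,
        )
    return NormFactors(
        factors=_center(totals),
        method="library_size",
        sample_ids=tuple(exp.sample_ids),
    )


def gof_stats(exp: ExperimentMatrix) -> pd.DataFrame:
    """Per-window Pearson goodness-of-fit variability across samples.

    Counts are library-size-scaled first, so the statistic reflects
    biological/technical variability rather than sequencing depth. For
    window w with scaled values y_ws and mean mu_w > 0,
    gof_w = sum_s (y_ws - mu_w)^2 / mu_w. All-zero windows get gof = inf
    and are never selected as normalization anchors.

    Returns a DataFrame indexed by window_id with columns gof, rank,
    selected (selection flag filled in by :func:`gof_factors`; False here).
    """
    if exp.n_samples < 2:
        raise ValidationError("GoF needs >= 2 samples")
    lib = exp.counts.sum(axis=0).astype(float)
    if np.any(lib <= 0):
        raise ValidationError("GoF needs positive library sizes")
    scaled = exp.counts / _center(lib)
    mu = scaled.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        gof = np.where(
            mu > 0,
            ((scaled - mu[:, None]) ** 2).sum(axis=1) / np.where(mu > 0, mu, 1),
            np.inf,
        )
    order = np.argsort(gof, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(gof) + 1)
    return pd.DataFrame(
        {"gof": gof, "rank": rank, "selected": False},
        index=pd.Index(exp.windows.ids, name="window_id"),
    )


def _median_of_ratios(
    counts: np.ndarray, window_ids: Sequence[str]
) -> np.ndarray:
    """Median over windows of count_ws / geometric-mean-over-samples, centered.

    Windows where any sample has a zero count are dropped (their geometric
    mean reference is zero or the ratio degenerate), as in standard
    median-of-ratios estimators.
    """
    counts = np.asarray(counts, dtype=float)
    usable = np.all(counts > 0, axis=1)
    if not usable.any():
        raise ValidationError(
            "no usable windows for median-of-ratios factors "
            "(every candidate window has a zero count)"
        )
    y = counts[usable]
    ref = np.exp(np.mean(np.log(y), axis=1))
    factors = np.median(y / ref[:, None], axis=0)
    return _center(factors)


def gof_factors(
    exp: ExperimentMatrix, quantile: float = GOF_QUANTILE
) -> NormFactors:
    """Median-of-ratios factors over the lowest-GoF (most stable) windows.

    Windows with gof <= the given quantile of the finite-GoF distribution
    are selected as anchors.
    """
    if not 0 < quantile <= 1:
        raise ValidationError("quantile must be in (0, 1]")
    table = gof_stats(exp)
    finite = np.isfinite(table["gof"].to_numpy())
    if finite.sum() < 2:
        raise ValidationError("fewer than 2 windows with finite GoF")
    cutoff = np.quantile(table["gof"].to_numpy()[finite], quantile)
    selected = finite & (table["gof"].to_numpy() <= cutoff)
    if not selected.any():
        raise ValidationError("no windows selected by the GoF quantile")
    ids = tuple(table.index[selected])
    factors = _median_of_ratios(exp.counts[selected], ids)
    return NormFactors(
        factors=factors,
        method="gof",
        sample_ids=tuple(exp.sample_ids),
        windows_used=ids,
        gof_quantile=quantile,
    )


def control_window_factors(
    exp: ExperimentMatrix, controls: WindowSet | Sequence[str]
) -> NormFactors:
    """Median-of-ratios factors over user-nominated control windows."""
    if isinstance(controls, WindowSet):
        wanted = list(controls.ids)
        intervals = {(w.chrom, w.start, w.end) for w in controls}
    else:
        wanted = list(controls)
        intervals = set()
    present: list[int] = []
    id_set = set(wanted)
    for i, w in enumerate(exp.windows):
        if w.window_id in id_set or (w.chrom, w.start, w.end) in intervals:
            present.append(i)
    if not present:
        raise ValidationError(
            f"control windows not found in the experiment: {sorted(wanted)}"
        )
    ids = tuple(exp.windows[i].window_id for i in present)
    factors = _median_of_ratios(exp.counts[present], ids)
    return NormFactors(
        factors=factors,
        method="control_windows",
        sample_ids=tuple(exp.sample_ids),
        windows_used=ids,
    )


def custom_factors(
    exp: ExperimentMatrix, factors: "pd.Series | dict[str, float] | Sequence[float]"
) -> NormFactors:
    """Wrap user-supplied factors (by sample_id or in sample order), centered."""
    if isinstance(factors, dict):
        factors = pd.Series(factors)
    if isinstance(factors, pd.Series):
        missing = [s for s in exp.sample_ids if s not in factors.index]
        if missing:
            raise ValidationError(f"custom factors missing samples {missing}")
        values = factors.reindex(exp.sample_ids).to_numpy(dtype=float)
    else:
        values = np.asarray(list(factors), dtype=float)
        if len(values) != exp.n_samples:
            raise ValidationError(
                f"{len(values)} factors for {exp.n_samples} samples"
            )
    return NormFactors(
        factors=_center(values),
        method="custom",
        sample_ids=tuple(exp.sample_ids),
    )


def read_factors_csv(path: str | Path) -> pd.Series:
    """Read a sample_id,factor CSV into a Series."""
    df = pd.read_csv(path)
    if not {"sample_id", "factor"}.issubset(df.columns):
        raise ValidationError(f"{path}: expected columns sample_id,factor")
    return df.set_index("sample_id")["factor"]


def apply_factors(exp: ExperimentMatrix, nf: NormFactors) -> ExperimentMatrix:
    """Add the ``normalized`` layer (count / factor); raw counts untouched.

    Returns the same experiment object for chaining. Re-applying overwrites
    the layer with a warning.
    """
    if len(nf.factors) != exp.n_samples:
        raise ValidationError(
            f"{len(nf.factors)} factors for {exp.n_samples} samples"
        )
    if tuple(exp.sample_ids) != tuple(nf.sample_ids):
        raise ValidationError("factor sample order does not match experiment")
    exp.add_layer("normalized", exp.counts / nf.factors[None, :])
    exp.norm_factors = nf
    return exp


def normalize(
    exp: ExperimentMatrix,
    method: str = "gof",
    controls: WindowSet | Sequence[str] | None = None,
    factors=None,
    quantile: float = GOF_QUANTILE,
) -> ExperimentMatrix:
    """One-stop normalization: compute factors by ``method`` and apply them."""
    if method in {"library_size", "library"}:
        nf = library_size_factors(exp)
    elif method == "gof":
        nf = gof_factors(exp, quantile=quantile)
    elif method in {"control_windows", "controls"}:
        if controls is None:
            raise ValidationError("control-window normalization needs controls")
        nf = control_window_factors(exp, controls)
    elif method == "custom":
        if factors is None:
            raise ValidationError("custom normalization needs factors")
        nf = custom_factors(exp, factors)
    else:
        raise ValidationError(f"unknown normalization method {method!r}")
    return apply_factors(exp, nf)
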