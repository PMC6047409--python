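"""Experiment QC summaries and plot-ready statistics.

All diagnostics are computed as tidy tables; the plotting functions are a
thin rendering layer over those tables so every number is testable without
image comparison.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ValidationError
from .experiment import ExperimentMatrix
from .windows import TargetClass

MA_PSEUDOCOUNT = 0.5


def sample_summary(exp: ExperimentMatrix) -> pd.DataFrame:
    """Per-sample totals, on-target fraction, and count summaries.

    The on-target fraction of an all-zero sample is defined as 0.
    """
    on_mask = np.array(
        [w.target_class == TargetClass.ON_TARGET for w in exp.windows]
    )
    rows = []
    for j, s in enumerate(exp.samples):
        col = exp.counts[:, j]
        total = int(col.sum())
        on = int(col[on_mask].sum())
        rows.append(
            {
                "sample_id": s.sample_id,
                "treatment": s.treatment,
                "total_count": total,
                "on_target_count": on,
                "on_target_fraction": on / total if total > 0 else 0.0,
                "mean_count": float(col.mean()),
                "median_count": float(np.median(col)),
                "windows_nonzero": int((col > 0).sum()),
            }
        )
    return pd.DataFrame(rows)


def ma_values(
    exp: ExperimentMatrix,
    reference_sample: str,
    pseudocount: float = MA_PSEUDOCOUNT,
) -> pd.DataFrame:
    """M (log2 ratio) and A (mean log2 intensity) per window vs a reference.

    M = log2((x+c)/(ref+c)), A = 0.5*log2((x+c)*(ref+c)) with pseudocount c.
    """
    ref = exp.counts[:, exp.sample_index(reference_sample)].astype(float)
    frames = []
    for j, s in enumerate(exp.samples):
        x = exp.counts[:, j].astype(float)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": s.sample_id,
                    "window_id": exp.windows.ids,
                    "M": np.log2(x + pseudocount) - np.log2(ref + pseudocount),
                    "A": 0.5
                    * (np.log2(x + pseudocount) + np.log2(ref + pseudocount)),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def sample_similarity(
    exp: ExperimentMatrix, method: Literal["pearson", "spearman"] = "pearson"
) -> pd.DataFrame:
    """Sample × sample correlation of log2(count+1).

    Constant (zero-variance) samples get NaN rows/columns with a warning;
    the diagonal is always 1.
    """
    if exp.n_samples < 2:
        raise ValidationError("similarity needs >= 2 samples")
    log_counts = pd.DataFrame(
        np.log2(exp.counts + 1.0), columns=exp.sample_ids
    )
    constant = [c for c in log_counts if log_counts[c].nunique() == 1]
    if constant:
        warnings.warn(
            f"zero-variance samples in similarity matrix: {constant}",
            stacklevel=2,
        )
    corr = log_counts.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def coverage_density(
    exp: ExperimentMatrix, per: Literal["sample", "chromosome"] = "sample"
) -> pd.DataFrame:
    """Tidy (sample, chrom, window_id, count) table for density/histogram plots."""
    rows = {
        "sample_id": np.repeat(exp.sample_ids, exp.n_windows),
        "chrom": np.tile([w.chrom for w in exp.windows], exp.n_samples),
        "window_id": np.tile(exp.windows.ids, exp.n_samples),
        "count": exp.counts.T.ravel(),
    }
    df = pd.DataFrame(rows)
    if per == "chromosome":
        df = df.sort_values(
            ["chrom", "sample_id", "window_id"], kind="stable"
        ).reset_index(drop=True)
    return df


def render_plots(exp: ExperimentMatrix, outdir: str | Path) -> list[Path]:
    """Write the five standard QC figures; returns the files created.

    Figures: per-sample count density, MA vs the first sample, similarity
    heat map, on/off-target count density, GoF density. GoF falls back to
    all windows when no control windows are present.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .normalization import gof_stats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _save(fig, name: str) -> None:
        path = outdir / name
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    # count density
    fig, ax = plt.subplots(figsize=(6, 4))
    for j, sid in enumerate(exp.sample_ids):
        ax.hist(
            np.log2(exp.counts[:, j] + 1.0),
            bins=30,
            histtype="step",
            label=sid,
        )
    ax.set_xlabel("log2(count + 1)")
    ax.set_ylabel("windows")
    ax.legend(fontsize=6)
    _save(fig, "count_density.png")

    # MA vs first sample
    ma = ma_values(exp, exp.sample_ids[0])
    fig, ax = plt.subplots(figsize=(6, 4))
    for sid, grp in ma.groupby("sample_id"):
        ax.scatter(grp["A"], grp["M"], s=6, alpha=0.5, label=sid)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("A")
    ax.set_ylabel("M")
    ax.legend(fontsize=6)
    _save(fig, "ma_plot.png")

    # similarity heat map
    corr = sample_similarity(exp)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(corr.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(exp.n_samples), exp.sample_ids, rotation=90, fontsize=6)
    ax.set_yticks(range(exp.n_samples), exp.sample_ids, fontsize=6)
    fig.colorbar(im, ax=ax)
    _save(fig, "sample_similarity.png")

    # on/off target density
    classes = np.array([w.target_class.value for w in exp.windows])
    fig, ax = plt.subplots(figsize=(6, 4))
    for cls in np.unique(classes):
        vals = np.log2(exp.counts[classes == cls] + 1.0).ravel()
        ax.hist(vals, bins=30, histtype="step", density=True, label=cls)
    ax.set_xlabel("log2(count + 1)")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    _save(fig, "target_class_density.png")

    # GoF density (all windows if no controls nominated)
    gof = gof_stats(exp)
    has_controls = any(
        w.target_class == TargetClass.CONTROL for w in exp.windows
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    finite = gof["gof"].replace(np.inf, np.nan).dropna()
    if has_controls:
        ctrl_ids = set(exp.subset_by("control").windows.ids)
        is_ctrl = gof.index.isin(ctrl_ids)
        for label, mask in [("control", is_ctrl), ("non-control", ~is_ctrl)]:
            vals = np.log10(gof["gof"][mask].replace(np.inf, np.nan).dropna() + 1e-6)
            if len(vals):
                ax.hist(vals, bins=30, histtype="step", density=True, label=label)
        ax.legend(fontsize=8)
    else:
        ax.hist(np.log10(finite + 1e-6), bins=30, histtype="step", density=True)
    ax.set_xlabel("log10 GoF")
    ax.set_ylabel("density")
    _save(fig, "gof_density.png")

    return written
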