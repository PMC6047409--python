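"""Differential window abundance between two treatment groups.

Three detectors are provided:

``nb_exact``
    The classic conditional negative-binomial exact test with a single
    common dispersion phi, the statistical core of the edgeR exact test.
    Conditional on a window's total count T, the group-a sum follows a
    beta-binomial(T, n_a/phi, n_b/phi) distribution (binomial with
    p = n_a/(n_a+n_b) in the Poisson limit phi = 0), assuming counts have
    been normalized to a common effective library size. Two-sided p-values
    use the minimum-likelihood rule (sum of conditional probabilities no
    larger than the observed outcome's); the phi = 0 binomial case uses
    equal-tail doubling capped at 1.

``bootstrap_t``
    Welch t on log2(x+0.5)-transformed normalized counts, with a null
    distribution built by centering each group at its own mean and
    resampling with replacement within groups; p = (1 + k)/(B + 1) where k
    resampled |t*| reach |t_obs|.

``bayes_factor``
    Pooled-variance two-sample t converted to a JZS (Jeffreys–Zellner–Siow)
    Bayes factor BF10 with a Cauchy effect-size prior of scale r; windows
    with BF10 at or above a threshold are called.

Significance is strict (p < alpha, BF >= threshold) and unadjusted by
default; :func:`bh_adjust` offers optional Benjamini–Hochberg control.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .errors import ValidationError
from .experiment import ExperimentMatrix

JZS_R_SCALE = math.sqrt(2) / 2
_LOG_TIE_TOL = 1e-9  # outcomes this close in log-probability count as ties


@dataclass(frozen=True)
class TestConfig:
    """Shared settings for the differential tests."""

    alpha: float = 0.05
    bf_threshold: float = 1.5
    bootstrap_iterations: int = 1000
    rng_seed: int = 0
    transform: Literal["log2_pseudo", "none"] = "log2_pseudo"
    dispersion: float | None = None
    r_scale: float = JZS_R_SCALE

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.bf_threshold <= 1:
            raise ValidationError("bf_threshold must exceed 1")
        if self.bootstrap_iterations < 100:
            raise ValidationError("bootstrap_iterations must be >= 100")
        if self.dispersion is not None and self.dispersion < 0:
            raise ValidationError("dispersion must be non-negative")


def _transform(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "log2_pseudo":
        return np.log2(x + 0.5)
    if kind == "none":
        return np.asarray(x, dtype=float)
    raise ValidationError(f"unknown transform {kind!r}")


def _group_matrices(
    exp: ExperimentMatrix, group_a: str, group_b: str
) -> tuple[np.ndarray, np.ndarray]:
    y = exp.working_counts()
    a = y[:, exp.treatment_columns(group_a)]
    b = y[:, exp.treatment_columns(group_b)]
    return a, b


def _base_table(
    exp: ExperimentMatrix, a: np.ndarray, b: np.ndarray, method: str
) -> pd.DataFrame:
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    return pd.DataFrame(
        {
            "window_id": exp.windows.ids,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fc": np.log2(mean_b + 0.5) - np.log2(mean_a + 0.5),
            "statistic": np.nan,
            "p_value": np.nan,
            "bayes_factor": np.nan,
            "is_significant": False,
            "method": method,
        }
    )


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------


def estimate_common_dispersion(
    exp: ExperimentMatrix,
    groups: Sequence[str] | None = None,
) -> float:
    """Method-of-moments common NB dispersion across windows.

    Per window, the within-group variance is pooled over all groups with
    replication and compared with the mean of the group means mu:
    phi_w = max(0, (s2 - mu) / mu^2). The estimate is the median of phi_w
    over windows with mu > 0. Counts are taken from the normalized layer
    when present.
    """
    if groups is None:
        groups = exp.treatments
    y = exp.working_counts()
    cols = [exp.treatment_columns(g) for g in groups]
    replicated = [c for c in cols if len(c) >= 2]
    if not replicated:
        raise ValidationError(
            "no group has replication; supply the dispersion explicitly"
        )
    num = np.zeros(exp.n_windows)
    dof = 0
    means = []
    for c in replicated:
        sub = y[:, c]
        num += sub.var(axis=1, ddof=1) * (len(c) - 1)
        dof += len(c) - 1
        means.append(sub.mean(axis=1))
    s2 = num / dof
    mu = np.mean(means, axis=0)
    ok = mu > 0
    if not ok.any():
        return 0.0
    phi_w = np.maximum(0.0, (s2[ok] - mu[ok]) / mu[ok] ** 2)
    return float(np.median(phi_w))


# ---------------------------------------------------------------------------
# NB exact test
# ---------------------------------------------------------------------------


def _exact_p_poisson(k: int, total: int, n_a: int, n_b: int) -> float:
    """Equal-tail-doubled conditional binomial p at phi = 0."""
    if total == 0:
        return 1.0
    p = n_a / (n_a + n_b)
    lower = stats.binom.cdf(k, total, p)
    upper = stats.binom.sf(k - 1, total, p)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _exact_p_nb(
    k: int, total: int, n_a: int, n_b: int, dispersion: float
) -> float:
    """Minimum-likelihood two-sided p from the beta-binomial conditional law.

    The set of outcomes strictly more probable than the observed one is a
    contiguous run around the mode (the conditional pmf is unimodal); the
    p-value is one minus its probability, so ties with the observed outcome
    are included exactly once.
    """
    if total == 0:
        return 1.0
    dist = stats.betabinom(total, n_a / dispersion, n_b / dispersion)
    lp_obs = dist.logpmf(k)
    # locate the mode by local search from the conditional mean
    m = int(round(total * n_a / (n_a + n_b)))
    m = min(max(m, 0), total)
    while m + 1 <= total and dist.logpmf(m + 1) > dist.logpmf(m):
        m += 1
    while m - 1 >= 0 and dist.logpmf(m - 1) > dist.logpmf(m):
        m -= 1
    if dist.logpmf(m) <= lp_obs + _LOG_TIE_TOL:
        return 1.0

    def _boundary(lo: int, hi: int, increasing: bool) -> int:
        # first index (increasing side) / last index (decreasing side)
        # with logpmf strictly above the observed level
        while lo < hi:
            mid = (lo + hi) // 2 if increasing else (lo + hi + 1) // 2
            above = dist.logpmf(mid) > lp_obs + _LOG_TIE_TOL
            if increasing:
                if above:
                    hi = mid
                else:
                    lo = mid + 1
            else:
                if above:
                    lo = mid
                else:
                    hi = mid - 1
        return lo

    left = _boundary(0, m, increasing=True)
    right = _boundary(m, total, increasing=False)
    inside = dist.pmf(np.arange(left, right + 1)).sum()
    return float(min(1.0, max(0.0, 1.0 - inside)))


def nb_exact_p(
    y_a: int, y_b: int, n_a: int, n_b: int, dispersion: float
) -> float:
    """Two-sided exact p for group sums (y_a, y_b) from groups of size n_a, n_b."""
    if dispersion < 0:
        raise ValidationError("dispersion must be non-negative")
    total = int(y_a) + int(y_b)
    if dispersion == 0:
        return _exact_p_poisson(int(y_a), total, n_a, n_b)
    return _exact_p_nb(int(y_a), total, n_a, n_b, dispersion)


def nb_exact_test(
    exp: ExperimentMatrix,
    group_a: str,
    group_b: str,
    cfg: TestConfig = TestConfig(),
) -> pd.DataFrame:
    """Common-dispersion conditional NB exact test per window.

    Counts are taken from the normalized layer (rounded group sums), so the
    equal-effective-library-size assumption of the conditional argument
    holds after normalization.
    """
    a, b = _group_matrices(exp, group_a, group_b)
    n_a, n_b = a.shape[1], b.shape[1]
    phi = (
        cfg.dispersion
        if cfg.dispersion is not None
        else estimate_common_dispersion(exp, [group_a, group_b])
    )
    table = _base_table(exp, a, b, "nb_exact")
    sums_a = np.rint(a.sum(axis=1)).astype(np.int64)
    sums_b = np.rint(b.sum(axis=1)).astype(np.int64)
    table["p_value"] = [
        nb_exact_p(ya, yb, n_a, n_b, phi) for ya, yb in zip(sums_a, sums_b)
    ]
    table["is_significant"] = table["p_value"] < cfg.alpha
    return table


# ---------------------------------------------------------------------------
# bootstrap t test
# ---------------------------------------------------------------------------


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Welch t along the last axis; 0/0 -> 0, x/0 -> +-inf."""
    n_a, n_b = a.shape[-1], b.shape[-1]
    num = a.mean(axis=-1) - b.mean(axis=-1)
    den = np.sqrt(a.var(axis=-1, ddof=1) / n_a + b.var(axis=-1, ddof=1) / n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / den
        t = np.where(
            den == 0, np.where(num == 0, 0.0, np.sign(num) * np.inf), t
        )
    return t


def bootstrap_t_test(
    exp: ExperimentMatrix,
    group_a: str,
    group_b: str,
    cfg: TestConfig = TestConfig(),
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Bootstrap Welch t test on transformed normalized counts.

    The null is enforced by centering each group at its own mean; the
    centered residuals of both groups are then pooled, and null groups of
    the original sizes are drawn from the pool with replacement. Pooling
    doubles the resampling support, which keeps the tail of the null t*
    distribution honest at small replicate numbers where within-group
    resampling is too coarse. Per-window RNG substreams are derived from
    (rng_seed, window index) so results are reproducible and independent of
    evaluation order. With ``exhaustive=True`` every resample combination
    is enumerated instead of sampled (feasible only for tiny groups); the
    same (1+k)/(B+1) estimator is used.
    """
    a, b = _group_matrices(exp, group_a, group_b)
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValidationError("bootstrap t needs >= 2 replicates per group")
    ta = _transform(a, cfg.transform)
    tb = _transform(b, cfg.transform)
    t_obs = _welch_t(ta, tb)
    table = _base_table(exp, a, b, "bootstrap_t")
    table["statistic"] = t_obs

    n_pool = n_a + n_b
    if exhaustive:
        idx_a = np.array(
            list(itertools.product(range(n_pool), repeat=n_a)), dtype=np.intp
        )
        idx_b = np.array(
            list(itertools.product(range(n_pool), repeat=n_b)), dtype=np.intp
        )
        # all cross combinations of pool draws for the two null groups
        rep_a = np.repeat(idx_a, len(idx_b), axis=0)
        rep_b = np.tile(idx_b, (len(idx_a), 1))
        B = len(rep_a)
        if B > 2_000_000:
            raise ValidationError(
                f"exhaustive enumeration infeasible: {B} resamples"
            )
    else:
        B = cfg.bootstrap_iterations

    p_values = np.empty(exp.n_windows)
    for w in range(exp.n_windows):
        pool = np.concatenate([ta[w] - ta[w].mean(), tb[w] - tb[w].mean()])
        if exhaustive:
            t_star = _welch_t(pool[rep_a], pool[rep_b])
        else:
            rng = np.random.default_rng([cfg.rng_seed, w])
            t_star = _welch_t(
                pool[rng.integers(0, n_pool, size=(B, n_a))],
                pool[rng.integers(0, n_pool, size=(B, n_b))],
            )
        # a degenerate resample (no within-group variability) carries no
        # Studentized evidence; counting it as infinitely extreme would give
        # a single atom unbounded weight
        t_star = np.where(np.isfinite(t_star), t_star, 0.0)
        k = int(np.count_nonzero(np.abs(t_star) >= abs(t_obs[w])))
        p_values[w] = (1 + k) / (B + 1)
    table["p_value"] = p_values
    table["is_significant"] = table["p_value"] < cfg.alpha
    return table


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------


def jzs_bayes_factor(
    t: float, n_a: int, n_b: int, r_scale: float = JZS_R_SCALE
) -> float:
    """Two-sample JZS Bayes factor BF10 for a t statistic.

    The alternative places a Cauchy(0, r) prior on the standardized effect
    (equivalently a scaled inverse-chi^2 mixture over the variance ratio g),
    giving the one-dimensional integral over g evaluated here by adaptive
    quadrature; the null marginal is the central t density term. BF10 > 1
    favours a mean difference.
    """
    if not np.isfinite(t):
        raise ValidationError("t statistic must be finite")
    if n_a < 2 or n_b < 2:
        raise ValidationError("need >= 2 observations per group")
    if r_scale <= 0:
        raise ValidationError("r_scale must be positive")
    nu = n_a + n_b - 2
    N = n_a * n_b / (n_a + n_b)
    r2 = r_scale**2
    t2 = t * t

    def log_f(g: np.ndarray) -> np.ndarray:
        a = 1.0 + N * g * r2
        return (
            -0.5 * np.log(a)
            - (nu + 1) / 2 * np.log1p(t2 / (a * nu))
            - 0.5 * np.log(2 * np.pi)
            - 1.5 * np.log(g)
            - 1.0 / (2.0 * g)
        )

    # rescale by the integrand's peak so quadrature works at extreme t
    grid = np.logspace(-6, 6, 400)
    m = float(np.max(log_f(grid)))
    val, _ = integrate.quad(
        lambda g: math.exp(log_f(np.asarray(g)) - m),
        0.0,
        np.inf,
        epsabs=0.0,
        epsrel=1e-10,
        limit=400,
    )
    log_null = -(nu + 1) / 2 * math.log1p(t2 / nu)
    return math.exp(m + math.log(val) - log_null)


def bayes_factor_t_test(
    exp: ExperimentMatrix,
    group_a: str,
    group_b: str,
    cfg: TestConfig = TestConfig(),
) -> pd.DataFrame:
    """JZS Bayes factor per window from the pooled-variance two-sample t.

    Windows with zero pooled variance get BF10 = 1 (no evidence) with a
    warning.
    """
    a, b = _group_matrices(exp, group_a, group_b)
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValidationError("Bayes factor t needs >= 2 replicates per group")
    ta = _transform(a, cfg.transform)
    tb = _transform(b, cfg.transform)
    nu = n_a + n_b - 2
    sp2 = (
        ta.var(axis=1, ddof=1) * (n_a - 1) + tb.var(axis=1, ddof=1) * (n_b - 1)
    ) / nu
    num = ta.mean(axis=1) - tb.mean(axis=1)
    den = np.sqrt(sp2 * (1 / n_a + 1 / n_b))
    table = _base_table(exp, a, b, "bayes_factor")
    bf = np.ones(exp.n_windows)
    t_stat = np.zeros(exp.n_windows)
    degenerate = den == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} windows with zero pooled variance; "
            "their Bayes factor is set to 1",
            stacklevel=2,
        )
    for w in range(exp.n_windows):
        if degenerate[w]:
            continue
        t_stat[w] = num[w] / den[w]
        bf[w] = jzs_bayes_factor(t_stat[w], n_a, n_b, cfg.r_scale)
    table["statistic"] = t_stat
    table["bayes_factor"] = bf
    table["is_significant"] = table["bayes_factor"] >= cfg.bf_threshold
    return table


# ---------------------------------------------------------------------------
# front door
# ---------------------------------------------------------------------------

METHODS = {
    "nb_exact": nb_exact_test,
    "bootstrap_t": bootstrap_t_test,
    "bayes_factor": bayes_factor_t_test,
}


def detect(
    exp: ExperimentMatrix,
    group_a: str,
    group_b: str,
    method: str = "nb_exact",
    cfg: TestConfig = TestConfig(),
) -> pd.DataFrame:
    """Run one detector by name."""
    if method not in METHODS:
        raise ValidationError(
            f"unknown method {method!r}; choose from {sorted(METHODS)}"
        )
    return METHODS[method](exp, group_a, group_b, cfg)


def compare_to_reference(
    exp: ExperimentMatrix,
    reference_treatment: str,
    method: str = "nb_exact",
    cfg: TestConfig = TestConfig(),
) -> dict[str, pd.DataFrame]:
    """Test every non-reference treatment against a common reference."""
    exp.treatment_columns(reference_treatment)  # validates
    others = [t for t in exp.treatments if t != reference_treatment]
    if not others:
        raise ValidationError(
            f"no treatments other than the reference {reference_treatment!r}"
        )
    return {
        t: detect(exp, reference_treatment, t, method, cfg) for t in others
    }


def bh_adjust(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Optional Benjamini–Hochberg layer over a p-value detection table."""
    from statsmodels.stats.multitest import multipletests

    if table["p_value"].isna().all():
        raise ValidationError("table has no p-values to adjust")
    out = table.copy()
    reject, q, _, _ = multipletests(
        out["p_value"].to_numpy(), alpha=alpha, method="fdr_bh"
    )
    out["q_value"] = q
    out["is_significant"] = reject
    return out
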