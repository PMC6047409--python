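import itertools
import math
import shutil
import subprocess

import numpy as np
import pytest
from scipy import stats

from capwin.differential import (
    TestConfig,
    bayes_factor_t_test,
    bh_adjust,
    bootstrap_t_test,
    compare_to_reference,
    estimate_common_dispersion,
    jzs_bayes_factor,
    nb_exact_p,
    nb_exact_test,
)
from capwin.errors import ValidationError
from capwin.normalization import normalize
from capwin.simulate import BUILTIN_BASE_COUNTS, SimulationSpec, simulate_experiment
from conftest import make_experiment


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def conditional_binomial_p(k, total, n_a, n_b):
    """Equal-tail doubled binomial p by explicit enumeration."""
    if total == 0:
        return 1.0
    p = n_a / (n_a + n_b)
    pmf = [math.comb(total, i) * p**i * (1 - p) ** (total - i) for i in range(total + 1)]
    lower = sum(pmf[: k + 1])
    upper = sum(pmf[k:])
    return min(1.0, 2 * min(lower, upper))


def conditional_nb_p(k, total, n_a, n_b, phi, mu=10.0):
    """Minimum-likelihood p by brute-force summation over all splits of the
    total, using normalized products of NB pmfs."""
    r_a, r_b = n_a / phi, n_b / phi
    p = 1.0 / (1.0 + phi * mu)
    ks = np.arange(total + 1)
    w = stats.nbinom.pmf(ks, r_a, p) * stats.nbinom.pmf(total - ks, r_b, p)
    w = w / w.sum()
    return float(w[w <= w[k] * (1 + 1e-10)].sum())


def jzs_oracle(t, n_a, n_b, r=math.sqrt(2) / 2):
    """High-precision JZS Bayes factor via mpmath quadrature."""
    import mpmath as mp

    nu = n_a + n_b - 2
    N = mp.mpf(n_a) * n_b / (n_a + n_b)
    r2 = mp.mpf(r) ** 2
    t = mp.mpf(t)

    def f(g):
        a = 1 + N * g * r2
        return (
            a ** mp.mpf("-0.5")
            * (1 + t**2 / (a * nu)) ** (-(nu + 1) / mp.mpf(2))
            / mp.sqrt(2 * mp.pi)
            * g ** mp.mpf("-1.5")
            * mp.exp(-1 / (2 * g))
        )

    num = mp.quad(f, [0, 1, mp.inf])
    den = (1 + t**2 / nu) ** (-(nu + 1) / mp.mpf(2))
    return float(num / den)


def welch_t_scalar(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    num = a.mean() - b.mean()
    den = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    if den == 0:
        return 0.0 if num == 0 else math.copysign(math.inf, num)
    return num / den


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------


class TestDispersion:
    def _sim_counts(self, rng, phi, reps=10, n_windows=52, min_mean=100):
        means = rng.choice(
            [m for m in BUILTIN_BASE_COUNTS if m >= min_mean], n_windows
        ).astype(float)
        mu = np.tile(means[:, None], (1, 2 * reps))
        if phi == 0:
            return rng.poisson(mu)
        r = 1 / phi
        return rng.negative_binomial(r, r / (r + mu))

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(10)
        exp = make_experiment(self._sim_counts(rng, phi=0.0))
        assert estimate_common_dispersion(exp) <= 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(11)
        exp = make_experiment(self._sim_counts(rng, phi=0.2))
        assert 0.1 <= estimate_common_dispersion(exp) <= 0.3

    def test_constant_windows_zero_dispersion(self):
        exp = make_experiment(np.full((5, 6), 40))
        assert estimate_common_dispersion(exp) == 0.0

    def test_no_replication_errors(self):
        exp = make_experiment([[1, 2], [3, 4]], treatments=["a", "b"])
        with pytest.raises(ValidationError, match="dispersion"):
            estimate_common_dispersion(exp)


# ---------------------------------------------------------------------------
# NB exact test
# ---------------------------------------------------------------------------


class TestNbExactP:
    def test_balanced_split_p_one(self):
        assert nb_exact_p(5, 5, 3, 3, 0.0) == pytest.approx(1.0)

    def test_extreme_split_doubled_tail(self):
        # all 10 counts in one group, equal group sizes
        assert nb_exact_p(0, 10, 4, 4, 0.0) == pytest.approx(2 * 0.5**10)

    def test_poisson_case_matches_enumeration_grid(self):
        """phi=0 agrees with explicit binomial enumeration to 1e-12."""
        for n_a, n_b in [(1, 1), (2, 3), (5, 5), (3, 1)]:
            for total in (0, 1, 7, 23):
                for k in range(total + 1):
                    assert nb_exact_p(k, total - k, n_a, n_b, 0.0) == pytest.approx(
                        conditional_binomial_p(k, total, n_a, n_b), abs=1e-12
                    )

    def test_nb_case_matches_bruteforce_oracle(self):
        """phi>0 minimum-likelihood p agrees with summation over all splits."""
        for phi in (0.05, 0.5, 2.0):
            for n_a, n_b in [(3, 3), (2, 5)]:
                for ya, yb in [(2, 20), (0, 9), (10, 10), (33, 12)]:
                    got = nb_exact_p(ya, yb, n_a, n_b, phi)
                    want = conditional_nb_p(ya, ya + yb, n_a, n_b, phi)
                    assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValidationError):
            nb_exact_p(1, 1, 2, 2, -0.1)


class TestNbExactTable:
    def test_label_swap_negates_fc_keeps_p(self):
        rng = np.random.default_rng(12)
        exp = make_experiment(rng.integers(20, 400, size=(10, 6)))
        normalize(exp, method="library")
        cfg = TestConfig(dispersion=0.1)
        ab = nb_exact_test(exp, "control", "treatment", cfg)
        ba = nb_exact_test(exp, "treatment", "control", cfg)
        np.testing.assert_allclose(ab["p_value"], ba["p_value"], atol=1e-12)
        np.testing.assert_allclose(ab["log2_fc"], -ba["log2_fc"], atol=1e-12)

    def test_matches_edger_smallp(self, tmp_path):
        """Cross-check against edgeR's exact test with the min-likelihood
        (smallp) rejection region, run through Rscript."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(13)
        counts = rng.integers(10, 100, size=(9, 6))
        # equalize column totals so no pseudo-count adjustment happens
        target = counts.sum(axis=0).max() + 50
        counts = np.vstack([counts, target - counts.sum(axis=0)])
        phi = 0.1
        exp = make_experiment(counts)
        exp.add_layer("normalized", counts.astype(float))
        table = nb_exact_test(
            exp, "control", "treatment", TestConfig(dispersion=phi)
        )
        np.savetxt(tmp_path / "counts.txt", counts, fmt="%d")
        script = tmp_path / "oracle.R"
        script.write_text(
            f"""
            suppressMessages(library(edgeR))
            counts <- as.matrix(read.table("{tmp_path}/counts.txt"))
            group <- factor(c(1,1,1,2,2,2))
            d <- DGEList(counts=counts, group=group)
            res <- exactTest(d, dispersion={phi}, rejection.region="smallp")
            write(res$table$PValue, "{tmp_path}/pvals.txt", ncolumns=1)
            """
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        edger_p = np.loadtxt(tmp_path / "pvals.txt")
        np.testing.assert_allclose(table["p_value"], edger_p, rtol=1e-6)


# ---------------------------------------------------------------------------
# bootstrap t
# ---------------------------------------------------------------------------


class TestBootstrapT:
    def test_identical_groups_p_one(self):
        counts = np.tile([[40], [90], [10]], (1, 6))
        exp = make_experiment(counts)
        exp.add_layer("normalized", counts.astype(float))
        table = bootstrap_t_test(exp, "control", "treatment", TestConfig(rng_seed=1))
        np.testing.assert_allclose(table["p_value"], 1.0)

    def test_separated_groups_near_minimum_p(self):
        """A 5x separation with tight replicates sits at the bottom of the
        resampled null. Resampling a 6-atom pool occasionally draws
        near-degenerate groups with tiny variance and hence huge |t*|, so p
        reaches the floor only up to those rare atoms; the exact count is
        frozen for the fixed seed."""
        counts = np.array([[100, 101, 99, 500, 502, 498]])
        exp = make_experiment(counts)
        exp.add_layer("normalized", counts.astype(float))
        cfg = TestConfig(bootstrap_iterations=1000, rng_seed=99)
        table = bootstrap_t_test(exp, "control", "treatment", cfg)
        assert table["p_value"].item() <= 5 / 1001
        assert table["p_value"].item() == pytest.approx(3 / 1001)

    def test_exhaustive_matches_independent_enumeration(self):
        """n=2 per group: p equals the exhaustively enumerated resampling
        distribution, computed here with plain loops."""
        counts = np.array([[12, 19, 31, 24]])
        exp = make_experiment(counts, treatments=["a", "a", "b", "b"])
        exp.add_layer("normalized", counts.astype(float))
        cfg = TestConfig(transform="none", rng_seed=0)
        table = bootstrap_t_test(exp, "a", "b", cfg, exhaustive=True)

        a, b = [12.0, 19.0], [31.0, 24.0]
        t_obs = welch_t_scalar(a, b)
        pool = [x - np.mean(a) for x in a] + [x - np.mean(b) for x in b]
        k = 0
        n_resamples = 0
        for ia in itertools.product(range(4), repeat=2):
            for ib in itertools.product(range(4), repeat=2):
                t_star = welch_t_scalar(
                    [pool[i] for i in ia], [pool[i] for i in ib]
                )
                if math.isinf(t_star):
                    t_star = 0.0  # degenerate resample: no evidence
                n_resamples += 1
                if abs(t_star) >= abs(t_obs):
                    k += 1
        assert n_resamples == 256
        assert table["p_value"].item() == pytest.approx((1 + k) / 257, abs=0)

    def test_label_swap_invariant_under_enumeration(self):
        counts = np.array([[5, 9, 14, 11]])
        exp = make_experiment(counts, treatments=["a", "a", "b", "b"])
        exp.add_layer("normalized", counts.astype(float))
        cfg = TestConfig(transform="none")
        p_ab = bootstrap_t_test(exp, "a", "b", cfg, exhaustive=True)["p_value"]
        p_ba = bootstrap_t_test(exp, "b", "a", cfg, exhaustive=True)["p_value"]
        np.testing.assert_allclose(p_ab, p_ba)

    def test_zero_variance_conventions(self):
        counts = np.array([[10, 10, 10, 10], [10, 10, 50, 50]])
        exp = make_experiment(counts, treatments=["a", "a", "b", "b"])
        exp.add_layer("normalized", counts.astype(float))
        table = bootstrap_t_test(exp, "a", "b", TestConfig(rng_seed=5))
        B = 1000
        assert table["p_value"][0] == pytest.approx(1.0)
        assert table["p_value"][1] == pytest.approx(1 / (B + 1))

    def test_single_replicate_rejected(self):
        exp = make_experiment([[1, 2]], treatments=["a", "b"])
        with pytest.raises(ValidationError):
            bootstrap_t_test(exp, "a", "b")


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------


class TestJzsBayesFactor:
    def test_null_t_favours_null(self):
        assert jzs_bayes_factor(0.0, 5, 5) < 1.0

    def test_matches_mpmath_oracle(self):
        for t, n in [(0.0, 5), (1.5, 3), (2.5, 10), (4.0, 20)]:
            got = jzs_bayes_factor(t, n, n)
            want = jzs_oracle(t, n, n)
            assert got == pytest.approx(want, rel=1e-6)

    def test_strictly_increasing_in_t(self):
        bfs = [jzs_bayes_factor(t, 10, 10) for t in (0, 1, 2, 3, 4)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_nonfinite_t_rejected(self):
        with pytest.raises(ValidationError):
            jzs_bayes_factor(math.inf, 5, 5)


class TestBayesFactorTable:
    def test_identical_groups_not_significant(self):
        counts = np.tile([[40], [90]], (1, 6)) + np.array([0, 1, 2, 0, 1, 2])
        exp = make_experiment(counts)
        exp.add_layer("normalized", counts.astype(float))
        table = bayes_factor_t_test(exp, "control", "treatment",
                                    TestConfig(bf_threshold=1.1))
        assert (table["bayes_factor"] < 1).all()
        assert not table["is_significant"].any()

    def test_strong_t_significant_at_threshold_two(self):
        # t about 5 with 3+3 gives BF10 comfortably above 2 (oracle > 4)
        counts = np.array([[100, 104, 102, 151, 155, 153]])
        exp = make_experiment(counts)
        exp.add_layer("normalized", counts.astype(float))
        table = bayes_factor_t_test(
            exp, "control", "treatment",
            TestConfig(bf_threshold=2.0, transform="none"),
        )
        t = table["statistic"].item()
        assert abs(t) > 5
        assert table["bayes_factor"].item() == pytest.approx(
            jzs_oracle(t, 3, 3, math.sqrt(2) / 2), rel=1e-6
        )
        assert bool(table["is_significant"].item())

    def test_threshold_nesting(self):
        rng = np.random.default_rng(21)
        exp = make_experiment(rng.integers(50, 400, size=(30, 6)))
        normalize(exp, method="library")
        loose = bayes_factor_t_test(exp, "control", "treatment",
                                    TestConfig(bf_threshold=1.1))
        strict = bayes_factor_t_test(exp, "control", "treatment",
                                     TestConfig(bf_threshold=2.0))
        called_loose = set(loose.loc[loose["is_significant"], "window_id"])
        called_strict = set(strict.loc[strict["is_significant"], "window_id"])
        assert called_strict <= called_loose

    def test_zero_variance_bf_one_with_warning(self):
        counts = np.full((1, 4), 7)
        exp = make_experiment(counts, treatments=["a", "a", "b", "b"])
        exp.add_layer("normalized", counts.astype(float))
        with pytest.warns(UserWarning, match="zero pooled variance"):
            table = bayes_factor_t_test(exp, "a", "b")
        assert table["bayes_factor"].item() == 1.0

    def test_label_swap_keeps_bf(self):
        rng = np.random.default_rng(22)
        exp = make_experiment(rng.integers(50, 400, size=(8, 6)))
        normalize(exp, method="library")
        ab = bayes_factor_t_test(exp, "control", "treatment")
        ba = bayes_factor_t_test(exp, "treatment", "control")
        np.testing.assert_allclose(ab["bayes_factor"], ba["bayes_factor"],
                                   rtol=1e-9)
        np.testing.assert_allclose(ab["log2_fc"], -ba["log2_fc"], atol=1e-12)


# ---------------------------------------------------------------------------
# multi-treatment comparisons, separation power, BH
# ---------------------------------------------------------------------------


class TestCompareToReference:
    def _three_treatment_exp(self):
        rng = np.random.default_rng(30)
        return make_experiment(
            rng.integers(50, 400, size=(10, 6)),
            treatments=["ctrl", "ctrl", "t1", "t1", "t2", "t2"],
        )

    def test_one_table_per_non_reference(self):
        exp = self._three_treatment_exp()
        normalize(exp, method="library")
        tables = compare_to_reference(exp, "ctrl", "nb_exact",
                                      TestConfig(dispersion=0.1))
        assert set(tables) == {"t1", "t2"}

    def test_matches_pairwise_calls(self):
        exp = self._three_treatment_exp()
        normalize(exp, method="library")
        cfg = TestConfig(dispersion=0.1)
        tables = compare_to_reference(exp, "ctrl", "nb_exact", cfg)
        direct = nb_exact_test(exp, "ctrl", "t1", cfg)
        np.testing.assert_allclose(
            tables["t1"]["p_value"], direct["p_value"], atol=0
        )

    def test_unknown_reference_errors(self):
        exp = self._three_treatment_exp()
        with pytest.raises(ValidationError):
            compare_to_reference(exp, "nope")

    def test_reference_alone_errors(self):
        exp = make_experiment(
            np.ones((3, 2), dtype=int), treatments=["ctrl", "ctrl"]
        )
        with pytest.raises(ValidationError):
            compare_to_reference(exp, "ctrl")


def test_all_methods_full_recall_on_separated_fixture():
    """Fold-100 changes on high-count windows are found by every method."""
    spec = SimulationSpec(
        n_windows=20,
        replicates=10,
        n_changed=5,
        fold_change=100.0,
        noise_cv=0.05,
        base_counts=tuple(c for c in BUILTIN_BASE_COUNTS if c >= 500),
        rng_seed=77,
    )
    exp, truth = simulate_experiment(spec)
    normalize(exp)
    for method in ("nb_exact", "bootstrap_t", "bayes_factor"):
        from capwin.differential import detect

        table = detect(exp, "control", "treatment", method,
                       TestConfig(rng_seed=77))
        calls = set(table.loc[table["is_significant"], "window_id"])
        assert truth <= calls, method


def test_bh_adjust_controls_calls():
    rng = np.random.default_rng(40)
    exp = make_experiment(rng.integers(20, 400, size=(20, 6)))
    normalize(exp, method="library")
    raw = nb_exact_test(exp, "control", "treatment", TestConfig(dispersion=0.05))
    adj = bh_adjust(raw, alpha=0.05)
    assert "q_value" in adj
    assert (adj["q_value"] >= raw["p_value"] - 1e-15).all()
    assert adj["is_significant"].sum() <= (raw["p_value"] < 0.05).sum()
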