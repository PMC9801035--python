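"""psi algebra, marginal likelihood, LRTs, FDR and the Fisher baseline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, gammaln, logit, logsumexp
from scipy.stats import binom, hypergeom, norm

from circdec import (
    CircLocus,
    CjcTable,
    EffectiveLengths,
    GroupDesign,
    LjcTable,
    bh_fdr,
    binomial_rate,
    compute_psi,
    fisher_baseline,
    loglik_group,
    lrt_paired,
    lrt_unpaired,
    run_dec,
)

EL_LARGE = EffectiveLengths(150, 10, 1000)  # e >= 2L
EL_SMALL = EffectiveLengths(110, 10, 100)  # L = 100, e = 100 < 2L


# ------------------------------------------------------------------ psi


class TestPsi:
    def test_large_circle_example(self):
        assert compute_psi(10, 20, EL_LARGE) == pytest.approx(0.5)

    def test_boundaries(self):
        assert compute_psi(0, 5, EL_LARGE) == 0.0
        assert compute_psi(5, 0, EL_LARGE) == 1.0
        assert math.isnan(compute_psi(0, 0, EL_LARGE))

    def test_small_circle_example(self):
        # L = 100, e = 100: Il = 300, Ic = 100
        assert compute_psi(10, 20, EL_SMALL) == pytest.approx(0.6)

    def test_large_circle_identity_on_grid(self):
        """For e >= 2L, psi == CJC/(LJC/2 + CJC) exactly."""
        rng = np.random.default_rng(0)
        for _ in range(300):
            read_len = int(rng.integers(50, 300))
            oh = int(rng.integers(0, read_len - 1))
            L = read_len - oh
            e = int(rng.integers(2 * L, 10 * L))
            el = EffectiveLengths(read_len, oh, e)
            c = int(rng.integers(0, 500))
            l = int(rng.integers(0, 500))
            if c == l == 0:
                continue
            assert compute_psi(c, l, el) == pytest.approx(
                c / (l / 2 + c), abs=1e-12
            )

    def test_strictly_monotone(self):
        base = compute_psi(10, 20, EL_LARGE)
        assert compute_psi(11, 20, EL_LARGE) > base
        assert compute_psi(10, 21, EL_LARGE) < base

    @given(
        psi=st.floats(min_value=0.0, max_value=1.0),
        e=st.integers(min_value=50, max_value=2000),
    )
    @settings(max_examples=100, deadline=None)
    def test_rate_round_trip(self, psi, e):
        """binomial_rate inverts compute_psi: psi -> p -> psi is identity."""
        el = EffectiveLengths(110, 10, e)
        p = binomial_rate(psi, el)
        assert 0.0 <= p <= 1.0
        n = 10_000
        back = compute_psi(p * n, (1 - p) * n, el)
        if psi == 0:
            assert back == 0.0
        else:
            assert back == pytest.approx(psi, abs=1e-12)

    def test_rate_examples(self):
        assert binomial_rate(0.0, EL_LARGE) == 0.0
        assert binomial_rate(1.0, EL_LARGE) == 1.0
        assert binomial_rate(0.5, EL_LARGE) == pytest.approx(1 / 3)


# ------------------------------------------------------------- likelihood


def dense_grid_loglik(counts, el, mu, sigma, ngrid=200_001):
    """Trapezoid-rule numeric integration oracle on the logit scale."""
    a = math.log(el.Ic / el.Il)
    m = float(logit(mu))
    total = 0.0
    for c, l in counts:
        n = c + l
        if n == 0:
            continue
        half = 12 * max(sigma, 1e-3) + 6
        x = np.linspace(m - half, m + half, ngrid)
        p = expit(x + a)
        logf = (
            c * np.log(p)
            + (n - c) * np.log1p(-p)
            + norm.logpdf(x, m, sigma)
        )
        total += logsumexp(logf) + np.log(x[1] - x[0])
        total += gammaln(n + 1) - gammaln(c + 1) - gammaln(n - c + 1)
    return total


class TestLoglik:
    def test_matches_dense_grid_oracle(self):
        """Quadrature agrees with trapezoid integration within 1e-6."""
        rng = np.random.default_rng(3)
        el = EffectiveLengths(100, 6, 700)
        for _ in range(50):
            counts = []
            for _ in range(int(rng.integers(1, 5))):
                n = int(rng.integers(1, 800))
                c = int(rng.integers(0, n + 1))
                counts.append((c, n - c))
            mu = float(rng.uniform(0.02, 0.98))
            sigma = float(rng.uniform(0.05, 2.0))
            got = loglik_group(counts, el, mu, sigma)
            want = dense_grid_loglik(counts, el, mu, sigma)
            assert got == pytest.approx(want, abs=1e-6)

    def test_sigma_zero_limit_is_binomial(self):
        el = EffectiveLengths(100, 6, 1000)
        mu = 0.4
        p = binomial_rate(mu, el)
        got = loglik_group([(3, 9)], el, mu, 1e-6)
        assert got == pytest.approx(binom.logpmf(3, 12, p), abs=1e-4)

    def test_single_replicate_example(self):
        el = EffectiveLengths(100, 6, 1000)
        got = loglik_group([(3, 9)], el, 0.4, 0.5)
        want = dense_grid_loglik([(3, 9)], el, 0.4, 0.5)
        assert got == pytest.approx(want, abs=1e-6)

    def test_empty_replicate_changes_nothing(self):
        el = EffectiveLengths(100, 6, 1000)
        a = loglik_group([(3, 9), (5, 12)], el, 0.3, 0.4)
        b = loglik_group([(3, 9), (5, 12), (0, 0)], el, 0.3, 0.4)
        assert a == pytest.approx(b, abs=1e-12)

    def test_all_zero_replicates_rejected(self):
        el = EffectiveLengths(100, 6, 1000)
        with pytest.raises(ValueError):
            loglik_group([(0, 0)], el, 0.3, 0.4)


# ------------------------------------------------------------------- LRT


class TestUnpairedLrt:
    EL = EffectiveLengths(100, 6, 1000)

    def test_identical_groups_null(self):
        g = [(10, 40), (12, 38), (9, 41)]
        fit, llr, p = lrt_unpaired(g, g, self.EL, 0.05)
        assert llr == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0)

    def test_strong_signal_detected(self):
        """True ratios 0.05 vs 0.40, 3v3, totals ~500."""
        rng = np.random.default_rng(11)
        groups = []
        for r in (0.05, 0.40):
            p = binomial_rate(r, self.EL)
            reps = []
            for _ in range(3):
                n = int(rng.poisson(500))
                c = int(rng.binomial(n, p))
                reps.append((c, n - c))
            groups.append(reps)
        fit, llr, pval = lrt_unpaired(groups[0], groups[1], self.EL, 0.05)
        assert pval < 1e-3
        assert abs(fit.mu1 - 0.05) < 0.05 and abs(fit.mu2 - 0.40) < 0.08

    def test_llr_nonnegative_pvalue_one_at_zero(self):
        g1 = [(5, 45), (6, 44)]
        g2 = [(6, 44), (5, 45)]
        _, llr, p = lrt_unpaired(g1, g2, self.EL, 0.05)
        assert llr >= 0.0
        if llr == 0.0:
            assert p == 1.0

    def test_unreachable_delta_never_significant(self):
        g1 = [(50, 0), (48, 2)]
        g2 = [(0, 50), (1, 49)]
        _, llr, p = lrt_unpaired(g1, g2, self.EL, 1.0)
        assert p == pytest.approx(1.0)


class TestPairedLrt:
    EL = EffectiveLengths(100, 6, 1000)

    def test_identical_pairs_null(self):
        g = [(10, 40), (30, 20), (5, 45)]
        fit, llr, p = lrt_paired(g, g, self.EL, 0.05)
        assert llr == pytest.approx(0.0, abs=1e-4)
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_consistent_within_pair_shift_detected(self):
        """A constant shift on top of large pair effects: the paired test
        should be far more sensitive than the unpaired one."""
        rng = np.random.default_rng(5)
        g1, g2 = [], []
        for _ in range(6):
            base = float(rng.uniform(0.1, 0.6))
            for grp, r in ((g1, base), (g2, base + 0.12)):
                n = 400
                c = int(rng.binomial(n, binomial_rate(r, self.EL)))
                grp.append((c, n - c))
        _, _, p_paired = lrt_paired(g1, g2, self.EL, 0.05)
        _, _, p_unpaired = lrt_unpaired(g1, g2, self.EL, 0.05)
        assert p_paired < 0.05
        assert p_paired < p_unpaired

    def test_rho_recovery(self):
        """rho within +/- 0.2 of truth at 10 pairs, deep counts."""
        rng = np.random.default_rng(17)
        rho_true = 0.8
        m, s = float(logit(0.3)), 0.6
        cov = s * s * np.array([[1, rho_true], [rho_true, 1]])
        xs = rng.multivariate_normal([m, m], cov, size=10)
        g1, g2 = [], []
        for x1, x2 in xs:
            for grp, x in ((g1, x1), (g2, x2)):
                p = binomial_rate(float(expit(x)), self.EL)
                n = 2000
                c = int(rng.binomial(n, p))
                grp.append((c, n - c))
        fit, _, _ = lrt_paired(g1, g2, self.EL, 0.05)
        assert fit.rho == pytest.approx(rho_true, abs=0.2)

    def test_unequal_lengths_rejected(self):
        from circdec.types import ConfigError

        with pytest.raises(ConfigError):
            lrt_paired([(1, 1)], [(1, 1), (2, 2)], self.EL, 0.05)


# ------------------------------------------------------------ FDR / Fisher


def bh_oracle(pvalues):
    """Naive two-pass step-up implementation."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return adj


class TestBhFdr:
    def test_small_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, size=100)
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def fisher_oracle(table):
    """Two-sided Fisher p by full enumeration over the hypergeometric."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(1.0, total)


class TestFisherBaseline:
    def test_no_association(self):
        assert fisher_baseline([(10, 10)], [(10, 10)]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        p = fisher_baseline([(20, 5)], [(5, 20)])
        assert p == pytest.approx(fisher_oracle([[20, 5], [5, 20]]), rel=1e-9)

    def test_pools_replicates(self):
        p_pooled = fisher_baseline([(12, 3), (8, 2)], [(2, 13), (3, 7)])
        assert p_pooled == pytest.approx(fisher_oracle([[20, 5], [5, 20]]), rel=1e-9)

    def test_all_zero_table(self):
        assert fisher_baseline([(0, 0)], [(0, 0)]) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fisher_baseline([(1, 1)], [])


# ---------------------------------------------------------------- run_dec


def make_tables(counts_by_locus, samples):
    """counts_by_locus: list of per-sample (cjc, ljc) lists."""
    loci = [
        CircLocus("chr1", 1000 * (i + 1), 1000 * (i + 1) + 500, "+")
        for i in range(len(counts_by_locus))
    ]
    cjc = np.array([[c for c, _ in row] for row in counts_by_locus])
    ljc = np.array([[l for _, l in row] for row in counts_by_locus])
    up = ljc // 2
    return (
        CjcTable(loci, samples, cjc),
        LjcTable(loci, samples, up, ljc - up),
        {loc.locus_id: EffectiveLengths(100, 6, 1000) for loc in loci},
    )


class TestRunDec:
    SAMPLES = ["a1", "a2", "a3", "b1", "b2", "b3"]
    DESIGN = GroupDesign(["a1", "a2", "a3"], ["b1", "b2", "b3"])

    def test_planted_dec_is_flagged(self):
        """One strong signal among 200 null loci is the only DEC."""
        rng = np.random.default_rng(23)
        el = EffectiveLengths(100, 6, 1000)
        rows = []
        for i in range(200):
            r = float(rng.beta(2, 10))
            p = binomial_rate(r, el)
            row = []
            for _ in range(6):
                n = int(rng.poisson(80))
                c = int(rng.binomial(n, p))
                row.append((c, n - c))
            rows.append(row)
        planted = []
        for r in (0.45, 0.45, 0.45, 0.15, 0.15, 0.15):
            n = 2000
            c = int(rng.binomial(n, binomial_rate(r, el)))
            planted.append((c, n - c))
        rows.append(planted)
        cjc, ljc, lengths = make_tables(rows, self.SAMPLES)
        tests = run_dec(cjc, ljc, lengths, self.DESIGN, min_mean_cjc=0.0)
        decs = [t for t in tests if t.is_dec]
        assert len(decs) == 1
        assert decs[0].locus_id == cjc.locus_ids[-1]
        assert decs[0].delta_psi == pytest.approx(0.30, abs=0.07)

    def test_unreachable_delta_threshold_yields_no_decs(self):
        rows = [
            [(50, 10), (55, 5), (52, 8), (2, 58), (1, 59), (3, 57)],
        ]
        cjc, ljc, lengths = make_tables(rows, self.SAMPLES)
        tests = run_dec(cjc, ljc, lengths, self.DESIGN, delta_threshold=1.0,
                        min_mean_cjc=0.0)
        assert not any(t.is_dec for t in tests)

    def test_mean_cjc_filter_applied(self):
        rows = [
            [(1, 10)] * 6,  # mean CJC 1 < 2: filtered
            [(5, 10)] * 6,
        ]
        cjc, ljc, lengths = make_tables(rows, self.SAMPLES)
        tests = run_dec(cjc, ljc, lengths, self.DESIGN, min_mean_cjc=2.0)
        assert [t.locus_id for t in tests] == [cjc.locus_ids[1]]

    def test_mismatched_locus_sets_error_lists_difference(self):
        rows = [[(5, 10)] * 6, [(5, 10)] * 6]
        cjc, ljc, lengths = make_tables(rows, self.SAMPLES)
        short_ljc = LjcTable(ljc.loci[:1], ljc.samples, ljc.ljc_up[:1], ljc.ljc_down[:1])
        with pytest.raises(ValueError, match=cjc.locus_ids[1].replace("+", "\\+")):
            run_dec(cjc, short_ljc, lengths, self.DESIGN)

    def test_psi_missing_only_when_both_zero(self):
        rows = [[(5, 10), (0, 0), (4, 12), (5, 9), (6, 11), (0, 20)]]
        cjc, ljc, lengths = make_tables(rows, self.SAMPLES)
        [t] = run_dec(cjc, ljc, lengths, self.DESIGN, min_mean_cjc=0.0)
        assert math.isnan(t.psi_per_sample[1])
        assert not math.isnan(t.psi_per_sample[5])
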