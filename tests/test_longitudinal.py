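"""Repeated-measures pipeline: binning, ANOVA, sphericity, FDR, Tukey, rules.

The statistical routines are checked against independent oracles: an
explicit-loop two-way decomposition for the ANOVA, a hand Gram-Schmidt /
closed-form-determinant route (plus pingouin) for Mauchly's W, a hand-coded
step-up for BH-FDR, and Gauss-Legendre numerical integration of the
studentized-range distribution for Tukey p-values.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from phenomarks import longitudinal as lg

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_rm_anova(x):
    """Two-way (subject, time) decomposition by explicit summation."""
    n, k = x.shape
    gm = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    subj = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    time = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_time = n * sum((t - gm) ** 2 for t in time)
    ss_err = sum(
        (x[i][j] - subj[i] - time[j] + gm) ** 2 for i in range(n) for j in range(k)
    )
    f = (ss_time / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    return f


def oracle_mauchly_w_k3(x):
    """Mauchly W for k=3 via hand Gram-Schmidt contrasts and a 2x2 determinant."""
    n = len(x)
    means = [sum(row[j] for row in x) / n for j in range(3)]
    s = [[0.0] * 3 for _ in range(3)]
    for a in range(3):
        for b in range(3):
            s[a][b] = sum((row[a] - means[a]) * (row[b] - means[b]) for row in x) / (n - 1)
    # Gram-Schmidt on difference contrasts (1,-1,0) and (0,1,-1)
    import math

    c1 = [1 / math.sqrt(2), -1 / math.sqrt(2), 0.0]
    v2 = [0.0, 1.0, -1.0]
    dot = sum(v2[i] * c1[i] for i in range(3))
    v2 = [v2[i] - dot * c1[i] for i in range(3)]
    nrm = math.sqrt(sum(v * v for v in v2))
    c2 = [v / nrm for v in v2]
    m = [c1, c2]
    c = [[0.0, 0.0], [0.0, 0.0]]
    for a in range(2):
        for b in range(2):
            c[a][b] = sum(m[a][i] * s[i][j] * m[b][j] for i in range(3) for j in range(3))
    det = c[0][0] * c[1][1] - c[0][1] * c[1][0]
    tr = c[0][0] + c[1][1]
    return det / (tr / 2) ** 2


def oracle_bh(p):
    """Benjamini-Hochberg step-up computed by hand."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


_GL_Z = np.polynomial.legendre.leggauss(240)
_GL_S = np.polynomial.legendre.leggauss(240)


def oracle_studentized_range_sf(q, k, nu):
    """P(Q > q) by Gauss-Legendre quadrature of the defining double integral."""
    z, wz = _GL_Z
    z = z * 8.0
    wz = wz * 8.0
    s, ws = _GL_S
    s = (s + 1.0) * 2.0  # (0, 4]
    ws = ws * 2.0
    phi = stats.norm.pdf(z)
    inner = (
        k
        * (wz * phi * (stats.norm.cdf(z) - stats.norm.cdf(z[None, :] - q * s[:, None])) ** (k - 1)).sum(axis=1)
    )
    log_fs = (
        np.log(2.0)
        + (nu / 2) * np.log(nu / 2)
        - gammaln(nu / 2)
        + (nu - 1) * np.log(s)
        - nu * s**2 / 2
    )
    cdf = float((ws * np.exp(log_fs) * inner).sum())
    return 1.0 - cdf


# ---------------------------------------------------------------------------
# binning / matrices
# ---------------------------------------------------------------------------

class TestBinning:
    @pytest.mark.parametrize(
        "day,expected",
        [
            (0, "baseline"),
            (6, "baseline"),
            (7, "week2"),
            (21, "week2"),
            (22, "week4"),
            (35, "week4"),
            (36, "excluded"),
        ],
    )
    def test_visit_windows(self, day, expected):
        assert lg.assign_bin(day) == expected

    def test_negative_day_rejected(self):
        with pytest.raises(ValueError):
            lg.assign_bin(-1)


def tidy_from(rows):
    return pd.DataFrame(rows, columns=["subject_id", "study_day", "stimulus_class", "marker", "value"])


class TestAggregate:
    def test_incomplete_subject_dropped_and_week2_averaged(self):
        rows = [
            ("A", 0, "neutral", "m", 1.0),
            ("A", 7, "neutral", "m", 0.2),
            ("A", 14, "neutral", "m", 0.4),
            ("A", 28, "neutral", "m", 2.0),
            ("B", 0, "neutral", "m", 1.0),
            ("B", 7, "neutral", "m", 1.0),
            ("B", 28, "neutral", "m", 1.0),
            ("C", 7, "neutral", "m", 1.0),  # no baseline -> dropped
            ("C", 14, "neutral", "m", 1.0),
            ("C", 28, "neutral", "m", 1.0),
        ]
        vm = lg.aggregate_and_filter(tidy_from(rows), "m", "neutral")
        assert list(vm.values.index) == ["A", "B"]
        assert vm.values.loc["A", "week2"] == pytest.approx(0.3)

    def test_too_few_subjects_refused_with_diagnostic(self):
        rows = [("A", 0, "neutral", "m", 1.0), ("A", 28, "neutral", "m", 1.0)]
        with pytest.raises(ValueError, match="complete subjects"):
            lg.aggregate_and_filter(tidy_from(rows), "m", "neutral")


class TestNormalize:
    def test_examples(self):
        vm = lg.VisitMatrix(pd.DataFrame({"baseline": [2.0], "week2": [4.0], "week4": [6.0]}))
        out = lg.minmax_normalize(vm).values.to_numpy().ravel()
        assert out == pytest.approx([0.0, 0.5, 1.0])

    def test_range_is_unit(self, rng):
        vm = lg.VisitMatrix(pd.DataFrame(rng.normal(0, 3, (6, 3)), columns=list(lg.BIN_ORDER)))
        out = lg.minmax_normalize(vm).values.to_numpy()
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_matrix_rejected(self):
        vm = lg.VisitMatrix(pd.DataFrame(np.ones((4, 3)), columns=list(lg.BIN_ORDER)))
        with pytest.raises(ValueError):
            lg.minmax_normalize(vm)


# ---------------------------------------------------------------------------
# ANOVA / sphericity
# ---------------------------------------------------------------------------

class TestRmAnova:
    def test_analytic_df_18x3(self, rng):
        f, dn, dd, p = lg.rm_anova(rng.normal(0, 1, (18, 3)))
        assert (dn, dd) == (2, 34)

    def test_identical_columns_give_zero_f(self, rng):
        col = rng.normal(0, 1, 10)
        x = np.column_stack([col, col, col])
        f, *_ = lg.rm_anova(x)
        assert f == 0.0

    def test_matches_loop_oracle(self, rng):
        for _ in range(25):
            n, k = rng.integers(4, 26), rng.integers(2, 5)
            x = rng.normal(0, 1, (n, k)) + rng.normal(0, 1, (n, 1))
            f, *_ = lg.rm_anova(x)
            assert f == pytest.approx(oracle_rm_anova(x), abs=1e-8)

    def test_zero_error_variance_is_degenerate(self):
        x = np.tile([1.0, 2.0, 3.0], (5, 1)) + np.arange(5)[:, None]
        with pytest.warns(RuntimeWarning):
            f, _, _, p = lg.rm_anova(x)
        assert np.isinf(f) and p == 0.0


class TestMauchly:
    def test_k2_trivially_spherical(self, rng):
        w, p = lg.mauchly_test(rng.normal(0, 1, (10, 2)))
        assert (w, p) == (1.0, 1.0)

    def test_w_near_one_under_compound_symmetry(self, rng):
        # CS covariance is spherical: W -> 1 at large n
        cov = 0.5 * np.ones((3, 3)) + 0.5 * np.eye(3)
        x = rng.multivariate_normal(np.zeros(3), cov, size=200)
        w, p = lg.mauchly_test(x)
        assert w > 0.95

    def test_rejection_rate_calibrated_under_sphericity(self, rng):
        rejections = 0
        for _ in range(500):
            x = rng.normal(0, 1, (20, 3))
            _, p = lg.mauchly_test(x)
            rejections += p < 0.05
        assert 0.03 <= rejections / 500 <= 0.08

    def test_w_matches_hand_oracle(self, rng):
        for _ in range(25):
            x = rng.normal(0, 1, (rng.integers(6, 15), 3))
            w, _ = lg.mauchly_test(x)
            assert w == pytest.approx(oracle_mauchly_w_k3(x.tolist()), abs=1e-10)

    def test_requires_more_subjects_than_levels(self, rng):
        with pytest.raises(ValueError):
            lg.mauchly_test(rng.normal(0, 1, (3, 3)))


class TestFdr:
    def test_single_p_identity(self):
        assert lg.bh_fdr([0.03]) == pytest.approx([0.03])

    def test_tied_family(self):
        assert lg.bh_fdr([0.01] * 17) == pytest.approx([0.01] * 17)

    def test_hand_computed_step_up(self):
        assert lg.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_oracle_and_never_decreases(self, rng):
        for _ in range(25):
            p = rng.uniform(0, 1, rng.integers(1, 30)).tolist()
            adj = lg.bh_fdr(p)
            assert adj == pytest.approx(oracle_bh(p), abs=1e-12)
            assert np.all(adj >= np.asarray(p) - 1e-15)

    def test_order_equivariance(self, rng):
        p = rng.uniform(0, 1, 12)
        perm = rng.permutation(12)
        assert lg.bh_fdr(p)[perm] == pytest.approx(lg.bh_fdr(p[perm]), abs=1e-15)


class TestTukey:
    def test_identical_columns_null(self, rng):
        col = rng.normal(0, 1, 8)
        vm = pd.DataFrame({b: col for b in lg.BIN_ORDER})
        f, dn, dd, p = lg.rm_anova(vm)
        pairs = lg.tukey_pairwise(vm, lg._ms_error(vm), dd)
        assert all(c.q == 0.0 and c.p_tukey == 1.0 for c in pairs)

    def test_label_swap_symmetry(self, rng):
        x = rng.normal(0, 1, (10, 3))
        vm = pd.DataFrame(x, columns=list(lg.BIN_ORDER))
        swapped = vm[["baseline", "week4", "week2"]]
        swapped.columns = list(lg.BIN_ORDER)
        ms, dd = lg._ms_error(vm), 18
        a = {c.contrast: c for c in lg.tukey_pairwise(vm, ms, dd)}
        b = {c.contrast: c for c in lg.tukey_pairwise(swapped, ms, dd)}
        assert a["week2-week4"].p_tukey == pytest.approx(b["week2-week4"].p_tukey)
        assert a["week2-week4"].estimate == pytest.approx(-b["week2-week4"].estimate)

    def test_p_matches_numerical_integration_oracle(self, rng):
        x = rng.normal(0, 1, (10, 3)) + np.arange(3) * 0.8
        vm = pd.DataFrame(x, columns=list(lg.BIN_ORDER))
        _, _, dd, _ = lg.rm_anova(vm)
        for c in lg.tukey_pairwise(vm, lg._ms_error(vm), dd):
            assert c.p_tukey == pytest.approx(
                oracle_studentized_range_sf(c.q, 3, dd), abs=1e-6
            )

    def test_conservative_vs_paired_t(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, (9, 3)) + rng.normal(0, 0.5, 3)
            vm = pd.DataFrame(x, columns=list(lg.BIN_ORDER))
            _, _, dd, _ = lg.rm_anova(vm)
            ms = lg._ms_error(vm)
            for c in lg.tukey_pairwise(vm, ms, dd):
                t = abs(c.estimate) / np.sqrt(2 * ms / len(vm))
                p_t = 2 * stats.t.sf(t, dd)
                assert c.p_tukey >= p_t - 1e-12


class TestAnalyzeMarker:
    def test_k2_always_f(self, rng):
        vm = lg.VisitMatrix(
            pd.DataFrame(rng.normal(0, 1, (10, 2)), columns=["baseline", "week4"]),
            marker="m",
        )
        res = lg.analyze_marker(vm)
        assert res.statistic_kind == "F" and res.sphericity_ok

    def test_strong_trend_flags_positive(self, rng):
        x = rng.normal(0, 0.3, (14, 3)) + np.array([0.0, 1.0, 2.0])
        vm = lg.VisitMatrix(pd.DataFrame(x, columns=list(lg.BIN_ORDER)), marker="m")
        res = lg.analyze_marker(vm)
        delta = float(x[:, 2].mean() - x[:, 0].mean())
        lg.analyze_family([res], [delta])
        assert res.direction == "+"
        assert res.p_fdr == res.p_raw

    def test_violated_sphericity_reports_w(self, rng):
        cov = np.array([[1.0, 0.95, 0.1], [0.95, 1.0, 0.1], [0.1, 0.1, 1.0]])
        x = rng.multivariate_normal(np.zeros(3), cov, size=40)
        vm = lg.VisitMatrix(pd.DataFrame(x, columns=list(lg.BIN_ORDER)), marker="m")
        res = lg.analyze_marker(vm)
        assert not res.sphericity_ok
        assert res.statistic_kind == "W"
        assert res.statistic == res.mauchly_w
        assert np.isfinite(res.gg_p)  # GG-corrected F kept as robustness field

    def test_gg_epsilon_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(0, 1, (12, 4))
        df = (
            pd.DataFrame(x, columns=[f"t{j}" for j in range(4)])
            .assign(subj=range(12))
            .melt(id_vars="subj", var_name="time")
        )
        eps_pg = pg.epsilon(df, dv="value", subject="subj", within="time", correction="gg")
        assert lg.gg_epsilon(x) == pytest.approx(float(eps_pg), abs=1e-10)


# ---------------------------------------------------------------------------
# clinical rules
# ---------------------------------------------------------------------------

class TestClinicalRules:
    @pytest.mark.parametrize("score,ok", [(20, True), (19, False), (45, True)])
    def test_eligibility(self, score, ok):
        assert lg.eligibility_filter(score) is ok

    @pytest.mark.parametrize(
        "b,w4,ok", [(30, 21, True), (30, 22, False), (40, 20, True)]
    )
    def test_responder(self, b, w4, ok):
        assert lg.responder_filter(b, w4) is ok

    def test_responder_needs_positive_baseline(self):
        with pytest.raises(ValueError):
            lg.responder_filter(0, 0)

    @pytest.mark.parametrize(
        "score,band",
        [
            (35, "severe"),
            (34, "moderate"),
            (20, "moderate"),
            (19, "mild"),
            (7, "mild"),
            (6, "asymptomatic"),
            (0, "asymptomatic"),
        ],
    )
    def test_severity_bands(self, score, band):
        assert lg.madrs_severity(score) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lg.madrs_severity(61)
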