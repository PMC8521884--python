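"""Longitudinal treatment-response analysis of digital markers and MADRS.

Assessments are binned into baseline / week-2 / week-4 visits, averaged per
subject and bin, reduced to complete cases, and tested for a time effect with
a one-way repeated-measures ANOVA.  Sphericity is tested with Mauchly's W;
when it is violated the row statistic reported is W with its p-value (the
report convention used here), and the Greenhouse-Geisser-corrected F is kept
alongside as a robustness field.  Omnibus p-values are corrected across the
marker family with Benjamini-Hochberg FDR; pairwise time-point contrasts use
Tukey's HSD on the common ANOVA error term.

MADRS utilities (eligibility >= 20, responder >= 30% reduction, severity
bands) live here too since they gate the same analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Visit-bin day windows (inclusive).
BASELINE_DAYS = (0, 6)
WEEK2_DAYS = (7, 21)
WEEK4_DAYS = (22, 35)

BIN_ORDER = ("baseline", "week2", "week4")

#: Significance level for the Mauchly sphericity screen.
SPHERICITY_ALPHA = 0.05
#: Significance level for direction calls on FDR-adjusted p-values.
ALPHA = 0.05


# ---------------------------------------------------------------------------
# binning and visit matrices
# ---------------------------------------------------------------------------

def assign_bin(study_day: int) -> str:
    """Map a study day to its visit bin (or ``excluded`` past day 35)."""
    if study_day < 0:
        raise ValueError("study day cannot be negative")
    if study_day <= BASELINE_DAYS[1]:
        return "baseline"
    if study_day <= WEEK2_DAYS[1]:
        return "week2"
    if study_day <= WEEK4_DAYS[1]:
        return "week4"
    return "excluded"


@dataclass
class VisitMatrix:
    """Complete subject x visit matrix for one marker (or MADRS).

    ``values`` has one row per retained subject and columns
    ``baseline, week2, week4`` (or the available bin subset) with no NaN.
    """

    values: pd.DataFrame
    marker: str = ""
    condition: str = "n/a"

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def k(self) -> int:
        return self.values.shape[1]


def aggregate_and_filter(
    tidy: pd.DataFrame,
    marker: str,
    condition: str | None = None,
    min_subjects: int = 2,
) -> VisitMatrix:
    """Build a complete-case visit matrix from the tidy marker table.

    ``tidy`` columns: ``subject_id, study_day, stimulus_class, marker, value``.
    Per subject and visit bin, available assessments are averaged; subjects
    with any empty bin are dropped (complete-case rule).

    Raises ``ValueError`` if fewer than ``min_subjects`` complete subjects
    survive, with a diagnostic of per-bin availability.
    """
    df = tidy[tidy["marker"] == marker]
    if condition is not None:
        df = df[df["stimulus_class"] == condition]
    if df.empty:
        raise ValueError(f"no rows for marker '{marker}' (condition {condition!r})")
    df = df.assign(bin=df["study_day"].map(assign_bin))
    df = df[df["bin"] != "excluded"].dropna(subset=["value"])
    wide = (
        df.groupby(["subject_id", "bin"])["value"]
        .mean()
        .unstack("bin")
        .reindex(columns=list(BIN_ORDER))
    )
    complete = wide.dropna()
    if len(complete) < min_subjects:
        avail = wide.notna().sum().to_dict()
        raise ValueError(
            f"only {len(complete)} complete subjects for marker '{marker}' "
            f"(condition {condition!r}); per-bin availability: {avail}"
        )
    return VisitMatrix(complete, marker=marker, condition=condition or "n/a")


def minmax_normalize(matrix: VisitMatrix) -> VisitMatrix:
    """Rescale all cells to [0, 1] by the matrix-wide min and max.

    For plotting and cross-marker visual comparison only; the ANOVA always
    runs on raw values.
    """
    x = matrix.values.to_numpy(dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("constant matrix cannot be min-max normalized")
    scaled = (matrix.values - lo) / (hi - lo)
    return VisitMatrix(scaled, marker=matrix.marker, condition=matrix.condition)


# ---------------------------------------------------------------------------
# repeated-measures machinery
# ---------------------------------------------------------------------------

def rm_anova(values: pd.DataFrame | np.ndarray) -> tuple[float, int, int, float]:
    """One-way within-subject ANOVA on a complete n x k matrix.

    Returns ``(F, df_num, df_den, p)`` with ``df_num = k-1`` and
    ``df_den = (n-1)(k-1)``.  Zero error variance yields ``F = inf, p = 0``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D subject x time matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 time points, got {n}x{k}")
    if np.isnan(x).any():
        raise ValueError("matrix must be complete (no NaN) for the RM-ANOVA")
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_time = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_time
    df_num = k - 1
    df_den = (n - 1) * (k - 1)
    ms_time = ss_time / df_num
    ms_err = ss_err / df_den
    tol = 1e-12 * max(ss_total, 1e-300)
    if ss_err <= tol:
        if ss_time <= tol:
            return 0.0, df_num, df_den, 1.0
        import warnings

        warnings.warn("zero within-subject error variance; F degenerate", RuntimeWarning)
        return float("inf"), df_num, df_den, 0.0
    f = ms_time / ms_err
    p = float(stats.f.sf(f, df_num, df_den))
    return float(f), df_num, df_den, p


def _contrast_basis(k: int) -> np.ndarray:
    """Orthonormal basis of the (k-1)-dim contrast space (columns sum to 0)."""
    helmert = np.zeros((k, k - 1))
    for j in range(1, k):
        helmert[:j, j - 1] = 1.0
        helmert[j, j - 1] = -j
    return helmert / np.linalg.norm(helmert, axis=0)


def mauchly_test(values: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on a complete n x k repeated-measures matrix.

    ``W = det(C) / (tr(C)/(k-1))^(k-1)`` with ``C = M' S M``, ``S`` the sample
    covariance of the k measures and ``M`` an orthonormal contrast basis;
    the p-value uses the standard chi-square approximation with
    ``df = k(k-1)/2 - 1``.  With ``k = 2`` sphericity holds trivially
    (``W = 1, p = 1``).
    """
    x = np.asarray(values, dtype=float)
    n, k = x.shape
    if k == 2:
        return 1.0, 1.0
    if k < 2:
        raise ValueError("need k >= 2 time points")
    if n <= k:
        raise ValueError(f"Mauchly's test requires n > k, got n={n}, k={k}")
    s = np.cov(x, rowvar=False, ddof=1)
    m = _contrast_basis(k)
    c = m.T @ s @ m
    d = k - 1
    tr = np.trace(c)
    if tr <= 0:
        return 1.0, 1.0
    w = float(np.linalg.det(c) / (tr / d) ** d)
    w = min(max(w, 0.0), 1.0)
    dof = k * (k - 1) // 2 - 1
    if w <= 0:
        return w, 0.0
    # Box series chi-square approximation (first + second order terms)
    factor = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288.0 * ((n - 1) * d * factor) ** 2)
    )
    chi2 = -(n - 1) * factor * np.log(w)
    p1 = stats.chi2.sf(chi2, dof)
    p2 = stats.chi2.sf(chi2, dof + 4)
    p = float(p1 + w2 * (p2 - p1))
    return w, min(max(p, 0.0), 1.0)


def gg_epsilon(values: pd.DataFrame | np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the contrast-space covariance."""
    x = np.asarray(values, dtype=float)
    n, k = x.shape
    if k == 2:
        return 1.0
    s = np.cov(x, rowvar=False, ddof=1)
    m = _contrast_basis(k)
    c = m.T @ s @ m
    d = k - 1
    eps = np.trace(c) ** 2 / (d * np.trace(c @ c))
    return float(min(max(eps, 1.0 / d), 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PairwiseContrast:
    contrast: str
    estimate: float  # mean(second) - mean(first)
    q: float
    p_tukey: float


def tukey_pairwise(
    values: pd.DataFrame, ms_error: float, df_den: int
) -> list[PairwiseContrast]:
    """Tukey HSD contrasts between every pair of time points.

    ``q = |mean difference| / sqrt(MS_error / n)``; p from the studentized
    range distribution with ``(k, df_den)``.  A degenerate (non-positive)
    error term flags all contrasts with NaN p rather than computing them.
    """
    cols = list(values.columns)
    n = len(values)
    k = len(cols)
    out: list[PairwiseContrast] = []
    means = values.mean()
    scale = float(np.abs(values.to_numpy()).max()) or 1.0
    degenerate = ms_error <= 1e-12 * scale**2 or not np.isfinite(ms_error)
    for i in range(k):
        for j in range(i + 1, k):
            name = f"{cols[i]}-{cols[j]}"
            est = float(means[cols[j]] - means[cols[i]])
            if degenerate:
                # zero mean difference with zero error is a well-defined null
                if abs(est) <= 1e-12 * scale:
                    out.append(PairwiseContrast(name, 0.0, 0.0, 1.0))
                else:
                    out.append(PairwiseContrast(name, est, float("nan"), float("nan")))
                continue
            q = abs(est) / np.sqrt(ms_error / n)
            p = float(stats.studentized_range.sf(q, k, df_den))
            out.append(PairwiseContrast(name, est, float(q), min(max(p, 0.0), 1.0)))
    return out


# ---------------------------------------------------------------------------
# per-marker analysis and the results family
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """One results-table row for a marker under one stimulus condition."""

    marker: str
    condition: str
    n: int
    statistic_kind: str  # "F" (sphericity held) or "W" (violated)
    statistic: float
    df_num: int
    df_den: int
    p_raw: float
    p_fdr: float = float("nan")
    sphericity_ok: bool = True
    mauchly_w: float = 1.0
    mauchly_p: float = 1.0
    f_stat: float = float("nan")
    f_p: float = float("nan")
    gg_eps: float = 1.0
    gg_p: float = float("nan")
    direction: str = "n/a"
    pairwise: list[PairwiseContrast] = field(default_factory=list)


def analyze_marker(
    matrix: VisitMatrix, sphericity_alpha: float = SPHERICITY_ALPHA
) -> AnovaResult:
    """Run the full per-marker repeated-measures analysis.

    Sphericity is screened with Mauchly's test.  When it holds, the row
    statistic is the ANOVA F with its p-value; when violated, the row
    statistic is Mauchly's W with its p-value (report convention), and the
    Greenhouse-Geisser-corrected F p-value is stored in ``gg_p`` as a
    robustness field.  ``p_fdr`` and ``direction`` are filled by
    :func:`analyze_family` once the whole marker family is available.
    """
    values = matrix.values
    f, df_num, df_den, f_p = rm_anova(values)
    w, w_p = mauchly_test(values)
    eps = gg_epsilon(values)
    if np.isfinite(f):
        gg_p = float(stats.f.sf(f, eps * df_num, eps * df_den))
    else:
        gg_p = 0.0
    sph_ok = w_p > sphericity_alpha
    ms_err = _ms_error(values)
    pairs = tukey_pairwise(values, ms_err, df_den)
    if sph_ok:
        kind, stat, p_row = "F", f, f_p
    else:
        kind, stat, p_row = "W", w, w_p
    return AnovaResult(
        marker=matrix.marker,
        condition=matrix.condition,
        n=matrix.n,
        statistic_kind=kind,
        statistic=float(stat),
        df_num=df_num,
        df_den=df_den,
        p_raw=float(p_row),
        sphericity_ok=sph_ok,
        mauchly_w=float(w),
        mauchly_p=float(w_p),
        f_stat=float(f),
        f_p=float(f_p),
        gg_eps=float(eps),
        gg_p=gg_p,
        pairwise=pairs,
    )


def _ms_error(values: pd.DataFrame | np.ndarray) -> float:
    x = np.asarray(values, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_err = (
        ((x - grand) ** 2).sum()
        - k * ((x.mean(axis=1) - grand) ** 2).sum()
        - n * ((x.mean(axis=0) - grand) ** 2).sum()
    )
    return float(ss_err / ((n - 1) * (k - 1)))


def analyze_family(
    results: list[AnovaResult], deltas: list[float], alpha: float = ALPHA
) -> list[AnovaResult]:
    """Apply BH-FDR across a marker family and set direction flags.

    The family is the set of omnibus tests passed in (by default the markers
    within one stimulus condition).  ``deltas`` holds each marker's week-4
    minus baseline mean change; a marker's direction is the sign of its delta
    when its adjusted p-value is below ``alpha``, else ``n/a``.  Mutates and
    returns ``results``.
    """
    if not results:
        return results
    adj = bh_fdr([r.p_raw for r in results])
    for r, p, d in zip(results, adj, deltas):
        r.p_fdr = float(p)
        r.direction = ("+" if d >= 0 else "-") if r.p_fdr < alpha else "n/a"
    return results


def analyze_condition(
    tidy: pd.DataFrame,
    markers: tuple[str, ...],
    condition: str | None,
    alpha: float = ALPHA,
    sphericity_alpha: float = SPHERICITY_ALPHA,
    min_subjects: int = 2,
) -> list[AnovaResult]:
    """Analyze every marker under one condition; FDR family = this condition.

    Markers whose visit matrix cannot be formed (too few complete subjects)
    are skipped.  Direction flags use the week-4 minus baseline change of the
    marker's complete-case matrix.
    """
    results: list[AnovaResult] = []
    deltas: list[float] = []
    for m in markers:
        try:
            vm = aggregate_and_filter(tidy, m, condition, min_subjects=min_subjects)
        except ValueError:
            continue
        res = analyze_marker(vm, sphericity_alpha=sphericity_alpha)
        deltas.append(float(vm.values["week4"].mean() - vm.values["baseline"].mean()))
        results.append(res)
    return analyze_family(results, deltas, alpha=alpha)


# ---------------------------------------------------------------------------
# MADRS clinical rules
# ---------------------------------------------------------------------------

def eligibility_filter(madrs_baseline: float) -> bool:
    """Study eligibility: baseline MADRS total >= 20."""
    return madrs_baseline >= 20


def responder_filter(madrs_baseline: float, madrs_week4: float) -> bool:
    """Treatment responder: >= 30% reduction in MADRS from baseline to week 4."""
    if madrs_baseline <= 0:
        raise ValueError("baseline MADRS must be positive")
    return (madrs_baseline - madrs_week4) / madrs_baseline >= 0.30


def madrs_severity(score: float) -> str:
    """Severity band: >34 severe, 20-34 moderate, 7-19 mild, <7 asymptomatic."""
    if not (0 <= score <= 60):
        raise ValueError(f"MADRS total must lie in [0, 60], got {score}")
    if score > 34:
        return "severe"
    if score >= 20:
        return "moderate"
    if score >= 7:
        return "mild"
    return "asymptomatic"
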