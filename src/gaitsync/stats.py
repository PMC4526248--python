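"""Statistical battery: rank tests, RM-ANOVA with linear contrast, basin analysis.

The rank tests are implemented from their defining formulas with the exact
conventions used throughout this package: mean ranks on ties, the min-U
convention for Mann-Whitney, Z from the normal approximation (continuity
correction for the signed-rank test, tie-corrected variances), and exact
enumeration of the permutation null for small samples (<= 8 observations
per group / pairs), where the normal approximation is unreliable.  Effect
sizes follow the r^2 = Z^2/N convention.

The basin analysis mirrors the study design: Friedman across the 11 tempo
conditions, then Wilcoxon signed-rank of every shifted condition against
the 0 % control with Bonferroni-corrected alpha 0.05/10 = 0.005.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError

#: sample-size threshold below which exact enumeration replaces the
#: normal approximation for p-values
EXACT_THRESHOLD = 8


@dataclass
class TestResult:
    """One test's outcome: statistic, auxiliary Z, df/n, p, effect size."""

    statistic_name: str
    statistic_value: float
    p_value: float
    df: float | None = None
    n: int | None = None
    z: float | None = None
    effect_size: float | None = None
    method: str = ""

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None and v != ""}


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


# ---------------------------------------------------------------------------
# Friedman test


def friedman(matrix) -> TestResult:
    """Friedman rank test across conditions (columns) within subjects (rows).

    Tie-corrected chi-square statistic on within-row mean ranks,
    df = k - 1; without ties it reduces to
    12/(n k (k+1)) * sum R_j^2 - 3 n (k+1).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError("need a 2-D matrix with >= 2 rows and >= 2 columns")
    if np.any(~np.isfinite(m)):
        raise ValidationError("missing cells in the design matrix")
    n, k = m.shape
    ranks = np.apply_along_axis(_rank, 1, m)
    R = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(R**2) - 3.0 * n * (k + 1)
    # tie correction over within-row tie groups
    tie_sum = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += np.sum(counts**3 - counts)
    denom = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if denom <= 0:
        return TestResult("chi2", 0.0, 1.0, df=k - 1, n=n, method="friedman (all ties)")
    chi2 /= denom
    chi2 = max(chi2, 0.0)
    p = float(sps.chi2.sf(chi2, df=k - 1))
    return TestResult("chi2", float(chi2), p, df=k - 1, n=n, method="friedman")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test


def _signed_rank_stats(d: np.ndarray):
    """(W+, ranks of |d|, mean, tie-corrected sd of W+) for nonzero diffs."""
    n = len(d)
    r = _rank(np.abs(d))
    w_plus = float(np.sum(r[d > 0]))
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie = np.sum(counts**3 - counts)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie / 48.0
    return w_plus, r, mean, np.sqrt(var)


def wilcoxon_signed_rank(x, y, method: str = "auto") -> TestResult:
    """Paired signed-rank test of x vs y (differences d = x - y).

    Zero differences are dropped; |d| ties get mean ranks.  The reported
    statistic is W+ (sum of positive-difference ranks), Z its normal
    approximation with continuity correction, and r^2 = Z^2 / n.  For
    n <= 8 nonzero pairs (or ``method='exact'``) the two-sided p comes
    from full enumeration of the 2^n sign patterns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D samples")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    w_plus, ranks, mean, sd = _signed_rank_stats(d)
    cc = 0.5 if w_plus != mean else 0.0
    z = (w_plus - mean - np.sign(w_plus - mean) * cc) / sd if sd > 0 else 0.0

    use_exact = method == "exact" or (method == "auto" and n <= EXACT_THRESHOLD)
    if use_exact:
        dist = np.array([np.sum(np.compress(signs, ranks)) for signs in product((0, 1), repeat=n)])
        p = float(np.mean(np.abs(dist - mean) >= abs(w_plus - mean) - 1e-12))
        how = "wilcoxon signed-rank (exact)"
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
        how = "wilcoxon signed-rank (normal approx.)"
    return TestResult(
        "W+", w_plus, min(p, 1.0), n=n, z=float(z), effect_size=float(z**2 / n), method=how
    )


# ---------------------------------------------------------------------------
# Bonferroni correction


def bonferroni_alpha(familywise: float, m: int) -> float:
    """Per-comparison alpha for ``m`` tests at familywise level."""
    if not 0.0 < familywise <= 1.0:
        raise ValidationError("familywise alpha must be in (0, 1]")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return familywise / m


# ---------------------------------------------------------------------------
# Mann-Whitney U test


def mann_whitney(x, y, method: str = "auto") -> TestResult:
    """Independent two-sample rank test; statistic U = min(U_x, U_y).

    Z uses the tie-corrected normal approximation (no continuity
    correction); r^2 = Z^2 / (n1 + n2).  For groups of <= 8 each (or
    ``method='exact'``) the two-sided p comes from enumerating all
    C(n1+n2, n1) group labelings of the pooled ranks.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _rank(pooled)
    r1 = float(np.sum(ranks[:n1]))
    u_x = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1
    u_y = n1 * n2 - u_x
    u = min(u_x, u_y)
    mean = n1 * n2 / 2.0
    N = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * (N + 1 - tie / (N * (N - 1)))
    sd = np.sqrt(var)
    z = (u_x - mean) / sd if sd > 0 else 0.0

    use_exact = method == "exact" or (
        method == "auto" and max(n1, n2) <= EXACT_THRESHOLD
    )
    if sd == 0:
        p = 1.0
        how = "mann-whitney (degenerate: all values tied)"
    elif use_exact:
        dist = []
        idx = np.arange(N)
        for comb in combinations(idx, n1):
            rs = float(np.sum(ranks[list(comb)]))
            dist.append(n1 * n2 + n1 * (n1 + 1) / 2.0 - rs)
        dist = np.asarray(dist)
        p = float(np.mean(np.abs(dist - mean) >= abs(u_x - mean) - 1e-12))
        how = "mann-whitney (exact)"
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
        how = "mann-whitney (normal approx.)"
    return TestResult(
        "U", float(u), min(p, 1.0), n=N, z=float(z), effect_size=float(z**2 / N), method=how
    )


# ---------------------------------------------------------------------------
# Spearman correlation


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with two-tailed p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("need two equal-length 1-D samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("correlation undefined for a constant vector")
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return TestResult("rho", rho, p, n=n, method="spearman (t approx.)")


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov normality (Lilliefors)


def ks_normality(x) -> TestResult:
    """KS distance to a normal with estimated mean/sd; Lilliefors p-value.

    Because the reference normal is fitted to the same data, the plain KS
    null is anticonservative; the p-value therefore comes from the
    Lilliefors distribution (statsmodels table).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 5:
        raise ValidationError("need a 1-D sample with n >= 5")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero variance: normality test undefined")
    xs = np.sort(x)
    n = len(xs)
    cdf = sps.norm.cdf(xs, loc=np.mean(x), scale=sd)
    d = float(np.max(np.maximum(np.arange(1, n + 1) / n - cdf, cdf - np.arange(0, n) / n)))
    from statsmodels.stats.diagnostic import lilliefors as _lilliefors

    _, p = _lilliefors(x, dist="norm", pvalmethod="table")
    return TestResult("D", d, float(p), n=n, method="lilliefors")


# ---------------------------------------------------------------------------
# One-way repeated-measures ANOVA with linear polynomial contrast


def rm_anova_linear(matrix, condition_scores) -> tuple[TestResult, TestResult]:
    """(omnibus F, linear-contrast F) for a subjects x conditions matrix.

    Omnibus: condition df = k-1, error df = (n-1)(k-1).  The linear
    contrast uses centred ``condition_scores`` as coefficients; its error
    term is the subject-by-contrast variability (df = n-1) and
    r^2 = SS_contrast / (SS_contrast + SS_error_contrast).
    """
    m = np.asarray(matrix, dtype=float)
    scores = np.asarray(condition_scores, dtype=float)
    if m.ndim != 2 or m.shape[1] != len(scores):
        raise ValidationError("matrix columns must match condition_scores")
    if np.any(~np.isfinite(m)):
        raise ValidationError("missing cells in the design matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValidationError("need >= 2 subjects and >= 2 conditions")

    grand = m.mean()
    col_means = m.mean(axis=0)
    row_means = m.mean(axis=1)
    ss_cond = n * np.sum((col_means - grand) ** 2)
    ss_subj = k * np.sum((row_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond, df_err = k - 1, (n - 1) * (k - 1)
    ms_err = ss_err / df_err
    if ms_err > 0:
        f_omni = (ss_cond / df_cond) / ms_err
    else:
        f_omni = 0.0 if ss_cond <= 1e-12 else np.inf  # no within-subject variability
    p_omni = float(sps.f.sf(f_omni, df_cond, df_err)) if np.isfinite(f_omni) else 0.0
    omnibus = TestResult(
        "F", float(f_omni), p_omni, df=df_cond, n=n, method=f"rm-anova omnibus, error df {df_err}"
    )

    c = scores - scores.mean()
    csq = np.sum(c**2)
    L = m @ c  # per-subject contrast values
    ss_contrast = n * L.mean() ** 2 / csq
    ss_err_contrast = np.sum((L - L.mean()) ** 2) / csq
    df_errc = n - 1
    ms_errc = ss_err_contrast / df_errc
    f_con = ss_contrast / ms_errc if ms_errc > 0 else np.inf
    p_con = float(sps.f.sf(f_con, 1, df_errc)) if np.isfinite(f_con) else 0.0
    denom = ss_contrast + ss_err_contrast
    r2 = float(ss_contrast / denom) if denom > 0 else 0.0
    contrast = TestResult(
        "F", float(f_con), p_con, df=1, n=n, effect_size=r2,
        method=f"linear polynomial contrast, error df {df_errc}",
    )
    return omnibus, contrast


# ---------------------------------------------------------------------------
# Entrainment-basin analysis


@dataclass
class BasinResult:
    """Per-condition entrainment summaries and Wilcoxon-vs-control tests."""

    shifts: list[float]
    n: int
    medians: dict[float, float]
    means: dict[float, float]
    ses: dict[float, float]
    wilcoxon: dict[float, TestResult]  # shifted conditions only
    bonferroni_alpha: float
    significant: dict[float, bool] = field(init=False)
    flagged_lower: dict[float, bool] = field(init=False)

    def __post_init__(self):
        ctrl = self.medians[0.0]
        self.significant = {s: r.p_value < self.bonferroni_alpha for s, r in self.wilcoxon.items()}
        self.flagged_lower = {
            s: self.significant[s] and self.medians[s] < ctrl for s in self.wilcoxon
        }

    def to_dict(self) -> dict:
        return {
            "shifts": self.shifts,
            "n": self.n,
            "bonferroni_alpha": self.bonferroni_alpha,
            "medians": {str(s): v for s, v in self.medians.items()},
            "means": {str(s): v for s, v in self.means.items()},
            "ses": {str(s): v for s, v in self.ses.items()},
            "wilcoxon": {str(s): r.to_dict() for s, r in self.wilcoxon.items()},
            "significant": {str(s): bool(v) for s, v in self.significant.items()},
            "flagged_lower": {str(s): bool(v) for s, v in self.flagged_lower.items()},
        }


def basin_analysis(metrics: pd.DataFrame, familywise: float = 0.05) -> BasinResult:
    """Compare every shifted condition's entrainment against the 0 % control.

    Expects the tidy metric table (one row per participant x condition,
    complete grid).  Wilcoxon signed-rank per shifted condition vs control,
    Bonferroni alpha = familywise / (#shifted conditions).
    """
    required = {"participant_id", "shift_pct", "entrainment_pct"}
    if not required.issubset(metrics.columns):
        raise ValidationError(f"metric table must have columns {sorted(required)}")
    wide = metrics.pivot(index="participant_id", columns="shift_pct", values="entrainment_pct")
    if wide.isna().any().any():
        raise ValidationError("incomplete participant x condition grid")
    shifts = sorted(wide.columns)
    if 0.0 not in shifts:
        raise ValidationError("control condition (0 % shift) missing")
    ctrl = wide[0.0].to_numpy()
    n = len(wide)
    alpha = bonferroni_alpha(familywise, m=len(shifts) - 1)
    medians = {s: float(wide[s].median()) for s in shifts}
    means = {s: float(wide[s].mean()) for s in shifts}
    ses = {s: float(wide[s].std(ddof=1) / np.sqrt(n)) for s in shifts}
    tests = {}
    for s in shifts:
        if s == 0.0:
            continue
        try:
            tests[s] = wilcoxon_signed_rank(wide[s].to_numpy(), ctrl)
        except DegenerateDataError:
            tests[s] = TestResult("W+", 0.0, 1.0, n=n, z=0.0, effect_size=0.0,
                                  method="wilcoxon signed-rank (degenerate: all diffs zero)")
    return BasinResult(
        shifts=[float(s) for s in shifts],
        n=n,
        medians=medians,
        means=means,
        ses=ses,
        wilcoxon=tests,
        bonferroni_alpha=alpha,
    )
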