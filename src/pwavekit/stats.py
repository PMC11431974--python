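"""Cohort statistics: group summaries, normality-gated two-sample tests,
categorical tests, univariable Cox hazard ratios and intraobserver
variability.

Policy, stated once:

* continuous summaries are mean ± SEM (sample SD, n−1 denominator);
* the two-sample test is Welch's t when both groups pass Shapiro–Wilk at
  α = 0.05, otherwise Mann–Whitney U (normal approximation with tie
  correction);
* 2×2 tables use Fisher's exact test when any expected cell is below 5,
  otherwise Pearson's χ² without continuity correction;
* hazard ratios come from a single-covariate Cox proportional-hazards
  model fitted by Newton–Raphson on the Breslow partial likelihood, with
  Wald 95% confidence intervals; continuous covariates are
  z-standardised by default so hazard ratios are per-SD;
* two-sided p < 0.05 is flagged significant, with no multiplicity
  adjustment across rows (a Benjamini–Hochberg column is emitted
  additionally for transparency).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult", "CoxResult",
    "mean_sem", "compare_continuous", "compare_categorical",
    "cox_univariable", "intraobserver_variability",
    "variability_protocol_count", "cohort_report",
]


@dataclass
class ComparisonResult:
    variable: str
    n_success: int
    n_failure: int
    test_name: str                      # t | mann_whitney | chi2 | fisher
    statistic: float
    p_two_sided: float
    mean_success: float | None = None
    sem_success: float | None = None
    mean_failure: float | None = None
    sem_failure: float | None = None
    count_success: int | None = None
    count_failure: int | None = None
    hr: float | None = None
    hr_ci_low: float | None = None
    hr_ci_high: float | None = None
    hr_p: float | None = None

    @property
    def significant(self) -> bool:
        return self.p_two_sided < 0.05


@dataclass
class CoxResult:
    hr: float | None
    ci_low: float | None
    ci_high: float | None
    p: float | None
    beta: float | None
    se: float | None
    n_events: int
    separation: bool = False


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean (SD with n−1 denominator)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("mean ± SEM needs at least two values")
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(vals.size))


def compare_continuous(x_success, x_failure, normality_alpha: float = 0.05,
                       variable: str = "") -> ComparisonResult:
    """Two-sample comparison with a Shapiro–Wilk normality gate on each
    group: both normal → Welch's t; otherwise Mann–Whitney U."""
    x = np.asarray(list(x_success), dtype=float)
    y = np.asarray(list(x_failure), dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least three values")

    m_x, s_x = mean_sem(x)
    m_y, s_y = mean_sem(y)

    if x.std() == 0 and y.std() == 0 and m_x == m_y:
        warnings.warn(f"{variable or 'variable'}: both groups constant and "
                      "equal; p set to 1")
        return ComparisonResult(variable, len(x), len(y), "t", 0.0, 1.0,
                                m_x, s_x, m_y, s_y)

    def _normal(v):
        if v.std() == 0:
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sps.shapiro(v).pvalue > normality_alpha

    if _normal(x) and _normal(y):
        res = sps.ttest_ind(x, y, equal_var=False)
        name = "t"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
        name = "mann_whitney"
    return ComparisonResult(variable, len(x), len(y), name,
                            float(res.statistic), float(res.pvalue),
                            m_x, s_x, m_y, s_y)


def compare_categorical(table, variable: str = "") -> ComparisonResult:
    """2×2 association test: Fisher's exact if any expected cell < 5,
    else Pearson's χ² without continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("need a 2×2 table of non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("2×2 table has an empty margin")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected < 5).any():
        res = sps.fisher_exact(t.astype(int))
        name, stat, p = "fisher", float(res[0]), float(res[1])
    else:
        chi2 = sps.chi2_contingency(t, correction=False)
        name, stat, p = "chi2", float(chi2[0]), float(chi2[1])
    return ComparisonResult(variable, int(t[0].sum()), int(t[1].sum()),
                            name, stat, p,
                            count_success=int(t[0, 0]),
                            count_failure=int(t[1, 0]))


# ---------------------------------------------------------------------------
# univariable Cox proportional hazards


def cox_univariable(covariate, event_time_months, event_flag,
                    standardize: bool = False,
                    max_iter: int = 100, tol: float = 1e-10) -> CoxResult:
    """Single-covariate Cox fit: Newton–Raphson on the Breslow partial
    likelihood, Wald 95% CI.

    With ``standardize=True`` the covariate is z-scored first, so the
    hazard ratio is per standard deviation.  Monotone likelihoods
    (complete separation in the risk sets) are flagged; no CI is
    reported for them.
    """
    x = np.asarray(list(covariate), dtype=float)
    t = np.asarray(list(event_time_months), dtype=float)
    d = np.asarray(list(event_flag)).astype(bool)
    if not (len(x) == len(t) == len(d)):
        raise ValueError("covariate, time and event vectors must align")
    n_events = int(d.sum())
    if n_events < 5:
        raise ValueError(f"need at least 5 events, got {n_events}")
    if x.std() == 0:
        raise ValueError("covariate is constant")
    if standardize:
        x = (x - x.mean()) / x.std(ddof=1)

    # sort by time descending so risk sets are cumulative prefixes
    order = np.argsort(-t, kind="stable")
    x, t, d = x[order], t[order], d[order]

    # group tied event times (Breslow)
    event_times = np.unique(t[d])

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        w = np.exp(beta * x)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * x)
        s2 = np.cumsum(w * x * x)
        # risk set for time tau = all with t >= tau = prefix up to the
        # last index with t >= tau
        last_ge = np.searchsorted(-t, -event_times, side="right") - 1
        u_score = 0.0
        info = 0.0
        for tau, j in zip(event_times, last_ge):
            at_tau = d & (t == tau)
            dj = int(at_tau.sum())
            u_score += x[at_tau].sum() - dj * s1[j] / s0[j]
            info += dj * (s2[j] / s0[j] - (s1[j] / s0[j]) ** 2)
        if info <= 1e-12:
            return CoxResult(None, None, None, None, beta=beta, se=None,
                             n_events=n_events, separation=True)
        step = u_score / info
        beta += step
        if abs(step) < tol:
            converged = True
            break

    if not converged or abs(beta) > 15:
        return CoxResult(None, None, None, None, beta=beta, se=None,
                         n_events=n_events, separation=True)

    se = 1.0 / np.sqrt(info)
    z = beta / se
    p = 2 * sps.norm.sf(abs(z))
    return CoxResult(hr=float(np.exp(beta)),
                     ci_low=float(np.exp(beta - 1.959963984540054 * se)),
                     ci_high=float(np.exp(beta + 1.959963984540054 * se)),
                     p=float(p), beta=float(beta), se=float(se),
                     n_events=n_events)


# ---------------------------------------------------------------------------
# intraobserver variability


def intraobserver_variability(day1, day2) -> tuple[float, float, float]:
    """Paired repeat-measurement agreement.

    Returns (mean |difference|, SEM of |difference|, percentage), where
    the percentage divides the mean absolute difference by the mean of
    the pairwise means.
    """
    a = np.asarray(list(day1), dtype=float)
    b = np.asarray(list(day2), dtype=float)
    if a.shape != b.shape:
        raise ValueError("day-1 and day-2 vectors must have equal length")
    d = np.abs(a - b)
    mean_d = float(d.mean())
    sem_d = float(d.std(ddof=1) / np.sqrt(d.size)) if d.size > 1 else 0.0
    denom = float(((a + b) / 2).mean())
    percent = 0.0 if mean_d == 0 else 100.0 * mean_d / denom
    return mean_d, sem_d, percent


def variability_protocol_count(n_ecgs: int = 22, n_leads: int = 12,
                               n_beats: int = 20) -> int:
    """Number of paired P waves analysed in a repeat-measurement protocol
    (ECGs × leads × beats averaged per lead)."""
    return n_ecgs * n_leads * n_beats


# ---------------------------------------------------------------------------
# cohort report


def _event_vectors(cohort: pd.DataFrame):
    fail = cohort["outcome"].astype(str).str.lower() == "failure"
    time = np.where(fail, cohort["event_time_months"],
                    cohort["followup_months"]).astype(float)
    return time, fail.to_numpy()


def cohort_report(cohort: pd.DataFrame,
                  continuous_vars: list[str] | None = None,
                  binary_vars: list[str] | None = None,
                  alpha: float = 0.05,
                  standardize: bool = True) -> pd.DataFrame:
    """One report row per variable: group summaries, the selected test
    and p-value, and the univariable hazard ratio with 95% CI.

    ``cohort`` needs columns ``outcome`` (success/failure),
    ``event_time_months`` (failures), ``followup_months``, plus the
    feature columns.  Unknown columns are skipped with a warning; an
    empty failure arm is a hard error.
    """
    outcome = cohort["outcome"].astype(str).str.lower()
    succ = cohort[outcome == "success"]
    fail = cohort[outcome == "failure"]
    if len(fail) == 0:
        raise ValueError("cohort has no failures; nothing to compare")
    if len(succ) == 0:
        raise ValueError("cohort has no successes; nothing to compare")

    if continuous_vars is None and binary_vars is None:
        skip = {"patient_id", "outcome", "event_time_months",
                "followup_months"}
        numeric = [c for c in cohort.columns
                   if c not in skip and pd.api.types.is_numeric_dtype(cohort[c])]
        binary_vars = [c for c in numeric
                       if set(cohort[c].dropna().unique()) <= {0, 1}]
        continuous_vars = [c for c in numeric if c not in binary_vars]
    continuous_vars = continuous_vars or []
    binary_vars = binary_vars or []

    time, event = _event_vectors(cohort)
    rows = []
    for var in list(continuous_vars) + list(binary_vars):
        if var not in cohort.columns:
            warnings.warn(f"cohort table lacks column {var!r}; skipped")
            continue
        vals = cohort[var]
        mask = vals.notna().to_numpy()
        is_binary = var in binary_vars
        try:
            if is_binary:
                table = np.array([
                    [int(succ[var].sum()), int((1 - succ[var]).sum())],
                    [int(fail[var].sum()), int((1 - fail[var]).sum())],
                ])
                cmp_res = compare_categorical(table, variable=var)
            else:
                cmp_res = compare_continuous(succ[var].dropna(),
                                             fail[var].dropna(),
                                             variable=var)
        except ValueError as exc:
            warnings.warn(f"{var}: comparison failed ({exc}); skipped")
            continue
        try:
            cox = cox_univariable(vals.to_numpy()[mask], time[mask],
                                  event[mask],
                                  standardize=standardize and not is_binary)
        except ValueError as exc:
            warnings.warn(f"{var}: Cox fit unavailable ({exc})")
            cox = CoxResult(None, None, None, None, None, None, 0)
        row = {
            "variable": var,
            "n_success": cmp_res.n_success,
            "n_failure": cmp_res.n_failure,
            "mean_success": cmp_res.mean_success,
            "sem_success": cmp_res.sem_success,
            "mean_failure": cmp_res.mean_failure,
            "sem_failure": cmp_res.sem_failure,
            "count_success": cmp_res.count_success,
            "count_failure": cmp_res.count_failure,
            "test": cmp_res.test_name,
            "statistic": cmp_res.statistic,
            "p": cmp_res.p_two_sided,
            "hr": cox.hr,
            "hr_ci_low": cox.ci_low,
            "hr_ci_high": cox.ci_high,
            "hr_p": cox.p,
            "hr_scale": ("per_unit" if is_binary or not standardize
                         else "per_sd"),
            "separation": cox.separation,
            "significant": cmp_res.p_two_sided < alpha,
        }
        rows.append(row)
    report = pd.DataFrame(rows)
    if not report.empty:
        report["p_bh"] = multipletests(report["p"], method="fdr_bh")[1]
    return report
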