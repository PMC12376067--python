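"""Clinical classification rules and the cohort statistical battery.

Covers the remission definitions (center-specific and consensus), the
derived clinical categories (preoperative GH bins, ICA-encasement degree,
radiological invasiveness), GH/IGF-1 discordance, univariate two-group
testing with a Shapiro-Wilk normality gate, Enter-method multivariate
logistic regression, and seeded quasi-Bayesian mediation analysis.

Test-selection rules (fixed so printed two-by-two tables recompute exactly):
continuous factors use Welch's t-test when Shapiro-Wilk accepts normality in
both outcome groups at alpha = 0.05, otherwise the two-sided Mann-Whitney U
test; categorical factors use the Pearson chi-square WITHOUT continuity
correction unless any expected cell count is below 5, in which case Fisher's
exact test is used (Monte-Carlo p for tables larger than 2x2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PatientRecord",
    "TestResult",
    "LogisticTermResult",
    "LogisticModelResult",
    "MediationResult",
    "classify_remission_center",
    "classify_remission_consensus",
    "categorize_record",
    "discordance_rate",
    "univariate_tests",
    "fit_multivariate_logistic",
    "mediation_analysis",
    "cohort_summary",
    "records_to_frame",
]

ALPHA_NORMALITY = 0.05
Z95 = 1.959963984540054

ANALYSIS_CONFIG_DEFAULTS = {
    "gh_upper_normal": None,  # center-specific, must be supplied
    "alpha": 0.05,
    "n_sim": 1000,
    "seed": 0,
}


def load_analysis_config(path) -> dict:
    """Read the YAML run configuration (gh_upper_normal, alpha, n_sim, seed)."""
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(ANALYSIS_CONFIG_DEFAULTS)
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(ANALYSIS_CONFIG_DEFAULTS)
    cfg.update(user)
    return cfg


@dataclass
class PatientRecord:
    """Clinical covariates and outcomes for one patient.

    Hormones in ng/mL, volumes in cm^3, ICA encasement as a combined
    percentage over both sides (0-100).  ``hardy_grade`` uses Roman numerals
    I-IV; ``hardy_stage`` is one of 0/A/B/C/D/E.
    """

    patient_id: object
    age: float
    sex: str  # "M" | "F"
    surgery_approach: str  # MTS | ETS | TCS
    ihc_class: str  # GH-only | SL-multiple | ML-multiple
    gh_preop: float
    gh_post24h: float
    tumor_volume: float
    residual_volume: float
    residual_present: bool
    residual_suprasellar: bool = False
    residual_intrasellar: bool = False
    residual_parasellar: bool = False
    ica_encasement_pct: float = 0.0
    knosp_grade: int = 0
    hardy_grade: str = "I"
    hardy_stage: str = "0"
    ith_score: float = 0.0
    subclusters: int = 1
    igf1_normalized: Optional[bool] = None

    def __post_init__(self):
        if self.gh_preop < 0 or self.gh_post24h < 0:
            raise ValueError("hormone levels must be >= 0")
        if self.residual_volume > self.tumor_volume + 1e-9:
            raise ValueError("residual volume exceeds tumor volume")
        if not 0 <= self.ica_encasement_pct <= 100:
            raise ValueError("ICA encasement must be in [0, 100]")


@dataclass(frozen=True)
class TestResult:
    factor: str
    test: str  # t | mann_whitney | chi_square | fisher
    statistic: float
    p_value: float
    group_summaries: dict

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0,1]")


@dataclass(frozen=True)
class LogisticTermResult:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self):
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI must bracket the OR")


@dataclass(frozen=True)
class LogisticModelResult:
    terms: tuple
    reference_levels: dict
    n_obs: int
    converged: bool

    def __getitem__(self, term: str) -> LogisticTermResult:
        for t in self.terms:
            if t.term == term:
                return t
        raise KeyError(term)


@dataclass(frozen=True)
class MediationResult:
    acme: float
    acme_ci: tuple
    acme_p: float
    ade: float
    ade_ci: tuple
    ade_p: float
    total_effect: float
    proportion_mediated: float
    n_simulations: int
    seed: int


# ---------------------------------------------------------------------------
# classification rules


def classify_remission_center(gh_post24h: float, gh_upper_normal: float) -> bool:
    """Center rule: remission iff postoperative GH strictly below the
    center's upper normal limit (a required configuration value)."""
    if gh_upper_normal is None:
        raise ValueError("gh_upper_normal is required configuration")
    if gh_upper_normal <= 0 or gh_post24h < 0:
        raise ValueError("GH values must be >= 0 with a positive limit")
    return gh_post24h < gh_upper_normal


def classify_remission_consensus(
    gh_random: Optional[float],
    gh_nadir_ogtt: Optional[float],
    igf1_normalized: bool,
) -> bool:
    """Consensus rule: (random GH < 1 or OGTT nadir < 0.4) and normalized IGF-1."""
    if gh_random is None and gh_nadir_ogtt is None:
        raise ValueError("at least one GH measurement is required")
    gh_ok = (gh_random is not None and gh_random < 1.0) or (
        gh_nadir_ogtt is not None and gh_nadir_ogtt < 0.4
    )
    return gh_ok and bool(igf1_normalized)


def categorize_record(r: PatientRecord) -> dict:
    """Derived categories: preoperative GH bin, ICA-encasement degree,
    radiological invasiveness.

    GH bins: <=10 / (10,30] / >30.  Encasement: exactly 0 is its own
    category, then (0,30] / (30,50] / >50.  Invasive iff Knosp grade 3-4 or
    Hardy grade III/IV or Hardy stage C/D/E.
    """
    gh = r.gh_preop
    gh_bin = "<=10" if gh <= 10 else ("10-30" if gh <= 30 else ">30")
    pct = r.ica_encasement_pct
    if not 0 <= pct <= 100:
        raise ValueError("encasement out of range")
    if pct == 0:
        enc = "0"
    elif pct <= 30:
        enc = "0-30"
    elif pct <= 50:
        enc = "30-50"
    else:
        enc = ">50"
    invasive = (
        r.knosp_grade in (3, 4)
        or r.hardy_grade in ("III", "IV")
        or r.hardy_stage in ("C", "D", "E")
    )
    return {"gh_preop_bin": gh_bin, "ica_encasement_cat": enc, "invasive": invasive}


def discordance_rate(gh_remission: Sequence[bool], igf1_normalized: Sequence[bool]) -> float:
    """Percent of patients whose GH-remission flag disagrees with IGF-1
    normalization (records with a missing IGF-1 flag must be excluded by
    the caller)."""
    gh = np.asarray(gh_remission, dtype=bool)
    igf = np.asarray(igf1_normalized, dtype=bool)
    if gh.size == 0 or gh.shape != igf.shape:
        raise ValueError("need matched, nonempty flag sequences")
    return float(100.0 * (gh != igf).mean())


# ---------------------------------------------------------------------------
# univariate battery


def _continuous_test(x0: np.ndarray, x1: np.ndarray) -> tuple[str, float, float]:
    norm0 = stats.shapiro(x0).pvalue > ALPHA_NORMALITY if len(x0) >= 3 else False
    norm1 = stats.shapiro(x1).pvalue > ALPHA_NORMALITY if len(x1) >= 3 else False
    if norm0 and norm1:
        res = stats.ttest_ind(x0, x1, equal_var=False)
        return "t", float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(x0, x1, alternative="two-sided", method="asymptotic")
    return "mann_whitney", float(res.statistic), float(res.pvalue)


def categorical_test(
    table: np.ndarray, rng: Optional[np.random.Generator] = None, n_mc: int = 20000
) -> tuple[str, float, float]:
    """Chi-square (no continuity correction) or Fisher when any expected
    count < 5.  Fisher on tables larger than 2x2 uses a Monte-Carlo p-value
    over tables sampled with fixed margins."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table (empty row/column)")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected >= 5).all():
        return "chi_square", float(chi2), float(p)
    if table.shape == (2, 2):
        res = stats.fisher_exact(table.astype(int))
        return "fisher", float(res[0]), float(res[1])
    # r x c Fisher: Monte-Carlo under the fixed-margin hypergeometric null,
    # ranking tables by probability (more extreme = less probable).
    rng = np.random.default_rng(0) if rng is None else rng
    logp_obs = _log_table_prob(table)
    samples = stats.random_table(table.sum(axis=1), table.sum(axis=0)).rvs(
        n_mc, random_state=rng
    )
    logp_s = np.array([_log_table_prob(t) for t in samples])
    p_mc = (np.sum(logp_s <= logp_obs + 1e-9) + 1) / (n_mc + 1)
    return "fisher", float("nan"), float(p_mc)


def _log_table_prob(t: np.ndarray) -> float:
    from scipy.special import gammaln

    t = np.asarray(t, dtype=float)
    n = t.sum()
    return float(
        gammaln(t.sum(axis=1) + 1).sum()
        + gammaln(t.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(t + 1).sum()
    )


def univariate_tests(
    cohort: pd.DataFrame,
    outcome: str,
    factors: Sequence[str],
    categorical: Sequence[str] = (),
    seed: int = 0,
) -> list[TestResult]:
    """Two-group comparisons of each factor against a boolean outcome.

    Continuous factors pass through the Shapiro-Wilk gate; factors listed in
    *categorical* are cross-tabulated against the outcome.
    """
    y = cohort[outcome].astype(bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need >= 2 records per outcome group")
    rng = np.random.default_rng(seed)
    results = []
    for f in factors:
        if f in categorical:
            table = pd.crosstab(cohort[f], y).to_numpy()
            test, statv, p = categorical_test(table, rng)
            summaries = {
                "table": pd.crosstab(cohort[f], y).to_dict(),
            }
        else:
            x0 = cohort.loc[~y, f].to_numpy(dtype=float)
            x1 = cohort.loc[y, f].to_numpy(dtype=float)
            if len(x0) < 2 or len(x1) < 2:
                raise ValueError(f"factor {f}: degenerate group sizes")
            test, statv, p = _continuous_test(x0, x1)
            summaries = {
                "mean_sd_nonoutcome": (float(x0.mean()), float(x0.std(ddof=1))),
                "mean_sd_outcome": (float(x1.mean()), float(x1.std(ddof=1))),
            }
        results.append(TestResult(f, test, statv, p, summaries))
    return results


# ---------------------------------------------------------------------------
# multivariate logistic regression (Enter method)


def fit_multivariate_logistic(
    cohort: pd.DataFrame,
    outcome: str,
    terms: Sequence[str],
    reference_levels: Optional[dict] = None,
) -> LogisticModelResult:
    """Maximum-likelihood logistic regression with all terms entered at once.

    Categorical (object/categorical dtype) terms are dummy-coded against the
    stated reference level.  Reports per-term OR = exp(coef) with Wald 95%
    CIs and p-values.
    """
    reference_levels = dict(reference_levels or {})
    y = cohort[outcome].astype(float)
    if y.nunique() != 2:
        raise ValueError("outcome must be binary with both classes present")
    cols = []
    for t in terms:
        s = cohort[t]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = list(pd.unique(s))
            ref = reference_levels.get(t, sorted(levels)[0])
            reference_levels[t] = ref
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent for {t}")
            for lv in [l for l in sorted(levels) if l != ref]:
                cols.append(pd.Series((s == lv).astype(float), name=f"{t}[{lv}]"))
        elif s.dtype == bool:
            cols.append(pd.Series(s.astype(float), name=t))
        else:
            cols.append(pd.Series(s.astype(float), name=t))
    X = sm.add_constant(pd.concat(cols, axis=1))
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as e:
        raise RuntimeError(f"logistic fit failed: {e}") from e
    if not fit.mle_retvals.get("converged", False):
        raise RuntimeError("logistic fit did not converge")
    se = np.asarray(fit.bse)
    if np.any(~np.isfinite(se)) or np.any(se > 50):
        raise RuntimeError("quasi-separation: unstable standard errors")
    out = []
    for name, coef, s_e, p in zip(X.columns, fit.params, se, fit.pvalues):
        if name == "const":
            continue
        out.append(
            LogisticTermResult(
                name,
                float(np.exp(coef)),
                float(np.exp(coef - Z95 * s_e)),
                float(np.exp(coef + Z95 * s_e)),
                float(p),
            )
        )
    return LogisticModelResult(tuple(out), reference_levels, int(len(y)), True)


# ---------------------------------------------------------------------------
# mediation analysis (quasi-Bayesian, Imai-style)


def mediation_analysis(
    cohort: pd.DataFrame,
    exposure: str,
    mediator: str,
    outcome: str,
    n_sim: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Regression-based causal mediation with a binary exposure and outcome.

    Fits (i) a linear model mediator ~ exposure and (ii) a logistic model
    outcome ~ exposure + mediator, then draws ``n_sim`` parameter vectors
    from each fit's asymptotic normal and evaluates potential-outcome
    contrasts averaged over the sample: ACME(t) = E[Y(t, M(1)) - Y(t, M(0))]
    and ADE(m-arm t) likewise, reported as the average over t in {0, 1},
    with percentile 95% CIs and two-sided simulation p-values.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    a = cohort[exposure].astype(float).to_numpy()
    m = cohort[mediator].astype(float).to_numpy()
    y = cohort[outcome].astype(float).to_numpy()
    n = len(a)

    Xm = sm.add_constant(a)
    med_fit = sm.OLS(m, Xm).fit()
    Xy = sm.add_constant(np.column_stack([a, m]))
    out_fit = sm.Logit(y, Xy).fit(disp=0, maxiter=200)
    if not out_fit.mle_retvals.get("converged", False):
        raise RuntimeError("outcome model did not converge")

    med_draws = rng.multivariate_normal(med_fit.params, med_fit.cov_params(), size=n_sim)
    out_draws = rng.multivariate_normal(
        np.asarray(out_fit.params), np.asarray(out_fit.cov_params()), size=n_sim
    )
    sigma_m = float(np.sqrt(med_fit.scale))
    # simulate mediator draws under each exposure arm, shared errors
    eps = rng.standard_normal((n_sim, n)) * sigma_m

    def expit(z):
        return 1.0 / (1.0 + np.exp(-z))

    acme = np.empty(n_sim)
    ade = np.empty(n_sim)
    for s in range(n_sim):
        g0, g1 = med_draws[s, 0], med_draws[s, 0] + med_draws[s, 1]
        m0 = g0 + eps[s]
        m1 = g1 + eps[s]
        b0, ba, bm = out_draws[s]
        acme_t = [
            np.mean(expit(b0 + ba * t + bm * m1) - expit(b0 + ba * t + bm * m0))
            for t in (0.0, 1.0)
        ]
        ade_t = [
            np.mean(expit(b0 + ba * 1 + bm * mt) - expit(b0 + ba * 0 + bm * mt))
            for mt in (m0, m1)
        ]
        acme[s] = np.mean(acme_t)
        ade[s] = np.mean(ade_t)

    total = acme + ade

    def _summ(v):
        lo, hi = np.percentile(v, [2.5, 97.5])
        p = 2 * min(np.mean(v <= 0), np.mean(v >= 0))
        return float(np.mean(v)), (float(lo), float(hi)), float(min(p, 1.0))

    acme_m, acme_ci, acme_p = _summ(acme)
    ade_m, ade_ci, ade_p = _summ(ade)
    tot_m = float(np.mean(total))
    prop = float(np.mean(acme / total)) if abs(tot_m) > 1e-12 else float("nan")
    return MediationResult(
        acme_m, acme_ci, acme_p, ade_m, ade_ci, ade_p, tot_m, prop, n_sim, seed
    )


# ---------------------------------------------------------------------------
# summaries


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = dict(r.__dict__)
        d.update(categorize_record(r))
        d["resection_rate"] = (
            (r.tumor_volume - r.residual_volume) / r.tumor_volume if r.tumor_volume > 0 else np.nan
        )
        rows.append(d)
    return pd.DataFrame(rows)


def cohort_summary(cohort: pd.DataFrame, stratifier: Optional[str] = None) -> dict:
    """Counts with percentages per categorical level and mean +/- SD for
    continuous columns, overall and (optionally) by a boolean stratifier."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if stratifier is not None and stratifier not in cohort.columns:
        raise KeyError(f"unknown stratifier {stratifier!r}")

    def one(df: pd.DataFrame) -> dict:
        out: dict = {"n": int(len(df))}
        for col in df.columns:
            s = df[col]
            if s.dtype == object or s.dtype == bool or isinstance(s.dtype, pd.CategoricalDtype):
                counts = s.value_counts(dropna=True)
                out[col] = {
                    str(k): {"count": int(v), "pct": float(100.0 * v / counts.sum())}
                    for k, v in counts.items()
                }
            elif np.issubdtype(s.dtype, np.number):
                sd = float(s.std(ddof=1)) if len(s) > 1 else float("nan")
                out[col] = {"mean": float(s.mean()), "sd": sd, "sd_defined": len(s) > 1}
        return out

    summary = {"overall": one(cohort)}
    if stratifier is not None:
        for val, grp in cohort.groupby(cohort[stratifier].astype(bool)):
            summary[f"{stratifier}={val}"] = one(grp.drop(columns=[stratifier]))
    return summary
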