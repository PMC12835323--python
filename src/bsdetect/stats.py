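"""Cohort-level statistics: contingency analysis, effect sizes, power,
logistic POD models and the anesthetic x burst-suppression interaction.

The analysis surface mirrors a standard perioperative-cohort workflow:

* 2x2 agent x POD contingency table with arm incidences, Pearson
  chi-square (uncorrected by default), relative risk with a log-scale Wald
  CI, Cohen's h and a post-hoc two-proportion power calculation;
* multivariable logistic regressions of POD on anesthetic agent, age, ASA
  score, surgery duration (hours), care location and a choice of
  burst-suppression representations (continuous BSR, raw duration in
  seconds, binary any-BS, or none), with subgroup and dose-response
  (BS-only) variants;
* an interaction model with a sevoflurane x any-BS product term, decomposed
  into the four conditional odds ratios relative to propofol without BS.

Estimation is maximum-likelihood via statsmodels; CIs are 95% Wald.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ValidationError

__all__ = [
    "ContingencyResult",
    "ModelResult",
    "incidence_table",
    "cohens_h",
    "two_proportion_power",
    "fit_pod_model",
    "fit_interaction_model",
    "group_compare",
    "log_transform_for_plot",
]

#: Covariates of the primary multivariable model, beyond the BS term.
FULL_COVARIATES = ("agent", "age", "asa", "surgery_duration", "care_location")


@dataclass
class ContingencyResult:
    """Agent x POD contingency analysis with effect sizes and power.

    ``counts`` is a 2x2 DataFrame (rows sevoflurane/propofol, columns
    pod/no_pod); every derived number is recomputable from it, which
    :meth:`audit` asserts.
    """

    counts: pd.DataFrame
    incidence: dict[str, float]  # per-arm POD incidence, percent
    overall_incidence: float  # percent
    chi_square: float
    p_value: float
    relative_risk: float
    rr_ci: tuple[float, float]
    cohens_h: float
    achieved_power: float

    def audit(self) -> None:
        """Re-derive incidences from counts and assert self-consistency."""
        for arm in self.counts.index:
            pod, no = self.counts.loc[arm, "pod"], self.counts.loc[arm, "no_pod"]
            assert abs(self.incidence[arm] - 100.0 * pod / (pod + no)) < 1e-9
        total = self.counts.values.sum()
        assert abs(self.overall_incidence - 100.0 * self.counts["pod"].sum() / total) < 1e-9


@dataclass
class ModelResult:
    """A fitted logistic model: per-term ORs, Wald CIs, p-values."""

    model_name: str
    table: pd.DataFrame  # index term; columns coef, or, ci_low, ci_high, p
    n_used: int
    n_dropped: int
    converged: bool
    separation: bool = False
    conditional_or: pd.DataFrame | None = None

    def odds_ratio(self, term: str) -> float:
        return float(self.table.loc[term, "or"])


def cohens_h(p1: float, p2: float) -> float:
    """Cohen's effect size for two proportions, |2 asin sqrt(p1) - 2 asin sqrt(p2)|."""
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValidationError("proportions must lie in [0, 1]")
    return float(abs(2 * np.arcsin(np.sqrt(p1)) - 2 * np.arcsin(np.sqrt(p2))))


def two_proportion_power(
    p1: float, p2: float, n1: int, n2: int, alpha: float = 0.05, tails: int = 2
) -> float:
    """Normal-approximation power of the two-sample proportions z-test.

    Under H0 the standard error pools the proportions
    (``se0 = sqrt(pbar qbar (1/n1 + 1/n2))``); under H1 it does not
    (``se1 = sqrt(p1 q1/n1 + p2 q2/n2)``).  Power is the probability that
    ``|p1_hat - p2_hat|`` exceeds ``z_{1-alpha/tails} * se0``:

        power = Phi((d - z se0)/se1) + Phi((-d - z se0)/se1),  d = p1 - p2

    (the second term is the far-tail contribution; for one-tailed tests
    only the first applies).
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("need at least 2 subjects per arm")
    if tails not in (1, 2):
        raise ValidationError("tails must be 1 or 2")
    z = sps.norm.ppf(1 - alpha / tails)
    pbar = (p1 * n1 + p2 * n2) / (n1 + n2)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    se1 = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    if se1 == 0:
        return 1.0 if abs(p1 - p2) > z * se0 else 0.0
    d = abs(p1 - p2)
    power = sps.norm.cdf((d - z * se0) / se1)
    if tails == 2:
        power += sps.norm.cdf((-d - z * se0) / se1)
    return float(power)


def incidence_table(cohort: pd.DataFrame, yates: bool = False) -> ContingencyResult:
    """Agent x POD contingency analysis.

    Pearson chi-square on the 2x2 table (df = 1), by default without the
    Yates continuity correction; relative risk (sevoflurane vs propofol)
    with a log-scale Wald 95% CI; Cohen's h between the arm incidences; and
    the achieved power of the two-proportion z-test at alpha = 0.05,
    two-sided.
    """
    for agent in ("propofol", "sevoflurane"):
        if not (cohort["agent"] == agent).any():
            raise ValidationError(f"no patients in the {agent} arm")
    counts = pd.DataFrame(
        {
            "pod": [
                int(((cohort["agent"] == a) & (cohort["pod"] == 1)).sum())
                for a in ("sevoflurane", "propofol")
            ],
            "no_pod": [
                int(((cohort["agent"] == a) & (cohort["pod"] == 0)).sum())
                for a in ("sevoflurane", "propofol")
            ],
        },
        index=["sevoflurane", "propofol"],
    )
    n_sevo, n_prop = counts.sum(axis=1)
    p_sevo = counts.loc["sevoflurane", "pod"] / n_sevo
    p_prop = counts.loc["propofol", "pod"] / n_prop

    chi2, p, _, _ = sps.chi2_contingency(counts.values, correction=yates)

    rr = p_sevo / p_prop
    # log-RR Wald CI
    a, c = counts.loc["sevoflurane", "pod"], counts.loc["propofol", "pod"]
    se_log = np.sqrt(1 / a - 1 / n_sevo + 1 / c - 1 / n_prop)
    z = sps.norm.ppf(0.975)
    rr_ci = (float(rr * np.exp(-z * se_log)), float(rr * np.exp(z * se_log)))

    result = ContingencyResult(
        counts=counts,
        incidence={
            "sevoflurane": float(100 * p_sevo),
            "propofol": float(100 * p_prop),
        },
        overall_incidence=float(100 * counts["pod"].sum() / counts.values.sum()),
        chi_square=float(chi2),
        p_value=float(p),
        relative_risk=float(rr),
        rr_ci=rr_ci,
        cohens_h=cohens_h(p_sevo, p_prop),
        achieved_power=two_proportion_power(p_sevo, p_prop, int(n_sevo), int(n_prop)),
    )
    result.audit()
    return result


# ---------------------------------------------------------------------------
# Logistic models

_BS_TERMS = {
    "continuous_bsr": "bsr",
    "raw_duration": "bs_duration",
    "binary": "any_bs",
    "none": None,
}


def _design(
    cohort: pd.DataFrame,
    bs_mode: str,
    include_agent: bool,
    covariates: str,
    log_duration: bool = False,
) -> tuple[pd.DataFrame, pd.Series, int]:
    cols = ["pod"]
    terms: list[str] = []
    if include_agent:
        cols.append("agent")
    if covariates == "full":
        cols += ["age", "asa", "surgery_duration", "care_location"]
    bs_col = _BS_TERMS[bs_mode]
    if bs_col is not None:
        cols.append(bs_col)
    df = cohort[list(dict.fromkeys(cols))].copy()
    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)

    X = pd.DataFrame(index=df.index)
    if include_agent:
        X["sevoflurane"] = (df["agent"] == "sevoflurane").astype(float)
    if bs_col is not None:
        if bs_col == "bs_duration" and log_duration:
            X["log1p_bs_duration"] = np.log1p(df[bs_col].astype(float))
        else:
            X[bs_col] = df[bs_col].astype(float)
    if covariates == "full":
        X["age"] = df["age"].astype(float)
        X["asa"] = df["asa"].astype(float)
        X["surgery_duration"] = df["surgery_duration"].astype(float)
        X["pacu_icu"] = (df["care_location"] == "pacu_icu").astype(float)
    X.insert(0, "intercept", 1.0)
    y = df["pod"].astype(float)
    return X, y, n_dropped


def _fit_logit(X: pd.DataFrame, y: pd.Series, model_name: str, n_dropped: int) -> ModelResult:
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    if y.nunique() < 2:
        raise ValidationError(
            f"{model_name}: outcome has a single class in this subset"
        )
    separation = False
    converged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", False))
        # diverging coefficients with exploded SEs indicate (quasi-)separation
        separation = (not converged) or bool(
            np.any(np.abs(fit.params.values[1:]) > 15)
        )
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return ModelResult(
            model_name=model_name,
            table=pd.DataFrame(columns=["coef", "or", "ci_low", "ci_high", "p"]),
            n_used=len(y),
            n_dropped=n_dropped,
            converged=False,
            separation=True,
        )
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "or": np.exp(fit.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "p": fit.pvalues,
        }
    )
    return ModelResult(
        model_name=model_name,
        table=table,
        n_used=int(len(y)),
        n_dropped=n_dropped,
        converged=converged,
        separation=separation,
    )


def fit_pod_model(
    cohort: pd.DataFrame,
    bs_mode: str = "binary",
    subset: str = "all",
    covariates: str = "full",
    log_duration_dose: bool = True,
) -> ModelResult:
    """Multivariable logistic regression of POD.

    Parameters
    ----------
    cohort : DataFrame
        Patient table with columns ``pod, agent, age, asa,
        surgery_duration, care_location, bs_duration, bsr, any_bs``.
    bs_mode : {"continuous_bsr", "raw_duration", "binary", "none"}
        Representation of burst suppression entering the model.
    subset : {"all", "sevoflurane", "propofol", "bs_only"}
        Full cohort, one anesthetic subgroup (the agent term is then
        dropped), or the dose-response subset restricted to patients with
        measurable BS (duration > 0).
    covariates : {"full", "reduced"}
        "full" adjusts for age, ASA, surgery duration and care location;
        "reduced" keeps only the agent and BS terms.
    log_duration_dose : bool
        In the ``bs_only`` subset with ``raw_duration``, model
        ``log(1 + duration)`` as the dose variable (the duration
        distribution is heavily right-skewed); set False for raw seconds.

    Missing covariate rows are dropped listwise; the dropped count is
    reported on the result.  Perfect separation is flagged, never silently
    returned as estimates.
    """
    if bs_mode not in _BS_TERMS:
        raise ValidationError(f"unknown bs_mode {bs_mode!r}")
    if subset not in ("all", "sevoflurane", "propofol", "bs_only"):
        raise ValidationError(f"unknown subset {subset!r}")
    df = cohort
    include_agent = True
    log_dose = False
    if subset in ("sevoflurane", "propofol"):
        df = cohort[cohort["agent"] == subset]
        include_agent = False
    elif subset == "bs_only":
        df = cohort[cohort["bs_duration"] > 0]
        log_dose = log_duration_dose
    if df.empty:
        raise ValidationError(f"subset {subset!r} selects no patients")
    X, y, n_dropped = _design(df, bs_mode, include_agent, covariates, log_dose)
    name = f"pod~{bs_mode}|{subset}|{covariates}"
    return _fit_logit(X, y, name, n_dropped)


def fit_interaction_model(
    cohort: pd.DataFrame, covariates: str = "reduced"
) -> ModelResult:
    """Logistic POD model with a sevoflurane x any-BS product term.

    Requires all four agent x BS cells to be populated.  Besides the
    coefficient table (the product term's exponent is the interaction OR),
    the result carries ``conditional_or``: the odds of each cell relative
    to propofol without BS, i.e. (1, exp(b_bs), exp(b_sevo),
    exp(b_sevo + b_bs + b_int)) — so the sevoflurane-with-BS OR is exactly
    the product of the other three by construction.
    """
    for agent in ("propofol", "sevoflurane"):
        for bs in (0, 1):
            cell = cohort[(cohort["agent"] == agent) & (cohort["any_bs"] == bs)]
            if cell.empty:
                raise ValidationError(
                    f"empty cell: agent={agent}, any_bs={bs}"
                )
    X, y, n_dropped = _design(cohort, "binary", include_agent=True, covariates=covariates)
    X["sevoflurane_x_any_bs"] = X["sevoflurane"] * X["any_bs"]
    result = _fit_logit(X, y, f"pod~interaction|{covariates}", n_dropped)
    if result.separation or result.table.empty:
        return result
    b_bs = result.table.loc["any_bs", "coef"]
    b_sevo = result.table.loc["sevoflurane", "coef"]
    b_int = result.table.loc["sevoflurane_x_any_bs", "coef"]
    result.conditional_or = pd.DataFrame(
        {
            "or": [
                1.0,
                float(np.exp(b_bs)),
                float(np.exp(b_sevo)),
                float(np.exp(b_sevo + b_bs + b_int)),
            ]
        },
        index=[
            "propofol_no_bs",
            "propofol_bs",
            "sevoflurane_no_bs",
            "sevoflurane_bs",
        ],
    )
    return result


def group_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction (normal approximation).

    Returns ``(U, p)``.  When the pooled sample is constant the statistic
    carries no information and p = 1 is returned.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def log_transform_for_plot(durations) -> np.ndarray:
    """log(1 + x) display transform for right-skewed BS durations.

    Maps zero to zero and preserves order; used only for visualization of
    duration distributions, never inside the models.
    """
    x = np.asarray(durations, dtype=float)
    if (x < 0).any():
        raise ValidationError("durations must be non-negative")
    return np.log1p(x)
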