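"""Association statistics: 2x2 odds-ratio analysis and adjusted regressions.

The 2x2 analysis reports the sample odds ratio with a Woolf (log-scale)
95% confidence interval,

    OR = ad/bc,   SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d),
    CI = exp(log OR +/- 1.96 SE),

and the Yates continuity-corrected chi-squared statistic

    chi2 = N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)),  df = 1.

Regression models are fitted by maximum likelihood with canonical links
(identity / log / logit), always adjusting for age and sex unless the model
is sex-stratified; qualifications use a multinomial log-linear model with
the combined "other categories" group as baseline. Fecundity (children
fathered / live births) is modelled per sex by Poisson regression with a
pooled deletion-by-sex interaction test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "OutcomeSpec",
    "TermEstimate",
    "RegressionResult",
    "or_ci_chi2",
    "preprocess_outcome",
    "fit_adjusted_model",
    "fecundity_analysis",
    "attainment_proportions",
    "OUTCOME_SPECS",
]

Z95 = 1.96


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier-by-phenotype counts.

    a: carriers among cases; b: non-carriers among cases;
    c: carriers among controls; d: non-carriers among controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    p: float
    prevalence_cases: float  # percent
    prevalence_controls: float  # percent
    haldane_corrected: bool = False


def or_ci_chi2(
    table: ContingencyTable, ci_method: str = "woolf"
) -> AssociationResult:
    """Odds ratio with 95% CI and Yates-corrected chi-squared test.

    ``ci_method="woolf"`` (default) gives the sample OR with the log-scale
    Woolf interval; ``"exact"`` gives the conditional maximum-likelihood OR
    with an exact (central hypergeometric) interval. Prevalences are
    reported in percent (carriers / group total). With a zero margin (no
    cases or no controls) the odds ratio is undefined and a ValueError is
    raised; a single zero cell triggers the Haldane-Anscombe correction
    (0.5 added to all cells) for the Woolf method, flagged in the result.
    Prevalences and the test statistic always use the uncorrected counts.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0:
        raise ValueError("zero margin: odds ratio undefined")
    prev_cases = 100.0 * a / (a + b)
    prev_controls = 100.0 * c / (c + d)

    haldane = False
    if ci_method == "exact":
        res = sps.contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
        ci = res.confidence_interval(0.95)
        or_, ci_low, ci_high = res.statistic, float(ci.low), float(ci.high)
    elif ci_method == "woolf":
        haldane = 0 in (a, b, c, d)
        if haldane:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        or_ = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ci_low = float(np.exp(np.log(or_) - Z95 * se))
        ci_high = float(np.exp(np.log(or_) + Z95 * se))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    a, b, c, d = table.a, table.b, table.c, table.d

    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    corrected = max(abs(a * d - b * c) - n / 2, 0.0)
    chi2 = float(n * corrected**2 / denom)
    p = float(sps.chi2.sf(chi2, df=1))

    return AssociationResult(
        float(or_), ci_low, ci_high, chi2, p, prev_cases, prev_controls, haldane
    )


# ---------------------------------------------------------------------------
# outcome preprocessing


@dataclass(frozen=True)
class OutcomeSpec:
    """Name, model family and preprocessing rule for one outcome."""

    name: str
    family: str  # linear | poisson | logistic | multinomial
    preprocessing: str  # sd5_outliers | binarize_gt0 | binarize_gt6 | fecundity_caps | none


OUTCOME_SPECS = {
    "reaction_time": OutcomeSpec("reaction_time", "linear", "sd5_outliers"),
    "fluid_intelligence": OutcomeSpec("fluid_intelligence", "poisson", "none"),
    "numeric_memory": OutcomeSpec("numeric_memory", "logistic", "binarize_gt6"),
    "pairs_matching": OutcomeSpec("pairs_matching", "logistic", "binarize_gt0"),
    "qualifications": OutcomeSpec("qualifications", "multinomial", "none"),
    "fecundity": OutcomeSpec("fecundity", "poisson", "fecundity_caps"),
}

#: sex-specific hard caps applied to fecundity after the 5-SD rule
FECUNDITY_CAPS = {"male": 8, "female": 7}


def _check_numeric(values: pd.Series) -> pd.Series:
    numeric = pd.to_numeric(values, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"non-numeric outcome value at row {idx}")
    return numeric.astype(float)


def preprocess_outcome(
    spec: OutcomeSpec, values: pd.Series, sex: pd.Series | None = None
) -> tuple[pd.Series, dict]:
    """Apply the outcome's preprocessing rule; return kept values and a log.

    The 5-SD outlier rule drops values with |x - mean| > 5 SD where mean and
    SD come from the full pre-removal sample, applied once (not iterated).
    Fecundity additionally applies sex-specific integer caps (>8 children
    fathered for males, >7 live births for females, removed). Binarizations:
    pairs-matching errors map 0 -> 0 and >0 -> 1; numeric-memory scores map
    <=6 -> 0 and >6 -> 1.
    """
    values = _check_numeric(values)
    log: dict = {"rule": spec.preprocessing, "n_input": int(values.notna().sum())}

    if spec.preprocessing == "none":
        kept = values
        log["n_removed"] = 0
    elif spec.preprocessing == "binarize_gt0":
        kept = (values > 0).astype(float).where(values.notna())
        log["n_removed"] = 0
    elif spec.preprocessing == "binarize_gt6":
        kept = (values > 6).astype(float).where(values.notna())
        log["n_removed"] = 0
    elif spec.preprocessing in ("sd5_outliers", "fecundity_caps"):
        mean, sd = values.mean(), values.std()
        keep = values.notna() & ((values - mean).abs() <= 5 * sd)
        if spec.preprocessing == "fecundity_caps":
            if sex is None:
                raise ValueError("fecundity preprocessing requires a sex column")
            keep &= ~((sex == "male") & (values > FECUNDITY_CAPS["male"]))
            keep &= ~((sex == "female") & (values > FECUNDITY_CAPS["female"]))
        kept = values.where(keep)
        log["n_removed"] = int((values.notna() & ~keep).sum())
        log["mean"], log["sd"] = float(mean), float(sd)
    else:
        raise ValueError(f"unknown preprocessing rule {spec.preprocessing!r}")
    return kept, log


# ---------------------------------------------------------------------------
# adjusted regression battery


@dataclass(frozen=True)
class TermEstimate:
    coef: float
    se: float
    p: float

    @property
    def ci(self) -> tuple[float, float]:
        return (self.coef - Z95 * self.se, self.coef + Z95 * self.se)


@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    family: str
    terms: dict[str, TermEstimate]
    n_used: int
    n_removed_as_outliers: int = 0
    converged: bool = True
    # multinomial only: per-category odds ratios for the deletion term
    category_odds: dict[str, TermEstimate] = field(default_factory=dict)


class FitFailure(RuntimeError):
    """Model did not converge or the design is degenerate (e.g. separation)."""


def _design(rows: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "deletion": rows["carrier"].astype(float),
            "age": rows["age"].astype(float),
            "sex": (rows["sex"] == "male").astype(float),
        },
        index=rows.index,
    )
    return sm.add_constant(X, has_constant="add")


def _terms_from_fit(fit, names) -> dict[str, TermEstimate]:
    return {
        name: TermEstimate(
            float(fit.params[name]), float(fit.bse[name]), float(fit.pvalues[name])
        )
        for name in names
        if name in fit.params.index
    }


def fit_adjusted_model(
    spec: OutcomeSpec, rows: pd.DataFrame, adjust: bool = True
) -> RegressionResult:
    """Fit the outcome's model with the deletion term, adjusting for age/sex.

    ``rows`` must contain columns outcome (named after the spec), carrier,
    age, sex; preprocessing is applied here (removal counts are reported in
    the result). Requires at least one carrier and one non-carrier.
    """
    needed = [spec.name, "carrier", "age", "sex"]
    rows = rows[needed].dropna(subset=[spec.name]).copy()
    if spec.family == "multinomial":  # categorical outcome, no numeric rules
        log = {"n_removed": 0}
    else:
        values, log = preprocess_outcome(spec, rows[spec.name], sex=rows["sex"])
        rows[spec.name] = values
        rows = rows.dropna(subset=[spec.name])
    if rows["carrier"].nunique() < 2:
        raise FitFailure("need both carriers and non-carriers to estimate the effect")

    X = _design(rows) if adjust else sm.add_constant(
        rows[["carrier"]].astype(float).rename(columns={"carrier": "deletion"}),
        has_constant="add",
    )
    if spec.family == "multinomial":
        return _fit_multinomial(spec, rows, X)
    y = rows[spec.name].astype(float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if spec.family == "linear":
                fit = sm.OLS(y, X).fit()
            elif spec.family == "poisson":
                fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            elif spec.family == "logistic":
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            else:
                raise ValueError(f"unknown family {spec.family!r}")
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise FitFailure(f"{spec.family} fit failed: {exc}") from exc

    converged = bool(getattr(fit, "converged", True))
    params = np.asarray(fit.params, dtype=float)
    bse = np.asarray(fit.bse, dtype=float)
    degenerate = (
        not np.all(np.isfinite(params))
        or not np.all(np.isfinite(bse))
        or (
            spec.family in ("poisson", "logistic")
            and (np.abs(params).max() > 25 or np.abs(bse).max() > 1e3)
        )
    )
    if not converged or degenerate:
        raise FitFailure(
            f"{spec.family} fit did not converge or is degenerate (possible "
            f"separation / empty outcome group); params={params}"
        )
    return RegressionResult(
        spec.name,
        spec.family,
        _terms_from_fit(fit, ["deletion", "age", "sex", "const"]),
        n_used=int(len(rows)),
        n_removed_as_outliers=log["n_removed"],
        converged=converged,
    )


#: categories of the highest-qualification outcome; "other" is the baseline
QUALIFICATION_CATEGORIES = ("other", "degree", "a_levels")


def _fit_multinomial(spec: OutcomeSpec, rows: pd.DataFrame, X: pd.DataFrame):
    cats = pd.Categorical(rows[spec.name], categories=QUALIFICATION_CATEGORIES)
    if cats.isna().any():
        bad = rows[spec.name][np.asarray(cats.isna())].iloc[0]
        raise ValueError(f"unknown qualification category {bad!r}")
    y = pd.Series(cats.codes, index=rows.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MNLogit(y, X).fit(disp=False, maxiter=200)
    if not fit.mle_retvals.get("converged", False):
        raise FitFailure("multinomial fit did not converge")
    params = fit.params  # columns: one per non-baseline category, in code order
    bse, pvals = fit.bse, fit.pvalues
    category_odds = {}
    for j, cat in enumerate(QUALIFICATION_CATEGORIES[1:]):
        coef = float(params.iloc[params.index.get_loc("deletion"), j])
        category_odds[cat] = TermEstimate(
            coef,
            float(bse.iloc[bse.index.get_loc("deletion"), j]),
            float(pvals.iloc[pvals.index.get_loc("deletion"), j]),
        )
    return RegressionResult(
        spec.name,
        spec.family,
        {"deletion": category_odds["degree"]},
        n_used=int(len(rows)),
        category_odds=category_odds,
    )


def fecundity_analysis(
    rows: pd.DataFrame,
) -> tuple[RegressionResult | None, RegressionResult | None, float | None]:
    """Sex-stratified Poisson fecundity models plus an interaction test.

    ``rows`` columns: fecundity (children fathered for males, live births
    for females), carrier, age, sex. Returns (male result, female result,
    interaction p). Per-sex fits regress the count on the deletion only
    (the stratification absorbs sex); the interaction p is the Wald test of
    the deletion-by-sex term in a pooled model. With a single sex present
    the other result and the interaction p are None.
    """
    spec = OUTCOME_SPECS["fecundity"]
    values, _ = preprocess_outcome(spec, rows["fecundity"], sex=rows["sex"])
    rows = rows.assign(fecundity=values).dropna(subset=["fecundity"])

    results: dict[str, RegressionResult | None] = {"male": None, "female": None}
    for sex in ("male", "female"):
        sub = rows[rows["sex"] == sex]
        if len(sub) == 0:
            continue
        sub_spec = OutcomeSpec("fecundity", "poisson", "none")
        results[sex] = fit_adjusted_model(sub_spec, sub, adjust=False)

    interaction_p = None
    if results["male"] is not None and results["female"] is not None:
        X = pd.DataFrame(
            {
                "deletion": rows["carrier"].astype(float),
                "sex": (rows["sex"] == "male").astype(float),
            },
            index=rows.index,
        )
        X["deletion_x_sex"] = X["deletion"] * X["sex"]
        X = sm.add_constant(X, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(
                rows["fecundity"].astype(float), X, family=sm.families.Poisson()
            ).fit()
        interaction_p = float(fit.pvalues["deletion_x_sex"])
    return results["male"], results["female"], interaction_p


def attainment_proportions(freq: pd.DataFrame) -> pd.DataFrame:
    """Per-group qualification-category percentages, rounded to 1 dp.

    ``freq`` is a table of non-negative integer counts with qualification
    categories as rows and groups (e.g. carrier / non_carrier) as columns;
    each percentage is category count / group total over all categories.
    """
    freq = freq.astype(float)
    if (freq < 0).to_numpy().any():
        raise ValueError("frequencies must be non-negative")
    totals = freq.sum(axis=0)
    if (totals == 0).any():
        zero = totals[totals == 0].index.tolist()
        raise ValueError(f"zero group total for {zero}")
    return (100.0 * freq / totals).round(1)
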