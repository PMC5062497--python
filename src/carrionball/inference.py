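"""Statistical analysis of the breeding-study table.

The study asked four questions of its 45 breeding pairs: (1) do larger
parents roll rounder carcass nests, (2) do rounder nests lower maintenance
costs (longer post-reproduction lifespan), (3) do rounder nests reduce
variance in brood outcomes, and (4) do rounder nests improve brood size or
larval mass.  Questions 1, 2 and 4 are answered with Gaussian linear
models reduced by AIC backward elimination; question 3 with Levene's
variance-homogeneity test after splitting pairs at the mean roundness.

Conventions
-----------
* AIC is ``-2*loglik + 2*k`` with ``k`` counting every regression
  coefficient (intercept included) plus the residual variance — the same
  convention R's ``AIC``/``stepAIC`` use, so elimination traces are
  comparable to an R workflow.  The constant offset is irrelevant to
  ranking but is fixed and documented.
* Elimination is greedy: each round refits the model without each
  remaining candidate and drops the single term whose removal lowers AIC
  the most; it stops when no removal lowers AIC.  The intercept is never
  dropped.
* p-values of dropped terms are reported from the last model that
  contained them, flagged as such.
* Levene's test is median-centered by default (the Brown-Forsythe
  variant); the mean-centered variant is always computed alongside.
* Rows with a missing value in any column a model touches are dropped for
  that model only, and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    CollinearityError,
    DegenerateInputError,
    InsufficientGroupError,
    InvalidInputError,
    SchemaError,
)

logger = logging.getLogger(__name__)

INTERCEPT = "Intercept"

#: Columns every full study table must provide.
REQUIRED_COLUMNS = [
    "pair_id",
    "male_size",
    "female_size",
    "carcass_mass_unprepared",
    "carcass_mass_prepared",
    "mass_change",
    "roundness",
    "male_desertion_time",
    "female_desertion_time",
    "male_lifespan",
    "female_lifespan",
    "brood_size",
    "brood_mass",
    "avg_larval_mass",
    "larval_density",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """A response plus an ordered candidate covariate set over a table."""

    response: str
    candidates: tuple[str, ...]
    data: pd.DataFrame

    def __post_init__(self):
        object.__setattr__(self, "candidates", tuple(self.candidates))
        missing = [
            c
            for c in (self.response, *self.candidates)
            if c not in self.data.columns
        ]
        if missing:
            raise SchemaError(missing)
        if self.response in self.candidates:
            raise InvalidInputError(
                f"response {self.response!r} cannot also be a candidate"
            )


@dataclass(frozen=True)
class TermStats:
    estimate: float
    se: float
    t: float
    p: float
    #: True when the p-value comes from the last model that contained a
    #: term dropped during elimination, not from the final model.
    from_pre_drop_model: bool = False


@dataclass
class FitSummary:
    """A fitted (possibly reduced) linear model."""

    response: str
    terms: dict[str, TermStats]  # final-model terms, intercept included
    dropped: dict[str, TermStats]  # eliminated terms, pre-drop statistics
    aic: float
    n_used: int
    n_missing_dropped: int
    residuals: np.ndarray
    #: (dropped term, AIC before, AIC after) per elimination round.
    elimination_trace: list[tuple[str, float, float]] = field(default_factory=list)
    mass_variant: str | None = None

    @property
    def retained(self) -> list[str]:
        return [t for t in self.terms if t != INTERCEPT]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, ts in self.terms.items():
            rows.append(
                {
                    "term": name,
                    "estimate": ts.estimate,
                    "se": ts.se,
                    "t": ts.t,
                    "p": ts.p,
                    "retained": True,
                }
            )
        for name, ts in self.dropped.items():
            rows.append(
                {
                    "term": name,
                    "estimate": ts.estimate,
                    "se": ts.se,
                    "t": ts.t,
                    "p": ts.p,
                    "retained": False,
                }
            )
        return pd.DataFrame(
            rows, columns=["term", "estimate", "se", "t", "p", "retained"]
        )


@dataclass(frozen=True)
class VarianceComparison:
    """Levene comparison of a response's spread between 'round' (above
    mean roundness) and 'not round' carcasses.

    Degrees of freedom are reported in the conventional (numerator,
    denominator) = (1, n - 2) order.
    """

    split_variable: str
    split_value: float
    response: str
    n_round: int
    n_not_round: int
    f: float
    df: tuple[int, int]
    p: float
    f_mean_centered: float
    p_mean_centered: float
    center: str = "median"


# ---------------------------------------------------------------------------
# basic checks
# ---------------------------------------------------------------------------


def check_normality(column: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (W, p)."""
    x = np.asarray(column, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3 or len(x) > 5000:
        raise DegenerateInputError(
            f"Shapiro-Wilk requires 3 <= n <= 5000, got {len(x)}"
        )
    if np.all(x == x[0]):
        raise DegenerateInputError("normality test on a constant column")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise DegenerateInputError("correlation requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("correlation of a constant column")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# linear models
# ---------------------------------------------------------------------------


def _design(data: pd.DataFrame, response: str, terms: Sequence[str]):
    cols = [response, *terms]
    sub = data[cols].dropna()
    y = sub[response].to_numpy(dtype=float)
    X = sm.add_constant(
        sub[list(terms)].to_numpy(dtype=float), has_constant="add"
    )
    return y, X, len(data) - len(sub), len(sub)


def _check_rank(X: np.ndarray, terms: Sequence[str]) -> None:
    if np.linalg.matrix_rank(X) >= X.shape[1]:
        return
    # identify offending columns: those whose removal restores full rank
    offenders = []
    for j, name in enumerate(terms, start=1):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == reduced.shape[1]:
            offenders.append(name)
    raise CollinearityError(offenders or list(terms))


def _aic(result, n_terms: int) -> float:
    # -2*loglik + 2*k, k = coefficients (incl. intercept) + residual variance
    return float(-2.0 * result.llf + 2.0 * (n_terms + 2))


def _fit(data: pd.DataFrame, response: str, terms: Sequence[str]):
    y, X, n_missing, n_used = _design(data, response, terms)
    if n_used <= len(terms) + 1:
        raise InvalidInputError(
            f"{n_used} complete rows cannot identify {len(terms)} terms "
            "plus an intercept"
        )
    _check_rank(X, terms)
    result = sm.OLS(y, X).fit()
    return result, n_missing, n_used


def _term_stats(result, terms: Sequence[str], pre_drop=False) -> dict[str, TermStats]:
    names = [INTERCEPT, *terms]
    return {
        name: TermStats(
            estimate=float(result.params[i]),
            se=float(result.bse[i]),
            t=float(result.tvalues[i]),
            p=float(result.pvalues[i]),
            from_pre_drop_model=pre_drop,
        )
        for i, name in enumerate(names)
    }


def fit_ols(spec: ModelSpec) -> FitSummary:
    """Ordinary least squares on the full candidate set (no elimination)."""
    result, n_missing, n_used = _fit(spec.data, spec.response, spec.candidates)
    return FitSummary(
        response=spec.response,
        terms=_term_stats(result, spec.candidates),
        dropped={},
        aic=_aic(result, len(spec.candidates)),
        n_used=n_used,
        n_missing_dropped=n_missing,
        residuals=np.asarray(result.resid),
    )


def backward_eliminate(spec: ModelSpec) -> FitSummary:
    """AIC backward elimination from the full candidate model.

    Greedy: each round drops the single term whose removal lowers AIC the
    most, stopping when no removal helps.  The final AIC is therefore no
    greater than that of any model visited.
    """
    current = list(spec.candidates)
    result, n_missing, n_used = _fit(spec.data, spec.response, current)
    aic = _aic(result, len(current))
    trace: list[tuple[str, float, float]] = []
    dropped: dict[str, TermStats] = {}

    while current:
        best_term, best_aic, best_result = None, aic, None
        for term in current:
            remaining = [t for t in current if t != term]
            cand_result, _, _ = _fit(spec.data, spec.response, remaining)
            cand_aic = _aic(cand_result, len(remaining))
            if cand_aic < best_aic - 1e-12:
                best_term, best_aic, best_result = term, cand_aic, cand_result
        if best_term is None:
            break
        stats_before = _term_stats(result, current, pre_drop=True)
        dropped[best_term] = stats_before[best_term]
        trace.append((best_term, aic, best_aic))
        current = [t for t in current if t != best_term]
        result, aic = best_result, best_aic
        logger.info(
            "dropped %s from %s model (AIC %.2f -> %.2f)",
            best_term,
            spec.response,
            trace[-1][1],
            best_aic,
        )

    return FitSummary(
        response=spec.response,
        terms=_term_stats(result, current),
        dropped=dropped,
        aic=aic,
        n_used=n_used,
        n_missing_dropped=n_missing,
        residuals=np.asarray(result.resid),
        elimination_trace=trace,
    )


# ---------------------------------------------------------------------------
# the study's prediction models
# ---------------------------------------------------------------------------

#: Carcass-mass variants tried for each model; the one whose reduced model
#: attains the lowest AIC is reported, flagged in ``FitSummary.mass_variant``.
_MASS_VARIANTS = ("carcass_mass_prepared", "carcass_mass_unprepared", "mass_change")

_PREDICTION_MODELS: dict[str, dict] = {
    "roundness": {
        "base": (
            "male_size",
            "female_size",
            "male_desertion_time",
            "female_desertion_time",
        ),
        # roundness is regressed on the pre-preparation mass or the mass lost,
        # never on the prepared mass it partly determines
        "mass_variants": ("carcass_mass_unprepared", "mass_change"),
    },
    "female_lifespan": {
        "base": (
            "roundness",
            "male_size",
            "female_size",
            "male_desertion_time",
            "female_desertion_time",
        ),
        "mass_variants": _MASS_VARIANTS,
    },
    "male_lifespan": {
        "base": (
            "roundness",
            "male_size",
            "female_size",
            "male_desertion_time",
            "female_desertion_time",
        ),
        "mass_variants": _MASS_VARIANTS,
    },
    "brood_size": {
        "base": (
            "roundness",
            "male_size",
            "female_size",
            "male_desertion_time",
            "female_desertion_time",
        ),
        "mass_variants": _MASS_VARIANTS,
    },
    "avg_larval_mass": {
        "base": (
            "roundness",
            "male_size",
            "female_size",
            "male_desertion_time",
            "female_desertion_time",
            "brood_size",
        ),
        "mass_variants": _MASS_VARIANTS,
    },
}


def require_schema(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(missing)


def run_prediction_models(table: pd.DataFrame) -> dict[str, FitSummary]:
    """Fit and reduce the five study models.

    Each model is fitted once per carcass-mass variant (prepared mass,
    unprepared mass, or the preparation mass change); the variant whose
    reduced model has the lowest AIC is reported and flagged.
    """
    require_schema(table)
    out: dict[str, FitSummary] = {}
    for response, cfg in _PREDICTION_MODELS.items():
        best: FitSummary | None = None
        for variant in cfg["mass_variants"]:
            spec = ModelSpec(
                response=response,
                candidates=(*cfg["base"], variant),
                data=table,
            )
            summary = backward_eliminate(spec)
            summary.mass_variant = variant
            if best is None or summary.aic < best.aic:
                best = summary
        out[response] = best
    return out


# ---------------------------------------------------------------------------
# variance comparisons
# ---------------------------------------------------------------------------


def compare_variances(
    table: pd.DataFrame,
    response: str,
    split_variable: str = "roundness",
    center: Literal["median", "mean"] = "median",
) -> VarianceComparison:
    """Levene test of variance homogeneity between round and not-round nests.

    Pairs are split at the sample mean of ``split_variable`` ('round' means
    strictly above the mean).  The default is the median-centered
    (Brown-Forsythe) statistic; the mean-centered one is computed too so a
    disagreement about significance is visible in the output.
    """
    for col in (response, split_variable):
        if col not in table.columns:
            raise SchemaError([col])
    sub = table[[response, split_variable]].dropna()
    cut = float(sub[split_variable].mean())
    round_grp = sub.loc[sub[split_variable] > cut, response].to_numpy(float)
    flat_grp = sub.loc[sub[split_variable] <= cut, response].to_numpy(float)
    if len(round_grp) < 2 or len(flat_grp) < 2:
        raise InsufficientGroupError(
            f"groups of sizes {len(round_grp)} and {len(flat_grp)}; "
            "need >= 2 each"
        )

    def _levene(c):
        groups = (round_grp, flat_grp)
        if all(np.ptp(g) == 0 for g in groups):
            return 0.0, 1.0  # no spread anywhere: variances trivially equal
        f, p = stats.levene(*groups, center=c)
        return float(f), float(p)

    f_med, p_med = _levene("median")
    f_mean, p_mean = _levene("mean")
    f, p = (f_med, p_med) if center == "median" else (f_mean, p_mean)
    n = len(round_grp) + len(flat_grp)
    return VarianceComparison(
        split_variable=split_variable,
        split_value=cut,
        response=response,
        n_round=len(round_grp),
        n_not_round=len(flat_grp),
        f=f,
        df=(1, n - 2),
        p=p,
        f_mean_centered=f_mean,
        p_mean_centered=p_mean,
        center=center,
    )


VARIANCE_RESPONSES = ("brood_size", "avg_larval_mass", "larval_density")


def run_variance_comparisons(
    table: pd.DataFrame, center: Literal["median", "mean"] = "median"
) -> dict[str, VarianceComparison]:
    """Run the three study variance comparisons (brood size, average larval
    mass, larval density) split at mean roundness."""
    return {
        resp: compare_variances(table, resp, center=center)
        for resp in VARIANCE_RESPONSES
    }
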