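"""Inferential statistics: 2x2 odds ratios and spline prevalence curves.

The odds ratio for a 2x2 table uses the cross-product estimate with the
Woolf (logit) confidence interval, exp(ln OR ± z·sqrt(1/a+1/b+1/c+1/d)),
and a two-sided Wald p-value — for a single binary predictor this is
identical to a simple logistic regression. Prevalence over a continuous
predictor (age in years, imputed body weight in kg) is modelled by
logistic regression on a natural cubic spline basis with 4 degrees of
freedom by default, with a pointwise 95% band from the delta method on
the linear predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import build_design_matrices, dmatrix
from scipy.special import expit
from scipy.stats import norm

from .model import ContingencyTable2x2, ORResult, SplineModelSpec


class SplineFitError(RuntimeError):
    """Spline logistic fit failed (separation, non-convergence, or too few
    events)."""


def odds_ratio(
    table: ContingencyTable2x2,
    alpha: float = 0.05,
    continuity_correction: bool = False,
) -> ORResult:
    """Odds ratio with Woolf (logit) CI and two-sided Wald p-value.

    A zero cell leaves the OR undefined; pass
    ``continuity_correction=True`` to add 0.5 to every cell (Haldane-
    Anscombe) instead of erroring.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if table.has_zero_cell:
        if not continuity_correction:
            raise ValueError(
                "odds ratio undefined with a zero cell; re-run with "
                "continuity_correction=True to apply the 0.5 correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(1 - alpha / 2)
    log_or = np.log(or_point)
    ci_low = float(np.exp(log_or - z * se))
    ci_high = float(np.exp(log_or + z * se))
    p = float(2 * norm.sf(abs(log_or) / se))
    return ORResult(float(or_point), ci_low, ci_high, p)


def _require_both_levels(flags: pd.Series, name: str) -> None:
    n_yes = int(flags.sum())
    n_no = int((~flags).sum())
    if n_yes == 0 or n_no == 0:
        empty = f"{name}=yes" if n_yes == 0 else f"{name}=no"
        raise ValueError(f"empty stratum: no consultations with {empty}")


def _table(flags: pd.Series, outcome: pd.Series) -> ContingencyTable2x2:
    flags = flags.astype(bool)
    outcome = outcome.astype(bool)
    return ContingencyTable2x2(
        a=int((flags & outcome).sum()),
        b=int((flags & ~outcome).sum()),
        c=int((~flags & outcome).sum()),
        d=int((~flags & ~outcome).sum()),
    )


def indication_occurrence_table(
    consults: pd.DataFrame, flag: str, category: str
) -> ContingencyTable2x2:
    """Predisposition flag x occurrence of an indication category, over all
    consultations."""
    flags = consults[flag].fillna(False).astype(bool)
    _require_both_levels(flags, flag)
    return _table(flags, consults["indication"] == category)


def treatment_table(consults: pd.DataFrame, flag: str) -> ContingencyTable2x2:
    """Predisposition flag x antibiotic treatment, over all consultations."""
    flags = consults[flag].fillna(False).astype(bool)
    _require_both_levels(flags, flag)
    return _table(flags, consults["treated"])


def treatment_within_indication_table(
    consults: pd.DataFrame, flag: str, category: str
) -> ContingencyTable2x2:
    """Predisposition flag x treatment, restricted to consultations with the
    related indication."""
    subset = consults[consults["indication"] == category]
    if len(subset) == 0:
        raise ValueError(f"empty stratum: no consultations with indication {category!r}")
    flags = subset[flag].fillna(False).astype(bool)
    _require_both_levels(flags, flag)
    return _table(flags, subset["treated"])


@dataclass
class PrevalenceCurve:
    """Fitted prevalence over a predictor grid with a pointwise CI band."""

    predictor: str
    curve: pd.DataFrame  # columns: grid value, probability, lower, upper
    n_observations: int
    n_events: int
    degrees_of_freedom: int
    converged: bool


def fit_spline_prevalence(
    consults: pd.DataFrame,
    spec: SplineModelSpec = SplineModelSpec(),
    grid: np.ndarray | None = None,
    n_grid: int = 25,
    alpha: float = 0.05,
    min_events: int = 10,
) -> PrevalenceCurve:
    """Fit the natural-spline logistic prevalence model.

    Knots sit at quantiles of the predictor (the basis default). The
    returned table carries the probability and the pointwise
    ``1 - alpha`` band over the grid (2nd-98th percentile of the data by
    default); coefficient values are deliberately not part of the
    interface.
    """
    x = pd.to_numeric(consults[spec.predictor], errors="coerce")
    y = consults[spec.outcome].astype(bool)
    mask = x.notna() & np.isfinite(x)
    x = x[mask].to_numpy(float)
    y = y[mask].to_numpy()
    n_events = int(y.sum())
    n_nonevents = int((~y).sum())
    if n_events < min_events or n_nonevents < min_events:
        raise SplineFitError(
            f"too few events/non-events for a stable fit "
            f"({n_events} events, {n_nonevents} non-events; need >= {min_events})"
        )
    design = dmatrix(
        f"cr(x, df={spec.degrees_of_freedom})", {"x": x}, return_type="dataframe"
    )
    model = sm.GLM(y.astype(float), design, family=sm.families.Binomial())
    try:
        fit = model.fit(maxiter=100)
    except Exception as err:  # pragma: no cover - statsmodels failure modes
        raise SplineFitError(f"spline logistic fit failed: {err}") from err
    params = np.asarray(fit.params, float)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 50:
        raise SplineFitError("fit diverged (possible separation)")

    if grid is None:
        lo, hi = np.quantile(x, [0.02, 0.98])
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, float)
    (new_design,) = build_design_matrices([design.design_info], {"x": grid})
    X = np.asarray(new_design)
    eta = X @ params
    cov = np.asarray(fit.cov_params())
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
    z = norm.ppf(1 - alpha / 2)
    curve = pd.DataFrame(
        {
            spec.predictor: grid,
            "probability": expit(eta),
            "lower": expit(eta - z * se),
            "upper": expit(eta + z * se),
        }
    )
    return PrevalenceCurve(
        predictor=spec.predictor,
        curve=curve,
        n_observations=len(x),
        n_events=n_events,
        degrees_of_freedom=spec.degrees_of_freedom,
        converged=bool(getattr(fit, "converged", True)),
    )


@dataclass
class CrossbreedComparison:
    """Treatment share of crossbreeds vs pure breeds, with the OR."""

    table: ContingencyTable2x2
    crossbreed_percent: float
    purebreed_percent: float
    n_crossbreed: int
    n_purebreed: int
    or_result: ORResult


def crossbreed_comparison(consults: pd.DataFrame) -> CrossbreedComparison:
    """Compare antibiotic-treatment probability between crossbreed and
    pure-breed dogs (exposure = crossbreed, outcome = treated)."""
    dogs = consults[consults["species"] == "dog"]
    flags = dogs["crossbreed"].fillna(False).astype(bool)
    _require_both_levels(flags, "crossbreed")
    table = _table(flags, dogs["treated"])
    return CrossbreedComparison(
        table=table,
        crossbreed_percent=table.percent_outcome_exposed(),
        purebreed_percent=table.percent_outcome_unexposed(),
        n_crossbreed=table.a + table.b,
        n_purebreed=table.c + table.d,
        or_result=odds_ratio(table),
    )


def simulate_null_coverage(
    n_replicates: int = 1000,
    n_per_arm: int = 200,
    p_outcome: float = 0.3,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null (OR = 1) replicates whose Woolf CI contains 1.

    Each replicate draws outcome counts from two independent binomials with
    the same outcome probability; replicates with a zero cell (essentially
    impossible at the default sizes) use the continuity correction.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        a = int(rng.binomial(n_per_arm, p_outcome))
        c = int(rng.binomial(n_per_arm, p_outcome))
        table = ContingencyTable2x2(a, n_per_arm - a, c, n_per_arm - c)
        result = odds_ratio(table, alpha=alpha, continuity_correction=True)
        if result.ci_low <= 1.0 <= result.ci_high:
            hits += 1
    return hits / n_replicates
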