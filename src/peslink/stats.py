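"""Statistical layer: contingency tables, crude odds ratios with Woolf
confidence intervals, Pearson chi-square tests, linkage-bias diagnostics,
and multivariable logistic regression fitted by iteratively reweighted
least squares (IRLS) with Wald intervals and pseudo-R-squared measures.

The logistic fitter is authored here rather than delegated so that every
numerical choice (convergence rule, separation handling, covariance) is
explicit and auditable; an off-the-shelf GLM fit serves as a cross-check
oracle in the test suite only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist

from .errors import (DegenerateTableError, RankDeficiencyError,
                     SeparationError, ValidationError)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

#: Fixed reference levels of the multivariable models.
REFERENCE_LEVELS = {
    "sex": "male",
    "age_group": "45-54",
    "los_group": "1-3",
    "cssa": False,
    "specialty_group": "Others",
}

#: Dummy-coded model terms: (column name, source variable, matching level).
MODEL_TERMS: tuple[tuple[str, str, object], ...] = (
    ("female", "sex", "female"),
    ("age_55_64", "age_group", "55-64"),
    ("age_65_74", "age_group", "65-74"),
    ("age_75p", "age_group", "75+"),
    ("los_4_7", "los_group", "4-7"),
    ("los_8p", "los_group", "8+"),
    ("cssa", "cssa", True),
    ("medicine", "specialty_group", "Medicine"),
    ("oncology", "specialty_group", "Oncology"),
    ("surgery", "specialty_group", "Surgery"),
)

OUTCOME_COLUMNS = {"any": "readmit_any", "ae": "readmit_ae", "opd": "readmit_opd"}
EXPOSURE_COLUMNS = {"quality": "quality_high", "experience": "experience_high"}


# --------------------------------------------------------------------------
# Contingency tables


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple
    col_labels: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or (self.counts < 0).any():
            raise DegenerateTableError(
                "a contingency table must be a 2-D array of non-negative counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def crosstab(analysis: pd.DataFrame, row_var: str, outcome_flag: str,
             level_order: Sequence | None = None) -> pd.DataFrame:
    """Per-level outcome counts and row percentages (descriptive-table layout).

    Returns one row per level of ``row_var`` with the level size ``n``, the
    count of outcome-positive patients ``events`` and the within-level
    percentage ``pct`` (``None`` when the level is empty).
    """
    for col in (row_var, outcome_flag):
        if col not in analysis.columns:
            raise ValidationError(f"unknown variable {col!r}")
    levels = (list(level_order) if level_order is not None
              else sorted(analysis[row_var].dropna().unique(), key=str))
    rows = []
    for level in levels:
        sub = analysis[analysis[row_var] == level]
        n, events = len(sub), int(sub[outcome_flag].sum())
        pct = round(100.0 * events / n, 1) if n else None
        rows.append({"level": level, "n": n, "events": events, "pct": pct})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Crude odds ratio with Woolf CI


@dataclass
class OddsRatioEstimate:
    or_: float
    log_or: float
    se_log_or: float
    ci_low: float
    ci_high: float
    continuity_applied: bool = False


def odds_ratio_woolf(a: float, b: float, c: float, d: float,
                     continuity: bool = False) -> OddsRatioEstimate:
    """Crude odds ratio of a 2x2 table with a Woolf (log-scale) 95% CI.

    Cell orientation: (exposed-event, exposed-nonevent, unexposed-event,
    unexposed-nonevent). A zero cell is an error unless ``continuity=True``
    applies the Haldane-Anscombe +0.5 to every cell (flagged in the result).
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise DegenerateTableError("negative cell count")
    if 0 in cells:
        if not continuity:
            raise DegenerateTableError(
                "zero cell in the 2x2 table; pass continuity=True for the "
                "Haldane-Anscombe correction")
        a, b, c, d = (x + 0.5 for x in cells)
        applied = True
    else:
        applied = False
    log_or = float(np.log((a * d) / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return OddsRatioEstimate(
        or_=float(np.exp(log_or)), log_or=log_or, se_log_or=se,
        ci_low=float(np.exp(log_or - Z_95 * se)),
        ci_high=float(np.exp(log_or + Z_95 * se)),
        continuity_applied=applied)


# --------------------------------------------------------------------------
# Pearson chi-square


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p_value: float


def pearson_chi2(table: ContingencyTable | np.ndarray) -> Chi2Result:
    """Pearson chi-square test of independence, no continuity correction.

    E is the usual margins product; df = (r-1)(c-1); p from the upper tail.
    """
    counts = table.counts if isinstance(table, ContingencyTable) \
        else np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise DegenerateTableError("need an r x c table with r, c >= 2")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise DegenerateTableError("zero row or column margin")
    expected = np.outer(row, col) / counts.sum()
    statistic = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return Chi2Result(statistic=statistic, df=df,
                      p_value=float(chi2_dist.sf(statistic, df)))


DEFAULT_EXPERIENCE_BINS: tuple[int, ...] = (4, 5, 6, 7, 8, 9)
"""Upper edges splitting the 0-10 score into {<=4, 5, 6, 7, 8, 9, 10}."""


def bin_scores(scores: Sequence[int], upper_edges: Sequence[int]) -> np.ndarray:
    """Map ordinal scores to category indices by inclusive upper edges."""
    return np.searchsorted(np.asarray(upper_edges), np.asarray(scores))


def linkage_bias_test(matched_scores: Sequence[int],
                      unmatched_scores: Sequence[int],
                      upper_edges: Sequence[int] | None = None) -> Chi2Result:
    """Chi-square comparison of an evaluative score between linkage groups.

    Builds the 2 x k matched-status-by-category table and delegates to
    :func:`pearson_chi2`. ``upper_edges=None`` keeps each distinct score as
    its own category (the native binning of the 5-level quality rating);
    categories empty in both groups are dropped so margins stay positive.
    """
    matched = np.asarray(matched_scores)
    unmatched = np.asarray(unmatched_scores)
    if upper_edges is None:
        levels = np.unique(np.concatenate([matched, unmatched]))
        m_idx = np.searchsorted(levels, matched)
        u_idx = np.searchsorted(levels, unmatched)
        k = len(levels)
    else:
        m_idx = bin_scores(matched, upper_edges)
        u_idx = bin_scores(unmatched, upper_edges)
        k = len(upper_edges) + 1
    counts = np.zeros((2, k))
    np.add.at(counts[0], m_idx, 1)
    np.add.at(counts[1], u_idx, 1)
    counts = counts[:, counts.sum(axis=0) > 0]
    return pearson_chi2(counts)


# --------------------------------------------------------------------------
# Logistic regression by IRLS


@dataclass
class LogisticFit:
    names: tuple[str, ...]
    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    null_log_likelihood: float
    converged: bool
    n_iterations: int
    n_obs: int

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def conf_int(self) -> np.ndarray:
        """Wald 95% intervals on the odds-ratio scale, one (low, high) row
        per coefficient."""
        se = self.standard_errors
        with np.errstate(over="ignore"):  # huge SEs give an infinite bound
            return np.exp(np.column_stack([self.coefficients - Z_95 * se,
                                           self.coefficients + Z_95 * se]))

    @property
    def r2_mcfadden(self) -> float:
        return 1.0 - self.log_likelihood / self.null_log_likelihood \
            if self.null_log_likelihood != 0 else 0.0

    @property
    def r2_nagelkerke(self) -> float:
        n = self.n_obs
        cox_snell = 1.0 - np.exp(2.0 * (self.null_log_likelihood
                                        - self.log_likelihood) / n)
        ceiling = 1.0 - np.exp(2.0 * self.null_log_likelihood / n)
        return float(cox_snell / ceiling) if ceiling > 0 else 0.0

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "term": self.names,
            "coef": self.coefficients,
            "se": self.standard_errors,
            "or": self.odds_ratios,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        })


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps
    deficient = s < tol
    if deficient.any():
        loadings = np.abs(vt[deficient]).max(axis=0)
        cols = [n for n, w in zip(names, loadings) if w > 0.1]
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear columns: {cols}")


def fit_logistic_irls(design: pd.DataFrame | np.ndarray,
                      outcome: Sequence[int] | np.ndarray,
                      names: Sequence[str] | None = None,
                      max_iter: int = 100, tol: float = 1e-10) -> LogisticFit:
    """Fit a binary logistic model by Newton/IRLS.

    Converges when the relative change in log-likelihood falls below
    ``tol``. Perfect (or quasi-perfect) separation is detected — diverging
    linear predictor with error-free classification — and raises
    :class:`SeparationError` rather than reporting meaningless estimates.
    """
    if isinstance(design, pd.DataFrame):
        names = tuple(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = tuple(names) if names is not None \
            else tuple(f"x{i}" for i in range(X.shape[1]))
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    if X.shape[0] != y.shape[0]:
        raise ValidationError("design and outcome lengths differ")
    _check_rank(X, names)

    beta = np.zeros(X.shape[1])
    ll_old = _log_likelihood(y, X @ beta)
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        eta = X @ beta
        if np.abs(eta).max() > 30.0:
            mu = expit(eta)
            if np.all((mu > 0.5) == (y == 1.0)):
                raise SeparationError(
                    "perfect separation detected: estimates diverge")
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        xtw = X.T * w
        beta = np.linalg.solve(xtw @ X, xtw @ z)
        ll = _log_likelihood(y, X @ beta)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1e-12):
            converged = True
            ll_old = ll
            break
        ll_old = ll

    eta = X @ beta
    mu = expit(eta)
    if np.abs(beta).max() > 30.0:
        raise SeparationError("perfect separation detected: estimates diverge")
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    covariance = np.linalg.inv((X.T * w) @ X)

    p_bar = y.mean()
    if p_bar in (0.0, 1.0):
        ll0 = 0.0
    else:
        ll0 = float(len(y) * (p_bar * np.log(p_bar)
                              + (1 - p_bar) * np.log(1 - p_bar)))
    return LogisticFit(names=names, coefficients=beta, covariance=covariance,
                       log_likelihood=ll_old, null_log_likelihood=ll0,
                       converged=converged, n_iterations=iteration,
                       n_obs=len(y))


# --------------------------------------------------------------------------
# Model assembly on the analysis table


def build_design(analysis: pd.DataFrame, exposure: str = "quality"
                 ) -> pd.DataFrame:
    """Dummy-code the analysis table against the fixed reference levels.

    ``exposure`` selects which evaluative response enters the model:
    ``"quality"`` (top-two levels vs rest) or ``"experience"`` (score >= 8
    vs below).
    """
    if exposure not in EXPOSURE_COLUMNS:
        raise ValidationError(f"unknown exposure {exposure!r}")
    cols = {"intercept": np.ones(len(analysis))}
    for name, var, level in MODEL_TERMS:
        cols[name] = (analysis[var] == level).astype(float).to_numpy()
    cols["quality_high" if exposure == "quality" else "experience_high"] = \
        analysis[EXPOSURE_COLUMNS[exposure]].astype(float).to_numpy()
    return pd.DataFrame(cols, index=analysis.index)


def fit_outcome_models(analysis: pd.DataFrame, exposure: str = "quality"
                       ) -> dict[str, LogisticFit]:
    """Fit the three readmission-source models (any / A&E / outpatient)."""
    design = build_design(analysis, exposure)
    return {model: fit_logistic_irls(design, analysis[col].astype(int))
            for model, col in OUTCOME_COLUMNS.items()}


def model_tables(fits: Mapping[str, LogisticFit]) -> pd.DataFrame:
    """Render adjusted ORs as a publication-style table.

    Reference levels show "Ref"; estimates whose 95% CI excludes 1 carry a
    trailing ``*`` (two-sided 0.05 convention); the intercept row is
    included.
    """
    variables: list[tuple[str, str | None]] = [("intercept", None)]
    seen = set()
    for name, var, level in MODEL_TERMS:
        if var not in seen:
            seen.add(var)
            ref = REFERENCE_LEVELS[var]
            variables.append((f"{var}={ref}", "REF"))
        variables.append((name, None))
    any_fit = next(iter(fits.values()))
    exposure = any_fit.names[-1]
    exposure_var = "quality_rating" if exposure == "quality_high" \
        else "experience_score"
    variables.append((f"{exposure_var}=low", "REF"))
    variables.append((exposure, None))

    table = {"term": [v for v, _ in variables]}
    for model, fit in fits.items():
        ci = fit.conf_int()
        rendered = []
        lookup = {n: i for i, n in enumerate(fit.names)}
        for term, kind in variables:
            if kind == "REF":
                rendered.append("Ref")
                continue
            i = lookup[term]
            star = "*" if ci[i, 0] > 1.0 or ci[i, 1] < 1.0 else ""
            rendered.append(
                f"{fit.odds_ratios[i]:.2f} ({ci[i, 0]:.2f}-{ci[i, 1]:.2f}){star}")
        table[model] = rendered
    return pd.DataFrame(table)
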