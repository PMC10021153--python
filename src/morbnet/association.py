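"""Age-adjusted pairwise logistic regression and edge selection.

For every unordered disease pair the outcome disease is regressed on an
intercept, the exposure disease indicator and age (in years, centered
at 60), by maximum likelihood via iteratively reweighted least squares
(IRLS).  ``exp`` of the exposure coefficient is the age-adjusted odds
ratio; a Wald normal-approximation p-value accompanies it.

Because the final network is undirected, each pair is fitted in both
outcome/exposure orientations and the symmetric edge statistic is the
geometric mean of the two adjusted ORs with the larger (more
conservative) of the two p-values; a single-orientation mode is
available for comparison.  An edge enters the network iff
``p < alpha`` and ``OR >= or_min`` (defaults 0.05 and 1.2; the OR
boundary is inclusive, the p boundary exclusive).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codebook import Cohort, DiseaseCode

__all__ = [
    "PairwiseAssociation",
    "EdgeRecord",
    "LogisticFit",
    "irls_logistic",
    "fit_age_adjusted_logistic",
    "all_pairs",
    "filter_edges",
    "benjamini_hochberg",
    "AGE_CENTER",
    "MAX_ITER",
    "TOL",
    "SEPARATION_BOUND",
]

AGE_CENTER = 60.0          # years; centering aids IRLS conditioning
MAX_ITER = 50
TOL = 1e-8                 # max |coefficient change| declaring convergence
SEPARATION_BOUND = 15.0    # |logit coefficient| beyond which we flag separation


@dataclass(frozen=True)
class PairwiseAssociation:
    """Symmetrized age-adjusted association for one unordered pair."""

    outcome: str
    exposure: str
    or_adj: float
    se_log_or: float
    p_value: float
    converged: bool


@dataclass(frozen=True)
class EdgeRecord:
    """One candidate network edge with its inclusion decision."""

    node_a: str
    node_b: str
    weight: float
    included: bool


@dataclass
class LogisticFit:
    """Raw IRLS output for one orientation of one pair."""

    coef: np.ndarray          # (intercept, exposure, [age])
    se: np.ndarray
    converged: bool
    n_iter: int
    has_age_term: bool


def irls_logistic(X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None,
                  robust: bool = False) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Logistic maximum likelihood by iteratively reweighted least squares.

    Newton-Raphson with the expected (= observed, for the canonical
    link) information; ``weights`` are frequency-style case weights.
    Returns ``(coef, se, converged, n_iter)``.  Convergence is declared
    when the largest absolute coefficient update falls below 1e-8;
    divergence beyond +/-15 on the logit scale (perfect or quasi-perfect
    separation) or hitting the 50-iteration cap reports
    ``converged=False``.  With ``robust=True`` the standard errors are
    the sandwich (Huber-White) variant, appropriate when the case
    weights are survey expansion factors rather than replicate counts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    beta = np.zeros(p)
    converged = False
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        wz = w * mu * (1.0 - mu)
        H = (X * wz[:, None]).T @ X
        g = X.T @ (w * (y - mu))
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.abs(beta).max() > SEPARATION_BOUND:
            break
        if np.abs(step).max() < TOL:
            converged = True
            break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    wz = w * mu * (1.0 - mu)
    H = (X * wz[:, None]).T @ X
    try:
        H_inv = np.linalg.inv(H)
        if robust:
            score = X * (w * (y - mu))[:, None]
            V = H_inv @ (score.T @ score) @ H_inv
        else:
            V = H_inv
        se = np.sqrt(np.clip(np.diag(V), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    return beta, se, converged, n_iter


def _design(cohort: Cohort, outcome_code: str, exposure_code: str
            ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Design matrix (intercept, exposure, age-60); age dropped if constant."""
    y = cohort.df[outcome_code].to_numpy(dtype=float)
    x = cohort.df[exposure_code].to_numpy(dtype=float)
    age = cohort.age - AGE_CENTER
    has_age = bool(np.ptp(age) > 0)
    if has_age:
        X = np.column_stack([np.ones_like(y), x, age])
    else:
        # constant age is collinear with the intercept: adjustment is vacuous
        X = np.column_stack([np.ones_like(y), x])
    return X, y, has_age


def _fit_one(cohort: Cohort, outcome_code: str, exposure_code: str,
             use_weights: bool, robust_se: bool) -> LogisticFit:
    X, y, has_age = _design(cohort, outcome_code, exposure_code)
    x = X[:, 1]
    if y.min() == y.max():
        raise ValueError(f"outcome {outcome_code} is degenerate (all {int(y[0])})")
    if x.min() == x.max():
        raise ValueError(f"exposure {exposure_code} is degenerate (all {int(x[0])})")
    w = cohort.weight if use_weights else None
    coef, se, converged, n_iter = irls_logistic(X, y, weights=w, robust=robust_se)
    return LogisticFit(coef, se, converged, n_iter, has_age)


def fit_age_adjusted_logistic(cohort: Cohort, outcome, exposure,
                              use_weights: bool = True,
                              robust_se: bool = False) -> PairwiseAssociation:
    """Fit one orientation: logistic of ``outcome`` on ``exposure`` + age.

    Returns the adjusted OR (``exp`` of the exposure coefficient), the
    Wald standard error on the log-OR scale, and the two-sided normal
    p-value.  Survey weights enter as frequency-style case weights by
    default.  Perfect separation or non-convergence is reported as
    ``converged=False`` with NaN statistics rather than a spurious
    estimate; a degenerate outcome or exposure column raises.
    """
    out_code = outcome.code if isinstance(outcome, DiseaseCode) else str(outcome)
    exp_code = exposure.code if isinstance(exposure, DiseaseCode) else str(exposure)
    if out_code == exp_code:
        raise ValueError("outcome and exposure must differ")
    if cohort.n == 0:
        raise ValueError("cannot fit on an empty cohort")
    fit = _fit_one(cohort, out_code, exp_code, use_weights, robust_se)
    if not fit.converged or not np.isfinite(fit.se[1]) or fit.se[1] <= 0:
        return PairwiseAssociation(out_code, exp_code, np.nan, np.nan, np.nan, False)
    log_or = fit.coef[1]
    se = fit.se[1]
    z = log_or / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return PairwiseAssociation(out_code, exp_code, float(np.exp(log_or)), float(se), p, True)


def _symmetrize(a_on_b: PairwiseAssociation, b_on_a: PairwiseAssociation,
                pair: tuple[str, str], orientation: str) -> PairwiseAssociation:
    a, b = pair
    if orientation == "first":
        f = a_on_b
        return PairwiseAssociation(f.outcome, f.exposure, f.or_adj, f.se_log_or,
                                   f.p_value, f.converged)
    if orientation != "both-geomean":
        raise ValueError(f"unknown orientation rule {orientation!r}")
    if not (a_on_b.converged and b_on_a.converged):
        return PairwiseAssociation(a, b, np.nan, np.nan, np.nan, False)
    or_geo = float(np.sqrt(a_on_b.or_adj * b_on_a.or_adj))
    p = float(max(a_on_b.p_value, b_on_a.p_value))
    se = float(max(a_on_b.se_log_or, b_on_a.se_log_or))  # conservative
    return PairwiseAssociation(a, b, or_geo, se, p, True)


def all_pairs(cohort: Cohort, use_weights: bool = True, robust_se: bool = False,
              orientation: str = "both-geomean") -> list[PairwiseAssociation]:
    """Symmetrized age-adjusted association for every unordered pair.

    One record per pair (120 for the 16-disease codebook), in codebook
    order.  With ``orientation="both-geomean"`` (default) each pair is
    fitted in both directions and symmetrized; ``"first"`` keeps only
    the fit of the codebook-later disease on the codebook-earlier one.
    Pairs involving a degenerate (all-0 or all-1) disease are carried
    through flagged ``converged=False`` instead of raising.
    """
    codes = cohort.codes
    degenerate = {c for c in codes
                  if cohort.df[c].min() == cohort.df[c].max()}
    results: list[PairwiseAssociation] = []
    for a, b in itertools.combinations(codes, 2):
        if a in degenerate or b in degenerate:
            results.append(PairwiseAssociation(a, b, np.nan, np.nan, np.nan, False))
            continue
        # outcome=b, exposure=a is the "first" (codebook-order) orientation
        b_on_a = fit_age_adjusted_logistic(cohort, b, a, use_weights, robust_se)
        a_on_b = fit_age_adjusted_logistic(cohort, a, b, use_weights, robust_se)
        results.append(_symmetrize(b_on_a, a_on_b, (a, b), orientation))
    return results


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(p_values, dtype=float)
    adj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    q = p[ok]
    m = q.size
    order = np.argsort(q)
    ranked = q[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    adj[ok] = out
    return adj


def filter_edges(associations: list[PairwiseAssociation], or_min: float = 1.2,
                 alpha: float = 0.05, bh: bool = False) -> list[EdgeRecord]:
    """Apply the edge-inclusion rule: ``p < alpha`` and ``OR >= or_min``.

    Boundary semantics: an OR exactly at ``or_min`` is included, a
    p-value exactly at ``alpha`` is excluded.  Non-converged pairs are
    never included.  ``bh=True`` applies a Benjamini-Hochberg correction
    across the pairs before thresholding (a documented deviation from
    the raw-p rule).  Returns one :class:`EdgeRecord` per association,
    preserving order.
    """
    if or_min <= 0 or alpha <= 0:
        raise ValueError("thresholds must be positive")
    p_vals = np.array([a.p_value for a in associations], dtype=float)
    if bh:
        p_vals = benjamini_hochberg(p_vals)
    edges = []
    for assoc, p in zip(associations, p_vals):
        a, b = assoc.outcome, assoc.exposure
        ok = bool(assoc.converged and np.isfinite(p)
                  and p < alpha and assoc.or_adj >= or_min)
        weight = float(assoc.or_adj) if np.isfinite(assoc.or_adj) else np.nan
        edges.append(EdgeRecord(a, b, weight, ok))
    return edges


def associations_frame(associations: list[PairwiseAssociation],
                       edges: list[EdgeRecord] | None = None) -> pd.DataFrame:
    """Tabular view of associations (columns of the edges file)."""
    rows = []
    for i, assoc in enumerate(associations):
        row = {
            "disease_a": assoc.outcome,
            "disease_b": assoc.exposure,
            "or_adj": assoc.or_adj,
            "se_log_or": assoc.se_log_or,
            "p_value": assoc.p_value,
            "converged": assoc.converged,
        }
        if edges is not None:
            row["included"] = edges[i].included
        rows.append(row)
    return pd.DataFrame(rows)
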