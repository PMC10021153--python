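"""Weighted prevalence, gender chi-square comparison, and dyad matrix.

The descriptive stage mirrors the preliminary analysis of a gender-
stratified multimorbidity survey: per-disease weighted prevalence with
unweighted counts, a Pearson chi-square comparing each disease's burden
between women and men, and the 16 x 16 matrix of pairwise (dyad)
co-occurrence prevalences whose 120 upper-triangle cells underlie the
usual heat maps.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codebook import Cohort, DiseaseCode

__all__ = [
    "GenderComparison",
    "weighted_prevalence",
    "prevalence_table",
    "gender_chi_square",
    "dyad_matrix",
    "dyad_long_format",
    "rank_dyads",
    "n_dyads",
]


@dataclass(frozen=True)
class GenderComparison:
    """Pearson chi-square comparison of one disease between the genders."""

    disease: str
    chi2: float
    df: int
    p_value: float


def _code(disease) -> str:
    return disease.code if isinstance(disease, DiseaseCode) else str(disease)


def n_dyads(cohort: Cohort) -> int:
    """Number of unordered disease pairs: C(k, 2), 120 for 16 diseases."""
    k = len(cohort.codebook)
    return k * (k - 1) // 2


def weighted_prevalence(cohort: Cohort, disease) -> float:
    """Survey-weighted prevalence of one disease: sum(w*x) / sum(w)."""
    if cohort.n == 0:
        raise ValueError("weighted prevalence of an empty cohort is undefined")
    x = cohort.df[_code(disease)].to_numpy(dtype=float)
    w = cohort.weight
    return float(np.sum(w * x) / np.sum(w))


def prevalence_table(cohort: Cohort) -> pd.DataFrame:
    """Per-disease unweighted counts and weighted prevalences.

    Columns: ``disease, label, n_unweighted, prev_weighted``; rows in
    codebook order.
    """
    rows = []
    for d in cohort.codebook:
        rows.append({
            "disease": d.code,
            "label": d.label,
            "n_unweighted": int(cohort.df[d.code].sum()),
            "prev_weighted": weighted_prevalence(cohort, d),
        })
    return pd.DataFrame(rows)


def gender_chi_square(cohort_women: Cohort, cohort_men: Cohort, disease,
                      weighted: bool = False) -> GenderComparison:
    """Pearson chi-square on the 2x2 gender-by-disease table, df = 1.

    The default uses raw unweighted counts.  With ``weighted=True`` the
    cells are weighted totals rescaled so each stratum's weights sum to
    its sample size (a design-naive weighted variant; the survey's exact
    design correction is out of scope).  A zero margin (disease absent
    or universal in both strata) yields chi2 = 0, p = 1 with a warning.
    """
    code = _code(disease)
    if cohort_women.n == 0 or cohort_men.n == 0:
        raise ValueError("both gender strata must be non-empty")
    table = np.empty((2, 2), dtype=float)
    for i, cohort in enumerate((cohort_women, cohort_men)):
        x = cohort.df[code].to_numpy(dtype=float)
        if weighted:
            w = cohort.weight * (cohort.n / cohort.weight.sum())
            table[i] = (np.sum(w * x), np.sum(w * (1.0 - x)))
        else:
            table[i] = (x.sum(), len(x) - x.sum())

    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn(f"degenerate 2x2 margin for {code}; chi-square undefined, "
                      "reporting chi2=0, p=1")
        return GenderComparison(code, 0.0, 1, 1.0)

    (a, b), (c, d) = table
    n = table.sum()
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p = float(stats.chi2.sf(chi2, df=1))
    return GenderComparison(code, float(chi2), 1, p)


def dyad_matrix(cohort: Cohort, weighted: bool = True) -> pd.DataFrame:
    """16 x 16 symmetric matrix of pairwise co-occurrence prevalences.

    Cell (j, k), j != k, is the (weighted) proportion of records with
    both diseases j and k present.  The diagonal is masked with NaN;
    the 120 informative cells live in the upper triangle.
    """
    if cohort.n == 0:
        raise ValueError("dyad matrix of an empty cohort is undefined")
    ind = cohort.indicators().astype(float)
    w = cohort.weight if weighted else np.ones(cohort.n)
    joint = (ind * w[:, None]).T @ ind / w.sum()
    np.fill_diagonal(joint, np.nan)
    return pd.DataFrame(joint, index=cohort.codes, columns=cohort.codes)


def dyad_long_format(matrix: pd.DataFrame) -> pd.DataFrame:
    """Upper triangle of a dyad matrix as 120 long-format rows.

    Columns ``disease_a, disease_b, prevalence`` with the pair in
    codebook order; the machine-readable twin of the heat maps.
    """
    codes = list(matrix.index)
    rows = [{"disease_a": a, "disease_b": b, "prevalence": matrix.loc[a, b]}
            for a, b in itertools.combinations(codes, 2)]
    return pd.DataFrame(rows)


def rank_dyads(matrix: pd.DataFrame, top_k: int | None = None) -> list[tuple[tuple[str, str], float]]:
    """Dyads sorted by descending prevalence; ties broken by codebook order.

    Returns ``[((disease_a, disease_b), prevalence), ...]`` for the
    ``top_k`` most recurrent pairs (all 120 when ``top_k`` is None).
    """
    long = dyad_long_format(matrix)
    if top_k is not None and top_k > len(long):
        raise ValueError(f"top_k={top_k} exceeds the {len(long)} dyads")
    codes = list(matrix.index)
    order = {c: i for i, c in enumerate(codes)}
    ranked = sorted(
        ((tuple(r[:2]), float(r[2])) for r in long.itertuples(index=False)),
        key=lambda item: (-item[1], order[item[0][0]], order[item[0][1]]),
    )
    return ranked[:top_k] if top_k is not None else ranked
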