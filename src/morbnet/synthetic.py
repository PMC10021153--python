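"""Synthetic survey-like cohorts with known statistical structure.

Two generators cover the two properties the downstream stages must
recover:

* :func:`generate_cohort` — a latent-Gaussian (Gaussian copula)
  threshold model over all 16 diseases.  Each person draws a correlated
  16-dimensional standard normal; indicator *j* fires when the latent
  value exceeds the upper quantile of that person's age-shifted marginal
  probability.  A single correlation matrix thus controls every pairwise
  association while the marginals stay calibrated, which is what the
  edge-selection stage assumes of the real survey data (gendered
  marginal prevalences, positive pairwise association, age-dependent
  odds, heterogeneous sampling weights).
* :func:`pair_logistic_cohort` — a two-disease cohort whose
  exposure→outcome relation is an exact logistic model, so the
  age-adjusted odds ratio the association stage should recover is known
  analytically.

Both are fully reproducible from their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import special, stats

from .codebook import CODES, DEFAULT_CODEBOOK, Cohort, DiseaseCode
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "ConfigurationError",
    "default_config",
    "exchangeable_corr",
    "corr_with_pair",
    "generate_cohort",
    "pair_logistic_cohort",
    "LASI_MARGINAL_PREV",
]


class ConfigurationError(ValueError):
    """Invalid synthetic configuration (e.g. non-PSD latent correlation)."""


#: Per-gender marginal disease prevalences (proportions, codebook order)
#: of the LASI 2017-18 multimorbid strata; the default generator margins.
LASI_MARGINAL_PREV: dict[str, tuple[float, ...]] = {
    "women": (0.1075, 0.0193, 0.0387, 0.1033, 0.0428, 0.0149, 0.3469, 0.3834,
              0.0681, 0.7168, 0.4467, 0.0651, 0.1191, 0.0391, 0.1134, 0.0823),
    "men":   (0.1430, 0.0126, 0.0294, 0.1296, 0.0373, 0.0254, 0.3594, 0.3927,
              0.0728, 0.6280, 0.3241, 0.0720, 0.1499, 0.0791, 0.0382, 0.0905),
}


def exchangeable_corr(rho: float, k: int = 16) -> np.ndarray:
    """Exchangeable (compound-symmetric) correlation matrix."""
    if not -1.0 / (k - 1) < rho < 1.0:
        raise ConfigurationError(f"exchangeable rho {rho} outside valid range")
    return np.full((k, k), rho) + (1.0 - rho) * np.eye(k)


def corr_with_pair(pair: tuple[str, str], rho: float, k: int = 16,
                   codes: Sequence[str] = CODES) -> np.ndarray:
    """Identity correlation except latent correlation ``rho`` for one pair."""
    corr = np.eye(k)
    i, j = (list(codes).index(c) for c in pair)
    corr[i, j] = corr[j, i] = rho
    return corr


@dataclass
class SyntheticConfig:
    """Full parameterization of the simulated population.

    Parameters
    ----------
    n_per_gender : int
        Records drawn per gender stratum.
    marginal_prev : mapping gender -> 16 probabilities
        Target marginal prevalence of each disease at the reference age
        (60 years), strictly inside (0, 1).
    latent_corr : (16, 16) array
        Latent-normal correlation matrix; symmetric, unit diagonal,
        positive semi-definite up to 1e-8.
    age_mean, age_sd, age_min : float
        Truncated-normal age distribution in years (lower truncation 45,
        mirroring a 45-plus study population).
    age_slope : 16 floats
        Per-disease change in log-odds of disease per year of age.
    weight_logmean, weight_logsd : float
        Log-normal sampling-weight distribution.
    seed : int
        Seed for the whole draw.
    """

    n_per_gender: int = 10_000
    marginal_prev: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(LASI_MARGINAL_PREV))
    latent_corr: np.ndarray = field(default_factory=lambda: exchangeable_corr(0.15))
    age_mean: float = 60.0
    age_sd: float = 10.0
    age_min: float = 45.0
    age_slope: Sequence[float] = (0.02,) * 16
    weight_logmean: float = 0.0
    weight_logsd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        corr = np.asarray(self.latent_corr, dtype=float)
        if corr.shape != (16, 16):
            raise ConfigurationError("latent_corr must be 16x16")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ConfigurationError("latent_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ConfigurationError("latent_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ConfigurationError("latent_corr is not positive semi-definite")
        for gender, prev in self.marginal_prev.items():
            p = np.asarray(prev, dtype=float)
            if p.shape != (16,) or not ((p > 0) & (p < 1)).all():
                raise ConfigurationError(
                    f"marginal_prev[{gender!r}] must be 16 probabilities in (0,1)")
        if self.n_per_gender < 1:
            raise ConfigurationError("n_per_gender must be positive")


def default_config(**overrides) -> SyntheticConfig:
    """The default study-like configuration, with keyword overrides."""
    cfg = SyntheticConfig(**overrides)
    cfg.validate()
    return cfg


def _psd_cholesky(corr: np.ndarray) -> np.ndarray:
    """Cholesky-like factor tolerating tiny negative eigenvalues."""
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        if w.min() < -1e-8:
            raise ConfigurationError("latent_corr is not positive semi-definite")
        return v * np.sqrt(np.clip(w, 0.0, None))


def _draw_stratum(cfg: SyntheticConfig, gender: str, rng: np.random.Generator,
                  id_offset: int) -> pd.DataFrame:
    n = cfg.n_per_gender
    # ages from a truncated normal, lower-truncated at age_min
    a = (cfg.age_min - cfg.age_mean) / cfg.age_sd
    age = stats.truncnorm.rvs(a, np.inf, loc=cfg.age_mean, scale=cfg.age_sd,
                              size=n, random_state=rng)
    weight = rng.lognormal(cfg.weight_logmean, cfg.weight_logsd, size=n)

    # latent correlated normals -> age-shifted thresholds on the logit scale
    chol = _psd_cholesky(np.asarray(cfg.latent_corr, dtype=float))
    z = rng.standard_normal((n, 16)) @ chol.T
    p_ref = np.asarray(cfg.marginal_prev[gender], dtype=float)
    slope = np.asarray(cfg.age_slope, dtype=float)
    logit_p = special.logit(p_ref)[None, :] + slope[None, :] * (age[:, None] - cfg.age_mean)
    p = special.expit(logit_p)
    # indicator fires when the latent normal exceeds the upper p-quantile
    threshold = stats.norm.isf(p)
    ind = (z > threshold).astype(np.int8)

    df = pd.DataFrame(ind, columns=list(CODES))
    df.insert(0, "weight", weight)
    df.insert(0, "age", age)
    df.insert(0, "gender", gender)
    df.insert(0, "person_id", [f"S{gender[0].upper()}{id_offset + i:07d}" for i in range(n)])
    return df


def generate_cohort(config: SyntheticConfig | None = None, **overrides) -> Cohort:
    """Draw a two-stratum cohort from the latent-Gaussian threshold model.

    Returns a :class:`~morbnet.codebook.Cohort` with ``selection="all"``
    of ``2 * n_per_gender`` records (women first, then men).  With
    identity latent correlation and zero age slope each disease is an
    independent Bernoulli draw at its marginal prevalence; positive
    latent correlation induces positive odds ratios while leaving the
    marginals calibrated.
    """
    cfg = config or SyntheticConfig()
    if overrides:
        cfg = SyntheticConfig(**{**cfg.__dict__, **overrides})
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    frames = [
        _draw_stratum(cfg, "women", rng, 0),
        _draw_stratum(cfg, "men", rng, cfg.n_per_gender),
    ]
    df = pd.concat(frames, ignore_index=True)
    return Cohort(df, DEFAULT_CODEBOOK, "all")


def pair_logistic_cohort(n: int, p_exposure: float = 0.3, beta0: float = -0.85,
                         beta_exp: float = 0.0, beta_age: float = 0.0,
                         seed: int = 0, exposure: str = "HYP",
                         outcome: str = "DM", gender: str = "women") -> Cohort:
    """Two-disease cohort with an exact logistic exposure→outcome model.

    ``exposure ~ Bernoulli(p_exposure)``, ``age ~ Uniform(45, 80)`` and
    ``outcome ~ Bernoulli(expit(beta0 + beta_exp*exposure +
    beta_age*(age - 60)))``; the other 14 indicators are identically 0.
    The true age-adjusted odds ratio for the exposure is exactly
    ``exp(beta_exp)``, which makes this the recovery harness for the
    pairwise regression stage.  Uniform sampling weights.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    expo = (rng.random(n) < p_exposure).astype(np.int8)
    age = rng.uniform(45.0, 80.0, size=n)
    p_out = special.expit(beta0 + beta_exp * expo + beta_age * (age - 60.0))
    out = (rng.random(n) < p_out).astype(np.int8)

    df = pd.DataFrame(0, index=range(n), columns=list(CODES), dtype=np.int8)
    df[exposure] = expo
    df[outcome] = out
    df.insert(0, "weight", np.ones(n))
    df.insert(0, "age", age)
    df.insert(0, "gender", gender)
    df.insert(0, "person_id", [f"P{i:07d}" for i in range(n)])
    return Cohort(df, DEFAULT_CODEBOOK, "all")
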