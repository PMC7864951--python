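"""Couple-level models of ART outcomes against male age.

Fertilization and embryo-quality outcomes are per-couple success
proportions out of the retrieved oocytes, modelled by logistic regression
with the oocyte count as a frequency (observation) weight — equivalent to
expanding each couple into one row per oocyte.  Live birth is a single
event per couple and is modelled unweighted.  All outcome models adjust for
male BMI, male smoking, male infertility and female age; estimates are
odds ratios per 1 year of male age with Wald 95% CIs.

The frequency-weight semantics treat oocytes within a couple as
independent; standard errors inherit that assumption (a documented
limitation of the design).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoupleRecord",
    "OutcomeFit",
    "SeparationError",
    "fit_weighted_logistic",
    "fit_livebirth_logistic",
    "run_art_outcomes",
    "OUTCOME_COVARIATES",
    "couples_to_frame",
    "read_phenotypes",
]

# outcome models additionally adjust for female age (unlike methylation models)
OUTCOME_COVARIATES = ["male_bmi", "male_smoking", "male_infertile", "female_age"]

OUTCOME_DEFS = {
    # name -> (numerator column, denominator column or None, weighted)
    "fertilization": ("n_fertilized", "n_oocytes", True),
    "day3_hq": ("n_day3_hq", "n_fertilized", True),
    "day5_hq": ("n_day5_hq", "n_fertilized", True),
    "day5_tq": ("n_day5_tq", "n_fertilized", True),
    "live_birth": ("live_birth", None, False),
}


@dataclass
class CoupleRecord:
    """One treatment cycle: male/female covariates and ART outcome counts."""

    couple_id: str
    male_age: float
    male_bmi: float
    male_smoking: bool
    male_infertile: bool
    female_age: float
    n_oocytes: int
    n_fertilized: int
    n_day3_hq: int
    n_day5_hq: int
    n_day5_tq: int
    live_birth: bool

    def __post_init__(self) -> None:
        if not (18 <= self.male_age <= 60 and 18 <= self.female_age <= 60):
            raise ValueError(f"{self.couple_id}: age outside plausible bounds [18, 60]")
        if self.n_oocytes < 1:
            raise ValueError(f"{self.couple_id}: n_oocytes must be >= 1")
        if not (self.n_fertilized <= self.n_oocytes):
            raise ValueError(f"{self.couple_id}: fertilized exceeds oocytes")
        for col in ("n_day3_hq", "n_day5_hq", "n_day5_tq"):
            if getattr(self, col) > self.n_fertilized:
                raise ValueError(f"{self.couple_id}: {col} exceeds fertilized count")


def couples_to_frame(couples: list[CoupleRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(c) for c in couples]).set_index("couple_id")
    df["male_smoking"] = df["male_smoking"].astype(int)
    df["male_infertile"] = df["male_infertile"].astype(int)
    df["live_birth"] = df["live_birth"].astype(int)
    return df


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"couple_id": str}).set_index("couple_id")
    # route rows through CoupleRecord validation
    couples = [CoupleRecord(couple_id=str(i), **row._asdict())
               for i, row in zip(df.index, df[list(df.columns)].itertuples(index=False))]
    return couples_to_frame(couples)


class SeparationError(RuntimeError):
    """Complete (or quasi-complete) separation; names the covariate."""

    def __init__(self, covariate: str):
        self.covariate = covariate
        super().__init__(f"complete separation detected on covariate {covariate!r}")


@dataclass
class OutcomeFit:
    """A fitted logistic model; index 1 of the coefficient vector is age."""

    outcome: str
    params: np.ndarray
    se: np.ndarray
    term_names: list[str]
    weighted: bool
    loglik_trace: list[float] = field(default_factory=list, repr=False)
    n: int = 0

    @property
    def or_per_year(self) -> float:
        return float(np.exp(self.params[1]))

    @property
    def ci(self) -> tuple[float, float]:
        lo = np.exp(self.params[1] - 1.96 * self.se[1])
        hi = np.exp(self.params[1] + 1.96 * self.se[1])
        return float(lo), float(hi)

    @property
    def age_p(self) -> float:
        from scipy import stats
        z = self.params[1] / self.se[1]
        return float(2 * stats.norm.sf(abs(z)))


def _loglik(y, mu, w):
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log1p(-mu))))


def fit_weighted_logistic(
    y: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray | None = None,
    term_names: list[str] | None = None,
    outcome: str = "outcome",
    max_iter: int = 100,
    score_tol: float = 1e-8,
) -> OutcomeFit:
    """Maximum-likelihood logistic regression of a proportion outcome with
    frequency weights, by Newton–Raphson IRLS.

    `y` holds per-couple success proportions in [0, 1]; `weights` the trial
    counts (1 for binary outcomes).  Converged when every score component is
    below `score_tol`.  Step-halving keeps the weighted log-likelihood
    non-decreasing; divergence of a coefficient is diagnosed as complete
    separation and reported with the offending covariate's name.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, k = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    if ((y < 0) | (y > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    names = term_names or ["intercept", "male_age"] + [f"x{j}" for j in range(2, k)]
    if np.all(y == y[0]) and y[0] in (0.0, 1.0):
        # all-success / all-failure: the MLE intercept is at the boundary
        raise SeparationError(names[0])
    beta = np.zeros(k)
    ybar = np.clip(np.average(y, weights=w), 1e-6, 1 - 1e-6)
    beta[0] = np.log(ybar / (1 - ybar))
    eta = X @ beta
    mu = 1 / (1 + np.exp(-eta))
    ll = _loglik(y, mu, w)
    trace = [ll]
    for _ in range(max_iter):
        score = X.T @ (w * (y - mu))
        if np.max(np.abs(score)) < score_tol:
            break
        W = w * mu * (1 - mu)
        if np.max(W) < 1e-12:
            raise SeparationError(names[int(np.argmax(np.abs(beta)))])
        info = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(names[int(np.argmax(np.abs(beta)))]) from exc
        # step-halving: never decrease the weighted log-likelihood
        lam = 1.0
        improved = False
        for _half in range(30):
            cand = beta + lam * step
            mu_c = 1 / (1 + np.exp(-(X @ cand)))
            ll_c = _loglik(y, mu_c, w)
            if ll_c >= ll - 1e-12:
                improved = True
                break
            lam /= 2
        if not improved or np.max(np.abs(lam * step)) < 1e-13:
            # numerical optimum: the likelihood cannot be improved further
            break
        beta, mu, ll = cand, mu_c, ll_c
        trace.append(ll)
        if np.max(np.abs(beta)) > 30:
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError(names[j])
    else:
        raise RuntimeError(f"IRLS did not converge in {max_iter} iterations")
    W = w * mu * (1 - mu)
    info = X.T @ (X * W[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return OutcomeFit(outcome, beta, se, names, weights is not None, trace, n)


def _design(pheno: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(pheno)), pheno["male_age"].to_numpy(float)]
    for c in covariates:
        cols.append(pheno[c].to_numpy(float))
    return np.column_stack(cols), ["intercept", "male_age"] + list(covariates)


def fit_livebirth_logistic(
    pheno: pd.DataFrame, covariates: list[str] = OUTCOME_COVARIATES
) -> OutcomeFit:
    """Unweighted logistic of live birth (a single embryo per cycle)."""
    X, names = _design(pheno, covariates)
    y = pheno["live_birth"].to_numpy(float)
    return fit_weighted_logistic(y, X, None, names, "live_birth")


def run_art_outcomes(
    pheno: pd.DataFrame,
    covariates: list[str] = OUTCOME_COVARIATES,
    stratify_infertility: bool = False,
    min_stratum: int = 10,
) -> pd.DataFrame:
    """Fit the five outcome models (four oocyte-weighted proportions plus
    unweighted live birth); optionally refit within infertility strata.

    Outcomes unavailable for every couple are reported as NA rows.
    """
    rows = []
    strata = [("all", pheno)]
    if stratify_infertility:
        for flag in (0, 1):
            sub = pheno[pheno["male_infertile"] == flag]
            name = "infertile" if flag else "fertile"
            if len(sub) < min_stratum:
                rows.append({"stratum": name, "outcome": "all", "note": "stratum too small"})
                continue
            cov = [c for c in covariates if c != "male_infertile"]
            strata.append((name, sub))
    for stratum, sub in strata:
        cov = [c for c in covariates if not (stratum != "all" and c == "male_infertile")]
        X, names = _design(sub, cov)
        for name, (num, den, weighted) in OUTCOME_DEFS.items():
            if num not in sub.columns or sub[num].isna().all():
                rows.append({"stratum": stratum, "outcome": name, "or_per_year": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                             "weighted": weighted, "note": "missing outcome"})
                continue
            if den is None:
                y = sub[num].to_numpy(float)
                w = None
            else:
                denom = sub[den].to_numpy(float)
                with np.errstate(invalid="ignore", divide="ignore"):
                    y = np.where(denom > 0, sub[num].to_numpy(float) / denom, 0.0)
                w = np.maximum(denom, 1e-12)
            try:
                fit = fit_weighted_logistic(y, X, w, names, name)
                lo, hi = fit.ci
                rows.append({"stratum": stratum, "outcome": name,
                             "or_per_year": fit.or_per_year, "ci_low": lo, "ci_high": hi,
                             "p": fit.age_p, "weighted": weighted, "note": ""})
            except (SeparationError, RuntimeError) as exc:
                rows.append({"stratum": stratum, "outcome": name, "or_per_year": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                             "weighted": weighted, "note": str(exc)})
    return pd.DataFrame(rows)
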