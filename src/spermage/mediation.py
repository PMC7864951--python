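"""High-dimensional mediation of the male-age effect through sperm DMRs.

The estimand is the natural indirect effect (NIE): the change in log-odds
of an ART outcome per 1 year of male age that is transmitted through the
methylation of selected differentially methylated regions, and the
mediation proportion, NIE over the (rescaled) total effect.

Candidate mediators are the gene-assigned DMRs (regions within 1500 bp of
a TSS), summarised per subject as the mean M-value of their probes.  The
selection pipeline is:

1. *stage-1 screen*: the outcome is regressed (oocyte-weighted logistic
   for fertilization, unweighted for live birth) on each candidate plus
   covariates; candidates with BH q < 0.05 survive;
2. *stage-2 stability selection*: over n leave-one-out subsamples, sure
   independence screening (SIS) keeps the d = floor(n/log n) candidates
   with the largest standardized marginal association, then a minimum
   concave penalty (MCP) logistic fit with BIC-selected lambda sparsifies
   them; candidates retained in at least 20 % of the iterations form the
   final mediator set.

The NIE uses the rescaled difference of coefficients between the outcome
model with and without the mediators.  Nested logistic coefficients are
not directly comparable (the latent residual variance pi^2/3 is fixed, so
adding mediators rescales the linear predictor); the total-effect
coefficient is therefore multiplied by c = s_full / s_reduced, where
s = sqrt(var(linear predictor) + pi^2/3) for each model, before
differencing:  NIE_log = c*theta_tot - theta_dir.  In the identity-link
limit c = 1 and the estimator reduces to the classical product /
difference-of-coefficients.  Confidence intervals are nonparametric
percentile bootstrap over couples with the mediator set held fixed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .core import MethylomeDataset, beta_to_m
from .ewas import adjust_bh
from .outcomes import OUTCOME_COVARIATES, SeparationError, fit_weighted_logistic

__all__ = [
    "summarize_region_mediators",
    "stage1_screen",
    "sis_rank",
    "mcp_fit",
    "MCPFit",
    "loo_stability_select",
    "estimate_mediation",
    "run_mediation",
    "MediationResult",
]

log = logging.getLogger(__name__)

LOGISTIC_VAR = np.pi**2 / 3.0


# --------------------------------------------------------------------------
# candidate construction and screening


def summarize_region_mediators(
    dmr_table: pd.DataFrame,
    region_probes: dict[str, list[str]],
    ds: MethylomeDataset,
    gene_map: pd.DataFrame,
) -> pd.DataFrame:
    """Mediator matrix (subjects x regions) for gene-assigned DMRs.

    Keeps only DMRs with a gene within the TSS window (per `gene_map`);
    the mediator value is the mean M-value of the region's probes for each
    subject.  Excluded-count bookkeeping lives in ``attrs['n_excluded']``.
    """
    assigned = gene_map[gene_map["gene_id"].notna()].index
    keep = [r for r in dmr_table["region_id"] if r in set(assigned)]
    cols = {}
    for rid in keep:
        idx = ds.probe_index(region_probes[rid])
        cols[rid] = beta_to_m(ds.beta[idx]).mean(axis=0)
    out = pd.DataFrame(cols, index=ds.subject_ids)
    out.attrs["n_excluded"] = len(dmr_table) - len(keep)
    return out


def _covariate_design(pheno: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    return np.column_stack(
        [np.ones(len(pheno))] + [pheno[c].to_numpy(float) for c in covariates]
    )


def stage1_screen(
    candidates: pd.DataFrame,
    y: np.ndarray,
    pheno: pd.DataFrame,
    covariates: list[str] = OUTCOME_COVARIATES,
    weights: np.ndarray | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Single-mediator logistic screen with BH control across candidates.

    Each candidate is tested in `outcome ~ mediator + covariates` (weighted
    when oocyte weights are supplied); candidates whose mediator Wald test
    passes BH q < `q_threshold` survive.  Separation drops the candidate
    with a log entry.
    """
    Z = _covariate_design(pheno, covariates)
    rows = []
    for rid in candidates.columns:
        x = candidates[rid].to_numpy(float)
        X = np.column_stack([Z[:, :1], x, Z[:, 1:]])
        try:
            fit = fit_weighted_logistic(y, X, weights, outcome=rid)
            rows.append({"region_id": rid, "stage1_p": fit.age_p})
        except (SeparationError, RuntimeError) as exc:
            log.warning("stage-1 candidate %s dropped: %s", rid, exc)
            rows.append({"region_id": rid, "stage1_p": np.nan})
    tab = pd.DataFrame(rows)
    tab["stage1_q"] = adjust_bh(tab["stage1_p"].to_numpy())
    return tab[tab["stage1_q"] < q_threshold].reset_index(drop=True)


def _sis_rank_idx(Xv: np.ndarray, ids: np.ndarray, y_working: np.ndarray,
                  d: int, weights: np.ndarray | None) -> np.ndarray:
    w = np.ones(len(y_working)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    yc = y_working - float(w @ y_working)
    mu = w @ Xv
    sd = np.sqrt(np.maximum(w @ (Xv - mu) ** 2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.abs((w * yc) @ ((Xv - mu) / sd))
    score[~np.isfinite(score)] = 0.0  # zero-variance candidates rank last
    order = np.lexsort((ids, -score))
    return order[:d]


def sis_rank(
    X: pd.DataFrame, y_working: np.ndarray, d: int, weights: np.ndarray | None = None
) -> list[str]:
    """Sure independence screening: top-d candidates by the magnitude of the
    standardized univariate coefficient against the working response.

    Deterministic: exact ties (and zero-variance candidates, whose
    coefficient is 0) break to the lexicographically smaller region id.
    """
    if d > X.shape[1]:
        raise ValueError("d exceeds the number of candidates")
    ids = np.asarray([str(c) for c in X.columns])
    idx = _sis_rank_idx(X.to_numpy(float), ids, np.asarray(y_working, float), d, weights)
    return [X.columns[j] for j in idx]


# --------------------------------------------------------------------------
# MCP-penalized regression (coordinate descent, firm thresholding)


@njit(cache=False)
def _cd_penalized_wls(A, w, z, beta, n_unpen, lam, gamma, max_sweeps, tol):
    """Cyclic coordinate descent for (1/2n) sum w (z - A beta)^2 + MCP.

    Columns 0..n_unpen-1 are unpenalized; the rest carry the MCP penalty
    with parameters (lam, gamma).  The univariate update is the firm
    threshold rule.  Modifies `beta` in place; returns sweeps used.
    """
    n, k = A.shape
    v = np.empty(k)
    for j in range(k):
        s = 0.0
        for i in range(n):
            s += w[i] * A[i, j] * A[i, j]
        v[j] = s / n
    r = z - A @ beta
    for sweep in range(max_sweeps):
        delta = 0.0
        for j in range(k):
            if v[j] <= 0.0:
                continue
            u = 0.0
            for i in range(n):
                u += w[i] * A[i, j] * r[i]
            u = u / n + v[j] * beta[j]
            if j < n_unpen:
                b_new = u / v[j]
            else:
                au = abs(u)
                if au <= lam:
                    b_new = 0.0
                elif au <= gamma * lam * v[j]:
                    b_new = (u - lam * np.sign(u)) / (v[j] - 1.0 / gamma)
                else:
                    b_new = u / v[j]
            diff = b_new - beta[j]
            if diff != 0.0:
                for i in range(n):
                    r[i] -= diff * A[i, j]
                beta[j] = b_new
                if abs(diff) > delta:
                    delta = abs(diff)
        if delta < tol:
            return sweep + 1
    return max_sweeps


@njit(cache=False)
def _irls_solve(A, y, w, beta, k0, lam, gamma, binomial):
    """Solve one lambda in place; IRLS around the penalized WLS for the
    binomial family, a single weighted CD problem for the gaussian."""
    if not binomial:
        _cd_penalized_wls(A, w, y, beta, k0, lam, gamma, 5000, 1e-8)
        return True
    n = A.shape[0]
    W = np.empty(n)
    z = np.empty(n)
    for _ in range(15):
        eta = A @ beta
        delta_ok = True
        old = beta.copy()
        for i in range(n):
            e = min(max(eta[i], -30.0), 30.0)
            m = 1.0 / (1.0 + np.exp(-e))
            v = m * (1.0 - m)
            if v < 1e-6:
                v = 1e-6
            W[i] = w[i] * v
            z[i] = eta[i] + (y[i] - m) / v
        _cd_penalized_wls(A, W, z, beta, k0, lam, gamma, 500, 1e-6)
        for j in range(len(beta)):
            if abs(beta[j] - old[j]) >= 1e-5:
                delta_ok = False
                break
        if delta_ok:
            return True
    return False


@njit(cache=False)
def _mcp_path_solve(A, y, w, k0, lambdas, gamma, binomial, beta0, phi, penalty):
    """Warm-started path solve; returns (beta path, -2 loglik, df, solved).

    The path is truncated once the running information criterion
    (n2ll / phi + df * penalty) sits far above its minimum with a growing
    support — the optimum cannot lie further down the path."""
    L = len(lambdas)
    n, k = A.shape
    path = np.zeros((L, k))
    n2ll = np.full(L, np.inf)
    dfs = np.zeros(L, np.int64)
    solved = np.zeros(L, np.uint8)
    beta = beta0.copy()
    best_ic = np.inf
    for li in range(L):
        ok = _irls_solve(A, y, w, beta, k0, lambdas[li], gamma, binomial)
        if not ok:
            continue
        solved[li] = 1
        path[li] = beta
        df = k0
        for j in range(k0, k):
            if beta[j] != 0.0:
                df += 1
        dfs[li] = df
        eta = A @ beta
        if binomial:
            s = 0.0
            for i in range(n):
                e = min(max(eta[i], -30.0), 30.0)
                m = 1.0 / (1.0 + np.exp(-e))
                m = min(max(m, 1e-12), 1.0 - 1e-12)
                s += w[i] * (y[i] * np.log(m) + (1.0 - y[i]) * np.log(1.0 - m))
            n2ll[li] = -2.0 * s
        else:
            rss = 0.0
            for i in range(n):
                rss += w[i] * (y[i] - eta[i]) ** 2
            n2ll[li] = n * np.log(max(rss / n, 1e-300))
        ic = n2ll[li] / phi + dfs[li] * penalty
        if ic < best_ic:
            best_ic = ic
        elif ic > best_ic + 30.0 * penalty and dfs[li] - k0 >= 10:
            break
    return path, n2ll, dfs, solved


@dataclass
class MCPFit:
    """Path fit: `coef_` / `support_` are at the BIC-selected lambda."""

    coef_: np.ndarray          # penalized-column coefficients (original scale)
    unpenalized_coef_: np.ndarray
    support_: np.ndarray       # boolean over penalized columns
    lambda_: float
    lambdas_: np.ndarray
    bic_: np.ndarray
    coef_path_: np.ndarray     # (n_lambda, n_penalized)


def mcp_fit(
    X,
    y: np.ndarray,
    lambda_path: np.ndarray | None = None,
    gamma: float = 3.0,
    unpenalized: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    family: str = "binomial",
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    ebic_gamma: float = 0.5,
    ebic_p: int | None = None,
) -> MCPFit:
    """MCP-penalized (weighted) regression over a lambda path with extended
    BIC selection.

    Penalized columns are standardized internally (coefficients are
    returned on the original scale); `unpenalized` columns (an intercept is
    added automatically) are never shrunk.  For the binomial family each
    lambda is solved by outer IRLS around the penalized weighted
    least-squares coordinate descent; the path is warm-started from the
    largest lambda, at which all penalized coefficients are zero.

    Lambda is chosen by the extended BIC, deviance / phi + df (log n +
    2 gamma_EBIC log p): `ebic_p` should be the size of the candidate pool
    the columns were screened from, and for weighted proportion outcomes
    the deviance is scaled by a Pearson over-dispersion estimate phi taken
    at the least-penalized solution on the path.
    """
    if gamma <= 1:
        raise ValueError("gamma must be > 1")
    X = pd.DataFrame(X)
    cols = list(X.columns)
    Xv = X.to_numpy(float)
    n, p = Xv.shape
    w_orig = np.ones(n) if weights is None else np.asarray(weights, float)
    # the solver uses mean-1 weights so column curvatures stay ~1 and the
    # firm-threshold rule keeps its MCP (not soft-threshold) geometry; the
    # selection criterion below restores the true weighted likelihood
    wbar = float(w_orig.mean())
    w = w_orig / wbar
    Z = np.ones((n, 1)) if unpenalized is None else np.column_stack(
        [np.ones(n), np.asarray(unpenalized, float)]
    )
    k0 = Z.shape[1]
    # project penalized columns orthogonal to the unpenalized block (in the
    # weighted metric), then standardize.  Candidate mediators are strongly
    # collinear with the exposure column, so their marginal score — which
    # gates path entry in coordinate descent — can be near zero even when
    # their partial likelihood gain is large (suppression); penalizing the
    # partial effects makes entry order track the adjusted association.
    # The unpenalized block is refit freely at every lambda, so the span of
    # the model is unchanged.
    sw = np.sqrt(w)
    Q, _ = np.linalg.qr(Z * sw[:, None])
    Xr = Xv - (Q @ (Q.T @ (Xv * sw[:, None]))) / sw[:, None]
    mu_x = np.average(Xr, axis=0, weights=w)
    sd_x = np.sqrt(np.average((Xr - mu_x) ** 2, axis=0, weights=w))
    sd_x[sd_x == 0] = 1.0
    Xs = (Xr - mu_x) / sd_x
    A = np.ascontiguousarray(np.column_stack([Z, Xs]))
    y = np.asarray(y, float)

    binomial = family == "binomial"

    # null (unpenalized-only) fit defines lambda_max via the score
    null_beta = np.zeros(k0 + p)
    _irls_solve(A, y, w, null_beta, k0, 1e30, gamma, binomial)
    eta0 = A @ null_beta
    if family == "gaussian":
        resid0, W0 = y - eta0, w
    else:
        mu0 = 1.0 / (1.0 + np.exp(-eta0))
        resid0 = (y - mu0) / np.clip(mu0 * (1 - mu0), 1e-6, None)
        W0 = w * mu0 * (1 - mu0)
    score = np.abs((W0 * resid0) @ Xs) / n
    lam_max = float(score.max()) if p else 1.0
    if lambda_path is None:
        lam_max = max(lam_max, 1e-8)
        lambdas = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambda)
    else:
        lambdas = np.asarray(lambda_path, float)

    n_eff = n
    # over-dispersion phi from the saturated (all-screened-candidates,
    # unpenalized) model when the sample affords it: frequency-weighted
    # proportion outcomes are over-dispersed relative to the weighted
    # binomial, which would otherwise swamp the selection penalty
    phi = 1.0
    phi_estimated = False
    if binomial and n - k0 - p >= 10:
        sat = null_beta.copy()
        _irls_solve(A, y, w, sat, k0 + p, 0.0, gamma, True)
        mu_sat = np.clip(1.0 / (1.0 + np.exp(-(A @ sat))), 1e-9, 1 - 1e-9)
        pearson = float(np.sum(w_orig * (y - mu_sat) ** 2 / (mu_sat * (1 - mu_sat))))
        phi = max(1.0, pearson / (n - k0 - p))
        phi_estimated = True
    p_model_space = ebic_p if ebic_p is not None else p
    penalty = np.log(n_eff) + 2.0 * ebic_gamma * np.log(max(p_model_space, 1))
    phi_kernel = phi / wbar if binomial else 1.0
    raw_path, neg2ll, dfs, solved_u8 = _mcp_path_solve(
        A, y, w, k0, lambdas, gamma, binomial, null_beta, phi_kernel, penalty
    )
    solved = solved_u8.astype(bool)
    if not solved.all():
        log.warning("MCP failed to converge at %d lambda values", int((~solved).sum()))
    if not solved.any():
        raise RuntimeError("MCP failed to converge at every lambda")
    if binomial:
        neg2ll = neg2ll * wbar  # back to the original frequency-weight scale
        if not phi_estimated:
            # fall back to the least-penalized path solution for phi
            last = np.flatnonzero(solved)[-1]
            mu = np.clip(1.0 / (1.0 + np.exp(-(A @ raw_path[last]))), 1e-9, 1 - 1e-9)
            pearson = float(np.sum(w_orig * (y - mu) ** 2 / (mu * (1 - mu))))
            phi = max(1.0, pearson / max(n_eff - int(dfs[last]), 1))
    coef_path = raw_path[:, k0:] / sd_x
    unpen_path = raw_path[:, :k0].copy()
    unpen_path[:, 0] -= coef_path @ mu_x
    # extended BIC: candidates reaching this fit were screened for marginal
    # association, so the plain log(n) penalty cannot reject the extreme
    # order statistics among nulls; the 2*gamma*log(p) term restores
    # selection consistency (gamma = 0.5, the standard recommendation)
    bic = np.where(solved, neg2ll / phi + dfs * penalty, np.inf)
    best = int(np.argmin(bic))
    return MCPFit(
        coef_=coef_path[best],
        unpenalized_coef_=unpen_path[best],
        support_=coef_path[best] != 0.0,
        lambda_=float(lambdas[best]),
        lambdas_=lambdas,
        bic_=bic,
        coef_path_=coef_path,
    )


# --------------------------------------------------------------------------
# leave-one-out stability selection


def loo_stability_select(
    candidates: pd.DataFrame,
    y: np.ndarray,
    pheno: pd.DataFrame,
    covariates: list[str] = OUTCOME_COVARIATES,
    weights: np.ndarray | None = None,
    freq_threshold: float = 0.20,
    gamma: float = 3.0,
    working_response: str = "raw",
    pool_size: int | None = None,
) -> pd.DataFrame:
    """Leave-one-out SIS + MCP stability selection of mediator regions.

    For each of the n subsamples, SIS keeps the top d = floor(m/log m)
    candidates (m = subsample size) and an MCP logistic fit (exposure and
    covariates unpenalized, extended-BIC-selected lambda) sparsifies them.
    A candidate's frequency is the fraction of iterations in which the MCP
    support contains it; the final set is frequency >= `freq_threshold`
    ("at least 20 %", so the boundary counts).  Deterministic given the
    data: no random subsampling is involved.

    Male age enters the MCP model unpenalized: candidate mediators are all
    age-driven, so conditioning on the exposure is what separates each
    mediator's own outcome signal from the age signal they share.
    """
    n = len(y)
    ids = list(candidates.columns)
    pool = pool_size if pool_size is not None else len(ids)
    hits = {rid: 0 for rid in ids}
    Xc = candidates.to_numpy(float)
    cov = pheno[["male_age"] + [c for c in covariates if c != "male_age"]].to_numpy(float)
    order_ids = np.array(ids)
    for i in range(n):
        keep = np.arange(n) != i
        m = n - 1
        d = min(max(int(m / math.log(m)), 1), len(ids))
        X_sub = Xc[keep]
        w_sub = None if weights is None else weights[keep]
        y_sub = y[keep]
        if working_response == "residualized":
            Z = np.column_stack([np.ones(m), cov[keep]])
            ww = np.ones(m) if w_sub is None else w_sub
            coef, *_ = np.linalg.lstsq(Z * np.sqrt(ww)[:, None],
                                       y_sub * np.sqrt(ww), rcond=None)
            y_work = y_sub - Z @ coef
        else:
            y_work = y_sub
        top_idx = _sis_rank_idx(X_sub, order_ids, y_work, d, w_sub)
        fit = mcp_fit(X_sub[:, top_idx], y_sub, gamma=gamma, unpenalized=cov[keep],
                      weights=w_sub, family="binomial", ebic_p=pool)
        for j, kept in zip(top_idx, fit.support_):
            if kept:
                hits[ids[j]] += 1
    out = pd.DataFrame(
        {"region_id": ids, "frequency": [hits[r] / n for r in ids]}
    )
    out["selected"] = out["frequency"] >= freq_threshold
    return out


# --------------------------------------------------------------------------
# mediation estimator


@dataclass
class MediationResult:
    """Selected mediators with path coefficients and rescaled effects.

    All effects are per 1 year of male age: `nie_log`/`nde_log`/`te_log`
    on the (full-model) log-odds scale, `nie_or` = exp(nie_log), and the
    mediation proportion nie_log / te_log, where te_log = c * theta_tot is
    the rescaled total effect.  The decomposition nie_log + nde_log =
    te_log holds by construction.
    """

    outcome: str
    selected: list[str]
    alpha: dict[str, tuple[float, float]] = field(default_factory=dict)  # (est, se)
    beta: dict[str, tuple[float, float]] = field(default_factory=dict)
    theta_dir: float = np.nan
    theta_tot: float = np.nan
    rescale_c: float = np.nan
    nie_log: float = np.nan
    nde_log: float = np.nan
    te_log: float = np.nan
    nie_or: float = np.nan
    proportion: float = np.nan
    nie_or_ci: tuple[float, float] = (np.nan, np.nan)
    proportion_ci: tuple[float, float] = (np.nan, np.nan)
    bootstrap_B: int = 0
    seed: int | None = None
    frequencies: dict[str, float] = field(default_factory=dict)
    stage_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.selected

    def contributions(self) -> dict[str, float]:
        """Per-mediator product-of-coefficients alpha_k * beta_k."""
        return {r: self.alpha[r][0] * self.beta[r][0] for r in self.selected}

    def edge_table(self) -> pd.DataFrame:
        """Path-diagram edges: age->mediator, mediator->outcome, age->outcome."""
        rows = []
        for r in self.selected:
            rows.append({"from": "male_age", "to": r, "estimate": self.alpha[r][0],
                         "se": self.alpha[r][1]})
            rows.append({"from": r, "to": self.outcome, "estimate": self.beta[r][0],
                         "se": self.beta[r][1]})
        rows.append({"from": "male_age", "to": self.outcome,
                     "estimate": self.theta_dir, "se": np.nan})
        return pd.DataFrame(rows)


def _latent_sd(eta: np.ndarray, w: np.ndarray | None) -> float:
    ww = np.ones(len(eta)) if w is None else w
    mu = np.average(eta, weights=ww)
    return math.sqrt(np.average((eta - mu) ** 2, weights=ww) + LOGISTIC_VAR)


def _fit_pair(y, age, Msel, cov, weights):
    """Full (with mediators) and reduced outcome logistics; returns fits."""
    n = len(y)
    Z = np.column_stack([np.ones(n), age, cov])
    full_X = np.column_stack([Z[:, :2], Msel, Z[:, 2:]])
    names_full = ["intercept", "male_age"] + [f"m{k}" for k in range(Msel.shape[1])]
    full = fit_weighted_logistic(y, full_X, weights,
                                 names_full + [f"c{k}" for k in range(cov.shape[1])])
    reduced = fit_weighted_logistic(y, Z, weights)
    return full, reduced, full_X, Z


def estimate_mediation(
    selected: pd.DataFrame,
    y: np.ndarray,
    pheno: pd.DataFrame,
    covariates: list[str] = OUTCOME_COVARIATES,
    weights: np.ndarray | None = None,
    bootstrap_B: int = 1000,
    seed: int = 0,
    outcome: str = "outcome",
) -> MediationResult:
    """Rescaled difference-of-coefficients mediation estimate.

    `selected` is the subjects x mediators M-value matrix of the final
    mediator set.  See the module docstring for the estimator; bootstrap
    CIs are percentile intervals over couples with the mediator set fixed.
    Resamples hitting separation are redrawn (at most 10*B attempts).
    """
    if selected.shape[1] == 0:
        return MediationResult(outcome=outcome, selected=[])
    ids = list(selected.columns)
    age = pheno["male_age"].to_numpy(float)
    cov = pheno[covariates].to_numpy(float)
    Msel = selected.to_numpy(float)
    y = np.asarray(y, float)

    def point(y_, age_, M_, cov_, w_):
        full, reduced, full_X, Z = _fit_pair(y_, age_, M_, cov_, w_)
        theta_dir = float(full.params[1])
        theta_tot = float(reduced.params[1])
        c = _latent_sd(full_X @ full.params, w_) / _latent_sd(Z @ reduced.params, w_)
        te = c * theta_tot
        nie = te - theta_dir
        prop = nie / te if abs(te) > 1e-8 else np.nan
        return full, reduced, theta_dir, theta_tot, c, nie, prop

    full, reduced, theta_dir, theta_tot, c, nie, prop = point(y, age, Msel, cov, weights)
    if np.isnan(prop):
        log.warning("total effect ~ 0; mediation proportion undefined")

    # mediator models: linear regression of each mediator on age + covariates
    n = len(y)
    Z = np.column_stack([np.ones(n), age, cov])
    alpha = {}
    zz_inv = np.linalg.inv(Z.T @ Z)
    for j, rid in enumerate(ids):
        coef = zz_inv @ (Z.T @ Msel[:, j])
        resid = Msel[:, j] - Z @ coef
        s2 = float(resid @ resid) / (n - Z.shape[1])
        alpha[rid] = (float(coef[1]), math.sqrt(s2 * zz_inv[1, 1]))
    beta = {rid: (float(full.params[2 + j]), float(full.se[2 + j]))
            for j, rid in enumerate(ids)}

    rng = np.random.default_rng(seed)
    boot_or, boot_prop = [], []
    attempts = 0
    while len(boot_or) < bootstrap_B and attempts < 10 * bootstrap_B:
        attempts += 1
        idx = rng.integers(0, n, n)
        try:
            *_, nie_b, prop_b = point(
                y[idx], age[idx], Msel[idx], cov[idx],
                None if weights is None else weights[idx],
            )
        except (SeparationError, RuntimeError, np.linalg.LinAlgError):
            continue
        boot_or.append(math.exp(nie_b))
        boot_prop.append(prop_b)
    if boot_or:
        or_ci = tuple(np.percentile(boot_or, [2.5, 97.5]))
        pr_ci = tuple(np.nanpercentile(boot_prop, [2.5, 97.5]))
    else:
        or_ci = pr_ci = (np.nan, np.nan)

    return MediationResult(
        outcome=outcome,
        selected=ids,
        alpha=alpha,
        beta=beta,
        theta_dir=theta_dir,
        theta_tot=theta_tot,
        rescale_c=c,
        nie_log=nie,
        nde_log=theta_dir,
        te_log=c * theta_tot,
        nie_or=math.exp(nie),
        proportion=prop,
        nie_or_ci=or_ci,
        proportion_ci=pr_ci,
        bootstrap_B=len(boot_or),
        seed=seed,
    )


def run_mediation(
    outcome_name: str,
    dmr_table: pd.DataFrame,
    region_probes: dict[str, list[str]],
    ds: MethylomeDataset,
    gene_map: pd.DataFrame,
    pheno: pd.DataFrame,
    covariates: list[str] = OUTCOME_COVARIATES,
    q_threshold: float = 0.05,
    freq_threshold: float = 0.20,
    bootstrap_B: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Chain the full mediation pipeline for one outcome.

    `outcome_name` is "fertilization" (oocyte-weighted throughout) or
    "live_birth" (unweighted throughout).  An empty stage-1 or stability
    set terminates cleanly with an empty result.
    """
    if list(pheno.index) != list(ds.subject_ids):
        pheno = pheno.loc[ds.subject_ids]
    if outcome_name == "fertilization":
        w = pheno["n_oocytes"].to_numpy(float)
        y = pheno["n_fertilized"].to_numpy(float) / w
    elif outcome_name == "live_birth":
        w = None
        y = pheno["live_birth"].to_numpy(float)
    else:
        raise ValueError(f"unknown mediation outcome {outcome_name!r}")

    candidates = summarize_region_mediators(
        dmr_table[dmr_table["q"] < q_threshold], region_probes, ds, gene_map
    )
    sizes = {"gene_assigned_dmrs": candidates.shape[1]}
    if candidates.shape[1] == 0:
        log.info("%s: no gene-assigned DMRs; mediation skipped", outcome_name)
        return MediationResult(outcome=outcome_name, selected=[], stage_sizes=sizes)

    stage1 = stage1_screen(candidates, y, pheno, covariates, w, q_threshold)
    sizes["stage1_survivors"] = len(stage1)
    if stage1.empty:
        log.info("%s: stage-1 screen empty; mediation skipped", outcome_name)
        return MediationResult(outcome=outcome_name, selected=[], stage_sizes=sizes)

    survivors = candidates[stage1["region_id"].tolist()]
    stability = loo_stability_select(
        survivors, y, pheno, covariates, w, freq_threshold,
        pool_size=candidates.shape[1],
    )
    sizes["selected_mediators"] = int(stability["selected"].sum())
    chosen = stability.loc[stability["selected"], "region_id"].tolist()
    if not chosen:
        log.info("%s: no mediators pass the %.0f%% frequency rule",
                 outcome_name, 100 * freq_threshold)
        return MediationResult(outcome=outcome_name, selected=[], stage_sizes=sizes,
                               frequencies=dict(zip(stability["region_id"],
                                                    stability["frequency"])))

    result = estimate_mediation(
        candidates[chosen], y, pheno, covariates, w, bootstrap_B, seed, outcome_name
    )
    result.frequencies = dict(zip(stability["region_id"], stability["frequency"]))
    result.stage_sizes = sizes
    return result
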