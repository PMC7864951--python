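"""Per-CpG epigenome-wide association scan of methylation on male age.

Inference runs on M-values (log2-odds of methylation), whose variance is
closer to constant across the (0,1) range; effect sizes are re-estimated on
the beta scale from the same design so they read directly as percent
methylation.  The reported effect is the change in percent methylation per
5 years of age.  Multiplicity is controlled by Benjamini–Hochberg q-values
and a Bonferroni flag over all tested probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MethylomeDataset

__all__ = ["adjust_bh", "fit_cpg", "run_ewas", "build_design", "EWAS_COVARIATES"]

# methylation models adjust for male covariates only (no female age)
EWAS_COVARIATES = ["male_bmi", "male_smoking", "male_infertile"]


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Sort ascending, set q_(i) = min_{j >= i} p_(j) * m / j capped at 1,
    return in the input order.  NaNs propagate and do not count toward m.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    qs = np.empty(m)
    qs[order] = q
    out[ok] = qs
    return out


def build_design(pheno: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """Intercept + age + covariate columns as a float design matrix."""
    cols = [np.ones(len(pheno)), pheno["male_age"].to_numpy(float)]
    for c in covariates:
        cols.append(pheno[c].to_numpy(float))
    return np.column_stack(cols)


def _ols_scan(Y: np.ndarray, X: np.ndarray):
    """OLS of every row of Y on X; returns (age slope, se, t, p) arrays.

    The age coefficient is column 1 of X.  Zero-variance (or otherwise
    degenerate) rows get NaN rather than a fabricated p-value.
    """
    n, k = X.shape
    dof = n - k
    if dof < 1:
        raise ValueError("more model terms than subjects")
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(xtx)
    coefs = Y @ X @ xtx_inv.T  # (p, k)
    resid = Y - coefs @ X.T
    sigma2 = (resid**2).sum(axis=1) / dof
    var_age = sigma2 * xtx_inv[1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_age)
        t = coefs[:, 1] / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    degenerate = np.ptp(Y, axis=1) == 0.0
    for arr in (se, t, p):
        arr[degenerate] = np.nan
    slope = coefs[:, 1].copy()
    slope[degenerate] = np.nan
    return slope, se, t, p


def fit_cpg(m_row: np.ndarray, pheno: pd.DataFrame, covariates: list[str] = EWAS_COVARIATES):
    """OLS of one probe's M-values on age + covariates -> (effect_M, p).

    effect_M is M-units per year of age; p is the two-sided t-test on the
    age coefficient with residual degrees of freedom.
    """
    X = build_design(pheno, covariates)
    slope, _, _, p = _ols_scan(np.asarray(m_row, float)[None, :], X)
    return float(slope[0]), float(p[0])


@dataclass
class EWASResult:
    """Per-probe scan results with dual-scale effects and adjusted p-values."""

    table: pd.DataFrame  # probe_id, chrom, pos, effect_M, effect_per_5yr_beta, p, q, bonf_sig
    n_tested: int
    bonferroni_threshold: float

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < q_threshold]

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_ewas(
    ds: MethylomeDataset,
    pheno: pd.DataFrame,
    covariates: list[str] = EWAS_COVARIATES,
    q_threshold: float = 0.05,
) -> EWASResult:
    """Scan every probe: p from the M-value model, effect size from a
    beta-value refit of the same design (percent methylation per 5 years).
    """
    if list(pheno.index) != list(ds.subject_ids):
        pheno = pheno.loc[ds.subject_ids]
    X = build_design(pheno, covariates)
    slope_m, _, _, p = _ols_scan(ds.m_values(), X)
    slope_b, _, _, _ = _ols_scan(ds.beta, X)
    q = adjust_bh(p)
    n_tested = int((~np.isnan(p)).sum())
    bonf_thr = 0.05 / max(n_tested, 1)
    table = pd.DataFrame(
        {
            "probe_id": ds.manifest.table["probe_id"].to_numpy(),
            "chrom": ds.manifest.table["chrom"].to_numpy(),
            "pos": ds.manifest.table["pos"].to_numpy(),
            "effect_M": slope_m,
            "effect_per_5yr_beta": slope_b * 5.0 * 100.0,
            "p": p,
            "q": q,
            "bonf_sig": p < bonf_thr,
        }
    )
    return EWASResult(table, n_tested, bonf_thr)
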