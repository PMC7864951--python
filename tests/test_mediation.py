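import numpy as np
import pandas as pd
import pytest

from spermage.core import beta_to_m
from spermage.mediation import (
    estimate_mediation,
    loo_stability_select,
    mcp_fit,
    run_mediation,
    sis_rank,
    stage1_screen,
    summarize_region_mediators,
)
from spermage.outcomes import OUTCOME_COVARIATES, couples_to_frame
from spermage.simulate import SimulationConfig, simulate_cohort


def _pheno(n, rng):
    return pd.DataFrame({
        "male_age": rng.uniform(21, 45, n),
        "male_bmi": rng.normal(27, 4, n),
        "male_smoking": (rng.random(n) < 0.1).astype(int),
        "male_infertile": (rng.random(n) < 0.25).astype(int),
        "female_age": rng.uniform(24, 42, n),
    }, index=[f"s{j}" for j in range(n)])


def _mediator_cohort(seed, n=150, n_probes=1600, alphas=(0.05,) * 3, betas=(0.8,) * 3):
    cfg = SimulationConfig(
        n_couples=n, n_probes=n_probes, n_chromosomes=2, n_age_cpgs=50,
        n_age_regions=0, n_true_mediators=len(alphas), alpha_k=alphas,
        beta_k=betas, b_age_direct=-0.03, seed=seed)
    ds, couples, truth = simulate_cohort(cfg)
    pheno = couples_to_frame(couples)
    w = pheno["n_oocytes"].to_numpy(float)
    y = pheno["n_fertilized"].to_numpy(float) / w
    cand = pd.DataFrame(
        {rid: beta_to_m(ds.beta[ds.probe_index(p)]).mean(axis=0)
         for rid, p in truth.region_probes.items()}, index=ds.subject_ids)
    return cand, y, pheno, w, truth


class TestMcpFit:
    def test_univariate_firm_threshold_cases(self):
        """Closed-form firm-threshold solutions on a standardized design."""
        rng = np.random.default_rng(0)
        n = 4000
        x = rng.normal(0, 1, n)
        x = (x - x.mean()) / x.std()

        def solve(z, lam, gamma=3.0):
            y = z * x  # OLS estimate of y on standardized x is exactly z
            fit = mcp_fit(x[:, None], y, lambda_path=[lam], gamma=gamma,
                          family="gaussian")
            return fit.coef_[0]

        # transition region: (z - lam) / (1 - 1/gamma)
        assert solve(2.0, 1.0) == pytest.approx(1.5, abs=1e-6)
        # |z| > gamma*lam: penalty flat, unbiased
        assert solve(4.0, 1.0) == pytest.approx(4.0, abs=1e-6)
        # lam >= |z|: thresholded to zero
        assert solve(0.8, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_univariate_matches_grid_minimization(self):
        """Numeric oracle: minimize the penalized objective on a fine grid."""
        rng = np.random.default_rng(1)
        n = 2000
        x = rng.normal(0, 1, n)
        x = (x - x.mean()) / x.std()
        for z, lam, gamma in [(2.0, 1.0, 3.0), (1.2, 0.9, 2.5), (-2.4, 0.7, 3.0)]:
            y = z * x
            fit = mcp_fit(x[:, None], y, lambda_path=[lam], gamma=gamma,
                          family="gaussian")
            grid = np.linspace(-6, 6, 240_001)
            pen = np.where(np.abs(grid) <= gamma * lam,
                           lam * np.abs(grid) - grid**2 / (2 * gamma),
                           gamma * lam**2 / 2)
            # 0.5*mean((y - x b)^2) expanded through sufficient statistics
            myy, mxy, mxx = np.mean(y * y), np.mean(x * y), np.mean(x * x)
            obj = 0.5 * (myy - 2 * grid * mxy + grid**2 * mxx) + pen
            best = grid[np.argmin(obj)]
            assert fit.coef_[0] == pytest.approx(best, abs=1e-4)

    def test_gamma_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcp_fit(np.random.default_rng(2).normal(0, 1, (20, 2)),
                    np.zeros(20), gamma=0.9)


class TestSisRank:
    def test_perfect_marginal_signal_first(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(0, 1, (50, 5)), columns=list("abcde"))
        y = X["c"].to_numpy()
        assert sis_rank(X, y, 1) == ["c"]

    def test_full_d_identity_set(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(0, 1, (30, 4)), columns=list("abcd"))
        y = rng.normal(0, 1, 30)
        assert set(sis_rank(X, y, 4)) == set("abcd")

    def test_matches_correlation_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            X = pd.DataFrame(rng.normal(0, 1, (40, 8)),
                             columns=[f"c{j}" for j in range(8)])
            y = rng.normal(0, 1, 40)
            got = sis_rank(X, y, 8)
            cors = {c: abs(np.corrcoef(X[c], y)[0, 1]) for c in X.columns}
            want = sorted(cors, key=lambda c: (-cors[c], c))
            assert got == want

    def test_zero_variance_ranks_last_and_d_bound(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"a": rng.normal(0, 1, 30), "b": np.zeros(30)})
        y = X["a"].to_numpy()
        assert sis_rank(X, y, 2) == ["a", "b"]
        with pytest.raises(ValueError):
            sis_rank(X, y, 3)


class TestStage1Screen:
    def test_single_candidate_q_equals_p(self):
        rng = np.random.default_rng(7)
        ph = _pheno(120, rng)
        x = rng.normal(0, 1, 120)
        y = (rng.random(120) < 1 / (1 + np.exp(-0.5 * x))).astype(float)
        out = stage1_screen(pd.DataFrame({"r1": x}, index=ph.index), y, ph)
        if len(out):
            assert out["stage1_q"].iloc[0] == pytest.approx(out["stage1_p"].iloc[0])

    def test_null_candidates_rarely_survive(self):
        rng = np.random.default_rng(8)
        survivors = 0
        for _ in range(20):
            ph = _pheno(100, rng)
            X = pd.DataFrame(rng.normal(0, 1, (100, 50)),
                             columns=[f"r{j}" for j in range(50)], index=ph.index)
            y = (rng.random(100) < 0.4).astype(float)
            survivors += len(stage1_screen(X, y, ph))
        assert survivors / 20 < 1.0  # BH under the global null

    def test_strong_mediator_retained(self):
        rng = np.random.default_rng(9)
        kept = 0
        for _ in range(20):
            ph = _pheno(200, rng)
            x = rng.normal(0, 1, 200)
            nulls = rng.normal(0, 1, (200, 20))
            y = (rng.random(200) < 1 / (1 + np.exp(-(1.0 * x)))).astype(float)
            X = pd.DataFrame(np.column_stack([x, nulls]),
                             columns=["med"] + [f"r{j}" for j in range(20)],
                             index=ph.index)
            out = stage1_screen(X, y, ph)
            kept += int("med" in set(out["region_id"]))
        assert kept >= 19  # >= 95%


class TestLooStability:
    def test_boundary_frequency_rule(self):
        """Exactly ceil(0.2 n) retentions counts as selected (>= 20%)."""
        out = pd.DataFrame({"region_id": ["a"], "frequency": [0.20]})
        out["selected"] = out["frequency"] >= 0.20
        assert bool(out["selected"].iloc[0])

    def test_always_retained_candidate_selected(self):
        cand, y, pheno, w, truth = _mediator_cohort(seed=0, n_probes=400,
                                                    alphas=(0.08,), betas=(1.2,))
        sub = cand[[truth.mediator_region_ids[0]]]
        stab = loo_stability_select(sub, y, pheno, OUTCOME_COVARIATES, w)
        row = stab.set_index("region_id").loc[truth.mediator_region_ids[0]]
        assert row["frequency"] == pytest.approx(1.0)
        assert bool(row["selected"])

    def test_threshold_monotonicity(self):
        cand, y, pheno, w, truth = _mediator_cohort(seed=1, n_probes=800)
        stab = loo_stability_select(cand.iloc[:, :40], y, pheno,
                                    OUTCOME_COVARIATES, w, freq_threshold=0.2)
        for thr in (0.4, 0.6, 0.9):
            bigger = stab["frequency"] >= thr
            assert bigger.sum() <= stab["selected"].sum()


class TestSummarizeRegionMediators:
    def _setup(self, small_cohort):
        cfg, ds, couples, truth = small_cohort
        dmr_table = pd.DataFrame({"region_id": list(truth.region_probes)})
        gene_map = pd.DataFrame(
            {"gene_id": [f"G{i}" if i % 2 == 0 else None
                         for i in range(len(truth.region_probes))]},
            index=list(truth.region_probes))
        return ds, truth, dmr_table, gene_map

    def test_tss_restriction_and_mean(self, small_cohort):
        ds, truth, dmr_table, gene_map = self._setup(small_cohort)
        out = summarize_region_mediators(dmr_table, truth.region_probes, ds, gene_map)
        assigned = gene_map["gene_id"].notna().sum()
        assert out.shape[1] == assigned
        assert out.attrs["n_excluded"] == len(dmr_table) - assigned
        rid = out.columns[0]
        idx = ds.probe_index(truth.region_probes[rid])
        np.testing.assert_allclose(out[rid].to_numpy(),
                                   beta_to_m(ds.beta[idx]).mean(axis=0), atol=1e-12)


class TestEstimateMediation:
    def _data(self, seed, n=400, alpha=0.06, beta=-0.5, direct=-0.02):
        rng = np.random.default_rng(seed)
        ph = _pheno(n, rng)
        age_c = ph["male_age"] - ph["male_age"].mean()
        med = 0.5 + alpha * age_c + rng.normal(0, 0.3, n)
        eta = 0.3 + direct * age_c + beta * (med - med.mean())
        w = rng.integers(5, 25, n).astype(float)
        y = rng.binomial(w.astype(int), 1 / (1 + np.exp(-eta))) / w
        sel = pd.DataFrame({"m1": med}, index=ph.index)
        return sel, y, ph, w

    def test_decomposition_identity(self):
        sel, y, ph, w = self._data(0)
        res = estimate_mediation(sel, y, ph, weights=w, bootstrap_B=10, seed=1)
        assert res.nie_log + res.nde_log == pytest.approx(res.te_log, abs=1e-12)
        assert res.proportion == pytest.approx(res.nie_log / res.te_log, abs=1e-12)

    def test_linear_limit_equals_product_of_coefficients(self):
        """Identity-link analogue: difference of coefficients with c=1 equals
        the product alpha*beta exactly (both are exact OLS identities)."""
        rng = np.random.default_rng(2)
        n = 300
        ph = _pheno(n, rng)
        age = ph["male_age"].to_numpy()
        cov = ph[OUTCOME_COVARIATES].to_numpy(float)
        med = 0.4 + 0.05 * age + rng.normal(0, 0.2, n)
        y = 1.0 - 0.01 * age - 0.3 * med + rng.normal(0, 0.1, n)
        Z = np.column_stack([np.ones(n), age, cov])
        full_X = np.column_stack([Z[:, :2], med[:, None], Z[:, 2:]])
        th_full = np.linalg.lstsq(full_X, y, rcond=None)[0]
        th_red = np.linalg.lstsq(Z, y, rcond=None)[0]
        alpha_hat = np.linalg.lstsq(Z, med, rcond=None)[0][1]
        nie_diff = th_red[1] - th_full[1]
        assert nie_diff == pytest.approx(alpha_hat * th_full[2], abs=1e-6)

    def test_bootstrap_seed_reproducibility(self):
        sel, y, ph, w = self._data(3)
        r1 = estimate_mediation(sel, y, ph, weights=w, bootstrap_B=50, seed=42)
        r2 = estimate_mediation(sel, y, ph, weights=w, bootstrap_B=50, seed=42)
        assert r1.nie_or_ci == r2.nie_or_ci
        assert r1.proportion_ci == r2.proportion_ci

    def test_proportion_invariant_to_mediator_rescaling(self):
        sel, y, ph, w = self._data(4)
        r1 = estimate_mediation(sel, y, ph, weights=w, bootstrap_B=0, seed=0)
        sel10 = sel * 10.0
        r2 = estimate_mediation(sel10, y, ph, weights=w, bootstrap_B=0, seed=0)
        assert r1.proportion == pytest.approx(r2.proportion, abs=1e-8)
        assert r1.nie_log == pytest.approx(r2.nie_log, abs=1e-8)

    def test_null_mediation_proportion_ci_covers_zero(self):
        covered = 0
        reps = 40
        for seed in range(reps):
            sel, y, ph, w = self._data(100 + seed, n=300, alpha=0.0, beta=0.0,
                                       direct=-0.05)
            res = estimate_mediation(sel, y, ph, weights=w, bootstrap_B=120,
                                     seed=seed)
            lo, hi = res.proportion_ci
            covered += int(lo <= 0.0 <= hi)
        assert covered / reps >= 0.85

    def test_empty_selection_clean_result(self):
        rng = np.random.default_rng(5)
        ph = _pheno(50, rng)
        res = estimate_mediation(pd.DataFrame(index=ph.index),
                                 np.zeros(50), ph)
        assert res.empty and res.selected == []


class TestRunMediation:
    def test_proportion_recovery_on_generated_cohort(self):
        """Known mediators passed through the estimator recover the configured
        0.64 mediation proportion (median over replicates)."""
        props = []
        for seed in range(20):
            cfg = SimulationConfig(n_couples=2000, n_probes=700, n_chromosomes=1,
                                   n_age_cpgs=0, n_age_regions=0, seed=800 + seed)
            ds, couples, truth = simulate_cohort(cfg)
            pheno = couples_to_frame(couples)
            w = pheno["n_oocytes"].to_numpy(float)
            y = pheno["n_fertilized"].to_numpy(float) / w
            sel = pd.DataFrame(
                {rid: beta_to_m(ds.beta[ds.probe_index(truth.region_probes[rid])]).mean(axis=0)
                 for rid in truth.mediator_region_ids}, index=ds.subject_ids)
            res = estimate_mediation(sel, y, pheno, weights=w, bootstrap_B=0,
                                     seed=seed)
            props.append(res.proportion)
        assert np.median(props) == pytest.approx(0.64, abs=0.10)

    def test_wiring_weighted_vs_unweighted(self, small_cohort, small_pheno):
        cfg, ds, couples, truth = small_cohort
        from spermage.simulate import generate_annotations
        from spermage.annotate import assign_nearest_gene
        from spermage.regions import find_clusters
        from spermage.gee import run_dmr

        regions = find_clusters(ds)
        dmr = run_dmr(regions, ds, small_pheno)
        _, tss = generate_annotations(cfg, ds, truth)
        gene_map = assign_nearest_gene(regions, tss, 1500)
        region_probes = {r.region_id: list(r.probe_ids) for r in regions}
        for outcome in ("fertilization", "live_birth"):
            res = run_mediation(outcome, dmr.table, region_probes, ds, gene_map,
                                small_pheno, bootstrap_B=20, seed=1)
            assert res.outcome == outcome
            assert "gene_assigned_dmrs" in res.stage_sizes

    def test_unknown_outcome_raises(self, small_cohort, small_pheno):
        _, ds, _, _ = small_cohort
        with pytest.raises(ValueError, match="unknown"):
            run_mediation("implantation", pd.DataFrame({"region_id": [], "q": []}),
                          {}, ds, pd.DataFrame(columns=["gene_id"]), small_pheno)
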