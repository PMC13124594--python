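"""Permutation machinery, GPD tails, FDR, effect sizes, PCA, trends and
the equation suite."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from oneirolex import inference as inf
from oneirolex.glmm import GaussianRandomIntercept
from oneirolex.inference import (ModelSpec, actigraphy_pca, adjusted_values,
                                 cohens_d, fdr_bh, fit_glme, gpd_tail_pvalue,
                                 permutation_null, polynomial_trend,
                                 run_model_suite)


def _paired_frame(seed=0, nG=12, m=8, beta_state=0.8, su=0.6):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(nG):
        u = rng.normal(0, su)
        for i in range(m):
            state = i % 2
            y = 5.0 + beta_state * state + u + rng.normal(0, 1)
            rows.append((f"p{g:02d}", state, y, rng.normal(0, 1)))
    return pd.DataFrame(rows, columns=["participant_id", "state", "y", "age"])


class TestFitGlme:
    def test_gaussian_recovers_state_effect(self):
        df = _paired_frame(seed=1, nG=40, m=10, beta_state=1.5)
        spec = ModelSpec("y", "gaussian", "state + age", ["state"])
        res = fit_glme(spec, df)
        prm = res.params.loc["state"]
        assert abs(prm["estimate"] - 1.5) < 3 * prm["se"]
        assert prm["ci_low"] < prm["estimate"] < prm["ci_high"]
        assert res.full_model_p < 0.001
        assert 0 < res.adj_r2 < 1

    def test_binomial_family_on_binary_outcome(self):
        rng = np.random.default_rng(3)
        df = _paired_frame(seed=3, nG=30, m=8)
        eta = -0.5 + 1.0 * df["state"]
        df["hit"] = (rng.random(len(df)) <
                     1.0 / (1.0 + np.exp(-eta))).astype(int)
        spec = ModelSpec("hit", "binomial", "state", ["state"])
        res = fit_glme(spec, df)
        prm = res.params.loc["state"]
        assert abs(prm["estimate"] - 1.0) < 3 * prm["se"]

    def test_missing_covariate_rows_are_dropped(self, caplog):
        df = _paired_frame(seed=4)
        df.loc[:5, "age"] = np.nan
        spec = ModelSpec("y", "gaussian", "state + age", ["state"])
        res = fit_glme(spec, df)
        assert res.n_obs == len(df) - 6


class TestPermutation:
    def test_preserves_per_participant_state_counts(self):
        rng = np.random.default_rng(0)
        groups = np.repeat(np.arange(6), 5)
        state = rng.integers(0, 2, 30).astype(float)
        idx_list = inf._group_indices(groups)
        for _ in range(50):
            perm = inf._permute_within(state, idx_list, rng)
            for idx in idx_list:
                assert perm[idx].sum() == state[idx].sum()

    def test_matches_exhaustive_enumeration_on_four_pairs(self):
        """4 participants x (1 dream + 1 wake): the 2^4 within-participant
        arrangements are enumerable; the Monte-Carlo null must match the
        exhaustive null's mean and sd within 3 Monte-Carlo SEs."""
        rng = np.random.default_rng(7)
        df = _paired_frame(seed=7, nG=4, m=2, beta_state=0.5)
        spec = ModelSpec("y", "gaussian", "state", ["state"])
        # exhaustive null over all within-participant swap patterns
        eng = GaussianRandomIntercept()
        y = df["y"].to_numpy()
        groups = df["participant_id"].to_numpy()
        base_state = df["state"].to_numpy().astype(float)
        betas = []
        for pattern in itertools.product([0, 1], repeat=4):
            state = base_state.copy()
            for g, swap in enumerate(pattern):
                if swap:
                    state[2 * g], state[2 * g + 1] = (state[2 * g + 1],
                                                      state[2 * g])
            X = np.column_stack([np.ones(len(y)), state])
            betas.append(eng.fit(y, X, groups).beta[1])
        exhaustive = np.array(betas)

        n_perm = 5000
        null = permutation_null(spec, df, n_perm=n_perm, seed=123)
        se_mean = exhaustive.std() / np.sqrt(n_perm)
        assert abs(null.mean() - exhaustive.mean()) < 3 * se_mean
        se_sd = exhaustive.std() / np.sqrt(2 * n_perm)
        assert abs(null.std() - exhaustive.std()) < 3 * se_sd
        # every Monte-Carlo draw must be one of the 16 exhaustive values
        assert np.all(np.isclose(null[:, None], exhaustive[None, :],
                                 atol=1e-8).any(axis=1))

    def test_small_n_perm_warns(self):
        df = _paired_frame(seed=9, nG=4, m=4)
        spec = ModelSpec("y", "gaussian", "state", ["state"])
        with pytest.warns(RuntimeWarning, match="coarse"):
            permutation_null(spec, df, n_perm=50, seed=0)


class TestGpdTail:
    def test_central_observation_gives_half(self, rng):
        null = rng.standard_normal(5000)
        obs = np.median(np.abs(null))
        p = gpd_tail_pvalue(obs, null)
        assert p == pytest.approx(0.5, abs=2 * 0.5 / np.sqrt(5000) * 3)

    def test_exponential_tail_extrapolation_within_factor_two(self, rng):
        """Null with an exponential tail; observation at the analytic 0.001
        quantile; the GPD-extrapolated p must be within a factor of 2."""
        ps = []
        for s in range(10):
            null = np.random.default_rng(s).exponential(1.0, size=5000)
            obs = -np.log(0.001)          # P(X >= obs) = 0.001 exactly
            ps.append(gpd_tail_pvalue(obs, null))
        med = np.median(ps)
        assert 0.0005 <= med <= 0.002

    def test_agrees_with_empirical_when_exceedances_plenty(self, rng):
        null = rng.standard_normal(5000)
        obs = np.quantile(np.abs(null), 0.97)    # ~150 exceedances
        p_emp = gpd_tail_pvalue(obs, null)       # empirical branch
        p_gpd = gpd_tail_pvalue(obs, null, exceed_trigger=10**9)
        assert abs(p_gpd - p_emp) / p_emp < 0.2

    def test_floor_at_one_over_n_plus_one(self, rng):
        null = rng.standard_normal(200)
        p = gpd_tail_pvalue(1e9, null, exceed_trigger=0)
        assert p == pytest.approx(1.0 / 201.0)

    def test_needs_enough_null_values(self):
        with pytest.raises(ValueError):
            gpd_tail_pvalue(1.0, np.ones(50))


def _bh_bruteforce(p, q):
    """Independent step-up: largest i with p_(i) <= i q / m."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    reject = np.zeros(m, dtype=bool)
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject[order[:k]] = True
    qvals = np.empty(m)
    prev = 1.0
    for i in range(m, 0, -1):
        prev = min(prev, p[order[i - 1]] * m / i)
        qvals[order[i - 1]] = prev
    return qvals, reject


class TestFdrBh:
    def test_step_up_enumeration_example(self):
        qv, rej = fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert rej.all()

    def test_all_ones_rejects_none(self):
        _, rej = fdr_bh([1.0, 1.0, 1.0])
        assert not rej.any()

    def test_single_p_reduces_to_raw_comparison(self):
        _, rej = fdr_bh([0.04], q=0.05)
        assert rej.all()

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(rng.integers(1, 30))
            qv, rej = fdr_bh(p, q=0.05)
            qv2, rej2 = _bh_bruteforce(p, 0.05)
            np.testing.assert_allclose(qv, qv2, atol=1e-12)
            np.testing.assert_array_equal(rej, rej2)

    def test_empty_input(self):
        qv, rej = fdr_bh([])
        assert qv.size == 0 and rej.size == 0


class TestCohensD:
    def test_identical_distributions_give_zero(self):
        v = np.r_[1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        assert cohens_d(v, np.r_[np.ones(5), np.zeros(5)].astype(bool)) == 0.0

    def test_zero_pooled_sd_is_undefined(self):
        v = np.ones(10)
        with pytest.warns(RuntimeWarning, match="pooled sd"):
            d = cohens_d(v, np.r_[np.ones(5), np.zeros(5)].astype(bool))
        assert np.isnan(d)

    def test_unit_difference_unit_sd(self, rng):
        a = rng.normal(1.0, 1.0, 50000)
        b = rng.normal(0.0, 1.0, 50000)
        d = cohens_d(np.r_[a, b],
                     np.r_[np.ones(50000), np.zeros(50000)].astype(bool))
        assert d == pytest.approx(1.0, abs=0.03)

    def test_matches_pooled_sd_formula_on_toy(self):
        vals = np.array([1.0, 2, 3, 4, 5, 2, 2, 3, 3, 4])
        mask = np.r_[np.ones(5), np.zeros(5)].astype(bool)
        a, b = vals[:5], vals[5:]
        sp = np.sqrt(((4 * a.var(ddof=1)) + (4 * b.var(ddof=1))) / 8)
        assert cohens_d(vals, mask) == pytest.approx(
            (a.mean() - b.mean()) / sp, abs=1e-12)


class TestAdjustedValues:
    def test_shift_of_nuisance_covariate_is_absorbed(self):
        df = _paired_frame(seed=11, nG=20, m=6, beta_state=1.0)
        df["y"] = df["y"] + 0.7 * df["age"]
        spec = ModelSpec("y", "gaussian", "state + age", ["state"])
        adj1 = adjusted_values(fit_glme(spec, df), ["age"])
        df2 = df.copy()
        df2["age"] = df2["age"] + 100.0
        adj2 = adjusted_values(fit_glme(spec, df2), ["age"])
        np.testing.assert_allclose(adj1, adj2, atol=1e-6)

    def test_adjusted_group_difference_matches_state_beta(self):
        df = _paired_frame(seed=12, nG=40, m=8, beta_state=1.2)
        df["y"] = df["y"] + 0.5 * df["age"]
        spec = ModelSpec("y", "gaussian", "state + age", ["state"])
        res = fit_glme(spec, df)
        adj = adjusted_values(res, ["age"])
        is_dream = res.X["state"].to_numpy() == 1
        diff = adj[is_dream].mean() - adj[~is_dream].mean()
        assert diff == pytest.approx(res.beta["state"], abs=0.05)

    def test_unknown_covariate_errors(self):
        df = _paired_frame(seed=13)
        res = fit_glme(ModelSpec("y", "gaussian", "state", ["state"]), df)
        with pytest.raises(ValueError, match="not a model term"):
            adjusted_values(res, ["education"])


class TestActigraphyPca:
    def test_recovers_planted_four_factor_structure(self, rng):
        n, k = 300, 4
        loadings = np.zeros((24, k))
        for j in range(24):
            loadings[j, j % k] = rng.uniform(0.8, 1.0)
        X = rng.standard_normal((n, k)) @ loadings.T \
            + 0.2 * rng.standard_normal((n, 24))
        pcs = actigraphy_pca(pd.DataFrame(X), n_pcs=4)
        assert pcs.variance_explained.sum() > 85.0

    def test_scores_are_uncorrelated_and_variance_bounded(self, rng):
        X = rng.standard_normal((60, 24))
        pcs = actigraphy_pca(pd.DataFrame(X), n_pcs=4)
        cov = np.cov(pcs.scores.to_numpy().T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8
        assert pcs.variance_explained.sum() <= 100.0 + 1e-9
        assert np.all(np.diff(pcs.variance_explained) <= 1e-9)

    def test_constant_column_dropped(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 5)))
        X[5] = 1.0
        with pytest.warns(RuntimeWarning, match="constant"):
            pcs = actigraphy_pca(X, n_pcs=2)
        assert 5 not in pcs.loadings.index


class TestPolynomialTrend:
    def test_exact_quadratic_recovery(self):
        x = np.linspace(0, 1, 40)
        y = 2.0 - 3.0 * x + 1.5 * x ** 2
        fit = polynomial_trend(x, y)
        assert fit.degree == 2
        np.testing.assert_allclose(fit.coefficients, [1.5, -3.0, 2.0],
                                   atol=1e-6)

    def test_constant_data_degree_zero(self):
        x = np.linspace(0, 1, 20)
        fit = polynomial_trend(x, np.full(20, 4.2))
        assert fit.degree == 0
        assert fit.predict(np.array([0.5]))[0] == pytest.approx(4.2)

    def test_degree_bound_holds_on_noise(self, rng):
        for s in range(5):
            x = np.linspace(0, 1, 30)
            y = np.random.default_rng(s).standard_normal(30)
            assert polynomial_trend(x, y).degree <= 3


class TestModelSuite:
    @pytest.fixture()
    def suite_frame(self):
        rng = np.random.default_rng(21)
        df = _paired_frame(seed=21, nG=24, m=8, beta_state=0.0)
        df = df.rename(columns={"y": "dimA"})
        df["dimB"] = 0.6 * df["dimA"] + rng.normal(0, 0.5, len(df))
        df["dimC"] = rng.normal(5, 1, len(df))
        df["sex"] = np.where(
            df["participant_id"].str[1:].astype(int) % 2 == 0,
            "female", "male")
        df["education"] = rng.normal(16, 3, len(df))
        df["BADA"] = rng.normal(4.5, 0.4, len(df))
        df["time_rank"] = rng.random(len(df))
        return df

    def test_eq1_builds_all_ordered_pairs(self, suite_frame):
        res = run_model_suite(1, suite_frame,
                              dimension_cols=["dimA", "dimB", "dimC"])
        assert len(res) == 6          # 3 x 2 ordered pairs
        strong = res[(res["outcome"] == "dimB") & (res["term"] == "dimA")]
        assert strong["significant"].all()

    def test_eq12_has_interaction_and_main_terms(self, suite_frame):
        res = run_model_suite(12, suite_frame, dimension_cols=["dimA"])
        assert set(res["term"]) == {"state:time_rank", "time_rank"}
        # FDR families are separate: q-values present for both terms
        assert res["q_value"].notna().all()

    def test_eq4_detects_planted_state_effect(self):
        df = _paired_frame(seed=30, nG=30, m=8, beta_state=1.0)
        rng = np.random.default_rng(30)
        df = df.rename(columns={"y": "dimA"})
        df["dimNull"] = rng.normal(5, 1, len(df))
        df["sex"] = "female"
        df.loc[df["participant_id"].str[1:].astype(int) % 2 == 0,
               "sex"] = "male"
        df["education"] = rng.normal(16, 3, len(df))
        df["BADA"] = rng.normal(4.5, 0.4, len(df))
        res = run_model_suite(4, df, dimension_cols=["dimA", "dimNull"],
                              n_perm=300, seed=4)
        tab = res.set_index("outcome")
        assert tab.loc["dimA", "significant"]
        assert not tab.loc["dimNull", "significant"]
        assert tab.loc["dimA", "cohens_d"] > 0.3

    def test_eq6_interaction_suite_has_main_and_interaction_terms(self):
        rng = np.random.default_rng(40)
        df = _paired_frame(seed=40, nG=30, m=8, beta_state=0.5)
        df = df.rename(columns={"y": "dimA"})
        df["sex"] = np.where(
            df["participant_id"].str[1:].astype(int) % 2 == 0,
            "female", "male")
        per_part = {p: rng.normal(0, 1, 11) for p in df["participant_id"].unique()}
        for i, name in enumerate(["education", "BADA", "STAI", "PSQI", "ATD",
                                  "MW", "BSRT", "ROCFr", "MEQ", "VVIQ",
                                  "SCWT"]):
            df[name] = df["participant_id"].map(lambda p: per_part[p][i])
        res = run_model_suite(6, df, dimension_cols=["dimA"])
        terms = set(res["term"])
        assert "state" in terms and "state:MW" in terms and "MW" in terms
        # q-values computed within the single model
        assert res["q_value"].notna().all()

    def test_eq8_uses_prior_significant_predictors_plus_pcs(self):
        rng = np.random.default_rng(41)
        df = _paired_frame(seed=41, nG=30, m=8, beta_state=0.0)
        df = df.rename(columns={"y": "dimA"})
        for pc in ("PC1", "PC2", "PC3", "PC4"):
            df[pc] = rng.standard_normal(len(df))
        df["dimA"] += 0.8 * df["PC1"]
        prior = pd.DataFrame({"outcome": ["dimA", "dimA"],
                              "term": ["age", "STAI"],
                              "p_param": [0.01, 0.50]})
        df["STAI"] = rng.standard_normal(len(df))
        res = run_model_suite(8, df, dimension_cols=["dimA"],
                              prior_results=prior)
        assert set(res["term"]) == {"PC1", "PC2", "PC3", "PC4"}
        tab = res.set_index("term")
        assert tab.loc["PC1", "significant"]
        assert not tab.loc["PC3", "significant"]

    def test_eq10_contrasts_experiment_cohorts(self):
        rng = np.random.default_rng(43)
        df = _paired_frame(seed=43, nG=30, m=6, beta_state=0.0)
        df = df.rename(columns={"y": "dimA"})
        df["experiment"] = (df["participant_id"].str[1:].astype(int) < 15).astype(int)
        df["dimA"] += 1.0 * df["experiment"]
        df["sex"] = "female"
        df["education"] = rng.normal(16, 2, len(df))
        df["WC_part"] = rng.normal(4.0, 0.3, len(df))
        res = run_model_suite(10, df, dimension_cols=["dimA"])
        assert res.loc[0, "term"] == "experiment"
        assert res.loc[0, "significant"]

    def test_unknown_equation_errors(self, suite_frame):
        with pytest.raises(ValueError):
            run_model_suite(99, suite_frame)


def test_eq5_detects_planted_dream_enrichment(scenario, scored,
                                              analysis_table):
    """End to end: the binomial state models flag the discovered domains
    that correspond to the generator's dream-enriched domains."""
    enriched = {f"d{k:02d}" for k in
                scenario["truths"]["corpus"].enriched_domains}
    model_tops = scored["rdm"].retained_domains
    # map each discovered domain to the generator domain of its top lemmas
    from collections import Counter
    mapping = {}
    for name, lemmas in zip(scored["M"].domains,
                            _discovered_top_lemmas(scored)):
        prefixes = Counter(lem.split("_")[0] for lem in lemmas
                           if lem.startswith("d"))
        if prefixes:
            mapping[name] = prefixes.most_common(1)[0][0]
    res = run_model_suite(5, analysis_table, domain_cols=model_tops, seed=0)
    tab = res.set_index("outcome")
    enriched_cols = [d for d in model_tops if mapping.get(d) in enriched]
    other_cols = [d for d in model_tops if mapping.get(d) not in enriched]
    assert enriched_cols, "discovery must recover some enriched domain"
    # enriched domains: positive state coefficients, mostly significant
    hits = sum(tab.loc[d, "significant"] and tab.loc[d, "estimate"] > 0
               for d in enriched_cols)
    assert hits >= max(1, len(enriched_cols) - 1)
    # non-enriched domains rarely significant
    false_hits = sum(bool(tab.loc[d, "significant"]) for d in other_cols)
    assert false_hits <= max(1, len(other_cols) // 4)


def _discovered_top_lemmas(scored):
    """Top lemmas per discovered domain, via the nonzero rows of M."""
    import numpy as _np
    M = scored["M"]
    out = []
    for k in range(len(M.domains)):
        col = M.M[:, k]
        idx = _np.argsort(col)[::-1][:10]
        out.append([M.lemmas[i] for i in idx if col[i] > 0])
    return out
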