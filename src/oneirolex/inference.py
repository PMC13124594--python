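"""Mixed-model inference for semantic dimensions and lexical domains.

The model suite mirrors the study design: every outcome (a 1–9 dimension
score or a binary domain indicator) is regressed on a focal predictor plus
demographic/verbosity covariates with a per-participant random intercept.
Gaussian models handle dimension outcomes, random-intercept logistic models
handle domain outcomes.  The vigilance-state coefficient additionally gets a
within-participant permutation null (state labels shuffled inside each
participant, preserving the repeated-measures structure) with
generalized-Pareto tail refinement of extreme p-values, and
Benjamini–Hochberg FDR correction within the family the equation defines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .glmm import GaussianRandomIntercept, LogisticRandomIntercept, MixedFit

__all__ = [
    "ModelSpec",
    "ModelResult",
    "ActigraphyPCs",
    "fit_glme",
    "permutation_null",
    "gpd_tail_pvalue",
    "fdr_bh",
    "cohens_d",
    "adjusted_values",
    "actigraphy_pca",
    "polynomial_trend",
    "run_model_suite",
    "state_permutation_test",
    "TRAIT_PREDICTORS",
    "BASE_COVARIATES",
]

logger = logging.getLogger(__name__)

#: covariates of no interest present in most models
BASE_COVARIATES = "C(sex) + age + education + BADA"

#: trait battery entering the interaction models
TRAIT_PREDICTORS = ["C(sex)", "age", "education", "BADA", "STAI", "PSQI",
                    "ATD", "MW", "BSRT", "ROCFr", "MEQ", "VVIQ", "SCWT"]


@dataclass
class ModelSpec:
    """One generalized linear mixed-effects model to fit.

    ``rhs`` is a formula right-hand side (patsy syntax); ``focal`` lists the
    design-column names whose coefficients are of scientific interest.
    The vigilance state enters as the numeric column ``state`` (0 = wake,
    1 = dream).
    """

    outcome: str
    family: str                      # 'gaussian' or 'binomial'
    rhs: str
    focal: list[str]
    group: str = "participant_id"
    equation_id: int | None = None

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class ModelResult:
    """A fitted model with everything downstream steps need."""

    spec: ModelSpec
    params: pd.DataFrame             # estimate, se, ci_low, ci_high, p_param
    adj_r2: float
    full_model_p: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    X: pd.DataFrame = field(repr=False)
    y: pd.Series = field(repr=False)
    groups: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)   # conditional (incl. BLUPs)
    perm_p: dict = field(default_factory=dict)
    q_value: dict = field(default_factory=dict)
    cohens_d: float | None = None

    @property
    def beta(self) -> pd.Series:
        return self.params["estimate"]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _design(spec: ModelSpec, data: pd.DataFrame):
    y_df, X_df = patsy.dmatrices(f"{spec.outcome} ~ {spec.rhs}", data,
                                 return_type="dataframe", NA_action="drop")
    dropped = len(data) - len(X_df)
    if dropped:
        logger.warning("model %s ~ %s: %d row(s) dropped for missing values",
                       spec.outcome, spec.rhs, dropped)
    groups = data.loc[X_df.index, spec.group].to_numpy()
    y = y_df.iloc[:, 0]
    missing = [f for f in spec.focal if f not in X_df.columns]
    if missing:
        raise ValueError(f"focal column(s) not in design: {missing}; "
                         f"available: {list(X_df.columns)}")
    return y, X_df, groups


def fit_glme(spec: ModelSpec, data: pd.DataFrame) -> ModelResult:
    """Fit one random-intercept model and collect its summary statistics.

    Gaussian outcomes use statsmodels ``MixedLM`` (ML); binomial outcomes use
    the package's Gauss–Hermite logistic mixed model.  The full-model p-value
    is a likelihood-ratio test against the intercept-only model (same random
    structure); the adjusted R² is the squared correlation between
    conditional fitted values and observations, adjusted for the number of
    fixed effects.
    """
    y, X_df, groups = _design(spec, data)
    X = X_df.to_numpy()
    n, p = X.shape
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 participants")

    if spec.family == "gaussian":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM(y.to_numpy(), X, groups).fit(reml=False)
            null = MixedLM(y.to_numpy(), np.ones((n, 1)), groups).fit(reml=False)
        beta = np.asarray(res.fe_params)
        se = np.asarray(res.bse_fe)
        converged = bool(res.converged)
        loglik = float(res.llf)
        lr = max(0.0, 2.0 * (loglik - float(null.llf)))
        re = res.random_effects
        fitted = X @ beta + np.array(
            [float(re[g].iloc[0]) for g in groups])
    else:
        fit: MixedFit = LogisticRandomIntercept().fit(y.to_numpy(), X, groups)
        null_fit = LogisticRandomIntercept().fit(
            y.to_numpy(), np.ones((n, 1)), groups)
        beta, se = fit.beta, fit.se
        converged = fit.converged
        loglik = fit.loglik
        lr = max(0.0, 2.0 * (loglik - null_fit.loglik))
        fitted = fit.fitted
    if not converged:
        warnings.warn(f"model for {spec.outcome!r} did not converge",
                      RuntimeWarning)

    z = stats.norm.ppf(0.975)
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = 2 * stats.norm.sf(np.abs(beta / se))
    params = pd.DataFrame({
        "estimate": beta, "se": se,
        "ci_low": beta - z * se, "ci_high": beta + z * se,
        "p_param": pvals,
    }, index=X_df.columns)
    full_model_p = float(stats.chi2.sf(lr, max(p - 1, 1)))
    yv = y.to_numpy()
    if np.std(fitted) > 0 and np.std(yv) > 0:
        r2 = float(np.corrcoef(fitted, yv)[0, 1] ** 2)
    else:
        r2 = 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / max(n - p, 1)
    return ModelResult(spec=spec, params=params, adj_r2=adj_r2,
                       full_model_p=full_model_p, loglik=loglik,
                       n_obs=n, n_groups=len(np.unique(groups)),
                       converged=converged, X=X_df, y=y, groups=groups,
                       fitted=fitted)


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def _group_indices(groups: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(groups == g) for g in np.unique(groups)]


def _permute_within(values: np.ndarray, idx_list: list[np.ndarray],
                    rng: np.random.Generator) -> np.ndarray:
    out = values.copy()
    for idx in idx_list:
        out[idx] = values[idx][rng.permutation(len(idx))]
    return out


def permutation_null(
    spec: ModelSpec,
    data: pd.DataFrame,
    n_perm: int = 5000,
    seed: int = 0,
    focal: str = "state",
) -> np.ndarray:
    """Null distribution of the focal (vigilance-state) coefficient.

    The binary state variable is shuffled within each participant and the
    model refitted for every permutation, so each participant keeps their
    exact dream/wake counts and the repeated-measures structure is intact.
    Participants with a single report contribute no permutation variability
    (they are kept; logged).  Gaussian refits run through the fast profiled
    engine; binomial refits reuse the Gauss–Hermite fitter warm-started at
    the observed solution.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse null", RuntimeWarning)
    y, X_df, groups = _design(spec, data)
    if focal not in X_df.columns:
        raise ValueError(f"focal column {focal!r} not in design")
    # the fast path swaps the focal column in-place, which is only valid
    # when the state enters the design through that single column
    involved = [c for c in X_df.columns if focal in c.split(":")]
    if involved != [focal]:
        raise NotImplementedError(
            "permutation_null requires the state as a main effect only")
    n_single = int((pd.Series(groups).value_counts() == 1).sum())
    if n_single:
        logger.info("%d participant(s) with a single report kept; they "
                    "contribute no permutation variability", n_single)
    X = X_df.to_numpy()
    j = X_df.columns.get_loc(focal)
    state = X[:, j].copy()
    idx_list = _group_indices(groups)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    yv = y.to_numpy()
    if spec.family == "gaussian":
        engine = GaussianRandomIntercept()
        for b in range(n_perm):
            X[:, j] = _permute_within(state, idx_list, rng)
            null[b] = engine.fit(yv, X, groups).beta[j]
    else:
        engine = LogisticRandomIntercept(n_nodes=15)
        base = engine.fit(yv, X, groups)
        start = np.concatenate([base.beta, [np.log(max(base.sigma_u, 1e-3))]])
        for b in range(n_perm):
            X[:, j] = _permute_within(state, idx_list, rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                null[b] = engine.fit(yv, X, groups, start=start.copy()).beta[j]
    X[:, j] = state
    return null


def gpd_tail_pvalue(
    observed_beta: float,
    null_betas: np.ndarray,
    exceed_trigger: int = 10,
    n_tail: int = 250,
) -> float:
    """Two-sided permutation p-value with generalized-Pareto tail refinement.

    With at least ``exceed_trigger`` null values as extreme as the observed
    one the empirical estimate ``(1 + #exceedances) / (n + 1)`` is returned
    directly.  Otherwise a generalized Pareto distribution is fitted to the
    largest ``n_tail`` absolute null values (threshold midway between the
    tail and the rest) and the tail probability is extrapolated, giving
    resolution below ``1/n_perm``.  A failed fit falls back to the empirical
    estimate with a warning.
    """
    null = np.abs(np.asarray(null_betas, dtype=float))
    if null.size < 100:
        raise ValueError("need at least 100 null values")
    obs = abs(float(observed_beta))
    n = null.size
    n_exc = int(np.sum(null >= obs))
    p_emp = (1.0 + n_exc) / (n + 1.0)
    if n_exc >= exceed_trigger:
        return p_emp
    n_tail = min(n_tail, n // 2)
    srt = np.sort(null)[::-1]
    thresh = 0.5 * (srt[n_tail - 1] + srt[n_tail])
    excess = srt[:n_tail] - thresh
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c, loc, scale = stats.genpareto.fit(excess, floc=0.0)
        p_gpd = (n_tail / n) * float(
            stats.genpareto.sf(obs - thresh, c, loc=0.0, scale=scale))
        if not np.isfinite(p_gpd) or p_gpd <= 0:
            raise ValueError("degenerate GPD tail probability")
    except Exception:
        warnings.warn("GPD tail fit failed; falling back to the empirical "
                      "permutation p-value", RuntimeWarning)
        return p_emp
    return min(p_gpd, 1.0)


def state_permutation_test(
    spec: ModelSpec,
    data: pd.DataFrame,
    n_perm: int = 5000,
    seed: int = 0,
    focal: str = "state",
) -> tuple[float, np.ndarray]:
    """Observed focal beta's permutation/GPD p-value plus the null draws."""
    result = fit_glme(spec, data)
    null = permutation_null(spec, data, n_perm=n_perm, seed=seed, focal=focal)
    p = gpd_tail_pvalue(result.beta[focal], null, )
    return p, null


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: returns (q_values, rejection mask)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


# ---------------------------------------------------------------------------
# effect sizes and adjusted displays
# ---------------------------------------------------------------------------

def cohens_d(values: np.ndarray, is_dream: np.ndarray) -> float:
    """Standardized dream-minus-wake mean difference with pooled sd."""
    values = np.asarray(values, dtype=float)
    is_dream = np.asarray(is_dream, dtype=bool)
    a, b = values[is_dream], values[~is_dream]
    n1, n0 = len(a), len(b)
    if n1 < 2 or n0 < 2:
        return np.nan
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n0 - 1) * b.var(ddof=1)) / (n1 + n0 - 2)
    if sp2 == 0:
        warnings.warn("zero pooled sd; Cohen's d undefined", RuntimeWarning)
        return np.nan
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def adjusted_values(
    result: ModelResult,
    drop_covariates: list[str],
) -> np.ndarray:
    """Outcome values with the nuisance covariates' contribution removed.

    The removed contribution is mean-centered so that adjusted values stay
    on the outcome's scale and are invariant to constant shifts of a
    nuisance covariate.  Gaussian: response minus the centered nuisance
    contribution.  Binomial: response-scale residual (observed minus fitted
    probability) added back onto the fitted probability of the reduced
    linear predictor.
    """
    info = result.X.design_info
    cols: list[str] = []
    for name in drop_covariates:
        matches = [t for t in info.term_names if t == name]
        if not matches:
            raise ValueError(f"covariate {name!r} not a model term; "
                             f"terms: {info.term_names}")
        sl = info.term_name_slices[matches[0]]
        cols.extend(result.X.columns[sl])
    Xd = result.X[cols].to_numpy()
    bd = result.beta[cols].to_numpy()
    contrib = Xd @ bd
    contrib = contrib - contrib.mean()
    yv = result.y.to_numpy()
    if result.spec.family == "gaussian":
        return yv - contrib
    # binomial: response residual + reduced-model fitted probability
    from scipy.special import expit, logit
    eta_full = logit(np.clip(result.fitted, 1e-12, 1 - 1e-12))
    p_red = expit(eta_full - contrib)
    return (yv - result.fitted) + p_red


# ---------------------------------------------------------------------------
# actigraphy PCA and trend fits
# ---------------------------------------------------------------------------

@dataclass
class ActigraphyPCs:
    loadings: pd.DataFrame           # index x PCs
    scores: pd.DataFrame             # nights x PCs
    variance_explained: np.ndarray   # percent, per retained PC
    n_pcs: int


def actigraphy_pca(index_table: pd.DataFrame, n_pcs: int = 4) -> ActigraphyPCs:
    """Correlation-matrix PCA of the actigraphic indices.

    Columns are z-scored (the indices have heterogeneous units); constant
    columns are dropped with a warning.  The first ``n_pcs`` components are
    retained (four in the reference analysis).
    """
    num = index_table.select_dtypes(include=[np.number])
    if len(num) < 5:
        raise ValueError("need at least 5 nights for a stable PCA")
    sd = num.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"constant actigraphic column(s) dropped: {constant}",
                      RuntimeWarning)
        num = num.drop(columns=constant)
        sd = sd.drop(constant)
    Z = (num - num.mean()) / sd
    pca = PCA()
    scores = pca.fit_transform(Z.to_numpy())
    n_pcs = min(n_pcs, scores.shape[1])
    names = [f"PC{i + 1}" for i in range(n_pcs)]
    return ActigraphyPCs(
        loadings=pd.DataFrame(pca.components_[:n_pcs].T, index=num.columns,
                              columns=names),
        scores=pd.DataFrame(scores[:, :n_pcs], index=num.index, columns=names),
        variance_explained=pca.explained_variance_ratio_[:n_pcs] * 100.0,
        n_pcs=n_pcs,
    )


@dataclass
class PolynomialTrend:
    degree: int
    coefficients: np.ndarray         # numpy polynomial coefficients, high->low

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(x, dtype=float))


def polynomial_trend(x, y, max_degree: int = 3) -> PolynomialTrend:
    """Visualization-only polynomial fit of adjusted values against time.

    Candidate degrees 0..``max_degree`` are compared by AIC; the lowest
    degree within 2 AIC units of the best is chosen (parsimony tie-break).
    Never feeds inference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    feasible = max_degree
    if n < max_degree + 2:
        feasible = max(0, n - 2)
        warnings.warn(f"only {n} points; reducing max degree to {feasible}",
                      RuntimeWarning)
    aics, fits = [], []
    for d in range(feasible + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", np.exceptions.RankWarning)
            coeffs = np.polyfit(x, y, d)
        rss = float(np.sum((np.polyval(coeffs, x) - y) ** 2))
        aics.append(n * np.log(max(rss, 1e-300) / n) + 2 * (d + 1))
        fits.append(coeffs)
    best = min(aics)
    degree = next(d for d, a in enumerate(aics) if a <= best + 2.0)
    return PolynomialTrend(degree=degree, coefficients=fits[degree])


# ---------------------------------------------------------------------------
# the model suite (equations 1-13)
# ---------------------------------------------------------------------------

def _tidy(results: list[ModelResult], focal_rows) -> pd.DataFrame:
    rows = []
    for res, focal in focal_rows:
        prm = res.params.loc[focal]
        rows.append({
            "equation": res.spec.equation_id,
            "outcome": res.spec.outcome,
            "term": focal,
            "family": res.spec.family,
            "estimate": prm["estimate"],
            "ci_low": prm["ci_low"],
            "ci_high": prm["ci_high"],
            "p_param": prm["p_param"],
            "adj_r2": res.adj_r2,
            "full_model_p": res.full_model_p,
            "n_obs": res.n_obs,
            "n_participants": res.n_groups,
            "converged": res.converged,
            "p_perm": res.perm_p.get(focal, np.nan),
            "cohens_d": res.cohens_d,
        })
    return pd.DataFrame(rows)


def run_model_suite(
    equation_id: int,
    table: pd.DataFrame,
    dimension_cols: list[str] | None = None,
    domain_cols: list[str] | None = None,
    n_perm: int = 0,
    seed: int = 0,
    prior_results: pd.DataFrame | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Fit one equation of the model suite over all its outcomes.

    ``table`` holds one row per report with outcome columns (dimensions
    and/or binary domains), ``participant_id``, the numeric ``state``
    (1 = dream), demographics and traits, and — depending on the equation —
    ``time_rank``, ``experiment``, ``WC_part`` and ``PC1..PC4``.

    Families for FDR follow the study design: across outcomes for the
    state/experiment coefficient (equations 4, 5, 10, 11) and for each
    pairwise family (1-3); within each model for the trait and sleep models
    (6-9); separately for the time-by-state interaction and the time main
    effect (12, 13).  When ``n_perm`` > 0, equations 4 and 5 add the
    within-participant permutation + GPD p-value for the state coefficient
    (q-values are then computed on the permutation p-values) and the
    adjusted-values Cohen's d.
    """
    dims = dimension_cols or []
    doms = domain_cols or []
    rng = np.random.default_rng(seed)
    results: list[ModelResult] = []
    focal_rows: list[tuple[ModelResult, str]] = []

    def fit_and_track(spec: ModelSpec, focal_terms: list[str] | None = None):
        res = fit_glme(spec, table)
        results.append(res)
        for f in (focal_terms or spec.focal):
            focal_rows.append((res, f))
        return res

    if equation_id in (1, 2, 3):
        family = "gaussian" if equation_id == 1 else "binomial"
        outcomes = dims if equation_id == 1 else doms
        predictors = {1: dims, 2: doms, 3: dims}[equation_id]
        for out in outcomes:
            for pred in predictors:
                if pred == out:
                    continue
                spec = ModelSpec(out, family, f"{pred} + {BASE_COVARIATES}",
                                 [pred], equation_id=equation_id)
                fit_and_track(spec)
        tidy = _tidy(results, focal_rows)
        tidy["q_value"], tidy["significant"] = fdr_bh(tidy["p_param"], q)
        return tidy

    if equation_id in (4, 5, 10, 11):
        family = "gaussian" if equation_id in (4, 10) else "binomial"
        outcomes = dims if equation_id in (4, 10) else doms
        focal = "state" if equation_id in (4, 5) else "experiment"
        covs = (BASE_COVARIATES if equation_id in (4, 5)
                else "C(sex) + age + education + WC_part")
        for out in outcomes:
            spec = ModelSpec(out, family, f"{focal} + {covs}", [focal],
                             equation_id=equation_id)
            res = fit_and_track(spec)
            if n_perm > 0 and focal == "state":
                null = permutation_null(spec, table, n_perm=n_perm,
                                        seed=int(rng.integers(2**31 - 1)),
                                        focal=focal)
                res.perm_p[focal] = gpd_tail_pvalue(res.beta[focal], null)
                adj = adjusted_values(res, ["C(sex)", "age", "education", "BADA"])
                is_dream = res.X["state"].to_numpy() == 1
                res.cohens_d = cohens_d(adj, is_dream)
        tidy = _tidy(results, focal_rows)
        p_for_fdr = (tidy["p_perm"].fillna(tidy["p_param"])
                     if n_perm > 0 and focal == "state" else tidy["p_param"])
        tidy["q_value"], tidy["significant"] = fdr_bh(p_for_fdr, q)
        return tidy

    if equation_id in (6, 7):
        family = "gaussian" if equation_id == 6 else "binomial"
        outcomes = dims if equation_id == 6 else doms
        rhs = "state * (" + " + ".join(TRAIT_PREDICTORS) + ")"
        frames = []
        for out in outcomes:
            spec = ModelSpec(out, family, rhs, ["state"],
                             equation_id=equation_id)
            res = fit_glme(spec, table)
            terms = [c for c in res.X.columns if c != "Intercept"]
            tidy = _tidy([res] * len(terms), [(res, t) for t in terms])
            # FDR within each model
            tidy["q_value"], tidy["significant"] = fdr_bh(tidy["p_param"], q)
            frames.append(tidy)
        return pd.concat(frames, ignore_index=True)

    if equation_id in (8, 9):
        family = "gaussian" if equation_id == 8 else "binomial"
        outcomes = dims if equation_id == 8 else doms
        if prior_results is None:
            raise ValueError("equations 8/9 need the equation 6/7 results to "
                             "select significant predictors")
        pcs = ["PC1", "PC2", "PC3", "PC4"]
        dreams = table[table["state"] == 1]
        frames = []
        for out in outcomes:
            prior = prior_results[(prior_results["outcome"] == out)
                                  & (prior_results["p_param"] < 0.05)]
            keep = [t for t in prior["term"]
                    if ":" not in t and t not in pcs]
            # map design columns like 'C(sex)[T.male]' back to terms
            keep = sorted({t.split("[")[0] for t in keep})
            rhs = " + ".join(keep + pcs) if keep else " + ".join(pcs)
            spec = ModelSpec(out, family, rhs, pcs, equation_id=equation_id)
            res = fit_glme(spec, dreams)
            tidy = _tidy([res] * len(pcs), [(res, t) for t in pcs])
            tidy["q_value"], tidy["significant"] = fdr_bh(tidy["p_param"], q)
            frames.append(tidy)
        return pd.concat(frames, ignore_index=True)

    if equation_id in (12, 13):
        family = "gaussian" if equation_id == 12 else "binomial"
        outcomes = dims if equation_id == 12 else doms
        rhs = f"state * time_rank + {BASE_COVARIATES}"
        for out in outcomes:
            spec = ModelSpec(out, family, rhs,
                             ["state:time_rank", "time_rank"],
                             equation_id=equation_id)
            fit_and_track(spec)
        tidy = _tidy(results, focal_rows)
        # separate FDR families for the interaction and the time main effect
        tidy["q_value"] = np.nan
        tidy["significant"] = False
        for term_kind in ("state:time_rank", "time_rank"):
            m = tidy["term"] == term_kind
            qv, rej = fdr_bh(tidy.loc[m, "p_param"], q)
            tidy.loc[m, "q_value"] = qv
            tidy.loc[m, "significant"] = rej
        return tidy

    raise ValueError(f"unknown equation id {equation_id}")
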