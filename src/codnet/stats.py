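"""Inferential layer: count mixed models, collinearity screening, and the
seasonal/site comparison tests.

The centrepiece is a maximum-likelihood negative-binomial generalized linear
mixed model (and its zero-inflated variant) for weekly connectivity counts:

    y_ij | b_i ~ NB2(mu_ij, theta),   log mu_ij = x_ij' beta + b_i,
    b_i ~ Normal(0, sigma_b^2)

with one random intercept per fish.  NB2 means Var(y) = mu + mu^2/theta.
The marginal likelihood integrates the random intercept out per subject by
adaptive Gauss–Hermite quadrature (default 15 nodes, recentred and rescaled
at each subject's conditional mode), and is maximised by L-BFGS-B over
(beta, log theta, log sigma_b).  The zero-inflated variant mixes in an
intercept-only structural-zero process on the logit scale:

    P(y_ij = 0) = pi + (1 - pi) NB(0 | mu_ij, theta)

with the random intercept living in the count part.  Standard errors are
Wald, from the numerical Hessian at the optimum.

The remaining operations are the standard toolkit around those models:
predictor transforms, VIF screening, Welch's heteroscedastic F with a
Games–Howell post hoc, Spearman rank correlation (with permutation or
exhaustive p-values at small n), and two-sample site comparisons.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

__all__ = [
    "MixedModelFit",
    "ComparisonResult",
    "fit_nb_glmm",
    "fit_zinb_glmm",
    "transform_predictors",
    "vif_screen",
    "welch_anova",
    "games_howell",
    "spearman_test",
    "site_comparison",
]


# --------------------------------------------------------------------------
# results containers
# --------------------------------------------------------------------------


@dataclass
class MixedModelFit:
    """Fitted count GLMM with a per-subject random intercept."""

    terms: pd.DataFrame | None  # index: term; columns: estimate, se, z, p
    theta: float | None = None  # NB2 size (dispersion) parameter
    sigma_b: float | None = None  # random-intercept SD
    zi_prob: float | None = None  # structural-zero probability (ZINB only)
    loglik: float | None = None
    converged: bool = False
    estimable: bool = True
    message: str = ""
    n_obs: int = 0
    n_subjects: int = 0
    n_quad: int = 0
    nll_trace: list = field(default_factory=list)

    @classmethod
    def non_estimable(cls, reason: str, n_obs: int = 0, n_subjects: int = 0):
        return cls(terms=None, estimable=False, converged=False, message=reason,
                   n_obs=n_obs, n_subjects=n_subjects)

    def coef(self, term: str) -> float:
        return float(self.terms.loc[term, "estimate"])

    def wald_ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        z = sps.norm.ppf(0.5 + level / 2)
        est, se = self.terms.loc[term, ["estimate", "se"]]
        return float(est - z * se), float(est + z * se)

    def to_json(self) -> str:
        payload = {
            "terms": None if self.terms is None else {
                t: {k: float(v) for k, v in row.items()}
                for t, row in self.terms.iterrows()
            },
            "theta": self.theta,
            "sigma_b": self.sigma_b,
            "zi_prob": self.zi_prob,
            "loglik": self.loglik,
            "converged": self.converged,
            "estimable": self.estimable,
            "message": self.message,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "n_quad": self.n_quad,
        }
        return json.dumps(payload, indent=1)


@dataclass
class ComparisonResult:
    """Result of a univariate comparison test."""

    statistic: float
    pvalue: float
    df: float | tuple | None = None
    method: str = ""
    table: pd.DataFrame | None = None


# --------------------------------------------------------------------------
# negative binomial building blocks
# --------------------------------------------------------------------------

_ETA_CLIP = 30.0


def _nb2_logpmf(y: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB2 log pmf with size theta: Var = mu + mu^2 / theta.

    Written in log1p form so the Poisson limit (huge theta) stays
    numerically stable — the naive ``theta * log(theta / (theta + mu))``
    cancels catastrophically there.
    """
    r = np.log1p(mu / theta)
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        - theta * r
        + y * (np.log(mu) - math.log(theta) - r)
    )


class _RandomInterceptLikelihood:
    """Marginal log-likelihood of a random-intercept count model via AGQ.

    Data are sorted subject-major at construction so per-subject sums reduce
    to ``np.add.reduceat``.  Conditional modes are found by a damped Newton
    iteration using finite-difference derivatives of the per-subject joint
    log density in the scalar random effect — the same code path serves the
    plain and zero-inflated models.
    """

    def __init__(self, y, X, groups, n_quad=15):
        order = np.argsort(groups, kind="mergesort")
        self.y = np.asarray(y, dtype=float)[order]
        self.X = np.asarray(X, dtype=float)[order]
        g = np.asarray(groups)[order]
        self.subjects, self.g = np.unique(g, return_inverse=True)
        self.m = len(self.subjects)
        self.starts = np.searchsorted(self.g, np.arange(self.m))
        self.n_quad = n_quad
        self.z, w = np.polynomial.hermite.hermgauss(n_quad)
        self.logw = np.log(w)
        self._modes = np.zeros(self.m)

    # subclasses define the conditional per-observation log-likelihood
    def obs_loglik(self, b_per_obs: np.ndarray, pars: dict) -> np.ndarray:
        raise NotImplementedError

    def _subject_joint(self, B: np.ndarray, pars: dict, sigma: float) -> np.ndarray:
        """Joint log density per subject at random-effect values B (m, q)."""
        ll = self.obs_loglik(B[self.g, :], pars)  # (n, q)
        out = np.add.reduceat(ll, self.starts, axis=0)
        out += -0.5 * (B / sigma) ** 2 - math.log(sigma) - 0.5 * math.log(2 * math.pi)
        return out

    def loglik(self, pars: dict, sigma: float) -> float:
        # locate conditional modes (warm-started damped Newton, FD derivatives)
        b = self._modes.copy()
        h = 1e-4
        for _ in range(60):
            B = np.column_stack([b - h, b, b + h])
            f = self._subject_joint(B, pars, sigma)
            g1 = (f[:, 2] - f[:, 0]) / (2 * h)
            g2 = (f[:, 2] - 2 * f[:, 1] + f[:, 0]) / h**2
            g2 = np.minimum(g2, -1e-8)
            step = np.clip(-g1 / g2, -1.0, 1.0)
            b = np.clip(b + step, -15 * sigma - 5, 15 * sigma + 5)
            if np.max(np.abs(step)) < 1e-9:
                break
        self._modes = b
        # curvature at the mode for the adaptive rescaling
        B = np.column_stack([b - h, b, b + h])
        f = self._subject_joint(B, pars, sigma)
        curv = np.maximum(-(f[:, 2] - 2 * f[:, 1] + f[:, 0]) / h**2, 1e-8)
        scale = 1.0 / np.sqrt(curv)
        nodes = b[:, None] + math.sqrt(2.0) * scale[:, None] * self.z[None, :]
        fz = self._subject_joint(nodes, pars, sigma)
        per_subject = (
            0.5 * math.log(2.0)
            + np.log(scale)
            + special.logsumexp(self.logw[None, :] + self.z[None, :] ** 2 + fz, axis=1)
        )
        return float(per_subject.sum())


class _NBLikelihood(_RandomInterceptLikelihood):
    def obs_loglik(self, b, pars):
        eta = np.clip(self.X @ pars["beta"] , -_ETA_CLIP, _ETA_CLIP)[:, None] + b
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        return _nb2_logpmf(self.y[:, None], mu, pars["theta"])


class _ZINBLikelihood(_RandomInterceptLikelihood):
    def obs_loglik(self, b, pars):
        eta = np.clip(self.X @ pars["beta"], -_ETA_CLIP, _ETA_CLIP)[:, None] + b
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        lp = _nb2_logpmf(self.y[:, None], mu, pars["theta"])
        log_pi = -np.logaddexp(0.0, -pars["gamma0"])   # log pi
        log_1mpi = -np.logaddexp(0.0, pars["gamma0"])  # log(1 - pi)
        zero = self.y[:, None] == 0
        return np.where(zero, np.logaddexp(log_pi, log_1mpi + lp), log_1mpi + lp)


def _design(covariates, n_obs, add_intercept=True):
    if covariates is None:
        X = np.ones((n_obs, 0))
        names = []
    elif isinstance(covariates, pd.DataFrame):
        X = covariates.to_numpy(dtype=float)
        names = list(covariates.columns)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["(Intercept)"] + names
    return X, names


def _numeric_hessian(fn, x, step=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    hs = step * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = hs[i]
            ej = np.zeros(k); ej[j] = hs[j]
            f_pp = fn(x + ei + ej)
            f_pm = fn(x + ei - ej)
            f_mp = fn(x - ei + ej)
            f_mm = fn(x - ei - ej)
            H[i, j] = H[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * hs[i] * hs[j])
    return H


def _fit_count_glmm(y, covariates, subjects, *, zero_inflated, n_quad, add_intercept,
                    maxiter, fixed_theta=None):
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("response must be non-negative integer counts")
    subjects = np.asarray(subjects)
    n_sub = len(np.unique(subjects))
    if y.sum() == 0:
        return MixedModelFit.non_estimable(
            "all-zero response: count model not estimable",
            n_obs=len(y), n_subjects=n_sub,
        )
    if zero_inflated and not np.any(y == 0):
        return MixedModelFit.non_estimable(
            "no zeros in response: zero-inflation probability not identifiable",
            n_obs=len(y), n_subjects=n_sub,
        )
    X, names = _design(covariates, len(y), add_intercept)

    lik_cls = _ZINBLikelihood if zero_inflated else _NBLikelihood
    lik = lik_cls(y, X, subjects, n_quad=n_quad)

    # moment/Poisson starting values
    import statsmodels.api as sm

    try:
        beta0 = sm.GLM(y, X, family=sm.families.Poisson()).fit().params
    except Exception:
        beta0 = np.zeros(X.shape[1])
        if add_intercept:
            beta0[0] = math.log(max(y.mean(), 0.1))
    p = X.shape[1]
    free_theta = fixed_theta is None

    def unpack(x):
        i = p
        pars = {"beta": x[:p]}
        if free_theta:
            pars["theta"] = math.exp(x[i])
            i += 1
        else:
            pars["theta"] = float(fixed_theta)
        if zero_inflated:
            pars["gamma0"] = x[i]
            i += 1
        return pars, math.exp(x[i])

    def nll(x):
        pars, sigma = unpack(x)
        try:
            return -lik.loglik(pars, sigma)
        except FloatingPointError:
            return 1e12

    x0 = np.concatenate(
        [beta0, [0.0] if free_theta else [], [-1.5] if zero_inflated else [],
         [math.log(0.5)]]
    )
    bounds = (
        [(-_ETA_CLIP, _ETA_CLIP)] * p
        + ([(-5.0, 12.0)] if free_theta else [])
        + ([(-8.0, 8.0)] if zero_inflated else [])
        + [(-6.0, 3.0)]
    )
    trace: list[float] = []
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        callback=lambda xk: trace.append(float(nll(xk))),
        options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7},
    )

    pars, sigma = unpack(res.x)
    H = _numeric_hessian(nll, res.x)
    se = np.full(len(res.x), np.nan)
    try:
        cov = np.linalg.pinv(H)
        d = np.diag(cov)
        se = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        pass

    est = res.x[:p]
    zval = est / se[:p]
    terms = pd.DataFrame(
        {"estimate": est, "se": se[:p], "z": zval, "p": 2 * sps.norm.sf(np.abs(zval))},
        index=names,
    )
    fit = MixedModelFit(
        terms=terms,
        theta=pars["theta"],
        sigma_b=sigma,
        zi_prob=float(special.expit(pars["gamma0"])) if zero_inflated else None,
        loglik=-float(res.fun),
        converged=bool(res.success) and np.isfinite(se[:p]).all(),
        message=str(res.message),
        n_obs=len(y),
        n_subjects=lik.m,
        n_quad=n_quad,
        nll_trace=trace,
    )
    return fit


def fit_nb_glmm(counts, covariates, subjects, *, n_quad: int = 15,
                add_intercept: bool = True, maxiter: int = 300,
                fixed_theta: float | None = None) -> MixedModelFit:
    """Fit the NB2 random-intercept GLMM by adaptive Gauss–Hermite ML.

    Parameters
    ----------
    counts
        Non-negative integer response (e.g. weekly summed node strength).
    covariates
        DataFrame (column names become term names) or array of fixed-effect
        covariates; an intercept is prepended unless ``add_intercept=False``.
    subjects
        Grouping labels (one random intercept per unique label).
    n_quad
        Number of Gauss–Hermite nodes for the random-effect integral.

    Returns a :class:`MixedModelFit` with Wald z and two-sided p per
    fixed-effect term.  Non-convergence is flagged, never silent.
    """
    return _fit_count_glmm(counts, covariates, subjects, zero_inflated=False,
                           n_quad=n_quad, add_intercept=add_intercept, maxiter=maxiter,
                           fixed_theta=fixed_theta)


def fit_zinb_glmm(counts, covariates, subjects, *, n_quad: int = 15,
                  add_intercept: bool = True, maxiter: int = 300) -> MixedModelFit:
    """Fit the zero-inflated NB2 random-intercept GLMM.

    The structural-zero process is intercept-only on the logit scale (the
    fitted probability is reported as ``zi_prob``); the random intercept
    enters the count process.  With no zeros in the response the mixture is
    not identifiable and a flagged, non-estimable fit is returned.
    """
    return _fit_count_glmm(counts, covariates, subjects, zero_inflated=True,
                           n_quad=n_quad, add_intercept=add_intercept, maxiter=maxiter)


# --------------------------------------------------------------------------
# covariate preparation
# --------------------------------------------------------------------------


def transform_predictors(env: pd.DataFrame) -> pd.DataFrame:
    """Standard transforms of the weekly environmental covariates.

    SST stays on its natural scale; wind speed is log-transformed and PAR
    square-root transformed (both right-skewed); wind direction (degrees)
    and sea level pass through.  Raises on non-positive wind speed.
    """
    if (env["wind_speed"] <= 0).any():
        raise ValueError("wind_speed must be positive for the log transform")
    if (env["par"] < 0).any():
        raise ValueError("par must be non-negative")
    out = pd.DataFrame(index=env.index)
    if "week_start" in env.columns:
        out["week_start"] = env["week_start"]
    out["sst"] = env["sst"].astype(float)
    out["log_wind_speed"] = np.log(env["wind_speed"].astype(float))
    out["sqrt_par"] = np.sqrt(env["par"].astype(float))
    out["wind_direction"] = env["wind_direction"].astype(float)
    out["sea_level"] = env["sea_level"].astype(float)
    return out


def vif_screen(covariates: pd.DataFrame, threshold: float = 3.0):
    """Iterative variance-inflation-factor screen.

    VIF_j = 1 / (1 - R^2_j) from regressing covariate j on the others (with
    intercept).  The covariate with the largest VIF above ``threshold`` is
    dropped and VIFs recomputed until all survivors pass.  Returns
    ``(retained DataFrame, table)`` where the table records covariate, step,
    vif, dropped.  Perfectly collinear covariates get infinite VIF and go
    first.
    """
    cols = list(covariates.columns)
    if len(cols) < 2:
        raise ValueError("need at least two covariates to screen")
    if len(covariates) < len(cols) + 1:
        raise ValueError("need more rows than covariates")

    def vif_of(df: pd.DataFrame) -> pd.Series:
        out = {}
        Xall = df.to_numpy(dtype=float)
        for j, c in enumerate(df.columns):
            yj = Xall[:, j]
            Xj = np.column_stack(
                [np.ones(len(df))] + [Xall[:, k] for k in range(Xall.shape[1]) if k != j]
            )
            coef, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
            resid = yj - Xj @ coef
            sst = np.sum((yj - yj.mean()) ** 2)
            r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 1.0
            out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return pd.Series(out)

    records = []
    current = covariates.copy()
    step = 0
    while True:
        v = vif_of(current)
        worst = v.idxmax()
        drop = len(current.columns) > 2 and v[worst] > threshold
        for c in current.columns:
            records.append(
                {"step": step, "covariate": c, "vif": float(v[c]),
                 "dropped": bool(drop and c == worst)}
            )
        if not drop:
            if v[worst] > threshold:
                # two covariates left but still collinear: drop the worst anyway
                records[-2 if worst == current.columns[0] else -1]["dropped"] = True
                current = current.drop(columns=[worst])
            break
        current = current.drop(columns=[worst])
        step += 1
    table = pd.DataFrame(records)
    return current, table


# --------------------------------------------------------------------------
# comparison tests
# --------------------------------------------------------------------------


def _check_groups(groups, min_size=2, require_variance=True):
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    for i, a in enumerate(arrs):
        if len(a) < min_size:
            raise ValueError(f"group {i} has fewer than {min_size} values")
        if require_variance and np.var(a, ddof=1) <= 0:
            raise ValueError(f"group {i} has zero variance")
    return arrs


def welch_anova(groups) -> ComparisonResult:
    """Welch's heteroscedastic one-way F test across k groups.

    Uses the weights w_i = n_i / s_i^2 and the Welch–Satterthwaite
    denominator degrees of freedom; reduces to the classical one-way ANOVA
    F when variances and group sizes are equal.
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    n = np.array([len(a) for a in arrs], dtype=float)
    mean = np.array([a.mean() for a in arrs])
    var = np.array([a.var(ddof=1) for a in arrs])
    w = n / var
    mw = np.sum(w * mean) / np.sum(w)
    a_term = np.sum(w * (mean - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / w.sum()) ** 2 / (n - 1))
    b_term = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    f = a_term / b_term
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3 * lam)
    p = float(sps.f.sf(f, df1, df2))
    return ComparisonResult(statistic=float(f), pvalue=p, df=(df1, float(df2)),
                            method="welch_anova")


def games_howell(groups, labels=None) -> ComparisonResult:
    """Games–Howell post hoc pairwise comparisons (unequal variances/sizes).

    For each pair: q = |mean difference| / sqrt((s_i^2/n_i + s_j^2/n_j)/2),
    Welch–Satterthwaite df, and p from the studentized range distribution
    with k groups.  Returns the pairwise table; the overall statistic is the
    largest q.
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    labels = list(labels) if labels is not None else list(range(k))
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        ai, aj = arrs[i], arrs[j]
        vi, vj = ai.var(ddof=1) / len(ai), aj.var(ddof=1) / len(aj)
        diff = ai.mean() - aj.mean()
        se = math.sqrt((vi + vj) / 2.0)
        q = abs(diff) / se
        df = (vi + vj) ** 2 / (vi**2 / (len(ai) - 1) + vj**2 / (len(aj) - 1))
        p = float(np.clip(sps.studentized_range.sf(q, k, df), 0.0, 1.0))
        rows.append({"group1": labels[i], "group2": labels[j], "mean_diff": diff,
                     "q": q, "df": df, "pvalue": p})
    table = pd.DataFrame(rows)
    best = table.loc[table["q"].idxmax()]
    return ComparisonResult(statistic=float(best["q"]), pvalue=float(best["pvalue"]),
                            df=float(best["df"]), method="games_howell", table=table)


def _rank_rho(rx: np.ndarray, RY: np.ndarray) -> np.ndarray:
    """Pearson correlation of centred rank vector rx with each row of RY."""
    rx = rx - rx.mean()
    RY = RY - RY.mean(axis=1, keepdims=True)
    num = RY @ rx
    den = math.sqrt(rx @ rx) * np.sqrt(np.sum(RY**2, axis=1))
    return num / den


def spearman_test(x, y, *, method: str = "auto", n_permutations: int = 10_000,
                  seed: int | None = 0) -> ComparisonResult:
    """Spearman rank correlation with tie correction.

    p-value methods: ``"exact"`` enumerates all permutations (n <= 8),
    ``"permutation"`` uses ``n_permutations`` seeded random permutations,
    ``"asymptotic"`` uses the t approximation, and ``"auto"`` picks exact
    for n <= 8 and permutation otherwise.  Constant inputs are rejected
    (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("x and y must have equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(_rank_rho(rx, ry[None, :])[0])

    n = len(x)
    if method == "auto":
        method = "exact" if n <= 8 else "permutation"
    if method == "asymptotic":
        p = float(sps.spearmanr(x, y).pvalue)
    elif method == "exact":
        perms = np.array(list(itertools.permutations(ry)))
        rhos = _rank_rho(rx, perms)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(ry) for _ in range(n_permutations)])
        rhos = _rank_rho(rx, perms)
        p = float((np.sum(np.abs(rhos) >= abs(rho) - 1e-12) + 1) / (n_permutations + 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return ComparisonResult(statistic=rho, pvalue=p, method=f"spearman_{method}")


def site_comparison(a, b, method: str = "t") -> ComparisonResult:
    """Two-sample comparison between sites.

    ``method="t"`` is Welch's two-sample t-test; ``method="wilcoxon"`` is the
    Wilcoxon rank-sum (Mann–Whitney U) with tie handling.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each site needs at least two values")
    if method == "t":
        res = sps.ttest_ind(a, b, equal_var=False)
        return ComparisonResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                                df=float(res.df), method="welch_t")
    if method == "wilcoxon":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        return ComparisonResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                                method="wilcoxon_ranksum")
    raise ValueError(f"unknown method {method!r}")
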