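"""Mixed-model variance components for transition-rate phenotypes.

Univariate model (background effects and mutational bias)
---------------------------------------------------------
For each log transition rate, a Gaussian linear mixed model with fixed
effects for MA status, genotype background and their interaction, and
crossed random intercepts of MA line and assay block:

    ln q = alpha + beta_MA + delta_bg + eta_MA:bg + line + block + e

Fitting is by direct (restricted) maximum likelihood profiled over the
fixed effects: the three variance components are optimized on the log
scale, with the GLS fixed-effect solution evaluated in closed form at
each candidate.  Fixed effects are tested with likelihood-ratio tests
(chi-square, 1 df per dropped effect) on ML fits, and homogeneity of
residual variance across the four genotype-by-MA groups is checked with
Levene's test on the conditional residuals of the final model.

Multivariate model (M and G matrices)
-------------------------------------
The six log rates are a multivariate response with fixed covariate
effects (temperature, humidity, log density) and 6x6 line, block and
residual covariance matrices:

    y_plate = B' x_plate + u_line + w_block + e_plate

Estimation is Bayesian by Gibbs sampling: fixed effects and the random
effect vectors have multivariate-normal full conditionals; each
covariance matrix has an inverse-Wishart full conditional with prior
scale the diagonal matrix of empirical phenotypic variances and prior
degrees of freedom n_traits + 1 (configurable).  The mutational
covariance matrix is half the posterior line covariance, because fixed
mutations in fully selfed lines are homozygous.  Null distributions come
from refits after independently permuting line and block labels across
plates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

from .synthetic import TRAIT_COLS, COVARIATE_COLS

_LOG2PI = np.log(2.0 * np.pi)


# -- phenotypic standardization ---------------------------------------------

def standardize(table: pd.DataFrame, traits: Sequence[str] = TRAIT_COLS) -> pd.DataFrame:
    """Center each trait and divide all by the mean per-trait SD.

    Each trait is centered by its own mean; the scale divisor is the
    single scalar mean of the six per-trait standard deviations, so the
    standardized traits keep their relative spreads while their average
    SD is exactly one.
    """
    if len(table) < 2:
        raise ValueError("standardization needs at least two rows")
    out = table.copy()
    vals = out[list(traits)].to_numpy(float)
    sds = vals.std(axis=0, ddof=1)
    sbar = sds.mean()
    if sbar <= 0:
        raise ValueError("mean trait standard deviation is zero")
    out[list(traits)] = (vals - vals.mean(axis=0)) / sbar
    return out


# -- univariate LMM ----------------------------------------------------------

FIXED_TERMS = ("background", "ma", "interaction")


@dataclass
class LmmFit:
    """A fitted Gaussian LMM with crossed random intercepts."""

    fixed_names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    varcomps: dict[str, float]  # random-effect and residual variances
    log_lik: float
    method: str  # "ML" or "REML"
    converged: bool
    n_obs: int
    trait: str
    #: conditional residuals y - X beta - Z u (BLUPs plugged in)
    residuals: np.ndarray

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_names)

    def coef(self, name: str) -> tuple[float, float]:
        """(estimate, standard error) of a named fixed effect."""
        i = self.fixed_names.index(name)
        return float(self.beta[i]), float(self.se[i])


def _design_matrices(
    table: pd.DataFrame,
    fixed_effects: Sequence[str],
    random_effects: Sequence[str],
) -> tuple[np.ndarray, tuple[str, ...], list[np.ndarray], list[str]]:
    """Fixed design matrix and random-effect index columns.

    The genotype reference level is "N2" when present (else the first
    sorted label); the MA reference is "ancestor".
    """
    n = len(table)
    cols = [np.ones(n)]
    names = ["intercept"]
    if "background" in fixed_effects or "interaction" in fixed_effects:
        genos = sorted(table["genotype"].unique())
        ref_geno = "N2" if "N2" in genos else genos[0]
        alt = [g for g in genos if g != ref_geno]
        if len(alt) != 1:
            raise ValueError(f"expected two genotype levels, got {genos}")
        bg = (table["genotype"] == alt[0]).to_numpy(float)
    if "ma" in fixed_effects or "interaction" in fixed_effects:
        ma = (table["ma_status"] == "MA").to_numpy(float)
    if "background" in fixed_effects:
        cols.append(bg)
        names.append("background")
    if "ma" in fixed_effects:
        cols.append(ma)
        names.append("ma")
    if "interaction" in fixed_effects:
        for status in ("ancestor", "MA"):
            for geno_is_alt in (0.0, 1.0):
                present = np.any(
                    ((table["ma_status"] == status).to_numpy())
                    & (bg == geno_is_alt)
                )
                if not present:
                    raise ValueError(
                        f"design cell missing: ma_status={status}, "
                        f"background={'alt' if geno_is_alt else 'ref'}"
                    )
        cols.append(bg * ma)
        names.append("interaction")
    X = np.column_stack(cols)
    Z_idx = []
    re_names = []
    for re in random_effects:
        col = {"line": "line_id", "block": "block_id"}.get(re, re)
        codes, _ = pd.factorize(table[col])
        Z_idx.append(codes)
        re_names.append(re)
    return X, tuple(names), Z_idx, re_names


def _re_crossprods(Z_idx: list[np.ndarray], n: int) -> list[np.ndarray]:
    """Dense Z_j Z_j' membership matrices (1 where rows share a level)."""
    mats = []
    for codes in Z_idx:
        mats.append((codes[:, None] == codes[None, :]).astype(float))
    return mats

def _profiled_nll(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    ZZt: list[np.ndarray],
    reml: bool,
) -> float:
    n, p = X.shape
    V = np.exp(theta[-1]) * np.eye(n)
    for k, G in enumerate(ZZt):
        V += np.exp(theta[k]) * G
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return 1e12
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_X = cho_solve((c, low), X)
    Vi_y = cho_solve((c, low), y)
    XtViX = X.T @ Vi_X
    try:
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    except np.linalg.LinAlgError:
        return 1e12
    r = y - X @ beta
    quad = float(r @ cho_solve((c, low), r))
    ll = -0.5 * (logdet_V + quad + n * _LOG2PI)
    if reml:
        sign, logdet_XtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e12
        ll += -0.5 * logdet_XtViX + 0.5 * p * _LOG2PI
    return -ll


def fit_univariate_lmm(
    table: pd.DataFrame,
    trait: str,
    fixed_effects: Sequence[str] = FIXED_TERMS,
    random_effects: Sequence[str] = ("line", "block"),
    method: str = "ML",
) -> LmmFit:
    """Fit one trait's LMM by profiled (restricted) maximum likelihood.

    Variance components are optimized on the log scale (Nelder-Mead from
    a moment-based start), which keeps them non-negative; effectively
    zero components land at a tiny positive floor.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be ML or REML")
    for re in random_effects:
        col = {"line": "line_id", "block": "block_id"}.get(re, re)
        if table[col].nunique() < 2:
            raise ValueError(f"random effect {re!r} needs >= 2 levels")
    y = table[trait].to_numpy(float)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"missing or non-finite values in trait {trait!r}")
    X, fixed_names, Z_idx, re_names = _design_matrices(
        table, fixed_effects, random_effects
    )
    n = len(y)
    ZZt = _re_crossprods(Z_idx, n)
    vy = max(y.var(ddof=1), 1e-8)
    k = len(ZZt)
    theta0 = np.log(np.full(k + 1, vy / (k + 1)))
    reml = method == "REML"
    res = minimize(
        _profiled_nll,
        theta0,
        args=(y, X, ZZt, reml),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000},
    )
    theta = res.x
    # recompute quantities at the optimum
    V = np.exp(theta[-1]) * np.eye(n)
    for j, G in enumerate(ZZt):
        V += np.exp(theta[j]) * G
    c, low = cho_factor(V, lower=True)
    Vi_X = cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    XtViX_inv = np.linalg.inv(XtViX)
    beta = XtViX_inv @ (Vi_X.T @ y)
    se = np.sqrt(np.diag(XtViX_inv))
    r_marg = y - X @ beta
    Vi_r = cho_solve((c, low), r_marg)
    # conditional residuals: subtract BLUPs u_j = s2_j * Z_j' V^-1 r
    resid = r_marg.copy()
    for j, codes in enumerate(Z_idx):
        u = np.exp(theta[j]) * np.bincount(codes, weights=Vi_r)
        resid -= u[codes]
    varcomps = {name: float(np.exp(theta[j])) for j, name in enumerate(re_names)}
    varcomps["residual"] = float(np.exp(theta[-1]))
    return LmmFit(
        fixed_names=fixed_names,
        beta=beta,
        se=se,
        varcomps=varcomps,
        log_lik=-float(res.fun),
        method=method,
        converged=bool(res.success),
        n_obs=n,
        trait=trait,
        residuals=resid,
    )


def lrt(full: LmmFit, reduced: LmmFit) -> tuple[float, float]:
    """Likelihood-ratio test of nested fixed-effect structures.

    Both fits must be ML on the same data; the statistic 2*(ll_full -
    ll_reduced) is referred to chi-square with df = difference in fixed
    effect count.
    """
    if full.method != "ML" or reduced.method != "ML":
        raise ValueError("LRT on fixed effects requires ML fits")
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits are not on the same data")
    df = full.n_fixed - reduced.n_fixed
    if df < 0 or not set(reduced.fixed_names) <= set(full.fixed_names):
        raise ValueError("reduced model is not nested in the full model")
    stat = max(0.0, 2.0 * (full.log_lik - reduced.log_lik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return stat, p


def levene_test(residuals: np.ndarray, groups: Sequence) -> tuple[float, float]:
    """Classic Levene test (mean-centered absolute deviations)."""
    residuals = np.asarray(residuals, float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("Levene's test needs at least two groups")
    samples = [residuals[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least two observations")
    stat, p = stats.levene(*samples, center="mean")
    return float(stat), float(p)


def mutational_bias_analysis(
    table: pd.DataFrame,
    traits: Sequence[str] = TRAIT_COLS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Background-effect and mutational-bias report over the six traits.

    Per trait: test the background-by-MA interaction first; when it is
    not significant at ``alpha`` it is removed, and the MA (bias) and
    background effects are each tested by LRT against the model without
    the interaction.  Levene's test for variance homogeneity across the
    four genotype-by-MA groups runs on the conditional residuals of the
    final model.
    """
    required = {"genotype", "ma_status", "line_id", "block_id"}
    if not required <= set(table.columns):
        raise ValueError(f"table missing columns: {sorted(required - set(table.columns))}")
    group_labels = (
        table["genotype"].astype(str) + ":" + table["ma_status"].astype(str)
    ).to_numpy()
    if len(np.unique(group_labels)) != 4:
        raise ValueError("all four genotype x MA groups must be present")
    rows = []
    for trait in traits:
        full = fit_univariate_lmm(table, trait, FIXED_TERMS, method="ML")
        noint = fit_univariate_lmm(table, trait, ("background", "ma"), method="ML")
        _, p_int = lrt(full, noint)
        final = full if p_int < alpha else noint
        no_ma = fit_univariate_lmm(table, trait, ("background",), method="ML")
        no_bg = fit_univariate_lmm(table, trait, ("ma",), method="ML")
        _, p_bias = lrt(noint, no_ma)
        _, p_back = lrt(noint, no_bg)
        bg_est, bg_se = noint.coef("background")
        ma_est, ma_se = noint.coef("ma")
        _, levene_p = levene_test(final.residuals, group_labels)
        rows.append(
            {
                "trait": trait,
                "background_effect": bg_est,
                "background_se": bg_se,
                "background_p": p_back,
                "bias_effect": ma_est,
                "bias_se": ma_se,
                "bias_p": p_bias,
                "interaction_p": p_int,
                "interaction_dropped": p_int >= alpha,
                "levene_p": levene_p,
            }
        )
    return pd.DataFrame(rows)


# -- multivariate Gibbs sampler ----------------------------------------------

@dataclass
class MatrixPosterior:
    """Thinned posterior samples of the 6x6 covariance components."""

    line: np.ndarray  # (n_samples, 6, 6)
    block: np.ndarray
    residual: np.ndarray
    n_iter: int
    burnin: int
    thin: int
    traits: tuple[str, ...] = TRAIT_COLS

    @property
    def n_samples(self) -> int:
        return self.line.shape[0]

    def mean_line(self) -> np.ndarray:
        return self.line.mean(axis=0)

    def autocorrelation(self, component: str = "line", lag: int = 1) -> float:
        """Max |lag-k autocorrelation| across the component's 21 distinct
        elements at the thinned lag; the convergence guideline is that it
        stays below 0.05."""
        arr = getattr(self, component)
        iu = np.triu_indices(arr.shape[1])
        series = arr[:, iu[0], iu[1]]
        x = series - series.mean(axis=0)
        denom = np.sum(x * x, axis=0)
        num = np.sum(x[:-lag] * x[lag:], axis=0)
        ac = np.where(denom > 0, num / denom, 0.0)
        return float(np.max(np.abs(ac)))


def _inv_wishart_rvs(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One inverse-Wishart draw by the Bartlett decomposition.

    If S = L L' and A is the Bartlett factor of a Wishart(df, I) draw,
    then B = L A'^{-1} gives B B' ~ IW(df, S).
    """
    d = scale.shape[0]
    L = np.linalg.cholesky(scale)
    A = np.zeros((d, d))
    A[np.tril_indices(d, -1)] = rng.standard_normal(d * (d - 1) // 2)
    np.fill_diagonal(A, np.sqrt(rng.chisquare(df - np.arange(d))))
    Bt = solve_triangular(A, L.T, lower=True)  # B' = A^{-1} L'
    return Bt.T @ Bt


DEFAULT_MCMC = {"n_iter": 500_000, "burnin": 50_000, "thin": 10}
#: Reduced settings for desk-scale runs; labelled scaled-down.
REDUCED_MCMC = {"n_iter": 20_000, "burnin": 2_000, "thin": 10}


def _build_fixed_design(
    table: pd.DataFrame,
    covariates: Sequence[str],
    extra_fixed: Sequence[str],
) -> np.ndarray:
    n = len(table)
    cols = [np.ones(n)]
    for c in covariates:
        x = table[c].to_numpy(float)
        cols.append(x - x.mean())  # mean-centered for interpretability
    for c in extra_fixed:
        dummies = pd.get_dummies(table[c], drop_first=True)
        for name in dummies:
            cols.append(dummies[name].to_numpy(float))
    return np.column_stack(cols)


def fit_multivariate(
    table: pd.DataFrame,
    traits: Sequence[str] = TRAIT_COLS,
    covariates: Sequence[str] = COVARIATE_COLS,
    n_iter: int = 20_000,
    burnin: int = 2_000,
    thin: int = 10,
    prior_df: Optional[float] = None,
    prior_scale: Optional[np.ndarray] = None,
    extra_fixed: Sequence[str] = (),
    rng: Optional[np.random.Generator] = None,
) -> MatrixPosterior:
    """Gibbs sampler for the multivariate line/block/residual model.

    Full conditionals: fixed effects are matrix-normal given the random
    effects and the residual covariance; line and block effect vectors
    are multivariate normal; each covariance matrix is inverse-Wishart
    with prior scale ``diag(phenotypic variances)`` (default) and prior
    degrees of freedom ``n_traits + 1`` (default).  The chain is fully
    reproducible given ``rng``.
    """
    rng = np.random.default_rng() if rng is None else rng
    traits = tuple(traits)
    d = len(traits)
    Y = table[list(traits)].to_numpy(float)
    if np.any(~np.isfinite(Y)):
        raise ValueError("missing or non-finite trait values")
    n = len(Y)
    line_codes, line_levels = pd.factorize(table["line_id"])
    block_codes, block_levels = pd.factorize(table["block_id"])
    n_lines = len(line_levels)
    n_blocks = len(block_levels)
    if n_lines < 5:
        raise ValueError("need at least 5 lines")
    X = _build_fixed_design(table, covariates, extra_fixed)
    p = X.shape[1]

    nu0 = float(d + 1) if prior_df is None else float(prior_df)
    S0 = np.diag(Y.var(axis=0, ddof=1)) if prior_scale is None else np.asarray(prior_scale, float)
    w = np.linalg.eigvalsh((S0 + S0.T) / 2)
    if w.min() <= 0:
        raise ValueError("prior scale must be positive definite")

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    cXtX = cholesky(XtX_inv, lower=True)
    # per-level replicate counts, grouped so equal-count levels share a solve
    line_counts = np.bincount(line_codes, minlength=n_lines)
    block_counts = np.bincount(block_codes, minlength=n_blocks)

    def init_cov() -> np.ndarray:
        return np.diag(Y.var(axis=0, ddof=1)) / 3.0

    Vl, Vb, Ve = init_cov(), init_cov(), init_cov()
    B = XtX_inv @ (X.T @ Y)
    U = np.zeros((n_lines, d))
    W = np.zeros((n_blocks, d))

    n_samples = (n_iter - burnin) // thin
    if n_samples < 1:
        raise ValueError("MCMC settings leave no stored samples")
    out_l = np.empty((n_samples, d, d))
    out_b = np.empty((n_samples, d, d))
    out_e = np.empty((n_samples, d, d))

    def sample_effects(
        resid: np.ndarray,
        codes: np.ndarray,
        counts: np.ndarray,
        Vg: np.ndarray,
        Ve_inv: np.ndarray,
        it: int,
    ) -> np.ndarray:
        n_lev = counts.size
        try:
            Vg_inv = np.linalg.inv(Vg)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular covariance at iteration {it}") from exc
        sums = np.zeros((n_lev, d))
        np.add.at(sums, codes, resid)
        eff = np.empty((n_lev, d))
        for cnt in np.unique(counts):
            sel = counts == cnt
            prec = cnt * Ve_inv + Vg_inv
            try:
                C = np.linalg.inv(prec)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError(
                    f"non-positive-definite conditional scale at iteration {it}"
                ) from exc
            C = (C + C.T) / 2
            mean = sums[sel] @ Ve_inv @ C.T
            cc = np.linalg.cholesky(C)
            eff[sel] = mean + rng.standard_normal((int(sel.sum()), d)) @ cc.T
        return eff

    stored = 0
    for it in range(n_iter):
        Ve_inv = np.linalg.inv(Ve)
        # fixed effects | rest: matrix-normal around the GLS solution
        Yt = Y - U[line_codes] - W[block_codes]
        Bhat = XtX_inv @ (X.T @ Yt)
        cVe = np.linalg.cholesky(Ve)
        B = Bhat + cXtX @ rng.standard_normal((p, d)) @ cVe.T
        XB = X @ B
        # line effects
        U = sample_effects(Y - XB - W[block_codes], line_codes, line_counts, Vl, Ve_inv, it)
        # block effects
        W = sample_effects(Y - XB - U[line_codes], block_codes, block_counts, Vb, Ve_inv, it)
        # covariance matrices: inverse-Wishart full conditionals
        Vl = _inv_wishart_rvs(nu0 + n_lines, S0 + U.T @ U, rng)
        Vb = _inv_wishart_rvs(nu0 + n_blocks, S0 + W.T @ W, rng)
        E = Y - XB - U[line_codes] - W[block_codes]
        Ve = _inv_wishart_rvs(nu0 + n, S0 + E.T @ E, rng)
        if it >= burnin and (it - burnin) % thin == 0 and stored < n_samples:
            out_l[stored] = Vl
            out_b[stored] = Vb
            out_e[stored] = Ve
            stored += 1

    return MatrixPosterior(
        line=out_l[:stored],
        block=out_b[:stored],
        residual=out_e[:stored],
        n_iter=n_iter,
        burnin=burnin,
        thin=thin,
        traits=traits,
    )


def m_matrix(posterior: MatrixPosterior) -> np.ndarray:
    """Posterior samples of M = 0.5 x line covariance (homozygous lines)."""
    return 0.5 * posterior.line


def randomized_null_matrices(
    table: pd.DataFrame,
    n_rand: int,
    rng: np.random.Generator,
    traits: Sequence[str] = TRAIT_COLS,
    covariates: Sequence[str] = COVARIATE_COLS,
    n_iter: int = 2_000,
    burnin: int = 500,
    thin: int = 10,
    **fit_kwargs,
) -> np.ndarray:
    """Null M estimates from label-permutation refits.

    Each replicate independently permutes the line labels and the block
    labels across plate rows (trait values and covariates stay with
    their rows), refits the multivariate model and stores the
    posterior-mean M.  Returns an (n_rand, 6, 6) array from which null
    credible bands are taken.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    out = np.empty((n_rand, len(traits), len(traits)))
    lines = table["line_id"].to_numpy()
    blocks = table["block_id"].to_numpy()
    for r in range(n_rand):
        shuffled = table.copy()
        shuffled["line_id"] = rng.permutation(lines)
        shuffled["block_id"] = rng.permutation(blocks)
        post = fit_multivariate(
            shuffled,
            traits=traits,
            covariates=covariates,
            n_iter=n_iter,
            burnin=burnin,
            thin=thin,
            rng=rng,
            **fit_kwargs,
        )
        out[r] = 0.5 * post.mean_line()
    return out
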