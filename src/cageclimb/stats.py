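"""Mixed-model analysis of cage activity.

The analysis chain mirrors standard practice for repeated-measures home-cage
data: the response (mean distance or mean climbing seconds per cage x day,
in a phase or transition window) is Box-Cox transformed, then modelled with
a linear mixed-effects model with categorical fixed effects (Age, Genotype,
Sex and their interactions), a random intercept per cage, and a random
day-of-recording slope per cage. Group differences are read off as
estimated marginal means (EMMs) with pairwise contrasts, Satterthwaite
degrees of freedom, and Benjamini-Hochberg adjustment across contrasts.

Model fitting is delegated to statsmodels' MixedLM (REML); EMMs,
Satterthwaite df and the BH step-up rule are implemented here.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "LMMSpec",
    "LMMFit",
    "ContrastResult",
    "boxcox",
    "fit_lmm",
    "compare_models",
    "emmeans_contrasts",
    "benjamini_hochberg",
    "significance_stars",
    "transition_analysis",
]


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

def boxcox(x, lmbda: float | str = "mle", allow_shift: bool = False):
    """Box-Cox transform ``(x**lam - 1)/lam`` (``ln x`` at ``lam = 0``).

    ``lmbda="mle"`` maximises the profile log-likelihood over
    ``lam in [-3, 3]`` (bounded Brent search). Inputs must be positive;
    with ``allow_shift`` non-positive data are shifted so the minimum
    maps to a small positive value, with a warning.

    Returns ``(y, lam, shift)``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty input")
    shift = 0.0
    if x.min() <= 0:
        if not allow_shift:
            raise ValueError(
                "Box-Cox requires positive values; pass allow_shift=True to "
                "shift the data"
            )
        span = np.ptp(x)
        shift = -x.min() + (1e-6 * span if span > 0 else 1e-6)
        warnings.warn(f"shifting non-positive data by {shift:g} before Box-Cox",
                      stacklevel=2)
        x = x + shift
    if lmbda == "mle":
        if np.ptp(x) == 0:
            lam = 1.0  # degenerate constant input; likelihood flat
        else:
            res = optimize.minimize_scalar(
                lambda l: -sps.boxcox_llf(l, x), bounds=(-3.0, 3.0), method="bounded"
            )
            lam = float(res.x)
    else:
        lam = float(lmbda)
    y = np.log(x) if lam == 0.0 else (np.power(x, lam) - 1.0) / lam
    return y, lam, shift


# ---------------------------------------------------------------------------
# model specification and fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LMMSpec:
    """Mixed-model specification.

    ``interaction="full"`` fits main effects plus all interactions of the
    factors (needed for estimable cell means in the EMM step);
    ``"three_way_only"`` fits the literal single three-way interaction
    term. The random part is a per-cage intercept plus, when
    ``day_slope``, a per-cage slope in day of recording (numeric 1..3).
    """

    response: str = "mean_activity"
    factors: tuple[str, ...] = ("Age", "Genotype", "Sex")
    interaction: str = "full"
    groups: str = "cage_id"
    day: str = "day_of_recording"
    day_slope: bool = True
    transform: str = "boxcox"  # "boxcox" | "none"

    def fixed_formula(self) -> str:
        terms = [f"C({f})" for f in self.factors]
        if self.interaction == "full":
            rhs = " * ".join(terms)
        elif self.interaction == "three_way_only":
            rhs = ":".join(terms)
        else:
            raise ValueError("interaction must be 'full' or 'three_way_only'")
        return f"__response__ ~ {rhs}"

    def re_formula(self) -> str:
        return f"~{self.day}" if self.day_slope else "~1"


@dataclass
class LMMFit:
    """A fitted mixed model plus the transform that produced its response."""

    result: object  # statsmodels MixedLMResults
    spec: LMMSpec
    data: pd.DataFrame  # with the transformed __response__ column
    lam: float | None
    shift: float
    reml: bool
    singular: bool
    simplified: bool  # True when the day slope was dropped after a singular fit

    @property
    def params(self) -> pd.Series:
        return self.result.fe_params

    @property
    def loglike(self) -> float:
        return float(self.result.llf)

    @property
    def n_fixed(self) -> int:
        return int(self.result.fe_params.size)


def _is_singular(res, tol: float = 1e-6) -> bool:
    cov_re = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
    if cov_re.size == 0:
        return False
    scale = float(res.scale)
    eigs = np.linalg.eigvalsh(cov_re)
    return bool(eigs.min() < tol * max(scale, eigs.max(), 1e-12))


def fit_lmm(
    data: pd.DataFrame,
    spec: LMMSpec = LMMSpec(),
    reml: bool = True,
    simplify_on_singular: bool = True,
) -> LMMFit:
    """Fit the mixed model of ``spec`` to per-cage-per-day summaries.

    The response is Box-Cox transformed first when the spec asks for it
    (lambda by maximum likelihood, per response). REML is the default;
    refit with ``reml=False`` before likelihood-ratio comparisons. A
    singular random-effects fit (a variance component estimated at the
    boundary) is reported via ``singular``; when ``simplify_on_singular``
    and the spec has a day slope, the slope is dropped and the model
    refit, recorded via ``simplified``.
    """
    df = data.copy()
    if df[spec.groups].nunique() < 2:
        raise ValueError("need at least 2 cages")
    missing = [c for c in (spec.response, spec.groups, spec.day, *spec.factors)
               if c not in df.columns]
    if missing:
        raise ValueError(f"data missing column(s): {missing}")
    y = df[spec.response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response is constant: zero residual variance (degenerate)")
    lam = None
    shift = 0.0
    if spec.transform == "boxcox":
        yt, lam, shift = boxcox(y, "mle", allow_shift=True)
    elif spec.transform == "none":
        yt = y
    else:
        raise ValueError("transform must be 'boxcox' or 'none'")
    df["__response__"] = yt

    def _fit(current: LMMSpec):
        best = None
        # try a few optimizers and keep the best REML/ML optimum found
        for method in ("lbfgs", "powell", "cg"):
            model = smf.mixedlm(
                current.fixed_formula(),
                df,
                groups=df[current.groups],
                re_formula=current.re_formula(),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    cand = model.fit(reml=reml, method=method)
                except (np.linalg.LinAlgError, ValueError):
                    continue
            if np.isfinite(cand.llf) and (best is None or cand.llf > best.llf + 1e-8):
                best = cand
        if best is None:
            raise RuntimeError("mixed-model optimisation failed for every optimizer")
        return best

    res = _fit(spec)
    singular = _is_singular(res)
    simplified = False
    if singular and simplify_on_singular and spec.day_slope:
        spec_simple = replace(spec, day_slope=False)
        res2 = _fit(spec_simple)
        res, spec, simplified = res2, spec_simple, True
        singular = _is_singular(res)
    return LMMFit(
        result=res, spec=spec, data=df, lam=lam, shift=shift,
        reml=reml, singular=singular, simplified=simplified,
    )


def compare_models(fits: list[LMMFit]) -> pd.DataFrame:
    """Likelihood-ratio tests between successive nested models.

    Models must be ordered smallest-first, all fitted by ML (not REML);
    each row compares a model to its predecessor with
    ``chi2 = 2 * delta(loglik)`` on ``delta(n_params)`` df.
    """
    if len(fits) < 2:
        raise ValueError("need at least two models to compare")
    for f in fits:
        if f.reml:
            raise ValueError("likelihood-ratio comparison requires ML fits (reml=False)")
    rows = []
    for small, big in zip(fits[:-1], fits[1:]):
        df_diff = big.n_fixed - small.n_fixed + _n_re_params(big) - _n_re_params(small)
        if df_diff < 0:
            raise ValueError("models must be ordered smallest-first (nested)")
        stat = max(0.0, 2.0 * (big.loglike - small.loglike))
        p = 1.0 if df_diff == 0 and stat == 0 else float(sps.chi2.sf(stat, max(df_diff, 1)))
        if df_diff == 0:
            p = 1.0 if stat <= 1e-10 else np.nan
        rows.append(
            {
                "loglik_small": small.loglike,
                "loglik_big": big.loglike,
                "chi2": stat,
                "df": df_diff,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def _n_re_params(fit: LMMFit) -> int:
    k = np.atleast_2d(np.asarray(fit.result.cov_re)).shape[0] if np.asarray(fit.result.cov_re).size else 0
    return k * (k + 1) // 2


# ---------------------------------------------------------------------------
# estimated marginal means and Satterthwaite df
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    """One pairwise EMM contrast."""

    contrast: str
    estimate: float
    se: float
    df: float
    p_value: float
    p_adjusted: float | None = None
    estimable: bool = True


def _blocks(res):
    """Per-group (y, X, Z) blocks from a fitted MixedLM."""
    model = res.model
    groups = np.asarray(model.groups)
    X = np.asarray(model.exog, dtype=float)
    Z = np.asarray(model.exog_re, dtype=float)
    y = np.asarray(model.endog, dtype=float)
    out = []
    for g in pd.unique(groups):
        idx = groups == g
        out.append((y[idx], X[idx], Z[idx]))
    return out


def _pack_theta(cov_re: np.ndarray, scale: float) -> np.ndarray:
    k = cov_re.shape[0]
    tri = cov_re[np.tril_indices(k)]
    return np.concatenate([tri, [scale]])


def _unpack_theta(theta: np.ndarray, k: int):
    G = np.zeros((k, k))
    G[np.tril_indices(k)] = theta[:-1]
    G = G + np.tril(G, -1).T
    return G, float(theta[-1])


def _fixed_cov(theta: np.ndarray, blocks, k: int) -> np.ndarray:
    """(X' V^-1 X)^-1 as a function of the variance parameters."""
    G, scale = _unpack_theta(theta, k)
    p = blocks[0][1].shape[1]
    XtVX = np.zeros((p, p))
    for _, X, Z in blocks:
        V = Z @ G @ Z.T + scale * np.eye(Z.shape[0])
        XtVX += X.T @ np.linalg.solve(V, X)
    return np.linalg.pinv(XtVX)


def _reml_loglik(theta: np.ndarray, blocks, k: int) -> float:
    G, scale = _unpack_theta(theta, k)
    if scale <= 0:
        return -np.inf
    p = blocks[0][1].shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdet = 0.0
    for y, X, Z in blocks:
        V = Z @ G @ Z.T + scale * np.eye(Z.shape[0])
        sign, ld = np.linalg.slogdet(V)
        if sign <= 0:
            return -np.inf
        logdet += ld
        Vi_X = np.linalg.solve(V, X)
        XtVX += X.T @ Vi_X
        XtVy += Vi_X.T @ y
    beta = np.linalg.solve(XtVX, XtVy)
    quad = 0.0
    for y, X, Z in blocks:
        V = Z @ G @ Z.T + scale * np.eye(Z.shape[0])
        r = y - X @ beta
        quad += r @ np.linalg.solve(V, r)
    sign, ld_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    return -0.5 * (logdet + ld_x + quad)


def _satterthwaite_df(res, L: np.ndarray) -> float:
    """Satterthwaite df for the scalar contrast L'beta, via the delta method
    on the REML profile likelihood in the variance parameters."""
    cov_re = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
    k = cov_re.shape[0]
    scale = float(res.scale)
    theta = _pack_theta(cov_re, scale)
    blocks = _blocks(res)

    def f(th):
        return float(L @ _fixed_cov(th, blocks, k) @ L)

    h = 1e-5 + 1e-4 * np.abs(theta)
    m = theta.size
    grad = np.zeros(m)
    for j in range(m):
        e = np.zeros(m)
        e[j] = h[j]
        grad[j] = (f(theta + e) - f(theta - e)) / (2 * h[j])
    # asymptotic covariance of theta-hat from the numerical REML Hessian
    H = np.zeros((m, m))
    ll0 = _reml_loglik(theta, blocks, k)
    if not np.isfinite(ll0):
        return float(res.df_resid)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            lpp = _reml_loglik(theta + ei + ej, blocks, k)
            lpm = _reml_loglik(theta + ei - ej, blocks, k)
            lmp = _reml_loglik(theta - ei + ej, blocks, k)
            lmm = _reml_loglik(theta - ei - ej, blocks, k)
            if not all(np.isfinite(v) for v in (lpp, lpm, lmp, lmm)):
                return float(res.df_resid)
            H[i, j] = H[j, i] = (lpp - lpm - lmp + lmm) / (4 * h[i] * h[j])
    try:
        A = np.linalg.pinv(-H)
    except np.linalg.LinAlgError:
        return float(res.df_resid)
    denom = float(grad @ A @ grad)
    fval = f(theta)
    if denom <= 0 or not np.isfinite(denom) or fval <= 0:
        return float(res.df_resid)
    df = 2.0 * fval**2 / denom
    return float(np.clip(df, 1.0, res.df_resid))


def _reference_grid(fit: LMMFit) -> pd.DataFrame:
    levels = {f: sorted(fit.data[f].astype(str).unique()) for f in fit.spec.factors}
    combos = list(itertools.product(*levels.values()))
    return pd.DataFrame(combos, columns=list(levels))


def _design_rows(fit: LMMFit, grid: pd.DataFrame) -> np.ndarray:
    from patsy import build_design_matrices

    design_info = fit.result.model.data.design_info
    (mat,) = build_design_matrices([design_info], grid)
    return np.asarray(mat)


def emmeans_contrasts(
    fit: LMMFit,
    by: tuple[str, ...] | list[str],
    adjust: str = "bh",
    df_method: str = "satterthwaite",
) -> list[ContrastResult]:
    """Pairwise contrasts of estimated marginal means.

    EMMs are model-predicted cell means on the reference grid (the
    Cartesian product of observed factor levels) averaged with equal
    weights over the levels of factors not in ``by``. Pairwise
    differences carry standard errors from the fixed-effect covariance;
    df by Satterthwaite (default), ``"residual"`` or ``"normal"``.
    Adjusted p-values (Benjamini-Hochberg) span the returned contrast set.
    Combinations whose EMM vector is outside the row space of the design
    (empty cells) are reported non-estimable.
    """
    by = tuple(by)
    unknown = set(by) - set(fit.spec.factors)
    if unknown:
        raise ValueError(f"factor(s) {sorted(unknown)} not in the model")
    grid = _reference_grid(fit)
    rows = _design_rows(fit, grid)
    beta = fit.result.fe_params.to_numpy()
    cov_beta = np.asarray(fit.result.cov_params())[: beta.size, : beta.size]
    X = np.asarray(fit.result.model.exog, dtype=float)

    observed = set(map(tuple, fit.data[list(fit.spec.factors)].astype(str).itertuples(index=False)))
    combos = grid.groupby(list(by), sort=True).indices  # combo -> row indices
    L_by: dict[tuple, np.ndarray | None] = {}
    for combo, idx in combos.items():
        key = combo if isinstance(combo, tuple) else (combo,)
        # estimable only when every averaged cell was actually observed
        cells = grid.iloc[idx]
        all_observed = all(
            tuple(r[f] for f in fit.spec.factors) in observed for _, r in cells.iterrows()
        )
        L = rows[idx].mean(axis=0)
        if not all_observed and not _in_row_space(L, X):
            L_by[key] = None
        else:
            L_by[key] = L

    results: list[ContrastResult] = []
    keys = sorted(L_by)
    for a, b in itertools.combinations(keys, 2):
        label = f"{_fmt(a)} - {_fmt(b)}"
        if L_by[a] is None or L_by[b] is None:
            results.append(ContrastResult(label, np.nan, np.nan, np.nan, np.nan,
                                          estimable=False))
            continue
        L = L_by[a] - L_by[b]
        est = float(L @ beta)
        var = float(L @ cov_beta @ L)
        if not np.isfinite(var) or var < 0:
            # degenerate covariance (boundary/singular fit): no valid SE
            results.append(ContrastResult(label, est, np.nan, np.nan, np.nan,
                                          estimable=False))
            continue
        se = float(np.sqrt(var))
        if df_method == "satterthwaite":
            df = _satterthwaite_df(fit.result, L)
        elif df_method == "residual":
            df = float(fit.result.df_resid)
        elif df_method == "normal":
            df = np.inf
        else:
            raise ValueError("df_method must be satterthwaite, residual or normal")
        if se == 0:
            p = 1.0 if est == 0 else 0.0
        elif np.isinf(df):
            p = float(2 * sps.norm.sf(abs(est / se)))
        else:
            p = float(2 * sps.t.sf(abs(est / se), df))
        results.append(ContrastResult(label, est, se, df, p))
    if adjust == "bh":
        ps = [r.p_value for r in results if r.estimable]
        adj = benjamini_hochberg(ps) if ps else []
        it = iter(adj)
        for r in results:
            if r.estimable:
                r.p_adjusted = float(next(it))
    elif adjust != "none":
        raise ValueError("adjust must be 'bh' or 'none'")
    return results


def _fmt(combo: tuple) -> str:
    return ",".join(str(c) for c in combo)


def _in_row_space(L: np.ndarray, X: np.ndarray, tol: float = 1e-8) -> bool:
    # row space of X is the column space of X.T
    proj = X.T @ np.linalg.pinv(X.T) @ L
    return bool(np.allclose(proj, L, atol=tol * max(1.0, np.abs(L).max())))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values, returned in the original order.

    ``p_adj[(i)] = min_{j >= i} min(1, m * p[(j)] / j)`` over the
    ascending order statistics.
    """
    p = np.asarray(pvals, dtype=np.float64).ravel()
    if p.size == 0:
        return p
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


def significance_stars(p: float) -> str:
    """Figure-legend convention: ns, *, **, ***, ****."""
    if np.isnan(p):
        return "na"
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# end-to-end transition-window analysis
# ---------------------------------------------------------------------------

def transition_analysis(
    binned: pd.DataFrame,
    value: str | None = None,
    factors: tuple[str, ...] = ("Age", "Genotype", "Sex"),
    windows: tuple[str, ...] = ("end_of_dark", "end_of_light"),
    contrast_factor: str = "Genotype",
    transform: str = "boxcox",
    df_method: str = "satterthwaite",
) -> pd.DataFrame:
    """Fit the mixed model per transition window and contrast one factor.

    For each window: average the 5 six-min bins per cage x day, Box-Cox
    the response, fit the full-factorial mixed model with cage intercept
    and day slope, and compute the pairwise EMM contrast of
    ``contrast_factor`` averaged over the other factors. P-values are
    BH-adjusted across all windows' contrasts together. Returns a tidy
    table with window, contrast, estimate, se, df, p, p_adj, stars.
    """
    from .ethogram import window_means

    cage_factors = binned[["cage_id", *factors]].drop_duplicates("cage_id")
    rows = []
    per_window: list[tuple[str, ContrastResult]] = []
    for window in windows:
        wm = window_means(binned, window, value=value)
        data = wm.merge(cage_factors, on="cage_id", validate="many_to_one")
        spec = LMMSpec(response="mean_activity", factors=factors, transform=transform)
        fit = fit_lmm(data, spec)
        contrasts = emmeans_contrasts(
            fit, by=(contrast_factor,), adjust="none", df_method=df_method
        )
        for c in contrasts:
            per_window.append((window, c))
    raw = np.array([c.p_value for _, c in per_window])
    adj = np.full(raw.size, np.nan)
    finite = np.isfinite(raw)
    if finite.any():
        adj[finite] = benjamini_hochberg(raw[finite])
    for (window, c), pa in zip(per_window, adj):
        rows.append(
            {
                "window": window,
                "contrast": c.contrast,
                "estimate": c.estimate,
                "se": c.se,
                "df": c.df,
                "p_value": c.p_value,
                "p_adjusted": float(pa),
                "stars": significance_stars(float(pa)),
            }
        )
    return pd.DataFrame(rows)
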