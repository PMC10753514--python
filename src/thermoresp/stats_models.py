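"""Inferential layer: heteroscedastic mixed models and post hoc tests.

Responses (RMR in W, matched body temperature in degC) are modelled as
linear mixed models with method, ambient temperature and age as factors,
body mass as a covariate, a random intercept per bird, and a distinct
residual SD per measurement method (varIdent-style heteroscedasticity).
The candidate set varies only the method x t_air and method x age
interactions; candidates are fitted by maximum likelihood, compared by
AICc, and the winner is refitted by REML for estimates. Summaries are
Wald chi-square tests per fixed term, estimated marginal means on a
reference grid (equal weights over age, mass at its grand mean), pairwise
contrasts with Bonferroni correction, and a likelihood-ratio test of the
random intercept.

Variability indices are compared with Welch's heteroscedastic ANOVA and
Games-Howell pairwise tests, implemented from the standard formulas.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


class StatsError(ValueError):
    pass


def bonferroni(p, m: int):
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    return np.minimum(1.0, m * np.asarray(p, dtype=float))


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# --- design matrices ---------------------------------------------------------


@dataclass
class Design:
    """Treatment-coded design matrix builder for a fixed set of terms.

    Terms are factor names, covariate names, or ``f1:f2`` factor
    interactions; an intercept is always included. Factor levels are fixed
    at construction so prediction rows for arbitrary grids stay aligned.
    """

    terms: list
    factor_levels: dict              # factor -> ordered levels
    covariates: list
    columns: list = field(default_factory=list)
    term_cols: dict = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, terms: list, factors: list,
                   covariates: list) -> "Design":
        levels = {f: sorted(df[f].unique().tolist()) for f in factors}
        d = cls(terms=list(terms), factor_levels=levels,
                covariates=list(covariates))
        d.columns = ["(Intercept)"]
        d.term_cols = {}
        for term in d.terms:
            cols = []
            if term in levels:
                cols = [f"{term}[{l}]" for l in levels[term][1:]]
            elif term in d.covariates:
                cols = [term]
            elif ":" in term:
                f1, f2 = term.split(":")
                cols = [f"{f1}[{l1}]:{f2}[{l2}]"
                        for l1 in levels[f1][1:] for l2 in levels[f2][1:]]
            else:
                raise StatsError(f"unknown term {term!r}")
            d.term_cols[term] = list(range(len(d.columns),
                                           len(d.columns) + len(cols)))
            d.columns.extend(cols)
        return d

    def row(self, values: dict) -> np.ndarray:
        out = [1.0]
        for term in self.terms:
            if term in self.factor_levels:
                lv = self.factor_levels[term]
                out.extend([1.0 if values[term] == l else 0.0 for l in lv[1:]])
            elif term in self.covariates:
                out.append(float(values[term]))
            else:
                f1, f2 = term.split(":")
                for l1 in self.factor_levels[f1][1:]:
                    for l2 in self.factor_levels[f2][1:]:
                        out.append(float(values[f1] == l1 and values[f2] == l2))
        return np.asarray(out)

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        return np.vstack([self.row(rec) for rec in df.to_dict("records")])


# --- heteroscedastic random-intercept LMM ------------------------------------


@dataclass
class LMMFit:
    """A fitted random-intercept LMM with per-group residual SDs."""

    design: Design
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma_b: float
    resid_sd: dict                   # variance group -> residual SD
    loglik: float                    # of the estimation criterion used
    method: str                      # "ML" or "REML"
    n: int
    k: int                           # parameters counted for AICc
    converged: bool
    data_means: dict                 # covariate grand means (reference grid)
    group_col: str = "bird_id"
    variance_by: str | None = "method"

    @property
    def p(self) -> int:
        return len(self.beta)


def _cluster_stats(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                   vargroup: np.ndarray):
    """Per-cluster sufficient statistics for the profiled likelihood."""
    order = np.argsort(groups, kind="stable")
    X, y, groups, vargroup = X[order], y[order], groups[order], vargroup[order]
    uniq, start = np.unique(groups, return_index=True)
    bounds = np.append(np.sort(start), len(y))
    XtX, Xt1, Xty, yty, y1, ns, vg = [], [], [], [], [], [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        Xi, yi = X[a:b], y[a:b]
        XtX.append(Xi.T @ Xi)
        Xt1.append(Xi.sum(axis=0))
        Xty.append(Xi.T @ yi)
        yty.append(yi @ yi)
        y1.append(yi.sum())
        ns.append(b - a)
        vg.append(vargroup[a])       # one variance group per cluster (one method)
    return (np.array(XtX), np.array(Xt1), np.array(Xty), np.array(yty),
            np.array(y1), np.array(ns, dtype=float), np.array(vg))


def fit_lmm(df: pd.DataFrame, response: str, terms: list, factors: list,
            covariates: list, group: str = "bird_id",
            variance_by: str | None = "method", method: str = "ML",
            random_intercept: bool = True) -> LMMFit:
    """Profiled-likelihood fit of the heteroscedastic random-intercept LMM.

    The GLS coefficients are profiled out; the optimizer runs over log
    variance components (random-intercept SD plus one residual SD per
    level of ``variance_by``). Cluster covariance inverses use the
    Sherman-Morrison identity, so each likelihood evaluation is closed
    form.
    """
    df = df.dropna(subset=[response]).reset_index(drop=True)
    design = Design.from_frame(df, terms, factors, covariates)
    X = design.matrix(df)
    y = df[response].to_numpy(dtype=float)
    n, p = X.shape
    groups = df[group].to_numpy()
    if variance_by is not None:
        vlevels = sorted(df[variance_by].unique().tolist())
        vidx = pd.Categorical(df[variance_by], categories=vlevels).codes
    else:
        vlevels = ["resid"]
        vidx = np.zeros(n, dtype=int)
    XtX, Xt1, Xty, yty, y1, ns, vg = _cluster_stats(X, y, groups,
                                                    np.asarray(vidx))
    nvar = len(vlevels)
    reml = method.upper() == "REML"
    full_rank = np.linalg.matrix_rank(X) == p

    def profile(theta):
        sb2 = np.exp(2 * theta[0]) if random_intercept else 0.0
        off = 1 if random_intercept else 0
        s2 = np.exp(2 * theta[off:off + nvar])[vg]        # per cluster
        c = sb2 / (s2 + ns * sb2)
        w = 1.0 / s2
        XtWX = np.einsum("i,ijk->jk", w, XtX) \
            - np.einsum("i,ij,ik->jk", w * c, Xt1, Xt1)
        XtWy = np.einsum("i,ij->j", w, Xty) - (w * c * y1) @ Xt1
        ytWy = float(np.sum(w * yty) - np.sum(w * c * y1**2))
        logdet = float(np.sum(ns * np.log(s2) + np.log1p(ns * sb2 / s2)))
        if full_rank:
            beta = np.linalg.solve(XtWX, XtWy)
        else:
            beta = np.linalg.pinv(XtWX) @ XtWy   # aliased terms: flagged below

        quad = ytWy - beta @ XtWy
        if reml:
            sign, ld_x = np.linalg.slogdet(XtWX)
            ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdet + ld_x + quad)
        else:
            ll = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
        return ll, beta, XtWX

    def objective(theta):
        if np.any(np.abs(theta) > 23):    # keep variances representable
            return 1e12
        try:
            ll, _, _ = profile(theta)
        except np.linalg.LinAlgError:
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    if not full_rank:
        # aliased fixed effects (e.g. an empty factor cell): report the
        # candidate as non-converged so model selection can skip it
        import warnings as _warnings
        _warnings.warn("rank-deficient fixed-effect design; candidate flagged "
                       "as non-converged", stacklevel=2)
        beta = np.linalg.pinv(X) @ y
        return LMMFit(design=design, beta=beta,
                      cov_beta=np.full((p, p), np.nan), sigma_b=0.0,
                      resid_sd={lv: np.nan for lv in vlevels},
                      loglik=-np.inf, method=method.upper(), n=n,
                      k=p + (1 if random_intercept else 0) + nvar,
                      converged=False,
                      data_means={c: float(df[c].mean()) for c in covariates},
                      group_col=group, variance_by=variance_by)

    s0 = max(np.std(y - X @ np.linalg.lstsq(X, y, rcond=None)[0], ddof=p), 1e-6)
    theta0 = ([np.log(0.5 * s0)] if random_intercept else []) \
        + [np.log(s0)] * nvar
    res = optimize.minimize(objective, np.asarray(theta0), method="Nelder-Mead",
                            options={"maxiter": 6000, "maxfev": 12000,
                                     "xatol": 1e-6, "fatol": 1e-9})
    converged = bool(res.success)
    if not converged:
        # restart from the terminal simplex; a negligible further gain means
        # the first run had already reached a stationary point
        res2 = optimize.minimize(objective, res.x, method="Nelder-Mead",
                                 options={"maxiter": 6000, "maxfev": 12000,
                                          "xatol": 1e-6, "fatol": 1e-9})
        if res2.fun <= res.fun:
            converged = bool(res2.success) or (res.fun - res2.fun) < 1e-6
            res = res2
    ll, beta, XtWX = profile(res.x)
    off = 1 if random_intercept else 0
    fit = LMMFit(
        design=design, beta=beta, cov_beta=np.linalg.inv(XtWX),
        sigma_b=float(np.exp(res.x[0])) if random_intercept else 0.0,
        resid_sd={lv: float(np.exp(res.x[off + i]))
                  for i, lv in enumerate(vlevels)},
        loglik=float(ll), method=method.upper(), n=n,
        k=p + off + nvar, converged=converged,
        data_means={c: float(df[c].mean()) for c in covariates},
        group_col=group, variance_by=variance_by)
    return fit


# --- model selection ---------------------------------------------------------

BASE_TERMS = ["method", "t_air", "age", "mass"]
CANDIDATE_INTERACTIONS = ([], ["method:t_air"], ["method:age"],
                          ["method:t_air", "method:age"])


def fit_candidates_and_select(df: pd.DataFrame, response: str,
                              base_terms: list = BASE_TERMS,
                              candidates=CANDIDATE_INTERACTIONS,
                              factors=("method", "t_air", "age"),
                              covariates=("mass",),
                              variance_by: str | None = "method"
                              ) -> tuple[LMMFit, pd.DataFrame]:
    """ML-fit the interaction candidate set, select by AICc, refit by REML.

    All main effects are retained in every candidate. Non-converged
    candidates are excluded from selection with a flag in the AICc table.
    Returns the REML refit of the winner and the AICc table sorted by
    AICc (with a ``delta_aicc`` column).
    """
    rows, fits = [], {}
    for extra in candidates:
        terms = list(base_terms) + list(extra)
        name = " + ".join(extra) if extra else "no interaction"
        fit = fit_lmm(df, response, terms, list(factors), list(covariates),
                      variance_by=variance_by, method="ML")
        fits[name] = (fit, terms)
        rows.append({"model": name, "k": fit.k, "loglik": fit.loglik,
                     "aicc": aicc(fit.loglik, fit.k, fit.n),
                     "converged": fit.converged})
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if len(ok) == 0:
        raise StatsError("no candidate model converged")
    best_name = ok.loc[ok["aicc"].idxmin(), "model"]
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    table = table.sort_values("aicc").reset_index(drop=True)
    _, best_terms = fits[best_name]
    final = fit_lmm(df, response, best_terms, list(factors), list(covariates),
                    variance_by=variance_by, method="REML")
    return final, table


# --- inference on a fitted model ---------------------------------------------


def wald_chisq(fit: LMMFit) -> pd.DataFrame:
    """Wald chi-square test of each fixed term's coefficient block."""
    rows = []
    for term, cols in fit.design.term_cols.items():
        if not cols:
            continue
        b = fit.beta[cols]
        C = fit.cov_beta[np.ix_(cols, cols)]
        chi2 = float(b @ np.linalg.solve(C, b))
        rows.append({"term": term, "chisq": chi2, "df": len(cols),
                     "p": float(stats.chi2.sf(chi2, len(cols)))})
    return pd.DataFrame(rows)


def _grid_rows(fit: LMMFit, specs: list) -> pd.DataFrame:
    """Reference-grid combinations for the requested factors."""
    levels = [fit.design.factor_levels[f] for f in specs]
    return pd.DataFrame([dict(zip(specs, combo))
                         for combo in itertools.product(*levels)])


def _emmean_vector(fit: LMMFit, fixed: dict) -> np.ndarray:
    """L-vector for one grid cell: average over unfixed factors, grand-mean
    covariates."""
    free = [f for f in fit.design.factor_levels if f not in fixed]
    combos = itertools.product(*[fit.design.factor_levels[f] for f in free])
    rows = []
    for combo in combos:
        values = dict(fixed)
        values.update(dict(zip(free, combo)))
        values.update(fit.data_means)
        rows.append(fit.design.row(values))
    return np.mean(rows, axis=0)


def emmeans(fit: LMMFit, specs: list) -> pd.DataFrame:
    """Estimated marginal means over a reference grid.

    Averages with equal weight over factor levels not named in ``specs``
    and fixes covariates at their grand means.
    """
    grid = _grid_rows(fit, specs)
    out = []
    for rec in grid.to_dict("records"):
        L = _emmean_vector(fit, rec)
        est = float(L @ fit.beta)
        se = float(np.sqrt(L @ fit.cov_beta @ L))
        out.append({**rec, "emmean": est, "se": se})
    return pd.DataFrame(out)


def emmeans_pairwise(fit: LMMFit, factor: str = "method",
                     by: str | None = None) -> pd.DataFrame:
    """All pairwise contrasts of a factor's marginal means.

    With ``by`` set, contrasts are computed within each level of that
    factor and the Bonferroni family is the full table (pairs x by-levels).
    z statistics use the normal approximation.
    """
    by_levels = fit.design.factor_levels[by] if by else [None]
    levels = fit.design.factor_levels[factor]
    rows = []
    for bl in by_levels:
        vecs = {}
        for lv in levels:
            fixed = {factor: lv}
            if by:
                fixed[by] = bl
            vecs[lv] = _emmean_vector(fit, fixed)
        est_tol = 1e-8 * max(1.0, float(np.abs(fit.beta).max()))
        for l1, l2 in itertools.combinations(levels, 2):
            L = vecs[l1] - vecs[l2]
            est = float(L @ fit.beta)
            se = float(np.sqrt(max(L @ fit.cov_beta @ L, 0.0)))
            z = 0.0 if abs(est) < est_tol else est / se
            rows.append({**({by: bl} if by else {}),
                         "contrast": f"{l1} - {l2}", "estimate": est,
                         "se": se, "z": z,
                         "p": float(2 * stats.norm.sf(abs(z)))})
    table = pd.DataFrame(rows)
    table["p_adj"] = bonferroni(table["p"], len(table))
    return table


def lrt_random_intercept(df: pd.DataFrame, response: str, terms: list,
                         factors: list, covariates: list,
                         variance_by: str | None = "method") -> dict:
    """Likelihood-ratio test of the bird random intercept (ML fits).

    The chi-square df=1 reference is conservative for a variance tested on
    its boundary.
    """
    full = fit_lmm(df, response, terms, factors, covariates,
                   variance_by=variance_by, method="ML", random_intercept=True)
    null = fit_lmm(df, response, terms, factors, covariates,
                   variance_by=variance_by, method="ML", random_intercept=False)
    stat = max(0.0, 2 * (full.loglik - null.loglik))
    return {"lrt": stat, "df": 1, "p": float(stats.chi2.sf(stat, 1))}


# --- heteroscedastic one-way comparisons -------------------------------------


def welch_anova(groups: dict) -> dict:
    """Welch's heteroscedastic one-way ANOVA from the standard formulas.

    ``groups`` maps label -> 1-D array. Weights are n_i / s_i^2; the
    denominator df is Satterthwaite-type.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise StatsError("Welch ANOVA needs >= 2 groups")
    ns = np.array([len(np.asarray(groups[l])) for l in labels], dtype=float)
    if np.any(ns < 2):
        raise StatsError("each group needs n >= 2")
    means = np.array([np.mean(groups[l]) for l in labels])
    variances = np.array([np.var(groups[l], ddof=1) for l in labels])
    if np.any(variances <= 0):
        raise StatsError("zero within-group variance")
    k = len(labels)
    w = ns / variances
    W = w.sum()
    mw = (w * means).sum() / W
    a = (w * (means - mw) ** 2).sum() / (k - 1)
    lam = np.sum((1 - w / W) ** 2 / (ns - 1))
    b = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    F = a / b
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * lam)
    return {"F": float(F), "df1": float(df1), "df2": float(df2),
            "p": float(stats.f.sf(F, df1, df2))}


def games_howell(groups: dict) -> pd.DataFrame:
    """Games-Howell pairwise comparisons for unequal variances and n.

    For each pair, q = |mean_i - mean_j| / sqrt((s_i^2/n_i + s_j^2/n_j)/2)
    is referred to the studentized range distribution with k groups and
    Welch-Satterthwaite degrees of freedom.
    """
    labels = list(groups)
    k = len(labels)
    if k < 2:
        raise StatsError("Games-Howell needs >= 2 groups")
    stats_by = {}
    for l in labels:
        x = np.asarray(groups[l], dtype=float)
        if len(x) < 2:
            raise StatsError("each group needs n >= 2")
        v = np.var(x, ddof=1)
        if v <= 0:
            raise StatsError("zero within-group variance")
        stats_by[l] = (len(x), np.mean(x), v)
    rows = []
    for l1, l2 in itertools.combinations(labels, 2):
        n1, m1, v1 = stats_by[l1]
        n2, m2, v2 = stats_by[l2]
        se2 = v1 / n1 + v2 / n2
        q = abs(m1 - m2) / np.sqrt(se2 / 2.0)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = float(stats.studentized_range.sf(q, k, df))
        rows.append({"contrast": f"{l1} - {l2}", "estimate": m1 - m2,
                     "se": float(np.sqrt(se2)), "q": float(q),
                     "df": float(df), "p": min(1.0, p)})
    return pd.DataFrame(rows)


# --- design balance ----------------------------------------------------------


def balance_checks(birds: pd.DataFrame) -> dict:
    """Group-balance checks mirroring the study's sample-size bookkeeping.

    One-way ANOVA of each mass variable across methods and Pearson
    chi-squared tests of the age x method and sex x method tables.
    """
    import warnings as _warnings

    out = {}
    for var in ("mass_capture", "mass_pre", "mass_post"):
        if var not in birds.columns:
            continue
        arrays = [g[var].to_numpy(dtype=float)
                  for _, g in birds.groupby("method")]
        grand = np.concatenate(arrays).mean()
        ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
        if ssb == 0:                       # identical group means: F is 0
            F, p = 0.0, 1.0
        else:
            F, p = stats.f_oneway(*arrays)
        out[var] = {"F": float(F), "df1": len(arrays) - 1,
                    "df2": len(birds) - len(arrays), "p": float(p)}
    for var in ("age", "sex"):
        tab = pd.crosstab(birds[var], birds["method"])
        if (tab.to_numpy() == 0).any():
            _warnings.warn(f"empty cells in {var} x method table",
                           stacklevel=2)
        chi2, p, dof, _ = stats.chi2_contingency(tab, correction=False)
        out[var] = {"chisq": float(chi2), "df": int(dof), "p": float(p)}
    return out
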