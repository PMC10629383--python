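"""Segment-level count models.

Tweedie (compound Poisson-gamma) quasi-likelihood regression with log link,
log-area offsets and optional flight / transect-in-flight random intercepts
(penalised quasi-likelihood), extended-quasi-likelihood profiling of the
variance power, zero-truncated Poisson regression for group sizes, Wald
backwards selection respecting marginality, and exponentiated effect ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import norm


@dataclass
class Term:
    """One model term: a name and the design columns it owns."""

    name: str
    columns: list[int]
    is_interaction: bool = False
    parents: tuple[str, ...] = ()


@dataclass
class CountModelFit:
    response: str
    family: str
    terms: list[Term]
    names: list[str]
    beta: np.ndarray
    vcov: np.ndarray
    tweedie_power: float | None
    dispersion: float
    var_flight: float
    var_transect: float
    logLik: float | None
    deviance: float
    n: int
    converged: bool
    offset_col: str | None = None
    wald: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0, None))


# ---------------------------------------------------------------------------
# design construction


def build_design(
    data: pd.DataFrame,
    terms: list[str],
    categorical: tuple[str, ...] = ("platform", "visibility", "cloud"),
) -> tuple[np.ndarray, list[str], list[Term]]:
    """Intercept + main effects + `a:b` interactions with treatment coding."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    term_list = [Term("(Intercept)", [0])]

    def encode(var: str) -> tuple[list[np.ndarray], list[str]]:
        if var in categorical or data[var].dtype == object:
            levels = sorted(pd.unique(data[var]))
            vecs = [(data[var] == lev).to_numpy(dtype=float) for lev in levels[1:]]
            labels = [f"{var}[{lev}]" for lev in levels[1:]]
            return vecs, labels
        return [data[var].to_numpy(dtype=float)], [var]

    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            va, la = encode(a)
            vb, lb = encode(b)
            idx = []
            for xa, na_ in zip(va, la):
                for xb, nb_ in zip(vb, lb):
                    idx.append(len(cols))
                    cols.append(xa * xb)
                    names.append(f"{na_}:{nb_}")
            term_list.append(Term(term, idx, is_interaction=True, parents=(a, b)))
        else:
            vecs, labels = encode(term)
            idx = []
            for v, lab in zip(vecs, labels):
                idx.append(len(cols))
                cols.append(v)
                names.append(lab)
            term_list.append(Term(term, idx))
    return np.column_stack(cols), names, term_list


def _random_effect_design(data: pd.DataFrame) -> tuple[np.ndarray, int, int]:
    """Indicator matrix [flight blocks | transect-in-flight blocks]."""
    flights = sorted(pd.unique(data.flight_id))
    pairs = sorted({(f, t) for f, t in zip(data.flight_id, data.transect_id)})
    Zf = np.column_stack(
        [(data.flight_id == f).to_numpy(dtype=float) for f in flights]
    )
    Zt = np.column_stack(
        [
            ((data.flight_id == f) & (data.transect_id == t)).to_numpy(dtype=float)
            for f, t in pairs
        ]
    )
    return np.hstack([Zf, Zt]), len(flights), len(pairs)


# ---------------------------------------------------------------------------
# Tweedie deviance / EQL


def tweedie_unit_deviance(y: np.ndarray, mu: np.ndarray, power: float) -> np.ndarray:
    """2 [ y (y^(1-p) - mu^(1-p))/(1-p) - (y^(2-p) - mu^(2-p))/(2-p) ] for 1<p<2."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    p = power
    term1 = np.where(
        y > 0, y * (np.power(np.maximum(y, 1e-300), 1 - p) - mu ** (1 - p)) / (1 - p), 0.0
    )
    # y^(2-p) is 0 at y=0 since 2-p>0
    term2 = (np.power(y, 2 - p) - mu ** (2 - p)) / (2 - p)
    return 2.0 * (term1 - term2)


def fit_tweedie(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    power: float = 1.5,
    offset_col: str | None = "area",
    random_effects: bool = False,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> CountModelFit:
    """Quasi-likelihood IRLS with V(mu) = mu^power and log link.

    With `random_effects`, flight and transect-in-flight intercepts are
    estimated by penalised quasi-likelihood: Henderson's mixed-model
    equations on the IRLS working response, with EM updates for the two
    variance components. Dispersion is the Pearson statistic over residual
    degrees of freedom.
    """
    if not 1.0 < power < 2.0:
        raise ValueError("tweedie power must be in (1, 2)")
    y = data[response].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError("response must be >= 0")
    X, names, term_list = build_design(data, terms)
    n, k = X.shape
    offset = (
        np.log(data[offset_col].to_numpy(dtype=float))
        if offset_col is not None
        else np.zeros(n)
    )
    if offset_col is not None and np.any(data[offset_col].to_numpy(dtype=float) <= 0):
        raise ValueError("offset areas must be > 0")

    all_zero = bool(np.all(y == 0))
    if all_zero:
        warnings.warn("all-zero response; intercept at boundary", stacklevel=2)

    Z, n_f, n_t = (None, 0, 0)
    if random_effects:
        Z, n_f, n_t = _random_effect_design(data)

    beta = np.zeros(k)
    mu = np.maximum(y, np.mean(y) if y.mean() > 0 else 0.1) + 0.1
    eta = np.log(mu) - offset
    u = np.zeros(Z.shape[1]) if Z is not None else None
    sig_f, sig_t = 0.1, 0.1
    converged = False
    for it in range(max_iter):
        mu = np.exp(eta + offset)
        mu = np.clip(mu, 1e-10, 1e10)
        z = eta + (y - mu) / mu  # working response (link scale, offset removed)
        w = mu ** (2.0 - power)  # 1/var of working response (up to phi)
        beta_old = beta.copy()
        if Z is None:
            WX = X * w[:, None]
            beta = np.linalg.solve(X.T @ WX, WX.T @ z)
            eta_new = X @ beta
        else:
            # Henderson MME with D = diag(sig_f I, sig_t I)
            d_inv = np.concatenate(
                [np.full(n_f, 1.0 / max(sig_f, 1e-8)), np.full(n_t, 1.0 / max(sig_t, 1e-8))]
            )
            WX = X * w[:, None]
            WZ = Z * w[:, None]
            A = np.block(
                [
                    [X.T @ WX, X.T @ WZ],
                    [WZ.T @ X, Z.T @ WZ + np.diag(d_inv)],
                ]
            )
            rhs = np.concatenate([WX.T @ z, WZ.T @ z])
            sol = np.linalg.solve(A, rhs)
            beta, u = sol[:k], sol[k:]
            eta_new = X @ beta + Z @ u
            # EM variance-component updates using the MME inverse blocks
            Ainv = np.linalg.inv(A)
            Cuu = Ainv[k:, k:]
            uf, ut = u[:n_f], u[n_f:]
            tf = np.trace(Cuu[:n_f, :n_f])
            tt = np.trace(Cuu[n_f:, n_f:])
            sig_f = float((uf @ uf + tf) / n_f)
            sig_t = float((ut @ ut + tt) / n_t)
            # clamp vanishing components: EM shrinks them geometrically and
            # would otherwise drift beta below tolerance for hundreds of iters
            if sig_f < 1e-6:
                sig_f = 0.0
            if sig_t < 1e-6:
                sig_t = 0.0
        eta = eta_new
        beta_change = np.max(np.abs(beta - beta_old)) / max(np.max(np.abs(beta)), 1.0)
        if it > 0 and beta_change < tol:
            converged = True
            break
        # EM updates of near-zero variance components shrink geometrically and
        # keep nudging beta below any practical resolution; accept that state
        if Z is not None and it > 20 and beta_change < 1e-6:
            converged = True
            break
    if not converged and not all_zero:
        warnings.warn("Tweedie IRLS did not fully converge", stacklevel=2)

    mu = np.clip(np.exp(eta + offset), 1e-10, 1e10)
    pearson = float(np.sum((y - mu) ** 2 / mu**power))
    dof = max(n - k - (1 if random_effects else 0), 1)
    phi = pearson / dof
    w = mu ** (2.0 - power)
    if Z is None:
        vcov = phi * np.linalg.inv(X.T @ (X * w[:, None]))
    else:
        d_inv = np.concatenate(
            [np.full(n_f, 1.0 / max(sig_f, 1e-8)), np.full(n_t, 1.0 / max(sig_t, 1e-8))]
        )
        WX = X * w[:, None]
        WZ = Z * w[:, None]
        A = np.block(
            [[X.T @ WX, X.T @ WZ], [WZ.T @ X, Z.T @ WZ + phi * np.diag(d_inv)]]
        )
        vcov = phi * np.linalg.inv(A)[:k, :k]
    dev = float(np.sum(tweedie_unit_deviance(y, mu, power)))
    fit = CountModelFit(
        response=response,
        family="tweedie",
        terms=term_list,
        names=names,
        beta=beta,
        vcov=vcov,
        tweedie_power=power,
        dispersion=phi,
        var_flight=sig_f if random_effects else 0.0,
        var_transect=sig_t if random_effects else 0.0,
        logLik=None,
        deviance=dev,
        n=n,
        converged=converged or all_zero,
        offset_col=offset_col,
    )
    fit.wald = wald_table(fit)
    return fit


def extended_quasi_loglik(
    y: np.ndarray, mu: np.ndarray, power: float, phi: float
) -> float:
    """Nelder-Pregibon EQL: -1/2 sum[ d_i/phi + log(2 pi phi V(y_i*)) ],
    with y* = max(y, 1/6) in the variance term to handle zeros."""
    d = tweedie_unit_deviance(y, mu, power)
    y_star = np.maximum(y, 1.0 / 6.0)
    return float(-0.5 * np.sum(d / phi + np.log(2 * np.pi * phi * y_star**power)))


def tweedie_series_loglik(
    y: np.ndarray, mu: np.ndarray, power: float, phi: float, jmax: int = 150
) -> float:
    """Exact compound Poisson-gamma log-likelihood via the series expansion.

    f(0) = exp(-lambda); for y > 0 the density is the Poisson-mixture of
    gamma densities summed over the latent event count j (truncated at jmax,
    combined with logsumexp for stability).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    lam = mu ** (2 - power) / (phi * (2 - power))
    alpha = (2 - power) / (power - 1)
    gam = phi * (power - 1) * mu ** (power - 1)
    zero = y <= 0
    ll = float(-lam[zero].sum())
    if np.any(~zero):
        yp, lp, gp = y[~zero], lam[~zero], gam[~zero]
        j = np.arange(1, jmax + 1)[:, None]
        terms = (
            -lp
            + j * np.log(lp)
            - gammaln(j + 1)
            + (j * alpha - 1) * np.log(yp)
            - yp / gp
            - gammaln(j * alpha)
            - j * alpha * np.log(gp)
        )
        ll += float(logsumexp(terms, axis=0).sum())
    return ll


def profile_power(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    grid: np.ndarray | None = None,
    offset_col: str | None = "area",
    random_effects: bool = False,
    method: str = "series",
) -> tuple[float, pd.DataFrame]:
    """Variance power maximising a profile criterion over a grid.

    method='series' (default) profiles the exact compound Poisson-gamma
    log-likelihood, maximising over the dispersion at each candidate power;
    method='eql' uses the Nelder-Pregibon extended quasi-likelihood with the
    Pearson dispersion plug-in (kept for comparison — it is biased toward
    low powers when zeros are frequent).
    """
    if grid is None:
        grid = np.round(np.arange(1.1, 1.9001, 0.05), 4)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid <= 1.0) | (grid >= 2.0)):
        raise ValueError("power grid must lie inside (1, 2)")
    y = data[response].to_numpy(dtype=float)
    offset = (
        np.log(data[offset_col].to_numpy(dtype=float))
        if offset_col
        else np.zeros(len(data))
    )
    rows = []
    for p in grid:
        f = fit_tweedie(
            data, response, terms, power=float(p), offset_col=offset_col,
            random_effects=random_effects,
        )
        X, _, _ = build_design(data, terms)
        # fixed-effects mean; BLUP shifts are second-order for the profile
        mu = np.exp(X @ f.beta + offset)
        if method == "series":
            from scipy.optimize import minimize_scalar

            res = minimize_scalar(
                lambda lphi, p=p, mu=mu: -tweedie_series_loglik(y, mu, p, math.exp(lphi)),
                bounds=(-6.0, 4.0),
                method="bounded",
            )
            rows.append(dict(power=float(p), criterion=-float(res.fun)))
        elif method == "eql":
            rows.append(
                dict(
                    power=float(p),
                    criterion=extended_quasi_loglik(y, mu, p, f.dispersion),
                )
            )
        else:
            raise ValueError("method must be 'series' or 'eql'")
    prof = pd.DataFrame(rows)
    best = float(prof.loc[prof.criterion.idxmax(), "power"])
    if best in (float(grid[0]), float(grid[-1])):
        warnings.warn(
            f"profile optimum {best} at the grid edge; consider widening the grid",
            stacklevel=2,
        )
    return best, prof


# ---------------------------------------------------------------------------
# zero-truncated Poisson


def ztp_loglik(y: np.ndarray, lam: np.ndarray) -> float:
    """log prod lam^y e^-lam / (y! (1 - e^-lam))."""
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    return float(
        np.sum(y * np.log(lam) - lam - gammaln(y + 1) - np.log1p(-np.exp(-lam)))
    )


def fit_ztp(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CountModelFit:
    """Zero-truncated Poisson ML with log link on the untruncated rate.

    Newton-Raphson on beta; E[Y] = lam / (1 - e^-lam). All-ones responses
    push lambda to the lower boundary and are flagged.
    """
    y = data[response].to_numpy(dtype=float)
    if np.any(y < 1):
        raise ValueError("zero-truncated response must be >= 1")
    X, names, term_list = build_design(data, terms)
    n, k = X.shape
    boundary = bool(np.all(y == 1))
    if boundary:
        warnings.warn("all group sizes are 1; lambda at lower boundary", stacklevel=2)

    beta = np.zeros(k)
    beta[0] = math.log(max(y.mean() - 0.9, 0.05))
    converged = False
    for _ in range(max_iter):
        lam = np.exp(np.clip(X @ beta, -30, 30))
        e = np.exp(-lam)
        mean_y = lam / (1 - e)
        # score and information wrt eta = log lam
        score_eta = y - lam - lam * e / (1 - e)  # d logL / d eta_i
        # Fisher info: Var(Y) for ZTP = mean_y (1 - e lam/(1-e)) ... use observed
        info_eta = lam + lam * e * (1 - lam - e) / (1 - e) ** 2
        info_eta = np.maximum(info_eta, 1e-10)
        g = X.T @ score_eta
        H = X.T @ (X * info_eta[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    lam = np.exp(np.clip(X @ beta, -30, 30))
    ll = ztp_loglik(y, lam)
    try:
        info_eta = lam + lam * np.exp(-lam) * (1 - lam - np.exp(-lam)) / (
            1 - np.exp(-lam)
        ) ** 2
        vcov = np.linalg.inv(X.T @ (X * np.maximum(info_eta, 1e-10)[:, None]))
    except np.linalg.LinAlgError:
        vcov = np.full((k, k), np.nan)
    fit = CountModelFit(
        response=response,
        family="zt_poisson",
        terms=term_list,
        names=names,
        beta=beta,
        vcov=vcov,
        tweedie_power=None,
        dispersion=1.0,
        var_flight=0.0,
        var_transect=0.0,
        logLik=ll,
        deviance=-2 * ll,
        n=n,
        converged=converged or boundary,
        extras={"boundary": boundary},
    )
    fit.wald = wald_table(fit)
    return fit


# ---------------------------------------------------------------------------
# inference helpers


def wald_table(fit: CountModelFit) -> pd.DataFrame:
    """Per-term Wald chi-square tests (joint over the term's columns)."""
    rows = []
    for term in fit.terms:
        if term.name == "(Intercept)":
            continue
        idx = term.columns
        b = fit.beta[idx]
        V = fit.vcov[np.ix_(idx, idx)]
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            stat = float("nan")
        df = len(idx)
        from scipy.stats import chi2

        pval = float(chi2.sf(stat, df)) if np.isfinite(stat) else float("nan")
        rows.append(
            dict(term=term.name, df=df, wald=stat, p_value=pval,
                 interaction=term.is_interaction)
        )
    return pd.DataFrame(rows)


def backward_select(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    fitter,
    alpha: float = 0.05,
    **fit_kwargs,
) -> tuple[CountModelFit, list[str]]:
    """Drop the least-significant removable term until all are significant.

    A main effect is removable only when no retained interaction contains it
    (marginality). `fitter` is fit_tweedie or fit_ztp; the selection path of
    removed terms is returned alongside the final fit.
    """
    current = list(terms)
    path: list[str] = []
    while True:
        fit = fitter(data, response, current, **fit_kwargs)
        tab = fit.wald
        if tab is None or tab.empty:
            return fit, path
        protected = set()
        for t in current:
            if ":" in t:
                protected.update(t.split(":"))
        removable = tab[~tab.term.isin(protected)]
        candidates = removable[removable.p_value > alpha]
        if candidates.empty:
            return fit, path
        worst = candidates.sort_values("p_value", ascending=False).iloc[0]
        current = [t for t in current if t != worst.term]
        path.append(str(worst.term))


def effect_ratio(fit: CountModelFit, coefficient: str) -> dict:
    """exp(beta) with 95% Wald CI, as percentages of the reference level."""
    if coefficient not in fit.names:
        raise KeyError(f"coefficient {coefficient!r} not in model ({fit.names})")
    i = fit.names.index(coefficient)
    b = fit.beta[i]
    se = fit.se[i]
    z = norm.ppf(0.975)
    return dict(
        coefficient=coefficient,
        ratio_pct=100.0 * math.exp(b),
        lo_pct=100.0 * math.exp(b - z * se),
        hi_pct=100.0 * math.exp(b + z * se),
    )


# ---------------------------------------------------------------------------
# compound Poisson-gamma sampler (simulation oracle for the Tweedie family)


def rtweedie(
    rng: np.random.Generator, mu: np.ndarray, power: float, phi: float
) -> np.ndarray:
    """Compound Poisson-gamma draws with mean mu, Var = phi mu^power."""
    mu = np.asarray(mu, dtype=float)
    if not 1.0 < power < 2.0:
        raise ValueError("power must be in (1, 2)")
    lam = mu ** (2 - power) / (phi * (2 - power))
    alpha = (2 - power) / (power - 1)
    gamma_scale = phi * (power - 1) * mu ** (power - 1)
    N = rng.poisson(lam)
    out = np.zeros_like(mu)
    pos = N > 0
    out[pos] = rng.gamma(shape=N[pos] * alpha, scale=gamma_scale[pos])
    return out


def fit_to_dict(fit: CountModelFit) -> dict:
    return dict(
        response=fit.response,
        family=fit.family,
        power=fit.tweedie_power,
        dispersion=fit.dispersion,
        var_flight=fit.var_flight,
        var_transect=fit.var_transect,
        n=fit.n,
        converged=fit.converged,
        coefficients=[
            dict(name=nm, estimate=float(b), se=float(s))
            for nm, b, s in zip(fit.names, fit.beta, fit.se)
        ],
        wald=fit.wald.to_dict(orient="records") if fit.wald is not None else [],
    )
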