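"""Huggins closed-capture perception-bias estimation.

The likelihood conditions on detection by at least one occasion, so the
number of missed groups drops out and per-occasion detection probabilities
(optionally covariate-dependent, logit link) can be estimated directly.
Candidate structures — constant, by role (occasion), by side, saturated,
plus covariate models for the three-reviewer data — are fitted by
quasi-Newton on the logit scale and ranked by AICc. Per-occasion estimates
are combined as 1 - prod(1 - p_i) with a delta-method standard error.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from skystrip.sightings import CaptureHistory

_BOUNDARY_LOGIT = 8.0


@dataclass(frozen=True)
class ModelSpec:
    """Structure of a Huggins candidate model.

    structure: 'constant' (one p), 'by_role' (one p per occasion; occasions
    are seats for observers, reviewers for imagery), 'by_side' (one p per
    aircraft side, pooling occasions), or 'saturated' (per occasion — for
    2 occasions identical to by_role; for observers with sides, occasion x
    side). covariates: subset of {'size_bin', 'visibility', 'glitter'},
    additive on the logit scale; 'interactions' adds occasion x covariate
    terms (3-reviewer data only).
    """

    structure: str = "by_role"
    covariates: tuple[str, ...] = ()
    interactions: bool = False
    name: str | None = None

    def __post_init__(self) -> None:
        if self.structure not in ("constant", "by_role", "by_side", "saturated"):
            raise ValueError(f"unknown structure {self.structure!r}")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        parts = [self.structure]
        parts += list(self.covariates)
        if self.interactions:
            parts.append("x")
        return "+".join(parts)


@dataclass
class PerceptionEstimate:
    """Fitted per-occasion probabilities and model summaries."""

    spec: ModelSpec
    p_hat: np.ndarray
    se: np.ndarray
    vcov_p: np.ndarray
    beta: np.ndarray
    vcov_beta: np.ndarray
    p_d: float
    se_d: float
    logLik: float
    k: int
    n: int
    aicc: float
    converged: bool = True
    boundary: bool = False
    delta_aicc: float = 0.0


def _covariate_levels(histories: list[CaptureHistory], cov: str) -> list:
    vals = sorted({getattr(h, cov if cov != "size_bin" else "size_bin") for h in histories
                   if getattr(h, cov if cov != "size_bin" else "size_bin") is not None})
    return vals


def build_design(
    histories: list[CaptureHistory], spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Design tensor X of shape (n_hist, n_occ, n_params): logit p = X @ beta."""
    n = len(histories)
    n_occ = len(histories[0].occasions)
    cols: list[np.ndarray] = []
    names: list[str] = []

    if spec.structure == "constant":
        cols.append(np.ones((n, n_occ)))
        names.append("p")
    elif spec.structure in ("by_role", "saturated"):
        for i in range(n_occ):
            c = np.zeros((n, n_occ))
            c[:, i] = 1.0
            cols.append(c)
            names.append(f"p{i + 1}")
    elif spec.structure == "by_side":
        sides = sorted({h.side for h in histories if h.side is not None})
        if not sides:
            raise ValueError("by_side model requires side covariates on histories")
        for s in sides:
            c = np.zeros((n, n_occ))
            for j, h in enumerate(histories):
                if h.side == s:
                    c[j, :] = 1.0
            cols.append(c)
            names.append(f"p[{s}]")

    for cov in spec.covariates:
        levels = _covariate_levels(histories, cov)
        if cov == "glitter":  # continuous
            c = np.zeros((n, n_occ))
            for j, h in enumerate(histories):
                c[j, :] = h.glitter if h.glitter is not None else 0.0
            cols.append(c)
            names.append("glitter")
            if spec.interactions:
                for i in range(1, n_occ):
                    ci = np.zeros((n, n_occ))
                    ci[:, i] = c[:, i]
                    cols.append(ci)
                    names.append(f"glitter:p{i + 1}")
            continue
        for lev in levels[1:]:  # reference = first level
            c = np.zeros((n, n_occ))
            for j, h in enumerate(histories):
                if getattr(h, cov) == lev:
                    c[j, :] = 1.0
            cols.append(c)
            names.append(f"{cov}[{lev}]")
            if spec.interactions:
                for i in range(1, n_occ):
                    ci = np.zeros((n, n_occ))
                    ci[:, i] = c[:, i]
                    cols.append(ci)
                    names.append(f"{cov}[{lev}]:p{i + 1}")
    X = np.stack(cols, axis=2)
    return X, names


def huggins_loglik(
    histories: list[CaptureHistory] | np.ndarray,
    params: np.ndarray,
    spec: ModelSpec | None = None,
    design: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Conditional (on >=1 detection) log-likelihood at logit-scale params.

    sum_w log[ prod_i p_i^w_i (1-p_i)^(1-w_i) / (1 - prod_i (1-p_i)) ].
    """
    if design is None:
        if spec is None:
            raise ValueError("need either a design tensor or a ModelSpec")
        design, _ = build_design(list(histories), spec)
    if isinstance(histories, np.ndarray):
        Y = histories
    else:
        Y = np.array([h.occasions for h in histories], dtype=float)
    if np.any(Y.sum(axis=1) < 1):
        raise ValueError("all-zero capture history in conditional data")
    eta = design @ np.asarray(params, dtype=float)
    # stable log p / log (1-p)
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    log_num = (Y * log_p + (1 - Y) * log_q).sum(axis=1)
    log_q_all = log_q.sum(axis=1)
    log_denom = np.log1p(-np.exp(np.minimum(log_q_all, -1e-12)))
    contrib = log_num - log_denom
    if weights is not None:
        contrib = contrib * weights
    return float(contrib.sum())


def _aggregate(histories: list[CaptureHistory], spec: ModelSpec):
    """Collapse histories sharing (occasions, covariates) into weighted rows."""
    X, names = build_design(histories, spec)
    Y = np.array([h.occasions for h in histories], dtype=float)
    key = np.concatenate([Y, X.reshape(len(histories), -1)], axis=1)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    w = np.bincount(inv).astype(float)
    first = np.array([np.flatnonzero(inv == g)[0] for g in range(len(uniq))])
    return Y[first], X[first], w, names


def fit_huggins(
    histories: list[CaptureHistory],
    spec: ModelSpec = ModelSpec("by_role"),
    starts: tuple[float, ...] = (-1.0, 0.0, 1.0),
    gtol: float = 1e-8,
) -> PerceptionEstimate:
    """Maximum conditional likelihood on the logit scale with multi-start BFGS.

    SEs come from the inverse observed information (central-difference
    Hessian). Estimates pushed to the logit boundary (|eta| > 8) are flagged
    and their probability-scale SEs reported as NaN.
    """
    n = len(histories)
    if n == 0:
        raise ValueError("no capture histories")
    Y, X, w, names = _aggregate(histories, spec)
    k = X.shape[2]
    if n < k + 2:
        raise ValueError(f"need n >= k + 2 (n={n}, k={k})")

    def nll(beta):
        return -huggins_loglik(Y, beta, design=X, weights=w)

    best = None
    for s in starts:
        res = minimize(
            nll,
            np.full(k, s),
            method="BFGS",
            options={"gtol": gtol, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    beta = np.clip(best.x, -_BOUNDARY_LOGIT - 4, _BOUNDARY_LOGIT + 4)
    boundary = bool(np.any(np.abs(beta) > _BOUNDARY_LOGIT))
    converged = bool(best.success or np.linalg.norm(best.jac) < 1e-4 or boundary)
    if not converged:
        warnings.warn(f"Huggins fit did not converge for {spec.label}", stacklevel=2)

    from statsmodels.tools.numdiff import approx_hess2

    H = approx_hess2(beta, nll)
    try:
        vcov_beta = np.linalg.inv(H)
        if np.any(np.diag(vcov_beta) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        vcov_beta = np.full((k, k), np.nan)

    # per-occasion probabilities at the reference covariate level: average the
    # design over histories so structures without pure occasion columns
    # (constant, by_side) still yield occasion-level p-hats
    n_occ = Y.shape[1]
    Xbar = np.average(X, axis=0, weights=w)  # (n_occ, k)
    eta = Xbar @ beta
    p_hat = 1.0 / (1.0 + np.exp(-eta))
    grad = (p_hat * (1 - p_hat))[:, None] * Xbar  # d p_i / d beta
    if np.all(np.isfinite(vcov_beta)):
        vcov_p = grad @ vcov_beta @ grad.T
        se = np.sqrt(np.clip(np.diag(vcov_p), 0, None))
    else:
        vcov_p = np.full((n_occ, n_occ), np.nan)
        se = np.full(n_occ, np.nan)
    if boundary:
        se = np.where(np.abs(eta) > _BOUNDARY_LOGIT, np.nan, se)

    p_d = combined_probability(p_hat)
    se_d = (
        delta_se_combined(p_hat, vcov_p)
        if np.all(np.isfinite(vcov_p))
        else float("nan")
    )
    ll = -best.fun
    return PerceptionEstimate(
        spec=spec,
        p_hat=p_hat,
        se=se,
        vcov_p=vcov_p,
        beta=beta,
        vcov_beta=vcov_beta,
        p_d=p_d,
        se_d=se_d,
        logLik=ll,
        k=k,
        n=n,
        aicc=aicc(ll, k, n),
        converged=converged,
        boundary=boundary,
    )


def combined_probability(p_vector) -> float:
    """1 - prod(1 - p_i): detection by at least one occasion."""
    p = np.asarray(p_vector, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must be in [0, 1]")
    return float(1.0 - np.prod(1.0 - p))


def delta_se_combined(p_vector, vcov) -> float:
    """Delta-method SE of 1 - prod(1-p_i); gradient g_i = prod_{j!=i}(1-p_j)."""
    p = np.asarray(p_vector, dtype=float)
    V = np.asarray(vcov, dtype=float)
    if V.shape != (p.size, p.size):
        raise ValueError("vcov not conformable with p")
    q = 1.0 - p
    g = np.array([np.prod(np.delete(q, i)) for i in range(p.size)])
    var = float(g @ V @ g)
    return float(np.sqrt(max(var, 0.0)))


def aicc(logLik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        warnings.warn("AICc undefined for n <= k + 1; returning +inf", stacklevel=2)
        return float("inf")
    return -2.0 * logLik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def default_candidates(n_occasions: int, with_sides: bool = False,
                       with_covariates: bool = False) -> list[ModelSpec]:
    """The candidate set: constant / by-role (/ by-side) (/ covariate models)."""
    specs = [ModelSpec("constant"), ModelSpec("by_role")]
    if with_sides:
        specs.append(ModelSpec("by_side"))
        specs.append(ModelSpec("saturated"))
    if with_covariates:
        covs = ["size_bin", "visibility", "glitter"]
        for r in range(1, len(covs) + 1):
            for combo in itertools.combinations(covs, r):
                specs.append(ModelSpec("by_role", covariates=combo))
        specs.append(
            ModelSpec("by_role", covariates=tuple(covs), interactions=True, name="full")
        )
    return specs


def select_model(
    histories: list[CaptureHistory], candidate_specs: list[ModelSpec]
) -> list[PerceptionEstimate]:
    """Fit all candidates and rank ascending by AICc (ties -> smaller k)."""
    if not candidate_specs:
        raise ValueError("need at least one candidate model")
    fits = []
    for spec in candidate_specs:
        try:
            fits.append(fit_huggins(histories, spec))
        except (ValueError, np.linalg.LinAlgError) as err:
            warnings.warn(f"candidate {spec.label} failed: {err}", stacklevel=2)
    if not fits:
        raise RuntimeError("all candidate models failed to fit")
    fits.sort(key=lambda f: (round(f.aicc, 6), f.k))
    best = fits[0].aicc
    for f in fits:
        f.delta_aicc = f.aicc - best
    return fits


def estimate_to_dict(est: PerceptionEstimate) -> dict:
    return dict(
        model=est.spec.label,
        p_hat=[float(x) for x in est.p_hat],
        se=[float(x) for x in est.se],
        p_d=est.p_d,
        se_d=est.se_d,
        logLik=est.logLik,
        k=est.k,
        n=est.n,
        AICc=est.aicc,
        dAICc=est.delta_aicc,
        converged=est.converged,
        boundary=est.boundary,
    )
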