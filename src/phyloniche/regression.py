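"""Comparative regression: LASSO screening, PGLS, AICc selection, model averaging.

The inference chain works on *contrasts* first and tip values second:

1. :func:`lasso_screen` — L1-penalized regression of response contrasts on
   predictor contrasts (no intercept: contrasts force regression through the
   origin), with the penalty chosen by k-fold cross-validation on a 100-point
   log-spaced grid.  Its job is variable screening in the p >> n regime where
   a direct multivariate fit is singular.
2. :func:`pgls_fit` — generalized least squares on tip values with residual
   covariance proportional to the Brownian-motion matrix of the tree,
   maximum-likelihood profile variance, and small-sample AICc.
3. :func:`enumerate_models` / :func:`select_best` / :func:`model_average` —
   all-subsets AICc comparison, Akaike weights, and averaging over the
   smallest set of top-ranked models holding >= 95% of the weight.
4. :func:`significance_gate` — the final strict ``p < alpha`` acceptance rule.

Likelihoods are ML (not REML) so AICc is comparable across models with
different fixed effects; a REML toggle exists for single-model reporting.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .trees import PhyloTree, brownian_covariance

__all__ = [
    "ContrastDesign",
    "LassoFit",
    "PGLSFit",
    "AveragedModel",
    "SingularDesignError",
    "NotPositiveDefiniteError",
    "lasso_fit",
    "kkt_residual",
    "lasso_screen",
    "pgls_fit",
    "pgls_fit_arrays",
    "enumerate_models",
    "select_best",
    "model_average",
    "significance_gate",
]


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the (whitened) design matrix is rank-deficient."""


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    """Raised when the phylogenetic covariance matrix fails its factorization."""


# ---------------------------------------------------------------------------
# LASSO on contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastDesign:
    """Response and predictor contrasts ready for through-origin regression."""

    y: np.ndarray
    X: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.shape[1] != len(self.names):
            raise ValueError("names must match X columns")
        if not (np.isfinite(self.y).all() and np.isfinite(self.X).all()):
            raise ValueError("contrasts must be finite")

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]


def _column_scales(X: np.ndarray) -> np.ndarray:
    """Root-mean-square per column; no centering (through-origin design)."""
    s = np.sqrt((X**2).mean(axis=0))
    return s


def lasso_fit(design: ContrastDesign, lam: float) -> np.ndarray:
    """Solve ``min (1/(2m))||y - Xb||^2 + lam * sum|b_j|`` with no intercept.

    Columns are standardized to unit RMS internally; returned coefficients
    are on the original predictor scale.  ``lam = 0`` reduces to least
    squares through the origin.  An all-zero column gets coefficient 0 with
    a warning.
    """
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    X, y = design.X, design.y
    s = _column_scales(X)
    zero = s == 0
    if zero.any():
        warnings.warn(
            f"all-zero predictor columns forced to 0: "
            f"{[design.names[i] for i in np.flatnonzero(zero)]}"
        )
    s_safe = np.where(zero, 1.0, s)
    Xs = X / s_safe
    if lam == 0:
        beta_s, *_ = np.linalg.lstsq(Xs[:, ~zero], y, rcond=None)
        beta = np.zeros(X.shape[1])
        beta[~zero] = beta_s
    else:
        _, coefs, _ = lasso_path(Xs, y, alphas=[lam], max_iter=100_000, tol=1e-12)
        beta = coefs[:, 0]
    beta[zero] = 0.0
    return beta / s_safe


def kkt_residual(design: ContrastDesign, lam: float, beta: np.ndarray) -> float:
    """Maximum violation of the LASSO stationarity conditions (standardized).

    At an exact solution the subgradient conditions give
    ``X'(y - Xb)/m = lam * sign(b_j)`` for active coefficients and
    ``|X'(y - Xb)/m| <= lam`` for inactive ones; the return value is the
    largest deviation from these.
    """
    X = design.X
    s = _column_scales(X)
    s_safe = np.where(s == 0, 1.0, s)
    Xs = X / s_safe
    b = np.asarray(beta, dtype=float) * s_safe  # to standardized scale
    g = Xs.T @ (design.y - Xs @ b) / design.n_obs
    active = b != 0
    viol = np.abs(np.abs(g[~active]).clip(min=lam) - lam)
    resid = np.abs(g[active] - lam * np.sign(b[active]))
    parts = np.concatenate([viol, resid]) if len(b) else np.array([0.0])
    return float(parts.max()) if parts.size else 0.0


@dataclass
class LassoFit:
    """Cross-validated LASSO screen: chosen penalty, coefficients, CV curve."""

    lam: float
    coef: np.ndarray
    selected: tuple[str, ...]
    names: tuple[str, ...]
    lambda_grid: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    seed: int
    folds: int


def lasso_screen(
    design: ContrastDesign,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-4,
    rule: str = "min",
    cv_repeats: int = 1,
) -> LassoFit:
    """Variable screening by cross-validated LASSO on contrasts.

    The penalty grid is 100 log-spaced values from the null threshold (the
    smallest penalty at which every coefficient is zero) down by a factor of
    1e-4.  Mean squared prediction error is estimated by k-fold CV with a
    seeded fold shuffle; the selected grid point either minimizes mean CV
    error (``rule='min'``) or is the largest penalty within one standard
    error of that minimum (``rule='1se'``, the sparser conventional choice).
    The model is refit on all contrasts at the selected penalty.
    Deterministic given ``seed``.
    """
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    if design.X.shape[1] == 0:
        raise ValueError("no predictors to screen")
    m = design.n_obs
    if not (2 <= folds <= m):
        raise ValueError(f"folds must be in [2, {m}]")

    s = _column_scales(design.X)
    s_safe = np.where(s == 0, 1.0, s)
    Xs = design.X / s_safe
    y = design.y

    lam_max = np.abs(Xs.T @ y).max() / m
    if lam_max == 0:
        lam_max = 1e-8  # response orthogonal to every predictor
    grid = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    if cv_repeats < 1:
        raise ValueError("cv_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    sq_err = np.zeros((folds * cv_repeats, len(grid)))
    for rep in range(cv_repeats):
        perm = rng.permutation(m)
        fold_ids = np.empty(m, dtype=int)
        fold_ids[perm] = np.arange(m) % folds
        for f in range(folds):
            test = fold_ids == f
            with warnings.catch_warnings():
                # the deep end of the penalty grid is past the interpolation
                # threshold; slow convergence there does not affect selection
                warnings.simplefilter("ignore", category=ConvergenceWarning)
                _, coefs, _ = lasso_path(Xs[~test], y[~test], alphas=grid,
                                         max_iter=10_000, tol=1e-6)
            pred = Xs[test] @ coefs  # (n_test, n_lambda)
            sq_err[rep * folds + f] = ((y[test, None] - pred) ** 2).mean(axis=0)
    cv_mean = sq_err.mean(axis=0)
    # fold-spread standard error (the conventional CV uncertainty measure);
    # repeats stabilize the mean curve but do not shrink this band, keeping
    # the one-standard-error rule conservative
    cv_se = sq_err.std(axis=0, ddof=1) / np.sqrt(folds)

    best = int(np.argmin(cv_mean))
    if rule == "1se":
        ceiling = cv_mean[best] + cv_se[best]
        best = int(np.flatnonzero(cv_mean <= ceiling)[0])  # grid is descending
    lam = float(grid[best])
    _, coefs, _ = lasso_path(Xs, y, alphas=grid[: best + 1],
                             max_iter=100_000, tol=1e-12)
    beta = coefs[:, -1] / s_safe
    beta[s == 0] = 0.0
    selected = tuple(n for n, b in zip(design.names, beta) if b != 0)
    return LassoFit(lam=lam, coef=beta, selected=selected, names=design.names,
                    lambda_grid=grid, cv_mean=cv_mean, cv_se=cv_se,
                    seed=seed, folds=folds)


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class PGLSFit:
    """One phylogenetic GLS fit with ML likelihood and small-sample AICc.

    ``names`` includes the leading intercept; ``predictors`` excludes it.
    ``k`` counts estimated parameters (coefficients + 1 for the residual
    variance); ``aicc = -2 logLik + 2k + 2k(k+1)/(n-k-1)`` (NaN when the
    correction denominator is nonpositive).
    """

    names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    tvals: np.ndarray
    pvals: np.ndarray
    loglik: float
    sigma2: float
    k: int
    n: int
    aicc: float
    df_resid: int
    predictors: tuple[str, ...]
    reml: bool = False
    degenerate: bool = False

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.beta, "se": self.se, "t": self.tvals,
             "p": self.pvals},
            index=pd.Index(self.names, name="variable"),
        )


def _aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return float("nan")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def pgls_fit_arrays(
    y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str],
    C: np.ndarray,
    add_intercept: bool = True,
    reml: bool = False,
) -> PGLSFit:
    """PGLS from arrays: ``y`` (n,), ``X`` (n, p) without intercept, ``C`` (n, n).

    Under the model ``y ~ MVN(Xb, sigma^2 C)``: the GLS estimate is
    ``b = (X'C^-1 X)^-1 X'C^-1 y``; the ML profile variance is
    ``r'C^-1 r / n``; standard errors use the conventional ``n/(n-k)``
    bias adjustment and two-sided t p-values on ``n - k`` degrees of freedom
    (k = number of coefficients).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["(Intercept)"] + names
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than coefficients ({k})")

    try:
        L = np.linalg.cholesky(np.asarray(C, dtype=float))
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(
            "phylogenetic covariance matrix is not positive definite"
        ) from exc
    yw = sla.solve_triangular(L, y, lower=True)
    Xw = sla.solve_triangular(L, X, lower=True)

    Q, R = np.linalg.qr(Xw)
    diag = np.abs(np.diag(R))
    tol = max(Xw.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = np.flatnonzero(diag <= tol)
    if bad.size:
        raise SingularDesignError(
            f"collinear design columns: {[names[i] for i in bad]}"
        )
    beta = sla.solve_triangular(R, Q.T @ yw, lower=False)
    r = yw - Xw @ beta
    rss = float(r @ r)
    logdetC = 2.0 * float(np.log(np.diag(L)).sum())

    Rinv = sla.solve_triangular(R, np.eye(k), lower=False)
    xtx_inv_diag = (Rinv**2).sum(axis=1)

    degenerate = rss <= 1e-12 * max(1.0, float(yw @ yw))
    if degenerate:
        sigma2 = 0.0
        loglik = float("inf")
        se = np.zeros(k)
        tvals = np.where(beta == 0, 0.0, np.inf * np.sign(beta))
        pvals = np.where(beta == 0, 1.0, 0.0)
    else:
        if reml:
            sigma2 = rss / (n - k)
            _, logdet_xtx = np.linalg.slogdet(Xw.T @ Xw)
            loglik = -0.5 * (
                (n - k) * np.log(2 * np.pi * sigma2) + logdetC + logdet_xtx + (n - k)
            )
        else:
            sigma2 = rss / n
            loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetC + n)
        se = np.sqrt(xtx_inv_diag * rss / (n - k))
        tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - k)

    k_params = k + 1  # coefficients + residual variance
    return PGLSFit(
        names=tuple(names), beta=beta, se=se, tvals=tvals, pvals=pvals,
        loglik=float(loglik), sigma2=float(sigma2), k=k_params, n=n,
        aicc=_aicc(loglik, k_params, n), df_resid=n - k,
        predictors=tuple(names[1:] if add_intercept else names),
        reml=reml, degenerate=degenerate,
    )


def pgls_fit(
    y: Mapping[str, float] | pd.Series,
    predictors: Mapping[str, Mapping[str, float] | pd.Series],
    tree: PhyloTree,
    reml: bool = False,
) -> PGLSFit:
    """PGLS of a response trait on named predictor traits under the tree.

    Traits are joined on species labels; species absent from the tree or
    from any trait are dropped with a warning (the covariance of the
    remaining tips is the corresponding submatrix of the full Brownian
    matrix).  An intercept is always included.
    """
    y = pd.Series(y, dtype=float)
    preds = {name: pd.Series(v, dtype=float) for name, v in predictors.items()}
    shared = [lbl for lbl in tree.tip_labels
              if lbl in y.index and all(lbl in p.index for p in preds.values())]
    everything = set(y.index).union(*[set(p.index) for p in preds.values()],
                                    tree.tip_labels)
    dropped = sorted(everything - set(shared))
    if dropped:
        warnings.warn(f"species dropped from PGLS (not shared by all inputs): {dropped}")
    if not shared:
        raise ValueError("no species shared between tree and traits")

    C_full = brownian_covariance(tree, tree.tip_labels)
    idx = [tree.tip_labels.index(lbl) for lbl in shared]
    C = C_full[np.ix_(idx, idx)]
    yv = y.loc[shared].to_numpy()
    X = np.column_stack([p.loc[shared].to_numpy() for p in preds.values()]) \
        if preds else np.empty((len(shared), 0))
    return pgls_fit_arrays(yv, X, list(preds.keys()), C, reml=reml)


# ---------------------------------------------------------------------------
# Model selection and averaging
# ---------------------------------------------------------------------------

def enumerate_models(full: Sequence[str], max_predictors: int = 16) -> list[tuple[str, ...]]:
    """All subsets of the full predictor list, intercept-only model included.

    Deterministic order: by subset size, then by position in ``full``.
    Guarded at 16 predictors (65 536 models) against combinatorial blow-up.
    """
    names = list(full)
    if len(names) > max_predictors:
        raise ValueError(
            f"{len(names)} predictors would give 2^{len(names)} models; "
            f"screen the predictor set below {max_predictors} first"
        )
    out: list[tuple[str, ...]] = []
    for size in range(len(names) + 1):
        out.extend(itertools.combinations(names, size))
    return out


def select_best(fits: Sequence[PGLSFit]) -> PGLSFit:
    """Minimum-AICc fit; ties go to fewer parameters, then lexical predictors."""
    if not fits:
        raise ValueError("no fits to select from")
    valid = []
    for f in fits:
        if np.isnan(f.aicc):
            warnings.warn(
                f"model {f.predictors} excluded: AICc undefined (n - k - 1 <= 0)"
            )
        else:
            valid.append(f)
    if not valid:
        raise ValueError("AICc undefined for every candidate model")
    return min(valid, key=lambda f: (f.aicc, f.k, f.predictors))


@dataclass
class AveragedModel:
    """AICc model-averaged coefficients over the top confidence set.

    ``weight`` are Akaike weights over *all* fitted models (they sum to 1);
    ``in_set`` flags the smallest weight-ordered prefix with cumulative
    weight >= ``conf``.  ``beta_full`` substitutes 0 where a model omits a
    term (shrinkage toward zero); ``beta_cond`` averages only over models
    containing the term.  ``se`` is the unconditional standard error
    combining within-model variance and between-model spread, and p-values
    are z-based (no single model supplies degrees of freedom).
    """

    conf: float
    model_predictors: tuple[tuple[str, ...], ...]
    aicc: np.ndarray
    delta: np.ndarray
    weight: np.ndarray
    in_set: np.ndarray
    terms: tuple[str, ...]
    beta_full: np.ndarray
    beta_cond: np.ndarray
    se: np.ndarray
    pvals: np.ndarray

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.beta_full, "estimate_conditional": self.beta_cond,
             "se": self.se, "p": self.pvals},
            index=pd.Index(self.terms, name="variable"),
        )

    def model_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"predictors": ["+".join(p) if p else "(Intercept)"
                            for p in self.model_predictors],
             "AICc": self.aicc, "delta_AICc": self.delta,
             "weight": self.weight, "in_confidence_set": self.in_set}
        )


def model_average(fits: Sequence[PGLSFit], conf: float = 0.95) -> AveragedModel:
    """Average coefficients over the smallest top-weight model set >= ``conf``."""
    if not (0 < conf <= 1):
        raise ValueError("confidence level must be in (0, 1]")
    if not fits:
        raise ValueError("no fits to average")
    fits = [f for f in fits if not np.isnan(f.aicc)]
    if not fits:
        raise ValueError("AICc undefined for every candidate model")

    aicc = np.array([f.aicc for f in fits])
    delta = aicc - aicc.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()

    order = np.argsort(-w, kind="stable")
    in_set = np.zeros(len(fits), dtype=bool)
    cum = 0.0
    for i in order:
        in_set[i] = True
        cum += w[i]
        if cum >= conf:
            break
    w_set = np.where(in_set, w, 0.0)
    w_set /= w_set.sum()

    terms: list[str] = []
    for f in fits:
        for name in f.names:
            if name not in terms:
                terms.append(name)

    beta_full = np.zeros(len(terms))
    beta_cond = np.zeros(len(terms))
    se = np.zeros(len(terms))
    for j, term in enumerate(terms):
        b = np.zeros(len(fits))
        s = np.zeros(len(fits))
        has = np.zeros(len(fits), dtype=bool)
        for i, f in enumerate(fits):
            if term in f.names:
                pos = f.names.index(term)
                b[i], s[i], has[i] = f.beta[pos], f.se[pos], True
        beta_full[j] = float(w_set @ b)
        wc = w_set * has
        beta_cond[j] = float(wc @ b / wc.sum()) if wc.sum() > 0 else 0.0
        se[j] = float(np.sqrt(w_set @ (s**2 + (b - beta_full[j]) ** 2)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta_full / se, np.inf * np.sign(beta_full))
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals[beta_full == 0] = 1.0

    return AveragedModel(
        conf=conf,
        model_predictors=tuple(f.predictors for f in fits),
        aicc=aicc, delta=delta, weight=w, in_set=in_set,
        terms=tuple(terms), beta_full=beta_full, beta_cond=beta_cond,
        se=se, pvals=pvals,
    )


def significance_gate(p: float, alpha: float = 0.01) -> bool:
    """Strict acceptance rule: contribution stands only when ``p < alpha``."""
    if not (0 <= p <= 1):
        raise ValueError("p must lie in [0, 1]")
    return p < alpha
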