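"""Two-inbred-strain analysis of social genetic effects.

In the paired design two mice (strains B6 and/or D2) share each cage; the
focal animal's phenotype is modelled with fixed effects for its own strain
(direct genetic effect, DGE), its cage mate's strain (social genetic
effect, SGE) and their interaction,

    y_f = beta_D X_f + beta_S X_cm + beta_DS X_f X_cm + e_f

with strain coded 0 (B6) / 1 (D2) and an exchangeable (compound-symmetry)
residual correlation rho within cages, -1 <= rho <= 1. With constant group
size the direct/social/cage environmental variances are not separately
identifiable and the single (sigma2_E, rho) residual is the model.

Model selection is by AIC on maximum-likelihood fits; per-strain SGE tests
are likelihood-ratio tests of beta_S; variance partitioning uses REML and a
Monte-Carlo evaluation of the sample phenotypic variance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

logger = logging.getLogger(__name__)

__all__ = [
    "boxcox_transform",
    "fit_paired_model",
    "aic_select",
    "sge_test_per_strain",
    "fixed_effect_variance",
    "InbredFit",
    "validate_paired",
    "TERM_COLUMNS",
]

#: mapping from model terms to design columns of the paired table
TERM_COLUMNS = {
    "DGE": "focal_strain",
    "SGE": "cagemate_strain",
    "DGE:SGE": None,  # product of the two strain codes
}

REQUIRED_COLUMNS = ("focal_id", "focal_strain", "cagemate_strain", "cage", "value")


def validate_paired(obs: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format paired-design table (one row per focal mouse)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"paired table missing columns: {missing}")
    for col in ("focal_strain", "cagemate_strain"):
        vals = set(pd.unique(obs[col]))
        if not vals <= {0, 1}:
            raise ValueError(f"{col} must be coded 0 (B6) / 1 (D2); saw {sorted(vals)[:5]}")
    counts = obs.groupby("cage")["focal_id"].count()
    if (counts > 2).any():
        raise ValueError("more than two focal animals share a cage")
    return obs


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

def _boxcox_apply(y: np.ndarray, lam: float) -> np.ndarray:
    if abs(lam) < 1e-12:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def _boxcox_profile_ll(lam: float, y: np.ndarray, X: np.ndarray, logy_sum: float) -> float:
    z = _boxcox_apply(y, lam)
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    rss = float(np.sum((z - X @ beta) ** 2))
    n = y.size
    return -0.5 * n * math.log(rss / n) + (lam - 1.0) * logy_sum


def boxcox_transform(
    y: np.ndarray,
    X: np.ndarray | None = None,
    grid: tuple[float, float] = (-2.0, 2.0),
    n_grid: int = 41,
) -> tuple[np.ndarray, float]:
    """Covariate-aware Box-Cox power transform.

    lambda maximizes the profile likelihood of the linear model z(lambda) ~ X
    over a grid refined by bounded scalar optimization. X informs the fit of
    lambda only (so genetic design covariates can shape the transform without
    being regressed out); the returned vector is the transformed y itself.
    Non-positive values are shifted by a logged offset before transforming.
    """
    y = np.asarray(y, dtype=float).ravel()
    if X is None:
        X = np.ones((y.size, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    ymin = np.min(y)
    if ymin <= 0:
        span = np.max(y) - ymin
        offset = -ymin + (0.01 * span if span > 0 else 1.0)
        logger.warning("boxcox_transform: shifting phenotype by %g to make it positive", offset)
        y = y + offset
        if np.min(y) <= 0:
            raise ValueError("phenotype not positive after shift")
    logy_sum = float(np.sum(np.log(y)))
    lams = np.linspace(grid[0], grid[1], n_grid)
    lls = np.array([_boxcox_profile_ll(l, y, X, logy_sum) for l in lams])
    k = int(np.argmax(lls))
    lo = lams[max(k - 1, 0)]
    hi = lams[min(k + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda l: -_boxcox_profile_ll(l, y, X, logy_sum),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(res.x)
    return _boxcox_apply(y, lam), lam


# ---------------------------------------------------------------------------
# Compound-symmetry GLS
# ---------------------------------------------------------------------------

@dataclass
class InbredFit:
    """A fixed-effect fit with exchangeable within-cage residuals."""

    terms: tuple[str, ...]
    residual: str  # "iid" | "cs"
    criterion: str  # "ML" | "REML"
    beta: pd.Series
    cov_beta: pd.DataFrame
    sigma2_E: float
    rho: float
    loglik: float
    loglik_ml: float
    loglik_reml: float
    n: int
    k_params: int  # fixed effects + free covariance parameters

    @property
    def aic(self) -> float:
        """AIC on the maximum-likelihood fit, 2k - 2 LL."""
        return 2.0 * self.k_params - 2.0 * self.loglik_ml


def _cs_blocks(cage: np.ndarray) -> list[np.ndarray]:
    """Row-index groups sharing a cage, in input order."""
    order: dict = {}
    for i, c in enumerate(cage):
        order.setdefault(c, []).append(i)
    return [np.asarray(v, dtype=np.int64) for v in order.values()]


def _cs_quadratics(y, X, blocks, rho):
    """r'R^-1 r pieces and log|R| for the exchangeable correlation matrix.

    For a block of size k, R = (1-rho)I + rho J, with closed-form inverse and
    determinant; requires rho in (-1/(k-1), 1).
    """
    n, p = X.shape
    XtRiX = np.zeros((p, p))
    XtRiy = np.zeros(p)
    ytRiy = 0.0
    logdetR = 0.0
    for idx in blocks:
        k = idx.size
        Xb, yb = X[idx], y[idx]
        if k == 1:
            XtRiX += np.outer(Xb[0], Xb[0])
            XtRiy += Xb[0] * yb[0]
            ytRiy += yb[0] ** 2
            continue
        denom1 = 1.0 - rho
        denomk = 1.0 + (k - 1) * rho
        if denom1 <= 0 or denomk <= 0:
            raise np.linalg.LinAlgError("rho outside the positive-definite range")
        logdetR += (k - 1) * math.log(denom1) + math.log(denomk)
        # R^-1 = (I - rho/(1+(k-1)rho) J) / (1-rho)
        c = rho / denomk
        Xs, ys = Xb.sum(axis=0), yb.sum()
        XtRiX += (Xb.T @ Xb - c * np.outer(Xs, Xs)) / denom1
        XtRiy += (Xb.T @ yb - c * Xs * ys) / denom1
        ytRiy += (yb @ yb - c * ys * ys) / denom1
    return XtRiX, XtRiy, ytRiy, logdetR


def _cs_loglik(y, X, blocks, rho, criterion):
    n, p = X.shape
    XtRiX, XtRiy, ytRiy, logdetR = _cs_quadratics(y, X, blocks, rho)
    beta = np.linalg.solve(XtRiX, XtRiy)
    rss = float(ytRiy - beta @ XtRiy)  # r'R^-1 r at the GLS solution
    rss = max(rss, 1e-300)
    if criterion == "ML":
        s2 = rss / n
        ll = -0.5 * (n * math.log(2 * math.pi) + n * math.log(s2) + logdetR + n)
    else:
        s2 = rss / (n - p)
        sign, logdet_XtRiX = np.linalg.slogdet(XtRiX)
        ll = -0.5 * ((n - p) * (math.log(2 * math.pi) + math.log(s2) + 1.0)
                     + logdetR + logdet_XtRiX)
    return ll, beta, s2, XtRiX


def _fit_cs(y, X, cage, criterion="ML", rho_fixed=None):
    blocks = _cs_blocks(np.asarray(cage))
    max_k = max(idx.size for idx in blocks)
    if rho_fixed is not None:
        rho = float(rho_fixed)
        ll, beta, s2, XtRiX = _cs_loglik(y, X, blocks, rho, criterion)
        return rho, ll, beta, s2, XtRiX, blocks
    eps = 1e-6
    lo = -1.0 / (max_k - 1) + eps if max_k > 1 else -1.0 + eps
    hi = 1.0 - eps
    res = minimize_scalar(
        lambda r: -_cs_loglik(y, X, blocks, r, criterion)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(res.x)
    ll, beta, s2, XtRiX = _cs_loglik(y, X, blocks, rho, criterion)
    return rho, ll, beta, s2, XtRiX, blocks


def _design(obs: pd.DataFrame, terms: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(obs))]
    names = ["(Intercept)"]
    if "DGE:SGE" in terms and not {"DGE", "SGE"} <= set(terms):
        raise ValueError("DGE:SGE interaction requires both main effects (marginality)")
    for t in terms:
        if t == "DGE":
            x = obs["focal_strain"].to_numpy(dtype=float)
        elif t == "SGE":
            x = obs["cagemate_strain"].to_numpy(dtype=float)
        elif t == "DGE:SGE":
            x = (obs["focal_strain"] * obs["cagemate_strain"]).to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown term {t!r}")
        if np.var(x) == 0:
            raise ValueError(f"term {t!r} has no design variation in this subset")
        cols.append(x)
        names.append(t)
    return np.column_stack(cols), names


def fit_paired_model(
    obs: pd.DataFrame,
    terms: tuple[str, ...] = ("SGE",),
    residual: str = "cs",
    criterion: str = "REML",
) -> InbredFit:
    """Generalized-least-squares fit of the paired two-strain model.

    ``residual="cs"`` estimates the within-cage exchangeable correlation rho
    jointly with sigma2_E by the stated criterion; ``"iid"`` fixes rho = 0,
    in which case the coefficients equal ordinary least squares.
    """
    obs = validate_paired(obs)
    if criterion not in ("ML", "REML"):
        raise ValueError("criterion must be 'ML' or 'REML'")
    if residual not in ("iid", "cs"):
        raise ValueError("residual must be 'iid' or 'cs'")
    y = obs["value"].to_numpy(dtype=float)
    X, names = _design(obs, terms)
    cage = obs["cage"].to_numpy()
    rho_fixed = 0.0 if residual == "iid" else None
    rho, ll, beta, s2, XtRiX, blocks = _fit_cs(y, X, cage, criterion, rho_fixed)
    # both criteria evaluated at the selected rho, for AIC and reporting
    ll_ml = ll if criterion == "ML" else _cs_loglik(y, X, blocks, rho, "ML")[0]
    ll_reml = ll if criterion == "REML" else _cs_loglik(y, X, blocks, rho, "REML")[0]
    cov_beta = s2 * np.linalg.inv(XtRiX)
    k = X.shape[1] + (1 if residual == "iid" else 2)
    return InbredFit(
        terms=tuple(terms),
        residual=residual,
        criterion=criterion,
        beta=pd.Series(beta, index=names),
        cov_beta=pd.DataFrame(cov_beta, index=names, columns=names),
        sigma2_E=float(s2),
        rho=float(rho),
        loglik=float(ll),
        loglik_ml=float(ll_ml),
        loglik_reml=float(ll_reml),
        n=len(obs),
        k_params=k,
    )


CANDIDATE_TERMS: tuple[tuple[str, ...], ...] = (
    (),
    ("DGE",),
    ("SGE",),
    ("DGE", "SGE"),
    ("DGE", "SGE", "DGE:SGE"),
)


def aic_select(
    obs: pd.DataFrame,
    residuals: tuple[str, ...] = ("iid", "cs"),
) -> tuple[str, pd.DataFrame]:
    """Select the best term/residual combination by AIC on ML fits.

    Candidates are the marginality-respecting subsets of
    {DGE, SGE, DGE:SGE} crossed with iid / compound-symmetry residuals.
    Unfittable candidates (no design variation) are excluded with a warning.
    Returns (best model id, table of candidates sorted by AIC).
    """
    rows = []
    for terms in CANDIDATE_TERMS:
        for residual in residuals:
            label = ("+".join(terms) or "null") + "|" + residual
            try:
                fit = fit_paired_model(obs, terms=terms, residual=residual, criterion="ML")
            except ValueError as exc:
                logger.warning("candidate %s excluded: %s", label, exc)
                continue
            rows.append(
                {"model": label, "terms": "+".join(terms) or "null",
                 "residual": residual, "k": fit.k_params,
                 "loglik_ml": fit.loglik_ml, "aic": fit.aic}
            )
    if not rows:
        raise ValueError("no candidate model could be fitted")
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    return str(table.loc[0, "model"]), table


def sge_test_per_strain(
    obs: pd.DataFrame,
    focal_strain: int,
    criterion: str = "ML",
) -> tuple[float, InbredFit, InbredFit]:
    """Likelihood-ratio test of the SGE coefficient within one focal strain.

    Fits y ~ 1 + cagemate_strain against y ~ 1, both with compound-symmetry
    residuals, on the focal-strain subset; p from chi-square(1).
    """
    sub = obs[obs["focal_strain"] == focal_strain].reset_index(drop=True)
    if sub["cagemate_strain"].nunique() < 2:
        raise ValueError("both cage-mate strains must be present in the focal subset")
    full = fit_paired_model(sub, terms=("SGE",), residual="cs", criterion=criterion)
    null = fit_paired_model(sub, terms=(), residual="cs", criterion=criterion)
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    p = float(chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return p, full, null


def _draw_denominator(fit: InbredFit, obs: pd.DataFrame, X: np.ndarray,
                      n_draws: int, rng: np.random.Generator) -> float:
    """Mean sample variance of phenotypes drawn from the fitted model."""
    mean = X @ fit.beta.to_numpy()
    n = len(obs)
    blocks = _cs_blocks(obs["cage"].to_numpy())
    E = np.empty((n, n_draws))
    sd = math.sqrt(fit.sigma2_E)
    for idx in blocks:
        k = idx.size
        if k == 1:
            E[idx[0]] = sd * rng.standard_normal(n_draws)
        else:
            R = np.full((k, k), fit.rho) + (1.0 - fit.rho) * np.eye(k)
            L = np.linalg.cholesky(fit.sigma2_E * R + 1e-12 * np.eye(k))
            E[idx] = L @ rng.standard_normal((k, n_draws))
    Y = mean[:, None] + E
    return float(np.mean(np.var(Y, axis=0, ddof=1)))


def fixed_effect_variance(
    fit: InbredFit,
    obs: pd.DataFrame,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Percentage of phenotypic variance explained by each fixed term.

    The numerator is the sample variance across individuals of the term's
    fitted contribution (e.g. var(beta_S * X_cm) for SGE); the denominator is
    the average sample variance of phenotypes drawn from the fitted model
    (Monte Carlo, >= 10,000 draws). Standard errors are obtained by
    first-order (Gaussian) propagation of the coefficient uncertainty
    through the ratio.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X, names = _design(obs, fit.terms)
    denom = _draw_denominator(fit, obs, X, n_draws, rng)
    if denom <= 0:
        raise ValueError("degenerate phenotypic variance in the fitted model")
    beta = fit.beta.to_numpy()
    cov = fit.cov_beta.to_numpy()

    def proportion(b: np.ndarray, j: int) -> float:
        num = float(np.var(b[j] * X[:, j], ddof=1))
        # analytic denominator for the smooth propagation path
        den = float(np.var(X @ b, ddof=1)) + denom - float(np.var(X @ beta, ddof=1))
        return num / den

    rows = []
    for j, name in enumerate(names):
        if name == "(Intercept)":
            continue
        prop = float(np.var(beta[j] * X[:, j], ddof=1)) / denom
        # gradient of the proportion wrt all coefficients, finite differences
        grad = np.zeros(len(beta))
        h = 1e-6 * max(1.0, float(np.max(np.abs(beta))))
        for i in range(len(beta)):
            bp, bm = beta.copy(), beta.copy()
            bp[i] += h
            bm[i] -= h
            grad[i] = (proportion(bp, j) - proportion(bm, j)) / (2 * h)
        se = math.sqrt(max(float(grad @ cov @ grad), 0.0))
        rows.append({"term": name, "variance_pct": 100.0 * prop, "se_pct": 100.0 * se})
    return pd.DataFrame(rows)
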