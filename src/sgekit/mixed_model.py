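"""Variance-component model for direct and social genetic effects.

Phenotypes of group-housed, genetically related individuals are modelled as

    y = X b + a_D + Z a_S + e_D + Z e_S + W c

where a_D are direct genetic effects (breeding values), a_S social genetic
effects transmitted by cage mates through the cage-mate indicator Z
(Z_ii = 0), e_D / e_S their environmental analogues, and c a shared cage
effect with incidence W. Direct and social effects of each kind are
correlated, giving the phenotypic covariance

    cov(y_i, y_j) = s2_AD H1 + s_ADS (H2 Z' + Z H2') + s2_AS Z H3 Z'
                  + s2_ED I1 + s_EDS (I2 Z' + Z I2') + s2_ES Z I3 Z'
                  + s2_C W I4 W'

with the H/I matrices pre-scaled (see :mod:`sgekit.relatedness`) so each
component reads directly as its share of the sample phenotypic variance.
Estimation is by restricted maximum likelihood over Cholesky-parameterized
2x2 covariance blocks, with analytic gradients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import chi2

from .relatedness import RelationshipMatrix, ScaledMatrices, sample_var, scale_components

logger = logging.getLogger(__name__)

__all__ = [
    "CageDesign",
    "VarianceComponents",
    "ComponentBasis",
    "FitResult",
    "build_covariance",
    "fit_reml",
    "variance_partition",
    "fisher_se",
    "lrt_sge",
    "FULL_COMPONENTS",
]

FULL_COMPONENTS = ("AD", "ADS", "AS", "ED", "EDS", "ES", "C")


@dataclass
class CageDesign:
    """Cage membership for a set of housed individuals.

    Derives the cage-mate indicator Z (zero diagonal, symmetric) and the
    cage incidence W (rows sum to one).
    """

    ids: list[str]
    cages: list[str]

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.cages = [str(c) for c in self.cages]
        if len(self.ids) != len(self.cages):
            raise ValueError("ids and cages must align")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids in cage design")
        self._cage_labels = sorted(set(self.cages))
        cage_idx = {c: k for k, c in enumerate(self._cage_labels)}
        self._cage_of = np.array([cage_idx[c] for c in self.cages], dtype=np.int64)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_cages(self) -> int:
        return len(self._cage_labels)

    @property
    def W(self) -> np.ndarray:
        W = np.zeros((self.n, self.n_cages))
        W[np.arange(self.n), self._cage_of] = 1.0
        return W

    @property
    def Z(self) -> np.ndarray:
        same = self._cage_of[:, None] == self._cage_of[None, :]
        Z = same.astype(float)
        np.fill_diagonal(Z, 0.0)
        return Z

    def cage_sizes(self) -> np.ndarray:
        return np.bincount(self._cage_of, minlength=self.n_cages)

    @property
    def constant_size(self) -> bool:
        sizes = self.cage_sizes()
        return bool(np.all(sizes == sizes[0]))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CageDesign":
        cols = list(df.columns[:2])
        return cls(ids=[str(v) for v in df[cols[0]]], cages=[str(v) for v in df[cols[1]]])

    @classmethod
    def from_tsv(cls, path) -> "CageDesign":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        pd.DataFrame({"id": self.ids, "cage": self.cages}).to_csv(path, sep="\t", index=False)


@dataclass
class VarianceComponents:
    """The seven (co)variance parameters of the social-effects model.

    On the scaled design each variance reads as a proportion of the sample
    phenotypic variance. ``sigma_ADS`` is a covariance; ``rho_ads`` the
    implied correlation between direct and social genetic effects.
    """

    sigma2_AD: float = 0.0
    sigma_ADS: float = 0.0
    sigma2_AS: float = 0.0
    sigma2_ED: float = 0.0
    sigma_EDS: float = 0.0
    sigma2_ES: float = 0.0
    sigma2_C: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma2_AD", "sigma2_AS", "sigma2_ED", "sigma2_ES", "sigma2_C"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for blk, (v1, c, v2) in {
            "genetic": (self.sigma2_AD, self.sigma_ADS, self.sigma2_AS),
            "environmental": (self.sigma2_ED, self.sigma_EDS, self.sigma2_ES),
        }.items():
            if c * c > v1 * v2 + 1e-12:
                raise ValueError(f"{blk} covariance implies |correlation| > 1")

    @property
    def rho_ads(self) -> float:
        denom = math.sqrt(self.sigma2_AD * self.sigma2_AS)
        return float("nan") if denom == 0 else self.sigma_ADS / denom

    @property
    def rho_eds(self) -> float:
        denom = math.sqrt(self.sigma2_ED * self.sigma2_ES)
        return float("nan") if denom == 0 else self.sigma_EDS / denom

    @classmethod
    def from_proportions(
        cls,
        dge: float,
        sge: float,
        rho_ads: float,
        dee: float,
        see: float,
        rho_eds: float,
        cage: float,
    ) -> "VarianceComponents":
        """Build from variance proportions (0..1 scale) and correlations.

        On the sample-variance-scaled design the proportions serve directly
        as component magnitudes.
        """
        if abs(rho_ads) > 1 or abs(rho_eds) > 1:
            raise ValueError("|correlation| > 1 requested")
        return cls(
            sigma2_AD=dge,
            sigma_ADS=rho_ads * math.sqrt(dge * sge),
            sigma2_AS=sge,
            sigma2_ED=dee,
            sigma_EDS=rho_eds * math.sqrt(dee * see),
            sigma2_ES=see,
            sigma2_C=cage,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "AD": self.sigma2_AD,
            "ADS": self.sigma_ADS,
            "AS": self.sigma2_AS,
            "ED": self.sigma2_ED,
            "EDS": self.sigma_EDS,
            "ES": self.sigma2_ES,
            "C": self.sigma2_C,
        }


class ComponentBasis:
    """Per-component covariance basis matrices K_k over the analysed rows.

    Built from the scaled relationship matrices and the full housed-set
    Z/W so that unphenotyped cage mates still act as social partners:
    when ``rows`` selects a subset of phenotyped individuals, Z keeps all
    of its columns inside the quadratic forms.
    """

    def __init__(self, scaled: ScaledMatrices, Z: np.ndarray, W: np.ndarray,
                 rows: np.ndarray | None = None):
        Z = np.asarray(Z, dtype=float)
        W = np.asarray(W, dtype=float)
        n_all = Z.shape[0]
        if rows is None:
            rows = np.arange(n_all)
        rows = np.asarray(rows, dtype=np.int64)
        Zr = Z[rows, :]            # phenotyped rows, all social columns
        Zrr = Z[np.ix_(rows, rows)]
        Wr = W[rows, :]
        B = scaled.H2[rows, :] @ Zr.T
        K = {
            "AD": scaled.H1[np.ix_(rows, rows)],
            "ADS": B + B.T,
            "AS": Zr @ scaled.H3 @ Zr.T,
            "ED": np.eye(len(rows)),
            "EDS": (Zrr + Zrr.T) / math.sqrt(scaled.var_ZZ),
            "ES": (Zr @ Zr.T) / scaled.var_ZZ,
            "C": (Wr @ Wr.T) / scaled.var_WW,
            # bases of the collapsed exchangeable residual (constant cage size)
            "E_I": np.eye(len(rows)),
            "E_Z": Zrr,
        }
        self.K = K
        self.rows = rows
        self.n = len(rows)
        # cage sizes among analysed rows (for the identifiability guard)
        counts = Wr.sum(axis=0)
        self._row_sizes = counts[counts > 0]
        self._Zrr = Zrr

    @classmethod
    def from_design(cls, H: RelationshipMatrix | np.ndarray, cages: CageDesign,
                    rows: np.ndarray | None = None) -> "ComponentBasis":
        from .relatedness import DegenerateDesignError

        Z, W = cages.Z, cages.W
        try:
            scaled = scale_components(H, Z, W)
        except DegenerateDesignError:
            if np.any(Z):
                raise
            # no co-housed animals: social bases vanish, unit scales are inert
            Hv = H.values if isinstance(H, RelationshipMatrix) else np.asarray(H, float)
            n = Hv.shape[0]
            vH = sample_var(Hv)
            vWW = sample_var(W @ W.T)
            scaled = ScaledMatrices(
                H1=Hv / vH, H2=Hv / math.sqrt(vH), H3=Hv.copy(),
                I1=np.eye(n), I2=np.eye(n), I3=np.eye(n),
                I4=np.eye(W.shape[1]) / vWW if vWW > 0 else np.eye(W.shape[1]),
                var_H=vH, var_ZHZ=1.0, var_ZZ=1.0,
                var_WW=vWW if vWW > 0 else 1.0,
            )
            logger.info("no co-housed pairs: social scale factors set to 1")
        return cls(scaled, Z, W, rows=rows)

    @property
    def constant_cage_size(self) -> bool:
        return self._row_sizes.size > 0 and bool(np.all(self._row_sizes == self._row_sizes[0]))

    @property
    def cage_size(self) -> int:
        return int(self._row_sizes[0])

    @property
    def social_contacts(self) -> bool:
        return bool(np.any(self._Zrr))

    def assemble(self, coeffs: dict[str, float]) -> np.ndarray:
        V = np.zeros((self.n, self.n))
        for name, c in coeffs.items():
            if c != 0.0:
                V += c * self.K[name]
        return V


def build_covariance(
    vc: VarianceComponents,
    basis: ComponentBasis,
    check_pd: bool = True,
) -> np.ndarray:
    """Assemble the phenotypic covariance implied by the variance components."""
    V = basis.assemble(vc.as_dict())
    V = 0.5 * (V + V.T)
    if check_pd:
        w = np.linalg.eigvalsh(V)
        if w[0] < -1e-8 * max(1.0, w[-1]):
            raise ValueError(
                f"assembled covariance is indefinite (smallest eigenvalue {w[0]:.3e})"
            )
    return V


# ---------------------------------------------------------------------------
# REML engine
# ---------------------------------------------------------------------------

class _Block:
    """A parameter block mapping raw parameters to coefficients on named
    basis matrices, with jacobian."""

    names: tuple[str, ...]
    n_par: int

    def coeffs(self, th: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def jac(self, th: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def start(self, target: dict[str, float]) -> np.ndarray:
        raise NotImplementedError


class _VarBlock(_Block):
    """sigma2 = theta^2 on a single basis matrix (non-negativity built in)."""

    n_par = 1

    def __init__(self, name: str):
        self.names = (name,)

    def coeffs(self, th):
        return np.array([th[0] ** 2])

    def jac(self, th):
        return np.array([[2.0 * th[0]]])

    def start(self, target):
        return np.array([math.sqrt(max(target.get(self.names[0], 0.0), 1e-6))])


class _Chol2Block(_Block):
    """2x2 covariance block [[v1, c], [c, v2]] = L L' with L = [[a,0],[b,c]].

    Guarantees positive semidefiniteness, hence |correlation| <= 1.
    Coefficient order: (v1, cov, v2) on (direct, cross, social) bases.
    """

    n_par = 3

    def __init__(self, names: tuple[str, str, str]):
        self.names = names

    def coeffs(self, th):
        a, b, c = th
        return np.array([a * a, a * b, b * b + c * c])

    def jac(self, th):
        a, b, c = th
        # rows: d(v1, cov, v2)/d(a, b, c)
        return np.array([
            [2 * a, b, 0.0],
            [0.0, a, 2 * b],
            [0.0, 0.0, 2 * c],
        ])

    def start(self, target):
        v1 = max(target.get(self.names[0], 0.0), 1e-6)
        v2 = max(target.get(self.names[2], 0.0), 1e-6)
        cov = target.get(self.names[1], 0.0)
        a = math.sqrt(v1)
        b = np.clip(cov / a, -0.99 * math.sqrt(v2), 0.99 * math.sqrt(v2))
        c = math.sqrt(max(v2 - b * b, 1e-8))
        return np.array([a, b, c])


class _Eig2Block(_Block):
    """Collapsed exchangeable environmental covariance sigma2_E I + tau Z for
    constant cage size s, parameterized by the per-cage block eigenvalues
    lam1 = sigma2_E + (s-1) tau (cage-mean direction) and lam2 = sigma2_E - tau,
    both kept non-negative as squares. Coefficients on ("E_I", "E_Z")."""

    n_par = 2
    names = ("E_I", "E_Z")

    def __init__(self, size: int):
        self.s = size

    def coeffs(self, th):
        u, v = th
        lam1, lam2 = u * u, v * v
        s = self.s
        return np.array([(lam1 + (s - 1) * lam2) / s, (lam1 - lam2) / s])

    def jac(self, th):
        u, v = th
        s = self.s
        return np.array([
            [2 * u / s, 2 * u / s],
            [2 * (s - 1) * v / s, -2 * v / s],
        ])

    def start(self, target):
        s2 = max(target.get("E_I", 1.0), 1e-4)
        tau = target.get("E_Z", 0.0)
        lam1 = max(s2 + (self.s - 1) * tau, 1e-6)
        lam2 = max(s2 - tau, 1e-6)
        return np.array([math.sqrt(lam1), math.sqrt(lam2)])


@dataclass
class FitResult:
    """REML estimates of the social-effects variance components."""

    coefficients: dict[str, float]
    beta: np.ndarray
    loglik: float
    converged: bool
    n: int
    p: int
    components: tuple[str, ...]
    collapsed: bool
    messages: list[str] = field(default_factory=list)
    se: dict[str, float] | None = None
    n_starts_used: int = 0

    @property
    def varcomp(self) -> VarianceComponents:
        """Estimates as a VarianceComponents object (zero for absent terms).

        For collapsed environmental fits the exchangeable residual
        (sigma2_E, tau) is folded into sigma2_ED and sigma2_C as the
        non-negative decomposition when tau >= 0; otherwise sigma_EDS
        carries the negative within-cage covariance.
        """
        c = self.coefficients
        if not self.collapsed:
            return VarianceComponents(
                sigma2_AD=c.get("AD", 0.0),
                sigma_ADS=c.get("ADS", 0.0),
                sigma2_AS=c.get("AS", 0.0),
                sigma2_ED=c.get("ED", 0.0),
                sigma_EDS=c.get("EDS", 0.0),
                sigma2_ES=c.get("ES", 0.0),
                sigma2_C=c.get("C", 0.0),
            )
        s2, tau = c.get("E_I", 0.0), c.get("E_Z", 0.0)
        if tau >= 0:
            return VarianceComponents(
                sigma2_AD=c.get("AD", 0.0), sigma_ADS=c.get("ADS", 0.0),
                sigma2_AS=c.get("AS", 0.0), sigma2_ED=max(s2 - tau, 0.0),
                sigma2_C=tau,
            )
        # negative within-cage covariance: representable only as a
        # boundary direct/social environmental correlation
        return VarianceComponents(
            sigma2_AD=c.get("AD", 0.0), sigma_ADS=c.get("ADS", 0.0),
            sigma2_AS=c.get("AS", 0.0), sigma2_ED=s2, sigma_EDS=tau / 2.0,
            sigma2_ES=tau * tau / (4.0 * s2) if s2 > 0 else 0.0,
        )

    @property
    def rho_ads(self) -> float:
        c = self.coefficients
        denom = math.sqrt(c.get("AD", 0.0) * c.get("AS", 0.0))
        return float("nan") if denom == 0 else c.get("ADS", 0.0) / denom


def _block_jacobian(theta, blocks):
    """Coefficient values, basis names, and the (n_theta x n_coeff)
    jacobian d coeff / d theta of the block parameterization."""
    names: list[str] = []
    coeff_vals: list[float] = []
    off = 0
    n_coeff = sum(len(b.names) for b in blocks)
    J = np.zeros((sum(b.n_par for b in blocks), n_coeff))
    ci = 0
    for blk in blocks:
        th = theta[off: off + blk.n_par]
        coeff_vals.extend(blk.coeffs(th))
        names.extend(blk.names)
        J[off: off + blk.n_par, ci: ci + len(blk.names)] = blk.jac(th)
        off += blk.n_par
        ci += len(blk.names)
    return np.asarray(coeff_vals), names, J


def _reml_eval(theta, blocks, basis, X, y, logdet_XtX):
    """Negative restricted log-likelihood and its gradient on the theta scale.

    The restricted likelihood includes + 1/2 log|X'X| so it is invariant to
    the choice of fixed-effect basis.
    """
    n, p = X.shape
    coeff_vals, names, J = _block_jacobian(theta, blocks)
    Ks = [basis.K[name] for name in names]
    V = np.zeros((n, n))
    for c, K in zip(coeff_vals, Ks):
        if c != 0.0:
            V += c * K
    from scipy.linalg.lapack import dpotrf, dpotri

    L = None
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        Vj = V if jitter == 0.0 else V + jitter * np.eye(n)
        L, info = dpotrf(Vj, lower=1, clean=0, overwrite_a=0)
        if info == 0:
            break
        L = None
    if L is None:
        # strongly penalize an indefinite proposal
        return 1e10, np.zeros_like(theta)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    Vi, info = dpotri(L, lower=1, overwrite_c=1)
    if info != 0:
        return 1e10, np.zeros_like(theta)
    Vi = np.tril(Vi) + np.tril(Vi, -1).T  # dpotri fills the lower triangle only
    ViX = Vi @ X
    XtViX = X.T @ ViX
    cho2 = cho_factor(XtViX, lower=True, check_finite=False)
    logdetXVX = 2.0 * float(np.sum(np.log(np.diag(cho2[0]))))
    P = Vi - ViX @ cho_solve(cho2, ViX.T, check_finite=False)
    Py = P @ y
    quad = float(y @ Py)
    nll = 0.5 * ((n - p) * math.log(2.0 * math.pi) + logdetV + logdetXVX
                 - logdet_XtX + quad)
    # gradient on the coefficient scale, then chained through the blocks
    m = len(Ks)
    gc = np.empty(m)
    for k, K in enumerate(Ks):
        gc[k] = 0.5 * (float(np.vdot(P, K)) - float(Py @ (K @ Py)))
    return nll, J @ gc


_restricted_ll_and_grad = _reml_eval


def _make_blocks(components: tuple[str, ...], basis: ComponentBasis,
                 collapse: bool) -> tuple[list[_Block], bool]:
    comp = set(components)
    blocks: list[_Block] = []
    if {"AD", "ADS", "AS"} <= comp:
        blocks.append(_Chol2Block(("AD", "ADS", "AS")))
    else:
        if "ADS" in comp:
            raise ValueError("ADS requires both AD and AS in the model")
        for g in ("AD", "AS"):
            if g in comp:
                blocks.append(_VarBlock(g))
    env = comp & {"ED", "EDS", "ES", "C"}
    collapsed = False
    if collapse and len(env) >= 3:
        blocks.append(_Eig2Block(basis.cage_size))
        collapsed = True
    else:
        if {"ED", "EDS", "ES"} <= comp:
            blocks.append(_Chol2Block(("ED", "EDS", "ES")))
        else:
            if "EDS" in comp:
                raise ValueError("EDS requires both ED and ES in the model")
            for e in ("ED", "ES"):
                if e in comp:
                    blocks.append(_VarBlock(e))
        if "C" in comp:
            blocks.append(_VarBlock("C"))
    return blocks, collapsed


def _start_targets(s2y: float, components: set[str], policy: str) -> dict[str, float]:
    """The 3-point restart schedule: null / DGE-heavy / equal-split starts."""
    t: dict[str, float] = {}
    if policy == "null":
        t["ED"] = 0.9 * s2y
        t["E_I"] = 0.9 * s2y
        for name in components - {"ED"}:
            t[name] = 0.02 * s2y
        t["ADS"] = 0.0
        t["EDS"] = 0.0
        t["E_Z"] = 0.0
    elif policy == "dge":
        t["AD"] = 0.5 * s2y
        t["ED"] = 0.45 * s2y
        t["E_I"] = 0.45 * s2y
        for name in components - {"AD", "ED"}:
            t[name] = 0.02 * s2y
        t["ADS"] = 0.0
        t["EDS"] = 0.0
        t["E_Z"] = 0.1 * s2y
    else:  # equal split
        k = max(len(components), 1)
        for name in components:
            t[name] = s2y / k
        t["E_I"] = 2 * s2y / k
        t["E_Z"] = 0.5 * s2y / k
        t["ADS"] = 0.0
        t["EDS"] = 0.0
    return t


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    basis: ComponentBasis,
    components: tuple[str, ...] = FULL_COMPONENTS,
    compute_se: bool = False,
    n_starts: int = 3,
    gtol: float = 1e-5,
) -> FitResult:
    """Fit the social-effects model by restricted maximum likelihood.

    Parameters are the Cholesky factors of the genetic and environmental
    2x2 covariance blocks plus the cage variance, optimized by L-BFGS-B
    from up to three starting points (null, direct-genetics-heavy, equal
    split); the best restricted likelihood wins.

    Components can be any subset of ("AD","ADS","AS","ED","EDS","ES","C");
    a covariance term requires both of its variance terms. Identifiability
    guards: with no co-housed pairs the social terms are dropped; with a
    constant cage size the environmental terms collapse to an exchangeable
    within-cage residual (coefficients reported on "E_I" and "E_Z"); a
    direct-genetic basis indistinguishable from the identity is dropped.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if n != basis.n:
        raise ValueError("basis rows do not match data length")
    if np.linalg.matrix_rank(X) < p:
        r = np.linalg.qr(X, mode="r")
        bad = [j for j in range(p) if abs(r[j, j] if j < r.shape[0] else 0) < 1e-10]
        raise ValueError(f"rank-deficient fixed-effect matrix (columns {bad})")
    messages: list[str] = []
    comp = tuple(components)
    if not basis.social_contacts and set(comp) & {"ADS", "AS", "EDS", "ES"}:
        comp = tuple(c for c in comp if c not in {"ADS", "AS", "EDS", "ES"})
        messages.append("no co-housed pairs among analysed rows: social terms dropped")
        logger.info(messages[-1])
    if {"AD", "ED"} <= set(comp):
        if np.max(np.abs(basis.K["AD"] - basis.K["ED"])) < 1e-10:
            comp = tuple(c for c in comp if c not in {"AD", "ADS", "AS"})
            messages.append(
                "direct-genetic covariance equals the identity (no genetic "
                "information): genetic terms dropped"
            )
            logger.info(messages[-1])
    if {"C", "ED"} <= set(comp):
        if np.max(np.abs(basis.K["C"] - basis.K["ED"])) < 1e-10:
            comp = tuple(c for c in comp if c != "C")
            messages.append(
                "cage-effect covariance equals the identity (singleton cages): "
                "cage term dropped"
            )
            logger.info(messages[-1])
    collapse = basis.constant_cage_size and len(set(comp) & {"ED", "EDS", "ES", "C"}) >= 3
    if collapse:
        messages.append(
            f"constant cage size ({basis.cage_size}): environmental terms "
            "collapsed to an exchangeable within-cage residual"
        )
        logger.info(messages[-1])
    blocks, collapsed = _make_blocks(comp, basis, collapse)

    # scale heuristic from OLS residuals
    bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ bhat
    s2y = max(float(resid @ resid) / max(n - p, 1), 1e-8)
    sign, logdet_XtX = np.linalg.slogdet(X.T @ X)

    policies = ["null", "dge", "equal"][: max(1, n_starts)]
    best: tuple[np.ndarray, float, np.ndarray, bool] | None = None
    n_used = 0
    for policy in policies:
        targets = _start_targets(s2y, set(comp), policy)
        theta0 = np.concatenate([blk.start(targets) for blk in blocks])
        res = minimize(
            _restricted_ll_and_grad,
            theta0,
            args=(blocks, basis, X, y, logdet_XtX),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-13, "gtol": gtol},
        )
        n_used += 1
        out = (res.x, float(res.fun), res.jac,
               bool(res.success or np.max(np.abs(res.jac)) < 10 * gtol))
        agree = best is not None and abs(out[1] - best[1]) < 1e-4
        if best is None or out[1] < best[1] - 1e-9:
            best = out
        if agree and best[3]:
            break  # two starts found the same optimum
    assert best is not None
    theta, fval, gvec, ok = best
    converged = bool(ok or np.max(np.abs(gvec)) < 1e-3)
    if not converged:
        messages.append("optimizer did not fully converge (gradient norm "
                        f"{np.max(np.abs(gvec)):.2e})")
        logger.warning(messages[-1])

    coeffs: dict[str, float] = {}
    off = 0
    for blk in blocks:
        for name, c in zip(blk.names, blk.coeffs(theta[off: off + blk.n_par])):
            coeffs[name] = float(c)
        off += blk.n_par
    # GLS fixed effects at the optimum
    V = basis.assemble(coeffs)
    cho = cho_factor(V + 1e-10 * np.eye(n), lower=True)
    ViX = cho_solve(cho, X)
    beta = np.linalg.solve(X.T @ ViX, ViX.T @ y)
    fit = FitResult(
        coefficients=coeffs,
        beta=beta,
        loglik=-float(fval),
        converged=converged,
        n=n,
        p=p,
        components=comp,
        collapsed=collapsed,
        messages=messages,
        n_starts_used=n_used,
    )
    if compute_se:
        fit.se = fisher_se(fit, basis, X)
    return fit


def fisher_se(fit: FitResult, basis: ComponentBasis, X: np.ndarray) -> dict[str, float] | None:
    """Standard errors from the expected information of the restricted
    likelihood, I_jk = Tr(P K_j P K_k)/2, evaluated at the REML estimates."""
    n = basis.n
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    names = [nm for nm in fit.coefficients]
    V = basis.assemble(fit.coefficients)
    eye = np.eye(n)
    cho = cho_factor(V + 1e-10 * eye, lower=True)
    Vi = cho_solve(cho, eye)
    ViX = Vi @ X
    P = Vi - ViX @ np.linalg.solve(X.T @ ViX, ViX.T)
    K = {nm: basis.K[nm] for nm in names}
    PK = {nm: P @ K[nm] for nm in names}
    m = len(names)
    info = np.empty((m, m))
    for i, ni in enumerate(names):
        for j, nj in enumerate(names[: i + 1]):
            info[i, j] = info[j, i] = 0.5 * float(np.vdot(PK[ni].T, PK[nj]))
    # components pinned at a boundary can leave the information matrix
    # numerically singular; report SEs for the well-conditioned subset
    out: dict[str, float] = {}
    keep = list(range(m))
    for _ in range(m):
        sub = info[np.ix_(keep, keep)]
        try:
            cov = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            cov = None
        if cov is not None and np.all(np.diag(cov) > 0) and \
                np.linalg.cond(sub) < 1e10:
            for pos, idx in enumerate(keep):
                out[names[idx]] = float(math.sqrt(cov[pos, pos]))
            break
        if len(keep) == 1:
            break
        # drop the row most responsible for the ill conditioning
        w, v = np.linalg.eigh(sub)
        keep.pop(int(np.argmax(np.abs(v[:, 0]))))
    if not out:
        logger.warning("singular Fisher information: standard errors unavailable")
        return None
    dropped = [nm for nm in names if nm not in out]
    if dropped:
        logger.warning("standard errors unavailable for boundary components %s",
                       dropped)
    return out


def variance_partition(fit: FitResult, basis: ComponentBasis) -> dict[str, float]:
    """Proportion of phenotypic variance per component, in percent.

    Numerators are each component's contribution to the sample variance of
    the fitted covariance (for the scaled direct and social genetic bases
    this is the component itself); the denominator is the sample variance of
    the full fitted covariance.
    """
    contrib = {
        name: c * sample_var(basis.K[name]) for name, c in fit.coefficients.items()
    }
    total = sum(contrib.values())
    if total <= 0:
        raise ValueError("fitted covariance has non-positive sample variance")
    return {name: 100.0 * v / total for name, v in contrib.items()}


def lrt_sge(
    y: np.ndarray,
    X: np.ndarray,
    basis: ComponentBasis,
    components: tuple[str, ...] = FULL_COMPONENTS,
    **fit_kw,
) -> tuple[float, FitResult, FitResult]:
    """Restricted likelihood-ratio test for social genetic effects.

    The null model removes the social genetic variance and the direct-social
    genetic covariance but keeps all environmental terms; the statistic is
    referred to a chi-square with 2 degrees of freedom (conservative, since
    the variance sits on the boundary of its parameter space).

    Returns (p_value, full_fit, null_fit).
    """
    null_components = tuple(c for c in components if c not in {"AS", "ADS"})
    full = fit_reml(y, X, basis, components=components, **fit_kw)
    null = fit_reml(y, X, basis, components=null_components, **fit_kw)
    if null.loglik > full.loglik + 1e-6:
        # null nested in full: refit the full model from more starts
        full2 = fit_reml(y, X, basis, components=components, n_starts=3)
        if full2.loglik > full.loglik:
            full = full2
        if null.loglik > full.loglik + 1e-6:
            full.messages.append("null likelihood exceeds full after restarts")
            logger.warning(full.messages[-1])
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    if stat < 1e-8:  # boundary: the social terms added nothing
        stat = 0.0
    p = float(chi2.sf(stat, df=2)) if stat > 0 else 1.0
    return p, full, null
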