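"""Relationship matrices for mixed-model analysis of social genetic effects.

Provides the pedigree numerator relationship matrix A (Wright's tabular
method), the genomic relationship matrix G from centered allele dosages,
the base-population blending G* = 0.95*(a + b*G) + 0.05*A_gg, the
single-step H matrix that combines pedigree and genomic information for
partially genotyped populations, and the sample-variance scaling
sampleVar(M) = Tr(PMP)/(n-1) used to put every variance component of the
social-effects model on a comparable scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Pedigree",
    "GenotypeMatrix",
    "RelationshipMatrix",
    "pedigree_A",
    "genomic_G",
    "blend_G",
    "blend_constants",
    "build_H",
    "sample_var",
    "scale_components",
    "ScaledMatrices",
    "PedigreeError",
    "DegenerateDesignError",
]

#: Blending constants matching average relationship and inbreeding between
#: the pedigree and genomic matrices of the reference heterogeneous-stock
#: colony; used as defaults when no matrices are supplied to re-derive them.
DEFAULT_BLEND_A = 0.015
DEFAULT_BLEND_B = 0.982


class PedigreeError(ValueError):
    """Raised for cyclic pedigrees or references to unknown individuals."""


class DegenerateDesignError(ValueError):
    """Raised when a design matrix has zero sample variance (e.g. no cages)."""


@dataclass
class Pedigree:
    """A three-column pedigree: individual, sire, dam.

    Parent indices are positions into ``ids``; -1 encodes an unknown parent
    (treated as an unrelated, non-inbred founder). Construction validates
    uniqueness of ids and acyclicity, and stores a topological order with
    parents before offspring.
    """

    ids: list[str]
    sire: np.ndarray  # int index into ids, -1 unknown
    dam: np.ndarray
    order: np.ndarray = field(init=False)  # topological order (indices)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise PedigreeError("duplicate individual ids in pedigree")
        for arr in (self.sire, self.dam):
            if arr.shape != (n,):
                raise PedigreeError("parent arrays must match number of ids")
            if np.any(arr >= n) or np.any(arr < -1):
                raise PedigreeError("parent index out of range")
        self.order = self._toposort()

    def _toposort(self) -> np.ndarray:
        """Kahn's algorithm; raises with an offending chain on a cycle."""
        n = len(self.ids)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for i in range(n):
            for p in (self.sire[i], self.dam[i]):
                if p >= 0:
                    children[p].append(i)
                    indeg[i] += 1
        queue = [i for i in range(n) if indeg[i] == 0]
        order = []
        while queue:
            i = queue.pop()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != n:
            stuck = [self.ids[i] for i in range(n) if indeg[i] > 0]
            raise PedigreeError(
                f"pedigree contains a cycle involving: {', '.join(stuck[:10])}"
            )
        return np.asarray(order, dtype=np.int64)

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        """Build from a DataFrame with columns (id, sire, dam).

        '0', 'NA', '', NaN all encode an unknown parent. A parent referenced
        but not listed as an individual is an error.
        """
        cols = list(df.columns[:3])
        ids = [str(v) for v in df[cols[0]]]
        index = {v: i for i, v in enumerate(ids)}
        unknown = {"0", "NA", "", "nan", "None"}

        def parent_idx(v) -> int:
            s = "" if pd.isna(v) else str(v)
            if s in unknown:
                return -1
            if s not in index:
                raise PedigreeError(f"parent id {s!r} not listed as an individual")
            return index[s]

        sire = np.array([parent_idx(v) for v in df[cols[1]]], dtype=np.int64)
        dam = np.array([parent_idx(v) for v in df[cols[2]]], dtype=np.int64)
        return cls(ids=ids, sire=sire, dam=dam)

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        def name(p: int) -> str:
            return self.ids[p] if p >= 0 else "0"

        pd.DataFrame(
            {
                "id": self.ids,
                "sire": [name(p) for p in self.sire],
                "dam": [name(p) for p in self.dam],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeMatrix:
    """Allele dosages (0/1/2 reference-allele counts), individuals x loci.

    Missing dosages are NaN and are mean-imputed per locus before centering.
    """

    ids: list[str]
    loci: list[str]
    dosages: np.ndarray  # float (n, m), entries 0/1/2 or NaN

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.ids) or m != len(self.loci):
            raise ValueError("dosage matrix shape does not match ids/loci")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.all(np.isin(finite, (0.0, 1.0, 2.0))):
            raise ValueError("dosages must be 0, 1, 2, or missing")

    @property
    def freqs(self) -> np.ndarray:
        """Observed reference-allele frequency per locus (missing skipped)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        """Read dosages from a TSV matrix (rows = individuals, columns =
        loci) or a PLINK --recode A style table (FID IID PAT MAT SEX
        PHENOTYPE followed by one additive-coded column per SNP); the
        dialect is detected from the header."""
        with open(path) as fh:
            header = fh.readline()
        first = header.replace("\t", " ").split()
        if first[:2] == ["FID", "IID"]:
            df = pd.read_csv(path, sep=r"\s+")
            ids = [str(v) for v in df["IID"]]
            snp_cols = list(df.columns[6:])
            return cls(ids=ids, loci=snp_cols,
                       dosages=df[snp_cols].to_numpy(dtype=float))
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            ids=[str(i) for i in df.index],
            loci=[str(c) for c in df.columns],
            dosages=df.to_numpy(dtype=float),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.dosages, index=self.ids, columns=self.loci).to_csv(
            path, sep="\t", index_label="id"
        )


@dataclass
class RelationshipMatrix:
    """A symmetric matrix of relationship coefficients with id labels."""

    ids: list[str]
    values: np.ndarray
    kind: str = "A"  # A | G_raw | G_star | H | scaled

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > 1e-8:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym:.2e})")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, ids) -> "RelationshipMatrix":
        idx = {v: i for i, v in enumerate(self.ids)}
        sel = np.array([idx[str(i)] for i in ids], dtype=np.int64)
        return RelationshipMatrix(
            ids=[str(i) for i in ids],
            values=self.values[np.ix_(sel, sel)],
            kind=self.kind,
        )

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset(
                "ids", data=np.array(self.ids, dtype=h5py.string_dtype())
            )
            f.attrs["kind"] = self.kind

    @classmethod
    def from_hdf5(cls, path) -> "RelationshipMatrix":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                ids=[s.decode() if isinstance(s, bytes) else str(s) for s in f["ids"][:]],
                values=f["values"][:],
                kind=str(f.attrs.get("kind", "A")),
            )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id"
        )


def pedigree_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    A_ii = 1 + F_i with F_i = A(sire_i, dam_i)/2; A_ij for j earlier than i
    is the mean of i's parental relationships with j. Unknown parents
    contribute zero relationship.
    """
    n = ped.n
    A = np.zeros((n, n))
    for i in ped.order:
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(n)
        if s >= 0:
            row += 0.5 * A[s]
        if d >= 0:
            row += 0.5 * A[d]
        A[i, :] = row
        A[:, i] = row
        f = 0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + f
    return RelationshipMatrix(ids=list(ped.ids), values=A, kind="A")


def genomic_G(geno: GenotypeMatrix) -> RelationshipMatrix:
    """Genomic relationship matrix G = M M' / (2 sum p_i q_i).

    Rows of M are dosages centered by 2p using observed allele frequencies;
    monomorphic loci are dropped (logged) before forming the denominator.
    Missing dosages are mean-imputed per locus prior to centering.
    """
    X = geno.dosages.copy()
    p = np.nanmean(X, axis=0) / 2.0
    # mean imputation == setting missing centered entries to zero
    for j in np.where(np.any(~np.isfinite(X), axis=0))[0]:
        miss = ~np.isfinite(X[:, j])
        X[miss, j] = 2.0 * p[j]
    poly = (p > 0.0) & (p < 1.0)
    n_mono = int(np.sum(~poly))
    if n_mono:
        logger.info("genomic_G: dropping %d monomorphic loci", n_mono)
    if not np.any(poly):
        raise ValueError("all loci monomorphic: zero denominator for G")
    M = X[:, poly] - 2.0 * p[poly]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    G = (M @ M.T) / denom
    return RelationshipMatrix(ids=list(geno.ids), values=G, kind="G_raw")


def blend_constants(
    G_raw: RelationshipMatrix, A_gg: RelationshipMatrix
) -> tuple[float, float]:
    """Solve for (a, b) so that b*G + a matches A_gg in mean diagonal and
    mean off-diagonal (drift / lost-heterozygosity correction)."""
    if G_raw.ids != A_gg.ids:
        raise ValueError("G and A_gg must cover the same individuals")
    n = G_raw.n
    dG, dA = np.mean(np.diag(G_raw.values)), np.mean(np.diag(A_gg.values))
    off = ~np.eye(n, dtype=bool)
    oG, oA = np.mean(G_raw.values[off]), np.mean(A_gg.values[off])
    if abs(dG - oG) < 1e-12:
        raise ValueError("G has no diagonal/off-diagonal contrast; cannot solve for (a, b)")
    b = (dA - oA) / (dG - oG)
    a = dA - b * dG
    return float(a), float(b)


def blend_G(
    G_raw: RelationshipMatrix,
    A_gg: RelationshipMatrix,
    a: float | None = DEFAULT_BLEND_A,
    b: float | None = DEFAULT_BLEND_B,
) -> RelationshipMatrix:
    """G* = 0.95*(a + b*G) + 0.05*A_gg, elementwise.

    The 5% pedigree admixture guarantees G* is invertible even when more
    individuals than loci are genotyped. Pass ``a=None``/``b=None`` to derive
    the constants from the matrices via :func:`blend_constants`.
    """
    if list(G_raw.ids) != list(A_gg.ids):
        raise ValueError("G and A_gg must cover the same individuals in the same order")
    if a is None or b is None:
        a, b = blend_constants(G_raw, A_gg)
    values = 0.95 * (a + b * G_raw.values) + 0.05 * A_gg.values
    return RelationshipMatrix(ids=list(G_raw.ids), values=values, kind="G_star")


def _chol_inverse(M: np.ndarray, label: str) -> np.ndarray:
    """Symmetric PD inverse via Cholesky, with escalating diagonal jitter.

    Jitter steps 1e-10 -> 1e-6 are logged; total failure raises with a
    condition-number report.
    """
    from scipy.linalg import cho_factor, cho_solve

    n = M.shape[0]
    eye = np.eye(n)
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            c = cho_factor(M + jitter * eye, lower=True)
        except np.linalg.LinAlgError:
            continue
        except Exception:
            continue
        if jitter:
            logger.warning("inverting %s required diagonal jitter %g", label, jitter)
        return cho_solve(c, eye)
    cond = float(np.linalg.cond(M))
    raise np.linalg.LinAlgError(
        f"{label} is singular (condition number {cond:.3e}); cannot invert"
    )


def build_H(
    A: RelationshipMatrix,
    G_star: RelationshipMatrix,
    genotyped_ids,
) -> RelationshipMatrix:
    """Single-step relationship matrix H for a partially genotyped population.

    H^-1 = A^-1 + blockdiag(0, G*^-1 - A_gg^-1) on the (non-genotyped,
    genotyped) partition, then H = (H^-1)^-1, returned in A's id order.
    With no genotyped individuals H = A; with everyone genotyped H = G*.
    """
    genotyped = [str(i) for i in genotyped_ids]
    pos = {v: i for i, v in enumerate(A.ids)}
    missing = [g for g in genotyped if g not in pos]
    if missing:
        raise ValueError(f"genotyped ids not in A: {missing[:5]}")
    if not genotyped:
        return RelationshipMatrix(ids=list(A.ids), values=A.values.copy(), kind="H")
    if list(G_star.ids) != genotyped:
        G_star = G_star.subset(genotyped)
    gi = np.array([pos[g] for g in genotyped], dtype=np.int64)
    Ainv = _chol_inverse(A.values, "A")
    A_gg = A.values[np.ix_(gi, gi)]
    Ginv = _chol_inverse(G_star.values, "G*")
    Agg_inv = _chol_inverse(A_gg, "A_gg")
    Hinv = Ainv.copy()
    Hinv[np.ix_(gi, gi)] += Ginv - Agg_inv
    H = _chol_inverse(Hinv, "H^-1")
    H = 0.5 * (H + H.T)
    return RelationshipMatrix(ids=list(A.ids), values=H, kind="H")


def sample_var(M: np.ndarray | RelationshipMatrix) -> float:
    """sampleVar(M) = Tr(P M P)/(n-1) with P = I - 11'/n the centering matrix.

    Equals the expected sample variance of a draw with covariance M;
    sampleVar(I) = 1 for any n.
    """
    V = M.values if isinstance(M, RelationshipMatrix) else np.asarray(M, dtype=float)
    n = V.shape[0]
    if V.ndim != 2 or V.shape[1] != n:
        raise ValueError("sample_var requires a square matrix")
    if n < 2:
        raise ValueError("sample_var requires n >= 2")
    # Tr(PMP) = Tr(MP) by idempotence of P = sum of M's diagonal minus the
    # grand mean contribution
    return float((np.trace(V) - V.sum() / n) / (n - 1))


@dataclass
class ScaledMatrices:
    """The scaled relationship/identity matrices entering the phenotype
    covariance, together with the scale factors used."""

    H1: np.ndarray
    H2: np.ndarray
    H3: np.ndarray
    I1: np.ndarray
    I2: np.ndarray
    I3: np.ndarray
    I4: np.ndarray
    var_H: float
    var_ZHZ: float
    var_ZZ: float
    var_WW: float


def scale_components(H: RelationshipMatrix | np.ndarray, Z: np.ndarray, W: np.ndarray) -> ScaledMatrices:
    """Scale H and I so each variance component contributes its own value to
    the sample phenotypic variance.

    H1 = H/sampleVar(H) acts through the focal animal; H3 = H/sampleVar(ZHZ')
    through cage mates; H2 = H/sqrt(sampleVar(H)*sampleVar(ZHZ')) carries the
    direct-social covariance. I1..I3 are the environmental analogues and
    I4 = I/sampleVar(WW') the cage-effect scaling.
    """
    Hv = H.values if isinstance(H, RelationshipMatrix) else np.asarray(H, dtype=float)
    Z = np.asarray(Z, dtype=float)
    W = np.asarray(W, dtype=float)
    n = Hv.shape[0]
    if Z.shape != (n, n):
        raise ValueError("Z must be n x n over the same individuals as H")
    if np.any(np.diag(Z) != 0):
        raise ValueError("cage-mate indicator Z must have a zero diagonal")
    eye = np.eye(n)
    vH = sample_var(Hv)
    vZHZ = sample_var(Z @ Hv @ Z.T)
    vZZ = sample_var(Z @ Z.T)
    vWW = sample_var(W @ W.T)
    for name, v in (("sampleVar(H)", vH), ("sampleVar(ZHZ')", vZHZ),
                    ("sampleVar(ZZ')", vZZ), ("sampleVar(WW')", vWW)):
        if v <= 0:
            raise DegenerateDesignError(f"{name} = {v:.3g} <= 0: degenerate design")
    return ScaledMatrices(
        H1=Hv / vH,
        H2=Hv / np.sqrt(vH * vZHZ),
        H3=Hv / vZHZ,
        I1=eye.copy(),
        I2=eye / np.sqrt(vZZ),
        I3=eye / vZZ,
        I4=np.eye(W.shape[1]) / vWW,  # identity over cages
        var_H=vH,
        var_ZHZ=vZHZ,
        var_ZZ=vZZ,
        var_WW=vWW,
    )
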