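"""Synthetic populations, cage assignments and phenotypes.

Emulates the statistical structure of a group-housed outbred mouse colony:
a pedigree of many full-sib families, biallelic genotypes dropped through
the pedigree under Mendelian inheritance, cage assignment that co-houses
relatives more often than chance (so direct and social genetic effects are
correlated by design), and phenotypes drawn from the full social-effects
model with stated variance proportions. Also generates the paired
two-inbred-strain experiment (B6/B6, B6/D2, D2/D2 cages).

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixed_model import CageDesign, ComponentBasis, VarianceComponents
from .relatedness import (
    GenotypeMatrix,
    Pedigree,
    RelationshipMatrix,
    ScaledMatrices,
    blend_G,
    build_H,
    genomic_G,
    pedigree_A,
    scale_components,
)

__all__ = [
    "PopulationSpec",
    "SimulationSpec",
    "Population",
    "simulate_population",
    "assign_cages",
    "PhenotypeSimulator",
    "simulate_phenotype",
    "simulate_inbred_experiment",
    "SCENARIOS",
    "scenario",
    "ReferenceDesign",
    "build_reference_design",
]


@dataclass
class PopulationSpec:
    """Shape of the synthetic pedigree-structured population."""

    n_families: int = 200
    family_size: int = 3
    n_loci: int = 2000
    founder_freq: tuple[float, float] = (0.1, 0.9)
    generations: int = 1

    def __post_init__(self) -> None:
        if min(self.n_families, self.family_size, self.n_loci) < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.founder_freq
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("founder frequency range must lie inside (0, 1)")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


@dataclass
class Population:
    """A simulated population: pedigree, genotypes, and the housed cohort
    (the final generation) with its full-sib family labels."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    cohort: list[str]
    family: dict[str, int]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_population(spec: PopulationSpec, seed=0) -> Population:
    """Found a population in Hardy-Weinberg equilibrium and gene-drop.

    Founders are drawn at per-locus frequencies uniform on the configured range;
    each subsequent generation pairs parents at random and every pair
    produces ``family_size`` full sibs, each inheriting one allele per
    parent per locus. ``generations=0`` returns founders only (A = I).
    """
    rng = _rng(seed)
    freqs = rng.uniform(*spec.founder_freq, size=spec.n_loci)
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    dosages: list[np.ndarray] = []

    def add(name: str, s: int, d: int, dose: np.ndarray) -> int:
        ids.append(name)
        sire.append(s)
        dam.append(d)
        dosages.append(dose)
        return len(ids) - 1

    n_founders = 2 * spec.n_families
    current = [
        add(f"G0_{i:04d}", -1, -1,
            rng.binomial(2, freqs).astype(float))
        for i in range(n_founders)
    ]
    family_of: dict[str, int] = {}
    for g in range(1, spec.generations + 1):
        perm = rng.permutation(len(current))
        nxt: list[int] = []
        for fam in range(spec.n_families):
            s = current[perm[2 * fam]]
            d = current[perm[2 * fam + 1]]
            for k in range(spec.family_size):
                # one allele transmitted per parent: Bernoulli(dosage/2)
                t_s = (rng.random(spec.n_loci) < dosages[s] / 2.0).astype(float)
                t_d = (rng.random(spec.n_loci) < dosages[d] / 2.0).astype(float)
                idx = add(f"G{g}_{fam:04d}_{k}", s, d, t_s + t_d)
                nxt.append(idx)
                if g == spec.generations:
                    family_of[ids[idx]] = fam
        current = nxt
    if spec.generations == 0:
        family_of = {ids[i]: i for i in current}
    ped = Pedigree(ids=list(ids), sire=np.array(sire), dam=np.array(dam))
    geno = GenotypeMatrix(ids=list(ids),
                          loci=[f"snp{j:05d}" for j in range(spec.n_loci)],
                          dosages=np.vstack(dosages))
    cohort = [ids[i] for i in current]
    return Population(pedigree=ped, genotypes=geno, cohort=cohort, family=family_of)


def assign_cages(
    individuals: list[str],
    family: dict[str, int],
    cage_sizes: int | list[int] | dict[int, float] = 3,
    cohousing_weight: float = 0.5,
    seed=0,
) -> CageDesign:
    """Fill cages preferring same-family animals with the given weight.

    Each cage is seeded with a random unassigned animal; every further slot
    is filled by a same-family animal with probability ``cohousing_weight``
    (when one is available) and by a uniform draw otherwise. Weight 0 gives
    exchangeable (random) assignment; weight 1 packs full-sib groups, which
    reproduces the above-average within-cage relatedness of real colonies.
    """
    if not 0.0 <= cohousing_weight <= 1.0:
        raise ValueError("cohousing_weight must lie in [0, 1]")
    rng = _rng(seed)
    n = len(individuals)
    if isinstance(cage_sizes, int):
        sizes: list[int] = []
        while sum(sizes) < n:
            sizes.append(cage_sizes)
    elif isinstance(cage_sizes, dict):
        ks = np.array(sorted(cage_sizes))
        ps = np.array([cage_sizes[k] for k in ks], dtype=float)
        ps = ps / ps.sum()
        sizes = []
        while sum(sizes) < n:
            sizes.append(int(rng.choice(ks, p=ps)))
    else:
        sizes = [int(s) for s in cage_sizes]
        if sum(sizes) < n:
            raise ValueError("cage size list does not cover all individuals")
    if any(s < 1 for s in sizes):
        raise ValueError("cage sizes must be >= 1")
    # trim the final cage to fit exactly
    total = 0
    trimmed: list[int] = []
    for s in sizes:
        if total + s >= n:
            trimmed.append(n - total)
            total = n
            break
        trimmed.append(s)
        total += s
    if total != n:
        raise ValueError("infeasible cage partition")

    unassigned = set(range(n))
    fam = np.array([family.get(str(i), -1) for i in individuals])
    by_family: dict[int, set[int]] = {}
    for i, f in enumerate(fam):
        by_family.setdefault(int(f), set()).add(i)
    cage_of = np.empty(n, dtype=np.int64)
    for c, s in enumerate(trimmed):
        pool = list(unassigned)
        first = int(pool[rng.integers(len(pool))])
        members = [first]
        unassigned.discard(first)
        by_family[int(fam[first])].discard(first)
        for _ in range(s - 1):
            sibs = by_family[int(fam[first])]
            if sibs and rng.random() < cohousing_weight:
                pick = int(rng.choice(sorted(sibs)))
            else:
                pool = sorted(unassigned)
                pick = int(pool[rng.integers(len(pool))])
            members.append(pick)
            unassigned.discard(pick)
            by_family[int(fam[pick])].discard(pick)
        cage_of[members] = c
    return CageDesign(ids=[str(i) for i in individuals],
                      cages=[f"cage{c:04d}" for c in cage_of])


class PhenotypeSimulator:
    """Draws phenotype replicates from the full social-effects model.

    The direct and social genetic effects (a_D, a_S) are drawn jointly from
    the 2n-dimensional normal with covariance
    [[s2_AD H1, s_ADS H2], [s_ADS H2', s2_AS H3]] (a small diagonal jitter
    stabilizes the factorization); the environmental pair (e_D, e_S)
    analogously with identity blocks; cage effects from s2_C I4. Phenotypes
    assemble as y = X b + a_D + Z a_S + e_D + Z e_S + W c. Under the
    sample-variance scaling each component contributes its stated proportion
    to the expected sample phenotypic variance.
    """

    def __init__(
        self,
        vc: VarianceComponents,
        scaled: ScaledMatrices,
        cages: CageDesign,
        X: np.ndarray | None = None,
        b: np.ndarray | None = None,
        jitter: float = 1e-8,
    ):
        n = scaled.H1.shape[0]
        if cages.n != n:
            raise ValueError("cage design does not match relationship matrices")
        self.vc = vc
        self.Z = cages.Z
        self.W = cages.W
        self.n = n
        if X is None:
            X = np.ones((n, 1))
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.b = np.zeros(self.X.shape[1]) if b is None else np.asarray(b, dtype=float)
        self.mean = self.X @ self.b

        g = np.array([[vc.sigma2_AD, vc.sigma_ADS], [vc.sigma_ADS, vc.sigma2_AS]])
        if np.any(np.linalg.eigvalsh(g) < -1e-10):
            raise ValueError("genetic block is indefinite (|rho_ADS| > 1)")
        self._Lg = None
        if np.any(g != 0):
            big = np.block([
                [vc.sigma2_AD * scaled.H1, vc.sigma_ADS * scaled.H2],
                [vc.sigma_ADS * scaled.H2.T, vc.sigma2_AS * scaled.H3],
            ])
            self._Lg = np.linalg.cholesky(big + jitter * np.eye(2 * n))
        e = np.array([
            [vc.sigma2_ED, vc.sigma_EDS / math.sqrt(scaled.var_ZZ)],
            [vc.sigma_EDS / math.sqrt(scaled.var_ZZ), vc.sigma2_ES / scaled.var_ZZ],
        ])
        if np.any(np.linalg.eigvalsh(e) < -1e-12):
            raise ValueError("environmental block is indefinite (|rho_EDS| > 1)")
        self._Le = None if not np.any(e) else np.linalg.cholesky(e + 1e-14 * np.eye(2))
        self._sd_c = math.sqrt(vc.sigma2_C / scaled.var_WW)

    def draw(self, seed=0, n_reps: int = 1) -> np.ndarray:
        """Return an (n, n_reps) matrix of phenotype replicates."""
        rng = _rng(seed)
        n = self.n
        y = np.tile(self.mean[:, None], (1, n_reps)).astype(float)
        if self._Lg is not None:
            a = self._Lg @ rng.standard_normal((2 * n, n_reps))
            y += a[:n] + self.Z @ a[n:]
        if self._Le is not None:
            eps = rng.standard_normal((2, n, n_reps))
            e_pair = np.einsum("ij,jnr->inr", self._Le, eps)
            y += e_pair[0] + self.Z @ e_pair[1]
        if self._sd_c > 0:
            c = self._sd_c * rng.standard_normal((self.W.shape[1], n_reps))
            y += self.W @ c
        return y


def simulate_phenotype(
    vc: VarianceComponents,
    scaled: ScaledMatrices,
    cages: CageDesign,
    X: np.ndarray | None = None,
    b: np.ndarray | None = None,
    seed=0,
) -> np.ndarray:
    """One phenotype replicate from the full model (see PhenotypeSimulator)."""
    return PhenotypeSimulator(vc, scaled, cages, X=X, b=b).draw(seed=seed, n_reps=1)[:, 0]


# ---------------------------------------------------------------------------
# The simulation-study scenarios
# ---------------------------------------------------------------------------

#: Variance proportions (DGE, SGE, rho_ADS, DEE, SEE, rho_EDS, cage) of the
#: two headline simulation scenarios: parameters averaged over all organismal
#: phenotypes, and over the six phenotypes with strongest social genetic
#: effects.
SCENARIOS: dict[str, VarianceComponents] = {
    "average": VarianceComponents.from_proportions(0.15, 0.04, 0.5, 0.52, 0.0, 0.0, 0.22),
    "high-sge": VarianceComponents.from_proportions(0.05, 0.27, 0.92, 0.05, 0.0, 0.0, 0.51),
}

_GRID_DEFAULTS = dict(dge=0.15, sge=0.04, rho_ads=0.5, dee=0.52, see=0.0,
                      rho_eds=0.0, cage=0.22)


def scenario(name: str, **overrides) -> VarianceComponents:
    """Look up a named scenario, or build a grid point: e.g.
    ``scenario("grid", sge=0.30)`` varies one parameter holding the others
    at their all-phenotype averages."""
    if name in SCENARIOS and not overrides:
        return SCENARIOS[name]
    if name == "grid" or overrides:
        params = dict(_GRID_DEFAULTS)
        if name in SCENARIOS:
            base = SCENARIOS[name]
            params = dict(dge=base.sigma2_AD, sge=base.sigma2_AS,
                          rho_ads=0.0 if base.sigma2_AS == 0 else base.rho_ads,
                          dee=base.sigma2_ED, see=base.sigma2_ES,
                          rho_eds=0.0, cage=base.sigma2_C)
        params.update(overrides)
        if params["sge"] == 0 or params["dge"] == 0:
            params["rho_ads"] = 0.0
        if params["see"] == 0 or params["dee"] == 0:
            params["rho_eds"] = 0.0
        return VarianceComponents.from_proportions(**params)
    raise KeyError(f"unknown scenario {name!r}")


@dataclass
class SimulationSpec:
    """A replicated simulation experiment under one parameter set."""

    vc: VarianceComponents
    n_reps: int = 100
    base_seed: int = 0
    cage_sizes: int | list[int] | dict[int, float] = 3
    cohousing_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("replicate count must be >= 1")


# ---------------------------------------------------------------------------
# The reference design used by the simulation study
# ---------------------------------------------------------------------------

#: a realistic group-housing size mix (groups of two to seven, mostly four
#: to six) for callers who want variable cage sizes; note that group-size
#: variation lets the social-environmental and cage variances absorb the
#: size-correlated part of the social genetic signal, trading test power
#: for a richer environmental model
REALISTIC_CAGE_SIZES: dict[int, float] = {2: 0.06, 3: 0.12, 4: 0.28, 5: 0.30,
                                          6: 0.18, 7: 0.06}


@dataclass
class ReferenceDesign:
    """A housed cohort with its single-step relatedness and scaled matrices."""

    population: Population
    cages: CageDesign
    H: RelationshipMatrix
    scaled: ScaledMatrices
    basis: ComponentBasis
    genotyped: list[str] = field(default_factory=list)


def build_reference_design(
    n_families: int = 200,
    family_size: int = 3,
    n_loci: int = 2000,
    cage_sizes: int | list[int] | dict[int, float] = 3,
    cohousing_weight: float = 0.5,
    genotyped_fraction: float = 0.8,
    seed=0,
) -> ReferenceDesign:
    """Build the package's reference cohort: 600 housed mice from 200
    full-sib families, cages of three with sibling co-housing, 80% of the
    cohort genotyped so relatedness flows through the single-step H matrix.

    The constant cage size triggers the fitter's documented collapse of
    the environmental terms to an exchangeable within-cage residual; pass
    a size mix (e.g. :data:`REALISTIC_CAGE_SIZES`) for variable groups.
    The blending constants (a, b) are derived from the synthetic pedigree
    and genotypes rather than taken from any particular colony.
    """
    rng = _rng(seed)
    pop = simulate_population(
        PopulationSpec(n_families=n_families, family_size=family_size, n_loci=n_loci),
        seed=rng,
    )
    cages = assign_cages(pop.cohort, pop.family, cage_sizes=cage_sizes,
                         cohousing_weight=cohousing_weight, seed=rng)
    A = pedigree_A(pop.pedigree)
    n_geno = int(round(genotyped_fraction * len(pop.cohort)))
    genotyped = sorted(rng.choice(pop.cohort, size=n_geno, replace=False)) if n_geno else []
    if genotyped:
        idx = {v: i for i, v in enumerate(pop.genotypes.ids)}
        sel = [idx[g] for g in genotyped]
        sub = GenotypeMatrix(ids=list(genotyped),
                             loci=list(pop.genotypes.loci),
                             dosages=pop.genotypes.dosages[sel])
        G = genomic_G(sub)
        A_gg = A.subset(genotyped)
        G_star = blend_G(G, A_gg, a=None, b=None)
        H_all = build_H(A, G_star, genotyped)
    else:
        H_all = RelationshipMatrix(ids=list(A.ids), values=A.values.copy(), kind="H")
    H = H_all.subset(cages.ids)
    scaled = scale_components(H, cages.Z, cages.W)
    basis = ComponentBasis(scaled, cages.Z, cages.W)
    return ReferenceDesign(population=pop, cages=cages, H=H, scaled=scaled,
                           basis=basis, genotyped=list(genotyped))


# ---------------------------------------------------------------------------
# Paired two-strain experiment
# ---------------------------------------------------------------------------

def simulate_inbred_experiment(
    beta_d: float = 0.0,
    beta_s: float = 0.0,
    beta_ds: float = 0.0,
    rho: float = 0.0,
    sigma2_e: float = 1.0,
    n_bb: int = 14,
    n_bd: int = 16,
    n_dd: int = 13,
    intercept: float = 0.0,
    seed=0,
) -> pd.DataFrame:
    """Simulate the paired two-inbred-strain experiment.

    Cage counts default to the reference design (14 B6/B6, 16 B6/D2 and
    13 D2/D2 cages). Both animals of a cage are focal; residuals within a
    cage are bivariate normal with correlation rho. A strain-specific social
    effect is induced by ``beta_ds`` (the interaction term), which adds to
    the cage-mate effect only for D2 focal animals with D2 cage mates.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    if min(n_bb, n_bd, n_dd) < 0 or n_bb + n_bd + n_dd < 1:
        raise ValueError("at least one cage is required")
    rng = _rng(seed)
    rows = []
    cage_no = 0
    L = np.linalg.cholesky(
        sigma2_e * (np.array([[1.0, rho], [rho, 1.0]]) + 1e-12 * np.eye(2))
    )
    for group, count in (("BB", n_bb), ("BD", n_bd), ("DD", n_dd)):
        strains = {"BB": (0, 0), "BD": (0, 1), "DD": (1, 1)}[group]
        for _ in range(count):
            e = L @ rng.standard_normal(2)
            cage = f"{group}{cage_no:03d}"
            for a in (0, 1):
                xf, xcm = strains[a], strains[1 - a]
                y = (intercept + beta_d * xf + beta_s * xcm
                     + beta_ds * xf * xcm + e[a])
                rows.append({
                    "focal_id": f"m{cage_no:03d}_{a}",
                    "focal_strain": xf,
                    "cagemate_strain": xcm,
                    "cage": cage,
                    "value": y,
                })
            cage_no += 1
    return pd.DataFrame(rows)
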