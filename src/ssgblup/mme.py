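"""Henderson mixed-model equations for the three GBLUP model variants.

The evaluation model is y = X beta + Z u + W p + e with Var(u) given
by a relationship matrix (H for single-step, A for pedigree BLUP, G
for genotyped-only comparators), Var(p) = I sigma2_p per breed, and
heteroscedastic residuals Var(e_i) = sigma2_e / w_i weighted by
lactation weights.  Three variants are supported:

- ``multi_breed``: both breeds pooled as one population, one set of
  genetic parameters, pooled-frequency H.
- ``within_breed``: each breed evaluated separately with its own
  parameters and breed-frequency H.
- ``multiple_trait``: the trait in one breed treated as a distinct,
  correlated trait; Var(u) = T (x) H with T the 2x2 breed genetic
  covariance matrix, trait-major equation ordering.

Variance components are treated as known at evaluation time; REML
estimation lives in :mod:`ssgblup.reml`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .genomic import HInverse
from .pedigree import UNKNOWN, PedigreeTable

__all__ = [
    "VarianceComponents",
    "ModelSpec",
    "Design",
    "MMESystem",
    "MMESolution",
    "build_design",
    "assemble_mme",
    "solve_mme",
    "compute_pev",
    "reliability_from_pev",
    "run_evaluation",
    "run_within_breed",
    "pedigree_subset",
    "EvaluationResult",
]


class VarianceError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


@dataclass
class VarianceComponents:
    """Breed-indexed variance components for one trait.

    ``sigma2_u``, ``sigma2_p`` and ``sigma2_e`` are pairs ordered like
    ``breeds``; ``sigma_u_sa`` is the across-breed genetic covariance.
    For single-population (multi-breed) use, both entries of each pair
    are equal and the first is used.
    """

    breeds: tuple
    sigma2_u: tuple
    sigma2_e: tuple
    sigma2_p: tuple = (0.0, 0.0)
    sigma_u_sa: float = 0.0

    def __post_init__(self):
        if any(v <= 0 for v in self.sigma2_u) or any(v <= 0 for v in self.sigma2_e):
            raise VarianceError("genetic and residual variances must be positive")
        if any(v < 0 for v in self.sigma2_p):
            raise VarianceError("permanent-environment variances must be non-negative")

    @classmethod
    def single(cls, sigma2_u, sigma2_e, sigma2_p=0.0, breeds=("alpine", "saanen")):
        return cls(
            breeds=tuple(breeds),
            sigma2_u=(sigma2_u, sigma2_u),
            sigma2_e=(sigma2_e, sigma2_e),
            sigma2_p=(sigma2_p, sigma2_p),
            sigma_u_sa=sigma2_u,  # rho = 1 within one population
        )

    @property
    def rho(self) -> float:
        return self.sigma_u_sa / np.sqrt(self.sigma2_u[0] * self.sigma2_u[1])

    def T(self) -> np.ndarray:
        """2x2 across-breed genetic covariance matrix."""
        return np.array(
            [
                [self.sigma2_u[0], self.sigma_u_sa],
                [self.sigma_u_sa, self.sigma2_u[1]],
            ]
        )

    def with_rho(self, rho: float) -> "VarianceComponents":
        """Same variances with the across-breed correlation replaced."""
        if not (-1.0 < rho < 1.0):
            raise VarianceError("|rho| must be < 1 for an invertible T; cap at 0.99")
        cov = rho * np.sqrt(self.sigma2_u[0] * self.sigma2_u[1])
        return VarianceComponents(
            self.breeds, self.sigma2_u, self.sigma2_e, self.sigma2_p, cov
        )

    def heritability(self) -> tuple:
        return tuple(
            u / (u + p + e)
            for u, p, e in zip(self.sigma2_u, self.sigma2_p, self.sigma2_e)
        )


@dataclass
class ModelSpec:
    """Which model variant to run and how records map to effects."""

    kind: str  # multi_breed | within_breed | multiple_trait
    trait: str = "milk_yield"
    fixed_effects: tuple = ("herd", "parity")
    intercept: bool = True
    repeatable: bool = True  # include permanent-environment effects
    weight_col: str = "weight"
    rho_mode: str | float | None = None  # for multiple_trait reporting
    breed_fixed: bool = True  # multi_breed: include breed as fixed effect

    def __post_init__(self):
        if self.kind not in ("multi_breed", "within_breed", "multiple_trait"):
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass
class Design:
    """Incidence structures tying records to equations."""

    X: sp.csr_matrix
    Z: sp.csr_matrix
    W: sp.csr_matrix | None
    y: np.ndarray
    weights: np.ndarray
    rec_breed: np.ndarray  # int index into vc.breeds per record
    n_animals: int
    n_traits: int
    pe_animal_idx: np.ndarray  # pedigree index per PE equation
    pe_breed: np.ndarray
    fixed_labels: list
    ped: PedigreeTable
    breeds: tuple


def _factor_columns(df: pd.DataFrame, factors, intercept: bool, prefix: str = ""):
    """Cell-means dummy coding with one reference level per factor.

    With an intercept every factor drops its first (sorted) level;
    without one the first factor keeps all its levels.  Empty levels
    simply never appear (they are dropped by construction).
    """
    n = len(df)
    cols: list[sp.csr_matrix] = []
    labels: list[str] = []
    if intercept:
        cols.append(sp.csr_matrix(np.ones((n, 1))))
        labels.append(prefix + "intercept")
    first_free = not intercept
    for f in factors:
        if f not in df.columns:
            raise KeyError(f"fixed-effect column {f!r} missing from phenotypes")
        codes, levels = pd.factorize(df[f], sort=True)
        drop = 0 if first_free else 1
        first_free = False
        keep_levels = levels[drop:]
        if len(keep_levels) == 0:
            continue
        level_pos = {lv: k for k, lv in enumerate(keep_levels)}
        rows, ccols = [], []
        for i, c in enumerate(codes):
            lv = levels[c]
            if lv in level_pos:
                rows.append(i)
                ccols.append(level_pos[lv])
        mat = sp.csr_matrix(
            (np.ones(len(rows)), (rows, ccols)), shape=(n, len(keep_levels))
        )
        cols.append(mat)
        labels.extend(f"{prefix}{f}={lv}" for lv in keep_levels)
    if not cols:
        return sp.csr_matrix((n, 0)), []
    return sp.hstack(cols, format="csr"), labels


def build_design(
    phenos: pd.DataFrame, spec: ModelSpec, ped: PedigreeTable, breeds: tuple | None = None
) -> Design:
    """Incidence matrices X (fixed), Z (genetic) and W (permanent env.).

    Every pedigree animal gets a genetic equation whether phenotyped or
    not; PE equations exist only for animals with records.  For the
    multiple-trait variant each record loads the genetic equation of
    its own breed-trait (trait-major ordering: trait block, then
    animal).
    """
    if breeds is None:
        breeds = tuple(sorted(set(ped.breed)))
    ph = phenos.reset_index(drop=True)
    animal_idx = ped.indices_of(ph["animal"])
    breed_pos = {b: i for i, b in enumerate(breeds)}
    try:
        rec_breed = np.array([breed_pos[b] for b in ph["breed"]], dtype=np.int64)
    except KeyError as exc:
        raise KeyError(f"record breed {exc.args[0]!r} not in model breeds {breeds}") from None

    n = len(ph)
    N = ped.n
    n_traits = 2 if spec.kind == "multiple_trait" else 1

    if spec.kind == "multiple_trait":
        blocks = []
        labels: list = []
        rows_order = []
        for b, bname in enumerate(breeds):
            m = rec_breed == b
            Xb, lb = _factor_columns(ph[m], spec.fixed_effects, spec.intercept, prefix=f"{bname}:")
            blocks.append((np.nonzero(m)[0], Xb))
            labels.extend(lb)
        p = sum(Xb.shape[1] for _, Xb in blocks)
        rr, cc, vv = [], [], []
        off = 0
        for rows, Xb in blocks:
            coo = Xb.tocoo()
            rr.append(rows[coo.row])
            cc.append(coo.col + off)
            vv.append(coo.data)
            off += Xb.shape[1]
        X = sp.csr_matrix(
            (np.concatenate(vv), (np.concatenate(rr), np.concatenate(cc))), shape=(n, p)
        )
        zcols = rec_breed * N + animal_idx
    else:
        factors = list(spec.fixed_effects)
        if spec.kind == "multi_breed" and spec.breed_fixed and len(set(ph["breed"])) > 1:
            factors = ["breed"] + factors
        X, labels = _factor_columns(ph, tuple(factors), spec.intercept)
        zcols = animal_idx

    Z = sp.csr_matrix((np.ones(n), (np.arange(n), zcols)), shape=(n, n_traits * N))

    W = None
    pe_animal_idx = np.array([], dtype=np.int64)
    pe_breed = np.array([], dtype=np.int64)
    if spec.repeatable:
        pe_animals, pe_codes = np.unique(animal_idx, return_inverse=True)
        W = sp.csr_matrix(
            (np.ones(n), (np.arange(n), pe_codes)), shape=(n, len(pe_animals))
        )
        pe_animal_idx = pe_animals
        first_rec = np.zeros(len(pe_animals), dtype=np.int64)
        first_rec[pe_codes[::-1]] = np.arange(n)[::-1]
        pe_breed = rec_breed[first_rec]

    weights = (
        ph[spec.weight_col].to_numpy(float)
        if spec.weight_col in ph.columns
        else np.ones(n)
    )
    return Design(
        X=X,
        Z=Z,
        W=W,
        y=ph["value"].to_numpy(float),
        weights=weights,
        rec_breed=rec_breed,
        n_animals=N,
        n_traits=n_traits,
        pe_animal_idx=pe_animal_idx,
        pe_breed=pe_breed,
        fixed_labels=labels,
        ped=ped,
        breeds=breeds,
    )


@dataclass
class MMESystem:
    """Assembled symmetric system C s = rhs with an equation index map."""

    C: sp.csr_matrix
    rhs: np.ndarray
    n_fixed: int
    n_u: int
    n_pe: int
    design: Design
    spec: ModelSpec
    vc: VarianceComponents

    @property
    def n_eq(self) -> int:
        return self.n_fixed + self.n_u + self.n_pe

    def u_slice(self) -> slice:
        return slice(self.n_fixed, self.n_fixed + self.n_u)


def _as_sparse(rel_inv) -> sp.csr_matrix:
    if isinstance(rel_inv, HInverse):
        return rel_inv.to_sparse()
    if sp.issparse(rel_inv):
        return rel_inv.tocsr()
    return sp.csr_matrix(np.asarray(rel_inv, dtype=float))


def assemble_mme(design: Design, rel_inv, vc: VarianceComponents, spec: ModelSpec) -> MMESystem:
    """Henderson MME for the chosen variant.

    R^-1 = diag(w_i / sigma2_e(breed_i)); the genetic block adds
    H^-1 / sigma2_u (single-trait kinds) or T^-1 (x) H^-1 (multiple
    trait); the PE block adds I / sigma2_p per breed.  ``rel_inv`` may
    be an :class:`~ssgblup.genomic.HInverse`, a sparse matrix or a
    dense array (e.g. A^-1 for pedigree BLUP).
    """
    Hinv = _as_sparse(rel_inv)
    N = design.n_animals
    if Hinv.shape[0] != N:
        raise ValueError(
            f"relationship inverse is {Hinv.shape[0]}x{Hinv.shape[0]} "
            f"but the pedigree has {N} animals"
        )
    mats = [design.X, design.Z] + ([design.W] if design.W is not None else [])
    B = sp.hstack(mats, format="csr")
    sig_e = np.array([vc.sigma2_e[b] for b in design.rec_breed])
    rinv = design.weights / sig_e
    Rinv = sp.diags(rinv)
    C = (B.T @ Rinv @ B).tocsr()
    rhs = B.T @ (rinv * design.y)

    p = design.X.shape[1]
    if spec.kind == "multiple_trait":
        T = vc.T()
        if abs(vc.rho) >= 1.0 or np.linalg.det(T) <= 0:
            raise VarianceError(
                "across-breed genetic covariance matrix is singular "
                "(|rho| >= 1); cap rho at 0.99"
            )
        T_inv = np.linalg.inv(T)
        G_term = sp.kron(sp.csr_matrix(T_inv), Hinv, format="csr")
        n_u = 2 * N
    else:
        G_term = Hinv * (1.0 / vc.sigma2_u[0])
        n_u = N
    n_pe = design.W.shape[1] if design.W is not None else 0

    blocks = [sp.csr_matrix((p, p)), G_term]
    if n_pe:
        sig_p = np.array([vc.sigma2_p[b] for b in design.pe_breed])
        if np.any(sig_p <= 0):
            raise VarianceError("PE effects requested but sigma2_p is zero")
        blocks.append(sp.diags(1.0 / sig_p))
    C = C + sp.block_diag(blocks, format="csr")
    return MMESystem(
        C=C.tocsr(), rhs=rhs, n_fixed=p, n_u=n_u, n_pe=n_pe,
        design=design, spec=spec, vc=vc,
    )


@dataclass
class MMESolution:
    beta: np.ndarray
    u: np.ndarray  # (n_traits, N) genetic solutions
    pe: np.ndarray
    vector: np.ndarray
    system: MMESystem
    chol: object = field(default=None, repr=False)


def solve_mme(
    system: MMESystem,
    method: str = "direct",
    tol: float = 1e-10,
    max_iter: int = 5000,
) -> MMESolution:
    """Solve the MME directly (dense Cholesky) or by diagonal-PCG.

    Deterministic: PCG starts from the zero vector.  Non-convergence
    raises :class:`SolverError` with the residual reached.
    """
    C, rhs = system.C, system.rhs
    if method == "direct":
        Cd = C.toarray()
        try:
            cf = la.cho_factor(Cd, check_finite=False)
            x = la.cho_solve(cf, rhs, check_finite=False)
        except la.LinAlgError:
            cf = None
            x = la.solve(Cd, rhs, assume_a="sym")
    elif method == "pcg":
        M = sp.diags(1.0 / C.diagonal())
        x, info = spla.cg(C, rhs, rtol=tol, maxiter=max_iter, M=M)
        cf = None
        if info != 0:
            res = np.linalg.norm(C @ x - rhs) / np.linalg.norm(rhs)
            raise SolverError(
                f"PCG did not converge in {max_iter} iterations "
                f"(relative residual {res:.2e})"
            )
    else:
        raise ValueError(f"unknown solver method {method!r}")
    p, n_u = system.n_fixed, system.n_u
    N = system.design.n_animals
    u = x[p : p + n_u].reshape(system.design.n_traits, N)
    pe = x[p + n_u :]
    return MMESolution(beta=x[:p], u=u, pe=pe, vector=x, system=system, chol=cf)


def compute_pev(system: MMESystem, solution: MMESolution | None = None) -> np.ndarray:
    """Prediction error variances: diagonal of the genetic block of C^-1.

    Returns shape (n_traits, N) on the trait variance scale.  Direct
    dense inversion; intended for desk-scale systems.
    """
    Cd = system.C.toarray()
    if solution is not None and solution.chol is not None:
        cf = solution.chol
    else:
        cf = la.cho_factor(Cd, check_finite=False)
    Cinv_diag = np.diag(la.cho_solve(cf, np.eye(system.n_eq), check_finite=False))
    sl = system.u_slice()
    N = system.design.n_animals
    return Cinv_diag[sl].reshape(system.design.n_traits, N).copy()


def reliability_from_pev(pev, sigma2_u, h_ii, denominator: str = "h_diag"):
    """reliability = 1 - PEV / (h_ii sigma2_u), accuracy = sqrt(reliability).

    ``denominator='plain'`` drops h_ii (uses sigma2_u alone); both
    conventions appear in practice and the choice is reported, not
    hidden.  Values are clipped to [0, 1].
    """
    pev = np.asarray(pev, dtype=float)
    if np.any(pev < -1e-8):
        raise ValueError("negative PEV")
    if np.any(np.asarray(sigma2_u) <= 0):
        raise ValueError("sigma2_u must be positive")
    denom = np.asarray(sigma2_u, dtype=float)
    if denominator == "h_diag":
        denom = denom * np.asarray(h_ii, dtype=float)
    rel = np.clip(1.0 - pev / denom, 0.0, 1.0)
    return rel, np.sqrt(rel)


@dataclass
class EvaluationResult:
    """Per-animal GEBV table plus the solved system for downstream use."""

    frame: pd.DataFrame  # animal, breed, gebv [, pev, reliability, accuracy]
    model: str
    solutions: dict  # breed -> MMESolution ('all' for joint models)
    systems: dict

    def gebv_series(self) -> pd.Series:
        return self.frame.set_index("animal")["gebv"]


def pedigree_subset(ped: PedigreeTable, mask: np.ndarray) -> PedigreeTable:
    """Restrict a pedigree to ``mask``; parents outside become unknown."""
    sel = np.nonzero(mask)[0]
    remap = {int(old): new for new, old in enumerate(sel)}

    def rm(parent):
        out = np.full(len(sel), UNKNOWN, dtype=np.int64)
        for new, old in enumerate(sel):
            p = parent[old]
            if p != UNKNOWN and int(p) in remap:
                out[new] = remap[int(p)]
        return out

    return PedigreeTable(
        ids=ped.ids[sel],
        sire=rm(ped.sire),
        dam=rm(ped.dam),
        birth_year=ped.birth_year[sel],
        breed=ped.breed[sel],
        sex=ped.sex[sel],
    )


def run_evaluation(
    phenos: pd.DataFrame,
    ped: PedigreeTable,
    rel_inv,
    spec: ModelSpec,
    vc: VarianceComponents,
    pev: bool = False,
    h_diag: np.ndarray | None = None,
    method: str = "direct",
    reliability_denominator: str = "h_diag",
) -> EvaluationResult:
    """Full evaluation for the joint variants (multi-breed / multiple-trait).

    Builds the design, assembles and solves the MME and, optionally,
    computes PEV-based reliabilities.  For the multiple-trait variant
    each animal's reported GEBV is its own-breed trait solution.  Use
    :func:`run_within_breed` for the per-breed variant.
    """
    if spec.kind == "within_breed":
        raise ValueError("use run_within_breed for the within-breed variant")
    breeds = vc.breeds
    design = build_design(phenos, spec, ped, breeds=breeds)
    system = assemble_mme(design, rel_inv, vc, spec)
    sol = solve_mme(system, method=method)
    bpos = {b: i for i, b in enumerate(breeds)}
    own = np.array([bpos.get(b, 0) for b in ped.breed])
    if spec.kind == "multiple_trait":
        gebv = sol.u[own, np.arange(ped.n)]
        s2u = np.array([vc.sigma2_u[b] for b in own])
    else:
        gebv = sol.u[0]
        s2u = np.full(ped.n, vc.sigma2_u[0])
    frame = pd.DataFrame({"animal": ped.ids, "breed": ped.breed, "gebv": gebv})
    if pev:
        pevs = compute_pev(system, sol)
        pev_own = pevs[own if spec.kind == "multiple_trait" else np.zeros(ped.n, int), np.arange(ped.n)]
        hd = np.ones(ped.n) if h_diag is None else np.asarray(h_diag)
        rel, acc = reliability_from_pev(pev_own, s2u, hd, denominator=reliability_denominator)
        frame["pev"] = pev_own
        frame["reliability"] = rel
        frame["accuracy"] = acc
    return EvaluationResult(
        frame=frame, model=spec.kind, solutions={"all": sol}, systems={"all": system}
    )


def run_within_breed(
    phenos: pd.DataFrame,
    ped: PedigreeTable,
    rel_inv_by_breed: dict,
    spec: ModelSpec,
    vc: VarianceComponents,
    pev: bool = False,
    h_diag_by_breed: dict | None = None,
    method: str = "direct",
    reliability_denominator: str = "h_diag",
) -> EvaluationResult:
    """Separate evaluation per breed with breed-specific parameters.

    ``rel_inv_by_breed`` maps breed -> (pedigree_subset, relationship
    inverse) pairs, or breed -> relationship inverse over the breed's
    pedigree subset (taken in pedigree order).  GEBV are reported on
    each breed's own scale; cross-breed centering is applied at the
    validation stage.
    """
    frames = []
    sols: dict = {}
    systems: dict = {}
    for b_i, b in enumerate(vc.breeds):
        entry = rel_inv_by_breed[b]
        if isinstance(entry, tuple):
            ped_b, rel_b = entry
        else:
            ped_b = pedigree_subset(ped, ped.breed == b)
            rel_b = entry
        ph_b = phenos[phenos["breed"] == b]
        vc_b = VarianceComponents(
            breeds=(b, b),
            sigma2_u=(vc.sigma2_u[b_i],) * 2,
            sigma2_e=(vc.sigma2_e[b_i],) * 2,
            sigma2_p=(vc.sigma2_p[b_i],) * 2,
            sigma_u_sa=vc.sigma2_u[b_i],
        )
        spec_b = ModelSpec(
            kind="multi_breed",
            trait=spec.trait,
            fixed_effects=spec.fixed_effects,
            intercept=spec.intercept,
            repeatable=spec.repeatable,
            weight_col=spec.weight_col,
            breed_fixed=False,
        )
        design = build_design(ph_b, spec_b, ped_b, breeds=(b, b))
        system = assemble_mme(design, rel_b, vc_b, spec_b)
        sol = solve_mme(system, method=method)
        frame = pd.DataFrame({"animal": ped_b.ids, "breed": b, "gebv": sol.u[0]})
        if pev:
            pevs = compute_pev(system, sol)[0]
            hd = (
                h_diag_by_breed[b]
                if h_diag_by_breed is not None
                else np.ones(ped_b.n)
            )
            rel, acc = reliability_from_pev(
                pevs, vc.sigma2_u[b_i], hd, denominator=reliability_denominator
            )
            frame["pev"] = pevs
            frame["reliability"] = rel
            frame["accuracy"] = acc
        frames.append(frame)
        sols[b] = sol
        systems[b] = system
    return EvaluationResult(
        frame=pd.concat(frames, ignore_index=True),
        model="within_breed",
        solutions=sols,
        systems=systems,
    )
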