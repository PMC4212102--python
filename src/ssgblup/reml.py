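"""REML estimation of breed-specific genetic parameters.

Estimates the across-breed genetic covariance matrix T (per-breed
genetic variances and their covariance, hence the across-breed genetic
correlation rho) together with per-breed residual variances, from
single-record data (first lactations, no permanent-environment term)
under Var(u) = T (x) H with H the single-step relationship matrix.

Algorithms: average-information (AI) REML with step halving and an
EM fallback, or pure EM.  Standard errors come from the inverse AI
matrix at the optimum, with first-order delta-method SEs for the
heritabilities and for rho.

Numerical core
--------------
The mixed-model coefficient matrix is assembled sparse.  Equations of
terminal animals (childless, non-genotyped) are absorbed analytically:
their coefficient block is block-diagonal with one small trait-block
per animal because H^-1 couples such an animal only to its parents.
What remains is a dense parent-level system whose inverse supplies,
exactly, every trace of C^-1 that the AI/EM updates need.  This keeps
REML at thousands of phenotyped females a seconds-per-iteration
problem instead of a dense problem in all animal equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp

from .genomic import HInverse
from .mme import Design, VarianceComponents

__all__ = [
    "RemlResult",
    "estimate_varcomps",
    "heritability_from",
    "varcomps_from_h2_rep",
    "first_lactation_records",
    "approx_standard_errors",
]


def varcomps_from_h2_rep(sigma2_u: float, h2: float, t: float | None = None):
    """Split an official (sigma2_u, h2, repeatability) triplet into variances.

    total = sigma2_u / h2; sigma2_p = (t - h2) * total (zero when the
    trait is not repeatable, t=None); sigma2_e is the remainder.
    Returns ``(sigma2_p, sigma2_e)``.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must lie in (0, 1)")
    if t is None:
        t = h2
    if t < h2 or t >= 1.0:
        raise ValueError("repeatability must satisfy h2 <= t < 1")
    total = sigma2_u / h2
    sigma2_p = (t - h2) * total
    sigma2_e = (1.0 - t) * total
    return sigma2_p, sigma2_e


def heritability_from(vc: VarianceComponents, repeatable: bool = False):
    """Per-breed h2 = su/(su+sp+se) and, when repeatable, t = (su+sp)/total."""
    h2 = []
    rep = []
    for b in range(2):
        su, sp_, se = vc.sigma2_u[b], vc.sigma2_p[b], vc.sigma2_e[b]
        total = su + sp_ + se
        h2.append(su / total)
        rep.append((su + sp_) / total)
    if repeatable:
        return tuple(h2), tuple(rep)
    return tuple(h2)


def first_lactation_records(phenos: pd.DataFrame) -> pd.DataFrame:
    """Earliest record per animal (by parity, then year): the REML subset."""
    cols = [c for c in ("parity", "year") if c in phenos.columns]
    ph = phenos.sort_values(cols, kind="stable") if cols else phenos
    return ph.groupby("animal", sort=False).head(1).reset_index(drop=True)


@dataclass
class RemlResult:
    """REML estimates with SEs, the likelihood trace and convergence info."""

    vc: VarianceComponents
    estimates: dict
    standard_errors: dict
    loglik_trace: list
    converged: bool
    criterion: float
    n_iter: int
    algorithm: str
    ai_matrix: np.ndarray | None = None
    message: str = ""

    @property
    def rho(self) -> float:
        return self.estimates.get("rho", 1.0)


# ---------------------------------------------------------------------------
# internal engine


class _Engine:
    """Holds the fixed structure of one REML problem."""

    def __init__(self, design: Design, rel_inv, log_det_rel):
        if design.W is not None:
            raise ValueError("REML expects a design without PE effects (repeatable=False)")
        counts = np.bincount(design.Z.indices % design.n_animals, minlength=design.n_animals)
        if counts.max() > 1:
            raise ValueError("REML expects a single record per animal; subset to first records")
        self.design = design
        self.b = design.n_traits
        self.N = design.n_animals
        self.p = design.X.shape[1]
        self.n = len(design.y)
        self.W = sp.hstack([design.X, design.Z], format="csr")
        self.y = design.y
        self.weights = design.weights
        self.group_labels = np.unique(design.rec_breed)
        self.groups = np.arange(len(self.group_labels))
        self.g_of_rec = np.searchsorted(self.group_labels, design.rec_breed)
        # record -> (animal, trait)
        zc = design.Z.tocoo()
        order = np.argsort(zc.row)
        zcol = zc.col[order]
        self.rec_animal = zcol % self.N
        self.rec_trait = zcol // self.N

        # relationship inverse in structured form; the dense genotyped-block
        # correction is kept apart so the sparse Kronecker stays pedigree-sized
        self.corr = None
        self.corr_idx = None
        if isinstance(rel_inv, HInverse):
            self.Hinv = rel_inv.to_sparse()
            self.A_sp = rel_inv.A_inv.tocsr()
            self.corr = rel_inv.correction
            self.corr_idx = np.asarray(rel_inv.genotyped_idx, dtype=np.int64)
            genotyped = np.zeros(self.N, dtype=bool)
            genotyped[rel_inv.genotyped_idx] = True
            if log_det_rel is None:
                log_det_rel = rel_inv.log_det_H
            absorbable_ok = True
        elif sp.issparse(rel_inv):
            self.Hinv = rel_inv.tocsr()
            self.A_sp = self.Hinv
            genotyped = np.zeros(self.N, dtype=bool)
            absorbable_ok = True
        else:
            self.Hinv = sp.csr_matrix(np.asarray(rel_inv, dtype=float))
            self.A_sp = self.Hinv
            genotyped = np.ones(self.N, dtype=bool)
            absorbable_ok = False
        if log_det_rel is None:
            if self.N > 4000:
                raise ValueError("pass log_det_rel (log|H|) for large problems")
            sign, ld = np.linalg.slogdet(self.Hinv.toarray())
            log_det_rel = -ld
        self.log_det_H = float(log_det_rel)

        ped = design.ped
        has_child = np.zeros(self.N, dtype=bool)
        for par in (ped.sire, ped.dam):
            known = par >= 0
            has_child[par[known]] = True
        self.absorbed = (
            (~has_child) & (~genotyped) if absorbable_ok else np.zeros(self.N, dtype=bool)
        )
        self.kept = ~self.absorbed
        self.abs_anim = np.nonzero(self.absorbed)[0]
        # genotyped animals last among the kept, as one contiguous block, so
        # the dense H^-1 correction lands in contiguous slices of the
        # reduced system
        kept_all = np.nonzero(self.kept)[0]
        if self.corr is not None:
            is_g = np.zeros(self.N, dtype=bool)
            is_g[self.corr_idx] = True
            self.kept_anim = np.concatenate(
                [kept_all[~is_g[kept_all]], self.corr_idx]
            )
        else:
            self.kept_anim = kept_all
        self.q = len(self.abs_anim)
        self.nk = len(self.kept_anim)
        b, p, N = self.b, self.p, self.N
        self.permB = (
            (p + np.arange(b)[None, :] * N + self.abs_anim[:, None]).ravel()
            if self.q
            else np.array([], dtype=np.int64)
        )
        self.permR = np.concatenate(
            [np.arange(p)] + [p + t * N + self.kept_anim for t in range(b)]
        ).astype(np.int64)
        self.nR = len(self.permR)
        # H^-1 sub-patterns used by the trace machinery
        self.H_kk = self.Hinv[self.kept_anim][:, self.kept_anim].tocsr()
        self.H_ab = self.Hinv[self.abs_anim][:, self.kept_anim].tocoo()
        self.H_aa_diag = self.Hinv.diagonal()[self.abs_anim]
        # per-record bookkeeping
        kept_pos = -np.ones(self.N, dtype=np.int64)
        kept_pos[self.kept_anim] = np.arange(self.nk)
        if self.corr is not None:
            self.gk = kept_pos[self.corr_idx]
            if np.any(self.gk < 0):  # pragma: no cover - structural guarantee
                raise RuntimeError("genotyped animal classified as absorbable")
        abs_pos = -np.ones(self.N, dtype=np.int64)
        abs_pos[self.abs_anim] = np.arange(self.q)
        self.rec_on_abs = self.absorbed[self.rec_animal]
        self.rec_abs_row = (
            self.b * abs_pos[self.rec_animal] + self.rec_trait
        )  # row in B ordering, valid where rec_on_abs
        self.rec_kept_col = self.p + self.rec_trait * self.nk + kept_pos[self.rec_animal]
        self.log_det_R_w = -float(np.sum(np.log(self.weights)))

    # -- one full pass at parameter values (T, sig_e) --------------------
    def iterate(self, T: np.ndarray, sig_e: np.ndarray) -> dict:
        b, p, N, n = self.b, self.p, self.N, self.n
        T = np.atleast_2d(T)
        T_inv = np.linalg.inv(T)
        rinv = self.weights / sig_e[self.g_of_rec]
        Rinv = sp.diags(rinv)
        C = (self.W.T @ Rinv @ self.W).tocsr()
        C = C + sp.block_diag(
            [sp.csr_matrix((p, p)), sp.kron(sp.csr_matrix(T_inv), self.A_sp)], format="csr"
        )
        rhs = self.W.T @ (rinv * self.y)

        permB, permR = self.permB, self.permR
        q, nk, nR = self.q, self.nk, self.nR
        if q:
            Ccc = C[permB][:, permB]
            d0 = Ccc.diagonal(0)
            blocks = np.zeros((q, b, b))
            for m in range(b):
                blocks[:, m, m] = d0[m::b]
            if b == 2:
                d1 = Ccc.diagonal(1)
                blocks[:, 0, 1] = blocks[:, 1, 0] = d1[0::2]
            logdet_BB = float(np.sum(np.log(np.linalg.det(blocks)))) if b > 1 else float(
                np.sum(np.log(blocks[:, 0, 0]))
            )
            inv_blocks = np.linalg.inv(blocks)
            rr = np.repeat(np.arange(q) * b, b * b) + np.tile(
                np.repeat(np.arange(b), b), q
            )
            cc = np.repeat(np.arange(q) * b, b * b) + np.tile(np.tile(np.arange(b), b), q)
            Cbb_inv = sp.csr_matrix((inv_blocks.ravel(), (rr, cc)), shape=(b * q, b * q))
            C_BR = C[permB][:, permR].tocsr()
            Wm = (Cbb_inv @ C_BR).tocsr()
            S = (C[permR][:, permR] - C_BR.T @ Wm).toarray()
            rhs_R = rhs[permR] - Wm.T @ rhs[permB]
        else:
            inv_blocks = np.zeros((0, b, b))
            logdet_BB = 0.0
            Wm = sp.csr_matrix((0, nR))
            C_BR = sp.csr_matrix((0, nR))
            S = C[permR][:, permR].toarray()
            rhs_R = rhs[permR]
        if self.corr is not None:
            # dense genotyped-block part of T^-1 (x) H^-1 goes straight
            # into the reduced system (genotyped animals are never absorbed;
            # they sit in one contiguous block at the end of each trait slab)
            ng = len(self.corr_idx)
            for m in range(b):
                cm = slice(p + (m + 1) * nk - ng, p + (m + 1) * nk)
                for nn in range(b):
                    cn = slice(p + (nn + 1) * nk - ng, p + (nn + 1) * nk)
                    S[cm, cn] += T_inv[m, nn] * self.corr
        cf = la.cho_factor(S, check_finite=False)
        logdet_S = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        sol_R = la.cho_solve(cf, rhs_R, check_finite=False)
        sol_B = (
            Cbb_inv @ (rhs[permB] - C_BR @ sol_R) if q else np.zeros(0)
        )
        sol = np.empty(p + b * N)
        sol[permR] = sol_R
        if q:
            sol[permB] = sol_B

        # restricted log-likelihood (MME identity), constants included
        yPy = float(self.y @ (rinv * self.y) - rhs @ sol)
        n_g = np.array([(self.g_of_rec == g).sum() for g in self.groups])
        log_det_R = float(np.sum(n_g * np.log(sig_e[: len(self.groups)]))) + self.log_det_R_w
        sign, logdet_T = np.linalg.slogdet(T)
        loglik = -0.5 * (
            yPy + logdet_BB + logdet_S + log_det_R + N * logdet_T + b * self.log_det_H
        )

        S_inv = _chol_inverse(cf)
        G1 = (Wm @ S_inv) if q else np.zeros((0, nR))

        # M[m, n] = tr(C^uu_{mn} H^-1), assembled from three index sets
        M = np.zeros((b, b))
        for m in range(b):
            for nn in range(b):
                blk = S_inv[p + m * nk : p + (m + 1) * nk, p + nn * nk : p + (nn + 1) * nk]
                M[m, nn] = self.H_kk.multiply(blk).sum()
        if q:
            CinvBB = inv_blocks.copy()
            for m in range(b):
                for nn in range(b):
                    rows_m = np.arange(q) * b + m
                    rows_n = np.arange(q) * b + nn
                    prod = np.asarray(
                        Wm[rows_n].multiply(G1[rows_m]).sum(axis=1)
                    ).ravel()
                    CinvBB[:, m, nn] += prod
                    M[m, nn] += float(self.H_aa_diag @ CinvBB[:, m, nn])
            jj, pp, vv = self.H_ab.row, self.H_ab.col, self.H_ab.data
            for m in range(b):
                for nn in range(b):
                    t1 = -G1[b * jj + m, p + nn * nk + pp]
                    t2 = -G1[b * jj + nn, p + m * nk + pp]
                    M[m, nn] += float(vv @ (t1 + t2))
        else:
            CinvBB = inv_blocks

        # genetic sufficient statistics
        Uhat = sol[p:].reshape(b, N)
        HU = np.asarray((self.Hinv @ Uhat.T))
        S_u = Uhat @ HU

        # residuals and per-group traces of w_i t_i' C^-1 t_i
        fitted = self.W @ sol
        e_hat = self.y - fitted
        tr_g = np.zeros(len(sig_e))
        ssq_g = np.zeros(len(sig_e))
        X = self.design.X.tocsr()
        on_abs = self.rec_on_abs
        # kept-animal records: whole row lives in the reduced system
        idx_k = np.nonzero(~on_abs)[0]
        if len(idx_k):
            Xk = X[idx_k]
            rows = np.arange(len(idx_k))
            Zk = sp.csr_matrix(
                (np.ones(len(idx_k)), (rows, self.rec_kept_col[idx_k])),
                shape=(len(idx_k), nR),
            )
            Tk = sp.hstack(
                [Xk, sp.csr_matrix((len(idx_k), nR - p))], format="csr"
            ) + Zk
            qf_k = np.asarray(Tk.multiply(Tk @ S_inv).sum(axis=1)).ravel()
        idx_a = np.nonzero(on_abs)[0]
        if len(idx_a):
            Xa = X[idx_a]
            ra = self.rec_abs_row[idx_a]
            qf_x = np.asarray(Xa.multiply(Xa @ S_inv[:p, :p]).sum(axis=1)).ravel()
            cross = np.asarray(Xa.multiply(G1[ra][:, :p]).sum(axis=1)).ravel()
            ta = self.rec_trait[idx_a]
            jpos = ra // b
            diagBB = CinvBB[jpos, ta, ta]
            qf_a = qf_x - 2.0 * cross + diagBB
        for gi, g in enumerate(self.groups):
            m_k = self.g_of_rec[idx_k] == g if len(idx_k) else np.array([], bool)
            m_a = self.g_of_rec[idx_a] == g if len(idx_a) else np.array([], bool)
            tr = 0.0
            if len(idx_k):
                tr += float(self.weights[idx_k][m_k] @ qf_k[m_k])
            if len(idx_a):
                tr += float(self.weights[idx_a][m_a] @ qf_a[m_a])
            tr_g[g] = tr
            sel = self.g_of_rec == g
            ssq_g[g] = float(self.weights[sel] @ (e_hat[sel] ** 2))

        return {
            "T": T,
            "T_inv": T_inv,
            "sig_e": sig_e,
            "loglik": loglik,
            "sol": sol,
            "Uhat": Uhat,
            "S_u": S_u,
            "M": M,
            "e_hat": e_hat,
            "rinv": rinv,
            "tr_g": tr_g,
            "ssq_g": ssq_g,
            "n_g": {int(g): int((self.g_of_rec == g).sum()) for g in self.groups},
            "_solve": (cf, Wm, Cbb_inv if q else None, C_BR, permR, permB),
        }

    def solve_C(self, state, rhs_full: np.ndarray) -> np.ndarray:
        """C^-1 rhs via the stored absorption factorization."""
        cf, Wm, Cbb_inv, C_BR, permR, permB = state["_solve"]
        rhs_R = rhs_full[permR]
        if self.q:
            rhs_R = rhs_R - Wm.T @ rhs_full[permB]
        sol_R = la.cho_solve(cf, rhs_R, check_finite=False)
        out = np.empty_like(rhs_full)
        out[permR] = sol_R
        if self.q:
            out[permB] = Cbb_inv @ (rhs_full[permB] - C_BR @ sol_R)
        return out

    # -- derivatives ------------------------------------------------------
    def _bases(self):
        if self.b == 1:
            return [np.array([[1.0]])]
        E = []
        E.append(np.array([[1.0, 0.0], [0.0, 0.0]]))
        E.append(np.array([[0.0, 0.0], [0.0, 1.0]]))
        E.append(np.array([[0.0, 1.0], [1.0, 0.0]]))
        return E

    def score(self, state) -> np.ndarray:
        T_inv, M, S_u = state["T_inv"], state["M"], state["S_u"]
        sig_e = state["sig_e"]
        out = []
        for E in self._bases():
            A = T_inv @ E @ T_inv
            tr_term = self.N * np.trace(E @ T_inv) - np.sum(A * M)
            data_term = np.sum(A * S_u)
            out.append(-0.5 * (tr_term - data_term))
        for g in self.groups:
            s2 = sig_e[g]
            n_g = state["n_g"][int(g)]
            trP = n_g / s2 - state["tr_g"][g] / s2**2
            yP = state["ssq_g"][g] / s2**2
            out.append(-0.5 * (trP - yP))
        return np.array(out)

    def ai_matrix(self, state) -> np.ndarray:
        """Average information: 0.5 f_k' P f_l via MME solves."""
        T_inv, Uhat = state["T_inv"], state["Uhat"]
        sig_e, rinv, e_hat = state["sig_e"], state["rinv"], state["e_hat"]
        fs = []
        for E in self._bases():
            Ut = (E @ T_inv) @ Uhat  # b x N working breeding values
            fs.append(Ut[self.rec_trait, self.rec_animal])
        for g in self.groups:
            f = np.where(self.g_of_rec == g, e_hat / sig_e[g], 0.0)
            fs.append(f)
        k = len(fs)
        gvecs = [self.W.T @ (rinv * f) for f in fs]
        svecs = [self.solve_C(state, gv) for gv in gvecs]
        AI = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                val = 0.5 * (float(fs[i] @ (rinv * fs[j])) - float(gvecs[i] @ svecs[j]))
                AI[i, j] = AI[j, i] = val
        return AI

    def em_step(self, state):
        Tn = (state["S_u"] + state["M"]) / self.N
        sig = state["sig_e"].copy()
        for g in self.groups:
            sig[g] = (state["ssq_g"][g] + state["tr_g"][g]) / state["n_g"][int(g)]
        return _project_psd(Tn), sig


try:  # numba makes the O(n^2) triangle mirror free next to the O(n^3) LAPACK work
    import numba

    @numba.njit(cache=True)
    def _mirror_triangle(a, lower):  # pragma: no cover - exercised via _chol_inverse
        n = a.shape[0]
        if lower:
            for i in range(n):
                for j in range(i):
                    a[j, i] = a[i, j]
        else:
            for i in range(n):
                for j in range(i):
                    a[i, j] = a[j, i]

except ImportError:  # pragma: no cover

    def _mirror_triangle(a, lower):
        n = a.shape[0]
        if lower:
            a[np.triu_indices(n, 1)] = a.T[np.triu_indices(n, 1)]
        else:
            a[np.tril_indices(n, -1)] = a.T[np.tril_indices(n, -1)]


def _chol_inverse(cf) -> np.ndarray:
    """Inverse of a matrix from its cho_factor, via LAPACK potri."""
    from scipy.linalg import lapack

    c, lower = cf
    inv, info = lapack.dpotri(c, lower=lower)
    if info != 0:
        raise la.LinAlgError(f"dpotri failed with info={info}")
    # dpotri fills one triangle; mirror it in place (the other is stale)
    _mirror_triangle(inv, bool(lower))
    return inv


def _project_psd(T: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    w, V = np.linalg.eigh(T)
    if w.min() > floor:
        return T
    w = np.maximum(w, floor * max(1.0, float(np.max(np.abs(w)))))
    return (V * w) @ V.T


def _theta_to_Tsig(theta, b, n_groups):
    if b == 1:
        T = np.array([[theta[0]]])
        sig = np.array(theta[1:])
    else:
        T = np.array([[theta[0], theta[2]], [theta[2], theta[1]]])
        sig = np.array(theta[3:])
    return T, sig


def _Tsig_to_theta(T, sig):
    if T.shape[0] == 1:
        return np.concatenate([[T[0, 0]], sig])
    return np.concatenate([[T[0, 0], T[1, 1], T[0, 1]], sig])


def approx_standard_errors(ai: np.ndarray, T: np.ndarray, sig_e: np.ndarray):
    """Parameter SEs from the inverse AI matrix, delta method for h2 and rho.

    Returns a dict; empty (flagged unavailable) when AI is not positive
    definite at the optimum.
    """
    b = T.shape[0]
    try:
        cov = la.inv(ai)
        if np.any(np.diag(cov) <= 0):
            raise la.LinAlgError
    except la.LinAlgError:
        return {"available": False}
    se = {"available": True, "cov": cov}
    names = (
        ["sigma2_u_0", "sigma2_u_1", "sigma_u_sa"] if b == 2 else ["sigma2_u_0"]
    )
    names += [f"sigma2_e_{g}" for g in range(len(sig_e))]
    for i, nm in enumerate(names):
        se[nm] = float(np.sqrt(cov[i, i]))
    # delta method: h2_b = T_bb / (T_bb + sig_e_b)
    for t in range(b):
        iu = t if b == 2 else 0
        ie = (3 if b == 2 else 1) + min(t, len(sig_e) - 1)
        tot = T[t, t] + sig_e[min(t, len(sig_e) - 1)]
        grad = np.zeros(ai.shape[0])
        grad[iu] = sig_e[min(t, len(sig_e) - 1)] / tot**2
        grad[ie] = -T[t, t] / tot**2
        se[f"h2_{t}"] = float(np.sqrt(grad @ cov @ grad))
    if b == 2:
        rho = T[0, 1] / np.sqrt(T[0, 0] * T[1, 1])
        grad = np.zeros(ai.shape[0])
        grad[0] = -rho / (2 * T[0, 0])
        grad[1] = -rho / (2 * T[1, 1])
        grad[2] = 1.0 / np.sqrt(T[0, 0] * T[1, 1])
        se["rho"] = float(np.sqrt(grad @ cov @ grad))
    return se


def estimate_varcomps(
    design: Design,
    rel_inv,
    start: VarianceComponents | None = None,
    algorithm: str = "ai",
    tol: float = 1e-8,
    max_iter: int = 100,
    log_det_rel: float | None = None,
    em_warmup: int = 1,
    verbose: bool = False,
) -> RemlResult:
    """Maximize the restricted likelihood over T and residual variances.

    ``design`` must come from :func:`ssgblup.mme.build_design` on
    single-record data with ``repeatable=False`` (multiple-trait kind
    for the two-breed analysis; a single-trait design degenerates to
    classical animal-model REML).  ``algorithm`` is 'ai' (AI with
    step-halving and EM fallback) or 'em'.  Convergence: maximum
    relative parameter change < tol.  On non-convergence the last
    iterate is returned flagged.
    """
    if algorithm not in ("ai", "em"):
        raise ValueError("algorithm must be 'ai' or 'em'")
    eng = _Engine(design, rel_inv, log_det_rel)
    b = eng.b
    n_groups = len(eng.groups)

    if start is None:
        # phenotypic-variance split at h2 = 0.3; rho starts at 0.5
        var_y = np.ones(max(n_groups, b))
        for g in eng.groups:
            var_y[g] = float(np.var(eng.y[eng.g_of_rec == g]))
        T0 = np.diag(0.3 * var_y[:b])
        if b == 2:
            T0[0, 1] = T0[1, 0] = 0.5 * np.sqrt(T0[0, 0] * T0[1, 1])
        sig0 = 0.7 * var_y[:n_groups]
    else:
        T0 = start.T()[:b, :b]
        sig0 = np.array(start.sigma2_e[:n_groups])
    T, sig = _project_psd(T0), sig0.copy()

    state = eng.iterate(T, sig)
    trace = [state["loglik"]]
    converged = False
    crit = np.inf
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        theta = _Tsig_to_theta(T, sig)
        use_em = algorithm == "em" or it <= em_warmup
        if use_em:
            T_new, sig_new = eng.em_step(state)
            step_kind = "em"
        else:
            sc = eng.score(state)
            AI = eng.ai_matrix(state)
            try:
                delta = la.solve(AI, sc, assume_a="sym")
                step_kind = "ai"
            except la.LinAlgError:
                T_new, sig_new = eng.em_step(state)
                delta = None
                step_kind = "em-fallback"
            if delta is not None:
                # damp wild early steps: keep relative parameter change <= 80%
                maxrel = float(np.max(np.abs(delta) / np.maximum(np.abs(theta), 1e-12)))
                step = min(1.0, 0.8 / maxrel) if maxrel > 0 else 1.0
                T_new = sig_new = None
                for _ in range(12):
                    cand = theta + step * delta
                    Tc, sigc = _theta_to_Tsig(cand, b, n_groups)
                    if np.any(sigc <= 0):
                        step *= 0.5
                        continue
                    ev_min = float(np.linalg.eigvalsh(Tc).min())
                    if ev_min <= 1e-6 * float(np.abs(np.diag(Tc)).max()):
                        # a (near-)singular T makes the likelihood numerically
                        # meaningless: shorten the step instead of projecting
                        step *= 0.5
                        continue
                    try:
                        st_c = eng.iterate(Tc, sigc)
                    except (la.LinAlgError, np.linalg.LinAlgError):
                        step *= 0.5
                        continue
                    if st_c["loglik"] >= state["loglik"] - 1e-8:
                        T_new, sig_new = Tc, sigc
                        state_new = st_c
                        break
                    step *= 0.5
                if T_new is None:  # AI failed to improve: EM rescue
                    T_new, sig_new = eng.em_step(state)
                    step_kind = "em-fallback"
        if step_kind != "ai":
            state_new = eng.iterate(T_new, sig_new)
            if algorithm == "em" and state_new["loglik"] < state["loglik"] - 1e-6:
                message = "EM step decreased the restricted likelihood"
        theta_new = _Tsig_to_theta(T_new, sig_new)
        denom = np.maximum(np.abs(theta), 1e-12)
        crit = float(np.max(np.abs(theta_new - theta) / denom))
        T, sig, state = T_new, sig_new, state_new
        trace.append(state["loglik"])
        if verbose:
            print(f"iter {it:3d} [{step_kind}] loglik={state['loglik']:.6f} crit={crit:.2e}")
        if crit < tol:
            converged = True
            break

    AI_final = eng.ai_matrix(state)
    ses = approx_standard_errors(AI_final, T, sig)
    breeds = design.breeds if b == 2 else (design.breeds[0],) * 2
    sig_pair = (
        (float(sig[0]), float(sig[min(1, len(sig) - 1)])) if len(sig) else (1.0, 1.0)
    )
    if b == 2:
        vc = VarianceComponents(
            breeds=tuple(breeds),
            sigma2_u=(float(T[0, 0]), float(T[1, 1])),
            sigma2_e=sig_pair,
            sigma2_p=(0.0, 0.0),
            sigma_u_sa=float(T[0, 1]),
        )
        rho = float(T[0, 1] / np.sqrt(T[0, 0] * T[1, 1]))
    else:
        vc = VarianceComponents(
            breeds=tuple(breeds),
            sigma2_u=(float(T[0, 0]),) * 2,
            sigma2_e=(sig_pair[0],) * 2,
            sigma2_p=(0.0, 0.0),
            sigma_u_sa=float(T[0, 0]),
        )
        rho = 1.0
    h2 = tuple(
        float(T[t, t] / (T[t, t] + sig[min(t, len(sig) - 1)])) for t in range(b)
    )
    estimates = {
        "T": T,
        "sigma2_u": tuple(float(T[t, t]) for t in range(b)),
        "sigma_u_sa": float(T[0, 1]) if b == 2 else float(T[0, 0]),
        "sigma2_e": tuple(float(s) for s in sig),
        "h2": h2,
        "rho": max(-1.0, min(1.0, rho)),
    }
    return RemlResult(
        vc=vc,
        estimates=estimates,
        standard_errors=ses,
        loglik_trace=trace,
        converged=converged,
        criterion=crit,
        n_iter=it,
        algorithm=algorithm,
        ai_matrix=AI_final,
        message=message,
    )
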