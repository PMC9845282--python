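"""Animal-model mixed-model equations and variance-component estimation.

The model is

    y = X b + Z u + W c + e,   u ~ N(0, K sigma_g),  c ~ N(0, I sigma_c),
                               e ~ N(0, I sigma_e)

where K is the pedigree relationship A (PBLUP) or the single-step H
(ssGBLUP), and c is the common full-sib family effect shared by sibs reared
together.  Omitting the Wc term gives the reduced model used to study the
bias from ignoring the family environment.

Henderson's mixed-model equations are assembled in variance-scaled form

    C = M' M / sigma_e + diag(0, K^-1 / sigma_g, I / sigma_c),
    C theta = M' y / sigma_e,          M = [X Z W]

so that C^-1 is directly the sampling/prediction-error covariance of the
solutions.  Variance components are estimated by average-information REML
with EM fallback steps, or by blocked Gibbs sampling with conjugate
scaled-inverse-chi-square updates.  Restricted likelihoods use the MME
identity  -2 l = n log se + log|K sg| + log|I sc| + log|C| + y'Py + const,
which is consistent across nested models, so likelihood-ratio tests for the
family effect are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, sparse, stats
from scipy.linalg import lapack
from sklearn.base import BaseEstimator

from .genomic import GenotypeMatrix, HInverseParts, blend_G, build_G, build_H_inverse, sparse_logdet
from .pedigree import Pedigree, build_A_inverse, extract_A22

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "BivariateVarianceComponents",
    "MMESolution",
    "DesignMatrices",
    "MMESystem",
    "build_design",
    "make_kinship_inverse",
    "solve_mme",
    "aireml",
    "reml_loglik",
    "lrt_c2",
    "gibbs_sampler",
    "GibbsResult",
    "fit_bivariate",
    "AnimalModel",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """REML or solver failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class ModelSpec:
    """What goes into the linear mixed model."""

    response: str = "tag_weight_g"
    fixed_factors: tuple[str, ...] = ("generation", "batch")
    covariates: tuple[str, ...] = ("age_d",)
    include_c2: bool = True
    relationship: str = "A"  # "A" (PBLUP) or "H" (ssGBLUP)
    traits: tuple[str, ...] = ("tag_weight_g",)


@dataclass
class VarianceComponents:
    """sigma_g / sigma_c / sigma_e with derived ratios and (optional) SEs."""

    sigma_g: float
    sigma_e: float
    sigma_c: float | None = None
    se: dict = field(default_factory=dict)
    boundary: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.sigma_g + (self.sigma_c or 0.0) + self.sigma_e

    @property
    def h2(self) -> float:
        return self.sigma_g / self.total

    @property
    def c2(self) -> float | None:
        return None if self.sigma_c is None else self.sigma_c / self.total

    def as_dict(self) -> dict:
        d = {"sigma_g": self.sigma_g, "sigma_e": self.sigma_e, "h2": self.h2}
        if self.sigma_c is not None:
            d["sigma_c"] = self.sigma_c
            d["c2"] = self.c2
        return d


@dataclass
class BivariateVarianceComponents:
    """2x2 genetic / family / residual covariance blocks."""

    G0: np.ndarray
    C0: np.ndarray
    R0: np.ndarray

    @property
    def genetic_correlation(self) -> float:
        return float(self.G0[0, 1] / np.sqrt(self.G0[0, 0] * self.G0[1, 1]))

    def h2(self, t: int) -> float:
        tot = self.G0[t, t] + self.C0[t, t] + self.R0[t, t]
        return float(self.G0[t, t] / tot)


@dataclass
class MMESolution:
    b: pd.Series
    u: pd.Series
    c: pd.Series | None
    residual_norm: float
    iterations: int = 0
    loglik: float | None = None

    def ebv(self) -> pd.Series:
        return self.u


@dataclass
class DesignMatrices:
    X: np.ndarray
    x_names: list[str]
    Z: sparse.csr_matrix
    W: sparse.csr_matrix | None
    family_levels: np.ndarray | None
    record_animal_code: np.ndarray  # 1-based pedigree codes per record
    dropped_aliased: list[str] = field(default_factory=list)


def build_design(data: pd.DataFrame, spec: ModelSpec, ped: Pedigree) -> DesignMatrices:
    """Incidence matrices for the model.

    X gets an intercept, one dummy per non-reference factor level and the
    (centred) covariates.  Dummy columns made exactly collinear by nesting
    (e.g. spawning batches nested within generation) are detected by
    pivoted QR and dropped as aliased; any remaining rank deficiency that
    involves the intercept or a covariate is an error naming the columns.
    """
    n = len(data)
    cols = [np.ones(n)]
    names = ["intercept"]
    factor_cols: set[str] = set()
    for f in spec.fixed_factors:
        levels = pd.unique(data[f].astype(str))
        levels = np.sort(levels)
        for lev in levels[1:]:
            cols.append((data[f].astype(str) == lev).to_numpy(float))
            names.append(f"{f}[{lev}]")
            factor_cols.add(names[-1])
    for cv in spec.covariates:
        v = data[cv].to_numpy(float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"covariate {cv!r} has non-finite values")
        cols.append(v - v.mean())
        names.append(cv)
    X = np.column_stack(cols)

    # prune exactly-aliased dummy columns (pivoted QR)
    dropped: list[str] = []
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps * 10
    bad = [piv[k] for k in range(len(diag)) if diag[k] <= tol]
    bad += list(piv[len(diag):])
    if bad:
        bad_names = [names[j] for j in sorted(bad)]
        non_factor = [b for b in bad_names if b not in factor_cols]
        if non_factor:
            raise ValueError(f"design matrix rank-deficient; confounded columns: {bad_names}")
        keep = np.setdiff1d(np.arange(X.shape[1]), bad)
        X = X[:, keep]
        names = [names[j] for j in keep]
        dropped = bad_names

    codes = ped.code_of(data["animal_id"])
    rows = np.arange(n)
    Z = sparse.csr_matrix(
        (np.ones(n), (rows, codes - 1)), shape=(n, ped.n_animals)
    )
    W = None
    fam_levels = None
    if spec.include_c2:
        fam = data["family_id"].astype(str).to_numpy()
        fam_levels = np.sort(pd.unique(fam))
        lut = {f: j for j, f in enumerate(fam_levels)}
        fidx = np.asarray([lut[f] for f in fam])
        W = sparse.csr_matrix((np.ones(n), (rows, fidx)), shape=(n, len(fam_levels)))
    return DesignMatrices(X, names, Z, W, fam_levels, codes, dropped)


def make_kinship_inverse(
    ped: Pedigree,
    genotypes: GenotypeMatrix | None = None,
    relationship: str = "A",
    tau: float = 0.95,
    omega: float = 0.05,
) -> tuple[sparse.csr_matrix, float, HInverseParts | None]:
    """(K^-1 sparse, log|K|, H parts) for the requested relationship source."""
    a_inv = build_A_inverse(ped)
    if relationship == "A" or genotypes is None or genotypes.n_samples == 0:
        return a_inv, -sparse_logdet(a_inv), None
    if relationship != "H":
        raise ValueError(f"unknown relationship source {relationship!r}")
    A22 = extract_A22(ped, genotypes.sample_ids)
    G = build_G(genotypes)
    G_star = blend_G(G, A22, tau=tau, omega=omega)
    geno_index = ped.code_of(genotypes.sample_ids) - 1
    parts = build_H_inverse(a_inv, G_star, A22, geno_index, tau=tau, omega=omega)
    return parts.to_sparse(), float(parts.logdet_H), parts


class MMESystem:
    """Assembled mixed-model equations for one variance-component setting.

    Holds the y/X/Z/W data once; re-assembly for new components reuses the
    cached cross-product blocks.  Dense Cholesky is used up to
    ``max_dense`` unknowns (the trace work REML needs has no sparse
    shortcut without a supernodal selected inverse); above that the system
    falls back to a sparse LU that supports solves and log-determinants.
    """

    def __init__(
        self,
        y: np.ndarray,
        design: DesignMatrices,
        K_inv: sparse.spmatrix,
        logdet_K: float,
        max_dense: int = 9000,
    ):
        self.y = np.asarray(y, float)
        self.design = design
        self.K_inv = sparse.csr_matrix(K_inv)
        self.logdet_K = float(logdet_K)
        X, Z, W = design.X, design.Z, design.W
        self.n, self.p = X.shape
        self.q_u = Z.shape[1]
        self.q_c = 0 if W is None else W.shape[1]
        self.dim = self.p + self.q_u + self.q_c
        self.sl_b = slice(0, self.p)
        self.sl_u = slice(self.p, self.p + self.q_u)
        self.sl_c = slice(self.p + self.q_u, self.dim)
        blocks = [sparse.csr_matrix(X), Z] + ([W] if W is not None else [])
        self.M = sparse.hstack(blocks, format="csr")
        self.MtM = (self.M.T @ self.M).tocsr()
        self.Mty = self.M.T @ self.y
        self.yty = float(self.y @ self.y)
        self.max_dense = max_dense
        self._dense = self.dim <= max_dense
        if self._dense:
            # Fortran order keeps LAPACK from copying the factor each call
            self._MtM_dense = np.asfortranarray(self.MtM.toarray())
            self._Kinv_dense = np.asfortranarray(self.K_inv.toarray())
            self._C_buf = np.empty((self.dim, self.dim), order="F")
        self._factor = None
        self.varcomp: VarianceComponents | None = None

    # -- assembly / factorisation -------------------------------------
    def set_components(self, vc: VarianceComponents) -> None:
        if vc.sigma_g <= 0 or vc.sigma_e <= 0 or (self.q_c and (vc.sigma_c or 0) <= 0):
            raise ValueError("variance components must be strictly positive")
        self.varcomp = vc
        if self._dense:
            C = self._C_buf
            np.multiply(self._MtM_dense, 1.0 / vc.sigma_e, out=C)
            Cu = C[self.sl_u, self.sl_u]
            Cu += self._Kinv_dense * (1.0 / vc.sigma_g)
            if self.q_c:
                idx = np.arange(self.sl_c.start, self.sl_c.stop)
                C[idx, idx] += 1.0 / vc.sigma_c
            cf, info = lapack.dpotrf(C, lower=1, overwrite_a=1)
            if info != 0:
                raise ConvergenceError(f"MME coefficient matrix not PD (dpotrf info={info})")
            self._factor = ("chol", cf)
            self._logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf))))
        else:
            C = self.MtM / vc.sigma_e
            pad_pre = sparse.csr_matrix((self.p, self.p))
            mids = [self.K_inv / vc.sigma_g]
            if self.q_c:
                mids.append(sparse.identity(self.q_c, format="csr") / vc.sigma_c)
            C = (C + sparse.block_diag([pad_pre] + mids, format="csr")).tocsc()
            lu = sparse.linalg.splu(C, permc_spec="MMD_AT_PLUS_A")
            self._factor = ("lu", lu)
            self._logdet_C = float(np.sum(np.log(np.abs(lu.U.diagonal()))))

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        kind, f = self._factor
        if kind == "chol":
            out, info = lapack.dpotrs(f, rhs, lower=1)
            return out
        return f.solve(rhs)

    def solution(self) -> np.ndarray:
        return self.solve(self.Mty / self.varcomp.sigma_e)

    def inverse_dense(self) -> np.ndarray:
        kind, f = self._factor
        if kind == "chol":
            inv, info = lapack.dpotri(f.copy(), lower=1)
            inv = np.tril(inv) + np.tril(inv, -1).T
            return inv
        return self.solve(np.eye(self.dim))

    def pev_block(self, u_positions: np.ndarray) -> np.ndarray:
        """Prediction-error covariance of u-hat for selected animals
        (columns of C^-1, never the full inverse for the sparse path)."""
        cols = np.zeros((self.dim, len(u_positions)))
        cols[self.p + np.asarray(u_positions), np.arange(len(u_positions))] = 1.0
        sol = self.solve(cols)
        return sol[self.p + np.asarray(u_positions), :]

    # -- likelihood ----------------------------------------------------
    def loglik(self, theta: np.ndarray | None = None) -> float:
        vc = self.varcomp
        if theta is None:
            theta = self.solution()
        yPy = (self.yty - float(theta @ self.Mty)) / vc.sigma_e
        m2ll = (
            self.n * np.log(vc.sigma_e)
            + self.q_u * np.log(vc.sigma_g)
            + self.logdet_K
            + (self.q_c * np.log(vc.sigma_c) if self.q_c else 0.0)
            + self._logdet_C
            + yPy
            + (self.n - self.p) * np.log(2.0 * np.pi)
        )
        return -0.5 * m2ll


def solve_mme(
    y: np.ndarray,
    design: DesignMatrices,
    K_inv: sparse.spmatrix,
    varcomp: VarianceComponents,
    animal_ids: np.ndarray | None = None,
    logdet_K: float = 0.0,
) -> MMESolution:
    """Solve Henderson's equations at fixed variance components.

    The normal-equation residual is checked against the contract
    ||C theta - rhs|| < 1e-8 ||rhs||.
    """
    sys_ = MMESystem(y, design, K_inv, logdet_K)
    sys_.set_components(varcomp)
    theta = sys_.solution()
    rhs = sys_.Mty / varcomp.sigma_e
    kind, _ = sys_._factor
    if kind == "chol":
        C_theta = sys_._MtM_dense @ theta / varcomp.sigma_e
        C_theta[sys_.sl_u] += sys_._Kinv_dense @ theta[sys_.sl_u] / varcomp.sigma_g
        if sys_.q_c:
            C_theta[sys_.sl_c] += theta[sys_.sl_c] / varcomp.sigma_c
    else:
        C_theta = sys_.MtM @ theta / varcomp.sigma_e
        C_theta[sys_.sl_u] += sys_.K_inv @ theta[sys_.sl_u] / varcomp.sigma_g
        if sys_.q_c:
            C_theta[sys_.sl_c] += theta[sys_.sl_c] / varcomp.sigma_c
    res = float(np.linalg.norm(C_theta - rhs))
    if res > 1e-8 * max(np.linalg.norm(rhs), 1.0):
        raise ConvergenceError(f"MME solve residual {res:.3e} violates tolerance")
    return _pack_solution(theta, design, animal_ids, res, loglik=sys_.loglik(theta))


def _pack_solution(theta, design: DesignMatrices, animal_ids, res, loglik=None, iters=0):
    p = design.X.shape[1]
    q_u = design.Z.shape[1]
    b = pd.Series(theta[:p], index=design.x_names)
    idx = animal_ids if animal_ids is not None else np.arange(1, q_u + 1).astype(object)
    u = pd.Series(theta[p : p + q_u], index=idx)
    c = None
    if design.W is not None:
        c = pd.Series(theta[p + q_u :], index=design.family_levels)
    return MMESolution(b, u, c, res, iterations=iters, loglik=loglik)


# ---------------------------------------------------------------------------
# AI-REML
# ---------------------------------------------------------------------------


def _sparse_weighted_trace(K: sparse.csr_matrix, B: np.ndarray) -> float:
    """tr(K B) when K is sparse and B dense-symmetric: sum K_ij B_ij."""
    coo = K.tocoo()
    return float(np.sum(coo.data * B[coo.row, coo.col]))


@dataclass
class _RemlState:
    theta: np.ndarray
    ll: float
    grad: np.ndarray
    ai: np.ndarray
    sol: np.ndarray


def aireml(
    y: np.ndarray,
    design: DesignMatrices,
    K_inv: sparse.spmatrix,
    logdet_K: float,
    start: VarianceComponents | None = None,
    max_rounds: int = 60,
    tol: float = 1e-8,
    gtol: float = 1e-6,
    animal_ids: np.ndarray | None = None,
    verbose: bool = False,
) -> tuple[VarianceComponents, MMESolution]:
    """Average-information REML for (sigma_g, [sigma_c,] sigma_e).

    Newton steps use the AI matrix with a backtracking line search on the
    restricted likelihood; a direction that cannot improve it falls back
    to an EM update (which is monotone, so the likelihood never
    decreases).  Components hitting the floor (1e-6 x phenotypic
    variance) are clamped, leave the active set, and are flagged as
    boundary estimates.
    """
    y = np.asarray(y, float)
    vary = float(np.var(y))
    floor = 1e-6 * vary
    with_c = design.W is not None
    if start is None:
        s0 = vary / (3.0 if with_c else 2.0)
        start = VarianceComponents(s0, s0, s0 if with_c else None)
    names = ["sigma_g"] + (["sigma_c"] if with_c else []) + ["sigma_e"]
    theta = np.array(
        [start.sigma_g] + ([start.sigma_c] if with_c else []) + [start.sigma_e], float
    )
    theta = np.maximum(theta, floor)

    sys_ = MMESystem(y, design, K_inv, logdet_K)
    Kcsr = sparse.csr_matrix(K_inv)
    trace_rows = []

    def quick_ll(t: np.ndarray) -> float:
        try:
            sys_.set_components(_vc_from(t, with_c))
            return sys_.loglik()
        except ConvergenceError:
            # e.g. a runaway component leaving recordless animals with a
            # numerically void diagonal: reject the candidate
            return -np.inf

    ai = None
    converged = False
    prev_rel = np.inf
    ll = quick_ll(theta)
    for it in range(max_rounds):
        # full evaluation at the current (already accepted) point
        vc = _vc_from(theta, with_c)
        sys_.set_components(vc)
        sol = sys_.solution()
        Cinv = sys_.inverse_dense()
        Cuu = Cinv[sys_.sl_u, sys_.sl_u]
        u_hat = sol[sys_.sl_u]
        e_hat = y - sys_.M @ sol
        tr_K_Cuu = _sparse_weighted_trace(Kcsr, Cuu)
        uKu = float(u_hat @ (Kcsr @ u_hat))
        n, p, q_u, q_c = sys_.n, sys_.p, sys_.q_u, sys_.q_c
        sg = vc.sigma_g
        se = vc.sigma_e
        grad = [-0.5 * (q_u / sg - tr_K_Cuu / sg**2 - uKu / sg**2)]
        if with_c:
            sc = vc.sigma_c
            c_hat = sol[sys_.sl_c]
            tr_Ccc = float(np.trace(Cinv[sys_.sl_c, sys_.sl_c]))
            cc = float(c_hat @ c_hat)
            grad.append(-0.5 * (q_c / sc - tr_Ccc / sc**2 - cc / sc**2))
        else:
            tr_Ccc = cc = 0.0
            sc = None
        trP = (
            n - p - q_u - q_c + tr_K_Cuu / sg + (tr_Ccc / sc if with_c else 0.0)
        ) / se
        ee = float(e_hat @ e_hat)
        grad.append(-0.5 * (trP - ee / se**2))
        grad = np.asarray(grad)

        # average-information matrix from working vectors f_i = V_i P y
        fs = [design.Z @ u_hat / sg]
        if with_c:
            fs.append(design.W @ c_hat / sc)
        fs.append(e_hat / se)
        k = len(fs)
        Pf = []
        for f in fs:
            rhs = sys_.M.T @ f / se
            th_f = sys_.solve(rhs)
            Pf.append((f - sys_.M @ th_f) / se)
        ai = 0.5 * np.array([[float(fs[i] @ Pf[j]) for j in range(k)] for i in range(k)])

        trace_rows.append(dict(zip(names, theta), loglik=ll, grad_norm=float(np.linalg.norm(grad))))
        if verbose:  # pragma: no cover
            print(f"round {it}: ll={ll:.6f} theta={theta} |g|={np.linalg.norm(grad):.2e}")

        # parameters pinned at the floor with downhill gradient leave the
        # active set; convergence is judged on the free parameters only
        free = ~((theta <= floor * 1.01) & (grad < 0.0))
        if prev_rel < tol and (not free.any() or np.linalg.norm(grad[free]) < gtol):
            converged = True
            break

        # AI (Newton) direction on the active set, backtracked on the
        # restricted likelihood
        accepted = None
        if free.any():
            fi = np.flatnonzero(free)
            try:
                delta_f = np.linalg.solve(ai[np.ix_(fi, fi)], grad[fi])
            except np.linalg.LinAlgError:
                delta_f = None
            if delta_f is not None and np.all(np.isfinite(delta_f)):
                delta = np.zeros_like(theta)
                delta[fi] = delta_f
                step = 1.0
                for _ in range(8):
                    # cap each component's growth at x50 per round
                    cand = np.clip(theta + step * delta, floor, 50.0 * np.maximum(theta, floor))
                    cand_ll = quick_ll(cand)
                    if np.isfinite(cand_ll) and cand_ll >= ll - 1e-10:
                        accepted = (cand, cand_ll)
                        break
                    step /= 2.0
        if accepted is None:
            # EM update never decreases the likelihood
            cand = np.maximum(
                _em_step(theta, with_c, q_u, q_c, n, p, uKu, tr_K_Cuu, cc, tr_Ccc, ee, Cinv, sys_),
                floor,
            )
            cand_ll = quick_ll(cand)
            for _ in range(6):
                if np.isfinite(cand_ll):
                    break
                cand = 0.5 * (cand + theta)  # retreat toward the last good point
                cand_ll = quick_ll(cand)
            accepted = (cand, cand_ll)
        new, ll = accepted
        prev_rel = (
            float(np.max(np.abs(new - theta)[free] / np.maximum(theta, floor)[free]))
            if free.any()
            else 0.0
        )
        theta = new
    if not converged:
        big_grad = bool(free.any() and np.linalg.norm(grad[free]) > 50 * gtol)
        if big_grad:
            raise ConvergenceError(
                f"AI-REML did not converge in {max_rounds} rounds", trace=trace_rows
            )
        warnings.warn("AI-REML stopped at max rounds with a small but non-zero gradient")

    vc = _vc_from(theta, with_c)
    vc.boundary = {nm: bool(v <= floor * 1.01) for nm, v in zip(names, theta)}
    try:
        cov = np.linalg.inv(ai)
        vc.se = dict(zip(names, np.sqrt(np.maximum(np.diag(cov), 0.0))))
        vc.se.update(_ratio_se(theta, cov, with_c))
    except np.linalg.LinAlgError:  # pragma: no cover
        vc.se = {}
    sys_.set_components(vc)
    sol = sys_.solution()
    solution = _pack_solution(sol, design, animal_ids, 0.0, loglik=sys_.loglik(sol), iters=it + 1)
    return vc, solution


def _vc_from(theta: np.ndarray, with_c: bool) -> VarianceComponents:
    if with_c:
        return VarianceComponents(theta[0], theta[2], theta[1])
    return VarianceComponents(theta[0], theta[1], None)


def _em_step(theta, with_c, q_u, q_c, n, p, uKu, tr_K_Cuu, cc, tr_Ccc, ee, Cinv, sys_):
    sg = (uKu + tr_K_Cuu) / q_u
    out = [sg]
    if with_c:
        out.append((cc + tr_Ccc) / q_c)
    se_old = theta[-1]
    sg_old = theta[0]
    dim_rand = q_u + q_c + p
    tr_CSig = tr_K_Cuu / sg_old + (tr_Ccc / theta[1] if with_c else 0.0)
    se = (ee + se_old * (dim_rand - tr_CSig)) / n
    out.append(se)
    return np.asarray(out)


def _ratio_se(theta, cov, with_c):
    """Delta-method SEs for h2 (and c2)."""
    tot = theta.sum()
    out = {}
    g = theta[0]
    d = np.full(len(theta), -g / tot**2)
    d[0] += 1.0 / tot
    out["h2"] = float(np.sqrt(max(d @ cov @ d, 0.0)))
    if with_c:
        c = theta[1]
        d = np.full(len(theta), -c / tot**2)
        d[1] += 1.0 / tot
        out["c2"] = float(np.sqrt(max(d @ cov @ d, 0.0)))
    return out


def reml_loglik(
    varcomp: VarianceComponents,
    y: np.ndarray,
    design: DesignMatrices,
    K_inv: sparse.spmatrix,
    logdet_K: float,
) -> float:
    """Restricted log-likelihood at fixed components (MME identity)."""
    sys_ = MMESystem(np.asarray(y, float), design, K_inv, logdet_K)
    sys_.set_components(varcomp)
    return sys_.loglik()


def lrt_c2(loglik_full: float, loglik_reduced: float, boundary_mixture: bool = False):
    """Likelihood-ratio test for the common full-sib term (df = 1).

    ``boundary_mixture`` switches to the 50:50 chi0/chi1 mixture
    appropriate for a variance tested on its boundary.
    """
    chi2 = 2.0 * (loglik_full - loglik_reduced)
    if chi2 < -1e-6:
        warnings.warn(
            f"full-model likelihood below reduced ({chi2:.3g}); chi-square clipped to 0"
        )
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=1))
    if boundary_mixture:
        p = 0.5 * p if chi2 > 0 else 1.0
    return chi2, p


# ---------------------------------------------------------------------------
# Gibbs sampling
# ---------------------------------------------------------------------------


@dataclass
class GibbsResult:
    draws: pd.DataFrame
    varcomp: VarianceComponents
    solution: MMESolution
    stable: dict
    geweke_z: dict


def _gibbs_sweep_kernel():
    """Compile (once) the numba single-site Gauss-Seidel sampling sweep."""
    global _SWEEP
    if _SWEEP is not None:
        return _SWEEP
    import numba

    @numba.njit(cache=False)
    def sweep(indptr, indices, data, diag_pos, rhs, theta):
        for i in range(theta.shape[0]):
            s = rhs[i]
            for k in range(indptr[i], indptr[i + 1]):
                j = indices[k]
                if j != i:
                    s -= data[k] * theta[j]
            cii = data[diag_pos[i]]
            theta[i] = s / cii + np.random.normal() / np.sqrt(cii)

    @numba.njit(cache=False)
    def set_seed(seed):
        np.random.seed(seed)

    _SWEEP = (sweep, set_seed)
    return _SWEEP


_SWEEP = None


def gibbs_sampler(
    y: np.ndarray,
    design: DesignMatrices,
    K_inv: sparse.spmatrix,
    logdet_K: float,
    total_cycles: int = 20_000,
    burn_in: int = 2_000,
    thin: int = 1,
    seed: int = 0,
    animal_ids: np.ndarray | None = None,
    start: VarianceComponents | None = None,
    prior_bound: float = 5.0,
    divergence_guard: float = 1e4,
    scheme: str = "auto",
    max_dense: int = 1200,
) -> GibbsResult:
    """Gibbs sampler for the univariate animal model.

    Location effects are drawn either jointly from their multivariate
    normal full conditional (``scheme='blocked'``: a dense Cholesky of the
    MME matrix per cycle, exact but cubic in the system size) or one at a
    time by a single-site Gauss-Seidel sweep (``scheme='single_site'``,
    the classic animal-breeding sampler, linear in the number of MME
    non-zeros and practical at the full study scale).  ``'auto'`` picks
    blocked below ``max_dense`` unknowns.  Variances use scaled
    inverse-chi-square conditionals under flat bounded priors.
    Post-burn-in variance traces are checked for stability (Geweke z
    between the first and second half); an unstable trace gates the
    summary to the stabilised second half.
    """
    if not 0 < burn_in < total_cycles:
        raise ValueError("need 0 < burn_in < total_cycles")
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    with_c = design.W is not None
    vary = float(np.var(y))
    guard = divergence_guard * vary
    bound = prior_bound * vary
    if start is None:
        s0 = vary / (3.0 if with_c else 2.0)
        start = VarianceComponents(s0, s0, s0 if with_c else None)

    sys_ = MMESystem(y, design, K_inv, logdet_K, max_dense=max_dense)
    if scheme == "auto":
        scheme = "blocked" if sys_.dim <= max_dense else "single_site"
    Kcsr = sparse.csr_matrix(K_inv)
    n, p, q_u, q_c = sys_.n, sys_.p, sys_.q_u, sys_.q_c
    sg, se = start.sigma_g, start.sigma_e
    sc = start.sigma_c if with_c else None

    if scheme == "single_site":
        # union sparsity pattern of C with per-term value arrays, so the
        # coefficient values track the variance draws in O(nnz)
        pads = [sparse.csr_matrix((p, p)), Kcsr]
        if q_c:
            pads.append(sparse.csr_matrix((q_c, q_c)))
        Kpad = sparse.block_diag(pads, format="csr")
        Cpad = sparse.identity(sys_.dim, format="csr") * 0.0
        if q_c:
            cd = np.zeros(sys_.dim)
            cd[p + q_u :] = 1.0
            Cpad = sparse.diags(cd).tocsr()
        union = (
            abs(sys_.MtM) + abs(Kpad) + abs(Cpad) + sparse.identity(sys_.dim, format="csr")
        ).tocsr()
        union.sort_indices()
        dim = sys_.dim
        rows_u = np.repeat(np.arange(dim, dtype=np.int64), np.diff(union.indptr))
        key_u = rows_u * dim + union.indices

        def aligned(Mat):
            coo = sparse.csr_matrix(Mat).tocoo()
            key = coo.row.astype(np.int64) * dim + coo.col
            pos = np.searchsorted(key_u, key)
            data = np.zeros(len(key_u))
            np.add.at(data, pos, coo.data)
            return data

        a_M = aligned(sys_.MtM)
        a_K = aligned(Kpad)
        a_C = aligned(Cpad)
        indptr, indices = union.indptr, union.indices
        diag_pos = np.empty(sys_.dim, dtype=np.int64)
        for i in range(sys_.dim):
            row = indices[indptr[i] : indptr[i + 1]]
            diag_pos[i] = indptr[i] + int(np.searchsorted(row, i))
        sweep, set_seed = _gibbs_sweep_kernel()
        set_seed(int(rng.integers(0, 2**31 - 1)))
        theta = np.zeros(sys_.dim)
        Mty = sys_.Mty
    elif scheme == "blocked":
        if not sys_._dense:
            raise ValueError(
                f"blocked Gibbs needs a dense factorisation; system dimension {sys_.dim} "
                f"exceeds max_dense={max_dense}"
            )
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    kept = []
    theta_sum = np.zeros(sys_.dim)
    n_kept = 0
    for cycle in range(total_cycles):
        if scheme == "blocked":
            vc = VarianceComponents(sg, se, sc)
            sys_.set_components(vc)
            mu = sys_.solution()
            _, cf = sys_._factor
            z = rng.standard_normal(sys_.dim)
            # C = L L' (lower); draw theta = mu + L'^-1 z  ~ N(mu, C^-1)
            dev = linalg.solve_triangular(cf, z, lower=True, trans="T")
            theta = mu + dev
        else:
            data = a_M / se + a_K / sg + (a_C / sc if with_c else 0.0 * a_C)
            sweep(indptr, indices, data, diag_pos, Mty / se, theta)
        u = theta[sys_.sl_u]
        e = y - sys_.M @ theta

        def draw_var(ssq, df):
            # scaled inverse-chi-square truncated at the flat prior's bound
            for _ in range(100):
                v = ssq / rng.chisquare(max(df, 1))
                if v <= bound:
                    return v
            return bound

        sg = draw_var(float(u @ (Kcsr @ u)), q_u - 2)
        if with_c:
            c = theta[sys_.sl_c]
            sc = draw_var(float(c @ c), q_c - 2)
        se = draw_var(float(e @ e), n - 2)
        if max(sg, se, sc or 0.0) > guard:
            raise ConvergenceError(
                f"Gibbs chain diverged at cycle {cycle}: variance exceeded guard {guard:.3g}",
                trace=kept,
            )
        if cycle >= burn_in and (cycle - burn_in) % thin == 0:
            row = {"cycle": cycle, "sigma_g": sg, "sigma_e": se}
            tot = sg + se + (sc or 0.0)
            row["h2"] = sg / tot
            if with_c:
                row["sigma_c"] = sc
                row["c2"] = sc / tot
            kept.append(row)
            theta_sum += theta
            n_kept += 1

    draws = pd.DataFrame(kept)
    stable, zscores = {}, {}
    use = draws
    for colname in ("sigma_g", "sigma_c", "sigma_e"):
        if colname not in draws:
            continue
        v = draws[colname].to_numpy()
        h = len(v) // 2
        z1, z2 = v[:h], v[h:]
        pooled = np.sqrt(z1.var() / h + z2.var() / (len(v) - h))
        zsc = float(abs(z1.mean() - z2.mean()) / pooled) if pooled > 0 else 0.0
        zscores[colname] = zsc
        stable[colname] = zsc < 4.0
    if not all(stable.values()):
        warnings.warn("variance trace not stabilised; summarising the second half only")
        use = draws.iloc[len(draws) // 2 :]
    vc = VarianceComponents(
        float(use["sigma_g"].mean()),
        float(use["sigma_e"].mean()),
        float(use["sigma_c"].mean()) if with_c else None,
    )
    theta_mean = theta_sum / max(n_kept, 1)
    solution = _pack_solution(theta_mean, design, animal_ids, 0.0)
    return GibbsResult(draws, vc, solution, stable, zscores)


# ---------------------------------------------------------------------------
# Bivariate REML (quasi-Newton on a log-Cholesky parameterisation)
# ---------------------------------------------------------------------------


def _chol_param_to_cov(v: np.ndarray) -> np.ndarray:
    L = np.array([[np.exp(v[0]), 0.0], [v[1], np.exp(v[2])]])
    return L @ L.T


def _cov_to_chol_param(S: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(S)
    return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])


class BivariateModel:
    """Two-trait animal model sharing the additive relationship structure.

    Trait 1 is fully recorded; trait-2 records may be missing (per-trait
    incidence, no phenotype imputation).  ``loglik`` evaluates the
    restricted likelihood at given 2x2 genetic/family/residual covariance
    blocks through the stacked MME identity; ``fit_reml`` maximises it by
    quasi-Newton steps on log-Cholesky coordinates, and ``fit_gibbs`` runs
    a blocked sampler with inverse-Wishart conditionals, drawing missing
    trait-2 residuals from their conditional each cycle.
    """

    def __init__(self, data, spec: ModelSpec, ped: Pedigree, K_inv, logdet_K: float):
        t1, t2 = spec.traits
        self.spec = spec
        self.ped = ped
        self.logdet_K = float(logdet_K)
        self.d1 = build_design(data, spec, ped)
        self.y1 = data[t1].to_numpy(float)
        self.obs2 = data[t2].notna().to_numpy()
        self.y2 = data.loc[self.obs2, t2].to_numpy(float)
        self.d2 = build_design(data.loc[self.obs2], spec, ped)
        self.n1, self.n2 = len(self.y1), len(self.y2)
        self.p1, self.p2 = self.d1.X.shape[1], self.d2.X.shape[1]
        self.q_u = self.d1.Z.shape[1]
        self.with_c = spec.include_c2
        self.q_c = self.d1.W.shape[1] if self.with_c else 0
        self.fam_levels = self.d1.family_levels
        if self.with_c:
            # trait-2 family incidence must share trait-1 level order
            lut = {f: j for j, f in enumerate(self.fam_levels)}
            fam2 = data.loc[self.obs2, "family_id"].astype(str).to_numpy()
            self.W2 = sparse.csr_matrix(
                (np.ones(self.n2), (np.arange(self.n2), [lut[f] for f in fam2])),
                shape=(self.n2, self.q_c),
            )
        else:
            self.W2 = None
        self.y = np.concatenate([self.y1, self.y2])
        self.Kcsc = sparse.csc_matrix(K_inv)
        self.pair_pos = np.flatnonzero(self.obs2)
        self.n_pair = len(self.pair_pos)

        Zero = sparse.csr_matrix
        n1, n2, p1, p2, q_u, q_c = self.n1, self.n2, self.p1, self.p2, self.q_u, self.q_c
        M1 = sparse.hstack(
            [self.d1.X, Zero((n1, p2)), self.d1.Z, Zero((n1, q_u))]
            + ([self.d1.W, Zero((n1, q_c))] if self.with_c else []),
            format="csr",
        )
        M2 = sparse.hstack(
            [Zero((n2, p1)), self.d2.X, Zero((n2, q_u)), self.d2.Z]
            + ([Zero((n2, q_c)), self.W2] if self.with_c else []),
            format="csr",
        )
        self.M = sparse.vstack([M1, M2], format="csr")
        self.dim = self.M.shape[1]

        # R^-1 has only four distinct scalar weights (unpaired trait-1
        # diagonal, paired diagonals, cross term), so M'R^-1M, M'R^-1y and
        # y'R^-1y decompose over fixed cross-products computed once here;
        # every likelihood evaluation is then scalar algebra plus one
        # Cholesky
        unpaired = np.flatnonzero(~self.obs2)
        M1p = M1[self.pair_pos]
        M1u = M1[unpaired]
        self._D_1u = (M1u.T @ M1u).toarray()
        self._D_1p = (M1p.T @ M1p).toarray()
        self._D_2 = (M2.T @ M2).toarray()
        cross = (M1p.T @ M2).toarray()
        self._D_x = cross + cross.T
        self._Kd = self.Kcsc.toarray()
        y1p = self.y1[self.pair_pos]
        y1u = self.y1[unpaired]
        self._r_1u = M1u.T @ y1u
        self._r_1p = M1p.T @ y1p
        self._r_2 = M2.T @ self.y2
        self._r_x = M1p.T @ self.y2 + M2.T @ y1p
        self._s_1u = float(y1u @ y1u)
        self._s_1p = float(y1p @ y1p)
        self._s_2 = float(self.y2 @ self.y2)
        self._s_x = float(y1p @ self.y2)

    def _weights(self, R0):
        r11, r12, r22 = R0[0, 0], R0[0, 1], R0[1, 1]
        det = r11 * r22 - r12 * r12
        if det <= 0 or r11 <= 0:
            raise ValueError("residual block not PD")
        logdet_R = float((self.n1 - self.n_pair) * np.log(r11) + self.n_pair * np.log(det))
        return 1.0 / r11, r22 / det, r11 / det, -r12 / det, logdet_R

    def _assemble_dense(self, G0, C0, R0):
        a1u, a1p, a2, ax, logdet_R = self._weights(R0)
        C = a1u * self._D_1u + a1p * self._D_1p + a2 * self._D_2 + ax * self._D_x
        G0i = np.linalg.inv(G0)
        p12 = self.p1 + self.p2
        q = self.q_u
        for i in range(2):
            for j in range(2):
                blk = C[p12 + i * q : p12 + (i + 1) * q, p12 + j * q : p12 + (j + 1) * q]
                blk += G0i[i, j] * self._Kd
        if self.with_c:
            C0i = np.linalg.inv(C0)
            base = p12 + 2 * q
            idx = np.arange(self.q_c)
            for i in range(2):
                for j in range(2):
                    C[base + i * self.q_c + idx, base + j * self.q_c + idx] += C0i[i, j]
        rhs = a1u * self._r_1u + a1p * self._r_1p + a2 * self._r_2 + ax * self._r_x
        yRy = a1u * self._s_1u + a1p * self._s_1p + a2 * self._s_2 + 2.0 * ax * self._s_x
        return C, rhs, yRy, logdet_R

    # -- likelihood machinery ------------------------------------------
    def _r_inverse(self, R0):
        """Sparse R^-1 over stacked records (2x2 blocks where both traits
        are recorded, scalar 1/r11 otherwise)."""
        n1, n2 = self.n1, self.n2
        r11, r12, r22 = R0[0, 0], R0[0, 1], R0[1, 1]
        det = r11 * r22 - r12 * r12
        if det <= 0 or r11 <= 0:
            raise ValueError("residual block not PD")
        d_1 = np.full(n1, 1.0 / r11)
        d_1[self.pair_pos] = r22 / det
        d_2 = np.full(n2, r11 / det)
        off = np.full(n2, -r12 / det)
        rows = np.concatenate(
            [np.arange(n1), n1 + np.arange(n2), self.pair_pos, n1 + np.arange(n2)]
        )
        cols = np.concatenate(
            [np.arange(n1), n1 + np.arange(n2), n1 + np.arange(n2), self.pair_pos]
        )
        vals = np.concatenate([d_1, d_2, off, off])
        Rinv = sparse.coo_matrix((vals, (rows, cols)), shape=(n1 + n2, n1 + n2)).tocsr()
        logdet_R = float((n1 - self.n_pair) * np.log(r11) + self.n_pair * np.log(det))
        return Rinv, logdet_R

    def _assemble(self, G0, C0, R0):
        Rinv, logdet_R = self._r_inverse(R0)
        MtRi = self.M.T @ Rinv
        C = (MtRi @ self.M).tocsc()
        G0i = np.linalg.inv(G0)
        pads = [
            sparse.csc_matrix((self.p1 + self.p2, self.p1 + self.p2)),
            sparse.kron(sparse.csr_matrix(G0i), self.Kcsc, format="csc"),
        ]
        if self.with_c:
            C0i = np.linalg.inv(C0)
            pads.append(
                sparse.kron(sparse.csr_matrix(C0i), sparse.identity(self.q_c), format="csc")
            )
        C = C + sparse.block_diag(pads, format="csc")
        return C, MtRi @ self.y, Rinv, logdet_R

    def loglik(self, G0, C0, R0, want_solution: bool = False):
        """Restricted log-likelihood at the given covariance blocks."""
        Cd, rhs, yRy, logdet_R = self._assemble_dense(G0, C0, R0)
        Cd = np.asfortranarray(Cd)
        cf, info = lapack.dpotrf(Cd, lower=1, overwrite_a=1)
        if info != 0:
            raise np.linalg.LinAlgError("stacked MME matrix not PD")
        theta, _ = lapack.dpotrs(cf, rhs, lower=1)
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf))))
        _, ldG0 = np.linalg.slogdet(G0)
        logdet_G = self.q_u * ldG0 + 2.0 * self.logdet_K
        if self.with_c:
            _, ldC0 = np.linalg.slogdet(C0)
            logdet_G += self.q_c * ldC0
        yPy = yRy - float(theta @ rhs)
        ptot = self.p1 + self.p2
        m2ll = (
            logdet_R
            + logdet_G
            + logdet_C
            + yPy
            + (self.n1 + self.n2 - ptot) * np.log(2 * np.pi)
        )
        if want_solution:
            return -0.5 * m2ll, theta
        return -0.5 * m2ll

    def _default_start(self):
        """Univariate AI-REML fits per trait seed the diagonals; the
        covariances start near zero."""
        try:
            vc1, _ = aireml(
                self.y1, self.d1, self.Kcsc, self.logdet_K, tol=1e-4, gtol=1e-2
            )
            vc2, _ = aireml(
                self.y2, self.d2, self.Kcsc, self.logdet_K, tol=1e-4, gtol=1e-2
            )
            floor1 = 1e-3 * float(np.var(self.y1))
            floor2 = 1e-3 * float(np.var(self.y2))
            G0 = np.diag([max(vc1.sigma_g, floor1), max(vc2.sigma_g, floor2)])
            C0 = (
                np.diag([max(vc1.sigma_c, floor1), max(vc2.sigma_c, floor2)])
                if self.with_c
                else None
            )
            R0 = np.diag([max(vc1.sigma_e, floor1), max(vc2.sigma_e, floor2)])
        except (ConvergenceError, ValueError):  # pragma: no cover - fallback
            vp = float(np.var(self.y1))
            vp2 = float(np.var(self.y2)) if self.n2 > 1 else vp
            k = 3 if self.with_c else 2
            G0 = np.diag([vp / k, vp2 / k])
            C0 = G0.copy() if self.with_c else None
            R0 = np.diag([vp / k, vp2 / k])
        G0[0, 1] = G0[1, 0] = 0.05 * np.sqrt(G0[0, 0] * G0[1, 1])
        if self.with_c:
            C0[0, 1] = C0[1, 0] = 0.0
        return G0, C0, R0

    def _pack(self, theta, ll=None):
        p12 = self.p1 + self.p2
        b = pd.Series(
            theta[:p12],
            index=[f"t1:{s}" for s in self.d1.x_names] + [f"t2:{s}" for s in self.d2.x_names],
        )
        u = pd.Series(theta[p12 : p12 + self.q_u], index=self.ped.ids)
        c = None
        if self.with_c:
            c = pd.Series(
                theta[p12 + 2 * self.q_u : p12 + 2 * self.q_u + self.q_c],
                index=self.fam_levels,
            )
        return MMESolution(b, u, c, 0.0, loglik=ll)

    # -- fitting --------------------------------------------------------
    def fit_reml(self, start=None, maxiter: int = 60):
        """Two-stage REML: the three cross-trait covariances are profiled
        first with the univariate variances held fixed (a 3-parameter
        search), then all nine parameters are polished jointly."""
        from scipy.optimize import minimize

        if start is None:
            G0, C0, R0 = self._default_start()
        else:
            G0, C0, R0 = start.G0, start.C0, start.R0

        def unpack(v):
            G0 = _chol_param_to_cov(v[0:3])
            k = 3
            C0 = None
            if self.with_c:
                C0 = _chol_param_to_cov(v[3:6])
                k = 6
            R0 = _chol_param_to_cov(v[k : k + 3])
            return G0, C0, R0

        def neg(v):
            try:
                return -self.loglik(*unpack(v))
            except (np.linalg.LinAlgError, ValueError):
                return 1e12

        # stage 1: covariances only, correlations parameterised on (-1, 1)
        blocks = [G0] + ([C0] if self.with_c else []) + [R0]

        def cov_from_rho(rho):
            out = []
            for S, r in zip(blocks, rho):
                S = S.copy()
                S[0, 1] = S[1, 0] = r * np.sqrt(S[0, 0] * S[1, 1])
                out.append(S)
            if not self.with_c:
                out.insert(1, None)
            return out[0], out[1], out[2]

        def neg_rho(rho):
            if np.any(np.abs(rho) >= 0.99):
                return 1e12
            try:
                G, C, R = cov_from_rho(rho)
                return -self.loglik(G, C, R)
            except (np.linalg.LinAlgError, ValueError):
                return 1e12

        k = len(blocks)
        res1 = minimize(
            neg_rho, np.zeros(k), method="L-BFGS-B",
            bounds=[(-0.98, 0.98)] * k, options={"maxiter": 40, "ftol": 1e-10},
        )
        G0, C0, R0 = cov_from_rho(res1.x)

        # stage 2: joint polish on log-Cholesky coordinates with loose box
        # bounds keeping the search away from degenerate regions
        v0 = np.concatenate(
            [_cov_to_chol_param(G0)]
            + ([_cov_to_chol_param(C0)] if self.with_c else [])
            + [_cov_to_chol_param(R0)]
        )
        vp = max(float(np.var(self.y1)), float(np.var(self.y2)) if self.n2 > 1 else 0.0)
        lo_d, hi_d = 0.5 * np.log(1e-5 * vp), 0.5 * np.log(50.0 * vp)
        hi_o = 10.0 * np.sqrt(vp)
        bounds = []
        for _ in range(len(v0) // 3):
            bounds += [(lo_d, hi_d), (-hi_o, hi_o), (lo_d, hi_d)]
        res = minimize(
            neg, v0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11},
        )
        G0, C0, R0 = unpack(res.x)
        ll, theta = self.loglik(G0, C0, R0, want_solution=True)
        vc = BivariateVarianceComponents(G0, C0 if self.with_c else np.zeros((2, 2)), R0)
        return vc, self._pack(theta, ll)

    def fit_gibbs(self, start=None, cycles: int = 4000, burn_in: int = 800, seed: int = 0):
        rng = np.random.default_rng(seed)
        if start is None:
            G0, C0, R0 = self._default_start()
        else:
            G0, C0, R0 = start.G0, start.C0, start.R0
        keep_G, keep_C, keep_R = [], [], []
        theta_sum = np.zeros(self.dim)
        kept = 0
        p12 = self.p1 + self.p2
        for cycle in range(cycles):
            C, rhs, Rinv, _ = self._assemble(G0, C0 if self.with_c else np.eye(2), R0)
            Cd = C.toarray()
            cf, info = lapack.dpotrf(Cd, lower=1, overwrite_a=1)
            if info != 0:
                raise ConvergenceError("bivariate Gibbs: stacked MME matrix not PD")
            mu, _ = lapack.dpotrs(cf, rhs, lower=1)
            z = rng.standard_normal(self.dim)
            theta = mu + linalg.solve_triangular(cf, z, lower=True, trans="T")
            U = theta[p12 : p12 + 2 * self.q_u].reshape(2, self.q_u).T
            Su = U.T @ (self.Kcsc @ U)
            G0 = stats.invwishart.rvs(df=self.q_u, scale=Su + 1e-8 * np.eye(2), random_state=rng)
            if self.with_c:
                Cc = theta[p12 + 2 * self.q_u :].reshape(2, self.q_c).T
                C0 = stats.invwishart.rvs(
                    df=self.q_c, scale=Cc.T @ Cc + 1e-8 * np.eye(2), random_state=rng
                )
            resid = self.y - self.M @ theta
            e1 = resid[: self.n1]
            e2 = resid[self.n1 :]
            # residual scatter over paired records; unpaired trait-1
            # residuals get a conditional draw for the missing trait-2 part
            E = np.column_stack([e1[self.pair_pos], e2])
            unpaired = np.flatnonzero(~self.obs2)
            if len(unpaired):
                r11, r12, r22 = R0[0, 0], R0[0, 1], R0[1, 1]
                cond_mu = r12 / r11 * e1[unpaired]
                cond_sd = np.sqrt(max(r22 - r12**2 / r11, 1e-12))
                e2_aug = cond_mu + cond_sd * rng.standard_normal(len(unpaired))
                E = np.vstack([E, np.column_stack([e1[unpaired], e2_aug])])
            R0 = stats.invwishart.rvs(
                df=self.n1, scale=E.T @ E + 1e-8 * np.eye(2), random_state=rng
            )
            if cycle >= burn_in:
                keep_G.append(G0)
                keep_C.append(C0 if self.with_c else np.zeros((2, 2)))
                keep_R.append(R0)
                theta_sum += theta
                kept += 1
        vc = BivariateVarianceComponents(
            np.mean(keep_G, axis=0), np.mean(keep_C, axis=0), np.mean(keep_R, axis=0)
        )
        return vc, self._pack(theta_sum / max(kept, 1))


def fit_bivariate(
    data: pd.DataFrame,
    spec: ModelSpec,
    ped: Pedigree,
    K_inv: sparse.spmatrix,
    logdet_K: float,
    method: str = "reml",
    start: BivariateVarianceComponents | None = None,
    maxiter: int = 300,
    gibbs_cycles: int = 4000,
    gibbs_burn_in: int = 800,
    seed: int = 0,
) -> tuple[BivariateVarianceComponents, MMESolution]:
    """Fit the two-trait model; thin wrapper over :class:`BivariateModel`."""
    model = BivariateModel(data, spec, ped, K_inv, logdet_K)
    if method == "gibbs":
        return model.fit_gibbs(start=start, cycles=gibbs_cycles, burn_in=gibbs_burn_in, seed=seed)
    if method != "reml":
        raise ValueError(f"unknown method {method!r}")
    return model.fit_reml(start=start, maxiter=maxiter)


# ---------------------------------------------------------------------------
# sklearn-style front end
# ---------------------------------------------------------------------------


class AnimalModel(BaseEstimator):
    """Scikit-learn style front end for the animal model.

    Parameters mirror :class:`ModelSpec`; ``fit`` takes the phenotype
    DataFrame, estimates variance components (AI-REML by default, Gibbs on
    request, or uses fixed ``varcomp``) and solves the MME.  Fitted
    attributes follow sklearn conventions (``varcomp_``, ``solution_``,
    ``h2_`` ...); ``predict`` returns EBVs for any pedigree animals.
    """

    def __init__(
        self,
        pedigree: Pedigree | None = None,
        genotypes: GenotypeMatrix | None = None,
        response: str = "tag_weight_g",
        fixed_factors: tuple[str, ...] = ("generation", "batch"),
        covariates: tuple[str, ...] = ("age_d",),
        include_c2: bool = True,
        relationship: str = "A",
        method: str = "aireml",
        varcomp: VarianceComponents | None = None,
        tau: float = 0.95,
        omega: float = 0.05,
        gibbs_cycles: int = 20_000,
        gibbs_burn_in: int = 2_000,
        seed: int = 0,
        options: dict | None = None,
    ):
        self.pedigree = pedigree
        self.genotypes = genotypes
        self.response = response
        self.fixed_factors = fixed_factors
        self.covariates = covariates
        self.include_c2 = include_c2
        self.relationship = relationship
        self.method = method
        self.varcomp = varcomp
        self.tau = tau
        self.omega = omega
        self.gibbs_cycles = gibbs_cycles
        self.gibbs_burn_in = gibbs_burn_in
        self.seed = seed
        self.options = options

    def spec(self) -> ModelSpec:
        return ModelSpec(
            response=self.response,
            fixed_factors=tuple(self.fixed_factors),
            covariates=tuple(self.covariates),
            include_c2=self.include_c2,
            relationship=self.relationship,
        )

    def fit(self, data: pd.DataFrame, y=None):
        if self.pedigree is None:
            raise ValueError("AnimalModel requires a pedigree")
        spec = self.spec()
        K_inv, logdet_K, hparts = make_kinship_inverse(
            self.pedigree,
            self.genotypes if spec.relationship == "H" else None,
            spec.relationship,
            self.tau,
            self.omega,
        )
        design = build_design(data, spec, self.pedigree)
        yv = data[spec.response].to_numpy(float)
        opts = dict(self.options or {})
        if self.varcomp is not None:
            self.varcomp_ = self.varcomp
            self.solution_ = solve_mme(
                yv, design, K_inv, self.varcomp, animal_ids=self.pedigree.ids,
                logdet_K=logdet_K,
            )
        elif self.method == "aireml":
            self.varcomp_, self.solution_ = aireml(
                yv, design, K_inv, logdet_K, animal_ids=self.pedigree.ids, **opts
            )
        elif self.method == "gibbs":
            res = gibbs_sampler(
                yv, design, K_inv, logdet_K,
                total_cycles=self.gibbs_cycles, burn_in=self.gibbs_burn_in,
                seed=self.seed, animal_ids=self.pedigree.ids, **opts,
            )
            self.gibbs_ = res
            self.varcomp_ = res.varcomp
            self.solution_ = res.solution
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.design_ = design
        self.K_inv_ = K_inv
        self.logdet_K_ = logdet_K
        self.h_parts_ = hparts
        self.h2_ = self.varcomp_.h2
        self.c2_ = self.varcomp_.c2
        self.loglik_ = self.solution_.loglik
        return self

    def predict(self, animal_ids) -> np.ndarray:
        """EBV (g) for the requested animals."""
        if not hasattr(self, "solution_"):
            raise ValueError("model is not fitted")
        return self.solution_.u.reindex(np.asarray(animal_ids, dtype=object)).to_numpy()
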