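"""Multi-population GBLUP mixed model with EM-REML variance components.

Phenotypes recorded in two pure lines and their F1 cross are treated as
three correlated traits, each individual expressing only the trait of its
own population.  The model for a record is

    y = X beta + u* + v* + p + e,

where u* (genotypic additive) has covariance G_o (x) G across the three
population scales, v* (genotypic dominance) has covariance D_o (x) D,
p is a permanent-environment effect shared by an individual's repeated
records, and e the residual; p and e have population-specific variances,
diagonal across populations.  G and D are the trace-normalized genomic
relationship matrices; G_o and D_o are 3x3 covariance matrices among the
population scales whose diagonals back-solve to per-SNP variances through
the scale factors tZ and tW.

Estimation is EM-REML (monotone in the restricted likelihood), followed
by one average-information (AI) evaluation whose inverse supplies
asymptotic standard errors.  Because each individual expresses one trait,
the observed-data covariance collapses to Hadamard products of the
population-level covariance matrices with G and D, and all linear algebra
is done at individual scale via the Woodbury identity; the EM conditional
expectations are taken in marker space (complete data = scaled SNP
effects), which remains exact when G has deficient rank (fewer markers
than individuals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

from .genotypes import (
    GenotypeMatrix,
    RelationshipMatrices,
    build_relationships,
    homozygosity,
)

__all__ = [
    "ModelSpec",
    "ComponentEstimates",
    "SNPVariances",
    "BlupSolutions",
    "build_model",
    "em_reml",
    "backsolve_snp_variances",
    "genotypic_correlations",
    "blup_solutions",
    "CrossbredGBLUP",
]


@dataclass
class ModelSpec:
    """Assembled design: records, fixed-effect matrix and genomic kernels.

    ``rec_ind`` maps each record to its individual's row in G/D;
    ``ind_pop`` and ``rec_pop`` are integer population codes indexing
    ``populations``.
    """

    y: np.ndarray
    X: np.ndarray
    fixed_names: list
    rec_ind: np.ndarray
    rec_pop: np.ndarray
    ind_pop: np.ndarray
    populations: list
    G: np.ndarray
    D: np.ndarray
    tZ: float
    tW: float
    n_markers: int
    individual_ids: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.G.shape[0]

    @property
    def n_records(self) -> int:
        return self.y.shape[0]


@dataclass
class ComponentEstimates:
    """REML estimates: population-scale covariance matrices, variances,
    fixed effects, asymptotic SEs and the likelihood trace."""

    populations: list
    G_o: np.ndarray
    D_o: np.ndarray
    perm_env: np.ndarray
    residual: np.ndarray
    beta: np.ndarray
    fixed_names: list
    se_G_o: np.ndarray
    se_D_o: np.ndarray
    se_perm_env: np.ndarray
    se_residual: np.ndarray
    ai_matrix: np.ndarray | None
    ai_cov: np.ndarray | None
    param_labels: list
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray
    tZ: float
    tW: float
    n_markers: int

    def param_index(self, label) -> int:
        return self.param_labels.index(label)


@dataclass
class SNPVariances:
    """Per-SNP additive and dominance variances per population, obtained
    by dividing population-scale variances by tZ and tW."""

    populations: list
    sigma2_a: np.ndarray
    sigma2_d: np.ndarray
    se_sigma2_a: np.ndarray
    se_sigma2_d: np.ndarray


@dataclass
class BlupSolutions:
    """BLUPs of genotypic additive (u) and dominance (v) values on every
    population scale (n_pop x n_individuals), permanent-environment
    effects, and GLS fixed-effect solutions."""

    populations: list
    individual_ids: np.ndarray
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    beta: np.ndarray
    fixed_names: list


# ---------------------------------------------------------------------------
# model assembly

def build_model(
    phenotypes: pd.DataFrame,
    geno,
    fixed_effects=(),
    covariates=(),
    include_homozygosity: bool = True,
) -> ModelSpec:
    """Assemble the multi-population mixed model.

    ``phenotypes`` needs columns ``individual_id``, ``population`` and
    ``phenotype`` plus any categorical ``fixed_effects`` and numeric
    ``covariates``.  ``geno`` is a (QC'd) GenotypeMatrix or a precomputed
    RelationshipMatrices.  Every phenotyped individual must be genotyped;
    an individual's records must all belong to its genotype population.
    With ``include_homozygosity`` the genomic homozygosity F_Ho enters as
    a population-specific fixed regression (one coefficient per
    population); if ``geno`` is a RelationshipMatrices a phenotype column
    ``F_Ho`` must supply the covariate instead.
    """
    req = {"individual_id", "population", "phenotype"}
    if not req.issubset(phenotypes.columns):
        raise ValueError(f"phenotypes must have columns {sorted(req)}")
    fho_ind = None
    if isinstance(geno, GenotypeMatrix):
        if include_homozygosity:
            fho_ind = dict(zip(geno.individual_ids, homozygosity(geno)))
        rel = build_relationships(geno)
    elif isinstance(geno, RelationshipMatrices):
        rel = geno
        if include_homozygosity:
            if "F_Ho" not in phenotypes.columns:
                raise ValueError(
                    "include_homozygosity=True with precomputed relationship "
                    "matrices requires an F_Ho phenotype column"
                )
    else:
        raise TypeError("geno must be a GenotypeMatrix or RelationshipMatrices")

    row_of = {str(i): k for k, i in enumerate(rel.individual_ids)}
    phen = phenotypes.reset_index(drop=True)
    unknown = sorted(set(map(str, phen["individual_id"])) - set(row_of))
    if unknown:
        raise ValueError(f"phenotyped individuals without genotypes: {unknown[:10]}")

    for iid, grp in phen.groupby("individual_id"):
        pops = set(grp["population"])
        gpop = str(rel.pop_labels[row_of[str(iid)]])
        if pops != {gpop}:
            raise ValueError(
                f"individual {iid}: phenotype population(s) {sorted(pops)} "
                f"do not match genotype population {gpop}"
            )

    rows = np.array([row_of[str(i)] for i in phen["individual_id"]])
    keep = np.unique(rows)  # preserves relationship-matrix order
    sub_of = {r: k for k, r in enumerate(keep)}
    rec_ind = np.array([sub_of[r] for r in rows])
    pop_of_ind = rel.pop_labels[keep]
    populations = list(pd.unique(pop_of_ind))
    pop_code = {p: k for k, p in enumerate(populations)}
    ind_pop = np.array([pop_code[p] for p in pop_of_ind])
    rec_pop = ind_pop[rec_ind]

    # fixed-effect design: population means, categorical dummies, covariates,
    # population-specific F_Ho regressions
    cols, names = [], []
    for p in populations:
        cols.append((phen["population"] == p).to_numpy(float))
        names.append(f"mu:{p}")
    for fe in fixed_effects:
        if fe not in phen.columns:
            raise ValueError(f"missing fixed-effect column {fe!r}")
        levels = sorted(map(str, pd.unique(phen[fe].astype(str))))
        for lev in levels[1:]:  # first level absorbed in the means
            cols.append((phen[fe].astype(str) == lev).to_numpy(float))
            names.append(f"{fe}:{lev}")
    for cv in covariates:
        if cv not in phen.columns:
            raise ValueError(f"missing covariate column {cv!r}")
        cols.append(phen[cv].to_numpy(float))
        names.append(cv)
    if include_homozygosity:
        if fho_ind is not None:
            fho_rec = np.array([fho_ind[i] for i in phen["individual_id"]], float)
        else:
            fho_rec = phen["F_Ho"].to_numpy(float)
        for p in populations:
            cols.append(fho_rec * (phen["population"] == p).to_numpy(float))
            names.append(f"F_Ho:{p}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "fixed-effect design is rank deficient (confounded levels) "
            f"among columns {names}"
        )

    return ModelSpec(
        y=phen["phenotype"].to_numpy(float),
        X=X,
        fixed_names=names,
        rec_ind=rec_ind,
        rec_pop=rec_pop,
        ind_pop=ind_pop,
        populations=populations,
        G=rel.G[np.ix_(keep, keep)],
        D=rel.D[np.ix_(keep, keep)],
        tZ=rel.tZ,
        tW=rel.tW,
        n_markers=rel.n_markers,
        individual_ids=rel.individual_ids[keep],
    )


# ---------------------------------------------------------------------------
# restricted-likelihood workspace (Woodbury, individual scale)

class _Workspace:
    """All P-matrix functionals needed by EM, AI and BLUP at given
    parameter values, computed without forming any N x N matrix."""

    def __init__(self, md: ModelSpec, G_o, D_o, sp, se):
        n = md.n_individuals
        popi = md.ind_pop
        K = G_o[np.ix_(popi, popi)] * md.G + D_o[np.ix_(popi, popi)] * md.D
        K[np.diag_indices_from(K)] += sp[popi]
        self.rinv = 1.0 / se[md.rec_pop]
        c = np.bincount(md.rec_ind, weights=self.rinv, minlength=n)
        dinv = 1.0 / c
        A = K + np.diag(dinv)
        cA = _chol(A)
        logdetA = 2.0 * np.sum(np.log(np.diag(cA[0])))
        Ainv = _chol_inverse(cA)
        # (K^{-1} + Z'R^{-1}Z)^{-1} via the swapped Woodbury identity;
        # valid for singular K, and Z'V^{-1}Z equals Ainv exactly
        Q = np.diag(dinv) - (dinv[:, None] * Ainv) * dinv[None, :]
        self.Q = 0.5 * (Q + Q.T)
        self.md = md

        X, y = md.X, md.y
        RX = self.rinv[:, None] * X
        tX = np.zeros((n, X.shape[1]))
        np.add.at(tX, md.rec_ind, RX)
        self.ViX = RX - self.rinv[:, None] * (self.Q @ tX)[md.rec_ind]
        self.Viy = self._Vi(y)
        XtViX = X.T @ self.ViX
        self.cXtViX = _chol(0.5 * (XtViX + XtViX.T))
        self.beta = cho_solve(self.cXtViX, self.ViX.T @ y)
        self.Py = self.Viy - self.ViX @ self.beta
        self.r_n = np.bincount(md.rec_ind, weights=self.Py, minlength=n)

        ZtViX = np.zeros((n, X.shape[1]))
        np.add.at(ZtViX, md.rec_ind, self.ViX)
        M = Ainv - ZtViX @ cho_solve(self.cXtViX, ZtViX.T)
        self.M = 0.5 * (M + M.T)

        diagVi = self.rinv - self.rinv**2 * np.diag(self.Q)[md.rec_ind]
        T = cho_solve(self.cXtViX, self.ViX.T)
        self.diagP = diagVi - np.einsum("ij,ji->i", self.ViX, T)

        logdetV = -np.sum(np.log(self.rinv)) + logdetA + np.sum(np.log(c))
        logdetXtViX = 2.0 * np.sum(np.log(np.diag(self.cXtViX[0])))
        self.loglik = -0.5 * (logdetV + logdetXtViX + float(y @ self.Py))

    def _Vi(self, x):
        """V^{-1} x for record-level vectors/matrices."""
        md = self.md
        n = self.Q.shape[0]
        x = np.asarray(x, float)
        if x.ndim == 1:
            rx = self.rinv * x
            t = np.bincount(md.rec_ind, weights=rx, minlength=n)
            return rx - self.rinv * (self.Q @ t)[md.rec_ind]
        rx = self.rinv[:, None] * x
        t = np.zeros((n, x.shape[1]))
        np.add.at(t, md.rec_ind, rx)
        return rx - self.rinv[:, None] * (self.Q @ t)[md.rec_ind]

    def project(self, qmat):
        """P @ qmat for record-level columns (applies the REML projection)."""
        Viq = self._Vi(qmat)
        return Viq - self.ViX @ cho_solve(self.cXtViX, self.ViX.T @ qmat)


def _chol(A):
    """Cholesky with escalating diagonal jitter on failure."""
    for jit in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            B = A if jit == 0.0 else A + jit * np.mean(np.diag(A)) * np.eye(len(A))
            return cho_factor(B, lower=True)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance matrix is not positive definite")


def _chol_inverse(cA):
    """Full symmetric inverse from a cho_factor result (LAPACK potri)."""
    from scipy.linalg.lapack import dpotri

    c, lower = cA
    inv, info = dpotri(c, lower=lower)
    if info != 0:
        raise np.linalg.LinAlgError(f"dpotri failed with info={info}")
    if lower:
        return np.tril(inv) + np.tril(inv, -1).T
    return np.triu(inv) + np.triu(inv, 1).T


def _project_psd(Mo, what):
    w, V = np.linalg.eigh(0.5 * (Mo + Mo.T))
    if w.min() < -1e-8 * max(w.max(), 1.0):
        warnings.warn(f"{what} update was not PSD; projecting", stacklevel=3)
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T


def _moment_init(model: ModelSpec):
    """Method-of-moments starting values from OLS residuals.

    The pooled within-individual mean square estimates the residual
    variance; the remainder of the phenotypic variance is split between
    the additive (one half) and the dominance and permanent-environment
    components (one quarter each).  Covariances start at zero.
    """
    P = len(model.populations)
    beta, *_ = np.linalg.lstsq(model.X, model.y, rcond=None)
    resid = model.y - model.X @ beta
    se = np.empty(P)
    between = np.empty(P)
    for k in range(P):
        rec = model.rec_pop == k
        r = resid[rec]
        ind = model.rec_ind[rec]
        dev = r - np.bincount(ind, weights=r)[ind] / np.bincount(ind)[ind]
        df = len(r) - len(np.unique(ind))  # sum of (n_i - 1)
        ss = float(np.sum(dev**2))
        vtot = float(np.var(r))
        se[k] = ss / df if df > 0 else 0.5 * vtot
        se[k] = np.clip(se[k], 0.1 * vtot, vtot)
        between[k] = max(vtot - se[k], 0.1 * vtot)
    G_o = np.diag(0.5 * between)
    D_o = np.diag(0.25 * between)
    sp = 0.25 * between
    return G_o, D_o, sp, se


def _theta(G_o, D_o, sp, se):
    iu = np.triu_indices(G_o.shape[0])
    return np.concatenate([G_o[iu], D_o[iu], sp, se])


# ---------------------------------------------------------------------------
# EM-REML

def em_reml(
    model: ModelSpec,
    init: dict | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    compute_se: bool = True,
    verbose: bool = False,
    accelerate: bool = True,
) -> ComponentEstimates:
    """Estimate variance components by EM-REML plus one AI evaluation.

    EM iterates the marker-space conditional-expectation updates for G_o
    and D_o and the classical trace-form updates for the permanent-
    environment and residual variances; the restricted log-likelihood is
    non-decreasing across the sequence of accepted iterates.  With
    ``accelerate`` (default) the EM map is extrapolated by a squared
    step-length scheme; an extrapolated point is accepted only if its
    restricted log-likelihood does not fall below the plain EM step's, so
    monotonicity is preserved while the crawl along near-ridges of the
    likelihood (dominance vs. permanent environment) is shortened by an
    order of magnitude.  Convergence is declared when the relative change
    of the full parameter vector over one step falls below ``tol``;
    ``max_iter`` caps the number of likelihood evaluations.  After the
    loop one average-information matrix is computed at the final
    estimates; its (pseudo-)inverse provides asymptotic SEs.  ``init``
    may provide any of G_o, D_o, perm_env, residual; the default is a
    method-of-moments split of the OLS residual variance.
    """
    est, _ = _em_core(model, init, tol, max_iter, compute_se, verbose,
                      accelerate)
    return est


class _EMProblem:
    """EM update map and parameter packing for one model."""

    def __init__(self, model: ModelSpec):
        self.model = model
        self.P = len(model.populations)
        self.m = model.n_markers
        self.n_by_pop = np.bincount(model.ind_pop, minlength=self.P).astype(float)
        self.N_by_pop = np.bincount(model.rec_pop, minlength=self.P).astype(float)
        vy = float(np.var(model.y))
        self.se_floor = 1e-8 * max(vy, 1e-12)
        self.iu = np.triu_indices(self.P)

    def step(self, ws: _Workspace, params):
        """One EM update from the workspace at ``params``."""
        G_o, D_o, sp, se = params
        model, m, P = self.model, self.m, self.P
        popi = model.ind_pop
        r, M, diagP, Py = ws.r_n, ws.M, ws.diagP, ws.Py

        Wg = G_o[:, popi]
        T1 = Wg @ (M * model.G) @ Wg.T
        Ug = Wg * r
        T2 = Ug @ model.G @ Ug.T
        G_o_new = _project_psd(G_o - (T1 - T2) / m, "G_o")

        Wd = D_o[:, popi]
        T1 = Wd @ (M * model.D) @ Wd.T
        Ud = Wd * r
        T2 = Ud @ model.D @ Ud.T
        D_o_new = _project_psd(D_o - (T1 - T2) / m, "D_o")

        mdiag = np.bincount(popi, weights=np.diag(M) - r**2, minlength=P)
        sp_new = np.maximum(sp - sp**2 * mdiag / self.n_by_pop, 0.0)
        pdiag = np.bincount(model.rec_pop, weights=diagP - Py**2, minlength=P)
        se_new = np.maximum(se - se**2 * pdiag / self.N_by_pop, self.se_floor)
        return G_o_new, D_o_new, sp_new, se_new

    def pack(self, params):
        G_o, D_o, sp, se = params
        return np.concatenate([G_o[self.iu], D_o[self.iu], sp, se])

    def unpack(self, theta):
        P, k = self.P, len(self.iu[0])
        G_o = np.zeros((P, P))
        D_o = np.zeros((P, P))
        G_o[self.iu] = theta[:k]
        D_o[self.iu] = theta[k:2 * k]
        G_o = G_o + np.triu(G_o, 1).T
        D_o = D_o + np.triu(D_o, 1).T
        sp = theta[2 * k:2 * k + P]
        se = theta[2 * k + P:]
        return G_o, D_o, sp, se

    def sanitize(self, params):
        """Pull an extrapolated point back into the parameter space."""
        G_o, D_o, sp, se = params
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            G_o = _project_psd(G_o, "G_o")
            D_o = _project_psd(D_o, "D_o")
        return (G_o, D_o, np.maximum(sp, 0.0), np.maximum(se, self.se_floor))


def _em_core(model, init, tol, max_iter, compute_se, verbose, accelerate=True):
    P = len(model.populations)
    n = model.n_individuals
    m = model.n_markers
    prob = _EMProblem(model)
    G_o, D_o, sp, se = _moment_init(model)
    if init:
        G_o = np.array(init.get("G_o", G_o), float)
        D_o = np.array(init.get("D_o", D_o), float)
        sp = np.array(init.get("perm_env", sp), float)
        se = np.array(init.get("residual", se), float)
    if np.linalg.eigvalsh(G_o).min() <= 0 or np.linalg.eigvalsh(D_o).min() <= 0:
        raise ValueError("initial G_o and D_o must be positive definite")
    params = (G_o, D_o, sp, se)

    trace = []
    converged = False
    it = 0
    step_max = 4.0  # adaptive extrapolation cap, grows while steps succeed

    def relchange(a, b):
        ta, tb = prob.pack(a), prob.pack(b)
        return np.linalg.norm(tb - ta) / max(np.linalg.norm(ta), 1e-300)

    while it < max_iter and not converged:
        ws0 = _Workspace(model, *params)
        trace.append(ws0.loglik)
        it += 1
        if verbose:
            print(f"EM eval {it}: loglik={ws0.loglik:.6f}")
        p1 = prob.step(ws0, params)
        if relchange(params, p1) <= tol:
            params, converged = p1, True
            break
        if not accelerate or it >= max_iter:
            params = p1
            continue

        ws1 = _Workspace(model, *p1)
        trace.append(ws1.loglik)
        it += 1
        p2 = prob.step(ws1, p1)
        if relchange(p1, p2) <= tol:
            params, converged = p2, True
            break

        t0, t1, t2 = prob.pack(params), prob.pack(p1), prob.pack(p2)
        rstep = t1 - t0
        v = (t2 - t1) - rstep
        nv = np.linalg.norm(v)
        if nv < 1e-300 or it >= max_iter:
            params = p2
            continue
        alpha = float(np.clip(-np.linalg.norm(rstep) / nv, -step_max, -1.0))
        prop = prob.sanitize(prob.unpack(t0 - 2.0 * alpha * rstep + alpha**2 * v))
        wsp = _Workspace(model, *prop)
        it += 1
        if wsp.loglik >= ws1.loglik - 1e-10 * abs(ws1.loglik):
            # accelerated point is at least as good as one EM step;
            # stabilize with a further EM step from it
            trace.append(wsp.loglik)
            stepped = prob.step(wsp, prop)
            if relchange(prop, stepped) <= tol:
                converged = True
            params = stepped
            if alpha == -step_max:
                step_max *= 2.0
        else:
            params = p2
            step_max = max(step_max / 2.0, 4.0)
    G_o, D_o, sp, se = params
    if not converged:
        warnings.warn(f"EM-REML did not converge in {max_iter} evaluations")

    ws = _Workspace(model, G_o, D_o, sp, se)  # at the final estimates
    trace.append(ws.loglik)

    labels = (
        [("G_o", k, l) for k in range(P) for l in range(k, P)]
        + [("D_o", k, l) for k in range(P) for l in range(k, P)]
        + [("perm_env", k) for k in range(P)]
        + [("residual", k) for k in range(P)]
    )
    ai = ai_cov = None
    se_G_o = np.full((P, P), np.nan)
    se_D_o = np.full((P, P), np.nan)
    se_sp = np.full(P, np.nan)
    se_se = np.full(P, np.nan)
    if compute_se:
        ai, ai_cov = _average_information(model, ws, labels)
        sd = np.sqrt(np.clip(np.diag(ai_cov), 0.0, None))
        for pos, lab in enumerate(labels):
            if lab[0] == "G_o":
                se_G_o[lab[1], lab[2]] = se_G_o[lab[2], lab[1]] = sd[pos]
            elif lab[0] == "D_o":
                se_D_o[lab[1], lab[2]] = se_D_o[lab[2], lab[1]] = sd[pos]
            elif lab[0] == "perm_env":
                se_sp[lab[1]] = sd[pos]
            else:
                se_se[lab[1]] = sd[pos]

    est = ComponentEstimates(
        populations=list(model.populations),
        G_o=G_o, D_o=D_o, perm_env=sp, residual=se,
        beta=ws.beta, fixed_names=list(model.fixed_names),
        se_G_o=se_G_o, se_D_o=se_D_o, se_perm_env=se_sp, se_residual=se_se,
        ai_matrix=ai, ai_cov=ai_cov, param_labels=labels,
        converged=converged, n_iter=it,
        loglik_trace=np.asarray(trace), tZ=model.tZ, tW=model.tW,
        n_markers=model.n_markers,
    )
    return est, ws


def _dV_Py(model, ws, lab):
    """(dV/d theta) P y at record level for one variance parameter."""
    r = ws.r_n
    popi = model.ind_pop
    if lab[0] in ("G_o", "D_o"):
        Kmat = model.G if lab[0] == "G_o" else model.D
        _, k, l = lab
        ik = (popi == k).astype(float)
        il = (popi == l).astype(float)
        dKr = ik * (Kmat @ (il * r))
        if k != l:
            dKr = dKr + il * (Kmat @ (ik * r))
        return dKr[model.rec_ind]
    if lab[0] == "perm_env":
        return ((popi == lab[1]) * r)[model.rec_ind]
    return (model.rec_pop == lab[1]) * ws.Py


def _average_information(model, ws, labels):
    """AI matrix 0.5 * (dV_i Py)' P (dV_j Py) and its pseudo-inverse."""
    Qm = np.column_stack([_dV_Py(model, ws, lab) for lab in labels])
    PQ = ws.project(Qm)
    ai = 0.5 * (Qm.T @ PQ)
    ai = 0.5 * (ai + ai.T)
    ai_cov = np.linalg.pinv(ai, hermitian=True)
    return ai, ai_cov


# ---------------------------------------------------------------------------
# derived quantities

def backsolve_snp_variances(
    est: ComponentEstimates, tZ: float | None = None, tW: float | None = None
) -> SNPVariances:
    """Per-SNP variances: sigma2_a = G_o[k,k]/tZ, sigma2_d = D_o[k,k]/tW."""
    tZ = est.tZ if tZ is None else tZ
    tW = est.tW if tW is None else tW
    if tZ <= 0 or tW <= 0:
        raise ValueError("scale factors tZ and tW must be positive")
    return SNPVariances(
        populations=list(est.populations),
        sigma2_a=np.diag(est.G_o) / tZ,
        sigma2_d=np.diag(est.D_o) / tW,
        se_sigma2_a=np.diag(est.se_G_o) / tZ,
        se_sigma2_d=np.diag(est.se_D_o) / tW,
    )


def genotypic_correlations(est: ComponentEstimates):
    """Genotypic correlations r = cov/sqrt(var_i var_j) among population
    scales for additive and dominance effects, with delta-method SEs from
    the AI matrix.  Correlations with a non-positive variance are NaN.
    """
    P = len(est.populations)

    def corr_with_se(Mo, name):
        r = np.full((P, P), np.nan)
        se = np.full((P, P), np.nan)
        np.fill_diagonal(r, 1.0)
        for k in range(P):
            for l in range(k + 1, P):
                vk, vl, c = Mo[k, k], Mo[l, l], Mo[k, l]
                if vk <= 0 or vl <= 0:
                    continue
                s = np.sqrt(vk * vl)
                r[k, l] = r[l, k] = c / s
                if est.ai_cov is None:
                    continue
                idx = [
                    est.param_index((name, k, k)),
                    est.param_index((name, l, l)),
                    est.param_index((name, k, l)),
                ]
                grad = np.array([-c / (2 * vk * s), -c / (2 * vl * s), 1.0 / s])
                cov = est.ai_cov[np.ix_(idx, idx)]
                var = float(grad @ cov @ grad)
                se[k, l] = se[l, k] = np.sqrt(max(var, 0.0))
        pops = est.populations
        return (
            pd.DataFrame(r, index=pops, columns=pops),
            pd.DataFrame(se, index=pops, columns=pops),
        )

    corr_A, se_A = corr_with_se(est.G_o, "G_o")
    corr_D, se_D = corr_with_se(est.D_o, "D_o")
    return corr_A, corr_D, se_A, se_D


def blup_solutions(model: ModelSpec, est: ComponentEstimates) -> BlupSolutions:
    """BLUPs of u*, v* (on every population scale) and p at the estimates.

    u_hat[k] = (G_o[k, pop(.)] o r)' G with r = Z' P y, and analogously
    for v_hat; cross-population rows predict an individual's genotypic
    value were it expressed on another population's scale.
    """
    ws = _Workspace(model, est.G_o, est.D_o, est.perm_env, est.residual)
    return _blups_from_ws(model, est, ws)


def _blups_from_ws(model, est, ws):
    popi = model.ind_pop
    r = ws.r_n
    u = (est.G_o[:, popi] * r) @ model.G
    v = (est.D_o[:, popi] * r) @ model.D
    p = est.perm_env[popi] * r
    return BlupSolutions(
        populations=list(model.populations),
        individual_ids=model.individual_ids,
        u=u, v=v, p=p, beta=ws.beta, fixed_names=list(model.fixed_names),
    )


# ---------------------------------------------------------------------------
# sklearn-style estimator

class CrossbredGBLUP(BaseEstimator):
    """GBLUP variance-component estimator for two pure lines and their F1.

    Fits the multi-population mixed model by EM-REML and exposes the
    estimated covariance matrices, SNP-level variances, genotypic
    correlations and BLUP solutions as fitted attributes.

    Parameters
    ----------
    fixed_effects : sequence of str
        Categorical phenotype columns entering the fixed design.
    covariates : sequence of str
        Numeric phenotype columns entering as global regressions.
    include_homozygosity : bool
        Add the genomic homozygosity F_Ho as a population-specific fixed
        regression (the inbreeding-depression covariate).
    tol, max_iter : float, int
        EM convergence tolerance (relative parameter change) and cap.
    init : dict or None
        Optional starting values (keys G_o, D_o, perm_env, residual).
    compute_se : bool
        Evaluate the average-information matrix for asymptotic SEs.
    """

    def __init__(self, fixed_effects=(), covariates=(),
                 include_homozygosity=True, tol=1e-8, max_iter=500,
                 init=None, compute_se=True, verbose=False):
        self.fixed_effects = fixed_effects
        self.covariates = covariates
        self.include_homozygosity = include_homozygosity
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.compute_se = compute_se
        self.verbose = verbose

    def fit(self, phenotypes: pd.DataFrame, genotypes):
        """Fit from a phenotype table and a GenotypeMatrix (or
        precomputed RelationshipMatrices)."""
        model = build_model(
            phenotypes, genotypes,
            fixed_effects=tuple(self.fixed_effects),
            covariates=tuple(self.covariates),
            include_homozygosity=self.include_homozygosity,
        )
        est, ws = _em_core(model, self.init, self.tol, self.max_iter,
                           self.compute_se, self.verbose)
        blups = _blups_from_ws(model, est, ws)
        self.model_ = model
        self.estimates_ = est
        self.populations_ = est.populations
        self.G_o_, self.D_o_ = est.G_o, est.D_o
        self.perm_env_, self.residual_ = est.perm_env, est.residual
        self.beta_ = est.beta
        self.fixed_effect_names_ = est.fixed_names
        self.se_G_o_, self.se_D_o_ = est.se_G_o, est.se_D_o
        self.se_perm_env_, self.se_residual_ = est.se_perm_env, est.se_residual
        self.converged_ = est.converged
        self.n_iter_ = est.n_iter
        self.loglik_trace_ = est.loglik_trace
        self.tZ_, self.tW_ = est.tZ, est.tW
        self.u_, self.v_, self.p_ = blups.u, blups.v, blups.p
        self.individual_ids_ = blups.individual_ids
        return self

    def predict(self, individual_ids=None) -> np.ndarray:
        """Total genotypic value u* + v* of fitted individuals on their
        own population's scale."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        own = self.model_.ind_pop
        total = self.u_[own, np.arange(len(own))] + self.v_[own, np.arange(len(own))]
        if individual_ids is None:
            return total
        pos = {str(i): k for k, i in enumerate(self.individual_ids_)}
        return np.array([total[pos[str(i)]] for i in individual_ids])

    def backsolve_snp_variances(self) -> SNPVariances:
        return backsolve_snp_variances(self.estimates_)

    def genotypic_correlations(self):
        return genotypic_correlations(self.estimates_)
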