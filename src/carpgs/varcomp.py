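"""REML variance components under the additive animal model.

Model: y = Xb + Zu + e with u ~ N(0, K sigma_g2) for a relationship matrix
K (pedigree A or genomic G) and e ~ N(0, I sigma_e2); the only fixed effect
besides the intercept is the factorial-cross factor.  Heritability is
h2 = sigma_g2 / (sigma_g2 + sigma_e2).

Estimation is average-information (AI) REML.  The relationship matrix is
eigendecomposed once, K = U D U'; rotating y and X by U' makes the
phenotypic covariance diagonal (univariate) or 2x2-block-diagonal
(bivariate), so every AI iteration costs O(n) / O(n) small-matrix work.
This is algebraically the same REML problem, not an approximation.  When an
AI step leaves the parameter space the univariate fitter falls back to an
EM step; the bivariate fitter step-halves and, if needed, projects the
updated covariance matrices to the nearest positive semidefinite matrix.
Standard errors come from the inverse AI matrix at convergence;
heritability and genetic-correlation SEs by the delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .relmat import RelationshipMatrix

_FLOOR_FRAC = 1e-8  # component floor as a fraction of phenotypic variance


@dataclass
class ModelSpec:
    """Which traits and fixed factor to fit, plus convergence control."""

    traits: tuple[str, ...] = ("length_mm",)
    fixed: str = "cross"
    tol: float = 1e-8
    max_iter: int = 200


@dataclass
class VarianceEstimates:
    """(Co)variance components and derived genetic parameters.

    ``sigma_g2`` and ``sigma_e2`` are t x t matrices (1 x 1 in the
    univariate case); ``h2`` and ``se_h2`` are per-trait arrays.
    """

    traits: tuple[str, ...]
    sigma_g2: np.ndarray
    sigma_e2: np.ndarray
    h2: np.ndarray
    se_h2: np.ndarray
    rg: float | None
    se_rg: float | None
    loglik: float
    iterations: int
    converged: bool
    param_cov: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def sg2(self) -> float:
        return float(self.sigma_g2[0, 0])

    @property
    def se2(self) -> float:
        return float(self.sigma_e2[0, 0])

    @property
    def lambda_ratio(self) -> float:
        """sigma_e2 / sigma_g2 shrinkage ratio of the mixed-model equations."""
        return self.se2 / self.sg2

    def to_dict(self) -> dict:
        return {
            "traits": list(self.traits),
            "sigma_g2": self.sigma_g2.tolist(),
            "sigma_e2": self.sigma_e2.tolist(),
            "h2": self.h2.tolist(),
            "se_h2": [None if np.isnan(v) else float(v) for v in self.se_h2],
            "rg": self.rg,
            "se_rg": self.se_rg,
            "loglik": self.loglik,
            "iterations": self.iterations,
            "converged": self.converged,
        }


def fixed_design(phenotypes: pd.DataFrame, fixed: str | None = "cross") -> np.ndarray:
    """Full-rank fixed-effect design: intercept + treatment-coded factor.

    ``fixed=None`` (or a column absent from the table) gives an
    intercept-only design; the sentinel ``"none"`` gives an empty design
    (no fixed effects at all, useful for closed-form checks).
    """
    n = len(phenotypes)
    if fixed == "none":
        return np.zeros((n, 0))
    if fixed is None or fixed not in phenotypes.columns:
        return np.ones((n, 1))
    levels = pd.unique(phenotypes[fixed])
    x = np.ones((n, len(levels)))
    for j, lev in enumerate(levels[1:], start=1):
        x[:, j] = (phenotypes[fixed] == lev).astype(float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("singular fixed-effect design")
    return x


def relmat_eig(relmat: RelationshipMatrix, ids) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of K restricted to ``ids`` (in that order).

    Returns (U, d) with tiny negative eigenvalues clipped to zero.
    """
    k = relmat.subset(list(ids)).values
    d, u = np.linalg.eigh(k)
    return u, np.clip(d, 0.0, None)


# ---------------------------------------------------------------------------
# univariate AI-REML


def _uni_inner(theta, yt, xt, d):
    """Common per-iteration quantities in the rotated basis."""
    sg, se = theta
    v = sg * d + se
    w = 1.0 / v
    xw = xt * w[:, None]
    c_mat = xt.T @ xw
    cho = linalg.cho_factor(c_mat)
    b = linalg.cho_solve(cho, xw.T @ yt)
    r = yt - xt @ b
    py = w * r
    ypy = float(yt @ py)
    ll = -0.5 * (np.log(v).sum() + np.linalg.slogdet(c_mat)[1] + ypy)
    return v, w, xw, cho, py, ll


def _uni_trace_p(w, xw, xt, cho, weights):
    """tr(P diag(weights)) with P the REML projection matrix."""
    t1 = float(w @ weights)
    m = xw.T @ (weights[:, None] * xw)
    t2 = float(np.trace(linalg.cho_solve(cho, m)))
    return t1 - t2


def _uni_p_apply(f, w, xw, xt, cho):
    """P f for a vector f in the rotated basis."""
    t = xw.T @ f
    return w * f - xw @ linalg.cho_solve(cho, t)


def reml_fit(phenotypes: pd.DataFrame, spec: ModelSpec, relmat: RelationshipMatrix,
             eig: tuple[np.ndarray, np.ndarray] | None = None) -> VarianceEstimates:
    """Univariate AI-REML fit of the animal model.

    ``phenotypes`` needs columns ``id``, the trait named in ``spec.traits``
    and (optionally) the fixed factor.  Rows with a missing trait value are
    dropped.  ``eig`` optionally supplies a precomputed ``relmat_eig`` for
    the phenotyped ids, in the row order of ``phenotypes``.
    """
    if len(spec.traits) != 1:
        raise ValueError("reml_fit is univariate; use bivariate_reml_fit for two traits")
    trait = spec.traits[0]
    ph = phenotypes.dropna(subset=[trait]).reset_index(drop=True)
    n = len(ph)
    x = fixed_design(ph, spec.fixed)
    if n < x.shape[1] + 2:
        raise ValueError("too few records for the fixed-effect structure")
    y = ph[trait].to_numpy(dtype=float)
    u, d = relmat_eig(relmat, ph["id"]) if eig is None else eig
    yt = u.T @ y
    xt = u.T @ x

    var_y = float(np.var(y, ddof=1))
    floor = _FLOOR_FRAC * var_y
    theta = np.array([var_y / 2, var_y / 2])
    converged = False
    ai = np.eye(2)
    it = 0
    for it in range(1, spec.max_iter + 1):
        v, w, xw, cho, py, ll = _uni_inner(theta, yt, xt, d)
        f_g, f_e = d * py, py
        tr_pg = _uni_trace_p(w, xw, xt, cho, d)
        tr_pe = _uni_trace_p(w, xw, xt, cho, np.ones_like(d))
        score = -0.5 * np.array([tr_pg - py @ f_g, tr_pe - py @ f_e])
        pf_g = _uni_p_apply(f_g, w, xw, xt, cho)
        pf_e = _uni_p_apply(f_e, w, xw, xt, cho)
        ai = 0.5 * np.array([[f_g @ pf_g, f_g @ pf_e], [f_e @ pf_g, f_e @ pf_e]])
        try:
            delta = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            delta = score / max(np.abs(np.diag(ai)).max(), 1.0)
        # AI step with halving until the REML likelihood does not decrease;
        # EM step (positivity-preserving) if no acceptable AI step exists
        new = None
        step = 1.0
        for _ in range(10):
            cand = np.maximum(theta + step * delta, floor)
            if (cand > 0).all():
                cll = _uni_inner(cand, yt, xt, d)[-1]
                if cll >= ll - 1e-10:
                    new = cand
                    break
            step /= 2
        if new is None:
            em = theta + theta ** 2 / n * np.array([py @ f_g - tr_pg, py @ f_e - tr_pe])
            new = np.maximum(em, floor)
        change = np.max(np.abs(new - theta) / (np.abs(theta) + floor))
        theta = new
        if change < spec.tol:
            converged = True
            break

    *_, ll = _uni_inner(theta, yt, xt, d)
    sg, se = theta
    h2 = sg / (sg + se)
    at_boundary = bool(min(sg, se) <= floor * (1 + 1e-6))
    try:
        cov = np.linalg.inv(ai)
        se_comp = np.sqrt(np.clip(np.diag(cov), 0, None))
        grad = np.array([se, -sg]) / (sg + se) ** 2
        se_h2 = math.sqrt(max(float(grad @ cov @ grad), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = np.full((2, 2), np.nan)
        se_comp = np.array([np.nan, np.nan])
        se_h2 = np.nan
    if at_boundary:
        se_h2 = np.nan
    return VarianceEstimates(
        traits=(trait,),
        sigma_g2=np.array([[sg]]), sigma_e2=np.array([[se]]),
        h2=np.array([h2]), se_h2=np.array([se_h2]),
        rg=None, se_rg=None, loglik=ll, iterations=it, converged=converged,
        param_cov=cov,
    )


# ---------------------------------------------------------------------------
# bivariate AI-REML

_E_BASIS = (
    np.array([[1.0, 0.0], [0.0, 0.0]]),
    np.array([[0.0, 1.0], [1.0, 0.0]]),
    np.array([[0.0, 0.0], [0.0, 1.0]]),
)


def _mats_from_theta(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g0 = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
    r0 = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
    return g0, r0


def _nearest_psd(m: np.ndarray, floor: float) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    return (v * np.clip(w, floor, None)) @ v.T


def _bi_inner(theta, yt, xt, d):
    g0, r0 = _mats_from_theta(theta)
    n, p = xt.shape
    v = d[:, None, None] * g0 + r0  # (n, 2, 2)
    det = v[:, 0, 0] * v[:, 1, 1] - v[:, 0, 1] ** 2
    # reject singular or numerically meaningless states (cond >~ 1e12)
    if (v[:, 0, 0] <= 0).any() or (det <= 1e-12 * v[:, 0, 0] * v[:, 1, 1]).any():
        return None
    w = np.empty_like(v)
    w[:, 0, 0] = v[:, 1, 1] / det
    w[:, 1, 1] = v[:, 0, 0] / det
    w[:, 0, 1] = w[:, 1, 0] = -v[:, 0, 1] / det
    c = np.einsum("nts,np,nq->tpsq", w, xt, xt).reshape(2 * p, 2 * p)
    rhs = np.einsum("nts,ns,np->tp", w, yt, xt).reshape(2 * p)
    try:
        cho = linalg.cho_factor(c)
    except np.linalg.LinAlgError:
        return None
    b = linalg.cho_solve(cho, rhs).reshape(2, p)
    r = yt - xt @ b.T  # (n, 2)
    py = np.einsum("nts,ns->nt", w, r)
    ypy = float(np.einsum("nt,nt->", yt, py))
    ll = -0.5 * (np.log(det).sum() + 2 * np.sum(np.log(np.diag(cho[0]))) + ypy)
    return v, w, cho, py, ll


def _bi_p_apply(f, w, xt, cho):
    wf = np.einsum("nts,ns->nt", w, f)
    t = np.einsum("nt,np->tp", wf, xt).reshape(-1)
    h = linalg.cho_solve(cho, t).reshape(2, -1)
    xh = xt @ h.T  # (n, 2)
    return np.einsum("nts,ns->nt", w, f - xh)


def bivariate_reml_fit(phenotypes: pd.DataFrame, spec: ModelSpec,
                       relmat: RelationshipMatrix,
                       eig: tuple[np.ndarray, np.ndarray] | None = None
                       ) -> VarianceEstimates:
    """Two-trait AI-REML on 2x2 genetic and residual covariance matrices.

    Both traits must be recorded on the same individuals (rows missing
    either trait are dropped); the fixed structure is the same per trait.
    """
    if len(spec.traits) != 2:
        raise ValueError("bivariate_reml_fit needs exactly two traits")
    t1, t2 = spec.traits
    ph = phenotypes.dropna(subset=[t1, t2]).reset_index(drop=True)
    n = len(ph)
    x = fixed_design(ph, spec.fixed)
    p = x.shape[1]
    if n < p + 3:
        raise ValueError("too few records for the fixed-effect structure")
    y = ph[[t1, t2]].to_numpy(dtype=float)
    u, d = relmat_eig(relmat, ph["id"]) if eig is None else eig
    yt = u.T @ y
    xt = u.T @ x

    cov_y = np.cov(y.T)
    scale = float(np.trace(cov_y)) / 2
    floor = _FLOOR_FRAC * scale
    psd_floor = 1e-6 * scale  # projection floor; keeps 2x2 inverses stable
    g0 = 0.5 * cov_y
    r0 = 0.5 * cov_y
    theta = np.array([g0[0, 0], g0[0, 1], g0[1, 1], r0[0, 0], r0[0, 1], r0[1, 1]])

    coeffs = [d, d, d, np.ones_like(d), np.ones_like(d), np.ones_like(d)]
    bases = list(_E_BASIS) * 2
    converged = False
    ai = np.eye(6)
    it = 0
    for it in range(1, spec.max_iter + 1):
        state = _bi_inner(theta, yt, xt, d)
        if state is None:
            g0, r0 = _mats_from_theta(theta)
            g0, r0 = _nearest_psd(g0, floor), _nearest_psd(r0, psd_floor)
            theta = np.array([g0[0, 0], g0[0, 1], g0[1, 1], r0[0, 0], r0[0, 1], r0[1, 1]])
            state = _bi_inner(theta, yt, xt, d)
            if state is None:  # pragma: no cover
                raise RuntimeError("bivariate REML: could not recover a valid covariance")
        v, w, cho, py, ll = state

        scores = np.empty(6)
        fs = []
        for k in range(6):
            e, c = bases[k], coeffs[k]
            # tr(P dV_k): direct part minus fixed-effect correction
            tr_wd = float(np.einsum("nts,st,n->", w, e, c))
            a_k = np.einsum("nab,bc,ncd->nad", w, e, w) * c[:, None, None]
            m = np.einsum("nts,np,nq->tpsq", a_k, xt, xt).reshape(2 * p, 2 * p)
            tr_corr = float(np.trace(linalg.cho_solve(cho, m)))
            f_k = np.einsum("ts,ns->nt", e, py) * c[:, None]
            quad = float(np.einsum("nt,nt->", py, f_k))
            scores[k] = -0.5 * (tr_wd - tr_corr - quad)
            fs.append(f_k)
        pfs = [_bi_p_apply(f, w, xt, cho) for f in fs]
        for k in range(6):
            for l in range(6):
                ai[k, l] = 0.5 * float(np.einsum("nt,nt->", fs[k], pfs[l]))
        ai = (ai + ai.T) / 2

        if not (np.isfinite(scores).all() and np.isfinite(ai).all()):
            break  # numerically degenerate boundary; keep the last iterate
        try:
            delta = np.linalg.solve(ai, scores)
        except np.linalg.LinAlgError:
            delta = scores / max(np.abs(np.diag(ai)).max(), 1.0)
        if not np.isfinite(delta).all():
            break
        big = np.abs(delta).max()
        if big > 10 * scale:  # trust region: AI steps can blow up near boundaries
            delta = delta * (10 * scale / big)

        step = 1.0
        cand = None
        for _ in range(12):
            trial = theta + step * delta
            g0c, r0c = _mats_from_theta(trial)
            if (np.trace(g0c) + np.trace(r0c) <= 1e4 * scale
                    and np.linalg.eigvalsh(g0c).min() >= 0
                    and np.linalg.eigvalsh(r0c).min() > 0):
                st = _bi_inner(trial, yt, xt, d)
                if st is not None and st[-1] >= ll - 1e-10:
                    cand = trial
                    break
            step /= 2
        if cand is None:  # project the full AI update to the nearest PSD pair
            g0c, r0c = _mats_from_theta(theta + delta)
            g0c, r0c = _nearest_psd(g0c, floor), _nearest_psd(r0c, psd_floor)
            cand = np.array([g0c[0, 0], g0c[0, 1], g0c[1, 1], r0c[0, 0], r0c[0, 1], r0c[1, 1]])
            st = _bi_inner(cand, yt, xt, d)
            if st is None or st[-1] < ll - 1e-10:
                break  # cannot improve without leaving the valid region
        change = np.max(np.abs(cand - theta) / (np.abs(theta) + floor))
        theta = cand
        if change < spec.tol:
            converged = True
            break

    state = _bi_inner(theta, yt, xt, d)
    ll = state[-1] if state is not None else np.nan
    g0, r0 = _mats_from_theta(theta)
    h2 = np.array([g0[0, 0] / (g0[0, 0] + r0[0, 0]), g0[1, 1] / (g0[1, 1] + r0[1, 1])])
    denom = math.sqrt(max(g0[0, 0] * g0[1, 1], floor ** 2))
    rg = float(g0[0, 1] / denom) if denom > 0 else np.nan

    try:
        cov = np.linalg.inv(ai)
        se_h2 = np.empty(2)
        for t, (gi, ri) in enumerate(((0, 3), (2, 5))):
            gv, rv = theta[gi], theta[ri]
            grad = np.zeros(6)
            grad[gi] = rv / (gv + rv) ** 2
            grad[ri] = -gv / (gv + rv) ** 2
            se_h2[t] = math.sqrt(max(float(grad @ cov @ grad), 0.0))
        grad = np.zeros(6)
        grad[0] = -rg / (2 * theta[0])
        grad[1] = 1.0 / denom
        grad[2] = -rg / (2 * theta[2])
        se_rg = math.sqrt(max(float(grad @ cov @ grad), 0.0))
    except (np.linalg.LinAlgError, ZeroDivisionError):  # pragma: no cover
        cov = np.full((6, 6), np.nan)
        se_h2 = np.array([np.nan, np.nan])
        se_rg = np.nan

    return VarianceEstimates(
        traits=(t1, t2), sigma_g2=g0, sigma_e2=r0, h2=h2, se_h2=se_h2,
        rg=rg, se_rg=float(se_rg), loglik=float(ll), iterations=it,
        converged=converged, param_cov=cov,
    )
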