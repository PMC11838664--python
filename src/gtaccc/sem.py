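"""Severity-factor structural models fit to (R, V) by diagonally weighted
least squares.

The implied matrix is ``sigma(theta) = Lambda Psi Lambda' + Theta`` with
standardized factors (unit variances, free pattern loadings) and a diagonal
residual matrix.  External single-indicator traits enter as standardized
latents (loading fixed to 1, residual fixed to 0) free to correlate with
every severity factor.  The fit function weights squared moment residuals
by the inverse diagonal of the sampling covariance matrix V; the full V is
used only for sandwich standard errors and the residual-based chi-square.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .ldsc import GeneticCovStruct, smooth_to_psd, vech_indices

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# model specification

@dataclass
class FactorModelSpec:
    """Loading/covariance/residual masks of a severity-factor model."""

    indicators: list[str]            # cut traits then external traits
    factor_names: list[str]
    lambda_mask: np.ndarray          # (k, m) bool: free loading
    lambda_fixed: np.ndarray         # (k, m) float: fixed values where not free
    theta_free: np.ndarray           # (k,) bool: free residual variance
    theta_fixed: np.ndarray          # (k,) float: fixed residuals where not free
    psi_free: np.ndarray             # (m, m) bool, symmetric: free correlation
    external: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        k, m = self.lambda_mask.shape
        if len(self.indicators) != k or len(self.factor_names) != m:
            raise ValueError("mask dimensions inconsistent with names")
        loads = self.lambda_mask | (self.lambda_fixed != 0)
        if not np.all(loads.any(axis=1)):
            raise ValueError("every indicator must load on at least one factor")
        if self.q > self.p_star:
            raise ValueError(
                f"model not identified: {self.q} free parameters > {self.p_star} moments"
            )

    @property
    def k(self) -> int:
        return len(self.indicators)

    @property
    def m(self) -> int:
        return len(self.factor_names)

    @property
    def p_star(self) -> int:
        return self.k * (self.k + 1) // 2

    @property
    def q(self) -> int:
        n_load = int(self.lambda_mask.sum())
        n_psi = int(np.triu(self.psi_free, 1).sum())
        n_theta = int(self.theta_free.sum())
        return n_load + n_psi + n_theta

    @property
    def df(self) -> int:
        return self.p_star - self.q

    def parameter_names(self) -> list[str]:
        names = []
        for i in range(self.k):
            for f in range(self.m):
                if self.lambda_mask[i, f]:
                    names.append(f"lambda[{self.indicators[i]},{self.factor_names[f]}]")
        for f in range(self.m):
            for g in range(f + 1, self.m):
                if self.psi_free[f, g]:
                    names.append(f"psi[{self.factor_names[f]},{self.factor_names[g]}]")
        for i in range(self.k):
            if self.theta_free[i]:
                names.append(f"theta[{self.indicators[i]}]")
        return names


def _anchor_ranges(k: int, n_factors: int) -> list[tuple[int, int]]:
    """1-based inclusive indicator ranges per factor.

    For ``k = 12`` these are the canonical anchor patterns
    (2 factors: 1-11 / 2-12; 3 factors: 1-5 / 2-10 / 8-12); other ``k``
    scale the 12-indicator anchors proportionally.
    """
    if n_factors == 1:
        return [(1, k)]
    if n_factors == 2:
        return [(1, k - 1), (2, k)]
    if n_factors == 3:
        def scale(v: int) -> int:
            return int(round(v * k / 12))
        lo = (1, max(scale(5), 2))
        mid = (2, max(scale(10), 3))
        hi = (min(scale(8), k - 1), k)
        return [lo, mid, hi]
    raise ValueError("n_factors must be 1, 2 or 3")


def build_severity_factor_model(
    k_cuts: int,
    n_factors: int,
    external_traits: Sequence[str] = (),
    cut_names: Sequence[str] | None = None,
) -> FactorModelSpec:
    """Severity-factor model with overlapping anchored loading ranges.

    Cut-point indicators load freely on the factors whose range covers
    their rank and have free residual variances; external traits are
    standardized single-indicator latents (loading 1, residual 0) freely
    correlated with all severity factors and each other.
    """
    if k_cuts < n_factors + 1:
        raise ValueError("need at least n_factors + 1 cut points")
    cut_names = list(cut_names) if cut_names is not None else [
        f"cut{i + 1}" for i in range(k_cuts)
    ]
    if len(cut_names) != k_cuts:
        raise ValueError("cut_names length mismatch")
    external_traits = list(external_traits)

    ranges = _anchor_ranges(k_cuts, n_factors)
    sev_factors = {1: ["F1"], 2: ["Flow", "Fhigh"], 3: ["Flow", "Fmid", "Fhigh"]}[n_factors]
    factor_names = sev_factors + [f"L_{t}" for t in external_traits]
    indicators = cut_names + external_traits
    k = len(indicators)
    m = len(factor_names)

    lam_mask = np.zeros((k, m), dtype=bool)
    lam_fixed = np.zeros((k, m))
    for f, (lo, hi) in enumerate(ranges):
        lam_mask[lo - 1 : hi, f] = True
    for e, _t in enumerate(external_traits):
        lam_fixed[k_cuts + e, n_factors + e] = 1.0

    theta_free = np.array([True] * k_cuts + [False] * len(external_traits))
    theta_fixed = np.zeros(k)
    psi_free = np.ones((m, m), dtype=bool)
    np.fill_diagonal(psi_free, False)

    return FactorModelSpec(
        indicators=indicators,
        factor_names=factor_names,
        lambda_mask=lam_mask,
        lambda_fixed=lam_fixed,
        theta_free=theta_free,
        theta_fixed=theta_fixed,
        psi_free=psi_free,
        external=external_traits,
    )


# ---------------------------------------------------------------------------
# parameter packing and implied moments

def _unpack(spec: FactorModelSpec, theta: np.ndarray):
    k, m = spec.k, spec.m
    pos = 0
    lam = spec.lambda_fixed.copy()
    n_load = int(spec.lambda_mask.sum())
    lam[spec.lambda_mask] = theta[pos : pos + n_load]
    pos += n_load
    psi = np.eye(m)
    for f in range(m):
        for g in range(f + 1, m):
            if spec.psi_free[f, g]:
                psi[f, g] = psi[g, f] = theta[pos]
                pos += 1
    th = spec.theta_fixed.copy()
    n_theta = int(spec.theta_free.sum())
    th[spec.theta_free] = theta[pos : pos + n_theta]
    return lam, psi, th


def implied_matrix(spec: FactorModelSpec, theta: np.ndarray) -> np.ndarray:
    lam, psi, th = _unpack(spec, theta)
    return lam @ psi @ lam.T + np.diag(th)


def _moment_jacobian(spec: FactorModelSpec, theta: np.ndarray) -> np.ndarray:
    """Analytic Jacobian d vech(sigma) / d theta, shape (p*, q)."""
    lam, psi, _ = _unpack(spec, theta)
    pairs = vech_indices(spec.k)
    p_star, q = len(pairs), len(theta)
    J = np.zeros((p_star, q))
    lp = lam @ psi                      # (k, m)
    col = 0
    for i in range(spec.k):
        for f in range(spec.m):
            if not spec.lambda_mask[i, f]:
                continue
            for r, (a, b) in enumerate(pairs):
                val = 0.0
                if a == i:
                    val += lp[b, f]
                if b == i:
                    val += lp[a, f]
                J[r, col] = val
            col += 1
    for f in range(spec.m):
        for g in range(f + 1, spec.m):
            if not spec.psi_free[f, g]:
                continue
            for r, (a, b) in enumerate(pairs):
                J[r, col] = lam[a, f] * lam[b, g] + lam[a, g] * lam[b, f]
            col += 1
    diag_pos = {pq: r for r, pq in enumerate(pairs)}
    for i in range(spec.k):
        if not spec.theta_free[i]:
            continue
        J[diag_pos[(i, i)], col] = 1.0
        col += 1
    return J


# ---------------------------------------------------------------------------
# fitting

@dataclass
class SEMFit:
    spec: FactorModelSpec
    theta: np.ndarray
    se: np.ndarray
    cov_theta: np.ndarray
    chi2: float
    df: int
    p_value: float
    cfi: float
    srmr: float
    aic: float
    fmin: float
    converged: bool
    n_iter: int
    grad_norm: float
    heywood: bool
    loadings: np.ndarray = None
    psi: np.ndarray = None
    residual_var: np.ndarray = None

    def parameter_table(self) -> dict:
        names = self.spec.parameter_names()
        return {
            name: {"estimate": float(est), "se": float(se)}
            for name, est, se in zip(names, self.theta, self.se)
        }

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "parameters": self.parameter_table(),
            "loadings": self.loadings.tolist(),
            "factor_correlations": self.psi.tolist(),
            "residual_variances": self.residual_var.tolist(),
            "fit": {
                "chi2": self.chi2,
                "df": self.df,
                "p": self.p_value,
                "cfi": self.cfi,
                "srmr": self.srmr,
                "aic": self.aic,
                "fmin": self.fmin,
            },
            "converged": self.converged,
            "heywood": self.heywood,
            "indicators": self.spec.indicators,
            "factors": self.spec.factor_names,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path


def _start_values(spec: FactorModelSpec, jitter: np.ndarray | None = None) -> np.ndarray:
    theta = []
    theta += [0.7] * int(spec.lambda_mask.sum())
    theta += [0.5] * int(np.triu(spec.psi_free, 1).sum())
    theta += [1.0 - 0.49] * int(spec.theta_free.sum())
    theta = np.array(theta)
    if jitter is not None:
        theta = theta + jitter
    return theta


def _bounds(spec: FactorModelSpec) -> list[tuple[float, float]]:
    b: list[tuple[float, float]] = []
    b += [(-2.0, 2.0)] * int(spec.lambda_mask.sum())
    b += [(-0.999, 0.999)] * int(np.triu(spec.psi_free, 1).sum())
    # residual variances intentionally unbounded below: Heywood cases are
    # flagged, not forcibly bounded
    b += [(-1.0, 5.0)] * int(spec.theta_free.sum())
    return b


def residual_chi2(
    resid: np.ndarray, V: np.ndarray, J: np.ndarray | None
) -> float:
    """Residual-based quadratic-form statistic using the full V.

    ``T = r' [V^-1 - V^-1 J (J' V^-1 J)^-1 J' V^-1] r`` with J the moment
    Jacobian at the optimum; the projection removes the directions the
    model can absorb, making T asymptotically chi-square with p* - q df.
    With ``J = None`` (independence-style evaluation) the plain quadratic
    form ``r' V^-1 r`` is returned.
    """
    V = 0.5 * (V + V.T)
    Vinv = np.linalg.pinv(V)
    if J is None or J.size == 0:
        return float(resid @ Vinv @ resid)
    A = J.T @ Vinv @ J
    middle = Vinv - Vinv @ J @ np.linalg.pinv(A) @ J.T @ Vinv
    return float(resid @ middle @ resid)


def fit_indices(
    resid: np.ndarray,
    s_obs: np.ndarray,
    V: np.ndarray,
    spec: FactorModelSpec,
    J: np.ndarray,
    diag_idx: np.ndarray,
) -> dict:
    """Chi-square, CFI, SRMR and AIC from the optimum residuals."""
    df = spec.df
    if df < 0:
        raise ValueError("negative degrees of freedom")
    chi2 = residual_chi2(resid, V, J) if df > 0 else 0.0
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    # independence model: free diagonal, zero off-diagonals
    resid_ind = s_obs.copy()
    resid_ind[diag_idx] = 0.0
    p_star = len(s_obs)
    J_ind = np.zeros((p_star, len(diag_idx)))
    for c, r in enumerate(diag_idx):
        J_ind[r, c] = 1.0
    df_ind = p_star - len(diag_idx)
    chi2_ind = residual_chi2(resid_ind, V, J_ind) if df_ind > 0 else 0.0

    denom = chi2_ind - df_ind
    if denom <= 0:
        cfi = 1.0
    else:
        cfi = (denom - max(chi2 - df, 0.0)) / denom
    cfi = float(np.clip(cfi, 0.0, 1.0))

    # SRMR over distinct elements, standardized by observed variances
    d = np.sqrt(np.abs(s_obs[diag_idx]))
    pairs = vech_indices(int((np.sqrt(8 * p_star + 1) - 1) / 2))
    std = np.array([d[i] * d[j] for i, j in pairs])
    std[std == 0] = 1.0
    srmr = float(np.sqrt(np.mean((resid / std) ** 2)))

    aic = chi2 + 2.0 * spec.q
    return {"chi2": chi2, "df": df, "p": p, "cfi": cfi, "srmr": srmr, "aic": aic}


def sem_fit_dwls(
    spec: FactorModelSpec,
    struct: GeneticCovStruct,
    use_R: bool = True,
    n_restarts: int = 4,
    seed: int = 0,
    full_wls: bool = False,
) -> SEMFit:
    """Fit the factor model to (R or S, V) by diagonally weighted least squares.

    Minimizes ``(s - sigma(theta))' W^-1 (s - sigma(theta))`` with
    ``W = diag(V)`` (or the full smoothed V when ``full_wls``), from the
    default start plus ``n_restarts`` jittered restarts; reports sandwich
    standard errors and residual-based fit statistics computed with the
    full V.
    """
    if use_R:
        if struct.R is None or struct.V_R is None:
            raise ValueError("struct has no R/V_R")
        mat, V = struct.R, struct.V_R
    else:
        mat, V = struct.S, struct.V_S

    order = [struct.trait_index(t) for t in spec.indicators]
    mat = mat[np.ix_(order, order)]
    pairs_full = vech_indices(struct.k)
    pos_full = {pq: r for r, pq in enumerate(pairs_full)}
    rows = []
    for i, j in vech_indices(spec.k):
        a, b = order[i], order[j]
        rows.append(pos_full[(a, b) if a >= b else (b, a)])
    V = V[np.ix_(rows, rows)]
    V, _ = smooth_to_psd(V)

    pairs = vech_indices(spec.k)
    s_obs = np.array([mat[i, j] for i, j in pairs])
    diag_idx = np.array([r for r, (i, j) in enumerate(pairs) if i == j])

    w_diag = np.diag(V).copy()
    w_diag[w_diag <= 0] = max(w_diag.max(), 1e-8) * 1e-4
    if full_wls:
        W, _ = smooth_to_psd(V)
        W = W + 1e-10 * np.eye(len(s_obs)) * max(np.abs(W).max(), 1.0)
        Winv = np.linalg.inv(W)
    else:
        Winv = np.diag(1.0 / w_diag)
    # rescale the fit function to O(1) so optimizer tolerances are meaningful;
    # the optimum and all downstream statistics are unaffected
    obj_scale = float(np.median(w_diag))
    Winv_obj = Winv * obj_scale

    tri = np.tril_indices(spec.k)

    def objective(theta: np.ndarray):
        sigma = implied_matrix(spec, theta)
        r = s_obs - sigma[tri]
        J = _moment_jacobian(spec, theta)
        f = r @ Winv_obj @ r
        grad = -2.0 * J.T @ (Winv_obj @ r)
        return f, grad

    rng = np.random.default_rng(seed)
    bounds = _bounds(spec)
    best = None
    for attempt in range(n_restarts + 1):
        jitter = None if attempt == 0 else rng.uniform(-0.2, 0.2, size=len(bounds))
        x0 = _start_values(spec, jitter)
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or (res.fun < best.fun - 1e-12):
            best = res
    assert best is not None

    # Gauss-Newton polish: quadratic local convergence on the (locally)
    # linear least-squares structure; stays within bounds
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    theta_p = best.x.copy()
    f_p, _ = objective(theta_p)
    for _ in range(20):
        sigma = implied_matrix(spec, theta_p)
        r = s_obs - sigma[tri]
        Jp = _moment_jacobian(spec, theta_p)
        JtW = Jp.T @ Winv_obj
        A = JtW @ Jp
        try:
            step = np.linalg.solve(A + 1e-12 * np.trace(A) * np.eye(len(theta_p)), JtW @ r)
        except np.linalg.LinAlgError:
            break
        cand = np.clip(theta_p + step, lo, hi)
        f_c, _ = objective(cand)
        if f_c <= f_p:
            move = np.abs(cand - theta_p).max()
            theta_p, f_p = cand, f_c
            if move < 1e-12:
                break
        else:
            break
    if f_p <= best.fun:
        best.x, best.fun = theta_p, f_p
        best.jac = objective(theta_p)[1]

    converged = bool(best.success) or float(np.linalg.norm(best.jac)) < 1e-4
    if not converged:
        logger.warning("DWLS optimization did not converge: %s", best.message)

    theta_hat = best.x
    sigma = implied_matrix(spec, theta_hat)
    resid = s_obs - np.array([sigma[i, j] for i, j in pairs])
    J = _moment_jacobian(spec, theta_hat)

    # sandwich covariance: (J'W^-1 J)^-1 J'W^-1 V W^-1 J (J'W^-1 J)^-1
    JtW = J.T @ Winv
    bread = np.linalg.pinv(JtW @ J)
    meat = JtW @ V @ JtW.T
    cov_theta = bread @ meat @ bread
    se = np.sqrt(np.maximum(np.diag(cov_theta), 0.0))

    indices = fit_indices(resid, s_obs, V, spec, J, diag_idx)
    lam, psi, th = _unpack(spec, theta_hat)
    heywood = bool(np.any(th[spec.theta_free] < 0)) or bool(
        np.any(np.linalg.eigvalsh(psi) < -1e-8)
    )
    if heywood:
        logger.warning("Heywood case: inadmissible estimates flagged (not bounded)")

    return SEMFit(
        spec=spec,
        theta=theta_hat,
        se=se,
        cov_theta=cov_theta,
        chi2=indices["chi2"],
        df=indices["df"],
        p_value=indices["p"],
        cfi=indices["cfi"],
        srmr=indices["srmr"],
        aic=indices["aic"],
        fmin=float(best.fun),
        converged=converged,
        n_iter=int(best.nit),
        grad_norm=float(np.linalg.norm(best.jac)),
        heywood=heywood,
        loadings=lam,
        psi=psi,
        residual_var=th,
    )
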