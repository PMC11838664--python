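"""Generalized least squares models for genetic correlations as a function
of severity.

The outcome vector ``y`` holds selected elements of the genetic
correlation (or standardized covariance) matrix; the weight matrix is the
corresponding submatrix of the joint jackknife sampling covariance, so
unequal precision and correlated estimation errors across binarizations of
the same measure are both accounted for.

Coefficients follow the closed forms
``beta = (X' V^-1 X)^-1 X' V^-1 y`` and ``cov(beta) = (X' V^-1 X)^-1``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg, stats

from .ldsc import GeneticCovStruct, smooth_to_psd
from .severity import SeverityMap

logger = logging.getLogger(__name__)

CONDITION_WARN_THRESHOLD = 1e10


@dataclass
class GLSDesign:
    """Outcome vector, design matrix and sampling covariance submatrix."""

    y: np.ndarray
    X: np.ndarray
    V_y: np.ndarray
    labels: list[str] = field(default_factory=list)       # per-row element names
    coef_names: list[str] = field(default_factory=list)   # per-column names
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.V_y = np.asarray(self.V_y, dtype=float)
        n = len(self.y)
        if self.X.shape[0] != n or self.V_y.shape != (n, n):
            raise ValueError("y, X rows and V_y dimension must agree")
        if n < self.X.shape[1]:
            raise ValueError(
                f"need >= {self.X.shape[1]} elements for {self.X.shape[1]} coefficients"
            )
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")


@dataclass
class GLSFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    coef_names: list[str]
    meta: dict = field(default_factory=dict)

    def coef_table(self) -> dict:
        return {
            name: {"beta": float(b), "se": float(s), "z": float(z), "p": float(p)}
            for name, b, s, z, p in zip(self.coef_names, self.beta, self.se, self.z, self.p)
        }

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "coefficients": self.coef_table(),
            "cov_beta": self.cov_beta.tolist(),
            "residuals": self.residuals.tolist(),
            "fitted": self.fitted.tolist(),
            "meta": self.meta,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path


def gls_fit(design: GLSDesign, df_correction: bool = False) -> GLSFit:
    """Closed-form GLS with Wald tests.

    ``df_correction`` switches the p-values from the normal reference to a
    t reference with ``n - p`` degrees of freedom.
    """
    y, X, V = design.y, design.X, design.V_y
    n, p = X.shape

    cond = np.linalg.cond(V)
    if cond > CONDITION_WARN_THRESHOLD:
        warnings.warn(
            f"V_y condition number {cond:.2e} exceeds {CONDITION_WARN_THRESHOLD:.0e}; "
            "consider smoothing",
            UserWarning,
            stacklevel=2,
        )
    cho = linalg.cho_factor(V)
    Vinv_X = linalg.cho_solve(cho, X)
    Vinv_y = linalg.cho_solve(cho, y)
    xtvx = X.T @ Vinv_X
    try:
        cov_beta = np.linalg.inv(xtvx)
    except np.linalg.LinAlgError as exc:
        raise ValueError("X' V^-1 X is singular") from exc
    beta = cov_beta @ (X.T @ Vinv_y)
    fitted = X @ beta
    resid = y - fitted
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    if df_correction and n - p > 0:
        pvals = 2.0 * stats.t.sf(np.abs(z), df=n - p)
    else:
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    if n == p:
        warnings.warn("zero residual degrees of freedom; fit is exactly determined",
                      UserWarning, stacklevel=2)
    return GLSFit(
        beta=beta,
        cov_beta=cov_beta,
        se=se,
        z=z,
        p=pvals,
        residuals=resid,
        fitted=fitted,
        coef_names=list(design.coef_names) or [f"b{i}" for i in range(p)],
        meta=dict(design.meta),
    )


def _matrix_and_v(struct: GeneticCovStruct, use_R: bool) -> tuple[np.ndarray, np.ndarray]:
    if use_R:
        if struct.R is None or struct.V_R is None:
            raise ValueError("struct has no R/V_R; run standardization first")
        return struct.R, struct.V_R
    return struct.S, struct.V_S


def build_gls_inputs(
    struct: GeneticCovStruct,
    severity: SeverityMap,
    selection: str,
    external_trait: str | None = None,
    cut_traits: list[str] | None = None,
    quadratic: bool = False,
    use_R: bool = True,
    smooth: bool = True,
) -> GLSDesign:
    """Extract y, X and V_y for a severity-trend or decay analysis.

    ``selection="external"`` takes each cut trait's correlation with
    ``external_trait`` and regresses on intercept + severity z (+ centered
    z^2 when ``quadratic``); ``selection="decay"`` takes the correlations of
    the first (least severe) cut with every later cut and regresses on
    intercept + severity distance from the first cut.
    """
    mat, V = _matrix_and_v(struct, use_R)
    if cut_traits is None:
        cut_traits = [t for t in struct.trait_ids if t != external_trait]
    missing = [t for t in cut_traits if t not in struct.trait_ids]
    if missing:
        raise ValueError(f"traits not in struct: {missing}")
    if len(cut_traits) != severity.n_cuts:
        raise ValueError("severity map length must match the number of cut traits")
    zsev = severity.severity_z

    if selection == "external":
        if external_trait is None or external_trait not in struct.trait_ids:
            raise ValueError("external mode needs an external trait present in struct")
        ext = struct.trait_index(external_trait)
        rows = [struct.element_index(struct.trait_index(t), ext) for t in cut_traits]
        y = np.array([mat[struct.trait_index(t), ext] for t in cut_traits])
        if quadratic:
            zc = zsev - zsev.mean()
            X = np.column_stack([np.ones_like(zsev), zsev, zc**2])
            coef_names = ["intercept", "severity", "severity_sq_centered"]
        else:
            X = np.column_stack([np.ones_like(zsev), zsev])
            coef_names = ["intercept", "severity"]
        labels = [f"r({t},{external_trait})" for t in cut_traits]
        meta = {
            "selection": "external",
            "external_trait": external_trait,
            "quadratic": quadratic,
            "severity_centered_at": float(zsev.mean()) if quadratic else None,
        }
    elif selection == "decay":
        anchor = cut_traits[0]
        a = struct.trait_index(anchor)
        rows = [struct.element_index(a, struct.trait_index(t)) for t in cut_traits[1:]]
        y = np.array([mat[a, struct.trait_index(t)] for t in cut_traits[1:]])
        dist = zsev[1:] - zsev[0]
        X = np.column_stack([np.ones_like(dist), dist])
        coef_names = ["intercept", "severity_distance"]
        labels = [f"r({anchor},{t})" for t in cut_traits[1:]]
        meta = {"selection": "decay", "anchor": anchor}
    else:
        raise ValueError(f"unknown selection mode {selection!r}")

    V_y = V[np.ix_(rows, rows)]
    if smooth:
        V_y, _ = smooth_to_psd(V_y)
        # guard exact zeros on the diagonal after smoothing
        jitter = 1e-12 * max(np.abs(V_y).max(), 1.0)
        V_y = V_y + jitter * np.eye(len(y))
    return GLSDesign(y=y, X=X, V_y=V_y, labels=labels, coef_names=coef_names, meta=meta)


def severity_trend_test(
    struct: GeneticCovStruct,
    severity: SeverityMap,
    external_trait: str,
    quadratic: bool = False,
    use_R: bool = True,
) -> GLSFit:
    """Regress each cut's genetic correlation with an external trait on severity."""
    design = build_gls_inputs(
        struct, severity, "external", external_trait=external_trait,
        quadratic=quadratic, use_R=use_R,
    )
    return gls_fit(design)


def decay_test(
    struct: GeneticCovStruct,
    severity: SeverityMap,
    cut_traits: list[str] | None = None,
    use_R: bool = True,
) -> GLSFit:
    """Regress correlations with the least severe cut on severity distance."""
    design = build_gls_inputs(
        struct, severity, "decay", cut_traits=cut_traits, use_R=use_R,
    )
    return gls_fit(design)
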