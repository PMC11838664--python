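"""LD score regression: heritabilities, genetic covariances and the joint
block-jackknife sampling covariance matrix.

Univariate fits regress per-variant chi-square on ``N * l / M`` with a free
intercept; bivariate fits regress the cross-trait Z product on
``sqrt(N1*N2) * l / M`` with a free cross-intercept that absorbs sample
overlap.  Both use the standard two-pass heteroskedasticity/overcounting
weights.  ``multivariate_ldsc`` estimates every cell of the k-trait genetic
covariance matrix on one shared variant set and block partition, so the
delete-one-block pseudovalues of all half-vectorized elements are coherent
and yield the full joint sampling covariance matrix V.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenoPanel
from .sumstats import SumStats, align_traits

logger = logging.getLogger(__name__)

DEFAULT_N_BLOCKS = 200


# ---------------------------------------------------------------------------
# vech helpers: row-major lower triangle, diagonal included
# order for k traits: (0,0), (1,0), (1,1), (2,0), (2,1), (2,2), ...

def vech_indices(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(i + 1)]


def vech(mat: np.ndarray) -> np.ndarray:
    k = mat.shape[0]
    return np.array([mat[i, j] for i, j in vech_indices(k)])


def unvech(v: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((k, k))
    for idx, (i, j) in enumerate(vech_indices(k)):
        out[i, j] = out[j, i] = v[idx]
    return out


# ---------------------------------------------------------------------------
# LD scores

@dataclass
class LDScoreTable:
    """Per-variant LD scores and the regression denominator M."""

    snp: np.ndarray
    ld: np.ndarray
    M: int
    window: int | None = None   # window half-width in variants

    def __post_init__(self) -> None:
        self.snp = np.asarray(self.snp)
        self.ld = np.asarray(self.ld, dtype=float)
        if not np.all(np.isfinite(self.ld)):
            raise ValueError("LD scores must be finite")
        if self.M <= 0:
            raise ValueError("M must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"SNP": self.snp, "L2": self.ld})

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps({"M": self.M, "window": self.window})
        )
        return path

    @classmethod
    def read(cls, path: str | Path) -> "LDScoreTable":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            snp=df["SNP"].to_numpy(),
            ld=df["L2"].to_numpy(),
            M=int(meta.get("M", len(df))),
            window=meta.get("window"),
        )


def compute_ld_scores(
    panel: GenoPanel, window: int = 50, adjusted: bool = True
) -> LDScoreTable:
    """LD scores from sample dosage correlations within a variant window.

    ``l_j`` sums ``r^2`` between variant ``j`` and every variant within
    ``window`` positions (self term included, so the unadjusted score is
    >= 1).  ``adjusted`` applies the small-sample bias correction
    ``r2_adj = r2 - (1 - r2) / (n - 2)``.  Monomorphic variants are
    excluded with a logged warning.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    g = panel.dosage.astype(np.float32)
    sd = g.std(axis=0)
    poly = sd > 0
    if not np.all(poly):
        logger.warning("compute_ld_scores: excluding %d monomorphic variants", int((~poly).sum()))
    g = g[:, poly]
    g = (g - g.mean(axis=0)) / g.std(axis=0)
    n, m = g.shape

    # self term r^2 = 1 (the adjusted correction vanishes at r^2 = 1)
    ld = np.ones(m)
    # banded accumulation: for each offset d, r between j and j+d for all j
    for d in range(1, min(window, m - 1) + 1):
        r = np.einsum("ij,ij->j", g[:, :-d], g[:, d:]) / n
        r2 = r * r
        if adjusted:
            r2 = r2 - (1.0 - r2) / (n - 2)
        ld[:-d] += r2
        ld[d:] += r2
    return LDScoreTable(snp=panel.snp[poly], ld=ld, M=m, window=window)


# ---------------------------------------------------------------------------
# regression machinery

def _partition_blocks(m: int, n_blocks: int) -> np.ndarray:
    """Contiguous block id per variant; blocks differ in size by at most 1."""
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    if n_blocks > m // 2:
        raise ValueError("fewer than 2 variants per block")
    return np.floor(np.arange(m) * n_blocks / m).astype(int)


def _jackknife_wls(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, block: np.ndarray, n_blocks: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted 2-parameter regression with delete-one-block estimates.

    Returns (full-fit [intercept, slope], delete-one-block coefficient
    array of shape (n_blocks, 2), jackknife covariance 2x2).
    """
    # per-block sufficient statistics of the 2-parameter weighted regression
    sw = np.bincount(block, w, minlength=n_blocks)
    swx = np.bincount(block, w * x, minlength=n_blocks)
    swxx = np.bincount(block, w * x * x, minlength=n_blocks)
    swy = np.bincount(block, w * y, minlength=n_blocks)
    swxy = np.bincount(block, w * x * y, minlength=n_blocks)

    def _solve(a11, a12, a22, b1, b2):
        det = a11 * a22 - a12 * a12
        return np.stack([(a22 * b1 - a12 * b2) / det, (a11 * b2 - a12 * b1) / det], axis=-1)

    T = (sw.sum(), swx.sum(), swxx.sum(), swy.sum(), swxy.sum())
    coef_full = _solve(T[0], T[1], T[2], T[3], T[4])
    coef_del = _solve(T[0] - sw, T[1] - swx, T[2] - swxx, T[3] - swy, T[4] - swxy)

    mean_del = coef_del.mean(axis=0)
    dev = coef_del - mean_del
    cov = (n_blocks - 1) / n_blocks * (dev.T @ dev)
    return coef_full, coef_del, cov


def _match_ld(s: SumStats, ld: LDScoreTable) -> tuple[pd.DataFrame, np.ndarray]:
    ld_map = pd.Series(ld.ld, index=ld.snp)
    df = s.df[s.df["SNP"].isin(ld_map.index)].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no variants shared between sumstats and LD scores")
    return df, ld_map.loc[df["SNP"]].to_numpy()


@dataclass
class UnivariateFit:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    mean_chi2: float
    n_variants: int
    coef_del: np.ndarray = field(repr=False)    # (n_blocks, 2) delete-one-block


def _univariate_weights(ell, x, h2, a):
    het = np.maximum(x * h2 + a, 1e-6)
    return 1.0 / (np.maximum(ell, 1.0) * het**2)


def fit_ldsc_univariate(
    s: SumStats, ld: LDScoreTable, n_blocks: int = DEFAULT_N_BLOCKS
) -> UnivariateFit:
    """Heritability and intercept from one trait's chi-square statistics.

    Weighted regression of ``chi2_j`` on ``N_j * l_j / M`` with free
    intercept; two weighting passes; delete-one-block jackknife SEs.
    """
    df, ell = _match_ld(s, ld)
    m = len(df)
    if m < 200:
        raise ValueError(f"only {m} variants shared; need >= 200")
    if np.ptp(ell) == 0:
        raise ValueError("LD scores constant across variants; slope unidentified")
    chi2 = df["Z"].to_numpy() ** 2
    N = df["N"].to_numpy(dtype=float)
    x = N * ell / ld.M
    block = _partition_blocks(m, n_blocks)

    # pass 1: rough h2 from mean chi2
    h2_0 = np.clip((chi2.mean() - 1.0) / x.mean(), 0.0, 1.0)
    w = _univariate_weights(ell, x, h2_0, 1.0)
    coef, _, _ = _jackknife_wls(x, chi2, w, block, n_blocks)
    # pass 2: weights from pass-1 fit
    w = _univariate_weights(ell, x, np.clip(coef[1], 0.0, 1.0), max(coef[0], 0.1))
    coef, coef_del, cov = _jackknife_wls(x, chi2, w, block, n_blocks)

    return UnivariateFit(
        h2=float(coef[1]),
        h2_se=float(np.sqrt(cov[1, 1])),
        intercept=float(coef[0]),
        intercept_se=float(np.sqrt(cov[0, 0])),
        mean_chi2=float(chi2.mean()),
        n_variants=m,
        coef_del=coef_del,
    )


@dataclass
class BivariateFit:
    gencov: float
    gencov_se: float
    intercept: float             # cross-trait intercept
    intercept_se: float
    n_variants: int
    coef_del: np.ndarray = field(repr=False)


def fit_ldsc_bivariate(
    s1: SumStats,
    s2: SumStats,
    ld: LDScoreTable,
    n_blocks: int = DEFAULT_N_BLOCKS,
    align: bool = True,
) -> BivariateFit:
    """Genetic covariance between two traits from the Z-score cross product.

    The free cross-intercept absorbs phenotypic correlation in overlapping
    samples, keeping the slope (the genetic covariance) unbiased.
    """
    if align:
        s1, s2 = align_traits([s1, s2])
    df1, ell = _match_ld(s1, ld)
    df2, _ = _match_ld(s2, ld)
    if not np.array_equal(df1["SNP"].to_numpy(), df2["SNP"].to_numpy()):
        raise ValueError("traits must share an identical variant set (align first)")
    m = len(df1)
    if m < 200:
        raise ValueError(f"only {m} variants shared; need >= 200")
    block = _partition_blocks(m, n_blocks)

    z1 = df1["Z"].to_numpy()
    z2 = df2["Z"].to_numpy()
    n1 = df1["N"].to_numpy(dtype=float)
    n2 = df2["N"].to_numpy(dtype=float)
    y = z1 * z2
    x = np.sqrt(n1 * n2) * ell / ld.M

    # first-pass variance ingredients from quick univariate fits
    u1 = fit_ldsc_univariate(s1, ld, n_blocks)
    u2 = fit_ldsc_univariate(s2, ld, n_blocks)
    x1 = n1 * ell / ld.M
    x2 = n2 * ell / ld.M

    def _weights(cov_g, a12):
        v1 = np.maximum(x1 * np.clip(u1.h2, 0, 1) + max(u1.intercept, 0.1), 1e-6)
        v2 = np.maximum(x2 * np.clip(u2.h2, 0, 1) + max(u2.intercept, 0.1), 1e-6)
        c12 = x * cov_g + a12
        return 1.0 / (np.maximum(ell, 1.0) * (v1 * v2 + c12**2))

    w = _weights(0.0, 0.0)
    coef, _, _ = _jackknife_wls(x, y, w, block, n_blocks)
    w = _weights(float(np.clip(coef[1], -1, 1)), float(coef[0]))
    coef, coef_del, cov = _jackknife_wls(x, y, w, block, n_blocks)

    return BivariateFit(
        gencov=float(coef[1]),
        gencov_se=float(np.sqrt(cov[1, 1])),
        intercept=float(coef[0]),
        intercept_se=float(np.sqrt(cov[0, 0])),
        n_variants=m,
        coef_del=coef_del,
    )


# ---------------------------------------------------------------------------
# multivariate estimation

@dataclass
class GeneticCovStruct:
    """k-trait genetic covariance/correlation matrices with joint sampling
    covariance of their half-vectorized elements.

    vech order is row-major over the lower triangle with the diagonal
    included; ``V_S`` and ``V_R`` follow the same order as ``vech(S)`` and
    ``vech(R)``.
    """

    trait_ids: list[str]
    S: np.ndarray
    V_S: np.ndarray
    intercepts: np.ndarray
    R: np.ndarray | None = None
    V_R: np.ndarray | None = None
    h2_se: np.ndarray | None = None
    n_blocks: int = DEFAULT_N_BLOCKS
    liability: bool = False
    r_method: str = "delta"      # how R/V_R were produced

    @property
    def k(self) -> int:
        return len(self.trait_ids)

    def element_index(self, i: int, j: int) -> int:
        """Position of S[i, j] within vech(S)."""
        if j > i:
            i, j = j, i
        return vech_indices(self.k).index((i, j))

    def trait_index(self, trait_id: str) -> int:
        return self.trait_ids.index(trait_id)

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        def _tsv(name: str, mat: np.ndarray, labels: bool = True) -> None:
            if labels and mat.shape[0] == self.k:
                pd.DataFrame(mat, index=self.trait_ids, columns=self.trait_ids).to_csv(
                    outdir / name, sep="\t"
                )
            else:
                pd.DataFrame(mat).to_csv(outdir / name, sep="\t", index=False)

        _tsv("S.tsv", self.S)
        _tsv("intercepts.tsv", self.intercepts)
        _tsv("V_S.tsv", self.V_S, labels=False)
        if self.R is not None:
            _tsv("R.tsv", self.R)
        if self.V_R is not None:
            _tsv("V_R.tsv", self.V_R, labels=False)
        manifest = {
            "trait_ids": self.trait_ids,
            "vech_order": "row-major lower triangle, diagonal included",
            "n_blocks": self.n_blocks,
            "liability": self.liability,
            "r_method": self.r_method,
            "h2_se": None if self.h2_se is None else list(self.h2_se),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return outdir

    @classmethod
    def read(cls, outdir: str | Path) -> "GeneticCovStruct":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        trait_ids = manifest["trait_ids"]

        def _mat(name: str, labelled: bool):
            p = outdir / name
            if not p.exists():
                return None
            if labelled:
                return pd.read_csv(p, sep="\t", index_col=0).to_numpy()
            return pd.read_csv(p, sep="\t").to_numpy()

        return cls(
            trait_ids=trait_ids,
            S=_mat("S.tsv", True),
            V_S=_mat("V_S.tsv", False),
            intercepts=_mat("intercepts.tsv", True),
            R=_mat("R.tsv", True),
            V_R=_mat("V_R.tsv", False),
            h2_se=None if manifest.get("h2_se") is None else np.array(manifest["h2_se"]),
            n_blocks=manifest.get("n_blocks", DEFAULT_N_BLOCKS),
            liability=manifest.get("liability", False),
            r_method=manifest.get("r_method", "delta"),
        )


def multivariate_ldsc(
    traits: Sequence[SumStats],
    ld: LDScoreTable,
    n_blocks: int = DEFAULT_N_BLOCKS,
    r_method: str = "delta",
    align: bool = True,
) -> GeneticCovStruct:
    """Estimate S, intercepts, and the joint jackknife V over all cells.

    Every diagonal (univariate) and off-diagonal (bivariate) cell is fit on
    the same aligned variant set with the same contiguous block partition,
    so delete-one-block estimates of all vech(S) elements are coherent and
    their empirical covariance across blocks gives V_S.  ``r_method`` picks
    how R and V_R are produced: ``"delta"`` standardizes the full-sample S
    and propagates V_S by the delta method; ``"jackknife"`` standardizes
    each delete-one-block S and jackknifes the standardized elements
    directly.
    """
    traits = list(traits)
    k = len(traits)
    if k < 1:
        raise ValueError("need at least one trait")
    if k >= 2 and align:
        traits = align_traits(traits)

    # shared variant set with LD scores
    dfs = []
    ell = None
    for t in traits:
        df_t, ell_t = _match_ld(t, ld)
        dfs.append(df_t)
        ell = ell_t
    snp0 = dfs[0]["SNP"].to_numpy()
    for df_t in dfs[1:]:
        if not np.array_equal(df_t["SNP"].to_numpy(), snp0):
            raise ValueError("aligned traits must share one variant set")
    m = len(snp0)
    block = _partition_blocks(m, n_blocks)

    Z = np.column_stack([df_t["Z"].to_numpy() for df_t in dfs])
    N = np.column_stack([df_t["N"].to_numpy(dtype=float) for df_t in dfs])

    idx_pairs = vech_indices(k)
    n_cells = len(idx_pairs)
    coef_full = np.empty((n_cells, 2))
    coef_del = np.empty((n_cells, n_blocks, 2))

    # univariate pass to seed bivariate weights
    uni: list[tuple[float, float]] = []
    for t_idx in range(k):
        chi2 = Z[:, t_idx] ** 2
        x = N[:, t_idx] * ell / ld.M
        h2_0 = np.clip((chi2.mean() - 1.0) / x.mean(), 0.0, 1.0)
        w = _univariate_weights(ell, x, h2_0, 1.0)
        c, _, _ = _jackknife_wls(x, chi2, w, block, n_blocks)
        uni.append((float(np.clip(c[1], 0.0, 1.0)), float(max(c[0], 0.1))))

    for cell, (i, j) in enumerate(idx_pairs):
        y = Z[:, i] * Z[:, j]
        x = np.sqrt(N[:, i] * N[:, j]) * ell / ld.M
        vi = np.maximum(N[:, i] * ell / ld.M * uni[i][0] + uni[i][1], 1e-6)
        vj = np.maximum(N[:, j] * ell / ld.M * uni[j][0] + uni[j][1], 1e-6)
        if i == j:
            # second univariate pass: weights from the pass-1 fit, exactly as
            # in fit_ldsc_univariate (k = 1 reduces to the univariate fit)
            w = 1.0 / (np.maximum(ell, 1.0) * vi**2)
        else:
            w = 1.0 / (np.maximum(ell, 1.0) * vi * vj)
            c, _, _ = _jackknife_wls(x, y, w, block, n_blocks)
            c12 = x * np.clip(c[1], -1.0, 1.0) + c[0]
            w = 1.0 / (np.maximum(ell, 1.0) * (vi * vj + c12**2))
        coef_full[cell], coef_del[cell], _ = _jackknife_wls(x, y, w, block, n_blocks)

    s_vech = coef_full[:, 1]
    S = unvech(s_vech, k)
    intercepts = unvech(coef_full[:, 0], k)

    # joint jackknife covariance of vech(S)
    slopes_del = coef_del[:, :, 1]                     # (n_cells, n_blocks)
    dev = slopes_del - slopes_del.mean(axis=1, keepdims=True)
    V_S = (n_blocks - 1) / n_blocks * (dev @ dev.T)

    h2_se = np.array([np.sqrt(V_S[c, c]) for c, (i, j) in enumerate(idx_pairs) if i == j])

    R = V_R = None
    diag = np.diag(S)
    if np.all(diag > 0):
        if r_method == "jackknife":
            r_del = np.empty_like(slopes_del)
            ok = True
            for b in range(n_blocks):
                S_b = unvech(slopes_del[:, b], k)
                d_b = np.diag(S_b)
                if np.any(d_b <= 0):
                    ok = False
                    break
                inv = 1.0 / np.sqrt(d_b)
                r_del[:, b] = vech(S_b * np.outer(inv, inv))
            if ok:
                R = _standardize(S)
                dev_r = r_del - r_del.mean(axis=1, keepdims=True)
                V_R = (n_blocks - 1) / n_blocks * (dev_r @ dev_r.T)
            else:
                logger.warning("direct-R jackknife hit non-positive diagonal; falling back to delta")
                r_method = "delta"
        if r_method == "delta":
            R, V_R = standardize_S_matrices(S, V_S)
    else:
        logger.warning("non-positive diagonal in S; R not computed")

    return GeneticCovStruct(
        trait_ids=[t.trait_id for t in traits],
        S=S,
        V_S=V_S,
        intercepts=intercepts,
        R=R,
        V_R=V_R,
        h2_se=h2_se,
        n_blocks=n_blocks,
        r_method=r_method,
    )


# ---------------------------------------------------------------------------
# transformations

def _standardize(S: np.ndarray) -> np.ndarray:
    inv = 1.0 / np.sqrt(np.diag(S))
    return S * np.outer(inv, inv)


def standardize_S_matrices(S: np.ndarray, V_S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix and delta-method sampling covariance.

    ``r_pq = s_pq / sqrt(s_pp s_qq)``; the Jacobian of the map from
    vech(S) to vech(R) has, for element (p, q):
    ``d r/d s_pq = 1/sqrt(s_pp s_qq)``, ``d r/d s_pp = -r/(2 s_pp)``,
    ``d r/d s_qq = -r/(2 s_qq)``.
    """
    diag = np.diag(S)
    if np.any(diag <= 0):
        raise ValueError(
            "non-positive genetic variance on the diagonal; increase effective "
            "sample size or pool cut points before standardizing"
        )
    k = S.shape[0]
    pairs = vech_indices(k)
    pos = {pq: c for c, pq in enumerate(pairs)}
    R = _standardize(S)
    J = np.zeros((len(pairs), len(pairs)))
    for c, (p, q) in enumerate(pairs):
        if p == q:
            continue  # r_pp = 1 identically, zero row
        J[c, pos[(p, q)]] = 1.0 / np.sqrt(diag[p] * diag[q])
        J[c, pos[(p, p)]] = -R[p, q] / (2.0 * diag[p])
        J[c, pos[(q, q)]] = -R[p, q] / (2.0 * diag[q])
    V_R = J @ V_S @ J.T
    return R, V_R


def standardize_S(struct: GeneticCovStruct) -> GeneticCovStruct:
    """Return a copy of ``struct`` with delta-method R and V_R filled in."""
    R, V_R = standardize_S_matrices(struct.S, struct.V_S)
    return GeneticCovStruct(
        trait_ids=list(struct.trait_ids),
        S=struct.S.copy(),
        V_S=struct.V_S.copy(),
        intercepts=struct.intercepts.copy(),
        R=R,
        V_R=V_R,
        h2_se=None if struct.h2_se is None else struct.h2_se.copy(),
        n_blocks=struct.n_blocks,
        liability=struct.liability,
        r_method="delta",
    )


def liability_factor(P: float, K: float) -> float:
    """Observed-to-liability conversion factor ``K^2(1-K)^2 / (P(1-P) phi(t)^2)``.

    ``t = Phi^-1(1-K)``.  At ``P = K = 0.5`` the factor is ``pi/2``.
    """
    if not (0.0 < P < 1.0 and 0.0 < K < 1.0):
        raise ValueError("prevalences must lie in (0, 1)")
    t = stats.norm.ppf(1.0 - K)
    phi = stats.norm.pdf(t)
    return K**2 * (1.0 - K) ** 2 / (P * (1.0 - P) * phi**2)


def liability_convert(
    struct: GeneticCovStruct,
    sample_prev: Sequence[float | None],
    pop_prev: Sequence[float | None],
) -> GeneticCovStruct:
    """Rescale S (and V_S, R, V_R) from observed to liability scale.

    Continuous traits pass ``None`` for both prevalences and get factor 1.
    Covariance element (i, j) is scaled by ``sqrt(c_i c_j)``; each element
    of V_S by the product of the scale factors of its two vech coordinates.
    """
    k = struct.k
    if len(sample_prev) != k or len(pop_prev) != k:
        raise ValueError("need one prevalence pair per trait")
    c = np.ones(k)
    for t in range(k):
        if sample_prev[t] is None and pop_prev[t] is None:
            continue
        if sample_prev[t] is None or pop_prev[t] is None:
            raise ValueError(f"trait {struct.trait_ids[t]}: both prevalences required")
        c[t] = liability_factor(float(sample_prev[t]), float(pop_prev[t]))

    sqrt_c = np.sqrt(c)
    scale = np.outer(sqrt_c, sqrt_c)
    S = struct.S * scale
    pairs = vech_indices(k)
    scale_vech = np.array([scale[i, j] for i, j in pairs])
    V_S = struct.V_S * np.outer(scale_vech, scale_vech)

    R = V_R = None
    if np.all(np.diag(S) > 0):
        if struct.r_method == "delta":
            R, V_R = standardize_S_matrices(S, V_S)
        else:
            # correlations are scale invariant
            R, V_R = struct.R, struct.V_R
    h2_se = None
    if struct.h2_se is not None:
        h2_se = struct.h2_se * c

    return GeneticCovStruct(
        trait_ids=list(struct.trait_ids),
        S=S,
        V_S=V_S,
        intercepts=struct.intercepts.copy(),
        R=R,
        V_R=V_R,
        h2_se=h2_se,
        n_blocks=struct.n_blocks,
        liability=True,
        r_method=struct.r_method,
    )


def smooth_to_psd(V: np.ndarray, eps_rel: float = 1e-10) -> tuple[np.ndarray, float]:
    """Clip eigenvalues at ``eps_rel * max eigenvalue`` and reconstruct.

    Returns the smoothed matrix and the maximum absolute element change.
    PSD input is returned unchanged (max change 0).
    """
    V = np.asarray(V, dtype=float)
    if not np.allclose(V, V.T, atol=1e-8):
        raise ValueError("V must be symmetric")
    V = 0.5 * (V + V.T)
    vals, vecs = np.linalg.eigh(V)
    if len(vals) == 0 or vals.max() <= 0:
        floor = 0.0
    else:
        floor = eps_rel * vals.max()
    if vals.min() >= floor:
        return V, 0.0
    clipped = np.maximum(vals, floor)
    V_new = (vecs * clipped) @ vecs.T
    V_new = 0.5 * (V_new + V_new.T)
    return V_new, float(np.abs(V_new - V).max())
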