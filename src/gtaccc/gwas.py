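"""Per-variant association scans on dosage panels.

Ordinary least squares of the phenotype on each variant's dosage (plus
optional covariates), run as vectorized matrix operations.  Binary
phenotypes are analysed on the observed scale with a linear model, matching
standard LD-score-regression practice; conversion to the liability scale
happens downstream.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenoPanel
from .sumstats import COLUMNS, SumStats

logger = logging.getLogger(__name__)

#: |Z| is capped here so perfect associations stay finite
Z_MAX = 1e4


def assoc_scan_batch(
    panel: GenoPanel,
    phenotypes: np.ndarray,
    trait_ids: Sequence[str],
    pop_prev: Sequence[float | None] | None = None,
) -> list[SumStats]:
    """OLS scan of several complete-case phenotypes sharing one sample.

    One matrix product covers all traits, so scanning the full binarized
    family costs barely more than a single trait.  Phenotypes must have no
    missing values (use :func:`assoc_scan` for subset/missing handling).
    """
    Y = np.asarray(phenotypes, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, t = Y.shape
    if n != panel.n_ind:
        raise ValueError("phenotype rows must equal panel individuals")
    if np.isnan(Y).any():
        raise ValueError("batch scan requires complete phenotypes")
    if len(trait_ids) != t:
        raise ValueError("need one trait id per phenotype column")

    g = panel.dosage.astype(np.float32)
    frq = g.mean(axis=0, dtype=np.float64) / 2.0
    g -= (2.0 * frq).astype(np.float32)
    sxx = np.einsum("ij,ij->j", g, g)
    poly = sxx > 0
    if not np.all(poly):
        logger.warning("assoc_scan_batch: skipping %d monomorphic variants", int((~poly).sum()))

    Yc = Y - Y.mean(axis=0)
    sxy = Yc.T @ g                       # (t, m)
    syy = np.einsum("it,it->t", Yc, Yc)
    df_resid = n - 2

    out: list[SumStats] = []
    keep = poly & (frq > 0) & (frq < 1)
    for ti in range(t):
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = sxy[ti] / np.where(poly, sxx, 1.0)
            rss = np.maximum(syy[ti] - beta * sxy[ti], 0.0)
            se = np.sqrt(rss / df_resid / np.where(poly, sxx, 1.0))
            z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.sign(beta) * Z_MAX)
        z = np.clip(z, -Z_MAX, Z_MAX)
        uniq = np.unique(Y[:, ti])
        binary = uniq.size == 2 and set(uniq) <= {0.0, 1.0}
        prev = float(Y[:, ti].mean()) if binary else None
        df = pd.DataFrame(
            {
                "SNP": panel.snp[keep],
                "CHR": panel.chrom[keep],
                "BP": panel.pos[keep],
                "A1": "A",
                "A2": "G",
                "FRQ": frq[keep],
                "N": n,
                "Z": z[keep],
                "P": 2.0 * stats.norm.sf(np.abs(z[keep])),
            }
        )
        kprev = None if pop_prev is None else pop_prev[ti]
        out.append(
            SumStats(
                trait_id=trait_ids[ti],
                df=df[COLUMNS],
                binary=binary,
                sample_prev=prev,
                pop_prev=kprev if kprev is not None else prev,
            )
        )
    return out


def assoc_scan(
    panel: GenoPanel,
    phenotype,
    covariates: np.ndarray | None = None,
    trait_id: str = "trait",
    subset: np.ndarray | None = None,
    pop_prev: float | None = None,
) -> SumStats:
    """OLS scan of ``phenotype`` on each variant's dosage.

    ``subset`` restricts the scan to the given individual indices (used for
    ascertained or downsampled analyses).  Individuals with a missing
    phenotype are dropped.  Monomorphic variants are skipped with a logged
    warning and do not appear in the output.  Binary (0/1) phenotypes are
    detected automatically and their sample prevalence recorded in the
    trait metadata.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != panel.n_ind:
        raise ValueError("phenotype length must equal panel individuals")

    idx = np.arange(panel.n_ind) if subset is None else np.asarray(subset)
    y = y[idx]
    keep = ~np.isnan(y)
    idx = idx[keep]
    y = y[keep]
    n = len(y)
    if n < 3:
        raise ValueError("fewer than 3 individuals with observed phenotype")
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")

    uniq = np.unique(y)
    binary = uniq.size == 2 and set(uniq) <= {0.0, 1.0}
    sample_prev = float(y.mean()) if binary else None

    g = panel.dosage[idx].astype(np.float32)
    frq = g.mean(axis=0, dtype=np.float64) / 2.0

    if covariates is not None:
        c_full = np.asarray(covariates, dtype=float)
        if c_full.ndim == 1:
            c_full = c_full[:, None]
        if c_full.shape[0] != panel.n_ind:
            raise ValueError("covariate rows must equal panel individuals")
        c = np.column_stack([np.ones(n), c_full[idx]])
        if np.linalg.matrix_rank(c) < c.shape[1]:
            raise ValueError("covariate matrix (with intercept) is rank deficient")
        # residualize phenotype and dosages on covariates
        q, _ = np.linalg.qr(c)
        y = y - q @ (q.T @ y)
        g = g - q @ (q.T @ g)
        df_resid = n - 2 - (c.shape[1] - 1)
    else:
        y = y - y.mean()
        g = g - g.mean(axis=0)
        df_resid = n - 2

    sxx = np.einsum("ij,ij->j", g, g)
    poly = sxx > 0
    if not np.all(poly):
        logger.warning("assoc_scan: skipping %d monomorphic variants", int((~poly).sum()))
    sxy = y @ g
    syy = float(y @ y)

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(poly, sxy / np.where(poly, sxx, 1.0), np.nan)
        rss = np.maximum(syy - beta * sxy, 0.0)
        sigma2 = rss / df_resid
        se = np.sqrt(sigma2 / np.where(poly, sxx, 1.0))
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.sign(beta) * Z_MAX)
    z = np.clip(z, -Z_MAX, Z_MAX)

    df = pd.DataFrame(
        {
            "SNP": panel.snp,
            "CHR": panel.chrom,
            "BP": panel.pos,
            "A1": "A",
            "A2": "G",
            "FRQ": frq,
            "N": n,
            "Z": z,
            "P": 2.0 * stats.norm.sf(np.abs(z)),
        }
    )
    df = df.loc[poly & (df["FRQ"] > 0) & (df["FRQ"] < 1)].reset_index(drop=True)
    return SumStats(
        trait_id=trait_id,
        df=df[COLUMNS],
        binary=binary,
        sample_prev=sample_prev,
        pop_prev=pop_prev if pop_prev is not None else sample_prev,
    )
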