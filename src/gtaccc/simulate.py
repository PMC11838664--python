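"""Synthetic cohorts with a planted severity-gradient genetic architecture.

Two simulation routes are provided:

* an individual-level route (``simulate_genotypes`` ->
  ``simulate_item_phenotypes`` -> ``simulate_disorder``) that produces
  genotype dosages with block LD, dichotomous item responses whose genetic
  content shifts from a "low severity" factor to a "high severity" factor
  with item rank, and an ascertained case-control disorder trait;

* a direct summary-statistic route (``simulate_sumstats_direct``) that
  draws per-variant Z-score vectors straight from the LD score regression
  model, for fast estimator round-trip and jackknife-calibration tests.

Every generator is bit-reproducible given its seed, and ground truth is
recorded in a :class:`TruthRecord`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import COLUMNS, SumStats


# ---------------------------------------------------------------------------
# domain types

@dataclass
class GenoPanel:
    """Dosage panel with block LD structure.

    Variants are partitioned into contiguous blocks; within a block adjacent
    haplotype alleles follow a first-order Markov chain with correlation
    ``r`` (all variants in a block share one minor-allele frequency so the
    chain preserves marginals exactly); variants in different blocks are
    independent.
    """

    dosage: np.ndarray          # (n_ind, n_var) int8, values 0/1/2
    maf: np.ndarray             # (n_var,) target minor-allele frequency
    block: np.ndarray           # (n_var,) block index
    r: np.ndarray               # per-variant adjacent-haplotype correlation
    snp: np.ndarray             # variant ids
    chrom: np.ndarray
    pos: np.ndarray

    @property
    def n_ind(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_var(self) -> int:
        return self.dosage.shape[1]

    def standardized(self, dtype=np.float32) -> np.ndarray:
        """Column-standardized dosage matrix (sample mean 0, variance 1)."""
        g = self.dosage.astype(dtype)
        g -= g.mean(axis=0)
        sd = g.std(axis=0)
        sd[sd == 0] = 1.0
        return g / sd

    def frequencies(self) -> np.ndarray:
        """Realized effect-allele frequencies."""
        return self.dosage.mean(axis=0) / 2.0


@dataclass
class TruthRecord:
    """Ground truth of one simulated cohort, for recovery tests."""

    h2_low: float               # heritability interpolation anchor, low-severity items
    h2_high: float              # anchor for the most severe item
    rg_fact: float              # genetic correlation between the two factors
    weights: list[float]        # per-item high-factor mixing weight w_j in [0, 1]
    thresholds: list[float]     # per-item latent-normal endorsement threshold
    b_low: float = 0.0          # disorder loading on the low-severity factor
    b_high: float = 0.0         # disorder loading on the high-severity factor
    pop_prev: float | None = None        # disorder population prevalence K
    sample_prev: float | None = None     # realized prevalence after ascertainment
    seed: int = 0
    common_env: float = 0.0     # optional shared environmental loading on items

    def __post_init__(self) -> None:
        for name in ("h2_low", "h2_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1.0 <= self.rg_fact <= 1.0:
            raise ValueError("rg_fact must lie in [-1, 1]")
        if any(not 0.0 <= w <= 1.0 for w in self.weights):
            raise ValueError("mixing weights must lie in [0, 1]")
        if any(b - a <= 0 for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing in severity rank")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class Cohort:
    """Individual-level data: factor scores, items, sum score, disorder status."""

    panel: GenoPanel
    f_low: np.ndarray
    f_high: np.ndarray
    items: np.ndarray           # (n_ind, n_items) 0/1
    sum_score: np.ndarray
    truth: TruthRecord
    disorder: np.ndarray | None = None
    genetic_low: np.ndarray | None = None    # genetic component of each factor
    genetic_high: np.ndarray | None = None
    sample_index: np.ndarray | None = None   # set after ascertainment

    @property
    def n_items(self) -> int:
        return self.items.shape[1]


# ---------------------------------------------------------------------------
# generators

def default_mixing_weights(n_items: int) -> np.ndarray:
    """Default high-factor weights, linear in item severity rank."""
    return np.arange(n_items) / (n_items - 1)


def thresholds_from_prevalence(endorse_prev: Sequence[float]) -> np.ndarray:
    """Latent-normal thresholds reproducing target endorsement rates.

    ``endorse_prev`` must be strictly decreasing in severity rank so the
    thresholds come out strictly increasing.
    """
    p = np.asarray(endorse_prev, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("endorsement prevalences must lie in (0, 1)")
    tau = stats.norm.ppf(1.0 - p)
    if np.any(np.diff(tau) <= 0):
        raise ValueError("endorsement prevalences must be strictly decreasing in rank")
    return tau


def simulate_genotypes(
    n_ind: int,
    n_var: int,
    n_blocks: int,
    r: float = 0.0,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> GenoPanel:
    """Simulate a dosage panel with first-order-Markov LD inside blocks.

    Each of the two haplotypes per individual is generated independently.
    Within a block, the allele at variant ``t+1`` copies the allele at
    ``t`` with probability ``r`` and is otherwise redrawn from the marginal
    Bernoulli(maf); since all variants in a block share one MAF (drawn from
    ``maf_range``) the marginal is preserved exactly and adjacent alleles —
    and hence dosages — have correlation ``r``.  Blocks are independent.
    """
    if n_ind < 1 or n_var < 1 or n_blocks < 1:
        raise ValueError("dimensions must be positive")
    r_lo, r_hi = (r, r) if np.isscalar(r) else (r[0], r[1])
    if not (0.0 <= r_lo <= r_hi < 1.0):
        raise ValueError("r must lie in [0, 1)")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be a subset of (0, 0.5]")
    if n_blocks > n_var:
        raise ValueError("more blocks than variants")

    rng = np.random.default_rng(seed)
    block = np.sort(np.arange(n_var) % n_blocks) if n_var % n_blocks == 0 else np.sort(
        np.floor(np.arange(n_var) * n_blocks / n_var).astype(int)
    )
    block_maf = rng.uniform(lo, hi, size=n_blocks)
    maf = block_maf[block]
    # per-block LD strength: a scalar r is used everywhere; a (lo, hi) pair
    # spreads LD across blocks, which spreads the LD scores
    block_r = rng.uniform(r_lo, r_hi, size=n_blocks) if r_hi > r_lo else np.full(n_blocks, r_lo)
    r_var = block_r[block]

    # Vectorized Markov scan: allele_j equals the fresh draw at the most
    # recent "renewal" position <= j (renewals: block starts and non-copy
    # events), found with a running maximum over positions.
    block_start = np.r_[True, np.diff(block) != 0]
    positions = np.arange(n_var, dtype=np.int64)
    dosage = np.zeros((n_ind, n_var), dtype=np.int8)
    for _hap in range(2):
        fresh = (rng.random((n_ind, n_var)) < maf[None, :]).astype(np.int8)
        renew = rng.random((n_ind, n_var)) >= r_var[None, :]
        renew[:, block_start] = True
        last = np.where(renew, positions[None, :], -1)
        np.maximum.accumulate(last, axis=1, out=last)
        dosage += np.take_along_axis(fresh, last, axis=1)

    return GenoPanel(
        dosage=dosage,
        maf=maf,
        block=block,
        r=r_var,
        snp=np.array([f"rs{j + 1}" for j in range(n_var)]),
        chrom=np.ones(n_var, dtype=int),
        pos=np.arange(1, n_var + 1) * 1000,
    )


def _draw_factor_effects(
    n_var: int, rg_fact: float, rng: np.random.Generator, causal_fraction: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly Gaussian per-variant effects with correlation ``rg_fact``."""
    u = rng.standard_normal((n_var, 2))
    # manual 2x2 factor handles the singular |rg| = 1 limits exactly
    betas = np.column_stack(
        [u[:, 0], rg_fact * u[:, 0] + np.sqrt(max(1.0 - rg_fact**2, 0.0)) * u[:, 1]]
    )
    if causal_fraction < 1.0:
        causal = rng.random(n_var) < causal_fraction
        betas[~causal] = 0.0
    return betas[:, 0], betas[:, 1]


def simulate_item_phenotypes(
    panel: GenoPanel,
    truth: TruthRecord,
    n_items: int | None = None,
    causal_fraction: float = 1.0,
) -> Cohort:
    """Generate dichotomous item responses from two correlated genetic factors.

    Factor scores are standardized genetic scores built from jointly drawn
    effect vectors whose correlation targets ``truth.rg_fact``.  Item ``j``
    mixes the factors as ``(1-w_j)*F_low + w_j*F_high`` (standardized), so
    low-rank items carry the low-severity factor and high-rank items the
    high-severity one.  The item liability adds unique noise so that the
    item's heritability interpolates between ``h2_low`` and ``h2_high`` with
    rank; item ``j`` is endorsed iff its liability exceeds ``tau_j``.
    """
    if n_items is None:
        n_items = len(truth.weights)
    if n_items < 2:
        raise ValueError("need at least 2 items")
    if len(truth.weights) != n_items or len(truth.thresholds) != n_items:
        raise ValueError("truth weights/thresholds inconsistent with n_items")

    rng = np.random.default_rng(truth.seed)
    g_std = panel.standardized()
    beta_low, beta_high = _draw_factor_effects(panel.n_var, truth.rg_fact, rng, causal_fraction)

    def _standardize(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        if sd == 0:
            raise ValueError("degenerate genetic score (zero variance)")
        return (v - v.mean()) / sd

    f_low = _standardize(g_std @ beta_low)
    f_high = _standardize(g_std @ beta_high)
    rg = truth.rg_fact

    w = np.asarray(truth.weights, dtype=float)
    tau = np.asarray(truth.thresholds, dtype=float)
    h2_item = (1.0 - w) * truth.h2_low + w * truth.h2_high

    c_env = truth.common_env
    shared_env = rng.standard_normal(panel.n_ind) if c_env > 0 else 0.0

    items = np.empty((panel.n_ind, n_items), dtype=np.int8)
    for j in range(n_items):
        mix = (1.0 - w[j]) * f_low + w[j] * f_high
        mix_var = (1.0 - w[j]) ** 2 + w[j] ** 2 + 2.0 * w[j] * (1.0 - w[j]) * rg
        if mix_var <= 0:
            raise ValueError("mixing normalizer is zero; adjust weights or rg_fact")
        common = np.sqrt(h2_item[j]) * mix / np.sqrt(mix_var)
        resid_var = 1.0 - h2_item[j] - c_env**2
        if resid_var < 0:
            raise ValueError("common_env loading too large for item heritability")
        liability = common + c_env * shared_env + np.sqrt(resid_var) * rng.standard_normal(panel.n_ind)
        items[:, j] = liability > tau[j]

    return Cohort(
        panel=panel,
        f_low=f_low,
        f_high=f_high,
        items=items,
        sum_score=items.sum(axis=1).astype(float),
        truth=truth,
        genetic_low=f_low,
        genetic_high=f_high,
    )


def simulate_disorder(
    cohort: Cohort,
    b_low: float,
    b_high: float,
    K: float,
    P_target: float | None = None,
    seed: int = 0,
) -> Cohort:
    """Add a liability-threshold disorder loading on the two genetic factors.

    Disorder liability is ``b_low*F_low + b_high*F_high`` plus unique normal
    noise completing unit variance; case iff liability exceeds
    ``Phi^-1(1-K)``.  When ``P_target`` is given, an ascertained subsample
    with exactly that case share is recorded in ``sample_index``
    (resampling without replacement; minority class never duplicated).
    """
    rg = cohort.truth.rg_fact
    var_g = b_low**2 + b_high**2 + 2.0 * b_low * b_high * rg
    if var_g > 1.0 + 1e-12:
        raise ValueError("disorder loadings imply genetic variance > 1")
    if not 0.0 < K < 1.0:
        raise ValueError("population prevalence K must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    n = cohort.panel.n_ind
    liability = (
        b_low * cohort.f_low
        + b_high * cohort.f_high
        + np.sqrt(max(1.0 - var_g, 0.0)) * rng.standard_normal(n)
    )
    status = (liability > stats.norm.ppf(1.0 - K)).astype(np.int8)

    sample_index = None
    realized_p = float(status.mean())
    if P_target is not None:
        if not 0.0 < P_target < 1.0:
            raise ValueError("P_target must lie in (0, 1)")
        cases = np.flatnonzero(status == 1)
        controls = np.flatnonzero(status == 0)
        if len(cases) == 0 or len(controls) == 0:
            raise ValueError("cannot ascertain: one class is empty")
        # keep whichever class is limiting in full, subsample the other
        n_cases_max = len(cases)
        n_controls_needed = int(round(n_cases_max * (1.0 - P_target) / P_target))
        if n_controls_needed <= len(controls):
            kept = np.concatenate(
                [cases, rng.choice(controls, n_controls_needed, replace=False)]
            )
        else:
            n_cases_needed = int(round(len(controls) * P_target / (1.0 - P_target)))
            if n_cases_needed > len(cases):
                raise ValueError("ascertainment target unreachable without replacement")
            kept = np.concatenate(
                [rng.choice(cases, n_cases_needed, replace=False), controls]
            )
        sample_index = np.sort(kept)
        realized_p = float(status[sample_index].mean())

    truth = TruthRecord(
        **{
            **asdict(cohort.truth),
            "b_low": b_low,
            "b_high": b_high,
            "pop_prev": K,
            "sample_prev": realized_p,
        }
    )
    return Cohort(
        panel=cohort.panel,
        f_low=cohort.f_low,
        f_high=cohort.f_high,
        items=cohort.items,
        sum_score=cohort.sum_score,
        truth=truth,
        disorder=status,
        genetic_low=cohort.genetic_low,
        genetic_high=cohort.genetic_high,
        sample_index=sample_index,
    )


# ---------------------------------------------------------------------------
# direct summary-statistic draws under the LDSC model

def synthetic_ld_scores(
    n_var: int, mean: float = 2.0, spread: float = 1.0, seed: int = 0
) -> np.ndarray:
    """LD scores for direct simulation: uniform on [mean-spread, mean+spread], >= 1."""
    rng = np.random.default_rng(seed)
    ld = rng.uniform(mean - spread, mean + spread, size=n_var)
    return np.maximum(ld, 1.0)


def simulate_sumstats_direct(
    ld_scores: np.ndarray,
    M: int,
    traits: Sequence[dict],
    rg_matrix: np.ndarray | None = None,
    overlap: dict | None = None,
    seed: int = 0,
) -> list[SumStats]:
    """Draw per-variant Z-score vectors directly from the LDSC model.

    Each trait dict carries ``h2`` and ``N`` (and optionally ``intercept``
    — default 1 — plus ``P``/``K`` prevalence metadata).  For variant ``j``
    the Z vector across traits is multivariate normal with

    * ``var(z_tj)   = N_t h2_t l_j / M + a_t``
    * ``cov(z_sj,z_tj) = sqrt(N_s N_t) rg_st sqrt(h2_s h2_t) l_j / M
      + pheno_corr * N_overlap / sqrt(N_s N_t)``

    and draws are independent across variants (LD-induced correlation of
    neighbouring Z's is deliberately ignored in this route).
    """
    ld = np.asarray(ld_scores, dtype=float)
    if np.any(ld <= 0):
        raise ValueError("LD scores must be positive")
    k = len(traits)
    if rg_matrix is None:
        rg_matrix = np.eye(k)
    rg_matrix = np.asarray(rg_matrix, dtype=float)
    if rg_matrix.shape != (k, k) or not np.allclose(rg_matrix, rg_matrix.T):
        raise ValueError("rg_matrix must be a symmetric k x k matrix")
    if not np.allclose(np.diag(rg_matrix), 1.0):
        raise ValueError("rg_matrix must have unit diagonal")
    eig = np.linalg.eigvalsh(rg_matrix)
    if eig.min() < -1e-10:
        raise ValueError("rg_matrix must be positive semidefinite")

    h2 = np.array([t["h2"] for t in traits], dtype=float)
    if np.any((h2 < 0) | (h2 > 1)):
        raise ValueError("h2 must lie in [0, 1]")
    N = np.array([t["N"] for t in traits], dtype=float)
    a = np.array([t.get("intercept", 1.0) for t in traits], dtype=float)

    # slope matrix A: Sigma_j = A * l_j + B
    A = rg_matrix * np.sqrt(np.outer(N * h2, N * h2)) / M
    B = np.diag(a)
    if overlap:
        n_s = float(overlap.get("N_s", 0.0))
        rho = float(overlap.get("pheno_corr", 0.0))
        off = rho * n_s / np.sqrt(np.outer(N, N))
        off = off - np.diag(np.diag(off))
        B = B + off

    m = len(ld)
    rng = np.random.default_rng(seed)
    sig = A[None, :, :] * ld[:, None, None] + B[None, :, :]
    try:
        chol = np.linalg.cholesky(sig)
    except np.linalg.LinAlgError as exc:
        raise ValueError("per-variant Z covariance is not positive definite") from exc
    z = np.einsum("jkl,jl->jk", chol, rng.standard_normal((m, k)))

    out = []
    for t_idx, t in enumerate(traits):
        df = pd.DataFrame(
            {
                "SNP": [f"rs{j + 1}" for j in range(m)],
                "CHR": 1,
                "BP": np.arange(1, m + 1) * 1000,
                "A1": "A",
                "A2": "G",
                "FRQ": 0.5,
                "N": N[t_idx],
                "Z": z[:, t_idx],
            }
        )
        df["P"] = 2.0 * stats.norm.sf(np.abs(df["Z"]))
        out.append(
            SumStats(
                trait_id=t.get("trait_id", f"trait{t_idx + 1}"),
                df=df[COLUMNS],
                binary=t.get("P") is not None,
                sample_prev=t.get("P"),
                pop_prev=t.get("K"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# serialization

def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write dosages (npz), phenotypes (TSV) and the truth record (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = cohort.panel
    np.savez_compressed(
        outdir / "panel.npz",
        dosage=panel.dosage,
        maf=panel.maf,
        block=panel.block,
        r=panel.r,
        snp=panel.snp,
        chrom=panel.chrom,
        pos=panel.pos,
    )
    pheno = pd.DataFrame(
        cohort.items, columns=[f"item{j + 1}" for j in range(cohort.n_items)]
    )
    pheno.insert(0, "IID", [f"ind{i + 1}" for i in range(panel.n_ind)])
    pheno["sumscore"] = cohort.sum_score
    if cohort.disorder is not None:
        pheno["disorder"] = cohort.disorder
    pheno.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    cohort.truth.to_json(outdir / "truth.json")
    if cohort.sample_index is not None:
        np.savetxt(outdir / "ascertained_index.txt", cohort.sample_index, fmt="%d")
    return outdir
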