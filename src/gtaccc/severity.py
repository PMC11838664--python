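"""Binarized phenotype families and latent-normal severity scores.

A continuous score binarized at cut ``c`` codes individuals at or above the
cut as 1 (cases) and below as 0 (controls).  The severity value attached to
a cut is the standard-normal quantile of the realized below-cut prevalence,
placing every cut on a common latent liability scale regardless of the
(possibly non-interval) metric of the raw score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: below this effective sample size LDSC estimates are considered unstable
DEFAULT_NEFF_FLOOR = 15_000


@dataclass
class SeverityMap:
    """Cut points with their prevalences and latent-normal severity scores."""

    cuts: np.ndarray            # cut values, score units, strictly increasing
    n_case: np.ndarray          # individuals at/above cut
    n_control: np.ndarray       # individuals below cut
    prev_below: np.ndarray      # below-cut share of the analyzed sample
    severity_z: np.ndarray      # Phi^-1(prev_below)

    def __post_init__(self) -> None:
        for name in ("cuts", "n_case", "n_control", "prev_below", "severity_z"):
            setattr(self, name, np.asarray(getattr(self, name)))
        n_total = self.n_case + self.n_control
        if not np.all(n_total == n_total[0]):
            raise ValueError("case/control counts must sum to the same total at every cut")
        if not np.all(np.diff(self.prev_below) > 0):
            raise ValueError("below-cut prevalence must be strictly increasing in cut point")

    @property
    def n_cuts(self) -> int:
        return len(self.cuts)

    @property
    def sample_prev(self) -> np.ndarray:
        """Case (at-or-above-cut) share per cut."""
        return 1.0 - self.prev_below

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cut": self.cuts,
                "n_case": self.n_case,
                "n_control": self.n_control,
                "prev_below": self.prev_below,
                "severity_z": self.severity_z,
            }
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def read(cls, path: str | Path) -> "SeverityMap":
        df = pd.read_csv(path, sep="\t")
        return cls(
            cuts=df["cut"].to_numpy(),
            n_case=df["n_case"].to_numpy(),
            n_control=df["n_control"].to_numpy(),
            prev_below=df["prev_below"].to_numpy(),
            severity_z=df["severity_z"].to_numpy(),
        )


def severity_from_prevalence(prev_below) -> np.ndarray:
    """Map below-cut prevalences to latent-normal severity scores.

    ``z = Phi^-1(prev_below)`` elementwise; strictly monotone on (0, 1).
    """
    prev = np.asarray(prev_below, dtype=float)
    if np.any((prev <= 0) | (prev >= 1)):
        raise ValueError("prevalences must lie strictly inside (0, 1)")
    return stats.norm.ppf(prev)


def binarize_scores(scores, cuts: Sequence[float]) -> tuple[np.ndarray, SeverityMap]:
    """Binarize a continuous score at each cut: below cut -> 0, at/above -> 1.

    Returns an (n_individuals, n_cuts) float matrix (NaN where the score is
    missing) and the :class:`SeverityMap` built from realized prevalences in
    the non-missing sample.  Raises if any cut leaves an empty class.
    """
    scores = np.asarray(scores, dtype=float)
    cuts_arr = np.asarray(sorted(cuts), dtype=float)
    if len(cuts_arr) == 0:
        raise ValueError("need at least one cut")
    observed = ~np.isnan(scores)
    n_obs = int(observed.sum())
    if n_obs == 0:
        raise ValueError("all scores missing")

    binary = np.full((scores.shape[0], len(cuts_arr)), np.nan)
    n_case = np.zeros(len(cuts_arr), dtype=int)
    n_control = np.zeros(len(cuts_arr), dtype=int)
    for k, c in enumerate(cuts_arr):
        col = (scores[observed] >= c).astype(float)
        n_case[k] = int(col.sum())
        n_control[k] = n_obs - n_case[k]
        if n_case[k] == 0:
            raise ValueError(f"cut {c}: empty case class")
        if n_control[k] == 0:
            raise ValueError(f"cut {c}: empty control class")
        binary[observed, k] = col

    prev_below = n_control / n_obs
    sev = SeverityMap(
        cuts=cuts_arr,
        n_case=n_case,
        n_control=n_control,
        prev_below=prev_below,
        severity_z=severity_from_prevalence(prev_below),
    )
    return binary, sev


def downsample_balanced(
    phenotype,
    target_prev: float = 0.5,
    seed: int | np.random.Generator = 0,
    neff_floor: float = DEFAULT_NEFF_FLOOR,
) -> np.ndarray:
    """Subsample the majority class to hit ``target_prev`` exactly.

    Returns sorted indices of the retained individuals (minority class kept
    intact).  Deterministic given ``seed``.  Emits a warning when the
    effective sample size of the balanced subset falls below ``neff_floor``.
    """
    pheno = np.asarray(phenotype, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = np.flatnonzero(~np.isnan(pheno))
    cases = obs[pheno[obs] == 1]
    controls = obs[pheno[obs] == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be non-empty")
    if not 0.0 < target_prev < 1.0:
        raise ValueError("target_prev must lie in (0, 1)")

    prev = len(cases) / (len(cases) + len(controls))
    if prev > target_prev:
        # too many cases: keep all controls, subsample cases
        n_keep_cases = int(round(len(controls) * target_prev / (1.0 - target_prev)))
        if n_keep_cases > len(cases):
            raise ValueError("target prevalence unreachable by subsampling")
        kept = np.concatenate([rng.choice(cases, n_keep_cases, replace=False), controls])
    else:
        n_keep_controls = int(round(len(cases) * (1.0 - target_prev) / target_prev))
        if n_keep_controls > len(controls):
            raise ValueError("target prevalence unreachable by subsampling")
        kept = np.concatenate([cases, rng.choice(controls, n_keep_controls, replace=False)])

    kept = np.sort(kept)
    realized = float(pheno[kept].mean())
    n_eff = effective_n(realized, len(kept))
    if n_eff < neff_floor:
        warnings.warn(
            f"balanced subset n_eff={n_eff:.0f} below floor {neff_floor:.0f}; "
            "LDSC on this subset may be unstable",
            UserWarning,
            stacklevel=2,
        )
    return kept


def effective_n(v: float, n: float) -> float:
    """Balanced-design-equivalent sample size ``4*v*(1-v)*n`` of one cohort."""
    if not 0.0 < v < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    if n <= 0:
        raise ValueError("sample size must be positive")
    return 4.0 * v * (1.0 - v) * n


def effective_n_sum(cohorts: Sequence[tuple[float, float]]) -> float:
    """Sum of per-cohort effective sample sizes over (prevalence, n) pairs."""
    return float(sum(effective_n(v, n) for v, n in cohorts))


def person_mean_rescale(items: np.ndarray, min_items: int | None = None) -> np.ndarray:
    """Sum score with person-mean imputation for partially missing item sets.

    For each row, the mean of answered items is multiplied by the number of
    items; rows answering fewer than ``min_items`` (default: 3/4 of the item
    count) are set to NaN.
    """
    items = np.asarray(items, dtype=float)
    n_items = items.shape[1]
    if min_items is None:
        min_items = int(np.ceil(0.75 * n_items))
    answered = (~np.isnan(items)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        score = np.nanmean(items, axis=1) * n_items
    score[answered < min_items] = np.nan
    return score
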