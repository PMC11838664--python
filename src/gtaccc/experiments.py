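"""Reference experiment recipes at desk scale.

These bundle the simulation architecture and analysis settings used by the
validation experiments: a severity-gradient cohort (two genetic factors,
item mixing shifting from the low to the high factor with severity rank,
an ascertained disorder loading on the high factor) analysed by the full
binarize -> GWAS -> multivariate LDSC -> GLS/SEM pipeline.

The scale is chosen so that per-variant association signal sits in the
regime LD score regression is designed for (mean chi-square of a few), the
genetic-correlation estimator is approximately unbiased, and a single
replicate runs in tens of seconds on one CPU.
"""

from __future__ import annotations

from typing import Any

import numpy as np

from .pipeline import analyze_cohort
from .simulate import (
    Cohort,
    TruthRecord,
    simulate_disorder,
    simulate_genotypes,
    simulate_item_phenotypes,
    thresholds_from_prevalence,
)

#: desk-scale defaults of the gradient-detection experiment
GRADIENT_SCALE: dict[str, Any] = {
    "n_ind": 20_000,
    "n_var": 3_600,
    "block_size": 20,
    "ld_r": (0.2, 0.95),
    "maf_range": (0.05, 0.5),
    "n_items": 12,
    "h2": 0.75,
    "weight_steepness": 12.0,
    "endorse_range": (0.72, 0.28),
    "b_low": 0.0,
    "b_high": 0.9,
    "K": 0.15,
    "n_blocks": 120,
    "ld_window": 20,
}


def steep_mixing_weights(n_items: int, steepness: float) -> np.ndarray:
    """Logistic-in-rank mixing weights rescaled to span [0, 1] exactly."""
    lin = np.arange(n_items) / (n_items - 1)
    w = 1.0 / (1.0 + np.exp(-steepness * (lin - 0.5)))
    return (w - w.min()) / (w.max() - w.min())


def gradient_cohort(seed: int, rg_fact: float = 0.6, **overrides) -> Cohort:
    """Simulate one severity-gradient cohort at the reference scale.

    ``rg_fact = 1`` is the single-liability null (no differentiation);
    lower values plant a genuine severity gradient.
    """
    cfg = {**GRADIENT_SCALE, **overrides}
    panel = simulate_genotypes(
        n_ind=cfg["n_ind"],
        n_var=cfg["n_var"],
        n_blocks=cfg["n_var"] // cfg["block_size"],
        r=cfg["ld_r"],
        maf_range=cfg["maf_range"],
        seed=seed,
    )
    n_items = cfg["n_items"]
    endorse = np.linspace(*cfg["endorse_range"], n_items)
    truth = TruthRecord(
        h2_low=cfg["h2"],
        h2_high=cfg["h2"],
        rg_fact=rg_fact,
        weights=list(steep_mixing_weights(n_items, cfg["weight_steepness"])),
        thresholds=list(thresholds_from_prevalence(endorse)),
        seed=seed + 1,
    )
    cohort = simulate_item_phenotypes(panel, truth, n_items)
    return simulate_disorder(
        cohort, cfg["b_low"], cfg["b_high"], cfg["K"], seed=seed + 2
    )


def gradient_replicate(seed: int, rg_fact: float = 0.6, **overrides) -> dict[str, Any]:
    """One full replicate: simulate and analyse; returns analyze_cohort output."""
    cfg = {**GRADIENT_SCALE, **overrides}
    cohort = gradient_cohort(seed, rg_fact, **overrides)
    return analyze_cohort(
        cohort, n_blocks=cfg["n_blocks"], ld_window=cfg["ld_window"]
    )
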