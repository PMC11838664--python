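"""End-to-end orchestration: simulate -> binarize -> GWAS -> LDSC -> GLS/SEM.

``run_pipeline`` reads a single YAML config, runs every stage, and writes
all artifacts plus a manifest (seeds, config hash, stage status) into the
run directory.  Completed stages are skipped on rerun when their outputs
exist and the config hash matches.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import gls as gls_mod
from . import sem as sem_mod
from .gwas import assoc_scan, assoc_scan_batch
from .ldsc import (
    GeneticCovStruct,
    LDScoreTable,
    compute_ld_scores,
    liability_convert,
    multivariate_ldsc,
)
from .severity import SeverityMap, binarize_scores
from .simulate import (
    Cohort,
    TruthRecord,
    default_mixing_weights,
    simulate_disorder,
    simulate_genotypes,
    simulate_item_phenotypes,
    write_cohort,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "n_blocks": 120,
    "ld_window": 20,
    "matrix": "R",                 # "R" (standardized S, delta-method V) or "S"
    "quadratic": False,
    "factors": [1, 2],
    "simulate": {
        "n_ind": 20_000,
        "n_var": 3_600,
        "ld_blocks": 180,
        "ld_r": [0.2, 0.95],
        "maf_range": [0.05, 0.5],
        "n_items": 12,
        "h2_low": 0.75,
        "h2_high": 0.75,
        "rg_fact": 0.6,
        "item_prev_range": [0.72, 0.28],
        "weight_steepness": 12.0,   # null -> linear mixing weights
        "disorder": {"b_low": 0.0, "b_high": 0.9, "K": 0.15, "P_target": None},
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


@dataclass
class RunConfig:
    outdir: Path
    options: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        out = Path(outdir) if outdir else Path(raw.get("outdir", "gtaccc_run"))
        return cls(outdir=out, options=_merge(DEFAULT_CONFIG, raw))

    @classmethod
    def from_dict(cls, options: dict, outdir: str | Path) -> "RunConfig":
        return cls(outdir=Path(outdir), options=_merge(DEFAULT_CONFIG, options))

    def hash(self) -> str:
        blob = json.dumps(self.options, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def simulate_cohort_from_config(sim_cfg: dict, seed: int) -> Cohort:
    """Build a full cohort (items + disorder) from the ``simulate`` block."""
    n_items = sim_cfg["n_items"]
    ld_r = sim_cfg["ld_r"]
    panel = simulate_genotypes(
        n_ind=sim_cfg["n_ind"],
        n_var=sim_cfg["n_var"],
        n_blocks=sim_cfg["ld_blocks"],
        r=tuple(ld_r) if isinstance(ld_r, (list, tuple)) else ld_r,
        maf_range=tuple(sim_cfg["maf_range"]),
        seed=seed,
    )
    p_hi, p_lo = sim_cfg["item_prev_range"]
    endorse = np.linspace(p_hi, p_lo, n_items)
    from .simulate import thresholds_from_prevalence

    steep = sim_cfg.get("weight_steepness")
    if steep:
        from .experiments import steep_mixing_weights

        weights = steep_mixing_weights(n_items, float(steep))
    else:
        weights = default_mixing_weights(n_items)
    truth = TruthRecord(
        h2_low=sim_cfg["h2_low"],
        h2_high=sim_cfg["h2_high"],
        rg_fact=sim_cfg["rg_fact"],
        weights=list(weights),
        thresholds=list(thresholds_from_prevalence(endorse)),
        seed=seed + 1,
    )
    cohort = simulate_item_phenotypes(panel, truth, n_items)
    dis = sim_cfg.get("disorder")
    if dis:
        cohort = simulate_disorder(
            cohort,
            b_low=dis["b_low"],
            b_high=dis["b_high"],
            K=dis["K"],
            P_target=dis.get("P_target"),
            seed=seed + 2,
        )
    return cohort


def analyze_cohort(
    cohort: Cohort,
    cuts: list[float] | None = None,
    n_blocks: int = 100,
    ld_window: int = 50,
    quadratic: bool = False,
    use_R: bool = True,
    precomputed_ld: LDScoreTable | None = None,
) -> dict[str, Any]:
    """Binarize, scan, estimate (S, V) and run the GLS severity analyses.

    Returns a dict with the severity map, the covariance structure and the
    trend/decay fits.  This is the in-memory core reused by the CLI
    pipeline, tests and the acceptance experiments.
    """
    if cuts is None:
        cuts = list(range(1, cohort.n_items + 1))
    binary, sev = binarize_scores(cohort.sum_score, cuts)

    ld = precomputed_ld or compute_ld_scores(cohort.panel, window=ld_window)
    traits = assoc_scan_batch(
        cohort.panel, binary, [f"cut{kidx + 1}" for kidx in range(binary.shape[1])]
    )
    external = None
    if cohort.disorder is not None:
        external = assoc_scan(
            cohort.panel,
            cohort.disorder.astype(float),
            trait_id="disorder",
            subset=cohort.sample_index,
            pop_prev=cohort.truth.pop_prev,
        )
        traits.append(external)

    struct = multivariate_ldsc(traits, ld, n_blocks=n_blocks)
    out: dict[str, Any] = {"severity": sev, "struct": struct, "ld": ld}

    if external is not None and struct.R is not None:
        out["trend"] = gls_mod.severity_trend_test(
            struct, sev, "disorder", quadratic=quadratic, use_R=use_R
        )
    if struct.R is not None:
        out["decay"] = gls_mod.decay_test(
            struct, sev, cut_traits=[f"cut{i + 1}" for i in range(binary.shape[1])],
            use_R=use_R,
        )
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage, writing artifacts and a manifest under ``config.outdir``."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    opts = config.options
    seed = int(opts["seed"])
    cfg_hash = config.hash()

    manifest_path = outdir / "manifest.json"
    manifest: dict[str, Any] = {"config_hash": cfg_hash, "seed": seed, "stages": {}}
    if manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") == cfg_hash:
            manifest = prev

    def stage_done(name: str, *paths: Path) -> bool:
        return manifest["stages"].get(name, {}).get("status") == "done" and all(
            p.exists() for p in paths
        )

    def mark(name: str, **extra) -> None:
        manifest["stages"][name] = {"status": "done", "time": time.time(), **extra}
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str))

    sim_cfg = opts.get("simulate")
    if sim_cfg is None:
        raise ValueError("config has no 'simulate' block and no precomputed inputs")

    cohort_dir = outdir / "cohort"
    if stage_done("simulate", cohort_dir / "phenotypes.tsv"):
        logger.info("simulate: skipped (up to date)")
        cohort = _read_cohort(cohort_dir)
    else:
        cohort = simulate_cohort_from_config(sim_cfg, seed)
        write_cohort(cohort, cohort_dir)
        mark("simulate")

    results = analyze_cohort(
        cohort,
        n_blocks=int(opts["n_blocks"]),
        ld_window=int(opts["ld_window"]),
        quadratic=bool(opts["quadratic"]),
        use_R=opts["matrix"] == "R",
    )

    sev: SeverityMap = results["severity"]
    if not stage_done("binarize", outdir / "severity.tsv"):
        sev.write(outdir / "severity.tsv")
        mark("binarize")

    struct: GeneticCovStruct = results["struct"]
    if not stage_done("ldsc", outdir / "covstruct" / "S.tsv"):
        results["ld"].write(outdir / "ldscores.tsv")
        struct.write(outdir / "covstruct")
        mark("ldsc")

    if "trend" in results and not stage_done("gls_trend", outdir / "gls_trend.json"):
        results["trend"].to_json(outdir / "gls_trend.json")
        mark("gls_trend")
    if "decay" in results and not stage_done("gls_decay", outdir / "gls_decay.json"):
        results["decay"].to_json(outdir / "gls_decay.json")
        mark("gls_decay")

    if struct.R is not None:
        external = ["disorder"] if cohort.disorder is not None else []
        k_cuts = cohort.n_items
        for nf in opts["factors"]:
            name = f"sem_{nf}factor"
            path = outdir / f"{name}.json"
            if stage_done(name, path):
                continue
            spec = sem_mod.build_severity_factor_model(k_cuts, nf, external)
            fit = sem_mod.sem_fit_dwls(spec, struct, seed=seed)
            fit.to_json(path)
            mark(name, aic=fit.aic)

    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return outdir


def _read_cohort(cohort_dir: Path) -> Cohort:
    import pandas as pd

    from .simulate import GenoPanel

    npz = np.load(cohort_dir / "panel.npz", allow_pickle=False)
    panel = GenoPanel(
        dosage=npz["dosage"],
        maf=npz["maf"],
        block=npz["block"],
        r=np.atleast_1d(npz["r"]),
        snp=npz["snp"],
        chrom=npz["chrom"],
        pos=npz["pos"],
    )
    pheno = pd.read_csv(cohort_dir / "phenotypes.tsv", sep="\t")
    truth = TruthRecord.from_json(cohort_dir / "truth.json")
    item_cols = [c for c in pheno.columns if c.startswith("item")]
    idx_path = cohort_dir / "ascertained_index.txt"
    cohort = Cohort(
        panel=panel,
        f_low=np.zeros(panel.n_ind),
        f_high=np.zeros(panel.n_ind),
        items=pheno[item_cols].to_numpy(dtype=np.int8),
        sum_score=pheno["sumscore"].to_numpy(dtype=float),
        truth=truth,
        disorder=pheno["disorder"].to_numpy(dtype=np.int8) if "disorder" in pheno else None,
        sample_index=np.loadtxt(idx_path, dtype=int) if idx_path.exists() else None,
    )
    return cohort
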